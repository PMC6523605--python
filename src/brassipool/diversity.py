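"""Population diversity statistics and neighbor-joining clustering.

Implements the summary statistics usually reported for multi-allelic marker
panels — mean alleles per locus, Nei gene diversity (expected
heterozygosity, 1 − Σ p_i²), observed heterozygosity — per subpopulation and
per genome partition, pairwise Nei (1972) standard genetic distance (the
1983 D_A distance is switchable), and Saitou–Nei neighbor joining on the
resulting distance matrix.

Gene diversity uses the plain (biased) estimator 1 − Σ p̂², the common
PowerMarker default; the small-sample correction n/(n−1)·(1 − Σ p̂²) is
available as an option. Individual-level trees treat each accession as a
population of one diploid sample (frequencies in {0, 0.5, 1}).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import ConfigurationError, GenotypeMatrix, SchemaError, logger

FreqTable = dict[str, "pd.Series"]   # locus -> allele frequencies


# ---------------------------------------------------------------------------
# frequencies and per-locus statistics
# ---------------------------------------------------------------------------

def allele_frequencies(genotypes: GenotypeMatrix,
                       subset: list[str] | None = None) -> FreqTable:
    """Per-locus allele frequencies over a sample subset.

    Missing cells are excluded from the denominators; loci at which every
    subset sample is missing are omitted (undefined). Each returned Series
    sums to 1 over observed alleles.
    """
    gm = genotypes if subset is None else genotypes.subset_samples(subset)
    if not gm.samples:
        raise SchemaError("empty sample subset")
    d = gm.data
    obs = d[d["allele1"].notna()]
    if obs.empty:
        return {}
    melted = pd.concat([
        obs[["locus", "allele1"]].rename(columns={"allele1": "allele"}),
        obs[["locus", "allele2"]].rename(columns={"allele2": "allele"}),
    ])
    counts = melted.groupby(["locus", "allele"]).size()
    out: FreqTable = {}
    for locus, sub in counts.groupby(level=0):
        s = sub.droplevel(0).astype(float)
        out[str(locus)] = s / s.sum()
    return out


def gene_diversity(freqs: FreqTable | pd.Series, *,
                   unbiased_n: dict[str, int] | None = None) -> tuple[pd.Series, float]:
    """Nei gene diversity D = 1 − Σ p_i² per locus, and its unweighted mean.

    Accepts a single frequency Series (returned as a one-locus table) or a
    locus -> Series mapping. With ``unbiased_n`` (locus -> number of sampled
    gene copies) the small-sample correction n/(n−1) is applied.
    """
    if isinstance(freqs, pd.Series):
        freqs = {"locus": freqs}
    vals = {}
    for locus, p in freqs.items():
        arr = np.asarray(p, float)
        if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-6:
            raise ConfigurationError(f"{locus}: frequencies must sum to 1")
        d = 1.0 - float(np.sum(arr ** 2))
        if unbiased_n is not None:
            n = unbiased_n[locus]
            d *= n / (n - 1)
        vals[locus] = d
    per_locus = pd.Series(vals, dtype=float)
    return per_locus, float(per_locus.mean()) if len(per_locus) else float("nan")


def alleles_per_locus(freqs: FreqTable) -> tuple[pd.Series, float]:
    per_locus = pd.Series({l: float(len(p)) for l, p in freqs.items()}, dtype=float)
    return per_locus, float(per_locus.mean()) if len(per_locus) else float("nan")


def observed_heterozygosity(genotypes: GenotypeMatrix,
                            subset: list[str] | None = None
                            ) -> tuple[pd.Series, float]:
    """Per-locus fraction of non-missing samples with two different alleles."""
    gm = genotypes if subset is None else genotypes.subset_samples(subset)
    if not gm.samples:
        raise SchemaError("empty sample subset")
    d = gm.data
    obs = d[d["allele1"].notna()]
    het = (obs["allele1"] != obs["allele2"]).groupby(obs["locus"]).mean()
    per_locus = het.astype(float)
    per_locus.index = per_locus.index.astype(str)
    return per_locus, float(per_locus.mean()) if len(per_locus) else float("nan")


# ---------------------------------------------------------------------------
# genetic distance
# ---------------------------------------------------------------------------

def nei_distance(freqs_x: FreqTable, freqs_y: FreqTable, *,
                 method: str = "nei1972", max_distance: float = 10.0) -> float:
    """Genetic distance between two allele-frequency tables.

    ``nei1972`` is Nei's standard distance
    D = −ln( Σ_l Σ_i p_xi p_yi / sqrt(Σ_l Σ p_xi² · Σ_l Σ p_yi²) ),
    computed over the loci defined in both tables. ``da1983`` is Nei's D_A,
    1 − (1/L) Σ_l Σ_i sqrt(p_xi p_yi). Zero shared identity (including the
    degenerate case of no co-defined loci, e.g. populations carrying disjoint
    subgenomes) would be an infinite 1972 distance; it is capped at
    ``max_distance`` with a warning.
    """
    shared = sorted(set(freqs_x) & set(freqs_y))
    if not shared:
        warnings.warn("no co-defined loci; distance capped", RuntimeWarning,
                      stacklevel=2)
        return max_distance
    if method == "nei1972":
        jxy = jx = jy = 0.0
        for locus in shared:
            px, py = freqs_x[locus], freqs_y[locus]
            alleles = px.index.union(py.index)
            ax = px.reindex(alleles, fill_value=0.0).to_numpy(float)
            ay = py.reindex(alleles, fill_value=0.0).to_numpy(float)
            jxy += float(ax @ ay)
            jx += float(ax @ ax)
            jy += float(ay @ ay)
        identity = jxy / np.sqrt(jx * jy)
        if identity <= np.exp(-max_distance):
            warnings.warn("zero/near-zero shared identity; distance capped",
                          RuntimeWarning, stacklevel=2)
            return max_distance
        return float(-np.log(identity))
    if method == "da1983":
        total = 0.0
        for locus in shared:
            px, py = freqs_x[locus], freqs_y[locus]
            alleles = px.index.union(py.index)
            ax = px.reindex(alleles, fill_value=0.0).to_numpy(float)
            ay = py.reindex(alleles, fill_value=0.0).to_numpy(float)
            total += float(np.sum(np.sqrt(ax * ay)))
        return 1.0 - total / len(shared)
    raise ConfigurationError(f"unknown distance method {method!r}")


def individual_frequencies(genotypes: GenotypeMatrix,
                           sample: str) -> FreqTable:
    """Treat one diploid accession as a population (frequencies 0/0.5/1)."""
    return allele_frequencies(genotypes, [sample])


def distance_matrix(freq_tables: dict[str, FreqTable], *,
                    method: str = "nei1972",
                    max_distance: float = 10.0) -> pd.DataFrame:
    names = list(freq_tables)
    n = len(names)
    mat = np.zeros((n, n), float)
    for i, j in itertools.combinations(range(n), 2):
        d = nei_distance(freq_tables[names[i]], freq_tables[names[j]],
                         method=method, max_distance=max_distance)
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=names, columns=names)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def build_nj_tree(dist: pd.DataFrame, labels: list[str] | None = None) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted scikit-bio TreeNode.

    The input must be a symmetric matrix with zero diagonal and n >= 3 taxa.
    Q-matrix ties are broken toward the lexicographically smallest pair of
    clade labels (the smallest leaf name in each clade), making output
    deterministic. The final three nodes are joined to one internal node with
    closed-form branch lengths, so additive matrices are recovered exactly.
    """
    d = np.asarray(dist, float)
    if labels is None:
        labels = [str(x) for x in dist.index]
    n = len(labels)
    if d.shape != (n, n):
        raise SchemaError("distance matrix shape does not match labels")
    if n < 3:
        raise SchemaError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise SchemaError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise SchemaError("distance matrix diagonal must be zero")

    nodes = [TreeNode(name=lab) for lab in labels]
    tie_key = list(labels)            # smallest leaf label within each clade
    d = d.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        pairs = sorted(
            ((tuple(sorted((tie_key[i], tie_key[j]))), (i, j))
             for i, j in ties if i < j))
        i, j = pairs[0][1]
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(float(li), 0.0)
        nodes[j].length = max(float(lj), 0.0)
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.empty((m - 1, m - 1), float)
        d_next[:-1, :-1] = d[np.ix_(keep, keep)]
        d_next[-1, :-1] = dnew[keep]
        d_next[:-1, -1] = dnew[keep]
        d_next[-1, -1] = 0.0
        new_key = min(tie_key[i], tie_key[j])
        nodes = [nodes[k] for k in keep] + [parent]
        tie_key = [tie_key[k] for k in keep] + [new_key]
        d = d_next

    # closed-form star resolution of the last three nodes
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = max(float(length), 0.0)
    root = TreeNode(children=list(nodes))
    return root


# ---------------------------------------------------------------------------
# Table-1-shaped summary
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    table: pd.DataFrame            # one row per (partition, population)
    metadata: dict


def _partition_loci(genotypes: GenotypeMatrix,
                    locus_partition: pd.Series | None) -> dict[str, list[str]]:
    """Whole / A / C locus sets. A/B-classified loci are counted with A."""
    loci = genotypes.loci
    parts = {"whole": list(loci)}
    if locus_partition is None and genotypes.locus_info is not None:
        locus_partition = genotypes.locus_info["genome"]
    if locus_partition is not None:
        genome = locus_partition.reindex(loci)
        a_like = genome.isin(["A", "A/B", "AB"])
        parts["A"] = [l for l, keep in zip(loci, a_like) if keep]
        parts["C"] = [l for l in loci if genome.get(l) == "C"]
    return parts


def diversity_summary(genotypes: GenotypeMatrix, groups: dict[str, list[str]], *,
                      locus_partition: pd.Series | None = None,
                      reference_group: str | None = None,
                      method: str = "nei1972") -> DiversitySummary:
    """Per-subpopulation, per-partition diversity table.

    ``groups`` maps subpopulation name -> sample ids. For each subpopulation
    and partition (whole genome / A loci / C loci) the table reports the mean
    alleles per locus, mean gene diversity, mean observed heterozygosity, the
    within-population range of pairwise individual-level distances and, if a
    ``reference_group`` is given, the range of cross-population individual
    distances against it (all cross pairs).
    """
    parts = _partition_loci(genotypes, locus_partition)
    ind_freqs = {s: individual_frequencies(genotypes, s) for s in genotypes.samples}
    rows = []
    for part_name, loci in parts.items():
        sub = genotypes.subset_loci(loci)
        part_ind_freqs = {
            s: {l: p for l, p in ind_freqs[s].items() if l in set(loci)}
            for s in genotypes.samples}
        for pop_name, samples in groups.items():
            freqs = allele_frequencies(sub, samples)
            _, apl = alleles_per_locus(freqs)
            _, gd = gene_diversity(freqs)
            _, het = observed_heterozygosity(sub, samples)
            within = _pair_distances(part_ind_freqs, samples, samples, method)
            row = {
                "partition": part_name, "population": pop_name,
                "n_samples": len(samples), "n_loci": len(freqs),
                "alleles_per_locus": apl, "gene_diversity": gd,
                "heterozygosity": het,
                "dist_within_min": within[0], "dist_within_max": within[1],
            }
            if reference_group is not None and pop_name != reference_group:
                cross = _pair_distances(part_ind_freqs, samples,
                                        groups[reference_group], method)
                row["dist_vs_ref_min"], row["dist_vs_ref_max"] = cross
            rows.append(row)
    table = pd.DataFrame(rows)
    meta = {"distance_method": method,
            "individual_distance": "each accession treated as a population of "
                                   "one diploid sample (frequencies 0/0.5/1)",
            "reference_group": reference_group}
    return DiversitySummary(table, meta)


def _pair_distances(ind_freqs: dict[str, FreqTable], xs: list[str],
                    ys: list[str], method: str) -> tuple[float, float]:
    vals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for x in xs:
            for y in ys:
                if x >= y and ys is xs:
                    continue
                if x == y:
                    continue
                fx, fy = ind_freqs[x], ind_freqs[y]
                if not (set(fx) & set(fy)):
                    continue
                vals.append(nei_distance(fx, fy, method=method))
    if not vals:
        return (float("nan"), float("nan"))
    return (float(min(vals)), float(max(vals)))


def accession_tree(genotypes: GenotypeMatrix, *, method: str = "nei1972",
                   max_distance: float = 10.0) -> TreeNode:
    """Individual-level NJ tree over all accessions of a genotype matrix."""
    freqs = {s: individual_frequencies(genotypes, s) for s in genotypes.samples}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dist = distance_matrix(freqs, method=method, max_distance=max_distance)
    logger.info("accession tree over %d samples", len(dist))
    return build_nj_tree(dist)
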