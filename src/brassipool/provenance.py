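"""Locus-to-genome assignment and allele-origin classification.

Multi-allelic markers in an interspecific *Brassica* gene pool may amplify
loci from more than one basic genome. Which genome(s) a marker interrogates
is decided jointly from the alignment hits of its primers and from which
reference taxa its alleles appear in:

(i)   alleles seen only in *B. napus* and/or *B. carinata*, marker aligned to
      the C genome -> one C-genome-specific locus;
(ii)  alleles seen only in *B. napus* and/or *B. rapa*, aligned to the A
      genome -> one A-genome-specific locus;
(iii) alleles split into a napus/carinata group and a napus/rapa group, with
      hits on both C and A -> the marker amplifies a C locus and an A locus;
(iv)  alleles seen across all three taxa, hits on A and B -> an A/B-specific
      locus pair (the carinata alleles enter via the homoeologous B locus).

Patterns matching none of the rules are returned *unassigned* with a reason;
contradictory evidence (e.g. rapa-only alleles with only C-genome hits) is
flagged as a conflict rather than silently assigned.

Given an assigned locus, each allele gets exactly one origin label: private
to one reference taxon (Ar/An on A loci, Cc/Cn on C loci, Bc on B loci),
``shared`` when observed in two or more reference taxa, or ``novel`` when it
appears only in the derived (new-type) samples. The new-type samples never
contribute to reference presence.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import GenotypeMatrix, SchemaError, logger
from .simulate import NEW_TYPE, TAXA

ORIGIN_LABELS = ("Ar_specific", "An_specific", "Cc_specific", "Cn_specific",
                 "Bc_specific", "shared", "novel")
#: labels that mark introgression from a parental species
PARENTAL_SPECIFIC = ("Ar_specific", "Cc_specific", "Bc_specific")

REFERENCE_GROUPS = ("B_rapa", "B_carinata", "T_napus")


@dataclass(frozen=True)
class Hit:
    """One alignment hit of a marker against a reference genome."""

    genome: str
    chrom: str
    pos: int
    reference: str = "napus_AC"


@dataclass
class PresencePattern:
    """Observed evidence for one marker.

    ``alleles`` maps each allele symbol to the set of groups it was seen in
    (a subset of B_rapa / B_carinata / T_napus / new_type); ``hits`` are the
    marker's alignment hits.
    """

    marker: str
    alleles: dict[str, frozenset[str]]
    hits: tuple[Hit, ...]

    def __post_init__(self):
        if not self.alleles:
            raise SchemaError(f"{self.marker}: pattern has no alleles")
        for a, groups in self.alleles.items():
            if not groups:
                raise SchemaError(f"{self.marker}/{a}: allele observed nowhere")
            unknown = set(groups) - set(REFERENCE_GROUPS) - {NEW_TYPE}
            if unknown:
                raise SchemaError(f"{self.marker}/{a}: unknown groups {unknown}")

    def reference_taxa(self) -> set[str]:
        out: set[str] = set()
        for groups in self.alleles.values():
            out |= set(groups) & set(REFERENCE_GROUPS)
        return out

    def hit_genomes(self) -> set[str]:
        return {h.genome for h in self.hits}


@dataclass(frozen=True)
class LocusAssignment:
    marker: str
    genome: str          # 'A' / 'B' / 'C', or '' for unassigned/conflict
    rule: str            # 'i' | 'ii' | 'iii' | 'iv' | 'unassigned' | 'conflict'
    reason: str = ""


def assign_locus_genome(pattern: PresencePattern) -> list[LocusAssignment]:
    """Apply the four assignment rules to one marker's presence pattern.

    Returns one assignment per amplified locus; unmatched or contradictory
    patterns yield a single 'unassigned'/'conflict' entry carrying the reason.
    """
    if not pattern.hits:
        raise SchemaError(f"{pattern.marker}: pattern has no alignment hits")
    m = pattern.marker
    taxa = pattern.reference_taxa()
    genomes = pattern.hit_genomes()
    rapa, cari, napus = ("B_rapa" in taxa, "B_carinata" in taxa, "T_napus" in taxa)

    if not taxa:
        return [LocusAssignment(m, "", "unassigned",
                                "alleles observed only in new-type samples")]

    # rule (iv): all three taxa detected, aligned to A and B
    if rapa and cari and napus and {"A", "B"} <= genomes:
        return [LocusAssignment(m, "A", "iv"), LocusAssignment(m, "B", "iv")]

    # rule (iii): a napus/carinata group and a napus/rapa group, hits on C and A
    if rapa and cari and {"A", "C"} <= genomes:
        mixed = [a for a, g in pattern.alleles.items()
                 if "B_rapa" in g and "B_carinata" in g]
        if not mixed:
            return [LocusAssignment(m, "C", "iii"), LocusAssignment(m, "A", "iii")]
        return [LocusAssignment(m, "", "conflict",
                                f"alleles {sorted(mixed)} present in both diploid "
                                "parents but no A+B alignment")]

    # rule (i): no rapa presence, C alignment
    if not rapa and "C" in genomes:
        return [LocusAssignment(m, "C", "i")]

    # rule (ii): no carinata presence, A alignment
    if not cari and "A" in genomes:
        return [LocusAssignment(m, "A", "ii")]

    # contradictions: presence requires a genome the hits do not support
    if rapa and not ({"A"} & genomes):
        return [LocusAssignment(m, "", "conflict",
                                "B. rapa alleles but no A-genome alignment")]
    if cari and not ({"B", "C"} & genomes):
        return [LocusAssignment(m, "", "conflict",
                                "B. carinata alleles but no B/C-genome alignment")]
    return [LocusAssignment(m, "", "unassigned",
                            f"presence {sorted(taxa)} with hits {sorted(genomes)} "
                            "matches no rule")]


def classify_allele_origin(assignments: list[LocusAssignment],
                           pattern: PresencePattern) -> dict[str, str]:
    """One origin label per allele, given the marker's locus assignments.

    Requires at least one assigned (non-conflict) locus. Alleles present only
    in new-type samples are ``novel``; alleles present in two or more
    reference taxa are ``shared``; single-taxon alleles map through the locus
    genome (rapa -> Ar on A; carinata -> Cc on C or Bc on B; napus -> An/Cn).
    At dual A+C markers a napus-only allele is designated to the A locus.
    """
    genomes = sorted({a.genome for a in assignments if a.genome})
    if not genomes:
        raise SchemaError(f"{pattern.marker}: no assigned locus to classify against")
    out: dict[str, str] = {}
    for allele, groups in pattern.alleles.items():
        ref = set(groups) & set(REFERENCE_GROUPS)
        if not ref:
            out[allele] = "novel"
        elif len(ref) >= 2:
            out[allele] = "shared"
        else:
            (taxon,) = ref
            out[allele] = _single_taxon_label(taxon, genomes, pattern.marker, allele)
    return out


def _single_taxon_label(taxon: str, genomes: list[str], marker: str,
                        allele: str) -> str:
    if taxon == "B_rapa":
        if "A" in genomes:
            return "Ar_specific"
        raise SchemaError(f"{marker}/{allele}: rapa-only allele at non-A locus")
    if taxon == "B_carinata":
        if "C" in genomes:
            return "Cc_specific"
        if "B" in genomes:
            return "Bc_specific"
        raise SchemaError(f"{marker}/{allele}: carinata-only allele at A-only locus")
    # T_napus
    if genomes == ["C"]:
        return "Cn_specific"
    return "An_specific"    # A-only loci, and A-designation at dual-genome markers


# ---------------------------------------------------------------------------
# building patterns from genotype matrices
# ---------------------------------------------------------------------------

def build_presence_patterns(genotypes: GenotypeMatrix, hits: pd.DataFrame, *,
                            min_count: int = 1) -> dict[str, PresencePattern]:
    """Derive one presence pattern per marker from observed genotypes.

    Sample group membership comes from the matrix's ``taxon`` annotation;
    reference taxa are B_rapa / B_carinata / T_napus, everything labelled
    new_type contributes only to the new-type flag. An allele counts as
    present in a group when seen in at least ``min_count`` samples of it.
    ``hits`` is a frame with columns marker/reference/genome/chrom/pos.
    """
    if genotypes.sample_info is None:
        raise SchemaError("genotype matrix lacks sample taxon annotation")
    taxon = genotypes.sample_info["taxon"]
    d = genotypes.data
    counts: dict[tuple[str, str, str], int] = {}
    for sample, marker, a1, a2 in zip(d["sample"], d["marker"],
                                      d["allele1"], d["allele2"]):
        if a1 is None:
            continue
        group = taxon.get(sample, "unknown")
        if group not in REFERENCE_GROUPS and group != NEW_TYPE:
            continue
        for a in {a1, a2}:
            key = (marker, a, group)
            counts[key] = counts.get(key, 0) + 1
    alleles_by_marker: dict[str, dict[str, set[str]]] = {}
    for (marker, allele, group), n in counts.items():
        if n >= min_count:
            alleles_by_marker.setdefault(marker, {}).setdefault(allele, set()).add(group)
    hit_map: dict[str, list[Hit]] = {}
    for _, row in hits.iterrows():
        hit_map.setdefault(str(row["marker"]), []).append(
            Hit(str(row["genome"]), str(row["chrom"]), int(row["pos"]),
                str(row["reference"])))
    patterns = {}
    for marker, alleles in alleles_by_marker.items():
        patterns[marker] = PresencePattern(
            marker,
            {a: frozenset(g) for a, g in alleles.items()},
            tuple(hit_map.get(marker, ())))
    return patterns


def hits_from_marker_panel(marker_panel) -> pd.DataFrame:
    """Alignment-hit table implied by a simulated marker panel's locus defs."""
    rows = [(m.marker_id, l.source_ref, l.genome, l.chrom, l.pos)
            for m in marker_panel for l in m.loci]
    return pd.DataFrame(rows, columns=["marker", "reference", "genome",
                                       "chrom", "pos"])


def classify_genotypes(genotypes: GenotypeMatrix, hits: pd.DataFrame, *,
                       min_count: int = 1) -> pd.DataFrame:
    """Run assignment + classification over every marker of a genotype matrix.

    Returns a long frame (marker, locus_genome, rule, allele, origin, reason);
    markers without assignable loci keep empty origin and carry the reason.
    """
    patterns = build_presence_patterns(genotypes, hits, min_count=min_count)
    rows = []
    for marker in sorted(patterns):
        pattern = patterns[marker]
        if not pattern.hits:
            rows.append((marker, "", "unassigned", "", "",
                         "no alignment hits for marker"))
            continue
        assignments = assign_locus_genome(pattern)
        genomes = "/".join(a.genome for a in assignments if a.genome)
        rule = assignments[0].rule
        if not genomes:
            rows.append((marker, "", rule, "", "", assignments[0].reason))
            continue
        origins = classify_allele_origin(assignments, pattern)
        for allele in sorted(origins):
            rows.append((marker, genomes, rule, allele, origins[allele], ""))
    df = pd.DataFrame(rows, columns=["marker", "locus_genome", "rule",
                                     "allele", "origin", "reason"])
    n_bad = int((df["origin"] == "").sum())
    if n_bad:
        logger.info("classification: %d markers unassigned or in conflict", n_bad)
    return df


def summarize_introgressed_loci(genotypes: GenotypeMatrix,
                                classifications: pd.DataFrame) -> dict:
    """Tally parental-specific introgression over the detected loci.

    A locus (marker) counts as carrying specific introgression when at least
    one of its alleles is Ar/Cc/Bc-specific. Returns exact counts plus the
    specific-locus fraction of all detected loci, and per-origin allele
    counts.
    """
    detected = set(genotypes.markers)
    classified = set(classifications["marker"])
    uncovered = detected - classified
    if uncovered:
        raise SchemaError(
            f"classifications missing for {len(uncovered)} markers, "
            f"e.g. {sorted(uncovered)[:3]}")
    cls = classifications[classifications["marker"].isin(detected)
                          & (classifications["origin"] != "")]
    spec = cls[cls["origin"].isin(PARENTAL_SPECIFIC)]
    per_marker = spec.groupby("marker")["allele"].nunique()
    origin_counts = cls.groupby("origin")["allele"].count().to_dict()
    n_total = len(detected)
    n_specific = int((per_marker >= 1).sum())
    return {
        "total_loci": n_total,
        "specific_loci": n_specific,
        "specific_fraction": n_specific / n_total if n_total else 0.0,
        "multi_specific_loci": int((per_marker > 1).sum()),
        "alleles_per_origin": {k: int(v) for k, v in origin_counts.items()},
    }
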