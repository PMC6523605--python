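"""Forward simulation of a DGMS-mediated mass recurrent-selection scheme.

The simulator emulates the construction of a reconstituted *Brassica napus*
gene pool: three founder taxa (*B. rapa*, A genome; *B. carinata*, B + C
genomes; traditional *B. napus*, A + C genomes) contribute ancestral
haplotypes; two polymorphic interspecific subpopulations (Poly-Ar, mostly
exotic in the A subgenome; Poly-Cc, mostly exotic in C) form the base
population together with dominant-genic-male-sterile (DGMS, Msms) lines; the
population is then driven through rounds of random intercrossing (sterile
plants as seed parents, fertile plants as pollen donors) and truncation mass
selection on a weighted phenotype index of additive traits.

Genomes are diploidized: every line carries two homologues of each A and C
chromosome; B-genome material is modelled as hemizygous presence/absence
segments, since the derived lines are 2n = 38 AACC with only small B
introgressions. Crossovers per chromosome are Poisson with mean equal to the
chromosome map length in Morgans, positions uniform, no interference. Each
homologue is a mosaic of segments pointing at concrete ancestral haplotypes,
which is simultaneously the ancestry truth track and the source of marker
alleles, so truth and genotypes are consistent by construction.

All randomness flows through a single ``numpy.random.Generator`` derived from
an explicit seed; identical seeds give identical output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (ConfigurationError, GenotypeMatrix, LocusDef, MarkerDef,
                 SchemaError, logger)

TAXA = ("B_rapa", "B_carinata", "T_napus")
NEW_TYPE = "new_type"

#: which founder taxa carry each basic genome
GENOME_CARRIERS = {
    "A": ("B_rapa", "T_napus"),
    "C": ("B_carinata", "T_napus"),
    "B": ("B_carinata",),
}

#: subgenome-of-origin label for (taxon, genome)
ORIGIN_LABEL = {
    ("B_rapa", "A"): "Ar",
    ("T_napus", "A"): "An",
    ("B_carinata", "C"): "Cc",
    ("T_napus", "C"): "Cn",
    ("B_carinata", "B"): "Bc",
}

SOURCE_REF = {"A": "napus_AC", "C": "napus_AC", "B": "nigra_B"}


class SimulationError(Exception):
    """Raised when a breeding round cannot proceed (e.g. no parents left)."""


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    genome: str            # 'A', 'B' or 'C'
    length_bp: int
    map_length_m: float    # Morgans


@dataclass
class GenomeModel:
    """Chromosome complement plus marker positions (1-based bp)."""

    chromosomes: list[Chromosome]
    marker_positions: dict[str, list[int]]

    def __post_init__(self):
        counts = {"A": 0, "B": 0, "C": 0}
        for c in self.chromosomes:
            if c.genome not in counts:
                raise ConfigurationError(f"unknown genome {c.genome!r}")
            counts[c.genome] += 1
            if c.length_bp <= 0 or c.map_length_m <= 0:
                raise ConfigurationError(f"{c.name}: lengths must be positive")
        expected = {"A": 10, "B": 8, "C": 9}
        if counts != expected:
            raise ConfigurationError(
                f"chromosome counts {counts} != required {expected}")
        by_name = self.by_name
        for chrom, positions in self.marker_positions.items():
            if chrom not in by_name:
                raise ConfigurationError(f"marker positions on unknown chromosome {chrom}")
            arr = np.asarray(positions)
            if len(arr) and (np.any(np.diff(arr) <= 0) or arr[0] < 1
                             or arr[-1] > by_name[chrom].length_bp):
                raise ConfigurationError(
                    f"{chrom}: positions must be strictly increasing within the chromosome")

    @property
    def by_name(self) -> dict[str, Chromosome]:
        return {c.name: c for c in self.chromosomes}

    def chroms_of_genome(self, genome: str) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.genome == genome]

    def locus_defs(self) -> list[LocusDef]:
        """One LocusDef per marker position, id '<chrom>:<pos>'."""
        out = []
        for c in self.chromosomes:
            for pos in self.marker_positions.get(c.name, []):
                out.append(LocusDef(f"{c.name}:{pos}", c.genome, c.name,
                                    int(pos), SOURCE_REF[c.genome]))
        return out


def default_genome_model(n_markers: int = 500) -> GenomeModel:
    """A-genome 10 x 25 Mb, C 9 x 45 Mb, B 8 x 35 Mb; ~1.2-1.5 M maps.

    Markers are spread over chromosomes proportionally to physical length,
    evenly spaced within each chromosome.
    """
    chroms = (
        [Chromosome(f"A{i:02d}", "A", 25_000_000, 1.2) for i in range(1, 11)]
        + [Chromosome(f"C{i:02d}", "C", 45_000_000, 1.5) for i in range(1, 10)]
        + [Chromosome(f"B{i:02d}", "B", 35_000_000, 1.3) for i in range(1, 9)]
    )
    total = sum(c.length_bp for c in chroms)
    positions: dict[str, list[int]] = {}
    for c in chroms:
        k = max(2, round(n_markers * c.length_bp / total))
        positions[c.name] = [int(c.length_bp * (i + 0.5) / k) for i in range(k)]
    return GenomeModel(chroms, positions)


def make_marker_panel(genome_model: GenomeModel, *, frac_dual_ac: float = 0.08,
                      frac_ab: float = 0.04, seed: int = 0) -> list[MarkerDef]:
    """Bundle loci into SSR-style markers.

    Most markers amplify a single locus; a fraction amplify a homoeologous
    A+C locus pair, and a smaller fraction an A+B pair (the patterns that
    drive the dual-locus assignment rules).
    """
    rng = np.random.default_rng(seed)
    loci = genome_model.locus_defs()
    a = [l for l in loci if l.genome == "A"]
    c = [l for l in loci if l.genome == "C"]
    b = [l for l in loci if l.genome == "B"]
    n_ac = min(int(round(frac_dual_ac * len(a))), len(c))
    n_ab = min(int(round(frac_ab * len(a))), len(b))
    a_idx = rng.permutation(len(a))
    ac_a = [a[i] for i in a_idx[:n_ac]]
    ab_a = [a[i] for i in a_idx[n_ac:n_ac + n_ab]]
    single_a = [a[i] for i in a_idx[n_ac + n_ab:]]
    c_idx = rng.permutation(len(c))
    ac_c = [c[i] for i in c_idx[:n_ac]]
    single_c = [c[i] for i in c_idx[n_ac:]]
    b_idx = rng.permutation(len(b))
    ab_b = [b[i] for i in b_idx[:n_ab]]
    single_b = [b[i] for i in b_idx[n_ab:]]

    groups: list[tuple[LocusDef, ...]] = (
        [(x, y) for x, y in zip(ac_a, ac_c)]
        + [(x, y) for x, y in zip(ab_a, ab_b)]
        + [(l,) for l in single_a + single_c + single_b]
    )
    groups.sort(key=lambda g: (g[0].chrom, g[0].pos))
    return [MarkerDef(f"M{i + 1:04d}", tuple(g)) for i, g in enumerate(groups)]


# ---------------------------------------------------------------------------
# founder allele-frequency panel
# ---------------------------------------------------------------------------

@dataclass
class DiversityConfig:
    alleles_per_locus: tuple[int, int] = (2, 6)
    private_proportion: float = 0.25
    dirichlet_alpha: float = 2.0
    novel_rate: float = 0.005    # per-cell novel-allele probability in derived lines

    def validate(self):
        lo, hi = self.alleles_per_locus
        if lo < 1 or hi < lo:
            raise ConfigurationError("alleles_per_locus range invalid")
        if not 0 <= self.private_proportion <= 1:
            raise ConfigurationError("private_proportion must be in [0, 1]")
        if self.dirichlet_alpha <= 0:
            raise ConfigurationError("dirichlet_alpha must be positive")
        if not 0 <= self.novel_rate < 1:
            raise ConfigurationError("novel_rate must be in [0, 1)")


@dataclass
class FounderPanel:
    """Per taxon x locus allele-frequency tables plus the private-allele registry."""

    loci: list[LocusDef]
    freqs: dict[tuple[str, str], dict[str, float]]   # (taxon, locus_id) -> allele -> p
    private: dict[tuple[str, str], str]              # (locus_id, allele) -> owning taxon
    novel_rate: float = 0.005

    def __post_init__(self):
        for (taxon, locus), table in self.freqs.items():
            if not table:
                raise ConfigurationError(f"empty frequency table for {taxon}/{locus}")
            vals = np.array(list(table.values()), float)
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"frequencies for {taxon}/{locus} must be >=0 and sum to 1")
        # a private allele must have nonzero frequency in exactly one taxon
        for (locus, allele), owner in self.private.items():
            holders = [t for t in TAXA
                       if self.freqs.get((t, locus), {}).get(allele, 0.0) > 0]
            if holders != [owner]:
                raise ConfigurationError(
                    f"private allele {locus}/{allele} held by {holders}, owner {owner}")

    @property
    def locus_by_id(self) -> dict[str, LocusDef]:
        return {l.locus_id: l for l in self.loci}

    def alleles(self, locus_id: str) -> set[str]:
        out: set[str] = set()
        for t in TAXA:
            out |= set(self.freqs.get((t, locus_id), {}))
        return out


def make_founders(genome_model: GenomeModel, diversity_config: DiversityConfig,
                  seed: int) -> FounderPanel:
    """Draw taxon allele-frequency tables for every locus of the genome model.

    Each locus gets k alleles (uniform in the configured range, SSR-size-like
    symbols). An allele is made taxon-private with the configured probability
    and assigned to one uniformly drawn carrier of that genome; other alleles
    are shared by all carriers. Frequencies are Dirichlet. A carrier left with
    no allele receives one extra private allele so its table is never empty.
    """
    diversity_config.validate()
    rng = np.random.default_rng(seed)
    loci = genome_model.locus_defs()
    lo, hi = diversity_config.alleles_per_locus
    freqs: dict[tuple[str, str], dict[str, float]] = {}
    private: dict[tuple[str, str], str] = {}
    for locus in loci:
        carriers = GENOME_CARRIERS[locus.genome]
        k = int(rng.integers(lo, hi + 1))
        # fragment-size-like symbols; per-genome ranges keep the loci of a
        # dual-locus marker distinguishable, as SSR size classes are in practice
        size_range = {"A": (100, 180), "C": (200, 280), "B": (300, 380)}[locus.genome]
        base = int(rng.integers(*size_range))
        alleles = [str(base + 2 * j) for j in range(k)]
        owners: dict[str, str | None] = {}
        for a in alleles:
            if len(carriers) > 1 and rng.random() < diversity_config.private_proportion:
                owners[a] = str(rng.choice(carriers))
            elif len(carriers) == 1:
                owners[a] = carriers[0]   # single-carrier genome: all alleles private
            else:
                owners[a] = None
        for taxon in carriers:
            avail = [a for a in alleles if owners[a] in (None, taxon)]
            if not avail:
                extra = str(base + 2 * len(alleles))
                alleles.append(extra)
                owners[extra] = taxon
                avail = [extra]
            p = rng.dirichlet(np.full(len(avail), diversity_config.dirichlet_alpha))
            freqs[(taxon, locus.locus_id)] = dict(zip(avail, p.tolist()))
        for a, owner in owners.items():
            if owner is not None:
                private[(locus.locus_id, a)] = owner
    return FounderPanel(loci, freqs, private, diversity_config.novel_rate)


# ---------------------------------------------------------------------------
# ancestral haplotypes and individuals
# ---------------------------------------------------------------------------

@dataclass
class TraitSpec:
    name: str
    unit: str
    baseline: float
    n_qtl: int
    effect: float          # per favourable allele copy, in trait units
    h2: float
    weight: float          # sign encodes selection direction

    def validate(self):
        if not 0 < self.h2 <= 1:
            raise ConfigurationError(f"{self.name}: h2 must be in (0, 1]")
        if self.n_qtl < 1:
            raise ConfigurationError(f"{self.name}: n_qtl >= 1 required")


def default_traits() -> list[TraitSpec]:
    """Seed-quality and agronomic traits of an oilseed recurrent-selection scheme.

    Oil content (OC, %), erucic acid (EAC, %), glucosinolates (GSLC, umol/g)
    are seed-quality traits; erucic acid and glucosinolates are controlled by
    a few major loci (high heritability) and selected downward. Thousand-seed
    weight (TSW, g), pod density (PD, pods/cm) and seeds per pod (SN) are
    lower-heritability agronomic traits selected upward.
    """
    return [
        TraitSpec("OC", "%", 44.2, 10, 0.3, 0.4, 1.0),
        TraitSpec("EAC", "%", 9.4, 3, 2.8, 0.8, -1.0),
        TraitSpec("GSLC", "umol/g", 60.9, 4, 7.0, 0.8, -1.0),
        TraitSpec("TSW", "g", 3.5, 8, 0.15, 0.4, 0.5),
        TraitSpec("PD", "pods/cm", 1.0, 8, 0.06, 0.3, 0.5),
        TraitSpec("SN", "count", 20.0, 8, 0.6, 0.3, 0.5),
    ]


@dataclass
class BreedingScheme:
    """Parameters of the DGMS mass recurrent-selection design (desk scale)."""

    n_dgms: int = 20                   # Msms founder seed parents
    n_inbred_per_subpop: int = 40      # fertile founders per polymorphic subpopulation
    n_haplotypes_per_taxon: int = 40   # ancestral haplotype pool size
    n_rounds: int = 5
    round_size: int = 200
    selection_fraction: float = 0.3
    traits: list[TraitSpec] = field(default_factory=default_traits)
    # base-population mosaic composition: exotic fraction per subgenome
    poly_ar_exotic: tuple[float, float] = (0.75, 0.20)   # (A-genome, C-genome)
    poly_cc_exotic: tuple[float, float] = (0.20, 0.75)
    base_blocks_per_chrom: float = 3.0
    b_segment_prob: float = 0.25       # per B chromosome in base founders
    b_segment_len: tuple[int, int] = (1_000_000, 4_000_000)

    def validate(self):
        if not 0 < self.selection_fraction <= 1:
            raise ConfigurationError("selection_fraction must be in (0, 1]")
        if self.n_rounds < 0:
            raise ConfigurationError("n_rounds must be >= 0")
        if self.n_dgms < 1 or self.n_inbred_per_subpop < 1:
            raise ConfigurationError("founder counts must be >= 1")
        for t in self.traits:
            t.validate()


@dataclass
class AncestralHaplotype:
    hap_id: int
    taxon: str
    alleles: dict[str, str]            # locus_id -> allele symbol
    qtl_alleles: dict[str, np.ndarray]  # trait name -> 0/1 per QTL


#: one ancestry segment of a homologue: (start, end, hap_id), 1-based inclusive
Seg = tuple[int, int, int]


@dataclass
class Individual:
    ind_id: str
    taxon: str
    generation: int
    sterile: bool                       # Msms (True) vs msms (False)
    homologues: dict[str, tuple[list[Seg], list[Seg]]]   # A/C chromosomes
    b_segments: dict[str, list[Seg]]    # hemizygous B-genome material

    @property
    def dgms_genotype(self) -> tuple[str, str]:
        return ("Ms", "ms") if self.sterile else ("ms", "ms")


@dataclass
class Population:
    """A cohort plus everything needed to genotype it."""

    individuals: list[Individual]
    hap_pool: dict[int, AncestralHaplotype]
    founder_panel: FounderPanel
    genome_model: GenomeModel
    name: str = "population"

    def __len__(self) -> int:
        return len(self.individuals)

    def by_id(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.ind_id == ind_id:
                return ind
        raise SchemaError(f"unknown individual {ind_id}")


@dataclass
class SimulationResult:
    populations: list[Population]      # index 0 = base, i = selected after round i
    truth: pd.DataFrame                # ancestry truth track, all rounds
    trait_table: pd.DataFrame          # harvested sterile plants per round
    scheme: BreedingScheme

    @property
    def final(self) -> Population:
        return self.populations[-1]


# -- haplotype pool ---------------------------------------------------------

def make_haplotype_pool(panel: FounderPanel, scheme: BreedingScheme,
                        rng: np.random.Generator) -> dict[int, AncestralHaplotype]:
    pool: dict[int, AncestralHaplotype] = {}
    hap_id = 0
    for taxon in TAXA:
        genomes = [g for g, carriers in GENOME_CARRIERS.items() if taxon in carriers]
        loci = [l for l in panel.loci if l.genome in genomes]
        for _ in range(scheme.n_haplotypes_per_taxon):
            alleles = {}
            for l in loci:
                table = panel.freqs[(taxon, l.locus_id)]
                keys = list(table)
                alleles[l.locus_id] = str(rng.choice(keys, p=list(table.values())))
            qtl = {t.name: (rng.random(t.n_qtl) < 0.5).astype(np.int8)
                   for t in scheme.traits}
            pool[hap_id] = AncestralHaplotype(hap_id, taxon, alleles, qtl)
            hap_id += 1
    return pool


def _haps_of(pool: dict[int, AncestralHaplotype], taxon: str) -> list[int]:
    return [h for h, hap in pool.items() if hap.taxon == taxon]


# -- mosaic construction and meiosis ----------------------------------------

def _mosaic_homologue(chrom: Chromosome, taxon_probs: dict[str, float],
                      haps_by_taxon: dict[str, list[int]], blocks: float,
                      rng: np.random.Generator) -> list[Seg]:
    n_breaks = int(rng.poisson(blocks))
    cuts = np.sort(rng.integers(2, chrom.length_bp, size=n_breaks)) if n_breaks else []
    bounds = [1] + [int(c) for c in cuts] + [chrom.length_bp + 1]
    taxa = list(taxon_probs)
    probs = np.array([taxon_probs[t] for t in taxa], float)
    probs /= probs.sum()
    segs: list[Seg] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e <= s:
            continue
        taxon = taxa[int(rng.choice(len(taxa), p=probs))]
        hap = int(rng.choice(haps_by_taxon[taxon]))
        segs.append((s, e - 1, hap))
    return _coalesce(segs)


def _coalesce(segs: list[Seg]) -> list[Seg]:
    out: list[Seg] = []
    for s in segs:
        if out and out[-1][2] == s[2] and out[-1][1] + 1 == s[0]:
            out[-1] = (out[-1][0], s[1], s[2])
        else:
            out.append(tuple(s))
    return out


def _slice_segments(segs: list[Seg], start: int, end: int) -> list[Seg]:
    """Segments overlapping [start, end], clipped (1-based inclusive)."""
    out = []
    for s, e, h in segs:
        if e < start or s > end:
            continue
        out.append((max(s, start), min(e, end), h))
    return out


def recombine(hom0: list[Seg], hom1: list[Seg], chrom: Chromosome,
              rng: np.random.Generator) -> list[Seg]:
    """One meiotic product: Poisson(map length) crossovers, uniform positions."""
    n_x = int(rng.poisson(chrom.map_length_m))
    current = int(rng.integers(0, 2))
    if n_x == 0:
        return list((hom0, hom1)[current])
    cuts = np.sort(rng.integers(2, chrom.length_bp + 1, size=n_x))
    bounds = [1] + [int(c) for c in cuts] + [chrom.length_bp + 1]
    homs = (hom0, hom1)
    out: list[Seg] = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e > s:
            out.extend(_slice_segments(homs[current], s, e - 1))
        current = 1 - current
    return _coalesce(out)


def segment_at(segs: list[Seg], pos: int) -> int | None:
    """hap_id of the segment covering ``pos``, or None."""
    for s, e, h in segs:
        if s <= pos <= e:
            return h
    return None


# -- base population ---------------------------------------------------------

def _base_individual(ind_id: str, exotic: tuple[float, float], *, sterile: bool,
                     inbred: bool, genome_model: GenomeModel,
                     haps_by_taxon: dict[str, list[int]], scheme: BreedingScheme,
                     rng: np.random.Generator) -> Individual:
    pA, pC = exotic
    homologues: dict[str, tuple[list[Seg], list[Seg]]] = {}
    for chrom in genome_model.chromosomes:
        if chrom.genome == "B":
            continue
        if chrom.genome == "A":
            probs = {"B_rapa": pA, "T_napus": 1 - pA}
        else:
            probs = {"B_carinata": pC, "T_napus": 1 - pC}
        h0 = _mosaic_homologue(chrom, probs, haps_by_taxon,
                               scheme.base_blocks_per_chrom, rng)
        h1 = (list(h0) if inbred else
              _mosaic_homologue(chrom, probs, haps_by_taxon,
                                scheme.base_blocks_per_chrom, rng))
        homologues[chrom.name] = (list(h0), list(h1))
    b_segments: dict[str, list[Seg]] = {}
    lo, hi = scheme.b_segment_len
    for chrom in genome_model.chroms_of_genome("B"):
        b_segments[chrom.name] = []
        if rng.random() < scheme.b_segment_prob:
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(1, max(2, chrom.length_bp - length)))
            hap = int(rng.choice(haps_by_taxon["B_carinata"]))
            b_segments[chrom.name].append((start, start + length - 1, hap))
    return Individual(ind_id, NEW_TYPE, 0, sterile, homologues, b_segments)


def make_base_population(panel: FounderPanel, scheme: BreedingScheme,
                         genome_model: GenomeModel,
                         rng: np.random.Generator) -> Population:
    pool = make_haplotype_pool(panel, scheme, rng)
    haps_by_taxon = {t: _haps_of(pool, t) for t in TAXA}
    inds: list[Individual] = []
    for i in range(scheme.n_dgms):
        exotic = scheme.poly_ar_exotic if i % 2 == 0 else scheme.poly_cc_exotic
        inds.append(_base_individual(f"DGMS{i + 1:03d}", exotic, sterile=True,
                                     inbred=False, genome_model=genome_model,
                                     haps_by_taxon=haps_by_taxon, scheme=scheme,
                                     rng=rng))
    for i in range(scheme.n_inbred_per_subpop):
        inds.append(_base_individual(f"PA{i + 1:03d}", scheme.poly_ar_exotic,
                                     sterile=False, inbred=True,
                                     genome_model=genome_model,
                                     haps_by_taxon=haps_by_taxon, scheme=scheme,
                                     rng=rng))
    for i in range(scheme.n_inbred_per_subpop):
        inds.append(_base_individual(f"PC{i + 1:03d}", scheme.poly_cc_exotic,
                                     sterile=False, inbred=True,
                                     genome_model=genome_model,
                                     haps_by_taxon=haps_by_taxon, scheme=scheme,
                                     rng=rng))
    return Population(inds, pool, panel, genome_model, name="base")


# -- crossing ----------------------------------------------------------------

def make_gamete(ind: Individual, genome_model: GenomeModel,
                rng: np.random.Generator) -> tuple[dict[str, list[Seg]],
                                                   dict[str, list[Seg]]]:
    """(A/C meiotic products, transmitted B segments)."""
    ac: dict[str, list[Seg]] = {}
    for chrom in genome_model.chromosomes:
        if chrom.genome == "B" or chrom.name not in ind.homologues:
            continue
        h0, h1 = ind.homologues[chrom.name]
        ac[chrom.name] = recombine(h0, h1, chrom, rng)
    b: dict[str, list[Seg]] = {}
    for chrom_name, segs in ind.b_segments.items():
        kept = [s for s in segs if rng.random() < 0.5]   # hemizygous: 50% transmission
        if kept:
            b[chrom_name] = kept
    return ac, b


def cross(mother: Individual, father: Individual, ind_id: str, generation: int,
          genome_model: GenomeModel, rng: np.random.Generator) -> Individual:
    """One offspring of a sterile seed parent x fertile pollen donor.

    The dominant sterility allele Ms segregates from the Msms mother with
    probability 1/2; the msms father always transmits ms, so progeny are
    sterile:fertile 1:1 in expectation.
    """
    if not mother.sterile:
        raise SimulationError("seed parent must be male-sterile (Msms)")
    if father.sterile:
        raise SimulationError("sterile plants set no pollen")
    m_ac, m_b = make_gamete(mother, genome_model, rng)
    f_ac, f_b = make_gamete(father, genome_model, rng)
    homologues = {c: (m_ac[c], f_ac[c]) for c in m_ac if c in f_ac}
    b_segments: dict[str, list[Seg]] = {}
    for chrom in genome_model.chroms_of_genome("B"):
        merged = m_b.get(chrom.name, []) + f_b.get(chrom.name, [])
        b_segments[chrom.name] = sorted(merged)
    sterile = bool(rng.random() < 0.5)   # Ms from the Msms mother
    return Individual(ind_id, NEW_TYPE, generation, sterile, homologues, b_segments)


# -- traits ------------------------------------------------------------------

def assign_qtl_positions(scheme: BreedingScheme, genome_model: GenomeModel,
                         rng: np.random.Generator) -> dict[str, list[tuple[str, int]]]:
    ac = [c for c in genome_model.chromosomes if c.genome in ("A", "C")]
    out: dict[str, list[tuple[str, int]]] = {}
    for t in scheme.traits:
        positions = []
        for _ in range(t.n_qtl):
            chrom = ac[int(rng.integers(len(ac)))]
            positions.append((chrom.name, int(rng.integers(1, chrom.length_bp + 1))))
        out[t.name] = positions
    return out


def genetic_values(inds: list[Individual], pool: dict[int, AncestralHaplotype],
                   scheme: BreedingScheme,
                   qtl_positions: dict[str, list[tuple[str, int]]]) -> pd.DataFrame:
    rows = {}
    for t in scheme.traits:
        sign = 1.0 if t.weight >= 0 else -1.0
        vals = []
        for ind in inds:
            dose = 0
            for q, (chrom, pos) in enumerate(qtl_positions[t.name]):
                if chrom not in ind.homologues:
                    continue
                for hom in ind.homologues[chrom]:
                    hap = segment_at(hom, pos)
                    if hap is not None:
                        dose += int(pool[hap].qtl_alleles[t.name][q])
            # centred so the base-population mean sits at the baseline
            # (expected dose is n_qtl at allele frequency 1/2 over two copies)
            vals.append(t.baseline + sign * t.effect * (dose - t.n_qtl))
        rows[t.name] = vals
    return pd.DataFrame(rows, index=[i.ind_id for i in inds])


def phenotypes(g: pd.DataFrame, scheme: BreedingScheme, sigma_g: pd.Series,
               rng: np.random.Generator) -> pd.DataFrame:
    p = g.copy()
    for t in scheme.traits:
        if t.h2 >= 1.0:
            continue
        sd_e = float(sigma_g[t.name]) * np.sqrt((1 - t.h2) / t.h2)
        p[t.name] = p[t.name] + rng.normal(0.0, sd_e, size=len(p))
    return p


def selection_index(p: pd.DataFrame, scheme: BreedingScheme) -> pd.Series:
    z = pd.Series(0.0, index=p.index)
    for t in scheme.traits:
        col = p[t.name]
        sd = float(col.std(ddof=0))
        if sd > 0:
            z = z + t.weight * (col - col.mean()) / sd
    return z


# -- the scheme --------------------------------------------------------------

def simulate_recurrent_selection(founders: FounderPanel, scheme: BreedingScheme,
                                 genome_model: GenomeModel,
                                 seed: int) -> SimulationResult:
    """Run the full breeding scheme.

    Each round: sterile (Msms) plants are seed parents pollinated by random
    fertile plants; offspring phenotypes are scored on all traits and a
    weighted standardized index; truncation selection keeps the configured
    fraction of steriles (harvested seed parents) and of fertiles (pollen
    donors for the next round). Harvested sterile plants' trait values are
    recorded per round as RS1..RSn.
    """
    scheme.validate()
    rng = np.random.default_rng(seed)
    base = make_base_population(founders, scheme, genome_model, rng)
    qtl_positions = assign_qtl_positions(scheme, genome_model, rng)
    g0 = genetic_values(base.individuals, base.hap_pool, scheme, qtl_positions)
    sigma_g = g0.std(ddof=0).replace(0.0, 1e-9)

    populations = [base]
    trait_rows: list[tuple] = []
    current = base.individuals
    for r in range(1, scheme.n_rounds + 1):
        mothers = [i for i in current if i.sterile]
        fathers = [i for i in current if not i.sterile]
        if not mothers or not fathers:
            raise SimulationError(
                f"round {r}: no {'sterile seed parents' if not mothers else 'fertile pollen donors'} left")
        offspring = [
            cross(mothers[int(rng.integers(len(mothers)))],
                  fathers[int(rng.integers(len(fathers)))],
                  f"RS{r}_{k + 1:04d}", r, genome_model, rng)
            for k in range(scheme.round_size)
        ]
        g = genetic_values(offspring, base.hap_pool, scheme, qtl_positions)
        p = phenotypes(g, scheme, sigma_g, rng)
        idx = selection_index(p, scheme)
        by_id = {i.ind_id: i for i in offspring}
        selected: list[Individual] = []
        for group in (True, False):
            ids = [i.ind_id for i in offspring if i.sterile is group]
            n_keep = max(1, int(np.ceil(scheme.selection_fraction * len(ids)))) if ids else 0
            ranked = idx.loc[ids].sort_values(ascending=False, kind="stable")
            selected.extend(by_id[s] for s in ranked.index[:n_keep])
        if not any(i.sterile for i in selected) or not any(not i.sterile for i in selected):
            raise SimulationError(f"round {r}: selection left no usable parents")
        for ind in selected:
            if ind.sterile:     # harvested seed parents are the scored lines
                for t in scheme.traits:
                    trait_rows.append((ind.ind_id, f"RS{r}", t.name, t.unit,
                                       float(p.loc[ind.ind_id, t.name])))
        populations.append(Population(selected, base.hap_pool, founders,
                                      genome_model, name=f"RS{r}"))
        current = selected
        logger.info("round %d: %d offspring, %d selected (%d sterile)",
                    r, len(offspring), len(selected),
                    sum(i.sterile for i in selected))

    trait_table = pd.DataFrame(
        trait_rows, columns=["sample", "generation", "trait", "unit", "value"])
    truth = ancestry_truth(populations)
    return SimulationResult(populations, truth, trait_table, scheme)


def ancestry_truth(populations: list[Population]) -> pd.DataFrame:
    """Truth track: one row per ancestry segment per homologue per sample."""
    rows = []
    for pop in populations:
        gm = pop.genome_model.by_name
        for ind in pop.individuals:
            for chrom, (h0, h1) in ind.homologues.items():
                genome = gm[chrom].genome
                for hom_i, segs in ((0, h0), (1, h1)):
                    for s, e, h in segs:
                        taxon = pop.hap_pool[h].taxon
                        rows.append((pop.name, ind.ind_id, ind.generation, chrom,
                                     hom_i, s, e, h, ORIGIN_LABEL[(taxon, genome)],
                                     "".join(ind.dgms_genotype)))
            for chrom, segs in ind.b_segments.items():
                for s, e, h in segs:
                    rows.append((pop.name, ind.ind_id, ind.generation, chrom,
                                 "B", s, e, h, "Bc", "".join(ind.dgms_genotype)))
    return pd.DataFrame(rows, columns=["population", "sample", "generation",
                                       "chrom", "homologue", "start", "end",
                                       "hap_id", "origin", "dgms"])


def simulate_dgms_progeny(n: int, seed: int) -> pd.Series:
    """Genotypes at the sterility locus for n progeny of an Msms x msms cross.

    Pure Mendelian segregation at one locus: the Msms seed parent transmits
    Ms or ms with probability 1/2, the msms pollen donor always ms.
    Returns a Series of 'Msms' / 'msms' strings.
    """
    if n < 1:
        raise ConfigurationError("need n >= 1 progeny")
    rng = np.random.default_rng(seed)
    maternal = np.where(rng.random(n) < 0.5, "Ms", "ms")
    return pd.Series([m + "ms" for m in maternal], name="dgms")


# ---------------------------------------------------------------------------
# marker ascertainment
# ---------------------------------------------------------------------------

def genotype_markers(population: Population, marker_panel: list[MarkerDef],
                     missing_rate: float, seed: int) -> GenotypeMatrix:
    """Read marker calls off the ancestry mosaics.

    Each marker yields one call per locus it amplifies. A and C loci report
    the two alleles of the haplotypes underlying the sample's two homologues;
    B-genome loci report the (hemizygous) carinata allele as a homozygous-like
    call when a B segment covers the position and are missing otherwise —
    including in samples that carry no B-genome material at all, which is what
    makes B loci blank in traditional *B. napus* panels. Calls are masked
    missing with probability ``missing_rate``; derived (new_type) samples
    additionally acquire novel alleles at the panel's novel-allele rate.
    """
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must be in [0, 1)")
    panel = population.founder_panel
    known = panel.locus_by_id
    for m in marker_panel:
        for l in m.loci:
            if l.locus_id not in known:
                raise SchemaError(f"marker {m.marker_id} references unknown locus {l.locus_id}")
    rng = np.random.default_rng(seed)
    pool = population.hap_pool
    rows = []
    novel_counter: dict[str, int] = {}
    for ind in population.individuals:
        for m in marker_panel:
            for l in m.loci:
                if l.genome == "B":
                    hap = segment_at(ind.b_segments.get(l.chrom, []), l.pos)
                    if hap is None:
                        a1 = a2 = None
                    else:
                        a = pool[hap].alleles[l.locus_id]
                        a1 = a2 = a
                elif l.chrom in ind.homologues:
                    h0, h1 = ind.homologues[l.chrom]
                    haps = (segment_at(h0, l.pos), segment_at(h1, l.pos))
                    if None in haps:
                        a1 = a2 = None
                    else:
                        a1, a2 = (pool[h].alleles[l.locus_id] for h in haps)
                else:
                    a1 = a2 = None     # taxon lacks this subgenome
                if a1 is not None and rng.random() < missing_rate:
                    a1 = a2 = None
                if (a1 is not None and ind.taxon == NEW_TYPE
                        and panel.novel_rate > 0
                        and rng.random() < panel.novel_rate):
                    k = novel_counter.get(l.locus_id, 0) % 3 + 1
                    novel_counter[l.locus_id] = novel_counter.get(l.locus_id, 0) + 1
                    novel = f"n{k}"
                    if rng.random() < 0.5:
                        a1 = novel
                    else:
                        a2 = novel
                rows.append((ind.ind_id, m.marker_id, l.locus_id, a1, a2))
    data = pd.DataFrame(rows, columns=["sample", "marker", "locus",
                                       "allele1", "allele2"])
    sample_info = pd.DataFrame(
        {"taxon": [i.taxon for i in population.individuals],
         "generation": [i.generation for i in population.individuals]},
        index=pd.Index([i.ind_id for i in population.individuals], name="sample"))
    locus_info = pd.DataFrame(
        {"genome": [l.genome for l in panel.loci],
         "chrom": [l.chrom for l in panel.loci],
         "pos": [l.pos for l in panel.loci],
         "source_ref": [l.source_ref for l in panel.loci]},
        index=pd.Index([l.locus_id for l in panel.loci], name="locus"))
    locus_info = locus_info.loc[[l.locus_id for m in marker_panel for l in m.loci]]
    return GenotypeMatrix(data, sample_info, locus_info)


# ---------------------------------------------------------------------------
# auxiliary panels used by downstream analyses
# ---------------------------------------------------------------------------

def make_taxon_reference_panel(population: Population, n_per_taxon: int,
                               seed: int) -> Population:
    """Pure-taxon reference accessions drawn from the ancestral haplotype pool.

    *B. rapa* accessions carry only A chromosomes, *B. carinata* carries C
    plus full-length (hemizygous-modelled) B chromosomes, traditional
    *B. napus* carries A + C. Used as the control panels that define allele
    specificity downstream. Haplotypes are dealt round-robin from a seeded
    shuffle of the pool, so a panel with ``n_per_taxon`` at least the pool
    size represents every ancestral haplotype (a reference panel is meant to
    cover the species' diversity, not to be a random population sample).
    """
    rng = np.random.default_rng(seed)
    gm = population.genome_model
    pool = population.hap_pool
    haps_by_taxon = {t: _haps_of(pool, t) for t in TAXA}
    inds = []
    for taxon, prefix in (("B_rapa", "RAPA"), ("B_carinata", "CARI"),
                          ("T_napus", "TNAP")):
        genomes = [g for g, carriers in GENOME_CARRIERS.items() if taxon in carriers]
        order = list(rng.permutation(haps_by_taxon[taxon]))
        for i in range(n_per_taxon):
            homologues = {}
            for chrom in gm.chromosomes:
                if chrom.genome == "B" or chrom.genome not in genomes:
                    continue
                h0 = int(order[(2 * i) % len(order)])
                h1 = int(order[(2 * i + 1) % len(order)])
                homologues[chrom.name] = ([(1, chrom.length_bp, h0)],
                                          [(1, chrom.length_bp, h1)])
            b_segments = {}
            if "B" in genomes:
                for chrom in gm.chroms_of_genome("B"):
                    h = int(order[i % len(order)])
                    b_segments[chrom.name] = [(1, chrom.length_bp, h)]
            inds.append(Individual(f"{prefix}{i + 1:03d}", taxon, -1, False,
                                   homologues, b_segments))
    return Population(inds, pool, population.founder_panel, gm, name="reference_panel")


def make_dh_lines(population: Population, n: int, seed: int) -> Population:
    """Doubled-haploid lines from random fertile plants of a population."""
    rng = np.random.default_rng(seed)
    fertile = [i for i in population.individuals if not i.sterile]
    if not fertile:
        raise SimulationError("no fertile plants to derive DH lines from")
    inds = []
    for k in range(n):
        donor = fertile[int(rng.integers(len(fertile)))]
        ac, b = make_gamete(donor, population.genome_model, rng)
        homologues = {c: (list(segs), list(segs)) for c, segs in ac.items()}
        b_segments = {c.name: list(b.get(c.name, []))
                      for c in population.genome_model.chroms_of_genome("B")}
        inds.append(Individual(f"DH{k + 1:03d}", NEW_TYPE, donor.generation,
                               False, homologues, b_segments))
    return Population(inds, population.hap_pool, population.founder_panel,
                      population.genome_model, name="dh_panel")


def make_planted_dh_panel(panel: FounderPanel, genome_model: GenomeModel,
                          fractions: list[float], seed: int, *,
                          blocks_per_chrom: float = 4.0,
                          n_b_segments: int = 2,
                          b_segment_len: tuple[int, int] = (2_000_000, 6_000_000),
                          ) -> tuple[Population, pd.Series]:
    """DH panel with *planted* exotic ancestry fractions, plus the parent line.

    Every line is a homozygous mosaic of one shared recurrent-parent
    haplotype (the 'HS3' traditional *B. napus* haplotype, included in the
    output population as sample ``HS3``) and one exotic haplotype per genome
    (rapa on A, carinata on C); each chromosome is cut into Poisson blocks and
    each block is exotic with the line's target probability. A few B-genome
    segments are planted per line. Returns the population and the realized
    (bp-weighted) exotic fraction per line from the truth mosaics.
    """
    rng = np.random.default_rng(seed)
    hap_parent = 0
    hap_rapa, hap_cari = 1, 2
    pool: dict[int, AncestralHaplotype] = {}

    def _draw(taxon, hap_id):
        genomes = [g for g, c in GENOME_CARRIERS.items() if taxon in c]
        loci = [l for l in panel.loci if l.genome in genomes]
        alleles = {}
        for l in loci:
            table = panel.freqs[(taxon, l.locus_id)]
            alleles[l.locus_id] = str(rng.choice(list(table), p=list(table.values())))
        pool[hap_id] = AncestralHaplotype(hap_id, taxon, alleles, {})

    _draw("T_napus", hap_parent)
    _draw("B_rapa", hap_rapa)
    _draw("B_carinata", hap_cari)

    inds = []
    realized = {}
    ac = [c for c in genome_model.chromosomes if c.genome in ("A", "C")]
    b_chroms = genome_model.chroms_of_genome("B")
    for k, f in enumerate(fractions):
        if not 0 <= f <= 1:
            raise ConfigurationError("planted fractions must be in [0, 1]")
        homologues = {}
        exotic_bp = total_bp = 0
        for chrom in ac:
            exo_hap = hap_rapa if chrom.genome == "A" else hap_cari
            n_breaks = int(rng.poisson(blocks_per_chrom))
            cuts = np.sort(rng.integers(2, chrom.length_bp, size=n_breaks)) if n_breaks else []
            bounds = [1] + [int(c) for c in cuts] + [chrom.length_bp + 1]
            segs = []
            for s, e in zip(bounds[:-1], bounds[1:]):
                if e <= s:
                    continue
                hap = exo_hap if rng.random() < f else hap_parent
                segs.append((s, e - 1, hap))
                if hap != hap_parent:
                    exotic_bp += e - s
                total_bp += e - s
            segs = _coalesce(segs)
            homologues[chrom.name] = (list(segs), list(segs))
        b_segments = {c.name: [] for c in b_chroms}
        for _ in range(n_b_segments):
            chrom = b_chroms[int(rng.integers(len(b_chroms)))]
            length = int(rng.integers(*b_segment_len))
            start = int(rng.integers(1, chrom.length_bp - length))
            b_segments[chrom.name].append((start, start + length - 1, hap_cari))
        for c in b_segments:
            b_segments[c] = sorted(b_segments[c])
        line = f"DH{k + 1:03d}"
        inds.append(Individual(line, NEW_TYPE, 5, False, homologues, b_segments))
        realized[line] = exotic_bp / total_bp
    # the recurrent parent itself
    hs3_hom = {c.name: ([(1, c.length_bp, hap_parent)], [(1, c.length_bp, hap_parent)])
               for c in ac}
    inds.append(Individual("HS3", "T_napus", -1, False, hs3_hom,
                           {c.name: [] for c in b_chroms}))
    pop = Population(inds, pool, panel, genome_model, name="planted_dh")
    return pop, pd.Series(realized, name="exotic_fraction")
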