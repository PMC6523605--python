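# Methods

## The breeding system being modelled

*Brassica napus* (A^n^A^n^C^n^C^n^, 2n = 38) is a young allotetraploid with
narrow diversity, especially in its C genome. A reconstituted gene pool
replaces its subgenomes with material from *B. rapa* (A^r^A^r^) and
*B. carinata* (B^c^B^c^C^c^C^c^): interspecific crosses produce two
polymorphic subpopulations — one mostly exotic in the A subgenome
(Poly-A^r^), one in C (Poly-C^c^) — which are then intercrossed and improved
by mass recurrent selection. Random outcrossing at scale is enforced by a
dominant genic male sterility (DGMS) locus: Msms plants set no pollen and
serve as seed parents, msms plants are fertile pollen donors, and progeny of
any Msms × msms mating segregate 1:1 sterile:fertile. Doubled-haploid (DH)
lines fixed from the pool are compared marker-by-marker with the recurrent
*B. napus* parent (called `HS3` throughout) to quantify exotic
introgression.

## Simulator

**Genome.** Diploidized AACC plus hemizygous B. Each line carries two
homologues of every A chromosome (A01–A10) and C chromosome (C01–C09).
B-genome material (B01–B08) is modelled as hemizygous presence/absence
segments, because the target lines are 2n = 38 AACC with only small B
introgressions — full hexaploid meiosis is out of scope. Default physical
and map lengths: A 25 Mb / 1.2 M, C 45 Mb / 1.5 M, B 35 Mb / 1.3 M per
chromosome, i.e. ~100–150 cM maps typical of *Brassica* linkage maps.

**Ancestry representation.** Every homologue is a list of segments
`(start, end, haplotype id)` pointing at concrete ancestral haplotypes.
Each ancestral haplotype belongs to one founder taxon and carries a drawn
allele at every locus plus 0/1 alleles at every QTL. Genotypes and the
ancestry truth track are therefore two views of the same data structure and
cannot disagree; the truth-decoding test in the suite verifies this
round-trip explicitly.

**Founder allele frequencies.** Each locus receives 2–6 alleles
(SSR-fragment-size-like symbols; the size ranges differ per basic genome so
the two loci of a dual-locus marker stay distinguishable, as SSR size
classes do in practice). An allele is made taxon-private with probability
0.25 by default (a coarse match to the observed rate of parental-specific
alleles in such pools); frequencies are Dirichlet(α = 2). B-genome loci are
carried by *B. carinata* only, so all their alleles are private by
construction. Derived lines additionally acquire novel alleles (absent from
every founder) at a per-cell rate of 0.005, emulating the small number of
loci at which new-type lines show alleles absent from all parental panels.

**Meiosis.** Crossovers per chromosome are Poisson with mean equal to the
map length in Morgans, positions uniform, no interference — the simplest
defensible model. Hemizygous B segments are transmitted independently with
probability 1/2 each.

**The scheme.** The base population holds 20 DGMS (Msms) founder lines with
mosaic genomes drawn alternately from the two subpopulation profiles
(Poly-A^r^: 75 % exotic A, 20 % exotic C; Poly-C^c^ reversed) and 40
fertile inbreds per subpopulation. Each round mates random sterile seed
parents to random fertile pollen donors (200 offspring/round by default),
scores six traits, and applies truncation selection on a standardized
weighted index, keeping the top 30 % of steriles (harvested, and the
recorded trait observations) and of fertiles (next round's pollen). Five
rounds by default. Per-round population sizes and selection intensities were
not fixed quantities of the original breeding programme, so they are plain
configuration with these defaults.

**Traits.** Additive QTL models with per-trait heritability; environmental
noise is scaled from the base population's genetic variance as
σ²_E = σ²_G (1 − h²)/h². Defaults emulate an oilseed quality/agronomic
selection profile: oil content (44.2 %, h² 0.4, selected up), erucic acid
(9.4 %, 3 QTL, h² 0.8, down), glucosinolates (60.9 μmol/g, 4 QTL, h² 0.8,
down), thousand-seed weight, pod density and seeds/pod (h² 0.3–0.4, up).
Few-QTL high-h² quality traits respond fastest, as in real schemes. The
index weights both quality (weight 1) and agronomic traits (weight 0.5).

**What the generator does and does not emulate.** It reproduces the
*structure* of the design — taxon-private alleles, mosaic subgenomes,
sparse hemizygous B segments, 1:1 DGMS segregation, truncation response,
SSR-style multi-locus amplification and missingness. It does not model
cytogenetic instability (aneuploidy, translocation), transposon activation,
epistasis, genotype × environment interaction, linkage between the DGMS
locus and markers (the sterility locus segregates independently), or
sequence-level artefacts of GBS. Tests passing on these simulations
demonstrate the *procedures* are correct given their assumptions, not that
real populations obey the assumptions.

## Provenance classification

Reference presence is defined by the three control panels (*B. rapa*,
*B. carinata*, traditional *B. napus*); derived new-type samples never
contribute to reference presence. An allele counts as present in a panel
when observed in ≥ 1 sample (threshold configurable). The four assignment
rules are applied in the order (iv), (iii), (i), (ii): dual rules are more
specific and must pre-empt the single-locus rules. Contradictory evidence
(e.g. rapa-only alleles with no A-genome alignment, or an allele present in
both diploid parents without an A+B alignment) is flagged `conflict`;
patterns matching no rule (including B-only markers, which the SSR rule set
does not cover) are `unassigned` with a reason — never silently assigned.
Conflicts between genetic-map position and alignment hits are likewise
flagged rather than adjudicated.

At a dual A+C marker a traditional-napus-only allele cannot be placed on
either locus from presence alone; it is designated to the A locus
(An-specific), mirroring the convention that dual A/B loci are designated A
for partitioned statistics. This affects only the An/Cn split, never the
parental-specific (Ar/Cc/Bc) or novel calls.

## Diversity statistics

Gene diversity uses the plain estimator 1 − Σ p̂² (the common PowerMarker
default); the small-sample correction n/(n−1) is an option. Nei's (1972)
standard distance is the default and the 1983 D_A distance is switchable,
since distance software defaults vary. Individual-level trees treat each
accession as a population of one diploid sample (frequencies 0/0.5/1); this
choice is recorded in the summary metadata. Populations with disjoint locus
sets (e.g. *B. rapa* vs *B. carinata* panels, which share no subgenome)
have undefined (infinite) 1972 distance; it is capped at a configurable
maximum (default 10) with a warning. Neighbor joining breaks Q-matrix ties
toward the lexicographically smallest pair of clade labels, so output is
deterministic; the final three nodes are resolved in closed form, which
makes additive matrices reconstruct exactly (verified against random
additive trees and an exhaustive quartet oracle).

## Introgression calling

"Different from parent" compares unordered allele sets; heterozygous calls
against a homozygous parent count as differing (the rule must be total even
though DH panels are homozygous). The missing-rate filter is strict
(`< 50 %`): a marker missing in exactly half the samples is removed; a
threshold of 1.0 disables the filter. Markers at which the parent is
missing are undefined in the track — in particular all B-genome markers,
since the AC parent has no B genome; B-specific markers are instead flagged
when blank in every traditional line, and segment merging counts a flagged
B marker as supporting wherever the line itself is called. The population
union counts a marker once regardless of how many lines differ, which is
what makes the union fraction dominate every per-line fraction.

Segment coordinates are marker-supported spans (first to last supporting
marker), 1-based inclusive internally; BED export converts to 0-based
half-open. Segment length is reported as `end − start` of the 1-based
coordinates — the arithmetic used for printed marker-delimited intervals
(a span of 3,563,715–3,723,750 is reported as 160,035 bp ≈ 160 kb).

## Trait statistics

ΔG is stored as a signed fraction and rendered as percent on request. The
ΔG matrix between all generation pairs satisfies
ΔG(i→n) = −ΔG(n→i)/(1 + ΔG(n→i)) and gains compose multiplicatively; both
identities are property-tested. No particular test is canonical for
across-generation comparisons in this design, so one-way ANOVA is the
default (recorded in output metadata) with a Kruskal–Wallis alternative,
used automatically when within-group variance is degenerate; fully constant
data return p = 1. The test's type-I error is calibrated by simulation in
the suite (1,000 null replicates at n = 80/group).

## Numerical and interface choices

- All randomness flows through one `numpy.random.Generator` per entry
  point, seeded explicitly; equal seeds give identical outputs.
- Frequency tables must sum to 1 within 1e−9 (panel validation) / 1e−6
  (statistics input); closed-form oracles in the suite are checked to
  1e−12.
- Coordinates are 1-based inclusive in memory, 0-based half-open in BED;
  newick output is semicolon-terminated and re-parse-checked.
- Taxon reference panels deal ancestral haplotypes round-robin from a
  seeded shuffle, so a panel at least as large as the haplotype pool
  represents every founder haplotype — a reference panel is meant to cover
  the species' diversity, not to be a random population sample.
- Desk-scale defaults (≤ 500 markers, 200 plants/round, 20–40 founders per
  group) keep any analysis in this package in the seconds-to-minutes range
  while preserving the design's structure.

## Known limitations and flagged ambiguities

- Single-B-locus markers are `unassigned` under the SSR rule set by design;
  B-genome evidence enters through the dual A/B rule and through the
  GBS-stage B-marker flag.
- The exact cross-reference marker matching criteria of a real multi-genome
  GBS pipeline (identity/coverage thresholds of the upstream alignment) are
  outside scope; `harmonize_marker_sets` consumes a precomputed match
  table.
- Reports of quality-trait levels in the source breeding literature mix
  percent and μmol/g for glucosinolates and give two figures (3.3 % / 5.3 %)
  for the same seeds-per-pod improvement; this package keeps explicit units
  on every trait record and adjudicates neither figure.
- ΔG is undefined for a zero initial mean (explicit error), and is a ratio
  of means, not a heritability-adjusted response estimate.
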