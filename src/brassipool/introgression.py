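"""Multi-reference introgression calling against a recurrent parent.

GBS-style SNP/Indel matrices are discovered against several reference
genomes (the *B. napus* AC reference plus the *B. rapa* A, *B. oleracea* C
and *B. nigra* B references). This module harmonizes those marker sets,
flags B-genome markers that are blank across every traditional *B. napus*
line (the signature of *B. carinata* B-genome material, which has no home in
an AC genome), filters markers by missingness, calls per-line differences
from the recurrent parent, and merges supporting markers into genomic
segments.

A line "differs" from the parent at a marker when its unordered allele set
differs from the parent's; for doubled-haploid (homozygous) lines this
reduces to allele inequality, and heterozygous calls against a homozygous
parent count as differing. The per-line introgression fraction is
differs / (differs + same) with missing calls excluded; the population union
fraction counts a marker once if any line differs there.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (ConfigurationError, GenotypeMatrix, SchemaError, Segment,
                 logger)

SAME, DIFFERS, MISSING_STATE = 0, 1, -1


# ---------------------------------------------------------------------------
# marker-set harmonization
# ---------------------------------------------------------------------------

@dataclass
class MultiRefMarkerSet:
    """Unified marker table after cross-reference matching.

    ``markers`` has columns marker/source/genome/chrom/pos/species_specific;
    matched alt-reference markers are represented by their *B. napus*
    counterpart (napus coordinates canonical), unmatched ones keep their alt
    coordinates and carry the additional species-specific flag.
    """

    markers: pd.DataFrame
    counts: dict = field(default_factory=dict)


MARKER_COLUMNS = ["marker", "source", "genome", "chrom", "pos"]


def harmonize_marker_sets(napus_set: pd.DataFrame, alt_sets: pd.DataFrame,
                          match_table: pd.DataFrame) -> MultiRefMarkerSet:
    """Merge alt-reference marker sets into the napus-reference set.

    ``match_table`` has columns alt_marker / napus_marker (empty or NaN for
    no hit). Alt markers matched to a napus marker are dropped (the napus
    marker already represents the site); unmatched alt markers join the
    unified set as additional species-specific markers. An alt marker matched
    to two different napus markers is ambiguous and excluded with a log
    entry.
    """
    for df, what in ((napus_set, "napus_set"), (alt_sets, "alt_sets")):
        missing = [c for c in MARKER_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{what}: missing columns {missing}")
    match = match_table.copy()
    if not {"alt_marker", "napus_marker"} <= set(match.columns):
        raise SchemaError("match_table needs alt_marker / napus_marker columns")
    match["napus_marker"] = match["napus_marker"].replace("", np.nan)
    hits = match.dropna(subset=["napus_marker"])
    ambiguous = (hits.groupby("alt_marker")["napus_marker"].nunique()
                     .pipe(lambda s: set(s.index[s > 1])))
    if ambiguous:
        logger.warning("harmonize: %d alt markers matched to multiple napus "
                       "markers, excluded: %s", len(ambiguous),
                       sorted(ambiguous)[:5])
    matched = set(hits["alt_marker"]) - ambiguous
    alt = alt_sets[~alt_sets["marker"].isin(matched | ambiguous)].copy()
    alt["species_specific"] = True
    nap = napus_set.copy()
    nap["species_specific"] = False
    unified = pd.concat([nap, alt], ignore_index=True)
    counts = {
        "napus": len(nap),
        "alt_total": len(alt_sets),
        "alt_matched": len(set(alt_sets["marker"]) & matched),
        "alt_ambiguous": len(set(alt_sets["marker"]) & ambiguous),
        "additional_specific": len(alt),
    }
    return MultiRefMarkerSet(unified, counts)


# ---------------------------------------------------------------------------
# B-genome flagging and missingness filtering
# ---------------------------------------------------------------------------

def flag_b_genome_markers(genotypes: GenotypeMatrix,
                          traditional_panel: list[str]) -> set[str]:
    """B-genome markers blank in *every* traditional *B. napus* line.

    Such markers have no amplifiable site in an AC genome and therefore tag
    *B. carinata* B-genome introgression wherever they are called.
    """
    if not traditional_panel:
        raise SchemaError("traditional panel must be nonempty")
    if genotypes.locus_info is None:
        raise SchemaError("genotype matrix lacks locus genome annotation")
    b_loci = set(genotypes.locus_info.index[genotypes.locus_info["genome"] == "B"])
    if not b_loci:
        return set()
    trad = genotypes.subset_samples(traditional_panel)
    wide = trad.allele_sets()
    flagged = set()
    for locus in b_loci:
        if locus not in wide.columns or wide[locus].isna().all():
            flagged.add(locus)
    return flagged


def filter_missing(genotypes: GenotypeMatrix,
                   max_missing_rate: float = 0.5) -> GenotypeMatrix:
    """Retain markers whose missing fraction is strictly below the threshold.

    The boundary is strict: a marker missing in exactly half the samples is
    removed at the default threshold of 0.5. A threshold of 1.0 disables the
    filter entirely (nothing removed).
    """
    if not 0 < max_missing_rate <= 1:
        raise ConfigurationError("max_missing_rate must be in (0, 1]")
    frac = genotypes.missing_fraction()
    keep = frac.index if max_missing_rate >= 1.0 else frac.index[frac < max_missing_rate]
    logger.info("filter_missing: %d/%d loci retained at < %.2f",
                len(keep), len(frac), max_missing_rate)
    return genotypes.subset_loci(keep)


# ---------------------------------------------------------------------------
# calls against the recurrent parent
# ---------------------------------------------------------------------------

@dataclass
class IntrogressionTrack:
    """Per line x marker difference states against the recurrent parent."""

    states: pd.DataFrame        # lines x loci, values SAME/DIFFERS/MISSING_STATE
    parent_id: str
    positions: pd.DataFrame     # locus -> chrom, pos (sorted by chrom, pos)
    called: pd.DataFrame | None = None   # lines x loci: line itself has a call

    @property
    def per_line_fraction(self) -> pd.Series:
        s = self.states
        differs = (s == DIFFERS).sum(axis=1)
        informative = (s != MISSING_STATE).sum(axis=1)
        return (differs / informative).rename("fraction_differing")

    @property
    def union_fraction(self) -> float:
        """Fraction of markers at which at least one line differs."""
        s = self.states
        informative = (s != MISSING_STATE).any(axis=0)
        if not informative.any():
            return float("nan")
        any_diff = (s == DIFFERS).any(axis=0)
        return float(any_diff[informative].mean())


def call_vs_parent(genotypes: GenotypeMatrix, parent_id: str) -> IntrogressionTrack:
    """Compare every line's allele set with the recurrent parent's.

    Markers at which the parent is missing are set missing in the whole
    track (the comparison is undefined there). The parent itself is excluded
    from the line set. Raises if the parent is unknown or entirely missing.
    """
    if parent_id not in genotypes.samples:
        raise SchemaError(f"unknown parent sample {parent_id!r}")
    wide = genotypes.allele_sets()
    parent = wide.loc[parent_id]
    if parent.isna().all():
        raise SchemaError(f"parent {parent_id} has no called markers")
    lines = [s for s in wide.index if s != parent_id]
    states = pd.DataFrame(MISSING_STATE, index=lines, columns=wide.columns,
                          dtype=np.int8)
    parent_ok = parent.notna()
    for line in lines:
        row = wide.loc[line]
        ok = parent_ok & row.notna()
        same = ok & (row == parent)
        states.loc[line, ok & ~same] = DIFFERS
        states.loc[line, same] = SAME
    if genotypes.locus_info is not None:
        pos = genotypes.locus_info.loc[wide.columns, ["chrom", "pos"]].copy()
    else:
        raise SchemaError("genotype matrix lacks locus positions")
    pos["pos"] = pos["pos"].astype(int)
    order = pos.sort_values(["chrom", "pos"]).index
    called = wide.loc[lines].notna()
    return IntrogressionTrack(states.loc[:, order], parent_id, pos.loc[order],
                              called.loc[:, order])


# ---------------------------------------------------------------------------
# segment merging
# ---------------------------------------------------------------------------

def merge_segments(track: IntrogressionTrack, *, max_gap_markers: int = 0,
                   min_markers: int = 1,
                   b_flags: set[str] | None = None) -> list[Segment]:
    """Merge consecutive differing calls into marker-supported segments.

    Within one chromosome, runs of DIFFERS calls (markers in ``b_flags``
    count as supporting wherever the line itself is called, since the
    recurrent parent is blank at B-genome markers) separated by at most
    ``max_gap_markers`` non-supporting markers merge into one segment whose
    coordinates span the first to the last supporting marker. Segments with
    fewer than ``min_markers`` supporting markers are dropped. Requires the
    track's markers sorted by (chrom, pos); unsorted input is an error, never
    silently re-sorted.
    """
    if max_gap_markers < 0 or min_markers < 1:
        raise ConfigurationError("max_gap_markers >= 0 and min_markers >= 1 required")
    pos = track.positions
    for chrom, sub in pos.groupby("chrom", sort=False):
        if np.any(np.diff(sub["pos"].to_numpy()) < 0):
            raise SchemaError(f"markers not sorted by position on {chrom}")
    b_flags = b_flags or set()
    segments: list[Segment] = []
    for line in track.states.index:
        row = track.states.loc[line]
        for chrom, sub in pos.groupby("chrom", sort=False):
            loci = list(sub.index)
            called = track.called.loc[line] if track.called is not None else None
            support = [
                (l, int(sub.loc[l, "pos"])) for l in loci
                if row[l] == DIFFERS
                or (l in b_flags and called is not None and bool(called[l]))
            ]
            if not support:
                continue
            idx_of = {l: i for i, l in enumerate(loci)}
            run: list[tuple[str, int]] = []
            last_idx = None
            for l, p in support:
                i = idx_of[l]
                if last_idx is not None and i - last_idx - 1 > max_gap_markers:
                    segments.extend(_emit(line, chrom, run, min_markers))
                    run = []
                run.append((l, p))
                last_idx = i
            segments.extend(_emit(line, chrom, run, min_markers))
    return segments


def _emit(line: str, chrom: str, run: list[tuple[str, int]],
          min_markers: int) -> list[Segment]:
    if len(run) < min_markers or not run:
        return []
    return [Segment(line, chrom, run[0][1], run[-1][1], len(run))]


def segments_frame(segments: list[Segment]) -> pd.DataFrame:
    rows = [(s.line, s.chrom, s.start, s.end, s.n_markers, s.length_bp,
             s.length_kb) for s in segments]
    return pd.DataFrame(rows, columns=["line", "chrom", "start", "end",
                                       "n_markers", "length_bp", "length_kb"])


def introgression_summary(track: IntrogressionTrack) -> pd.DataFrame:
    """Per-line summary plus the population union row."""
    frac = track.per_line_fraction
    informative = (track.states != MISSING_STATE).sum(axis=1)
    out = pd.DataFrame({
        "fraction_differing": frac,
        "n_informative_markers": informative,
    })
    out.loc["UNION"] = [track.union_fraction,
                        int((track.states != MISSING_STATE).any(axis=0).sum())]
    return out
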