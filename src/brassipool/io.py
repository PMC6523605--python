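"""Shared containers, readers and writers for the pipeline.

Genotype data move through the pipeline as a long-format table
(sample, marker, locus, allele1, allele2) wrapped in :class:`GenotypeMatrix`.
A *marker* is an assay (e.g. one SSR primer pair) that may interrogate more
than one genome-specific *locus*; for SNP data marker and locus coincide.
Missing calls are stored as ``None`` in memory and ``"."`` on disk.

Coordinates are 1-based inclusive in memory (matching how positions are
printed in the literature); BED export converts to 0-based half-open.
"""
from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("brassipool")

MISSING = "."

GENOTYPE_COLUMNS = ["sample", "marker", "locus", "allele1", "allele2"]
LOCUS_INFO_COLUMNS = ["genome", "chrom", "pos", "source_ref"]


class BrassipoolError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(BrassipoolError, ValueError):
    """Invalid configuration (frequencies, fractions, thresholds)."""


class SchemaError(BrassipoolError, ValueError):
    """Malformed input table or unknown identifier."""


# ---------------------------------------------------------------------------
# marker / locus definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusDef:
    """One genome-specific locus interrogated by a marker."""

    locus_id: str
    genome: str           # 'A', 'B' or 'C'
    chrom: str
    pos: int              # 1-based bp
    source_ref: str = "napus_AC"

    def __post_init__(self):
        if self.genome not in ("A", "B", "C"):
            raise SchemaError(f"unknown genome {self.genome!r} for locus {self.locus_id}")
        if self.pos < 1:
            raise SchemaError(f"position must be 1-based positive: {self.locus_id}")


@dataclass(frozen=True)
class MarkerDef:
    """An assay and the one-or-more loci it amplifies."""

    marker_id: str
    loci: tuple[LocusDef, ...]

    def __post_init__(self):
        if not self.loci:
            raise SchemaError(f"marker {self.marker_id} has no loci")


@dataclass(frozen=True)
class Segment:
    """A merged run of introgression-supporting markers.

    Coordinates are 1-based inclusive; ``length_bp`` is end − start, the
    arithmetic used for printed marker-delimited intervals.
    """

    line: str
    chrom: str
    start: int
    end: int
    n_markers: int

    def __post_init__(self):
        if self.start > self.end:
            raise SchemaError(f"segment start > end on {self.chrom}")
        if self.n_markers < 1:
            raise SchemaError("segment must be supported by >=1 marker")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

def _norm_allele(a) -> str | None:
    if a is None or (isinstance(a, float) and np.isnan(a)):
        return None
    s = str(a).strip()
    if s in ("", MISSING, "NA", "nan", "None"):
        return None
    return s


class GenotypeMatrix:
    """Samples x loci table of unordered diploid allele calls.

    Parameters
    ----------
    data:
        Long-format frame with columns sample, marker, locus, allele1, allele2.
        A cell is missing iff both alleles are missing; half-missing cells are
        rejected as malformed.
    sample_info:
        Optional frame indexed by sample with at least a ``taxon`` column.
    locus_info:
        Optional frame indexed by locus with genome/chrom/pos/source_ref.
    """

    def __init__(self, data: pd.DataFrame,
                 sample_info: pd.DataFrame | None = None,
                 locus_info: pd.DataFrame | None = None):
        missing_cols = [c for c in GENOTYPE_COLUMNS if c not in data.columns]
        if missing_cols:
            raise SchemaError(f"genotype table lacks columns {missing_cols}")
        data = data.loc[:, GENOTYPE_COLUMNS].copy()
        data["allele1"] = data["allele1"].map(_norm_allele)
        data["allele2"] = data["allele2"].map(_norm_allele)
        half = (data["allele1"].isna() != data["allele2"].isna())
        if half.any():
            idx = int(np.flatnonzero(half.to_numpy())[0])
            raise SchemaError(f"half-missing genotype call at row {idx}")
        dup = data.duplicated(subset=["sample", "locus"])
        if dup.any():
            idx = int(np.flatnonzero(dup.to_numpy())[0])
            raise SchemaError(f"duplicate (sample, locus) call at row {idx}")
        self.data = data.reset_index(drop=True)
        self.sample_info = sample_info
        self.locus_info = locus_info

    # -- basic views --------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.data["sample"]))

    @property
    def loci(self) -> list[str]:
        return list(pd.unique(self.data["locus"]))

    @property
    def markers(self) -> list[str]:
        return list(pd.unique(self.data["marker"]))

    def __len__(self) -> int:
        return len(self.data)

    def taxon_of(self, sample: str) -> str:
        if self.sample_info is None or sample not in self.sample_info.index:
            return "unknown"
        return str(self.sample_info.loc[sample, "taxon"])

    def samples_of_taxon(self, taxon: str) -> list[str]:
        if self.sample_info is None:
            return []
        return list(self.sample_info.index[self.sample_info["taxon"] == taxon])

    def subset_samples(self, samples: Iterable[str]) -> "GenotypeMatrix":
        keep = set(samples)
        unknown = keep - set(self.samples)
        if unknown:
            raise SchemaError(f"unknown samples {sorted(unknown)[:5]}")
        data = self.data[self.data["sample"].isin(keep)]
        info = None
        if self.sample_info is not None:
            info = self.sample_info.loc[self.sample_info.index.isin(keep)]
        return GenotypeMatrix(data, info, self.locus_info)

    def subset_loci(self, loci: Iterable[str]) -> "GenotypeMatrix":
        keep = set(loci)
        data = self.data[self.data["locus"].isin(keep)]
        info = None
        if self.locus_info is not None:
            info = self.locus_info.loc[self.locus_info.index.isin(keep)]
        return GenotypeMatrix(data, self.sample_info, info)

    def allele_sets(self) -> pd.DataFrame:
        """Samples x loci frame of frozenset allele calls (NaN = missing)."""
        d = self.data
        vals = [
            frozenset((a1, a2)) if a1 is not None else np.nan
            for a1, a2 in zip(d["allele1"], d["allele2"])
        ]
        frame = pd.DataFrame({"sample": d["sample"], "locus": d["locus"], "gt": vals})
        wide = frame.pivot(index="sample", columns="locus", values="gt")
        return wide.reindex(index=self.samples, columns=self.loci)

    def missing_fraction(self) -> pd.Series:
        """Per-locus fraction of samples with a missing call (absent rows count)."""
        wide = self.allele_sets()
        return wide.isna().mean(axis=0)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        a = self.data.sort_values(["sample", "locus"]).reset_index(drop=True)
        b = other.data.sort_values(["sample", "locus"]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        # unordered allele pairs compare as sets
        def canon(df):
            pairs = [
                tuple(sorted((x, y), key=str)) if x is not None else None
                for x, y in zip(df["allele1"], df["allele2"])
            ]
            out = df[["sample", "marker", "locus"]].copy()
            out["gt"] = pairs
            return out
        return canon(a).equals(canon(b))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read a genotype matrix from long TSV or VCF.

    TSV requires the header columns sample/marker/locus/allele1/allele2 and may
    carry the optional locus columns genome/chrom/pos/source_ref and a sample
    ``taxon`` column, which are restored into ``locus_info``/``sample_info``.
    VCF is read with pysam; ``./.`` genotypes become missing cells.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing_cols = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    bad = df["sample"].isna() | df["locus"].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise SchemaError(f"{path}: malformed row at line {line}")
    locus_info = None
    if all(c in df.columns for c in LOCUS_INFO_COLUMNS):
        locus_info = (df.drop_duplicates("locus")
                        .set_index("locus")[LOCUS_INFO_COLUMNS].copy())
        locus_info["pos"] = locus_info["pos"].astype(int)
    sample_info = None
    if "taxon" in df.columns:
        sample_info = df.drop_duplicates("sample").set_index("sample")[["taxon"]].copy()
    gm = GenotypeMatrix(df, sample_info, locus_info)
    logger.info("read %s: %d samples x %d loci", path, len(gm.samples), len(gm.loci))
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    rows = []
    locus_rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            contig = rec.chrom
            if "." in contig:
                source, chrom = contig.split(".", 1)
            else:
                source, chrom = "napus_AC", contig
            genome = chrom[0].upper()
            if genome not in ("A", "B", "C"):
                raise SchemaError(f"{path}: cannot infer genome from contig {contig!r}")
            locus = f"{chrom}:{rec.pos}"
            alleles = (rec.ref,) + tuple(rec.alts or ())
            locus_rows.append((locus, genome, chrom, rec.pos, source))
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(g is None for g in gt):
                    a1 = a2 = None
                else:
                    a1, a2 = (alleles[g] for g in (gt + gt)[:2])
                rows.append((s, locus, locus, a1, a2))
    data = pd.DataFrame(rows, columns=["sample", "marker", "locus", "allele1", "allele2"])
    locus_info = (pd.DataFrame(locus_rows, columns=["locus"] + LOCUS_INFO_COLUMNS)
                    .drop_duplicates("locus").set_index("locus"))
    return GenotypeMatrix(data, None, locus_info)


def read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a generic TSV and check required columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def read_hits_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, ["marker", "reference", "genome", "chrom", "pos"])
    df["pos"] = df["pos"].astype(int)
    return df


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _check_target(path: Path, overwrite: bool):
    if path.exists() and not overwrite:
        raise BrassipoolError(f"{path} exists (pass overwrite=True to replace)")
    path.parent.mkdir(parents=True, exist_ok=True)


def write_genotype_table(gm: GenotypeMatrix, path: str | Path, *,
                         overwrite: bool = True) -> None:
    path = Path(path)
    _check_target(path, overwrite)
    df = gm.data.copy()
    if gm.locus_info is not None:
        df = df.join(gm.locus_info, on="locus")
    if gm.sample_info is not None and "taxon" in gm.sample_info.columns:
        df = df.join(gm.sample_info[["taxon"]], on="sample")
    for c in ("allele1", "allele2"):
        df[c] = df[c].map(lambda a: MISSING if a is None else a)
    df.to_csv(path, sep="\t", index=False)


def write_bed(segments: Sequence[Segment], path: str | Path, *,
              overwrite: bool = True) -> None:
    """Write segments as 0-based half-open BED with kb lengths."""
    path = Path(path)
    _check_target(path, overwrite)
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tline\tn_markers\tlength_kb\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.line}\t"
                     f"{s.n_markers}\t{s.length_kb:.3f}\n")


def write_newick(tree, path: str | Path, *, overwrite: bool = True) -> None:
    path = Path(path)
    _check_target(path, overwrite)
    tree.write(str(path), format="newick")
    # skbio terminates with ';\n' already; assert the convention
    text = path.read_text()
    if not text.rstrip().endswith(";"):
        raise BrassipoolError("newick output not semicolon-terminated")


def write_phylip_matrix(dist: pd.DataFrame, path: str | Path, *,
                        overwrite: bool = True) -> None:
    path = Path(path)
    _check_target(path, overwrite)
    with open(path, "w") as fh:
        fh.write(f"{len(dist)}\n")
        for name, row in dist.iterrows():
            fh.write(str(name) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def write_manifest(config: Mapping, out_dir: str | Path, *, seed: int | None = None,
                   overwrite: bool = True) -> Path:
    """Write the resolved run configuration next to the outputs."""
    from brassipool import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_manifest.json"
    _check_target(path, overwrite)
    payload = {
        "tool": "brassipool",
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "seed": seed,
        "config": _jsonable(config),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
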