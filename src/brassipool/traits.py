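"""Recurrent-selection genetic gain and generation comparisons.

The genetic gain of a trait between selection rounds i and n is the relative
change of the population mean, ΔG = (μ_n − μ_i) / μ_i, stored as a signed
fraction and rendered as percent on request. Generation differences are
tested with one-way ANOVA by default (an assumption recorded in the output
metadata — no particular test is canonical for this design); a rank-based
Kruskal–Wallis alternative is switchable and used as fallback under
degenerate variance. The library reports p-values and never makes the
significance decision itself.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConfigurationError, SchemaError, logger

TRAIT_COLUMNS = ["sample", "generation", "trait", "value"]


def _check_table(trait_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in trait_table.columns]
    if missing:
        raise SchemaError(f"trait table lacks columns {missing}")
    t = trait_table.copy()
    t["value"] = t["value"].astype(float)
    if not np.isfinite(t["value"]).all():
        raise SchemaError("trait values must be finite")
    return t


def delta_g(mu_i: float, mu_n: float, *, percent: bool = False) -> float:
    """Relative genetic gain (μ_n − μ_i) / μ_i between two round means."""
    if mu_i == 0:
        raise ConfigurationError("ΔG undefined for a zero initial mean")
    g = (mu_n - mu_i) / mu_i
    return 100.0 * g if percent else g


@dataclass
class GenerationSummary:
    stats: pd.DataFrame                     # per generation x trait
    delta_g: dict[str, pd.DataFrame]        # trait -> gain matrix (from -> to)
    metadata: dict


def generation_summary(trait_table: pd.DataFrame) -> GenerationSummary:
    """Exact per-generation statistics and the full ΔG matrix per trait.

    Generations are ordered by their natural sort (RS1 < RS2 < ... ).
    ``delta_g[trait].loc[i, n]`` is the gain from generation i to n; the
    matrix satisfies ΔG(i→n) = −ΔG(n→i)/(1+ΔG(n→i)).
    """
    t = _check_table(trait_table)
    if t.empty:
        raise SchemaError("empty trait table")
    gens = sorted(t["generation"].unique())
    agg = (t.groupby(["generation", "trait"])["value"]
             .agg(["mean", "min", "max", "count"])
             .rename(columns={"count": "n"})
             .reset_index())
    matrices: dict[str, pd.DataFrame] = {}
    for trait, sub in t.groupby("trait"):
        means = sub.groupby("generation")["value"].mean()
        present = [g for g in gens if g in means.index]
        mat = pd.DataFrame(np.nan, index=present, columns=present)
        for gi in present:
            for gn in present:
                if means[gi] != 0:
                    mat.loc[gi, gn] = delta_g(float(means[gi]), float(means[gn]))
        matrices[str(trait)] = mat
    empty = set(gens) - set(agg["generation"])
    if empty:
        logger.warning("generations without records omitted: %s", sorted(empty))
    meta = {"gain_definition": "(mu_n - mu_i) / mu_i, signed fraction",
            "generations": gens}
    return GenerationSummary(agg, matrices, meta)


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n_groups: int


def generation_difference_test(trait_table: pd.DataFrame, trait: str, *,
                               method: str = "anova") -> TestResult:
    """Test whether a trait differs among generations.

    ``anova`` runs one-way ANOVA across generation groups; ``kruskal`` runs
    the Kruskal–Wallis rank test. With exactly two generations these reduce
    to the corresponding two-sample tests. Degenerate variance under ANOVA
    falls back to the rank test with a log entry; fully constant data return
    p = 1.
    """
    t = _check_table(trait_table)
    sub = t[t["trait"] == trait]
    if sub.empty:
        raise SchemaError(f"no records for trait {trait!r}")
    groups = [g["value"].to_numpy(float)
              for _, g in sub.groupby("generation")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise SchemaError("need >= 2 generations with >= 2 records each")
    if method not in ("anova", "kruskal"):
        raise ConfigurationError(f"unknown method {method!r}")
    values = np.concatenate(groups)
    if np.allclose(values, values[0]):
        return TestResult(0.0, 1.0, f"{method} (constant data)", len(groups))
    if method == "anova":
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = stats.f_oneway(*groups)
        if not np.isfinite(p):
            logger.info("degenerate within-group variance; falling back to "
                        "Kruskal-Wallis for trait %s", trait)
            stat, p = stats.kruskal(*groups)
            return TestResult(float(stat), float(p), "kruskal (fallback)",
                              len(groups))
        return TestResult(float(stat), float(p), "anova", len(groups))
    stat, p = stats.kruskal(*groups)
    return TestResult(float(stat), float(p), "kruskal", len(groups))
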