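"""Overlap-enrichment statistics: percent-difference enrichment, BH-FDR,
rank concordance between two methods' results, and the per-trait pipeline.

Overlap enrichment I is the percent difference between a trait's observed
gene-annotation overlap and the mean overlap of the length-matched random
background:  I = (observed - mean(background)) / mean(background) * 100.
Values above 0% indicate enrichment.  The per-base-pair statistic is primary
(its denominator matches the p-value statistic); the raw-count variant is
also reported for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .background import (
    BackgroundDistribution,
    build_background,
    intersections_per_bp,
    weibull_pvalue,
)
from .intervals import GenomeDefinition, IntervalSet, count_elements_with_overlap
from .mapping import ElementSet

__all__ = [
    "EnrichmentResult",
    "ConcordanceResult",
    "enrichment_percent",
    "bh_fdr",
    "rank_concordance",
    "run_trait",
    "finalize_results",
    "results_to_frame",
    "write_results_tsv",
    "read_results_tsv",
    "read_sldsc_results",
]

RESULT_COLUMNS = [
    "trait_id",
    "annot_id",
    "set_size",
    "observed",
    "bg_mean",
    "I_percent",
    "I_percent_count",
    "p",
    "q",
]


@dataclass
class EnrichmentResult:
    """One trait x annotation enrichment row."""

    trait_id: str
    annot_id: str
    set_size: int
    observed: float  # intersections per bp
    observed_count: int  # raw overlap count
    bg_mean: float
    I_percent: float | None  # per-bp enrichment (primary)
    I_percent_count: float | None
    p: float
    q: float | None = None
    fit_note: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class ConcordanceResult:
    statistic: float
    pvalue: float
    n_pairs: int
    degenerate: bool = False


def enrichment_percent(observed_overlap: float, bg_overlaps: Sequence[float]) -> float:
    """Signed percent difference of observed overlap vs the background mean."""
    bg_mean = float(np.mean(bg_overlaps))
    if bg_mean <= 0:
        raise ValueError(
            "enrichment undefined: background mean overlap is zero"
        )
    return (float(observed_overlap) - bg_mean) / bg_mean * 100.0


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_concordance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    value_col: str = "enrichment",
) -> ConcordanceResult:
    """Two-sided Wilcoxon signed-rank test on independently ranked results.

    Each table is converted to within-table ranks of its enrichment values
    *before* joining on (trait_id, annot_id); the signed-rank test is then
    applied to the paired rank differences.  Identical rankings give zero
    differences everywhere, reported as a degenerate p = 1.0.
    """
    keys = ["trait_id", "annot_id"]
    for label, df in (("a", a), ("b", b)):
        missing = set(keys + [value_col]) - set(df.columns)
        if missing:
            raise ValueError(f"table {label} missing columns: {sorted(missing)}")
        if df.duplicated(keys).any():
            raise ValueError(f"table {label} has duplicate (trait_id, annot_id) rows")
    a = a.assign(_rank=sps.rankdata(a[value_col]))
    b = b.assign(_rank=sps.rankdata(b[value_col]))
    paired = a[keys + ["_rank"]].merge(b[keys + ["_rank"]], on=keys, suffixes=("_a", "_b"))
    n_pairs = len(paired)
    if n_pairs == 0:
        raise ValueError("no paired rows between the two tables")
    if n_pairs < 6:
        import warnings

        warnings.warn(
            f"only {n_pairs} paired rows; signed-rank test is underpowered",
            stacklevel=2,
        )
    diffs = paired["_rank_a"].to_numpy() - paired["_rank_b"].to_numpy()
    if np.all(diffs == 0):
        return ConcordanceResult(0.0, 1.0, n_pairs, degenerate=True)
    nonzero = diffs[diffs != 0]
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not ties) else "approx"
    res = sps.wilcoxon(
        diffs, zero_method="wilcox", alternative="two-sided",
        correction=(method == "approx"), method=method,
    )
    return ConcordanceResult(float(res.statistic), float(res.pvalue), n_pairs)


def run_trait(
    es: ElementSet,
    annot: IntervalSet,
    genome: GenomeDefinition,
    annot_id: str = "annot",
    n_reps: int = 1000,
    rng_seed=None,
    count_mode: str = "unique",
) -> EnrichmentResult:
    """Observed statistic, length-matched background, enrichment, and p-value
    for one trait x annotation pair.  BH q-values are filled in per batch by
    :func:`finalize_results`.
    """
    observed_count = count_elements_with_overlap(es.elements, annot, mode=count_mode)
    observed = intersections_per_bp(es.elements, annot, mode=count_mode)
    bg = build_background(es, annot, genome, n_reps=n_reps, rng_seed=rng_seed)
    bg_mean = bg.mean
    degenerate = False
    if bg_mean > 0:
        I_bp = enrichment_percent(observed, bg.values)
        # raw-count variant: background counts are values * simulated total bp
        from .background import make_length_bins

        sim_bp = make_length_bins(es).total_bp
        bg_counts = bg.values * sim_bp
        I_count = enrichment_percent(observed_count, bg_counts)
    else:
        I_bp = None
        I_count = None
        degenerate = True
    p = weibull_pvalue(bg, observed)
    return EnrichmentResult(
        trait_id=es.trait_id,
        annot_id=annot_id,
        set_size=es.size,
        observed=observed,
        observed_count=observed_count,
        bg_mean=bg_mean,
        I_percent=I_bp,
        I_percent_count=I_count,
        p=p,
        fit_note=bg.fit_note,
        degenerate=degenerate,
    )


def finalize_results(
    results: Sequence[EnrichmentResult], family: str = "batch"
) -> list[EnrichmentResult]:
    """Fill BH q-values across a results batch.

    family="batch" corrects across every row of the invocation (the default,
    matching FDR correction over all results of an analysis); "per_annotation"
    corrects within each annotation separately.
    """
    results = list(results)
    if family == "batch":
        groups = {None: results}
    elif family == "per_annotation":
        groups = {}
        for r in results:
            groups.setdefault(r.annot_id, []).append(r)
    else:
        raise ValueError(f"unknown FDR family {family!r}")
    for rows in groups.values():
        qvals = bh_fdr([r.p for r in rows])
        for r, q in zip(rows, qvals):
            r.q = float(q)
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "trait_id": r.trait_id,
            "annot_id": r.annot_id,
            "set_size": r.set_size,
            "observed": r.observed,
            "bg_mean": r.bg_mean,
            "I_percent": r.I_percent,
            "I_percent_count": r.I_percent_count,
            "p": r.p,
            "q": r.q,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_tsv(results, path, header_lines: Sequence[str] = ()) -> None:
    """Write results with stable column order and fixed 6-decimal formatting."""
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            out = []
            for col, val in zip(RESULT_COLUMNS, row):
                if col in ("trait_id", "annot_id"):
                    out.append(str(val))
                elif col == "set_size":
                    out.append(str(int(val)))
                else:
                    out.append("NA" if val is None or (isinstance(val, float) and np.isnan(val)) else f"{val:.6f}")
            fh.write("\t".join(out) + "\n")


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


def read_sldsc_results(path, trait_id: str, annot_prefix: str = "L2_1") -> pd.DataFrame:
    """Adapter for a partitioned-heritability ``.results`` table.

    Reads the whitespace-delimited layout (Category, Prop._SNPs, Prop._h2,
    Enrichment, Enrichment_std_error, Enrichment_p) and returns the generic
    (trait_id, annot_id, enrichment, se, p) frame used by the concordance and
    meta-analysis stages.
    """
    df = pd.read_csv(path, sep=r"\s+")
    required = {"Category", "Enrichment", "Enrichment_std_error", "Enrichment_p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f".results table missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "trait_id": trait_id,
            "annot_id": df["Category"].str.replace(annot_prefix + "$", "", regex=True),
            "enrichment": df["Enrichment"].astype(float),
            "se": df["Enrichment_std_error"].astype(float),
            "p": df["Enrichment_p"].astype(float),
        }
    )
    return out
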