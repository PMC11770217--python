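"""Correlated random-effects meta-analysis of enrichment estimates.

Trait-level enrichment estimates within a category (e.g. skeletal,
psychiatric) are not independent: the underlying GWAS traits are genetically
correlated.  The model is

    y = mu * 1 + u + eps,      u ~ N(0, tau^2 I),
    Cov(eps) = diag(s) . R . diag(s)

where y are the per-trait estimates, s their standard errors, and R the
trait-trait (genetic) correlation matrix.  tau^2 is estimated by REML via a
bounded 1-D profile; mu by generalized least squares given tau^2.  An
alternative structure placing the correlation on the random effect
(Cov(u) = tau^2 R) is available behind the ``structure`` switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .enrichment import bh_fdr

__all__ = [
    "CategoryBlock",
    "MetaResult",
    "repair_correlation",
    "meta_random_effects",
    "meta_batch",
    "read_category_map",
    "read_correlation_matrix",
]

EIG_CLIP = 1e-8


def repair_correlation(R: np.ndarray) -> np.ndarray:
    """Symmetrize, clip negative eigenvalues, rescale to unit diagonal."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    if w.min() < EIG_CLIP:
        w = np.clip(w, EIG_CLIP, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class CategoryBlock:
    """Effect estimates, SEs, and trait correlation for one category."""

    category: str
    traits: list
    y: np.ndarray
    s: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        n = len(self.y)
        if not (len(self.s) == n == len(self.traits)):
            raise ValueError("y, s, traits length mismatch")
        if np.any(self.s <= 0):
            raise ValueError(f"category {self.category!r}: standard errors must be > 0")
        R = np.asarray(self.R, dtype=float)
        if R.shape != (n, n):
            raise ValueError(f"category {self.category!r}: R must be {n}x{n}")
        self.R = repair_correlation(R)


@dataclass(frozen=True)
class MetaResult:
    category: str
    annot_id: Optional[str]
    n_traits: int
    mu_hat: float
    se_mu: float
    z: float
    p: float
    tau2: float
    q: Optional[float] = None


def _build_V(block: CategoryBlock, tau2: float, structure: str) -> np.ndarray:
    Sigma = np.outer(block.s, block.s) * block.R
    if structure == "sampling":
        return Sigma + tau2 * np.eye(len(block.y))
    if structure == "tau2R":
        return Sigma + tau2 * block.R
    raise ValueError(f"unknown variance structure {structure!r}")


def _reml_neg_loglik(tau2: float, block: CategoryBlock, structure: str) -> float:
    V = _build_V(block, tau2, structure)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    one = np.ones(len(block.y))
    Vi_y = np.linalg.solve(V, block.y)
    Vi_1 = np.linalg.solve(V, one)
    denom = one @ Vi_1
    mu = (one @ Vi_y) / denom
    resid = block.y - mu
    quad = resid @ np.linalg.solve(V, resid)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return 0.5 * (logdet + np.log(denom) + quad)


def meta_random_effects(
    block: CategoryBlock, structure: str = "sampling", tau2: float | None = None
) -> MetaResult:
    """REML random-effects summary estimate for one category block.

    Pass ``tau2`` to fix the between-trait variance instead of estimating it
    (e.g. tau2=0 gives the common-effect GLS / inverse-variance estimator).
    """
    n = len(block.y)
    if n == 1:
        mu, se = float(block.y[0]), float(block.s[0])
        z = mu / se
        return MetaResult(
            block.category, None, 1, mu, se, z,
            float(2 * stats.norm.sf(abs(z))), 0.0,
        )
    if tau2 is None:
        var_y = float(np.var(block.y, ddof=1))
        hi = max(10.0 * var_y, 1e-6)
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(0.0, hi), args=(block, structure),
            method="bounded", options={"xatol": 1e-10},
        )
        tau2 = float(res.x)
        # prefer the boundary when it is at least as good (bounded search
        # never evaluates exactly 0)
        if _reml_neg_loglik(0.0, block, structure) <= res.fun + 1e-10:
            tau2 = 0.0
    elif tau2 < 0:
        raise ValueError("tau2 must be nonnegative")
    V = _build_V(block, tau2, structure)
    one = np.ones(n)
    try:
        Vi_1 = np.linalg.solve(V, one)
        Vi_y = np.linalg.solve(V, block.y)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            f"singular covariance for category {block.category!r}"
        ) from None
    denom = float(one @ Vi_1)
    if denom <= 0 or not np.isfinite(denom):
        raise np.linalg.LinAlgError(
            f"singular covariance for category {block.category!r}"
        )
    mu = float(one @ Vi_y) / denom
    se = denom ** -0.5
    z = mu / se
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaResult(block.category, None, n, mu, se, z, p, tau2)


def meta_batch(
    table: pd.DataFrame,
    categories: Mapping[str, str],
    R_full: pd.DataFrame,
    structure: str = "sampling",
) -> list[MetaResult]:
    """One random-effects meta-analysis per (category, annotation) with BH-FDR.

    ``table`` needs columns trait_id, annot_id, enrichment, se; ``categories``
    maps trait_id -> category; ``R_full`` is a trait x trait correlation frame
    indexed and columned by trait id.  Traits missing an SE or a category are
    excluded with a warning.
    """
    required = {"trait_id", "annot_id", "enrichment", "se"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    table = table.copy()
    bad_se = table["se"].isna() | (table["se"] <= 0)
    if bad_se.any():
        warnings.warn(
            f"excluding {int(bad_se.sum())} rows with missing/non-positive SE",
            stacklevel=2,
        )
        table = table[~bad_se]
    known = table["trait_id"].isin(categories)
    if (~known).any():
        unknowns = sorted(table.loc[~known, "trait_id"].unique())
        warnings.warn(f"traits without category, excluded: {unknowns}", stacklevel=2)
        table = table[known]
    table["category"] = table["trait_id"].map(categories)

    results: list[MetaResult] = []
    for (annot_id, category), grp in table.groupby(["annot_id", "category"], sort=True):
        traits = grp["trait_id"].tolist()
        in_R = [t for t in traits if t in R_full.index and t in R_full.columns]
        if len(in_R) < len(traits):
            dropped = sorted(set(traits) - set(in_R))
            warnings.warn(
                f"traits absent from correlation matrix, excluded: {dropped}",
                stacklevel=2,
            )
            grp = grp[grp["trait_id"].isin(in_R)]
            traits = in_R
        if len(traits) == 0:
            continue
        R = R_full.loc[traits, traits].to_numpy(dtype=float)
        block = CategoryBlock(
            category=category,
            traits=traits,
            y=grp["enrichment"].to_numpy(dtype=float),
            s=grp["se"].to_numpy(dtype=float),
            R=R,
        )
        r = meta_random_effects(block, structure=structure)
        results.append(
            MetaResult(
                category, annot_id, r.n_traits, r.mu_hat, r.se_mu, r.z, r.p, r.tau2
            )
        )
    if results:
        qvals = bh_fdr([r.p for r in results])
        results = [
            MetaResult(
                r.category, r.annot_id, r.n_traits, r.mu_hat, r.se_mu, r.z, r.p,
                r.tau2, float(q),
            )
            for r, q in zip(results, qvals)
        ]
    return results


def read_category_map(path) -> dict[str, str]:
    """Read a two-column TSV (trait_id, category) with header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"trait_id", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"category map missing columns: {sorted(missing)}")
    return dict(zip(df["trait_id"], df["category"]))


def read_correlation_matrix(path) -> pd.DataFrame:
    """Read a square TSV with trait ids as header row and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("correlation matrix row and column trait ids differ")
    return df.astype(float)
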