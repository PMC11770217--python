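"""Length-matched resampling null and Weibull tail p-values.

The test statistic for a trait is *intersections per base pair*: the number
of element-set genes overlapping an annotation divided by the element set's
total length.  Because gene lengths are heavy-tailed, the null distribution
is built by resampling random genomic intervals that match the element set's
length profile: elements are binned into length deciles, and each replicate
draws, per decile, the bin's count of intervals at the bin's mean length,
placed uniformly on the genome.  A two-parameter Weibull fitted to the
replicate values by maximum likelihood supplies an upper-tail p-value for
the observed statistic; when the fit is ill-posed (mostly-zero or constant
backgrounds) the empirical rank p-value is used instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomeDefinition, IntervalSet, count_elements_with_overlap
from .mapping import ElementSet

__all__ = [
    "LengthBins",
    "BackgroundDistribution",
    "make_length_bins",
    "sample_background_set",
    "intersections_per_bp",
    "build_background",
    "weibull_pvalue",
]

N_DECILES = 10
DEFAULT_N_REPS = 1000
#: if more than this fraction of replicates is zero, skip the Weibull fit
MAX_ZERO_FRACTION = 0.5


@dataclass(frozen=True)
class LengthBins:
    """Decile length profile of an element set: (count, mean length) pairs."""

    bins: tuple  # of (n_k, l_k)

    def __post_init__(self):
        for n_k, l_k in self.bins:
            if n_k < 0 or (n_k > 0 and l_k < 1):
                raise ValueError(f"invalid length bin (n={n_k}, l={l_k})")

    @property
    def total_elements(self) -> int:
        return sum(n for n, _ in self.bins)

    @property
    def total_bp(self) -> int:
        return sum(n * l for n, l in self.bins)


@dataclass
class BackgroundDistribution:
    """Resampled intersections-per-bp values plus the fitted Weibull null."""

    values: np.ndarray
    weibull_shape: float | None
    weibull_scale: float | None
    n_zero: int
    fit_note: str = ""
    seed: int | None = None

    @property
    def fit_ok(self) -> bool:
        return self.weibull_shape is not None

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_reps": int(len(self.values)),
                "weibull_shape": self.weibull_shape,
                "weibull_scale": self.weibull_scale,
                "n_zero": int(self.n_zero),
                "fit_note": self.fit_note,
                "seed": self.seed,
            }
        )


def make_length_bins(es: ElementSet | IntervalSet, n_bins: int = N_DECILES) -> LengthBins:
    """Split element lengths into contiguous sorted-index decile bins.

    Bin k (0-based) covers sorted indices floor(k*N/10) .. floor((k+1)*N/10)-1;
    ties in length stay in sorted order.  Mean lengths round to integer bp
    (at least 1).
    """
    intervals = es.elements if isinstance(es, ElementSet) else es
    lengths = np.sort(intervals.lengths)
    n = len(lengths)
    if n == 0:
        raise ValueError("cannot bin an empty element set")
    edges = [(k * n) // n_bins for k in range(n_bins + 1)]
    bins = []
    for k in range(n_bins):
        chunk = lengths[edges[k] : edges[k + 1]]
        if len(chunk) == 0:
            bins.append((0, 0))
        else:
            bins.append((int(len(chunk)), max(1, int(round(float(np.mean(chunk)))))))
    return LengthBins(tuple(bins))


def _placement_arrays(bins: LengthBins, genome: GenomeDefinition):
    """Per-bin chromosome weights and start ranges for uniform placement."""
    chrom_names = list(genome.chromosomes)
    chrom_lengths = np.array([genome.chromosomes[c] for c in chrom_names], dtype=np.int64)
    per_bin = []
    for n_k, l_k in bins.bins:
        if n_k == 0:
            per_bin.append(None)
            continue
        slots = chrom_lengths - l_k + 1  # number of valid start positions
        valid = slots > 0
        if not np.any(valid):
            raise ValueError(
                f"bin length {l_k} bp exceeds every chromosome in build "
                f"{genome.build_label!r}"
            )
        weights = np.where(valid, slots, 0).astype(float)
        per_bin.append((weights / weights.sum(), slots))
    return chrom_names, per_bin


def sample_background_set(
    bins: LengthBins, genome: GenomeDefinition, rng_seed
) -> IntervalSet:
    """One length-matched random interval set placed uniformly on the genome.

    Chromosomes are chosen with probability proportional to the number of
    valid start positions (length - l + 1); starts are uniform.
    """
    rng = np.random.default_rng(rng_seed)
    chrom_names, per_bin = _placement_arrays(bins, genome)
    rows = []
    for (n_k, l_k), placement in zip(bins.bins, per_bin):
        if n_k == 0:
            continue
        probs, slots = placement
        chrom_idx = rng.choice(len(chrom_names), size=n_k, p=probs)
        starts = rng.integers(0, slots[chrom_idx])  # uniform over [0, L - l]
        for ci, st in zip(chrom_idx, starts):
            rows.append((chrom_names[ci], int(st), int(st) + l_k))
    return IntervalSet.from_intervals(rows, build_label=genome.build_label)


def intersections_per_bp(
    elements: IntervalSet, annot: IntervalSet, mode: str = "unique"
) -> float:
    """Overlap count divided by the element set's total base pairs."""
    total = elements.total_bp
    if total == 0:
        raise ValueError("intersections_per_bp undefined for empty element set")
    return count_elements_with_overlap(elements, annot, mode=mode) / total


def _background_values(
    bins: LengthBins,
    annot: IntervalSet,
    genome: GenomeDefinition,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized replicate statistics: all bins and replicates drawn at once."""
    chrom_names = list(genome.chromosomes)
    _, per_bin = _placement_arrays(bins, genome)
    annot_slices = annot.chrom_slices()
    total_bp = bins.total_bp
    counts = np.zeros(n_reps, dtype=np.int64)
    for (n_k, l_k), placement in zip(bins.bins, per_bin):
        if n_k == 0:
            continue
        probs, slots = placement
        size = n_reps * n_k
        chrom_idx = rng.choice(len(slots), size=size, p=probs)
        starts = rng.integers(0, slots[chrom_idx])
        ends = starts + l_k
        overlaps = np.zeros(size, dtype=bool)
        for ci, chrom in enumerate(chrom_names):
            asl = annot_slices.get(chrom)
            if asl is None:
                continue
            mask = chrom_idx == ci
            if not np.any(mask):
                continue
            ann_starts, ann_ends = annot.starts[asl], annot.ends[asl]
            idx = np.searchsorted(ann_starts, ends[mask], side="left")
            hit = idx > 0
            hit[hit] = ann_ends[idx[hit] - 1] > starts[mask][hit]
            overlaps[mask] = hit
        counts += overlaps.reshape(n_reps, n_k).sum(axis=1)
    return counts / total_bp


def _fit_weibull(positive: np.ndarray):
    shape, _, scale = stats.weibull_min.fit(positive, floc=0)
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise ValueError("Weibull MLE did not converge to finite positive parameters")
    return float(shape), float(scale)


def build_background(
    es: ElementSet | LengthBins,
    annot: IntervalSet,
    genome: GenomeDefinition,
    n_reps: int = DEFAULT_N_REPS,
    rng_seed=None,
) -> BackgroundDistribution:
    """Resample n_reps length-matched sets and fit the Weibull null.

    Zero-valued replicates are excluded from the MLE (Weibull support is
    x > 0).  If more than half the replicates are zero, or the positive
    values are (near-)constant, the fit is skipped and p-values fall back to
    the empirical rank; the condition is recorded in ``fit_note``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not annot.merged:
        raise ValueError("annotation must be merged before background sampling")
    bins = es if isinstance(es, LengthBins) else make_length_bins(es)
    rng = np.random.default_rng(rng_seed)
    values = _background_values(bins, annot, genome, n_reps, rng)
    n_zero = int(np.sum(values == 0))
    seed_repr = rng_seed if isinstance(rng_seed, (int, np.integer)) else None

    positive = values[values > 0]
    if n_zero > MAX_ZERO_FRACTION * n_reps:
        return BackgroundDistribution(
            values, None, None, n_zero,
            fit_note=f"{n_zero}/{n_reps} zero replicates; empirical rank p-value",
            seed=seed_repr,
        )
    if np.ptp(positive) == 0:
        return BackgroundDistribution(
            values, None, None, n_zero,
            fit_note="degenerate background (constant positive values); "
            "empirical rank p-value",
            seed=seed_repr,
        )
    try:
        shape, scale = _fit_weibull(positive)
    except Exception as exc:  # fit failure is a flagged fallback, not fatal
        return BackgroundDistribution(
            values, None, None, n_zero,
            fit_note=f"Weibull fit failed ({exc}); empirical rank p-value",
            seed=seed_repr,
        )
    note = "" if n_zero == 0 else f"{n_zero} zero replicates excluded from MLE"
    return BackgroundDistribution(values, shape, scale, n_zero, fit_note=note, seed=seed_repr)


def weibull_pvalue(bg: BackgroundDistribution, observed: float) -> float:
    """Upper-tail P(X >= observed) under the fitted null.

    exp(-(observed/scale)^shape) when the Weibull fit succeeded, otherwise the
    empirical rank (1 + #{values >= observed}) / (n + 1).
    """
    if observed < 0:
        raise ValueError("observed statistic must be nonnegative")
    if bg.fit_ok:
        return float(np.exp(-((observed / bg.weibull_scale) ** bg.weibull_shape)))
    n = len(bg.values)
    return float((1 + np.sum(bg.values >= observed)) / (n + 1))
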