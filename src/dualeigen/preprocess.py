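"""Spatial chip normalization and robust probe-set summarization.

Spatial variation (uneven hybridization, washing) dominates the unwanted
variance of probe-level arrays.  The *sub-sub* scheme normalizes a target
chip against a reference chip locally: the grid is decomposed into
overlapping square subarrays (default 50x50, overlap 25), within each
window a one-knot piecewise-linear map from target to reference intensity
is fitted by least trimmed squares (LTS), each probe is pushed through the
fitted map, and probes covered by several windows receive the average of
their adjusted values.  All fitting is on the log2 scale.

Summarization collapses the 11 probes of a probe set into one value per
chip with an additive probe + chip model fitted by median polish; a set of
designated reference chips participates in every fit and is dropped from
the reported profile (a probe/treatment/reference layout).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .profiles import ExpressionProfile


@dataclass
class ProbeChip:
    """2-D probe intensity grid (log2 scale) with a probe-set map.

    ``probeset_map`` assigns each grid cell the id of its probe set
    (empty string = unmapped control/border cell).
    """

    values: np.ndarray        # (rows, cols) float, log2 intensities
    probeset_map: np.ndarray  # (rows, cols) str ids, "" = unmapped

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probeset_map = np.asarray(self.probeset_map)
        if self.values.ndim != 2:
            raise ValueError("chip values must be a 2-D grid")
        if self.values.shape != self.probeset_map.shape:
            raise ValueError("intensity grid and probeset map differ in shape")
        if not np.isfinite(self.values).all():
            raise ValueError("chip intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SubsubConfig:
    subarray_size: int = 50
    overlap: int = 25
    lts_coverage_fraction: float = 0.75
    knot_quantiles: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    exhaustive_limit: int = 20000     # max C(n, h) for the exact small-n path
    n_random_starts: int = 5          # concentration-step restarts for large n
    max_csteps: int = 30

    def validate(self) -> None:
        if not (0 < self.overlap < self.subarray_size):
            raise ValueError("require 0 < overlap < subarray_size")
        if not (0.5 <= self.lts_coverage_fraction <= 1.0):
            raise ValueError("lts_coverage_fraction must be in [0.5, 1]")


@dataclass
class PiecewiseFit:
    """One-knot continuous piecewise-linear LTS fit y ~ f(x).

    Parametrized as f(x) = b0 + b1*x + b2*max(x - knot, 0); the two
    segments are continuous at the knot by construction.
    """

    knot: float
    coef: np.ndarray            # (b0, b1, b2)
    trimmed_rss: float
    h: int                      # coverage count
    degenerate: bool = False    # all-constant x fallback

    @property
    def left_slope(self) -> float:
        return float(self.coef[1])

    @property
    def left_intercept(self) -> float:
        return float(self.coef[0])

    @property
    def right_slope(self) -> float:
        return float(self.coef[1] + self.coef[2])

    @property
    def right_intercept(self) -> float:
        return float(self.coef[0] - self.coef[2] * self.knot)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.coef[0] + self.coef[1] * x + self.coef[2] * np.maximum(x - self.knot, 0.0)


# ----------------------------------------------------------------------
# window partition
# ----------------------------------------------------------------------

def _axis_starts(length: int, size: int, step: int) -> list[int]:
    starts = list(range(0, length - size + 1, step))
    if starts[-1] + size < length:
        starts.append(length - size)   # edge-anchored final window
    return starts


def partition_subarrays(rows: int, cols: int, config: SubsubConfig) -> list[tuple[int, int, int]]:
    """Ordered (row_start, col_start, size) windows covering the whole grid.

    Regular starts every ``size - overlap`` cells; if the last regular
    window misses the edge, one extra window anchored at ``length - size``
    is appended per axis.
    """
    config.validate()
    size = config.subarray_size
    if rows < size or cols < size:
        raise ValueError("grid smaller than the subarray size")
    step = size - config.overlap
    return [
        (r, c, size)
        for r in _axis_starts(rows, size, step)
        for c in _axis_starts(cols, size, step)
    ]


# ----------------------------------------------------------------------
# least trimmed squares
# ----------------------------------------------------------------------

def _design(x: np.ndarray, knot: float) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, np.maximum(x - knot, 0.0)])


def _knot_candidates(x: np.ndarray, config: SubsubConfig) -> list[float]:
    lo, hi = x.min(), x.max()
    cands = np.unique(np.quantile(x, config.knot_quantiles))
    return [float(k) for k in cands if lo < k < hi]


def _location_lts(y: np.ndarray, h: int) -> tuple[float, float]:
    """Exact LTS for a constant model: best h-window of the sorted sample."""
    ys = np.sort(y)
    n = len(ys)
    best = (math.inf, ys.mean())
    for i in range(n - h + 1):
        w = ys[i: i + h]
        mu = w.mean()
        rss = float(((w - mu) ** 2).sum())
        if rss < best[0]:
            best = (rss, float(mu))
    return best[1], best[0]


_TIE_TOL = 1e-10

#: minimum subset points strictly on each side of the knot; with fewer the
#: knotted segment is unconstrained by the trimmed subset and the fit
#: collapses to a single line on that subset
MIN_SEGMENT_SUPPORT = 3


def _better(cand: tuple, best: tuple | None) -> bool:
    """Strictly-smaller trimmed RSS wins; near-ties keep the earlier candidate."""
    if best is None:
        return True
    return cand[0] < best[0] - _TIE_TOL * (1.0 + best[0])


def _exhaustive_lts(x: np.ndarray, y: np.ndarray, knots: list[float], h: int):
    """Exact LTS over every h-subset, batched per knot candidate.

    Subsets whose points do not support both segments (fewer than
    MIN_SEGMENT_SUPPORT on either side of the knot) are fitted as a single
    line; otherwise the full one-knot model is fitted.
    """
    n = len(x)
    subsets = np.array(list(itertools.combinations(range(n), h)))
    xs_sub = x[subsets]                       # (nsub, h)
    ys = y[subsets]
    # single-line fits are knot-independent: compute once
    X2 = np.stack([np.ones_like(x), x], axis=1)
    X2s = X2[subsets]                         # (nsub, h, 2)
    xtx2 = np.einsum("nhi,nhj->nij", X2s, X2s)
    xty2 = np.einsum("nhi,nh->ni", X2s, ys)
    beta2 = np.einsum("nij,nj->ni", np.linalg.pinv(xtx2), xty2)
    rss2 = ((ys - np.einsum("nhi,ni->nh", X2s, beta2)) ** 2).sum(axis=1)

    best = None
    for knot in knots:
        below = (xs_sub < knot).sum(axis=1)
        supported = (below >= MIN_SEGMENT_SUPPORT) & (h - below >= MIN_SEGMENT_SUPPORT)
        X = _design(x, knot)
        Xs = X[subsets]                       # (nsub, h, 3)
        xtx = np.einsum("nhi,nhj->nij", Xs, Xs)
        xty = np.einsum("nhi,nh->ni", Xs, ys)
        beta3 = np.einsum("nij,nj->ni", np.linalg.pinv(xtx), xty)
        rss3 = ((ys - np.einsum("nhi,ni->nh", Xs, beta3)) ** 2).sum(axis=1)
        rss = np.where(supported, rss3, rss2)
        i = int(np.argmin(rss))
        if supported[i]:
            cand = (float(rss[i]), knot, beta3[i])
        else:
            cand = (float(rss[i]), knot, np.array([beta2[i, 0], beta2[i, 1], 0.0]))
        if _better(cand, best):
            best = cand
    return best


def _cstep_lts(x: np.ndarray, y: np.ndarray, knots: list[float], h: int, config: SubsubConfig):
    """FAST-LTS style concentration steps from deterministic seeded starts."""
    n = len(x)
    rng = default_rng(0)   # internal: fit is deterministic given inputs/config
    starts = [np.arange(n)[np.argsort(np.abs(y - np.median(y)), kind="stable")[:h]]]
    for _ in range(config.n_random_starts):
        starts.append(rng.choice(n, size=h, replace=False))
    def fit_subset(X3, knot, subset):
        """Knot model when both segments are supported, else a single line."""
        xs = x[subset]
        below = int((xs < knot).sum())
        if below >= MIN_SEGMENT_SUPPORT and len(subset) - below >= MIN_SEGMENT_SUPPORT:
            Xs = X3[subset]
        else:
            Xs = X3[subset][:, :2]
        ys = y[subset]
        try:
            beta = np.linalg.solve(Xs.T @ Xs, Xs.T @ ys)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        if len(beta) == 2:
            beta = np.array([beta[0], beta[1], 0.0])
        return beta

    best = None
    for knot in knots:
        X = _design(x, knot)
        for subset in starts:
            subset = np.sort(subset)
            prev = None
            beta = None
            for _ in range(config.max_csteps):
                beta = fit_subset(X, knot, subset)
                resid_all = y - X @ beta
                new = np.sort(np.argpartition(resid_all**2, h - 1)[:h])
                if prev is not None and np.array_equal(new, prev):
                    break
                prev, subset = subset, new
            rss = float(((y[subset] - X[subset] @ beta) ** 2).sum())
            cand = (rss, knot, beta)
            if _better(cand, best):
                best = cand
    return best


def fit_piecewise_lts(x: np.ndarray, y: np.ndarray, config: SubsubConfig | None = None) -> PiecewiseFit:
    """One-knot piecewise-linear least-trimmed-squares fit of y on x.

    Knot candidates are interior deciles of x; for each candidate the LTS
    criterion (sum of the h smallest squared residuals, h = ceil(coverage
    fraction * n)) is minimized — exactly, over all h-subsets, when C(n, h)
    is small; otherwise by seeded concentration steps.  Deterministic given
    inputs and config.
    """
    config = config or SubsubConfig()
    config.validate()
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 6:
        raise ValueError("need at least 6 points for a one-knot piecewise fit")
    h = math.ceil(config.lts_coverage_fraction * n)

    if np.ptp(x) == 0.0:
        mu, rss = _location_lts(y, h)
        return PiecewiseFit(knot=float(x[0]), coef=np.array([mu, 0.0, 0.0]),
                            trimmed_rss=rss, h=h, degenerate=True)

    knots = _knot_candidates(x, config)
    if not knots:
        knots = [float(np.median(x))]   # ties collapse the deciles; midpoint knot
    if math.comb(n, h) <= config.exhaustive_limit:
        rss, knot, beta = _exhaustive_lts(x, y, knots, h)
    else:
        rss, knot, beta = _cstep_lts(x, y, knots, h, config)
    return PiecewiseFit(knot=float(knot), coef=np.asarray(beta, dtype=float),
                        trimmed_rss=float(rss), h=h)


# ----------------------------------------------------------------------
# sub-sub normalization
# ----------------------------------------------------------------------

def subsub_normalize(target: ProbeChip, reference: ProbeChip,
                     config: SubsubConfig | None = None) -> ProbeChip:
    """Adjust a target chip toward a reference chip, window by window.

    Within each window the reference intensity is regressed on the target
    intensity (one-knot piecewise LTS) and each target probe is replaced by
    its fitted reference-scale value; probes in several windows get the
    mean of their adjusted values.  A window where target and reference
    agree elementwise is the identity map, making self-normalization exact.
    """
    config = config or SubsubConfig()
    if target.shape != reference.shape:
        raise ValueError("target and reference chip geometries differ")
    rows, cols = target.shape
    windows = partition_subarrays(rows, cols, config)

    delta_sum = np.zeros((rows, cols))
    counts = np.zeros((rows, cols))
    for r0, c0, size in windows:
        sl = (slice(r0, r0 + size), slice(c0, c0 + size))
        tx = target.values[sl].ravel()
        ty = reference.values[sl].ravel()
        counts[sl] += 1.0
        if np.array_equal(tx, ty):
            continue   # identity window: zero adjustment
        fit = fit_piecewise_lts(tx, ty, config)
        delta = (fit.predict(tx) - tx).reshape(size, size)
        delta_sum[sl] += delta
    adjusted = target.values + delta_sum / counts
    return ProbeChip(adjusted, target.probeset_map.copy())


# ----------------------------------------------------------------------
# probe + chip summarization (median polish)
# ----------------------------------------------------------------------

def median_polish(mat: np.ndarray, max_iter: int = 20, tol: float = 1e-10):
    """Tukey median polish of an additive two-way table.

    Returns (overall, row_effects, col_effects, residuals) with row and
    column effects median-constrained to zero.
    """
    z = np.asarray(mat, dtype=float).copy()
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        rmed = np.median(z, axis=1)
        z -= rmed[:, None]
        row += rmed
        shift = np.median(row)
        row -= shift
        overall += shift
        cmed = np.median(z, axis=0)
        z -= cmed[None, :]
        col += cmed
        shift = np.median(col)
        col -= shift
        overall += shift
        if max(np.abs(rmed).max(), np.abs(cmed).max()) < tol:
            break
    return overall, row, col, z


@dataclass
class SummarizationResult:
    profile: ExpressionProfile          # probe sets x non-reference chips
    flagged_probesets: list = field(default_factory=list)


def summarize_ptr(chips: dict[str, ProbeChip], references: list[str],
                  min_probes: int = 2) -> SummarizationResult:
    """Summarize normalized chips into one log2 value per probe set per chip.

    Per probe set, fits log2 I(probe p, chip j) = mu + alpha_p + beta_j by
    median polish (probe effects median-constrained to 0) across *all*
    chips including the designated references; the reported expression on
    chip j is mu + beta_j, and reference chips are excluded from the output
    profile.  Probe sets with fewer than ``min_probes`` probes fall back to
    the per-chip mean and are flagged.
    """
    if not references:
        raise ValueError("at least one reference chip must be designated")
    unknown = set(references) - set(chips)
    if unknown:
        raise KeyError(f"unknown reference chips: {sorted(unknown)}")
    names = list(chips)
    first = chips[names[0]]
    for name in names[1:]:
        if not np.array_equal(chips[name].probeset_map, first.probeset_map):
            raise ValueError("all chips must share the same probeset map")

    flat_map = first.probeset_map.ravel()
    mapped = flat_map != ""
    order = np.argsort(flat_map[mapped], kind="stable")
    idx_mapped = np.where(mapped)[0][order]
    ids_sorted = flat_map[idx_mapped]
    set_ids, set_starts = np.unique(ids_sorted, return_index=True)
    boundaries = np.append(set_starts, len(ids_sorted))

    stack = np.stack([chips[name].values.ravel() for name in names], axis=1)

    rows = np.empty((len(set_ids), len(names)))
    flagged: list[str] = []
    for si in range(len(set_ids)):
        probes = idx_mapped[boundaries[si]: boundaries[si + 1]]
        block = stack[probes, :]    # (n_probes, n_chips)
        if block.shape[0] < min_probes:
            flagged.append(str(set_ids[si]))
            rows[si] = block.mean(axis=0)
            continue
        overall, _, col, _ = median_polish(block)
        rows[si] = overall + col

    values = pd.DataFrame(rows, index=pd.Index(set_ids, name="gene_id"), columns=names)
    keep = [name for name in names if name not in set(references)]
    if not keep:
        raise ValueError("every chip is a reference; nothing to report")
    return SummarizationResult(
        profile=ExpressionProfile(values[keep]), flagged_probesets=flagged
    )
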