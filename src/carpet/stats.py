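"""Statistical kernel: rank/product-moment correlation, equal-count binning, mean +/- SEM.

Every analysis stage funnels through these four primitives, so they are kept
dependency-light and deterministic.  The correlations are implemented from
first principles (average-rank Spearman, product-moment Pearson) so that the
test suite can check them against an independent reference implementation
rather than restating it.

Conventions (documented, deterministic):

* ties receive average ranks (the standard Spearman convention);
* "equal-sized" bins whose count does not divide n differ in size by at most
  one, with the larger bins at the low end of the sorted covariate;
* the SEM of a singleton group is defined as 0 so tables never hold NaN;
* R^2 is the square of the correlation coefficient (not a regression R^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidInputError


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    method: str  # "spearman" | "pearson"
    n_points: int
    input_kind: str = "unbinned"  # "unbinned" | "binned_means"


@dataclass(frozen=True)
class BinSummary:
    bin_index: int
    mean_covariate: float
    mean_response: float
    sem_response: float
    n_members: int


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise InvalidInputError("inputs must be one-dimensional")
    if x.size != y.size:
        raise InvalidInputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InvalidInputError(f"need at least 3 points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidInputError("inputs contain non-finite values; filter first")
    return x, y


def rankdata_average(a: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their ranks."""
    a = np.asarray(a, dtype=float)
    order = np.argsort(a, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(a.size)
    sorted_a = a[order]
    # group boundaries of equal values in sorted order
    boundary = np.concatenate([[True], sorted_a[1:] != sorted_a[:-1]])
    group_id = np.cumsum(boundary) - 1
    counts = np.bincount(group_id)
    firsts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    avg_rank = firsts[group_id] + (counts[group_id] + 1) / 2.0
    return avg_rank[inv]


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero variance in correlation input")
    return float(np.dot(xc, yc) / (sx * sy))


def pearson_r2(x, y) -> CorrelationResult:
    """Squared Pearson product-moment correlation."""
    x, y = _check_xy(x, y)
    r = _pearson_r(x, y)
    return CorrelationResult(min(r * r, 1.0), "pearson", x.size)


def spearman_r2(x, y, input_kind: str = "unbinned") -> CorrelationResult:
    """Squared Spearman rank correlation on average-ranked data."""
    x, y = _check_xy(x, y)
    r = _pearson_r(rankdata_average(x), rankdata_average(y))
    return CorrelationResult(min(r * r, 1.0), "spearman", x.size, input_kind)


def mean_sem(values) -> tuple[float, float]:
    """Arithmetic mean and standard error (n-1 denominator; 0 for n == 1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("mean_sem of empty input")
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def equal_count_bins(values, n_bins: int) -> np.ndarray:
    """Assign each input index to one of ``n_bins`` rank bins.

    Values are stably sorted (ties keep input order) and split into contiguous
    groups whose sizes differ by at most one; when n is not divisible the
    larger groups sit at the low end.  Returns the bin index per *input*
    position.
    """
    v = np.asarray(values, dtype=float)
    if n_bins < 1:
        raise InvalidInputError("n_bins must be >= 1")
    if v.size < n_bins:
        raise InvalidInputError(f"cannot split {v.size} values into {n_bins} bins")
    order = np.argsort(v, kind="stable")
    base, rem = divmod(v.size, n_bins)
    sizes = np.full(n_bins, base, dtype=np.int64)
    sizes[:rem] += 1
    bin_of_sorted = np.repeat(np.arange(n_bins), sizes)
    assignment = np.empty(v.size, dtype=np.int64)
    assignment[order] = bin_of_sorted
    return assignment


def summarize_bins(covariate, response, n_bins: int) -> list[BinSummary]:
    """Equal-count bins of ``covariate``; mean +/- SEM of ``response`` per bin.

    Bins are returned ordered by increasing mean covariate (coincides with bin
    index because binning is contiguous in sorted covariate order).
    """
    cov = np.asarray(covariate, dtype=float)
    resp = np.asarray(response, dtype=float)
    if cov.size != resp.size:
        raise InvalidInputError("covariate/response length mismatch")
    assignment = equal_count_bins(cov, n_bins)
    out = []
    for b in range(n_bins):
        mask = assignment == b
        m_resp, sem = mean_sem(resp[mask])
        m_cov, _ = mean_sem(cov[mask])
        out.append(BinSummary(b, m_cov, m_resp, sem, int(mask.sum())))
    out.sort(key=lambda s: (s.mean_covariate, s.bin_index))
    return out
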