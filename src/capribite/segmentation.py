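"""Segmentation-clustering of cumulative intake curves.

The cumulative intake curve of a goat-day is approximately piecewise linear:
eating bouts are stretches of roughly constant slope and pauses are flat.
This module (i) cuts a curve into linear segments at slope change-points by
exact penalized dynamic programming, (ii) classifies the pooled segment
slopes of a dataset into eight ordered clusters (8 = fastest eating, 1 = no
eating), and (iii) applies the first-meal rule: the first meal accumulates
the intake of eating segments (clusters >= 3) and ends at the first
near-zero-slope segment (clusters <= 2) lasting at least 30 min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .profiles import IntakeProfile

MIN_SEGMENT_LEN = 2  # samples


@dataclass
class Segment:
    t_start: float  # minutes, inclusive
    t_end: float  # minutes, exclusive
    slope: float  # g DM/kg BW per min (OLS within the segment)
    intake: float  # g DM/kg BW gained over the segment
    cluster: int | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ClusterModel:
    """Eight ordered slope classes; centroid ascending = cluster 1..k.

    ``boundaries`` are the decision thresholds between consecutive clusters
    (midpoints between centroids in the space the model was fitted in; raw
    midpoints when constructed directly).
    """

    centroids: np.ndarray  # ascending, raw slope units
    k: int = 8
    boundaries_: np.ndarray | None = None

    @property
    def boundaries(self) -> np.ndarray:
        if self.boundaries_ is not None:
            return self.boundaries_
        return (self.centroids[:-1] + self.centroids[1:]) / 2.0

    def label(self, slopes) -> np.ndarray:
        """Nearest-centroid labels 1..k; a slope exactly on a boundary goes
        to the lower-slope cluster."""
        slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
        return np.searchsorted(self.boundaries, slopes, side="left") + 1


@dataclass
class MealResult:
    first_meal_end: float  # minutes
    first_meal_intake: float  # g DM/kg BW
    n_segments_in_meal: int
    ended_by_pause: bool  # False if the meal ran to the window end


def _segment_cost_matrix(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """cost[i, j] = SSE of the OLS line through points i..j-1 (inf if j-i < 2).

    Built from prefix sums so the full n x n table is O(n^2).
    """
    n = t.size
    one = np.concatenate(([0.0], np.cumsum(np.ones(n))))
    st = np.concatenate(([0.0], np.cumsum(t)))
    sy = np.concatenate(([0.0], np.cumsum(y)))
    stt = np.concatenate(([0.0], np.cumsum(t * t)))
    sty = np.concatenate(([0.0], np.cumsum(t * y)))
    syy = np.concatenate(([0.0], np.cumsum(y * y)))

    i = np.arange(n + 1)[:, None]
    j = np.arange(n + 1)[None, :]
    m = one[j] - one[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        Sxx = (stt[j] - stt[i]) - (st[j] - st[i]) ** 2 / m
        Sxy = (sty[j] - sty[i]) - (st[j] - st[i]) * (sy[j] - sy[i]) / m
        Syy = (syy[j] - syy[i]) - (sy[j] - sy[i]) ** 2 / m
        sse = Syy - np.where(Sxx > 1e-12, Sxy**2 / np.where(Sxx > 0, Sxx, 1.0), 0.0)
    sse = np.where(m >= MIN_SEGMENT_LEN, np.maximum(sse, 0.0), np.inf)
    return sse


def _dp_segment(cost: np.ndarray, n: int, penalty: float) -> list[int]:
    """Exact minimizer of total SSE + penalty per segment; returns breakpoints
    0 = b0 < b1 < ... < bm = n."""
    F = np.full(n + 1, np.inf)
    F[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    for j in range(MIN_SEGMENT_LEN, n + 1):
        cand = F[: j - MIN_SEGMENT_LEN + 1] + cost[: j - MIN_SEGMENT_LEN + 1, j] + penalty
        i = int(np.argmin(cand))
        F[j] = cand[i]
        back[j] = i
    bps = [n]
    while bps[-1] > 0:
        bps.append(int(back[bps[-1]]))
    return bps[::-1]


def _segments_from_breakpoints(profile: IntakeProfile, bps: list[int]) -> list[Segment]:
    t, y = profile.t, profile.y
    n = t.size
    interval = profile.interval
    segs = []
    for i, j in zip(bps[:-1], bps[1:]):
        ts, te = t[i], (t[j] if j < n else t[-1] + interval)
        slope = float(np.polyfit(t[i:j], y[i:j], 1)[0]) if j - i >= 2 else 0.0
        y_end = y[j] if j < n else y[n - 1]
        segs.append(Segment(t_start=float(ts), t_end=float(te),
                            slope=slope, intake=float(y_end - y[i])))
    return segs


def estimate_noise_variance(y: np.ndarray) -> float:
    """Robust noise-variance estimate from second differences.

    For a piecewise-linear signal plus noise the second difference is
    noise-dominated away from the (few) change-points; its median absolute
    value scaled for normality and for Var(d2) = 6 sigma^2 estimates the
    per-sample noise variance, which for quantized recordings is of the
    order of the quantization step.
    """
    d2 = np.diff(y, 2)
    if d2.size == 0:
        return 0.0
    # trim the largest 2% of |d2| (the change-points themselves), then RMS
    cut = np.quantile(np.abs(d2), 0.98)
    core = d2[np.abs(d2) <= cut]
    return float(np.mean(core**2) / 6.0)


def segment_profile(profile: IntakeProfile,
                    penalty: float | None = None) -> list[Segment]:
    """Cut a cumulative intake curve into linear segments at slope changes.

    The segmentation minimizes ``SSE + penalty * n_segments`` exactly by
    dynamic programming (equivalent to a per-change-point penalty up to a
    constant).  By default the penalty is the known-variance BIC charge for
    one extra segment, ``3 * sigma^2 * log(n)`` (two line parameters plus a
    breakpoint), with ``sigma^2`` estimated robustly from second
    differences; this keeps the segmentation from chasing the quantization
    staircase while still cutting at every real slope change.

    Segment intakes telescope: their sum equals the final cumulative value.
    """
    t, y = profile.t, profile.y
    n = t.size
    cost = _segment_cost_matrix(t, y)
    if penalty is None:
        penalty = max(3.0 * estimate_noise_variance(y) * np.log(n), 1e-10)
    elif penalty <= 0:
        raise ValueError("penalty must be positive")
    bps = _dp_segment(cost, n, penalty)
    return _segments_from_breakpoints(profile, bps)


#: Pseudocount for the log-rate transform, g DM/kg BW per min.  Well below
#: any nibbling rate, so zero and near-zero slopes map to one tight mass.
LOG_SLOPE_EPS = 1e-3


def _log_slopes(slopes: np.ndarray) -> np.ndarray:
    return np.log10(np.maximum(slopes, 0.0) + LOG_SLOPE_EPS)


def _eating_gap(slopes: np.ndarray) -> float | None:
    """Threshold separating the "almost no intake" band from eating.

    The midpoint of the widest raw-slope gap between consecutive sorted
    slopes whose below-gap mass fraction lies in [0.15, 0.85].  Raw units,
    because near-zero is an absolute-rate notion: on the raw scale the
    sparse region between nibbling and committed eating is the dominant gap
    of a pooled segmentation, dwarfing any structure inside the near-zero
    band.  ``None`` when no balanced gap exists.
    """
    xs = np.sort(slopes)
    n = xs.size
    lo, hi = int(np.ceil(0.15 * n)), int(np.floor(0.85 * n))
    if hi - lo < 2:
        return None
    gaps = xs[lo:hi] - xs[lo - 1:hi - 1]
    i = int(np.argmax(gaps))
    if gaps[i] <= 0:
        return None
    return float((xs[lo + i] + xs[lo + i - 1]) / 2.0)


def _kmeans_centres(z: np.ndarray, k: int, seed: int) -> np.ndarray:
    if np.unique(z).size < k:  # degenerate band: spread pseudo-centres
        qs = np.quantile(z, np.linspace(0, 1, k + 2))[1:-1]
        return np.sort((qs[:-1] + qs[1:]) / 2.0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(z[:, None])
    return np.sort(km.cluster_centers_.ravel())


def fit_cluster_model(slopes, k: int = 8, seed: int = 0) -> ClusterModel:
    """1-D k-means on pooled segment slopes, relabeled so that cluster k has
    the highest centroid (fastest eating) and cluster 1 the lowest.

    Clustering is performed on ``log10(slope + eps)``: eating rates are
    ratio-scale and the biologically meaningful distinctions (true pause vs
    slow nibbling vs committed eating) live at very different magnitudes.
    The model's defining property is that clusters 1-2 hold the "almost no
    intake" slopes.  Plain k-means does not guarantee it, so the fit is
    band-aware: when a dominant balanced gap splits the slopes into a
    near-zero band and an eating band, and the plain k-means solution does
    not place exactly two centroids below that gap, the fit is redone
    constrained — 2 clusters below the gap, k-2 above, the gap becoming the
    cluster-2/3 decision boundary.  A plain solution that already separates
    the data essentially perfectly (k well-separated slope groups) is kept
    as is.  Centroids are reported in raw slope units; other boundaries are
    centroid midpoints in log space.

    With fewer than ``k`` distinct slopes the model falls back to quantile
    boundaries with a warning.
    """
    slopes = np.asarray([s.slope if isinstance(s, Segment) else s for s in slopes],
                        dtype=float)
    distinct = np.unique(slopes)
    if distinct.size < k:
        warnings.warn(
            f"only {distinct.size} distinct slopes for {k} clusters; "
            "falling back to quantile boundaries"
        )
        qs = np.quantile(slopes, np.linspace(0, 1, k + 1))[1:-1]
        mids = np.concatenate(([slopes.min()], qs, [slopes.max()]))
        centroids = (mids[:-1] + mids[1:]) / 2.0
        return ClusterModel(centroids=np.sort(centroids), k=k)
    z = _log_slopes(slopes)
    zc = _kmeans_centres(z, k, seed)
    boundaries = 10.0 ** ((zc[:-1] + zc[1:]) / 2.0) - LOG_SLOPE_EPS
    centroids = 10.0**zc - LOG_SLOPE_EPS
    plain_sse = float(np.min((z[:, None] - zc[None, :]) ** 2, axis=1).sum())
    total_ss = float(((z - z.mean()) ** 2).sum())
    essentially_exact = plain_sse <= 1e-3 * max(total_ss, 1e-12)
    tau = _eating_gap(slopes)
    if (tau is not None and not essentially_exact
            and not (centroids[1] < tau <= centroids[2])):
        z_tau = np.log10(tau + LOG_SLOPE_EPS)
        low, high = z[z < z_tau], z[z >= z_tau]
        if low.size >= 2 and high.size >= k - 2:
            zc = np.concatenate([_kmeans_centres(low, 2, seed),
                                 _kmeans_centres(high, k - 2, seed)])
            centroids = 10.0**zc - LOG_SLOPE_EPS
            boundaries = 10.0 ** ((zc[:-1] + zc[1:]) / 2.0) - LOG_SLOPE_EPS
            boundaries[1] = tau  # the band gap is the cluster-2/3 boundary
    return ClusterModel(centroids=centroids, k=k, boundaries_=boundaries)


def assign_clusters(segments: list[Segment], model: ClusterModel) -> list[Segment]:
    """Label each segment 1..k by nearest slope centroid (in place and
    returned); order-independent."""
    labels = model.label([s.slope for s in segments])
    for seg, lab in zip(segments, labels):
        seg.cluster = int(lab)
    return segments


def first_meal(segments: list[Segment], min_pause: float = 30.0) -> MealResult:
    """Apply the first-meal rule to labeled segments in time order.

    Intake of eating segments (cluster >= 3) is accumulated until the first
    near-zero-slope stretch (a maximal run of consecutive cluster <= 2
    segments) of at least ``min_pause`` minutes; shorter low-slope
    stretches neither end the meal nor contribute intake.  Judging the
    pause on the merged run rather than a single segment makes the rule
    invariant to the segmentation splitting one homogeneous slow stretch
    into several segments.  If no qualifying pause exists the meal extends
    to the window end (``ended_by_pause=False``).
    """
    ordered = sorted(segments, key=lambda s: s.t_start)
    if any(s.cluster is None for s in ordered):
        raise ValueError("segments must be labeled before meal detection")
    intake = 0.0
    n_in_meal = 0
    i = 0
    while i < len(ordered):
        seg = ordered[i]
        if seg.cluster <= 2:
            run_start = seg.t_start
            run_end = seg.t_end
            while i + 1 < len(ordered) and ordered[i + 1].cluster <= 2:
                i += 1
                run_end = ordered[i].t_end
            if run_end - run_start >= min_pause:
                return MealResult(first_meal_end=run_start,
                                  first_meal_intake=intake,
                                  n_segments_in_meal=n_in_meal,
                                  ended_by_pause=True)
        else:
            intake += seg.intake
            n_in_meal += 1
        i += 1
    return MealResult(first_meal_end=ordered[-1].t_end,
                      first_meal_intake=intake,
                      n_segments_in_meal=n_in_meal,
                      ended_by_pause=False)
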