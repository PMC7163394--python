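import numpy as np
import pytest

import capribite as cb


@pytest.fixture(scope="session")
def small_design():
    return cb.HerdDesign(n_goats=6, n_alpine=3, n_periods=2, n_days_per_period=2)


@pytest.fixture(scope="session")
def small_herd(small_design):
    return cb.simulate_herd(small_design, cb.VarianceSpec(), seed=42)


@pytest.fixture(scope="session")
def clean_profile():
    """A noiseless two-bout profile on the 450-point grid."""
    t = 2.0 * np.arange(450)
    y = 0.3 * np.clip(t, 0, 60) + 0.15 * np.clip(t - 200, 0, 80)
    return cb.IntakeProfile(goat_id="G01", period="P1", day="D1",
                            t=t, y=y, bw=50.0, breed="A")


def brute_force_segmentation_cost(t, y, penalty, min_len=2):
    """Exhaustive minimum of SSE + penalty * n_segments over all breakpoint
    sets with segments of >= min_len points.  Independent of the DP: segment
    SSE comes from np.polyfit residuals, enumeration from recursion."""

    n = len(t)

    def seg_sse(i, j):
        if j - i == min_len == 2:
            return 0.0
        res = np.polyfit(t[i:j], y[i:j], 1, full=True)[1]
        return float(res[0]) if len(res) else 0.0

    best = [np.inf]

    def rec(start, acc):
        if acc >= best[0]:
            return
        for end in range(start + min_len, n + 1):
            c = acc + seg_sse(start, end) + penalty
            if end == n:
                if c < best[0]:
                    best[0] = c
            elif n - end >= min_len:
                rec(end, c)

    rec(0, 0.0)
    return best[0]


def optimal_1d_kmeans_cost(values, k):
    """Exact optimal 1-D k-clustering SSE by dynamic programming on the
    sorted values (independent oracle for the k-means objective)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    pref = np.concatenate(([0.0], np.cumsum(x)))
    pref2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(i, j):  # cluster of x[i:j]
        m = j - i
        s = pref[j] - pref[i]
        return (pref2[j] - pref2[i]) - s * s / m

    D = np.full((k + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            D[c, j] = min(D[c - 1, i] + sse(i, j) for i in range(c - 1, j))
    return D[k, n]
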