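"""Length-class analysis of lncRNA transcripts.

The transcript-length population is summarised by its inverse cumulative
distribution (iCDF): the fraction of transcripts at least L nt long,
plotted in double-log coordinates.  In that space a pure power law is a
straight line and an "extended" power law a quadratic; the population is
modelled as a piecewise quadratic with ``n_components`` segments.  The
segmentation is chosen by exhaustive least-squares search over candidate
breakpoint pairs on the distinct-length grid, each segment fitted by OLS;
nt cutoffs between classes come from the intersection points of adjacent
fitted components.  The shortest class is additionally summarised by a
log-normal body fit.

The reference analysis of the U133 lncRNA catalogue yields cutoffs near
386 nt and 2,345 nt, splitting lncRNAs (>= 200 nt) into three classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LncArrayError
from .io import kv_log

__all__ = [
    "MixtureComponent", "MixtureFit", "empirical_icdf", "fit_mixture",
    "component_intersection", "classify_lengths", "CLASS_LABELS",
]

CLASS_LABELS = ("below_min", "class1", "class2", "class3")


@dataclass(frozen=True)
class MixtureComponent:
    """One quadratic component y = a0 + a1*x + a2*x^2 in log10-log10 space."""

    a0: float
    a1: float
    a2: float
    fit_range: tuple

    def __post_init__(self):
        if not self.fit_range[0] < self.fit_range[1]:
            raise LncArrayError(f"invalid fit_range {self.fit_range}")

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.a0 + self.a1 * x + self.a2 * x * x

    def slope(self, x):
        x = np.asarray(x, dtype=float)
        return self.a1 + 2.0 * self.a2 * x

    def is_monotone_decreasing(self, tol: float = 1e-9) -> bool:
        """Predicted iCDF must not increase anywhere on the fitted range."""
        lo, hi = self.fit_range
        return bool(self.slope(lo) <= tol and self.slope(hi) <= tol)


@dataclass(frozen=True)
class MixtureFit:
    components: tuple
    breakpoints_x: tuple
    cutoffs_nt: tuple
    sse: float
    class_proportions: tuple
    lognormal_body: tuple

    def __post_init__(self):
        if len(self.breakpoints_x) != len(self.components) - 1:
            raise LncArrayError("breakpoint count must be n_components - 1")
        cuts = self.cutoffs_nt
        if any(cuts[i] >= cuts[i + 1] for i in range(len(cuts) - 1)):
            raise LncArrayError(f"cutoffs not strictly increasing: {cuts}")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise LncArrayError("class proportions must sum to 1")


def empirical_icdf(lengths):
    """Return (length, fraction >= length) pairs at each distinct length.

    Fractions are non-increasing and the fraction at the minimum observed
    length is exactly 1.
    """
    arr = np.asarray(lengths)
    if arr.size == 0:
        raise LncArrayError("empirical_icdf: empty length list")
    if (arr < 1).any():
        raise LncArrayError("empirical_icdf: lengths must be >= 1 nt")
    distinct, counts = np.unique(arr, return_counts=True)
    # fraction >= L = 1 - (cumulative count strictly below L) / n
    below = np.concatenate([[0], np.cumsum(counts)[:-1]])
    frac = (arr.size - below) / arr.size
    return np.column_stack([distinct.astype(float), frac])


class _SegmentSSE:
    """O(1) quadratic-OLS residual sums over contiguous index ranges.

    Prefix sums of x^0..x^4, x^k*y and y^2 let the 3x3 normal equations of
    any segment be assembled and solved in closed form.  x is centred once
    globally for conditioning; SSE is shift-invariant so the segmentation
    search is unaffected.
    """

    def __init__(self, x, y):
        xc = x - x.mean()
        pows = np.stack([np.ones_like(xc), xc, xc ** 2, xc ** 3, xc ** 4])
        self._sx = np.concatenate([np.zeros((5, 1)), np.cumsum(pows, axis=1)], axis=1)
        ky = np.stack([y, xc * y, xc * xc * y])
        self._sy = np.concatenate([np.zeros((3, 1)), np.cumsum(ky, axis=1)], axis=1)
        self._syy = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(self, i, j):
        """Residual SSE of the quadratic OLS fit over points [i, j)."""
        s = self._sx[:, j] - self._sx[:, i]
        t = self._sy[:, j] - self._sy[:, i]
        m = np.array([[s[0], s[1], s[2]],
                      [s[1], s[2], s[3]],
                      [s[2], s[3], s[4]]])
        try:
            beta = np.linalg.solve(m, t)
        except np.linalg.LinAlgError:
            return np.inf
        return float(max(self._syy[j] - self._syy[i] - beta @ t, 0.0))


def _fit_segment(x, y) -> tuple:
    """OLS quadratic coefficients (a0, a1, a2) on raw x."""
    coeffs = np.polyfit(x, y, 2)  # highest power first
    return float(coeffs[2]), float(coeffs[1]), float(coeffs[0])


def _candidate_indices(m: int, min_pts: int, grid_max: int):
    lo, hi = min_pts, m - min_pts
    full = np.arange(lo, hi + 1)
    if full.size <= grid_max:
        return full, 1
    step = int(np.ceil(full.size / grid_max))
    return full[::step], step


def _best_pair(seg: _SegmentSSE, m: int, min_pts: int, grid_max: int):
    """Exhaustive coarse scan plus exhaustive local refinement on the full grid."""
    cand, step = _candidate_indices(m, min_pts, grid_max)

    def scan(i_values, j_values):
        best = (np.inf, None, None)
        for i in i_values:
            s1 = seg.sse(0, i)
            for j in j_values:
                if j - i < min_pts or m - j < min_pts:
                    continue
                total = s1 + seg.sse(i, j) + seg.sse(j, m)
                if total < best[0]:
                    best = (total, int(i), int(j))
        return best

    best = scan(cand, cand)
    if best[1] is None:
        raise LncArrayError(
            "fit_mixture: too few distinct lengths per segment; try fewer components")
    if step > 1:
        i0, j0 = best[1], best[2]
        i_win = np.arange(max(min_pts, i0 - step), min(m - min_pts, i0 + step) + 1)
        j_win = np.arange(max(min_pts, j0 - step), min(m - min_pts, j0 + step) + 1)
        refined = scan(i_win, j_win)
        if refined[0] < best[0]:
            best = refined
    return best


def component_intersection(c1: MixtureComponent, c2: MixtureComponent,
                           search: tuple, boundary: float | None = None) -> float:
    """nt position where two components' extrapolated curves intersect.

    Solves the quadratic (a0_1-a0_2) + (a1_1-a1_2)x + (a2_1-a2_2)x^2 = 0 and
    returns 10^x for the root inside ``search``; with two interior roots,
    the one nearer the segments' shared boundary wins.
    """
    d0, d1, d2 = c1.a0 - c2.a0, c1.a1 - c2.a1, c1.a2 - c2.a2
    if abs(d2) < 1e-12:
        if abs(d1) < 1e-12:
            raise LncArrayError("components are identical or parallel: no unique intersection")
        roots = np.array([-d0 / d1])
    else:
        disc = d1 * d1 - 4.0 * d2 * d0
        if disc < 0:
            raise LncArrayError("components do not intersect (no real root)")
        sq = np.sqrt(disc)
        roots = np.array([(-d1 - sq) / (2 * d2), (-d1 + sq) / (2 * d2)])
    lo, hi = search
    inside = roots[(roots >= lo) & (roots <= hi)]
    if inside.size == 0:
        raise LncArrayError(
            f"no component intersection inside search window ({lo:.3g}, {hi:.3g})")
    if boundary is None:
        boundary = 0.5 * (c1.fit_range[1] + c2.fit_range[0])
    x = float(inside[np.argmin(np.abs(inside - boundary))])
    return float(10.0 ** x)


def fit_mixture(lengths, n_components: int = 3, min_points_per_segment: int = 8,
                grid_max: int = 160) -> MixtureFit:
    """Fit the piecewise-quadratic iCDF mixture and derive nt cutoffs.

    Deterministic given the input: the breakpoint pair minimising total
    SSE over the candidate grid is selected, each segment refitted by OLS,
    and adjacent components intersected to give class cutoffs.
    """
    if n_components not in (1, 2, 3):
        raise LncArrayError("n_components must be 1, 2 or 3")
    pts = empirical_icdf(lengths)
    m = pts.shape[0]
    if m < 30:
        raise LncArrayError(f"fit_mixture needs >= 30 distinct lengths, got {m}")
    x = np.log10(pts[:, 0])
    y = np.log10(pts[:, 1])
    seg = _SegmentSSE(x, y)

    if n_components == 1:
        bounds = [0, m]
    elif n_components == 2:
        cand, _ = _candidate_indices(m, min_points_per_segment, 10 ** 9)
        sses = [seg.sse(0, i) + seg.sse(i, m) for i in cand]
        bounds = [0, int(cand[int(np.argmin(sses))]), m]
    else:
        _, i, j = _best_pair(seg, m, min_points_per_segment, grid_max)
        bounds = [0, i, j, m]

    components = []
    sse_total = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        a0, a1, a2 = _fit_segment(x[a:b], y[a:b])
        components.append(MixtureComponent(a0, a1, a2, (float(x[a]), float(x[b - 1]))))
        pred = components[-1].predict(x[a:b])
        sse_total += float(np.sum((y[a:b] - pred) ** 2))

    breakpoints_x, cutoffs = [], []
    for left, right in zip(components[:-1], components[1:]):
        boundary = 0.5 * (left.fit_range[1] + right.fit_range[0])
        try:
            cut = component_intersection(
                left, right, (left.fit_range[0], right.fit_range[1]),
                boundary=boundary)
        except LncArrayError:
            # adjacent quadratics may fail to cross; fall back to their point
            # of closest approach (vertex of the difference parabola), clamped
            # to the fitted segment boundary -- deterministic and logged
            d1, d2 = left.a1 - right.a1, left.a2 - right.a2
            x_star = -d1 / (2.0 * d2) if abs(d2) > 1e-12 else boundary
            if not left.fit_range[0] <= x_star <= right.fit_range[1]:
                x_star = boundary
            cut = float(10.0 ** x_star)
            kv_log("fit_mixture_fallback", cutoff_nt=f"{cut:.1f}",
                   reason="no real intersection; closest approach used")
        cutoffs.append(cut)
        breakpoints_x.append(float(np.log10(cut)))

    arr = np.asarray(lengths, dtype=float)
    edges = [-np.inf] + cutoffs + [np.inf]
    proportions = tuple(
        float(np.mean((arr > edges[k]) & (arr <= edges[k + 1])))
        for k in range(len(components)))

    # log-normal body of the shortest class (natural-log moments)
    body = arr[arr <= cutoffs[0]] if cutoffs else arr
    if body.size >= 2:
        logs = np.log(body)
        lognormal_body = (float(logs.mean()), float(logs.std(ddof=1)))
    else:
        lognormal_body = (float("nan"), float("nan"))

    return MixtureFit(
        components=tuple(components), breakpoints_x=tuple(breakpoints_x),
        cutoffs_nt=tuple(cutoffs), sse=sse_total,
        class_proportions=proportions, lognormal_body=lognormal_body)


def classify_lengths(lengths, cutoffs_nt, min_nt: int = 200):
    """Assign each length to below_min / class1 / class2 / class3.

    class1 = [min_nt, c1], class2 = (c1, c2], class3 = (c2, inf); ties at a
    cutoff go to the lower class.  The partition is total.
    """
    c1, c2 = cutoffs_nt
    if not (min_nt < c1 < c2):
        raise LncArrayError(f"require min_nt < c1 < c2, got {min_nt}, {c1}, {c2}")
    arr = np.asarray(lengths, dtype=float)
    labels = np.full(arr.shape, "below_min", dtype=object)
    labels[(arr >= min_nt) & (arr <= c1)] = "class1"
    labels[(arr > c1) & (arr <= c2)] = "class2"
    labels[arr > c2] = "class3"
    return labels
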