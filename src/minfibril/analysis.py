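"""Mechanical analysis of stress-strain curves: regime segmentation,
moduli, toughness, ultimate point, contraction/internal stress and
density-normalized performance.

Toughness is the area under the tensile stress-strain curve up to the
ultimate strength.  Deformation regimes (toe, elastic I-a/I-b, saw-tooth
slippage II, backbone-stretching III) are recovered by piecewise-linear
change-point fitting on a lightly smoothed copy of the curve; the raw
curve is always retained for integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats


@dataclass
class StressStrainCurve:
    """Sampled tensile response.

    ``strain`` is engineering strain in the stated convention: relative to
    the relaxed (possibly contracted) length, or to the fixed unmineralized
    reference length L0.
    """

    strain: np.ndarray
    stress: np.ndarray  # GPa
    convention: str = "relaxed-length"  # or "fixed-L0"
    L_relaxed: float = 0.0  # Å
    L0: float = 0.0  # Å

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, float)
        self.stress = np.asarray(self.stress, float)
        if len(self.strain) != len(self.stress):
            raise ValueError("strain and stress must have equal length")
        if len(self.strain) > 1 and np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain grid must be strictly increasing")

    def to_fixed_L0(self) -> "StressStrainCurve":
        """Re-express strain relative to the unmineralized length L0."""
        if self.convention == "fixed-L0":
            return self
        if not (self.L_relaxed and self.L0):
            raise ValueError("conversion requires stored L_relaxed and L0")
        eps = (self.L_relaxed / self.L0) * (1.0 + self.strain) - 1.0
        return StressStrainCurve(eps, self.stress, "fixed-L0", self.L_relaxed, self.L0)

    def smoothed(self, window_strain: float = 0.01) -> "StressStrainCurve":
        """Centered moving average over a strain window (default 1% strain)."""
        if len(self.strain) < 5:
            return self
        de = np.median(np.diff(self.strain))
        w = max(1, int(round(window_strain / de)))
        if w <= 1:
            return self
        kernel = np.ones(2 * (w // 2) + 1)
        kernel /= kernel.sum()
        sm = np.convolve(self.stress, kernel, mode="same")
        # restore the untouched edges
        h = len(kernel) // 2
        sm[:h] = self.stress[:h]
        sm[-h:] = self.stress[-h:]
        return StressStrainCurve(
            self.strain, sm, self.convention, self.L_relaxed, self.L0
        )


def ultimate_point(curve: StressStrainCurve) -> tuple[float, float, int]:
    """(sigma_max, eps_at_max, index); first global maximum wins on ties."""
    i = int(np.argmax(curve.stress))
    if np.all(curve.stress == curve.stress[0]):
        i = len(curve.stress) - 1  # flat curve: the whole curve is the plateau
    return float(curve.stress[i]), float(curve.strain[i]), i


def toughness(curve: StressStrainCurve) -> float:
    """Area under the stress-strain curve up to the ultimate strength, GPa
    (trapezoidal rule from zero strain to the strain of maximum stress)."""
    if len(curve.strain) < 2:
        raise ValueError("curve too short")
    _, _, i = ultimate_point(curve)
    if i == 0:
        return 0.0
    return float(np.trapezoid(curve.stress[: i + 1], curve.strain[: i + 1]))


def failure_strain(curve: StressStrainCurve, fraction: float = 0.5) -> float:
    """Strain at which the stress first falls below ``fraction`` of the
    ultimate stress after the ultimate point (post-peak collapse strain).

    Brittle curves collapse just past their peak; ductile (pull-out
    dominated) curves keep carrying load well beyond it.  Returns NaN when
    the recorded curve never collapses that far.
    """
    smax, _, i = ultimate_point(curve)
    post = np.flatnonzero(
        (np.arange(len(curve.stress)) > i) & (curve.stress < fraction * smax)
    )
    if not len(post):
        return float("nan")
    return float(curve.strain[post[0]])


# --------------------------------------------------------------------------
# regime segmentation (piecewise-linear change-point fit)
# --------------------------------------------------------------------------


@dataclass
class Segment:
    start: int
    stop: int  # exclusive
    slope: float  # GPa per unit strain
    intercept: float
    r2: float


@dataclass
class RegimeReport:
    boundaries: np.ndarray  # strain values (k-1 interior breakpoints)
    segments: list[Segment]
    moduli: np.ndarray  # GPa per segment
    toe_extent: float  # strain where the toe (first low-slope segment) ends
    has_sawtooth: bool
    sawtooth_segment: Optional[int]
    partial: bool = False


def _linfit_cost(sx, sy, sxx, sxy, syy, n):
    """SSE of the least-squares line through n points given moment sums."""
    det = n * sxx - sx * sx
    if det <= 0:
        return np.inf, 0.0, 0.0
    b = (n * sxy - sx * sy) / det
    a = (sy - b * sx) / n
    sse = syy - a * sy - b * sxy
    return max(sse, 0.0), b, a


def piecewise_linear_fit(
    x: np.ndarray, y: np.ndarray, n_segments: int, min_pts: int = 5
) -> tuple[list[int], float]:
    """Optimal breakpoints for a k-segment piecewise-linear fit (dynamic
    programming over sample indices); returns interior breakpoint indices
    and the total SSE."""
    n = len(x)
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost_vec(i_arr, j):
        """SSE of segments [i, j) for a vector of start indices (length >= min_pts)."""
        m = j - i_arr
        sx = cx[j] - cx[i_arr]
        sy = cy[j] - cy[i_arr]
        sxx = cxx[j] - cxx[i_arr]
        sxy = cxy[j] - cxy[i_arr]
        syy = cyy[j] - cyy[i_arr]
        det = m * sxx - sx * sx
        with np.errstate(divide="ignore", invalid="ignore"):
            b = (m * sxy - sx * sy) / det
            a = (sy - b * sx) / m
            sse = syy - a * sy - b * sxy
        sse = np.where((det <= 0) | (m < min_pts), np.inf, np.maximum(sse, 0.0))
        return sse

    K = n_segments
    INF = np.inf
    dp = np.full((K + 1, n + 1), INF)
    back = np.zeros((K + 1, n + 1), int)
    dp[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k * min_pts, n + 1):
            i_arr = np.arange((k - 1) * min_pts, j - min_pts + 1)
            cand = dp[k - 1, i_arr] + seg_cost_vec(i_arr, j)
            arg = int(np.argmin(cand))
            dp[k, j] = cand[arg]
            back[k, j] = i_arr[arg]
    if not np.isfinite(dp[K, n]):
        raise ValueError("not enough points for the requested segmentation")
    cuts = []
    j = n
    for k in range(K, 0, -1):
        i = back[k, j]
        if k > 1:
            cuts.append(i)
        j = i
    return sorted(cuts), float(dp[K, n])


def segment_regimes(
    curve: StressStrainCurve,
    max_segments: int = 5,
    min_pts: int = 5,
    smooth_window: float = 0.01,
    toe_slope_fraction: float = 0.35,
) -> RegimeReport:
    """Detect deformation regimes by piecewise-linear change-point fitting.

    The number of segments is chosen by BIC over 1..max_segments on the
    smoothed curve.  The toe is a leading segment whose slope is below
    ``toe_slope_fraction`` of the maximum segment slope; a saw-tooth regime
    is a post-peak-slope segment with repeated stress drops.
    """
    sm = curve.smoothed(smooth_window)
    x, y = sm.strain, sm.stress
    n = len(x)
    if n < 2 * min_pts:
        return RegimeReport(
            boundaries=np.zeros(0),
            segments=[_fit_segment(x, y, 0, n)],
            moduli=np.array([_fit_segment(x, y, 0, n).slope]),
            toe_extent=0.0,
            has_sawtooth=False,
            sawtooth_segment=None,
            partial=True,
        )
    best_k, best_cuts, best_bic = 1, [], np.inf
    for k in range(1, max_segments + 1):
        if n < k * min_pts:
            break
        try:
            cuts, sse = piecewise_linear_fit(x, y, k, min_pts)
        except ValueError:
            break
        sse = max(sse, 1e-12)
        bic = n * np.log(sse / n) + (3 * k) * np.log(n)
        if bic < best_bic - 1e-9:
            best_bic, best_k, best_cuts = bic, k, cuts
    bounds = [0] + best_cuts + [n]
    segments = [
        _fit_segment(x, y, a, b) for a, b in zip(bounds[:-1], bounds[1:])
    ]
    moduli = np.array([s.slope for s in segments])
    max_slope = np.max(np.abs(moduli)) if len(moduli) else 0.0
    toe_extent = 0.0
    if len(segments) > 1 and abs(segments[0].slope) < toe_slope_fraction * max_slope:
        toe_extent = float(x[segments[0].stop - 1])
    # saw-tooth: a post-elastic segment with repeated significant stress
    # drops (single-sample decreases beyond 2% of the stress range)
    has_saw, saw_idx = False, None
    raw = curve.stress
    drop_thresh = 0.02 * max(np.ptp(raw), 1e-12)
    for si, s in enumerate(segments[1:], start=1):
        seg_raw = raw[s.start : s.stop]
        drops = np.sum(np.diff(seg_raw) < -drop_thresh)
        if len(seg_raw) >= min_pts and drops >= 3 and (
            abs(s.slope) < 0.8 * max_slope
        ):
            has_saw, saw_idx = True, si
            break
    return RegimeReport(
        boundaries=np.array([x[c] for c in best_cuts]),
        segments=segments,
        moduli=moduli,
        toe_extent=toe_extent,
        has_sawtooth=has_saw,
        sawtooth_segment=saw_idx,
        partial=len(segments) < 2,
    )


def _fit_segment(x, y, a, b) -> Segment:
    xs, ys = x[a:b], y[a:b]
    if len(xs) < 2 or np.ptp(xs) == 0:
        return Segment(a, b, 0.0, float(np.mean(ys)), 0.0)
    res = stats.linregress(xs, ys)
    return Segment(a, b, float(res.slope), float(res.intercept), float(res.rvalue**2))


def fit_modulus(
    curve: StressStrainCurve, window: tuple[float, float]
) -> tuple[float, float]:
    """Least-squares modulus (GPa) over a strain window, with the 95%
    confidence half-width of the slope.  Requires >= 5 samples."""
    lo, hi = window
    sel = (curve.strain >= lo) & (curve.strain <= hi)
    if np.sum(sel) < 5:
        raise ValueError("modulus window contains fewer than 5 samples")
    xs, ys = curve.strain[sel], curve.stress[sel]
    if np.ptp(xs) == 0:
        raise ValueError("singular modulus fit: zero strain range")
    res = stats.linregress(xs, ys)
    tval = stats.t.ppf(0.975, len(xs) - 2) if len(xs) > 2 else np.inf
    return float(res.slope), float(tval * res.stderr)


# --------------------------------------------------------------------------
# contraction / internal stress / summaries
# --------------------------------------------------------------------------


def contraction_percent(L0: float, L_relaxed: float) -> float:
    """Mineralization-induced contraction vs. the unmineralized length, %."""
    if L0 <= 0:
        raise ValueError("missing unmineralized reference length")
    return 100.0 * (L0 - L_relaxed) / L0


def contraction_and_internal_stress(
    state,
    L0: float,
    hold_steps: int = 2000,
    sample_every: int = 100,
) -> tuple[float, float]:
    """Contraction (%) of an equilibrated state vs. the unmineralized
    reference length L0, and the internal axial stress (GPa) measured with
    the box re-extended to L0 and held there.
    """
    if L0 <= 0:
        raise ValueError("missing unmineralized reference length")
    m = state.model
    L_rel = m.box.Lx
    contraction = contraction_percent(L0, L_rel)
    mu = L0 / L_rel
    m.positions[:, 0] *= mu
    m.box.lengths[0] = L0
    state._nl = None
    stresses = []
    done = 0
    while done < hold_steps:
        state.run(sample_every, thermostat=True)
        done += sample_every
        stresses.append(state.axial_stress())
    # restore the relaxed length
    m.positions[:, 0] /= mu
    m.box.lengths[0] = L_rel
    state._nl = None
    tail = stresses[len(stresses) // 2 :]
    return contraction, float(np.mean(tail))


@dataclass
class MechanicalSummary:
    sigma_max: float  # GPa
    eps_max: float  # ultimate strain, relaxed-length convention
    eps_max_fixed_L0: float
    toughness: float  # GPa
    contraction: float  # %
    internal_stress: float  # GPa
    toughness_over_density: float
    strength_over_density: float
    relative_density: float


def relative_density(mineral_wt_percent: float) -> float:
    """Fibril mass density relative to the unmineralized fibril (same
    constant-diameter volume): 1 / (1 - w)."""
    w = mineral_wt_percent / 100.0
    return 1.0 / (1.0 - w)


def density_normalized_performance(
    toughness_gpa: float, sigma_max: float, mineral_wt_percent: float
) -> tuple[float, float]:
    """(toughness/relative density, strength/relative density)."""
    rd = relative_density(mineral_wt_percent)
    return toughness_gpa / rd, sigma_max / rd


def summarize(
    curve: StressStrainCurve,
    mineral_wt_percent: float = 0.0,
    contraction: float = 0.0,
    internal_stress: float = 0.0,
) -> MechanicalSummary:
    """Headline mechanics of one tensile test."""
    smax, emax, _ = ultimate_point(curve)
    tough = toughness(curve)
    if curve.L_relaxed and curve.L0:
        emax_fixed = (curve.L_relaxed / curve.L0) * (1.0 + emax) - 1.0
    else:
        emax_fixed = emax
    t_d, s_d = density_normalized_performance(tough, smax, mineral_wt_percent)
    return MechanicalSummary(
        sigma_max=smax,
        eps_max=emax,
        eps_max_fixed_L0=emax_fixed,
        toughness=tough,
        contraction=contraction,
        internal_stress=internal_stress,
        toughness_over_density=t_d,
        strength_over_density=s_d,
        relative_density=relative_density(mineral_wt_percent),
    )
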