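"""Force-extension analysis of polyprotein unfolding traces.

The analysis chain mirrors standard constant-velocity force
spectroscopy: sawtooth peaks are detected, the rising edge before each
peak is fitted with a one-parameter worm-like chain (persistence length
fixed), contour-length increments between consecutive segments identify
the unfolded domain class (E vs G5), and per-class histograms of force
and dLc give modal statistics.  The extension axis is the protein
extension (tip-sample separation corrected for cantilever deflection);
generator and analyzer share this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit, least_squares
from scipy.signal import find_peaks

from .constants import ANGSTROM_PER_NM
from .wlc import wlc_force

DEFAULT_MIN_DROP_PN = 30.0
DEFAULT_MIN_FORCE_PN = 50.0
DEFAULT_P_NM = 0.4
#: dLc classification windows (nm): E covers ~145-154 A, G5 ~216-227 A.
E_WINDOW_NM = (12.0, 18.5)
G5_WINDOW_NM = (18.5, 26.0)
DLC_BIN_NM = 0.5          # 5 A histogram bins for dLc
SMOOTH_SAMPLES = 5
MIN_SEGMENT_POINTS = 15


@dataclass
class ForceExtensionTrace:
    """A constant-velocity retraction trace."""

    time: np.ndarray        # s
    extension: np.ndarray   # nm, protein extension, non-decreasing
    force: np.ndarray       # pN
    speed: float            # nm/s
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, float)
        x = np.asarray(self.extension, float)
        f = np.asarray(self.force, float)
        if not (t.size == x.size == f.size):
            raise ValueError("time/extension/force must have equal length")
        if t.size < 100:
            raise ValueError("trace must have >= 100 samples")
        if np.any(np.diff(x) < -1e-9):
            raise ValueError("extension must be non-decreasing")
        self.time, self.extension, self.force = t, x, f


@dataclass
class Peak:
    index: int
    force: float            # pN, from the smoothed trace
    extension: float        # nm
    is_detachment: bool = False


def detect_events(trace: ForceExtensionTrace,
                  min_drop: float = DEFAULT_MIN_DROP_PN,
                  min_force: float = DEFAULT_MIN_FORCE_PN,
                  smooth: int = SMOOTH_SAMPLES) -> list[Peak]:
    """Sawtooth peaks: local maxima followed by a drop >= min_drop.

    Peak finding runs on a median-filtered copy of the force channel to
    keep single-sample noise from inflating peak forces.  The final
    peak is labelled as the detachment event.  An empty list is a valid
    result.
    """
    f = median_filter(trace.force, size=max(1, smooth), mode="nearest")
    idx, _ = find_peaks(f, height=min_force, prominence=min_drop)
    # refine each peak to the rupture edge: the steepest raw-force drop
    # near the smoothed maximum marks the last sample before the event
    d = np.diff(trace.force)
    half = max(3 * smooth, 15)
    peaks = []
    for i in idx:
        lo = max(int(i) - half, 0)
        hi = min(int(i) + half, d.size)
        j = lo + int(np.argmin(d[lo:hi])) if hi > lo else int(i)
        # raw force at the edge: unbiased by smoothing across the drop
        peaks.append(Peak(j, float(trace.force[j]),
                          float(trace.extension[j])))
    if peaks:
        peaks[-1].is_detachment = True
    return peaks


@dataclass
class WLCSegmentFit:
    lc: float               # nm
    p: float                # nm, fixed
    start: int
    stop: int
    residual_norm: float
    converged: bool


def fit_segment(trace: ForceExtensionTrace, start: int, stop: int,
                p: float = DEFAULT_P_NM,
                temperature_k: float = 298.0) -> WLCSegmentFit:
    """One-parameter WLC fit (contour length only) of a rising edge.

    ``p`` is never varied.  Requires at least 15 samples in the segment.
    """
    if stop - start < MIN_SEGMENT_POINTS:
        raise ValueError(
            f"segment needs >= {MIN_SEGMENT_POINTS} points, has {stop - start}")
    x = trace.extension[start:stop]
    f = trace.force[start:stop]
    xmax = float(x.max())

    def resid(lc):
        return wlc_force(x, lc[0], p, temperature_k) - f

    lc0 = xmax * 1.05 + 1.0
    sol = least_squares(resid, [lc0], bounds=([xmax * (1 + 1e-9) + 1e-6],
                                              [np.inf]),
                        xtol=1e-12, ftol=1e-12)
    return WLCSegmentFit(float(sol.x[0]), p, start, stop,
                         float(np.linalg.norm(sol.fun)), bool(sol.success))


def delta_lc(fits: list[WLCSegmentFit]) -> np.ndarray:
    """Contour-length increments between consecutive fitted segments (nm)."""
    if len(fits) < 2:
        raise ValueError("need at least two fitted segments")
    lcs = np.array([f.lc for f in fits])
    return np.diff(lcs)


def classify_event(dlc_nm: float,
                   e_window: tuple[float, float] = E_WINDOW_NM,
                   g5_window: tuple[float, float] = G5_WINDOW_NM) -> str:
    """Assign a contour-length increment to a domain class."""
    if not np.isfinite(dlc_nm):
        raise ValueError("dLc must be finite")
    if e_window[0] <= dlc_nm < e_window[1]:
        return "E"
    if g5_window[0] <= dlc_nm <= g5_window[1]:
        return "G5"
    return "other"


@dataclass
class UnfoldingEvent:
    peak_force: float       # pN
    peak_index: int
    lc_before: float        # nm
    dlc: float | None       # nm; None for detachment
    domain_class: str       # E | G5 | other | detachment

    @property
    def dlc_angstrom(self) -> float | None:
        return None if self.dlc is None else self.dlc * ANGSTROM_PER_NM


@dataclass
class TraceAnalysis:
    events: list[UnfoldingEvent]
    fits: list[WLCSegmentFit]
    accepted: bool
    reject_reason: str | None


def _segment_bounds(trace: ForceExtensionTrace,
                    peaks: list[Peak]) -> list[tuple[int, int]]:
    """Rising-edge sample ranges (valley -> peak) preceding each peak."""
    bounds = []
    prev_end = 0
    for pk in peaks:
        seg = trace.force[prev_end:pk.index + 1]
        valley = prev_end + int(np.argmin(seg)) if seg.size else prev_end
        bounds.append((valley, pk.index + 1))
        prev_end = pk.index + 1
    return bounds


def analyze_trace(trace: ForceExtensionTrace,
                  min_drop: float = DEFAULT_MIN_DROP_PN,
                  min_force: float = DEFAULT_MIN_FORCE_PN,
                  p: float = DEFAULT_P_NM,
                  max_e: int = 6, max_g5: int = 7) -> TraceAnalysis:
    """Full per-trace pipeline: peaks -> WLC fits -> dLc -> classes.

    Event i's increment is the contour-length difference between the
    segments after and before its peak; the last peak is the detachment
    and carries no increment.  Events whose segment fit fails or is too
    short are dropped.
    """
    peaks = detect_events(trace, min_drop, min_force)
    fits: list[WLCSegmentFit] = []
    kept_peaks: list[Peak] = []
    for pk, (start, stop) in zip(peaks, _segment_bounds(trace, peaks)):
        if stop - start < MIN_SEGMENT_POINTS:
            continue
        fit = fit_segment(trace, start, stop, p)
        if not fit.converged:
            continue
        fits.append(fit)
        kept_peaks.append(pk)

    events: list[UnfoldingEvent] = []
    for i, pk in enumerate(kept_peaks):
        if pk.is_detachment:
            events.append(UnfoldingEvent(pk.force, pk.index, fits[i].lc,
                                         None, "detachment"))
        elif i + 1 < len(fits):
            d = fits[i + 1].lc - fits[i].lc
            cls = classify_event(d) if d > 0 else "other"
            events.append(UnfoldingEvent(pk.force, pk.index, fits[i].lc,
                                         d, cls))
    accepted, reason = accept_trace(events, max_e, max_g5)
    return TraceAnalysis(events, fits, accepted, reason)


def accept_trace(events: list[UnfoldingEvent], max_e: int = 6,
                 max_g5: int = 7, min_classified: int = 3
                 ) -> tuple[bool, str | None]:
    """Trace-level QC: enough classified events, a detachment, and
    per-class counts within the construct composition."""
    n_e = sum(1 for e in events if e.domain_class == "E")
    n_g5 = sum(1 for e in events if e.domain_class == "G5")
    has_detach = any(e.domain_class == "detachment" for e in events)
    if n_e + n_g5 < min_classified:
        return False, "too few events"
    if not has_detach:
        return False, "no detachment"
    if n_e > max_e or n_g5 > max_g5:
        return False, "exceeds composition"
    return True, None


@dataclass
class ModalStat:
    mode: float
    sd: float
    n: int
    bin_edges: np.ndarray
    counts: np.ndarray
    degenerate: bool = False


def modal_stats(values, bin_width: float | None = None,
                min_n: int = 20) -> ModalStat:
    """Mode and width from a Gaussian least-squares fit to the histogram.

    ``bin_width=None`` uses the Freedman-Diaconis rule.  Refuses fewer
    than ``min_n`` values.  All-identical input returns a degenerate
    stat (mode = the value, sd = 0).
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_n:
        raise ValueError(f"need >= {min_n} values for a modal statistic, "
                         f"have {v.size}")
    if np.ptp(v) == 0:
        edges = np.array([v[0] - 0.5, v[0] + 0.5])
        return ModalStat(float(v[0]), 0.0, v.size, edges,
                         np.array([v.size]), degenerate=True)
    if bin_width is None:
        q75, q25 = np.percentile(v, [75, 25])
        bin_width = 2.0 * (q75 - q25) * v.size ** (-1.0 / 3.0)
        if bin_width <= 0:
            bin_width = np.ptp(v) / 10.0
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(v, edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    if np.count_nonzero(counts) < 3:
        return ModalStat(float(v.mean()), float(v.std()), v.size, edges,
                         counts, degenerate=True)

    def gauss(x, a, mu, sd):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    mu0 = float(np.average(centers, weights=counts))
    sd0 = max(float(np.sqrt(np.average((centers - mu0) ** 2,
                                       weights=counts))), bin_width / 2)
    try:
        popt, _ = curve_fit(gauss, centers, counts,
                            p0=[counts.max(), mu0, sd0],
                            bounds=([0, -np.inf, 1e-9],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=10000)
        return ModalStat(float(popt[1]), float(abs(popt[2])), v.size,
                         edges, counts)
    except RuntimeError:
        return ModalStat(mu0, sd0, v.size, edges, counts, degenerate=True)


@dataclass
class SpeedSeriesFit:
    slope: float            # pN per e-fold of speed
    intercept: float        # pN
    slope_se: float
    xu_nm: float            # kBT / slope, Bell-Evans estimate


def speed_series(speeds, modal_forces, modal_sds=None,
                 temperature_k: float = 298.0) -> SpeedSeriesFit:
    """Weighted linear regression of modal force on ln(retraction speed).

    Under the Bell-Evans picture the slope equals kBT/xu, giving an
    estimate of the distance to the unfolding transition state.
    """
    from .constants import kbt
    v = np.asarray(speeds, dtype=float)
    f = np.asarray(modal_forces, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 speeds")
    w = (np.ones_like(f) if modal_sds is None
         else 1.0 / np.asarray(modal_sds, dtype=float) ** 2)
    lnv = np.log(v)
    W = np.sum(w)
    xm = np.sum(w * lnv) / W
    ym = np.sum(w * f) / W
    sxx = np.sum(w * (lnv - xm) ** 2)
    slope = np.sum(w * (lnv - xm) * (f - ym)) / sxx
    intercept = ym - slope * xm
    resid = f - (intercept + slope * lnv)
    dof = max(v.size - 2, 1)
    s2 = np.sum(w * resid ** 2) / dof
    slope_se = float(np.sqrt(s2 / sxx))
    xu = kbt(temperature_k) / slope if slope > 0 else np.inf
    return SpeedSeriesFit(float(slope), float(intercept), slope_se,
                          float(xu))
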