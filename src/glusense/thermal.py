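"""Melt-curve analysis for fluorescence-based thermal shift (FTS/DSF) assays.

Ligand binding stabilizes a protein and raises its melting temperature Tm.
In a dye-based thermal shift assay the fluorescence rises sigmoidally through
the unfolding transition (and often quenches again at high temperature as the
unfolded protein aggregates). Tm is taken as the maximum of the smoothed
first derivative dF/dT — the derivative-melt-curve convention — and a ligand
is called a binder when its dTm against the no-ligand control exceeds a
threshold (2 degC by default, strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

BINDER_THRESHOLD_C = 2.0
DEFAULT_SEARCH_RANGE = (30.0, 90.0)
#: smoothing span in degC; converted to an odd point count per curve grid
DEFAULT_SMOOTHING_SPAN_C = 2.0
DEFAULT_WINDOW = 11


def _auto_window(temperature_C: np.ndarray, span_C: float) -> int:
    """Odd Savitzky-Golay window covering ``span_C`` on this curve's grid."""
    step = float(np.median(np.diff(temperature_C)))
    pts = int(round(span_C / step)) | 1
    n = temperature_C.size
    largest_odd = n - 1 if (n - 1) % 2 == 1 else n - 2
    return max(5, min(pts, largest_odd))


@dataclass
class MeltCurve:
    """One temperature-fluorescence melt trace."""

    sample_id: str
    temperature_C: np.ndarray
    fluorescence: np.ndarray
    ligand: str = ""
    ligand_conc_uM: float = 0.0

    def __post_init__(self) -> None:
        self.temperature_C = np.asarray(self.temperature_C, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature_C.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence lengths differ")
        if self.temperature_C.size < 10:
            raise ValueError(
                f"melt curve {self.sample_id!r} has "
                f"{self.temperature_C.size} points; need >= 10"
            )
        if np.any(np.diff(self.temperature_C) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.temperature_C[0] < 20.0 or self.temperature_C[-1] > 100.0:
            raise ValueError("temperatures must lie within [20, 100] degC")


@dataclass
class TmResult:
    """Tm estimate for a single curve; Tm is NaN when no transition exists."""

    tm_C: float
    derivative_peak_height: float
    qc_flags: set = field(default_factory=set)

    @property
    def has_transition(self) -> bool:
        return "no_transition" not in self.qc_flags


@dataclass
class ThermalShiftResult:
    """Tm, ligand-induced shift and binder call for one sample."""

    sample_id: str
    tm_C: float
    delta_Tm_C: float
    is_binder: bool
    derivative_peak_height: float
    qc_flags: set = field(default_factory=set)


def compute_melt_derivative(
    curve: MeltCurve, window: int = DEFAULT_WINDOW, polyorder: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed first derivative dF/dT of a melt curve.

    Fluorescence is smoothed with a Savitzky-Golay (moving-polynomial) filter
    before differencing; near the ends the filter falls back to the edge
    polynomial, equivalent to shrinking the effective window.
    """
    n = curve.temperature_C.size
    if window >= n:
        raise ValueError(f"smoothing window {window} >= curve length {n}")
    if window < 5 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 5")
    smooth = savgol_filter(curve.fluorescence, window, polyorder, mode="interp")
    deriv = np.gradient(smooth, curve.temperature_C)
    return curve.temperature_C, deriv


class TmEstimator(BaseEstimator):
    """Melting-temperature extraction from a single melt curve.

    Tm is the location of the maximum of the smoothed first derivative within
    ``search_range``, refined by a local quadratic fit over the contiguous
    peak region above ``refine_frac`` of the peak height (at a fine
    acquisition grid a 3-point vertex is noise-dominated; fitting the whole
    upper peak region uses the transition's full curvature). The search is
    additionally restricted to temperatures at or below the global (smoothed)
    fluorescence maximum, which tolerates post-transition quenching where the
    signal falls again.

    Parameters
    ----------
    smoothing_window : int or None
        Odd Savitzky-Golay window in points; None (default) chooses the odd
        count spanning ``smoothing_span_C`` on the curve's grid.
    smoothing_span_C : float
        Temperature span of the automatic smoothing window.
    refine_frac : float
        Fraction of the derivative peak height bounding the quadratic
        refinement region.

    Attributes
    ----------
    tm_C_ : float
        Estimated Tm (NaN when no transition is found).
    derivative_peak_height_ : float
    qc_flags_ : set of str
        ``no_transition`` when the derivative is nowhere positive in range,
        ``boundary_peak`` when the maximum sits on a range edge.
    """

    def __init__(
        self,
        smoothing_window: int | None = None,
        smoothing_span_C: float = DEFAULT_SMOOTHING_SPAN_C,
        polyorder: int = 2,
        search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
        refine_frac: float = 0.5,
    ):
        self.smoothing_window = smoothing_window
        self.smoothing_span_C = smoothing_span_C
        self.polyorder = polyorder
        self.search_range = search_range
        self.refine_frac = refine_frac

    def fit(self, curve: MeltCurve, y=None) -> "TmEstimator":
        window = (
            self.smoothing_window
            if self.smoothing_window is not None
            else _auto_window(curve.temperature_C, self.smoothing_span_C)
        )
        T, deriv = compute_melt_derivative(curve, window, self.polyorder)
        lo, hi = self.search_range
        if lo >= hi:
            raise ValueError("search range must satisfy Tlow < Thigh")
        smooth = savgol_filter(
            curve.fluorescence, window, self.polyorder, mode="interp"
        )
        # quench tolerance: only search up to the global fluorescence maximum
        t_fmax = T[int(np.argmax(smooth))]
        mask = (T >= lo) & (T <= min(hi, t_fmax))
        flags: set = set()
        if mask.sum() < 3:
            mask = (T >= lo) & (T <= hi)
            flags.add("quench_dominates")
        if not mask.any():
            raise ValueError("search range does not intersect the curve")
        idx = np.flatnonzero(mask)
        peak_local = idx[int(np.argmax(deriv[idx]))]
        peak_height = float(deriv[peak_local])
        if peak_height <= 0:
            self.tm_C_ = float("nan")
            self.derivative_peak_height_ = peak_height
            self.qc_flags_ = flags | {"no_transition"}
            return self
        if peak_local in (idx[0], idx[-1]):
            flags.add("boundary_peak")
            tm = float(T[peak_local])
        else:
            tm = _refine_peak(T, deriv, idx, peak_local, self.refine_frac)
        self.tm_C_ = float(tm)
        self.derivative_peak_height_ = peak_height
        self.qc_flags_ = flags
        return self

    def result_(self) -> TmResult:
        check_is_fitted(self, "tm_C_")
        return TmResult(self.tm_C_, self.derivative_peak_height_, set(self.qc_flags_))


def _refine_peak(
    T: np.ndarray, deriv: np.ndarray, idx: np.ndarray, peak: int, frac: float
) -> float:
    """Quadratic-vertex refinement over the contiguous region above
    ``frac`` of the peak derivative (within the searchable indices)."""
    thr = frac * deriv[peak]
    lo = peak
    while lo > idx[0] and deriv[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < idx[-1] and deriv[hi + 1] >= thr:
        hi += 1
    t = T[lo : hi + 1]
    d = deriv[lo : hi + 1]
    if t.size < 3:
        return float(T[peak])
    tc = t - t.mean()
    a, b, _ = np.polyfit(tc, d, 2)
    if a >= 0:  # degenerate (not a peak): keep the grid maximum
        return float(T[peak])
    vertex = t.mean() - b / (2.0 * a)
    return float(np.clip(vertex, t[0], t[-1]))


def estimate_tm(
    curve: MeltCurve,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
    smoothing_window: int | None = None,
) -> TmResult:
    """Tm of a melt curve (first-derivative maximum, quadratically refined)."""
    est = TmEstimator(
        smoothing_window=smoothing_window, search_range=search_range
    ).fit(curve)
    return est.result_()


def delta_tm(sample_tm_C: float, reference_tm_C: float) -> float:
    """Ligand-induced melting shift, sample minus no-ligand reference."""
    return float(sample_tm_C) - float(reference_tm_C)


@dataclass
class BinderCall:
    """Binder decision for one ligand, optionally with a dose trend."""

    is_binder: bool
    delta_Tm_C: float
    threshold_C: float
    dose_trend_nondecreasing: bool | None = None


def call_binder(
    delta_Tm_C: float,
    threshold_C: float = BINDER_THRESHOLD_C,
    concentration_series: Sequence[tuple[float, float]] | None = None,
) -> BinderCall:
    """Call a ligand a binder when dTm strictly exceeds the threshold.

    ``concentration_series`` is an optional list of (ligand_conc, dTm) pairs;
    when given, the call also reports whether dTm is non-decreasing with
    concentration (the expected dose trend for genuine binding).
    """
    if np.isnan(delta_Tm_C):
        return BinderCall(False, float("nan"), threshold_C)
    trend = None
    if concentration_series is not None and len(concentration_series) >= 2:
        ordered = sorted(concentration_series)
        shifts = np.array([d for _, d in ordered], dtype=float)
        trend = bool(np.all(np.diff(shifts) >= -1e-9))
    return BinderCall(
        is_binder=bool(delta_Tm_C > threshold_C),
        delta_Tm_C=float(delta_Tm_C),
        threshold_C=float(threshold_C),
        dose_trend_nondecreasing=trend,
    )


def analyze_thermal_shift(
    curves: Sequence[MeltCurve],
    reference_ligand: str = "",
    threshold_C: float = BINDER_THRESHOLD_C,
    search_range: tuple[float, float] = DEFAULT_SEARCH_RANGE,
    smoothing_window: int | None = None,
) -> list[ThermalShiftResult]:
    """Per-sample Tm/dTm/binder calls against the no-ligand reference.

    The reference Tm is the mean over curves whose ligand equals
    ``reference_ligand`` (default: empty/none label).
    """
    results: dict[str, TmResult] = {}
    for c in curves:
        results[c.sample_id] = estimate_tm(
            c, search_range=search_range, smoothing_window=smoothing_window
        )
    ref_tms = [
        results[c.sample_id].tm_C
        for c in curves
        if (c.ligand or "") == reference_ligand
        and results[c.sample_id].has_transition
    ]
    if not ref_tms:
        raise ValueError(
            f"no usable reference curves with ligand == {reference_ligand!r}"
        )
    ref_tm = float(np.mean(ref_tms))
    out = []
    for c in curves:
        res = results[c.sample_id]
        d = delta_tm(res.tm_C, ref_tm) if res.has_transition else float("nan")
        call = call_binder(d, threshold_C)
        out.append(
            ThermalShiftResult(
                sample_id=c.sample_id,
                tm_C=res.tm_C,
                delta_Tm_C=d,
                is_binder=call.is_binder,
                derivative_peak_height=res.derivative_peak_height,
                qc_flags=set(res.qc_flags),
            )
        )
    return out
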