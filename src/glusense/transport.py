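"""Transporter kinetics from biosensor uptake time courses.

An intracellular ratiometric sensor turns transporter activity into a ratio
time course: inverting the calibration curve point-by-point yields the
intracellular concentration trajectory, the slope of its initial linear
segment is the uptake rate, and rates across substrate levels are fitted to
Michaelis-Menten kinetics v = Vmax * S / (Km + S). Inhibitor/competitor
panels are classified from percent inhibition against the untreated baseline
(a protonophore such as CCCP abolishing uptake indicates proton coupling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .calibration import DoseResponseFit, invert_ratio

#: default initial-rate window (s): six samples at the 1-min kinetic interval
DEFAULT_RATE_WINDOW_S = 300.0
COMPLETE_SUPPRESSION_PCT = 90.0
PARTIAL_SUPPRESSION_PCT = 50.0

TransportLabel = Literal[
    "proton_coupled", "thiol_sensitive", "metabolically_gated", "unaffected",
    "indeterminate",
]


@dataclass
class UptakeTimecourse:
    """Intracellular concentration trajectory under one condition."""

    time_s: np.ndarray
    conc_uM: np.ndarray
    substrate_conc_uM: float = 0.0
    competitor: str | None = None
    inhibitor: str | None = None
    od600: float = 5.0
    censored: np.ndarray | None = None  # bool mask of censored points
    calibration: DoseResponseFit | None = None  # fit used for the inversion

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("times must be strictly increasing")
        ok = self.conc_uM[~np.isnan(self.conc_uM)]
        if np.any(ok < 0):
            raise ValueError("concentrations must be non-negative")
        if self.censored is None:
            self.censored = np.zeros(self.time_s.shape, dtype=bool)


@dataclass
class KineticsFit:
    """Michaelis-Menten parameters of transporter-mediated uptake."""

    Km_uM: float
    Vmax_uM_per_min: float
    se_Km_uM: float
    se_Vmax: float
    residual_sd: float
    flags: set = field(default_factory=set)


@dataclass
class TransportCall:
    """Threshold-based transport-type classification."""

    label: TransportLabel
    percent_inhibition: dict[str, float]
    competitor_overlap: dict[str, float] = field(default_factory=dict)


def timecourse_to_concentration(
    fit: DoseResponseFit,
    time_s: Sequence[float],
    ratios: Sequence[float],
    lod_uM: float = 0.0,
    max_censored_frac: float = 0.5,
    **condition,
) -> UptakeTimecourse:
    """Invert a reference-corrected ratio trace into concentrations.

    Points whose ratio falls outside the open (Rmin, Rmax) interval are
    censored: below-range points are carried as 0 (a lower bound, still
    usable in rate fits), above-range points as NaN with the censored mask
    set. A trace with more than ``max_censored_frac`` censored points is
    rejected as unusable.
    """
    t = np.asarray(time_s, dtype=float)
    r = np.asarray(ratios, dtype=float)
    lo, hi = sorted((fit.Rmin, fit.Rmax))
    conc = np.asarray(invert_ratio(fit, r), dtype=float)
    below = r <= lo
    above = r >= hi
    conc[below] = 0.0
    conc[above] = np.nan
    censored = below | above
    if censored.mean() > max_censored_frac:
        raise ValueError(
            f"{censored.sum()}/{censored.size} points censored; "
            "trace unusable for rate estimation"
        )
    return UptakeTimecourse(
        time_s=t, conc_uM=conc, censored=censored, calibration=fit, **condition
    )


@dataclass
class InitialRate:
    """OLS initial uptake rate with its standard error."""

    rate_uM_per_min: float
    se_uM_per_min: float
    n_points: int
    window_s: float
    qc_flags: set = field(default_factory=set)


def initial_rate(
    tc: UptakeTimecourse,
    window_s: float | Literal["adaptive"] = DEFAULT_RATE_WINDOW_S,
    curvature_alpha: float = 0.05,
    weighting: Literal["auto", "sensitivity", "uniform"] = "auto",
) -> InitialRate:
    """Initial uptake rate: weighted LS slope over the initial window, uM/min.

    Sensor-derived concentrations have heteroscedastic noise — the ratio
    noise is roughly constant, so the concentration error grows as the
    inverse of the local calibration slope dR/dC. When the trace carries its
    calibration (``weighting="auto"``/``"sensitivity"``) points are weighted
    by (dR/dC)^2, the inverse-variance weights under constant ratio noise;
    ``"uniform"`` gives the ordinary least-squares slope. Above-range
    censored points are excluded; below-range points enter as 0.

    ``window_s="adaptive"`` starts from the full trace and shrinks the window
    until the quadratic curvature term is statistically insignificant
    (t-test at ``curvature_alpha``), guarding against saturation bias.
    A negative slope at positive substrate is returned with a QC flag.
    """
    t0 = tc.time_s[0]
    usable = ~np.isnan(tc.conc_uM)
    flags: set = set()

    def _fit_window(limit_s: float):
        m = usable & (tc.time_s - t0 <= limit_s + 1e-9)
        return tc.time_s[m], tc.conc_uM[m]

    if window_s == "adaptive":
        limit = float(tc.time_s[-1] - t0)
        while True:
            t, c = _fit_window(limit)
            if len(t) < 4 or not _curvature_significant(t, c, curvature_alpha):
                break
            limit *= 0.5
        if len(t) < 3:
            t, c = _fit_window(float(tc.time_s[-1] - t0))
            flags.add("adaptive_window_exhausted")
        window = limit
    else:
        window = float(window_s)
        t, c = _fit_window(window)
    if len(t) < 3:
        raise ValueError(
            f"only {len(t)} usable points inside the {window:g}-s window; need >= 3"
        )
    t_min = (t - t[0]) / 60.0
    fit = tc.calibration
    use_weights = weighting == "sensitivity" or (
        weighting == "auto" and fit is not None
    )
    if use_weights:
        if fit is None:
            raise ValueError("sensitivity weighting needs tc.calibration")

        def weights_at(conc):
            conc = np.maximum(conc, 0.0)
            dRdC = (
                abs(fit.Rmax - fit.Rmin)
                * fit.hill_p
                * fit.Kd_uM**fit.hill_p
                * np.maximum(conc, 1e-9) ** (fit.hill_p - 1.0)
                / (fit.Kd_uM**fit.hill_p + conc**fit.hill_p) ** 2
            )
            return dRdC**2

        def wls(w):
            X = np.column_stack([np.ones_like(t_min), t_min])
            WX = X * w[:, None]
            beta, *_ = np.linalg.lstsq(X.T @ WX, WX.T @ c, rcond=None)
            return beta, X, WX

        # two-pass: final weights evaluated on the fitted line, not on the
        # noisy points, so weight noise does not correlate with residuals
        beta, X, WX = wls(weights_at(c))
        for _ in range(2):
            pred = np.maximum(beta[0] + beta[1] * t_min, 0.0)
            w = weights_at(pred)
            beta, X, WX = wls(w)
        resid = c - X @ beta
        dof = max(len(t_min) - 2, 1)
        sigma2 = float(resid @ (w * resid)) / dof
        cov = sigma2 * np.linalg.inv(X.T @ WX)
        slope, se = float(beta[1]), float(np.sqrt(max(cov[1, 1], 0.0)))
    else:
        slope, _, _, _, se = stats.linregress(t_min, c)
    if slope < 0 and tc.substrate_conc_uM > 0:
        flags.add("negative_uptake_slope")
    return InitialRate(
        rate_uM_per_min=float(slope),
        se_uM_per_min=float(se),
        n_points=len(t),
        window_s=window,
        qc_flags=flags,
    )


def _curvature_significant(t: np.ndarray, c: np.ndarray, alpha: float) -> bool:
    """t-test on the quadratic coefficient of a degree-2 polynomial fit."""
    x = (t - t[0]) / 60.0
    X = np.column_stack([np.ones_like(x), x, x**2])
    coef, res, rank, _ = np.linalg.lstsq(X, c, rcond=None)
    dof = len(x) - 3
    if dof <= 0 or rank < 3:
        return False
    sse = float(res[0]) if res.size else float(np.sum((c - X @ coef) ** 2))
    sigma2 = sse / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_q = np.sqrt(cov[2, 2])
    if se_q == 0:
        return False
    tstat = abs(coef[2]) / se_q
    return tstat > stats.t.ppf(1 - alpha / 2, dof)


class MichaelisMentenEstimator(BaseEstimator, RegressorMixin):
    """Michaelis-Menten rate law v = Vmax*S/(Km+S) as an sklearn regressor.

    ``fit(S, v)`` estimates Km and Vmax by nonlinear least squares with a
    Lineweaver-Burk-seeded start; standard errors come from the Jacobian.
    On non-convergence the Lineweaver-Burk estimate is attached to the
    raised error as a diagnostic, never reported as the primary fit.

    Attributes
    ----------
    Km_uM_, Vmax_ : fitted parameters
    se_Km_uM_, se_Vmax_ : asymptotic standard errors
    residual_sd_ : residual standard deviation
    flags_ : QC flags (``narrow_substrate_span`` when the substrate levels
        fail to span [Km/3, 3*Km] of the estimate)
    """

    def __init__(self, min_levels: int = 5):
        self.min_levels = min_levels

    def fit(self, X, y) -> "MichaelisMentenEstimator":
        S = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        if S.shape != v.shape:
            raise ValueError("substrate and rate vectors must match")
        if len(np.unique(S[S > 0])) < self.min_levels:
            raise ValueError(
                f"need >= {self.min_levels} distinct positive substrate levels"
            )
        km0, vmax0 = _lineweaver_burk(S, v)
        try:
            popt, pcov = optimize.curve_fit(
                lambda s, vmax, km: vmax * s / (km + s),
                S,
                v,
                p0=[max(vmax0, v.max(), 1e-9), max(km0, 1e-9)],
                bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as err:
            err.lineweaver_burk = {"Km_uM": km0, "Vmax": vmax0}
            raise
        vmax, km = popt
        self.Vmax_, self.Km_uM_ = float(vmax), float(km)
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        self.se_Vmax_, self.se_Km_uM_ = float(se[0]), float(se[1])
        dof = max(len(S) - 2, 1)
        resid = v - vmax * S / (km + S)
        self.residual_sd_ = float(np.sqrt(resid @ resid / dof))
        self.flags_ = set()
        span_lo, span_hi = S[S > 0].min(), S.max()
        if span_lo > km / 3.0 or span_hi < 3.0 * km:
            self.flags_.add("narrow_substrate_span")
            warnings.warn(
                "substrate levels do not span [Km/3, 3*Km] of the estimate",
                stacklevel=2,
            )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "Km_uM_")
        S = np.asarray(X, dtype=float).ravel()
        return self.Vmax_ * S / (self.Km_uM_ + S)

    def as_fit(self) -> KineticsFit:
        check_is_fitted(self, "Km_uM_")
        return KineticsFit(
            Km_uM=self.Km_uM_,
            Vmax_uM_per_min=self.Vmax_,
            se_Km_uM=self.se_Km_uM_,
            se_Vmax=self.se_Vmax_,
            residual_sd=self.residual_sd_,
            flags=set(self.flags_),
        )


def _lineweaver_burk(S: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Double-reciprocal seed estimate (1/v vs 1/S); robust to its own noise
    only as a starting point."""
    m = (S > 0) & (v > 0)
    if m.sum() < 2:
        return float(np.median(S[S > 0])), float(v.max() if len(v) else 1.0)
    slope, intercept, *_ = stats.linregress(1.0 / S[m], 1.0 / v[m])
    if intercept <= 0:
        return float(np.median(S[S > 0])), float(v.max())
    vmax = 1.0 / intercept
    km = slope * vmax
    return float(max(km, 1e-9)), float(vmax)


def fit_michaelis_menten(substrate_uM, rates) -> KineticsFit:
    """Fit v = Vmax*S/(Km+S) to per-level initial rates."""
    return MichaelisMentenEstimator().fit(substrate_uM, rates).as_fit()


#: treatment-class keywords used by classify_transport
PROTONOPHORE_CLASS = "protonophore"
THIOL_CLASS = "thiol_reagent"
METABOLIC_CLASS = "metabolic_inhibitor"


def classify_transport(
    baseline_rate: float,
    treated_rates: Mapping[str, float],
    treatment_classes: Mapping[str, str],
    complete_pct: float = COMPLETE_SUPPRESSION_PCT,
    partial_pct: float = PARTIAL_SUPPRESSION_PCT,
    competitor_rates: Mapping[str, float] | None = None,
) -> TransportCall:
    """Classify the transport mechanism from an inhibitor panel.

    Percent inhibition per treatment is 100*(1 - treated/baseline). The call
    is ``proton_coupled`` when a protonophore-class treatment (e.g. CCCP)
    reaches the complete-suppression threshold while every other class stays
    below the partial threshold; analogous rules give ``thiol_sensitive`` and
    ``metabolically_gated``. Without any protonophore-class treatment the
    classification is ``indeterminate``. Competitor substrates are reported
    as percent rate reduction, not used for the label.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline rate must be positive")
    inhibition = {
        name: 100.0 * (1.0 - rate / baseline_rate)
        for name, rate in treated_rates.items()
    }
    by_class: dict[str, float] = {}
    for name, pct in inhibition.items():
        cls = treatment_classes.get(name, "other")
        by_class[cls] = max(by_class.get(cls, -np.inf), pct)
    overlap = {}
    if competitor_rates:
        overlap = {
            name: 100.0 * (1.0 - rate / baseline_rate)
            for name, rate in competitor_rates.items()
        }
    if PROTONOPHORE_CLASS not in by_class:
        return TransportCall("indeterminate", inhibition, overlap)
    label: TransportLabel = "unaffected"
    for cls, lab in (
        (PROTONOPHORE_CLASS, "proton_coupled"),
        (THIOL_CLASS, "thiol_sensitive"),
        (METABOLIC_CLASS, "metabolically_gated"),
    ):
        others = [v for k, v in by_class.items() if k != cls]
        if (
            by_class.get(cls, -np.inf) >= complete_pct
            and all(v < partial_pct for v in others)
        ):
            label = lab
            break
    return TransportCall(label, inhibition, overlap)
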