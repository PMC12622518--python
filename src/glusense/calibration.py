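"""Ratiometric dose-response calibration, inversion, LOD and quantification.

The biosensor reports ligand concentration through the excitation ratio
R = F405/F488 (emission 528 nm). Calibration fits the Hill-type model

    R([G]) = Rmax + (Rmin - Rmax) / (1 + ([G]/Kd)^p)

so that R(0) = Rmin, R(inf) = Rmax, R(Kd) = (Rmin + Rmax)/2 for any Hill
slope p. The maximum fractional response is dRmax = (Rmax - Rmin)/Rmin.
Absolute quantification inverts the fitted curve,

    [G] = Kd * ((R - Rmin)/(Rmax - R))^(1/p),

with censoring outside (Rmin, Rmax), and the detection limit follows the
conventional blank + 3*sigma criterion mapped through the inverse curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

Censoring = Literal["quantified", "below_LOD", "above_range", "below_range"]

#: default dilution for the 3:1 sample:sensor mixing of the plate assay
MIXING_DILUTION = 4.0 / 3.0


@dataclass
class RatioMeasurement:
    """One dual-channel fluorescence reading."""

    ratio_R: float
    F405: float | None = None
    F488: float | None = None
    reference_ratio: float | None = None
    condition: str = ""
    analyte_conc_uM: float | None = None
    replicate: int = 1
    timepoint_s: float | None = None
    well_id: str = ""

    def __post_init__(self) -> None:
        if self.ratio_R <= 0:
            raise ValueError("ratio must be positive")
        if self.F405 is not None and self.F488 is not None:
            if abs(self.ratio_R - self.F405 / self.F488) > 1e-9 * self.ratio_R:
                raise ValueError("ratio_R inconsistent with F405/F488")


@dataclass
class DoseResponseFit:
    """Fitted Hill dose-response parameters with uncertainties."""

    Rmin: float
    Rmax: float
    Kd_uM: float
    hill_p: float
    covariance: np.ndarray
    delta_Rmax: float
    n_points: int
    residual_sd: float
    valid_range_uM: tuple[float, float]
    flags: set = field(default_factory=set)

    @property
    def se(self) -> dict[str, float]:
        d = np.sqrt(np.clip(np.diag(self.covariance), 0, np.inf))
        return dict(zip(("Rmin", "Rmax", "Kd_uM", "hill_p"), d))


@dataclass
class ConcentrationEstimate:
    """Inverted sample concentration with censoring status."""

    conc_uM: float
    ci_low_uM: float
    ci_high_uM: float
    censoring: Censoring
    dilution_factor: float = 1.0
    sample_id: str = ""
    n_replicates: int = 1


@dataclass
class AgreementStats:
    """OLS agreement of sensor estimates against a reference method."""

    slope: float
    intercept_uM: float
    r_squared: float
    mean_relative_error_pct: float
    cv_pct_by_level: dict[float, float] = field(default_factory=dict)
    n: int = 0


def hill_ratio(conc_uM, Rmin: float, Rmax: float, Kd_uM: float, hill_p: float):
    """Evaluate the dose-response model; conc = 0 maps exactly to Rmin."""
    c = np.asarray(conc_uM, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    with np.errstate(divide="ignore"):
        x = np.power(c / Kd_uM, hill_p)
    return Rmax + (Rmin - Rmax) / (1.0 + x)


class HillCalibrator(BaseEstimator, RegressorMixin):
    """Hill dose-response calibration as a scikit-learn regressor.

    ``fit(conc_uM, ratio)`` estimates (Rmin, Rmax, Kd, p) by nonlinear least
    squares with multi-start over the Hill slope; ``predict`` evaluates the
    curve and ``inverse`` maps measured ratios back to concentrations.

    Parameters
    ----------
    fix_hill_slope : float or None
        If a number, the Hill slope is fixed there (its covariance entries
        are zero); if None (default) p is free within ``p_bounds``.
    p_bounds : (float, float)
        Box bounds for the free Hill slope.
    direction : {"on", "off"}
        Expected response direction: "on" sensors increase the ratio with
        ligand (Rmax > Rmin); "off" sensors decrease it.
    error_model : {"relative", "absolute"}
        "relative" (default) assumes multiplicative measurement noise and
        iteratively reweights residuals by the fitted curve — the realistic
        model for plate-reader fluorescence, and the one that makes the
        parameter covariance (hence CIs) honest; "absolute" is plain
        unweighted least squares.
    monotonicity_rho : float
        |Spearman rho| between concentration and ratio below which the fit
        is flagged non-monotone.

    Attributes
    ----------
    Rmin_, Rmax_, Kd_uM_, hill_p_ : fitted parameters
    covariance_ : (4, 4) parameter covariance (Rmin, Rmax, Kd, p order)
    delta_Rmax_ : (Rmax - Rmin)/Rmin
    residual_sd_ : residual standard deviation
    valid_range_uM_ : 10-90% response band, the quantifiable range
    flags_ : QC flags raised during fitting
    """

    _PARAM_NAMES = ("Rmin", "Rmax", "Kd_uM", "hill_p")

    def __init__(
        self,
        fix_hill_slope: float | None = None,
        p_bounds: tuple[float, float] = (0.3, 4.0),
        direction: Literal["on", "off"] = "on",
        error_model: Literal["relative", "absolute"] = "relative",
        monotonicity_rho: float = 0.5,
    ):
        self.fix_hill_slope = fix_hill_slope
        self.p_bounds = p_bounds
        self.direction = direction
        self.error_model = error_model
        self.monotonicity_rho = monotonicity_rho

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "HillCalibrator":
        conc = np.asarray(X, dtype=float).ravel()
        ratio = np.asarray(y, dtype=float).ravel()
        if conc.shape != ratio.shape:
            raise ValueError("conc and ratio must have the same length")
        if np.any(ratio <= 0):
            raise ValueError("ratios must be positive")
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0")
        n_distinct = len(np.unique(conc))
        if n_distinct < 5 or 0.0 not in conc:
            raise ValueError(
                "calibration needs >= 5 distinct concentrations including 0"
            )
        self.flags_ = set()

        pos = conc[conc > 0]
        kd_lo, kd_hi = pos.min() / 10.0, conc.max() * 10.0

        rho, _ = stats.spearmanr(conc, ratio)
        if abs(rho) < self.monotonicity_rho:
            self.flags_.add("non_monotone_data")

        span = ratio.max() - ratio.min()
        if span < 1e-9 * ratio.mean():
            self.flags_.add("flat_curve")

        if self.direction == "on":
            r_lo, r_hi = ratio.min(), ratio.max()
        else:
            r_lo, r_hi = ratio.max(), ratio.min()
        # Kd init: concentration whose ratio is nearest half-response
        half = 0.5 * (r_lo + r_hi)
        if len(pos):
            kd0 = float(pos[np.argmin(np.abs(ratio[conc > 0] - half))])
            kd0 = min(max(kd0, kd_lo), kd_hi)
        else:
            kd0 = np.sqrt(kd_lo * kd_hi)

        fixed_p = self.fix_hill_slope
        starts = [1.0, 0.5, 2.0] if fixed_p is None else [float(fixed_p)]

        best = None
        for p0 in starts:
            try:
                popt, pcov = self._curve_fit(
                    conc, ratio, (r_lo, r_hi, kd0, p0), (kd_lo, kd_hi), fixed_p
                )
            except RuntimeError:
                continue
            resid = ratio - hill_ratio(conc, *popt)
            cost = float(resid @ resid)
            if best is None or cost < best[2]:
                best = (popt, pcov, cost)
        if best is None:
            raise RuntimeError(
                "dose-response fit failed to converge from all starts "
                f"(Kd bounds [{kd_lo:g}, {kd_hi:g}] uM)"
            )
        popt, pcov, cost = best
        Rmin, Rmax, Kd, p = popt
        if Rmin <= 0:
            raise ValueError("fitted Rmin must be positive")
        if self.direction == "on" and Rmax <= Rmin:
            self.flags_.add("inverted_response")
        rel = 1e-6
        if Kd <= kd_lo * (1 + rel) or Kd >= kd_hi * (1 - rel):
            self.flags_.add("kd_at_bound")

        self.Rmin_, self.Rmax_, self.Kd_uM_, self.hill_p_ = map(float, popt)
        self.covariance_ = pcov
        self.delta_Rmax_ = (self.Rmax_ - self.Rmin_) / self.Rmin_
        dof = max(len(conc) - (3 if fixed_p is not None else 4), 1)
        self.residual_sd_ = float(np.sqrt(cost / dof))
        band = 9.0 ** (1.0 / self.hill_p_)
        self.valid_range_uM_ = (self.Kd_uM_ / band, self.Kd_uM_ * band)
        self.n_points_ = len(conc)
        return self

    def _curve_fit(self, conc, ratio, x0, kd_bounds, fixed_p):
        r0_lo, r0_hi, kd0, p0 = x0
        eps = 1e-12
        if fixed_p is None:
            model = hill_ratio
            p_init = [r0_lo, r0_hi, kd0, p0]
            bounds = (
                [eps, eps, kd_bounds[0], self.p_bounds[0]],
                [np.inf, np.inf, kd_bounds[1], self.p_bounds[1]],
            )
        else:
            def model(c, rmin, rmax, kd):
                return hill_ratio(c, rmin, rmax, kd, fixed_p)

            p_init = [r0_lo, r0_hi, kd0]
            bounds = (
                [eps, eps, kd_bounds[0]], [np.inf, np.inf, kd_bounds[1]]
            )
        popt, pcov = optimize.curve_fit(
            model, conc, ratio, p0=p_init, bounds=bounds, maxfev=20000
        )
        if self.error_model == "relative":
            # IRLS with sigma proportional to the fitted curve: the honest
            # covariance under multiplicative readout noise
            for _ in range(2):
                sigma = np.clip(model(conc, *popt), 1e-12, np.inf)
                popt, pcov = optimize.curve_fit(
                    model, conc, ratio, p0=popt, bounds=bounds, sigma=sigma,
                    absolute_sigma=False, maxfev=20000,
                )
        elif self.error_model != "absolute":
            raise ValueError(f"unknown error model {self.error_model!r}")
        if fixed_p is not None:
            popt = np.append(popt, fixed_p)
            full = np.zeros((4, 4))
            full[:3, :3] = pcov
            pcov = full
        return popt, pcov

    # -- evaluation --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "Kd_uM_")
        conc = np.asarray(X, dtype=float).ravel()
        return hill_ratio(conc, self.Rmin_, self.Rmax_, self.Kd_uM_, self.hill_p_)

    def inverse(self, ratio) -> np.ndarray:
        """Concentration for measured ratios; NaN outside (Rmin, Rmax)."""
        check_is_fitted(self, "Kd_uM_")
        R = np.asarray(ratio, dtype=float)
        lo, hi = sorted((self.Rmin_, self.Rmax_))
        with np.errstate(divide="ignore", invalid="ignore"):
            arg = (R - self.Rmin_) / (self.Rmax_ - R)
            out = self.Kd_uM_ * np.power(arg, 1.0 / self.hill_p_)
        out = np.where((R > lo) & (R < hi), out, np.nan)
        return out if out.ndim else float(out)

    def as_fit(self) -> DoseResponseFit:
        check_is_fitted(self, "Kd_uM_")
        return DoseResponseFit(
            Rmin=self.Rmin_,
            Rmax=self.Rmax_,
            Kd_uM=self.Kd_uM_,
            hill_p=self.hill_p_,
            covariance=self.covariance_,
            delta_Rmax=self.delta_Rmax_,
            n_points=self.n_points_,
            residual_sd=self.residual_sd_,
            valid_range_uM=self.valid_range_uM_,
            flags=set(self.flags_),
        )


# -- functional surface ----------------------------------------------------


def _calibrator_from_fit(fit: DoseResponseFit) -> HillCalibrator:
    cal = HillCalibrator()
    cal.Rmin_, cal.Rmax_ = fit.Rmin, fit.Rmax
    cal.Kd_uM_, cal.hill_p_ = fit.Kd_uM, fit.hill_p
    cal.covariance_ = fit.covariance
    cal.delta_Rmax_ = fit.delta_Rmax
    cal.residual_sd_ = fit.residual_sd
    cal.valid_range_uM_ = fit.valid_range_uM
    cal.n_points_ = fit.n_points
    cal.flags_ = set(fit.flags)
    return cal


def make_fit(
    Rmin: float, Rmax: float, Kd_uM: float, hill_p: float = 1.0
) -> DoseResponseFit:
    """Construct a fit record from known parameters (e.g. a prior calibration)."""
    band = 9.0 ** (1.0 / hill_p)
    return DoseResponseFit(
        Rmin=Rmin,
        Rmax=Rmax,
        Kd_uM=Kd_uM,
        hill_p=hill_p,
        covariance=np.zeros((4, 4)),
        delta_Rmax=(Rmax - Rmin) / Rmin,
        n_points=0,
        residual_sd=0.0,
        valid_range_uM=(Kd_uM / band, Kd_uM * band),
    )


def fit_dose_response(
    conc_uM,
    ratio=None,
    *,
    fix_hill_slope: float | None = None,
    direction: Literal["on", "off"] = "on",
) -> DoseResponseFit:
    """Fit the Hill dose-response model to calibration points.

    Accepts either (conc array, ratio array) or a sequence of
    :class:`RatioMeasurement` with known ``analyte_conc_uM``.
    """
    if ratio is None:
        points = list(conc_uM)
        conc_uM = [m.analyte_conc_uM for m in points]
        ratio = [m.ratio_R for m in points]
        if any(c is None for c in conc_uM):
            raise ValueError("calibration measurements need analyte_conc_uM")
    cal = HillCalibrator(fix_hill_slope=fix_hill_slope, direction=direction)
    cal.fit(conc_uM, ratio)
    return cal.as_fit()


def delta_r_max(fit: DoseResponseFit) -> float:
    """Maximum fractional ratio change, (Rmax - Rmin)/Rmin."""
    if fit.Rmin <= 0:
        raise ValueError("Rmin must be positive")
    return (fit.Rmax - fit.Rmin) / fit.Rmin


def predict_ratio(fit: DoseResponseFit, conc_uM) -> float | np.ndarray:
    """Evaluate the fitted dose-response curve at given concentrations."""
    out = hill_ratio(conc_uM, fit.Rmin, fit.Rmax, fit.Kd_uM, fit.hill_p)
    return float(out) if np.ndim(out) == 0 else out


def invert_ratio(fit: DoseResponseFit, ratio) -> float | np.ndarray:
    """Raw curve inversion; NaN outside the open interval (Rmin, Rmax)."""
    out = _calibrator_from_fit(fit).inverse(ratio)
    return out


def invert_dose_response(
    fit: DoseResponseFit, ratio: float, dilution_factor: float = 1.0
) -> ConcentrationEstimate:
    """Invert one measured ratio into a censoring-aware concentration."""
    lo, hi = sorted((fit.Rmin, fit.Rmax))
    on = fit.Rmax >= fit.Rmin
    if ratio <= lo:
        cens = "below_range" if on else "above_range"
        return ConcentrationEstimate(0.0, 0.0, 0.0, cens, dilution_factor)
    if ratio >= hi:
        cens = "above_range" if on else "below_range"
        return ConcentrationEstimate(np.inf, np.inf, np.inf, cens, dilution_factor)
    conc = float(invert_ratio(fit, ratio)) * dilution_factor
    return ConcentrationEstimate(conc, conc, conc, "quantified", dilution_factor)


def estimate_lod(fit: DoseResponseFit, blanks: Sequence[float]) -> float:
    """Limit of detection: blank mean + 3*sd mapped through the inverse curve.

    Returns 0 for noiseless blanks; NaN (with a warning) when the blank
    criterion already exceeds the sensor's dynamic range.
    """
    blanks = np.asarray(blanks, dtype=float)
    if blanks.size < 3:
        raise ValueError("LOD estimation needs >= 3 blank replicates")
    sd = float(blanks.std(ddof=1))
    if sd == 0.0:
        return 0.0
    on = fit.Rmax >= fit.Rmin
    crit = float(blanks.mean()) + (3.0 * sd if on else -3.0 * sd)
    hi = max(fit.Rmin, fit.Rmax)
    lo = min(fit.Rmin, fit.Rmax)
    if (on and crit >= hi) or (not on and crit <= lo):
        warnings.warn(
            "blank + 3*sd exceeds the sensor range; LOD undefined", stacklevel=2
        )
        return float("nan")
    conc = invert_ratio(fit, crit)
    if np.isnan(conc):
        return 0.0
    return float(conc)


def reference_correct(sensor_ratio, reference_ratio):
    """pH/reference correction: sensor ratio divided by the reference ratio."""
    ref = np.asarray(reference_ratio, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference ratio must be positive")
    out = np.asarray(sensor_ratio, dtype=float) / ref
    return float(out) if np.ndim(out) == 0 else out


def normalize_to_control(values, control_values):
    """Divide values by the mean of the control group (control maps to 1)."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control set is empty")
    mean = control.mean()
    if mean <= 0:
        raise ValueError("control mean must be positive")
    out = np.asarray(values, dtype=float) / mean
    return float(out) if np.ndim(out) == 0 else out


def _inverse_gradient(fit: DoseResponseFit, R: float) -> tuple[np.ndarray, float]:
    """Gradient of the inverse curve wrt (Rmin, Rmax, Kd, p) and wrt R."""
    rmin, rmax, kd, p = fit.Rmin, fit.Rmax, fit.Kd_uM, fit.hill_p
    a = R - rmin
    b = rmax - R
    c = kd * (a / b) ** (1.0 / p)
    dc_dkd = (a / b) ** (1.0 / p)
    dc_da = c / (p * a)
    dc_db = -c / (p * b)
    dc_drmin = -dc_da
    dc_drmax = dc_db
    dc_dp = -c * np.log(a / b) / p**2
    dc_dR = dc_da - dc_db
    return np.array([dc_drmin, dc_drmax, dc_dkd, dc_dp]), float(dc_dR)


def quantify_samples(
    fit: DoseResponseFit,
    samples: Mapping[str, Sequence[float]],
    dilution_factor: float = MIXING_DILUTION,
    lod_uM: float | None = None,
) -> list[ConcentrationEstimate]:
    """Quantify samples from replicate ratios via curve inversion.

    Parameters
    ----------
    samples : mapping sample_id -> replicate ratios
    dilution_factor : float
        Sample dilution in the assay well; the default 4/3 corresponds to
        mixing sample and sensor 3:1, so well concentration = 3/4 sample.
    lod_uM : float, optional
        Detection limit; estimates below it are censored ``below_LOD``.

    The 95% CI combines, in quadrature, the delta-method variance from the
    calibration covariance with the replicate scatter propagated through the
    inverse-curve slope.
    """
    if dilution_factor < 1.0:
        raise ValueError("dilution factor must be >= 1")
    out: list[ConcentrationEstimate] = []
    lo, hi = sorted((fit.Rmin, fit.Rmax))
    for sample_id, ratios in samples.items():
        r = np.asarray(list(ratios), dtype=float)
        n = r.size
        mean_r = float(r.mean())
        if mean_r <= lo or mean_r >= hi:
            est = invert_dose_response(fit, mean_r, dilution_factor)
            est.sample_id = sample_id
            est.n_replicates = n
            out.append(est)
            continue
        conc_well = float(invert_ratio(fit, mean_r))
        conc = conc_well * dilution_factor
        grad, dc_dR = _inverse_gradient(fit, mean_r)
        var_fit = float(grad @ fit.covariance @ grad)
        sem_r = float(r.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        var_rep = (dc_dR * sem_r) ** 2
        sd = dilution_factor * np.sqrt(max(var_fit + var_rep, 0.0))
        ci_lo, ci_hi = max(conc - 1.96 * sd, 0.0), conc + 1.96 * sd
        censoring: Censoring = "quantified"
        if lod_uM is not None and conc_well < lod_uM:
            censoring = "below_LOD"
        out.append(
            ConcentrationEstimate(
                conc_uM=conc,
                ci_low_uM=ci_lo,
                ci_high_uM=ci_hi,
                censoring=censoring,
                dilution_factor=dilution_factor,
                sample_id=sample_id,
                n_replicates=n,
            )
        )
    return out


def method_agreement(
    estimates_uM: Sequence[float],
    reference_uM: Sequence[float],
    estimate_sds_uM: Sequence[float] | None = None,
    replicate_estimates: Mapping[float, Sequence[float]] | None = None,
) -> AgreementStats:
    """Agreement of sensor estimates with a reference method (e.g. HPLC).

    Regressing estimate on reference gives slope/intercept/R-squared; the
    mean relative error is computed over strictly positive reference levels.
    Sensor estimates are heteroscedastic across the dynamic range, so when
    per-estimate standard deviations (e.g. from the quantification CIs) are
    supplied the regression is inverse-variance weighted and R-squared is the
    weighted version; without them plain OLS is used. Per-level CVs come
    from ``replicate_estimates`` when provided.
    """
    est = np.asarray(estimates_uM, dtype=float)
    ref = np.asarray(reference_uM, dtype=float)
    if est.shape != ref.shape or est.size < 3:
        raise ValueError("need >= 3 paired estimates")
    if np.allclose(ref, ref[0]):
        raise ValueError("reference values have zero variance")
    if estimate_sds_uM is not None:
        sds = np.asarray(estimate_sds_uM, dtype=float)
        w = 1.0 / np.clip(sds, np.max(sds) * 1e-6, np.inf) ** 2
        X = np.column_stack([np.ones_like(ref), ref])
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ est)
        intercept, slope = float(beta[0]), float(beta[1])
        yhat = X @ beta
        ybar = float(np.sum(w * est) / np.sum(w))
        ss_res = float(np.sum(w * (est - yhat) ** 2))
        ss_tot = float(np.sum(w * (est - ybar) ** 2))
        r_value = np.sqrt(max(1.0 - ss_res / ss_tot, 0.0))
    else:
        slope, intercept, r_value, _, _ = stats.linregress(ref, est)
    mask = ref > 0
    mre = float(np.mean(np.abs(est[mask] - ref[mask]) / ref[mask]) * 100.0)
    cvs: dict[float, float] = {}
    if replicate_estimates:
        for level, reps in replicate_estimates.items():
            reps = np.asarray(list(reps), dtype=float)
            if reps.size > 1 and reps.mean() > 0:
                cvs[float(level)] = float(reps.std(ddof=1) / reps.mean() * 100.0)
    return AgreementStats(
        slope=float(slope),
        intercept_uM=float(intercept),
        r_squared=float(r_value**2),
        mean_relative_error_pct=mre,
        cv_pct_by_level=cvs,
        n=int(est.size),
    )
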