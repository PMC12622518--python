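"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of (config, seed): reruns are bit-identical
and every dataset ships a truth record so recovery can be tested end-to-end.
Scenario defaults are the study conditions of the assays being emulated:

* dose-response truth (Rmin 1, Rmax 7.46 i.e. dRmax 646%, Kd 60.68 uM, p 1)
  — the purified-sensor calibration;
* melt curves over 25-95 degC with post-transition quenching;
* uptake truth Km 23.34 uM with the in-cell calibration (Kd 10.22 uM);
* labeling truth f_hydroxylation 0.9338 from a 50:50 13C/12C glutarate feed
  at 99% tracer purity.

Noise models: multiplicative Gaussian on the ratiometric readout
(common-mode fluorescence noise cancels in a ratio) and additive Gaussian
per isotopologue channel, scaled to the total peak area.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import hill_ratio
from .flux import build_correction_matrix
from .isotopes import binomial_shift_vector
from .thermal import MeltCurve

_ROLE = {"melt": 1, "dose": 2, "uptake": 3, "labeling": 4, "comparison": 5, "ph": 6}


def _rng(seed: int, role: str) -> np.random.Generator:
    # one stream per generated file role: adding replicates elsewhere never
    # perturbs this file
    return np.random.default_rng([int(seed) % (2**31), _ROLE[role]])


@dataclass
class MeltConfig:
    Tm_C: float = 52.3
    amplitude: float = 1000.0
    transition_width_C: float = 1.5
    baseline: float = 200.0
    quench_rate: float = 0.015  # fraction of amplitude lost per degC
    noise_sd_frac: float = 0.01
    grid_step_C: float = 0.1
    t_start_C: float = 25.0
    t_end_C: float = 95.0
    # (sample_id, ligand, ligand_conc_uM, programmed shift degC)
    samples: tuple = (("control", "", 0.0, 0.0),)


@dataclass
class DoseConfig:
    Rmin: float = 1.0
    Rmax: float = 7.46
    Kd_uM: float = 60.68
    hill_p: float = 1.0
    concentrations_uM: tuple = (
        0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0, 2000.0,
    )
    replicates: int = 3
    noise_model: str = "multiplicative"
    noise_sd: float = 0.03
    F488: float = 1000.0


@dataclass
class UptakeConfig:
    Km_uM: float = 23.34
    Vmax_uM_per_min: float = 10.0
    substrate_levels_uM: tuple = (5.0, 10.0, 15.0, 25.0, 40.0, 60.0, 100.0, 200.0)
    sample_interval_s: float = 60.0
    duration_s: float = 600.0
    ratio_noise_sd: float = 0.05
    # in-cell sensor calibration used to map concentration -> ratio
    sensor_Rmin: float = 1.0
    sensor_Rmax: float = 7.46
    sensor_Kd_uM: float = 10.22
    sensor_hill_p: float = 1.0
    od600: float = 5.0
    F488: float = 1000.0
    # treatment -> (class, percent inhibition), applied at one substrate level
    inhibition_pct: tuple = (
        ("CCCP", "protonophore", 95.0),
        ("NEM", "thiol_reagent", 10.0),
        ("azide", "metabolic_inhibitor", 10.0),
    )
    treatment_substrate_uM: float = 100.0


@dataclass
class LabelingConfig:
    f_hydroxylation: float = 0.9338
    feed_label_fraction: float = 0.5
    tracer_purity: float = 0.99
    fragment_formulas: tuple = (("L2HG", "C5H8O5"), ("citrate", "C6H8O7"))
    n_tracer_carbons: int = 5
    # illustrative boundary citrate MDVs: hydroxylation route concentrates
    # label at m+4/m+5, the acetyl-CoA route at m+2/m+3
    boundary_H: tuple = (0.44, 0.02, 0.03, 0.06, 0.15, 0.30)
    boundary_D: tuple = (0.50, 0.05, 0.25, 0.15, 0.04, 0.01)
    noise_sd: float = 0.01  # additive, as a fraction of total area
    replicates: int = 3
    total_area: float = 1.0e6


@dataclass
class ComparisonConfig:
    spike_levels_uM: tuple = (
        0.0, 5.0, 10.0, 20.0, 30.0, 50.0, 75.0, 100.0, 150.0, 200.0,
        250.0, 300.0, 400.0, 500.0, 600.0, 750.0, 1000.0, 1250.0, 1500.0, 2000.0,
    )
    ratio_noise_sd: float = 0.01
    reference_noise_sd: float = 0.01
    replicates: int = 3
    dilution_factor: float = 4.0 / 3.0
    matrix_baseline_shift: float = 0.0  # additive ratio offset of the matrix
    F488: float = 1000.0


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic experiment."""

    seed: int = 0
    melt: MeltConfig = field(default_factory=MeltConfig)
    dose: DoseConfig = field(default_factory=DoseConfig)
    uptake: UptakeConfig = field(default_factory=UptakeConfig)
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        kwargs = {}
        parts = {
            "melt": MeltConfig, "dose": DoseConfig, "uptake": UptakeConfig,
            "labeling": LabelingConfig, "comparison": ComparisonConfig,
        }
        for key, sub in parts.items():
            if key in d:
                payload = {
                    k: tuple(map(tuple, v)) if isinstance(v, list)
                    and v and isinstance(v[0], (list, tuple))
                    else (tuple(v) if isinstance(v, list) else v)
                    for k, v in dict(d[key]).items()
                }
                kwargs[key] = sub(**payload)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_melt_curve(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[list[MeltCurve], dict]:
    """Sigmoidal melt curves with post-transition quenching.

    F(T) = baseline + amplitude * logistic((T - Tm)/width) - quench, where
    the quench term declines linearly past Tm + 3*width; Gaussian noise has
    sd = noise_sd_frac * amplitude. Programmed per-sample shifts are recorded
    as truth.
    """
    m = cfg.melt
    if m.transition_width_C <= 0:
        raise ValueError("transition width must be positive")
    if not 0.05 <= m.grid_step_C <= 1.0:
        raise ValueError("grid step must lie in [0.05, 1] degC")
    rng = _rng(cfg.seed if seed is None else seed, "melt")
    T = np.arange(m.t_start_C, m.t_end_C + m.grid_step_C / 2, m.grid_step_C)
    curves, truth_samples = [], []
    for sample_id, ligand, conc, shift in m.samples:
        tm = m.Tm_C + shift
        F = m.baseline + m.amplitude * _logistic((T - tm) / m.transition_width_C)
        beyond = np.clip(T - (tm + 3.0 * m.transition_width_C), 0.0, None)
        F = F - m.quench_rate * m.amplitude * beyond
        F = F + rng.normal(0.0, m.noise_sd_frac * m.amplitude, size=T.shape)
        F = np.clip(F, 1e-6, None)
        curves.append(
            MeltCurve(
                sample_id=sample_id,
                temperature_C=T,
                fluorescence=F,
                ligand=ligand,
                ligand_conc_uM=conc,
            )
        )
        truth_samples.append(
            {"sample_id": sample_id, "Tm_C": tm, "delta_Tm_C": shift}
        )
    truth = {
        "scenario_digest": cfg.digest(),
        "Tm_C": m.Tm_C,
        "samples": truth_samples,
    }
    return curves, truth


def melt_curves_to_frame(curves: Sequence[MeltCurve]) -> pd.DataFrame:
    """Serialize melt curves to the melt-curve CSV layout."""
    rows = []
    for c in curves:
        for t, f in zip(c.temperature_C, c.fluorescence):
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "ligand": c.ligand,
                    "ligand_conc": c.ligand_conc_uM,
                    "temperature_C": t,
                    "fluorescence": f,
                }
            )
    return pd.DataFrame(rows)


def _plate_rows(
    well: str, condition: str, conc, ratio: float, F488: float, replicate: int,
    construct: str = "sensor", timepoint_s: float | None = None,
) -> list[dict]:
    base = {
        "well_id": well,
        "condition": condition,
        "analyte_conc_uM": conc,
        "replicate": replicate,
        "construct": construct,
    }
    if timepoint_s is not None:
        base["timepoint_s"] = timepoint_s
    return [
        {**base, "channel": "F405", "value": ratio * F488},
        {**base, "channel": "F488", "value": F488},
    ]


def gen_dose_response(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Calibration plate: two-channel rows from the Hill truth + ratio noise."""
    d = cfg.dose
    if len([c for c in d.concentrations_uM]) < 5 or 0.0 not in d.concentrations_uM:
        raise ValueError("need >= 5 concentrations including 0")
    rng = _rng(cfg.seed if seed is None else seed, "dose")
    rows = []
    widx = 0
    for conc in d.concentrations_uM:
        r_true = float(hill_ratio(conc, d.Rmin, d.Rmax, d.Kd_uM, d.hill_p))
        for rep in range(1, d.replicates + 1):
            if d.noise_model == "multiplicative":
                r = r_true * (1.0 + rng.normal(0.0, d.noise_sd))
            elif d.noise_model == "additive":
                r = r_true + rng.normal(0.0, d.noise_sd)
            else:
                raise ValueError(f"unknown noise model {d.noise_model!r}")
            r = max(r, 1e-6)
            well = f"{chr(ord('A') + widx // 12)}{widx % 12 + 1}"
            widx += 1
            rows.extend(
                _plate_rows(well, "calibration", conc, r, d.F488, rep)
            )
    truth = {
        "scenario_digest": cfg.digest(),
        "Rmin": d.Rmin,
        "Rmax": d.Rmax,
        "Kd_uM": d.Kd_uM,
        "hill_p": d.hill_p,
        "delta_Rmax": (d.Rmax - d.Rmin) / d.Rmin,
    }
    return pd.DataFrame(rows), truth


def gen_ph_series(
    cfg: ScenarioConfig,
    seed: int | None = None,
    ph_values: Sequence[float] = (6.6, 7.0, 7.4, 7.8, 8.2),
    conc_uM: float = 1000.0,
    ph_sensitivity: float = 0.25,
    reference_ratio: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Sensor and reference constructs sharing a common pH response.

    Both constructs' ratios are scaled by the same factor g(pH) =
    1 + ph_sensitivity*(pH - 7.4), so dividing sensor by reference cancels
    the pH dependence — the pH-correction design.
    """
    d = cfg.dose
    rng = _rng(cfg.seed if seed is None else seed, "ph")
    r_true = float(hill_ratio(conc_uM, d.Rmin, d.Rmax, d.Kd_uM, d.hill_p))
    rows = []
    for i, ph in enumerate(ph_values):
        g = 1.0 + ph_sensitivity * (ph - 7.4)
        for rep in range(1, d.replicates + 1):
            noise = 1.0 + rng.normal(0.0, d.noise_sd)
            rows.extend(
                _plate_rows(
                    f"S{i}", f"pH={ph}", conc_uM, r_true * g * noise, d.F488, rep
                )
            )
            noise_ref = 1.0 + rng.normal(0.0, d.noise_sd)
            rows.extend(
                _plate_rows(
                    f"R{i}", f"pH={ph}", conc_uM,
                    reference_ratio * g * noise_ref, d.F488, rep,
                    construct="reference",
                )
            )
    truth = {
        "scenario_digest": cfg.digest(),
        "ratio_at_conc": r_true,
        "ph_sensitivity": ph_sensitivity,
    }
    return pd.DataFrame(rows), truth


def gen_uptake_assay(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Sensor-reported uptake time courses under Michaelis-Menten transport.

    Intracellular concentration rises at dC/dt = Vmax*S/(Km+S) (extracellular
    substrate in excess), scaled by (1 - inhibition) under treatments, and is
    mapped through the in-cell calibration to noisy ratio readings.
    """
    u = cfg.uptake
    if u.duration_s < 3 * u.sample_interval_s:
        raise ValueError("duration must cover >= 3 sampling intervals")
    rng = _rng(cfg.seed if seed is None else seed, "uptake")
    t = np.arange(0.0, u.duration_s + u.sample_interval_s / 2, u.sample_interval_s)
    rows = []
    truth_rates = {}

    def emit(well: str, S: float, treatment: str, cls: str, inhibition: float):
        rate = (
            u.Vmax_uM_per_min * S / (u.Km_uM + S) * (1.0 - inhibition / 100.0)
        )
        truth_rates[well] = rate
        conc = rate * t / 60.0
        ratio_true = hill_ratio(
            conc, u.sensor_Rmin, u.sensor_Rmax, u.sensor_Kd_uM, u.sensor_hill_p
        )
        noisy = ratio_true * (1.0 + rng.normal(0.0, u.ratio_noise_sd, size=t.shape))
        noisy = np.clip(noisy, 1e-6, None)
        for ti, r in zip(t, noisy):
            rows.extend(
                _plate_rows(well, treatment or "baseline", S, r, u.F488, 1,
                            timepoint_s=ti)
            )
            rows[-1]["treatment_class"] = cls
            rows[-2]["treatment_class"] = cls

    for i, S in enumerate(u.substrate_levels_uM):
        emit(f"S{i}", S, "", "", 0.0)
    emit("T_base", u.treatment_substrate_uM, "", "", 0.0)
    for j, (name, cls, pct) in enumerate(u.inhibition_pct):
        emit(f"T{j}", u.treatment_substrate_uM, name, cls, pct)

    truth = {
        "scenario_digest": cfg.digest(),
        "Km_uM": u.Km_uM,
        "Vmax_uM_per_min": u.Vmax_uM_per_min,
        "od600": u.od600,
        "rates_uM_per_min": truth_rates,
        "inhibition_pct": {name: pct for name, _, pct in u.inhibition_pct},
    }
    return pd.DataFrame(rows), truth


def feed_mdv(n: int, label_fraction: float, purity: float) -> np.ndarray:
    """MDV of the tracer feed: unlabeled + fully labeled at given purity."""
    labeled = binomial_shift_vector(n, purity)
    out = (1.0 - label_fraction) * np.eye(n + 1)[0] + label_fraction * labeled
    return out


def gen_labeling_dataset(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Isotopologue peak areas for WT and the two single-pathway knockouts.

    True MDVs (L-2-HG = feed signature; citrate = f*H + (1-f)*D with f = 1,
    0, f_true for the d_gcdH, d_csiD and WT strains) are forward-convolved
    with natural abundance through the correction matrix, scaled to peak
    areas and noised per channel.
    """
    lab = cfg.labeling
    if not 0.0 <= lab.f_hydroxylation <= 1.0:
        raise ValueError("f_hydroxylation must lie in [0, 1]")
    H = np.asarray(lab.boundary_H, dtype=float)
    D = np.asarray(lab.boundary_D, dtype=float)
    for name, vec in (("boundary_H", H), ("boundary_D", D)):
        if np.any(vec < 0) or not np.isclose(vec.sum(), 1.0, atol=1e-9):
            raise ValueError(f"{name} is not a probability distribution")
    rng = _rng(cfg.seed if seed is None else seed, "labeling")
    formulas = dict(lab.fragment_formulas)
    n = lab.n_tracer_carbons
    feed = feed_mdv(n, lab.feed_label_fraction, lab.tracer_purity)
    strain_f = {"WT": lab.f_hydroxylation, "d_csiD": 0.0, "d_gcdH": 1.0}
    rows = []
    true_mdvs: dict[str, dict[str, list[float]]] = {}
    for strain, f in strain_f.items():
        true_mdvs[strain] = {}
        for metabolite, formula in formulas.items():
            if metabolite == "L2HG":
                x = feed
            else:
                x = f * H + (1.0 - f) * D
            true_mdvs[strain][metabolite] = list(map(float, x))
            M = build_correction_matrix(
                formula, n, tracer_purity=lab.tracer_purity
            ).matrix
            clean = lab.total_area * (M @ x)
            for rep in range(1, lab.replicates + 1):
                noisy = clean + rng.normal(
                    0.0, lab.noise_sd * lab.total_area, size=clean.shape
                )
                noisy = np.clip(noisy, 0.0, None)
                for shift, area in enumerate(noisy):
                    rows.append(
                        {
                            "strain": strain,
                            "metabolite": metabolite,
                            "fragment_formula": formula,
                            "mass_shift": shift,
                            "peak_area": area,
                            "replicate": rep,
                        }
                    )
    truth = {
        "scenario_digest": cfg.digest(),
        "f_hydroxylation": lab.f_hydroxylation,
        "feed_label_fraction": lab.feed_label_fraction,
        "tracer_purity": lab.tracer_purity,
        "boundary_H": list(H),
        "boundary_D": list(D),
        "true_mdvs": true_mdvs,
    }
    return pd.DataFrame(rows), truth


def gen_method_comparison(
    cfg: ScenarioConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired spike-recovery tables: sensor plate + reference-method table.

    Spiked samples are mixed 3:1 with sensor (well concentration =
    spike / dilution_factor), read through the Hill truth with ratio noise;
    the reference method reports the spike with its own proportional noise.
    """
    comp, d = cfg.comparison, cfg.dose
    rng = _rng(cfg.seed if seed is None else seed, "comparison")
    sensor_rows, ref_rows = [], []
    flagged = []
    band = 9.0 ** (1.0 / d.hill_p)
    lo_w, hi_w = d.Kd_uM / band, d.Kd_uM * band
    for i, spike in enumerate(comp.spike_levels_uM):
        well_conc = spike / comp.dilution_factor
        in_range = lo_w <= well_conc <= hi_w
        r_true = (
            float(hill_ratio(well_conc, d.Rmin, d.Rmax, d.Kd_uM, d.hill_p))
            + comp.matrix_baseline_shift
        )
        for rep in range(1, comp.replicates + 1):
            r = max(r_true * (1.0 + rng.normal(0.0, comp.ratio_noise_sd)), 1e-6)
            rows = _plate_rows(
                f"Q{i}", f"spike_{spike:g}", spike, r, comp.F488, rep
            )
            for row in rows:
                row["in_working_range"] = in_range
            sensor_rows.extend(rows)
        ref = spike * (1.0 + rng.normal(0.0, comp.reference_noise_sd))
        ref_rows.append(
            {
                "condition": f"spike_{spike:g}",
                "true_conc_uM": spike,
                "reference_conc_uM": max(ref, 0.0),
                "in_working_range": in_range,
            }
        )
        if not in_range:
            flagged.append(spike)
    truth = {
        "scenario_digest": cfg.digest(),
        "spike_levels_uM": list(comp.spike_levels_uM),
        "dilution_factor": comp.dilution_factor,
        "working_range_uM_well": [lo_w, hi_w],
        "out_of_range_spikes": flagged,
    }
    return pd.DataFrame(sensor_rows), pd.DataFrame(ref_rows), truth
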