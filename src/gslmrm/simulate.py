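"""Synthetic scheduled-MRM data with the statistical structure the
pipeline assumes.

The instrument model is deliberately simple: within each transition's
scheduled retention-time window, points are laid down at the acquisition
cycle time; the analyte contributes one Gaussian (optionally
exponentially-modified Gaussian) peak whose area is

    area = amount * response_factor * matrix_factor * extraction_efficiency,

multiplied by a per-peak log-normal fluctuation (spray/injection
variability — this is what drives realistic CVs, since purely additive
trace noise averages out under integration).  Additive Gaussian noise
plus a signal-proportional term is added per point, and intensities are
floored at zero and capped at detector saturation.

Sample plans cover the assay's study designs: serial-dilution
calibrators, low/high QC replicates, storage-stability series with
first-order decay, and a control vs GM2-gangliosidosis cohort whose
control amounts are log-normal per class, calibrated to the packaged
serum cohort table.

Peak positions (RT jitter) are derived from the sample/transition
identity, not from the noise seed, so two noise realizations of the
same plan share identical peak locations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .panel import Transition

__all__ = [
    "AcquisitionModel",
    "SamplePlan",
    "CohortModel",
    "STANDARD_MIX",
    "simulate_chromatograms",
    "simulate_plans",
    "make_calibration_series",
    "make_qc_series",
    "make_cohort",
    "make_stability_series",
    "fit_cohort_model",
    "default_cohort_model",
]

#: The eleven-component calibration standard mixture, mapped onto default
#: panel species ids (d18:1/18:0 = d36:1, d18:1/16:0 = d34:1,
#: d18:1/24:0 = d42:1).
STANDARD_MIX: Tuple[str, ...] = (
    "GM3 d36:1",
    "GM2 d36:1",
    "GM1 d36:1",
    "GD3 d36:1",
    "GD2 d36:1",
    "GD1 d36:1",
    "GT1 d36:1",
    "GlcCer d34:1",
    "LacCer d36:1",
    "LacCer d42:1",
    "Gb3 d36:1",
)


@dataclass(frozen=True)
class AcquisitionModel:
    """Instrument/acquisition parameters for trace synthesis."""

    cycle_time_s: float = 0.5          # point spacing inside the window
    peak_sigma_s: float = 2.5          # chromatographic peak SD
    peak_shape: str = "gaussian"       # "gaussian" | "emg"
    emg_tau_s: float = 2.0             # EMG tail constant (if shape="emg")
    baseline: float = 50.0             # counts
    noise_sigma: float = 10.0          # additive Gaussian SD, counts
    noise_proportional: float = 0.01   # per-point SD as fraction of signal
    amplitude_cv: float = 0.03         # per-peak log-normal area fluctuation
    rt_jitter_sd_min: float = 0.02     # peak-position jitter, minutes
    response_per_fmol: float = 1000.0  # default area counts per fmol
    class_response: Dict[str, float] = field(default_factory=dict)
    saturation: float = 1.0e9

    def __post_init__(self):
        if self.noise_sigma < 0 or self.noise_proportional < 0:
            raise ValueError("noise terms must be >= 0")
        if self.cycle_time_s <= 0 or self.peak_sigma_s <= 0:
            raise ValueError("cycle time and peak sigma must be > 0")
        if self.peak_shape not in ("gaussian", "emg"):
            raise ValueError(f"unknown peak shape {self.peak_shape!r}")

    def response_for(self, class_name: str) -> float:
        return self.class_response.get(class_name, self.response_per_fmol)


@dataclass
class SamplePlan:
    """True composition and provenance of one injected sample."""

    sample_id: str
    group: str  # control | tay_sachs | sandhoff | qc_low | qc_high | calibrator | blank | stability
    amounts: Dict[str, float] = field(default_factory=dict)  # species_id -> fmol
    is_spike: float = 500.0  # fmol of every internal standard
    matrix_factor: float = 1.0
    extraction_efficiency: float = 1.0
    storage_condition: Optional[str] = None
    storage_days: float = 0.0
    freeze_thaw_cycles: int = 0
    seed: int = 0

    def __post_init__(self):
        for sid, amt in self.amounts.items():
            if amt < 0:
                raise ValueError(f"negative amount for {sid}: {amt}")
        for name, v in (
            ("matrix_factor", self.matrix_factor),
            ("extraction_efficiency", self.extraction_efficiency),
        ):
            if not (0.0 < v <= 1.2):
                raise ValueError(f"{name} must be in (0, 1.2], got {v}")


def _stable_u32(*parts: str) -> int:
    h = hashlib.sha256("|".join(parts).encode()).digest()
    return int.from_bytes(h[:4], "big")


def _peak_profile(times_min, rt_min, area, sigma_min, shape, tau_min):
    if shape == "gaussian":
        return (
            area
            / (sigma_min * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((times_min - rt_min) / sigma_min) ** 2)
        )
    # exponentially-modified Gaussian via scipy's exponnorm parameterization
    from scipy.stats import exponnorm

    k = tau_min / sigma_min
    return area * exponnorm.pdf(times_min, K=k, loc=rt_min, scale=sigma_min)


def simulate_chromatograms(
    panel: Sequence[Transition],
    plan: SamplePlan,
    acq: AcquisitionModel = AcquisitionModel(),
) -> pd.DataFrame:
    """Synthesize one sample's scheduled-MRM traces.

    Returns a long-format frame (sample_id, transition_id, time_min,
    intensity).  Analyte peak areas follow the plan's true amounts times
    response, matrix and extraction factors; internal-standard peaks are
    spiked post-extraction, so only the matrix factor applies to them.
    Deterministic for a fixed plan (seed included).
    """
    panel_ids = {t.species_id for t in panel}
    missing = set(plan.amounts) - panel_ids
    if missing:
        raise KeyError(f"plan species absent from panel: {sorted(missing)}")

    rng = np.random.default_rng(plan.seed)
    sigma_min = acq.peak_sigma_s / 60.0
    tau_min = acq.emg_tau_s / 60.0
    dt_min = acq.cycle_time_s / 60.0
    frames = []
    for t in panel:
        lo, hi = t.window
        n_pts = max(int(round((hi - lo) / dt_min)) + 1, 2)
        times = lo + np.arange(n_pts) * dt_min
        if t.role == "internal_standard":
            amount = plan.is_spike
            eff = plan.matrix_factor  # spiked after extraction
        else:
            amount = plan.amounts.get(t.species_id, 0.0)
            eff = plan.matrix_factor * plan.extraction_efficiency
        signal = np.zeros_like(times)
        if amount > 0:
            area = amount * acq.response_for(t.class_name) * eff
            if acq.amplitude_cv > 0:
                # mean-one log-normal with the configured CV
                s2 = np.log(1 + acq.amplitude_cv**2)
                area *= rng.lognormal(-0.5 * s2, np.sqrt(s2))
            # jitter keyed to identity, not the noise seed: noise
            # realizations differ between seeds, peak locations do not
            jit_rng = np.random.default_rng(_stable_u32(plan.sample_id, t.transition_id))
            rt = t.rt_min + jit_rng.normal(0.0, acq.rt_jitter_sd_min)
            rt = float(np.clip(rt, lo + 3 * sigma_min, hi - 3 * sigma_min))
            signal = _peak_profile(times, rt, area, sigma_min, acq.peak_shape, tau_min)
        trace = signal + acq.baseline
        if acq.noise_sigma > 0 or acq.noise_proportional > 0:
            sd = np.sqrt(acq.noise_sigma**2 + (acq.noise_proportional * trace) ** 2)
            trace = trace + rng.normal(0.0, 1.0, size=trace.shape) * sd
        trace = np.clip(trace, 0.0, acq.saturation)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": plan.sample_id,
                    "transition_id": t.transition_id,
                    "time_min": times,
                    "intensity": trace,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_plans(
    panel: Sequence[Transition],
    plans: Sequence[SamplePlan],
    acq: AcquisitionModel = AcquisitionModel(),
) -> pd.DataFrame:
    """Concatenated chromatograms for a list of plans."""
    return pd.concat(
        [simulate_chromatograms(panel, p, acq) for p in plans], ignore_index=True
    )


# -- study designs -----------------------------------------------------------


def make_calibration_series(
    levels: Sequence[float] = tuple(5000.0 / 4**i for i in range(7)),
    replicates: int = 1,
    species: Sequence[str] = STANDARD_MIX,
    is_spike: float = 500.0,
    seed: int = 0,
) -> List[SamplePlan]:
    """Calibrator plans: each level carries the full standard mixture.

    The default is a 7-point 1:4 serial dilution from 5 pmol/ul (in
    per-injection fmol equivalents).
    """
    levels = list(levels)
    if not levels:
        raise ValueError("empty calibration level list")
    if any(lv <= 0 for lv in levels):
        raise ValueError("calibration levels must be strictly positive")
    plans = []
    for r in range(replicates):
        for i, lv in enumerate(levels):
            plans.append(
                SamplePlan(
                    sample_id=f"CAL_L{i + 1}_R{r + 1}",
                    group="calibrator",
                    amounts={sid: float(lv) for sid in species},
                    is_spike=is_spike,
                    seed=seed + 1000 * r + i,
                )
            )
    return plans


def make_qc_series(
    low: float = 50.0,
    high: float = 1000.0,
    replicates: int = 5,
    days: int = 1,
    species: Sequence[str] = STANDARD_MIX,
    is_spike: float = 500.0,
    seed: int = 0,
) -> List[SamplePlan]:
    """Low/high QC replicate plans, optionally over several days
    (``replicates`` injections per level per day)."""
    plans = []
    for d in range(days):
        for level_name, level in (("qc_low", low), ("qc_high", high)):
            for r in range(replicates):
                plans.append(
                    SamplePlan(
                        sample_id=f"QC_{level_name[3:].upper()}_D{d + 1}_R{r + 1}",
                        group=level_name,
                        amounts={sid: level for sid in species},
                        is_spike=is_spike,
                        seed=seed + 10000 * d + 100 * (level_name == "qc_high") + r,
                    )
                )
    return plans


@dataclass
class CohortModel:
    """Generative model for a control vs GM2-gangliosidosis serum cohort.

    Control amounts of the reference (d36:1) species of each class are
    log-normal with per-class parameters ``class_lognorm`` (mu, sigma of
    log fmol); other chain-length species scale by ``species_weights``.
    Patient samples multiply the class draw by a per-class fold factor
    (``sandhoff_extra`` applies on top for the Sandhoff group only —
    GA2 accumulates only when beta-hexosaminidase B is lost).
    """

    class_lognorm: Dict[str, Tuple[float, float]]
    patient_fold: Dict[str, float] = field(
        default_factory=lambda: {"GM2": 10.0, "GM1": 6.0, "GM3": 0.57}
    )
    sandhoff_extra: Dict[str, float] = field(default_factory=lambda: {"GA2": 2.4})
    species_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "d34:1": 0.6,
            "d36:1": 1.0,
            "d38:1": 0.35,
            "d40:1": 0.25,
            "d41:1": 0.05,
            "d42:1": 0.3,
        }
    )
    n_controls: int = 36
    n_tay_sachs: int = 2
    n_sandhoff: int = 1

    def __post_init__(self):
        if min(self.n_controls, self.n_tay_sachs + self.n_sandhoff) < 1:
            raise ValueError("need >= 1 sample per group")
        for d in (self.patient_fold, self.sandhoff_extra):
            if any(v <= 0 for v in d.values()):
                raise ValueError("fold multipliers must be > 0")

    def fold_for(self, class_name: str, group: str) -> float:
        f = self.patient_fold.get(class_name, 1.0) if group != "control" else 1.0
        if group == "sandhoff":
            f *= self.sandhoff_extra.get(class_name, 1.0)
        return f

    def draw_control_class_amounts(self, n: int, rng: np.random.Generator) -> Dict[str, np.ndarray]:
        """Vectorized control draws of the reference species per class."""
        return {
            c: rng.lognormal(mu, sg, size=n) for c, (mu, sg) in self.class_lognorm.items()
        }


def fit_cohort_model(
    cohort: pd.DataFrame,
    extra_classes: Optional[Dict[str, Tuple[float, float]]] = None,
    **kwargs,
) -> CohortModel:
    """Fit per-class log-normal control distributions from a cohort table.

    sigma^2 is the sample variance of log amounts; mu is set to
    log(mean) - sigma^2/2 so the generative arithmetic mean equals the
    observed control mean exactly (mean-calibrated log-moment fit).
    Species columns are "<class> d36:1"; rows with group == "control"
    are used.
    """
    ctrl = cohort[cohort["group"] == "control"]
    params: Dict[str, Tuple[float, float]] = {}
    for col in cohort.columns:
        if not col.endswith(" d36:1"):
            continue
        cname = col[: -len(" d36:1")]
        x = ctrl[col].to_numpy(float)
        if (x <= 0).any():
            raise ValueError(f"non-positive amounts in column {col}")
        sg = float(np.std(np.log(x), ddof=1))
        mu = float(np.log(x.mean()) - 0.5 * sg**2)
        params[cname] = (mu, sg)
    if extra_classes:
        params.update(extra_classes)
    return CohortModel(class_lognorm=params, **kwargs)


#: Nominal control levels for classes absent from the packaged cohort
#: table (placeholder serum abundances; log-sigma 0.4 throughout).
_PLACEHOLDER_CLASSES: Dict[str, Tuple[float, float]] = {
    c: (float(np.log(m) - 0.5 * 0.4**2), 0.4)
    for c, m in {
        "GlcCer": 1500.0,
        "LacCer": 4000.0,
        "Gb3": 1200.0,
        "GA2": 60.0,
        "GT2": 20.0,
        "GT3": 15.0,
        "GQ1": 10.0,
    }.items()
}


def default_cohort_model(**kwargs) -> CohortModel:
    """Cohort model calibrated to the packaged serum cohort table for the
    seven quantified ganglioside classes, with placeholder levels for the
    remaining classes."""
    from .cohort import load_cohort_table

    return fit_cohort_model(
        load_cohort_table(), extra_classes=dict(_PLACEHOLDER_CLASSES), **kwargs
    )


def make_cohort(
    model: CohortModel,
    seed: int = 0,
    is_spike: float = 500.0,
) -> Tuple[List[SamplePlan], pd.DataFrame]:
    """Draw a cohort: sample plans plus the ground-truth amount table.

    Returns ``(plans, truth)`` where ``truth`` has one row per sample
    (columns: sample_id, group, then one column per species id in fmol).
    """
    rng = np.random.default_rng(seed)
    groups = (
        [("control", f"CS{i + 1:02d}") for i in range(model.n_controls)]
        + [("tay_sachs", f"TSD{i + 1:02d}") for i in range(model.n_tay_sachs)]
        + [("sandhoff", f"SD{i + 1:02d}") for i in range(model.n_sandhoff)]
    )
    plans, rows = [], []
    for group, sid in groups:
        amounts: Dict[str, float] = {}
        for cname, (mu, sg) in model.class_lognorm.items():
            base = rng.lognormal(mu, sg) * model.fold_for(cname, group)
            for cer, w in model.species_weights.items():
                amounts[f"{cname} {cer}"] = base * w
        plans.append(
            SamplePlan(
                sample_id=sid,
                group=group,
                amounts=amounts,
                is_spike=is_spike,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        rows.append({"sample_id": sid, "group": group, **amounts})
    return plans, pd.DataFrame(rows)


_STABILITY_CONDITIONS = ("room", "fridge", "freezer", "freeze_thaw", "autosampler")


def make_stability_series(
    condition: str,
    time_points: Sequence[float],
    decay_rate_per_day: float = 0.0,
    per_cycle_loss: float = 0.0,
    base_amounts: Optional[Dict[str, float]] = None,
    is_spike: float = 500.0,
    seed: int = 0,
) -> List[SamplePlan]:
    """Storage-stability plans with first-order decay.

    ``time_points`` are days (baseline 0 must be included or is added);
    for ``condition == "freeze_thaw"`` they are integer cycle counts and
    recovery is ``(1 - per_cycle_loss)**cycles``.  The decay applies
    uniformly to all analytes (per-class rates can be emulated by
    separate series).
    """
    if condition not in _STABILITY_CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; choose from {_STABILITY_CONDITIONS}"
        )
    if base_amounts is None:
        base_amounts = {sid: 500.0 for sid in STANDARD_MIX}
    pts = sorted(set(float(t) for t in time_points) | {0.0})
    plans = []
    for i, t in enumerate(pts):
        if condition == "freeze_thaw":
            recovery = (1.0 - per_cycle_loss) ** t
            kw = {"freeze_thaw_cycles": int(t)}
        else:
            recovery = float(np.exp(-decay_rate_per_day * t))
            kw = {"storage_days": t}
        plans.append(
            SamplePlan(
                sample_id=f"STAB_{condition}_{t:g}",
                group="stability",
                amounts={sid: a * recovery for sid, a in base_amounts.items()},
                is_spike=is_spike,
                storage_condition=condition,
                seed=seed + i,
                **kw,
            )
        )
    return plans
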