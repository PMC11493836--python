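"""Chromatogram quantification: XIC peak integration, internal-standard
normalization, calibration and limit of detection.

The integration algorithm is deterministic and fully specified so it can
be tested against closed-form areas: the trace is median-smoothed over 3
points; the baseline is the median of the whole window (robust because a
peak occupies a small fraction of its scheduled window) and the noise is
the median absolute deviation of the window's lowest-intensity quartile,
scaled so it estimates the SD of the smoothed noise; a peak is
"detected" only if the smoothed apex exceeds baseline + 3*noise;
boundaries walk outward from the apex to the nearest points at or below
baseline + 1*noise; the area is the trapezoid over [left, right] after
baseline subtraction.

Calibration is unweighted ordinary least squares of response ratio on
amount; Sy is the residual standard deviation (n-2 denominator) and
LOD = 3.3 * Sy / S with S the slope.  An optional low-level-subset mode
restricts the fit to the lowest calibration levels, and 1/x weighting is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .panel import Transition

__all__ = [
    "PeakResult",
    "QuantRecord",
    "CalibrationFit",
    "integrate_peak",
    "match_internal_standard",
    "fit_calibration",
    "quantify_sample",
    "quantify_all",
    "calibrate_from_records",
]


@dataclass(frozen=True)
class PeakResult:
    """Integrated peak for one transition in one sample."""

    transition_id: str
    detected: bool
    area: float = 0.0
    height: float = 0.0
    apex_rt: float = float("nan")
    left_rt: float = float("nan")
    right_rt: float = float("nan")
    baseline: float = 0.0
    noise: float = 0.0

    @property
    def signal_to_noise(self) -> float:
        return self.height / self.noise if self.noise > 0 else float("inf")


def integrate_peak(
    times: np.ndarray, intensities: np.ndarray, transition_id: str = ""
) -> PeakResult:
    """Integrate one scheduled window's trace (see module docstring).

    An empty or flat trace yields a not-detected result, never an
    exception.  Area is floored at zero.
    """
    times = np.asarray(times, float)
    y = np.asarray(intensities, float)
    if times.size < 3:
        return PeakResult(transition_id, detected=False)
    order = np.argsort(times)
    times, y = times[order], y[order]

    smooth = median_filter(y, size=3, mode="nearest")
    baseline = float(np.median(smooth))
    # noise from the lowest-intensity quartile; 3.3 calibrates the
    # quartile MAD to the SD of 3-point-median-smoothed Gaussian noise
    q = np.quantile(smooth, 0.25)
    low = smooth[smooth <= q]
    noise = float(3.3 * np.median(np.abs(low - np.median(low))))

    apex_i = int(np.argmax(smooth))
    height = float(smooth[apex_i] - baseline)
    if height <= 3.0 * noise or height <= 0.0:
        return PeakResult(transition_id, detected=False, baseline=baseline, noise=noise)

    thresh = baseline + noise
    left_i = apex_i
    while left_i > 0 and smooth[left_i - 1] > thresh:
        left_i -= 1
    right_i = apex_i
    while right_i < len(smooth) - 1 and smooth[right_i + 1] > thresh:
        right_i += 1
    seg_t = times[left_i : right_i + 1]
    seg_y = y[left_i : right_i + 1] - baseline
    area = float(max(np.trapezoid(seg_y, seg_t), 0.0))
    return PeakResult(
        transition_id,
        detected=True,
        area=area,
        height=height,
        apex_rt=float(times[apex_i]),
        left_rt=float(times[left_i]),
        right_rt=float(times[right_i]),
        baseline=baseline,
        noise=noise,
    )


def match_internal_standard(species_id: str, class_name: str, is_map: Dict[str, str]) -> str:
    """Internal standard for an analyte: the structurally closest IS, via
    the class-level assignment map."""
    if class_name not in is_map:
        raise KeyError(f"no internal standard assigned for class {class_name!r}")
    return is_map[class_name]


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration of response ratio vs amount for one species."""

    species_id: str
    slope: float
    intercept: float
    r_squared: float
    sy: float
    lod: float
    level_range: Tuple[float, float]
    n_points: int

    def back_calculate(self, ratio: float) -> Tuple[float, bool]:
        """Amount (fmol) from a response ratio; negative back-calculations
        are floored at 0 and flagged (second return value True)."""
        amount = (ratio - self.intercept) / self.slope
        if amount < 0:
            return 0.0, True
        return float(amount), False


def fit_calibration(
    points: Sequence[Tuple[float, float]],
    species_id: str = "",
    low_subset: Optional[int] = None,
    weighting: Optional[str] = None,
) -> CalibrationFit:
    """Fit a calibration line through (amount, response ratio) points.

    Unweighted OLS by default; ``weighting="1/x"`` applies inverse-amount
    weights.  ``low_subset`` restricts the fit to the n lowest distinct
    levels (for LOD estimation near the detection limit).  Requires >= 3
    distinct amount levels.  Sy uses the n-2 denominator;
    LOD = 3.3 * Sy / S.
    """
    pts = [(float(a), float(r)) for a, r in points]
    if low_subset is not None:
        keep = sorted(set(a for a, _ in pts))[:low_subset]
        pts = [(a, r) for a, r in pts if a in set(keep)]
    x = np.array([a for a, _ in pts])
    y = np.array([r for _, r in pts])
    levels = np.unique(x)
    if levels.size < 3:
        raise ValueError(
            f"calibration needs >= 3 distinct levels, got {levels.size}"
        )
    if np.ptp(x) == 0:
        raise ValueError("zero-variance calibration amounts")
    w = 1.0 / x if weighting == "1/x" else np.ones_like(x)
    W = np.diag(w)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    slope, intercept = float(beta[0]), float(beta[1])
    resid = y - (slope * x + intercept)
    n = len(x)
    sy = float(np.sqrt(np.sum(w * resid**2) / (n - 2))) if n > 2 else 0.0
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if slope <= 0:
        raise ValueError(f"non-positive calibration slope for {species_id or 'species'}")
    return CalibrationFit(
        species_id=species_id,
        slope=slope,
        intercept=intercept,
        r_squared=max(min(r2, 1.0), 0.0),
        sy=sy,
        lod=3.3 * sy / slope,
        level_range=(float(levels.min()), float(levels.max())),
        n_points=n,
    )


@dataclass(frozen=True)
class QuantRecord:
    """One analyte's quantification in one sample."""

    sample_id: str
    species_id: str
    class_name: str
    area: float
    is_id: str
    is_area: float
    response_ratio: Optional[float]
    amount_fmol: Optional[float] = None
    flags: Tuple[str, ...] = ()


def _integrate_sample(
    chroms: pd.DataFrame, panel: Sequence[Transition]
) -> Dict[str, PeakResult]:
    grouped = dict(tuple(chroms.groupby("transition_id", sort=False)))
    peaks: Dict[str, PeakResult] = {}
    for t in panel:
        g = grouped.get(t.transition_id)
        if g is None:
            peaks[t.transition_id] = PeakResult(t.transition_id, detected=False)
        else:
            peaks[t.transition_id] = integrate_peak(
                g["time_min"].to_numpy(), g["intensity"].to_numpy(), t.transition_id
            )
    return peaks


def quantify_sample(
    chroms: pd.DataFrame,
    panel: Sequence[Transition],
    is_map: Dict[str, str],
    calibrations: Optional[Dict[str, CalibrationFit]] = None,
    sample_id: Optional[str] = None,
) -> List[QuantRecord]:
    """Quantify every analyte transition of one sample.

    ``chroms`` is the long-format trace table for a single sample.
    Response ratio = analyte area / IS area; amounts are back-calculated
    when a calibration for the species is supplied.  Records whose IS
    was not detected are flagged ``is_not_detected`` and carry no ratio.
    """
    if sample_id is None:
        ids = chroms["sample_id"].unique()
        if len(ids) != 1:
            raise ValueError("chromatogram table holds multiple samples; pass sample_id")
        sample_id = str(ids[0])
    else:
        chroms = chroms[chroms["sample_id"] == sample_id]
    peaks = _integrate_sample(chroms, panel)
    by_species = {t.species_id: t for t in panel}
    records: List[QuantRecord] = []
    for t in panel:
        if t.role != "analyte":
            continue
        is_id = match_internal_standard(t.species_id, t.class_name, is_map)
        is_t = by_species.get(is_id)
        if is_t is None:
            raise KeyError(f"internal standard {is_id!r} missing from panel")
        pk = peaks[t.transition_id]
        is_pk = peaks[is_t.transition_id]
        flags: List[str] = []
        if not pk.detected:
            flags.append("not_detected")
        ratio: Optional[float] = None
        amount: Optional[float] = None
        if not is_pk.detected or is_pk.area <= 0:
            flags.append("is_not_detected")
        else:
            ratio = pk.area / is_pk.area
            if calibrations and t.species_id in calibrations:
                amount, floored = calibrations[t.species_id].back_calculate(ratio)
                if floored:
                    flags.append("below_calibration")
        records.append(
            QuantRecord(
                sample_id=sample_id,
                species_id=t.species_id,
                class_name=t.class_name,
                area=pk.area,
                is_id=is_id,
                is_area=is_pk.area,
                response_ratio=ratio,
                amount_fmol=amount,
                flags=tuple(flags),
            )
        )
    return records


def quantify_all(
    chroms: pd.DataFrame,
    panel: Sequence[Transition],
    is_map: Dict[str, str],
    calibrations: Optional[Dict[str, CalibrationFit]] = None,
) -> pd.DataFrame:
    """Quantify every sample in a multi-sample chromatogram table;
    returns the quantification table as a DataFrame."""
    rows = []
    for sid, g in chroms.groupby("sample_id", sort=False):
        for rec in quantify_sample(g, panel, is_map, calibrations, sample_id=str(sid)):
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "species_id": rec.species_id,
                    "class": rec.class_name,
                    "area": rec.area,
                    "is_id": rec.is_id,
                    "is_area": rec.is_area,
                    "response_ratio": rec.response_ratio,
                    "amount_fmol": rec.amount_fmol,
                    "flags": ";".join(rec.flags),
                }
            )
    return pd.DataFrame(rows)


def calibrate_from_records(
    quant: pd.DataFrame,
    true_amounts: Dict[str, float],
    weighting: Optional[str] = "1/x",
    **fit_kwargs,
) -> Dict[str, CalibrationFit]:
    """Fit per-species calibrations from a quantified calibrator series.

    ``true_amounts`` maps calibrator sample_id -> spiked amount (fmol,
    identical for every standard in the mixture).  Unlike the bare
    :func:`fit_calibration` primitive, the pipeline-level builder
    defaults to 1/x weighting: over a serial-dilution range spanning
    three orders of magnitude with signal-proportional noise, an
    unweighted fit leaves intercept errors of several fmol that ruin
    back-calculation at the low end (pass ``weighting=None`` to disable).
    """
    fit_kwargs = {"weighting": weighting, **fit_kwargs}
    fits: Dict[str, CalibrationFit] = {}
    cal = quant[quant["sample_id"].isin(true_amounts)]
    for sid, g in cal.groupby("species_id"):
        g = g.dropna(subset=["response_ratio"])
        pts = [
            (true_amounts[row.sample_id], row.response_ratio)
            for row in g.itertuples()
        ]
        if len({a for a, _ in pts}) < 3:
            continue
        if max((r for _, r in pts), default=0.0) <= 0.0:
            continue  # species not spiked in the series: nothing to fit
        try:
            fits[str(sid)] = fit_calibration(pts, species_id=str(sid), **fit_kwargs)
        except ValueError:
            # unspiked species whose stray noise "peaks" do not scale with
            # amount (non-positive slope): no usable calibration
            continue
    return fits
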