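"""Cohort biomarker statistics for GM2-gangliosidosis.

Works on a samples x species amount table (fmol) with group labels
(control / tay_sachs / sandhoff).  Implements iterative two-sided Grubbs
outlier screening, pooled-variance t-tests with multiplicity adjustment,
mean- and median-based fold-changes, per-sample GM2/GM3 ratios, PCA by
autoscaling + SVD, and heatmap-ready z-scores.  The packaged serum
cohort table (36 controls, 2 Tay-Sachs, 1 Sandhoff; seven ganglioside
classes at d36:1) loads via :func:`load_cohort_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "load_cohort_table",
    "species_columns",
    "grubbs_critical_value",
    "grubbs_filter",
    "StatsResult",
    "group_compare",
    "gm2_gm3_ratio",
    "PCAResult",
    "pca",
    "heatmap_zscores",
    "PATIENT_GROUPS",
]

PATIENT_GROUPS = ("tay_sachs", "sandhoff")
_GROUP_VOCAB = ("control",) + PATIENT_GROUPS


def load_cohort_table(path=None) -> pd.DataFrame:
    """Load a cohort table (default: the packaged 39-sample serum table).

    Expected layout: columns group, sample_id, sex, age, then one amount
    column per species.  Amounts must be >= 0 and groups must come from
    the fixed vocabulary.
    """
    if path is None:
        src = resources.files("gslmrm.data").joinpath("serum_cohort_d36_1.csv")
        with src.open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    bad = set(df["group"]) - set(_GROUP_VOCAB)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    sp = species_columns(df)
    if not sp:
        raise ValueError("cohort table has no species amount columns")
    if (df[sp] < 0).any().any():
        raise ValueError("negative amounts in cohort table")
    return df


def species_columns(table: pd.DataFrame) -> List[str]:
    """The amount columns (everything numeric except metadata)."""
    meta = {"group", "sample_id", "sex", "age"}
    return [c for c in table.columns if c not in meta]


# -- Grubbs outlier screening ------------------------------------------------


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t-quantile(1 - alpha/(2n), n-2).
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values: Sequence[float],
    alpha: float = 0.05,
    ids: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Iterative two-sided Grubbs screening.

    Repeatedly removes the single most extreme point while
    G = max|x - mean| / SD exceeds the critical value at ``alpha``.
    Returns (retained values, removed ids).  With n < 3 nothing is
    filtered (a warning-level no-op per the method's contract).
    """
    x = np.asarray(values, float)
    if ids is None:
        ids = [str(i) for i in range(len(x))]
    ids = list(ids)
    if len(ids) != len(x):
        raise ValueError("ids and values length mismatch")
    removed: List[str] = []
    while len(x) >= 3:
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g <= grubbs_critical_value(len(x), alpha):
            break
        removed.append(ids[i])
        x = np.delete(x, i)
        del ids[i]
    return x, removed


# -- group comparison --------------------------------------------------------


@dataclass(frozen=True)
class StatsResult:
    species_id: str
    control_mean: float
    control_median: float
    patient_mean: float
    patient_median: float
    fold_change_mean: float
    fold_change_median: float
    t_statistic: float
    p_value: float
    p_adjusted: float
    n_control: int
    n_patient: int
    outliers_removed: Tuple[str, ...] = ()


def group_compare(
    table: pd.DataFrame,
    species: Optional[Sequence[str]] = None,
    adjust: str = "bh",
    welch: bool = False,
    grubbs_alpha: Optional[float] = None,
) -> List[StatsResult]:
    """Patient-vs-control comparison per species.

    Two-tailed Student's (pooled-variance) t-test by default
    (``welch=True`` switches to Welch); p-values are adjusted across
    species by Benjamini-Hochberg (``adjust="bh"``) or Bonferroni.
    Fold-changes are patient/control, both mean- and median-based.
    ``grubbs_alpha`` enables per-group Grubbs outlier removal before
    testing (off by default: the headline fold-changes and group means
    are plain arithmetic over all samples).
    """
    if adjust not in ("bh", "bonferroni"):
        raise ValueError(f"adjust must be bh|bonferroni, got {adjust!r}")
    if species is None:
        species = species_columns(table)
    is_patient = table["group"].isin(PATIENT_GROUPS)
    results = []
    pvals = []
    for sp in species:
        ctrl = table.loc[~is_patient, sp].to_numpy(float)
        pat = table.loc[is_patient, sp].to_numpy(float)
        removed: List[str] = []
        if grubbs_alpha is not None:
            ctrl, rem_c = grubbs_filter(
                ctrl, grubbs_alpha, table.loc[~is_patient, "sample_id"].tolist()
            )
            pat, rem_p = grubbs_filter(
                pat, grubbs_alpha, table.loc[is_patient, "sample_id"].tolist()
            )
            removed = rem_c + rem_p
        if len(ctrl) < 2 or len(pat) < 2:
            raise ValueError(f"need >= 2 samples per group for {sp}")
        t, p = stats.ttest_ind(pat, ctrl, equal_var=not welch)
        pvals.append(float(p))
        results.append(
            dict(
                species_id=sp,
                control_mean=float(ctrl.mean()),
                control_median=float(np.median(ctrl)),
                patient_mean=float(pat.mean()),
                patient_median=float(np.median(pat)),
                fold_change_mean=float(pat.mean() / ctrl.mean()),
                fold_change_median=float(np.median(pat) / np.median(ctrl)),
                t_statistic=float(t),
                p_value=float(p),
                n_control=len(ctrl),
                n_patient=len(pat),
                outliers_removed=tuple(removed),
            )
        )
    method = "fdr_bh" if adjust == "bh" else "bonferroni"
    adj = multipletests(pvals, method=method)[1]
    return [StatsResult(p_adjusted=float(a), **r) for r, a in zip(results, adj)]


def stats_to_frame(results: Sequence[StatsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "control_mean": r.control_mean,
                "control_median": r.control_median,
                "patient_mean": r.patient_mean,
                "patient_median": r.patient_median,
                "fold_change_mean": r.fold_change_mean,
                "fold_change_median": r.fold_change_median,
                "t_statistic": r.t_statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "n_control": r.n_control,
                "n_patient": r.n_patient,
                "outliers_removed": ";".join(r.outliers_removed),
            }
            for r in results
        ]
    )


def gm2_gm3_ratio(
    table: pd.DataFrame,
    gm2_col: str = "GM2 d36:1",
    gm3_col: str = "GM3 d36:1",
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-sample GM2/GM3 ratio and its patient/control fold-change.

    Returns (per-sample frame with a ``gm2_gm3_ratio`` column, summary
    dict with mean-based and median-based group fold-changes).
    """
    for col in (gm2_col, gm3_col):
        if col not in table.columns:
            raise KeyError(f"column {col!r} missing from cohort table")
    if (table[gm3_col] <= 0).any():
        raise ValueError("GM2/GM3 ratio undefined: non-positive GM3 amounts")
    out = table[["sample_id", "group"]].copy()
    out["gm2_gm3_ratio"] = table[gm2_col] / table[gm3_col]
    is_pat = out["group"].isin(PATIENT_GROUPS)
    r_pat = out.loc[is_pat, "gm2_gm3_ratio"]
    r_ctl = out.loc[~is_pat, "gm2_gm3_ratio"]
    summary = {
        "fold_change_mean": float(r_pat.mean() / r_ctl.mean()),
        "fold_change_median": float(r_pat.median() / r_ctl.median()),
    }
    return out, summary


# -- PCA and heatmap export --------------------------------------------------


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # species x components
    explained_variance_ratio: np.ndarray


def pca(
    table: pd.DataFrame,
    species: Optional[Sequence[str]] = None,
    n_components: Optional[int] = None,
    autoscale: bool = True,
) -> PCAResult:
    """PCA of the amount matrix: column-wise autoscaling (mean 0, SD 1)
    then SVD.  Sign convention: each loading vector's largest-magnitude
    element is made positive, so score signs are reproducible."""
    if species is None:
        species = species_columns(table)
    if len(species) < 2:
        raise ValueError("PCA needs >= 2 species")
    X = table[list(species)].to_numpy(float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs >= 3 samples")
    Xc = X - X.mean(axis=0)
    if autoscale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [s for s, z in zip(species, sd == 0) if z]
            raise ValueError(f"zero-variance species: {bad}")
        Xc = Xc / sd
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or min(Xc.shape)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    # deterministic signs
    for j in range(k):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    var = s**2 / (Xc.shape[0] - 1)
    total_var = np.sum(np.var(Xc, axis=0, ddof=1))
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table["sample_id"], columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=list(species), columns=comp_names),
        explained_variance_ratio=var / total_var,
    )


def heatmap_zscores(
    table: pd.DataFrame, species: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Per-species z-scores over all samples (heatmap export; no
    rendering).  z = (x - mean) / SD, SD with n-1 denominator."""
    if species is None:
        species = species_columns(table)
    X = table[list(species)].astype(float)
    sd = X.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance species: {zero}")
    z = (X - X.mean()) / sd
    z.index = table["sample_id"]
    return z
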