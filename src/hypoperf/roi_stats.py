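"""Per-ROI perfusion statistics: means, paired t-tests, COV.

The study design is within-subject: every subject is measured under
euglycemia and hypoglycemia with both modalities, so condition effects are
tested with a paired t-test on per-subject ROI means (df = n - 1, two-sided
p, significance at p < 0.05).

Test-retest reliability is summarized by the coefficient of variation
(COV): the average across subjects of the within-subject SD of repeat-level
ROI means, divided by the grand mean of those means.  The repeat unit is
modality specific — one of the 4 injections for PET-like data, one
tag/control pair for ASL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .asl_quant import CbfMap

ROI_MEANS_COLUMNS = [
    "subject_id",
    "modality",
    "condition",
    "roi_name",
    "mean_cbf",
    "n_voxels",
    "repeat_index",
]


@dataclass(frozen=True)
class PairedTestResult:
    roi_name: str
    modality: str
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float
    n: int

    def __post_init__(self) -> None:
        if self.df != self.n - 1:
            raise ValueError("df must equal n - 1")


@dataclass(frozen=True)
class CovResult:
    roi_name: str
    modality: str
    cov: float
    n_repeats: int
    n_subjects: int

    @property
    def percent(self) -> float:
        return 100.0 * self.cov


def roi_means(
    cbf: CbfMap,
    labels: np.ndarray,
    roi_set: Mapping[str, int],
) -> pd.DataFrame:
    """Mean CBF over the valid voxels of each requested ROI.

    Returns one row per ROI with columns ``roi_name``, ``mean_cbf`` and
    ``n_voxels``; caller-side identifiers (subject, modality, condition,
    repeat) are added by the caller.
    """
    labels = np.asarray(labels)
    if labels.shape != cbf.cbf.shape:
        raise ValueError("labels grid does not match CBF grid")
    rows = []
    for name, label in roi_set.items():
        in_roi = labels == label
        if not in_roi.any():
            raise ValueError(f"ROI {name!r} (label {label}) absent from label volume")
        use = in_roi & cbf.valid_mask
        if not use.any():
            raise ValueError(f"ROI {name!r} has no valid voxels")
        rows.append(
            {
                "roi_name": name,
                "mean_cbf": float(cbf.cbf[use].mean()),
                "n_voxels": int(use.sum()),
            }
        )
    return pd.DataFrame(rows)


def paired_ttest(
    eu: Sequence[float],
    hypo: Sequence[float],
    roi_name: str = "",
    modality: str = "",
) -> PairedTestResult:
    """Two-sided paired t-test of hypo - eu on subject-aligned values.

    t = mean(d) / (sd(d) / sqrt(n)) with the sample SD (n - 1 denominator)
    and df = n - 1.  A zero-variance difference with nonzero mean is
    reported as the limit t = +/-inf, p = 0.
    """
    eu_arr = np.asarray(eu, dtype=float)
    hypo_arr = np.asarray(hypo, dtype=float)
    if eu_arr.shape != hypo_arr.shape or eu_arr.ndim != 1:
        raise ValueError("eu and hypo must be 1D subject-aligned sequences of equal length")
    n = eu_arr.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    d = hypo_arr - eu_arr
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean_d == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.copysign(math.inf, mean_d), 0.0
    else:
        t_stat = mean_d / (sd / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    return PairedTestResult(
        roi_name=roi_name,
        modality=modality,
        t_statistic=t_stat,
        df=df,
        p_value=p,
        mean_difference=mean_d,
        n=n,
    )


def cov(
    repeat_means: pd.DataFrame | Mapping[object, Sequence[float]],
    roi_name: str = "",
    modality: str = "",
) -> CovResult:
    """Coefficient of variation of repeated ROI measurements.

    Accepts either a DataFrame with ``subject_id`` and ``mean_cbf`` columns
    (one row per repeat) or a mapping of subject -> repeat values.  For each
    subject with >= 2 repeats the within-subject sample SD is taken; the COV
    is the mean of those SDs divided by the grand mean of all repeat values.
    """
    if isinstance(repeat_means, pd.DataFrame):
        groups = {
            subj: grp["mean_cbf"].to_numpy(dtype=float)
            for subj, grp in repeat_means.groupby("subject_id")
        }
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in repeat_means.items()}
    usable = {k: v for k, v in groups.items() if v.size >= 2}
    if not usable:
        raise ValueError("COV needs at least one subject with >= 2 repeats")
    sds = [float(v.std(ddof=1)) for v in usable.values()]
    all_values = np.concatenate(list(usable.values()))
    grand_mean = float(all_values.mean())
    if grand_mean == 0:
        raise ValueError("grand mean of repeat measurements is zero")
    return CovResult(
        roi_name=roi_name,
        modality=modality,
        cov=float(np.mean(sds)) / grand_mean,
        n_repeats=int(min(v.size for v in usable.values())),
        n_subjects=len(usable),
    )


def roi_significance_summary(
    results: Sequence[PairedTestResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag ROIs with a significant CBF increase, per modality and jointly.

    A result is flagged when p < alpha (strict) and the mean difference is
    positive.  ``both_modalities`` marks ROIs significant in every modality
    present for that ROI (the cross-method agreement criterion).
    """
    rows = [
        {
            "roi_name": r.roi_name,
            "modality": r.modality,
            "t_statistic": r.t_statistic,
            "p_value": r.p_value,
            "mean_difference": r.mean_difference,
            "significant_increase": bool(r.p_value < alpha and r.mean_difference > 0),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        df["both_modalities"] = pd.Series(dtype=bool)
        return df
    agreement = df.groupby("roi_name")["significant_increase"].transform("all")
    df["both_modalities"] = agreement
    return df
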