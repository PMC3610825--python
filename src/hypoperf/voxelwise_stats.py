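"""Voxel-wise paired comparison of condition CBF maps with FWE control.

Per in-mask voxel, the same paired t-test used for ROI means is applied
across subjects to the hypo - eu difference maps.  Family-wise error over
voxels is controlled by Bonferroni, Holm, or a sign-flip max-T permutation
test — the latter is exact for a paired design because under the null each
subject's difference map is symmetric about zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .asl_quant import CbfMap

CORRECTION_METHODS = ("holm", "bonferroni", "permutation_maxT")


@dataclass
class StatMap:
    """Voxel-wise paired-test results on a common grid."""

    t_map: np.ndarray
    p_map: np.ndarray
    difference_map: np.ndarray
    mask: np.ndarray
    df: int
    #: per-subject difference volumes (n_subjects, x, y, z); retained so a
    #: permutation correction can re-randomize the original data.
    subject_differences: np.ndarray | None = field(default=None, repr=False)


def _paired_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t over axis 0; returns (t, two-sided p)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    zero_sd = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(zero_sd & (mean == 0), 0.0, t)
        t = np.where(zero_sd & (mean != 0), np.sign(mean) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return t, p


def paired_t_map(
    eu_maps: list[CbfMap],
    hypo_maps: list[CbfMap],
    mask: np.ndarray | None = None,
) -> StatMap:
    """Voxel-wise paired t-test of subject-aligned condition map lists.

    ``mask`` defaults to the intersection of every subject's valid mask.
    Outside the mask, t and the difference are 0 and p is 1.
    """
    if len(eu_maps) != len(hypo_maps):
        raise ValueError("eu and hypo map lists must be subject-aligned and equal length")
    n = len(eu_maps)
    if n < 2:
        raise ValueError("voxel-wise paired test needs at least 2 subjects")
    shape = eu_maps[0].cbf.shape
    for m in (*eu_maps, *hypo_maps):
        if m.cbf.shape != shape:
            raise ValueError("all condition maps must share a grid")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
        for m in (*eu_maps, *hypo_maps):
            mask &= m.valid_mask
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask grid does not match the maps")
    diffs = np.stack([h.cbf - e.cbf for e, h in zip(eu_maps, hypo_maps)])
    t_in, p_in = _paired_t(diffs[:, mask])
    t_map = np.zeros(shape)
    p_map = np.ones(shape)
    diff_map = np.zeros(shape)
    t_map[mask] = t_in
    p_map[mask] = p_in
    diff_map[mask] = diffs[:, mask].mean(axis=0)
    return StatMap(
        t_map=t_map,
        p_map=p_map,
        difference_map=diff_map,
        mask=mask,
        df=n - 1,
        subject_differences=diffs,
    )


def _maxt_null(diffs_in_mask: np.ndarray, n_permutations: int, seed) -> np.ndarray:
    """Max |t| distribution over sign-flip permutations.

    All 2^n sign patterns are enumerated when they fit in ``n_permutations``;
    otherwise ``n_permutations`` random sign vectors are drawn (the identity
    pattern is always included, making the test valid).
    """
    n = diffs_in_mask.shape[0]
    if 2**n <= n_permutations:
        sign_sets = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        sign_sets = rng.choice((1.0, -1.0), size=(n_permutations, n))
        sign_sets[0] = 1.0
    null = np.empty(len(sign_sets))
    for i, signs in enumerate(sign_sets):
        t, _ = _paired_t(diffs_in_mask * signs[:, None])
        null[i] = np.max(np.abs(t))
    return null


def correct_multiple(
    stat: StatMap,
    method: str = "holm",
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Boolean volume of voxels surviving family-wise control at ``alpha``.

    Returns ``(survival_mask, metadata)``; metadata records method and
    parameters so the correction is reproducible from the outputs.
    """
    if method not in CORRECTION_METHODS:
        raise ValueError(f"unknown correction method {method!r}; choose from {CORRECTION_METHODS}")
    mask = stat.mask
    out = np.zeros(stat.p_map.shape, dtype=bool)
    meta = {"method": method, "alpha": alpha, "n_voxels_tested": int(mask.sum())}
    p_in = stat.p_map[mask]
    if p_in.size == 0:
        return out, meta
    if method in ("holm", "bonferroni"):
        reject, *_ = multipletests(p_in, alpha=alpha, method=method)
        out[mask] = reject
        return out, meta
    if n_permutations < 100:
        raise ValueError("permutation_maxT needs n_permutations >= 100")
    if stat.subject_differences is None:
        raise ValueError(
            "permutation_maxT needs the per-subject differences; build the "
            "StatMap with paired_t_map"
        )
    diffs = stat.subject_differences[:, mask]
    null = _maxt_null(diffs, n_permutations, seed)
    t_obs = np.abs(stat.t_map[mask])
    # FWE-adjusted p: fraction of permutations whose max |t| reaches the voxel's |t|
    p_fwe = (null[None, :] >= t_obs[:, None] - 1e-12).mean(axis=1)
    out[mask] = p_fwe <= alpha
    meta.update(
        {
            "n_permutations": int(len(null)),
            "exhaustive": bool(2 ** diffs.shape[0] <= n_permutations),
            "seed": seed,
        }
    )
    return out, meta
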