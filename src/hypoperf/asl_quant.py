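"""Quantitative CBF from pulsed-ASL tag/control series.

Implements the PICORE QUIPSS II single-compartment closed form: with a bolus
of arterial blood tagged for a duration ``TI1`` and imaged at ``TI2``, the
perfusion-weighted difference signal ``dM = control - tag`` maps to cerebral
blood flow as

    f = lambda * dM / (2 * alpha * M0 * TI1 * exp(-TI2 / T1a))

where ``f`` is in mL/g/s, ``lambda`` is the blood/tissue water partition
coefficient (mL/g), ``alpha`` the inversion (tag) efficiency, ``M0`` the
equilibrium magnetization of tissue and ``T1a`` the longitudinal relaxation
time of arterial blood.  Maps are stored in the conventional physiological
unit mL/100 g/min; the single conversion constant lives in
:data:`ML_G_S_TO_ML_100G_MIN`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

#: mL/g/s -> mL/100 g/min (x100 per-mass, x60 per-minute).
ML_G_S_TO_ML_100G_MIN = 6000.0

#: Physiological range (mL/100 g/min) the pulsed-ASL method can map reliably;
#: voxels outside it are flagged invalid rather than censored.
CBF_VALID_RANGE = (10.0, 150.0)

#: Voxels whose M0 falls below this fraction of the robust (99th percentile)
#: maximum are treated as non-brain: the kinetic formula divides by M0.
M0_FLOOR_FRACTION = 0.10

TAG = "tag"
CONTROL = "control"


@dataclass(frozen=True)
class AcqParams:
    """Pulsed-ASL acquisition and quantification parameters.

    Defaults are the study values for a PICORE QUIPSS II protocol at 1.5 T:
    TI1 = 700 ms (tag delivery), TI2 = 1800 ms (image collection),
    alpha = 0.98, lambda = 0.9 mL/g, T1a = 1.6 s.  ``tr`` and ``te`` are
    carried as metadata only.
    """

    ti1: float = 0.7
    ti2: float = 1.8
    alpha: float = 0.98
    lam: float = 0.9
    t1a: float = 1.6
    tag_order: str = "tag_first"
    tr: float = 2.5
    te: float = 0.013

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.ti1 <= 0:
            raise ValueError(f"ti1 must be positive, got {self.ti1}")
        if self.ti2 < self.ti1:
            raise ValueError(f"ti2 ({self.ti2}) must be >= ti1 ({self.ti1})")
        if self.t1a <= 0:
            raise ValueError(f"t1a must be positive, got {self.t1a}")
        if self.lam <= 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        if self.tag_order not in ("tag_first", "control_first"):
            raise ValueError(f"unknown tag_order: {self.tag_order!r}")

    @property
    def bolus_scaling(self) -> float:
        """The denominator factor 2 * alpha * TI1 * exp(-TI2 / T1a)."""
        return 2.0 * self.alpha * self.ti1 * math.exp(-self.ti2 / self.t1a)

    @property
    def frame_cycle(self) -> tuple[str, str]:
        if self.tag_order == "tag_first":
            return (TAG, CONTROL)
        return (CONTROL, TAG)


@dataclass
class AslSeries:
    """A 4D pulsed-ASL acquisition: frames plus their tag/control labels."""

    data: np.ndarray
    frame_labels: tuple[str, ...]
    acq: AcqParams = field(default_factory=AcqParams)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.frame_labels = tuple(self.frame_labels)
        if self.data.ndim != 4:
            raise ValueError("AslSeries data must be 4D (x, y, z, frame)")
        if self.data.shape[-1] != len(self.frame_labels):
            raise ValueError(
                f"{self.data.shape[-1]} frames but "
                f"{len(self.frame_labels)} frame labels"
            )
        bad = [lab for lab in self.frame_labels if lab not in (TAG, CONTROL)]
        if bad:
            raise ValueError(f"frame labels must be tag/control, got {bad[0]!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def frame(self, index: int) -> np.ndarray:
        return self.data[..., index]


@dataclass
class PerfusionImage:
    """Mean perfusion-weighted difference image (control - tag)."""

    delta_m: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class M0Image:
    """Equilibrium-magnetization image in scanner units."""

    m0: np.ndarray


@dataclass
class CbfMap:
    """Quantitative perfusion volume in mL/100 g/min with validity flags.

    ``valid_mask`` is True only where the value is physiologically mappable:
    inside the brain and within :data:`CBF_VALID_RANGE`.
    """

    cbf: np.ndarray
    valid_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.cbf = np.asarray(self.cbf, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.cbf.shape != self.valid_mask.shape:
            raise ValueError("cbf and valid_mask shapes differ")


def split_pairs(series: AslSeries) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split an alternating series into ordered (tag, control) frame pairs.

    The label sequence must strictly alternate according to
    ``series.acq.tag_order``; the first inconsistent frame is reported.
    """
    n = series.n_frames
    if n % 2 != 0:
        raise ValueError(f"cannot pair an odd number of frames ({n})")
    cycle = series.acq.frame_cycle
    for i, lab in enumerate(series.frame_labels):
        if lab != cycle[i % 2]:
            raise ValueError(
                f"frame {i} labelled {lab!r} but {cycle[i % 2]!r} expected "
                f"for tag_order={series.acq.tag_order!r}"
            )
    pairs = []
    for k in range(n // 2):
        a, b = series.frame(2 * k), series.frame(2 * k + 1)
        tag, control = (a, b) if cycle[0] == TAG else (b, a)
        pairs.append((tag, control))
    return pairs


def subtract_pairs(pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> PerfusionImage:
    """Average the pairwise control - tag differences into one dM image."""
    if len(pairs) == 0:
        raise ValueError("no tag/control pairs to subtract")
    shape = pairs[0][0].shape
    for i, (tag, control) in enumerate(pairs):
        if tag.shape != shape or control.shape != shape:
            raise ValueError(f"pair {i} frames do not share the series grid")
    delta = np.mean([control - tag for tag, control in pairs], axis=0)
    return PerfusionImage(delta_m=delta, n_pairs=len(pairs))


def estimate_m0(series: AslSeries, m0: np.ndarray | None = None) -> M0Image:
    """Estimate M0 as the mean control image, or pass a supplied map through.

    Without a dedicated equilibrium scan the mean of the control frames is
    the standard proxy for PICORE QUIPSS II data.
    """
    if m0 is not None:
        return M0Image(m0=np.asarray(m0, dtype=float))
    control = [series.frame(i) for i, lab in enumerate(series.frame_labels)
               if lab == CONTROL]
    if not control:
        raise ValueError("series contains no control frames")
    return M0Image(m0=np.mean(control, axis=0))


def quantify_cbf(dm: PerfusionImage, m0: M0Image, acq: AcqParams) -> CbfMap:
    """Apply the QUIPSS II closed form voxel-wise and flag valid voxels.

    Voxels with M0 below ``M0_FLOOR_FRACTION`` of its robust maximum are set
    to zero and marked invalid (air has no meaningful M0 denominator); the
    remaining voxels get ``valid_mask`` from :data:`CBF_VALID_RANGE`.
    """
    delta = np.asarray(dm.delta_m, dtype=float)
    m0v = np.asarray(m0.m0, dtype=float)
    if delta.shape != m0v.shape:
        raise ValueError(
            f"dM grid {delta.shape} does not match M0 grid {m0v.shape}"
        )
    robust_max = np.percentile(m0v, 99)
    floor = M0_FLOOR_FRACTION * robust_max
    in_brain = m0v > max(floor, 0.0)
    cbf = np.zeros_like(delta)
    np.divide(
        acq.lam * delta * ML_G_S_TO_ML_100G_MIN,
        acq.bolus_scaling * m0v,
        out=cbf,
        where=in_brain,
    )
    cbf[~in_brain] = 0.0
    lo, hi = CBF_VALID_RANGE
    valid = in_brain & (cbf >= lo) & (cbf <= hi)
    return CbfMap(cbf=cbf, valid_mask=valid)


def quantify_series(
    series: AslSeries, m0: np.ndarray | None = None
) -> CbfMap:
    """Full pooled quantification: split, subtract, estimate M0, quantify."""
    pairs = split_pairs(series)
    dm = subtract_pairs(pairs)
    m0_img = estimate_m0(series, m0)
    out = quantify_cbf(dm, m0_img, series.acq)
    out.affine = np.array(series.affine)
    return out


def per_pair_cbf(
    series: AslSeries, m0: np.ndarray | None = None
) -> list[CbfMap]:
    """Quantify each tag/control pair separately (repeat-level CBF maps).

    Used for test-retest metrics: each single-pair map is one 'repeat'
    measurement of the same underlying perfusion state.
    """
    pairs = split_pairs(series)
    m0_img = estimate_m0(series, m0)
    maps = []
    for tag, control in pairs:
        dm = PerfusionImage(delta_m=control - tag, n_pairs=1)
        maps.append(quantify_cbf(dm, m0_img, series.acq))
    return maps


def compute_brain_mask(
    m0: M0Image | np.ndarray, threshold_fraction: float = 0.5
) -> np.ndarray:
    """Threshold M0 at a fraction of its robust maximum; keep the largest
    connected component."""
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    m0v = np.asarray(m0.m0 if isinstance(m0, M0Image) else m0, dtype=float)
    robust_max = np.percentile(m0v, 99)
    mask = m0v >= threshold_fraction * robust_max
    if robust_max <= 0 or not mask.any():
        raise ValueError("brain mask is empty (M0 carries no signal)")
    labelled, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labelled, index=np.arange(1, n + 1))
        mask = labelled == (1 + int(np.argmax(sizes)))
    return mask
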