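"""Processing of PET-like relative perfusion volumes.

[15O]water PET yields maps proportional to perfusion with an arbitrary
per-session scale (dose, decay, scanner calibration).  Comparability across
subjects and conditions is restored by global-mean normalization: every map
is rescaled so its whole-brain mean equals a reference CBF, here
50 mL/100 g/min.  Repeats within a condition are averaged first (noise
efficiency), then the mean image is normalized; because normalization is
scale invariant, the order does not affect ROI contrasts when the repeats
share a global scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .asl_quant import CbfMap

#: Reference whole-brain CBF, mL/100 g/min.
GLOBAL_MEAN_TARGET = 50.0


@dataclass
class PetCondition:
    """The repeat volumes acquired within one glycemic condition."""

    repeats: list[np.ndarray]
    mask: np.ndarray
    condition: str = "eu"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if len(self.repeats) < 1:
            raise ValueError("a PET condition needs at least one repeat")
        self.repeats = [np.asarray(r, dtype=float) for r in self.repeats]
        self.mask = np.asarray(self.mask, dtype=bool)
        shape = self.repeats[0].shape
        for i, rep in enumerate(self.repeats):
            if rep.shape != shape:
                raise ValueError(f"repeat {i} does not share the condition grid")
        if self.mask.shape != shape:
            raise ValueError("mask does not share the repeat grid")


def average_repeats(cond: PetCondition) -> np.ndarray:
    """Voxel-wise arithmetic mean over the condition's repeat volumes."""
    return np.mean(cond.repeats, axis=0)


def normalize_global(
    volume: np.ndarray,
    mask: np.ndarray,
    target: float = GLOBAL_MEAN_TARGET,
) -> CbfMap:
    """Rescale a relative perfusion volume to a whole-brain mean of ``target``.

    The output carries mL/100 g/min units from here on.  All in-mask voxels
    are flagged valid: a globally normalized PET map has no per-voxel
    physiological validity flags of its own.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must share a grid")
    if not mask.any():
        raise ValueError("brain mask is empty")
    in_mask_mean = volume[mask].mean()
    if in_mask_mean <= 0:
        raise ValueError(
            f"in-mask mean must be positive to normalize, got {in_mask_mean:g}"
        )
    scaled = volume * (target / in_mask_mean)
    return CbfMap(cbf=scaled, valid_mask=mask.copy())


def process_condition(cond: PetCondition, target: float = GLOBAL_MEAN_TARGET) -> CbfMap:
    """Average the repeats, then normalize the mean image (the fixed order)."""
    out = normalize_global(average_repeats(cond), cond.mask, target)
    out.affine = np.array(cond.affine)
    return out
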