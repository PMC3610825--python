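"""Phantom cohort generator with known perfusion ground truth.

Emulates the measurement structure of a paired euglycemia/hypoglycemia
perfusion study: 9 subjects, each measured in both glycemic conditions with
a 140-frame pulsed-ASL tag/control series (70 pairs) and 4 PET-like
relative perfusion repeats.  Hypoglycemia raises CBF by a configurable
fraction (default +10%) in three responsive regions — thalamus, medial
prefrontal cortex and globus pallidum — while the remaining gray and white
matter are unaffected.

The anatomy is parametric: an ellipsoidal brain containing spherical named
ROIs, an inner white-matter ellipsoid, and background gray matter.  All
downstream analysis sees only a label volume, so parametric shapes preserve
the full analysis contract without anatomical segmentation.

ASL frames are forward simulations that invert the QUIPSS II quantification
formula (so noiseless quantification reproduces the truth exactly);
PET-like images are the truth under an arbitrary, unrecoverable global
scale with multiplicative voxel noise.  Noise defaults are calibrated by
:func:`calibrate_noise` so the pipeline-measured ROI COV matches the study
reliability figures of ~6% (PET) and ~12% (ASL).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import pet_proc, roi_stats
from .asl_quant import (
    ML_G_S_TO_ML_100G_MIN,
    AcqParams,
    AslSeries,
    CbfMap,
    CBF_VALID_RANGE,
    per_pair_cbf,
)
from .registration import RigidTransform, resample

#: Fixed label codes for the phantom label volume.
ROI_LABELS = {
    "thalamus": 1,
    "medial_prefrontal": 2,
    "globus_pallidum": 3,
    "right_orbitoprefrontal": 4,
    "background_gray": 5,
    "white_matter": 6,
}

#: The anatomically named ROIs whose means enter the paired tests and COV.
NAMED_ROIS = (
    "thalamus",
    "medial_prefrontal",
    "globus_pallidum",
    "right_orbitoprefrontal",
)

#: ROIs with a hypoglycemia CBF response in the default phantom.
RESPONSIVE_ROIS = ("thalamus", "medial_prefrontal", "globus_pallidum")

CONDITIONS = ("eu", "hypo")


@dataclass(frozen=True)
class RoiSphere:
    """A spherical ROI placement in voxel-index coordinates."""

    center_vox: tuple[float, float, float]
    radius_vox: float


def _default_roi_geometry() -> dict[str, RoiSphere]:
    return {
        "thalamus": RoiSphere((11.0, 11.0, 6.0), 2.0),
        "globus_pallidum": RoiSphere((7.0, 11.0, 6.0), 1.6),
        "medial_prefrontal": RoiSphere((11.0, 16.0, 6.0), 2.0),
        "right_orbitoprefrontal": RoiSphere((15.0, 16.0, 4.0), 1.6),
    }


def _default_baseline_cbf() -> dict[str, float]:
    # Gray matter ~60, white matter ~20 mL/100 g/min.
    return {
        "thalamus": 60.0,
        "medial_prefrontal": 60.0,
        "globus_pallidum": 60.0,
        "right_orbitoprefrontal": 60.0,
        "background_gray": 60.0,
        "white_matter": 20.0,
    }


def _default_effect_fraction() -> dict[str, float]:
    out = {name: 0.0 for name in ROI_LABELS}
    for name in RESPONSIVE_ROIS:
        out[name] = 0.10
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the synthetic study; defaults are the study conditions.

    ``asl_noise_sd`` (additive frame noise, fraction of in-brain M0) and
    ``pet_noise_sd`` (multiplicative voxel noise fraction) default to values
    calibrated with :func:`calibrate_noise` so the measured repeat-level ROI
    COV is ~12% for ASL and ~6% for PET.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 8.0)
    n_subjects: int = 9
    roi_geometry: Mapping[str, RoiSphere] = field(default_factory=_default_roi_geometry)
    # Triaxial in world units (40 x 32 x 36 mm semiaxes): a rotationally
    # asymmetric outline keeps all three rotation angles observable by
    # intensity-based registration.
    brain_semiaxes_vox: tuple[float, float, float] = (10.0, 8.0, 4.5)
    white_matter_semiaxes_vox: tuple[float, float, float] = (5.5, 4.5, 2.5)
    baseline_cbf: Mapping[str, float] = field(default_factory=_default_baseline_cbf)
    effect_fraction: Mapping[str, float] = field(default_factory=_default_effect_fraction)
    between_subject_sd: float = 0.10
    asl_noise_sd: float = 0.0037
    pet_noise_sd: float = 0.33
    n_asl_frames: int = 140
    n_pet_repeats: int = 4
    motion_translation_mm: float = 8.0
    motion_rotation_deg: float = 3.0
    m0_value: float = 1000.0
    acq: AcqParams = field(default_factory=AcqParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asl_frames % 2 != 0:
            raise ValueError("n_asl_frames must be even (tag/control pairing)")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for name, value in self.baseline_cbf.items():
            if value < 0:
                raise ValueError(f"baseline CBF for {name!r} is negative")
        for name, value in self.effect_fraction.items():
            if value <= -1:
                raise ValueError(f"effect_fraction for {name!r} must exceed -1")
        if self.asl_noise_sd < 0 or self.pet_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")

    @property
    def brain_center_vox(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, float) - 1.0) / 2.0

    @property
    def affine(self) -> np.ndarray:
        out = np.diag((*self.voxel_size_mm, 1.0))
        return out


@dataclass
class PhantomTruth:
    """Ground truth for one simulated cohort; the oracle for recovery tests."""

    labels: np.ndarray
    truth_cbf: dict[tuple[int, str], CbfMap]
    m0: np.ndarray
    injected_motion: dict[tuple[int, str], list[RigidTransform]]
    spec: PhantomSpec
    subject_multipliers: np.ndarray | None = None


class RoiOverlapError(ValueError):
    """Two named ROI placements collide."""


def _ellipsoid(shape: Sequence[int], center: np.ndarray, semiaxes: Sequence[float]) -> np.ndarray:
    grids = np.indices(shape).astype(float)
    acc = np.zeros(shape)
    for axis in range(3):
        acc += ((grids[axis] - center[axis]) / semiaxes[axis]) ** 2
    return acc <= 1.0


def _sphere(shape: Sequence[int], sphere: RoiSphere) -> np.ndarray:
    return _ellipsoid(shape, np.asarray(sphere.center_vox, float), (sphere.radius_vox,) * 3)


def make_roi_labels(spec: PhantomSpec) -> np.ndarray:
    """Build the integer ROI label volume for a spec.

    0 is outside the brain; named ROIs are carved first (any overlap raises
    :class:`RoiOverlapError` naming the colliding pair), then the inner
    white-matter ellipsoid claims remaining central voxels and background
    gray matter fills the rest of the brain.
    """
    shape = spec.grid_shape
    brain = _ellipsoid(shape, spec.brain_center_vox, spec.brain_semiaxes_vox)
    labels = np.zeros(shape, dtype=np.int16)
    masks: dict[str, np.ndarray] = {}
    for name, geom in spec.roi_geometry.items():
        if name not in ROI_LABELS:
            raise ValueError(f"unknown ROI name {name!r}")
        vox = _sphere(shape, geom)
        if not np.all(brain[vox]):
            raise ValueError(f"ROI {name!r} extends outside the phantom brain")
        masks[name] = vox
    for a, b in itertools.combinations(masks, 2):
        if np.any(masks[a] & masks[b]):
            raise RoiOverlapError(f"ROI placements overlap: {a!r} and {b!r}")
    for name, vox in masks.items():
        labels[vox] = ROI_LABELS[name]
    white = _ellipsoid(shape, spec.brain_center_vox, spec.white_matter_semiaxes_vox)
    labels[white & brain & (labels == 0)] = ROI_LABELS["white_matter"]
    labels[brain & (labels == 0)] = ROI_LABELS["background_gray"]
    return labels


def _label_value_map(spec: PhantomSpec, condition: str) -> dict[int, float]:
    values = {}
    for name, label in ROI_LABELS.items():
        base = spec.baseline_cbf[name]
        if condition == "hypo":
            base = base * (1.0 + spec.effect_fraction.get(name, 0.0))
        values[label] = base
    return values


def subject_multiplier(spec: PhantomSpec, subject_index: int) -> float:
    """Per-subject global CBF multiplier, shared by both conditions.

    Drawn once per subject from N(1, between_subject_sd) on a substream
    keyed by (spec.seed, subject) so the paired design holds by
    construction; floored away from zero for physical plausibility.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7001, subject_index]))
    return max(0.2, float(rng.normal(1.0, spec.between_subject_sd)))


def simulate_truth_cbf(
    spec: PhantomSpec,
    subject_index: int,
    condition: str,
    labels: np.ndarray | None = None,
) -> CbfMap:
    """Ground-truth CBF map for one subject and condition.

    Per-label baseline x (1 + effect under hypoglycemia) x the subject's
    multiplier; zero outside the brain.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValueError(f"subject_index {subject_index} out of range")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if labels is None:
        labels = make_roi_labels(spec)
    mult = subject_multiplier(spec, subject_index)
    cbf = np.zeros(spec.grid_shape)
    for label, value in _label_value_map(spec, condition).items():
        cbf[labels == label] = value * mult
    lo, hi = CBF_VALID_RANGE
    valid = (labels > 0) & (cbf >= lo) & (cbf <= hi)
    return CbfMap(cbf=cbf, valid_mask=valid, affine=spec.affine)


def truth_template(spec: PhantomSpec, condition: str, labels: np.ndarray | None = None) -> CbfMap:
    """The noiseless population template (subject multiplier = 1)."""
    if labels is None:
        labels = make_roi_labels(spec)
    cbf = np.zeros(spec.grid_shape)
    for label, value in _label_value_map(spec, condition).items():
        cbf[labels == label] = value
    lo, hi = CBF_VALID_RANGE
    valid = (labels > 0) & (cbf >= lo) & (cbf <= hi)
    return CbfMap(cbf=cbf, valid_mask=valid, affine=spec.affine)


def make_m0(spec: PhantomSpec, labels: np.ndarray | None = None) -> np.ndarray:
    """Binary brain/air equilibrium-magnetization map in scanner units."""
    if labels is None:
        labels = make_roi_labels(spec)
    return np.where(labels > 0, spec.m0_value, 0.0)


def simulate_asl_series(
    truth: CbfMap,
    m0: np.ndarray,
    acq: AcqParams,
    noise_sd: float,
    n_frames: int,
    rng: np.random.Generator,
) -> AslSeries:
    """Forward-simulate a tag/control series from a truth CBF map.

    The control frame is the M0 image (proportionality 1 by convention);
    the tag frame is control minus the difference signal predicted by the
    QUIPSS II formula.  Independent Gaussian noise with SD ``noise_sd`` x
    mean in-brain M0 is added to every frame, so a noiseless series inverts
    exactly under quantification.
    """
    if n_frames % 2 != 0:
        raise ValueError("n_frames must be even")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    m0 = np.asarray(m0, float)
    f_ml_g_s = truth.cbf / ML_G_S_TO_ML_100G_MIN
    dm_true = f_ml_g_s * acq.bolus_scaling * m0 / acq.lam
    sd = noise_sd * (m0[m0 > 0].mean() if np.any(m0 > 0) else 1.0)
    cycle = acq.frame_cycle
    frames = np.empty((*truth.cbf.shape, n_frames))
    for k in range(n_frames):
        base = m0 if cycle[k % 2] == "control" else m0 - dm_true
        noise = rng.normal(0.0, sd, size=m0.shape) if noise_sd > 0 else 0.0
        frames[..., k] = base + noise
    labels = tuple(cycle[k % 2] for k in range(n_frames))
    return AslSeries(data=frames, frame_labels=labels, acq=acq, affine=truth.affine)


def simulate_pet_image(
    truth: CbfMap,
    scale: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """PET-like relative perfusion image: scale x truth x (1 + noise).

    The global scale is unrecoverable by design; only global-mean
    normalization restores cross-image comparability.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    noise = rng.normal(0.0, noise_sd, size=truth.cbf.shape) if noise_sd > 0 else 0.0
    return scale * truth.cbf * (1.0 + noise)


def random_motion(
    spec: PhantomSpec, n_frames: int, rng: np.random.Generator
) -> list[RigidTransform]:
    """Draw per-frame rigid transforms within the phantom's motion amplitude."""
    center = tuple(spec.brain_center_vox * np.asarray(spec.voxel_size_mm))
    out = []
    for _ in range(n_frames):
        t = rng.uniform(-spec.motion_translation_mm, spec.motion_translation_mm, 3)
        r = rng.uniform(-spec.motion_rotation_deg, spec.motion_rotation_deg, 3)
        out.append(RigidTransform(tuple(r), tuple(t), center))
    return out


def inject_motion(series: AslSeries, transforms: Sequence[RigidTransform]) -> AslSeries:
    """Resample each frame under its transform (trilinear)."""
    if len(transforms) != series.n_frames:
        raise ValueError(
            f"{len(transforms)} transforms for {series.n_frames} frames"
        )
    vs = series.voxel_size_mm
    moved = np.empty_like(series.data)
    for k, t in enumerate(transforms):
        moved[..., k] = resample(series.frame(k), t, vs)
    return AslSeries(
        data=moved,
        frame_labels=series.frame_labels,
        acq=series.acq,
        affine=np.array(series.affine),
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def simulate_cohort(
    spec: PhantomSpec,
    with_motion: bool = False,
) -> tuple[PhantomTruth, dict[tuple[int, str], dict]]:
    """Simulate a full paired cohort from a spec.

    Returns ``(truth, data)`` where ``data[(subject, condition)]`` holds the
    ASL series under ``"asl"`` and the list of PET repeat volumes under
    ``"pet"``.  PET repeats within a subject/condition share one arbitrary
    global scale (the averaged-then-normalized pipeline order assumes it).
    All randomness derives from ``spec.seed`` via named substreams, so equal
    seeds give bit-identical cohorts.
    """
    labels = make_roi_labels(spec)
    m0 = make_m0(spec, labels)
    truth_maps: dict[tuple[int, str], CbfMap] = {}
    motion: dict[tuple[int, str], list[RigidTransform]] = {}
    data: dict[tuple[int, str], dict] = {}
    mults = np.array([subject_multiplier(spec, s) for s in range(spec.n_subjects)])
    for s in range(spec.n_subjects):
        for ci, cond in enumerate(CONDITIONS):
            truth = simulate_truth_cbf(spec, s, cond, labels)
            truth_maps[(s, cond)] = truth
            rng_asl = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, s, ci]))
            series = simulate_asl_series(
                truth, m0, spec.acq, spec.asl_noise_sd, spec.n_asl_frames, rng_asl
            )
            if with_motion:
                rng_mot = np.random.default_rng(np.random.SeedSequence([spec.seed, 2, s, ci]))
                transforms = random_motion(spec, spec.n_asl_frames, rng_mot)
                series = inject_motion(series, transforms)
                motion[(s, cond)] = transforms
            else:
                motion[(s, cond)] = [
                    RigidTransform() for _ in range(spec.n_asl_frames)
                ]
            rng_pet = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, s, ci]))
            scale = float(rng_pet.uniform(0.5, 2.0))
            pet = [
                simulate_pet_image(truth, scale, spec.pet_noise_sd, rng_pet)
                for _ in range(spec.n_pet_repeats)
            ]
            data[(s, cond)] = {"asl": series, "pet": pet}
    truth_bundle = PhantomTruth(
        labels=labels,
        truth_cbf=truth_maps,
        m0=m0,
        injected_motion=motion,
        spec=spec,
        subject_multipliers=mults,
    )
    return truth_bundle, data


# ---------------------------------------------------------------------------
# Noise calibration against the measured COV
# ---------------------------------------------------------------------------


def measured_roi_cov(
    spec: PhantomSpec,
    modality: str,
    noise_sd: float | None = None,
    seed: int | None = None,
    rois: Sequence[str] = NAMED_ROIS,
) -> float:
    """Pipeline-measured repeat-level ROI COV, averaged over named ROIs.

    ASL repeats are single tag/control pairs quantified individually; PET
    repeats are individually normalized injections.  One condition
    (euglycemia) over ``spec.n_subjects`` subjects is used.
    """
    if modality not in ("asl", "pet"):
        raise ValueError("modality must be 'asl' or 'pet'")
    if noise_sd is None:
        noise_sd = spec.asl_noise_sd if modality == "asl" else spec.pet_noise_sd
    if seed is None:
        seed = spec.seed
    labels = make_roi_labels(spec)
    m0 = make_m0(spec, labels)
    brain = labels > 0
    roi_set = {name: ROI_LABELS[name] for name in rois}
    frames = []
    for s in range(spec.n_subjects):
        truth = simulate_truth_cbf(spec, s, "eu", labels)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4, s]))
        if modality == "asl":
            series = simulate_asl_series(
                truth, m0, spec.acq, noise_sd, spec.n_asl_frames, rng
            )
            repeat_maps = per_pair_cbf(series)
        else:
            scale = float(rng.uniform(0.5, 2.0))
            repeat_maps = [
                pet_proc.normalize_global(
                    simulate_pet_image(truth, scale, noise_sd, rng), brain
                )
                for _ in range(spec.n_pet_repeats)
            ]
        for rep_idx, cbf_map in enumerate(repeat_maps):
            try:
                tab = roi_stats.roi_means(cbf_map, labels, roi_set)
            except ValueError:
                # An ROI with no physiologically mappable voxel in a repeat
                # means the noise level is beyond anything calibratable.
                return float("inf")
            tab["subject_id"] = s
            tab["repeat_index"] = rep_idx
            frames.append(tab)
    full = pd.concat(frames, ignore_index=True)
    covs = []
    for name in rois:
        sub = full[full["roi_name"] == name]
        covs.append(roi_stats.cov(sub, roi_name=name, modality=modality).cov)
    return float(np.mean(covs))


def calibrate_noise(
    spec: PhantomSpec,
    modality: str,
    target_cov: float,
    seed: int | None = None,
    max_iter: int = 40,
    rel_tol: float = 0.02,
) -> float:
    """Bisect the modality noise SD until the measured ROI COV hits target.

    The measured COV uses a fixed random substream per evaluation, making
    the objective deterministic and monotone in ``noise_sd``; the returned
    value reproduces the target within ``rel_tol`` relative (and always
    within the +/-25% band the calibration contract promises).
    """
    if target_cov <= 0:
        raise ValueError("target_cov must be positive")
    if modality == "asl":
        lo, hi = 1e-5, 0.05
    elif modality == "pet":
        lo, hi = 1e-3, 2.0
    else:
        raise ValueError("modality must be 'asl' or 'pet'")
    f_lo = measured_roi_cov(spec, modality, lo, seed)
    f_hi = measured_roi_cov(spec, modality, hi, seed)
    if not (f_lo < target_cov < f_hi):
        raise ValueError(
            f"target COV {target_cov} not bracketed: measured COV is "
            f"{f_lo:.4f} at noise_sd={lo} and {f_hi:.4f} at noise_sd={hi}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = measured_roi_cov(spec, modality, mid, seed)
        if abs(f_mid - target_cov) <= rel_tol * target_cov:
            return mid
        if f_mid < target_cov:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)
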