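"""End-to-end orchestration: simulate/load -> quantify -> normalize -> compare.

Two entry layers are provided.  The in-memory layer (:func:`analyze_cohort`,
:func:`cohort_summary`) drives simulated cohorts and is what the power and
calibration studies run on.  The file-based layer (:func:`run_pipeline`)
consumes a :class:`StudyDesign` pointing at NIfTI/TSV inputs on disk,
writes result tables and a provenance manifest, and backs the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from . import pet_proc, roi_stats, synthetic
from .asl_quant import AcqParams, CbfMap, quantify_series
from .registration import motion_correct
from .synthetic import CONDITIONS, NAMED_ROIS, ROI_LABELS, PhantomSpec, PhantomTruth


# ---------------------------------------------------------------------------
# In-memory cohort analysis
# ---------------------------------------------------------------------------


def condition_maps(
    truth: PhantomTruth,
    data: dict,
    modality: str,
    with_moco: bool = False,
) -> dict[tuple[int, str], CbfMap]:
    """Per subject/condition CBF maps for one modality.

    ASL: pooled quantification over all pairs (after optional motion
    correction).  PET: repeats averaged, then globally normalized to
    50 mL/100 g/min over the brain mask.
    """
    brain = truth.labels > 0
    out: dict[tuple[int, str], CbfMap] = {}
    for key, bundle in data.items():
        if modality == "asl":
            series = bundle["asl"]
            if with_moco:
                series, _ = motion_correct(series)
            out[key] = quantify_series(series)
        elif modality == "pet":
            cond = pet_proc.PetCondition(repeats=bundle["pet"], mask=brain, condition=key[1])
            out[key] = pet_proc.process_condition(cond)
        else:
            raise ValueError(f"unknown modality {modality!r}")
    return out


def analyze_cohort(
    truth: PhantomTruth,
    data: dict,
    modalities: tuple[str, ...] = ("pet", "asl"),
    rois: tuple[str, ...] = NAMED_ROIS,
    alpha: float = 0.05,
    with_moco: bool = False,
) -> dict:
    """ROI means, paired tests and a significance summary for a cohort."""
    spec = truth.spec
    roi_set = {name: ROI_LABELS[name] for name in rois}
    mean_rows = []
    tests = []
    for modality in modalities:
        maps = condition_maps(truth, data, modality, with_moco=with_moco)
        table = {}
        for (s, cond), cbf_map in maps.items():
            tab = roi_stats.roi_means(cbf_map, truth.labels, roi_set)
            tab["subject_id"], tab["modality"], tab["condition"] = s, modality, cond
            mean_rows.append(tab)
            for _, row in tab.iterrows():
                table[(s, cond, row["roi_name"])] = row["mean_cbf"]
        for name in rois:
            eu = [table[(s, "eu", name)] for s in range(spec.n_subjects)]
            hypo = [table[(s, "hypo", name)] for s in range(spec.n_subjects)]
            tests.append(roi_stats.paired_ttest(eu, hypo, roi_name=name, modality=modality))
    summary = roi_stats.roi_significance_summary(tests, alpha=alpha)
    return {
        "roi_means": pd.concat(mean_rows, ignore_index=True),
        "paired_tests": tests,
        "summary": summary,
    }


def cohort_summary(spec: PhantomSpec, seed: int | None = None, **kwargs) -> pd.DataFrame:
    """Simulate one cohort at the given seed and return its summary table."""
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    truth, data = synthetic.simulate_cohort(spec)
    return analyze_cohort(truth, data, **kwargs)["summary"]


def detection_rate(
    spec: PhantomSpec,
    n_cohorts: int,
    seed: int,
    rois: tuple[str, ...] = synthetic.RESPONSIVE_ROIS,
) -> float:
    """Fraction of simulated cohorts where every responsive ROI shows a
    significant increase in both modalities."""
    hits = 0
    for c in range(n_cohorts):
        summary = cohort_summary(spec, seed=seed + 1000 + c)
        sub = summary[summary["roi_name"].isin(rois)]
        if bool(sub["significant_increase"].all()):
            hits += 1
    return hits / n_cohorts


def null_rejection_rate(
    spec: PhantomSpec,
    n_cohorts: int,
    seed: int,
    modality: str | None = None,
) -> float:
    """Empirical two-sided rejection rate at alpha=0.05 under a null phantom.

    The phantom's effect fractions are zeroed; rejections are pooled over the
    named ROIs (and over modalities unless one is requested), which are
    independent tests under the null.
    """
    null_spec = dataclasses.replace(
        spec, effect_fraction={name: 0.0 for name in ROI_LABELS}
    )
    rejections = []
    for c in range(n_cohorts):
        summary = cohort_summary(null_spec, seed=seed + 5000 + c)
        if modality is not None:
            summary = summary[summary["modality"] == modality]
        rejections.extend((summary["p_value"] < 0.05).tolist())
    return float(np.mean(rejections))


# ---------------------------------------------------------------------------
# File-based study runs
# ---------------------------------------------------------------------------


@dataclass
class SubjectPaths:
    subject_id: str
    asl: dict[str, str] = field(default_factory=dict)        # condition -> NIfTI path
    aslcontext: dict[str, str] = field(default_factory=dict)  # condition -> TSV path
    pet: dict[str, list[str]] = field(default_factory=dict)   # condition -> repeat paths


@dataclass
class StudyDesign:
    """Paths and parameters of a paired two-condition study on disk."""

    subjects: list[SubjectPaths]
    labels_path: str
    acq_path: str | None = None
    seed: int = 0
    moco: bool = False

    def validate(self) -> None:
        if not self.subjects:
            raise ValueError("study design lists no subjects")
        for subj in self.subjects:
            for cond in CONDITIONS:
                if cond not in subj.asl or cond not in subj.aslcontext:
                    raise ValueError(
                        f"subject {subj.subject_id!r} is missing the ASL series "
                        f"for condition {cond!r} (paired design needs both)"
                    )
                if cond not in subj.pet or not subj.pet[cond]:
                    raise ValueError(
                        f"subject {subj.subject_id!r} is missing PET repeats "
                        f"for condition {cond!r} (paired design needs both)"
                    )
        missing = [
            p
            for subj in self.subjects
            for p in (
                *subj.asl.values(),
                *subj.aslcontext.values(),
                *(q for reps in subj.pet.values() for q in reps),
            )
            if not Path(p).exists()
        ]
        if Path(self.labels_path).exists() is False:
            missing.append(self.labels_path)
        if missing:
            raise FileNotFoundError(f"design references missing files: {missing[:5]}")

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def resolve(p):
            return str((base / p) if not Path(p).is_absolute() else Path(p))

        subjects = []
        for s in raw["subjects"]:
            subjects.append(
                SubjectPaths(
                    subject_id=str(s["id"]),
                    asl={c: resolve(v["asl"]) for c, v in s["conditions"].items()},
                    aslcontext={c: resolve(v["aslcontext"]) for c, v in s["conditions"].items()},
                    pet={c: [resolve(p) for p in v["pet"]] for c, v in s["conditions"].items()},
                )
            )
        return cls(
            subjects=subjects,
            labels_path=resolve(raw["labels"]),
            acq_path=resolve(raw["acq"]) if raw.get("acq") else None,
            seed=int(raw.get("seed", 0)),
            moco=bool(raw.get("moco", False)),
        )


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(design: StudyDesign, out_dir, alpha: float = 0.05) -> dict:
    """Run the full file-based analysis and write tables plus a manifest.

    Deterministic given the design; any per-subject failure aborts with an
    error attributing the stage, subject and condition.
    """
    design.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels, labels_affine = hio.load_labels(design.labels_path)
    acq = hio.load_acq_params(design.acq_path) if design.acq_path else AcqParams()
    brain = labels > 0
    roi_set = {name: ROI_LABELS[name] for name in NAMED_ROIS if np.any(labels == ROI_LABELS[name])}
    if not roi_set:
        raise ValueError("label volume contains none of the named ROIs")

    mean_rows = []
    per_subject: dict[tuple[str, str, str], dict] = {}
    for subj in design.subjects:
        for cond in CONDITIONS:
            stage = f"subject {subj.subject_id!r} condition {cond!r}"
            try:
                series = hio.load_asl_series(subj.asl[cond], subj.aslcontext[cond], acq)
                if design.moco:
                    series, transforms = motion_correct(series)
                    hio.save_transforms(
                        out / f"moco_{subj.subject_id}_{cond}.json", transforms
                    )
                asl_map = quantify_series(series)
                pet_vols = [hio.load_volume(p)[0] for p in subj.pet[cond]]
                pet_map = pet_proc.process_condition(
                    pet_proc.PetCondition(repeats=pet_vols, mask=brain, condition=cond)
                )
            except Exception as exc:  # re-raise with stage attribution
                raise RuntimeError(f"pipeline failed at {stage}: {exc}") from exc
            for modality, cbf_map in (("asl", asl_map), ("pet", pet_map)):
                hio.save_cbf_map(
                    out / f"cbf_{modality}_{subj.subject_id}_{cond}.nii.gz", cbf_map
                )
                tab = roi_stats.roi_means(cbf_map, labels, roi_set)
                tab["subject_id"] = subj.subject_id
                tab["modality"] = modality
                tab["condition"] = cond
                mean_rows.append(tab)
                for _, row in tab.iterrows():
                    per_subject[(subj.subject_id, modality, cond)] = per_subject.get(
                        (subj.subject_id, modality, cond), {}
                    )
                    per_subject[(subj.subject_id, modality, cond)][row["roi_name"]] = row["mean_cbf"]

    means = pd.concat(mean_rows, ignore_index=True)
    means.to_csv(out / "roi_means.tsv", sep="\t", index=False)

    subject_ids = [s.subject_id for s in design.subjects]
    tests = []
    for modality in ("asl", "pet"):
        for name in roi_set:
            eu = [per_subject[(sid, modality, "eu")][name] for sid in subject_ids]
            hypo = [per_subject[(sid, modality, "hypo")][name] for sid in subject_ids]
            tests.append(roi_stats.paired_ttest(eu, hypo, roi_name=name, modality=modality))
    summary = roi_stats.roi_significance_summary(tests, alpha=alpha)
    summary.to_csv(out / "paired_tests.tsv", sep="\t", index=False)

    manifest = {
        "seed": design.seed,
        "alpha": alpha,
        "moco": design.moco,
        "acq": dataclasses.asdict(acq),
        "units": "mL/100 g/min",
        "subjects": subject_ids,
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"roi_means": means, "summary": summary, "manifest": manifest}


def write_phantom_dataset(spec: PhantomSpec, out_dir, with_motion: bool = False) -> StudyDesign:
    """Simulate a cohort and write it as a file-based study (NIfTI + TSV).

    Also writes ``truth.json`` (spec echo, seed, injected transforms) and a
    ``design.yaml`` that :func:`run_pipeline` and the CLI can consume.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, data = synthetic.simulate_cohort(spec, with_motion=with_motion)
    hio.save_labels(out / "labels.nii.gz", truth.labels, spec.affine)
    hio.save_volume(out / "m0.nii.gz", truth.m0, spec.affine, description="M0 scanner units")
    acq_path = out / "acq.yaml"
    acq_path.write_text(yaml.safe_dump(dataclasses.asdict(spec.acq)))
    subjects_yaml = []
    subjects = []
    for s in range(spec.n_subjects):
        sid = f"sub-{s:02d}"
        cond_block = {}
        paths = SubjectPaths(subject_id=sid)
        for cond in CONDITIONS:
            bundle = data[(s, cond)]
            asl_p = out / f"{sid}_{cond}_asl.nii.gz"
            tsv_p = out / f"{sid}_{cond}_aslcontext.tsv"
            hio.save_asl_series(bundle["asl"], asl_p, tsv_p)
            pet_ps = []
            for r, vol in enumerate(bundle["pet"]):
                p = out / f"{sid}_{cond}_pet{r}.nii.gz"
                hio.save_volume(p, vol, spec.affine, description="relative perfusion")
                pet_ps.append(p)
            hio.save_volume(
                out / f"{sid}_{cond}_truth_cbf.nii.gz",
                truth.truth_cbf[(s, cond)].cbf,
                spec.affine,
                description="truth CBF mL/100g/min",
            )
            paths.asl[cond] = str(asl_p)
            paths.aslcontext[cond] = str(tsv_p)
            paths.pet[cond] = [str(p) for p in pet_ps]
            cond_block[cond] = {
                "asl": asl_p.name,
                "aslcontext": tsv_p.name,
                "pet": [p.name for p in pet_ps],
            }
        subjects.append(paths)
        subjects_yaml.append({"id": sid, "conditions": cond_block})
    design = StudyDesign(
        subjects=subjects,
        labels_path=str(out / "labels.nii.gz"),
        acq_path=str(acq_path),
        seed=spec.seed,
        moco=with_motion,
    )
    (out / "design.yaml").write_text(
        yaml.safe_dump(
            {
                "subjects": subjects_yaml,
                "labels": "labels.nii.gz",
                "acq": "acq.yaml",
                "seed": spec.seed,
                "moco": with_motion,
            }
        )
    )
    truth_manifest = {
        "spec": _spec_to_jsonable(spec),
        "seed": spec.seed,
        "subject_multipliers": truth.subject_multipliers.tolist(),
        "injected_motion": {
            f"{s}_{cond}": [t.as_dict() for t in transforms]
            for (s, cond), transforms in truth.injected_motion.items()
        }
        if with_motion
        else {},
    }
    (out / "truth.json").write_text(json.dumps(truth_manifest, indent=2))
    return design


def _spec_to_jsonable(spec: PhantomSpec) -> dict:
    raw = dataclasses.asdict(spec)
    raw["roi_geometry"] = {
        name: {"center_vox": list(g.center_vox), "radius_vox": g.radius_vox}
        for name, g in spec.roi_geometry.items()
    }
    raw["baseline_cbf"] = dict(spec.baseline_cbf)
    raw["effect_fraction"] = dict(spec.effect_fraction)
    return raw
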