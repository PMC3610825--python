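"""File-format plumbing: NIfTI-1 volumes, aslcontext TSV sidecars, configs.

The frame-label sidecar follows the BIDS aslcontext dialect: one row per
frame with ``volume_type`` of ``label`` (tagged) or ``control``.  In-memory
frame labels use ``tag``/``control``; the mapping happens only here.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .asl_quant import AcqParams, AslSeries, CbfMap
from .registration import RigidTransform

_SIDECAR_TO_FRAME = {"label": "tag", "control": "control"}
_FRAME_TO_SIDECAR = {"tag": "label", "control": "control"}


def save_volume(path, data, affine=None, description: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine if affine is not None else np.eye(4))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def save_labels(path, labels, affine=None) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


def load_labels(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(np.int16), np.asarray(img.affine)


def save_cbf_map(path, cbf_map: CbfMap, mask_path=None) -> None:
    save_volume(path, cbf_map.cbf, cbf_map.affine, description="CBF mL/100g/min")
    if mask_path is not None:
        save_volume(mask_path, cbf_map.valid_mask.astype(np.float64), cbf_map.affine,
                    description="validity mask")


def load_cbf_map(path, mask_path=None) -> CbfMap:
    data, affine = load_volume(path)
    if mask_path is not None:
        mask, _ = load_volume(mask_path)
        valid = mask > 0.5
    else:
        valid = np.ones(data.shape, dtype=bool)
    return CbfMap(cbf=data, valid_mask=valid, affine=affine)


def write_aslcontext(path, frame_labels) -> None:
    df = pd.DataFrame(
        {
            "frame_index": np.arange(len(frame_labels)),
            "volume_type": [_FRAME_TO_SIDECAR[lab] for lab in frame_labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_aslcontext(path) -> tuple[str, ...]:
    df = pd.read_csv(path, sep="\t")
    if "volume_type" not in df.columns:
        raise ValueError(f"{path}: aslcontext sidecar needs a volume_type column")
    bad = set(df["volume_type"]) - set(_SIDECAR_TO_FRAME)
    if bad:
        raise ValueError(f"{path}: unknown volume_type values {sorted(bad)}")
    if "frame_index" in df.columns:
        df = df.sort_values("frame_index")
    return tuple(_SIDECAR_TO_FRAME[v] for v in df["volume_type"])


def save_asl_series(series: AslSeries, nii_path, sidecar_path) -> None:
    img = nib.Nifti1Image(series.data, series.affine)
    nib.save(img, str(nii_path))
    write_aslcontext(sidecar_path, series.frame_labels)


def load_asl_series(nii_path, sidecar_path, acq: AcqParams | None = None) -> AslSeries:
    data, affine = load_volume(nii_path)
    labels = read_aslcontext(sidecar_path)
    return AslSeries(data=data, frame_labels=labels, acq=acq or AcqParams(), affine=affine)


_ACQ_KEY_MAP = {"lambda": "lam"}


def load_acq_params(path) -> AcqParams:
    """Acquisition parameters from a YAML or JSON config file.

    Recognized keys: ti1, ti2, alpha, lambda (or lam), t1a, tag_order, tr, te.
    """
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of acquisition parameters")
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(AcqParams)}
    for key, value in raw.items():
        key = _ACQ_KEY_MAP.get(key, key)
        if key not in valid:
            raise ValueError(f"{path}: unknown acquisition parameter {key!r}")
        kwargs[key] = value
    return AcqParams(**kwargs)


def save_transforms(path, transforms: list[RigidTransform]) -> None:
    Path(path).write_text(json.dumps([t.as_dict() for t in transforms], indent=2))


def load_transforms(path) -> list[RigidTransform]:
    return [RigidTransform.from_dict(d) for d in json.loads(Path(path).read_text())]
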