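"""NIfTI / YAML / CSV interchange helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .aif import AIFModelParams, ArterialCurve
from .signal_model import AcquisitionParams

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_aif_params",
    "load_aif_params",
    "load_acquisition",
    "load_arterial_curve_csv",
    "save_arterial_curve_csv",
]


def save_nifti(data, path, affine=None):
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_aif_params(params_by_site: dict, path):
    """Write fitted AIF parameters as YAML, keyed by site."""
    doc = {site: p.as_dict() for site, p in params_by_site.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_aif_params(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    return {site: AIFModelParams(**d) for site, d in doc.items()}


def load_acquisition(path) -> AcquisitionParams:
    doc = yaml.safe_load(Path(path).read_text())
    if "flip_angles" in doc:
        doc["flip_angles"] = tuple(doc["flip_angles"])
    return AcquisitionParams(**doc)


def load_arterial_curve_csv(path, site="pulmonary") -> ArterialCurve:
    """Read a (time_min, conc_mM) CSV into an ArterialCurve."""
    df = pd.read_csv(path)
    return ArterialCurve(times=df["time_min"].to_numpy(),
                        conc_blood=df["conc_mM"].to_numpy(), site=site)


def save_arterial_curve_csv(curve: ArterialCurve, path):
    pd.DataFrame({"time_min": curve.times, "conc_mM": curve.conc_blood}).to_csv(
        path, index=False)
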