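"""Readers/writers for the standard on-disk formats.

Surfaces go to GIFTI ``.surf.gii``, per-vertex scalars to ``.func.gii``,
winner maps to ``.label.gii`` with a fixed label table, and all tabular
results to UTF-8 tab-separated files with a header row.
"""

from __future__ import annotations

import os
from typing import Mapping, Tuple

import numpy as np
import pandas as pd
import nibabel as nib
from nibabel import gifti

from .synthetic import SurfaceMesh
from .topography import UNASSIGNED, WinnerMap

# fixed label table for winner maps
WINNER_LABELS: Mapping[int, str] = {0: "unassigned", 1: "forehead", 2: "nose",
                                    3: "lips", 4: "tongue"}
_LABEL_RGBA = {0: (0.5, 0.5, 0.5, 1.0), 1: (1.0, 0.0, 0.0, 1.0),
               2: (1.0, 1.0, 0.0, 1.0), 3: (0.0, 0.0, 1.0, 1.0),
               4: (0.0, 1.0, 0.0, 1.0)}


def write_surface_gii(mesh: SurfaceMesh, path: str) -> None:
    img = gifti.GiftiImage(darrays=[
        gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                             intent="NIFTI_INTENT_POINTSET"),
        gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                             intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, path)


def read_surface_gii(path: str) -> SurfaceMesh:
    img = nib.load(path)
    vertices = img.darrays[0].data.astype(float)
    triangles = img.darrays[1].data.astype(int)
    return SurfaceMesh(vertices=vertices, triangles=triangles,
                       axis=vertices[:, 0].copy())


def write_func_gii(values: np.ndarray, path: str) -> None:
    img = gifti.GiftiImage(darrays=[
        gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                             intent="NIFTI_INTENT_NONE")])
    nib.save(img, path)


def read_func_gii(path: str) -> np.ndarray:
    return nib.load(path).darrays[0].data.astype(float)


def write_label_gii(wmap: WinnerMap, n_vertices: int, path: str) -> None:
    """Winner map as a GIFTI label file over the full mesh (0 outside ROI)."""
    data = np.zeros(n_vertices, dtype=np.int32)
    for i, cond in enumerate(wmap.conditions):
        code = [k for k, v in WINNER_LABELS.items() if v == cond]
        if code:
            data[wmap.roi[wmap.labels == i]] = code[0]
    table = gifti.GiftiLabelTable()
    for key, name in WINNER_LABELS.items():
        lab = gifti.GiftiLabel(key, *_LABEL_RGBA[key])
        lab.label = name
        table.labels.append(lab)
    img = gifti.GiftiImage(labeltable=table, darrays=[
        gifti.GiftiDataArray(data, intent="NIFTI_INTENT_LABEL",
                             datatype="NIFTI_TYPE_INT32")])
    nib.save(img, path)


def write_run_nifti(run, path: str) -> None:
    """Run data as a vertices x 1 x 1 x time NIfTI image (TR in the header)."""
    data = run.data.astype(np.float32)[:, None, None, :]
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    nib.save(img, path)


def read_run_nifti(path: str) -> Tuple[np.ndarray, float]:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(float)[:, 0, 0, :]
    return data, float(img.header.get_zooms()[3])


def write_tsv(df: pd.DataFrame, path: str, float_decimals: int = 6) -> None:
    """Deterministic TSV output: fixed float formatting, no index."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    df.to_csv(path, sep="\t", index=False,
              float_format=f"%.{float_decimals}g", encoding="utf-8")


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")
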