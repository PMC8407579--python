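"""Reading and writing the pipeline's on-disk formats.

Delimited tables (TSV) for RDMs and activation matrices, NIfTI for volumes
and masks, YAML for configuration, JSON for reports.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .rdm import RDM, ActivationMatrix
from .searchlight import VolumeGrid

__all__ = [
    "read_rdm_tsv",
    "write_rdm_tsv",
    "read_activation_tsv",
    "write_activation_tsv",
    "read_volume_nifti",
    "write_volume_nifti",
    "write_mask_nifti",
    "read_yaml",
    "write_yaml",
    "write_json",
]

#: reader tolerance for RDM symmetry / zero diagonal
_READ_ATOL = 1e-9


def write_rdm_tsv(rdm: RDM, path: str | Path) -> None:
    """Square TSV with condition ids as header row and index column."""
    df = pd.DataFrame(rdm.values, index=rdm.condition_ids, columns=rdm.condition_ids)
    df.to_csv(path, sep="\t", index_label="condition_id")


def read_rdm_tsv(path: str | Path) -> RDM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != ids:
        raise ValueError(f"{path}: row and column condition ids differ")
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=_READ_ATOL, rtol=0.0):
        raise ValueError(f"{path}: matrix is not symmetric within {_READ_ATOL}")
    if not np.allclose(np.diag(values), 0.0, atol=_READ_ATOL):
        raise ValueError(f"{path}: diagonal is not zero within {_READ_ATOL}")
    return RDM(values, ids)


def write_activation_tsv(acts: ActivationMatrix, path: str | Path) -> None:
    """Feature x condition TSV; the header row carries the condition ids."""
    df = pd.DataFrame(
        acts.values.T,
        index=[f"f{i}" for i in range(acts.n_features)],
        columns=acts.condition_ids,
    )
    df.to_csv(path, sep="\t", index_label="feature")


def read_activation_tsv(path: str | Path, source_tag: str = "") -> ActivationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(c) for c in df.columns)
    return ActivationMatrix(
        df.to_numpy(dtype=float).T, ids, source_tag=source_tag or str(path)
    )


def write_volume_nifti(volume: VolumeGrid, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.responses.astype(np.float32), volume.affine), str(path))


def write_mask_nifti(
    mask: np.ndarray, affine: np.ndarray, path: str | Path
) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(mask).astype(np.uint8), np.asarray(affine)),
        str(path),
    )


def write_map_nifti(values: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(values, dtype=np.float32), np.asarray(affine)),
        str(path),
    )


def read_volume_nifti(
    path: str | Path,
    mask_path: str | Path,
    condition_ids: Sequence[str],
    subject_id: str = "",
) -> VolumeGrid:
    img = nib.load(str(path))
    mask = nib.load(str(mask_path))
    return VolumeGrid(
        responses=np.asarray(img.dataobj, dtype=float),
        mask=np.asarray(mask.dataobj) > 0,
        affine=img.affine,
        condition_ids=tuple(condition_ids),
        subject_id=subject_id,
    )


def read_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def write_yaml(data: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(data: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
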