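"""NIfTI, gradient-table and table I/O.

All volume I/O goes through nibabel; affines are preserved verbatim and
label volumes round-trip integer-exact.  Gradient tables use the FSL
dialect: ``bvecs`` as three whitespace-separated rows (x, y, z), ``bvals``
as one row, one column per volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme
from .errors import SchemeError
from .phantom import PhantomCohort
from .tensor import ScalarMaps, tensors_to_components

__all__ = [
    "save_volume",
    "load_volume",
    "load_labels",
    "save_labels",
    "write_gradient_table",
    "read_gradient_table",
    "scheme_from_gradient_table",
    "write_cohort",
    "load_scalar_maps",
    "save_scalar_maps",
]


def _default_affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def save_volume(
    path: str | Path,
    data: np.ndarray,
    affine: np.ndarray | None = None,
    voxel_size: float = 1.0,
) -> Path:
    path = Path(path)
    aff = affine if affine is not None else _default_affine(voxel_size)
    nib.save(nib.Nifti1Image(np.asarray(data), aff), str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_labels(
    path: str | Path,
    labels: np.ndarray,
    affine: np.ndarray | None = None,
    voxel_size: float = 1.0,
) -> Path:
    return save_volume(
        path, np.asarray(labels, dtype=np.int32), affine, voxel_size
    )


def load_labels(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.array_equal(data, np.round(data)):
            raise ValueError(
                f"{path}: label volume has non-integer values; re-save the "
                "atlas with an integer datatype (e.g. int16/int32)"
            )
        data = np.round(data).astype(np.int32)
    return data.astype(np.int32), img.affine


def write_gradient_table(
    prefix: str | Path, scheme: AcquisitionScheme
) -> tuple[Path, Path]:
    """Write ``<prefix>.bvec`` / ``<prefix>.bval`` (FSL row layout)."""
    prefix = Path(prefix)
    bvec_path = prefix.with_suffix(".bvec")
    bval_path = prefix.with_suffix(".bval")
    np.savetxt(bvec_path, scheme.bvecs(), fmt="%.8f")
    np.savetxt(bval_path, scheme.bvals()[None, :], fmt="%g")
    return bvec_path, bval_path


def read_gradient_table(
    bvec_path: str | Path, bval_path: str | Path
) -> tuple[np.ndarray, np.ndarray]:
    bvecs = np.loadtxt(bvec_path)
    bvals = np.atleast_1d(np.loadtxt(bval_path))
    if bvecs.shape[0] != 3:
        raise SchemeError(f"{bvec_path}: expected 3 rows, got {bvecs.shape[0]}")
    if bvecs.shape[1] != bvals.size:
        raise SchemeError(
            f"bvec/bval mismatch: {bvecs.shape[1]} directions vs "
            f"{bvals.size} b-values"
        )
    return bvecs, bvals


def scheme_from_gradient_table(
    bvec_path: str | Path, bval_path: str | Path
) -> AcquisitionScheme:
    """Build a single-shell scheme from FSL files (B0 volumes first)."""
    bvecs, bvals = read_gradient_table(bvec_path, bval_path)
    b0 = bvals == 0
    nonzero = np.unique(bvals[~b0])
    if nonzero.size != 1:
        raise SchemeError(
            f"expected a single non-zero shell, found b-values {nonzero}"
        )
    if not b0[: int(b0.sum())].all():
        raise SchemeError("B0 volumes must precede diffusion-weighted volumes")
    return AcquisitionScheme(
        b_value=float(nonzero[0]),
        directions=bvecs[:, ~b0].T,
        n_b0=int(b0.sum()),
    )


def write_cohort(cohort: PhantomCohort, out_dir: str | Path) -> list[Path]:
    """Per-subject NIfTI volumes plus one shared gradient table.

    Writes ``sub-XXX_dwi.nii.gz``, ``sub-XXX_labels.nii.gz`` and the ground
    truth ``sub-XXX_tensor.nii.gz`` in 6-component symmetric storage
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _default_affine(cohort.voxel_size)
    written: list[Path] = []
    for i, sub in enumerate(cohort.subjects):
        stem = f"sub-{i:03d}"
        written.append(save_volume(out_dir / f"{stem}_dwi.nii.gz", sub.dwi, aff))
        written.append(save_labels(out_dir / f"{stem}_labels.nii.gz", sub.labels, aff))
        written.append(
            save_volume(
                out_dir / f"{stem}_tensor.nii.gz",
                tensors_to_components(sub.tensors),
                aff,
            )
        )
    written.extend(write_gradient_table(out_dir / "cohort", cohort.scheme))
    return written


_SCALAR_NAMES = ("fa", "trace", "ad", "rd")


def save_scalar_maps(
    out_dir: str | Path, stem: str, scalars: ScalarMaps
) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = (
        scalars.affine
        if scalars.affine is not None
        else _default_affine(scalars.voxel_size)
    )
    paths = []
    for name in _SCALAR_NAMES:
        paths.append(
            save_volume(out_dir / f"{stem}_{name}.nii.gz", getattr(scalars, name), aff)
        )
    paths.append(
        save_volume(
            out_dir / f"{stem}_valid.nii.gz",
            scalars.valid.astype(np.uint8),
            aff,
        )
    )
    return paths


def load_scalar_maps(paths: dict[str, str | Path]) -> ScalarMaps:
    """Assemble ScalarMaps from per-scalar NIfTI paths.

    ``paths`` maps 'fa', 'trace', 'ad', 'rd' (and optionally 'valid') to
    files; all volumes must share shape and affine.
    """
    vols = {}
    affine = None
    for name in _SCALAR_NAMES:
        data, aff = load_volume(paths[name])
        if affine is None:
            affine = aff
            shape = data.shape
        elif data.shape != shape or not np.allclose(aff, affine, atol=1e-6):
            raise ValueError(
                f"scalar map {name!r} is not co-registered with {paths['fa']}"
            )
        vols[name] = data
    if "valid" in paths and paths["valid"] is not None:
        valid, _ = load_volume(paths["valid"])
        valid = valid > 0
    else:
        valid = np.ones(shape, dtype=bool)
    return ScalarMaps(valid=valid, affine=affine, **vols)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(table.to_dict(orient="records"), indent=2))
    else:
        table.to_csv(path, index=False)
    return path
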