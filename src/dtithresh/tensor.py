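"""Diffusion tensor estimation and scalar maps.

The fit is ordinary (unweighted) log-linear least squares of the
monoexponential signal model: for each diffusion-weighted volume i,

    ln(S_i / S0) = −b · g_iᵀ D g_i

is linear in the six unique tensor components, so a single pseudoinverse
solves every voxel.  S0 is the mean of the B0 volumes.  Voxels where S0 or
any S_i is non-positive are marked invalid rather than clamped: a floored
logarithm would silently produce near-zero tensors that pass downstream
FA thresholds as tissue.

Scalars follow the standard definitions: FA (normalised eigenvalue
dispersion), trace (λ1+λ2+λ3), AD (λ1), RD ((λ2+λ3)/2).  Negative
eigenvalues from noisy fits are kept for trace/AD/RD (preserving the
trace-based CSF regime) and clamped to zero for FA only, keeping FA in
[0, 1]; the clamp count is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme
from .errors import SchemeError

__all__ = [
    "TensorVolume",
    "ScalarMaps",
    "design_matrix",
    "fit_tensor",
    "eigendecompose",
    "compute_scalars",
    "scalar_maps_from_tensors",
    "tensors_to_components",
    "components_to_tensors",
]

# component order used throughout: Dxx, Dxy, Dxz, Dyy, Dyz, Dzz
_COMP_IDX = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


@dataclass(frozen=True)
class TensorVolume:
    """Per-voxel symmetric tensors in 6-component storage.

    ``components`` has shape (..., 6) ordered Dxx, Dxy, Dxz, Dyy, Dyz, Dzz
    (mm²/s); ``valid`` marks voxels with a trustworthy fit.
    """

    components: np.ndarray
    valid: np.ndarray
    voxel_size: float = 1.0
    affine: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.components.shape[:-1]

    def as_matrices(self) -> np.ndarray:
        return components_to_tensors(self.components)


@dataclass(frozen=True)
class ScalarMaps:
    """Co-registered FA, trace, AD and RD volumes sharing one validity mask."""

    fa: np.ndarray
    trace: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    valid: np.ndarray
    n_negative_eigenvalues: int = 0
    voxel_size: float = 1.0
    affine: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.fa.shape


def tensors_to_components(tensors: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices → (..., 6) unique components."""
    return np.stack([tensors[..., i, j] for i, j in _COMP_IDX], axis=-1)


def components_to_tensors(components: np.ndarray) -> np.ndarray:
    """(..., 6) unique components → (..., 3, 3) symmetric matrices."""
    out = np.empty(components.shape[:-1] + (3, 3), dtype=components.dtype)
    for k, (i, j) in enumerate(_COMP_IDX):
        out[..., i, j] = components[..., k]
        out[..., j, i] = components[..., k]
    return out


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(n_dirs, 6) matrix B with row_i · d = g_iᵀ D g_i for d in component
    order; off-diagonal entries carry the factor 2."""
    g = scheme.directions
    return np.stack(
        [
            g[:, 0] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            g[:, 1] ** 2,
            2 * g[:, 1] * g[:, 2],
            g[:, 2] ** 2,
        ],
        axis=1,
    )


def fit_tensor(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    voxel_size: float = 1.0,
    affine: np.ndarray | None = None,
) -> TensorVolume:
    """Log-linear OLS tensor fit of a (..., n_volumes) DWI array.

    Requires at least six non-collinear directions and one B0; raises
    :class:`SchemeError` on a rank-deficient design.
    """
    if dwi.shape[-1] != scheme.n_volumes:
        raise SchemeError(
            f"DWI has {dwi.shape[-1]} volumes but scheme describes "
            f"{scheme.n_volumes}"
        )
    if scheme.n_directions < 6:
        raise SchemeError("tensor fit needs at least 6 diffusion directions")
    b_mat = design_matrix(scheme)
    if np.linalg.matrix_rank(b_mat) < 6:
        raise SchemeError("gradient directions are collinear (rank-deficient)")

    s0 = dwi[..., : scheme.n_b0].mean(axis=-1)
    s = dwi[..., scheme.n_b0 :]
    valid = (s0 > 0) & np.all(s > 0, axis=-1)

    y = np.zeros_like(s)
    np.log(
        np.divide(s, s0[..., None], where=valid[..., None], out=np.ones_like(s)),
        where=valid[..., None],
        out=y,
    )
    # D solves B d = −y/b in the least-squares sense, one pinv for all voxels
    pinv = np.linalg.pinv(b_mat)
    components = -np.einsum("ki,...i->...k", pinv, y) / scheme.b_value
    components[~valid] = 0.0
    return TensorVolume(
        components=components, valid=valid, voxel_size=voxel_size, affine=affine
    )


def eigendecompose(tensors: TensorVolume) -> tuple[np.ndarray, np.ndarray, int]:
    """Eigenvalues sorted descending (..., 3), matching eigenvectors
    (..., 3, 3) with vectors in columns, and the count of negative
    eigenvalues on valid voxels (kept, not clamped)."""
    mats = tensors.as_matrices()
    vals, vecs = np.linalg.eigh(mats)  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    n_negative = int((vals[tensors.valid] < 0).sum())
    return vals, vecs, n_negative


def compute_scalars(
    eigenvalues: np.ndarray,
    valid: np.ndarray | None = None,
    n_negative: int | None = None,
    voxel_size: float = 1.0,
    affine: np.ndarray | None = None,
) -> ScalarMaps:
    """Scalar maps from descending eigenvalues (..., 3).

    FA uses eigenvalues clamped at zero (and is defined as 0 for an
    all-zero voxel); trace, AD and RD use the raw values.
    """
    lams = np.asarray(eigenvalues, dtype=float)
    if valid is None:
        valid = np.ones(lams.shape[:-1], dtype=bool)
    if n_negative is None:
        n_negative = int((lams[valid] < 0).sum())

    trace = lams.sum(axis=-1)
    ad = lams[..., 0]
    rd = 0.5 * (lams[..., 1] + lams[..., 2])

    clamped = np.clip(lams, 0.0, None)
    mean = clamped.mean(axis=-1, keepdims=True)
    num = np.sqrt(((clamped - mean) ** 2).sum(axis=-1))
    den = np.sqrt((clamped**2).sum(axis=-1))
    fa = np.zeros_like(num)
    np.divide(num, den, where=den > 0, out=fa)
    fa *= np.sqrt(1.5)
    fa = np.clip(fa, 0.0, 1.0)
    return ScalarMaps(
        fa=fa,
        trace=trace,
        ad=ad,
        rd=rd,
        valid=np.asarray(valid, dtype=bool),
        n_negative_eigenvalues=n_negative,
        voxel_size=voxel_size,
        affine=affine,
    )


def scalar_maps_from_tensors(tensors: TensorVolume) -> ScalarMaps:
    """Eigendecompose and derive the four scalar maps in one step."""
    vals, _, n_neg = eigendecompose(tensors)
    return compute_scalars(
        vals,
        valid=tensors.valid,
        n_negative=n_neg,
        voxel_size=tensors.voxel_size,
        affine=tensors.affine,
    )
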