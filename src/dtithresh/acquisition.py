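"""Diffusion acquisition scheme: b-value, gradient directions, B0 count.

The default scheme mirrors a single-shell neonatal protocol: 25 diffusion
directions at b = 1000 s/mm² plus three B0 (b = 0) images.  The direction
set was generated once by minimising an antipodally-symmetric Coulomb
energy on the sphere (electrostatic repulsion) and is shipped verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme", "DEFAULT_DIRECTIONS", "default_scheme"]

# 25 unit vectors from electrostatic-repulsion optimisation (seeded, one-off).
DEFAULT_DIRECTIONS: np.ndarray = np.array(
    [
        [-0.13196188, 0.99124066, -0.00529240],
        [0.23760288, 0.43925569, -0.86637135],
        [0.79942232, -0.01764323, 0.60051034],
        [-0.00378977, 0.56131777, 0.82759169],
        [-0.86977200, 0.36184530, 0.33550654],
        [0.83244596, 0.41951554, 0.36199509],
        [0.86861673, -0.44038042, 0.22709041],
        [-0.54266745, 0.40754066, 0.73445398],
        [-0.42060763, -0.18840579, -0.88746407],
        [-0.23081512, 0.27073685, -0.93457260],
        [-0.33870344, 0.79755491, 0.49918549],
        [0.08347230, -0.75343884, 0.65219804],
        [0.53321779, 0.84003095, 0.10013388],
        [0.14218990, 0.90496092, 0.40103338],
        [0.47992089, 0.61134181, 0.62923536],
        [0.99747597, 0.01602291, 0.06917339],
        [-0.64314930, 0.75502842, 0.12763645],
        [-0.25760985, -0.91301366, 0.31629610],
        [-0.13267201, 0.10492629, 0.98559049],
        [0.89234026, 0.12715135, -0.43308359],
        [0.58201456, 0.60235330, -0.54628706],
        [0.58357273, -0.46258992, 0.66742298],
        [0.58785112, 0.08449722, -0.80454414],
        [0.46210144, -0.82055087, 0.33639045],
        [-0.84184821, -0.52402368, 0.12919279],
    ]
)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Single-shell DWI scheme.

    Parameters
    ----------
    b_value : float
        Diffusion weighting in s/mm².
    directions : ndarray, shape (n_dirs, 3)
        Unit gradient directions.
    n_b0 : int
        Number of non-diffusion-weighted (b = 0) volumes, acquired first.
    """

    b_value: float = 1000.0
    directions: np.ndarray = field(
        default_factory=lambda: DEFAULT_DIRECTIONS.copy()
    )
    n_b0: int = 3

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3 or dirs.shape[0] == 0:
            raise ValueError("directions must be a non-empty (n, 3) array")
        norms = np.linalg.norm(dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("every gradient direction must have unit norm")
        if self.n_b0 < 1:
            raise ValueError("at least one B0 volume is required")
        if self.b_value < 0:
            raise ValueError("b_value must be non-negative")
        object.__setattr__(self, "directions", dirs)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + self.n_directions

    def bvals(self) -> np.ndarray:
        """Per-volume b-values, B0 volumes first (FSL row convention)."""
        return np.concatenate(
            [np.zeros(self.n_b0), np.full(self.n_directions, self.b_value)]
        )

    def bvecs(self) -> np.ndarray:
        """Per-volume gradient directions as a (3, n_volumes) array."""
        vecs = np.concatenate(
            [np.zeros((self.n_b0, 3)), self.directions], axis=0
        )
        return vecs.T


def default_scheme() -> AcquisitionScheme:
    """25 directions at b = 1000 s/mm² with three B0 images."""
    return AcquisitionScheme()
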