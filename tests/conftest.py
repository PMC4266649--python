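import numpy as np
import pytest

from dtithresh.acquisition import AcquisitionScheme
from dtithresh.phantom import RegionSpec, build_template, sample_subject_tensors


@pytest.fixture(scope="session")
def scheme() -> AcquisitionScheme:
    return AcquisitionScheme()


@pytest.fixture(scope="session")
def small_regions() -> list[RegionSpec]:
    """Three bilateral regions spanning the neonatal FA range."""
    out = []
    specs = [("LOW", 0.15, "crossing", 0.3), ("MID", 0.30, "smoothly-varying", 0.0),
             ("HIGH", 0.50, "uniform-axis", 0.0)]
    for i, (name, fa, mode, xfrac) in enumerate(specs):
        for side, off in (("left", 0), ("right", 10)):
            out.append(
                RegionSpec(
                    name=name,
                    hemisphere=side,
                    label_id=i + 1 + off,
                    target_fa_mean=fa,
                    target_fa_sd_between_subjects=0.02,
                    target_ad_mean=1.6e-3,
                    orientation_mode=mode,
                    crossing_fraction=xfrac,
                )
            )
    return out


@pytest.fixture(scope="session")
def small_template(small_regions) -> np.ndarray:
    return build_template(small_regions, grid_shape=(24, 24, 24))


@pytest.fixture(scope="session")
def small_tensors(small_template, small_regions) -> np.ndarray:
    """Noise-free ground truth with zero between-subject offsets."""
    return sample_subject_tensors(
        small_template, small_regions, subject_effects={}, seed=11
    )
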