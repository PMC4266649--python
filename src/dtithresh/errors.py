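"""Exception types raised across the pipeline."""


class SizingError(ValueError):
    """Grid too small to host the requested region layout."""


class ParameterizationError(ValueError):
    """No positive-eigenvalue tensor exists for the requested FA/AD pair."""


class SimulationError(RuntimeError):
    """Signal simulation encountered an invalid (non-PSD) tensor."""


class SchemeError(ValueError):
    """Acquisition scheme unusable for tensor estimation."""


class GridMismatchError(ValueError):
    """Two volumes expected on the same grid differ in shape or affine."""


class IntegrityError(ValueError):
    """Table-level consistency violation (e.g. duplicate cells)."""
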