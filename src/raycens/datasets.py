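"""Bundled example data."""

from importlib import resources

import numpy as np

__all__ = ["load_strength"]


def load_strength() -> np.ndarray:
    """Carbon-fiber strength measurements (n = 69), treated as complete data.

    Strengths of single carbon fibers / impregnated tows, a classical
    benchmark for threshold lifetime models: the smallest value (0.562) sits
    well above zero, which is what motivates a location parameter.
    """
    with resources.files("raycens").joinpath("data/carbon_fiber_strength.csv").open() as fh:
        return np.loadtxt(fh, skiprows=1)
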