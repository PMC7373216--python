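"""Bundled example data.

The pigeon vanishing-bearing sample is a classic small circular dataset:
the departure directions of 13 homing pigeons, recorded to the nearest
5 degrees (so the sample is grouped with m = 72 and contains tied values).
By eye the bearings cluster around North and South, a bimodal pattern that
defeats the Rayleigh test but not spacing- or pairwise-difference-based
tests.
"""

from __future__ import annotations

from .core import CircularSample, normalize

__all__ = ["PIGEON_BEARINGS_DEG", "pigeon_sample", "PIGEON_REFERENCE_PVALUES"]

#: vanishing bearings of 13 released homing pigeons, degrees from North
PIGEON_BEARINGS_DEG = (20, 135, 145, 165, 170, 200, 300, 325, 335, 350, 350, 350, 355)


def pigeon_sample() -> CircularSample:
    """The 13 pigeon bearings as a grouped sample (5-degree resolution, m=72)."""
    s = normalize(PIGEON_BEARINGS_DEG, units="degrees")
    return CircularSample(s.angles, units_original="degrees", grouping_m=72)


#: reference p-values for this dataset from the circular-statistics
#: literature: {test: (standard, tie_breaking)}; table-bound standard
#: results are given as range strings, chi-squared has no TB version.
PIGEON_REFERENCE_PVALUES = {
    "rayleigh": (0.555, None),
    "watson": ("p > 0.1", 0.138),
    "kuiper": ("p > 0.15", 0.162),
    "rao": ("0.1 > p > 0.05", 0.0685),
    "gini": (0.044, 0.048),
    "hr": (0.0034, 0.0039),
    "chisq": (0.046, None),
}
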