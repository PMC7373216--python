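"""Angle containers, normalization, circular spacings and the grouping operator.

All angles are held internally in radians on [0, 2pi).  Degrees are accepted
only at I/O boundaries (:func:`normalize`, :func:`read_angles`).  Grouped data
— angles restricted to ``m`` evenly spaced values around the circle, as
produced by rounding measurements to the nearest 360/m degrees — carry their
resolution in :attr:`CircularSample.grouping_m`; it is this grouping that
breaks the continuity assumption of most uniformity tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

__all__ = [
    "CircularSample",
    "SpacingSet",
    "normalize",
    "spacings",
    "group",
    "read_angles",
    "write_angles",
]


@dataclass(frozen=True)
class CircularSample:
    """A sample of angles in radians on [0, 2pi), in observation order.

    Parameters
    ----------
    angles
        The observations, radians in [0, 2pi).
    units_original
        ``"degrees"`` or ``"radians"``: the unit the data arrived in.
    grouping_m
        If the angles are restricted to ``m`` evenly spaced values
        (every angle a multiple of 2pi/m), the value of ``m``; ``None``
        for continuously distributed data.
    """

    angles: np.ndarray
    units_original: str = "radians"
    grouping_m: Optional[int] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", a)
        if a.ndim != 1 or a.size == 0:
            raise ValueError("empty sample")
        if np.any(a < 0) or np.any(a >= TWO_PI):
            raise ValueError("angles must lie in [0, 2*pi); use normalize()")

    @property
    def n(self) -> int:
        return int(self.angles.size)

    def sorted(self) -> np.ndarray:
        """Angles sorted ascending (stable; exact ties are legal)."""
        return np.sort(self.angles, kind="stable")

    def has_ties(self) -> bool:
        s = self.sorted()
        return bool(np.any(np.diff(s) == 0.0))

    def rotated(self, delta: float) -> "CircularSample":
        return replace(self, angles=np.mod(self.angles + delta, TWO_PI))


@dataclass(frozen=True)
class SpacingSet:
    """The n arc lengths between circularly adjacent sorted sample points.

    Always sums to 2pi; tied observations produce zero spacings.
    """

    spacings: np.ndarray = field()

    def __post_init__(self) -> None:
        t = np.asarray(self.spacings, dtype=float)
        object.__setattr__(self, "spacings", t)
        if np.any(t < -1e-12) or np.any(t > TWO_PI + 1e-12):
            raise ValueError("spacings must lie in [0, 2*pi]")
        if abs(t.sum() - TWO_PI) > 1e-9:
            raise ValueError("spacings must sum to 2*pi")

    @property
    def n(self) -> int:
        return int(self.spacings.size)


def normalize(
    angles: Sequence[float],
    units: str = "degrees",
) -> CircularSample:
    """Convert raw angles to a :class:`CircularSample` in radians on [0, 2pi).

    Order is preserved; negative angles and angles beyond a full turn are
    reduced modulo the circle.

    Parameters
    ----------
    angles
        At least one finite value.
    units
        ``"degrees"`` (default) or ``"radians"``.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty sample")
    bad = np.flatnonzero(~np.isfinite(a))
    if bad.size:
        raise ValueError(f"non-finite angle at index {bad[0]}")
    if units not in ("degrees", "radians"):
        raise ValueError(f"unknown units {units!r}; expected 'degrees' or 'radians'")
    if units == "degrees":
        a = np.deg2rad(a)
    a = np.mod(a, TWO_PI)
    # mod can return 2*pi for tiny negative inputs via rounding
    a[a >= TWO_PI] = 0.0
    return CircularSample(a, units_original=units)


def spacings(sample: CircularSample) -> SpacingSet:
    """Arc lengths T_i between circularly adjacent points of the sorted sample.

    With sorted angles phi_(1) <= ... <= phi_(n),
    T_i = phi_(i+1) - phi_(i) for i < n and T_n = 2pi - phi_(n) + phi_(1),
    so the n spacings partition the circle and sum to 2pi.
    """
    if sample.n < 2:
        raise ValueError("need at least two points")
    s = sample.sorted()
    t = np.empty(sample.n)
    t[:-1] = np.diff(s)
    t[-1] = TWO_PI - s[-1] + s[0]
    return SpacingSet(t)


def group(sample: CircularSample, m: int) -> CircularSample:
    """Round every angle to the nearest of m evenly spaced values.

    Emulates measurement at finite resolution, e.g. m=36 is rounding to the
    nearest 10 degrees.  Ties at bin midpoints round half-up (toward the
    larger multiple); angles within half a bin below 2pi wrap to 0.
    """
    if m < 2:
        raise ValueError("grouping resolution m must be at least 2")
    w = TWO_PI / m
    k = np.floor(sample.angles / w + 0.5).astype(np.int64) % m
    return CircularSample(k * w, units_original=sample.units_original, grouping_m=int(m))


def group_angles(angles: np.ndarray, m: int) -> np.ndarray:
    """Array version of :func:`group` for (..., n) batches of raw radians."""
    w = TWO_PI / m
    return (np.floor(angles / w + 0.5).astype(np.int64) % m) * w


def read_angles(
    path: Union[str, Path],
    units: str = "degrees",
    column: Optional[str] = None,
) -> CircularSample:
    """Read angles from a plain-text or CSV file.

    Plain text: one angle per line, ``#`` starts a comment.  CSV: the named
    ``column``, or the single/first numeric column when ``column`` is None.
    """
    path = Path(path)
    text = path.read_text()
    looks_csv = path.suffix.lower() == ".csv" or ("," in text.splitlines()[0] if text.strip() else False)
    if looks_csv or column is not None:
        df = pd.read_csv(path, comment="#")
        if column is None:
            num = df.select_dtypes("number")
            if num.shape[1] == 0:
                raise ValueError(f"no numeric column in {path}")
            values = num.iloc[:, 0].to_numpy()
        else:
            if column not in df.columns:
                raise ValueError(f"column {column!r} not found in {path}")
            values = df[column].to_numpy(dtype=float)
    else:
        values = []
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                values.append(float(line))
    return normalize(values, units=units)


def write_angles(
    sample: CircularSample,
    path: Union[str, Path],
    units: str = "degrees",
) -> None:
    """Write angles one per line, mirroring :func:`read_angles`."""
    a = sample.angles
    if units == "degrees":
        a = np.rad2deg(a)
    elif units != "radians":
        raise ValueError(f"unknown units {units!r}")
    Path(path).write_text("".join(f"{x:.12g}\n" for x in a))
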