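"""Double-angle (Jackson power-vector) algebra for astigmatism.

An astigmatism is held either as a positive cylinder ``C`` with the axis of
its *flat* meridian ``A`` (:class:`CylAstig`), or as the Cartesian pair

    J0  = (C/2) * cos(2A)
    J45 = (C/2) * sin(2A)

(:class:`PowerVector`).  J0 carries the 0/90-degree component of the
astigmatism, J45 the 45/135-degree component.  Doubling the angle makes the
180-degree periodicity of meridians an ordinary 360-degree rotation, so
differences between measurements become Euclidean distances in the
(J0, J45) plane.

All public angles are degrees; radians appear only inside the trig calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .errors import UndefinedAxisError

__all__ = [
    "CylAstig",
    "PowerVector",
    "normalize_axis",
    "cyl_to_pv",
    "pv_to_cyl",
    "pv_difference_magnitude",
    "steep_axis",
    "classify_wtr_atr",
]


def normalize_axis(angle: float) -> float:
    """Reduce a meridian angle to the canonical half-open range [0, 180).

    Meridians are 180-degree periodic, so 190 -> 10, -45 -> 135, 180 -> 0.

    Raises
    ------
    ValueError
        If ``angle`` is NaN or infinite.
    """
    angle = float(angle)
    if not math.isfinite(angle):
        raise ValueError(f"axis angle must be finite, got {angle!r}")
    r = angle % 180.0
    if r >= 180.0:  # guard against float rounding of tiny negatives
        r -= 180.0
    return r


@dataclass(frozen=True)
class CylAstig:
    """Astigmatism as a positive cylinder magnitude plus flat-meridian axis.

    Parameters
    ----------
    magnitude : float
        Cylinder power in diopters, >= 0 (positive-cylinder convention).
    axis : float
        Axis of the flat (least-power) meridian in degrees, in [0, 180).
        Stored as 0 when the magnitude is 0, where the axis is meaningless.
    """

    magnitude: float
    axis: float = 0.0

    def __post_init__(self):
        m = float(self.magnitude)
        a = float(self.axis)
        if not math.isfinite(m) or m < 0:
            raise ValueError(f"cylinder magnitude must be finite and >= 0, got {m!r}")
        if not math.isfinite(a) or not (0.0 <= a < 180.0):
            raise ValueError(f"axis must lie in [0, 180), got {a!r}")
        if m == 0.0:
            a = 0.0
        object.__setattr__(self, "magnitude", m)
        object.__setattr__(self, "axis", a)

    @classmethod
    def from_unnormalized(cls, magnitude: float, axis: float) -> "CylAstig":
        """Build a :class:`CylAstig`, folding the axis into [0, 180) first."""
        return cls(magnitude, normalize_axis(axis))


@dataclass(frozen=True)
class PowerVector:
    """Astigmatism in double-angle Cartesian form (J0, J45), diopters."""

    j0: float
    j45: float

    def __post_init__(self):
        if not (math.isfinite(self.j0) and math.isfinite(self.j45)):
            raise ValueError(f"power-vector components must be finite: {self!r}")
        object.__setattr__(self, "j0", float(self.j0))
        object.__setattr__(self, "j45", float(self.j45))

    @property
    def magnitude(self) -> float:
        """Euclidean length sqrt(J0^2 + J45^2), in diopters."""
        return math.hypot(self.j0, self.j45)

    @property
    def cylinder_magnitude(self) -> float:
        """Cylinder recoverable from this vector: 2 * magnitude."""
        return 2.0 * self.magnitude

    def __add__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.j0 + other.j0, self.j45 + other.j45)

    def __sub__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.j0 - other.j0, self.j45 - other.j45)

    def __mul__(self, k: float) -> "PowerVector":
        return PowerVector(self.j0 * k, self.j45 * k)

    __rmul__ = __mul__

    def __neg__(self) -> "PowerVector":
        return PowerVector(-self.j0, -self.j45)


def cyl_to_pv(c: CylAstig) -> PowerVector:
    """Decompose a cylinder into Jackson coefficients.

    J0 = (C/2) cos(2A), J45 = (C/2) sin(2A) with A the flat meridian in
    degrees.  A 0.40 D cylinder flat at 0 degrees maps to (0.20, 0).
    """
    half = 0.5 * c.magnitude
    two_a = math.radians(2.0 * c.axis)
    return PowerVector(half * math.cos(two_a), half * math.sin(two_a))


def pv_to_cyl(pv: PowerVector) -> CylAstig:
    """Invert :func:`cyl_to_pv`.

    C = 2 sqrt(J0^2 + J45^2); A = half the double angle of (J0, J45),
    folded into [0, 180).  The zero vector maps to (C=0, A=0) by the
    package's zero-cylinder convention.
    """
    c = pv.cylinder_magnitude
    if c == 0.0:
        return CylAstig(0.0, 0.0)
    a = 0.5 * math.degrees(math.atan2(pv.j45, pv.j0))
    return CylAstig(c, normalize_axis(a))


def pv_difference_magnitude(a: PowerVector, b: PowerVector) -> float:
    """Euclidean distance between two power vectors, in diopters.

    sqrt((J0a - J0b)^2 + (J45a - J45b)^2): the root of the sum of squared
    J0 and J45 differences.  This is the per-eye discrepancy metric used
    both for inter-device deltas and for ocular residual astigmatism.
    Note it is *half* the cylinder that would express the same difference;
    callers wanting cylinder units double it (``as_cylinder`` options
    downstream).
    """
    return math.hypot(a.j0 - b.j0, a.j45 - b.j45)


def steep_axis(c: CylAstig) -> float:
    """Axis of the steep (most-power) meridian: the stored flat axis + 90.

    Raises
    ------
    UndefinedAxisError
        For zero-cylinder input, whose meridians are indistinct.
    """
    if c.magnitude == 0.0:
        raise UndefinedAxisError("steep axis undefined for zero cylinder")
    return normalize_axis(c.axis + 90.0)


def classify_wtr_atr(c: CylAstig) -> Literal["WTR", "ATR"]:
    """Label astigmatism with-the-rule or against-the-rule.

    WTR when the steep meridian lies in the closed band [45, 135] degrees
    (steep axis near vertical), ATR otherwise.  Zero-cylinder eyes cannot
    be classified and raise :class:`UndefinedAxisError`; callers exclude
    them from axis-classified tables.
    """
    s = steep_axis(c)
    return "WTR" if 45.0 <= s <= 135.0 else "ATR"
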