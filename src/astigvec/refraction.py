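"""Manifest refraction handling: vertex-distance transport, surgically
induced astigmatism (SIA) modeling, and ocular residual astigmatism (ORA).

A spectacle-plane refraction measured at vertex distance ``d`` metres is
moved to the corneal plane by correcting each principal meridian power F
independently:

    Fc = F / (1 - d * F)

(d = 0.012 m for the conventional 12 mm).  The corneal-plane astigmatism
is then decomposed into Jackson coefficients and compared with a
keratometric measurement; the length of the difference vector is the ORA.

Because individual SIAs are usually unknown retrospectively, the ORA is
computed under a small set of assumed SIA magnitudes (0, 0.20, 0.40 D by
default), giving the refraction variants RA, RA1, RA2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, TYPE_CHECKING

from .errors import MissingFieldError, SingularConversionError
from .powervec import CylAstig, PowerVector, cyl_to_pv, normalize_axis, pv_difference_magnitude

if TYPE_CHECKING:  # pragma: no cover
    from .records import EyeRecord

__all__ = [
    "SpheroCylinder",
    "SiaSpec",
    "OraSet",
    "KERATOMETRY_SOURCES",
    "RA_VARIANTS",
    "vertex_correct_power",
    "inverse_vertex_correct_power",
    "refraction_to_corneal_plane",
    "sia_flattening_vector",
    "adjust_ra_for_sia",
    "compute_ora",
    "compute_ora_set",
]

Notation = Literal["positive", "negative"]

#: Keratometry sources an OraSet covers: automated keratometry and total
#: corneal refractive power over 3- and 4-mm pupil-centred zones.
KERATOMETRY_SOURCES = ("AK", "TCRP3", "TCRP4")
#: Refraction variants by assumed SIA magnitude (0, 0.20, 0.40 D defaults).
RA_VARIANTS = ("RA", "RA1", "RA2")
DEFAULT_SIA_MAGNITUDES = (0.0, 0.20, 0.40)
DEFAULT_VERTEX_DISTANCE = 0.012  # metres


@dataclass(frozen=True)
class SpheroCylinder:
    """A sphere/cylinder/axis refraction in an explicit cylinder notation.

    The two principal meridian powers are S and S + C regardless of
    notation; transposing between positive- and negative-cylinder forms
    preserves them.  In positive-cylinder form the axis is the flat
    (least-power) meridian, matching :class:`~astigvec.powervec.CylAstig`.
    """

    sphere: float
    cylinder: float
    axis: float = 0.0
    notation: Notation = "negative"

    def __post_init__(self):
        for name in ("sphere", "cylinder", "axis"):
            v = float(getattr(self, name))
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            object.__setattr__(self, name, v)
        if not (0.0 <= self.axis < 180.0):
            raise ValueError(f"axis must lie in [0, 180), got {self.axis!r}")
        if self.notation not in ("positive", "negative"):
            raise ValueError(f"notation must be 'positive' or 'negative', got {self.notation!r}")
        if self.notation == "positive" and self.cylinder < 0:
            raise ValueError("positive-cylinder notation requires cylinder >= 0")
        if self.notation == "negative" and self.cylinder > 0:
            raise ValueError("negative-cylinder notation requires cylinder <= 0")

    def meridian_powers(self) -> tuple[float, float]:
        """Powers of the two principal meridians, (S, S + C)."""
        return self.sphere, self.sphere + self.cylinder

    def transposed(self) -> "SpheroCylinder":
        """The same lens in the opposite cylinder notation."""
        other: Notation = "negative" if self.notation == "positive" else "positive"
        return SpheroCylinder(
            sphere=self.sphere + self.cylinder,
            cylinder=-self.cylinder,
            axis=normalize_axis(self.axis + 90.0) if self.cylinder != 0.0 else self.axis,
            notation=other,
        )

    def to_notation(self, notation: Notation) -> "SpheroCylinder":
        return self if self.notation == notation else self.transposed()

    @property
    def spherical_equivalent(self) -> float:
        return self.sphere + 0.5 * self.cylinder

    def astigmatism(self) -> CylAstig:
        """The cylindrical component as a positive cylinder on its flat axis."""
        pos = self.to_notation("positive")
        return CylAstig(pos.cylinder, pos.axis)


@dataclass(frozen=True)
class SiaSpec:
    """Surgically induced astigmatism of the cataract incision.

    ``incision_axis`` is the meridian the incision flattens; a temporal
    clear corneal incision flattens the horizontal meridian (axis 0).
    """

    magnitude: float
    incision_axis: float = 0.0

    def __post_init__(self):
        if not math.isfinite(self.magnitude) or self.magnitude < 0:
            raise ValueError(f"SIA magnitude must be finite and >= 0, got {self.magnitude!r}")
        if not (0.0 <= self.incision_axis < 180.0):
            raise ValueError(f"incision axis must lie in [0, 180), got {self.incision_axis!r}")


def vertex_correct_power(f: float, vertex_distance: float = DEFAULT_VERTEX_DISTANCE) -> float:
    """Transport a power from the spectacle plane to the corneal plane.

    Fc = F / (1 - d F), with d in metres.  -10 D at 12 mm becomes
    -8.9286 D; +10 D becomes +11.3636 D.

    Raises
    ------
    SingularConversionError
        When d * F == 1, where the conversion has a pole.
    """
    denom = 1.0 - vertex_distance * f
    if denom == 0.0:
        raise SingularConversionError(
            f"vertex conversion singular: 1 - d*F == 0 for F={f}, d={vertex_distance}"
        )
    return f / denom


def inverse_vertex_correct_power(fc: float, vertex_distance: float = DEFAULT_VERTEX_DISTANCE) -> float:
    """Inverse transport, corneal plane back to the spectacle plane."""
    denom = 1.0 + vertex_distance * fc
    if denom == 0.0:
        raise SingularConversionError(
            f"inverse vertex conversion singular for Fc={fc}, d={vertex_distance}"
        )
    return fc / denom


def refraction_to_corneal_plane(
    sc: SpheroCylinder, vertex_distance: float = DEFAULT_VERTEX_DISTANCE
) -> SpheroCylinder:
    """Vertex-correct a refraction meridian by meridian.

    Each principal power (S and S + C) is moved to the corneal plane
    independently; the result is reassembled on the same axis and in the
    same notation.  The single-power formula applies to one meridian at a
    time, so correcting (sphere, cylinder) directly would be wrong for
    nonzero cylinders.
    """
    f1, f2 = sc.meridian_powers()
    g1 = vertex_correct_power(f1, vertex_distance)
    g2 = vertex_correct_power(f2, vertex_distance)
    return SpheroCylinder(sphere=g1, cylinder=g2 - g1, axis=sc.axis, notation=sc.notation)


def sia_flattening_vector(sia: SiaSpec) -> PowerVector:
    """Power vector of the incision's flattening effect.

    The incision removes a cylinder of the SIA magnitude whose flat
    meridian is the incision meridian, so the vector is the Jackson
    decomposition of (magnitude @ incision_axis): a 0.40 D temporal
    incision (axis 0) gives (J0=0.20, J45=0).
    """
    return cyl_to_pv(CylAstig(sia.magnitude, sia.incision_axis))


def adjust_ra_for_sia(
    ra_pv: PowerVector, sia_pv: PowerVector, sign: int = +1
) -> PowerVector:
    """Apply an assumed SIA to a postoperative refractive-astigmatism vector.

    With the default ``sign=+1`` the flattening vector is added back, so
    the adjusted refraction estimates what the total ocular astigmatism
    would have been without the incision — comparable with *pre*operative
    keratometry.  ``sign=-1`` is exposed for sensitivity analysis.
    """
    if sign not in (+1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign!r}")
    return ra_pv + (sia_pv * float(sign))


def compute_ora(
    keratometry_pv: PowerVector,
    ra_adjusted_pv: PowerVector,
    as_cylinder: bool = False,
) -> float:
    """Ocular residual astigmatism between keratometry and refraction.

    The length of the difference vector in (J0, J45); ``as_cylinder``
    doubles it to express the mismatch as a cylinder power.
    """
    d = pv_difference_magnitude(keratometry_pv, ra_adjusted_pv)
    return 2.0 * d if as_cylinder else d


@dataclass(frozen=True)
class OraSet:
    """ORA for every keratometry source x refraction variant combination.

    Nine non-negative values keyed by (source, variant) with sources
    ``AK/TCRP3/TCRP4`` and variants ``RA/RA1/RA2``.
    """

    values: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        expected = {(s, v) for s in KERATOMETRY_SOURCES for v in RA_VARIANTS}
        got = set(self.values)
        if got != expected:
            raise ValueError(f"OraSet must hold exactly the 9 combinations; missing {expected - got}, extra {got - expected}")
        for key, val in self.values.items():
            if not math.isfinite(val) or val < 0:
                raise ValueError(f"ORA for {key} must be finite and >= 0, got {val!r}")
        object.__setattr__(self, "values", dict(self.values))

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.values[key]

    def as_flat_dict(self) -> dict[str, float]:
        """``{"ora_ak_ra": ..., ...}`` keys suitable for table columns."""
        return {
            f"ora_{s.lower()}_{v.lower()}": self.values[(s, v)]
            for s in KERATOMETRY_SOURCES
            for v in RA_VARIANTS
        }


def compute_ora_set(
    eye: "EyeRecord",
    sia_magnitudes: tuple[float, ...] = DEFAULT_SIA_MAGNITUDES,
    vertex_distance: float = DEFAULT_VERTEX_DISTANCE,
    incision_axis: float = 0.0,
    sia_sign: int = +1,
    as_cylinder: bool = False,
) -> OraSet:
    """Full per-eye ORA table.

    The postoperative manifest refraction is moved to the corneal plane,
    decomposed into a power vector, adjusted for each assumed SIA
    magnitude in turn (variants RA, RA1, RA2), and compared with each
    keratometric astigmatism (AK, TCRP3, TCRP4).

    Raises
    ------
    MissingFieldError
        Naming the first absent measurement.
    """
    if len(sia_magnitudes) != len(RA_VARIANTS):
        raise ValueError(
            f"expected {len(RA_VARIANTS)} SIA magnitudes (variants {RA_VARIANTS}), got {len(sia_magnitudes)}"
        )
    for name in ("ak", "tcrp3", "tcrp4", "ra_postop"):
        if getattr(eye, name, None) is None:
            raise MissingFieldError(name, getattr(eye, "eye_id", None))

    ra_corneal = refraction_to_corneal_plane(eye.ra_postop, vertex_distance)
    ra_pv = cyl_to_pv(ra_corneal.astigmatism())
    k_pvs = {
        "AK": cyl_to_pv(eye.ak),
        "TCRP3": cyl_to_pv(eye.tcrp3),
        "TCRP4": cyl_to_pv(eye.tcrp4),
    }

    values: dict[tuple[str, str], float] = {}
    for variant, mag in zip(RA_VARIANTS, sia_magnitudes):
        sia_pv = sia_flattening_vector(SiaSpec(mag, incision_axis))
        adjusted = adjust_ra_for_sia(ra_pv, sia_pv, sign=sia_sign)
        for source, k_pv in k_pvs.items():
            values[(source, variant)] = compute_ora(k_pv, adjusted, as_cylinder=as_cylinder)
    return OraSet(values)
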