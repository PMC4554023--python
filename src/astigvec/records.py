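"""Per-eye measurement record shared by the analysis and I/O layers."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import MissingFieldError
from .powervec import CylAstig
from .refraction import SpheroCylinder

__all__ = ["EyeRecord"]


@dataclass(frozen=True)
class EyeRecord:
    """One eye's full preoperative measurement set plus postoperative refraction.

    Attributes
    ----------
    eye_id : str
        Opaque identifier.
    age : float
        Patient age in years (> 0).
    ak, tcrp3, tcrp4 : CylAstig
        Corneal astigmatism by automated keratometry and by ray-traced
        total corneal refractive power over 3- and 4-mm zones.
    ir : float
        Corneal irregularity index from Fourier analysis, in mm (>= 0).
    irregular_astig : float
        Total corneal irregular astigmatism at the 4-mm zone, in microns.
    anterior_radius, posterior_radius : float
        Mean central corneal curvature radii in mm (> 0).
    ra_postop : SpheroCylinder
        Postoperative manifest refraction at the spectacle plane.
    spherical_aberration : float, optional
        Corneal spherical aberration in microns, if measured.
    """

    eye_id: str
    age: float
    ak: Optional[CylAstig] = None
    tcrp3: Optional[CylAstig] = None
    tcrp4: Optional[CylAstig] = None
    ir: Optional[float] = None
    irregular_astig: Optional[float] = None
    anterior_radius: Optional[float] = None
    posterior_radius: Optional[float] = None
    ra_postop: Optional[SpheroCylinder] = None
    spherical_aberration: Optional[float] = None

    def __post_init__(self):
        if not (math.isfinite(self.age) and self.age > 0):
            raise ValueError(f"age must be finite and > 0, got {self.age!r} (eye {self.eye_id})")
        for name, lower_ok in (
            ("ir", True),
            ("irregular_astig", True),
            ("anterior_radius", False),
            ("posterior_radius", False),
        ):
            v = getattr(self, name)
            if v is None:
                continue
            v = float(v)
            if not math.isfinite(v) or v < 0 or (not lower_ok and v == 0):
                bound = ">= 0" if lower_ok else "> 0"
                raise ValueError(f"{name} must be finite and {bound}, got {v!r} (eye {self.eye_id})")
            object.__setattr__(self, name, v)

    @property
    def ap_ratio(self) -> float:
        """Anterior-to-posterior corneal curvature radius ratio."""
        if self.anterior_radius is None:
            raise MissingFieldError("anterior_radius", self.eye_id)
        if self.posterior_radius is None:
            raise MissingFieldError("posterior_radius", self.eye_id)
        return self.anterior_radius / self.posterior_radius

    def require(self, field: str):
        """Return a field's value, raising :class:`MissingFieldError` if unset."""
        v = getattr(self, field)
        if v is None:
            raise MissingFieldError(field, self.eye_id)
        return v
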