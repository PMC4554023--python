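"""Flat-CSV cohort interchange: one row per eye, explicit notation flags.

The schema keeps magnitudes and axes in separate columns and records the
refraction's cylinder-sign convention in ``ra_notation`` ({pos, neg})
rather than inferring it from the cylinder's sign.  ``sa_um`` (corneal
spherical aberration) is the only optional column.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import CohortReadError, SchemaError
from .powervec import CylAstig
from .records import EyeRecord
from .refraction import SpheroCylinder

__all__ = ["COHORT_COLUMNS", "OPTIONAL_COLUMNS", "read_cohort", "write_cohort"]

COHORT_COLUMNS = [
    "eye_id",
    "age_years",
    "ak_cyl_d",
    "ak_axis_deg",
    "tcrp3_cyl_d",
    "tcrp3_axis_deg",
    "tcrp4_cyl_d",
    "tcrp4_axis_deg",
    "ir_mm",
    "irregular_astig_um",
    "ant_radius_mm",
    "post_radius_mm",
    "ra_sphere_d",
    "ra_cyl_d",
    "ra_axis_deg",
    "ra_notation",
]
OPTIONAL_COLUMNS = ["sa_um"]

_NOTATION_IN = {"pos": "positive", "neg": "negative"}
_NOTATION_OUT = {"positive": "pos", "negative": "neg"}


def _fmt(x: float) -> str:
    return f"{float(x):.6g}"


def write_cohort(cohort: Sequence[EyeRecord], path: str | Path) -> None:
    """Write a cohort as a schema-conformant CSV (6 significant digits).

    Validates finiteness of every numeric field before touching the file;
    an empty cohort produces a header-only file.
    """
    rows = []
    for eye in cohort:
        ak = eye.require("ak")
        tcrp3 = eye.require("tcrp3")
        tcrp4 = eye.require("tcrp4")
        ra = eye.require("ra_postop")
        numeric = {
            "age_years": eye.age,
            "ak_cyl_d": ak.magnitude,
            "ak_axis_deg": ak.axis,
            "tcrp3_cyl_d": tcrp3.magnitude,
            "tcrp3_axis_deg": tcrp3.axis,
            "tcrp4_cyl_d": tcrp4.magnitude,
            "tcrp4_axis_deg": tcrp4.axis,
            "ir_mm": eye.require("ir"),
            "irregular_astig_um": eye.require("irregular_astig"),
            "ant_radius_mm": eye.require("anterior_radius"),
            "post_radius_mm": eye.require("posterior_radius"),
            "ra_sphere_d": ra.sphere,
            "ra_cyl_d": ra.cylinder,
            "ra_axis_deg": ra.axis,
        }
        for name, v in numeric.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite {name}={v!r} in eye {eye.eye_id}")
        row = {"eye_id": eye.eye_id}
        row.update({k: _fmt(v) for k, v in numeric.items()})
        row["ra_notation"] = _NOTATION_OUT[ra.notation]
        row["sa_um"] = (
            _fmt(eye.spherical_aberration) if eye.spherical_aberration is not None else ""
        )
        rows.append(row)
    columns = COHORT_COLUMNS + OPTIONAL_COLUMNS
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, encoding="utf-8")


def read_cohort(path: str | Path) -> list[EyeRecord]:
    """Read a cohort CSV, validating every row.

    Raises
    ------
    SchemaError
        When required columns are missing or misnamed.
    CohortReadError
        Collecting every invalid row with its line number and eye id.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing required column(s): {missing}")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        raise SchemaError(f"cohort CSV has unknown column(s): {unknown}")

    cohort: list[EyeRecord] = []
    errors: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        eye_id = str(row["eye_id"])
        try:
            cohort.append(_parse_row(row, eye_id))
        except (ValueError, KeyError) as err:
            errors.append((line, eye_id, str(err)))
    if errors:
        raise CohortReadError(errors)
    return cohort


def _parse_row(row, eye_id: str) -> EyeRecord:
    def num(col: str) -> float:
        raw = str(row[col]).strip()
        if raw == "":
            raise ValueError(f"empty value in column '{col}'")
        try:
            return float(raw)
        except ValueError:
            raise ValueError(f"unparsable value {raw!r} in column '{col}'") from None

    notation_raw = str(row["ra_notation"]).strip()
    if notation_raw not in _NOTATION_IN:
        raise ValueError(f"ra_notation must be 'pos' or 'neg', got {notation_raw!r}")
    sa_raw = str(row.get("sa_um", "")).strip()
    return EyeRecord(
        eye_id=eye_id,
        age=num("age_years"),
        ak=CylAstig(num("ak_cyl_d"), num("ak_axis_deg")),
        tcrp3=CylAstig(num("tcrp3_cyl_d"), num("tcrp3_axis_deg")),
        tcrp4=CylAstig(num("tcrp4_cyl_d"), num("tcrp4_axis_deg")),
        ir=num("ir_mm"),
        irregular_astig=num("irregular_astig_um"),
        anterior_radius=num("ant_radius_mm"),
        posterior_radius=num("post_radius_mm"),
        ra_postop=SpheroCylinder(
            sphere=num("ra_sphere_d"),
            cylinder=num("ra_cyl_d"),
            axis=num("ra_axis_deg"),
            notation=_NOTATION_IN[notation_raw],
        ),
        spherical_aberration=float(sa_raw) if sa_raw else None,
    )
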