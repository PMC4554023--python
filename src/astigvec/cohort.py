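"""Cohort-level statistics: per-eye derived quantities, subgroup
comparisons, correlations and log-linear regressions.

The analysis mirrors a method-comparison study design for keratometry:

* per-eye discrepancy ``delta`` between ray-traced total corneal power
  (TCRP, 3- and 4-mm zones) and automated keratometry (AK), measured as
  the power-vector difference length;
* with-the-rule / against-the-rule classification on the AK steep axis;
* low/high corneal-irregularity subgrouping by two thresholds (cohort
  median, and cohort mean + 2 SD);
* ocular residual astigmatism (ORA) per keratometry source and assumed
  SIA, compared between subgroups and paired within eyes;
* multiple linear regressions of log-transformed outcomes (irregularity
  index, delta) on age and ocular covariates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import EmptyCohortError, MissingFieldError, PairingError
from .powervec import classify_wtr_atr, cyl_to_pv, pv_difference_magnitude
from .records import EyeRecord
from .refraction import (
    DEFAULT_SIA_MAGNITUDES,
    DEFAULT_VERTEX_DISTANCE,
    KERATOMETRY_SOURCES,
    RA_VARIANTS,
    compute_ora_set,
    refraction_to_corneal_plane,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DeltaColumns",
    "RegressionResult",
    "AnalysisConfig",
    "CohortAnalysisReport",
    "compute_deltas",
    "group_by_ir",
    "fit_log_linear",
    "fit_linear",
    "correlate",
    "compare_groups",
    "analyze_cohort",
]

#: Printed fixed thresholds of the reference cohort (mm): median, mean+2SD.
FIXED_IR_THRESHOLDS = {1: 0.036, 2: 0.077}


@dataclass(frozen=True)
class DeltaColumns:
    """Per-eye TCRP-vs-AK discrepancy magnitudes, diopters (>= 0)."""

    delta_tcrp3_ak: float
    delta_tcrp4_ak: float


def compute_deltas(eye: EyeRecord, as_cylinder: bool = False) -> DeltaColumns:
    """Power-vector distance of each TCRP measurement from AK.

    ``as_cylinder`` doubles the distances to express them as cylinders.
    """
    ak = eye.require("ak")
    tcrp3 = eye.require("tcrp3")
    tcrp4 = eye.require("tcrp4")
    ak_pv = cyl_to_pv(ak)
    scale = 2.0 if as_cylinder else 1.0
    return DeltaColumns(
        delta_tcrp3_ak=scale * pv_difference_magnitude(cyl_to_pv(tcrp3), ak_pv),
        delta_tcrp4_ak=scale * pv_difference_magnitude(cyl_to_pv(tcrp4), ak_pv),
    )


def group_by_ir(
    cohort: Sequence[EyeRecord],
    method: Literal[1, 2],
    threshold_mode: Literal["cohort", "fixed"] = "cohort",
    fixed_value: Optional[float] = None,
) -> tuple[list[str], float]:
    """Label each eye ``low``/``high`` by its corneal irregularity index.

    Method 1 thresholds at the cohort median IR, method 2 at mean + 2 SD
    (sample SD).  ``threshold_mode="fixed"`` uses ``fixed_value`` if given,
    else the published threshold for the method (0.036 / 0.077 mm).  An
    eye is ``high`` iff IR >= threshold.

    Returns the labels (cohort order) and the threshold used.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot derive IR grouping from an empty cohort")
    if method not in (1, 2):
        raise ValueError(f"grouping method must be 1 or 2, got {method!r}")
    ir = np.array([eye.require("ir") for eye in cohort], dtype=float)
    if threshold_mode == "fixed":
        threshold = FIXED_IR_THRESHOLDS[method] if fixed_value is None else float(fixed_value)
    elif threshold_mode == "cohort":
        if method == 1:
            threshold = float(np.median(ir))
        else:
            threshold = float(ir.mean() + 2.0 * ir.std(ddof=1)) if len(ir) > 1 else float(ir[0])
    else:
        raise ValueError(f"threshold_mode must be 'cohort' or 'fixed', got {threshold_mode!r}")
    labels = ["high" if v >= threshold else "low" for v in ir]
    return labels, threshold


@dataclass(frozen=True)
class RegressionResult:
    """An ordinary-least-squares fit summary.

    ``coefficients`` and ``standard_errors`` share keys (``const`` plus
    predictor names); ``r_squared`` is the coefficient of determination.
    """

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    r_squared: float
    n: int

    def __post_init__(self):
        if set(self.coefficients) != set(self.standard_errors):
            raise ValueError("coefficient and standard-error key sets differ")
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared!r}")


def _ols(y: np.ndarray, predictors: pd.DataFrame) -> RegressionResult:
    x = sm.add_constant(predictors.astype(float), has_constant="add")
    model = sm.OLS(y, x)
    fit = model.fit()
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    r2 = float(fit.rsquared)
    if math.isnan(r2):  # constant y: no variance to explain
        r2 = 0.0
    return RegressionResult(
        coefficients={k: float(v) for k, v in fit.params.items()},
        standard_errors={k: float(v) for k, v in fit.bse.items()},
        r_squared=min(max(r2, 0.0), 1.0),
        n=int(fit.nobs),
    )


def fit_log_linear(y: Sequence[float], predictors: pd.DataFrame) -> RegressionResult:
    """OLS of ln(y) on an intercept plus the given predictor columns.

    ``y`` must be strictly positive; coefficients are on the log scale.
    """
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("log-linear fit requires strictly positive, finite y")
    if len(y) != len(predictors):
        raise ValueError("y and predictors must have equal length")
    if len(y) <= predictors.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    return _ols(np.log(y), predictors)


def fit_linear(y: Sequence[float], predictors: pd.DataFrame) -> RegressionResult:
    """Raw-scale OLS companion to :func:`fit_log_linear`."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(predictors):
        raise ValueError("y and predictors must have equal length")
    return _ols(y, predictors)


def correlate(
    x: Sequence[float], y: Sequence[float], method: Literal["pearson", "spearman"] = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("correlate needs two equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance sample")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r.statistic), float(r.pvalue)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: Literal["t", "mann_whitney", "paired_t"] = "t",
) -> tuple[float, float]:
    """Two-sided two-sample comparison.

    ``t`` is the independent-samples Student t test, ``mann_whitney`` its
    rank-based analogue, ``paired_t`` the within-eye paired t test.  A
    degenerate paired test (every difference exactly zero) reports
    (0.0, 1.0) rather than NaN, with a warning logged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "paired_t":
        if len(a) != len(b):
            raise PairingError(f"paired test requires equal lengths, got {len(a)} vs {len(b)}")
        diff = a - b
        if np.all(diff == 0):
            logger.warning("paired t test degenerate: all differences zero; reporting p = 1")
            return 0.0, 1.0
        res = stats.ttest_rel(a, b)
    elif test == "t":
        res = stats.ttest_ind(a, b)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of :func:`analyze_cohort`.

    sia_magnitudes : assumed SIA magnitudes for the RA/RA1/RA2 variants (D).
    vertex_distance : spectacle-to-cornea distance in metres.
    incision_axis : meridian flattened by the incision (degrees).
    sia_sign : +1 adds the flattening vector back to postoperative
        refraction (default), -1 subtracts it (sensitivity analysis).
    ir_threshold_mode : "cohort" recomputes the grouping thresholds from
        the analysed cohort; "fixed" uses the published 0.036 / 0.077 mm.
    delta_as_cylinder : express deltas and ORAs as cylinders (doubled).
    table5_grouping : which IR grouping defines the high-irregularity
        subgroup for the paired ORA comparison (2 = mean + 2 SD).
    """

    sia_magnitudes: tuple[float, ...] = DEFAULT_SIA_MAGNITUDES
    vertex_distance: float = DEFAULT_VERTEX_DISTANCE
    incision_axis: float = 0.0
    sia_sign: int = +1
    ir_threshold_mode: Literal["cohort", "fixed"] = "cohort"
    delta_as_cylinder: bool = False
    table5_grouping: Literal[1, 2] = 2


_ORA_COLUMNS = [
    f"ora_{s.lower()}_{v.lower()}" for s in KERATOMETRY_SOURCES for v in RA_VARIANTS
]

#: Per-eye variables summarised in the group-comparison tables.
_SUMMARY_VARIABLES = [
    "age",
    "ak_mag",
    "tcrp3_mag",
    "tcrp4_mag",
    "ak_j0",
    "ak_j45",
    "ra_corneal_cyl",
    "delta_tcrp3_ak",
    "delta_tcrp4_ak",
    "ir_mm",
    "irregular_astig_um",
    "ap_ratio",
    "sa_um",
]


@dataclass
class CohortAnalysisReport:
    """Everything :func:`analyze_cohort` derives from a cohort.

    ``per_eye`` holds one row per input eye (order preserved);
    ``tables`` the four summary tables; ``regressions`` the fitted
    log-scale and raw-scale OLS models; ``counts`` bookkeeping
    (group sizes, zero-cylinder exclusions, thresholds used).
    """

    per_eye: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    regressions: dict[str, RegressionResult]
    tests: list[dict] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def save(self, out_dir: str | Path) -> None:
        """Write per-eye and summary tables as CSV plus a JSON summary."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_eye.to_csv(out / "per_eye.csv", index=False)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        summary = {
            "counts": self.counts,
            "regressions": {
                name: {
                    "coefficients": r.coefficients,
                    "standard_errors": r.standard_errors,
                    "r_squared": r.r_squared,
                    "n": r.n,
                }
                for name, r in self.regressions.items()
            },
            "tests": self.tests,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2))


def _per_eye_frame(cohort: Sequence[EyeRecord], config: AnalysisConfig) -> tuple[pd.DataFrame, int]:
    rows = []
    excluded_zero_cyl = 0
    for eye in cohort:
        ak = eye.require("ak")
        deltas = compute_deltas(eye, as_cylinder=config.delta_as_cylinder)
        try:
            ora = compute_ora_set(
                eye,
                sia_magnitudes=config.sia_magnitudes,
                vertex_distance=config.vertex_distance,
                incision_axis=config.incision_axis,
                sia_sign=config.sia_sign,
                as_cylinder=config.delta_as_cylinder,
            )
        except MissingFieldError as err:
            raise MissingFieldError(err.field, eye.eye_id) from err
        ra_corneal = refraction_to_corneal_plane(eye.ra_postop, config.vertex_distance)
        ak_pv = cyl_to_pv(ak)
        if ak.magnitude == 0.0:
            axis_class = ""
            excluded_zero_cyl += 1
        else:
            axis_class = classify_wtr_atr(ak)
        row = {
            "eye_id": eye.eye_id,
            "age": eye.age,
            "ak_mag": ak.magnitude,
            "ak_axis": ak.axis,
            "tcrp3_mag": eye.tcrp3.magnitude,
            "tcrp4_mag": eye.tcrp4.magnitude,
            "ak_j0": ak_pv.j0,
            "ak_j45": ak_pv.j45,
            "ir_mm": eye.require("ir"),
            "irregular_astig_um": eye.irregular_astig,
            "ap_ratio": (
                eye.anterior_radius / eye.posterior_radius
                if eye.anterior_radius and eye.posterior_radius
                else np.nan
            ),
            "sa_um": eye.spherical_aberration if eye.spherical_aberration is not None else np.nan,
            "ra_corneal_cyl": ra_corneal.astigmatism().magnitude,
            "delta_tcrp3_ak": deltas.delta_tcrp3_ak,
            "delta_tcrp4_ak": deltas.delta_tcrp4_ak,
            "axis_class": axis_class,
        }
        row.update(ora.as_flat_dict())
        rows.append(row)
    return pd.DataFrame(rows), excluded_zero_cyl


def _two_group_table(df: pd.DataFrame, mask_a, mask_b, label_a: str, label_b: str,
                     variables: Sequence[str]) -> pd.DataFrame:
    rows = []
    for var in variables:
        if var not in df.columns:
            continue
        a = df.loc[mask_a, var].dropna().to_numpy()
        b = df.loc[mask_b, var].dropna().to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            _, p = compare_groups(a, b, test="t")
        else:
            p = np.nan
        rows.append(
            {
                "variable": var,
                f"n_{label_a}": len(a),
                f"mean_{label_a}": a.mean() if len(a) else np.nan,
                f"sd_{label_a}": a.std(ddof=1) if len(a) > 1 else np.nan,
                f"n_{label_b}": len(b),
                f"mean_{label_b}": b.mean() if len(b) else np.nan,
                f"sd_{label_b}": b.std(ddof=1) if len(b) > 1 else np.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def analyze_cohort(
    cohort: Sequence[EyeRecord], config: AnalysisConfig | None = None
) -> CohortAnalysisReport:
    """Run the full cohort analysis.

    Produces per-eye derived columns (deltas, axis class, IR group labels,
    the nine ORA values), the four summary tables, and the regressions of
    ln(IR) on age + irregular astigmatism and of ln(delta) on age + IR +
    AK magnitude (raw-scale companions included).  Deterministic given
    cohort and config.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot analyze an empty cohort")
    config = config or AnalysisConfig()
    df, excluded_zero_cyl = _per_eye_frame(cohort, config)

    thresholds = {}
    for method in (1, 2):
        labels, thr = group_by_ir(cohort, method, threshold_mode=config.ir_threshold_mode)
        df[f"ir_group{method}"] = labels
        thresholds[method] = thr
    if excluded_zero_cyl:
        logger.info("excluded %d zero-cylinder eye(s) from WTR/ATR tables", excluded_zero_cyl)

    tables: dict[str, pd.DataFrame] = {}

    # WTR vs ATR comparison (clinical-characteristics analogue)
    wtr = df["axis_class"] == "WTR"
    atr = df["axis_class"] == "ATR"
    tables["table1_wtr_atr"] = _two_group_table(df, wtr, atr, "wtr", "atr", _SUMMARY_VARIABLES)

    # low vs high irregularity under both groupings
    t3_parts = []
    for method in (1, 2):
        col = f"ir_group{method}"
        part = _two_group_table(
            df, df[col] == "low", df[col] == "high", "low", "high", _SUMMARY_VARIABLES
        )
        part.insert(0, "grouping", method)
        t3_parts.append(part)
    tables["table3_ir_groups"] = pd.concat(t3_parts, ignore_index=True)

    # ORA by irregularity group
    t4_rows = []
    for method in (1, 2):
        col = f"ir_group{method}"
        low, high = df[col] == "low", df[col] == "high"
        for source in KERATOMETRY_SOURCES:
            for variant in RA_VARIANTS:
                ora_col = f"ora_{source.lower()}_{variant.lower()}"
                a = df.loc[low, ora_col].to_numpy()
                b = df.loc[high, ora_col].to_numpy()
                p = compare_groups(a, b, test="t")[1] if len(a) >= 2 and len(b) >= 2 else np.nan
                t4_rows.append(
                    {
                        "grouping": method,
                        "source": source,
                        "variant": variant,
                        "n_low": len(a),
                        "mean_low": a.mean() if len(a) else np.nan,
                        "sd_low": a.std(ddof=1) if len(a) > 1 else np.nan,
                        "n_high": len(b),
                        "mean_high": b.mean() if len(b) else np.nan,
                        "sd_high": b.std(ddof=1) if len(b) > 1 else np.nan,
                        "p_value": p,
                    }
                )
    tables["table4_ora"] = pd.DataFrame(t4_rows)

    # paired ORA comparison (AK vs each TCRP) within the high-IR subgroup
    high_mask = df[f"ir_group{config.table5_grouping}"] == "high"
    t5_rows = []
    for tcrp in ("TCRP3", "TCRP4"):
        for variant in RA_VARIANTS:
            ak_col = f"ora_ak_{variant.lower()}"
            tc_col = f"ora_{tcrp.lower()}_{variant.lower()}"
            a = df.loc[high_mask, ak_col].to_numpy()
            b = df.loc[high_mask, tc_col].to_numpy()
            if len(a) >= 2:
                t_stat, p = compare_groups(a, b, test="paired_t")
                try:
                    r, r_p = correlate(a, b, method="pearson")
                except ValueError:
                    r, r_p = np.nan, np.nan
            else:
                t_stat, p, r, r_p = (np.nan,) * 4
            t5_rows.append(
                {
                    "comparison": f"AK_vs_{tcrp}",
                    "variant": variant,
                    "n": len(a),
                    "mean_ak": a.mean() if len(a) else np.nan,
                    "mean_tcrp": b.mean() if len(b) else np.nan,
                    "mean_diff": (a - b).mean() if len(a) else np.nan,
                    "t_statistic": t_stat,
                    "p_value": p,
                    "pearson_r": r,
                    "pearson_p": r_p,
                }
            )
    tables["table5_paired_ora"] = pd.DataFrame(t5_rows)

    # regressions: ln(IR) ~ age + irregular astig; ln(delta) ~ age + IR + AK
    regressions: dict[str, RegressionResult] = {}
    dropped = {}
    ir_pred = df[["age", "irregular_astig_um"]].rename(
        columns={"irregular_astig_um": "irregular_astig"}
    )
    def _try_fit(name, fitter, y, predictors):
        # degenerate hand-built cohorts (constant covariates) skip the fit
        try:
            regressions[name] = fitter(y, predictors)
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("skipping regression %s: %s", name, err)

    ir_ok = df["ir_mm"] > 0
    if ir_ok.sum() > 3 and df["irregular_astig_um"].notna().all():
        _try_fit("ln_ir_on_age_irregular_astig", fit_log_linear,
                 df.loc[ir_ok, "ir_mm"], ir_pred.loc[ir_ok])
        _try_fit("ir_on_age_irregular_astig", fit_linear, df["ir_mm"], ir_pred)
        dropped["ln_ir"] = int((~ir_ok).sum())
    for which in ("tcrp3", "tcrp4"):
        y_col = f"delta_{which}_ak"
        pred = df[["age", "ir_mm", "ak_mag"]].rename(columns={"ir_mm": "ir", "ak_mag": "ak"})
        ok = df[y_col] > 0
        dropped[y_col] = int((~ok).sum())
        if ok.sum() > 4:
            _try_fit(f"ln_delta_{which}_on_age_ir_ak", fit_log_linear,
                     df.loc[ok, y_col], pred.loc[ok])
            _try_fit(f"delta_{which}_on_age_ir_ak", fit_linear, df[y_col], pred)

    tests = []
    for var in ("delta_tcrp3_ak", "delta_tcrp4_ak"):
        a = df.loc[wtr, var].to_numpy()
        b = df.loc[atr, var].to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            stat, p = compare_groups(a, b, test="t")
            tests.append({"name": f"{var}_wtr_vs_atr_t", "statistic": stat, "p_value": p})

    counts = {
        "n": len(df),
        "wtr": int(wtr.sum()),
        "atr": int(atr.sum()),
        "zero_cylinder_excluded": excluded_zero_cyl,
        "ir_thresholds": thresholds,
        "ir_group_sizes": {
            m: df[f"ir_group{m}"].value_counts().to_dict() for m in (1, 2)
        },
        "regression_rows_dropped_nonpositive": dropped,
    }
    return CohortAnalysisReport(
        per_eye=df,
        tables=tables,
        regressions=regressions,
        tests=tests,
        counts=counts,
        config=config,
    )
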