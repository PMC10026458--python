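"""Linear relaxivity model linking gel ingredients to relaxation rates.

The phantom tubes are agarose gels doped with nickel chloride.  Agarose
concentration chiefly shortens T2 and Ni2+ chiefly shortens T1, and over
the calibration range both relaxation *rates* are well described as linear
in the two concentrations:

    R1 = 1/T1 [1/s] = r1_0 + r1_ni * [Ni2+ mM] + r1_ag * [agarose %w/v]
    R2 = 1/T2 [1/s] = r2_0 + r2_ni * [Ni2+ mM] + r2_ag * [agarose %w/v]

Fitting these two planes to a calibration table allows any target (T1, T2)
pair to be translated into a recipe by solving the 2x2 linear system — the
forward (predict) and inverse (design) directions are exact linear algebra.

Times are milliseconds throughout the public API; rates are converted to
1/s internally so that the relaxivity coefficients carry their customary
magnitudes (roughly 0.1–10 1/s per unit concentration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCalibrationError,
    InfeasibleTargetError,
    NonInvertibleModelError,
    UnphysicalPredictionError,
)
from .tables import calibration_table

__all__ = [
    "IngredientConcentration",
    "RelaxationPair",
    "RelaxivityModel",
    "FIELD_COLUMNS",
    "calibration_fixture",
    "read_calibration_csv",
    "write_calibration_csv",
    "fit_relaxivity_model",
    "predict_relaxation",
    "design_recipe",
    "leave_one_out_errors",
]

#: Calibration-table column pairs (T1, T2) per field label.
FIELD_COLUMNS = {
    "1.4T": ("t1_1p4T_ms", "t2_1p4T_ms"),
    "1.5T": ("t1_1p5T_ms", "t2_1p5T_ms"),
    "3T": ("t1_3T_ms", "t2_3T_ms"),
}

CALIBRATION_COLUMNS = [
    "agarose_pct",
    "ni_mM",
    "t1_1p4T_ms",
    "t1_1p5T_ms",
    "t1_3T_ms",
    "t2_1p4T_ms",
    "t2_1p5T_ms",
    "t2_3T_ms",
]


@dataclass(frozen=True)
class IngredientConcentration:
    """Gel recipe: agarose mass fraction (% w/v) and NiCl2 concentration (mM)."""

    agarose_pct: float
    ni_mM: float

    def __post_init__(self) -> None:
        if self.agarose_pct < 0 or self.ni_mM < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class RelaxationPair:
    """Longitudinal (T1) and transverse (T2) relaxation times in ms.

    For physical gels T2 <= T1; a violation is suspicious but not fatal
    (e.g. a deliberately extreme design target), so it only warns.
    """

    t1_ms: float
    t2_ms: float

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError("relaxation times must be positive")
        if self.t2_ms > self.t1_ms:
            warnings.warn(
                f"T2 ({self.t2_ms} ms) exceeds T1 ({self.t1_ms} ms); "
                "unphysical for gels",
                stacklevel=3,
            )

    @property
    def r1(self) -> float:
        """Longitudinal rate 1/T1 in 1/s."""
        return 1000.0 / self.t1_ms

    @property
    def r2(self) -> float:
        """Transverse rate 1/T2 in 1/s."""
        return 1000.0 / self.t2_ms


@dataclass(frozen=True)
class RelaxivityModel:
    """Fitted linear ingredient->rate model at one field strength.

    Intercepts ``r*_0`` are the rates of the undoped water/gel background;
    ``r*_ni`` / ``r*_ag`` are rate increments per mM NiCl2 and per % w/v
    agarose.  ``residual_sd_*`` are the fit residual scales (1/s) so that
    model inadequacy (e.g. neglected Ni–agarose cross-terms) stays visible.
    """

    field_label: str
    r1_0: float
    r1_ni: float
    r1_ag: float
    r2_0: float
    r2_ni: float
    r2_ag: float
    residual_sd_r1: float = 0.0
    residual_sd_r2: float = 0.0
    temperature_c: float = 22.0
    n_rows: int = 0

    @property
    def slope_matrix(self) -> np.ndarray:
        """2x2 matrix mapping (ni_mM, agarose_pct) to (R1, R2) increments."""
        return np.array([[self.r1_ni, self.r1_ag], [self.r2_ni, self.r2_ag]])


def calibration_fixture() -> pd.DataFrame:
    """The embedded calibration table (9 tubes A–I plus the outer fill)."""
    return calibration_table()


def read_calibration_csv(path) -> pd.DataFrame:
    """Read a calibration table CSV (empty cells = missing measurements)."""
    df = pd.read_csv(path, index_col="tube_id")
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calibration CSV missing columns: {missing}")
    if df.index.duplicated().any():
        raise ValueError("duplicate tube ids in calibration CSV")
    return df[CALIBRATION_COLUMNS]


def write_calibration_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="tube_id")


def _design_rows(calibration: pd.DataFrame, field_label: str):
    try:
        t1_col, t2_col = FIELD_COLUMNS[field_label]
    except KeyError:
        raise ValueError(
            f"unknown field label {field_label!r}; expected one of "
            f"{sorted(FIELD_COLUMNS)}"
        ) from None
    rows = calibration.dropna(subset=["agarose_pct", "ni_mM", t1_col, t2_col])
    return rows, t1_col, t2_col


def fit_relaxivity_model(
    calibration: pd.DataFrame,
    field_label: str,
    *,
    include_outer: bool = False,
    temperature_c: float = 22.0,
) -> RelaxivityModel:
    """Fit the two rate planes by ordinary least squares.

    Parameters
    ----------
    calibration
        Table with ``agarose_pct``, ``ni_mM`` and per-field T1/T2 columns
        (ms), indexed by tube id.
    field_label
        One of ``"1.4T"``, ``"1.5T"``, ``"3T"``.
    include_outer
        Whether to include the ``outer`` matrix-fill row.  Off by default:
        the outer fill is a different formulation (HDPE-bead loaded) and is
        not part of the tube recipe chemistry.

    Raises
    ------
    DegenerateCalibrationError
        Fewer than 3 usable rows, or all rows collinear in concentration
        space (rank-deficient design).
    """
    if not include_outer and "outer" in calibration.index:
        calibration = calibration.drop(index="outer")
    rows, t1_col, t2_col = _design_rows(calibration, field_label)
    if len(rows) < 3:
        raise DegenerateCalibrationError(
            f"need >= 3 complete rows at {field_label}, got {len(rows)}"
        )

    conc = np.column_stack(
        [rows["ni_mM"].to_numpy(float), rows["agarose_pct"].to_numpy(float)]
    )
    X = np.column_stack([np.ones(len(rows)), conc])
    r1 = 1000.0 / rows[t1_col].to_numpy(float)
    r2 = 1000.0 / rows[t2_col].to_numpy(float)

    # Rank of the *centered* concentrations decides the fit:
    # 0 (all recipes identical) -> intercept-only model with zero slopes;
    # 1 (recipes on a line)     -> the two slopes are not identifiable.
    conc_rank = np.linalg.matrix_rank(conc - conc.mean(axis=0), tol=1e-10)
    if conc_rank == 0:
        coef1 = np.array([r1.mean(), 0.0, 0.0])
        coef2 = np.array([r2.mean(), 0.0, 0.0])
    elif conc_rank < 2:
        raise DegenerateCalibrationError(
            "calibration rows are collinear in concentration space"
        )
    else:
        coef1, *_ = np.linalg.lstsq(X, r1, rcond=None)
        coef2, *_ = np.linalg.lstsq(X, r2, rcond=None)

    dof = max(len(rows) - 3, 1)
    sd1 = float(np.sqrt(np.sum((r1 - X @ coef1) ** 2) / dof))
    sd2 = float(np.sqrt(np.sum((r2 - X @ coef2) ** 2) / dof))

    model = RelaxivityModel(
        field_label=field_label,
        r1_0=float(coef1[0]),
        r1_ni=float(coef1[1]),
        r1_ag=float(coef1[2]),
        r2_0=float(coef2[0]),
        r2_ni=float(coef2[1]),
        r2_ag=float(coef2[2]),
        residual_sd_r1=sd1,
        residual_sd_r2=sd2,
        temperature_c=temperature_c,
        n_rows=len(rows),
    )

    pred1 = X @ coef1
    pred2 = X @ coef2
    if np.any(pred1 <= 0) or np.any(pred2 <= 0):
        raise DegenerateCalibrationError(
            "fitted model predicts non-positive rates on calibration rows"
        )
    return model


def predict_relaxation(
    conc: IngredientConcentration, model: RelaxivityModel
) -> RelaxationPair:
    """Forward model: recipe -> (T1, T2) in ms."""
    rate1 = model.r1_0 + model.r1_ni * conc.ni_mM + model.r1_ag * conc.agarose_pct
    rate2 = model.r2_0 + model.r2_ni * conc.ni_mM + model.r2_ag * conc.agarose_pct
    if rate1 <= 0 or rate2 <= 0:
        raise UnphysicalPredictionError(
            f"predicted rates R1={rate1:.4g}, R2={rate2:.4g} 1/s; both must be > 0"
        )
    return RelaxationPair(t1_ms=1000.0 / rate1, t2_ms=1000.0 / rate2)


def design_recipe(
    target: RelaxationPair, model: RelaxivityModel
) -> IngredientConcentration:
    """Inverse model: solve for the recipe hitting a target (T1, T2).

    Solves the exact 2x2 linear system for (ni_mM, agarose_pct); raises
    :class:`InfeasibleTargetError` if either solved concentration is
    negative (the target lies outside the reachable quadrant).
    """
    A = model.slope_matrix
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    scale = np.abs(A).max()
    if scale == 0 or abs(det) < 1e-12 * scale * scale:
        raise NonInvertibleModelError("relaxivity slope matrix is singular")
    b = np.array([target.r1 - model.r1_0, target.r2 - model.r2_0])
    ni, ag = np.linalg.solve(A, b)
    tol = -1e-12 * max(1.0, scale)
    if ni < tol or ag < tol:
        bad = []
        if ni < tol:
            bad.append(f"ni_mM = {ni:.4g} < 0")
        if ag < tol:
            bad.append(f"agarose_pct = {ag:.4g} < 0")
        raise InfeasibleTargetError(
            f"target (T1={target.t1_ms} ms, T2={target.t2_ms} ms) requires "
            + " and ".join(bad)
        )
    return IngredientConcentration(agarose_pct=max(ag, 0.0), ni_mM=max(ni, 0.0))


def leave_one_out_errors(
    calibration: pd.DataFrame, field_label: str, *, include_outer: bool = False
) -> pd.DataFrame:
    """Leave-one-out prediction errors (ms) for every calibration row.

    Each row is dropped in turn, the model refitted on the rest, and the
    held-out (T1, T2) predicted.  No row is silently skipped: a row whose
    removal makes the fit degenerate propagates the error.
    """
    if not include_outer and "outer" in calibration.index:
        calibration = calibration.drop(index="outer")
    rows, t1_col, t2_col = _design_rows(calibration, field_label)
    records = []
    for tube in rows.index:
        m = fit_relaxivity_model(rows.drop(index=tube), field_label)
        conc = IngredientConcentration(
            agarose_pct=float(rows.loc[tube, "agarose_pct"]),
            ni_mM=float(rows.loc[tube, "ni_mM"]),
        )
        pred = predict_relaxation(conc, m)
        records.append(
            {
                "tube_id": tube,
                "t1_measured_ms": float(rows.loc[tube, t1_col]),
                "t1_predicted_ms": pred.t1_ms,
                "t2_measured_ms": float(rows.loc[tube, t2_col]),
                "t2_predicted_ms": pred.t2_ms,
            }
        )
    df = pd.DataFrame.from_records(records).set_index("tube_id")
    df["t1_error_ms"] = df["t1_predicted_ms"] - df["t1_measured_ms"]
    df["t2_error_ms"] = df["t2_predicted_ms"] - df["t2_measured_ms"]
    return df
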