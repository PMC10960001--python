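"""Concentration regression: single-analyte calibration over seven decades
and binary-mixture multiplex quantification at fixed total concentration.

Single-analyte models regress log10 molar concentration on the 95 peak
features (standardized, linear-kernel support-vector regression).
The log target is the only scale on which a 1e-4 to 1e-10 M series is
near-linear; predictions are inverse-transformed back to molarity.  The
multiplex model regresses the GalCer24:1 mol fraction of a binary
GlcCer24:1/GalCer24:1 mixture and derives the GlcCer24:1 share by
complement, so the predicted pair always sums to the fixed total.

Percent differences follow |experimental - predicted| / experimental.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ._sk import make_linear_svr
from .errors import DegenerateInputError, SchemaError, ValidationError
from .taxonomy import feature_columns

__all__ = [
    "QuantModel",
    "MultiplexModel",
    "train_quant",
    "predict_concentration",
    "percent_difference",
    "train_multiplex",
    "predict_mixture",
    "aef",
]

#: Default SVR settings for concentration regression.  epsilon is in log10-M
#: units; 1e-3 decades corresponds to a 0.23% concentration dead-band, far
#: below the target precision, so the fit is limited by the data rather than
#: the loss plateau.  The kernel is linear (see serstax._sk.make_linear_svr).
QUANT_SVR_C = 1.0
QUANT_SVR_EPSILON = 1e-3

#: Multiplex mol% regression: same linear SVR; the tiny epsilon keeps the
#: noise-free calibration residual negligible on the 0-100 mol% scale.
MULTIPLEX_SVR_C = 1.0
MULTIPLEX_SVR_EPSILON = 1e-4


def _r_squared(y_true, y_pred) -> float:
    """Squared Pearson correlation (chemometrics convention)."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.size < 2 or np.std(y_true) == 0 or np.std(y_pred) == 0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)


@dataclass
class QuantModel:
    """Per-analyte log-concentration regression with calibration stats."""

    analyte: str
    pipeline: object
    schema: list
    r2: float
    rmsep: float                 # log10-M units, on the held-out split
    log_range: tuple             # (min, max) log10 concentration trained
    seed: int


@dataclass
class MultiplexModel:
    """GalCer24:1 mol% regression for binary mixtures at fixed total."""

    pipeline: object
    schema: list
    total_M: float
    r2_cv: float
    rmse_calibration: float      # mol%, on the calibration split
    seed: int


def train_quant(df: pd.DataFrame, seed: int = 0,
                c: float = QUANT_SVR_C,
                epsilon: float = QUANT_SVR_EPSILON) -> QuantModel:
    """Train a single-analyte concentration model.

    ``df`` holds the feature table of one analyte across its dilution
    series (``concentration_M`` column).  The rows are stratified by
    concentration level into 75% train / 25% test in one iteration; the
    reported R^2 and RMSEP come from the 25% test split.
    """
    cols = feature_columns(df)
    analytes = df["analyte"].unique() if "analyte" in df else ["?"]
    if len(analytes) != 1:
        raise ValidationError(
            f"train_quant expects a single analyte, got {list(analytes)}"
        )
    conc = df["concentration_M"].astype(float).to_numpy()
    levels = np.unique(conc)
    if levels.size < 2:
        raise DegenerateInputError(
            "need at least two concentration levels for a calibration"
        )
    y = np.log10(conc)
    X = df[cols].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=0.75, stratify=y, random_state=seed
    )
    pipe = make_linear_svr(c, epsilon)
    pipe.fit(X_tr, y_tr)
    pred = pipe.predict(X_te)
    return QuantModel(
        analyte=str(analytes[0]),
        pipeline=pipe,
        schema=cols,
        r2=_r_squared(y_te, pred),
        rmsep=float(np.sqrt(np.mean((pred - y_te) ** 2))),
        log_range=(float(y.min()), float(y.max())),
        seed=seed,
    )


def predict_concentration(df_or_X, model: QuantModel,
                          truth: float | np.ndarray | None = None
                          ) -> pd.DataFrame:
    """Predict molar concentrations; one row per spectrum.

    Adds ``out_of_range`` flags for estimates more than one decade outside
    the calibrated range (the estimate is still returned) and, when truth
    is supplied, the percent difference |true - predicted| / true.
    """
    if isinstance(df_or_X, pd.DataFrame):
        X = df_or_X[model.schema].to_numpy()
    else:
        X = np.asarray(df_or_X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(model.schema):
            raise SchemaError(
                f"expected {len(model.schema)} features, got {X.shape[1]}"
            )
    log_pred = model.pipeline.predict(X)
    conc = 10.0 ** log_pred
    lo, hi = model.log_range
    out = pd.DataFrame({
        "log10_predicted": log_pred,
        "predicted_M": conc,
        "out_of_range": (log_pred < lo - 1) | (log_pred > hi + 1),
    })
    if truth is not None:
        truth = np.broadcast_to(np.asarray(truth, float), conc.shape)
        out["truth_M"] = truth
        out["percent_difference"] = percent_difference(truth, conc)
    return out


def percent_difference(experimental, predicted) -> np.ndarray:
    """|experimental - predicted| / experimental, in percent."""
    experimental = np.asarray(experimental, float)
    predicted = np.asarray(predicted, float)
    if np.any(experimental <= 0):
        raise ValidationError("experimental value must be > 0")
    return 100.0 * np.abs(experimental - predicted) / experimental


def train_multiplex(df: pd.DataFrame, seed: int = 0,
                    c: float = MULTIPLEX_SVR_C,
                    epsilon: float = MULTIPLEX_SVR_EPSILON) -> MultiplexModel:
    """Train the binary-mixture mol% model on a calibration set.

    ``df`` is a mixture feature table (``frac_gal`` in mol% and ``total_M``
    columns) covering at least three calibration levels.  Rows are
    stratified by level into 80% calibration / 20% cross-validation;
    the reported R^2 comes from the cross-validation split and the RMSE
    from the calibration split.
    """
    cols = feature_columns(df)
    frac = df["frac_gal"].astype(float).to_numpy()
    levels = np.unique(frac)
    if levels.size < 3:
        raise DegenerateInputError(
            "need at least three mixture levels for a calibration"
        )
    totals = df["total_M"].astype(float).unique()
    if len(totals) != 1:
        raise ValidationError("mixture calibration must share one total")
    X = df[cols].to_numpy()
    X_tr, X_cv, y_tr, y_cv = train_test_split(
        X, frac, train_size=0.8, stratify=frac, random_state=seed
    )
    pipe = make_linear_svr(c, epsilon)
    pipe.fit(X_tr, y_tr)
    return MultiplexModel(
        pipeline=pipe,
        schema=cols,
        total_M=float(totals[0]),
        r2_cv=_r_squared(y_cv, pipe.predict(X_cv)),
        rmse_calibration=float(np.sqrt(np.mean(
            (pipe.predict(X_tr) - y_tr) ** 2
        ))),
        seed=seed,
    )


def predict_mixture(df_or_X, model: MultiplexModel,
                    truth_frac_gal: float | None = None) -> dict:
    """Quantify both epimers in blind binary-mixture replicates.

    Returns per-replicate micromolar estimates for GalCer24:1 and (by
    complement) GlcCer24:1, their mean +- SD, and — when the true GalCer
    mol% is supplied — the absolute differences in uM.  Estimates outside
    [0, total] are clipped and flagged.
    """
    if isinstance(df_or_X, pd.DataFrame):
        X = df_or_X[model.schema].to_numpy()
    else:
        X = np.asarray(df_or_X, float)
        if X.ndim == 1:
            X = X[None, :]
    frac = model.pipeline.predict(X)
    clipped = (frac < 0) | (frac > 100)
    frac_c = np.clip(frac, 0.0, 100.0)
    total_uM = model.total_M * 1e6
    gal = frac_c / 100.0 * total_uM
    glc = total_uM - gal
    table = pd.DataFrame({
        "frac_gal_pred": frac,
        "galcer_uM": gal,
        "glccer_uM": glc,
        "clipped": clipped,
    })
    out = {
        "table": table,
        "total_uM": total_uM,
        "galcer_uM_mean": float(gal.mean()),
        "galcer_uM_sd": float(gal.std(ddof=1)) if gal.size > 1 else 0.0,
        "glccer_uM_mean": float(glc.mean()),
        "glccer_uM_sd": float(glc.std(ddof=1)) if glc.size > 1 else 0.0,
    }
    if truth_frac_gal is not None:
        gal_true = truth_frac_gal / 100.0 * total_uM
        glc_true = total_uM - gal_true
        out["galcer_uM_true"] = gal_true
        out["glccer_uM_true"] = glc_true
        out["galcer_abs_diff_uM"] = float(np.abs(gal - gal_true).mean())
        out["glccer_abs_diff_uM"] = float(np.abs(glc - glc_true).mean())
    return out


def aef(i_sers: float, i_raman: float, c_raman: float,
        c_sers: float) -> float:
    """Analytical enhancement factor: (I_SERS / I_Raman) * (C_Raman / C_SERS).

    Signal-per-concentration ratio of the SERS substrate against normal
    Raman; all inputs must be positive.
    """
    for name, v in (("i_sers", i_sers), ("i_raman", i_raman),
                    ("c_raman", c_raman), ("c_sers", c_sers)):
        if not (v > 0):
            raise ValidationError(f"{name} must be > 0")
    return (i_sers / i_raman) * (c_raman / c_sers)
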