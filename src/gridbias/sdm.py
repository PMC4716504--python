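"""Weighted binomial GLM fitting and post-fit diagnostics.

The model is logit(P(presence)) ~ intercept + four climate predictors
entered linearly and quadratically (nine columns).  Predictors enter
*unstandardized*; coefficients are standardized after fitting by the
weighted standard deviation of their own design column.

Weights multiply each cell's Bernoulli log-likelihood contribution
(``var_weights`` in statsmodels terms): coefficients are invariant to a
common rescaling of the weights, standard errors come from the weighted
Fisher information with the weights as given.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .world import PREDICTOR_NAMES

#: design-matrix column names, in order
DESIGN_COLUMNS = (
    "intercept",
    *PREDICTOR_NAMES,
    *[f"{n}_sq" for n in PREDICTOR_NAMES],
)

VARIANT_ABBREVIATIONS = ("L", "LA", "LL", "LLA", "M", "ML")


class FitError(ValueError):
    pass


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class ModelVariant:
    """One projection/weighting configuration.

    Exactly six combinations are valid: the long-lat grid unweighted (L),
    area-weighted (LA), land-cover-weighted (LL) or both (LLA), and the
    equal-area grid unweighted (M) or land-cover-weighted (ML).  Area
    weighting on the equal-area grid is a no-op and therefore not a
    defined variant.
    """

    projection: str
    area_weighting: bool
    landcover_weighting: bool
    abbreviation: str

    def __post_init__(self):
        expected = _abbreviate(self.projection, self.area_weighting, self.landcover_weighting)
        if expected is None or expected != self.abbreviation:
            raise FitError(
                f"invalid variant: {self.projection}, area={self.area_weighting}, "
                f"land={self.landcover_weighting}, abbr={self.abbreviation!r}"
            )

    def weights(self, table: pd.DataFrame) -> np.ndarray:
        w = np.ones(len(table))
        if self.area_weighting:
            w = w * table["weight_area"].to_numpy()
        if self.landcover_weighting:
            w = w * table["weight_land"].to_numpy()
        return w


def _abbreviate(projection, area, land):
    key = (projection, bool(area), bool(land))
    return {
        ("longlat", False, False): "L",
        ("longlat", True, False): "LA",
        ("longlat", False, True): "LL",
        ("longlat", True, True): "LLA",
        ("equalarea", False, False): "M",
        ("equalarea", False, True): "ML",
    }.get(key)


VARIANTS: dict[str, ModelVariant] = {
    "L": ModelVariant("longlat", False, False, "L"),
    "LA": ModelVariant("longlat", True, False, "LA"),
    "LL": ModelVariant("longlat", False, True, "LL"),
    "LLA": ModelVariant("longlat", True, True, "LLA"),
    "M": ModelVariant("equalarea", False, False, "M"),
    "ML": ModelVariant("equalarea", False, True, "ML"),
}

REFERENCE_VARIANT = "ML"


@dataclass
class FitResult:
    """Everything the bias analysis consumes from one fitted variant."""

    coefficients: np.ndarray          # 9: intercept + 8 slopes
    standard_errors: np.ndarray       # 9
    standardized_coefficients: np.ndarray  # 8 slopes
    partial_deviance: np.ndarray      # 4, share of null deviance
    pseudo_r2: float
    prevalence: float
    n_cells: int
    converged: bool
    deviance: float
    null_deviance: float
    columns: tuple[str, ...] = DESIGN_COLUMNS
    variant: Optional[str] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]

    @property
    def slope_standard_errors(self) -> np.ndarray:
        return self.standard_errors[1:]

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "standardized_coefficients": self.standardized_coefficients.tolist(),
            "partial_deviance": self.partial_deviance.tolist(),
            "pseudo_r2": self.pseudo_r2,
            "prevalence": self.prevalence,
            "n_cells": self.n_cells,
            "converged": self.converged,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "columns": list(self.columns),
            "warnings": self.warnings,
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            coefficients=np.asarray(d["coefficients"]),
            standard_errors=np.asarray(d["standard_errors"]),
            standardized_coefficients=np.asarray(d["standardized_coefficients"]),
            partial_deviance=np.asarray(d["partial_deviance"]),
            pseudo_r2=d["pseudo_r2"],
            prevalence=d["prevalence"],
            n_cells=d["n_cells"],
            converged=d["converged"],
            deviance=d["deviance"],
            null_deviance=d["null_deviance"],
            columns=tuple(d["columns"]),
            variant=d.get("variant"),
            warnings=list(d.get("warnings", [])),
        )


def design_matrix(
    table: pd.DataFrame, quadratic: bool = True
) -> tuple[np.ndarray, tuple[str, ...], list[str]]:
    """Design matrix for the niche model.

    Returns (X, column names, warnings).  Rows must already be restricted
    to land cells; missing predictor values raise :class:`FitError`.
    A rank-deficient design (e.g. duplicated predictors) is flagged via
    the warnings list, not an exception.
    """
    if len(table) < 1:
        raise FitError("empty cell table")
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for name in PREDICTOR_NAMES:
        v = table[name].to_numpy(dtype=float)
        if np.any(np.isnan(v)):
            raise FitError(f"missing values in predictor {name!r} among land cells")
        cols.append(v)
        names.append(name)
    if quadratic:
        for name in PREDICTOR_NAMES:
            cols.append(table[name].to_numpy(dtype=float) ** 2)
            names.append(f"{name}_sq")
    X = np.column_stack(cols)
    warn = []
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warn.append("rank-deficient design matrix (collinear or constant predictors)")
    return X, tuple(names), warn


def fit_weighted_glm(
    X: np.ndarray,
    y: np.ndarray,
    w: Optional[np.ndarray] = None,
    columns: Sequence[str] = DESIGN_COLUMNS,
    variant: Optional[str] = None,
    compute_partials: bool = True,
) -> FitResult:
    """Maximize the weighted Bernoulli log-likelihood and package the fit.

    Rows with zero weight are dropped (they contribute nothing to the
    likelihood).  Perfect separation or IRLS non-convergence is reported
    through ``converged=False`` rather than an exception, so a batch run
    survives a degenerate variant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones(len(y))
    w = np.asarray(w, dtype=float)
    if X.shape[0] != len(y) or len(w) != len(y):
        raise SchemaError("X, y, w lengths differ")
    if np.any(w < 0):
        raise FitError("negative weights")
    keep = w > 0
    if not keep.any():
        raise FitError("all weights are zero")
    X, y, w = X[keep], y[keep], w[keep]
    classes = np.unique(y)
    if len(classes) < 2:
        raise FitError("only one response class among positive-weight cells")

    messages: list[str] = []
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
        res = model.fit(maxiter=100)
    for item in caught:
        if issubclass(item.category, PerfectSeparationWarning):
            separated = True
            messages.append("perfect separation detected")

    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    deviance = float(res.deviance)
    null_dev = float(res.null_deviance)
    # IRLS can report "converged" on a separated fit whose deviance is junk
    degenerate = null_dev > 0 and deviance > null_dev * (1 + 1e-8)
    converged = bool(
        res.converged and not separated and not degenerate and np.all(np.isfinite(bse))
    )
    if degenerate:
        messages.append("degenerate fit: residual deviance exceeds null deviance")
    prevalence = float(np.sum(w * y) / np.sum(w))
    std_coefs = standardize_coefficients(params, X, w)

    n_bases = len([c for c in columns if c != "intercept" and not c.endswith("_sq")])
    if compute_partials and converged:
        partial = partial_explained_deviance(X, y, w, deviance, null_dev, columns, messages)
    else:
        partial = np.full(n_bases, np.nan)

    return FitResult(
        coefficients=params,
        standard_errors=bse,
        standardized_coefficients=std_coefs,
        partial_deviance=partial,
        pseudo_r2=pseudo_r2(deviance, null_dev),
        prevalence=prevalence,
        n_cells=int(len(y)),
        converged=converged,
        deviance=deviance,
        null_deviance=null_dev,
        columns=tuple(columns),
        variant=variant,
        warnings=messages,
    )


def fit_variant(
    table: pd.DataFrame, variant: ModelVariant | str, presence_col: str = "presence"
) -> FitResult:
    """Fit one model variant on a (land-only) cell table."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    X, names, warn = design_matrix(table)
    y = table[presence_col].to_numpy(dtype=float)
    result = fit_weighted_glm(
        X, y, variant.weights(table), columns=names, variant=variant.abbreviation
    )
    result.warnings.extend(warn)
    return result


def weighted_sd(x: np.ndarray, w: np.ndarray) -> float:
    sw = np.sum(w)
    mean = np.sum(w * x) / sw
    return float(np.sqrt(np.sum(w * (x - mean) ** 2) / sw))


def standardize_coefficients(
    coefficients: np.ndarray, X: np.ndarray, w: Optional[np.ndarray] = None
) -> np.ndarray:
    """Post-fit standardization: each slope times the weighted standard
    deviation of its own design column (linear slope by sd(x), quadratic
    slope by sd(x^2)); the intercept is excluded.  A zero-variance column
    yields NaN for that slope."""
    if w is None:
        w = np.ones(X.shape[0])
    out = np.empty(X.shape[1] - 1)
    for j in range(1, X.shape[1]):
        sd = weighted_sd(X[:, j], w)
        out[j - 1] = coefficients[j] * sd if sd > 0 else np.nan
    return out


def _refit_deviance(X, y, w) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit(maxiter=100)
    if not res.converged:
        raise FitError("reduced fit did not converge")
    return float(res.deviance)


def partial_explained_deviance(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    deviance_full: float,
    deviance_null: float,
    columns: Sequence[str] = DESIGN_COLUMNS,
    messages: Optional[list[str]] = None,
) -> np.ndarray:
    """Per-predictor share of null deviance explained uniquely.

    A "predictor" is one base variable: its linear column and (if present)
    its quadratic partner ``<name>_sq`` are dropped together, the model is
    refitted, and w_i = (deviance_reduced - deviance_full) / deviance_null,
    clipped at 0.  Predictor groups are derived from the column names.
    """
    columns = list(columns)
    bases = [c for c in columns if c != "intercept" and not c.endswith("_sq")]
    out = np.empty(len(bases))
    for i, name in enumerate(bases):
        drop = {columns.index(name)}
        sq = f"{name}_sq"
        if sq in columns:
            drop.add(columns.index(sq))
        keep = [j for j in range(X.shape[1]) if j not in drop]
        try:
            dev_reduced = _refit_deviance(X[:, keep], y, w)
            out[i] = max((dev_reduced - deviance_full) / deviance_null, 0.0)
        except (FitError, np.linalg.LinAlgError):
            out[i] = np.nan
            if messages is not None:
                messages.append(f"partial deviance for {name!r} unavailable (reduced fit failed)")
    return out


def pseudo_r2(deviance: float, null_deviance: float) -> float:
    """McFadden: 1 - residual deviance / null deviance."""
    if null_deviance == 0:
        return 0.0
    return float(1.0 - deviance / null_deviance)


def vif(X_linear: np.ndarray) -> np.ndarray:
    """Variance inflation factors for the four *linear* predictor columns.

    VIF_j = 1 / (1 - R^2_j) from OLS of column j on the other three (plus
    an intercept).  Perfect collinearity reports infinity.
    """
    X = np.asarray(X_linear, dtype=float)
    if X.ndim != 2:
        raise SchemaError("expected a 2-D array of predictor columns")
    k = X.shape[1]
    out = np.empty(k)
    for j in range(k):
        others = np.column_stack([np.ones(X.shape[0]), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def predict_occurrence(fit: FitResult, X: np.ndarray, columns: Sequence[str] | None = None) -> np.ndarray:
    """Inverse-logit of the linear predictor; columns must match training."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(fit.coefficients):
        raise SchemaError(
            f"design has {X.shape[1]} columns, fit expects {len(fit.coefficients)}"
        )
    if columns is not None and tuple(columns) != tuple(fit.columns):
        raise SchemaError("design columns do not match the training metadata")
    return expit(X @ fit.coefficients)
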