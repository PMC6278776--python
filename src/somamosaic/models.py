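"""Linear-model suite linking somatic instability, expansion size and onset.

The suite mirrors the standard modelling chain for DM1 somatic mosaicism:

* ``M8``  — log10(SI) ~ ePAL + AS: somatic instability explained by the
  progenitor allele length and age at sampling.  Its *standardised
  residual* quantifies individual-specific instability (the part not
  explained by length and age).
* ``M8_5prime`` — the same form fitted to the 5'-end view of interrupted
  expansions.
* ``M9``  — log10(AO) ~ ePAL: age at onset against progenitor length.
* ``M10`` — log10(AO) ~ log10(ePAL).
* ``M11`` — M10 plus the standardised SI residual from M8: tests whether
  individual-specific instability modifies onset beyond expansion size.
* ``INCR`` — observed modal-size increment ~ modal size + time interval
  between samplings.

Functional forms are configuration, not doctrine: each model is a
:class:`ModelSpec` (response/predictor transforms, optionally fixed
published coefficients) and any spec can be fitted with
:class:`RepeatRegression`, a statsmodels-backed model object whose
:meth:`~RepeatRegression.fit` returns a :class:`RegressionFit` results
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "DEFAULT_SPECS",
    "RepeatRegression",
    "RegressionFit",
    "attach_si_residual",
    "expected_increment",
    "standardize",
]

_TRANSFORMS = {
    "identity": (lambda x: x, lambda y: y),
    "log10": (np.log10, lambda y: np.power(10.0, y)),
    "ln": (np.log, np.exp),
}


def _forward(name: str):
    try:
        return _TRANSFORMS[name][0]
    except KeyError:
        raise ValueError(f"unknown transform {name!r}") from None


def _inverse(name: str):
    return _TRANSFORMS[name][1]


@dataclass(frozen=True)
class ModelSpec:
    """Design specification for one model of the suite.

    ``predictors`` is an ordered list of (column, transform) pairs;
    ``fixed_coefficients`` (intercept first) bypasses fitting, e.g. to use
    coefficients published from an external reference cohort.
    """

    name: str
    response: str
    response_transform: str = "identity"
    predictors: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    fixed_coefficients: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        _forward(self.response_transform)
        for _, t in self.predictors:
            _forward(t)
        if self.fixed_coefficients is not None and len(
            self.fixed_coefficients
        ) != len(self.predictors) + 1:
            raise ValueError(
                f"{self.name}: fixed_coefficients needs "
                f"{len(self.predictors) + 1} values (intercept first)"
            )

    def with_predictor(self, column: str, transform: str = "identity") -> "ModelSpec":
        return replace(
            self,
            predictors=self.predictors + ((column, transform),),
            fixed_coefficients=None,
        )

    @property
    def param_names(self) -> list[str]:
        return ["intercept"] + [
            (c if t == "identity" else f"{t}({c})") for c, t in self.predictors
        ]


SI_RESIDUAL_COLUMN = "si_residual"

DEFAULT_SPECS: dict[str, ModelSpec] = {
    "M8": ModelSpec(
        "M8", "si", "log10",
        (("epal", "identity"), ("age_at_sampling", "identity")),
    ),
    "M8_5prime": ModelSpec(
        "M8_5prime", "si_5prime", "log10",
        (("epal_5prime", "identity"), ("age_at_sampling", "identity")),
    ),
    "M9": ModelSpec("M9", "age_at_onset", "log10", (("epal", "identity"),)),
    "M10": ModelSpec("M10", "age_at_onset", "log10", (("epal", "log10"),)),
    "M11": ModelSpec(
        "M11", "age_at_onset", "log10",
        (("epal", "log10"), (SI_RESIDUAL_COLUMN, "identity")),
    ),
    "INCR": ModelSpec(
        "INCR", "observed_increment", "identity",
        (("mode", "identity"), ("interval", "identity")),
    ),
}


def standardize(values: np.ndarray) -> np.ndarray:
    """Centre to mean 0 and scale to sample SD 1 (ddof=1)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (values - values.mean()) / sd


class RepeatRegression:
    """OLS model for one :class:`ModelSpec` on a per-subject cohort table.

    Parameters
    ----------
    spec : ModelSpec
    data : pandas.DataFrame
        One row per subject; must contain the spec's response and predictor
        columns.  The index identifies subjects.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        missing = [
            c
            for c in [spec.response] + [c for c, _ in spec.predictors]
            if c not in data.columns
        ]
        if missing:
            raise ValueError(f"{spec.name}: data lacks columns {missing}")
        cols = [spec.response] + [c for c, _ in spec.predictors]
        self.data = data.loc[:, cols].dropna()
        n, p = len(self.data), len(spec.predictors)
        if n < p + 2:
            raise ValueError(
                f"{spec.name}: needs at least {p + 2} complete rows, got {n}"
            )
        self._validate_positive(spec.response, spec.response_transform)
        for c, t in spec.predictors:
            self._validate_positive(c, t)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, spec: ModelSpec | str
    ) -> "RepeatRegression":
        if isinstance(spec, str):
            spec = DEFAULT_SPECS[spec]
        return cls(spec, data)

    def _validate_positive(self, column: str, transform: str) -> None:
        if transform in ("log10", "ln"):
            bad = self.data.index[self.data[column] <= 0].tolist()
            if bad:
                raise ValueError(
                    f"{self.spec.name}: non-positive {column} under "
                    f"{transform} for subjects {bad[:10]}"
                )

    def _design(self, data: pd.DataFrame) -> np.ndarray:
        cols = [
            _forward(t)(data[c].to_numpy(dtype=float))
            for c, t in self.spec.predictors
        ]
        return sm.add_constant(np.column_stack(cols) if cols else
                               np.empty((len(data), 0)), has_constant="add")

    def fit(self) -> "RegressionFit":
        """Ordinary least squares on the transformed variables."""
        y = _forward(self.spec.response_transform)(
            self.data[self.spec.response].to_numpy(dtype=float)
        )
        X = self._design(self.data)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"{self.spec.name}: design matrix is rank deficient")
        if self.spec.fixed_coefficients is not None:
            beta = np.asarray(self.spec.fixed_coefficients, dtype=float)
            fitted = X @ beta
            resid = y - fitted
            ss_res = float(resid @ resid)
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
            bse = np.full_like(beta, np.nan)
        else:
            res = sm.OLS(y, X).fit()
            beta, bse = res.params, res.bse
            fitted, resid, r2 = res.fittedvalues, res.resid, float(res.rsquared)
        return RegressionFit(
            spec=self.spec,
            model=self,
            params=np.asarray(beta, dtype=float),
            bse=np.asarray(bse, dtype=float),
            r_squared=float(r2),
            fitted_transformed=pd.Series(fitted, index=self.data.index),
            residuals=pd.Series(resid, index=self.data.index),
        )


@dataclass
class RegressionFit:
    """Results of fitting (or evaluating) one model spec.

    Residuals live on the response's *transformed* scale;
    ``std_residuals`` are scaled to mean 0, SD 1 over the fit cohort.
    """

    spec: ModelSpec
    model: RepeatRegression | None
    params: np.ndarray
    bse: np.ndarray
    r_squared: float
    fitted_transformed: pd.Series
    residuals: pd.Series

    def __post_init__(self) -> None:
        resid = self.residuals.to_numpy()
        if resid.std(ddof=1) == 0:
            # perfect fit (or fixed coefficients reproducing the data)
            std = np.zeros_like(resid)
        else:
            std = standardize(resid)
        self.std_residuals = pd.Series(std, index=self.residuals.index)

    @property
    def n(self) -> int:
        return len(self.residuals)

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        missing = [c for c, _ in self.spec.predictors if c not in data.columns]
        if missing:
            raise ValueError(f"{self.spec.name}: subjects lack predictors {missing}")
        sub = data.loc[:, [c for c, _ in self.spec.predictors]]
        if sub.isna().any().any():
            bad = sub.index[sub.isna().any(axis=1)].tolist()
            raise ValueError(
                f"{self.spec.name}: missing predictor values for {bad[:10]}"
            )
        cols = [
            _forward(t)(sub[c].to_numpy(dtype=float))
            for c, t in self.spec.predictors
        ]
        X = np.column_stack([np.ones(len(sub))] + cols)
        return X @ self.params

    def predict(self, data: pd.DataFrame) -> pd.Series:
        """Expected response on the natural scale (inverse transform of the
        linear predictor)."""
        eta = self.linear_predictor(data)
        return pd.Series(_inverse(self.spec.response_transform)(eta),
                         index=data.index)

    def summary(self) -> str:
        lines = [
            f"Model {self.spec.name}: "
            f"{self.spec.response_transform}({self.spec.response}) ~ "
            + " + ".join(self.spec.param_names[1:] or ["1"]),
            f"n = {self.n}    R^2 = {self.r_squared:.4f}",
            f"{'term':<22}{'coef':>12}{'se':>12}",
        ]
        for name, b, se in zip(self.spec.param_names, self.params, self.bse):
            se_txt = f"{se:>12.4g}" if np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<22}{b:>12.4g}{se_txt}")
        return "\n".join(lines)


def attach_si_residual(
    cohort: pd.DataFrame, fit_m8: RegressionFit, column: str = SI_RESIDUAL_COLUMN
) -> pd.DataFrame:
    """Attach each subject's standardised instability residual as a covariate.

    Every subject of ``cohort`` must be present in the M8 fit; the attached
    column feeds model M11.
    """
    missing = [i for i in cohort.index if i not in fit_m8.std_residuals.index]
    if missing:
        raise ValueError(
            f"subjects missing from {fit_m8.spec.name} fit: {missing[:10]}"
        )
    out = cohort.copy()
    out[column] = fit_m8.std_residuals.reindex(cohort.index)
    return out


def expected_increment(
    fit_or_spec: RegressionFit | ModelSpec, mode: float, interval: float
) -> float:
    """Expected modal-size increment from the increment model.

    Accepts either a fitted ``INCR`` model or a spec carrying fixed
    coefficients (intercept, mode, interval).
    """
    if isinstance(fit_or_spec, RegressionFit):
        fit = fit_or_spec
    elif fit_or_spec.fixed_coefficients is not None:
        b0, b1, b2 = fit_or_spec.fixed_coefficients
        return float(b0 + b1 * mode + b2 * interval)
    else:
        raise ValueError(
            "expected_increment needs a fitted model or fixed coefficients"
        )
    data = pd.DataFrame({"mode": [mode], "interval": [interval]})
    return float(fit.predict(data).iloc[0])
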