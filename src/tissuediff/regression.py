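"""Second-order (response-surface) regression of diffusion on morphology.

Each tissue specimen carries a six-part morphological composition
(parenchyma P, stroma St, adipose tissue AT, pericellular edema PCE,
perivascular edema PVE, vessels V, as percentages of a histological
section).  The diffusion parameters of the two-phase water model are
modelled as second-order polynomials of five of those constituents (PVE is
excluded because it is determined by the others):

    y = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 [+ sum_{i<j} b_ij x_i x_j]

fitted by ordinary least squares.  Two designs are exposed:

* ``pure_quadratic`` — intercept, linear and squared terms only; used for
  the five morphology predictors (11 coefficients).
* ``full_second_order`` — adds pairwise products; used for the 2-3 diffusion
  predictors (6 or 10 coefficients).

Unit contract: the regression layer always works on *scaled* diffusion
values — fast diffusivity in 1e-9 m^2/s, slow diffusivity in 1e-11 m^2/s
(numeric magnitudes ~0.3-4) — and raw composition percentages.  The
published coefficient sets apply to these scales; no standardization is
performed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import (
    CollinearityError,
    InvalidInputError,
    UnderdeterminedDesignError,
)

__all__ = [
    "SCALE_FAST",
    "SCALE_SLOW",
    "Composition",
    "QuadraticModel",
    "QuadraticSurface",
    "build_design",
    "design_term_names",
    "fit_quadratic",
    "evaluate_model",
    "printed_predictors",
    "load_printed_coefficients",
]

#: Multiply an SI fast diffusivity (m^2/s) by this to get scaled units (1e-9).
SCALE_FAST = 1e9
#: Multiply an SI slow diffusivity (m^2/s) by this to get scaled units (1e-11).
SCALE_SLOW = 1e11

MORPHOLOGY_PREDICTORS = ("P", "St", "AT", "PCE", "V")


@dataclass(frozen=True)
class Composition:
    """Six-part morphological composition of one specimen, in percent.

    ``predictors()`` returns the five regression inputs (P, St, AT, PCE, V);
    perivascular edema is carried along but never enters a design.
    """

    parenchyma: float
    stroma: float
    adipose: float
    pce: float
    pve: float
    vessels: float

    def __post_init__(self):
        vals = self.as_array(include_pve=True)
        if np.any(vals < 0) or np.any(vals > 100):
            raise InvalidInputError(f"composition percentages must lie in [0, 100]: {vals}")
        if vals.sum() > 100.5:  # 0.5 slack for rounded inputs
            raise InvalidInputError(
                f"composition percentages sum to {vals.sum():.2f} > 100.5"
            )

    def as_array(self, include_pve: bool = True) -> np.ndarray:
        if include_pve:
            return np.array(
                [self.parenchyma, self.stroma, self.adipose, self.pce, self.pve, self.vessels]
            )
        return self.predictors()

    def predictors(self) -> np.ndarray:
        """Regression inputs (P, St, AT, PCE, V) — PVE excluded."""
        return np.array(
            [self.parenchyma, self.stroma, self.adipose, self.pce, self.vessels]
        )


def design_term_names(feature_names: list[str], design_kind: str) -> list[str]:
    """Ordered term labels: intercept, linears, squares[, pairwise products]."""
    names = ["intercept"] + list(feature_names) + [f"{n}^2" for n in feature_names]
    if design_kind == "full_second_order":
        k = len(feature_names)
        names += [
            f"{feature_names[i]}*{feature_names[j]}"
            for i in range(k)
            for j in range(i + 1, k)
        ]
    elif design_kind != "pure_quadratic":
        raise InvalidInputError(f"unknown design_kind {design_kind!r}")
    return names


def build_design(rows, design_kind: str = "pure_quadratic") -> np.ndarray:
    """Second-order design matrix.

    Columns are ordered: intercept, linear terms in input order, squared
    terms in input order, then (``full_second_order`` only) pairwise
    products x_i * x_j for i < j in lexicographic order of (i, j).
    """
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InvalidInputError("rows must form a 2-D array with k >= 1 predictors")
    n, k = X.shape
    cols = [np.ones(n), *(X[:, i] for i in range(k)), *(X[:, i] ** 2 for i in range(k))]
    if design_kind == "full_second_order":
        cols += [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)]
    elif design_kind != "pure_quadratic":
        raise InvalidInputError(f"unknown design_kind {design_kind!r}")
    return np.column_stack(cols)


@dataclass(frozen=True)
class QuadraticModel:
    """A second-order coefficient set, fitted or transcribed from print.

    ``r_squared`` is the coefficient of determination; for transcribed
    fixtures it is the published value (``source='printed'``).
    """

    design_kind: str
    term_names: tuple[str, ...]
    coefficients: np.ndarray
    feature_names: tuple[str, ...]
    response_name: str = "response"
    response_units: str = ""
    r_squared: float | None = None
    source: str = "fitted"
    p_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        expected = design_term_names(list(self.feature_names), self.design_kind)
        if list(self.term_names) != expected:
            raise InvalidInputError(
                f"term_names do not match the {self.design_kind} layout: "
                f"expected {expected}, got {list(self.term_names)}"
            )
        if coef.size != len(expected):
            raise InvalidInputError(
                f"{len(expected)} coefficients required, got {coef.size}"
            )

    def evaluate(self, x) -> float | np.ndarray:
        """Predicted response at predictor vector(s) ``x``."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        rows = x.reshape(1, -1) if single else x
        if rows.shape[1] != len(self.feature_names):
            raise InvalidInputError(
                f"expected {len(self.feature_names)} predictors, got {rows.shape[1]}"
            )
        out = build_design(rows, self.design_kind) @ self.coefficients
        return float(out[0]) if single else out


class QuadraticSurface(RegressorMixin, BaseEstimator):
    """Ordinary least-squares second-order response surface.

    Parameters
    ----------
    design : {"pure_quadratic", "full_second_order"}
    feature_names : sequence of str, optional
        Labels for the predictors; defaults to x1..xk at fit time.

    Attributes
    ----------
    coef_ : ndarray
        Coefficients aligned with ``term_names_``.
    r_squared_ : float
        1 - SS_res/SS_tot (0 by convention for a constant response).
    p_values_ : ndarray
        Classical OLS t-test p-values per coefficient, reported for
        information only; no term pruning is performed.
    model_ : QuadraticModel
    """

    def __init__(self, design: str = "pure_quadratic", feature_names=None):
        self.design = design
        self.feature_names = feature_names

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.shape[0] != y.size:
            raise InvalidInputError("X and y have inconsistent lengths")
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"x{i+1}" for i in range(X.shape[1])]
        )
        if len(names) != X.shape[1]:
            raise InvalidInputError("feature_names length does not match X")
        D = build_design(X, self.design)
        terms = design_term_names(names, self.design)
        n, p = D.shape
        if n <= p:
            raise UnderdeterminedDesignError(
                f"need more observations than design columns: n={n}, columns={p}"
            )
        rank = np.linalg.matrix_rank(D)
        if rank < p:
            # QR with column pivoting: pivots beyond the rank are the
            # columns that are linear combinations of earlier ones.
            _, _, piv = linalg.qr(D, mode="economic", pivoting=True)
            offending = sorted(terms[j] for j in piv[rank:])
            raise CollinearityError(
                f"rank-deficient design (rank {rank} < {p}); "
                f"offending columns: {offending}",
                columns=offending,
            )
        ols = sm.OLS(y, D).fit()
        self.coef_ = np.asarray(ols.params, dtype=float)
        self.term_names_ = tuple(terms)
        self.feature_names_ = tuple(names)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            self.r_squared_ = 0.0  # constant response: R^2 defined as 0
        else:
            self.r_squared_ = float(ols.rsquared)
        self.p_values_ = np.asarray(ols.pvalues, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.model_ = QuadraticModel(
            design_kind=self.design,
            term_names=self.term_names_,
            coefficients=self.coef_,
            feature_names=self.feature_names_,
            r_squared=self.r_squared_,
            source="fitted",
            p_values=self.p_values_,
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        return build_design(X, self.design) @ self.coef_


def fit_quadratic(
    X, y, design_kind: str = "pure_quadratic", feature_names=None,
    response_name: str = "response", response_units: str = "",
) -> QuadraticModel:
    """OLS second-order fit; thin wrapper over :class:`QuadraticSurface`."""
    est = QuadraticSurface(design=design_kind, feature_names=feature_names).fit(X, y)
    m = est.model_
    return QuadraticModel(
        design_kind=m.design_kind,
        term_names=m.term_names,
        coefficients=m.coefficients,
        feature_names=m.feature_names,
        response_name=response_name,
        response_units=response_units,
        r_squared=m.r_squared,
        source="fitted",
        p_values=m.p_values,
    )


def evaluate_model(model: QuadraticModel, x) -> float | np.ndarray:
    """Predicted response at ``x``; see :meth:`QuadraticModel.evaluate`."""
    return model.evaluate(x)


_MODEL_META = {
    "d_fast": dict(
        design="pure_quadratic", features=MORPHOLOGY_PREDICTORS,
        units="1e-9 m^2/s", r2=0.92,
    ),
    "d_slow": dict(
        design="pure_quadratic", features=MORPHOLOGY_PREDICTORS,
        units="1e-11 m^2/s", r2=0.81,
    ),
    "p1": dict(
        design="pure_quadratic", features=MORPHOLOGY_PREDICTORS,
        units="", r2=0.93,
    ),
    "canp_morphology": dict(
        design="pure_quadratic", features=MORPHOLOGY_PREDICTORS,
        units="", r2=0.66,
    ),
    "canp_diffusion2": dict(
        design="full_second_order", features=("D_FDP", "D_SDP"),
        units="", r2=0.69,
    ),
    "canp_diffusion3": dict(
        design="full_second_order", features=("D_FDP", "D_SDP", "P1"),
        units="", r2=0.85,
    ),
}


def load_printed_coefficients() -> dict[str, QuadraticModel]:
    """All transcribed coefficient sets, keyed by model name.

    Read from the shipped plain-text fixture (``data/printed_coefficients.tsv``)
    so the transcription is auditable; coefficients are reordered into the
    canonical design layout.
    """
    raw: dict[str, dict[str, float]] = {}
    path = importlib.resources.files("tissuediff.data") / "printed_coefficients.tsv"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        model, term, value = line.split("\t")
        raw.setdefault(model, {})[term] = float(value)
    out = {}
    for name, meta in _MODEL_META.items():
        terms = design_term_names(list(meta["features"]), meta["design"])
        coefs = raw[name]
        missing = set(terms) - set(coefs)
        extra = set(coefs) - set(terms)
        if missing or extra:
            raise InvalidInputError(
                f"coefficient file mismatch for {name!r}: missing {missing}, extra {extra}"
            )
        out[name] = QuadraticModel(
            design_kind=meta["design"],
            term_names=tuple(terms),
            coefficients=np.array([coefs[t] for t in terms]),
            feature_names=tuple(meta["features"]),
            response_name=name,
            response_units=meta["units"],
            r_squared=meta["r2"],
            source="printed",
        )
    return out


def printed_predictors() -> dict[str, QuadraticModel]:
    """The three published morphology -> diffusion predictors.

    Keys ``d_fast`` (response in 1e-9 m^2/s), ``d_slow`` (1e-11 m^2/s) and
    ``p1`` (dimensionless), each a pure-quadratic function of
    (P, St, AT, PCE, V) with 11 coefficients.
    """
    models = load_printed_coefficients()
    return {k: models[k] for k in ("d_fast", "d_slow", "p1")}
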