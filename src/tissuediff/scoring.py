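"""Malignancy scoring from morphology or water-diffusion parameters.

The malignancy score CanP is a second-order polynomial surface evaluated on
one of three predictor sets:

* ``morphology``  — (P, St, AT, PCE, V) constituent percentages,
  pure-quadratic design;
* ``diffusion2``  — (D_FDP in 1e-9 m^2/s, D_SDP in 1e-11 m^2/s),
  full second-order design;
* ``diffusion3``  — (D_FDP, D_SDP, P1), full second-order design.

The raw polynomial value is interpreted on a 0 -> 1 probability scale, so it
is clamped to [0, 1]; the clamp is what produces the flat saturation regions
of the published response surfaces.  A specimen is called malignant when the
clamped probability reaches the decision threshold (default 0.5).

Training uses a linear-probability OLS fit of the 0/1 malignancy label on
the variant's design — the same procedure that produced the published
coefficient sets — not logistic regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import DegenerateLabelsError, InvalidInputError
from .regression import (
    QuadraticModel,
    QuadraticSurface,
    load_printed_coefficients,
)

__all__ = [
    "VARIANTS",
    "ScoreResult",
    "CancerProbabilityScorer",
    "score",
    "fit_canp",
    "surface_grid",
    "printed_scorers",
]

#: Predictor list and design per scoring variant.
VARIANTS = {
    "morphology": dict(
        features=("P", "St", "AT", "PCE", "V"), design="pure_quadratic"
    ),
    "diffusion2": dict(features=("D_FDP", "D_SDP"), design="full_second_order"),
    "diffusion3": dict(features=("D_FDP", "D_SDP", "P1"), design="full_second_order"),
}

_PRINTED_KEY = {
    "morphology": "canp_morphology",
    "diffusion2": "canp_diffusion2",
    "diffusion3": "canp_diffusion3",
}


@dataclass(frozen=True)
class ScoreResult:
    """One scored specimen: raw polynomial value, clamped probability, label."""

    raw_score: float
    probability: float
    label: str  # "malignant" | "nonmalignant"


def _check_variant(variant: str) -> dict:
    if variant not in VARIANTS:
        raise InvalidInputError(
            f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}"
        )
    return VARIANTS[variant]


class CancerProbabilityScorer(ClassifierMixin, BaseEstimator):
    """Quadratic-surface malignancy scorer with probability clamping.

    Parameters
    ----------
    variant : {"morphology", "diffusion2", "diffusion3"}
    threshold : float, default 0.5
        Clamped probability at or above which a specimen is called malignant.

    Attributes
    ----------
    model_ : QuadraticModel
        The coefficient surface, either fitted or installed from print.
    classes_ : ndarray
        ``[0, 1]`` (nonmalignant, malignant).
    """

    def __init__(self, variant: str = "diffusion2", threshold: float = 0.5):
        self.variant = variant
        self.threshold = threshold

    # -- construction from the published coefficient sets ------------------
    @classmethod
    def from_printed(cls, variant: str, threshold: float = 0.5) -> "CancerProbabilityScorer":
        """Scorer carrying the published coefficient set for ``variant``."""
        _check_variant(variant)
        est = cls(variant=variant, threshold=threshold)
        est._install(load_printed_coefficients()[_PRINTED_KEY[variant]])
        return est

    def _install(self, model: QuadraticModel):
        spec = _check_variant(self.variant)
        if tuple(model.feature_names) != spec["features"]:
            raise InvalidInputError(
                f"model features {model.feature_names} do not match variant "
                f"{self.variant!r} ({spec['features']})"
            )
        self.model_ = model
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(spec["features"])
        return self

    # -- training -----------------------------------------------------------
    def fit(self, X, y):
        """Linear-probability OLS of 0/1 labels on the variant's design."""
        spec = _check_variant(self.variant)
        y = np.asarray(y, dtype=float).reshape(-1)
        if np.unique(y).size < 2:
            raise DegenerateLabelsError("training labels contain a single class")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise InvalidInputError("labels must be 0 (nonmalignant) / 1 (malignant)")
        surf = QuadraticSurface(
            design=spec["design"], feature_names=list(spec["features"])
        ).fit(X, y)
        model = QuadraticModel(
            design_kind=surf.model_.design_kind,
            term_names=surf.model_.term_names,
            coefficients=surf.model_.coefficients,
            feature_names=surf.model_.feature_names,
            response_name=f"canp_{self.variant}",
            r_squared=surf.r_squared_,
            source="fitted",
            p_values=surf.p_values_,
        )
        return self._install(model)

    # -- inference ----------------------------------------------------------
    def _rows(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        rows = X.reshape(1, -1) if X.ndim == 1 else X
        if rows.shape[1] != self.n_features_in_:
            raise InvalidInputError(
                f"expected {self.n_features_in_} predictors, got {rows.shape[1]}"
            )
        if self.variant in ("diffusion2", "diffusion3"):
            d = rows[:, :2]  # heuristic unit check on the two diffusivities
            if np.any((np.abs(d) > 0) & ((np.abs(d) < 0.01) | (np.abs(d) > 100))):
                warnings.warn(
                    "diffusion inputs outside [0.01, 100]: expected scaled "
                    "units (1e-9 / 1e-11 m^2/s), not SI",
                    stacklevel=3,
                )
        return rows

    def decision_function(self, X) -> np.ndarray:
        """Raw (unclamped) polynomial scores."""
        return np.asarray(self.model_.evaluate(self._rows(X)), dtype=float)

    def predict_probability(self, X) -> np.ndarray:
        """Scores clamped to the [0, 1] probability scale."""
        return np.clip(self.decision_function(X), 0.0, 1.0)

    def predict(self, X) -> np.ndarray:
        """1 (malignant) where clamped probability >= threshold, else 0."""
        return (self.predict_probability(X) >= self.threshold).astype(int)

    def score_one(self, x) -> ScoreResult:
        """Full :class:`ScoreResult` for a single predictor vector."""
        raw = float(self.decision_function(np.asarray(x, dtype=float).reshape(1, -1))[0])
        prob = min(1.0, max(0.0, raw))
        label = "malignant" if prob >= self.threshold else "nonmalignant"
        return ScoreResult(raw_score=raw, probability=prob, label=label)


def printed_scorers(threshold: float = 0.5) -> dict[str, CancerProbabilityScorer]:
    """All three published scoring variants, keyed by variant name."""
    return {
        v: CancerProbabilityScorer.from_printed(v, threshold=threshold) for v in VARIANTS
    }


def score(scorer: CancerProbabilityScorer, x) -> ScoreResult:
    """Score a single specimen; see :meth:`CancerProbabilityScorer.score_one`."""
    return scorer.score_one(x)


def fit_canp(X, labels, variant: str, threshold: float = 0.5) -> CancerProbabilityScorer:
    """Train a malignancy scorer on 0/1 labels; thin wrapper over ``fit``."""
    return CancerProbabilityScorer(variant=variant, threshold=threshold).fit(X, labels)


def surface_grid(
    scorer: CancerProbabilityScorer,
    axis1: tuple[str, float, float],
    axis2: tuple[str, float, float],
    fixed: dict[str, float] | None = None,
    n: int = 50,
):
    """Clamped-probability surface over a regular 2-D predictor grid.

    ``axis1``/``axis2`` are ``(predictor_name, low, high)``; every remaining
    predictor of the variant is held at its value in ``fixed`` (for the
    published figures these were the whole-cohort means).  Returns
    ``(values1, values2, grid)`` with ``grid[i, j]`` the probability at
    ``values1[i]``, ``values2[j]``; all entries lie in [0, 1].
    """
    if n < 2:
        raise InvalidInputError("grid size must be >= 2 per axis")
    features = list(scorer.model_.feature_names)
    (name1, lo1, hi1), (name2, lo2, hi2) = axis1, axis2
    if name1 == name2:
        raise InvalidInputError(f"duplicated axis {name1!r}")
    for nm in (name1, name2):
        if nm not in features:
            raise InvalidInputError(f"unknown predictor {nm!r}; variant uses {features}")
    if not (np.isfinite([lo1, hi1, lo2, hi2]).all()):
        raise InvalidInputError("axis ranges must be finite")
    fixed = dict(fixed or {})
    missing = [f for f in features if f not in (name1, name2) and f not in fixed]
    if missing:
        raise InvalidInputError(f"no fixed value supplied for {missing}")

    v1 = np.linspace(lo1, hi1, n)
    v2 = np.linspace(lo2, hi2, n)
    G1, G2 = np.meshgrid(v1, v2, indexing="ij")
    rows = np.empty((n * n, len(features)))
    for j, f in enumerate(features):
        if f == name1:
            rows[:, j] = G1.ravel()
        elif f == name2:
            rows[:, j] = G2.ravel()
        else:
            rows[:, j] = fixed[f]
    probs = scorer.predict_probability(rows).reshape(n, n)
    return v1, v2, probs
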