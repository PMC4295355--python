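"""Synthetic specimen cohort emulating the in-vitro breast-tissue study.

The study design is two groups — control (mastopathy / peritumoral tissue,
n = 6) and breast cancer (T2 tumors, n = 11; 6 T2N0M0 + 5 T2N1M0) — each
specimen carrying a six-part morphological composition (percent of a
histological section) and two-phase water diffusion parameters.  Only
per-group summary statistics (mean, SD, range) of those variables are
available, so the generator reproduces the printed marginals, not the real
joint distribution.

Compositions: the six constituent percentages of a section are exhaustive
(group means sum to ~100), so each specimen is drawn as the group mean
vector plus a zero-sum Gaussian deviation (per-variable scale = printed SD,
excess allocated across variables in proportion to their variances),
rejected until every constituent lies inside its printed range.  This keeps
the printed means and ranges and the <= 100% closure simultaneously;
independent truncated normals cannot, because truncation inflates each mean
and pushes the expected sum well above 100.

Diffusion parameters, two modes:

* ``group_parameter`` — independent truncated normals per group with the
  printed mean/SD/range (fast diffusivity in 1e-9 m^2/s, slow in 1e-11,
  fast-phase population as a fraction).
* ``equation_driven`` — responses computed from the published second-order
  morphology predictors at the sampled composition, plus Gaussian residuals
  whose variance is calibrated once per cohort to hit a target R^2:
  sigma^2 = Var(predicted) * (1 - R^2) / R^2.

Every specimen can carry a simulated PFG decay curve on the extended
b-value grid.  Generation is fully deterministic given the seed, with
per-specimen streams independent of group ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigError
from .regression import Composition, QuadraticModel, printed_predictors
from .signal import CompartmentSet, DecayCurve, extended_b_grid, synthesize_on_grid

__all__ = [
    "VariableParams",
    "GroupParams",
    "CohortConfig",
    "Specimen",
    "CONTROL_GROUP",
    "CANCER_GROUP",
    "TNM_OVERRIDES",
    "DEFAULT_TARGET_R2",
    "sample_composition",
    "sample_compartments",
    "generate_cohort",
    "specimen_frame",
]


@dataclass(frozen=True)
class VariableParams:
    """Printed summary of one variable: mean, SD and admissible range."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self):
        if self.min > self.max:
            raise ConfigError(f"infeasible bounds: min {self.min} > max {self.max}")
        if not self.min <= self.mean <= self.max:
            raise ConfigError(f"mean {self.mean} outside [{self.min}, {self.max}]")
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")

    def truncnorm_mean(self) -> float:
        """Mean of the truncated normal with these parameters."""
        if self.sd == 0:
            return self.mean
        a = (self.min - self.mean) / self.sd
        b = (self.max - self.mean) / self.sd
        return float(sps.truncnorm.mean(a, b, loc=self.mean, scale=self.sd))


COMPOSITION_VARS = ("p", "st", "at", "pce", "pve", "v")
DIFFUSION_VARS = ("d_fast", "d_slow", "p1")  # scaled units: 1e-9, 1e-11, share


@dataclass(frozen=True)
class GroupParams:
    """Per-group generation parameters for composition and diffusion."""

    group: str
    n: int
    composition: dict[str, VariableParams]
    diffusion: dict[str, VariableParams]

    def __post_init__(self):
        for key in COMPOSITION_VARS:
            if key not in self.composition:
                raise ConfigError(f"group {self.group!r} missing composition var {key!r}")
        for key in DIFFUSION_VARS:
            if key not in self.diffusion:
                raise ConfigError(f"group {self.group!r} missing diffusion var {key!r}")
        if self.n < 0:
            raise ConfigError("group size must be >= 0")


# Printed group parameters: morphometry (percent of section) and diffusion
# (d_fast in 1e-9 m^2/s, d_slow in 1e-11 m^2/s, p1 as a share).
CONTROL_GROUP = GroupParams(
    group="control",
    n=6,
    composition={
        "p": VariableParams(16.7, 19.7, 0.01, 54.7),
        "st": VariableParams(35.7, 8.8, 25.5, 49.0),
        "at": VariableParams(32.6, 21.0, 0.01, 53.8),
        "pce": VariableParams(4.0, 6.4, 0.01, 17.0),
        "pve": VariableParams(5.9, 5.8, 0.01, 13.6),
        "v": VariableParams(5.1, 4.9, 0.2, 14.1),
    },
    diffusion={
        "d_fast": VariableParams(1.25, 0.13, 1.10, 1.40),
        "d_slow": VariableParams(1.67, 0.15, 0.50, 1.91),
        "p1": VariableParams(0.48, 0.17, 0.27, 0.77),
    },
)

# NOTE: the printed whole-cancer-group slow diffusivity (0.86 +/- 0.68,
# range 0.40-3.84, 1e-11 m^2/s) sits below both printed TNM sub-group means
# (1.75, 2.00); the transcription keeps the printed numbers verbatim.
CANCER_GROUP = GroupParams(
    group="cancer",
    n=11,
    composition={
        "p": VariableParams(30.7, 15.7, 10.3, 56.6),
        "st": VariableParams(39.9, 13.6, 26.1, 64.2),
        "at": VariableParams(11.6, 16.1, 0.01, 50.4),
        "pce": VariableParams(7.1, 6.9, 0.01, 16.0),
        "pve": VariableParams(7.5, 11.1, 0.01, 32.3),
        "v": VariableParams(3.1, 2.6, 0.1, 7.3),
    },
    diffusion={
        "d_fast": VariableParams(0.97, 0.25, 0.57, 1.25),
        "d_slow": VariableParams(0.86, 0.68, 0.40, 3.84),
        "p1": VariableParams(0.75, 0.22, 0.23, 0.97),
    },
)

#: Optional diffusion overrides for the TNM sub-cohorts of the cancer group.
TNM_OVERRIDES = {
    "T2N0M0": {
        "d_fast": VariableParams(0.93, 0.24, 0.60, 1.20),
        "d_slow": VariableParams(1.75, 0.17, 1.50, 1.98),
        "p1": VariableParams(0.74, 0.28, 0.23, 0.97),
    },
    "T2N1M0": {
        "d_fast": VariableParams(1.01, 0.28, 0.57, 1.29),
        "d_slow": VariableParams(2.00, 1.03, 1.40, 3.84),
        "p1": VariableParams(0.78, 0.14, 0.63, 0.95),
    },
}

#: Published determination coefficients of the morphology -> diffusion fits,
#: used as the default residual-calibration targets in equation-driven mode.
DEFAULT_TARGET_R2 = {"d_fast": 0.92, "d_slow": 0.81, "p1": 0.93}


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of one synthetic cohort.

    ``mode`` is ``group_parameter`` (diffusion sampled from the printed
    group statistics) or ``equation_driven`` (diffusion computed from the
    published morphology predictors with R^2-calibrated residuals).
    ``noise_sigma`` is the additive amplitude noise of the decay curves.
    """

    groups: tuple[GroupParams, ...] = (CONTROL_GROUP, CANCER_GROUP)
    mode: str = "group_parameter"
    target_r2: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TARGET_R2))
    noise_sigma: float = 0.005
    seed: int = 0
    with_curves: bool = True
    curve_n_steps: int = 25

    def __post_init__(self):
        if self.mode not in ("group_parameter", "equation_driven"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for k, v in self.target_r2.items():
            if not 0 < v <= 1:
                raise ConfigError(f"target_r2[{k!r}] must lie in (0, 1], got {v}")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")

    def resize(self, n_control: int | None = None, n_cancer: int | None = None):
        """Copy of the config with overridden group sizes."""
        groups = []
        for gp in self.groups:
            if gp.group == "control" and n_control is not None:
                gp = replace(gp, n=n_control)
            if gp.group == "cancer" and n_cancer is not None:
                gp = replace(gp, n=n_cancer)
            groups.append(gp)
        return replace(self, groups=tuple(groups))


@dataclass
class Specimen:
    """One synthetic specimen: labels, composition, true diffusion, curve."""

    specimen_id: str
    group: str
    tnm: str
    stroma_class: str
    composition: Composition
    d_fast_1e9: float
    d_slow_1e11: float
    p1: float
    curve: DecayCurve | None = None

    @property
    def true_compartments(self) -> CompartmentSet:
        return CompartmentSet(
            d_fast=self.d_fast_1e9 * 1e-9,
            d_slow=self.d_slow_1e11 * 1e-11,
            p1=self.p1,
        )

    @property
    def adc_1e9(self) -> float:
        """Population-weighted ADC of the true compartments, 1e-9 m^2/s."""
        return self.p1 * self.d_fast_1e9 + (1 - self.p1) * self.d_slow_1e11 * 1e-2


_GROUP_CODE = {"control": 0, "cancer": 1}


def _stream(seed: int, group: str, index: int, stage: int) -> np.random.Generator:
    """Per-specimen, per-stage RNG stream, independent of group ordering."""
    code = _GROUP_CODE.get(group)
    if code is None:
        code = (abs(hash(group)) % 1000) + 2  # user-defined extra groups
    return np.random.default_rng([seed, code, index, stage])


def sample_composition(gp: GroupParams, rng: np.random.Generator) -> Composition:
    """Draw one six-part composition respecting printed means and ranges.

    Group mean vector plus a zero-sum deviation vector: each per-variable
    deviation is a normal of the printed SD truncated *symmetrically* to
    +/- min(mean - min, max - mean), so it has exactly zero mean and stays
    inside the printed range on both sides; the deviations are then
    projected to zero sum (excess allocated in proportion to the
    variances, so zero-SD variables stay fixed) and the draw is rejected
    if the projection pushed any constituent out of range.

    This keeps the printed group means (to within the small, roughly
    symmetric rejection effect), the printed ranges, and the <= 100%
    closure simultaneously; the cost is a narrower spread than the printed
    SD for strongly skewed variables (e.g. adipose tissue), where mean
    fidelity is preferred over SD fidelity.
    """
    params = [gp.composition[k] for k in COMPOSITION_VARS]
    m = np.array([p.mean for p in params])
    sd = np.array([p.sd for p in params])
    lo = np.array([p.min for p in params])
    hi = np.array([p.max for p in params])
    if m.sum() > 100.5:
        raise ConfigError(f"composition means sum to {m.sum():.2f} > 100.5")
    half_width = np.minimum(m - lo, hi - m)
    var = sd**2
    for _ in range(1000):
        z = np.zeros_like(sd)
        free = sd > 0
        if free.any():
            a = half_width[free] / sd[free]
            z[free] = sps.truncnorm.rvs(
                -a, a, loc=0.0, scale=sd[free], random_state=rng
            )
        if var.sum() > 0:
            z = z - var * z.sum() / var.sum()
        x = m + z
        if np.all(x >= lo) and np.all(x <= hi):
            return Composition(
                parenchyma=x[0], stroma=x[1], adipose=x[2], pce=x[3], pve=x[4], vessels=x[5]
            )
    raise ConfigError(
        f"composition sampling for group {gp.group!r} failed 1000 draws; "
        "check the mean/SD/range configuration"
    )


def _truncnorm_draw(vp: VariableParams, rng: np.random.Generator) -> float:
    if vp.sd == 0:
        return vp.mean
    a = (vp.min - vp.mean) / vp.sd
    b = (vp.max - vp.mean) / vp.sd
    return float(sps.truncnorm.rvs(a, b, loc=vp.mean, scale=vp.sd, random_state=rng))


def sample_compartments(
    gp: GroupParams,
    mode: str,
    composition: Composition,
    rng: np.random.Generator,
    residual_scale: dict[str, float] | None = None,
    models: dict[str, QuadraticModel] | None = None,
    max_tries: int = 100,
) -> dict[str, float]:
    """Draw (d_fast [1e-9], d_slow [1e-11], p1) for one specimen.

    ``group_parameter`` mode ignores the composition; ``equation_driven``
    mode evaluates the published predictors at it and adds Gaussian
    residuals of scale ``residual_scale`` (per response, calibrated by the
    caller).  The physical ordering d_fast > d_slow (in SI units) is
    enforced by redrawing, up to ``max_tries`` times.
    """
    if mode == "group_parameter":
        for _ in range(max_tries):
            vals = {k: _truncnorm_draw(gp.diffusion[k], rng) for k in DIFFUSION_VARS}
            if vals["d_fast"] * 1e-9 > vals["d_slow"] * 1e-11 > 0:
                return vals
        raise ConfigError("could not draw ordered diffusion parameters in 100 tries")
    if mode != "equation_driven":
        raise ConfigError(f"unknown mode {mode!r}")
    if models is None:
        models = printed_predictors()
    residual_scale = residual_scale or {k: 0.0 for k in DIFFUSION_VARS}
    x = composition.predictors()
    pred = {k: models[k].evaluate(x) for k in DIFFUSION_VARS}
    for _ in range(max_tries):
        vals = {k: pred[k] + rng.normal(0.0, residual_scale.get(k, 0.0)) for k in DIFFUSION_VARS}
        vals["p1"] = float(np.clip(vals["p1"], 0.01, 0.99))
        # The published surfaces are unconstrained polynomials and can dip
        # below zero at composition extremes; floor the diffusivities at a
        # small positive value (scaled units) to stay physical.
        vals["d_fast"] = float(max(vals["d_fast"], 0.05))
        vals["d_slow"] = float(max(vals["d_slow"], 0.05))
        if vals["d_fast"] * 1e-9 > vals["d_slow"] * 1e-11 > 0:
            return vals
    raise ConfigError("could not draw ordered diffusion parameters in 100 tries")


def _equation_residual_scales(
    compositions: list[Composition],
    target_r2: dict[str, float],
    models: dict[str, QuadraticModel],
) -> dict[str, float]:
    """Residual SD per response so the cohort hits the target R^2.

    With signal variance V = Var(predicted) over the sampled cohort and
    noise variance s^2, the population R^2 is V / (V + s^2); solving for
    s gives s = sqrt(V * (1 - R^2) / R^2).
    """
    X = np.array([c.predictors() for c in compositions])
    scales = {}
    for k in DIFFUSION_VARS:
        pred = np.asarray(models[k].evaluate(X), dtype=float)
        v = float(np.var(pred))
        r2 = target_r2.get(k, 1.0)
        scales[k] = float(np.sqrt(v * (1.0 - r2) / r2))
    return scales


def generate_cohort(config: CohortConfig) -> list[Specimen]:
    """Generate the full synthetic cohort, deterministic given the seed.

    Per-specimen RNG streams are keyed by (seed, group, index, stage) so the
    draws for one specimen do not depend on group ordering or on how many
    specimens precede it.  In equation-driven mode the residual scales are
    calibrated on the whole cohort's predicted responses before noise is
    added.  Decay curves (when ``with_curves``) are synthesized from each
    specimen's true compartments on the extended b grid.
    """
    models = printed_predictors() if config.mode == "equation_driven" else None

    # Stage 0: compositions for everyone.
    comps: list[tuple[GroupParams, int, Composition]] = []
    for gp in config.groups:
        for i in range(gp.n):
            comp = sample_composition(gp, _stream(config.seed, gp.group, i, 0))
            comps.append((gp, i, comp))

    residual_scale = None
    if config.mode == "equation_driven":
        residual_scale = _equation_residual_scales(
            [c for _, _, c in comps], config.target_r2, models
        )

    b_grid = extended_b_grid(config.curve_n_steps) if config.with_curves else None
    specimens: list[Specimen] = []
    for gp, i, comp in comps:
        vals = sample_compartments(
            gp,
            config.mode,
            comp,
            _stream(config.seed, gp.group, i, 1),
            residual_scale=residual_scale,
            models=models,
        )
        if gp.group == "cancer":
            tnm = "T2N0M0" if (i % 11) < 6 else "T2N1M0"  # 6:5 split per 11
        else:
            tnm = "none"
        sid = f"{gp.group}_{i + 1:03d}"
        spec = Specimen(
            specimen_id=sid,
            group=gp.group,
            tnm=tnm,
            stroma_class="ge50" if comp.stroma >= 50.0 else "lt50",
            composition=comp,
            d_fast_1e9=vals["d_fast"],
            d_slow_1e11=vals["d_slow"],
            p1=vals["p1"],
        )
        if config.with_curves:
            spec.curve = synthesize_on_grid(
                b_grid,
                spec.true_compartments,
                noise_sigma=config.noise_sigma,
                rng=_stream(config.seed, gp.group, i, 2),
                curve_id=sid,
            )
        specimens.append(spec)
    return specimens


def specimen_frame(specimens: list[Specimen]) -> pd.DataFrame:
    """Specimen table in the canonical column layout."""
    rows = []
    for s in specimens:
        c = s.composition
        rows.append(
            dict(
                specimen_id=s.specimen_id,
                group=s.group,
                tnm=s.tnm,
                stroma_class=s.stroma_class,
                p=c.parenchyma,
                st=c.stroma,
                at=c.adipose,
                pce=c.pce,
                pve=c.pve,
                v=c.vessels,
                d_fast_1e9=s.d_fast_1e9,
                d_slow_1e11=s.d_slow_1e11,
                p1=s.p1,
                adc_1e9=s.adc_1e9,
            )
        )
    return pd.DataFrame(rows)
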