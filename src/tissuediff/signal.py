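"""Forward model for pulsed-field-gradient (PFG) spin-echo diffusion decays.

A stimulated-echo PFG experiment encodes molecular displacement through a pair
of gradient pulses of amplitude ``g`` and duration ``delta`` separated by the
diffusion time ``t_d``.  The diffusion weighting is the Stejskal-Tanner factor

    b = gamma^2 * delta^2 * g^2 * t_d

and tissue water, treated as two phases in slow exchange (a fast diffusion
phase FDP and a slow diffusion phase SDP), attenuates the normalized echo
amplitude as

    A(b)/A(0) = p1 * exp(-b * D_fast) + (1 - p1) * exp(-b * D_slow)

with spin populations p1 + p2 = 1.  The population-weighted mean diffusivity

    ADC = p1 * D_fast + (1 - p1) * D_slow

is what an initial-slope measurement of the decay returns.

All quantities in this module are SI: diffusivities in m^2/s, b-values in
s/m^2, gradients in T/m, times in s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "GAMMA_PROTON",
    "WATER_STANDARD_D",
    "PulseSequenceParams",
    "CompartmentSet",
    "DecayCurve",
    "compute_b_value",
    "biexp_signal",
    "weighted_adc",
    "synthesize_curve",
    "synthesize_on_grid",
    "default_acquisition",
    "extended_acquisitions",
    "extended_b_grid",
    "water_standard_curve",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.675e8

#: Self-diffusion coefficient of the water calibration standard, m^2/s.
WATER_STANDARD_D = 2.7e-9


@dataclass(frozen=True)
class PulseSequenceParams:
    """Acquisition geometry of one PFG sweep over gradient amplitudes.

    Parameters
    ----------
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.
    delta : float
        Gradient pulse duration, s.
    t_d : float
        Diffusion time, s.
    g_values : array-like of float
        Ordered gradient amplitudes, T/m; non-negative, non-decreasing.
    tau : float, optional
        Half echo spacing, s (informational).
    repetition_time : float, optional
        Repetition time, s (informational).
    """

    gamma: float
    delta: float
    t_d: float
    g_values: tuple[float, ...]
    tau: float | None = None
    repetition_time: float | None = None

    def __post_init__(self):
        if self.gamma <= 0:
            raise InvalidInputError("gamma must be positive")
        if self.delta <= 0:
            raise InvalidInputError("delta must be positive")
        if self.t_d <= 0:
            raise InvalidInputError("t_d must be positive")
        g = np.asarray(self.g_values, dtype=float)
        object.__setattr__(self, "g_values", tuple(g.tolist()))
        if g.size and (np.any(g < 0) or np.any(np.diff(g) < 0)):
            raise InvalidInputError("g_values must be non-negative and non-decreasing")

    @property
    def b_values(self) -> np.ndarray:
        """b-value for every gradient amplitude, s/m^2."""
        g = np.asarray(self.g_values, dtype=float)
        return self.gamma**2 * self.delta**2 * g**2 * self.t_d


@dataclass(frozen=True)
class CompartmentSet:
    """Two-phase water model: fast/slow diffusivities and fast-phase fraction.

    ``d_fast`` and ``d_slow`` are in m^2/s with ``d_fast > d_slow > 0``;
    ``p1`` is the fast-phase spin population in [0, 1] (p2 = 1 - p1 implied).
    """

    d_fast: float
    d_slow: float
    p1: float

    def __post_init__(self):
        if not self.d_fast > self.d_slow > 0:
            raise InvalidInputError(
                f"require d_fast > d_slow > 0, got {self.d_fast!r}, {self.d_slow!r}"
            )
        if not 0.0 <= self.p1 <= 1.0:
            raise InvalidInputError(f"p1 must lie in [0, 1], got {self.p1!r}")

    @property
    def p2(self) -> float:
        return 1.0 - self.p1


@dataclass
class DecayCurve:
    """Normalized echo attenuation A(g)/A(0) sampled on a b-value grid.

    ``b_values`` must be strictly increasing with first entry >= 0.
    ``noise_sigma`` records the additive noise scale used at synthesis and is
    ``None`` for measured or unknown-noise curves.
    """

    b_values: np.ndarray
    amplitudes: np.ndarray
    noise_sigma: float | None = None
    curve_id: str = field(default="curve")

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if b.ndim != 1 or a.shape != b.shape:
            raise InvalidInputError("b_values and amplitudes must be equal-length 1-D")
        if b.size and (b[0] < 0 or np.any(np.diff(b) <= 0)):
            raise InvalidInputError("b_values must be strictly increasing, first >= 0")
        self.b_values = b
        self.amplitudes = a

    def __len__(self) -> int:
        return self.b_values.size


def compute_b_value(seq: PulseSequenceParams, g: float) -> float:
    """Stejskal-Tanner diffusion weighting b = gamma^2 delta^2 g^2 t_d.

    Parameters
    ----------
    seq : PulseSequenceParams
    g : float
        Gradient amplitude, T/m; must be >= 0.

    Returns
    -------
    float
        b-value in s/m^2; monotone increasing (quadratic) in g.
    """
    if g < 0:
        raise InvalidInputError(f"gradient amplitude must be >= 0, got {g!r}")
    return seq.gamma**2 * seq.delta**2 * g**2 * seq.t_d


def biexp_signal(b, c: CompartmentSet):
    """Two-phase normalized attenuation p1 e^{-b D_fast} + (1-p1) e^{-b D_slow}.

    Accepts scalar or array ``b`` (s/m^2, >= 0) and returns the matching shape.
    Values lie in (0, 1] and equal 1 at b = 0.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise InvalidInputError("b must be >= 0")
    out = c.p1 * np.exp(-b * c.d_fast) + (1.0 - c.p1) * np.exp(-b * c.d_slow)
    return float(out) if out.ndim == 0 else out


def weighted_adc(c: CompartmentSet) -> float:
    """Population-weighted mean diffusivity p1*D_fast + (1-p1)*D_slow, m^2/s.

    This is the volume-weighted apparent diffusion coefficient of the
    two-phase model and the limit of the initial slope of ln A(b).
    """
    return c.p1 * c.d_fast + (1.0 - c.p1) * c.d_slow


def synthesize_on_grid(
    b_values: np.ndarray,
    c: CompartmentSet,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    curve_id: str = "curve",
) -> DecayCurve:
    """Biexponential decay on an explicit b grid plus additive Gaussian noise."""
    b = np.asarray(b_values, dtype=float)
    if b.size == 0:
        raise InvalidInputError("b grid is empty")
    if noise_sigma < 0:
        raise InvalidInputError("noise_sigma must be >= 0")
    a = biexp_signal(b, c)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        a = a + rng.normal(0.0, noise_sigma, size=b.shape)
    return DecayCurve(b, a, noise_sigma=noise_sigma, curve_id=curve_id)


def synthesize_curve(
    seq: PulseSequenceParams,
    c: CompartmentSet,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
    curve_id: str = "curve",
) -> DecayCurve:
    """Simulate one PFG sweep: b grid from the acquisition, biexp decay, noise.

    With ``noise_sigma = 0`` the amplitudes equal the exact forward model;
    the same ``seed`` always yields a bit-identical curve.
    """
    if len(seq.g_values) == 0:
        raise InvalidInputError("acquisition has no gradient values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return synthesize_on_grid(seq.b_values, c, noise_sigma, rng, curve_id=curve_id)


def default_acquisition(t_d: float = 0.020, n_steps: int = 25) -> PulseSequenceParams:
    """Default acquisition: delta = 0.2 ms, g ramp 0 -> 4 T/m, t_d = 20 ms.

    Mirrors the stimulated-echo geometry used for the tissue measurements
    (2*tau = 20 ms, repetition time 2 s).  At this diffusion time
    max(b) ~ 9.2e8 s/m^2, so the slow phase (D ~ 1.7e-11 m^2/s) is barely
    attenuated; use :func:`extended_b_grid` when both phases must be resolved.
    """
    g = np.linspace(0.0, 4.0, n_steps)
    return PulseSequenceParams(
        gamma=GAMMA_PROTON,
        delta=0.2e-3,
        t_d=t_d,
        g_values=tuple(g.tolist()),
        tau=0.010,
        repetition_time=2.0,
    )


#: Diffusion times (s) of the extended sweep used to reach large b-values.
EXTENDED_T_D = (0.011, 0.050, 0.200, 0.800)


def extended_acquisitions(n_steps: int = 25) -> list[PulseSequenceParams]:
    """One gradient ramp per diffusion time in {11, 50, 200, 800} ms."""
    return [default_acquisition(t_d=t, n_steps=n_steps) for t in EXTENDED_T_D]


def extended_b_grid(n_steps: int = 25) -> np.ndarray:
    """Merged, strictly increasing b grid of the four extended sweeps.

    Spans b = 0 up to ~3.7e10 s/m^2, where the slow phase attenuates by
    ~e^-0.6: enough leverage to separate both exponentials.  The short-t_d
    sweeps contribute the dense small-b coverage needed for the fast phase
    and the initial-slope ADC.
    """
    bs = np.concatenate([seq.b_values for seq in extended_acquisitions(n_steps)])
    return np.unique(bs)


def water_standard_curve(
    d: float = WATER_STANDARD_D,
    seq: PulseSequenceParams | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> DecayCurve:
    """Mono-exponential calibration curve of the water standard.

    Pure water attenuates as A(g)/A(0) = exp(-b D) with D = 2.7e-9 m^2/s
    (30 degrees C); used as the round-trip check of the mono-exponential
    fitter.  Implemented as the p1 -> 1 limit of the two-phase model.
    """
    if seq is None:
        seq = default_acquisition()
    # p1=1 makes the slow phase irrelevant; any valid d_slow < d works.
    c = CompartmentSet(d_fast=d, d_slow=d * 1e-3, p1=1.0)
    return synthesize_curve(seq, c, noise_sigma=noise_sigma, seed=seed, curve_id="water_standard")
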