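"""Synthetic acquisition emulation for fast-field-cycling and benchtop TD-NMR.

Generates every input the analysis pipeline consumes -- NMRD dispersion
profiles, field-cycling magnetization curves (pre-polarized below 10 MHz,
non-polarized above), saturation-recovery curves, and CPMG echo decays --
from known ground-truth parameters, with the acquisition structure of the
instruments being emulated:

* dispersion profiles from 10 kHz to 20 MHz (plus a conventional
  high-field point at 500 MHz), relative error on R1 bounded by 5 %;
* magnetization curves with 22 logarithmically spaced delays and
  mono-exponential evolution;
* CPMG trains with 100 us echo spacing, echo maxima at t_k = k * echo_time.

Every generator is a pure function of (parameters, seed).

``SAMPLE_NMRD_PARAMS`` / ``SAMPLE_T2_PARAMS`` hold the published fitted
parameter sets for the four confectionery-gel formulations (SUC: sucrose
original; SBF10 / SCG40 / SCG60: corn-syrup substitutes) so tests and the
pipeline can reference the study conditions symbolically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relax_models import (
    ANGSTROM,
    NS,
    CompositeModelParams,
    PhysicalConstants,
    DEFAULT_CONSTANTS,
    RotationalParams,
    TranslationalParams,
    total_r1,
)

__all__ = [
    "AcquisitionSpec",
    "NMRDProfile",
    "MagnetizationCurve",
    "make_frequency_grid",
    "simulate_nmrd_profile",
    "simulate_magnetization_curve",
    "simulate_cpmg_decay",
    "sequence_for_frequency",
    "SAMPLE_NMRD_PARAMS",
    "SAMPLE_T2_PARAMS",
    "SAMPLE_MOISTURE_PCT",
    "SAMPLE_NAMES",
    "nmrd_params_for",
]

SEQUENCES = ("PP", "NP", "SR", "CPMG")

PP_NP_CROSSOVER_HZ = 10e6  # pre-polarized below, non-polarized at/above


def sequence_for_frequency(evolution_frequency_hz: float) -> str:
    """Field-cycling sequence used at a given evolution frequency."""
    return "PP" if evolution_frequency_hz < PP_NP_CROSSOVER_HZ else "NP"


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition settings of one relaxation measurement.

    Defaults mirror the emulated instruments: 22-point magnetization
    curves, polarization at the field of 20 MHz for 5*T1 (PP), CPMG with
    100 us echo time and 128 echoes, saturation recovery with a 300 ms
    relaxation period.
    """

    sequence: str
    n_points: int = 22
    polarization_equivalent_frequency: float = 20e6
    polarization_duration_multiple: float = 5.0
    echo_time: float = 100e-6
    n_echoes: int = 128
    relaxation_period: float = 0.300

    def __post_init__(self):
        if self.sequence not in SEQUENCES:
            raise ValueError(
                f"unknown sequence {self.sequence!r}; expected one of {SEQUENCES}"
            )
        if self.sequence == "CPMG":
            if not self.echo_time > 0 or self.n_echoes < 1:
                raise ValueError("CPMG needs echo_time > 0 and n_echoes >= 1")
        elif self.n_points < 2:
            raise ValueError("n_points must be >= 2")


@dataclass(frozen=True)
class NMRDProfile:
    """One sample's dispersion curve: R1 vs. Larmor frequency.

    Points are stored sorted by frequency (any input order is accepted);
    frequencies are strictly positive and distinct, R1 positive, and the
    relative error is bounded by 5 % under the default acquisition
    emulation.
    """

    sample_id: str
    temperature_C: float
    frequency_hz: np.ndarray
    R1: np.ndarray
    relative_error: np.ndarray

    def __post_init__(self):
        for name in ("frequency_hz", "R1", "relative_error"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.frequency_hz.shape != self.R1.shape or self.R1.shape != self.relative_error.shape:
            raise ValueError("frequency, R1 and relative_error must have equal length")
        if np.any(self.frequency_hz <= 0):
            raise ValueError("frequencies must be strictly positive")
        order = np.argsort(self.frequency_hz, kind="stable")
        if np.any(np.diff(order) != 1):  # accept any point order, store sorted
            object.__setattr__(self, "frequency_hz", self.frequency_hz[order])
            object.__setattr__(self, "R1", self.R1[order])
            object.__setattr__(self, "relative_error", self.relative_error[order])
        if np.any(np.diff(self.frequency_hz) <= 0):
            raise ValueError("frequencies must be distinct")
        if np.any(self.R1 <= 0):
            raise ValueError("R1 values must be strictly positive")
        if np.any(self.relative_error < 0):
            raise ValueError("relative errors must be non-negative")

    def __len__(self) -> int:
        return self.frequency_hz.size


@dataclass(frozen=True)
class MagnetizationCurve:
    """Time/amplitude pairs of one relaxation measurement."""

    spec: AcquisitionSpec
    times: np.ndarray
    amplitudes: np.ndarray
    truth: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if self.times.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        expected = self.spec.n_echoes if self.spec.sequence == "CPMG" else self.spec.n_points
        if self.times.size != expected:
            raise ValueError(
                f"curve length {self.times.size} does not match the "
                f"{self.spec.sequence} acquisition spec ({expected} points)"
            )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def make_frequency_grid(f_min: float, f_max: float, n: int, extra_points=()):
    """Logarithmic frequency grid plus extra points, merged, deduplicated, sorted."""
    if not (f_min > 0 and f_max > f_min):
        raise ValueError("need 0 < f_min < f_max")
    if n < 2:
        raise ValueError("n must be >= 2")
    extra = np.asarray(list(extra_points), dtype=float)
    if extra.size and np.any(extra <= 0):
        raise ValueError("extra points must be strictly positive")
    grid = np.geomspace(f_min, f_max, n)
    return np.unique(np.concatenate([grid, extra]))


def simulate_nmrd_profile(
    params: CompositeModelParams,
    grid,
    noise_fraction: float = 0.02,
    seed: int = 0,
    sample_id: str = "synthetic",
    temperature_C: float = 25.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> NMRDProfile:
    """Forward-simulate a dispersion profile with relative Gaussian noise.

    R1 at each frequency is the composite forward model scaled by
    (1 + N(0, noise_fraction)).  ``noise_fraction`` is bounded by the 5 %
    instrumental error of the emulated acquisition.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be non-negative")
    if noise_fraction > 0.05:
        raise ValueError("noise_fraction above the 5 % acquisition error bound")
    grid = np.asarray(grid, dtype=float)
    clean = total_r1(2.0 * np.pi * grid, params, constants)
    rng = np.random.default_rng(seed)
    noisy = clean * (1.0 + rng.normal(0.0, noise_fraction, size=clean.shape)) if noise_fraction else clean.copy()
    return NMRDProfile(
        sample_id=sample_id,
        temperature_C=temperature_C,
        frequency_hz=grid,
        R1=noisy,
        relative_error=np.full(grid.shape, noise_fraction),
    )


def simulate_magnetization_curve(
    T1: float,
    spec: AcquisitionSpec,
    M0: float,
    M_inf: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MagnetizationCurve:
    """Mono-exponential magnetization evolution sampled at log-spaced delays.

    amplitude(t) = M_inf + (M0 - M_inf) exp(-t / T1), on ``n_points``
    delays spanning [T1/50, 5 T1].  PP observation is a decay (M0 > M_inf),
    NP and saturation recovery build up from M0 ~ 0.
    """
    if not T1 > 0:
        raise ValueError(f"T1 must be positive, got {T1}")
    if spec.sequence == "CPMG":
        raise ValueError("use simulate_cpmg_decay for CPMG acquisitions")
    times = np.geomspace(T1 / 50.0, 5.0 * T1, spec.n_points)
    amps = M_inf + (M0 - M_inf) * np.exp(-times / T1)
    if noise_sd:
        rng = np.random.default_rng(seed)
        amps = amps + rng.normal(0.0, noise_sd, size=amps.shape)
    return MagnetizationCurve(
        spec=spec,
        times=times,
        amplitudes=amps,
        truth={"T1_s": T1, "M0": M0, "M_inf": M_inf, "noise_sd": noise_sd, "seed": seed},
    )


def simulate_cpmg_decay(
    components,
    spec: AcquisitionSpec,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MagnetizationCurve:
    """Multi-exponential CPMG echo train, echo maxima at t_k = k * echo_time.

    ``components`` is a sequence of (T2_seconds, fraction) pairs whose
    fractions sum to one; ``noise_sd`` is absolute Gaussian noise expressed
    as a fraction of the (unit) initial amplitude.
    """
    components = [(float(t2), float(fr)) for t2, fr in components]
    if any(t2 <= 0 for t2, _ in components):
        raise ValueError("all T2 values must be positive")
    fractions = np.array([fr for _, fr in components])
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions.sum()}")
    if spec.sequence != "CPMG":
        raise ValueError("spec.sequence must be 'CPMG'")
    times = spec.echo_time * np.arange(1, spec.n_echoes + 1)
    amps = np.zeros_like(times)
    for t2, fr in components:
        amps += fr * np.exp(-times / t2)
    if noise_sd:
        rng = np.random.default_rng(seed)
        amps = amps + rng.normal(0.0, noise_sd, size=amps.shape)
    return MagnetizationCurve(
        spec=spec,
        times=times,
        amplitudes=amps,
        truth={
            "components": [{"T2_s": t2, "fraction": fr} for t2, fr in components],
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Published parameter fixtures (study conditions)
# ---------------------------------------------------------------------------

SAMPLE_NAMES = ("SUC", "SBF10", "SCG40", "SCG60")

# Fitted dispersion-model parameters per sample and temperature:
# (C_intra 1e9 s^-2, tau_rot ns, D_MM 1e-12 m^2/s, D_LM 1e-13 m^2/s).
# Spin densities (N_MM, N_LM in 1e28 m^-3) were determined at 25 C and are
# shared by the 4 C entry of the same sample.
_NMRD_TABLE = {
    "SUC": {
        "N": (4.39, 1.33),
        25.0: (4.20, 0.57, 1.70, 3.90),
        4.0: (3.86, 1.08, 1.11, 2.71),
    },
    "SBF10": {
        "N": (6.57, 3.79),
        25.0: (4.95, 0.29, 2.83, 5.43),
        4.0: (3.86, 1.44, 0.58, 2.06),
    },
    "SCG40": {
        "N": (4.48, 5.37),
        25.0: (4.45, 0.35, 2.67, 6.65),
        4.0: (3.43, 1.66, 0.62, 1.84),
    },
    "SCG60": {
        "N": (7.24, 6.20),
        25.0: (4.01, 0.11, 6.51, 7.11),
        4.0: (3.19, 0.52, 1.83, 1.62),
    },
}

D_CLOSEST_APPROACH_M = 3.6 * ANGSTROM
DELTA_ROT_DECADES = 1.5


def _build_params(c9, tau_ns, d_mm12, d_lm13, n_mm28, n_lm28) -> CompositeModelParams:
    return CompositeModelParams(
        rot=RotationalParams(
            C_intra=c9 * 1e9, tau_rot=tau_ns * NS, delta_rot=DELTA_ROT_DECADES
        ),
        mm=TranslationalParams(
            D=d_mm12 * 1e-12, N=n_mm28 * 1e28, d=D_CLOSEST_APPROACH_M
        ),
        lm=TranslationalParams(
            D=d_lm13 * 1e-13, N=n_lm28 * 1e28, d=D_CLOSEST_APPROACH_M
        ),
    )


SAMPLE_NMRD_PARAMS: dict[str, dict[float, CompositeModelParams]] = {
    name: {
        temp: _build_params(*row, *table["N"])
        for temp, row in table.items()
        if temp != "N"
    }
    for name, table in _NMRD_TABLE.items()
}

# Discrete transverse-relaxation decomposition per sample:
# [(T2 seconds, relative area as fraction), ...], short component first.
SAMPLE_T2_PARAMS: dict[str, list[tuple[float, float]]] = {
    "SUC": [(2.31e-3, 0.545), (13.17e-3, 0.455)],
    "SBF10": [(1.14e-3, 0.595), (7.38e-3, 0.405)],
    "SCG40": [(0.51e-3, 0.675), (5.59e-3, 0.325)],
    "SCG60": [(0.58e-3, 0.745), (5.17e-3, 0.255)],
}

# Moisture content, % wet basis.
SAMPLE_MOISTURE_PCT: dict[str, float] = {
    "SUC": 4.0,
    "SBF10": 8.2,
    "SCG40": 7.5,
    "SCG60": 9.1,
}


def nmrd_params_for(sample: str, temperature_C: float) -> CompositeModelParams:
    """Fixture lookup with a helpful error listing the available samples."""
    try:
        by_temp = SAMPLE_NMRD_PARAMS[sample]
    except KeyError:
        raise KeyError(
            f"unknown sample {sample!r}; available fixtures: {', '.join(SAMPLE_NAMES)}"
        ) from None
    try:
        return by_temp[float(temperature_C)]
    except KeyError:
        raise KeyError(
            f"no fixture for {sample} at {temperature_C} C; "
            f"available temperatures: {sorted(t for t in by_temp)}"
        ) from None
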