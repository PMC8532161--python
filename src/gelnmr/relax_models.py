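"""Forward models for frequency-dependent proton spin-lattice relaxation.

The composite dispersion model implemented here describes the "mobile"
proton fraction (water plus dissolved sugar) of a starch-sugar gel as the
sum of three relaxation channels,

    R1(omega) = R1_rot(omega) + R1_trans^MM(omega) + R1_trans^LM(omega),

where the rotational channel is a BPP-type Lorentzian spectral density
averaged over a log-Gaussian distribution of rotational correlation times,
and each translational channel is Torrey's jump-diffusion intermolecular
spectral density for a pool of protons with self-diffusion coefficient D
and spin density N.  MM and LM label the more-mobile and less-mobile pools
(large vs. confined water pockets of the gel microstructure).

All functions work in SI units internally (s, m, rad/s).  The flat
serialization layer accepts the conventional bench units (ns, angstrom)
and converts once at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysicalConstants",
    "DEFAULT_CONSTANTS",
    "RotationalParams",
    "TranslationalParams",
    "CompositeModelParams",
    "lorentzian_bpp_r1",
    "log_gaussian_weights",
    "rotational_r1_distributed",
    "torrey_reduced_spectral_density",
    "torrey_translational_r1",
    "total_r1",
    "total_r1_components",
    "omega_from_frequency",
    "frequency_from_omega",
]

ANGSTROM = 1e-10
NS = 1e-9

# Torrey's reduced jump parameter delta = <a^2>/(12 d^2); with the mean jump
# length pinned to the closest-approach distance (a = d) it is exactly 1/12.
DELTA_JUMP_A_EQ_D = 1.0 / 12.0


def omega_from_frequency(nu_hz):
    """Angular frequency (rad/s) from Larmor frequency (Hz)."""
    return 2.0 * np.pi * np.asarray(nu_hz, dtype=float)


def frequency_from_omega(omega):
    """Larmor frequency (Hz) from angular frequency (rad/s)."""
    return np.asarray(omega, dtype=float) / (2.0 * np.pi)


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants entering the intermolecular dipolar prefactor.

    gamma          proton gyromagnetic ratio, rad s^-1 T^-1
    mu0_over_4pi   mu_0 / 4 pi, T m A^-1
    hbar           reduced Planck constant, J s
    """

    gamma: float = 2.6752218708e8
    mu0_over_4pi: float = 1e-7
    hbar: float = 1.054571817e-34

    @property
    def c_inter(self) -> float:
        """Intermolecular dipolar constant (9/8)(mu0 gamma^2 hbar / 4 pi)^2, m^6 s^-2."""
        return 9.0 / 8.0 * (self.mu0_over_4pi * self.gamma**2 * self.hbar) ** 2


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class RotationalParams:
    """Rotational (intramolecular) relaxation channel.

    C_intra    intramolecular dipolar relaxation constant, s^-2
    tau_rot    centre of the correlation-time distribution, s
    delta_rot  width of the log-Gaussian distribution, decades of tau
    """

    C_intra: float
    tau_rot: float
    delta_rot: float = 1.5

    def __post_init__(self):
        if not self.C_intra > 0:
            raise ValueError(f"C_intra must be positive, got {self.C_intra}")
        if not self.tau_rot > 0:
            raise ValueError(f"tau_rot must be positive, got {self.tau_rot}")
        if self.delta_rot < 0:
            raise ValueError(f"delta_rot must be >= 0, got {self.delta_rot}")


@dataclass(frozen=True)
class TranslationalParams:
    """One translational (intermolecular) pool.

    D   translational self-diffusion coefficient, m^2 s^-1
    N   proton (spin) density, m^-3
    d   closest approach distance between interacting molecules, m
    """

    D: float
    N: float
    d: float = 3.6 * ANGSTROM

    def __post_init__(self):
        if not self.D > 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.N < 0:
            raise ValueError(f"N must be non-negative, got {self.N}")
        if not self.d > 0:
            raise ValueError(f"d must be positive, got {self.d}")

    @property
    def tau_trans(self) -> float:
        """Mean time between translational jumps, d^2/(6 D) under a = d."""
        return self.d**2 / (6.0 * self.D)

    @property
    def delta_jump(self) -> float:
        """Reduced jump parameter <a^2>/(12 d^2); exactly 1/12 under a = d."""
        return DELTA_JUMP_A_EQ_D


@dataclass(frozen=True)
class CompositeModelParams:
    """Full parameter set of the three-channel dispersion model."""

    rot: RotationalParams
    mm: TranslationalParams
    lm: TranslationalParams

    def __post_init__(self):
        if self.mm.D <= self.lm.D:
            raise ValueError(
                "labeling rule violated: the MM pool must diffuse faster "
                f"(D_MM={self.mm.D} <= D_LM={self.lm.D})"
            )
        if self.mm.d != self.lm.d:
            raise ValueError("both pools must share the closest-approach distance d")

    def to_flat_dict(self) -> dict:
        """Flat key-value form with unit-suffixed keys (ns, angstrom at the boundary)."""
        return {
            "C_intra_per_s2": self.rot.C_intra,
            "tau_rot_ns": self.rot.tau_rot / NS,
            "delta_rot_decades": self.rot.delta_rot,
            "d_angstrom": self.mm.d / ANGSTROM,
            "D_mm_m2s": self.mm.D,
            "N_mm_per_m3": self.mm.N,
            "D_lm_m2s": self.lm.D,
            "N_lm_per_m3": self.lm.N,
        }

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "CompositeModelParams":
        d = flat["d_angstrom"] * ANGSTROM
        return cls(
            rot=RotationalParams(
                C_intra=flat["C_intra_per_s2"],
                tau_rot=flat["tau_rot_ns"] * NS,
                delta_rot=flat["delta_rot_decades"],
            ),
            mm=TranslationalParams(D=flat["D_mm_m2s"], N=flat["N_mm_per_m3"], d=d),
            lm=TranslationalParams(D=flat["D_lm_m2s"], N=flat["N_lm_per_m3"], d=d),
        )


# ---------------------------------------------------------------------------
# Rotational channel: BPP Lorentzian and its log-Gaussian average
# ---------------------------------------------------------------------------

def lorentzian_bpp_r1(omega, tau: float, C_intra: float):
    """Single-correlation-time BPP rate C[J(w) + 4 J(2w)], J(w) = tau/(1+w^2 tau^2)."""
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not C_intra > 0:
        raise ValueError(f"C_intra must be positive, got {C_intra}")
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    wt2 = (omega * tau) ** 2
    return C_intra * tau * (1.0 / (1.0 + wt2) + 4.0 / (1.0 + 4.0 * wt2))


def log_gaussian_weights(
    tau_center: float,
    delta_rot: float,
    n_nodes: int = 128,
    span_decades: float | None = None,
):
    """Quadrature nodes and weights for the log-Gaussian correlation-time distribution.

    The distribution is Gaussian in log10(tau) with standard deviation
    ``delta_rot`` decades, centred on ``tau_center``.  Trapezoidal weights on
    an even log10 grid spanning +-``span_decades`` (default 4 * delta_rot)
    are renormalized to sum to one, so the degenerate delta_rot = 0 case
    reduces to a point mass at tau_center.

    Returns (tau_nodes, weights); weights are non-negative and sum to 1.
    """
    if not tau_center > 0:
        raise ValueError(f"tau_center must be positive, got {tau_center}")
    if delta_rot < 0:
        raise ValueError(f"delta_rot must be >= 0, got {delta_rot}")
    if delta_rot == 0.0:
        return np.array([tau_center]), np.array([1.0])
    if n_nodes < 16:
        raise ValueError(f"n_nodes must be >= 16, got {n_nodes}")
    if span_decades is None:
        span_decades = 4.0 * delta_rot
    elif span_decades < 4.0 * delta_rot:
        raise ValueError(
            f"span_decades={span_decades} must cover at least 4*delta_rot on each side"
        )
    centre = math.log10(tau_center)
    grid = np.linspace(centre - span_decades, centre + span_decades, n_nodes)
    density = np.exp(-((grid - centre) ** 2) / (2.0 * delta_rot**2))
    # trapezoid weights on an even grid: half weight at the two endpoints
    w = density.copy()
    w[0] *= 0.5
    w[-1] *= 0.5
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ArithmeticError("log-Gaussian quadrature degenerated to zero mass")
    return 10.0**grid, w / total


def rotational_r1_distributed(
    omega,
    params: RotationalParams,
    n_nodes: int = 128,
    span_decades: float | None = None,
):
    """Rotational R1 averaged over the log-Gaussian distribution of tau.

    Equals the weighted sum of ``lorentzian_bpp_r1`` over the distribution
    nodes; reduces to the single-tau BPP rate when delta_rot = 0.
    """
    taus, weights = log_gaussian_weights(
        params.tau_rot, params.delta_rot, n_nodes=n_nodes, span_decades=span_decades
    )
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    wt2 = (omega[..., None] * taus) ** 2
    j_sum = taus * (1.0 / (1.0 + wt2) + 4.0 / (1.0 + 4.0 * wt2))
    out = params.C_intra * (j_sum * weights).sum(axis=-1)
    if not np.all(np.isfinite(out)):
        raise ArithmeticError("rotational quadrature produced non-finite values")
    return out


# ---------------------------------------------------------------------------
# Translational channel: Torrey's jump-diffusion spectral density
# ---------------------------------------------------------------------------
#
# For isotropic random jumps with mean jump time tau_trans and mean square
# jump length <a^2> = 6 D tau_trans, the intermolecular dipolar spectral
# density (uniform spin density N outside the distance of closest approach d)
# is, with x = k d, B = 2 delta x^2 and delta = <a^2>/(12 d^2),
#
#   J(omega) = (32/15) (N tau/d^3) * I(delta, omega tau)
#   I(delta, u) = int_0^inf j1(x)^2 B(1+B) / (B^2 + u^2 (1+B)^2) dx .
#
# The integrand is a rational function of x^2 times j1(x)^2, so I has a
# closed form by contour integration: the only contributions are the
# residues at the complex wavenumbers z_p with B(z_p) = (-u^2 +- iu)/(1+u^2),
#
#   I(delta, u) = Re[ pi i  sum_p  M(z_p) B(1+B) / D'(z_p) ] ,
#   M(z) = ((1+z^2) + (z+i)^2 e^{2iz}) / (2 z^4) ,
#   D'(z) = (2B + 2u^2(1+B)) * 4 delta z ,
#
# taking for each root the branch with Im z_p > 0.  M(z) vanishes like z^3/3
# at the origin; for small |z| it is evaluated through its Taylor series to
# avoid cancellation.  At u = 0 the integral is elementary:
# I(delta, 0) = pi/6 + pi/(30 delta).

_M_SERIES_NMAX = 60


def _m_series_coefficients(nmax: int = _M_SERIES_NMAX) -> np.ndarray:
    # Taylor coefficients a_n of g(z) = (1+z^2) + (z+i)^2 exp(2iz); a_0..a_2 = 0.
    coef = np.zeros(nmax + 1, dtype=complex)
    for n in range(3, nmax + 1):
        c = (2j) ** (n - 2) / math.factorial(n - 2)
        c += 2j * (2j) ** (n - 1) / math.factorial(n - 1)
        c -= (2j) ** n / math.factorial(n)
        coef[n] = c
    return coef


_M_COEF = _m_series_coefficients()


def _m_function(z: np.ndarray) -> np.ndarray:
    """M(z) = ((1+z^2) + (z+i)^2 e^{2iz}) / (2 z^4), cancellation-safe."""
    z = np.atleast_1d(np.asarray(z, dtype=complex))
    out = np.empty_like(z)
    small = np.abs(z) < 2.5
    if np.any(small):
        zs = z[small]
        acc = np.zeros_like(zs)
        for n in range(_M_SERIES_NMAX, 2, -1):
            acc = acc * zs + _M_COEF[n]
        out[small] = acc * zs**3 / (2.0 * zs**4)
    if np.any(~small):
        zl = z[~small]
        out[~small] = ((1.0 + zl**2) + (zl + 1j) ** 2 * np.exp(2j * zl)) / (2.0 * zl**4)
    return out


def torrey_reduced_spectral_density(u, delta_jump: float = DELTA_JUMP_A_EQ_D):
    """Reduced Torrey spectral density f(delta, u) with u = omega * tau_trans.

    Normalized so that the translational rate is
    ``C_inter * (N tau_trans / d^3) * (f(delta, u) + 4 f(delta, 2u))``;
    f(delta, u) = (32/15) * I(delta, u) with I as in the module notes.
    Finite at u = 0 and strictly decreasing in u.
    """
    if not delta_jump > 0:
        raise ValueError(f"delta_jump must be positive, got {delta_jump}")
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any(u < 0):
        raise ValueError("u (= omega * tau_trans) must be non-negative")
    out = np.empty_like(u)
    zero = u == 0.0
    out[zero] = np.pi / 6.0 + np.pi / (30.0 * delta_jump)
    uv = u[~zero]
    if uv.size:
        usq = uv * uv
        total = np.zeros(uv.shape, dtype=complex)
        for sign in (+1.0, -1.0):
            B = (-usq + sign * 1j * uv) / (1.0 + usq)
            z = np.sqrt(B / (2.0 * delta_jump))
            z = np.where(z.imag < 0, -z, z)
            num = B * (1.0 + B)
            dprime = (2.0 * B + 2.0 * usq * (1.0 + B)) * 4.0 * delta_jump * z
            total += _m_function(z) * num / dprime
        out[~zero] = (np.pi * 1j * total).real
    return (32.0 / 15.0) * out


def torrey_translational_r1(
    omega,
    params: TranslationalParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Intermolecular R1 of one translational pool (Torrey jump-diffusion model)."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    tau = params.tau_trans
    u = omega * tau
    f = torrey_reduced_spectral_density(u, params.delta_jump)
    f2 = torrey_reduced_spectral_density(2.0 * u, params.delta_jump)
    prefactor = constants.c_inter * params.N * tau / params.d**3
    return prefactor * (f + 4.0 * f2)


# ---------------------------------------------------------------------------
# Composite model
# ---------------------------------------------------------------------------

def total_r1_components(
    omega,
    params: CompositeModelParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    n_nodes: int = 128,
) -> dict:
    """The three relaxation contributions, separately, on the given omega grid.

    Keys: 'rotational', 'translational_mm', 'translational_lm'.  Their
    pointwise sum is exactly (bit-for-bit) what ``total_r1`` returns.
    """
    return {
        "rotational": rotational_r1_distributed(omega, params.rot, n_nodes=n_nodes),
        "translational_mm": torrey_translational_r1(omega, params.mm, constants),
        "translational_lm": torrey_translational_r1(omega, params.lm, constants),
    }


def total_r1(
    omega,
    params: CompositeModelParams,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    n_nodes: int = 128,
):
    """Composite spin-lattice relaxation rate R1(omega), s^-1."""
    comps = total_r1_components(omega, params, constants, n_nodes=n_nodes)
    return (
        comps["rotational"] + comps["translational_mm"] + comps["translational_lm"]
    )
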