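"""Time-domain relaxometry: mono-exponential fits, discrete T2 decomposition,
regularized inverse-Laplace T2 spectra, and the zero-method T1 conversion.

The discrete two-component decomposition is the primary route to the
(T2a, T2b, RA1, RA2) fingerprint that separates sucrose-based gels from
corn-syrup formulations; the non-negative inverse Laplace transform gives
the corresponding continuous relaxation spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, nnls

from .synth import MagnetizationCurve

__all__ = [
    "MonoExpFit",
    "DiscreteT2Result",
    "T2Spectrum",
    "TdnmrFitError",
    "fit_monoexp",
    "zero_method_t1",
    "zero_crossing_time",
    "fit_discrete_multiexp",
    "ilt_t2_spectrum",
    "default_t2_grid",
    "l_curve_scan",
    "spectrum_peaks",
    "spectrum_peak_modes",
]

LN2 = math.log(2.0)

DECAY_SEQUENCES = {"CPMG", "PP"}
RECOVERY_SEQUENCES = {"SR", "NP"}


class TdnmrFitError(RuntimeError):
    """A relaxation fit could not bracket a positive time constant."""


@dataclass
class MonoExpFit:
    """offset + amplitude * exp(-t / relaxation_time)."""

    relaxation_time: float
    amplitude: float
    offset: float
    residual_norm: float


@dataclass(frozen=True)
class DiscreteT2Result:
    """Discrete multi-exponential decomposition.

    components: [(T2 seconds, relative area %)], ascending in T2;
    relative areas are non-negative and sum to 100.
    """

    components: tuple

    def __post_init__(self):
        comps = tuple((float(t2), float(ra)) for t2, ra in self.components)
        object.__setattr__(self, "components", comps)
        t2s = [t2 for t2, _ in comps]
        ras = [ra for _, ra in comps]
        if any(np.diff(t2s) <= 0):
            raise ValueError("T2 values must be strictly increasing")
        if any(ra < 0 for ra in ras):
            raise ValueError("relative areas must be non-negative")
        if abs(sum(ras) - 100.0) > 1e-6:
            raise ValueError(f"relative areas must sum to 100, got {sum(ras)}")

    @property
    def t2_values(self) -> np.ndarray:
        return np.array([t2 for t2, _ in self.components])

    @property
    def relative_areas(self) -> np.ndarray:
        return np.array([ra for _, ra in self.components])

    def report(self) -> dict:
        """T2 in ms and RA in %, labelled like the published tables."""
        out = {}
        for i, (t2, ra) in enumerate(self.components, start=1):
            out[f"T2{'abcdefgh'[i-1]}_ms"] = t2 * 1e3
            out[f"RA{i}_pct"] = ra
        return out


@dataclass(frozen=True)
class T2Spectrum:
    """Non-negative T2 relaxation spectrum on a log-spaced grid (seconds)."""

    grid: np.ndarray
    amplitudes: np.ndarray
    regularization_strength: float

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if self.grid.shape != self.amplitudes.shape:
            raise ValueError("grid and amplitudes must have equal length")
        if np.any(self.amplitudes < 0):
            raise ValueError("spectrum amplitudes must be non-negative")


# ---------------------------------------------------------------------------
# mono-exponential analysis
# ---------------------------------------------------------------------------

def fit_monoexp(curve: MagnetizationCurve) -> MonoExpFit:
    """Least-squares mono-exponential fit of a relaxation curve.

    The functional form is offset + amplitude * exp(-t/T); the acquisition
    sequence selects the expected orientation (decay for CPMG/PP, recovery
    for SR/NP), which seeds the initial guess.
    """
    t = curve.times
    y = curve.amplitudes
    if t.size < 4:
        raise ValueError("need at least 4 points for a mono-exponential fit")
    recovery = curve.spec.sequence in RECOVERY_SEQUENCES
    offset0 = y[-1]
    amp0 = y[0] - offset0
    scale = np.ptp(y)
    if scale == 0 or abs(amp0) < 1e-12 * max(scale, 1.0):
        raise TdnmrFitError("curve has no resolvable exponential component")
    if recovery and amp0 > 0 or (not recovery and amp0 < 0):
        warnings.warn(
            f"curve orientation does not match the {curve.spec.sequence} sequence tag"
        )
    # initial time constant from where |y - offset| falls to 1/e of the amplitude
    rel = (y - offset0) / amp0
    below = np.nonzero(rel < math.exp(-1.0))[0]
    T0 = t[below[0]] if below.size else t[t.size // 2]
    lo = np.array([math.log10(t[0] / 100.0), -np.inf, -np.inf])
    hi = np.array([math.log10(t[-1] * 100.0), np.inf, np.inf])

    def resid(x):
        logT, amp, off = x
        return off + amp * np.exp(-t / 10.0**logT) - y

    sol = least_squares(
        resid,
        np.array([math.log10(T0), amp0, offset0]),
        bounds=(lo, hi),
        method="trf",
        xtol=1e-13, ftol=1e-13, gtol=1e-13,
    )
    T_fit = 10.0 ** sol.x[0]
    if not np.isfinite(T_fit) or T_fit <= 0:
        raise TdnmrFitError("mono-exponential fit failed to bracket a positive time constant")
    if T_fit > t[-1] * 50 or T_fit < t[0] / 50:
        raise TdnmrFitError(
            f"fitted time constant {T_fit:g} s lies far outside the sampled window"
        )
    return MonoExpFit(
        relaxation_time=float(T_fit),
        amplitude=float(sol.x[1]),
        offset=float(sol.x[2]),
        residual_norm=float(np.linalg.norm(sol.fun)),
    )


def zero_method_t1(t_zero: float) -> float:
    """T1 from the inversion-recovery zero crossing: T1 = t(Mz=0) / ln 2."""
    if not t_zero > 0:
        raise ValueError(f"t_zero must be positive, got {t_zero}")
    return t_zero / LN2


def zero_crossing_time(curve: MagnetizationCurve) -> float:
    """Zero-crossing delay of a sampled magnetization curve (linear interpolation)."""
    y = curve.amplitudes
    sign_change = np.nonzero(np.diff(np.signbit(y)))[0]
    if sign_change.size == 0:
        raise ValueError("curve does not cross zero")
    i = int(sign_change[0])
    t0, t1 = curve.times[i], curve.times[i + 1]
    y0, y1 = y[i], y[i + 1]
    return float(t0 - y0 * (t1 - t0) / (y1 - y0))


# ---------------------------------------------------------------------------
# discrete multi-exponential decomposition
# ---------------------------------------------------------------------------

def _varpro_amplitudes(t, y, t2s):
    """Non-negative amplitudes for fixed time constants (separable problem)."""
    K = np.exp(-t[:, None] / t2s[None, :])
    amps, _ = nnls(K, y)
    return amps, K


def fit_discrete_multiexp(
    decay: MagnetizationCurve,
    n_components: int = 2,
    collapse_rtol: float = 0.01,
) -> DiscreteT2Result:
    """Discrete n-component exponential decomposition of a CPMG decay.

    Variable-projection least squares: the outer optimization runs over
    log10(T2); for each trial set of time constants the amplitudes are the
    non-negative linear least-squares solution.  Relative areas are
    RA_i = 100 * A_i / sum(A); components are sorted ascending in T2.
    Components that collapse within ``collapse_rtol`` in T2 (or lose all
    amplitude) are merged and the reduced model is returned with a warning.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    t = decay.times
    y = decay.amplitudes
    if t.size < 2 * n_components + 1:
        raise ValueError(
            f"{t.size} points cannot constrain {n_components} exponential components"
        )

    lo_log = math.log10(t[0] / 10.0)
    hi_log = math.log10(t[-1] * 10.0)

    def resid(x):
        amps, K = _varpro_amplitudes(t, y, 10.0**x)
        return K @ amps - y

    # deterministic multistart: nested spreads of the sampled time window
    inner = (hi_log - lo_log) / 6.0
    starts = [
        np.linspace(lo_log + 1.0, hi_log - 1.0, n_components),
        np.linspace(lo_log + inner, hi_log - inner, n_components),
        np.linspace(lo_log + 2.0, hi_log - 0.5, n_components),
    ]
    if n_components == 1:
        starts = [np.array([0.5 * (lo_log + hi_log)])]
    best = None
    for x0 in starts:
        sol = least_squares(
            resid, x0, bounds=(lo_log, hi_log), method="trf",
            xtol=1e-13, ftol=1e-13, gtol=1e-13,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    t2s = np.sort(10.0 ** best.x)
    amps, _ = _varpro_amplitudes(t, y, t2s)

    # collapse handling: nearly equal time constants or vanished amplitudes
    keep = amps > 1e-12 * max(amps.sum(), 1.0)
    collapsed = False
    for i in range(len(t2s) - 1):
        if keep[i] and keep[i + 1] and t2s[i + 1] / t2s[i] - 1.0 < collapse_rtol:
            keep[i + 1] = False
            collapsed = True
    if collapsed or keep.sum() < n_components:
        warnings.warn(
            f"{n_components}-component model degenerated to "
            f"{int(keep.sum())} resolvable component(s); returning the reduced model"
        )
        if keep.sum() == 0:
            raise TdnmrFitError("no exponential component with positive amplitude found")
        return fit_discrete_multiexp(decay, int(keep.sum()), collapse_rtol)

    total = amps.sum()
    comps = [(t2s[i], 100.0 * amps[i] / total) for i in range(len(t2s))]
    return DiscreteT2Result(components=tuple(comps))


# ---------------------------------------------------------------------------
# inverse Laplace transform (regularized NNLS) and peak extraction
# ---------------------------------------------------------------------------

def default_t2_grid(n: int = 100, t2_min: float = 10e-6, t2_max: float = 1.0) -> np.ndarray:
    """Default log-spaced T2 grid, 100 nodes over [10 us, 1 s]."""
    return np.geomspace(t2_min, t2_max, n)


def ilt_t2_spectrum(
    decay: MagnetizationCurve,
    grid: np.ndarray | None = None,
    regularization_strength: float = 0.1,
) -> T2Spectrum:
    """Tikhonov-regularized non-negative T2 spectrum of a decay.

    Solves min_a>=0 ||K a - y||^2 + lambda^2 ||a||^2 with the exponential
    kernel K[t, T2] = exp(-t/T2) via NNLS on the augmented system.  The
    default grid must span at least [echo_time/10, 10 * max time].
    """
    if regularization_strength < 0:
        raise ValueError("regularization_strength must be >= 0")
    y = decay.amplitudes
    if np.all(y == 0):
        raise ValueError("decay is identically zero")
    t = decay.times
    if grid is None:
        grid = default_t2_grid()
    grid = np.asarray(grid, dtype=float)
    if grid[0] > t[0] / 10.0 or grid[-1] < t[-1] * 10.0:
        raise ValueError(
            "T2 grid must span at least [first time / 10, 10 * last time]"
        )
    K = np.exp(-t[:, None] / grid[None, :])
    if regularization_strength > 0:
        A = np.vstack([K, regularization_strength * np.eye(grid.size)])
        b = np.concatenate([y, np.zeros(grid.size)])
    else:
        A, b = K, y
    amplitudes, _ = nnls(A, b, maxiter=10 * A.shape[1])
    return T2Spectrum(
        grid=grid, amplitudes=amplitudes, regularization_strength=regularization_strength
    )


def l_curve_scan(decay: MagnetizationCurve, grid=None, strengths=None):
    """Residual-norm / solution-norm ladder for choosing the regularization.

    Returns a list of (strength, residual_norm, solution_norm) triples.
    """
    if strengths is None:
        strengths = np.geomspace(1e-4, 10.0, 12)
    t = decay.times
    if grid is None:
        grid = default_t2_grid()
    K = np.exp(-t[:, None] / np.asarray(grid)[None, :])
    out = []
    for lam in strengths:
        spec = ilt_t2_spectrum(decay, grid, float(lam))
        r = float(np.linalg.norm(K @ spec.amplitudes - decay.amplitudes))
        out.append((float(lam), r, float(np.linalg.norm(spec.amplitudes))))
    return out


def _peak_slices(amplitudes: np.ndarray):
    """Contiguous positive regions, split at strict interior local minima."""
    positive = amplitudes > 0
    slices = []
    i = 0
    n = amplitudes.size
    while i < n:
        if not positive[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and positive[j + 1]:
            j += 1
        start = i
        for k in range(i + 1, j):
            if amplitudes[k] < amplitudes[k - 1] and amplitudes[k] < amplitudes[k + 1]:
                slices.append((start, k + 1))
                start = k + 1
        slices.append((start, j + 1))
        i = j + 1
    return slices


def spectrum_peaks(spectrum: T2Spectrum) -> DiscreteT2Result:
    """Segment a T2 spectrum into peaks and summarize them.

    Per-peak T2 is the amplitude-weighted mean in log10(T2) (geometric
    mean, the natural average on a log-spaced relaxation grid); relative
    area is 100 * (peak amplitude sum / total amplitude sum), so the peak
    areas partition the total exactly.
    """
    a = spectrum.amplitudes
    if np.all(a == 0):
        raise ValueError("spectrum is empty")
    total = a.sum()
    comps = []
    for start, stop in _peak_slices(a):
        seg = a[start:stop]
        logs = np.log10(spectrum.grid[start:stop])
        t2 = 10.0 ** (np.average(logs, weights=seg))
        comps.append((t2, 100.0 * seg.sum() / total))
    comps.sort(key=lambda c: c[0])
    return DiscreteT2Result(components=tuple(comps))


def spectrum_peak_modes(spectrum: T2Spectrum) -> np.ndarray:
    """Grid T2 value of each peak maximum, ascending."""
    a = spectrum.amplitudes
    if np.all(a == 0):
        raise ValueError("spectrum is empty")
    modes = []
    for start, stop in _peak_slices(a):
        k = start + int(np.argmax(a[start:stop]))
        modes.append(spectrum.grid[k])
    return np.sort(np.asarray(modes))
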