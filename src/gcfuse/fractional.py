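"""Variable-order fractional operator machinery for the PSO velocity update.

Two faithful routes to a fractional "inertia" with memory are provided:

* the **Grünwald–Letnikov (GL) path** (default): the fractional derivative of
  order ``alpha`` of the velocity signal is truncated to a short memory of
  past velocities with Pochhammer/gamma weights
  ``c_1 = alpha, c_{k+1} = c_k (k - alpha)/(k + 1)``; at ``alpha = 1`` this
  collapses to the classic unit-inertia term.

* the **Oustaloup path**: the frequency-domain rational approximation of
  ``s^alpha`` over a band, its polynomial coefficients fitted as degree-5
  polynomials of ``alpha`` so the transfer function can be evaluated for any
  order, and an adapter that discretises the filter and reads off effective
  memory weights.  This route is shipped and tested as a component; the
  velocity update in the optimizer uses the GL path because applying a
  rational function to powers of a velocity *vector* is not well defined.

The order itself follows a linearly decreasing schedule ``alpha(t)`` between
configurable bounds (default [0.6, 1.0]): high order early for aggressive
exploration, lower order late for longer memory and finer exploitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "FractionalSchedule",
    "gl_coefficients",
    "alpha_schedule",
    "OustaloupModel",
    "oustaloup_coefficients",
    "fit_coefficient_polynomials",
    "evaluate_fitted_coefficients",
    "oustaloup_memory_weights",
    "fractional_velocity_term",
]


@dataclass(frozen=True)
class FractionalSchedule:
    """Linearly decreasing fractional order alpha(t) over a run of T iterations."""

    alpha_lo: float = 0.6
    alpha_hi: float = 1.0
    T: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_lo <= self.alpha_hi):
            raise ValueError("need 0 < alpha_lo <= alpha_hi")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def gl_coefficients(alpha: float, depth: int) -> np.ndarray:
    """Grünwald–Letnikov memory weights c_1..c_depth for order ``alpha``.

    c_k weighs velocity v_{t-k+1}; the recurrence folds the alternating-sign
    GL binomial expansion into positive, strictly decreasing weights for
    alpha in (0, 1).  At alpha = 1 only c_1 = 1 survives.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    c = np.empty(depth, dtype=float)
    c[0] = alpha
    for k in range(1, depth):
        c[k] = c[k - 1] * (k - alpha) / (k + 1)
    return c


def alpha_schedule(sched: FractionalSchedule, t: int) -> float:
    """Order at iteration t: alpha_hi at t=0, alpha_lo at t=T, linear between."""
    if not (0 <= t <= sched.T):
        raise ValueError(f"iteration {t} outside [0, {sched.T}]")
    frac = t / sched.T
    return sched.alpha_hi + frac * (sched.alpha_lo - sched.alpha_hi)


@dataclass(frozen=True)
class OustaloupModel:
    """Band-limited rational approximation setup for s^alpha.

    N fixes the filter order (2N+1 pole/zero pairs, 2N+2 polynomial
    coefficients per side); M controls how many orders (M-1) are sampled
    when fitting the coefficient-vs-alpha polynomials.  The frequency band
    [omega_b, omega_h] is in rad/s.
    """

    N: int = 2
    M: int = 20
    omega_b: float = 0.01
    omega_h: float = 100.0
    alpha_range: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self) -> None:
        if self.N < 1 or self.M < 7:
            raise ValueError("need N >= 1 and M >= 7 (degree-5 fit needs 6 samples)")
        if not (0 < self.omega_b < self.omega_h):
            raise ValueError("need 0 < omega_b < omega_h")


def oustaloup_zpk(alpha: float, model: OustaloupModel = OustaloupModel()):
    """Zeros, poles and gain of the order-(2N+1) Oustaloup ladder for s^alpha.

    The 2N+1 zeros/poles are log-spaced over [omega_b, omega_h]; the gain is
    normalised so the magnitude at the geometric centre frequency
    omega_c = sqrt(omega_b * omega_h) equals omega_c**alpha exactly.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1) for the Oustaloup ladder")
    N = model.N
    n_sections = 2 * N + 1
    ratio = model.omega_h / model.omega_b
    ks = np.arange(-N, N + 1)
    zeros = -model.omega_b * ratio ** ((ks + N + 0.5 * (1 - alpha)) / n_sections)
    poles = -model.omega_b * ratio ** ((ks + N + 0.5 * (1 + alpha)) / n_sections)
    omega_c = np.sqrt(model.omega_b * model.omega_h)
    jwc = 1j * omega_c
    raw_gain = np.abs(np.prod(jwc - zeros) / np.prod(jwc - poles))
    gain = omega_c**alpha / raw_gain
    return zeros, poles, gain


def oustaloup_coefficients(
    alpha: float, model: OustaloupModel = OustaloupModel()
) -> tuple[np.ndarray, np.ndarray]:
    """Denominator and numerator coefficients (a, b) of the rational s^alpha fit.

    Both are length 2N+2, highest power first; the denominator is monic.
    """
    zeros, poles, gain = oustaloup_zpk(alpha, model)
    b = gain * np.real(np.poly(zeros))
    a = np.real(np.poly(poles))
    return a, b


def fit_coefficient_polynomials(
    model: OustaloupModel = OustaloupModel(),
) -> tuple[np.ndarray, np.ndarray]:
    """Degree-5 least-squares fits of each a[k], b[k] as a function of alpha.

    M-1 orders are sampled uniformly over the model's alpha range.  Returns
    (phi_a, phi_b), each of shape (6, 2N+2): column k holds the polynomial
    coefficients (highest power first) for the k-th transfer-function
    coefficient.
    """
    n_samples = model.M - 1
    if n_samples < 6:
        raise ValueError("M - 1 sampled orders must be >= 6 for a degree-5 fit")
    lo, hi = model.alpha_range
    # keep samples strictly inside (0, 1): the ladder is singular at the ends
    alphas = np.linspace(max(lo, 1e-3), min(hi, 1 - 1e-3), n_samples)
    A = np.empty((n_samples, 2 * model.N + 2))
    B = np.empty_like(A)
    for i, al in enumerate(alphas):
        A[i], B[i] = oustaloup_coefficients(al, model)
    phi_a = np.polyfit(alphas, A, 5)
    phi_b = np.polyfit(alphas, B, 5)
    return phi_a, phi_b


def evaluate_fitted_coefficients(
    phi: np.ndarray, alpha: float
) -> np.ndarray:
    """Evaluate the fitted degree-5 polynomials at one order."""
    return np.polyval(phi, alpha)


def oustaloup_memory_weights(
    alpha: float, depth: int, model: OustaloupModel = OustaloupModel(), dt: float = 1.0
) -> np.ndarray:
    """Effective discrete memory weights from the discretised Oustaloup filter.

    Adapter between the frequency-domain machinery and the velocity update:
    the rational approximation of s^alpha is discretised by Tustin's method
    at step ``dt`` and its impulse response truncated to ``depth`` samples.
    These play the same role as the GL weights (weight on v_t, v_{t-1}, ...);
    the leading weight is scaled to match the GL normalisation c_1 = alpha so
    the two routes are interchangeable in magnitude.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    a, b = oustaloup_coefficients(alpha, model)
    bz, az = signal.bilinear(b, a, fs=1.0 / dt)
    impulse = np.zeros(depth)
    impulse[0] = 1.0
    h = signal.lfilter(bz, az, impulse)
    if h[0] != 0:
        h = h * (alpha / h[0])
    return h


def fractional_velocity_term(
    history: list[np.ndarray] | np.ndarray,
    alpha: float,
    depth: int = 4,
) -> np.ndarray:
    """GL fractional memory term: sum_k c_k(alpha) * v_{t-k+1}.

    ``history`` holds the most recent velocity first; histories shorter than
    ``depth`` are implicitly zero-padded.  Replaces the inertia term of the
    classic velocity update; at alpha = 1 it returns v_t exactly.
    """
    if len(history) == 0:
        raise ValueError("velocity history is empty")
    c = gl_coefficients(alpha, depth)
    out = np.zeros_like(np.asarray(history[0], dtype=float))
    for k in range(min(depth, len(history))):
        out += c[k] * np.asarray(history[k], dtype=float)
    return out
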