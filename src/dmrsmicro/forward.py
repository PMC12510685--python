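"""Analytical forward models for powder-averaged metabolite diffusion.

Implements, under the Gaussian phase distribution (GPD) approximation with
ideal rectangular gradient pulses:

* restricted diffusion inside an impermeable sphere (Murday–Cotts/Neuman),
* randomly oriented sticks ("astrosticks", the powder-averaged zero-radius
  cylinder),
* randomly oriented infinite cylinders ("astrocylinders", Van Gelderen
  radial attenuation times free axial diffusion),
* the two-compartment sphere + astrosticks mixture used to describe
  soma-like and neurite-like signal fractions,
* the model-predicted two-point ADC.

Units: µm, ms, µm²/ms; b in ms/µm².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf, jnp_zeros

from .scheme import DiffusionScheme

__all__ = [
    "SphereSticksParams",
    "sphere_signal_gpd",
    "astrosticks_signal",
    "astrocylinders_signal",
    "sphere_sticks_signal",
    "model_adc",
]

D_INTRA_RANGE = (0.1, 1.0)


@dataclass(frozen=True)
class SphereSticksParams:
    """Parameters of the sphere + astrosticks mixture.

    f_sphere is the signal fraction of the restricted-sphere (soma-like)
    compartment, R_sphere its radius in µm, and D_intra the intracellular
    free diffusivity in µm²/ms shared by both compartments.
    """

    f_sphere: float
    R_sphere: float
    D_intra: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_sphere <= 1.0:
            raise ValueError("f_sphere must be in [0, 1]")
        if not self.R_sphere > 0:
            raise ValueError("R_sphere must be > 0")
        if not D_INTRA_RANGE[0] <= self.D_intra <= D_INTRA_RANGE[1]:
            raise ValueError(f"D_intra must be in {D_INTRA_RANGE}")


@lru_cache(maxsize=8)
def _sphere_bessel_roots(n_roots: int) -> np.ndarray:
    """Positive roots x_m of d/dx j1(x) = 0, i.e. 2x·cos x + (x²−2)·sin x = 0.

    These set the eigenmodes of diffusion in a reflecting sphere.
    """

    def f(x: float) -> float:
        return 2.0 * x * np.cos(x) + (x * x - 2.0) * np.sin(x)

    roots = []
    m = 0
    while len(roots) < n_roots:
        # avoid the trivial x = 0 zero of f (f ~ x^5 near the origin)
        lo, hi = max(m * np.pi, 1.0) + (1e-9 if m else 0.0), (m + 1) * np.pi - 1e-9
        if np.sign(f(lo)) != np.sign(f(hi)):
            roots.append(brentq(f, lo, hi, xtol=1e-14))
        m += 1
    return np.asarray(roots)


def _gpd_log_attenuation(
    alpha: np.ndarray,
    weight: np.ndarray,
    D: float,
    delta: float,
    Delta: float,
    gamma2g2: np.ndarray,
    rel_tol: float = 1e-12,
) -> np.ndarray:
    """Shared GPD series −ln E = 2 γ²g² Σ_m w_m · T_m(αδΔD).

    ``alpha`` are the eigen-wavenumbers (1/µm), ``weight`` the geometry
    weights; ``gamma2g2`` is (γ g)² in 1/(ms·µm²)·(1/ms) units consistent
    with b = (γ g δ)²·(Δ − δ/3).
    """
    a2D = alpha**2 * D  # 1/ms
    time_term = (
        2.0 * delta
        - (
            2.0
            + np.exp(-a2D * (Delta - delta))
            - 2.0 * np.exp(-a2D * delta)
            - 2.0 * np.exp(-a2D * Delta)
            + np.exp(-a2D * (Delta + delta))
        )
        / a2D
    )
    terms = weight * time_term  # per mode
    total = np.sum(terms)
    # early stop: drop the tail once a term's relative contribution is below rel_tol
    small = np.abs(terms) < rel_tol * abs(total)
    if np.any(small):
        cut = int(np.argmax(small))
        total = np.sum(terms[: max(cut, 1)])
    elif terms.size > 1 and abs(terms[-1]) > 1e-9 * abs(total):
        warnings.warn(
            "GPD series under-truncated: last term contributes "
            f"{abs(terms[-1]) / abs(total):.2e} relative; increase n_roots.",
            stacklevel=3,
        )
    return 2.0 * np.asarray(gamma2g2) * total


def _gamma2g2(b: np.ndarray, delta: float, Delta: float) -> np.ndarray:
    """(γ g)² from the rectangular-PGSE relation b = (γ g)² δ² (Δ − δ/3)."""
    return np.asarray(b, dtype=float) / (delta**2 * (Delta - delta / 3.0))


def sphere_signal_gpd(
    R: float,
    D: float,
    scheme: DiffusionScheme,
    b: float | np.ndarray | None = None,
    n_roots: int = 100,
) -> np.ndarray | float:
    """GPD attenuation for diffusion restricted in an impermeable sphere.

    Parameters
    ----------
    R : float
        Sphere radius, µm.
    D : float
        Free intracellular diffusivity, µm²/ms.
    scheme : DiffusionScheme
        Supplies δ and Δ (rectangular pulses).
    b : scalar or array, optional
        Diffusion weighting(s); defaults to ``scheme.b_values``.
    n_roots : int
        Number of retained radial eigenmodes (>= 50 recommended).

    Returns E = S/S0 in (0, 1], monotone non-increasing in b.
    """
    if not R > 0:
        raise ValueError("R must be > 0")
    if not D > 0:
        raise ValueError("D must be > 0")
    b_arr = np.atleast_1d(np.asarray(scheme.b_values if b is None else b, dtype=float))
    if np.any(b_arr < 0):
        raise ValueError("b must be >= 0")
    x = _sphere_bessel_roots(n_roots)
    alpha = x / R
    # Murday–Cotts weights: 1 / (α^4 (α²R² − 2)) per mode, divided by D later
    weight = 1.0 / (D * alpha**4 * (alpha**2 * R**2 - 2.0))
    g2 = _gamma2g2(b_arr, scheme.delta, scheme.Delta)
    neg_log = np.array(
        [
            _gpd_log_attenuation(alpha, weight, D, scheme.delta, scheme.Delta, gg)
            for gg in g2
        ]
    )
    E = np.exp(-neg_log)
    return E if (b is None or np.ndim(b) > 0) else float(E[0])


def astrosticks_signal(D: float, b: float | np.ndarray) -> np.ndarray | float:
    """Powder-averaged stick signal: E = √(π/(4bD))·erf(√(bD)).

    The closed form of the average of exp(−b D cos²θ) over uniformly
    distributed orientations; continuous at b = 0 with E = 1.
    """
    if not D > 0:
        raise ValueError("D must be > 0")
    b_arr = np.atleast_1d(np.asarray(b, dtype=float))
    if np.any(b_arr < 0):
        raise ValueError("b must be >= 0")
    bd = b_arr * D
    E = np.ones_like(bd)
    nz = bd > 1e-12
    E[nz] = np.sqrt(np.pi / (4.0 * bd[nz])) * erf(np.sqrt(bd[nz]))
    return E if np.ndim(b) > 0 else float(E[0])


@lru_cache(maxsize=8)
def _cylinder_bessel_roots(n_roots: int) -> np.ndarray:
    """Positive roots of J1' (cylinder eigenmodes), cached."""
    return jnp_zeros(1, n_roots)


def _cylinder_perp_neglog(
    R_cyl: float,
    D: float,
    delta: float,
    Delta: float,
    gamma2g2: float,
    n_roots: int = 100,
) -> float:
    """−ln E for the radial (Van Gelderen) GPD attenuation at full gradient."""
    y = _cylinder_bessel_roots(n_roots)
    beta = y / R_cyl
    weight = 1.0 / (D * beta**4 * (beta**2 * R_cyl**2 - 1.0))
    return float(_gpd_log_attenuation(beta, weight, D, delta, Delta, gamma2g2))


_GL_U, _GL_W = np.polynomial.legendre.leggauss(64)
_GL_U = 0.5 * (_GL_U + 1.0)  # map to [0, 1]; u = cos θ
_GL_W = 0.5 * _GL_W


def astrocylinders_signal(
    R_cyl: float,
    D: float,
    scheme: DiffusionScheme,
    b: float | np.ndarray | None = None,
    n_roots: int = 100,
) -> np.ndarray | float:
    """Powder-averaged infinite-cylinder signal.

    For a cylinder at angle θ to the gradient, the axial component attenuates
    freely as exp(−b D cos²θ) and the radial component follows the Van
    Gelderen GPD expression evaluated with the transverse gradient g·sinθ.
    The powder average integrates over u = cosθ with Gauss–Legendre
    quadrature. Reduces to astrosticks as R_cyl → 0.
    """
    if not R_cyl > 0:
        raise ValueError("R_cyl must be > 0")
    if not D > 0:
        raise ValueError("D must be > 0")
    b_arr = np.atleast_1d(np.asarray(scheme.b_values if b is None else b, dtype=float))
    g2 = _gamma2g2(b_arr, scheme.delta, scheme.Delta)
    E = np.empty_like(b_arr)
    for i, (bi, gg) in enumerate(zip(b_arr, g2)):
        if bi == 0:
            E[i] = 1.0
            continue
        # −ln E_perp scales with (g sinθ)² = g²(1 − u²)
        c_perp = _cylinder_perp_neglog(
            R_cyl, D, scheme.delta, scheme.Delta, gg, n_roots
        )
        integrand = np.exp(-c_perp * (1.0 - _GL_U**2) - bi * D * _GL_U**2)
        E[i] = float(np.sum(_GL_W * integrand))
    return E if (b is None or np.ndim(b) > 0) else float(E[0])


def sphere_sticks_signal(
    params: SphereSticksParams,
    scheme: DiffusionScheme,
    b_values: np.ndarray | None = None,
) -> np.ndarray:
    """Two-compartment mixture E(b) = f·E_sphere(b) + (1−f)·E_sticks(b)."""
    b = np.atleast_1d(
        np.asarray(scheme.b_values if b_values is None else b_values, dtype=float)
    )
    E_sticks = np.atleast_1d(astrosticks_signal(params.D_intra, b))
    if params.f_sphere == 0.0:
        return E_sticks
    E_sphere = np.atleast_1d(
        sphere_signal_gpd(params.R_sphere, params.D_intra, scheme, b)
    )
    return params.f_sphere * E_sphere + (1.0 - params.f_sphere) * E_sticks


def model_adc(
    params: SphereSticksParams,
    scheme: DiffusionScheme,
    b0: float | None = None,
    b1: float | None = None,
) -> float:
    """Model-predicted two-point ADC = −ln(E(b1)/E(b0)) / (b1 − b0).

    Mirrors the measured ADC definition so the mixture model can be fitted
    jointly to decays and ADC-vs-diffusion-time series.
    """
    if b0 is None or b1 is None:
        b0, b1 = scheme.b_pair
    if not b1 > b0 >= 0:
        raise ValueError("need b1 > b0 >= 0")
    E = sphere_sticks_signal(params, scheme, np.array([b0, b1]))
    if np.any(E <= 0):
        raise FloatingPointError("non-positive model attenuation")
    return float(-np.log(E[1] / E[0]) / (b1 - b0))
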