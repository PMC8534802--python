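"""Quemada shear-thinning blood rheology.

Blood is modelled as a generalized Newtonian fluid whose apparent viscosity
depends on the local shear rate ``gamma`` and on the hematocrit ``Hct``
through the Quemada closure

    mu = mu_p * (1 - K(gamma) * f(Hct))**-2
    K(gamma) = (k0 + k_inf * sqrt(gamma/gamma_c)) / (1 + sqrt(gamma/gamma_c))

where ``mu_p`` is the plasma viscosity, ``K`` the shear-rate-dependent
intrinsic viscosity of the erythrocyte phase, ``k0``/``k_inf`` its zero- and
infinite-shear limits and ``gamma_c`` the critical shear rate.  Two readings
of the hematocrit factor are supported:

* ``form="printed"``  -> ``f(Hct) = Hct**2``
* ``form="classic"``  -> ``f(Hct) = Hct / 2`` (the classical Quemada law)

Both reduce to the plasma viscosity at ``Hct = 0``.  The closure is
shear-thinning whenever ``k0 > k_inf`` and viscosity rises monotonically with
hematocrit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BloodProperties",
    "RheologySaturationError",
    "inner_viscosity_K",
    "viscosity",
    "viscosity_field",
    "tabulate_viscosity_curve",
]

#: Density of whole blood, kg/m^3 (constant, incompressible model).
BLOOD_DENSITY = 1040.0


class RheologySaturationError(ValueError):
    """Raised when 1 - K*f(Hct) <= 0, i.e. the Quemada law diverges."""


@dataclass(frozen=True)
class BloodProperties:
    """Constitutive constants of the blood model.

    Parameters
    ----------
    rho : float
        Density, kg/m^3.
    mu_p : float
        Plasma viscosity, Pa*s.
    hct : float
        Hematocrit as a volume fraction in [0, 1).
    k0, k_inf : float
        Zero- and infinite-shear intrinsic viscosities (k0 >= k_inf > 0
        for shear thinning).
    gamma_c : float
        Critical shear rate, 1/s.
    form : str
        ``"printed"`` (Hct**2 factor) or ``"classic"`` (Hct/2 factor).
    gamma_floor : float
        Lower clip applied to shear rates by :func:`viscosity_field`;
        also the shear rate at which admissibility is checked on
        construction.  1/s.
    """

    rho: float = BLOOD_DENSITY
    mu_p: float = 1.32e-3
    hct: float = 0.40
    k0: float = 4.33
    k_inf: float = 2.07
    gamma_c: float = 1.88
    form: str = "printed"
    gamma_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"density must be positive, got {self.rho}")
        if self.mu_p <= 0:
            raise ValueError(f"plasma viscosity must be positive, got {self.mu_p}")
        if not 0.0 <= self.hct < 1.0:
            raise ValueError(f"hematocrit must lie in [0, 1), got {self.hct}")
        if self.gamma_c <= 0:
            raise ValueError(f"critical shear rate must be positive, got {self.gamma_c}")
        if not self.k0 >= self.k_inf > 0:
            raise ValueError(
                f"shear thinning requires k0 >= k_inf > 0, got k0={self.k0}, k_inf={self.k_inf}"
            )
        if self.form not in ("printed", "classic"):
            raise ValueError(f"form must be 'printed' or 'classic', got {self.form!r}")
        if self.gamma_floor <= 0:
            raise ValueError(f"gamma_floor must be positive, got {self.gamma_floor}")
        # Admissibility: the denominator must stay positive down to the
        # shear-rate floor, otherwise the solver could hit a singularity.
        viscosity(self.gamma_floor, self)

    def hct_factor(self) -> float:
        return self.hct**2 if self.form == "printed" else 0.5 * self.hct


def inner_viscosity_K(gamma, props: BloodProperties):
    """Intrinsic (inner) viscosity K of the erythrocyte phase.

    ``K = (k0 + k_inf*sqrt(gamma/gamma_c)) / (1 + sqrt(gamma/gamma_c))``.
    Decreases monotonically from ``k0`` at rest to ``k_inf`` at infinite
    shear when ``k0 > k_inf``.  Accepts scalars or arrays.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("shear rate must be non-negative")
    s = np.sqrt(gamma / props.gamma_c)
    out = (props.k0 + props.k_inf * s) / (1.0 + s)
    return float(out) if out.ndim == 0 else out


def viscosity(gamma, props: BloodProperties):
    """Apparent blood viscosity mu(gamma), Pa*s.

    Raises :class:`RheologySaturationError` when the Quemada denominator
    ``1 - K*f(Hct)`` is non-positive at the requested shear rate.
    """
    K = inner_viscosity_K(gamma, props)
    denom = 1.0 - np.asarray(K) * props.hct_factor()
    if np.any(denom <= 0):
        bad = np.argmin(denom)
        g = np.atleast_1d(np.asarray(gamma, dtype=float)).ravel()
        g_bad = g[bad] if g.size > 1 else g[0]
        raise RheologySaturationError(
            f"Quemada denominator non-positive at gamma={g_bad:.4g} 1/s, "
            f"Hct={props.hct} (form={props.form}); reduce Hct or raise the shear floor"
        )
    out = props.mu_p * denom**-2
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def viscosity_field(shear_rate_field, props: BloodProperties):
    """Elementwise viscosity of a shear-rate field (any shape), Pa*s.

    Shear rates are clipped from below at ``props.gamma_floor`` — the
    regularization used by the flow solver in stagnant zones.
    """
    gamma = np.asarray(shear_rate_field, dtype=float)
    if np.any(gamma < 0):
        raise ValueError("shear rates must be non-negative")
    return np.asarray(viscosity(np.maximum(gamma, props.gamma_floor), props))


def tabulate_viscosity_curve(props: BloodProperties, gamma_grid=None):
    """mu(gamma) samples for reporting; returns (gamma, mu) arrays."""
    if gamma_grid is None:
        gamma_grid = np.logspace(-3, 4, 200)
    gamma = np.asarray(gamma_grid, dtype=float)
    return gamma, viscosity_field(gamma, props)
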