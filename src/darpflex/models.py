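"""Closed-form 1:1 binding models and an exact ODE oracle.

This module is the pure model core of the package.  It contains the three
closed-form signal models used throughout the pipeline:

* the tight-binding (ligand-depletion) equilibrium isotherm, i.e. the
  quadratic solution of ``A + B <=> AB`` expressed as a fluorescence change,
* mono-exponential decay / rise transients for chase and pseudo-first-order
  association experiments,
* the 1:1 Langmuir SPR sensorgram (exponential approach to ``R_eq`` during
  the injection, exponential wash-out afterwards),

plus a brute-force numerical integrator of the underlying mass-action scheme
that serves as the independent accuracy standard for all of them.

All quantities are SI internally: concentrations in mol/L, times in s,
rate constants in 1/(M*s) and 1/s.  Conversion to nM etc. happens only at
I/O and reporting layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "IsothermParams",
    "ExponentialParams",
    "LangmuirParams",
    "OdeTrajectory",
    "eval_isotherm",
    "eval_exponential",
    "eval_langmuir_sensorgram",
    "ode_oracle",
    "equilibrium_complex",
]


class ModelValidationError(ValueError):
    """Raised when model parameters or evaluation inputs are invalid."""


class OdeIntegrationError(RuntimeError):
    """Raised when the mass-action integrator fails to converge."""


def _require_positive_finite(**fields: float) -> None:
    for name, value in fields.items():
        if not np.isfinite(value) or value <= 0:
            raise ModelValidationError(
                f"{name} must be strictly positive and finite, got {value!r}"
            )


@dataclass(frozen=True)
class IsothermParams:
    """Parameters of the depletion-corrected 1:1 equilibrium isotherm.

    Attributes
    ----------
    k_d : float
        Equilibrium dissociation constant (mol/L).
    fluo_max : float
        Fluorescence change at saturating ligand (arbitrary units).
    probe_conc : float
        Total labeled-probe concentration ``[D*]`` (mol/L).
    """

    k_d: float
    fluo_max: float
    probe_conc: float

    def __post_init__(self) -> None:
        _require_positive_finite(
            k_d=self.k_d, fluo_max=self.fluo_max, probe_conc=self.probe_conc
        )


@dataclass(frozen=True)
class ExponentialParams:
    """Parameters of a mono-exponential transient.

    ``direction="decay"`` gives ``baseline + amplitude * exp(-k_obs t)``
    with *baseline* the signal at infinite time; ``direction="rise"`` gives
    ``baseline + amplitude * (1 - exp(-k_obs t))`` with *baseline* the
    signal at time zero.
    """

    baseline: float
    amplitude: float
    k_obs: float
    direction: Literal["decay", "rise"]

    def __post_init__(self) -> None:
        if not np.isfinite(self.k_obs) or self.k_obs <= 0:
            raise ModelValidationError(f"k_obs must be > 0, got {self.k_obs!r}")
        if not (np.isfinite(self.baseline) and np.isfinite(self.amplitude)):
            raise ModelValidationError("baseline and amplitude must be finite")
        if self.direction not in ("decay", "rise"):
            raise ModelValidationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class LangmuirParams:
    """Parameters of the 1:1 Langmuir SPR model at one analyte concentration."""

    k_on: float
    k_off: float
    r_max: float
    analyte_conc: float

    def __post_init__(self) -> None:
        _require_positive_finite(
            k_on=self.k_on,
            k_off=self.k_off,
            r_max=self.r_max,
            analyte_conc=self.analyte_conc,
        )

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on

    @property
    def r_eq(self) -> float:
        """Equilibrium response at this analyte concentration (<= r_max)."""
        c = self.analyte_conc
        return self.r_max * c / (c + self.k_d)


@dataclass(frozen=True)
class OdeTrajectory:
    """Mass-action trajectory of the ``A + B <=> AB`` scheme.

    ``free_probe + complex`` and ``free_ligand + complex`` are conserved
    along the trajectory (``free_ligand`` is held constant in flow mode).
    """

    time: np.ndarray
    free_probe: np.ndarray
    free_ligand: np.ndarray
    complex: np.ndarray


def _validate_conc_array(name: str, values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ModelValidationError(f"{name} contains non-finite values")
    if np.any(arr < 0):
        raise ModelValidationError(f"{name} contains negative values")
    return arr


def eval_isotherm(params: IsothermParams, ligand_conc: np.ndarray) -> np.ndarray:
    """Fluorescence change of the tight-binding 1:1 isotherm.

    Evaluates the quadratic (probe-depletion-corrected) solution

    ``dFluo = fluo_max * ((K_D + T + D) - sqrt((K_D + T + D)^2 - 4 T D)) / (2 D)``

    with ``T`` the total ligand and ``D`` the total probe concentration.
    The result is the bound-probe fraction scaled by ``fluo_max``; it lies
    in ``[0, fluo_max)`` and is non-decreasing in ``T``.
    """
    t = _validate_conc_array("ligand_conc", ligand_conc)
    k_d, d = params.k_d, params.probe_conc
    s = k_d + t + d
    disc = s * s - 4.0 * t * d
    # Floating-point safety at exact stoichiometric points: the discriminant
    # is mathematically >= 0 but can round slightly below zero.
    disc = np.where(disc < 0, np.where(disc > -1e-12 * s * s, 0.0, disc), disc)
    if np.any(disc < 0):
        raise ModelValidationError("isotherm discriminant negative beyond tolerance")
    bound = (s - np.sqrt(disc)) / (2.0 * d)
    return params.fluo_max * bound


def eval_exponential(params: ExponentialParams, t: np.ndarray) -> np.ndarray:
    """Evaluate a mono-exponential decay or rise on a time grid (t >= 0)."""
    tt = _validate_conc_array("t", t)
    decay = np.exp(-params.k_obs * tt)
    if params.direction == "decay":
        return params.baseline + params.amplitude * decay
    return params.baseline + params.amplitude * (1.0 - decay)


def eval_langmuir_sensorgram(
    params: LangmuirParams,
    t_assoc: np.ndarray,
    t_dissoc: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """1:1 Langmuir sensorgram over an association and a dissociation phase.

    Association (t measured from injection start):
    ``R(t) = R_eq * (1 - exp(-(k_on C + k_off) t))``.
    Dissociation (t measured on the same clock, starting at the end of the
    association window): ``R(t) = R(t_end) * exp(-k_off (t - t_end))``.
    The curve is continuous at the phase boundary.

    Returns the pair of response arrays (association, dissociation).
    """
    ta = _validate_conc_array("t_assoc", t_assoc)
    td = _validate_conc_array("t_dissoc", t_dissoc)
    for name, arr in (("t_assoc", ta), ("t_dissoc", td)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise ModelValidationError(f"{name} must be sorted ascending")
    k_obs = params.k_on * params.analyte_conc + params.k_off
    r_assoc = params.r_eq * (1.0 - np.exp(-k_obs * ta))
    if ta.size == 0:
        raise ModelValidationError("association phase must contain at least one time")
    t_end = ta[-1]
    if td.size and td[0] < t_end:
        raise ModelValidationError("dissociation must start where association ends")
    r_end = params.r_eq * (1.0 - math.exp(-k_obs * t_end))
    r_dissoc = r_end * np.exp(-params.k_off * (td - t_end))
    return r_assoc, r_dissoc


def equilibrium_complex(
    k_d: float, probe_total: float, ligand_total: float
) -> float:
    """Equilibrium complex concentration of the 1:1 scheme (mol/L)."""
    s = k_d + probe_total + ligand_total
    disc = max(s * s - 4.0 * probe_total * ligand_total, 0.0)
    return (s - math.sqrt(disc)) / 2.0


def ode_oracle(
    k_on: float,
    k_off: float,
    probe_total: float,
    ligand_total: float,
    t_grid: np.ndarray,
    constant_ligand: bool = False,
) -> OdeTrajectory:
    """Numerically integrate ``d[AB]/dt = k_on [A][B] - k_off [AB]``.

    The brute-force standard against which every closed form in this module
    is checked.  Starts from zero complex.  With ``constant_ligand=True``
    the free-ligand concentration is pinned at ``ligand_total`` (the SPR
    flow-cell condition); otherwise both totals are conserved.

    The integration is performed on the dimensionless bound fraction
    ``u = [AB]/probe_total`` with atol 1e-12 and rtol 1e-9, so the accuracy
    is relative to the probe concentration whatever its absolute scale —
    deliberately tighter than anything the oracle is used to validate.
    """
    _require_positive_finite(
        k_on=k_on, probe_total=probe_total, ligand_total=ligand_total
    )
    if k_off < 0 or not np.isfinite(k_off):
        raise ModelValidationError(f"k_off must be >= 0, got {k_off!r}")
    t = np.asarray(t_grid, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ModelValidationError("t_grid must be sorted strictly ascending, size >= 2")

    if constant_ligand:
        def rhs(_t: float, y: np.ndarray) -> np.ndarray:
            u = y[0]
            return np.array([k_on * (1.0 - u) * ligand_total - k_off * u])
    else:
        def rhs(_t: float, y: np.ndarray) -> np.ndarray:
            u = y[0]
            return np.array(
                [
                    k_on * (1.0 - u) * (ligand_total - u * probe_total)
                    - k_off * u
                ]
            )

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [0.0],
        t_eval=t,
        method="LSODA",
        atol=1e-12,
        rtol=1e-9,
    )
    if not sol.success:
        raise OdeIntegrationError(
            f"mass-action integration failed: {sol.message} "
            f"(k_on={k_on}, k_off={k_off}, probe={probe_total}, "
            f"ligand={ligand_total}, t_span=({t[0]}, {t[-1]}))"
        )
    c = np.clip(sol.y[0], 0.0, None) * probe_total
    free_probe = probe_total - c
    free_ligand = (
        np.full_like(c, ligand_total) if constant_ligand else ligand_total - c
    )
    return OdeTrajectory(time=t, free_probe=free_probe, free_ligand=free_ligand, complex=c)
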