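"""Eyring-Kramers rate model and closed-form temperature-correction formulas.

The central quantity is the activation heat capacity dCp_act (kJ/mol/K) of a
folding or unfolding reaction, which curves the Eyring plot ln(k/T) vs T.
With dCp_act assumed temperature-independent and T_H the temperature where
the activation enthalpy vanishes (the extremum of the Eyring plot), the plot
is

    ln(k/T) = C2 - dCp_act/(R*T) * [T - T_H - T*ln(T/T_H)]

and the log rate constant measured at one temperature can be transported to
any other.  Folding reactions have dCp_act < 0 (convex plot, maximum at
T_H); unfolding reactions have dCp_act > 0 (concave plot, minimum at T_H).

All temperatures are handled in Kelvin internally; Celsius is accepted only
through :class:`Temperature` constructors.  Heat capacities are plain floats
in kJ/mol/K, so every dCp/R ratio is dimensionless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

__all__ = [
    "R_GAS",
    "T_STANDARD",
    "CELSIUS_OFFSET",
    "Temperature",
    "EyringParams",
    "RateValue",
    "as_kelvin",
    "delta_cp_from_length",
    "t_h_from_enthalpy",
    "beta_from_activation",
    "ln_k_over_t",
    "correct_rate",
    "tanford_beta",
    "beta_u_two_state",
    "beta_u_non_two_state",
    "average_parallel_pathways",
    "MIN_CHAIN_LENGTH",
]

#: Gas constant in kJ/mol/K (CODATA), so dCp [kJ/mol/K] / R is dimensionless.
R_GAS: float = 8.314462618e-3

#: Celsius -> Kelvin offset.
CELSIUS_OFFSET: float = 273.15

#: Shortest chain length in the curated dataset; the empirical dCp(L)
#: regressions are not applied below it.
MIN_CHAIN_LENGTH: int = 34


@dataclass(frozen=True, order=True)
class Temperature:
    """An absolute temperature, stored in Kelvin.

    Use :meth:`from_celsius` at I/O boundaries; everything internal is K.
    """

    kelvin: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.kelvin) or self.kelvin <= 0.0:
            raise ValueError(f"temperature must be a positive finite Kelvin value, got {self.kelvin!r}")

    @classmethod
    def from_celsius(cls, celsius: float) -> "Temperature":
        return cls(celsius + CELSIUS_OFFSET)

    @classmethod
    def from_kelvin(cls, kelvin: float) -> "Temperature":
        return cls(kelvin)

    @property
    def celsius(self) -> float:
        return self.kelvin - CELSIUS_OFFSET

    def __float__(self) -> float:
        return self.kelvin

    def __repr__(self) -> str:  # 2 dp display, full precision retained
        return f"Temperature({self.kelvin:.2f} K)"


#: Standard reporting temperature, 25 C exactly.
T_STANDARD: Temperature = Temperature(298.15)

TemperatureLike = Union[Temperature, float, int]


def as_kelvin(t: TemperatureLike) -> float:
    """Coerce a Temperature or bare Kelvin number to a float in K."""
    k = float(t)
    if not math.isfinite(k) or k <= 0.0:
        raise ValueError(f"temperature must be positive and finite in Kelvin, got {k!r}")
    return k


@dataclass(frozen=True)
class EyringParams:
    """Parameters of one reaction's Eyring curve ln(k/T).

    Attributes
    ----------
    delta_cp_act : float
        Activation heat capacity dCp_act, kJ/mol/K.  Negative for folding,
        positive for unfolding.
    t_h : Temperature
        Temperature of zero activation enthalpy (extremum of the plot), K.
    intercept : float
        The temperature-independent constant C2; equals ln(k/T) at T = T_H.
    """

    delta_cp_act: float
    t_h: Temperature
    intercept: float

    def __post_init__(self) -> None:
        if isinstance(self.t_h, (int, float)):
            object.__setattr__(self, "t_h", Temperature(float(self.t_h)))


@dataclass(frozen=True)
class RateValue:
    """A log rate constant ln(k / s^-1) together with its temperature."""

    ln_k: float
    temperature: Temperature

    def __post_init__(self) -> None:
        if not math.isfinite(self.ln_k):
            raise ValueError("ln_k must be finite")


def delta_cp_from_length(l_pdb: int, model: str = "with_intercept") -> float:
    """Equilibrium unfolding heat capacity dCp (kJ/mol/K) from chain length.

    Two empirical regressions on the number of residues in the PDB
    structure are supported:

    * ``"with_intercept"`` (default): dCp = 0.062 * L_PDB - 0.53
    * ``"zero_intercept"``:           dCp = 0.058 * L_PDB

    For chains of >= 34 residues the two give essentially identical
    temperature corrections; the regression is not applied below that
    length (shorter polypeptides fall outside the curated dataset).
    """
    l_pdb = int(l_pdb)
    if l_pdb < MIN_CHAIN_LENGTH:
        raise ValueError(
            f"chain length {l_pdb} is below dataset minimum length {MIN_CHAIN_LENGTH}; "
            "the empirical dCp(L) regression does not apply"
        )
    if model == "with_intercept":
        return 0.062 * l_pdb - 0.53
    if model == "zero_intercept":
        return 0.058 * l_pdb
    raise ValueError(f"unknown dCp model {model!r}; expected 'with_intercept' or 'zero_intercept'")


def t_h_from_enthalpy(t_a: TemperatureLike, delta_h_act: float, delta_cp_act: float) -> Temperature:
    """Temperature of zero activation enthalpy from (T_a, dH_act, dCp_act).

    With dCp_act constant, dH_act(T) = dCp_act * (T - T_H), so

        T_H = T_a - dH_act(T_a) / dCp_act.

    ``delta_h_act`` is in kJ/mol at the reference temperature ``t_a``;
    ``delta_cp_act`` in kJ/mol/K and must be nonzero.
    """
    if delta_cp_act == 0.0:
        raise ValueError("T_H is undefined when the activation heat capacity is zero")
    return Temperature(as_kelvin(t_a) - delta_h_act / delta_cp_act)


def beta_from_activation(delta_cp_act: float, delta_cp_eq: float) -> float:
    """Proportionality constant beta = dCp_act / dCp.

    ``delta_cp_eq`` is the equilibrium unfolding heat capacity (> 0).
    Negative for folding, positive for unfolding.
    """
    if delta_cp_eq <= 0.0:
        raise ValueError(f"equilibrium heat capacity must be positive, got {delta_cp_eq!r}")
    return delta_cp_act / delta_cp_eq


def ln_k_over_t(params: EyringParams, t: TemperatureLike) -> float:
    """Evaluate the Eyring curve ln(k/T) at temperature ``t`` (K).

    ln(k/T) = C2 - dCp_act/(R*T) * [T - T_H - T*ln(T/T_H)]

    At T = T_H the bracket vanishes and the value is exactly C2.
    """
    t_k = as_kelvin(t)
    t_h = params.t_h.kelvin
    bracket = t_k - t_h - t_k * math.log(t_k / t_h)
    return params.intercept - params.delta_cp_act / (R_GAS * t_k) * bracket


def correct_rate(
    ln_k_x: float,
    t_x: TemperatureLike,
    delta_cp_act: float,
    t_h: TemperatureLike,
    t_target: TemperatureLike = T_STANDARD,
) -> float:
    """Transport a log rate constant from ``t_x`` to ``t_target``.

    Given ln k measured at T_x, the predicted value at the target
    temperature T_0 (default 298.15 K) is

        ln k(T_0) = ln k(T_x)
                    + [1 + dCp_act/R] * ln(T_0/T_x)
                    + dCp_act/R * (1/T_0 - 1/T_x) * T_H

    When ``t_x == t_target`` every correction term is exactly zero and the
    input is returned bit-identically.
    """
    t_x_k = as_kelvin(t_x)
    t_0_k = as_kelvin(t_target)
    t_h_k = as_kelvin(t_h)
    ratio = delta_cp_act / R_GAS
    return (
        ln_k_x
        + (1.0 + ratio) * math.log(t_0_k / t_x_k)
        + ratio * (1.0 / t_0_k - 1.0 / t_x_k) * t_h_k
    )


def tanford_beta(m_u_act: float, m_nu: float) -> float:
    """Tanford beta_T = 1 - m_u_act / m_NU.

    ``m_u_act`` is the denaturant dependence of the unfolding activation
    free energy and ``m_nu`` that of the N->U unfolding free energy (both
    kJ/mol/M).  beta_T locates the transition state between the unfolded
    (0) and native (1) states on the denaturant m-value coordinate.
    """
    if m_nu == 0.0:
        raise ValueError("beta_T is undefined when m_NU is zero")
    return 1.0 - m_u_act / m_nu


def beta_u_two_state(beta_f: float) -> float:
    """Unfolding proportionality constant for two-state folders.

    A two-state reaction crosses a single barrier, so the folding and
    unfolding activation heat capacities sum to the equilibrium dCp:
    beta_u = 1 + beta_f.
    """
    return 1.0 + beta_f


def beta_u_non_two_state(mean_beta_t: float) -> float:
    """Unfolding proportionality constant for non-two-state folders.

    The Tanford beta locates the rate-limiting transition state on the
    m-value coordinate, and 1 - beta_T estimates beta_u when a stable
    intermediate decouples the folding-side relation.
    """
    if not 0.0 <= mean_beta_t <= 1.0:
        raise ValueError(f"mean Tanford beta must lie in [0, 1], got {mean_beta_t!r}")
    return 1.0 - mean_beta_t


def average_parallel_pathways(
    fractions: Sequence[float],
    rates: Sequence[float],
    tol: float = 0.01,
) -> float:
    """Amplitude-weighted rate constant over parallel folding pathways.

    k_f = sum_i f_i * k_i, with f_i the fractional amplitude and k_i the
    observed rate constant (s^-1) of pathway i.  Fractions must be
    nonnegative and sum to 1 within ``tol``; sums inside the tolerance but
    not exactly 1 are renormalized.
    """
    fractions = [float(f) for f in fractions]
    rates = [float(k) for k in rates]
    if len(fractions) != len(rates):
        raise ValueError(f"{len(fractions)} fractions but {len(rates)} rates")
    if not fractions:
        raise ValueError("at least one pathway is required")
    if any(f < 0.0 for f in fractions):
        raise ValueError("fractional amplitudes must be nonnegative")
    if any(k <= 0.0 for k in rates):
        raise ValueError("rate constants must be positive")
    total = sum(fractions)
    if abs(total - 1.0) > tol:
        raise ValueError(f"fractional amplitudes sum to {total:.4f}, outside 1 +/- {tol}")
    if total != 1.0:
        warnings.warn(
            f"fractional amplitudes sum to {total:.4f}; renormalizing to 1",
            stacklevel=2,
        )
    return sum(f * k for f, k in zip(fractions, rates)) / total
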