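"""Arrhenius temperature correction for biological and chemical rates.

All rate constants in the model (energy conductance, maintenance,
toxicokinetic rates, exposure decay, plant growth) are defined at a
reference temperature and multiplied by a dimensionless correction
factor ``c_T`` at the ambient temperature.  The correction follows the
five-parameter Arrhenius formulation used throughout dynamic energy
budget (DEB) modelling: a core exponential term with Arrhenius
temperature ``T_A`` and optional boundary terms that depress rates
below a lower boundary ``T_L`` and above an upper boundary ``T_H``.

Two response shapes are shipped: a both-boundaries response for the
whitefly and an upper-boundary-only response for the cotton host
plant, whose rate peaks at an intermediate temperature.

Public interfaces accept temperatures in degrees Celsius; conversion
to Kelvin happens internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "BoundaryMode",
    "TemperatureResponse",
    "arrhenius_factor",
    "validate_temperature_params",
]

KELVIN_OFFSET = 273.15
ABSOLUTE_ZERO_C = -273.15

# exp() argument clip: keeps boundary terms finite far outside the
# viable range without affecting any temperature a scenario would use
_EXP_CLIP = 700.0


class BoundaryMode(str, Enum):
    """Which boundary terms of the Arrhenius response are active."""

    BOTH_BOUNDARIES = "both_boundaries"
    UPPER_ONLY = "upper_only"
    PLAIN = "plain"


@dataclass(frozen=True)
class TemperatureResponse:
    """Five-parameter Arrhenius temperature response.

    Parameters
    ----------
    T_ref:
        Reference temperature (K) at which rate constants are defined;
        the correction factor is exactly 1 there.
    T_A:
        Arrhenius temperature (K) of the core exponential term.
    T_L, T_AL:
        Lower boundary temperature and its Arrhenius temperature (K);
        used only in ``both_boundaries`` mode.
    T_H, T_AH:
        Upper boundary temperature and its Arrhenius temperature (K);
        used in ``both_boundaries`` and ``upper_only`` modes.
    mode:
        Boundary configuration.
    """

    T_ref: float
    T_A: float
    T_L: float | None = None
    T_H: float | None = None
    T_AL: float | None = None
    T_AH: float | None = None
    mode: BoundaryMode = BoundaryMode.PLAIN

    def factor(self, T_celsius):
        """Correction factor at ambient temperature(s) in Celsius."""
        return arrhenius_factor(T_celsius, self)


def _boundary_term(T_K: np.ndarray, resp: TemperatureResponse) -> np.ndarray:
    """s(T) = 1 + lower term + upper term, per mode."""
    mode = BoundaryMode(resp.mode)
    s = np.ones_like(T_K)
    if mode is BoundaryMode.PLAIN:
        return s
    if mode is BoundaryMode.BOTH_BOUNDARIES:
        s = s + np.exp(
            np.clip(resp.T_AL / T_K - resp.T_AL / resp.T_L, -_EXP_CLIP, _EXP_CLIP)
        )
    s = s + np.exp(
        np.clip(resp.T_AH / resp.T_H - resp.T_AH / T_K, -_EXP_CLIP, _EXP_CLIP)
    )
    return s


def arrhenius_factor(T_celsius, resp: TemperatureResponse):
    """Dimensionless rate multiplier at ambient temperature ``T_celsius``.

    The core factor ``exp(T_A/T_ref - T_A/T)`` is multiplied by the
    boundary correction ``s(T_ref)/s(T)``, so the result is normalized
    to 1 at the reference temperature by construction.

    Accepts scalars or arrays; returns the matching shape.
    """
    violations = validate_temperature_params(resp)
    if violations:
        raise ValueError("invalid TemperatureResponse: " + "; ".join(violations))
    T_arr = np.asarray(T_celsius, dtype=float)
    if not np.all(np.isfinite(T_arr)):
        raise ValueError("temperature must be finite")
    if np.any(T_arr <= ABSOLUTE_ZERO_C):
        raise ValueError("temperature below absolute zero")
    T_K = T_arr + KELVIN_OFFSET
    core = np.exp(resp.T_A / resp.T_ref - resp.T_A / T_K)
    s_ref = _boundary_term(np.asarray(resp.T_ref, dtype=float), resp)
    out = core * (s_ref / _boundary_term(T_K, resp))
    if np.isscalar(T_celsius) or np.ndim(T_celsius) == 0:
        return float(out)
    return out


def validate_temperature_params(resp: TemperatureResponse) -> list[str]:
    """Return a list of invariant violations (empty when well-formed)."""
    violations: list[str] = []
    mode = resp.mode
    if not isinstance(mode, BoundaryMode):
        try:
            mode = BoundaryMode(mode)
        except ValueError:
            return [f"mode: unknown boundary mode {resp.mode!r}"]

    def _check_finite_positive(name: str) -> bool:
        value = getattr(resp, name)
        if value is None:
            violations.append(f"{name}: required for mode {mode.value}")
            return False
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            violations.append(f"{name}: must be finite, got {value!r}")
            return False
        if value <= 0:
            violations.append(f"{name}: must be > 0 K, got {value!r}")
            return False
        return True

    ok = _check_finite_positive("T_ref") & _check_finite_positive("T_A")
    needs_upper = mode in (BoundaryMode.BOTH_BOUNDARIES, BoundaryMode.UPPER_ONLY)
    needs_lower = mode is BoundaryMode.BOTH_BOUNDARIES
    if needs_upper:
        ok &= _check_finite_positive("T_H") & _check_finite_positive("T_AH")
    if needs_lower:
        ok &= _check_finite_positive("T_L") & _check_finite_positive("T_AL")
        if ok and resp.T_H is not None and resp.T_L is not None:
            if resp.T_H <= resp.T_L:
                violations.append(
                    f"T_H: upper boundary {resp.T_H} K must exceed "
                    f"lower boundary T_L={resp.T_L} K"
                )
    return violations
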