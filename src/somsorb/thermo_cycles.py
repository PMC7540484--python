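"""Thermodynamic-cycle composition of decoupling free energies.

Sorption and hydration free energies are differences of decoupling free
energies around a closed cycle: ΔG_sorb = ΔG_vac − ΔG_env (env = humic-acid
matrix) and ΔG_hyd = ΔG_vac − ΔG_water.  Errors propagate in quadrature.
Experimental partition coefficients map to free energies as −RT ln K + c,
with c an unknown additive constant: all comparisons against experiment are
therefore shift-invariant (correlations and fixed-slope-1 offsets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, rt
from .errors import InvalidInputError
from .work_estimators import FreeEnergyEstimate

__all__ = [
    "CompoundRecord",
    "sorption_free_energy",
    "hydration_free_energy",
    "relative_sorption",
    "water_activity",
    "partition_to_free_energy",
    "anchor_nonpositive",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One sorbate: calculated dry/hydrated sorption ΔG (kJ/mol) with
    bootstrap errors, their hydrated−dry difference with propagated error,
    and anchored experimental values for both hydration states."""

    name: str
    group: str
    dg_dry_calc: float
    dg_dry_err: float
    dg_hyd_calc: float
    dg_hyd_err: float
    ddg_calc: float
    ddg_err: float
    ddg_exp_dry: float
    ddg_exp_hyd: float

    def consistent(self, tol: float = 0.05) -> bool:
        """Printed ΔΔG column agrees with hydrated − dry within rounding."""
        return abs((self.dg_hyd_calc - self.dg_dry_calc) - self.ddg_calc) <= tol


def _compose(a: FreeEnergyEstimate, b: FreeEnergyEstimate) -> FreeEnergyEstimate:
    if not (math.isfinite(a.value) and math.isfinite(b.value)):
        raise InvalidInputError("free-energy estimates must be finite")
    return FreeEnergyEstimate(
        value=a.value - b.value,
        uncertainty=math.hypot(a.uncertainty, b.uncertainty),
        method="derived",
    )


def sorption_free_energy(
    dg_vac: FreeEnergyEstimate, dg_env: FreeEnergyEstimate
) -> FreeEnergyEstimate:
    """ΔG_sorb = ΔG_vac − ΔG_env with quadrature error propagation."""
    return _compose(dg_vac, dg_env)


def hydration_free_energy(
    dg_vac: FreeEnergyEstimate, dg_water: FreeEnergyEstimate
) -> FreeEnergyEstimate:
    """ΔG_hyd = ΔG_vac − ΔG_water; same cycle with water as environment."""
    return _compose(dg_vac, dg_water)


def relative_sorption(
    hyd: FreeEnergyEstimate, dry: FreeEnergyEstimate
) -> FreeEnergyEstimate:
    """ΔΔG_sorb = hydrated − dry, errors in quadrature."""
    if not (math.isfinite(hyd.value) and math.isfinite(dry.value)):
        raise InvalidInputError("free-energy estimates must be finite")
    return FreeEnergyEstimate(
        value=hyd.value - dry.value,
        uncertainty=math.hypot(hyd.uncertainty, dry.uncertainty),
        method="derived",
    )


def water_activity(
    dg_water_to_env: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """a_w = exp(ΔG_water→env / RT): the transfer free energy of one water
    molecule from bulk water into the matrix sets its activity there."""
    return math.exp(dg_water_to_env / rt(temperature))


def partition_to_free_energy(
    k: float, temperature: float = DEFAULT_TEMPERATURE, c: float = 0.0
) -> float:
    """Experimental-scale conversion ΔG = −RT ln K + c (K a matrix/air
    partition coefficient, c the elusive additive constant)."""
    if k <= 0:
        raise InvalidInputError(f"partition coefficient must be positive, got {k}")
    return -rt(temperature) * math.log(k) + c


def anchor_nonpositive(values: Iterable[float] | Sequence[float]) -> np.ndarray:
    """Shift a free-energy series so its maximum is 0 (all values ≤ 0).

    Pairwise differences, ordering and all correlation statistics are
    unaffected; only the arbitrary additive constant changes.
    """
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if v.size == 0:
        raise InvalidInputError("cannot anchor an empty series")
    return v - v.max()
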