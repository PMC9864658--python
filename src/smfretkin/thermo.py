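"""Arrhenius activation energies, free-energy landscapes, and distances.

Inverting the Arrhenius relation ``k = A exp(-E_a / RT)`` gives the
activation energy of a transition, ``E_a = RT (ln A - ln k)``.  The
pre-exponential factor is not measurable from a single-temperature
experiment; the default A = 1e3 1/s is an order-of-magnitude convention,
so absolute barrier heights shift by ``RT ln A`` while *differences* —
well-depth gaps ``dG(i->j) = RT ln(k_ji / k_ij)`` — are prefactor-free and
are the physically meaningful output.

A landscape orders the states along a reaction coordinate, accumulates
well energies from the detailed-balance differences of adjacent rate
pairs, shifts the deepest well to zero, and reports each barrier height
above its departure well.  By construction
``barrier(i->j) - barrier(j->i) = well(j) - well(i)``.

Mean donor-acceptor distances follow from the FRET efficiency via
``r = R0 (1/E - 1)^(1/6)``; the Förster radius default (5.4 nm) is a
common literature figure for the Cy3/Cy5 pair and is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import RateTable

__all__ = [
    "ArrheniusParams",
    "EnergyLandscape",
    "LandscapeError",
    "arrhenius_energy",
    "build_landscape",
    "fret_to_distance",
    "distance_to_fret",
]

#: Default Förster radius for the Cy3/Cy5 pair, nm.
DEFAULT_R0_NM = 5.4


class LandscapeError(ValueError):
    """A rate needed for the requested reaction coordinate is missing."""


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius inversion constants: prefactor A (1/s), R (J/K/mol), T (K)."""

    A: float = 1e3
    R: float = 8.31
    T: float = 297.0

    def __post_init__(self) -> None:
        if self.A <= 0 or self.R <= 0 or self.T <= 0:
            raise ValueError("A, R, T must all be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


def arrhenius_energy(k: float, p: ArrheniusParams = ArrheniusParams()) -> float:
    """Activation energy E_a = RT (ln A - ln k) in J/mol.

    Exactly linear in ln k with slope -RT; zero at k = A; negative (with a
    warning) for rates faster than the prefactor.
    """
    if not k > 0:
        raise ValueError(f"rate must be > 0, got {k}")
    e_a = p.RT * (np.log(p.A) - np.log(k))
    if k > p.A:
        warnings.warn(
            f"rate {k} 1/s exceeds the prefactor A={p.A} 1/s; "
            f"activation energy is negative",
            stacklevel=2,
        )
    return float(e_a)


@dataclass
class EnergyLandscape:
    """Wells and barriers along an ordered reaction coordinate (J/mol).

    Well energies are relative to the condition's most stable state (0);
    ``barriers[(i, j)]`` is the height above well ``i`` for the ordered
    transition i -> j.
    """

    states: list[str]
    wells: dict[str, float]
    barriers: dict[tuple[str, str], float]
    condition: str = ""
    params: ArrheniusParams = field(default_factory=ArrheniusParams)

    def delta_g(self, i: str, j: str) -> float:
        """Well-depth difference well(j) - well(i)."""
        return self.wells[j] - self.wells[i]


def build_landscape(
    rates: RateTable,
    state_order: list[str],
    p: ArrheniusParams = ArrheniusParams(),
    condition: str = "",
) -> EnergyLandscape:
    """Assemble the free-energy landscape along ``state_order``.

    Every adjacent ordered pair must carry a non-excluded forward and
    backward rate.  Well energies accumulate the detailed-balance
    differences ``dG(i->j) = RT ln(k_ji / k_ij)`` along the coordinate and
    are shifted so the deepest well sits at 0; barriers are the Arrhenius
    energies of the individual rates, measured above the departure well.
    """
    if len(state_order) < 2:
        raise LandscapeError("need at least two states on the coordinate")
    for a, b in zip(state_order[:-1], state_order[1:]):
        for pair in ((a, b), (b, a)):
            e = rates.entries.get(pair)
            if e is None or e.excluded or e.k is None:
                why = e.reason if e is not None else "not observed"
                raise LandscapeError(
                    f"rate {pair[0]}->{pair[1]} unavailable ({why}); "
                    f"cannot build landscape {state_order}"
                )

    wells = {state_order[0]: 0.0}
    for a, b in zip(state_order[:-1], state_order[1:]):
        dg = p.RT * np.log(rates.rate(b, a) / rates.rate(a, b))
        wells[b] = wells[a] + dg
    shift = min(wells.values())
    wells = {s: w - shift for s, w in wells.items()}

    barriers: dict[tuple[str, str], float] = {}
    for a, b in zip(state_order[:-1], state_order[1:]):
        barriers[(a, b)] = arrhenius_energy(rates.rate(a, b), p)
        barriers[(b, a)] = arrhenius_energy(rates.rate(b, a), p)
    return EnergyLandscape(
        states=list(state_order), wells=wells, barriers=barriers,
        condition=condition, params=p,
    )


def fret_to_distance(E: float, R0: float = DEFAULT_R0_NM) -> float:
    """Donor-acceptor distance r = R0 (1/E - 1)^(1/6), in R0's units."""
    if not 0.0 < E < 1.0:
        raise ValueError(f"E must lie strictly in (0, 1), got {E}")
    if not R0 > 0:
        raise ValueError("R0 must be positive")
    return float(R0 * (1.0 / E - 1.0) ** (1.0 / 6.0))


def distance_to_fret(r: float, R0: float = DEFAULT_R0_NM) -> float:
    """Inverse of :func:`fret_to_distance`: E = 1 / (1 + (r/R0)^6)."""
    if not r > 0 or not R0 > 0:
        raise ValueError("r and R0 must be positive")
    return float(1.0 / (1.0 + (r / R0) ** 6))
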