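"""Conceptual-DFT reactivity descriptors from frontier-orbital energies.

Electrophilicity is the chemistry behind the alert statistics: reactive
metabolites damage proteins because they are strong electrophiles. Given
HOMO/LUMO energies from any electronic-structure source, this module
computes the global descriptors

    hardness            eta   = (E_LUMO - E_HOMO) / 2
    chemical potential  mu    = (E_LUMO + E_HOMO) / 2
    electrophilicity    omega = mu**2 / (2 * eta)

and ranks compounds by omega (a higher index means a stronger electrophile,
e.g. nitrosobenzene or quinone imine versus their parent aniline). Energies
default to hartree; quantum-chemistry runs themselves are out of scope —
the module consumes whatever orbital energies the user supplies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import DataError, FormatError

HARTREE_TO_EV = 27.211386

__all__ = [
    "HARTREE_TO_EV",
    "FrontierOrbitalEnergies",
    "ReactivityDescriptors",
    "compute_descriptors",
    "rank_by_electrophilicity",
    "load_orbital_energies",
    "write_descriptors",
]


@dataclass(frozen=True)
class FrontierOrbitalEnergies:
    """HOMO/LUMO energies of one compound; the gap must be positive."""

    compound_id: str
    e_homo: float
    e_lumo: float
    unit: str = "hartree"

    def __post_init__(self) -> None:
        if self.e_lumo <= self.e_homo:
            raise DataError(
                f"{self.compound_id}: E_LUMO ({self.e_lumo}) must exceed E_HOMO ({self.e_homo})"
            )
        if self.unit not in {"hartree", "eV"}:
            raise DataError(f"{self.compound_id}: unknown energy unit {self.unit!r}")

    def to_ev(self) -> "FrontierOrbitalEnergies":
        if self.unit == "eV":
            return self
        return FrontierOrbitalEnergies(
            self.compound_id, self.e_homo * HARTREE_TO_EV, self.e_lumo * HARTREE_TO_EV, "eV"
        )

    def to_hartree(self) -> "FrontierOrbitalEnergies":
        if self.unit == "hartree":
            return self
        return FrontierOrbitalEnergies(
            self.compound_id, self.e_homo / HARTREE_TO_EV, self.e_lumo / HARTREE_TO_EV, "hartree"
        )


@dataclass(frozen=True)
class ReactivityDescriptors:
    """Global hardness eta, chemical potential mu, electrophilicity omega.

    All three share the unit of the input energies. Note that omega is not
    invariant under a uniform shift of both orbital energies: it equals
    (E_LUMO + E_HOMO)^2 / (4 * (E_LUMO - E_HOMO)), so shifting changes the
    numerator but not the denominator.
    """

    eta: float
    mu: float
    omega: float
    unit: str = "hartree"


def compute_descriptors(energies: FrontierOrbitalEnergies) -> ReactivityDescriptors:
    """eta, mu and omega from one compound's frontier-orbital energies."""
    eta = (energies.e_lumo - energies.e_homo) / 2.0
    mu = (energies.e_lumo + energies.e_homo) / 2.0
    omega = mu * mu / (2.0 * eta)
    return ReactivityDescriptors(eta=eta, mu=mu, omega=omega, unit=energies.unit)


def rank_by_electrophilicity(
    compounds: Sequence[FrontierOrbitalEnergies],
) -> list[tuple[FrontierOrbitalEnergies, ReactivityDescriptors]]:
    """Order compounds as an electrophile ranking.

    Primary key: descending omega (stronger electrophile first); secondary
    key: ascending E_LUMO (an easier-to-fill LUMO breaks ties); final
    tie-break: compound_id, for a stable, reproducible order. Mixing energy
    units across compounds is an error.
    """
    if not compounds:
        raise DataError("rank_by_electrophilicity needs at least one compound")
    units = {c.unit for c in compounds}
    if len(units) > 1:
        raise DataError(f"mixed energy units {sorted(units)}; convert before ranking")
    ranked = [(c, compute_descriptors(c)) for c in compounds]
    ranked.sort(key=lambda pair: (-pair[1].omega, pair[0].e_lumo, pair[0].compound_id))
    return ranked


def load_orbital_energies(path: str | Path) -> list[FrontierOrbitalEnergies]:
    """Read a CSV of compound_id,e_homo,e_lumo[,unit] (unit defaults to hartree)."""
    frame = pd.read_csv(path)
    required = {"compound_id", "e_homo", "e_lumo"}
    if not required.issubset(frame.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    out = []
    for row in frame.itertuples(index=False):
        unit = getattr(row, "unit", "hartree")
        if pd.isna(unit):
            unit = "hartree"
        out.append(
            FrontierOrbitalEnergies(
                compound_id=str(row.compound_id),
                e_homo=float(row.e_homo),
                e_lumo=float(row.e_lumo),
                unit=str(unit),
            )
        )
    return out


def write_descriptors(
    ranked: Sequence[tuple[FrontierOrbitalEnergies, ReactivityDescriptors]],
    path: str | Path,
) -> None:
    """Write the ranked descriptor table (input columns plus eta, mu, omega)."""
    pd.DataFrame(
        {
            "compound_id": [c.compound_id for c, _ in ranked],
            "e_homo": [c.e_homo for c, _ in ranked],
            "e_lumo": [c.e_lumo for c, _ in ranked],
            "unit": [c.unit for c, _ in ranked],
            "eta": [d.eta for _, d in ranked],
            "mu": [d.mu for _, d in ranked],
            "omega": [d.omega for _, d in ranked],
        }
    ).to_csv(path, index=False)
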