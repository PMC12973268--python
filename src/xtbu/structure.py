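"""Molecular structures with spin-channel electron bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_PER_ANGSTROM, normalize_symbol


@dataclass
class AtomicStructure:
    """A molecule: element symbols, Cartesian coordinates, charge, and the
    per-spin-channel electron counts.

    Coordinates are stored in Bohr (``coordinates_bohr``); construct from
    Angstrom via :meth:`from_angstrom`.  ``n_alpha``/``n_beta`` are resolved
    from charge and multiplicity against the valence electron count of the
    parameterization (see :meth:`resolve_electrons`), with
    ``n_alpha - n_beta = multiplicity - 1``.
    """

    elements: list[str]
    coordinates_bohr: np.ndarray
    total_charge: int = 0
    multiplicity: int = 1
    n_alpha: int | None = None
    n_beta: int | None = None
    comment: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.elements = [normalize_symbol(s) for s in self.elements]
        self.coordinates_bohr = np.asarray(self.coordinates_bohr, dtype=float)
        if len(self.elements) < 1:
            raise ValueError("structure needs at least one atom")
        if self.coordinates_bohr.shape != (len(self.elements), 3):
            raise ValueError(
                f"coordinate shape {self.coordinates_bohr.shape} does not match "
                f"{len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(self.coordinates_bohr)):
            raise ValueError("coordinates must be finite")

    @classmethod
    def from_angstrom(
        cls,
        elements: list[str],
        coordinates_angstrom,
        total_charge: int = 0,
        multiplicity: int = 1,
        comment: str = "",
    ) -> "AtomicStructure":
        coords = np.asarray(coordinates_angstrom, dtype=float) * BOHR_PER_ANGSTROM
        return cls(list(elements), coords, total_charge, multiplicity, comment=comment)

    @property
    def natoms(self) -> int:
        return len(self.elements)

    def resolve_electrons(self, valence_counts: dict[str, int]) -> None:
        """Fill n_alpha / n_beta from charge + multiplicity.

        ``valence_counts`` maps element symbol to its valence electron count.
        Raises if the multiplicity is inconsistent with the electron count
        (parity or exceeding the total).
        """
        nelec = sum(valence_counts[el] for el in self.elements) - self.total_charge
        if nelec < 0:
            raise ValueError(f"negative electron count ({nelec}) for charge {self.total_charge}")
        nspin = self.multiplicity - 1
        if nspin < 0 or (nelec - nspin) % 2 != 0 or nspin > nelec:
            raise ValueError(
                f"multiplicity {self.multiplicity} inconsistent with {nelec} electrons"
            )
        self.n_beta = (nelec - nspin) // 2
        self.n_alpha = nelec - self.n_beta
        assert self.n_alpha >= self.n_beta

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coordinates_bohr[i] - self.coordinates_bohr[j]))

    def translated(self, shift_bohr) -> "AtomicStructure":
        return AtomicStructure(
            list(self.elements),
            self.coordinates_bohr + np.asarray(shift_bohr, float),
            self.total_charge,
            self.multiplicity,
            self.n_alpha,
            self.n_beta,
        )

    def rotated(self, rotation_matrix) -> "AtomicStructure":
        R = np.asarray(rotation_matrix, float)
        return AtomicStructure(
            list(self.elements),
            self.coordinates_bohr @ R.T,
            self.total_charge,
            self.multiplicity,
            self.n_alpha,
            self.n_beta,
        )
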