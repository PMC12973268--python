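"""Shell-resolved minimal basis built from the parameter table.

Shell ordering is fixed: atoms in input order, shells per atom in increasing
angular momentum, and the 2l+1 spherical components of a shell ordered
m = -l ... +l.  All matrices in the package use this AO ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet
from .slater import sto_ng
from .structure import AtomicStructure


class UnsupportedElementError(ValueError):
    pass


@dataclass(frozen=True)
class Shell:
    atom: int
    element: str
    ish: int  # shell index within the element's parameter record
    l: int
    ao_start: int  # first AO index; the shell spans 2l+1 consecutive AOs
    alphas: np.ndarray
    coeffs: np.ndarray  # contraction over radially normalized primitives

    @property
    def nao(self) -> int:
        return 2 * self.l + 1

    @property
    def ao_slice(self) -> slice:
        return slice(self.ao_start, self.ao_start + self.nao)


@dataclass(frozen=True)
class ShellBasis:
    structure: AtomicStructure
    shells: tuple[Shell, ...]
    nao: int
    ao_atom: np.ndarray  # AO index -> atom index
    ao_shell: np.ndarray  # AO index -> shell index

    def atom_shells(self, atom: int) -> list[Shell]:
        return [sh for sh in self.shells if sh.atom == atom]

    @property
    def nshells(self) -> int:
        return len(self.shells)


def build_basis(structure: AtomicStructure, params: ParameterSet) -> ShellBasis:
    """Construct the shell basis; deterministic pure function of its inputs."""
    shells: list[Shell] = []
    ao_atom: list[int] = []
    ao_shell: list[int] = []
    offset = 0
    for iat, sym in enumerate(structure.elements):
        try:
            el = params.element(sym)
        except Exception as exc:
            raise UnsupportedElementError(str(exc)) from exc
        for ish, l in enumerate(el.shells):
            alphas, coeffs = sto_ng(el.pqn[ish], l, el.slater_exp[ish])
            sh = Shell(iat, sym, ish, l, offset, alphas, coeffs)
            shells.append(sh)
            ao_atom.extend([iat] * sh.nao)
            ao_shell.extend([len(shells) - 1] * sh.nao)
            offset += sh.nao
    return ShellBasis(
        structure=structure,
        shells=tuple(shells),
        nao=offset,
        ao_atom=np.asarray(ao_atom, dtype=int),
        ao_shell=np.asarray(ao_shell, dtype=int),
    )
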