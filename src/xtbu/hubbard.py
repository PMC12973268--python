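"""On-site Hubbard +U corrections (FLL, AMF, pSIC).

The correction acts on shell-block occupation matrices built from the
density and overlap by the symmetrized Mulliken projection

    n^sigma[mu, nu] = 1/2 (S P^sigma + P^sigma S)[mu, nu],   mu, nu in one
    same-atom, same-shell block,

and penalizes fractional occupation of the shell.  Three energy functionals
are implemented per shell l with Hubbard parameter U_l and global scaling
alpha (default 0.5):

    FLL :  -alpha U/2 sum_sigma [ tr(n n) - tr(n) ]
    pSIC:  -alpha U/2 sum_sigma tr(n n)
    AMF :  -alpha U/2 sum_sigma tr(dn dn),  dn = n - tr(n)/(2l+1) I

The AO Fock contribution is the exact derivative of the energy with respect
to the density matrix: the occupation-space potential V = dE/dn is mapped to
AO space through the same symmetric chain rule, F = 1/2 (S V + V S).  For
pSIC this gives V = -alpha U n (twice the magnitude a naive reading of the
potential as "energy per electron" would suggest); the finite-difference
variational tests pin this convention down.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .basis import ShellBasis


class UVariant(Enum):
    FLL = "fll"
    AMF = "amf"
    PSIC = "psic"

    @classmethod
    def from_string(cls, s: str | None):
        if s is None or s.lower() in ("none", "off"):
            return None
        try:
            return cls(s.lower())
        except ValueError:
            raise ValueError(f"unknown +U variant {s!r}; use fll, amf, psic or none") from None


@dataclass
class ShellOccupation:
    """Shell-block occupation matrices per spin channel.

    ``n_alpha[k]`` / ``n_beta[k]`` are the (2l+1)x(2l+1) symmetric blocks for
    shell ``k`` in basis order.
    """

    n_alpha: list[np.ndarray]
    n_beta: list[np.ndarray]
    basis: ShellBasis

    def traces(self, channel: str) -> np.ndarray:
        blocks = self.n_alpha if channel == "alpha" else self.n_beta
        return np.array([float(np.trace(b)) for b in blocks])

    def delta_n(self, k: int, channel: str) -> np.ndarray:
        """Deviation from the shell-averaged (isotropic) occupation."""
        n = (self.n_alpha if channel == "alpha" else self.n_beta)[k]
        deg = n.shape[0]
        return n - (np.trace(n) / deg) * np.eye(deg)


def occupation_matrix(
    Pa: np.ndarray, Pb: np.ndarray, S: np.ndarray, basis: ShellBasis
) -> ShellOccupation:
    """Symmetrized Mulliken shell-block occupation matrices for both channels."""
    if Pa.shape != S.shape or Pb.shape != S.shape:
        raise ValueError(
            f"density/overlap dimension mismatch: {Pa.shape}, {Pb.shape} vs {S.shape}"
        )
    na, nb = [], []
    for P, out in ((Pa, na), (Pb, nb)):
        M = 0.5 * (S @ P + P @ S)
        for sh in basis.shells:
            out.append(np.array(M[sh.ao_slice, sh.ao_slice]))
    return ShellOccupation(na, nb, basis)


def _shell_u(params, sh) -> float:
    el = params.element(sh.element)
    u = el.U[sh.ish]
    if u < 0:
        raise ValueError(f"negative Hubbard U for {sh.element} shell {sh.ish}")
    return u


def hubbard_energy(occ: ShellOccupation, variant: UVariant, params) -> float:
    alpha = params.globals.alpha_u
    e = 0.0
    for k, sh in enumerate(occ.basis.shells):
        u = _shell_u(params, sh)
        if u == 0.0:
            continue
        for channel in ("alpha", "beta"):
            n = (occ.n_alpha if channel == "alpha" else occ.n_beta)[k]
            if variant is UVariant.FLL:
                e += -alpha * u / 2.0 * (float(np.sum(n * n)) - float(np.trace(n)))
            elif variant is UVariant.PSIC:
                e += -alpha * u / 2.0 * float(np.sum(n * n))
            elif variant is UVariant.AMF:
                dn = occ.delta_n(k, channel)
                e += -alpha * u / 2.0 * float(np.sum(dn * dn))
    return float(e)


def occupation_potential(
    occ: ShellOccupation, variant: UVariant, params
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """dE_U/dn per shell and channel (occupation-space potential)."""
    alpha = params.globals.alpha_u
    va, vb = [], []
    for k, sh in enumerate(occ.basis.shells):
        u = _shell_u(params, sh)
        deg = 2 * sh.l + 1
        for channel, out in (("alpha", va), ("beta", vb)):
            if u == 0.0:
                out.append(np.zeros((deg, deg)))
                continue
            n = (occ.n_alpha if channel == "alpha" else occ.n_beta)[k]
            if variant is UVariant.FLL:
                v = -alpha * u * (n - 0.5 * np.eye(deg))
            elif variant is UVariant.PSIC:
                v = -alpha * u * n
            elif variant is UVariant.AMF:
                v = -alpha * u * occ.delta_n(k, channel)
            out.append(v)
    return va, vb


def hubbard_fock(
    occ: ShellOccupation, variant: UVariant, params, S: np.ndarray, basis: ShellBasis
) -> tuple[np.ndarray, np.ndarray]:
    """AO-basis Fock contribution per channel (exact derivative of E_U)."""
    va, vb = occupation_potential(occ, variant, params)
    nao = basis.nao
    out = []
    for vlist in (va, vb):
        V = np.zeros((nao, nao))
        for k, sh in enumerate(basis.shells):
            V[sh.ao_slice, sh.ao_slice] = vlist[k]
        out.append(0.5 * (S @ V + V @ S))
    return out[0], out[1]
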