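"""Tight-binding Hamiltonian: energy terms and spin-channel Fock assembly.

The total electronic (free) energy is decomposed as

    E_tot = E_rep + E_EHT + E_IES + E_IXC + E_AES + E_AXC + E_spin
            + E_Fermi + E_U

with a classical pairwise repulsion, an extended-Hueckel band term, isotropic
second-order (shell-charge) electrostatics+XC with a diagonal third-order
term, anisotropic electrostatics from cumulative atomic dipoles/quadrupoles
with damped interaction kernels plus on-site multipole XC, the shell-resolved
spin-polarization energy, the Fermi-smearing entropy (owned by the SCF
driver) and the optional on-site Hubbard correction (owned by
:mod:`xtbu.hubbard`).

Every density-dependent term enters through Mulliken-symmetrized moments
``m = Tr(P M)`` with a symmetric moment matrix ``M``; the Fock contribution
is then exactly ``sum_k (dE/dm_k) M_k``, which makes the analytic Fock the
literal derivative of the energy expression (checked by finite differences in
the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import ShellBasis, build_basis
from .integrals import Integrals, compute_integrals, shift_first_moment, shift_second_moment
from .params import ParameterSet
from .structure import AtomicStructure


class GeometryError(ValueError):
    pass


@dataclass
class EnergyBreakdown:
    """Term-resolved energies in Hartree; E_tot is their exact sum."""

    E_rep: float = 0.0
    E_EHT: float = 0.0
    E_IES: float = 0.0
    E_IXC: float = 0.0
    E_AES: float = 0.0
    E_AXC: float = 0.0
    E_spin: float = 0.0
    E_Fermi: float = 0.0
    E_U: float = 0.0

    TERMS = ("E_rep", "E_EHT", "E_IES", "E_IXC", "E_AES", "E_AXC", "E_spin", "E_Fermi", "E_U")

    @property
    def E_tot(self) -> float:
        return float(sum(getattr(self, t) for t in self.TERMS))

    def as_dict(self) -> dict[str, float]:
        d = {t: float(getattr(self, t)) for t in self.TERMS}
        d["E_tot"] = self.E_tot
        return d


@dataclass
class SpinPopulations:
    """Per-shell alpha-minus-beta Mulliken populations p_Al."""

    by_shell: np.ndarray  # (nshells,)
    basis: ShellBasis = field(repr=False)

    def total(self) -> float:
        return float(self.by_shell.sum())


def coordination_numbers(structure: AtomicStructure, params: ParameterSet) -> np.ndarray:
    """GFN-style coordination numbers from a double-logistic counting function."""
    from .constants import BOHR_PER_ANGSTROM

    n = structure.natoms
    cn = np.zeros(n)
    scale = params.globals.cn_radius_scale
    rcov = np.array(
        [params.element(el).cov_radius * BOHR_PER_ANGSTROM for el in structure.elements]
    )
    for i in range(n):
        for j in range(i + 1, n):
            r = structure.distance(i, j)
            r0 = scale * (rcov[i] + rcov[j])
            f = 1.0 / (1.0 + np.exp(-10.0 * (r0 / r - 1.0)))
            f *= 1.0 / (1.0 + np.exp(-20.0 * ((r0 + 2.0) / r - 1.0)))
            cn[i] += f
            cn[j] += f
    return cn


def repulsion_energy(structure: AtomicStructure, params: ParameterSet) -> float:
    """Pairwise atomic repulsion; vanishes at dissociation."""
    e = 0.0
    light = {"H", "He"}
    for i in range(structure.natoms):
        eli = params.element(structure.elements[i])
        for j in range(i + 1, structure.natoms):
            elj = params.element(structure.elements[j])
            r = structure.distance(i, j)
            if r < 0.1:
                raise GeometryError(
                    f"atoms {i} and {j} are {r:.3f} Bohr apart (overlapping nuclei)"
                )
            kexp = (
                params.globals.rep_kexp_light
                if structure.elements[i] in light and structure.elements[j] in light
                else params.globals.rep_kexp
            )
            e += (
                eli.rep_zeff
                * elj.rep_zeff
                / r
                * np.exp(-np.sqrt(eli.rep_alpha * elj.rep_alpha) * r**kexp)
            )
    return float(e)


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


class TBModel:
    """Precomputed Hamiltonian for one structure + parameter set.

    Exposes ``energy_and_fock(Pa, Pb)`` which evaluates every term of the
    energy decomposition (except E_Fermi, added by the SCF driver) on the
    given spin-channel densities and returns the matching Fock matrices.

    ``u_variant`` is ``None`` or one of the :class:`xtbu.hubbard.UVariant`
    members; terms can be switched off individually for the reduced
    Hamiltonian used in parts of the test-suite.
    """

    def __init__(
        self,
        structure: AtomicStructure,
        params: ParameterSet,
        *,
        u_variant=None,
        include_aes: bool = True,
        include_spin: bool = True,
        include_third_order: bool = True,
    ):
        self.structure = structure
        self.params = params
        self.u_variant = u_variant
        self.include_aes = include_aes
        self.include_spin = include_spin
        self.include_third_order = include_third_order

        if structure.n_alpha is None or structure.n_beta is None:
            structure.resolve_electrons(params.valence_counts())
        self.n_alpha = int(structure.n_alpha)
        self.n_beta = int(structure.n_beta)

        self.basis: ShellBasis = build_basis(structure, params)
        self.ints: Integrals = compute_integrals(self.basis)
        self.overlap = self.ints.overlap
        self.cn = coordination_numbers(structure, params)
        self.e_rep = repulsion_energy(structure, params)
        self.h0 = self._build_h0()
        self._build_isotropic_kernels()
        self._build_moment_matrices()
        self._build_aes_kernels()

    def with_params(self, params: ParameterSet, u_variant=...) -> "TBModel":
        """Shallow copy with swapped interaction parameters.

        Only parameters that do not enter the precomputed geometry/basis
        quantities may differ: the spin constants W, the Hubbard U values and
        the +U scaling alpha.  Changing levels, exponents, hardnesses or
        radii requires constructing a fresh model.
        """
        import copy

        clone = copy.copy(self)
        clone.params = params
        if u_variant is not ...:
            clone.u_variant = u_variant
        return clone

    # ---------------- zeroth order ----------------

    def _shell_level(self, sh) -> float:
        el = self.params.element(sh.element)
        return el.levels[sh.ish] - el.k_cn[sh.ish] * self.cn[sh.atom]

    def _build_h0(self) -> np.ndarray:
        from .constants import BOHR_PER_ANGSTROM

        g = self.params.globals
        basis = self.basis
        nao = basis.nao
        H = np.zeros((nao, nao))
        coords = self.structure.coordinates_bohr
        for ia, sa in enumerate(basis.shells):
            ela = self.params.element(sa.element)
            ha = self._shell_level(sa)
            for ib in range(ia, len(basis.shells)):
                sb = basis.shells[ib]
                if sa.atom == sb.atom:
                    if ia == ib:
                        H[sa.ao_slice, sb.ao_slice] = np.eye(sa.nao) * ha
                    continue
                elb = self.params.element(sb.element)
                hb = self._shell_level(sb)
                K = 0.5 * (g.k_shell[sa.l] + g.k_shell[sb.l])
                x_en = 1.0 + g.k_en * (ela.en - elb.en) ** 2
                r = np.linalg.norm(coords[sa.atom] - coords[sb.atom])
                r0 = g.cn_radius_scale * (ela.cov_radius + elb.cov_radius) * BOHR_PER_ANGSTROM
                ratio = (r / r0) ** g.wexp
                pi_ab = (1.0 + ela.shell_poly[sa.ish] * ratio) * (
                    1.0 + elb.shell_poly[sb.ish] * ratio
                )
                pref = 0.5 * K * (ha + hb) * x_en * pi_ab
                blk = pref * self.overlap[sa.ao_slice, sb.ao_slice]
                H[sa.ao_slice, sb.ao_slice] = blk
                H[sb.ao_slice, sa.ao_slice] = blk.T
        return H

    # ---------------- isotropic SCC ----------------

    def _build_isotropic_kernels(self) -> None:
        g = self.params.globals
        basis = self.basis
        nsh = basis.nshells
        coords = self.structure.coordinates_bohr
        eta = np.array(
            [self.params.element(sh.element).shell_eta(sh.ish) for sh in basis.shells]
        )
        gamma = np.zeros((nsh, nsh))
        for i, si in enumerate(basis.shells):
            for j, sj in enumerate(basis.shells):
                etam = 2.0 * eta[i] * eta[j] / (eta[i] + eta[j])  # harmonic mean
                if si.atom == sj.atom:
                    gamma[i, j] = etam
                else:
                    r = np.linalg.norm(coords[si.atom] - coords[sj.atom])
                    gamma[i, j] = (r**g.gexp + etam ** (-g.gexp)) ** (-1.0 / g.gexp)
        self.gamma2 = gamma
        self.gamma3 = np.array(
            [
                self.params.element(sh.element).gam3 * g.third_order_shell_scale[sh.l]
                for sh in basis.shells
            ]
        )
        self.ref_occ = np.array(
            [self.params.element(sh.element).ref_occ[sh.ish] for sh in basis.shells]
        )

    # ---------------- moment matrices (Mulliken chain rule) ----------------

    def _build_moment_matrices(self) -> None:
        basis = self.basis
        S = self.overlap
        nao = basis.nao
        nsh = basis.nshells
        # shell population moments: pop_k = Tr(P Msh_k), Msh = 1/2 (J S + S J)
        Msh = np.zeros((nsh, nao, nao))
        for k, sh in enumerate(basis.shells):
            J = np.zeros((nao, nao))
            J[sh.ao_slice, sh.ao_slice] = np.eye(sh.nao)
            Msh[k] = 0.5 * (J @ S + S @ J)
        self.Msh = Msh

        if not self.include_aes:
            return
        coords = self.structure.coordinates_bohr
        nat = self.structure.natoms
        MD = np.zeros((nat, 3, nao, nao))
        MQ = np.zeros((nat, 3, 3, nao, nao))
        onatom = [basis.ao_atom == a for a in range(nat)]
        for a in range(nat):
            d1 = shift_first_moment(self.ints, coords[a])
            d2 = shift_second_moment(self.ints, coords[a])
            tr = d2[0, 0] + d2[1, 1] + d2[2, 2]
            sel = onatom[a].astype(float)
            W = 0.5 * (sel[:, None] + sel[None, :])
            for x in range(3):
                MD[a, x] = -W * d1[x]
                for y in range(3):
                    theta = 1.5 * d2[x, y] - (0.5 * tr if x == y else 0.0)
                    MQ[a, x, y] = -W * theta
        self.MD = MD
        self.MQ = MQ

    # ---------------- anisotropic kernels ----------------

    def _build_aes_kernels(self) -> None:
        if not self.include_aes:
            return
        g = self.params.globals
        nat = self.structure.natoms
        coords = self.structure.coordinates_bohr
        rad = np.empty(nat)
        for a, sym in enumerate(self.structure.elements):
            el = self.params.element(sym)
            gate = _logistic(g.mp_kexp * (self.cn[a] - el.mp_vcn - g.mp_shift))
            rad[a] = el.mp_rad + (g.mp_rmax - el.mp_rad) * gate
        f3 = np.zeros((nat, nat))
        f5 = np.zeros((nat, nat))
        for a in range(nat):
            for b in range(a + 1, nat):
                r = np.linalg.norm(coords[a] - coords[b])
                r0 = 0.5 * (rad[a] + rad[b])
                f3[a, b] = f3[b, a] = 1.0 / (r**3 * (1.0 + 6.0 * (r0 / r) ** g.mp_dmp3))
                f5[a, b] = f5[b, a] = 1.0 / (r**5 * (1.0 + 6.0 * (r0 / r) ** g.mp_dmp5))
        self._aes_f3 = f3
        self._aes_f5 = f5

    # ---------------- density contractions ----------------

    def shell_populations(self, P: np.ndarray) -> np.ndarray:
        """Mulliken shell populations of one density matrix."""
        return np.einsum("kij,ji->k", self.Msh, P)

    def shell_charges(self, P_total: np.ndarray) -> np.ndarray:
        return self.ref_occ - self.shell_populations(P_total)

    def spin_populations(self, Pa: np.ndarray, Pb: np.ndarray) -> SpinPopulations:
        p = self.shell_populations(Pa) - self.shell_populations(Pb)
        return SpinPopulations(p, self.basis)

    def atomic_multipoles(self, P_total: np.ndarray):
        """Cumulative atomic dipoles (nat,3) and traceless quadrupoles (nat,3,3)."""
        mu = np.einsum("axij,ji->ax", self.MD, P_total)
        theta = np.einsum("axyij,ji->axy", self.MQ, P_total)
        return mu, theta

    # ---------------- energy + Fock ----------------

    def energy_and_fock(self, Pa: np.ndarray, Pb: np.ndarray):
        """Evaluate all density-dependent terms on (Pa, Pb).

        Returns ``(EnergyBreakdown, Fa, Fb)``; E_Fermi is left zero for the
        SCF driver to fill in.
        """
        from . import hubbard

        P = Pa + Pb
        S = self.overlap
        nao = self.basis.nao
        eb = EnergyBreakdown(E_rep=self.e_rep)
        Fa = self.h0.copy()
        Fb = self.h0.copy()
        eb.E_EHT = float(np.einsum("ij,ji->", self.h0, P))

        # isotropic second + third order on shell charges
        q = self.shell_charges(P)
        v2 = self.gamma2 @ q
        eb.E_IES = 0.5 * float(q @ v2)
        vsh = v2
        if self.include_third_order:
            eb.E_IXC = float(np.sum(self.gamma3 * q**3) / 3.0)
            vsh = v2 + self.gamma3 * q**2
        # charge moments are -Msh, so F += -sum_k vsh_k Msh_k
        Fiso = -np.einsum("k,kij->ij", vsh, self.Msh)
        Fa += Fiso
        Fb += Fiso

        # anisotropic electrostatics + on-site multipole XC
        if self.include_aes:
            mu, theta = self.atomic_multipoles(P)
            # atomic charges from shell charges
            qsh = q
            qa = np.zeros(self.structure.natoms)
            for k, sh in enumerate(self.basis.shells):
                qa[sh.atom] += qsh[k]
            coords = self.structure.coordinates_bohr
            nat = self.structure.natoms
            e_aes = 0.0
            vq = np.zeros(nat)
            vmu = np.zeros((nat, 3))
            vth = np.zeros((nat, 3, 3))
            for a in range(nat):
                for b in range(nat):
                    if a == b:
                        continue
                    Rab = coords[b] - coords[a]
                    f3 = self._aes_f3[a, b]
                    f5 = self._aes_f5[a, b]
                    # charge(B)-dipole(A)
                    proj = float(mu[a] @ Rab)
                    e_aes += qa[b] * proj * f3
                    vq[b] += proj * f3
                    vmu[a] += qa[b] * Rab * f3
                    # charge(B)-quadrupole(A)
                    quadproj = float(Rab @ theta[a] @ Rab)
                    e_aes += qa[b] * quadproj * f5
                    vq[b] += quadproj * f5
                    vth[a] += qa[b] * np.outer(Rab, Rab) * f5
                    # dipole-dipole, counted once per unordered pair
                    if b > a:
                        r2 = float(Rab @ Rab)
                        dd = float(mu[a] @ mu[b]) * r2 - 3.0 * float(mu[a] @ Rab) * float(
                            mu[b] @ Rab
                        )
                        e_aes += dd * f5
                        vmu[a] += (mu[b] * r2 - 3.0 * Rab * float(mu[b] @ Rab)) * f5
                        vmu[b] += (mu[a] * r2 - 3.0 * Rab * float(mu[a] @ Rab)) * f5
            eb.E_AES = e_aes
            e_axc = 0.0
            for a, sym in enumerate(self.structure.elements):
                el = self.params.element(sym)
                e_axc += el.dip_kernel * float(mu[a] @ mu[a])
                e_axc += el.quad_kernel * float(np.sum(theta[a] * theta[a]))
                vmu[a] += 2.0 * el.dip_kernel * mu[a]
                vth[a] += 2.0 * el.quad_kernel * theta[a]
            eb.E_AXC = e_axc
            # fold multipole potentials through the moment matrices
            Fmp = np.einsum("ax,axij->ij", vmu, self.MD) + np.einsum(
                "axy,axyij->ij", vth, self.MQ
            )
            # atomic-charge potential distributes over the atom's shells
            vq_sh = np.array([vq[sh.atom] for sh in self.basis.shells])
            Fmp += -np.einsum("k,kij->ij", vq_sh, self.Msh)
            Fa += Fmp
            Fb += Fmp

        # spin polarization
        if self.include_spin:
            pops = self.spin_populations(Pa, Pb)
            e_spin = 0.0
            vspin = np.zeros(self.basis.nshells)
            for a in range(self.structure.natoms):
                ash = [k for k, sh in enumerate(self.basis.shells) if sh.atom == a]
                el = self.params.element(self.structure.elements[a])
                W = np.array(el.W)
                pvec = pops.by_shell[ash]
                e_spin += 0.5 * float(pvec @ W @ pvec)
                vloc = W @ pvec
                for idx, k in enumerate(ash):
                    vspin[k] = vloc[idx]
            eb.E_spin = e_spin
            Fsp = np.einsum("k,kij->ij", vspin, self.Msh)
            Fa += Fsp
            Fb -= Fsp

        # Hubbard +U
        if self.u_variant is not None:
            occ = hubbard.occupation_matrix(Pa, Pb, S, self.basis)
            eb.E_U = hubbard.hubbard_energy(occ, self.u_variant, self.params)
            dFa, dFb = hubbard.hubbard_fock(occ, self.u_variant, self.params, S, self.basis)
            Fa += dFa
            Fb += dFb

        for name, F in (("alpha", Fa), ("beta", Fb)):
            asym = np.abs(F - F.T).max()
            if asym > 1e-10:
                raise RuntimeError(f"{name} Fock asymmetry {asym:.2e}")
        return eb, Fa, Fb
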