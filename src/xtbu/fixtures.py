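"""Deterministic generators for test systems: the LiF dissociation series,
octahedral hexammine complexes, toy model Hamiltonians and randomized small
molecules.  Everything is a pure function of its arguments, so the
repository needs no stored geometries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .hamiltonian import EnergyBreakdown
from .structure import AtomicStructure

# Table 1 bond-length grid (Angstrom)
LIF_BOND_LENGTHS = (1.25, 1.40, 1.60, 2.00, 2.50, 3.00, 4.00)

NH3_NH_ANGSTROM = 1.012
NH3_HNH_DEGREES = 106.7


def make_lif(bond_length: float) -> AtomicStructure:
    """LiF diatomic: Li at the origin, F on +z at ``bond_length`` Angstrom."""
    if bond_length <= 0:
        raise ValueError("bond length must be positive")
    return AtomicStructure.from_angstrom(
        ["Li", "F"], [[0.0, 0.0, 0.0], [0.0, 0.0, bond_length]],
        total_charge=0, multiplicity=1,
    )


_AMMINE_AXES = {
    2: [(0, 0, 1), (0, 0, -1)],
    4: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)],
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}


def make_ammine_complex(
    metal: str = "Fe",
    charge: int = 3,
    multiplicity: int = 6,
    n_ligands: int = 6,
    d_mn: float = 2.2,
) -> AtomicStructure:
    """[M(NH3)_n] complex with n = 2 (linear), 4 (square planar) or 6
    (octahedral) ammine ligands.

    NH3 internal geometry is fixed (N-H 1.012 A, H-N-H 106.7 deg); ligand
    nitrogens sit on Cartesian axes at ``d_mn`` (Angstrom) with the lone
    pair pointing at the metal.  Deterministic by construction.
    """
    if n_ligands not in _AMMINE_AXES:
        raise ValueError(f"n_ligands must be one of {sorted(_AMMINE_AXES)}")
    elements = [metal]
    coords = [np.zeros(3)]
    # tilt of the N-H bond away from the ligand C3 axis
    cos_hnh = math.cos(math.radians(NH3_HNH_DEGREES))
    cos_t = math.sqrt((2.0 * cos_hnh + 1.0) / 3.0)
    sin_t = math.sqrt(1.0 - cos_t**2)
    axes = [np.array(v, float) for v in _AMMINE_AXES[n_ligands]]
    for z in axes:
        # local orthonormal frame with z pointing outward (metal -> N)
        ref = np.array([0.0, 0.0, 1.0]) if abs(z[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        x = np.cross(ref, z)
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        npos = d_mn * z
        elements.append("N")
        coords.append(npos)
        for k in range(3):
            phi = 2.0 * math.pi * k / 3.0
            bond = sin_t * (math.cos(phi) * x + math.sin(phi) * y) + cos_t * z
            elements.append("H")
            coords.append(npos + NH3_NH_ANGSTROM * bond)
    return AtomicStructure.from_angstrom(
        elements, np.array(coords), total_charge=charge, multiplicity=multiplicity
    )


def make_hexammine(
    metal: str = "Fe",
    charge: int = 3,
    multiplicity: int = 6,
    d_mn: float = 2.2,
) -> AtomicStructure:
    """Ideal octahedral [M(NH3)6] complex (see :func:`make_ammine_complex`)."""
    return make_ammine_complex(metal, charge, multiplicity, 6, d_mn)


# standard closed-shell geometries (Angstrom) used for solver-equivalence
# and invariance tests; seeded jitter provides variety without leaving the
# physically reasonable regime
TEMPLATE_MOLECULES = {
    "H2": (["H", "H"], [[0, 0, 0], [0, 0, 0.74]]),
    "HF": (["H", "F"], [[0, 0, 0], [0, 0, 0.92]]),
    "LiF": (["Li", "F"], [[0, 0, 0], [0, 0, 1.56]]),
    "H2O": (["O", "H", "H"],
            [[0, 0, 0.1173], [0, 0.7572, -0.4692], [0, -0.7572, -0.4692]]),
    "NH3": (["N", "H", "H", "H"],
            [[0, 0, 0], [0.9377, 0, -0.3816], [-0.4689, 0.8121, -0.3816],
             [-0.4689, -0.8121, -0.3816]]),
    "CH4": (["C", "H", "H", "H", "H"],
            [[0, 0, 0], [0.6276, 0.6276, 0.6276], [-0.6276, -0.6276, 0.6276],
             [-0.6276, 0.6276, -0.6276], [0.6276, -0.6276, -0.6276]]),
    "N2": (["N", "N"], [[0, 0, 0], [0, 0, 1.098]]),
    "F2": (["F", "F"], [[0, 0, 0], [0, 0, 1.412]]),
    "CO": (["C", "O"], [[0, 0, 0], [0, 0, 1.128]]),
    "CO2": (["O", "C", "O"], [[0, 0, -1.16], [0, 0, 0], [0, 0, 1.16]]),
}


def perturbed_molecule(name: str, rng: np.random.Generator,
                       sigma: float = 0.02) -> AtomicStructure:
    """A template molecule with Gaussian coordinate jitter (Angstrom)."""
    elements, coords = TEMPLATE_MOLECULES[name]
    coords = np.asarray(coords, float) + rng.normal(scale=sigma, size=(len(elements), 3))
    return AtomicStructure.from_angstrom(elements, coords, 0, 1)


def random_molecule(
    rng: np.random.Generator,
    elements=("H", "C", "N", "O", "F"),
    natoms: int | None = None,
    min_dist: float = 1.7,
    box: float = 4.5,
    charge: int = 0,
    closed_shell: bool = True,
) -> AtomicStructure:
    """Random well-separated small molecule for seeded property tests."""
    natoms = natoms or int(rng.integers(2, 5))
    while True:
        syms = [str(rng.choice(elements)) for _ in range(natoms)]
        coords = rng.uniform(-box / 2, box / 2, size=(natoms, 3))
        ok = all(
            np.linalg.norm(coords[i] - coords[j]) > min_dist
            for i in range(natoms)
            for j in range(i + 1, natoms)
        )
        if not ok:
            continue
        val = {"H": 1, "Li": 1, "C": 4, "N": 5, "O": 6, "F": 7, "Fe": 8}
        nelec = sum(val[s] for s in syms) - charge
        if closed_shell and nelec % 2 != 0:
            continue
        mult = 1 if nelec % 2 == 0 else 2
        return AtomicStructure.from_angstrom(syms, coords, charge, mult)


# ---------------- toy model Hamiltonians ----------------


class _BaseModel:
    """Minimal object satisfying the SCF model protocol."""

    def __init__(self, h0: np.ndarray, n_alpha: int, n_beta: int):
        self.h0 = np.asarray(h0, float)
        self.nao = self.h0.shape[0]
        self.overlap = np.eye(self.nao)
        self.n_alpha = n_alpha
        self.n_beta = n_beta

    def energy_and_fock(self, Pa, Pb):
        eb = EnergyBreakdown()
        P = Pa + Pb
        eb.E_EHT = float(np.einsum("ij,ji->", self.h0, P))
        return eb, self.h0.copy(), self.h0.copy()


class TwoLevelModel(_BaseModel):
    """Two orbitals with energies (-e, +e) and coupling t; one electron per
    requested channel.  Ground-state single-particle energy is the closed
    form -sqrt(e^2 + t^2)."""

    def __init__(self, e: float = 1.0, t: float = 0.4, n_alpha: int = 1, n_beta: int = 0):
        super().__init__(np.array([[-e, t], [t, e]]), n_alpha, n_beta)
        self.e, self.t = e, t

    def exact_orbital_energy(self) -> float:
        return -math.hypot(self.e, self.t)


class HubbardDimerModel(_BaseModel):
    """Two-site mean-field Hubbard model: E = Tr(P h0) + U sum_i n_i^a n_i^b.

    The Fock matrices are the exact density derivatives, F^a = h0 + U
    diag(n^b) and vice versa.  Exact (full-CI) singlet ground-state energies
    are available from 2x2 diagonalization for the 2-electron sector.
    """

    def __init__(self, t: float = 1.0, u: float = 2.0, de: float = 0.0,
                 n_alpha: int = 1, n_beta: int = 1):
        super().__init__(np.array([[0.5 * de, -t], [-t, -0.5 * de]]), n_alpha, n_beta)
        self.t, self.u, self.de = t, u, de

    def energy_and_fock(self, Pa, Pb):
        eb = EnergyBreakdown()
        eb.E_EHT = float(np.einsum("ij,ji->", self.h0, Pa + Pb))
        na = np.diag(Pa).copy()
        nb = np.diag(Pb).copy()
        eb.E_IES = float(self.u * np.sum(na * nb))
        Fa = self.h0 + self.u * np.diag(nb)
        Fb = self.h0 + self.u * np.diag(na)
        return eb, Fa, Fb

    def exact_two_electron_energy(self) -> float:
        # singlet sector basis {|20>, |02>, |S>} with site energies +-de/2
        H = np.array(
            [[self.u + self.de, 0.0, -math.sqrt(2) * self.t],
             [0.0, self.u - self.de, -math.sqrt(2) * self.t],
             [-math.sqrt(2) * self.t, -math.sqrt(2) * self.t, 0.0]]
        )
        return float(np.linalg.eigvalsh(H)[0])


class LinearInNModel(_BaseModel):
    """Non-interacting diagonal levels: total energy is exactly linear in
    each orbital occupation, so fractional-charge scans give E_dev = 0."""

    def __init__(self, levels=(-1.0, -0.5, 0.25), n_alpha: int = 1, n_beta: int = 1):
        super().__init__(np.diag(levels), n_alpha, n_beta)


class QuadraticNModel(_BaseModel):
    """Diagonal levels plus a charging parabola c/2 (N - N0)^2.

    Both the frontier-eigenvalue difference and the second difference
    E(N-1) - 2E(N) + E(N+1) equal ``c`` exactly, which makes this the oracle
    for the linear-response U estimator.
    """

    def __init__(self, levels=(-0.9, -0.5, -0.1), c: float = 0.3, n0: float = 2.0,
                 n_alpha: int = 1, n_beta: int = 1):
        super().__init__(np.diag(levels), n_alpha, n_beta)
        self.c, self.n0 = c, n0

    def energy_and_fock(self, Pa, Pb):
        eb = EnergyBreakdown()
        P = Pa + Pb
        eb.E_EHT = float(np.einsum("ij,ji->", self.h0, P))
        n = float(np.trace(P))
        eb.E_IES = 0.5 * self.c * (n - self.n0) ** 2
        F = self.h0 + self.c * (n - self.n0) * np.eye(self.nao)
        return eb, F.copy(), F.copy()


def make_model_hamiltonian(kind: str, **kwargs):
    """Factory for the toy models: 'two-level', 'hubbard-dimer',
    'linear-in-N', 'quadratic-in-N'."""
    table = {
        "two-level": TwoLevelModel,
        "hubbard-dimer": HubbardDimerModel,
        "linear-in-N": LinearInNModel,
        "quadratic-in-N": QuadraticNModel,
    }
    try:
        cls = table[kind]
    except KeyError:
        raise ValueError(f"unknown model kind {kind!r}; options: {sorted(table)}") from None
    return cls(**kwargs)
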