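"""Closed forms, invariances and derivative consistency of the +U module."""

import numpy as np
import pytest
from scipy.stats import ortho_group

from xtbu.basis import build_basis
from xtbu.hamiltonian import TBModel
from xtbu.hubbard import (
    ShellOccupation,
    UVariant,
    hubbard_energy,
    hubbard_fock,
    occupation_matrix,
)
from xtbu.integrals import compute_integrals
from xtbu.scf import SCFSettings, scf_solve
from xtbu.structure import AtomicStructure

from conftest import random_symmetric


@pytest.fixture(scope="module")
def fe_basis(params):
    st = AtomicStructure.from_angstrom(["Fe"], [[0, 0, 0]], 0, 5)
    return build_basis(st, params)


def _occ_from_blocks(basis, blocks_a, blocks_b):
    return ShellOccupation(
        [np.asarray(b, float) for b in blocks_a],
        [np.asarray(b, float) for b in blocks_b],
        basis,
    )


def _fe_occ(params, fe_basis, nd_alpha, nd_beta):
    """Occupation with given diagonal d-shell entries, s/p shells empty."""
    blocks = lambda d: [np.zeros((1, 1)), np.zeros((3, 3)), np.diag(d)]
    return _occ_from_blocks(fe_basis, blocks(nd_alpha), blocks(nd_beta))


def test_identity_overlap_blocks_equal_density(params, fe_basis, rng):
    n = fe_basis.nao
    Pa = random_symmetric(rng, n)
    Pb = random_symmetric(rng, n)
    S = np.eye(n)
    occ = occupation_matrix(Pa, Pb, S, fe_basis)
    for k, sh in enumerate(fe_basis.shells):
        np.testing.assert_allclose(occ.n_alpha[k], Pa[sh.ao_slice, sh.ao_slice], atol=1e-14)
        np.testing.assert_allclose(occ.n_beta[k], Pb[sh.ao_slice, sh.ao_slice], atol=1e-14)


def test_occupation_matches_dense_oracle(params, lif_short, rng):
    """Blocks equal 1/2 (SP + PS) restricted to shell blocks, random P and
    the molecule's true overlap."""
    basis = build_basis(lif_short, params)
    S = compute_integrals(basis).overlap
    Pa = random_symmetric(rng, basis.nao)
    Pb = random_symmetric(rng, basis.nao)
    occ = occupation_matrix(Pa, Pb, S, basis)
    for P, blocks in ((Pa, occ.n_alpha), (Pb, occ.n_beta)):
        M = 0.5 * (S @ P + P @ S)
        for k, sh in enumerate(basis.shells):
            np.testing.assert_allclose(blocks[k], M[sh.ao_slice, sh.ao_slice], atol=1e-13)


def test_mulliken_conservation_on_converged_lif(params, lif_short):
    model = TBModel(lif_short, params)
    s = scf_solve(model, settings=SCFSettings(solver="diis"))
    occ = occupation_matrix(s.Pa, s.Pb, model.overlap, model.basis)
    assert occ.traces("alpha").sum() == pytest.approx(model.n_alpha, abs=1e-8)
    assert occ.traces("beta").sum() == pytest.approx(model.n_beta, abs=1e-8)


def test_dimension_mismatch_rejected(params, fe_basis):
    with pytest.raises(ValueError, match="mismatch"):
        occupation_matrix(np.eye(3), np.eye(3), np.eye(9), fe_basis)


def test_fll_zero_at_integer_occupations(params, fe_basis):
    occ = _fe_occ(params, fe_basis, [1, 1, 1, 0, 0], [1, 0, 0, 0, 0])
    p = params.with_hubbard_u("Fe", {"d": 0.25})
    assert hubbard_energy(occ, UVariant.FLL, p) == pytest.approx(0.0, abs=1e-15)


def test_psic_closed_form_single_electron(params, fe_basis):
    # one d electron, alpha = 0.5, U = 0.2 -> E = -0.5 * 0.1 * 1 = -0.05
    occ = _fe_occ(params, fe_basis, [1, 0, 0, 0, 0], [0, 0, 0, 0, 0])
    p = params.with_hubbard_u("Fe", {"d": 0.2})
    assert hubbard_energy(occ, UVariant.PSIC, p) == pytest.approx(-0.05, abs=1e-15)


def test_fll_closed_form_half_filled_d(params, fe_basis):
    # n = I/2 in both spins, alpha = 0.5, U = 0.1:
    # E = -0.5*0.05*2*(1.25 - 2.5) = +0.0625
    occ = _fe_occ(params, fe_basis, [0.5] * 5, [0.5] * 5)
    p = params.with_hubbard_u("Fe", {"d": 0.1})
    assert hubbard_energy(occ, UVariant.FLL, p) == pytest.approx(0.0625, abs=1e-15)


def test_zero_u_gives_zero_energy_and_fock(params, fe_basis, rng):
    occ = _fe_occ(params, fe_basis, rng.uniform(0, 1, 5), rng.uniform(0, 1, 5))
    S = np.eye(fe_basis.nao)
    for v in UVariant:
        assert hubbard_energy(occ, v, params) == 0.0
        Fa, Fb = hubbard_fock(occ, v, params, S, fe_basis)
        assert np.abs(Fa).max() == 0.0 and np.abs(Fb).max() == 0.0


def test_fll_potential_vanishes_at_half_filling(params, fe_basis):
    occ = _fe_occ(params, fe_basis, [0.5] * 5, [0.5] * 5)
    p = params.with_hubbard_u("Fe", {"d": 0.3})
    Fa, Fb = hubbard_fock(occ, UVariant.FLL, p, np.eye(fe_basis.nao), fe_basis)
    dblock = fe_basis.shells[2].ao_slice
    assert np.abs(Fa[dblock, dblock]).max() < 1e-14


def test_fll_psic_exact_relation(params, fe_basis, rng):
    """E_FLL = E_pSIC + alpha sum_l U_l/2 sum_sigma tr(n)."""
    p = params.with_hubbard_u("Fe", {"d": 0.17, "s": 0.05})
    na = [random_symmetric(rng, 1, 0.4), random_symmetric(rng, 3, 0.2),
          random_symmetric(rng, 5, 0.2)]
    nb = [random_symmetric(rng, 1, 0.4), random_symmetric(rng, 3, 0.2),
          random_symmetric(rng, 5, 0.2)]
    occ = _occ_from_blocks(fe_basis, na, nb)
    e_fll = hubbard_energy(occ, UVariant.FLL, p)
    e_psic = hubbard_energy(occ, UVariant.PSIC, p)
    alpha = p.globals.alpha_u
    lin = 0.0
    for k, sh in enumerate(fe_basis.shells):
        u = p.element("Fe").U[sh.ish]
        lin += alpha * u / 2.0 * (np.trace(na[k]) + np.trace(nb[k]))
    assert e_fll == pytest.approx(e_psic + lin, abs=1e-14)


def test_amf_vanishes_iff_isotropic(params, fe_basis, rng):
    p = params.with_hubbard_u("Fe", {"d": 0.2})
    iso = _fe_occ(params, fe_basis, [0.37] * 5, [0.81] * 5)
    assert hubbard_energy(iso, UVariant.AMF, p) == pytest.approx(0.0, abs=1e-15)
    aniso = _fe_occ(params, fe_basis, [0.4, 0.34] + [0.37] * 3, [0.81] * 5)
    assert hubbard_energy(aniso, UVariant.AMF, p) < 0.0  # strictly stabilizing


def test_rotational_invariance_within_shell(params, fe_basis, rng):
    """E_U unchanged under any orthogonal rotation of a shell block."""
    p = params.with_hubbard_u("Fe", {"d": 0.21})
    nd_a = random_symmetric(rng, 5, 0.2) + 0.4 * np.eye(5)
    nd_b = random_symmetric(rng, 5, 0.2) + 0.2 * np.eye(5)
    occ = _occ_from_blocks(
        fe_basis, [np.zeros((1, 1)), np.zeros((3, 3)), nd_a],
        [np.zeros((1, 1)), np.zeros((3, 3)), nd_b])
    R = ortho_group.rvs(5, random_state=7)
    occ_rot = _occ_from_blocks(
        fe_basis, [np.zeros((1, 1)), np.zeros((3, 3)), R @ nd_a @ R.T],
        [np.zeros((1, 1)), np.zeros((3, 3)), R @ nd_b @ R.T])
    for v in UVariant:
        e = hubbard_energy(occ, v, p)
        e_rot = hubbard_energy(occ_rot, v, p)
        assert abs(e - e_rot) <= 1e-10, v


def test_fll_minimized_at_integer_occupations(params, fe_basis):
    """For fixed trace 1 on a 2-orbital sub-block, integer filling minimizes
    E_FLL over a 1e-2 grid of fractional diagonal occupations."""
    p = params.with_hubbard_u("Fe", {"d": 0.2})

    def e_fll(x):
        occ = _fe_occ(params, fe_basis, [x, 1.0 - x, 0, 0, 0], [0] * 5)
        return hubbard_energy(occ, UVariant.FLL, p)

    grid = np.arange(0.0, 1.0 + 1e-9, 0.01)
    energies = np.array([e_fll(x) for x in grid])
    e_int = e_fll(0.0)
    assert energies.min() >= e_int - 1e-15
    assert np.argmin(energies) in (0, len(grid) - 1)


def test_fock_matches_finite_difference(params, rng):
    """AO Fock of every variant vs central differences of the energy through
    the full Mulliken chain (real overlap, random densities)."""
    st = AtomicStructure.from_angstrom(["Fe", "N"], [[0, 0, 0], [0, 0, 2.0]], 0, 4)
    p = params.with_hubbard_u("Fe", {"d": 0.2, "p": 0.1, "s": 0.05})
    basis = build_basis(st, p)
    S = compute_integrals(basis).overlap
    n = basis.nao
    Pa = random_symmetric(rng, n)
    Pb = random_symmetric(rng, n)
    h = 1e-6
    for v in UVariant:
        occ = occupation_matrix(Pa, Pb, S, basis)
        Fa, Fb = hubbard_fock(occ, v, p, S, basis)
        worst = 0.0
        for i, j in [(0, 0), (1, 5), (4, 4), (2, 9), (7, 12)]:
            dP = np.zeros((n, n))
            dP[i, j] += h
            dP[j, i] += h
            ep = hubbard_energy(occupation_matrix(Pa + dP, Pb, S, basis), v, p)
            em = hubbard_energy(occupation_matrix(Pa - dP, Pb, S, basis), v, p)
            worst = max(worst, abs((ep - em) / (2 * h) - (Fa[i, j] + Fa[j, i])))
        assert worst <= 1e-7, (v, worst)


def test_negative_u_rejected(params, fe_basis):
    bad = params.with_element_update("Fe", U=(0.0, 0.0, -0.1))
    occ = _fe_occ(params, fe_basis, [1, 0, 0, 0, 0], [0] * 5)
    with pytest.raises(ValueError, match="negative"):
        hubbard_energy(occ, UVariant.FLL, bad)
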