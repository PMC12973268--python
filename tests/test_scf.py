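"""Fermi smearing, DIIS, GDM and fixed-point driver behavior."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from xtbu.fixtures import TEMPLATE_MOLECULES, make_lif, make_model_hamiltonian, perturbed_molecule
from xtbu.hamiltonian import TBModel
from xtbu.scf import (
    SCFSettings,
    diis_extrapolate,
    fermi_occupations,
    gdm_minimize,
    initial_guess,
    scf_solve,
)
from xtbu.structure import AtomicStructure


# ---------------- Fermi occupations ----------------


def test_zero_temperature_aufbau():
    eps = np.array([-1.0, -0.5, 0.2, 0.9])
    f, mu, ef = fermi_occupations(eps, 2, 0.0)
    np.testing.assert_array_equal(f, [1, 1, 0, 0])
    assert ef == 0.0


def test_degenerate_frontier_symmetric_split():
    eps = np.array([-1.0, -1.0])
    for temp in (0.0, 300.0):
        f, _, _ = fermi_occupations(eps, 1, temp)
        np.testing.assert_allclose(f, [0.5, 0.5], atol=1e-12)


def test_partial_degenerate_shell_at_zero_t():
    # 3 degenerate levels, 2 electrons on top of one filled level
    eps = np.array([-2.0, -1.0, -1.0, -1.0])
    f, _, _ = fermi_occupations(eps, 3, 0.0)
    np.testing.assert_allclose(f, [1.0, 2 / 3, 2 / 3, 2 / 3], atol=1e-12)


@given(st.integers(0, 2**31 - 1))
@hsettings(max_examples=25, deadline=None, derandomize=True)
def test_count_conservation_vs_grid_oracle(seed):
    """Bisected chemical potential reproduces a brute-force mu grid search."""
    rng = np.random.default_rng(seed)
    eps = np.sort(rng.normal(scale=0.5, size=12))
    n = int(rng.integers(1, 12))
    f, mu, _ = fermi_occupations(eps, n, 300.0)
    assert f.sum() == pytest.approx(n, abs=1e-9)
    kt = 3.166811563e-6 * 300.0
    grid = np.linspace(eps.min() - 0.1, eps.max() + 0.1, 200001)
    counts = 1.0 / (1.0 + np.exp(np.clip((eps[None, :] - grid[:, None]) / kt, -60, 60)))
    mu_grid = grid[np.argmin(np.abs(counts.sum(axis=1) - n))]
    f_grid = 1.0 / (1.0 + np.exp(np.clip((eps - mu_grid) / kt, -60, 60)))
    np.testing.assert_allclose(f, f_grid, atol=1e-3)


def test_entropy_sign_and_zero_limits():
    eps = np.array([-1.0, 1.0])
    f, _, ef = fermi_occupations(eps, 1, 5000.0)
    assert ef < 0.0  # -T*S with S > 0
    _, _, ef0 = fermi_occupations(eps, 1, 0.0)
    assert ef0 == 0.0


def test_too_many_electrons_rejected():
    with pytest.raises(ValueError, match="electrons"):
        fermi_occupations(np.array([0.0, 1.0]), 3, 300.0)


# ---------------- initial guess ----------------


def test_guess_single_h_atom(params):
    stc = AtomicStructure.from_angstrom(["H"], [[0, 0, 0]], 0, 2)
    state = initial_guess(TBModel(stc, params))
    assert state.Pa[0, 0] == pytest.approx(1.0, abs=1e-10)
    assert abs(state.Pb[0, 0]) < 1e-12


def test_guess_traces_and_determinism(params, lif_short):
    model = TBModel(lif_short, params)
    s1 = initial_guess(model)
    s2 = initial_guess(model)
    S = model.overlap
    assert np.einsum("ij,ji->", s1.Pa, S) == pytest.approx(model.n_alpha, abs=1e-8)
    np.testing.assert_array_equal(s1.Pa, s2.Pa)
    np.testing.assert_array_equal(s1.eps_a, s2.eps_a)


# ---------------- DIIS ----------------


def test_diis_single_entry_returns_fock():
    F = np.array([[1.0, 0.2], [0.2, -1.0]])
    history = [(F, F.copy(), np.array([0.1, 0.0]))]
    Fa, Fb = diis_extrapolate(history)
    np.testing.assert_array_equal(Fa, F)


def test_diis_converged_fixed_point():
    """All-zero error vectors leave the (converged) Fock unchanged."""
    F = np.diag([1.0, 2.0])
    history = [(F, F, np.zeros(4)), (F, F, np.zeros(4))]
    Fa, _ = diis_extrapolate(history)
    np.testing.assert_allclose(Fa, F, atol=1e-12)


def test_diis_residual_decreases_on_linear_model():
    """Mean-field Hubbard dimer: DIIS error norm decays over iterations."""
    model = make_model_hamiltonian("hubbard-dimer", t=1.0, u=0.5, de=0.6)
    s = scf_solve(model, settings=SCFSettings(solver="diis", etemp=0.0))
    errs = [t["error"] for t in s.trace]
    assert s.converged
    assert all(e2 <= e1 * 1.5 for e1, e2 in zip(errs, errs[1:]))  # no blow-up
    assert errs[-1] < errs[0]


# ---------------- GDM ----------------


def test_gdm_from_converged_state_keeps_energy(params, lif_short):
    model = TBModel(lif_short, params)
    sett = SCFSettings(solver="gdm")
    s = scf_solve(model, settings=sett)
    assert s.converged
    s2 = gdm_minimize(model, sett, state=s)
    assert s2.E_tot <= s.E_tot + 1e-12
    assert abs(s2.E_tot - s.E_tot) < 1e-8


def test_gdm_matches_fixed_point_on_h2(params):
    h2 = AtomicStructure.from_angstrom(["H", "H"], [[0, 0, 0], [0, 0, 0.74]], 0, 1)
    e_fp = scf_solve(h2, params, settings=SCFSettings(solver="fixed-point", max_iter=600)).E_tot
    e_gdm = scf_solve(h2, params, settings=SCFSettings(solver="gdm")).E_tot
    assert e_gdm == pytest.approx(e_fp, abs=1e-8)


def test_gdm_accepted_energies_non_increasing(params):
    for d in (1.25, 4.0):
        s = scf_solve(make_lif(d), params, settings=SCFSettings(solver="gdm"))
        energies = [t["E"] for t in s.trace]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(energies, energies[1:]))


def test_gdm_stationarity_at_convergence(params, lif_short):
    s = scf_solve(make_lif(2.5), params, settings=SCFSettings(solver="gdm"))
    assert s.converged
    # occupied-virtual Fock block in the MO basis below threshold
    for C, F, occ in ((s.Ca, s.Fa, s.occ_a), (s.Cb, s.Fb, s.occ_b)):
        Fmo = C.T @ F @ C
        o = occ > 0.5
        v = ~o
        assert np.abs(Fmo[o][:, v]).max() < 5e-6


def test_solver_equivalence_seeded_molecules(params):
    rng = np.random.default_rng(4213)
    for name in list(TEMPLATE_MOLECULES)[:6]:
        mol = perturbed_molecule(name, rng)
        e_diis = scf_solve(mol, params, settings=SCFSettings(solver="diis"))
        e_gdm = scf_solve(mol, params, settings=SCFSettings(solver="gdm", max_iter=800))
        assert e_diis.converged and e_gdm.converged, name
        assert abs(e_diis.E_tot - e_gdm.E_tot) <= 1e-6, name


def test_smearing_consistency_on_gapped_fixture(params):
    """300 K vs 0 K free energy differ negligibly when the gap is large."""
    e300 = scf_solve(make_lif(1.6), params, settings=SCFSettings(solver="gdm")).E_tot
    e0 = scf_solve(make_lif(1.6), params, settings=SCFSettings(solver="gdm", etemp=0.0)).E_tot
    assert abs(e300 - e0) <= 1e-4


def test_nonconvergence_is_flagged_not_raised(params, lif_short):
    s = scf_solve(lif_short, params, settings=SCFSettings(solver="diis", max_iter=2))
    assert not s.converged
    assert s.n_iter == 2
    assert len(s.trace) == 2


def test_electron_counts_conserved(params, lif_short):
    model = TBModel(lif_short, params)
    s = scf_solve(model, settings=SCFSettings(solver="diis"))
    s.check_electron_counts(tol=1e-8)


# ---------------- toy models through the same drivers ----------------


def test_two_level_model_closed_form():
    m = make_model_hamiltonian("two-level", e=1.0, t=0.4)
    s = scf_solve(m, settings=SCFSettings(solver="fixed-point", etemp=0.0))
    assert s.E_tot == pytest.approx(m.exact_orbital_energy(), abs=1e-10)


def test_hubbard_dimer_exact_limits():
    # U = 0: mean field equals exact diagonalization
    m0 = make_model_hamiltonian("hubbard-dimer", t=0.7, u=0.0)
    s0 = scf_solve(m0, settings=SCFSettings(solver="fixed-point", etemp=0.0))
    assert s0.E_tot == pytest.approx(m0.exact_two_electron_energy(), abs=1e-9)
    # single electron: no interaction regardless of U
    m1 = make_model_hamiltonian("hubbard-dimer", t=0.7, u=3.0, n_alpha=1, n_beta=0)
    s1 = scf_solve(m1, settings=SCFSettings(solver="fixed-point", etemp=0.0))
    assert s1.E_tot == pytest.approx(-0.7, abs=1e-9)
    # interacting mean field is a variational upper bound to full CI
    m2 = make_model_hamiltonian("hubbard-dimer", t=0.7, u=2.0)
    s2 = scf_solve(m2, settings=SCFSettings(solver="fixed-point", etemp=0.0, max_iter=800))
    assert s2.E_tot >= m2.exact_two_electron_energy() - 1e-10
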