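"""Self-consistent field drivers: DIIS, geometric direct minimization (GDM),
and a damped fixed-point iteration, all under finite-temperature Fermi
smearing in an unrestricted (spin-channel) formalism.

Non-convergence is data, not an exception: every driver returns an
:class:`SCFState` with ``converged`` set accordingly and a per-iteration
trace, so parameter-optimization layers can penalize failed points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg as sla

from .constants import KB_HARTREE
from .hamiltonian import EnergyBreakdown, TBModel


@dataclass
class SCFSettings:
    solver: str = "diis"  # diis | gdm | fixed-point
    e_thresh: float = 1e-6
    error_thresh: float = 1e-6
    max_iter: int = 250
    etemp: float = 300.0  # K
    diis_history: int = 8
    diis_cond_max: float = 1e12
    mixing: float = 0.4  # fixed-point damping
    gdm_max_macro: int = 80
    gdm_lbfgs_history: int = 12
    gdm_min_curvature: float = 0.05
    # damping of the Fermi re-occupation between GDM macro-iterations;
    # 1.0 = undamped.  Stabilizes systems whose near-degenerate fractional
    # occupations couple back into the self-consistent field.
    gdm_occ_mixing: float = 0.5
    gdm_inner_per_macro: int = 50
    # optional override of the occupation rule: f(eps, nelec, channel) ->
    # (occ, mu, e_fermi); used e.g. by the fractional-charge scan
    occupation_fn: Callable | None = None

    def __post_init__(self) -> None:
        if self.e_thresh <= 0 or self.error_thresh <= 0:
            raise ValueError("convergence thresholds must be positive")
        if self.etemp < 0:
            raise ValueError("electronic temperature must be >= 0")


@dataclass
class SCFState:
    model: TBModel = field(repr=False)
    Pa: np.ndarray = field(repr=False, default=None)
    Pb: np.ndarray = field(repr=False, default=None)
    Fa: np.ndarray = field(repr=False, default=None)
    Fb: np.ndarray = field(repr=False, default=None)
    Ca: np.ndarray = field(repr=False, default=None)
    Cb: np.ndarray = field(repr=False, default=None)
    eps_a: np.ndarray = None
    eps_b: np.ndarray = None
    occ_a: np.ndarray = None
    occ_b: np.ndarray = None
    mu_a: float = np.nan
    mu_b: float = np.nan
    energy: EnergyBreakdown = None
    converged: bool = False
    n_iter: int = 0
    solver: str = ""
    trace: list = field(default_factory=list, repr=False)

    @property
    def E_tot(self) -> float:
        return self.energy.E_tot

    def density(self, channel: str) -> np.ndarray:
        return self.Pa if channel == "alpha" else self.Pb

    def check_electron_counts(self, tol: float = 1e-8) -> None:
        S = self.model.overlap
        for P, n in ((self.Pa, self.model.n_alpha_eff), (self.Pb, self.model.n_beta_eff)):
            tr = float(np.einsum("ij,ji->", P, S))
            if abs(tr - n) > tol:
                raise RuntimeError(f"tr(PS) = {tr} but channel holds {n} electrons")


def fermi_occupations(
    eps: np.ndarray, nelec: float, etemp: float, degeneracy_tol: float = 1e-9
) -> tuple[np.ndarray, float, float]:
    """Fermi-Dirac occupations, chemical potential, and entropy term.

    Returns ``(f, mu, e_fermi)`` with ``sum(f) = nelec`` (bisection on mu to
    1e-10) and ``e_fermi = -T S_el = kT sum_i [f ln f + (1-f) ln(1-f)]``.  At
    ``etemp == 0`` an aufbau filling is used; electrons remaining at an
    exactly degenerate frontier (within ``degeneracy_tol``) are split
    symmetrically over the degenerate levels.
    """
    eps = np.asarray(eps, float)
    norb = eps.size
    if nelec < -1e-12 or nelec > norb + 1e-12:
        raise ValueError(f"cannot place {nelec} electrons in {norb} orbitals")
    nelec = float(np.clip(nelec, 0.0, norb))
    if nelec == 0.0:
        return np.zeros(norb), -np.inf, 0.0

    order = np.argsort(eps, kind="stable")
    if etemp == 0.0:
        f = np.zeros(norb)
        nfull = int(np.floor(nelec + 1e-12))
        rem = nelec - nfull
        f[order[:nfull]] = 1.0
        if rem > 1e-12 or (nfull > 0 and nfull < norb):
            # frontier degeneracy handling
            if nfull < norb:
                e_edge = eps[order[nfull]] if rem > 1e-12 else eps[order[nfull - 1]]
                group = np.where(np.abs(eps - e_edge) <= degeneracy_tol)[0]
                if rem > 1e-12:
                    # distribute (partial) electrons symmetrically over the
                    # empty degenerate frontier levels
                    empty = [i for i in group if f[i] == 0.0]
                    for i in empty:
                        f[i] = rem / len(empty)
                else:
                    # integer filling that ends inside a degenerate group:
                    # spread the top electrons evenly
                    if len(group) > 1 and any(f[i] == 0.0 for i in group):
                        n_in_group = sum(f[i] for i in group)
                        for i in group:
                            f[i] = n_in_group / len(group)
        mu = float(eps[order[min(nfull, norb - 1)]])
        return f, mu, 0.0

    kt = KB_HARTREE * etemp

    def occ(mu):
        x = np.clip((eps - mu) / kt, -60.0, 60.0)
        return 1.0 / (1.0 + np.exp(x))

    lo = eps.min() - 50.0 * kt - 1.0
    hi = eps.max() + 50.0 * kt + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if occ(mid).sum() < nelec:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14 * max(1.0, abs(mid)):
            break
    mu = 0.5 * (lo + hi)
    f = occ(mu)
    # polish the count
    s = f.sum()
    if abs(s - nelec) > 1e-10 and 0 < s < norb:
        pass  # bisection above is already at machine resolution
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = f * np.log(f) + (1.0 - f) * np.log(1.0 - f)
    ent = np.where((f > 1e-300) & (f < 1.0 - 1e-16), ent, 0.0)
    e_fermi = kt * float(ent.sum())
    return f, float(mu), e_fermi


def _entropy_term(f: np.ndarray, kt: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = f * np.log(f) + (1.0 - f) * np.log(1.0 - f)
    ent = np.where((f > 1e-300) & (f < 1.0 - 1e-16), ent, 0.0)
    return kt * float(ent.sum())


def _default_occupations(settings: SCFSettings):
    def occ_fn(eps, nelec, channel):
        return fermi_occupations(eps, nelec, settings.etemp)

    return settings.occupation_fn or occ_fn


def initial_guess(model: TBModel, settings: SCFSettings | None = None) -> SCFState:
    """Deterministic guess: diagonalize H0, occupy by the settings' rule."""
    settings = settings or SCFSettings()
    occ_fn = _default_occupations(settings)
    eps, C = sla.eigh(model.h0, model.overlap)
    state = SCFState(model=model, solver="guess")
    state.Ca = C.copy()
    state.Cb = C.copy()
    state.eps_a = eps.copy()
    state.eps_b = eps.copy()
    na, nb = _effective_counts(model)
    state.occ_a, state.mu_a, efa = occ_fn(eps, na, "alpha")
    state.occ_b, state.mu_b, efb = occ_fn(eps, nb, "beta")
    state.Pa = (C * state.occ_a) @ C.T
    state.Pb = (C * state.occ_b) @ C.T
    eb, Fa, Fb = model.energy_and_fock(state.Pa, state.Pb)
    eb.E_Fermi = efa + efb
    state.energy = eb
    state.Fa, state.Fb = Fa, Fb
    return state


def warm_state(model: TBModel, settings: SCFSettings, src: SCFState) -> SCFState:
    """Fresh SCF state seeded with the orbitals of a previous solution."""
    occ_fn = _default_occupations(settings)
    state = SCFState(model=model, solver="warm")
    state.Ca, state.Cb = src.Ca.copy(), src.Cb.copy()
    state.eps_a, state.eps_b = src.eps_a.copy(), src.eps_b.copy()
    na, nb = _effective_counts(model)
    state.occ_a, state.mu_a, efa = occ_fn(state.eps_a, na, "alpha")
    state.occ_b, state.mu_b, efb = occ_fn(state.eps_b, nb, "beta")
    state.Pa = (state.Ca * state.occ_a) @ state.Ca.T
    state.Pb = (state.Cb * state.occ_b) @ state.Cb.T
    eb, Fa, Fb = model.energy_and_fock(state.Pa, state.Pb)
    eb.E_Fermi = efa + efb
    state.energy = eb
    state.Fa, state.Fb = Fa, Fb
    return state


def _effective_counts(model) -> tuple[float, float]:
    """Channel electron counts; models may carry fractional analysis counts."""
    na = getattr(model, "n_alpha_frac", None)
    nb = getattr(model, "n_beta_frac", None)
    model.n_alpha_eff = float(na if na is not None else model.n_alpha)
    model.n_beta_eff = float(nb if nb is not None else model.n_beta)
    return model.n_alpha_eff, model.n_beta_eff


def _diis_error(F, P, S, X):
    e = F @ P @ S - S @ P @ F
    return X.T @ e @ X


def diis_extrapolate(history: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
                     cond_max: float = 1e12):
    """Solve the Pulay least-squares system over the stored (Fa, Fb, err) history.

    Returns extrapolated (Fa, Fb).  Ill-conditioned systems drop the oldest
    entries and retry; a single-entry history returns that Fock unchanged.
    """
    work = list(history)
    while len(work) > 1:
        m = len(work)
        B = np.empty((m + 1, m + 1))
        B[-1, :] = -1.0
        B[:, -1] = -1.0
        B[-1, -1] = 0.0
        for i in range(m):
            for j in range(m):
                B[i, j] = float(np.sum(work[i][2] * work[j][2]))
        try:
            cond = np.linalg.cond(B)
            if not np.isfinite(cond) or cond > cond_max:
                raise np.linalg.LinAlgError
            rhs = np.zeros(m + 1)
            rhs[-1] = -1.0
            c = np.linalg.solve(B, rhs)[:m]
        except np.linalg.LinAlgError:
            work = work[1:]
            continue
        Fa = sum(ci * w[0] for ci, w in zip(c, work))
        Fb = sum(ci * w[1] for ci, w in zip(c, work))
        return Fa, Fb
    return work[0][0], work[0][1]


def _iterate(model: TBModel, settings: SCFSettings, mode: str,
             initial: SCFState | None = None) -> SCFState:
    """Shared loop for the DIIS and damped fixed-point drivers."""
    occ_fn = _default_occupations(settings)
    S = model.overlap
    w, V = np.linalg.eigh(S)
    X = V @ np.diag(w**-0.5) @ V.T
    state = initial if initial is not None else initial_guess(model, settings)
    state.solver = mode
    na, nb = _effective_counts(model)
    history: list = []
    e_old = state.E_tot
    for it in range(1, settings.max_iter + 1):
        eb, Fa, Fb = model.energy_and_fock(state.Pa, state.Pb)
        erra = _diis_error(Fa, state.Pa, S, X)
        errb = _diis_error(Fb, state.Pb, S, X)
        err = np.concatenate([erra.ravel(), errb.ravel()])
        err_norm = float(np.abs(err).max())
        if mode == "diis":
            history.append((Fa, Fb, err))
            if len(history) > settings.diis_history:
                history.pop(0)
            Fa_use, Fb_use = diis_extrapolate(history, settings.diis_cond_max)
        else:
            Fa_use, Fb_use = Fa, Fb
        eps_a, Ca = sla.eigh(Fa_use, S)
        eps_b, Cb = sla.eigh(Fb_use, S)
        fa, mu_a, ef_a = occ_fn(eps_a, na, "alpha")
        fb, mu_b, ef_b = occ_fn(eps_b, nb, "beta")
        Pa_new = (Ca * fa) @ Ca.T
        Pb_new = (Cb * fb) @ Cb.T
        if mode == "fixed-point" and it > 1:
            d = settings.mixing
            Pa_new = (1 - d) * Pa_new + d * state.Pa
            Pb_new = (1 - d) * Pb_new + d * state.Pb
        eb.E_Fermi = ef_a + ef_b
        e_new = eb.E_tot
        de = e_new - e_old
        state.trace.append(
            {"iter": it, "E": e_new, "dE": de, "error": err_norm, "solver": mode}
        )
        state.Pa, state.Pb = Pa_new, Pb_new
        state.Fa, state.Fb = Fa, Fb
        state.Ca, state.Cb = Ca, Cb
        state.eps_a, state.eps_b = eps_a, eps_b
        state.occ_a, state.occ_b = fa, fb
        state.mu_a, state.mu_b = mu_a, mu_b
        state.energy = eb
        state.n_iter = it
        if abs(de) < settings.e_thresh and err_norm < settings.error_thresh:
            state.converged = True
            # rebuild energy on the final (re-occupied) density for reporting
            eb2, Fa2, Fb2 = model.energy_and_fock(state.Pa, state.Pb)
            eb2.E_Fermi = ef_a + ef_b
            state.energy = eb2
            state.Fa, state.Fb = Fa2, Fb2
            break
        e_old = e_new
    return state


# ---------------- geometric direct minimization ----------------


def _pair_index(f: np.ndarray, tol: float = 1e-8):
    """Orbital pairs with differing occupations (rotation generators)."""
    n = f.size
    pairs = [(p, q) for p in range(n) for q in range(p + 1, n) if abs(f[p] - f[q]) > tol]
    return pairs


def _build_kappa(x: np.ndarray, pairs, n: int) -> np.ndarray:
    K = np.zeros((n, n))
    for val, (p, q) in zip(x, pairs):
        K[p, q] = val
        K[q, p] = -val
    return K


def _gdm_energy(model, Ca, Cb, fa, fb, efermi):
    Pa = (Ca * fa) @ Ca.T
    Pb = (Cb * fb) @ Cb.T
    eb, Fa, Fb = model.energy_and_fock(Pa, Pb)
    eb.E_Fermi = efermi
    return eb, Fa, Fb, Pa, Pb


def gdm_minimize(model: TBModel, settings: SCFSettings | None = None,
                 state: SCFState | None = None) -> SCFState:
    """Direct minimization of the electronic (free) energy over orbital
    rotations, with L-BFGS curvature accumulation, an orbital-energy-gap
    diagonal preconditioner, and a backtracking line search that guarantees a
    non-increasing accepted-energy sequence at fixed occupations.

    Occupations are re-resolved from Fermi smearing at each macro-iteration.
    """
    settings = settings or SCFSettings(solver="gdm")
    occ_fn = _default_occupations(settings)
    if state is None:
        state = initial_guess(model, settings)
    state.solver = "gdm"
    na, nb = _effective_counts(model)
    total_inner = 0
    e_macro_old = np.inf
    fa_prev = fb_prev = None
    for macro in range(settings.gdm_max_macro):
        # occupations from current orbital energies, damped across macros
        fa, mu_a, ef_a = occ_fn(state.eps_a, na, "alpha")
        fb, mu_b, ef_b = occ_fn(state.eps_b, nb, "beta")
        mix = 1.0 if macro < 2 else settings.gdm_occ_mixing
        if fa_prev is not None and 0.0 < mix < 1.0:
            fa = mix * fa + (1.0 - mix) * fa_prev
            fb = mix * fb + (1.0 - mix) * fb_prev
            kt = KB_HARTREE * settings.etemp
            if kt > 0.0:
                ef_a, ef_b = (_entropy_term(f, kt) for f in (fa, fb))
        fa_prev, fb_prev = fa, fb
        efermi = ef_a + ef_b
        Ca, Cb = state.Ca.copy(), state.Cb.copy()
        pairs_a = _pair_index(fa)
        pairs_b = _pair_index(fb)
        nA, nB = len(pairs_a), len(pairs_b)
        eb, Fa, Fb, Pa, Pb = _gdm_energy(model, Ca, Cb, fa, fb, efermi)
        e_cur = eb.E_tot

        def gradient(Fa, Fb, Ca, Cb):
            g = np.empty(nA + nB)
            FmoA = Ca.T @ Fa @ Ca
            FmoB = Cb.T @ Fb @ Cb
            for i, (p, q) in enumerate(pairs_a):
                g[i] = 2.0 * (fa[p] - fa[q]) * FmoA[p, q]
            for i, (p, q) in enumerate(pairs_b):
                g[nA + i] = 2.0 * (fb[p] - fb[q]) * FmoB[p, q]
            return g

        # diagonal preconditioner from occupation-weighted orbital-energy gaps
        def precondition(g):
            h = np.empty_like(g)
            for i, (p, q) in enumerate(pairs_a):
                h[i] = max(2.0 * abs(fa[p] - fa[q]) * abs(state.eps_a[q] - state.eps_a[p]),
                           settings.gdm_min_curvature)
            for i, (p, q) in enumerate(pairs_b):
                h[nA + i] = max(2.0 * abs(fb[p] - fb[q]) * abs(state.eps_b[q] - state.eps_b[p]),
                                settings.gdm_min_curvature)
            return g / h

        s_hist: list = []
        y_hist: list = []
        g = gradient(Fa, Fb, Ca, Cb)
        inner_converged = False
        for inner in range(min(settings.max_iter, settings.gdm_inner_per_macro)):
            gnorm = float(np.abs(g).max()) if g.size else 0.0
            if gnorm < settings.error_thresh:
                inner_converged = True
                break
            # L-BFGS two-loop recursion
            qv = g.copy()
            alphas = []
            for s, y in reversed(list(zip(s_hist, y_hist))):
                rho = 1.0 / float(y @ s)
                a = rho * float(s @ qv)
                alphas.append((a, rho, s, y))
                qv -= a * y
            qv = precondition(qv)
            for a, rho, s, y in reversed(alphas):
                b = rho * float(y @ qv)
                qv += (a - b) * s
            d = -qv
            gd = float(g @ d)
            if gd >= 0.0:  # not a descent direction: reset history
                s_hist.clear()
                y_hist.clear()
                d = -precondition(g)
                gd = float(g @ d)
            step = 1.0
            accepted = False
            for _ in range(30):
                Ka = _build_kappa(step * d[:nA], pairs_a, Ca.shape[0])
                Kb = _build_kappa(step * d[nA:], pairs_b, Cb.shape[0])
                Ca_t = Ca @ sla.expm(-Ka)
                Cb_t = Cb @ sla.expm(-Kb)
                eb_t, Fa_t, Fb_t, Pa_t, Pb_t = _gdm_energy(model, Ca_t, Cb_t, fa, fb, efermi)
                if eb_t.E_tot <= e_cur + 1e-4 * step * gd:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            g_new = gradient(Fa_t, Fb_t, Ca_t, Cb_t)
            s_vec = step * d
            y_vec = g_new - g
            if float(s_vec @ y_vec) > 1e-14:
                s_hist.append(s_vec)
                y_hist.append(y_vec)
                if len(s_hist) > settings.gdm_lbfgs_history:
                    s_hist.pop(0)
                    y_hist.pop(0)
            Ca, Cb = Ca_t, Cb_t
            Fa, Fb = Fa_t, Fb_t
            Pa, Pb = Pa_t, Pb_t
            eb = eb_t
            e_cur = eb.E_tot
            g = g_new
            total_inner += 1
            state.trace.append(
                {"iter": total_inner, "E": e_cur, "dE": float(e_cur - e_macro_old)
                 if inner == 0 else np.nan, "error": float(np.abs(g).max()),
                 "solver": "gdm", "macro": macro}
            )
            if total_inner >= settings.max_iter:
                break
        # semi-canonicalize: orbital energies from the current Fock
        eps_a, Ua = np.linalg.eigh(Ca.T @ Fa @ Ca)
        eps_b, Ub = np.linalg.eigh(Cb.T @ Fb @ Cb)
        state.Ca, state.Cb = Ca @ Ua, Cb @ Ub
        state.eps_a, state.eps_b = eps_a, eps_b
        state.Pa, state.Pb = Pa, Pb
        state.Fa, state.Fb = Fa, Fb
        state.occ_a, state.occ_b = fa, fb
        state.mu_a, state.mu_b = mu_a, mu_b
        state.energy = eb
        state.n_iter = total_inner
        de = e_cur - e_macro_old
        if inner_converged and abs(de) < settings.e_thresh:
            state.converged = True
            break
        e_macro_old = e_cur
        if total_inner >= settings.max_iter:
            break
    return state


def scf_solve(model_or_structure, params=None, settings: SCFSettings | None = None,
              initial: SCFState | None = None, **model_kwargs) -> SCFState:
    """Converge the SCF with the configured driver.

    Accepts either a prebuilt model (anything exposing the model protocol:
    ``overlap``, ``h0``, ``n_alpha``, ``n_beta``, ``energy_and_fock``) or an
    :class:`AtomicStructure` plus a :class:`ParameterSet`.  ``initial`` may
    carry a previous solution whose orbitals seed the iteration.
    """
    settings = settings or SCFSettings()
    if params is not None:
        model = TBModel(model_or_structure, params, **model_kwargs)
    else:
        model = model_or_structure
    if initial is not None:
        initial = warm_state(model, settings, initial)
    if settings.solver == "gdm":
        state = gdm_minimize(model, settings, state=initial)
    elif settings.solver in ("diis", "fixed-point"):
        state = _iterate(model, settings, settings.solver, initial=initial)
    else:
        raise ValueError(f"unknown solver {settings.solver!r}")
    return state
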