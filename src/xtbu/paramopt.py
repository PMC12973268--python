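"""Spin-gap parameter workflows: RMSE/sign objectives over spin-gap tasks,
Sobol variance-based sensitivity, two-stage derivative-free + quasi-Newton
optimization, and 2-D parameter grid scans.

Free parameters are addressed by dotted names that resolve into the
parameter set: ``"Fe.W.dd"`` is the d-d spin constant of iron and
``"Fe.U.d"`` its d-shell Hubbard parameter (both Hartree).

Sensitivity analysis uses Saltelli-style radial sampling on a scrambled
Sobol sequence (scipy.stats.qmc) with the Jansen estimators for first- and
total-order indices and bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .analysis import SpinGapRecord
from .params import ParameterSet
from .scf import SCFSettings
from .structure import AtomicStructure


class ObjectiveError(RuntimeError):
    pass


@dataclass
class SpinGapTask:
    structure: AtomicStructure
    multiplicity_hs: int
    multiplicity_ls: int
    reference_kcal: float
    system_id: str = ""


@dataclass
class ObjectiveSpec:
    tasks: list[SpinGapTask]
    free_parameters: list[str]
    bounds: list[tuple[float, float]]
    base_params: ParameterSet
    settings: SCFSettings | None = None
    penalty_kcal: float = 100.0
    model_kwargs: dict = field(default_factory=dict)
    u_variant: object = None
    warm_start: bool = True

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValueError("objective needs at least one spin-gap task")
        if len(self.bounds) != len(self.free_parameters):
            raise ValueError("one (lo, hi) bound pair per free parameter")
        for name, (lo, hi) in zip(self.free_parameters, self.bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lo < hi")
            _parse_param_name(name)  # validates syntax
        # check the names resolve into the parameter set
        apply_parameters(np.array([0.5 * (lo + hi) for lo, hi in self.bounds]), self)
        # geometry/basis quantities are parameter-step invariant (only W/U
        # move), so each task's models are built once and reused
        self._models: dict = {}
        self._warm: dict = {}

    def model_for(self, itask: int, multiplicity: int, params, u_variant):
        from .hamiltonian import TBModel
        from .structure import AtomicStructure

        key = (itask, multiplicity)
        if key not in self._models:
            task = self.tasks[itask]
            st = AtomicStructure(
                list(task.structure.elements), task.structure.coordinates_bohr.copy(),
                task.structure.total_charge, multiplicity,
            )
            self._models[key] = TBModel(st, self.base_params, u_variant=u_variant,
                                        **self.model_kwargs)
        return self._models[key].with_params(params, u_variant=u_variant)


def _parse_param_name(name: str):
    parts = name.split(".")
    if len(parts) != 3 or parts[1] not in ("W", "U"):
        raise ValueError(
            f"free parameter {name!r} must look like 'Fe.W.dd' or 'Fe.U.d'"
        )
    el, kind, sh = parts
    if kind == "W" and len(sh) != 2:
        raise ValueError(f"spin-constant name {name!r} needs a shell pair like 'dd'")
    if kind == "U" and len(sh) != 1:
        raise ValueError(f"Hubbard name {name!r} needs a single shell like 'd'")
    return el, kind, sh


def apply_parameters(vec: np.ndarray, spec: ObjectiveSpec) -> ParameterSet:
    vec = np.asarray(vec, float)
    if vec.shape != (len(spec.free_parameters),):
        raise ValueError(
            f"parameter vector has {vec.size} entries, expected {len(spec.free_parameters)}"
        )
    p = spec.base_params
    for name, val in zip(spec.free_parameters, vec):
        el, kind, sh = _parse_param_name(name)
        if kind == "W":
            p = p.with_spin_constant(el, sh[0], sh[1], float(val))
        else:
            p = p.with_hubbard_u(el, {sh: float(max(val, 0.0))})
    return p


def rmse_and_signs(gaps, refs) -> tuple[float, int]:
    """Root-mean-square error and count of sign agreements between predicted
    and reference gaps (a zero reference counts as agreeing only with a zero
    gap)."""
    gaps = np.asarray(gaps, float)
    refs = np.asarray(refs, float)
    if gaps.shape != refs.shape or gaps.size == 0:
        raise ValueError("gaps and references must be equal-length and non-empty")
    rmse = float(np.sqrt(np.mean((gaps - refs) ** 2)))
    nsign = int(np.sum(np.where(refs == 0.0, gaps == 0.0, np.sign(gaps) == np.sign(refs))))
    return rmse, nsign


@dataclass
class ObjectiveResult:
    rmse_kcal: float
    n_sign_correct: int
    n_tasks: int
    n_failed: int
    records: list[SpinGapRecord] = field(default_factory=list)


def objective(vec: np.ndarray, spec: ObjectiveSpec) -> ObjectiveResult:
    """RMSE (kcal/mol) and sign-correct count of the spin-gap tasks at the
    given free-parameter values.  Non-converged tasks contribute the fixed
    penalty and are counted separately."""
    from .constants import HARTREE_TO_KCAL
    from .scf import SCFSettings, scf_solve

    params = apply_parameters(vec, spec)
    settings = spec.settings or SCFSettings(solver="gdm", max_iter=800)
    errors = []
    nsign = 0
    nfail = 0
    records = []
    for itask, task in enumerate(spec.tasks):
        states = {}
        for mult in (task.multiplicity_hs, task.multiplicity_ls):
            model = spec.model_for(itask, mult, params, spec.u_variant)
            initial = spec._warm.get((itask, mult)) if spec.warm_start else None
            st = scf_solve(model, settings=settings, initial=initial)
            if spec.warm_start and st.converged:
                spec._warm[(itask, mult)] = st
            states[mult] = st
        hs, ls = states[task.multiplicity_hs], states[task.multiplicity_ls]
        rec = SpinGapRecord(
            system_id=task.system_id or f"task{itask}",
            multiplicity_hs=task.multiplicity_hs,
            multiplicity_ls=task.multiplicity_ls,
            E_hs=hs.E_tot, E_ls=ls.E_tot,
            gap_kcal=float((hs.E_tot - ls.E_tot) * HARTREE_TO_KCAL),
            reference_kcal=task.reference_kcal,
            converged=bool(hs.converged and ls.converged),
        )
        records.append(rec)
        if rec.converged:
            errors.append(rec.gap_kcal - task.reference_kcal)
            if rec.sign_correct:
                nsign += 1
        else:
            errors.append(spec.penalty_kcal)
            nfail += 1
    if nfail == len(spec.tasks):
        raise ObjectiveError("every spin-gap task failed to converge")
    rmse = float(np.sqrt(np.mean(np.square(errors))))
    return ObjectiveResult(rmse, nsign, len(spec.tasks), nfail, records)


def objective_rmse(vec: np.ndarray, spec: ObjectiveSpec) -> float:
    return objective(vec, spec).rmse_kcal


# ---------------- Sobol sensitivity ----------------


@dataclass
class SensitivityResult:
    parameters: list[str]
    first_order: np.ndarray
    total_order: np.ndarray
    first_order_ci: np.ndarray  # 95% half-widths
    total_order_ci: np.ndarray
    n_samples: int


def sobol_sensitivity(
    func,
    bounds,
    n_base_samples: int,
    seed: int,
    parameter_names: list[str] | None = None,
    n_bootstrap: int = 200,
) -> SensitivityResult:
    """First- and total-order Sobol indices of ``func`` over a box.

    ``func`` maps a 1-D parameter vector to a scalar; ``n_base_samples``
    must be a power of two (Sobol-sequence balance).  Saltelli radial
    sampling costs ``n_base_samples * (d + 2)`` evaluations.  Estimators:
    Saltelli-2010 for S1, Jansen for ST; confidence intervals are 95%
    normal-approximation bootstrap half-widths.
    """
    bounds = np.asarray(bounds, float)
    d = bounds.shape[0]
    n = int(n_base_samples)
    if n <= 0 or (n & (n - 1)) != 0:
        raise ValueError("n_base_samples must be a positive power of 2")
    eng = qmc.Sobol(2 * d, scramble=True, seed=seed)
    base = eng.random(n)
    lo, hi = bounds[:, 0], bounds[:, 1]
    A = lo + (hi - lo) * base[:, :d]
    B = lo + (hi - lo) * base[:, d:]

    fA = np.array([func(x) for x in A])
    fB = np.array([func(x) for x in B])
    fAB = np.empty((d, n))
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fAB[i] = [func(x) for x in ABi]

    allf = np.concatenate([fA, fB])
    var = float(np.var(allf))
    names = parameter_names or [f"x{i}" for i in range(d)]
    if var < 1e-30:
        warnings.warn("objective is (numerically) constant; all Sobol indices are 0")
        z = np.zeros(d)
        return SensitivityResult(names, z, z.copy(), z.copy(), z.copy(), n)

    rng = np.random.default_rng(seed + 1)

    def estimates(idx):
        v = np.var(np.concatenate([fA[idx], fB[idx]]))
        s1 = np.mean(fB[idx] * (fAB[:, idx] - fA[idx]), axis=1) / v
        st = 0.5 * np.mean((fA[idx] - fAB[:, idx]) ** 2, axis=1) / v
        return s1, st

    s1, st = estimates(np.arange(n))
    boots1 = np.empty((n_bootstrap, d))
    bootst = np.empty((n_bootstrap, d))
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        boots1[b], bootst[b] = estimates(idx)
    ci1 = 1.96 * boots1.std(axis=0)
    cit = 1.96 * bootst.std(axis=0)
    return SensitivityResult(names, s1, st, ci1, cit, n)


def sobol_sensitivity_spec(spec: ObjectiveSpec, n_base_samples: int, seed: int,
                           **kwargs) -> SensitivityResult:
    """Sobol indices of the spin-gap RMSE w.r.t. the spec's free parameters."""
    return sobol_sensitivity(
        lambda x: objective_rmse(x, spec), spec.bounds, n_base_samples, seed,
        parameter_names=list(spec.free_parameters), **kwargs,
    )


# ---------------- two-stage optimization ----------------


@dataclass
class OptimizationResult:
    x: np.ndarray
    fun: float
    x_start: np.ndarray
    fun_start: float
    trace: list = field(default_factory=list)
    success: bool = True


def two_stage_optimize(
    func,
    start,
    bounds,
    seed: int = 42,
    powell_maxiter: int = 200,
    lbfgsb_maxiter: int = 200,
    fd_step: float = 1e-5,
) -> OptimizationResult:
    """Coarse derivative-free Powell search followed by bounded L-BFGS-B
    refinement with numerical gradients.  The best point ever evaluated is
    returned, so the final objective never exceeds the starting one."""
    start = np.asarray(start, float)
    bounds = [tuple(b) for b in np.asarray(bounds, float)]
    for x0, (lo, hi) in zip(start, bounds):
        if not (lo <= x0 <= hi):
            raise ValueError(f"start value {x0} outside bounds [{lo}, {hi}]")
    trace: list = []
    best = {"x": start.copy(), "f": np.inf}

    def wrapped(x, stage):
        f = float(func(np.asarray(x, float)))
        trace.append({"stage": stage, "x": np.array(x, float), "f": f})
        if f < best["f"]:
            best["x"] = np.array(x, float)
            best["f"] = f
        return f

    f0 = wrapped(start, "start")
    ok = True
    try:
        r1 = minimize(
            wrapped, start, args=("powell",), method="Powell", bounds=bounds,
            options={"maxiter": powell_maxiter, "xtol": 1e-6, "ftol": 1e-8},
        )
        x1 = np.clip(r1.x, [b[0] for b in bounds], [b[1] for b in bounds])
        r2 = minimize(
            wrapped, x1, args=("lbfgsb",), method="L-BFGS-B", bounds=bounds,
            options={"maxiter": lbfgsb_maxiter, "eps": fd_step, "ftol": 1e-12,
                     "gtol": 1e-8},
        )
        ok = bool(r1.success or r2.success)
    except Exception:
        ok = False
    return OptimizationResult(best["x"], best["f"], start, f0, trace, ok)


def two_stage_optimize_spec(spec: ObjectiveSpec, start, seed: int = 42,
                            **kwargs) -> OptimizationResult:
    return two_stage_optimize(
        lambda x: objective_rmse(x, spec), start, spec.bounds, seed=seed, **kwargs
    )


# ---------------- 2-D grid scans ----------------


@dataclass
class GridScanResult:
    param_x: str
    param_y: str
    grid_x: np.ndarray
    grid_y: np.ndarray
    rmse: np.ndarray  # (nx, ny)
    sign_correct: np.ndarray  # (nx, ny) ints
    n_failed: np.ndarray  # (nx, ny) ints

    def argmin_rmse(self) -> tuple[int, int]:
        i, j = np.unravel_index(np.argmin(self.rmse), self.rmse.shape)
        return int(i), int(j)

    def argmax_sign(self, prefer=(0.0, 0.0)) -> tuple[int, int]:
        """Cell with most correct signs; ties broken toward the parameter
        values in ``prefer`` (default parameters)."""
        bestv = self.sign_correct.max()
        cands = np.argwhere(self.sign_correct == bestv)
        dist = [
            (self.grid_x[i] - prefer[0]) ** 2 + (self.grid_y[j] - prefer[1]) ** 2
            for i, j in cands
        ]
        i, j = cands[int(np.argmin(dist))]
        return int(i), int(j)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, x in enumerate(self.grid_x):
            for j, y in enumerate(self.grid_y):
                rows.append(
                    {self.param_x: x, self.param_y: y, "rmse_kcal": self.rmse[i, j],
                     "sign_correct": int(self.sign_correct[i, j]),
                     "n_failed": int(self.n_failed[i, j])}
                )
        return pd.DataFrame(rows)


def grid_scan_2d(spec: ObjectiveSpec, param_x: str, param_y: str,
                 grid_x, grid_y) -> GridScanResult:
    """Exhaustive (RMSE, sign-count) evaluation over a 2-D parameter grid."""
    grid_x = np.atleast_1d(np.asarray(grid_x, float))
    grid_y = np.atleast_1d(np.asarray(grid_y, float))
    if grid_x.size == 0 or grid_y.size == 0:
        raise ValueError("grids must be non-empty")
    ix = spec.free_parameters.index(param_x)
    iy = spec.free_parameters.index(param_y)
    mid = np.array([0.5 * (lo + hi) for lo, hi in spec.bounds])
    rmse = np.empty((grid_x.size, grid_y.size))
    sign = np.empty_like(rmse, dtype=int)
    fail = np.empty_like(sign)
    for i, x in enumerate(grid_x):
        for j, y in enumerate(grid_y):
            vec = mid.copy()
            vec[ix] = x
            vec[iy] = y
            res = objective(vec, spec)
            rmse[i, j] = res.rmse_kcal
            sign[i, j] = res.n_sign_correct
            fail[i, j] = res.n_failed
    return GridScanResult(param_x, param_y, grid_x, grid_y, rmse, sign, fail)


def load_tasks_csv(path, default_charge: int = 0) -> list[SpinGapTask]:
    """Spin-gap task table: columns xyz_path, charge, multiplicity_hs,
    multiplicity_ls, reference_kcal[, system_id]."""
    import pandas as pd

    from .io import read_xyz

    df = pd.read_csv(path)
    tasks = []
    for _, row in df.iterrows():
        st = read_xyz(row["xyz_path"])
        st.total_charge = int(row.get("charge", default_charge))
        tasks.append(
            SpinGapTask(
                structure=st,
                multiplicity_hs=int(row["multiplicity_hs"]),
                multiplicity_ls=int(row["multiplicity_ls"]),
                reference_kcal=float(row["reference_kcal"]),
                system_id=str(row.get("system_id", "")),
            )
        )
    return tasks
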