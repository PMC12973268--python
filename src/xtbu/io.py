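"""XYZ reading/writing and result serialization (JSON/CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .constants import ANGSTROM_PER_BOHR
from .structure import AtomicStructure

RESULT_SCHEMA_VERSION = 1


from dataclasses import asdict, dataclass, field  # noqa: E402


@dataclass
class RunConfig:
    """A complete run description: structure, electronic state, solver
    settings, +U configuration, paths, and the single seed every stochastic
    stage draws from (via :meth:`rng`)."""

    structure_path: str = ""
    charge: int | None = None
    multiplicity: int | None = None
    solver: str = "diis"
    etemp: float = 300.0
    max_iter: int = 250
    u_variant: str = "none"
    u_element: str = "Fe"
    u_values: dict = field(default_factory=dict)  # shell label -> Hartree
    param_file: str | None = None
    output_path: str | None = None
    seed: int = 42
    verbose: bool = False

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


class XYZParseError(ValueError):
    pass


def _comment_tokens(comment: str) -> dict[str, int]:
    out = {}
    for tok in comment.replace(",", " ").split():
        if "=" in tok:
            key, _, val = tok.partition("=")
            key = key.strip().lower()
            if key in ("charge", "multiplicity"):
                try:
                    out[key] = int(val)
                except ValueError as exc:
                    raise XYZParseError(f"bad {key} token {tok!r} in XYZ comment") from exc
    return out


def read_xyz(path, charge: int | None = None, multiplicity: int | None = None) -> AtomicStructure:
    """Read a standard XYZ file (Angstrom).

    The comment line may carry ``charge=<int>`` and ``multiplicity=<int>``
    tokens; explicit arguments override them.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZParseError(f"{path}: line 1 must hold the atom count") from None
    if len(lines) < natoms + 2:
        raise XYZParseError(
            f"{path}: line 1 announces {natoms} atoms but only "
            f"{max(len(lines) - 2, 0)} atom lines follow"
        )
    comment = lines[1] if len(lines) > 1 else ""
    tokens = _comment_tokens(comment)
    elements, coords = [], []
    for i, line in enumerate(lines[2 : 2 + natoms], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}: malformed atom record on line {i}")
        elements.append(parts[0])
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise XYZParseError(f"{path}: non-numeric coordinate on line {i}") from None
    return AtomicStructure.from_angstrom(
        elements,
        np.array(coords),
        total_charge=charge if charge is not None else tokens.get("charge", 0),
        multiplicity=multiplicity if multiplicity is not None else tokens.get("multiplicity", 1),
        comment=comment,
    )


def write_xyz(structure: AtomicStructure, path) -> None:
    lines = [str(structure.natoms),
             f"charge={structure.total_charge} multiplicity={structure.multiplicity}"]
    for el, xyz in zip(structure.elements, structure.coordinates_bohr * ANGSTROM_PER_BOHR):
        lines.append(f"{el:2s} {xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f}")
    Path(path).write_text("\n".join(lines) + "\n")


def state_to_dict(state) -> dict:
    """JSON-serializable summary of an SCF state: term-resolved energies,
    frontier data, occupations, and the convergence trace."""
    d = {
        "schema_version": RESULT_SCHEMA_VERSION,
        "converged": bool(state.converged),
        "solver": state.solver,
        "n_iterations": int(state.n_iter),
        "energy": state.energy.as_dict(),
        "orbital_energies": {
            "alpha": np.asarray(state.eps_a).tolist(),
            "beta": np.asarray(state.eps_b).tolist(),
        },
        "occupations": {
            "alpha": np.asarray(state.occ_a).tolist(),
            "beta": np.asarray(state.occ_b).tolist(),
        },
        "chemical_potential": {"alpha": float(state.mu_a), "beta": float(state.mu_b)},
        "trace": [
            {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in t.items()}
            for t in state.trace
        ],
    }
    return d


def emit_results(obj, path, fmt: str = "json") -> None:
    """Write a results object (SCF state dict, scan dataframe, records) to disk."""
    path = Path(path)
    if fmt == "json":
        if hasattr(obj, "converged") and hasattr(obj, "energy"):
            obj = state_to_dict(obj)
        path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    elif fmt == "csv":
        import pandas as pd

        if not isinstance(obj, pd.DataFrame):
            obj = pd.DataFrame(obj)
        obj.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def _json_default(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialize {type(x)}")
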