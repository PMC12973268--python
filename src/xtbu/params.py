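"""Element-wise tight-binding parameter model.

The parameter file is a flat TOML schema: a ``[global]`` table for the
method-wide constants and one ``[element.X]`` table per element carrying the
shell structure (angular momenta and principal quantum numbers), Hueckel
levels, Slater exponents, hardness and third-order constants, repulsion
parameters, multipole kernels, the symmetric spin-constant matrix ``W`` and
the per-shell Hubbard parameters ``U``.

Defaults are applied on load: missing ``U`` entries are zero, a missing
``alpha_u`` is 0.5, and a missing ``W`` matrix is all zeros.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import ANGULAR_MOMENTUM, HARTREE_PER_EV


class ParameterError(ValueError):
    """Malformed or incomplete parameter file."""


@dataclass(frozen=True)
class ElementParams:
    symbol: str
    shells: tuple[int, ...]  # angular momenta, increasing
    pqn: tuple[int, ...]  # principal quantum number per shell
    levels: tuple[float, ...]  # Hartree
    slater_exp: tuple[float, ...]
    ref_occ: tuple[float, ...]
    k_cn: tuple[float, ...]  # Hartree per CN unit
    shell_poly: tuple[float, ...]
    gam: float
    shell_hardness: tuple[float, ...]  # multiplicative per-shell factors
    gam3: float
    rep_alpha: float
    rep_zeff: float
    en: float
    cov_radius: float  # Angstrom
    dip_kernel: float
    quad_kernel: float
    mp_rad: float  # Bohr
    mp_vcn: float
    W: tuple[tuple[float, ...], ...]  # Hartree, symmetric in shell pair
    U: tuple[float, ...]  # Hartree, per shell

    @property
    def nshells(self) -> int:
        return len(self.shells)

    @property
    def n_valence(self) -> int:
        return int(round(sum(self.ref_occ)))

    def shell_eta(self, ish: int) -> float:
        """Shell-resolved chemical hardness."""
        return self.gam * self.shell_hardness[ish]


@dataclass(frozen=True)
class GlobalParams:
    alpha_u: float = 0.5
    rep_kexp: float = 1.5
    rep_kexp_light: float = 1.0
    k_shell: tuple[float, float, float] = (1.85, 2.23, 2.23)
    k_en: float = 0.02
    wexp: float = 0.5
    gexp: float = 2.0
    third_order_shell_scale: tuple[float, float, float] = (1.0, 0.5, 0.25)
    cn_radius_scale: float = 4.0 / 3.0
    mp_dmp3: float = 3.0
    mp_dmp5: float = 4.0
    mp_kexp: float = 4.0
    mp_shift: float = 1.2
    mp_rmax: float = 5.0


@dataclass(frozen=True)
class ParameterSet:
    globals: GlobalParams
    elements: dict[str, ElementParams] = field(default_factory=dict)

    def element(self, symbol: str) -> ElementParams:
        try:
            return self.elements[symbol]
        except KeyError:
            raise ParameterError(
                f"element {symbol!r} is not parameterized (available: "
                f"{sorted(self.elements)})"
            ) from None

    def valence_counts(self) -> dict[str, int]:
        return {sym: el.n_valence for sym, el in self.elements.items()}

    def with_element_update(self, symbol: str, **changes) -> "ParameterSet":
        """Functional update of one element's parameters (e.g. U or W values)."""
        el = self.element(symbol)
        new = dict(self.elements)
        new[symbol] = replace(el, **changes)
        return ParameterSet(self.globals, new)

    def with_hubbard_u(self, symbol: str, u_by_l: dict[str, float]) -> "ParameterSet":
        """Return a copy with Hubbard U values set on the shells of one element.

        ``u_by_l`` maps shell labels ('s', 'p', 'd') to U in Hartree.
        """
        el = self.element(symbol)
        new_u = list(el.U)
        for lab, val in u_by_l.items():
            if val < 0:
                raise ParameterError(f"negative Hubbard U for {symbol}.{lab}: {val}")
            l = ANGULAR_MOMENTUM[lab]
            if l not in el.shells:
                raise ParameterError(f"element {symbol} has no {lab} shell")
            new_u[el.shells.index(l)] = float(val)
        return self.with_element_update(symbol, U=tuple(new_u))

    def with_spin_constant(self, symbol: str, l1: str, l2: str, value: float) -> "ParameterSet":
        el = self.element(symbol)
        i = el.shells.index(ANGULAR_MOMENTUM[l1])
        j = el.shells.index(ANGULAR_MOMENTUM[l2])
        W = np.array(el.W, dtype=float)
        W[i, j] = W[j, i] = value
        return self.with_element_update(symbol, W=tuple(map(tuple, W)))


def _require(table: dict, key: str, context: str):
    if key not in table:
        raise ParameterError(f"missing key {key!r} in {context}")
    return table[key]


def _parse_element(symbol: str, tab: dict) -> ElementParams:
    ctx = f"[element.{symbol}]"
    shell_labels = _require(tab, "shells", ctx)
    try:
        shells = tuple(ANGULAR_MOMENTUM[lab] for lab in shell_labels)
    except KeyError as exc:
        raise ParameterError(f"bad shell label {exc} in {ctx}") from None
    if list(shells) != sorted(shells) or len(set(shells)) != len(shells):
        raise ParameterError(f"shells must be unique and in increasing l in {ctx}")
    nsh = len(shells)

    def vec(key, default=None):
        if default is not None and key not in tab:
            v = default
        else:
            v = _require(tab, key, ctx)
        v = tuple(float(x) for x in v)
        if len(v) != nsh:
            raise ParameterError(f"{key!r} in {ctx} must have {nsh} entries, got {len(v)}")
        return v

    W_raw = tab.get("W")
    if W_raw is None:
        W = tuple(tuple(0.0 for _ in range(nsh)) for _ in range(nsh))
    else:
        W_arr = np.array(W_raw, dtype=float)
        if W_arr.shape != (nsh, nsh):
            raise ParameterError(f"'W' in {ctx} must be {nsh}x{nsh}")
        if not np.allclose(W_arr, W_arr.T, atol=1e-12):
            raise ParameterError(f"'W' in {ctx} must be symmetric")
        W = tuple(map(tuple, W_arr))

    U = vec("U", default=(0.0,) * nsh)
    if any(u < 0 for u in U):
        raise ParameterError(f"'U' in {ctx} must be non-negative")

    return ElementParams(
        symbol=symbol,
        shells=shells,
        pqn=tuple(int(n) for n in _require(tab, "pqn", ctx)),
        levels=tuple(x * HARTREE_PER_EV for x in vec("levels_ev")),
        slater_exp=vec("slater_exp"),
        ref_occ=vec("ref_occ"),
        k_cn=tuple(x * HARTREE_PER_EV for x in vec("k_cn_ev", default=(0.0,) * nsh)),
        shell_poly=vec("shell_poly", default=(0.0,) * nsh),
        gam=float(_require(tab, "gam", ctx)),
        shell_hardness=vec("shell_hardness", default=(1.0,) * nsh),
        gam3=float(tab.get("gam3", 0.0)),
        rep_alpha=float(_require(tab, "rep_alpha", ctx)),
        rep_zeff=float(_require(tab, "rep_zeff", ctx)),
        en=float(_require(tab, "en", ctx)),
        cov_radius=float(_require(tab, "cov_radius", ctx)),
        dip_kernel=float(tab.get("dip_kernel", 0.0)),
        quad_kernel=float(tab.get("quad_kernel", 0.0)),
        mp_rad=float(tab.get("mp_rad", 3.0)),
        mp_vcn=float(tab.get("mp_vcn", 1.0)),
        W=W,
        U=U,
    )


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter file; ``None`` loads the shipped defaults."""
    if path is None:
        data = resources.files("xtbu.data").joinpath("params_default.toml").read_bytes()
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        data = p.read_bytes()
    try:
        doc = tomllib.loads(data.decode())
    except tomllib.TOMLDecodeError as exc:
        raise ParameterError(f"parameter file parse error: {exc}") from exc

    g = doc.get("global", {})
    defaults = GlobalParams()
    known = set(GlobalParams.__dataclass_fields__)
    unknown = set(g) - known
    if unknown:
        raise ParameterError(f"unknown [global] keys: {sorted(unknown)}")
    kwargs = {}
    for key in known:
        if key in g:
            v = g[key]
            if key == "k_shell":
                v = (float(v["s"]), float(v["p"]), float(v["d"]))
            elif key == "third_order_shell_scale":
                v = tuple(float(x) for x in v)
            else:
                v = float(v)
            kwargs[key] = v
    glob = replace(defaults, **kwargs)
    if not (0.0 <= glob.alpha_u <= 1.0):
        raise ParameterError(f"alpha_u must lie in [0, 1], got {glob.alpha_u}")

    elements = {}
    for sym, tab in doc.get("element", {}).items():
        elements[sym] = _parse_element(sym, tab)
    if not elements:
        raise ParameterError("parameter file defines no elements")
    return ParameterSet(glob, elements)


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Serialize a ParameterSet back to the TOML schema (round-trips with load)."""
    from .constants import EV_PER_HARTREE, L_LABEL

    lines: list[str] = ["[global]"]
    g = params.globals
    lines.append(f"alpha_u = {g.alpha_u!r}")
    lines.append(f"rep_kexp = {g.rep_kexp!r}")
    lines.append(f"rep_kexp_light = {g.rep_kexp_light!r}")
    ks = g.k_shell
    lines.append(f"k_shell = {{ s = {ks[0]!r}, p = {ks[1]!r}, d = {ks[2]!r} }}")
    lines.append(f"k_en = {g.k_en!r}")
    lines.append(f"wexp = {g.wexp!r}")
    lines.append(f"gexp = {g.gexp!r}")
    lines.append(f"third_order_shell_scale = {list(g.third_order_shell_scale)!r}")
    lines.append(f"cn_radius_scale = {g.cn_radius_scale!r}")
    for key in ("mp_dmp3", "mp_dmp5", "mp_kexp", "mp_shift", "mp_rmax"):
        lines.append(f"{key} = {getattr(g, key)!r}")
    for sym, el in params.elements.items():
        lines.append("")
        lines.append(f"[element.{sym}]")
        lines.append(f"shells = {[L_LABEL[l] for l in el.shells]!r}".replace("'", '"'))
        lines.append(f"pqn = {list(el.pqn)!r}")
        lines.append(f"levels_ev = {[x * EV_PER_HARTREE for x in el.levels]!r}")
        lines.append(f"slater_exp = {list(el.slater_exp)!r}")
        lines.append(f"ref_occ = {list(el.ref_occ)!r}")
        lines.append(f"k_cn_ev = {[x * EV_PER_HARTREE for x in el.k_cn]!r}")
        lines.append(f"shell_poly = {list(el.shell_poly)!r}")
        lines.append(f"gam = {el.gam!r}")
        lines.append(f"shell_hardness = {list(el.shell_hardness)!r}")
        lines.append(f"gam3 = {el.gam3!r}")
        lines.append(f"rep_alpha = {el.rep_alpha!r}")
        lines.append(f"rep_zeff = {el.rep_zeff!r}")
        lines.append(f"en = {el.en!r}")
        lines.append(f"cov_radius = {el.cov_radius!r}")
        lines.append(f"dip_kernel = {el.dip_kernel!r}")
        lines.append(f"quad_kernel = {el.quad_kernel!r}")
        lines.append(f"mp_rad = {el.mp_rad!r}")
        lines.append(f"mp_vcn = {el.mp_vcn!r}")
        lines.append(f"W = {[[float(x) for x in row] for row in el.W]!r}")
        lines.append(f"U = {[float(u) for u in el.U]!r}")
    Path(path).write_text("\n".join(lines) + "\n")
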