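"""Overlap and multipole-moment integrals over contracted spherical Gaussians.

One-dimensional Obara-Saika recurrences build Cartesian primitive integrals;
Cartesian monomials are transformed to real spherical harmonics (orthonormal
angular parts, m = -l..+l ordering).  Moment integrals are returned with a
global origin at the coordinate origin; per-atom origins are obtained by
analytic shifting (see :func:`shift_first_moment`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .basis import ShellBasis

# Cartesian monomial exponent lists per l, and the transformation from
# unnormalized Cartesian monomials (x^i y^j z^k e^{-a r^2}) to real spherical
# AOs whose radial part is the radially-normalized pure-l Gaussian.
_CART = {
    0: [(0, 0, 0)],
    1: [(0, 1, 0), (0, 0, 1), (1, 0, 0)],  # m = -1, 0, +1 -> y, z, x
    2: [(1, 1, 0), (0, 1, 1), (0, 0, 2), (1, 0, 1), (2, 0, 0)],  # placeholder rows
}

_SQ4PI = math.sqrt(4.0 * math.pi)


def _sph_rows(l: int) -> list[list[tuple[float, tuple[int, int, int]]]]:
    """Rows of the Cartesian->spherical map: angular-normalized solid harmonics."""
    if l == 0:
        return [[(1.0 / _SQ4PI, (0, 0, 0))]]
    if l == 1:
        c = math.sqrt(3.0 / (4.0 * math.pi))
        return [
            [(c, (0, 1, 0))],  # p_y
            [(c, (0, 0, 1))],  # p_z
            [(c, (1, 0, 0))],  # p_x
        ]
    if l == 2:
        c2 = math.sqrt(15.0 / (4.0 * math.pi))
        cz = math.sqrt(5.0 / (16.0 * math.pi))
        cx = math.sqrt(15.0 / (16.0 * math.pi))
        return [
            [(c2, (1, 1, 0))],  # d_xy
            [(c2, (0, 1, 1))],  # d_yz
            [(2 * cz, (0, 0, 2)), (-cz, (2, 0, 0)), (-cz, (0, 2, 0))],  # d_z2
            [(c2, (1, 0, 1))],  # d_xz
            [(cx, (2, 0, 0)), (-cx, (0, 2, 0))],  # d_x2-y2
        ]
    raise NotImplementedError(f"l={l}")


def _radial_norm(l: int, alpha: float) -> float:
    return math.sqrt(2.0 * (2.0 * alpha) ** (l + 1.5) / math.gamma(l + 1.5))


def _os_1d(pa: float, pb: float, p: float, imax: int, jmax: int) -> np.ndarray:
    """1D overlap table S[i, j] = <(x-A)^i | (x-B)^j> over exp(-p x'^2) factors.

    ``pa`` = P-A, ``pb`` = P-B where P is the Gaussian product center; the
    common prefactor sqrt(pi/p)*exp(-mu AB^2) is applied by the caller.
    """
    S = np.zeros((imax + 1, jmax + 1))
    S[0, 0] = 1.0
    inv2p = 0.5 / p
    for i in range(imax + 1):
        for j in range(jmax + 1):
            if i == 0 and j == 0:
                continue
            if j > 0:
                val = pb * S[i, j - 1]
                if j > 1:
                    val += (j - 1) * inv2p * S[i, j - 2]
                if i > 0:
                    val += i * inv2p * S[i - 1, j - 1]
            else:
                val = pa * S[i - 1, 0]
                if i > 1:
                    val += (i - 1) * inv2p * S[i - 2, 0]
            S[i, j] = val
    return S


@dataclass
class Integrals:
    overlap: np.ndarray  # (nao, nao)
    moment1: np.ndarray  # (3, nao, nao), origin at 0
    moment2: np.ndarray  # (3, 3, nao, nao), symmetric in xy, origin at 0

    def condition_number(self) -> float:
        w = np.linalg.eigvalsh(self.overlap)
        return float(w[-1] / w[0])


class OverlapConditionError(RuntimeError):
    pass


def compute_integrals(basis: ShellBasis, cond_threshold: float = 1e12) -> Integrals:
    nao = basis.nao
    S = np.zeros((nao, nao))
    M1 = np.zeros((3, nao, nao))
    M2 = np.zeros((3, 3, nao, nao))
    coords = basis.structure.coordinates_bohr
    shells = basis.shells

    sph = {l: _sph_rows(l) for l in (0, 1, 2)}

    for isa, sa in enumerate(shells):
        A = coords[sa.atom]
        rows_a = sph[sa.l]
        for isb in range(isa, len(shells)):
            sb = shells[isb]
            B = coords[sb.atom]
            rows_b = sph[sb.l]
            AB2 = float(np.dot(A - B, A - B))
            la, lb = sa.l, sb.l
            # accumulate monomial-pair integrals over primitives
            ncarta = len(rows_a)
            ncartb = len(rows_b)
            blkS = np.zeros((ncarta, ncartb))
            blkM1 = np.zeros((3, ncarta, ncartb))
            blkM2 = np.zeros((3, 3, ncarta, ncartb))
            for a_i, c_i in zip(sa.alphas, sa.coeffs):
                na = _radial_norm(la, a_i)
                for b_j, c_j in zip(sb.alphas, sb.coeffs):
                    nb = _radial_norm(lb, b_j)
                    p = a_i + b_j
                    mu = a_i * b_j / p
                    pref = c_i * c_j * na * nb * (math.pi / p) ** 1.5 * math.exp(-mu * AB2)
                    if abs(pref) < 1e-18:
                        continue
                    P = (a_i * A + b_j * B) / p
                    t1d = [
                        _os_1d(P[d] - A[d], P[d] - B[d], p, la, lb + 2) for d in range(3)
                    ]
                    # 1D first/second moments about the global origin:
                    m1d = []
                    m2d = []
                    for d in range(3):
                        t = t1d[d]
                        Bd = B[d]
                        m1 = t[:, 1 : lb + 2] + Bd * t[:, 0 : lb + 1]
                        m2 = (
                            t[:, 2 : lb + 3]
                            + 2.0 * Bd * t[:, 1 : lb + 2]
                            + Bd * Bd * t[:, 0 : lb + 1]
                        )
                        m1d.append(m1)
                        m2d.append(m2)
                    for ia, row_a in enumerate(rows_a):
                        for ib, row_b in enumerate(rows_b):
                            sval = 0.0
                            m1val = np.zeros(3)
                            m2val = np.zeros((3, 3))
                            for ca, (ax, ay, az) in row_a:
                                for cb, (bx, by, bz) in row_b:
                                    w = ca * cb
                                    e = (ax, ay, az)
                                    f = (bx, by, bz)
                                    s3 = [t1d[d][e[d], f[d]] for d in range(3)]
                                    m3 = [m1d[d][e[d], f[d]] for d in range(3)]
                                    q3 = [m2d[d][e[d], f[d]] for d in range(3)]
                                    sval += w * s3[0] * s3[1] * s3[2]
                                    for d in range(3):
                                        oth = [s3[k] for k in range(3) if k != d]
                                        m1val[d] += w * m3[d] * oth[0] * oth[1]
                                    for d1 in range(3):
                                        for d2 in range(d1, 3):
                                            if d1 == d2:
                                                oth = [s3[k] for k in range(3) if k != d1]
                                                m2val[d1, d1] += w * q3[d1] * oth[0] * oth[1]
                                            else:
                                                d3 = 3 - d1 - d2
                                                m2val[d1, d2] += w * m3[d1] * m3[d2] * s3[d3]
                            sval *= pref
                            m1val *= pref
                            m2val *= pref
                            m2val[1, 0] = m2val[0, 1]
                            m2val[2, 0] = m2val[0, 2]
                            m2val[2, 1] = m2val[1, 2]
                            blkS[ia, ib] += sval
                            blkM1[:, ia, ib] += m1val
                            blkM2[:, :, ia, ib] += m2val
            sl_a, sl_b = sa.ao_slice, sb.ao_slice
            S[sl_a, sl_b] = blkS
            M1[:, sl_a, sl_b] = blkM1
            M2[:, :, sl_a, sl_b] = blkM2
            if isb != isa:
                S[sl_b, sl_a] = blkS.T
                M1[:, sl_b, sl_a] = np.transpose(blkM1, (0, 2, 1))
                M2[:, :, sl_b, sl_a] = np.transpose(blkM2, (0, 1, 3, 2))

    ints = Integrals(S, M1, M2)
    cond = ints.condition_number()
    if not np.isfinite(cond) or cond > cond_threshold or cond < 0:
        raise OverlapConditionError(
            f"overlap matrix is near-singular (condition number {cond:.3e})"
        )
    return ints


def shift_first_moment(ints: Integrals, origin: np.ndarray) -> np.ndarray:
    """First-moment integrals <mu|(r - origin)|nu> from global-origin ones."""
    return ints.moment1 - origin[:, None, None] * ints.overlap[None, :, :]


def shift_second_moment(ints: Integrals, origin: np.ndarray) -> np.ndarray:
    """Second moments <mu|(r-o)(r-o)^T|nu> from global-origin ones."""
    o = origin
    out = (
        ints.moment2
        - o[:, None, None, None] * ints.moment1[None, :, :, :]
        - o[None, :, None, None] * ints.moment1[:, None, :, :]
        + (o[:, None] * o[None, :])[:, :, None, None] * ints.overlap[None, None, :, :]
    )
    return out
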