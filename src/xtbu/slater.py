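"""Expansion of Slater-type orbitals in Gaussian primitives.

A normalized radial STO ``R_nl(r) = N r^(n-1) exp(-zeta r)`` is expanded in
``ng`` Gaussian primitives of the same angular momentum by maximizing the
radial overlap of the normalized contracted Gaussian with the STO (the
classic STO-nG construction).  For fixed primitive exponents the optimal
contraction is a linear problem; the exponents themselves are optimized
numerically.  Tables for zeta = 1 are generated once (see
``fit_sto_ng``) and frozen in :data:`STO_NG_TABLES`; an exponent ``zeta`` is
applied by scaling every primitive exponent with ``zeta**2``.

Expansions use 6 primitives per shell throughout.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize


def _sto_norm(n: int, zeta: float) -> float:
    return (2.0 * zeta) ** (n + 0.5) / math.sqrt(math.factorial(2 * n))


def _gauss_norm(l: int, alpha: float) -> float:
    return math.sqrt(2.0 * (2.0 * alpha) ** (l + 1.5) / math.gamma(l + 1.5))


def _gg_overlap(l: int, a: float, b: float) -> float:
    return (2.0 * math.sqrt(a * b) / (a + b)) ** (l + 1.5)


def _sg_overlap(n: int, l: int, zeta: float, alpha: float) -> float:
    ns, ng = _sto_norm(n, zeta), _gauss_norm(l, alpha)
    val, _ = quad(
        lambda r: r ** (n + l + 1) * math.exp(-zeta * r - alpha * r * r), 0.0, np.inf
    )
    return ns * ng * val


def _best_contraction(n: int, l: int, alphas: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal contraction coefficients and resulting overlap for fixed exponents."""
    m = len(alphas)
    M = np.array([[_gg_overlap(l, alphas[i], alphas[j]) for j in range(m)] for i in range(m)])
    v = np.array([_sg_overlap(n, l, 1.0, a) for a in alphas])
    c = np.linalg.solve(M, v)
    s = float(v @ c / math.sqrt(c @ M @ c))
    c = c / math.sqrt(c @ M @ c)
    return c, s


def fit_sto_ng(n: int, l: int, ng: int = 6) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a zeta=1 STO(n,l) with ng Gaussians; returns (alphas, coeffs, overlap)."""

    def neg_overlap(logalpha):
        a = np.exp(logalpha)
        try:
            _, s = _best_contraction(n, l, a)
        except np.linalg.LinAlgError:
            return 0.0
        return -s

    start = np.log(np.geomspace(5e-2 / n, 60.0 / n**2 * 10, ng))
    res = minimize(neg_overlap, start, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-14})
    alphas = np.exp(res.x)
    order = np.argsort(alphas)[::-1]
    alphas = alphas[order]
    coeffs, s = _best_contraction(n, l, alphas)
    return alphas, coeffs, s


# zeta = 1 STO-6G expansions generated with fit_sto_ng / _best_contraction
# (frozen output of the in-repo fit; the comment above each entry records the
# achieved radial overlap with the exact Slater function).
# (n, l) -> (exponents, contraction coefficients of normalized primitives)
STO_NG_TABLES: dict[tuple[int, int], tuple[tuple[float, ...], tuple[float, ...]]] = {
    # overlap 0.999999381
    (1, 0): (
        (2.3103176000e+01, 4.2359419172e+00, 1.1850631675e+00, 4.0710056499e-01, 1.5808879837e-01, 6.5109616945e-02),
        (9.1635253934e-03, 4.9361132208e-02, 1.6853748959e-01, 3.7056248011e-01, 4.1649255629e-01, 1.3033462686e-01),
    ),
    # overlap 0.999999836
    (2, 0): (
        (2.7685338666e+01, 5.0771561907e+00, 1.4267855648e+00, 2.0403370692e-01, 9.2603053729e-02, 4.4161855786e-02),
        (-4.1512337986e-03, -2.0670272529e-02, -5.1503073948e-02, 3.3462657154e-01, 5.6210638313e-01, 1.7129978614e-01),
    ),
    # overlap 0.999999728
    (2, 1): (
        (5.8682822617e+00, 1.5303320742e+00, 5.4756790606e-01, 2.2889382178e-01, 1.0466583699e-01, 4.9482308601e-02),
        (7.9242310873e-03, 5.1440837658e-02, 1.8983935399e-01, 4.0498577670e-01, 4.0123689896e-01, 1.0518630851e-01),
    ),
    # overlap 0.999999813
    (3, 0): (
        (7.5765251700e+00, 1.2643202474e+00, 4.0376951543e-01, 7.9279679593e-02, 4.0216728040e-02, 1.3664212359e-02),
        (-1.8860448103e-03, -3.9798858090e-02, -1.6948920495e-01, 6.9515031116e-01, 4.1616373734e-01, 5.0830731778e-03),
    ),
    # overlap 0.999999960
    (3, 1): (
        (5.0780189967e+00, 1.3407945888e+00, 2.2484306420e-01, 1.1317387694e-01, 6.0763867239e-02, 3.3154123431e-02),
        (-3.3298799627e-03, -1.4194887940e-02, 1.6394051312e-01, 4.4853755435e-01, 3.9087993768e-01, 7.4113218571e-02),
    ),
    # overlap 0.999999856
    (3, 2): (
        (2.4882963037e+00, 7.9814567370e-01, 3.3113165433e-01, 1.5591110727e-01, 7.8777267265e-02, 4.0584847589e-02),
        (7.2838700152e-03, 5.3868433476e-02, 2.0721465093e-01, 4.2662683210e-01, 3.8430897479e-01, 8.9028180783e-02),
    ),
    # overlap 0.999999971
    (4, 0): (
        (3.9672583807e+00, 2.3336752086e+00, 3.8146850484e-01, 1.7926558554e-01, 5.0003263385e-02, 2.7883928234e-02),
        (5.9626376267e-04, 1.0085924248e-03, -7.2306930651e-02, -3.1509980135e-01, 9.0357234698e-01, 3.2889370510e-01),
    ),
    # overlap 0.999999939
    (4, 1): (
        (2.2402499451e+01, 1.0686501535e+00, 3.6989789381e-01, 8.5780268229e-02, 4.7438565284e-02, 2.6745863994e-02),
        (-1.4742621715e-04, -1.1799430417e-02, -6.3001000268e-02, 4.4443942431e-01, 5.2871319068e-01, 9.3227734242e-02),
    ),
}


@lru_cache(maxsize=None)
def sto_ng(n: int, l: int, zeta: float) -> tuple[np.ndarray, np.ndarray]:
    """Primitive exponents and coefficients for an STO(n, l, zeta)."""
    key = (n, l)
    if key not in STO_NG_TABLES:
        raise KeyError(f"no STO-nG table for n={n}, l={l}")
    alphas, coeffs = STO_NG_TABLES[key]
    return np.asarray(alphas) * zeta**2, np.asarray(coeffs).copy()
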