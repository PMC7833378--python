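"""Independent reference implementations used by the test suite.

These deliberately avoid the production code paths: Mathieu characteristic
values and a real cosine/sine-basis diagonalization for the Hermitian case,
arbitrary-precision eigenvalues for small non-Hermitian matrices, and plain
real-line quadrature for the classical action.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.linalg import eigh_tridiagonal
from scipy.special import mathieu_a, mathieu_b

from .model import GasModel

__all__ = [
    "mathieu_levels",
    "cosine_basis_levels",
    "high_precision_eig",
    "real_line_action",
]


def mathieu_levels(alpha: float, q: float, n: int = 6) -> np.ndarray:
    """Lowest eigenvalues of the (1,1) Hamiltonian from Mathieu characteristic values.

    theta = 2x maps the Hamiltonian to the Mathieu equation
    y'' + (a - 2Q cos 2x) y = 0 with a = 4 eps and Q = -4 alpha; the sign of
    Q is absorbed with a_{2r}(-Q)=a_{2r}(Q), a_{2r+1}(-Q)=b_{2r+1}(Q),
    b_{r}(-Q)=b_r(Q)-type relations, leaving the stated order sets.
    """
    Q = 4.0 * alpha
    if q == 0.0:
        vals = [mathieu_a(0, Q)]
        r = 2
        while len(vals) < n:
            vals += [mathieu_b(r, Q), mathieu_a(r, Q)]
            r += 2
    elif q == 0.5:
        vals = []
        r = 1
        while len(vals) < n:
            vals += [mathieu_b(r, Q), mathieu_a(r, Q)]
            r += 2
    else:
        raise ValueError("Mathieu oracle defined at q=0 and q=1/2 only")
    return np.sort(np.array(vals[:n])) / 4.0


def cosine_basis_levels(alpha: float, q: float, n_modes: int = 64) -> np.ndarray:
    """Hermitian (1,1) eigenvalues from real symmetric tridiagonal blocks.

    Basis {1, sqrt2 cos k theta, sqrt2 sin k theta} for q=0 and
    {cos((k+1/2) theta), sin((k+1/2) theta)} for q=1/2; the potential
    -2 alpha cos theta couples neighbouring modes with -alpha (with the
    standard sqrt2 and half-integer edge anomalies).
    """
    if q == 0.0:
        k = np.arange(n_modes, dtype=float)
        diag_c = k**2
        off_c = np.full(n_modes - 1, -alpha)
        off_c[0] = -alpha * math.sqrt(2.0)
        wc = eigh_tridiagonal(diag_c, off_c, eigvals_only=True)
        ks = np.arange(1, n_modes, dtype=float)
        ws = eigh_tridiagonal(ks**2, np.full(n_modes - 2, -alpha), eigvals_only=True)
    elif q == 0.5:
        k = np.arange(n_modes, dtype=float) + 0.5
        diag_c = k**2
        diag_c[0] -= alpha
        wc = eigh_tridiagonal(diag_c, np.full(n_modes - 1, -alpha), eigvals_only=True)
        diag_s = k**2
        diag_s[0] += alpha
        ws = eigh_tridiagonal(diag_s, np.full(n_modes - 1, -alpha), eigvals_only=True)
    else:
        raise ValueError("cosine-basis oracle defined at q=0 and q=1/2 only")
    return np.sort(np.concatenate([wc, ws]))


def high_precision_eig(model: GasModel, cutoff: int, dps: int = 40) -> np.ndarray:
    """Eigenvalues of the Bloch matrix in arbitrary precision (small cutoffs).

    An independent construction of the matrix is used on purpose.
    """
    import mpmath as mp

    if cutoff > 256:
        raise ValueError("high-precision oracle limited to cutoff <= 256")
    v = model.valencies
    n = 2 * cutoff + 1
    with mp.workdps(dps):
        h = mp.zeros(n)
        for i in range(n):
            k = i - cutoff
            h[i, i] = mp.mpf(k + model.q) ** 2
            if i - v.n1 >= 0:
                h[i, i - v.n1] = -mp.mpf(model.alpha) / v.n1
            if i + v.n2 < n:
                h[i, i + v.n2] = -mp.mpf(model.alpha) / v.n2
        evals, _ = mp.eig(h)
    out = np.array([complex(e) for e in evals])
    return out[np.argsort(out.real)]


def high_precision_bandwidth(
    model: GasModel, cutoff: int, dps: int = 50
) -> float:
    """Lowest-band width eps0(1/2) - eps0(0) with the subtraction done in
    arbitrary precision (the width is exponentially small in sqrt(alpha) and
    vanishes in double precision already at moderate alpha)."""
    import mpmath as mp

    with mp.workdps(dps):
        edges = []
        for q in (0.0, 0.5):
            v = model.valencies
            n = 2 * cutoff + 1
            h = mp.zeros(n)
            for i in range(n):
                k = i - cutoff
                h[i, i] = mp.mpf(k + q) ** 2
                if i - v.n1 >= 0:
                    h[i, i - v.n1] = -mp.mpf(model.alpha) / v.n1
                if i + v.n2 < n:
                    h[i, i + v.n2] = -mp.mpf(model.alpha) / v.n2
            evals, _ = mp.eig(h)
            edges.append(min(evals, key=lambda e: mp.re(e)))
        return float(mp.re(edges[1]) - mp.re(edges[0]))


def real_line_action(u: float) -> float:
    """(1,1) classical action 2 * integral of sqrt(2u + 2 cos theta) over the
    allowed interval |theta| < arccos(-u); real adaptive quadrature."""
    if not -1.0 <= u <= 1.0:
        raise ValueError("real-line action defined for u in [-1, 1]")
    if u == -1.0:
        return 0.0
    theta_t = math.acos(max(-1.0, min(1.0, -u)))
    val, err = quad(
        lambda th: math.sqrt(max(0.0, 2.0 * u + 2.0 * math.cos(th))),
        -theta_t,
        theta_t,
        limit=200,
    )
    return 2.0 * val
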