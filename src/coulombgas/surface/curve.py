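"""The spectral curve of the complexified classical mechanics.

For the gas with valencies (n1, n2) the classical energy conservation law in
the variable z = exp(i theta) reads

    p^2 = P(z) / (n1 n2 z^{n2}),   P(z) = n2 z^{n1+n2} + (n1+n2) u z^{n2} + n1.

The n1+n2 roots of P are the (complexified) classical turning points; together
with z = 0 and z = infinity (branch points when n2, resp. n1, is odd) they
define a compact Riemann surface of genus 1 for (1,1), (2,1) and genus 2 for
(3,1), (4,1), (3,2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..model import ValencyPair

__all__ = [
    "SpectralCurve",
    "turning_points",
    "turning_polynomial",
    "singular_energies",
    "distance_to_singular_set",
]


@dataclass(frozen=True)
class SpectralCurve:
    """Branch-point data of the curve F(p, z) = 0 at complex energy ``u``."""

    valencies: ValencyPair
    u: complex
    coefficients: tuple[complex, ...]   # of P(z), highest degree first
    branch_points: tuple[complex, ...]  # roots of P
    zero_is_branch_point: bool          # n2 odd
    infinity_is_branch_point: bool      # n1 odd
    degenerate: bool                    # u (numerically) in the singular set

    @property
    def genus(self) -> int:
        return self.valencies.genus

    def momentum_squared(self, z: np.ndarray | complex) -> np.ndarray | complex:
        """p^2 = P(z)/(n1 n2 z^{n2}) evaluated elementwise."""
        v = self.valencies
        return np.polyval(np.asarray(self.coefficients), z) / (
            v.n1 * v.n2 * np.asarray(z, dtype=complex) ** v.n2
        )


def turning_polynomial(v: ValencyPair, u: complex) -> np.ndarray:
    """Coefficients (highest first) of P(z) = n2 z^{n1+n2} + (n1+n2) u z^{n2} + n1."""
    coeffs = np.zeros(v.total + 1, dtype=complex)
    coeffs[0] = v.n2
    coeffs[v.n1] = v.total * u          # z^{n2} term sits n1 places below z^{n1+n2}
    coeffs[v.total] = v.n1
    return coeffs


def _polish_roots(coeffs: np.ndarray, roots: np.ndarray, iters: int = 3) -> np.ndarray:
    """A few Newton steps on the companion-matrix roots; safe near double roots
    (the step is skipped when P' underflows)."""
    deriv = np.polyder(coeffs)
    z = roots.astype(complex)
    for _ in range(iters):
        pz = np.polyval(coeffs, z)
        dpz = np.polyval(deriv, z)
        mask = np.abs(dpz) > 1e-12
        step = np.zeros_like(z)
        step[mask] = pz[mask] / dpz[mask]
        # damp: never move more than a small fraction of the local root spacing
        z = z - np.clip(np.abs(step), 0, 0.5) * np.exp(1j * np.angle(step))
    return z


def turning_points(v: ValencyPair, u: complex, singular_tol: float = 1e-9) -> SpectralCurve:
    """Roots of the turning polynomial with parity flags and degeneracy check.

    Roots come from companion-matrix eigenvalues polished by Newton iteration.
    ``degenerate`` is set when ``u`` lies within ``singular_tol`` of the
    singular set (equivalently, two turning points coincide).
    """
    coeffs = turning_polynomial(v, u)
    roots = _polish_roots(coeffs, np.roots(coeffs))
    degenerate = distance_to_singular_set(v, u) < singular_tol
    return SpectralCurve(
        valencies=v,
        u=complex(u),
        coefficients=tuple(coeffs),
        branch_points=tuple(roots),
        zero_is_branch_point=(v.n2 % 2 == 1),
        infinity_is_branch_point=(v.n1 % 2 == 1),
        degenerate=degenerate,
    )


def singular_energies(v: ValencyPair) -> np.ndarray:
    """The n1+n2 energies u = -exp(2 pi i m/(n1+n2)) at which the curve is singular.

    They are the termination points of the narrow-band spectral branches.  The
    array is ordered along the rotation orbit that permutes the homology
    cycles: entry ``j`` is the energy at which cycle ``gamma_j`` collapses,
    u_j = -exp(-2 pi i j n2/(n1+n2)); as a set this equals the m-enumeration.
    """
    j = np.arange(v.total)
    return -np.exp(-2j * np.pi * j * v.n2 / v.total)


def distance_to_singular_set(v: ValencyPair, u: complex) -> float:
    return float(np.min(np.abs(u - singular_energies(v))))
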