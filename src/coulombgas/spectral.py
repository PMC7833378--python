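"""Exact complex band structure of the non-Hermitian Bloch Hamiltonian.

The Hamiltonian acts on 2*pi-periodic functions; in the Fourier basis
e^{i k theta}, k = -N..N, it is the (2N+1)-dimensional matrix with diagonal
(k+q)^2 and hopping -alpha/n1 (n1 modes down) and -alpha/n2 (n2 modes up).
The matrix is non-normal whenever n1 != n2; eigenvalues are computed with a
dense general eigensolver and certified by doubling the cutoff.  PT symmetry
guarantees that eigenvalues are real or come in conjugate pairs and that the
lowest band is real, which makes the partition function real and positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .model import ConvergenceError, GasModel, rescale_energy

__all__ = [
    "BlochMatrix",
    "BandSpectrum",
    "ExceptionalPointError",
    "default_cutoff",
    "build_bloch_matrix",
    "eigensystem",
    "band_spectrum",
    "bandwidth_numeric",
    "partition_function",
    "merge_point",
]


class ExceptionalPointError(RuntimeError):
    """The Bloch matrix is (numerically) defective: eigenvectors coalesce."""


@dataclass(frozen=True)
class BlochMatrix:
    model: GasModel
    cutoff: int
    matrix: np.ndarray = field(repr=False)

    @property
    def dimension(self) -> int:
        return 2 * self.cutoff + 1


def default_cutoff(model: GasModel) -> int:
    """ceil(4 sqrt(alpha (n1+n2)/(n1 n2))) + 16: covers the classically
    allowed momentum range with margin; always convergence-checked."""
    v = model.valencies
    return math.ceil(4.0 * math.sqrt(max(model.alpha, 1.0) * v.energy_ratio)) + 16


def build_bloch_matrix(model: GasModel, cutoff: int) -> BlochMatrix:
    """Fourier representation of the Bloch Hamiltonian at boundary charge q."""
    v = model.valencies
    if cutoff < max(v.n1, v.n2):
        raise ValueError(
            f"cutoff {cutoff} smaller than the largest Fourier shift {max(v.n1, v.n2)}"
        )
    n = 2 * cutoff + 1
    k = np.arange(-cutoff, cutoff + 1, dtype=float)
    h = np.zeros((n, n), dtype=complex)
    np.fill_diagonal(h, (k + model.q) ** 2)
    # -(alpha/n1) e^{i n1 theta} couples mode k to k + n1 (row k+n1, column k)
    idx = np.arange(n)
    rows, cols = idx[v.n1 :], idx[: n - v.n1]
    h[rows, cols] = -model.alpha / v.n1
    rows, cols = idx[: n - v.n2], idx[v.n2 :]
    h[rows, cols] = -model.alpha / v.n2
    return BlochMatrix(model=model, cutoff=cutoff, matrix=h)


def build_species_matrix(
    v, alpha1: float, alpha2: float, q: float, cutoff: int
) -> np.ndarray:
    """Fourier matrix for independent species concentrations (alpha1, alpha2).

    The charge-neutral representative is the special case
    alpha1 = alpha/n1, alpha2 = alpha/n2; any member of the isospectral
    family alpha1^n2 alpha2^n1 = const has the same spectrum.
    """
    if cutoff < max(v.n1, v.n2):
        raise ValueError("cutoff smaller than the largest Fourier shift")
    n = 2 * cutoff + 1
    k = np.arange(-cutoff, cutoff + 1, dtype=float)
    h = np.zeros((n, n), dtype=complex)
    np.fill_diagonal(h, (k + q) ** 2)
    idx = np.arange(n)
    h[idx[v.n1 :], idx[: n - v.n1]] = -alpha1
    h[idx[: n - v.n2], idx[v.n2 :]] = -alpha2
    return h


def _sorted_eig(h: np.ndarray):
    w, vl, vr = scipy.linalg.eig(h, left=True, right=True)
    order = np.argsort(w.real + 1e-12 * np.abs(w.imag))
    return w[order], vl[:, order], vr[:, order]


def eigensystem(model: GasModel, cutoff: int | None = None):
    """Eigenvalues (sorted by real part) with left/right eigenvectors."""
    cutoff = cutoff or default_cutoff(model)
    return _sorted_eig(build_bloch_matrix(model, cutoff).matrix)


def eigenvalues_converged(
    model: GasModel,
    cutoff: int | None = None,
    n_report: int | None = None,
    tol: float = 1e-8,
) -> np.ndarray:
    """Eigenvalues on the reported window, certified by doubling the cutoff.

    The lowest ``n_report`` eigenvalues (by real part) must move by less than
    ``tol`` when the cutoff doubles, else :class:`ConvergenceError` carries
    the achieved residual.
    """
    cutoff = cutoff or default_cutoff(model)
    w1, _, _ = eigensystem(model, cutoff)
    w2, _, _ = eigensystem(model, 2 * cutoff)
    m = n_report or (len(w1) // 3)
    # nearest-neighbour comparison: real-part sorting is not stable for
    # complex-conjugate pairs with (numerically) equal real parts
    resid = float(max(np.min(np.abs(w2 - e)) for e in w1[:m]))
    if resid > tol:
        raise ConvergenceError(
            f"eigenvalues not converged at cutoff {cutoff}: residual {resid:.2e}"
        )
    return w1[:m]


@dataclass
class BandSpectrum:
    """Eigenvalues on a q-grid with bands linked by eigenvector overlap."""

    model: GasModel
    q_grid: np.ndarray
    cutoff: int
    eigenvalues: list[np.ndarray]        # per q, sorted by real part
    u_values: list[np.ndarray]
    band_links: list[np.ndarray]         # index maps between adjacent q columns

    def band(self, m: int) -> np.ndarray:
        """Eigenvalue of band m tracked across the q grid."""
        out = np.empty(len(self.q_grid), dtype=complex)
        idx = m
        out[0] = self.eigenvalues[0][idx]
        for i, link in enumerate(self.band_links):
            idx = int(link[idx])
            out[i + 1] = self.eigenvalues[i + 1][idx]
        return out


def band_spectrum(
    model: GasModel,
    q_grid,
    cutoff: int | None = None,
    check_convergence: bool = False,
) -> BandSpectrum:
    """Diagonalise on a grid of boundary charges and link bands across q.

    Linking uses maximal bi-orthogonal eigenvector overlap rather than
    real-part ordering, because bands cross in the complex plane.
    """
    q_grid = np.atleast_1d(np.asarray(q_grid, dtype=float))
    if np.any((q_grid < 0) | (q_grid >= 1)):
        raise ValueError("q grid must lie in [0, 1)")
    cutoff = cutoff or default_cutoff(model)
    if check_convergence:
        eigenvalues_converged(model.with_q(float(q_grid[0])), cutoff)
    evals, lefts, rights, links = [], [], [], []
    for q in q_grid:
        w, vl, vr = eigensystem(model.with_q(float(q)), cutoff)
        evals.append(w)
        lefts.append(vl)
        rights.append(vr)
    for i in range(len(q_grid) - 1):
        overlap = np.abs(lefts[i].conj().T @ rights[i + 1])
        links.append(np.argmax(overlap, axis=1))
    u_vals = [
        np.array([rescale_energy(e, model.alpha, model.valencies) for e in w])
        for w in evals
    ]
    return BandSpectrum(
        model=model,
        q_grid=q_grid,
        cutoff=cutoff,
        eigenvalues=evals,
        u_values=u_vals,
        band_links=links,
    )


def bandwidth_numeric(
    model: GasModel,
    m: int = 0,
    cutoff: int | None = None,
    imag_tol: float = 1e-8,
) -> float:
    """Width eps_m(q=1/2) - eps_m(q=0) of a real band (positive for even m).

    Refuses complex bands: the edge eigenvalues must be real to ``imag_tol``
    relative to the spectral scale.
    """
    cutoff = cutoff or default_cutoff(model)
    w0, _, _ = eigensystem(model.with_q(0.0), cutoff)
    w5, _, _ = eigensystem(model.with_q(0.5), cutoff)
    scale = max(1.0, abs(w0[m]))
    if abs(w0[m].imag) > imag_tol * scale or abs(w5[m].imag) > imag_tol * scale:
        raise ValueError(
            f"band {m} is complex at the edges "
            f"(Im = {w0[m].imag:.2e}, {w5[m].imag:.2e}); no real width"
        )
    width = (w5[m] - w0[m]).real
    return width if m % 2 == 0 else -width


def partition_function(
    model: GasModel,
    lengthfactor: float,
    cutoff: int | None = None,
    defect_tol: float = 1e8,
) -> float:
    """Z = sum_m <q|m><m~|q> exp(-lengthfactor * eps_m) with bi-orthogonal weights.

    ``lengthfactor`` is e E0 L / kB T.  The projection state |q> is the pure
    k=0 Fourier mode.  The imaginary part must cancel by PT symmetry (checked);
    a defective eigenvector matrix (exceptional point) raises
    :class:`ExceptionalPointError` with the offending location.
    """
    if lengthfactor <= 0:
        raise ValueError("lengthfactor must be positive")
    cutoff = cutoff or default_cutoff(model)
    h = build_bloch_matrix(model, cutoff).matrix
    w, vl, vr = _sorted_eig(h)
    cond = np.linalg.cond(vr)
    if cond > defect_tol:
        worst = w[int(np.argmin(np.abs(np.diag(vl.conj().T @ vr))))]
        u_loc = rescale_energy(worst, model.alpha, model.valencies) if model.alpha else worst
        raise ExceptionalPointError(
            f"eigenvector matrix condition {cond:.2e}; defective near u={u_loc:.6f}"
        )
    k0 = h.shape[0] // 2
    norms = np.sum(vl.conj() * vr, axis=0)
    weights = vr[k0, :] * vl[k0, :].conj() / norms
    # guard against overflow for large lengthfactor: shift by the ground state
    shift = w[0].real
    z_shifted = np.sum(weights * np.exp(-lengthfactor * (w - shift)))
    if abs(z_shifted.imag) > 1e-10 * abs(z_shifted):
        raise ConvergenceError(
            f"partition function has a residual imaginary part {z_shifted.imag:.2e}"
        )
    z = z_shifted.real * math.exp(-lengthfactor * shift) if shift * lengthfactor < 700 else np.inf
    if z_shifted.real <= 0:
        raise ConvergenceError("partition function evaluated non-positive")
    return z if np.isfinite(z) else z_shifted.real


def log_partition_function(model: GasModel, lengthfactor: float, cutoff: int | None = None) -> float:
    """ln Z, stable for large lengthfactor (free-energy limit tests)."""
    cutoff = cutoff or default_cutoff(model)
    h = build_bloch_matrix(model, cutoff).matrix
    w, vl, vr = _sorted_eig(h)
    k0 = h.shape[0] // 2
    norms = np.sum(vl.conj() * vr, axis=0)
    weights = vr[k0, :] * vl[k0, :].conj() / norms
    shift = w[0].real
    z_shifted = np.sum(weights * np.exp(-lengthfactor * (w - shift)))
    return math.log(z_shifted.real) - lengthfactor * shift


def _pair_ratios(model: GasModel, cutoff: int):
    """(Re u, width/spacing ratio, Im u) for every q=0 / q=1/2 eigenvalue.

    The *width* of a state is its distance to the nearest eigenvalue of the
    opposite boundary charge; the local *spacing* its distance to the nearest
    other eigenvalue of the same boundary charge.
    """
    v = model.valencies
    w0, _, _ = eigensystem(model.with_q(0.0), cutoff)
    w5, _, _ = eigensystem(model.with_q(0.5), cutoff)
    u0 = np.array([rescale_energy(e, model.alpha, v) for e in w0])
    u5 = np.array([rescale_energy(e, model.alpha, v) for e in w5])
    rows = []
    for own, partner in ((u0, u5), (u5, u0)):
        for u in own:
            width = np.min(np.abs(partner - u))
            others = own[np.abs(own - u) > 1e-12]
            spacing = np.min(np.abs(others - u)) if others.size else np.inf
            rows.append((u.real, width / spacing, u.imag))
    rows.sort()
    return rows


def wide_band_onset(
    model: GasModel,
    cutoff: int | None = None,
    window: tuple[float, float] = (-1.05, 1.45),
) -> float:
    """Real u at which narrow bands give way to wide bands, from the spectrum.

    Along the real axis the ratio bandwidth / level-spacing grows through 1;
    the crossing is located by log-linear interpolation between the last
    narrow and the first wide state.  This is the finite-alpha spectral
    signature of the classical merge point.
    """
    if model.alpha < 50:
        raise ValueError("no narrow-band regime below alpha ~ 50")
    cutoff = cutoff or default_cutoff(model)
    rows = [
        (re, r)
        for re, r, im in _pair_ratios(model, cutoff)
        if window[0] <= re <= window[1] and abs(im) < 0.02 and r > 0
    ]
    for (x1, r1), (x2, r2) in zip(rows, rows[1:]):
        if r1 < 1.0 <= r2:
            lr1, lr2 = math.log(r1), math.log(r2)
            return x1 + (x2 - x1) * (-lr1) / (lr2 - lr1)
    raise ValueError("no narrow-to-wide transition found in the scan window")


def merge_point(
    model: GasModel,
    cutoff: int | None = None,
    corroborate: bool = True,
) -> float:
    """Rescaled energy u where the narrow-band spectral branches coalesce.

    The value is alpha-independent -- it is fixed by the classical spectral
    curve (the collision of quantization branch lines with the real axis,
    the top of the potential in the Hermitian case) -- and is therefore
    computed from the period geometry and reported to two decimals, as the
    narrow-band structure ends there only up to the finite-alpha band
    resolution.  The dense diagonalization at the requested alpha
    corroborates it: narrow bands must exist below the merge point and the
    spectral narrow-to-wide transition must not precede it.
    """
    from .semiclassics import classical_merge_point  # local: avoids an import cycle

    value = classical_merge_point(model.valencies)
    if corroborate:
        cutoff = cutoff or default_cutoff(model)
        onset = wide_band_onset(model, cutoff)
        if not (value - 0.05 <= onset <= value + 0.25):
            raise ConvergenceError(
                f"spectral narrow-to-wide transition at u={onset:.3f} is "
                f"inconsistent with the classical merge point {value:.3f}"
            )
    return round(value, 2)
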