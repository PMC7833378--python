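"""Period integrals of the action 1-form by numerical contour integration.

A homology cycle is represented by the ordered pair of turning points it
encircles together with a smooth connecting path (the branch cut it is a
tube around).  The period

    S = clockwise-oriented integral of  p(z) dz/(i z)

is evaluated either as twice the line integral of ``p dz/(iz)`` along the cut
(the square root changes sign across the cut, the end caps contribute nothing
because ``p`` vanishes like a square root at the turning points) or by the
trapezoidal rule on a confocal ellipse around the pair, which converges
geometrically and can be differentiated under the integral with respect to
the energy ``u``.

Cycles are continued in ``u`` by tracking the turning-point pair and bending
the connecting path around obstructions (the other turning points and the
origin); the square-root branch and the overall sign are propagated by
continuity, with the first-order perturbative prediction ``S + S'(u) du`` as
the matching criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..model import ValencyPair
from .curve import singular_energies, turning_polynomial

__all__ = [
    "Bump",
    "CyclePath",
    "PinchError",
    "QuadratureError",
    "anchor_cycle",
    "continue_cycle",
    "line_period",
    "ellipse_periods",
    "harmonic_slope",
]


class PinchError(RuntimeError):
    """The contour is pinched between branch points (u too close to the
    singular set); carries the offending distance as ``args[1]``."""


class QuadratureError(RuntimeError):
    """A period integral failed to reach the requested tolerance."""


# --------------------------------------------------------------------------
# path representation: straight segment plus analytic Gaussian bumps,
# endpoint-corrected so the path always terminates exactly at the pair
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Bump:
    t0: float
    amp: complex
    sigma: float


@dataclass(frozen=True)
class CyclePath:
    """A tracked homology cycle at energy ``u``: turning-point pair, connecting
    path, current period value and its u-derivative."""

    v: ValencyPair
    u: complex
    za: complex
    zb: complex
    bumps: tuple[Bump, ...]
    S: complex
    dS: complex
    label: str = ""

    def path(self, t: np.ndarray) -> np.ndarray:
        return _path_eval(self.za, self.zb, self.bumps, np.asarray(t, dtype=float))

    def path_deriv(self, t: np.ndarray) -> np.ndarray:
        return _path_deriv(self.za, self.zb, self.bumps, np.asarray(t, dtype=float))

    def path_full(self, t: np.ndarray):
        """(z, z - za, z - zb) with the endpoint differences evaluated in a
        cancellation-free form (needed very close to a collapsing pair)."""
        t = np.asarray(t, dtype=float)
        corr = np.zeros_like(t, dtype=complex)
        for b in self.bumps:
            g = np.exp(-(((t - b.t0) / b.sigma) ** 2))
            g0 = math.exp(-((b.t0 / b.sigma) ** 2))
            g1 = math.exp(-(((1.0 - b.t0) / b.sigma) ** 2))
            corr = corr + b.amp * (g - (1.0 - t) * g0 - t * g1)
        span = self.zb - self.za
        dza = span * t + corr
        dzb = span * (t - 1.0) + corr
        return self.za + dza, dza, dzb


def _path_eval(za, zb, bumps, t):
    z = za + (zb - za) * t
    for b in bumps:
        g = np.exp(-(((t - b.t0) / b.sigma) ** 2))
        g0 = math.exp(-((b.t0 / b.sigma) ** 2))
        g1 = math.exp(-(((1.0 - b.t0) / b.sigma) ** 2))
        z = z + b.amp * (g - (1.0 - t) * g0 - t * g1)
    return z


def _path_deriv(za, zb, bumps, t):
    dz = np.full_like(np.asarray(t, dtype=complex), zb - za)
    for b in bumps:
        g = np.exp(-(((t - b.t0) / b.sigma) ** 2))
        dg = g * (-2.0 * (t - b.t0) / b.sigma**2)
        g0 = math.exp(-((b.t0 / b.sigma) ** 2))
        g1 = math.exp(-(((1.0 - b.t0) / b.sigma) ** 2))
        dz = dz + b.amp * (dg + g0 - g1)
    return dz


# --------------------------------------------------------------------------
# square root with continuous branch along a sample sequence
# --------------------------------------------------------------------------


def _tracked_sqrt(w: np.ndarray) -> np.ndarray:
    """sqrt(w) with the branch tracked continuously along the sample order."""
    phase = np.unwrap(np.angle(w))
    return np.sqrt(np.abs(w)) * np.exp(0.5j * phase)


def _momentum_sq(v: ValencyPair, u: complex, z: np.ndarray) -> np.ndarray:
    coeffs = turning_polynomial(v, u)
    return np.polyval(coeffs, z) / (v.n1 * v.n2 * z**v.n2)


def _momentum_sq_product(
    v: ValencyPair,
    u: complex,
    z: np.ndarray,
    dza: np.ndarray,
    dzb: np.ndarray,
    za: complex,
    zb: complex,
) -> np.ndarray:
    """p^2 in product form over the turning points.

    ``dza = z - za`` and ``dzb = z - zb`` are supplied by the caller in a
    cancellation-free form, which keeps the evaluation accurate arbitrarily
    close to a collapsing pair; P(z) = n2 * prod_j (z - z_j).
    """
    coeffs = turning_polynomial(v, u)
    roots = _polish(coeffs, np.roots(coeffs))
    ia = int(np.argmin(np.abs(roots - za)))
    rest = np.delete(roots, ia)
    ib = int(np.argmin(np.abs(rest - zb)))
    others = np.delete(rest, ib)
    w = np.full_like(z, v.n2 / (v.n1 * v.n2), dtype=complex) / z**v.n2
    w = w * dza * dzb
    for r in others:
        w = w * (z - r)
    return w


def _polish(coeffs: np.ndarray, roots: np.ndarray) -> np.ndarray:
    deriv = np.polyder(coeffs)
    z = roots.astype(complex)
    for _ in range(2):
        dp = np.polyval(deriv, z)
        ok = np.abs(dp) > 1e-12
        z[ok] = z[ok] - np.polyval(coeffs, z[ok]) / dp[ok]
    return z


# --------------------------------------------------------------------------
# line-integral evaluation (orders 0 and 1)
# --------------------------------------------------------------------------

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(m: int) -> tuple[np.ndarray, np.ndarray]:
    if m not in _GL_CACHE:
        from scipy.special import roots_legendre  # O(m), unlike the dense
        # companion-matrix eigendecomposition route

        x, w = roots_legendre(m)
        # map to s in [0, pi]
        _GL_CACHE[m] = (0.5 * np.pi * (x + 1.0), 0.5 * np.pi * w)
    return _GL_CACHE[m]


def line_period(
    cyc: CyclePath,
    order: int = 0,
    rtol: float = 1e-11,
    max_nodes: int = 8192,
) -> complex:
    """2 * integral of the (u-differentiated) action form along the cut.

    ``order=0`` gives the period of p dz/(iz); ``order=1`` the period of its
    u-derivative, nu/(2p) dz/(iz) with nu=(n1+n2)/(n1 n2).  Higher orders have
    non-integrable endpoint behaviour on the cut and are served by
    :func:`ellipse_periods`.  Sign is that induced by the branch tracked from
    the za endpoint; callers fix the global sign by continuity.
    """
    if order not in (0, 1):
        raise ValueError("line_period supports orders 0 and 1 only")
    v = cyc.v
    nu = v.energy_ratio
    prev = None
    best_change = np.inf
    m = 128
    while m <= max_nodes:
        s, wts = _gl_nodes(m)
        t = 0.5 * (1.0 - np.cos(s))
        dt_ds = 0.5 * np.sin(s)
        z, dza, dzb = cyc.path_full(t)
        dz = cyc.path_deriv(t)
        w = _momentum_sq_product(v, cyc.u, z, dza, dzb, cyc.za, cyc.zb)
        p = _tracked_sqrt(w)
        if order == 0:
            integrand = p * dz / (1j * z)
        else:
            integrand = (nu / (2.0 * p)) * dz / (1j * z)
        val = 2.0 * np.sum(wts * integrand * dt_ds)
        if prev is not None:
            change = abs(val - prev)
            best_change = min(best_change, change)
            if change <= rtol * max(1.0, abs(val)):
                return val
        prev = val
        m *= 2
    # round-off at the turning points caps the attainable accuracy; accept a
    # soft floor two decades above the request, otherwise fail loudly
    if best_change <= 100.0 * rtol * max(1.0, abs(val)):
        return val
    raise QuadratureError(
        f"line period did not converge below rtol={rtol} with {max_nodes} nodes "
        f"(best change {best_change:.2e})"
    )


# --------------------------------------------------------------------------
# confocal-ellipse evaluation (orders 0..3, differentiated under the integral)
# --------------------------------------------------------------------------

# d^k p / du^k on the curve: p' = nu/(2p), p'' = -nu^2/(4 p^3), p''' = 3 nu^3/(8 p^5)
_DERIV_FACTORS = {
    0: lambda p, nu: p,
    1: lambda p, nu: nu / (2.0 * p),
    2: lambda p, nu: -(nu**2) / (4.0 * p**3),
    3: lambda p, nu: 3.0 * nu**3 / (8.0 * p**5),
}


def ellipse_periods(
    cyc: CyclePath,
    orders: tuple[int, ...] = (0, 1, 2),
    rtol: float = 1e-11,
    max_nodes: int = 65536,
    margin: float = 0.8,
) -> dict[int, complex]:
    """Periods of the action form and its u-derivatives on a confocal ellipse.

    The ellipse has foci at the turning-point pair; its elliptic radius is
    chosen between the cut (which must stay inside) and the nearest
    obstruction (other turning points and the origin, which must stay
    outside).  Raises :class:`PinchError` when no such ellipse exists, e.g.
    when a third branch point sits on the cut's doorstep.
    """
    v = cyc.v
    nu = v.energy_ratio
    requested = tuple(orders)
    # order 0 is always evaluated: the recovered period fixes the sign of the
    # sqrt branch, which every derivative inherits
    orders = tuple(sorted(set(requested) | {0}))
    c = 0.5 * (cyc.za + cyc.zb)
    delta = 0.5 * (cyc.zb - cyc.za)
    if abs(delta) == 0:
        raise PinchError("turning-point pair is degenerate", 0.0)

    def elliptic_radius(pts: np.ndarray) -> np.ndarray:
        w = (pts - c) / delta
        return np.abs(np.imag(np.arccos(w.astype(complex))))

    coeffs = turning_polynomial(v, cyc.u)
    roots = np.roots(coeffs)
    others = [r for r in roots if min(abs(r - cyc.za), abs(r - cyc.zb)) > 1e-9]
    obstructions = np.array(others + [0.0], dtype=complex)
    mu_obs = float(np.min(elliptic_radius(obstructions))) if obstructions.size else np.inf

    t = np.linspace(0.0, 1.0, 257)
    mu_path = float(np.max(elliptic_radius(cyc.path(t))))

    if not mu_obs * margin > mu_path + 1e-12:
        raise PinchError(
            "no confocal ellipse separates the cut from obstructions "
            f"(cut radius {mu_path:.3e}, obstruction radius {mu_obs:.3e})",
            mu_obs,
        )
    mu = 0.5 * (mu_path + mu_obs * margin) if mu_path > 0 else 0.5 * mu_obs * margin

    prev: dict[int, complex] | None = None
    best: dict[int, complex] | None = None
    best_change = np.inf
    m = 256
    while m <= max_nodes:
        theta = 2.0 * np.pi * np.arange(m) / m
        half = 0.5 * (theta - 1j * mu)
        zt = c + delta * np.cos(theta - 1j * mu)
        dz = -delta * np.sin(theta - 1j * mu)
        # z - za = 2 delta cos^2(half), z - zb = -2 delta sin^2(half): exact,
        # no cancellation even for nearly collapsed pairs
        dza = 2.0 * delta * np.cos(half) ** 2
        dzb = -2.0 * delta * np.sin(half) ** 2
        w = _momentum_sq_product(v, cyc.u, zt, dza, dzb, cyc.za, cyc.zb)
        phase = np.unwrap(np.angle(w))
        # consistency: w must wind by exactly 4 pi around a two-branch-point tube
        wrap = phase[-1] - phase[0] + (np.angle(w[0]) - np.angle(w[-1]))
        p = np.sqrt(np.abs(w)) * np.exp(0.5j * phase)
        vals = {
            k: (2.0 * np.pi / m) * np.sum(_DERIV_FACTORS[k](p, nu) * dz / (1j * zt))
            for k in orders
        }
        if m >= 1024 and abs(abs(wrap) - 4.0 * np.pi) > 1.0:
            raise QuadratureError(
                f"contour encloses the wrong branch structure (winding {wrap:.3f})"
            )
        if prev is not None:
            change = max(
                abs(vals[k] - prev[k]) / max(1.0, abs(vals[k])) for k in orders
            )
            if change < best_change:
                best_change, best = change, vals
            if change <= rtol:
                break
        prev = vals
        m *= 2
    else:
        # round-off on near-degenerate pairs caps the attainable accuracy for
        # the high-order integrands; accept a soft floor, else fail loudly
        if best is None or best_change > 1e4 * rtol:
            raise QuadratureError(
                f"ellipse period did not converge below rtol={rtol} "
                f"(best relative change {best_change:.2e})"
            )
        vals = best
    # orient/sign-match order 0 against the tracked value, then apply the
    # same flip to every derivative
    if abs(vals[0] - cyc.S) > abs(-vals[0] - cyc.S):
        vals = {k: -val for k, val in vals.items()}
    return {k: vals[k] for k in requested}


# --------------------------------------------------------------------------
# anchoring and continuation
# --------------------------------------------------------------------------


def harmonic_slope(v: ValencyPair) -> float:
    """dS0/du at the potential bottom u=-1: pi sqrt(2(n1+n2))/(n1 n2)."""
    return math.pi * math.sqrt(2.0 * v.total) / (v.n1 * v.n2)


def _roots_at(v: ValencyPair, u: complex) -> np.ndarray:
    return np.roots(turning_polynomial(v, u))


def _closest_pair(roots: np.ndarray) -> tuple[complex, complex]:
    n = len(roots)
    best, pair = np.inf, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            d = abs(roots[i] - roots[j])
            if d < best:
                best, pair = d, (i, j)
    return complex(roots[pair[0]]), complex(roots[pair[1]])


def anchor_cycle(v: ValencyPair, j: int, delta: float = 0.02) -> CyclePath:
    """Create cycle gamma_j just inside its collapse energy u_j = -e^{-2 pi i j n2/N}.

    The two colliding turning points are connected by a straight cut; the sign
    of the period is fixed by the harmonic expansion
    S_j(u) ~ harmonic_slope * e^{i pi j n2 / N} * (u - u_j), which follows from
    the rotation symmetry relating gamma_j to gamma_0 and from S_0 growing
    with positive slope out of the potential bottom.
    """
    using = singular_energies(v)
    j = int(j) % v.total
    u_s = complex(using[j])
    u_a = (1.0 - delta) * u_s
    za, zb = _closest_pair(_roots_at(v, u_a))
    # Slope of S_j out of its collapse energy.  Cycles come in conjugate
    # pairs gamma_j / gamma_{N-j} (their collapse energies are conjugate),
    # so the slope phase for j > N/2 is the conjugate of its partner's;
    # for j < N/2 the rotation symmetry gives exp(i pi j n2 / N) relative
    # to the real positive slope of gamma_0.
    N = v.total
    if 2 * j <= N:
        slope_phase = np.exp(1j * np.pi * j * v.n2 / N)
        if 2 * j == N:  # self-conjugate cycle collapsing at u=+1
            slope_phase = -1j if v.n2 % 2 else 1.0
    else:
        slope_phase = np.exp(-1j * np.pi * (N - j) * v.n2 / N)
    expected = harmonic_slope(v) * slope_phase * (u_a - u_s)
    cyc = CyclePath(v=v, u=u_a, za=za, zb=zb, bumps=(), S=expected, dS=0.0, label=f"g{j}")
    s_raw = line_period(cyc)
    if abs(s_raw - expected) > abs(-s_raw - expected):
        s_raw = -s_raw
    ds = line_period(replace(cyc, S=s_raw), order=1, rtol=1e-8, max_nodes=4096)
    # derivative sign must follow the period's branch: check finite-difference
    if abs(ds - expected / (u_a - u_s)) > abs(-ds - expected / (u_a - u_s)):
        ds = -ds
    return replace(cyc, S=s_raw, dS=ds)


def _repel(za, zb, bumps, obstructions, pinch_tol):
    """Bend the cut away from obstructions; returns updated bumps."""
    bumps = list(bumps)
    for _ in range(6):
        t = np.linspace(0.0, 1.0, 201)
        z = _path_eval(za, zb, tuple(bumps), t)
        moved = False
        for x in obstructions:
            d_end = min(abs(x - za), abs(x - zb))
            if d_end < pinch_tol:
                raise PinchError(
                    f"obstruction at {x:.4f} within {d_end:.2e} of a turning point",
                    d_end,
                )
            dist = np.abs(z - x)
            i_min = int(np.argmin(dist))
            d = float(dist[i_min])
            clearance = min(0.3 * d_end, 0.45 * abs(zb - za))
            if d < clearance and 0 < i_min < len(t) - 1:
                direction = (z[i_min] - x) / d if d > 1e-14 else 1.0
                amp = direction * (clearance - d) * 1.3
                t0 = float(t[i_min])
                for k, b in enumerate(bumps):
                    if abs(b.t0 - t0) < 0.12:
                        bumps[k] = Bump(b.t0, b.amp + amp, b.sigma)
                        break
                else:
                    bumps.append(Bump(t0, amp, 0.16))
                moved = True
        if not moved:
            return tuple(bumps)
    return tuple(bumps)


def _match_root(roots: np.ndarray, prediction: complex, taken: complex | None) -> complex:
    order = np.argsort(np.abs(roots - prediction))
    for idx in order:
        r = complex(roots[idx])
        if taken is None or abs(r - taken) > 1e-12:
            return r
    raise RuntimeError("root matching failed")


def continue_cycle(
    cyc: CyclePath,
    u_target: complex,
    max_step: float = 0.06,
    pinch_tol: float = 4e-3,
    rtol: float = 1e-10,
) -> CyclePath:
    """Analytically continue a cycle along the straight segment to ``u_target``.

    The turning points are tracked with first-order prediction through the
    implicit function theorem, the cut is bent around approaching
    obstructions, and the period sign follows the perturbative prediction
    S + S' du.  Raises :class:`PinchError` when the cycle would be pinched.
    """
    u_target = complex(u_target)
    v = cyc.v
    rejections = 0
    max_step_orig = max_step
    steps = 0
    while abs(u_target - cyc.u) > 0:
        steps += 1
        if steps > 3000:
            raise QuadratureError(
                f"cycle continuation to {u_target:.5f} exceeded the step budget "
                f"(stalled near u={cyc.u:.5f}; likely pinched)"
            )
        span = u_target - cyc.u
        h = min(max_step, abs(span))
        while True:
            u_new = cyc.u + h * span / abs(span)
            roots = _roots_at(v, u_new)
            # implicit-derivative prediction dz/du = -N z^{n2} / P'(z)
            dcoef = np.polyder(turning_polynomial(v, cyc.u))
            preds = []
            for z0 in (cyc.za, cyc.zb):
                dpz = np.polyval(dcoef, z0)
                dz_du = -v.total * z0**v.n2 / dpz if abs(dpz) > 1e-13 else 0.0
                preds.append(z0 + dz_du * (u_new - cyc.u))
            za_new = _match_root(roots, preds[0], None)
            zb_new = _match_root(roots, preds[1], za_new)
            sep = abs(zb_new - za_new)
            motion = max(abs(za_new - cyc.za), abs(zb_new - cyc.zb))
            # a collapsing pair (u at its own singular energy) is regular --
            # the period goes to zero smoothly; only third branch points near
            # the cut pinch the contour, which _repel detects
            if motion < 0.35 * max(sep, 1e-12) or h < 1e-9:
                break
            h *= 0.5
        # rotate the cut's bumps with the segment but never rescale them:
        # shrinking amplitudes with a collapsing pair would drag the path
        # across obstructions and silently change the homology class
        scale = (zb_new - za_new) / (cyc.zb - cyc.za)
        phase = scale / abs(scale) if abs(scale) > 0 else 1.0
        bumps = tuple(Bump(b.t0, b.amp * phase, b.sigma) for b in cyc.bumps)
        others = [
            r for r in roots if min(abs(r - za_new), abs(r - zb_new)) > 1e-9
        ]
        bumps = _repel(za_new, zb_new, bumps, others + [0.0], pinch_tol)
        trial = CyclePath(
            v=v, u=u_new, za=za_new, zb=zb_new, bumps=bumps,
            S=cyc.S, dS=cyc.dS, label=cyc.label,
        )
        s_pred = cyc.S + cyc.dS * (u_new - cyc.u)
        s_raw = line_period(trial, rtol=rtol, max_nodes=16384)
        if abs(s_raw - s_pred) > abs(-s_raw - s_pred):
            s_raw = -s_raw
        ds_pred = cyc.dS if cyc.dS != 0 else (s_raw - cyc.S) / (u_new - cyc.u)
        try:
            ds_raw = line_period(trial, order=1, rtol=1e-6, max_nodes=4096)
            if abs(ds_raw - ds_pred) > abs(-ds_raw - ds_pred):
                ds_raw = -ds_raw
        except QuadratureError:
            # the derivative only steers prediction; a secant is good enough
            ds_raw = (s_raw - cyc.S) / (u_new - cyc.u)
        # reject the step when the prediction badly misses (possible branch slip)
        if abs(s_raw - s_pred) > 0.25 * (abs(s_raw) + abs(cyc.S)) + 0.05 and h > 1e-6:
            rejections += 1
            if rejections > 12:
                raise QuadratureError(
                    f"cycle continuation to {u_target:.5f} keeps losing its "
                    f"homology class near u={u_new:.5f} "
                    f"(period {s_raw:.5f} vs predicted {s_pred:.5f})"
                )
            max_step = h * 0.5
            continue
        cyc = replace(trial, S=s_raw, dS=ds_raw)
        # recover the step size after accepted steps so a single rejection
        # does not condemn the rest of the walk to a crawl
        max_step = min(max_step * 1.4, max_step_orig)
    return cyc
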