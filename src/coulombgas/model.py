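"""Problem definition, unit conversions and normalisation conventions.

The physical system is a quasi-1D gas of cations (valency ``n1``) and anions
(valency ``-n2``) confined to a narrow water-filled channel.  Its grand
canonical statistical mechanics maps onto an effective quantum problem on the
circle with Hamiltonian

    H = (-i d/dtheta - q)^2 - (alpha/n1) e^{i n1 theta} - (alpha/n2) e^{-i n2 theta}

where ``q`` is the fractional boundary charge (Bloch quasi-momentum) and
``alpha`` the dimensionless salt concentration of the charge-neutral
representative.  ``alpha**-0.5`` plays the role of the effective Planck
constant.  All modules share the sign convention fixed here: the potential is
``V(theta) = -(1/n1) e^{i n1 theta} - (1/n2) e^{-i n2 theta}`` so that the
monovalent case reduces to ``-2 cos(theta)``, the classical minimum sits at
``theta = 0`` and the rescaled energy of that minimum is exactly ``u = -1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ValencyPair",
    "GasModel",
    "ChannelGeometry",
    "EnergyScales",
    "SEMICLASSICAL_PAIRS",
    "energy_scales",
    "neutral_alpha",
    "rescale_energy",
    "energy_from_u",
    "ConvergenceError",
]

# Gaussian (CGS) constants; lengths in cm internally, Angstrom at the API.
_E_ESU = 4.80320471e-10       # elementary charge [esu]
_KB_ERG = 1.380649e-16        # Boltzmann constant [erg/K]
_CM_PER_ANGSTROM = 1e-8

#: Valency pairs with full semiclassical support (genus-1 and genus-2 curves).
SEMICLASSICAL_PAIRS = frozenset({(1, 1), (2, 1), (3, 1), (4, 1), (3, 2)})


class ConvergenceError(RuntimeError):
    """An iterative numerical procedure failed to reach its tolerance."""


@dataclass(frozen=True)
class ValencyPair:
    """Cation valency ``n1`` and anion valency magnitude ``n2``.

    Requires ``n1 >= n2 >= 1`` and ``gcd(n1, n2) == 1``; a pair with a common
    divisor ``n`` describes the same gas after the substitution
    ``theta -> n*theta`` and is rejected rather than silently reduced.
    """

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (isinstance(self.n1, int) and isinstance(self.n2, int)):
            raise TypeError("valencies must be integers")
        if not self.n1 >= self.n2 >= 1:
            raise ValueError(f"require n1 >= n2 >= 1, got ({self.n1}, {self.n2})")
        if math.gcd(self.n1, self.n2) != 1:
            raise ValueError(
                f"({self.n1}, {self.n2}) share a common factor; rescale theta instead"
            )

    @property
    def total(self) -> int:
        """n1 + n2 (number of finite turning points of the spectral curve)."""
        return self.n1 + self.n2

    @property
    def energy_ratio(self) -> float:
        """(n1 + n2)/(n1*n2): conversion factor between u and eps/alpha."""
        return self.total / (self.n1 * self.n2)

    @property
    def genus(self) -> int:
        """Genus of the compactified spectral curve (1 or 2 for supported pairs)."""
        if (self.n1, self.n2) in {(1, 1), (2, 1)}:
            return 1
        if (self.n1, self.n2) in {(3, 1), (4, 1), (3, 2)}:
            return 2
        raise ValueError(f"genus only tabulated for {sorted(SEMICLASSICAL_PAIRS)}")

    @property
    def semiclassical(self) -> bool:
        return (self.n1, self.n2) in SEMICLASSICAL_PAIRS

    def as_tuple(self) -> tuple[int, int]:
        return (self.n1, self.n2)


@dataclass(frozen=True)
class GasModel:
    """A charge-neutral 1D Coulomb gas at concentration ``alpha``, boundary charge ``q``.

    ``q`` enters the spectrum only modulo 1 and is stored reduced to [0, 1).
    """

    valencies: ValencyPair
    alpha: float
    q: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        object.__setattr__(self, "q", self.q % 1.0)

    @classmethod
    def from_species(
        cls, valencies: ValencyPair, alpha1: float, alpha2: float, q: float = 0.0
    ) -> "GasModel":
        """Build the isospectral charge-neutral representative of a general
        (``alpha1``, ``alpha2``) gas."""
        return cls(valencies, neutral_alpha(alpha1, alpha2, valencies), q)

    @property
    def hbar_eff(self) -> float:
        """Effective Planck constant alpha**-1/2 of the mapped quantum problem."""
        if self.alpha == 0:
            raise ZeroDivisionError("free gas (alpha=0) has no semiclassical limit")
        return self.alpha ** -0.5

    def with_q(self, q: float) -> "GasModel":
        return GasModel(self.valencies, self.alpha, q)


@dataclass(frozen=True)
class ChannelGeometry:
    """Channel radius/length in Angstrom, dielectric constants, temperature in K.

    ``kappa2`` defaults to 2 (lipid); lipids and silicon oxide span roughly 2-4.
    """

    a: float
    L: float
    kappa1: float = 80.0
    kappa2: float = 2.0
    T: float = 300.0

    def __post_init__(self) -> None:
        if not (self.kappa1 > self.kappa2 > 0):
            raise ValueError("require kappa1 > kappa2 > 0")
        if min(self.a, self.L, self.T) <= 0:
            raise ValueError("a, L, T must all be positive")


@dataclass(frozen=True)
class EnergyScales:
    """Derived electrostatic scales of a channel.

    E0 is the electric field of a unit charge in the channel [statvolt/cm],
    lambdaB the Bjerrum length [Angstrom], xi the field-escape length
    [Angstrom], U0_bare the bare single-ion self-energy barrier [kBT].
    """

    E0: float
    lambdaB: float
    xi: float
    U0_bare: float
    geometry: ChannelGeometry = field(repr=False)

    @property
    def length_factor(self) -> float:
        """e*E0*L/(kB*T) = 2*lambdaB*L/a**2: converts eigenvalues to kBT units."""
        g = self.geometry
        return 2.0 * self.lambdaB * g.L / g.a**2


def bjerrum_length(kappa1: float = 80.0, T: float = 300.0) -> float:
    """Bjerrum length e^2/(kappa1 kB T) in Angstrom (Gaussian units)."""
    lam_cm = _E_ESU**2 / (kappa1 * _KB_ERG * T)
    return lam_cm / _CM_PER_ANGSTROM


def energy_scales(geom: ChannelGeometry) -> EnergyScales:
    """Compute E0, lambdaB, the implicit field-escape length xi and the bare
    Parsegian barrier for a channel geometry.

    xi solves xi^2 = a^2 * kappa1/(2 kappa2) * ln(2 xi / a) by damped fixed
    point iteration, converged to 1e-10 relative; failure raises
    :class:`ConvergenceError` rather than returning a stale value.
    """
    a_cm = geom.a * _CM_PER_ANGSTROM
    E0 = 2.0 * _E_ESU / (geom.kappa1 * a_cm**2)
    lamB = bjerrum_length(geom.kappa1, geom.T)
    U0_bare = lamB * geom.L / (2.0 * geom.a**2)

    # xi in units of a: x^2 = c * ln(2x), c = kappa1/(2 kappa2)
    c = geom.kappa1 / (2.0 * geom.kappa2)
    x = max(math.sqrt(c * math.log(2.0)) if c * math.log(2.0) > 1 else 1.5, 1.0)
    for _ in range(500):
        arg = 2.0 * x
        if arg <= 1.0:
            raise ConvergenceError("xi iteration left its domain (2*xi <= a)")
        x_new = math.sqrt(c * math.log(arg))
        if abs(x_new - x) <= 1e-12 * x:
            x = x_new
            break
        x = 0.5 * (x + x_new)
    else:
        raise ConvergenceError("xi fixed-point iteration did not converge")
    # certify the implicit equation itself
    if abs(x * x - c * math.log(2 * x)) > 1e-10 * max(x * x, 1.0):
        raise ConvergenceError("xi iterate does not satisfy its defining equation")
    return EnergyScales(E0=E0, lambdaB=lamB, xi=x * geom.a, U0_bare=U0_bare, geometry=geom)


def neutral_alpha(alpha1: float, alpha2: float, v: ValencyPair) -> float:
    """Concentration ``alpha`` of the isospectral charge-neutral representative.

    The combination alpha1^n2 * alpha2^n1 is invariant under the coordinate
    shifts that connect isospectral Hamiltonians; matching it against the
    neutral parametrisation alpha1 = alpha/n1, alpha2 = alpha/n2 gives

        alpha = (alpha1^n2 * alpha2^n1 * n1^n2 * n2^n1)^(1/(n1+n2)).
    """
    if alpha1 <= 0 or alpha2 <= 0:
        raise ValueError("species concentrations must be positive")
    n1, n2 = v.n1, v.n2
    log_alpha = (
        n2 * math.log(alpha1)
        + n1 * math.log(alpha2)
        + n2 * math.log(n1)
        + n1 * math.log(n2)
    ) / (n1 + n2)
    return math.exp(log_alpha)


def rescale_energy(eps: complex, alpha: float, v: ValencyPair) -> complex:
    """Map a raw eigenvalue eps to the rescaled energy u = n1 n2/(n1+n2) * eps/alpha.

    The rescaling pins the classical potential minimum at u = -1 for every
    valency pair and concentration.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive to rescale energies")
    return eps / (alpha * v.energy_ratio)


def energy_from_u(u: complex, alpha: float, v: ValencyPair) -> complex:
    """Inverse of :func:`rescale_energy`: eps = u * alpha * (n1+n2)/(n1 n2)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return u * alpha * v.energy_ratio


def from_config(mapping: dict) -> tuple[GasModel, ChannelGeometry | None]:
    """Build a model (and optional geometry) from a plain key-value mapping.

    Recognised keys: ``n1``, ``n2``, either ``alpha`` or the species pair
    ``alpha1``/``alpha2`` (reduced to the neutral representative), optional
    ``q`` and an optional ``geometry`` block with the
    :class:`ChannelGeometry` fields.
    """
    data = dict(mapping)
    try:
        v = ValencyPair(int(data.pop("n1")), int(data.pop("n2")))
    except KeyError as exc:
        raise ValueError(f"config missing required key: {exc}") from exc
    q = float(data.pop("q", 0.0))
    if "alpha" in data:
        model = GasModel(v, float(data.pop("alpha")), q)
        data.pop("alpha1", None), data.pop("alpha2", None)
    elif "alpha1" in data and "alpha2" in data:
        model = GasModel.from_species(
            v, float(data.pop("alpha1")), float(data.pop("alpha2")), q
        )
    else:
        raise ValueError("config must give alpha, or alpha1 and alpha2")
    geom = None
    if "geometry" in data:
        geom = ChannelGeometry(**{k: float(x) for k, x in data.pop("geometry").items()})
    if data:
        raise ValueError(f"unknown config keys: {sorted(data)}")
    return model, geom
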