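"""Pair potentials for short-range-attractive colloids.

Two families are supported:

* a generalized Lennard-Jones (Mie) potential with steep exponents
  (n, m) = (30, 20) by default, giving an attractive well of width
  ~0.08 in units of the small-particle radius, and
* a "continuous square-well" (CSW): a smooth sigmoid approximation of a
  square well with very steep walls.

Both are truncated at ``r_c`` and shifted so the energy vanishes at the
cutoff.  The module also computes the derived geometry (minimum,
inflection point — used as the bond criterion), second virial
coefficients by quadrature, and the mapping onto the Baxter
adhesive-hard-sphere stickiness parameter via the reduced B2.

Lengths are measured in units of the small-particle radius r_a, energies
in units of the well depth ε unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "MiePotential",
    "ContinuousSquareWell",
    "SquareWell",
    "VirialResult",
    "mie_energy_force",
    "csw_energy",
    "csw_energy_force",
    "inflection_radius",
    "second_virial",
    "barker_henderson_diameter",
    "baxter_stickiness",
    "calibrate_csw",
]


@dataclass(frozen=True)
class MiePotential:
    """Mie (n, m) potential, U(r) = C ε [(σ/r)^n − (σ/r)^m].

    The prefactor C = n/(n−m) · (n/m)^(m/(n−m)) normalizes the well
    depth to exactly −ε at r_min = (n/m)^(1/(n−m)) σ.  The potential is
    truncated at ``cutoff`` and shifted to zero there (energy shift
    only; forces are untouched, so the well depth is preserved up to the
    small constant shift).

    Parameters are per species pair through ``sigma``; a binary mixture
    uses sigma_aa = 1, sigma_bb = size_ratio, sigma_ab = their mean.
    """

    n: float = 30.0
    m: float = 20.0
    epsilon: float = 1.0
    sigma: float = 1.0
    cutoff: float = 1.5

    def __post_init__(self):
        if not (self.n > self.m > 0):
            raise ValueError(f"require n > m > 0, got n={self.n}, m={self.m}")
        if self.epsilon < 0:
            raise ValueError("well depth must be non-negative")

    @property
    def prefactor(self) -> float:
        n, m = self.n, self.m
        return (n / (n - m)) * (n / m) ** (m / (n - m))

    @property
    def r_min(self) -> float:
        """Location of the potential minimum."""
        return (self.n / self.m) ** (1.0 / (self.n - self.m)) * self.sigma

    def unshifted(self, r):
        sr = self.sigma / np.asarray(r, dtype=float)
        return self.prefactor * self.epsilon * (sr**self.n - sr**self.m)

    @property
    def shift(self) -> float:
        """Energy shift so that U(cutoff) = 0."""
        return -float(self.unshifted(self.cutoff))

    def energy(self, r):
        r = np.asarray(r, dtype=float)
        u = self.unshifted(r) + self.shift
        return np.where(r < self.cutoff, u, 0.0)

    def force(self, r):
        """Radial force F = −dU/dr (positive = repulsive)."""
        r = np.asarray(r, dtype=float)
        sr = self.sigma / r
        f = self.prefactor * self.epsilon / r * (self.n * sr**self.n - self.m * sr**self.m)
        return np.where(r < self.cutoff, f, 0.0)

    def second_derivative(self, r):
        r = np.asarray(r, dtype=float)
        sr = self.sigma / r
        n, m = self.n, self.m
        return self.prefactor * self.epsilon / r**2 * (
            n * (n + 1) * sr**n - m * (m + 1) * sr**m
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["family"] = "mie"
        return d


@dataclass(frozen=True)
class ContinuousSquareWell:
    """Smooth square well: steep power-law core plus a sigmoid wall.

    U(r) = (ε/2) [ (1/r)^n + tanh(m (r−1)(r−r_sw) / 2) − 1 ]

    with r in units of the pair contact distance.  The tanh form is the
    numerically safe rewriting of (1−e^(−x))/(1+e^(−x)); it saturates to
    ±1 instead of overflowing.  For 1 < r < r_sw the sigmoid sits at −1
    and the energy is −ε; at r = 1 the power term is 1 and the sigmoid 0,
    so U = 0 exactly.  Default steepnesses m = 7000, n = 700 make the
    walls nearly vertical.
    """

    epsilon: float = 1.0
    n: float = 700.0
    m: float = 7000.0
    r_sw: float = 1.08
    cutoff: float = 1.5

    def _core(self, r, extra_power=0.0):
        # r^-(n+extra) without overflow warnings: saturates at e^700
        return np.exp(np.clip(-(self.n + extra_power) * np.log(r), None, 700.0))

    def energy(self, r):
        r = np.asarray(r, dtype=float)
        x = self.m * (r - 1.0) * (r - self.r_sw)
        u = 0.5 * self.epsilon * (self._core(r) + np.tanh(0.5 * x) - 1.0)
        return np.where(r < self.cutoff, u, 0.0)

    def force(self, r):
        r = np.asarray(r, dtype=float)
        x = self.m * (r - 1.0) * (r - self.r_sw)
        xp = self.m * (2.0 * r - 1.0 - self.r_sw)
        sech2 = 1.0 / np.cosh(np.clip(0.5 * x, -350.0, 350.0)) ** 2
        du = 0.5 * self.epsilon * (-self.n * self._core(r, 1.0) + 0.5 * xp * sech2)
        return np.where(r < self.cutoff, -du, 0.0)

    def second_derivative(self, r):
        r = np.asarray(r, dtype=float)
        x = self.m * (r - 1.0) * (r - self.r_sw)
        xp = self.m * (2.0 * r - 1.0 - self.r_sw)
        t = np.tanh(np.clip(0.5 * x, -350.0, 350.0))
        sech2 = 1.0 - t**2
        # d/dr [0.5 xp sech2] = 0.5 [2m sech2 + xp * (-xp t sech2)]
        return 0.5 * self.epsilon * (
            self.n * (self.n + 1.0) * self._core(r, 2.0)
            + self.m * sech2
            - 0.5 * xp**2 * t * sech2
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["family"] = "csw"
        return d


@dataclass(frozen=True)
class SquareWell:
    """Ideal square well: hard core at ``diameter``, depth −ε out to
    ``width_ratio``·diameter.  Its B2 has the closed form

        B2 = (2π/3) d³ [1 − (λ_w³ − 1)(e^{ε/kT} − 1)],

    used as the analytic reference for the quadrature."""

    depth: float = 1.0
    width_ratio: float = 1.1
    diameter: float = 1.0

    def energy(self, r):
        r = np.asarray(r, dtype=float)
        return np.where(r < self.diameter, np.inf,
                        np.where(r < self.width_ratio * self.diameter,
                                 -self.depth, 0.0))

    def b2_closed_form(self, kT: float) -> float:
        lam = self.width_ratio
        return (2.0 * np.pi / 3.0 * self.diameter**3
                * (1.0 - (lam**3 - 1.0) * (np.expm1(self.depth / kT))))


@dataclass(frozen=True)
class VirialResult:
    """Second virial coefficient and its adhesive-hard-sphere reduction."""

    B2: float                  # volume, units r_a^3
    effective_diameter: float  # length used for the hard-sphere reference
    beta_epsilon: float        # ε/kT at which B2 was evaluated

    @property
    def B2_hs(self) -> float:
        return 2.0 * np.pi / 3.0 * self.effective_diameter**3

    @property
    def B2_reduced(self) -> float:
        return self.B2 / self.B2_hs

    @property
    def baxter_tau(self) -> float:
        return baxter_stickiness(self)


def mie_energy_force(r, pot: MiePotential):
    """Energy and radial force of the truncated-shifted Mie potential.

    Force is −dU/dr, evaluated analytically.  Raises for r <= 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    return pot.energy(r), pot.force(r)


def csw_energy(r, pot: ContinuousSquareWell):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    return pot.energy(r)


def csw_energy_force(r, pot: ContinuousSquareWell):
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    return pot.energy(r), pot.force(r)


def inflection_radius(pot) -> float:
    """Smallest r > r_min where U''(r) = 0 (the bond-distance criterion).

    For a Mie potential the closed form is
    r = (n(n+1) / (m(m+1)))^(1/(n−m)) σ; the numeric bracketed root of
    the analytic second derivative is returned for any potential and
    agrees with the closed form to root-solver precision.
    """
    if isinstance(pot, MiePotential):
        lo = pot.r_min
    elif isinstance(pot, ContinuousSquareWell):
        # minimum sits inside the flat well; search from mid-well out
        lo = 0.5 * (1.0 + pot.r_sw)
    else:
        raise TypeError(f"unsupported potential {type(pot).__name__}")
    hi = pot.cutoff
    f = lambda r: float(pot.second_derivative(r))
    # walk out from lo until the sign changes
    rs = np.linspace(lo * 1.000001, hi, 4096)
    vals = np.array([f(r) for r in rs])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("no inflection point found between the minimum and the cutoff")
    i = sign_change[0]
    return brentq(f, rs[i], rs[i + 1], xtol=1e-14)


def barker_henderson_diameter(pot, kT: float) -> float:
    """Barker–Henderson effective hard-sphere diameter.

    d = ∫_0^{r0} [1 − exp(−U(r)/kT)] dr over the repulsive branch,
    where r0 is the zero crossing of the (shifted) potential.  The
    integrand is 1 to machine precision deep in the core, so the
    integral is split at the point where U = 50 kT.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    if isinstance(pot, SquareWell):
        return pot.diameter          # integrand is exactly 1 inside the core
    # zero crossing of the shifted potential
    r0 = brentq(lambda r: float(pot.energy(r)), 0.5, _r_attr(pot), xtol=1e-14)
    # point where U = 50 kT (integrand indistinguishable from 1 below it)
    try:
        r_hot = brentq(lambda r: float(pot.energy(r)) - 50.0 * kT, 1e-3, r0, xtol=1e-14)
    except ValueError:
        r_hot = 1e-3
    tail, _ = quad(lambda r: 1.0 - np.exp(-float(pot.energy(r)) / kT), r_hot, r0,
                   limit=200)
    return r_hot + tail


def _r_attr(pot) -> float:
    """A radius safely inside the attractive well (U < 0)."""
    if isinstance(pot, MiePotential):
        return pot.r_min
    if isinstance(pot, ContinuousSquareWell):
        return 0.5 * (1.0 + pot.r_sw)
    raise TypeError(f"unsupported potential {type(pot).__name__}")


def second_virial(pot, kT: float, effective_diameter: str | float = "barker-henderson") -> VirialResult:
    """B2 = 2π ∫_0^∞ (1 − e^(−U(r)/kT)) r² dr by adaptive quadrature.

    The truncated-shifted potential is identically zero beyond the
    cutoff, so the integral terminates at r_c.  The quadrature is split
    at the potential's characteristic radii (zero crossing, minimum) to
    resolve the near-discontinuous well of steep potentials.

    ``effective_diameter`` selects the hard-sphere reference for the
    reduced B2: "barker-henderson" (default), "sigma" (the nominal
    contact distance), or an explicit number.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    if isinstance(pot, SquareWell):
        # hard core contributes d^3/3 exactly; the well segment is smooth
        d = pot.diameter
        well, err = quad(lambda r: (1.0 - np.exp(pot.depth / kT)) * r * r,
                         d, pot.width_ratio * d, epsabs=1e-13, epsrel=1e-12)
        B2 = 2.0 * np.pi * (d**3 / 3.0 + well)
        eff = d if effective_diameter in ("barker-henderson", "sigma") \
            else float(effective_diameter)
        return VirialResult(B2=B2, effective_diameter=eff,
                            beta_epsilon=pot.depth / kT)
    r0 = brentq(lambda r: float(pot.energy(r)), 0.5, _r_attr(pot), xtol=1e-14)
    points = sorted({r0, _r_attr(pot), pot.cutoff * 0.999})

    def integrand(r):
        return (1.0 - np.exp(-float(pot.energy(r)) / kT)) * r * r

    # hard-core part: integrand = r^2 to machine precision below r_hot
    try:
        r_hot = brentq(lambda r: float(pot.energy(r)) - 50.0 * kT, 1e-3, r0, xtol=1e-14)
    except ValueError:
        r_hot = 1e-3
    core = r_hot**3 / 3.0
    segs = [r_hot] + [p for p in points if p > r_hot] + [pot.cutoff]
    total = core
    for a, b in zip(segs[:-1], segs[1:]):
        val, err = quad(integrand, a, b, limit=400, epsabs=1e-12, epsrel=1e-10)
        if not np.isfinite(val):
            raise RuntimeError(f"B2 quadrature failed on [{a}, {b}]: {val}, err={err}")
        total += val
    B2 = 2.0 * np.pi * total

    if effective_diameter == "barker-henderson":
        d = barker_henderson_diameter(pot, kT)
    elif effective_diameter == "sigma":
        d = pot.sigma if isinstance(pot, MiePotential) else 1.0
    else:
        d = float(effective_diameter)
    return VirialResult(B2=B2, effective_diameter=d, beta_epsilon=getattr(pot, "epsilon", 1.0) / kT)


def baxter_stickiness(virial: VirialResult) -> float:
    """Baxter adhesive-hard-sphere stickiness τ_B with matched B2.

    The adhesive hard sphere has B2/B2_hs = 1 − 1/(4τ_B); inverting,
    τ_B = 1 / (4 (1 − B2_reduced)).  Smaller τ_B means stronger
    adhesion; requires net attraction (B2_reduced < 1).
    """
    b2r = virial.B2_reduced
    if b2r >= 1.0:
        raise ValueError(f"B2_reduced = {b2r:.4f} >= 1: no net attraction to map")
    return 1.0 / (4.0 * (1.0 - b2r))


def calibrate_csw(target: MiePotential, kT: float,
                  r_sw: float | None = None,
                  steep_m: float = 7000.0, steep_n: float = 700.0) -> ContinuousSquareWell:
    """Construct a CSW whose B2 at the given kT matches the target Mie B2.

    The well width r_sw is fixed by the geometry (default: the target's
    inflection radius, i.e. the bond distance) and the well depth ε is
    root-found so the two second virial coefficients coincide.  For a
    binary mixture the per-pair width scales with the pair contact
    distance.
    """
    b2_target = second_virial(target, kT).B2
    if r_sw is None:
        r_sw = inflection_radius(target) / target.sigma

    def mismatch(eps):
        pot = ContinuousSquareWell(epsilon=eps, n=steep_n, m=steep_m, r_sw=r_sw,
                                   cutoff=target.cutoff / target.sigma)
        return second_virial(pot, kT).B2 * target.sigma**3 - b2_target

    lo, hi = 1e-6, max(10.0 * target.epsilon, 1.0)
    flo, fhi = mismatch(lo), mismatch(hi)
    while flo * fhi > 0 and hi < 1e3:      # widen until the well overcomes the core
        hi *= 3.0
        fhi = mismatch(hi)
    if flo * fhi > 0:
        raise ValueError("no CSW depth in bracket matches the target B2")
    eps = brentq(mismatch, lo, hi, xtol=1e-12, rtol=1e-12)
    return ContinuousSquareWell(epsilon=eps, n=steep_n, m=steep_m, r_sw=r_sw,
                                cutoff=target.cutoff / target.sigma)
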