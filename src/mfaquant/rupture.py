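"""Serial-bond rupture competition under a linear force ramp.

In a molecular force assay every sample bond (a protein-DNA complex) is
loaded in series with its own reference bond (a DNA duplex of chosen
length).  Pulling the surfaces apart ramps the force on both bonds until
one of them breaks; the fraction of constructs whose *reference* breaks
first is exactly the quantity the fluorescence read-out measures.

Each bond is modelled with Bell kinetics: the off-rate under force F is

    k(F) = k0 * exp(F / f_beta)

with ``k0`` the zero-force off-rate (1/s) and ``f_beta`` the force scale
(pN).  Under a linear ramp F = r*t the two bonds are competing risks with
hazards h_i(F) = k_i(F)/r per unit force, and

    P(reference first) = \\int_0^Fmax h_ref(F) * S(F) dF,
    S(F) = exp(-\\int_0^F [h_ref + h_sample] dF')

where the inner integral has the closed form k0*f_beta/r * (exp(F/f_beta)-1)
for a Bell bond.  ``reference_rupture_probability`` evaluates the outer
integral by adaptive quadrature; ``simulate_rupture`` draws the same
process by inverse-CDF kinetic Monte Carlo so the two routes cross-check
each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate

from .errors import NumericalIntegrationError, UnsupportedGeometryError

__all__ = [
    "BellBond",
    "DuplexSpec",
    "RampProtocol",
    "DEFAULT_PER_BP_PARAMS",
    "bond_from_duplex",
    "reference_rupture_probability",
    "simulate_rupture",
    "solve_sample_bond",
]

# survival below this is treated as zero when choosing the quadrature cutoff
_SURVIVAL_FLOOR = 1e-12
_QUAD_ABS_TOL = 1e-8
# exponent cap keeps exp() finite while bracketing far beyond any rupture force
_EXP_CAP = 700.0

GEOMETRIES = ("shear", "zipper")


@dataclass(frozen=True)
class BellBond:
    """One molecular bond with a single-exponential (Bell) force-dependent off-rate."""

    label: str
    k0: float
    f_beta: float

    def __post_init__(self) -> None:
        if not (self.k0 > 0 and math.isfinite(self.k0)):
            raise ValueError(f"k0 must be positive and finite, got {self.k0}")
        if not (self.f_beta > 0 and math.isfinite(self.f_beta)):
            raise ValueError(f"f_beta must be positive and finite, got {self.f_beta}")

    def hazard(self, force):
        """Off-rate k(F) = k0 * exp(F/f_beta), 1/s."""
        return self.k0 * np.exp(np.minimum(np.asarray(force, float) / self.f_beta, _EXP_CAP))

    def cumulative_hazard(self, force, loading_rate: float):
        """Integral of k(F')/r over [0, F]: (k0*f_beta/r) * (exp(F/f_beta) - 1)."""
        x = np.minimum(np.asarray(force, float) / self.f_beta, _EXP_CAP)
        return self.k0 * self.f_beta / loading_rate * np.expm1(x)


@dataclass(frozen=True)
class DuplexSpec:
    """A DNA duplex acting as a bond, defined by length and loading geometry."""

    n_bp: int
    geometry: str = "shear"

    def __post_init__(self) -> None:
        if int(self.n_bp) != self.n_bp or self.n_bp < 1:
            raise ValueError(f"n_bp must be an integer >= 1, got {self.n_bp}")
        if self.geometry not in GEOMETRIES:
            raise UnsupportedGeometryError(
                f"geometry {self.geometry!r} not supported (expected one of {GEOMETRIES})"
            )


@dataclass(frozen=True)
class RampProtocol:
    """Linear force ramp: F(t) = loading_rate * t, optionally capped at f_max."""

    loading_rate: float = 100.0  # pN/s
    f_max: float | None = None  # pN; None = ramp until rupture

    def __post_init__(self) -> None:
        if not self.loading_rate > 0:
            raise ValueError(f"loading_rate must be > 0, got {self.loading_rate}")
        if self.f_max is not None and not self.f_max > 0:
            raise ValueError(f"f_max must be > 0 when given, got {self.f_max}")


# Per-base-pair rule mapping duplex length to Bell parameters:
#   k0(n_bp) = k0_1 * exp(-delta_g_per_bp * n_bp),   f_beta constant.
# Longer duplexes therefore dissociate more slowly, and in shear geometry the
# per-bp stability increment is large (all base pairs load in parallel) while
# zipper peeling gains little stability per added base pair.
DEFAULT_PER_BP_PARAMS: Mapping[str, Mapping[str, float]] = {
    "shear": {"k0_1": 30.0, "delta_g_per_bp": 0.6, "f_beta": 8.0},
    "zipper": {"k0_1": 30.0, "delta_g_per_bp": 0.12, "f_beta": 4.0},
}


def bond_from_duplex(
    duplex: DuplexSpec, per_bp_params: Mapping | None = None
) -> BellBond:
    """Map a duplex of ``n_bp`` base pairs onto a Bell bond.

    ``per_bp_params`` may be keyed by geometry (like ``DEFAULT_PER_BP_PARAMS``)
    or be a flat mapping with keys ``k0_1``, ``delta_g_per_bp``, ``f_beta``.
    The rule is monotone by construction: k0 strictly decreases with n_bp,
    f_beta is constant, so longer duplexes are strictly harder to rupture.
    """
    if per_bp_params is None:
        per_bp_params = DEFAULT_PER_BP_PARAMS
    if duplex.geometry in per_bp_params:
        params = per_bp_params[duplex.geometry]
    elif "k0_1" in per_bp_params:
        params = per_bp_params
    else:
        raise UnsupportedGeometryError(
            f"no per-bp parameters for geometry {duplex.geometry!r}"
        )
    k0 = float(params["k0_1"]) * math.exp(-float(params["delta_g_per_bp"]) * duplex.n_bp)
    return BellBond(
        label=f"{duplex.geometry}-{duplex.n_bp}bp", k0=k0, f_beta=float(params["f_beta"])
    )


def _total_cumulative_hazard(force, bonds: Sequence[BellBond], rate: float):
    total = 0.0
    for b in bonds:
        total = total + b.cumulative_hazard(force, rate)
    return total


def _upper_force_cutoff(bonds: Sequence[BellBond], rate: float) -> float:
    """Force beyond which joint survival is below _SURVIVAL_FLOOR."""
    target = -math.log(_SURVIVAL_FLOOR)
    hi = max(b.f_beta for b in bonds)
    for _ in range(200):
        if _total_cumulative_hazard(hi, bonds, rate) >= target:
            break
        hi *= 2.0
    else:  # pragma: no cover - requires absurd parameters
        raise NumericalIntegrationError("could not bracket the survival cutoff force")
    lo = 0.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _total_cumulative_hazard(mid, bonds, rate) < target:
            lo = mid
        else:
            hi = mid
    return hi


def reference_rupture_probability(
    sample: BellBond, reference: BellBond, ramp: RampProtocol
) -> float:
    """P(reference ruptures before sample) under the linear ramp.

    Evaluated by adaptive quadrature of the competing-hazards density
    (absolute tolerance 1e-8) with the upper limit placed where the joint
    survival has dropped below 1e-12, or at ``f_max`` if the ramp is capped.
    Without a cap the two rupture probabilities sum to one, so this is also
    the expected transferred fraction for a pad of identical constructs.
    """
    bonds = (sample, reference)
    rate = ramp.loading_rate
    upper = _upper_force_cutoff(bonds, rate)
    if ramp.f_max is not None:
        upper = min(upper, ramp.f_max)

    def density(force: float) -> float:
        surv = math.exp(-float(_total_cumulative_hazard(force, bonds, rate)))
        return float(reference.hazard(force)) / rate * surv

    value, abserr = integrate.quad(density, 0.0, upper, epsabs=_QUAD_ABS_TOL, limit=200)
    if abserr > 1e-6:
        raise NumericalIntegrationError(
            f"quadrature did not converge: value={value}, abserr={abserr}, "
            f"upper={upper}, bonds={bonds}, rate={rate}"
        )
    return float(min(max(value, 0.0), 1.0))


def _invert_total_hazard(
    targets: np.ndarray, bonds: Sequence[BellBond], rate: float
) -> np.ndarray:
    """Vectorized bisection solving total cumulative hazard == target per element."""
    hi_scalar = max(b.f_beta for b in bonds)
    tmax = float(targets.max())
    for _ in range(200):
        if float(_total_cumulative_hazard(hi_scalar, bonds, rate)) >= tmax:
            break
        hi_scalar *= 2.0
    else:  # pragma: no cover
        raise NumericalIntegrationError("could not bracket rupture forces")
    lo = np.zeros_like(targets)
    hi = np.full_like(targets, hi_scalar)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        below = _total_cumulative_hazard(mid, bonds, rate) < targets
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def simulate_rupture(
    sample: BellBond,
    reference: BellBond,
    ramp: RampProtocol,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Kinetic Monte Carlo of the rupture competition for ``n`` constructs.

    The total rupture force is drawn by inverse-CDF sampling of the joint
    time-varying hazard (vectorized bisection on the closed-form cumulative
    hazard); which bond broke is then a Bernoulli split with probability
    h_ref/(h_ref+h_sample) evaluated at the rupture force.  With a force cap
    some constructs survive the whole ramp and are recorded as ``winner
    "none"`` with NaN rupture force.

    Returns a DataFrame with columns ``replicate``, ``winner`` ("reference",
    "sample" or "none") and ``rupture_force_pN``; identical seeds reproduce
    it exactly.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    columns = ["replicate", "winner", "rupture_force_pN"]
    if n == 0:
        return pd.DataFrame({c: [] for c in columns}).astype(
            {"replicate": int, "winner": str, "rupture_force_pN": float}
        )
    rng = np.random.default_rng(seed)
    bonds = (sample, reference)
    rate = ramp.loading_rate
    targets = rng.exponential(size=n)  # -log U, the cumulative hazard at rupture
    if ramp.f_max is not None:
        reachable = _total_cumulative_hazard(ramp.f_max, bonds, rate)
        censored = targets > reachable
    else:
        censored = np.zeros(n, dtype=bool)
    forces = _invert_total_hazard(targets, bonds, rate)
    h_ref = reference.hazard(forces)
    h_sam = sample.hazard(forces)
    ref_wins = rng.random(n) < h_ref / (h_ref + h_sam)
    winner = np.where(censored, "none", np.where(ref_wins, "reference", "sample"))
    forces = np.where(censored, np.nan, forces)
    return pd.DataFrame(
        {"replicate": np.arange(n), "winner": winner, "rupture_force_pN": forces}
    )


def solve_sample_bond(
    target_probability: float,
    reference: BellBond,
    ramp: RampProtocol,
    f_beta: float = 8.0,
    k0_bracket: tuple[float, float] = (1e-18, 1e6),
) -> BellBond:
    """Find a sample bond whose reference-rupture probability equals a target.

    Solves for the sample k0 (at fixed ``f_beta``) such that
    ``reference_rupture_probability(sample, reference, ramp)`` equals
    ``target_probability``; bisection on log10(k0).  Used to parametrize
    ground truths whose transferred fraction matches a desired value.
    """
    if not 0.0 < target_probability < 1.0:
        raise ValueError("target_probability must be in (0, 1)")

    def prob(log_k0: float) -> float:
        bond = BellBond("sample", 10.0**log_k0, f_beta)
        return reference_rupture_probability(bond, reference, ramp)

    lo, hi = (math.log10(k0_bracket[0]), math.log10(k0_bracket[1]))
    # P(reference first) decreases as the sample weakens (larger sample k0)
    if not (prob(lo) >= target_probability >= prob(hi)):
        raise ValueError("target_probability not bracketed by k0_bracket")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if prob(mid) > target_probability:
            lo = mid
        else:
            hi = mid
    return BellBond("sample", 10.0 ** (0.5 * (lo + hi)), f_beta)
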