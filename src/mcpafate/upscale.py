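"""Scale-transition decomposition of the macroscopic degradation rate.

For Monod kinetics ``R = mu_max rho_b B C/(K_M + C)`` with spatially uniform
rate parameters, a second-order Taylor expansion of the spatial average of R
around the mean substrate and biomass concentrations gives

    R_bar = MFA + COV + VAR + sum(HOT)

with the mean-field approximation MFA = R(C_bar, B_bar) (the perfectly mixed
rate), a covariance term proportional to Cov(C, B), and a variance term
proportional to Var(C); the term in Var(B) vanishes because R is linear in B.
The higher-order remainder HOT is reported as the residual of the identity.
A negative COV (substrate depleted where degraders aggregate) quantifies
transport limitation; VAR is always <= 0 by concavity of the Monod factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ReactionParams
from .units import SECONDS_PER_DAY


@dataclass(frozen=True)
class MomentSet:
    """Weighted spatial moments of substrate and biomass over a region."""

    mean_C: float  # [umol C/m^3]
    mean_B: float  # [umol C/kg]
    var_C: float
    var_B: float
    cov_CB: float
    region: str = ""
    time: float = 0.0  # [s]

    def __post_init__(self) -> None:
        if self.var_C < 0 or self.var_B < 0:
            raise ValueError("variances must be non-negative")
        bound = np.sqrt(self.var_C * self.var_B)
        if abs(self.cov_CB) > bound * (1.0 + 1e-9) + 1e-300:
            raise ValueError("covariance violates the Cauchy-Schwarz bound")


@dataclass(frozen=True)
class RateDecomposition:
    """Terms of the second-order scale-transition expansion [umol C/m^3/s]."""

    R_bar: float
    MFA: float
    COV: float
    VAR: float
    HOT: float
    time: float = 0.0  # [s]

    def as_dict(self, per_day: bool = True) -> dict:
        f = SECONDS_PER_DAY if per_day else 1.0
        return {
            "time_days": self.time / SECONDS_PER_DAY,
            "R_bar": self.R_bar * f,
            "MFA": self.MFA * f,
            "COV": self.COV * f,
            "VAR": self.VAR * f,
            "HOT": self.HOT * f,
        }


def spatial_moments(C_L, B, weights=None, region: str = "",
                    time: float = 0.0) -> MomentSet:
    """Volume-weighted population moments of C_L and B over a region.

    ``weights`` are cell volumes (or any positive weights); the averaging
    operator is a volume integral, so population (not sample) statistics are
    used.
    """
    c = np.asarray(C_L, dtype=float).ravel()
    b = np.asarray(B, dtype=float).ravel()
    if c.size == 0:
        raise ValueError("empty region")
    w = np.ones_like(c) if weights is None else np.asarray(weights, float).ravel()
    w = w / w.sum()
    mc = float(w @ c)
    mb = float(w @ b)
    var_c = float(w @ (c - mc) ** 2)
    var_b = float(w @ (b - mb) ** 2)
    cov = float(w @ ((c - mc) * (b - mb)))
    return MomentSet(mc, mb, var_c, var_b, cov, region, time)


def monod_volumetric(C_L, B, rho_b, reaction: ReactionParams):
    """Monod degradation rate R [umol C/m^3/s] (B immobile, mass-based)."""
    C_L = np.asarray(C_L, dtype=float)
    return reaction.mu_max * rho_b * np.asarray(B, float) * C_L / (reaction.K_M + C_L)


def mean_field_rate(m: MomentSet, reaction: ReactionParams, rho_b: float) -> float:
    """Rate of a perfectly mixed system: Monod at the spatial means."""
    return float(monod_volumetric(m.mean_C, m.mean_B, rho_b, reaction))


def covariance_term(m: MomentSet, reaction: ReactionParams, rho_b: float) -> float:
    """(d2R/dC dB) at the means times Cov(C, B)."""
    d2 = reaction.mu_max * rho_b * reaction.K_M / (reaction.K_M + m.mean_C) ** 2
    return float(d2 * m.cov_CB)


def variance_term(m: MomentSet, reaction: ReactionParams, rho_b: float) -> float:
    """(1/2)(d2R/dC2) at the means times Var(C); always <= 0."""
    d2 = -reaction.mu_max * rho_b * m.mean_B * reaction.K_M \
        / (reaction.K_M + m.mean_C) ** 3
    return float(d2 * m.var_C)


def decompose(C_L, B, rho_b: float, reaction: ReactionParams,
              weights=None, region: str = "", time: float = 0.0) -> RateDecomposition:
    """Full decomposition; HOT closes the identity exactly by construction."""
    m = spatial_moments(C_L, B, weights, region, time)
    w = None if weights is None else np.asarray(weights, float).ravel()
    rates = monod_volumetric(C_L, B, rho_b, reaction).ravel()
    if w is None:
        r_bar = float(rates.mean())
    else:
        r_bar = float((w / w.sum()) @ rates)
    mfa = mean_field_rate(m, reaction, rho_b)
    cov = covariance_term(m, reaction, rho_b)
    var = variance_term(m, reaction, rho_b)
    return RateDecomposition(r_bar, mfa, cov, var, r_bar - mfa - cov - var, time)


def scale_transition_correction(d: RateDecomposition) -> float:
    """Dimensionless correction (R_bar - MFA)/MFA; 0 for uniform fields."""
    if d.MFA == 0.0:
        raise ZeroDivisionError("correction undefined for MFA = 0")
    return (d.R_bar - d.MFA) / d.MFA
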