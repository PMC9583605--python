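"""Parameter containers and the default parameter registry.

All defaults describe the reference arable Luvisol soil column: three
hydraulically distinct layers (topsoil 0-30 cm, subsoil 30-60 and 60-90 cm),
MCPA transport/sorption properties, and Monod degradation kinetics of an
immobile degrader population proxied by tfdA gene abundance.  Every parameter
carries a provenance tag so run outputs are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VanGenuchtenLayer:
    """Van Genuchten-Mualem hydraulic parameters of one soil layer.

    Depths are positive downward; ``depth_top <= y < depth_bottom`` selects the
    layer.
    """

    theta_s: float  # saturated volumetric water content [1]
    theta_r: float  # residual volumetric water content [1]
    alpha_vg: float  # inverse air-entry value [1/m]
    n_vg: float  # pore-size distribution measure [1]
    l_vg: float  # tortuosity/connectivity exponent [1]
    K_s: float  # saturated hydraulic conductivity [m/s]
    rho_b: float  # dry bulk density [kg/m^3]
    depth_top: float  # [m]
    depth_bottom: float  # [m]

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_r < self.theta_s <= 1.0):
            raise ValueError("require 0 <= theta_r < theta_s <= 1")
        if self.alpha_vg <= 0 or self.n_vg <= 1 or self.K_s <= 0:
            raise ValueError("require alpha_vg > 0, n_vg > 1, K_s > 0")
        if self.depth_bottom <= self.depth_top:
            raise ValueError("layer interval must have positive thickness")

    @property
    def m_vg(self) -> float:
        return 1.0 - 1.0 / self.n_vg


def default_layers(buffer_bottom: float = 2.0) -> list[VanGenuchtenLayer]:
    """Reference soil column layers.

    The measured column is 0.9 m deep; an additional buffer zone down to
    ``buffer_bottom`` (default 2.0 m) with the 60-90 cm layer's properties
    reduces the influence of the free-drainage outflow boundary.
    """
    layers = [
        VanGenuchtenLayer(0.49, 0.00, 12.30, 1.10, 0.5, 1.85e-5, 1.24e3, 0.0, 0.3),
        VanGenuchtenLayer(0.46, 0.15, 13.40, 1.12, 0.5, 24.00e-5, 1.32e3, 0.3, 0.6),
        VanGenuchtenLayer(0.43, 0.00, 3.63, 1.12, 0.5, 2.31e-5, 1.46e3, 0.6, 0.9),
    ]
    if buffer_bottom > 0.9:
        layers.append(
            VanGenuchtenLayer(0.43, 0.00, 3.63, 1.12, 0.5, 2.31e-5, 1.46e3, 0.9, buffer_bottom)
        )
    else:
        # shallow (desk) columns: truncate/clip the layer stack
        layers = [
            VanGenuchtenLayer(
                l.theta_s, l.theta_r, l.alpha_vg, l.n_vg, l.l_vg, l.K_s, l.rho_b,
                l.depth_top, min(l.depth_bottom, buffer_bottom),
            )
            for l in layers
            if l.depth_top < buffer_bottom
        ]
    return layers


@dataclass(frozen=True)
class TransportParams:
    """MCPA transport and equilibrium sorption parameters."""

    D_m: float = 6.33e-10  # aqueous molecular diffusion coefficient [m^2/s]
    K_F: float = 1.79e-3  # Freundlich coefficient [umol C/kg (m^3/umol C)^n_F]
    n_F: float = 0.86  # Freundlich exponent [1]
    lambda_L: float = 0.03  # longitudinal dispersivity [m]
    lambda_T: float = 0.01  # transversal dispersivity [m]

    def __post_init__(self) -> None:
        if not (0.0 < self.n_F <= 1.0):
            raise ValueError("require 0 < n_F <= 1")
        if not (self.lambda_L >= self.lambda_T > 0.0):
            raise ValueError("require lambda_L >= lambda_T > 0")
        if self.D_m <= 0:
            raise ValueError("require D_m > 0")


@dataclass(frozen=True)
class ReactionParams:
    """Monod degradation kinetics of the immobile MCPA degraders."""

    mu_max: float = 2.94e-4  # maximal rate coefficient [1/s]
    K_M: float = 1.93e6  # Monod constant [umol C/m^3]

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.K_M <= 0:
            raise ValueError("require mu_max > 0 and K_M > 0")


@dataclass(frozen=True)
class DepthProfileParams:
    """Horizontally averaged degrader biomass depth profile.

    Constant ``B_TS`` in the topsoil (y <= d_TS), exponential decay with
    constant ``gamma`` below.  ``f_mg`` converts tfdA gene counts to biomass
    carbon.
    """

    B_TS: float = 12.21  # topsoil mean degrader biomass [umol C/kg]
    gamma: float = 3.0  # depth decay constant [1/m]
    d_TS: float = 0.3  # topsoil depth [m]
    f_mg: float = 1.10e-7  # biomass C per gene [umol C/gene]

    def __post_init__(self) -> None:
        if min(self.B_TS, self.gamma, self.d_TS, self.f_mg) <= 0:
            raise ValueError("all depth-profile parameters must be positive")


@dataclass(frozen=True)
class LGCPParams:
    """Log-Gaussian Cox process parameters for degrader point patterns."""

    sigma2: float  # log-field variance [1]
    beta: float  # exponential correlation scale [m]
    f_S: float = 1.0  # intensity scaling factor [genes/m^2]
    d_v_sts: float = 0.05e-3  # virtual soil thin-section thickness [m]
    fine_dx: float = 1.0e-3  # fine sampling grid resolution [m]

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("require sigma2 >= 0")
        if self.beta <= 0 or self.d_v_sts <= 0 or self.fine_dx <= 0:
            raise ValueError("require beta, d_v_sts, fine_dx > 0")


#: virtual soil column (out-of-plane) thickness [m], used to convert areal
#: application rates and report absolute masses from the 2-D xy plane
D_Z_DEFAULT = 0.1

# CV targets [%] defining the heterogeneity scenarios
CV_TARGETS = {"HOM": 0.0, "LOW": 16.0, "HIGH": 161.0, "EXTR": 400.0}
#: target practical range of the fitted exponential semivariogram [m]
PRACTICAL_RANGE_TARGET = 27.0e-3
PRACTICAL_RANGE_TOL = 2.0e-3

#: detection threshold for MCPA in soil [ug/kg]
DETECTION_THRESHOLD_UG_KG = 3.0
#: colonization threshold [genes/g soil]
COLONIZATION_THRESHOLD_GENES_PER_G = 100.0


def _registry_entry(value, unit: str, provenance: str, description: str) -> dict:
    return {
        "value": value,
        "unit": unit,
        "provenance": provenance,
        "description": description,
    }


def parameter_registry() -> dict:
    """Full registry of model parameters with units and provenance tags.

    Per-layer entries are ordered topsoil (0-30 cm), 30-60 cm, 60-90 cm; the
    last layer's values also parametrize the deep buffer zone.
    """
    reg = {
        "theta_s": _registry_entry([0.49, 0.46, 0.43], "1", "measured",
                                   "saturated volumetric water content"),
        "theta_r": _registry_entry([0.00, 0.15, 0.00], "1", "calibrated",
                                   "residual volumetric water content"),
        "alpha_vg": _registry_entry([12.30, 13.40, 3.63], "1/m", "calibrated",
                                    "inverse of air entry value"),
        "n_vg": _registry_entry([1.10, 1.12, 1.12], "1", "calibrated",
                                "measure of pore size distribution"),
        "l_vg": _registry_entry(0.5, "1", "assumed",
                                "Mualem tortuosity/connectivity exponent"),
        "K_s": _registry_entry([1.85e-5, 24.00e-5, 2.31e-5], "m/s", "measured",
                               "saturated hydraulic conductivity"),
        "D_m": _registry_entry(6.33e-10, "m^2/s", "computed",
                               "MCPA molecular diffusion coefficient in water"),
        "K_F": _registry_entry(1.79e-3, "umol C/kg (m^3/umol C)^n_F", "measured",
                               "MCPA Freundlich coefficient"),
        "n_F": _registry_entry(0.86, "1", "measured", "MCPA Freundlich exponent"),
        "lambda_L": _registry_entry(0.03, "m", "assumed", "longitudinal dispersivity"),
        "lambda_T": _registry_entry(0.01, "m", "assumed", "transversal dispersivity"),
        "B_TS": _registry_entry(12.21, "umol C/kg", "measured",
                                "topsoil tfdA gene abundance as biomass C"),
        "f_mg": _registry_entry(1.10e-7, "umol C/gene", "calibrated",
                                "biomass C per tfdA gene"),
        "gamma": _registry_entry(3.0, "1/m", "assumed", "depth decay constant"),
        "mu_max": _registry_entry(2.94e-4, "1/s", "calibrated", "maximal rate coefficient"),
        "K_M": _registry_entry(1.93e6, "umol C/m^3", "calibrated", "Monod constant"),
        "rho_F": _registry_entry(1.00e3, "kg/m^3", "assumed", "water density"),
        "rho_b": _registry_entry([1.24e3, 1.32e3, 1.46e3], "kg/m^3", "measured",
                                 "soil dry bulk density"),
        "g": _registry_entry(9.81, "m/s^2", "assumed", "gravitational acceleration"),
        "n_mol": _registry_entry(200.62, "g/mol", "assumed", "MCPA molecular weight"),
        "n_C": _registry_entry(9, "1", "assumed", "C atoms per MCPA molecule"),
        "d_TS": _registry_entry(0.3, "m", "assumed", "topsoil depth"),
        "d_z": _registry_entry(D_Z_DEFAULT, "m", "assumed", "virtual soil column thickness"),
        "d_v_sts": _registry_entry(0.05e-3, "m", "assumed",
                                   "virtual soil thin section thickness"),
    }
    return reg
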