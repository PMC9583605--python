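"""Stochastic degrader abundance fields via a log-Gaussian Cox process.

Each tfdA gene is one point of a Cox process whose intensity is the
exponential of a stationary Gaussian random field with exponential covariance
``sigma^2 exp(-r/beta)``.  The depth-dependent mean intensity follows the
measured profile (constant in the topsoil, exponential decay below), and the
Gaussian field mean carries the ``-sigma^2/2`` correction so that the process
intensity equals the measured mean at every depth.  Point counts are sampled
on a fine (default 1 mm) grid by circulant-embedding FFT synthesis of the
Gaussian field followed by Poisson thinning, then aggregated to the 5 mm
reaction mesh; heterogeneity below the mesh resolution is deliberately not
represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.fft import fft2, next_fast_len

from .params import (
    COLONIZATION_THRESHOLD_GENES_PER_G,
    DepthProfileParams,
    LGCPParams,
)


# ---------------------------------------------------------------------------
# deterministic depth structure
# ---------------------------------------------------------------------------

def depth_mean_profile(y, p: DepthProfileParams):
    """Horizontally averaged degrader biomass [umol C/kg] at depth ``y`` [m]."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("depth must be non-negative")
    return np.where(y <= p.d_TS, p.B_TS, p.B_TS * np.exp(-p.gamma * (y - p.d_TS)))


def genes_to_biomass(abundance, f_mg: float):
    """Convert gene abundance [genes/kg] to biomass [umol C/kg]."""
    abundance = np.asarray(abundance, dtype=float)
    if np.any(abundance < 0):
        raise ValueError("gene abundance must be non-negative")
    return abundance * f_mg


def mean_intensity(y, p: DepthProfileParams, lg: LGCPParams, rho_b):
    """Mean areal gene intensity lambda_bar(y) [genes/m^2].

    A virtual soil thin section of thickness ``d_v_sts`` converts the
    mass-based mean biomass into genes per unit area of the xy plane.
    """
    return depth_mean_profile(y, p) * np.asarray(rho_b, float) * lg.d_v_sts / p.f_mg


# ---------------------------------------------------------------------------
# Gaussian random field synthesis (circulant embedding)
# ---------------------------------------------------------------------------

def _embedding_eigenvalues(ny: int, nx: int, dx: float, sigma2: float,
                           beta: float, pad: int):
    """Eigenvalues of the periodic covariance embedding; grows until PD."""
    for grow in range(5):
        My = next_fast_len(ny + pad * (1 + grow))
        Mx = next_fast_len(nx + pad * (1 + grow))
        iy = np.minimum(np.arange(My), My - np.arange(My)) * dx
        ix = np.minimum(np.arange(Mx), Mx - np.arange(Mx)) * dx
        r = np.hypot(iy[:, None], ix[None, :])
        cov = sigma2 * np.exp(-r / beta)
        lam = fft2(cov).real
        neg = lam.min()
        if neg > -1e-8 * max(lam.max(), 1.0):
            return np.maximum(lam, 0.0), My, Mx
    # fall back: clip the (small) negative part and report via the caller
    return np.maximum(lam, 0.0), My, Mx


def gaussian_field(ny: int, nx: int, dx: float, sigma2: float, beta: float,
                   rng: np.random.Generator, pad_corr: float = 8.0) -> np.ndarray:
    """Sample a zero-mean stationary Gaussian field with exponential covariance."""
    if sigma2 == 0.0:
        return np.zeros((ny, nx))
    pad = int(np.ceil(pad_corr * beta / dx))
    lam, My, Mx = _embedding_eigenvalues(ny, nx, dx, sigma2, beta, pad)
    noise = rng.normal(size=(My, Mx)) + 1j * rng.normal(size=(My, Mx))
    spec = np.sqrt(lam / (My * Mx)) * noise
    f = fft2(spec)
    return f.real[:ny, :nx]


# ---------------------------------------------------------------------------
# field container and sampling
# ---------------------------------------------------------------------------

@dataclass
class DegraderField:
    """Immobile degrader biomass on a uniform grid (y down, x across).

    ``B`` is biomass [umol C/kg soil]; ``gene_count`` are raw point counts per
    grid cell; ``genes_per_g`` the mass-based abundance used for colonization.
    """

    B: np.ndarray
    gene_count: np.ndarray
    genes_per_g: np.ndarray
    y_centers: np.ndarray
    x_centers: np.ndarray
    cell_size: float  # [m]
    seed: int | None = None
    scenario: str = ""
    meta: dict = dc_field(default_factory=dict)

    @property
    def shape(self):
        return self.B.shape

    def region_mask(self, y_top: float, y_bottom: float) -> np.ndarray:
        return (self.y_centers >= y_top) & (self.y_centers < y_bottom)


def uniform_field(p: DepthProfileParams, lg: LGCPParams, rho_b_of_y,
                  width: float, depth: float, cell: float = 5e-3,
                  scenario: str = "HOM") -> DegraderField:
    """Deterministic (homogeneous-in-x) field following the depth profile."""
    ny = int(round(depth / cell))
    nx = int(round(width / cell))
    yc = (np.arange(ny) + 0.5) * cell
    xc = (np.arange(nx) + 0.5) * cell
    rho = np.asarray(rho_b_of_y(yc), dtype=float)
    B = np.repeat(depth_mean_profile(yc, p)[:, None], nx, axis=1)
    cell_mass_g = cell * cell * lg.d_v_sts * rho * 1e3  # [g], per row
    counts = B * (cell_mass_g[:, None] * 1e-3) / p.f_mg
    genes_per_g = counts / cell_mass_g[:, None]
    return DegraderField(B, counts, genes_per_g, yc, xc, cell, None, scenario)


def sample_field(
    p: DepthProfileParams,
    lg: LGCPParams,
    rho_b_of_y,
    width: float,
    depth: float,
    cell: float = 5e-3,
    rng: np.random.Generator | int | None = None,
    scenario: str = "",
) -> DegraderField:
    """Draw one LGCP realization aggregated to the reaction mesh resolution.

    ``rho_b_of_y`` maps depth [m] to bulk density [kg/m^3] (layer lookup).
    The ensemble expectation of cell biomass equals ``depth_mean_profile``.
    """
    seed = None
    if not isinstance(rng, np.random.Generator):
        seed = rng
        rng = np.random.default_rng(rng)
    agg = int(round(cell / lg.fine_dx))
    if abs(agg * lg.fine_dx - cell) > 1e-12:
        raise ValueError("mesh cell size must be a multiple of the fine grid")
    ny = int(round(depth / cell))
    nx = int(round(width / cell))
    fy, fx = ny * agg, nx * agg
    yc_fine = (np.arange(fy) + 0.5) * lg.fine_dx
    rho_fine = np.asarray(rho_b_of_y(yc_fine), dtype=float)
    lam_bar = mean_intensity(yc_fine, p, lg, rho_fine)  # genes/m^2, per fine row

    G = gaussian_field(fy, fx, lg.fine_dx, lg.sigma2, lg.beta, rng)
    log_mean = np.log(lam_bar / lg.f_S) - lg.sigma2 / 2.0
    intensity = lg.f_S * np.exp(log_mean[:, None] + G)  # genes/m^2
    mean_counts = intensity * lg.fine_dx ** 2
    counts_fine = rng.poisson(mean_counts).astype(float)

    counts = counts_fine.reshape(ny, agg, nx, agg).sum(axis=(1, 3))
    yc = (np.arange(ny) + 0.5) * cell
    xc = (np.arange(nx) + 0.5) * cell
    rho = np.asarray(rho_b_of_y(yc), dtype=float)
    cell_mass_kg = cell * cell * lg.d_v_sts * rho  # per row, [kg]
    B = counts * p.f_mg / cell_mass_kg[:, None]
    genes_per_g = counts / (cell_mass_kg[:, None] * 1e3)
    return DegraderField(
        B, counts, genes_per_g, yc, xc, cell, seed, scenario,
        meta={"sigma2": lg.sigma2, "beta": lg.beta},
    )


# ---------------------------------------------------------------------------
# spatial metrics
# ---------------------------------------------------------------------------

def compute_cv(field: DegraderField, y_top: float = 0.0,
               y_bottom: float = 0.3) -> float:
    """Spatial coefficient of variation [%] of cell biomass in a depth region."""
    mask = field.region_mask(y_top, y_bottom)
    vals = field.B[mask, :].ravel()
    if vals.size == 0:
        raise ValueError("empty region")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero-mean field")
    return 100.0 * vals.std() / mean


def colonization_ratio(field: DegraderField, y_top: float = 0.0,
                       y_bottom: float = 0.3,
                       threshold: float = COLONIZATION_THRESHOLD_GENES_PER_G) -> float:
    """Share of cells [%] with abundance >= ``threshold`` genes/g soil."""
    mask = field.region_mask(y_top, y_bottom)
    vals = field.genes_per_g[mask, :].ravel()
    return 100.0 * np.mean(vals >= threshold)
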