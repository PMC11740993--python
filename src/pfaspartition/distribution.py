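"""Concentration-dependent HSA/water distribution versus membrane partitioning.

Because protein binding saturates, the distribution coefficient of a
compound between an HSA phase and water falls as the aqueous
concentration rises, while the membrane-water partition coefficient
K_MW is concentration-independent. Extrapolating the single-site
binding fit to a mass-concentration ratio gives

    D_HSA/W = B_max * rho_HSA / (MW_HSA * (K_D + C_aq / MW_PFAS))

with rho_HSA the density of the HSA phase (g/L), MW_HSA and MW_PFAS the
molar masses (g/mol), K_D in mol/L and C_aq the aqueous PFAS
concentration in g/L. D is pseudounitless (bound mass per HSA mass over
aqueous mass concentration, both phases on a mass/volume basis), finite
at C_aq = 0 and strictly decreasing; wherever the falling log D curve
meets the flat log K_MW line, dominance shifts from protein to membrane.
That crossover has the closed form

    C* = MW_PFAS * (B_max * rho_HSA / (MW_HSA * K_MW) - K_D)

and does not exist (membrane dominates everywhere) when the expression
is non-positive.

The basis of D (mass-concentration ratio) is a documented modelling
choice: the symbol set above fixes the units but not the basis, and a
mol/mol convention would shift every profile by a constant. See
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import BindingFit

__all__ = [
    "DistributionParams",
    "PartitionProfile",
    "d_hsa_w",
    "crossover_concentration",
    "partition_profile",
]

#: Default density of the protein phase, g/L (typical packed-protein value;
#: exposed as a parameter because measured values for an HSA-rich phase vary).
DEFAULT_RHO_HSA = 1360.0

#: Molar mass of human serum albumin, g/mol (66.4 kDa).
DEFAULT_MW_HSA = 66400.0

NG_PER_ML_TO_G_PER_L = 1e-6


@dataclass(frozen=True)
class DistributionParams:
    """Physical constants of the HSA/water distribution model."""

    mw_pfas: float
    rho_hsa: float = DEFAULT_RHO_HSA
    mw_hsa: float = DEFAULT_MW_HSA
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("mw_pfas", "rho_hsa", "mw_hsa", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PartitionProfile:
    """Per-compound log D_HSA/W over an aqueous concentration grid.

    ``grid`` is in ng/mL; ``log_kmw`` is the concentration-independent
    membrane line; ``crossover_conc`` (ng/mL) is where the two curves
    meet, or None when the membrane dominates at all concentrations.
    """

    compound: str
    grid: np.ndarray
    log_d_hsa_w: np.ndarray
    log_kmw: float
    crossover_conc: float | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        logd = np.asarray(self.log_d_hsa_w, dtype=float)
        if grid.shape != logd.shape:
            raise ValueError("grid and log_d_hsa_w must align")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(logd) > 1e-12):
            raise ValueError("log D_HSA/W must be non-increasing in concentration")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "log_d_hsa_w", logd)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound": self.compound,
                "c_aq_ng_per_ml": self.grid,
                "log_d_hsa_w": self.log_d_hsa_w,
                "log_kmw": self.log_kmw,
                "crossover_ng_per_ml": (
                    self.crossover_conc if self.crossover_conc is not None
                    else np.nan
                ),
            }
        )


def _require_converged(fit: BindingFit) -> None:
    if not fit.converged:
        raise ValueError(
            f"{fit.compound or 'fit'}: distribution model needs a converged "
            "binding fit"
        )


def d_hsa_w(fit: BindingFit, c_aq: float | np.ndarray,
            params: DistributionParams) -> float | np.ndarray:
    """Distribution coefficient D_HSA/W at aqueous concentration ``c_aq`` (g/L)."""
    _require_converged(fit)
    c_aq = np.asarray(c_aq, dtype=float)
    if np.any(c_aq < 0):
        raise ValueError("aqueous concentration must be >= 0")
    d = fit.bmax * params.rho_hsa / (
        params.mw_hsa * (fit.kd + c_aq / params.mw_pfas)
    )
    return float(d) if d.ndim == 0 else d


def crossover_concentration(fit: BindingFit, log_kmw: float,
                            params: DistributionParams) -> float | None:
    """Aqueous concentration (ng/mL) where D_HSA/W equals K_MW, or None.

    Closed form: ``C* = MW_PFAS * (B_max*rho_HSA/(MW_HSA*K_MW) - K_D)``
    in g/L, converted to ng/mL. None when C* <= 0, i.e. K_MW already
    exceeds the zero-concentration plateau of D and the decreasing curve
    can never meet it.
    """
    _require_converged(fit)
    kmw = 10.0 ** float(log_kmw)
    c_star_g_l = params.mw_pfas * (
        fit.bmax * params.rho_hsa / (params.mw_hsa * kmw) - fit.kd
    )
    if c_star_g_l <= 0:
        return None
    return c_star_g_l / NG_PER_ML_TO_G_PER_L


def partition_profile(
    fit: BindingFit,
    log_kmw: float,
    params: DistributionParams,
    grid_min: float = 0.1,
    grid_max: float = 10000.0,
    n_points: int = 100,
) -> PartitionProfile:
    """Tabulate log10 D_HSA/W against log K_MW over a log-spaced grid.

    The default grid spans 0.1-10,000 ng/mL, the range of mean PFAS
    serum concentrations reported across occupational and background
    populations.
    """
    _require_converged(fit)
    if grid_min <= 0 or grid_max <= grid_min:
        raise ValueError("need 0 < grid_min < grid_max")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.geomspace(grid_min, grid_max, n_points)
    d = d_hsa_w(fit, grid * NG_PER_ML_TO_G_PER_L, params)
    return PartitionProfile(
        compound=fit.compound,
        grid=grid,
        log_d_hsa_w=np.log10(d),
        log_kmw=float(log_kmw),
        crossover_conc=crossover_concentration(fit, log_kmw, params),
    )
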