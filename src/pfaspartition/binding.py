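"""HSA binding analysis: dialysis mass balance, Langmuir fit, affinities.

A dialysis dose ladder yields one bound-vs-free point per measurement:
the no-HSA control fixes the total recoverable PFAS per dose (which also
compensates nonspecific losses, since control and sample see the same
container surfaces), the dialysate measurement gives the free
concentration, and the deficit — divided by the moles of HSA in the cup —
is the bound amount per mole of protein, B. Fitting
``B = B_max * C / (K_D + C)`` (the single-site Langmuir isotherm) by
nonlinear least squares gives K_D and B_max; the association constant is
K_A = 1/K_D and affinities are reported as log10 K_A.

Docking free energies interconvert with affinities through
``dG = -RT ln K_A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .registry import Registry
from .synthetic import DialysisAssay

__all__ = [
    "GAS_CONSTANT_KCAL",
    "BindingPoint",
    "BindingFit",
    "bound_free_from_dialysis",
    "fit_single_site",
    "fits_to_frame",
    "group_affinity_summary",
    "delta_g_to_log_ka",
    "log_ka_to_delta_g",
]

# Molar gas constant, kcal/(mol K).
GAS_CONSTANT_KCAL = 1.98720425e-3

DEFAULT_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class BindingPoint:
    """One bound-vs-free observation.

    ``free_conc`` is the aqueous PFAS concentration at equilibrium
    (mol/L); ``bound_per_hsa`` is B, mol PFAS per mol HSA. Noise can push
    B negative at low doses; such points are kept (clipping would bias
    B_max) and ``flagged`` marks them.
    """

    free_conc: float
    bound_per_hsa: float
    dose_ratio: float

    @property
    def flagged(self) -> bool:
        return self.bound_per_hsa < 0


@dataclass(frozen=True)
class BindingFit:
    """Single-site Langmuir parameters for one compound."""

    compound: str
    kd: float
    bmax: float
    kd_se: float
    bmax_se: float
    converged: bool
    n_points: int
    message: str = ""

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.converged and self.bmax <= 0:
            raise ValueError("bmax must be positive for a converged fit")

    @property
    def ka(self) -> float:
        """Association constant, L/mol (exactly 1/K_D)."""
        return 1.0 / self.kd

    @property
    def log_ka(self) -> float:
        """log10 of K_A with K_D expressed in mol/L."""
        return -math.log10(self.kd)


def bound_free_from_dialysis(assay: DialysisAssay) -> list[BindingPoint]:
    """Convert a dialysis dose ladder into bound-vs-free points.

    Per dose the total recoverable PFAS is inferred from the no-HSA
    control, ``n_tot = control_free * V_tot`` (the control normalisation
    is what compensates nonspecific binding to the apparatus); then
    ``B = (n_tot - measured_free * V_tot) / n_HSA`` for every replicate.
    """
    des = assay.design
    v_tot = des.total_volume_l
    n_hsa = des.n_hsa_mol
    points = []
    for i, ratio in enumerate(des.ratios):
        n_tot = assay.control_free[i] * v_tot
        for j in range(assay.replicates):
            free = float(assay.measured_free[i, j])
            bound = (n_tot - free * v_tot) / n_hsa
            points.append(BindingPoint(free_conc=free, bound_per_hsa=bound,
                                       dose_ratio=ratio))
    return points


def _langmuir(c: np.ndarray, kd: float, bmax: float) -> np.ndarray:
    return bmax * c / (kd + c)


def fit_single_site(
    points: Sequence[BindingPoint],
    compound: str = "",
    n_starts: int = 5,
) -> BindingFit:
    """Fit ``B = B_max*C/(K_D + C)`` by nonlinear least squares.

    Positivity is enforced by optimising over (log10 K_D, log10 B_max).
    The optimiser is restarted from ``n_starts`` log-spaced K_D initials
    bracketing the observed free-concentration range (generously, one
    decade below to two above) and the lowest-SSE solution wins.
    Negative bound points participate in the SSE unclipped. On optimiser
    failure the fit is returned with ``converged=False`` and diagnostics
    rather than raising.
    """
    usable = [p for p in points if p.free_conc > 0]
    if len(usable) < 3:
        raise ValueError(
            f"single-site fit needs >= 3 points with positive free "
            f"concentration, got {len(usable)}"
        )
    c = np.array([p.free_conc for p in usable])
    b = np.array([p.bound_per_hsa for p in usable])

    def residuals(theta: np.ndarray) -> np.ndarray:
        kd, bmax = 10.0 ** theta
        return _langmuir(c, kd, bmax) - b

    lo, hi = math.log10(c.min()) - 1.0, math.log10(c.max()) + 2.0
    kd_starts = np.linspace(lo, hi, n_starts)
    bmax_start = math.log10(max(b.max(), 1e-3))
    bounds = ([-14.0, -4.0], [2.0, 3.0])

    best = None
    for kd0 in kd_starts:
        try:
            sol = least_squares(
                residuals,
                x0=[kd0, bmax_start],
                bounds=bounds,
                method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None or not best.success:
        return BindingFit(
            compound=compound, kd=1.0, bmax=1.0, kd_se=math.nan,
            bmax_se=math.nan, converged=False, n_points=len(usable),
            message="optimizer failed from every start",
        )

    log_kd, log_bmax = best.x
    kd, bmax = 10.0 ** log_kd, 10.0 ** log_bmax

    # Covariance in log-parameter space from the Jacobian; delta method
    # back to the natural scale.
    kd_se = bmax_se = math.nan
    dof = len(usable) - 2
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (2.0 * best.cost / dof)
            diag = np.diag(cov)
            if np.all(diag >= 0):
                log_kd_se, log_bmax_se = np.sqrt(diag)
                kd_se = kd * math.log(10.0) * float(log_kd_se)
                bmax_se = bmax * math.log(10.0) * float(log_bmax_se)
        except np.linalg.LinAlgError:
            pass

    return BindingFit(
        compound=compound, kd=float(kd), bmax=float(bmax),
        kd_se=kd_se, bmax_se=bmax_se, converged=True,
        n_points=len(usable),
    )


def fits_to_frame(fits: Sequence[BindingFit]) -> pd.DataFrame:
    """Tabular view of binding fits for CSV export."""
    return pd.DataFrame(
        [
            {
                "compound": f.compound,
                "kd": f.kd,
                "kd_se": f.kd_se,
                "bmax": f.bmax,
                "bmax_se": f.bmax_se,
                "log_ka": f.log_ka,
                "converged": f.converged,
                "n_points": f.n_points,
            }
            for f in fits
        ]
    )


def group_affinity_summary(
    fits: Sequence[BindingFit],
    registry: Registry,
) -> pd.DataFrame:
    """Per-group affinity summary, ranked by median log10 K_A.

    Returns one row per structural group with the median and quartiles of
    log K_A over converged fits, the strongest-binding compound and its
    fluorinated-carbon count. Groups tie-broken alphabetically (the order
    column makes ranking explicit); groups with no converged fit are
    listed in ``attrs["omitted"]``.
    """
    if not fits:
        raise ValueError("no binding fits supplied")
    rows = []
    for f in fits:
        comp = registry.lookup(f.compound)
        if f.converged:
            rows.append(
                {"group": comp.group, "compound": f.compound,
                 "log_ka": f.log_ka, "fc_n": comp.fc_n}
            )
    if not rows:
        raise ValueError("no converged fits to summarise")
    df = pd.DataFrame(rows)
    summaries = []
    for group, sub in df.groupby("group"):
        top = sub.loc[sub["log_ka"].idxmax()]
        summaries.append(
            {
                "group": group,
                "n": len(sub),
                "median_log_ka": sub["log_ka"].median(),
                "q1_log_ka": sub["log_ka"].quantile(0.25),
                "q3_log_ka": sub["log_ka"].quantile(0.75),
                "top_compound": top["compound"],
                "top_fc_n": int(top["fc_n"]),
                "top_log_ka": top["log_ka"],
            }
        )
    out = pd.DataFrame(summaries).sort_values(
        ["median_log_ka", "group"], ascending=[False, True]
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    seen = set(df["group"])
    all_groups = {registry.lookup(f.compound).group for f in fits}
    out.attrs["omitted"] = sorted(all_groups - seen)
    out.attrs["tie_break"] = "alphabetical by group label"
    return out


def delta_g_to_log_ka(delta_g: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """log10 K_A from a binding free energy (kcal/mol) via dG = -RT ln K_A."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return -delta_g / (math.log(10.0) * GAS_CONSTANT_KCAL * temperature)


def log_ka_to_delta_g(log_ka: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Binding free energy (kcal/mol) from log10 K_A; inverse of the above."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return -log_ka * math.log(10.0) * GAS_CONSTANT_KCAL * temperature
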