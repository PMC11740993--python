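"""Membrane-water partition coefficient (K_MW) estimation from SSLM assays.

The SSLM assay measures depletion: the mass moved into the phospholipid
membrane is the spiked mass minus what remains in the water (and, for the
rinse-corrected workflow, minus what the methanol container rinse
recovers from the vial wall). K_MW is then the slope of membrane mass
against ``C_aq * V_lipid`` across the six vials — a regression through
the origin, since zero aqueous concentration implies zero membrane load.

Chain-length trends (log10 K_MW per fluorinated carbon) are ordinary
least squares over a homologous series, and the pH comparison pairs the
same compounds measured under two conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .registry import Registry
from .synthetic import SSLMAssay

__all__ = [
    "KmwEstimate",
    "TrendFit",
    "KmwEstimationError",
    "estimate_log_kmw",
    "estimates_to_frame",
    "fit_chain_length_trend",
    "compare_ph",
]

Method = Literal["mass_balance", "rinse_corrected"]


class KmwEstimationError(ValueError):
    """No quantifiable membrane partitioning in an assay."""


@dataclass(frozen=True)
class KmwEstimate:
    """Fitted log10 K_MW for one compound at one pH.

    ``per_vial`` holds the per-measurement implied log10 K_MW values for
    diagnostics; ``n_dropped`` counts measurements excluded because the
    implied membrane mass was non-positive.
    """

    compound: str
    log_kmw: float
    se: float
    method: Method
    ph: float
    per_vial: tuple[float, ...]
    n_points: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")
        if self.n_points < 1:
            raise ValueError("need at least one usable measurement")


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of log10 K_MW on fluorinated-carbon count for one class."""

    class_label: str
    slope: float
    slope_se: float
    intercept: float
    r2: float
    n_compounds: int

    def __post_init__(self) -> None:
        if self.n_compounds < 3:
            raise ValueError("trend fit needs >= 3 compounds")
        if not -1e-9 <= self.r2 <= 1 + 1e-9:
            raise ValueError("r2 outside [0, 1]")


def estimate_log_kmw(assay: SSLMAssay, method: Method = "mass_balance") -> KmwEstimate:
    """Estimate log10 K_MW from one SSLM series.

    Per measurement the membrane mass is
    ``M_mem = spike - C_aq*V_water`` (``mass_balance``) or
    ``M_mem = spike - C_aq*V_water - rinse`` (``rinse_corrected``);
    K_MW is the zero-intercept least-squares slope of M_mem on
    ``C_aq * V_lipid`` pooled over vials and replicates. Measurements
    with non-positive M_mem are dropped (noise can push the implied
    membrane mass negative for weak partitioning) and counted.

    Raises :class:`KmwEstimationError` when no measurement carries a
    positive membrane mass or the pooled slope is non-positive — the
    compound's partitioning is then below what the assay can quantify.
    """
    if method not in ("mass_balance", "rinse_corrected"):
        raise ValueError(f"unknown method {method!r}")
    if method == "rinse_corrected" and assay.rinse_mass is None:
        raise ValueError("rinse_corrected requires rinse masses in the assay")

    lay = assay.layout
    v_lip_ml = np.asarray(lay.lipid_volumes) * 1e-3
    c_aq = assay.measured_aqueous  # (vials, reps)
    m_mem = lay.spike_mass - c_aq * lay.water_volume
    if method == "rinse_corrected":
        m_mem = m_mem - assay.rinse_mass
    x = c_aq * v_lip_ml[:, None]  # ng * (mL lipid / mL water)

    usable = (m_mem > 0) & (c_aq > 0)
    n_total = m_mem.size
    n_dropped = int(n_total - usable.sum())
    if not usable.any():
        raise KmwEstimationError(
            f"{assay.compound}: no vial shows quantifiable membrane partitioning"
        )

    xs, ys = x[usable], m_mem[usable]
    sxx = float(np.sum(xs * xs))
    kmw = float(np.sum(xs * ys) / sxx)
    if kmw <= 0:
        raise KmwEstimationError(
            f"{assay.compound}: pooled membrane-mass slope is non-positive"
        )

    # Slope se from the zero-intercept regression residuals; delta method
    # to the log10 scale.
    n_used = int(usable.sum())
    if n_used > 1:
        resid = ys - kmw * xs
        sigma2 = float(np.sum(resid**2) / (n_used - 1))
        slope_se = math.sqrt(sigma2 / sxx)
    else:
        slope_se = 0.0
    log_se = slope_se / (kmw * math.log(10.0))

    per_vial = tuple(np.log10(ys / xs))
    return KmwEstimate(
        compound=assay.compound,
        log_kmw=math.log10(kmw),
        se=log_se,
        method=method,
        ph=lay.ph,
        per_vial=per_vial,
        n_points=n_used,
        n_dropped=n_dropped,
    )


def estimates_to_frame(estimates: Sequence[KmwEstimate]) -> pd.DataFrame:
    """Tabular view of estimates for CSV export."""
    return pd.DataFrame(
        [
            {
                "compound": e.compound,
                "ph": e.ph,
                "method": e.method,
                "log_kmw": e.log_kmw,
                "se": e.se,
                "n_points": e.n_points,
                "n_dropped": e.n_dropped,
            }
            for e in estimates
        ]
    )


def fit_chain_length_trend(
    estimates: Sequence[KmwEstimate],
    registry: Registry,
    class_label: str,
) -> TrendFit:
    """OLS of log10 K_MW on fluorinated-carbon count within one class.

    Uses every estimate whose compound resolves to ``class_label`` in the
    registry (synthetic homolog acronyms of the form ``<class>-FC<n>``
    are understood as well). Order of the input does not affect the fit.
    """
    points = []
    for est in estimates:
        if est.compound in registry:
            comp = registry.lookup(est.compound)
            if comp.group != class_label:
                continue
            fc = comp.fc_n
        elif est.compound.startswith(f"{class_label}-FC"):
            fc = int(est.compound.rsplit("FC", 1)[1])
        else:
            continue
        points.append((fc, est.log_kmw))
    if len(points) < 3:
        raise ValueError(
            f"chain-length trend for {class_label!r} needs >= 3 estimated "
            f"compounds, got {len(points)}"
        )
    points.sort()
    fc_n = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points])
    res = stats.linregress(fc_n, y)
    return TrendFit(
        class_label=class_label,
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r2=min(float(res.rvalue**2), 1.0),
        n_compounds=len(points),
    )


def compare_ph(
    estimates_a: Sequence[KmwEstimate],
    estimates_b: Sequence[KmwEstimate],
) -> pd.DataFrame:
    """Pair estimates of shared compounds and difference them (a - b).

    Returns a table with per-compound ``delta_log_kmw = a - b`` and the
    propagated standard error ``sqrt(se_a^2 + se_b^2)``; compounds present
    in only one input are listed in the frame's ``attrs["skipped"]``. The
    sign convention (a minus b) is recorded in ``attrs["convention"]``.
    """
    by_a = {e.compound: e for e in estimates_a}
    by_b = {e.compound: e for e in estimates_b}
    shared = sorted(by_a.keys() & by_b.keys())
    if not shared:
        raise ValueError("no shared compounds between the two estimate sets")
    rows = []
    for acronym in shared:
        ea, eb = by_a[acronym], by_b[acronym]
        rows.append(
            {
                "compound": acronym,
                "ph_a": ea.ph,
                "ph_b": eb.ph,
                "delta_log_kmw": ea.log_kmw - eb.log_kmw,
                "se": math.sqrt(ea.se**2 + eb.se**2),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = sorted(by_a.keys() ^ by_b.keys())
    out.attrs["convention"] = "delta_log_kmw = a - b"
    return out
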