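"""Seeded forward simulators of the two in-vitro assays.

Two experiment types are emulated with known ground truth so every
estimator in the package can be exercised against planted parameters:

* a solid-supported lipid membrane (SSLM) depletion series — six vials
  with increasing phospholipid volume, each spiked with the same PFAS
  mass; the aqueous concentration remaining at equilibrium encodes the
  membrane-water partition coefficient K_MW through the closed mass
  balance ``spike = C_aq*V_water + K_MW*C_aq*V_lipid + loss``;

* an equilibrium-dialysis ladder — a 1.0 mL sample compartment dialysing
  against a 0.1 mL cup of 1.0 uM human serum albumin at PFAS:HSA molar
  ratios 1:16 ... 2:1, where the free concentration equalises across the
  membrane and the bound amount follows the single-site Langmuir isotherm
  ``B = B_max*C/(K_D + C)``.

Measurement noise is multiplicative lognormal, parameterised so the
*median* of the measured value equals the noiseless value (log-scale
estimators then see symmetric, zero-median errors). An optional
container-surface loss diverts a fraction of the aqueous (unbound) mass
to the vial wall and records it as a methanol-rinse mass, emulating the
nonspecific sorption that affects the highly hydrophobic compounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import Compound, Registry, load_registry, parse_formula

__all__ = [
    "SSLMLayout",
    "SSLMAssay",
    "DialysisDesign",
    "DialysisAssay",
    "default_layout",
    "simulate_sslm",
    "simulate_dialysis",
    "make_series_preset",
    "TEXT_LOG_KMW",
    "default_true_log_kmw",
    "default_binding_truth",
    "sslm_to_frame",
    "sslm_from_frame",
    "dialysis_to_frame",
    "dialysis_from_frame",
    "save_sslm_assays",
    "load_sslm_assays",
    "save_dialysis_assays",
    "load_dialysis_assays",
]

# Log K_MW values the study reports in its text for named compounds.
TEXT_LOG_KMW: dict[str, float] = {"6:2 diPAP": 4.1, "8:2 diPAP": 4.4}

# Per-CF2 increments of log10 K_MW for the two homologous acid series.
PFCA_SLOPE = 0.36
PFSA_SLOPE = 0.37


@dataclass(frozen=True)
class SSLMLayout:
    """Vial layout of one SSLM dilution series.

    ``lipid_volumes`` are per-vial phospholipid volumes in uL (strictly
    increasing); ``water_volume`` is the aqueous volume per vial in mL and
    ``spike_mass`` the PFAS mass spiked per vial in ng.
    """

    lipid_volumes: tuple[float, ...]
    water_volume: float = 0.05
    spike_mass: float = 10.0
    ph: float = 7.0

    def __post_init__(self) -> None:
        vols = np.asarray(self.lipid_volumes, dtype=float)
        if vols.size == 0 or np.any(vols <= 0):
            raise ValueError("lipid volumes must be positive")
        if np.any(np.diff(vols) <= 0):
            raise ValueError("lipid volumes must be strictly increasing")
        if self.water_volume <= 0:
            raise ValueError("water volume must be positive")
        if self.spike_mass <= 0:
            raise ValueError("spike mass must be positive")
        object.__setattr__(self, "lipid_volumes", tuple(float(v) for v in vols))


def default_layout(ph: float = 7.0, water_volume: float = 0.05,
                   spike_mass: float = 10.0) -> SSLMLayout:
    """Six-vial geometric lipid ladder spanning 0.067-2.166 uL."""
    vols = np.geomspace(0.067, 2.166, 6)
    return SSLMLayout(lipid_volumes=tuple(vols), water_volume=water_volume,
                      spike_mass=spike_mass, ph=ph)


@dataclass(frozen=True)
class SSLMAssay:
    """One compound's measured SSLM series.

    ``measured_aqueous`` has shape (n_vials, n_replicates), ng/mL;
    ``rinse_mass`` (same shape, ng) is present only when the container
    rinse workflow was run. ``truth`` carries the planted parameters for
    simulated assays and is absent for real data.
    """

    compound: str
    layout: SSLMLayout
    measured_aqueous: np.ndarray
    rinse_mass: np.ndarray | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        meas = np.atleast_2d(np.asarray(self.measured_aqueous, dtype=float))
        if meas.shape[0] != len(self.layout.lipid_volumes):
            raise ValueError("measured_aqueous rows must match vial count")
        if np.any(meas < 0):
            raise ValueError("measured aqueous concentrations must be >= 0")
        object.__setattr__(self, "measured_aqueous", meas)
        if self.rinse_mass is not None:
            rinse = np.atleast_2d(np.asarray(self.rinse_mass, dtype=float))
            if rinse.shape != meas.shape:
                raise ValueError("rinse_mass shape must match measured_aqueous")
            object.__setattr__(self, "rinse_mass", rinse)

    @property
    def replicates(self) -> int:
        return self.measured_aqueous.shape[1]


@dataclass(frozen=True)
class DialysisDesign:
    """Equilibrium-dialysis design: volumes in mL, HSA in uM in the cup."""

    sample_volume: float = 1.0
    cup_volume: float = 0.1
    hsa_conc: float = 1.0
    ratios: tuple[float, ...] = (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 2.0)
    equilibration_h: float = 48.0

    def __post_init__(self) -> None:
        if self.sample_volume <= 0 or self.cup_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.hsa_conc <= 0:
            raise ValueError("HSA concentration must be positive")
        ratios = tuple(float(r) for r in self.ratios)
        if any(r <= 0 for r in ratios) or len(set(ratios)) != len(ratios):
            raise ValueError("dose ratios must be positive and distinct")
        object.__setattr__(self, "ratios", ratios)

    @property
    def total_volume_l(self) -> float:
        """Total free-solution volume (sample + cup), litres."""
        return (self.sample_volume + self.cup_volume) * 1e-3

    @property
    def n_hsa_mol(self) -> float:
        """Moles of HSA in the cup."""
        return self.hsa_conc * 1e-6 * self.cup_volume * 1e-3


@dataclass(frozen=True)
class DialysisAssay:
    """One compound's dialysis dose ladder.

    ``measured_free`` has shape (n_doses, n_replicates), mol/L;
    ``control_free`` is the per-dose no-HSA spike concentration, mol/L.
    """

    compound: str
    design: DialysisDesign
    measured_free: np.ndarray
    control_free: np.ndarray
    truth: dict | None = None

    def __post_init__(self) -> None:
        meas = np.atleast_2d(np.asarray(self.measured_free, dtype=float))
        ctrl = np.asarray(self.control_free, dtype=float)
        if meas.shape[0] != len(self.design.ratios):
            raise ValueError("measured_free rows must match dose count")
        if ctrl.shape != (meas.shape[0],):
            raise ValueError("control_free must have one value per dose")
        if np.any(meas < 0) or np.any(ctrl <= 0):
            raise ValueError("concentrations must be non-negative (controls positive)")
        object.__setattr__(self, "measured_free", meas)
        object.__setattr__(self, "control_free", ctrl)

    @property
    def replicates(self) -> int:
        return self.measured_free.shape[1]


def _lognormal_factor(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    # Median-one multiplicative noise: exp(sd * Z), Z ~ N(0, 1).
    if sd == 0:
        return np.ones(shape)
    return np.exp(sd * rng.standard_normal(shape))


def simulate_sslm(
    compound: Compound | str,
    true_log_kmw: float,
    layout: SSLMLayout | None = None,
    noise_sd: float = 0.05,
    surface_loss_frac: float = 0.0,
    seed: int | None = None,
    replicates: int = 3,
) -> SSLMAssay:
    """Simulate one SSLM depletion series with planted log10 K_MW.

    Per vial the noiseless aqueous concentration solves the closed mass
    balance ``spike = C*V_water + K_MW*C*V_lipid + loss`` with
    ``loss = surface_loss_frac * C * V_water`` (sorption of unbound mass
    to the container wall); the loss is recorded as the methanol-rinse
    mass. Median-one lognormal noise is then applied to the measured
    aqueous concentrations and rinse masses. Same seed, same output.
    """
    if not 0 <= surface_loss_frac < 1:
        raise ValueError("surface_loss_frac must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    layout = layout or default_layout()
    acronym = compound.acronym if isinstance(compound, Compound) else str(compound)

    kmw = 10.0 ** float(true_log_kmw)
    v_lip_ml = np.asarray(layout.lipid_volumes) * 1e-3  # uL -> mL
    denom = layout.water_volume * (1.0 + surface_loss_frac) + kmw * v_lip_ml
    c_aq = layout.spike_mass / denom  # ng/mL, noiseless
    loss = surface_loss_frac * c_aq * layout.water_volume  # ng per vial

    rng = np.random.default_rng(seed)
    shape = (len(v_lip_ml), replicates)
    measured = c_aq[:, None] * _lognormal_factor(rng, noise_sd, shape)
    rinse = loss[:, None] * _lognormal_factor(rng, noise_sd, shape)

    truth = {
        "true_log_kmw": float(true_log_kmw),
        "surface_loss_frac": float(surface_loss_frac),
        "noise_sd": float(noise_sd),
    }
    return SSLMAssay(
        compound=acronym,
        layout=layout,
        measured_aqueous=measured,
        rinse_mass=rinse,
        truth=truth,
    )


def _equilibrium_free_conc(n_tot: float, kd: float, bmax: float,
                           n_hsa: float, v_tot: float) -> float:
    """Positive root of the dialysis mass balance.

    Solves ``n_tot = C*V_tot + n_HSA*B_max*C/(kd + C)`` for the free
    concentration C (mol/L), i.e. the quadratic
    ``V_tot*C^2 + (V_tot*kd + n_HSA*B_max - n_tot)*C - n_tot*kd = 0``.
    """
    a = v_tot
    b = v_tot * kd + n_hsa * bmax - n_tot
    c = -n_tot * kd
    # c < 0 guarantees one positive root; this form avoids cancellation.
    disc = math.sqrt(b * b - 4.0 * a * c)
    if b <= 0:
        return (-b + disc) / (2.0 * a)
    return (2.0 * -c) / (b + disc)


def simulate_dialysis(
    compound: Compound | str,
    true_kd: float,
    bmax: float,
    design: DialysisDesign | None = None,
    noise_sd: float = 0.05,
    seed: int | None = None,
    replicates: int = 2,
) -> DialysisAssay:
    """Simulate one equilibrium-dialysis dose ladder.

    For each PFAS:HSA dose ratio the total PFAS distributes between the
    uniform free solution (sample + cup volume) and the HSA-bound pool
    following the single-site Langmuir isotherm; the noiseless free
    concentration is the positive root of the resulting quadratic.
    Controls (no HSA) give ``n_tot / V_tot`` exactly; median-one lognormal
    noise is applied to the measured free concentrations.
    """
    if true_kd <= 0 or bmax <= 0:
        raise ValueError("true_kd and bmax must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    design = design or DialysisDesign()
    acronym = compound.acronym if isinstance(compound, Compound) else str(compound)

    v_tot = design.total_volume_l
    n_hsa = design.n_hsa_mol
    free = np.array(
        [
            _equilibrium_free_conc(r * n_hsa, true_kd, bmax, n_hsa, v_tot)
            for r in design.ratios
        ]
    )
    control = np.array([r * n_hsa / v_tot for r in design.ratios])

    rng = np.random.default_rng(seed)
    shape = (len(design.ratios), replicates)
    measured = free[:, None] * _lognormal_factor(rng, noise_sd, shape)

    truth = {"true_kd": float(true_kd), "bmax": float(bmax),
             "noise_sd": float(noise_sd)}
    return DialysisAssay(
        compound=acronym,
        design=design,
        measured_free=measured,
        control_free=control,
        truth=truth,
    )


def _homolog_compound(class_label: str, fc: int, registry: Registry) -> Compound:
    """Registry entry for (class, fc) if unique, else a synthesised homolog."""
    members = [c for c in registry.group(class_label) if c.fc_n == fc]
    if len(members) == 1:
        return members[0]
    n = fc + 1 if class_label == "PFCA" else fc
    if class_label == "PFCA":
        formula = f"C{n}F{2 * n - 1}O2"
        headgroup = "carboxylate"
    else:
        formula = f"C{n}F{2 * n + 1}O3S"
        headgroup = "sulfonate"
    return Compound(
        acronym=f"{class_label}-FC{fc}",
        name=f"synthetic {class_label} homolog with {fc} fluorinated carbons",
        group=class_label,
        fc_n=fc,
        total_carbons=n,
        molecular_formula=parse_formula(formula),
        species="anion",
        headgroup=headgroup,
    )


def make_series_preset(
    class_label: str,
    fc_range: tuple[int, int] | None = None,
    slope: float | None = None,
    intercept: float = -1.0,
    registry: Registry | None = None,
) -> list[tuple[Compound, float]]:
    """Homologous series with planted linear chain-length trend.

    ``true_log_kmw = intercept + slope * fc_n`` for every fluorinated-carbon
    count in ``fc_range`` (inclusive). The PFCA preset defaults to the
    carboxylate series FC3-FC15 with slope 0.36 log-units per CF2; the
    PFSA preset to the sulfonate series FC4-FC11 with slope 0.37. Output
    is deterministic. ``custom`` requires explicit ``slope``/``fc_range``
    and raises, since no homologous series is defined for it.
    """
    presets = {"PFCA": (PFCA_SLOPE, (3, 15)), "PFSA": (PFSA_SLOPE, (4, 11))}
    if class_label not in presets:
        raise ValueError(
            f"no homologous-series preset for class {class_label!r}; "
            "use 'PFCA' or 'PFSA'"
        )
    default_slope, default_range = presets[class_label]
    slope = default_slope if slope is None else float(slope)
    lo, hi = fc_range if fc_range is not None else default_range
    if lo > hi or lo < 1:
        raise ValueError(f"invalid fc_range ({lo}, {hi})")
    registry = registry or load_registry()
    covered = [c.fc_n for c in registry.group(class_label)]
    if lo < min(covered) - 1 or hi > max(covered) + 1:
        raise ValueError(
            f"fc_range ({lo}, {hi}) outside registry coverage for {class_label}"
        )
    return [
        (_homolog_compound(class_label, fc, registry),
         intercept + slope * fc)
        for fc in range(lo, hi + 1)
    ]


# --------------------------------------------------------------------------
# Default ground-truth scenario for whole-registry simulations.
#
# The study prints per-compound values only for a few compounds; full-registry
# pipeline runs therefore use a documented synthetic scenario: log K_MW rises
# linearly in FC_n with the published per-CF2 slopes and a headgroup-dependent
# intercept, and HSA affinities follow the observed group ordering
# (sulfonates strongest, sulfonamides weakest) with a mild chain-length bump.

_KMW_INTERCEPTS = {
    "carboxylate": -1.0,
    "sulfonate": -1.0,
    "sulfonamide": -1.3,
    "alcohol": -1.1,
    "phosphate": -1.0,
    "betaine/zwitterion": -1.4,
    "other": -1.0,
}

_LOG_KA_BASE = {
    "PFSA": 6.3, "ESA": 6.1, "FTS": 6.0, "FTCA": 5.7, "FTUCA": 5.5,
    "diPAP": 5.2, "PFECA": 5.2, "PFCA": 5.0, "PFOSAA": 4.7,
    "PFOSAm": 4.4, "PFOSE": 4.3, "Other": 5.5,
}


def default_true_log_kmw(compound: Compound) -> float:
    """Scenario truth for log10 K_MW (text values where the study prints them)."""
    if compound.acronym in TEXT_LOG_KMW:
        return TEXT_LOG_KMW[compound.acronym]
    slope = PFSA_SLOPE if compound.headgroup == "sulfonate" else PFCA_SLOPE
    intercept = _KMW_INTERCEPTS[compound.headgroup]
    fc = min(compound.fc_n, 16)
    return intercept + slope * fc


def default_binding_truth(compound: Compound) -> tuple[float, float]:
    """Scenario truth ``(kd mol/L, bmax mol/mol)`` for HSA binding."""
    log_ka = _LOG_KA_BASE[compound.group] + 0.1 * (min(compound.fc_n, 8) - 4)
    return 10.0 ** (-log_ka), 1.0


# --------------------------------------------------------------------------
# Tidy CSV serialisation (one row per vial/dose x replicate) with a JSON
# sidecar holding the planted truth, so estimator tests can read ground truth
# separately from the measurements.


def sslm_to_frame(assays: Sequence[SSLMAssay]) -> pd.DataFrame:
    rows = []
    for assay in assays:
        lay = assay.layout
        for i, v_lip in enumerate(lay.lipid_volumes):
            for j in range(assay.replicates):
                row = {
                    "compound": assay.compound,
                    "ph": lay.ph,
                    "vial": i + 1,
                    "replicate": j + 1,
                    "lipid_volume_ul": v_lip,
                    "water_volume_ml": lay.water_volume,
                    "spike_mass_ng": lay.spike_mass,
                    "measured_aqueous_ng_ml": assay.measured_aqueous[i, j],
                    "rinse_mass_ng": (
                        assay.rinse_mass[i, j] if assay.rinse_mass is not None
                        else np.nan
                    ),
                }
                rows.append(row)
    return pd.DataFrame(rows)


def sslm_from_frame(df: pd.DataFrame) -> list[SSLMAssay]:
    required = {
        "compound", "ph", "vial", "replicate", "lipid_volume_ul",
        "water_volume_ml", "spike_mass_ng", "measured_aqueous_ng_ml",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SSLM table missing columns {sorted(missing)}")
    assays = []
    for (acronym, ph), sub in df.groupby(["compound", "ph"], sort=False):
        piv = sub.pivot_table(
            index="vial", columns="replicate",
            values="measured_aqueous_ng_ml", sort=True
        )
        vial_info = sub.drop_duplicates("vial").sort_values("vial")
        layout = SSLMLayout(
            lipid_volumes=tuple(vial_info["lipid_volume_ul"]),
            water_volume=float(vial_info["water_volume_ml"].iloc[0]),
            spike_mass=float(vial_info["spike_mass_ng"].iloc[0]),
            ph=float(ph),
        )
        rinse = None
        if "rinse_mass_ng" in sub.columns and sub["rinse_mass_ng"].notna().all():
            rinse = sub.pivot_table(
                index="vial", columns="replicate",
                values="rinse_mass_ng", sort=True
            ).to_numpy()
        assays.append(
            SSLMAssay(
                compound=str(acronym), layout=layout,
                measured_aqueous=piv.to_numpy(), rinse_mass=rinse,
            )
        )
    return assays


def dialysis_to_frame(assays: Sequence[DialysisAssay]) -> pd.DataFrame:
    rows = []
    for assay in assays:
        des = assay.design
        for i, ratio in enumerate(des.ratios):
            for j in range(assay.replicates):
                rows.append(
                    {
                        "compound": assay.compound,
                        "dose_ratio": ratio,
                        "replicate": j + 1,
                        "sample_volume_ml": des.sample_volume,
                        "cup_volume_ml": des.cup_volume,
                        "hsa_conc_um": des.hsa_conc,
                        "measured_free_mol_l": assay.measured_free[i, j],
                        "control_free_mol_l": assay.control_free[i],
                    }
                )
    return pd.DataFrame(rows)


def dialysis_from_frame(df: pd.DataFrame) -> list[DialysisAssay]:
    required = {
        "compound", "dose_ratio", "replicate", "sample_volume_ml",
        "cup_volume_ml", "hsa_conc_um", "measured_free_mol_l",
        "control_free_mol_l",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dialysis table missing columns {sorted(missing)}")
    assays = []
    for acronym, sub in df.groupby("compound", sort=False):
        doses = sub.drop_duplicates("dose_ratio").sort_values("dose_ratio")
        design = DialysisDesign(
            sample_volume=float(doses["sample_volume_ml"].iloc[0]),
            cup_volume=float(doses["cup_volume_ml"].iloc[0]),
            hsa_conc=float(doses["hsa_conc_um"].iloc[0]),
            ratios=tuple(doses["dose_ratio"]),
        )
        piv = sub.pivot_table(
            index="dose_ratio", columns="replicate",
            values="measured_free_mol_l", sort=True
        )
        assays.append(
            DialysisAssay(
                compound=str(acronym), design=design,
                measured_free=piv.to_numpy(),
                control_free=doses["control_free_mol_l"].to_numpy(),
            )
        )
    return assays


def _save_with_truth(df: pd.DataFrame, truths: dict, path: str | Path) -> None:
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".truth.json")
    with open(sidecar, "w", encoding="utf-8") as handle:
        json.dump(truths, handle, indent=1, sort_keys=True)


def save_sslm_assays(assays: Sequence[SSLMAssay], path: str | Path) -> None:
    truths = {a.compound: a.truth for a in assays if a.truth is not None}
    _save_with_truth(sslm_to_frame(assays), truths, path)


def load_sslm_assays(path: str | Path) -> list[SSLMAssay]:
    assays = sslm_from_frame(pd.read_csv(path))
    sidecar = Path(path).with_suffix(".truth.json")
    if sidecar.exists():
        truths = json.loads(sidecar.read_text(encoding="utf-8"))
        assays = [replace(a, truth=truths.get(a.compound)) for a in assays]
    return assays


def save_dialysis_assays(assays: Sequence[DialysisAssay], path: str | Path) -> None:
    truths = {a.compound: a.truth for a in assays if a.truth is not None}
    _save_with_truth(dialysis_to_frame(assays), truths, path)


def load_dialysis_assays(path: str | Path) -> list[DialysisAssay]:
    assays = dialysis_from_frame(pd.read_csv(path))
    sidecar = Path(path).with_suffix(".truth.json")
    if sidecar.exists():
        truths = json.loads(sidecar.read_text(encoding="utf-8"))
        assays = [replace(a, truth=truths.get(a.compound)) for a in assays]
    return assays
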