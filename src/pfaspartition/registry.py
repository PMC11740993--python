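"""Registry of the 60 target PFAS with structural metadata.

Each compound carries its structural group, the number of fluorinated
carbon atoms (FC_n, the chain-length covariate used throughout the
partitioning trend analyses), an element-count formula and the molar mass
derived from it. Acids are stored as their deprotonated anions, matching
the aqueous speciation assumed for strong perfluoroalkyl acids; weak-acid
sulfonamides and the sulfonamidoethanols are stored neutral, and betaines
as net-neutral zwitterions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "ATOMIC_MASSES",
    "Compound",
    "Registry",
    "load_registry",
    "molar_mass",
    "parse_formula",
]

# IUPAC 2021 standard atomic weights, g/mol (conventional values).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.90447,
    "Na": 22.98976928,
    "K": 39.0983,
}

GROUPS = frozenset(
    {
        "PFCA", "PFSA", "FTS", "PFOSAm", "PFOSAA", "PFOSE",
        "PFECA", "ESA", "FTCA", "FTUCA", "diPAP", "Other",
    }
)

HEADGROUPS = frozenset(
    {
        "carboxylate", "sulfonate", "phosphate", "sulfonamide",
        "betaine/zwitterion", "alcohol", "other",
    }
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string (e.g. ``C8F15O2``) into counts."""
    if not formula or not formula.strip():
        raise ValueError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula.strip()):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
        pos = match.end()
        symbol, digits = match.groups()
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(formula.strip()):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molar_mass(formula: Mapping[str, int] | str) -> float:
    """Molar mass (g/mol) of an element-count map or formula string.

    Raises ``ValueError`` naming the offending symbol if an element is not
    in the atomic-mass table.
    """
    counts = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    if not counts:
        raise ValueError("empty molecular formula")
    total = 0.0
    for symbol, n in counts.items():
        try:
            total += ATOMIC_MASSES[symbol] * n
        except KeyError:
            raise ValueError(f"unknown element symbol: {symbol!r}") from None
    return total


@dataclass(frozen=True)
class Compound:
    """One registry entry.

    ``fc_n`` counts fluorinated carbon atoms; ``molecular_formula`` is the
    element-count map of the species given by ``species`` (anion for strong
    acids, neutral or zwitterion otherwise). ``hydrophobic_flag`` marks the
    highly hydrophobic members whose membrane assays need the methanol
    container-rinse correction.
    """

    acronym: str
    name: str
    group: str
    fc_n: int
    total_carbons: int
    molecular_formula: Mapping[str, int]
    species: str = "anion"
    hydrophobic_flag: bool = False
    headgroup: str = "other"
    casrn: str | None = None
    mw: float = field(init=False)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.acronym}: unknown group {self.group!r}")
        if self.headgroup not in HEADGROUPS:
            raise ValueError(f"{self.acronym}: unknown headgroup {self.headgroup!r}")
        if not (1 <= self.fc_n <= self.total_carbons):
            raise ValueError(
                f"{self.acronym}: fc_n={self.fc_n} outside [1, {self.total_carbons}]"
            )
        object.__setattr__(self, "mw", molar_mass(self.molecular_formula))
        if self.mw <= 0:
            raise ValueError(f"{self.acronym}: non-positive molar mass")

    def neutral_mw(self) -> float:
        """Molar mass of the neutral (protonated) form.

        For anions this adds one hydrogen per negative charge (all acids in
        the registry are monoprotic except the diPAP phosphate diesters,
        which are also singly deprotonated); neutral and zwitterionic
        species are returned unchanged.
        """
        if self.species == "anion":
            counts = dict(self.molecular_formula)
            counts["H"] = counts.get("H", 0) + 1
            return molar_mass(counts)
        return self.mw


class Registry:
    """Lookup table of compounds keyed by acronym."""

    def __init__(self, compounds: list[Compound]):
        self._by_acronym: dict[str, Compound] = {}
        for c in compounds:
            if c.acronym in self._by_acronym:
                raise ValueError(f"duplicate acronym in registry: {c.acronym!r}")
            self._by_acronym[c.acronym] = c

    def __len__(self) -> int:
        return len(self._by_acronym)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_acronym.values())

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._by_acronym

    def lookup(self, acronym: str) -> Compound:
        try:
            return self._by_acronym[acronym]
        except KeyError:
            raise KeyError(f"compound not found in registry: {acronym!r}") from None

    __getitem__ = lookup

    def group(self, label: str) -> list[Compound]:
        """All compounds of one structural group, in registry order."""
        if label not in GROUPS:
            raise ValueError(f"unknown group {label!r}")
        return [c for c in self if c.group == label]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self:
            counts[c.group] = counts.get(c.group, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (one row per compound) for CSV round-trips."""
        rows = []
        for c in self:
            rows.append(
                {
                    "acronym": c.acronym,
                    "name": c.name,
                    "group": c.group,
                    "fc_n": c.fc_n,
                    "total_carbons": c.total_carbons,
                    "formula": "".join(
                        f"{el}{n if n > 1 else ''}"
                        for el, n in c.molecular_formula.items()
                    ),
                    "species": c.species,
                    "hydrophobic": c.hydrophobic_flag,
                    "headgroup": c.headgroup,
                    "casrn": c.casrn or "",
                    "mw": c.mw,
                }
            )
        return pd.DataFrame(rows)


def _registry_from_frame(df: pd.DataFrame, source: str) -> Registry:
    required = {
        "acronym", "name", "group", "fc_n", "total_carbons",
        "formula", "species", "hydrophobic", "headgroup",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source}: missing registry columns {sorted(missing)}")
    compounds = []
    for _, row in df.iterrows():
        try:
            casrn = row.get("casrn")
            casrn = None if pd.isna(casrn) or casrn == "" else str(casrn)
            hydro = row["hydrophobic"]
            if isinstance(hydro, str):
                hydro = hydro.strip().lower() in {"true", "1", "yes"}
            compounds.append(
                Compound(
                    acronym=str(row["acronym"]),
                    name=str(row["name"]),
                    group=str(row["group"]),
                    fc_n=int(row["fc_n"]),
                    total_carbons=int(row["total_carbons"]),
                    molecular_formula=parse_formula(str(row["formula"])),
                    species=str(row["species"]),
                    hydrophobic_flag=bool(hydro),
                    headgroup=str(row["headgroup"]),
                    casrn=casrn,
                )
            )
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(
                f"{source}: corrupted registry row acronym={row.get('acronym')!r}: {exc}"
            ) from exc
    return Registry(compounds)


def load_registry(path: str | None = None) -> Registry:
    """Load the packaged 60-compound registry (or a user CSV at ``path``)."""
    if path is not None:
        return _registry_from_frame(pd.read_csv(path), str(path))
    ref = resources.files("pfaspartition").joinpath("data/pfas_registry.csv")
    with ref.open("r", encoding="utf-8") as handle:
        df = pd.read_csv(handle)
    return _registry_from_frame(df, "packaged registry")
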