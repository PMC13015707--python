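"""Study-design metadata: phage and host records, lifestyle and tRNA-group labels.

A curated table of 154 phages infecting 7 bacterial host genera ships with the
package (``data/phage_table.tsv``), together with the 11 host strains
(``data/host_table.tsv``) and a per-phage host-strain assignment
(``data/phage_host_map.tsv``). Numeric values in the phage table are preserved
verbatim from the source metadata, including known typographical anomalies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Lifestyle",
    "TRNAGroup",
    "PhageRecord",
    "HostRecord",
    "classify_trna_group",
    "load_phage_table",
    "load_host_table",
    "load_phage_host_map",
    "study_design_summary",
    "write_phage_table",
]

PHAGE_COLUMNS = [
    "name",
    "accession",
    "host_genus",
    "classification",
    "morphology",
    "lifestyle",
    "genome_bp",
    "n_trna",
]

HOST_COLUMNS = ["species", "accession", "genus"]


class Lifestyle(str, enum.Enum):
    VIRULENT = "Virulent"
    TEMPERATE = "Temperate"


class TRNAGroup(str, enum.Enum):
    """Phage tRNA-gene-count category: High (>5), Low (1-5), None (0)."""

    HIGH = "High"
    LOW = "Low"
    NONE = "None"


@dataclass(frozen=True)
class PhageRecord:
    name: str
    accession: str
    host_genus: str
    classification: str
    morphology: str
    lifestyle: Lifestyle
    genome_bp: int
    n_trna: int

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.genome_bp <= 0:
            raise ValueError(f"{self.name}: genome_bp must be positive")
        if self.n_trna < 0:
            raise ValueError(f"{self.name}: n_trna must be >= 0")

    @property
    def trna_group(self) -> TRNAGroup:
        return classify_trna_group(self.n_trna)


@dataclass(frozen=True)
class HostRecord:
    species: str
    accession: str
    genus: str


def classify_trna_group(n_trna: int) -> TRNAGroup:
    """Categorize a phage by tRNA gene count: 0 -> None, 1-5 -> Low, >5 -> High."""
    if isinstance(n_trna, bool) or not isinstance(n_trna, (int,)):
        raise TypeError(f"n_trna must be an integer, got {n_trna!r}")
    if n_trna < 0:
        raise ValueError(f"n_trna must be >= 0, got {n_trna}")
    if n_trna == 0:
        return TRNAGroup.NONE
    if n_trna <= 5:
        return TRNAGroup.LOW
    return TRNAGroup.HIGH


def _bundled(name: str) -> Path:
    return Path(str(resources.files("phagecodon").joinpath("data", name)))


def _canonical_lifestyle(token: str, row: int) -> Lifestyle:
    t = str(token).strip().lower()
    for ls in Lifestyle:
        if t == ls.value.lower():
            return ls
    raise ValueError(
        f"row {row}: unknown lifestyle {token!r} (expected Virulent or Temperate)"
    )


def load_phage_table(source: str | Path | None = None) -> list[PhageRecord]:
    """Read a phage metadata TSV; with no argument, the bundled 154-phage table.

    Lifestyle and genus tokens are case-insensitive on input and canonical
    (title-case) on output. Raises on missing columns or unknown lifestyle
    tokens, naming the offending row.
    """
    path = _bundled("phage_table.tsv") if source is None else Path(source)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in PHAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phage table missing column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        records.append(
            PhageRecord(
                name=str(row["name"]),
                accession=str(row["accession"]),
                host_genus=str(row["host_genus"]).strip().title(),
                classification=str(row["classification"]),
                morphology=str(row["morphology"]),
                lifestyle=_canonical_lifestyle(row["lifestyle"], i),
                genome_bp=int(row["genome_bp"]),
                n_trna=int(row["n_trna"]),
            )
        )
    return records


def write_phage_table(records: Iterable[PhageRecord], path: str | Path) -> None:
    """Write records as TSV in the bundled-table schema (round-trips exactly)."""
    rows = [
        {
            "name": r.name,
            "accession": r.accession,
            "host_genus": r.host_genus,
            "classification": r.classification,
            "morphology": r.morphology,
            "lifestyle": r.lifestyle.value,
            "genome_bp": r.genome_bp,
            "n_trna": r.n_trna,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PHAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_host_table(source: str | Path | None = None) -> list[HostRecord]:
    path = _bundled("host_table.tsv") if source is None else Path(source)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in HOST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"host table missing column(s): {', '.join(missing)}")
    return [
        HostRecord(
            species=str(r["species"]),
            accession=str(r["accession"]),
            genus=str(r["genus"]).strip().title(),
        )
        for _, r in df.iterrows()
    ]


def load_phage_host_map(source: str | Path | None = None) -> dict[str, str]:
    """Per-phage host-strain assignment: phage accession -> host accession."""
    path = _bundled("phage_host_map.tsv") if source is None else Path(source)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return dict(zip(df["phage_accession"], df["host_accession"]))


def study_design_summary(records: list[PhageRecord]) -> pd.DataFrame:
    """Cross-tabulate genus x lifestyle x tRNA group and flag confounded cells.

    Returns a long-format DataFrame with one row per (genus, lifestyle,
    trna_group) combination plus a boolean ``confounded`` column that is True
    for every row of a genus in which lifestyle and tRNA group are perfectly
    confounded (each lifestyle maps to exactly one tRNA group and vice versa,
    e.g. a genus where all temperate phages lack tRNAs and all virulent
    phages fall in one group).
    """
    if not records:
        raise ValueError("empty record list")
    df = pd.DataFrame(
        {
            "genus": [r.host_genus for r in records],
            "lifestyle": [r.lifestyle.value for r in records],
            "trna_group": [r.trna_group.value for r in records],
        }
    )
    counts = (
        df.groupby(["genus", "lifestyle", "trna_group"]).size().rename("n").reset_index()
    )
    confounded_genera = set()
    for genus, sub in df.groupby("genus"):
        pairs = sub[["lifestyle", "trna_group"]].drop_duplicates()
        one_to_one = (
            pairs.groupby("lifestyle")["trna_group"].nunique().le(1).all()
            and pairs.groupby("trna_group")["lifestyle"].nunique().le(1).all()
        )
        if one_to_one and sub["lifestyle"].nunique() > 1:
            confounded_genera.add(genus)
    counts["confounded"] = counts["genus"].isin(confounded_genera)
    assert counts["n"].sum() == len(records)
    return counts
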