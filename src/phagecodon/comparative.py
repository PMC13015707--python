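"""Host-subtracted Δ-metrics and the grouped comparison datasets.

Every phage is summarized against its assigned host by signed differences:
ΔGC (percentage points, phage gene mean minus host gene mean, per GC type),
ΔEnC (mean over genes with defined EnC), ΔRSCU (per codon, genome-mean RSCU
difference, Met/Trp and either-side-undefined codons excluded) and ΔtAI
(per phage gene against a host summary statistic). Self-comparison yields
all-zero deltas and each Δ is antisymmetric in its two arguments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .genetic_code import CODON_TO_AA, SENSE_CODONS, SINGLE_CODON_AAS
from .indices import GCProfile, GeneTAI, RSCUVector, wright_expected_nc
from .metadata import Lifestyle, TRNAGroup

logger = logging.getLogger(__name__)

__all__ = [
    "DeltaRecord",
    "NcPlotPoint",
    "CONTRASTS",
    "delta_gc",
    "delta_enc",
    "delta_rscu",
    "delta_tai",
    "nc_plot_data",
    "assemble_comparisons",
]

#: named group contrasts applied to every Δ-metric
CONTRASTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "High_vs_Low": (("High",), ("Low",)),
    "High_vs_None": (("High",), ("None",)),
    "Low_vs_None": (("Low",), ("None",)),
    "HighLow_vs_None": (("High", "Low"), ("None",)),
    "Virulent_vs_Temperate": (("Virulent",), ("Temperate",)),
}


@dataclass(frozen=True)
class DeltaRecord:
    """One phage's host-subtracted metrics with its design labels."""

    phage_id: str
    host_id: str
    genus: str
    lifestyle: Lifestyle
    trna_group: TRNAGroup
    delta_gc_total: float
    delta_gc1: float
    delta_gc2: float
    delta_gc3: float
    delta_enc: float
    delta_rscu: dict[str, float] = field(default_factory=dict)
    delta_tai_per_gene: list[float] = field(default_factory=list)
    delta_tai_mean: float = math.nan
    delta_tai_median: float = math.nan


@dataclass(frozen=True)
class NcPlotPoint:
    gene_id: str
    gc3: float
    enc: float
    expected_nc: float

    @property
    def residual(self) -> float:
        return self.enc - self.expected_nc

    @property
    def below_curve(self) -> bool:
        return self.residual < 0


def _mean(values: list[float], what: str) -> float:
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        raise ValueError(f"no defined {what} values to average")
    return float(np.mean(vals))


def delta_gc(
    phage_profiles: list[GCProfile], host_profiles: list[GCProfile]
) -> dict[str, float]:
    """Phage-mean minus host-mean GC, in percentage points, per GC type."""
    if not phage_profiles or not host_profiles:
        raise ValueError("both sides need at least one gene")
    out = {}
    for attr, key in (
        ("gc_total", "delta_gc_total"),
        ("gc1", "delta_gc1"),
        ("gc2", "delta_gc2"),
        ("gc3", "delta_gc3"),
    ):
        p = np.mean([getattr(g, attr) for g in phage_profiles])
        h = np.mean([getattr(g, attr) for g in host_profiles])
        out[key] = 100.0 * (p - h)
    return out


def delta_enc(phage_encs: list[float], host_encs: list[float]) -> float:
    """Mean defined phage EnC minus mean defined host EnC; NaN entries excluded."""
    return _mean(phage_encs, "phage EnC") - _mean(host_encs, "host EnC")


def delta_rscu(
    phage_mean: RSCUVector, host_mean: RSCUVector
) -> dict[str, float]:
    """Per-codon phage-minus-host genome-mean RSCU.

    Met/Trp are excluded, as is any codon undefined (family absent) on either
    side; exclusions are logged.
    """
    out: dict[str, float] = {}
    for codon in SENSE_CODONS:
        if CODON_TO_AA[codon] in SINGLE_CODON_AAS:
            continue
        p, h = phage_mean.values[codon], host_mean.values[codon]
        if math.isnan(p) or math.isnan(h):
            logger.info("delta_rscu: codon %s undefined on one side, excluded", codon)
            continue
        out[codon] = p - h
    return out


def delta_tai(
    phage_gene_tais: list[GeneTAI],
    host_gene_tais: list[GeneTAI],
    summary: Literal["mean", "median"] = "mean",
) -> tuple[list[float], float, float]:
    """Per-phage-gene tAI minus a host summary statistic.

    Both inputs must be genome-normalized (tai_final set). Returns
    (per-gene deltas against the chosen host summary, phage-level mean Δ,
    phage-level median Δ).
    """
    if not host_gene_tais:
        raise ValueError("empty host gene set")
    if not phage_gene_tais:
        raise ValueError("empty phage gene set")
    host_vals = [g.tai_final for g in host_gene_tais]
    phage_vals = [g.tai_final for g in phage_gene_tais]
    if any(v is None for v in host_vals + phage_vals):
        raise ValueError("tAI values must be genome-normalized (tai_final)")
    baseline = float(np.mean(host_vals) if summary == "mean" else np.median(host_vals))
    per_gene = [v - baseline for v in phage_vals]
    return per_gene, float(np.mean(per_gene)), float(np.median(per_gene))


def nc_plot_data(index_table: pd.DataFrame) -> pd.DataFrame:
    """EnC-vs-GC3 points with Wright's expected curve value and residual.

    Input is a per-gene index table (``genome_index_table`` output, possibly
    concatenated across organisms with label columns attached); genes with
    undefined EnC are excluded. Label columns (organism, genus, lifestyle,
    trna_group) are carried through when present.
    """
    df = index_table.dropna(subset=["enc"]).copy()
    df["expected_nc"] = df["gc3"].map(wright_expected_nc)
    df["residual"] = df["enc"] - df["expected_nc"]
    df["below_curve"] = df["residual"] < 0
    keep = [
        c
        for c in (
            "gene_id",
            "organism",
            "genus",
            "lifestyle",
            "trna_group",
            "gc3",
            "enc",
            "expected_nc",
            "residual",
            "below_curve",
        )
        if c in df.columns
    ]
    return df[keep].reset_index(drop=True)


def _labels_of(record: DeltaRecord) -> set[str]:
    return {record.lifestyle.value, record.trna_group.value}


def assemble_comparisons(
    records: list[DeltaRecord],
    level: Literal["per_genus", "global"] = "global",
) -> pd.DataFrame:
    """Named contrast datasets for every group comparison.

    Returns a long-format frame with one row per (scope, contrast, arm,
    phage); contrasts with an empty arm are emitted with ``skipped=True``
    rather than dropped, so downstream reporting can surface them (e.g. the
    High arm in a genus whose phages all carry <=5 tRNAs).
    """
    if not records:
        raise ValueError("no delta records")
    scopes: dict[str, list[DeltaRecord]]
    if level == "global":
        scopes = {"global": records}
    else:
        scopes = {}
        for r in records:
            scopes.setdefault(r.genus, []).append(r)
    rows = []
    for scope, recs in scopes.items():
        for contrast, (arm_a, arm_b) in CONTRASTS.items():
            members_a = [r for r in recs if _labels_of(r) & set(arm_a)]
            members_b = [r for r in recs if _labels_of(r) & set(arm_b)]
            skipped = not members_a or not members_b
            for arm_name, arm_levels, members in (
                ("A", arm_a, members_a),
                ("B", arm_b, members_b),
            ):
                if not members:
                    rows.append(
                        {
                            "scope": scope,
                            "contrast": contrast,
                            "arm": arm_name,
                            "arm_levels": "+".join(arm_levels),
                            "phage_id": None,
                            "skipped": True,
                        }
                    )
                for r in members:
                    rows.append(
                        {
                            "scope": scope,
                            "contrast": contrast,
                            "arm": arm_name,
                            "arm_levels": "+".join(arm_levels),
                            "phage_id": r.phage_id,
                            "skipped": skipped,
                        }
                    )
    return pd.DataFrame(rows)
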