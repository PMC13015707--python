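"""Synthetic host/phage study generator.

Generates multi-gene coding sequences with controllable third-position GC
(GC3) and codon-bias strength, tRNA pools with quality scores, and a full
host x phage study design (lifestyle x tRNA group, tunable phage-host codon
divergence) whose output files mirror the real-data interfaces exactly
(CDS FASTA per organism, generic tRNA-pool TSV, metadata TSV).

Codon model: amino-acid frequencies are held constant (documented default
below) across all organisms, so Δ-metrics isolate synonymous-choice
divergence. Within each synonymous family the codon probabilities are drawn
from a symmetric Dirichlet with concentration kappa (kappa -> 0 gives one
dominant codon per family, i.e. extreme bias; kappa -> inf gives uniform
usage) and then exponentially tilted on third-position G+C so the profile's
expected GC3 hits a target. Genes are i.i.d. codon draws from the profile,
with lognormal lengths; no in-frame stops can occur by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetic_code import FAMILIES, SENSE_CODONS, anticodon_for
from .metadata import Lifestyle, classify_trna_group
from .seqio import CodingSequence, TRNAPool, write_cds_fasta, write_trna_pool

__all__ = [
    "AA_FREQUENCIES",
    "PhageSpec",
    "SyntheticConfig",
    "SyntheticStudy",
    "make_codon_profile",
    "generate_genome",
    "generate_pool",
    "generate_study",
]

#: default amino-acid frequencies (approximate average bacterial proteome
#: composition, normalized over the 20 amino acids). Held fixed across all
#: synthetic organisms.
AA_FREQUENCIES: dict[str, float] = {
    "A": 0.089, "R": 0.055, "N": 0.039, "D": 0.054, "C": 0.012,
    "Q": 0.039, "E": 0.061, "G": 0.072, "H": 0.021, "I": 0.059,
    "L": 0.102, "K": 0.051, "M": 0.027, "F": 0.039, "P": 0.043,
    "S": 0.061, "T": 0.054, "W": 0.013, "Y": 0.032, "V": 0.071,
}

_GC3_MASK = np.array([c[2] in "GC" for c in SENSE_CODONS], dtype=float)
_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


def _tilt(profile: np.ndarray, lam: float) -> np.ndarray:
    """Exponentially tilt third-position G/C within each family, renormalized."""
    tilted = profile * np.exp(lam * _GC3_MASK)
    out = np.zeros_like(tilted)
    for codons in FAMILIES.values():
        idx = [_CODON_INDEX[c] for c in codons]
        fam = tilted[idx]
        total_orig = profile[idx].sum()
        out[idx] = fam / fam.sum() * total_orig
    return out


def make_codon_profile(
    target_gc3: float, kappa: float, seed: int
) -> np.ndarray:
    """A 61-codon probability vector with expected GC3 within 0.02 of target.

    Within-family codon weights are Dirichlet(kappa) draws, then tilted by
    bisection on the tilting parameter until the profile's expected GC3
    matches `target_gc3`. Raises when the target is outside [0, 1] or
    unreachable (single-codon families pin part of the GC3 mass).
    """
    if not 0.0 <= target_gc3 <= 1.0:
        raise ValueError(f"target_gc3 must be in [0, 1], got {target_gc3}")
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    rng = np.random.default_rng(seed)
    profile = np.zeros(len(SENSE_CODONS))
    for aa, codons in FAMILIES.items():
        idx = [_CODON_INDEX[c] for c in codons]
        if len(codons) == 1:
            weights = np.array([1.0])
        else:
            weights = rng.dirichlet(np.full(len(codons), kappa))
        profile[idx] = AA_FREQUENCIES[aa] * weights
    profile /= profile.sum()

    def gc3_at(lam: float) -> float:
        return float(_tilt(profile, lam) @ _GC3_MASK)

    lo, hi = -60.0, 60.0
    if not gc3_at(lo) - 0.02 <= target_gc3 <= gc3_at(hi) + 0.02:
        raise ValueError(
            f"target_gc3={target_gc3} unreachable given fixed amino-acid usage "
            f"(achievable range [{gc3_at(lo):.3f}, {gc3_at(hi):.3f}])"
        )
    for _ in range(200):
        mid = (lo + hi) / 2
        if gc3_at(mid) < target_gc3:
            lo = mid
        else:
            hi = mid
    tilted = _tilt(profile, (lo + hi) / 2)
    assert abs(tilted @ _GC3_MASK - target_gc3) <= 0.02
    return tilted / tilted.sum()


@dataclass(frozen=True)
class LengthSpec:
    """Lognormal gene-length distribution in codons."""

    median_codons: int = 250
    sigma: float = 0.45
    min_codons: int = 30


def generate_genome(
    profile: np.ndarray,
    n_genes: int,
    length_spec: LengthSpec | None = None,
    seed: int = 0,
    prefix: str = "gene",
) -> list[CodingSequence]:
    """`n_genes` coding sequences of i.i.d. codons drawn from `profile`."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    spec = length_spec or LengthSpec()
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        spec.min_codons,
        np.round(
            np.exp(rng.normal(math.log(spec.median_codons), spec.sigma, n_genes))
        ).astype(int),
    )
    codons = np.array(SENSE_CODONS)
    out = []
    for i, L in enumerate(lengths):
        draw = rng.choice(len(codons), size=L, p=profile)
        out.append(
            CodingSequence(gene_id=f"{prefix}_{i + 1:05d}", sequence="".join(codons[draw]))
        )
    return out


def generate_pool(
    anticodon_set: list[str],
    seed: int = 0,
    score_low: float = 20.0,
    score_high: float = 100.0,
) -> TRNAPool:
    """A tRNA pool with uniform random quality scores over the given anticodons."""
    if not anticodon_set:
        raise ValueError("empty anticodon set")
    rng = np.random.default_rng(seed)
    scores = {
        ac.upper().replace("U", "T"): float(rng.uniform(score_low, score_high))
        for ac in anticodon_set
    }
    isotypes = {ac: "Und" for ac in scores}
    return TRNAPool(scores=scores, isotypes=isotypes)


def default_anticodon_set(profile: np.ndarray, rng: np.random.Generator, n: int = 40) -> list[str]:
    """Anticodons matching the `n` most probable codons: every amino-acid
    family retains at least one decodable option."""
    order = np.argsort(profile)[::-1]
    chosen: list[str] = []
    seen_aa = set()
    from .genetic_code import CODON_TO_AA

    # one anticodon per family first, then fill by codon probability
    for i in order:
        aa = CODON_TO_AA[SENSE_CODONS[i]]
        if aa not in seen_aa:
            chosen.append(anticodon_for(SENSE_CODONS[i]))
            seen_aa.add(aa)
    for i in order:
        if len(chosen) >= n:
            break
        ac = anticodon_for(SENSE_CODONS[i])
        if ac not in chosen:
            chosen.append(ac)
    return chosen[:n]


@dataclass(frozen=True)
class PhageSpec:
    name: str
    divergence: float  # delta in [0, 1]: mixing toward the alternative profile
    n_trna: int
    lifestyle: Lifestyle
    n_genes: int = 150

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")


def _default_phage_specs() -> list[PhageSpec]:
    """Default design: 20 phages spanning lifestyle x tRNA group x divergence,
    mirroring one genus of the real study (17-24 phages per host genus)."""
    specs = []
    rng = np.random.default_rng(20_240_101)
    for i in range(20):
        virulent = i % 2 == 0
        group = ("none", "low", "high")[i % 3]
        n_trna = {"none": 0, "low": int(rng.integers(1, 6)), "high": int(rng.integers(6, 30))}[group]
        divergence = {"none": 0.10, "low": 0.20, "high": 0.35}[group]
        specs.append(
            PhageSpec(
                name=f"phage_{i + 1:02d}",
                divergence=divergence,
                n_trna=n_trna,
                lifestyle=Lifestyle.VIRULENT if virulent else Lifestyle.TEMPERATE,
                n_genes=int(rng.integers(50, 251)),
            )
        )
    return specs


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level configuration.

    Defaults mirror the smallest real host case: one host of 4,000 genes with
    GC3 0.54 and moderate bias (kappa 0.8), 20 phages of 50-250 genes with
    divergence rising with tRNA group.
    """

    seed: int = 0
    host_name: str = "host"
    n_host_genes: int = 4_000
    target_gc3: float = 0.54
    kappa: float = 0.8
    alt_target_gc3: float = 0.30
    alt_kappa: float = 0.8
    length_spec: LengthSpec = field(default_factory=LengthSpec)
    phages: tuple[PhageSpec, ...] = field(
        default_factory=lambda: tuple(_default_phage_specs())
    )
    n_pool_anticodons: int = 40


@dataclass
class SyntheticStudy:
    host_name: str
    host_cds: list[CodingSequence]
    host_pool: TRNAPool
    phage_cds: dict[str, list[CodingSequence]]
    metadata: "object"  # pandas DataFrame; annotated loosely to avoid import cycle

    def write(self, outdir: str | Path) -> None:
        """Emit FASTA + TSV files in the real-data interchange schemas."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_cds_fasta(self.host_cds, out / f"{self.host_name}.cds.fasta")
        write_trna_pool(self.host_pool, out / f"{self.host_name}.trna.tsv")
        for name, cds in self.phage_cds.items():
            write_cds_fasta(cds, out / f"{name}.cds.fasta")
        self.metadata.to_csv(out / "phage_table.tsv", sep="\t", index=False)


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Host + phage CDS sets, host tRNA pool, and a metadata table.

    Each phage's codon profile is (1 - delta) * host_profile + delta *
    alternative_profile; metadata rows carry lifestyle and n_trna so
    `classify_trna_group` reproduces the intended design groups.
    """
    import pandas as pd

    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    host_profile = make_codon_profile(cfg.target_gc3, cfg.kappa, seed=cfg.seed)
    alt_profile = make_codon_profile(
        cfg.alt_target_gc3, cfg.alt_kappa, seed=cfg.seed + 104_729
    )
    host_cds = generate_genome(
        host_profile, cfg.n_host_genes, cfg.length_spec,
        seed=int(rng.integers(2**31)), prefix=f"{cfg.host_name}_g",
    )
    pool = generate_pool(
        default_anticodon_set(host_profile, rng, cfg.n_pool_anticodons),
        seed=int(rng.integers(2**31)),
    )
    phage_cds = {}
    meta_rows = []
    for spec in cfg.phages:
        profile = (1 - spec.divergence) * host_profile + spec.divergence * alt_profile
        profile /= profile.sum()
        phage_cds[spec.name] = generate_genome(
            profile, spec.n_genes, cfg.length_spec,
            seed=int(rng.integers(2**31)), prefix=f"{spec.name}_g",
        )
        meta_rows.append(
            {
                "name": spec.name,
                "accession": f"SYN_{spec.name}",
                "host_genus": cfg.host_name.title(),
                "classification": "Synthetic",
                "morphology": "synthetic",
                "lifestyle": spec.lifestyle.value,
                "genome_bp": sum(c.n_codons * 3 for c in phage_cds[spec.name]),
                "n_trna": spec.n_trna,
            }
        )
        assert classify_trna_group(spec.n_trna) is not None
    metadata = pd.DataFrame(meta_rows)
    return SyntheticStudy(
        host_name=cfg.host_name,
        host_cds=host_cds,
        host_pool=pool,
        phage_cds=phage_cds,
        metadata=metadata,
    )
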