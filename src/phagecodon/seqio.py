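"""Readers for annotated genomes (GenBank), CDS FASTA, and tRNA-pool tables.

Every coding sequence passes a single QC gate before any index is computed:
length divisible by 3, at least 3 codons, no internal stop under the bacterial
code, only A/C/G/T. A single terminal stop codon, if present, is stripped.
Sequences failing QC are dropped (never masked) and the reason is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .genetic_code import STOP_CODONS, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "CodingSequence",
    "TRNAPool",
    "QCLog",
    "validate_cds",
    "extract_cds",
    "read_cds_fasta",
    "write_cds_fasta",
    "read_trna_pool",
]


@dataclass(frozen=True)
class CodingSequence:
    """One validated protein-coding nucleotide sequence (terminal stop removed)."""

    gene_id: str
    sequence: str
    product: str | None = None

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codons(self) -> list[str]:
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s), 3)]


@dataclass
class QCLog:
    """Per-source record of genes read and dropped, with reasons."""

    n_read: int = 0
    n_kept: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def drop(self, gene_id: str, reason: str) -> None:
        self.dropped.append((gene_id, reason))
        logger.warning("QC drop %s: %s", gene_id, reason)


@dataclass(frozen=True)
class TRNAPool:
    """Anticodon -> (raw score, isotype) map for one organism's tRNA pool.

    Raw scores are tRNAscan-SE covariance-model (COVE) quality scores or, for
    score-free sources, 1. Normalized scores are raw/max and lie in (0, 1].
    """

    scores: dict[str, float]
    isotypes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("empty tRNA pool")
        if any(v <= 0 for v in self.scores.values()):
            raise ValueError("all raw scores must be > 0")

    @property
    def max_score(self) -> float:
        return max(self.scores.values())

    def normalized(self) -> dict[str, float]:
        m = self.max_score
        return {ac: s / m for ac, s in self.scores.items()}


def validate_cds(gene_id: str, raw: str, product: str | None, log: QCLog) -> CodingSequence | None:
    """Apply the QC gate to one raw nucleotide string; None if it fails."""
    log.n_read += 1
    seq = raw.upper()
    if any(b not in "ACGT" for b in seq):
        log.drop(gene_id, "non-ACGT base")
        return None
    if len(seq) % 3 != 0:
        log.drop(gene_id, "length not divisible by 3")
        return None
    # strip one terminal stop codon if annotated
    if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    if len(seq) < 9:
        log.drop(gene_id, "fewer than 3 codons")
        return None
    for i in range(0, len(seq), 3):
        if seq[i : i + 3] in STOP_CODONS:
            log.drop(gene_id, f"internal stop codon at codon {i // 3 + 1}")
            return None
    log.n_kept += 1
    return CodingSequence(gene_id=gene_id, sequence=seq, product=product)


def _cds_feature_id(feature, index: int) -> str:
    for key in ("locus_tag", "protein_id", "gene"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return f"CDS_{index}"


def extract_cds(record: SeqRecord, log: QCLog | None = None) -> list[CodingSequence]:
    """Extract validated coding sequences from one GenBank record.

    Multi-interval CDS features are joined and minus-strand features
    reverse-complemented (Biopython's feature extraction handles both);
    pseudogene-flagged features are excluded. Returns survivors in file order.
    """
    log = log if log is not None else QCLog()
    out = []
    idx = 0
    for feature in record.features:
        if feature.type != "CDS":
            continue
        idx += 1
        if "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers:
            continue
        gene_id = _cds_feature_id(feature, idx)
        product = feature.qualifiers.get("product", [None])[0]
        raw = str(feature.extract(record.seq))
        cds = validate_cds(gene_id, raw, product, log)
        if cds is not None:
            out.append(cds)
    if idx == 0:
        logger.warning("record %s contains no CDS features", record.id)
    return out


def read_genbank_cds(path: str | Path, log: QCLog | None = None) -> list[CodingSequence]:
    """All validated CDS from a (possibly multi-record) GenBank flat file."""
    log = log if log is not None else QCLog()
    out: list[CodingSequence] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "genbank"):
        n_records += 1
        out.extend(extract_cds(record, log))
    if n_records == 0:
        raise IOError(f"no GenBank records parsed from {path}")
    return out


def read_cds_fasta(path: str | Path, log: QCLog | None = None) -> list[CodingSequence]:
    """Validated coding sequences from a FASTA of in-frame CDS nucleotides."""
    log = log if log is not None else QCLog()
    out = []
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise IOError(f"no FASTA records in {path}")
    for rec in records:
        cds = validate_cds(rec.id, str(rec.seq), rec.description or None, log)
        if cds is not None:
            out.append(cds)
    return out


def write_cds_fasta(cds_list: Iterable[CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.gene_id, description="") for c in cds_list
    ]
    SeqIO.write(records, str(path), "fasta")


Dialect = Literal["trnascan", "aragorn", "generic_tsv"]


def _norm_anticodon(token: str) -> str:
    ac = token.strip().upper().replace("U", "T")
    if len(ac) != 3 or any(b not in "ACGT" for b in ac):
        raise ValueError(f"invalid anticodon {token!r}")
    return ac


def read_trna_pool(path: str | Path, dialect: Dialect = "generic_tsv") -> TRNAPool:
    """Read a tRNA-pool table into a scored anticodon map.

    Dialects:

    - ``trnascan``: tab-delimited tRNAscan-SE 2.0 output (two header lines;
      columns: name, nr, begin, end, isotype, anticodon, intron begin/end,
      score[, note]). Rows whose note column flags a pseudogene are dropped.
    - ``aragorn``: whitespace table with isotype ``tRNA-Xxx`` and anticodon in
      parentheses; carries no score, so every row gets raw score 1.
    - ``generic_tsv``: header ``anticodon<TAB>isotype<TAB>score`` — the
      package's canonical interchange format.

    Duplicate anticodons are aggregated by maximum raw score.
    """
    scores: dict[str, float] = {}
    isotypes: dict[str, str] = {}

    def add(ac: str, isotype: str, score: float) -> None:
        ac = _norm_anticodon(ac)
        if ac not in scores or score > scores[ac]:
            scores[ac] = score
            isotypes[ac] = isotype

    text = Path(path).read_text()
    lines = [l for l in text.splitlines() if l.strip()]
    if dialect == "generic_tsv":
        header, *rows = lines
        cols = [c.strip().lower() for c in header.split("\t")]
        for need in ("anticodon", "isotype", "score"):
            if need not in cols:
                raise ValueError(f"generic tRNA TSV missing column {need!r}")
        ia, ii, isc = cols.index("anticodon"), cols.index("isotype"), cols.index("score")
        for row in rows:
            f = row.split("\t")
            add(f[ia], f[ii].strip(), float(f[isc]))
    elif dialect == "trnascan":
        for line in lines:
            if line.startswith(("Sequence", "Name", "----")) or "\t" not in line:
                continue
            f = [x.strip() for x in line.split("\t")]
            if len(f) < 9:
                continue
            isotype, anticodon, score = f[4], f[5], float(f[8])
            note = f[9].lower() if len(f) > 9 else ""
            if "pseudo" in note or isotype.lower() == "pseudo":
                continue
            add(anticodon, isotype, score)
    elif dialect == "aragorn":
        for line in lines:
            f = line.split()
            token = next((x for x in f if x.lower().startswith("trna-")), None)
            ac = next((x for x in f if x.startswith("(") and x.endswith(")")), None)
            if token is None or ac is None:
                continue
            isotype = token.split("-")[1]
            add(ac.strip("()"), isotype, 1.0)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if not scores:
        raise ValueError(f"empty tRNA pool from {path}")
    return TRNAPool(scores=scores, isotypes=isotypes)


def write_trna_pool(pool: TRNAPool, path: str | Path) -> None:
    """Write a pool in the generic 3-column interchange TSV."""
    with open(path, "w") as fh:
        fh.write("anticodon\tisotype\tscore\n")
        for ac in sorted(pool.scores):
            fh.write(f"{ac}\t{pool.isotypes.get(ac, 'Und')}\t{pool.scores[ac]:g}\n")
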