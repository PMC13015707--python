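# phagecodon

Comparative codon-usage analysis of bacteriophages and their bacterial hosts.

Bacteriophages translate their proteins on the host machinery, yet their codon
usage often diverges sharply from the host's — and many phages carry their own
tRNA genes, possibly to compensate. `phagecodon` quantifies that divergence.
For every coding sequence it computes four indices, subtracts the host value
to obtain standardized Δ-metrics, and compares groups of phages (virulent vs.
temperate lifestyle; High/Low/None tRNA-gene classes) with a nonparametric
statistics battery. It ships with the 154-phage / 7-host-genus study table it
was designed around and a synthetic-data generator so that the entire pipeline
is testable without downloading genomes.

Intended users: microbial genomicists and phage biologists comparing codon
adaptation between mobile elements and their hosts.

## The indices

For a gene with codon counts `X_ij` (codon *j* of amino acid *i*, family size
`n_i`), under the standard bacterial genetic code:

- **GC content by codon position** — GC1/GC2/GC3 and the total; GC3 is the
  wobble position, most responsive to synonymous-choice pressure.
- **Effective number of codons (EnC)** — Wright's estimator from per-family
  codon homozygosity `F̂ = (n·Σp² − 1)/(n − 1)`:

  ```
  EnC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆          (capped at 61)
  ```

  where `F̄_k` averages `F̂` over families of degeneracy *k*. EnC ranges from
  20 (one codon per amino acid, maximal bias) to 61 (uniform usage). The null
  expectation when composition alone drives usage is
  `EnC(s) = 2 + s + 29/(s² + (1−s)²)` with `s` = GC3; genes below that curve
  suggest selection on codon choice.
- **Relative synonymous codon usage (RSCU)** —
  `RSCU_ij = X_ij / ((1/n_i)·Σ_j X_ij)`, i.e. observed over equal-usage
  expectation; the family mean is 1, a sole-used leucine codon scores 6.
- **tRNA adaptation index (tAI)** — each codon matched by an exact
  Watson–Crick anticodon in the organism's tRNA pool gets weight
  `(RSCU + ε)·(tRNA quality score / max score)` with `ε = 10⁻⁶`; the gene
  value is the geometric mean of weights over matched codon occurrences,
  normalized per genome so the best-adapted gene scores exactly 1.

Δ-metrics subtract the host mean from the phage mean (ΔGC in percentage
points, ΔEnC in EnC units, ΔRSCU per codon, ΔtAI per gene), standardizing
across hosts of different composition. Group comparisons use Wilcoxon
rank-sum / signed-rank tests, Kruskal–Wallis with Dunn's post-hoc
(Bonferroni or Benjamini–Hochberg adjustment), Cliff's delta and η²_H effect
sizes, a seeded permutation Wilcoxon test, multi-factor PERMANOVA with
sequential sums of squares plus a homogeneity-of-dispersion check, PCA of
ΔRSCU profiles, and design-matrix construction for a beta mixed model on
rescaled per-gene ΔtAI and a linear mixed model `ΔGC ~ lifestyle + (1|host)`.

## Worked example

```python
from phagecodon import (CodingSequence, TRNAPool, count_codons, gc_profile,
                        gene_tai, normalize_tai, rscu, wright_expected_nc)

gene = CodingSequence("demo", "ATGCTGCTGCTGAAACCGGAATTTTTC")
counts = count_codons(gene)
gc = gc_profile(gene)
print(f"codons: {counts.n_codons}, GC3 = {gc.gc3:.3f}")
print(f"expected EnC at this GC3 = {wright_expected_nc(gc.gc3):.2f}")
print(f"RSCU(CTG) = {rscu(counts).values['CTG']:.1f}")
pool = TRNAPool(scores={"CAG": 82.4, "TTT": 41.2},
                isotypes={"CAG": "Leu", "TTT": "Lys"})
raw = gene_tai(gene, pool)
print(f"raw tAI = {raw.raw_tai:.4f} over {raw.n_matched} matched codons")
print(f"tAI_final (single-gene genome) = {normalize_tai([raw])[0].tai_final}")
```

prints

```
codons: 9, GC3 = 0.667
expected EnC at this GC3 = 54.87
RSCU(CTG) = 6.0
raw tAI = 3.8337 over 4 matched codons
tAI_final (single-gene genome) = 1.0
```

`RSCU(CTG) = 6.0` because CTG is the only leucine codon the gene uses; the
raw tAI is the geometric mean `6^(3/4)·1^(1/4) ≈ 3.83` of the four matched
codon occurrences (three CTG at weight ≈ 6, one AAA at weight ≈ 1); and the
single gene necessarily normalizes to a tAI of 1.

## Pipeline

```sh
phagecodon simulate --outdir data --seed 3 --n-host-genes 400
printf 'data_dir: data\noutdir: out\nhosts: [host]\nseed: 5\n' > run.yaml
phagecodon all --config run.yaml
```

This writes per-gene index tables, a per-phage Δ table, long-format ΔRSCU and
ΔtAI tables, contrast statistics, PERMANOVA and PCA results, Nc-plot data,
the beta-model design matrix, and a manifest with seeds and QC counts:

```
phage_id lifestyle trna_group  delta_gc_total  delta_enc_mean  delta_tai_mean
phage_01  Virulent       None       -0.967728        2.444465        0.026592
phage_02 Temperate        Low       -1.629593        4.420886        0.087894
phage_03  Virulent       High       -2.856108        6.433645        0.105705
phage_04 Temperate       None       -0.732680        2.388896        0.042675
```

In this synthetic study, phage–host divergence rises with the tRNA group by
construction, and the PERMANOVA on the phage × codon ΔRSCU matrix recovers
it (tRNA group R² = 0.87, p = 1e-4; lifestyle carries no signal, p = 0.33).

Real data enter the same way: convert GenBank records with
`phagecodon extract-cds genome.gb genome.cds.fasta`, place tRNA-pool tables
(tRNAscan-SE 2.0 output or the generic `anticodon/isotype/score` TSV) next to
them, and point the config at that directory. The bundled 154-phage metadata
table, 11 host strains and the per-phage host-strain assignment load via
`phagecodon.metadata`.

Note when re-reading output TSVs with pandas: pass `keep_default_na=False`
so the tRNA-group label `None` is kept as a string.

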