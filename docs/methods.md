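# Methods

## Scope and model

`phagecodon` compares the codon usage of bacteriophages against their
bacterial hosts. The unit of observation is a validated coding sequence (CDS)
under the standard bacterial genetic code (stops TAA/TAG/TGA; ATG and TGG are
single-codon families). Validation is a single QC gate applied at every entry
point (GenBank extraction, CDS FASTA, synthetic generation): length divisible
by 3, at least 3 codons after removing one terminal stop, no internal stop,
no base outside A/C/G/T. A sequence failing any check is dropped whole and
logged — never masked — because the downstream indices are ratio statistics
over complete codons and a partial codon would bias them. Pseudogene-flagged
CDS features are excluded.

## Indices

**GC by position.** `gc_k` is the G+C fraction at codon position *k* over all
codons of the gene; the total is their mean (all positions have equal counts
in a validated CDS). GC3 doubles as the argument *s* of the expected-EnC
curve.

**Effective number of codons.** Wright's estimator: per synonymous family
with total count `n ≥ 2` and codon proportions `p_j`, the homozygosity is
`F̂ = (n·Σp² − 1)/(n − 1)`. Families with `n < 2` or `F̂ ≤ 0` are treated as
undefined and excluded from their degeneracy-class mean. EnC is
`2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` (the coefficients are the family counts
per degeneracy class in the bacterial code). When the 3-fold class (Ile) is
absent, `F̄₃` is interpolated as `(F̄₂ + F̄₄)/2`; if the 2-, 4-, or 6-fold
class mean cannot be formed, the gene's EnC is undefined and excluded from
summaries. Values are capped at 61; the 20 floor holds analytically
(`F̂ ≤ 1` for every family). These degenerate-family conventions follow
Wright's original treatment.

**RSCU.** `X_ij / ((1/n_i)·Σ_j X_ij)` per sense codon. Families absent from
a gene are undefined (NaN), an unused codon of a used family is 0, and the
defined values of each used family average exactly 1 (property-tested).
ATG and TGG are computed but flagged for exclusion from all comparative
analyses, since their RSCU is always 0 or 1.

**tAI.** A codon is *matched* when the organism's tRNA pool contains its
exact Watson–Crick reverse-complement anticodon; no wobble rules are applied,
because the index is defined here against a single complementary anticodon
per codon (unlike the classical wobble-weighted tAI, which is deliberately
out of scope). The matched codon's weight is `(RSCU + ε) · s_norm` with
`ε = 10⁻⁶` (guards the log at RSCU = 0) and `s_norm` the anticodon's quality
score divided by the pool maximum, so `s_norm ∈ (0, 1]`. The gene's raw tAI
is the geometric mean of weights over matched codon **occurrences** — every
elongation step at a matched codon contributes — and `N` is that occurrence
count. An alternative reading would average per unique anticodon; the
occurrence reading is adopted because translational-efficiency indices weight
each elongation event. A gene with no matched codons receives the floor ε.
Per genome, values are divided by the genome maximum, so `max(tAI_final) = 1`
exactly. The RSCU entering the weights is the gene's own by default (tAI is
a per-gene quantity in the downstream mixed models); a genome-mean RSCU can
be passed instead. tAI is invariant under uniform rescaling of pool scores.

**tRNA pools.** Parsed from tRNAscan-SE 2.0 tab output, ARAGORN-style text
(score-free rows get raw score 1), or a generic `anticodon/isotype/score`
TSV. Anticodons are uppercased with U→T; pseudogene rows are dropped;
duplicate anticodons aggregate by **maximum** raw score, not sum — the weight
formula names a single normalized score per anticodon, and copy-number
weighting is not part of this index. Mean aggregation is the other defensible
choice; max was selected as the least lossy for quality scores.

## Δ-metrics and study design

Each phage is compared to one assigned host strain: ΔGC (phage gene mean −
host gene mean, percentage points, per GC type), ΔEnC (means over genes with
defined EnC), ΔRSCU (per codon, genome-mean RSCU difference; Met/Trp and
codons undefined on either side excluded), and per-gene ΔtAI against a host
summary statistic (mean by default; the median is always reported alongside
because either is a defensible baseline and the two can diverge on skewed
tAI distributions). All Δs are signed and antisymmetric.

Phages carry two design labels: lifestyle (Virulent/Temperate) and tRNA
group — None (0 tRNA genes), Low (1–5), High (>5). Five contrasts are
assembled per scope (per genus and global): High vs Low, High vs None, Low
vs None, High+Low vs None, Virulent vs Temperate. A contrast with an empty
arm is emitted with a skip flag rather than dropped, so confounded designs
(e.g. a genus where every virulent phage is Low and every temperate phage is
None) stay visible.

The bundled metadata fixture holds 154 phages across 7 host genera with
name, accession, host genus, classification, morphology, lifestyle, genome
size and tRNA-gene count, typed exactly as tabulated in the source metadata
— including the anomalous phiPV83 genome size (456,636 bp), which is
preserved verbatim rather than silently corrected. For genera with several
host strains (Bacillus, Lactobacillus, Salmonella) a separate mapping file
assigns each phage one strain; where the source does not record the pairing
the assignment is best-effort (name-implied where possible) and the file
says so. Genus-level statistics pool host genes across that genus's strains.

## Statistics

Scalar tests wrap SciPy: rank-sum with exact enumeration when
`min(n, m) ≤ 8` and tie-free, else midrank normal approximation with
continuity correction; one-sample signed-rank exact up to n = 15 tie-free.
Kruskal–Wallis is tie-corrected, with effect size `η²_H = H/(N − 1)`.
Dunn's post-hoc z-tests on mean ranks (with the `Σ(t³ − t)` tie term) are
implemented here and adjusted by Bonferroni or Benjamini–Hochberg
(statsmodels); each result row records its adjustment family. Cliff's delta
is computed by sorted-search in O((n+m)log(n+m)) and cross-checked against
brute-force pair counting in tests. The permutation Wilcoxon test permutes
pooled midranks of the centered rank-sum statistic, default 10,000
resamples, `p = (#{|T*| ≥ |T|} + 1)/(B + 1)`. Spearman correlations carry a
strength label (|ρ| ≤ 0.10 very weak, ≤ 0.30 weak, ≤ 0.50 moderate, else
strong; boundaries to the lower bin, since the verbal bins overlap at their
edges).

**PERMANOVA.** Multi-factor with sequential (Type-I) sums of squares on a
Gower-centered distance matrix (hat-matrix trace formulation), factor order
as given — tRNA group before lifestyle in the pipeline, matching the
reporting order of the comparisons. The distance is Euclidean on the signed
ΔRSCU matrix: Bray–Curtis is undefined for negative entries, and no metric
is otherwise dictated. Pseudo-F uses the full-model residual; p-values come
from 9,999 row permutations by default; a perfect within-group fit yields an
infinite pseudo-F handled explicitly. Perfectly confounded joint designs
raise an error instructing single-factor runs, which the pipeline performs
automatically as a fallback. Each factor also gets a homogeneity-of-
dispersion check: distance to group centroid in principal-coordinate space,
ANOVA F, permutation p. Both routines reproduce vegan's `adonis2(by="terms")`
and `betadisper(type="centroid")` to four significant figures in the test
suite, and the single-factor pseudo-F matches a full-enumeration oracle at
n = 6 exactly.

**Beta-model preprocessing.** Per-gene ΔtAI is min-max rescaled into (0, 1):
`(x − d_min + ε)/(d_max − d_min + 2ε)`, with an ε/1−ε clamp as a boundary
guard, and back-transformed by the printed inverse
`μ·(d_max − d_min + 2ε) − ε + d_min` (round trip verified to 1e-9). The
min-max reading is primary because the inverse formula forces it; the clamp
covers the alternative "raise non-positive values to ε" reading. The package
builds the design matrices for `logit(μ) = α + β₁·lifestyle + β₂·tRNA group
(+ host at global scope)` with a random intercept per phage genome and
baselines Temperate/None; numerical fitting of the beta GLMM is delegated to
any established mixed-model routine via the documented `(response, fixed,
groups)` interface. The Gaussian LMM `ΔGC ~ lifestyle + (1|host)` ships with
a convenience fit through statsmodels MixedLM.

All stochastic procedures take a mandatory seed; identical seeds give
byte-identical outputs, and thread count never affects results.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
sequence evolution. Amino-acid frequencies are fixed at an average bacterial
proteome composition and shared by all organisms, so ΔRSCU isolates
synonymous-choice divergence (RSCU is invariant to amino-acid usage).
Within each family, codon probabilities are symmetric-Dirichlet(κ) draws —
κ→0 one dominant codon (strong bias, low EnC), κ→∞ uniform (EnC→61) — then
exponentially tilted on third-position G+C by bisection until the expected
GC3 hits the target within ±0.02 (unreachable targets raise; Met/Trp pin
part of the GC3 mass). Genes are i.i.d. codon draws with lognormal lengths
(default median 250 codons, σ = 0.45, floor 30), so no in-frame stops can
occur; all of the indices here are functions of codon composition, which
i.i.d. sampling spans. Phage profiles mix the host profile with an
independent alternative profile: `(1−δ)·host + δ·alt`, δ ∈ [0, 1] the
divergence. tRNA pools draw uniform quality scores over anticodons matching
the most probable host codons, with at least one decodable anticodon per
family.

Default study scale mirrors the smallest real case: one host of 4,000 genes
(GC3 0.54, κ 0.8), 20 phages of 50–250 genes crossing lifestyle × tRNA group
with divergence rising by group (0.10/0.20/0.35). What passing tests on this
generator do **not** show: robustness to operon structure, position-dependent
codon usage, amino-acid composition differences, horizontal transfer mosaics,
or phylogenetic non-independence among phages — real-data conclusions must
stand on the real-data path.

Test and acceptance simulations use scaled-down studies (hosts of 150–500
genes, genes of ~100–220 codons, 12–100 replicates per property) chosen as
the smallest sizes at which the targeted effects are unambiguous.

## Numerical and policy choices

- ε = 10⁻⁶ throughout (tAI weights, beta rescale), matching the index
  definition.
- Stop codons never enter any index; terminal stops are stripped before
  counting.
- Undefined values (EnC, RSCU of absent families) propagate as None/NaN and
  are excluded from means with logging, never imputed.
- GenBank coordinates are 1-based inclusive at the boundary, 0-based
  half-open internally (Biopython's convention).
- The pipeline's permutation seeds derive deterministically from the run
  seed (per-codon offsets use a byte encoding of the codon, not Python's
  randomized string hash).
- Output tables embed a provenance hash over analysis parameters (file
  locations excluded so identical analyses in different directories hash
  identically).

## Known limitations

- tAI uses strict Watson–Crick matching; organisms relying heavily on wobble
  decoding will have unmatched codons excluded from the geometric mean.
- No phylogenetic correction: near-identical phages are treated as
  independent observations in all tests.
- The beta GLMM itself is not fitted here; only its design matrices,
  rescaling and back-transformation are provided.
- Real-genome retrieval is out of scope; GenBank files are consumed locally.
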