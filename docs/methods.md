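# Methods

## Model and procedure

The package decides, per disputed locus, which of two competing gene models
bulk RNA-seq supports: one merged gene, or two or more separate genes. The
underlying assumption is biological: exons of a single transcribed gene share
one regulatory program, so their expression co-varies across tissues, while
distinct neighbouring genes follow different programs. The M2f statistic
quantifies that divergence, and two simulated null distributions turn it into
a decision rule without any parametric model of expression noise.

### Candidate detection

Candidates come from a syntenic homology comparison of two annotations:

1. Each gene is reduced to its representative transcript — the isoform with
   the longest total CDS. Ties are broken by lexicographically smallest
   transcript ID; the tie-break is arbitrary but must be deterministic so
   reruns are reproducible. Genes with no CDS are skipped (they cannot seed a
   transcript BLAST database).
2. blastn hits between representative transcripts are deduplicated per
   (query gene, subject gene) pair — minimum e-value, ties by maximal aligned
   length — and hits with e-value ≥ 1e-4 are discarded (strict cutoff).
3. A hit survives only if its query and subject genes overlap the two sides
   of one and the same whole-genome-alignment block, each side extended by
   500 kb. Overlap (not containment) is used so genes straddling block edges
   are not lost.
4. Per-gene correspondence classes (none / single / multiple) are confirmed
   reciprocally. A one-to-many relation is kept only when every "many" gene
   maps back exclusively to the one gene; anything else is logged and
   dropped rather than guessed at — many-to-many resolution is out of scope.
5. One-to-many relations are filtered into testable split-gene candidates:
   split genes pairwise non-overlapping, same strand, within a 5-gene rank
   window, all genes expressed, and tandem ratio L1/L2 < 0.1 (strict), where
   L2 is the union of the split genes' aligned intervals on the single gene's
   transcript and L1 the portion covered by more than one split gene.
   Failing candidates are retained with per-filter reasons so exclusion
   statistics stay computable; they are simply not testable.

Genomic rank order (dense per-chromosome ordering by start coordinate) is the
canonical proximity measure. Gene-ID numeric suffixes encode the same
information in some annotation projects but are assembly-specific and break
on re-annotation, so rank is used throughout.

### Expression and M2f

Exon-level counts are the unit of quantification because split/merge disputes
are disputes about which exons belong together. Exons shorter than 50 bp are
dropped (50 bp reads cannot be assigned to them reliably), each library is
TPM-normalized over all retained exons — a global per-library denominator,
preserving cross-gene comparability — and a gene's expression per library is
the unweighted mean of its exons' TPM. A gene is *expressed* when its mean
over libraries is ≥ 0.01 TPM; the mean is taken over all of the relevant
genotype's libraries rather than per library, since candidacy requires the
gene be expressed in the dataset as a whole.

For genes g₁…g_k with expression xᵢ(ℓ) in library ℓ:

    M2f = (1/L) Σ_ℓ  (1/C(k,2)) Σ_{i<j} |log₂((xᵢ(ℓ)+ε)/(xⱼ(ℓ)+ε))|

Only libraries of the genotype whose annotation holds the split (multiple)
gene models are used — they are the data the annotation was built from, and
using another genotype would confound genuine inter-genotype differential
expression with misannotation signal. Replicates enter the flat mean as
independent libraries; no per-tissue pre-averaging is done.

The pseudocount ε (default 0.01 TPM, equal to the expression floor) is a
package design choice: the expression floor guarantees the *mean* expression
is positive but individual libraries can still be zero, and an additive
pseudocount is a bounded, symmetric way to keep the log ratio finite. ε = 0
is supported and used in closed-form tests. For a 2-gene candidate with a
constant fold change f and ε = 0, M2f = |log₂ f| exactly.

### Null distributions and thresholds

- **Split null** — candidates removed; 20% of remaining genes with ≥ 4 exons
  sampled without replacement; each split at a uniformly random internal exon
  junction leaving ≥ 2 exons per side; M2f computed between the half-genes
  (each half's expression is the mean of its exons' TPM). The random split
  position is an exon junction, not a base-pair coordinate: the ≥ 4-exon
  eligibility rule exists precisely so both halves are multi-exon genes, and
  exon counts cannot support sub-exon splits.
- **Merged null** — candidates removed; 30% of remaining expressed genes
  sampled without replacement, each paired with its upstream neighbour
  (next-lower rank on the same chromosome, strand ignored — coordinate
  adjacency is how merge misannotations arise physically); M2f computed on
  the original two loci. Anchors without an eligible neighbour are never
  drawn; the realized sample size is reported.

Thresholds are empirical percentiles with linear interpolation between order
statistics (rank h = 1 + (n−1)p/100); the convention is pinned because the
threshold values depend on it. t_split is the split-null 90th percentile,
t_merge the merged-null 10th percentile, by default pooled across
annotations. Calls use strict inequalities: M2f < t_merge supports the
merged model, M2f > t_split the split models, everything else (including
exact threshold equality) is ambiguous. When the two nulls are widely
separated — common on clean synthetic data — t_merge can exceed t_split; a
value between them then satisfies both strict conditions yet fits neither
null, and is called ambiguous with a warning. On real, noisy data the nulls
overlap and t_merge < t_split, recovering the usual three-band rule.

Fixed percentile cutoffs, not per-candidate p-values, are used deliberately:
the nulls are calibration distributions, and no multiple-testing correction
is applied.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| max_evalue | 1e-4 | — | BLAST hit retention (strict <) |
| margin_bp | 500 000 | bp | synteny block extension |
| window | 5 | gene models | proximity window for "multiple" genes |
| tandem_max | 0.1 | — | L1/L2 tandem-duplicate cutoff (strict <) |
| min_exon_len | 50 | bp | exon length filter (< 50 removed) |
| expression_floor | 0.01 | TPM | expressed-gene cutoff (mean over libraries) |
| epsilon | 0.01 | TPM | pseudocount in log ratios |
| split_fraction / merged_fraction | 0.20 / 0.30 | — | null sampling fractions |
| min_exons_for_split | 4 | exons | split-null eligibility |
| split/merged percentile | 90 / 10 | — | threshold percentiles |

## Synthetic data generator

The generator (`splitgene.fixtures`) emulates the statistical structure the
classifier relies on, not sequences: it emits annotations, post-alignment
BLAST/coords-like tables and exon count matrices directly, so no aligner is
needed anywhere in the test suite. Loci are laid out along one chromosome —
one-to-one background genes first (giving the merged null adjacent
non-candidate pairs), then candidate loci, each one A gene spanning two B
genes. Classes: true_merged (one true gene, B fragments share its profile),
true_split (two true genes), tandem (hits overlap 30% of the subject
transcript), strand-fail and overlap-fail decoys.

Expression: each true gene's per-tissue rate is
`mean_expression · 2^(u_t + d_{g,t})` with locus profile u_t ~ N(0, 1) and,
for the two distinct genes of a locus, offsets d ~ N(0, σ²/2) so their
per-tissue log₂ difference is N(0, σ²). An exon's expected count is the gene
rate scaled by exon length / mean exon length; counts are negative-binomial
(gamma–Poisson) with dispersion 0.1 by default, a standard bulk RNA-seq noise
model; dispersion 0 yields deterministic expected counts for noiseless-limit
tests. Defaults — 10 tissues × 2 replicates, ~50 expected reads per
mean-length exon, σ = 1 (1.5 for recovery studies) — mirror a
ten-tissue developmental atlas with two biological replicates.

What the generator does *not* emulate: mapping bias and multireads, isoform
structure beyond one representative transcript, 3′ coverage bias, correlated
exon-level noise within genes, and genuinely ambiguous loci (partial
read-through). Real split nulls therefore have heavier tails than synthetic
ones — the synthetic split null reflects counting noise only — so passing
recovery tests show the statistic and decision rule work when the model's
assumptions hold, not that real-data accuracy reaches the same level.

## Numerical and design notes

- All intervals are 0-based half-open internally; GFF3 and BLAST coordinates
  convert at the parser boundary.
- All sampling goes through one `numpy.random.Generator`; identical seeds
  give bitwise-identical fixture files, null draws and pipeline outputs.
- `best_hits` tie-breaks (e-value, then length, then subject interval) are
  total, so the dedup is order-independent and idempotent.
- Problem sizes in the test suite and acceptance script — 600 background
  genes, 500 + 500 candidates, 240/360 pooled null draws — were chosen as the
  smallest study at which the empirical percentiles are stable to a few
  percent; the whole acceptance run takes a few seconds.
- When a candidate's two pairwise comparisons disagree only in decisiveness
  (one decisive, one ambiguous), both calls are reported ("partial") and not
  reconciled into a single verdict.

## Known limitations

- Only pairwise comparisons; three-way corroboration operates on two
  candidate lists sharing an annotation, not on a joint three-genome model.
- Many-to-many homologies and tandem arrays beyond the one-to-many pattern
  are dropped, not resolved.
- No uncertainty is attached to an individual M2f value; calls near a
  threshold flip under resampling and the percentile bands are the only
  guard.
- The merged null requires expressed adjacent non-candidate neighbours;
  in gene-sparse or candidate-dense regions its realized n can fall short of
  the nominal fraction (it is reported).
- GTF input and automatic GFF3 rewriting of the supported models are not
  implemented; calls carry the gene IDs and coordinates needed for curation.
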