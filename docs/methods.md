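# Methods

This note documents the models, parameter choices and numerical
conventions behind `cpuorf`, and what the synthetic fixtures do and do
not establish about real data.

## uORF definition and counting

A uORF is an ATG codon within the 5′-UTR of one splice variant together
with its *nearest* downstream in-frame stop codon, the stop lying
entirely within the UTR. Every ATG is reported, so nested and
overlapping uORFs each yield a record. ORFs whose nearest in-frame stop
falls beyond the UTR (i.e. mORF-overlapping ORFs) are not uORFs here;
non-ATG initiation is out of scope. The minimum length is two codons
including the stop (`min_codons`, configurable), so an ATG immediately
followed by a stop counts. Codons containing N never match ATG or a stop;
uORFs with internal ambiguous codons are kept and flagged.

For counting, records of one gene that share a genomic start codon **or**
a genomic stop codon merge transitively into one unit. Merging uses
genomic codon coordinates (multi-block for intron-split codons), so
splice variants with different UTR lengths still merge; the records
themselves are never deleted — every variant's uORF continues through the
pipeline.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
is converted at the parser boundary only. The phase column of the first
CDS segment is honoured; CDS lengths not divisible by three after phase
adjustment cause the transcript to be skipped with a warning. Annotated
`five_prime_UTR` features are cross-checked against the UTR inferred
from exon/CDS structure; inference wins on conflict (logged). Transcripts
with annotated non-ATG start codons are retained and counted in a
warning counter.

## Search engines

Both engines satisfy one contract: peptide query → tabular hits with
BLAST coordinate conventions (1-based; subject nucleotide coordinates
orientation-encoded; frame ±1..±3).

The **builtin engine** translates each record in six frames and computes
one best ungapped local alignment per (record, frame) with BLOSUM62
(gap scores set prohibitively negative), scored with the ungapped
Karlin–Altschul parameters (λ = 0.3176, K = 0.134) and
E = K·m·N·exp(−λS), N being the collection size in residues (total
nt/3). It is exhaustive and deterministic — no seeding heuristics — so it
serves as the reference for tests and small collections.

The **external engine** wraps NCBI BLAST+ `tblastn`/`blastp` with tabular
output (12 standard columns + sframe). For the permissive uORF regime
(E ≤ 2000, short queries) the configuration is
`-seg no -word_size 2 -matrix BLOSUM62`. On the bundled fixtures the two
engines agree on the hit set (subject, frame) for hits at E ≤ 10⁻³;
E-values themselves differ (BLAST applies composition-based corrections)
and are not compared.

## Fusion ratio

A matching record must carry an HSP against the uORF peptide (E ≤ 2000)
and an HSP against the mORF peptide (E < 0.1) downstream of it on the
same strand. A record is *fused* when any such HSP pair shares a reading
frame with no in-frame stop between the uORF HSP end and the mORF HSP
start. r = fused/matching; r ≥ 0.3 discards the uORF; records with no
match leave the ratio undefined and the uORF passes (no evidence of
fusion). The same-frame/no-stop operationalisation is this package's
declared criterion; tolerances for gapped HSP frame inference are not
modelled.

## Putative uORFs and mORF confirmation

Within the frame of a uORF-search hit, the maximal stop-free codon run
containing the HSP is located. The 5′ boundary is the 5′-most in-frame
ATG of the run at or upstream of the HSP start — the maximal ORF
containing the hit. If the run reaches the subject's 5′ end without an
ATG the ORF is accepted as 5′-partial (ESTs are frequently truncated);
otherwise the hit yields no putative uORF. The 3′ boundary is the first
in-frame stop (subject end → 3′-partial). 5′-partial putative uORFs
enter Ka/Ks flagged. mORF confirmation searches only the subject region
downstream of the putative uORF and requires E < 0.1 against the
collection-wide effective database size.

Contaminant removal drops hits whose record lineage is missing or
outside Metazoa, plus records carrying a collection-builder conflict
flag (a `contaminant_flag` column in the taxonomy sidecar). The
predicate is pluggable.

## Ka/Ks and the permutation test

Pairs are aligned at the peptide level (global Needleman–Wunsch with
affine gaps, BLOSUM62, open −11 / extend −1) and back-translated to
codons; gap and ambiguous columns are dropped for counting. Ka and Ks
follow Nei–Gojobori (1986) counting: per-codon synonymous site fractions
averaged over both sequences; multi-site codon differences averaged over
all mutational pathways, each single-base step classified by comparing
translations (steps between two stop codons count as synonymous, other
stop-involving steps as nonsynonymous; mutations to stops count as
nonsynonymous when tallying sites); Jukes–Cantor correction
d = −3/4·ln(1 − 4p/3), undefined (+∞, flagged `saturated`) at p ≥ 3/4.
These conventions match the reference implementation in Biopython's
codon-alignment module to ≤ 1e-9, which the tests exploit as an
independent oracle. Degenerate cases: identical pair → (0, 0), ratio 0,
flagged; Ks = 0 with Ka > 0 → ratio undefined, the pair is excluded from
aggregation.

The empirical null shuffles the codon order of each sequence
independently (preserving codon composition) and re-pairs columns by
index; p = (1 + #{null ≤ observed})/(n_perm + 1), deterministic under a
fixed seed (per-pair seeds derive from the run seed and a CRC of the
pair identity). The test statistic is the **uncorrected pN/pS ratio**
rather than the JC-corrected Ka/Ks: the two are strictly monotone
transforms of each other wherever both corrections are defined, but a
shuffled null pair routinely saturates Ks, where the corrected ratio
degenerates (0/∞ conventions) and would rank maximally diverged null
pairs *below* genuinely conserved pairs, destroying the test's power.
The reported Ka, Ks and the 0.5 selection threshold remain JC-corrected
NG86 values. Alignments with ≤ 2 usable columns get p = 1.

Per uORF, one representative hit per order (lowest mORF-confirmation E;
ties → longer putative uORF, then subject id) is tested; BH adjustment
is applied jointly across all pairs of the run; the uORF is a candidate
iff its median ratio < 0.5 **and** median q < 0.05 (strict, medians over
its per-order pairs — robust to one aberrant order). Default n_perm is
999 in the pipeline (resolution 10⁻³).

## Taxonomic categories and range

Twenty categories partition Metazoa by first-match on a fixed
innermost-first ladder of anchor clades ("X other than Y" = in X after
inner clades are claimed). Ctenophora is kept in the type system and
reported as zero. Distality of a category relative to the query species'
category is the number of clade steps from the query anchor up to their
last common ancestor on the reference cladogram; categories branching at
the same ancestor tie, and the range label picks the most distal
non-empty category with ties broken deterministically by ladder position
(the more inclusive category). Lineages come from a TSV snapshot
(record → semicolon-joined clade list), not live taxonomy queries.

## Families and HG numbering

Ortholog groups ("mORF clusters") use reciprocal protein-search hits
(E < 10⁻³ both directions) and connected components; an external
OrthoFinder-style grouping can substitute behind the same contract — the
reciprocal-component fallback is the default since it requires no
external binaries. Within a group, uORF peptides get binarized distances
(0 when either search direction hits at E < 2000 — asymmetric hits are
OR-symmetrized) and single-linkage clustering cut at h = 0.5; with 0/1
distances this cut provably equals connected components of the hit
graph, and the scipy dendrogram implementation is property-tested
against that oracle. Families sort by (descending range distality,
descending total conserved-order count, ascending representative gene
id) — a total key, so numbering is invariant to input order. HG numbers
enumerate ortholog groups in that order; subnumbers enumerate the uORF
clusters within one group.

Between splice variants, genomically overlapping surviving uORFs
resolve by the declared precedence: same-frame overlaps keep the record
with the longest conserved region — computed programmatically as the
number of original-uORF alignment columns at which ≥ 50% of the
per-order representatives carry the identical residue (a proxy for the
visual judgement the workflow otherwise delegates to a reviewer) — then
the lowest Ka/Ks; different-frame overlaps go directly to the lowest
Ka/Ks. A reviewer-supplied removal list (subject record ids) is
ingested after candidate selection; profiles are recomputed on the
surviving hits (orders, not sequences, are counted, so removing a
redundant record does not shrink the range) and candidates left with
fewer than the minimum orders are discarded.

## Synthetic data

The fixture generator emulates: query genes with planted uORFs (single-
and multi-exon, both strands, two-variant genes), homolog transcripts
from named orders spanning mammalian, avian, fish and insect categories,
fusion transcripts (uORF and mORF joined in frame in every
reference-class homolog, ratio 1.0), mORF-only homologs restricted to
one order, and contaminant records with non-metazoan lineages.
UTR backbones use a {C,T} alphabet so no stray ATG can arise in any
frame, and planted ORF interiors avoid ATG/stop codons at every offset —
the truth table is therefore exact. Homolog uORFs diverge codon-wise
with per-codon substitution probability p = 0.2 and synonymous bias
β = 0.9 (low true ω); mORFs with p = 0.08, β = 0.5 — divergences typical
of confident cross-order homology. The default fixture has 20 genes
(6 conserved / 4 fusion / 4 non-conserved / 3 uORF-free / 3 contaminant)
and runs end to end in seconds with the builtin engine.

What passing fixtures show: every stage implements its declared rule,
and the stages compose correctly. What they do not show: performance on
genome-scale annotation dialects, EST sequencing error, genuinely
borderline homology, or taxonomies with conflicting lineages — real
collections will exercise thresholds far closer to their boundaries
than the planted scenarios do.

For the statistical checks, "neutral" pairs are two independent random
codon sequences: that is exactly the exchangeable null of the
codon-shuffle test, so its p-value is uniform by construction and the
measured type-I error (≈ 0.046 at the 0.05 level, 1,000 pairs) reflects
only discreteness of the permutation distribution. Pairs evolved from a
common ancestor at ω = 1 are *not* exchangeable under codon shuffling
and are used only for parameter recovery of the Ka/Ks estimator
(median estimate ≈ 0.10 at true ω = 0.1 and ≈ 0.99 at ω = 1.0, 100
pairs of 200 codons, branch length 0.2 proposals/site).

## Problem sizes and determinism

Default test and acceptance sizes — 1,000 random UTRs for the scan
oracle, 500 random share graphs and 500 binary matrices for the
clustering oracles, 1,000 neutral pairs (n_perm = 199) for calibration,
100 replicates per ω, and the 20-gene end-to-end fixture — were chosen
so the complete suite runs in well under a minute while keeping Monte
Carlo error small against the stated bands. All randomness flows from
explicit seeds (NumPy `default_rng`); per-pair permutation seeds are
derived from the run seed plus a CRC32 of the pair identity, so results
are independent of iteration order and reruns are byte-identical.

## Known limitations

- Ka/Ks is pairwise NG86 only; no maximum-likelihood codon models,
  branch/site models, or phylogeny-aware estimates (explicit non-goals).
- The builtin engine reports one HSP per (record, frame) and has no
  gapped extension; highly fragmented homologies favour the external
  engine.
- The fusion criterion and the putative-uORF boundary rule are declared
  operationalisations; alternative conventions (e.g. nearest ATG instead
  of 5′-most) would shift boundaries for hits inside long ORFs.
- EST/TSA assembly is out of scope: the collection is consumed as
  provided, and record-level contamination beyond the lineage/flag
  heuristics is not detected.
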