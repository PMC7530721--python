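# cpuorf

Genome-wide discovery of **conserved peptide upstream open reading frames
(CPuORFs)** in animal genomes.

Most upstream ORFs (uORFs) in 5′-UTRs regulate translation of the main ORF
(mORF) in a sequence-independent way, but a minority encode peptides whose
amino-acid sequence is itself under purifying selection — these CPuORFs are
strong candidates for peptide-mediated translational control. `cpuorf`
implements the full search: exhaustive uORF extraction from annotated
5′-UTRs, removal of uORF–mORF fusion artifacts, translated homology search
against transcript evidence collections (RefSeq-like, EST/TSA-like),
selection testing with Ka/Ks, taxonomic-range classification over metazoan
categories, and systematic numbering of CPuORF families (homology groups,
HGs).

It is intended for comparative genomicists who have a genome FASTA, an
Ensembl-dialect GFF3, and a transcript collection with taxonomy metadata,
and want a reproducible, end-to-end CPuORF catalogue.

## The method

For each annotated splice variant, every ATG in the 5′-UTR paired with its
nearest in-frame stop codon (both inside the UTR) defines a uORF. The
pipeline then filters:

1. **Fusion ratio** — for reference-class transcripts matching both the
   uORF and the downstream mORF peptide, the fraction *r* in which the two
   regions form a single reading frame (no intervening in-frame stop).
   uORFs with *r* ≥ 0.3 are discarded as mORF fragments.
2. **Homology** — the uORF peptide is searched permissively (tBLASTn-like,
   E ≤ 2000) against the collection; from each hit the ORF containing the
   HSP is excised (the *putative uORF*), and the hit is accepted only if
   the sequence downstream of the putative uORF also matches the query's
   mORF (E < 0.1). Contaminant records (non-metazoan lineages) are removed.
3. **Conservation & selection** — uORFs conserved in ≥ 2 taxonomic orders
   besides the query's own are tested for purifying selection: one
   representative hit per order, pairwise Ka/Ks by Nei–Gojobori (1986)
   counting with Jukes–Cantor correction, an empirical codon-shuffling
   permutation null per pair, and Benjamini–Hochberg adjustment across all
   pairs. Candidates must have median Ka/Ks < 0.5 and median q < 0.05.
4. **Taxonomic range** — per-order representative hits are mapped onto 20
   mutually exclusive metazoan categories (Euarchontoglires, "Eutheria
   other than Euarchontoglires", …, "Metazoa other than Eumetazoa"); the
   range of conservation is the most distal non-empty category relative to
   the query species.
5. **Families** — CPuORF-containing genes are grouped into ortholog groups
   by mORF similarity; within each group, uORF peptides are clustered by
   single linkage on binarized (0 = hit / 1 = no hit) BLASTp-like
   distances cut at h = 0.5. HG numbers are assigned so that families
   conserved across wider ranges — and, at equal range, in more orders —
   receive smaller numbers ("HG0001.1", "HG0001.2", …).

Homology searches run either on NCBI BLAST+ (`tblastn`/`blastp`) or on a
deterministic builtin engine (six-frame translation + ungapped local
alignment with BLOSUM62 and Karlin–Altschul E-values) that needs no
external binaries.

## Worked example

The package ships a synthetic-data generator that plants uORFs with known
fates (conserved, fusion-artifact, non-conserved, contaminant-only) and a
truth table:

```sh
cpuorf make-fixture --outdir demo_fx --seed 5
cpuorf run-all \
    --genome demo_fx/genome.fa --gff3 demo_fx/genes.gff3 \
    --collection demo_fx/collection.fa --taxonomy demo_fx/taxonomy.tsv \
    --outdir demo_out --query-species "Homo exemplaris" \
    --query-order Primates --seed 1
```

Output:

```
Step 1      uORFs=17  genes=17  records=0
Step 2      uORFs=13  genes=13  records=0
Step 3.1    uORFs=13  genes=13  records=37
Step 3.2    uORFs=13  genes=13  records=37
Step 4.1    uORFs=10  genes=10  records=26
Step 4.2    uORFs=7   genes=7   records=19
Step 4.3    uORFs=6   genes=6   records=18
Step 5      uORFs=6   genes=6   records=18
Step 7-support  uORFs=6  genes=6  records=18
CPuORFs: 6
```

Each row is one pipeline stage: 17 uORFs are extracted (counting uORFs
that share a start or stop codon once), the fusion filter removes the four
planted fusion artifacts, mORF confirmation and contaminant removal strip
non-homologous and non-metazoan hits, and the order/selection filters
leave exactly the six planted conserved uORFs. The resulting
`demo_out/hg_table.tsv` ranks families by conservation breadth:

```
gene_id  uorf_id           hg_label  range_label                           n_orders
G003     G003|G003.t1|30   HG0001.1  Insecta                               4
G006     G006|G006.t1|30   HG0002.1  Insecta                               3
G004     G004|G004.t1|30   HG0003.1  Ostarioclupeomorpha                   3
G001     G001|G001.t1|30   HG0004.1  Aves                                  3
G005     G005|G005.t1|30   HG0005.1  Aves                                  3
G002     G002|G002.t1|30   HG0006.1  Eutheria other than Euarchontoglires  2
```

A uORF conserved out to insects outranks one conserved only within
placental mammals; ties at equal range are broken by the number of
conserved orders. Per-pair Ka/Ks values, permutation p, BH q, taxonomic
profiles and review alignments are written alongside
(`kaks_pairs.tsv`, `profiles.tsv`, `alignments/`).

The same functionality is available as a library; see `examples/` for
short narrative scripts (uORF scanning, Ka/Ks and the permutation test,
taxonomic ranges, family numbering, and the full pipeline).

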