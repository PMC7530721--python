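"""End-to-end CPuORF pipeline: uORF extraction through HG numbering.

Stages (counts are reported per stage in the run report, uORFs counted
with the shared start/stop merging rule):

1.   uORF extraction from all splice variants.
2.   uORF–mORF fusion-ratio filter (reference-class records, r >= 0.3
     discarded).
3.1  Permissive translated search of each uORF peptide (E <= 2000,
     other species only).
3.2  Putative-uORF extraction from each hit.
4.1  mORF confirmation on the sequence downstream of each putative uORF
     (E < 0.1).
4.2  Contaminant removal.
4.3  Conservation in >= 2 non-query orders; identical splice-variant
     uORFs deduplicated by median search E-value.
5.   Per-order representatives, pairwise Ka/Ks + permutation test, BH
     adjustment, candidates with median ratio < 0.5 and median q < 0.05.
6.   Taxonomic conservation range per candidate.
7s.  Support for manual validation: overlap resolution between splice
     variants, optional reviewer removal list, alignment export, and HG
     classification/numbering.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio.Align import PairwiseAligner, substitution_matrices

from . import annotation, families, fusion, homology, selection, taxonomy, uorfs
from .engines import SequenceCollection, get_engine

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults are the published operating point: fusion ratio
    0.3, uORF-search E 2000, mORF confirmation E 0.1, Ka/Ks < 0.5 with
    q < 0.05, >= 2 non-query orders, uORF-cluster cut h = 0.5.
    """

    genome: Path
    gff3: Path
    collection_fasta: Path
    taxonomy_tsv: Path
    outdir: Path
    query_species: str
    query_order: str
    fusion_ratio_max: float = 0.3
    uorf_evalue: float = 2000.0
    morf_evalue: float = 0.1
    kaks_max: float = 0.5
    q_max: float = 0.05
    min_other_orders: int = 2
    min_codons: int = 2
    cluster_h: float = 0.5
    blastp_e: float = 2000.0
    n_perm: int = 999
    seed: int = 0
    engine: str = "builtin"
    removal_list: Path | None = None  #: reviewer-supplied subject ids to drop

    def __post_init__(self):
        for name in ("genome", "gff3", "collection_fasta", "taxonomy_tsv", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.removal_list is not None:
            self.removal_list = Path(self.removal_list)
        for name in ("genome", "gff3", "collection_fasta", "taxonomy_tsv"):
            p = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p}")

    def to_yaml(self, path: Path) -> None:
        d = {k: (str(v) if isinstance(v, Path) else v) for k, v in asdict(self).items()}
        path.write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d.update({k: v for k, v in overrides.items() if v is not None})
        if d.get("removal_list") in ("None", "", None):
            d["removal_list"] = None
        return cls(**d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    models: list = field(default_factory=list)
    records: list = field(default_factory=list)  #: all extracted uORF records
    step_counts: list = field(default_factory=list)  #: (step, n_uorfs, n_genes, n_subjects)
    fusion_stats: dict = field(default_factory=dict)
    confirmed: dict = field(default_factory=dict)  #: uorf_id -> [ConfirmedHit]
    kaks_results: dict = field(default_factory=dict)  #: uorf_id -> [KaKsResult]
    candidates: set = field(default_factory=set)
    profiles: dict = field(default_factory=dict)  #: uorf_id -> TaxonomicProfile
    final_records: list = field(default_factory=list)  #: after step-7 support
    hg_assignments: list = field(default_factory=list)

    @property
    def cpuorf_ids(self) -> set:
        return {a.uorf_id for a in self.hg_assignments}


def _count(step: str, recs, collection_ids=None):
    n_uorfs, n_genes = uorfs.count_distinct_uorfs(recs)
    return (step, n_uorfs, n_genes, len(collection_ids) if collection_ids is not None else 0)


def _aa_aligner():
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def conserved_region_length(uorf_aa: str, rep_peptides: list[str]) -> int:
    """Columns of the original uORF peptide at which >= 50% of the
    representative putative peptides carry the identical residue —
    a programmatic proxy for the manually judged conserved region."""
    if not rep_peptides:
        return 0
    aligner = _aa_aligner()
    match_counts = [0] * len(uorf_aa)
    for pep in rep_peptides:
        if not pep:
            continue
        aln = aligner.align(uorf_aa, pep)[0]
        qb, sb = aln.aligned
        for (q0, q1), (s0, s1) in zip(qb, sb):
            for k in range(q1 - q0):
                if uorf_aa[q0 + k] == pep[s0 + k]:
                    match_counts[q0 + k] += 1
    need = len(rep_peptides) / 2.0
    return sum(1 for c in match_counts if c >= need)


def run_pipeline(config: PipelineConfig, force: bool = True) -> PipelineResult:
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    report_path = out / "report.tsv"
    if report_path.exists() and not force:
        logger.info("report exists and force=False; skipping run")
        return PipelineResult(config=config)
    config.to_yaml(out / "config.yaml")
    engine = get_engine(config.engine)
    collection = SequenceCollection.load(config.collection_fasta, config.taxonomy_tsv)
    res = PipelineResult(config=config)

    # step 0.1 + 1: transcript models and uORF extraction
    warn = annotation.AnnotationWarnings()
    models = annotation.load_annotation(config.gff3, config.genome, warnings=warn)
    res.models = models
    annotation.write_transcript_table(models, out / "transcripts.tsv")
    model_by_tid = {m.transcript_id: m for m in models}
    records = uorfs.extract_gene_uorfs(models, min_codons=config.min_codons)
    res.records = records
    res.step_counts.append(_count("Step 1", records))
    _write_uorf_fastas(records, out)

    # step 2: fusion-ratio filter against reference-class records
    refseq = collection.subset({"refseq"})
    stats = {}
    for r in records:
        morf_aa = model_by_tid[r.transcript_id].morf_aa
        stats[r.uorf_id] = fusion.compute_fusion_stats(
            r, morf_aa, refseq, engine,
            uorf_e_max=config.uorf_evalue, morf_e_max=config.morf_evalue,
        )
    res.fusion_stats = stats
    surviving = fusion.fusion_filter(records, stats, threshold=config.fusion_ratio_max)
    res.step_counts.append(_count("Step 2", surviving))
    _write_fusion_table(stats, config.fusion_ratio_max, out)

    # step 3.1: permissive uORF search, other species only
    hits_by_uorf = {}
    for r in surviving:
        hits = homology.uorf_homology_search(
            r.uorf_id, r.aa_seq, collection, engine,
            query_species=config.query_species, e_max=config.uorf_evalue,
        )
        if hits:
            hits_by_uorf[r.uorf_id] = hits
    surviving = [r for r in surviving if r.uorf_id in hits_by_uorf]
    subjects_31 = {h.subject_id for hs in hits_by_uorf.values() for h in hs}
    res.step_counts.append(_count("Step 3.1", surviving, subjects_31))

    # step 3.2: putative uORF extraction
    putative_by_uorf = {}
    for r in surviving:
        puts = []
        for h in hits_by_uorf[r.uorf_id]:
            p = homology.extract_putative_uorf(h, collection.records[h.subject_id])
            if p is not None:
                puts.append((h, p))
        if puts:
            putative_by_uorf[r.uorf_id] = puts
    surviving = [r for r in surviving if r.uorf_id in putative_by_uorf]
    subjects_32 = {p.subject_id for ps in putative_by_uorf.values() for _, p in ps}
    res.step_counts.append(_count("Step 3.2", surviving, subjects_32))

    # step 4.1: mORF confirmation downstream of the putative uORF
    db_res = collection.total_nt // 3
    confirmed = {}
    rec_by_id = {r.uorf_id: r for r in records}
    for r in surviving:
        morf_aa = model_by_tid[r.transcript_id].morf_aa
        chits = []
        for h, p in putative_by_uorf[r.uorf_id]:
            mh = homology.morf_confirmation(
                morf_aa, p, collection.records[h.subject_id], engine,
                e_max=config.morf_evalue, db_residues=db_res,
            )
            if mh is None:
                continue
            tax = collection.taxonomy.get(h.subject_id)
            chits.append(
                homology.ConfirmedHit(
                    uorf_id=r.uorf_id, subject_id=h.subject_id, putative=p,
                    uorf_hit=h, morf_hit=mh,
                    order=tax.order if tax else "",
                    species=tax.species if tax else "",
                )
            )
        if chits:
            confirmed[r.uorf_id] = chits
    surviving = [r for r in surviving if r.uorf_id in confirmed]
    res.step_counts.append(
        _count("Step 4.1", surviving, {h.subject_id for hs in confirmed.values() for h in hs})
    )

    # step 4.2: contaminant removal
    for uid in list(confirmed):
        confirmed[uid] = homology.filter_contaminants(confirmed[uid], collection)
        if not confirmed[uid]:
            del confirmed[uid]
    surviving = [r for r in surviving if r.uorf_id in confirmed]
    res.step_counts.append(
        _count("Step 4.2", surviving, {h.subject_id for hs in confirmed.values() for h in hs})
    )

    # step 4.3: >= 2 non-query orders; splice-variant dedup by median E
    kept_ids = selection.order_conservation_filter(
        confirmed, config.query_order, min_other_orders=config.min_other_orders
    )
    surviving = [r for r in surviving if r.uorf_id in kept_ids]
    evalues = {
        uid: [h.evalue for h in hits_by_uorf[uid]] for uid in kept_ids if uid in hits_by_uorf
    }
    surviving = selection.dedupe_identical_uorfs(surviving, evalues)
    res.confirmed = {r.uorf_id: confirmed[r.uorf_id] for r in surviving}
    res.step_counts.append(
        _count("Step 4.3", surviving, {h.subject_id for hs in res.confirmed.values() for h in hs})
    )

    # step 5: representatives, Ka/Ks, permutation p, BH q, candidate cut
    reps_by_uorf = {}
    all_results = []
    for r in surviving:
        reps = selection.select_representatives(res.confirmed[r.uorf_id])
        reps = {o: h for o, h in reps.items() if o != config.query_order}
        reps_by_uorf[r.uorf_id] = reps
        all_results.extend(
            selection.kaks_for_pairs(r, reps, n_perm=config.n_perm, seed=config.seed)
        )
    all_results = selection.attach_qvalues(all_results)
    per_uorf = {}
    for kr in all_results:
        per_uorf.setdefault(kr.uorf_id, []).append(kr)
    res.kaks_results = per_uorf
    res.candidates = selection.select_candidates(
        per_uorf, ratio_max=config.kaks_max, q_max=config.q_max
    )
    surviving = [r for r in surviving if r.uorf_id in res.candidates]
    res.step_counts.append(
        _count(
            "Step 5", surviving,
            {h.subject_id for r in surviving for h in res.confirmed[r.uorf_id]},
        )
    )
    _write_kaks_table(all_results, out)

    # step 6: taxonomic range of conservation
    lineages = {rid: t.lineage for rid, t in collection.taxonomy.items()}
    query_category = taxonomy.assign_category(_query_lineage(collection, config))
    for r in surviving:
        res.profiles[r.uorf_id] = taxonomy.conservation_profile(
            reps_by_uorf[r.uorf_id], r.uorf_id, query_category, lineages
        )

    # step 7 support: reviewer removals, overlap resolution, HG numbering
    removed: set = set()
    if config.removal_list and Path(config.removal_list).exists():
        removed = {
            line.strip()
            for line in Path(config.removal_list).read_text().splitlines()
            if line.strip()
        }
        for r in list(surviving):
            uid = r.uorf_id
            hits_by_order: dict[str, list] = {}
            for h in res.confirmed[uid]:
                hits_by_order.setdefault(h.order, []).append(h)
            prof = taxonomy.recompute_after_removal(
                hits_by_order, removed, uid, query_category, lineages
            )
            if prof.n_orders_total < config.min_other_orders:
                surviving.remove(r)
                res.profiles.pop(uid, None)
                res.candidates.discard(uid)
            else:
                res.profiles[uid] = prof

    ratios = {}
    clens = {}
    for r in surviving:
        med_ratio, _ = selection.aggregate(per_uorf.get(r.uorf_id, []))
        ratios[r.uorf_id] = med_ratio if med_ratio is not None else float("inf")
        reps = reps_by_uorf[r.uorf_id]
        clens[r.uorf_id] = conserved_region_length(
            r.aa_seq, [h.putative.orf_aa for h in reps.values()]
        )
    final_records = families.splice_variant_resolution(surviving, clens, ratios)
    res.final_records = final_records
    res.step_counts.append(
        _count(
            "Step 7-support", final_records,
            {h.subject_id for r in final_records for h in res.confirmed[r.uorf_id]},
        )
    )
    _write_alignments(final_records, reps_by_uorf, out)

    # HG classification
    gene_of_uorf = {r.uorf_id: r.gene_id for r in final_records}
    morf_peptides = {}
    for r in final_records:
        pep = model_by_tid[r.transcript_id].morf_aa
        if r.gene_id not in morf_peptides or len(pep) > len(morf_peptides[r.gene_id]):
            morf_peptides[r.gene_id] = pep
    morf_clusters = (
        families.cluster_orthologs(morf_peptides, engine) if morf_peptides else {}
    )
    uorf_clusters = {}
    by_mc: dict[int, list] = {}
    for r in final_records:
        by_mc.setdefault(morf_clusters[r.gene_id], []).append(r)
    for mc, rs in sorted(by_mc.items()):
        peps = {r.uorf_id: r.aa_seq for r in rs}
        ids, dmat = families.uorf_distance_matrix(peps, engine, e_max=config.blastp_e)
        labels = families.single_linkage_cut(dmat, h=config.cluster_h)
        for uid, lab in zip(ids, labels):
            uorf_clusters[uid] = (mc, int(lab))
    res.hg_assignments = families.assign_hg_numbers(
        morf_clusters, uorf_clusters, res.profiles, gene_of_uorf, query_category
    )
    _write_hg_table(res, out)
    _write_profiles(res, out)
    _write_report(res.step_counts, report_path)
    return res


def _query_lineage(collection: SequenceCollection, config: PipelineConfig):
    for t in collection.taxonomy.values():
        if t.species == config.query_species and t.lineage:
            return t.lineage
    raise ValueError(
        f"query species {config.query_species!r} absent from the taxonomy table"
    )


def _write_uorf_fastas(records, out: Path) -> None:
    with open(out / "uorfs_nt.fasta", "w") as fnt, open(out / "uorfs_aa.fasta", "w") as faa:
        for r in records:
            fnt.write(f">{r.uorf_id}\n{r.nt_seq}\n")
            faa.write(f">{r.uorf_id}\n{r.aa_seq}\n")
    with open(out / "uorfs.bed", "w") as bed:
        for r in records:
            (chrom, strand), start_blocks = r.genomic_start_codon
            _, stop_blocks = r.genomic_stop_codon
            blocks = sorted(set(start_blocks) | set(stop_blocks))
            lo, hi = blocks[0][0], blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - lo) for s, e in blocks)
            bed.write(
                f"{chrom}\t{lo}\t{hi}\t{r.uorf_id}\t0\t{strand}\t{lo}\t{hi}\t0\t"
                f"{len(blocks)}\t{sizes}\t{starts}\n"
            )


def _write_fusion_table(stats, threshold, out: Path) -> None:
    with open(out / "fusion.tsv", "w") as fh:
        fh.write("uorf_id\tn_matching\tn_fused\tratio\tverdict\n")
        for uid in sorted(stats):
            st = stats[uid]
            ratio = "" if st.ratio is None else f"{st.ratio:.4f}"
            fh.write(f"{uid}\t{st.n_matching}\t{st.n_fused}\t{ratio}\t{st.verdict(threshold)}\n")


def _write_kaks_table(results, out: Path) -> None:
    with open(out / "kaks_pairs.tsv", "w") as fh:
        fh.write("uorf_id\tsubject_id\torder\tka\tks\tratio\tp_perm\tq\tflags\n")
        for r in sorted(results, key=lambda r: (r.uorf_id, r.order)):
            ratio = "" if r.ratio is None else f"{r.ratio:.6f}"
            fh.write(
                f"{r.uorf_id}\t{r.subject_id}\t{r.order}\t{r.ka:.6f}\t{r.ks:.6f}\t"
                f"{ratio}\t{r.p_perm:.6f}\t{r.q:.6f}\t{','.join(r.flags)}\n"
            )


def _write_profiles(res: PipelineResult, out: Path) -> None:
    with open(out / "profiles.tsv", "w") as fh:
        fh.write("uorf_id\t" + "\t".join(taxonomy.CATEGORIES) + "\trange_label\tn_orders\n")
        for uid in sorted(res.profiles):
            p = res.profiles[uid]
            counts = "\t".join(str(c) for c in p.counts_vector())
            fh.write(f"{uid}\t{counts}\t{p.range_label}\t{p.n_orders_total}\n")


def _write_hg_table(res: PipelineResult, out: Path) -> None:
    with open(out / "hg_table.tsv", "w") as fh:
        fh.write("gene_id\tuorf_id\thg_label\trange_label\tn_orders\n")
        for a in res.hg_assignments:
            prof = res.profiles.get(a.uorf_id)
            fh.write(
                f"{a.gene_id}\t{a.uorf_id}\t{a.label}\t"
                f"{prof.range_label if prof else ''}\t"
                f"{prof.n_orders_total if prof else 0}\n"
            )


def _write_alignments(final_records, reps_by_uorf, out: Path) -> None:
    """Aligned FASTA per candidate for manual review."""
    adir = out / "alignments"
    adir.mkdir(exist_ok=True)
    aligner = _aa_aligner()
    for r in final_records:
        lines = [f">{r.uorf_id}", r.aa_seq]
        for order in sorted(reps_by_uorf.get(r.uorf_id, {})):
            h = reps_by_uorf[r.uorf_id][order]
            if h.putative.orf_aa:
                lines.append(f">{h.subject_id}|{order}")
                lines.append(h.putative.orf_aa)
        safe = r.uorf_id.replace("|", "_").replace("/", "_")
        (adir / f"{safe}.fasta").write_text("\n".join(lines) + "\n")


def _write_report(step_counts, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tn_uorfs\tn_genes\tn_subject_records\n")
        for step, nu, ng, ns in step_counts:
            fh.write(f"{step}\t{nu}\t{ng}\t{ns}\n")
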