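"""CPuORF family (homology-group, HG) classification and numbering.

Genes carrying CPuORFs are first partitioned into ortholog groups (mORF
clusters) by mORF peptide similarity; within each ortholog group, uORF
peptides are compared all-vs-all (E < 2000) to build a binarized 0/1
distance matrix, and single-linkage clustering cut at h = 0.5 yields the
uORF clusters.  With 0/1 distances that cut provably equals the
connected components of the hit (d = 0) graph; the implementation uses a
generic dendrogram cut and is property-tested against the component
oracle.  HG numbers order families by breadth: descending range
distality, then descending total order count, then ascending
representative gene id; subnumbers enumerate the uORF clusters of one
ortholog group in the same order (labels "HG%04d.%d").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .taxonomy import TaxonomicProfile, _LADDER_INDEX, distality

__all__ = [
    "ClusterConfig",
    "HGAssignment",
    "cluster_orthologs",
    "uorf_distance_matrix",
    "single_linkage_cut",
    "assign_hg_numbers",
    "splice_variant_resolution",
]


@dataclass(frozen=True)
class ClusterConfig:
    blastp_e_max: float = 2000.0
    linkage: str = "single"
    cut_height: float = 0.5


@dataclass(frozen=True)
class HGAssignment:
    gene_id: str
    uorf_id: str
    morf_cluster: int
    uorf_cluster: int
    hg_number: int
    hg_subnumber: int

    @property
    def label(self) -> str:
        return f"HG{self.hg_number:04d}.{self.hg_subnumber}"


def cluster_orthologs(
    morf_peptides: dict[str, str],
    engine,
    e_max: float = 1e-3,
) -> dict[str, int]:
    """Partition genes into ortholog groups by reciprocal mORF similarity.

    Built-in grouping: an edge joins two genes when a protein search
    finds each peptide in the other with E < e_max (reciprocal hits);
    clusters are connected components.  An external OrthoFinder-style
    grouping can replace this behind the same gene -> cluster contract.
    Singleton genes form singleton clusters.
    """
    genes = sorted(morf_peptides)
    hit: dict[str, set[str]] = {g: set() for g in genes}
    subjects = dict(morf_peptides)
    for g in genes:
        for h in engine.search_protein(g, morf_peptides[g], subjects, e_max=e_max):
            if h.subject_id != g and h.evalue < e_max:
                hit[g].add(h.subject_id)
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for g in genes:
        for other in hit[g]:
            if g in hit[other]:  # reciprocal
                parent[find(g)] = find(other)
    roots = sorted({find(g) for g in genes})
    root_id = {r: i + 1 for i, r in enumerate(roots)}
    return {g: root_id[find(g)] for g in genes}


def uorf_distance_matrix(
    uorf_peptides: dict[str, str],
    engine,
    e_max: float = 2000.0,
) -> tuple[list[str], np.ndarray]:
    """Binarized distance matrix over one ortholog group's uORF peptides.

    d(i, j) = 0 when either search direction yields a hit with E < e_max
    (OR-symmetrized), else 1; diagonal 0.
    """
    ids = sorted(uorf_peptides)
    n = len(ids)
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    subjects = dict(uorf_peptides)
    for i, qid in enumerate(ids):
        for h in engine.search_protein(qid, uorf_peptides[qid], subjects, e_max=e_max):
            if h.evalue < e_max and h.subject_id in uorf_peptides:
                j = ids.index(h.subject_id)
                d[i, j] = d[j, i] = 0.0
    return ids, d


def single_linkage_cut(matrix: np.ndarray, h: float = 0.5) -> np.ndarray:
    """Single-linkage clustering of a symmetric distance matrix, cut at h.

    Returns integer labels 1..k (scipy ``fcluster`` convention).
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if n == 0:
        return np.empty(0, dtype=int)
    if n == 1:
        return np.array([1])
    z = linkage(squareform(matrix, checks=False), method="single")
    return fcluster(z, t=h, criterion="distance")


@dataclass(frozen=True)
class _Family:
    morf_cluster: int
    uorf_cluster_local: int
    members: tuple[tuple[str, str], ...]  #: (gene_id, uorf_id)
    range_distality: int
    ladder_index: int
    n_orders: int


def assign_hg_numbers(
    morf_clusters: dict[str, int],
    uorf_clusters: dict[str, tuple[int, int]],  #: uorf_id -> (morf_cluster, local uorf cluster)
    profiles: dict[str, TaxonomicProfile],
    gene_of_uorf: dict[str, str],
    query_category: str,
) -> list[HGAssignment]:
    """Number families by conservation breadth.

    Family profile = union of member profiles (max distality, summed
    distinct orders).  Sort: descending distality, descending order
    count, ascending representative (minimum) gene id.  Subnumbers within
    an ortholog group follow the same order, starting at 1.
    """
    fams: dict[tuple[int, int], list[str]] = {}
    for uorf_id, key in uorf_clusters.items():
        fams.setdefault(key, []).append(uorf_id)
    families = []
    for (mc, uc), members in fams.items():
        dist, lad, n_orders = 0, 0, 0
        for u in members:
            prof = profiles[u]
            if prof.range_label:
                d = distality(prof.range_label, query_category)
                lad_i = _LADDER_INDEX[prof.range_label]
                if (d, lad_i) > (dist, lad):
                    dist, lad = d, lad_i
            n_orders += prof.n_orders_total
        families.append(
            _Family(
                morf_cluster=mc,
                uorf_cluster_local=uc,
                members=tuple(sorted((gene_of_uorf[u], u) for u in members)),
                range_distality=dist,
                ladder_index=lad,
                n_orders=n_orders,
            )
        )
    order = sorted(
        families,
        key=lambda f: (-f.range_distality, -f.ladder_index, -f.n_orders, f.members[0][0], f.members[0][1]),
    )
    # HG numbers: one per ortholog group, in first-appearance order of the sort
    hg_of_mc: dict[int, int] = {}
    sub_counter: dict[int, int] = {}
    out: list[HGAssignment] = []
    for fam in order:
        if fam.morf_cluster not in hg_of_mc:
            hg_of_mc[fam.morf_cluster] = len(hg_of_mc) + 1
            sub_counter[fam.morf_cluster] = 0
        sub_counter[fam.morf_cluster] += 1
        hg = hg_of_mc[fam.morf_cluster]
        sub = sub_counter[fam.morf_cluster]
        for gene_id, uorf_id in fam.members:
            out.append(
                HGAssignment(
                    gene_id=gene_id,
                    uorf_id=uorf_id,
                    morf_cluster=fam.morf_cluster,
                    uorf_cluster=fam.uorf_cluster_local,
                    hg_number=hg,
                    hg_subnumber=sub,
                )
            )
    return sorted(out, key=lambda a: (a.hg_number, a.hg_subnumber, a.gene_id, a.uorf_id))


def splice_variant_resolution(
    records: list,
    conserved_len: dict[str, int],
    ratios: dict[str, float],
) -> list:
    """Resolve genomically overlapping candidate uORFs within each gene.

    ``conserved_len`` maps uorf_id to the number of alignment columns
    with majority identity across its representatives (a proxy for the
    manually judged conserved-region length); ``ratios`` maps uorf_id to
    the aggregated Ka/Ks ratio.  Overlap groups (shared genomic
    nucleotides) keep one record: same-frame groups prefer the longest
    conserved region, then the lowest ratio; different-frame overlaps go
    straight to the lowest ratio.  Ties fall back to transcript id.
    """
    by_gene: dict[str, list] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    survivors = []
    for gene, rs in sorted(by_gene.items()):
        spans = {}
        frames = {}
        for r in rs:
            key, start_blocks = r.genomic_start_codon
            _, stop_blocks = r.genomic_stop_codon
            lo = min(b[0] for b in start_blocks + stop_blocks)
            hi = max(b[1] for b in start_blocks + stop_blocks)
            spans[r.uorf_id] = (lo, hi)
            frames[r.uorf_id] = min(b[0] for b in start_blocks) % 3
        # overlap components (union-find over interval intersection)
        parent = {r.uorf_id: r.uorf_id for r in rs}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(rs):
            for b in rs[i + 1 :]:
                (a0, a1), (b0, b1) = spans[a.uorf_id], spans[b.uorf_id]
                if a0 < b1 and b0 < a1:
                    parent[find(a.uorf_id)] = find(b.uorf_id)
        groups: dict[str, list] = {}
        for r in rs:
            groups.setdefault(find(r.uorf_id), []).append(r)
        for group in groups.values():
            if len(group) == 1:
                survivors.append(group[0])
                continue
            same_frame = len({frames[r.uorf_id] for r in group}) == 1

            def key(r):
                clen = conserved_len.get(r.uorf_id, 0)
                ratio = ratios.get(r.uorf_id, float("inf"))
                if same_frame:
                    return (-clen, ratio, r.transcript_id, r.uorf_id)
                return (ratio, r.transcript_id, r.uorf_id)

            survivors.append(min(group, key=key))
    return sorted(survivors, key=lambda r: r.uorf_id)
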