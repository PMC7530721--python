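"""Ortholog grouping, uORF clustering, HG numbering, overlap resolution."""

import networkx as nx
import numpy as np

from cpuorf.families import (
    assign_hg_numbers,
    cluster_orthologs,
    single_linkage_cut,
    splice_variant_resolution,
    uorf_distance_matrix,
)
from cpuorf.taxonomy import TaxonomicProfile
from cpuorf.uorfs import UORFRecord


def _random_binary_dist(rng, n):
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                d[i, j] = d[j, i] = 0.0
    return d


def _component_labels(d):
    g = nx.Graph()
    n = d.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] == 0.0:
                g.add_edge(i, j)
    label = {}
    for k, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            label[node] = k
    return [label[i] for i in range(n)]


def _same_partition(a, b):
    return len(set(zip(a, b))) == len(set(a)) == len(set(b))


def test_single_linkage_cut_examples():
    assert list(single_linkage_cut(np.zeros((3, 3)), 0.5)) == [1, 1, 1]
    d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
    labels = single_linkage_cut(d, 0.5)
    assert labels[0] == labels[1] != labels[2]
    chain = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    assert len(set(single_linkage_cut(chain, 0.5))) == 1  # chaining joins A-C
    assert single_linkage_cut(np.zeros((1, 1)), 0.5).tolist() == [1]
    assert single_linkage_cut(np.zeros((0, 0)), 0.5).size == 0


def test_single_linkage_equals_components_on_random_matrices():
    """Dendrogram cut at h = 0.5 on 0/1 distances == connected components
    of the hit graph (networkx oracle)."""
    rng = np.random.default_rng(17)
    for _ in range(200):
        n = int(rng.integers(2, 15))
        d = _random_binary_dist(rng, n)
        assert _same_partition(single_linkage_cut(d, 0.5), _component_labels(d))


def test_cluster_orthologs_reciprocal_components(engine):
    """Two near-identical mORFs and one diverged: {A,B},{C}; unrelated
    peptides give singletons."""
    pep = "MEDLQKWFNAHTPRVEYGSMEDLQKWFNAHT"
    peps = {
        "A": pep,
        "B": pep[:15] + "A" + pep[16:],
        "C": "MWWYYRRKKDDEEGGHHIIPPLLVV",
    }
    clusters = cluster_orthologs(peps, engine)
    assert clusters["A"] == clusters["B"] != clusters["C"]
    singletons = cluster_orthologs({"X": "MAAAA", "Y": "MWWWW"}, engine)
    assert singletons["X"] != singletons["Y"]
    assert cluster_orthologs({"only": pep}, engine) == {"only": 1}


def test_uorf_distance_matrix_blocks(engine):
    fam1 = "MKHLLQRSTVWDKHLLQRST"
    fam2 = "MGGEEPPFFYYNNCCIIVVA"
    ids, d = uorf_distance_matrix(
        {"a1": fam1, "a2": fam1[:10] + fam1[10:].replace("K", "R")},
        engine, e_max=1e-2,
    )
    assert d[ids.index("a1"), ids.index("a2")] == 0.0
    ids2, d2 = uorf_distance_matrix({"a1": fam1, "b1": fam2}, engine, e_max=1e-6)
    assert d2[ids2.index("a1"), ids2.index("b1")] == 1.0
    assert np.all(d2 == d2.T) and np.all(np.diag(d2) == 0.0)


def _profile(uid, label, n_orders):
    return TaxonomicProfile(
        uorf_id=uid, category_counts={label: n_orders},
        range_label=label, n_orders_total=n_orders,
    )


def test_hg_numbering_breadth_then_orders_then_gene():
    """Wider taxonomic range gets the smaller HG number; ties break by
    order count, then by representative gene id; uORF clusters within one
    ortholog group share the HG number with distinct subnumbers."""
    morf_clusters = {"gA": 1, "gB": 2, "gC": 3, "gD": 3}
    uorf_clusters = {
        "uA": (1, 1),  # Insecta-wide, 4 orders
        "uB": (2, 1),  # Euarchontoglires only, 10 orders
        "uC": (3, 1),  # Aves, 3 orders -> same ortholog group as uD
        "uD": (3, 2),  # Aves, 2 orders
    }
    profiles = {
        "uA": _profile("uA", "Insecta", 4),
        "uB": _profile("uB", "Euarchontoglires", 10),
        "uC": _profile("uC", "Aves", 3),
        "uD": _profile("uD", "Aves", 2),
    }
    gene_of = {"uA": "gA", "uB": "gB", "uC": "gC", "uD": "gD"}
    out = assign_hg_numbers(morf_clusters, uorf_clusters, profiles, gene_of,
                            query_category="Euarchontoglires")
    labels = {a.uorf_id: a.label for a in out}
    assert labels["uA"] == "HG0001.1"  # widest range
    assert labels["uC"] == "HG0002.1"  # Aves beats Euarchontoglires-only
    assert labels["uD"] == "HG0002.2"  # same ortholog group, next subnumber
    assert labels["uB"] == "HG0003.1"


def test_hg_numbering_equal_range_more_orders_wins():
    morf_clusters = {"g1": 1, "g2": 2}
    uorf_clusters = {"u1": (1, 1), "u2": (2, 1)}
    profiles = {
        "u1": _profile("u1", "Aves", 3),
        "u2": _profile("u2", "Aves", 10),
    }
    out = assign_hg_numbers(morf_clusters, uorf_clusters, profiles,
                            {"u1": "g1", "u2": "g2"}, "Euarchontoglires")
    labels = {a.uorf_id: a.label for a in out}
    assert labels["u2"] == "HG0001.1" and labels["u1"] == "HG0002.1"


def test_hg_numbering_invariant_to_input_order():
    rng = np.random.default_rng(23)
    morf_clusters = {f"g{i}": i for i in range(1, 7)}
    uorf_clusters = {f"u{i}": (i, 1) for i in range(1, 7)}
    profiles = {
        f"u{i}": _profile(f"u{i}", lab, n)
        for i, (lab, n) in enumerate(
            [("Insecta", 2), ("Aves", 3), ("Aves", 3), ("Cnidaria", 1),
             ("Euarchontoglires", 5), ("Ostarioclupeomorpha", 2)], start=1)
    }
    gene_of = {f"u{i}": f"g{i}" for i in range(1, 7)}
    baseline = assign_hg_numbers(morf_clusters, uorf_clusters, profiles,
                                 gene_of, "Euarchontoglires")
    base_labels = {(a.uorf_id, a.label) for a in baseline}
    for _ in range(5):
        keys = list(uorf_clusters)
        rng.shuffle(keys)
        shuffled = {k: uorf_clusters[k] for k in keys}
        again = assign_hg_numbers(morf_clusters, shuffled, profiles,
                                  gene_of, "Euarchontoglires")
        assert {(a.uorf_id, a.label) for a in again} == base_labels


def _rec(tid, start, end, gene="g"):
    return UORFRecord(
        uorf_id=f"{gene}|{tid}|{start}", gene_id=gene, transcript_id=tid,
        utr_start=0, utr_stop_end=6,
        genomic_start_codon=(("c", "+"), ((start, start + 3),)),
        genomic_stop_codon=(("c", "+"), ((end - 3, end),)),
        nt_seq="ATGTAA", aa_seq="M",
    )


def test_overlap_resolution_longest_conserved_region_wins():
    a = _rec("t1", 0, 30)
    b = _rec("t2", 9, 39)  # same frame (9 % 3 == 0), overlapping
    out = splice_variant_resolution([a, b], {a.uorf_id: 30, b.uorf_id: 18},
                                    {a.uorf_id: 0.3, b.uorf_id: 0.1})
    assert out == [a]


def test_overlap_resolution_equal_length_lowest_ratio():
    a = _rec("t1", 0, 30)
    b = _rec("t2", 9, 39)
    out = splice_variant_resolution([a, b], {a.uorf_id: 20, b.uorf_id: 20},
                                    {a.uorf_id: 0.3, b.uorf_id: 0.1})
    assert out == [b]


def test_overlap_resolution_different_frames_lowest_ratio():
    a = _rec("t1", 0, 30)
    b = _rec("t2", 10, 40)  # different frame (10 % 3 != 0)
    out = splice_variant_resolution([a, b], {a.uorf_id: 30, b.uorf_id: 5},
                                    {a.uorf_id: 0.4, b.uorf_id: 0.2})
    assert out == [b]


def test_non_overlapping_records_all_survive():
    a = _rec("t1", 0, 30)
    b = _rec("t2", 100, 130)
    out = splice_variant_resolution([a, b], {}, {})
    assert sorted(r.uorf_id for r in out) == sorted([a.uorf_id, b.uorf_id])
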