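"""Cluster CPuORFs into families and assign HG numbers.

Two genes with near-identical mORFs fall into one ortholog group; their
dissimilar uORF peptides split into two uORF clusters, producing
HG labels that share a number with distinct subnumbers.  Numbering
follows conservation breadth: wider taxonomic range first, then more
conserved orders.
"""

from cpuorf import BuiltinEngine, assign_hg_numbers, single_linkage_cut
from cpuorf.families import cluster_orthologs, uorf_distance_matrix
from cpuorf.taxonomy import TaxonomicProfile

engine = BuiltinEngine()

morfs = {
    "geneA": "MEDLQKWFNAHTPRVEYGSMEDLQKWFNAHT",
    "geneB": "MEDLQKWFNAHTPRVEYGSMEDLQKWFNAHA",  # near-identical to geneA
    "geneC": "MWWYYRRKKDDEEGGHHIIPPLLVVSSTTAA",  # unrelated
}
morf_clusters = cluster_orthologs(morfs, engine)
print("ortholog groups:", morf_clusters)

uorfs_in_group = {
    "uA": "MKHLLQRSTVWDKHLLQRST",
    "uB": "MGGEEPPFFYYNNCCIIVVA",  # dissimilar peptide, same ortholog group
}
ids, dist = uorf_distance_matrix(uorfs_in_group, engine, e_max=1e-2)
labels = single_linkage_cut(dist, h=0.5)
print("uORF clusters:", dict(zip(ids, labels)))


def prof(uid, label, n):
    return TaxonomicProfile(uorf_id=uid, category_counts={label: n},
                            range_label=label, n_orders_total=n)


mc = {"geneA": morf_clusters["geneA"], "geneB": morf_clusters["geneB"],
      "geneC": morf_clusters["geneC"]}
uc = {"uA": (mc["geneA"], 1), "uB": (mc["geneB"], 2), "uC": (mc["geneC"], 1)}
profiles = {
    "uA": prof("uA", "Insecta", 5),            # widest range
    "uB": prof("uB", "Euarchontoglires", 2),
    "uC": prof("uC", "Aves", 3),
}
gene_of = {"uA": "geneA", "uB": "geneB", "uC": "geneC"}
for a in assign_hg_numbers(mc, uc, profiles, gene_of, "Euarchontoglires"):
    p = profiles[a.uorf_id]
    print(f"{a.uorf_id} ({a.gene_id}): {a.label}  range={p.range_label}")

print()
print("uA and uB share an HG number (same ortholog group) with different")
print("subnumbers; the Insecta-wide family outranks the others.")
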