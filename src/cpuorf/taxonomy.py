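"""Metazoan taxonomic categories and conservation-range profiles.

Twenty mutually exclusive categories partition Metazoa, each defined by
membership in a named clade minus already-claimed inner clades (e.g.
"Eutheria other than Euarchontoglires").  Assignment is first-match on a
fixed ladder ordered innermost-first, so every metazoan lineage maps to
exactly one category.  "Ctenophora" is kept in the type system but is
expected to stay empty in practice.

The *taxonomic range* of a uORF's conservation is the most distal
category with at least one representative hit, distality being measured
on a fixed cladogram relative to the query species' own category: the
number of clade steps from the query category's anchor up to the last
common ancestor with the other category's anchor.  Categories branching
at the same ancestor tie; ties are broken deterministically by ladder
position (the later, more inclusive category wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CATEGORIES",
    "assign_category",
    "category_of_order",
    "distality",
    "TaxonomicProfile",
    "conservation_profile",
    "recompute_after_removal",
]

#: (category name, anchor clade) ordered innermost-first for first-match
CATEGORY_LADDER: tuple[tuple[str, str], ...] = (
    ("Euarchontoglires", "Euarchontoglires"),
    ("Eutheria other than Euarchontoglires", "Eutheria"),
    ("Mammalia other than Eutheria", "Mammalia"),
    ("Aves", "Aves"),
    ("Sauropsida other than Aves", "Sauropsida"),
    ("Amphibia", "Tetrapoda"),  # Tetrapoda other than Sauropsida and Mammalia
    ("Sarcopterygii other than Tetrapoda", "Sarcopterygii"),
    ("Ostarioclupeomorpha", "Ostarioclupeomorpha"),
    ("Actinopterygii other than Ostarioclupeomorpha", "Actinopterygii"),
    ("Vertebrata other than Euteleostomi", "Vertebrata"),
    ("Chordata other than Vertebrata", "Chordata"),
    ("Deuterostomia other than Chordata", "Deuterostomia"),
    ("Insecta", "Insecta"),
    ("Arthropoda other than Insecta", "Arthropoda"),
    ("Ecdysozoa other than Arthropoda", "Ecdysozoa"),
    ("Lophotrochozoa", "Protostomia"),  # Protostomia other than Ecdysozoa
    ("Bilateria other than Protostomia and Deuterostomia", "Bilateria"),
    ("Cnidaria", "Cnidaria"),
    ("Ctenophora", "Eumetazoa"),  # Eumetazoa other than Cnidaria and Bilateria
    ("Metazoa other than Eumetazoa", "Metazoa"),
)

CATEGORIES: tuple[str, ...] = tuple(name for name, _ in CATEGORY_LADDER)
_LADDER_INDEX = {name: i for i, (name, _) in enumerate(CATEGORY_LADDER)}
_ANCHOR = dict(CATEGORY_LADDER)

#: reference cladogram: clade -> parent clade
_PARENT: dict[str, str] = {
    "Eumetazoa": "Metazoa",
    "Bilateria": "Eumetazoa",
    "Cnidaria": "Eumetazoa",
    "Deuterostomia": "Bilateria",
    "Protostomia": "Bilateria",
    "Chordata": "Deuterostomia",
    "Vertebrata": "Chordata",
    "Euteleostomi": "Vertebrata",
    "Actinopterygii": "Euteleostomi",
    "Sarcopterygii": "Euteleostomi",
    "Ostarioclupeomorpha": "Actinopterygii",
    "Tetrapoda": "Sarcopterygii",
    "Mammalia": "Tetrapoda",
    "Sauropsida": "Tetrapoda",
    "Eutheria": "Mammalia",
    "Euarchontoglires": "Eutheria",
    "Aves": "Sauropsida",
    "Ecdysozoa": "Protostomia",
    "Arthropoda": "Ecdysozoa",
    "Insecta": "Arthropoda",
}


def assign_category(lineage) -> str:
    """Map an ordered clade list (NCBI-style lineage) to its category.

    Raises ValueError for lineages outside Metazoa — those should have
    been removed by the contaminant filter.
    """
    names = set(lineage)
    if "Metazoa" not in names:
        raise ValueError(f"lineage outside Metazoa: {list(lineage)!r}")
    for category, anchor in CATEGORY_LADDER:
        if anchor in names:
            return category
    return "Metazoa other than Eumetazoa"


def _path_to_root(clade: str) -> list[str]:
    path = [clade]
    while path[-1] in _PARENT:
        path.append(_PARENT[path[-1]])
    return path


def distality(category: str, query_category: str) -> int:
    """Clade steps from the query category's anchor up to the MRCA with
    ``category``'s anchor on the reference cladogram (0 = same category)."""
    if category == query_category:
        return 0
    qpath = _path_to_root(_ANCHOR[query_category])
    apath = set(_path_to_root(_ANCHOR[category]))
    for steps, clade in enumerate(qpath):
        if clade in apath:
            return steps
    return len(qpath)


@dataclass
class TaxonomicProfile:
    """Per-uORF conservation profile over the 20 categories."""

    uorf_id: str
    category_counts: dict[str, int] = field(default_factory=dict)
    range_label: str = ""
    n_orders_total: int = 0

    def counts_vector(self) -> list[int]:
        return [self.category_counts.get(c, 0) for c in CATEGORIES]


def category_of_order(hits, order: str) -> str:
    """Category of one order, from any hit of that order."""
    for h in hits:
        if h.order == order:
            return assign_category(h.lineage)
    raise KeyError(order)


def conservation_profile(
    representatives: dict[str, "object"],
    uorf_id: str,
    query_category: str,
    lineages: dict[str, tuple[str, ...]],
) -> TaxonomicProfile:
    """Profile from per-order representative hits.

    ``lineages`` maps subject record id -> lineage.  Counts are distinct
    orders per category; the range label is the most distal nonzero
    category (ties by ladder position).
    """
    counts: dict[str, int] = {}
    orders_by_cat: dict[str, set[str]] = {}
    for order, hit in representatives.items():
        first = hit[0] if isinstance(hit, (list, tuple)) else hit
        lineage = lineages[first.subject_id]
        cat = assign_category(lineage)
        orders_by_cat.setdefault(cat, set()).add(order)
    for cat, orders in orders_by_cat.items():
        counts[cat] = len(orders)
    label = ""
    if counts:
        label = max(
            counts, key=lambda c: (distality(c, query_category), _LADDER_INDEX[c])
        )
    return TaxonomicProfile(
        uorf_id=uorf_id,
        category_counts=counts,
        range_label=label,
        n_orders_total=sum(counts.values()),
    )


def recompute_after_removal(
    representatives: dict[str, "object"],
    removed_subjects: set[str],
    uorf_id: str,
    query_category: str,
    lineages: dict[str, tuple[str, ...]],
) -> TaxonomicProfile:
    """Re-derive the profile after excluding manually removed subjects.

    Values of ``representatives`` may be single hits or lists of hits of
    one order; an order survives while it retains at least one hit, so
    removing a redundant sequence does not change order-level counts.
    """
    surviving: dict[str, list] = {}
    for order, hit in representatives.items():
        hits = list(hit) if isinstance(hit, (list, tuple)) else [hit]
        left = [h for h in hits if h.subject_id not in removed_subjects]
        if left:
            surviving[order] = left
    return conservation_profile(surviving, uorf_id, query_category, lineages)
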