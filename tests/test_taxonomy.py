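"""Category assignment, the category partition property, distality and
conservation-range profiles."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpuorf.taxonomy import (
    CATEGORIES,
    CATEGORY_LADDER,
    _PARENT,
    assign_category,
    conservation_profile,
    distality,
    recompute_after_removal,
)

_MUS = ("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata",
        "Vertebrata", "Euteleostomi", "Sarcopterygii", "Tetrapoda", "Mammalia",
        "Eutheria", "Euarchontoglires", "Rodentia")
_BOS = ("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata",
        "Vertebrata", "Euteleostomi", "Sarcopterygii", "Tetrapoda", "Mammalia",
        "Eutheria", "Laurasiatheria", "Artiodactyla")
_DANIO = ("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata",
          "Vertebrata", "Euteleostomi", "Actinopterygii", "Ostarioclupeomorpha",
          "Cypriniformes")
_FLY = ("Metazoa", "Eumetazoa", "Bilateria", "Protostomia", "Ecdysozoa",
        "Arthropoda", "Insecta", "Diptera")
_HYDRA = ("Metazoa", "Eumetazoa", "Cnidaria", "Hydrozoa")
_SPONGE = ("Metazoa", "Porifera")


@pytest.mark.parametrize(
    "lineage, expected",
    [
        (_MUS, "Euarchontoglires"),
        (_BOS, "Eutheria other than Euarchontoglires"),
        (_DANIO, "Ostarioclupeomorpha"),
        (_FLY, "Insecta"),
        (_HYDRA, "Cnidaria"),
        (_SPONGE, "Metazoa other than Eumetazoa"),
        (("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata",
          "Vertebrata", "Euteleostomi", "Sarcopterygii", "Tetrapoda",
          "Sauropsida", "Aves", "Galliformes"), "Aves"),
        (("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata",
          "Vertebrata", "Euteleostomi", "Sarcopterygii", "Tetrapoda",
          "Amphibia", "Anura"), "Amphibia"),
        (("Metazoa", "Eumetazoa", "Bilateria", "Protostomia", "Lophotrochozoa",
          "Mollusca"), "Lophotrochozoa"),
    ],
)
def test_assign_category(lineage, expected):
    assert assign_category(lineage) == expected


def test_non_metazoan_lineage_rejected():
    with pytest.raises(ValueError):
        assign_category(("Eukaryota", "Alveolata", "Apicomplexa"))


def _lineage_for_clade(clade: str) -> tuple[str, ...]:
    """Root-to-clade path on the reference cladogram."""
    path = [clade]
    while path[-1] in _PARENT:
        path.append(_PARENT[path[-1]])
    return tuple(reversed(path))


@settings(max_examples=200, deadline=None)
@given(
    anchor=st.sampled_from([a for _, a in CATEGORY_LADDER]),
    extra=st.lists(st.sampled_from(["OrderX", "FamilyY", "GenusZ"]), max_size=3),
)
def test_category_partition_exhaustive_and_disjoint(anchor, extra):
    """Every lineage that descends from any anchor clade maps to exactly
    one of the 20 categories."""
    lineage = _lineage_for_clade(anchor) + tuple(extra)
    cat = assign_category(lineage)
    assert cat in CATEGORIES
    # first-match semantics: no earlier category's anchor is in the lineage
    names = set(lineage)
    for name, a in CATEGORY_LADDER:
        if name == cat:
            break
        assert a not in names


def test_distality_ladder_for_euarchontoglires_query():
    """From a Euarchontoglires query: Eutheria < Mammalia < the Tetrapoda
    trio (tied) < Sarcopterygii < the fish categories < ... < Metazoa."""
    q = "Euarchontoglires"
    assert distality("Euarchontoglires", q) == 0
    assert distality("Eutheria other than Euarchontoglires", q) == 1
    assert distality("Mammalia other than Eutheria", q) == 2
    trio = {distality("Aves", q), distality("Sauropsida other than Aves", q),
            distality("Amphibia", q)}
    assert trio == {3}
    assert distality("Sarcopterygii other than Tetrapoda", q) == 4
    assert distality("Ostarioclupeomorpha", q) == 5
    assert distality("Actinopterygii other than Ostarioclupeomorpha", q) == 5
    assert distality("Insecta", q) == 9
    assert distality("Cnidaria", q) == 10
    assert distality("Metazoa other than Eumetazoa", q) == 11


class _Hit:
    def __init__(self, subject_id):
        self.subject_id = subject_id


def test_conservation_profile_counts_orders_and_range():
    reps = {"Rodentia": _Hit("r1"), "Carnivora": _Hit("c1")}
    lineages = {"r1": _MUS, "c1": _BOS}
    prof = conservation_profile(reps, "u", "Euarchontoglires", lineages)
    assert prof.category_counts == {
        "Euarchontoglires": 1,
        "Eutheria other than Euarchontoglires": 1,
    }
    assert prof.range_label == "Eutheria other than Euarchontoglires"
    assert prof.n_orders_total == 2
    assert len(prof.counts_vector()) == len(CATEGORIES)


def test_profile_range_extends_with_distal_hits():
    reps = {"Rodentia": _Hit("r1"), "Diptera": _Hit("f1")}
    prof = conservation_profile(
        reps, "u", "Euarchontoglires", {"r1": _MUS, "f1": _FLY}
    )
    assert prof.range_label == "Insecta"


def test_recompute_after_removal_contracts_range():
    reps = {"Rodentia": [_Hit("r1")], "Galliformes": [_Hit("a1")]}
    lineages = {
        "r1": _MUS,
        "a1": ("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata",
               "Vertebrata", "Euteleostomi", "Sarcopterygii", "Tetrapoda",
               "Sauropsida", "Aves", "Galliformes"),
    }
    full = conservation_profile(reps, "u", "Euarchontoglires", lineages)
    assert full.range_label == "Aves"
    cut = recompute_after_removal(reps, {"a1"}, "u", "Euarchontoglires", lineages)
    assert cut.range_label == "Euarchontoglires"
    same = recompute_after_removal(reps, set(), "u", "Euarchontoglires", lineages)
    assert same.category_counts == full.category_counts


def test_removal_of_redundant_sequence_keeps_order_counts():
    """Orders, not sequences, are counted: dropping one of two hits of the
    same order leaves the profile unchanged."""
    reps = {"Rodentia": [_Hit("r1"), _Hit("r2")]}
    lineages = {"r1": _MUS, "r2": _MUS}
    before = conservation_profile(reps, "u", "Euarchontoglires", lineages)
    after = recompute_after_removal(reps, {"r2"}, "u", "Euarchontoglires", lineages)
    assert after.category_counts == before.category_counts == {"Euarchontoglires": 1}
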