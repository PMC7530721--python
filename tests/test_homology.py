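"""Putative-uORF extraction, mORF confirmation, contaminant removal."""

import pytest
from Bio.Seq import Seq

from cpuorf.engines import SearchHit, SequenceCollection, TaxonRecord
from cpuorf.homology import (
    ConfirmedHit,
    extract_putative_uorf,
    filter_contaminants,
    morf_confirmation,
    uorf_homology_search,
)

_STOPS = {"TAA", "TAG", "TGA"}


def _hit(subject_id, frame, s_start, s_end, q_len, evalue=1e-6):
    return SearchHit(
        query_id="q", subject_id=subject_id, evalue=evalue, identity_pct=95.0,
        q_start=1, q_end=q_len, s_start=s_start, s_end=s_end, frame=frame,
    )


def brute_force_orfs(seq: str):
    """All maximal ORF-like codon runs in all 6 frames (oracle)."""
    out = []
    for oriented, sign in ((seq, 1), (str(Seq(seq).reverse_complement()), -1)):
        for off in range(3):
            codons = [
                oriented[i : i + 3]
                for i in range(off, len(oriented) - 2, 3)
            ]
            run = []
            for idx, c in enumerate(codons):
                if c in _STOPS:
                    out.append((sign * (off + 1), run, idx))
                    run = []
                else:
                    run.append((idx, c))
            out.append((sign * (off + 1), run, len(codons)))
    return out


def test_exact_uorf_copy_recovered():
    """Subject carrying ATG...TAA copy; HSP covering it -> that ORF."""
    orf = "ATGAAACATCTTCAACGTTAA"
    seq = "CCTCCT" + orf + "CCTCCT"
    # HSP over the coding part: aa 1..6, nt 7..24 (frame +1)
    hit = _hit("s", 1, 7, 24, 6)
    p = extract_putative_uorf(hit, seq)
    assert p is not None
    assert p.orf_nt == orf
    assert p.orf_aa == "MKHLQR"
    assert not p.five_prime_partial and not p.three_prime_partial


def test_boundaries_extend_to_upstream_atg_and_downstream_stop():
    """HSP mid-ORF with the ATG 4 codons upstream and the stop 3 codons
    downstream: boundaries land on that ATG and stop (verified against a
    brute-force enumeration of all ORFs in all frames)."""
    up = "ATG" + "CAT" * 3  # ATG + 3 codons before the HSP
    hsp = "CTTCAACGTTCTACT"  # 5 codons
    down = "GTT" * 2 + "TAA"
    seq = "TCC" + up + hsp + down + "TCC"
    hsp_start_nt = 3 + len(up) + 1  # 1-based
    hit = _hit("s", 1, hsp_start_nt, hsp_start_nt + len(hsp) - 1, 5)
    p = extract_putative_uorf(hit, seq)
    assert p is not None
    assert p.orf_nt == up + hsp + down
    # cross-check against the 6-frame brute-force ORF enumeration
    frame_runs = [
        run for frame, run, stop_idx in brute_force_orfs(seq)
        if frame == 1 and any(c == "ATG" for _, c in run)
    ]
    (run,) = frame_runs
    start_idx = next(i for i, c in run if c == "ATG")
    oracle_nt = "".join(c for i, c in run if i >= start_idx) + "TAA"
    assert p.orf_nt == oracle_nt


def test_no_atg_no_subject_edge_returns_none():
    seq = "TCCTAA" + "CATCTTCAACGT" + "TAATCC"  # stop-bounded run, no ATG
    hit = _hit("s", 1, 7, 18, 4)
    assert extract_putative_uorf(hit, seq) is None


def test_truncated_record_yields_five_prime_partial():
    seq = "CATCTTCAACGTTAATCC"  # run starts at the subject 5' end, no ATG
    hit = _hit("s", 1, 1, 12, 4)
    p = extract_putative_uorf(hit, seq)
    assert p is not None and p.five_prime_partial
    assert p.orf_nt.startswith("CAT")


def test_minus_strand_extraction():
    orf = "ATGAAACATCTTCAACGTTAA"
    plus = "CCTCCT" + orf + "CCTCCT"
    seq = str(Seq(plus).reverse_complement())
    n = len(seq)
    # hit on frame -1..-3: coding part occupies plus-strand coords 7..24
    s_start = n - 6  # maps to oriented nt0 = 6 (0-based)
    hit = _hit("s", -(((6) % 3) + 1), s_start, s_start - 17, 6)
    p = extract_putative_uorf(hit, seq)
    assert p is not None
    assert p.orf_nt == orf


def test_hsp_outside_subject_raises():
    with pytest.raises(ValueError):
        extract_putative_uorf(_hit("s", 1, 100, 130, 10), "ATGCCC")


_MORF_NT = "ATGGAAGATCTTCAAAAATGGTTTAATGCTCATACTCCTCGTGTTGAATATGGTTCT"
_MORF_AA = "MEDLQKWFNAHTPRVEYGS"


def test_morf_confirmation_threshold(engine):
    orf = "ATGAAACATCTTCAACGTTAA"
    seq = "CCT" + orf + "CCCTAA" + _MORF_NT + "CC"
    hit = _hit("s", 1, 4, 21, 6)
    p = extract_putative_uorf(hit, seq)
    mh = morf_confirmation(_MORF_AA, p, seq, engine, e_max=0.1)
    assert mh is not None and mh.evalue < 0.1
    # an unrelated downstream region fails confirmation
    seq2 = "CCT" + orf + "CCTCCTCCTCCTCCTCCTCCT"
    hit2 = _hit("s2", 1, 4, 21, 6)
    p2 = extract_putative_uorf(hit2, seq2)
    assert morf_confirmation(_MORF_AA, p2, seq2, engine, e_max=0.1) is None


def test_morf_confirmation_no_downstream_sequence(engine):
    orf = "ATGAAACATCTTCAACGTTAA"
    seq = "CCT" + orf  # ORF ends at the subject 3' end
    hit = _hit("s", 1, 4, 21, 6)
    p = extract_putative_uorf(hit, seq)
    assert morf_confirmation(_MORF_AA, p, seq, engine) is None


def test_own_species_hits_excluded(engine):
    pep = "MKHLQR"
    nt = "CCT" + "ATGAAACATCTTCAACGT" + "TAACC"
    coll = SequenceCollection(
        {"own": nt, "other": nt},
        {
            "own": TaxonRecord("own", 1, "Homo exemplaris", "Primates", ("Metazoa",), "refseq"),
            "other": TaxonRecord("other", 2, "Mus fictus", "Rodentia", ("Metazoa",), "refseq"),
        },
    )
    hits = uorf_homology_search("u", pep, coll, engine, query_species="Homo exemplaris")
    assert {h.subject_id for h in hits} == {"other"}


def _chit(subject_id):
    h = _hit(subject_id, 1, 1, 9, 3)
    return ConfirmedHit(
        uorf_id="u", subject_id=subject_id, putative=None, uorf_hit=h,
        morf_hit=h, order="Rodentia", species="x",
    )


def test_contaminant_filter_rules():
    taxonomy = {
        "ok": TaxonRecord("ok", 1, "Mus fictus", "Rodentia",
                          ("Metazoa", "Eumetazoa"), "refseq"),
        "nonmetazoan": TaxonRecord("nonmetazoan", 2, "Plasmodium f.", "Haemosporida",
                                   ("Eukaryota", "Apicomplexa"), "est"),
        "nolineage": TaxonRecord("nolineage", 3, "?", "?", (), "est"),
        "flagged": TaxonRecord("flagged", 4, "Mus fictus", "Rodentia",
                               ("Metazoa",), "est", contaminant_flag=True),
    }
    coll = SequenceCollection({k: "ATG" for k in taxonomy}, taxonomy)
    hits = [_chit(k) for k in ("ok", "nonmetazoan", "nolineage", "flagged", "unknown")]
    kept = filter_contaminants(hits, coll)
    assert {h.subject_id for h in kept} == {"ok"}
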