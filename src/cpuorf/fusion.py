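"""uORF–mORF fusion-ratio filter.

Some apparent uORFs are conserved only because they encode the N-terminus
of the main protein in most homologous transcripts (the annotated stop
between uORF and mORF being absent there).  For each uORF, reference-class
(RefSeq-like) records matching both the uORF peptide and the downstream
mORF peptide are collected; a matching record is *fused* when its uORF
and mORF HSPs lie in the same reading frame with no intervening in-frame
stop codon.  The fusion ratio r = fused / matching; uORFs with r >= 0.3
are discarded, and uORFs with no matching record are retained (the ratio
is undefined, so there is no evidence of fusion).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .engines import SearchHit, SequenceCollection
from .uorfs import UORFRecord

__all__ = ["FusionStats", "find_matching_records", "is_fused", "compute_fusion_stats", "fusion_filter"]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class FusionStats:
    uorf_id: str
    n_matching: int
    n_fused: int

    @property
    def ratio(self) -> float | None:
        return self.n_fused / self.n_matching if self.n_matching else None

    def verdict(self, threshold: float = 0.3) -> str:
        r = self.ratio
        return "discard" if (r is not None and r >= threshold) else "pass"


def _oriented_interval(hit: SearchHit) -> tuple[int, int, int]:
    """(start0, end0, strand) on the subject's plus strand, 0-based half-open."""
    if hit.s_start <= hit.s_end:
        return hit.s_start - 1, hit.s_end, 1
    return hit.s_end - 1, hit.s_start, -1


def find_matching_records(
    uorf: UORFRecord,
    morf_aa: str,
    collection: SequenceCollection,
    engine,
    uorf_e_max: float = 2000.0,
    morf_e_max: float = 0.1,
) -> list[tuple[str, SearchHit, SearchHit]]:
    """Records with HSPs against both the uORF and its downstream mORF.

    The mORF HSP must lie downstream of the uORF HSP on the subject (in
    the orientation of the hits, which must agree).  One best pair per
    record is kept; every qualifying (uORF-HSP, mORF-HSP) pair is
    examined by the fusion test separately via :func:`compute_fusion_stats`.
    """
    uorf_hits = engine.search_translated(uorf.uorf_id, uorf.aa_seq, collection, e_max=uorf_e_max)
    if not uorf_hits:
        return []
    morf_hits = engine.search_translated(uorf.uorf_id + "|morf", morf_aa, collection, e_max=morf_e_max)
    morf_by_subject: dict[str, list[SearchHit]] = {}
    for h in morf_hits:
        morf_by_subject.setdefault(h.subject_id, []).append(h)
    out = []
    seen: set[str] = set()
    for uh in uorf_hits:
        for mh in morf_by_subject.get(uh.subject_id, []):
            if (uh.frame > 0) != (mh.frame > 0):
                continue
            u0, u1, strand = _oriented_interval(uh)
            m0, m1, _ = _oriented_interval(mh)
            downstream = m0 >= u1 if strand > 0 else m1 <= u0
            if downstream and uh.subject_id not in seen:
                seen.add(uh.subject_id)
                out.append((uh.subject_id, uh, mh))
    return out


def is_fused(uorf_hit: SearchHit, morf_hit: SearchHit, subject_seq: str) -> bool:
    """True iff the two HSPs share a reading frame with no in-frame stop between them."""
    if uorf_hit.frame == 0 or morf_hit.frame == 0:
        raise ValueError("fusion test requires translated-search hits with frames")
    if uorf_hit.frame != morf_hit.frame:
        return False
    seq = subject_seq.upper()
    if uorf_hit.frame < 0:
        seq = str(Seq(seq).reverse_complement())
    # oriented coordinates on the reading strand
    def oriented(hit: SearchHit) -> tuple[int, int]:
        if hit.frame > 0:
            return hit.s_start - 1, hit.s_end
        n = len(seq)
        return n - hit.s_start, n - hit.s_end + 1

    u0, u1 = oriented(uorf_hit)
    m0, m1 = oriented(morf_hit)
    if m0 < u1:
        return False
    for p in range(u1, m0 - 2, 3):
        if seq[p : p + 3] in _STOPS:
            return False
    return True


def compute_fusion_stats(
    uorf: UORFRecord,
    morf_aa: str,
    collection: SequenceCollection,
    engine,
    uorf_e_max: float = 2000.0,
    morf_e_max: float = 0.1,
) -> FusionStats:
    matches = find_matching_records(
        uorf, morf_aa, collection, engine, uorf_e_max=uorf_e_max, morf_e_max=morf_e_max
    )
    n_fused = sum(
        1 for sid, uh, mh in matches if is_fused(uh, mh, collection.records[sid])
    )
    return FusionStats(uorf_id=uorf.uorf_id, n_matching=len(matches), n_fused=n_fused)


def fusion_filter(
    records: list[UORFRecord],
    stats: dict[str, FusionStats],
    threshold: float = 0.3,
) -> list[UORFRecord]:
    """Drop uORFs whose defined fusion ratio meets or exceeds the threshold."""
    out = []
    for r in records:
        st = stats.get(r.uorf_id)
        verdict = st.verdict(threshold) if st is not None else "pass"
        r.status["fusion_pass"] = verdict == "pass"
        if verdict == "pass":
            out.append(r)
    return out
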