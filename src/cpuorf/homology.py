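"""Translated homology search steps: permissive uORF search, putative-uORF
extraction, mORF orthology confirmation, and contaminant removal.

The uORF peptide is first searched permissively (E <= 2000) against the
whole transcript evidence collection, keeping only hits from species
other than the query species.  From each hit, the open reading frame
containing the HSP is cut out as a *putative uORF* (first in-frame ATG of
the stop-free segment at or upstream of the HSP; partial records at the
subject 5' end are tolerated and flagged).  A hit is accepted as coming
from a genuine homolog only if the sequence downstream of the putative
uORF also matches the query's mORF peptide (E < 0.1).  Finally, hits
from contaminant records (non-metazoan lineage, missing lineage, or a
collection-builder conflict flag) are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

from Bio.Seq import Seq

from .engines import SearchHit, SequenceCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PutativeUORF",
    "ConfirmedHit",
    "uorf_homology_search",
    "extract_putative_uorf",
    "morf_confirmation",
    "filter_contaminants",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class PutativeUORF:
    """ORF cut from a translated-search hit around its HSP."""

    subject_id: str
    orf_nt: str  #: includes the stop codon when one was found
    orf_aa: str  #: no stop symbol
    subject_interval: tuple[int, int]  #: 0-based half-open, on the reading strand
    five_prime_partial: bool
    three_prime_partial: bool
    source_hit: SearchHit


@dataclass(frozen=True)
class ConfirmedHit:
    """A uORF-search hit that passed mORF confirmation."""

    uorf_id: str
    subject_id: str
    putative: PutativeUORF
    uorf_hit: SearchHit
    morf_hit: SearchHit
    order: str
    species: str


def uorf_homology_search(
    uorf_id: str,
    uorf_aa: str,
    collection: SequenceCollection,
    engine,
    query_species: str,
    e_max: float = 2000.0,
) -> list[SearchHit]:
    """Permissive translated search of a uORF peptide, other species only.

    One best-E hit is kept per subject record.
    """
    hits = engine.search_translated(uorf_id, uorf_aa, collection, e_max=e_max)
    best: dict[str, SearchHit] = {}
    for h in hits:
        tax = collection.taxonomy.get(h.subject_id)
        if tax is not None and tax.species == query_species:
            continue
        if h.subject_id not in best or h.evalue < best[h.subject_id].evalue:
            best[h.subject_id] = h
    return sorted(best.values(), key=lambda h: (h.evalue, h.subject_id))


def _oriented(seq: str, frame: int) -> str:
    return str(Seq(seq).reverse_complement()) if frame < 0 else seq


def extract_putative_uorf(hit: SearchHit, subject_seq: str) -> PutativeUORF | None:
    """Cut the ORF containing the HSP out of the subject, in the hit frame.

    Boundaries: the maximal stop-free codon run containing the HSP; the
    5' boundary is the 5'-most in-frame ATG of that run at or upstream of
    the HSP start (none and the run touches the subject 5' end →
    5'-partial starting at the run start; none otherwise → no ORF); the
    3' boundary is the first in-frame stop after the HSP (subject end →
    3'-partial).
    """
    if hit.frame == 0:
        raise ValueError("putative uORF extraction requires a translated-search hit")
    seq = _oriented(subject_seq.upper(), hit.frame)
    n = len(seq)
    off = abs(hit.frame) - 1
    # HSP aa interval -> codon indices in this frame
    if hit.frame > 0:
        nt0 = hit.s_start - 1
    else:
        nt0 = n - hit.s_start
    if nt0 < 0 or nt0 >= n or (nt0 - off) % 3:
        raise ValueError("HSP coordinates inconsistent with subject/frame")
    aa_len = hit.q_end - hit.q_start + 1
    c_hsp0 = (nt0 - off) // 3
    c_hsp1 = c_hsp0 + aa_len  # exclusive
    n_codons = (n - off) // 3
    if c_hsp1 > n_codons:
        raise ValueError("HSP extends past subject end")

    def codon(i: int) -> str:
        return seq[off + 3 * i : off + 3 * i + 3]

    # expand to the maximal stop-free run containing the HSP
    lo = c_hsp0
    while lo > 0 and codon(lo - 1) not in _STOPS:
        lo -= 1
    hi = c_hsp1  # first codon index after the run's coding part
    while hi < n_codons and codon(hi) not in _STOPS:
        hi += 1
    three_partial = hi >= n_codons
    # 5' boundary: 5'-most ATG in [lo, c_hsp0]
    start = None
    for i in range(lo, c_hsp0 + 1):
        if codon(i) == "ATG":
            start = i
            break
    five_partial = False
    if start is None:
        if lo == 0:
            # run reaches the subject 5' end: tolerate a truncated record
            start = lo
            five_partial = True
        else:
            return None
    end = hi + (0 if three_partial else 1)  # include the stop codon when present
    orf_nt = seq[off + 3 * start : off + 3 * end]
    aa = str(Seq(orf_nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return PutativeUORF(
        subject_id=hit.subject_id,
        orf_nt=orf_nt,
        orf_aa=aa,
        subject_interval=(off + 3 * start, off + 3 * end),
        five_prime_partial=five_partial,
        three_prime_partial=three_partial,
        source_hit=hit,
    )


def morf_confirmation(
    morf_aa: str,
    putative: PutativeUORF,
    subject_seq: str,
    engine,
    e_max: float = 0.1,
    db_residues: int | None = None,
) -> SearchHit | None:
    """Search the query mORF peptide against the region downstream of the
    putative uORF; best hit with E < e_max, else None."""
    seq = _oriented(subject_seq.upper(), putative.source_hit.frame)
    downstream = seq[putative.subject_interval[1] :]
    if len(downstream) < 3:
        return None
    sub = SequenceCollection({putative.subject_id: downstream}, {})
    hits = engine.search_translated(
        putative.subject_id + "|down", morf_aa, sub, e_max=e_max, db_residues=db_residues
    )
    hits = [h for h in hits if h.evalue < e_max]
    return hits[0] if hits else None


def default_contaminant_predicate(tax) -> bool:
    """True when a record should be treated as a contaminant."""
    if tax is None or not tax.lineage:
        return True
    if "Metazoa" not in tax.lineage:
        return True
    return bool(tax.contaminant_flag)


def filter_contaminants(
    hits: list[ConfirmedHit],
    collection: SequenceCollection,
    predicate: Callable = default_contaminant_predicate,
) -> list[ConfirmedHit]:
    """Remove hits from records outside Metazoa, without lineage, or flagged."""
    out = []
    for h in hits:
        tax = collection.taxonomy.get(h.subject_id)
        if predicate(tax):
            logger.info("contaminant removed: %s (%s)", h.subject_id, getattr(tax, "species", "?"))
            continue
        out.append(h)
    return out
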