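"""Candidate CPuORF selection: taxonomic-order conservation, per-order
representatives, Ka/Ks with an empirical null, and thresholding.

A uORF must be conserved in mORF-confirmed homologs from at least two
taxonomic orders other than the query's own order.  Identical-sequence
uORFs from splice variants of one gene collapse to the record with the
lowest median uORF-search E-value.  One representative hit per order
(lowest mORF-confirmation E-value) enters pairwise Ka/Ks against the
original uORF; each pair gets a codon-shuffling permutation p-value, all
p-values are BH-adjusted jointly, and a uORF becomes a candidate when its
median Ka/Ks ratio < 0.5 and median q < 0.05 (both strict).
"""

from __future__ import annotations

import statistics
import zlib
from dataclasses import dataclass, replace

import numpy as np
from statsmodels.stats.multitest import multipletests

from .homology import ConfirmedHit
from .kaks import KaKs, codon_align, compute_kaks, permutation_null
from .uorfs import UORFRecord

__all__ = [
    "KaKsResult",
    "order_conservation_filter",
    "dedupe_identical_uorfs",
    "select_representatives",
    "kaks_for_pairs",
    "bh_qvalues",
    "aggregate",
    "select_candidates",
]


@dataclass(frozen=True)
class KaKsResult:
    """Ka/Ks outcome for one (uORF, representative hit) pair."""

    uorf_id: str
    subject_id: str
    order: str
    ka: float
    ks: float
    ratio: float | None
    p_perm: float
    q: float = float("nan")
    flags: tuple[str, ...] = ()


def order_conservation_filter(
    confirmed: dict[str, list[ConfirmedHit]],
    original_order: str,
    min_other_orders: int = 2,
) -> set[str]:
    """uORF ids with confirmed hits from >= min_other_orders orders other
    than the query's own order.  Hits without an order are ignored."""
    keep = set()
    for uorf_id, hits in confirmed.items():
        orders = {h.order for h in hits if h.order and h.order != original_order}
        if len(orders) >= min_other_orders:
            keep.add(uorf_id)
    return keep


def dedupe_identical_uorfs(
    records: list[UORFRecord],
    hit_evalues: dict[str, list[float]],
) -> list[UORFRecord]:
    """Within each gene, keep one record per identical nt sequence: the
    one with the lowest median uORF-search E-value (ties: smaller
    transcript_id)."""
    by_key: dict[tuple[str, str], list[UORFRecord]] = {}
    for r in records:
        by_key.setdefault((r.gene_id, r.nt_seq), []).append(r)
    out = []
    for group in by_key.values():
        def sort_key(r: UORFRecord):
            evs = hit_evalues.get(r.uorf_id, [])
            med = statistics.median(evs) if evs else float("inf")
            return (med, r.transcript_id)
        out.append(min(group, key=sort_key))
    return sorted(out, key=lambda r: r.uorf_id)


def select_representatives(hits: list[ConfirmedHit]) -> dict[str, ConfirmedHit]:
    """One hit per order: lowest mORF-confirmation E-value, ties broken by
    longer putative-uORF alignment then lexicographic subject id."""
    best: dict[str, ConfirmedHit] = {}
    def key(h: ConfirmedHit):
        return (h.morf_hit.evalue, -len(h.putative.orf_aa), h.subject_id)
    for h in hits:
        if not h.order:
            continue
        if h.order not in best or key(h) < key(best[h.order]):
            best[h.order] = h
    return best


def kaks_for_pairs(
    uorf: UORFRecord,
    representatives: dict[str, ConfirmedHit],
    n_perm: int = 1000,
    seed: int = 0,
) -> list[KaKsResult]:
    """Pairwise Ka/Ks of the original uORF against each per-order
    representative putative uORF.  The permutation seed is derived
    deterministically from (seed, uORF id, order)."""
    results = []
    for order in sorted(representatives):
        h = representatives[order]
        aln = codon_align(uorf.nt_seq, h.putative.orf_nt)
        kk = compute_kaks(aln)
        tag = zlib.crc32(f"{uorf.uorf_id}|{order}".encode()) % (2**31)
        pair_seed = np.random.SeedSequence([seed, tag])
        p = permutation_null(aln, n_perm=n_perm, seed=np.random.default_rng(pair_seed))
        results.append(
            KaKsResult(
                uorf_id=uorf.uorf_id,
                subject_id=h.subject_id,
                order=order,
                ka=kk.ka,
                ks=kk.ks,
                ratio=kk.ratio,
                p_perm=p,
                flags=kk.flags,
            )
        )
    return results


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def attach_qvalues(results: list[KaKsResult]) -> list[KaKsResult]:
    """BH-adjust all permutation p-values jointly across pairs."""
    if not results:
        return []
    q = bh_qvalues([r.p_perm for r in results])
    return [replace(r, q=float(qi)) for r, qi in zip(results, q)]


def aggregate(results: list[KaKsResult]) -> tuple[float | None, float | None]:
    """(median ratio, median q) over a uORF's pairs.

    Pairs with an undefined ratio (Ks = 0 with Ka > 0, or Ka saturated)
    are excluded; if none remain, both aggregates are None.
    """
    defined = [r for r in results if r.ratio is not None]
    if not defined:
        return None, None
    med_ratio = float(np.median([r.ratio for r in defined]))
    med_q = float(np.median([r.q for r in defined]))
    return med_ratio, med_q


def select_candidates(
    per_uorf: dict[str, list[KaKsResult]],
    ratio_max: float = 0.5,
    q_max: float = 0.05,
) -> set[str]:
    """uORFs whose aggregated ratio < ratio_max and aggregated q < q_max
    (strict inequalities at both thresholds)."""
    out = set()
    for uorf_id, results in per_uorf.items():
        med_ratio, med_q = aggregate(results)
        if med_ratio is None:
            continue
        if med_ratio < ratio_max and med_q < q_max:
            out.add(uorf_id)
    return out
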