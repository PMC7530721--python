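"""Exhaustive uORF extraction from 5'-UTR sequences.

A uORF is an ATG codon inside the 5'-UTR together with its nearest
downstream in-frame stop codon, the stop lying entirely within the UTR.
Every ATG is scanned, so nested and overlapping uORFs are all reported;
all splice variants contribute records.  For counting, uORFs of a gene
that share a genomic start codon or a genomic stop codon are merged into
one (records themselves are never deleted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .annotation import TranscriptModel

__all__ = ["UORFRecord", "scan_uorfs", "extract_gene_uorfs", "count_distinct_uorfs"]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class UORFRecord:
    """One uORF instance on one splice variant."""

    uorf_id: str
    gene_id: str
    transcript_id: str
    utr_start: int  #: 0-based offset of the A of ATG in utr5_seq
    utr_stop_end: int  #: one past the stop codon
    genomic_start_codon: tuple  #: ((chrom, strand), blocks)
    genomic_stop_codon: tuple
    nt_seq: str
    aa_seq: str
    has_internal_n: bool = False
    status: dict = field(default_factory=dict)


def scan_uorfs(utr5_seq: str, min_codons: int = 2) -> list[tuple[int, int]]:
    """All (start, end) intervals of uORFs in a 5'-UTR, 0-based half-open.

    ``end`` is one past the stop codon.  Codons containing N never match
    ATG or a stop; ATGs without an in-frame stop inside the UTR yield
    nothing.  ``min_codons`` counts the stop codon (default 2: ATG
    immediately followed by a stop is accepted).
    """
    seq = utr5_seq.upper().replace("U", "T")
    out: list[tuple[int, int]] = []
    n = len(seq)
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, n - 2, 3):
            codon = seq[j : j + 3]
            if codon in _STOPS:
                if (j + 3 - i) // 3 >= min_codons:
                    out.append((i, j + 3))
                break
    return out


def extract_gene_uorfs(
    models: list[TranscriptModel], min_codons: int = 2
) -> list[UORFRecord]:
    """uORF records from every splice variant of every model.

    Genomic codon coordinates are computed through the exon structure, so
    start/stop codons split across introns carry multi-block intervals.
    """
    records: list[UORFRecord] = []
    for m in sorted(models, key=lambda m: (m.gene_id, m.transcript_id)):
        if not m.utr5_seq:
            continue
        for (start, end) in scan_uorfs(m.utr5_seq, min_codons=min_codons):
            nt = m.utr5_seq[start:end]
            aa = str(Seq(nt).translate())[:-1]
            key = (m.chrom, m.strand)
            records.append(
                UORFRecord(
                    uorf_id=f"{m.gene_id}|{m.transcript_id}|{start}",
                    gene_id=m.gene_id,
                    transcript_id=m.transcript_id,
                    utr_start=start,
                    utr_stop_end=end,
                    genomic_start_codon=(key, m.tx_to_genomic(start, start + 3)),
                    genomic_stop_codon=(key, m.tx_to_genomic(end - 3, end)),
                    nt_seq=nt,
                    aa_seq=aa,
                    has_internal_n="N" in nt,
                )
            )
    return records


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_components(records: list[UORFRecord]) -> list[list[UORFRecord]]:
    """Group a gene's records into share-components.

    Two records are linked when they share the same genomic start codon
    OR the same genomic stop codon; components are the transitive
    closure.
    """
    uf = _UnionFind(len(records))
    by_key: dict[tuple, int] = {}
    for i, r in enumerate(records):
        for key in (("start", r.genomic_start_codon), ("stop", r.genomic_stop_codon)):
            if key in by_key:
                uf.union(by_key[key], i)
            else:
                by_key[key] = i
    groups: dict[int, list[UORFRecord]] = {}
    for i, r in enumerate(records):
        groups.setdefault(uf.find(i), []).append(r)
    return list(groups.values())


def count_distinct_uorfs(records: list[UORFRecord]) -> tuple[int, int]:
    """(n_uorfs, n_genes) after merging shared-start/stop uORFs per gene.

    Records are not deleted: only the count collapses shared codons.
    """
    by_gene: dict[str, list[UORFRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    n_uorfs = sum(len(merge_components(rs)) for rs in by_gene.values())
    return n_uorfs, len(by_gene)
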