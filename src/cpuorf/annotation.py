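"""Transcript model construction from genome FASTA + GFF3.

Builds one :class:`TranscriptModel` per annotated mRNA, splicing exon
sequences in transcription order and slicing out the 5'-UTR and the main
ORF (mORF).  GFF3 coordinates are 1-based inclusive; everything stored on
the models is 0-based half-open, and minus-strand transcripts are
reverse-complemented so all sequences read 5'->3'.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "AnnotationWarnings",
    "load_annotation",
    "count_protein_coding_genes",
    "write_transcript_table",
]


@dataclass(frozen=True)
class TranscriptModel:
    """One splice variant with its 5'-UTR and mORF sequences.

    ``exons`` and ``cds`` are genomic 0-based half-open intervals in
    transcription order (for minus-strand transcripts, descending
    genomic coordinates).  Sequences are always transcript-oriented.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    utr5_seq: str
    morf_nt: str
    morf_aa: str

    @property
    def coding(self) -> bool:
        return bool(self.morf_nt)

    def spliced_seq_prefix(self) -> str:
        """utr5 + mORF; by construction a prefix of the spliced transcript."""
        return self.utr5_seq + self.morf_nt

    def tx_to_genomic(self, tx_start: int, tx_end: int) -> tuple[tuple[int, int], ...]:
        """Map a transcript-coordinate interval to genomic blocks.

        Returns 0-based half-open genomic intervals in ascending genomic
        order, suitable for BED blocks.  Codons split across introns map
        to multiple blocks.
        """
        blocks: list[tuple[int, int]] = []
        offset = 0
        for (start, end) in self.exons:
            elen = end - start
            lo = max(tx_start - offset, 0)
            hi = min(tx_end - offset, elen)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((start + lo, start + hi))
                else:
                    blocks.append((end - hi, end - lo))
            offset += elen
        return tuple(sorted(blocks))


@dataclass
class AnnotationWarnings:
    """Counters for oddities tolerated during model construction."""

    non_atg_start: int = 0
    skipped_bad_cds: int = 0
    utr5_feature_conflicts: int = 0
    skipped: list[str] = field(default_factory=list)


def _read_genome(genome_path: str | Path) -> dict[str, str]:
    path = Path(genome_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


_MRNA_TYPES = {"mRNA", "transcript"}


def load_annotation(
    gff3_path: str | Path,
    genome_path: str | Path,
    warnings: AnnotationWarnings | None = None,
) -> list[TranscriptModel]:
    """Parse GFF3 + genome FASTA into transcript models.

    One model per mRNA/transcript feature; transcripts without CDS are
    excluded from the protein-coding set (they carry no mORF and are not
    returned).  Transcripts whose CDS length is not a multiple of three
    after honouring the phase of the first CDS segment are skipped with
    a warning.  A missing chromosome is fatal.
    """
    if warnings is None:
        warnings = AnnotationWarnings()
    genome = _read_genome(genome_path)
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[TranscriptModel] = []
    for mrna in db.all_features():
        if mrna.featuretype not in _MRNA_TYPES:
            continue
        tid = mrna.id
        parents = mrna.attributes.get("Parent", [])
        gene_id = parents[0].split(":")[-1] if parents else tid
        tid = tid.split(":")[-1]
        if mrna.seqid not in genome:
            raise ValueError(f"chromosome {mrna.seqid!r} referenced by {tid} missing from genome FASTA")
        chrom_seq = genome[mrna.seqid]
        strand = mrna.strand
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds_feats:
            continue  # non-coding transcript: no mORF, excluded
        cds = [(f.start - 1, f.end) for f in cds_feats]
        if not exons:
            exons = list(cds)
        if strand == "-":
            exons = exons[::-1]
            cds = cds[::-1]
            cds_feats = cds_feats[::-1]

        def exon_seq(iv: tuple[int, int]) -> str:
            s = chrom_seq[iv[0] : iv[1]]
            return str(Seq(s).reverse_complement()) if strand == "-" else s

        spliced = "".join(exon_seq(iv) for iv in exons)
        # phase of the first CDS segment in transcription order
        try:
            phase = int(cds_feats[0].frame)
        except (TypeError, ValueError):
            phase = 0
        morf_nt = "".join(exon_seq(iv) for iv in cds)[phase:]
        if len(morf_nt) % 3 or len(morf_nt) == 0:
            warnings.skipped_bad_cds += 1
            warnings.skipped.append(tid)
            logger.warning("skipping %s: CDS length %d not a multiple of 3", tid, len(morf_nt))
            continue
        # 5'-UTR: transcript sequence upstream of the CDS start
        cds_tx_start = _tx_offset(exons, cds[0], strand) + phase
        utr5 = spliced[:cds_tx_start]
        utr_feats = list(db.children(mrna, featuretype="five_prime_UTR"))
        if utr_feats:
            declared = sum(f.end - f.start + 1 for f in utr_feats)
            if declared != len(utr5):
                # exon/CDS inference wins over annotated five_prime_UTR features
                warnings.utr5_feature_conflicts += 1
                logger.warning(
                    "%s: five_prime_UTR features total %d nt but inference gives %d nt",
                    tid, declared, len(utr5),
                )
        aa = str(Seq(morf_nt).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if not morf_nt.startswith("ATG"):
            warnings.non_atg_start += 1
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=strand,
                exons=tuple(exons),
                cds=tuple(cds),
                utr5_seq=utr5,
                morf_nt=morf_nt,
                morf_aa=aa,
            )
        )
    return models


def _tx_offset(exons: list[tuple[int, int]], cds_first: tuple[int, int], strand: str) -> int:
    """Transcript-coordinate offset of the CDS start within the spliced exons."""
    offset = 0
    for (start, end) in exons:
        if strand == "+":
            if start <= cds_first[0] < end:
                return offset + (cds_first[0] - start)
        else:
            if start < cds_first[1] <= end:
                return offset + (end - cds_first[1])
        offset += end - start
    raise ValueError("CDS start not contained in any exon")


def count_protein_coding_genes(models: list[TranscriptModel]) -> int:
    """Number of distinct genes with >= 1 transcript carrying a translatable mORF."""
    return len({m.gene_id for m in models if m.coding})


def write_transcript_table(models: list[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tutr5_len\tmorf_len\n")
        for m in sorted(models, key=lambda m: (m.gene_id, m.transcript_id)):
            fh.write(f"{m.transcript_id}\t{m.gene_id}\t{len(m.utr5_seq)}\t{len(m.morf_nt)}\n")
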