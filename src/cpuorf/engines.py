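"""Homology-search engines and the transcript evidence collection.

Two interchangeable engines satisfy one contract — map a peptide query
against a nucleotide collection (translated search, tBLASTn-like) or a
peptide collection (protein search, BLASTp-like) to tabular hits:

* :class:`BuiltinEngine` — exhaustive six-frame translation plus ungapped
  local alignment (BLOSUM62) scored with a Karlin–Altschul E-value.
  Deterministic, dependency-free, intended for fixtures and tests.
* :class:`BlastEngine` — thin wrapper over NCBI BLAST+ ``tblastn`` /
  ``blastp`` with tabular output (the 12 standard columns + sframe).
  The permissive uORF search regime (E <= 2000, short queries) uses
  ``-seg no -word_size 2 -matrix BLOSUM62``.

Hit coordinates follow BLAST conventions: 1-based, subject nucleotide
coordinates orientation-encoded (s_start > s_end on the minus strand),
frame in {±1, ±2, ±3} (0 for protein-protein searches).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "SearchHit",
    "TaxonRecord",
    "SequenceCollection",
    "BuiltinEngine",
    "BlastEngine",
    "get_engine",
]

# Karlin-Altschul parameters for ungapped BLOSUM62
_KA_LAMBDA = 0.3176
_KA_K = 0.134


@dataclass(frozen=True)
class SearchHit:
    """One HSP from a translated or protein search."""

    query_id: str
    subject_id: str
    evalue: float
    identity_pct: float
    q_start: int  #: 1-based aa position on the query
    q_end: int
    s_start: int  #: 1-based subject position (nt for translated searches)
    s_end: int
    frame: int  #: ±1..±3 translated, 0 for protein-protein
    bitscore: float = 0.0
    aligned_subject_aa: str = ""

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("negative E-value")
        if self.q_start > self.q_end:
            raise ValueError("q_start > q_end")


@dataclass(frozen=True)
class TaxonRecord:
    """Taxonomy sidecar row for one collection record."""

    record_id: str
    taxid: int
    species: str
    order: str
    lineage: tuple[str, ...]  #: ordered clade names, Metazoa..species
    source: str  #: refseq | est | tsa | contig
    contaminant_flag: bool = False


class SequenceCollection:
    """Transcript evidence collection: FASTA records + taxonomy sidecar."""

    def __init__(self, records: dict[str, str], taxonomy: dict[str, TaxonRecord]):
        self.records = records
        self.taxonomy = taxonomy

    @classmethod
    def load(cls, fasta_path: str | Path, taxonomy_path: str | Path) -> "SequenceCollection":
        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
        tax = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
        taxonomy = {}
        for row in tax.itertuples(index=False):
            lineage = tuple(x for x in row.lineage.split(";") if x)
            flag = str(getattr(row, "contaminant_flag", "0")) in ("1", "True", "true")
            taxonomy[row.record_id] = TaxonRecord(
                record_id=row.record_id,
                taxid=int(row.taxid or 0),
                species=row.species,
                order=row.order,
                lineage=lineage,
                source=row.source,
                contaminant_flag=flag,
            )
        return cls(records, taxonomy)

    def subset(self, sources: set[str]) -> "SequenceCollection":
        keep = {rid for rid, t in self.taxonomy.items() if t.source in sources}
        return SequenceCollection(
            {rid: s for rid, s in self.records.items() if rid in keep},
            {rid: t for rid, t in self.taxonomy.items() if rid in keep},
        )

    @property
    def total_nt(self) -> int:
        return sum(len(s) for s in self.records.values())

    def write(self, fasta_path: str | Path, taxonomy_path: str | Path) -> None:
        with open(fasta_path, "w") as fh:
            for rid in sorted(self.records):
                fh.write(f">{rid}\n{self.records[rid]}\n")
        with open(taxonomy_path, "w") as fh:
            fh.write("record_id\ttaxid\tspecies\torder\tlineage\tsource\tcontaminant_flag\n")
            for rid in sorted(self.taxonomy):
                t = self.taxonomy[rid]
                fh.write(
                    f"{t.record_id}\t{t.taxid}\t{t.species}\t{t.order}\t"
                    f"{';'.join(t.lineage)}\t{t.source}\t{int(t.contaminant_flag)}\n"
                )


def six_frame_translations(nt: str) -> list[tuple[int, str]]:
    """(frame, peptide) for frames +1..+3, -1..-3; stops appear as '*'."""
    nt = nt.upper().replace("U", "T")
    rc = str(Seq(nt).reverse_complement())
    out = []
    for f in (1, 2, 3):
        for strand_seq, sign in ((nt, 1), (rc, -1)):
            sub = strand_seq[f - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate()) if sub else ""
            out.append((sign * f, pep))
    return out


def frame_aa_to_nt(frame: int, subject_len: int, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map a 0-based half-open aa interval on a frame to 1-based nt coords.

    Returns BLAST-style (s_start, s_end): ascending on plus frames,
    descending on minus frames.
    """
    f = abs(frame)
    nt0 = (f - 1) + 3 * aa_start  # 0-based start on the oriented strand
    nt1 = (f - 1) + 3 * aa_end - 1  # 0-based inclusive end
    if frame > 0:
        return nt0 + 1, nt1 + 1
    return subject_len - nt0, subject_len - nt1


class BuiltinEngine:
    """Exhaustive translated / protein search with ungapped local alignment.

    One best HSP is reported per (query, subject record, frame); the
    E-value is Karlin–Altschul ``K * m * N * exp(-lambda * S)`` with N
    the collection size in residues (total nt / 3 for translated
    searches).
    """

    name = "builtin"

    def __init__(self):
        self._aligner = PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self._aligner.open_gap_score = -1e4
        self._aligner.extend_gap_score = -1e4
        self._frame_cache: dict[int, list[tuple[int, str]]] = {}

    def _frames(self, seq: str) -> list[tuple[int, str]]:
        key = hash(seq)
        if key not in self._frame_cache:
            self._frame_cache[key] = six_frame_translations(seq)
        return self._frame_cache[key]

    def _local(self, query: str, subject_pep: str):
        if not query or not subject_pep:
            return None
        aln = self._aligner.align(query, subject_pep)
        if len(aln) == 0:
            return None
        best = aln[0]
        if best.score <= 0:
            return None
        return best

    @staticmethod
    def _evalue(score: float, m: int, n_residues: int) -> float:
        return _KA_K * m * max(n_residues, 1) * float(np.exp(-_KA_LAMBDA * score))

    def search_translated(
        self,
        query_id: str,
        query_aa: str,
        collection: SequenceCollection,
        e_max: float = 2000.0,
        db_residues: int | None = None,
    ) -> list[SearchHit]:
        """tBLASTn-like: peptide query vs six-frame-translated records."""
        n_res = db_residues if db_residues is not None else collection.total_nt // 3
        hits = []
        for sid in sorted(collection.records):
            seq = collection.records[sid]
            for frame, pep in self._frames(seq):
                aln = self._local(query_aa, pep)
                if aln is None:
                    continue
                ev = self._evalue(aln.score, len(query_aa), n_res)
                if ev > e_max:
                    continue
                qb, sb = aln.aligned
                qs, qe = qb[0][0], qb[-1][1]
                sa0, sa1 = sb[0][0], sb[-1][1]
                qseg, sseg = query_aa[qs:qe], pep[sa0:sa1]
                ident = 100.0 * sum(a == b for a, b in zip(qseg, sseg)) / max(len(qseg), 1)
                s1, s2 = frame_aa_to_nt(frame, len(seq), sa0, sa1)
                hits.append(
                    SearchHit(
                        query_id=query_id,
                        subject_id=sid,
                        evalue=ev,
                        identity_pct=round(ident, 2),
                        q_start=qs + 1,
                        q_end=qe,
                        s_start=s1,
                        s_end=s2,
                        frame=frame,
                        bitscore=float(aln.score),
                        aligned_subject_aa=sseg,
                    )
                )
        hits.sort(key=lambda h: (h.evalue, h.subject_id, h.frame))
        return hits

    def search_protein(
        self,
        query_id: str,
        query_aa: str,
        subjects: dict[str, str],
        e_max: float = 2000.0,
        db_residues: int | None = None,
    ) -> list[SearchHit]:
        """BLASTp-like: peptide query vs peptide subjects."""
        n_res = db_residues if db_residues is not None else sum(len(s) for s in subjects.values())
        hits = []
        for sid in sorted(subjects):
            aln = self._local(query_aa, subjects[sid])
            if aln is None:
                continue
            ev = self._evalue(aln.score, len(query_aa), n_res)
            if ev > e_max:
                continue
            qb, sb = aln.aligned
            qs, qe = qb[0][0], qb[-1][1]
            ss, se = sb[0][0], sb[-1][1]
            qseg = query_aa[qs:qe]
            sseg = subjects[sid][ss:se]
            ident = 100.0 * sum(a == b for a, b in zip(qseg, sseg)) / max(len(qseg), 1)
            hits.append(
                SearchHit(
                    query_id=query_id,
                    subject_id=sid,
                    evalue=ev,
                    identity_pct=round(ident, 2),
                    q_start=qs + 1,
                    q_end=qe,
                    s_start=ss + 1,
                    s_end=se,
                    frame=0,
                    bitscore=float(aln.score),
                    aligned_subject_aa=sseg,
                )
            )
        hits.sort(key=lambda h: (h.evalue, h.subject_id))
        return hits


_TBLASTN_COLS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore sframe"
)


class BlastEngine:
    """NCBI BLAST+ wrapper (external engine).

    Requires ``makeblastdb`` plus ``tblastn``/``blastp`` on PATH.  The
    reference configuration for the permissive uORF regime is
    ``-seg no -word_size 2 -evalue 2000 -matrix BLOSUM62``.
    """

    name = "blast"

    def __init__(self, workdir: str | Path | None = None):
        if shutil.which("tblastn") is None:
            raise RuntimeError("BLAST+ not found on PATH; use the builtin engine")
        self._tmp = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="cpuorf_blast_"))
        self._tmp.mkdir(parents=True, exist_ok=True)
        self._dbs: dict[str, Path] = {}

    def _ensure_db(self, key: str, seqs: dict[str, str], dbtype: str) -> Path:
        if key in self._dbs:
            return self._dbs[key]
        fa = self._tmp / f"{key}.fa"
        with open(fa, "w") as fh:
            for sid in sorted(seqs):
                fh.write(f">{sid}\n{seqs[sid]}\n")
        cmd = ["makeblastdb", "-in", str(fa), "-dbtype", dbtype, "-parse_seqids"]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode:
            raise RuntimeError(f"makeblastdb failed: {proc.stderr}")
        self._dbs[key] = fa
        return fa

    def _run(self, program: str, query_id: str, query_aa: str, db: Path, e_max: float,
             extra: list[str]) -> list[SearchHit]:
        qf = self._tmp / "query.fa"
        qf.write_text(f">{query_id}\n{query_aa}\n")
        cols = _TBLASTN_COLS if program == "tblastn" else _TBLASTN_COLS.replace(" sframe", "")
        cmd = [
            program, "-query", str(qf), "-db", str(db),
            "-outfmt", f"6 {cols}", "-evalue", str(e_max), "-matrix", "BLOSUM62",
        ] + extra
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode:
            raise RuntimeError(f"{program} failed: {proc.stderr}")
        hits = []
        for line in proc.stdout.splitlines():
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                continue
            frame = int(f[12]) if program == "tblastn" else 0
            hits.append(
                SearchHit(
                    query_id=f[0], subject_id=f[1], evalue=float(f[10]),
                    identity_pct=float(f[2]), q_start=int(f[6]), q_end=int(f[7]),
                    s_start=int(f[8]), s_end=int(f[9]), frame=frame,
                    bitscore=float(f[11]),
                )
            )
        # keep best HSP per (subject, frame), mirroring the builtin engine
        best: dict[tuple, SearchHit] = {}
        for h in hits:
            key = (h.subject_id, h.frame)
            if key not in best or h.evalue < best[key].evalue:
                best[key] = h
        out = sorted(best.values(), key=lambda h: (h.evalue, h.subject_id, h.frame))
        return out

    def search_translated(self, query_id, query_aa, collection, e_max=2000.0,
                          db_residues=None) -> list[SearchHit]:
        key = "nt_%x" % (hash(tuple(sorted(collection.records))) & 0xFFFFFFFF)
        db = self._ensure_db(key, collection.records, "nucl")
        extra = ["-seg", "no"]
        if len(query_aa) < 30:
            extra += ["-word_size", "2"]
        return self._run("tblastn", query_id, query_aa, db, e_max, extra)

    def search_protein(self, query_id, query_aa, subjects, e_max=2000.0,
                       db_residues=None) -> list[SearchHit]:
        key = "aa_%x" % (hash(tuple(sorted(subjects))) & 0xFFFFFFFF)
        db = self._ensure_db(key, subjects, "prot")
        extra = ["-seg", "no"]
        if len(query_aa) < 30:
            extra += ["-word_size", "2"]
        return self._run("blastp", query_id, query_aa, db, e_max, extra)


def get_engine(name: str, **kwargs):
    if name == "builtin":
        return BuiltinEngine()
    if name in ("blast", "external"):
        return BlastEngine(**kwargs)
    raise ValueError(f"unknown engine {name!r}")
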