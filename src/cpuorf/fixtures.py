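"""Self-contained synthetic inputs for the CPuORF pipeline.

Generates a toy genome + GFF3, a homolog transcript collection with a
taxonomy sidecar, and a truth table, so every stage and the end-to-end
pipeline run without downloads.  Per-gene plans:

* ``conserved_uorf`` — the planted uORF has codon-aware diverged copies
  (synonymous-biased, so Ka/Ks is low) in transcripts from several
  non-query orders; homologs keep the stop codon between uORF and mORF.
* ``fused_homologs`` — every reference-class homolog joins the uORF and
  mORF into one reading frame (fusion ratio 1.0 → discarded at the
  fusion step).
* ``nonconserved_uorf`` — homologs carry the mORF but no uORF copy, and
  only one non-query order is represented.
* ``no_uorf`` — the 5'-UTR contains no ATG.
* ``contaminant_homolog`` — uORF copies exist but only on records with
  non-metazoan lineages (removed by the contaminant filter).

UTRs are built over {C, T} outside the planted uORF so no stray ATG can
arise in any frame; planted ORF interiors avoid ATG and stop codons at
every trinucleotide offset, making the truth table exact.  All sampling
is driven by one seed; identical seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .engines import SequenceCollection, TaxonRecord
from .taxonomy import assign_category, distality, _LADDER_INDEX

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "mutate_codons", "DEFAULT_PLANS", "ORDER_TABLE"]

_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [
    "".join(c)
    for c in product("TCAG", repeat=3)
    if "".join(c) not in _STOPS and "".join(c) != "ATG"
]

#: order name -> (species, lineage) used for homolog records
ORDER_TABLE: dict[str, tuple[str, tuple[str, ...]]] = {
    "Rodentia": (
        "Mus fictus",
        ("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata", "Vertebrata",
         "Euteleostomi", "Sarcopterygii", "Tetrapoda", "Mammalia", "Eutheria",
         "Euarchontoglires", "Rodentia"),
    ),
    "Carnivora": (
        "Canis fictus",
        ("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata", "Vertebrata",
         "Euteleostomi", "Sarcopterygii", "Tetrapoda", "Mammalia", "Eutheria",
         "Laurasiatheria", "Carnivora"),
    ),
    "Galliformes": (
        "Gallus fictus",
        ("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata", "Vertebrata",
         "Euteleostomi", "Sarcopterygii", "Tetrapoda", "Sauropsida", "Aves", "Galliformes"),
    ),
    "Cypriniformes": (
        "Danio fictus",
        ("Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata", "Vertebrata",
         "Euteleostomi", "Actinopterygii", "Ostarioclupeomorpha", "Cypriniformes"),
    ),
    "Diptera": (
        "Drosophila ficta",
        ("Metazoa", "Eumetazoa", "Bilateria", "Protostomia", "Ecdysozoa", "Arthropoda",
         "Insecta", "Diptera"),
    ),
}

QUERY_SPECIES = "Homo exemplaris"
QUERY_ORDER = "Primates"
QUERY_LINEAGE = (
    "Metazoa", "Eumetazoa", "Bilateria", "Deuterostomia", "Chordata", "Vertebrata",
    "Euteleostomi", "Sarcopterygii", "Tetrapoda", "Mammalia", "Eutheria",
    "Euarchontoglires", "Primates",
)

_CONTAMINANT_LINEAGE = ("Eukaryota", "Alveolata", "Apicomplexa")

#: default 20-gene plan mix
DEFAULT_PLANS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("conserved_uorf", ("Rodentia", "Carnivora", "Galliformes")),
    ("conserved_uorf", ("Rodentia", "Carnivora")),
    ("conserved_uorf", ("Rodentia", "Carnivora", "Cypriniformes", "Diptera")),
    ("conserved_uorf", ("Carnivora", "Galliformes", "Cypriniformes")),
    ("conserved_uorf", ("Rodentia", "Carnivora", "Galliformes")),
    ("conserved_uorf", ("Rodentia", "Galliformes", "Diptera")),
    ("fused_homologs", ("Rodentia", "Carnivora")),
    ("fused_homologs", ("Rodentia", "Carnivora")),
    ("fused_homologs", ("Carnivora", "Galliformes")),
    ("fused_homologs", ("Rodentia", "Galliformes")),
    ("nonconserved_uorf", ("Rodentia",)),
    ("nonconserved_uorf", ("Carnivora",)),
    ("nonconserved_uorf", ("Rodentia",)),
    ("nonconserved_uorf", ("Galliformes",)),
    ("no_uorf", ()),
    ("no_uorf", ()),
    ("no_uorf", ()),
    ("contaminant_homolog", ("Rodentia", "Carnivora")),
    ("contaminant_homolog", ("Rodentia", "Carnivora", "Galliformes")),
    ("contaminant_homolog", ("Carnivora", "Galliformes")),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    plans: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_PLANS
    uorf_codons: int = 30  #: planted uORF length excluding the stop codon
    morf_codons: int = 60
    divergence: float = 0.2  #: per-codon substitution probability p
    syn_bias: float = 0.9  #: probability beta that a substitution is synonymous
    morf_divergence: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        for i, (plan, orders) in enumerate(self.plans):
            if plan == "conserved_uorf" and len(orders) < 2:
                raise ValueError(f"plan {i}: a conserved plant needs >= 2 non-query orders")
            for o in orders:
                if o not in ORDER_TABLE:
                    raise ValueError(f"plan {i}: unknown order {o!r}")
            if plan not in (
                "conserved_uorf", "fused_homologs", "nonconserved_uorf",
                "no_uorf", "contaminant_homolog",
            ):
                raise ValueError(f"plan {i}: unknown plan {plan!r}")


@dataclass
class Fixture:
    """In-memory fixture plus the paths it was written to."""

    genome_path: Path
    gff3_path: Path
    collection_fasta: Path
    taxonomy_path: Path
    truth_path: Path
    truth: list[dict] = field(default_factory=list)
    collection: SequenceCollection | None = None


def _ct_run(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["C", "T"], size=n))


def _safe_orf_interior(rng: np.random.Generator, n_codons: int, prev: str = "") -> str:
    """Codon run avoiding stop/ATG codons and ATG at every offset."""
    out = prev
    made = 0
    while made < n_codons:
        codon = _SAFE_CODONS[rng.integers(len(_SAFE_CODONS))]
        if "ATG" in (out[-2:] + codon):
            continue
        out += codon
        made += 1
    return out[len(prev):]


def _synonymous_neighbors(codon: str) -> tuple[list[str], list[str]]:
    syn, nonsyn = [], []
    aa = str(Seq(codon).translate())
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS or alt == "ATG":
                continue
            if str(Seq(alt).translate()) == aa:
                syn.append(alt)
            else:
                nonsyn.append(alt)
    return syn, nonsyn


def mutate_codons(
    nt: str,
    p: float,
    beta: float,
    rng: np.random.Generator,
    keep_first: bool = True,
) -> str:
    """Codon-aware mutation: each codon substituted with probability ``p``,
    synonymously with probability ``beta`` (else nonsynonymously), never
    creating a stop or ATG codon.  A trailing stop codon is preserved."""
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    out = []
    for i, codon in enumerate(codons):
        if (keep_first and i == 0) or codon in _STOPS:
            out.append(codon)
            continue
        if rng.random() < p:
            syn, nonsyn = _synonymous_neighbors(codon)
            # a codon lacking neighbors of the drawn class is left intact
            pool = syn if rng.random() < beta else nonsyn
            if pool:
                codon = pool[rng.integers(len(pool))]
        out.append(codon)
    return "".join(out)


def _expected_range_label(orders: tuple[str, ...]) -> str:
    cats = [assign_category(ORDER_TABLE[o][1]) for o in orders]
    qcat = assign_category(QUERY_LINEAGE)
    return max(cats, key=lambda c: (distality(c, qcat), _LADDER_INDEX[c]))


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> Fixture:
    """Write genome FASTA, GFF3, collection FASTA, taxonomy TSV and truth TSV."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chrom_seqs: dict[str, str] = {"chr1": "", "chr2": ""}
    gff_lines: list[str] = ["##gff-version 3"]
    coll_records: dict[str, str] = {}
    taxonomy: dict[str, TaxonRecord] = {}
    truth: list[dict] = []
    taxid_counter = iter(range(9001, 99999))

    for gi, (plan, orders) in enumerate(spec.plans):
        gene = f"G{gi + 1:03d}"
        uorf_nt = ""
        if plan != "no_uorf":
            uorf_nt = "ATG" + _safe_orf_interior(rng, spec.uorf_codons - 1, prev="ATG") + "TAA"
        morf_nt = "ATG" + _safe_orf_interior(rng, spec.morf_codons - 1, prev="ATG") + "TGA"
        utr = _ct_run(rng, 30) + uorf_nt + _ct_run(rng, 24)
        utr3 = _ct_run(rng, 18)
        tx = utr + morf_nt + utr3

        # gene placement: a few genes exercise minus strand and introns
        minus = gi % 7 == 3
        introned = gi % 5 == 2 and plan != "no_uorf"
        chrom = "chr2" if (minus or introned) else "chr1"
        offset = len(chrom_seqs[chrom]) + 20
        chrom_seqs[chrom] += _ct_run(rng, 20)

        if introned:
            # intron inside the UTR, downstream of the uORF
            cut = len(utr) - 10
            intron = "GT" + _ct_run(rng, 36) + "AG"
            genomic = tx[:cut] + intron + tx[cut:]
            exon_ivs = [(offset, offset + cut), (offset + cut + len(intron), offset + len(genomic))]
        else:
            genomic = tx
            exon_ivs = [(offset, offset + len(genomic))]
        if minus:
            glen = len(genomic)
            genomic = str(Seq(genomic).reverse_complement())
            exon_ivs = [
                (2 * offset + glen - e, 2 * offset + glen - s) for (s, e) in exon_ivs
            ][::-1]
        chrom_seqs[chrom] += genomic

        strand = "-" if minus else "+"
        # CDS interval in transcript coords -> genomic
        cds_tx = (len(utr), len(utr) + len(morf_nt))
        cds_ivs = _tx_interval_to_genomic(exon_ivs, strand, cds_tx)
        g0 = min(iv[0] for iv in exon_ivs)
        g1 = max(iv[1] for iv in exon_ivs)
        gff_lines.append(
            f"{chrom}\tfixture\tgene\t{g0 + 1}\t{g1}\t.\t{strand}\t.\tID=gene:{gene}"
        )
        n_tx = 2 if (plan == "conserved_uorf" and gi % 2 == 0) else 1
        for v in range(1, n_tx + 1):
            tid = f"{gene}.t{v}"
            gff_lines.append(
                f"{chrom}\tfixture\tmRNA\t{g0 + 1}\t{g1}\t.\t{strand}\t.\t"
                f"ID=transcript:{tid};Parent=gene:{gene}"
            )
            for (s, e) in sorted(exon_ivs):
                gff_lines.append(
                    f"{chrom}\tfixture\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent=transcript:{tid}"
                )
            for i, (s, e) in enumerate(sorted(cds_ivs)):
                gff_lines.append(
                    f"{chrom}\tfixture\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\t"
                    f"ID=CDS:{tid};Parent=transcript:{tid}"
                )

        # homolog records
        contaminated = plan == "contaminant_homolog"
        for oi, order in enumerate(orders):
            species, lineage = ORDER_TABLE[order]
            rid = f"R_{gene}_{order}"
            if plan in ("conserved_uorf", "contaminant_homolog"):
                u = mutate_codons(uorf_nt, spec.divergence, spec.syn_bias, rng)
                m = mutate_codons(morf_nt, spec.morf_divergence, 0.5, rng)
                seq = _ct_run(rng, 21) + u + "CCCTAACCCTAA" + m + _ct_run(rng, 15)
            elif plan == "fused_homologs":
                u = mutate_codons(uorf_nt, spec.divergence, spec.syn_bias, rng)[:-3]
                m = mutate_codons(morf_nt, spec.morf_divergence, 0.5, rng)
                seq = _ct_run(rng, 21) + u + "GGCGGC" + m + _ct_run(rng, 15)
            else:  # nonconserved: mORF only
                m = mutate_codons(morf_nt, spec.morf_divergence, 0.5, rng)
                seq = _ct_run(rng, 60) + m + _ct_run(rng, 15)
            coll_records[rid] = seq
            taxonomy[rid] = TaxonRecord(
                record_id=rid,
                taxid=next(taxid_counter),
                species="Plasmodium fictum" if contaminated else species,
                order=order,
                lineage=_CONTAMINANT_LINEAGE if contaminated else lineage,
                source="refseq" if oi == 0 else ("est" if oi % 2 else "tsa"),
            )

        expected = {
            "conserved_uorf": "cpuorf",
            "fused_homologs": "dropped_fusion",
            "nonconserved_uorf": "dropped_order_filter",
            "no_uorf": "no_uorf",
            "contaminant_homolog": "dropped_contaminant",
        }[plan]
        truth.append(
            {
                "gene_id": gene,
                "plan": plan,
                "expected_final_status": expected,
                "expected_range_label": _expected_range_label(orders)
                if plan == "conserved_uorf"
                else "",
            }
        )

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        for chrom in sorted(chrom_seqs):
            fh.write(f">{chrom}\n{chrom_seqs[chrom]}\n")
    gff3_path = outdir / "genes.gff3"
    gff3_path.write_text("\n".join(gff_lines) + "\n")
    collection = SequenceCollection(coll_records, taxonomy)
    collection_fasta = outdir / "collection.fa"
    taxonomy_path = outdir / "taxonomy.tsv"
    collection.write(collection_fasta, taxonomy_path)
    # the query species itself appears in the taxonomy sidecar
    with open(taxonomy_path, "a") as fh:
        fh.write(
            f"QUERY\t9606\t{QUERY_SPECIES}\t{QUERY_ORDER}\t{';'.join(QUERY_LINEAGE)}\tquery\t0\n"
        )
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("gene_id\tplan\texpected_final_status\texpected_range_label\n")
        for row in truth:
            fh.write(
                f"{row['gene_id']}\t{row['plan']}\t{row['expected_final_status']}\t"
                f"{row['expected_range_label']}\n"
            )
    return Fixture(
        genome_path=genome_path,
        gff3_path=gff3_path,
        collection_fasta=collection_fasta,
        taxonomy_path=taxonomy_path,
        truth_path=truth_path,
        truth=truth,
        collection=collection,
    )


def _tx_interval_to_genomic(
    exon_ivs: list[tuple[int, int]], strand: str, tx_iv: tuple[int, int]
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval onto genomic exon blocks."""
    blocks = []
    offset = 0
    ordered = sorted(exon_ivs, reverse=(strand == "-"))
    for (s, e) in ordered:
        elen = e - s
        lo = max(tx_iv[0] - offset, 0)
        hi = min(tx_iv[1] - offset, elen)
        if lo < hi:
            if strand == "+":
                blocks.append((s + lo, s + hi))
            else:
                blocks.append((e - hi, e - lo))
        offset += elen
    return sorted(blocks)
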