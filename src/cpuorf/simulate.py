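"""Codon-pair simulators for validating the Ka/Ks machinery.

``neutral_pair`` draws two *independent* random codon sequences — the
exchangeable null of the codon-shuffling permutation test, under which
its p-value is uniform by construction.  ``evolve_pair`` evolves two
descendants of a common ancestor under a Jukes–Cantor mutation process
thinned by a selection factor omega on nonsynonymous changes, giving
pairs with a known true dN/dS for parameter-recovery checks.
"""

from __future__ import annotations

import numpy as np

from .kaks import CODONS, CodonAlignment, encode_codons

__all__ = ["random_codon_seq", "neutral_pair", "evolve_pair"]

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [c for c in CODONS if c not in _STOPS]


def random_codon_seq(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(_SENSE[i] for i in rng.integers(0, len(_SENSE), size=n_codons))


def neutral_pair(rng: np.random.Generator, n_codons: int) -> CodonAlignment:
    """Two independent random codon sequences paired column-by-column."""
    a = encode_codons(random_codon_seq(rng, n_codons))
    b = encode_codons(random_codon_seq(rng, n_codons))
    return CodonAlignment(a, b)


def _evolve(seq: list[str], omega: float, t: float, rng: np.random.Generator) -> list[str]:
    """Propose ~3*L*t point mutations; accept synonymous ones always,
    nonsynonymous with probability omega; never accept stops."""
    from Bio.Seq import Seq

    seq = list(seq)
    L = len(seq)
    n_events = rng.poisson(3 * L * t)
    for _ in range(n_events):
        ci = int(rng.integers(L))
        pos = int(rng.integers(3))
        codon = seq[ci]
        alt_base = "ACGT"[int(rng.integers(4))]
        if alt_base == codon[pos]:
            continue
        alt = codon[:pos] + alt_base + codon[pos + 1 :]
        if alt in _STOPS:
            continue
        if str(Seq(alt).translate()) == str(Seq(codon).translate()):
            seq[ci] = alt
        elif rng.random() < omega:
            seq[ci] = alt
    return seq


def evolve_pair(
    rng: np.random.Generator,
    n_codons: int,
    omega: float,
    t: float = 0.2,
) -> CodonAlignment:
    """Ancestor + two independently evolved descendants (branch length t
    expected proposals per nucleotide site on each branch)."""
    ancestor = [
        _SENSE[i] for i in rng.integers(0, len(_SENSE), size=n_codons)
    ]
    d1 = _evolve(ancestor, omega, t, rng)
    d2 = _evolve(ancestor, omega, t, rng)
    return CodonAlignment(encode_codons("".join(d1)), encode_codons("".join(d2)))
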