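"""Pairwise Ka/Ks estimation for uORF peptide conservation testing.

Implements the Nei–Gojobori (1986) counting method with Jukes–Cantor
multiple-hit correction, a codon-aware pairwise aligner, and a
codon-shuffling permutation test that supplies an empirical null for the
observed Ka/Ks ratio.

The NG86 conventions used here: synonymous/nonsynonymous site counts per
codon are averaged over the two sequences; substitutions between codons
differing at more than one position are averaged over all mutational
pathways, each single-base step classified by comparing the translations
of the intermediate codons (stop codons translate to '*', so a step
between two stop codons counts as synonymous, any step into or out of a
stop otherwise as nonsynonymous); mutations to stop codons count as
nonsynonymous when tallying sites.  Ka = JC(pN), Ks = JC(pS) with
JC(p) = -3/4 ln(1 - 4p/3), undefined (+inf) at saturation p >= 3/4.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "KaKs",
    "CodonAlignment",
    "codon_align",
    "compute_kaks",
    "permutation_null",
]

_BASES = "TCAG"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: codon index = 16*b0 + 4*b1 + b2 with T,C,A,G -> 0..3
CODONS = ["".join(c) for c in product(_BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_STOPS = {"TAA", "TAG", "TGA"}
STOP_INDICES = frozenset(CODON_INDEX[c] for c in _STOPS)


def _translate_codon(codon: str) -> str:
    if codon in _STOPS:
        return "*"
    return str(Seq(codon).translate())


AA_BY_CODON = [_translate_codon(c) for c in CODONS]


def _site_counts() -> np.ndarray:
    """Synonymous sites per codon (S_sites[c]); N sites = 3 - S."""
    s = np.full(64, np.nan)
    for ci, codon in enumerate(CODONS):
        if codon in _STOPS:
            continue
        syn = 0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                neighbor = codon[:pos] + b + codon[pos + 1 :]
                # mutations to stop codons count as nonsynonymous sites
                if neighbor not in _STOPS and AA_BY_CODON[CODON_INDEX[neighbor]] == AA_BY_CODON[ci]:
                    syn += 1
        s[ci] = syn / 3.0
    return s


def _step_syn(c1: str, c2: str) -> bool:
    """Is the single-base step c1 -> c2 synonymous (by translation equality)?"""
    return AA_BY_CODON[CODON_INDEX[c1]] == AA_BY_CODON[CODON_INDEX[c2]]


def _pair_counts() -> tuple[np.ndarray, np.ndarray]:
    """Pathway-averaged (Sd, Nd) for every ordered codon pair."""
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, c1 in enumerate(CODONS):
        for j, c2 in enumerate(CODONS):
            if c1 == c2:
                continue
            diff = [p for p in range(3) if c1[p] != c2[p]]
            if len(diff) == 1:
                if _step_syn(c1, c2):
                    sd[i, j] = 1.0
                else:
                    nd[i, j] = 1.0
            else:
                paths = list(permutations(diff))
                w = 1.0 / len(paths)
                for path in paths:
                    cur = c1
                    for p in path:
                        nxt = cur[:p] + c2[p] + cur[p + 1 :]
                        if _step_syn(cur, nxt):
                            sd[i, j] += w
                        else:
                            nd[i, j] += w
                        cur = nxt
    return sd, nd


S_SITES = _site_counts()
SD_PAIR, ND_PAIR = _pair_counts()


def encode_codons(nt: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as codon indices.

    Raises ValueError on length not divisible by 3 or non-ACGT bases.
    """
    nt = nt.upper().replace("U", "T")
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    try:
        flat = np.array([_BASE_INDEX[b] for b in nt], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc} in codon sequence") from exc
    return flat[0::3] * 16 + flat[1::3] * 4 + flat[2::3]


@dataclass(frozen=True)
class KaKs:
    """Result of one pairwise NG86 computation."""

    ka: float
    ks: float
    ratio: float | None  #: None when Ks == 0 with Ka > 0, or saturated
    n_codons: int
    flags: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free paired codon columns extracted from a pairwise alignment."""

    codons1: np.ndarray  #: codon indices, one per retained column
    codons2: np.ndarray
    n_dropped: int = 0  #: columns dropped (gaps, ambiguous bases)
    score: float = 0.0  #: peptide alignment score (BLOSUM62, affine gaps)

    def __len__(self) -> int:
        return len(self.codons1)


_ALIGNER: PairwiseAligner | None = None


def _peptide_aligner() -> PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def _strip_stop(nt: str) -> str:
    nt = nt.upper().replace("U", "T")
    if len(nt) >= 3 and nt[-3:] in _STOPS:
        return nt[:-3]
    return nt


def codon_align(nt1: str, nt2: str) -> CodonAlignment:
    """Codon-aware pairwise alignment of two in-frame coding sequences.

    The peptides are aligned globally (BLOSUM62, gap open -11, extend -1)
    and the alignment is back-translated onto the codons.  Columns with a
    gap or an ambiguous codon in either sequence are dropped from the
    paired-column output (counted in ``n_dropped``).  Terminal stop
    codons are removed before alignment.
    """
    nt1, nt2 = _strip_stop(nt1), _strip_stop(nt2)
    if len(nt1) % 3 or len(nt2) % 3:
        raise ValueError("codon_align requires in-frame sequences (length % 3 == 0)")

    def pep(nt: str) -> str:
        return "".join(
            "X" if any(b not in _BASE_INDEX for b in nt[i : i + 3])
            else AA_BY_CODON[CODON_INDEX[nt[i : i + 3]]]
            for i in range(0, len(nt), 3)
        )

    p1, p2 = pep(nt1), pep(nt2)
    if not p1 or not p2:
        return CodonAlignment(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    if "*" in p1 or "*" in p2:
        raise ValueError("internal stop codon in sequence passed to codon_align")
    aln = _peptide_aligner().align(p1, p2)[0]
    blocks1, blocks2 = aln.aligned
    idx1: list[int] = []
    idx2: list[int] = []
    for (a0, a1), (b0, b1) in zip(blocks1, blocks2):
        idx1.extend(range(a0, a1))
        idx2.extend(range(b0, b1))
    total_cols = max(len(p1), len(p2))
    keep1, keep2 = [], []
    dropped = total_cols - len(idx1)
    for i, j in zip(idx1, idx2):
        c1, c2 = nt1[3 * i : 3 * i + 3], nt2[3 * j : 3 * j + 3]
        if all(b in _BASE_INDEX for b in c1 + c2):
            keep1.append(CODON_INDEX[c1])
            keep2.append(CODON_INDEX[c2])
        else:
            dropped += 1
    return CodonAlignment(
        np.array(keep1, dtype=np.int64),
        np.array(keep2, dtype=np.int64),
        n_dropped=dropped,
        score=aln.score,
    )


def _jc(p: float) -> float:
    if p < 0.75:
        return abs(-0.75 * np.log1p(-4.0 * p / 3.0))
    return float("inf")


def compute_kaks(alignment: CodonAlignment) -> KaKs:
    """NG86 Ka, Ks and their ratio for a paired codon alignment.

    Degenerate cases: an identical pair gives (0, 0) with ratio 0
    (flagged ``degenerate``); Ks == 0 with Ka > 0 gives an undefined
    ratio (None, flagged ``ks_zero``); a saturated Jukes–Cantor argument
    gives +inf for the affected rate and the ratio is 0 (Ks saturated)
    or None (Ka saturated), flagged ``saturated``.
    """
    a, b = alignment.codons1, alignment.codons2
    if len(a) == 0:
        return KaKs(0.0, 0.0, None, 0, flags=("empty",))
    s_sites = (S_SITES[a].sum() + S_SITES[b].sum()) / 2.0
    n_sites = 3.0 * len(a) - s_sites
    sd = SD_PAIR[a, b].sum()
    nd = ND_PAIR[a, b].sum()
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jc(ps)
    ka = _jc(pn)
    flags: list[str] = []
    if np.isinf(ka) or np.isinf(ks):
        flags.append("saturated")
    if np.isinf(ka):
        ratio: float | None = None
    elif np.isinf(ks):
        ratio = 0.0 if ka < np.inf else None
    elif ks == 0.0:
        if ka == 0.0:
            ratio = 0.0
            flags.append("degenerate")
        else:
            ratio = None
            flags.append("ks_zero")
    else:
        ratio = ka / ks
    return KaKs(float(ka), float(ks), ratio, len(a), flags=tuple(flags))


def _raw_ratio(sd, nd, s_sites: float, n_sites: float):
    """Uncorrected pN/pS — the permutation test statistic.

    Monotone in Ka/Ks wherever both Jukes–Cantor corrections are
    defined, but stays finite-ordered under saturation (a shuffled null
    pair with saturated Ks is maximally diverged and must rank as *less*
    purifying than any conserved pair, not collapse to ratio 0).
    ps == 0 maps to 0 when pn == 0 and to +inf otherwise.
    """
    ps = np.asarray(sd, dtype=float) / s_sites
    pn = np.asarray(nd, dtype=float) / n_sites
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ps > 0, pn / np.where(ps > 0, ps, 1.0), np.where(pn == 0, 0.0, np.inf))
    return out


def _null_stats(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """pN/pS statistics for codon-shuffled null pairings (vectorised).

    Site totals are invariant under codon-order shuffling, so only the
    pathway-averaged difference counts need recomputing per permutation.
    """
    L = len(a)
    s_sites = (S_SITES[a].sum() + S_SITES[b].sum()) / 2.0
    n_sites = 3.0 * L - s_sites
    perm_a = np.argsort(rng.random((n_perm, L)), axis=1)
    perm_b = np.argsort(rng.random((n_perm, L)), axis=1)
    sd = SD_PAIR[a[perm_a], b[perm_b]].sum(axis=1)
    nd = ND_PAIR[a[perm_a], b[perm_b]].sum(axis=1)
    return _raw_ratio(sd, nd, s_sites, n_sites)


def permutation_null(
    alignment: CodonAlignment,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """One-sided permutation p-value for purifying selection.

    The null shuffles the codon order of each sequence independently
    (preserving codon composition) and re-pairs columns by index;
    p = (1 + #{null statistic <= observed}) / (n_perm + 1), the statistic
    being the uncorrected pN/pS ratio (see :func:`_raw_ratio`).
    Alignments with two or fewer columns return p = 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(alignment) <= 2:
        return 1.0
    a, b = alignment.codons1, alignment.codons2
    L = len(a)
    s_sites = (S_SITES[a].sum() + S_SITES[b].sum()) / 2.0
    n_sites = 3.0 * L - s_sites
    obs = float(_raw_ratio(SD_PAIR[a, b].sum(), ND_PAIR[a, b].sum(), s_sites, n_sites))
    nulls = _null_stats(a, b, n_perm, rng)
    return float((1 + np.sum(nulls <= obs)) / (n_perm + 1))
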