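"""Shared sequence utilities: BLOSUM62 scoring, pairwise alignment, translation.

All protein alignments in the package use BLOSUM62 with affine gaps
(open 11, extend 1). Percent identity is computed from one optimal global
alignment as identical columns / alignment columns, with terminal gap
columns excluded from the denominator.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

GAP_OPEN = -11
GAP_EXTEND = -1

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: codons per amino acid (standard table), for seeded reverse translation
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_BY_AA:
    CODONS_BY_AA[_aa].sort()

STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))


@lru_cache(maxsize=1)
def blosum62() -> substitution_matrices.Array:
    return substitution_matrices.load("BLOSUM62")


@lru_cache(maxsize=1)
def blosum62_lookup() -> np.ndarray:
    """BLOSUM62 as a dense int array indexed by ord(aa) & 31 for both axes.

    Letters absent from the matrix alphabet (and 'X') score the matrix
    minimum; the stop symbol '*' keeps its strongly negative row.
    """
    mat = blosum62()
    lut = np.full((32, 32), int(mat.min()), dtype=np.int32)
    for a in mat.alphabet:
        for b in mat.alphabet:
            lut[ord(a) & 31, ord(b) & 31] = int(mat[a, b])
    return lut


def make_aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local" if mode == "local" else "global"
    aligner.substitution_matrix = blosum62()
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@lru_cache(maxsize=1)
def _global_aligner() -> PairwiseAligner:
    return make_aligner("global")


def global_score(a: str, b: str) -> float:
    """Needleman-Wunsch score of two protein sequences."""
    return float(_global_aligner().score(a, b))


def percent_identity(a: str, b: str) -> float:
    """Percent identity from one optimal global alignment.

    Identical columns over alignment columns, terminal gap columns excluded.
    """
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    alignment = next(iter(_global_aligner().align(a, b)))
    sa, sb = alignment[0], alignment[1]
    # trim columns where either sequence has a terminal gap
    start = max(len(sa) - len(sa.lstrip("-")), len(sb) - len(sb.lstrip("-")))
    end = len(sa) - max(len(sa) - len(sa.rstrip("-")), len(sb) - len(sb.rstrip("-")))
    columns = end - start
    if columns <= 0:
        return 0.0
    matches = sum(1 for i in range(start, end) if sa[i] == sb[i])
    return 100.0 * matches / columns


def translate(dna: str) -> str:
    """Translate a DNA string (trimmed to whole codons), stops as '*'."""
    usable = len(dna) - len(dna) % 3
    return str(Seq(dna[:usable]).translate())


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate choosing uniformly among synonymous codons."""
    parts = []
    for aa in protein:
        codons = CODONS_BY_AA[aa]
        parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)


def mutate_protein(
    protein: str,
    divergence: float,
    rng: np.random.Generator,
    keep_first: bool = True,
) -> str:
    """Substitute a `divergence` fraction of residues with distinct ones.

    Positions are drawn without replacement; the initial methionine is kept
    when `keep_first` so the coding sequence retains its start codon.
    """
    n = len(protein)
    k = int(round(divergence * n))
    lo = 1 if keep_first else 0
    positions = rng.choice(np.arange(lo, n), size=min(k, n - lo), replace=False)
    seq = list(protein)
    for pos in positions:
        choices = [aa for aa in AA_ALPHABET if aa != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return "".join(seq)


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Random protein starting with methionine (uniform residue usage)."""
    body = rng.integers(0, len(AA_ALPHABET), size=length - 1)
    return "M" + "".join(AA_ALPHABET[i] for i in body)
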