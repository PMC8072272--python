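"""Universal genetic code tables used by the codon substitution machinery.

Everything here is precomputed once at import: the 61 sense codons, their
amino-acid translations, and pairwise single-nucleotide-change relationships
(which position differs, transition vs transversion, synonymous vs
nonsynonymous).
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: The 61 sense codons of the universal code, in TCAG enumeration order.
SENSE_CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)
N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: Amino acid (one-letter) encoded by each sense codon.
CODON_AA: tuple[str, ...] = tuple(_STANDARD.forward_table[c] for c in SENSE_CODONS)

_PURINES = frozenset("AG")


def is_transition(n1: str, n2: str) -> bool:
    """True for A<->G or C<->T changes."""
    return n1 != n2 and ((n1 in _PURINES) == (n2 in _PURINES))


def _pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    diff_pos = np.full((N_CODONS, N_CODONS), -1, dtype=np.int8)
    is_ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    is_syn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            (k,) = diffs
            diff_pos[i, j] = k
            is_ts[i, j] = is_transition(ci[k], cj[k])
            is_syn[i, j] = CODON_AA[i] == CODON_AA[j]
    return diff_pos, is_ts, is_syn


#: DIFF_POS[i, j] = position (0-2) where codons i, j differ, or -1 if they are
#: identical or differ at more than one position.
DIFF_POS, IS_TRANSITION, IS_SYNONYMOUS = _pair_tables()

#: Boolean mask of codon pairs reachable by a single nucleotide change.
SINGLE_STEP = DIFF_POS >= 0


def f3x4_frequencies(sequences, floor: float = 1e-6) -> np.ndarray:
    """F3x4 stationary codon frequencies from codon-position nucleotide counts.

    ``sequences`` is an iterable of in-frame nucleotide strings. Frequencies of
    the four nucleotides are tabulated separately at each codon position, codon
    frequencies formed as their product, stop codons removed, and the result
    renormalized over the 61 sense codons. A small floor keeps every sense
    codon representable (zero stationary mass breaks the reversible
    eigendecomposition).
    """
    pos_counts = np.zeros((3, 4))
    lookup = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for seq in sequences:
        if len(seq) % 3:
            raise ValueError("sequence length not a multiple of 3")
        for i in range(0, len(seq), 3):
            for p in range(3):
                pos_counts[p, lookup[seq[i + p]]] += 1
    if pos_counts.sum() == 0:
        raise ValueError("no codons supplied")
    pos_freqs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            pos_freqs[0, lookup[c[0]]] * pos_freqs[1, lookup[c[1]]] * pos_freqs[2, lookup[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum()


def uniform_frequencies() -> np.ndarray:
    """Equal frequency 1/61 for every sense codon."""
    return np.full(N_CODONS, 1.0 / N_CODONS)
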