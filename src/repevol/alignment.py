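"""Codon alignments: container, FASTA reading/cleaning, concatenation.

Alignments are stored as arrays of sense-codon indices (taxa x codon
columns). Cleaning removes any codon column containing a gap, a stop codon or
an ambiguity code, mirroring the usual pre-filtering applied before codon
model fitting; loci shorter than the minimum length after cleaning are
rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .genetics import CODON_INDEX, SENSE_CODONS

logger = logging.getLogger(__name__)

#: Loci must be longer than 200 bp after gap/indel removal, i.e. >= 67 codons.
MIN_CODONS = 67

_VALID_NUCS = frozenset("TCAG")


class AlignmentError(ValueError):
    """Malformed or inadmissible codon alignment."""


@dataclass
class CodonAlignment:
    """Gap-free in-frame codon alignment for a fixed set of taxa.

    ``codons`` holds sense-codon indices, shape (n_taxa, n_codons).
    """

    locus_id: str
    taxa: tuple[str, ...]
    codons: np.ndarray
    boundaries: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise AlignmentError(
                f"{self.locus_id}: codon matrix shape {self.codons.shape} does not "
                f"match {len(self.taxa)} taxa"
            )
        if self.codons.size and (self.codons.min() < 0 or self.codons.max() >= 61):
            raise AlignmentError(f"{self.locus_id}: codon index out of range")

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence(self, taxon: str) -> str:
        row = self.codons[self.taxa.index(taxon)]
        return "".join(SENSE_CODONS[i] for i in row)

    @classmethod
    def from_sequences(cls, locus_id: str, taxa, sequences) -> "CodonAlignment":
        """Build from clean nucleotide strings (no gaps/stops/ambiguity)."""
        rows = []
        for taxon, seq in zip(taxa, sequences):
            seq = seq.upper().replace("U", "T")
            if len(seq) % 3:
                raise AlignmentError(f"{locus_id}/{taxon}: length {len(seq)} not a multiple of 3")
            try:
                rows.append([CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq), 3)])
            except KeyError as exc:
                raise AlignmentError(f"{locus_id}/{taxon}: invalid codon {exc}") from exc
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise AlignmentError(f"{locus_id}: unequal sequence lengths")
        return cls(locus_id, tuple(taxa), np.array(rows, dtype=np.int16))

    def pattern_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns (n_patterns x n_taxa) and their counts."""
        patterns, counts = np.unique(self.codons.T, axis=0, return_counts=True)
        return patterns, counts


def clean_columns(taxa, raw_sequences, locus_id: str = "locus") -> tuple[CodonAlignment, int]:
    """Drop codon columns containing gaps, stops or ambiguity codes.

    Returns the cleaned alignment and the number of dropped columns.
    """
    seqs = [s.upper().replace("U", "T") for s in raw_sequences]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(f"{locus_id}: unaligned input (unequal lengths)")
    (length,) = lengths
    if length % 3:
        raise AlignmentError(f"{locus_id}: alignment length {length} not a multiple of 3")
    kept_rows: list[list[int]] = [[] for _ in seqs]
    dropped = 0
    for i in range(0, length, 3):
        cods = [s[i : i + 3] for s in seqs]
        ok = all(set(c) <= _VALID_NUCS and c in CODON_INDEX for c in cods)
        if ok:
            for row, c in zip(kept_rows, cods):
                row.append(CODON_INDEX[c])
        else:
            dropped += 1
    if dropped:
        logger.info("%s: dropped %d codon columns during cleaning", locus_id, dropped)
    aln = CodonAlignment(locus_id, tuple(taxa), np.array(kept_rows, dtype=np.int16).reshape(len(seqs), -1))
    return aln, dropped


def read_alignment_fasta(
    path,
    expected_taxa=None,
    min_codons: int = MIN_CODONS,
    aliases: dict[str, str] | None = None,
) -> CodonAlignment:
    """Read a 4-record locus FASTA, clean it and enforce the length filter.

    ``expected_taxa`` fixes the row order; ``aliases`` maps record ids onto
    configured taxon names. Loci whose cleaned length is not longer than
    200 bp (67 codons) are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 4:
        raise AlignmentError(f"{path}: expected 4 records, found {len(records)}")
    names = [(aliases or {}).get(r.id, r.id) for r in records]
    seqs = [str(r.seq) for r in records]
    if expected_taxa is not None:
        order = []
        for taxon in expected_taxa:
            if taxon not in names:
                raise AlignmentError(f"{path}: taxon {taxon!r} missing (found {names})")
            order.append(names.index(taxon))
        names = [names[i] for i in order]
        seqs = [seqs[i] for i in order]
    aln, _ = clean_columns(names, seqs, locus_id=path.stem)
    if aln.n_codons < min_codons:
        raise AlignmentError(
            f"{path}: {aln.n_codons * 3} bp after cleaning; loci must exceed 200 bp"
        )
    return aln


def write_alignment_fasta(aln: CodonAlignment, path) -> None:
    with open(path, "w") as fh:
        for taxon in aln.taxa:
            fh.write(f">{taxon}\n{aln.sequence(taxon)}\n")


def concatenate(alignments, locus_ids=None, new_id: str = "concat") -> CodonAlignment:
    """Column-wise concatenation of loci sharing a taxon set, in input order.

    ``locus_ids`` optionally restricts (and orders by input order) the loci
    included. Locus boundaries are recorded as (locus_id, n_codons) pairs.
    """
    alignments = list(alignments)
    if locus_ids is not None:
        wanted = set(locus_ids)
        alignments = [a for a in alignments if a.locus_id in wanted]
    if not alignments:
        raise AlignmentError("no alignments to concatenate")
    taxa = alignments[0].taxa
    for a in alignments:
        if a.taxa != taxa:
            raise AlignmentError(f"{a.locus_id}: taxon set differs from {alignments[0].locus_id}")
    mat = np.concatenate([a.codons for a in alignments], axis=1)
    boundaries = [(a.locus_id, a.n_codons) for a in alignments]
    return CodonAlignment(new_id, taxa, mat, boundaries=boundaries)
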