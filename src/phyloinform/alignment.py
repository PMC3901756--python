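"""Aligned DNA matrices (FASTA I/O, symbol encoding).

Sequences are stored uppercase as a taxa x columns character array. The
four unambiguous bases A, C, G, T are the only states used in downstream
computations; gaps ('-'), '?', 'N' and every IUPAC ambiguity code are all
treated as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SeqMatrix", "AlignmentError", "read_fasta", "write_fasta"]

_BASES = "ACGT"
_MISSING = "-?N" + "RYSWKMBDHV" + "U"  # ambiguity codes count as missing
_ALPHABET = set(_BASES) | set(_MISSING)

#: integer codes: A=0 C=1 G=2 T=3, anything missing = 4
MISSING_CODE = 4


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


@dataclass
class SeqMatrix:
    """A multiple sequence alignment over the DNA alphabet."""

    labels: list
    chars: np.ndarray  # (n_taxa, n_sites) of single uppercase characters

    def __post_init__(self):
        self.chars = np.asarray(self.chars, dtype="U1")
        if self.chars.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-D")
        if len(self.labels) != self.chars.shape[0]:
            raise AlignmentError("label count does not match row count")
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dup}")
        bad = set(np.unique(self.chars)) - _ALPHABET
        if bad:
            raise AlignmentError(f"illegal symbols in alignment: {sorted(bad)}")
        self._codes: np.ndarray | None = None

    @classmethod
    def from_strings(cls, labels, seqs) -> "SeqMatrix":
        seqs = [s.upper() for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(
                f"sequences are not aligned: lengths {sorted(lengths)}"
            )
        arr = np.array([list(s) for s in seqs], dtype="U1")
        if arr.size == 0:
            arr = arr.reshape(len(seqs), 0)
        return cls(list(labels), arr)

    @property
    def n_taxa(self) -> int:
        return self.chars.shape[0]

    @property
    def n_sites(self) -> int:
        return self.chars.shape[1]

    def codes(self) -> np.ndarray:
        """uint8 matrix with A=0 C=1 G=2 T=3 and missing=4 (cached)."""
        if self._codes is None:
            out = np.full(self.chars.shape, MISSING_CODE, dtype=np.uint8)
            for k, base in enumerate(_BASES):
                out[self.chars == base] = k
            self._codes = out
        return self._codes

    def sequence(self, label: str) -> str:
        try:
            row = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown taxon: {label!r}") from None
        return "".join(self.chars[row])

    def take_columns(self, cols0: np.ndarray) -> "SeqMatrix":
        """Sub-alignment of the given 0-based columns (order preserved)."""
        return SeqMatrix(list(self.labels), self.chars[:, cols0])


def read_fasta(path) -> SeqMatrix:
    """Read a FASTA alignment; sequences are uppercased and must be equal
    length. Duplicate headers are an error."""
    from Bio import SeqIO

    labels, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        seqs.append(str(rec.seq))
    if not labels:
        raise AlignmentError(f"no FASTA records in {path}")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise AlignmentError(f"duplicate FASTA headers: {dup}")
    return SeqMatrix.from_strings(labels, seqs)


def write_fasta(matrix: SeqMatrix, path, width: int = 70) -> None:
    """Write the alignment as wrapped FASTA (round-trips with read_fasta)."""
    with open(path, "w") as fh:
        for lab, row in zip(matrix.labels, matrix.chars):
            fh.write(f">{lab}\n")
            seq = "".join(row)
            for i in range(0, max(len(seq), 1), width):
                fh.write(seq[i : i + width] + "\n")
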