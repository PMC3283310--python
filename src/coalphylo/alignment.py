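"""In-memory multiple sequence alignment keyed by taxon, with FASTA I/O."""

from __future__ import annotations

from typing import Dict, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment"]

# byte-code lookup: A,C,G,T -> 0..3, everything else (gaps, ambiguity) -> -1
_CODE = np.full(256, -1, dtype=np.int8)
for i, ch in enumerate("ACGT"):
    _CODE[ord(ch)] = i
    _CODE[ord(ch.lower())] = i


class Alignment(Mapping):
    """Aligned sequences over {A, C, G, T, -, N}, all of equal length.

    Behaves as a read-only mapping taxon -> sequence string.  Taxon order is
    preserved from construction (and from file order for FASTA input).
    """

    def __init__(self, sequences: Dict[str, str]):
        if not sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        self._seqs = {str(k): str(v).upper() for k, v in sequences.items()}
        if len(self._seqs) != len(sequences):
            raise ValueError("duplicate taxon names")
        self._length = lengths.pop()

    # Mapping interface -----------------------------------------------------
    def __getitem__(self, taxon: str) -> str:
        return self._seqs[taxon]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def taxa(self) -> list:
        return list(self._seqs)

    @property
    def length(self) -> int:
        """Number of columns."""
        return self._length

    # numeric view ----------------------------------------------------------
    def as_codes(self) -> np.ndarray:
        """(n_taxa, n_cols) int8 matrix: A..T -> 0..3, gap/other -> -1."""
        rows = [
            _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
            for s in self._seqs.values()
        ]
        return np.vstack(rows) if rows else np.empty((0, 0), dtype=np.int8)

    def without_gaps(self) -> Dict[str, str]:
        """Unaligned sequences (gaps stripped per taxon)."""
        return {k: v.replace("-", "") for k, v in self._seqs.items()}

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        """Nonparametric bootstrap replicate: columns drawn with replacement."""
        idx = rng.integers(0, self._length, size=self._length)
        out = {}
        for k, v in self._seqs.items():
            arr = np.frombuffer(v.encode("ascii"), dtype=np.uint8)
            out[k] = arr[idx].tobytes().decode("ascii")
        return Alignment(out)

    # I/O -------------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=name, description="")
            for name, s in self._seqs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({len(self)} taxa x {self.length} columns)"
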