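"""Sequence I/O and canonical k-mer decomposition.

FASTA reading/writing is delegated to Biopython; this module adds the
validation the pipeline relies on (unique ids, alphabet checks) and the
2-bit-packed canonical k-mer machinery shared by every sketch-based stage.

A canonical k-mer is the lexicographic minimum of a k-mer and its reverse
complement, so that detection is strand-agnostic.  K-mers are encoded as
unsigned 64-bit integers with 2 bits per base (A=0, C=1, G=2, T=3), which
bounds usable k at 31; the pipeline default is k=23.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

Moltype = Literal["nucleotide", "protein"]


class FastaFormatError(ValueError):
    """Raised when a file is not parseable FASTA or violates record invariants."""


@dataclass
class SequenceRecord:
    """A single named sequence (nucleotide or protein)."""

    id: str
    seq: str
    moltype: Moltype = "nucleotide"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        self.seq = self.seq.upper()
        alphabet = NUCLEOTIDE_ALPHABET if self.moltype == "nucleotide" else PROTEIN_ALPHABET
        extra = set(self.seq) - alphabet
        if extra:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(extra)} are not valid "
                f"for moltype {self.moltype!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class KmerSet:
    """Deduplicated canonical k-mers of one sequence source.

    ``kmers`` is a sorted ``uint64`` array; set semantics are guaranteed by
    construction (``np.unique``).
    """

    source_id: str
    k: int
    kmers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd positive integer, got {self.k}")
        if self.k > 31:
            raise ValueError("2-bit packing limits k to 31")
        self.kmers = np.asarray(self.kmers, dtype=np.uint64)

    def __len__(self) -> int:
        return int(self.kmers.size)


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, moltype: Moltype = "nucleotide") -> list[SequenceRecord]:
    """Read a (optionally gzip-compressed) FASTA file into records.

    Headers are split at the first whitespace to form the id; sequence bodies
    are uppercased.  Raises :class:`FastaFormatError` if the file does not
    begin with a header line or contains duplicate ids.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno} is not a FASTA header ('>' expected)"
                )
            break
        else:
            return []
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), moltype=moltype))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base → 2-bit code lookup; anything outside ACGT maps to the sentinel 255
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def sorted_unique(values: np.ndarray) -> np.ndarray:
    """np.unique without the stable-sort overhead (quicksort + dedup mask)."""
    if values.size == 0:
        return values
    values = np.sort(values)
    return values[np.concatenate(([True], values[1:] != values[:-1]))]


def canonical_kmer_array(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical k-mers of ``seq`` as packed uint64 codes.

    Windows containing any non-ACGT character are dropped.  A sequence
    shorter than k yields an empty array (with a warning).
    """
    if k < 1 or k > 31:
        raise ValueError("k must be in [1, 31]")
    codes = _encode(seq)
    n = codes.size
    if k > n:
        warnings.warn(f"k={k} exceeds sequence length {n}; empty k-mer set")
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    invalid = (codes == 255).astype(np.int64)
    if invalid.any():
        csum = np.concatenate(([0], np.cumsum(invalid)))
        ok = (csum[k:] - csum[:-k]) == 0
    else:
        ok = np.ones(m, dtype=bool)
    c = np.where(codes == 255, 0, codes).astype(np.uint64)
    comp = np.uint64(3) - c
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c[j : j + m]
        rev |= comp[j : j + m] << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return sorted_unique(canon[ok])


def canonical_kmers(record: SequenceRecord, k: int = 23) -> KmerSet:
    """Canonical k-mer set of a nucleotide record."""
    if record.moltype != "nucleotide":
        raise ValueError("canonical k-mers are defined for nucleotide records only")
    if k % 2 == 0:
        raise ValueError("k must be odd so no k-mer equals its own reverse complement")
    return KmerSet(source_id=record.id, k=k, kmers=canonical_kmer_array(record.seq, k))


def decode_kmer(code: int, k: int) -> str:
    """Inverse of the 2-bit packing, mainly for debugging and reports."""
    bases = "ACGT"
    out = []
    for _ in range(k):
        out.append(bases[code & 3])
        code >>= 2
    return "".join(reversed(out))
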