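"""Base encoding and reference-sequence access.

Bases are held as small unsigned integers throughout the package so that
pileup and consensus arithmetic can be vectorised: A=0, C=1, G=2, T=3,
N=4.  Code 5 marks a reference position removed by a deletion inside an
aligned read ("gap"); it never appears in a molecule or reference.
"""

from __future__ import annotations

import numpy as np
from pyfaidx import Fasta

A, C, G, T, N_CODE, GAP = 0, 1, 2, 3, 4, 5

_ALPHABET = np.frombuffer(b"ACGTN-", dtype=np.uint8)
_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _ch in enumerate(b"ACGTN-"):
    _ENCODE[_ch] = _i
    _ENCODE[_ch + 32] = _i  # lower case


def encode(seq: str) -> np.ndarray:
    """Encode a base string into uint8 codes (unknown letters become N)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back into a base string."""
    return _ALPHABET[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


class Reference:
    """In-memory reference genome keyed by contig name.

    Thin wrapper around a ``{contig: uint8 code array}`` mapping with
    FASTA import/export.  Hybrid-capture panels cover kilobases, so whole
    contigs are held in memory.
    """

    def __init__(self, contigs: dict[str, np.ndarray]):
        self.contigs = {name: np.asarray(arr, dtype=np.uint8) for name, arr in contigs.items()}

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "Reference":
        return cls({name: encode(seq) for name, seq in sequences.items()})

    @classmethod
    def from_fasta(cls, path) -> "Reference":
        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: encode(str(fa[name][:])) for name in fa.keys()})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, arr in self.contigs.items():
                fh.write(f">{name}\n")
                seq = decode(arr)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> np.ndarray:
        return self.contigs[name]

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def base(self, chrom: str, pos: int) -> str:
        return decode(self.contigs[chrom][pos : pos + 1])

    def slice(self, chrom: str, start: int, end: int) -> str:
        return decode(self.contigs[chrom][start:end])
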