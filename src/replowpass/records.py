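"""Core read/tag records and the batch read-set container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np


@dataclass
class SequenceRead:
    """A sequencing read: identifier, bases, optional per-base Phred scores."""

    id: str
    bases: str
    qualities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities, dtype=np.int16)
            if len(self.qualities) != len(self.bases):
                raise ValueError(
                    f"read {self.id!r}: {len(self.qualities)} qualities for "
                    f"{len(self.bases)} bases"
                )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class SequenceTag:
    """A quality-trimmed 30-nt tag used for repeat quantification."""

    id: str
    bases: str
    source_sample: str | None = None

    def __post_init__(self) -> None:
        if len(self.bases) != 30:
            raise ValueError(f"tag {self.id!r}: length {len(self.bases)} != 30")


@dataclass
class ReadSet:
    """A homogeneous batch of reads; quality scores stored as one matrix.

    ``qualities`` is an (n_reads, read_length) int16 matrix for fixed-length
    short-read batches, or ``None`` for long reads.
    """

    ids: list[str]
    seqs: list[str]
    qualities: np.ndarray | None = None
    sample: str | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[SequenceRead]:
        for i in range(len(self.ids)):
            q = self.qualities[i] if self.qualities is not None else None
            yield SequenceRead(self.ids[i], self.seqs[i], q)

    def total_bases(self) -> int:
        return sum(len(s) for s in self.seqs)

    @classmethod
    def from_reads(cls, reads: Sequence[SequenceRead], sample: str | None = None) -> "ReadSet":
        ids = [r.id for r in reads]
        seqs = [r.bases for r in reads]
        quals = None
        if reads and reads[0].qualities is not None:
            quals = np.vstack([r.qualities for r in reads])
        return cls(ids, seqs, quals, sample)

    def extend(self, other: "ReadSet") -> "ReadSet":
        quals = None
        if self.qualities is not None and other.qualities is not None:
            quals = np.vstack([self.qualities, other.qualities])
        elif self.qualities is not None or other.qualities is not None:
            raise ValueError("cannot mix reads with and without qualities")
        return ReadSet(self.ids + other.ids, self.seqs + other.seqs, quals, self.sample)


def read_origin(read_id: str) -> dict:
    """Parse the provenance fields the simulator encodes in read ids.

    Simulated ids look like ``m_longs_12|pos=3301|strand=-|src=genome`` and
    optionally carry ``dup_of=<id>`` for artificial duplicates.
    """
    parts = read_id.split("|")
    info: dict = {"name": parts[0]}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            info[k] = int(v) if v.lstrip("-").isdigit() else v
    return info
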