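"""Sequence I/O and the partitioned read universe.

FASTQ here is strictly the 4-line-per-record layout with phred+33
qualities, which is what short-read archives emit. Reads keep their
qualities bit-for-bit through a round trip; the recruitment stages work
on bare sequences and qualities are restored from the original files
just before assembly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ReadRecord",
    "ReadPool",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "restore_qualities",
]

PAIR_ROLES = ("single", "fwd", "rev", "merged")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read.

    pair_role distinguishes single-end reads, the two mates of a pair,
    and pairs fused by overlap merging. mate_id links mates (and, for a
    merged read, the reverse mate it absorbed).
    """

    id: str
    seq: str
    qual: str | None = None
    pair_role: str = "single"
    mate_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if self.pair_role not in PAIR_ROLES:
            raise ValueError(f"read {self.id!r}: bad pair_role {self.pair_role!r}")

    def __len__(self) -> int:
        return len(self.seq)


UNRECRUITED = "unrecruited"


class ReadPool:
    """The read universe, partitioned into unrecruited reads and reads
    recruited at cycle c (seeds are cycle 0).

    The partition is exhaustive and exclusive: every read carries
    exactly one label, and recruitment only ever moves reads out of the
    unrecruited set.
    """

    def __init__(self, records: Iterable[ReadRecord] = ()):
        self._records: dict[str, ReadRecord] = {}
        self._partition: dict[str, str] = {}
        for r in records:
            self.add(r)

    def add(self, record: ReadRecord) -> None:
        if record.id in self._records:
            raise ValueError(f"duplicate read id {record.id!r}")
        self._records[record.id] = record
        self._partition[record.id] = UNRECRUITED

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self._records

    def __getitem__(self, read_id: str) -> ReadRecord:
        return self._records[read_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def records(self) -> Iterator[ReadRecord]:
        return iter(self._records.values())

    def label(self, read_id: str) -> str:
        return self._partition[read_id]

    def unrecruited_ids(self) -> list[str]:
        return [i for i, lab in self._partition.items() if lab == UNRECRUITED]

    def recruited_ids(self, cycle: int | None = None) -> list[str]:
        """Ids recruited at a given cycle, or at any cycle if None."""
        if cycle is None:
            return [i for i, lab in self._partition.items() if lab != UNRECRUITED]
        want = f"recruited@{cycle}"
        return [i for i, lab in self._partition.items() if lab == want]

    def recruit(self, ids: Iterable[str], cycle: int) -> None:
        """Relabel unrecruited reads as recruited@cycle."""
        if cycle < 0:
            raise ValueError("cycle must be >= 0")
        label = f"recruited@{cycle}"
        for i in ids:
            if i not in self._records:
                raise KeyError(f"read id {i!r} not in pool")
            if self._partition[i] != UNRECRUITED:
                raise ValueError(
                    f"read {i!r} already labelled {self._partition[i]!r}"
                )
            self._partition[i] = label

    def partition_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self._partition.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, pair_role: str = "single") -> list[ReadRecord]:
    """Parse a 4-line-per-record phred+33 FASTQ file.

    Ids are the header token before the first whitespace; record order
    is preserved. Malformed records (truncated block, quality/sequence
    length mismatch, missing sigils) raise ValueError naming the
    0-based record index.
    """
    if pair_role not in PAIR_ROLES:
        raise ValueError(f"bad pair_role {pair_role!r}")
    records: list[ReadRecord] = []
    with _open_text(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                break
            if header.strip() == "":
                continue
            lines = [header, fh.readline(), fh.readline(), fh.readline()]
            if any(l == "" for l in lines):
                raise ValueError(f"record {idx}: truncated FASTQ block")
            header, seq, plus, qual = (l.rstrip("\n").rstrip("\r") for l in lines)
            if not header.startswith("@"):
                raise ValueError(f"record {idx}: header does not start with '@'")
            if not plus.startswith("+"):
                raise ValueError(f"record {idx}: separator line does not start with '+'")
            if len(qual) != len(seq):
                raise ValueError(
                    f"record {idx}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            rid = header[1:].split()[0] if header[1:].split() else ""
            if not rid:
                raise ValueError(f"record {idx}: empty read id")
            records.append(ReadRecord(rid, seq.upper(), qual, pair_role))
            idx += 1
    return records


def write_fastq(records: Iterable[ReadRecord], path) -> None:
    """Write records as 4-line FASTQ. Records without qualities get Q40 ('I')."""
    with _open_text(path, "wt") as fh:
        for r in records:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly line-wrapped) FASTA file as (id, sequence) pairs."""
    entries: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    entries.append((name, "".join(chunks)))
                name = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.upper())
    if name is not None:
        entries.append((name, "".join(chunks)))
    return entries


def write_fasta(entries: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def restore_qualities(ids: Iterable[str], original) -> list[ReadRecord]:
    """Fetch reads byte-identical to the original FASTQ for the given ids.

    `original` is a FASTQ path or a list of FASTQ paths. Raises KeyError
    listing every requested id that is absent from the originals.
    """
    wanted = set(ids)
    if not wanted:
        return []
    paths = [original] if isinstance(original, (str, Path)) else list(original)
    found: dict[str, ReadRecord] = {}
    for p in paths:
        for rec in read_fastq(p):
            if rec.id in wanted and rec.id not in found:
                found[rec.id] = rec
    missing = sorted(wanted - found.keys())
    if missing:
        raise KeyError(f"ids absent from original FASTQ: {missing}")
    return [found[i] for i in sorted(wanted)]
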