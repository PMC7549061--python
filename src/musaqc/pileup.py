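"""Per-position read support against the A-genome reference.

A :class:`PileupColumn` summarises, for one reference position, how many
aligned reads support each nucleotide and how many support an indel.  It is
the interchange record between the read simulator, the variant caller and the
dosage/ploidy stages, and replaces a full alignment: every downstream
computation in this package is column-wise.

Columns serialise to a samtools-pileup-like TSV with five fields::

    chrom  pos  ref  depth  bases

where ``bases`` spells out the supporting reads, e.g. ``AAAAG++`` for four
reads calling A, one calling G and two supporting an indel (``+``).  A column
with no base support is written as ``*``.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, NamedTuple, Sequence

from .exceptions import MalformedInputError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: for each base index, the indices of the three other bases, in ACGT order
OTHER_BASES = tuple(
    tuple(j for j in range(4) if j != i) for i in range(4)
)


class PileupColumn(NamedTuple):
    chrom: str
    pos: int  # 1-based
    ref: str
    depth: int
    base_counts: tuple[int, int, int, int]  # counts for A, C, G, T
    indel_support: int = 0

    def count(self, base: str) -> int:
        return self.base_counts[BASE_INDEX[base]]

    @property
    def ref_count(self) -> int:
        return self.base_counts[BASE_INDEX[self.ref]]

    @property
    def alt_count(self) -> int:
        """Total non-reference base support."""
        return sum(self.base_counts) - self.ref_count


def check_sorted(columns: Sequence[PileupColumn]) -> None:
    """Raise if columns are not coordinate-sorted (per chromosome).

    Chromosomes must form contiguous blocks; within a block positions must be
    strictly increasing.
    """
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = 0
    for col in columns:
        if col.chrom != prev_chrom:
            if col.chrom in seen_chroms:
                raise MalformedInputError(
                    f"chromosome {col.chrom!r} appears in more than one block"
                )
            seen_chroms.add(col.chrom)
            prev_chrom = col.chrom
            prev_pos = 0
        if col.pos <= prev_pos:
            raise MalformedInputError(
                f"{col.chrom}:{col.pos} out of order (previous {prev_pos})"
            )
        prev_pos = col.pos


def _bases_string(col: PileupColumn) -> str:
    parts = [b * n for b, n in zip(BASES, col.base_counts)]
    parts.append("+" * col.indel_support)
    s = "".join(parts)
    return s if s else "*"


def write_pileup_tsv(columns: Iterable[PileupColumn], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for col in columns:
            fh.write(
                f"{col.chrom}\t{col.pos}\t{col.ref}\t{col.depth}\t{_bases_string(col)}\n"
            )


def read_pileup_tsv(path: str | os.PathLike) -> list[PileupColumn]:
    columns: list[PileupColumn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise MalformedInputError(
                    f"{path}: line {lineno}: expected 5 fields, got {len(fields)}"
                )
            chrom, pos_s, ref, depth_s, bases = fields
            counts = [0, 0, 0, 0]
            indel = 0
            if bases != "*":
                for ch in bases:
                    if ch == "+":
                        indel += 1
                    elif ch in BASE_INDEX:
                        counts[BASE_INDEX[ch]] += 1
                    else:
                        raise MalformedInputError(
                            f"{path}: line {lineno}: bad base character {ch!r}"
                        )
            columns.append(
                PileupColumn(chrom, int(pos_s), ref, int(depth_s), tuple(counts), indel)
            )
    return columns


def index_by_site(columns: Iterable[PileupColumn]) -> dict[tuple[str, int], PileupColumn]:
    """Map (chrom, pos) -> column for random access joins."""
    return {(c.chrom, c.pos): c for c in columns}


def iter_chrom_blocks(
    columns: Sequence[PileupColumn],
) -> Iterator[tuple[str, Sequence[PileupColumn]]]:
    """Yield (chrom, block) for contiguous chromosome blocks."""
    start = 0
    for i in range(1, len(columns) + 1):
        if i == len(columns) or columns[i].chrom != columns[start].chrom:
            yield columns[start].chrom, columns[start:i]
            start = i
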