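"""Variant calling from pileup columns, in the style of mpileup + calling.

Each pileup column with enough non-reference support becomes a
:class:`VariantCall` annotated with the fields the downstream filter chain
consumes: a phred-scaled quality, the column depth (``DP``), the number of
reads supporting an indel (``IDV``) and an indel flag (``INDEL``).

QUAL is defined as the phred-scaled probability of observing at least the
seen number of alternate reads if every one of them were a sequencing error:
``-10 * log10 P(X >= n_alt)`` with ``X ~ Binomial(depth, error_rate)``,
capped at ``qual_cap``.  This is not the multiallelic caller's exact model,
but it is monotone in the same quantities (more alternate reads -> higher
quality; higher assumed error -> lower quality) and fully specified, which
is what the threshold-based filters downstream require.

A maximum-likelihood diploid genotype (GT) is attached to each call for VCF
completeness; the dosage analysis deliberately never uses it — allele depth,
not genotype, is the signal of interest in polyploids.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import binom

from .exceptions import InvalidParameterError, VcfParseError
from .pileup import BASES, BASE_INDEX, PileupColumn, check_sorted

__all__ = ["VariantCall", "call_variants", "write_vcf", "read_vcf"]

DEFAULT_QUAL_CAP = 999.0


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]  # ordered by read support, descending
    qual: float
    dp: int
    idv: int = 0
    is_indel: bool = False
    gt: str = "./."


def _phred_tail(n_alt: int, depth: int, error_rate: float, cap: float) -> float:
    """-10*log10 P(X >= n_alt), X ~ Binomial(depth, error_rate), capped."""
    if n_alt <= 0:
        return 0.0
    p = binom.sf(n_alt - 1, depth, error_rate)
    if p <= 0.0:
        return cap
    return min(cap, -10.0 * math.log10(p))


def _diploid_gt(n_ref: int, n_alt: int, error_rate: float) -> str:
    """Maximum-likelihood genotype among 0/0, 0/1, 1/1 under a binomial model."""
    n = n_ref + n_alt
    if n == 0:
        return "./."
    ll = []
    for gt, p_alt in (("0/0", error_rate), ("0/1", 0.5), ("1/1", 1.0 - error_rate)):
        p_alt = min(max(p_alt, 1e-12), 1.0 - 1e-12)
        ll.append((n_alt * math.log(p_alt) + n_ref * math.log(1.0 - p_alt), gt))
    return max(ll)[1]


def call_variants(
    pileup: Sequence[PileupColumn],
    error_rate: float = 0.005,
    min_alt_reads: int = 2,
    qual_cap: float = DEFAULT_QUAL_CAP,
) -> list[VariantCall]:
    """Emit variant calls at columns with non-reference support.

    Only variant sites are emitted: a substitution call requires at least
    ``min_alt_reads`` non-reference bases in total; any indel read support
    produces a separate indel record at the same position (its evidential
    weight is judged downstream via the IDV threshold).  Multiallelic columns
    list every observed alternate base, ordered by support.
    """
    if not 0.0 < error_rate < 0.25:
        raise InvalidParameterError(
            f"error_rate must be in (0, 0.25), got {error_rate}"
        )
    if min_alt_reads < 1:
        raise InvalidParameterError("min_alt_reads must be >= 1")
    check_sorted(pileup)

    calls: list[VariantCall] = []
    for col in pileup:
        ref_i = BASE_INDEX[col.ref]
        n_ref = col.base_counts[ref_i]
        alts = [
            (cnt, b)
            for b, cnt in zip(BASES, col.base_counts)
            if b != col.ref and cnt > 0
        ]
        total_alt = sum(cnt for cnt, _ in alts)
        if total_alt >= min_alt_reads:
            # descending support; ties broken by base order for determinism
            alts.sort(key=lambda t: (-t[0], t[1]))
            calls.append(
                VariantCall(
                    chrom=col.chrom,
                    pos=col.pos,
                    ref_allele=col.ref,
                    alt_alleles=tuple(b for _, b in alts),
                    qual=_phred_tail(total_alt, col.depth, error_rate, qual_cap),
                    dp=col.depth,
                    idv=0,
                    is_indel=False,
                    gt=_diploid_gt(n_ref, alts[0][0], error_rate),
                )
            )
        if col.indel_support > 0:
            calls.append(
                VariantCall(
                    chrom=col.chrom,
                    pos=col.pos,
                    ref_allele=col.ref,
                    alt_alleles=(col.ref + "N",),
                    qual=_phred_tail(col.indel_support, col.depth, error_rate, qual_cap),
                    dp=col.depth,
                    idv=col.indel_support,
                    is_indel=True,
                    gt=_diploid_gt(
                        col.depth - col.indel_support, col.indel_support, error_rate
                    ),
                )
            )
    return calls


# --- VCF 4.2 serialization -------------------------------------------------

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    "##source=musaqc",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
    '##INFO=<ID=IDV,Number=1,Type=Integer,Description="Number of reads supporting an indel">',
    '##INFO=<ID=INDEL,Number=0,Type=Flag,Description="Indicates that the variant is an indel">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def _format_qual(q: float) -> str:
    # Python's shortest round-trip float repr, so write -> read is lossless
    if q == int(q):
        return str(int(q))
    return repr(q)


def write_vcf(calls: Iterable[VariantCall], path: str | os.PathLike) -> None:
    """Write calls as an uncompressed VCF 4.2 file (single sample)."""
    calls = list(calls)
    contigs: list[str] = []
    for c in calls:
        if c.chrom not in contigs:
            contigs.append(c.chrom)
    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for c in calls:
            info = f"DP={c.dp};IDV={c.idv}"
            if c.is_indel:
                info += ";INDEL"
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.pos),
                        ".",
                        c.ref_allele,
                        ",".join(c.alt_alleles),
                        _format_qual(c.qual),
                        ".",
                        info,
                        "GT",
                        c.gt,
                    ]
                )
                + "\n"
            )


def read_vcf(path: str | os.PathLike) -> list[VariantCall]:
    """Read a VCF written by :func:`write_vcf` (or a compatible subset).

    Raises :class:`VcfParseError` with the offending 1-based line number on
    malformed records.
    """
    calls: list[VariantCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise VcfParseError(lineno, f"expected >= 8 fields, got {len(fields)}")
            chrom, pos_s, _id, ref, alt, qual_s, _filt, info = fields[:8]
            gt = "./."
            if len(fields) >= 10:
                fmt_keys = fields[8].split(":")
                fmt_vals = fields[9].split(":")
                if "GT" in fmt_keys:
                    gt = fmt_vals[fmt_keys.index("GT")]
            try:
                pos = int(pos_s)
            except ValueError:
                raise VcfParseError(lineno, f"bad POS {pos_s!r}") from None
            try:
                qual = 0.0 if qual_s == "." else float(qual_s)
            except ValueError:
                raise VcfParseError(lineno, f"bad QUAL {qual_s!r}") from None
            dp = 0
            idv = 0
            is_indel = False
            for item in info.split(";"):
                if item == "INDEL":
                    is_indel = True
                elif "=" in item:
                    key, val = item.split("=", 1)
                    try:
                        if key == "DP":
                            dp = int(val)
                        elif key == "IDV":
                            idv = int(val)
                    except ValueError:
                        raise VcfParseError(
                            lineno, f"bad INFO value {item!r}"
                        ) from None
            if not alt or alt == ".":
                raise VcfParseError(lineno, "missing ALT allele")
            calls.append(
                VariantCall(
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_alleles=tuple(alt.split(",")),
                    qual=qual,
                    dp=dp,
                    idv=idv,
                    is_indel=is_indel,
                    gt=gt,
                )
            )
    return calls
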