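"""Filter chain and informative-SNP discovery.

The filter chain mirrors the classic bcftools recipe for cleaning candidate
SNPs before dosage analysis: discard SNPs of low quality (QUAL < 35 by
default), shallow depth (DP < 5), or lying within a gap distance (100 bp) of
a credible indel, where an indel is credible only if at least ``idv_min``
reads support it.  Indel records themselves never pass the filter.

A *diagnostic* (informative) SNP is a filtered site at which a B-genome
accession, aligned against the A reference, is apparently homozygous for the
alternate base: such sites discriminate the two subgenomes and allow
per-read subgenome attribution in hybrids.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .exceptions import ConsistencyError, MalformedInputError
from .pileup import BASE_INDEX, PileupColumn, index_by_site
from .variant_calling import VariantCall, read_vcf

__all__ = [
    "FilterConfig",
    "DiagnosticSNP",
    "filter_variants",
    "identify_informative_snps",
    "write_diagnostic_tsv",
    "read_diagnostic_tsv",
    "write_diagnostic_vcf",
    "read_diagnostic_vcf",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the SNP filter chain.

    ``snp_gap`` follows the "within N bp" convention: a SNP whose distance to
    the nearest credible indel is <= ``snp_gap`` is excluded (so the boundary
    case, exactly ``snp_gap`` away, is excluded).
    """

    qual_min: float = 35.0
    dp_min: int = 5
    idv_min: int = 2
    snp_gap: int = 100
    exclude_indels: bool = True

    def __post_init__(self) -> None:
        if min(self.qual_min, self.dp_min, self.idv_min, self.snp_gap) < 0:
            raise ValueError("all filter thresholds must be >= 0")


class DiagnosticSNP(NamedTuple):
    chrom: str
    pos: int  # 1-based
    a_allele: str  # reference (A-genome) base
    b_allele: str  # base fixed in the B genome


def _check_call_order(calls: Sequence[VariantCall]) -> None:
    seen: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = 0
    for c in calls:
        if c.chrom != prev_chrom:
            if c.chrom in seen:
                raise MalformedInputError(
                    f"chromosome {c.chrom!r} appears in more than one block"
                )
            seen.add(c.chrom)
            prev_chrom = c.chrom
            prev_pos = 0
        if c.pos < prev_pos:  # equal allowed: SNP + indel records share a position
            raise MalformedInputError(
                f"{c.chrom}:{c.pos} out of order (previous {prev_pos})"
            )
        prev_pos = c.pos


def filter_variants(
    calls: Sequence[VariantCall], cfg: FilterConfig = FilterConfig()
) -> list[VariantCall]:
    """Apply the quality / depth / indel-gap filter chain.

    Returns the SNP calls with ``qual >= qual_min``, ``dp >= dp_min`` and no
    credible indel (``idv >= idv_min``) within ``snp_gap`` bp.  The pass is
    idempotent: its output contains no indel records, so re-filtering changes
    nothing.
    """
    _check_call_order(calls)

    indel_pos: dict[str, list[int]] = {}
    for c in calls:
        if c.is_indel and c.idv >= cfg.idv_min:
            indel_pos.setdefault(c.chrom, []).append(c.pos)
    indel_arr = {chrom: np.asarray(p, dtype=np.int64) for chrom, p in indel_pos.items()}

    kept: list[VariantCall] = []
    for c in calls:
        if c.is_indel:
            if cfg.exclude_indels:
                continue
            if c.idv < cfg.idv_min or c.qual < cfg.qual_min or c.dp < cfg.dp_min:
                continue
            kept.append(c)
            continue
        if c.qual < cfg.qual_min or c.dp < cfg.dp_min:
            continue
        pos_arr = indel_arr.get(c.chrom)
        if pos_arr is not None and pos_arr.size:
            i = int(np.searchsorted(pos_arr, c.pos))
            dist = min(
                abs(c.pos - int(pos_arr[i - 1])) if i > 0 else np.iinfo(np.int64).max,
                abs(int(pos_arr[i]) - c.pos) if i < pos_arr.size else np.iinfo(np.int64).max,
            )
            if dist <= cfg.snp_gap:
                continue
        kept.append(c)
    return kept


def identify_informative_snps(
    b_calls_filtered: Sequence[VariantCall],
    b_pileup: Sequence[PileupColumn],
    hom_fraction: float = 0.9,
) -> list[DiagnosticSNP]:
    """Derive A-vs-B diagnostic SNPs from a filtered B-accession call set.

    A filtered SNP becomes diagnostic when the B accession is apparently
    homozygous for its major alternate base: the fraction of that base among
    all called bases at the site is at least ``hom_fraction``.  Sites where
    the B accession is heterozygous (segregating within B) are excluded —
    they cannot attribute reads to a subgenome.
    """
    if not 0.0 < hom_fraction <= 1.0:
        raise ValueError(f"hom_fraction must be in (0, 1], got {hom_fraction}")
    by_site = index_by_site(b_pileup)
    snps: list[DiagnosticSNP] = []
    seen: set[tuple[str, int]] = set()
    for call in b_calls_filtered:
        if call.is_indel:
            continue
        key = (call.chrom, call.pos)
        col = by_site.get(key)
        if col is None:
            raise ConsistencyError(
                f"no pileup column for filtered call at {call.chrom}:{call.pos}"
            )
        major_alt = call.alt_alleles[0]
        if major_alt not in BASE_INDEX:
            continue
        total = sum(col.base_counts)
        if total == 0:
            continue
        if col.count(major_alt) / total >= hom_fraction and key not in seen:
            seen.add(key)
            snps.append(DiagnosticSNP(call.chrom, call.pos, call.ref_allele, major_alt))
    return snps


def write_diagnostic_tsv(snps: Iterable[DiagnosticSNP], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\ta_allele\tb_allele\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.a_allele}\t{s.b_allele}\n")


def read_diagnostic_tsv(path: str | os.PathLike) -> list[DiagnosticSNP]:
    snps: list[DiagnosticSNP] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, a, b = line.rstrip("\n").split("\t")
            snps.append(DiagnosticSNP(chrom, int(pos), a, b))
    return snps


def write_diagnostic_vcf(snps: Iterable[DiagnosticSNP], path: str | os.PathLike) -> None:
    """Write diagnostic SNPs as a minimal sites-only VCF 4.2 file."""
    snps = list(snps)
    contigs: list[str] = []
    for s in snps:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=musaqc\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.a_allele}\t{s.b_allele}\t.\t.\t.\n")


def read_diagnostic_vcf(path: str | os.PathLike) -> list[DiagnosticSNP]:
    calls = read_vcf(path)
    return [
        DiagnosticSNP(c.chrom, c.pos, c.ref_allele, c.alt_alleles[0]) for c in calls
    ]
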