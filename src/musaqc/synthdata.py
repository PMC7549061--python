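"""Synthetic allopolyploid genomes, accessions and read pileups.

This module emulates the data situation of interspecific *Musa* hybrids: an
A (M. acuminata-like) reference genome, a diverged B (M. balbisiana-like)
subgenome, and polyploid accessions whose chromosome copies are drawn from
the two subgenomes (AA, AAB, ABB, BB, AAAA, ...), optionally carrying
homeologous-exchange segments where a stretch of one copy has been replaced
by the homeologous sequence from the other subgenome.  Shotgun sequencing is
emulated column-wise: per-position Poisson read depth, uniform choice of the
source chromosome copy per read, and a uniform base-miscall error.

All coordinates are 1-based; intervals are half-open ``[start, end)``,
matching the VCF position convention.

Every generated object carries its ground truth (divergent sites, per-site
B-allele dosage, indel positions), so each downstream pipeline stage can be
tested against known answers without any external data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .exceptions import InvalidParameterError
from .pileup import BASES, OTHER_BASES, PileupColumn

__all__ = [
    "TruthSite",
    "IndelSite",
    "HxSegment",
    "SubgenomePair",
    "GenotypeSpec",
    "SimulatedAccession",
    "generate_subgenomes",
    "compose_genotype",
    "simulate_pileup",
    "simulate_heterozygous_sites",
    "write_reference_fastas",
    "write_truth_sites",
    "read_truth_sites",
]

_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)


class TruthSite(NamedTuple):
    chrom: str
    pos: int  # 1-based
    a_allele: str
    b_allele: str


class IndelSite(NamedTuple):
    """A short (1-3 bp) insertion/deletion private to the B subgenome."""

    chrom: str
    pos: int  # anchor position, 1-based
    length: int
    kind: str  # "ins" or "del"


class HxSegment(NamedTuple):
    """Homeologous exchange: on ``copy_index``, the interval [start, end)
    carries sequence from ``donor`` ('A' or 'B') instead of the copy's own
    subgenome."""

    chrom: str
    start: int
    end: int
    donor: str
    copy_index: int


@dataclass(frozen=True)
class SubgenomePair:
    """A pair of homeologous subgenome references of identical coordinates.

    ``a_seqs`` and ``b_seqs`` differ exactly at ``truth_sites`` (single-base
    substitutions).  B-private indels are carried as annotations in
    ``indel_sites`` rather than applied to the sequence, which keeps the two
    subgenomes on a common coordinate system (the pipeline consumes pileups
    against the A reference, where a B indel manifests only as per-column
    indel read support).
    """

    chrom_names: tuple[str, ...]
    a_seqs: Mapping[str, str]
    b_seqs: Mapping[str, str]
    truth_sites: tuple[TruthSite, ...]
    indel_sites: tuple[IndelSite, ...] = ()

    def chrom_length(self, chrom: str) -> int:
        return len(self.a_seqs[chrom])


@dataclass(frozen=True)
class GenotypeSpec:
    """Composition of a polyploid accession, e.g. ``"AAB"``.

    ``ploidy`` is the length of the composition string.  ``hx_segments``
    describe homeologous exchanges on individual copies; segments on the same
    copy must not overlap.
    """

    composition: str
    hx_segments: tuple[HxSegment, ...] = ()

    @property
    def ploidy(self) -> int:
        return len(self.composition)

    def validate(self, pair: SubgenomePair) -> None:
        if not self.composition or set(self.composition) - {"A", "B"}:
            raise InvalidParameterError(
                f"composition must be a non-empty string over {{A,B}}, "
                f"got {self.composition!r}"
            )
        if self.ploidy not in (2, 3, 4):
            raise InvalidParameterError(
                f"ploidy must be 2, 3 or 4, got {self.ploidy}"
            )
        per_copy: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for seg in self.hx_segments:
            if seg.donor not in ("A", "B"):
                raise InvalidParameterError(f"hx donor must be A or B: {seg}")
            if not 0 <= seg.copy_index < self.ploidy:
                raise InvalidParameterError(f"hx copy_index out of range: {seg}")
            if seg.chrom not in pair.a_seqs:
                raise InvalidParameterError(f"hx chrom unknown: {seg}")
            length = pair.chrom_length(seg.chrom)
            if not (1 <= seg.start < seg.end <= length + 1):
                raise InvalidParameterError(
                    f"hx segment outside chromosome bounds (length {length}): {seg}"
                )
            per_copy.setdefault((seg.chrom, seg.copy_index), []).append(
                (seg.start, seg.end)
            )
        for key, ivals in per_copy.items():
            ivals.sort()
            for (s1, e1), (s2, _e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise InvalidParameterError(
                        f"overlapping hx segments on {key}: [{s1},{e1}) and from {s2}"
                    )


@dataclass(frozen=True)
class SimulatedAccession:
    """A polyploid accession with known truth.

    ``haplotypes[chrom][i]`` is the nucleotide string of chromosome copy
    ``i``; ``truth_b_dosage[j]`` is the fraction of copies carrying the B
    allele at ``pair.truth_sites[j]`` (always ``k/ploidy``), and
    ``indel_b_dosage[j]`` the fraction of copies carrying the B-private indel
    at ``pair.indel_sites[j]``.
    """

    spec: GenotypeSpec
    pair: SubgenomePair
    haplotypes: Mapping[str, tuple[str, ...]]
    truth_b_dosage: tuple[float, ...]
    indel_b_dosage: tuple[float, ...] = ()

    @property
    def ploidy(self) -> int:
        return self.spec.ploidy


def _seq_to_array(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 array of base indices (A=0..T=3)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(raw.shape, dtype=np.uint8)
    for i, b in enumerate(BASES):
        out[raw == ord(b)] = i
    return out


def _array_to_seq(arr: np.ndarray) -> str:
    return _BASE_ARR[arr].tobytes().decode()


def generate_subgenomes(
    seed: int,
    n_chrom: int = 3,
    chrom_length: int = 100_000,
    divergence_rate: float = 0.005,
    indel_rate: float = 0.0,
) -> SubgenomePair:
    """Generate a diverged A/B subgenome pair.

    Each position substitutes independently with probability
    ``divergence_rate`` (so the per-chromosome count of divergent sites is
    Binomial(chrom_length, divergence_rate)).  B-private indels of 1-3 bp are
    placed independently at ``indel_rate`` per bp, never on top of a
    substitution site.  The same seed and parameters reproduce the pair
    byte-for-byte.
    """
    if n_chrom < 1:
        raise InvalidParameterError(f"n_chrom must be >= 1, got {n_chrom}")
    if chrom_length < 1:
        raise InvalidParameterError(f"chrom_length must be >= 1, got {chrom_length}")
    for name, rate in (("divergence_rate", divergence_rate), ("indel_rate", indel_rate)):
        if not 0.0 <= rate <= 0.1:
            raise InvalidParameterError(f"{name} must be in [0, 0.1], got {rate}")

    rng = np.random.default_rng(seed)
    chrom_names = tuple(f"chr{i + 1:02d}" for i in range(n_chrom))
    a_seqs: dict[str, str] = {}
    b_seqs: dict[str, str] = {}
    truth_sites: list[TruthSite] = []
    indel_sites: list[IndelSite] = []

    for chrom in chrom_names:
        a = rng.integers(0, 4, size=chrom_length, dtype=np.uint8)
        b = a.copy()
        sub_pos = np.flatnonzero(rng.random(chrom_length) < divergence_rate)
        # substitute to one of the three other bases, uniformly
        b[sub_pos] = (a[sub_pos] + rng.integers(1, 4, size=sub_pos.size)) % 4
        a_seq = _array_to_seq(a)
        b_seq = _array_to_seq(b)
        a_seqs[chrom] = a_seq
        b_seqs[chrom] = b_seq
        for p in sub_pos:
            truth_sites.append(
                TruthSite(chrom, int(p) + 1, a_seq[p], b_seq[p])
            )
        if indel_rate > 0:
            sub_set = set(sub_pos.tolist())
            ind_pos = np.flatnonzero(rng.random(chrom_length) < indel_rate)
            lengths = rng.integers(1, 4, size=ind_pos.size)
            kinds = rng.integers(0, 2, size=ind_pos.size)
            for p, ln, k in zip(ind_pos, lengths, kinds):
                if int(p) in sub_set:
                    continue
                indel_sites.append(
                    IndelSite(chrom, int(p) + 1, int(ln), "ins" if k else "del")
                )

    return SubgenomePair(
        chrom_names=chrom_names,
        a_seqs=a_seqs,
        b_seqs=b_seqs,
        truth_sites=tuple(truth_sites),
        indel_sites=tuple(indel_sites),
    )


def compose_genotype(
    pair: SubgenomePair, spec: GenotypeSpec, seed: int = 0
) -> SimulatedAccession:
    """Assemble a polyploid accession from subgenome copies.

    Copy ``i`` is the A sequence where ``composition[i] == 'A'`` and the B
    sequence otherwise, with homeologous-exchange segments substituted from
    the donor subgenome.  The construction is deterministic; ``seed`` is
    accepted for interface symmetry with the stochastic generators.
    """
    del seed  # composition is deterministic
    spec.validate(pair)
    ploidy = spec.ploidy

    haplotypes: dict[str, tuple[str, ...]] = {}
    # origin[chrom][copy] = boolean array, True where the copy carries B sequence
    origins: dict[str, np.ndarray] = {}
    for chrom in pair.chrom_names:
        length = pair.chrom_length(chrom)
        origin = np.zeros((ploidy, length), dtype=bool)
        for i, c in enumerate(spec.composition):
            if c == "B":
                origin[i, :] = True
        for seg in spec.hx_segments:
            if seg.chrom != chrom:
                continue
            origin[seg.copy_index, seg.start - 1 : seg.end - 1] = seg.donor == "B"
        a_arr = _seq_to_array(pair.a_seqs[chrom])
        b_arr = _seq_to_array(pair.b_seqs[chrom])
        haps = tuple(
            _array_to_seq(np.where(origin[i], b_arr, a_arr)) for i in range(ploidy)
        )
        haplotypes[chrom] = haps
        origins[chrom] = origin

    truth_b_dosage = []
    for site in pair.truth_sites:
        haps = haplotypes[site.chrom]
        k = sum(1 for h in haps if h[site.pos - 1] == site.b_allele)
        truth_b_dosage.append(k / ploidy)
    indel_b_dosage = []
    for site in pair.indel_sites:
        origin = origins[site.chrom]
        indel_b_dosage.append(float(origin[:, site.pos - 1].mean()))

    return SimulatedAccession(
        spec=spec,
        pair=pair,
        haplotypes=haplotypes,
        truth_b_dosage=tuple(truth_b_dosage),
        indel_b_dosage=tuple(indel_b_dosage),
    )


def _validate_read_params(mean_depth: float, error_rate: float) -> None:
    if not mean_depth > 0:
        raise InvalidParameterError(f"mean_depth must be > 0, got {mean_depth}")
    if not 0.0 <= error_rate < 0.25:
        raise InvalidParameterError(
            f"error_rate must be in [0, 0.25), got {error_rate}"
        )


def _spread_errors(
    rng: np.random.Generator,
    counts: np.ndarray,
    n_true: np.ndarray,
    true_idx: np.ndarray,
    rows: np.ndarray,
    error_rate: float,
) -> None:
    """Add ``n_true`` reads of base ``true_idx`` to ``counts`` rows, miscalling
    each read to a uniformly chosen other base with probability ``error_rate``."""
    if error_rate > 0:
        errs = rng.binomial(n_true, error_rate)
        e1 = rng.binomial(errs, 1.0 / 3.0)
        rest = errs - e1
        e2 = rng.binomial(rest, 0.5)
        e3 = rest - e2
    else:
        errs = np.zeros_like(n_true)
        e1 = e2 = e3 = errs
    others = np.asarray(OTHER_BASES, dtype=np.intp)[true_idx]  # (n, 3)
    np.add.at(counts, (rows, true_idx), n_true - errs)
    np.add.at(counts, (rows, others[:, 0]), e1)
    np.add.at(counts, (rows, others[:, 1]), e2)
    np.add.at(counts, (rows, others[:, 2]), e3)


def simulate_pileup(
    acc: SimulatedAccession,
    mean_depth: float = 30.0,
    error_rate: float = 0.005,
    seed: int = 0,
    positions: Mapping[str, Sequence[int]] | None = None,
) -> list[PileupColumn]:
    """Simulate per-position read pileups against the A reference.

    Depth is Poisson(``mean_depth``) per position; each read draws its source
    chromosome copy uniformly, takes that copy's base, and is miscalled to a
    uniformly chosen other base with probability ``error_rate``.  At B-private
    indel sites, reads drawn from B-origin copies additionally support the
    indel.  Columns are emitted in coordinate order.

    ``positions`` optionally restricts simulation to the given 1-based
    positions per chromosome (e.g. the diagnostic-SNP sites of a target
    accession); each listed position must be sorted ascending.
    """
    _validate_read_params(mean_depth, error_rate)
    rng = np.random.default_rng(seed)
    pair = acc.pair

    # per-chromosome truth lookups
    truth_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in pair.chrom_names:
        idx = [
            j for j, s in enumerate(pair.truth_sites) if s.chrom == chrom
        ]
        pos = np.array([pair.truth_sites[j].pos for j in idx], dtype=np.int64)
        dos = np.array([acc.truth_b_dosage[j] for j in idx])
        balle = np.array(
            [BASES.index(pair.truth_sites[j].b_allele) for j in idx], dtype=np.intp
        )
        truth_by_chrom[chrom] = (pos, dos, balle)
    indel_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in pair.chrom_names:
        idx = [j for j, s in enumerate(pair.indel_sites) if s.chrom == chrom]
        pos = np.array([pair.indel_sites[j].pos for j in idx], dtype=np.int64)
        dos = np.array([acc.indel_b_dosage[j] for j in idx])
        indel_by_chrom[chrom] = (pos, dos)

    columns: list[PileupColumn] = []
    for chrom in pair.chrom_names:
        a_idx = _seq_to_array(pair.a_seqs[chrom])
        length = len(a_idx)
        if positions is None:
            pos_arr = np.arange(1, length + 1, dtype=np.int64)
        else:
            pos_arr = np.asarray(positions.get(chrom, ()), dtype=np.int64)
            if pos_arr.size == 0:
                continue
        n = pos_arr.size
        depth = rng.poisson(mean_depth, size=n)

        dosage = np.zeros(n)
        b_base = a_idx[pos_arr - 1].astype(np.intp)  # placeholder, ref where no truth
        t_pos, t_dos, t_ball = truth_by_chrom[chrom]
        if t_pos.size:
            loc = np.searchsorted(pos_arr, t_pos)
            hit = (loc < n) & (pos_arr[np.minimum(loc, n - 1)] == t_pos)
            dosage[loc[hit]] = t_dos[hit]
            b_base[loc[hit]] = t_ball[hit]

        n_b = rng.binomial(depth, dosage)
        n_a = depth - n_b

        counts = np.zeros((n, 4), dtype=np.int64)
        rows = np.arange(n, dtype=np.intp)
        ref_idx = a_idx[pos_arr - 1].astype(np.intp)
        _spread_errors(rng, counts, n_a, ref_idx, rows, error_rate)
        het = np.flatnonzero(n_b > 0)
        if het.size:
            _spread_errors(
                rng, counts, n_b[het], b_base[het], rows[het], error_rate
            )

        indel_support = np.zeros(n, dtype=np.int64)
        i_pos, i_dos = indel_by_chrom[chrom]
        if i_pos.size:
            loc = np.searchsorted(pos_arr, i_pos)
            hit = (loc < n) & (pos_arr[np.minimum(loc, n - 1)] == i_pos)
            loc, dos = loc[hit], i_dos[hit]
            indel_support[loc] = rng.binomial(depth[loc], dos)

        ref_bases = [BASES[i] for i in ref_idx]
        counts_t = counts
        for i in range(n):
            columns.append(
                PileupColumn(
                    chrom,
                    int(pos_arr[i]),
                    ref_bases[i],
                    int(depth[i]),
                    (
                        int(counts_t[i, 0]),
                        int(counts_t[i, 1]),
                        int(counts_t[i, 2]),
                        int(counts_t[i, 3]),
                    ),
                    int(indel_support[i]),
                )
            )
    return columns


def simulate_heterozygous_sites(
    ploidy: int,
    n_sites: int,
    depth: int = 30,
    error_rate: float = 0.0,
    seed: int = 0,
    chrom: str = "sim1",
) -> tuple[list[PileupColumn], np.ndarray]:
    """Simulate pileup columns at heterozygous sites of a known ploidy.

    Each site carries the alternate allele on ``k`` of ``ploidy`` copies with
    ``k`` uniform on ``1..ploidy-1`` (the dosage classes a ploidy-``p``
    heterozygous site can take); read support is Binomial(``depth``, k/p) for
    the alternate allele, with the usual uniform miscall error.  Depth is held
    fixed so the allele-frequency signal is not confounded by coverage
    variation.  Returns the columns and the true per-site dosages.
    """
    if ploidy not in (2, 3, 4):
        raise InvalidParameterError(f"ploidy must be 2, 3 or 4, got {ploidy}")
    if n_sites < 1 or depth < 1:
        raise InvalidParameterError("n_sites and depth must be >= 1")
    _validate_read_params(depth, error_rate)
    rng = np.random.default_rng(seed)

    k = rng.integers(1, ploidy, size=n_sites)
    dosage = k / ploidy
    ref_idx = rng.integers(0, 4, size=n_sites).astype(np.intp)
    alt_idx = ((ref_idx + rng.integers(1, 4, size=n_sites)) % 4).astype(np.intp)
    depth_arr = np.full(n_sites, depth, dtype=np.int64)
    n_alt = rng.binomial(depth_arr, dosage)
    n_ref = depth_arr - n_alt

    counts = np.zeros((n_sites, 4), dtype=np.int64)
    rows = np.arange(n_sites, dtype=np.intp)
    _spread_errors(rng, counts, n_ref, ref_idx, rows, error_rate)
    _spread_errors(rng, counts, n_alt, alt_idx, rows, error_rate)

    columns = [
        PileupColumn(
            chrom,
            (i + 1) * 100,
            BASES[ref_idx[i]],
            int(depth_arr[i]),
            tuple(int(c) for c in counts[i]),
            0,
        )
        for i in range(n_sites)
    ]
    return columns, dosage


def write_reference_fastas(
    pair: SubgenomePair, a_path: str | os.PathLike, b_path: str | os.PathLike
) -> None:
    """Write the two subgenome references as multi-FASTA files."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    for path, seqs, label in ((a_path, pair.a_seqs, "A"), (b_path, pair.b_seqs, "B")):
        records = [
            SeqRecord(Seq(seqs[c]), id=c, description=f"subgenome {label}")
            for c in pair.chrom_names
        ]
        SeqIO.write(records, str(path), "fasta")


def write_truth_sites(pair: SubgenomePair, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\ta_allele\tb_allele\n")
        for s in pair.truth_sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.a_allele}\t{s.b_allele}\n")


def read_truth_sites(path: str | os.PathLike) -> list[TruthSite]:
    sites: list[TruthSite] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, pos, a, b = line.rstrip("\n").split("\t")
            sites.append(TruthSite(chrom, int(pos), a, b))
    return sites
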