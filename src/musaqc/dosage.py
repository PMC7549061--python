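"""B-allele dosage quantification, LOESS smoothing and genome painting.

At every diagnostic SNP with adequate depth, the percent of reads carrying
the B allele estimates the local B-subgenome dosage: a site present on k of
p chromosome copies is expected near ``100*k/p`` percent.  Smoothing those
per-site percentages along each chromosome with LOESS (locally weighted
polynomial regression, tricube weights) yields a dosage curve whose level
shifts mark homeologous-exchange segments, and classifying the curve into
three bands — A-like (< 33%), mixed (33-66%) and B-like (>= 66%) — paints
the genome by subgenome content.  Tracks serialise to the plain-text
``chrom start end value`` format circular genome plotters consume.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .diagnostic_snps import DiagnosticSNP
from .pileup import BASE_INDEX, PileupColumn, index_by_site

logger = logging.getLogger(__name__)

__all__ = [
    "DosagePoint",
    "DosageTrack",
    "quantify_b_fraction",
    "loess_smooth",
    "classify_track",
    "build_track",
    "build_tracks",
    "class_runs",
    "write_circos_track",
    "read_circos_track",
    "genome_median_pct_b",
]

CLASS_BOUNDS = (33.0, 66.0)  # percent; painting band edges
CLASS_NAMES = ("A_like", "mixed", "B_like")


class DosagePoint(NamedTuple):
    chrom: str
    pos: int
    depth: int
    b_count: int
    a_count: int
    pct_b: float


def quantify_b_fraction(
    target_pileup: Sequence[PileupColumn],
    snps: Sequence[DiagnosticSNP],
    depth_min: int = 10,
    depth_max: int = 50,
) -> list[DosagePoint]:
    """Percent-B read support at each diagnostic SNP of adequate depth.

    Only sites whose column depth lies in the inclusive window
    ``[depth_min, depth_max]`` are instantiated.  Reads supporting bases
    other than the two diagnostic alleles are excluded from both numerator
    and denominator.  Diagnostic sites without a pileup column are skipped
    (their count is logged), never an error — a target accession can simply
    lack coverage.
    """
    by_site = index_by_site(target_pileup)
    points: list[DosagePoint] = []
    n_missing = 0
    n_uninformative = 0
    for snp in snps:
        col = by_site.get((snp.chrom, snp.pos))
        if col is None:
            n_missing += 1
            continue
        if not depth_min <= col.depth <= depth_max:
            continue
        a = col.base_counts[BASE_INDEX[snp.a_allele]]
        b = col.base_counts[BASE_INDEX[snp.b_allele]]
        if a + b == 0:
            n_uninformative += 1
            continue
        points.append(
            DosagePoint(snp.chrom, snp.pos, col.depth, b, a, 100.0 * b / (a + b))
        )
    if n_missing:
        logger.info("quantify_b_fraction: %d diagnostic sites had no pileup column", n_missing)
    if n_uninformative:
        logger.info(
            "quantify_b_fraction: %d sites had no reads on either diagnostic allele",
            n_uninformative,
        )
    return points


def loess_smooth(
    positions: Sequence[int] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    span: float = 0.5,
    degree: int = 2,
    weights: Sequence[float] | np.ndarray | None = None,
) -> np.ndarray:
    """LOESS: locally weighted polynomial regression along a chromosome.

    For each point, the nearest ``ceil(span * n)`` neighbours (by position)
    are fitted with a degree-``degree`` polynomial under tricube distance
    weights, and the fit is evaluated at the point.  ``weights`` optionally
    multiplies the tricube weights (e.g. by read depth).  Output is clamped
    to [0, 100].  A single-point input is returned unchanged with a warning.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if degree < 0:
        raise ValueError(f"degree must be >= 0, got {degree}")
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("positions and values must be 1-D and the same length")
    n = x.size
    if n == 0:
        return np.empty(0)
    if n == 1:
        warnings.warn("loess_smooth: single-point input returned unchanged")
        return np.clip(y.copy(), 0.0, 100.0)
    w_extra = None if weights is None else np.asarray(weights, dtype=float)

    k = max(degree + 1, int(math.ceil(span * n)))
    k = min(k, n)
    out = np.empty(n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ws = None if w_extra is None else w_extra[order]
    for j in range(n):
        x0 = xs[j]
        d = np.abs(xs - x0)
        if k < n:
            idx = np.argpartition(d, k - 1)[:k]
        else:
            idx = np.arange(n)
        dmax = d[idx].max()
        if dmax == 0:
            w = np.ones(idx.size)
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        if ws is not None:
            w = w * ws[idx]
        wsum = w.sum()
        if wsum <= 0:
            w = np.ones(idx.size)
            wsum = w.sum()
        scale = dmax if dmax > 0 else 1.0
        t = (xs[idx] - x0) / scale
        # degree is limited by the number of points carrying weight, else the
        # local design matrix is rank-deficient
        n_support = int(np.count_nonzero(w))
        deg = min(degree, idx.size - 1, n_support - 1)
        if deg <= 0:
            out[j] = float(np.sum(w * ys[idx]) / wsum)
        else:
            # np.polyfit weights multiply residuals linearly, so pass sqrt(w)
            coeffs = np.polyfit(t, ys[idx], deg, w=np.sqrt(w))
            out[j] = float(coeffs[-1])  # polynomial evaluated at t = 0
    result = np.empty(n)
    result[order] = out
    return np.clip(result, 0.0, 100.0)


def classify_track(
    smoothed: Sequence[float] | np.ndarray,
    bounds: tuple[float, float] = CLASS_BOUNDS,
) -> list[str]:
    """Three-band painting of smoothed percent-B values.

    ``A_like`` below ``bounds[0]``, ``mixed`` in ``[bounds[0], bounds[1])``,
    ``B_like`` at or above ``bounds[1]`` (half-open band convention).
    """
    low, high = bounds
    if not 0.0 < low < high < 100.0:
        raise ValueError(f"require 0 < low < high < 100, got {bounds}")
    labels = []
    for v in np.asarray(smoothed, dtype=float):
        if v < low:
            labels.append("A_like")
        elif v < high:
            labels.append("mixed")
        else:
            labels.append("B_like")
    return labels


@dataclass(frozen=True)
class DosageTrack:
    """Per-chromosome dosage curve: raw points, smoothed values, paint classes."""

    chrom: str
    points: tuple[DosagePoint, ...]
    smoothed: np.ndarray
    classes: tuple[str, ...]
    span: float
    degree: int
    bounds: tuple[float, float]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.pos for p in self.points], dtype=np.int64)

    def plot(self, ax=None):
        """Simple per-chromosome line plot (raw points + smoothed curve)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 2.5))
        pos = self.positions
        ax.plot(pos, [p.pct_b for p in self.points], ".", ms=2, alpha=0.4, label="% B")
        ax.plot(pos, self.smoothed, "-", lw=1.5, label="LOESS")
        for bound in self.bounds:
            ax.axhline(bound, color="grey", lw=0.5, ls=":")
        ax.set_ylim(-2, 102)
        ax.set_xlabel(f"{self.chrom} position (bp)")
        ax.set_ylabel("% B allele")
        ax.legend(loc="upper right", fontsize="small")
        return ax


def build_track(
    points: Sequence[DosagePoint],
    span: float = 0.5,
    degree: int = 2,
    bounds: tuple[float, float] = CLASS_BOUNDS,
    weight_by_depth: bool = False,
) -> DosageTrack:
    """Smooth and classify the dosage points of one chromosome."""
    chroms = {p.chrom for p in points}
    if len(chroms) != 1:
        raise ValueError(f"build_track expects a single chromosome, got {sorted(chroms)}")
    pts = tuple(sorted(points, key=lambda p: p.pos))
    weights = [p.depth for p in pts] if weight_by_depth else None
    smoothed = loess_smooth(
        [p.pos for p in pts], [p.pct_b for p in pts], span, degree, weights
    )
    classes = tuple(classify_track(smoothed, bounds))
    return DosageTrack(pts[0].chrom, pts, smoothed, classes, span, degree, bounds)


def build_tracks(
    points: Sequence[DosagePoint],
    span: float = 0.5,
    degree: int = 2,
    bounds: tuple[float, float] = CLASS_BOUNDS,
    weight_by_depth: bool = False,
) -> dict[str, DosageTrack]:
    """Smooth per chromosome; returns chrom -> track."""
    by_chrom: dict[str, list[DosagePoint]] = {}
    for p in points:
        by_chrom.setdefault(p.chrom, []).append(p)
    return {
        chrom: build_track(pts, span, degree, bounds, weight_by_depth)
        for chrom, pts in by_chrom.items()
    }


def class_runs(track: DosageTrack) -> list[tuple[str, int, int]]:
    """Maximal runs of identical paint class as (label, start_pos, end_pos)."""
    runs: list[tuple[str, int, int]] = []
    for point, label in zip(track.points, track.classes):
        if runs and runs[-1][0] == label:
            runs[-1] = (label, runs[-1][1], point.pos)
        else:
            runs.append((label, point.pos, point.pos))
    return runs


_CLASS_COLOURS = {"A_like": "green", "mixed": "grey", "B_like": "red"}


def write_circos_track(
    track: DosageTrack,
    path: str | os.PathLike,
    highlights_path: str | os.PathLike | None = None,
) -> None:
    """Write the smoothed curve as Circos 2D data (``chrom start end value``).

    Optionally writes a companion highlight file with one interval per paint
    run, coloured by class.
    """
    with open(path, "w") as fh:
        for point, value in zip(track.points, track.smoothed):
            fh.write(f"{track.chrom} {point.pos} {point.pos} {value:.4f}\n")
    if highlights_path is not None:
        with open(highlights_path, "w") as fh:
            for label, start, end in class_runs(track):
                fh.write(
                    f"{track.chrom} {start} {end} fill_color={_CLASS_COLOURS[label]}\n"
                )


def read_circos_track(path: str | os.PathLike) -> list[tuple[str, int, int, float]]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, value = line.split()
            records.append((chrom, int(start), int(end), float(value)))
    return records


def genome_median_pct_b(tracks: Iterable[DosageTrack]) -> float:
    """Genome-wide median of the smoothed percent-B values."""
    values = np.concatenate([t.smoothed for t in tracks if t.smoothed.size])
    if values.size == 0:
        raise ValueError("no smoothed dosage values to summarise")
    return float(np.median(values))
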