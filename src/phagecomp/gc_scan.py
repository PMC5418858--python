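"""Window-based GC profiling, composition summaries, and intergenic regions.

Windows tile the genome without overlap by default (a configurable step
enables sliding mode); ``N`` bases are excluded from both numerator and
denominator of every GC fraction. All coordinates are 0-based half-open
and never wrap, regardless of genome topology.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .genome_model import GeneFeature, GenomeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GCWindow:
    start: int
    end: int
    gc_fraction: float | None  # None when the window is all N
    partial: bool = False


@dataclass(frozen=True)
class WindowProfile:
    genome_id: str
    window: int
    step: int
    values: tuple[GCWindow, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.genome_id, w.start, w.end, w.gc_fraction, w.partial) for w in self.values],
            columns=["genome_id", "start", "end", "gc_fraction", "partial"],
        )


@dataclass(frozen=True)
class RegionComposition:
    """Base composition of a genomic interval (fractions over non-N bases)."""

    genome_id: str
    start: int
    end: int
    fractions: dict[str, float]  # keys A, C, G, T
    gc_fraction: float | None
    n_count: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start


def _gc_of(seq: str) -> tuple[float | None, int]:
    """(GC fraction over non-N bases or None if all-N, count of N)."""
    n = seq.count("N")
    denom = len(seq) - n
    if denom == 0:
        return None, n
    gc = seq.count("G") + seq.count("C")
    return gc / denom, n


def gc_windows(genome: GenomeRecord, window: int = 100, step: int | None = None) -> WindowProfile:
    """GC fraction in fixed-size windows along the genome.

    A trailing partial window is included and flagged. If *window*
    exceeds the genome length, a single whole-genome window is returned
    with a warning.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    if step is None:
        step = window
    if step < 1:
        raise ValidationError("step must be >= 1")
    L = genome.length
    if window > L:
        logger.warning(
            "genome %s: window %d exceeds length %d; single whole-genome window",
            genome.genome_id, window, L,
        )
        gc, _ = _gc_of(genome.sequence)
        return WindowProfile(
            genome.genome_id, window, step, (GCWindow(0, L, gc, partial=True),)
        )
    values = []
    for start in range(0, L, step):
        end = min(start + window, L)
        gc, _ = _gc_of(genome.sequence[start:end])
        values.append(GCWindow(start, end, gc, partial=(end - start) < window))
        if end == L:
            break
    return WindowProfile(genome.genome_id, window, step, tuple(values))


def base_composition(
    genome: GenomeRecord, start: int = 0, end: int | None = None
) -> RegionComposition:
    """Per-base fractions (over non-N positions) and GC fraction of a region."""
    if end is None:
        end = genome.length
    if not (0 <= start < end <= genome.length):
        raise ValidationError(
            f"region [{start},{end}) out of bounds for genome of length {genome.length}"
        )
    seq = genome.sequence[start:end]
    n = seq.count("N")
    denom = len(seq) - n
    if denom == 0:
        return RegionComposition(genome.genome_id, start, end, {}, None, n_count=n)
    fractions = {b: seq.count(b) / denom for b in "ACGT"}
    return RegionComposition(
        genome.genome_id, start, end, fractions,
        fractions["G"] + fractions["C"], n_count=n,
    )


def intergenic_regions(
    genome: GenomeRecord,
    features: Iterable[GeneFeature],
    min_len: int = 200,
) -> list[RegionComposition]:
    """Maximal gaps between annotated genes, with composition per gap.

    Gene intervals of every kind are unioned and complemented within
    [0, length); gaps shorter than *min_len* are dropped. Each region's
    composition can be compared to the whole genome via
    :func:`composition_deviation`.
    """
    intervals = sorted((f.start, f.end) for f in features)
    merged: list[list[int]] = []
    for s, e in intervals:
        s, e = max(0, s), min(genome.length, e)
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps: list[tuple[int, int]] = []
    prev = 0
    for s, e in merged:
        if s - prev >= min_len:
            gaps.append((prev, s))
        prev = max(prev, e)
    if genome.length - prev >= min_len:
        gaps.append((prev, genome.length))
    return [base_composition(genome, s, e) for s, e in gaps]


def composition_deviation(
    region: RegionComposition, whole: RegionComposition
) -> dict[str, float]:
    """Per-base fraction differences (region minus whole genome)."""
    return {
        b: region.fractions.get(b, math.nan) - whole.fractions.get(b, math.nan)
        for b in "ACGT"
    }


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    length: int
    gc_percent: int  # integer-rounded for report parity
    gc_fraction: float | None
    n_cds: int
    n_trna: int


def genome_summary(genome: GenomeRecord, features: Iterable[GeneFeature]) -> GenomeSummary:
    """Length, integer GC%, CDS count, and tRNA count of one genome."""
    comp = base_composition(genome)
    feats = list(features)
    gc = comp.gc_fraction
    return GenomeSummary(
        genome_id=genome.genome_id,
        length=genome.length,
        gc_percent=round(gc * 100) if gc is not None else 0,
        gc_fraction=gc,
        n_cds=sum(1 for f in feats if f.kind == "CDS"),
        n_trna=sum(1 for f in feats if f.kind == "tRNA"),
    )


def summary_frame(summaries: Sequence[GenomeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.genome_id, s.length, s.gc_percent, s.n_cds, s.n_trna)
            for s in summaries
        ],
        columns=["genome_id", "length_bp", "gc_percent", "n_genes", "n_trna"],
    )


def regions_frame(regions: Sequence[RegionComposition]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "start": r.start,
                "end": r.end,
                "length": r.length,
                "gc_fraction": r.gc_fraction,
                **{f"frac_{b}": r.fractions.get(b) for b in "ACGT"},
            }
            for r in regions
        ]
    )
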