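"""Permutation test for overlap between hotspot regions and annotations.

Observed overlap between query regions (hotspots) and an annotation set
is compared with the overlap obtained after re-placing the annotation
intervals uniformly at random in the allowed genomic space (length- and
strand-matched, mutually non-overlapping, excluded intervals avoided).
A qualifying overlap must cover at least ``min_fraction`` (default 50%)
of one declared side: the annotation side for compact features such as
protein binding sites, or the query side for broad regions such as
essential/nonessential territory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import GenomeLayout

__all__ = [
    "GenomicInterval",
    "AnnotationSet",
    "OverlapRule",
    "EnrichmentResult",
    "count_overlaps",
    "permute_annotations",
    "permutation_enrichment",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AnnotationSet:
    name: str
    intervals: tuple[GenomicInterval, ...]
    strand_aware: bool = False

    def __post_init__(self):
        object.__setattr__(self, "intervals", tuple(self.intervals))


@dataclass(frozen=True)
class OverlapRule:
    """Which side must be >=50% covered for an overlap to count."""

    covered_side: str = "annotation"     # "annotation" or "query"
    min_fraction: float = 0.5

    def __post_init__(self):
        if self.covered_side not in ("annotation", "query"):
            raise ValueError("covered_side must be 'annotation' or 'query'")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    annotation_name: str
    observed: int
    expected_mean: float
    expected_sd: float
    log2_fold_change: float          # nan when expected_mean == 0
    fold_undefined: bool
    empirical_p: float
    p_corrected: float               # (r+1)/(n+1)
    direction: str                   # "enrichment" or "depletion"
    n_permutations: int
    p_bonferroni: float


def count_overlaps(queries: Sequence[GenomicInterval],
                   annotations: Sequence[GenomicInterval],
                   rule: OverlapRule | None = None,
                   strand_aware: bool = False) -> int:
    """Number of queries with at least one qualifying annotation overlap."""
    rule = rule or OverlapRule()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for a in annotations:
        by_chrom.setdefault(a.chrom, []).append(a)
    n = 0
    for q in queries:
        for a in by_chrom.get(q.chrom, ()):
            if strand_aware and q.strand != a.strand:
                continue
            ov = min(q.end, a.end) - max(q.start, a.start)
            if ov <= 0:
                continue
            denom = a.length if rule.covered_side == "annotation" else q.length
            if denom > 0 and ov / denom >= rule.min_fraction:
                n += 1
                break
    return n


class PlacementError(RuntimeError):
    """No remaining slot can hold an interval; relax the exclusions."""


class _FreeSpace:
    """Per-chromosome free gaps supporting uniform non-overlapping placement."""

    def __init__(self, layout: GenomeLayout,
                 exclusions: Sequence[GenomicInterval]):
        self.gaps: list[tuple[str, int, int]] = []
        excl: dict[str, list[tuple[int, int]]] = {}
        for x in exclusions:
            excl.setdefault(x.chrom, []).append((x.start, x.end))
        for lay in layout:
            segs = [(0, lay.length)]
            for s, e in sorted(excl.get(lay.name, [])):
                nxt = []
                for a, b in segs:
                    if s < b and e > a:
                        if a < s:
                            nxt.append((a, s))
                        if e < b:
                            nxt.append((e, b))
                    else:
                        nxt.append((a, b))
                segs = nxt
            self.gaps.extend((lay.name, a, b) for a, b in segs if b > a)

    def place(self, length: int, rng: np.random.Generator) -> tuple[str, int]:
        """Pick a start uniformly over all valid non-overlapping slots."""
        slots = np.array([max(0, (e - s) - length + 1)
                          for _, s, e in self.gaps], dtype=np.int64)
        total = int(slots.sum())
        if total == 0:
            raise PlacementError(
                f"no free slot of {length} bp left; relax the exclusions or "
                f"reduce annotation density")
        gi = int(rng.choice(len(self.gaps), p=slots / total))
        chrom, s, e = self.gaps[gi]
        start = int(s + rng.integers(0, slots[gi]))
        # split the gap around the placed interval
        self.gaps.pop(gi)
        if start > s:
            self.gaps.append((chrom, s, start))
        if start + length < e:
            self.gaps.append((chrom, start + length, e))
        return chrom, start


def permute_annotations(annotations: Sequence[GenomicInterval],
                        layout: GenomeLayout,
                        exclusions: Sequence[GenomicInterval] = (),
                        seed: int | np.random.Generator = 0,
                        per_chromosome: bool = False
                        ) -> list[GenomicInterval]:
    """Re-place each interval uniformly in allowed space (length/strand kept).

    Placement is genome-wide by default (a start is drawn uniformly over
    every currently valid position on any chromosome, so chromosomes are
    weighted by their free space); ``per_chromosome=True`` restricts each
    interval to its source chromosome for sensitivity analysis.  Placed
    intervals never overlap each other or the exclusions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if per_chromosome:
        out: list[GenomicInterval] = []
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for a in annotations:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom, annos in by_chrom.items():
            sub = GenomeLayout([layout[chrom]])
            space = _FreeSpace(sub, [x for x in exclusions if x.chrom == chrom])
            for a in annos:
                c, start = space.place(a.length, rng)
                out.append(GenomicInterval(c, start, start + a.length, a.strand))
        return out
    space = _FreeSpace(layout, exclusions)
    out = []
    for a in annotations:
        chrom, start = space.place(a.length, rng)
        out.append(GenomicInterval(chrom, start, start + a.length, a.strand))
    return out


def permutation_enrichment(queries: Sequence[GenomicInterval],
                           annotations: AnnotationSet,
                           layout: GenomeLayout,
                           rule: OverlapRule | None = None,
                           n_perm: int = 1000,
                           exclusions: Sequence[GenomicInterval] = (),
                           seed: int = 0,
                           n_tests: int = 1,
                           per_chromosome: bool = False) -> EnrichmentResult:
    """Observed versus permuted overlap with a one-sided empirical p.

    The p-value is one-sided in the direction of the observed effect
    (fraction of permutations with overlap >= observed for enrichment,
    <= observed for depletion); ``n_tests`` supplies the Bonferroni
    multiplier when several annotation sets are tested in one run.
    """
    if not queries:
        raise ValueError("no query regions supplied")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rule = rule or OverlapRule()
    observed = count_overlaps(queries, annotations.intervals, rule,
                              annotations.strand_aware)
    rng = np.random.default_rng(seed)
    dist = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        perm = permute_annotations(annotations.intervals, layout, exclusions,
                                   rng, per_chromosome=per_chromosome)
        dist[i] = count_overlaps(queries, perm, rule, annotations.strand_aware)
    mean = float(dist.mean())
    sd = float(dist.std(ddof=1)) if n_perm > 1 else 0.0
    if observed >= mean:
        r = int((dist >= observed).sum())
        direction = "enrichment"
    else:
        r = int((dist <= observed).sum())
        direction = "depletion"
    undefined = mean == 0
    if undefined:
        log2fc = math.nan
    elif observed == 0:
        log2fc = -math.inf
    else:
        log2fc = math.log2(observed / mean)
    p = r / n_perm
    return EnrichmentResult(
        annotation_name=annotations.name, observed=observed,
        expected_mean=mean, expected_sd=sd, log2_fold_change=log2fc,
        fold_undefined=undefined, empirical_p=p,
        p_corrected=(r + 1) / (n_perm + 1), direction=direction,
        n_permutations=n_perm, p_bonferroni=min(1.0, p * n_tests))
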