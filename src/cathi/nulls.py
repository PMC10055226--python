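"""Null models: shuffled genomes, GCR-placement Monte Carlo, strand-switch test.

Three independent chance models used to interpret hotspot maps:

* composition-preserving shuffle — each chromosome's nucleotides are
  permuted within its adjusted bounds, keeping length and base
  composition while destroying sequence structure; rescanning shuffled
  genomes gives the expected score spectrum under the null;
* GCR placement model — given n repair events placed uniformly in a
  recoverable region, the Monte-Carlo (and exact binomial) probability
  that k or more land inside a fixed test window; used to set the
  activity threshold for calling a sequence a hotspot;
* strand-switch model — whether hotspots on a chromosome alternate
  between strands more or less often than random, assessed by permuting
  strand labels within each chromosome while preserving per-strand
  counts.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeLayout, SiRTARecord

__all__ = [
    "GCRModelParams",
    "GCRTailResult",
    "StrandRunStats",
    "NullSummary",
    "shuffle_genome",
    "shuffle_replicates",
    "score_spectrum",
    "gcr_event_model",
    "strand_switch_observed",
    "strand_switch_null",
]


def _adjusted_sequence(seq: str, lay) -> str:
    """Analysis-bounds sequence with subtelomeric intervals excised."""
    segments = [(lay.analysis_start, lay.analysis_end)]
    for s, e in sorted(lay.subtelomeres):
        nxt = []
        for a, b in segments:
            if s < b and e > a:
                if a < s:
                    nxt.append((a, s))
                if e < b:
                    nxt.append((e, b))
            else:
                nxt.append((a, b))
        segments = nxt
    return "".join(seq[a:b] for a, b in segments)


def shuffle_genome(genome: Mapping[str, str], layout: GenomeLayout | None = None,
                   seed: int | np.random.Generator = 0) -> dict[str, str]:
    """Permute nucleotides within each (adjusted) chromosome.

    The output chromosome is an exact permutation of the input's
    adjusted sequence: identical length and base multiset.  Deterministic
    for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for chrom, seq in genome.items():
        s = _adjusted_sequence(seq, layout[chrom]) if layout else seq
        arr = np.frombuffer(s.encode("ascii"), dtype="S1")
        out[chrom] = b"".join(rng.permutation(arr)).decode("ascii")
    return out


def shuffle_replicates(genome: Mapping[str, str], layout: GenomeLayout | None,
                       master_seed: int, n_replicates: int = 5
                       ) -> list[dict[str, str]]:
    """Independent shuffled genomes with seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [shuffle_genome(genome, layout, np.random.default_rng(child))
            for child in ss.spawn(n_replicates)]


def score_spectrum(records: Sequence[SiRTARecord]) -> dict[int, int]:
    """Counts of regions binned by score rounded down to the nearest integer."""
    return dict(sorted(Counter(math.floor(r.score) for r in records).items()))


# ---------------------------------------------------------------------------
# GCR placement model

@dataclass(frozen=True)
class GCRModelParams:
    """Uniform placement of repair events within a recoverable region.

    Defaults reflect a 300-bp test insert inside the 21,922-bp interval
    between an induced break and the first essential gene, with 30
    recovered events per experiment.
    """

    n_events: int = 30
    target_len: int = 300
    region_len: int = 21_922
    iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_len <= self.region_len):
            raise ValueError("need 0 < target_len <= region_len")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class GCRTailResult:
    """Tail probabilities P(X >= k) for k = 1..n_events."""

    k: np.ndarray
    p_empirical: np.ndarray
    p_exact: np.ndarray          # binomial oracle
    params: GCRModelParams

    def empirical(self, k: int) -> float:
        return float(self.p_empirical[k - 1])

    def exact(self, k: int) -> float:
        return float(self.p_exact[k - 1])


def gcr_event_model(params: GCRModelParams) -> GCRTailResult:
    """Monte-Carlo tail of events falling inside a fixed target window.

    Each trial drops ``n_events`` points uniformly on [0, region_len) and
    counts those inside a fixed window of ``target_len``.  The exact
    Binomial(n_events, target_len/region_len) tail is returned alongside
    as an analytic cross-check.
    """
    p = params.target_len / params.region_len
    n = params.n_events
    ks = np.arange(1, max(n, 1) + 1)
    if n == 0:
        zero = np.zeros(1)
        return GCRTailResult(np.array([1]), zero, zero, params)
    rng = np.random.default_rng(params.seed)
    counts = np.zeros(params.iterations, dtype=np.int64)
    # chunked so huge iteration counts stay within memory
    chunk = 200_000
    done = 0
    while done < params.iterations:
        m = min(chunk, params.iterations - done)
        pos = rng.uniform(0.0, params.region_len, size=(m, n))
        counts[done:done + m] = (pos < params.target_len).sum(axis=1)
        done += m
    hist = np.bincount(counts, minlength=n + 1)
    tail = hist[::-1].cumsum()[::-1] / params.iterations   # P(X >= k), k=0..n
    p_emp = tail[1:]
    p_exact = stats.binom.sf(ks - 1, n, p)
    return GCRTailResult(ks, p_emp, p_exact, params)


# ---------------------------------------------------------------------------
# strand distribution

@dataclass(frozen=True)
class StrandRunStats:
    """Runs of same-strand neighbours, summed across chromosomes."""

    n_switches: int
    run_length_histogram: dict[int, int]
    n_singlets: int
    n_records: int


@dataclass(frozen=True)
class NullSummary:
    """Observed statistic versus its permutation distribution."""

    observed: float
    mean: float
    sd: float
    p_empirical: float           # raw fraction r/n, one-sided
    p_corrected: float           # (r+1)/(n+1)
    direction: str               # "depletion" (<= observed) or "excess"
    iterations: int
    seed: int


def _strands_by_chrom(records: Sequence[SiRTARecord]) -> list[np.ndarray]:
    groups: dict[str, list[SiRTARecord]] = {}
    for r in records:
        groups.setdefault(r.chrom, []).append(r)
    out = []
    for chrom in sorted(groups):
        recs = sorted(groups[chrom], key=lambda r: (r.start, r.end))
        out.append(np.array([1 if r.strand == "+" else 0 for r in recs],
                            dtype=np.int8))
    return out


def _runs(labels: np.ndarray) -> list[int]:
    if len(labels) == 0:
        return []
    change = np.flatnonzero(np.diff(labels) != 0)
    bounds = np.concatenate(([0], change + 1, [len(labels)]))
    return list(np.diff(bounds))


def strand_switch_observed(records: Sequence[SiRTARecord]) -> StrandRunStats:
    """Strand switches, run lengths and singlets across all chromosomes."""
    switches = 0
    hist: Counter[int] = Counter()
    total = 0
    for labels in _strands_by_chrom(records):
        runs = _runs(labels)
        switches += max(len(runs) - 1, 0)
        hist.update(runs)
        total += len(labels)
    return StrandRunStats(n_switches=switches,
                          run_length_histogram=dict(sorted(hist.items())),
                          n_singlets=hist.get(1, 0), n_records=total)


def _switch_and_singlet_matrix(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row switch and singlet counts for a (iterations x n) label matrix."""
    if m.shape[1] < 2:
        sw = np.zeros(m.shape[0], dtype=np.int64)
        sg = np.full(m.shape[0], m.shape[1], dtype=np.int64)
        return sw, sg
    diff = m[:, 1:] != m[:, :-1]
    sw = diff.sum(axis=1)
    pad = np.ones((m.shape[0], 1), dtype=bool)
    b = np.hstack([pad, diff, pad])      # run boundary before each position
    sg = (b[:, :-1] & b[:, 1:]).sum(axis=1)
    return sw, sg


def strand_switch_null(records: Sequence[SiRTARecord], iterations: int = 10_000,
                       seed: int = 0) -> tuple[NullSummary, NullSummary]:
    """Permutation null for strand switches and singlet count.

    Within each chromosome, strand labels are permuted uniformly while
    preserving the per-strand counts; switches and singlets are summed
    across chromosomes per iteration.  Returns summaries for (switches,
    singlets); each p-value is one-sided in the direction of the
    observed deviation from the permutation mean.
    """
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    obs = strand_switch_observed(records)
    rng = np.random.default_rng(seed)
    total_sw = np.zeros(iterations, dtype=np.int64)
    total_sg = np.zeros(iterations, dtype=np.int64)
    for labels in _strands_by_chrom(records):
        m = np.tile(labels, (iterations, 1))
        m = rng.permuted(m, axis=1)
        sw, sg = _switch_and_singlet_matrix(m)
        total_sw += sw
        total_sg += sg

    def summarize(dist: np.ndarray, observed: int) -> NullSummary:
        mean = float(dist.mean())
        sd = float(dist.std(ddof=1)) if iterations > 1 else 0.0
        if observed <= mean:
            r = int((dist <= observed).sum())
            direction = "depletion"
        else:
            r = int((dist >= observed).sum())
            direction = "excess"
        return NullSummary(observed=float(observed), mean=mean, sd=sd,
                           p_empirical=r / iterations,
                           p_corrected=(r + 1) / (iterations + 1),
                           direction=direction, iterations=iterations,
                           seed=seed)

    return summarize(total_sw, obs.n_switches), summarize(total_sg, obs.n_singlets)
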