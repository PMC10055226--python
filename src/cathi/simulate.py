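"""Synthetic genomes and read sets with machine-readable truth.

Planted-genome fixtures embed telomere-like tracts (e.g. ``(TG)15``) at
known coordinates in either a G-free background (no spurious tract can
ever open, so recovery is exact) or a composition-matched random
background.  Read-set fixtures compose target-prefix + telomeric-tail
reads at known junctions, emulating the irregular yeast telomeric
pattern of a single T followed by one to three Gs.  Truth tables are
sufficient to compute precision and recall without re-deriving
anything, and everything is reproducible bit-exactly under a seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import reverse_complement
from .reference import reference_score
from .scoring import ScoringParams

__all__ = [
    "PlantSpec",
    "PlantTruth",
    "ReadSimSpec",
    "expand_pattern",
    "make_planted_genome",
    "make_ptseq_reads",
]

#: Canonical telomere-like tail head; contains the plus seed GGGTGTGG so
#: every simulated event is detectable by the 8-mer seed.
TAIL_HEAD = "GTGTGGGTGTGG"

_PATTERN_RE = re.compile(r"^\(([ACGT]+)\)(\d+)$")


def expand_pattern(pattern: str) -> str:
    """Expand '(TG)15'-style patterns; other strings pass through literally."""
    m = _PATTERN_RE.match(pattern)
    if m:
        return m.group(1) * int(m.group(2))
    if not re.fullmatch(r"[ACGT]+", pattern):
        raise ValueError(f"invalid plant pattern {pattern!r}")
    return pattern


@dataclass(frozen=True)
class PlantSpec:
    """A tract to embed: pattern, chromosome, forward-strand position, strand."""

    pattern: str
    chrom: str
    position: int
    strand: str = "+"

    @property
    def sequence(self) -> str:
        return expand_pattern(self.pattern)


@dataclass(frozen=True)
class PlantTruth:
    chrom: str
    start: int
    end: int
    strand: str
    expected_score: float


def make_planted_genome(n_chrom: int, chrom_len: int,
                        plants: Sequence[PlantSpec],
                        background: str = "g_free",
                        seed: int = 0,
                        base_freqs: Mapping[str, float] | None = None,
                        params: ScoringParams | None = None
                        ) -> tuple[dict[str, str], list[PlantTruth]]:
    """Synthetic genome with planted tracts plus a truth table.

    ``background='g_free'`` draws only A/T, which is G-free on *both*
    strands (a C on the forward strand would be a G on the reverse), so
    no tract can open outside a plant on either strand — guaranteed zero
    false positives in a two-strand scan.  ``'composition'`` draws from
    ``base_freqs`` (default yeast-like A/T-rich frequencies).
    Minus-strand plants are inserted as their reverse complement.  Each
    plant is flanked by one guard base (A for plus plants, T for minus
    plants, i.e. a non-G/T base on the plant's TG-rich strand) so that
    background bases can never extend a planted tract and the expected
    score is exactly the tract's own.  Expected scores come from the
    reference enumeration scorer.
    """
    params = params or ScoringParams()
    rng = np.random.default_rng(seed)
    if background == "g_free":
        alphabet, freqs = np.array(list("AT")), None
    elif background == "composition":
        bf = dict(base_freqs or {"A": 0.31, "C": 0.19, "G": 0.19, "T": 0.31})
        alphabet = np.array(sorted(bf))
        freqs = np.array([bf[b] for b in sorted(bf)])
        freqs = freqs / freqs.sum()
    else:
        raise ValueError("background must be 'g_free' or 'composition'")

    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    genome = {c: rng.choice(alphabet, size=chrom_len, p=freqs)
              for c in chroms}

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    truth: list[PlantTruth] = []
    for p in plants:
        if p.chrom not in genome:
            raise ValueError(f"unknown chromosome {p.chrom!r}")
        tract = p.sequence
        start, end = p.position, p.position + len(tract)
        if not (0 <= start and end <= chrom_len):
            raise ValueError(f"plant at {p.chrom}:{start} does not fit")
        for a, b in occupied[p.chrom]:
            if start - 1 < b and end + 1 > a:
                raise ValueError(
                    f"overlapping plants on {p.chrom} at [{start}, {end})")
        occupied[p.chrom].append((start - 1, end + 1))
        inserted = tract if p.strand == "+" else reverse_complement(tract)
        genome[p.chrom][start:end] = list(inserted)
        guard = "A" if p.strand == "+" else "T"
        if start > 0:
            genome[p.chrom][start - 1] = guard
        if end < chrom_len:
            genome[p.chrom][end] = guard
        truth.append(PlantTruth(p.chrom, start, end, p.strand,
                                reference_score(tract, params)))
    return {c: "".join(genome[c]) for c in chroms}, truth


@dataclass(frozen=True)
class ReadSimSpec:
    """Planted telomere-addition events and sequencing depth.

    ``junction_reads`` maps each junction (0-based target coordinate of
    the last chromosome-matching base) to the number of event reads to
    simulate there.  Tails start with :data:`TAIL_HEAD` followed by
    random T(G){1..3} repeats; ``degenerate_tail`` replaces the tail
    with plain TGG repeats that contain no seed motif, to exercise the
    detector's miss behaviour.
    """

    junction_reads: Mapping[int, int] = field(default_factory=dict)
    n_control: int = 1000
    read_len: int = 150
    seed: int = 0
    degenerate_tail: bool = False
    error_rate: float = 0.0
    minus_orientation: bool = False


def _random_tail(rng: np.random.Generator, length: int,
                 degenerate: bool) -> str:
    if degenerate:
        return ("TGG" * (length // 3 + 1))[:length]
    parts = [TAIL_HEAD]
    n = len(TAIL_HEAD)
    while n < length:
        unit = "T" + "G" * int(rng.integers(1, 4))
        parts.append(unit)
        n += len(unit)
    return "".join(parts)[:length]


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        others = [b for b in "ACGT" if b != arr[i]]
        arr[i] = others[int(rng.integers(0, 3))]
    return "".join(arr)


def make_ptseq_reads(target_seq: str, control_seq: str, spec: ReadSimSpec
                     ) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Simulated PT-seq reads plus a read_id -> junction truth table.

    Event reads are a target prefix ending at the junction followed by a
    telomeric tail; control reads are exact substrings of the control
    locus.  With ``minus_orientation`` event reads are emitted as their
    reverse complement (the junction truth is unchanged).
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[tuple[str, str]] = []
    truth: dict[str, int] = {}
    for junction, count in sorted(spec.junction_reads.items()):
        if not (0 <= junction < len(target_seq)):
            raise ValueError(f"junction {junction} outside target bounds")
        for i in range(count):
            anchor = min(junction + 1, max(spec.read_len // 2, 40))
            prefix = target_seq[junction + 1 - anchor: junction + 1]
            tail = _random_tail(rng, spec.read_len - len(prefix),
                                spec.degenerate_tail)
            seq = _with_errors(prefix + tail, spec.error_rate, rng)
            if spec.minus_orientation:
                seq = reverse_complement(seq)
            rid = f"event_{junction}_{i}"
            reads.append((rid, seq))
            truth[rid] = junction
    for i in range(spec.n_control):
        start = int(rng.integers(0, max(1, len(control_seq) - spec.read_len + 1)))
        seq = control_seq[start: start + spec.read_len]
        reads.append((f"control_{i}", _with_errors(seq, spec.error_rate, rng)))
    return reads, truth
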