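"""Sliding-window scoring of telomere-like sequence tracts (the CATHI score).

Budding-yeast telomeric DNA is an irregular TG_1-3 repeat: on the G-rich
strand, a single T followed by one to three Gs.  A window's score measures
how much of it looks telomere-like: tracts of consecutive Gs and Ts that
begin with a G earn one point per base, with optional penalties for
GGTGG pentanucleotides (a word never found in yeast telomeres) and for Ts
flanking a tract.  A score of 20 in a 75-nt window is the operating
threshold that separates sequences able to act as hotspots of de novo
telomere addition (SiRTAs) from background.

Tract rules.  A tract opens at a G that begins a run of at least four
consecutive G/T characters.  Extension stops at the first T of a TT pair
(that T is included) or at the third G of a run of four or more Gs; the
scan resumes at the character after the stop point, so one long G/T run
can yield several tracts.  After truncation, fragments shorter than four
bases and fragments without any T are discarded.  Characters outside
A/C/G/T break tracts; lowercase input is uppercased.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "ScoringParams",
    "CandidateTract",
    "WindowScore",
    "ScoredRegion",
    "tokenize_window",
    "count_ggtgg",
    "score_window",
    "scan_sequence",
    "signal_arrays",
    "cluster_windows",
]

MIN_TRACT_LEN = 4
_GT = frozenset("GT")
_GGTGG_RE = re.compile(r"(?=GGTGG)")
_RUN_RE = re.compile(r"[GT]{4,}")


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the window scorer.

    ``ggtgg_penalty`` defaults to 0 (no penalties unless requested); the
    genome-analysis value is 1.5 points per GGTGG occurrence.  The
    magnitude of the flanking-T penalty is user-chosen.
    """

    window_size: int = 75
    step: int = 1
    ggtgg_penalty: float = 0.0
    tt_penalty: float = 0.0
    cluster_threshold: float = 20.0
    min_tract_len: int = field(default=MIN_TRACT_LEN, init=False)

    def __post_init__(self) -> None:
        if self.window_size < MIN_TRACT_LEN:
            raise ValueError("window_size must be >= %d" % MIN_TRACT_LEN)
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.ggtgg_penalty < 0 or self.tt_penalty < 0:
            raise ValueError("penalties must be >= 0")
        if self.cluster_threshold < 0:
            raise ValueError("cluster_threshold must be >= 0")


#: Parameter set used for genome-wide SiRTA mapping (75-nt windows, step 1,
#: 1.5-point GGTGG penalty, cluster threshold 20).
GENOME_SCAN_PARAMS = ScoringParams(window_size=75, step=1, ggtgg_penalty=1.5,
                                   cluster_threshold=20.0)


@dataclass(frozen=True)
class CandidateTract:
    """A telomere-like G/T tract inside one window (0-based half-open)."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowScore:
    """Score of one window; coordinates on the scanned sequence."""

    start: int
    end: int
    score: float
    strand: str = "+"


@dataclass(frozen=True)
class ScoredRegion:
    """A merged run of above-threshold windows on one chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    n_windows: int


def tokenize_window(seq: str) -> list[CandidateTract]:
    """Decompose a sequence into telomere-like candidate tracts.

    Left-to-right greedy scan implementing the tract rules described in
    the module docstring.  Returns tracts in coordinate order.
    """
    if not isinstance(seq, str):
        raise TypeError("sequence must be a string, got %r" % type(seq).__name__)
    s = seq.upper()
    n = len(s)
    tracts: list[CandidateTract] = []
    i = 0
    while i < n:
        if s[i] != "G":
            i += 1
            continue
        # extent of the maximal G/T run starting here
        j = i
        while j < n and s[j] in _GT:
            j += 1
        if j - i < MIN_TRACT_LEN:
            i = j
            continue
        # walk the run looking for the first truncation trigger
        end = j          # exclusive tract end
        resume = j
        g_run = 0
        for k in range(i, j):
            if s[k] == "G":
                g_run += 1
                if g_run == 4:
                    end = k          # keep up to the third G
                    resume = k       # rescan from the fourth G
                    break
            else:
                g_run = 0
                if k + 1 < j and s[k + 1] == "T":
                    end = k + 1      # keep the first T of the pair
                    resume = k + 1   # rescan from the second T
                    break
        if end - i >= MIN_TRACT_LEN and "T" in s[i:end]:
            tracts.append(CandidateTract(i, end))
        i = resume if resume > i else i + 1
    return tracts


def count_ggtgg(seq: str) -> int:
    """Number of (possibly overlapping) GGTGG occurrences in ``seq``."""
    return len(_GGTGG_RE.findall(seq.upper()))


def score_window(seq: str, params: ScoringParams | None = None) -> float:
    """CATHI score of a single window.

    Sum of candidate-tract lengths, minus ``ggtgg_penalty`` per GGTGG
    occurrence anywhere in the window, minus ``tt_penalty`` per T
    immediately adjacent to a tract.  Not floored at zero.
    """
    params = params or ScoringParams()
    s = seq.upper()
    tracts = tokenize_window(s)
    score = float(sum(t.length for t in tracts))
    if params.ggtgg_penalty:
        score -= params.ggtgg_penalty * count_ggtgg(s)
    if params.tt_penalty:
        flanking = 0
        for t in tracts:
            if t.start > 0 and s[t.start - 1] == "T":
                flanking += 1
            if t.end < len(s) and s[t.end] == "T":
                flanking += 1
        score -= params.tt_penalty * flanking
    return score


def _candidate_mask(s: str, starts: np.ndarray, window: int) -> np.ndarray:
    """Windows that could score non-zero: those touching a G/T run >= 4 nt.

    A window with no such run has no tract, no GGTGG and hence score 0.
    """
    mask = np.zeros(len(starts), dtype=bool)
    if len(starts) == 0:
        return mask
    step = int(starts[1] - starts[0]) if len(starts) > 1 else 1
    last = int(starts[-1])
    for m in _RUN_RE.finditer(s):
        lo = max(0, m.start() - window + 1)
        hi = min(last, m.end() - 1)
        if hi < lo:
            continue
        # indices of starts within [lo, hi]
        a = (lo - starts[0] + step - 1) // step
        b = (hi - starts[0]) // step
        mask[a : b + 1] = True
    return mask


def signal_arrays(seq: str, params: ScoringParams | None = None
                  ) -> tuple[np.ndarray, np.ndarray, int]:
    """All window starts and scores for one sequence.

    Returns ``(starts, scores, effective_window)``.  Sequences shorter
    than the window are scored whole as a single window.
    """
    params = params or ScoringParams()
    if not seq:
        raise ValueError("cannot scan an empty sequence")
    s = seq.upper()
    w = min(params.window_size, len(s))
    starts = np.arange(0, len(s) - w + 1, params.step, dtype=np.int64)
    scores = np.zeros(len(starts), dtype=np.float64)
    mask = _candidate_mask(s, starts, w)
    for idx in np.flatnonzero(mask):
        p = int(starts[idx])
        scores[idx] = score_window(s[p : p + w], params)
    return starts, scores, w


def scan_sequence(seq: str, params: ScoringParams | None = None,
                  mode: Literal["score", "signal"] = "score"):
    """Scan a sequence with sliding windows.

    ``score`` mode returns the maximum window score; ``signal`` mode
    returns every window as a :class:`WindowScore`.
    """
    params = params or ScoringParams()
    if mode not in ("score", "signal"):
        raise ValueError("mode must be 'score' or 'signal'")
    starts, scores, w = signal_arrays(seq, params)
    if mode == "score":
        return float(scores.max())
    return [WindowScore(int(p), int(p) + w, float(sc))
            for p, sc in zip(starts, scores)]


def cluster_windows(windows: Iterable[WindowScore], threshold: float,
                    chrom: str = "") -> list[ScoredRegion]:
    """Merge overlapping/abutting windows meeting or exceeding ``threshold``.

    Windows must come from a single chromosome strand; unsorted input is
    sorted internally.  The merged region spans from the most upstream to
    the most downstream window and carries the maximum member score.
    """
    kept = sorted((w for w in windows if w.score >= threshold),
                  key=lambda w: (w.start, w.end))
    regions: list[ScoredRegion] = []
    if not kept:
        return regions
    strand = kept[0].strand
    cur_start, cur_end = kept[0].start, kept[0].end
    cur_score, n = kept[0].score, 1
    for w in kept[1:]:
        if w.start <= cur_end:  # overlap or abut
            cur_end = max(cur_end, w.end)
            cur_score = max(cur_score, w.score)
            n += 1
        else:
            regions.append(ScoredRegion(chrom, cur_start, cur_end, strand,
                                        cur_score, n))
            cur_start, cur_end, cur_score, n = w.start, w.end, w.score, 1
    regions.append(ScoredRegion(chrom, cur_start, cur_end, strand, cur_score, n))
    return regions
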