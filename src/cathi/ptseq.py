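"""Quantifying de novo telomere addition from pooled sequencing (PT-seq).

Thirty clones that survived an induced double-strand break are pooled
and sequenced.  Reads are assigned to a 300-bp target locus (the
candidate hotspot) or a 300-bp control locus inside an essential gene;
target reads that carry telomeric sequence (an 8-mer seed, GGGTGTGG on
the TG-rich strand or its reverse complement CCACACCC) beyond their
chromosome-matching segment are telomere-addition events.  The junction
is the last target-matching base on the TG-rich strand — the 3'-most
position at which telomerase could have initiated synthesis.  Event
counts are normalised to control-read depth and converted to a
per-clone efficiency via a linear standard curve calibrated against
clone-by-clone PCR mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .genome import reverse_complement

__all__ = [
    "TelomereMotifs",
    "ReadMatch",
    "ReadAssignments",
    "TelomereAdditionEvent",
    "PTSeqSummary",
    "StandardCurve",
    "CHR7_CURVE",
    "CHR9_CURVE",
    "read_fastq",
    "assign_reads",
    "assign_from_sam",
    "detect_telomere_addition",
    "summarize",
    "apply_standard_curve",
    "classify_active",
]

DEFAULT_MIN_MATCH = 30
ACTIVITY_THRESHOLD_PCT = 6.6


@dataclass(frozen=True)
class TelomereMotifs:
    """Seed motifs marking telomeric sequence in a read."""

    plus_seed: str = "GGGTGTGG"
    minus_seed: str = "CCACACCC"

    def __post_init__(self):
        if reverse_complement(self.plus_seed) != self.minus_seed:
            raise ValueError("minus_seed must be the reverse complement of "
                             "plus_seed")


@dataclass(frozen=True)
class StandardCurve:
    """Linear map from normalised read percentage to per-clone efficiency."""

    slope: float
    intercept: float

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")


#: Calibrations from clone-by-clone PCR mapping at the two assay loci.
CHR7_CURVE = StandardCurve(slope=3.961, intercept=-2.039)
CHR9_CURVE = StandardCurve(slope=3.8022, intercept=-0.5505)


@dataclass(frozen=True)
class ReadMatch:
    """Best contiguous exact match of one read to one locus."""

    read_id: str
    locus: str                   # "target" / "control"
    orientation: str             # "plus": read as given matches the locus
    length: int
    read_start: int              # on the oriented read, half-open
    read_end: int
    ref_start: int               # on the locus, half-open
    ref_end: int


@dataclass
class ReadAssignments:
    target: dict[str, ReadMatch]
    control: dict[str, ReadMatch]
    unassigned: list[str]

    @property
    def n_target(self) -> int:
        return len(self.target)

    @property
    def n_control(self) -> int:
        return len(self.control)


@dataclass(frozen=True)
class TelomereAdditionEvent:
    read_id: str
    junction: int                # last target-matching base, TG-rich strand
    tail_length: int
    orientation: str             # "plus" / "minus"


@dataclass(frozen=True)
class PTSeqSummary:
    n_control_reads: int
    n_target_reads: int
    n_telomere_reads: int
    normalized_pct: float
    junction_profile: dict[int, float]


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def _longest_common_substring(a: np.ndarray, b: np.ndarray
                              ) -> tuple[int, int, int]:
    """(length, a_start, b_start) of the longest exact match, diagonal sweep."""
    la, lb = len(a), len(b)
    best = (0, 0, 0)
    for d in range(-(la - 1), lb):
        i0 = max(0, -d)
        i1 = min(la, lb - d)
        if i1 - i0 <= best[0]:
            continue
        eq = a[i0:i1] == b[i0 + d:i1 + d]
        if not eq.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([0], eq.astype(np.int8), [0]))))
        starts, ends = edges[0::2], edges[1::2]
        runs = ends - starts
        j = int(runs.argmax())
        if runs[j] > best[0]:
            s = i0 + int(starts[j])
            best = (int(runs[j]), s, s + d)
    return best


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def best_match(read: str, locus_seq: str) -> tuple[str, int, int, int]:
    """Best match of a read to either strand of a locus.

    Returns ``(orientation, length, read_start, ref_start)`` where
    ``read_start`` is on the oriented read (the read itself for "plus",
    its reverse complement for "minus").
    """
    ref = _encode(locus_seq)
    fwd = _longest_common_substring(_encode(read), ref)
    rev = _longest_common_substring(_encode(reverse_complement(read)), ref)
    if fwd[0] >= rev[0]:
        return ("plus", *fwd)
    return ("minus", *rev)


def assign_reads(reads: Iterable[tuple[str, str]], target_seq: str,
                 control_seq: str,
                 min_match: int = DEFAULT_MIN_MATCH) -> ReadAssignments:
    """Assign reads to target/control by contiguous exact match >= min_match.

    A read matching both loci goes to the one with the longer match.
    """
    out = ReadAssignments(target={}, control={}, unassigned=[])
    for read_id, seq in reads:
        candidates = []
        for locus, ref in (("target", target_seq), ("control", control_seq)):
            orient, length, rs, ts = best_match(seq, ref)
            if length >= min_match:
                candidates.append(ReadMatch(
                    read_id, locus, orient, length, rs, rs + length,
                    ts, ts + length))
        if not candidates:
            out.unassigned.append(read_id)
            continue
        m = max(candidates, key=lambda c: c.length)
        (out.target if m.locus == "target" else out.control)[read_id] = m
    return out


def assign_from_sam(path: str | Path, target_name: str, control_name: str,
                    min_match: int = DEFAULT_MIN_MATCH) -> ReadAssignments:
    """Assignments from an external aligner's SAM/BAM output.

    A read is assigned to the locus named by its reference when its
    aligned length is >= ``min_match``; junction calling still uses the
    exact-match logic on the read sequence, so only locus membership is
    taken from the alignment.
    """
    import pysam

    out = ReadAssignments(target={}, control={}, unassigned=[])
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                out.unassigned.append(aln.query_name)
                continue
            length = aln.query_alignment_length
            ref = aln.reference_name
            if length < min_match or ref not in (target_name, control_name):
                out.unassigned.append(aln.query_name)
                continue
            orient = "minus" if aln.is_reverse else "plus"
            m = ReadMatch(aln.query_name,
                          "target" if ref == target_name else "control",
                          orient, length,
                          aln.query_alignment_start, aln.query_alignment_end,
                          aln.reference_start, aln.reference_end)
            (out.target if m.locus == "target" else out.control)[aln.query_name] = m
    return out


def detect_telomere_addition(read_id: str, read: str, target_seq: str,
                             motifs: TelomereMotifs | None = None,
                             min_match: int = DEFAULT_MIN_MATCH,
                             require_outside: bool = True
                             ) -> TelomereAdditionEvent | None:
    """Call a telomere-addition event in one target-assigned read.

    The read is oriented onto the TG-rich strand of the target; an event
    requires a telomeric seed motif in the read.  With
    ``require_outside`` (default) the seed must lie in the unmatched 3'
    tail beyond the target-matching segment — this avoids counting the
    hotspot's own TG-rich tract as telomeric sequence; without it, a
    seed anywhere in the read suffices.
    """
    motifs = motifs or TelomereMotifs()
    orient, length, rs, ts = best_match(read, target_seq)
    if length < min_match:
        return None
    oriented = read if orient == "plus" else reverse_complement(read)
    tail = oriented[rs + length:]
    if require_outside:
        has_seed = motifs.plus_seed in tail
    else:
        has_seed = (motifs.plus_seed in oriented
                    or motifs.minus_seed in oriented)
    if not has_seed or not tail:
        return None
    return TelomereAdditionEvent(read_id=read_id,
                                 junction=ts + length - 1,
                                 tail_length=len(tail),
                                 orientation=orient)


def summarize(events: Sequence[TelomereAdditionEvent],
              assignments: ReadAssignments) -> PTSeqSummary:
    """Normalise event counts to control depth and profile the junctions."""
    n_control = assignments.n_control
    if n_control == 0:
        raise ValueError("no control reads: normalisation undefined")
    n_tel = len(events)
    profile: dict[int, float] = {}
    if n_tel:
        counts: dict[int, int] = {}
        for ev in events:
            counts[ev.junction] = counts.get(ev.junction, 0) + 1
        profile = {j: c / n_tel for j, c in sorted(counts.items())}
    return PTSeqSummary(
        n_control_reads=n_control,
        n_target_reads=assignments.n_target,
        n_telomere_reads=n_tel,
        normalized_pct=100.0 * n_tel / n_control,
        junction_profile=profile)


def apply_standard_curve(normalized_pct: float,
                         curve: StandardCurve = CHR7_CURVE) -> float:
    """Estimated per-clone dnTA efficiency (%), clamped to [0, 100]."""
    if normalized_pct < 0:
        raise ValueError("normalized_pct must be >= 0")
    return float(min(100.0, max(0.0, curve.slope * normalized_pct
                                + curve.intercept)))


def classify_active(efficiency_pct: float,
                    threshold: float = ACTIVITY_THRESHOLD_PCT) -> bool:
    """Active hotspot iff efficiency is strictly above the threshold."""
    return efficiency_pct > threshold
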