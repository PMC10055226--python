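"""Two-strand genome scans, SiRTA naming/annotation and standard-format IO.

A genome scan restricts each chromosome to its analysis bounds (terminal
telomeric repeats trimmed), optionally excises subtelomeric X/Y' element
intervals, scans both strands in signal mode, clusters above-threshold
windows into regions and annotates each region with its chromosome arm,
orientation and a compact name such as ``6R210(+)`` (chromosome 6, right
arm, 210 kb from the left telomere, plus strand).

Orientation: a region whose TG-rich strand matches the strand carrying
the 3' TG overhang at the nearest telomere is "TG"-oriented (minus strand
on left arms, plus strand on right arms); the opposite is "CA".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO

from .scoring import (ScoringParams, ScoredRegion, WindowScore,
                      cluster_windows, signal_arrays)

__all__ = [
    "ChromosomeLayout",
    "GenomeLayout",
    "SiRTARecord",
    "reverse_complement",
    "read_fasta",
    "scan_genome",
    "chromosome_number",
    "name_sirta",
    "classify_genic",
    "load_genes_gff3",
    "write_bed",
    "read_bed",
]

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ROMAN = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


Interval = tuple[int, int]


@dataclass(frozen=True)
class ChromosomeLayout:
    """Coordinates describing one chromosome (all 0-based half-open)."""

    name: str
    length: int
    analysis_start: int = 0
    analysis_end: int | None = None
    centromere: Interval | None = None
    subtelomeres: tuple[Interval, ...] = ()
    nonessential: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        end = self.length if self.analysis_end is None else self.analysis_end
        object.__setattr__(self, "analysis_end", end)
        if not (0 <= self.analysis_start < end <= self.length):
            raise ValueError(
                f"{self.name}: analysis bounds [{self.analysis_start}, {end}) "
                f"invalid for length {self.length}")
        for s, e in (self.centromere,) if self.centromere else ():
            if not (0 <= s < e <= self.length):
                raise ValueError(f"{self.name}: centromere outside chromosome")


class GenomeLayout:
    """Per-chromosome layout table (lengths, centromeres, trims, subtelomeres)."""

    def __init__(self, chromosomes: Iterable[ChromosomeLayout]):
        self.chromosomes: dict[str, ChromosomeLayout] = {
            c.name: c for c in chromosomes}

    def __getitem__(self, name: str) -> ChromosomeLayout:
        try:
            return self.chromosomes[name]
        except KeyError:
            raise KeyError(f"no layout entry for chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self):
        return iter(self.chromosomes.values())

    @classmethod
    def from_yaml(cls, path: str | Path, one_based: bool = False) -> "GenomeLayout":
        """Load a layout from YAML.

        Expected structure: a mapping ``chromosomes:`` of name -> fields
        (``length``, ``analysis_start``, ``analysis_end``, ``centromere``
        as [start, end], ``subtelomeres`` / ``nonessential`` as lists of
        [start, end]).  With ``one_based=True`` intervals are interpreted
        as 1-based inclusive and converted.
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        off = 1 if one_based else 0

        def iv(pair) -> Interval:
            return (int(pair[0]) - off, int(pair[1]))

        chroms = []
        for name, f in doc["chromosomes"].items():
            chroms.append(ChromosomeLayout(
                name=str(name),
                length=int(f["length"]),
                analysis_start=int(f.get("analysis_start", 1 if one_based else 0)) - off,
                analysis_end=int(f["analysis_end"]) if "analysis_end" in f else None,
                centromere=iv(f["centromere"]) if f.get("centromere") else None,
                subtelomeres=tuple(iv(p) for p in f.get("subtelomeres", [])),
                nonessential=tuple(iv(p) for p in f.get("nonessential", [])),
            ))
        return cls(chroms)

    @classmethod
    def trivial(cls, genome: Mapping[str, str]) -> "GenomeLayout":
        """A layout with full-length analysis bounds and no landmarks."""
        return cls(ChromosomeLayout(name=n, length=len(s))
                   for n, s in genome.items())


@dataclass(frozen=True)
class SiRTARecord:
    """A scored region annotated with genomic context."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    n_windows: int
    name: str = ""
    arm: str = ""                      # L or R
    orientation: str = ""              # TG or CA
    in_subtelomere: bool = False
    in_nonessential: bool = False
    genic_status: str | None = None    # "genic" / "intergenic"
    gene_strand_relation: str = "not_applicable"  # template / coding


def _overlaps(start: int, end: int, intervals: Sequence[Interval]) -> bool:
    return any(start < e and end > s for s, e in intervals)


def orientation_of(arm: str, strand: str) -> str:
    """TG if (L, −) or (R, +); CA otherwise."""
    return "TG" if (arm, strand) in (("L", "-"), ("R", "+")) else "CA"


def chromosome_number(chrom: str) -> int:
    """Parse a chromosome number from names like 'chrVI', 'VI', 'chr6' or '6'."""
    s = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if s.isdigit():
        return int(s)
    s = s.upper()
    if s and all(c in _ROMAN for c in s):
        total = 0
        for a, b in zip(s, s[1:] + "\0"):
            v = _ROMAN[a]
            total += -v if _ROMAN.get(b, 0) > v else v
        return total
    raise ValueError(f"cannot parse a chromosome number from {chrom!r}")


def name_sirta(record: SiRTARecord, layout: GenomeLayout | None = None) -> str:
    """Paper-style name: chromosome number, arm, kb from left telomere, strand.

    The kb distance is the region's forward-strand start divided by 1000,
    rounded half-up.
    """
    if not record.arm:
        raise ValueError("record has no arm assigned")
    kb = math.floor(record.start / 1000 + 0.5)
    return f"{chromosome_number(record.chrom)}{record.arm}{kb}({record.strand})"


def _scan_segment(seq: str, offset: int, params: ScoringParams
                  ) -> tuple[list[WindowScore], list[WindowScore]]:
    """Signal-mode windows for one forward-strand segment, both strands.

    Minus-strand windows are computed on the reverse complement and
    mapped back to forward coordinates.
    """
    starts, scores, w = signal_arrays(seq, params)
    plus = [WindowScore(offset + int(p), offset + int(p) + w, float(sc), "+")
            for p, sc in zip(starts, scores)]
    rc = reverse_complement(seq)
    rstarts, rscores, rw = signal_arrays(rc, params)
    L = len(seq)
    minus = [WindowScore(offset + L - int(p) - rw, offset + L - int(p),
                         float(sc), "-")
             for p, sc in zip(rstarts, rscores)]
    minus.reverse()
    return plus, minus


def scan_genome(genome: Mapping[str, str], layout: GenomeLayout,
                params: ScoringParams | None = None,
                exclude_subtelomeres: bool = False) -> list[SiRTARecord]:
    """Scan both strands of every chromosome and return annotated regions.

    Each chromosome is restricted to its analysis bounds; with
    ``exclude_subtelomeres`` the subtelomeric intervals are excised by
    splitting the chromosome into segments, so windows never straddle an
    excluded interval.
    """
    params = params or ScoringParams()
    records: list[SiRTARecord] = []
    for chrom, seq in genome.items():
        if chrom not in layout:
            raise KeyError(f"no layout entry for chromosome {chrom!r}")
        lay = layout[chrom]
        if lay.analysis_end > len(seq):
            raise ValueError(
                f"{chrom}: analysis_end {lay.analysis_end} exceeds sequence "
                f"length {len(seq)}")
        segments = [(lay.analysis_start, lay.analysis_end)]
        if exclude_subtelomeres:
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
        for a, b in segments:
            if b <= a:
                continue
            plus, minus = _scan_segment(seq[a:b], a, params)
            for windows in (plus, minus):
                for reg in cluster_windows(windows, params.cluster_threshold,
                                           chrom=chrom):
                    records.append(_annotate(reg, lay))
    records.sort(key=lambda r: (r.chrom, r.start, r.strand))
    return records


def _annotate(reg: ScoredRegion, lay: ChromosomeLayout) -> SiRTARecord:
    mid = (reg.start + reg.end) / 2
    if lay.centromere is not None:
        cen_mid = sum(lay.centromere) / 2
        arm = "L" if mid < cen_mid else "R"
    else:
        arm = "L" if mid < lay.length / 2 else "R"
    rec = SiRTARecord(
        chrom=reg.chrom, start=reg.start, end=reg.end, strand=reg.strand,
        score=reg.score, n_windows=reg.n_windows,
        arm=arm, orientation=orientation_of(arm, reg.strand),
        in_subtelomere=_overlaps(reg.start, reg.end, lay.subtelomeres),
        in_nonessential=_overlaps(reg.start, reg.end, lay.nonessential),
    )
    return replace(rec, name=name_sirta(rec))


# ---------------------------------------------------------------------------
# gene overlap

@dataclass(frozen=True)
class Gene:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str = ""


def load_genes_gff3(path: str | Path) -> list[Gene]:
    """Extract gene intervals (start codon to stop codon, stranded) from GFF3."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for f in db.features_of_type("gene"):
        if f.strand not in ("+", "-"):
            log.warning("skipping gene %s with strand %r", f.id, f.strand)
            continue
        genes.append(Gene(f.seqid, f.start - 1, f.end, f.strand, f.id))
    return genes


def classify_genic(records: Sequence[SiRTARecord], genes: Sequence[Gene]
                   ) -> list[SiRTARecord]:
    """Mark each record genic/intergenic and, if genic, template vs coding.

    A record is genic if it overlaps any gene by >=1 bp.  The TG-rich
    strand of the record is the transcription template when the record
    and gene are on opposite strands.  Multi-gene overlaps resolve to the
    largest overlap, ties to the leftmost gene start.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for rec in records:
        best: Gene | None = None
        best_ov = 0
        for g in by_chrom.get(rec.chrom, ()):
            ov = min(rec.end, g.end) - max(rec.start, g.start)
            if ov > 0 and (ov > best_ov or
                           (ov == best_ov and best is not None
                            and g.start < best.start)):
                best, best_ov = g, ov
        if best is None:
            out.append(replace(rec, genic_status="intergenic",
                               gene_strand_relation="not_applicable"))
        else:
            rel = "template" if rec.strand != best.strand else "coding"
            out.append(replace(rec, genic_status="genic",
                               gene_strand_relation=rel))
    return out


# ---------------------------------------------------------------------------
# BED IO (BED6: chrom, start, end, name, score, strand; 0-based half-open)

def write_bed(records: Sequence[SiRTARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or '.'}\t"
                     f"{r.score!r}\t{r.strand}\n")


def read_bed(path: str | Path) -> list[SiRTARecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            records.append(SiRTARecord(chrom, start, end, strand, score,
                                       n_windows=0, name=name))
    return records
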