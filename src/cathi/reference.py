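"""Reference tract enumeration, written independently of the scanner.

This module re-states the tract rules with a different mechanism (regex
run decomposition + recursive truncation, versus the character state
machine in :mod:`cathi.scoring`).  It exists to validate the production
scorer and to compute expected scores for synthetic truth tables; it is
deliberately simple rather than fast.
"""

from __future__ import annotations

import re

from .scoring import MIN_TRACT_LEN, ScoringParams

__all__ = ["reference_tracts", "reference_score"]

_GT_RUN = re.compile(r"[GT]+")


def _tracts_in_run(run: str, offset: int) -> list[tuple[int, int]]:
    """Tracts within one maximal G/T run, as (start, end) on the full sequence."""
    g = run.find("G")
    if g < 0:
        return []
    rem = run[g:]
    if len(rem) < MIN_TRACT_LEN:
        return []
    # earliest truncation trigger: second T of a TT pair, or fourth G of a
    # >=4-G run; the tract keeps the first T / third G respectively.
    tt = rem.find("TT")
    gggg = rem.find("GGGG")
    trigger_tt = tt + 1 if tt >= 0 else None
    trigger_gggg = gggg + 3 if gggg >= 0 else None
    if trigger_tt is None and trigger_gggg is None:
        end, resume = len(rem), len(rem)
    elif trigger_gggg is None or (trigger_tt is not None and trigger_tt < trigger_gggg):
        end, resume = tt + 1, tt + 1
    else:
        end, resume = gggg + 3, gggg + 3
    frag = rem[:end]
    out: list[tuple[int, int]] = []
    if len(frag) >= MIN_TRACT_LEN and "T" in frag:
        out.append((offset + g, offset + g + end))
    out.extend(_tracts_in_run(rem[resume:], offset + g + resume))
    return out


def reference_tracts(seq: str) -> list[tuple[int, int]]:
    """All candidate tracts of ``seq`` as 0-based half-open intervals."""
    s = seq.upper()
    tracts: list[tuple[int, int]] = []
    for m in _GT_RUN.finditer(s):
        tracts.extend(_tracts_in_run(m.group(), m.start()))
    return tracts


def reference_score(seq: str, params: ScoringParams | None = None) -> float:
    """Window score recomputed from the reference tract enumeration."""
    params = params or ScoringParams()
    s = seq.upper()
    tracts = reference_tracts(s)
    score = float(sum(e - b for b, e in tracts))
    if params.ggtgg_penalty:
        n = 0
        for i in range(len(s) - 4):
            if s[i : i + 5] == "GGTGG":
                n += 1
        score -= params.ggtgg_penalty * n
    if params.tt_penalty:
        flanking = 0
        for b, e in tracts:
            if b > 0 and s[b - 1] == "T":
                flanking += 1
            if e < len(s) and s[e] == "T":
                flanking += 1
        score -= params.tt_penalty * flanking
    return score
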