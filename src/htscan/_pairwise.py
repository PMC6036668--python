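"""Shared pairwise-alignment kernel.

Identity is defined once, here, and used unchanged by every caller:
``matches / alignment columns``, counting internal gap columns and excluding
terminal gap runs.  Global alignments are end-gap free (terminal gaps carry
no cost and no columns).

Two alignment routes back the kernel:

* ``edlib`` (bit-parallel edit distance) for global/"containment" alignment
  of nucleotide sequences — this is the workhorse for clustering, K2P and
  divergence profiling;
* ``Bio.Align.PairwiseAligner`` for score-based local alignment where the
  classic BLAST-style scoring (match +2, mismatch -3, gap open -5,
  extend -2) matters: hit refinement in mining and single-linkage hit
  detection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class AlignmentResult:
    """Summary of one pairwise alignment.

    ``columns`` excludes terminal gap runs; spans are 0-based half-open on
    the original (unaligned) sequences and cover only the terminal-gap-free
    core of the alignment.
    """

    matches: int
    columns: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str
    score: float = 0.0

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _expand_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _edlib_result(a: str, b: str, mode: str) -> AlignmentResult:
    res = edlib.align(a, b, mode=mode, task="path")
    ops = _expand_cigar(res["cigar"])
    loc = res["locations"][0]
    b_off = loc[0] if loc[0] is not None else 0
    qa, ta = [], []
    qi, ti = 0, b_off
    for n, op in ops:
        if op in ("=", "X", "M"):
            qa.append(a[qi : qi + n])
            ta.append(b[ti : ti + n])
            qi += n
            ti += n
        elif op == "I":  # insertion in query => gap in target
            qa.append(a[qi : qi + n])
            ta.append("-" * n)
            qi += n
        elif op == "D":  # deletion from query => gap in query
            qa.append("-" * n)
            ta.append(b[ti : ti + n])
            ti += n
    return _from_aligned("".join(qa), "".join(ta), a_off=0, b_off=b_off)


def _from_aligned(aligned_a: str, aligned_b: str, a_off: int = 0, b_off: int = 0) -> AlignmentResult:
    """Build a result from two gapped strings, trimming terminal gap runs."""
    n = len(aligned_a)
    lead = 0
    while lead < n and (aligned_a[lead] == "-" or aligned_b[lead] == "-"):
        lead += 1
    trail = n
    while trail > lead and (aligned_a[trail - 1] == "-" or aligned_b[trail - 1] == "-"):
        trail -= 1
    a_lead = aligned_a[:lead].count("-")
    b_lead = aligned_b[:lead].count("-")
    core_a = aligned_a[lead:trail]
    core_b = aligned_b[lead:trail]
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    a_start = a_off + (lead - a_lead)
    b_start = b_off + (lead - b_lead)
    a_end = a_start + len(core_a) - core_a.count("-")
    b_end = b_start + len(core_b) - core_b.count("-")
    return AlignmentResult(
        matches=matches,
        columns=len(core_a),
        a_start=a_start,
        a_end=a_end,
        b_start=b_start,
        b_end=b_end,
        aligned_a=core_a,
        aligned_b=core_b,
    )


def global_align(a: str, b: str) -> AlignmentResult:
    """End-gap-free global alignment (edit-distance optimal)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return _edlib_result(a, b, mode="NW")


def infix_align(query: str, target: str) -> AlignmentResult:
    """Align the whole query inside the target (free target end gaps)."""
    if not query or not target:
        raise ValueError("cannot align an empty sequence")
    return _edlib_result(query, target, mode="HW")


def containment_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned within the longer one."""
    if len(a) <= len(b):
        return infix_align(a, b).identity
    return infix_align(b, a).identity


@lru_cache(maxsize=4)
def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def local_align(a: str, b: str) -> AlignmentResult | None:
    """Best-scoring local alignment under the BLAST-style scores.

    Returns None when no positive-scoring alignment exists.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _local_aligner()
    score = aligner.score(a, b)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(a, b)))
    blocks_a, blocks_b = aln.aligned
    qa, ta = [], []
    prev_a = prev_b = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            qa.append(a[prev_a:a0])
            ta.append("-" * (a0 - prev_a))
            qa.append("-" * (b0 - prev_b))
            ta.append(b[prev_b:b0])
        qa.append(a[a0:a1])
        ta.append(b[b0:b1])
        prev_a, prev_b = a1, b1
    result = _from_aligned(
        "".join(qa), "".join(ta), a_off=blocks_a[0][0], b_off=blocks_b[0][0]
    )
    result.score = float(score)
    return result
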