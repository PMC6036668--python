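"""Per-species representatives, ORF discovery and RT-domain scoring.

Two representative strategies mirror common practice for TE families:

* consensus: cluster a species' full-length copies at 70-90% identity and
  take the majority-rule column consensus of each cluster's alignment
  (degraded families can yield over-long consensi, which are flagged);
* centroid: the longest intact copy within the 2-4 kb window, a robust
  single-sequence representative.

The reverse-transcriptase domain — the most conserved part of the element —
is located by a position-specific scoring matrix built from a seed alignment
of RT sequences, with a 200-aa minimum envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import greedy_centroid_cluster
from .formats import SeqRecord, revcomp
from .phylo import align_progressive

__all__ = [
    "Representative",
    "OrfRecord",
    "RTDomain",
    "Pssm",
    "build_consensus",
    "select_centroid",
    "find_orfs",
    "build_pssm",
    "score_rt_domain",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def _translate(nt: str) -> str:
    table = _codon_table()
    return "".join(
        table.get(nt[i : i + 3], "X") for i in range(0, len(nt) - len(nt) % 3, 3)
    )


@dataclass
class Representative:
    species: str
    family: str
    method: str  # "consensus" or "centroid"
    seq: str
    n_supporting_copies: int
    overlong: bool = False  # consensus longer than every supporting copy


@dataclass
class OrfRecord:
    parent_id: str
    frame: int  # +1..+3 / -1..-3
    aa_seq: str
    nt_seq: str
    nt_start: int  # on the input (plus) strand, 0-based half-open
    nt_end: int


@dataclass
class RTDomain:
    parent_id: str
    envelope: tuple[int, int]  # [start, end) on the aa sequence
    score: float  # bits
    aa_seq: str


# ---------------------------------------------------------------------------
# representatives


def build_consensus(
    copies: list[SeqRecord],
    cluster_identity: float = 0.8,
    species: str = "",
    family: str = "",
) -> list[Representative]:
    """Majority-rule consensus per cluster of copies.

    Copies are clustered at ``cluster_identity`` (greedy centroid engine),
    each cluster is aligned, and the most frequent base per column wins
    (ties broken by the first-seen base in member order; columns with a gap
    majority are dropped).
    """
    if not 0.5 <= cluster_identity <= 1.0:
        raise ValueError("cluster_identity must lie in [0.5, 1.0]")
    if not copies:
        return []
    by_id = {c.id: c for c in copies}
    reps: list[Representative] = []
    for cluster in greedy_centroid_cluster(copies, cluster_identity):
        members = [by_id[m] for m in cluster.member_ids]
        if len(members) == 1:
            consensus = members[0].seq
        else:
            msa = align_progressive(members)
            cols = []
            length = len(msa[0].seq)
            for j in range(length):
                counts: dict[str, int] = {}
                order: list[str] = []
                for rec in msa:
                    c = rec.seq[j]
                    if c not in counts:
                        order.append(c)
                    counts[c] = counts.get(c, 0) + 1
                base_counts = {c: n for c, n in counts.items() if c != "-"}
                # a gap wins a column only by strict majority; base ties go
                # to the first-seen base
                if base_counts:
                    best = max(base_counts.values())
                    if counts.get("-", 0) <= best:
                        cols.append(next(c for c in order if c != "-" and counts[c] == best))
            consensus = "".join(cols)
        overlong = len(consensus) > max(len(m.seq) for m in members)
        reps.append(
            Representative(
                species=species,
                family=family,
                method="consensus",
                seq=consensus,
                n_supporting_copies=len(members),
                overlong=overlong,
            )
        )
    return reps


def select_centroid(
    copies: list[SeqRecord],
    min_len: int = 2000,
    max_len: int = 4000,
    species: str = "",
    family: str = "",
) -> Representative | None:
    """Longest copy within [min_len, max_len]; ties by smallest id."""
    eligible = [c for c in copies if min_len <= len(c.seq) <= max_len]
    if not eligible:
        return None
    winner = min(eligible, key=lambda c: (-len(c.seq), c.id))
    return Representative(
        species=species,
        family=family,
        method="centroid",
        seq=winner.seq,
        n_supporting_copies=len(eligible),
    )


# ---------------------------------------------------------------------------
# ORFs


def find_orfs(
    nt_seq: str,
    min_aa_len: int = 200,
    allow_nonstandard_starts: bool = True,
    parent_id: str = "",
) -> list[OrfRecord]:
    """ORFs on all six frames.

    With non-standard starts allowed an ORF is any stop-free stretch of at
    least ``min_aa_len`` residues ending at a stop codon or the end of the
    frame; standard mode additionally requires the stretch to begin at ATG.
    """
    results: list[OrfRecord] = []
    n = len(nt_seq)
    for strand, seq in (("+", nt_seq), ("-", revcomp(nt_seq))):
        for offset in range(3):
            aa = _translate(seq[offset:])
            start = 0
            segments = []
            for i, c in enumerate(aa):
                if c == "*":
                    segments.append((start, i))
                    start = i + 1
            segments.append((start, len(aa)))
            for s, e in segments:
                if allow_nonstandard_starts:
                    o_start = s
                else:
                    m = next((i for i in range(s, e) if aa[i] == "M"), None)
                    if m is None:
                        continue
                    o_start = m
                if e - o_start < min_aa_len:
                    continue
                nt_a = offset + 3 * o_start
                nt_b = offset + 3 * e
                if strand == "+":
                    nt_start, nt_end = nt_a, nt_b
                    frame = offset + 1
                else:
                    nt_start, nt_end = n - nt_b, n - nt_a
                    frame = -(offset + 1)
                results.append(
                    OrfRecord(
                        parent_id=parent_id,
                        frame=frame,
                        aa_seq=aa[o_start:e],
                        nt_seq=seq[nt_a:nt_b],
                        nt_start=nt_start,
                        nt_end=nt_end,
                    )
                )
    results.sort(key=lambda o: (-len(o.aa_seq), o.frame, o.nt_start))
    return results


# ---------------------------------------------------------------------------
# PSSM / RT domain


@dataclass
class Pssm:
    """Position-specific log-odds scores (bits) over the 20 amino acids."""

    matrix: np.ndarray  # (length, 20)
    alphabet: str = _AA

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(self.alphabet[i] for i in self.matrix.argmax(axis=1))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pos\t" + "\t".join(self.alphabet) + "\n")
            for i, row in enumerate(self.matrix):
                fh.write(f"{i}\t" + "\t".join(f"{x:.4f}" for x in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Pssm":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            alphabet = "".join(header[1:])
            rows = [list(map(float, line.split("\t")[1:])) for line in fh if line.strip()]
        return cls(matrix=np.array(rows), alphabet=alphabet)


def build_pssm(aligned_aa: list[SeqRecord], pseudocount: float = 1.0) -> Pssm:
    """Log-odds PSSM (base 2, uniform 1/20 background) from a seed alignment.

    Gap-majority columns are dropped so the matrix models the conserved
    core; gaps elsewhere contribute the background distribution.
    """
    if not aligned_aa:
        raise ValueError("empty seed alignment")
    length = len(aligned_aa[0].seq)
    if any(len(r.seq) != length for r in aligned_aa):
        raise ValueError("seed sequences must be aligned (equal length)")
    n = len(aligned_aa)
    background = 1.0 / 20.0
    rows = []
    for j in range(length):
        col = [r.seq[j] for r in aligned_aa]
        gaps = col.count("-")
        if gaps * 2 > n:
            continue
        counts = np.full(20, pseudocount)
        for c in col:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1.0
            elif c != "-":  # X or other: spread over alphabet
                counts += 1.0 / 20.0
        freqs = counts / counts.sum()
        rows.append(np.log2(freqs / background))
    return Pssm(matrix=np.array(rows))


def score_rt_domain(
    aa_seq: str,
    pssm: Pssm,
    min_len: int = 200,
    min_score: float = 50.0,
    parent_id: str = "",
) -> list[RTDomain]:
    """Best gapless PSSM match envelopes of length >= ``min_len``.

    The sequence is slid against the matrix at every offset; for each
    offset, the maximal-scoring window of at least ``min_len`` columns is
    found from prefix sums.  Non-overlapping envelopes with score >=
    ``min_score`` bits are reported, best first.
    """
    if pssm.alphabet != _AA:
        raise ValueError("PSSM alphabet mismatch")
    L = len(pssm)
    n = len(aa_seq)
    if n < min_len or L < min_len:
        return []
    codes = np.full(n, -1, dtype=np.int64)
    for i, c in enumerate(aa_seq):
        codes[i] = _AA_INDEX.get(c, -1)
    # score of matrix column j against residue i (unknown residues ~ background 0)
    candidates: list[tuple[float, int, int]] = []
    for offset in range(-(L - min_len), n - min_len + 1):
        j0 = max(0, -offset)
        j1 = min(L, n - offset)
        if j1 - j0 < min_len:
            continue
        idx = codes[offset + j0 : offset + j1]
        scores = np.where(idx >= 0, pssm.matrix[np.arange(j0, j1), np.clip(idx, 0, 19)], 0.0)
        pre = np.concatenate([[0.0], np.cumsum(scores)])
        m = len(scores)
        # max over windows [a, b) with b - a >= min_len, via prefix minima
        minpre = np.minimum.accumulate(pre[: m - min_len + 1])
        vals = pre[min_len:] - minpre
        bi = int(np.argmax(vals))
        best_score = float(vals[bi])
        best_b = bi + min_len
        best_a = int(np.argmin(pre[: best_b - min_len + 1]))
        if best_score >= min_score:
            seq_a = offset + j0 + best_a
            seq_b = offset + j0 + best_b
            candidates.append((float(best_score), seq_a, seq_b))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    domains: list[RTDomain] = []
    for score, a, b in candidates:
        if any(not (b <= d.envelope[0] or a >= d.envelope[1]) for d in domains):
            continue
        domains.append(
            RTDomain(parent_id=parent_id, envelope=(a, b), score=score, aa_seq=aa_seq[a:b])
        )
    return domains
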