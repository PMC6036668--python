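"""Distances, alignment and trees: K2P, progressive MSA, conserved blocks,
neighbour joining with bootstrap, tree comparison and divergence landscapes.

The Kimura two-parameter (K2P) model separates transitions (A<->G, C<->T;
observed fraction P) from transversions (fraction Q) and estimates the
substitution distance

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Saturated pairs (arguments of the logarithm non-positive) raise
:class:`SaturationError` rather than returning infinity.

Divergence landscapes bin copy coverage by K2P distance to a family
reference; amplification bursts appear as modes at the burst age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._pairwise import GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH
from .formats import SeqRecord, tree_from_string

__all__ = [
    "SaturationError",
    "DistanceMatrix",
    "DivergenceProfile",
    "k2p",
    "k2p_pair",
    "scored_global_align",
    "align_progressive",
    "conserved_blocks",
    "nj_tree",
    "bootstrap",
    "rf_distance",
    "divergence_landscape",
]


class SaturationError(ValueError):
    """Raised when observed divergence exceeds the K2P model's domain."""


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (gaps, N) -> 255."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def k2p(a_aligned: str, b_aligned: str) -> tuple[float, float, float]:
    """K2P estimate from an aligned pair.

    Columns containing a gap or N in either sequence are excluded.  Returns
    ``(P, Q, K)`` with P the transition and Q the transversion fraction.
    """
    if len(a_aligned) != len(b_aligned):
        raise ValueError("aligned sequences must have equal length")
    a = _encode(a_aligned)
    b = _encode(b_aligned)
    valid = (a != 255) & (b != 255)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable columns")
    diff = a[valid] ^ b[valid]
    # codes A0 C1 G2 T3: xor 2 flips within a purine/pyrimidine pair
    p = float(np.count_nonzero(diff == 2)) / n
    q = float(np.count_nonzero((diff == 1) | (diff == 3))) / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P saturated: P={p:.3f}, Q={q:.3f} (1-2P-Q={w1:.3f}, 1-2Q={w2:.3f})"
        )
    k = -0.5 * math.log(w1 * math.sqrt(w2))
    return p, q, k + 0.0  # avoid -0.0 for identical pairs


def scored_global_align(a: str, b: str) -> tuple[str, str]:
    """End-gap-free global alignment under match +2, mismatch -3, affine
    gaps (-5 open, -2 extend).

    Gaps cost more than mismatches, so substitution-only divergence aligns
    without gaps and distance estimates stay unbiased (an edit-distance
    path can trade mismatches for match-creating shifts).  N columns score
    0 against everything.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    ea, eb = _encode(a), _encode(b)
    S = np.where(
        ea[:, None] == eb[None, :], np.float32(MATCH), np.float32(MISMATCH)
    )
    S[ea == 255, :] = 0.0
    S[:, eb == 255] = 0.0
    moves = _gotoh_moves(S)
    rows_a, rows_b = _apply_moves([a], [b], moves)
    return rows_a[0], rows_b[0]


def k2p_pair(a: str, b: str) -> tuple[float, float, float]:
    """K2P of two unaligned sequences via score-based global alignment."""
    aligned_a, aligned_b = scored_global_align(a, b)
    return k2p(aligned_a, aligned_b)


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    @classmethod
    def from_k2p(cls, seqs: list[SeqRecord]) -> "DistanceMatrix":
        """Pairwise K2P distances (saturated pairs raise SaturationError)."""
        n = len(seqs)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                _, _, k = k2p_pair(seqs[i].seq, seqs[j].seq)
                m[i, j] = m[j, i] = k
        return cls([s.id for s in seqs], m)


# ---------------------------------------------------------------------------
# progressive multiple alignment

_GAP_VS_BASE = -1.0  # profile column scoring only

# 5-state column scoring matrix: A C G T gap
_COLSCORE = np.full((5, 5), float(MISMATCH))
np.fill_diagonal(_COLSCORE, float(MATCH))
_COLSCORE[4, :] = _GAP_VS_BASE
_COLSCORE[:, 4] = _GAP_VS_BASE
_COLSCORE[4, 4] = 0.0

_NEG = -1e30


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 5) column frequencies over A,C,G,T,gap; N spread over bases."""
    length = len(rows[0])
    prof = np.zeros((length, 5), dtype=np.float32)
    for row in rows:
        enc = _encode(row)
        arr = np.frombuffer(row.encode(), dtype=np.uint8)
        for code in range(4):
            prof[enc == code, code] += 1.0
        prof[arr == ord("-"), 4] += 1.0
        is_n = (enc == 255) & (arr != ord("-"))
        prof[is_n, :4] += 0.25
    prof /= len(rows)
    return prof


def _align_profiles(pa: np.ndarray, pb: np.ndarray) -> list[str]:
    """Affine-gap, end-gap-free profile-profile alignment."""
    return _gotoh_moves((pa @ _COLSCORE @ pb.T).astype(np.float32))


def _gotoh_moves(S: np.ndarray) -> list[str]:
    """End-gap-free affine-gap DP over a column-score matrix.

    Returns the move string over {'D' diagonal, 'U' consume-A, 'L'
    consume-B} covering all rows and columns of S (terminal overhangs
    included as U/L runs).  Row-vectorised; the horizontal gap state is
    solved per row with a running-maximum over gap-open candidates.
    """
    n, m = S.shape

    M = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.float32)  # gap in B (vertical)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.float32)  # gap in A (horizontal)
    # free terminal gaps: zero-cost leading skip along either edge
    M[0, 0] = 0.0
    Y[0, 1:] = 0.0
    X[1:, 0] = 0.0
    ptrM = np.zeros((n + 1, m + 1), dtype=np.uint8)  # source of best at (i-1,j-1)
    fromX = np.zeros((n + 1, m + 1), dtype=bool)  # X extended (vs opened)
    ksrc = np.zeros((n + 1, m + 1), dtype=np.int32)  # Y: column the gap run left from

    js = np.arange(m + 1)
    for i in range(1, n + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        # M: diagonal move
        stacked = np.vstack([prevM[:-1], prevX[:-1], prevY[:-1]])
        src = np.argmax(stacked, axis=0)
        best_prev = stacked[src, np.arange(m)]
        M[i, 1:] = S[i - 1] + best_prev
        ptrM[i, 1:] = src
        # X: vertical gap
        open_x = np.maximum(prevM, prevY) + GAP_OPEN
        ext_x = prevX + GAP_EXTEND
        X[i, 1:] = np.maximum(open_x[1:], ext_x[1:])
        fromX[i, 1:] = ext_x[1:] >= open_x[1:]
        # Y: horizontal gap via running-max trick (first gap column costs
        # GAP_OPEN, each further one GAP_EXTEND)
        C = np.maximum(M[i], X[i]) + GAP_OPEN - GAP_EXTEND * (js + 1)
        acc = np.maximum.accumulate(C[:-1])
        arg = np.maximum.accumulate(np.where(C[:-1] >= acc, np.arange(m), 0))
        Y[i, 1:] = np.maximum(acc + GAP_EXTEND * js[1:], Y[i, 1:])
        ksrc[i, 1:] = arg

    # best end on last row or column (free trailing gaps)
    end_candidates = [(M, "M"), (X, "X"), (Y, "Y")]
    best_score, best_state, bi, bj = _NEG, "M", n, m
    for mat, state in end_candidates:
        j = int(np.argmax(mat[n]))
        if mat[n, j] > best_score:
            best_score, best_state, bi, bj = float(mat[n, j]), state, n, j
        i = int(np.argmax(mat[:, m]))
        if mat[i, m] > best_score:
            best_score, best_state, bi, bj = float(mat[i, m]), state, i, m

    moves: list[str] = []
    moves.extend("U" * (n - bi))  # trailing overhang of A
    moves.extend("L" * (m - bj))
    i, j, state = bi, bj, best_state
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            moves.append("D")
            state = "MXY"[ptrM[i, j]]
            i, j = i - 1, j - 1
        elif state == "X":
            if i == 0:
                break
            moves.append("U")
            if j == 0:
                i -= 1  # free leading column
                continue
            state = "X" if fromX[i, j] else ("M" if M[i - 1, j] >= Y[i - 1, j] else "Y")
            i -= 1
        else:  # Y
            if j == 0:
                break
            k = int(ksrc[i, j])
            moves.extend("L" * (j - k))
            j = k
            if i == 0 or j == 0:
                state = "M"
                continue
            state = "M" if M[i, j] >= X[i, j] else "X"
    moves.extend("U" * i)
    moves.extend("L" * j)
    moves.reverse()
    return moves


def _apply_moves(rows_a: list[str], rows_b: list[str], moves: list[str]) -> tuple[list[str], list[str]]:
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for mv in moves:
        if mv in ("D", "U"):
            for r, o in zip(rows_a, out_a):
                o.append(r[ia])
            ia += 1
        else:
            for o in out_a:
                o.append("-")
        if mv in ("D", "L"):
            for r, o in zip(rows_b, out_b):
                o.append(r[ib])
            ib += 1
        else:
            for o in out_b:
                o.append("-")
    return ["".join(o) for o in out_a], ["".join(o) for o in out_b]


def _kmer_distance(a: str, b: str, k: int = 8) -> float:
    ka = {a[i : i + k] for i in range(max(len(a) - k + 1, 1))}
    kb = {b[i : i + k] for i in range(max(len(b) - k + 1, 1))}
    inter = len(ka & kb)
    return 1.0 - inter / min(len(ka), len(kb))


def align_progressive(seqs: list[SeqRecord]) -> list[SeqRecord]:
    """Progressive MSA: UPGMA guide tree on 8-mer distances, profile merges.

    Deterministic given input order; returns gapped records in input order.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    if len(seqs) == 2:
        row_a, row_b = scored_global_align(seqs[0].seq, seqs[1].seq)
        return [
            SeqRecord(seqs[0].id, row_a, seqs[0].description),
            SeqRecord(seqs[1].id, row_b, seqs[1].description),
        ]

    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(seqs[i].seq, seqs[j].seq)
    Z = hierarchy.linkage(squareform(dm, checks=False), method="average")

    # node id -> (member indices, gapped rows)
    nodes: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i].seq]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ia, ib = int(a), int(b)
        idx_a, rows_a = nodes.pop(ia)
        idx_b, rows_b = nodes.pop(ib)
        moves = _align_profiles(_profile(rows_a), _profile(rows_b))
        new_a, new_b = _apply_moves(rows_a, rows_b, moves)
        nodes[n + step] = (idx_a + idx_b, new_a + new_b)

    indices, rows = nodes.popitem()[1]
    by_index = dict(zip(indices, rows))
    return [
        SeqRecord(seqs[i].id, by_index[i], seqs[i].description) for i in range(n)
    ]


def conserved_blocks(
    msa: list[SeqRecord],
    min_block: int = 5,
    min_conserved_fraction: float = 0.5,
) -> list[SeqRecord]:
    """Keep maximal runs of >= ``min_block`` conserved columns.

    A column is conserved when its most frequent non-gap character reaches
    ``min_conserved_fraction`` of the sequences; gaps are allowed within
    kept columns ("allowed gaps: all").
    """
    if not msa:
        return []
    nrow = len(msa)
    length = len(msa[0].seq)
    rows = [r.seq for r in msa]
    conserved = []
    for j in range(length):
        counts: dict[str, int] = {}
        for row in rows:
            c = row[j]
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        top = max(counts.values()) if counts else 0
        conserved.append(top / nrow >= min_conserved_fraction)
    keep: list[int] = []
    run: list[int] = []
    for j, ok in enumerate(conserved):
        if ok:
            run.append(j)
        else:
            if len(run) >= min_block:
                keep.extend(run)
            run = []
    if len(run) >= min_block:
        keep.extend(run)
    return [
        SeqRecord(r.id, "".join(r.seq[j] for j in keep), r.description)
        for r in msa
    ] if keep else []


# ---------------------------------------------------------------------------
# neighbour joining


def _fmt_bl(x: float) -> str:
    return format(x, ".17g")


def nj_tree(dm: DistanceMatrix):
    """Neighbour-joining tree (unrooted, trifurcating at the root node).

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sibling branch.  Returns a dendropy Tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ requires at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    nodes = [f"{label}" for label in dm.labels]

    def clamp(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return la, max(lb, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        new_label = f"({nodes[i]}:{_fmt_bl(li)},{nodes[j]}:{_fmt_bl(lj)})"
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [new_label]

    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = (
        f"({nodes[0]}:{_fmt_bl(la)},{nodes[1]}:{_fmt_bl(lb)},{nodes[2]}:{_fmt_bl(lc)});"
    )
    return tree_from_string(newick)


def tree_splits(tree) -> set[frozenset[str]]:
    """Non-trivial unrooted splits, each as the leaf set not containing the
    alphabetically first taxon."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = labels[0]
    all_set = set(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(all_set) - 1:
            splits.add(frozenset(side))
    return splits


def rf_distance(t1, t2) -> int:
    """Robinson–Foulds distance: splits present in exactly one tree."""
    s1, s2 = tree_splits(t1), tree_splits(t2)
    l1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    l2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees must share the same leaf set")
    return len(s1 ^ s2)


def _msa_k2p_matrix(msa: list[SeqRecord], cols: np.ndarray | None = None, cap: float = 5.0) -> DistanceMatrix:
    """K2P distances from MSA rows; saturated pairs capped at ``cap``.

    The cap is used only here (bootstrap replicates may saturate by
    resampling); single-pair estimates elsewhere raise instead.
    """
    rows = []
    for rec in msa:
        if cols is None:
            rows.append(rec.seq)
        else:
            s = rec.seq
            rows.append("".join(s[c] for c in cols))
    n = len(rows)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                _, _, k = k2p(rows[i], rows[j])
            except SaturationError:
                k = cap
            except ValueError:
                k = cap
            m[i, j] = m[j, i] = k
    return DistanceMatrix([r.id for r in msa], m)


def bootstrap(msa: list[SeqRecord], n_reps: int = 1000, seed: int = 0):
    """NJ tree with bootstrap supports from column resampling.

    Internal nodes of the returned tree carry ``label`` = fraction of
    replicates containing the corresponding split.
    """
    if len(msa) < 4:
        raise ValueError("bootstrap support needs at least 4 sequences")
    length = len(msa[0].seq)
    if length < 2:
        raise ValueError("MSA must have at least 2 columns")
    main = nj_tree(_msa_k2p_matrix(msa))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep_tree = nj_tree(_msa_k2p_matrix(msa, cols=cols))
        for split in tree_splits(rep_tree):
            counts[split] = counts.get(split, 0) + 1

    labels = sorted(leaf.taxon.label for leaf in main.leaf_node_iter())
    ref = labels[0]
    all_set = set(labels)
    for node in main.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if ref in side:
            side = all_set - side
        if 1 < len(side) < len(all_set) - 1:
            node.label = f"{counts.get(frozenset(side), 0) / n_reps:.3f}"
    return main


# ---------------------------------------------------------------------------
# divergence landscapes


@dataclass
class DivergenceProfile:
    """Coverage (bp) per K2P-percent bin for one species x family."""

    species: str
    family: str
    bin_width: float = 1.0
    coverage: dict[int, int] = field(default_factory=dict)
    n_excluded: int = 0

    def add(self, k_percent: float, bases: int) -> None:
        b = int(k_percent // self.bin_width)
        self.coverage[b] = self.coverage.get(b, 0) + bases

    @property
    def total_coverage(self) -> int:
        return sum(self.coverage.values())

    def modal_bin(self) -> int:
        if not self.coverage:
            raise ValueError("empty divergence profile")
        return max(self.coverage, key=lambda b: (self.coverage[b], -b))

    def modes(self, min_separation: int = 5) -> list[int]:
        """Local maxima separated by at least ``min_separation`` bins."""
        if not self.coverage:
            return []
        bins = sorted(self.coverage)
        found: list[int] = []
        for b in sorted(bins, key=lambda x: -self.coverage[x]):
            if all(abs(b - f) >= min_separation for f in found):
                found.append(b)
        return sorted(found)

    def to_rows(self) -> list[tuple[float, float, int]]:
        return [
            (b * self.bin_width, (b + 1) * self.bin_width, self.coverage[b])
            for b in sorted(self.coverage)
        ]


def divergence_landscape(
    copies: list[SeqRecord],
    reference: SeqRecord,
    bin_width: float = 1.0,
    species: str = "",
    family: str = "",
    min_aligned_fraction: float = 0.5,
) -> DivergenceProfile:
    """Bin copy coverage by K2P distance to a family reference.

    Each copy is globally aligned (end-gap free) to the reference; copies
    with < ``min_aligned_fraction`` of their length aligned, or saturated
    distances, are excluded and counted in ``n_excluded``.
    """
    profile = DivergenceProfile(species=species, family=family, bin_width=bin_width)
    for copy in copies:
        aligned_a, aligned_b = scored_global_align(copy.seq, reference.seq)
        aligned_bases = sum(
            1 for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"
        )
        if aligned_bases / len(copy.seq) < min_aligned_fraction:
            profile.n_excluded += 1
            continue
        try:
            _, _, k = k2p(aligned_a, aligned_b)
        except SaturationError:
            profile.n_excluded += 1
            continue
        profile.add(k * 100.0, aligned_bases)
    return profile
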