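"""All-against-all clustering of TE sequences.

Two engines mirror the two strategies used in large-scale TE surveys:

* **greedy centroid** (UCLUST/VSEARCH style): sequences are processed
  longest-first; each either joins the first centroid it matches at or above
  the identity threshold or founds a new cluster.  Appropriate for ancient
  transfer events, where the centroid is ideally the transferred element.
* **single linkage** (BLAST+SiLiX style): any above-threshold pairwise hit
  with sufficient overlap connects two sequences; clusters are the connected
  components.  Sensitive for recent events but chains degraded copies into
  one family.

Identity is matches / alignment columns (internal gaps counted, terminal
gaps excluded) — see :mod:`htscan._pairwise`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import pandas as pd

from ._pairwise import local_align
from .formats import SeqRecord

__all__ = [
    "Cluster",
    "pairwise_identity",
    "greedy_centroid_cluster",
    "single_linkage_cluster",
    "threshold_sweep",
]

#: cluster id prefixes by sequence kind: nucleotide, nucleotide ORF, RT amino acid
KIND_PREFIX = {"nt": "c", "orf": "o", "rt": "r"}


@dataclass
class Cluster:
    cluster_id: str
    member_ids: list[str]
    threshold: float
    centroid_id: str | None = None
    member_identity: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.member_ids)


def pairwise_identity(a: str, b: str, mode: str = "global") -> float:
    """Identity fraction between two sequences, symmetric and in [0, 1].

    ``global`` is the Levenshtein ratio ``1 - d / max(|a|, |b|)`` with d the
    optimal global edit distance: for substitution-only differences this
    equals matches over alignment columns exactly, and unlike a
    matches-over-columns count on one optimal path it cannot be inflated by
    co-optimal gap placements between divergent sequences.  ``local`` is
    matches over columns of the best-scoring local alignment (0.0 when
    nothing scores positively).
    """
    if not a or not b:
        raise ValueError("cannot compute identity of an empty sequence")
    if mode == "global":
        d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        return 1.0 - d / max(len(a), len(b))
    if mode == "local":
        res = local_align(a, b)
        return res.identity if res is not None else 0.0
    raise ValueError(f"unknown identity mode {mode!r}")


def _ordered(seqs: Sequence[SeqRecord]) -> list[SeqRecord]:
    # length-descending, ties by id: deterministic cluster_fast-style order
    return sorted(seqs, key=lambda r: (-len(r.seq), r.id))


def _shared_kmer_fraction(a: str, b: str, k: int = 8) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / min(len(ka), len(kb))


def greedy_centroid_cluster(
    seqs: Sequence[SeqRecord],
    threshold: float,
    kind: str = "nt",
    prefilter: bool = False,
) -> list[Cluster]:
    """Greedy centroid clustering at an identity ``threshold``.

    Sequences are taken length-descending (ties by id); each is assigned to
    the first centroid it matches at >= threshold, else it founds a new
    cluster.  When ``prefilter`` is on, centroid candidates sharing no 8-mer
    with the sequence are skipped before alignment; this is a speed device
    only and must not change the partition on realistic inputs.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    prefix = KIND_PREFIX.get(kind, kind)
    clusters: list[Cluster] = []
    centroids: list[SeqRecord] = []
    for rec in _ordered(seqs):
        assigned = False
        for cluster, centroid in zip(clusters, centroids):
            if prefilter and _shared_kmer_fraction(rec.seq, centroid.seq) == 0.0:
                continue
            ident = pairwise_identity(rec.seq, centroid.seq)
            if ident >= threshold:
                cluster.member_ids.append(rec.id)
                cluster.member_identity[rec.id] = ident
                assigned = True
                break
        if not assigned:
            cluster = Cluster(
                cluster_id=f"{prefix}_{len(clusters) + 1}",
                member_ids=[rec.id],
                threshold=threshold,
                centroid_id=rec.id,
                member_identity={rec.id: 1.0},
            )
            clusters.append(cluster)
            centroids.append(rec)
    for cluster in clusters:  # structural guarantee of the greedy engine
        assert all(v >= threshold for v in cluster.member_identity.values())
    return clusters


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def _hit_edge(a: SeqRecord, b: SeqRecord, threshold: float, min_overlap_fraction: float) -> bool:
    res = local_align(a.seq, b.seq)
    if res is None:
        return False
    shorter = min(len(a.seq), len(b.seq))
    overlap = min(res.a_end - res.a_start, res.b_end - res.b_start) / shorter
    return res.identity >= threshold and overlap >= min_overlap_fraction


def single_linkage_cluster(
    seqs: Sequence[SeqRecord],
    threshold: float,
    min_overlap_fraction: float = 0.5,
    kind: str = "nt",
) -> list[Cluster]:
    """Single-linkage families over above-threshold pairwise hits.

    An edge joins two sequences when their best local alignment reaches the
    identity threshold and covers at least ``min_overlap_fraction`` of the
    shorter sequence; clusters are connected components (union-find).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = _ordered(seqs)
    uf = _UnionFind(r.id for r in ordered)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if _hit_edge(ordered[i], ordered[j], threshold, min_overlap_fraction):
                uf.union(ordered[i].id, ordered[j].id)
    groups: dict[str, list[str]] = {}
    for rec in ordered:
        groups.setdefault(uf.find(rec.id), []).append(rec.id)
    prefix = KIND_PREFIX.get(kind, kind)
    clusters = []
    for k, root in enumerate(sorted(groups, key=lambda r: (-len(groups[r]), r)), start=1):
        clusters.append(
            Cluster(
                cluster_id=f"{prefix}_{k}",
                member_ids=groups[root],
                threshold=threshold,
            )
        )
    return clusters


def threshold_sweep(
    seqs: Sequence[SeqRecord],
    thresholds: Sequence[float],
    engine: str = "greedy",
    **kwargs,
) -> pd.DataFrame:
    """Cluster at each threshold and tabulate cluster/singleton counts.

    Used to find the highest identity at which a set still forms a given
    number of families (e.g. the bat/frog two-family analysis).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    rows = []
    for t in thresholds:
        if engine == "greedy":
            clusters = greedy_centroid_cluster(seqs, t, **kwargs)
        elif engine == "single":
            clusters = single_linkage_cluster(seqs, t, **kwargs)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        rows.append(
            {
                "threshold": t,
                "n_clusters": len(clusters),
                "n_singletons": sum(1 for c in clusters if len(c) == 1),
            }
        )
    return pd.DataFrame(rows)
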