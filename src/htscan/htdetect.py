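"""From clusters to validated horizontal-transfer candidates.

A cluster becomes an HT candidate when its members span at least two taxa
at the chosen rank (class by default: vertical inheritance rarely keeps
cross-class copies more similar than within-class ones).  Each candidate is
then validated:

* flank contrast — high identity must be restricted to the element itself;
  flanks as similar as the element indicate contamination or orthology;
* reciprocal best hit — each copy's best hit in the partner species must lie
  in the partner's cluster, confirming the clustering;
* scaffold quality — copies whose flanks are truncated by scaffold ends
  (short/unplaced scaffolds) cannot be validated and demote the candidate;
* phylogenetic discordance — in the NJ tree of cluster members the
  cross-rank pair must group together to the exclusion of same-rank copies,
  and the cross-rank K2P distance must undercut the within-rank background
  (support_score < 1).

``confirmed`` requires all four verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from ._pairwise import global_align
from .clustering import Cluster, pairwise_identity
from .formats import SeqRecord, TaxonomyMap
from .mining import FlankPair, TECopy
from .phylo import DistanceMatrix, SaturationError, k2p, nj_tree

__all__ = [
    "HTCandidate",
    "filter_cross_rank",
    "flank_contrast_test",
    "rbh_confirm",
    "score_ht_support",
    "assemble_report",
]

FLANK_MAX = 0.6
CONTAMINATION_MARGIN = 0.1


@dataclass
class HTCandidate:
    cluster_id: str
    rank: str
    pairs: list[tuple[str, str]]  # cross-rank (species_a, species_b)
    best_pair: tuple[str, str] | None = None
    best_pair_copies: tuple[str, str] | None = None
    pair_identity: float = 0.0
    flank_ok: bool | None = None
    rbh_ok: bool | None = None
    scaffold_ok: bool | None = None
    tree_discordant: bool | None = None
    support_score: float | None = None
    background_k: float | None = None  # within-rank K2P median (denominator)
    status: str = "candidate"
    notes: list[str] = field(default_factory=list)

    @property
    def confirmed(self) -> bool:
        return self.status == "confirmed"

    def finalize(self, contamination: bool) -> None:
        verdicts = (self.flank_ok, self.rbh_ok, self.scaffold_ok, self.tree_discordant)
        if contamination:
            self.status = "likely_contamination"
        elif self.scaffold_ok is False:
            self.status = "likely_artefact"
        elif all(v is True for v in verdicts) and (
            self.support_score is not None and self.support_score < 1.0
        ):
            self.status = "confirmed"
        else:
            self.status = "rejected"


def filter_cross_rank(
    clusters: list[Cluster],
    copies: dict[str, TECopy],
    taxonomy: TaxonomyMap,
    rank: str = "class",
) -> list[HTCandidate]:
    """Keep clusters whose members span >= 2 taxa at ``rank``.

    Emits every cross-rank species pair; raises KeyError naming the first
    species missing from the taxonomy.
    """
    candidates: list[HTCandidate] = []
    for cluster in clusters:
        species = sorted({copies[m].species for m in cluster.member_ids})
        ranks = {sp: taxonomy.rank_of(sp, rank) for sp in species}
        if len(set(ranks.values())) < 2:
            continue
        pairs = [
            (a, b)
            for i, a in enumerate(species)
            for b in species[i + 1 :]
            if ranks[a] != ranks[b]
        ]
        candidates.append(HTCandidate(cluster_id=cluster.cluster_id, rank=rank, pairs=pairs))
    return candidates


def flank_contrast_test(
    flank_a: FlankPair,
    flank_b: FlankPair,
    te_identity: float,
    flank_max: float = FLANK_MAX,
    margin: float = CONTAMINATION_MARGIN,
) -> tuple[bool, bool, bool]:
    """Compare flanks of two candidate copies.

    Returns ``(flank_ok, contamination, scaffold_ok)``: ``flank_ok`` when
    both flank-to-flank identities stay at or below ``flank_max``
    (unrelated flanks sit near the random-DNA baseline of ~0.5 under the
    global identity kernel); ``contamination`` when a flank is nearly as
    similar as the elements themselves (identity >= te_identity - margin);
    ``scaffold_ok`` is False when any flank is truncated by a scaffold end.
    """
    scaffold_ok = not (
        flank_a.left_truncated
        or flank_a.right_truncated
        or flank_b.left_truncated
        or flank_b.right_truncated
    )
    flank_ok = True
    contamination = False
    for sa, sb in ((flank_a.left, flank_b.left), (flank_a.right, flank_b.right)):
        if not sa or not sb:
            continue  # missing flank (scaffold edge): nothing to compare
        ident = pairwise_identity(sa, sb)
        if ident > flank_max:
            flank_ok = False
        if ident >= te_identity - margin:
            contamination = True
            flank_ok = False
    return flank_ok, contamination, scaffold_ok


def rbh_confirm(
    copy_a: TECopy,
    copy_b: TECopy,
    copies: dict[str, TECopy],
    cluster_of: dict[str, str],
) -> bool:
    """True iff each copy's best hit in the partner species is in the
    partner copy's cluster (reciprocal best-hit check)."""
    for this, other in ((copy_a, copy_b), (copy_b, copy_a)):
        partners = [c for c in copies.values() if c.species == other.species]
        if not partners:
            return False
        best = max(
            partners,
            key=lambda c: (pairwise_identity(this.seq, c.seq), c.copy_id),
        )
        if cluster_of.get(best.copy_id) != cluster_of.get(other.copy_id):
            return False
    return True


def _pair_k2p(a: str, b: str) -> float:
    res = global_align(a, b)
    try:
        _, _, k = k2p(res.aligned_a, res.aligned_b)
    except SaturationError:
        k = 5.0  # saturated background pairs just need to be "large"
    return k


def score_ht_support(
    candidate: HTCandidate,
    cluster: Cluster,
    copies: dict[str, TECopy],
    taxonomy: TaxonomyMap,
    species_tree=None,
) -> tuple[float, bool | None]:
    """Distance-ratio support and NJ-tree discordance for the best pair.

    ``support_score`` = K2P(best cross-rank pair) / median K2P among
    within-rank pairs of the older (more internally diverged) rank group; a
    transferred element sits closer to its donor than the donor's own
    within-rank background, so scores < 1 support HT.  ``tree_discordant``
    is True when in the NJ tree of cluster members the cross-rank pair form
    a clade of their two species only, excluding same-rank copies from
    species that are closer in the species tree — the transferred copies
    look "too closely related" to the donor (None for clusters of < 4
    copies).
    """
    members = [copies[m] for m in cluster.member_ids]
    rank = candidate.rank
    rank_of = {c.copy_id: taxonomy.rank_of(c.species, rank) for c in members}

    # closest cross-rank copy pair
    best = None
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if rank_of[a.copy_id] == rank_of[b.copy_id]:
                continue
            k = _pair_k2p(a.seq, b.seq)
            if best is None or k < best[0]:
                best = (k, a, b)
    if best is None:
        raise ValueError("candidate cluster has no cross-rank pair")
    k_cross, copy_a, copy_b = best
    candidate.best_pair = (copy_a.species, copy_b.species)
    candidate.best_pair_copies = (copy_a.copy_id, copy_b.copy_id)

    # within-rank background, per rank group; "older" = larger median
    within: dict[str, list[float]] = {}
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            if rank_of[a.copy_id] != rank_of[b.copy_id] or a.species == b.species:
                continue
            within.setdefault(rank_of[a.copy_id], []).append(_pair_k2p(a.seq, b.seq))
    if not within:  # no cross-species within-rank pairs: fall back to within-species
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if rank_of[a.copy_id] == rank_of[b.copy_id]:
                    within.setdefault(rank_of[a.copy_id], []).append(
                        _pair_k2p(a.seq, b.seq)
                    )
    if within:
        background = max(median(v) for v in within.values())
        support = k_cross / background if background > 0 else (0.0 if k_cross == 0 else float("inf"))
    else:
        background = 0.0
        support = float("inf")
    candidate.background_k = background

    tree_discordant: bool | None = None
    if len(members) >= 4:
        dm_labels = [c.copy_id for c in members]
        import numpy as np

        n = len(members)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = _pair_k2p(members[i].seq, members[j].seq)
        tree = nj_tree(DistanceMatrix(dm_labels, m))
        species_of = {c.copy_id: c.species for c in members}
        tree_discordant = _pair_is_discordant(
            tree, copy_a.copy_id, copy_b.copy_id, species_of, rank_of, species_tree
        )
    return support, tree_discordant


def _species_distance(species_tree, a: str, b: str) -> float | None:
    if species_tree is None:
        return None
    try:
        pdm = species_tree.phylogenetic_distance_matrix()
        ta = species_tree.taxon_namespace.get_taxon(a)
        tb = species_tree.taxon_namespace.get_taxon(b)
        if ta is None or tb is None:
            return None
        return pdm.patristic_distance(ta, tb)
    except Exception:
        return None


def _pair_is_discordant(
    tree,
    id_a: str,
    id_b: str,
    species_of: dict[str, str],
    rank_of: dict[str, str],
    species_tree=None,
) -> bool:
    """Vertical descent keeps a species' copies grouped with its near
    relatives; transfer makes the donor/recipient pair form a two-species
    clade that excludes same-rank copies from closer species."""
    tree.is_rooted = True
    pdm = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if id_a not in pdm or id_b not in pdm:
        return False
    all_leaves = set(pdm)
    mrca = tree.mrca(taxa=[pdm[id_a].taxon, pdm[id_b].taxon])
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if clade == all_leaves:
        # the trifurcating NJ root may split the pair; reroot away from it
        far = max(
            (l for l in all_leaves if l != id_a),
            key=lambda l: len(tree.mrca(taxa=[pdm[id_a].taxon, pdm[l].taxon]).leaf_nodes()),
        )
        reroot = tree.clone(depth=1)
        reroot.is_rooted = True
        far_leaf = next(
            leaf for leaf in reroot.leaf_node_iter() if leaf.taxon.label == far
        )
        reroot.reroot_at_edge(far_leaf.edge, update_bipartitions=False)
        pdm = {leaf.taxon.label: leaf for leaf in reroot.leaf_node_iter()}
        mrca = reroot.mrca(taxa=[pdm[id_a].taxon, pdm[id_b].taxon])
        clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        if clade == all_leaves:
            return False
    sp_a, sp_b = species_of[id_a], species_of[id_b]
    if {species_of[x] for x in clade} - {sp_a, sp_b}:
        return False  # third species inside the pair's clade: looks vertical
    d_ab = _species_distance(species_tree, sp_a, sp_b)
    ranks_ab = {rank_of[id_a], rank_of[id_b]}
    for leaf in all_leaves - clade:
        if rank_of[leaf] not in ranks_ab:
            continue
        if d_ab is not None:
            sp_c = species_of[leaf]
            d_ca = _species_distance(species_tree, sp_c, sp_a)
            d_cb = _species_distance(species_tree, sp_c, sp_b)
            vals = [x for x in (d_ca, d_cb) if x is not None]
            if vals and min(vals) >= d_ab:
                continue
        return True
    return False


def assemble_report(candidates: list[HTCandidate]) -> pd.DataFrame:
    """Tabular HT report, sorted by support score (best candidates first)."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "rank": c.rank,
                "species_a": c.best_pair[0] if c.best_pair else "",
                "species_b": c.best_pair[1] if c.best_pair else "",
                "copy_a": c.best_pair_copies[0] if c.best_pair_copies else "",
                "copy_b": c.best_pair_copies[1] if c.best_pair_copies else "",
                "pair_identity": round(c.pair_identity, 4),
                "support_score": (
                    round(c.support_score, 4) if c.support_score is not None else ""
                ),
                "flank_ok": c.flank_ok,
                "rbh_ok": c.rbh_ok,
                "scaffold_ok": c.scaffold_ok,
                "tree_discordant": c.tree_discordant,
                "status": c.status,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "rank",
            "species_a",
            "species_b",
            "copy_a",
            "copy_b",
            "pair_identity",
            "support_score",
            "flank_ok",
            "rbh_ok",
            "scaffold_ok",
            "tree_discordant",
            "status",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            by=["support_score", "cluster_id"],
            key=lambda col: col.map(lambda v: float("inf") if v == "" else v)
            if col.name == "support_score"
            else col,
        ).reset_index(drop=True)
    return df
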