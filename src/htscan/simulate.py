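"""Synthetic TE evolution along a species tree, with ground truth.

The generator emulates the data a TE survey mines from real assemblies:
multi-species genomes containing retrotransposon copies produced by

* vertical descent: copies travel down the species tree accumulating
  substitutions under a K2P process (branch lengths in expected
  substitutions/site, transition/transversion ratio ``kappa``);
* amplification: active copies replicate ("copy and paste") as a birth
  process at ``amplification_rate`` new copies per active copy per unit
  branch length; newly inserted copies may be born inactive;
* decay: segmental deletions of 31 bp - 10 kb fragment copies
  (:func:`fragment`);
* horizontal transfer: explicit, user-specified events that carry the
  donor-lineage sequence state into a recipient branch.

Every emitted copy is recorded in a truth table (:class:`SimTruth`), so
mining recall, clustering membership and HT recovery are all measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .formats import (
    GenomeInterval,
    SeqRecord,
    TaxonomyMap,
    revcomp,
    tree_from_string,
    write_fasta,
)

__all__ = [
    "HTEvent",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "generate_species_tree",
    "plant_cross_class_events",
    "make_master_te",
    "evolve",
    "fragment",
    "write_outputs",
    "taxonomy_from_tree",
]

_BASES = np.array([65, 67, 71, 84], dtype=np.uint8)  # A C G T
_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# species trees


def generate_species_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0, height: float | None = None
):
    """Ultrametric Yule (pure-birth) tree with leaves sp1..spN.

    ``height`` rescales the root-to-tip distance (expected
    substitutions/site for the downstream simulation).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    class _N:
        __slots__ = ("start", "split", "children")

        def __init__(self, start):
            self.start = start
            self.split = None
            self.children = []

    root = _N(0.0)
    tips = [root]
    t = 0.0
    while len(tips) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        parent = tips[int(rng.integers(len(tips)))]
        parent.split = t
        parent.children = [_N(t), _N(t)]
        tips.remove(parent)
        tips.extend(parent.children)
    t += rng.exponential(1.0 / (birth_rate * len(tips)))
    present = t

    scale = 1.0
    if height is not None:
        scale = height / present

    counter = [0]

    def newick(node) -> str:
        end = node.split if node.children else present
        bl = (end - node.start) * scale
        if node.children:
            inner = ",".join(newick(c) for c in node.children)
            return f"({inner}):{bl:.10f}"
        counter[0] += 1
        return f"sp{counter[0]}:{bl:.10f}"

    return tree_from_string(newick(root) + ";")


def plant_cross_class_events(
    tree, taxonomy: TaxonomyMap, time_fraction: float = 0.9
) -> list["HTEvent"]:
    """Two reciprocal cross-class transfer events for a simulated tree.

    Deterministic rule: first species of class 1 donates into the first
    species of class 2, and the last species of class 2 donates into the
    last species of class 1.  Late ``time_fraction`` makes the transfers
    recent, the regime in which cross-class clusters are detectable.
    """
    by_class: dict[str, list[str]] = {}
    for sp in taxonomy.species():
        by_class.setdefault(taxonomy.rank_of(sp, "class"), []).append(sp)
    classes = sorted(by_class)
    if len(classes) < 2:
        raise ValueError("need at least two classes to plant cross-class events")
    c1, c2 = (sorted(by_class[c]) for c in classes[:2])
    return [
        HTEvent(donor=c1[0], recipient=c2[0], time_fraction=time_fraction),
        HTEvent(donor=c2[-1], recipient=c1[-1], time_fraction=time_fraction),
    ]


def taxonomy_from_tree(tree, n_phyla: int = 1) -> TaxonomyMap:
    """Taxonomy with classes = the two root subtrees, orders = the next split.

    With ``n_phyla`` = 2 each class also gets its own phylum, so cross-class
    and cross-phylum filters both have signal.
    """
    tax = TaxonomyMap()
    root_children = tree.seed_node.child_nodes()
    for ci, child in enumerate(root_children, start=1):
        clazz = f"Class_{ci}"
        phylum = f"Phylum_{ci if n_phyla > 1 else 1}"
        grandchildren = child.child_nodes() or [child]
        for oi, grand in enumerate(grandchildren, start=1):
            order = f"Order_{ci}_{oi}"
            leaves = [grand] if grand.is_leaf() else list(grand.leaf_iter())
            for leaf in leaves:
                tax.add(leaf.taxon.label, phylum, clazz, order)
    return tax


# ---------------------------------------------------------------------------
# master element


def make_master_te(length: int = 3200, seed: int = 0, family: str = "BovB") -> SeqRecord:
    """A synthetic canonical element of ``length`` bp (default 3.2 kb).

    Layout mimics a non-LTR retrotransposon: short 5' leader, one long open
    reading frame free of stop codons (ATG start), 3' tail.  The ORF midpoint
    region stands in for the reverse-transcriptase domain.
    """
    if length < 900:
        raise ValueError("master element must be at least 900 bp")
    rng = np.random.default_rng(seed)
    leader = 150
    tail = 150
    orf_nt = ((length - leader - tail) // 3) * 3
    n_codons = orf_nt // 3 - 2  # minus start and stop

    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS and a + b + c != "ATG"
    ]
    codons = ["ATG"] + [sense[i] for i in rng.integers(0, len(sense), n_codons)] + ["TAA"]
    orf = "".join(codons)

    def rand_dna(n: int) -> str:
        return bytes(_BASES[rng.integers(0, 4, n)]).decode()

    seq = rand_dna(leader) + orf + rand_dna(length - leader - len(orf))
    return SeqRecord(id=family, seq=seq, description=f"synthetic master element ({family})")


# ---------------------------------------------------------------------------
# configuration and truth


@dataclass(frozen=True)
class HTEvent:
    """One horizontal transfer: donor branch -> recipient branch.

    Branches are named by their child node (leaf label or internal label);
    ``time_fraction`` is the position along each branch in [0, 1].
    """

    donor: str
    recipient: str
    time_fraction: float = 0.5
    n_copies: int = 1

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("HT recipient must differ from donor")
        if not 0.0 <= self.time_fraction <= 1.0:
            raise ValueError("time_fraction must lie within the branch")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")


@dataclass
class SimConfig:
    species_tree: object  # dendropy Tree or newick string
    master_te: SeqRecord | None = None
    background_genome_length: int = 60_000
    n_ancestral_copies: int = 4
    amplification_rate: float = 1.0
    inactivation_prob: float = 0.3
    deletion_rate: float = 0.0
    deletion_size_range: tuple[int, int] = (31, 10_000)
    min_intact_length: int = 2_400
    kappa: float = 2.0
    ht_events: list[HTEvent] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.species_tree, str):
            self.species_tree = tree_from_string(self.species_tree)
        for rate in (self.amplification_rate, self.deletion_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        if not 0.0 <= self.inactivation_prob <= 1.0:
            raise ValueError("inactivation_prob must be a probability")
        lo, hi = self.deletion_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid deletion size range")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.master_te is None:
            self.master_te = make_master_te(seed=self.seed)
        labels = {leaf.taxon.label for leaf in self.species_tree.leaf_node_iter()}
        for node in self.species_tree.preorder_node_iter():
            if node.label:
                labels.add(node.label)
        for ev in self.ht_events:
            for who in (ev.donor, ev.recipient):
                if who not in labels:
                    raise ValueError(f"HT event names unknown branch {who!r}")


@dataclass
class SimTruth:
    copy_id: str
    species: str
    insertion_branch: str
    insertion_time: float
    parent_copy_id: str
    horizontal: bool
    intact: bool
    interval: GenomeInterval | None = None

    @property
    def length(self) -> int:
        return len(self.interval) if self.interval is not None else 0


@dataclass
class SimResult:
    genomes: dict[str, SeqRecord]
    truth: list[SimTruth]
    copies: dict[str, SeqRecord]  # copy_id -> element-orientation sequence
    config: SimConfig
    deletion_sizes: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence evolution


def _k2p_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(same, transition, each-transversion) probabilities after time t.

    Rates normalised to one expected substitution per site per unit time.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return p_same, p_ti, p_tv


def evolve_sequence(codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Apply the K2P substitution process for time ``t`` to base codes 0..3."""
    if t <= 0:
        return codes.copy()
    p_same, p_ti, p_tv = _k2p_probs(t, kappa)
    u = rng.random(codes.shape[0])
    out = codes.copy()
    ti_mask = (u >= p_same) & (u < p_same + p_ti)
    tv1_mask = (u >= p_same + p_ti) & (u < p_same + p_ti + p_tv)
    tv2_mask = u >= p_same + p_ti + p_tv
    out[ti_mask] ^= 2  # A<->G, C<->T
    out[tv1_mask] ^= 1
    out[tv2_mask] ^= 3
    return out


def _encode_dna(seq: str) -> np.ndarray:
    lookup = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lookup[ord(b)] = i
    return lookup[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode_dna(codes: np.ndarray) -> str:
    return bytes(_BASES[codes]).decode()


@dataclass
class _Copy:
    copy_id: str
    codes: np.ndarray
    active: bool
    birth_time: float
    birth_branch: str
    parent_id: str
    horizontal: bool
    t_updated: float


class _Sim:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.counter = 0
        self.snapshots: dict[tuple[str, float], list[_Copy]] = {}

    def new_id(self) -> str:
        self.counter += 1
        return f"te{self.counter:05d}"

    def _advance(self, cp: _Copy, t: float) -> None:
        if t > cp.t_updated:
            cp.codes = evolve_sequence(cp.codes, t - cp.t_updated, self.cfg.kappa, self.rng)
            cp.t_updated = t

    def simulate_branch(
        self,
        copies: list[_Copy],
        branch_name: str,
        t0: float,
        t1: float,
        snapshot_times: Iterable[float] = (),
        horizontal: bool = False,
    ) -> list[_Copy]:
        """Amplification + substitution along one branch (Gillespie)."""
        cfg = self.cfg
        snap_times = sorted(snapshot_times)
        t = t0
        while True:
            active = [c for c in copies if c.active]
            rate = cfg.amplification_rate * len(active)
            t_next = t + (self.rng.exponential(1.0 / rate) if rate > 0 else np.inf)
            while snap_times and snap_times[0] <= min(t_next, t1):
                ts = snap_times.pop(0)
                for c in copies:
                    self._advance(c, ts)
                self.snapshots[(branch_name, ts)] = [
                    replace(c, codes=c.codes.copy()) for c in copies
                ]
            if t_next > t1:
                break
            t = t_next
            parent = active[int(self.rng.integers(len(active)))]
            self._advance(parent, t)
            child = _Copy(
                copy_id=self.new_id(),
                codes=parent.codes.copy(),
                active=bool(self.rng.random() >= cfg.inactivation_prob),
                birth_time=t,
                birth_branch=branch_name,
                parent_id=parent.copy_id,
                horizontal=horizontal or parent.horizontal,
                t_updated=t,
            )
            copies.append(child)
        for c in copies:
            self._advance(c, t1)
        return copies

    def _branch_name(self, node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or f"node{id(node) % 10_000}"


def _node_times(tree) -> dict:
    times = {}
    for node in tree.preorder_node_iter():
        parent_t = times[node.parent_node] if node.parent_node else 0.0
        bl = node.edge.length or 0.0
        times[node] = parent_t + bl
    return times


def evolve(config: SimConfig) -> SimResult:
    """Run the simulation: returns genomes, truth table and copy sequences."""
    tree = config.species_tree
    sim = _Sim(config)
    master_codes = _encode_dna(config.master_te.seq)
    times = _node_times(tree)

    # label internal nodes deterministically for branch naming
    internal_counter = [0]
    names: dict[object, str] = {}
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            names[node] = node.taxon.label
        elif node.label:
            names[node] = node.label
        else:
            internal_counter[0] += 1
            names[node] = f"anc{internal_counter[0]}"

    events_by_donor: dict[str, list[HTEvent]] = {}
    for ev in config.ht_events:
        events_by_donor.setdefault(ev.donor, []).append(ev)

    def branch_window(name: str) -> tuple[object, float, float]:
        for node in tree.preorder_node_iter():
            if names[node] == name:
                t1 = times[node]
                t0 = times[node.parent_node] if node.parent_node else 0.0
                return node, t0, t1
        raise KeyError(name)

    # phase 1: vertical descent, recording donor snapshots
    root = tree.seed_node
    ancestral = []
    for _ in range(config.n_ancestral_copies):
        ancestral.append(
            _Copy(
                copy_id=sim.new_id(),
                codes=master_codes.copy(),
                active=True,
                birth_time=0.0,
                birth_branch=names[root],
                parent_id="master",
                horizontal=False,
                t_updated=0.0,
            )
        )

    leaf_copies: dict[str, list[_Copy]] = {}

    def descend(node, copies: list[_Copy]) -> None:
        name = names[node]
        t1 = times[node]
        t0 = times[node.parent_node] if node.parent_node else 0.0
        snaps = []
        for ev in events_by_donor.get(name, ()):  # donor sampling times
            snaps.append(t0 + ev.time_fraction * (t1 - t0))
        copies = sim.simulate_branch(copies, name, t0, t1, snapshot_times=snaps)
        if node.is_leaf():
            leaf_copies[name] = copies
            return
        for child in node.child_nodes():
            cloned = [replace(c, codes=c.codes.copy()) for c in copies]
            descend(child, cloned)

    descend(root, ancestral)

    # phase 2: horizontal lineages, seeded from donor snapshots
    for ev in config.ht_events:
        d_node, d0, d1 = branch_window(ev.donor)
        t_evt_donor = d0 + ev.time_fraction * (d1 - d0)
        snapshot = sim.snapshots.get((ev.donor, t_evt_donor))
        if not snapshot:
            raise RuntimeError(f"no donor snapshot for event {ev}")
        donors = [c for c in snapshot if c.active] or snapshot
        r_node, r0, r1 = branch_window(ev.recipient)
        t_evt = r0 + ev.time_fraction * (r1 - r0)
        founders = []
        for _ in range(ev.n_copies):
            src = donors[int(sim.rng.integers(len(donors)))]
            founders.append(
                _Copy(
                    copy_id=sim.new_id(),
                    codes=src.codes.copy(),
                    active=True,
                    birth_time=t_evt,
                    birth_branch=names[r_node],
                    parent_id=src.copy_id,
                    horizontal=True,
                    t_updated=t_evt,
                )
            )

        def descend_ht(node, copies: list[_Copy], t_from: float) -> None:
            name = names[node]
            copies = sim.simulate_branch(copies, name, t_from, times[node], horizontal=True)
            if node.is_leaf():
                leaf_copies[name].extend(copies)
                return
            for child in node.child_nodes():
                cloned = [replace(c, codes=c.codes.copy()) for c in copies]
                descend_ht(child, cloned, times[node])

        descend_ht(r_node, founders, t_evt)

    # genome emission
    genomes: dict[str, SeqRecord] = {}
    truth: list[SimTruth] = []
    copy_records: dict[str, SeqRecord] = {}
    bg_len = config.background_genome_length
    for species in sorted(leaf_copies):
        copies = leaf_copies[species]
        if bg_len < 10 * max(len(copies), 1):
            raise ValueError("background genome too small for the copy load")
        bg = sim.rng.integers(0, 4, bg_len).astype(np.uint8)
        offsets = np.sort(sim.rng.choice(bg_len, size=len(copies), replace=False))
        pieces = []
        prev = 0
        shift = 0
        scaffold = f"{species}_scaf1"
        for cp, off in zip(copies, offsets):
            pieces.append(bg[prev:off])
            strand = "+" if sim.rng.random() < 0.5 else "-"
            element = _decode_dna(cp.codes)
            inserted = element if strand == "+" else revcomp(element)
            pieces.append(_encode_dna(inserted))
            start = off + shift
            interval = GenomeInterval(scaffold, start, start + len(element), strand)
            shift += len(element)
            prev = off
            truth.append(
                SimTruth(
                    copy_id=f"{species}.{cp.copy_id}",
                    species=species,
                    insertion_branch=cp.birth_branch,
                    insertion_time=cp.birth_time,
                    parent_copy_id=cp.parent_id,
                    horizontal=cp.horizontal,
                    intact=len(element) >= config.min_intact_length,
                    interval=interval,
                )
            )
            copy_records[f"{species}.{cp.copy_id}"] = SeqRecord(
                id=f"{species}.{cp.copy_id}", seq=element
            )
        pieces.append(bg[prev:])
        genomes[species] = SeqRecord(id=scaffold, seq=_decode_dna(np.concatenate(pieces)))

    result = SimResult(genomes=genomes, truth=truth, copies=copy_records, config=config)
    if config.deletion_rate > 0:
        result = fragment(
            result,
            deletion_rate=config.deletion_rate,
            size_range=config.deletion_size_range,
            min_intact_length=config.min_intact_length,
            seed=config.seed + 1,
        )
    return result


# ---------------------------------------------------------------------------
# decay


def fragment(
    result: SimResult,
    deletion_rate: float,
    size_range: tuple[int, int] = (31, 10_000),
    min_intact_length: int = 2_400,
    seed: int = 0,
) -> SimResult:
    """Apply segmental deletions (sizes uniform in ``size_range``) to copies.

    ``deletion_rate`` is the expected number of deletion events per copy.
    Truth intervals are shifted/shrunk; copies whose remainder falls below
    ``min_intact_length`` are marked not intact.
    """
    if deletion_rate <= 0:
        return result
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    genomes = dict(result.genomes)
    truth = [replace(t) for t in result.truth]
    by_species: dict[str, list[SimTruth]] = {}
    for t in truth:
        by_species.setdefault(t.species, []).append(t)

    new_copies = dict(result.copies)
    deletion_sizes: list[int] = []
    for species, rows in by_species.items():
        genome = genomes[species].seq
        deletions: list[tuple[int, int]] = []
        for row in rows:
            n_del = rng.poisson(deletion_rate)
            for _ in range(n_del):
                size = int(rng.integers(lo, hi + 1))
                deletion_sizes.append(size)
                centre = int(rng.integers(row.interval.start, row.interval.end))
                d0 = max(centre - size // 2, 0)
                d1 = min(d0 + size, len(genome))
                deletions.append((d0, d1))
        if not deletions:
            continue
        deletions.sort()
        merged = [list(deletions[0])]
        for d0, d1 in deletions[1:]:
            if d0 <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], d1)
            else:
                merged.append([d0, d1])
        keep = []
        prev = 0
        for d0, d1 in merged:
            keep.append(genome[prev:d0])
            prev = d1
        keep.append(genome[prev:])
        genomes[species] = SeqRecord(id=genomes[species].id, seq="".join(keep))

        def remap(pos: int) -> int:
            shift = 0
            for d0, d1 in merged:
                if pos <= d0:
                    break
                shift += min(pos, d1) - d0
            return pos - shift

        for row in rows:
            iv = row.interval
            new_start, new_end = remap(iv.start), remap(iv.end)
            if new_end - new_start <= 0:
                row.interval = None
                row.intact = False
                new_copies.pop(row.copy_id, None)
                continue
            row.interval = GenomeInterval(iv.scaffold, new_start, new_end, iv.strand)
            row.intact = (new_end - new_start) >= min_intact_length
            piece = genomes[species].seq[new_start:new_end]
            element = piece if iv.strand == "+" else revcomp(piece)
            new_copies[row.copy_id] = SeqRecord(id=row.copy_id, seq=element)

    return SimResult(
        genomes=genomes,
        truth=truth,
        copies=new_copies,
        config=result.config,
        deletion_sizes=result.deletion_sizes + deletion_sizes,
    )


# ---------------------------------------------------------------------------
# output


def write_outputs(result: SimResult, out_dir: str | Path, taxonomy: TaxonomyMap | None = None) -> None:
    """Emit per-species FASTA, truth.tsv, species_tree.nwk and provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gdir = out / "genomes"
    gdir.mkdir(exist_ok=True)
    for species in sorted(result.genomes):
        write_fasta([result.genomes[species]], gdir / f"{species}.fa")
    write_fasta([result.config.master_te], out / "library.fa")
    with open(out / "truth.tsv", "w") as fh:
        fh.write(
            "copy_id\tspecies\tscaffold\tstart\tend\tstrand\tinsertion_branch\t"
            "insertion_time\tparent_copy_id\thorizontal\tintact\n"
        )
        for row in result.truth:
            iv = row.interval
            fh.write(
                "\t".join(
                    [
                        row.copy_id,
                        row.species,
                        iv.scaffold if iv else "",
                        str(iv.start) if iv else "",
                        str(iv.end) if iv else "",
                        iv.strand if iv else "",
                        row.insertion_branch,
                        f"{row.insertion_time:.6f}",
                        row.parent_copy_id,
                        str(int(row.horizontal)),
                        str(int(row.intact)),
                    ]
                )
                + "\n"
            )
    result.config.species_tree.write(
        path=str(out / "species_tree.nwk"), schema="newick", suppress_rooting=True
    )
    if taxonomy is not None:
        taxonomy.write_tsv(out / "taxonomy.tsv")
    with open(out / "provenance.txt", "w") as fh:
        cfg = result.config
        fh.write(
            f"seed={cfg.seed}\nn_species={len(result.genomes)}\n"
            f"amplification_rate={cfg.amplification_rate}\n"
            f"inactivation_prob={cfg.inactivation_prob}\n"
            f"deletion_rate={cfg.deletion_rate}\n"
            f"ht_events={[(e.donor, e.recipient, e.time_fraction, e.n_copies) for e in cfg.ht_events]}\n"
        )
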