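"""End-to-end orchestration: simulate -> mine -> features -> cluster ->
detect -> divergence.

Each stage is a plain function over in-memory objects; :func:`run_pipeline`
wires them together on disk with per-stage outputs, a provenance log and a
fixed seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clustering import Cluster, greedy_centroid_cluster, pairwise_identity, single_linkage_cluster
from .features import find_orfs
from .formats import (
    SeqRecord,
    TaxonomyMap,
    copy_description,
    read_fasta,
    read_taxonomy,
    write_cluster_table,
    write_fasta,
)
from .htdetect import (
    HTCandidate,
    assemble_report,
    filter_cross_rank,
    flank_contrast_test,
    rbh_confirm,
    score_ht_support,
)
from .mining import TECopy, extract_flanks, mine_genome
from .phylo import divergence_landscape
from .simulate import (
    HTEvent,
    SimConfig,
    evolve,
    generate_species_tree,
    taxonomy_from_tree,
    write_outputs,
)

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline", "detect_ht"]


class ConfigError(ValueError):
    pass


_DEFAULTS: dict = {
    "seed": 0,
    "out": "htscan_run",
    "rank": "class",
    "simulate": {
        "enabled": True,
        "n_species": 12,
        "tree_height": 0.35,
        "birth_rate": 1.0,
        "master_length": 3200,
        "background_genome_length": 60_000,
        "n_ancestral_copies": 4,
        "amplification_rate": 1.0,
        "inactivation_prob": 0.3,
        "deletion_rate": 0.0,
        "kappa": 2.0,
        "ht_events": [],  # list of {donor, recipient, time_fraction, n_copies}
    },
    "inputs": {
        "genomes_dir": "",
        "library": "",
        "taxonomy": "",
        "species_tree": "",
    },
    "mine": {
        "word_size": 11,
        "x_drop": 20.0,
        "min_identity": 0.5,
        "min_length": 100,
        "max_gap": 500,
    },
    "cluster": {"engine": "greedy", "threshold": 0.6},
    "detect": {"flank_len": 1000, "flank_max": 0.6, "margin": 0.1},
    "divergence": {"enabled": True, "bin_width": 1.0},
}


@dataclass
class PipelineConfig:
    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, value in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown config key {path + key!r}")
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict) and isinstance(uval, dict):
                out[key] = _merge(dval, uval, path=f"{path}{key}.")
            else:
                out[key] = uval
        else:
            out[key] = json.loads(json.dumps(dval))  # deep copy
    return out


def validate_config(user: dict | None = None) -> PipelineConfig:
    """Merge user settings over defaults; unknown keys and bad ranges fail."""
    cfg = _merge(_DEFAULTS, user or {})
    t = cfg["cluster"]["threshold"]
    if not 0.0 < t <= 1.0:
        raise ConfigError(f"cluster.threshold must be in (0, 1], got {t}")
    if cfg["cluster"]["engine"] not in ("greedy", "single"):
        raise ConfigError(f"unknown cluster.engine {cfg['cluster']['engine']!r}")
    if cfg["rank"] not in ("class", "phylum"):
        raise ConfigError(f"rank must be class or phylum, got {cfg['rank']!r}")
    if cfg["mine"]["word_size"] < 8:
        raise ConfigError("mine.word_size must be >= 8")
    if not cfg["simulate"]["enabled"]:
        for key in ("genomes_dir", "library", "taxonomy"):
            if not cfg["inputs"][key]:
                raise ConfigError(f"inputs.{key} is required when simulation is off")
    for ev in cfg["simulate"]["ht_events"]:
        for need in ("donor", "recipient"):
            if need not in ev:
                raise ConfigError(f"ht_event missing {need!r}: {ev}")
    return PipelineConfig(cfg)


# ---------------------------------------------------------------------------
# detect stage


def detect_ht(
    copies: dict[str, TECopy],
    clusters: list[Cluster],
    scaffolds: dict[str, SeqRecord],
    taxonomy: TaxonomyMap,
    rank: str = "class",
    flank_len: int = 1000,
    flank_max: float = 0.6,
    margin: float = 0.1,
    species_tree=None,
) -> list[HTCandidate]:
    """Validate every cross-rank cluster and assign statuses."""
    cluster_of = {m: c.cluster_id for c in clusters for m in c.member_ids}
    cluster_by_id = {c.cluster_id: c for c in clusters}
    candidates = filter_cross_rank(clusters, copies, taxonomy, rank)
    from .htdetect import _pair_k2p

    def _global_best_partner(fixed, partner_rank):
        pool = [
            c
            for c in copies.values()
            if taxonomy.rank_of(c.species, rank) == partner_rank
        ]
        return max(pool, key=lambda c: (pairwise_identity(fixed.seq, c.seq), c.copy_id))

    for cand in candidates:
        cluster = cluster_by_id[cand.cluster_id]
        support, discordant = score_ht_support(
            cand, cluster, copies, taxonomy, species_tree=species_tree
        )
        cand.support_score = support
        cand.tree_discordant = discordant
        copy_a = copies[cand.best_pair_copies[0]]
        copy_b = copies[cand.best_pair_copies[1]]
        # refine the reported pair against every mined copy: greedy
        # clustering may strand the closest partner (e.g. the transfer
        # donor) in a different cluster
        copy_a = _global_best_partner(copy_b, taxonomy.rank_of(copy_a.species, rank))
        copy_b = _global_best_partner(copy_a, taxonomy.rank_of(copy_b.species, rank))
        cand.best_pair = (copy_a.species, copy_b.species)
        cand.best_pair_copies = (copy_a.copy_id, copy_b.copy_id)
        if cand.background_k and cand.background_k > 0:
            cand.support_score = _pair_k2p(copy_a.seq, copy_b.seq) / cand.background_k
        cand.pair_identity = pairwise_identity(copy_a.seq, copy_b.seq)
        flank_a = extract_flanks(copy_a, scaffolds[copy_a.interval.scaffold], flank_len)
        flank_b = extract_flanks(copy_b, scaffolds[copy_b.interval.scaffold], flank_len)
        flank_ok, contamination, scaffold_ok = flank_contrast_test(
            flank_a, flank_b, cand.pair_identity, flank_max=flank_max, margin=margin
        )
        cand.flank_ok = flank_ok
        cand.scaffold_ok = scaffold_ok
        cand.rbh_ok = rbh_confirm(copy_a, copy_b, copies, cluster_of)
        cand.finalize(contamination)
    return candidates


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path | None = None):
    """Run all stages; returns (candidates, report DataFrame, run directory)."""
    if isinstance(config, dict):
        config = validate_config(config)
    cfg = config.data
    out = Path(out_dir if out_dir is not None else cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log_lines = [f"htscan {__version__}", f"seed={seed}", f"config_hash={_hash(cfg)}"]

    # --- stage: inputs (simulated or provided) ---
    if cfg["simulate"]["enabled"]:
        sim = cfg["simulate"]
        tree = generate_species_tree(
            sim["n_species"], birth_rate=sim["birth_rate"], seed=seed,
            height=sim["tree_height"],
        )
        taxonomy = taxonomy_from_tree(tree, n_phyla=2)
        events = [
            HTEvent(
                donor=ev["donor"],
                recipient=ev["recipient"],
                time_fraction=ev.get("time_fraction", 0.5),
                n_copies=ev.get("n_copies", 1),
            )
            for ev in sim["ht_events"]
        ]
        sim_config = SimConfig(
            species_tree=tree,
            background_genome_length=sim["background_genome_length"],
            n_ancestral_copies=sim["n_ancestral_copies"],
            amplification_rate=sim["amplification_rate"],
            inactivation_prob=sim["inactivation_prob"],
            deletion_rate=sim["deletion_rate"],
            kappa=sim["kappa"],
            ht_events=events,
            seed=seed,
        )
        result = evolve(sim_config)
        write_outputs(result, out / "sim", taxonomy=taxonomy)
        genomes = {sp: [rec] for sp, rec in result.genomes.items()}
        library = [result.config.master_te]
        species_tree = tree
        log_lines.append(f"simulated {len(genomes)} genomes")
    else:
        gdir = Path(cfg["inputs"]["genomes_dir"])
        genomes = {
            p.stem: read_fasta(p) for p in sorted(gdir.glob("*.fa")) + sorted(gdir.glob("*.fasta"))
        }
        if not genomes:
            raise FileNotFoundError(f"no genome FASTA found in {gdir}")
        library = read_fasta(cfg["inputs"]["library"])
        taxonomy = read_taxonomy(cfg["inputs"]["taxonomy"])
        species_tree = None
        if cfg["inputs"]["species_tree"]:
            from .formats import read_newick

            species_tree = read_newick(cfg["inputs"]["species_tree"])
        log_lines.append(f"loaded {len(genomes)} genomes")

    # --- stage: mine ---
    mine_cfg = cfg["mine"]
    copies: dict[str, TECopy] = {}
    scaffolds: dict[str, SeqRecord] = {}
    for species in sorted(genomes):
        for scaffold_rec in genomes[species]:
            scaffolds[scaffold_rec.id] = scaffold_rec
            for cp in mine_genome(
                scaffold_rec,
                library,
                species,
                word_size=mine_cfg["word_size"],
                x_drop=mine_cfg["x_drop"],
                min_identity=mine_cfg["min_identity"],
                min_length=mine_cfg["min_length"],
                max_gap=mine_cfg["max_gap"],
            ):
                copies[cp.copy_id] = cp
    copy_records = [
        SeqRecord(cp.copy_id, cp.seq, copy_description(cp.species, cp.interval))
        for cp in copies.values()
    ]
    write_fasta(copy_records, out / "copies.fa")
    _write_copy_table(copies, out / "copies.tsv")
    log_lines.append(f"mined {len(copies)} copies")

    # --- stage: features (intactness via ORF presence) ---
    for cp in copies.values():
        if cp.intact:
            cp.intact = bool(find_orfs(cp.seq, min_aa_len=200))

    # --- stage: cluster ---
    cl_cfg = cfg["cluster"]
    seq_records = [SeqRecord(cp.copy_id, cp.seq) for cp in copies.values()]
    if cl_cfg["engine"] == "greedy":
        clusters = greedy_centroid_cluster(seq_records, cl_cfg["threshold"])
    else:
        clusters = single_linkage_cluster(seq_records, cl_cfg["threshold"])
    write_cluster_table(clusters, out / "clusters.tsv", copies=copies, taxonomy=taxonomy)
    log_lines.append(f"{len(clusters)} clusters at threshold {cl_cfg['threshold']}")

    # --- stage: detect ---
    det = cfg["detect"]
    candidates = detect_ht(
        copies,
        clusters,
        scaffolds,
        taxonomy,
        rank=cfg["rank"],
        flank_len=det["flank_len"],
        flank_max=det["flank_max"],
        margin=det["margin"],
        species_tree=species_tree,
    )
    report = assemble_report(candidates)
    report.to_csv(out / "ht_report.tsv", sep="\t", index=False)
    n_confirmed = sum(1 for c in candidates if c.confirmed)
    log_lines.append(f"{len(candidates)} candidates, {n_confirmed} confirmed")

    # --- stage: divergence ---
    if cfg["divergence"]["enabled"]:
        with open(out / "landscapes.tsv", "w") as fh:
            fh.write("species\tfamily\tbin_start\tbin_end\tcoverage_bp\n")
            for species in sorted(genomes):
                for ref in library:
                    sp_copies = [
                        SeqRecord(cp.copy_id, cp.seq)
                        for cp in copies.values()
                        if cp.species == species and cp.family == ref.id
                    ]
                    if not sp_copies:
                        continue
                    profile = divergence_landscape(
                        sp_copies,
                        ref,
                        bin_width=cfg["divergence"]["bin_width"],
                        species=species,
                        family=ref.id,
                    )
                    for b0, b1, cov in profile.to_rows():
                        fh.write(f"{species}\t{ref.id}\t{b0:g}\t{b1:g}\t{cov}\n")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return candidates, report, out


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write_copy_table(copies: dict[str, TECopy], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "scaffold\tstart\tend\tcopy_id\tidentity\tstrand\tspecies\tfamily\tintact\tconfirmed\n"
        )
        for cp in copies.values():
            iv = cp.interval
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{cp.copy_id}\t"
                f"{cp.identity_to_query:.4f}\t{iv.strand}\t{cp.species}\t{cp.family}\t"
                f"{int(cp.intact)}\t{'' if cp.confirmed is None else int(cp.confirmed)}\n"
            )
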