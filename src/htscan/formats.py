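"""Sequence, tree and table I/O plus the coordinate conventions used pipeline-wide.

Conventions fixed here and relied on by every other module:

* DNA is uppercase over ``{A, C, G, T, N}``; ``U`` is mapped to ``T`` and any
  other ambiguity code to ``N`` on read.
* Genomic coordinates are 0-based half-open (BED-style).  Minus-strand
  extraction returns the reverse complement of the plus-strand slice.
* Mined-copy FASTA headers carry ``species|scaffold|start|end|strand``
  metadata in the description; plain headers are tolerated everywhere.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "GenomeInterval",
    "TaxonomyMap",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_taxonomy",
    "write_cluster_table",
]

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# anything that is not a canonical base collapses to N
_DNA_CLEAN = re.compile(r"[^ACGTN]")


@dataclass
class SeqRecord:
    """A named sequence (DNA or amino acid)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on a named scaffold."""

    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def extract(self, genome_seq: str) -> str:
        """Slice the plus-strand genome; reverse-complement for minus strand."""
        if self.end > len(genome_seq):
            raise ValueError(
                f"interval {self.start}-{self.end} beyond scaffold of "
                f"length {len(genome_seq)}"
            )
        piece = genome_seq[self.start : self.end]
        return revcomp(piece) if self.strand == "-" else piece


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def _sanitize_dna(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    return _DNA_CLEAN.sub("N", seq)


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SeqRecord]:
    """Read a (possibly wrapped) FASTA file into a list of :class:`SeqRecord`.

    DNA mode uppercases, maps U->T and collapses non-ACGTN ambiguity codes to
    N.  Duplicate ids and empty sequences are errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        if alphabet == "dna":
            seq = _sanitize_dna(seq)
        else:
            seq = seq.upper()
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(SeqRecord(id=rec.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def copy_description(species: str, interval: GenomeInterval) -> str:
    """Mined-copy metadata string: species|scaffold|start|end|strand."""
    return "|".join(
        [species, interval.scaffold, str(interval.start), str(interval.end), interval.strand]
    )


def parse_copy_description(desc: str) -> tuple[str, GenomeInterval] | None:
    """Inverse of :func:`copy_description`; None for plain headers."""
    parts = desc.split("|")
    if len(parts) != 5:
        return None
    species, scaffold, start, end, strand = parts
    try:
        return species, GenomeInterval(scaffold, int(start), int(end), strand)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# trees


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single newick tree; malformed input and duplicate leaf
    labels raise ValueError."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"cannot parse newick file {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate leaf labels in {path}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# taxonomy


@dataclass
class TaxonomyMap:
    """species -> (phylum, class, order) lookup.

    Rank names follow Linnaean usage; ``rank_of`` accepts "phylum", "class"
    or "order".
    """

    entries: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    _RANK_INDEX = {"phylum": 0, "class": 1, "order": 2}

    def add(self, species: str, phylum: str, clazz: str, order: str) -> None:
        self.entries[species] = (phylum, clazz, order)

    def rank_of(self, species: str, rank: str) -> str:
        try:
            entry = self.entries[species]
        except KeyError:
            raise KeyError(f"species {species!r} missing from taxonomy table") from None
        return entry[self._RANK_INDEX[rank]]

    def __contains__(self, species: str) -> bool:
        return species in self.entries

    def species(self) -> list[str]:
        return sorted(self.entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["species", "phylum", "class", "order"])
            for sp in sorted(self.entries):
                w.writerow([sp, *self.entries[sp]])


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    tax = TaxonomyMap()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        cols = {name.lower(): i for i, name in enumerate(header)}
        for need in ("species", "phylum", "class", "order"):
            if need not in cols:
                raise ValueError(f"taxonomy table {path} lacks column {need!r}")
        for row in reader:
            if not row:
                continue
            tax.add(
                row[cols["species"]],
                row[cols["phylum"]],
                row[cols["class"]],
                row[cols["order"]],
            )
    return tax


# ---------------------------------------------------------------------------
# cluster tables

_CLUSTER_COLUMNS = [
    "cluster_id",
    "member_id",
    "species",
    "class",
    "phylum",
    "length",
    "identity_to_centroid",
]


def write_cluster_table(
    clusters,
    path: str | Path,
    copies: Mapping[str, "object"] | None = None,
    taxonomy: TaxonomyMap | None = None,
) -> None:
    """Write a TSV of cluster membership.

    ``copies`` optionally maps member id -> TECopy-like object (``species``
    and ``seq`` attributes) to fill the species/length columns; taxonomy
    fills class/phylum.  Missing metadata leaves fields empty.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CLUSTER_COLUMNS)
        for cluster in clusters:
            for member in cluster.member_ids:
                species = length = clazz = phylum = ""
                if copies is not None and member in copies:
                    cp = copies[member]
                    species = getattr(cp, "species", "")
                    seq = getattr(cp, "seq", "")
                    length = str(len(seq)) if seq else ""
                if taxonomy is not None and species and species in taxonomy:
                    clazz = taxonomy.rank_of(species, "class")
                    phylum = taxonomy.rank_of(species, "phylum")
                ident = cluster.member_identity.get(member, "")
                w.writerow(
                    [
                        cluster.cluster_id,
                        member,
                        species,
                        clazz,
                        phylum,
                        length,
                        f"{ident:.4f}" if ident != "" else "",
                    ]
                )


def fasta_string(records: Iterable[SeqRecord]) -> str:
    buf = io.StringIO()
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        buf.write(f">{header}\n{rec.seq}\n")
    return buf.getvalue()
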