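"""Read/write the standard formats and assemble validated in-memory objects.

Coordinates are 0-based half-open everywhere internally; human-readable
reports convert to 1-based closed. Gap/N policy is *not* applied at read
time — each statistics module decides its own deletion rule, so there is a
single source of truth per statistic.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC_NUC = set("ACGTURYSWKMBDHVN-")
UNAMBIGUOUS = set("ACGTN-")


class AlignmentError(ValueError):
    """Sequences of unequal length where an alignment is required."""


class IdentityError(ValueError):
    """Duplicate identifiers."""


class ParseError(ValueError):
    """Malformed input file."""


class ReferenceError_(KeyError):
    """A cross-reference to an identifier that does not exist."""


class PhaseError(ValueError):
    """An individual without exactly two phased haplotypes."""


@dataclass
class CodonAlignment:
    """Aligned in-frame nucleotide sequences, the substrate of codon statistics.

    ``frame_offset`` is the 0-based nucleotide offset of the first codon.
    """

    taxa: list[str]
    sequences: list[str]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa and sequences differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise IdentityError("duplicate sequence identifiers")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        for taxon, seq in zip(self.taxa, self.sequences):
            bad = set(seq) - IUPAC_NUC
            if bad:
                raise ParseError(f"non-IUPAC symbols {sorted(bad)} in {taxon!r}")
        if self.frame_offset < 0 or (self.sequences and self.frame_offset > self.length):
            raise ValueError("frame_offset outside the alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame_offset) // 3

    def sequence(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise ReferenceError_(f"unknown taxon {taxon!r}") from None

    def coding(self, taxon: str) -> str:
        """In-frame coding portion of one sequence (whole codons only)."""
        seq = self.sequence(taxon)
        return seq[self.frame_offset : self.frame_offset + 3 * self.n_codons]

    def subset(self, taxa: Iterable[str]) -> "CodonAlignment":
        taxa = list(taxa)
        return CodonAlignment(taxa, [self.sequence(t) for t in taxa], self.frame_offset)


@dataclass
class PhyloTree:
    """Rooted tree over alignment taxa; branches are the analysis units.

    Wraps a dendropy tree. Every node carries a stable string id: the taxon
    label at leaves, the Newick label at labelled internal nodes, else
    ``nodeK`` assigned in preorder.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        counter = 0
        seen: set[str] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                node_id = node.taxon.label if node.taxon else node.label
            else:
                node_id = node.label
            if not node_id or node_id in seen:
                while f"node{counter}" in seen:
                    counter += 1
                node_id = f"node{counter}"
            seen.add(node_id)
            node.label = node_id if not node.is_leaf() else node.label
            node.annotations["node_id"] = node_id
            if node.edge.length is None:
                node.edge.length = 0.0
            if node.edge.length < 0:
                raise ValueError(f"negative branch length at {node_id}")

    @staticmethod
    def node_id(node: dendropy.Node) -> str:
        return str(node.annotations["node_id"].value)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def branches(self) -> list[tuple[str, str, float]]:
        """(parent_id, child_id, length) for every branch, preorder."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                out.append(
                    (self.node_id(node.parent_node), self.node_id(node), node.edge.length)
                )
        return out

    def postorder(self):
        return self.tree.postorder_node_iter()

    def preorder(self):
        return self.tree.preorder_node_iter()


@dataclass
class PopulationSample:
    """Phased haplotypes with individual/phase labels and a region map.

    Each individual contributes exactly two haplotypes. ``region_map`` holds
    named half-open intervals (e.g. coding, flank3) in alignment coordinates.
    """

    alignment: CodonAlignment
    individuals: list[str]
    phases: list[int]
    sequence_ids: list[str]
    populations: list[str | None]
    region_map: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts: dict[str, list[int]] = {}
        for ind, ph in zip(self.individuals, self.phases):
            counts.setdefault(ind, []).append(ph)
        for ind, phs in counts.items():
            if sorted(phs) != [1, 2]:
                raise PhaseError(
                    f"individual {ind!r} has phases {sorted(phs)}, expected [1, 2]"
                )
        for sid in self.sequence_ids:
            if sid not in self.alignment.taxa:
                raise ReferenceError_(f"sequence_id {sid!r} absent from alignment")
        for name, (start, end) in self.region_map.items():
            if not (0 <= start < end <= self.alignment.length):
                raise ValueError(f"region {name!r} [{start},{end}) outside alignment")

    @property
    def n_individuals(self) -> int:
        return len(set(self.individuals))

    def haplotypes(self, region: str | tuple[int, int] | None = None) -> list[str]:
        """Haplotype sequences, optionally sliced to a named or explicit region."""
        seqs = [self.alignment.sequence(sid) for sid in self.sequence_ids]
        if region is None:
            return seqs
        start, end = self.region_map[region] if isinstance(region, str) else region
        return [s[start:end] for s in seqs]


@dataclass
class RegionAnnotation:
    """Protein segments (TM/EC/IC) as half-open amino-acid intervals plus the
    set of functionally essential positions."""

    segments: dict[str, tuple[int, int]]
    essential_positions: frozenset[int]
    protein_length: int

    def __post_init__(self) -> None:
        ivals = sorted(self.segments.values())
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("overlapping protein segments")
        for s, e in ivals:
            if not (0 <= s < e <= self.protein_length):
                raise ValueError("segment outside protein length")
        if any(p < 0 or p >= self.protein_length for p in self.essential_positions):
            raise ValueError("essential position outside protein length")

    def region_of(self, position: int) -> str:
        for name, (s, e) in self.segments.items():
            if s <= position < e:
                return name
        return "unannotated"


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta_alignment(path: str | Path, frame_offset: int = 0) -> CodonAlignment:
    """Read an aligned FASTA file into a validated CodonAlignment.

    Input order is preserved; bases are uppercased; the identifier is the
    description line up to the first whitespace.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return CodonAlignment(
        taxa=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
        frame_offset=frame_offset,
    )


def write_fasta_alignment(aln: CodonAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n{seq}\n")


def read_newick(source: str | Path) -> PhyloTree:
    """Read a rooted Newick tree; missing branch lengths default to 0
    with a logged warning."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ParseError(f"malformed Newick: {exc}") from exc
    if any(e.length is None for e in tree.edges() if e.head_node.parent_node):
        logger.warning("missing branch lengths default to 0")
    return PhyloTree(tree)


def write_newick(ptree: PhyloTree, path: str | Path, internal_labels: bool = False) -> None:
    buf = io.StringIO()
    t = ptree.tree
    buf.write(
        t.as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=not internal_labels,
        )
    )
    Path(path).write_text(buf.getvalue())


def read_population_table(
    path: str | Path,
    alignment: CodonAlignment,
    region_map: Mapping[str, tuple[int, int]] | None = None,
) -> PopulationSample:
    """Read a TSV with columns individual_id, phase, sequence_id, population
    and cross-link it against the alignment."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "phase", "sequence_id"}
    if missing := required - set(df.columns):
        raise ParseError(f"population table missing columns {sorted(missing)}")
    pops = df["population"].tolist() if "population" in df.columns else [None] * len(df)
    return PopulationSample(
        alignment=alignment,
        individuals=df["individual_id"].tolist(),
        phases=[int(p) for p in df["phase"]],
        sequence_ids=df["sequence_id"].tolist(),
        populations=pops,
        region_map=dict(region_map or {}),
    )


def load_region_annotation(path: str | Path) -> RegionAnnotation:
    """Load TM/EC/IC segments and essential positions from YAML/JSON config.

    Expected keys: ``protein_length``, ``segments`` (name -> [start, end),
    0-based half-open), ``essential_positions`` (0-based indices).
    """
    cfg = yaml.safe_load(Path(path).read_text())
    return RegionAnnotation(
        segments={k: (int(v[0]), int(v[1])) for k, v in cfg["segments"].items()},
        essential_positions=frozenset(int(p) for p in cfg.get("essential_positions", [])),
        protein_length=int(cfg["protein_length"]),
    )
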