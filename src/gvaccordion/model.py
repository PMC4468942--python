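"""Domain types shared by every stage of the pipeline.

Genomes are ordered gene lists with 0-based half-open nucleotide
coordinates.  Trees wrap :class:`dendropy.Tree` so that Newick I/O,
rooting and traversal all go through one battle-tested library while the
rest of the package sees a small, stable surface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import dendropy

__all__ = [
    "GENE_FLAGS",
    "EVENT_TYPES",
    "GAIN_TYPES",
    "LOSS_TYPES",
    "GROUPS",
    "GeneRecord",
    "GenomeRecord",
    "PhyloTree",
    "EventRecord",
    "SummaryRow",
    "FormatError",
    "ConsistencyError",
]

GENE_FLAGS = frozenset({"MGE", "donor_labelled", "orphan_candidate"})

#: The closed vocabulary of genomic events.
EVENT_TYPES = frozenset(
    {
        "duplication",
        "lgt",
        "insertion",
        "loss",
        "excision",
        "translocation",
        "orphan",
        "ambiguous",
    }
)
GAIN_TYPES = frozenset({"duplication", "lgt", "insertion"})
LOSS_TYPES = frozenset({"loss", "excision"})

GROUPS = frozenset(
    {"mimivirus", "megavirus", "ostreococcus", "micromonas", "chlorella", "synthetic"}
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular/Newick format."""


class ConsistencyError(ValueError):
    """A record violates an arithmetic or structural invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: coordinates, family label and optional flags."""

    gene_id: str
    family_id: str
    start: int
    end: int
    strand: str = "+"
    flags: frozenset = frozenset()
    donor_taxon: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ConsistencyError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ConsistencyError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        object.__setattr__(self, "flags", frozenset(self.flags))
        if not self.flags <= GENE_FLAGS:
            raise ConsistencyError(
                f"gene {self.gene_id}: unknown flags {set(self.flags) - GENE_FLAGS}"
            )
        if ("donor_labelled" in self.flags) != (self.donor_taxon is not None):
            raise ConsistencyError(
                f"gene {self.gene_id}: donor_taxon must be present iff donor_labelled is set"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """An ordered gene complement for one virus genome."""

    genome_id: str
    group: str
    size_kb: float
    genes: list = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConsistencyError(
                f"genome {self.genome_id}: unknown group {self.group!r}"
            )
        self.genes = sorted(self.genes, key=lambda g: g.start)
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ConsistencyError(
                    f"genome {self.genome_id}: duplicate gene_id {g.gene_id!r}"
                )
            seen.add(g.gene_id)
            if g.end > self.size_nt:
                raise ConsistencyError(
                    f"genome {self.genome_id}: gene {g.gene_id} ends at {g.end} "
                    f"beyond genome size {self.size_nt} nt"
                )
        if self.sequence is not None and len(self.sequence) != self.size_nt:
            raise ConsistencyError(
                f"genome {self.genome_id}: sequence length {len(self.sequence)} "
                f"!= size {self.size_nt} nt"
            )

    @property
    def size_nt(self) -> int:
        # round half up, kb as printed
        return int(self.size_kb * 1000 + 0.5)

    def copy_number(self, family_id: str) -> int:
        return sum(1 for g in self.genes if g.family_id == family_id)

    def families(self) -> set:
        return {g.family_id for g in self.genes}

    def genes_of(self, family_id: str) -> list:
        return [g for g in self.genes if g.family_id == family_id]


class PhyloTree:
    """A (possibly rooted) phylogeny with branch lengths.

    Internal nodes are assigned stable labels ``N0, N1, ...`` in preorder
    at construction; tip labels come from the Newick taxa.  The label of
    a node doubles as the identifier of the branch above it, which is how
    :class:`EventRecord` refers to branches.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._relabel()

    def _relabel(self):
        i = 0
        for node in self._tree.preorder_node_iter():
            if node.taxon is not None:
                node.label = node.taxon.label
            elif not node.label or not str(node.label).startswith("N"):
                node.label = f"N{i}"
            i += 1

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise FormatError(f"invalid Newick: {exc}") from exc
        if not dtree.leaf_nodes():
            raise FormatError("Newick tree has no tips")
        return cls(dtree)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, suppress_internal_node_labels=True
        ).strip()

    # ------------------------------------------------------------ structure
    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def root(self):
        return self._tree.seed_node

    def is_binary_rooted(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def postorder(self):
        return self._tree.postorder_node_iter()

    def preorder(self):
        return self._tree.preorder_node_iter()

    def node(self, label: str):
        for n in self._tree.preorder_node_iter():
            if n.label == label:
                return n
        raise KeyError(label)

    @staticmethod
    def branch_length(node) -> float:
        return node.edge.length if node.edge.length is not None else 0.0

    def total_branch_length(self) -> float:
        return sum(
            self.branch_length(n) for n in self._tree.preorder_node_iter()
            if n.parent_node is not None
        )

    def depth_of(self, tip_label: str) -> float:
        node = self.node(tip_label)
        d = 0.0
        while node.parent_node is not None:
            d += self.branch_length(node)
            node = node.parent_node
        return d

    def reroot_with_outgroup(self, outgroup: str) -> "PhyloTree":
        """Root on the branch leading to *outgroup*, splitting it in half."""
        if outgroup not in self.tip_labels:
            raise KeyError(f"outgroup {outgroup!r} not among tips")
        dtree = self._tree.clone(depth=1)
        node = dtree.find_node_with_taxon_label(outgroup)
        length = node.edge.length or 0.0
        dtree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
        out = PhyloTree(dtree)
        return out

    def __repr__(self):
        return f"PhyloTree({self.n_tips} tips)"


@dataclass(frozen=True)
class EventRecord:
    """One genomic mutation, simulated or inferred.

    ``branch`` is the label of the node below the branch (tip genome_id
    for terminal branches).  ``position`` is the nucleotide coordinate of
    the targeted gene (gains store the insertion point for newly arriving
    families); ``dest_position`` carries the placement coordinate for
    duplications and translocations so that a simulated event log replays
    byte-exactly.
    """

    branch: str
    event_type: str
    family_id: str
    position: int | None = None
    in_paralog_family: bool = False
    dest_position: int | None = None

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ConsistencyError(f"unknown event type {self.event_type!r}")


# Columns of the per-virus event summary, in output order.
SUMMARY_COUNT_COLUMNS = (
    "duplication",
    "lgt",
    "insertion",
    "total_gain",
    "loss",
    "excision",
    "total_loss",
    "unknown",
    "orphan",
    "translocation",
    "genomic_events",
)


@dataclass
class SummaryRow:
    """Per-virus event counts in the layout of the published summary table.

    ``unknown`` is the full count of unresolved variants and ``orphan``
    the subset of those that are ORFans; rows transcribed from sources
    that do not break out the orphan subset carry ``orphan=None``.
    """

    genome_id: str
    identity_ancestor_pct: float
    size_kb: float
    duplication: int = 0
    lgt: int = 0
    insertion: int = 0
    total_gain: int = 0
    loss: int = 0
    excision: int = 0
    total_loss: int = 0
    unknown: int = 0
    orphan: int | None = 0
    translocation: int = 0
    genomic_events: int = 0
    group: str = "synthetic"
    accession: str = ""

    def violations(self) -> list:
        """Return the names of the arithmetic identities this row breaks."""
        bad = []
        if self.total_gain != self.duplication + self.lgt + self.insertion:
            bad.append("total_gain")
        if self.total_loss != self.loss + self.excision:
            bad.append("total_loss")
        if self.genomic_events != (
            self.total_gain + self.total_loss + self.unknown + self.translocation
        ):
            bad.append("genomic_events")
        return bad

    def validate(self):
        bad = self.violations()
        if bad:
            raise ConsistencyError(
                f"summary row {self.genome_id!r} violates {', '.join(bad)}"
            )

    @classmethod
    def from_counts(
        cls,
        genome_id: str,
        identity_ancestor_pct: float,
        size_kb: float,
        counts,
        group: str = "synthetic",
    ) -> "SummaryRow":
        """Build a row from a mapping event_type -> count; derived columns
        (total_gain, total_loss, unknown, genomic_events) are computed so
        the arithmetic identities hold by construction."""
        dup = int(counts.get("duplication", 0))
        lgt = int(counts.get("lgt", 0))
        ins = int(counts.get("insertion", 0))
        loss = int(counts.get("loss", 0))
        exc = int(counts.get("excision", 0))
        orphan = int(counts.get("orphan", 0))
        ambiguous = int(counts.get("ambiguous", 0))
        transloc = int(counts.get("translocation", 0))
        tg, tl = dup + lgt + ins, loss + exc
        unknown = ambiguous + orphan
        return cls(
            genome_id=genome_id,
            identity_ancestor_pct=identity_ancestor_pct,
            size_kb=size_kb,
            duplication=dup,
            lgt=lgt,
            insertion=ins,
            total_gain=tg,
            loss=loss,
            excision=exc,
            total_loss=tl,
            unknown=unknown,
            orphan=orphan,
            translocation=transloc,
            genomic_events=tg + tl + unknown + transloc,
            group=group,
        )
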