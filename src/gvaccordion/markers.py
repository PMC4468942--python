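"""Marker-gene divergence from the reconstructed group ancestor.

Four concatenated marker loci (DNA polymerase, A2L transcription factor,
D5 primase-helicase, packaging ATPase) act as the divergence clock:
alignments are trimmed to well-conserved blocks, the root sequence is
reconstructed by marginal posterior under Jukes–Cantor with Felsenstein's
pruning algorithm, and each extant genome's percent identity to that
ancestor is the clock reading.  Jukes–Cantor keeps the statistic testable
against its closed form; the substitution model is pluggable in
principle but the identity statistic is coarse enough (whole percent)
that richer models change nothing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ConsistencyError, PhyloTree

__all__ = [
    "MarkerAlignment",
    "AncestralSequence",
    "concat_markers",
    "filter_conserved_columns",
    "reconstruct_root",
    "percent_identity",
]

_BASE_ORDER = "ACGT"  # fixed tie-break order for the reconstructed state
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}


@dataclass
class MarkerAlignment:
    """Aligned rows (genome_id -> gapped sequence), concatenated loci."""

    rows: dict
    loci: list = field(default_factory=list)  # (name, start, end) column ranges
    mask: np.ndarray | None = None

    def __post_init__(self):
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ConsistencyError("alignment rows differ in length")
        if self.mask is not None and len(self.mask) != self.n_columns:
            raise ConsistencyError("mask length != alignment length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.rows.values())

    def masked(self) -> "MarkerAlignment":
        """Alignment restricted to retained columns."""
        if self.mask is None:
            return self
        keep = np.flatnonzero(self.mask)
        rows = {k: "".join(s[i] for i in keep) for k, s in self.rows.items()}
        return MarkerAlignment(rows=rows, loci=[])

    def split(self) -> dict:
        """Invert concatenation: locus name -> per-locus row dict."""
        return {
            name: {k: s[start:end] for k, s in self.rows.items()}
            for name, start, end in self.loci
        }


@dataclass
class AncestralSequence:
    node: str
    sequence: str
    posterior: np.ndarray  # per-site posterior of the reported state

    def __post_init__(self):
        if len(self.sequence) != len(self.posterior):
            raise ConsistencyError("sequence/posterior length mismatch")


def concat_markers(locus_alignments) -> MarkerAlignment:
    """Column-wise concatenation of per-locus alignments.

    ``locus_alignments`` maps locus name -> {genome_id: aligned sequence};
    every locus must cover the same genome set.
    """
    items = list(locus_alignments.items())
    if not items:
        raise ConsistencyError("no loci to concatenate")
    genome_set = set(items[0][1])
    for name, rows in items:
        if set(rows) != genome_set:
            raise ConsistencyError(
                f"locus {name!r} covers a different genome set"
            )
    order = sorted(genome_set)
    loci = []
    pos = 0
    parts = {g: [] for g in order}
    for name, rows in items:
        width = len(next(iter(rows.values())))
        loci.append((name, pos, pos + width))
        pos += width
        for g in order:
            parts[g].append(rows[g])
    return MarkerAlignment(rows={g: "".join(parts[g]) for g in order}, loci=loci)


def filter_conserved_columns(
    alignment: MarkerAlignment,
    max_gap_frac: float = 0.0,
    min_majority: float = 0.5,
    min_block: int = 10,
) -> np.ndarray:
    """Conserved-block column mask.

    A column is kept iff its gap fraction is <= ``max_gap_frac`` and the
    frequency of its modal non-gap residue (over all rows) is >=
    ``min_majority``; kept columns must additionally sit in runs of at
    least ``min_block`` consecutive kept columns.
    """
    if not alignment.rows or alignment.n_columns == 0:
        raise ConsistencyError("empty alignment")
    seqs = list(alignment.rows.values())
    n_rows = len(seqs)
    n_cols = alignment.n_columns
    keep = np.zeros(n_cols, dtype=bool)
    for i in range(n_cols):
        col = [s[i] for s in seqs]
        gaps = sum(1 for c in col if c == "-")
        if gaps / n_rows > max_gap_frac:
            continue
        residues = [c for c in col if c != "-"]
        if not residues:
            continue
        modal = max(set(residues), key=residues.count)
        if residues.count(modal) / n_rows >= min_majority:
            keep[i] = True
    # drop kept runs shorter than min_block
    i = 0
    while i < n_cols:
        if keep[i]:
            j = i
            while j < n_cols and keep[j]:
                j += 1
            if j - i < min_block:
                keep[i:j] = False
            i = j
        else:
            i += 1
    return keep


def _jc_transition(t: float) -> np.ndarray:
    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
    diff = 0.25 - 0.25 * np.exp(-4.0 * t / 3.0)
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def reconstruct_root(alignment: MarkerAlignment, tree: PhyloTree) -> AncestralSequence:
    """Marginal ancestral reconstruction at the root by pruning.

    Per site, the posterior over root states under Jukes–Cantor with a
    uniform prior; the reported base maximises the posterior, ties broken
    in fixed order A < C < G < T.  Gaps/N are treated as missing data.
    Expects an alignment already reduced to retained columns.
    """
    n_cols = alignment.n_columns
    if n_cols == 0:
        raise ConsistencyError("zero-length alignment")
    rows = alignment.rows
    # partial likelihoods per node: (sites, 4)
    partial: dict = {}
    for node in tree.postorder():
        if node.is_leaf():
            seq = rows.get(node.label)
            if seq is None:
                raise ConsistencyError(f"tip {node.label!r} missing from alignment")
            lik = np.ones((n_cols, 4))
            for i, ch in enumerate(seq):
                k = _BASE_INDEX.get(ch)
                if k is not None:
                    lik[i] = 0.0
                    lik[i, k] = 1.0
            partial[node.label] = lik
        else:
            lik = np.ones((n_cols, 4))
            for child in node.child_nodes():
                p = _jc_transition(PhyloTree.branch_length(child))
                lik *= partial[child.label] @ p.T
            partial[node.label] = lik
    root_lik = partial[tree.root.label] * 0.25
    total = root_lik.sum(axis=1, keepdims=True)
    post = root_lik / total
    best = post.argmax(axis=1)  # argmax returns the lowest index on ties: A<C<G<T
    seq = "".join(_BASE_ORDER[k] for k in best)
    return AncestralSequence(
        node=tree.root.label, sequence=seq, posterior=post[np.arange(n_cols), best]
    )


def percent_identity(tip_seq: str, ancestral_seq: str) -> float:
    """100 x matches / compared positions; positions where either sequence
    has a gap are excluded from the comparison."""
    if len(tip_seq) != len(ancestral_seq):
        raise ConsistencyError("sequences differ in length")
    compared = matches = 0
    for a, b in zip(tip_seq, ancestral_seq):
        if a == "-" or b == "-":
            continue
        compared += 1
        if a == b:
            matches += 1
    if compared == 0:
        raise ConsistencyError("no comparable (gap-free) positions")
    return 100.0 * matches / compared
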