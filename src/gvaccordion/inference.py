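"""Most-parsimonious-scenario inference of genomic events.

For every gene family the observed per-genome copy numbers are placed on
a rooted whole-genome tree and ancestral copy numbers are chosen to
minimise the total number of unit copy changes (a Sankoff-style dynamic
programme with cost ``|child - parent|`` per branch).  Co-optimal
labelings are counted exactly; where they disagree about the copy change
on a terminal branch the family is marked *ambiguous* on that branch
rather than typed.  Unambiguous terminal changes are classified as
duplication / lateral transfer / mobile-element insertion / orphan gain,
or loss / excision, from the parental copy number and the family's flags.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .model import ConsistencyError, EventRecord, PhyloTree

__all__ = [
    "CopyNumberMatrix",
    "ScenarioSet",
    "build_copy_matrix",
    "min_cost_scenarios",
    "classify_terminal_events",
    "internal_branch_changes",
    "summarize_terminal_events",
    "gene_content_distance",
    "build_rooted_tree",
]

DEFAULT_MAX_COPY = 20


@dataclass
class CopyNumberMatrix:
    """Family x genome copy counts plus per-family flags."""

    counts: pd.DataFrame  # index: family_id, columns: genome_id, int
    meta: dict  # family_id -> frozenset of flags
    donors: dict = field(default_factory=dict)  # family_id -> donor taxon

    @property
    def families(self) -> list:
        return list(self.counts.index)

    @property
    def genomes(self) -> list:
        return list(self.counts.columns)

    def profile(self, family_id: str) -> dict:
        return self.counts.loc[family_id].to_dict()


def build_copy_matrix(genomes) -> CopyNumberMatrix:
    """Count copies of each family in each genome; flags are propagated
    from genes to families by majority (conflicts warn)."""
    genomes = list(genomes)
    if not genomes:
        raise ConsistencyError("need at least one genome")
    ids = [g.genome_id for g in genomes]
    fams = sorted({g.family_id for gen in genomes for g in gen.genes})
    raw = {gid: dict.fromkeys(fams, 0) for gid in ids}
    flag_votes: dict = {}
    donors: dict = {}
    totals: dict = {}
    for gen in genomes:
        col = raw[gen.genome_id]
        for g in gen.genes:
            col[g.family_id] += 1
            totals[g.family_id] = totals.get(g.family_id, 0) + 1
            for f in g.flags:
                flag_votes.setdefault(g.family_id, {}).setdefault(f, 0)
                flag_votes[g.family_id][f] += 1
            if g.donor_taxon:
                donors.setdefault(g.family_id, g.donor_taxon)
    counts = pd.DataFrame(raw, dtype=int).loc[fams, ids]
    meta = {}
    for fam in fams:
        votes = flag_votes.get(fam, {})
        kept = frozenset(f for f, n in votes.items() if n * 2 >= totals[fam])
        dropped = set(votes) - set(kept)
        if dropped:
            warnings.warn(
                f"family {fam}: flags {sorted(dropped)} held by a minority of "
                "members; dropped by majority rule",
                stacklevel=2,
            )
        meta[fam] = kept
    return CopyNumberMatrix(counts=counts, meta=meta, donors=donors)


# ------------------------------------------------------------- parsimony DP
@dataclass
class ScenarioSet:
    """All minimum-cost ancestral copy-number assignments for one family."""

    family_id: str
    min_cost: int
    optimal_labelings: int
    #: tip label -> sorted tuple of signed copy changes on the terminal
    #: branch across co-optimal labelings (len > 1 <=> ambiguous there)
    terminal_deltas: dict
    #: one concrete co-optimal labeling, node label -> copy number
    canonical_labeling: dict

    def ambiguous_on(self, tip: str) -> bool:
        return len(self.terminal_deltas[tip]) > 1

    def delta_on(self, tip: str) -> int:
        """The signed change on an unambiguous terminal branch."""
        deltas = self.terminal_deltas[tip]
        if len(deltas) != 1:
            raise ConsistencyError(f"{self.family_id} is ambiguous on {tip}")
        return deltas[0]


def min_cost_scenarios(
    profile, tree: PhyloTree, max_copy: int = DEFAULT_MAX_COPY, family_id: str = ""
) -> ScenarioSet:
    """Sankoff DP over ancestral copy numbers 0..max_copy.

    ``profile`` maps every tip label to its observed copy count.  Returns
    the global minimum cost, the exact number of co-optimal ancestral
    assignments, and for each terminal branch the set of signed changes
    realised across co-optimal labelings.
    """
    observed_max = max(profile.values(), default=0)
    if observed_max > max_copy:
        raise ConsistencyError(
            f"observed copy number {observed_max} exceeds max_copy={max_copy}"
        )
    # Ancestral states above the observed maximum are never part of a
    # co-optimal labeling under |child - parent| cost (lowering such a
    # state strictly reduces every incident edge's cost), so the DP state
    # space can be capped there without changing costs, counts or deltas.
    n_states = observed_max + 1
    states = np.arange(n_states)
    trans = np.abs(states[:, None] - states[None, :])  # parent x child

    nodes = list(tree.postorder())
    cost: dict = {}
    count: dict = {}
    for node in nodes:
        if node.is_leaf():
            if node.label not in profile:
                raise ConsistencyError(f"tip {node.label!r} missing from profile")
            c = np.full(n_states, np.inf)
            c[profile[node.label]] = 0.0
            cost[node.label] = c
            count[node.label] = (c == 0).astype(np.int64)
        else:
            c = np.zeros(n_states)
            k = np.ones(n_states, dtype=np.int64)
            for child in node.child_nodes():
                through = cost[child.label][None, :] + trans  # parent x child
                best = through.min(axis=1)
                mask = through == best[:, None]
                k *= (mask * count[child.label][None, :]).sum(axis=1)
                c += best
            cost[node.label] = c
            count[node.label] = k

    root = tree.root
    root_cost = cost[root.label]
    min_cost = float(root_cost.min())
    root_opt = np.flatnonzero(root_cost == min_cost)
    n_labelings = int(count[root.label][root_opt].sum())

    # top-down feasibility: states a node takes in >= 1 co-optimal labeling
    feasible = {root.label: set(int(s) for s in root_opt)}
    canonical = {root.label: int(root_opt.min())}
    for node in tree.preorder():
        if node.is_leaf():
            continue
        for child in node.child_nodes():
            child_feas: set = set()
            for s_p in feasible[node.label]:
                through = cost[child.label] + trans[s_p]
                child_feas |= set(int(s) for s in np.flatnonzero(through == through.min()))
            feasible[child.label] = child_feas
            thr = cost[child.label] + trans[canonical[node.label]]
            canonical[child.label] = int(np.flatnonzero(thr == thr.min()).min())

    terminal_deltas = {}
    for node in tree.postorder():
        if not node.is_leaf():
            continue
        tip_state = profile[node.label]
        parent_states = feasible[node.parent_node.label]
        # a parent state contributes only if the tip transition from it is
        # part of a co-optimal labeling, which at a tip is automatic
        # (the tip state is fixed), provided the parent state is feasible
        # *jointly* with this tip's edge being optimal — at a leaf every
        # feasible parent state is jointly realisable.
        terminal_deltas[node.label] = tuple(
            sorted({tip_state - s_p for s_p in parent_states})
        )

    return ScenarioSet(
        family_id=family_id,
        min_cost=int(min_cost),
        optimal_labelings=n_labelings,
        terminal_deltas=terminal_deltas,
        canonical_labeling=canonical,
    )


# ----------------------------------------------------------- classification
def _gain_type(family_id: str, matrix: CopyNumberMatrix, genome_id: str) -> str:
    """Type of a gain arriving in a genome whose ancestor lacked the family."""
    flags = matrix.meta.get(family_id, frozenset())
    if "MGE" in flags:
        return "insertion"
    if "donor_labelled" in flags or family_id in matrix.donors:
        return "lgt"
    present_in = (matrix.counts.loc[family_id] > 0).sum()
    if "orphan_candidate" in flags or present_in <= 1:
        return "orphan"
    # family known elsewhere but unflagged: origin unresolved
    return "ambiguous"


def classify_terminal_events(scenarios, matrix: CopyNumberMatrix, tree: PhyloTree) -> list:
    """Turn per-family scenario sets into typed terminal-branch events.

    One ambiguous record is emitted per (family, branch) whose co-optimal
    labelings disagree; unambiguous changes emit one record per unit copy
    change.  ``in_paralog_family`` marks events in families with at least
    three other members in that genome.
    """
    if isinstance(scenarios, dict):
        scenarios = scenarios.values()
    events = []
    tips = set(tree.tip_labels)
    for sc in scenarios:
        fam = sc.family_id
        flags = matrix.meta.get(fam, frozenset())
        for tip in sorted(tips):
            deltas = sc.terminal_deltas[tip]
            tip_count = int(matrix.counts.loc[fam, tip])
            if len(deltas) > 1:
                events.append(
                    EventRecord(branch=tip, event_type="ambiguous", family_id=fam)
                )
                continue
            d = deltas[0]
            if d == 0:
                continue
            parent_copy = tip_count - d
            if d > 0:
                in_par = tip_count - 1 >= 3
                if parent_copy >= 1:
                    types = ["duplication"] * d
                else:
                    first = _gain_type(fam, matrix, tip)
                    types = [first] + ["duplication"] * (d - 1)
            else:
                in_par = tip_count >= 3
                per_loss = "excision" if "MGE" in flags else "loss"
                types = [per_loss] * (-d)
            for t in types:
                events.append(
                    EventRecord(
                        branch=tip,
                        event_type=t,
                        family_id=fam,
                        in_paralog_family=in_par,
                    )
                )
    return events


def attach_positions(events, genomes) -> list:
    """Give events a nucleotide position where one is defined: the start of
    a family member in the affected tip genome (gains and surviving-copy
    losses); events with no positional witness keep position=None."""
    by_id = {g.genome_id: g for g in genomes}
    out = []
    for ev in events:
        pos = ev.position
        genome = by_id.get(ev.branch)
        if pos is None and genome is not None:
            members = genome.genes_of(ev.family_id)
            if members:
                pos = members[0].start
        out.append(
            EventRecord(
                branch=ev.branch,
                event_type=ev.event_type,
                family_id=ev.family_id,
                position=pos,
                in_paralog_family=ev.in_paralog_family,
                dest_position=ev.dest_position,
            )
        )
    return out


def internal_branch_changes(scenarios, tree: PhyloTree) -> dict:
    """Signed copy changes on internal branches under each family's
    canonical co-optimal labeling: {branch_label: {family: delta}}."""
    if isinstance(scenarios, dict):
        scenarios = scenarios.values()
    tips = set(tree.tip_labels)
    out: dict = {}
    for sc in scenarios:
        for node in tree.preorder():
            if node.parent_node is None or node.label in tips:
                continue
            d = (
                sc.canonical_labeling[node.label]
                - sc.canonical_labeling[node.parent_node.label]
            )
            if d:
                out.setdefault(node.label, {})[sc.family_id] = d
    return out


def summarize_terminal_events(events, genomes, identity=None, translocations=None) -> list:
    """Aggregate classified events into per-genome summary rows.

    ``identity`` maps genome_id to percent identity with the reconstructed
    group ancestor (from the marker stage); ``translocations`` maps
    genome_id to a translocation count (from the synteny stage).
    """
    from .model import SummaryRow

    identity = identity or {}
    translocations = translocations or {}
    rows = []
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        counts: dict = {}
        for ev in events:
            if ev.branch == genome.genome_id:
                counts[ev.event_type] = counts.get(ev.event_type, 0) + 1
        counts["translocation"] = counts.get("translocation", 0) + int(
            translocations.get(genome.genome_id, 0)
        )
        rows.append(
            SummaryRow.from_counts(
                genome_id=genome.genome_id,
                identity_ancestor_pct=float(identity.get(genome.genome_id, float("nan"))),
                size_kb=genome.size_kb,
                counts=counts,
                group=genome.group,
            )
        )
    return rows


# ------------------------------------------------------- distances and tree
def gene_content_distance(matrix: CopyNumberMatrix, marker_alignment=None,
                          alpha: float = 0.5) -> pd.DataFrame:
    """Combined gene-content / substitution distance.

    ``d(a, b) = alpha * (1 - Jaccard(presence_a, presence_b))
    + (1 - alpha) * p_distance(markers_a, markers_b)``; with no marker
    alignment the substitution term is dropped (alpha acts as 1).
    """
    if len(matrix.genomes) < 2:
        raise ConsistencyError("need >= 2 genomes for distances")
    presence = matrix.counts > 0
    ids = matrix.genomes
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = presence[ids[i]], presence[ids[j]]
            union = (a | b).sum()
            jac = (a & b).sum() / union if union else 1.0
            dist = alpha * (1.0 - jac) if marker_alignment is not None else (1.0 - jac)
            if marker_alignment is not None:
                p = _p_distance(
                    marker_alignment.rows[ids[i]], marker_alignment.rows[ids[j]]
                )
                dist += (1.0 - alpha) * p
            d[i, j] = d[j, i] = dist
    return pd.DataFrame(d, index=ids, columns=ids)


def _p_distance(a: str, b: str) -> float:
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return 0.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def build_rooted_tree(distances: pd.DataFrame, outgroup: str) -> PhyloTree:
    """Neighbor joining on a distance matrix, rooted on the outgroup's
    terminal branch (split at its midpoint)."""
    ids = list(distances.index)
    if len(ids) < 3:
        raise ConsistencyError("neighbor joining needs >= 3 taxa")
    if outgroup not in ids:
        raise ConsistencyError(f"outgroup {outgroup!r} not among taxa")
    buf = _io.StringIO()
    buf.write("," + ",".join(ids) + "\n")
    for i in ids:
        buf.write(i + "," + ",".join(f"{distances.loc[i, j]:.10f}" for j in ids) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    nj = pdm.nj_tree()
    # NJ can produce tiny negative branch lengths on noisy input; clamp
    for edge in nj.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree = PhyloTree(nj)
    return tree.reroot_with_outgroup(outgroup)
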