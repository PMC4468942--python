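"""Aggregate statistics: summary-table totals, the events-per-kb clock
regression, mobile-element fractions, paralog-family context of
duplications and losses, positional hotspots, and the end-to-end
pipeline runner."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .model import (
    ConsistencyError,
    GAIN_TYPES,
    LOSS_TYPES,
    SUMMARY_COUNT_COLUMNS,
    SummaryRow,
)

__all__ = [
    "RegressionResult",
    "aggregate_summary",
    "events_per_kb",
    "fit_clock_regression",
    "group_mge_fraction",
    "duplication_family_context",
    "hotspot_fraction",
    "run_pipeline",
    "reproduce_table1",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ConsistencyError("r_squared outside [0, 1]")
        if self.n < 3:
            raise ConsistencyError("regression needs n >= 3")


def aggregate_summary(rows) -> dict:
    """Column-wise totals over summary rows (recomputed, never
    transcribed).  Rows with no orphan breakdown contribute 0 there."""
    rows = list(rows)
    if not rows:
        raise ConsistencyError("no rows to aggregate")
    totals = {col: 0 for col in SUMMARY_COUNT_COLUMNS}
    for r in rows:
        for col in SUMMARY_COUNT_COLUMNS:
            val = getattr(r, col)
            totals[col] += int(val) if val is not None else 0
    return totals


def events_per_kb(row: SummaryRow) -> float:
    if row.size_kb <= 0:
        raise ValueError("size_kb must be positive")
    return row.genomic_events / row.size_kb


def fit_clock_regression(rows) -> RegressionResult:
    """OLS of events/kb on percent marker identity to the group ancestor.

    The negative slope is the clock: more divergent genomes carry
    proportionally more genomic events per kb.
    """
    rows = list(rows)
    if len(rows) < 3:
        raise ConsistencyError("regression needs >= 3 rows")
    x = np.array([r.identity_ancestor_pct for r in rows], dtype=float)
    y = np.array([events_per_kb(r) for r in rows], dtype=float)
    if np.allclose(x, x[0]):
        raise ConsistencyError("undefined fit: identity is constant across rows")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(rows),
    )


def group_mge_fraction(rows, group: str) -> float:
    """Percent of a group's genomic events that are mobile-element
    insertions or excisions, rounded to the nearest integer."""
    sub = [r for r in rows if r.group == group]
    if not sub:
        raise ConsistencyError(f"no rows for group {group!r}")
    events = sum(r.genomic_events for r in sub)
    if events == 0:
        raise ConsistencyError(f"group {group!r} has zero genomic events")
    mge = sum(r.insertion + r.excision for r in sub)
    return round(100.0 * mge / events)


def duplication_family_context(events, matrix) -> dict:
    """Multigene-family context of duplications and losses.

    Returns ``frac_dup_in_big_families`` — the fraction of duplications in
    families with at least three additional members in that genome — and
    ``frac_loss_in_dup_families`` — the fraction of losses hitting
    families with at least two members.  A fraction with no qualifying
    events is None (undefined), never 0.
    """
    dups = [e for e in events if e.event_type == "duplication"]
    losses = [e for e in events if e.event_type in LOSS_TYPES]
    frac_dup = (
        sum(1 for e in dups if e.in_paralog_family) / len(dups) if dups else None
    )
    if losses:
        multi = 0
        for e in losses:
            if e.in_paralog_family:
                multi += 1
            elif matrix is not None and e.family_id in matrix.counts.index:
                # a surviving copy in the same genome means the family had >= 2
                if int(matrix.counts.loc[e.family_id, e.branch]) >= 1:
                    multi += 1
        frac_loss = multi / len(losses)
    else:
        frac_loss = None
    return {
        "frac_dup_in_big_families": frac_dup,
        "frac_loss_in_dup_families": frac_loss,
    }


def hotspot_fraction(events, genome, edge_frac: float = 0.1) -> float:
    """Fraction of positioned events on this genome's branch that fall in
    the first or last ``edge_frac`` of its length."""
    size = genome.size_nt
    positioned = [
        e for e in events if e.branch == genome.genome_id and e.position is not None
    ]
    if not positioned:
        raise ConsistencyError(f"no positioned events for {genome.genome_id}")
    lo, hi = edge_frac * size, (1.0 - edge_frac) * size
    at_edge = sum(1 for e in positioned if e.position < lo or e.position >= hi)
    return at_edge / len(positioned)


# ------------------------------------------------------------------ pipeline
def reproduce_table1(outdir=None) -> dict:
    """Recompute every aggregate of the published summary table from the
    bundled per-row transcription: column totals, the clock regression and
    the chlorovirus mobile-element fraction."""
    from . import io as gio

    rows = gio.load_table1()
    totals = aggregate_summary(rows)
    reg = fit_clock_regression(rows)
    out = {
        "rows": rows,
        "totals": totals,
        "regression": reg,
        "chlorella_mge_pct": group_mge_fraction(rows, "chlorella"),
        "mge_insertions_excisions": totals["insertion"] + totals["excision"],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_summary_table(rows, outdir / "table1_rows.tsv")
        plot_regression(rows, reg, outdir / "clock_regression.svg")
    return out


def run_pipeline(
    config,
    tree=None,
    tips: int = 5,
    outgroup: str | None = None,
    rebuild_tree: bool = False,
    outdir=None,
) -> dict:
    """End-to-end synthetic run: simulate -> copy matrix -> parsimony
    inference -> marker identity vs reconstructed ancestor -> summary ->
    clock regression.

    ``tree`` defaults to a random bifurcating clock tree with *tips* tips
    (seeded from the config).  With ``rebuild_tree`` the inference tree is
    re-estimated by neighbor joining on the combined gene-content/marker
    distance and rooted on ``outgroup`` (required), instead of using the
    simulation tree as the whole-genome tree template.
    """
    from . import inference, markers, simulate as sim
    from . import io as gio

    log: list = []
    if tree is None:
        tree = random_clock_tree(tips, seed=config.seed)
    result = sim.simulate(config, tree)
    log.append(f"simulated {len(result.events)} events on {tree.n_tips} tips")

    genomes = list(result.genomes.values())
    matrix = inference.build_copy_matrix(genomes)
    log.append(f"copy matrix: {len(matrix.families)} families x {len(matrix.genomes)} genomes")

    alignment = markers.MarkerAlignment(
        rows=dict(result.markers), loci=list(result.marker_loci)
    )
    if rebuild_tree:
        if outgroup is None:
            raise ConsistencyError(
                "build_rooted_tree requires an outgroup when rebuilding the tree"
            )
        distances = inference.gene_content_distance(matrix, alignment)
        infer_tree = inference.build_rooted_tree(distances, outgroup)
        log.append(f"rebuilt NJ tree rooted on {outgroup}")
    else:
        infer_tree = tree

    scenarios = {
        fam: inference.min_cost_scenarios(
            matrix.profile(fam), infer_tree, family_id=fam
        )
        for fam in matrix.families
    }
    events = inference.classify_terminal_events(scenarios, matrix, infer_tree)
    events = inference.attach_positions(events, genomes)
    log.append(f"inferred {len(events)} terminal-branch events")

    mask = markers.filter_conserved_columns(alignment)
    trimmed = markers.MarkerAlignment(rows=alignment.rows, mask=mask).masked()
    root_rec = markers.reconstruct_root(trimmed, tree)
    identity = {
        tip: markers.percent_identity(seq, root_rec.sequence)
        for tip, seq in trimmed.rows.items()
    }
    log.append(f"marker identity over {int(mask.sum())} retained columns")

    summary = inference.summarize_terminal_events(events, genomes, identity=identity)
    regression = (
        fit_clock_regression(summary) if len(summary) >= 3 else None
    )
    out = {
        "simulation": result,
        "matrix": matrix,
        "scenarios": scenarios,
        "events": events,
        "identity": identity,
        "summary": summary,
        "regression": regression,
        "log": log,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sim.write_outputs(result, outdir / "simulation")
        gio.write_summary_table(summary, outdir / "summary.tsv")
        _write_event_tracks(events, outdir / "event_tracks.tsv")
        if regression is not None:
            plot_regression(summary, regression, outdir / "clock_regression.svg")
        plot_event_tracks(events, genomes, outdir / "event_maps.svg")
    return out


def _write_event_tracks(events, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("genome\tevent_type\tfamily_id\tposition\tin_paralog_family\n")
        for e in events:
            fh.write(
                f"{e.branch}\t{e.event_type}\t{e.family_id}\t"
                f"{'' if e.position is None else e.position}\t{int(e.in_paralog_family)}\n"
            )


def random_clock_tree(tips: int, seed: int = 0, depth: float = 1.0):
    """Random rooted ultrametric tree: random coalescent-style topology,
    root-to-tip depth fixed at *depth*."""
    from .model import PhyloTree

    if tips < 2:
        raise ConsistencyError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    heights = sorted(rng.uniform(0.15, 1.0, tips - 1)) if tips > 2 else [1.0]
    lineages = [(f"T{i}", 0.0) for i in range(tips)]
    for h in heights:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        merged = (f"({na}:{(h - ha) * depth:.6f},{nb}:{(h - hb) * depth:.6f})", h)
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)] + [merged]
    # scale so root height == depth
    newick = lineages[0][0] + ";"
    tree = PhyloTree.from_newick(newick)
    scale = depth / max(tree.depth_of(t) for t in tree.tip_labels)
    for node in tree.preorder():
        if node.edge.length is not None:
            node.edge.length *= scale
    return tree


# -------------------------------------------------------------------- plots
def plot_regression(rows, regression: RegressionResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([r.identity_ancestor_pct for r in rows], float)
    y = np.array([events_per_kb(r) for r in rows], float)
    groups = sorted({r.group for r in rows})
    cmap = dict(zip(groups, plt.cm.tab10.colors))
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for g in groups:
        xs = [r.identity_ancestor_pct for r in rows if r.group == g]
        ys = [events_per_kb(r) for r in rows if r.group == g]
        ax.scatter(xs, ys, marker="s", label=g, color=cmap[g])
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, regression.intercept + regression.slope * grid, "b-",
            label=f"OLS (r$^2$={regression.r_squared:.2f})")
    ax.set_xlabel("% identity to reconstructed group ancestor")
    ax.set_ylabel("genomic events per kb")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_event_tracks(events, genomes, path) -> None:
    """Per-genome event maps: gains above the line, losses below."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genomes = sorted(genomes, key=lambda g: g.genome_id)
    fig, axes = plt.subplots(
        len(genomes), 1, figsize=(8, 1.2 * len(genomes)), squeeze=False
    )
    style = {
        "duplication": ("s", "tab:red", 1),
        "lgt": ("^", "tab:green", 1),
        "insertion": ("v", "tab:purple", 1),
        "orphan": ("x", "tab:gray", 1),
        "ambiguous": ("$?$", "tab:gray", 1),
        "loss": ("o", "tab:blue", -1),
        "excision": ("v", "tab:orange", -1),
        "translocation": ("*", "tab:brown", -1),
    }
    for ax, genome in zip(axes[:, 0], genomes):
        ax.hlines(0, 0, genome.size_nt / 1000, color="black", lw=1)
        for e in events:
            if e.branch != genome.genome_id or e.position is None:
                continue
            marker, color, side = style.get(e.event_type, ("o", "gray", 1))
            ax.scatter(e.position / 1000, 0.5 * side, marker=marker, color=color, s=18)
        ax.set_ylim(-1, 1)
        ax.set_yticks([])
        ax.set_ylabel(genome.genome_id, rotation=0, ha="right", fontsize=8)
    axes[-1, 0].set_xlabel("kb")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
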