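"""Positional homology between gene orders.

Orthology between closely related genomes is read off conserved gene
order: single-copy families shared by two genomes anchor collinear
blocks, chained by longest increasing (or decreasing, for inverted
segments) subsequences of the partner-genome positions.  Regions outside
all blocks that are long enough and contain an open reading frame are
the variable segments where gene-level change is sought, and anchors
stranded outside every block with conserved copy number are called
translocations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "AnchorSet",
    "SyntenyBlock",
    "VariableSegment",
    "anchor_genes",
    "chain_blocks",
    "extract_variable_segments",
    "find_orfs",
    "detect_translocations",
    "write_segments_bed",
]

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class AnchorPair:
    gene_a: object
    gene_b: object
    index_a: int  # rank of the gene in genome a's gene order
    index_b: int


@dataclass
class AnchorSet:
    genome_a: str
    genome_b: str
    pairs: list = field(default_factory=list)  # sorted by index_a


@dataclass
class SyntenyBlock:
    genome_a: str
    genome_b: str
    anchor_pairs: list  # list of AnchorPair, ordered by index_a
    orientation: str  # "same" | "inverted"

    def span(self, genome_id: str):
        """Nucleotide span covered by the block's anchor genes in one genome."""
        if genome_id == self.genome_a:
            genes = [p.gene_a for p in self.anchor_pairs]
        elif genome_id == self.genome_b:
            genes = [p.gene_b for p in self.anchor_pairs]
        else:
            raise KeyError(genome_id)
        return min(g.start for g in genes), max(g.end for g in genes)


@dataclass
class VariableSegment:
    genome_id: str
    start: int
    end: int
    contained_genes: list
    has_orf: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def anchor_genes(a, b) -> AnchorSet:
    """Candidate orthology anchors: families that are single-copy in both
    genomes.  Families duplicated in either genome are excluded as
    positionally ambiguous."""
    def single_copy(genome):
        counts: dict = {}
        for g in genome.genes:
            counts[g.family_id] = counts.get(g.family_id, 0) + 1
        return {g.family_id: g for g in genome.genes if counts[g.family_id] == 1}

    sa, sb = single_copy(a), single_copy(b)
    rank_a = {g.gene_id: i for i, g in enumerate(a.genes)}
    rank_b = {g.gene_id: i for i, g in enumerate(b.genes)}
    pairs = []
    for fam in sa:
        if fam in sb:
            ga, gb = sa[fam], sb[fam]
            pairs.append(
                AnchorPair(ga, gb, rank_a[ga.gene_id], rank_b[gb.gene_id])
            )
    pairs.sort(key=lambda p: p.index_a)
    return AnchorSet(a.genome_id, b.genome_id, pairs)


def _lis_indices(values, decreasing=False) -> list:
    """Indices of one longest strictly increasing (or decreasing)
    subsequence; O(n^2), deterministic (earliest predecessor wins)."""
    n = len(values)
    if n == 0:
        return []
    sign = -1 if decreasing else 1
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if sign * values[j] < sign * values[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -i))
    out = []
    while end != -1:
        out.append(end)
        end = prev[end]
    return out[::-1]


def chain_blocks(anchors: AnchorSet) -> list:
    """Chain anchors into collinear blocks.

    Repeatedly extracts the longest run that is monotone in genome-b
    position (increasing -> "same", decreasing -> "inverted") from the
    anchors not yet assigned; runs of fewer than 2 anchors are discarded.
    """
    remaining = list(anchors.pairs)
    blocks = []
    while len(remaining) >= 2:
        vals = [p.index_b for p in remaining]
        inc = _lis_indices(vals)
        dec = _lis_indices(vals, decreasing=True)
        chosen, orientation = (inc, "same") if len(inc) >= len(dec) else (dec, "inverted")
        if len(chosen) < 2:
            break
        block_pairs = [remaining[i] for i in chosen]
        blocks.append(
            SyntenyBlock(anchors.genome_a, anchors.genome_b, block_pairs, orientation)
        )
        chosen_set = set(chosen)
        remaining = [p for i, p in enumerate(remaining) if i not in chosen_set]
    return blocks


def extract_variable_segments(
    genome, blocks, min_len: int = 300, require_orf: bool = True
) -> list:
    """Maximal intervals of *genome* not covered by any block span,
    longer than *min_len*.

    A segment's ``has_orf`` is decided from the genome sequence when one
    is attached (six-frame scan), otherwise from the presence of at least
    one annotated gene inside the segment.  With ``require_orf`` (the
    default, matching the published filter) only ORF-bearing segments are
    returned.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    # coverage is the union of the individual anchor genes' spans, so an
    # insertion between two anchors of the same block is still exposed
    spans = []
    for blk in blocks:
        if genome.genome_id == blk.genome_a:
            spans += [(p.gene_a.start, p.gene_a.end) for p in blk.anchor_pairs]
        elif genome.genome_id == blk.genome_b:
            spans += [(p.gene_b.start, p.gene_b.end) for p in blk.anchor_pairs]
        else:
            raise KeyError(genome.genome_id)
    spans.sort()
    merged = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = []
    pos = 0
    for s, e in merged:
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < genome.size_nt:
        gaps.append((pos, genome.size_nt))

    segments = []
    for s, e in gaps:
        if e - s <= min_len:
            continue
        inside = [g.gene_id for g in genome.genes if g.start >= s and g.end <= e]
        if genome.sequence is not None:
            has_orf = bool(find_orfs(genome.sequence[s:e], min_nt=min_len))
        else:
            has_orf = bool(inside)
        if has_orf or not require_orf:
            segments.append(VariableSegment(genome.genome_id, s, e, inside, has_orf))
    return segments


def _scan_forward(seq: str, min_nt: int, strand: str, seq_len: int):
    """One ORF per (frame, stop): first ATG after the previous stop through
    the stop codon inclusive.  Codons containing N match nothing."""
    orfs = []
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in STOP_CODONS:
                end = i + 3
                if end - start >= min_nt:
                    if strand == "+":
                        orfs.append((start, end, "+"))
                    else:  # map back to forward coordinates
                        orfs.append((seq_len - end, seq_len - start, "-"))
                start = None
    return orfs


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def find_orfs(seq: str, min_nt: int = 300) -> list:
    """Six-frame ORF scan: ATG-to-stop spans of at least *min_nt*
    nucleotides (start through stop codon inclusive), standard code."""
    seq = seq.upper()
    fwd = _scan_forward(seq, min_nt, "+", len(seq))
    rev = _scan_forward(seq.translate(_COMPLEMENT)[::-1], min_nt, "-", len(seq))
    return sorted(fwd + rev)


def detect_translocations(a, b, blocks) -> list:
    """Genes (of genome *a*) whose family is single-copy and present in
    both genomes but whose anchor belongs to no collinear block:
    positionally displaced with conserved copy number."""
    anchors = anchor_genes(a, b)
    in_block = set()
    for blk in blocks:
        for p in blk.anchor_pairs:
            in_block.add(p.gene_a.gene_id)
    return [p.gene_a.gene_id for p in anchors.pairs if p.gene_a.gene_id not in in_block]


def write_segments_bed(segments, path) -> None:
    """Emit segments (or blocks spans) as BED-like TSV."""
    with Path(path).open("w") as fh:
        fh.write("genome_id\tstart\tend\tname\thas_orf\n")
        for i, seg in enumerate(segments):
            fh.write(
                f"{seg.genome_id}\t{seg.start}\t{seg.end}\tseg{i}\t{int(seg.has_orf)}\n"
            )
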