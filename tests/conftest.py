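import numpy as np
import pytest

from gvaccordion.model import GeneRecord, GenomeRecord, PhyloTree


def make_genome(genome_id, families, group="synthetic", gene_len=1000, spacer=50):
    """Build a genome from [(family_id, n_copies, flags, donor), ...] laid
    end to end in the given order."""
    genes = []
    pos = spacer
    counter = {}
    for entry in families:
        fam, n = entry[0], entry[1]
        flags = frozenset(entry[2]) if len(entry) > 2 else frozenset()
        donor = entry[3] if len(entry) > 3 else None
        for _ in range(n):
            counter[fam] = counter.get(fam, 0) + 1
            genes.append(
                GeneRecord(
                    gene_id=f"{fam}.{counter[fam]}",
                    family_id=fam,
                    start=pos,
                    end=pos + gene_len,
                    flags=flags,
                    donor_taxon=donor,
                )
            )
            pos += gene_len + spacer
    return GenomeRecord(
        genome_id=genome_id, group=group, size_kb=pos / 1000.0, genes=genes
    )


@pytest.fixture
def balanced4():
    return PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
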