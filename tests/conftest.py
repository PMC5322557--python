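import numpy as np
import pytest

from symbevol import Domain, GeneRecord, GenomeSet


def make_gene(
    gene_id,
    genome_id,
    aa_len=None,
    aa_seq=None,
    nt_seq=None,
    status="unclassified",
    domains=(),
    **kw,
):
    """Small helper: a valid GeneRecord with plausible coordinates."""
    if aa_seq is None and aa_len is not None:
        aa_seq = ("MKVLADGRTE" * (aa_len // 10 + 1))[:aa_len]
    length = 3 * (len(aa_seq) + 1) if aa_seq else 3
    return GeneRecord(
        gene_id=gene_id,
        genome_id=genome_id,
        start=1,
        end=length,
        aa_seq=aa_seq,
        nt_seq=nt_seq,
        status=status,
        domains=[Domain(*d) for d in domains],
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_genome_set():
    """Two ingroup genomes (one clade) + singleton ingroup + one outgroup."""

    def build(genes_by_genome, clades=None, roles=None):
        roles = roles or {
            g: ("outgroup" if g.startswith("out") else "ingroup")
            for g in genes_by_genome
        }
        return GenomeSet(genes_by_genome, roles, clades or {})

    return build
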