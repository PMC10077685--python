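"""Shared fixtures: hand-built genomes and a session-scoped simulated set."""

import numpy as np
import pytest

from mitostruct.genome_io import AnnotatedGenome, Feature, StrainMeta
from mitostruct.synthetic_data import SimParams, emit_genomes, simulate_evolution

BASES = np.array(list("ATGC"))


def random_seq(rng: np.random.Generator, n: int, at: float = 0.5) -> str:
    p = [at / 2, at / 2, (1 - at) / 2, (1 - at) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_gene_with_introns(name, start, exon_len, intron_seqs, strand="+"):
    """Features for a gene whose exons alternate with the given introns.

    ``exon_len`` may be an int (uniform exons) or a list of per-exon lengths
    of length ``len(intron_seqs) + 1``.
    """
    n_exons = len(intron_seqs) + 1
    exon_lens = [exon_len] * n_exons if isinstance(exon_len, int) else list(exon_len)
    feats = []
    pos = start
    exon_segs = []
    for i in range(n_exons):
        exon_segs.append((pos, pos + exon_lens[i]))
        pos += exon_lens[i]
        if i < len(intron_seqs):
            feats.append(
                Feature(f"{name}-i{i + 1}", "intron", strand,
                        [(pos, pos + len(intron_seqs[i]))],
                        {"host_gene": name})
            )
            pos += len(intron_seqs[i])
    feats.insert(0, Feature(name, "CDS", strand, exon_segs))
    return feats, pos


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One simulated 8-leaf data set, emitted to disk, with its truth."""
    params = SimParams(n_leaves=8, seed=1)
    truth = simulate_evolution(None, params)
    outdir = tmp_path_factory.mktemp("simdata")
    genomes = emit_genomes(truth, params, outdir)
    return {"params": params, "truth": truth, "dir": outdir, "genomes": genomes}


@pytest.fixture
def tiny_genome():
    seq_rng = np.random.default_rng(7)
    seq = random_seq(seq_rng, 2000, at=0.6)
    feats = [
        Feature("cox1", "CDS", "+", [(100, 400)]),
        Feature("rps3", "CDS", "+", [(600, 900)]),
        Feature("trnA", "tRNA", "-", [(1200, 1275)]),
    ]
    return AnnotatedGenome(
        strain_id="tiny", sequence=seq, features=feats,
        metadata=StrainMeta(clade="cladeA"),
    )
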