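"""Shared fixtures: a hand-built 2-intron toy gene and generated references."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from varsync import simulate as sim
from varsync.core_io import GeneModel, ReferenceGenome, SampleVariantSet, VariantCall

STOPS = {"TAA", "TAG", "TGA"}
SAFE_CODONS = [
    "".join(c)
    for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOPS and "".join(c) != "ATG"
]


def _mkseq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def toy_gene():
    """Plus-strand 3-exon gene (30 bp CDS per exon, GT..AG introns) embedded
    in a 320 bp chromosome, with handy coordinates attached."""
    rng = np.random.default_rng(7)
    ex1 = "ATG" + "".join(rng.choice(SAFE_CODONS, 9))
    ex2 = "".join(rng.choice(SAFE_CODONS, 10))
    ex3 = "".join(rng.choice(SAFE_CODONS, 9)) + "TAA"
    i1 = "GTAAG" + _mkseq(rng, 10) + "TTCAG"
    i2 = "GTAAG" + _mkseq(rng, 20) + "TTCAG"
    up, down = _mkseq(rng, 60), _mkseq(rng, 60)
    chrom = up + ex1 + i1 + ex2 + i2 + ex3 + down
    s1 = len(up)
    e1 = s1 + 30
    s2 = e1 + len(i1)
    e2 = s2 + 30
    s3 = e2 + len(i2)
    e3 = s3 + 30
    genome = ReferenceGenome(["chr1"], {"chr1": chrom})
    model = GeneModel(
        "toy", "toy.t1", "chr1", "+",
        [(s1, e1), (s2, e2), (s3, e3)], [(s1, e1), (s2, e2), (s3, e3)],
    )
    model.coords = {"s1": s1, "e1": e1, "s2": s2, "e2": e2, "s3": s3, "e3": e3}
    return genome, model


@pytest.fixture(scope="session")
def synth_ref():
    """A small generated reference with genes and repeat tracts."""
    cfg = sim.SimulationConfig(seed=11, n_samples=10, chrom_length=80_000, n_genes=6)
    return cfg, sim.gen_reference(cfg, np.random.default_rng(cfg.seed))


def varset_of(genome, sample, *calls):
    vs = SampleVariantSet(sample)
    for chrom, pos, ref, alt in calls:
        vs.add(VariantCall(chrom, pos, ref, alt, sample))
    vs.sort_and_validate(genome)
    return vs
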