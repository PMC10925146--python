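"""Shared fixtures: a hand-built two-gene toy genome and small simulations."""

from __future__ import annotations

import pytest

from lrfusion import GeneModel, Genome, SimConfig, Transcript, simulate


@pytest.fixture(scope="session")
def hand_genome() -> Genome:
    """Tiny hand-built genome with known splice-site sequences.

    chrP carries a plus-strand two-exon gene with a GT..AG intron;
    chrM carries the reverse complement of the same layout (minus strand);
    chrX carries a non-consensus (CT..AC) intron on the plus strand.
    """
    # exon1 (10 b) | GT + 4 b + AG | exon2 (10 b) | 10 b tail
    plus = "ATGGCCAAAC" + "GT" + "TTTT" + "AG" + "CCGGTTAACG" + "ACGTACGTAC"
    # Same gene structure mirrored: minus-strand gene occupies the revcomp.
    minus = plus.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    noncons = "ATGGCCAAAC" + "CT" + "TTTT" + "AC" + "CCGGTTAACG" + "ACGTACGTAC"
    return Genome({"chrP": plus, "chrM": minus, "chrX": noncons})


@pytest.fixture(scope="session")
def plus_gene() -> GeneModel:
    return GeneModel(
        gene_id="GP",
        symbol="GP",
        contig="chrP",
        strand="+",
        transcripts=[Transcript("GP.t1", ((0, 10), (18, 28)))],
    )


@pytest.fixture(scope="session")
def minus_gene() -> GeneModel:
    # chrM is the 38-base reverse complement of chrP: the gene's exons sit at
    # the mirrored coordinates, transcribed right-to-left.
    return GeneModel(
        gene_id="GM",
        symbol="GM",
        contig="chrM",
        strand="-",
        transcripts=[Transcript("GM.t1", ((10, 20), (28, 38)))],
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free simulation: 10 genes, 3 fusions, both read orientations."""
    return simulate(SimConfig(seed=11, gene_count=10, fusion_count=3))


@pytest.fixture(scope="session")
def noisy_sim():
    """Same conditions with a 2% substitution rate."""
    return simulate(
        SimConfig(seed=11, gene_count=10, fusion_count=3, substitution_rate=0.02)
    )
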