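"""Shared fixtures: a small synthetic dataset and a hand-built two-exon gene."""

import numpy as np
import pytest

from exopop.consequence import Transcript, TranscriptIndex
from exopop.simulate import (
    FounderSpec,
    GeneSpec,
    PopulationSpec,
    SimulationConfig,
    simulate_dataset,
)
from exopop.vcfio import CohortPanel, Variant


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_variants=400,
        populations=[
            PopulationSpec("AJ", 60, 0.05),
            PopulationSpec("EUR", 60, 0.01),
            PopulationSpec("AFR", 60, 0.02),
        ],
        founder=FounderSpec(n_planted=30),
        genes=GeneSpec(n_genes=10),
        consequence_mix={
            "stop_gained": 4,
            "stop_lost": 2,
            "splice_site": 4,
            "missense": 16,
            "synonymous": 10,
            "exonic_unknown": 4,
        },
        n_cases=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


# --- hand-built gene: 2 exons, 10-codon CDS, UTRs on both sides -------------
#
# chr1 (100 bp): exon1 = 11..40 (UTR 11..20, CDS 21..40), intron 41..60,
# exon2 = 61..100 (CDS 61..70, UTR 71..100).
# CDS codons: ATG TAC CTG AAA CCC GGG TTC ACT GAC TAA.

CDS_PART1 = "ATGTACCTGAAACCCGGGTT"
CDS_PART2 = "CACTGACTAA"


def _hand_chrom() -> str:
    seq = list("A" * 100)
    seq[20:40] = CDS_PART1
    seq[60:70] = CDS_PART2
    return "".join(seq)


@pytest.fixture(scope="session")
def hand_gene() -> tuple[Transcript, dict[str, str]]:
    t = Transcript(
        transcript_id="TX1",
        gene_id="GENE1",
        chrom="chr1",
        strand="+",
        exons=((11, 40), (61, 100)),
        cds=((21, 40), (61, 70)),
    )
    return t, {"chr1": _hand_chrom()}


@pytest.fixture(scope="session")
def hand_index(hand_gene) -> TranscriptIndex:
    t, ref = hand_gene
    return TranscriptIndex([t], ref, strict=True)


@pytest.fixture()
def tiny_panel() -> CohortPanel:
    """4 samples, 3 variants, one missing genotype."""
    variants = [
        Variant("chr1", 100, "A", "G"),
        Variant("chr1", 200, "C", "T"),
        Variant("chr1", 300, "G", "A"),
    ]
    genotypes = np.array(
        [
            [0, 1, 1, 2],
            [0, 0, 1, np.nan],
            [2, 2, 2, 2],
        ],
        dtype=float,
    )
    return CohortPanel(
        variants=variants,
        samples=["s1", "s2", "s3", "s4"],
        genotypes=genotypes,
        label="tiny",
        filters=["PASS", "PASS", "PASS"],
    )
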