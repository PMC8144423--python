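import numpy as np
import pytest

from epiguide.io import GtfFeature, TranscriptSet
from epiguide.library_design import CandidateGuide, DesignConfig, DomainInterval
from epiguide.offtarget import GenomeIndex


@pytest.fixture
def rng():
    return np.random.default_rng(20210524)


@pytest.fixture
def toy_transcripts():
    """One gene with a two-exon transcript plus a second single-exon gene."""
    feats = [
        GtfFeature("chr1", "t", "transcript", 50, 200, "+", "geneA", "geneA.t1"),
        GtfFeature("chr1", "t", "exon", 50, 120, "+", "geneA", "geneA.t1"),
        GtfFeature("chr1", "t", "exon", 150, 200, "+", "geneA", "geneA.t1"),
        GtfFeature("chr1", "t", "transcript", 400, 500, "-", "geneB", "geneB.t1"),
        GtfFeature("chr1", "t", "exon", 400, 500, "-", "geneB", "geneB.t1"),
    ]
    return TranscriptSet(feats)


def make_candidate(protospacer="GATATCATATACGATATCAT", gene_id="geneA",
                   category="catalytic", domain_name="dom1", strand="+",
                   start=100, chrom="chr1"):
    context = "AAAA" + protospacer + "AGG" + "AAA"
    return CandidateGuide(
        protospacer=protospacer, context30=context, guide23=context[4:27],
        chrom=chrom, cut_position=start + 17, strand=strand, gene_id=gene_id,
        domain_name=domain_name, category=category, start=start,
    )


@pytest.fixture
def candidate_factory():
    return make_candidate


@pytest.fixture
def genome_ACGT():
    return GenomeIndex({"chr1": "ACGTTGCAACGTACGTAGCTTGCA"})


@pytest.fixture
def design_cfg():
    return DesignConfig()
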