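import numpy as np
import pytest

from vdjoin import GeneSegmentRef, JunctionRead, LocusReference, RssSpec

RSS12 = RssSpec("CACAGTG", "ATCGATCGATCG", "ACAAAAACC")
RSS23 = RssSpec("CACAGTG", "GCTAGCTAGCTAGCTAGCTAGCT", "ACAAAAACC")

# flanks from the worked decomposition examples: left ends ...TACTTC,
# right starts GGAACA...
LEFT_FLANK = "GGTTAACCTGGTACTTC"
RIGHT_FLANK = "GGAACAGGGTTCATTAA"


def make_locus(left=LEFT_FLANK, right=RIGHT_FLANK, kind="coding", name="test-locus",
               rss_left=RSS23, rss_right=RSS12, anchors=(0, 0)):
    return LocusReference(
        locus_name=name,
        left_segment=GeneSegmentRef("V", left, rss_left, "upstream_of_junction",
                                    frame_anchor=anchors[0]),
        right_segment=GeneSegmentRef("J", right, rss_right, "downstream_of_junction",
                                     frame_anchor=anchors[1]),
        joint_kind=kind,
    )


@pytest.fixture
def coding_locus():
    return make_locus()


@pytest.fixture
def signal_locus():
    return make_locus(kind="signal", name="test-signal")


@pytest.fixture
def clean_locus():
    """Coding locus engineered for exact truth recovery: junction-proximal
    runs (A on the left, C on the right) share no 2-mer, and insertions
    drawn from {G, T} can extend neither flank match."""
    return make_locus(left="TGCGTGGTTGCG" + "A" * 20, right="C" * 20 + "GTTGGTGCGTGT",
                      name="clean-locus")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def read_for(locus, sequence, read_id="r", genotype=""):
    return JunctionRead(read_id, sequence, locus, genotype)
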