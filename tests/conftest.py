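import pytest

from dsrnatk import (
    AlignedRead,
    AnnotationFeature,
    AnnotationIndex,
    GenomicInterval,
)


@pytest.fixture
def chrom_sizes():
    return {"chr1": 10_000, "chr2": 5_000}


def read(chrom, start, end, strand="+", copies=1, n_hits=1, name="nr"):
    return AlignedRead(
        GenomicInterval(chrom, start, end, strand), copies=copies, n_hits=n_hits, name=name
    )


def feature(chrom, start, end, category, strand="+", fid=None, parent=None):
    return AnnotationFeature(
        GenomicInterval(chrom, start, end, strand),
        category=category,
        feature_id=fid or f"{category}_{start}",
        parent_id=parent,
    )


@pytest.fixture
def nested_annotation():
    """A tRNA nested inside an mRNA intron, plus UTRs and a transposon."""
    features = [
        feature("chr1", 1000, 2000, "intron", "+", fid="intron1"),
        feature("chr1", 1200, 1280, "tRNA", "+", fid="trna1"),
        feature("chr1", 2000, 2150, "UTR3", "+", fid="utr3_1"),
        feature("chr1", 3000, 3400, "transposable_element", "-", fid="te1"),
        feature("chr2", 100, 400, "exon_CDS", "-", fid="cds1"),
    ]
    return features


@pytest.fixture
def nested_index(nested_annotation):
    return AnnotationIndex(nested_annotation)
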