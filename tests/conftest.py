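import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from spliceflow import ExpressionMatrix, TranscriptModel

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def tx(tid, exons, gene="G1", strand="+", chrom="chr1"):
    """Shorthand transcript constructor for hand-built fixtures."""
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=tuple(tuple(e) for e in exons),
    )


def expr_matrix(data, design=None):
    """ExpressionMatrix from {transcript: {sample: tpm}} nested dicts."""
    df = pd.DataFrame(data).T.astype(float)
    return ExpressionMatrix(values=df, design=design)


@pytest.fixture
def write_gtf(tmp_path):
    def _write(text, name="test.gtf"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


def gtf_line(chrom, feature, start, end, strand, gene, tid):
    attrs = f'gene_id "{gene}"; transcript_id "{tid}";'
    return f"{chrom}\tsrc\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
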