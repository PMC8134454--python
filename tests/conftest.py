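import numpy as np
import pandas as pd
import pytest

from methdrift.io import AmpliconDef, BetaMatrix, SampleSheet


@pytest.fixture
def toy_beta() -> BetaMatrix:
    """3 CpGs x 4 samples, no missing values, annotated."""
    df = pd.DataFrame(
        {
            "s1": [0.10, 0.80, 0.50],
            "s2": [0.20, 0.70, 0.50],
            "s3": [0.30, 0.60, 0.50],
            "s4": [0.40, 0.50, 0.50],
        },
        index=["cgA", "cgB", "cgC"],
    )
    return BetaMatrix(df, cpg_annotation={"cgA": "chr1", "cgB": "chr2", "cgC": "chrX"})


@pytest.fixture
def toy_sheet() -> SampleSheet:
    return SampleSheet.from_records(
        {
            "sample_id": f"s{i}",
            "passage": p,
            "donor": "D1",
            "cell_type": "MSC",
        }
        for i, p in zip(range(1, 5), [1, 2, 3, 4])
    )


@pytest.fixture
def small_amplicon() -> AmpliconDef:
    """A hand-built 4-CpG amplicon with CpG-free primers."""
    #         0         1         2         3         4
    #         0123456789012345678901234567890123456789012345
    ref = "AATTAATTAACGTACGTTACGTTTCGATTAATTAATT"
    # CpGs at offsets 10, 14, 19, 24
    return AmpliconDef(
        name="toy4",
        reference_seq=ref,
        forward_primer=ref[:8],
        reverse_primer=ref[-8:],
        cpg_offsets=(10, 14, 19, 24),
    )


def make_sheet(passages, prefix="s", **extra) -> SampleSheet:
    return SampleSheet.from_records(
        {"sample_id": f"{prefix}{i}", "passage": p, "donor": "D1",
         "cell_type": "MSC", **extra}
        for i, p in enumerate(passages)
    )
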