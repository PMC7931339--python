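import numpy as np
import pandas as pd
import pytest

from placmir.seed_match import MatureMiRNA, TranscriptRegions


@pytest.fixture
def mir99a() -> MatureMiRNA:
    # mature miR-99a-5p; seed (nt 2-8) = ACCCGUA
    return MatureMiRNA("miR-99a", "AACCCGUAGAUCCGAUCUUGUG")


@pytest.fixture
def small_transcript() -> TranscriptRegions:
    seq = "A" * 10 + "UACGGGU" + "C" * 23 + "G" * 20  # planted site at 11-17
    return TranscriptRegions(
        "gene-x", seq, (("5UTR", 1, 10), ("CDS", 11, 40), ("3UTR", 41, 60))
    )


@pytest.fixture
def toy_cq_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "assay_id": ["a1", "a1", "a2", "a2"],
            "plate": ["A", "A", "B", "B"],
            "group": ["Con", "N3", "Con", "N3"],
            "cq": [20.0, 21.5, np.nan, 30.0],
            "undetermined": [False, False, True, False],
        }
    )
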