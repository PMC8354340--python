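import itertools

import pytest
from hypothesis import settings

from qsirs.scoring import CriterionPanel

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

# consistent (rr_qsofa, rr_sirs, rr_qsirs) triples, one per band of the
# single underlying respiratory rate: rr < 20, rr == 20, 20 < rr < 22, rr >= 22
RR_TRIPLES = [
    (False, False, False),
    (False, False, True),
    (False, True, True),
    (True, True, True),
]


def all_consistent_panels() -> list[CriterionPanel]:
    """Every criterion-flag combination realisable by a single observation."""
    panels = []
    for flags in itertools.product([False, True], repeat=5):
        sbp_low, gcs_low, temp_abnormal, hr_high, wbc_abnormal = flags
        for rr_qsofa, rr_sirs, rr_qsirs in RR_TRIPLES:
            panels.append(
                CriterionPanel(
                    sbp_low=sbp_low,
                    gcs_low=gcs_low,
                    temp_abnormal=temp_abnormal,
                    hr_high=hr_high,
                    wbc_abnormal=wbc_abnormal,
                    rr_qsofa=rr_qsofa,
                    rr_sirs=rr_sirs,
                    rr_qsirs=rr_qsirs,
                )
            )
    return panels


@pytest.fixture(scope="session")
def consistent_panels():
    return all_consistent_panels()
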