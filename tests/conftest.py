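import logging

import pytest

from gxepi import NRXN1, TNS1, write_cohort
from gxepi.datasets import reconstruct_cohort

# the rare-disease caveat for risk-ratio-scale measures is intentional
# and exercised explicitly; keep it out of the test log noise
logging.getLogger("gxepi.interaction").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def study_records():
    """The 188-child reconstruction of the replication study."""
    return reconstruct_cohort()


@pytest.fixture()
def cohort_file(tmp_path, study_records):
    path = tmp_path / "cohort.tsv"
    write_cohort(study_records, path, [TNS1, NRXN1])
    return path
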