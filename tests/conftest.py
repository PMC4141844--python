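import warnings

import numpy as np
import pytest

from crysprop.annotate import ResidueAnnotation, baseline_annotate
from crysprop.data.aaindex import default_aaindex_table
from crysprop.features import build_registry
from crysprop.seqio import ProteinRecord

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def aaindex_table():
    return default_aaindex_table()


@pytest.fixture(scope="session")
def registry(aaindex_table):
    return build_registry(aaindex_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_record(rng, length, rec_id="r"):
    from crysprop.data.scales import AA20

    seq = "".join(rng.choice(list(AA20), size=length))
    return ProteinRecord(id=rec_id, sequence=seq)


@pytest.fixture()
def sample_record():
    return ProteinRecord(
        id="sample",
        sequence=(
            "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK"
            "ALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE"
        ),
    )


@pytest.fixture()
def sample_annotation(sample_record):
    return baseline_annotate(sample_record)


@pytest.fixture()
def manual_annotation():
    """Fully hand-specified five-residue annotation for layout tests."""
    return ResidueAnnotation(
        length=5, ss="CCHHH", disorder="DDOOO", exposure="EEBBE", source="external"
    )
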