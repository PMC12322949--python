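import hypothesis
import pytest

hypothesis.settings.register_profile(
    "det", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("det")

from kinseq import KineticParams, RecognizerTable, default_table, packaged_peptides


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def peptides():
    return packaged_peptides()


@pytest.fixture(scope="session")
def table_bp1(table):
    """Default table with binding probability forced to 1 (no missed segments);
    used where a test needs every cognate residue to produce an RS."""
    kinetics = KineticParams(
        mean_pd=dict(table.kinetics.mean_pd),
        binding_prob={k: 1.0 for k in table.kinetics.mean_pd},
        mean_interpulse=table.kinetics.mean_interpulse,
    )
    return RecognizerTable(
        recognizers=list(table.recognizers),
        kinetics=kinetics,
        ptm_modifiers=list(table.ptm_modifiers),
        cleavage_mean_time=table.cleavage_mean_time,
    )
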