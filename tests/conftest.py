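import dataclasses

import pytest

import slemine as sm
from slemine.templates import EvidenceStyle


@pytest.fixture(scope="session")
def catalog():
    return sm.load_catalog()


@pytest.fixture(scope="session")
def perfect_config():
    """Reference cohort conditions with every record-degradation
    mechanism switched off: all evidence in-window, no titer traps, no
    unreported findings — extraction should recover truth exactly."""
    return dataclasses.replace(
        sm.reference_cohort_config(seed=101),
        out_of_window_prob=0.0,
        low_titer_trap_prob=0.0,
        n_full_determinations=None,
        evidence_style_mix={
            EvidenceStyle.NUMERICAL: 0.5,
            EvidenceStyle.PHRASE: 0.3,
            EvidenceStyle.DESCRIPTIVE: 0.2,
            EvidenceStyle.NOT_REPORTED: 0.0,
        },
    )


@pytest.fixture(scope="session")
def perfect_cohort(perfect_config):
    return sm.generate_cohort(perfect_config)


@pytest.fixture(scope="session")
def perfect_profiles(perfect_config, perfect_cohort):
    records, _ = perfect_cohort
    return sm.extract_cohort(records, window=perfect_config.window, seed=17)
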