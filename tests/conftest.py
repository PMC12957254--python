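import numpy as np
import pytest

from faersig.synthgen import SynthConfig, generate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(
        n_reports={"risankizumab": 300, "guselkumab": 300, "background": 900},
        injected_signals=[
            ("risankizumab", "pt 0050", 10.0),
            ("guselkumab", "pt 0040", 8.0),
        ],
        duplicate_rate=0.08,
        seed=42,
    )


@pytest.fixture(scope="session")
def synth_quarters(synth_config):
    quarters, manifest = generate(synth_config)
    return quarters, manifest


@pytest.fixture(scope="session")
def cleaned(synth_quarters):
    """Linked, deduplicated synthetic dataset with cases and records."""
    from faersig.cleaning import apply_dedup, build_records, case_table
    from faersig.faers_io import link_quarters

    quarters, manifest = synth_quarters
    deduped = apply_dedup(link_quarters(quarters))
    return {
        "dataset": deduped,
        "cases": case_table(deduped),
        "records": build_records(deduped),
        "manifest": manifest,
    }
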