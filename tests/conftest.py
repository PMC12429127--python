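import pytest
from hypothesis import settings

from cleavemap import (
    IdentificationSimConfig,
    ProteaseRule,
    ProteomeSpec,
    apply_filters,
    extract_sites,
    extract_windows,
    generate_proteome,
    simulate_identifications,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def proteome_small():
    """100 random proteins with lognormal lengths, uniform composition."""
    return generate_proteome(ProteomeSpec(n_proteins=100, seed=11))


@pytest.fixture(scope="session")
def gk_dataset(proteome_small):
    """A simulated glycine/lysine-preferring digestion run, carried through
    filtering, site extraction and window extraction."""
    rule = ProteaseRule("gk", {"G": 0.9, "K": 0.5})
    cfg = IdentificationSimConfig(seed=12)
    records, truth = simulate_identifications(proteome_small, rule, cfg)
    filtered = apply_filters(records)
    sites = extract_sites(filtered)
    windows = extract_windows(sites, dict(proteome_small))
    return {
        "proteome": proteome_small,
        "rule": rule,
        "records": records,
        "truth": truth,
        "filtered": filtered,
        "sites": sites,
        "windows": windows,
    }
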