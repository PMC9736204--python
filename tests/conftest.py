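import pytest

from hgblkit import variants as v
from hgblkit.synthetic import (
    DEFAULT_BCL6_EXONS,
    CohortConfig,
    default_templates,
    generate_cohort,
)


def noise_free_config(sizes, seed, **kwargs):
    """Cohort config with perfect callers and no artifact/germline injection."""
    defaults = dict(
        caller_sensitivity=(1.0,) * 5, artifact_rate=0.0, germline_rate=0.0
    )
    defaults.update(kwargs)
    return CohortConfig(group_sizes=sizes, seed=seed, **defaults)


def select_sample_mutations(bundle, cfg, sample):
    """Run one sample through merge -> consensus -> mask -> classify -> select."""
    merged = v.merge_caller_calls(bundle.caller_calls[sample], cfg.caller_count)
    confident = v.consensus_filter(merged)
    masked = v.apply_bcl6_exon_mask(confident, DEFAULT_BCL6_EXONS)
    return v.select_mutations(v.classify_variants(masked))


@pytest.fixture(scope="session")
def truth_cohort():
    """Study-sized cohort (10 DHL/THL, 10 SHL, 3 MCAD) with perfect caller
    sensitivity but artifact and germline injection switched on, so exact
    truth recovery through the filter chain is a meaningful check."""
    cfg = CohortConfig(
        group_sizes={"DHL_THL": 10, "SHL": 10, "MCAD": 3},
        caller_sensitivity=(1.0,) * 5,
        artifact_rate=2.0,
        germline_rate=3.0,
        seed=7,
    )
    return cfg, generate_cohort(cfg, default_templates())
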