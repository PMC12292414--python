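import numpy as np
import pytest

import starharvest as sh
from starharvest.features import cohort_opportunities


@pytest.fixture(scope="session")
def binary_design():
    return sh.DesignSpec(sh.MarkerCondition.BINARY)


@pytest.fixture(scope="session")
def rosters():
    return {
        cond: sh.make_roster(sh.DesignSpec(sh.MarkerCondition(cond)))
        for cond in ("binary", "multi", "gradient")
    }


@pytest.fixture(scope="session")
def colour_cohort():
    """Small all-avoiders binary cohort with a planted 30/70 colour mixture."""
    mix = (
        (sh.RuleParams(sh.RuleKind.COLOUR_BINARY, effect_logit=-1.5), 0.3),
        (sh.RuleParams(), 0.7),
    )
    spec = sh.CohortSpec(
        design=sh.DesignSpec(sh.MarkerCondition.BINARY),
        n_participants=40,
        rule_mixture=mix,
        seed=321,
    )
    return sh.simulate_cohort(spec)


@pytest.fixture(scope="session")
def colour_records(colour_cohort):
    return cohort_opportunities(colour_cohort)
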