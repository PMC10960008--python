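import numpy as np
import pytest

import misinfosim as m


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def posts():
    """One shared default stimulus set (40 true + 40 false posts)."""
    return m.generate_stimulus_set(seed=7)


@pytest.fixture(scope="session")
def small_run():
    """A small but complete experiment run (8 participants per cell)."""
    return m.run_experiment(m.ExperimentConfig(seed=11, n_per_cell=8))


@pytest.fixture(scope="session")
def replicate_bank():
    """Replicate experiments at the study's per-cell sample size.

    Each replicate runs the full default-calibrated experiment with
    n_per_cell = 104 and records the marginal intervention effects
    (badge/norm mean differences for false-post engagement, false belief
    and AUC) plus the ANOVA p-value for the badge effect on AUC. Shared by
    the power-contract and direction-reproduction tests.
    """
    records = []
    for k in range(200):
        res = m.run_experiment(m.ExperimentConfig(seed=10_000 + k, n_per_cell=104))
        summ = m.participant_summaries(res.trials, res.beliefs)
        rec = {}
        for factor in ("badge", "norm"):
            on = summ[summ[factor]]
            off = summ[~summ[factor].astype(bool)]
            for dv in ("composite_false", "belief_false", "auc"):
                rec[f"{factor}_{dv}_diff"] = float(on[dv].mean() - off[dv].mean())
        table = m.anova_2x2(summ["auc"], summ["badge"], summ["norm"], compute_ci=False)
        rec["auc_badge_p"] = table["badge"].p
        records.append(rec)
    return records
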