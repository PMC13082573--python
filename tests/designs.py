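"""Shared simulation designs and frozen oracle constants for acceptance tests.

The confounded design has two covariates (history counts H000, H001) that
affect both treatment and hazard — the true confounders — plus a noise
count (R000) and sex (treatment only).  The oracle risk difference was
computed once with ``oracle_estimands(confounded_config(...), n_mc=10**6,
seed=999)`` and frozen below; the survival ratio is exact in closed form
(``exp(-theta * tau_years)``) because the treatment hazard increment is
additive and constant.
"""

import numpy as np

from ehrcausal.synthetic import SimConfig

#: frozen 10^6-draw Monte-Carlo oracle (MC SE 1.1e-5)
TRUE_RD_CONFOUNDED = 0.064635
#: exact closed form exp(-0.02 * 1826/365.25)
TRUE_SR_CONFOUNDED = 0.904850

TRUE_CONFOUNDERS = ("H000_history", "H001_history")


def confounded_config(n=4000, seed=0, theta=0.02) -> SimConfig:
    return SimConfig(
        n_patients=n,
        n_history_features=2,
        n_recent_features=1,
        confounder_effect_on_treatment=[0.45, 0.35, 0.0, 0.55],
        confounder_effect_on_hazard=[0.015, 0.012, 0.0, 0.0],
        propensity_intercept=-0.55,
        baseline_hazard=0.04,
        treatment_effect=theta,
        death_hazard=0.0,
        censoring_mean_years=30.0,
        admin_horizon_years=10.0,
        seed=seed,
    )


def closed_form_config(n=5000, seed=0) -> SimConfig:
    """No covariate effects: survival ratio has the exact closed form."""
    return SimConfig(
        n_patients=n,
        n_history_features=1,
        n_recent_features=1,
        confounder_effect_on_treatment=[0.0, 0.0, 0.0],
        confounder_effect_on_hazard=[0.0, 0.0, 0.0],
        baseline_hazard=0.04,
        treatment_effect=0.02,
        death_hazard=0.0,
        censoring_mean_years=30.0,  # ~15% censored before the horizon
        admin_horizon_years=10.0,
        seed=seed,
    )
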