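import numpy as np
import pandas as pd
import pytest

import kpgrowth as kg
from kpgrowth import prepare, trend
from kpgrowth.cli import gradient_analysis, paired_records


@pytest.fixture(scope="session")
def default_campaign():
    """One full default campaign (8 seasons, kappa=1) shared across tests."""
    return kg.simulate_campaign(kg.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_records(default_campaign):
    c = default_campaign
    records, growth, kp_day = paired_records(c.intervals, c.temp_daily, c.kp_3h)
    return records, growth, kp_day


@pytest.fixture(scope="session")
def small_config():
    """A short campaign for fast end-to-end runs (window must be <= ~360)."""
    return kg.SyntheticConfig(seed=3, n_seasons=2, n_plots=2, shoots_per_sample=10)


def analyze_seed(seed: int, **overrides):
    """Full raw + residual gradient pass for one seeded campaign."""
    cfg = kg.SyntheticConfig(seed=seed, **overrides)
    c = kg.simulate_campaign(cfg)
    records, growth, kp_day = paired_records(c.intervals, c.temp_daily, c.kp_3h)
    raw = gradient_analysis(records)
    _, growth_resid = trend.fit_quadratic_per_season(growth)
    _, temp_resid = trend.fit_harmonic(c.temp_daily, cfg.temp_period_days)
    records_resid = prepare.lag_align(growth_resid, temp_resid, kp_day)
    resid = gradient_analysis(records_resid)
    return c, records, raw, resid


def make_pattern(values, start="2020-05-01", units="mm/day"):
    """Daily pattern on consecutive dates, for hand-computed examples."""
    idx = pd.date_range(start, periods=len(values), freq="D")
    return kg.DailyPattern(pd.Series(np.asarray(values, dtype=float), index=idx), units)
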