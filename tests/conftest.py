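import numpy as np
import pytest

from gvtrends.data import IntervalRecord
from gvtrends.simulate import SimTruth, simulate_media, simulate_state_panel
from gvtrends.spatial import SpatialZIPModel


@pytest.fixture(scope="session")
def default_panel():
    """Default-preset synthetic panel plus its ground truth."""
    return simulate_state_panel(seed=42)


@pytest.fixture(scope="session")
def small_zip_fit(default_panel):
    """One short shared ZIP-CAR fit for summary/diagnostic tests."""
    panel, _ = default_panel
    return SpatialZIPModel(panel).fit(n_chains=2, n_iter=1500, warmup=700, thin=4, seed=0)


def media_interval_records(n: int = 80, rho: float = -0.70, seed: int = 0,
                           days_seed: int = 1) -> list[IntervalRecord]:
    """Interval records with media covariates from the coupled generator."""
    rng = np.random.default_rng(days_seed)
    days = np.exp(rng.normal(3.5, 0.8, n)).round().clip(1)
    med = simulate_media(days, rho_target=rho, seed=seed)
    return [
        IntervalRecord(
            index=i,
            start_event=f"E{i:04d}",
            end_event=f"E{i + 1:04d}",
            interval_days=float(d),
            media_article_count=float(c),
            media_density=float(c) / float(d),
            search_interest=float(si),
        )
        for i, (d, c, si) in enumerate(
            zip(days, med["article_count"], med["search_interest"])
        )
    ]
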