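import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sharedness.embeddings import EmbeddingTable
from sharedness.records import DailyReport
from sharedness.synth import GeneratorConfig, generate_study

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_report(pid="P1", team="A", date="2022-09-01", wb=6.0, atm=6.0, diary="", ts=None):
    return DailyReport(
        participant_id=pid, team_id=team, date=dt.date.fromisoformat(date),
        wellbeing=wb, atmosphere=atm, diary=diary, submitted_at=ts,
    )


@pytest.fixture(scope="session")
def tiny_embeddings():
    """Six tokens at hand-placed 2-D positions for closed-form distances."""
    return EmbeddingTable(
        {
            "alpha": np.array([0.0, 0.0]),
            "beta": np.array([3.0, 4.0]),   # 5 from alpha
            "gamma": np.array([1.0, 0.0]),  # 1 from alpha
            "delta": np.array([0.0, 2.0]),
            "eps": np.array([6.0, 8.0]),
            "zeta": np.array([-1.0, 0.0]),
        }
    )


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study at the default conditions (shared, read-only)."""
    cfg = GeneratorConfig(seed=11)
    reports, ihs, truth = generate_study(cfg)
    return cfg, reports, ihs, truth
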