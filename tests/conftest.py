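import numpy as np
import pytest

from smartrct import TrialEngine, load_profile, make_synthetic_db
from smartrct.food_db import Product


@pytest.fixture(scope="session")
def au_config():
    return load_profile("australia")


@pytest.fixture(scope="session")
def nz_config():
    return load_profile("new_zealand")


@pytest.fixture(scope="session")
def db():
    return make_synthetic_db(n_products=60, n_categories=6, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_product(**overrides) -> Product:
    """A plain mid-range food product; override any field."""
    base = dict(
        barcode="9300601234569", name="test biscuit", category_id="biscuits",
        is_beverage=False, serving_size=50.0, energy_kj_100=2000.0,
        protein_g_100=6.0, fat_g_100=20.0, satfat_g_100=10.0,
        carb_g_100=60.0, sugars_g_100=30.0, sodium_mg_100=400.0,
        fibre_g_100=3.0, fvnl_pct=None,
    )
    base.update(overrides)
    return Product(**base)


@pytest.fixture
def product():
    return make_product()


def enroll(engine: TrialEngine, pid: str = "P1", day: int = 0,
           factors: dict | None = None, email: str | None = None):
    """Walk a participant through consent, screening, registration, baseline."""
    cfg = engine.config
    engine.add_participant(pid, day=day)
    engine.consent(pid, True, True, day=day)
    engine.screen(pid, {k: True for k in cfg.screening.required_true}, day=day)
    if factors is None:
        factors = {f: levels[0] for f, levels in cfg.stratification.items()}
    engine.register(pid, email or f"{pid}@example.org", day=day, factors=factors)
    engine.submit_baseline_questionnaire(pid, {"q": 1}, day=day)
    return engine.participants[pid]


def record_items(engine: TrialEngine, pid: str, n_items: int, day: int | None = None):
    """Scan n matched items and transmit the list at the current clock."""
    if day is not None:
        engine.advance_to(pid, day)
    barcode = next(iter(engine.db.products))
    for _ in range(n_items):
        engine.scan(pid, barcode)
    return engine.submit_list(pid)
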