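"""Shared fixtures: reference cohort data, small synthetic databases and a
scaled-down trained pipeline reused by the end-to-end checks."""

from pathlib import Path

import numpy as np
import pytest

from nutriplan.meals import SLOTS
from nutriplan.model import DietVAE, ModelConfig
from nutriplan.profiles import load_guidelines, read_profiles_csv
from nutriplan.synth import (CohortSpec, MealDistSpec, assemble_truth_plans,
                             simulate_meal_db, simulate_profiles)
from nutriplan.train import TrainConfig, build_dataset, split_dataset, train

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_users_path() -> Path:
    """CSV of the 20-user reference cohort (printed worked examples)."""
    return DATA_DIR / "reference_users.csv"


@pytest.fixture(scope="session")
def reference_users(reference_users_path):
    return read_profiles_csv(reference_users_path)


@pytest.fixture(scope="session")
def guidelines():
    return load_guidelines()


@pytest.fixture(scope="session")
def tiny_db():
    """Small meal database: 8 meals per slot, fixed seed."""
    return simulate_meal_db(
        MealDistSpec(slot_counts={s: 8 for s in SLOTS}, seed=42))


@pytest.fixture(scope="session")
def tiny_model(tiny_db, guidelines):
    """Untrained small model compatible with tiny_db."""
    return DietVAE(
        ModelConfig(vocab_size=tiny_db.vocab_size, encoder_hidden=16,
                    latent_dim=8, decoder_hidden=16, seed=7),
        bounds=guidelines["normalization_bounds"],
        vocab_hash=tiny_db.vocabulary_hash())


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_profiles(CohortSpec(n_users=100, seed=5))


@pytest.fixture(scope="session")
def trained_pipeline(guidelines):
    """Scaled-down study: 200 profiles, 10 meals per slot, 50 epochs.

    Session-scoped because training takes ~10 s; the end-to-end assertions
    all read from this one run.
    """
    profiles = simulate_profiles(CohortSpec(n_users=200, seed=11))
    db = simulate_meal_db(
        MealDistSpec(slot_counts={s: 10 for s in SLOTS}, seed=12))
    plans = assemble_truth_plans(profiles, db, days_per_user=7, seed=13)
    data = build_dataset(profiles, plans, guidelines)
    train_data, test_data = split_dataset(data, 0.8, seed=14)
    model = DietVAE(
        ModelConfig(vocab_size=db.vocab_size, encoder_hidden=64,
                    latent_dim=32, decoder_hidden=64, seed=15),
        bounds=guidelines["normalization_bounds"],
        vocab_hash=db.vocabulary_hash())
    config = TrainConfig(learning_rate=1e-4, epochs=50, batch_size=64,
                         seed=16)
    model, history = train(model, db, train_data, config, val_data=test_data)
    return {"profiles": profiles, "db": db, "plans": plans, "model": model,
            "history": history, "train_data": train_data,
            "test_data": test_data}
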