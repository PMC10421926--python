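"""Shared fixtures: a tiny simulated cohort and a trained small model.

The tiny cohort is deliberately narrow (4 temporal numerics, 1 temporal
categorical, T_max=8) so that training-based tests run in seconds; the
mimic-like preset is exercised separately in the acceptance suite.
"""

import numpy as np
import pytest

from synthehr.autoencoder import TrainingConfig
from synthehr.data import train_test_split
from synthehr.pipeline import PipelineConfig, train_pipeline
from synthehr.toygen import CategoricalLaw, NumericLaw, ToyConfig, generate_cohort


def tiny_config(seed: int = 0, n: int = 250, **overrides) -> ToyConfig:
    defaults = dict(
        n_patients=n,
        t_max=8,
        mean_length=4.0,
        static_numeric={
            "age": NumericLaw("gamma", {"shape": 9.0, "scale": 5.0, "shift": 20.0}),
        },
        static_categorical={
            "gender": CategoricalLaw(("F", "M"), (0.55, 0.45)),
            "admission_type": CategoricalLaw(("emergency", "elective", "urgent"), (0.7, 0.2, 0.1)),
        },
        temporal_numeric={
            "heart_rate": NumericLaw("normal", {"mu": 82.0, "sigma": 12.0}, severity_weight=6.0),
            "spo2": NumericLaw("normal", {"mu": 97.0, "sigma": 2.5}, severity_weight=-1.0),
            "resp_pressure": NumericLaw("normal", {"mu": 42.0, "sigma": 7.0}, round_to=5.0),
            "glucose": NumericLaw("lognormal", {"mu": 4.9, "sigma": 0.35}),
        },
        temporal_categorical={
            "o2_device": CategoricalLaw(("none", "cannula", "ventilator"), (0.55, 0.3, 0.15)),
        },
        missing_rates={"heart_rate": 0.3, "spo2": 0.4, "resp_pressure": 0.5,
                       "glucose": 0.6, "o2_device": 0.4},
        outcome_prevalence=0.2,
        seed=seed,
    )
    defaults.update(overrides)
    return ToyConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    config = tiny_config(seed=7)
    dataset, masks, gt = generate_cohort(config)
    return dataset, masks, gt


@pytest.fixture(scope="session")
def small_training_config():
    return PipelineConfig(
        seed=3,
        codec_epochs=60,
        training=TrainingConfig(epochs=30, d_e=24, hidden=48, batch_size=64,
                                learning_rate=2e-3, gan_iters=300,
                                gan_batch_size=64, seed=3),
    )


@pytest.fixture(scope="session")
def trained_small_model(tiny_cohort, small_training_config):
    dataset, masks, gt = tiny_cohort
    (tr, trm), (te, tem) = train_test_split(dataset, masks, seed=1)
    model = train_pipeline(tr, trm, gt["schema"], small_training_config)
    return {"model": model, "train": (tr, trm), "test": (te, tem),
            "schema": gt["schema"], "gt": gt}
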