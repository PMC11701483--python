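import numpy as np
import pytest

from biotypegcn import CohortSpec, TrainingConfig, build_graph, generate_cohort, train

# Desk-scale study conditions: 600 subjects (200 HC + 400 patients, two
# planted subtypes), standardized edge effect 0.8, edge noise SD 0.1.
# Tests run at C = 20 components (d = 190 edges) for speed.
TEST_SIZES = (2, 1, 3, 3, 6, 3, 2)


def make_spec(seed, effect_size=0.8, noise_sd=0.1, n_hc=200, n_patients=400):
    return CohortSpec(
        n_hc=n_hc,
        n_patients=n_patients,
        n_components=20,
        network_sizes=TEST_SIZES,
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_config(seed, **overrides):
    kw = dict(
        K=2,
        hidden_dims=(64,),
        embedding_dim=32,
        pretrain_epochs=60,
        joint_epochs=120,
        seed=seed,
    )
    kw.update(overrides)
    return TrainingConfig(**kw)


def planted_cohort(seed, effect_size=0.8, noise_sd=0.1):
    spec = make_spec(seed, effect_size, noise_sd)
    subjects, fnc = generate_cohort(spec)
    truth = np.array([s.true_subtype for s in subjects if s.diagnosis == "patient"])
    graph = build_graph(subjects, fnc)
    return spec, subjects, fnc, graph, truth


@pytest.fixture(scope="session")
def cohort_seed1():
    return planted_cohort(1)


@pytest.fixture(scope="session")
def model_seed1(cohort_seed1):
    _, _, _, graph, _ = cohort_seed1
    return train(graph, make_config(1))
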