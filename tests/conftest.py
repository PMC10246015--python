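import pytest
from hypothesis import settings, HealthCheck

from trajscale import GeneratorConfig, generate_session
from trajscale.preprocess import ConditionTensor, filter_and_normalize, preprocess_session
from trajscale.subspace import CommonSubspace
from trajscale import synth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

ROUNDED_MS = (300.0, 400.0, 500.0, 600.0)


def make_ideal_tensor(config: GeneratorConfig) -> ConditionTensor:
    """Noise-free 8 x 4 condition tensor built directly from the generator's
    latent curves (no spiking, no kinematics)."""
    family = synth.make_latent_family(config)
    labels, values, axes = [], [], []
    for d in range(8):
        for u, dur in enumerate(ROUNDED_MS):
            t_axis, rates = synth.ideal_condition_epoch(
                config, family, d * 45.0, dur)
            labels.append((d, u))
            values.append(rates)
            axes.append(t_axis)
    tensor = ConditionTensor(labels, values, axes, [1] * 32, "duration", 10.0)
    return filter_and_normalize(tensor)


@pytest.fixture(scope="session")
def ideal_tensor():
    return make_ideal_tensor(GeneratorConfig())


@pytest.fixture(scope="session")
def ideal_space(ideal_tensor):
    return CommonSubspace().fit(ideal_tensor)


@pytest.fixture(scope="session")
def ideal_trajectories(ideal_tensor, ideal_space):
    return {t.condition: t for t in ideal_space.transform(ideal_tensor)}


@pytest.fixture(scope="session")
def balanced_session():
    """Compact noisy session with every direction x duration bin populated."""
    return generate_session(GeneratorConfig(
        n_trials=48, balanced_conditions=True, latent_seed=11, spike_seed=12))


@pytest.fixture(scope="session")
def noisy_pipeline(balanced_session):
    tensor, spec, events = preprocess_session(balanced_session)
    space = CommonSubspace().fit(tensor)
    trajs = {t.condition: t for t in space.transform(tensor)}
    return dict(tensor=tensor, spec=spec, events=events, space=space,
                trajectories=trajs)
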