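import pytest

from eftrain import AgentSpec, Task, make_config


@pytest.fixture
def config_factory():
    """Session configs with sensible test defaults."""

    def factory(task=Task.WORKING_MEMORY, **overrides):
        kwargs = dict(
            study_id="S01",
            session_number=1,
            task=task,
            n_trials=50,
            seed=7,
        )
        kwargs.update(overrides)
        return make_config(**kwargs)

    return factory


@pytest.fixture
def perfect_spec():
    return AgentSpec(kind="perfect", agent_seed=11)
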