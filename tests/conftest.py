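import numpy as np
import pytest

from gazescan import (
    CohortManifest,
    CohortSpec,
    GazeRecording,
    ImageEntry,
    ParticipantRecord,
    generate_cohort,
)


@pytest.fixture
def tiny_recording() -> GazeRecording:
    """Hand-constructed 3-sample recording: (0,0) -> (3,4) -> (6,8) at 4 ms."""
    return GazeRecording(
        participant_id="p0",
        stimulus_id="s0",
        t=[0.0, 4.0, 8.0],
        x=[0.0, 3.0, 6.0],
        y=[0.0, 4.0, 8.0],
        valid=[True, True, True],
    )


@pytest.fixture
def small_manifest() -> CohortManifest:
    participants = [
        ParticipantRecord("a1", "ASD", cars=35.0),
        ParticipantRecord("a2", "ASD", cars=40.0),
        ParticipantRecord("t1", "non-ASD", cars=15.0),
        ParticipantRecord("t2", "non-ASD", cars=15.0),
    ]
    images = [
        ImageEntry(f"{p.participant_id}_s0_{k}.png", p.participant_id, "s0", k)
        for p in participants
        for k in range(3)
    ]
    return CohortManifest(participants=participants, images=images)


@pytest.fixture(scope="session")
def mini_cohort():
    """A small but non-trivial synthetic cohort shared across tests."""
    spec = CohortSpec(
        n_asd=4, n_td=4, recordings_per_participant=1, duration_s=3.0, seed=11
    )
    return generate_cohort(spec)


def random_recording(
    rng: np.random.Generator,
    n: int,
    screen=(1280, 1024),
    rate: float = 250.0,
    invalid_fraction: float = 0.0,
) -> GazeRecording:
    """Uniform random gaze positions with strictly increasing timestamps."""
    dt = 1000.0 / rate
    t = np.arange(n) * dt + rng.uniform(0, 0.1, n).cumsum()
    x = rng.uniform(0, screen[0], n)
    y = rng.uniform(0, screen[1], n)
    valid = rng.random(n) >= invalid_fraction
    return GazeRecording(
        participant_id="r", stimulus_id="s", t=t, x=x, y=y, valid=valid,
        screen=screen, sampling_rate=rate,
    )
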