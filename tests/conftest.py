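import numpy as np
import pytest

from napinsight import simulate
from napinsight.core import SessionData, TrialRecord


@pytest.fixture(scope="session")
def schedule():
    return simulate.generate_task_schedule(seed=1)


@pytest.fixture(scope="session")
def wake_hypnogram():
    return simulate.Hypnogram(["W"] * 40)


def single_channel_params(b=1.0, x=1.5, peaks=()):
    """One-channel EEG simulation parameters with a single Wake stage."""
    return simulate.EEGSimParams(
        channels={"F4": (0.4, 0.55)},
        stage_aperiodic={"W": (b, x)},
        stage_peaks={"W": list(peaks)},
    )


def make_session(block8_correct: int, subject_id: str = "s") -> SessionData:
    """Minimal hand-built session: 30 low-coherence trials per block 3-8,
    with a given number correct in block 8 (the classification block)."""
    trials = []
    idx = 0
    for block in range(1, 10):
        for i in range(100):
            idx += 1
            if block in range(3, 9) and i < 30:
                coh = 0.05
                correct = (
                    i < block8_correct if block == 8 else (idx % 2 == 0)
                )
            else:
                coh = 0.76
                correct = True
            trials.append(
                TrialRecord(
                    block=block, trial_index=idx, coherence=coh,
                    colour="orange", direction="NW",
                    response="left" if correct else "right",
                    correct=correct, rt_ms=600.0,
                    colour_predictive=idx >= 351, instructed=block == 9,
                )
            )
    return SessionData(trials=trials, subject_id=subject_id)


@pytest.fixture(scope="session")
def insight_fits():
    """Shared bank of fitted default-calibration agents (used by several
    behavioural checks): 120 insight and 60 non-insight agents."""
    from napinsight import behavior

    sched = simulate.generate_task_schedule(seed=1)
    bank = {"insight": [], "noninsight": []}
    for kind, n, truth in (("insight", 200, True), ("noninsight", 60, False)):
        for s in range(n):
            rng = np.random.default_rng(40_000 + s + (0 if truth else 10_000))
            agent = simulate.draw_agent(rng, truth)
            sess = simulate.simulate_agent_responses(
                sched, agent, seed=50_000 + s + (0 if truth else 10_000),
                subject_id=f"{kind}-{s}",
            )
            fit = behavior.fit_session_sigmoid(sess)
            label = behavior.classify_insight(sess, fit)
            bank[kind].append((agent, sess, fit, label))
    return bank
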