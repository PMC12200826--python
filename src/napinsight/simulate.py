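"""Synthetic cohort generator: task schedules, agents, hypnograms, nap EEG.

The generator produces data with the statistical structure the analysis
chain assumes, so every downstream stage can be exercised end-to-end
without any external recordings:

* a 900-trial random-dot motion/colour session (9 blocks x 100 trials,
  five coherence levels, hidden colour rule active from trial 351, nap
  between trials 400 and 401, colour instruction in block 9);
* behavioural agents whose probability correct mixes a coherence-dependent
  motion strategy with a colour strategy through a sigmoid transition
  centred on a latent switch trial — insight-like abrupt strategy switches;
* 20-minute, 200-Hz multichannel nap EEG whose power spectrum follows
  10^b / f^x per sleep stage plus Gaussian oscillatory peaks (alpha,
  spindles), with the aperiodic exponent steepening with sleep depth;
* 30-s AASM hypnograms consistent with a Wake / N1 / N2 group assignment.

Determinism: every public entry point takes a seed; cohort members draw
from per-subject ``numpy.random.SeedSequence`` streams keyed by (master
seed, group, index) so enlarging the cohort never reshuffles earlier
subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    COHERENCE_LEVELS,
    LEFT_DIRECTIONS,
    STAGE_ORDER,
    Hypnogram,
    Recording,
    SessionData,
    Subject,
    TrialRecord,
)
from .montage import DEFAULT_MONTAGE

DIRECTIONS = ("NW", "NE", "SW", "SE")

#: Per-block coherence composition. Block 1 is pure 100% coherence; block 2
#: uses only the three easiest levels; blocks 3-9 mix all five with the
#: noisiest level over-represented (30 per 100 vs 10/20/20/20).
_BLOCK3_9_COUNTS = {0.05: 30, 0.23: 10, 0.41: 20, 0.59: 20, 0.76: 20}
_BLOCK2_COUNTS = {0.41: 33, 0.59: 33, 0.76: 34}

COLOUR_ONSET_TRIAL = 351
NAP_BOUNDARY_TRIAL = 400
INSTRUCTION_BLOCK = 9

#: Fixed colour <-> response mapping once the colour rule is active:
#: orange predicts the left (NW/SE) diagonal, purple the right (NE/SW).
COLOUR_FOR_RESPONSE = {"left": "orange", "right": "purple"}

#: Default psychometric table: probability correct under the motion strategy
#: by coherence. Calibrated so that the *effective* accuracy — after the
#: default cohort lapse rate of 0.03 mixes in random responding — is ~56%
#: at 5% coherence and ~92% on low-noise (76%) trials, with a noiseless
#: ceiling at full coherence.
DEFAULT_P_MOTION = {
    0.05: 0.562,
    0.23: 0.727,
    0.41: 0.830,
    0.59: 0.892,
    0.76: 0.933,
    1.00: 1.00,
}


@dataclass(frozen=True)
class TaskSchedule:
    """The stimulus side of a 900-trial session (no responses yet)."""

    trials: list[TrialRecord]

    def __post_init__(self) -> None:
        if len(self.trials) != 900:
            raise ValueError("a task schedule has exactly 900 trials")


@dataclass
class AgentParams:
    """Latent behavioural parameters of one simulated participant.

    ``p_motion`` maps coherence to probability correct under the motion
    strategy; ``p_colour`` is the probability correct once the colour
    strategy is used. Insight agents transition between the two with
    logistic weight 1/(1+exp(-m_true*(t - t_s_true))) from colour onset;
    non-insight agents never switch. ``lapse`` mixes in random responding.
    """

    is_insight: bool
    t_s_true: float = 500.0
    m_true: float = 0.075
    p_motion: dict[float, float] = field(
        default_factory=lambda: dict(DEFAULT_P_MOTION)
    )
    p_colour: float = 0.97
    lapse: float = 0.0
    rt_pre_ms: float = 767.0
    rt_post_ms: float = 527.0
    rt_sigma: float = 0.30  # log-normal shape parameter

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")
        if not 0.5 < self.p_colour <= 1.0:
            raise ValueError("p_colour must lie in (0.5, 1]")
        cs = sorted(self.p_motion)
        ps = [self.p_motion[c] for c in cs]
        if any(not 0.5 <= p <= 1.0 for p in ps):
            raise ValueError("p_motion values must lie in [0.5, 1]")
        if any(b < a for a, b in zip(ps, ps[1:])):
            raise ValueError("p_motion must be monotone non-decreasing")
        if self.m_true < 0:
            raise ValueError("m_true must be non-negative")


@dataclass
class EEGSimParams:
    """Stage-resolved spectral parameters of the EEG simulator.

    ``stage_aperiodic`` maps stage code -> (offset b, exponent x) of the
    aperiodic density 10^b / f^x (power in µV²/Hz, f in Hz); the reported
    "spectral slope" is -x. ``stage_peaks`` maps stage -> list of Gaussian
    peaks (centre Hz, height in log10-power units, width=sd Hz) added to
    the log10 spectrum. Defaults encode the canonical steepening of the
    slope with sleep depth (Wake -1.37, N1 -1.47, N2 -1.79 group means)
    and stage-dependent alpha/spindle oscillations.
    """

    sampling_rate: float = 200.0
    channels: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MONTAGE)
    )
    stage_aperiodic: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "W": (1.0, 1.37),
            "N1": (1.0, 1.47),
            "N2": (1.1, 1.79),
            "N3": (1.2, 2.1),
        }
    )
    stage_peaks: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {
            # Wake rest: posterior-style alpha
            "W": [(10.0, 0.55, 1.2)],
            # N1: attenuated, slowed alpha
            "N1": [(9.0, 0.30, 1.4)],
            # N2: sleep spindles plus residual slow alpha
            "N2": [(13.5, 0.45, 1.0), (9.0, 0.15, 1.5)],
            "N3": [(13.0, 0.25, 1.2)],
        }
    )
    edge_taper_s: float = 0.1  # cosine cross-fade at 30-s epoch joins

    def validate(self, stages_present: set[str]) -> None:
        missing = stages_present - set(self.stage_aperiodic)
        if missing:
            raise ValueError(f"no aperiodic parameters for stages {missing}")
        nyq = self.sampling_rate / 2.0
        for stage, peaks in self.stage_peaks.items():
            for cf, _h, _w in peaks:
                if cf >= nyq:
                    raise ValueError(
                        f"peak at {cf} Hz exceeds Nyquist ({nyq} Hz) for {stage}"
                    )
                if not 1.0 <= cf <= 45.0:
                    raise ValueError("peak centres must lie within 1-45 Hz")
        for stage, (_b, x) in self.stage_aperiodic.items():
            if x < 0:
                raise ValueError("aperiodic exponent must be >= 0")


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

def generate_task_schedule(seed: int) -> TaskSchedule:
    """Build the 900-trial schedule, shuffling coherences within block."""
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    for block in range(1, 10):
        if block == 1:
            coherences = [1.00] * 100
        elif block == 2:
            coherences = [c for c, n in _BLOCK2_COUNTS.items() for _ in range(n)]
        else:
            coherences = [c for c, n in _BLOCK3_9_COUNTS.items() for _ in range(n)]
        coherences = list(rng.permutation(coherences))
        for i, coh in enumerate(coherences):
            trial_index = (block - 1) * 100 + i + 1
            direction = DIRECTIONS[rng.integers(4)]
            correct_response = "left" if direction in LEFT_DIRECTIONS else "right"
            predictive = trial_index >= COLOUR_ONSET_TRIAL
            if predictive:
                colour = COLOUR_FOR_RESPONSE[correct_response]
            else:
                colour = "orange" if rng.integers(2) == 0 else "purple"
            trials.append(
                TrialRecord(
                    block=block,
                    trial_index=trial_index,
                    coherence=float(coh),
                    colour=colour,
                    direction=direction,
                    response="",
                    correct=False,
                    rt_ms=float("nan"),
                    colour_predictive=predictive,
                    instructed=block == INSTRUCTION_BLOCK,
                )
            )
    return TaskSchedule(trials=trials)


def _switch_weight(trial_index: np.ndarray, agent: AgentParams) -> np.ndarray:
    """Logistic colour-strategy weight; zero before colour onset."""
    if not agent.is_insight:
        return np.zeros_like(trial_index, dtype=float)
    z = np.clip(-agent.m_true * (trial_index - agent.t_s_true), -500.0, 500.0)
    w = 1.0 / (1.0 + np.exp(z))
    w[trial_index < COLOUR_ONSET_TRIAL] = 0.0
    return w


def simulate_agent_responses(
    schedule: TaskSchedule, agent: AgentParams, seed: int, subject_id: str = ""
) -> SessionData:
    """Draw one session of Bernoulli responses from an agent.

    Probability correct on trial t is a lapse-contaminated mixture of the
    motion strategy (coherence-dependent) and the colour strategy, weighted
    by the sigmoid transition. During the instructed final block every
    agent uses the colour strategy. Reaction times are log-normal, their
    mean interpolating from pre- to post-switch level with the same weight.
    """
    if agent.is_insight and not (
        COLOUR_ONSET_TRIAL <= agent.t_s_true <= 900
    ):
        raise ValueError(
            "insight agents must have t_s_true within [351, 900]; "
            f"got {agent.t_s_true}"
        )
    rng = np.random.default_rng(seed)
    idx = np.array([t.trial_index for t in schedule.trials])
    w = _switch_weight(idx, agent)
    trials: list[TrialRecord] = []
    for t, wt in zip(schedule.trials, w):
        if t.instructed:
            wt = 1.0
        p_strategy = (1.0 - wt) * agent.p_motion[t.coherence] + wt * agent.p_colour
        p = (1.0 - agent.lapse) * p_strategy + agent.lapse * 0.5
        correct_response = "left" if t.direction in LEFT_DIRECTIONS else "right"
        correct = bool(rng.random() < p)
        response = (
            correct_response
            if correct
            else ("right" if correct_response == "left" else "left")
        )
        mean_rt = (1.0 - wt) * agent.rt_pre_ms + wt * agent.rt_post_ms
        mu = math.log(mean_rt) - agent.rt_sigma**2 / 2.0
        rt = float(rng.lognormal(mu, agent.rt_sigma))
        trials.append(
            TrialRecord(
                block=t.block,
                trial_index=t.trial_index,
                coherence=t.coherence,
                colour=t.colour,
                direction=t.direction,
                response=response,
                correct=correct,
                rt_ms=rt,
                colour_predictive=t.colour_predictive,
                instructed=t.instructed,
            )
        )
    return SessionData(trials=trials, subject_id=subject_id)


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def simulate_hypnogram(
    group: str,
    seed: int,
    n_epochs: int = 40,
    min_n2_minutes: float = 2.0,
    mean_latency_epochs: float = 8.0,
) -> Hypnogram:
    """Simulate a 20-minute nap hypnogram consistent with a vigilance group.

    Wake-group naps contain only W epochs. N1 naps show a wake latency
    followed by N1 episodes (interspersed with brief awakenings) and never
    reach N2. N2 naps descend W -> N1 -> N2 and hold at least
    ``min_n2_minutes`` of N2. Latency and episode durations are drawn from
    seeded geometric/uniform distributions.
    """
    if group not in ("Wake", "N1", "N2"):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    if group == "Wake":
        return Hypnogram(["W"] * n_epochs)

    latency = int(
        np.clip(rng.geometric(1.0 / mean_latency_epochs), 2, n_epochs // 2)
    )
    labels = ["W"] * latency
    if group == "N1":
        while len(labels) < n_epochs:
            n1_run = int(rng.integers(2, 8))
            labels.extend(["N1"] * n1_run)
            if len(labels) < n_epochs and rng.random() < 0.4:
                labels.extend(["W"] * int(rng.integers(1, 3)))
        labels = labels[:n_epochs]
        if "N1" not in labels:  # latency ate the nap; force one N1 epoch
            labels[-1] = "N1"
        return Hypnogram(labels)

    # N2 group: N1 transition then a sustained N2 run
    min_n2_epochs = max(1, math.ceil(min_n2_minutes * 60.0 / 30.0))
    n1_run = int(rng.integers(2, 6))
    labels.extend(["N1"] * n1_run)
    remaining = n_epochs - len(labels)
    n2_run = int(
        np.clip(rng.integers(min_n2_epochs, max(min_n2_epochs + 1, remaining + 1)),
                min_n2_epochs, max(min_n2_epochs, remaining))
    )
    if remaining < min_n2_epochs:  # make room by shortening N1/latency
        labels = labels[: n_epochs - min_n2_epochs]
        n2_run = min_n2_epochs
    labels.extend(["N2"] * n2_run)
    while len(labels) < n_epochs:
        labels.extend(
            ["N1"] * int(rng.integers(1, 4)) if rng.random() < 0.5
            else ["N2"] * int(rng.integers(1, 4))
        )
    return Hypnogram(labels[:n_epochs])


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _epoch_noise(
    n_samples: int,
    fs: float,
    b: float,
    x: float,
    peaks: list[tuple[float, float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Spectrally shaped Gaussian noise with target one-sided PSD.

    The target log10 density is b - x*log10(f) plus Gaussian peaks; white
    complex Gaussian Fourier coefficients are scaled so the expected
    periodogram equals the target exactly (the DC bin is zeroed). Below
    1 Hz the density plateaus at its 1-Hz value, mimicking the
    low-frequency plateau of real EEG spectra; without it, the diverging
    sub-1-Hz power-law energy leaks through the analysis taper and biases
    the estimated exponent steep.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    log_psd = np.full(freqs.shape, -np.inf)
    with np.errstate(divide="ignore"):
        log_psd[1:] = b - x * np.log10(np.maximum(freqs[1:], 1.0))
    for cf, height, width in peaks:
        log_psd[1:] = log_psd[1:] + height * np.exp(
            -((freqs[1:] - cf) ** 2) / (2.0 * width**2)
        )
    psd = np.where(np.isfinite(log_psd), 10.0**log_psd, 0.0)
    scale = np.sqrt(psd * fs * n_samples / 4.0)
    z = scale * (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    )
    z[0] = 0.0
    if n_samples % 2 == 0:
        z[-1] = z[-1].real * math.sqrt(2.0)
    return np.fft.irfft(z, n_samples)


def simulate_eeg(
    hypnogram: Hypnogram, params: EEGSimParams, seed: int
) -> Recording:
    """Synthesize a multichannel recording matching a hypnogram.

    Each 30-s scoring epoch is an independent realization of spectrally
    shaped noise with the aperiodic and peak parameters of its stage;
    epochs are concatenated with a short cosine cross-fade at the joins.
    Channels share parameters but use independent noise streams.
    """
    params.validate(set(hypnogram.epoch_labels))
    fs = params.sampling_rate
    n_ep_samples = int(round(hypnogram.epoch_length * fs))
    names = list(params.channels)
    rng = np.random.default_rng(seed)
    taper_n = int(round(params.edge_taper_s * fs))
    ramp = np.sin(np.linspace(0.0, np.pi / 2.0, max(taper_n, 1))) ** 2
    data = np.empty((len(names), n_ep_samples * len(hypnogram.epoch_labels)))
    for ci in range(len(names)):
        pieces = []
        for stage in hypnogram.epoch_labels:
            b, x = params.stage_aperiodic[stage]
            peaks = params.stage_peaks.get(stage, [])
            seg = _epoch_noise(n_ep_samples, fs, b, x, peaks, rng)
            if taper_n:
                seg[:taper_n] *= ramp
                seg[-taper_n:] *= ramp[::-1]
            pieces.append(seg)
        data[ci] = np.concatenate(pieces)
    return Recording(samples=data, sampling_rate=fs, channel_names=names)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

DEFAULT_GROUP_SIZES = {"N2": 28, "N1": 22, "Wake": 18}
DEFAULT_INSIGHT_RATES = {"N2": 24 / 28, "N1": 14 / 22, "Wake": 10 / 18}


def _subject_seed_seq(master_seed: int, group: str, index: int) -> np.random.SeedSequence:
    """Counter-based per-subject stream: stable under cohort-size changes."""
    gi = {"N2": 0, "N1": 1, "Wake": 2}[group]
    return np.random.SeedSequence(entropy=(int(master_seed), gi, int(index)))


def draw_agent(
    rng: np.random.Generator,
    is_insight: bool,
    t_s_range: tuple[float, float] = (405.0, 650.0),
    t_s_mean: float = 510.0,
    t_s_sd: float = 80.0,
    m_mean: float = 0.075,
    m_sd_log: float = 0.30,
    p_colour: float = 0.97,
    lapse: float = 0.03,
) -> AgentParams:
    """Draw heterogeneous agent parameters for one cohort member.

    Switch centres follow a truncated normal over the post-nap range
    (mean near block 5, matching the delayed, variable timing of insight);
    slopes are log-normal around the calibrated default. The defaults are
    calibrated once so the switch-aligned accuracy profile of a simulated
    insight cohort matches the canonical ~62%/~88% window means around the
    switch (a ~25% jump within 15 low-coherence trials).
    """
    t_s = float(np.clip(rng.normal(t_s_mean, t_s_sd), *t_s_range))
    m = float(np.clip(rng.lognormal(math.log(m_mean), m_sd_log), 0.005, 5.0))
    return AgentParams(
        is_insight=is_insight, t_s_true=t_s, m_true=m,
        p_colour=p_colour, lapse=lapse,
    )


def simulate_cohort(
    seed: int,
    n_per_group: dict[str, int] | None = None,
    insight_rates: dict[str, float] | None = None,
    quota: bool = False,
    with_eeg: bool = True,
    eeg_params: EEGSimParams | None = None,
    slope_insight_effect: float = 0.25,
    slope_subject_sd: float = 0.25,
    agent_kwargs: dict | None = None,
) -> list[Subject]:
    """Simulate a full nap cohort (behaviour + hypnogram + optional EEG).

    Each subject's insight status is Bernoulli(insight_rates[group]) — or,
    in ``quota`` mode, exactly round(rate*n) insight agents per group so a
    target contingency table is reproduced without sampling noise. The
    subject's aperiodic exponent gets an idiosyncratic offset
    N(0, slope_subject_sd) plus a mean-preserving insight contrast:
    insight agents are steeper by ``slope_insight_effect`` relative to
    their group's non-insight agents, centred so the group-mean exponent
    stays at the stage defaults. This couples the spectral slope to
    insight over and above the stage structure without distorting the
    group-level slope means.
    """
    n_per_group = dict(DEFAULT_GROUP_SIZES if n_per_group is None else n_per_group)
    insight_rates = dict(
        DEFAULT_INSIGHT_RATES if insight_rates is None else insight_rates
    )
    for g, r in insight_rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"insight rate for {g} outside [0,1]")
    if any(n < 0 for n in n_per_group.values()):
        raise ValueError("group sizes must be non-negative")
    base = EEGSimParams() if eeg_params is None else eeg_params
    schedule = generate_task_schedule(seed)
    subjects: list[Subject] = []
    for group in ("N2", "N1", "Wake"):
        n = n_per_group.get(group, 0)
        n_insight_quota = int(round(insight_rates.get(group, 0.0) * n))
        for i in range(n):
            ss = _subject_seed_seq(seed, group, i)
            streams = ss.spawn(4)
            rng = np.random.default_rng(streams[0])
            if quota:
                is_insight = i < n_insight_quota
            else:
                is_insight = bool(rng.random() < insight_rates.get(group, 0.0))
            agent = draw_agent(rng, is_insight, **(agent_kwargs or {}))
            session = simulate_agent_responses(
                schedule,
                agent,
                seed=int(streams[1].generate_state(1)[0] % (2**31)),
                subject_id=f"{group}-{i:02d}",
            )
            hyp = simulate_hypnogram(
                group, seed=int(streams[2].generate_state(1)[0] % (2**31))
            )
            rec = None
            subj_offset = float(rng.normal(0.0, slope_subject_sd))
            rate = insight_rates.get(group, 0.0)
            dx = subj_offset + slope_insight_effect * (
                (1.0 - rate) if is_insight else -rate
            )
            if with_eeg:
                p = EEGSimParams(
                    sampling_rate=base.sampling_rate,
                    channels=dict(base.channels),
                    stage_aperiodic={
                        s: (b, max(0.05, x + dx))
                        for s, (b, x) in base.stage_aperiodic.items()
                    },
                    stage_peaks={s: list(v) for s, v in base.stage_peaks.items()},
                    edge_taper_s=base.edge_taper_s,
                )
                rec = simulate_eeg(
                    hyp, p, seed=int(streams[3].generate_state(1)[0] % (2**31))
                )
            subjects.append(
                Subject(
                    subject_id=f"{group}-{i:02d}",
                    group=group,
                    session=session,
                    hypnogram=hyp,
                    recording=rec,
                    truth={
                        "is_insight": is_insight,
                        "t_s_true": agent.t_s_true,
                        "m_true": agent.m_true,
                        "exponent_offset": dx,
                    },
                )
            )
    return subjects
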