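"""Synthetic session designs and multimodal data with planted effects.

Everything downstream of this module is testable without any external
data: the generators emit trial tables, accuracy-coded behavior from the
diffusion model, oscillatory + aperiodic EEG-like epochs, pupil traces
with blink artifacts, and BOLD-like voxel patterns carrying a planted
brain-behavior latent variable.

All randomness flows from a single session seed through fixed-key child
streams (see :mod:`uapipe._rng`), so every generator is a pure function
of (config, seed).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .ddm import BehavioralTrial, DDMParams, simulate_ddm_trials
from .errors import ConfigurationError, ConstraintError

__all__ = [
    "FEATURES",
    "DEFAULT_CHANNELS",
    "DEFAULT_NEIGHBORS",
    "FRONTOCENTRAL",
    "CENTROPARIETAL",
    "POSTERIOR",
    "MOTOR_LEFT",
    "MOTOR_RIGHT",
    "TRIAL_TIMINGS",
    "StimulusEvidence",
    "TrialSpec",
    "TaskDesign",
    "StimulusConfig",
    "GroupEffects",
    "EffectConfig",
    "EpochedSignal",
    "PupilTrace",
    "BoldData",
    "generate_session_design",
    "generate_stimulus_evidence",
    "simulate_behavior",
    "simulate_eeg",
    "simulate_pupil",
    "simulate_bold",
]

FEATURES = ("color", "direction", "size", "saturation")

#: Fixed phase timings in seconds (cue, fixation, stimulus, probe, ITI).
TRIAL_TIMINGS = {"cue": 1.0, "fixation": 2.0, "stimulus": 3.0, "probe": 2.0, "iti": 1.5}

DEFAULT_CHANNELS = ("Fz", "Cz", "Pz", "POz", "Oz", "C3", "C4", "CP3", "CP4", "P3", "P4", "O1")
DEFAULT_NEIGHBORS = {
    "Fz": ["Cz"],
    "Cz": ["Fz", "Pz", "C3", "C4", "CP3", "CP4"],
    "Pz": ["Cz", "POz", "P3", "P4", "CP3", "CP4"],
    "POz": ["Pz", "Oz", "P3", "P4", "O1"],
    "Oz": ["POz", "O1"],
    "C3": ["Cz", "CP3"],
    "C4": ["Cz", "CP4"],
    "CP3": ["C3", "Cz", "Pz", "P3"],
    "CP4": ["C4", "Cz", "Pz", "P4"],
    "P3": ["CP3", "Pz", "POz"],
    "P4": ["CP4", "Pz", "POz"],
    "O1": ["POz", "Oz"],
}

FRONTOCENTRAL = ("Fz", "Cz")
CENTROPARIETAL = ("Cz", "Pz", "CP3", "CP4")
POSTERIOR = ("Pz", "POz", "Oz", "P3", "P4", "O1")
MOTOR_LEFT = ("C3", "CP3")
MOTOR_RIGHT = ("C4", "CP4")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSpec:
    """One trial of the session design (indices are 1-based)."""

    run: int
    block: int
    trial: int
    cue_set: tuple[str, ...]
    probe_feature: str
    dominant_option: dict[str, int]  # feature -> 0 (option A) or 1 (option B)

    @property
    def load(self) -> int:
        return len(self.cue_set)

    def __post_init__(self) -> None:
        if self.probe_feature not in self.cue_set:
            raise ConstraintError("probe feature must belong to the cue set")
        if not 1 <= self.load <= 4:
            raise ConstraintError("cue-set size must lie in 1..4")


@dataclass
class TaskDesign:
    trials: list[TrialSpec]
    n_runs: int
    blocks_per_run: int
    trials_per_block: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            row = {
                "run": t.run, "block": t.block, "trial": t.trial,
                "load": t.load,
                "cue_set": "+".join(t.cue_set),
                "probe_feature": t.probe_feature,
            }
            for f in FEATURES:
                row[f"dominant_{f}"] = t.dominant_option[f]
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_runs: int, blocks_per_run: int,
                   trials_per_block: int) -> "TaskDesign":
        trials = [
            TrialSpec(
                run=int(r.run), block=int(r.block), trial=int(r.trial),
                cue_set=tuple(r.cue_set.split("+")),
                probe_feature=str(r.probe_feature),
                dominant_option={f: int(getattr(r, f"dominant_{f}")) for f in FEATURES},
            )
            for r in frame.itertuples()
        ]
        return cls(trials, n_runs, blocks_per_run, trials_per_block)


@dataclass
class StimulusConfig:
    """Per-feature evidence ratios and abstract rendering parameters."""

    evidence_ratio: dict[str, float] = field(default_factory=lambda: {
        "color": 0.60, "direction": 0.80, "size": 0.65, "saturation": 0.60,
    })
    motion_coherence: float = 0.2
    n_elements: int = 64
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        for feat, ratio in self.evidence_ratio.items():
            # 0.5 (no net evidence) is allowed as a degenerate null setting
            if not 0.5 <= ratio <= 1.0:
                raise ConfigurationError(
                    f"dominant fraction for {feat!r} must lie in [0.5, 1], got {ratio}")
        if not 0.0 <= self.motion_coherence <= 1.0:
            raise ConfigurationError("motion coherence must lie in [0, 1]")
        if self.n_elements < 1 or self.frame_rate <= 0:
            raise ConfigurationError("n_elements >= 1 and frame_rate > 0 required")


@dataclass
class GroupEffects:
    """Per-group intercepts and linear load slopes of every planted effect.

    Load enters as (load - 1), so intercepts are the load-1 values.
    """

    # diffusion-model parameters
    drift: float = 2.2
    drift_slope: float = -0.45
    boundary: float = 1.3
    boundary_slope: float = 0.05
    ndt: float = 0.35
    ndt_slope: float = 0.01
    # EEG plants
    theta_amp: float = 1.0
    theta_amp_slope: float = 0.5
    alpha_amp: float = 3.0
    alpha_amp_slope: float = -0.6
    exponent: float = 1.6
    exponent_slope: float = -0.25
    entropy_noise: float = 0.3
    entropy_noise_slope: float = 0.08
    cpp_slope: float = 18.0
    cpp_slope_slope: float = -3.0
    mubeta_amp: float = 1.5
    # pupil
    pupil_gain: float = 0.10
    pupil_gain_slope: float = 0.05
    # BOLD latent-variable loading
    bold_loading: float = 1.0
    bold_loading_slope: float = 0.5

    def at_load(self, name: str, load: int) -> float:
        return getattr(self, name) + getattr(self, name + "_slope") * (load - 1)


def _default_groups() -> dict[str, GroupEffects]:
    young = GroupEffects()
    # older group: lower intercept drift and dampened load slopes throughout
    old = GroupEffects(
        drift=1.6, drift_slope=-0.10,
        boundary=1.3, boundary_slope=0.05,
        ndt=0.40, ndt_slope=0.01,
        theta_amp=1.0, theta_amp_slope=0.15,
        alpha_amp=2.5, alpha_amp_slope=-0.15,
        exponent=1.4, exponent_slope=-0.03,
        entropy_noise=0.3, entropy_noise_slope=0.02,
        cpp_slope=12.0, cpp_slope_slope=-0.8,
        pupil_gain=0.10, pupil_gain_slope=0.015,
        bold_loading=1.0, bold_loading_slope=0.15,
    )
    return {"young": young, "old": old}


@dataclass
class EffectConfig:
    """Planted effect sizes, oscillation frequencies and noise levels."""

    groups: dict[str, GroupEffects] = field(default_factory=_default_groups)
    theta_freq: float = 5.0
    alpha_freq: float = 10.0
    ssvep_freq: float = 30.0
    ssvep_amp: float = 1.0
    eeg_noise_sd: float = 1.0
    pupil_noise_sd: float = 0.05
    bold_noise_sd: float = 1.0
    blink_rate: float = 0.15  # blinks per second
    bold_feature_snr: float = 1.5
    bold_feature_snr_slope: float = -0.3  # probed/cued SNR change per load step
    bold_uncued_snr: float = 0.1

    def __post_init__(self) -> None:
        for name in ("eeg_noise_sd", "pupil_noise_sd", "bold_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.blink_rate < 0:
            raise ConfigurationError("blink_rate must be >= 0")

    def group(self, name: str) -> GroupEffects:
        try:
            return self.groups[name]
        except KeyError:
            raise ConfigurationError(f"no effect parameters for group {name!r}") from None


@dataclass
class EpochedSignal:
    """channel x time x trial array with a uniform event-relative time axis."""

    data: np.ndarray
    srate: float
    times: np.ndarray
    alignment: str
    channels: list[str]
    neighbors: dict[str, list[str]] | None = None
    trial_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ConfigurationError("data must be channel x time x trial")
        if self.data.shape[0] != len(self.channels):
            raise ConfigurationError("channel axis does not match channel labels")
        if self.data.shape[1] != self.times.size:
            raise ConfigurationError("time axis does not match data")
        dt = np.diff(self.times)
        if dt.size and (dt.min() <= 0 or not np.allclose(dt, 1.0 / self.srate, atol=1e-6)):
            raise ConfigurationError("time axis must increase uniformly at 1/srate")
        if self.neighbors is not None:
            missing = set(self.neighbors) - set(self.channels)
            if missing:
                raise ConfigurationError(f"neighbor map names unknown channels: {sorted(missing)}")

    def pick(self, channels: list[str] | tuple[str, ...]) -> np.ndarray:
        idx = [self.channels.index(c) for c in channels]
        return self.data[idx]


@dataclass
class PupilTrace:
    """One trial's pupil trace with blink annotations (seconds, trace-relative)."""

    samples: np.ndarray
    srate: float
    t0: float  # time of the first sample relative to stimulus onset
    blinks: list[tuple[float, float]] = field(default_factory=list)
    gaze_y: np.ndarray | None = None
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        dur = self.samples.size / self.srate
        for start, end in self.blinks:
            if not (0 <= start < end <= dur + 1e-9):
                raise ConfigurationError("blink annotation outside trace bounds")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.srate


@dataclass
class BoldData:
    """Trial-wise voxel patterns plus a condition-mean beta matrix."""

    patterns: np.ndarray          # trial x voxel x time (volumes)
    betas: np.ndarray             # voxel x load-condition
    loads: np.ndarray             # per-trial load
    trial_info: pd.DataFrame
    feature_voxels: dict[str, np.ndarray]
    latent_pattern: np.ndarray
    tr: float = 0.645


# ---------------------------------------------------------------------------
# session design
# ---------------------------------------------------------------------------

def _block_size_sequence(rng: np.random.Generator, n_runs: int,
                         blocks_per_run: int) -> list[int]:
    """Per-run balanced set sizes with no adjacent repeats across the session."""
    if blocks_per_run % 4 != 0:
        raise ConstraintError(
            "set-size balance: blocks_per_run must be a multiple of 4 so every "
            "cue-set size occurs equally often per run")
    reps = blocks_per_run // 4
    seq: list[int] = []
    for _ in range(n_runs):
        prev = seq[-1] if seq else None
        for _attempt in range(10_000):
            run = rng.permutation(np.repeat(np.arange(1, 5), reps)).tolist()
            if prev is not None and run[0] == prev:
                continue
            if all(x != y for x, y in zip(run, run[1:])):
                seq.extend(run)
                break
        else:  # pragma: no cover - unreachable for feasible counts
            raise ConstraintError("set-size sequencing: could not avoid adjacent repeats")
    return seq


def generate_session_design(
    config: StimulusConfig | None = None,
    n_runs: int = 4,
    blocks_per_run: int = 8,
    trials_per_block: int = 8,
    seed: int = 0,
) -> TaskDesign:
    """Generate a balanced session design.

    Guarantees: cue set constant within a block; no two consecutive blocks
    share a cue-set size; every cued feature is probed at least once per
    block; the 16 dominant-option combinations occur equally often over
    the session.
    """
    if min(n_runs, blocks_per_run, trials_per_block) < 1:
        raise ConstraintError("all design counts must be >= 1")
    if trials_per_block < 4:
        raise ConstraintError(
            "probe coverage: trials_per_block must be >= the maximum cue-set "
            "size (4) so every cued feature can be probed once per block")
    total = n_runs * blocks_per_run * trials_per_block
    if total % 16 != 0:
        raise ConstraintError(
            "dominant-option balance: total trial count must be divisible by "
            "the 16 dominant-option combinations")
    config = config or StimulusConfig()
    rng = child_rng(seed, "design")

    sizes = _block_size_sequence(rng, n_runs, blocks_per_run)

    combos = list(itertools.product((0, 1), repeat=4))
    combo_pool = np.repeat(np.arange(16), total // 16)
    rng.shuffle(combo_pool)

    trials: list[TrialSpec] = []
    idx = 0
    for b, size in enumerate(sizes):
        run = b // blocks_per_run + 1
        block = b % blocks_per_run + 1
        cue = tuple(FEATURES[i] for i in sorted(rng.choice(4, size=size, replace=False)))
        # probes: each cued feature once, remaining slots round-robin, shuffled
        probes = list(cue)
        fill = itertools.cycle(cue)
        while len(probes) < trials_per_block:
            probes.append(next(fill))
        probes = [probes[i] for i in rng.permutation(len(probes))]
        for t, probe in enumerate(probes):
            combo = combos[combo_pool[idx]]
            idx += 1
            trials.append(TrialSpec(
                run=run, block=block, trial=t + 1, cue_set=cue,
                probe_feature=probe,
                dominant_option=dict(zip(FEATURES, combo)),
            ))
    return TaskDesign(trials, n_runs, blocks_per_run, trials_per_block)


# ---------------------------------------------------------------------------
# stimulus evidence
# ---------------------------------------------------------------------------

@dataclass
class StimulusEvidence:
    """Per-frame element option assignments (1 = dominant option)."""

    options: dict[str, np.ndarray]   # feature -> frames x elements, values {0, 1}
    coherent: np.ndarray             # frames x elements boolean (direction feature)
    frame_rate: float


def generate_stimulus_evidence(
    trial: TrialSpec,
    config: StimulusConfig | None = None,
    seed: int = 0,
    duration: float = TRIAL_TIMINGS["stimulus"],
) -> StimulusEvidence:
    """Draw the abstract per-element attribute table of one stimulus.

    Every element carries the dominant option of each feature with the
    configured evidence probability; additionally a ``motion_coherence``
    fraction of elements is flagged as moving coherently (in the dominant
    direction), the rest moving randomly.
    """
    config = config or StimulusConfig()
    rng = child_rng(seed, "stimulus", trial.run, trial.block, trial.trial)
    n_frames = int(round(duration * config.frame_rate))
    shape = (n_frames, config.n_elements)
    options = {}
    for feat in FEATURES:
        ratio = config.evidence_ratio[feat]
        options[feat] = (rng.random(shape) < ratio).astype(np.int8)
    coherent = rng.random(shape) < config.motion_coherence
    return StimulusEvidence(options=options, coherent=coherent,
                            frame_rate=config.frame_rate)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    design: TaskDesign,
    effects: EffectConfig,
    seed: int = 0,
    group: str = "young",
    subject: str = "sub-01",
    p_outlier: float = 0.05,
    dt: float = 1e-3,
) -> list[BehavioralTrial]:
    """Simulate one subject's choices/RTs, one per design trial.

    Diffusion parameters are resolved per (group, load) from the effect
    configuration and passed to :func:`uapipe.ddm.simulate_ddm_trials`.
    """
    ge = effects.group(group)
    rng = child_rng(seed, "behavior")
    by_load: dict[int, list[int]] = {}
    for i, t in enumerate(design.trials):
        by_load.setdefault(t.load, []).append(i)

    out: list[BehavioralTrial | None] = [None] * len(design.trials)
    for load in sorted(by_load):
        params = DDMParams(
            v=ge.at_load("drift", load),
            a=max(ge.at_load("boundary", load), 0.2),
            t0=max(ge.at_load("ndt", load), 0.01),
            p_outlier=p_outlier,
            condition=load,
        )
        idx = by_load[load]
        sim = simulate_ddm_trials(params, len(idx), seed=rng, dt=dt,
                                  subject=subject, group=group)
        for i, tr in zip(idx, sim):
            tr.feature = design.trials[i].probe_feature
            out[i] = tr
    return [t for t in out if t is not None]


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _aperiodic_noise(rng: np.random.Generator, n: int, srate: float,
                     exponent: float, scale: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to f**(-exponent)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    # knee at 1 Hz: keeps the SD normalization independent of epoch length
    shaping = np.maximum(freqs, 1.0) ** (-exponent / 2.0)
    shaping[0] = 0.0
    sig = np.fft.irfft(spec * shaping, n=n)
    sd = sig.std()
    return sig * (scale / sd) if sd > 0 else sig


def simulate_eeg(
    design: TaskDesign,
    effects: EffectConfig,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    srate: float = 250.0,
    seed: int = 0,
    group: str = "young",
    trials: list[BehavioralTrial] | None = None,
    neighbors: dict[str, list[str]] | None = None,
) -> dict[str, EpochedSignal]:
    """Simulate stimulus-locked and response-locked EEG-like epochs.

    Epochs contain an aperiodic background with a load-dependent log-log
    slope, theta/alpha bursts whose amplitude scales with load, a 30 Hz
    entrained component during the stimulus, load-scaled broadband noise
    on posterior channels (irregularity plant), a response-locked ramp on
    centro-parietal channels, and lateralized motor-band power.
    """
    if srate < 250:
        raise ConfigurationError("srate must be >= 250 Hz")
    if len(channels) < 4:
        raise ConfigurationError("at least 4 channels required")
    neighbors = DEFAULT_NEIGHBORS if neighbors is None else neighbors
    missing = set(channels) - set(neighbors)
    if missing:
        raise ConfigurationError(f"channels missing from neighbor map: {sorted(missing)}")
    neighbors = {c: [n for n in neighbors[c] if n in channels] for c in channels}

    ge = effects.group(group)
    rng = child_rng(seed, "eeg")
    if trials is None:
        trials = simulate_behavior(design, effects, seed=seed, group=group)

    n_tr = len(design.trials)
    stim_times = np.arange(round(-1.0 * srate), round(4.25 * srate)) / srate
    resp_times = np.arange(round(-1.0 * srate), round(0.5 * srate)) / srate
    n_stim, n_resp = stim_times.size, resp_times.size

    ch_idx = {c: i for i, c in enumerate(channels)}
    fronto = [ch_idx[c] for c in FRONTOCENTRAL if c in ch_idx]
    postr = [ch_idx[c] for c in POSTERIOR if c in ch_idx]
    centro = [ch_idx[c] for c in CENTROPARIETAL if c in ch_idx]
    left = [ch_idx[c] for c in MOTOR_LEFT if c in ch_idx]
    right = [ch_idx[c] for c in MOTOR_RIGHT if c in ch_idx]

    stim = np.zeros((len(channels), n_stim, n_tr))
    resp = np.zeros((len(channels), n_resp, n_tr))
    stim_win = (stim_times >= 0) & (stim_times < TRIAL_TIMINGS["stimulus"])
    burst_env = np.zeros(n_stim)
    burst_env[stim_win] = np.hanning(stim_win.sum())

    sides = rng.integers(0, 2, n_tr)  # 0 = left hand, 1 = right hand
    loads = np.array([t.load for t in design.trials])
    rts = np.array([t.rt for t in trials])

    for i, spec in enumerate(design.trials):
        load = spec.load
        exponent = max(ge.at_load("exponent", load), 0.1)
        theta_a = max(ge.at_load("theta_amp", load), 0.0)
        alpha_a = max(ge.at_load("alpha_amp", load), 0.0)
        noise_a = max(ge.at_load("entropy_noise", load), 0.0)

        for c in range(len(channels)):
            stim[c, :, i] = _aperiodic_noise(rng, n_stim, srate, exponent,
                                             scale=effects.eeg_noise_sd)
            resp[c, :, i] = _aperiodic_noise(rng, n_resp, srate, exponent,
                                             scale=0.5 * effects.eeg_noise_sd)

        ph_t, ph_a, ph_s = rng.uniform(0, 2 * np.pi, 3)
        theta = theta_a * burst_env * np.sin(2 * np.pi * effects.theta_freq * stim_times + ph_t)
        alpha = alpha_a * burst_env * np.sin(2 * np.pi * effects.alpha_freq * stim_times + ph_a)
        ssvep = effects.ssvep_amp * stim_win * np.sin(2 * np.pi * effects.ssvep_freq * stim_times + ph_s)
        stim[fronto, :, i] += theta
        stim[postr, :, i] += alpha + ssvep
        if noise_a > 0:
            for c in postr:
                stim[c, :, i] += noise_a * rng.standard_normal(n_stim)

        # response-locked ramp: slope k over the final 400 ms, then decay
        k = ge.at_load("cpp_slope", load)
        ramp = np.zeros(n_resp)
        pre = (resp_times >= -0.4) & (resp_times <= 0)
        ramp[pre] = k * (resp_times[pre] + 0.4)
        post = resp_times > 0
        peak = k * 0.4
        ramp[post] = peak * np.clip(1 - resp_times[post] / 0.3, 0, 1)
        resp[centro, :, i] += ramp

        # lateralized motor-band power: contralateral desynchronizes pre-response
        contra, ipsi = (right, left) if sides[i] == 0 else (left, right)
        mu_wave = np.sin(2 * np.pi * 20.0 * resp_times + rng.uniform(0, 2 * np.pi))
        depth = np.clip((resp_times + 0.5) / 0.5, 0, 1)  # 1 at response
        resp[ipsi, :, i] += ge.mubeta_amp * mu_wave
        resp[contra, :, i] += ge.mubeta_amp * (1 - 0.8 * depth) * mu_wave

    info = pd.DataFrame({
        "load": loads, "response_side": np.where(sides == 0, "left", "right"),
        "rt": rts, "group": group,
    })
    common = dict(srate=srate, channels=list(channels), neighbors=neighbors,
                  trial_info=info)
    return {
        "stimulus": EpochedSignal(stim, times=stim_times, alignment="stimulus", **common),
        "response": EpochedSignal(resp, times=resp_times, alignment="response", **common),
    }


# ---------------------------------------------------------------------------
# pupil
# ---------------------------------------------------------------------------

def simulate_pupil(
    design: TaskDesign,
    effects: EffectConfig,
    srate: float = 500.0,
    seed: int = 0,
    group: str = "young",
) -> list[PupilTrace]:
    """Simulate per-trial pupil traces (epoch -3.5 s ... stimulus offset + 1 s).

    Traces combine a stimulus-locked constriction, a dilation component
    whose *rate* scales with load, slow drift noise, and randomly placed
    blink artifacts recorded in the annotations.
    """
    if srate < 100:
        raise ConfigurationError("srate must be >= 100 Hz")
    ge = effects.group(group)
    rng = child_rng(seed, "pupil")
    t0 = -3.5
    t_end = TRIAL_TIMINGS["stimulus"] + 1.0
    n = int(round((t_end - t0) * srate))
    times = t0 + np.arange(n) / srate
    stim_on = (times >= 0) & (times <= TRIAL_TIMINGS["stimulus"])

    traces = []
    for spec in design.trials:
        gain = max(ge.at_load("pupil_gain", spec.load), 0.0)
        base = 5.0
        # luminance-driven constriction at stimulus onset
        constr = -0.4 * np.clip(times / 0.5, 0, 1) * (times >= 0)
        dil = np.zeros(n)
        dil[stim_on] = gain * times[stim_on]
        plateau = gain * TRIAL_TIMINGS["stimulus"]
        after = times > TRIAL_TIMINGS["stimulus"]
        dil[after] = plateau * np.clip(1 - (times[after] - 3.0) / 2.0, 0, 1)
        drift = np.cumsum(rng.standard_normal(n)) / srate
        drift *= effects.pupil_noise_sd / max(drift.std(), 1e-12)
        noise = effects.pupil_noise_sd * 0.2 * rng.standard_normal(n)
        samples = base + constr + dil + drift + noise

        # smooth drifting gaze: artifact screening should only fire on blinks
        kernel = np.hanning(int(0.4 * srate))
        kernel /= kernel.sum()
        gaze = np.convolve(np.cumsum(rng.standard_normal(n)) / np.sqrt(srate),
                           kernel, mode="same")
        blinks: list[tuple[float, float]] = []
        if effects.blink_rate > 0:
            n_blinks = rng.poisson(effects.blink_rate * (t_end - t0))
            for _ in range(n_blinks):
                start = rng.uniform(0, t_end - t0 - 0.15)
                end = start + rng.uniform(0.08, 0.15)
                lo, hi = int(start * srate), int(end * srate)
                samples[lo:hi] = 0.0
                gaze[lo:hi] += 50.0
                blinks.append((start, end))
        traces.append(PupilTrace(samples=samples, srate=srate, t0=t0,
                                 blinks=sorted(blinks), gaze_y=gaze))
    return traces


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def simulate_bold(
    design: TaskDesign,
    effects: EffectConfig,
    n_voxels: int = 200,
    seed: int = 0,
    group: str = "young",
    subject_loading: float = 1.0,
    n_volumes: int = 16,
    active_volumes: tuple[int, int] = (6, 12),
) -> BoldData:
    """Simulate trial-wise voxel patterns and condition-wise betas.

    Dedicated voxel subsets carry the dominant option of cued features at
    a load-dependent SNR; the condition beta matrix is a planted rank-1
    pattern scaled by the group's load loading plus noise.
    """
    if n_voxels < 50:
        raise ConfigurationError("n_voxels must be >= 50")
    ge = effects.group(group)
    rng = child_rng(seed, "bold")
    n_tr = len(design.trials)

    per_feat = max(n_voxels // 10, 5)
    feature_voxels = {
        f: np.arange(i * per_feat, (i + 1) * per_feat)
        for i, f in enumerate(FEATURES)
    }
    patterns = effects.bold_noise_sd * rng.standard_normal((n_tr, n_voxels, n_volumes))
    lo, hi = active_volumes
    feat_patterns = {f: rng.standard_normal(per_feat) for f in FEATURES}
    for i, spec in enumerate(design.trials):
        for f in FEATURES:
            if f not in spec.cue_set:
                snr = effects.bold_uncued_snr
            else:
                snr = max(effects.bold_feature_snr
                          + effects.bold_feature_snr_slope * (spec.load - 1), 0.0)
            if snr <= 0:
                continue
            sign = 1.0 if spec.dominant_option[f] == 1 else -1.0
            vox = feature_voxels[f]
            patterns[i, vox, lo:hi] += sign * snr * feat_patterns[f][:, None]

    latent = rng.standard_normal(n_voxels)
    latent /= np.linalg.norm(latent)
    loads = np.arange(1, 5)
    loadings = np.array([ge.at_load("bold_loading", l) for l in loads])
    betas = (np.outer(latent, loadings) * subject_loading
             + 0.1 * effects.bold_noise_sd * rng.standard_normal((n_voxels, 4)))

    info = pd.DataFrame({
        "load": [t.load for t in design.trials],
        "probe_feature": [t.probe_feature for t in design.trials],
        "cue_set": ["+".join(t.cue_set) for t in design.trials],
        **{f"dominant_{f}": [t.dominant_option[f] for t in design.trials] for f in FEATURES},
    })
    return BoldData(patterns=patterns, betas=betas,
                    loads=np.array([t.load for t in design.trials]),
                    trial_info=info, feature_voxels=feature_voxels,
                    latent_pattern=latent)
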