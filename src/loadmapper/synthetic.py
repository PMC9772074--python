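"""Synthetic n-back / threat-of-shock fMRI sessions.

Emulates a two-run block design: each run holds 8 blocks (2 per crossing of
load {1-back, 3-back} x anxiety {safe, threat}), each block being 8 s of
instruction followed by 18 letters at 2 s intervals, with exactly 6 of the 18
trials being matches and 3 unpredictable shocks per run confined to threat
blocks.  Runs are 225 volumes at TR = 2 s; frames not covered by a block are
inter-block fixation.

BOLD is generated per parcel as baseline + network-level load and anxiety
boxcar effects (optionally convolved with a canonical double-gamma HRF) +
low-frequency drift + white noise, with 6-parameter motion traces (random
walk plus occasional spikes) emitted alongside.  A "segregated dynamics"
variant adds a parcel-heterogeneous load response so that 1-back and 3-back
frame vectors occupy distinct regions of activation space — the generative
ground truth for shape-graph segregation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import NETWORKS, ParcelTimeSeries

LOAD_LEVELS = ("1-back", "3-back")
ANXIETY_LEVELS = ("safe", "threat")
#: the four load x anxiety block conditions in canonical order
CONDITIONS = tuple((l, a) for l in LOAD_LEVELS for a in ANXIETY_LEVELS)

# consonants, as is usual for verbal n-back letter streams
_LETTERS = tuple("BCDFGHJKLMNPQRSTVWXZ")


class DesignSizingError(ValueError):
    """Raised when the requested blocks do not fit in the run duration."""


@dataclass
class TaskDesign:
    """Frame-level and trial-level description of a simulated session."""

    n_runs: int
    volumes_per_run: int
    tr_seconds: float
    frame_labels: pd.DataFrame  # frame, run, block, load, anxiety, phase
    trials: pd.DataFrame  # run, block, position, letter, is_match
    shock_events: list[tuple[int, int]]  # (run, frame) pairs

    @property
    def n_frames(self) -> int:
        return self.n_runs * self.volumes_per_run

    @property
    def run_boundaries(self) -> list[int]:
        return [r * self.volumes_per_run for r in range(self.n_runs + 1)]


@dataclass
class EffectSpec:
    """Generative ground truth for one subject's BOLD.

    ``a_true`` / ``b_true`` are per-network load (3-back minus 1-back) and
    anxiety (threat minus safe) amplitudes in signal units; ``noise_sd`` is
    the white-noise standard deviation in the same units.  ``hrf`` is
    ``"double-gamma"`` or ``"none"`` (pure boxcars — the mode in which the
    condition-mean estimator inverts the forward model exactly).
    ``state_separation`` scales a zero-mean per-parcel load-response pattern
    that makes 1-back and 3-back activation states geometrically distinct.
    """

    a_true: np.ndarray = field(default_factory=lambda: np.array([0.3, 0.3, 0.3, 0.3, 0.3, 0.8, -0.6]))
    b_true: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 0.3, 0.3, 0.0, 0.2]))
    baseline: float = 100.0
    noise_sd: float = 1.0
    drift_amplitude: float = 2.0
    spike_rate: float = 0.02
    spike_magnitude_mm: float = 0.5
    hrf: str = "double-gamma"
    state_separation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.a_true = np.broadcast_to(np.asarray(self.a_true, dtype=float), (len(NETWORKS),)).copy()
        self.b_true = np.broadcast_to(np.asarray(self.b_true, dtype=float), (len(NETWORKS),)).copy()
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.spike_rate <= 1:
            raise ValueError("spike_rate must lie in [0, 1]")
        if self.hrf not in ("double-gamma", "none"):
            raise ValueError(f"unknown hrf model {self.hrf!r}")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "MPH" or "PLA"
    age: int
    sex: str  # "F" or "M"
    accuracy: dict  # (load, anxiety) -> proportion correct


@dataclass
class Subject:
    """One simulated participant: covariates, design, data and motion."""

    record: SubjectRecord
    design: TaskDesign
    effects: EffectSpec
    timeseries: ParcelTimeSeries
    motion: list[np.ndarray]


def make_parcel_map(n_parcels: int = 400) -> dict[str, str]:
    """Assign ``n_parcels`` parcel ids to the 7 networks in contiguous blocks."""
    if n_parcels < len(NETWORKS):
        raise ValueError("need at least one parcel per network")
    ids = [f"parcel_{i:04d}" for i in range(n_parcels)]
    chunks = np.array_split(np.arange(n_parcels), len(NETWORKS))
    mapping: dict[str, str] = {}
    for net, chunk in zip(NETWORKS, chunks):
        for i in chunk:
            mapping[ids[i]] = net
    return mapping


def double_gamma_hrf(tr_seconds: float, duration: float = 32.0,
                     peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR, normalised to unit sum.

    Unit sum makes the plateau of a convolved long boxcar equal the boxcar
    amplitude, so block effects keep their nominal scale.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration, tr_seconds)
    h = gamma_dist.pdf(t, peak) - gamma_dist.pdf(t, undershoot) / ratio
    return h / h.sum()


def generate_task_design(
    seed: int = 0,
    n_runs: int = 2,
    blocks_per_run: int = 8,
    letters_per_block: int = 18,
    match_fraction: float = 1 / 3,
    tr_seconds: float = 2.0,
    volumes_per_run: int = 225,
    instruction_seconds: float = 8.0,
    letter_interval_seconds: float = 2.0,
    shocks_per_run: int = 3,
) -> TaskDesign:
    """Pseudo-randomised block design with matched constraints.

    Per run: ``blocks_per_run`` blocks in a seeded random order containing
    exactly ``blocks_per_run / 4`` of each load x anxiety condition; each
    block is an instruction phase followed by the letter stream; leftover
    frames are distributed evenly as inter-block fixation.  Match trials
    (``round(match_fraction * letters_per_block)`` per block) are placed
    uniformly among N-back-eligible positions (position > N), and shocks fall
    only inside threat-block letter frames.
    """
    rng = np.random.default_rng(seed)
    if blocks_per_run % len(CONDITIONS) != 0:
        raise ValueError("blocks_per_run must be a multiple of 4 (one per condition)")
    n_match = int(round(match_fraction * letters_per_block))
    instr_frames = int(round(instruction_seconds / tr_seconds))
    letter_frames = int(round(letters_per_block * letter_interval_seconds / tr_seconds))
    block_frames = instr_frames + letter_frames
    used = blocks_per_run * block_frames
    if used > volumes_per_run:
        raise DesignSizingError(
            f"{blocks_per_run} blocks x {block_frames} frames = {used} frames "
            f"exceed the run length of {volumes_per_run} volumes"
        )
    # inter-block fixation: leftover frames spread over the gaps before,
    # between and after blocks (blocks_per_run + 1 gaps)
    n_gaps = blocks_per_run + 1
    cuts = np.round(np.linspace(0, volumes_per_run - used, n_gaps + 1)).astype(int)
    gap_sizes = np.diff(cuts)

    frames = []
    trial_rows = []
    shocks: list[tuple[int, int]] = []
    for run in range(n_runs):
        order = list(CONDITIONS) * (blocks_per_run // len(CONDITIONS))
        order = [order[i] for i in rng.permutation(len(order))]
        frame = 0
        threat_letter_frames: list[int] = []
        for block, (gap, block_cond) in enumerate(zip(gap_sizes[:-1], order)):
            for _ in range(gap):
                frames.append((frame, run, -1, "none", "none", "fixation"))
                frame += 1
            load, anxiety = block_cond
            for _ in range(instr_frames):
                frames.append((frame, run, block, load, anxiety, "instruction"))
                frame += 1
            for _ in range(letter_frames):
                if anxiety == "threat":
                    threat_letter_frames.append(frame)
                frames.append((frame, run, block, load, anxiety, "letters"))
                frame += 1
            trial_rows.extend(
                _make_trials(rng, run, block, load, letters_per_block, n_match)
            )
        for _ in range(gap_sizes[-1]):
            frames.append((frame, run, -1, "none", "none", "fixation"))
            frame += 1
        assert frame == volumes_per_run
        shock_frames = rng.choice(threat_letter_frames, size=shocks_per_run, replace=False)
        shocks.extend((run, int(f)) for f in sorted(shock_frames))

    frame_labels = pd.DataFrame(
        frames, columns=["frame", "run", "block", "load", "anxiety", "phase"]
    )
    trials = pd.DataFrame(
        trial_rows, columns=["run", "block", "position", "letter", "is_match"]
    )
    return TaskDesign(
        n_runs=n_runs,
        volumes_per_run=volumes_per_run,
        tr_seconds=tr_seconds,
        frame_labels=frame_labels,
        trials=trials,
        shock_events=shocks,
    )


def _make_trials(rng: np.random.Generator, run: int, block: int, load: str,
                 letters_per_block: int, n_match: int) -> list[tuple]:
    """Letter stream for one block honouring the N-back match rule."""
    n_back = int(load.split("-")[0])
    eligible = np.arange(n_back + 1, letters_per_block + 1)  # 1-based positions
    if n_match > len(eligible):
        raise ValueError("more match trials requested than eligible positions")
    match_pos = set(rng.choice(eligible, size=n_match, replace=False).tolist())
    letters: list[str] = []
    rows = []
    for pos in range(1, letters_per_block + 1):
        if pos in match_pos:
            letter = letters[pos - 1 - n_back]
        else:
            letter = _LETTERS[rng.integers(len(_LETTERS))]
            # avoid accidental matches on non-match trials
            while pos > n_back and letter == letters[pos - 1 - n_back]:
                letter = _LETTERS[rng.integers(len(_LETTERS))]
        letters.append(letter)
        rows.append((run, block, pos, letter, pos in match_pos))
    return rows


def _condition_boxcars(design: TaskDesign) -> tuple[np.ndarray, np.ndarray]:
    """Load and anxiety boxcars over letter-phase frames (one per frame)."""
    lab = design.frame_labels
    x_load = ((lab["load"] == "3-back") & (lab["phase"] == "letters")).to_numpy(float)
    x_anx = ((lab["anxiety"] == "threat") & (lab["phase"] == "letters")).to_numpy(float)
    return x_load, x_anx


def _convolve_runs(x: np.ndarray, kernel: np.ndarray | None,
                   run_boundaries: Sequence[int]) -> np.ndarray:
    if kernel is None:
        return x
    out = np.empty_like(x)
    rb = list(run_boundaries)
    for start, stop in zip(rb[:-1], rb[1:]):
        out[start:stop] = np.convolve(x[start:stop], kernel)[: stop - start]
    return out


def generate_motion(rng: np.random.Generator, n_frames: int,
                    spike_rate: float, spike_magnitude_mm: float,
                    walk_sd_mm: float = 0.01) -> np.ndarray:
    """Six-parameter motion trace: random walk plus single-frame spikes.

    Translations in mm, rotations in radians (rotation walk scaled so its FD
    contribution matches the translation walk under the 50 mm convention).
    """
    steps = np.column_stack([
        rng.normal(0, walk_sd_mm, (n_frames, 3)),
        rng.normal(0, walk_sd_mm / 50.0, (n_frames, 3)),
    ])
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)
    spikes = rng.random(n_frames) < spike_rate
    spikes[0] = False
    for t in np.nonzero(spikes)[0]:
        axis = rng.integers(3)
        motion[t, axis] += spike_magnitude_mm * rng.choice([-1.0, 1.0])
    return motion


def generate_bold(
    design: TaskDesign,
    effects: EffectSpec,
    parcel_map: Mapping[str, str] | None = None,
) -> tuple[ParcelTimeSeries, list[np.ndarray]]:
    """Forward model: condition boxcars -> parcel BOLD + motion traces.

    Per parcel of network j:
    ``baseline + (a_true[j] + pattern_p) * load(t) + b_true[j] * threat(t)``
    (boxcars over letter frames, optionally HRF-convolved per run), plus a
    slow drift (linear + ~128 s sinusoid, random phase) and white noise.
    ``pattern_p`` is the subject's zero-mean segregation pattern, drawn i.i.d.
    N(0, state_separation^2) across parcels.
    """
    if parcel_map is None:
        parcel_map = make_parcel_map(400)
    rng = np.random.default_rng(effects.seed)
    parcel_ids = list(parcel_map.keys())
    P = len(parcel_ids)
    n = design.n_frames
    rb = design.run_boundaries

    kernel = None
    if effects.hrf == "double-gamma":
        kernel = double_gamma_hrf(design.tr_seconds)
    x_load, x_anx = _condition_boxcars(design)
    x_load = _convolve_runs(x_load, kernel, rb)
    x_anx = _convolve_runs(x_anx, kernel, rb)

    net_index = np.array([NETWORKS.index(parcel_map[p]) for p in parcel_ids])
    a_parcel = effects.a_true[net_index]
    b_parcel = effects.b_true[net_index]
    if effects.state_separation > 0:
        a_parcel = a_parcel + rng.normal(0, effects.state_separation, P)

    data = effects.baseline + np.outer(x_load, a_parcel) + np.outer(x_anx, b_parcel)
    if effects.drift_amplitude > 0:
        t = np.arange(n) * design.tr_seconds
        for start, stop in zip(rb[:-1], rb[1:]):
            tt = t[start:stop] - t[start]
            span = max(tt[-1], 1.0)
            slope = rng.normal(0, effects.drift_amplitude / span, P)
            amp = rng.normal(0, effects.drift_amplitude / 2, P)
            phase = rng.uniform(0, 2 * np.pi, P)
            data[start:stop] += np.outer(tt, slope)
            data[start:stop] += amp * np.sin(
                2 * np.pi * np.outer(tt, np.ones(P)) / 128.0 + phase
            )
    if effects.noise_sd > 0:
        data += rng.normal(0, effects.noise_sd, (n, P))

    motion = [
        generate_motion(rng, stop - start, effects.spike_rate, effects.spike_magnitude_mm)
        for start, stop in zip(rb[:-1], rb[1:])
    ]
    ts = ParcelTimeSeries(
        data=data,
        tr_seconds=design.tr_seconds,
        run_boundaries=rb,
        parcel_ids=parcel_ids,
        parcel_to_network=dict(parcel_map),
    )
    return ts, motion


def generate_cohort(
    n_per_group: int = 25,
    group_effect_delta: float = 0.4,
    base_effects: EffectSpec | None = None,
    seed: int = 0,
    parcel_map: Mapping[str, str] | None = None,
    variant: str = "uniform",
    state_separation: float = 1.0,
    design_kwargs: Mapping | None = None,
) -> list[Subject]:
    """Two-arm cohort (MPH vs PLA), each subject with own design seed.

    MPH subjects receive ``a_true + group_effect_delta``; under the
    ``"segregated"`` variant they additionally get a parcel-heterogeneous
    load-response pattern of scale ``state_separation`` (distinct 1-back /
    3-back activation centroids), while PLA subjects share a single
    network-level response.  Ages are sampled uniformly in 18-50; accuracy is
    a simple load/anxiety/drug-dependent proportion in [0, 1].
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if variant not in ("uniform", "segregated"):
        raise ValueError(f"unknown cohort variant {variant!r}")
    if base_effects is None:
        base_effects = EffectSpec()
    design_kwargs = dict(design_kwargs or {})
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    subjects: list[Subject] = []
    for i, child in enumerate(children):
        group = "MPH" if i < n_per_group else "PLA"
        sub_rng = np.random.default_rng(child)
        sub_seed = int(sub_rng.integers(2**31 - 1))
        a = base_effects.a_true.copy()
        sep = 0.0
        if group == "MPH":
            a = a + group_effect_delta
            if variant == "segregated":
                sep = state_separation
        effects = replace(base_effects, a_true=a, state_separation=sep, seed=sub_seed)
        design = generate_task_design(seed=sub_seed, **design_kwargs)
        ts, motion = generate_bold(design, effects, parcel_map)
        age = int(sub_rng.integers(18, 51))
        sex = str(sub_rng.choice(["F", "M"]))
        accuracy = {}
        for load, anx in CONDITIONS:
            acc = 0.85
            acc -= 0.10 if load == "3-back" else 0.0
            acc -= 0.04 if anx == "threat" else 0.0
            acc += 0.05 if group == "MPH" else 0.0
            accuracy[(load, anx)] = float(np.clip(acc + sub_rng.normal(0, 0.05), 0, 1))
        record = SubjectRecord(
            subject_id=f"sub-{i + 1:03d}", group=group, age=age, sex=sex, accuracy=accuracy
        )
        subjects.append(Subject(record=record, design=design, effects=effects,
                                timeseries=ts, motion=motion))
    return subjects
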