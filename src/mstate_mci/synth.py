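"""Synthetic multi-subject, two-paradigm EEG with known microstate ground truth.

The generator emulates the study conditions the rest of the pipeline is
built for: a two-group cohort (healthy controls and MCI patients), 62-channel
recordings, a continuous eyes-closed resting paradigm and a trial-based
Stroop-like task paradigm, four-class microstate structure with
group-dependent temporal statistics, and a per-subject MoCA score.

The temporal model is an explicit-run-length (semi-Markov) chain: the label
sequence alternates runs of the four states; run lengths are gamma
distributed with state-specific means, and the successor state is drawn from
a zero-diagonal row-stochastic transition matrix.  This makes the mean
duration, coverage, occurrence and transition-probability features of the
downstream pipeline recoverable with known targets.

Scalp signals are rendered as ``a(t) * template[label(t)] + noise(t)`` with a
rectified 10 Hz positive envelope ``a(t)`` (so global field power has
detectable peaks inside the 2-20 Hz analysis band) and spatially and
temporally white Gaussian noise scaled to a requested SNR.  Task trials are
rendered time-locked: every trial of a subject repeats that subject's evoked
label sequence and envelope, so trial averaging increases SNR the way it
does for real event-related potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import EEGRecording
from .montage import CLASS_NAMES, MontageSpec, canonical_maps, spherical_montage

__all__ = [
    "GroupSpec",
    "GroundTruth",
    "SyntheticCohort",
    "default_group_specs",
    "make_templates",
    "simulate_label_sequence",
    "render_eeg",
    "make_cohort",
    "simulate_feature_table",
]

N_STATES = len(CLASS_NAMES)


# --------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class GroupSpec:
    """Generative parameters for one (group, paradigm) condition.

    Attributes
    ----------
    group_label : str
        ``"HC"`` or ``"MCI"``.
    n_subjects : int
        Number of subjects drawn from this specification.
    transition_matrix : ndarray, shape (4, 4)
        Row-stochastic matrix over *distinct-state* transitions; the diagonal
        is structurally zero because runs are generated explicitly.
    mean_durations_ms : ndarray, shape (4,)
        Mean run length of each state, in milliseconds.
    duration_shape : float
        Gamma shape for run lengths (scale = mean / shape).
    snr : float
        Template-signal RMS over noise RMS of rendered recordings.
    moca_mean, moca_sd : float
        Group-level MoCA distribution (scores are rounded and clipped to
        the 0-30 scale when sampled).
    duration_subject_cv : float
        Between-subject coefficient of variation of the mean durations
        (log-normal multiplier per subject and state).
    transition_subject_kappa : float
        Dirichlet concentration for between-subject jitter of transition
        rows; larger means less jitter.  ``inf`` disables jitter.
    """

    group_label: str
    n_subjects: int
    transition_matrix: np.ndarray
    mean_durations_ms: np.ndarray
    duration_shape: float = 2.0
    snr: float = 5.0
    moca_mean: float = 25.0
    moca_sd: float = 1.5
    duration_subject_cv: float = 0.15
    transition_subject_kappa: float = 60.0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        d = np.asarray(self.mean_durations_ms, dtype=float)
        object.__setattr__(self, "transition_matrix", P)
        object.__setattr__(self, "mean_durations_ms", d)
        if P.shape != (N_STATES, N_STATES):
            raise ValueError("transition_matrix must be 4x4")
        if np.any(np.diag(P) != 0):
            raise ValueError("transition_matrix diagonal must be zero")
        if np.any(P < 0):
            raise ValueError("transition probabilities must be nonnegative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_matrix rows must sum to 1")
        if d.shape != (N_STATES,) or np.any(d <= 0):
            raise ValueError("mean_durations_ms must be 4 positive values")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_shape <= 0 or self.snr <= 0:
            raise ValueError("duration_shape and snr must be positive")


def _uniform_rows(into: np.ndarray | None = None) -> np.ndarray:
    """Zero-diagonal row-stochastic matrix; optionally biased per column."""
    P = np.full((N_STATES, N_STATES), 1.0, dtype=float)
    np.fill_diagonal(P, 0.0)
    if into is not None:
        P = P * np.asarray(into, dtype=float)[None, :]
        np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


def default_group_specs(
    n_hc: int = 31, n_mci: int = 32, snr: float = 5.0
) -> dict[tuple[str, str], GroupSpec]:
    """Default cohort conditions, keyed by ``(group, paradigm)``.

    The group contrasts mirror the qualitative picture reported for MCI
    cohorts: at rest, MCI shows a longer microstate-A duration and reduced
    microstate-D duration, coverage and occurrence; under task, MCI shows
    increased A duration/coverage/occurrence and reduced C duration and
    coverage.  Mean durations are on the tens-of-milliseconds scale of
    unsmoothed backfitting.
    """
    common = dict(duration_shape=2.0, snr=snr)
    hc = dict(moca_mean=25.48, moca_sd=1.48, **common)
    mci = dict(moca_mean=19.16, moca_sd=1.48, **common)
    # Underlying state dwell times sit at the classic 60-100 ms microstate
    # timescale; the relative group contrasts (MCI rest: longer A, shorter D
    # with fewer transitions into D; MCI task: A up, C down) set the
    # screening stage's true positives.  Observed backfit durations on noisy
    # unsmoothed data come out much shorter than these means.
    return {
        ("HC", "rest"): GroupSpec(
            "HC",
            n_hc,
            _uniform_rows(),
            np.array([57.6, 64.0, 68.0, 76.4]),
            **hc,
        ),
        ("MCI", "rest"): GroupSpec(
            "MCI",
            n_mci,
            _uniform_rows(into=[1.0, 1.0, 1.0, 0.6]),
            np.array([69.2, 64.0, 68.0, 65.6]),
            **mci,
        ),
        ("HC", "task"): GroupSpec(
            "HC",
            n_hc,
            _uniform_rows(into=[0.45, 1.0, 1.0, 1.0]),
            np.array([86.0, 100.0, 171.6, 120.0]),
            **hc,
        ),
        ("MCI", "task"): GroupSpec(
            "MCI",
            n_mci,
            _uniform_rows(into=[1.9, 1.0, 1.0, 1.0]),
            np.array([111.2, 100.0, 120.0, 112.0]),
            **mci,
        ),
    }


# --------------------------------------------------------------------------
# templates


def make_templates(
    montage: MontageSpec, k: int = 4, seed: int | None = 0, perturbation: float = 0.12
) -> np.ndarray:
    """Build ``k`` unit-norm, average-referenced microstate templates.

    The first four maps are the canonical A-D dipolar fields evaluated on
    the montage, each perturbed by a seeded smooth random field (a random
    low-order dipolar component) so different seeds give different but
    recognisable topographies.  Additional maps beyond four are random
    smooth fields.
    """
    n = montage.n_channels
    if k > n:
        raise ValueError(f"cannot build {k} templates for {n} channels")
    rng = np.random.default_rng(seed)
    base = canonical_maps(montage.positions)
    maps = []
    for m in range(k):
        if m < base.shape[0]:
            v = base[m].copy()
        else:
            axis = rng.standard_normal(3)
            v = montage.positions @ (axis / np.linalg.norm(axis))
        axis = rng.standard_normal(3)
        delta = montage.positions @ (axis / np.linalg.norm(axis))
        delta = delta - delta.mean()
        nrm = np.linalg.norm(delta)
        if nrm > 0:
            v = v + perturbation * delta / nrm
        v = v - v.mean()
        v = v / np.linalg.norm(v)
        maps.append(v)
    templates = np.asarray(maps)
    corr = templates @ templates.T
    off = np.abs(corr - np.diag(np.diag(corr)))
    if off.max() >= 0.8:
        raise RuntimeError("generated templates are too correlated (>= 0.8)")
    return templates


# --------------------------------------------------------------------------
# label sequences


def embedded_stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of the embedded (distinct-state) chain."""
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def expected_occupancy(P: np.ndarray, mean_durations_ms: np.ndarray) -> np.ndarray:
    """Long-run fraction of time in each state: occupancy_s ∝ pi_s * d_s."""
    pi = embedded_stationary(P)
    w = pi * np.asarray(mean_durations_ms, dtype=float)
    return w / w.sum()


def _simulate_runs(
    spec: GroupSpec, n_samples: int, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (states, run_lengths_in_samples) covering >= n_samples."""
    P = spec.transition_matrix
    if np.any(P.sum(axis=1) == 0):
        raise ValueError("degenerate transition row (all zero)")
    scale_ms = spec.mean_durations_ms / spec.duration_shape
    mean_samples = np.maximum(spec.mean_durations_ms * fs / 1000.0, 1.0)
    est = int(n_samples / mean_samples.min() * 1.25) + 32

    # Pre-draw per-state pools of run lengths and successors; the walk
    # itself is the only sequential part.
    length_pool = []
    succ_pool = []
    for s in range(N_STATES):
        runs_ms = rng.gamma(spec.duration_shape, scale_ms[s], size=est)
        lengths = np.maximum(1, np.rint(runs_ms * fs / 1000.0).astype(np.int64))
        length_pool.append(lengths.tolist())
        succ_pool.append(rng.choice(N_STATES, size=est, p=P[s]).tolist())

    pi = embedded_stationary(P)
    state = int(rng.choice(N_STATES, p=pi))
    states: list[int] = []
    lengths_out: list[int] = []
    counters = [0] * N_STATES
    total = 0
    while total < n_samples:
        c = counters[state]
        if c >= len(length_pool[state]):  # pool exhausted; top up (rare)
            runs_ms = rng.gamma(spec.duration_shape, scale_ms[state], size=est)
            length_pool[state].extend(
                np.maximum(1, np.rint(runs_ms * fs / 1000.0).astype(np.int64)).tolist()
            )
            succ_pool[state].extend(
                rng.choice(N_STATES, size=est, p=P[state]).tolist()
            )
        length = length_pool[state][c]
        states.append(state)
        lengths_out.append(length)
        total += length
        next_state = succ_pool[state][c]
        counters[state] = c + 1
        state = int(next_state)
    lengths_arr = np.asarray(lengths_out, dtype=np.int64)
    lengths_arr[-1] -= total - n_samples  # truncate final run at the boundary
    keep = lengths_arr > 0
    return np.asarray(states, dtype=np.int8)[keep], lengths_arr[keep]


def simulate_label_sequence(
    spec: GroupSpec,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate a per-sample microstate label sequence (int codes 0..3).

    Runs of each state are gamma distributed (shape ``spec.duration_shape``,
    mean ``spec.mean_durations_ms``) rounded to at least one sample; the
    successor state is drawn from the matching row of the transition matrix.
    The initial state is drawn from the embedded-chain stationary vector.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))
    states, lengths = _simulate_runs(spec, n_samples, fs, rng)
    return np.repeat(states, lengths)[:n_samples]


# --------------------------------------------------------------------------
# rendering


def render_eeg(
    labels: np.ndarray,
    templates: np.ndarray,
    snr: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    amp_uv: float = 30.0,
    envelope_freq_hz: float = 5.0,
    envelope_floor: float = 0.2,
    envelope_power: float = 2.0,
    envelope: np.ndarray | None = None,
    channel_names: list[str] | None = None,
    subject_id: str = "",
    group: str = "",
    paradigm: str = "",
) -> EEGRecording:
    """Render a label sequence into a multichannel recording.

    ``signal(t) = a(t) * template[label(t)]`` with the rectified positive
    envelope ``a(t) = floor + |sin(2 pi f t + phi)|^p`` (random phase unless
    an explicit ``envelope`` is supplied), plus white Gaussian noise scaled
    so that overall signal RMS / noise RMS equals ``snr``.  With the default
    base frequency of 5 Hz and exponent 2 the envelope's oscillatory power
    sits at 10 Hz -- mid-band for a 2-20 Hz analysis -- and waxes and wanes
    like bursting alpha, giving well-defined global field power peaks.  Both
    the templates and the noise are average-referenced, so the output passes
    CAR.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a nonempty 1-D sequence")
    if snr <= 0:
        raise ValueError("snr must be positive")
    templates = np.asarray(templates, dtype=float)
    n_ch = templates.shape[1]
    n = labels.size
    rng = np.random.default_rng(seed)
    if envelope is None:
        t = np.arange(n) / fs
        phase = rng.uniform(0.0, 2.0 * np.pi)
        envelope = envelope_floor + np.abs(
            np.sin(2.0 * np.pi * envelope_freq_hz * t + phase)
        ) ** envelope_power
    else:
        envelope = np.asarray(envelope, dtype=float)
        if envelope.shape != (n,):
            raise ValueError("envelope length must match labels")
    signal = (amp_uv * envelope)[None, :] * templates[labels].T  # (ch, n)
    data = signal
    if np.isfinite(snr):
        sig_rms = float(np.sqrt(np.mean(signal**2)))
        noise = rng.standard_normal((n_ch, n))
        noise -= noise.mean(axis=0, keepdims=True)  # CAR the noise too
        noise_rms = float(np.sqrt(np.mean(noise**2)))
        data = signal + noise * (sig_rms / snr / noise_rms)
    if channel_names is None:
        channel_names = [f"E{i + 1:02d}" for i in range(n_ch)]
    return EEGRecording(
        data=data,
        fs=fs,
        channel_names=list(channel_names),
        subject_id=subject_id,
        group=group,
        paradigm=paradigm,
    )


# --------------------------------------------------------------------------
# cohort


@dataclass
class GroundTruth:
    """What the generator knows: templates, label sequences, parameters."""

    templates: np.ndarray
    label_sequences: dict[tuple[str, str], np.ndarray]
    subject_specs: dict[tuple[str, str], GroupSpec]
    group_specs: dict[tuple[str, str], GroupSpec]


@dataclass
class _Subject:
    subject_id: str
    group: str
    moca: float
    render_seeds: dict[str, np.random.SeedSequence]


class SyntheticCohort:
    """A lazily rendered synthetic cohort.

    Ground-truth label sequences, per-subject parameters and MoCA scores are
    generated eagerly (they are small); the multichannel recordings are
    rendered on demand so a full-size cohort never has to be held in memory
    at once.
    """

    def __init__(
        self,
        montage: MontageSpec,
        templates: np.ndarray,
        subjects: list[_Subject],
        ground_truth: GroundTruth,
        fs: float,
        paradigms: tuple[str, ...],
        rest_duration_s: float,
        n_incongruent: int,
        n_congruent: int,
        trial_s: float,
        baseline_s: float,
        envelope_freq_hz: float = 5.0,
        envelope_floor: float = 0.2,
        envelope_power: float = 2.0,
    ) -> None:
        self.montage = montage
        self.templates = templates
        self.subjects = subjects
        self.ground_truth = ground_truth
        self.fs = fs
        self.paradigms = paradigms
        self.rest_duration_s = rest_duration_s
        self.n_incongruent = n_incongruent
        self.n_congruent = n_congruent
        self.trial_s = trial_s
        self.baseline_s = baseline_s
        self.envelope_freq_hz = envelope_freq_hz
        self.envelope_floor = envelope_floor
        self.envelope_power = envelope_power

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> _Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def moca_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "moca": [s.moca for s in self.subjects],
            }
        )

    def rest_recording(self, subject_id: str) -> EEGRecording:
        """Render the continuous resting recording of one subject."""
        s = self.subject(subject_id)
        labels = self.ground_truth.label_sequences[(subject_id, "rest")]
        spec = self.ground_truth.subject_specs[(subject_id, "rest")]
        return render_eeg(
            labels,
            self.templates,
            snr=spec.snr,
            fs=self.fs,
            seed=np.random.default_rng(s.render_seeds["rest"]),
            envelope_freq_hz=self.envelope_freq_hz,
            envelope_floor=self.envelope_floor,
            envelope_power=self.envelope_power,
            channel_names=list(self.montage.channel_names),
            subject_id=subject_id,
            group=s.group,
            paradigm="rest",
        )

    def task_recording(self, subject_id: str) -> tuple[EEGRecording, pd.DataFrame]:
        """Render the continuous task recording plus its event table.

        Trials are contiguous ``trial_s``-long segments; the stimulus onset
        of trial ``k`` is at ``k * trial_s + baseline_s``.  Incongruent
        trials repeat the subject's evoked label sequence (time-locked);
        congruent trials repeat an independent control sequence.  All trials
        carry ``correct = 1`` by default, giving exactly ``n_incongruent``
        correct-incongruent trials.
        """
        s = self.subject(subject_id)
        rng = np.random.default_rng(s.render_seeds["task"])
        fs = self.fs
        n_trial = int(round(self.trial_s * fs))
        proto_inc = self.ground_truth.label_sequences[(subject_id, "task")]
        proto_con = self.ground_truth.label_sequences[(subject_id, "task_congruent")]
        n_trials = self.n_incongruent + self.n_congruent
        conditions = np.array(
            ["incongruent"] * self.n_incongruent + ["congruent"] * self.n_congruent
        )
        rng.shuffle(conditions)
        labels = np.empty(n_trials * n_trial, dtype=np.int8)
        for k, cond in enumerate(conditions):
            proto = proto_inc if cond == "incongruent" else proto_con
            labels[k * n_trial : (k + 1) * n_trial] = proto
        # time-locked envelope: identical in every trial, phase 0 at trial start
        t = np.arange(n_trial) / fs
        env_trial = self.envelope_floor + np.abs(
            np.sin(2.0 * np.pi * self.envelope_freq_hz * t)
        ) ** self.envelope_power
        envelope = np.tile(env_trial, n_trials)
        spec = self.ground_truth.subject_specs[(subject_id, "task")]
        rec = render_eeg(
            labels,
            self.templates,
            snr=spec.snr,
            fs=fs,
            seed=rng,
            envelope=envelope,
            channel_names=list(self.montage.channel_names),
            subject_id=subject_id,
            group=s.group,
            paradigm="task",
        )
        events = pd.DataFrame(
            {
                "onset_s": np.arange(n_trials) * self.trial_s + self.baseline_s,
                "condition": conditions,
                "correct": np.ones(n_trials, dtype=int),
            }
        )
        return rec, events

    def iter_recordings(self):
        """Yield ``(subject, rest_recording, task_recording, events)``."""
        for s in self.subjects:
            rest = self.rest_recording(s.subject_id) if "rest" in self.paradigms else None
            task, events = (
                self.task_recording(s.subject_id)
                if "task" in self.paradigms
                else (None, None)
            )
            yield s, rest, task, events


def _subject_spec(
    spec: GroupSpec, rng: np.random.Generator
) -> GroupSpec:
    """Draw a per-subject variant of a group spec (between-subject effects)."""
    d = spec.mean_durations_ms
    cv = spec.duration_subject_cv
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv**2))
        d = d * rng.lognormal(-0.5 * sigma**2, sigma, size=N_STATES)
    P = spec.transition_matrix
    kappa = spec.transition_subject_kappa
    if np.isfinite(kappa):
        rows = []
        for s in range(N_STATES):
            off = [j for j in range(N_STATES) if j != s]
            alpha = np.maximum(P[s, off] * kappa, 1e-6)
            row = np.zeros(N_STATES)
            row[off] = rng.dirichlet(alpha)
            rows.append(row)
        P = np.asarray(rows)
    return replace(spec, transition_matrix=P, mean_durations_ms=d, n_subjects=1)


def sample_moca(spec: GroupSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample MoCA scores: rounded, clipped Gaussians on the 0-30 scale."""
    raw = rng.normal(spec.moca_mean, spec.moca_sd, size=n)
    return np.clip(np.rint(raw), 0, 30).astype(float)


def make_cohort(
    hc: GroupSpec | dict[str, GroupSpec] | None = None,
    mci: GroupSpec | dict[str, GroupSpec] | None = None,
    montage: MontageSpec | None = None,
    paradigms: tuple[str, ...] = ("rest", "task"),
    seed: int = 0,
    rest_duration_s: float = 200.0,
    n_incongruent: int = 150,
    n_congruent: int = 150,
    trial_s: float = 1.2,
    baseline_s: float = 0.2,
    fs: float = 250.0,
) -> SyntheticCohort:
    """Generate the default two-group, two-paradigm cohort.

    ``hc`` and ``mci`` may each be a single :class:`GroupSpec` (used for
    both paradigms) or a mapping ``{"rest": spec, "task": spec}``.  With the
    defaults this yields 31 HC + 32 MCI subjects, each with one 200-s
    resting recording and one task recording containing 150 correct
    incongruent trials of 1.2 s (including a 200-ms pre-stimulus baseline).
    """
    defaults = default_group_specs()
    def norm(specs, label):
        if specs is None:
            return {p: defaults[(label, p)] for p in ("rest", "task")}
        if isinstance(specs, GroupSpec):
            return {p: specs for p in ("rest", "task")}
        return dict(specs)

    spec_map = {"HC": norm(hc, "HC"), "MCI": norm(mci, "MCI")}
    if montage is None:
        montage = spherical_montage(62)

    root = np.random.SeedSequence(seed)
    ss_templates, ss_cohort = root.spawn(2)
    templates = make_templates(montage, k=N_STATES, seed=np.random.default_rng(ss_templates))

    subjects: list[_Subject] = []
    label_sequences: dict[tuple[str, str], np.ndarray] = {}
    subject_specs: dict[tuple[str, str], GroupSpec] = {}
    n_trial_samples = int(round(trial_s * fs))

    groups = [("HC", spec_map["HC"]["rest"].n_subjects), ("MCI", spec_map["MCI"]["rest"].n_subjects)]
    n_total = sum(n for _, n in groups)
    subject_seeds = ss_cohort.spawn(n_total)
    idx = 0
    for group, n_subj in groups:
        for j in range(n_subj):
            sid = f"{group}{j + 1:02d}"
            ss = subject_seeds[idx]
            idx += 1
            (ss_spec, ss_rest, ss_task, ss_render_rest, ss_render_task, ss_moca) = ss.spawn(6)
            rng_spec = np.random.default_rng(ss_spec)
            rng_moca = np.random.default_rng(ss_moca)
            rest_spec = _subject_spec(spec_map[group]["rest"], rng_spec)
            task_spec = _subject_spec(spec_map[group]["task"], rng_spec)
            moca = float(sample_moca(spec_map[group]["rest"], 1, rng_moca)[0])
            if "rest" in paradigms:
                label_sequences[(sid, "rest")] = simulate_label_sequence(
                    rest_spec, rest_duration_s, fs, np.random.default_rng(ss_rest)
                )
            if "task" in paradigms:
                rng_task = np.random.default_rng(ss_task)
                label_sequences[(sid, "task")] = simulate_label_sequence(
                    task_spec, trial_s, fs, rng_task
                )[:n_trial_samples]
                label_sequences[(sid, "task_congruent")] = simulate_label_sequence(
                    task_spec, trial_s, fs, rng_task
                )[:n_trial_samples]
            subject_specs[(sid, "rest")] = rest_spec
            subject_specs[(sid, "task")] = task_spec
            subjects.append(
                _Subject(
                    subject_id=sid,
                    group=group,
                    moca=moca,
                    render_seeds={"rest": ss_render_rest, "task": ss_render_task},
                )
            )

    gt = GroundTruth(
        templates=templates,
        label_sequences=label_sequences,
        subject_specs=subject_specs,
        group_specs={
            (g, p): spec_map[g][p] for g in ("HC", "MCI") for p in ("rest", "task")
        },
    )
    return SyntheticCohort(
        montage=montage,
        templates=templates,
        subjects=subjects,
        ground_truth=gt,
        fs=fs,
        paradigms=paradigms,
        rest_duration_s=rest_duration_s,
        n_incongruent=n_incongruent,
        n_congruent=n_congruent,
        trial_s=trial_s,
        baseline_s=baseline_s,
    )


# --------------------------------------------------------------------------
# feature-table shortcut (no rendering)


def simulate_feature_table(
    hc: GroupSpec,
    mci: GroupSpec,
    n_segments: int = 10,
    segment_s: float = 20.0,
    fs: float = 250.0,
    seed: int = 0,
    prefix: str = "r",
    gev_mean: float = 0.75,
    gev_sd: float = 0.02,
    include_moca: bool = False,
) -> pd.DataFrame:
    """Simulate a feature table directly from label sequences.

    Bypasses rendering, clustering and backfitting: each subject gets one
    long simulated label sequence, split into ``n_segments`` segments from
    which the 26 features are computed.  The GEV feature, which is undefined
    without scalp data, is drawn i.i.d. from a Gaussian shared by both
    groups.  Useful for calibration studies of the screening and
    classification stages where label statistics are the quantity of
    interest.
    """
    from .features import extract_all  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    rows = []
    n_seg_samples = int(round(segment_s * fs))
    for spec in (hc, mci):
        for j in range(spec.n_subjects):
            sid = f"{spec.group_label}{j + 1:02d}"
            sspec = _subject_spec(spec, rng)
            labels = simulate_label_sequence(
                sspec, n_segments * segment_s, fs, rng
            )
            moca = float(sample_moca(spec, 1, rng)[0])
            for seg in range(n_segments):
                seg_labels = labels[seg * n_seg_samples : (seg + 1) * n_seg_samples]
                gev = float(rng.normal(gev_mean, gev_sd))
                feats = extract_all(seg_labels, fs, gev=gev, prefix=prefix)
                row = {
                    "subject_id": sid,
                    "segment_id": seg,
                    "group": spec.group_label,
                }
                if include_moca:
                    row["moca"] = moca
                row.update(feats)
                rows.append(row)
    return pd.DataFrame(rows)
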