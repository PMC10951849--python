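"""Synthetic cohort generator.

Emulates the study design: two groups (people with borderline personality
disorder and matched controls) of 25 participants, three blocks of 50
trials across three conditions (neutral / maintain / reappraise), 13-s
epochs spanning -6..+7 s around the regulation instruction, with the
picture presented at -3 s.

Each trial's scalp signal is a leadfield projection of

* spatially distributed 1/f background noise sources,
* a phase-locked evoked transient after picture onset and after the
  instruction (identical across trials within a condition),
* a random-phase (induced) narrowband theta source at a right-frontal
  "effect" voxel, whose amplitude rises during the regulation window
  (1-5 s) in the reappraisal condition only, with a larger rise in the
  control group than in the BPD group,
* a second theta source coherent with the first at a fixed phase lag,
  planting genuine (non-volume-conduction) connectivity,
* optionally a low-frequency frontal drift to exercise ICA cleanup.

Behavioural ratings and Emotion Regulation Questionnaire (ERQ) facet
scores are drawn from truncated normal distributions at the study's
group means and standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .containers import (
    CONDITIONS,
    PICTURE_ONSET,
    REGULATION_WINDOW,
    DataError,
    EpochedRecording,
    Provenance,
)
from .headmodel import HeadModel, Leadfield, generate_leadfield, make_head_model

__all__ = [
    "SimConfig",
    "BEHAVIOUR_PARAMS",
    "GroundTruth",
    "CohortBundle",
    "simulate_behaviour",
    "simulate_participant",
    "generate_cohort",
    "condition_sequence",
]

#: group means and SDs of condition-mean emotion ratings (0-100) and ERQ
#: facet scores; the neutral-condition rating is not reported by the study
#: and is set to a plausibly low value.
BEHAVIOUR_PARAMS = {
    "bpd": {
        "rating_reappraise": (42.0, 21.0),
        "rating_maintain": (58.0, 25.0),
        "rating_neutral": (15.0, 10.0),
        "erq_reappraisal": (21.0, 8.0),
        "erq_suppression": (15.0, 5.0),
    },
    "control": {
        "rating_reappraise": (35.0, 19.0),
        "rating_maintain": (56.0, 21.0),
        "rating_neutral": (12.0, 8.0),
        "erq_reappraisal": (27.0, 7.0),
        "erq_suppression": (12.0, 5.0),
    },
}

RATING_BOUNDS = (0.0, 100.0)
ERQ_R_BOUNDS = (10.0, 42.0)
ERQ_S_BOUNDS = (4.0, 28.0)

GROUPS = ("bpd", "control")


@dataclass
class SimConfig:
    """Cohort simulation parameters.

    Amplitudes are source dipole moments in nAm (RMS for stochastic
    sources); the leadfield converts them to µV at the scalp.
    """

    n_per_group: int = 25
    n_blocks: int = 3
    trials_per_block: int = 50
    sfreq: float = 250.0
    epoch_span: tuple[float, float] = (-6.0, 7.0)
    n_voxels: int = 400
    # planted induced-theta effect
    effect_voxel_mm: tuple[float, float, float] = (41.0, 35.0, 40.0)
    coupled_voxel_mm: tuple[float, float, float] = (45.0, 10.0, 45.0)
    theta_amplitude_base: float = 60.0
    #: reappraisal-window source-amplitude multiplier per group
    theta_effect_gain: dict = field(
        default_factory=lambda: {"control": 2.0, "bpd": 1.4}
    )
    theta_band: tuple[float, float] = (4.5, 7.5)
    coupling_lag: float = np.pi / 2
    #: between-participant lognormal jitter (SD of log amplitude)
    participant_jitter: float = 0.15
    # background / evoked
    n_noise_sources: int = 30
    noise_amplitude: float = 20.0
    noise_exponent: float = 1.0
    evoked_amplitude: float = 5.0
    drift_amplitude: float = 0.0
    #: optional linear dependence of the planted reappraisal theta-power
    #: increment on the participant's ERQ reappraisal score (per point)
    erq_theta_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        n_trials = self.n_blocks * self.trials_per_block
        if n_trials % 3:
            raise DataError(
                "n_blocks * trials_per_block must divide into the three "
                "conditions (2:1 negative:neutral picture ratio), got "
                f"{n_trials} trials"
            )
        lo, hi = self.epoch_span
        if not (lo <= -4.2 and hi >= 5.0):
            raise DataError(
                "epoch span must cover the baseline [-4.2, -3.2] and "
                f"regulation [1, 5] windows, got {self.epoch_span}"
            )
        for g in self.theta_effect_gain:
            if g not in GROUPS:
                raise DataError(f"unknown group {g!r} in theta_effect_gain")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping for recovery tests."""

    effect_voxel: int
    coupled_voxel: int
    effect_channels: list[str]
    theta_amplitude_base: float
    theta_effect_gain: dict
    coupling_lag: float
    participant_gain: dict  # participant_id -> realised amplitude factor


@dataclass
class CohortBundle:
    config: SimConfig
    head_model: HeadModel
    leadfield: Leadfield
    table: pd.DataFrame
    ground_truth: GroundTruth
    epochs: dict  # participant_id -> EpochedRecording (may be empty)


def condition_sequence(n_trials: int, rng: np.random.Generator,
                       max_run: int = 3) -> np.ndarray:
    """Pseudo-randomised condition order with balanced counts.

    Equal numbers of the three conditions, shuffled under the constraint
    that no condition repeats more than ``max_run`` times in a row.
    """
    if n_trials % 3:
        raise DataError("n_trials must be divisible by 3")
    base = np.repeat(np.array(CONDITIONS, dtype=object), n_trials // 3)
    for _ in range(1000):
        seq = rng.permutation(base)
        runs = _longest_run(seq)
        if runs <= max_run:
            return seq
    raise RuntimeError("could not satisfy run-length constraint")


def _longest_run(seq) -> int:
    best = run = 1
    for a, b in zip(seq[:-1], seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _truncated_normal(mean, sd, lo, hi, rng, size=None):
    if sd == 0:
        return np.full(size, float(mean)) if size else float(mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_behaviour(config: SimConfig, group: str,
                       seed: int, params: dict | None = None) -> dict:
    """One participant's condition-mean ratings and ERQ facet scores.

    ``params`` overrides the study-level (mean, sd) table, e.g. to build
    degenerate (sd = 0) cohorts in tests.
    """
    if group not in GROUPS:
        raise DataError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(seed)
    p = (params or BEHAVIOUR_PARAMS)[group]
    row = {"group": group}
    for key in ("rating_neutral", "rating_maintain", "rating_reappraise"):
        row[key] = float(_truncated_normal(*p[key], *RATING_BOUNDS, rng))
    row["erq_reappraisal"] = float(
        _truncated_normal(*p["erq_reappraisal"], *ERQ_R_BOUNDS, rng))
    row["erq_suppression"] = float(
        _truncated_normal(*p["erq_suppression"], *ERQ_S_BOUNDS, rng))
    return row


def _oneoverf_noise(rng, n_sources, n_samples, sfreq, exponent):
    """Unit-RMS 1/f^exponent noise, one row per source."""
    freqs = np.fft.rfftfreq(n_samples, 1 / sfreq)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = (freqs[nz] + 0.5) ** (-exponent / 2)  # +0.5 Hz tames the DC pole
    coef = (rng.standard_normal((n_sources, len(freqs)))
            + 1j * rng.standard_normal((n_sources, len(freqs)))) * shape
    coef[:, 0] = 0
    x = np.fft.irfft(coef, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


def _narrowband_analytic(rng, n_samples, sfreq, band):
    """Complex analytic narrowband noise with unit-RMS real part."""
    freqs = np.fft.fftfreq(n_samples, 1 / sfreq)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    coef = np.zeros(n_samples, complex)
    coef[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    z = np.fft.ifft(coef)
    rms = np.sqrt(np.mean(z.real**2))
    return z / rms


def _evoked_waveform(t, onset, sfreq):
    """Phase-locked transient: damped 2-Hz oscillation over ~1.5 s."""
    tt = t - onset
    env = np.exp(-((tt - 0.4) ** 2) / (2 * 0.25**2)) * (tt >= 0)
    return env * np.sin(2 * np.pi * 2.0 * tt)


def _ramp_window(t, lo, hi, ramp=0.5):
    """Smooth 0..1 box over [lo, hi] with raised-cosine edges."""
    w = np.zeros_like(t)
    core = (t >= lo + ramp) & (t <= hi - ramp)
    w[core] = 1.0
    up = (t >= lo) & (t < lo + ramp)
    w[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - lo) / ramp))
    dn = (t > hi - ramp) & (t <= hi)
    w[dn] = 0.5 * (1 - np.cos(np.pi * (hi - t[dn]) / ramp))
    return w


def simulate_participant(
    config: SimConfig,
    group: str,
    leadfield: Leadfield,
    seed: int,
    participant_gain: float = 1.0,
) -> EpochedRecording:
    """Simulate one participant's epoched EEG (channels × time × trials)."""
    if group not in GROUPS:
        raise DataError(f"unknown group {group!r}; expected one of {GROUPS}")
    rng = np.random.default_rng(seed)
    hm = leadfield.head_model
    lo, hi = config.epoch_span
    n_samples = int(round((hi - lo) * config.sfreq)) + 1
    t = lo + np.arange(n_samples) / config.sfreq
    n_trials = config.n_trials
    conditions = condition_sequence(n_trials, rng)

    v_eff = hm.nearest_voxel(config.effect_voxel_mm)
    v_cpl = hm.nearest_voxel(config.coupled_voxel_mm)

    # fixed per-participant source layout
    noise_vox = rng.choice(hm.n_voxels, size=config.n_noise_sources, replace=False)
    noise_ori = rng.standard_normal((config.n_noise_sources, 3))
    noise_ori /= np.linalg.norm(noise_ori, axis=1, keepdims=True)
    noise_topo = np.einsum("so,soc->sc", noise_ori, leadfield.gain[noise_vox])

    def radial_topo(voxel):
        # fixed outward (radial) orientation, shared across participants:
        # a cortical patch projects with a consistent topography, which is
        # what makes a group-level sensor cluster coherent
        ori = hm.voxel_positions[voxel]
        ori = ori / np.linalg.norm(ori)
        return ori @ leadfield.gain[voxel]

    eff_topo = radial_topo(v_eff)
    cpl_topo = radial_topo(v_cpl)

    # evoked source: central posterior voxel, scaled to evoked_amplitude µV
    # at its best channel
    v_evk = hm.nearest_voxel((0.0, -40.0, 40.0))
    evk_topo = radial_topo(v_evk)
    evk_topo = evk_topo / np.max(np.abs(evk_topo)) * config.evoked_amplitude
    evoked_t = _evoked_waveform(t, PICTURE_ONSET, config.sfreq) + \
        _evoked_waveform(t, 0.0, config.sfreq)
    evoked_cond_scale = {"neutral": 0.8, "maintain": 1.0, "reappraise": 1.0}

    # frontal drift topography (for ICA exercise)
    front = hm.channel_positions[:, 1]  # anterior axis
    drift_topo = np.exp((front - front.max()) / (0.25 * hm.radius))

    reg_win = _ramp_window(t, *REGULATION_WINDOW)
    gain_grp = config.theta_effect_gain.get(group, 1.0)

    data = np.empty((hm.n_channels, n_samples, n_trials))
    for k in range(n_trials):
        cond = conditions[k]
        x = _oneoverf_noise(rng, config.n_noise_sources, n_samples,
                            config.sfreq, config.noise_exponent)
        sensors = (config.noise_amplitude * x.T @ noise_topo).T
        sensors += evoked_cond_scale[cond] * evoked_t[None, :] * evk_topo[:, None]

        # induced theta: amplitude_base everywhere, raised to
        # amplitude_base * gain during [1, 5] s in reappraisal trials
        z = _narrowband_analytic(rng, n_samples, config.sfreq, config.theta_band)
        amp = np.full(n_samples, config.theta_amplitude_base)
        if cond == "reappraise":
            amp = amp * (1 + (gain_grp - 1) * reg_win)
        amp = amp * participant_gain
        s1 = (amp * z.real)
        s2 = (amp * (z * np.exp(-1j * config.coupling_lag)).real)
        sensors += s1[None, :] * eff_topo[:, None]
        sensors += s2[None, :] * cpl_topo[:, None]

        if config.drift_amplitude:
            d = _oneoverf_noise(rng, 1, n_samples, config.sfreq, 3.0)[0]
            sensors += config.drift_amplitude * d[None, :] * drift_topo[:, None]
        data[:, :, k] = sensors

    return EpochedRecording(
        data=data, time_axis=t, condition=conditions,
        channel_labels=list(hm.channel_labels),
        channel_positions=hm.channel_positions, sfreq=config.sfreq,
        provenance=Provenance(),
    )


def effect_channels(leadfield: Leadfield, voxel: int, k: int = 6) -> list[str]:
    """The k channels with the strongest radial-dipole gain for a voxel
    (the orientation the planted sources use)."""
    hm = leadfield.head_model
    ori = hm.voxel_positions[voxel]
    ori = ori / np.linalg.norm(ori)
    topo = np.abs(ori @ leadfield.gain[voxel])
    order = np.argsort(topo)[::-1][:k]
    return [hm.channel_labels[i] for i in order]


def generate_cohort(
    config: SimConfig,
    leadfield: Leadfield | None = None,
    include_eeg: bool = True,
) -> CohortBundle:
    """Generate the full two-group cohort.

    Deterministic given ``config.seed``; per-participant streams are
    spawned from the master seed.  With ``include_eeg=False`` only the
    behavioural table and ground-truth record are produced (cheap).
    """
    if leadfield is None:
        hm = make_head_model(config.n_voxels)
        leadfield = generate_leadfield(hm)
    hm = leadfield.head_model

    ss = np.random.SeedSequence(config.seed)
    n_total = 2 * config.n_per_group
    child = ss.spawn(n_total)
    jit_rng = np.random.default_rng(ss.spawn(1)[0])

    v_eff = hm.nearest_voxel(config.effect_voxel_mm)
    v_cpl = hm.nearest_voxel(config.coupled_voxel_mm)
    gt = GroundTruth(
        effect_voxel=v_eff, coupled_voxel=v_cpl,
        effect_channels=effect_channels(leadfield, v_eff),
        theta_amplitude_base=config.theta_amplitude_base,
        theta_effect_gain=dict(config.theta_effect_gain),
        coupling_lag=config.coupling_lag,
        participant_gain={},
    )

    rows, epochs = [], {}
    idx = 0
    for group in GROUPS:
        for j in range(config.n_per_group):
            pid = f"{group}{j + 1:02d}"
            pseed = child[idx]
            idx += 1
            b_rng, e_rng = pseed.spawn(2)
            row = simulate_behaviour(config, group,
                                     np.random.default_rng(b_rng).integers(2**31))
            row["participant_id"] = pid
            rows.append(row)
            pgain = float(np.exp(jit_rng.normal(0, config.participant_jitter)))
            if config.erq_theta_slope:
                mean_erq = BEHAVIOUR_PARAMS[group]["erq_reappraisal"][0]
                pgain *= 1 + config.erq_theta_slope * (
                    row["erq_reappraisal"] - mean_erq)
            gt.participant_gain[pid] = pgain
            if include_eeg:
                epochs[pid] = simulate_participant(
                    config, group, leadfield,
                    np.random.default_rng(e_rng).integers(2**31),
                    participant_gain=pgain,
                )
    table = pd.DataFrame(rows)[
        ["participant_id", "group", "rating_neutral", "rating_maintain",
         "rating_reappraise", "erq_reappraisal", "erq_suppression"]
    ]
    return CohortBundle(config, hm, leadfield, table, gt, epochs)


def iter_participants(config: SimConfig, leadfield: Leadfield):
    """Yield (participant_id, group, EpochedRecording, gain) lazily.

    Identical seeding to :func:`generate_cohort`, for memory-bounded
    pipeline runs that process one participant at a time.
    """
    bundle = generate_cohort(config, leadfield, include_eeg=False)
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(2 * config.n_per_group)
    idx = 0
    for group in GROUPS:
        for j in range(config.n_per_group):
            pid = f"{group}{j + 1:02d}"
            _, e_rng = child[idx].spawn(2)
            idx += 1
            rec = simulate_participant(
                config, group, leadfield,
                np.random.default_rng(e_rng).integers(2**31),
                participant_gain=bundle.ground_truth.participant_gain[pid],
            )
            yield pid, group, rec, bundle
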