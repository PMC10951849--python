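"""End-to-end cohort analysis: simulate → clean → sensor theta →
cluster test → eLORETA power ratios → MIM connectivity → voxel tests →
behavioural statistics.

Participants are processed one at a time so memory stays bounded by a
single recording.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behaviour import mixed_anova_2x2, theta_regression
from .cluster import ClusterResult, build_neighbors, cluster_permutation_test
from .containers import DataError, EpochedRecording
from .headmodel import Leadfield, generate_leadfield, make_head_model
from .mim import mim_contrast_and_test, mim_voxel_to_whole_brain, voxel_cross_spectrum
from .preprocess import preprocess
from .simulate import SimConfig, iter_participants
from .source import (
    VoxelStatMap,
    band_fourier,
    eloreta_inverse,
    power_ratio_contrast,
    source_band_power,
    voxel_permutation_test,
)
from .timefreq import (
    baseline_subtract,
    regulation_contrast,
    subtract_erp,
    theta_summary,
    tfr_hanning,
)

logger = logging.getLogger("thetareg")

__all__ = ["CohortAnalysis", "analyze_participant", "analyze_cohort"]


@dataclass
class ParticipantDerived:
    participant_id: str
    group: str
    theta: np.ndarray              # per-channel theta summary
    ratio_contrast: np.ndarray     # per-voxel power-ratio contrast
    mim_maps: dict                 # condition -> per-voxel MIM map


@dataclass
class CohortAnalysis:
    config: SimConfig
    channel_labels: list[str]
    sensor_cluster: ClusterResult
    power_ratio_test: VoxelStatMap
    mim_test: VoxelStatMap
    behaviour_anova: object
    erq_anova: object
    regression_bpd: object
    ground_truth: object
    table: pd.DataFrame
    derived: list = field(default_factory=list)


def analyze_participant(
    rec: EpochedRecording,
    operator,
    participant_id: str = "",
    do_preprocess: bool = True,
    run_ica: bool = False,
    z_threshold: float = 4.0,
    seed: int = 0,
    fast: bool = False,
) -> ParticipantDerived:
    """All per-participant derived quantities from one epoched recording.

    ``fast=True`` restricts the TFR to the baseline and regulation
    windows (all summaries are unchanged).
    """
    if do_preprocess:
        rec, _, _ = preprocess(rec, z_threshold=z_threshold,
                               run_ica=run_ica, seed=seed)
    induced = subtract_erp(rec)

    from .containers import BASELINE_WINDOW, REGULATION_WINDOW

    windows = [BASELINE_WINDOW, REGULATION_WINDOW] if fast else None
    tfrs = tfr_hanning(induced, time_windows=windows)
    contrast = regulation_contrast(
        baseline_subtract(tfrs["reappraise"]), baseline_subtract(tfrs["maintain"]))
    theta = theta_summary(contrast, participant_id=participant_id).values

    power_reg, power_base, mim_maps = {}, {}, {}
    for cond in ("reappraise", "maintain"):
        mask = induced.select_condition(cond)
        spec_reg = band_fourier(induced, "regulation", trials=np.flatnonzero(mask))
        spec_base = band_fourier(induced, "baseline", trials=np.flatnonzero(mask))
        power_reg[cond] = source_band_power(operator, spec_reg)
        power_base[cond] = source_band_power(operator, spec_base)
        cs = voxel_cross_spectrum(operator, spec_reg)
        mim_maps[cond] = mim_voxel_to_whole_brain(cs).values
    ratio_contrast = power_ratio_contrast(power_reg, power_base)
    return ParticipantDerived(participant_id, "", theta, ratio_contrast, mim_maps)


def analyze_cohort(
    config: SimConfig,
    leadfield: Leadfield | None = None,
    n_perm: int = 2000,
    seed: int = 0,
    alpha_reg: float = 0.05,
    do_preprocess: bool = True,
    run_ica: bool = False,
    tails: str = "two",
    operator=None,
    fast: bool = False,
) -> CohortAnalysis:
    """Run the full analysis on a simulated cohort.

    A precomputed ``operator`` (matching the leadfield) avoids repeating
    the eLORETA iteration across runs on the same geometry.
    """
    if leadfield is None:
        leadfield = generate_leadfield(make_head_model(config.n_voxels))
    hm = leadfield.head_model
    if operator is None:
        operator = eloreta_inverse(leadfield, alpha_reg=alpha_reg)

    derived = []
    bundle = None
    for pid, group, rec, bundle in iter_participants(config, leadfield):
        d = analyze_participant(rec, operator, participant_id=pid,
                                do_preprocess=do_preprocess, run_ica=run_ica,
                                seed=seed, fast=fast)
        d.group = group
        derived.append(d)
        logger.info("analysed participant %s (%s)", pid, group)

    def stack(group, attr):
        return np.vstack([getattr(d, attr) for d in derived if d.group == group])

    graph = build_neighbors(list(hm.channel_labels), hm.channel_positions)
    sensor = cluster_permutation_test(
        stack("control", "theta"), stack("bpd", "theta"), graph,
        n_perm=n_perm, seed=seed)

    ratio_test = voxel_permutation_test(
        stack("control", "ratio_contrast"), stack("bpd", "ratio_contrast"),
        n_perm=n_perm, seed=seed, tails=tails,
        voxel_positions=hm.voxel_positions)

    maps_ctl = {c: np.vstack([d.mim_maps[c] for d in derived
                              if d.group == "control"])
                for c in ("reappraise", "maintain")}
    maps_bpd = {c: np.vstack([d.mim_maps[c] for d in derived
                              if d.group == "bpd"])
                for c in ("reappraise", "maintain")}
    mim_test = mim_contrast_and_test(
        maps_ctl, maps_bpd, n_perm=n_perm, seed=seed, tails=tails,
        voxel_positions=hm.voxel_positions)

    table = bundle.table
    behaviour_anova = mixed_anova_2x2(
        table, ("rating_reappraise", "rating_maintain"))
    erq_anova = mixed_anova_2x2(table, ("erq_reappraisal", "erq_suppression"))

    # regression within the BPD group: cluster-mean theta on ERQ facets and
    # rating difference
    best = sensor.best_cluster()
    members = best.members if best else list(range(min(4, hm.n_channels)))
    theta_bpd = stack("bpd", "theta")[:, members].mean(axis=1)
    tb = table[table.group == "bpd"]
    try:
        regression = theta_regression(
            theta_bpd, tb.erq_reappraisal.to_numpy(),
            tb.erq_suppression.to_numpy(),
            (tb.rating_reappraise - tb.rating_maintain).to_numpy())
    except DataError as exc:
        logger.warning("skipping theta regression: %s", exc)
        regression = None

    return CohortAnalysis(
        config=config, channel_labels=list(hm.channel_labels),
        sensor_cluster=sensor, power_ratio_test=ratio_test, mim_test=mim_test,
        behaviour_anova=behaviour_anova, erq_anova=erq_anova,
        regression_bpd=regression, ground_truth=bundle.ground_truth,
        table=table, derived=derived,
    )
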