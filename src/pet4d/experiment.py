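"""End-to-end synthetic replicate study.

Reproduces the study design on synthetic data: simulate every subject's
full-count scan, partition it into low-count replicate sets, reconstruct all
replicates with both arms at every iteration, then compute the
within-/between-subject variability metrics, the noise-induced-bias TAC
simulation (with noise levels taken from the pipeline's own reconstructed
replicates), the k2-boundary diagnostic, and the two-group power analysis.
All randomness flows from one experiment seed through named child seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bias import bias_table, estimate_frame_noise, full_count_noise, simulate_bias
from .kinetics import (BasisSet, FrameSchedule, fit_parametric_image,
                       frame_weights, make_basis_set)
from .metrics import (ParametricEnsemble, ROISet, between_subject_stats,
                      boundary_hit_fraction, roi_level_stats, roi_voxelwise_cv,
                      within_subject_stats)
from .phantom import (GM_REGIONS, REGION_NAMES, REPLICATES_PER_LEVEL,
                      PhantomSpec, ScanGeometry, downsample_replicates,
                      make_input_function, make_population,
                      simulate_dynamic_counts)
from .power import PowerSpec, two_sample_t_sample_size
from .projector import Projector
from .recon import (DirectConfig, DirectReconstruction, IndirectReconstruction,
                    OSEMConfig)

__all__ = ["ExperimentConfig", "ExperimentResults", "run_experiment"]

PARAMS = ("K1", "k2", "VT")


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved settings of one synthetic replicate study.

    ``count_levels`` maps each level to the number of replicates actually
    reconstructed (capped at the replicate-set sizes 1/5/10/10 for
    100%/20%/10%/5%).
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    count_levels: dict = field(default_factory=lambda: dict(REPLICATES_PER_LEVEL))
    methods: tuple = ("IR", "DR")
    n_iterations: int = 4
    n_subsets: int = 30
    n_bases: int = 500
    k2_min: float = 0.005
    k2_max: float = 1.0
    alt_k2_min: float = 0.001
    weight_mode: str = "duration-decay"
    skip_first_frames: int = 2
    bias_realizations: int = 10000
    bias_levels: tuple = (1.0, 0.2, 0.1)
    boundary_level: float = 0.1
    boundary_roi: str = "cortex"
    healthy_mean_vt: float = 8.72  # literature HC group mean, ml/cm3
    power_roi: str = "nigra"
    seed: int = 0

    def __post_init__(self):
        for level, n_rep in self.count_levels.items():
            if level not in REPLICATES_PER_LEVEL:
                raise ValueError(f"unsupported count level {level!r}")
            if n_rep > REPLICATES_PER_LEVEL[level]:
                raise ValueError(
                    f"level {level}: at most {REPLICATES_PER_LEVEL[level]} replicates")


@dataclass
class ExperimentResults:
    """Bundle of everything :func:`run_experiment` computes."""

    config: ExperimentConfig
    roi_set: ROISet
    variability: pd.DataFrame
    bias: pd.DataFrame | None
    bias_summary: pd.DataFrame | None
    boundary: pd.DataFrame | None
    power: pd.DataFrame | None
    maps: dict            # (method, level) -> [subject][replicate][iteration]
    subjects: list
    basis_set: BasisSet

    def summary(self) -> str:
        cfg = self.config
        grid = f"{cfg.phantom.grid_size}x{cfg.phantom.grid_size} / {cfg.phantom.n_subjects}"
        levels = ", ".join(f"{int(100 * k)}%({v})" for k, v in cfg.count_levels.items())
        methods = "+".join(cfg.methods) + f" / {cfg.n_iterations}"
        lines = [
            "Synthetic replicate study", "=" * 50,
            f"{'grid / subjects':<24}{grid:>24}",
            f"{'levels (replicates)':<24}{levels:>24}",
            f"{'methods / iterations':<24}{methods:>24}",
        ]
        return "\n".join(lines)


def _child_seed(base: int, *tags) -> int:
    import zlib

    ints = [zlib.crc32(repr(t).encode()) for t in tags]
    ss = np.random.SeedSequence([base, *ints])
    return int(ss.generate_state(1)[0] % 2**31)


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResults:
    cfg = config
    schedule = FrameSchedule.default(cfg.skip_first_frames)
    cp = make_input_function()
    basis = make_basis_set(cp, schedule, cfg.n_bases, cfg.k2_min, cfg.k2_max)
    subjects = make_population(cfg.phantom, _child_seed(cfg.seed, "population"))
    labels = cfg.phantom.labels()
    roi_masks = {name: (labels == lab).ravel() for lab, name in REGION_NAMES.items()}
    proj = Projector(cfg.phantom.grid_size, cfg.geometry)
    osem_cfg = OSEMConfig(cfg.n_subsets, cfg.n_iterations)
    dr_cfg = DirectConfig(cfg.n_subsets, cfg.n_iterations)
    fit_w = frame_weights(schedule, cfg.weight_mode)

    maps: dict = {(m, lv): [] for m in cfg.methods for lv in cfg.count_levels}
    noise_dynamics: dict = {}   # level -> [replicate][iteration] dynamic images
    boundary_stacks = []        # subject-0 stacks at the boundary level

    for s, subject in enumerate(subjects):
        full = simulate_dynamic_counts(subject, cp, schedule, cfg.geometry,
                                       _child_seed(cfg.seed, "simulate", s))
        stacks_by_level = {}
        for level, n_rep in cfg.count_levels.items():
            if level == 1.0:
                stacks_by_level[level] = [full]
            else:
                reps = downsample_replicates(
                    full, level, _child_seed(cfg.seed, "downsample", s, level))
                stacks_by_level[level] = reps.replicates[:n_rep]
        if s == 0 and cfg.boundary_level in stacks_by_level:
            boundary_stacks = stacks_by_level[cfg.boundary_level]
        for level, stacks in stacks_by_level.items():
            per_method = {m: [] for m in cfg.methods}
            for st in stacks:
                keep_dyn = (s == 0)
                if "IR" in cfg.methods:
                    res = IndirectReconstruction(
                        st, basis, osem_cfg, cfg.weight_mode, projector=proj
                    ).fit(keep_dynamic=keep_dyn)
                    per_method["IR"].append(res.parametric)
                    if keep_dyn and level != 1.0:
                        noise_dynamics.setdefault(level, []).append(res.dynamic)
                if "DR" in cfg.methods:
                    per_method["DR"].append(
                        DirectReconstruction(st, basis, dr_cfg, projector=proj)
                        .fit().parametric)
            for m in cfg.methods:
                maps[(m, level)].append(per_method[m])

    # frozen %CV reference denominators: IR (fall back to first method) at
    # full counts, iteration 2, group-averaged ROI means
    ref_method = "IR" if "IR" in cfg.methods else cfg.methods[0]
    ref_iter = min(2, cfg.n_iterations) - 1
    reference = {p: {} for p in PARAMS}
    for roi, mask in roi_masks.items():
        for p in PARAMS:
            vals = [getattr(maps[(ref_method, 1.0)][s][0][ref_iter], p).ravel()[mask].mean()
                    for s in range(len(subjects))]
            reference[p][roi] = float(np.mean(vals))
    roi_set = ROISet({r: m.copy() for r, m in roi_masks.items()}, reference)

    variability = _variability_table(cfg, maps, roi_set)
    bias_df, bias_summary = _bias_analysis(cfg, maps, noise_dynamics, roi_set,
                                           cp, schedule, basis, roi_masks)
    boundary = _boundary_diagnostic(cfg, maps, noise_dynamics, boundary_stacks,
                                    cp, schedule, basis, roi_masks, proj, fit_w)
    power = _power_analysis(cfg, maps, roi_set, roi_masks)

    results = ExperimentResults(cfg, roi_set, variability, bias_df, bias_summary,
                                boundary, power, maps, subjects, basis)
    if out_dir is not None:
        _write_outputs(results, Path(out_dir), labels)
    return results


def _param_ensemble(maps, method, level, it, param) -> ParametricEnsemble:
    per_subj = maps[(method, level)]
    # theta[j, r, s]
    th = np.stack([
        np.stack([getattr(rep[it], param).ravel() for rep in reps], axis=-1)
        for reps in per_subj], axis=-1)
    return ParametricEnsemble(th)


def _variability_table(cfg, maps, roi_set) -> pd.DataFrame:
    rows = []
    for method in cfg.methods:
        for level in cfg.count_levels:
            n_rep = len(maps[(method, level)][0])
            for it in range(cfg.n_iterations):
                for p in PARAMS:
                    ens = _param_ensemble(maps, method, level, it, p)
                    blocks = []
                    if n_rep >= 2:
                        m_j, s_j = within_subject_stats(ens)
                        df = roi_voxelwise_cv(m_j, s_j, roi_set, p)
                        df["kind"] = "within"
                        blocks.append(df)
                        dfl = roi_level_stats(ens, roi_set, p, kind="within")
                        dfl["kind"] = "within"
                        blocks.append(dfl)
                    if ens.n_subjects >= 2:
                        m_j, s_j = between_subject_stats(ens)
                        df = roi_voxelwise_cv(m_j, s_j, roi_set, p)
                        df["kind"] = "between"
                        blocks.append(df)
                        dfl = roi_level_stats(ens, roi_set, p, kind="between")
                        dfl["kind"] = "between"
                        blocks.append(dfl)
                    for df in blocks:
                        df["parameter"] = p
                        df["method"] = method
                        df["count_level"] = level
                        df["iteration"] = it + 1
                        rows.append(df)
    wide = pd.concat(rows, ignore_index=True)
    tidy = wide.melt(
        id_vars=["parameter", "method", "count_level", "iteration", "roi",
                 "mode", "kind"],
        value_vars=["mean", "sd", "cv_pct"], var_name="metric", value_name="value")
    tidy["metric"] = tidy["kind"] + "_" + tidy["metric"]
    return tidy.drop(columns="kind")


def _bias_analysis(cfg, maps, noise_dynamics, roi_set, cp, schedule, basis,
                   roi_masks):
    need = [lv for lv in (0.2, 0.1) if lv in noise_dynamics
            and len(noise_dynamics[lv]) >= 2]
    if set(need) != {0.2, 0.1} or "IR" not in cfg.methods:
        return None, None
    ref_params = {roi: (roi_set.reference_means["K1"][roi],
                        roi_set.reference_means["K1"][roi] /
                        roi_set.reference_means["VT"][roi],
                        roi_set.reference_means["VT"][roi])
                  for roi in roi_masks}
    frames = []
    for it in range(cfg.n_iterations):
        noise = {lv: estimate_frame_noise(
            [dyn[it] for dyn in noise_dynamics[lv]], roi_masks)
            for lv in (0.2, 0.1) if lv in noise_dynamics}
        if 0.05 in noise_dynamics and len(noise_dynamics[0.05]) >= 2:
            noise[0.05] = estimate_frame_noise(
                [dyn[it] for dyn in noise_dynamics[0.05]], roi_masks)
        noise[1.0] = full_count_noise(noise[0.2], noise[0.1])
        for lv in cfg.bias_levels:
            if lv not in noise:
                continue
            df = simulate_bias(ref_params, cp, schedule, noise[lv], basis,
                               seed=_child_seed(cfg.seed, "bias", it, lv),
                               n_realizations=cfg.bias_realizations)
            df["count_level"] = lv
            df["iteration"] = it + 1
            frames.append(df)
    bias_df = pd.concat(frames, ignore_index=True)
    summary = (bias_df.groupby(["count_level", "iteration"])
               .apply(lambda g: bias_table(g, GM_REGIONS), include_groups=False)
               .reset_index())
    return bias_df, summary


def _boundary_diagnostic(cfg, maps, noise_dynamics, boundary_stacks, cp,
                         schedule, basis, roi_masks, proj, fit_w):
    """Refit noisy maps with the default vs extended (lower k2_min) basis."""
    level = cfg.boundary_level
    if level not in cfg.count_levels or not boundary_stacks or \
            level not in noise_dynamics:
        return None
    alt_basis = make_basis_set(cp, schedule, cfg.n_bases, cfg.alt_k2_min,
                               cfg.k2_max)
    roi = np.asarray(roi_masks[cfg.boundary_roi])
    it = min(2, cfg.n_iterations) - 1
    rows = []
    if "IR" in cfg.methods:
        for tag, bs in (("default", basis), ("extended", alt_basis)):
            hits, vts = [], []
            for dyn in noise_dynamics[level]:
                pimg = fit_parametric_image(dyn[it], bs, weights=fit_w)
                hits.append(boundary_hit_fraction(pimg, roi.reshape(pimg.shape)))
                vts.append(pimg.VT.ravel()[roi].mean())
            rows.append({"method": "IR", "basis": tag,
                         "k2_min": bs.k2_min,
                         "boundary_hit_pct": float(np.mean(hits)),
                         "mean_vt": float(np.mean(vts))})
    if "DR" in cfg.methods:
        dr_cfg = DirectConfig(cfg.n_subsets, cfg.n_iterations)
        for tag, bs in (("default", basis), ("extended", alt_basis)):
            hits, vts = [], []
            for st in boundary_stacks:
                pimg = DirectReconstruction(st, bs, dr_cfg, projector=proj)\
                    .fit().parametric[it]
                hits.append(boundary_hit_fraction(pimg, roi.reshape(pimg.shape)))
                vts.append(pimg.VT.ravel()[roi].mean())
            rows.append({"method": "DR", "basis": tag,
                         "k2_min": bs.k2_min,
                         "boundary_hit_pct": float(np.mean(hits)),
                         "mean_vt": float(np.mean(vts))})
    df = pd.DataFrame(rows)
    df["count_level"] = level
    df["iteration"] = it + 1
    df["roi"] = cfg.boundary_roi
    return df


def _power_analysis(cfg, maps, roi_set, roi_masks):
    """Paper-style two-group design: literature healthy-control VT mean vs
    the synthetic (patient-like) group's mean, with the group SD set to the
    between-subject voxel SD of the target ROI, per method and count level."""
    roi = np.asarray(roi_masks[cfg.power_roi])
    it = min(2, cfg.n_iterations) - 1
    rows = []
    for method in cfg.methods:
        for level in cfg.count_levels:
            ens = _param_ensemble(maps, method, level, it, "VT")
            if ens.n_subjects < 2:
                continue
            m_j, s_j = between_subject_stats(ens)
            mean_pd = float(m_j[roi].mean())
            sd_pd = float(s_j[roi].mean())
            if sd_pd <= 0 or mean_pd == cfg.healthy_mean_vt:
                continue
            n, achieved = two_sample_t_sample_size(
                PowerSpec(cfg.healthy_mean_vt, mean_pd, sd_pd))
            rows.append({"method": method, "count_level": level,
                         "iteration": it + 1, "roi": cfg.power_roi,
                         "mean_hc": cfg.healthy_mean_vt, "mean_pd": mean_pd,
                         "sd": sd_pd, "n_per_group": n,
                         "achieved_power": achieved})
    return pd.DataFrame(rows) if rows else None


def _write_outputs(results: ExperimentResults, out_dir: Path, labels):
    from . import io as pio

    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = results.config
    files = []
    files.append(pio.write_labels(out_dir / "region_labels.nii.gz", labels,
                                  cfg.phantom.voxel_size_mm))
    for s, subj in enumerate(results.subjects):
        for p in PARAMS:
            files.append(pio.write_image(
                out_dir / f"truth_sub{s:02d}_{p}.nii.gz", getattr(subj, p),
                cfg.phantom.voxel_size_mm))
    for (method, level), per_subj in results.maps.items():
        pimg = per_subj[0][0][-1]
        for p in PARAMS:
            files.append(pio.write_image(
                out_dir / f"{method}_lvl{int(100 * level):03d}_sub00_rep00_"
                          f"iter{len(per_subj[0][0])}_{p}.nii.gz",
                getattr(pimg, p), cfg.phantom.voxel_size_mm))
    tables = {"variability.csv": results.variability,
              "bias.csv": results.bias, "bias_summary.csv": results.bias_summary,
              "boundary.csv": results.boundary, "power.csv": results.power}
    for name, df in tables.items():
        if df is not None:
            path = out_dir / name
            df.to_csv(path, index=False, float_format="%.10g")
            files.append(path)
    echo = out_dir / "config.json"
    echo.write_text(json.dumps(_config_dict(cfg), indent=2, default=str))
    files.append(echo)
    pio.write_manifest(out_dir, files, extra={"seed": cfg.seed})


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    d["count_levels"] = {str(k): v for k, v in cfg.count_levels.items()}
    return d
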