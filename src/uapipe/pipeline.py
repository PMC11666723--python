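"""End-to-end orchestration of the synthetic multimodal analysis.

``run_pipeline`` executes the stages in dependency order (synthesis ->
feature extraction -> decision-model fits -> decoding -> PLS -> group
statistics) on a config-declared cohort, writing tidy tables, a summary
JSON (with provenance: config hash and seeds) and a log into the run
directory.  Rerunning with the same config yields byte-identical
summaries.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import child_rng
from .ddm import fit_ddm, trials_to_frame
from .decoding import condition_decoding_curves, pseudo_trial_decode
from .eeg_features import (aperiodic_fit, cpp_slope, morlet_power,
                           sample_entropy_timeresolved, spectral_psd)
from .errors import ConfigurationError, DependencyError
from .group_stats import linear_load_slope, slope_group_tests
from .pls import DataMatrix, behavioral_pls, bootstrap_bsr, permutation_test
from .pupil import derivative_signature, preprocess_pupil
from .task_synth import (EffectConfig, FRONTOCENTRAL, POSTERIOR, StimulusConfig,
                         generate_session_design, simulate_behavior, simulate_bold,
                         simulate_eeg, simulate_pupil)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("synth", "ddm", "eeg", "pupil", "decode", "pls", "stats")

_STAGE_DEPS = {
    "synth": (),
    "ddm": ("synth",),
    "eeg": ("synth",),
    "pupil": ("synth",),
    "decode": ("synth",),
    "pls": ("synth", "ddm", "eeg", "pupil"),
    "stats": ("ddm", "eeg", "pupil"),
}

logger = logging.getLogger("uapipe.pipeline")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: dict[str, int] = field(default_factory=lambda: {"young": 4, "old": 4})
    n_runs: int = 1
    behavior_n_runs: int = 4   # the decision-model fit gets a full-size session
    blocks_per_run: int = 8
    trials_per_block: int = 8
    eeg_srate: float = 250.0
    pupil_srate: float = 500.0
    n_voxels: int = 100
    decode_n_boot: int = 20
    ddm_variant: str = "full"
    pls_n_perm: int = 200
    pls_n_boot: int = 200
    entropy_channels: tuple[str, ...] = ("POz", "Oz")
    entropy_window_range: tuple[float, float] = (0.5, 2.5)
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    stimulus: StimulusConfig = field(default_factory=StimulusConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages in config: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        from .io import load_effect_config  # local import to avoid cycles

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "stimulus" in raw:
            raw["stimulus"] = StimulusConfig(**raw["stimulus"])
        if "effects" in raw:
            tmp = Path(path).with_suffix(".effects.tmp.yaml")
            tmp.write_text(yaml.safe_dump(raw["effects"]))
            try:
                raw["effects"] = load_effect_config(tmp)
            finally:
                tmp.unlink(missing_ok=True)
        for key in ("entropy_channels", "entropy_window_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _require(done: set[str], stage: str) -> None:
    missing = [d for d in _STAGE_DEPS[stage] if d not in done]
    if missing:
        raise DependencyError(
            f"stage {stage!r} requires upstream stage(s) {missing}; "
            "enable them or provide their artifacts")


def _subject_ids(cfg: PipelineConfig) -> list[tuple[str, str, int]]:
    """(subject_id, group, subject_seed_key) triples, deterministic order."""
    out = []
    i = 0
    for group in sorted(cfg.n_subjects):
        for k in range(cfg.n_subjects[group]):
            out.append((f"sub-{i + 1:02d}", group, i))
            i += 1
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all enabled stages; returns the summary dict (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    cfg = config
    subjects = _subject_ids(cfg)
    done: set[str] = set()
    summary: dict = {
        "provenance": {
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "version": __version__,
            "n_subjects": dict(sorted(cfg.n_subjects.items())),
        },
        "signatures": {},
    }

    try:
        # ------------------------------------------------------------------ synth
        designs, behaviors, ddm_behaviors, eegs, pupils, bolds = {}, {}, {}, {}, {}, {}
        if cfg.stages["synth"]:
            logger.info("stage synth: %d subjects", len(subjects))
            rng = child_rng(cfg.seed, "design", 999)
            subj_gain = {}
            for sid, group, k in subjects:
                sseed = cfg.seed * 10_000 + k
                designs[sid] = generate_session_design(
                    cfg.stimulus, cfg.n_runs, cfg.blocks_per_run,
                    cfg.trials_per_block, seed=sseed)
                behaviors[sid] = simulate_behavior(
                    designs[sid], cfg.effects, seed=sseed, group=group, subject=sid)
                ddm_design = generate_session_design(
                    cfg.stimulus, cfg.behavior_n_runs, cfg.blocks_per_run,
                    cfg.trials_per_block, seed=sseed + 1_000_000)
                ddm_behaviors[sid] = simulate_behavior(
                    ddm_design, cfg.effects, seed=sseed + 1_000_000,
                    group=group, subject=sid)
                eegs[sid] = simulate_eeg(designs[sid], cfg.effects,
                                         srate=cfg.eeg_srate, seed=sseed,
                                         group=group, trials=behaviors[sid])
                pupils[sid] = simulate_pupil(designs[sid], cfg.effects,
                                             srate=cfg.pupil_srate, seed=sseed,
                                             group=group)
                subj_gain[sid] = 1.0 + 0.3 * rng.standard_normal()
                bolds[sid] = simulate_bold(designs[sid], cfg.effects,
                                           n_voxels=cfg.n_voxels, seed=sseed,
                                           group=group,
                                           subject_loading=subj_gain[sid])
            pd.concat([trials_to_frame(ddm_behaviors[s]) for s, _, _ in subjects]
                      ).to_csv(out / "behavior.tsv", sep="\t", index=False)
            done.add("synth")

        sig_rows: list[dict] = []

        # ------------------------------------------------------------------ ddm
        if cfg.stages["ddm"]:
            _require(done, "ddm")
            logger.info("stage ddm")
            for sid, group, _ in subjects:
                fit = fit_ddm(ddm_behaviors[sid], variant=cfg.ddm_variant)
                if not fit.converged:
                    logger.warning("ddm fit did not converge for %s", sid)
                for load, p in fit.params.items():
                    sig_rows.append({"subject": sid, "group": group, "load": load,
                                     "signature": "drift", "value": p.v})
            done.add("ddm")

        # ------------------------------------------------------------------ eeg
        if cfg.stages["eeg"]:
            _require(done, "eeg")
            logger.info("stage eeg")
            for sid, group, _ in subjects:
                stim = eegs[sid]["stimulus"]
                resp = eegs[sid]["response"]
                loads = stim.trial_info["load"].to_numpy()
                stim_win = (stim.times >= 0.25) & (stim.times <= 2.75)
                for load in (1, 2, 3, 4):
                    sel = loads == load
                    sub = _subset_epochs(stim, sel)
                    # theta / alpha band power (log10 single-trial, then mean)
                    for name, band, chans in (
                            ("theta", (4.0, 6.0), FRONTOCENTRAL),
                            ("alpha", (8.0, 12.0), POSTERIOR)):
                        tf = morlet_power(sub, np.arange(band[0], band[1] + 0.5, 1.0),
                                          step=0.1)
                        tsel = (tf.times >= 0.25) & (tf.times <= 2.75)
                        idx = [sub.channels.index(c) for c in chans]
                        sig_rows.append({"subject": sid, "group": group, "load": load,
                                         "signature": name,
                                         "value": float(tf.power[idx][:, :, tsel].mean())})
                    # aperiodic exponent over the final 2.5 s of the stimulus
                    psel = (sub.times >= 0.5) & (sub.times <= 3.0)
                    pidx = [sub.channels.index(c) for c in POSTERIOR]
                    freqs, psd = spectral_psd(
                        np.moveaxis(sub.data[pidx][:, psel, :], 1, -1), sub.srate)
                    fitres = aperiodic_fit(freqs, psd)
                    sig_rows.append({"subject": sid, "group": group, "load": load,
                                     "signature": "exponent", "value": fitres.exponent})
                    # sample entropy during the stimulus
                    ent = sample_entropy_timeresolved(
                        sub, channels=cfg.entropy_channels,
                        t_range=cfg.entropy_window_range, step=0.5)
                    sig_rows.append({"subject": sid, "group": group, "load": load,
                                     "signature": "entropy",
                                     "value": float(np.nanmean(ent.entropy))})
                    # pre-response ramp slope
                    rsub = _subset_epochs(resp, sel)
                    est = cpp_slope(rsub)
                    sig_rows.append({"subject": sid, "group": group, "load": load,
                                     "signature": "cpp_slope", "value": est.value})
            done.add("eeg")

        # ------------------------------------------------------------------ pupil
        if cfg.stages["pupil"]:
            _require(done, "pupil")
            logger.info("stage pupil")
            for sid, group, _ in subjects:
                loads = np.array([t.load for t in designs[sid].trials])
                per_load: dict[int, list[float]] = {l: [] for l in (1, 2, 3, 4)}
                for trace, load in zip(pupils[sid], loads):
                    try:
                        clean = preprocess_pupil(trace)
                    except ConfigurationError as exc:
                        logger.warning("pupil trace rejected (%s): %s", sid, exc)
                        continue
                    deriv = derivative_signature(clean)
                    tsel = (deriv.times >= 0.0) & (deriv.times <= 3.0)
                    val = float(np.nanmean(np.where(deriv.missing, np.nan,
                                                    deriv.samples)[tsel]))
                    if np.isfinite(val):
                        per_load[int(load)].append(val)
                for load, vals in per_load.items():
                    if vals:
                        sig_rows.append({"subject": sid, "group": group, "load": load,
                                         "signature": "pupil", "value": float(np.mean(vals))})
            done.add("pupil")

        # ------------------------------------------------------------------ decode
        if cfg.stages["decode"]:
            _require(done, "decode")
            logger.info("stage decode")
            rows = []
            for sid, group, k in subjects:
                bold = bolds[sid]
                active = bold.patterns[:, :, 6:12].mean(axis=2)
                info = bold.trial_info
                cued = info["cue_set"].str.contains("color").to_numpy()
                labels = info["dominant_color"].to_numpy()
                res = pseudo_trial_decode(active[cued], labels[cued],
                                          n_boot=cfg.decode_n_boot,
                                          seed=cfg.seed * 10_000 + k)
                curves = condition_decoding_curves(res, info.loc[cued, "load"].to_numpy())
                for load, c in curves["conditions"].items():
                    rows.append({"subject": sid, "group": group, "load": int(load),
                                 "accuracy": float(c["mean"][0])})
            dec = pd.DataFrame(rows)
            dec.to_csv(out / "decoding.tsv", sep="\t", index=False)
            acc_slopes = linear_load_slope(dec.rename(columns={"accuracy": "value"}))
            summary["decoding"] = {
                "mean_accuracy": round(float(dec["accuracy"].mean()), 6),
                "load_slope_mean": round(float(acc_slopes["beta"].mean()), 6),
            }
            done.add("decode")

        # ------------------------------------------------------------------ assemble signature table
        sig_table = pd.DataFrame(sig_rows)
        if len(sig_table):
            sig_table.to_csv(out / "signatures.tsv", sep="\t", index=False)

        # ------------------------------------------------------------------ pls
        if cfg.stages["pls"]:
            _require(done, "pls")
            logger.info("stage pls")
            mods, meta = [], []
            voxel_slopes = []
            for sid, group, _ in subjects:
                sub = sig_table[sig_table["subject"] == sid]
                row = []
                for name in ("drift", "theta", "alpha", "entropy", "exponent",
                             "pupil", "cpp_slope"):
                    vals = sub[sub["signature"] == name].sort_values("load")
                    row.append(float(np.polyfit(vals["load"], vals["value"], 1)[0])
                               if len(vals) >= 2 else np.nan)
                mods.append(row)
                meta.append((sid, group))
                loads = np.arange(1, 5)
                voxel_slopes.append(np.polyfit(loads, bolds[sid].betas.T, 1)[0])
            behavior = np.asarray(mods)
            keep_cols = ~np.isnan(behavior).any(axis=0)
            behavior = behavior[:, keep_cols]
            names = [n for n, k in zip(("drift", "theta", "alpha", "entropy",
                                        "exponent", "pupil", "cpp_slope"), keep_cols) if k]
            neural = DataMatrix(values=np.asarray(voxel_slopes),
                                subjects=np.array([m[0] for m in meta]),
                                groups=np.array([m[1] for m in meta]))
            model = behavioral_pls(neural, behavior, behavior_names=names)
            p = permutation_test(model, n_perm=cfg.pls_n_perm, seed=cfg.seed)
            bsr = bootstrap_bsr(model, n_boot=cfg.pls_n_boot, seed=cfg.seed)
            summary["pls"] = {
                "first_lv_p": round(float(p[0]), 6),
                "first_lv_singular_value": round(float(model.S[0]), 6),
                "n_reliable_voxels": int((np.abs(bsr[:, 0]) >= 3.0).sum()),
                "behavior_names": names,
                "behavior_saliences_lv1": [round(float(x), 6) for x in model.U[:, 0]],
            }
            done.add("pls")

        # ------------------------------------------------------------------ stats
        if cfg.stages["stats"]:
            _require(done, "stats")
            logger.info("stage stats")
            for name, sub in sig_table.groupby("signature"):
                slopes = linear_load_slope(sub.rename(columns={"value": "value"}))
                tests = slope_group_tests(slopes)
                group_means = {g: round(v["mean"], 6)
                               for g, v in tests["within"].items()}
                entry = {"load_slope_by_group": group_means}
                if tests["between"] is not None and {"young", "old"} <= set(group_means):
                    diff = group_means["young"] - group_means["old"]
                    entry["between_t"] = round(tests["between"]["t"], 6)
                    entry["between_p"] = round(tests["between"]["p"], 6)
                    entry["young_minus_old_slope"] = round(diff, 6)
                    entry["old_dampened"] = bool(abs(group_means["old"])
                                                 < abs(group_means["young"]))
                summary["signatures"][name] = entry
            done.add("stats")

    finally:
        logger.removeHandler(handler)
        handler.close()

    summary["stages_run"] = sorted(done)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
    _write_figure(sig_table if cfg.stages["stats"] and len(sig_rows) else None, out)
    return summary


def _subset_epochs(epochs, sel: np.ndarray):
    from .task_synth import EpochedSignal

    return EpochedSignal(
        data=epochs.data[:, :, sel], srate=epochs.srate, times=epochs.times,
        alignment=epochs.alignment, channels=epochs.channels,
        neighbors=epochs.neighbors,
        trial_info=epochs.trial_info.loc[sel].reset_index(drop=True)
        if epochs.trial_info is not None else None)


def _write_figure(sig_table, out: Path) -> None:
    if sig_table is None or not len(sig_table):
        return
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - matplotlib is expected but optional
        return
    sigs = sorted(sig_table["signature"].unique())
    fig, axes = plt.subplots(1, len(sigs), figsize=(3 * len(sigs), 3), squeeze=False)
    for ax, name in zip(axes[0], sigs):
        sub = sig_table[sig_table["signature"] == name]
        for group, g in sub.groupby("group"):
            m = g.groupby("load")["value"].mean()
            ax.plot(m.index, m.values, marker="o", label=group)
        ax.set_title(name)
        ax.set_xlabel("load")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(out / "signatures.png", dpi=100)
    plt.close(fig)
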