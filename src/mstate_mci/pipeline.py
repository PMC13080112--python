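"""End-to-end orchestration: synth -> preprocess -> microstate -> features ->
stats -> select/classify, with a manifest for reproducibility.

The pipeline streams subjects through synthesis and preprocessing (raw
multichannel EEG is never held for the whole cohort at once; preprocessed
epochs are kept in float32), fits one pooled microstate model per paradigm
across all subjects, backfits, extracts the 26 features per augmented
segment, screens them, and evaluates the four run configurations (rest,
task, fused, fused + MoCA) under the repeated grouped CV protocol.  Derived
artifacts -- the model, feature tables, screening tables, CV report and a
manifest with content hashes and seeds -- are written to the output
directory so the stats and classification stages can be re-run from files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .features import extract_all
from .group_stats import screen_features
from .microstate import backfit, fit_microstates, model_gev, peak_maps
from .preprocess import PreprocessConfig, preprocess_rest, preprocess_task
from .select_classify import CVConfig, CVReport, fuse, wrapper_ofs
from .synth import GroupSpec, make_cohort
from .containers import EpochSet

__all__ = ["RunConfig", "run_pipeline", "summarize"]


@dataclass
class RunConfig:
    """Everything a full run needs; YAML-serialisable."""

    seed: int = 0
    out_dir: str = "mstate_out"
    n_hc: int = 31
    n_mci: int = 32
    snr: float = 5.0
    fs: float = 250.0
    rest_duration_s: float = 200.0
    n_incongruent: int = 150
    n_congruent: int = 150
    paradigms: tuple[str, ...] = ("rest", "task")
    k: int = 4
    n_restarts: int = 20
    peaks_per_segment: int = 100
    include_moca: bool = True
    paper_mode: bool = False  # screen on the full data instead of per fold
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    n_folds: int = 5
    n_repeats: int = 5
    inner_folds: int = 5
    f_max: int = 5
    f_curve_max: int = 10

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        pre = d.pop("preprocess", {})
        cfg = cls(**d)
        if pre:
            cfg.preprocess = PreprocessConfig(**pre)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["paradigms"] = list(self.paradigms)
        d["preprocess"] = asdict(self.preprocess)
        d["preprocess"]["task_window_ms"] = list(self.preprocess.task_window_ms)
        d["preprocess"]["baseline_ms"] = list(self.preprocess.baseline_ms)
        return d

    def cv_config(self, seed: int) -> CVConfig:
        return CVConfig(
            n_folds=self.n_folds,
            n_repeats=self.n_repeats,
            inner_folds=self.inner_folds,
            f_max=self.f_max,
            f_curve_max=self.f_curve_max,
            in_fold_screening=not self.paper_mode,
            seed=seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _epoch_features(
    data: np.ndarray, fs: float, channel_names, model, prefix: str
) -> dict[str, float]:
    """Backfit one epoch and compute its 26 features."""
    rec_like = np.asarray(data, dtype=float)
    labels, _ = backfit(rec_like, model)
    eset = EpochSet(
        data=rec_like[None], fs=fs, channel_names=list(channel_names)
    )
    maps, gfps = peak_maps(eset)
    gev = model_gev(maps, gfps, model) if maps.shape[0] else float("nan")
    return extract_all(labels, fs, gev=gev, prefix=prefix)


def run_pipeline(
    cfg: RunConfig,
    hc_specs: dict[str, GroupSpec] | None = None,
    mci_specs: dict[str, GroupSpec] | None = None,
) -> dict:
    """Run all stages; returns models, tables, reports and diagnostics.

    ``hc_specs``/``mci_specs`` override the default generator conditions
    (mapping paradigm -> :class:`GroupSpec`); group sizes and SNR from the
    config apply only to the defaults.
    """
    out = Path(cfg.out_dir)
    for sub in ("models", "features", "stats", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    # ---- synth -----------------------------------------------------------
    if hc_specs is None and mci_specs is None:
        from .synth import default_group_specs

        specs = default_group_specs(n_hc=cfg.n_hc, n_mci=cfg.n_mci, snr=cfg.snr)
        hc_specs = {p: specs[("HC", p)] for p in ("rest", "task")}
        mci_specs = {p: specs[("MCI", p)] for p in ("rest", "task")}
    cohort = make_cohort(
        hc=hc_specs,
        mci=mci_specs,
        paradigms=cfg.paradigms,
        seed=cfg.seed,
        rest_duration_s=cfg.rest_duration_s,
        n_incongruent=cfg.n_incongruent,
        n_congruent=cfg.n_congruent,
        fs=cfg.fs,
    )
    moca = cohort.moca_table()
    moca.to_csv(out / "moca.csv", index=False)
    timings["synth"] = time.perf_counter() - t0

    # ---- preprocess (streamed per subject) ------------------------------
    t1 = time.perf_counter()
    root = np.random.SeedSequence(cfg.seed + 7)
    subj_seeds = root.spawn(cohort.n_subjects)
    store: dict[str, dict[str, np.ndarray]] = {}
    meta: dict[str, dict] = {}
    for i, (subj, rest, task, events) in enumerate(cohort.iter_recordings()):
        entry = {}
        if rest is not None:
            entry["rest"] = preprocess_rest(rest, cfg.preprocess).data.astype(
                np.float32
            )
        if task is not None:
            block_seed = int(subj_seeds[i].generate_state(1)[0] % 2**31)
            entry["task"] = preprocess_task(
                task, events, cfg.preprocess, seed=block_seed
            ).data.astype(np.float32)
        store[subj.subject_id] = entry
        meta[subj.subject_id] = {"group": subj.group, "moca": subj.moca}
    channel_names = list(cohort.montage.channel_names)
    fs = cfg.preprocess.target_fs_hz
    timings["preprocess"] = time.perf_counter() - t1

    # ---- microstate models (pooled across subjects, per paradigm) -------
    t2 = time.perf_counter()
    models = {}
    for paradigm in cfg.paradigms:
        maps_all, _ = _pooled_peaks(store, paradigm, fs, channel_names, cfg)
        model = fit_microstates(
            maps_all,
            k=cfg.k,
            n_restarts=cfg.n_restarts,
            seed=np.random.default_rng(cfg.seed + 13),
            positions=cohort.montage.positions,
            channel_names=channel_names,
        )
        models[paradigm] = model
        mio.model_to_json(model, out / "models" / f"model_{paradigm}.json")
    timings["microstate"] = time.perf_counter() - t2

    # ---- features --------------------------------------------------------
    t3 = time.perf_counter()
    tables = {}
    for paradigm in cfg.paradigms:
        prefix = "r" if paradigm == "rest" else "t"
        rows = []
        for sid, entry in store.items():
            if paradigm not in entry:
                continue
            for seg, ep in enumerate(entry[paradigm]):
                feats = _epoch_features(
                    ep, fs, channel_names, models[paradigm], prefix
                )
                rows.append(
                    {
                        "subject_id": sid,
                        "segment_id": seg,
                        "group": meta[sid]["group"],
                        **feats,
                    }
                )
        tables[paradigm] = pd.DataFrame(rows)
        mio.save_feature_table(
            tables[paradigm], out / "features" / f"features_{paradigm}.csv"
        )
    timings["features"] = time.perf_counter() - t3

    # ---- stats (full-data reporting tables) ------------------------------
    t4 = time.perf_counter()
    screening = {}
    for paradigm in cfg.paradigms:
        res = screen_features(tables[paradigm])
        screening[paradigm] = res
        res.results.to_csv(out / "stats" / f"stats_{paradigm}.csv", index=False)
    timings["stats"] = time.perf_counter() - t4

    # ---- recovery diagnostics -------------------------------------------
    recovery = {}
    gt = cohort.ground_truth.templates  # canonical A-D order, unit norm, CAR
    for paradigm, model in models.items():
        corr = np.abs(np.sum(model.templates * gt, axis=1))
        recovery[paradigm] = {
            "per_class_abs_corr": corr.tolist(),
            "min_abs_corr": float(corr.min()),
        }

    # ---- classification --------------------------------------------------
    t5 = time.perf_counter()
    reports: dict[str, CVReport] = {}
    cv_seed = cfg.seed + 29
    if "rest" in tables:
        reports["rest"] = wrapper_ofs(
            tables["rest"], cfg.cv_config(cv_seed), config_name="rest"
        )
    if "task" in tables:
        reports["task"] = wrapper_ofs(
            tables["task"], cfg.cv_config(cv_seed), config_name="task"
        )
    if "rest" in tables and "task" in tables:
        fused = fuse([tables["rest"], tables["task"]])
        reports["fused"] = wrapper_ofs(
            fused, cfg.cv_config(cv_seed), config_name="fused"
        )
        if cfg.include_moca:
            fused_m = fuse([tables["rest"], tables["task"]], moca=moca)
            reports["fused_moca"] = wrapper_ofs(
                fused_m,
                cfg.cv_config(cv_seed),
                config_name="fused_moca",
                include_moca=True,
            )
    timings["classify"] = time.perf_counter() - t5

    # ---- report + manifest ----------------------------------------------
    report = {
        "configurations": {k: r.to_dict() for k, r in reports.items()},
        "gev": {p: models[p].gev for p in models},
        "template_recovery": recovery,
        "screening_retained": {p: screening[p].retained for p in screening},
        "seed": cfg.seed,
    }
    (out / "report" / "report.json").write_text(json.dumps(report, indent=1))
    for name, r in reports.items():
        r.curve.to_csv(out / "report" / f"curve_{name}.csv", index=False)
    (out / "report" / "summary.md").write_text(summarize(report))

    artifacts = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {
        "cohort": cohort,
        "models": models,
        "tables": tables,
        "screening": screening,
        "reports": reports,
        "recovery": recovery,
        "report": report,
        "manifest": manifest,
    }


def _pooled_peaks(store, paradigm, fs, channel_names, cfg) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(cfg.seed + 17)
    maps_list, gfp_list = [], []
    for sid in sorted(store):
        entry = store[sid]
        if paradigm not in entry:
            continue
        eset = EpochSet(
            data=np.asarray(entry[paradigm], dtype=float),
            fs=fs,
            channel_names=channel_names,
            subject_id=sid,
        )
        maps, gfps = peak_maps(
            eset, max_per_epoch=cfg.peaks_per_segment, seed=rng
        )
        maps_list.append(maps)
        gfp_list.append(gfps)
    return np.concatenate(maps_list, axis=0), np.concatenate(gfp_list)


def summarize(report: dict) -> str:
    """Render a run report as human-readable markdown tables."""
    lines = ["# Classification summary", ""]
    lines.append(
        "| Configuration | Accuracy (mean ± SD) | Sensitivity | Specificity | OFS |"
    )
    lines.append("|---|---|---|---|---|")
    configs = report.get("configurations", {})
    if not configs:
        lines.append("| (no configurations evaluated) | – | – | – | – |")
    for name, r in configs.items():
        m = r["ofs_metrics"]
        ofs = ", ".join(r["ofs"]) if r["ofs"] else "(empty — warning)"
        lines.append(
            f"| {name} | {m['accuracy']:.1f} ± {m['accuracy_sd']:.1f}% "
            f"| {m['sensitivity']:.1f} ± {m['sensitivity_sd']:.1f}% "
            f"| {m['specificity']:.1f} ± {m['specificity_sd']:.1f}% "
            f"| {ofs} |"
        )
    lines.append("")
    if "gev" in report:
        for p, g in report["gev"].items():
            lines.append(f"- model GEV ({p}): {g:.3f}")
    if "template_recovery" in report:
        for p, r in report["template_recovery"].items():
            lines.append(
                f"- template recovery ({p}): min |corr| = {r['min_abs_corr']:.3f}"
            )
    lines.append("")
    for name, r in configs.items():
        lines.append(f"## Accuracy vs number of features — {name}")
        lines.append("")
        lines.append("| F | accuracy | sensitivity | specificity |")
        lines.append("|---|---|---|---|")
        curve = r["curve"]
        for i, F in enumerate(curve["F"]):
            lines.append(
                f"| {F} | {curve['acc_mean'][i]:.1f} ± {curve['acc_sd'][i]:.1f} "
                f"| {curve['sens_mean'][i]:.1f} | {curve['spec_mean'][i]:.1f} |"
            )
        lines.append("")
    return "\n".join(lines)
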