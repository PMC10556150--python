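"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full analysis sequence — simulate (or
load) time courses, post-process, windowed connectivity, state
clustering, temporal metrics, group statistics, mediation, and
classification — writing every intermediate artifact plus a manifest
(parameters, seeds, per-file hashes). Deterministic stages are
bit-identical across reruns with the same config.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, dfnc, io, mediation, postproc, states, stats, synthetic, temporal
from .types import WindowSpec


@dataclass
class PipelineConfig:
    """Serializable run plan for every stage."""

    out_dir: str = "results"
    run_id: str = "run"
    seed: int = 0
    # simulate
    simulate: bool = True
    n_group_a: int = 20
    n_group_b: int = 20
    input_dir: str | None = None
    # postproc
    detrend_order: int | None = 1
    despike_z: float | None = 3.5
    lowpass_hz: float | None = 0.15
    # dfnc
    width_tr: int = 30
    step_tr: int = 1
    lam: float = dfnc.DEFAULT_LAMBDA
    # states
    k: int | None = 4
    k_range: tuple[int, int] = (2, 8)
    k_method: str = "elbow"
    n_init: int = 5
    # stats
    fdr_q: float = 0.05
    # mediation
    mediator: str = "dwell_s1"
    outcome: str = "moca"
    n_boot: int = 5000
    # classification
    classify_mode: str = "fold_safe"
    folds: int = 10
    repeats: int = 100
    svm_c: float = 1.0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        cfg = cls(**payload)
        cfg.k_range = tuple(cfg.k_range)
        return cfg

    def to_file(self, path) -> None:
        payload = asdict(self)
        payload["k_range"] = list(self.k_range)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the results directory."""
    out = Path(config.out_dir) / config.run_id
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.yaml")
    manifest: dict = {"config": asdict(config), "stages": {}}
    manifest["config"]["k_range"] = list(config.k_range)

    def record(stage: str, *paths: Path):
        manifest["stages"].setdefault(stage, {})
        for p in paths:
            manifest["stages"][stage][p.name] = _sha256(p)

    # --- stage: simulate or load -------------------------------------
    if config.simulate:
        spec = synthetic.SyntheticSpec(
            n_group_a=config.n_group_a, n_group_b=config.n_group_b,
            seed=config.seed,
        )
        cohort = synthetic.make_cohort(
            spec, WindowSpec(config.width_tr, config.step_tr)
        )
        tcs = cohort.timecourses
        clinical = cohort.clinical
        tc_dir = out / "timecourses"
        tc_dir.mkdir(exist_ok=True)
        written = []
        for tc in tcs:
            p = tc_dir / f"{tc.subject_id}.tsv"
            io.write_timecourses(tc, p)
            written.extend([p, Path(str(p) + ".json")])
        io.write_clinical(clinical, out / "clinical.tsv")
        gt_labels = {
            g.subject_id: g.window_labels(WindowSpec(config.width_tr, config.step_tr))
            for g in cohort.ground_truths
        }
        io.write_labels(gt_labels, out / "ground_truth_labels.tsv")
        io.write_json(spec.to_jsonable(), out / "synthetic_spec.json")
        record("simulate", out / "clinical.tsv", out / "ground_truth_labels.tsv",
               out / "synthetic_spec.json", *written)
        groups = {g.subject_id: g.group for g in cohort.ground_truths}
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when simulate is disabled")
        in_dir = Path(config.input_dir)
        tcs = [io.read_timecourses(p) for p in sorted(in_dir.glob("*.tsv"))
               if not p.name.endswith("clinical.tsv")]
        clinical = io.read_clinical(in_dir / "clinical.tsv")
        groups = dict(zip(clinical["subject_id"], clinical["group"]))

    # --- stage: postproc ---------------------------------------------
    proc = postproc.TimecoursePostProcessor(
        detrend_order=config.detrend_order,
        despike_z=config.despike_z,
        lowpass_hz=config.lowpass_hz,
    ).fit()
    tcs = proc.transform(tcs)

    # --- stage: dfnc --------------------------------------------------
    sw = dfnc.SlidingWindowConnectivity(
        width_tr=config.width_tr, step_tr=config.step_tr, lam=config.lam
    ).fit()
    series = sw.transform(tcs)
    fnc_dir = out / "windowed_fnc"
    fnc_dir.mkdir(exist_ok=True)
    written = []
    for s in series:
        p = fnc_dir / f"{s.subject_id}.tsv"
        io.write_windowed_fnc(s, p)
        written.extend([p, Path(str(p) + ".json")])
    record("dfnc", *written)

    # --- stage: cluster ------------------------------------------------
    exemplars, _ = states.select_exemplars(series)
    if config.k is None:
        k, diag = states.choose_k(
            exemplars, range(config.k_range[0], config.k_range[1] + 1),
            method=config.k_method, n_init=config.n_init, seed=config.seed,
        )
    else:
        k, diag = config.k, {}
    model = states.fit_states(series, k=k, n_init=config.n_init, seed=config.seed)
    io.write_centroids(model.centroids, out / "centroids.tsv")
    io.write_labels(model.labels, out / "state_labels.tsv")
    io.write_json(
        {"k": k, "inertia": model.inertia, "n_init": model.n_init,
         "seed": model.seed, "diagnostics": diag,
         "summary": states.state_summary(model).to_dict(orient="list")},
        out / "state_model.json",
    )
    record("cluster", out / "centroids.tsv", out / "state_labels.tsv",
           out / "state_model.json")

    # --- stage: metrics -------------------------------------------------
    profiles = temporal.profiles_table(model.labels, groups, n_states=k)
    profiles.to_csv(out / "temporal_metrics.tsv", sep="\t", index=False)
    record("metrics", out / "temporal_metrics.tsv")

    # --- stage: stats ----------------------------------------------------
    results = stats.run_group_analysis(
        profiles, clinical, n_states=k, fdr_q=config.fdr_q,
        correlation_states=tuple(s for s in (1, 4) if s <= k),
    )
    results.to_csv(out / "group_stats.tsv", sep="\t", index=False)
    blocks = stats.block_contrast_analysis(
        series, model.labels, groups,
        states=tuple(s for s in (1, 4) if s <= k), fdr_q=config.fdr_q,
    )
    blocks.to_csv(out / "block_stats.tsv", sep="\t", index=False)
    record("stats", out / "group_stats.tsv", out / "block_stats.tsv")

    # --- stage: mediate ---------------------------------------------------
    merged = profiles.merge(clinical.drop(columns=["group"], errors="ignore"),
                            on="subject_id")
    x = (merged["group"] == "CD").to_numpy(dtype=float)
    med = mediation.bootstrap_bca(
        x, merged[config.mediator].to_numpy(), merged[config.outcome].to_numpy(),
        n_boot=config.n_boot, seed=config.seed,
    )
    io.write_json(
        {k2: v for k2, v in asdict(med).items() if k2 != "boot_indirect"},
        out / "mediation.json",
    )
    record("mediate", out / "mediation.json")

    # --- stage: classify ---------------------------------------------------
    extractor = classify.CentroidRegressionFeatures(n_states=k).fit(
        series, model.labels, groups
    )
    feats = extractor.transform(series)
    feat_df = pd.DataFrame(
        feats, columns=[f"beta_{g}_s{s}" for g, s in extractor.design_.labels]
    )
    feat_df.insert(0, "subject_id", [s.subject_id for s in series])
    feat_df.to_csv(out / "features.tsv", sep="\t", index=False)
    cls = classify.evaluate_dfnc_classifier(
        series, groups, n_states=k, mode=config.classify_mode,
        state_labels=model.labels, folds=config.folds, repeats=config.repeats,
        svm_c=config.svm_c, seed=config.seed,
    )
    io.write_json(cls.to_jsonable(), out / "classification.json")
    np.savetxt(out / "roc_points.tsv",
               np.column_stack([cls.roc_fpr, cls.roc_tpr]),
               delimiter="\t", header="fpr\ttpr", comments="")
    record("classify", out / "classification.json", out / "roc_points.tsv")

    io.write_json(manifest, out / "manifest.json")
    return out
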