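"""End-to-end orchestration: simulate -> QC -> transfer -> PCA -> CNN -> merits.

A :class:`RunConfig` (strictly schema-checked; unknown keys rejected) drives
one reproducible run.  Every stage persists its artifact under the run
directory and contributes to a manifest recording the config hash, seed,
per-stage row counts and wall times; identical config and seed reproduce
identical manifest counts and pooled confusion matrix.

Stage order is fixed: synthetic data generation (or loading), per-spectrum
QC with T2/Q outlier exclusion on the full grid, truncation to the
fingerprint window, piecewise direct standardization of non-master batches
(fit on truncated raw absorbance from paired transfer samples), PCA
stratification on the fully preprocessed spectra, repeated-split CNN
classification (per-split preprocessing, no leakage) and merit reporting.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import run_classification
from .dataset import stack
from .evaluate import chord_export
from .io import read_dataset, write_dataset
from .preprocess import PreprocessParams, preprocess_pipeline, truncate
from .qc import QualityThresholds, apply_outlier_filter, qc_report
from .simulate import SimConfig, paired_transfer_set, preset
from .transfer import fit_pds
from .unsupervised import confidence_ellipse, fit_pca, mardia_test

__all__ = ["RunConfig", "run_pipeline"]


class PipelineError(ValueError):
    pass


def _strict(section: str, given: dict, allowed: set) -> dict:
    unknown = set(given) - allowed
    if unknown:
        raise PipelineError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}"
        )
    return given


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    preset: str = "human"
    separation: str = "moderate"
    seed: int = 0
    out_dir: str = "serofir_run"
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    qc_enabled: bool = True
    qc: dict = field(default_factory=dict)           # thresholds + chart settings
    transfer_enabled: bool = True
    transfer: dict = field(default_factory=dict)     # half_width, rank_tol, n_transfer_subjects
    preprocess: dict = field(default_factory=dict)   # PreprocessParams overrides
    pca: dict = field(default_factory=dict)          # n_components
    classify: dict = field(default_factory=dict)     # run_classification overrides

    def __post_init__(self) -> None:
        if self.preset not in ("human", "mouse"):
            raise PipelineError(f"unknown preset {self.preset!r}")
        _strict("sim", self.sim, {f.name for f in fields(SimConfig)} - {"bands"})
        _strict("qc", self.qc, {"absorbance_min", "absorbance_max", "snr_min",
                                "water_vapor_max", "variance_fraction", "alpha"})
        _strict("transfer", self.transfer,
                {"half_width", "rank_tol", "n_transfer_subjects"})
        _strict("preprocess", self.preprocess,
                {f.name for f in fields(PreprocessParams)} - {"msc_reference"})
        _strict("pca", self.pca, {"n_components"})
        _strict("classify", self.classify,
                {"ratios", "grouping", "n_repeats", "split_mode", "bayes_budget",
                 "batch_size", "max_epochs", "patience", "learning_rate",
                 "momentum", "l2", "section_depth", "filter_size", "n_filters",
                 "dense_units", "dropout_rate"})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        allowed = {f.name for f in fields(cls)}
        _strict("<root>", data, allowed)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def sim_config(self) -> SimConfig:
        return preset(self.preset, self.separation, seed=self.seed, **self.sim)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _split_qc_settings(qc_cfg: dict):
    chart = {k: qc_cfg[k] for k in ("variance_fraction", "alpha") if k in qc_cfg}
    thr = {k: v for k, v in qc_cfg.items() if k not in ("variance_fraction", "alpha")}
    return QualityThresholds(**thr), chart.get("variance_fraction", 0.95), \
        chart.get("alpha", 0.05)


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Execute all enabled stages; returns the report bundle.

    ``resume=True`` reloads the persisted QC-filtered dataset from the run
    directory (if present) instead of regenerating — downstream artifacts
    are identical because every stage is deterministic in (config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }
    report: dict = {"manifest": manifest}

    def stage(name: str, rows_in: int, rows_out: int, t0: float, **extra) -> None:
        entry = {"stage": name, "rows_in": rows_in, "rows_out": rows_out,
                 "excluded": rows_in - rows_out,
                 "wall_time_s": round(time.perf_counter() - t0, 3), **extra}
        if entry["excluded"] < 0:
            raise PipelineError(f"stage {name} gained rows")
        manifest["stages"].append(entry)

    sim_cfg = config.sim_config()
    qc_path = out / "02_qc_filtered.csv"

    if resume and qc_path.exists():
        t0 = time.perf_counter()
        filtered = read_dataset(qc_path)
        stage("resume_qc_filtered", filtered.n_spectra, filtered.n_spectra, t0)
    else:
        # -- stage 1: synthetic data -----------------------------------------
        t0 = time.perf_counter()
        from .simulate import generate_dataset
        dataset, truth = generate_dataset(sim_cfg)
        truth.to_csv(out / "01_truth.tsv", sep="\t", index=False)
        write_dataset(dataset, out / "01_spectra.csv")
        stage("simulate", dataset.n_spectra, dataset.n_spectra, t0,
              n_subjects=sim_cfg.n_subjects_per_class * len(sim_cfg.classes))

        # -- stage 2: quality control ----------------------------------------
        t0 = time.perf_counter()
        if config.qc_enabled:
            thr, vf, alpha = _split_qc_settings(config.qc)
            qcr = qc_report(dataset, thr, vf, alpha)
            qcr.to_csv(out / "02_qc_report.tsv", sep="\t", index=False)
            filtered, excluded = apply_outlier_filter(dataset, qcr)
            report["qc"] = {"excluded_ids": excluded,
                            "pass_fraction": 1.0 - len(excluded) / dataset.n_spectra}
            stage("qc", dataset.n_spectra, filtered.n_spectra, t0,
                  pass_fraction=report["qc"]["pass_fraction"])
        else:
            filtered = dataset
            stage("qc", dataset.n_spectra, dataset.n_spectra, t0, skipped=True)
        write_dataset(filtered, qc_path)

    pp = PreprocessParams(**{**{"scale_mode": "mean-center"}, **config.preprocess})

    # -- stage 3: truncation + calibration transfer --------------------------
    t0 = time.perf_counter()
    trunc = truncate(filtered, pp.window_low, pp.window_high)
    batches = sorted(trunc.metadata["batch"].unique())
    if config.transfer_enabled and len(batches) > 1:
        half_width = config.transfer.get("half_width", 7)
        rank_tol = config.transfer.get("rank_tol", 1e-6)
        n_xfer = config.transfer.get("n_transfer_subjects", 6)
        master_set, slave_set = paired_transfer_set(sim_cfg, n_subjects=n_xfer)
        pds = fit_pds(truncate(master_set, pp.window_low, pp.window_high),
                      truncate(slave_set, pp.window_low, pp.window_high),
                      half_width=half_width, rank_tol=rank_tol)
        is_master = (trunc.metadata["batch"] == batches[0]).to_numpy()
        master_part = trunc.select_rows(is_master)
        slave_part = pds.transform(trunc.select_rows(~is_master))
        trunc = stack([master_part, slave_part])
        report["transfer"] = {"rms_before": pds.rms_before_,
                              "rms_after": pds.rms_after_,
                              "half_width": half_width}
        (out / "03_pds_model.json").write_text(json.dumps({
            "grid": list(pds.grid_) if pds.grid_ is not None else None,
            "half_width": half_width, "rank_tol": rank_tol,
            "intercepts": list(pds.intercept_),
            "operator_bands": {
                str(j): list(pds.operator_[max(0, j - half_width):
                                           j + half_width + 1, j])
                for j in range(0, pds.operator_.shape[1],
                               max(1, pds.operator_.shape[1] // 50))
            },
            "rms_before": pds.rms_before_, "rms_after": pds.rms_after_,
        }))
        stage("transfer", filtered.n_spectra, trunc.n_spectra, t0,
              rms_before=pds.rms_before_, rms_after=pds.rms_after_)
    else:
        stage("transfer", filtered.n_spectra, trunc.n_spectra, t0, skipped=True)

    # -- stage 4: preprocessing + PCA ----------------------------------------
    t0 = time.perf_counter()
    pre = preprocess_pipeline(trunc, pp)
    write_dataset(pre, out / "04_preprocessed.csv")
    n_comp = config.pca.get("n_components", 2)
    pca = fit_pca(pre, n_components=max(n_comp, 2))
    scores = pca.transform(pre)
    score_table = pre.metadata[["spectrum_id", "subject_id", "group", "batch"]].copy()
    for j in range(scores.shape[1]):
        score_table[f"PC{j + 1}"] = scores[:, j]
    score_table.to_csv(out / "04_pca_scores.tsv", sep="\t", index=False)
    ellipses = {}
    for cls, grp in score_table.groupby("group", sort=True):
        ell = confidence_ellipse(grp[["PC1", "PC2"]].to_numpy(), level=0.95)
        ellipses[cls] = {"center": list(ell.center),
                         "semi_axes": list(ell.semi_axes),
                         "angle": ell.angle, "level": ell.level}
    (out / "04_ellipses.json").write_text(json.dumps(ellipses, indent=1))
    mardia = mardia_test(scores[:, : min(5, scores.shape[1])])
    report["pca"] = {
        "explained_variance_ratio": list(pca.explained_variance_ratio_),
        "ellipses": ellipses,
        "mardia": {"b1": mardia.b1, "b2": mardia.b2, "skew_p": mardia.skew_p,
                   "kurt_p": mardia.kurt_p, "normal": mardia.normal},
    }
    stage("pca", pre.n_spectra, pre.n_spectra, t0,
          pc1=pca.explained_variance_ratio_[0],
          pc2=pca.explained_variance_ratio_[1])

    # -- stage 5: supervised classification ----------------------------------
    t0 = time.perf_counter()
    ccfg = dict(config.classify)
    arch_keys = {"section_depth", "filter_size", "n_filters", "dense_units",
                 "dropout_rate"}
    train_keys = {"batch_size", "max_epochs", "patience", "learning_rate",
                  "momentum", "l2"}
    from .classify import CNNArchitecture, TrainingParams
    arch = CNNArchitecture(**{k: ccfg.pop(k) for k in list(ccfg) if k in arch_keys})
    training = TrainingParams(**{k: ccfg.pop(k) for k in list(ccfg) if k in train_keys})
    run = run_classification(
        trunc,
        preprocess_params=PreprocessParams(
            window_low=pp.window_low, window_high=pp.window_high,
            sg_points=pp.sg_points, sg_polyorder=pp.sg_polyorder,
            scale_mode="standardize"),
        arch=arch, training=training, seed=config.seed,
        class_order=tuple(sim_cfg.classes), **ccfg)
    pd.concat(run.predictions).to_csv(out / "05_test_predictions.tsv",
                                      sep="\t", index=False)
    if run.trace is not None:
        run.trace.to_csv(out / "05_bayes_trace.tsv", sep="\t", index=False)
    for r, hist in enumerate(run.histories):
        hist.to_csv(out / f"05_history_rep{r:02d}.tsv", sep="\t", index=False)
    n_test = sum(len(p) for p in run.predictions)
    stage("classify", trunc.n_spectra, trunc.n_spectra, t0,
          pooled_test_predictions=n_test,
          best_hyperparams=run.best_hyperparams)

    # -- stage 6: merits ------------------------------------------------------
    t0 = time.perf_counter()
    chord = chord_export(run.confusion)
    chord.to_csv(out / "06_chord_edges.tsv", sep="\t", index=False)
    merits = {
        "class_order": list(run.class_order),
        "confusion": run.confusion.counts.tolist(),
        "accuracy": float(run.metrics["accuracy"].iloc[0]),
        "per_class": run.metrics.reset_index().to_dict(orient="records"),
    }
    (out / "06_metrics.json").write_text(json.dumps(merits, indent=1))
    report["classification"] = merits
    report["run"] = run
    stage("evaluate", n_test, n_test, t0, accuracy=merits["accuracy"])

    # manifest arithmetic: rows out of each stage = rows in minus exclusions
    for entry in manifest["stages"]:
        assert entry["rows_out"] == entry["rows_in"] - entry["excluded"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return report
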