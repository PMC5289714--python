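"""End-to-end orchestration: simulate -> preprocess -> extract -> select ->
classify -> maps, with declarative configuration and run logging.

`run_pipeline` executes the whole analysis on a (synthetic or loaded) cohort
and leaves a self-describing run directory: config echo, feature matrices,
ranking trace, cross-validation report and topographic map tables, all
deterministic functions of the configuration and its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .classify import CVReport, cross_validate, subset_sweep
from .features import band_coefficients, dwt_decompose, emd_features, emd_sift, stft_features
from .maps_stats import pca_scatter, topomaps_by_stratum, wilcoxon_channel_map
from .preprocessing import PreprocessConfig, preprocess_recording
from .selection import (FeatureMatrix, auc_rank, fit_reference, prune_correlated,
                        standardize, take_top)
from .synthetic_cohort import ArtifactConfig, CohortSpec, EEGRecording, generate_cohort

log = logging.getLogger("eegresp")


def setup_logging(logfile=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    task: str = "response"              # "response" or "diagnosis"
    feature_method: str = "wavelet"     # "wavelet", "stft" or "emd"
    bands: tuple[str, ...] = ("delta", "theta")
    dwt_levels: int = 5
    selector: str = "roc"               # "roc" or "mrmr"
    k_features: int = 15
    r_max: float | None = 0.9
    folds: int = 10
    repeats: int = 100
    subset_sizes: tuple[int, ...] | None = None
    group_by_subject: bool = True
    make_maps: bool = True
    make_scatter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("response", "diagnosis"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.feature_method not in ("wavelet", "stft", "emd"):
            raise ValueError(f"unknown feature_method {self.feature_method!r}")

    def to_dict(self) -> dict:
        # JSON round trip normalises tuples to lists, so the dict form is
        # YAML/JSON-stable and survives serialisation unchanged
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, data, where):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise ValueError(
                    f"unknown config key(s) {sorted(unknown)} in {where}")
            return data

        raw = dict(build(cls, raw, "pipeline"))
        if "cohort" in raw:
            c = dict(build(CohortSpec, raw["cohort"], "cohort"))
            if "artifact_config" in c:
                c["artifact_config"] = ArtifactConfig(
                    **build(ArtifactConfig, c["artifact_config"], "artifact_config"))
            raw["cohort"] = CohortSpec(**c)
        if "preprocess" in raw:
            raw["preprocess"] = PreprocessConfig(
                **build(PreprocessConfig, raw["preprocess"], "preprocess"))
        for key in ("bands", "subset_sizes", "effect_channels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# feature-matrix construction
# ---------------------------------------------------------------------------

def _recording_features(rec: EEGRecording, method: str, bands, levels: int):
    feats, meta = [], []
    for ci, ch in enumerate(rec.channel_labels):
        x = rec.data[ci]
        if method == "wavelet":
            v, m = band_coefficients(dwt_decompose(x, rec.fs, levels=levels), bands)
        elif method == "stft":
            v, m = stft_features(x, rec.fs, bands=bands)
        elif method == "emd":
            v, m = emd_features(emd_sift(x), rec.fs, bands=bands)
        else:
            raise ValueError(f"unknown feature method {method!r}")
        feats.append(v)
        meta.extend(dict(channel=ch, method=method, **mm) for mm in m)
    return np.concatenate(feats), meta


def build_feature_matrix(recordings: list[EEGRecording], method: str = "wavelet",
                         bands=("delta", "theta"), levels: int = 5,
                         conditions=("EC", "EO")) -> FeatureMatrix:
    """One instance per (subject, condition) recording, features column-wise.

    All recordings must share length and sampling rate so coefficient indices
    align across instances.
    """
    rows, inst = [], []
    n_cols = None
    for rec in recordings:
        if rec.condition not in conditions:
            continue
        v, meta = _recording_features(rec, method, bands, levels)
        if n_cols is None:
            n_cols, feature_meta = len(v), meta
        elif len(v) != n_cols:
            raise ValueError("recordings produce differing feature counts; "
                             "equalise lengths/sampling first")
        rows.append(v)
        inst.append(dict(subject_id=rec.subject_id, condition=rec.condition,
                         group=rec.group, sex=rec.sex))
    if not rows:
        raise ValueError("no recordings matched the requested conditions")
    return FeatureMatrix(np.vstack(rows), pd.DataFrame(feature_meta),
                         pd.DataFrame(inst))


def task_view(fm: FeatureMatrix, task: str) -> tuple[FeatureMatrix, str]:
    """Restrict/relabel instances for a task; returns (matrix, positive class).

    ``response`` keeps only patient instances (R vs NR); ``diagnosis``
    relabels every patient instance as MDD against the controls.
    """
    groups = fm.instance_meta["group"]
    if task == "response":
        rows = np.where(groups.isin(["R", "NR"]))[0]
        return fm.subset(rows=rows), "R"
    if task == "diagnosis":
        im = fm.instance_meta.copy()
        im["group"] = np.where(groups == "control", "control", "MDD")
        return FeatureMatrix(fm.values, fm.feature_meta, im), "MDD"
    raise ValueError(f"unknown task {task!r}")


def ranking_trace_frame(fm: FeatureMatrix, ranked) -> pd.DataFrame:
    """Flat trace table: feature id, channel, band, auc, |auc|, rank, retained."""
    rank_of = np.empty(len(ranked.order), dtype=int)
    rank_of[ranked.order] = np.arange(len(ranked.order))
    retained = set(ranked.retained.tolist())
    return pd.DataFrame(dict(
        feature_id=np.arange(fm.n_features),
        channel=fm.feature_meta["channel"],
        band=fm.feature_meta["band"],
        auc=ranked.auc,
        abs_auc=np.abs(ranked.auc),
        rank=rank_of,
        retained=[i in retained for i in range(fm.n_features)],
    )).sort_values("rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _report_json(report: CVReport) -> dict:
    return dict(
        folds=report.folds, repeats=report.repeats, subset_size=report.subset_size,
        summary={k: {"mean": m, "sd": s} for k, (m, s) in report.summary().items()},
        per_repeat={name: report.metric(name).tolist()
                    for name in ("accuracy", "sensitivity", "specificity", "f_measure")},
    )


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every stage in order and write a self-describing run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(outdir / "run.log")
    t0 = time.time()
    log.info("stage=simulate seed=%d", config.cohort.seed)
    recordings, metadata = generate_cohort(config.cohort)
    metadata.to_csv(outdir / "metadata.csv", index=False)

    log.info("stage=preprocess n_recordings=%d", len(recordings))
    clean = [preprocess_recording(r, config.preprocess) for r in recordings
             if r.condition in ("EC", "EO")]
    log.info("stage=extract method=%s bands=%s", config.feature_method, config.bands)
    patients = build_feature_matrix(
        [r for r in clean if r.group != "control"],
        method=config.feature_method, bands=config.bands, levels=config.dwt_levels)
    controls = build_feature_matrix(
        [r for r in clean if r.group == "control"],
        method=config.feature_method, bands=config.bands, levels=config.dwt_levels)
    log.info("patients=%s controls=%s", patients.values.shape, controls.values.shape)

    ref = fit_reference(controls)
    if config.task == "response":
        analysed = standardize(patients, ref)
        positive = "R"
    else:
        both = FeatureMatrix(
            np.vstack([patients.values, controls.values]),
            patients.feature_meta,
            pd.concat([patients.instance_meta.assign(group="MDD"),
                       controls.instance_meta], ignore_index=True))
        analysed = standardize(both, ref)
        positive = "MDD"

    log.info("stage=select selector=%s k=%d", config.selector, config.k_features)
    ranked = auc_rank(analysed, positive_class=positive)
    if config.r_max is not None:
        ranked = prune_correlated(ranked, analysed, r_max=config.r_max,
                                  max_keep=max(200, config.k_features))
    ranking_trace_frame(analysed, ranked).head(200).to_csv(
        outdir / "ranking_trace.csv", index=False)

    log.info("stage=classify repeats=%d folds=%d", config.repeats, config.folds)
    report = cross_validate(
        analysed, k_features=config.k_features, folds=config.folds,
        repeats=config.repeats, seed=config.seed, selector=config.selector,
        r_max=config.r_max, positive_class=positive,
        group_by_subject=config.group_by_subject)
    results = {"cv_report": _report_json(report)}
    if config.subset_sizes:
        sweep = subset_sweep(
            analysed, sizes=config.subset_sizes, folds=config.folds,
            repeats=config.repeats, seed=config.seed, selector=config.selector,
            r_max=config.r_max, positive_class=positive,
            group_by_subject=config.group_by_subject)
        results["subset_sweep"] = {str(k): _report_json(r) for k, r in sweep.items()}

    if config.make_maps and config.task == "response":
        log.info("stage=topomap")
        maps = topomaps_by_stratum(analysed, stratify_sex=True)
        maps.append(wilcoxon_channel_map(analysed))
        pd.concat([m.to_frame().assign(stratum=m.stratum) for m in maps],
                  ignore_index=True).to_csv(outdir / "topomaps.csv", index=False)
    if config.make_scatter:
        top = take_top(ranked, min(config.k_features, ranked.N_r))
        scores, varexp = pca_scatter(analysed.subset(cols=top))
        pd.DataFrame(dict(pc1=scores[:, 0], pc2=scores[:, 1],
                          group=analysed.instance_meta["group"])).to_csv(
            outdir / "pca_scatter.csv", index=False)
        results["pca_variance_explained"] = [float(v) for v in varexp]

    results["config"] = config.to_dict()
    eio.write_feature_matrix(analysed, outdir / "features.csv")
    with open(outdir / "report.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_json_default)
    log.info("stage=done elapsed=%.1fs", time.time() - t0)
    return outdir


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
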