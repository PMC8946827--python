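"""Staged orchestration: simulate → preprocess → features → train → evaluate.

Each stage reads its inputs from disk and writes its outputs next to them
(CSV for tables, HDF5 for image stacks, JSON for configs and reports), so
any stage can be re-run and inspected independently; a manifest with
checksums makes reruns verifiable.  :func:`run_subject_end_to_end` is the
in-memory equivalent used by tests and the acceptance experiments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ipgbp import synthetic, preprocess, features as feat
from ipgbp.ssrnet import SSRNetConfig, LossSpec, train_personalized
from ipgbp.evaluation import EvaluationReport, split_dataset, evaluate_predictions

log = logging.getLogger("ipgbp")

__all__ = ["RunConfig", "run_simulate", "run_preprocess", "run_features",
           "run_train_evaluate", "run_full", "subject_feature_set",
           "run_subject_end_to_end"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (JSON round-trippable)."""

    seed: int = 0
    n_subjects: int = 6
    n_trials: int = 30
    beats_per_trial: int = 5
    fs: float = 500.0
    snr_db: float = 20.0
    cuff_noise_sd: float = 1.5
    trial_sd: float = 5.0
    filter_low: float = 0.3
    filter_high: float = 5.0
    filter_order: int = 4
    target_len: int = 128
    n_scales: int = 64
    wavelet: str = "db8"
    image_shape: tuple[int, int] = (32, 32)
    alpha: float = 3.0
    alpha_grid: tuple[float, ...] = (3.0,)
    epochs: int = 300
    n_train: int = 120
    n_test: int = 30
    outdir: str = "runs/default"
    ssrnet: SSRNetConfig = field(default_factory=SSRNetConfig)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "ssrnet" in d and isinstance(d["ssrnet"], dict):
            ss = d["ssrnet"]
            for key in ("bins_per_stage", "input_shape", "bp_range"):
                if key in ss:
                    ss[key] = tuple(ss[key])
            d["ssrnet"] = SSRNetConfig(**ss)
        for key in ("image_shape", "alpha_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def write(self, outdir: str | Path) -> None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        (Path(outdir) / "run_config.json").write_text(self.to_json())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _subject_profile(config: RunConfig, subject_seed: int) -> synthetic.SubjectProfile:
    sc = synthetic.SubjectConfig(
        trial_sd=config.trial_sd, noise_snr=config.snr_db, cuff_noise_sd=config.cuff_noise_sd
    )
    return synthetic.generate_subject(subject_seed, sc)


def run_simulate(config: RunConfig) -> dict:
    """Generate and write every subject's dataset; returns the manifest."""
    outdir = Path(config.outdir) / "simulate"
    outdir.mkdir(parents=True, exist_ok=True)
    config.write(Path(config.outdir))
    manifest: dict = {"subjects": {}, "files": {}}
    for i in range(config.n_subjects):
        profile = _subject_profile(config, config.seed + i)
        trials = synthetic.emulate_protocol(
            profile, config.n_trials, config.beats_per_trial, fs=config.fs
        )
        paths = synthetic.write_subject_dataset(outdir, profile, trials)
        manifest["subjects"][profile.subject_id] = paths
        for name, p in paths.items():
            manifest["files"][p] = _sha256(Path(p))
        log.info("simulate: subject %s, %d trials", profile.subject_id, len(trials))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_preprocess(config: RunConfig) -> pd.DataFrame:
    """Band-pass, segment, select and normalize beats for every subject."""
    import h5py

    simdir = Path(config.outdir) / "simulate"
    outdir = Path(config.outdir) / "preprocess"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((simdir / "manifest.json").read_text())

    rows, all_beats = [], []
    for sid in manifest["subjects"]:
        _, trials = synthetic.read_subject_dataset(simdir, sid)
        for tr in trials:
            beats = preprocess.extract_trial_beats(
                tr, subject_id=sid, k=config.beats_per_trial, target_len=config.target_len
            )
            for b in beats:
                rows.append(
                    {"subject_id": sid, "trial_index": tr.trial_index, "beat_index": b.beat_index,
                     "t_anchor": b.t_anchor, "cuff_SBP": tr.cuff_SBP, "cuff_DBP": tr.cuff_DBP,
                     "true_SBP": tr.true_SBP, "true_DBP": tr.true_DBP}
                )
                all_beats.append(b.samples)
        log.info("preprocess: subject %s, %d beats", sid, len(trials) * config.beats_per_trial)
    meta = pd.DataFrame(rows)
    meta.to_csv(outdir / "beats.csv", index=False, float_format="%.8g")
    with h5py.File(outdir / "beats.h5", "w") as f:
        f.create_dataset("beats", data=np.asarray(all_beats, dtype=np.float32))
    return meta


def run_features(config: RunConfig) -> np.ndarray:
    """CWT scalogram images for every beat; writes HDF5 + index CSV."""
    import h5py

    predir = Path(config.outdir) / "preprocess"
    outdir = Path(config.outdir) / "features"
    outdir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(predir / "beats.csv")
    with h5py.File(predir / "beats.h5", "r") as f:
        beats = f["beats"][...].astype(float)
    scales = feat.default_scales(config.n_scales, wavelet=config.wavelet)
    images = feat.beats_to_images(list(beats), scales=scales, wavelet=config.wavelet,
                                  out_shape=config.image_shape)
    feat.write_scalograms(outdir / "scalograms.h5", images, meta)
    log.info("features: %d scalograms of shape %s", len(images), config.image_shape)
    return images


def run_train_evaluate(config: RunConfig) -> pd.DataFrame:
    """Per-subject, per-target training + evaluation from the features stage."""
    featdir = Path(config.outdir) / "features"
    outdir = Path(config.outdir) / "evaluate"
    outdir.mkdir(parents=True, exist_ok=True)
    images, meta = feat.read_scalograms(featdir / "scalograms.h5")

    rows = []
    for si, sid in enumerate(meta["subject_id"].unique()):
        mask = (meta["subject_id"] == sid).to_numpy()
        sub_meta = meta.loc[mask].reset_index(drop=True)
        sub_imgs = images[mask]
        for alpha in config.alpha_grid:
            reports = _train_eval_subject(
                sub_imgs, sub_meta, config, alpha=alpha, seed=config.seed + 7919 * si
            )
            for rep in reports.values():
                rows.append({"subject_id": sid, "alpha": alpha, "target": rep.target,
                             "n": rep.n, "ME": rep.ME, "ME_SD": rep.ME_SD,
                             "MAE": rep.MAE, "MAE_SD": rep.MAE_SD,
                             "ba_low": rep.bland_altman[1], "ba_high": rep.bland_altman[2],
                             "aami_pass": rep.aami_pass})
                log.info("evaluate: %s %s α=%g ME=%.2f±%.2f MAE=%.2f±%.2f AAMI=%s",
                         sid, rep.target, alpha, rep.ME, rep.ME_SD, rep.MAE, rep.MAE_SD, rep.aami_pass)
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "summary.csv", index=False, float_format="%.6g")
    return summary


def _train_eval_subject(images: np.ndarray, meta: pd.DataFrame, config: RunConfig,
                        alpha: float, seed: int) -> dict[str, EvaluationReport]:
    """Split one subject's pairs, train SBP and DBP models, evaluate the test set."""
    idx_pairs = list(range(len(images)))
    trial_ids = meta["trial_index"].to_numpy()
    train_idx, test_idx = split_dataset(idx_pairs, config.n_train, config.n_test,
                                        seed=seed, trial_ids=trial_ids)
    reports: dict[str, EvaluationReport] = {}
    for target, col in (("SBP", "cuff_SBP"), ("DBP", "cuff_DBP")):
        refs = meta[col].to_numpy()
        net_cfg = dataclasses.replace(
            config.ssrnet,
            bp_range=(80.0, 180.0) if target == "SBP" else (40.0, 120.0),
            epochs=config.epochs,
            input_shape=tuple(config.image_shape),
        )
        model, _ = train_personalized(
            (images[train_idx], refs[train_idx]),
            config=net_cfg,
            loss=LossSpec(alpha=alpha),
            seed=seed,
        )
        preds = model.forward(images[test_idx])
        reports[target] = evaluate_predictions(target, preds, refs[test_idx])
    return reports


def run_full(config: RunConfig) -> pd.DataFrame:
    """All stages in order; returns the (subject, target) summary table."""
    stages = [("simulate", run_simulate), ("preprocess", run_preprocess),
              ("features", run_features), ("evaluate", run_train_evaluate)]
    result = None
    for name, fn in stages:
        try:
            result = fn(config)
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return result


def subject_feature_set(subject_seed: int = 0, config: RunConfig | None = None) -> dict:
    """Simulate one subject and run it through preprocessing and features.

    Returns images (n_pairs, H, W), per-pair cuff references for both
    targets, trial ids, and the subject profile — the material every
    training experiment starts from.
    """
    config = config or RunConfig()
    profile = _subject_profile(config, subject_seed)
    trials = synthetic.emulate_protocol(profile, config.n_trials, config.beats_per_trial, fs=config.fs)

    beats, trial_ids, sbp_refs, dbp_refs = [], [], [], []
    for tr in trials:
        for b in preprocess.extract_trial_beats(tr, subject_id=profile.subject_id,
                                                k=config.beats_per_trial,
                                                target_len=config.target_len):
            beats.append(b.samples)
            trial_ids.append(tr.trial_index)
            sbp_refs.append(tr.cuff_SBP)
            dbp_refs.append(tr.cuff_DBP)

    scales = feat.default_scales(config.n_scales, wavelet=config.wavelet)
    images = feat.beats_to_images(beats, scales=scales, wavelet=config.wavelet,
                                  out_shape=config.image_shape)
    return {"profile": profile, "images": images, "trial_ids": np.asarray(trial_ids),
            "sbp_refs": np.asarray(sbp_refs), "dbp_refs": np.asarray(dbp_refs)}


def run_subject_end_to_end(
    subject_seed: int = 0,
    config: RunConfig | None = None,
    alpha: float = 3.0,
    epochs: int | None = None,
    feature_set: dict | None = None,
) -> dict:
    """In-memory single-subject pipeline; returns reports, errors and sizes.

    This is the canonical end-to-end experiment: one synthetic subject,
    30 trials × 5 beats = 150 (scalogram, cuff) pairs, a trial-stratified
    120/30 split, personalized SBP and DBP models, and the full evaluation
    battery on the 30 held-out pairs.  ``feature_set`` (from
    :func:`subject_feature_set`) skips the simulate/preprocess/feature
    stages when provided.
    """
    config = config or RunConfig()
    fs_ = feature_set or subject_feature_set(subject_seed, config)
    profile = fs_["profile"]
    images = fs_["images"]
    trial_ids = fs_["trial_ids"]
    sbp_refs, dbp_refs = fs_["sbp_refs"], fs_["dbp_refs"]
    n_pairs = len(images)

    idx = list(range(n_pairs))
    train_idx, test_idx = split_dataset(idx, config.n_train, config.n_test,
                                        seed=subject_seed, trial_ids=trial_ids)
    out = {"n_pairs": n_pairs, "n_train": len(train_idx), "n_test": len(test_idx),
           "profile": profile, "reports": {}, "errors": {}, "models": {}}
    for target, refs_list, bp_range in (("SBP", sbp_refs, (80.0, 180.0)),
                                        ("DBP", dbp_refs, (40.0, 120.0))):
        refs = np.asarray(refs_list)
        net_cfg = dataclasses.replace(config.ssrnet, bp_range=bp_range,
                                      input_shape=tuple(config.image_shape))
        model, report = train_personalized(
            (images[train_idx], refs[train_idx]),
            config=net_cfg,
            loss=LossSpec(alpha=alpha),
            epochs=epochs if epochs is not None else config.epochs,
            seed=subject_seed,
            test_pairs=(images[test_idx], refs[test_idx]),
        )
        preds = model.forward(images[test_idx])
        out["reports"][target] = evaluate_predictions(target, preds, refs[test_idx])
        out["errors"][target] = preds - refs[test_idx]
        out["models"][target] = (model, report)
    return out
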