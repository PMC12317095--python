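"""End-to-end pipeline driver: simulate -> train -> evaluate -> explain ->
survival, with a content-hashed artifact manifest and stage-level resume.

A single master seed is fanned out per stage (and per fold/epoch below
that) through :func:`duetmil.seeds.derive_seed`, so re-running a config
reproduces every deterministic artifact, and deleting a downstream stage's
outputs re-runs only that stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinoutcome, evalmetrics, explainmaps
from .duonet import DuetTransformer, DuoNetConfig
from .seeds import derive_seed
from .synthcohort import (Assay, SynthConfig, cohort_manifest, drop_equivocal,
                          generate_cohort)
from .tileenc import save_bag
from .trainer import TrainConfig, cross_validate

log = logging.getLogger("duetmil.orchestration")

STAGES = ("simulate", "train", "evaluate", "explain", "survival")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    master_seed: int = 0
    n_cases: int = 120
    prevalence: float = 0.10
    tiles_per_slide_range: tuple = (8, 16)
    assay: str = "MSI_LOCI"
    equivocal_rate: float = 0.0
    model: dict = field(default_factory=lambda: {"model_dim": 64, "n_heads": 4,
                                                 "mlp_hidden": 64})
    train: dict = field(default_factory=lambda: {"learning_rate": 1e-3, "epochs": 10})
    modes: tuple = ("DUET", "HE_ONLY", "IHC_ONLY")
    k_folds: int = 5
    threshold: float = 0.5
    n_explain_slides: int = 2

    def synth_config(self) -> SynthConfig:
        return SynthConfig(
            n_cases=self.n_cases, prevalence=self.prevalence,
            tiles_per_slide_range=tuple(self.tiles_per_slide_range),
            assay=Assay(self.assay), equivocal_rate=self.equivocal_rate,
            seed=derive_seed(self.master_seed, "simulate"),
        )

    def model_config(self) -> DuoNetConfig:
        return DuoNetConfig(**self.model)

    def train_config(self) -> TrainConfig:
        return TrainConfig(seed=derive_seed(self.master_seed, "train"), **self.train)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tiles_per_slide_range"] = list(self.tiles_per_slide_range)
        d["modes"] = list(self.modes)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["tiles_per_slide_range"] = tuple(d.get("tiles_per_slide_range", (8, 16)))
        d["modes"] = tuple(d.get("modes", ("DUET", "HE_ONLY", "IHC_ONLY")))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config_digest: str):
        self.path = out_dir / "manifest.json"
        self.out_dir = out_dir
        if self.path.exists():
            data = json.loads(self.path.read_text())
            if data.get("config") != config_digest:
                log.info("config changed; discarding previous manifest")
                data = {"config": config_digest, "stages": {}}
        else:
            data = {"config": config_digest, "stages": {}}
        self.data = data

    def stage_done(self, stage: str) -> bool:
        arts = self.data["stages"].get(stage)
        if arts is None:
            return False
        for rel, digest in arts.items():
            p = self.out_dir / rel
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage: str, artifacts: list[Path]) -> None:
        self.data["stages"][stage] = {
            str(p.relative_to(self.out_dir)): _sha256(p) for p in artifacts
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _validate_manifest_frame(df: pd.DataFrame) -> None:
    required = {"case_id", "label", "scanner", "site", "n_tiles"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort manifest missing columns: {sorted(missing)}")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages into ``out_dir``; skips stages whose recorded
    artifacts are present and hash-identical. Any stage failure aborts with
    the stage named."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    man = _Manifest(out, config.digest())

    cohort = drop_equivocal(generate_cohort(config.synth_config()))
    data = {c.case_id: c for c in cohort}

    cvs = {}

    def stage_simulate() -> list[Path]:
        df = cohort_manifest(cohort)
        _validate_manifest_frame(df)
        path = out / "cohort.csv"
        df.to_csv(path, index=False)
        bags = out / "bags.h5"
        if bags.exists():
            bags.unlink()
        for c in cohort:
            save_bag(c.he_bag, bags)
            save_bag(c.ihc_bag, bags)
        return [path]  # HDF5 is not hash-stable across writes; tracked by presence

    def stage_train() -> list[Path]:
        arts = []
        for mode in config.modes:
            cv = cross_validate(cohort, config.model_config(), config.train_config(),
                                mode=mode, k=config.k_folds)
            cvs[mode] = cv
            p = out / f"predictions_{mode}.csv"
            cv.predictions.to_csv(p, index=False, float_format="%.10g")
            f = out / f"fold_aurocs_{mode}.csv"
            pd.DataFrame({"fold": range(len(cv.fold_aurocs)),
                          "auroc": cv.fold_aurocs}).to_csv(f, index=False,
                                                           float_format="%.10g")
            for fold, model in cv.models.items():
                model.save(out / f"model_{mode}_fold{fold}.npz")
            arts += [p, f]
        return arts

    def _load_cv_predictions(mode):
        return pd.read_csv(out / f"predictions_{mode}.csv")

    def stage_evaluate() -> list[Path]:
        rows = []
        arts = []
        for mode in config.modes:
            fold_df = pd.read_csv(out / f"fold_aurocs_{mode}.csv")
            mean, (lo, hi) = evalmetrics.mean_auroc_ci(fold_df["auroc"].to_numpy())
            rows.append({"mode": mode, "mean_auroc": mean, "ci_low": lo, "ci_high": hi})
            preds = _load_cv_predictions(mode)
            for key in ("scanner", "site"):
                sp = out / f"stratified_{mode}_{key}.csv"
                evalmetrics.stratified_auroc(preds, key).to_csv(sp, index=False,
                                                                float_format="%.10g")
                arts.append(sp)
        mp = out / "metrics.csv"
        pd.DataFrame(rows).to_csv(mp, index=False, float_format="%.10g")
        duet_preds = _load_cv_predictions(config.modes[0])
        curve = evalmetrics.tradeoff_curve(duet_preds)
        tp = out / "tradeoff.csv"
        evalmetrics.curve_frame(curve).to_csv(tp, index=False, float_format="%.10g")
        hp = out / "probability_histogram.csv"
        evalmetrics.probability_histogram(duet_preds).to_csv(hp, index=False,
                                                             float_format="%.10g")
        return [mp, tp, hp] + arts

    def stage_explain() -> list[Path]:
        mode = config.modes[0]
        cv = cvs.get(mode)
        frames = []
        arts = []
        count = 0
        splits = cv.splits if cv else None
        for c in cohort:
            if count >= config.n_explain_slides or not c.label:
                continue
            if cv:
                fold = next(sp.fold_id for sp in splits if c.case_id in sp.test_ids)
                model = cv.models[fold]
            else:
                fold = 0
                model = DuetTransformer.load(out / f"model_{mode}_fold{fold}.npz")
            amap = explainmaps.explain_case(model, c.he_bag)
            frames.append(amap.frame())
            side = int(np.ceil(np.sqrt(c.he_bag.n_tiles))) * 224
            png = out / f"heatmap_{c.case_id}.png"
            explainmaps.render_heatmap(amap, (side, side), path=png)
            count += 1
        sp = out / "explain_scores.csv"
        pd.concat(frames, ignore_index=True).to_csv(sp, index=False,
                                                    float_format="%.10g")
        return [sp]

    def stage_survival() -> list[Path]:
        rows = []
        outcomes = {c.case_id: c.outcome for c in cohort}
        actual = {c.case_id: c.label for c in cohort}
        def summarize(tag: str, groups: dict) -> None:
            for endpoint in ("TOT", "OS"):
                recs = clinoutcome.build_survival_records(outcomes, groups, endpoint)
                try:
                    rows.append({"stratification": tag,
                                 **clinoutcome.survival_summary(recs)})
                except (ValueError, RuntimeError) as exc:
                    # degenerate stratification (empty group, monotone
                    # likelihood) is reported, not fatal
                    rows.append({"stratification": tag, "endpoint": endpoint,
                                 "error": str(exc)})

        summarize("actual", actual)
        for mode in config.modes:
            preds = _load_cv_predictions(mode)
            grp = {cid: int(p >= config.threshold)
                   for cid, p in zip(preds["case_id"], preds["probability"])}
            summarize(f"predicted_{mode}", grp)
        sp = out / "survival.csv"
        pd.DataFrame(rows).to_csv(sp, index=False, float_format="%.10g")
        recs = clinoutcome.build_survival_records(outcomes, actual, "OS")
        clinoutcome.plot_km(recs, path=out / "km_actual_os.png", title="OS by actual status")
        return [sp]

    runners = {"simulate": stage_simulate, "train": stage_train,
               "evaluate": stage_evaluate, "explain": stage_explain,
               "survival": stage_survival}
    for stage in STAGES:
        if man.stage_done(stage):
            log.info("stage %s up to date; skipping", stage)
            continue
        log.info("running stage %s", stage)
        try:
            artifacts = runners[stage]()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        man.record(stage, artifacts)
    return out
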