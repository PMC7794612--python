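"""Configuration-driven end-to-end runs: simulate -> indices -> stats -> classify.

The pipeline is an offline batch analogue of the original streaming system;
it preserves the 33 Hz tick / 5 s window granularity.  Every run writes its
artefacts (CSV/JSON) plus a manifest with content hashes and the config
hash, so reruns with identical configs and seeds are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import loo_fish_cv, posterior_shift_analysis
from .indices import INDEX_COLUMNS
from .simulate import CohortConfig, FishPlan, default_cohort_config, generate_cohort
from .stats import one_way_anova, pca_fit, pca_scores, welch_t

__all__ = ["ExperimentConfig", "run_pipeline", "run_stage"]

_STAGES = ("simulate", "indices", "stats", "classify")


@dataclass(eq=False)
class ExperimentConfig:
    """Everything one run needs, serialisable to YAML."""

    seed: int = 0
    window: float = 5.0
    sub_window: float = 1.0
    v_stop: float = 3.0
    edge_trim: float = 0.5
    f_low: float = 1.0
    f_high: float = 10.0
    ar_order: int = 10
    n_pcs: int = 4
    classifier: dict = field(default_factory=lambda: {"kind": "llgmn",
                                                      "n_components": 2})
    fish: list[dict] = field(default_factory=list)  # empty -> default cohort

    def validate(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError("need 0 < f_low < f_high")
        if self.window <= 0 or self.sub_window <= 0 or self.sub_window > self.window:
            raise ValueError("need 0 < sub_window <= window")
        if not (1 <= self.n_pcs <= 6):
            raise ValueError("n_pcs must be in 1..6")
        ids = [f["fish_id"] for f in self.fish]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate fish ids")

    def cohort_config(self) -> CohortConfig:
        if not self.fish:
            cfg = default_cohort_config(self.seed)
        else:
            ss = np.random.SeedSequence(self.seed)
            seeds = ss.generate_state(len(self.fish)) % (2 ** 31)
            cfg = CohortConfig(fish=[
                FishPlan(
                    fish_id=f["fish_id"], states=tuple(f["states"]),
                    duration=float(f.get("duration", 300.0)),
                    seed=int(f.get("seed", seeds[i])),
                )
                for i, f in enumerate(self.fish)
            ])
        cfg.window = self.window
        cfg.sub_window = self.sub_window
        cfg.v_stop = self.v_stop
        cfg.edge_trim = self.edge_trim
        return cfg

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_stage(name: str, config: ExperimentConfig, outdir,
              inputs: dict | None = None) -> dict:
    """Run one stage standalone; upstream artefacts come from ``inputs``.

    Stage names: ``simulate`` (ground-truth cohort), ``indices`` (index-window
    table), ``stats`` (per-index/PC tests + loadings), ``classify``
    (cross-validated report).  ``indices`` and ``simulate`` are fused here
    because the index-level cohort generator produces windows directly.
    """
    if name not in _STAGES:
        raise ValueError(f"unknown stage {name!r}; expected one of {_STAGES}")
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = inputs or {}

    if name in ("simulate", "indices"):
        table = generate_cohort(config.cohort_config())
        path = outdir / "index_windows.csv"
        table.to_csv(path, index=False)
        return {"table": table, "path": path}

    if "table" in inputs:
        table = inputs["table"]
    elif "table_path" in inputs:
        table = pd.read_csv(inputs["table_path"])
    else:
        raise FileNotFoundError("stats/classify stages need an index table "
                                "(pass inputs['table'] or inputs['table_path'])")

    if name == "stats":
        states = list(dict.fromkeys(table["state"]))
        results = {}
        for col in INDEX_COLUMNS:
            groups = [table.loc[table["state"] == s, col] for s in states]
            if len(groups) >= 3:
                r = one_way_anova(*groups)
                results[col] = {"anova_F": r.statistic, "df": r.df, "p": r.pvalue}
            else:
                r = welch_t(groups[0], groups[1])
                results[col] = {"welch_t": r.statistic, "df": r.df, "p": r.pvalue}
        pc = pca_fit(table)
        scores = pca_scores(pc, table)
        for j in range(scores.shape[1]):
            groups = [scores.loc[(table["state"] == s).to_numpy(), f"pc{j+1}"]
                      for s in states]
            if len(groups) >= 3:
                r = one_way_anova(*groups)
                results[f"pc{j+1}"] = {"anova_F": r.statistic, "df": r.df,
                                       "p": r.pvalue}
        loadings = pd.DataFrame(pc.loadings, index=INDEX_COLUMNS,
                                columns=[f"pc{j+1}" for j in range(6)])
        lpath = outdir / "pc_loadings.csv"
        loadings.to_csv(lpath)
        spath = outdir / "stats.json"
        spath.write_text(json.dumps(results, indent=2, default=float))
        return {"stats": results, "loadings": loadings,
                "path": spath, "loadings_path": lpath}

    # classify
    report = loo_fish_cv(table, config.classifier, n_pcs=config.n_pcs)
    rpath = outdir / "classifier_report.json"
    rpath.write_text(json.dumps(report.to_dict(), indent=2))
    ppath = outdir / "predictions.csv"
    report.predictions.to_csv(ppath, index=False)
    shifts = {}
    for treated in ("fear", "appetitive"):
        sub = report.predictions[
            report.predictions["fish_id"].isin(
                set(table.loc[table["state"] == treated, "fish_id"]))
        ]
        if len(sub) and treated in set(sub["state"]):
            shifts[treated] = posterior_shift_analysis(sub, "normal", treated)
    return {"report": report, "path": rpath, "predictions_path": ppath,
            "posterior_shifts": shifts}


def run_pipeline(config: ExperimentConfig, outdir) -> dict:
    """Run all stages in order and return the artefact manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    artefacts: dict[str, Path] = {"config": outdir / "config.yaml"}
    try:
        sim = run_stage("indices", config, outdir)
        artefacts["index_windows"] = sim["path"]
        stats = run_stage("stats", config, outdir, inputs={"table": sim["table"]})
        artefacts["stats"] = stats["path"]
        artefacts["pc_loadings"] = stats["loadings_path"]
        clf = run_stage("classify", config, outdir, inputs={"table": sim["table"]})
        artefacts["classifier_report"] = clf["path"]
        artefacts["predictions"] = clf["predictions_path"]
    except Exception as err:  # re-raise with stage context
        raise RuntimeError(f"pipeline aborted: {err}") from err
    manifest = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "artefacts": {k: {"path": str(p), "sha256": _sha256(p)}
                      for k, p in artefacts.items()},
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    manifest["manifest_path"] = str(mpath)
    return manifest
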