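"""Reproducible pipeline: simulate -> extract -> table1 -> reduce -> search -> report.

Each stage writes its artifact plus a manifest (stage name, parameters, seed,
package version) into the run directory; outputs are a pure function of the
configuration and seed, so re-running an identical configuration reproduces
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import ExtractionParams, extract_features
from .lasso import LassoLogisticCV
from .search import run_group_search, standard_groups
from .stats import GroupSummary, fisher_exact, welch_t_from_summaries
from .synthetic import (
    CATEGORICAL_COLUMNS,
    PhantomSpec,
    SyntheticConfig,
    generate_cohort,
    generate_phantom,
    read_cohort,
    write_cohort,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_table1_report", "ALL_STAGES"]

ALL_STAGES = ("simulate", "extract", "table1", "reduce", "search", "report")


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (overridable from YAML / CLI flags)."""

    outdir: str = "pcrad_run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "table1", "reduce", "search", "report")
    n_responders: int = 20
    n_nonresponders: int = 40
    n_phantoms: int = 0
    target_spacing: float = 0.90
    n_bins: int = 8
    normalization_scale: float = 100.0
    groups: tuple[str, ...] = ("G1", "Rad", "Hist", "NoRad", "All")
    classifiers: tuple[str, ...] = ("logit",)
    subset_cap: int = 2**14
    ci_level: float = 0.95
    aggregation: str = "printed"
    radiomic_columns: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5")

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("stages", "groups", "classifiers", "radiomic_columns"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("stages", "groups", "classifiers", "radiomic_columns"):
            d[key] = list(d[key])
        return d


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _manifest(config: PipelineConfig, outdir: Path, stage: str, inputs: list[str],
              outputs: list[str]) -> None:
    _write_json(
        {
            "stage": stage,
            "inputs": inputs,
            "outputs": outputs,
            "seed": config.seed,
            "parameters": config.to_dict(),
            "version": __version__,
        },
        outdir / f"manifest_{stage}.json",
    )


def make_table1_report(table: pd.DataFrame, outcome: str = "pCR") -> pd.DataFrame:
    """Per-covariate group summaries with the appropriate univariate test.

    Continuous covariates get per-group n/mean/sd and a Welch t-test;
    categorical covariates get per-group level counts and an exact Fisher
    test.  Single-level categoricals are dropped with a warning.
    """
    if outcome not in table.columns:
        raise ValueError(f"outcome column '{outcome}' missing")
    y = table[outcome].astype(int)
    rows = []
    for col in table.columns:
        if col == outcome:
            continue
        if pd.api.types.is_numeric_dtype(table[col]) and col not in CATEGORICAL_COLUMNS:
            g1 = table.loc[y == 1, col]
            g2 = table.loc[y == 0, col]
            res = welch_t_from_summaries(
                GroupSummary(len(g1), float(g1.mean()), float(g1.std(ddof=1))),
                GroupSummary(len(g2), float(g2.mean()), float(g2.std(ddof=1))),
            )
            rows.append(
                {
                    "covariate": col,
                    "test": "welch",
                    "responders": f"{g1.mean():.3g} (±{g1.std(ddof=1):.3g})",
                    "nonresponders": f"{g2.mean():.3g} (±{g2.std(ddof=1):.3g})",
                    "p": res.p,
                }
            )
        else:
            levels = sorted(table[col].astype(str).unique())
            if len(levels) < 2:
                warnings.warn(f"dropping single-level categorical '{col}'", stacklevel=2)
                continue
            counts = np.array(
                [
                    [(table.loc[y == 1, col].astype(str) == lv).sum() for lv in levels],
                    [(table.loc[y == 0, col].astype(str) == lv).sum() for lv in levels],
                ]
            ).T  # levels x groups
            p = fisher_exact(counts)
            rows.append(
                {
                    "covariate": col,
                    "test": "fisher",
                    "responders": "/".join(f"{lv}:{c}" for lv, c in zip(levels, counts[:, 0])),
                    "nonresponders": "/".join(f"{lv}:{c}" for lv, c in zip(levels, counts[:, 1])),
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    cohort = generate_cohort(
        SyntheticConfig(
            n_responders=config.n_responders,
            n_nonresponders=config.n_nonresponders,
            seed=config.seed,
        )
    )
    write_cohort(cohort, outdir / "cohort.tsv")
    outputs = ["cohort.tsv"]
    from .image import write_volume

    for k in range(config.n_phantoms):
        spec = PhantomSpec(seed=config.seed + k + 1)
        dyn, sub, mask = generate_phantom(spec)
        for name, vol in (("dynamic", dyn), ("subtracted", sub), ("mask", mask)):
            path = outdir / f"phantom{k:03d}_{name}.nii.gz"
            write_volume(vol, path)
            outputs.append(path.name)
    _manifest(config, outdir, "simulate", [], outputs)


def _stage_extract(config: PipelineConfig, outdir: Path) -> None:
    from .image import read_volume

    params = ExtractionParams(
        target_spacing=config.target_spacing,
        n_bins=config.n_bins,
        normalization_scale=config.normalization_scale,
    )
    rows = []
    for dyn_path in sorted(outdir.glob("phantom*_dynamic.nii.gz")):
        stem = dyn_path.name.replace("_dynamic.nii.gz", "")
        dyn = read_volume(dyn_path)
        sub = read_volume(outdir / f"{stem}_subtracted.nii.gz")
        mask = read_volume(outdir / f"{stem}_mask.nii.gz", as_mask=True)
        vec = extract_features(dyn, sub, mask, params)
        rows.append({"subject": stem, **vec.as_dict(),
                     "channel_dynamic": "F2,F4,F5", "channel_subtracted": "F1,F3",
                     "target_spacing": params.target_spacing, "n_bins": params.n_bins})
    if not rows:
        raise FileNotFoundError("extract stage found no phantom volumes in the run directory")
    pd.DataFrame(rows).to_csv(outdir / "features.tsv", sep="\t", index=False)
    _manifest(config, outdir, "extract", ["phantom*"], ["features.tsv"])


def _stage_table1(config: PipelineConfig, outdir: Path) -> None:
    cohort = read_cohort(outdir / "cohort.tsv")
    report = make_table1_report(cohort)
    report.to_csv(outdir / "table1.tsv", sep="\t", index=False)
    _manifest(config, outdir, "table1", ["cohort.tsv"], ["table1.tsv"])


def _stage_reduce(config: PipelineConfig, outdir: Path) -> None:
    cohort = read_cohort(outdir / "cohort.tsv")
    X = cohort.loc[:, list(config.radiomic_columns)]
    est = LassoLogisticCV().fit(X, cohort["pCR"])
    _write_json(
        {
            "lambda_grid": est.path_.lambda_grid.tolist(),
            "cv_deviance": est.path_.cv_deviance.tolist(),
            "lambda_min": est.lambda_min_,
            "coefficients_at_lambda_min": dict(zip(est.path_.names, est.coef_.tolist())),
            "selected": list(est.selected_),
        },
        outdir / "reduce.json",
    )
    _manifest(config, outdir, "reduce", ["cohort.tsv"], ["reduce.json"])


def _stage_search(config: PipelineConfig, outdir: Path) -> None:
    cohort = read_cohort(outdir / "cohort.tsv")
    groups = standard_groups()
    results = {}
    for gname in config.groups:
        results[gname] = {}
        for clf in config.classifiers:
            report = run_group_search(
                cohort, groups[gname], classifier=clf,
                subset_cap=config.subset_cap, seed=config.seed,
                ci_level=config.ci_level, aggregation=config.aggregation,
            )
            results[gname][clf] = report.to_dict()
    _write_json(results, outdir / "search.json")
    _manifest(config, outdir, "search", ["cohort.tsv"], ["search.json"])


def _stage_report(config: PipelineConfig, outdir: Path) -> None:
    search = json.loads((outdir / "search.json").read_text())
    best6_rows, freq_rows, magg_rows = [], [], []
    for gname, per_clf in search.items():
        for clf, rep in per_clf.items():
            for rank, m in enumerate(rep["best6"], start=1):
                best6_rows.append(
                    {"group": gname, "classifier": clf, "rank": rank,
                     "subset": "+".join(m["subset"]), "auc_mean": m["auc_mean"],
                     "ci_lo": m["ci"][0], "ci_hi": m["ci"][1], "p_adj": m["p_adj"]}
                )
            for cov, f in rep["frequency"].items():
                freq_rows.append({"group": gname, "classifier": clf,
                                  "covariate": cov, "frequency": f})
            if clf == "logit":
                for col, v in rep["m_agg"].items():
                    magg_rows.append({"group": gname, "column": col, "m_agg": v})
    pd.DataFrame(best6_rows).to_csv(outdir / "best6_auc.tsv", sep="\t", index=False)
    pd.DataFrame(freq_rows).to_csv(outdir / "frequencies.tsv", sep="\t", index=False)
    pd.DataFrame(magg_rows).to_csv(outdir / "m_agg.tsv", sep="\t", index=False)
    summary = {
        "groups": {g: {c: {"best_auc_mean": per_clf[c]["best6"][0]["auc_mean"],
                           "mean_p_adj_best6": per_clf[c]["mean_p_adj_best6"]}
                       for c in per_clf}
                   for g, per_clf in search.items()},
        "seed": config.seed,
        "version": __version__,
    }
    _write_json(summary, outdir / "report.json")
    _manifest(config, outdir, "report",
              ["search.json"], ["best6_auc.tsv", "frequencies.tsv", "m_agg.tsv", "report.json"])


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "table1": _stage_table1,
    "reduce": _stage_reduce,
    "search": _stage_search,
    "report": _stage_report,
}


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> Path:
    """Execute the enabled stages in canonical order; returns the run directory.

    A stage failure raises an error naming the stage; artifacts of completed
    stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = stages if stages is not None else config.stages
    for stage in ALL_STAGES:
        if stage not in enabled:
            continue
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return outdir
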