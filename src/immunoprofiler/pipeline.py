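"""Stage orchestration: run the analysis stages against an output directory.

Each stage reads its upstream outputs from the run directory, writes its own
outputs, and appends a manifest entry (inputs, parameters, seed, sha256 of
every output) so any file is traceable and deterministic stages reproduce
hash-identical results on rerun.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .clustering import consensus_cluster
from .diffexp import de_test
from .nanostring import assemble_counts, read_panel, read_rcc, tis_signature, write_panel, write_rcc
from .qc import factors_frame, normalize, qc_filter, qc_report_frame
from .scoring import linear_score, log2_transform
from .survival import bootstrap_cutoff_p, stratify_composite
from .tmb import tmb_per_sample

STAGES = ("simulate", "qc", "normalize", "score", "cluster", "diffexp", "survival", "tmb", "all")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    preset: str = "full_cohort"
    scale: float = 0.1
    qc_threshold: float = 100.0
    floor: float = 1.0
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 100
    subsample_frac: float = 0.8
    minprop: float = 0.1
    n_boot: int = 200
    boot_frac: float = 0.9
    tis_cut: float = 9.0
    tmb_cut: float = 100.0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
        if "out_dir" not in kwargs:
            raise ValueError("config must set out_dir")
        kwargs["out_dir"] = Path(kwargs["out_dir"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _append_manifest(out_dir: Path, stage: str, inputs: list[str], params: dict,
                     seed: int, outputs: list[Path]) -> None:
    manifest_path = out_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else []
    manifest.append({
        "stage": stage, "inputs": inputs, "params": params, "seed": seed,
        "outputs": {p.name: _sha256(p) for p in outputs},
    })
    manifest_path.write_text(json.dumps(manifest, indent=2))


def _require(out_dir: Path, filename: str, producing_stage: str) -> Path:
    path = out_dir / filename
    if not path.exists():
        raise FileNotFoundError(
            f"missing {filename}: run the {producing_stage!r} stage first")
    return path


def _cohort_config(config: RunConfig) -> sim.CohortConfig:
    presets = {
        "full_cohort": lambda: sim.full_cohort_config(config.seed, scale=config.scale),
        "braf_cluster": lambda: sim.braf_cluster_config(config.seed),
        "de": lambda: sim.de_config(config.seed),
        "survival_threshold": lambda: sim.survival_threshold_config(config.seed),
        "mmrd": lambda: sim.mmrd_config(config.seed),
        "null": lambda: sim.null_config(config.seed),
    }
    if config.preset not in presets:
        raise ValueError(f"unknown preset {config.preset!r}; options: {sorted(presets)}")
    return presets[config.preset]()


def run_stage(name: str, config: RunConfig) -> list[Path]:
    """Run one stage (or 'all'); returns the paths written."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; options: {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "all":
        written: list[Path] = []
        for stage in ("simulate", "qc", "normalize", "score", "cluster",
                      "diffexp", "survival", "tmb"):
            written += run_stage(stage, config)
        return written
    return _STAGE_FUNCS[name](config, out)


def _stage_simulate(config: RunConfig, out: Path) -> list[Path]:
    cohort = _cohort_config(config)
    samples, panel, truth = sim.simulate_counts(cohort)
    surv: pd.DataFrame | None = None
    rcc_dir = out / "rcc"
    rcc_dir.mkdir(exist_ok=True)
    outputs = []
    for s in samples:
        outputs.append(write_rcc(s, panel, rcc_dir / f"{s.sample_id}.rcc"))
    outputs.append(write_panel(panel, out / "panel.csv"))
    variants, planted = sim.simulate_variants(truth, cohort)
    truth = truth.merge(planted, on="sample_id")
    surv = sim.simulate_survival(truth, cohort)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    outputs += [out / "truth.tsv", out / "survival.tsv", out / "variants.tsv"]
    _append_manifest(out, "simulate", [], {"preset": config.preset, "scale": config.scale},
                     config.seed, outputs)
    return outputs


def _load_raw(config: RunConfig, out: Path):
    panel = read_panel(_require(out, "panel.csv", "simulate"))
    rcc_dir = out / "rcc"
    if not rcc_dir.exists():
        raise FileNotFoundError("missing rcc/: run the 'simulate' stage first")
    samples = [read_rcc(p) for p in sorted(rcc_dir.glob("*.rcc"))]
    return panel, assemble_counts(samples, panel)


def _stage_qc(config: RunConfig, out: Path) -> list[Path]:
    panel, counts = _load_raw(config, out)
    reports, passed = qc_filter(counts, panel, threshold=config.qc_threshold,
                                floor=config.floor)
    qc_path = out / "qc_report.tsv"
    qc_report_frame(reports).to_csv(qc_path, sep="\t", index=False)
    raw_path = out / "raw_counts.tsv"
    passed.data.to_csv(raw_path, sep="\t")
    _append_manifest(out, "qc", ["rcc/", "panel.csv"],
                     {"threshold": config.qc_threshold}, config.seed, [qc_path, raw_path])
    return [qc_path, raw_path]


def _stage_normalize(config: RunConfig, out: Path) -> list[Path]:
    panel = read_panel(_require(out, "panel.csv", "simulate"))
    raw = pd.read_csv(_require(out, "raw_counts.tsv", "qc"), sep="\t", index_col=0)
    from .nanostring import CountsMatrix
    norm = normalize(CountsMatrix(data=raw, stage="raw"), panel, floor=config.floor)
    norm_path = out / "normalized_counts.tsv"
    norm.data.to_csv(norm_path, sep="\t")
    fac_path = out / "normalization_factors.json"
    fac_path.write_text(factors_frame(norm).to_json(indent=2))
    _append_manifest(out, "normalize", ["raw_counts.tsv", "panel.csv"],
                     {"floor": config.floor}, config.seed, [norm_path, fac_path])
    return [norm_path, fac_path]


def _load_expression(config: RunConfig, out: Path):
    from .nanostring import CountsMatrix
    panel = read_panel(_require(out, "panel.csv", "simulate"))
    norm = pd.read_csv(_require(out, "normalized_counts.tsv", "normalize"),
                       sep="\t", index_col=0)
    counts = CountsMatrix(data=norm, stage="fully_normalized")
    expr = log2_transform(counts, floor=config.floor)
    endo = [g for g in panel.endogenous_probes if g in expr.data.index]
    expr.data = expr.data.loc[endo]
    return panel, expr


def _stage_score(config: RunConfig, out: Path) -> list[Path]:
    _, expr = _load_expression(config, out)
    tis = tis_signature()
    scores = linear_score(expr, tis)
    path = out / "scores.tsv"
    scores.rename("TIS").to_frame().to_csv(path, sep="\t")
    _append_manifest(out, "score", ["normalized_counts.tsv"],
                     {"signature": "TIS", **tis.metadata}, config.seed, [path])
    return [path]


def _stage_cluster(config: RunConfig, out: Path) -> list[Path]:
    _, expr = _load_expression(config, out)
    result = consensus_cluster(expr, k_range=range(config.k_min, config.k_max + 1),
                               n_resamples=config.n_resamples,
                               subsample_frac=config.subsample_frac, seed=config.seed)
    assign_path = out / "cluster_assignments.tsv"
    pd.DataFrame({f"k{k}": result.assignments[k] for k in result.k_range}) \
        .rename_axis("sample_id").to_csv(assign_path, sep="\t")
    diag_path = out / "cluster_diagnostics.json"
    diag_path.write_text(json.dumps({
        "chosen_k": result.chosen_k, "low_confidence": result.low_confidence,
        "area": result.area, "delta_area": result.delta_area,
        "consensus_gap": result.consensus_gap, "seed": result.rng_seed}, indent=2))
    _append_manifest(out, "cluster", ["normalized_counts.tsv"],
                     {"k_range": [config.k_min, config.k_max],
                      "n_resamples": config.n_resamples,
                      "subsample_frac": config.subsample_frac},
                     config.seed, [assign_path, diag_path])
    return [assign_path, diag_path]


def _stage_diffexp(config: RunConfig, out: Path) -> list[Path]:
    _, expr = _load_expression(config, out)
    truth = pd.read_csv(_require(out, "truth.tsv", "simulate"), sep="\t")
    truth = truth[truth["sample_id"].isin(expr.samples)]
    group_names = truth["group"].unique()
    if len(group_names) < 2:
        raise ValueError("diffexp needs at least two groups in the cohort")
    a, b = group_names[:2]
    res = de_test(expr,
                  truth.loc[truth["group"] == a, "sample_id"].tolist(),
                  truth.loc[truth["group"] == b, "sample_id"].tolist())
    path = out / "de_results.tsv"
    res.to_csv(path, sep="\t")
    _append_manifest(out, "diffexp", ["normalized_counts.tsv", "truth.tsv"],
                     {"group_a": str(a), "group_b": str(b)}, config.seed, [path])
    return [path]


def _stage_survival(config: RunConfig, out: Path) -> list[Path]:
    scores = pd.read_csv(_require(out, "scores.tsv", "score"), sep="\t", index_col=0)["TIS"]
    surv = pd.read_csv(_require(out, "survival.tsv", "simulate"), sep="\t")
    surv = surv[surv["sample_id"].isin(scores.index)]
    result = bootstrap_cutoff_p(scores, surv, n_boot=config.n_boot,
                                frac=config.boot_frac, seed=config.seed,
                                minprop=config.minprop)
    path = out / "survival_results.json"
    path.write_text(json.dumps({
        "cutoff": result.cutoff, "statistic": result.statistic,
        "logrank_p_full": result.logrank_p_full, "bootstrap_p": result.bootstrap_p,
        "n_boot": result.n_boot, "frac": result.frac, "minprop": result.minprop,
        "n": result.n, "seed": result.seed, "n_skipped": result.n_skipped}, indent=2))
    groups_path = out / "survival_groups.tsv"
    result.groups.rename("group").rename_axis("sample_id").to_frame() \
        .to_csv(groups_path, sep="\t")
    _append_manifest(out, "survival", ["scores.tsv", "survival.tsv"],
                     {"n_boot": config.n_boot, "frac": config.boot_frac,
                      "minprop": config.minprop}, config.seed, [path, groups_path])
    return [path, groups_path]


def _stage_tmb(config: RunConfig, out: Path) -> list[Path]:
    variants = pd.read_csv(_require(out, "variants.tsv", "simulate"), sep="\t")
    table = tmb_per_sample(variants)
    path = out / "tmb.tsv"
    table.to_csv(path, sep="\t")
    _append_manifest(out, "tmb", ["variants.tsv"], {}, config.seed, [path])
    return [path]


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "qc": _stage_qc, "normalize": _stage_normalize,
    "score": _stage_score, "cluster": _stage_cluster, "diffexp": _stage_diffexp,
    "survival": _stage_survival, "tmb": _stage_tmb,
}
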