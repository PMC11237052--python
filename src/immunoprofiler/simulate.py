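"""Synthetic cohort generator.

Emits complete cohorts — RCC-writable samples, panel definition, clinical
truth tables, survival times, and somatic variant tables — with the
statistical structure the downstream analyses assume:

* a per-sample *lane efficiency* (lognormal) multiplying every probe, which
  positive-control normalization removes;
* a per-sample *RNA content* factor (lognormal) multiplying housekeeping and
  endogenous probes, which housekeeping normalization removes;
* endogenous immune genes driven by a single latent infiltration level z per
  sample (group-specific mean/sd), counts negative-binomial around
  2^(a_g + beta_g * z);
* a planted fraction of degraded samples whose RNA-derived counts are
  suppressed below the housekeeping QC threshold;
* survival times with hazard depending on the latent inflammation score
  (log-linear, threshold, or composite TIS x TMB group models), with
  independent exponential censoring;
* per-sample variant tables whose post-filter SNV counts land in planted
  non-/hyper-/ultra-hypermutant burden classes, independent of inflammation.

Every draw is governed by a single seed; truth tables are always returned
next to the data (no hidden state).  Preset builders at the bottom encode
the cohort compositions and effect sizes the analyses are exercised at.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .nanostring import (POSITIVE_LADDER_FM, PanelDefinition, RawSample,
                         SignatureDefinition, tis_signature)

HK_GENES = ("DDX50", "EIF2B4", "MRPS5", "SAP130", "TLK2")
HK_LOG2_MEANS = (9.3, 9.8, 9.0, 9.6, 9.2)

# Non-TIS immune genes carried on the panel (infiltration-loaded).
EXTRA_IMMUNE_GENES = (
    "CD3E", "CD4", "CD68", "CD163", "FOXP3", "PDCD1", "HAVCR2", "CTLA4",
    "CSF1R", "CD47", "NT5E", "IL12A", "IL12B", "IFNG", "GZMB", "PRF1",
    "CD2", "ITGAM", "MRC1", "ARG1", "TNF", "IL10",
)

#: Baseline inflammation score of the reference (non-tumor) state and the
#: score gained per unit of latent infiltration; see `build_panel_model`.
REFERENCE_TIS = 7.66
TIS_SLOPE = 0.736


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n: int
    infiltration_mean: float
    infiltration_sd: float = 0.5


@dataclass(frozen=True)
class SurvivalModel:
    """Event-time model; times are in months.

    model = 'linear':    hazard = baseline * exp(log_hr_per_unit * (score - reference))
    model = 'threshold': hazard = baseline * hazard_ratio^[score > threshold]
    model = 'composite': hazard looked up per TIS x TMB composite group.
    """
    model: str = "linear"
    baseline_hazard: float = 0.03
    log_hr_per_unit: float = 0.8
    reference_score: float = REFERENCE_TIS
    threshold: float = 9.0
    hazard_ratio: float = 3.0
    composite_hazards: dict = field(default_factory=dict)
    tis_cut: float = 9.0
    censor_rate: float = 0.01
    max_follow_up: float | None = None


@dataclass(frozen=True)
class TMBModel:
    """Planted mutation-burden classes and per-class TMB distributions."""
    class_proportions: tuple[float, float, float] = (0.7, 0.2, 0.1)  # non, hyper, ultra
    non_median: float = 3.0
    non_sigma: float = 0.8
    hyper_range: tuple[float, float] = (12.0, 95.0)
    ultra_median: float = 355.0
    ultra_sigma: float = 0.45
    callable_mb: float = 50.0
    decoy_frac: float = 0.12     # extra variants that the somatic filter removes
    indel_frac: float = 0.03     # kept indels (excluded from the SNV numerator)


@dataclass(frozen=True)
class QCModel:
    fail_frac: float = 0.0
    degradation: float = 0.05    # RNA-content multiplier for degraded samples


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...]
    seed: int = 0
    n_endogenous: int = 103
    dispersion: float = 0.01     # NB overdispersion (var = mu + phi mu^2)
    lane_sd: float = 0.2         # lognormal sd, lane efficiency
    content_sd: float = 0.35     # lognormal sd, RNA content
    counts_per_fm: float = 60.0  # positive-control counts per fM
    count_noise: bool = True     # False: counts = round(mean), for degenerate checks
    pos_ladder: tuple[float, ...] = POSITIVE_LADDER_FM
    group_gene_offsets: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()
    qc: QCModel = field(default_factory=QCModel)
    survival: SurvivalModel = field(default_factory=SurvivalModel)
    tmb: TMBModel = field(default_factory=TMBModel)

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("config has no groups")
        if any(g.n < 1 for g in self.groups):
            raise ValueError("group sizes must be >= 1")
        if any(g.infiltration_sd < 0 for g in self.groups):
            raise ValueError("infiltration sd must be >= 0")
        if self.dispersion < 0 or self.lane_sd < 0 or self.content_sd < 0:
            raise ValueError("variances must be >= 0")
        if not (0 <= self.qc.fail_frac < 1):
            raise ValueError("qc fail_frac must be in [0, 1)")
        props = self.tmb.class_proportions
        if abs(sum(props) - 1) > 1e-9 or any(p < 0 for p in props):
            raise ValueError("tmb class proportions must be nonnegative and sum to 1")


@dataclass
class PanelModel:
    """Per-probe generative parameters: baseline log2 mean and latent loading."""
    panel: PanelDefinition
    baseline_log2: pd.Series  # endogenous + HK probes
    loading: pd.Series        # beta_g, endogenous probes (0 for background)
    tis: SignatureDefinition


def build_panel_model(config: CohortConfig, rng: np.random.Generator) -> PanelModel:
    """Construct the panel and its generative parameters.

    The signature genes' baselines and loadings are jittered but projected so
    that the weighted baseline sum equals REFERENCE_TIS and the weighted
    loading sum equals TIS_SLOPE — i.e. a sample's expected inflammation
    score is REFERENCE_TIS + TIS_SLOPE * z exactly.
    """
    tis = tis_signature()
    w = tis.entries
    n_named = len(tis.genes) + len(EXTRA_IMMUNE_GENES)
    n_background = config.n_endogenous - n_named
    if n_background < 0:
        raise ValueError(f"n_endogenous must be >= {n_named}")
    background = [f"BACK{i + 1:03d}" for i in range(n_background)]
    endo = list(tis.genes) + list(EXTRA_IMMUNE_GENES) + background

    baseline = pd.Series(0.0, index=endo + list(HK_GENES))
    loading = pd.Series(0.0, index=endo)

    # TIS genes: jitter, then project onto the weight-sum constraints.
    jb = rng.uniform(-1.2, 1.2, size=len(w))
    jb -= (w.to_numpy() @ jb) / w.sum()
    baseline[tis.genes] = REFERENCE_TIS / w.sum() + jb
    jl = rng.uniform(-0.2, 0.2, size=len(w))
    jl -= (w.to_numpy() @ jl) / w.sum()
    loading[tis.genes] = TIS_SLOPE / w.sum() + jl

    baseline[list(EXTRA_IMMUNE_GENES)] = rng.uniform(5.0, 9.0, size=len(EXTRA_IMMUNE_GENES))
    loading[list(EXTRA_IMMUNE_GENES)] = rng.uniform(0.4, 0.9, size=len(EXTRA_IMMUNE_GENES))
    if background:
        baseline[background] = rng.uniform(4.0, 10.0, size=len(background))
    baseline[list(HK_GENES)] = HK_LOG2_MEANS

    pos = [f"POS_{chr(ord('A') + i)}" for i in range(len(config.pos_ladder))]
    neg = [f"NEG_{chr(ord('A') + i)}" for i in range(8)]
    rows = ([(g, "Endogenous", f"NM_{i + 1:06d}.1", 0.0) for i, g in enumerate(endo)]
            + [(g, "Housekeeping", f"NM_HK{i + 1:04d}.1", 0.0) for i, g in enumerate(HK_GENES)]
            + [(p, "Positive", f"POS_{i}", conc) for i, (p, conc) in enumerate(zip(pos, config.pos_ladder))]
            + [(p, "Negative", f"NEG_{i}", 0.0) for i, p in enumerate(neg)])
    panel = PanelDefinition(table=pd.DataFrame(
        rows, columns=["probe", "code_class", "accession", "expected_conc_fM"]))
    return PanelModel(panel=panel, baseline_log2=baseline, loading=loading, tis=tis)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; Poisson when dispersion=0."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(config: CohortConfig
                    ) -> tuple[list[RawSample], PanelDefinition, pd.DataFrame]:
    """Draw a cohort of raw samples plus the ground-truth table.

    Truth columns: sample_id, group, z (latent infiltration), lane_eff,
    content, degraded, expected_tis.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = build_panel_model(config, rng)
    panel = model.panel

    n_total = sum(g.n for g in config.groups)
    groups = np.concatenate([[g.name] * g.n for g in config.groups])
    z = np.concatenate([rng.normal(g.infiltration_mean, g.infiltration_sd, size=g.n)
                        for g in config.groups])
    order = rng.permutation(n_total)  # interleave groups across the run order
    groups, z = groups[order], z[order]

    lane_eff = rng.lognormal(mean=0.0, sigma=config.lane_sd, size=n_total)
    content = rng.lognormal(mean=0.0, sigma=config.content_sd, size=n_total)

    n_fail = int(round(config.qc.fail_frac * n_total))
    degraded = np.zeros(n_total, dtype=bool)
    degraded[rng.choice(n_total, size=n_fail, replace=False)] = True

    offsets = {name: dict(entries) for name, entries in config.group_gene_offsets}
    endo = model.loading.index.tolist()
    hk = list(HK_GENES)
    pos = panel.positive_probes
    neg = panel.probes_of_class("Negative")
    pos_conc = panel.table.set_index("probe").loc[pos, "expected_conc_fM"].to_numpy()

    base_endo = model.baseline_log2[endo].to_numpy()
    beta = model.loading.to_numpy()
    base_hk = model.baseline_log2[hk].to_numpy()

    samples: list[RawSample] = []
    ids = [f"S{i + 1:04d}" for i in range(n_total)]
    for i in range(n_total):
        log2_mean = base_endo + beta * z[i]
        off = offsets.get(groups[i])
        if off:
            log2_mean = log2_mean + np.array([off.get(g, 0.0) for g in endo])
        rna_scale = lane_eff[i] * content[i] * (config.qc.degradation if degraded[i] else 1.0)
        counts: dict[str, int] = {}
        if config.count_noise:
            endo_counts = _nb_draw(rng, rna_scale * np.exp2(log2_mean), config.dispersion)
            hk_counts = _nb_draw(rng, rna_scale * np.exp2(base_hk), config.dispersion)
            pos_counts = rng.poisson(lane_eff[i] * config.counts_per_fm * pos_conc)
            neg_counts = rng.poisson(np.full(len(neg), 5.0))
        else:
            endo_counts = np.round(rna_scale * np.exp2(log2_mean))
            hk_counts = np.round(rna_scale * np.exp2(base_hk))
            pos_counts = np.round(lane_eff[i] * config.counts_per_fm * pos_conc)
            neg_counts = np.full(len(neg), 5)
        for names, vals in ((endo, endo_counts), (hk, hk_counts),
                            (pos, pos_counts), (neg, neg_counts)):
            counts.update(zip(names, (int(v) for v in vals)))
        samples.append(RawSample(
            sample_id=ids[i], counts=counts,
            sample_attributes={"ID": ids[i], "Owner": "synthetic"},
            lane_attributes={"ID": str(i % 12 + 1), "BindingDensity": "0.5"}))

    truth = pd.DataFrame({
        "sample_id": ids, "group": groups, "z": z,
        "lane_eff": lane_eff, "content": content, "degraded": degraded,
        "expected_tis": REFERENCE_TIS + TIS_SLOPE * z,
    })
    return samples, panel, truth


def simulate_survival(truth: pd.DataFrame, config: CohortConfig,
                      seed_offset: int = 1) -> pd.DataFrame:
    """Exponential event times whose hazard follows the configured model,
    with independent exponential censoring (sample_id, time, event)."""
    sv = config.survival
    rng = np.random.default_rng(config.seed + seed_offset)
    score = truth["expected_tis"].to_numpy(float)
    if sv.model == "linear":
        hazard = sv.baseline_hazard * np.exp(sv.log_hr_per_unit * (score - sv.reference_score))
    elif sv.model == "threshold":
        hazard = sv.baseline_hazard * np.power(sv.hazard_ratio, (score > sv.threshold).astype(float))
    elif sv.model == "composite":
        if "tmb_class" not in truth.columns:
            raise ValueError("composite survival model requires a tmb_class truth column")
        tis_hi = score > sv.tis_cut
        tmb_hi = truth["tmb_class"].to_numpy() == "ultra"
        labels = np.where(tis_hi, "TIS-hi", "TIS-lo")
        labels = np.char.add(np.char.add(labels, "/"), np.where(tmb_hi, "TMB-hi", "TMB-lo"))
        try:
            hazard = np.array([sv.composite_hazards[l] for l in labels])
        except KeyError as exc:
            raise ValueError(f"composite_hazards missing group {exc}") from exc
    else:
        raise ValueError(f"unknown survival model {sv.model!r}")
    if np.any(hazard <= 0) or sv.censor_rate < 0:
        raise ValueError("hazards must be positive and censor_rate >= 0")

    t_event = rng.exponential(1.0 / hazard)
    if sv.censor_rate > 0:
        t_censor = rng.exponential(1.0 / sv.censor_rate, size=len(t_event))
    else:
        t_censor = np.full(len(t_event), np.inf)
    if sv.max_follow_up is not None:
        t_censor = np.minimum(t_censor, sv.max_follow_up)
    time = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    return pd.DataFrame({"sample_id": truth["sample_id"].to_numpy(),
                         "time": np.maximum(time, 1e-6), "event": event})


def simulate_variants(truth: pd.DataFrame, config: CohortConfig,
                      seed_offset: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample annotated variant tables with planted burden classes.

    Returns (variants, planted) where ``variants`` is a MAF-like table with
    a sample_id column and ``planted`` records each sample's class and target
    TMB.  Classes are drawn independently of infiltration.  Filters recover
    the planted class exactly: kept SNV count = round(target_tmb * callable_mb),
    plus kept indels (excluded from TMB) and decoy variants that fail the
    quality / VAF / common-SNP gate.
    """
    tm = config.tmb
    rng = np.random.default_rng(config.seed + seed_offset)
    n = len(truth)
    classes = rng.choice(["non", "hyper", "ultra"], size=n, p=tm.class_proportions)
    target = np.empty(n)
    for i, cls in enumerate(classes):
        if cls == "non":
            target[i] = min(rng.lognormal(np.log(tm.non_median), tm.non_sigma), 9.5)
        elif cls == "hyper":
            target[i] = rng.uniform(*tm.hyper_range)
        else:
            target[i] = np.clip(rng.lognormal(np.log(tm.ultra_median), tm.ultra_sigma), 105.0, 830.0)

    n_snv = np.maximum(np.round(target * tm.callable_mb).astype(int), 1)
    n_indel = np.round(tm.indel_frac * n_snv).astype(int)
    n_decoy = np.round(tm.decoy_frac * n_snv).astype(int)
    total = n_snv + n_indel + n_decoy

    sample_ids = np.repeat(truth["sample_id"].to_numpy(), total)
    kind = np.concatenate([
        np.concatenate([np.repeat("snv", s), np.repeat("indel", i), np.repeat("decoy", d)])
        for s, i, d in zip(n_snv, n_indel, n_decoy)])
    m = len(kind)
    bases = np.array(["A", "C", "G", "T"])
    ref = bases[rng.integers(0, 4, size=m)]
    alt = bases[(np.searchsorted(bases, ref) + rng.integers(1, 4, size=m)) % 4]
    is_indel = kind == "indel"
    alt = np.where(is_indel, np.char.add(ref, "T"), alt)

    vaf = rng.uniform(0.05, 0.9, size=m)
    quality_pass = np.ones(m, dtype=bool)
    common_snp = np.zeros(m, dtype=bool)
    decoy_mode = rng.integers(0, 3, size=m)
    decoys = kind == "decoy"
    vaf = np.where(decoys & (decoy_mode == 0), rng.uniform(0.005, 0.049, size=m), vaf)
    quality_pass = np.where(decoys & (decoy_mode == 1), False, quality_pass)
    common_snp = np.where(decoys & (decoy_mode == 2), True, common_snp)

    consequence = rng.choice(["missense", "silent", "nonsense", "splice_region", "other"],
                             size=m, p=[0.55, 0.27, 0.06, 0.05, 0.07])
    consequence = np.where(is_indel, "frameshift_indel", consequence)
    clinvar = rng.choice(["none", "other", "benign", "likely_benign"],
                         size=m, p=[0.80, 0.14, 0.045, 0.015])
    cgc = rng.random(m) < 0.1

    variants = pd.DataFrame({
        "sample_id": pd.Categorical(sample_ids),
        "chrom": pd.Categorical(np.char.add("chr", rng.integers(1, 23, size=m).astype(str))),
        "pos": rng.integers(1, 200_000_000, size=m),
        "ref": pd.Categorical(ref), "alt": pd.Categorical(alt), "vaf": vaf,
        "consequence": pd.Categorical(consequence),
        "quality_pass": quality_pass, "common_snp": common_snp,
        "clinvar_class": pd.Categorical(clinvar), "cgc_listed": cgc,
    })
    planted = pd.DataFrame({"sample_id": truth["sample_id"].to_numpy(),
                            "tmb_class": classes,
                            "target_tmb": n_snv / tm.callable_mb})
    return variants, planted


# ---------------------------------------------------------------------------
# Presets — the cohort compositions and effect sizes the analyses assume.
# Latent means are solved from group median inflammation scores via
# mu = (median_TIS - REFERENCE_TIS) / TIS_SLOPE.
# ---------------------------------------------------------------------------

def _mu(median_tis: float) -> float:
    return (median_tis - REFERENCE_TIS) / TIS_SLOPE


def full_cohort_config(seed: int = 0, scale: float = 1.0) -> CohortConfig:
    """The full profiling-run cohort: 688 samples across tumor types, 7.5%
    planted QC failures; group median inflammation scores span the observed
    tumor-type range (non-tumor brain 7.66 ... MB 6.58 ... LGG 8.86).

    ``scale`` shrinks every group proportionally for quick runs.
    """
    spec = [("normal_brain", 12, 7.66, 0.5), ("LGG", 224, 8.86, 0.5),
            ("HGG", 170, 8.52, 0.5), ("ependymoma", 16, 8.09, 0.5),
            ("MB", 66, 6.58, 0.5), ("DMG", 59, 8.88, 0.5),
            ("MMRD_HGG", 83, 8.16, 1.95), ("AYA_HGG", 58, 8.30, 0.6)]
    groups = tuple(GroupSpec(name, max(2, int(round(n * scale))), _mu(med), sd)
                   for name, n, med, sd in spec)
    n_total = sum(g.n for g in groups)
    return CohortConfig(groups=groups, seed=seed,
                        qc=QCModel(fail_frac=52 / 688 if scale == 1.0 else 0.075))


#: Antigen-presentation / myeloid genes distinguishing the intermediate
#: immune cluster (APC-skewed rather than T-cell-skewed activation).
APC_GENES = ("HLA-DQA1", "HLA-DRB1", "PSMB10", "CMKLR1", "CD68", "CSF1R", "ITGAM", "MRC1")


def braf_cluster_config(seed: int = 0, n_per_cluster: int = 20) -> CohortConfig:
    """Three well-defined immune clusters of BRAF-mutant low-grade glioma:
    hot (median score 9.93, everything up), intermediate (8.69, skewed toward
    antigen-presenting-cell genes), and near-normal (8.15)."""
    groups = tuple(GroupSpec(f"cluster{i + 1}", n_per_cluster, _mu(med), 0.25)
                   for i, med in enumerate((9.93, 8.69, 8.15)))
    offsets = (("cluster2", tuple((g, 0.9) for g in APC_GENES)),)
    return CohortConfig(groups=groups, seed=seed, group_gene_offsets=offsets)


def de_config(seed: int = 0, n_per_group: int = 30) -> CohortConfig:
    """Two driver groups with planted differential genes: IL12B up by +1.3
    log2 in the SNV group, CD163 up by +1.7 in the fusion group.

    Both groups share the infiltration distribution so the planted per-gene
    offsets are the entire between-group effect.
    """
    groups = (GroupSpec("BRAF_V600E", n_per_group, _mu(9.0), 0.5),
              GroupSpec("BRAF_fusion", n_per_group, _mu(9.0), 0.5))
    offsets = (("BRAF_V600E", (("IL12B", 1.3),)),
               ("BRAF_fusion", (("CD163", 1.7),)))
    return CohortConfig(groups=groups, seed=seed, group_gene_offsets=offsets)


def survival_threshold_config(seed: int = 0, n: int = 120,
                              hazard_ratio: float = 3.0) -> CohortConfig:
    """Two inflammation states straddling score 9 with a step-hazard at the
    threshold: above-threshold samples progress ``hazard_ratio`` times faster."""
    half = n // 2
    groups = (GroupSpec("low_inflammation", n - half, _mu(8.0), 0.3),
              GroupSpec("high_inflammation", half, _mu(10.0), 0.3))
    survival = SurvivalModel(model="threshold", baseline_hazard=0.02,
                             threshold=9.0, hazard_ratio=hazard_ratio,
                             censor_rate=0.005)
    return CohortConfig(groups=groups, seed=seed, survival=survival)


def mmrd_config(seed: int = 0, n: int = 73) -> CohortConfig:
    """Mismatch-repair-deficient HGG cohort treated with checkpoint blockade.

    Inflammation: median 8.16, 75th percentile 9.13 (mu = 0.68, sd = 1.95 in
    latent units).  Burden classes: 12% non / 23% hyper / 65% ultra with the
    ultra log-normal median at 355 SNV/Mb, which puts the cohort median TMB
    near 254.  Overall survival: composite-group hazards set so 3-year OS is
    86% for TIS-hi/TMB-hi and 34% for TIS-lo/TMB-lo, with intermediates
    between.
    """
    groups = (GroupSpec("MMRD_HGG", n, 0.68, 1.95),)
    hazards = {"TIS-hi/TMB-hi": -np.log(0.86) / 36.0,
               "TIS-hi/TMB-lo": -np.log(0.55) / 36.0,
               "TIS-lo/TMB-hi": -np.log(0.50) / 36.0,
               "TIS-lo/TMB-lo": -np.log(0.34) / 36.0}
    survival = SurvivalModel(model="composite", composite_hazards=hazards,
                             tis_cut=9.0, censor_rate=0.004, max_follow_up=72.0)
    tmb = TMBModel(class_proportions=(0.12, 0.23, 0.65))
    return CohortConfig(groups=groups, seed=seed, survival=survival, tmb=tmb)


def null_config(seed: int = 0, n: int = 60) -> CohortConfig:
    """Single homogeneous group, no QC failures, survival unrelated to the
    inflammation score (log-HR = 0): the zero-effect generator."""
    groups = (GroupSpec("null", n, 0.0, 0.5),)
    survival = SurvivalModel(model="linear", log_hr_per_unit=0.0,
                             baseline_hazard=0.03, censor_rate=0.01)
    return CohortConfig(groups=groups, seed=seed, survival=survival)
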