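"""Survival analysis and score-based biomarker stratification.

Kaplan-Meier estimation and Cox proportional-hazards regression go through
lifelines (Efron tie handling); the log-rank test is implemented natively
(exact hypergeometric variance with ties) because the maximally-selected
cutpoint scan below evaluates it at every admissible cutpoint and needs a
vectorizable form.

``optimal_cutoff`` dichotomizes a continuous score (e.g. the tumor
inflammation signature) at the cutpoint maximizing the standardized
two-group log-rank statistic, subject to both groups holding at least
``minprop`` of the cohort.  Because the cutpoint is selected to maximize the
statistic, the naive log-rank p at the chosen cutpoint is anti-conservative;
the reported p-value therefore uses the improved-Bonferroni approximation
for maximally selected rank statistics (Miller-Siegmund/Lausen-Schumacher),
which is approximately uniform under the null.  ``bootstrap_cutoff_p``
repeats the selection on subsamples (default 1000 draws of 90% without
replacement) and summarizes the replicate p-values by their median, with the
full replicate distribution retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats


# ---------------------------------------------------------------------------
# Containers and validation
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("sample_id", "time", "event")


def as_survival_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Validate a survival table (sample_id, time > 0, boolean event)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"survival data missing columns: {missing}")
    out = data.copy()
    out["time"] = out["time"].astype(float)
    if (out["time"] <= 0).any():
        bad = out.loc[out["time"] <= 0, "sample_id"].tolist()
        raise ValueError(f"nonpositive survival times for samples: {bad}")
    if out["event"].isna().any():
        raise ValueError("missing event flags")
    out["event"] = out["event"].astype(bool)
    return out


@dataclass
class SurvivalCurve:
    """Product-limit estimate: S(t) after each death time, with at-risk counts."""

    times: np.ndarray      # distinct times with >= 1 observed event, ascending
    survival: np.ndarray   # S(t) immediately after each time
    at_risk: np.ndarray    # risk-set size just before each time

    def survival_at(self, t: float) -> float:
        """S(t); 1.0 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CutoffResult:
    cutoff: float
    groups: pd.Series              # sample -> "high" / "low" (high: score > cutoff)
    statistic: float               # standardized log-rank |z| at the cutoff
    logrank_p_full: float          # selection-adjusted p on the full data
    logrank_p_raw: float           # unadjusted log-rank p at the chosen cutoff
    minprop: float
    n: int
    bootstrap_p: float | None = None
    n_boot: int | None = None
    frac: float | None = None
    seed: int | None = None
    replicate_p: np.ndarray | None = None
    n_skipped: int = 0


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(data: pd.DataFrame) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator; censoring shrinks the risk set
    without a step."""
    df = as_survival_frame(data)
    if df.empty:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(df["time"], event_observed=df["event"])
    table = kmf.event_table
    steps = table[table["observed"] > 0]
    times = steps.index.to_numpy(float)
    surv = np.array([float(kmf.survival_function_.loc[t].iloc[0]) for t in times])
    at_risk = steps["at_risk"].to_numpy(float)
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

def _two_group_logrank(time: np.ndarray, event: np.ndarray, high: np.ndarray
                       ) -> tuple[float, float, float]:
    """(O-E, V, z) for the 'high' group, with exact hypergeometric variance."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order].astype(float), high[order].astype(float)
    n = len(t)
    uniq, first_idx = np.unique(t, return_index=True)
    inv = np.searchsorted(uniq, t)
    d_tot = np.bincount(inv, weights=e, minlength=len(uniq))
    d_hi = np.bincount(inv, weights=e * g, minlength=len(uniq))
    suffix_g = np.concatenate([np.cumsum(g[::-1])[::-1], [0.0]])
    n_tot = (n - first_idx).astype(float)
    n_hi = suffix_g[first_idx]
    keep = d_tot > 0
    d_tot, d_hi, n_tot, n_hi = d_tot[keep], d_hi[keep], n_tot[keep], n_hi[keep]
    if len(d_tot) == 0:
        return 0.0, 0.0, 0.0
    frac = n_hi / n_tot
    o_minus_e = float((d_hi - d_tot * frac).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        v_terms = d_tot * frac * (1 - frac) * (n_tot - d_tot) / np.maximum(n_tot - 1, 1.0)
    V = float(v_terms.sum())
    z = o_minus_e / np.sqrt(V) if V > 0 else 0.0
    return o_minus_e, V, z


def logrank_test(groups: Sequence[pd.DataFrame]) -> tuple[float, int, float]:
    """k-sample log-rank test: (chi2, df, p).

    ``groups`` is a list of survival tables; the statistic is the usual
    (O - E)' V^- (O - E) accumulated over event times, with df = k - 1.
    """
    if len(groups) < 2:
        raise ValueError("logrank_test needs at least 2 groups")
    frames = [as_survival_frame(g) for g in groups]
    if any(f.empty for f in frames):
        raise ValueError("empty group")
    k = len(frames)
    time = np.concatenate([f["time"].to_numpy() for f in frames])
    event = np.concatenate([f["event"].to_numpy() for f in frames])
    labels = np.concatenate([np.full(len(f), i) for i, f in enumerate(frames)])

    order = np.argsort(time, kind="stable")
    t, e, lab = time[order], event[order].astype(float), labels[order]
    n = len(t)
    uniq, first_idx = np.unique(t, return_index=True)
    inv = np.searchsorted(uniq, t)
    d_tot = np.bincount(inv, weights=e, minlength=len(uniq))
    n_tot = (n - first_idx).astype(float)
    # per-group at-risk and death counts at each unique time
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    n_g = np.zeros((len(uniq), k))
    d_g = np.zeros((len(uniq), k))
    for g in range(k):
        mask = (lab == g).astype(float)
        suffix = np.concatenate([np.cumsum(mask[::-1])[::-1], [0.0]])
        n_g[:, g] = suffix[first_idx]
        d_g[:, g] = np.bincount(inv, weights=e * mask, minlength=len(uniq))
    keep = d_tot > 0
    d_tot, n_tot, n_g, d_g = d_tot[keep], n_tot[keep], n_g[keep], d_g[keep]
    if len(d_tot) == 0:
        return 0.0, k - 1, 1.0
    prop = n_g / n_tot[:, None]
    O = d_g.sum(axis=0)
    E = (d_tot[:, None] * prop).sum(axis=0)
    mult = d_tot * (n_tot - d_tot) / np.maximum(n_tot - 1, 1.0)
    for a in range(k):
        for b in range(k):
            delta = 1.0 if a == b else 0.0
            V[a, b] = float((mult * prop[:, a] * (delta - prop[:, b])).sum())
    diff = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff) if np.any(Vsub) else 0.0
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def cox_fit(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    Returns a table indexed by covariate with columns HR, ci_lower, ci_upper,
    p, coef.  Constant covariates are rejected up front (no information).
    """
    df = as_survival_frame(data)
    covariates = list(covariates)
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ValueError(f"covariates not in data: {missing}")
    if not df["event"].any():
        raise ValueError("no events in data; Cox model is not identifiable")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant across samples (no information)")
    model_df = df[["time", "event", *covariates]].copy()
    model_df["event"] = model_df["event"].astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(model_df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    out = pd.DataFrame({
        "coef": summary["coef"],
        "HR": summary["exp(coef)"],
        "ci_lower": summary["exp(coef) lower 95%"],
        "ci_upper": summary["exp(coef) upper 95%"],
        "p": summary["p"],
    })
    out.index.name = "covariate"
    return out


# ---------------------------------------------------------------------------
# Maximally selected cutpoint
# ---------------------------------------------------------------------------

def maxsel_adjusted_p(b: float, minprop: float) -> float:
    """Improved-Bonferroni p for the maximum of |standardized log-rank| over
    admissible cutpoints (Miller-Siegmund / Lausen-Schumacher approximation).

    With cutpoints restricted to group proportions in [eps1, eps2]:
    p ~= phi(b) * (b - 1/b) * log(eps2(1-eps1) / (eps1(1-eps2))) + 4 phi(b)/b.
    """
    if b <= 0:
        return 1.0
    eps1, eps2 = minprop, 1.0 - minprop
    if b <= 1.0:  # formula degenerates; the bound is vacuous here
        return 1.0
    phi = stats.norm.pdf(b)
    p = phi * (b - 1.0 / b) * np.log(eps2 * (1 - eps1) / (eps1 * (1 - eps2))) + 4.0 * phi / b
    return float(min(max(p, 0.0), 1.0))


def _align_scores(scores: Mapping[str, float] | pd.Series, df: pd.DataFrame) -> np.ndarray:
    scores = pd.Series(scores, dtype=float)
    missing = [s for s in df["sample_id"] if s not in scores.index]
    if missing:
        raise KeyError(f"samples without scores: {missing}")
    vals = scores.loc[df["sample_id"]].to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite scores")
    return vals


def _scan_cutpoints(score: np.ndarray, time: np.ndarray, event: np.ndarray,
                    minprop: float) -> tuple[float, float] | None:
    """Best (cutoff, |z|) over admissible cutpoints, or None if none admissible.

    Candidate cutoffs are the observed score values; 'high' means score >
    cutoff; both groups must hold >= minprop * n samples.  Ties in |z| break
    toward the smallest cutoff for determinism.
    """
    n = len(score)
    min_size = minprop * n
    candidates = np.unique(score)
    best: tuple[float, float] | None = None
    for c in candidates:
        high = score > c
        n_high = int(high.sum())
        if n_high < min_size or (n - n_high) < min_size:
            continue
        _, _, z = _two_group_logrank(time, event, high)
        az = abs(z)
        if best is None or az > best[1] + 1e-12:
            best = (float(c), az)
    return best


def optimal_cutoff(scores: Mapping[str, float] | pd.Series, data: pd.DataFrame,
                   minprop: float = 0.1) -> CutoffResult:
    """Maximally selected log-rank cutpoint for a continuous score."""
    df = as_survival_frame(data)
    if not (0 < minprop < 0.5 or minprop == 0.5):
        raise ValueError("minprop must be in (0, 0.5]")
    if len(df) < int(np.ceil(1.0 / minprop)):
        raise ValueError(f"need at least {int(np.ceil(1 / minprop))} samples for minprop={minprop}")
    score = _align_scores(scores, df)
    if np.unique(score).size == 1:
        raise ValueError("all scores equal: no valid split")
    time = df["time"].to_numpy(float)
    event = df["event"].to_numpy(bool)
    best = _scan_cutpoints(score, time, event, minprop)
    if best is None:
        raise ValueError("no admissible cutpoint under the minprop constraint")
    cutoff, b = best
    high = score > cutoff
    _, _, z = _two_group_logrank(time, event, high)
    raw_p = float(stats.chi2.sf(z * z, 1)) if z != 0 else 1.0
    groups = pd.Series(np.where(high, "high", "low"), index=df["sample_id"].to_numpy())
    return CutoffResult(cutoff=cutoff, groups=groups, statistic=b,
                        logrank_p_full=maxsel_adjusted_p(b, minprop),
                        logrank_p_raw=raw_p, minprop=minprop, n=len(df))


def bootstrap_cutoff_p(scores: Mapping[str, float] | pd.Series, data: pd.DataFrame,
                       n_boot: int = 1000, frac: float = 0.9, seed: int = 0,
                       minprop: float = 0.1) -> CutoffResult:
    """Cutpoint selection with a subsampled p-value distribution.

    Each replicate draws floor(frac * n) samples without replacement,
    re-selects the cutpoint and records its selection-adjusted log-rank p.
    ``bootstrap_p`` is the median replicate p; the full distribution is kept
    on the result.  Replicates with no admissible cutpoint are skipped; more
    than 10% skipped is an error.
    """
    result = optimal_cutoff(scores, data, minprop=minprop)
    df = as_survival_frame(data)
    score = _align_scores(scores, df)
    time = df["time"].to_numpy(float)
    event = df["event"].to_numpy(bool)
    n = len(df)
    m = int(np.floor(frac * n))
    if m < 2:
        raise ValueError("subsample size too small")
    rng = np.random.default_rng(seed)
    reps: list[float] = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.choice(n, size=m, replace=False)
        s, t, e = score[idx], time[idx], event[idx]
        if np.unique(s).size == 1:
            skipped += 1
            continue
        best = _scan_cutpoints(s, t, e, minprop)
        if best is None:
            skipped += 1
            continue
        reps.append(maxsel_adjusted_p(best[1], minprop))
    if skipped > 0.1 * n_boot:
        raise RuntimeError(f"{skipped}/{n_boot} bootstrap replicates had no admissible cutpoint")
    rep_arr = np.asarray(reps)
    result.bootstrap_p = float(np.median(rep_arr))
    result.n_boot = n_boot
    result.frac = frac
    result.seed = seed
    result.replicate_p = rep_arr
    result.n_skipped = skipped
    return result


# ---------------------------------------------------------------------------
# Composite and quartile stratification
# ---------------------------------------------------------------------------

def stratify_composite(tis: Mapping[str, float] | pd.Series,
                       tmb: Mapping[str, float] | pd.Series,
                       tis_cut: float = 9.0, tmb_cut: float = 100.0) -> pd.Series:
    """Four-way TIS x TMB stratification; 'high' means strictly greater than
    the cutoff (TIS > 9, TMB > 100 SNV/Mb)."""
    tis = pd.Series(tis, dtype=float)
    tmb = pd.Series(tmb, dtype=float)
    if set(tis.index) != set(tmb.index):
        diff = set(tis.index) ^ set(tmb.index)
        raise ValueError(f"samples missing one of the scores: {sorted(diff)}")
    tmb = tmb.loc[tis.index]
    tis_lab = np.where(tis > tis_cut, "TIS-hi", "TIS-lo")
    tmb_lab = np.where(tmb > tmb_cut, "TMB-hi", "TMB-lo")
    return pd.Series([f"{a}/{b}" for a, b in zip(tis_lab, tmb_lab)], index=tis.index)


def quartile_groups(scores: Mapping[str, float] | pd.Series) -> pd.Series:
    """Three-way split: high > 75th percentile, low < 25th, medium between.

    Percentiles use the linear-interpolation (type-7) quantile definition.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 4:
        raise ValueError("need at least 4 samples for quartile stratification")
    q25, q75 = np.quantile(s.to_numpy(), [0.25, 0.75])
    labels = np.where(s > q75, "high", np.where(s < q25, "low", "medium"))
    return pd.Series(labels, index=s.index)
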