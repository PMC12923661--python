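"""Paired and grouped statistics for pre- vs intraoperative tract metrics.

The battery mirrors a typical paired surgical-change analysis: Wilcoxon
signed-rank tests within patients, linear mixed-effects models with a
patient random intercept and an optional covariate (SNR or age), paired
Cohen's d with the conventional 0.2 / 0.5 / 0.8 bands, Wilcoxon rank-sum
contrasts between outcome groups, per-segment z-tests of mean along-tract
change against zero with Benjamini-Hochberg FDR control, logistic
regression of the outcome on demographics, and correlation of tract change
with ventricular or tumor volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "StatResult",
    "effect_band",
    "cohens_d",
    "percent_change",
    "wilcoxon_signed_rank",
    "rank_sum",
    "paired_lmm",
    "bh_fdr",
    "segment_ztest",
    "change_correlation",
    "speech_label",
    "logistic_outcome",
]

BAND_EDGES = (0.2, 0.5, 0.8)  # negligible | small | moderate | large


@dataclass
class StatResult:
    statistic: float
    p_raw: float
    method: str
    p_fdr: float | None = None
    effect_size_d: float | None = None
    effect_band: str | None = None
    percent_change: float | None = None
    n: int | None = None
    flags: dict = field(default_factory=dict)


def effect_band(d: float) -> str:
    """Band of |d|; boundaries belong to the higher band ([0.2, 0.5) = small)."""
    a = abs(d)
    if not np.isfinite(a):
        return "undefined"
    if a < BAND_EDGES[0]:
        return "negligible"
    if a < BAND_EDGES[1]:
        return "small"
    if a < BAND_EDGES[2]:
        return "moderate"
    return "large"


def cohens_d(pre: np.ndarray, intra: np.ndarray) -> tuple[float, str]:
    """Paired Cohen's d: mean(intra - pre) / sample SD of the differences."""
    d = np.asarray(intra, dtype=float) - np.asarray(pre, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        return (np.inf if d.mean() != 0 else np.nan), "undefined"
    val = float(d.mean() / sd)
    return val, effect_band(val)


def percent_change(pre: float, intra: float) -> float:
    """Relative change in percent, (intra - pre) / pre * 100."""
    if pre == 0:
        raise ValueError("undefined for a zero baseline")
    return float(100.0 * (intra - pre) / pre)


def wilcoxon_signed_rank(pre: np.ndarray, intra: np.ndarray) -> StatResult:
    """Paired Wilcoxon signed-rank test on intra - pre.

    Exact null distribution (conditional on the observed ranks, ties
    included) when there are <= 25 non-zero differences; normal
    approximation with continuity and tie correction otherwise. Zero
    differences are discarded, their count flagged.
    """
    pre = np.asarray(pre, dtype=float)
    intra = np.asarray(intra, dtype=float)
    diff = intra - pre
    nz = diff[diff != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    if nz.size < 5:
        raise ValueError("need >= 5 non-zero paired differences")
    method = "exact" if nz.size <= 25 else "approx"
    res = sps.wilcoxon(nz, method=method, correction=(method == "approx"))
    d, band = cohens_d(pre, intra)
    return StatResult(
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        method=f"wilcoxon-signed-rank/{method}",
        effect_size_d=d,
        effect_band=band,
        n=int(nz.size),
        flags={"n_zero_diffs": int(diff.size - nz.size)},
    )


def rank_sum(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test between two groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return StatResult(
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        method="wilcoxon-rank-sum",
        n=int(x.size + y.size),
    )


def paired_lmm(
    values: np.ndarray,
    timepoint: np.ndarray,
    subject: np.ndarray,
    covariate: np.ndarray | None = None,
) -> StatResult:
    """Linear mixed model: value ~ timepoint (+ covariate), random intercept
    per subject. Reports the Wald p of the timepoint effect.

    With no covariate and balanced pairs, the timepoint estimate equals the
    mean paired difference. A singular/non-converged fit is flagged and a
    paired t-test fallback p is reported in the flags.
    """
    values = np.asarray(values, dtype=float)
    tp = np.asarray(timepoint, dtype=float)
    subj = np.asarray(subject)
    exog = pd.DataFrame({"const": 1.0, "timepoint": tp})
    if covariate is not None:
        exog["covariate"] = np.asarray(covariate, dtype=float)
    flags: dict = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = MixedLM(values, exog, groups=subj)
        fit = model.fit(reml=True)
    est = float(fit.params["timepoint"])
    p = float(fit.pvalues["timepoint"])
    if not fit.converged or not np.isfinite(p):
        flags["singular"] = True
        pre = values[tp == np.min(tp)]
        post = values[tp == np.max(tp)]
        if pre.size == post.size:
            flags["fallback_paired_t_p"] = float(sps.ttest_rel(post, pre).pvalue)
    d, band = (np.nan, None)
    subj_ids = pd.unique(subj)
    pre_map = {s: v for s, v, t in zip(subj, values, tp) if t == np.min(tp)}
    post_map = {s: v for s, v, t in zip(subj, values, tp) if t == np.max(tp)}
    common = [s for s in subj_ids if s in pre_map and s in post_map]
    if len(common) >= 2:
        d, band = cohens_d([pre_map[s] for s in common], [post_map[s] for s in common])
    return StatResult(
        statistic=est,
        p_raw=p,
        method="lmm-random-intercept" + ("" if covariate is None else "+covariate"),
        effect_size_d=d,
        effect_band=band,
        n=len(subj_ids),
        flags=flags,
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def segment_ztest(
    delta: np.ndarray, min_subjects: int = 3, max_missing_frac: float = 0.5
) -> pd.DataFrame:
    """Per-segment tests of the mean along-tract change against zero.

    ``delta`` is subjects x segments, NaN for missing. The statistic is the
    usual z = mean / standard-error; because the SD is estimated from the
    cohort, p-values reference the Student-t distribution with n-1 degrees
    of freedom (the normal reference is anticonservative at cohort sizes of
    ~30 and inflates the family-level false-positive rate roughly twofold).
    Segments missing in more than half the subjects (or observed in fewer
    than ``min_subjects``) are excluded from testing and from the FDR
    family. BH adjustment runs across the tested segments of this one
    family (one metric, one tract, one side).
    """
    delta = np.asarray(delta, dtype=float)
    if delta.ndim != 2:
        raise ValueError("delta must be subjects x segments")
    n_subj, n_seg = delta.shape
    n_obs = np.sum(np.isfinite(delta), axis=0)
    tested = (n_obs >= min_subjects) & (n_obs >= (1 - max_missing_frac) * n_subj)
    z = np.full(n_seg, np.nan)
    p = np.full(n_seg, np.nan)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isfinite(delta), delta, np.nan), axis=0)
        sd = np.array(
            [np.nanstd(delta[:, j], ddof=1) if n_obs[j] > 1 else np.nan for j in range(n_seg)]
        )
    se = sd / np.sqrt(np.maximum(n_obs, 1))
    valid = tested & (se > 0)
    z[valid] = mean[valid] / se[valid]
    p[valid] = 2 * sps.t.sf(np.abs(z[valid]), df=n_obs[valid] - 1)
    p_fdr = np.full(n_seg, np.nan)
    if valid.any():
        p_fdr[valid] = bh_fdr(p[valid])
    return pd.DataFrame(
        {
            "segment": np.arange(1, n_seg + 1),
            "n": n_obs,
            "mean_delta": mean,
            "z": z,
            "p_raw": p,
            "p_fdr": p_fdr,
            "tested": valid,
        }
    )


def change_correlation(
    tract_change: np.ndarray, volume: np.ndarray, method: str = "pearson"
) -> StatResult:
    """Correlation of a tract-change metric with ventricular or tumor volume."""
    x = np.asarray(tract_change, dtype=float)
    y = np.asarray(volume, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 matched observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return StatResult(statistic=float(r), p_raw=float(p), method=method, n=int(x.size))


def speech_label(sara_t0: int | None, sara_t1: int | None) -> bool | None:
    """Speech-disturbance increase: at least a one-point rise on the 0-6
    speech subscore between the pre- and early post-surgical assessments.
    Missing scores propagate as missing."""
    if sara_t0 is None or sara_t1 is None:
        return None
    for v in (sara_t0, sara_t1):
        if not 0 <= int(v) <= 6:
            raise ValueError("speech subscores must lie in 0..6")
    return bool(sara_t1 - sara_t0 >= 1)


def logistic_outcome(
    age: np.ndarray, sex: np.ndarray, label: np.ndarray
) -> dict[str, StatResult]:
    """Logistic regression of the binary outcome on age and sex.

    Returns per-covariate Wald results; complete separation is detected and
    flagged rather than silently reported.
    """
    import statsmodels.api as sm

    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    y = np.asarray(label, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    X = pd.DataFrame({"const": 1.0, "age": age, "sex": sex})
    separated = False
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            separated = True
            try:
                fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1.0, maxiter=500)
            except Exception:
                fit = None
    if fit is not None and not separated:
        separated = bool(np.any(np.abs(fit.params[["age", "sex"]]) > 50)) or bool(
            np.any(~np.isfinite(np.asarray(fit.bse)))
        )
    out = {}
    for name in ("age", "sex"):
        coef = float(fit.params[name]) if fit is not None else np.nan
        try:
            p = float(fit.pvalues[name])
        except Exception:
            p = np.nan
        out[name] = StatResult(
            statistic=coef,
            p_raw=p,
            method="logistic-wald",
            n=int(y.size),
            flags={"separation": separated},
        )
    return out
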