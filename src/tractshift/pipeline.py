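"""End-to-end driver: phantom -> tensor fit -> tracking -> gating ->
tractometry -> statistics, producing tidy tables and a statistics report.

The analysis treats each synthetic patient like a study participant: both
timepoints are processed identically, tracts are segmented per hemisphere
(side = hemisphere of the dentate nucleus, or of Wernicke's area for the
AF), the arcuate fasciculus is length-filtered at cohort level, and all
pre-vs-intra contrasts run on the resulting tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st
from .dwi import fa_md_maps, fit_tensor, wm_snr
from .gating import GateSpec, apply_gates, brain_height_mm, classify_drtt, filter_af
from .phantom import PhantomConfig, SubjectPair, make_cohort
from .tracking import StreamlineSet, TrackingParams, seed_grid, track
from .tractometry import compute_profile

__all__ = ["RunConfig", "process_dataset", "run_cohort", "run_stats", "run_pipeline"]

TRACTS = ("d_DRTT", "nd_DRTT", "AF")
WHOLE_METRICS = ("volume_norm", "diameter_mm", "fa_mean", "md_mean")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: phantom + tracking + analysis."""

    n_subjects: int = 4
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    n_segments: int = 55
    correlation_method: str = "pearson"


def drtt_gate(masks, side: str) -> GateSpec:
    """Dentate + thalamus + motor-cortex AND gates, callosum/tumor NOT gates."""
    m = masks.masks
    return GateSpec(
        include={
            "dentate": m[f"dentate_{side}"],
            "thalamus": m["thalamus_left"] | m["thalamus_right"],
            "motor_cortex": m["motor_cortex_left"] | m["motor_cortex_right"],
        },
        exclude={"corpus_callosum": m["corpus_callosum"], "tumor": m["tumor"]},
        endpoint_rois=("dentate", "motor_cortex"),
        side=side,
    )


def af_gate(masks, side: str) -> GateSpec:
    m = masks.masks
    return GateSpec(
        include={"wernicke": m[f"wernicke_{side}"], "broca": m[f"broca_{side}"]},
        exclude={"corpus_callosum": m["corpus_callosum"], "tumor": m["tumor"]},
        endpoint_rois=("wernicke", "broca"),
        side=side,
    )


def process_dataset(ds, params: TrackingParams) -> dict:
    """Whole-brain tracking plus tract segmentation for one dataset.

    Returns scalar maps, measured WM SNR, and per (tract, side) gated
    streamline sets (AF sets unfiltered; the length filter is cohort-level).
    """
    grid = ds.grid
    wm = ds.masks["white_matter"]
    tmap = fit_tensor(ds.dwi, ds.scheme, ds.masks.brain)
    fa_map, md_map = fa_md_maps(tmap)
    snr_meas, _ = wm_snr(ds.dwi[..., ds.scheme.b0_mask], wm)
    seeds = seed_grid(wm, grid, params.seed_spacing_mm)
    sls = track(ds.peaks, params, wm, seeds)

    tract_sets: dict[tuple[str, str], StreamlineSet] = {}
    motor = {s: ds.masks[f"motor_cortex_{s}"] for s in ("left", "right")}
    for side in ("left", "right"):
        gated = apply_gates(sls, drtt_gate(ds.masks, side), grid)
        parts = classify_drtt(gated, side, motor, grid)
        tract_sets[("d_DRTT", side)] = parts["d_DRTT"]
        tract_sets[("nd_DRTT", side)] = parts["nd_DRTT"]
        tract_sets[("AF", side)] = apply_gates(sls, af_gate(ds.masks, side), grid)
    return {
        "fa_map": fa_map,
        "md_map": md_map,
        "wm_snr": snr_meas,
        "tract_sets": tract_sets,
        "n_streamlines": len(sls),
    }


def _tissue_row(pair: SubjectPair, tp: str, ds, snr_meas: float) -> dict:
    grid = ds.grid
    vv = grid.voxel_volume_mm3
    wm_v = float(ds.masks["white_matter"].sum() * vv)
    gm_v = float(ds.masks["gray_matter"].sum() * vv)
    vent_v = float(ds.masks["ventricles"].sum() * vv)
    tumor_v = float(ds.masks["tumor"].sum() * vv)
    healthy = wm_v + gm_v + vent_v
    return {
        "subject": pair.subject_id,
        "timepoint": tp,
        "age_years": pair.age_years,
        "sex": pair.sex,
        "speech_increase": pair.speech_increase,
        "wm_volume_mm3": wm_v,
        "gm_volume_mm3": gm_v,
        "ventricle_volume_norm": 100.0 * vent_v / healthy,
        "tumor_volume_norm": 100.0 * tumor_v / (tumor_v + healthy),
        "wm_snr": snr_meas,
        "brain_height_mm": brain_height_mm(ds.masks.brain, grid),
    }


def run_cohort(
    pairs: list[SubjectPair],
    params: TrackingParams | None = None,
    n_segments: int = 55,
) -> dict[str, pd.DataFrame]:
    """Process every subject pair into tidy metric/profile/subject tables.

    The AF length filter (first percentile of the brain-height-normalized
    median AF length) pools all subjects and timepoints of the cohort, then
    per-tract metrics and 55-segment FA/MD profiles are computed.
    """
    params = params or TrackingParams()
    processed: dict[tuple[str, str], dict] = {}
    subject_rows = []
    af_sets: dict[str, StreamlineSet] = {}
    af_heights: dict[str, float] = {}
    for pair in pairs:
        for tp, ds in (("pre", pair.pre), ("intra", pair.intra)):
            res = process_dataset(ds, params)
            processed[(pair.subject_id, tp)] = {"res": res, "ds": ds}
            subject_rows.append(_tissue_row(pair, tp, ds, res["wm_snr"]))
            h = brain_height_mm(ds.masks.brain, ds.grid)
            for side in ("left", "right"):
                key = f"{pair.subject_id}|{tp}|{side}"
                af_sets[key] = res["tract_sets"][("AF", side)]
                af_heights[key] = h

    af_filtered, af_threshold = filter_af(af_sets, af_heights)

    metric_rows, profile_rows = [], []
    for pair in pairs:
        for tp in ("pre", "intra"):
            entry = processed[(pair.subject_id, tp)]
            ds, res = entry["ds"], entry["res"]
            stwm = ds.masks["supratentorial_wm"]
            for (tract, side), sset in res["tract_sets"].items():
                if tract == "AF":
                    sset = af_filtered[f"{pair.subject_id}|{tp}|{side}"]
                base = {"subject": pair.subject_id, "timepoint": tp, "tract": tract, "side": side}
                if len(sset) == 0:
                    metric_rows.append({**base, "failed": True})
                    continue
                prof = compute_profile(
                    sset, res["fa_map"], res["md_map"], ds.grid, stwm, tract, side, tp, n_segments
                )
                metric_rows.append(
                    {
                        **base,
                        "failed": False,
                        "volume_mm3": prof.volume_mm3,
                        "volume_norm": prof.volume_norm,
                        "length_mm": prof.length_mm,
                        "diameter_mm": prof.diameter_mm,
                        "fa_mean": prof.fa_mean,
                        "md_mean": prof.md_mean,
                        "n_streamlines": prof.n_streamlines,
                    }
                )
                for metric, arr in (("FA", prof.fa_profile), ("MD", prof.md_profile)):
                    for j, v in enumerate(arr):
                        profile_rows.append(
                            {**base, "metric": metric, "segment": j + 1, "value": v,
                             "count": int(prof.segment_counts[j])}
                        )
    return {
        "metrics": pd.DataFrame(metric_rows),
        "profiles": pd.DataFrame(profile_rows),
        "subjects": pd.DataFrame(subject_rows),
        "af_threshold": af_threshold,
    }


def _paired(metrics: pd.DataFrame, tract: str, side: str, metric: str) -> pd.DataFrame:
    sub = metrics[(metrics.tract == tract) & (metrics.side == side) & (~metrics.failed)]
    wide = sub.pivot(index="subject", columns="timepoint", values=metric).dropna()
    return wide


def delta_profiles(profiles: pd.DataFrame, tract: str, side: str, metric: str) -> pd.DataFrame:
    """Subjects x segments matrix of intra - pre along-tract change."""
    sub = profiles[
        (profiles.tract == tract) & (profiles.side == side) & (profiles.metric == metric)
    ]
    wide = sub.pivot_table(
        index="subject", columns=["timepoint", "segment"], values="value", aggfunc="first"
    )
    try:
        pre = wide["pre"]
        intra = wide["intra"]
    except KeyError:
        return pd.DataFrame()
    return intra.sub(pre)


def run_stats(tables: dict, correlation_method: str = "pearson") -> dict[str, pd.DataFrame]:
    """The full statistical battery over the cohort tables."""
    metrics, profiles, subjects = tables["metrics"], tables["profiles"], tables["subjects"]
    swide = subjects.pivot(index="subject", columns="timepoint")
    info = subjects[subjects.timepoint == "pre"].set_index("subject")

    # --- global tissue + SNR paired tests (Wilcoxon) -----------------------
    rows = []
    for col in ("wm_volume_mm3", "gm_volume_mm3", "ventricle_volume_norm", "wm_snr"):
        pre = swide[(col, "pre")].to_numpy()
        intra = swide[(col, "intra")].to_numpy()
        try:
            r = st.wilcoxon_signed_rank(pre, intra)
            rows.append(
                {"measure": col, "p_raw": r.p_raw, "statistic": r.statistic,
                 "effect_d": r.effect_size_d, "band": r.effect_band,
                 "percent_change": st.percent_change(pre.mean(), intra.mean()), "n": r.n}
            )
        except ValueError as e:
            rows.append({"measure": col, "error": str(e)})
    global_df = pd.DataFrame(rows)

    # --- per-tract paired metrics: Wilcoxon, Cohen's d, LMM(+-covariate) ---
    rows = []
    snr_long = subjects.set_index(["subject", "timepoint"])["wm_snr"]
    for tract in TRACTS:
        for side in ("left", "right"):
            for metric in WHOLE_METRICS:
                wide = _paired(metrics, tract, side, metric)
                n_pairs = wide.shape[0]
                row = {"tract": tract, "side": side, "metric": metric, "n_pairs": n_pairs,
                       "n_dropped": metrics[(metrics.tract == tract) & (metrics.side == side)]
                       .failed.sum()}
                if n_pairs >= 5:
                    pre, intra = wide["pre"].to_numpy(), wide["intra"].to_numpy()
                    try:
                        w = st.wilcoxon_signed_rank(pre, intra)
                        row.update(wilcoxon_p=w.p_raw, effect_d=w.effect_size_d, band=w.effect_band)
                    except ValueError:
                        row.update(wilcoxon_p=np.nan)
                    row["percent_change"] = st.percent_change(pre.mean(), intra.mean())
                    subj = np.repeat(wide.index.to_numpy(), 2)
                    tp = np.tile([0.0, 1.0], n_pairs)
                    vals = np.column_stack([pre, intra]).ravel()
                    lmm = st.paired_lmm(vals, tp, subj)
                    row.update(lmm_estimate=lmm.statistic, lmm_p=lmm.p_raw)
                    snr_cov = np.array(
                        [snr_long[(s, "pre" if t == 0 else "intra")]
                         for s, t in zip(subj, tp)]
                    )
                    row["lmm_p_snr"] = st.paired_lmm(vals, tp, subj, snr_cov).p_raw
                    age_cov = info.age_years.reindex(subj).to_numpy()
                    row["lmm_p_age"] = st.paired_lmm(vals, tp, subj, age_cov).p_raw
                rows.append(row)
    paired_df = pd.DataFrame(rows)
    if "wilcoxon_p" in paired_df:
        ok = paired_df.wilcoxon_p.notna()
        paired_df.loc[ok, "wilcoxon_p_fdr"] = st.bh_fdr(paired_df.loc[ok, "wilcoxon_p"].to_numpy())

    # --- along-tract segment z-tests, BH within metric x tract x side -----
    seg_frames = []
    for tract in TRACTS:
        for side in ("left", "right"):
            for metric in ("FA", "MD"):
                delta = delta_profiles(profiles, tract, side, metric)
                if delta.empty:
                    continue
                res = st.segment_ztest(delta.to_numpy())
                res.insert(0, "tract", tract)
                res.insert(1, "side", side)
                res.insert(2, "metric", metric)
                seg_frames.append(res)
    segments_df = pd.concat(seg_frames, ignore_index=True) if seg_frames else pd.DataFrame()

    # --- speech groups: rank-sum on whole-tract changes --------------------
    rows = []
    speech = info.speech_increase
    if speech.nunique() == 2:
        for tract in TRACTS:
            for side in ("left", "right"):
                for metric in ("fa_mean", "md_mean"):
                    wide = _paired(metrics, tract, side, metric)
                    if wide.shape[0] < 4:
                        continue
                    delta = (wide["intra"] - wide["pre"])
                    lab = speech.reindex(delta.index)
                    g1, g0 = delta[lab == True], delta[lab == False]  # noqa: E712
                    if len(g1) and len(g0):
                        r = st.rank_sum(g1.to_numpy(), g0.to_numpy())
                        rows.append({"tract": tract, "side": side, "metric": metric,
                                     "p_raw": r.p_raw, "statistic": r.statistic,
                                     "n_speech": len(g1), "n_no_speech": len(g0)})
    groups_df = pd.DataFrame(rows)
    if not groups_df.empty:
        groups_df["p_fdr"] = st.bh_fdr(groups_df.p_raw.to_numpy())

    # --- logistic: age/sex vs speech --------------------------------------
    logit_rows = []
    if speech.nunique() == 2:
        sex_num = (info.sex == "F").astype(float)
        try:
            res = st.logistic_outcome(
                info.age_years.to_numpy(), sex_num.to_numpy(), speech.astype(float).to_numpy()
            )
            for name, r in res.items():
                logit_rows.append({"covariate": name, "coef": r.statistic, "p": r.p_raw,
                                   "separation": r.flags.get("separation", False)})
        except ValueError as e:
            logit_rows.append({"covariate": "age+sex", "error": str(e)})
    logistic_df = pd.DataFrame(logit_rows)

    # --- correlation of tract change with ventricle / tumor volume --------
    corr_rows = []
    for tract in TRACTS:
        for side in ("left", "right"):
            for metric in ("volume_norm", "diameter_mm"):
                wide = _paired(metrics, tract, side, metric)
                if wide.shape[0] < 5:
                    continue
                change = 100.0 * (wide["intra"] - wide["pre"]) / wide["pre"]
                for vol_col in ("ventricle_volume_norm", "tumor_volume_norm"):
                    vols = info[vol_col].reindex(change.index)
                    try:
                        r = st.change_correlation(
                            change.to_numpy(), vols.to_numpy(), correlation_method
                        )
                        corr_rows.append({"tract": tract, "side": side, "metric": metric,
                                          "against": vol_col, "r": r.statistic, "p": r.p_raw,
                                          "n": r.n})
                    except ValueError:
                        pass
    corr_df = pd.DataFrame(corr_rows)

    return {
        "global": global_df,
        "paired": paired_df,
        "segments": segments_df,
        "groups": groups_df,
        "logistic": logistic_df,
        "correlations": corr_df,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Generate a cohort, analyze it, and write the artifact tree."""
    out = Path(out_dir)
    (out / "stats").mkdir(parents=True, exist_ok=True)
    pairs = make_cohort(config.n_subjects, config.seed, config.phantom)
    tables = run_cohort(pairs, config.tracking, config.n_segments)
    tables["metrics"].to_csv(out / "metrics.csv", index=False)
    tables["profiles"].to_csv(out / "profiles.csv", index=False)
    tables["subjects"].to_csv(out / "subjects.csv", index=False)
    report = run_stats(tables, config.correlation_method)
    for name, df in report.items():
        df.to_csv(out / "stats" / f"{name}.csv", index=False)
    import json

    with open(out / "run.json", "w") as fh:
        json.dump(
            {"n_subjects": config.n_subjects, "seed": config.seed,
             "n_segments": config.n_segments, "af_threshold": tables["af_threshold"]},
            fh, indent=2,
        )
    return out
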