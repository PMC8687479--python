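"""Reusable simulation studies over the pipeline.

Each function here runs a complete, self-contained experiment — type-I error
calibration of the cluster test, effect-recovery power, questionnaire
calibration, regression sign recovery, and the full study-shaped analysis —
from a single integer seed.  The test suite, the numbered analysis drivers
and the acceptance script all call these, so every reported number comes
from the same code path.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from . import regression as reg
from .groupstats import (
    classify_resilience,
    cluster_permutation_test,
    mean_pandemic_score,
    spearman,
)
from .reactivity import gmfa, local_response, score_subject
from .simulate import (
    LatentProfile,
    SimulationConfig,
    make_roi,
    simulate_cohort_table,
    simulate_subject_tep,
)

log = logging.getLogger(__name__)

#: shortened epoch for repeated-simulation studies — still covers the baseline
#: (-500..-3 ms) and response (15..400 ms) windows with margin
FAST_EPOCH_MS = (-1000.0, 500.0)


def fast_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(epoch_ms=FAST_EPOCH_MS)
    return replace(cfg, **overrides) if overrides else cfg


def _local_z(profile: LatentProfile, target: str, cfg: SimulationConfig, rng):
    src, _ = simulate_subject_tep(profile, target, cfg, rng, spaces=("source_roi",))
    return local_response(src, make_roi(target, cfg))


# ---------------------------------------------------------------------------
# cluster-test calibration and power
# ---------------------------------------------------------------------------

def null_cluster_rejection_rate(
    n_datasets: int = 500,
    n_per_group: int = 12,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> dict:
    """Fraction of effect-free datasets where any cluster survives correction.

    Both groups are drawn from the same generator (effect_size=0), so any
    surviving cluster is a false positive; the rate estimates the test's
    family-wise type-I error.
    """
    cfg = replace(config or fast_config(), effect_size=0.0)
    rng = np.random.default_rng(seed)
    n_reject = 0
    for _ in range(n_datasets):
        zs = [
            _local_z(LatentProfile(f"s{i}", float(rng.normal())), "DLPFC", cfg, rng)
            for i in range(2 * n_per_group)
        ]
        res = cluster_permutation_test(
            zs[:n_per_group], zs[n_per_group:], n_perm=n_perm, alpha=alpha,
            seed=int(rng.integers(2**31)),
        )
        n_reject += bool(res.surviving)
    rate = n_reject / n_datasets
    se = np.sqrt(alpha * (1 - alpha) / n_datasets)
    return {"rate": rate, "n_datasets": n_datasets, "alpha": alpha,
            "binomial_se": float(se), "bound": alpha + 2 * se}


def cluster_recovery_rates(
    n_datasets: int = 100,
    n_subjects: int = 48,
    n_perm: int = 500,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> dict:
    """Power of the pipeline to find the injected late DLPFC effect.

    Each dataset is a full synthetic cohort: PHQ trajectories are generated,
    subjects classified resilient/vulnerable by the rule, and the cluster
    test run per target on the local z-series of that target's completers.
    Reports the fraction of datasets with a surviving DLPFC cluster whose
    midpoint falls inside the injected late window, and the fraction with any
    surviving IPL cluster (expected: none beyond false positives).
    """
    cfg = replace(config or fast_config(), n_subjects=n_subjects)
    rng = np.random.default_rng(seed)
    hits = {"DLPFC": 0, "IPL": 0}
    valid = {"DLPFC": 0, "IPL": 0}
    midpoints: list[float] = []
    a, b = cfg.late_window_ms
    for _ in range(n_datasets):
        cohort, profiles = simulate_cohort_table(cfg, rng)
        vmap = dict(zip(profiles["subject_id"], profiles["vulnerability"]))
        for target in ("DLPFC", "IPL"):
            groups = {"resilient": [], "vulnerable": []}
            for _, r in cohort.df.iterrows():
                if target not in r["completed_targets"]:
                    continue
                label = classify_resilience(r["phq_pre"], r["phq_pandemic"]).label
                prof = LatentProfile(r["subject_id"], vmap[r["subject_id"]])
                groups[label].append(_local_z(prof, target, cfg, rng))
            if min(len(g) for g in groups.values()) < 2:
                continue
            valid[target] += 1
            res = cluster_permutation_test(
                groups["vulnerable"], groups["resilient"],
                n_perm=n_perm, seed=int(rng.integers(2**31)),
            )
            if target == "DLPFC":
                mids = [0.5 * (c.start_ms + c.end_ms) for c in res.surviving]
                in_window = [m for m in mids if a <= m <= b]
                if in_window:
                    hits[target] += 1
                    midpoints.append(in_window[0])
            elif res.surviving:
                hits[target] += 1
    return {
        "dlpfc_recovery_rate": hits["DLPFC"] / max(valid["DLPFC"], 1),
        "ipl_false_cluster_rate": hits["IPL"] / max(valid["IPL"], 1),
        "n_datasets": n_datasets,
        "n_valid_dlpfc": valid["DLPFC"],
        "n_valid_ipl": valid["IPL"],
        "median_midpoint_ms": float(np.median(midpoints)) if midpoints else float("nan"),
    }


# ---------------------------------------------------------------------------
# questionnaire generator calibration
# ---------------------------------------------------------------------------

def pss_phq_calibration(n_seeds: int = 50, n_subjects: int = 500, seed: int = 0
                        ) -> dict:
    """Median Spearman correlation between PSS-14 and mean pandemic PHQ-4
    across generator seeds (design target: the study's reported .69)."""
    rng = np.random.default_rng(seed)
    cfg = replace(SimulationConfig(), n_subjects=n_subjects)
    rhos = []
    for _ in range(n_seeds):
        cohort, _ = simulate_cohort_table(cfg, rng)
        pan = cohort.df["phq_pandemic"].map(mean_pandemic_score)
        rho, _p = spearman(cohort.df["pss14"].to_numpy(float), pan.to_numpy(float))
        rhos.append(rho)
    return {"median_rho": float(np.median(rhos)), "n_seeds": n_seeds,
            "n_subjects": n_subjects, "rhos": rhos}


# ---------------------------------------------------------------------------
# regression-stage calibrations
# ---------------------------------------------------------------------------

def _score_cohort(cohort, profiles, cfg, rng) -> pd.DataFrame:
    vmap = dict(zip(profiles["subject_id"], profiles["vulnerability"]))
    rows = []
    for _, r in cohort.df.iterrows():
        prof = LatentProfile(r["subject_id"], vmap[r["subject_id"]])
        for target in r["completed_targets"]:
            src, sen = simulate_subject_tep(prof, target, cfg, rng)
            score = score_subject(sen, src, make_roi(target, cfg))
            rows.append(vars(score))
    return pd.DataFrame(rows)


def sign_recovery_rate(n_reps: int = 100, n_subjects: int = 56, seed: int = 0,
                       config: SimulationConfig | None = None) -> dict:
    """Fraction of replicate cohorts where the reduced model recovers the
    generative signs: positive local reactivity, negative education."""
    cfg = replace(config or fast_config(), n_subjects=n_subjects)
    rng = np.random.default_rng(seed)
    n_ok = n_local = n_edu = 0
    for _ in range(n_reps):
        cohort, profiles = simulate_cohort_table(cfg, rng)
        scores = _score_cohort(cohort, profiles, cfg, rng)
        X, y, _ = reg.build_design(cohort, scores, reg.MODEL_SPECS["reduced_dlpfc"])
        yt, lam, shift = reg.boxcox(y.values)
        fit = reg.fit_ols(X, yt, name="reduced_dlpfc", lam=lam, shift=shift)
        loc_pos = fit.params["local_auc"] > 0
        edu_neg = fit.params["education_years"] < 0
        n_local += loc_pos
        n_edu += edu_neg
        n_ok += loc_pos and edu_neg
    return {"both_signs_rate": n_ok / n_reps,
            "local_positive_rate": n_local / n_reps,
            "education_negative_rate": n_edu / n_reps,
            "n_reps": n_reps}


def lrt_null_calibration(n_reps: int = 500, n: int = 400, k_reduced: int = 2,
                         k_extra: int = 6, seed: int = 0) -> dict:
    """Under a null where the extra predictors are pure noise, the LRT
    statistic should follow chi2 with k_extra degrees of freedom; returns the
    KS p-value of the simulated chi2 sample against that distribution."""
    rng = np.random.default_rng(seed)
    chi2s = []
    for _ in range(n_reps):
        X = pd.DataFrame(rng.normal(size=(n, k_reduced + k_extra)),
                         columns=[f"x{i}" for i in range(k_reduced + k_extra)])
        X.insert(0, "const", 1.0)
        beta = np.zeros(k_reduced + k_extra)
        beta[:k_reduced] = rng.normal(size=k_reduced)
        y = 1.0 + X.iloc[:, 1:].values @ beta + rng.normal(size=n)
        full = reg.fit_ols(X, y, name="full")
        red = reg.fit_ols(X.iloc[:, : 1 + k_reduced], y, name="reduced")
        chi2s.append(reg.likelihood_ratio_test(full, red).chi2)
    ks = stats.kstest(chi2s, stats.chi2(k_extra).cdf)
    return {"ks_p": float(ks.pvalue), "df": k_extra, "n_reps": n_reps,
            "mean_chi2": float(np.mean(chi2s))}


# ---------------------------------------------------------------------------
# the study-shaped end-to-end analysis
# ---------------------------------------------------------------------------

def study_run(seed: int = 0, n_subjects: int = 74, n_perm: int = 1000,
              config: SimulationConfig | None = None) -> dict:
    """One full analysis at study scale, in memory.

    Simulates a cohort (default n=74, full -1000..+2000 ms epoch at 1 kHz),
    scores every completed subject x target, classifies resilience, runs the
    four cluster tests (two targets x local/global measure), the Spearman
    stress/mental-health correlation, and the regression model suite.
    """
    cfg = replace(config or SimulationConfig(), n_subjects=n_subjects)
    rng = np.random.default_rng(seed)
    cohort, profiles = simulate_cohort_table(cfg, rng)
    vmap = dict(zip(profiles["subject_id"], profiles["vulnerability"]))

    score_rows = []
    series: dict[tuple[str, str, str], object] = {}
    labels: dict[str, str] = {}
    for _, r in cohort.df.iterrows():
        sid = r["subject_id"]
        labels[sid] = classify_resilience(r["phq_pre"], r["phq_pandemic"]).label
        prof = LatentProfile(sid, vmap[sid])
        for target in r["completed_targets"]:
            src, sen = simulate_subject_tep(prof, target, cfg, rng)
            roi = make_roi(target, cfg)
            z = local_response(src, roi)
            g = gmfa(sen)
            series[(sid, target, "local")] = z
            series[(sid, target, "global")] = g
            score_rows.append(vars(score_subject(sen, src, roi)))
    scores = pd.DataFrame(score_rows)

    cluster_results: dict[str, dict] = {}
    group_ns: dict[str, dict] = {}
    for target in ("DLPFC", "IPL"):
        for measure in ("local", "global"):
            ga = [series[k] for k in series
                  if k[1] == target and k[2] == measure and labels[k[0]] == "vulnerable"]
            gb = [series[k] for k in series
                  if k[1] == target and k[2] == measure and labels[k[0]] == "resilient"]
            res = cluster_permutation_test(
                ga, gb, n_perm=n_perm, seed=int(rng.integers(2**31)))
            key = f"{target}_{measure}"
            cluster_results[key] = res.to_dict()
            group_ns[key] = {"vulnerable": len(ga), "resilient": len(gb)}

    pan = cohort.df["phq_pandemic"].map(mean_pandemic_score)
    rho, rho_p = spearman(cohort.df["pss14"].to_numpy(float), pan.to_numpy(float))

    regress = reg.run_model_suite(cohort, scores, lilliefors_seed=seed)
    regress.pop("_fits", None)

    n_res = sum(1 for v in labels.values() if v == "resilient")
    return {
        "seed": seed,
        "n_subjects": n_subjects,
        "n_resilient": n_res,
        "n_vulnerable": n_subjects - n_res,
        "group_ns": group_ns,
        "spearman_pss_phq": {"rho": rho, "p": rho_p},
        "clusters": cluster_results,
        "regression": regress,
        "scores": scores,
        "cohort": cohort,
        "labels": labels,
    }
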