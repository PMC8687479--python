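"""File-based pipeline: simulate -> score -> classify -> cluster-test -> regress.

Every stage reads and writes the documented on-disk formats, so a run
directory is a complete, reproducible record: TEP arrays, cohort.csv,
scores.csv, one cluster-test JSON per target x measure, the regression
report, a run manifest with checksums, and a human-readable summary.
Outputs are a pure function of (config, seed).
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .groupstats import classify_resilience, cluster_permutation_test, spearman, mean_pandemic_score
from .io import CohortTable, read_cohort, read_tep
from .reactivity import gmfa, local_response, score_subject
from .regression import run_model_suite
from .simulate import SimulationConfig, config_from_dict, make_roi, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_perm: int = 1000
    alpha: float = 0.05
    percentile: float = 95.0
    null_mode: str = "max_per_perm"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and not isinstance(d["sim"], SimulationConfig):
            d["sim"] = config_from_dict(d["sim"])
        return cls(**d)


def _load_teps(data_dir: str) -> dict:
    """(subject_id, target, space) -> TEPTimeSeries for every .tep file."""
    teps = {}
    for path in sorted(glob.glob(os.path.join(data_dir, "*.tep"))):
        tep = read_tep(path)
        teps[(tep.subject_id, tep.target, tep.space)] = tep
    if not teps:
        raise FileNotFoundError(f"no .tep files found in {data_dir}")
    return teps


def _roi_for(target: str, tep) -> "object":
    """ROI vertex ids for a source-space TEP written by the generator: the
    target's contiguous id block (first half DLPFC, second half IPL)."""
    n = len(tep.series_ids) // 2
    cfg = SimulationConfig(n_roi_vertices=n)
    return make_roi(target, cfg)


def score_directory(data_dir: str) -> pd.DataFrame:
    """Reactivity scores (one row per subject x completed target) from a
    directory of TEP files containing both spaces per subject x target."""
    teps = _load_teps(data_dir)
    pairs = sorted({(s, t) for (s, t, _sp) in teps})
    rows = []
    for sid, target in pairs:
        sen = teps.get((sid, target, "sensor"))
        src = teps.get((sid, target, "source_roi"))
        score = score_subject(sen, src, _roi_for(target, src))
        rows.append(vars(score))
    return pd.DataFrame(rows)


def cluster_stage(data_dir: str, cohort: CohortTable, target: str,
                  measure: str, n_perm: int = 1000, alpha: float = 0.05,
                  percentile: float = 95.0, null_mode: str = "max_per_perm",
                  seed: int | None = None):
    """Run the resilient-vs-vulnerable cluster test for one target x measure
    ("local" = z-scored source ROI series, "global" = sensor GMFA)."""
    if measure not in ("local", "global"):
        raise ValueError(f"unknown measure {measure!r}")
    teps = _load_teps(data_dir)
    groups: dict[str, list] = {"resilient": [], "vulnerable": []}
    for _, r in cohort.df.iterrows():
        sid = r["subject_id"]
        space = "source_roi" if measure == "local" else "sensor"
        tep = teps.get((sid, target, space))
        if tep is None:
            continue
        label = classify_resilience(r["phq_pre"], r["phq_pandemic"]).label
        if measure == "local":
            series = local_response(tep, _roi_for(target, tep))
        else:
            series = gmfa(tep)
        groups[label].append(series)
    log.info("cluster test %s/%s: %d resilient vs %d vulnerable", target,
             measure, len(groups["resilient"]), len(groups["vulnerable"]))
    return cluster_permutation_test(
        groups["vulnerable"], groups["resilient"], n_perm=n_perm, alpha=alpha,
        percentile=percentile, null_mode=null_mode, seed=seed,
    ), {k: len(v) for k, v in groups.items()}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the whole pipeline into ``config.out_dir``; returns the summary.

    Stage failures abort with the stage name; outputs of completed stages are
    left in place.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    data_dir = os.path.join(out, "data")
    stage = "simulate"
    try:
        log.info("stage %s: n=%d seed=%d", stage, config.sim.n_subjects, config.seed)
        simulate_cohort(config.sim, seed=config.seed, out_dir=data_dir,
                        keep_in_memory=False)

        stage = "score"
        cohort = read_cohort(os.path.join(data_dir, "cohort.csv"))
        scores = score_directory(data_dir)
        scores_path = os.path.join(out, "scores.csv")
        scores.to_csv(scores_path, index=False)
        log.info("stage score: %d subject x target rows", len(scores))

        stage = "cluster-test"
        rng = np.random.default_rng(config.seed)
        cluster_summaries = {}
        for target in ("DLPFC", "IPL"):
            for measure in ("local", "global"):
                res, ns = cluster_stage(
                    data_dir, cohort, target, measure,
                    n_perm=config.n_perm, alpha=config.alpha,
                    percentile=config.percentile, null_mode=config.null_mode,
                    seed=int(rng.integers(2**31)),
                )
                name = f"cluster_{target}_{measure}.json"
                with open(os.path.join(out, name), "w") as fh:
                    json.dump({"group_ns": ns, **res.to_dict()}, fh, indent=2,
                              sort_keys=True)
                cluster_summaries[f"{target}_{measure}"] = {
                    "group_ns": ns,
                    "surviving": [(c.start_ms, c.end_ms) for c in res.surviving],
                }

        stage = "regress"
        report = run_model_suite(cohort, scores, lilliefors_seed=config.seed)
        report.pop("_fits", None)
        with open(os.path.join(out, "regression_report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

        stage = "summarize"
        pan = cohort.df["phq_pandemic"].map(mean_pandemic_score)
        rho, rho_p = spearman(cohort.df["pss14"].to_numpy(float),
                              pan.to_numpy(float))
        labels = [classify_resilience(r["phq_pre"], r["phq_pandemic"]).label
                  for _, r in cohort.df.iterrows()]
        summary = {
            "seed": config.seed,
            "tepkit_version": __version__,
            "n_subjects": len(cohort),
            "n_resilient": labels.count("resilient"),
            "n_vulnerable": labels.count("vulnerable"),
            "spearman_pss_phq": {"rho": rho, "p": rho_p},
            "clusters": cluster_summaries,
            "regression": {
                m: {k: e[k] for k in ("F", "F_p", "r2_adj", "aic", "bic", "n")}
                for m, e in report["models"].items()
            },
            "lrt_full_vs_reduced_dlpfc": report["lrt_full_vs_reduced_dlpfc"],
        }
        with open(os.path.join(out, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_summary_text(os.path.join(out, "summary.txt"), summary)

        manifest = {
            "seed": config.seed,
            "tepkit_version": __version__,
            "outputs": {
                os.path.relpath(p, out): _sha256(p)
                for p in sorted(
                    glob.glob(os.path.join(out, "*.json"))
                    + glob.glob(os.path.join(out, "*.csv"))
                    + glob.glob(os.path.join(out, "*.txt"))
                )
            },
        }
        with open(os.path.join(out, "run_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    return summary


def _write_summary_text(path: str, s: dict) -> None:
    lines = [
        f"tepkit {s['tepkit_version']} run (seed={s['seed']})",
        f"cohort: {s['n_subjects']} subjects "
        f"({s['n_resilient']} resilient / {s['n_vulnerable']} vulnerable)",
        "Spearman(PSS-14, mean pandemic PHQ-4): rho=%.3f p=%.2g"
        % (s["spearman_pss_phq"]["rho"], s["spearman_pss_phq"]["p"]),
        "",
        "cluster tests (surviving clusters, ms):",
    ]
    for key, c in s["clusters"].items():
        ns = c["group_ns"]
        surv = ", ".join(f"[{a:.0f}, {b:.0f}]" for a, b in c["surviving"]) or "none"
        lines.append(f"  {key}: n={ns['vulnerable']}/{ns['resilient']} "
                     f"(vulnerable/resilient) -> {surv}")
    lines.append("")
    lines.append("regression models (Box-Cox transformed response):")
    for m, e in s["regression"].items():
        lines.append(
            "  %s: F=%.2f (p=%.3g), R2adj=%.3f, AIC=%.2f, BIC=%.2f, n=%d"
            % (m, e["F"], e["F_p"], e["r2_adj"], e["aic"], e["bic"], e["n"]))
    lrt = s["lrt_full_vs_reduced_dlpfc"]
    lines.append("  LRT full vs reduced (DLPFC): chi2(%d)=%.2f, p=%.3f"
                 % (lrt["df"], lrt["chi2"], lrt["p"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
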