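"""End-to-end orchestration: simulate → feasibility → attribute → rhythms.

`run_pipeline` executes the stages in dependency order against either a
supplied flow log or a freshly simulated cohort, writes each stage's
output files, and records a JSON run manifest with content hashes so a
rerun under the same configuration can be checked for bit-identical
outputs.  `write_report` recomputes a cohort summary purely from the stage
CSVs (no independent arithmetic).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from netrhythm import attribution, feasibility, flow_io, rhythms, synthetic

logger = logging.getLogger("netrhythm")


@dataclass
class PipelineConfig:
    """All knobs for one run; every field lands in the run manifest."""

    out_dir: str = "netrhythm_run"
    flow_log: str | None = None  # existing log; None -> simulate
    apr_dir: str | None = None  # directory of APR JSON files; None -> simulate
    categories: str | None = None  # category-map CSV; None -> simulate
    n_participants: int = 24
    days: int = 14
    seed: int = 0
    tz_offset_minutes: int = -300
    coverage_bin_width: int = 60
    rhythm_bin_width: int = 10
    threshold_days: int = 5
    bootstrap_reps: int = 10_000
    min_obs_fraction: float = 0.5

    def validate(self) -> None:
        for path in (self.flow_log, self.apr_dir, self.categories):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")
        if 1440 % self.coverage_bin_width or 1440 % self.rhythm_bin_width:
            raise ValueError("bin widths must divide 1440")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return the manifest (also written to the output dir)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "status": "running"}
    t_start = time.perf_counter()

    def record(stage: str, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in files},
            "seconds": round(time.perf_counter() - t_start, 3),
        }

    try:
        # --- inputs: load or simulate ---
        apps = synthetic.default_apps()
        if config.flow_log:
            records = flow_io.read_flow_log(config.flow_log)
            cohort = flow_io.records_to_frame(records)
            truths = None
        else:
            cohort, truths = synthetic.simulate_cohort(
                synthetic.CohortConfig(
                    n_participants=config.n_participants,
                    days=config.days,
                    seed=config.seed,
                    tz_offset_minutes=config.tz_offset_minutes,
                )
            )
            log_path = out / "flow_log.csv"
            flow_io.write_flow_log(cohort, log_path)
            truth_path = out / "ground_truth.json"
            synthetic.write_ground_truth(truths, truth_path)
            record("simulate", [log_path, truth_path])
        per_participant = flow_io.split_by_participant(cohort)
        logger.info("loaded %d participants, %d flow records", len(per_participant), len(cohort))

        # --- feasibility ---
        rows = []
        hourly = {}
        for pid, frame in per_participant.items():
            series = flow_io.bin_traffic(frame, config.coverage_bin_width, config.tz_offset_minutes)
            hourly[pid] = series
            cov = feasibility.hour_coverage(series)
            strata = feasibility.stratify_coverage(series)
            gaps = cov.gaps
            rows.append(
                {
                    "participant_id": pid,
                    "window_hours": cov.window_hours,
                    "active_hours": cov.active_hours,
                    "coverage_fraction": cov.coverage_fraction,
                    "valid_days": cov.valid_days,
                    "n_gaps": len(gaps),
                    "median_gap_hours": float(np.median(gaps)) if gaps else 0.0,
                    "max_gap_hours": max(gaps) if gaps else 0.0,
                    **{f"coverage_{k}": v for k, v in strata.items()},
                }
            )
        coverage_frame = pd.DataFrame(rows)
        coverage_path = out / "coverage.csv"
        coverage_frame.to_csv(coverage_path, index=False)
        record("feasibility", [coverage_path])

        # --- attribution ---
        if config.apr_dir:
            reports = []
            for p in sorted(Path(config.apr_dir).glob("*.json")):
                payload = json.loads(p.read_text())
                source = "scripted" if "scripted" in p.stem else "participant"
                reports.append(attribution.read_apr_json(payload, source))
        else:
            reports = [
                attribution.read_apr_json(
                    synthetic.emit_apr_reports(apps, "scripted", seed=config.seed), "scripted"
                ),
                attribution.read_apr_json(
                    synthetic.emit_apr_reports(apps, "participant", seed=config.seed + 1),
                    "participant",
                ),
            ]
        if config.categories:
            categories = attribution.read_category_map(config.categories)
        else:
            cat_path = out / "categories.csv"
            categories_frame = synthetic.emit_category_map(apps, cat_path)
            categories = dict(zip(categories_frame["bundle_id"], categories_frame["genre"]))
        corpus = attribution.build_corpus(reports)
        umap = attribution.unique_app_domains(corpus)
        map_path = out / "unique_domains.tsv"
        umap.to_frame().to_csv(map_path, sep="\t", index=False)
        attributed = attribution.attribute(cohort, umap, categories)
        acov = attribution.attribution_coverage(attributed, umap, bin_width=config.rhythm_bin_width)
        attr_stats_path = out / "attribution.json"
        attr_stats_path.write_text(
            json.dumps(
                {
                    "n_apps": corpus.n_apps,
                    "n_domains": corpus.n_domains,
                    "unique_domain_fraction": umap.unique_fraction,
                    "byte_fraction_up": acov.byte_fraction_up,
                    "bin_fraction": acov.bin_fraction,
                },
                indent=1,
            )
        )
        record("attribute", [map_path, attr_stats_path])

        # --- rhythms ---
        metric_rows, cluster_input, radial_frames = [], [], []
        for pid, frame in per_participant.items():
            series = flow_io.bin_traffic(frame, config.rhythm_bin_width, config.tz_offset_minutes)
            matrix = rhythms.build_profile_matrix(series, direction="up")
            m = rhythms.compute_rhythm_metrics(matrix, config.min_obs_fraction)
            metric_rows.append(
                {
                    "participant_id": pid,
                    "stability": m.stability,
                    "circadian_power_ratio": m.circadian_power_ratio,
                    "n_days_used": m.n_days_used,
                }
            )
            cluster_input.append(m)
            radial_frames.append(rhythms.radial_grid(matrix))
        metrics_path = out / "rhythm_metrics.csv"
        pd.DataFrame(metric_rows).to_csv(metrics_path, index=False)
        radial_path = out / "radial_grid.csv"
        pd.concat(radial_frames, ignore_index=True).to_csv(radial_path, index=False)
        files = [metrics_path, radial_path]
        if len(cluster_input) >= 2:
            assign = rhythms.cluster_rhythms(cluster_input, seed=config.seed)
            cluster_path = out / "clusters.csv"
            pd.DataFrame(
                {"participant_id": list(assign.labels), "cluster": list(assign.labels.values())}
            ).to_csv(cluster_path, index=False)
            files.append(cluster_path)
        record("rhythms", files)
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def write_report(out_dir: str | Path, bootstrap_reps: int = 10_000, seed: int = 0, threshold_days: int = 5) -> dict:
    """Cohort summary recomputed from the stage CSVs.

    Writes ``report.json`` and a human-readable ``report.txt`` in the run
    directory; returns the JSON payload.
    """
    out = Path(out_dir)
    coverage_path = out / "coverage.csv"
    if not coverage_path.exists():
        raise FileNotFoundError(f"feasibility output missing: {coverage_path}")
    cov = pd.read_csv(coverage_path)
    if cov.empty:
        raise ValueError("empty cohort: no participants in coverage output")

    coverage = cov["coverage_fraction"].to_numpy()
    lo, hi = feasibility.bootstrap_mean_ci(coverage, reps=bootstrap_reps, seed=seed)
    retention = feasibility.retention_summary(cov["valid_days"], threshold=threshold_days)
    s, n, p, wlo, whi = retention.proportions["retained_among_contributors"]

    strata_cols = [c for c in cov.columns if c.startswith("coverage_")]
    report = {
        "n_participants": int(len(cov)),
        "coverage": {
            "mean": float(coverage.mean()),
            "median": float(np.median(coverage)),
            "iqr": [float(np.percentile(coverage, 25)), float(np.percentile(coverage, 75))],
            "bootstrap_ci95": [lo, hi],
        },
        "strata_mean_coverage": {
            c.removeprefix("coverage_"): float(cov[c].mean()) for c in strata_cols
        },
        "gaps": {
            "median_of_medians_hours": float(cov["median_gap_hours"].median()),
            "max_hours": float(cov["max_gap_hours"].max()),
        },
        "retention": {
            "threshold_days": threshold_days,
            "retained": int(s),
            "contributors": int(n),
            "proportion": p,
            "wilson_ci95": [wlo, whi],
        },
    }
    metrics_path = out / "rhythm_metrics.csv"
    if metrics_path.exists():
        met = pd.read_csv(metrics_path)
        report["rhythms"] = {
            "stability": {"mean": float(met["stability"].mean()), "sd": float(met["stability"].std())},
            "circadian_power_ratio": {
                "mean": float(met["circadian_power_ratio"].mean()),
                "sd": float(met["circadian_power_ratio"].std()),
            },
        }
    clusters_path = out / "clusters.csv"
    if clusters_path.exists():
        cl = pd.read_csv(clusters_path)
        report["cluster_sizes"] = cl["cluster"].value_counts().sort_index().to_dict()

    (out / "report.json").write_text(json.dumps(report, indent=1))
    lines = [
        f"Cohort of {report['n_participants']} participants",
        f"Coverage: mean {report['coverage']['mean']:.1%}, median {report['coverage']['median']:.1%} "
        f"(IQR {report['coverage']['iqr'][0]:.1%}-{report['coverage']['iqr'][1]:.1%}; "
        f"bootstrap 95% CI {lo:.1%}-{hi:.1%})",
        f"Retention (>= {threshold_days} valid days): {s}/{n} = {p:.0%} "
        f"(Wilson 95% CI {wlo:.0%}-{whi:.0%})",
    ]
    if "cluster_sizes" in report:
        lines.append(f"Rhythm clusters: {report['cluster_sizes']}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
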