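"""End-to-end orchestration: simulate -> ingest -> score -> neighborhoods.

A run reads (or simulates) the input tables, writes every stage output as
CSV under the configured output directory, and finishes with a manifest
recording the config hash, input/output file hashes, package version, ledger
rollup and wall timestamps. Identical config + seed + inputs reproduce
identical output hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

import sds
from sds.config import RunConfig
from sds.core import (
    aggregate_zip,
    citywide_complaint_curves,
    score_units,
    type_summary,
)
from sds.ingest import (
    FilterLedger,
    bin_six_hour,
    flag_complaints,
    load_tables,
    pool_to_buildings,
)
from sds.neighborhoods import (
    classify_quartiles,
    compare_groups,
    compare_police_by_group,
    correlate_indicators,
    police_action_rates,
)
from sds.synthetic import generate_city


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    started: str
    finished: str = ""
    input_hashes: dict = field(default_factory=dict)
    output_hashes: dict = field(default_factory=dict)
    ledger: list = field(default_factory=list)
    failed_stage: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False)
    manifest.output_hashes[path.name] = _sha256(path)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute a full run; outputs land in ``config.out_dir``.

    Stage failures abort with a partial manifest (``failed_stage`` set)
    written to the output directory before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(config.to_yaml().encode()).hexdigest(),
        package_version=sds.__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )
    ledger = FilterLedger()
    stage = "ingest"
    try:
        if config.synthetic is not None:
            stage = "simulate"
            poi, visits, complaints, covariates, truth = generate_city(config.synthetic)
            _write(poi, out / "poi.csv", manifest)
            _write(visits, out / "visits.csv", manifest)
            _write(complaints, out / "complaints.csv", manifest)
            _write(covariates, out / "covariates.csv", manifest)
            (out / "ground_truth.json").write_text(
                json.dumps({"theta": truth.theta}, indent=2, sort_keys=True)
            )
        else:
            stage = "ingest"
            poi, visits, complaints, ledger = load_tables(
                config.poi_path, config.visits_path, config.complaints_path, ledger
            )
            for p in (config.poi_path, config.visits_path, config.complaints_path):
                manifest.input_hashes[Path(p).name] = _sha256(Path(p))
            covariates = (
                pd.read_csv(config.covariates_path, dtype={"zip": str})
                if config.covariates_path
                else None
            )

        stage = "pooling"
        units, unit_visits, ledger = pool_to_buildings(poi, visits, ledger)
        stage = "binning"
        intervals = bin_six_hour(unit_visits, units)
        polygons = None
        if config.zips_geojson:
            from sds.geo import load_polygons

            polygons = load_polygons(config.zips_geojson)
        intervals, ledger = flag_complaints(intervals, complaints, ledger, polygons)

        stage = "scoring"
        est, ledger = score_units(intervals, units, config.score, ledger)
        zip_scores = aggregate_zip(est)
        curves = citywide_complaint_curves(intervals)
        summary = type_summary(est, units, complaints)
        _write(est, out / "thresholds.csv", manifest)
        _write(zip_scores, out / "zip_scores.csv", manifest)
        _write(curves, out / "curves.csv", manifest)
        _write(summary, out / "type_summary.csv", manifest)

        stage = "neighborhoods"
        if covariates is not None and len(zip_scores) >= 4:
            grouping = classify_quartiles(zip_scores)
            quart = grouping.labels.reset_index()
            quart.columns = ["zip", "quartile"]
            _write(quart, out / "quartiles.csv", manifest)
            comp = compare_groups(grouping, covariates)
            _write(comp, out / "group_comparison.csv", manifest)
            indicators = [
                i for i in config.analysis.indicators if i in covariates.columns
            ]
            if indicators:
                corr = correlate_indicators(zip_scores, covariates, indicators)
                _write(corr, out / "correlations.csv", manifest)
            if "police_action" in complaints.columns:
                rates = police_action_rates(complaints, units)
                pol = compare_police_by_group(
                    rates,
                    grouping,
                    covariates,
                    config.analysis.demographic_col,
                    config.analysis.police_low,
                    config.analysis.police_high,
                )
                _write(pol.rows, out / "police_comparison.csv", manifest)
    except Exception:
        manifest.failed_stage = stage
        manifest.ledger = ledger.steps
        manifest.finished = datetime.now(timezone.utc).isoformat()
        (out / "manifest.json").write_text(manifest.to_json())
        raise

    manifest.ledger = ledger.steps
    ledger.write(out / "ledger.json")
    manifest.finished = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def render_report(results_dir: str | Path, out_path: str | Path | None = None) -> str:
    """Assemble a markdown summary of a completed run.

    Sections appear only when their CSV exists; missing core outputs
    (thresholds, zip scores) raise. The filter ledger is appended verbatim.
    """
    results = Path(results_dir)
    out_path = Path(out_path) if out_path else results / "report.md"
    required = ["thresholds.csv", "zip_scores.csv"]
    missing = [f for f in required if not (results / f).exists()]
    if missing:
        raise FileNotFoundError(f"results directory incomplete, missing: {missing}")

    parts = ["# Social distancing sensitivity report\n"]
    est = pd.read_csv(results / "thresholds.csv")
    parts.append(
        f"Scored units: {len(est)}. Mean A = {est['A'].mean():.2f} visits per "
        f"10,000 sq ft per interval; mean D = {est['D'].mean():.2f}; "
        f"mean SDS = {est['SDS'].mean():.2f}.\n"
    )

    def _md_table(df: pd.DataFrame) -> str:
        cells = df.astype(str).values.tolist()
        header = list(df.columns)
        widths = [
            max(len(h), *(len(r[i]) for r in cells)) if cells else len(h)
            for i, h in enumerate(header)
        ]
        def row(vals):
            return "| " + " | ".join(v.ljust(w) for v, w in zip(vals, widths)) + " |"
        lines = [row(header), row(["-" * w for w in widths])]
        lines += [row(r) for r in cells]
        return "\n".join(lines)

    def _section(fname: str, title: str) -> None:
        p = results / fname
        if p.exists():
            df = pd.read_csv(p)
            parts.append(f"## {title}\n\n{_md_table(df)}\n")
        else:
            parts.append(f"## {title}\n\nnot computed\n")

    _section("type_summary.csv", "Sensitivity by establishment type")
    _section("zip_scores.csv", "Neighborhood scores")
    _section("quartiles.csv", "Sensitivity quartiles")
    _section("correlations.csv", "Health indicator correlations")
    _section("police_comparison.csv", "Police response by sensitivity group")

    curves_path = results / "curves.csv"
    if curves_path.exists():
        try:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            curves = pd.read_csv(curves_path, parse_dates=["interval_start"])
            fig, ax = plt.subplots(figsize=(9, 3))
            ax.plot(curves["interval_start"], curves["complaint_intensity"],
                    color="tab:red", lw=0.8, label="complaint reported")
            ax.plot(curves["interval_start"], curves["baseline_intensity"],
                    color="tab:blue", lw=0.8, label="baseline")
            ax.set_ylabel("visits / 10,000 sq ft / 6 h")
            ax.legend(frameon=False)
            fig.tight_layout()
            fig.savefig(results / "curves.png", dpi=120)
            plt.close(fig)
            parts.append("## Citywide complaint vs baseline intensity\n\n"
                         "![curves](curves.png)\n")
        except Exception:  # plotting is best-effort
            pass

    ledger_path = results / "ledger.json"
    if ledger_path.exists():
        parts.append("## Filter ledger\n\n```json\n"
                     + ledger_path.read_text() + "\n```\n")
    text = "\n".join(parts)
    out_path.write_text(text)
    return text
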