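"""End-to-end pipeline driver.

``run_pipeline`` takes a validated configuration and produces a results
directory containing per-PNN topology metrics, section-level PNN and
puncta tables, group statistics and a run log that records every
defaulted parameter.  Given the same configuration and seed the output
CSVs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path as FsPath

import pandas as pd

from . import __version__
from .config import PipelineConfig, defaulted_fields, dump_config
from .geometry import AcquisitionGeometry
from .nodes import DetectParams, detect_nodes
from .pnn import classify_pv, count_pnns, measure_pnn, subtract_background
from .puncta import PunctaDetectParams, quantify_channel
from .stats import analyze_metric
from .synthetic import (
    CohortParams,
    PnnStackParams,
    generate_cohort,
    make_design,
)
from .topology import summarize_topology

logger = logging.getLogger("pnnkit")

__all__ = ["run_pipeline", "topology_tables", "section_tables"]

_FLOAT_FMT = "%.9g"


def _geometry(config: PipelineConfig) -> AcquisitionGeometry:
    g = config.geometry
    return AcquisitionGeometry(g.lateral_spacing, g.axial_spacing, g.n_slices,
                               g.psf_sigma_lateral, g.psf_sigma_axial)


def _cohort(config: PipelineConfig):
    sim = config.simulate
    design = make_design(sim.n_animals_per_group, sim.subregion,
                         sim.n_sections, sim.n_pnns_per_section)
    params = CohortParams(
        stack=PnnStackParams(shell_radius=sim.shell_radius, snr=sim.snr),
        node_count=sim.node_count,
        animal_cv=sim.animal_cv,
        effects=config.effect_spec(),
    )
    return generate_cohort(design, params, seed=config.seed,
                           render=sim.render, sections=sim.sections)


def topology_tables(dataset, config: PipelineConfig) -> pd.DataFrame:
    """Per-PNN topology metrics for a cohort dataset.

    With rendered stacks the node clouds come from the detector; in
    summary mode they are the generator's ground-truth coordinates.
    """
    topo = config.topology
    det = DetectParams(config.detector.diameter_um,
                       config.detector.min_separation_um,
                       config.detector.threshold_k)
    rows = []
    for rec in dataset.pnn_records:
        if rec.get("stack") is not None:
            nodes = detect_nodes(rec["stack"], det)
            nodes.pnn_id = rec["pnn_id"]
        else:
            nodes = rec["truth"].node_set(rec["pnn_id"])
        labels = {k: rec[k] for k in ("animal_id", "genotype", "housing",
                                      "subregion", "section")}
        m = summarize_topology(nodes, topo.base_threshold, topo.r95_start,
                               topo.r95_step, topo.r95_max, labels=labels)
        rows.append(m.to_dict())
    return pd.DataFrame(rows)


def section_tables(dataset, config: PipelineConfig):
    """PNN-intensity and puncta tables from a cohort's rendered sections."""
    pq = config.puncta
    det = PunctaDetectParams(pq.threshold, pq.min_size_px, pq.max_size_px,
                             pq.projection)
    pnn_rows, puncta_frames = [], []
    for rec in dataset.section_records:
        channels, truth = rec["channels"], rec["truth"]
        labels = {k: rec[k] for k in ("animal_id", "genotype", "housing",
                                      "subregion", "section")}
        wfa = subtract_background(channels["WFA"], pq.ball_radius_px)
        measured = measure_pnn(wfa, truth.rois)
        flags = classify_pv(channels.get("PV"), truth.rois)
        for i, row in measured.iterrows():
            pnn_rows.append({**labels, **row.to_dict(),
                             "pv_positive": None if flags is None
                             else flags[i]})
        for channel in ("VGAT", "VGlut1"):
            if channel not in channels:
                continue
            sub = subtract_background(channels[channel], pq.ball_radius_px)
            tab = quantify_channel(
                type(channels[channel])(sub.data, channels[channel].geometry,
                                        channel=channel),
                truth.rois, det, channel)
            for k, v in labels.items():
                tab[k] = v
            puncta_frames.append(tab)
    pnn_table = pd.DataFrame(pnn_rows)
    puncta_table = (pd.concat(puncta_frames, ignore_index=True)
                    if puncta_frames else pd.DataFrame())
    return pnn_table, puncta_table


def _stats_rows(result, unit: str) -> list[dict]:
    rows = []
    for effect, (stat, p) in result.statistics.items():
        rows.append({"metric": result.metric, "unit": unit,
                     "test": result.test, "effect": effect,
                     "statistic": stat, "p": p,
                     "significant": bool(p < result.alpha),
                     "gate": result.gate.get("choice", "")})
    return rows


def run_pipeline(config: PipelineConfig) -> FsPath:
    """Run simulate → detect → topology → quantify → stats; return out dir."""
    out = FsPath(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pnnkit %s | seed=%d | out=%s", __version__, config.seed, out)
    logger.info("defaulted config fields: %s",
                ", ".join(defaulted_fields(config)) or "(none)")
    dump_config(config, out / "run_config.yaml")

    if not config.simulate.enabled:
        raise NotImplementedError(
            "only --simulate cohorts are wired into run_pipeline; call the "
            "stage functions directly for external data")

    dataset = _cohort(config)
    dataset.truth_table().to_csv(out / "truth_nodes.csv", index=False,
                                 float_format=_FLOAT_FMT)

    topo = topology_tables(dataset, config)
    topo = topo.sort_values("pnn_id", kind="mergesort").reset_index(drop=True)
    topo.to_csv(out / "topology_per_pnn.csv", index=False,
                float_format=_FLOAT_FMT)

    stats_rows: list[dict] = []
    for metric in ("n_nodes", "pct_connected", "mean_internode_dist",
                   "mean_degree", "r95"):
        table = topo.rename(columns={metric: "value"})[
            ["animal_id", "genotype", "housing", "value"]].dropna()
        if table.empty or table["value"].nunique() < 2:
            continue
        res = analyze_metric(table, metric,
                             force=config.stats.force_gate,
                             p_adjust=config.stats.p_adjust)
        stats_rows.extend(_stats_rows(res, unit="per-PNN"))
        res.posthoc.assign(metric=metric).to_csv(
            out / f"posthoc_{metric}.csv", index=False,
            float_format=_FLOAT_FMT)

    if config.simulate.sections:
        pnn_table, puncta_table = section_tables(dataset, config)
        pnn_table.to_csv(out / "pnn_per_roi.csv", index=False,
                         float_format=_FLOAT_FMT)
        puncta_table.to_csv(out / "puncta_per_roi.csv", index=False,
                            float_format=_FLOAT_FMT)
        counts = count_pnns(pnn_table.assign(
            pv_positive=pnn_table["pv_positive"]),
            group_keys=("animal_id", "genotype", "housing", "subregion"))
        counts.to_csv(out / "pnn_counts.csv", index=False)
        for metric_col, name in (("mean_intensity", "wfa_intensity"),):
            table = (pnn_table.groupby(
                ["animal_id", "genotype", "housing"], observed=True)
                [metric_col].mean().rename("value").reset_index())
            if table["value"].nunique() >= 2:
                res = analyze_metric(table, name,
                                     force=config.stats.force_gate,
                                     p_adjust=config.stats.p_adjust)
                stats_rows.extend(_stats_rows(res, unit="per-section-mean"))
        for channel in ("VGAT", "VGlut1"):
            for metric_col in ("density", "mean_size", "mean_intensity"):
                sel = puncta_table[puncta_table["channel"] == channel]
                table = sel.rename(columns={metric_col: "value"})[
                    ["animal_id", "genotype", "housing", "value"]].dropna()
                if table.empty or table["value"].nunique() < 2:
                    continue
                res = analyze_metric(table, f"{channel}_{metric_col}",
                                     force=config.stats.force_gate,
                                     p_adjust=config.stats.p_adjust)
                stats_rows.extend(_stats_rows(res, unit="per-PNN"))

    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(out / "stats_report.csv", index=False,
                    float_format=_FLOAT_FMT)
    summary = {
        "seed": config.seed,
        "n_pnns": len(dataset.pnn_records),
        "n_sections": len(dataset.section_records),
        "metrics_tested": sorted({r["metric"] for r in stats_rows}),
        "significant": sorted({f"{r['metric']}:{r['effect']}"
                               for r in stats_rows if r["significant"]}),
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("pipeline finished: %d PNNs, %d metrics tested",
                summary["n_pnns"], len(summary["metrics_tested"]))
    return out
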