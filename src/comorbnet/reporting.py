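"""Full-run orchestration, exports, summary reports and plots."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from comorbnet.config import PipelineConfig
from comorbnet.network import export_edge_list, export_graphml
from comorbnet.records import (
    CodeMap,
    apply_code_map,
    filter_codes,
    parse_records,
)
from comorbnet.temporal import PipelineResult, module_flow, run_yearly_pipeline
from comorbnet.topology import GREY, cluster_eigen_diseases

logger = logging.getLogger(__name__)


def cmd_run(config: PipelineConfig) -> Path:
    """Execute records -> networks -> modules -> temporal and write exports.

    The output directory receives the exact config used, a structured run
    log, per-year network/module exports, consecutive-year Jaccard matrices,
    and the summary report tables.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_used.yaml")
    log: dict[str, object] = {"stages": []}

    def stage(name: str, t0: float, **info) -> None:
        log["stages"].append({"stage": name, "seconds": round(time.perf_counter() - t0, 3), **info})

    t0 = time.perf_counter()
    records, parse_report = parse_records(config.records_path)
    stage("parse", t0, n_rows=parse_report.n_rows, n_rejected=parse_report.n_rejected)

    if config.apply_code_filter:
        t0 = time.perf_counter()
        records, filt = filter_codes(records)
        stage("filter_codes", t0, n_removed=filt.n_removed, n_unclassifiable=filt.n_unclassifiable)

    if config.code_map_path:
        t0 = time.perf_counter()
        cmap = CodeMap.from_csv(config.code_map_path)
        records, dropped = apply_code_map(records, cmap, on_unmapped=config.on_unmapped)
        stage("code_map", t0, n_dropped=int(sum(dropped.values())))

    t0 = time.perf_counter()
    result = run_yearly_pipeline(
        records,
        config.years,
        tau_policy=config.tau_policy,
        tau=config.tau,
        reference_year=config.reference_year,
        tau_grid=config.tau_grid(),
        r2_target=config.r2_target,
        adjacency_mode=config.adjacency_mode,
        min_module_size=config.min_module_size,
        cut_params=config.cut_params(),
    )
    stage("pipeline", t0, years=result.years, n_common_diseases=len(result.common_diseases))

    t0 = time.perf_counter()
    export_results(result, outdir, write_plots=config.write_plots)
    report_summary(result, outdir)
    stage("export", t0)

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return outdir


def export_results(result: PipelineResult, outdir: str | Path, *, write_plots: bool = False) -> None:
    """Per-year edge lists, GraphML, partitions, fits, Jaccard matrices."""
    outdir = Path(outdir)
    for y, res in result.per_year.items():
        ydir = outdir / f"year_{y}"
        ydir.mkdir(parents=True, exist_ok=True)
        export_edge_list(res.adjacency, ydir / "edges.csv")
        export_graphml(res.adjacency, ydir / "network.graphml")
        res.table.rename_axis("disease").to_csv(ydir / "partition.csv")
        if res.fit is not None:
            res.fit.to_frame().to_csv(ydir / "scale_free_fit.csv", index=False)
        if len(res.partition.eigen) >= 2:
            tree = cluster_eigen_diseases(res.partition.eigen)
            (ydir / "eigen_dendrogram.nwk").write_text(tree.to_newick() + "\n")
        if write_plots:
            _plot_year(res, ydir)
    for cmp_ in result.comparisons:
        y0, y1 = cmp_.year_pair
        cmp_.to_frame().rename_axis(f"module_{y1}").to_csv(outdir / f"jaccard_{y0}_{y1}.csv")
    module_flow(result).to_csv(outdir / "module_flow.csv", index=False)


def report_summary(result: PipelineResult, outdir: str | Path, *, top_n: int = 10) -> dict[str, Path]:
    """Top-prevalence, top-connectivity and per-module hub tables.

    ``top_prevalence.csv``: top diseases by prevalence per year.
    ``top_connectivity.csv``: top diseases by mean K across years.
    ``hubs.csv``: one row per non-grey module and year with the hub's
    connectivity and intramodular connectivity.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    prev_rows = []
    for y in result.years:
        occ = result.per_year[y].occurrence
        prev = (occ.P / occ.N).sort_values(ascending=False).head(top_n)
        for rank, (code, p) in enumerate(prev.items(), 1):
            prev_rows.append({"year": y, "rank": rank, "disease": code, "prevalence": round(p, 6)})
    paths["top_prevalence"] = outdir / "top_prevalence.csv"
    pd.DataFrame(prev_rows, columns=["year", "rank", "disease", "prevalence"]).to_csv(
        paths["top_prevalence"], index=False
    )

    K = pd.DataFrame({y: result.per_year[y].table["K"] for y in result.years})
    meanK = K.mean(axis=1).sort_values(ascending=False).head(top_n)
    paths["top_connectivity"] = outdir / "top_connectivity.csv"
    meanK.round(6).rename("mean_K").rename_axis("disease").reset_index().to_csv(
        paths["top_connectivity"], index=False
    )

    hub_rows = []
    for y in result.years:
        res = result.per_year[y]
        for colour in res.partition.colours:
            hub = res.partition.hubs.get(colour)
            if hub is None:
                continue
            hub_rows.append(
                {
                    "year": y,
                    "module": colour,
                    "hub": hub,
                    "module_size": int(res.partition.sizes()[colour]),
                    "connectivity": round(float(res.table["K"].get(hub, np.nan)), 6),
                    "intramodular_connectivity": round(
                        float(res.table["intramodular_K"].get(hub, np.nan)), 6
                    ),
                }
            )
    paths["hubs"] = outdir / "hubs.csv"
    pd.DataFrame(
        hub_rows,
        columns=["year", "module", "hub", "module_size", "connectivity", "intramodular_connectivity"],
    ).to_csv(paths["hubs"], index=False)
    return paths


def _plot_year(res, ydir: Path) -> None:
    """Module-ordered TOM heatmap and tau-fit diagnostics for one year."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(res.partition.labels.to_numpy())
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(res.tom.TOM[np.ix_(order, order)], cmap="viridis", interpolation="nearest")
    ax.set_title(f"TOM heatmap, year {res.year} (module-ordered)")
    fig.colorbar(im, ax=ax, label="TOM")
    fig.savefig(ydir / "tom_heatmap.png", dpi=100)
    plt.close(fig)

    if res.fit is not None:
        df = res.fit.to_frame()
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(df["tau"], df["r_squared"], "o-")
        ax.axvline(res.fit.chosen_tau, color="red", ls="--", label=f"chosen tau={res.fit.chosen_tau}")
        ax.set_xlabel("tau")
        ax.set_ylabel("scale-free fit R^2")
        ax.legend()
        fig.savefig(ydir / "scale_free_fit.png", dpi=100)
        plt.close(fig)
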