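"""Year-by-year pipeline execution and temporal comparison of modules.

Module structure is tracked across consecutive years with Jaccard indices
between membership sets (grey included); each later-year module is matched
to the earlier-year module maximising the Jaccard index, and a matched pair
with index above 0.5 is flagged as a stable correspondence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from comorbnet.network import (
    AdjacencyMatrix,
    ScaleFreeFit,
    SimilarityMatrix,
    build_adjacency,
    select_threshold,
    similarity_matrix,
)
from comorbnet.records import (
    DiagnosisRecord,
    YearlyOccurrence,
    build_yearly_occurrence,
    restrict_to_common,
)
from comorbnet.topology import (
    GREY,
    ModulePartition,
    TOMMatrix,
    connectivity_table,
    detect_modules,
    identify_hubs,
    tom,
)
from comorbnet.treecut import CutParams

logger = logging.getLogger(__name__)

STABLE_JACCARD = 0.5


def jaccard(set_a: set, set_b: set) -> float:
    """|A n B| / |A u B|; two empty sets give 0 (with a warning)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


@dataclass
class TemporalComparison:
    """Module correspondence between an earlier and a later partition."""

    year_pair: tuple[int, int]
    jaccard: pd.DataFrame  # rows: later modules (+grey), cols: earlier (+grey)
    matching: dict[str, tuple[str, float]]  # later -> (earlier argmax, index)
    sizes: pd.Series  # later-module sizes

    def stable(self) -> dict[str, str]:
        """Later -> earlier correspondences with Jaccard above 0.5."""
        return {l: e for l, (e, j) in self.matching.items() if j > STABLE_JACCARD}

    def to_frame(self) -> pd.DataFrame:
        out = self.jaccard.copy()
        out.insert(len(out.columns), "n_diseases", self.sizes.reindex(out.index))
        return out


def compare_partitions(p_early: ModulePartition, p_late: ModulePartition) -> TemporalComparison:
    """Full Jaccard matrix (grey included) plus greedy argmax matching.

    Partitions are restricted to their common disease universe first; each
    later module is assigned the earlier module with maximal Jaccard index
    (only pairs with a positive index are matched).
    """
    universe = set(p_early.labels.index) & set(p_late.labels.index)
    if not universe:
        raise ValueError("partitions share no diseases")
    early = p_early.labels[p_early.labels.index.isin(universe)]
    late = p_late.labels[p_late.labels.index.isin(universe)]
    e_year = getattr(p_early, "year", 0)
    l_year = getattr(p_late, "year", 1)
    e_mods = list(pd.Series(early).value_counts().index)
    l_mods = list(pd.Series(late).value_counts().index)
    J = pd.DataFrame(0.0, index=l_mods, columns=e_mods)
    for lm in l_mods:
        l_set = set(late.index[late == lm])
        for em in e_mods:
            e_set = set(early.index[early == em])
            J.loc[lm, em] = jaccard(l_set, e_set)
    matching: dict[str, tuple[str, float]] = {}
    for lm in l_mods:
        row = J.loc[lm]
        best = row.idxmax()
        if row[best] > 0:
            matching[lm] = (best, float(row[best]))
    sizes = late.value_counts().reindex(l_mods)
    return TemporalComparison((e_year, l_year), J, matching, sizes)


@dataclass
class YearResult:
    """All per-year artefacts of the pipeline."""

    year: int
    occurrence: YearlyOccurrence
    similarity: SimilarityMatrix
    fit: ScaleFreeFit | None
    adjacency: AdjacencyMatrix
    tom: TOMMatrix
    partition: ModulePartition
    table: pd.DataFrame  # per-disease connectivity table


@dataclass
class PipelineResult:
    years: list[int]
    common_diseases: list[str]
    tau: float | dict[int, float]
    per_year: dict[int, YearResult] = field(default_factory=dict)
    comparisons: list[TemporalComparison] = field(default_factory=list)

    def prevalence(self) -> pd.DataFrame:
        """Per-disease prevalence (P_i / N) by year."""
        cols = {}
        for y, res in self.per_year.items():
            occ = res.occurrence
            cols[y] = occ.P / occ.N
        return pd.DataFrame(cols)


def run_yearly_pipeline(
    records: list[DiagnosisRecord],
    years: list[int] | None = None,
    *,
    tau_policy: str = "reference",
    tau: float | None = None,
    reference_year: int | None = None,
    tau_grid=None,
    r2_target: float = 0.80,
    adjacency_mode: str = "magnitude",
    min_module_size: int = 20,
    cut_params: CutParams | None = None,
) -> PipelineResult:
    """Per-year network construction, module detection, and tracking.

    tau_policy: ``reference`` selects tau by the scale-free criterion on the
    reference year (default: first year) and applies it to all years, so
    edge semantics stay comparable across time; ``per-year`` re-selects
    annually; ``fixed`` uses the supplied ``tau``.  Years with no records
    are skipped with a warning.  Deterministic for fixed inputs.
    """
    if years is None:
        years = sorted({r.year for r in records})
    usable = [y for y in years if any(r.year == y for r in records)]
    for y in years:
        if y not in usable:
            logger.warning("run_yearly_pipeline: no records for year %d; skipped", y)
    if not usable:
        raise ValueError("no usable years")
    occs = [build_yearly_occurrence(records, y) for y in usable]
    common, occs = restrict_to_common(occs)
    sims = {occ.year: similarity_matrix(occ) for occ in occs}

    from comorbnet.network import DEFAULT_TAU_GRID

    grid = tuple(tau_grid) if tau_grid is not None else DEFAULT_TAU_GRID
    taus: dict[int, float] = {}
    fits: dict[int, ScaleFreeFit | None] = {y: None for y in usable}
    if tau_policy == "fixed":
        if tau is None:
            raise ValueError("tau_policy='fixed' requires tau")
        taus = {y: float(tau) for y in usable}
    elif tau_policy == "reference":
        ref = reference_year if reference_year is not None else usable[0]
        if ref not in sims:
            raise ValueError(f"reference year {ref} not among usable years {usable}")
        fit = select_threshold(sims[ref], grid=grid, r2_target=r2_target, mode=adjacency_mode)
        fits[ref] = fit
        taus = {y: fit.chosen_tau for y in usable}
    elif tau_policy == "per-year":
        for y in usable:
            fit = select_threshold(sims[y], grid=grid, r2_target=r2_target, mode=adjacency_mode)
            fits[y] = fit
            taus[y] = fit.chosen_tau
    else:
        raise ValueError(f"unknown tau_policy {tau_policy!r}")

    per_year: dict[int, YearResult] = {}
    for occ in occs:
        y = occ.year
        adj = build_adjacency(sims[y], taus[y], mode=adjacency_mode)
        T = tom(adj)
        S_signed = np.nan_to_num(sims[y].S, nan=0.0)
        partition = detect_modules(
            T, min_module_size=min_module_size, cut_params=cut_params, similarity=S_signed
        )
        identify_hubs(partition, occ, adj=adj)
        table = connectivity_table(adj, T, partition)
        per_year[y] = YearResult(y, occ, sims[y], fits[y], adj, T, partition, table)

    comparisons = []
    for y0, y1 in zip(usable, usable[1:]):
        cmp_ = compare_partitions(per_year[y0].partition, per_year[y1].partition)
        cmp_.year_pair = (y0, y1)
        comparisons.append(cmp_)

    tau_out: float | dict[int, float]
    tau_out = taus[usable[0]] if len(set(taus.values())) == 1 else taus
    return PipelineResult(usable, common, tau_out, per_year, comparisons)


@dataclass
class TrendSeries:
    """Per-year values of a scalar quantity with a nonparametric smooth."""

    name: str
    years: np.ndarray
    values: np.ndarray
    smooth: np.ndarray | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"year": self.years, self.name: self.values})
        if self.smooth is not None:
            df["smooth"] = self.smooth
        return df


def trend_series(values: pd.Series, *, name: str = "value", span: float = 0.5) -> TrendSeries:
    """Assemble a yearly series and add a loess-style smooth.

    ``values`` is indexed by year.  With fewer than two points the smooth is
    omitted.  The smooth is local linear regression (lowess) with the given
    span.
    """
    values = values.sort_index()
    years = values.index.to_numpy(dtype=float)
    vals = values.to_numpy(dtype=float)
    if len(vals) < 2:
        return TrendSeries(name, years, vals, None)
    from statsmodels.nonparametric.smoothers_lowess import lowess

    fitted = lowess(vals, years, frac=span, return_sorted=False)
    return TrendSeries(name, years, vals, fitted)


def connectivity_trends(result: PipelineResult, disease: str, *, span: float = 0.5) -> pd.DataFrame:
    """Prevalence, K and intramodular K of one disease across years."""
    rows = {}
    for y in result.years:
        res = result.per_year[y]
        occ = res.occurrence
        prev = occ.P.get(disease, np.nan) / occ.N
        rows[y] = {
            "prevalence": prev,
            "K": res.table["K"].get(disease, np.nan),
            "intramodular_K": res.table["intramodular_K"].get(disease, np.nan),
        }
    df = pd.DataFrame(rows).T.rename_axis("year")
    for col in df.columns:
        ts = trend_series(df[col].dropna(), name=col, span=span)
        if ts.smooth is not None:
            df[f"{col}_smooth"] = pd.Series(ts.smooth, index=ts.years.astype(int))
    return df


def module_flow(result: PipelineResult) -> pd.DataFrame:
    """(year, disease, module) long table for alluvial-style plotting."""
    rows = [
        (y, d, m)
        for y in result.years
        for d, m in result.per_year[y].partition.labels.items()
    ]
    return pd.DataFrame(rows, columns=["year", "disease", "module"])
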