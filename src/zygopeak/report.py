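"""Pipeline orchestration and report generation.

`run_pipeline` wires the full analysis together: peak table + sample sheet
-> presence calls -> reference-gene normalization (height and area) ->
pit/K-means zygosity calling -> segregation tests (3:1 and 1:2:1) per
population -> method concordance, trait correlations and population
summaries, written as a calls TSV and a deterministic JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import IO, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import peak_io
from .errors import IntegrityError
from .normalization import normalize_traits
from .segregation import (RATIO_1_2_1, RATIO_3_1, chisq_gof,
                          cluster_means_table, confirm_families,
                          confirmation_summary, summarize_populations,
                          with_average_row)
from .zygosity import CallConfig, ZygosityCallSet, call_presence, call_zygosity, concordance

__all__ = ["CorrelationMatrix", "trait_correlations", "run_pipeline"]


@dataclass
class CorrelationMatrix:
    """Pairwise product-moment correlations between marker/trait columns.

    ``r`` is symmetric with unit diagonal; entries with fewer than
    ``min_pairs`` pairwise-complete samples are NaN.  ``significant`` flags
    p < alpha from the standard correlation t-test.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


def trait_correlations(columns: pd.DataFrame, alpha: float = 0.05,
                       min_pairs: int = 3) -> CorrelationMatrix:
    """Correlate trait columns (samples x labeled marker/trait series)."""
    labels = list(columns.columns)
    k = len(labels)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = columns.iloc[:, [i, j]].dropna()
            if len(pair) < min_pairs:
                continue
            if pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                continue
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=labels, columns=labels)
    pdf = pd.DataFrame(p, index=labels, columns=labels)
    return CorrelationMatrix(r=rdf, p=pdf, significant=pdf < alpha, alpha=alpha)


def _jsonable(obj):
    """Recursively convert results (dataclasses, numpy, frames) to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _round1(x) -> float | None:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else round(float(x), 1)


def run_pipeline(
    peaks: str | IO[str],
    sheet: str | IO[str],
    config: CallConfig = CallConfig(),
    calls_out: str | None = None,
    report_out: str | None = None,
    panel: peak_io.MarkerPanel = peak_io.DEFAULT_PANEL,
) -> tuple[ZygosityCallSet, dict]:
    """Execute the full zygosity-genotyping analysis.

    Returns the call set and the report dict; optionally writes the calls
    TSV and the JSON report.  Reports are deterministic given inputs and
    config: populations are ordered alphabetically and trait means are
    formatted at one decimal.
    """
    table = peak_io.read_peak_table(peaks, panel)
    sheet_df = peak_io.read_sample_sheet(sheet)

    known = set(sheet_df["sample_id"])
    orphans = sorted(set(table.records["sample_id"]) - known)
    if orphans:
        raise IntegrityError(
            f"peak table sample(s) absent from sample sheet: {', '.join(orphans[:5])}")

    height = peak_io.build_trait_matrix(table, "height")
    area = peak_io.build_trait_matrix(table, "area")
    presence = call_presence(height, panel)
    grouping = sheet_df.set_index("sample_id")["population_id"]

    norm_h = normalize_traits(height, panel, grouping, trait="height")
    norm_a = normalize_traits(area, panel, grouping, trait="area")
    calls = call_zygosity({"height": norm_h, "area": norm_a}, presence, config)

    summary = summarize_populations(presence, calls, sheet_df)
    clusters = with_average_row(cluster_means_table(calls))

    segregation = {}
    for pop in sorted(summary.index.drop("Total")):
        row = summary.loc[pop]
        entry: dict = {}
        if row["n_transgenic"] > 0 and row["n_null"] > 0:
            entry["ratio_3_1"] = chisq_gof(
                [int(row["n_transgenic"]), int(row["n_null"])], RATIO_3_1,
                alpha=config.alpha)
        n_hom, n_hem = int(row["n_homozygous"]), int(row["n_hemizygous"])
        if min(n_hom, n_hem, int(row["n_null"])) > 0:
            entry["ratio_1_2_1"] = chisq_gof(
                [n_hom, n_hem, int(row["n_null"])], RATIO_1_2_1,
                alpha=config.alpha)
        segregation[str(pop)] = entry

    # correlation panel over normalized transgene trait values
    cols = {}
    for marker in panel.transgene_markers:
        cols[f"{marker} height"] = norm_h.values_for(marker)
        cols[f"{marker} area"] = norm_a.values_for(marker)
    corr = trait_correlations(pd.DataFrame(cols), alpha=config.alpha)

    conc = concordance(calls)

    families_report = None
    fam_sheet = sheet_df[sheet_df["generation"] == "BC1S2"]
    if len(fam_sheet):
        fams = confirm_families(calls, sheet_df, alpha=config.alpha)
        families_report = {
            "families": fams,
            "summary": confirmation_summary(fams),
        }

    cluster_json = clusters.copy()
    for col in ("homozygous_height", "homozygous_area",
                "hemizygous_height", "hemizygous_area"):
        cluster_json[col] = cluster_json[col].map(_round1)

    report = {
        "config": dataclasses.asdict(config),
        "n_samples": int(presence.size),
        "populations": _jsonable(summary),
        "cluster_means": _jsonable(cluster_json),
        "segregation": _jsonable(segregation),
        "concordance": _jsonable(conc),
        "correlations": {
            "r": _jsonable(corr.r.round(3)),
            "significant": _jsonable(corr.significant),
        },
        "population_flags": {
            pid: list(ps.flags) for pid, ps in sorted(calls.population_stats.items())
        },
    }
    if families_report is not None:
        report["confirmation"] = _jsonable(families_report)

    if calls_out is not None:
        peak_io.write_calls(calls, calls_out)
    if report_out is not None:
        with open(report_out, "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return calls, report
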