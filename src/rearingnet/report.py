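"""Full-pipeline orchestration and the study-table check.

:func:`run_full_analysis` sequences every analysis stage over a raw
dataset (or, at reduced depth, over a printed-table summary) and
returns a versioned, JSON-serialisable report in which every number is
traceable to one operation.  :func:`paper_check` recomputes the
summary statistics of the packaged study tables and compares each to
its published value.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib.metadata import version as _pkg_version

import numpy as np
import pandas as pd

from . import community, fixtures, network, niche
from .io import dataset_frames
from .records import PaperSummary, RearingDataset, summarize, validate_dataset

SCHEMA_VERSION = 1


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict("records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


@dataclass
class AnalysisReport:
    data: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(_jsonable(self.data), indent=indent)

    def __getitem__(self, key):
        return self.data[key]


def _input_hashes(ds: RearingDataset) -> dict[str, str]:
    return {name: hashlib.sha256(frame.to_csv(index=False).encode()).hexdigest()
            for name, frame in dataset_frames(ds).items()}


def _summary_blocks(summary: PaperSummary) -> dict:
    """Blocks computable from the printed-table level alone."""
    periods = summary.periods
    per_period: dict[str, dict] = {}
    for p in periods:
        oa = community.origin_relative_abundance(summary.fly_rows, p)
        ra = community.rank_abundance(summary.fly_rows[p].to_dict(), p)
        per_period[p] = {
            "richness": community.period_richness(summary.fly_rows, p),
            "total_abundance": int(summary.fly_rows[p].sum()),
            "origin_relative_abundance": {
                "exotic_pct": oa.exotic_pct, "neotropical_pct": oa.neotropical_pct,
                "exotic_raw": oa.exotic_raw, "neotropical_raw": oa.neotropical_raw},
            "rank_abundance": ra.table,
        }
    sr = network.success_rates(summary.plant_rows)
    pooled: dict = {
        "total_abundance": int(sum(summary.fly_rows[p].sum() for p in periods)),
        "n_plant_taxa": int(len(summary.plant_rows)),
        "n_plant_families": int(summary.plant_rows["family"].nunique()),
        "n_fly_species": int(len(summary.fly_rows)),
        "total_mass_g": float(summary.plant_rows["mass_total_g"].sum()),
        "success_rates": {
            "overall_pct": sr.overall.pct_1dp,
            "fleshy_fruit_pct": sr.fleshy_fruit.pct_1dp,
            "other_pooled_pct": sr.other_pooled.pct_1dp,
            "per_type": {k: {"emerged": v.emerged, "total": v.total,
                             "pct": v.pct} for k, v in sr.per_type.items()},
        },
    }
    if len(periods) == 2:
        t = community.period_turnover(summary.fly_rows, *periods)
        pooled["turnover"] = {"shared": t.shared, "only_first": t.only_a,
                              "only_second": t.only_b}
    return {"periods": per_period, "pooled": pooled}


def _occupancy_block(table: niche.OccupancyTable, gof_scale: str,
                     round_pct: int | None) -> dict:
    gof = niche.occupancy_gof(table, scale=gof_scale, round_to=round_pct)
    posthoc = niche.cell_binomial_tests(table)
    return {
        "cells": [{"fly_origin": r.fly_origin, "host_origin": r.host_origin,
                   "observed": r.k, "possible": r.n,
                   "pct": 100.0 * r.k / r.n, "binomial_p": r.p_value,
                   "direction": r.direction} for r in posthoc],
        "overall_pct": table.overall_pct,
        "chi2": gof.chi2, "df": gof.df, "p": gof.p_value,
        "scale": gof.scale, "rounding": gof.round_to,
    }


def run_full_analysis(ds: RearingDataset | None = None,
                      summary: PaperSummary | None = None, *,
                      seed: int = 0,
                      gof_scale: str = "count",
                      round_pct: int | None = None,
                      record_unit: str = "colonized_sample_units",
                      rarefaction_method: str = "analytic",
                      rarefaction_unit: str = "taxon",
                      n_perm: int = 1000) -> AnalysisReport:
    """Run every applicable stage and assemble the report.

    Given a raw dataset, all stages run; given only a summary, the
    stages that need raw records (rarefaction, densities, correlations,
    breadth) are skipped.  Deterministic for fixed inputs and seed.
    """
    if (ds is None) == (summary is None):
        raise ValueError("provide exactly one of ds or summary")

    options = {"gof_scale": gof_scale, "round_pct": round_pct,
               "record_unit": record_unit,
               "rarefaction_method": rarefaction_method,
               "rarefaction_unit": rarefaction_unit,
               "n_perm": n_perm if rarefaction_method == "permutation" else None}
    provenance = {"schema_version": SCHEMA_VERSION, "seed": seed,
                  "package_version": _pkg_version("rearingnet"),
                  "options": options}

    if ds is not None:
        vr = validate_dataset(ds)
        if not vr.ok:
            raise ValueError(f"dataset fails validation ({len(vr)} violations); "
                             "run validate first")
        report_summary = summarize(ds)
        provenance["input_hashes"] = _input_hashes(ds)
    else:
        report_summary = summary

    data = {"provenance": provenance}
    data.update(_summary_blocks(report_summary))

    if ds is not None:
        for p in report_summary.periods:
            inc = community.IncidenceData.from_dataset(ds, p, unit=rarefaction_unit)
            curve = community.rarefaction_curve(
                inc, method=rarefaction_method, n_perm=n_perm,
                seed=seed if rarefaction_method == "permutation" else None)
            block = data["periods"][p]
            block["rarefaction"] = curve.points
            block["density_flies_per_g"] = network.host_density(ds, p)
            try:
                block["mass_correlations"] = {
                    k: {"rho": v.rho, "p_value": v.p_value, "n": v.n,
                        "method": v.method}
                    for k, v in network.mass_correlations(ds, p).items()}
            except ValueError as exc:  # constant vectors on tiny assemblages
                block["mass_correlations"] = {"error": str(exc)}

        m = network.build_matrix(ds)
        deg = network.degree_stats(m, ds.taxa)
        breadth = {
            code: niche.classify_host_breadth(rec)
            for code, rec in niche.breadth_records(ds, record_unit=record_unit).items()}
        data["pooled"]["degree_stats"] = deg.per_fly
        data["pooled"]["host_breadth"] = {
            code: {"label": c.label, "top_family": c.top_family,
                   "top_fraction": c.top_fraction,
                   "max_other_fraction": c.max_other_fraction}
            for code, c in breadth.items()}
        occ = niche.occupancy_table(m, ds.taxa, ds.species)
        if (occ.cells["possible"] > 0).all() and occ.cells["observed"].sum() > 0:
            data["pooled"]["occupancy"] = _occupancy_block(occ, gof_scale, round_pct)
    else:
        occ = niche.OccupancyTable(report_summary.occupancy_cells.copy())
        data["pooled"]["occupancy"] = _occupancy_block(occ, gof_scale, round_pct)

    return AnalysisReport(data)


# ---------------------------------------------------------------------------
# Study-table check


@dataclass(frozen=True)
class CheckRow:
    name: str
    computed: float
    printed: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return abs(self.computed - self.printed) <= self.tolerance


@dataclass
class PaperCheck:
    rows: list[CheckRow]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rows)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.name, r.computed, r.printed, r.tolerance, r.passed) for r in self.rows],
            columns=["name", "computed", "printed", "tolerance", "passed"])


def paper_check(summary: PaperSummary | None = None) -> PaperCheck:
    """Recompute the study's published summary statistics from the tables.

    Each row compares one recomputed quantity with its printed value at
    the printed precision.  The occupancy chi-square row uses the
    percentage-scale statistic on 2-dp pre-rounded cell percentages,
    the form in which the study printed it.
    """
    s = summary if summary is not None else fixtures.load_paper_fixture()
    p1, p2 = s.periods
    rows: list[CheckRow] = []

    def add(name, computed, printed, tol=0.0):
        rows.append(CheckRow(name, float(computed), float(printed), float(tol)))

    add("total_emerged", s.fly_rows[p1].sum() + s.fly_rows[p2].sum(), 48894)
    add("n_plant_taxa", len(s.plant_rows), 50)
    add("n_plant_families", s.plant_rows["family"].nunique(), 28)
    add("n_fly_species", len(s.fly_rows), 16)
    add("total_mass_kg", s.plant_rows["mass_total_g"].sum() / 1000.0, 99.478, 0.01)

    add("richness_period1", community.period_richness(s.fly_rows, p1), 12)
    add("richness_period2", community.period_richness(s.fly_rows, p2), 13)
    t = community.period_turnover(s.fly_rows, p1, p2)
    add("species_shared", t.shared, 9)
    add("species_only_period1", t.only_a, 3)
    add("species_only_period2", t.only_b, 4)

    add("exotic_pct_period1",
        community.origin_relative_abundance(s.fly_rows, p1).exotic_pct, 98.7)
    add("exotic_pct_period2",
        community.origin_relative_abundance(s.fly_rows, p2).exotic_pct, 93.4)

    sr = network.success_rates(s.plant_rows)
    add("success_overall_pct", sr.overall.pct_1dp, 70.0)
    add("success_fleshy_fruit_pct", sr.fleshy_fruit.pct_1dp, 76.9)
    add("success_other_pooled_pct", sr.other_pooled.pct_1dp, 45.5)

    occ = fixtures.corrected_occupancy_table()
    add("occupancy_overall_pct", round(occ.overall_pct, 2), 18.11)
    pcts, overall = fixtures.printed_occupancy_percentages()
    gof = niche.percentage_gof(pcts, overall)
    add("occupancy_chi2_pct_scale", round(gof.chi2, 3), 7.311, 0.0005)
    add("occupancy_gof_p_above_0.05", float(gof.p_value > 0.05), 1.0)

    return PaperCheck(rows)
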