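"""Fly x host interaction matrices and the statistics built on them.

The interaction matrix pools emerged-individual counts over all sample
units of a scope (one period, or both pooled); its binary view (count
>= 1) defines a "breeding record" for host-range, occupancy and niche
statistics.  Host density divides a taxon's total emerged flies by its
*productive* mass only -- the summed grams of sample units that produced
at least one fly -- matching the empty-mass bookkeeping of rearing
surveys.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import FlySpecies, PlantTaxon, RearingDataset


@dataclass
class InteractionMatrix:
    """Counts of emerged individuals, flies as rows, host taxa as columns."""

    counts: pd.DataFrame
    period: str | None = None  # None means pooled over periods

    @property
    def binary(self) -> pd.DataFrame:
        return (self.counts >= 1).astype(int)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_matrix(ds: RearingDataset, period: str | None = None,
                 drop_empty: bool = False) -> InteractionMatrix:
    """Pool emergence counts into a fly x taxon matrix.

    All registry species/taxa are retained as (possibly all-zero) rows
    and columns unless ``drop_empty`` is set.
    """
    if period is not None and period not in ds.periods:
        raise ValueError(f"unknown period {period!r}")
    fly_codes = sorted(s.code for s in ds.species)
    taxon_codes = sorted(t.code for t in ds.taxa)
    fly_idx = {c: i for i, c in enumerate(fly_codes)}
    taxon_idx = {c: j for j, c in enumerate(taxon_codes)}
    sample_info = {s.sample_id: s for s in ds.samples}

    arr = np.zeros((len(fly_codes), len(taxon_codes)), dtype=int)
    for e in ds.emergences:
        s = sample_info[e.sample_id]
        if period is None or s.period == period:
            arr[fly_idx[e.fly_code], taxon_idx[s.taxon_code]] += e.count
    counts = pd.DataFrame(arr, index=fly_codes, columns=taxon_codes)

    if drop_empty:
        counts = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    return InteractionMatrix(counts, period)


@dataclass
class DegreeStats:
    """Host range per fly and fly richness per host, from binary cells."""

    per_fly: pd.DataFrame   # columns: n_hosts, n_families
    per_host: pd.Series     # n_flies per taxon code


def degree_stats(m: InteractionMatrix, taxa: Sequence[PlantTaxon]) -> DegreeStats:
    fam = {t.code: t.family for t in taxa}
    missing = [c for c in m.counts.columns if c not in fam]
    if missing:
        raise KeyError(f"taxa missing from registry: {missing}")
    b = m.binary
    n_hosts = b.sum(axis=1)
    n_families = pd.Series(
        {f: b.loc[f][b.loc[f] > 0].index.map(fam).nunique() for f in b.index},
        dtype=int)
    per_fly = pd.DataFrame({"n_hosts": n_hosts, "n_families": n_families})
    return DegreeStats(per_fly, b.sum(axis=0).rename("n_flies"))


def host_density(ds: RearingDataset, period: str | None = None,
                 productive_only: bool = True) -> pd.Series:
    """Emerged flies per gram for each host taxon (flies/g).

    By default the denominator is productive mass only (sample units
    with >= 1 emergence); taxa with no productive mass are omitted.
    ``productive_only=False`` divides by total mass instead, as a
    sensitivity variant.
    """
    if period is not None and period not in ds.periods:
        raise ValueError(f"unknown period {period!r}")
    samples = [s for s in ds.samples if period is None or s.period == period]
    ids = {s.sample_id for s in samples}
    flies_per_sample: dict[str, int] = {}
    for e in ds.emergences:
        if e.sample_id in ids:
            flies_per_sample[e.sample_id] = flies_per_sample.get(e.sample_id, 0) + e.count

    num: dict[str, int] = {}
    den: dict[str, float] = {}
    for s in samples:
        n = flies_per_sample.get(s.sample_id, 0)
        num[s.taxon_code] = num.get(s.taxon_code, 0) + n
        if n > 0 or not productive_only:
            den[s.taxon_code] = den.get(s.taxon_code, 0.0) + s.mass_g
    dens = {c: num[c] / den[c] for c in num if num[c] > 0 and den.get(c, 0.0) > 0}
    return pd.Series(dens, dtype=float).sort_index().rename("flies_per_g")


@dataclass(frozen=True)
class RateEntry:
    emerged: int
    total: int

    @property
    def pct(self) -> float:
        return 100.0 * self.emerged / self.total

    @property
    def pct_1dp(self) -> float:
        return round(self.pct, 1)


@dataclass
class SuccessRates:
    """Fraction of host taxa from which any fly emerged, by resource class."""

    overall: RateEntry
    fleshy_fruit: RateEntry
    other_pooled: RateEntry
    per_type: dict[str, RateEntry]


def success_rates(plant_rows: pd.DataFrame) -> SuccessRates:
    """Emergence success from a plant summary table.

    A taxon counts as successful when its empty-mass percentage is below
    100 (some sample unit produced at least one fly, in any period).
    """
    if plant_rows.empty:
        raise ValueError("empty plant registry")
    emerged = plant_rows["empty_mass_pct"] < 100.0
    ff = plant_rows["resource_type"] == "FF"

    def rate(mask: pd.Series) -> RateEntry:
        return RateEntry(int((emerged & mask).sum()), int(mask.sum()))

    per_type = {rt: rate(plant_rows["resource_type"] == rt)
                for rt in sorted(plant_rows["resource_type"].unique())}
    return SuccessRates(rate(pd.Series(True, index=plant_rows.index)),
                        rate(ff), rate(~ff), per_type)


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact-permutation" or "t-approximation"
    note: str = "ties handled by midranks"


def _midranks(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def spearman_mass_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of midranks.  For n <= 10 the p-value
    is from exhaustive enumeration of all n! rank permutations; for
    larger n the usual t-approximation t = rho sqrt((n-2)/(1-rho^2)) is
    used.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("undefined correlation: constant input vector")

    xr = _midranks(xa)
    yr = _midranks(ya)
    rho = float(np.corrcoef(xr, yr)[0, 1])

    if n <= 10:
        xs = (xr - xr.mean()) / xr.std()
        ys = (yr - yr.mean()) / yr.std()
        obs = abs(np.dot(xs, ys))
        hits = 0
        total = 0
        batch: list[tuple[int, ...]] = []
        for perm in itertools.permutations(range(n)):
            batch.append(perm)
            if len(batch) == 100_000:
                vals = np.abs(ys[np.array(batch)] @ xs)
                hits += int(np.sum(vals >= obs - 1e-9))
                total += len(batch)
                batch = []
        if batch:
            vals = np.abs(ys[np.array(batch)] @ xs)
            hits += int(np.sum(vals >= obs - 1e-9))
            total += len(batch)
        assert total == math.factorial(n)
        return CorrelationResult(rho, hits / total, n, "exact-permutation")

    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rho, min(1.0, p), n, "t-approximation")


def mass_correlations(ds: RearingDataset, period: str | None = None
                      ) -> dict[str, CorrelationResult]:
    """Per-taxon mass vs. fly abundance and vs. fly richness (Spearman).

    Only taxa sampled in the scope enter; taxa with zero emergence enter
    with abundance/richness 0, as they carry rank information.
    """
    m = build_matrix(ds, period)
    sampled = {s.taxon_code for s in ds.samples
               if period is None or s.period == period}
    mass: dict[str, float] = {}
    for s in ds.samples:
        if period is None or s.period == period:
            mass[s.taxon_code] = mass.get(s.taxon_code, 0.0) + s.mass_g
    codes = sorted(sampled)
    xs = [mass[c] for c in codes]
    ab = [int(m.counts[c].sum()) for c in codes]
    ri = [int(m.binary[c].sum()) for c in codes]
    return {"abundance": spearman_mass_correlation(xs, ab),
            "richness": spearman_mass_correlation(xs, ri)}


# ---------------------------------------------------------------------------
# Export / import

EDGE_COLUMNS = ["fly_code", "taxon_code", "count", "fly_origin", "host_origin"]


def export_network(m: InteractionMatrix, taxa: Sequence[PlantTaxon],
                   species: Sequence[FlySpecies], path: str | Path,
                   fmt: str = "edge_list_tsv") -> None:
    """Write the matrix as a sorted TSV edge list or a counts CSV.

    Edge rows cover binary-positive cells only, sorted by (fly code,
    taxon code) so the output is bit-reproducible.
    """
    path = Path(path)
    if fmt == "matrix_csv":
        m.counts.rename_axis("fly_code").to_csv(path)
        return
    if fmt != "edge_list_tsv":
        raise ValueError(f"unknown export format {fmt!r}")
    fly_origin = {s.code: s.origin.value for s in species}
    host_origin = {t.code: t.origin.value for t in taxa}
    rows = []
    for f in sorted(m.counts.index):
        for h in sorted(m.counts.columns):
            c = int(m.counts.loc[f, h])
            if c >= 1:
                rows.append((f, h, c, fly_origin[f], host_origin[h]))
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read back an exported edge list (column order preserved)."""
    return pd.read_csv(path, sep="\t", dtype={"fly_code": str, "taxon_code": str})
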