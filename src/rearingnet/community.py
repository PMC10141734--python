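"""Assemblage-level statistics.

Sample-based rarefaction here is the hypergeometric ("exact") form: with
T samples and species i occurring in T_i of them, the expected richness
in a random subset of t samples is

    E[S_t] = sum_i [ 1 - C(T - T_i, t) / C(T, t) ]

which is the mean over all C(T, t) equally likely subsets.  A
permutation variant averages the species-accumulation curve over random
orderings of the samples instead.  Binomial coefficients are evaluated
in log space so the analytic curve is stable for large T.

The default sampling unit for rarefaction is the plant taxon (each
taxon's pooled emergence list is one "sample"); individual sample units
are available as an alternative unit.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .records import RearingDataset


@dataclass(frozen=True)
class IncidenceData:
    """Per-sample presence sets for one assemblage.

    ``presence`` holds, for each sample, the set of species recorded in
    it (possibly empty).  ``counts`` maps each species to the number of
    samples containing it (T_i); ``n_samples`` is T.
    """

    presence: tuple[frozenset[str], ...]

    @property
    def n_samples(self) -> int:
        return len(self.presence)

    @property
    def counts(self) -> dict[str, int]:
        c: Counter[str] = Counter()
        for s in self.presence:
            c.update(s)
        return dict(c)

    @property
    def richness(self) -> int:
        return len(set().union(*self.presence)) if self.presence else 0

    @classmethod
    def from_presence_lists(cls, lists: Iterable[Iterable[str]]) -> "IncidenceData":
        return cls(tuple(frozenset(s) for s in lists))

    @classmethod
    def from_dataset(cls, ds: RearingDataset, period: str | None = None,
                     unit: str = "taxon") -> "IncidenceData":
        """Build incidence data at ``unit`` = "taxon" or "sample" level."""
        samples = [s for s in ds.samples if period is None or s.period == period]
        if period is not None and not samples:
            raise ValueError(f"unknown period {period!r}")
        by_sample: dict[str, set[str]] = {s.sample_id: set() for s in samples}
        for e in ds.emergences:
            if e.sample_id in by_sample:
                by_sample[e.sample_id].add(e.fly_code)
        if unit == "sample":
            return cls.from_presence_lists(by_sample.values())
        if unit == "taxon":
            by_taxon: dict[str, set[str]] = {}
            for s in samples:
                by_taxon.setdefault(s.taxon_code, set()).update(by_sample[s.sample_id])
            return cls.from_presence_lists(by_taxon.values())
        raise ValueError(f"unit must be 'taxon' or 'sample', got {unit!r}")


@dataclass
class RarefactionCurve:
    """Expected species richness as a function of accumulated samples."""

    points: pd.DataFrame  # columns: t, expected_richness, sd
    method: str
    n_perm: int | None = None
    seed: int | None = None


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_curve(inc: IncidenceData, method: str = "analytic",
                      n_perm: int = 1000, seed: int | None = None) -> RarefactionCurve:
    """Sample-based rarefaction curve for t = 1..T.

    method "analytic" is deterministic; "permutation" averages over
    ``n_perm`` random sample orderings and requires a seed.
    """
    T = inc.n_samples
    if T == 0:
        raise ValueError("no samples: cannot rarefy an empty survey")
    ts = np.arange(1, T + 1)

    if method == "analytic":
        Ti = np.array(sorted(inc.counts.values()), dtype=float)
        exp = np.empty(T, dtype=float)
        for j, t in enumerate(ts):
            # P(species i absent from a t-subset) = C(T - T_i, t) / C(T, t)
            absent = np.zeros_like(Ti)
            ok = T - Ti >= t
            absent[ok] = np.exp(_log_choose(T - Ti[ok], float(t))
                                - _log_choose(float(T), float(t)))
            exp[j] = np.sum(1.0 - absent)
        pts = pd.DataFrame({"t": ts, "expected_richness": exp, "sd": np.nan})
        return RarefactionCurve(pts, "analytic")

    if method == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if seed is None:
            raise ValueError("permutation rarefaction requires a seed")
        rng = np.random.default_rng(seed)
        acc = np.zeros((n_perm, T))
        presence = inc.presence
        for p in range(n_perm):
            order = rng.permutation(T)
            seen: set[str] = set()
            for j, idx in enumerate(order):
                seen |= presence[idx]
                acc[p, j] = len(seen)
        pts = pd.DataFrame({"t": ts, "expected_richness": acc.mean(axis=0),
                            "sd": acc.std(axis=0, ddof=1) if n_perm > 1 else np.nan})
        return RarefactionCurve(pts, "permutation", n_perm=n_perm, seed=seed)

    raise ValueError(f"unknown rarefaction method {method!r}")


@dataclass
class RankAbundance:
    """Whittaker-plot table: species ranked by decreasing abundance."""

    table: pd.DataFrame  # columns: rank, code, abundance, relative_abundance
    period: str | None = None


def rank_abundance(abundances: Mapping[str, int | float],
                   period: str | None = None) -> RankAbundance:
    """Rank species by abundance (ties broken by species code, stable)."""
    pos = {k: v for k, v in abundances.items() if v > 0}
    if not pos:
        raise ValueError("empty assemblage: no species with positive abundance")
    total = float(sum(pos.values()))
    ordered = sorted(pos.items(), key=lambda kv: (-kv[1], kv[0]))
    tab = pd.DataFrame({
        "rank": np.arange(1, len(ordered) + 1),
        "code": [k for k, _ in ordered],
        "abundance": [v for _, v in ordered],
    })
    tab["relative_abundance"] = tab["abundance"] / total
    return RankAbundance(tab, period)


def _period_column(fly_rows: pd.DataFrame, period: str) -> pd.Series:
    if period not in fly_rows.columns:
        raise ValueError(f"unknown period {period!r}")
    return fly_rows[period]


def period_richness(fly_rows: pd.DataFrame, period: str) -> int:
    """Number of fly species with positive abundance in one period."""
    return int((_period_column(fly_rows, period) > 0).sum())


@dataclass(frozen=True)
class Turnover:
    shared: int
    only_a: int
    only_b: int


def period_turnover(fly_rows: pd.DataFrame, period_a: str, period_b: str) -> Turnover:
    """Species shared between two periods and exclusive to each."""
    if period_a == period_b:
        raise ValueError("period_a and period_b must differ")
    a = _period_column(fly_rows, period_a) > 0
    b = _period_column(fly_rows, period_b) > 0
    return Turnover(int((a & b).sum()), int((a & ~b).sum()), int((~a & b).sum()))


@dataclass(frozen=True)
class OriginAbundance:
    """Relative abundance of exotic vs. neotropical species in a period.

    Raw values are exact percentages (they sum to 100); *_pct values are
    rounded to one decimal (round-half-even), the precision surveys
    usually print.
    """

    exotic_raw: float
    neotropical_raw: float

    @property
    def exotic_pct(self) -> float:
        return round(self.exotic_raw, 1)

    @property
    def neotropical_pct(self) -> float:
        return round(self.neotropical_raw, 1)


def origin_relative_abundance(fly_rows: pd.DataFrame, period: str) -> OriginAbundance:
    """Summed abundance of each origin class over the period total."""
    ab = _period_column(fly_rows, period)
    total = float(ab.sum())
    if total <= 0:
        raise ValueError(f"empty assemblage in period {period!r}")
    exotic_raw = 100.0 * float(ab[fly_rows["origin"] == "E"].sum()) / total
    # complement taken on the percentage so the pair sums to 100 exactly
    return OriginAbundance(exotic_raw, 100.0 - exotic_raw)
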