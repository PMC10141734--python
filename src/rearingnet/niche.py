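"""Niche breadth and origin-class matrix occupancy.

Two analyses live here.

**Host-breadth classification** follows the Magnacca two-condition rule
at the plant-family level: a fly species is a *specialist* when (i) at
least two-thirds of its breeding records fall in a single plant family
and (ii) no other family holds more than one quarter of its records;
otherwise it is a *generalist*.  The published worked example (a species
with 60 records qualifies when one family has >= 40 and no other family
exceeds 15) pins both thresholds to fractions of the *total* record
count, inclusive, and that is the default here; a strict mode reads
condition (ii) against the remaining (non-top) records instead.

**Matrix occupancy** partitions the possible fly x host pairs into four
blocks by geographic origin (neotropical/exotic flies x neotropical/
exotic hosts), counts the observed breeding pairs in each block, and
asks whether the four occupancy proportions are homogeneous: a
chi-square goodness-of-fit test against the overall occupancy (df = 3,
one proportion estimated), followed by an exact two-sided binomial test
per cell as a post hoc.  Two chi-square scales are provided: the
statistically standard count scale, and a percentage scale (cell
occupancy percentages treated as the observations) for compatibility
with how some surveys print the statistic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import InteractionMatrix
from .records import FlySpecies, Origin, PlantTaxon, RearingDataset

CELL_ORDER = (("N", "N"), ("N", "E"), ("E", "N"), ("E", "E"))

SPECIALIST_TOP_THRESHOLD = 2.0 / 3.0
SPECIALIST_OTHER_THRESHOLD = 1.0 / 4.0


# ---------------------------------------------------------------------------
# Host breadth


@dataclass(frozen=True)
class BreadthRecordSet:
    """Breeding records of one fly species, tallied by plant family."""

    species_code: str
    family_counts: Mapping[str, int]
    record_unit: str = "colonized_sample_units"  # or "emerged_individuals"

    @property
    def total(self) -> int:
        return int(sum(self.family_counts.values()))


@dataclass(frozen=True)
class BreadthClassification:
    label: str            # "specialist" | "generalist"
    top_family: str | None
    top_fraction: float
    max_other_fraction: float
    strict: bool = False
    top_threshold: float = SPECIALIST_TOP_THRESHOLD
    other_threshold: float = SPECIALIST_OTHER_THRESHOLD

    @property
    def is_specialist(self) -> bool:
        return self.label == "specialist"


def classify_host_breadth(r: BreadthRecordSet, strict: bool = False) -> BreadthClassification:
    """Apply the two-condition specialist rule to one record set.

    Comparisons are inclusive and exact on integer counts: top family
    count * 3 >= total * 2, and (default mode) every other family count
    * 4 <= total.  Strict mode instead requires every other family to
    hold < 25% of the records outside the top family.
    """
    total = r.total
    if total < 1:
        raise ValueError(f"{r.species_code}: no breeding records")
    counts = {f: int(c) for f, c in r.family_counts.items() if c > 0}
    top_family = min((f for f, c in counts.items() if c == max(counts.values())))
    top = counts[top_family]
    others = [c for f, c in counts.items() if f != top_family]
    max_other = max(others, default=0)

    cond_top = 3 * top >= 2 * total
    if strict:
        remaining = total - top
        cond_other = remaining == 0 or all(4 * c < remaining for c in others)
    else:
        cond_other = all(4 * c <= total for c in others)

    return BreadthClassification(
        label="specialist" if (cond_top and cond_other) else "generalist",
        top_family=top_family,
        top_fraction=top / total,
        max_other_fraction=max_other / total,
        strict=strict,
    )


def breadth_records(ds: RearingDataset, period: str | None = None,
                    record_unit: str = "colonized_sample_units"
                    ) -> dict[str, BreadthRecordSet]:
    """Tally breeding records per fly species and plant family.

    A "record" is by default one colonized sample unit (a fly species x
    sample-unit occurrence); ``record_unit="emerged_individuals"``
    weights by counts instead.  Species without records are omitted.
    """
    if record_unit not in ("colonized_sample_units", "emerged_individuals"):
        raise ValueError(f"unknown record_unit {record_unit!r}")
    fam = {t.code: t.family for t in ds.taxa}
    sample_info = {s.sample_id: s for s in ds.samples}
    tallies: dict[str, dict[str, int]] = {}
    for e in ds.emergences:
        s = sample_info[e.sample_id]
        if period is not None and s.period != period:
            continue
        w = 1 if record_unit == "colonized_sample_units" else e.count
        d = tallies.setdefault(e.fly_code, {})
        f = fam[s.taxon_code]
        d[f] = d.get(f, 0) + w
    return {code: BreadthRecordSet(code, counts, record_unit)
            for code, counts in sorted(tallies.items())}


# ---------------------------------------------------------------------------
# Occupancy


@dataclass
class OccupancyTable:
    """Observed vs. possible fly-host pairs in the four origin blocks."""

    cells: pd.DataFrame  # columns fly_origin, host_origin, observed, possible

    def __post_init__(self) -> None:
        c = self.cells
        if len(c) != 4 or (c["observed"] > c["possible"]).any():
            raise ValueError("occupancy table needs 4 cells with observed <= possible")

    @classmethod
    def from_counts(cls, observed: Sequence[int], possible: Sequence[int]
                    ) -> "OccupancyTable":
        """Build from counts given in NN, NE, EN, EE order."""
        return cls(pd.DataFrame({
            "fly_origin": [fo for fo, _ in CELL_ORDER],
            "host_origin": [ho for _, ho in CELL_ORDER],
            "observed": list(observed), "possible": list(possible)}))

    @property
    def occupancy_pct(self) -> pd.Series:
        return 100.0 * self.cells["observed"] / self.cells["possible"]

    @property
    def overall_proportion(self) -> float:
        return float(self.cells["observed"].sum() / self.cells["possible"].sum())

    @property
    def overall_pct(self) -> float:
        return 100.0 * self.overall_proportion


def occupancy_table(m: InteractionMatrix, taxa: Sequence[PlantTaxon],
                    species: Sequence[FlySpecies],
                    exclude_hybrid_hosts: bool = True) -> OccupancyTable:
    """Partition binary matrix cells by (fly origin, host origin).

    Possible counts come from the registries (block sizes), observed
    counts from binary-positive matrix cells.  Hosts of hybrid origin
    are excluded by default; with ``exclude_hybrid_hosts=False`` a
    hybrid host is an error, since it belongs to no block.
    """
    host_origin = {t.code: t.origin.value for t in taxa}
    hybrids = [t.code for t in taxa if t.origin is Origin.HYBRID]
    if hybrids and not exclude_hybrid_hosts:
        raise ValueError(f"hosts with hybrid origin and no exclusion rule: {hybrids}")
    fly_origin = {s.code: s.origin.value for s in species}

    hosts_in = {c for c in host_origin if host_origin[c] != "EN"}
    n_flies = {o: sum(1 for v in fly_origin.values() if v == o) for o in "NE"}
    n_hosts = {o: sum(1 for c in hosts_in if host_origin[c] == o) for o in "NE"}

    b = m.binary
    missing = [c for c in b.index if c not in fly_origin]
    missing += [c for c in b.columns if c not in host_origin]
    if missing:
        raise KeyError(f"matrix codes missing from registries: {missing}")
    arr = b.to_numpy()
    row_o = np.array([fly_origin[c] for c in b.index])
    col_o = np.array([host_origin[c] if c in hosts_in else "-" for c in b.columns])
    rows = []
    for fo, ho in CELL_ORDER:
        obs = int(arr[np.ix_(row_o == fo, col_o == ho)].sum())
        rows.append((fo, ho, obs, n_flies[fo] * n_hosts[ho]))
    return OccupancyTable(pd.DataFrame(
        rows, columns=["fly_origin", "host_origin", "observed", "possible"]))


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    p_value: float
    scale: str           # "count" | "percentage"
    round_to: int | None = None


def percentage_gof(pcts: Sequence[float], expected_pct: float) -> GofResult:
    """Chi-square on occupancy percentages supplied directly.

    This is the as-printed compatibility entry point: surveys sometimes print
    the statistic computed on their (rounded, occasionally truncated)
    percentage cells, so exact reproduction requires feeding the printed
    numbers in as-is rather than re-deriving them from counts.
    """
    if expected_pct <= 0:
        raise ValueError("degenerate null: expected percentage must be positive")
    arr = np.asarray(pcts, dtype=float)
    chi2 = float(np.sum((arr - expected_pct) ** 2 / expected_pct))
    df = len(arr) - 1
    return GofResult(chi2, df, float(sps.chi2.sf(chi2, df=df)), "percentage", None)


def occupancy_gof(t: OccupancyTable, scale: str = "count",
                  round_to: int | None = None) -> GofResult:
    """Chi-square goodness of fit of the four cells to the overall rate.

    scale "count" (default): the cells are four *independent* binomials
    (each possible pair is occupied or not), so the standard statistic
    is the homogeneity-of-proportions chi-square including the
    unoccupied column: chi2 = sum (O_c - E_c)^2 / (E_c (1 - p_bar))
    with E_c = M_c x p_bar -- identical to the 2x4 contingency-table
    chi-square.  Summing (O-E)^2/E over occupied cells alone would
    deflate the statistic by the factor (1 - p_bar), since the cells do
    not partition a fixed total the way multinomial categories do.

    scale "percentage": the cell occupancy percentages are the
    observations and the overall percentage the expectation, optionally
    pre-rounded to ``round_to`` decimals (the form some surveys print).

    df = 3 either way, one proportion having been estimated.
    """
    if (t.cells["possible"] <= 0).any():
        raise ValueError("every cell needs possible > 0")
    p_bar = t.overall_proportion
    if p_bar <= 0:
        raise ValueError("degenerate null: overall occupancy is zero")

    if scale == "count":
        if p_bar >= 1:
            raise ValueError("degenerate null: overall occupancy is one")
        O = t.cells["observed"].to_numpy(dtype=float)
        E = t.cells["possible"].to_numpy(dtype=float) * p_bar
        chi2 = float(np.sum((O - E) ** 2 / (E * (1.0 - p_bar))))
    elif scale == "percentage":
        pcts = t.occupancy_pct.to_numpy(dtype=float)
        overall = t.overall_pct
        if round_to is not None:
            pcts = np.round(pcts, round_to)
            overall = round(overall, round_to)
        chi2 = float(np.sum((pcts - overall) ** 2 / overall))
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return GofResult(chi2, 3, float(sps.chi2.sf(chi2, df=3)), scale, round_to)


@dataclass(frozen=True)
class CellBinomialResult:
    fly_origin: str
    host_origin: str
    k: int
    n: int
    p0: float
    p_value: float
    direction: str  # "above" | "below" | "at" expectation
    method: str


def exact_binomial_two_sided(k: int, n: int, p0: float,
                             method: str = "minlike") -> float:
    """Exact two-sided binomial p-value for k successes out of n.

    "minlike" sums P(X = j) over every outcome no more likely than the
    observed one; "central" doubles the smaller tail, capped at 1.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be strictly between 0 and 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    if method == "minlike":
        p = float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())
    elif method == "central":
        lower = float(pmf[: k + 1].sum())
        upper = float(pmf[k:].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown two-sided method {method!r}")
    return min(1.0, p)


def cell_binomial_tests(t: OccupancyTable, method: str = "minlike"
                        ) -> list[CellBinomialResult]:
    """Post hoc exact binomial test of each cell against the overall rate."""
    p0 = t.overall_proportion
    if not 0 < p0 < 1:
        raise ValueError("degenerate null: overall occupancy is 0 or 1")
    out = []
    for row in t.cells.itertuples(index=False):
        k, n = int(row.observed), int(row.possible)
        p = exact_binomial_two_sided(k, n, p0, method=method)
        delta = k - n * p0
        direction = "above" if delta > 0 else ("below" if delta < 0 else "at")
        out.append(CellBinomialResult(row.fly_origin, row.host_origin,
                                      k, n, p0, p, direction, method))
    return out
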