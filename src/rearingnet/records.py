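"""Core domain model for drosophilid rearing surveys.

A rearing survey collects discarded fruit and vegetable fragments
("sample units"), weighs each one, and monitors it in the laboratory for
the emergence of adult drosophilids.  The atomic observation is a
(sample unit, fly species, count) triple; every analysis in this package
is an aggregation of those triples keyed by two registries: the plant
taxa the samples came from and the fly species that emerged.

Both registries carry a geographic-origin class (neotropical vs. exotic
to the Neotropics; plants of deliberately mixed parentage are "hybrid"),
which is the grouping variable of the origin-association analysis, and
plants additionally carry a resource-type code (fleshy fruit, dry fruit,
tubers, bulbs, leaves) used for emergence success rates.
"""
from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import pandas as pd


class Origin(str, enum.Enum):
    """Geographic origin class relative to the Neotropical region."""

    NEOTROPICAL = "N"
    EXOTIC = "E"
    HYBRID = "EN"  # mixed-parentage plants only (e.g. table grape)


class ResourceType(str, enum.Enum):
    DRY_FRUIT = "DF"
    FLESHY_FRUIT = "FF"
    STEM_BULB = "SB"     # stem bulb with cataphylls (onion)
    STEM_TUBER = "ST"
    ROOT_TUBER = "RT"
    LEAF = "VL"          # vegetative leaves


@dataclass(frozen=True)
class PlantTaxon:
    """One registry entry for a host plant (species or named variety)."""

    code: str
    scientific_name: str
    family: str
    origin: Origin
    resource_type: ResourceType
    popular_name: str | None = None


@dataclass(frozen=True)
class FlySpecies:
    """One registry entry for a drosophilid species.

    Fly origin is strictly binary (neotropical or exotic); there are no
    hybrid-origin flies.
    """

    code: str
    name: str
    origin: Origin
    genus: str | None = None
    subgenus: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.origin is Origin.HYBRID:
            raise ValueError(f"fly {self.code!r}: origin must be N or E, not hybrid")


@dataclass(frozen=True)
class SampleUnit:
    """One individually bagged, weighed resource fragment."""

    sample_id: str
    period: str
    taxon_code: str
    mass_g: float


@dataclass(frozen=True)
class EmergenceRecord:
    """Count of one fly species emerging from one sample unit.

    Zero counts are implicit: a stored record always has count >= 1.
    """

    sample_id: str
    fly_code: str
    count: int


@dataclass
class RearingDataset:
    """A full survey: registries plus the raw sample/emergence tables."""

    taxa: list[PlantTaxon]
    species: list[FlySpecies]
    samples: list[SampleUnit]
    emergences: list[EmergenceRecord]

    def taxa_by_code(self) -> dict[str, PlantTaxon]:
        return {t.code: t for t in self.taxa}

    def species_by_code(self) -> dict[str, FlySpecies]:
        return {s.code: s for s in self.species}

    @property
    def periods(self) -> tuple[str, ...]:
        return tuple(sorted({s.period for s in self.samples}))

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.period, s.taxon_code, s.mass_g) for s in self.samples],
            columns=["sample_id", "period", "taxon_code", "mass_g"],
        )

    def emergences_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.sample_id, e.fly_code, e.count) for e in self.emergences],
            columns=["sample_id", "fly_code", "count"],
        )


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Violation:
    entity: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def validate_dataset(ds: RearingDataset) -> ValidationReport:
    """Check referential integrity and value constraints.

    Violations are returned as data, never raised: a report is empty
    exactly when every invariant holds.
    """
    v: list[Violation] = []

    for kind, codes in (("taxon", [t.code for t in ds.taxa]),
                        ("fly", [s.code for s in ds.species]),
                        ("sample", [s.sample_id for s in ds.samples])):
        seen: set[str] = set()
        for c in codes:
            if c in seen:
                v.append(Violation(f"{kind}:{c}", "duplicate code",
                                   f"{kind} code {c!r} appears more than once"))
            seen.add(c)

    taxon_codes = {t.code for t in ds.taxa}
    sample_ids = {s.sample_id for s in ds.samples}
    fly_codes = {s.code for s in ds.species}

    for s in ds.samples:
        if s.mass_g < 0:
            v.append(Violation(f"sample:{s.sample_id}", "negative mass",
                               f"mass_g = {s.mass_g}"))
        if s.taxon_code not in taxon_codes:
            v.append(Violation(f"sample:{s.sample_id}", "dangling reference",
                               f"unknown taxon_code {s.taxon_code!r}"))

    for e in ds.emergences:
        if e.sample_id not in sample_ids:
            v.append(Violation(f"emergence:{e.sample_id}/{e.fly_code}",
                               "dangling reference",
                               f"unknown sample_id {e.sample_id!r}"))
        if e.fly_code not in fly_codes:
            v.append(Violation(f"emergence:{e.sample_id}/{e.fly_code}",
                               "dangling reference",
                               f"unknown fly_code {e.fly_code!r}"))
        if e.count < 1:
            v.append(Violation(f"emergence:{e.sample_id}/{e.fly_code}",
                               "non-positive count", f"count = {e.count}"))

    if not ds.samples:
        v.append(Violation("dataset", "no samples",
                           "a dataset must contain at least one sample unit"))
    return ValidationReport(v)


# ---------------------------------------------------------------------------
# Table-level summary (the granularity at which surveys are published)


@dataclass
class PaperSummary:
    """Printed-table level view of a survey.

    plant_rows   -- per taxon: family, origin, resource type, total mass,
                    percentage of that mass in sample units that produced
                    no flies ("empty mass"), periods present and periods
                    with emergence.  Indexed by taxon code.
    fly_rows     -- per species: origin, pooled host range (distinct host
                    taxa / families with a breeding record) and one
                    abundance column per period.  Indexed by fly code.
    occupancy_cells -- observed and possible fly-host association counts
                    in the four (fly origin x host origin) classes.
    """

    plant_rows: pd.DataFrame
    fly_rows: pd.DataFrame
    occupancy_cells: pd.DataFrame
    periods: tuple[str, ...]


def summarize(ds: RearingDataset) -> PaperSummary:
    """Aggregate raw records up to the printed-table level.

    Empty-mass percentage is (mass of a taxon's sample units with zero
    emerged flies) / (total mass of its sample units) x 100, pooled over
    periods.  Occupancy cells count distinct fly-taxon pairs with at
    least one emerged individual, restricted to unambiguous N/E origins
    (hybrid-origin hosts are excluded from both observed and possible).
    """
    if not ds.samples:
        raise ValueError("no samples: cannot summarize an empty dataset")

    taxa = ds.taxa_by_code()
    flies = ds.species_by_code()
    periods = ds.periods

    sf = ds.samples_frame()
    ef = ds.emergences_frame()
    per_sample = ef.groupby("sample_id")["count"].sum() if len(ef) else pd.Series(dtype=int)
    sf["emerged"] = sf["sample_id"].map(per_sample).fillna(0).astype(int)
    sf["family"] = sf["taxon_code"].map(lambda c: taxa[c].family)

    plant_rows = []
    for code, g in sf.groupby("taxon_code", sort=True):
        t = taxa[code]
        total = g["mass_g"].sum()
        empty_mask = g["emerged"] == 0
        empty = g.loc[empty_mask, "mass_g"].sum()
        # pin the endpoints: summation order must not leave an all-empty
        # taxon epsilon-below 100 (the emergence flag is pct < 100)
        if empty_mask.all():
            pct = 100.0
        elif not empty_mask.any():
            pct = 0.0
        else:
            pct = 100.0 * empty / total if total > 0 else 100.0
        pres = tuple(sorted(g["period"].unique()))
        emerged_periods = tuple(sorted(g.loc[g["emerged"] > 0, "period"].unique()))
        plant_rows.append((code, t.scientific_name, t.family, t.origin.value,
                           t.resource_type.value, total, pct, pres, emerged_periods))
    plant_df = pd.DataFrame(plant_rows, columns=[
        "code", "scientific_name", "family", "origin", "resource_type",
        "mass_total_g", "empty_mass_pct", "periods", "emerged_periods",
    ]).set_index("code")
    # registry taxa never sampled still belong in the table: mass 0 and,
    # having produced nothing, an empty-mass percentage of 100
    for code, t in taxa.items():
        if code not in plant_df.index:
            plant_df.loc[code] = (t.scientific_name, t.family, t.origin.value,
                                  t.resource_type.value, 0.0, 100.0, (), ())

    if len(ef):
        merged = ef.merge(sf[["sample_id", "period", "taxon_code", "family"]],
                          on="sample_id", how="left")
    else:
        merged = pd.DataFrame(columns=["sample_id", "fly_code", "count",
                                       "period", "taxon_code", "family"])

    fly_rows = []
    for code in sorted(flies):
        s = flies[code]
        g = merged[merged["fly_code"] == code]
        abund = {p: int(g.loc[g["period"] == p, "count"].sum()) for p in periods}
        hosts = g["taxon_code"].nunique()
        fams = g["family"].nunique()
        fly_rows.append((code, s.name, s.origin.value, fams, hosts,
                         *[abund[p] for p in periods]))
    fly_df = pd.DataFrame(fly_rows, columns=[
        "code", "name", "origin", "n_families", "n_hosts", *periods,
    ]).set_index("code")

    # origin-class occupancy, by direct pair scan
    pairs = set(zip(merged["fly_code"], merged["taxon_code"]))
    n_flies = {o: sum(1 for s in flies.values() if s.origin.value == o)
               for o in ("N", "E")}
    n_hosts = {o: sum(1 for t in taxa.values() if t.origin.value == o)
               for o in ("N", "E")}
    cells = []
    for fo, ho in itertools.product(("N", "E"), repeat=2):
        obs = sum(1 for (f, h) in pairs
                  if flies[f].origin.value == fo and taxa[h].origin.value == ho)
        cells.append((fo, ho, obs, n_flies[fo] * n_hosts[ho]))
    cell_df = pd.DataFrame(cells, columns=["fly_origin", "host_origin",
                                           "observed", "possible"])

    return PaperSummary(plant_df, fly_df, cell_df, periods)
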