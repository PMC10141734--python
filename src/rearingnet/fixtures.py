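"""Packaged transcription of the study's printed summary tables.

The survey this package was built around published its data as three
summary tables: per-taxon collection totals (50 host taxa in 28
botanical families, with total and "empty" mass), per-species fly
abundances and pooled host ranges for two collection periods a decade
apart, and a four-cell origin-association (occupancy) table.  Those
tables are shipped verbatim as CSVs and loaded here into a
:class:`~rearingnet.records.PaperSummary`.

The printed occupancy table is internally inconsistent: its exotic-host
column header says 29 taxa, yet its exotic/exotic cell prints 280
possible pairs (= 10 x 28) and its neotropical-fly/exotic-host
percentage 8.93% equals 15/168 (= 15 / (6 x 28)), not 15/174.  Keeping
the named grape hybrid out of the origin classes gives 21 neotropical +
28 exotic hosts and reproduces every printed percentage including the
18.11% overall.  The fixture stores the printed cells untouched;
:func:`corrected_occupancy_table` applies the 28-host reading.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import FixtureIntegrityError
from .niche import OccupancyTable
from .records import PaperSummary

PERIOD_1 = "2007-2008"
PERIOD_2 = "2018-2019"
PERIODS = (PERIOD_1, PERIOD_2)

# row-count / column-sum integrity constants for the packaged tables
_N_PLANTS = 50
_N_FAMILIES = 28
_N_FLIES = 16
_TOTAL_ABUNDANCE = 48894
_TOTAL_MASS_G = (99478.8, 1.0)  # value, absolute tolerance
_OCC_OBSERVED = (19, 15, 40, 68)
_OCC_POSSIBLE_PRINTED = (126, 174, 210, 280)
_OCC_POSSIBLE_CORRECTED = (126, 168, 210, 280)


def _fixture_dir() -> Path:
    return Path(str(resources.files("rearingnet").joinpath("fixtures")))


def load_paper_fixture(directory: str | Path | None = None) -> PaperSummary:
    """Load the packaged study tables as a :class:`PaperSummary`.

    ``directory`` overrides the packaged location (used for integrity
    testing).  Raises :class:`FixtureIntegrityError` when row counts or
    column sums disagree with the published totals.
    """
    d = Path(directory) if directory is not None else _fixture_dir()
    plants = pd.read_csv(d / "paper_table1.csv", dtype={"code": str})
    flies = pd.read_csv(d / "paper_table2.csv", dtype={"code": str},
                        keep_default_na=False)
    cells = pd.read_csv(d / "paper_table3.csv", keep_default_na=False)

    if len(plants) != _N_PLANTS:
        raise FixtureIntegrityError(
            f"plant table: expected {_N_PLANTS} rows, found {len(plants)}")
    if plants["family"].nunique() != _N_FAMILIES:
        raise FixtureIntegrityError(
            f"plant table: expected {_N_FAMILIES} families, "
            f"found {plants['family'].nunique()}")
    mass_total = float(plants["mass_g"].sum())
    if abs(mass_total - _TOTAL_MASS_G[0]) > _TOTAL_MASS_G[1]:
        raise FixtureIntegrityError(
            f"plant table: mass column sums to {mass_total} g, "
            f"expected {_TOTAL_MASS_G[0]} g")
    if len(flies) != _N_FLIES:
        raise FixtureIntegrityError(
            f"fly table: expected {_N_FLIES} rows, found {len(flies)}")
    total_ab = int(flies["abundance_period1"].sum() + flies["abundance_period2"].sum())
    if total_ab != _TOTAL_ABUNDANCE:
        raise FixtureIntegrityError(
            f"fly table: abundance columns sum to {total_ab}, "
            f"expected {_TOTAL_ABUNDANCE}")
    if len(cells) != 4 or tuple(cells["observed"]) != _OCC_OBSERVED \
            or tuple(cells["possible"]) != _OCC_POSSIBLE_PRINTED:
        raise FixtureIntegrityError("occupancy table differs from the printed cells")

    status = {p: plants[f"period{i}"] for i, p in enumerate(PERIODS, start=1)}
    plant_rows = pd.DataFrame({
        "scientific_name": plants["scientific_name"],
        "family": plants["family"],
        "origin": plants["origin"],
        "resource_type": plants["resource_type"],
        "mass_total_g": plants["mass_g"].astype(float),
        "empty_mass_pct": plants["empty_mass_pct"].astype(float),
        "periods": [tuple(p for p in PERIODS if status[p][i] != "absent")
                    for i in plants.index],
        "emerged_periods": [tuple(p for p in PERIODS if status[p][i] == "emerged")
                            for i in plants.index],
    })
    plant_rows.index = plants["code"]

    fly_rows = pd.DataFrame({
        "name": flies["name"],
        "origin": flies["origin"],
        "n_families": flies["n_families"].astype(int),
        "n_hosts": flies["n_hosts"].astype(int),
        PERIOD_1: flies["abundance_period1"].astype(int),
        PERIOD_2: flies["abundance_period2"].astype(int),
    })
    fly_rows.index = flies["code"]

    occupancy = cells[["fly_origin", "host_origin", "observed", "possible"]].copy()
    return PaperSummary(plant_rows, fly_rows, occupancy, PERIODS)


def printed_occupancy_table() -> OccupancyTable:
    """The four origin cells exactly as printed (15/174 included)."""
    return OccupancyTable.from_counts(_OCC_OBSERVED, _OCC_POSSIBLE_PRINTED)


def corrected_occupancy_table() -> OccupancyTable:
    """The origin cells under the consistent 28-exotic-host reading.

    Observed counts are the printed ones; possible counts use 21
    neotropical and 28 exotic hosts (hybrid grape excluded) x 6
    neotropical and 10 exotic fly species, i.e. 784 possible pairs and
    an overall occupancy of 142/784 = 18.11%.
    """
    return OccupancyTable.from_counts(_OCC_OBSERVED, _OCC_POSSIBLE_CORRECTED)


def printed_occupancy_percentages() -> tuple[tuple[float, ...], float]:
    """Cell percentages and overall percentage as printed (2 dp)."""
    return (15.08, 8.93, 19.05, 24.28), 18.11
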