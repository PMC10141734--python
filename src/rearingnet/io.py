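"""CSV input/output for rearing datasets.

All tables are UTF-8, comma-separated, decimal-point, with a required
header row; masses are always grams.  The four-table schema is:

    plants.csv     code,scientific_name,family,origin,resource_type,popular_name
    flies.csv      code,name,genus,subgenus,group,origin
    samples.csv    sample_id,period,taxon_code,mass_g
    emergences.csv sample_id,fly_code,count

Origin tokens are N (neotropical), E (exotic) and, for plants only, EN
(hybrid).  Emergence rows with a non-positive count are rejected at read
time: zero counts are implicit, so stored records always mean "at least
one fly emerged".
"""
from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .errors import ParseError, SchemaError
from .records import (EmergenceRecord, FlySpecies, Origin, PlantTaxon,
                      RearingDataset, ResourceType, SampleUnit)

PLANT_COLUMNS = ["code", "scientific_name", "family", "origin", "resource_type"]
FLY_COLUMNS = ["code", "name", "origin"]
SAMPLE_COLUMNS = ["sample_id", "period", "taxon_code", "mass_g"]
EMERGENCE_COLUMNS = ["sample_id", "fly_code", "count"]

_RESOURCE_TOKENS = {rt.value for rt in ResourceType}


def _read_table(path: str | os.PathLike, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return df


def _origin(token: str, *, row: int, path, allow_hybrid: bool) -> Origin:
    try:
        o = Origin(token)
    except ValueError:
        raise ParseError(f"{path}: row {row}: unknown origin token {token!r}") from None
    if o is Origin.HYBRID and not allow_hybrid:
        raise ParseError(f"{path}: row {row}: fly origin must be N or E, got {token!r}")
    return o


def read_registry(path: str | os.PathLike, kind: str) -> list[PlantTaxon] | list[FlySpecies]:
    """Read a plant or fly registry CSV (``kind`` is "plants" or "flies").

    Row numbers in error messages are 1-based data rows (the header is
    row 0).
    """
    if kind == "plants":
        df = _read_table(path, PLANT_COLUMNS)
        out_p: list[PlantTaxon] = []
        for i, rec in enumerate(df.to_dict("records"), start=1):
            try:
                rt = ResourceType(rec["resource_type"])
            except ValueError:
                raise ParseError(
                    f"{path}: row {i}: unknown resource_type token "
                    f"{rec['resource_type']!r} (expected one of {sorted(_RESOURCE_TOKENS)})"
                ) from None
            out_p.append(PlantTaxon(
                code=rec["code"], scientific_name=rec["scientific_name"],
                family=rec["family"],
                origin=_origin(rec["origin"], row=i, path=path, allow_hybrid=True),
                resource_type=rt, popular_name=rec.get("popular_name") or None))
        return out_p
    if kind == "flies":
        df = _read_table(path, FLY_COLUMNS)
        out_f: list[FlySpecies] = []
        for i, rec in enumerate(df.to_dict("records"), start=1):
            out_f.append(FlySpecies(
                code=rec["code"], name=rec["name"],
                origin=_origin(rec["origin"], row=i, path=path, allow_hybrid=False),
                genus=rec.get("genus") or None, subgenus=rec.get("subgenus") or None,
                group=rec.get("group") or None))
        return out_f
    raise ValueError(f"kind must be 'plants' or 'flies', got {kind!r}")


def read_samples(path: str | os.PathLike) -> list[SampleUnit]:
    df = _read_table(path, SAMPLE_COLUMNS)
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            mass = float(rec["mass_g"])
        except ValueError:
            raise ParseError(f"{path}: row {i}: unparseable mass_g {rec['mass_g']!r}") from None
        out.append(SampleUnit(sample_id=rec["sample_id"], period=rec["period"],
                              taxon_code=rec["taxon_code"], mass_g=mass))
    return out


def read_emergences(path: str | os.PathLike) -> list[EmergenceRecord]:
    df = _read_table(path, EMERGENCE_COLUMNS)
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            count = int(rec["count"])
        except ValueError:
            raise ParseError(f"{path}: row {i}: unparseable count {rec['count']!r}") from None
        if count < 1:
            raise ParseError(
                f"{path}: row {i}: count must be >= 1 (zero counts are implicit)")
        out.append(EmergenceRecord(sample_id=rec["sample_id"],
                                   fly_code=rec["fly_code"], count=count))
    return out


def load_dataset(directory: str | os.PathLike) -> RearingDataset:
    """Load the four-table schema from a directory."""
    d = Path(directory)
    return RearingDataset(
        taxa=read_registry(d / "plants.csv", "plants"),
        species=read_registry(d / "flies.csv", "flies"),
        samples=read_samples(d / "samples.csv"),
        emergences=read_emergences(d / "emergences.csv"),
    )


def dataset_frames(ds: RearingDataset) -> dict[str, pd.DataFrame]:
    """The four tables as DataFrames in canonical column order."""
    plants = pd.DataFrame(
        [(t.code, t.scientific_name, t.family, t.origin.value,
          t.resource_type.value, t.popular_name or "") for t in ds.taxa],
        columns=PLANT_COLUMNS + ["popular_name"])
    flies = pd.DataFrame(
        [(s.code, s.name, s.genus or "", s.subgenus or "", s.group or "",
          s.origin.value) for s in ds.species],
        columns=["code", "name", "genus", "subgenus", "group", "origin"])
    samples = pd.DataFrame(
        [(s.sample_id, s.period, s.taxon_code, repr(s.mass_g)) for s in ds.samples],
        columns=SAMPLE_COLUMNS)
    emergences = pd.DataFrame(
        [(e.sample_id, e.fly_code, e.count) for e in ds.emergences],
        columns=EMERGENCE_COLUMNS)
    return {"plants": plants, "flies": flies, "samples": samples,
            "emergences": emergences}


def write_dataset(ds: RearingDataset, directory: str | os.PathLike) -> None:
    """Write the four-table schema to a directory (created if absent)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, frame in dataset_frames(ds).items():
        frame.to_csv(d / f"{name}.csv", index=False)
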