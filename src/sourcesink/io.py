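"""Reading and writing synthetic study datasets (CSV + YAML schedule).

Layout of a dataset directory::

    captures.csv   id, band_year, age_at_banding, <one column per year>
    breeders.csv   individual_id, population, year, age_class, attempts_observed
    nests.csv      nest_id, population, year, attempt_no, individual_id,
                   interval_days, interval_fate, fledged
    schedule.yaml  populations, invasion_year, study_years, available_from

Capture cells hold a population code or "0" for not seen.  A compact
single-string encoding of histories (e.g. ``A00B0C``) is also accepted on
read when a ``history`` column is present and all population codes are one
character.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .schedule import InvasionSchedule
from .simulate import Dataset, NOT_SEEN

__all__ = ["write_dataset", "read_dataset"]


class DatasetError(ValueError):
    """Schema violation in an on-disk dataset; messages name the row."""


def write_dataset(dataset: Dataset, directory: str | Path, force: bool = False) -> Path:
    """Write the three tables and the schedule; returns the directory.

    Refuses to overwrite an existing dataset unless ``force`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    target = directory / "captures.csv"
    if target.exists() and not force:
        raise FileExistsError(f"{target} exists; pass force=True to overwrite")
    dataset.captures.to_csv(directory / "captures.csv", index=False)
    dataset.breeders.to_csv(directory / "breeders.csv", index=False)
    nests = dataset.nests.copy()
    if "fledged" in nests.columns:
        nests["fledged"] = nests["fledged"].astype("Int64")
    nests.to_csv(directory / "nests.csv", index=False)
    meta = dataset.schedule.to_dict()
    if dataset.seed is not None:
        meta["seed"] = int(dataset.seed)
    with open(directory / "schedule.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return directory


def _expand_compact(captures: pd.DataFrame, schedule: InvasionSchedule) -> pd.DataFrame:
    years = [str(y) for y in schedule.years]
    codes = set(schedule.populations)
    if any(len(c) != 1 for c in codes):
        raise DatasetError("compact histories need single-character population codes")
    rows = []
    for i, row in captures.iterrows():
        h = str(row["history"])
        if len(h) != len(years):
            raise DatasetError(
                f"row {i}: history length {len(h)} != {len(years)} study years")
        for ch in h:
            if ch != NOT_SEEN and ch not in codes:
                raise DatasetError(f"row {i}: unknown state code {ch!r}")
        rows.append([row["id"], row["band_year"], row["age_at_banding"], *h])
    return pd.DataFrame(rows, columns=["id", "band_year", "age_at_banding", *years])


def read_dataset(directory: str | Path) -> Dataset:
    """Read a dataset directory; validates codes and schemas row-by-row."""
    directory = Path(directory)
    with open(directory / "schedule.yaml") as fh:
        meta = yaml.safe_load(fh)
    seed = meta.pop("seed", None)
    schedule = InvasionSchedule.from_dict(meta)
    years = [str(y) for y in schedule.years]
    codes = set(schedule.populations) | {NOT_SEEN}

    captures = pd.read_csv(directory / "captures.csv", dtype=str)
    if "history" in captures.columns:
        captures = _expand_compact(captures, schedule)
    missing = [c for c in ("id", "band_year", "age_at_banding", *years)
               if c not in captures.columns]
    if missing:
        raise DatasetError(f"captures.csv missing columns {missing}")
    captures = captures.astype(
        {"id": int, "band_year": int, "age_at_banding": int})
    for col in years:
        captures[col] = captures[col].astype(str)
        bad = ~captures[col].isin(codes)
        if bad.any():
            i = int(bad.idxmax())
            raise DatasetError(
                f"captures.csv row {i}: unknown state code "
                f"{captures.loc[i, col]!r} in year {col}")
    for i, row in captures.iterrows():
        b = str(row["band_year"])
        if b in years and row[b] == NOT_SEEN:
            raise DatasetError(f"captures.csv row {i}: not seen at banding occasion")

    breeders = pd.read_csv(directory / "breeders.csv")
    need = ["individual_id", "population", "year", "age_class", "attempts_observed"]
    if list(breeders.columns) != need and not set(need) <= set(breeders.columns):
        raise DatasetError(f"breeders.csv needs columns {need}")
    if len(breeders):
        bad = ~breeders["population"].isin(schedule.populations)
        if bad.any():
            i = int(bad.idxmax())
            raise DatasetError(
                f"breeders.csv row {i}: unknown population "
                f"{breeders.loc[i, 'population']!r}")
        if not breeders["age_class"].isin([1, 2]).all():
            i = int((~breeders["age_class"].isin([1, 2])).idxmax())
            raise DatasetError(f"breeders.csv row {i}: age_class must be 1 or 2")

    nests = pd.read_csv(directory / "nests.csv")
    if "fledged" in nests.columns:
        nests["fledged"] = nests["fledged"].astype("Int64")
    if len(nests):
        if (nests["interval_days"] < 1).any():
            i = int((nests["interval_days"] < 1).idxmax())
            raise DatasetError(f"nests.csv row {i}: interval_days must be >= 1")
        if not nests["interval_fate"].isin([0, 1]).all():
            i = int((~nests["interval_fate"].isin([0, 1])).idxmax())
            raise DatasetError(f"nests.csv row {i}: interval_fate must be 0 or 1")
        has_fledged = nests["fledged"].notna()
        if (has_fledged & (nests["interval_fate"] == 0)).any():
            i = int((has_fledged & (nests["interval_fate"] == 0)).idxmax())
            raise DatasetError(f"nests.csv row {i}: fledged present on a failed interval")

    return Dataset(schedule=schedule, captures=captures, nests=nests,
                   breeders=breeders, seed=seed)
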