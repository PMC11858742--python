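"""Canonical fossil-occurrence tables: ingest, validation, deduplication,
majority-rule time binning, and the four-way dataset partition.

The analytical unit throughout the package is the *occurrence*: a taxon
recorded at a collection (one locality/horizon), after per-collection
deduplication.  Every occurrence carries provenance flags saying whether it
is museum-only "dark data" (``in_dark``), part of the published record
(``in_published``), and additionally entered in the Paleobiology Database
(``in_pbdb``).  The four comparison datasets are

* ``A`` — dark data (museum-only, unpublished),
* ``B`` — the published record,
* ``C`` — the PBDB subset of B,
* ``D`` — the combined record, ``A ∪ B`` with ``A ∩ B = ∅``.

Tables are plain :class:`pandas.DataFrame` objects with a documented column
set (:data:`CANONICAL_COLUMNS`); helper functions validate and transform
them rather than wrapping them in a bespoke container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("species", "genus", "family", "above_family")
LITHOLOGIES = ("carbonate", "siliciclastic", "unknown")
GRAINSIZES = ("fine", "coarse", "unknown")

#: Canonical occurrence-table columns.  ``plon``/``plat`` (palaeocoordinates)
#: may be missing per-row; everything else is required.
CANONICAL_COLUMNS = (
    "occurrence_id", "species", "genus", "family", "rank", "collection_id",
    "lon", "lat", "plon", "plat", "max_ma", "min_ma",
    "lithology", "grainsize", "country_found", "country_housed",
    "n_specimens", "in_dark", "in_published", "in_pbdb",
)

_REQUIRED = tuple(c for c in CANONICAL_COLUMNS
                  if c not in ("plon", "plat", "n_specimens",
                               "species", "genus", "family",
                               "country_found", "country_housed"))

_NUMERIC = ("lon", "lat", "plon", "plat", "max_ma", "min_ma", "n_specimens")
_FLAGS = ("in_dark", "in_published", "in_pbdb")

#: Header names that identify a PBDB occurrence export.
PBDB_REQUIRED = ("accepted_name", "accepted_rank", "lng", "lat",
                 "max_ma", "min_ma", "collection_no")


class SchemaError(ValueError):
    """A required column is missing or the header is not recognised."""


class DialectError(SchemaError):
    """The file does not look like a PBDB occurrence export."""


class PartitionError(ValueError):
    """Provenance flags contradict the dataset-partition algebra."""


class BinTableError(ValueError):
    """A time-bin table violates ordering/contiguity requirements."""


# ---------------------------------------------------------------------------
# validation

def _truthy(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "t": True, "f": False, "yes": True, "no": False, "": False}
    return series.astype(str).str.strip().str.lower().map(mapping)


def validate_occurrences(df: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Validate a canonical occurrence table row by row.

    Returns the rows that satisfy every invariant, plus a list of
    ``{"row": index, "field": name, "message": str}`` diagnostics for the
    rejected rows.
    """
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    out = df.copy()
    for col in ("species", "genus", "family", "country_found", "country_housed"):
        if col not in out.columns:
            out[col] = ""
        out[col] = out[col].fillna("").astype(str).str.strip()
    for col in ("plon", "plat"):
        if col not in out.columns:
            out[col] = np.nan
    if "n_specimens" not in out.columns:
        out["n_specimens"] = 1

    errors: list[dict] = []

    def reject(mask: pd.Series, fld: str, msg: str) -> None:
        for idx in out.index[mask.fillna(True)]:
            errors.append({"row": int(idx), "field": fld,
                           "message": f"row {idx}: {fld} {msg}"})

    for col in _NUMERIC:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna() if col in ("plon", "plat") \
            else coerced.isna()
        if col in ("plon", "plat"):
            reject(bad & pd.Series(False, index=out.index), col, "unparsable")
            # unparsable palaeocoordinates degrade to absent, not rejection
        elif bad.any():
            reject(bad, col, "is not a number")
        out[col] = coerced

    for col in _FLAGS:
        out[col] = _truthy(out[col])
        bad = out[col].isna()
        if bad.any():
            reject(bad, col, "is not a boolean")
        out[col] = out[col].fillna(False).astype(bool)

    ok = ~out.index.isin([e["row"] for e in errors])
    chk = out[ok]

    def bound(mask, fld, msg):
        m = pd.Series(False, index=out.index)
        m.loc[chk.index[mask]] = True
        reject(m & pd.Series(m, index=out.index), fld, msg)

    bound(~(chk["max_ma"] > chk["min_ma"]) | (chk["min_ma"] < 0),
          "max_ma/min_ma", "must satisfy max_ma > min_ma >= 0")
    bound(~chk["lat"].between(-90, 90), "lat", "outside [-90, 90]")
    bound((chk["lon"] < -180) | (chk["lon"] >= 180), "lon", "outside [-180, 180)")
    bound(~(chk["n_specimens"] >= 1), "n_specimens", "must be >= 1")
    bound(~chk["rank"].isin(RANKS), "rank", f"not one of {RANKS}")
    bound(~chk["lithology"].isin(LITHOLOGIES), "lithology",
          f"not one of {LITHOLOGIES}")
    bound(~chk["grainsize"].isin(GRAINSIZES), "grainsize",
          f"not one of {GRAINSIZES}")
    bound(chk["in_pbdb"] & ~chk["in_published"], "in_pbdb",
          "set without in_published (PBDB is a subset of the published record)")
    bound(chk["in_dark"] == chk["in_published"], "in_dark",
          "must differ from in_published (museum-only xor published)")

    bad_rows = {e["row"] for e in errors}
    ok_df = out.loc[~out.index.isin(bad_rows)].copy()
    ok_df["n_specimens"] = ok_df["n_specimens"].astype(int)
    ok_df.attrs["row_errors"] = errors
    return ok_df, errors


def read_occurrences(path, schema: Mapping[str, str] | None = None,
                     strict: bool = False) -> pd.DataFrame:
    """Read a canonical occurrence CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional ``{file column -> canonical column}`` rename map.
    strict
        If True, any invalid row raises instead of being dropped.

    Invalid rows are dropped and reported in ``df.attrs["row_errors"]``.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})
    if schema:
        raw = raw.rename(columns=dict(schema))
    ok, errors = validate_occurrences(raw)
    if strict and errors:
        raise SchemaError("invalid rows: "
                          + "; ".join(e["message"] for e in errors[:10]))
    ok = ok.reset_index(drop=True)
    ok.attrs["row_errors"] = errors
    return ok[list(CANONICAL_COLUMNS)]


_PBDB_RANKS = {"species": "species", "subspecies": "species",
               "genus": "genus", "subgenus": "genus", "family": "family"}


def read_pbdb_dialect(path) -> pd.DataFrame:
    """Read a PBDB occurrence export into the canonical schema.

    Rows are flagged ``in_pbdb = in_published = True`` (the PBDB mirrors the
    published record).  Rows lacking palaeocoordinates are retained with
    ``plon``/``plat`` absent.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PBDB_REQUIRED if c not in raw.columns]
    if missing:
        raise DialectError(
            "not a PBDB occurrence export; missing field(s): "
            + ", ".join(missing))
    if raw.empty:
        df = pd.DataFrame(columns=CANONICAL_COLUMNS)
        out, _ = validate_occurrences(df) if len(df) else (df, [])
        return out[list(CANONICAL_COLUMNS)] if len(df) else df

    rank = raw["accepted_rank"].str.lower().map(_PBDB_RANKS).fillna("above_family")
    name = raw["accepted_name"].fillna("").str.strip()
    genus_col = raw["genus"].fillna("") if "genus" in raw.columns else \
        name.where(rank.isin(["genus"]), name.str.split().str[0].where(rank == "species", ""))
    df = pd.DataFrame({
        "occurrence_id": raw.get("occurrence_no", pd.Series(range(len(raw)))).astype(str),
        "species": name.where(rank == "species", ""),
        "genus": genus_col,
        "family": raw["family"].fillna("") if "family" in raw.columns else
                  name.where(rank == "family", ""),
        "rank": rank,
        "collection_id": raw["collection_no"].astype(str),
        "lon": raw["lng"], "lat": raw["lat"],
        "plon": raw.get("paleolng"), "plat": raw.get("paleolat"),
        "max_ma": raw["max_ma"], "min_ma": raw["min_ma"],
        "lithology": raw.get("lithology1", pd.Series("unknown", index=raw.index)).map(
            lambda s: s if s in LITHOLOGIES else "unknown"),
        "grainsize": "unknown",
        "country_found": raw.get("cc", pd.Series("", index=raw.index)).fillna(""),
        "country_housed": "",
        "n_specimens": 1,
        "in_dark": False, "in_published": True, "in_pbdb": True,
    })
    ok, errors = validate_occurrences(df)
    ok = ok.reset_index(drop=True)
    ok.attrs["row_errors"] = errors
    ok.attrs["n_missing_paleocoords"] = int(ok["plon"].isna().sum())
    return ok[list(CANONICAL_COLUMNS)]


# ---------------------------------------------------------------------------
# deduplication

def finest_name(df: pd.DataFrame) -> pd.Series:
    """The finest available taxon name per row (species > genus > family)."""
    name = df["species"].where(df["species"] != "", df["genus"])
    name = name.where(name != "", df["family"])
    return name


def deduplicate(occ: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate appearances of a taxon within one collection.

    Key: (finest taxon name, collection_id).  Specimen counts are summed and
    provenance flags OR-combined; because "dark" means museum-*only*, a
    merged record that is published anywhere ceases to be dark.  Rows with no
    taxon name at any level are never merged.
    """
    occ = occ.copy()
    key = finest_name(occ)
    anon = key == ""
    key = key.where(~anon, "\0anon-" + occ["occurrence_id"].astype(str))
    occ["_key"] = key

    agg = {c: "first" for c in occ.columns if c not in ("_key", "collection_id")}
    agg["n_specimens"] = "sum"
    for f in _FLAGS:
        agg[f] = "any"
    out = (occ.groupby(["_key", "collection_id"], as_index=False, sort=False)
              .agg(agg))
    out["in_dark"] = out["in_dark"] & ~out["in_published"]
    out = out.drop(columns="_key")
    return out[list(occ.columns.drop("_key"))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# time bins

def read_bins(path) -> pd.DataFrame:
    """Read and validate a time-bin table CSV (name, max_ma, min_ma, level)."""
    bins = pd.read_csv(path)
    return validate_bins(bins)


def validate_bins(bins: pd.DataFrame) -> pd.DataFrame:
    need = {"name", "max_ma", "min_ma"}
    if not need <= set(bins.columns):
        raise BinTableError(f"bin table needs columns {sorted(need)}")
    bins = bins.copy().sort_values("max_ma", ascending=False).reset_index(drop=True)
    if not (bins["max_ma"] > bins["min_ma"]).all():
        raise BinTableError("every bin needs max_ma > min_ma")
    gaps = bins["min_ma"].values[:-1] - bins["max_ma"].values[1:]
    if len(bins) > 1 and not np.allclose(gaps, 0.0, atol=1e-9):
        raise BinTableError("bins must be contiguous and non-overlapping")
    return bins


def palaeozoic_stages() -> pd.DataFrame:
    """Packaged stage-level Palaeozoic bin table (538.8–251.902 Ma)."""
    with resources.files("paleodark.data").joinpath(
            "palaeozoic_stages.csv").open("rb") as fh:
        return validate_bins(pd.read_csv(fh))


def palaeozoic_subperiods() -> pd.DataFrame:
    """Packaged sub-period table; splits the Carboniferous into the
    Mississippian and Pennsylvanian."""
    with resources.files("paleodark.data").joinpath(
            "palaeozoic_subperiods.csv").open("rb") as fh:
        return validate_bins(pd.read_csv(fh))


def assign_bins(occ: pd.DataFrame, bins: pd.DataFrame,
                rule: str = "majority", strict: bool = False) -> pd.DataFrame:
    """Assign each occurrence to the time bin holding the largest share of
    its age interval ("majority" binning).

    Ties go to the older bin.  With ``strict=True`` an occurrence whose best
    bin holds <= 50% of its interval is left unassigned.  Adds columns
    ``bin``, ``bin_frac``, ``bin_max_ma``, ``bin_min_ma``, ``bin_mid_ma``;
    unassigned rows get NA and are counted in ``attrs["n_unassigned"]``.
    """
    if rule != "majority":
        raise ValueError(f"unknown binning rule {rule!r}")
    bins = validate_bins(bins)
    out = occ.copy()
    lo = out["min_ma"].to_numpy(float)
    hi = out["max_ma"].to_numpy(float)
    bmax = bins["max_ma"].to_numpy(float)
    bmin = bins["min_ma"].to_numpy(float)

    ov = np.minimum(hi[:, None], bmax[None, :]) - np.maximum(lo[:, None], bmin[None, :])
    ov = np.clip(ov, 0.0, None)
    frac = ov / (hi - lo)[:, None]
    # bins are ordered old -> young, so argmax's first-match rule is the
    # older-bin tie-break
    best = np.argmax(np.round(frac, 12), axis=1)
    best_frac = frac[np.arange(len(out)), best]
    unassigned = best_frac <= 0.0
    if strict:
        unassigned |= best_frac <= 0.5

    names = bins["name"].to_numpy(object)[best]
    out["bin"] = pd.array(names, dtype="string")
    out.loc[unassigned, "bin"] = pd.NA
    out["bin_frac"] = np.where(unassigned, np.nan, best_frac)
    out["bin_max_ma"] = np.where(unassigned, np.nan, bmax[best])
    out["bin_min_ma"] = np.where(unassigned, np.nan, bmin[best])
    out["bin_mid_ma"] = (out["bin_max_ma"] + out["bin_min_ma"]) / 2.0
    out.attrs["n_unassigned"] = int(unassigned.sum())
    return out


# ---------------------------------------------------------------------------
# partition

@dataclass(frozen=True)
class DatasetPartition:
    """The four-way comparison partition: A dark, B published, C PBDB⊆B,
    D combined (A ∪ B, disjoint union)."""

    A: pd.DataFrame
    B: pd.DataFrame
    C: pd.DataFrame
    D: pd.DataFrame

    def labelled(self) -> Sequence[tuple[str, pd.DataFrame]]:
        return (("A", self.A), ("B", self.B), ("C", self.C), ("D", self.D))

    def subsets(self) -> Sequence[tuple[str, pd.DataFrame]]:
        return (("A", self.A), ("B", self.B), ("C", self.C))

    def complement(self, label: str) -> pd.DataFrame:
        """D with the named subset removed (D \\ S)."""
        if label == "A":
            return self.B
        if label == "B":
            return self.A
        if label == "C":
            return self.D[~self.D["in_pbdb"]]
        raise KeyError(label)

    @property
    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.labelled()}


def partition(occ: pd.DataFrame) -> DatasetPartition:
    """Split an occurrence table into datasets A/B/C/D by provenance flags.

    Raises :class:`PartitionError` on contradictory flags (a row both dark
    and published, or in the PBDB but not published).
    """
    both = occ["in_dark"] & occ["in_published"]
    if both.any():
        raise PartitionError(
            f"{int(both.sum())} row(s) flagged both dark and published")
    orphan = occ["in_pbdb"] & ~occ["in_published"]
    if orphan.any():
        raise PartitionError(
            f"{int(orphan.sum())} PBDB row(s) not flagged as published")
    return DatasetPartition(
        A=occ[occ["in_dark"]].copy(),
        B=occ[occ["in_published"]].copy(),
        C=occ[occ["in_pbdb"]].copy(),
        D=occ.copy(),
    )
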