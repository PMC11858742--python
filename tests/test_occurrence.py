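"""Ingest, validation, deduplication, majority binning and partition."""

import numpy as np
import pandas as pd
import pytest

from paleodark.occurrence import (BinTableError, DialectError, PartitionError,
                                  SchemaError, assign_bins, deduplicate,
                                  finest_name, palaeozoic_stages,
                                  palaeozoic_subperiods, partition,
                                  read_occurrences, read_pbdb_dialect,
                                  validate_bins, validate_occurrences)


# ---------------------------------------------------------------------------
# reading and validation

def test_read_well_formed_file(tmp_path, make_occ):
    path = tmp_path / "occ.csv"
    make_occ([{"genus": "Ga"}, {"genus": "Gb"}, {"genus": "Gc"}]).to_csv(
        path, index=False)
    df = read_occurrences(path)
    assert len(df) == 3
    assert df.attrs["row_errors"] == []


def test_missing_column_names_the_column(tmp_path, make_occ):
    path = tmp_path / "occ.csv"
    make_occ([{}]).drop(columns="lithology").to_csv(path, index=False)
    with pytest.raises(SchemaError, match="lithology"):
        read_occurrences(path)


@pytest.mark.parametrize("bad,field", [
    ({"lat": 123.0}, "lat"),
    ({"lon": 200.0}, "lon"),
    ({"max_ma": 300.0, "min_ma": 310.0}, "max_ma"),
    ({"n_specimens": 0}, "n_specimens"),
    ({"rank": "phylum"}, "rank"),
    ({"in_pbdb": True, "in_published": False, "in_dark": True}, "in_pbdb"),
    ({"in_dark": True, "in_published": True}, "in_dark"),
])
def test_invalid_row_rejected_with_named_field(tmp_path, make_occ, bad, field):
    path = tmp_path / "occ.csv"
    make_occ([{"genus": "Ok"}, dict({"genus": "Bad"}, **bad)]).to_csv(
        path, index=False)
    df = read_occurrences(path)
    assert len(df) == 1
    errs = df.attrs["row_errors"]
    assert any(e["field"].startswith(field) for e in errs)
    assert any("row 1" in e["message"] for e in errs)


def test_schema_rename_map(tmp_path, make_occ):
    path = tmp_path / "occ.csv"
    make_occ([{"genus": "Ga"}]).rename(columns={"genus": "Genus_name"}).to_csv(
        path, index=False)
    df = read_occurrences(path, schema={"Genus_name": "genus"})
    assert df.loc[0, "genus"] == "Ga"


# ---------------------------------------------------------------------------
# PBDB dialect

def _pbdb_frame(n=2, **over):
    base = pd.DataFrame({
        "occurrence_no": [str(i) for i in range(n)],
        "accepted_name": ["Genusa"] * n,
        "accepted_rank": ["genus"] * n,
        "collection_no": ["10"] * n,
        "lng": ["12.5"] * n, "lat": ["45.0"] * n,
        "paleolng": ["2.0"] * n, "paleolat": ["-10.0"] * n,
        "max_ma": ["330"] * n, "min_ma": ["320"] * n,
    })
    for k, v in over.items():
        base[k] = v
    return base


def test_pbdb_mapping(tmp_path):
    path = tmp_path / "pbdb.csv"
    _pbdb_frame().to_csv(path, index=False)
    df = read_pbdb_dialect(path)
    assert (df["rank"] == "genus").all()
    assert (df["genus"] == "Genusa").all()
    assert df["in_pbdb"].all() and df["in_published"].all()
    assert not df["in_dark"].any()


def test_pbdb_missing_coords_retained_and_flagged(tmp_path):
    path = tmp_path / "pbdb.csv"
    _pbdb_frame(paleolng=["", ""], paleolat=["", ""]).to_csv(path, index=False)
    df = read_pbdb_dialect(path)
    assert len(df) == 2
    assert df["plon"].isna().all()
    assert df.attrs["n_missing_paleocoords"] == 2


def test_pbdb_empty_export(tmp_path):
    path = tmp_path / "pbdb.csv"
    _pbdb_frame(0).to_csv(path, index=False)
    assert len(read_pbdb_dialect(path)) == 0


def test_pbdb_unrecognized_header(tmp_path, make_occ):
    path = tmp_path / "notpbdb.csv"
    make_occ([{}]).to_csv(path, index=False)
    with pytest.raises(DialectError, match="accepted_name"):
        read_pbdb_dialect(path)


# ---------------------------------------------------------------------------
# deduplication

def test_dedup_merges_same_taxon_same_collection(make_occ):
    occ = make_occ([
        {"genus": "Ga", "collection_id": "c1", "n_specimens": 2},
        {"genus": "Ga", "collection_id": "c1", "n_specimens": 3},
        {"genus": "Ga", "collection_id": "c2"},
        {"genus": "Gb", "collection_id": "c1"},
    ])
    out = deduplicate(occ)
    assert len(out) == 3
    merged = out[(finest_name(out) == "Ga")
                 & (out["collection_id"] == "c1")]
    assert merged["n_specimens"].item() == 5


def test_dedup_idempotent_and_specimen_conserving(small_dataset):
    occ, _, _ = small_dataset
    once = deduplicate(occ)
    assert once["n_specimens"].sum() == occ["n_specimens"].sum()
    twice = deduplicate(once)
    pd.testing.assert_frame_equal(
        once.reset_index(drop=True), twice.reset_index(drop=True))


def test_dedup_published_absorbs_dark(make_occ):
    """A taxon-collection pair seen both in a museum drawer and in print is
    published, not museum-only."""
    occ = make_occ([
        {"genus": "Ga", "collection_id": "c1",
         "in_dark": True, "in_published": False},
        {"genus": "Ga", "collection_id": "c1",
         "in_dark": False, "in_published": True},
    ])
    out = deduplicate(occ)
    assert len(out) == 1
    assert out["in_published"].item() and not out["in_dark"].item()


# ---------------------------------------------------------------------------
# time bins and majority binning

def test_packaged_bin_tables_are_valid():
    stages = palaeozoic_stages()
    subs = palaeozoic_subperiods()
    assert stages["max_ma"].iloc[0] == 538.8
    assert stages["min_ma"].iloc[-1] == 251.902
    assert {"Mississippian", "Pennsylvanian"} <= set(subs["name"])
    assert "Carboniferous" not in set(subs["name"])


def test_bin_table_must_be_contiguous():
    bad = pd.DataFrame({"name": ["x", "y"], "max_ma": [100.0, 80.0],
                        "min_ma": [90.0, 60.0]})
    with pytest.raises(BinTableError):
        validate_bins(bad)


def test_majority_binning_worked_split(make_occ, subperiod_bins):
    """Age 330-320 Ma overlaps the Mississippian by 6.8 Myr and the
    Pennsylvanian by 3.2 Myr -> Mississippian."""
    occ = make_occ([{"max_ma": 330.0, "min_ma": 320.0}])
    out = assign_bins(occ, subperiod_bins)
    assert out.loc[0, "bin"] == "Mississippian"
    assert out.loc[0, "bin_frac"] == pytest.approx(6.8 / 10.0)


def test_majority_binning_inside_one_bin(make_occ, subperiod_bins):
    occ = make_occ([{"max_ma": 340.0, "min_ma": 335.0}])
    out = assign_bins(occ, subperiod_bins)
    assert out.loc[0, "bin"] == "Mississippian"
    assert out.loc[0, "bin_frac"] == 1.0


def test_majority_binning_tie_goes_older(make_occ, subperiod_bins):
    occ = make_occ([{"max_ma": 328.2, "min_ma": 318.2}])   # 5 Myr each side
    out = assign_bins(occ, subperiod_bins)
    assert out.loc[0, "bin"] == "Mississippian"


def test_strict_mode_drops_sub_majority(make_occ, subperiod_bins):
    occ = make_occ([{"max_ma": 328.2, "min_ma": 318.2}])
    out = assign_bins(occ, subperiod_bins, strict=True)
    assert out["bin"].isna().all()
    assert out.attrs["n_unassigned"] == 1


def test_binning_out_of_span_counted(make_occ, subperiod_bins):
    occ = make_occ([{"max_ma": 200.0, "min_ma": 190.0},
                    {"max_ma": 330.0, "min_ma": 320.0}])
    out = assign_bins(occ, subperiod_bins)
    assert out.attrs["n_unassigned"] == 1
    assert out["bin"].notna().sum() == 1


def test_binning_deterministic_idempotent(small_dataset, stage_bins):
    occ, _, _ = small_dataset
    a = assign_bins(occ, stage_bins)
    b = assign_bins(a.drop(columns=["bin", "bin_frac", "bin_max_ma",
                                    "bin_min_ma", "bin_mid_ma"]), stage_bins)
    pd.testing.assert_series_equal(a["bin"], b["bin"])
    assert a["bin"].notna().sum() + a.attrs["n_unassigned"] == len(a)


# ---------------------------------------------------------------------------
# partition

def test_partition_algebra(small_partition):
    part = small_partition
    s = part.sizes
    assert s["D"] == s["A"] + s["B"]
    assert part.C["in_published"].all()
    assert not (part.A["occurrence_id"].isin(part.B["occurrence_id"])).any()


def test_partition_membership(make_occ):
    occ = make_occ([
        {"genus": "Ga", "in_dark": True, "in_published": False},
        {"genus": "Gb", "in_pbdb": True},
    ])
    part = partition(occ)
    assert part.sizes == {"A": 1, "B": 1, "C": 1, "D": 2}
    assert part.A["genus"].item() == "Ga"
    assert part.C["genus"].item() == "Gb"


def test_partition_rejects_contradiction(make_occ):
    occ = make_occ([{"in_dark": True, "in_published": True}])
    with pytest.raises(PartitionError):
        partition(occ)
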