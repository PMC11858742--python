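"""Synthetic fossil-occurrence generator with known ground truth.

Every downstream statistic in the package (geographic range, temporal
range, diversity, substrate affinity, diversity drivers) is exercised
against data from this module, where the true answer is known by
construction:

* each taxon's true geographic range is a spherical cap (centre, radius in
  km) with closed-form area ``2 π R² (1 − cos(r/R))``;
* its true temporal range is a [FAD, LAD] interval in Ma;
* its true substrate preference is a carbonate-hosting probability.

Occurrences are drawn through two sampling *channels* — "dark" (museum-only
specimens) and "published" — each with its own intensity, lithology /
grain-size / taphonomic-grade composition, within-range temporal weighting
(a dark channel can be "bottom-weighted" toward the old end of a taxon's
range), spatial reach (a channel may only sample an inner fraction of the
cap), and collection-practice country pools.  The PBDB dataset is a random
subsample of published rows, mirroring how database records are a subset of
the published record.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .occurrence import CANONICAL_COLUMNS, validate_occurrences

#: Authalic Earth radius, km.
EARTH_RADIUS_KM = 6371.0088


class ScenarioError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class TrueTaxon:
    """Ground-truth description of one simulated taxon (species level)."""

    family: str
    genus: str
    species: str
    centre_lon: float
    centre_lat: float
    radius_km: float
    fad_ma: float
    lad_ma: float
    carbonate_affinity: float
    abundance: float = 1.0

    def __post_init__(self):
        if not self.fad_ma > self.lad_ma >= 0:
            raise ScenarioError("need FAD > LAD >= 0")
        if self.radius_km < 0:
            raise ScenarioError("negative range radius")
        if not 0.0 <= self.carbonate_affinity <= 1.0:
            raise ScenarioError("carbonate_affinity outside [0, 1]")


@dataclass(frozen=True)
class TaxonHyperparams:
    """Distributions the taxon generator draws from."""

    genera_per_family: int = 8
    lat_sd: float = 25.0            # degrees; ranges concentrate at low latitudes
    radius_mean_km: float = 1500.0  # lognormal mean of true cap radius
    radius_sigma: float = 0.5       # lognormal shape
    fad_max: float = 530.0          # Ma, oldest possible first appearance
    fad_min: float = 300.0
    duration_mean: float = 25.0     # Myr, exponential mean
    duration_min: float = 6.0
    lad_floor: float = 252.0        # ranges truncated at the era top
    affinity_alpha: float = 2.0     # Beta prior on carbonate affinity
    affinity_beta: float = 2.0
    abundance_sigma: float = 0.6    # lognormal spread of abundance weights

    def check(self) -> None:
        if self.genera_per_family < 1 or self.radius_mean_km < 0 or \
                self.radius_sigma < 0 or self.duration_mean <= 0 or \
                not self.fad_max > self.fad_min >= self.lad_floor >= 0 or \
                min(self.affinity_alpha, self.affinity_beta) <= 0:
            raise ScenarioError("invalid taxon hyperparameters")


@dataclass(frozen=True)
class ChannelConfig:
    """Sampling behaviour of one provenance channel."""

    name: str
    intensity: float                 # mean occurrences per unit taxon abundance
    p_carbonate: float = 0.6         # lithology bias among known-lithology rows
    p_lith_unknown: float = 0.1
    p_coarse: float = 0.15           # grain-size bias among known rows
    p_grain_unknown: float = 0.15
    taph_probs: tuple = (0.3, 0.3, 0.2, 0.15, 0.05)  # grade 1 (best) .. 5
    temporal_exponent: float = 1.0   # r = u**e; e > 1 bottom-weights toward FAD
    radius_fraction: float = 1.0     # channel samples the inner cap r' = f·r
    rank_probs: tuple = (0.35, 0.3, 0.22, 0.13)      # species/genus/family/above
    countries: tuple = ("US", "UK", "DE", "FR", "BE", "RU", "CN", "AU")
    country_weights: tuple = (0.45, 0.18, 0.12, 0.08, 0.05, 0.05, 0.04, 0.03)
    p_domestic: float = 0.78         # probability housed country == found country
    housing_pool: tuple = ("US", "UK", "DE")
    housing_weights: tuple = (0.55, 0.25, 0.20)
    affinity_weight: float = 0.0     # 0: channel lithology bias; 1: taxon affinity
    mean_extra_specimens: float = 0.55
    age_halfwidth: tuple = (1.0, 4.0)  # Myr, occurrence age-interval half-width
    occ_per_collection: float = 3.0

    def check(self) -> None:
        probs = (self.p_carbonate, self.p_lith_unknown, self.p_coarse,
                 self.p_grain_unknown, self.p_domestic, self.affinity_weight)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ScenarioError(f"channel {self.name}: probability outside [0,1]")
        for dist, n in ((self.taph_probs, 5), (self.rank_probs, 4),
                        (self.country_weights, len(self.countries)),
                        (self.housing_weights, len(self.housing_pool))):
            if len(dist) != n or any(p < 0 for p in dist) or \
                    not math.isclose(sum(dist), 1.0, abs_tol=1e-9):
                raise ScenarioError(f"channel {self.name}: distribution must sum to 1")
        if self.intensity < 0 or not 0 <= self.radius_fraction <= 1 or \
                self.temporal_exponent <= 0:
            raise ScenarioError(f"channel {self.name}: invalid parameter")


@dataclass(frozen=True)
class Scenario:
    """A full generator configuration: taxa + the two sampling channels +
    the PBDB subsampling rate."""

    n_taxa: int = 120
    taxa: TaxonHyperparams = field(default_factory=TaxonHyperparams)
    dark: ChannelConfig = field(default_factory=lambda: ChannelConfig(
        name="dark",
        intensity=8.13,            # -> ~976 dark occurrences over 120 taxa
        p_carbonate=0.85,          # dark data are ~85% carbonate-hosted
        p_coarse=0.26,             # and the most coarse-grained channel
        taph_probs=(0.08, 0.15, 0.27, 0.30, 0.20),   # poorer preservation
        temporal_exponent=2.2,     # bottom-weighted within taxon ranges
        rank_probs=(0.33, 0.40, 0.21, 0.06),         # most genus-level IDs
        p_domestic=0.86,
    ))
    published: ChannelConfig = field(default_factory=lambda: ChannelConfig(
        name="published",
        intensity=10.39,           # -> ~1247 published occurrences
        p_carbonate=0.62,          # published record ~38% siliciclastic
        p_coarse=0.15,
        taph_probs=(0.28, 0.30, 0.22, 0.14, 0.06),
        temporal_exponent=1.0,     # ~even within-range occurrence spread
        rank_probs=(0.38, 0.28, 0.21, 0.13),
        p_domestic=0.80,
    ))
    pbdb_fraction: float = 590.0 / 1247.0   # PBDB ⊂ published subsample rate

    def check(self) -> None:
        if self.n_taxa < 1:
            raise ScenarioError("n_taxa must be >= 1")
        if not 0.0 <= self.pbdb_fraction <= 1.0:
            raise ScenarioError("pbdb_fraction outside [0, 1]")
        self.taxa.check()
        self.dark.check()
        self.published.check()


# ---------------------------------------------------------------------------
# taxa

def generate_taxa(n_taxa: int, seed: int,
                  hyper: TaxonHyperparams | None = None) -> list[TrueTaxon]:
    """Draw ``n_taxa`` ground-truth taxa reproducibly from ``seed``."""
    if n_taxa < 1:
        raise ScenarioError("n_taxa must be >= 1")
    hyper = hyper or TaxonHyperparams()
    hyper.check()
    rng = np.random.default_rng(seed)
    taxa = []
    for i in range(n_taxa):
        fam = i // hyper.genera_per_family
        lat = float(np.clip(rng.normal(0.0, hyper.lat_sd), -80.0, 80.0))
        lon = float(rng.uniform(-180.0, 180.0))
        radius = float(rng.lognormal(math.log(max(hyper.radius_mean_km, 1e-12)),
                                     hyper.radius_sigma)) \
            if hyper.radius_mean_km > 0 else 0.0
        fad = float(rng.uniform(hyper.fad_min, hyper.fad_max))
        dur = float(hyper.duration_min + rng.exponential(hyper.duration_mean))
        lad = max(fad - dur, hyper.lad_floor)
        if lad >= fad:           # guard against zero-length ranges at the floor
            fad = lad + hyper.duration_min
        taxa.append(TrueTaxon(
            family=f"Family{fam:02d}",
            genus=f"Genus{i:03d}",
            species=f"Genus{i:03d} species{i:03d}",
            centre_lon=lon, centre_lat=lat, radius_km=radius,
            fad_ma=fad, lad_ma=lad,
            carbonate_affinity=float(rng.beta(hyper.affinity_alpha,
                                              hyper.affinity_beta)),
            abundance=float(rng.lognormal(0.0, hyper.abundance_sigma)),
        ))
    return taxa


def ground_truth(taxa: list[TrueTaxon]) -> pd.DataFrame:
    """True per-taxon range areas, latitudinal widths, durations, affinities."""
    rows = []
    for t in taxa:
        ang = t.radius_km / EARTH_RADIUS_KM
        area = 2.0 * math.pi * EARTH_RADIUS_KM ** 2 * (1.0 - math.cos(ang))
        half_deg = math.degrees(ang)
        lat_lo = max(t.centre_lat - half_deg, -90.0)
        lat_hi = min(t.centre_lat + half_deg, 90.0)
        rows.append({
            "species": t.species, "genus": t.genus, "family": t.family,
            "centre_lon": t.centre_lon, "centre_lat": t.centre_lat,
            "radius_km": t.radius_km,
            "true_area_km2": area,
            "true_lat_width_deg": lat_hi - lat_lo,
            "fad_ma": t.fad_ma, "lad_ma": t.lad_ma,
            "true_duration_myr": t.fad_ma - t.lad_ma,
            "carbonate_affinity": t.carbonate_affinity,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occurrence sampling

def _cap_points(rng, lon0, lat0, radius_km, n):
    """Uniform points in the spherical cap of ``radius_km`` around a centre."""
    if n == 0:
        return np.empty(0), np.empty(0)
    theta_max = radius_km / EARTH_RADIUS_KM
    cos_t = rng.uniform(math.cos(min(theta_max, math.pi)), 1.0, size=n)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    brg = rng.uniform(0.0, 2.0 * math.pi, size=n)
    phi1 = math.radians(lat0)
    lam1 = math.radians(lon0)
    sin_phi2 = (math.sin(phi1) * np.cos(theta)
                + math.cos(phi1) * np.sin(theta) * np.cos(brg))
    phi2 = np.arcsin(np.clip(sin_phi2, -1.0, 1.0))
    lam2 = lam1 + np.arctan2(np.sin(brg) * np.sin(theta) * math.cos(phi1),
                             np.cos(theta) - math.sin(phi1) * sin_phi2)
    lon = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    return lon, np.degrees(phi2)


def _categorical(rng, values, probs, n):
    return rng.choice(np.asarray(values, dtype=object), size=n, p=list(probs))


def _sample_channel(rng, taxa, cfg: ChannelConfig, start_id: int):
    counts = rng.poisson([cfg.intensity * t.abundance for t in taxa])
    rows, spec_rows = [], []
    oid = start_id
    for t, n in zip(taxa, counts):
        if n == 0:
            continue
        lon, lat = _cap_points(rng, t.centre_lon, t.centre_lat,
                               cfg.radius_fraction * t.radius_km, n)
        u = rng.uniform(0.0, 1.0, size=n)
        r = u ** cfg.temporal_exponent          # 0 = FAD (old end)
        mid = t.fad_ma - r * (t.fad_ma - t.lad_ma)
        hw = rng.uniform(*cfg.age_halfwidth, size=n)
        max_ma = mid + hw
        min_ma = np.maximum(mid - hw, 0.0)

        p_carb = ((1.0 - cfg.affinity_weight) * cfg.p_carbonate
                  + cfg.affinity_weight * t.carbonate_affinity)
        lith = np.where(rng.uniform(size=n) < p_carb, "carbonate", "siliciclastic")
        lith = np.where(rng.uniform(size=n) < cfg.p_lith_unknown, "unknown", lith)
        grain = np.where(rng.uniform(size=n) < cfg.p_coarse, "coarse", "fine")
        grain = np.where(rng.uniform(size=n) < cfg.p_grain_unknown, "unknown", grain)

        rank = _categorical(rng, ("species", "genus", "family", "above_family"),
                            cfg.rank_probs, n)
        found = _categorical(rng, cfg.countries, cfg.country_weights, n)
        housed = np.where(rng.uniform(size=n) < cfg.p_domestic, found,
                          _categorical(rng, cfg.housing_pool,
                                       cfg.housing_weights, n))
        n_spec = 1 + rng.poisson(cfg.mean_extra_specimens, size=n)

        for j in range(n):
            rk = rank[j]
            rows.append({
                "occurrence_id": f"syn-{oid:06d}",
                "species": t.species if rk == "species" else "",
                "genus": t.genus if rk in ("species", "genus") else "",
                "family": t.family if rk != "above_family" else "",
                "rank": rk,
                "collection_id": "",          # assigned after pooling
                "lon": float(lon[j]), "lat": float(lat[j]),
                "plon": float(lon[j]), "plat": float(lat[j]),
                "max_ma": float(max_ma[j]), "min_ma": float(min_ma[j]),
                "lithology": lith[j], "grainsize": grain[j],
                "country_found": found[j], "country_housed": housed[j],
                "n_specimens": int(n_spec[j]),
                "in_dark": cfg.name == "dark",
                "in_published": cfg.name != "dark",
                "in_pbdb": False,
                "_channel": cfg.name,
            })
            grades = rng.choice([1, 2, 3, 4, 5], size=int(n_spec[j]),
                                p=list(cfg.taph_probs))
            for g in grades:
                spec_rows.append({"specimen_id": f"spm-{oid:06d}-{len(spec_rows)}",
                                  "occurrence_id": f"syn-{oid:06d}",
                                  "taph_grade": int(g)})
            oid += 1
    return rows, spec_rows, oid


def _assign_collections(df: pd.DataFrame, rng,
                        occ_per_collection: dict[str, float]) -> pd.Series:
    """Pool occurrences into collections (shared locality/horizon units):
    occurrences from the same channel, 5-degree cell and 10-Myr window are
    split among ~n/k collections."""
    mid = (df["max_ma"] + df["min_ma"]) / 2.0
    cell = (df["_channel"].astype(str) + "|"
            + np.floor(df["plon"] / 5.0).astype(int).astype(str) + "|"
            + np.floor(df["plat"] / 5.0).astype(int).astype(str) + "|"
            + np.floor(mid / 10.0).astype(int).astype(str))
    coll = pd.Series("", index=df.index, dtype=object)
    for key, idx in df.groupby(cell, sort=True).groups.items():
        k = occ_per_collection.get(str(key).split("|", 1)[0], 3.0)
        n_coll = max(1, int(round(len(idx) / max(k, 1e-9))))
        slots = rng.integers(0, n_coll, size=len(idx))
        tag = zlib.crc32(str(key).encode())   # deterministic across processes
        coll.loc[idx] = [f"coll-{tag}-{s}" for s in slots]
    return coll


def sample_occurrences(taxa: list[TrueTaxon], scenario: Scenario,
                       seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw an occurrence table (plus a specimen table) from the ground
    truth under the scenario's channel configurations.

    Returns ``(occurrences, specimens)``.  Occurrence rows satisfy every
    canonical-table invariant; the PBDB flag marks a Bernoulli subsample of
    published rows.
    """
    scenario.check()
    rng = np.random.default_rng(seed)
    rows, specs = [], []
    oid = 0
    for cfg in (scenario.dark, scenario.published):
        r, s, oid = _sample_channel(rng, taxa, cfg, oid)
        rows += r
        specs += s
    occ = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS) + ["_channel"])
    spec = pd.DataFrame(specs, columns=["specimen_id", "occurrence_id",
                                        "taph_grade"])
    if occ.empty:
        return occ.drop(columns="_channel"), spec

    occ["collection_id"] = _assign_collections(
        occ, rng, {"dark": scenario.dark.occ_per_collection,
                   "published": scenario.published.occ_per_collection})
    pub = occ["in_published"].to_numpy()
    pick = rng.uniform(size=len(occ)) < scenario.pbdb_fraction
    occ["in_pbdb"] = pub & pick
    occ = occ.drop(columns="_channel")

    ok, errors = validate_occurrences(occ)
    if errors:   # generator bug guard: synthetic rows must always validate
        raise AssertionError(f"generator produced invalid rows: {errors[:3]}")
    return ok.reset_index(drop=True), spec


def simulate(scenario: Scenario | None = None, seed: int = 0
             ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: returns (occurrences, specimens, ground truth)."""
    scenario = scenario or Scenario()
    taxa = generate_taxa(scenario.n_taxa, seed, scenario.taxa)
    occ, spec = sample_occurrences(taxa, scenario, seed + 1)
    return occ, spec, ground_truth(taxa)


# ---------------------------------------------------------------------------
# scenario files

def load_scenario(path) -> Scenario:
    """Load a scenario from a YAML file of nested key/value overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "n_taxa" in raw:
        kwargs["n_taxa"] = int(raw["n_taxa"])
    if "pbdb_fraction" in raw:
        kwargs["pbdb_fraction"] = float(raw["pbdb_fraction"])
    if "taxa" in raw:
        kwargs["taxa"] = TaxonHyperparams(**raw["taxa"])
    base = Scenario()
    for ch in ("dark", "published"):
        if ch in raw:
            over = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[ch].items()}
            kwargs[ch] = replace(getattr(base, ch), **over)
    sc = Scenario(**kwargs)
    sc.check()
    return sc


def write_outputs(occ: pd.DataFrame, spec: pd.DataFrame, truth: pd.DataFrame,
                  out_dir) -> dict[str, str]:
    """Emit the canonical occurrence CSV, specimen CSV and ground-truth CSV."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"occurrences": out / "occurrences.csv",
             "specimens": out / "specimens.csv",
             "ground_truth": out / "ground_truth.csv"}
    occ.to_csv(paths["occurrences"], index=False)
    spec.to_csv(paths["specimens"], index=False)
    truth.to_csv(paths["ground_truth"], index=False)
    return {k: str(v) for k, v in paths.items()}
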