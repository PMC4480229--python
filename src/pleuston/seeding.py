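"""Population initialization in a bathymetric depth band.

The drift experiments start from a virtual population of surface-floating
colonies scattered between two isobaths — by default the 20 m (inner shelf)
and 200 m (shelf break) depth contours, the band in which overwintering
*Physalia physalis* colonies sit when onshore winds arrive.  Sampling is
uniform over area within the band, via rejection sampling on the bounding
box with a cos(latitude) area correction, and is bit-reproducible from the
recorded provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .environment import DomainScenario

HANDEDNESS_CODES = {"none": 0, "left": 1, "right": 2}
HANDEDNESS_LABELS = {v: k for k, v in HANDEDNESS_CODES.items()}

STATUS_ACTIVE = 0
STATUS_STRANDED = 1
STATUS_EXITED = 2
STATUS_LABELS = {STATUS_ACTIVE: "active", STATUS_STRANDED: "stranded", STATUS_EXITED: "exited"}


@dataclass(eq=False)
class Particle:
    """Single-colony view of a :class:`Population` row."""

    id: int
    lon: float
    lat: float
    handedness: str
    status: str
    strand_time: Optional[np.datetime64] = None
    strand_segment: Optional[str] = None


@dataclass(eq=False)
class Population:
    """Array-backed colony population.

    Columns are parallel numpy arrays indexed by contiguous particle id;
    ``provenance`` records the creation parameters needed to regenerate the
    population bit-identically.
    """

    lon: np.ndarray
    lat: np.ndarray
    handedness: np.ndarray            # int8 codes, see HANDEDNESS_CODES
    status: np.ndarray                # int8 codes, see STATUS_LABELS
    strand_time: np.ndarray           # datetime64[s], NaT until stranded
    strand_segment: np.ndarray        # object (str or None)
    clamped: np.ndarray               # bool; backward-mode boundary clamping
    rng_seed: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.lon.size
        for name in ("lat", "handedness", "status", "strand_time", "strand_segment", "clamped"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name} has inconsistent length")

    @property
    def n(self) -> int:
        return int(self.lon.size)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n)

    def status_counts(self) -> dict:
        return {label: int(np.sum(self.status == code)) for code, label in STATUS_LABELS.items()}

    @property
    def particles(self) -> list[Particle]:
        out = []
        for i in range(self.n):
            st = self.strand_time[i]
            out.append(Particle(
                id=i, lon=float(self.lon[i]), lat=float(self.lat[i]),
                handedness=HANDEDNESS_LABELS[int(self.handedness[i])],
                status=STATUS_LABELS[int(self.status[i])],
                strand_time=None if np.isnat(st) else st,
                strand_segment=self.strand_segment[i],
            ))
        return out

    def copy(self) -> "Population":
        return Population(self.lon.copy(), self.lat.copy(), self.handedness.copy(),
                          self.status.copy(), self.strand_time.copy(),
                          self.strand_segment.copy(), self.clamped.copy(),
                          self.rng_seed, dict(self.provenance))

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "lon": self.lon,
            "lat": self.lat,
            "handedness": [HANDEDNESS_LABELS[int(h)] for h in self.handedness],
            "status": [STATUS_LABELS[int(s)] for s in self.status],
            "strand_time": self.strand_time,
            "strand_segment": [s if s is not None else "" for s in self.strand_segment],
        })

    def save(self, csv_path, sidecar_path=None):
        self.to_frame().to_csv(csv_path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                yaml.safe_dump({"rng_seed": self.rng_seed,
                                "provenance": _yaml_safe(self.provenance)}, fh)

    @classmethod
    def load(cls, csv_path, sidecar_path=None) -> "Population":
        df = pd.read_csv(csv_path, keep_default_na=False, na_values=[])
        n = len(df)
        strand_time = np.full(n, np.datetime64("NaT"), dtype="datetime64[s]")
        raw = df["strand_time"].astype(str).values
        for i, s in enumerate(raw):
            if s and s not in ("NaT", "nan"):
                strand_time[i] = np.datetime64(s[:19], "s")
        seed, prov = 0, {}
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                meta = yaml.safe_load(fh)
            seed = int(meta.get("rng_seed", 0))
            prov = meta.get("provenance", {})
        return cls(
            lon=df["lon"].to_numpy(float), lat=df["lat"].to_numpy(float),
            handedness=np.asarray([HANDEDNESS_CODES[h] for h in df["handedness"]], np.int8),
            status=np.asarray([{v: k for k, v in STATUS_LABELS.items()}[s] for s in df["status"]], np.int8),
            strand_time=strand_time,
            strand_segment=np.asarray([s if s else None for s in df["strand_segment"].astype(str)], object),
            clamped=np.zeros(n, bool), rng_seed=seed, provenance=prov,
        )


def _yaml_safe(d):
    return json_roundtrip(d)


def json_roundtrip(d):
    import json
    return json.loads(json.dumps(d, default=str))


def population_from_positions(lons, lats, handedness="none", rng_seed=0, provenance=None) -> Population:
    """Build an all-active population at explicit positions.

    ``handedness`` may be a single label or a per-particle sequence.
    """
    lons = np.atleast_1d(np.asarray(lons, float)).copy()
    lats = np.atleast_1d(np.asarray(lats, float)).copy()
    n = lons.size
    if isinstance(handedness, str):
        hand = np.full(n, HANDEDNESS_CODES[handedness], np.int8)
    else:
        hand = np.asarray([HANDEDNESS_CODES[h] if isinstance(h, str) else h for h in handedness], np.int8)
    return Population(
        lon=lons, lat=lats, handedness=hand,
        status=np.zeros(n, np.int8),
        strand_time=np.full(n, np.datetime64("NaT"), "datetime64[s]"),
        strand_segment=np.full(n, None, object),
        clamped=np.zeros(n, bool),
        rng_seed=rng_seed,
        provenance=provenance or {"method": "explicit_positions", "n": int(n)},
    )


def _handedness_counts(n: int, mix: dict) -> dict:
    """Exact per-label counts from fractions, largest-remainder rounding."""
    labels = [k for k in ("none", "left", "right") if mix.get(k, 0.0) > 0]
    raw = {k: n * mix[k] for k in labels}
    counts = {k: int(np.floor(raw[k])) for k in labels}
    short = n - sum(counts.values())
    for k in sorted(labels, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def seed_depth_band(scenario: DomainScenario, depth_min: float, depth_max: float,
                    n: int, handedness_mix: Optional[dict] = None, rng_seed: int = 0,
                    bbox: Optional[tuple] = None) -> Population:
    """Seed ``n`` active colonies uniformly over the area of a depth band.

    Positions are accepted when the nearest grid node is ocean and the
    bilinearly interpolated depth lies in ``[depth_min, depth_max]``.
    ``bbox = (lon_min, lon_max, lat_min, lat_max)`` optionally restricts the
    seeded region (default: the whole domain).  Handedness labels are
    assigned in exact proportion to ``handedness_mix`` (default all
    ``none``) and shuffled by the seeded RNG.
    """
    if not (0 < depth_min < depth_max):
        raise ValueError("require 0 < depth_min < depth_max")
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(handedness_mix) if handedness_mix else {"none": 1.0}
    unknown = set(mix) - set(HANDEDNESS_CODES)
    if unknown:
        raise ValueError(f"unknown handedness labels: {sorted(unknown)}")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("handedness fractions must sum to 1 (tolerance 1e-9)")

    g = scenario.grid
    if bbox is None:
        bbox = (g.lon_min, g.lon_max, g.lat_min, g.lat_max)
    lon_lo, lon_hi, lat_lo, lat_hi = bbox

    # feasibility check on the grid itself before burning rejection draws
    in_box = ((g.lons[None, :] >= lon_lo) & (g.lons[None, :] <= lon_hi)
              & (g.lats[:, None] >= lat_lo) & (g.lats[:, None] <= lat_hi))
    band = (~scenario.land_mask) & in_box & (scenario.bathymetry >= depth_min) & (scenario.bathymetry <= depth_max)
    if not band.any():
        raise ValueError("no ocean area inside the requested depth band")

    rng = np.random.default_rng(rng_seed)
    cos_ref = np.cos(np.radians(min(abs(lat_lo), abs(lat_hi)) if lat_lo * lat_hi > 0 else 0.0))
    lon_out = np.empty(n)
    lat_out = np.empty(n)
    got = 0
    attempts = 0
    while got < n:
        m = max(4 * (n - got), 1024)
        attempts += m
        if attempts > max(2_000_000, 2000 * n):
            raise ValueError("depth-band rejection sampling failed to converge")
        lo = rng.uniform(lon_lo, lon_hi, m)
        la = rng.uniform(lat_lo, lat_hi, m)
        u = rng.uniform(0.0, 1.0, m)
        depth = scenario.depth_at(lo, la)
        ok = ((~scenario.is_land(lo, la))
              & (depth >= depth_min) & (depth <= depth_max)
              & (u < np.cos(np.radians(la)) / cos_ref))
        k = min(int(ok.sum()), n - got)
        lon_out[got:got + k] = lo[ok][:k]
        lat_out[got:got + k] = la[ok][:k]
        got += k

    counts = _handedness_counts(n, mix)
    hand = np.concatenate([np.full(c, HANDEDNESS_CODES[k], np.int8) for k, c in counts.items()])
    hand = hand[rng.permutation(n)]

    prov = {"method": "seed_depth_band", "depth_min": depth_min, "depth_max": depth_max,
            "n": int(n), "handedness_mix": mix, "rng_seed": int(rng_seed),
            "bbox": [float(b) for b in bbox], "scenario": dict(scenario.provenance)}
    pop = population_from_positions(lon_out, lat_out, rng_seed=rng_seed, provenance=prov)
    pop.handedness = hand
    return pop
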