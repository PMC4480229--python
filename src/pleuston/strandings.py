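"""Beach-level stranding statistics and simulated-vs-observed comparison.

Stranding events are aggregated per beach segment, converted to cumulative
densities in colonies per 100 m of coastline, and compared between
simulation and observation by rank statistics: the headline similarity
measure is the Spearman correlation of per-beach densities (magnitudes are
deliberately de-emphasised, since sparsely resampled beaches make absolute
counts unreliable), complemented by a log-density RMS difference and the
west-to-east first-arrival concordance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .drift import StrandingRecord
from .environment import BeachSegment, DomainScenario, nearest_segment, point_to_segment_distance_m

UNASSIGNED = "unassigned"


@dataclass(eq=False)
class StrandingDensityTable:
    """Per-beach counts, densities and first arrivals, ordered west to east.

    ``table`` columns: beach_id, lon (segment minimum longitude), length_m,
    count, density_per_100m, first_arrival.
    """

    table: pd.DataFrame
    unassigned: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def beach_ids(self) -> list[str]:
        return list(self.table["beach_id"])

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def assign_to_beach(record: StrandingRecord, beaches: Sequence[BeachSegment],
                    max_dist_m: Optional[float] = None) -> str:
    """Beach id of the segment nearest the record's coordinates.

    Ties are broken by the lower id.  With ``max_dist_m`` set, records whose
    nearest segment is farther away are flagged ``unassigned`` (kept and
    reported rather than dropped).
    """
    seg, dist = nearest_segment(record.lon, record.lat, beaches)
    if max_dist_m is not None and dist > max_dist_m:
        return UNASSIGNED
    return seg.id


def count_per_beach(records: Sequence[StrandingRecord], beaches: Sequence[BeachSegment],
                    scenario: Optional[DomainScenario] = None,
                    max_dist_cells: float = 2.0) -> tuple[dict, dict, int]:
    """Aggregate records into per-beach counts and first-arrival times.

    Records already carrying a segment id are trusted; others are assigned
    by nearest distance with a threshold of ``max_dist_cells`` grid cells
    (requires ``scenario``).  Returns (counts, first_arrival, n_unassigned).
    """
    counts = {b.id: 0 for b in beaches}
    first = {b.id: None for b in beaches}
    unassigned = 0
    max_dist_m = None
    if scenario is not None:
        max_dist_m = max_dist_cells * scenario.grid.cell_size_m()
    for r in records:
        bid = r.segment_id if r.segment_id in counts else assign_to_beach(r, beaches, max_dist_m)
        if bid == UNASSIGNED or bid not in counts:
            unassigned += 1
            continue
        counts[bid] += 1
        if first[bid] is None or r.time < first[bid]:
            first[bid] = r.time
    return counts, first, unassigned


def density_per_100m(counts: dict, beaches: Sequence[BeachSegment],
                     first_arrival: Optional[dict] = None,
                     unassigned: int = 0) -> StrandingDensityTable:
    """Cumulative density table: density = 100 * count / length per beach.

    Zero-count beaches are included with density 0; beaches are ordered
    west to east (by segment minimum longitude, ties south to north).
    """
    rows = []
    first_arrival = first_arrival or {}
    by_id = {b.id: b for b in beaches}
    for bid, c in counts.items():
        if c < 0:
            raise ValueError(f"negative stranding count for beach {bid}")
        if bid not in by_id:
            raise KeyError(f"counted beach {bid!r} not in the beach list")
    for b in beaches:
        c = int(counts.get(b.id, 0))
        rows.append({
            "beach_id": b.id,
            "lon": b.min_lon,
            "lat": float(b.vertices[:, 1].min()),
            "length_m": b.length_m,
            "count": c,
            "density_per_100m": 100.0 * c / b.length_m,
            "first_arrival": first_arrival.get(b.id),
        })
    df = pd.DataFrame(rows).sort_values(["lon", "lat"], kind="mergesort").reset_index(drop=True)
    return StrandingDensityTable(df, unassigned=unassigned)


def read_observed_strandings(path) -> pd.DataFrame:
    """Read an observed-stranding ledger: beach_id,date,count,mean_size_cm."""
    df = pd.read_csv(path, dtype={"beach_id": str})
    if (df["count"] < 0).any():
        raise ValueError("observed stranding counts must be non-negative")
    df["date"] = pd.to_datetime(df["date"])
    return df


def observed_density(observed: pd.DataFrame, beaches: Sequence[BeachSegment],
                     window: Optional[tuple] = None) -> StrandingDensityTable:
    """Cumulative observed density per beach over an analysis window.

    Repeated survey dates per beach are summed ("cumulative density"); the
    first arrival is the earliest date with a positive count.
    """
    df = observed
    if window is not None:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        df = df[(df["date"] >= lo) & (df["date"] <= hi)]
    counts = df.groupby("beach_id")["count"].sum().to_dict()
    pos = df[df["count"] > 0]
    first = pos.groupby("beach_id")["date"].min().to_dict()
    known = {b.id for b in beaches}
    unknown = set(counts) - known
    if unknown:
        raise KeyError(f"observed beach ids not in the scenario: {sorted(unknown)}")
    return density_per_100m({b.id: int(counts.get(b.id, 0)) for b in beaches},
                            beaches, first_arrival=first)


def _arrival_concordance(df: pd.DataFrame) -> float:
    """Spearman correlation of beach longitude rank vs first-arrival rank."""
    sub = df[df["first_arrival"].notna() & (df["count"] > 0)]
    if len(sub) < 3:
        return float("nan")
    rho, _ = stats.spearmanr(sub["lon"], pd.to_datetime(sub["first_arrival"]).astype("int64"))
    return float(rho)


def compare_patterns(sim: StrandingDensityTable, obs: StrandingDensityTable) -> dict:
    """Compare simulated and observed beaching patterns.

    Tables are outer-joined on beach id (missing beaches count zero).
    Returns Spearman rank correlation of densities, the RMS difference of
    log10 densities over beaches where both are nonzero, and the
    west-to-east first-arrival concordance of each table.
    """
    s = sim.table.set_index("beach_id")
    o = obs.table.set_index("beach_id")
    ids = sorted(set(s.index) | set(o.index))
    if len(ids) < 3:
        raise ValueError("need at least 3 shared beaches for a rank correlation")
    ds = s["density_per_100m"].reindex(ids).fillna(0.0)
    do = o["density_per_100m"].reindex(ids).fillna(0.0)
    rho, _ = stats.spearmanr(ds.values, do.values)
    both = (ds > 0) & (do > 0)
    if both.any():
        log_rms = float(np.sqrt(np.mean((np.log10(ds[both]) - np.log10(do[both])) ** 2)))
    else:
        log_rms = float("nan")
    return {
        "n_beaches": len(ids),
        "n_both_nonzero": int(both.sum()),
        "spearman_density": float(rho),
        "log10_density_rms": log_rms,
        "arrival_concordance_sim": _arrival_concordance(sim.table),
        "arrival_concordance_obs": _arrival_concordance(obs.table),
    }


def records_to_frame(records: Sequence[StrandingRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "particle_id": r.particle_id, "time": r.time,
        "lon": r.lon, "lat": r.lat, "segment_id": r.segment_id,
    } for r in records], columns=["particle_id", "time", "lon", "lat", "segment_id"])


def plot_density_comparison(sim: StrandingDensityTable, obs: Optional[StrandingDensityTable] = None,
                            path=None):
    """Bar chart of per-beach densities, west to east (optionally vs observed)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    x = np.arange(len(sim.table))
    w = 0.4 if obs is not None else 0.8
    ax.bar(x - (w / 2 if obs is not None else 0), sim.table["density_per_100m"], w, label="simulated")
    if obs is not None:
        o = obs.table.set_index("beach_id").reindex(sim.table["beach_id"]).fillna(0.0)
        ax.bar(x + w / 2, o["density_per_100m"], w, label="observed")
    ax.set_xticks(x, sim.table["beach_id"], rotation=90, fontsize=6)
    ax.set_ylabel("colonies per 100 m")
    ax.set_xlabel("beach (west to east)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
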