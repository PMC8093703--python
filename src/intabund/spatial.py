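"""From raw geo-referenced sighting tables to model-ready inputs.

Sightings of the target population arrive as delimited text with
coordinates, counts and a source label (citizen-science survey responses,
ad-hoc public reports, or expert checks).  Because neighbours can report
the same individuals, records are clustered into sites: two records belong
to the same site whenever they are connected by a chain of pairwise
distances at or below the clustering radius (single linkage — the default
500 m radius corresponds to a circular home range of roughly 20 ha).
Within each site, citizen-science records become replicate counts and
expert records are pooled into the expert count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "SightingRecord",
    "ClusteredSites",
    "ModelInputs",
    "haversine_m",
    "cluster_sightings",
    "recode_survey_choice",
    "build_model_inputs",
    "records_from_frame",
]

EARTH_RADIUS_M = 6_371_000.0

CS_SOURCES = frozenset({"survey", "report"})
SOURCES = CS_SOURCES | {"expert"}


@dataclass(frozen=True)
class SightingRecord:
    """One geo-referenced sighting (or expert absence check).

    Coordinates are either geographic (``lon``/``lat`` in decimal degrees)
    or planar (``x``/``y`` in meters) — exactly one pair must be given.
    ``expert_absent`` marks an expert record stating the target was *not*
    present, which carries real information (a confirmed empty site).
    """

    record_id: object
    count: float
    source: str
    lon: float | None = None
    lat: float | None = None
    x: float | None = None
    y: float | None = None
    expert_absent: bool = False

    def __post_init__(self) -> None:
        geo = self.lon is not None and self.lat is not None
        planar = self.x is not None and self.y is not None
        if geo == planar:
            raise ValueError(
                f"record {self.record_id}: give either lon/lat or x/y"
            )
        coords = (self.lon, self.lat) if geo else (self.x, self.y)
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"record {self.record_id}: non-finite coordinates")
        if self.source not in SOURCES:
            raise ValueError(
                f"record {self.record_id}: source must be one of {sorted(SOURCES)}"
            )
        if self.count < 0:
            raise ValueError(f"record {self.record_id}: negative count")
        if self.expert_absent:
            if self.source != "expert":
                raise ValueError("expert_absent only applies to expert records")
            if self.count != 0:
                raise ValueError("an absence record must have count 0")

    @property
    def is_geographic(self) -> bool:
        return self.lon is not None


@dataclass(frozen=True)
class ClusteredSites:
    """A partition of sighting records into sites."""

    records: tuple[SightingRecord, ...]
    labels: np.ndarray  # cluster index per record
    radius: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.records) else 0

    def members(self, cluster: int) -> list[SightingRecord]:
        return [r for r, l in zip(self.records, self.labels) if l == cluster]

    def partition(self) -> frozenset[frozenset]:
        """Order-free view of the clustering, for comparisons."""
        groups: dict[int, set] = {}
        for rec, lab in zip(self.records, self.labels):
            groups.setdefault(int(lab), set()).add(rec.record_id)
        return frozenset(frozenset(g) for g in groups.values())


@dataclass(frozen=True)
class ModelInputs:
    """Site-by-replicate counts plus expert vector, ready for fitting."""

    y: np.ndarray  # (n_sites, max_replicates) float, NaN = missing
    w: np.ndarray  # (n_sites,) float
    expert_mask: np.ndarray  # (n_sites,) bool
    cluster_ids: np.ndarray  # original cluster index per retained site
    dropped_clusters: tuple[int, ...]


def haversine_m(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in meters between decimal-degree points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def _pairwise_distances(records: list[SightingRecord]) -> np.ndarray:
    geo = {r.is_geographic for r in records}
    if len(geo) > 1:
        raise ValueError("mixed geographic and planar coordinates in one input")
    if geo.pop():
        lon = np.radians([r.lon for r in records])
        lat = np.radians([r.lat for r in records])
        pts = np.column_stack([lon, lat])

        def hav(u, v):
            a = (math.sin((v[1] - u[1]) / 2) ** 2
                 + math.cos(u[1]) * math.cos(v[1])
                 * math.sin((v[0] - u[0]) / 2) ** 2)
            return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))

        return squareform(pdist(pts, metric=hav))
    pts = np.array([[r.x, r.y] for r in records])
    return squareform(pdist(pts))


def cluster_sightings(
    records, radius: float = 500.0
) -> ClusteredSites:
    """Single-linkage clustering at a distance threshold.

    Connected components of the graph joining every pair of records within
    ``radius`` meters; great-circle distance for lon/lat records, Euclidean
    for planar ones.  Cluster labels are canonicalized by each cluster's
    smallest record id, so the partition (and labelling) is invariant to
    record order.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to cluster")
    if radius <= 0:
        raise ValueError("radius must be positive")
    dist = _pairwise_distances(records)
    adj = csr_matrix(dist <= radius)
    _, raw_labels = connected_components(adj, directed=False)
    order = {}
    for lab in raw_labels:
        key = min(str(r.record_id) for r, l in zip(records, raw_labels) if l == lab)
        order[lab] = key
    remap = {
        lab: rank
        for rank, lab in enumerate(sorted(order, key=order.__getitem__))
    }
    labels = np.array([remap[l] for l in raw_labels], dtype=np.int64)
    return ClusteredSites(records=tuple(records), labels=labels, radius=radius)


_CHOICE_MAP = {
    "none": 0.0,
    "1-2": 1.5,
    "3-4": 3.5,
    "5-9": 7.0,
    "10 or more": 15.0,
    "10, or more": 15.0,
    "10+": 15.0,
}


def recode_survey_choice(choice: str) -> float:
    """Numeric count for a multiple-choice survey response.

    The central value of each range; ten-or-more maps to 15 (the average of
    reports that specified a number at or above ten).
    """
    key = str(choice).strip().lower().replace("–", "-").replace("—", "-")
    try:
        return _CHOICE_MAP[key]
    except KeyError:
        raise ValueError(f"unknown survey choice {choice!r}") from None


def round_half_up(x) -> np.ndarray:
    """Integerize recoded counts (1.5 -> 2) for the count likelihood."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def build_model_inputs(clusters: ClusteredSites) -> ModelInputs:
    """Assemble the site x replicate matrix and expert vector from clusters.

    Each citizen-science record is one replicate; rows are padded with NaN
    so unequal replicate counts stay missing data rather than zeros.
    Expert counts within a cluster are summed; an expert absence check sets
    the expert count to zero with the mask on.  Clusters containing no
    citizen-science record at all are dropped with a warning — they carry
    no observation layer to fit.
    """
    if not clusters.records:
        raise ValueError("empty clustering")
    n = clusters.n_clusters
    cs_counts: list[list[float]] = [[] for _ in range(n)]
    w = np.zeros(n)
    has_expert = np.zeros(n, dtype=bool)
    for rec, lab in zip(clusters.records, clusters.labels):
        if rec.source in CS_SOURCES:
            cs_counts[lab].append(rec.count)
        else:
            has_expert[lab] = True
            w[lab] += rec.count
    keep = [i for i in range(n) if cs_counts[i]]
    dropped = tuple(i for i in range(n) if not cs_counts[i])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} cluster(s) with no citizen-science "
            f"records: {dropped}",
            stacklevel=2,
        )
    if not keep:
        raise ValueError("no cluster has citizen-science records")
    max_rep = max(len(cs_counts[i]) for i in keep)
    y = np.full((len(keep), max_rep), np.nan)
    for row, i in enumerate(keep):
        vals = round_half_up(cs_counts[i])
        y[row, : len(vals)] = vals
    return ModelInputs(
        y=y,
        w=round_half_up(w[keep]).astype(float),
        expert_mask=has_expert[keep],
        cluster_ids=np.array(keep, dtype=np.int64),
        dropped_clusters=dropped,
    )


def records_from_frame(df: pd.DataFrame) -> list[SightingRecord]:
    """Build records from a table with columns id, lon/lat (or x/y), count,
    source and optionally expert_absent."""
    cols = {c.lower(): c for c in df.columns}
    geo = "lon" in cols and "lat" in cols
    planar = "x" in cols and "y" in cols
    if geo == planar:
        raise ValueError("table must have either lon/lat or x/y columns")
    records = []
    for _, row in df.iterrows():
        kwargs = dict(
            record_id=row[cols["id"]],
            count=float(row[cols["count"]]),
            source=str(row[cols["source"]]).strip().lower(),
            expert_absent=bool(row[cols["expert_absent"]])
            if "expert_absent" in cols
            else False,
        )
        if geo:
            kwargs.update(lon=float(row[cols["lon"]]), lat=float(row[cols["lat"]]))
        else:
            kwargs.update(x=float(row[cols["x"]]), y=float(row[cols["y"]]))
        records.append(SightingRecord(**kwargs))
    return records
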