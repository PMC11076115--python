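"""Reading and cleaning occurrence tables.

Input tables use Darwin-Core-style column names (``decimalLatitude``,
``decimalLongitude``) plus ``category`` and ``role``. Cleaning removes
the classic presence-data artefacts of aggregated occurrence databases:
records at exactly (0, 0), out-of-range coordinates, and records near
user-supplied exclusion points (capital cities, country centroids,
museum/institution coordinates — whatever list the analyst provides).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .gridding import GeoPoint, OccurrenceRecord, Role, ValidationError, haversine_km

REQUIRED_COLUMNS = ("category", "role", "decimalLatitude", "decimalLongitude")

#: Records with |lat| and |lon| both below this are treated as the (0, 0)
#: database artefact. Exact-zero detection is the intent; the tolerance only
#: absorbs float formatting noise.
ZERO_TOLERANCE_DEG = 1e-9


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass
class CleaningReport:
    """Bookkeeping for one cleaning pass; counts always reconcile."""

    n_input: int = 0
    n_removed_zeros: int = 0
    n_removed_range: int = 0
    n_removed_excluded: int = 0
    n_output: int = 0

    def __post_init__(self) -> None:
        removed = self.n_removed_zeros + self.n_removed_range + self.n_removed_excluded
        if self.n_output != self.n_input - removed or min(dataclasses.astuple(self)) < 0:
            raise ValidationError(f"inconsistent cleaning report: {self}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def read_occurrences(path, role_filter: Optional[Role] = None) -> List[OccurrenceRecord]:
    """Read an occurrence CSV into records.

    Rows whose coordinates do not parse as finite numbers are dropped
    silently (they are counted by a subsequent :func:`clean_coordinates`
    pass only if they parse; unparseable rows never become records).
    Out-of-range coordinates are *kept* here as raw rows for the cleaner
    to count — but since ``OccurrenceRecord`` construction validates
    ranges, such rows are also dropped at read time and reported by the
    returned list simply being shorter.
    """
    df = pd.read_csv(path, dtype={"category": str, "role": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence file {path} is missing required column(s): {missing}")

    records: List[OccurrenceRecord] = []
    lats = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    lons = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    sources = df["source"] if "source" in df.columns else None
    for i in range(len(df)):
        lat, lon = lats.iloc[i], lons.iloc[i]
        if pd.isna(lat) or pd.isna(lon):
            continue
        role_str = str(df["role"].iloc[i]).strip().lower()
        try:
            role = Role(role_str)
        except ValueError:
            continue
        if role_filter is not None and role != role_filter:
            continue
        try:
            point = GeoPoint(float(lat), float(lon))
        except ValidationError:
            continue
        src = "" if sources is None or pd.isna(sources.iloc[i]) else str(sources.iloc[i])
        records.append(
            OccurrenceRecord(category=str(df["category"].iloc[i]), role=role, point=point, source=src)
        )
    return records


def read_exclusion_points(path) -> List[GeoPoint]:
    """Read an exclusion-point CSV with columns ``lat``, ``lon`` (optional ``label``)."""
    df = pd.read_csv(path)
    for col in ("lat", "lon"):
        if col not in df.columns:
            raise SchemaError(f"exclusion file {path} is missing required column: {col}")
    return [GeoPoint(float(r.lat), float(r.lon)) for r in df.itertuples()]


def clean_coordinates(
    records: Sequence[OccurrenceRecord],
    exclusion_points: Sequence[GeoPoint] = (),
    exclusion_radius_km: float = 0.0,
    zero_tolerance_deg: float = ZERO_TOLERANCE_DEG,
) -> Tuple[List[OccurrenceRecord], CleaningReport]:
    """Remove artefactual records; order-preserving for survivors.

    Three filters, applied in order per record: the zeros test (both
    coordinates within ``zero_tolerance_deg`` of 0), the range test
    (redundant for records built through :class:`GeoPoint`, but kept so
    externally constructed records are still screened), and the
    exclusion-list test (within ``exclusion_radius_km`` of any supplied
    point). Removals are counted, never raised. Idempotent.
    """
    if exclusion_radius_km < 0:
        raise ValidationError("exclusion_radius_km must be >= 0")
    kept: List[OccurrenceRecord] = []
    n_zeros = n_range = n_excluded = 0
    for rec in records:
        p = rec.point
        if abs(p.lat) < zero_tolerance_deg and abs(p.lon) < zero_tolerance_deg:
            n_zeros += 1
            continue
        if not (-90.0 <= p.lat <= 90.0) or not (-180.0 <= p.lon < 180.0):
            n_range += 1
            continue
        if exclusion_points and any(
            haversine_km(p, q) <= exclusion_radius_km for q in exclusion_points
        ):
            n_excluded += 1
            continue
        kept.append(rec)
    report = CleaningReport(
        n_input=len(records),
        n_removed_zeros=n_zeros,
        n_removed_range=n_range,
        n_removed_excluded=n_excluded,
        n_output=len(kept),
    )
    return kept, report
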