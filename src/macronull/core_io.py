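"""Domain types, incidence-matrix construction and CSV I/O.

The substrate of every analysis in this package is a binary species x
latitudinal-band incidence matrix built over a bounded one-degree
discretization of a latitudinal domain (by default 18-56 degrees S, the
hard geometric limits of continental Chile's freshwater systems).
Latitudes are stored internally as degrees-South magnitudes (positive
numbers increasing poleward); CSV files may instead carry signed decimal
degrees (negative = south) and are converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BandDomain",
    "OccurrenceRecord",
    "RangeEntry",
    "IncidenceMatrix",
    "ranges_to_incidence",
    "records_to_incidence",
    "derive_ranges",
    "pack_matrix",
    "richness_per_band",
    "read_ranges_csv",
    "write_ranges_csv",
    "read_records_csv",
    "write_records_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_covariates_csv",
]


@dataclass(frozen=True)
class BandDomain:
    """Bounded 1-degree-band discretization of a latitudinal gradient.

    Band ``k`` covers the half-open interval ``[k, k+1)`` degrees S for
    ``k`` in ``north_limit .. south_limit - 1``; a latitude exactly at
    ``south_limit`` is clamped into the last band so the domain has
    exactly ``south_limit - north_limit`` bands (38 for 18-56 S).
    """

    north_limit: int = 18
    south_limit: int = 56

    def __post_init__(self) -> None:
        if not self.north_limit < self.south_limit:
            raise ValueError(
                f"north_limit ({self.north_limit}) must be < south_limit "
                f"({self.south_limit})"
            )

    @property
    def n_bands(self) -> int:
        return self.south_limit - self.north_limit

    @property
    def width(self) -> int:
        """Domain width in degrees (equals band count at 1-degree bands)."""
        return self.n_bands

    @property
    def band_labels(self) -> np.ndarray:
        """Northern edge of each band, degrees S ascending."""
        return np.arange(self.north_limit, self.south_limit)

    def contains(self, lat: float) -> bool:
        return self.north_limit <= lat <= self.south_limit

    def band_index(self, lat: float) -> int:
        """Index of the band containing latitude ``lat`` (degrees S)."""
        if not self.contains(lat):
            raise ValueError(
                f"latitude {lat} outside domain "
                f"[{self.north_limit}, {self.south_limit}] S"
            )
        return min(int(np.floor(lat)), self.south_limit - 1) - self.north_limit


@dataclass(frozen=True)
class OccurrenceRecord:
    """A single georeferenced record: species label + latitude (deg S)."""

    species: str
    latitude: float


@dataclass(frozen=True)
class RangeEntry:
    """One species' latitudinal extent, degrees S magnitudes."""

    species: str
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if self.lat_min > self.lat_max:
            raise ValueError(
                f"{self.species}: lat_min ({self.lat_min}) > lat_max "
                f"({self.lat_max})"
            )

    @property
    def midpoint(self) -> float:
        return (self.lat_min + self.lat_max) / 2.0

    @property
    def extent(self) -> float:
        return self.lat_max - self.lat_min


@dataclass
class IncidenceMatrix:
    """Binary species x band matrix with row (species) and column labels."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("incidence matrix must be 2-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("incidence matrix entries must be 0/1")
        if len(self.row_labels) != self.values.shape[0]:
            raise ValueError("row_labels length mismatch")
        if self.col_labels is None:
            self.col_labels = np.arange(self.values.shape[1])
        self.col_labels = np.asarray(self.col_labels)
        if len(self.col_labels) != self.values.shape[1]:
            raise ValueError("col_labels length mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    @property
    def fill(self) -> float:
        """Proportion of 1s."""
        return float(self.values.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def copy(self) -> "IncidenceMatrix":
        return IncidenceMatrix(
            self.values.copy(), list(self.row_labels), self.col_labels.copy()
        )


def _band_span(entry: RangeEntry, domain: BandDomain) -> tuple[int, int]:
    """Inclusive (first, last) band index covered by a closed range."""
    if entry.lat_min < domain.north_limit or entry.lat_max > domain.south_limit:
        raise ValueError(
            f"range for species {entry.species!r} "
            f"[{entry.lat_min}, {entry.lat_max}] lies outside domain "
            f"[{domain.north_limit}, {domain.south_limit}] S"
        )
    first = domain.band_index(entry.lat_min)
    last = domain.band_index(entry.lat_max)
    return first, last


def ranges_to_incidence(
    ranges: list[RangeEntry], domain: BandDomain
) -> IncidenceMatrix:
    """Interval-fill construction: species s occupies band k iff [k, k+1)
    intersects its closed latitudinal range.

    A range endpoint exactly at the south limit is clamped into the last
    band; point ranges occupy exactly one band.  Every row therefore is a
    contiguous run of 1s with at least one presence.
    """
    if not ranges:
        raise ValueError("no ranges given")
    values = np.zeros((len(ranges), domain.n_bands), dtype=np.int8)
    for i, entry in enumerate(ranges):
        first, last = _band_span(entry, domain)
        values[i, first : last + 1] = 1
    return IncidenceMatrix(values, [r.species for r in ranges], domain.band_labels)


def derive_ranges(records: list[OccurrenceRecord]) -> list[RangeEntry]:
    """Per-species min/max latitude over records, in first-seen order."""
    if not records:
        raise ValueError("no records given")
    order: list[str] = []
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    for rec in records:
        if rec.species not in lo:
            order.append(rec.species)
            lo[rec.species] = hi[rec.species] = rec.latitude
        else:
            lo[rec.species] = min(lo[rec.species], rec.latitude)
            hi[rec.species] = max(hi[rec.species], rec.latitude)
    return [RangeEntry(s, lo[s], hi[s]) for s in order]


def records_to_incidence(
    records: list[OccurrenceRecord], domain: BandDomain, fill: bool = True
) -> IncidenceMatrix:
    """Build an incidence matrix from raw occurrence records.

    With ``fill=True`` (default) per-species min/max latitudes are derived
    first and the interval is filled, matching :func:`ranges_to_incidence`;
    with ``fill=False`` only bands actually containing a record are marked.
    """
    if fill:
        return ranges_to_incidence(derive_ranges(records), domain)
    if not records:
        raise ValueError("no records given")
    order: list[str] = []
    idx: dict[str, int] = {}
    for rec in records:
        if rec.species not in idx:
            idx[rec.species] = len(order)
            order.append(rec.species)
    values = np.zeros((len(order), domain.n_bands), dtype=np.int8)
    for rec in records:
        values[idx[rec.species], domain.band_index(rec.latitude)] = 1
    return IncidenceMatrix(values, order, domain.band_labels)


def pack_matrix(m: IncidenceMatrix) -> IncidenceMatrix:
    """Sort rows and columns by decreasing totals (stable in original order).

    Common species end up on the top rows and the species-richest bands on
    the left-hand columns, the standard packing before nestedness scoring.
    """
    row_order = np.argsort(-m.row_sums, kind="stable")
    col_order = np.argsort(-m.col_sums, kind="stable")
    values = m.values[np.ix_(row_order, col_order)]
    return IncidenceMatrix(
        values,
        [m.row_labels[i] for i in row_order],
        m.col_labels[col_order],
    )


def richness_per_band(m: IncidenceMatrix) -> np.ndarray:
    """Species richness per band (column sums, band order)."""
    return m.col_sums.astype(int)


# ---------------------------------------------------------------------------
# CSV I/O.  All readers accept a path or file-like object; the latitude
# convention flag ``signed`` converts negative-south signed degrees to the
# internal degrees-S magnitude.
# ---------------------------------------------------------------------------


def _read_csv(path_or_buf, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"CSV missing required column(s): {', '.join(missing)}")
    bad = df[list(required)].isna().any(axis=1)
    if bad.any():
        lines = ", ".join(str(i + 2) for i in df.index[bad])  # +2: header + 1-based
        raise ValueError(f"malformed CSV rows (missing values) at line(s): {lines}")
    return df


def _to_south(series: pd.Series, signed: bool) -> pd.Series:
    return -series if signed else series


def read_ranges_csv(path_or_buf, signed: bool = False) -> list[RangeEntry]:
    """Read a species range table with columns species,lat_min,lat_max."""
    df = _read_csv(path_or_buf, ("species", "lat_min", "lat_max"))
    lo = _to_south(df["lat_min"].astype(float), signed)
    hi = _to_south(df["lat_max"].astype(float), signed)
    if signed:  # sign flip swaps the order
        lo, hi = hi.copy(), lo.copy()
        lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    return [
        RangeEntry(str(s), float(a), float(b))
        for s, a, b in zip(df["species"], lo, hi)
    ]


def write_ranges_csv(ranges: list[RangeEntry], path_or_buf) -> None:
    pd.DataFrame(
        {
            "species": [r.species for r in ranges],
            "lat_min": [r.lat_min for r in ranges],
            "lat_max": [r.lat_max for r in ranges],
        }
    ).to_csv(path_or_buf, index=False)


def read_records_csv(path_or_buf, signed: bool = False) -> list[OccurrenceRecord]:
    """Read an occurrence table with columns species,latitude."""
    df = _read_csv(path_or_buf, ("species", "latitude"))
    lat = _to_south(df["latitude"].astype(float), signed)
    return [OccurrenceRecord(str(s), float(v)) for s, v in zip(df["species"], lat)]


def write_records_csv(records: list[OccurrenceRecord], path_or_buf) -> None:
    pd.DataFrame(
        {
            "species": [r.species for r in records],
            "latitude": [r.latitude for r in records],
        }
    ).to_csv(path_or_buf, index=False)


def read_matrix_csv(path_or_buf) -> IncidenceMatrix:
    """Read an incidence matrix CSV (first column species, band columns)."""
    df = pd.read_csv(path_or_buf, index_col=0)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("matrix CSV contains non-binary entries")
    try:
        cols = df.columns.astype(int).to_numpy()
    except (TypeError, ValueError):
        cols = df.columns.to_numpy()
    return IncidenceMatrix(values, [str(s) for s in df.index], cols)


def write_matrix_csv(m: IncidenceMatrix, path_or_buf) -> None:
    m.to_frame().to_csv(path_or_buf, index_label="species")


def read_covariates_csv(
    path_or_buf, domain: BandDomain | None = None, band_col: str = "band"
) -> pd.DataFrame:
    """Read a per-band covariate table, indexed by band label.

    If ``domain`` is given the table must cover every band of the domain
    exactly once; a missing band is reported by label.
    """
    df = _read_csv(path_or_buf, (band_col,))
    df = df.set_index(band_col)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"covariate table has missing cells for band(s): {bad}")
    if domain is not None:
        missing = [b for b in domain.band_labels if b not in set(df.index)]
        if missing:
            raise ValueError(f"covariate table missing band(s): {missing}")
        df = df.loc[list(domain.band_labels)]
    return df


def matrix_from_string(text: str) -> IncidenceMatrix:
    """Convenience: parse a matrix CSV from an in-memory string."""
    return read_matrix_csv(io.StringIO(text))
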