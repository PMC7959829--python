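"""Vertex-wise cortical morphometry: reading, validation, parcel summaries.

The exchange format is a plain tab-separated vertex table with one row per
surface vertex and columns ``subject_id, hemisphere, vertex_index,
parcel_label, volume, area, thickness``.  Hemisphere is carried inside the
parcel label downstream (e.g. ``Vis(lh)``); nothing is merged across
hemispheres.  Parcels with fewer than ``min_vertices`` vertices (default
50) are excluded before any network is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from morphnet.errors import EmptyInputError, FormatError, ValidationError

MEASURES = ("volume", "area", "thickness")

REQUIRED_COLUMNS = (
    "subject_id",
    "hemisphere",
    "vertex_index",
    "parcel_label",
    "volume",
    "area",
    "thickness",
)

HEMISPHERES = ("lh", "rh")


@dataclass(frozen=True)
class Parcellation:
    """An ordered, fixed list of parcel labels defining matrix row order.

    Labels carry the hemisphere, e.g. ``"Vis(lh)"``.  The order recorded
    here is the row/column order of every downstream matrix.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("parcel labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class SubjectMorphometry:
    """Per-parcel multisets of vertex values for one subject.

    ``values[parcel][measure]`` is the 1-D array of that parcel's vertex
    values for the measure; arrays for the three measures of one parcel
    are index-aligned (same vertices, same order).
    """

    subject_id: str
    parcellation: Parcellation
    values: dict[str, dict[str, np.ndarray]] = field(repr=False, default_factory=dict)

    def vertex_count(self, parcel: str) -> int:
        return len(self.values[parcel]["volume"])

    @property
    def total_volume(self) -> float:
        return float(sum(v["volume"].sum() for v in self.values.values()))

    @property
    def total_area(self) -> float:
        return float(sum(v["area"].sum() for v in self.values.values()))

    @property
    def mean_thickness(self) -> float:
        """Unweighted mean over all retained vertices (not mean of parcel means)."""
        pooled = np.concatenate([v["thickness"] for v in self.values.values()])
        return float(pooled.mean())

    def global_summary(self, measure: str) -> float:
        """The whole-cortex covariate matched to a network measure."""
        if measure == "volume":
            return self.total_volume
        if measure == "area":
            return self.total_area
        if measure == "thickness":
            return self.mean_thickness
        raise ValueError(f"unknown measure {measure!r}")


def _validate_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: vertex table has no data rows")

    bad_hemi = ~df["hemisphere"].isin(HEMISPHERES)
    if bad_hemi.any():
        rows = (df.index[bad_hemi] + 2).tolist()[:5]
        raise ValidationError(
            f"{path}: hemisphere must be one of {HEMISPHERES}; offending file rows {rows}"
        )

    for col in MEASURES:
        vals = pd.to_numeric(df[col], errors="coerce")
        nan_mask = vals.isna()
        if nan_mask.any():
            rows = (df.index[nan_mask] + 2).tolist()[:5]
            raise FormatError(f"{path}: non-numeric {col} values at file rows {rows}")
        neg = vals < 0
        if neg.any():
            rows = (df.index[neg] + 2).tolist()[:5]
            raise ValidationError(f"{path}: negative {col} values at file rows {rows}")
        df[col] = vals.astype(float)

    dup = df.duplicated(subset=["subject_id", "hemisphere", "vertex_index"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValidationError(
            f"{path}: duplicate (subject, hemisphere, vertex_index) at file rows {rows}"
        )
    return df


def read_vertex_table(path) -> dict[str, SubjectMorphometry]:
    """Read a vertex TSV, validate it, and split it into per-subject objects.

    Returns an ordered mapping subject_id -> :class:`SubjectMorphometry`.
    Parcel order is the order of first appearance in the file, which
    thereafter defines the row order of every matrix for these subjects.

    Raises
    ------
    FormatError
        Missing column or non-numeric measure value.
    ValidationError
        Negative value, bad hemisphere code, or duplicate vertex.
    EmptyInputError
        Zero data rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "parcel_label": str})
    df = _validate_frame(df, path)

    parcel_order = tuple(dict.fromkeys(df["parcel_label"]))
    parcellation = Parcellation(parcel_order)

    out: dict[str, SubjectMorphometry] = {}
    for subject_id, sub in df.groupby("subject_id", sort=False):
        values: dict[str, dict[str, np.ndarray]] = {}
        for parcel, block in sub.groupby("parcel_label", sort=False):
            values[parcel] = {m: block[m].to_numpy(copy=True) for m in MEASURES}
        # keep the global parcel order, dropping parcels absent for this subject
        ordered = {p: values[p] for p in parcel_order if p in values}
        out[str(subject_id)] = SubjectMorphometry(
            subject_id=str(subject_id),
            parcellation=Parcellation(tuple(ordered)),
            values=ordered,
        )
    return out


def write_vertex_table(subjects, path) -> None:
    """Write one or more SubjectMorphometry objects back to a vertex TSV.

    The vertex_index column is regenerated as a running index per
    (subject, hemisphere); round-trips preserve parcel order and values.
    """
    if isinstance(subjects, SubjectMorphometry):
        subjects = [subjects]
    frames = []
    for sm in subjects:
        counters = {"lh": 0, "rh": 0}
        for parcel in sm.parcellation.labels:
            vals = sm.values[parcel]
            n = len(vals["volume"])
            hemi = "rh" if parcel.endswith("(rh)") else "lh"
            idx = np.arange(counters[hemi], counters[hemi] + n)
            counters[hemi] += n
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sm.subject_id,
                        "hemisphere": hemi,
                        "vertex_index": idx,
                        "parcel_label": parcel,
                        "volume": vals["volume"],
                        "area": vals["area"],
                        "thickness": vals["thickness"],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def filter_parcels(sm: SubjectMorphometry, min_vertices: int = 50) -> SubjectMorphometry:
    """Drop parcels with fewer than ``min_vertices`` vertices.

    A parcel with exactly ``min_vertices`` vertices is retained (the
    exclusion rule is strictly "< min_vertices").  Parcel order is
    preserved; global summaries are recomputed over the retained parcels
    because they are derived properties.  Idempotent.

    Raises
    ------
    ValueError
        ``min_vertices < 1``.
    ValidationError
        Fewer than 3 parcels survive (no meaningful network).
    """
    if min_vertices < 1:
        raise ValueError("min_vertices must be >= 1")
    kept = {
        p: v for p, v in sm.values.items() if len(v["volume"]) >= min_vertices
    }
    if len(kept) < 3:
        raise ValidationError(
            f"subject {sm.subject_id}: only {len(kept)} parcel(s) with >= "
            f"{min_vertices} vertices; need at least 3 to build a network"
        )
    order = tuple(p for p in sm.parcellation.labels if p in kept)
    return SubjectMorphometry(
        subject_id=sm.subject_id,
        parcellation=Parcellation(order),
        values={p: kept[p] for p in order},
    )


def summarize_parcels(sm: SubjectMorphometry) -> pd.DataFrame:
    """Per-parcel totals: summed volume/area, mean thickness, vertex count."""
    if not sm.values:
        raise ValidationError(f"subject {sm.subject_id}: no parcels to summarize")
    rows = []
    for parcel in sm.parcellation.labels:
        v = sm.values[parcel]
        rows.append(
            {
                "parcel": parcel,
                "total_volume": float(v["volume"].sum()),
                "total_area": float(v["area"].sum()),
                "mean_thickness": float(v["thickness"].mean()),
                "vertex_count": len(v["volume"]),
            }
        )
    return pd.DataFrame(rows)
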