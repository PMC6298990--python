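"""Reading, validating and writing ddPCR measurement tables.

The central object is :class:`MeasurementTable`: a samples x markers matrix of
per-sample ddPCR summaries. Each marker is either an allele-frequency (AF)
assay, constrained to [0, 1], or an absolute copy-number (CN) assay,
constrained to be non-negative. A gene may carry both an AF and a CN assay,
and may carry several CN assays at different loci, so the marker panel is
declared explicitly in a small config file rather than inferred from column
names.

File conventions: comma-separated UTF-8 with a header row; ``NA`` and the
empty string both denote a missing value. AF values are fractions in [0, 1];
percentage-scaled inputs are rejected rather than silently rescaled.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AssayKind",
    "Source",
    "Treatment",
    "MarkerDef",
    "SampleMeta",
    "MeasurementTable",
    "read_panel",
    "read_measurements",
    "read_sample_metadata",
    "write_measurements",
    "complete_case_subset",
]

MISSING_TOKENS = ["", "NA"]


class AssayKind(str, enum.Enum):
    AF = "AF"
    CN = "CN"


class Source(str, enum.Enum):
    xenograft = "xenograft"
    crpc_bulk = "crpc_bulk"
    crpc_clone = "crpc_clone"


class Treatment(str, enum.Enum):
    none = "none"
    vehicle = "vehicle"
    cisplatin = "cisplatin"
    cisplatin_retreat = "cisplatin_retreat"
    docetaxel = "docetaxel"
    doxorubicin = "doxorubicin"
    cyclophosphamide = "cyclophosphamide"


@dataclass(frozen=True)
class MarkerDef:
    """One ddPCR assay: a locus measured either as AF or as absolute CN."""

    marker_id: str
    gene: str
    assay_kind: AssayKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "assay_kind", AssayKind(self.assay_kind))


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotations used by the cohort-level analyses."""

    sample_id: str
    model_id: str = ""
    source: Source = Source.xenograft
    treatment: Treatment = Treatment.none
    volume_change_pct: float = math.nan
    days: float = math.nan
    spatial_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", Source(self.source))
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        v = self.volume_change_pct
        if not math.isnan(v) and v < -100.0:
            raise ValueError(
                f"sample {self.sample_id!r}: volume_change_pct {v} < -100"
            )


def _validate_values(values: pd.DataFrame, panel: list[MarkerDef]) -> None:
    by_id = {m.marker_id: m for m in panel}
    for col in values.columns:
        kind = by_id[col].assay_kind
        v = values[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if kind is AssayKind.AF:
                bad = (v < 0.0) | (v > 1.0)
            else:
                bad = v < 0.0
        if bad.any():
            row = values.index[int(np.flatnonzero(bad)[0])]
            raise ValueError(
                f"{kind.value} value {values.at[row, col]!r} out of range at "
                f"sample {row!r}, marker {col!r}"
            )


@dataclass
class MeasurementTable:
    """Samples x markers matrix of AF/CN values with missing data allowed.

    ``values`` is indexed by sample_id with one column per marker_id, in the
    order given by ``samples`` and ``markers``.
    """

    markers: list[MarkerDef]
    samples: list[SampleMeta]
    values: pd.DataFrame

    def __post_init__(self) -> None:
        marker_ids = [m.marker_id for m in self.markers]
        if len(set(marker_ids)) != len(marker_ids):
            raise ValueError("duplicate marker_id in panel")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id")
        if list(self.values.columns) != marker_ids or list(self.values.index) != sample_ids:
            raise ValueError("values matrix does not match marker/sample lists")
        self.values = self.values.astype(float)
        _validate_values(self.values, self.markers)

    # -- lookups -----------------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def marker(self, marker_id: str) -> MarkerDef:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)

    def markers_of_kind(self, kind: AssayKind) -> list[MarkerDef]:
        return [m for m in self.markers if m.assay_kind is AssayKind(kind)]

    def markers_of_gene(self, gene: str, kind: AssayKind | None = None) -> list[MarkerDef]:
        out = [m for m in self.markers if m.gene == gene]
        if kind is not None:
            out = [m for m in out if m.assay_kind is AssayKind(kind)]
        return out

    def meta(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    # -- derived tables ----------------------------------------------------
    def subset_samples(self, sample_ids: list[str]) -> "MeasurementTable":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        return MeasurementTable(
            markers=list(self.markers),
            samples=samples,
            values=self.values.loc[[s.sample_id for s in samples]].copy(),
        )

    def with_metadata(self, metadata: list[SampleMeta]) -> "MeasurementTable":
        """Attach externally-read metadata, matched by sample_id."""
        by_id = {m.sample_id: m for m in metadata}
        missing = [sid for sid in self.sample_ids if sid not in by_id]
        if missing:
            raise ValueError(f"no metadata for samples: {missing}")
        return MeasurementTable(
            markers=list(self.markers),
            samples=[by_id[sid] for sid in self.sample_ids],
            values=self.values.copy(),
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_panel(path) -> list[MarkerDef]:
    """Read a marker panel from YAML.

    Accepts either a top-level list of ``{marker_id, gene, assay_kind}``
    mappings or a mapping with a ``markers:`` key holding that list.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc.get("markers", doc)
    if not isinstance(doc, list):
        raise ValueError(f"panel file {path}: expected a list of markers")
    return [MarkerDef(str(d["marker_id"]), str(d["gene"]), d["assay_kind"]) for d in doc]


def write_panel(panel: list[MarkerDef], path) -> None:
    doc = [
        {"marker_id": m.marker_id, "gene": m.gene, "assay_kind": m.assay_kind.value}
        for m in panel
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"markers": doc}, fh, sort_keys=False)


def read_measurements(path, panel: list[MarkerDef]) -> MeasurementTable:
    """Read a measurement CSV (first column sample_id, one column per marker).

    Every non-sample_id column must be declared in ``panel``; values are
    validated against the assay-kind ranges and missing cells are preserved.
    """
    df = pd.read_csv(
        path, dtype={0: str}, na_values=MISSING_TOKENS, keep_default_na=False
    )
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    df = df.set_index("sample_id")
    known = {m.marker_id for m in panel}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"{path}: unknown marker columns {unknown}")
    markers = [m for m in panel if m.marker_id in set(df.columns)]
    df = df[[m.marker_id for m in markers]]
    samples = [SampleMeta(sample_id=sid) for sid in df.index]
    return MeasurementTable(markers=markers, samples=samples, values=df)


def write_measurements(table: MeasurementTable, path) -> None:
    """Write the values matrix as CSV; round-trips finite floats exactly."""
    table.values.to_csv(path, na_rep="NA")


def read_sample_metadata(path) -> list[SampleMeta]:
    """Read per-sample metadata; only ``sample_id`` is required."""
    df = pd.read_csv(
        path, dtype=str, na_values=MISSING_TOKENS, keep_default_na=False
    )
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")

    def _get(row, col, default):
        if col in df.columns and pd.notna(row[col]):
            return row[col]
        return default

    out = []
    for _, row in df.iterrows():
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                model_id=_get(row, "model_id", ""),
                source=Source(_get(row, "source", "xenograft")),
                treatment=Treatment(_get(row, "treatment", "none")),
                volume_change_pct=float(_get(row, "volume_change_pct", math.nan)),
                days=float(_get(row, "days", math.nan)),
                spatial_label=_get(row, "spatial_label", ""),
            )
        )
    return out


def write_sample_metadata(metadata: list[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "model_id": m.model_id,
            "source": m.source.value,
            "treatment": m.treatment.value,
            "volume_change_pct": m.volume_change_pct,
            "days": m.days,
            "spatial_label": m.spatial_label,
        }
        for m in metadata
    ]
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="NA")


def complete_case_subset(table: MeasurementTable, markers: list[str]) -> MeasurementTable:
    """Keep only samples with no missing value among ``markers`` (order kept)."""
    for mid in markers:
        table.marker(mid)  # KeyError on unknown marker
    mask = table.values[markers].notna().all(axis=1)
    keep = [sid for sid in table.sample_ids if mask[sid]]
    if not keep:
        warnings.warn(
            f"complete_case_subset: no sample has complete data for {markers}",
            stacklevel=2,
        )
    return table.subset_samples(keep)
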