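"""Bottleneck-outlier detection from AF panels.

Two kinds of dimension are screened. Loci not involved in the two-subclone
mixing (truncal markers) should sit at a constant allele frequency across
samples; each sample gets a median-centered z-score and is flagged at
|z| > 3. Loci that do mix are expected to lie on a straight segment in the
plane of that locus' AF versus the anchor (LRP1B) AF; a sample is flagged
when its perpendicular Euclidean distance D to the line exceeds 0.07,
roughly six-fold the ddPCR AF measurement uncertainty of 0.011.

Flags carry a direction: excess (above the line / above the median) or
deficient. The per-sample pattern of flagged dimensions and directions is the
fingerprint of the bottleneck that produced the outlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AssayKind, MeasurementTable, Source

__all__ = [
    "MixingLine",
    "OutlierCall",
    "median_z_scores",
    "perpendicular_distance",
    "signed_offset",
    "classify_outliers",
    "default_mixing_lines",
    "DEFAULT_STABLE_GENES",
    "DEFAULT_Z_THRESHOLD",
    "DEFAULT_D_THRESHOLD",
    "REFERENCE_LINE_COORDS",
]

DEFAULT_Z_THRESHOLD = 3.0
DEFAULT_D_THRESHOLD = 0.07

#: Genes whose AF is unaffected by mixing of the two recurrent subclones.
DEFAULT_STABLE_GENES = ("BRCA2", "PTCH1", "TP53", "CSMD3")

#: Reference mixing-line endpoints, as (gene, (x1, y1), (x2, y2)) vs LRP1B AF.
REFERENCE_LINE_COORDS = {
    "ERBB4": ((0.0, 0.0), (0.25, 0.33)),
    "MET": ((0.0, 0.67), (0.25, 0.5)),
    "SAAL1": ((0.0, 0.25), (0.25, 0.4)),
}


@dataclass(frozen=True)
class MixingLine:
    """A subclone-mixing segment in the (anchor AF, marker AF) plane."""

    x_marker: str
    y_marker: str
    endpoint_a: tuple[float, float]
    endpoint_b: tuple[float, float]

    def __post_init__(self) -> None:
        if self.endpoint_a == self.endpoint_b:
            raise ValueError("mixing line endpoints must be distinct")


def median_z_scores(values) -> np.ndarray:
    """Median-centered z-scores: (v - median(v)) / sd(v), NaN preserved.

    The scale is the ordinary n-1 sample standard deviation over all
    non-missing values (outlier candidates included, so extreme values mask
    themselves somewhat). A zero SD yields all-zero scores (no outliers).
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 non-missing values, got {int(ok.sum())}")
    med = float(np.median(v[ok]))
    sd = float(np.std(v[ok], ddof=1))
    z = np.full_like(v, np.nan)
    z[ok] = 0.0 if sd == 0.0 else (v[ok] - med) / sd
    return z


def signed_offset(point: tuple[float, float], line: MixingLine) -> float:
    """Signed perpendicular offset of ``point`` from the infinite line.

    Positive means the point lies above the line (excess y at its x), so the
    sign is invariant under swapping the line's endpoints.
    """
    (x1, y1), (x2, y2) = line.endpoint_a, line.endpoint_b
    px, py = point
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    length = math.hypot(x2 - x1, y2 - y1)
    d = cross / length
    if x2 != x1:
        d *= math.copysign(1.0, x2 - x1)
    return d


def perpendicular_distance(point: tuple[float, float], line: MixingLine) -> float:
    """Euclidean distance from ``point`` to the infinite line."""
    return abs(signed_offset(point, line))


def default_mixing_lines(table: MeasurementTable) -> list[MixingLine]:
    """The published mixing lines, matched to the table's AF assays."""
    def af_marker(gene: str) -> str | None:
        ms = table.markers_of_gene(gene, AssayKind.AF)
        return ms[0].marker_id if ms else None

    anchor = af_marker("LRP1B")
    lines = []
    if anchor is not None:
        for gene, (a, b) in REFERENCE_LINE_COORDS.items():
            y = af_marker(gene)
            if y is not None:
                lines.append(MixingLine(anchor, y, a, b))
    return lines


@dataclass
class OutlierCall:
    """Sample x dimension outlier calls with summaries.

    ``calls`` holds +1 (excess), -1 (deficient) or 0 per evaluable cell;
    ``scores`` holds the raw statistic (z for stable dimensions, signed
    perpendicular offset for mixing dimensions); ``evaluable`` marks cells
    with enough data to be judged.
    """

    calls: pd.DataFrame
    scores: pd.DataFrame
    evaluable: pd.DataFrame
    stable_dims: list[str]
    mixing_dims: list[str]
    z_threshold: float
    d_threshold: float

    @property
    def dims_per_sample(self) -> pd.Series:
        return (self.calls != 0).sum(axis=1)

    @property
    def flagged_samples(self) -> list[str]:
        d = self.dims_per_sample
        return list(d.index[d > 0])

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_samples)

    @property
    def max_dims_per_sample(self) -> int:
        return int(self.dims_per_sample.max()) if len(self.calls) else 0

    def pattern(self, sample_id: str) -> tuple[tuple[str, int], ...]:
        row = self.calls.loc[sample_id]
        return tuple(sorted((dim, int(v)) for dim, v in row.items() if v != 0))

    @property
    def n_patterns(self) -> int:
        """Distinct (dimension, direction) multisets among flagged samples."""
        return len({self.pattern(s) for s in self.flagged_samples})

    def flagged_fraction_by_source(self, table: MeasurementTable) -> dict[str, float]:
        """Fraction of samples flagged, split xenograft vs CRPC-derived."""
        groups: dict[str, list[str]] = {"xenograft": [], "crpc": []}
        for s in table.samples:
            key = "xenograft" if s.source is Source.xenograft else "crpc"
            groups[key].append(s.sample_id)
        flagged = set(self.flagged_samples)
        return {
            k: (len([s for s in ids if s in flagged]) / len(ids)) if ids else math.nan
            for k, ids in groups.items()
        }


def classify_outliers(
    table: MeasurementTable,
    stable_markers: list[str] | None = None,
    mixing_lines: list[MixingLine] | None = None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    d_threshold: float = DEFAULT_D_THRESHOLD,
) -> OutlierCall:
    """Flag samples whose AF values cannot arise from two-subclone mixing.

    Stable dimensions use strict |z| > z_threshold on median-centered
    z-scores; mixing dimensions use strict D > d_threshold on the
    perpendicular distance to the declared line, with direction taken from
    the sign of the y-residual. Missing values make a (sample, dimension)
    cell non-evaluable, never flagged.
    """
    if stable_markers is None:
        stable_markers = [
            m.marker_id
            for m in table.markers
            if m.assay_kind is AssayKind.AF and m.gene in DEFAULT_STABLE_GENES
        ]
    if mixing_lines is None:
        mixing_lines = default_mixing_lines(table)

    index = table.values.index
    dims = list(stable_markers) + [ln.y_marker for ln in mixing_lines]
    calls = pd.DataFrame(0, index=index, columns=dims, dtype=int)
    scores = pd.DataFrame(np.nan, index=index, columns=dims, dtype=float)
    evaluable = pd.DataFrame(False, index=index, columns=dims, dtype=bool)

    for mid in stable_markers:
        try:
            z = median_z_scores(table.values[mid])
        except ValueError:
            continue  # < 3 values: dimension stays non-evaluable
        ok = np.isfinite(z)
        scores[mid] = z
        evaluable[mid] = ok
        flag = ok & (np.abs(z) > z_threshold)
        calls.loc[flag, mid] = np.sign(z[flag]).astype(int)

    for line in mixing_lines:
        x = table.values[line.x_marker].to_numpy(dtype=float)
        y = table.values[line.y_marker].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        off = np.array(
            [
                signed_offset((xi, yi), line) if o else np.nan
                for xi, yi, o in zip(x, y, ok)
            ]
        )
        scores[line.y_marker] = off
        evaluable[line.y_marker] = ok
        flag = ok & (np.abs(off) > d_threshold)
        calls.loc[flag, line.y_marker] = np.sign(off[flag]).astype(int)

    return OutlierCall(
        calls=calls,
        scores=scores,
        evaluable=evaluable,
        stable_dims=list(stable_markers),
        mixing_dims=[ln.y_marker for ln in mixing_lines],
        z_threshold=z_threshold,
        d_threshold=d_threshold,
    )
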