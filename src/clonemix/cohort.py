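"""Cohort-level selection statistics.

Pairwise Pearson correlation matrices across markers (the block structure of
co-amplified subclone-1 loci vs. the anti-correlated subclone-2 amplification
is the fingerprint of two-subclone mixing), Welch's t-tests between treatment
cohorts with Benjamini-Hochberg correction, the association between a
marker's value and post-treatment tumor volume change, and mean subclone-1
prevalence per cohort.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AssayKind, MeasurementTable, SampleMeta, Treatment
from .mixture import LineFit, MixtureFit, fit_marker_pair

__all__ = [
    "CorrelationMatrix",
    "CohortTestResult",
    "correlation_matrix",
    "cohort_differential_tests",
    "volume_association",
    "prevalence_by_cohort",
    "CISPLATIN_TREATMENTS",
]

#: Treatments pooled as "cisplatin" in prevalence and volume analyses.
CISPLATIN_TREATMENTS = (Treatment.cisplatin, Treatment.cisplatin_retreat)


@dataclass
class CorrelationMatrix:
    markers: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def correlation_matrix(
    table: MeasurementTable,
    markers: list[str] | None = None,
    mode: str = "complete_case",
) -> CorrelationMatrix:
    """Pearson correlations among markers with two-sided t-transform p-values.

    ``complete_case`` (the default) first restricts to samples with data for
    all requested markers; ``pairwise`` uses each pair's complete cases. Pairs
    with fewer than 3 usable samples or a zero-variance member are reported as
    missing.
    """
    if mode not in ("complete_case", "pairwise"):
        raise ValueError(f"unknown mode {mode!r}")
    if markers is None:
        markers = table.marker_ids
    vals = table.values[markers]
    if mode == "complete_case":
        vals = vals.dropna(axis=0, how="any")

    r = pd.DataFrame(np.nan, index=markers, columns=markers)
    p = pd.DataFrame(np.nan, index=markers, columns=markers)
    n = pd.DataFrame(0, index=markers, columns=markers, dtype=int)
    for a in markers:
        cnt = int(vals[a].notna().sum())
        n.loc[a, a] = cnt
        if cnt >= 3 and np.ptp(vals[a].dropna().to_numpy()) > 0.0:
            r.loc[a, a] = 1.0
            p.loc[a, a] = 0.0
    for a, b in itertools.combinations(markers, 2):
        pair = vals[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(pair)
        if len(pair) < 3:
            continue
        xa, xb = pair[a].to_numpy(), pair[b].to_numpy()
        if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
            continue
        res = stats.pearsonr(xa, xb)
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return CorrelationMatrix(markers=list(markers), r=r, p=p, n=n)


@dataclass(frozen=True)
class CohortTestResult:
    """Welch's t-test for one marker between two treatment cohorts."""

    marker_id: str
    cohort_a: str
    cohort_b: str
    n_a: int
    n_b: int
    welch_t: float
    p_value: float
    q_value: float
    significant: bool


def cohort_differential_tests(
    table: MeasurementTable,
    metadata: list[SampleMeta] | None = None,
    alpha: float = 0.05,
    pool_cisplatin: bool = False,
    separate_families: bool = True,
) -> list[CohortTestResult]:
    """Welch's unequal-variance t-test for every marker x cohort pair.

    Cohorts are treatment arms; with ``pool_cisplatin`` the cisplatin and
    cisplatin-retreat arms form one cohort. Benjamini-Hochberg correction is
    applied within each assay family (AF tests and CN tests separately by
    default; ``separate_families=False`` pools them). Cohorts with fewer than
    2 non-missing values for a marker are skipped for that marker with a
    warning. Results are sorted by q-value then p-value.
    """
    metas = metadata if metadata is not None else table.samples
    by_id = {m.sample_id: m for m in metas}

    def cohort_of(sid: str) -> str:
        t = by_id[sid].treatment
        if pool_cisplatin and t in CISPLATIN_TREATMENTS:
            return "cisplatin"
        return t.value

    cohorts: dict[str, list[str]] = {}
    for sid in table.sample_ids:
        cohorts.setdefault(cohort_of(sid), []).append(sid)

    rows: list[dict] = []
    skipped: set[tuple[str, str]] = set()
    for m in table.markers:
        col = table.values[m.marker_id]
        groups = {
            c: col.loc[ids].dropna().to_numpy() for c, ids in cohorts.items()
        }
        for a, b in itertools.combinations(sorted(groups), 2):
            xa, xb = groups[a], groups[b]
            if len(xa) < 2 or len(xb) < 2:
                for c, x in ((a, xa), (b, xb)):
                    if len(x) < 2:
                        skipped.add((m.marker_id, c))
                continue
            res = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append(
                {
                    "marker_id": m.marker_id,
                    "cohort_a": a,
                    "cohort_b": b,
                    "n_a": len(xa),
                    "n_b": len(xb),
                    "welch_t": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "family": m.assay_kind.value if separate_families else "all",
                }
            )
    for marker_id, c in sorted(skipped):
        warnings.warn(
            f"cohort {c!r} has < 2 values for {marker_id!r}; pairs skipped",
            stacklevel=2,
        )
    if not rows:
        return []
    df = pd.DataFrame(rows)
    df["q_value"] = np.nan
    for fam, idx in df.groupby("family").groups.items():
        _, q, _, _ = multipletests(df.loc[idx, "p_value"], method="fdr_bh")
        df.loc[idx, "q_value"] = q
    df = df.sort_values(["q_value", "p_value"], kind="mergesort").reset_index(drop=True)
    return [
        CohortTestResult(
            marker_id=row.marker_id,
            cohort_a=row.cohort_a,
            cohort_b=row.cohort_b,
            n_a=int(row.n_a),
            n_b=int(row.n_b),
            welch_t=row.welch_t,
            p_value=row.p_value,
            q_value=row.q_value,
            significant=bool(row.q_value <= alpha),
        )
        for row in df.itertuples()
    ]


def volume_association(
    table: MeasurementTable,
    metadata: list[SampleMeta] | None = None,
    marker: str = "LRP1B_CN1",
    cohorts: list[Treatment] | None = None,
) -> LineFit:
    """OLS of % tumor-volume change on a marker value within a cohort filter.

    ``cohorts=None`` uses all samples with a volume measurement; passing e.g.
    the cisplatin treatments restricts to those arms (the pooled
    one-cycle-plus-retreat analysis).
    """
    metas = metadata if metadata is not None else table.samples
    by_id = {m.sample_id: m for m in metas}
    wanted = None if cohorts is None else {Treatment(c) for c in cohorts}
    x, y = [], []
    for sid in table.sample_ids:
        meta = by_id[sid]
        if wanted is not None and meta.treatment not in wanted:
            continue
        v = table.values.at[sid, marker]
        if np.isfinite(v) and not math.isnan(meta.volume_change_pct):
            x.append(float(v))
            y.append(meta.volume_change_pct)
    if len(x) < 3:
        label = "all samples" if wanted is None else ", ".join(t.value for t in wanted)
        raise ValueError(
            f"volume association needs >= 3 samples with {marker!r} and volume "
            f"in cohort [{label}]; got {len(x)}"
        )
    return fit_marker_pair(x, y)


def prevalence_by_cohort(
    fit: MixtureFit,
    metadata: list[SampleMeta],
    group_cisplatin: bool = True,
) -> dict[str, float]:
    """Mean subclone-1 mixing fraction per cohort.

    With ``group_cisplatin`` the cisplatin and cisplatin-retreat arms are
    pooled as "cisplatin" and every other arm as "non-cisplatin"; otherwise
    cohorts are the raw treatment labels. Cohorts with no usable fraction are
    omitted.
    """
    by_id = {m.sample_id: m for m in metadata}
    buckets: dict[str, list[float]] = {}
    for sid, p in fit.fractions.items():
        if sid not in by_id or not np.isfinite(p):
            continue
        t = by_id[sid].treatment
        if group_cisplatin:
            key = "cisplatin" if t in CISPLATIN_TREATMENTS else "non-cisplatin"
        else:
            key = t.value
        buckets.setdefault(key, []).append(float(p))
    return {k: float(np.mean(v)) for k, v in buckets.items() if v}
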