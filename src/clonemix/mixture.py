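"""Two-subclone mixture model over paired AF and absolute-CN measurements.

Model
-----
Every sample is a mixture of two recurrent subclones. Writing ``p`` for the
fraction of tumor cells belonging to subclone 1, the expected absolute copy
number at a locus is affine in ``p``::

    CN(p) = p * cn1 + (1 - p) * cn2

while the expected allele frequency is the ratio of mutant to total template
molecules in the pooled DNA::

    AF(p) = (p * md1 + (1 - p) * md2) / CN(p)

where ``md`` is the mean number of mutant copies per cell of each subclone.
Within-subclone copy-number heterogeneity is carried by a non-integer
``mean_cn``; the mutant dose scales proportionally (``md = mean_cn * m / T``)
so that the within-subclone allele frequency stays at the genotype ratio
``m/T``. AF(p) is therefore a ratio of affine functions of ``p`` — a gently
curved arc, of which the straight line used for inference is an
approximation.

Inference follows the published linear procedure: ordinary least-squares fits
of each marker against an anchor allele frequency (LRP1B by default), with
subclone values read off the fitted line at the anchor's two pure-subclone
allele frequencies (0.25 for subclone 1, 0.0 for subclone 2). Extrapolated
values are rounded to integer genotypes, and per-sample mixing fractions are
interpolated from the anchor copy number between the two called integer
endpoints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AssayKind, MarkerDef, MeasurementTable

__all__ = [
    "LocusGenotype",
    "SubcloneGenotype",
    "LineFit",
    "EndpointEstimate",
    "GenotypeCallResult",
    "MixtureFit",
    "expected_copy_number",
    "expected_allele_frequency",
    "call_integer_genotype",
    "fit_marker_pair",
    "infer_subclone_endpoints",
    "genotype_subclones",
    "estimate_mixing_fraction",
    "fit_two_subclone_model",
    "cellularity_uncertainty",
    "integer_deviation",
    "DEFAULT_ANCHOR_MARKER",
    "DEFAULT_ANCHOR_VALUES",
]

#: Anchor assay parameterizing the mixing axis, and its pure-subclone AFs.
DEFAULT_ANCHOR_MARKER = "LRP1B_AF"
DEFAULT_ANCHOR_VALUES = (0.25, 0.0)


@dataclass(frozen=True)
class LocusGenotype:
    """Integer genotype of one subclone at one locus: m mutant of T total."""

    mutant_copies: int
    total_copies: int

    def __post_init__(self) -> None:
        if self.total_copies < 1:
            raise ValueError("total_copies must be >= 1")
        if not 0 <= self.mutant_copies <= self.total_copies:
            raise ValueError("need 0 <= mutant_copies <= total_copies")

    @property
    def allele_frequency(self) -> float:
        return self.mutant_copies / self.total_copies


@dataclass
class SubcloneGenotype:
    """Per-locus integer genotypes of one subclone, keyed by gene.

    ``mean_cn`` optionally records a non-integer mean copy number per locus,
    representing copy-number heterogeneity among the subclone's own cells;
    where absent it defaults to the integer total.
    """

    loci: dict[str, LocusGenotype] = field(default_factory=dict)
    mean_cn: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, cn in self.mean_cn.items():
            if cn < 0:
                raise ValueError(f"mean_cn[{locus!r}] < 0")

    def cn(self, locus: str) -> float:
        """Mean copies per cell at ``locus`` (mean_cn, or T if unset)."""
        if locus in self.mean_cn:
            return self.mean_cn[locus]
        return float(self.loci[locus].total_copies)

    def mutant_dose(self, locus: str) -> float:
        """Mean mutant copies per cell; scales with mean_cn so AF stays m/T."""
        g = self.loci[locus]
        return self.cn(locus) * g.mutant_copies / g.total_copies


def expected_copy_number(
    p: float, g1: SubcloneGenotype, g2: SubcloneGenotype, locus: str
) -> float:
    """Mixture copy number p*cn1 + (1-p)*cn2 at ``locus``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mixing fraction {p} outside [0, 1]")
    if locus not in g1.loci or locus not in g2.loci:
        raise KeyError(f"locus {locus!r} missing from a subclone genotype")
    return p * g1.cn(locus) + (1.0 - p) * g2.cn(locus)


def expected_allele_frequency(
    p: float, g1: SubcloneGenotype, g2: SubcloneGenotype, locus: str
) -> float:
    """Exact mixture allele frequency (mutant dose over total copies)."""
    total = expected_copy_number(p, g1, g2, locus)
    if total == 0.0:
        raise ZeroDivisionError(f"mixture copy number is zero at {locus!r}")
    mutant = p * g1.mutant_dose(locus) + (1.0 - p) * g2.mutant_dose(locus)
    return mutant / total


def call_integer_genotype(af: float, cn: float) -> tuple[LocusGenotype, float]:
    """Round (AF, CN) to the nearest integer genotype.

    Total copies T = round(CN) (half rounds up, minimum 1); mutant copies m
    minimizes |AF - m/T| over 0..T with ties broken toward smaller m. Returns
    the genotype and the residual |AF - m/T| as a consistency score.
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    if not cn > 0.5:
        raise ValueError(f"copy number {cn} too small to call a genotype")
    total = max(1, math.floor(cn + 0.5))
    best_m, best_res = 0, abs(af)
    for m in range(1, total + 1):
        res = abs(af - m / total)
        if res < best_res:
            best_m, best_res = m, res
    return LocusGenotype(best_m, total), best_res


@dataclass(frozen=True)
class LineFit:
    """OLS fit of y on x with the Pearson correlation of the pair."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def fit_marker_pair(x, y) -> LineFit:
    """OLS of y on x over complete pairs; two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in x or y: correlation undefined")
    res = stats.linregress(x, y)
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(n),
    )


@dataclass
class EndpointEstimate:
    """Per-marker subclone values extrapolated along the anchor AF axis."""

    anchor: str
    anchor_values: tuple[float, float]
    endpoints: dict[str, tuple[float, float]]
    fits: dict[str, LineFit]
    constant: set[str]
    failed: dict[str, str]
    method: str = "local"


def _local_linear_predict(x: np.ndarray, y: np.ndarray, x0: float, k: int) -> float:
    """Predict y at ``x0`` from an OLS line through the k nearest samples in x.

    Near the edge of the data this extrapolates the local tangent rather than
    a global chord, which keeps endpoint estimates consistent when the true
    relation is gently curved (the exact mixture AF coordinate is not affine
    in the mixing fraction). Falls back to the global line when the local
    neighborhood is degenerate.
    """
    order = np.argsort(np.abs(x - x0), kind="stable")[:k]
    xs, ys = x[order], y[order]
    if np.ptp(xs) == 0.0:
        xs, ys = x, y
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(intercept + slope * x0)


def infer_subclone_endpoints(
    table: MeasurementTable,
    anchor: str = DEFAULT_ANCHOR_MARKER,
    anchor_values: tuple[float, float] = DEFAULT_ANCHOR_VALUES,
    method: str = "local",
    local_k: int | None = None,
) -> EndpointEstimate:
    """Extrapolate each marker to the anchor's pure-subclone AF values.

    For every marker, fits marker value vs. anchor AF over complete cases and
    evaluates the fit at ``anchor_values`` (subclone 1 first). With
    ``method="ols"`` the evaluation uses the single global least-squares line
    (the published procedure); the default ``method="local"`` evaluates a
    local linear fit anchored on the samples nearest each anchor value, which
    removes most of the extrapolation bias caused by the slight curvature of
    the exact mixture relation (see the module docstring). A marker with zero
    spread cannot be regressed; it is treated as constant across subclones
    (both endpoints at its mean) and flagged. Markers whose fit fails for
    other reasons are reported in ``failed``, not fatal.
    """
    if method not in ("local", "ols"):
        raise ValueError(f"unknown endpoint method {method!r}")
    if table.marker(anchor).assay_kind is not AssayKind.AF:
        raise ValueError(f"anchor {anchor!r} is not an AF assay")
    xa = table.values[anchor].to_numpy(dtype=float)
    if np.ptp(xa[np.isfinite(xa)]) == 0.0:
        raise ValueError(f"anchor {anchor!r} has zero variance")

    endpoints: dict[str, tuple[float, float]] = {}
    fits: dict[str, LineFit] = {}
    constant: set[str] = set()
    failed: dict[str, str] = {}
    a1, a2 = anchor_values
    for m in table.markers:
        y = table.values[m.marker_id].to_numpy(dtype=float)
        mask = np.isfinite(xa) & np.isfinite(y)
        if mask.sum() >= 3 and np.ptp(y[mask]) == 0.0:
            mean = float(y[mask][0])
            endpoints[m.marker_id] = (mean, mean)
            constant.add(m.marker_id)
            continue
        try:
            fit = fit_marker_pair(xa, y)
        except ValueError as exc:
            failed[m.marker_id] = str(exc)
            continue
        fits[m.marker_id] = fit
        if method == "ols":
            endpoints[m.marker_id] = (fit.predict(a1), fit.predict(a2))
        else:
            xm, ym = xa[mask], y[mask]
            k = local_k if local_k is not None else max(10, round(mask.sum() / 3))
            k = min(k, int(mask.sum()))
            endpoints[m.marker_id] = (
                _local_linear_predict(xm, ym, a1, k),
                _local_linear_predict(xm, ym, a2, k),
            )
    return EndpointEstimate(
        anchor=anchor,
        anchor_values=(a1, a2),
        endpoints=endpoints,
        fits=fits,
        constant=constant,
        failed=failed,
        method=method,
    )


@dataclass
class GenotypeCallResult:
    """Integer genotypes of both subclones plus bookkeeping flags.

    ``assumed_diploid`` lists genes genotyped from an AF endpoint alone under
    a T = 2 assumption; ``cn_only`` lists genes with no AF assay, whose mutant
    copy count is necessarily reported as 0.
    """

    subclone1: SubcloneGenotype
    subclone2: SubcloneGenotype
    assumed_diploid: set[str]
    cn_only: set[str]
    residuals: dict[str, tuple[float, float]]


def _clip_af(value: float, gene: str) -> float:
    if value < -1e-6 or value > 1.0 + 1e-6:
        warnings.warn(
            f"extrapolated AF {value:.4f} for {gene} outside [0, 1]; clipped",
            stacklevel=3,
        )
    return min(1.0, max(0.0, value))


def genotype_subclones(
    endpoints: dict[str, tuple[float, float]], panel: list[MarkerDef]
) -> GenotypeCallResult:
    """Resolve extrapolated endpoint values into per-gene integer genotypes.

    Genes with several CN assays (e.g. two LRP1B loci) use the mean of their
    CN endpoints. Genes with an AF endpoint but no CN endpoint are genotyped
    assuming two total copies and flagged. The non-integer CN endpoint is
    retained as ``mean_cn``.
    """
    genes = sorted({m.gene for m in panel if m.marker_id in endpoints})
    g1 = SubcloneGenotype()
    g2 = SubcloneGenotype()
    assumed_diploid: set[str] = set()
    cn_only: set[str] = set()
    residuals: dict[str, tuple[float, float]] = {}
    for gene in genes:
        af_ids = [
            m.marker_id
            for m in panel
            if m.gene == gene and m.assay_kind is AssayKind.AF and m.marker_id in endpoints
        ]
        cn_ids = [
            m.marker_id
            for m in panel
            if m.gene == gene and m.assay_kind is AssayKind.CN and m.marker_id in endpoints
        ]
        if not af_ids and not cn_ids:
            continue
        res_pair = []
        for k, sub in enumerate((g1, g2)):
            af = float(np.mean([endpoints[i][k] for i in af_ids])) if af_ids else 0.0
            af = _clip_af(af, gene) if af_ids else 0.0
            if cn_ids:
                cn = float(np.mean([endpoints[i][k] for i in cn_ids]))
                cn = max(cn, 0.0)
                sub.mean_cn[gene] = cn
            else:
                cn = 2.0
                assumed_diploid.add(gene)
            geno, res = call_integer_genotype(af, max(cn, 0.51))
            sub.loci[gene] = geno
            res_pair.append(res)
        if not af_ids:
            cn_only.add(gene)
        residuals[gene] = (res_pair[0], res_pair[1])
    return GenotypeCallResult(
        subclone1=g1,
        subclone2=g2,
        assumed_diploid=assumed_diploid,
        cn_only=cn_only,
        residuals=residuals,
    )


def estimate_mixing_fraction(
    cn: float,
    g1: SubcloneGenotype,
    g2: SubcloneGenotype,
    locus: str,
    use_mean_cn: bool = False,
) -> float:
    """Interpolate the subclone-1 fraction from an anchor copy number.

    p = (cn - cn2) / (cn1 - cn2), clipped to [0, 1]. By default the subclone
    copy numbers are the called integer totals (the 2 <-> 4 interpolation at
    the anchor); ``use_mean_cn=True`` interpolates between the non-integer
    extrapolated endpoints instead.
    """
    if use_mean_cn:
        cn1, cn2 = g1.cn(locus), g2.cn(locus)
    else:
        cn1 = float(g1.loci[locus].total_copies)
        cn2 = float(g2.loci[locus].total_copies)
    if cn1 == cn2:
        raise ValueError(f"anchor {locus!r} uninformative: cn1 == cn2 == {cn1}")
    p = (cn - cn2) / (cn1 - cn2)
    return min(1.0, max(0.0, p))


@dataclass
class MixtureFit:
    """Fitted two-subclone model: genotypes plus per-sample mixing fractions."""

    subclone1: SubcloneGenotype
    subclone2: SubcloneGenotype
    fractions: pd.Series
    anchor_marker: str
    endpoints: EndpointEstimate
    genotype_calls: GenotypeCallResult


def _endpoints_vs_fraction(
    table: MeasurementTable, fractions: pd.Series
) -> dict[str, tuple[float, float]]:
    """Re-estimate subclone endpoints by OLS of each marker on the fraction.

    Copy numbers are exactly affine in the mixing fraction, so once per-sample
    fractions are in hand this regression has no curvature bias; endpoints are
    the fitted values at p = 1 (subclone 1) and p = 0.
    """
    x = fractions.to_numpy(dtype=float)
    out: dict[str, tuple[float, float]] = {}
    for m in table.markers:
        y = table.values[m.marker_id].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 3:
            continue
        if np.ptp(y[mask]) == 0.0 or np.ptp(x[mask]) == 0.0:
            mean = float(np.mean(y[mask]))
            out[m.marker_id] = (mean, mean)
            continue
        slope, intercept = np.polyfit(x[mask], y[mask], 1)
        out[m.marker_id] = (float(intercept + slope), float(intercept))
    return out


def _anchor_fractions(
    table: MeasurementTable,
    calls: GenotypeCallResult,
    gene: str,
    use_mean_cn: bool,
) -> pd.Series:
    cn_ids = [m.marker_id for m in table.markers_of_gene(gene, AssayKind.CN)]
    if not cn_ids:
        raise ValueError(f"no CN assay for fraction gene {gene!r}")
    cn_obs = table.values[cn_ids].mean(axis=1, skipna=True)
    return pd.Series(
        [
            estimate_mixing_fraction(
                v, calls.subclone1, calls.subclone2, gene, use_mean_cn=use_mean_cn
            )
            if np.isfinite(v)
            else np.nan
            for v in cn_obs
        ],
        index=cn_obs.index,
        name="fraction_subclone1",
    )


def fit_two_subclone_model(
    table: MeasurementTable,
    anchor: str = DEFAULT_ANCHOR_MARKER,
    anchor_values: tuple[float, float] = DEFAULT_ANCHOR_VALUES,
    fraction_gene: str | None = None,
    use_mean_cn: bool = False,
    method: str = "local",
    refine: bool = True,
) -> MixtureFit:
    """End-to-end mixture fit: endpoints -> genotypes -> mixing fractions.

    Mixing fractions are interpolated from the mean of the fraction gene's CN
    assays (the anchor gene by default, averaging multiple loci of that gene)
    between the called integer subclone copy numbers. Samples missing all
    those assays get a NaN fraction.

    With ``refine`` (the default), endpoint values and genotypes are then
    re-estimated by regressing every marker on the first-pass fractions —
    copy number is exactly affine in the mixing fraction, so this second pass
    removes the residual curvature bias of extrapolating along the anchor AF
    axis — and the fractions are re-interpolated from the refined anchor
    genotype.
    """
    est = infer_subclone_endpoints(
        table, anchor=anchor, anchor_values=anchor_values, method=method
    )
    calls = genotype_subclones(est.endpoints, table.markers)
    gene = fraction_gene or table.marker(anchor).gene
    fractions = _anchor_fractions(table, calls, gene, use_mean_cn)

    if refine and fractions.notna().sum() >= 3 and np.ptp(fractions.dropna()) > 0:
        refined = _endpoints_vs_fraction(table, fractions)
        # keep the anchor AF endpoints pinned at their defining values
        for m in table.markers_of_gene(table.marker(anchor).gene, AssayKind.AF):
            if m.marker_id in refined:
                refined[m.marker_id] = anchor_values
        calls = genotype_subclones(refined, table.markers)
        est = EndpointEstimate(
            anchor=est.anchor,
            anchor_values=est.anchor_values,
            endpoints=refined,
            fits=est.fits,
            constant=est.constant,
            failed=est.failed,
            method=est.method + "+refined",
        )
        fractions = _anchor_fractions(table, calls, gene, use_mean_cn)

    return MixtureFit(
        subclone1=calls.subclone1,
        subclone2=calls.subclone2,
        fractions=fractions,
        anchor_marker=anchor,
        endpoints=est,
        genotype_calls=calls,
    )


def cellularity_uncertainty(af_sd: float) -> float:
    """SD of subclone cellularity implied by an AF SD.

    For a heterozygous mutation on a diploid background the cellularity of
    the mutant subclone is 2*AF, so its uncertainty is twice the AF
    uncertainty.
    """
    if af_sd < 0:
        raise ValueError("af_sd must be >= 0")
    return 2.0 * af_sd


def integer_deviation(cn: float) -> float:
    """Distance of a mean copy number from the nearest integer.

    Copy numbers are integers in each single cell, so a population mean far
    from an integer signals within-population heterogeneity.
    """
    if cn < 0:
        raise ValueError("cn must be >= 0")
    return abs(cn - round(cn))
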