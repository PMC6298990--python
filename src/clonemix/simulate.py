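"""Synthetic ddPCR panels with the statistical structure the analysis assumes.

The main generator emulates the two-subclone xenograft ecosystem: every
sample is a mixture of two fixed subclone genotypes at a per-sample fraction
drawn from its treatment cohort's distribution, AF values follow the exact
mixture formula and CN values the affine mixture, both with independent
Gaussian measurement noise (sigma_AF = 0.011, sigma_CN = 0.10 by default).
Optional ingredients reproduce the other phenomena seen in such panels:
bottleneck outliers (a single AF dimension displaced by a fixed amount),
CRPC cultures (clonal lines sit at quantized AF = m/T before noise), and a
per-cohort linear model coupling post-treatment volume change to the anchor
copy number (the cisplatin-specific selection signal).

A second generator produces spatial-drift panels: markers whose latent
cellularity follows a spatially autocorrelated random field on a dissection
grid, independent across markers, with occasional bottleneck takeovers.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import (
    AssayKind,
    MarkerDef,
    MeasurementTable,
    SampleMeta,
    Source,
    Treatment,
)
from .mixture import (
    LocusGenotype,
    SubcloneGenotype,
    expected_allele_frequency,
    expected_copy_number,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_subclone_genotypes",
    "default_panel",
    "simulate_two_subclone_panel",
    "simulate_spatial_drift_panel",
    "DEFAULT_SIGMA_AF",
    "DEFAULT_SIGMA_CN",
]

DEFAULT_SIGMA_AF = 0.011
DEFAULT_SIGMA_CN = 0.10

#: Marker AF maxima observed across spatially dissected drift samples.
DEFAULT_DRIFT_RANGES = {"TTN": 0.164, "ERBB4": 0.194, "DNMT3B": 0.023}


def default_subclone_genotypes() -> tuple[SubcloneGenotype, SubcloneGenotype]:
    """The reconstructed TM00099-like two-subclone ecosystem.

    Subclone 1 (the recent, cisplatin-sensitive expansion): LRP1B 1 mutant of
    4 copies, ERBB4 1 of 3 (mean 2.8 copies), MET wild-type-like 1 of 2,
    co-amplified EPHA3/EPHA5/PTPRD. Subclone 2 (ancestral): LRP1B diploid
    wild type, ERBB4 1.3 mean copies, MET 2 of 3, amplified AR. Truncal:
    PTCH1 2 of 3, TP53 3 of 3, BRCA2 2 of 4. SAAL1 mixes mildly
    (2 of 5 vs 1 of 4). EXOC4 and AKR1B1 are diploid controls.
    """
    g1 = SubcloneGenotype(
        loci={
            "LRP1B": LocusGenotype(1, 4),
            "ERBB4": LocusGenotype(1, 3),
            "MET": LocusGenotype(1, 2),
            "PTCH1": LocusGenotype(2, 3),
            "TP53": LocusGenotype(3, 3),
            "BRCA2": LocusGenotype(2, 4),
            "SAAL1": LocusGenotype(2, 5),
            "EPHA3": LocusGenotype(0, 4),
            "EPHA5": LocusGenotype(0, 4),
            "PTPRD": LocusGenotype(0, 3),
            "AR": LocusGenotype(0, 2),
            "EXOC4": LocusGenotype(0, 2),
            "AKR1B1": LocusGenotype(0, 2),
        },
        mean_cn={"ERBB4": 2.8},
    )
    g2 = SubcloneGenotype(
        loci={
            "LRP1B": LocusGenotype(0, 2),
            "ERBB4": LocusGenotype(0, 1),
            "MET": LocusGenotype(2, 3),
            "PTCH1": LocusGenotype(2, 3),
            "TP53": LocusGenotype(3, 3),
            "BRCA2": LocusGenotype(2, 4),
            "SAAL1": LocusGenotype(1, 4),
            "EPHA3": LocusGenotype(0, 2),
            "EPHA5": LocusGenotype(0, 2),
            "PTPRD": LocusGenotype(0, 2),
            "AR": LocusGenotype(0, 4),
            "EXOC4": LocusGenotype(0, 2),
            "AKR1B1": LocusGenotype(0, 2),
        },
        mean_cn={"ERBB4": 1.3},
    )
    return g1, g2


def default_panel() -> list[MarkerDef]:
    """7 AF assays plus 9 CN assays (two LRP1B loci, two diploid controls)."""
    af_genes = ["BRCA2", "PTCH1", "TP53", "SAAL1", "ERBB4", "LRP1B", "MET"]
    markers = [MarkerDef(f"{g}_AF", g, AssayKind.AF) for g in af_genes]
    markers += [
        MarkerDef("LRP1B_CN1", "LRP1B", AssayKind.CN),
        MarkerDef("LRP1B_CN2", "LRP1B", AssayKind.CN),
        MarkerDef("ERBB4_CN", "ERBB4", AssayKind.CN),
        MarkerDef("EPHA3_CN", "EPHA3", AssayKind.CN),
        MarkerDef("EPHA5_CN", "EPHA5", AssayKind.CN),
        MarkerDef("PTPRD_CN", "PTPRD", AssayKind.CN),
        MarkerDef("AR_CN", "AR", AssayKind.CN),
        MarkerDef("EXOC4_CN", "EXOC4", AssayKind.CN),
        MarkerDef("AKR1B1_CN", "AKR1B1", AssayKind.CN),
    ]
    return markers


def _default_fraction_distributions() -> dict[str, tuple[float, float]]:
    # Cohort means match the reported subclone-1 prevalences (0.70 non-
    # cisplatin, 0.43 cisplatin); SDs give the observed anchor-CN ranges.
    return {
        "cisplatin": (0.43, 0.15),
        "cisplatin_retreat": (0.43, 0.15),
        "__default__": (0.70, 0.10),
    }


def _default_volume_models() -> dict[str, tuple[float, float, float]]:
    # (intercept %, slope % per anchor copy, noise SD %): cisplatin couples
    # volume change to the subclone ratio; other arms mostly just grow.
    return {
        "cisplatin": (-300.0, 100.0, 30.0),
        "cisplatin_retreat": (-300.0, 100.0, 30.0),
        "cyclophosphamide": (0.0, 40.0, 60.0),
        "vehicle": (250.0, 0.0, 80.0),
        "doxorubicin": (150.0, 0.0, 80.0),
        "docetaxel": (-30.0, 0.0, 40.0),
        "none": (200.0, 0.0, 80.0),
    }


DEFAULT_TREATMENT_CYCLE = (
    Treatment.vehicle,
    Treatment.cisplatin,
    Treatment.docetaxel,
    Treatment.doxorubicin,
    Treatment.cyclophosphamide,
    Treatment.cisplatin_retreat,
)


@dataclass
class SimulationConfig:
    """Knobs of the two-subclone panel generator (defaults emulate TM00099)."""

    genotypes: tuple[SubcloneGenotype, SubcloneGenotype] = field(
        default_factory=default_subclone_genotypes
    )
    panel: list[MarkerDef] = field(default_factory=default_panel)
    n_samples: int = 47
    treatments: tuple[Treatment, ...] = DEFAULT_TREATMENT_CYCLE
    fraction_distribution: dict[str, tuple[float, float]] = field(
        default_factory=_default_fraction_distributions
    )
    sigma_af: float = DEFAULT_SIGMA_AF
    sigma_cn: float = DEFAULT_SIGMA_CN
    outlier_rate: float = 0.0
    outlier_displacement: float = 0.15
    crpc_fraction: float = 0.0
    volume_models: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_volume_models
    )
    anchor_gene: str = "LRP1B"
    model_id: str = "SIM99"
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "crpc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sigma_af < 0 or self.sigma_cn < 0:
            raise ValueError("noise SDs must be >= 0")
        g1, g2 = self.genotypes
        for g in (g1, g2):
            for gene in {m.gene for m in self.panel}:
                if gene not in g.loci:
                    raise ValueError(f"panel gene {gene!r} missing from genotypes")

    def fraction_params(self, cohort: str) -> tuple[float, float]:
        if cohort in self.fraction_distribution:
            return self.fraction_distribution[cohort]
        return self.fraction_distribution["__default__"]


@dataclass
class GroundTruth:
    """Simulator record for recovery testing."""

    true_fractions: pd.Series
    treatments: dict[str, str]
    sources: dict[str, str]
    outliers: list[tuple[str, str, float]]  # (sample_id, marker_id, displacement)
    genotypes: tuple[SubcloneGenotype, SubcloneGenotype] | None = None
    volume_models: dict[str, tuple[float, float, float]] | None = None
    latent_af: pd.DataFrame | None = None
    seed: int | None = None


def simulate_two_subclone_panel(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[MeasurementTable, list[SampleMeta], GroundTruth]:
    """Generate a two-subclone mixture panel with ground truth.

    Per sample: a cohort, a mixing fraction from that cohort's (clipped
    normal) distribution, exact-mixture AF and affine-mixture CN values plus
    Gaussian noise (AF truncated to [0, 1], CN to >= 0), an optional injected
    outlier displacing one AF dimension, and a volume change from the
    cohort's linear model in the true anchor copy number. CRPC clones carry a
    single pure genotype so their AF values sit at quantized m/T before
    noise. Same config and seed give bit-identical output.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    g1, g2 = cfg.genotypes

    n = cfg.n_samples
    n_crpc = int(round(cfg.crpc_fraction * n))
    n_xeno = n - n_crpc

    af_markers = [m for m in cfg.panel if m.assay_kind is AssayKind.AF]
    metas: list[SampleMeta] = []
    truths: dict[str, float] = {}
    rows: list[np.ndarray] = []
    outlier_log: list[tuple[str, str, float]] = []

    def measured_values(p: float, quantized: bool) -> np.ndarray:
        vals = np.empty(len(cfg.panel))
        for j, m in enumerate(cfg.panel):
            if m.assay_kind is AssayKind.AF:
                if quantized:
                    geno = (g1 if p >= 0.5 else g2).loci[m.gene]
                    mean = geno.allele_frequency
                else:
                    mean = expected_allele_frequency(p, g1, g2, m.gene)
                vals[j] = min(1.0, max(0.0, mean + rng.normal(0.0, cfg.sigma_af)))
            else:
                if quantized:
                    mean = float((g1 if p >= 0.5 else g2).loci[m.gene].total_copies)
                else:
                    mean = expected_copy_number(p, g1, g2, m.gene)
                vals[j] = max(0.0, mean + rng.normal(0.0, cfg.sigma_cn))
        return vals

    marker_index = {m.marker_id: j for j, m in enumerate(cfg.panel)}

    for i in range(n):
        is_crpc = i >= n_xeno
        if is_crpc:
            is_clone = (i - n_xeno) % 2 == 1
            source = Source.crpc_clone if is_clone else Source.crpc_bulk
            treatment = Treatment.none
            mu, sd = cfg.fraction_params("__default__")
            if is_clone:
                p = 1.0 if rng.random() < mu else 0.0
            else:
                p = float(np.clip(rng.normal(mu, 2.0 * sd), 0.0, 1.0))
            sid = f"{'clone' if is_clone else 'culture'}{i + 1:03d}"
        else:
            source = Source.xenograft
            treatment = cfg.treatments[i % len(cfg.treatments)]
            mu, sd = cfg.fraction_params(treatment.value)
            p = float(np.clip(rng.normal(mu, sd), 0.0, 1.0))
            sid = f"x{i + 1:03d}"

        vals = measured_values(p, quantized=is_crpc and source is Source.crpc_clone)

        if cfg.outlier_rate > 0 and rng.random() < cfg.outlier_rate:
            target = af_markers[rng.integers(len(af_markers))]
            disp = cfg.outlier_displacement * (1.0 if rng.random() < 0.5 else -1.0)
            j = marker_index[target.marker_id]
            vals[j] = min(1.0, max(0.0, vals[j] + disp))
            outlier_log.append((sid, target.marker_id, disp))

        a, b, vsd = cfg.volume_models.get(treatment.value, (0.0, 0.0, 0.0))
        anchor_cn = expected_copy_number(p, g1, g2, cfg.anchor_gene)
        volume = max(-100.0, a + b * anchor_cn + rng.normal(0.0, vsd))
        if treatment is Treatment.cisplatin_retreat:
            days = float(rng.integers(50, 81))
        elif treatment is Treatment.none:
            days = math.nan
        else:
            days = float(rng.integers(21, 36))

        metas.append(
            SampleMeta(
                sample_id=sid,
                model_id=cfg.model_id,
                source=source,
                treatment=treatment,
                volume_change_pct=volume if source is Source.xenograft else math.nan,
                days=days,
            )
        )
        truths[sid] = p
        rows.append(vals)

    values = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(cfg.panel))),
        index=pd.Index([m.sample_id for m in metas], name="sample_id"),
        columns=[m.marker_id for m in cfg.panel],
    )
    table = MeasurementTable(markers=list(cfg.panel), samples=metas, values=values)
    truth = GroundTruth(
        true_fractions=pd.Series(truths, name="fraction_subclone1"),
        treatments={m.sample_id: m.treatment.value for m in metas},
        sources={m.sample_id: m.source.value for m in metas},
        outliers=outlier_log,
        genotypes=(g1, g2),
        volume_models=dict(cfg.volume_models),
        seed=cfg.seed if seed is None else seed,
    )
    return table, metas, truth


def _grid_labels(n: int) -> tuple[list[str], np.ndarray]:
    side = max(1, math.ceil(math.sqrt(n)))
    labels, coords = [], []
    for i in range(n):
        r, c = divmod(i, side)
        labels.append(f"{string.ascii_uppercase[r % 26]}{c + 1}")
        coords.append((r, c))
    return labels, np.asarray(coords, dtype=float)


def simulate_spatial_drift_panel(
    n_samples: int = 8,
    marker_ranges: dict[str, float] | None = None,
    spatial_correlation: float = 0.6,
    sigma_af: float = DEFAULT_SIGMA_AF,
    bottleneck_rate: float = 0.08,
    seed: int = 1,
    model_id: str = "SIM96",
) -> tuple[MeasurementTable, list[SampleMeta], GroundTruth]:
    """Generate spatially dissected drift samples with independent markers.

    Samples sit on a dissection grid. Each marker's latent AF follows its own
    spatially autocorrelated Gaussian field (correlation ``rho**distance``
    between grid cells), mapped through the normal CDF and scaled to the
    marker's observed AF range, so nearby sections have more similar values
    while markers stay mutually independent. With probability
    ``bottleneck_rate`` per (sample, marker), the latent value is replaced by
    a high-cellularity takeover (AF 0.15-0.20, i.e. 30-40% of cells for a
    heterozygous locus). Measurement noise is added as in the main generator.
    """
    if not 0.0 <= spatial_correlation < 1.0:
        raise ValueError("spatial_correlation must be in [0, 1)")
    ranges = dict(DEFAULT_DRIFT_RANGES if marker_ranges is None else marker_ranges)
    for gene, mx in ranges.items():
        if not 0.0 <= mx <= 1.0:
            raise ValueError(f"AF maximum for {gene} outside [0, 1]")
    rng = np.random.default_rng(seed)
    labels, coords = _grid_labels(n_samples)
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if spatial_correlation == 0.0:
        cov = np.eye(n_samples)
    else:
        cov = spatial_correlation ** dist
    cov = cov + 1e-9 * np.eye(n_samples)
    chol = np.linalg.cholesky(cov)

    panel = [MarkerDef(f"{g}_AF", g, AssayKind.AF) for g in ranges]
    sample_ids = [f"s{model_id}_{lab}" for lab in labels]
    latent = pd.DataFrame(
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[m.marker_id for m in panel],
        dtype=float,
    )
    outlier_log: list[tuple[str, str, float]] = []
    for m in panel:
        z = chol @ rng.standard_normal(n_samples)
        af = _stats.norm.cdf(z) * ranges[m.gene]
        jumps = rng.random(n_samples) < bottleneck_rate
        for i in np.flatnonzero(jumps):
            boosted = rng.uniform(0.15, 0.20)
            outlier_log.append((sample_ids[i], m.marker_id, boosted - af[i]))
            af[i] = boosted
        latent[m.marker_id] = af
    noisy = np.clip(
        latent.to_numpy() + rng.normal(0.0, sigma_af, latent.shape), 0.0, 1.0
    )
    values = pd.DataFrame(noisy, index=latent.index, columns=latent.columns)
    metas = [
        SampleMeta(
            sample_id=sid,
            model_id=model_id,
            source=Source.xenograft,
            treatment=Treatment.none,
            days=58.0,
            spatial_label=lab,
        )
        for sid, lab in zip(sample_ids, labels)
    ]
    table = MeasurementTable(markers=panel, samples=metas, values=values)
    truth = GroundTruth(
        true_fractions=pd.Series(dtype=float),
        treatments={m.sample_id: m.treatment.value for m in metas},
        sources={m.sample_id: m.source.value for m in metas},
        outliers=outlier_log,
        latent_af=latent,
        seed=seed,
    )
    return table, metas, truth
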