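import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from clonemix import (
    LocusGenotype,
    SubcloneGenotype,
    call_integer_genotype,
    cellularity_uncertainty,
    estimate_mixing_fraction,
    expected_allele_frequency,
    expected_copy_number,
    fit_marker_pair,
    fit_two_subclone_model,
    genotype_subclones,
    infer_subclone_endpoints,
    integer_deviation,
)
from clonemix.io import AssayKind, MarkerDef
from conftest import CN_RESOLVABLE


def lrp1b_genotypes():
    g1 = SubcloneGenotype(loci={"LRP1B": LocusGenotype(1, 4)})
    g2 = SubcloneGenotype(loci={"LRP1B": LocusGenotype(0, 2)})
    return g1, g2


# ---------------------------------------------------------------------------
# forward model


def test_expected_copy_number_endpoints_and_interpolation():
    g1, g2 = lrp1b_genotypes()
    assert expected_copy_number(0.0, g1, g2, "LRP1B") == 2.0
    assert expected_copy_number(1.0, g1, g2, "LRP1B") == 4.0
    assert expected_copy_number(0.7, g1, g2, "LRP1B") == pytest.approx(3.4)


def test_expected_allele_frequency_exact_mixture_curve():
    g1, g2 = lrp1b_genotypes()
    assert expected_allele_frequency(1.0, g1, g2, "LRP1B") == pytest.approx(0.25)
    assert expected_allele_frequency(0.0, g1, g2, "LRP1B") == 0.0
    # closed form (0.5*1) / (0.5*4 + 0.5*2)
    assert expected_allele_frequency(0.5, g1, g2, "LRP1B") == pytest.approx(0.5 / 3)


def test_mean_cn_scales_mutant_dose_so_pure_af_stays_at_genotype_ratio():
    g1 = SubcloneGenotype(loci={"ERBB4": LocusGenotype(1, 3)}, mean_cn={"ERBB4": 2.8})
    g2 = SubcloneGenotype(loci={"ERBB4": LocusGenotype(0, 1)}, mean_cn={"ERBB4": 1.3})
    assert expected_copy_number(1.0, g1, g2, "ERBB4") == pytest.approx(2.8)
    assert expected_allele_frequency(1.0, g1, g2, "ERBB4") == pytest.approx(1 / 3)
    assert expected_allele_frequency(0.0, g1, g2, "ERBB4") == 0.0


def test_zero_total_copy_number_errors():
    g = SubcloneGenotype(loci={"X": LocusGenotype(0, 1)}, mean_cn={"X": 0.0})
    with pytest.raises(ZeroDivisionError):
        expected_allele_frequency(0.5, g, g, "X")


def test_unknown_locus_and_bad_fraction_error():
    g1, g2 = lrp1b_genotypes()
    with pytest.raises(KeyError):
        expected_copy_number(0.5, g1, g2, "NOPE")
    with pytest.raises(ValueError):
        expected_copy_number(1.5, g1, g2, "LRP1B")


@settings(max_examples=200, deadline=None)
@given(
    p=st.floats(0.0, 1.0),
    t1=st.integers(1, 8),
    t2=st.integers(1, 8),
    data=st.data(),
)
def test_mixture_predictions_stay_in_valid_ranges(p, t1, t2, data):
    m1 = data.draw(st.integers(0, t1))
    m2 = data.draw(st.integers(0, t2))
    g1 = SubcloneGenotype(loci={"X": LocusGenotype(m1, t1)})
    g2 = SubcloneGenotype(loci={"X": LocusGenotype(m2, t2)})
    cn = expected_copy_number(p, g1, g2, "X")
    af = expected_allele_frequency(p, g1, g2, "X")
    assert cn >= 0.0
    assert 0.0 <= af <= 1.0 + 1e-12


def test_expected_copy_number_affine_and_monotone_in_p():
    g1, g2 = lrp1b_genotypes()  # cn1=4 > cn2=2
    ps = np.linspace(0, 1, 11)
    cns = [expected_copy_number(p, g1, g2, "LRP1B") for p in ps]
    assert np.all(np.diff(cns) > 0)
    # affine: second differences vanish
    assert np.allclose(np.diff(cns, 2), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# integer genotype calling


@pytest.mark.parametrize(
    "af,cn,expected",
    [
        (0.33, 2.9, (1, 3)),
        (0.48, 2.00, (1, 2)),
        (0.66, 2.86, (2, 3)),
        (0.99, 3.01, (3, 3)),
        (0.50, 4.01, (2, 4)),
        (0.0, 2.0, (0, 2)),
    ],
)
def test_integer_genotype_worked_examples(af, cn, expected):
    geno, residual = call_integer_genotype(af, cn)
    assert (geno.mutant_copies, geno.total_copies) == expected
    assert residual == pytest.approx(abs(af - expected[0] / expected[1]))


def test_tie_breaks_toward_smaller_mutant_count():
    geno, _ = call_integer_genotype(0.25, 2.0)  # equidistant from 0/2 and 1/2
    assert (geno.mutant_copies, geno.total_copies) == (0, 2)


def test_genotype_call_preconditions():
    with pytest.raises(ValueError):
        call_integer_genotype(1.2, 2.0)
    with pytest.raises(ValueError):
        call_integer_genotype(0.5, 0.4)


@settings(max_examples=300, deadline=None)
@given(t=st.integers(1, 8), data=st.data())
def test_genotype_call_round_trip(t, data):
    m = data.draw(st.integers(0, t))
    geno, residual = call_integer_genotype(m / t, float(t))
    assert (geno.mutant_copies, geno.total_copies) == (m, t)
    assert residual == 0.0


def test_genotype_call_matches_exhaustive_search(rng):
    for _ in range(1000):
        af = rng.uniform(0, 1)
        cn = rng.uniform(0.51, 8.49)
        geno, _ = call_integer_genotype(af, cn)
        t = max(1, math.floor(cn + 0.5))
        best = min(range(t + 1), key=lambda m: (abs(af - m / t), m))
        assert geno.total_copies == t
        assert geno.mutant_copies == best


# ---------------------------------------------------------------------------
# line fitting


def test_fit_marker_pair_exact_line():
    x = np.arange(5.0)
    fit = fit_marker_pair(x, 2 * x)
    assert fit.slope == pytest.approx(2.0)
    assert fit.r == pytest.approx(1.0)
    assert fit.n == 5


def test_fit_marker_pair_hand_computed_least_squares():
    # x=(0,1,2,3), y=(1,2,2,4): Sxy=4.5, Sxx=5, Syy=4.75
    fit = fit_marker_pair([0, 1, 2, 3], [1, 2, 2, 4])
    assert fit.slope == pytest.approx(4.5 / 5)
    assert fit.r == pytest.approx(4.5 / math.sqrt(5 * 4.75))
    # two-sided p from the t transform with n-2 df
    t = fit.r * math.sqrt(2) / math.sqrt(1 - fit.r**2)
    assert fit.p_value == pytest.approx(2 * stats.t.sf(t, df=2))


def test_fit_marker_pair_degenerate_inputs():
    with pytest.raises(ValueError, match="variance"):
        fit_marker_pair([1, 2, 3], [5, 5, 5])
    with pytest.raises(ValueError, match="variance"):
        fit_marker_pair([2, 2, 2], [1, 2, 3])
    with pytest.raises(ValueError, match="3"):
        fit_marker_pair([1, 2], [1, 2])


def test_fit_marker_pair_ignores_incomplete_pairs():
    x = [0, 1, 2, 3, np.nan, 5]
    y = [0, 2, 4, 6, 8, np.nan]
    fit = fit_marker_pair(x, y)
    assert fit.n == 4
    assert fit.slope == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# endpoint extrapolation and genotyping


def test_anchor_endpoints_evaluate_to_anchor_values(noise_free_panel):
    table, _, _ = noise_free_panel
    est = infer_subclone_endpoints(table)
    v1, v2 = est.endpoints["LRP1B_AF"]
    assert v1 == pytest.approx(0.25, abs=1e-9)
    assert v2 == pytest.approx(0.0, abs=1e-9)


def test_constant_marker_reported_not_fatal(noise_free_panel):
    table, _, _ = noise_free_panel
    est = infer_subclone_endpoints(table)
    # noise-free diploid controls and truncal AFs have zero spread
    assert "EXOC4_CN" in est.constant
    assert est.endpoints["EXOC4_CN"] == (2.0, 2.0)
    assert "BRCA2_AF" in est.constant
    assert not est.failed


def test_noise_free_endpoint_recovery_within_curvature_bound(noise_free_panel):
    """The linear read-off of the curved exact mixture is biased but bounded.

    The global-OLS estimate carries the full chord-vs-curve bias; the local
    estimate stays within 0.35 of the true subclone means and rounds to the
    correct integers.
    """
    table, _, _ = noise_free_panel
    for method in ("local", "ols"):
        est = infer_subclone_endpoints(table, method=method)
        e1, e2 = est.endpoints["ERBB4_CN"]
        bound = 0.35 if method == "local" else 0.6
        assert abs(e1 - 2.8) < bound
        assert abs(e2 - 1.3) < bound


def test_genotype_subclones_resolves_reference_endpoints():
    panel = [
        MarkerDef("LRP1B_AF", "LRP1B", AssayKind.AF),
        MarkerDef("LRP1B_CN1", "LRP1B", AssayKind.CN),
        MarkerDef("TP53_AF", "TP53", AssayKind.AF),
        MarkerDef("TP53_CN", "TP53", AssayKind.CN),
    ]
    endpoints = {
        "LRP1B_AF": (0.25, 0.0),
        "LRP1B_CN1": (4.0, 2.0),
        "TP53_AF": (0.99, 0.99),
        "TP53_CN": (3.01, 3.01),
    }
    calls = genotype_subclones(endpoints, panel)
    g1, g2 = calls.subclone1, calls.subclone2
    assert (g1.loci["LRP1B"].mutant_copies, g1.loci["LRP1B"].total_copies) == (1, 4)
    assert (g2.loci["LRP1B"].mutant_copies, g2.loci["LRP1B"].total_copies) == (0, 2)
    assert (g1.loci["TP53"].mutant_copies, g1.loci["TP53"].total_copies) == (3, 3)
    assert (g2.loci["TP53"].mutant_copies, g2.loci["TP53"].total_copies) == (3, 3)
    assert g1.mean_cn["LRP1B"] == 4.0  # non-integer endpoint retained as mean_cn


def test_genotype_subclones_clips_small_extrapolation_overshoot():
    panel = [MarkerDef("ERBB4_AF", "ERBB4", AssayKind.AF)]
    with pytest.warns(UserWarning, match="clipped"):
        calls = genotype_subclones({"ERBB4_AF": (0.5, -0.02)}, panel)
    assert calls.subclone2.loci["ERBB4"].mutant_copies == 0
    assert "ERBB4" in calls.assumed_diploid  # no CN endpoint -> T = 2 flagged


def test_gene_with_multiple_cn_assays_uses_their_mean():
    panel = [
        MarkerDef("LRP1B_AF", "LRP1B", AssayKind.AF),
        MarkerDef("LRP1B_CN1", "LRP1B", AssayKind.CN),
        MarkerDef("LRP1B_CN2", "LRP1B", AssayKind.CN),
    ]
    endpoints = {
        "LRP1B_AF": (0.25, 0.0),
        "LRP1B_CN1": (3.8, 1.9),
        "LRP1B_CN2": (4.2, 2.1),
    }
    calls = genotype_subclones(endpoints, panel)
    assert calls.subclone1.mean_cn["LRP1B"] == pytest.approx(4.0)
    assert calls.subclone2.mean_cn["LRP1B"] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# mixing fractions and scalar helpers


def test_estimate_mixing_fraction_interpolation_and_clipping():
    g1, g2 = lrp1b_genotypes()
    assert estimate_mixing_fraction(3.4, g1, g2, "LRP1B") == pytest.approx(0.7)
    assert estimate_mixing_fraction(2.0, g1, g2, "LRP1B") == 0.0
    assert estimate_mixing_fraction(4.2, g1, g2, "LRP1B") == 1.0


def test_estimate_mixing_fraction_uninformative_anchor_errors():
    g = SubcloneGenotype(loci={"EXOC4": LocusGenotype(0, 2)})
    with pytest.raises(ValueError, match="uninformative"):
        estimate_mixing_fraction(2.0, g, g, "EXOC4")


@pytest.mark.parametrize("af_sd,expected", [(0.011, 0.022), (0.0, 0.0), (0.015, 0.030)])
def test_cellularity_uncertainty_doubles_af_sd(af_sd, expected):
    assert cellularity_uncertainty(af_sd) == pytest.approx(expected)


@pytest.mark.parametrize("cn,dev", [(2.8, 0.2), (1.3, 0.3), (4.0, 0.0)])
def test_integer_deviation_examples(cn, dev):
    assert integer_deviation(cn) == pytest.approx(dev)


# ---------------------------------------------------------------------------
# end-to-end identifiability


def test_noise_free_pipeline_recovers_genotypes_and_fractions(noise_free_panel):
    table, _, truth = noise_free_panel
    fit = fit_two_subclone_model(table)
    for gene, (want1, want2) in CN_RESOLVABLE.items():
        got1 = fit.subclone1.loci[gene]
        got2 = fit.subclone2.loci[gene]
        assert (got1.mutant_copies, got1.total_copies) == want1, gene
        assert (got2.mutant_copies, got2.total_copies) == want2, gene
    err = (fit.fractions - truth.true_fractions).abs()
    assert float(err.max()) <= 0.02
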