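"""Unit and property tests for the nine-step contaminant filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocuscrub import (
    CountTable,
    FilterConfig,
    FilterError,
    LuminosityTable,
    SampleMetadata,
    SimulationConfig,
    filter_samples_by_depth,
    fit_control_regression,
    generate_experiment,
    regression_retain,
    relative_luminosity,
    remove_rare_otus,
    run_contaminant_pipeline,
    sample_type_means,
    to_relative,
    truth_confusion,
    weight_by_luminosity,
)

# ---------------------------------------------------------------------------
# Independent oracle: closed-form OLS via explicit sums, residual enumeration


def ols_oracle(x, y):
    """Normal-equation OLS in plain Python, independent of the implementation."""
    n = len(x)
    xm = sum(x) / n
    ym = sum(y) / n
    sxx = sum((xi - xm) ** 2 for xi in x)
    sxy = sum((xi - xm) * (yi - ym) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = ym - slope * xm
    rss = sum((yi - (intercept + slope * xi)) ** 2 for xi, yi in zip(x, y))
    residual_se = math.sqrt(rss / (n - 2))
    return slope, intercept, residual_se, xm, sxx


def retain_oracle(x, y, otus, multiplier):
    """Enumerate residuals; keep points above m standard errors of the fit."""
    slope, intercept, se, xm, sxx = ols_oracle(x, y)
    n = len(x)
    kept = []
    for xi, yi, otu in zip(x, y, otus):
        residual = yi - (intercept + slope * xi)
        threshold = multiplier * se * math.sqrt(1.0 / n + (xi - xm) ** 2 / sxx)
        if residual > threshold:
            kept.append(otu)
    return sorted(kept)


def random_means_instance(rng, n_otus):
    otus = [f"OTU{i}" for i in range(n_otus)]
    subject = rng.lognormal(-6, 2, n_otus)
    control = rng.lognormal(-6, 2, n_otus)
    # sprinkle zeros to exercise the pseudocount
    subject[rng.random(n_otus) < 0.15] = 0.0
    control[rng.random(n_otus) < 0.15] = 0.0
    if not (subject + control).any():
        subject[0] = 1e-4
    return pd.Series(subject, index=otus), pd.Series(control, index=otus), otus


# ---------------------------------------------------------------------------
# Steps (a)-(e)


class TestDepthFilter:
    def test_strict_less_than_boundary(self):
        df = pd.DataFrame(
            {"O1": [10_000, 9_999, 54_652]}, index=["A", "B", "C"]
        )
        kept = filter_samples_by_depth(CountTable(df), 10_000)
        assert kept.sample_ids == ["A", "C"]
        assert kept.otu_ids == ["O1"]

    def test_identity_when_all_deep(self, tiny_counts):
        assert filter_samples_by_depth(tiny_counts, 1) == tiny_counts

    def test_all_shallow_is_fatal(self, tiny_counts):
        with pytest.raises(FilterError, match=r"step \(a\)"):
            filter_samples_by_depth(tiny_counts, 10**9)


class TestRelativeAbundance:
    def test_rows_sum_to_one(self):
        rel = to_relative(CountTable(pd.DataFrame({"a": [2], "b": [2], "c": [4]})))
        assert np.allclose(rel.to_numpy(), [[0.25, 0.25, 0.5]])
        one = to_relative(CountTable(pd.DataFrame({"a": [7]})))
        assert one.iloc[0, 0] == 1.0

    def test_zero_total_sample_rejected(self):
        table = CountTable(pd.DataFrame({"a": [0, 1], "b": [0, 1]}))
        with pytest.raises(FilterError, match=r"step \(b\)"):
            to_relative(table)


class TestLuminosityWeighting:
    def test_proportional_weights(self):
        w = relative_luminosity(pd.Series({"A": 200.0, "B": 100.0, "C": 50.0}))
        assert w.to_dict() == {"A": 1.0, "B": 0.5, "C": 0.25}

    def test_equal_luminosities_give_unit_weights(self):
        w = relative_luminosity(pd.Series({"A": 3.0, "B": 3.0}))
        assert (w == 1.0).all()

    def test_zero_band_gets_zero_weight(self):
        w = relative_luminosity(pd.Series({"A": 100.0, "B": 0.0}))
        assert w.to_dict() == {"A": 1.0, "B": 0.0}

    def test_literal_mode_inverts_the_weighting(self):
        w = relative_luminosity(
            pd.Series({"A": 200.0, "B": 100.0, "C": 50.0}), mode="literal"
        )
        assert w.to_dict() == {"A": 0.0, "B": 0.5, "C": 0.75}

    def test_weighting_scales_rows(self):
        rel = pd.DataFrame({"O1": [0.5, 0.4], "O2": [0.5, 0.6]}, index=["A", "B"])
        weighted = weight_by_luminosity(rel, pd.Series({"A": 0.5, "B": 0.0}))
        assert np.allclose(weighted.loc["A"], [0.25, 0.25])
        assert (weighted.loc["B"] == 0).all()

    def test_missing_weight_rejected(self):
        rel = pd.DataFrame({"O1": [0.5]}, index=["A"])
        with pytest.raises(FilterError, match="luminosity"):
            weight_by_luminosity(rel, pd.Series({"B": 1.0}))


class TestSampleTypeMeans:
    def test_zeros_count_toward_the_mean(self, tiny_metadata):
        weighted = pd.DataFrame(
            {"O1": [0.2, 0.4, 0.1, 0.0], "O2": [0.0, 0.0, 0.0, 0.0]},
            index=["A", "B", "C", "D"],
        )
        means = sample_type_means(weighted, tiny_metadata)
        assert means.loc["O1", "subject"] == pytest.approx(0.3)
        assert means.loc["O1", "blank_control"] == pytest.approx(0.1)  # single sample
        assert (means.loc["O2"] == 0).all()  # absent everywhere -> three zero means

    def test_missing_sample_type_rejected(self, tiny_metadata):
        weighted = pd.DataFrame({"O1": [0.2, 0.4]}, index=["A", "B"])
        with pytest.raises(FilterError, match=r"step \(d\)"):
            sample_type_means(weighted, tiny_metadata)


class TestRareOtuRemoval:
    def test_share_below_threshold_removed(self):
        means = pd.Series({"O1": 0.5, "O2": 0.5e-7})
        kept = remove_rare_otus(means, 1e-6)
        assert list(kept) == ["O1"]
        # direct-division check of the derived share
        assert 0.5e-7 / means.sum() < 1e-6

    def test_equal_means_all_retained(self):
        means = pd.Series({"O1": 0.1, "O2": 0.1, "O3": 0.1})
        assert len(remove_rare_otus(means, 1e-6)) == 3

    def test_boundary_share_is_retained(self):
        """Removal is strict 'less than': a share exactly at the cut stays."""
        rare = 0.25
        means = pd.Series({"O1": 0.75, "O2": 0.25})
        assert list(remove_rare_otus(means, rare)) == ["O1", "O2"]

    def test_empty_retention_is_fatal(self):
        with pytest.raises(FilterError, match=r"step \(e\)"):
            remove_rare_otus(pd.Series({"O1": 0.0}), 1e-6)


# ---------------------------------------------------------------------------
# Regression passes


class TestRegression:
    def test_perfect_fit_on_identical_means(self):
        means = pd.Series({"O1": 1e-3, "O2": 1e-2, "O3": 1e-1, "O4": 1.0})
        fit = fit_control_regression(means, means, means.index)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.residual_se == pytest.approx(0.0, abs=1e-12)
        # strict inequality: nothing exceeds a zero-width band
        assert regression_retain(fit, means, means, means.index, 5.0) == []

    def test_outlier_case_matches_oracle(self):
        subject = pd.Series({"O1": 0.1, "O2": 0.2, "O3": 0.3, "O4": 4.0})
        control = pd.Series({"O1": 0.1, "O2": 0.2, "O3": 0.3, "O4": 0.4})
        fit = fit_control_regression(subject, control, subject.index)
        eps = fit.pseudocount
        x = [math.log(v + eps) for v in control]
        y = [math.log(v + eps) for v in subject]
        slope, intercept, se, xm, sxx = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.residual_se == pytest.approx(se, abs=1e-10)
        for multiplier in (0.5, 1.0, 5.0):
            assert regression_retain(
                fit, subject, control, subject.index, multiplier
            ) == retain_oracle(x, y, list(subject.index), multiplier)

    def test_zero_predictor_variance_rejected(self):
        subject = pd.Series({"O1": 0.1, "O2": 0.2, "O3": 0.3})
        control = pd.Series({"O1": 0.2, "O2": 0.2, "O3": 0.2})
        with pytest.raises(FilterError, match="regression undefined"):
            fit_control_regression(subject, control, subject.index)

    def test_too_few_otus_rejected(self):
        means = pd.Series({"O1": 0.1, "O2": 0.2})
        with pytest.raises(FilterError, match="at least 3"):
            fit_control_regression(means, means, means.index)

    def test_huge_multiplier_retains_nothing(self):
        rng = np.random.default_rng(0)
        subject, control, otus = random_means_instance(rng, 20)
        fit = fit_control_regression(subject, control, otus)
        assert regression_retain(fit, subject, control, otus, 1e6) == []

    def test_random_instances_match_oracle(self):
        """OLS parameters to 1e-10 and retained sets exactly, many instances."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            subject, control, otus = random_means_instance(rng, n)
            try:
                fit = fit_control_regression(subject, control, otus)
            except FilterError:
                continue  # degenerate draw (zero predictor variance)
            eps = fit.pseudocount
            x = [math.log(v + eps) for v in control]
            y = [math.log(v + eps) for v in subject]
            slope, intercept, se, _, _ = ols_oracle(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.residual_se == pytest.approx(se, abs=1e-10)
            multiplier = float(rng.uniform(0.2, 6.0))
            assert regression_retain(fit, subject, control, otus, multiplier) == \
                retain_oracle(x, y, otus, multiplier)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_retained_set_shrinks_with_multiplier(self, seed):
        rng = np.random.default_rng(seed)
        subject, control, otus = random_means_instance(rng, 25)
        try:
            fit = fit_control_regression(subject, control, otus)
        except FilterError:
            return
        previous = None
        for multiplier in (0.5, 1.0, 2.0, 5.0, 10.0):
            kept = set(regression_retain(fit, subject, control, otus, multiplier))
            if previous is not None:
                assert kept <= previous
            previous = kept


# ---------------------------------------------------------------------------
# Full pipeline


def _run(bundle, config=None):
    return run_contaminant_pipeline(
        bundle.counts, bundle.metadata, bundle.luminosity, config
    )


class TestPipeline:
    def test_attrition_is_monotone(self, small_bundle):
        result = _run(small_bundle)
        assert result.report.otu_counts_monotone()
        letters = [s.step for s in result.report.steps]
        assert letters == list("abcdefghi")

    def test_luminosity_scale_equivariance(self, small_bundle):
        """Multiplying all luminosities by a constant changes nothing."""
        result = _run(small_bundle)
        scaled = LuminosityTable(small_bundle.luminosity.values * 37.5)
        result_scaled = run_contaminant_pipeline(
            small_bundle.counts, small_bundle.metadata, scaled
        )
        assert result.retained_otus == result_scaled.retained_otus

    def test_rare_filter_shrinks_with_rare_fraction(self):
        """The rare-OTU step retains nested sets as the threshold tightens.

        (The end-to-end retained set is *not* monotone in rare_fraction:
        changing the OTU pool refits the regression, so downstream retention
        can flip either way.  Monotonicity is a property of the step.)
        """
        rng = np.random.default_rng(8)
        means = pd.Series(rng.lognormal(-6, 3, 200),
                          index=[f"OTU{i:03d}" for i in range(200)])
        previous = None
        for rare in (1e-8, 1e-6, 1e-4, 1e-2):
            kept = set(remove_rare_otus(means, rare))
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_input_order_invariance(self, small_bundle):
        result = _run(small_bundle)
        rng = np.random.default_rng(5)
        shuffled = CountTable(
            small_bundle.counts.data
            .sample(frac=1, random_state=1)
            .sample(frac=1, axis=1, random_state=2)
        )
        result_shuffled = run_contaminant_pipeline(
            shuffled, small_bundle.metadata, small_bundle.luminosity
        )
        assert result.retained_otus == result_shuffled.retained_otus
        assert result.report.to_frame().equals(result_shuffled.report.to_frame())

    def test_no_excess_abundance_yields_empty_set(self):
        """Subject abundances fully predicted by controls -> nothing retained."""
        rng = np.random.default_rng(11)
        n_otus = 30
        otus = [f"OTU{i:03d}" for i in range(n_otus)]
        profile = rng.lognormal(-3, 1.5, n_otus)
        rows, index, types = [], [], []
        for i in range(6):
            depth_profile = profile * rng.lognormal(0, 0.05, n_otus)
            rows.append(np.round(depth_profile / depth_profile.sum() * 50_000))
            index.append(f"S{i}")
            types.append("subject")
        for i, stype in [(0, "blank_control"), (1, "blank_control"), (2, "water_control")]:
            depth_profile = profile * rng.lognormal(0, 0.05, n_otus)
            rows.append(np.round(depth_profile / depth_profile.sum() * 50_000))
            index.append(f"C{i}")
            types.append(stype)
        counts = CountTable(pd.DataFrame(np.array(rows), index=index, columns=otus))
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_type": types,
                    "subject_id": [f"P{i}" for i in range(6)] + [pd.NA] * 3,
                    "time_point": ["baseline"] * 6 + [pd.NA] * 3,
                },
                index=index,
            )
        )
        lum = LuminosityTable(pd.Series(100.0, index=index))
        result = run_contaminant_pipeline(counts, meta, lum)
        assert result.retained_otus == ()
        assert result.filtered_counts is None
        # report pinpoints where attrition reached zero
        by_step = {s.step: s.n_otus_retained for s in result.report.steps}
        assert by_step["i"] == 0
        assert result.report.otu_counts_monotone()

    def test_stage_errors_carry_step_letters(self, small_bundle):
        with pytest.raises(FilterError, match=r"step \(a\)"):
            _run(small_bundle, FilterConfig(min_depth=10**9))

    def test_recovers_residents_in_contaminant_rich_regime(self):
        """Parameter recovery in the regime the filter is designed for.

        With a large reagent pool (residents are ~2% of OTUs), the cascade
        keeps the resident OTUs and discards essentially all contaminants.
        """
        sens, spec = [], []
        for seed in range(5):
            cfg = SimulationConfig(seed=seed, n_contaminant_otus=2000)
            bundle = generate_experiment(cfg)
            result = _run(bundle)
            confusion = truth_confusion(result.retained_otus, bundle.truth)
            sens.append(confusion.sensitivity)
            spec.append(confusion.specificity)
        assert np.median(sens) >= 0.9
        assert np.median(spec) >= 0.9
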