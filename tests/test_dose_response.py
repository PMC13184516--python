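"""4PL fitting, standardized areas, normalization and binarization."""

import math

import numpy as np
import pandas as pd
import pytest

from drpeval import (
    DoseResponseExperiment,
    FourParamLogistic,
    FourPLResults,
    ResponseType,
    StandardRange,
    TripletDataset,
    aadrc,
    absolute_ic50,
    audrc,
    audrc_trapezoid_experimental,
    binarize,
    fit_4pl,
    four_pl,
    normalize_responses,
)


def _experiment(upper, lower, inflection, hill, conc=None, noise=None, seed=0):
    conc = np.logspace(-10, -4, 9) if conc is None else conc
    viab = four_pl(conc, upper, lower, inflection, hill)
    if noise:
        viab = viab + np.random.default_rng(seed).normal(0, noise, len(conc))
    return DoseResponseExperiment("e", "C", "D", conc, np.asarray(viab))


def _fit_result(upper, lower, inflection, hill):
    """A results object with prescribed parameters (no fitting)."""
    return FourPLResults(
        model=None, upper=upper, lower=lower, inflection=inflection, hill=hill,
        converged=True, identifiable=True, rss=0.0, n_points=9,
    )


def trapezoid_audrc_oracle(fit, srange=StandardRange(), n=10_001):
    """Independent dense-trapezoid reference for the standardized area."""
    x = np.linspace(math.log10(srange.cmin), math.log10(srange.cmax), n)
    y = np.clip(four_pl(10.0**x, fit.upper, fit.lower, fit.inflection, fit.hill), 0, 1)
    return np.trapezoid(y, x) / (x[-1] - x[0])


class TestFit4PL:
    @pytest.mark.parametrize(
        "params",
        [
            (1.0, 0.0, 1e-7, 1.0),
            (1.05, 0.1, 1e-8, 2.5),
            (0.95, 0.05, 1e-6, 0.7),
        ],
    )
    def test_noiseless_recovery(self, params):
        upper, lower, inflection, hill = params
        fit = fit_4pl(_experiment(*params))
        assert fit.converged
        assert fit.upper == pytest.approx(upper, rel=1e-6, abs=1e-6)
        assert fit.lower == pytest.approx(lower, rel=1e-6, abs=1e-6)
        assert fit.inflection == pytest.approx(inflection, rel=1e-6)
        assert fit.hill == pytest.approx(hill, rel=1e-6)

    def test_noisy_recovery_median_within_10pct(self):
        # 30 replicate fits here; the full 100-curve check runs in the
        # acceptance suite
        errs = []
        for seed in range(30):
            exp = _experiment(1.0, 0.0, 1e-7, 1.0, noise=0.02, seed=seed)
            fit = fit_4pl(exp)
            errs.append(abs(math.log10(fit.inflection / 1e-7)))
        assert np.median(errs) < math.log10(1.1)

    def test_flat_response_degenerate(self):
        exp = DoseResponseExperiment(
            "e", "C", "D", np.logspace(-9, -5, 5), np.ones(5)
        )
        fit = fit_4pl(exp)
        assert not fit.identifiable
        assert fit.upper == fit.lower == 1.0
        assert fit.hill == 0.0

    def test_model_results_summary(self, symmetric_curve_experiment):
        res = FourParamLogistic(symmetric_curve_experiment).fit()
        text = res.summary()
        assert "EC50" in text and "AUDRC" in text and "Hill" in text

    def test_fit_is_deterministic(self, symmetric_curve_experiment):
        a = fit_4pl(symmetric_curve_experiment)
        b = fit_4pl(symmetric_curve_experiment)
        assert (a.upper, a.lower, a.inflection, a.hill) == (
            b.upper, b.lower, b.inflection, b.hill
        )


class TestAbsoluteIC50:
    def test_symmetric_curve_ic50_equals_inflection(self):
        assert absolute_ic50(_fit_result(1, 0, 1e-7, 1)) == pytest.approx(1e-7)

    def test_unreached_threshold_is_undefined(self):
        assert math.isnan(absolute_ic50(_fit_result(1, 0.6, 1e-7, 1)))

    def test_closed_form_matches_numeric_root(self):
        fit = _fit_result(1, 0, 1e-7, 2)
        c = absolute_ic50(fit, threshold=0.2)
        assert c == pytest.approx(2e-7, rel=1e-12)
        # independent check: the curve actually crosses 0.2 there
        assert four_pl(c, 1, 0, 1e-7, 2) == pytest.approx(0.2, rel=1e-12)

    def test_zero_hill_is_undefined(self):
        assert math.isnan(absolute_ic50(_fit_result(1, 0, 1e-7, 0)))


class TestAUDRC:
    def test_flat_no_effect_curve_is_one(self):
        assert audrc(_fit_result(1.0, 1.0, 1e-7, 1.0)) == pytest.approx(1.0)

    def test_symmetric_curve_is_half(self):
        assert audrc(_fit_result(1, 0, 1e-7, 1)) == pytest.approx(0.5, abs=1e-8)

    def test_shifted_inflection_closed_form(self):
        # closed-form logistic integral: (1/6) * [u - log10(1+10^u)] over u in [-4, 2]
        val = audrc(_fit_result(1, 0, 1e-6, 1))
        expected = (
            (2 - math.log10(1 + 10**2)) - (-4 - math.log10(1 + 10**-4))
        ) / 6
        assert val == pytest.approx(expected, abs=1e-8)
        assert val == pytest.approx(0.6660, abs=5e-4)

    def test_aadrc_complement(self):
        fit = _fit_result(1, 0, 1e-6, 1)
        assert aadrc(fit) == pytest.approx(1 - audrc(fit))
        assert aadrc(_fit_result(1, 1, 1e-7, 1)) == pytest.approx(0.0)

    def test_quad_matches_dense_trapezoid_on_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(25):  # full 100-point grid runs in acceptance
            fit = _fit_result(
                rng.uniform(0.8, 1.2), rng.uniform(-0.1, 0.3),
                10 ** rng.uniform(-9, -5), rng.uniform(0.3, 5),
            )
            assert audrc(fit) == pytest.approx(trapezoid_audrc_oracle(fit), abs=1e-6)

    def test_monotone_in_potency(self):
        # a more potent drug (smaller EC50) kills over more of the window
        vals = [audrc(_fit_result(1, 0, e, 1.5)) for e in (1e-8, 1e-7, 1e-6)]
        assert vals[0] < vals[1] < vals[2]

    def test_clamping_bounds_result(self):
        # asymptotes far outside [0, 1] still give an area in [0, 1]
        val = audrc(_fit_result(1.8, -0.5, 1e-7, 1.0))
        assert 0.0 <= val <= 1.0


class TestStandardizationContrast:
    """Standardized AUDRC is range-invariant; the legacy trapezoid is not."""

    def test_flat_curve_trapezoid_is_one(self):
        exp = DoseResponseExperiment(
            "e", "C", "D", np.logspace(-8, -5, 5), np.ones(5)
        )
        assert audrc_trapezoid_experimental(exp) == pytest.approx(1.0)

    def test_trapezoid_depends_on_sampling_range(self):
        params = (1.0, 0.0, 1e-7, 1.0)
        narrow = _experiment(*params, conc=np.logspace(-9, -5, 9))
        wide = _experiment(*params, conc=np.logspace(-8, -4, 9))
        legacy_narrow = audrc_trapezoid_experimental(narrow)
        legacy_wide = audrc_trapezoid_experimental(wide)
        assert legacy_narrow != pytest.approx(legacy_wide, abs=1e-3)
        # whereas fitted standardized AUDRC agrees across ranges
        std_narrow = audrc(fit_4pl(narrow))
        std_wide = audrc(fit_4pl(wide))
        assert std_narrow == pytest.approx(std_wide, abs=1e-6)

    def test_trapezoid_deterministic(self):
        exp = _experiment(1, 0, 1e-7, 1)
        assert audrc_trapezoid_experimental(exp) == audrc_trapezoid_experimental(exp)

    def test_standard_range_span(self):
        assert StandardRange().span_log10 == pytest.approx(6.0)
        with pytest.raises(ValueError):
            StandardRange(cmin=1e-4, cmax=1e-10)


def _triplets(responses, drugs=None, cells=None):
    n = len(responses)
    df = pd.DataFrame(
        {
            "cell_id": cells or [f"C{i}" for i in range(n)],
            "drug_id": drugs or ["D0"] * n,
            "response": responses,
        }
    )
    return TripletDataset(df, ResponseType.LN_IC50)


class TestNormalizeResponses:
    def test_global_minmax_linear_map(self):
        out = normalize_responses(_triplets([2.0, 4.0, 6.0]), "minmax_global")
        assert out.df["response"].tolist() == [0.0, 0.5, 1.0]
        assert out.response_type is ResponseType.NORMALIZED

    def test_center_per_drug(self):
        ds = _triplets([1, 3, 10, 30], drugs=["A", "A", "B", "B"])
        out = normalize_responses(ds, "center_per_drug")
        assert out.df["response"].tolist() == [-1.0, 1.0, -10.0, 10.0]

    def test_center_per_drug_zero_mean_property(self):
        rng = np.random.default_rng(2)
        ds = _triplets(
            rng.normal(size=60),
            drugs=[f"D{i % 5}" for i in range(60)],
            cells=[f"C{i}" for i in range(60)],
        )
        out = normalize_responses(ds, "center_per_drug")
        means = out.df.groupby("drug_id")["response"].mean()
        assert np.abs(means.to_numpy()).max() < 1e-12

    def test_zero_variance_group_maps_to_midpoint(self, caplog):
        ds = _triplets([5.0, 5.0, 1.0, 2.0], drugs=["A", "A", "B", "B"])
        with caplog.at_level("WARNING", logger="drpeval"):
            out = normalize_responses(ds, "minmax_per_drug")
        assert out.df["response"].tolist() == [0.5, 0.5, 0.0, 1.0]

    def test_empty_dataset_rejected(self):
        empty = TripletDataset(pd.DataFrame(columns=["cell_id", "drug_id", "response"]))
        with pytest.raises(ValueError):
            normalize_responses(empty, "minmax_global")


class TestBinarize:
    def test_quartile_calls_with_interpolated_percentiles(self):
        ds = _triplets(list(range(1, 9)))
        calls = binarize(ds, 25, 75, scope="per_drug")
        by_resp = dict(zip(ds.df["cell_id"], calls.set_index("cell_id")["call"]))
        # P25 = 2.75, P75 = 6.25 under linear interpolation
        assert [by_resp[f"C{i}"] for i in range(8)] == [
            "sensitive", "sensitive", "undefined", "undefined",
            "undefined", "undefined", "resistant", "resistant",
        ]

    def test_boundary_percentiles_label_only_extremes(self):
        ds = _triplets([1.0, 2.0, 3.0, 4.0, 5.0])
        calls = binarize(ds, 0, 100).set_index("cell_id")["call"]
        assert calls["C0"] == "sensitive"
        assert calls["C4"] == "resistant"
        assert (calls[["C1", "C2", "C3"]] == "undefined").all()

    def test_constant_group_all_undefined(self, caplog):
        ds = _triplets([2.0] * 5)
        with caplog.at_level("WARNING", logger="drpeval"):
            calls = binarize(ds)
        assert (calls["call"] == "undefined").all()

    def test_small_group_skipped(self, caplog):
        ds = _triplets([1.0, 2.0, 3.0], cells=["C0", "C1", "C2"])
        with caplog.at_level("WARNING", logger="drpeval"):
            calls = binarize(ds)
        assert calls.empty

    def test_bad_percentile_order_rejected(self):
        with pytest.raises(ValueError):
            binarize(_triplets([1.0] * 4), low_pct=80, high_pct=20)
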