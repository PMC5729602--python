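"""Reference-range fitting, indeterminate regions and classification."""

import hashlib
from importlib import resources

import numpy as np
import pytest

from lvfractal import (
    ValidationError,
    classify,
    fit_reference,
    limits,
    load_reference_table,
    simulate_cohort,
    table_row,
)
from lvfractal.normative import LABELS, classify_row

# frozen digest of the packaged decade tables (FD + strain, both sexes)
TABLE_SHA256 = "94ff3bd0bd5f5986a807f9b709d53ab671298068e922dad1bb3aba6dd17b7632"


@pytest.fixture(scope="module")
def fitted_model():
    cohort = simulate_cohort(n_per_sex=500, seed=7)
    return fit_reference(cohort, metric="global_fd")


class TestFitReference:
    def test_recovers_generating_parameters(self, fitted_model):
        """Slope, sex gap and residual SD of the generator are recovered
        from a 500-per-sex cohort (generator parameters are the oracle)."""
        male = fitted_model.models["male"]
        female = fitted_model.models["female"]
        assert male.slope == pytest.approx(0.0004, abs=1e-4)
        assert female.slope == pytest.approx(0.0004, abs=1e-4)
        gap = male.intercept - female.intercept
        assert gap == pytest.approx(0.021, abs=0.004)
        assert male.resid_sd == pytest.approx(0.029, abs=0.003)
        assert female.resid_sd == pytest.approx(0.029, abs=0.003)

    def test_zero_noise_band_collapses_onto_line(self):
        cohort = simulate_cohort(n_per_sex=50, residual_sd=0.0, seed=1)
        model = fit_reference(cohort, metric="global_fd")
        sm = model.models["male"]
        lo, hi = sm.prediction_limits(45.0)
        assert hi - lo < 1e-10
        assert sm.predict(45.0) == pytest.approx(1.201 + 0.0004 * 45, abs=1e-9)

    def test_single_sex_cohort_warns_and_fits_present_sex(self):
        cohort = simulate_cohort(n_per_sex=50, seed=2)
        cohort = cohort[cohort["sex"] == "female"]
        with pytest.warns(UserWarning, match="male"):
            model = fit_reference(cohort, metric="global_fd")
        assert set(model.models) == {"female"}

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(n_per_sex=5)

    def test_prediction_band_covers_95_percent_of_fresh_draws(self, fitted_model):
        fresh = simulate_cohort(n_per_sex=2500, seed=123)
        inside = total = 0
        for sex, sm in fitted_model.models.items():
            sub = fresh[fresh["sex"] == sex]
            los, his = zip(*(sm.prediction_limits(a) for a in sub["age"]))
            v = sub["value"].to_numpy()
            inside += int(np.sum((v >= np.array(los)) & (v <= np.array(his))))
            total += len(sub)
        assert inside / total == pytest.approx(0.95, abs=0.015)


class TestLimits:
    def test_deterministic_for_fixed_seed(self, fitted_model):
        a = limits(fitted_model, "male", 40.0, n_boot=400, seed=9)
        b = limits(fitted_model, "male", 40.0, n_boot=400, seed=9)
        assert a == b

    def test_indeterminate_width_shrinks_with_sample_size(self):
        """Bootstrap CI of the reference limit narrows as n grows
        (sampling SD of the limit scales like 1/sqrt(n))."""
        widths = []
        for n in (50, 200, 800):
            cohort = simulate_cohort(n_per_sex=n, seed=21)
            model = fit_reference(cohort, metric="global_fd")
            row = limits(model, "male", 45.0, n_boot=600, seed=3)
            widths.append(row.upper_pair[1] - row.upper_pair[0])
        assert widths[0] > widths[1] > widths[2]

    def test_age_outside_span_rejected(self, fitted_model):
        with pytest.raises(ValidationError):
            limits(fitted_model, "male", 95.0)

    def test_small_bootstrap_rejected(self, fitted_model):
        with pytest.raises(ValidationError):
            limits(fitted_model, "male", 40.0, n_boot=100)

    def test_delta_method_agrees_with_bootstrap_roughly(self, fitted_model):
        boot = limits(fitted_model, "male", 45.0, n_boot=2000, seed=0)
        delta = limits(fitted_model, "male", 45.0, method="delta")
        bw = boot.upper_pair[1] - boot.upper_pair[0]
        dw = delta.upper_pair[1] - delta.upper_pair[0]
        assert dw == pytest.approx(bw, rel=0.35)


class TestPackagedTables:
    def test_table_checksum_frozen(self):
        data = (resources.files("lvfractal.data")
                .joinpath("reference_ranges.csv").read_bytes())
        assert hashlib.sha256(data).hexdigest() == TABLE_SHA256

    def test_table_covers_all_metrics_sexes_decades(self):
        t = load_reference_table()
        assert len(t) == 60  # 6 metrics x 2 sexes x 5 decades
        assert set(t["sex"]) == {"male", "female"}
        assert len(set(t["metric"])) == 6

    def test_male_global_fd_decade_rows(self):
        row = table_row("global_fd", "male", 25)
        assert row.lower_pair == (1.141, 1.156)
        assert row.mean == 1.199
        assert row.upper_pair == (1.243, 1.257)
        row = table_row("global_fd", "female", 65)
        assert row.lower_pair == (1.140, 1.154)
        assert row.mean == 1.197
        assert row.upper_pair == (1.240, 1.254)

    def test_fd_rows_are_ordered(self):
        t = load_reference_table()
        fd = t[t["metric"].str.endswith("fd")]
        assert (fd["lower_lo"] < fd["lower_hi"]).all()
        assert (fd["lower_hi"] < fd["mean"]).all()
        assert (fd["mean"] < fd["upper_lo"]).all()
        assert (fd["upper_lo"] < fd["upper_hi"]).all()


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.10, "abnormal-low"),
            (1.15, "indeterminate-low"),
            (1.199, "normal"),
            (1.25, "indeterminate-high"),
            (1.30, "abnormal-high"),
        ],
    )
    def test_male_age_25_global_fd_worked_examples(self, value, expected):
        c = classify(None, "global_fd", "male", 25, value)
        assert c.label == expected
        assert c.source == "packaged table"

    def test_monotone_in_value(self):
        """Increasing FD never moves the label toward normal/low."""
        row = table_row("global_fd", "female", 43)
        values = np.linspace(1.0, 1.45, 300)
        ranks = [LABELS.index(classify_row(row, v)) for v in values]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))

    def test_negative_strain_orientation(self):
        """Circumferential strain is negative: more negative than the
        tabulated upper pair is abnormal-high (hyper-deformation side)."""
        row = table_row("strain_circumferential", "male", 25)
        assert classify_row(row, -24.5) == "abnormal-high"
        assert classify_row(row, -19.4) == "normal"
        assert classify_row(row, -14.0) == "abnormal-low"
        assert classify_row(row, -15.5) == "indeterminate-low"

    def test_age_outside_table_coverage_rejected(self):
        with pytest.raises(ValidationError):
            classify(None, "global_fd", "male", 75, 1.2)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValidationError):
            classify(None, "nope", "male", 25, 1.2)

    def test_fitted_model_path(self, fitted_model):
        c = classify(fitted_model, "global_fd", "female", 30, 1.35,
                     n_boot=400, seed=2)
        assert c.label == "abnormal-high"
        assert c.source == "fitted model"
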