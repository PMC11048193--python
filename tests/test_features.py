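import math

import numpy as np
import pytest

import pulsepol as pp
from pulsepol.features import PAC_COLUMNS, PFEC_COLUMNS, STAT_NAMES
from pulsepol.pulse_processing import PulseRecord


def brute_force_statistics(x):
    """Independent loop-based evaluation of the eight pulse statistics."""
    n = len(x)
    mu = sum(x) / n
    peak = max(x) - min(x)
    var = sum((xi - mu) ** 2 for xi in x) / n
    std = math.sqrt(var)
    rms = math.sqrt(sum(xi * xi for xi in x) / n)
    sk = (sum((xi - mu) ** 3 for xi in x) / n) / std**3 if std > 0 else float("nan")
    ku = (sum((xi - mu) ** 4 for xi in x) / n) / std**4 if std > 0 else float("nan")
    S = rms / mu if mu != 0 else float("nan")
    L = peak / mu**2 if mu != 0 else float("nan")
    return (peak, var, std, rms, sk, ku, S, L)


def constant_trace(value=1.0, n=20, quv=(0.5, 0.5, 0.5), F=2.0):
    t = pp.StokesTrace(
        I_trace=np.full(n, value),
        q_trace=np.full(n, quv[0]),
        u_trace=np.full(n, quv[1]),
        v_trace=np.full(n, quv[2]),
        dop=pp.compute_dop(*quv),
        F=F,
        n_samples=n,
    )
    return t


class TestPulseStatistics:
    def test_constant_signal(self):
        st = pp.pulse_statistics([5.0, 5.0, 5.0, 5.0])
        assert st.peak == 0 and st.var == 0 and st.std == 0
        assert st.rms == pytest.approx(5.0)
        assert st.S == pytest.approx(1.0)
        assert st.L == 0.0
        assert math.isnan(st.sk) and math.isnan(st.ku)

    def test_frozen_reference_vector(self):
        """Hand-computed values for [1, 2, 3, 2] (population moments)."""
        st = pp.pulse_statistics([1.0, 2.0, 3.0, 2.0])
        assert st.peak == pytest.approx(2.0)
        assert st.var == pytest.approx(0.5)
        assert st.std == pytest.approx(0.70711, abs=1e-5)
        assert st.rms == pytest.approx(2.12132, abs=1e-5)
        assert st.sk == pytest.approx(0.0, abs=1e-12)
        assert st.ku == pytest.approx(2.0)
        assert st.S == pytest.approx(1.06066, abs=1e-5)
        assert st.L == pytest.approx(0.5)

    def test_scaling_laws(self):
        """Under X -> 3X: sk, ku, S invariant; peak, std, rms triple; L thirds."""
        rng = np.random.default_rng(1)
        x = rng.uniform(0.5, 2.0, size=50)
        a, b = pp.pulse_statistics(x), pp.pulse_statistics(3 * x)
        assert b.sk == pytest.approx(a.sk, rel=1e-12)
        assert b.ku == pytest.approx(a.ku, rel=1e-12)
        assert b.S == pytest.approx(a.S, rel=1e-12)
        assert b.peak == pytest.approx(3 * a.peak, rel=1e-12)
        assert b.std == pytest.approx(3 * a.std, rel=1e-12)
        assert b.rms == pytest.approx(3 * a.rms, rel=1e-12)
        assert b.L == pytest.approx(a.L / 3, rel=1e-12)

    def test_oracle_equivalence_on_random_vectors(self):
        """All eight statistics match brute force on 1,000 random vectors."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), size=n)
            got = pp.pulse_statistics(x).as_tuple()
            want = brute_force_statistics(list(x))
            for g, w in zip(got, want):
                if math.isnan(w):
                    assert math.isnan(g)
                else:
                    assert g == pytest.approx(w, rel=1e-10, abs=1e-10)

    def test_two_point_symmetric_signal_kurtosis_one(self):
        st = pp.pulse_statistics([1.0, -1.0, 1.0, -1.0])
        assert st.ku == pytest.approx(1.0)
        assert st.sk == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_multiset_has_zero_skewness(self):
        rng = np.random.default_rng(3)
        half = rng.normal(size=25)
        x = np.concatenate([half, -half])  # exactly symmetric multiset
        assert pp.pulse_statistics(x).sk == pytest.approx(0.0, abs=1e-10)

    def test_conventional_clearance_variant(self):
        x = [1.0, 2.0, 3.0, 2.0]
        st = pp.pulse_statistics(x, clearance="conventional")
        assert st.L == pytest.approx(2.0 / math.sqrt(4.5), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            pp.pulse_statistics([1.0])
        with pytest.raises(ValueError):
            pp.pulse_statistics([1.0, np.nan])
        with pytest.raises(ValueError):
            pp.pulse_statistics([1.0, 2.0], clearance="bogus")

    def test_invariant_var_equals_std_squared(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(size=30)
            st = pp.pulse_statistics(x)
            assert st.var == pytest.approx(st.std**2, rel=1e-12)
            assert st.rms >= abs(np.mean(x)) - 1e-12
            assert st.peak >= 0
            assert st.ku >= 1.0


class TestFeatureVectors:
    def test_pfec_vector_has_38_entries(self, analyzer_matrix):
        arch = pp.demo_panel()[0]
        pulse, _ = pp.simulate_pulse(arch, analyzer_matrix, 0.02, seed=5)
        vec = pp.pfec_vector(pp.to_stokes_trace(pulse, analyzer_matrix))
        assert vec.shape == (38,)
        assert np.all(np.isfinite(vec))
        assert len(PFEC_COLUMNS) == 38
        assert len(PAC_COLUMNS) == 6

    def test_constant_trace_statistics_and_imputation(self):
        """Constant traces reproduce the constant-signal case with imputation."""
        vec = pp.pfec_vector(constant_trace())
        names = dict(zip(PFEC_COLUMNS, vec))
        assert names["I_peak"] == 0.0
        assert names["I_var"] == 0.0
        assert names["I_rms"] == pytest.approx(1.0)
        assert names["I_S"] == pytest.approx(1.0)
        assert names["I_L"] == 0.0
        assert names["I_sk"] == 0.0  # imputed symmetric limit
        assert names["I_ku"] == 3.0  # imputed Gaussian reference

    def test_pac_vector_matches_analytic_averages(self):
        vec = pp.pac_vector(constant_trace(value=1.0, quv=(0.5, 0.5, 0.5), F=2.0))
        assert vec == pytest.approx([1.0, 0.5, 0.5, 0.5, 0.8660, 2.0], abs=1e-4)

    def test_unpolarized_trace_has_zero_dop_entry(self):
        vec = pp.pac_vector(constant_trace(quv=(0, 0, 0)))
        assert vec[4] == 0.0

    def test_pac_is_prefix_of_pfec(self, analyzer_matrix):
        arch = pp.demo_panel()[1]
        pulse, _ = pp.simulate_pulse(arch, analyzer_matrix, 0.02, seed=8)
        trace = pp.to_stokes_trace(pulse, analyzer_matrix)
        assert np.allclose(pp.pfec_vector(trace)[:6], pp.pac_vector(trace))

    def test_positive_asymmetry_gives_positive_mean_intensity_skewness(
        self, analyzer_matrix
    ):
        """Monte-Carlo oracle: the generator's asymmetry sign shows in I_sk."""
        from pulsepol.simulator import PulseShape

        arch = pp.SpeciesArchetype(
            label="x", mean_stokes=(1.0, 0.2, 0.0, 0.0),
            shape=PulseShape(mean_width=40, asymmetry=3.0),
        )
        rng = np.random.default_rng(44)
        sk = []
        for _ in range(200):
            pulse, _ = pp.simulate_pulse(arch, analyzer_matrix, 0.01, rng)
            trace = pp.to_stokes_trace(pulse, analyzer_matrix)
            sk.append(pp.pulse_statistics(trace.I_trace).sk)
        assert np.mean(sk) > 0


class TestFeatureFrame:
    def test_ordering_stable_and_round_trips(self, analyzer_matrix, tmp_path):
        from pulsepol.features import read_feature_table, write_feature_table

        traces = []
        rng = np.random.default_rng(10)
        for arch in pp.demo_panel():
            pulse, _ = pp.simulate_pulse(arch, analyzer_matrix, 0.02, rng)
            traces.append(pp.to_stokes_trace(pulse, analyzer_matrix))
        df = pp.feature_frame(traces, mode="pfec", labels=["a", "b", "c", "d"])
        assert list(df.columns[:38]) == list(PFEC_COLUMNS)
        write_feature_table(df, tmp_path / "f.csv")
        back = read_feature_table(tmp_path / "f.csv")
        assert list(back.columns) == list(df.columns)
        assert np.allclose(back[list(PFEC_COLUMNS)], df[list(PFEC_COLUMNS)])

    def test_pac_mode_has_six_feature_columns(self):
        df = pp.feature_frame([constant_trace()], mode="pac")
        assert list(df.columns) == list(PAC_COLUMNS)

    def test_imputation_counted_in_qc_column(self):
        df = pp.feature_frame([constant_trace()], mode="pfec")
        # constant traces: sk and ku missing on each of the 4 traces
        assert df.loc[0, "qc_imputed"] == 8

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pp.feature_frame([constant_trace()], labels=["a", "b"])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            pp.feature_frame([constant_trace()], mode="raw")


class TestStatisticProperties:
    """Randomized invariants of the printed statistic formulas."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    trace = st.lists(
        st.floats(min_value=0.05, max_value=100.0, allow_nan=False),
        min_size=2, max_size=60,
    )

    @given(trace, st.floats(min_value=0.1, max_value=10.0))
    @settings(derandomize=True, max_examples=200)
    def test_scale_invariants_hold_for_positive_traces(self, x, c):
        a = pp.pulse_statistics(x)
        b = pp.pulse_statistics([c * xi for xi in x])
        assert b.rms == pytest.approx(c * a.rms, rel=1e-9)
        assert b.peak == pytest.approx(c * a.peak, rel=1e-9, abs=1e-12)
        assert b.S == pytest.approx(a.S, rel=1e-9)
        # skewness is numerically meaningless when the spread is at rounding
        # level relative to the values themselves
        if not math.isnan(a.sk) and a.std > 1e-9 * max(abs(v) for v in x):
            assert b.sk == pytest.approx(a.sk, rel=1e-6, abs=1e-9)

    @given(trace)
    @settings(derandomize=True, max_examples=200)
    def test_rms_dominates_mean_and_kurtosis_floor(self, x):
        st_ = pp.pulse_statistics(x)
        assert st_.rms >= abs(sum(x) / len(x)) - 1e-9
        if not math.isnan(st_.ku):
            assert st_.ku >= 1.0 - 1e-9
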