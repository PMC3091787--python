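import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cnvfreq import hwe
from cnvfreq.io_genotypes import counts_from_matrix
from cnvfreq.simulate import MarkerModel, ScenarioSpec, simulate_genotypes


def freqs(p_o, q_o, pq_o, n=912, nocall_rate=0.0):
    return hwe.PhenotypeFrequencies(p_o, q_o, pq_o, n, nocall_rate)


def null_model_fractions(p, q, r):
    """Expected phenotype fractions (of all samples) under a null allele r:
    carriers look homozygous, rr homozygotes are no-calls."""
    return p * p + 2 * p * r, q * q + 2 * q * r, 2 * p * q


def gain_model_fractions(p, q, g):
    """Expected fractions under a both-allele duplication g: every carrier
    presents heterozygote-like."""
    return p * p, q * q, 1 - p * p - q * q


class TestPhenotypeFrequencies:
    def test_called_denominator(self):
        f = hwe.phenotype_frequencies(
            {"n_AA": 32, "n_AB": 32, "n_BB": 32, "n_nocall": 4}
        )
        assert f.p_o == f.q_o == f.pq_o == pytest.approx(1 / 3)
        assert f.n == 96
        assert f.p_o + f.q_o + f.pq_o == pytest.approx(1.0, abs=1e-12)

    def test_total_denominator(self):
        f = hwe.phenotype_frequencies(
            {"n_AA": 32, "n_AB": 32, "n_BB": 32, "n_nocall": 4},
            denominator="total",
        )
        assert f.p_o == pytest.approx(0.32)

    def test_all_nocall_is_degenerate(self):
        with pytest.raises(hwe.DegenerateMarkerError):
            hwe.phenotype_frequencies(
                {"n_AA": 0, "n_AB": 0, "n_BB": 0, "n_nocall": 10}
            )


class TestEstimators:
    def test_zero_at_hwe(self):
        f = freqs(0.25, 0.25, 0.5)
        assert hwe.estimate_loss(f) == pytest.approx(0.0, abs=1e-12)
        assert hwe.estimate_gain(f) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "p,q,r", [(0.6, 0.3, 0.1), (0.4, 0.4, 0.2), (0.05, 0.9, 0.05)]
    )
    def test_loss_recovers_null_frequency(self, p, q, r):
        """On model-expected fractions the closed form returns r exactly."""
        assert hwe.estimate_loss(freqs(*null_model_fractions(p, q, r))) == (
            pytest.approx(r, abs=1e-10)
        )

    @pytest.mark.parametrize(
        "p,q,g", [(0.5, 0.3, 0.2), (0.45, 0.45, 0.1), (0.8, 0.15, 0.05)]
    )
    def test_gain_recovers_gain_frequency(self, p, q, g):
        assert hwe.estimate_gain(freqs(*gain_model_fractions(p, q, g))) == (
            pytest.approx(g, abs=1e-10)
        )

    def test_analytic_recovery_on_simplex_grid(self):
        """Exact inversion across the whole (p, q, r) simplex, 0.05 step."""
        grid = np.arange(0.05, 1.0, 0.05)
        for p in grid:
            for q in grid:
                r = 1.0 - p - q
                if r < -1e-12 or p * q == 0:
                    continue
                r = max(r, 0.0)
                assert hwe.estimate_loss(
                    freqs(*null_model_fractions(p, q, r))
                ) == pytest.approx(r, abs=1e-10)
                assert hwe.estimate_gain(
                    freqs(*gain_model_fractions(p, q, r))
                ) == pytest.approx(r, abs=1e-10)

    def test_antisymmetry_between_models(self):
        """Loss loci drive r_g negative and gain loci drive r_l negative —
        the basis of the expected negative correlation between the two."""
        loss_f = freqs(*null_model_fractions(0.4, 0.4, 0.2))
        gain_f = freqs(*gain_model_fractions(0.4, 0.4, 0.2))
        assert hwe.estimate_gain(loss_f) < 0
        assert hwe.estimate_loss(gain_f) < 0

    def test_no_heterozygotes_gives_infinite_loss(self):
        f = freqs(0.6, 0.4, 0.0)
        assert hwe.estimate_loss(f) == np.inf

    def test_monomorphic_is_undefined(self):
        assert np.isnan(hwe.estimate_loss(freqs(1.0, 0.0, 0.0)))
        assert np.isnan(hwe.estimate_gain(freqs(1.0, 0.0, 0.0)))

    @given(
        n_aa=st.integers(0, 2000),
        n_ab=st.integers(1, 2000),
        n_bb=st.integers(0, 2000),
        n_nc=st.integers(0, 2000),
    )
    def test_radicand_never_negative(self, n_aa, n_ab, n_bb, n_nc):
        """estimate_loss is finite for any counts with heterozygotes
        observed: the radicand cannot go negative."""
        f = hwe.phenotype_frequencies(
            {"n_AA": n_aa, "n_AB": n_ab, "n_BB": n_bb, "n_nocall": n_nc}
        )
        assert np.isfinite(hwe.estimate_loss(f))
        assert np.isfinite(hwe.estimate_gain(f))

    def test_called_denominator_inflates_loss(self):
        """Dropping null homozygotes from the denominator slightly raises
        the loss estimate relative to the total-sample denominator."""
        counts = {"n_AA": 480, "n_AB": 360, "n_BB": 150, "n_nocall": 10}
        r_called = hwe.estimate_loss(hwe.phenotype_frequencies(counts))
        r_total = hwe.estimate_loss(
            hwe.phenotype_frequencies(counts, denominator="total")
        )
        assert r_called > r_total


class TestChi2:
    def test_exact_hwe_gives_zero(self):
        stat, p = hwe.hwe_chi2({"n_AA": 25, "n_AB": 50, "n_BB": 25})
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_no_heterozygotes_closed_form(self):
        """(50, 0, 50): expected (25, 50, 25), so chi2 = 25 + 50 + 25 = 100."""
        stat, p = hwe.hwe_chi2({"n_AA": 50, "n_AB": 0, "n_BB": 50})
        assert stat == pytest.approx(100.0)
        assert p < 1e-20

    def test_monomorphic_no_test(self):
        stat, p = hwe.hwe_chi2({"n_AA": 80, "n_AB": 0, "n_BB": 0})
        assert (stat, p) == (0.0, 1.0)


class TestExpectedNocalls:
    def test_arithmetic(self):
        assert hwe.expected_nocalls(0.5, 912) == pytest.approx(228.0)

    def test_negative_loss_clamped(self):
        assert hwe.expected_nocalls(-0.1, 912) == 0.0

    def test_simulated_null_homozygotes_match(self):
        """No-calls under a pure null model (r = 0.2, no technical failures)
        are Binomial(912, r^2); the observed count sits within 4 SE."""
        spec = ScenarioSpec(
            markers=(MarkerModel("m", "1", 100, "null_allele", 0.4, 0.4, 0.2),),
            n_samples=912, seed=5,
        )
        counts = counts_from_matrix(simulate_genotypes(spec).genotypes)
        observed = counts.loc["m", "n_nocall"]
        expected = hwe.expected_nocalls(0.2, 912)
        se = np.sqrt(912 * 0.04 * 0.96)
        assert abs(observed - expected) < 4 * se


class TestMarkerMetrics:
    def test_vector_agrees_with_scalar_ops(self, rng):
        codes = rng.integers(0, 3, size=(200, 30)).astype(float)
        codes[rng.random(codes.shape) < 0.05] = np.nan
        counts = counts_from_matrix(
            pd.DataFrame(codes, columns=[f"m{i}" for i in range(30)])
        )
        metrics = hwe.marker_metrics(counts)
        for m, row in counts.iterrows():
            f = hwe.phenotype_frequencies(row)
            assert metrics.loc[m, "r_l"] == pytest.approx(
                hwe.estimate_loss(f), nan_ok=True
            )
            assert metrics.loc[m, "r_g"] == pytest.approx(
                hwe.estimate_gain(f), nan_ok=True
            )
            stat, p = hwe.hwe_chi2(row)
            assert metrics.loc[m, "chi2"] == pytest.approx(stat)
            assert metrics.loc[m, "chi2_p"] == pytest.approx(p)

    def test_monomorphic_gets_null_metrics(self):
        counts = counts_from_matrix(pd.DataFrame({"mono": [0.0] * 20}))
        row = hwe.marker_metrics(counts).loc["mono"]
        assert not row.polymorphic
        assert np.isnan(row.r_l) and np.isnan(row.r_g)
        assert not row.nonautosomal_flag


class TestNonAutosomalFlagging:
    def test_hemizygous_marker_flagged_hwe_marker_not(self):
        spec = ScenarioSpec(
            markers=(
                MarkerModel("x1", "7", 100, "hemizygous_x", 0.6, 0.4),
                MarkerModel("a1", "7", 200, "hwe", 0.6, 0.4),
            ),
            n_samples=912, seed=9,
        )
        counts = counts_from_matrix(simulate_genotypes(spec).genotypes)
        metrics = hwe.marker_metrics(counts)
        assert metrics.loc["x1", "nonautosomal_flag"]
        assert not metrics.loc["a1", "nonautosomal_flag"]

    def test_adjacent_flagged_markers_grouped_into_one_run(self):
        """Five clustered hemizygous markers on one chromosome surface as a
        single contiguous run (a misplaced sex-chromosome block)."""
        markers = tuple(
            MarkerModel(f"x{i}", "7", 76_944_037 + 1000 * i, "hemizygous_x",
                        0.5, 0.5)
            for i in range(5)
        ) + tuple(
            MarkerModel(f"a{i}", "7", 70_000_000 + 1000 * i, "hwe", 0.5, 0.5)
            for i in range(3)
        ) + (MarkerModel("b1", "9", 500, "hwe", 0.5, 0.5),)
        spec = ScenarioSpec(markers=markers, n_samples=912, seed=13)
        counts = counts_from_matrix(simulate_genotypes(spec).genotypes)
        metrics = hwe.marker_metrics(counts)
        runs = hwe.flag_nonautosomal(metrics, spec.marker_map())
        assert len(runs) == 1
        run = runs.iloc[0]
        assert run.chromosome == "7"
        assert run.n_markers == 5
        assert run.start == 76_944_037
        assert run.markers.split(",") == [f"x{i}" for i in range(5)]
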