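"""Coupling-coefficient formula, image pipeline and cytometry gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from syncytia import synthetic
from syncytia.dye_exchange import (
    DualChannelImage,
    EventTable,
    coupling_coefficient,
    coupling_distribution,
    coupling_map,
    exchanged_fraction,
    gate_thresholds,
    normalize_channels,
)

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestCouplingCoefficient:
    @pytest.mark.parametrize(
        "fo,fv,expected",
        [
            (0.5, 0.5, 1.0),  # equal mixing maximizes the statistic
            (1.0, 0.0, 0.0),  # mono-culture: no exchange yet
            (0.0, 1.0, 0.0),
            (0.75, 0.25, 0.5),  # 3:1 mixture, hand evaluation
        ],
    )
    def test_anchor_points(self, fo, fv, expected):
        assert coupling_coefficient(fo, fv) == pytest.approx(expected)

    @given(positive, positive)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_symmetry_and_bounds(self, a, b):
        cc = coupling_coefficient(a, b)
        assert cc == pytest.approx(coupling_coefficient(b, a))
        assert 0.0 <= cc <= 1.0

    @given(positive)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_equals_one_iff_channels_equal(self, a):
        assert coupling_coefficient(a, a) == pytest.approx(1.0)
        assert coupling_coefficient(a, 2.1 * a) < 1.0

    def test_channel_swap_symmetry_on_random_images(self):
        rng = np.random.default_rng(0)
        fo = rng.uniform(0.01, 2.0, size=(64, 64))
        fv = rng.uniform(0.01, 2.0, size=(64, 64))
        np.testing.assert_allclose(
            coupling_coefficient(fo, fv), coupling_coefficient(fv, fo)
        )


class TestNormalization:
    def test_channel_equal_to_control_mean_maps_to_ones(self):
        img = DualChannelImage(
            channel_O=np.full((8, 8), 200.0),
            channel_V=np.full((8, 8), 50.0),
            mono_control_means=(200.0, 50.0),
        )
        f_o, f_v = normalize_channels(img)
        np.testing.assert_allclose(f_o, 1.0)
        np.testing.assert_allclose(f_v, 1.0)

    def test_doubling_control_mean_halves_normalized_channel(self):
        base = DualChannelImage(
            channel_O=np.full((4, 4), 100.0),
            channel_V=np.full((4, 4), 100.0),
            mono_control_means=(100.0, 100.0),
        )
        doubled = DualChannelImage(
            channel_O=base.channel_O,
            channel_V=base.channel_V,
            mono_control_means=(200.0, 100.0),
        )
        np.testing.assert_allclose(
            normalize_channels(doubled)[0], normalize_channels(base)[0] / 2
        )

    def test_pure_single_dye_cell_normalizes_to_unit_vector(self):
        img, aux, _ = synthetic.generate_coculture_image(
            fraction_exchanged=0.0, n_cells=40, noise_sd=0.0, seed=0
        )
        f_o, f_v = normalize_channels(img)
        labels = aux["labels"]
        pure_o_pixels = (labels > 0) & (img.channel_O > img.channel_V)
        assert f_o[pure_o_pixels].mean() == pytest.approx(1.0, abs=0.02)
        assert f_v[pure_o_pixels].mean() == pytest.approx(0.0, abs=0.02)


class TestImagePipeline:
    def test_unexchanged_culture_has_no_dual_positive_pixels(self):
        img, aux, _ = synthetic.generate_coculture_image(
            fraction_exchanged=0.0, n_cells=40, noise_sd=0.0, seed=1
        )
        labels = aux["labels"]
        both = (img.channel_O > 50) & (img.channel_V > 50) & (labels > 0)
        assert not both.any()

    def test_fully_exchanged_culture_masses_cc_at_one(self):
        img, aux, _ = synthetic.generate_coculture_image(
            fraction_exchanged=1.0, mixing_sd=0.0, noise_sd=0.0, n_cells=60, seed=2
        )
        cmap = coupling_map(img, background_sd=0.01)
        dist = coupling_distribution(cmap, labels=aux["labels"])
        assert np.median(dist.values) == pytest.approx(1.0, abs=1e-6)
        assert dist.fraction_above > 0.99

    def test_mono_culture_gives_negligible_cc(self):
        img, aux, _ = synthetic.generate_coculture_image(
            fraction_exchanged=0.0, n_cells=60, noise_sd=2.0, seed=3
        )
        cmap = coupling_map(img)
        dist = coupling_distribution(cmap, labels=aux["labels"])
        assert np.median(dist.values) < 0.05
        assert dist.fraction_above < 0.02

    def test_half_exchanged_culture_splits_cells_at_threshold(self):
        """Planted 50% mixing: the per-cell dual-positive count lands inside
        the binomial 95% interval and the above-threshold fraction matches
        the generated mixed-cell count."""
        img, aux, truth = synthetic.generate_coculture_image(
            fraction_exchanged=0.5, n_cells=200, shape=(700, 700), seed=4
        )
        cmap = coupling_map(img)
        dist = coupling_distribution(cmap, labels=aux["labels"])
        n_above = int(dist.fraction_above * dist.values.size)
        # binomial 95% interval around 100 of 200
        assert 86 <= truth.params["n_mixed"] <= 114
        assert n_above == truth.params["n_mixed"]

    def test_background_pixels_are_excluded_not_zeroed(self):
        img, _, _ = synthetic.generate_coculture_image(
            fraction_exchanged=0.5, n_cells=30, seed=5
        )
        cmap = coupling_map(img)
        assert np.isnan(cmap.cc).any()
        assert np.isfinite(cmap.cc).any()

    def test_empty_map_rejected(self):
        from syncytia.dye_exchange import CouplingMap

        with pytest.raises(ValueError, match="empty"):
            coupling_distribution(CouplingMap(cc=np.full((4, 4), np.nan)))


def make_tables(fraction, n=5000, seed=0):
    tables, truth = synthetic.generate_cytometry_events(
        n_per_population=n, exchanged_fraction=fraction, seed=seed
    )
    return tables, truth


class TestGating:
    def test_thresholds_match_off_channel_percentile(self):
        tables, _ = make_tables(0.5)
        gates = gate_thresholds(tables["mono_A"], tables["mono_B"], percentile=95)
        assert gates.threshold_B == pytest.approx(
            np.percentile(tables["mono_A"].events["channel_B"], 95)
        )
        assert gates.threshold_A == pytest.approx(
            np.percentile(tables["mono_B"].events["channel_A"], 95)
        )

    def test_percentile_100_is_observed_maximum(self):
        tables, _ = make_tables(0.5)
        gates = gate_thresholds(tables["mono_A"], tables["mono_B"], percentile=100)
        assert gates.threshold_B == tables["mono_A"].events["channel_B"].max()

    def test_threshold_invariant_under_event_shuffling(self):
        tables, _ = make_tables(0.3, seed=2)
        shuffled = EventTable(
            tables["mono_A"].events.sample(frac=1.0, random_state=9).reset_index(drop=True),
            source="mono_A",
        )
        g1 = gate_thresholds(tables["mono_A"], tables["mono_B"])
        g2 = gate_thresholds(shuffled, tables["mono_B"])
        assert g1.threshold_B == pytest.approx(g2.threshold_B)

    def test_empty_tables_rejected(self):
        empty = EventTable(pd.DataFrame({"channel_A": [], "channel_B": []}))
        tables, _ = make_tables(0.5)
        with pytest.raises(ValueError):
            gate_thresholds(empty, tables["mono_B"])


class TestExchangedFraction:
    @pytest.mark.parametrize("planted", [0.0, 0.3, 0.6, 1.0])
    def test_planted_fraction_recovered_within_3_binomial_sd(self, planted):
        n = 5000
        tables, _ = make_tables(planted, n=n, seed=11)
        gates = gate_thresholds(tables["mono_A"], tables["mono_B"])
        est = exchanged_fraction(tables["co_culture"], gates)
        tol = 3 * np.sqrt(max(planted * (1 - planted), 0.25 / n) / n) + 3 * 0.05 / np.sqrt(n)
        assert est == pytest.approx(planted, abs=max(tol, 0.02))

    def test_acute_mix_null_bounded_by_gating_false_positive_rate(self):
        tables, _ = make_tables(0.5, seed=3)
        gates = gate_thresholds(tables["mono_A"], tables["mono_B"])
        raw = exchanged_fraction(tables["acute_mix"], gates, fp_correction=False)
        assert raw <= 0.05 * 2

    def test_all_dual_positive_gives_one(self):
        tables, _ = make_tables(1.0, seed=4)
        gates = gate_thresholds(tables["mono_A"], tables["mono_B"])
        assert exchanged_fraction(tables["co_culture"], gates) == pytest.approx(
            1.0, abs=0.01
        )

    def test_monotone_in_planted_fraction(self):
        grid = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
        estimates = []
        for f in grid:
            tables, _ = make_tables(f, n=4000, seed=8)
            gates = gate_thresholds(tables["mono_A"], tables["mono_B"])
            estimates.append(exchanged_fraction(tables["co_culture"], gates))
        assert all(b >= a - 0.01 for a, b in zip(estimates, estimates[1:]))

    def test_empty_table_rejected(self):
        tables, _ = make_tables(0.5)
        gates = gate_thresholds(tables["mono_A"], tables["mono_B"])
        empty = EventTable(pd.DataFrame({"channel_A": [], "channel_B": []}))
        with pytest.raises(ValueError, match="empty"):
            exchanged_fraction(empty, gates)
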