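import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapcircuit import (
    BoundarySpline,
    GeneNetworkSpec,
    assemble_profile,
    boundaries_from_tsv,
    boundaries_to_tsv,
    boundary_profile,
    drop_posterior_kr,
    make_weights,
    median_boundary,
    postprocess,
    spatial_scaling_factor,
    packaged_boundaries,
    temporal_scaling_factor,
)
from gapcircuit.dataprep import FALLING, RISING


def rising(x0, x2, gene="g", tc="T1", bid="g_dom_A", embryo="e1"):
    return BoundarySpline(gene=gene, time_class=tc, boundary_id=bid,
                          polarity=RISING, x0=x0, y0=0.0, x2=x2, y2=1.0,
                          embryo_id=embryo)


def falling(x0, x2, gene="g", tc="T1", bid="g_dom_P", embryo="e1"):
    return BoundarySpline(gene=gene, time_class=tc, boundary_id=bid,
                          polarity=FALLING, x0=x0, y0=0.0, x2=x2, y2=1.0,
                          embryo_id=embryo)


class TestBoundaryProfile:
    def test_anchor_values(self):
        b = rising(40.0, 45.0)
        assert boundary_profile(b, 40.0) == 0.0
        assert boundary_profile(b, 45.0) == 1.0

    def test_midpoint_is_half(self):
        b = rising(40.0, 45.0)
        assert b.x1 == 42.5
        assert boundary_profile(b, b.x1) == pytest.approx(0.5)

    def test_zero_derivative_at_end_knots(self):
        b = rising(40.0, 50.0)
        eps = 1e-6
        d0 = (boundary_profile(b, 40.0 + eps) - boundary_profile(b, 40.0)) / eps
        d2 = (boundary_profile(b, 50.0) - boundary_profile(b, 50.0 - eps)) / eps
        assert abs(d0) < 1e-4
        assert abs(d2) < 1e-4

    def test_clamped_outside_span(self):
        b = rising(40.0, 45.0)
        assert boundary_profile(b, 10.0) == 0.0
        assert boundary_profile(b, 99.0) == 1.0

    @given(s=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_monotone_across_span(self, s):
        b = rising(30.0, 50.0)
        x = 30.0 + s * 20.0
        assert boundary_profile(b, x + 0.1) > boundary_profile(b, x)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            rising(40.0, 40.0)


class TestMedianBoundary:
    def test_median_of_three(self):
        group = [rising(x, x + 5) for x in (44.3, 45.3, 46.7)]
        med = median_boundary(group)
        assert med.x0 == 45.3
        assert med.x2 == 50.3
        assert med.embryo_id == "median"

    def test_singleton_identity(self):
        b = rising(42.0, 47.0)
        med = median_boundary([b])
        assert (med.x0, med.x2) == (b.x0, b.x2)

    def test_even_group_uses_mean_of_central_pair(self):
        group = [rising(x, x + 5) for x in (40.0, 42.0, 44.0, 50.0)]
        assert median_boundary(group).x0 == pytest.approx(43.0)

    def test_mixed_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            median_boundary([rising(40, 45, bid="a_A"), rising(41, 46, bid="b_A")])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            median_boundary([])


class TestAssembleProfile:
    def test_plateau_between_rising_and_falling(self):
        bs = [rising(43.0, 47.0), falling(62.0, 58.0)]
        prof = assemble_profile(bs, 100)
        centres = np.arange(100) + 0.5
        inside = (centres > 47.0) & (centres < 58.0)
        outside = (centres < 43.0) | (centres > 62.0)
        assert np.all(prof[inside] == 1.0)
        assert np.all(prof[outside] == 0.0)

    def test_no_boundaries_gives_zero(self):
        assert np.all(assemble_profile([], 50) == 0.0)

    def test_leading_falling_boundary_extends_from_anterior(self):
        prof = assemble_profile([falling(45.8, 40.8)], 100)
        assert prof[10] == 1.0   # anterior plateau
        assert prof[80] == 0.0

    def test_trailing_rising_boundary_extends_to_posterior(self):
        prof = assemble_profile([rising(89.5, 94.5)], 100)
        assert prof[99] == 1.0
        assert prof[50] == 0.0

    def test_overlapping_spans_rejected_with_ids(self):
        bs = [rising(40.0, 50.0, bid="dom_A"), falling(48.0, 44.0, bid="dom_P")]
        with pytest.raises(ValueError, match="dom_A.*dom_P|dom_P.*dom_A"):
            assemble_profile(bs, 100)

    def test_non_alternating_rejected(self):
        bs = [rising(40.0, 45.0, bid="a"), rising(50.0, 55.0, bid="b")]
        with pytest.raises(ValueError, match="alternate"):
            assemble_profile(bs, 100)

    def test_order_invariance(self):
        bs = [rising(43.0, 47.0), falling(62.0, 58.0),
              rising(80.0, 84.0, bid="g_dom2_A")]
        a = assemble_profile(bs, 100)
        b = assemble_profile(bs[::-1], 100)
        np.testing.assert_array_equal(a, b)


class TestScalingFactors:
    def test_spatial_anchors(self):
        assert spatial_scaling_factor(50.0) == 1.0
        assert spatial_scaling_factor(0.0) == 0.5
        assert spatial_scaling_factor(100.0) == 0.5
        assert spatial_scaling_factor(25.0) == 0.75

    def test_spatial_domain_check(self):
        with pytest.raises(ValueError):
            spatial_scaling_factor(-1.0)
        with pytest.raises(ValueError):
            spatial_scaling_factor(101.0)

    def test_temporal_anchors(self):
        assert temporal_scaling_factor(0.0) == pytest.approx(0.1)
        assert temporal_scaling_factor(48.0) == pytest.approx(1.0)
        assert temporal_scaling_factor(71.1) == pytest.approx(0.7)

    def test_temporal_interior_value(self):
        # independently derived by solving the 3x3 linear system for the
        # quadratic through the anchors and evaluating at t=24
        assert temporal_scaling_factor(24.0) == pytest.approx(0.807, abs=5e-4)

    def test_temporal_peak_between_40_and_50(self):
        t = np.linspace(0, 71.1, 7111)
        assert 40.0 < t[np.argmax(temporal_scaling_factor(t))] < 50.0

    def test_temporal_domain_check(self):
        with pytest.raises(ValueError):
            temporal_scaling_factor(-0.1)
        with pytest.raises(ValueError):
            temporal_scaling_factor(72.0)


class TestWeights:
    def test_weight_values(self):
        assert make_weights(0.0) == pytest.approx(100.0)
        assert make_weights(1.0) == pytest.approx(1.0 / 1.21, abs=1e-4)

    def test_weight_decreasing_in_expression(self):
        y = np.linspace(0, 1, 11)
        w = make_weights(y)
        assert np.all(np.diff(w) < 0)

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            make_weights(0.5, epsilon=0.0)

    def test_maximum_weight_where_silent(self, packaged_dataset):
        for tc in packaged_dataset.time_classes:
            v = packaged_dataset.slice_matrix(tc)
            w = packaged_dataset.weight_matrix(tc)
            silent = v == 0
            if silent.any():
                assert w[silent].max() == pytest.approx(w.max())


class TestPostprocess:
    def test_composed_factors_at_maximum(self):
        spec = GeneNetworkSpec(gap_genes=("g",), external_inputs=("m",),
                               ap_range=(45.0, 55.0))
        prof = np.ones(100)
        ds = postprocess({("g", "T5"): prof}, spec,
                         data_times={"T5": 48.0}, ap_range=(45.0, 55.0))
        v = ds.slice_matrix("T5")
        lat = ds.lattice_of("T5")
        col = list(lat.positions).index(50.5)
        # plateau 1.0 at x = 50.5, t = 48: 200 * spatial(50.5) * 1.0
        assert v[0, col] == pytest.approx(200.0 * spatial_scaling_factor(50.5))
        assert v.max() <= 200.0

    def test_composed_factors_at_pole_and_onset(self):
        spec = GeneNetworkSpec(gap_genes=("g",), external_inputs=("m",),
                               ap_range=(0.0, 5.0))
        prof = np.ones(100)
        ds = postprocess({("g", "T0"): prof}, spec,
                         data_times={"T0": 0.0}, ap_range=(0.0, 5.0))
        lat = ds.lattice_of("T0")
        v = ds.slice_matrix("T0")[0, 0]
        # 200 * spatial(x0) * temporal(0) with temporal(0) = 0.1
        assert v == pytest.approx(200.0 * spatial_scaling_factor(lat.positions[0])
                                  * 0.1)

    def test_all_zero_stays_zero(self):
        spec = GeneNetworkSpec(gap_genes=("g",), external_inputs=("m",))
        ds = postprocess({("g", "T1"): np.zeros(100)}, spec,
                         data_times={"T1": 24.225})
        assert np.all(ds.slice_matrix("T1") == 0.0)

    def test_spatial_temporal_scalings_commute(self):
        x = np.linspace(0, 100, 11)
        prof = np.random.default_rng(0).random(11)
        a = prof * spatial_scaling_factor(x) * temporal_scaling_factor(30.0)
        b = prof * temporal_scaling_factor(30.0) * spatial_scaling_factor(x)
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestTable2Fixture:
    def test_total_data_points(self, packaged_dataset):
        assert packaged_dataset.n_points == 4 * (27 + 8 * 53) == 1804

    def test_nine_time_classes(self, packaged_dataset):
        assert len(packaged_dataset.time_classes) == 9
        assert packaged_dataset.time_classes[0] == "C13"
        assert packaged_dataset.time_classes[-1] == "T8"

    def test_kr_central_boundaries_at_t8(self):
        bs = packaged_boundaries()
        kr_a = [b for b in bs if b.boundary_id == "Kr_central_A"
                and b.time_class == "T8"]
        assert len(kr_a) == 1
        assert kr_a[0].x0 == 42.7

    def test_kr_domain_extent_at_t1(self, packaged_dataset):
        """Kr expression at T1 is nonzero exactly between the printed
        anterior (45.3) and posterior (57.8) boundary spans."""
        spec = packaged_dataset.spec
        lat = packaged_dataset.lattice_of("T1")
        v = packaged_dataset.slice_matrix("T1")[spec.gene_index("Kr")]
        pos = lat.positions
        assert np.all(v[pos < 45.3] == 0.0)
        assert np.all(v[pos > 57.8] == 0.0)
        inside = (pos > 50.3) & (pos < 52.8)
        assert np.all(v[inside] > 0.0)

    def test_absent_boundaries_emit_nothing(self):
        bs = packaged_boundaries()
        assert not [b for b in bs if b.boundary_id == "hb_posterior_P"
                    and b.time_class == "C13"]
        assert [b for b in bs if b.boundary_id == "hb_posterior_P"
                and b.time_class == "T2"]

    def test_values_and_weights_valid(self, packaged_dataset):
        assert np.all(packaged_dataset.values >= 0)
        assert np.all(packaged_dataset.weights > 0)
        assert packaged_dataset.values.max() <= 200.0

    def test_dataset_tsv_roundtrip(self, packaged_dataset, tmp_path):
        path = tmp_path / "data.tsv"
        packaged_dataset.to_tsv(path)
        again = type(packaged_dataset).from_tsv(path)
        assert again.n_points == packaged_dataset.n_points
        np.testing.assert_allclose(again.values, packaged_dataset.values)
        np.testing.assert_allclose(again.weights, packaged_dataset.weights)


class TestDropPosteriorKr:
    def _with_posterior_kr(self):
        bs = list(packaged_boundaries())
        bs.append(rising(75.0, 80.0, gene="Kr", tc="T7", bid="Kr_posterior_A"))
        bs.append(falling(90.0, 85.0, gene="Kr", tc="T7", bid="Kr_posterior_P"))
        return bs

    def test_removes_posterior_domain_nuclei(self):
        bs = self._with_posterior_kr()
        kept = drop_posterior_kr(bs)
        assert not [b for b in kept if "Kr_posterior" in b.boundary_id]
        prof = assemble_profile(
            [b for b in kept if b.gene == "Kr" and b.time_class == "T7"], 100)
        centres = np.arange(100) + 0.5
        assert np.all(prof[centres > 80.0] == 0.0)

    def test_idempotent(self):
        bs = self._with_posterior_kr()
        once = drop_posterior_kr(bs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            twice = drop_posterior_kr(once)
        assert twice == once

    def test_warns_when_absent(self):
        bs = packaged_boundaries()
        with pytest.warns(UserWarning, match="no posterior Kr"):
            kept = drop_posterior_kr(bs)
        assert kept == bs


def test_annotation_tsv_roundtrip(tmp_path):
    bs = packaged_boundaries()[:10]
    path = tmp_path / "annot.tsv"
    boundaries_to_tsv(bs, path)
    again = boundaries_from_tsv(path)
    assert len(again) == len(bs)
    assert again[0].gene == bs[0].gene
    assert again[0].x0 == bs[0].x0
    assert again[0].polarity == bs[0].polarity


def test_profile_binning_matches_axis_bins():
    bs = [rising(43.0, 47.0), falling(62.0, 58.0)]
    assert assemble_profile(bs, 50).shape == (50,)
    assert assemble_profile(bs, 100).shape == (100,)
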