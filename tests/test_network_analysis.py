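import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapcircuit import (
    CircuitParameters,
    GeneNetworkSpec,
    ParameterMask,
    StateMatrix,
    build_lattice,
    classify_interaction,
    interaction_summary,
    mechanism_report,
    net_effect,
    overlap_region,
    reduce_boundaries,
    reduce_timeclasses,
)
from gapcircuit.dataprep import RISING, BoundarySpline
from gapcircuit.simulator import Trajectory


def gap_params(W, E=None, seed=0):
    spec = GeneNetworkSpec()
    W = np.asarray(W, dtype=float)
    E = np.zeros((4, 4)) if E is None else np.asarray(E, dtype=float)
    return CircuitParameters(
        spec=spec, W=W, E=E, R=np.full(4, 10.0), D=np.full(4, 0.05),
        lam=np.full(4, 0.1), h=np.full(4, -2.5),
        mask=ParameterMask.all_free(spec),
    )


def make_trajectory(values_by_gene, time=30.0, n_axis=100):
    """Single-snapshot trajectory over the full axis for region tests."""
    lat = build_lattice("C14A", (0.0, 100.0), n_axis=n_axis)
    values = np.asarray(values_by_gene, dtype=float)
    return Trajectory([StateMatrix(values, lat, time)])


class TestClassifyInteraction:
    @pytest.mark.parametrize("w, expected", [
        (0.004, "none"),
        (-0.2, "repressing"),
        (0.005, "none"),       # closed boundary goes to "none"
        (-0.005, "none"),
        (0.0051, "activating"),
        (0.3, "activating"),
    ])
    def test_cutoff_classification(self, w, expected):
        assert classify_interaction(w) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction(np.nan)

    @given(w=st.floats(-0.5, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_under_negation(self, w):
        flipped = {"repressing": "activating", "activating": "repressing",
                   "none": "none"}
        assert classify_interaction(-w) == flipped[classify_interaction(w)]


class TestInteractionSummary:
    def _ensemble(self):
        W1 = np.full((4, 4), 0.1)
        W2 = np.full((4, 4), -0.1)
        W3 = np.zeros((4, 4))
        return [gap_params(W) for W in (W1, W1, W2, W3)]

    def test_triplets_sum_to_ensemble_size(self):
        summary = interaction_summary(self._ensemble())
        for trip in summary.triplets.values():
            assert sum(trip) == 4

    def test_permutation_invariance(self):
        ens = self._ensemble()
        a = interaction_summary(ens)
        b = interaction_summary(ens[::-1])
        assert a.triplets == b.triplets
        assert a.consensus == b.consensus

    def test_strict_majority_consensus(self):
        ens = self._ensemble()
        summary = interaction_summary(ens)
        edge = ("hb", "Kr")
        # 2 activating, 1 repressing, 1 none: no strict majority
        assert summary.triplets[edge] == (1, 1, 2)
        assert summary.consensus[edge] == "ambiguous"
        summary3 = interaction_summary(ens[:3] + [ens[0]])
        assert summary3.consensus[edge] == "activating"


class TestOverlapAndNetEffect:
    def test_disjoint_profiles_give_empty_region(self):
        hb = np.zeros(100); hb[10:30] = 100.0
        kr = np.zeros(100); kr[60:80] = 100.0
        others = np.zeros((2, 100))
        traj = make_trajectory([hb, kr, *others])
        region = overlap_region(traj, "hb", "Kr", 30.0, spec=GeneNetworkSpec())
        assert region.size == 0

    def test_identical_profiles_give_full_expressed_region(self):
        prof = np.zeros(100); prof[40:60] = 50.0
        traj = make_trajectory([prof, prof, np.zeros(100), np.zeros(100)])
        region = overlap_region(traj, "hb", "Kr", 30.0, spec=GeneNetworkSpec())
        np.testing.assert_array_equal(region, np.arange(40, 60))

    def test_gaussian_overlap_matches_analytic_crossing(self):
        x = np.arange(100) + 0.5
        a = 100.0 * np.exp(-((x - 45.0) / 8.0) ** 2)
        b = 100.0 * np.exp(-((x - 65.0) / 8.0) ** 2)
        traj = make_trajectory([a, b, np.zeros(100), np.zeros(100)])
        region = overlap_region(traj, "hb", "Kr", 30.0, spec=GeneNetworkSpec(),
                                threshold=0.1)
        # analytic: both > 0.1*max where |x-45| and |x-65| < 8*sqrt(ln 10)
        half = 8.0 * np.sqrt(np.log(10.0))
        lo, hi = 65.0 - half, 45.0 + half
        assert abs(x[region[0]] - lo) <= 1.0
        assert abs(x[region[-1]] - hi) <= 1.0

    def test_posterior_most_run_selected_for_multidomain(self):
        hb = np.zeros(100); hb[5:20] = 100.0; hb[70:90] = 100.0
        kr = np.zeros(100); kr[0:100] = 80.0
        traj = make_trajectory([hb, kr, np.zeros(100), np.zeros(100)])
        region = overlap_region(traj, "hb", "Kr", 30.0, spec=GeneNetworkSpec())
        np.testing.assert_array_equal(region, np.arange(70, 90))

    def test_net_effect_arithmetic(self):
        prof = np.zeros(100); prof[50] = 10.0
        traj = make_trajectory([prof, prof, np.zeros(100), np.zeros(100)])
        W = np.zeros((4, 4))
        W[0, 1] = -0.1  # hb -> Kr
        params = gap_params(W)
        val = net_effect(traj, params, "hb", "Kr", region=[50], times=[30.0])
        assert val == pytest.approx(-1.0)

    def test_zero_weight_gives_zero(self):
        prof = np.full(100, 42.0)
        traj = make_trajectory([prof, prof, np.zeros(100), np.zeros(100)])
        params = gap_params(np.zeros((4, 4)))
        assert net_effect(traj, params, "hb", "Kr",
                          region=np.arange(30, 60), times=[30.0]) == 0.0

    def test_asymmetric_repression_sign(self):
        """When the posterior gene's |w * v| integral is larger, the net
        asymmetry matches the direct summation oracle."""
        hb = np.zeros(100); hb[40:60] = 20.0
        gt = np.zeros(100); gt[50:70] = 100.0
        traj = make_trajectory([hb, np.zeros(100), gt, np.zeros(100)])
        W = np.zeros((4, 4))
        spec = GeneNetworkSpec()
        W[spec.gene_index("hb"), spec.gene_index("gt")] = -0.1
        W[spec.gene_index("gt"), spec.gene_index("hb")] = -0.1
        params = gap_params(W)
        region = np.arange(50, 60)
        hb_on_gt = net_effect(traj, params, "hb", "gt", region, [30.0])
        gt_on_hb = net_effect(traj, params, "gt", "hb", region, [30.0])
        # oracle: direct summation
        assert hb_on_gt == pytest.approx(-0.1 * hb[50:60].mean())
        assert gt_on_hb == pytest.approx(-0.1 * gt[50:60].mean())
        assert gt_on_hb < hb_on_gt  # posterior gene represses more strongly

    def test_empty_region_rejected(self):
        prof = np.full(100, 1.0)
        traj = make_trajectory([prof, prof, np.zeros(100), np.zeros(100)])
        params = gap_params(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            net_effect(traj, params, "hb", "Kr", region=[], times=[30.0])


class TestMechanismReport:
    def test_all_cushions_repressing_gives_fraction_one(self):
        spec = GeneNetworkSpec()
        W = np.zeros((4, 4))
        for a, b in (("hb", "kni"), ("Kr", "gt")):
            W[spec.gene_index(a), spec.gene_index(b)] = -0.1
            W[spec.gene_index(b), spec.gene_index(a)] = -0.1
        ens = [gap_params(W) for _ in range(5)]
        report = mechanism_report(ens)
        assert report.alternating_cushions == 1.0

    def test_zero_self_weights_give_zero_auto_activation(self):
        ens = [gap_params(np.zeros((4, 4))) for _ in range(3)]
        report = mechanism_report(ens)
        assert all(v == 0.0 for v in report.auto_activation.values())

    def test_single_circuit_matches_per_rule_oracle(self):
        spec = GeneNetworkSpec()
        W = np.zeros((4, 4))
        E = np.zeros((4, 4))
        for a, b in (("hb", "kni"), ("Kr", "gt")):
            W[spec.gene_index(a), spec.gene_index(b)] = -0.2
            W[spec.gene_index(b), spec.gene_index(a)] = -0.2
        for g in spec.gap_genes:
            W[spec.gene_index(g), spec.gene_index(g)] = 0.02
        for g in spec.gap_genes:
            E[spec.input_index("bcd"), spec.gene_index(g)] = 0.05
        E[spec.input_index("cad"), spec.gene_index("gt")] = 0.05
        E[spec.input_index("cad"), spec.gene_index("kni")] = 0.05
        E[spec.input_index("hkb"), spec.gene_index("hb")] = -0.05
        for g in ("Kr", "gt", "kni"):
            E[spec.input_index("tll"), spec.gene_index(g)] = -0.05
        params = gap_params(W, E)
        report = mechanism_report([params])
        assert report.alternating_cushions == 1.0
        assert report.auto_activation == {g: True for g in spec.gap_genes}
        assert report.bcd_cad_activation == 1.0
        assert report.tll_hkb_inhibition == 1.0

    def test_report_is_average_of_per_circuit_reports(self):
        spec = GeneNetworkSpec()
        W_on = np.zeros((4, 4))
        for g in spec.gap_genes:
            W_on[spec.gene_index(g), spec.gene_index(g)] = 0.1
        ens = [gap_params(W_on), gap_params(np.zeros((4, 4)))]
        report = mechanism_report(ens)
        assert all(v == 0.5 for v in report.auto_activation.values())


class TestReducedData:
    def _annotations(self, n_embryos=5):
        out = []
        for tc in ["C13"] + [f"T{i}" for i in range(1, 9)]:
            for e in range(n_embryos):
                out.append(BoundarySpline(
                    gene="Kr", time_class=tc, boundary_id="Kr_central_A",
                    polarity=RISING, x0=45.0 + e, y0=0.0, x2=50.0 + e, y2=1.0,
                    embryo_id=f"e{e}"))
        return out

    def test_fraction_one_is_identity(self):
        ann = self._annotations()
        assert reduce_boundaries(ann, 1.0, seed=0) == ann

    def test_group_of_five_at_forty_percent_keeps_two(self):
        ann = self._annotations(n_embryos=5)
        reduced = reduce_boundaries(ann, 0.4, seed=1)
        per_tc = {}
        for b in reduced:
            per_tc[b.time_class] = per_tc.get(b.time_class, 0) + 1
        assert all(v == 2 for v in per_tc.values())

    def test_at_least_one_retained(self):
        ann = self._annotations(n_embryos=1)
        reduced = reduce_boundaries(ann, 0.2, seed=3)
        assert len(reduced) == len(ann)  # every singleton group survives

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            reduce_boundaries(self._annotations(), 0.0, seed=0)

    def test_boundary_reduction_mean_matches_fraction(self):
        """Measure preservation in expectation: mean retained count over many
        seeds is within 2% of round(fraction * n)."""
        ann = self._annotations(n_embryos=10)
        fraction = 0.6
        counts = [len(reduce_boundaries(ann, fraction, seed=s)) / len(ann)
                  for s in range(50)]
        assert np.mean(counts) == pytest.approx(0.6, abs=0.02)

    def test_k9_is_identity(self):
        ann = self._annotations()
        assert reduce_timeclasses(ann, 9, seed=0) == ann

    def test_k3_keeps_endpoints_and_one_middle(self):
        ann = self._annotations()
        reduced = reduce_timeclasses(ann, 3, seed=5)
        kept = {b.time_class for b in reduced}
        assert "C13" in kept and "T8" in kept
        assert len(kept) == 3
        middle = kept - {"C13", "T8"}
        assert middle.pop() in {f"T{i}" for i in range(1, 8)}

    def test_endpoints_never_removed_over_many_seeds(self):
        ann = self._annotations()
        for seed in range(1000):
            kept = {b.time_class
                    for b in reduce_timeclasses(ann, 3, seed=seed)}
            assert "C13" in kept and "T8" in kept

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reduce_timeclasses(self._annotations(), 2, seed=0)
        with pytest.raises(ValueError):
            reduce_timeclasses(self._annotations(), 10, seed=0)

    def test_deterministic_per_seed(self):
        ann = self._annotations()
        a = reduce_boundaries(ann, 0.6, seed=7)
        b = reduce_boundaries(ann, 0.6, seed=7)
        assert a == b
        c = reduce_timeclasses(ann, 5, seed=7)
        d = reduce_timeclasses(ann, 5, seed=7)
        assert c == d
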