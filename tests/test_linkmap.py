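import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kendalltau

from irilmap import linkmap, simpop
from irilmap.core import AA, AB, BB, FAILED, GenotypeMatrix
from irilmap.linkmap import chain, mapfunc
from irilmap.linkmap.binplace import FrameworkMessages, place_bins
from irilmap.linkmap.filtering import FilterConfig, filter_markers
from irilmap.linkmap.framework import extend_framework
from irilmap.linkmap.scaffold import build_scaffold
from irilmap.linkmap.twopoint import estimate_R, group_markers, pairwise_R

from conftest import true_cm_lookup


class TestMapFunction:
    def test_r_zero(self):
        for t in (0, 1, 4):
            assert mapfunc.R_from_r(0.0, t) == 0.0
            assert mapfunc.cm_from_R(0.0, t) == 0.0

    def test_t0_closed_form(self):
        # selfed RILs: R = 2r / (1 + 2r)
        assert mapfunc.R_from_r(0.25, 0) == pytest.approx(1 / 3)
        assert mapfunc.R_from_r(0.5, 0) == pytest.approx(0.5)

    def test_monotone_and_expansion(self):
        r = np.linspace(0.001, 0.499, 50)
        for t in (0, 2, 4):
            R = mapfunc.R_from_r(r, t)
            assert (np.diff(R) > 0).all()
        assert (mapfunc.R_from_r(r, 4) >= mapfunc.R_from_r(r, 0)).all()

    def test_round_trip_precision(self):
        r = np.linspace(1e-4, 0.4999, 200)
        for t in (0, 2, 4):
            back = mapfunc.r_from_R(mapfunc.R_from_r(r, t), t)
            assert np.max(np.abs(back - r)) < 1e-9

    def test_unlinked_distance_is_infinite(self):
        assert np.isinf(mapfunc.cm_from_R(0.5, 0))
        assert np.isinf(mapfunc.cm_from_R(0.5, 4))

    def test_pseudo_cm_exceeds_cm_for_positive_t(self):
        R = 0.3
        assert mapfunc.cm_from_R(R, 0) > mapfunc.cm_from_R(R, 4)

    @settings(max_examples=50, deadline=None)
    @given(r=st.floats(1e-4, 0.499), t=st.integers(0, 6))
    def test_round_trip_property(self, r, t):
        assert mapfunc.r_from_R(mapfunc.R_from_r(r, t), t) == pytest.approx(
            r, abs=1e-9)


class TestFilterMarkers:
    def matrix(self, calls, gc=None):
        calls = np.asarray(calls, dtype=np.int8)
        m = GenotypeMatrix(
            markers=np.array([f"m{i}" for i in range(calls.shape[0])], dtype=object),
            samples=np.array(["P1", "P2"] + [f"L{j}" for j in range(calls.shape[1] - 2)],
                             dtype=object),
            calls=calls,
            alleles=np.array([["A", "C"]] * calls.shape[0], dtype=object),
            gc=gc)
        return m

    def test_monomorphic_parents_excluded(self):
        m = self.matrix([[AA, AA, AA, AA, AA, AA]])
        res = filter_markers(m, "P1", "P2", FilterConfig())
        assert res.n_markers == 0
        assert res.diagnostics["excluded_reason"].iloc[0] == "parents"

    def test_missing_threshold_by_stage(self):
        # 40% missing among 10 lines
        row = [AA, BB] + [AA] * 3 + [BB] * 3 + [FAILED] * 4
        m = self.matrix([row])
        fw = filter_markers(m, "P1", "P2", FilterConfig(stage="framework"))
        cp = filter_markers(m, "P1", "P2", FilterConfig(stage="complete"))
        assert fw.n_markers == 0 and fw.diagnostics["excluded_reason"].iloc[0] == "missing"
        assert cp.n_markers == 1

    def test_low_maf_excluded_both_stages(self):
        row = [AA, BB] + [AA] * 19 + [BB]  # maf = 0.05
        m = self.matrix([row])
        for stage in ("framework", "complete"):
            res = filter_markers(m, "P1", "P2", FilterConfig(stage=stage))
            assert res.n_markers == 0
            assert res.diagnostics["excluded_reason"].iloc[0] == "maf"

    def test_het_and_low_gc_become_missing(self):
        row = [AA, BB, AA, AB, BB, BB, AA, BB]
        gc = np.array([[1, 1, 0.95, 0.95, 0.5, 0.95, 0.95, 0.95]])
        m = self.matrix([row], gc=gc)
        res = filter_markers(m, "P1", "P2",
                             FilterConfig(stage="complete", maf_min=0.0))
        # line calls: AA, AB->missing, BB(gc 0.5 < 0.6)->missing, BB, AA, BB
        assert res.n_markers == 1
        assert list(res.origins[0]) == [0, -1, -1, 1, 0, 1]

    def test_missing_parent_rejected(self):
        m = self.matrix([[AA, BB, AA, BB]])
        with pytest.raises(ValueError, match="parent"):
            filter_markers(m, "P1", "nope", FilterConfig())


class TestEstimateR:
    def test_identical_vectors(self):
        x = np.array([0, 1] * 20, dtype=np.int8)
        est = estimate_R(x, x)
        assert est.R_hat == 0.0
        assert est.lod == pytest.approx(40 * np.log10(2))

    def test_count_ratio(self):
        x1 = np.zeros(40, dtype=np.int8)
        x2 = np.zeros(40, dtype=np.int8)
        x2[:4] = 1
        assert estimate_R(x1, x2).R_hat == pytest.approx(0.10)

    def test_few_informative_flagged(self):
        x = np.full(20, -1, dtype=np.int8)
        x[:5] = 0
        est = estimate_R(x, x)
        assert not est.reliable

    def test_independent_markers(self):
        rng = np.random.default_rng(0)
        x1 = rng.choice([0, 1], size=239).astype(np.int8)
        x2 = rng.choice([0, 1], size=239).astype(np.int8)
        est = estimate_R(x1, x2)
        assert abs(est.R_hat - 0.5) <= 3 * np.sqrt(0.25 / 239) + 1e-9
        assert est.lod < 1.0


class TestGroupMarkers:
    def test_unlinked_markers_are_singletons(self):
        rng = np.random.default_rng(1)
        X = rng.choice([0, 1], size=(5, 300)).astype(np.int8)
        ids = np.array([f"m{i}" for i in range(5)], dtype=object)
        groups = group_markers(X, ids, lod_threshold=6.0, r_threshold=0.45)
        assert [len(g) for g in groups] == [1] * 5

    def test_zero_threshold_single_group(self):
        rng = np.random.default_rng(2)
        X = rng.choice([0, 1], size=(5, 100)).astype(np.int8)
        ids = np.array([f"m{i}" for i in range(5)], dtype=object)
        groups = group_markers(X, ids, lod_threshold=0.0, r_threshold=0.5)
        assert len(groups) == 1

    def test_two_chromosomes_two_groups(self, two_chrom_sim):
        _, _, noisy, truth = two_chrom_sim
        res = filter_markers(noisy, "P1", "P2", FilterConfig())
        groups = group_markers(res.origins, res.marker_ids)
        big = [g for g in groups if len(g) >= 3]
        chrom_of = truth.chrom_of_marker()
        for g in big:
            chroms = {chrom_of[str(m)] for m in res.marker_ids[g]}
            assert len(chroms) == 1


class TestChain:
    def test_two_markers_t0_distance(self):
        # R = 0.2479 -> r = R / (2 - 2R) (t=0 closed form), d via Haldane
        rng = np.random.default_rng(3)
        n = 4000
        R = 0.2479
        x1 = rng.choice([0, 1], size=n).astype(np.int8)
        flip = rng.random(n) < R
        x2 = np.where(flip, 1 - x1, x1).astype(np.int8)
        X = np.stack([x1, x2], axis=1)
        Rfit, _, _ = chain.fit_intervals(X, eps=1e-6, tol=1e-9)
        d = mapfunc.cm_from_R(float(Rfit[0]), 0)
        expected = mapfunc.cm_from_R(R, 0)
        assert expected == pytest.approx(19.97, abs=0.1)
        assert d == pytest.approx(expected, abs=1.0)

    def test_zero_recombination_zero_intervals(self):
        X = np.tile(np.array([0, 1, 0, 1] * 10, dtype=np.int8)[:, None], (1, 4))
        R, _, _ = chain.fit_intervals(X, eps=1e-6)
        assert np.all(mapfunc.cm_from_R(R, 0) < 1e-3)

    def test_true_order_beats_permuted(self, two_chrom_sim):
        _, _, noisy, truth = two_chrom_sim
        res = filter_markers(noisy, "P1", "P2", FilterConfig())
        chrom_of = truth.chrom_of_marker()
        rows = [i for i, m in enumerate(res.marker_ids) if chrom_of[str(m)] == "1"]
        X = res.origins[rows][:12].T
        Rt, _, ll_true = chain.fit_intervals(X, eps=0.005)
        perm = list(range(12))
        perm[0], perm[-1] = perm[-1], perm[0]  # swap distant ends
        Rp, _, ll_perm = chain.fit_intervals(X[:, perm], eps=0.005)
        assert ll_true > ll_perm

    def test_missing_marginalized(self):
        X = np.array([[0, -1, 0], [1, -1, 1], [0, 0, 0]], dtype=np.int8)
        ll = chain.loglik(X, np.array([0.1, 0.1]), eps=0.01)
        assert np.isfinite(ll)


@pytest.fixture(scope="module")
def one_chrom_group(two_chrom_sim):
    """Filtered origin matrix restricted to true chromosome 1."""
    _, _, noisy, truth = two_chrom_sim
    res = filter_markers(noisy, "P1", "P2", FilterConfig())
    chrom_of = truth.chrom_of_marker()
    rows = np.array([i for i, m in enumerate(res.marker_ids)
                     if chrom_of[str(m)] == "1"])
    return res.origins[rows], res.marker_ids[rows], truth


class TestScaffold:
    def test_order_and_spacing(self, one_chrom_group):
        X, ids, truth = one_chrom_group
        mapf = mapfunc.MapFunction(4)
        scaf = build_scaffold(X, ids, mapf, n_replicates=4)
        true_cm = true_cm_lookup(truth)
        pos = [true_cm[str(ids[i])] for i in scaf.idx]
        tau = abs(kendalltau(pos, range(len(pos))).statistic)
        assert tau == pytest.approx(1.0)
        spacings = mapf.cm(scaf.R) if scaf.R.ndim else []
        assert (np.asarray([mapf.cm(R) for R in scaf.R]) >= 8.0).all()

    def test_cosegregating_duplicate_not_added(self, one_chrom_group):
        X, ids, truth = one_chrom_group
        X2 = np.vstack([X, X[5][None, :]])  # marker 5 duplicated
        ids2 = np.append(ids, "dup_of_5")
        mapf = mapfunc.MapFunction(4)
        scaf = build_scaffold(X2, ids2, mapf, n_replicates=3)
        names = {str(ids2[i]) for i in scaf.idx}
        assert not ({str(ids[5]), "dup_of_5"} <= names)

    def test_needs_three_markers(self):
        with pytest.raises(ValueError):
            build_scaffold(np.zeros((2, 50), dtype=np.int8),
                           np.array(["a", "b"], dtype=object),
                           mapfunc.MapFunction(0))


@pytest.fixture(scope="module")
def built(one_chrom_group):
    X, ids, truth = one_chrom_group
    mapf = mapfunc.MapFunction(4)
    scaf = build_scaffold(X, ids, mapf, n_replicates=4)
    fwk = extend_framework(scaf, X, ids, mapf)
    return X, ids, truth, mapf, scaf, fwk


@pytest.fixture(scope="module")
def messages(one_chrom_group, built):
    X, ids, truth = one_chrom_group
    _, _, _, mapf, _, fwk = built
    msg = FrameworkMessages(X[fwk.idx].T, fwk, mapf)
    return X, ids, truth, fwk, msg


class TestFramework:
    def test_framework_contains_scaffold(self, built):
        _, _, _, _, scaf, fwk = built
        assert set(scaf.idx) <= set(fwk.idx)

    def test_order_recovery(self, built):
        _, ids, truth, _, _, fwk = built
        true_cm = true_cm_lookup(truth)
        pos = [true_cm[str(ids[i])] for i in fwk.idx]
        tau = abs(kendalltau(pos, range(len(pos))).statistic)
        assert tau >= 0.995

    def test_duplicate_of_member_rejected(self, built):
        X, ids, _, mapf, _, fwk = built
        X2 = np.vstack([X, X[fwk.idx[3]][None, :]])
        ids2 = np.append(ids, "clone")
        fwk2 = extend_framework(fwk, X2, ids2, mapf)
        assert X2.shape[0] - 1 not in fwk2.idx  # the clone's row index

    def test_coordinates_monotone(self, built):
        _, _, _, mapf, _, fwk = built
        cm = fwk.cm_positions(mapf)
        assert (np.diff(cm) >= 0).all()
        assert fwk.pseudo_cm_positions(mapf)[-1] > cm[-1]


class TestBinPlacement:
    def test_framework_marker_resubmitted_lands_at_itself(self, messages):
        X, ids, truth, fwk, msg = messages
        pos = 4
        y = X[fwk.idx[pos]]
        placements = place_bins({"1": msg}, {"self": y}, min_score=0.0)
        p = placements[0]
        assert p.mapped
        assert abs(p.cm - msg.cm[pos]) < 3.0

    def test_all_missing_unmapped(self, messages):
        _, _, _, _, msg = messages
        y = np.full(msg.alpha.shape[0], -1, dtype=np.int8)
        p = place_bins({"1": msg}, {"gone": y})[0]
        assert not p.mapped

    def test_placements_fall_in_true_interval(self, messages):
        X, ids, truth, fwk, msg = messages
        true_cm = true_cm_lookup(truth)
        fw_true = np.array([true_cm[str(ids[i])] for i in fwk.idx])
        ascending = fw_true[0] < fw_true[-1]
        candidates = {str(ids[i]): X[i] for i in range(len(ids))
                      if i not in set(fwk.idx)}
        placements = place_bins({"1": msg}, candidates, min_score=0.5)
        ok = tot = 0
        sorted_true = np.sort(fw_true)
        for p in placements:
            if not p.mapped:
                continue
            tot += 1
            t = true_cm[p.marker]
            slot_true = int(np.searchsorted(sorted_true, t))
            slot_pred = p.slot if ascending else len(fw_true) - p.slot
            ok += slot_pred == slot_true
        assert tot > 0
        assert ok / tot >= 0.9


class TestEndToEnd:
    def test_two_chrom_build(self, two_chrom_build, two_chrom_sim):
        _, _, _, truth = two_chrom_sim
        lm = two_chrom_build.linkage_map
        chrom_of = truth.chrom_of_marker()
        true_cm = true_cm_lookup(truth)
        assert len(lm.chromosomes) >= 2
        for chrom, df in lm.chromosomes.items():
            # group purity
            chroms = {chrom_of[m] for m in df["marker"]}
            assert len(chroms) == 1
            fw = df[df["tier"].isin(("scaffold", "framework"))]
            tau = abs(kendalltau([true_cm[m] for m in fw["marker"]],
                                 fw["cm"]).statistic)
            assert tau >= 0.995
            assert df["cm"].min() == 0.0
            assert (df["cm"].diff().dropna() >= 0).all()
        assert lm.total_length_pseudo_cm() > lm.total_length_cm()
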