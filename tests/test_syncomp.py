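import numpy as np
import pandas as pd
import pytest

from irilmap import simpop, syncomp
from irilmap.core import LinkageMap, PhysicalPlacement
from irilmap.simpop import Deletion, GenomeModel, Inversion, Translocation
from irilmap.syncomp import (
    call_regions,
    cluster_nonsyntenic,
    concordance,
    deserts,
    landscape,
    predict_physical,
)


def truth_map(truth, jitter_sd=0.0, seed=0, population="pop"):
    """Genetic map straight from simulator truth, optionally jittered."""
    rng = np.random.default_rng(seed)
    chroms = {}
    for chrom, ids in truth.true_order.items():
        cm = truth.true_cm[chrom].astype(float)
        if jitter_sd:
            cm = cm + rng.normal(0, jitter_sd, size=cm.size)
        cm = cm - cm.min()
        chroms[chrom] = pd.DataFrame({
            "marker": ids, "tier": "framework", "cm": cm,
            "pseudo_cm": cm * 2.0, "score": np.nan})
    return LinkageMap(chromosomes=chroms, population=population)


@pytest.fixture(scope="module")
def genome_truth():
    genome = GenomeModel.uniform(n_chromosomes=3, markers_per_chrom=60,
                                 length_cm=150, length_bp=150_000_000, seed=17)
    design = simpop.PopulationDesign(n_lines=10, rng_seed=0)
    _, truth = simpop.simulate_iril_population(genome, design)
    placement = simpop.placement_from_truth(truth.true_bp, truth.true_order)
    return truth, placement


class TestConcordance:
    def test_colinear_no_discordance(self, genome_truth):
        truth, placement = genome_truth
        records, counts = concordance(truth_map(truth), placement)
        assert counts["n_discordant"] == 0
        assert counts["n_mapped_and_placed"] == counts["n_mapped"]

    def test_planted_translocation_found_exactly(self, genome_truth):
        truth, placement = genome_truth
        chr3 = placement.for_chrom("3")
        edit = Translocation("3", int(chr3["bp"].iloc[20]),
                             int(chr3["bp"].iloc[26]), "2", 160_000_000)
        corrupted, log = simpop.plant_misassembly(placement, [edit])
        moved = set(log.edits[0]["markers"])
        assert len(moved) == 7
        records, counts = concordance(truth_map(truth), corrupted)
        disc = set(records.loc[records["concordant"] == False, "marker"])  # noqa: E712
        assert disc == moved
        assert counts["n_discordant"] == 7

    def test_unplaced_markers_unflagged(self, genome_truth):
        truth, placement = genome_truth
        victims = placement.df["marker"].iloc[:3].tolist()
        corrupted, _ = simpop.plant_misassembly(placement, [Deletion(victims)])
        records, counts = concordance(truth_map(truth), corrupted)
        sub = records[records["marker"].isin(victims)]
        assert sub["concordant"].isna().all()
        assert counts["n_unplaced"] == 3


class TestClusterNonsyntenic:
    def test_far_apart_singletons(self):
        records = pd.DataFrame({
            "marker": ["a", "b"],
            "genetic_chrom": ["2", "2"],
            "cm": [1.0, 2.0],
            "tier": "framework",
            "phys_chrom": ["1", "1"],
            "phys_bp": [1_000_000, 501_000_000],
            "concordant": pd.array([False, False], dtype="boolean"),
        })
        out = cluster_nonsyntenic(records)
        assert list(out["kind"]) == ["singleton", "singleton"]

    def test_planted_block_is_one_cluster(self, genome_truth):
        truth, placement = genome_truth
        chr3 = placement.for_chrom("3")
        edit = Translocation("3", int(chr3["bp"].iloc[20]),
                             int(chr3["bp"].iloc[26]), "2", 160_000_000)
        corrupted, log = simpop.plant_misassembly(placement, [edit])
        records, _ = concordance(truth_map(truth), corrupted)
        # gap scaled to this simulation's ~2.5 Mbp marker spacing
        out = cluster_nonsyntenic(records, max_gap_bp=20_000_000)
        assert len(out) == 1
        assert out["kind"].iloc[0] == "cluster"
        assert out["n_markers"].iloc[0] == 7
        assert out["phys_chrom"].iloc[0] == "2"
        assert out["genetic_chrom"].iloc[0] == "3"

    def test_empty_records(self, genome_truth):
        truth, placement = genome_truth
        records, _ = concordance(truth_map(truth), placement)
        assert cluster_nonsyntenic(records).empty


class TestCallRegions:
    def test_colinear_no_regions(self, genome_truth):
        truth, placement = genome_truth
        out = call_regions(truth_map(truth), placement)
        assert out.empty

    def test_planted_inversion_found_in_both_populations(self, genome_truth):
        truth, placement = genome_truth
        chr2 = placement.for_chrom("2")
        edit = Inversion("2", int(chr2["bp"].iloc[25]),
                         int(chr2["bp"].iloc[34]))
        corrupted, log = simpop.plant_misassembly(placement, [edit])
        span = (log.edits[0]["start_bp"], log.edits[0]["end_bp"])
        regions_i = call_regions(truth_map(truth, population="ibm"),
                                 corrupted, population_suffix="I")
        regions_l = call_regions(truth_map(truth, population="lhrf"),
                                 corrupted, other_regions=regions_i,
                                 population_suffix="L")
        for regions, suffix in ((regions_i, "I"), (regions_l, "L")):
            assert len(regions) == 1
            row = regions.iloc[0]
            assert row["chrom"] == "2"
            assert row["name"] == f"2.1{suffix}"
            assert row["start_bp"] >= span[0] and row["end_bp"] <= span[1]
            assert row["n_markers"] >= 5
        assert bool(regions_l["supported_by_other"].iloc[0])

    def test_single_displaced_marker_without_support_not_a_region(
            self, genome_truth):
        truth, placement = genome_truth
        # displace one marker genetically by swapping far along chromosome 1
        lmap = truth_map(truth)
        df = lmap.chromosomes["1"].copy()
        df.loc[5, "cm"] = df["cm"].max() - 1.0
        lmap2 = LinkageMap(chromosomes={**lmap.chromosomes, "1": df},
                           population="pop")
        out = call_regions(lmap2, placement, other_regions=None)
        assert out.empty

    def test_false_positive_rate_over_replicates(self, genome_truth):
        # colinear maps with coordinate jitter: <= 1 false region per
        # genome on average over 200 replicates
        truth, placement = genome_truth
        total = 0
        for rep in range(200):
            lmap = truth_map(truth, jitter_sd=0.4, seed=rep)
            total += len(call_regions(lmap, placement))
        assert total / 200 <= 1.0


class TestLandscape:
    def linear_setup(self, n=60):
        # x cM == x Mbp exactly
        bp = np.linspace(1, 100_000_000, n).astype(int)
        cm = (bp - 1) / 1e6
        chroms = {"1": pd.DataFrame({
            "marker": [f"m{i}" for i in range(n)], "tier": "framework",
            "cm": cm, "pseudo_cm": cm, "score": np.nan})}
        lmap = LinkageMap(chromosomes=chroms, population="p")
        placement = PhysicalPlacement.from_records(
            [(f"m{i}", "1", int(b)) for i, b in enumerate(bp)])
        return lmap, placement

    def test_linear_map_constant_unit_rate(self):
        lmap, placement = self.linear_setup()
        out = landscape(lmap, placement)["1"]
        assert np.allclose(out["rate_cm_per_mbp"], 1.0, atol=0.05)

    def test_rate_integrates_to_genetic_length(self):
        lmap, placement = self.linear_setup()
        out = landscape(lmap, placement)["1"]
        integral = np.trapezoid(out["rate_cm_per_mbp"], out["bp"] / 1e6)
        length = out["cm_smoothed"].iloc[-1] - out["cm_smoothed"].iloc[0]
        assert integral == pytest.approx(length, rel=0.01)

    def test_centromeric_suppression_recovered(self):
        def profile(f):  # flat middle third
            if f < 1 / 3:
                return 1.5 * f
            if f < 2 / 3:
                return 0.5
            return 0.5 + 1.5 * (f - 2 / 3)
        genome = GenomeModel.uniform(n_chromosomes=1, markers_per_chrom=120,
                                     length_cm=150, length_bp=150_000_000,
                                     seed=3, cm_profile=profile)
        design = simpop.PopulationDesign(n_lines=5, rng_seed=0)
        _, truth = simpop.simulate_iril_population(genome, design)
        placement = simpop.placement_from_truth(truth.true_bp, truth.true_order)
        out = landscape(truth_map(truth), placement,
                        bandwidth_bp=5_000_000)["1"]
        mid = out[(out["bp"] > 60_000_000) & (out["bp"] < 90_000_000)]
        assert (mid["rate_cm_per_mbp"] < 0.1).all()
        assert (out["cm_smoothed"].diff().dropna() >= 0).all()

    def test_too_few_markers_rejected(self):
        lmap, placement = self.linear_setup(n=10)
        with pytest.raises(ValueError, match="concordant markers"):
            landscape(lmap, placement)


class TestPredictPhysical:
    def anchored_map(self):
        chroms = {"1": pd.DataFrame({
            "marker": ["a", "x", "b"],
            "tier": ["framework", "placed", "framework"],
            "cm": [0.0, 5.0, 10.0],
            "pseudo_cm": [0.0, 10.0, 20.0],
            "score": np.nan})}
        lmap = LinkageMap(chromosomes=chroms, population="p")
        placement = PhysicalPlacement.from_records(
            [("a", "1", 10_000_000), ("b", "1", 20_000_000), ("x", None, None)])
        return lmap, placement

    def test_midpoint_interpolation(self):
        lmap, placement = self.anchored_map()
        out = predict_physical(["x"], lmap, placement)
        assert out["pred_chrom"].iloc[0] == "1"
        assert out["pred_bp"].iloc[0] == pytest.approx(15_000_000)

    def test_marker_at_anchor_position(self):
        lmap, placement = self.anchored_map()
        df = lmap.chromosomes["1"].copy()
        df.loc[df["marker"] == "x", "cm"] = 0.0
        lmap2 = LinkageMap(chromosomes={"1": df}, population="p")
        out = predict_physical(["x"], lmap2, placement)
        assert out["pred_bp"].iloc[0] == pytest.approx(10_000_000)

    def test_no_anchors_reported(self):
        chroms = {"1": pd.DataFrame({
            "marker": ["x"], "tier": ["placed"], "cm": [1.0],
            "pseudo_cm": [2.0], "score": np.nan})}
        lmap = LinkageMap(chromosomes=chroms, population="p")
        placement = PhysicalPlacement.from_records([("x", None, None)])
        out = predict_physical(["x"], lmap, placement)
        assert out["note"].iloc[0] == "no concordant anchors"

    def test_deleted_markers_recovered_near_truth(self, genome_truth):
        truth, placement = genome_truth
        chr1 = placement.for_chrom("1")
        victims = chr1["marker"].iloc[10:40:3].tolist()
        corrupted, _ = simpop.plant_misassembly(placement, [Deletion(victims)])
        out = predict_physical(victims, truth_map(truth), corrupted)
        true_bp = placement.bp_of()
        errors, spacings = [], []
        anchors = corrupted.for_chrom("1")["bp"].to_numpy(dtype=float)
        for row in out.itertuples(index=False):
            assert row.pred_chrom == "1"
            errors.append(abs(row.pred_bp - float(true_bp[row.marker])))
            i = np.searchsorted(anchors, true_bp[row.marker])
            lo = anchors[max(i - 1, 0)]
            hi = anchors[min(i, anchors.size - 1)]
            spacings.append(hi - lo)
        assert np.median(errors) < 0.5 * np.median(spacings) + 1.0


class TestDeserts:
    def test_identical_sets_no_deserts(self, genome_truth):
        _, placement = genome_truth
        markers = set(placement.df["marker"])
        out = deserts(placement, {"a": markers, "b": markers})
        assert out.empty

    def test_planted_ibd_block_found(self, genome_truth):
        _, placement = genome_truth
        chr2 = placement.for_chrom("2")
        lo, hi = 50_000_000, 80_000_000
        inside = set(chr2.loc[chr2["bp"].between(lo, hi), "marker"])
        assert len(inside) >= 5
        all_markers = set(placement.df["marker"])
        out = deserts(placement, {"ibm": all_markers - inside,
                                  "lhrf": all_markers},
                      min_span_mbp=20.0)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["empty_population"] == "ibm"
        assert row["chrom"] == "2"
        assert row["start_bp"] <= lo and row["end_bp"] >= hi - 30_000_000
        assert row["n_markers_other_pop"] >= 5

    def test_min_span_larger_than_chromosome(self, genome_truth):
        _, placement = genome_truth
        markers = set(placement.df["marker"])
        half = set(list(markers)[:50])
        out = deserts(placement, {"a": half, "b": markers},
                      min_span_mbp=1e6)
        assert out.empty


class TestRelabel:
    def test_groups_take_majority_physical_chromosome(self, genome_truth):
        truth, placement = genome_truth
        lmap = truth_map(truth)
        relabeled = syncomp.relabel_by_placement(
            LinkageMap(chromosomes={f"LG{c}": df for c, df
                                    in lmap.chromosomes.items()},
                       population="p"),
            placement)
        assert set(relabeled.chromosomes) == {"1", "2", "3"}
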