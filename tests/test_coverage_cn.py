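import numpy as np
import pytest

from cidscope.coverage_cn import (
    CoverageProfile,
    PlacementTable,
    RegionSet,
    compute_coverage,
    estimate_copy_number,
    map_reads_exact,
    normalize,
    qpcr_copy_ratio,
    region_mean,
)
from cidscope.errors import CoverageError, RegionError, TableError
from cidscope.synthetic_data import (
    simulate_qpcr,
    simulate_reads,
    simulate_strain,
)
from cidscope.util import revcomp


def placements(rows):
    starts, lengths, strands = zip(*rows)
    return PlacementTable(
        np.array(starts), np.array(lengths), np.array(strands)
    )


class TestMapReadsExact:
    def test_forward_exact_placement(self, model):
        ref = model.reference
        table = map_reads_exact([("r", ref[100:200])], ref)
        assert table.starts[0] == 100 and table.strands[0] == 0

    def test_reverse_complement_placement(self, model):
        ref = model.reference
        table = map_reads_exact([("r", revcomp(ref[0:100]))], ref)
        assert table.starts[0] == 0 and table.strands[0] == 1

    def test_empty_reference_raises(self):
        with pytest.raises(CoverageError):
            map_reads_exact([("r", "ACGT")], "")

    def test_multicopy_reads_pile_on_reference_copy(self, model):
        # brute-force all-substring oracle on a subsample of reads
        strain = simulate_strain(model, 3, seed=5)
        reads = simulate_reads(strain, 4, 100, 0.0, seed=6)
        table = map_reads_exact(reads, strain.reference_genome)
        ref = strain.reference_genome
        checked = 0
        for start, strand, read_idx in zip(
            table.starts, table.strands, table.read_indices
        ):
            if checked >= 40:
                break
            seq = reads[read_idx][1]
            oriented = seq if strand == 0 else revcomp(seq)
            idx = ref.find(oriented)
            if idx >= 0:  # exact-matching reads: leftmost occurrence
                assert start == idx
                checked += 1
        assert checked == 40

    def test_operon_density_about_three_fold(self, model):
        strain = simulate_strain(model, 3, seed=5)
        reads = simulate_reads(strain, 25, 100, 0.0, seed=6)
        table = map_reads_exact(reads, strain.reference_genome)
        prof = normalize(compute_coverage(table, len(strain.reference_genome)))
        op = region_mean(prof, strain.annotations["operon"],
                         list(strain.exclusions.values()))
        mk = region_mean(prof, strain.annotations["marker_05"], [])
        assert op / mk == pytest.approx(3.0, rel=0.15)


class TestComputeCoverage:
    def test_no_reads_all_zero(self):
        prof = compute_coverage(
            PlacementTable(np.array([], int), np.array([], int), np.array([], int)),
            50,
        )
        assert (prof.depth == 0).all()

    def test_single_read(self):
        prof = compute_coverage(placements([(0, 100, 0)]), 200)
        assert (prof.depth[:100] == 1).all() and (prof.depth[100:] == 0).all()

    def test_overlapping_reads_interval_stabbing(self):
        prof = compute_coverage(placements([(0, 100, 0), (50, 100, 0)]), 200)
        # interval-stabbing oracle
        for i in range(200):
            expected = sum(1 for s, l in [(0, 100), (50, 100)] if s <= i < s + l)
            assert prof.depth[i] == expected

    def test_depth_sum_equals_placed_read_lengths(self, model):
        strain = simulate_strain(model, 2, seed=1)
        reads = simulate_reads(strain, 3, 80, 0.0, seed=2)
        table = map_reads_exact(reads, strain.reference_genome)
        prof = compute_coverage(table, len(strain.reference_genome))
        assert prof.depth.sum() == table.lengths.sum()

    def test_out_of_bounds_placement_raises(self):
        with pytest.raises(CoverageError):
            compute_coverage(placements([(150, 100, 0)]), 200)


class TestNormalize:
    def test_uniform_profile(self):
        prof = normalize(CoverageProfile(np.full(10, 50.0)))
        assert np.allclose(prof.depth, 1.0)

    def test_hand_arithmetic(self):
        prof = normalize(CoverageProfile(np.array([2.0, 2.0, 6.0, 6.0])))
        assert np.allclose(prof.depth, [0.5, 0.5, 1.5, 1.5])

    def test_idempotent_and_mean_one(self):
        rng = np.random.default_rng(0)
        prof = normalize(CoverageProfile(rng.poisson(20, 500).astype(float)))
        assert prof.genome_mean == pytest.approx(1.0, abs=1e-9)
        twice = normalize(prof)
        assert np.allclose(prof.depth, twice.depth)

    def test_all_zero_raises(self):
        with pytest.raises(CoverageError):
            normalize(CoverageProfile(np.zeros(10)))


class TestRegionMean:
    def test_uniform(self):
        prof = CoverageProfile(np.ones(100), normalized=True)
        assert region_mean(prof, (10, 60)) == 1.0

    def test_exclusion_hand_arithmetic(self):
        depth = np.concatenate([np.full(5, 3.0), np.full(5, 1.0)])
        prof = CoverageProfile(depth)
        assert region_mean(prof, (0, 10), [(5, 10)]) == 3.0

    def test_tail_exclusion_removes_duplication_inflation(self, model):
        # constructed profile: depth 1 everywhere, 2 over the duplicated tail
        ref_len = len(model.reference)
        depth = np.ones(ref_len)
        tail = model.exclusions["exclude_cidB_tail"]
        depth[tail[0] : tail[1]] = 2.0
        prof = CoverageProfile(depth)
        cidB = model.annotations["cidB"]
        inflated = region_mean(prof, cidB, [])
        corrected = region_mean(prof, cidB, [tail])
        assert inflated > 1.0
        assert corrected == 1.0

    def test_fully_excluded_region_raises(self):
        prof = CoverageProfile(np.ones(10))
        with pytest.raises(RegionError):
            region_mean(prof, (2, 4), [(0, 10)])


class TestEstimateCopyNumber:
    def _tiling_scenario(self):
        """Deterministic tiling oracle: 400 nt reference; operon [100, 200)
        tiled twice, everything tiled once, in 20 nt reads."""
        rows = [(s, 20, 0) for s in range(0, 400, 20)]
        rows += [(s, 20, 0) for s in range(100, 200, 20)]
        prof = compute_coverage(placements(rows), 400)
        regions = RegionSet(
            operon={"cidA": (100, 200)},
            markers={f"marker_{i}": (200 + 40 * i, 240 + 40 * i) for i in range(4)},
        )
        return prof, regions

    def test_deterministic_tiling_exactly_two(self):
        prof, regions = self._tiling_scenario()
        est = estimate_copy_number(normalize(prof), regions)
        # normalization rescales operon and markers identically
        assert est.estimate == pytest.approx(2.0, abs=1e-12)

    def test_single_copy_estimate_near_one(self, model):
        strain = simulate_strain(model, 1, seed=3)
        reads = simulate_reads(strain, 50, 100, 0.0, seed=4)
        prof = normalize(compute_coverage(
            map_reads_exact(reads, strain.reference_genome),
            len(strain.reference_genome),
        ))
        regions = RegionSet.from_annotations(strain.annotations, strain.exclusions)
        est = estimate_copy_number(prof, regions)
        assert est.estimate == pytest.approx(1.0, rel=0.10)

    def test_three_copy_estimate_near_three(self, model):
        strain = simulate_strain(model, 3, seed=3)
        reads = simulate_reads(strain, 50, 100, 0.0, seed=4)
        prof = normalize(compute_coverage(
            map_reads_exact(reads, strain.reference_genome),
            len(strain.reference_genome),
        ))
        regions = RegionSet.from_annotations(strain.annotations, strain.exclusions)
        est = estimate_copy_number(prof, regions)
        assert est.estimate == pytest.approx(3.0, rel=0.10)

    def test_zero_marker_listed_in_error(self):
        prof, regions = self._tiling_scenario()
        prof.depth[200:240] = 0  # wipe marker_0
        with pytest.raises(CoverageError, match="marker_0"):
            estimate_copy_number(normalize(prof), regions)

    def test_no_markers_raises(self):
        prof, _ = self._tiling_scenario()
        with pytest.raises(CoverageError):
            estimate_copy_number(
                normalize(prof), RegionSet(operon={"cidA": (0, 10)}, markers={})
            )

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_estimator_recovery_over_seeds(self, model, k):
        # scaled-down version of the 20-seed recovery check (runtime budget)
        estimates = []
        for seed in range(5):
            strain = simulate_strain(model, k, seed=seed)
            reads = simulate_reads(strain, 30, 100, 0.0, seed=seed + 100)
            prof = normalize(compute_coverage(
                map_reads_exact(reads, strain.reference_genome),
                len(strain.reference_genome),
            ))
            regions = RegionSet.from_annotations(strain.annotations, strain.exclusions)
            estimates.append(estimate_copy_number(prof, regions).estimate)
        assert np.mean(estimates) == pytest.approx(k, rel=0.10)


class TestQpcrRatio:
    def _table(self, cq_map):
        import pandas as pd

        rows = [
            {"sample_id": "s", "locus": locus, "replicate": 1, "cq": cq}
            for locus, cq in cq_map.items()
        ]
        return pd.DataFrame(rows)

    def test_equal_cq_ratio_one(self):
        est = qpcr_copy_ratio(self._table({"cidA": 24.0, "wsp": 24.0}), "cidA")
        assert est.estimate == 1.0

    def test_two_cycle_delta_ratio_four(self):
        est = qpcr_copy_ratio(self._table({"cidA": 22.0, "wsp": 24.0}), "cidA")
        assert est.estimate == pytest.approx(4.0)

    def test_missing_locus_raises(self):
        with pytest.raises(TableError):
            qpcr_copy_ratio(self._table({"cidA": 22.0}), "cidA", "wsp")

    def test_cidA_cidB_ratio_one_on_noiseless_strain(self, strain_k3):
        table = simulate_qpcr(strain_k3, noise_sd=0.0)
        est = qpcr_copy_ratio(table, "cidA", "cidB")
        assert est.estimate == pytest.approx(1.0, abs=1e-12)

    def test_qpcr_recovers_k_with_noise(self, model):
        strain = simulate_strain(model, 3, seed=8)
        table = simulate_qpcr(strain, noise_sd=0.1, seed=9)
        est = qpcr_copy_ratio(table, "cidA")
        assert est.estimate == pytest.approx(3.0, rel=0.15)

    def test_methods_agree(self, model):
        strain = simulate_strain(model, 3, seed=3)
        reads = simulate_reads(strain, 50, 100, 0.0, seed=4)
        prof = normalize(compute_coverage(
            map_reads_exact(reads, strain.reference_genome),
            len(strain.reference_genome),
        ))
        regions = RegionSet.from_annotations(strain.annotations, strain.exclusions)
        cov_est = estimate_copy_number(prof, regions).estimate
        q_est = qpcr_copy_ratio(simulate_qpcr(strain, noise_sd=0.1, seed=5), "cidA").estimate
        assert abs(cov_est - q_est) / q_est < 0.20


def test_coverage_uniformity_over_single_copy_locus(model):
    # error-free reads from the reference itself, mapped back: mean
    # normalized depth over a marker within 5% of 1
    reads = simulate_reads(model.reference, 100, 100, 0.0, seed=21)
    prof = normalize(compute_coverage(
        map_reads_exact(reads, model.reference), len(model.reference)
    ))
    marker_means = [
        region_mean(prof, interval, [])
        for name, interval in model.annotations.items()
        if name.startswith("marker_")
    ]
    assert np.mean(marker_means) == pytest.approx(1.0, rel=0.05)
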