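"""Ancestry thresholding, block merging, copy counts and genome fractions."""

import numpy as np
import pandas as pd
import pytest

from insula import introgression as intro
from insula.synthetic import AncestrySimTruth, simulate_ancestry_tracks


def _track(probs, positions=None, ind="I1", hap=1, chrom="chr1"):
    positions = positions or list(range(100, 100 * (len(probs) + 1), 100))
    return pd.DataFrame(
        {
            "individual": ind,
            "haplotype": hap,
            "chrom": chrom,
            "pos": positions,
            "prob_sourceA": probs,
        }
    )


ALL_SIX = [(f"IND_{i}", h) for i in (1, 2, 3) for h in (1, 2)]


class TestCallIntrogressedSnps:
    def test_direct_thresholding_with_unknowns(self):
        calls = intro.call_introgressed_snps(
            _track([0.95, 0.5, 9.0, 0.91]), threshold=0.9
        )
        assert list(calls["call"][[0, 1, 3]]) == [True, False, True]
        assert calls["call"][2] is pd.NA

    def test_threshold_one_keeps_only_certain_calls(self):
        calls = intro.call_introgressed_snps(
            _track([1.0, 0.999, 0.5]), threshold=1.0
        )
        assert list(calls["call"]) == [True, False, False]

    def test_invalid_probability_rejected_with_record(self):
        with pytest.raises(ValueError, match="chr1:200"):
            intro.call_introgressed_snps(_track([0.5, 1.5]))

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            intro.call_introgressed_snps(
                _track([0.5, 0.6], positions=[200, 100])
            )

    def test_noise_free_calls_equal_truth_membership(self):
        truth = AncestrySimTruth(
            blocks=[("chr1", 200_000, 600_000, ALL_SIX[:2])],
            chrom_lengths={"chr1": 1_000_000},
            n_individuals=3,
            noise_sd=0.0,
        )
        track = simulate_ancestry_tracks(truth, snp_spacing=1000, seed=0)
        calls = intro.call_introgressed_snps(track)
        inside = (
            (track["pos"] - 1 >= 200_000)
            & (track["pos"] - 1 < 600_000)
            & (track["individual"] == "IND_1")
        )
        assert (calls.loc[inside, "call"] == True).all()  # noqa: E712
        assert not calls.loc[~inside, "call"].any()


class TestMergeBlocks:
    def test_runs_become_half_open_blocks(self):
        calls = intro.call_introgressed_snps(
            _track([0.95, 0.92, 0.5, 0.91], positions=[100, 200, 300, 400])
        )
        blocks = intro.merge_blocks(calls)
        assert list(
            blocks[["start", "end", "length"]].itertuples(index=False, name=None)
        ) == [(100, 201, 101), (400, 401, 1)]

    def test_brute_force_interval_scan_agrees(self):
        rng = np.random.default_rng(42)
        probs = rng.choice([0.95, 0.2], size=50)
        positions = np.sort(rng.choice(np.arange(1, 10_000), 50, replace=False))
        calls = intro.call_introgressed_snps(_track(probs, list(positions)))
        blocks = intro.merge_blocks(calls)
        # brute force: walk the SNPs, open/close runs
        expected = []
        run = None
        for p, c in zip(positions, probs >= 0.9):
            if c:
                run = (run[0], p) if run else (p, p)
            elif run:
                expected.append((run[0], run[1] + 1))
                run = None
        if run:
            expected.append((run[0], run[1] + 1))
        assert [
            (r.start, r.end) for r in blocks.itertuples(index=False)
        ] == expected

    def test_all_negative_yields_empty_frame(self):
        calls = intro.call_introgressed_snps(_track([0.1, 0.2, 0.3]))
        assert len(intro.merge_blocks(calls)) == 0

    def test_unknown_bridges_a_run(self):
        calls = intro.call_introgressed_snps(
            _track([0.95, 9.0, 0.95], positions=[100, 200, 300])
        )
        blocks = intro.merge_blocks(calls, gap_policy="bridge")
        assert list(blocks[["start", "end"]].iloc[0]) == [100, 301]

    def test_unknown_never_starts_or_ends_a_run(self):
        calls = intro.call_introgressed_snps(
            _track([9.0, 0.95, 9.0, 0.1], positions=[100, 200, 300, 400])
        )
        blocks = intro.merge_blocks(calls, gap_policy="bridge")
        assert list(blocks[["start", "end"]].iloc[0]) == [200, 201]

    def test_break_policy_splits_on_unknown(self):
        calls = intro.call_introgressed_snps(
            _track([0.95, 9.0, 0.95], positions=[100, 200, 300])
        )
        blocks = intro.merge_blocks(calls, gap_policy="break")
        assert [(r.start, r.end) for r in blocks.itertuples(index=False)] == [
            (100, 101),
            (300, 301),
        ]

    def test_idempotent_under_reapplication(self):
        calls = intro.call_introgressed_snps(
            _track([0.95, 0.92, 0.5, 0.91, 9.0, 0.93])
        )
        b1 = intro.merge_blocks(calls)
        # re-derive per-SNP calls from the blocks and merge again
        pos = calls["pos"].to_numpy()
        covered = np.zeros(len(pos), dtype=bool)
        for r in b1.itertuples(index=False):
            covered |= (pos >= r.start) & (pos < r.end)
        recalled = calls.copy()
        recalled["call"] = pd.array(covered, dtype="boolean")
        b2 = intro.merge_blocks(recalled)
        pd.testing.assert_frame_equal(b1, b2)


class TestCopyCountProfile:
    def test_six_identical_blocks_give_one_segment(self):
        blocks = pd.DataFrame(
            [
                (ind, hap, "chr1", 1000, 2001)
                for ind, hap in ALL_SIX
            ],
            columns=["individual", "haplotype", "chrom", "start", "end"],
        )
        profile = intro.copy_count_profile(blocks)
        seg = profile["chr1"]
        assert list(seg.itertuples(index=False, name=None)) == [(1000, 2001, 6)]

    def test_half_overlap_gives_three_segments(self):
        blocks = pd.DataFrame(
            [
                ("I1", 1, "chr1", 100, 301),
                ("I1", 2, "chr1", 200, 401),
            ],
            columns=["individual", "haplotype", "chrom", "start", "end"],
        )
        seg = intro.copy_count_profile(blocks)["chr1"]
        assert list(seg.itertuples(index=False, name=None)) == [
            (100, 200, 1),
            (200, 301, 2),
            (301, 401, 1),
        ]

    def test_empty_input_gives_empty_profile(self):
        blocks = pd.DataFrame(
            columns=["individual", "haplotype", "chrom", "start", "end"]
        )
        assert intro.copy_count_profile(blocks) == {}

    def test_same_haplotype_overlap_rejected(self):
        blocks = pd.DataFrame(
            [
                ("I1", 1, "chr1", 100, 301),
                ("I1", 1, "chr1", 200, 401),
            ],
            columns=["individual", "haplotype", "chrom", "start", "end"],
        )
        with pytest.raises(ValueError, match="overlapping"):
            intro.copy_count_profile(blocks)

    @pytest.mark.parametrize("seed", range(5))
    def test_sweep_line_equals_per_bp_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for ind in ("I1", "I2", "I3"):
            for hap in (1, 2):
                cuts = np.sort(
                    rng.choice(np.arange(1, 100_000), 8, replace=False)
                )
                for s, e in zip(cuts[::2], cuts[1::2]):
                    rows.append((ind, hap, "chr1", int(s), int(e)))
        blocks = pd.DataFrame(
            rows, columns=["individual", "haplotype", "chrom", "start", "end"]
        )
        seg = intro.copy_count_profile(blocks)["chr1"]
        per_bp = np.zeros(100_001, dtype=int)
        for r in blocks.itertuples(index=False):
            per_bp[r.start:r.end] += 1
        sweep = np.zeros(100_001, dtype=int)
        for r in seg.itertuples(index=False):
            sweep[r.start:r.end] = r.n_copies
        assert (sweep == per_bp).all()


class TestGenomeFraction:
    def _profile(self, segs):
        return {
            "chr1": pd.DataFrame(segs, columns=["start", "end", "n_copies"])
        }

    def test_single_block_fraction(self):
        profile = self._profile([(1, 10_000_001, 1)])
        summary = intro.genome_fraction(profile, {"chr1": 100_000_000})
        assert summary.fractions[1] == pytest.approx(0.10)

    def test_impossible_copy_count_gives_zero(self):
        profile = self._profile([(1, 1001, 6)])
        summary = intro.genome_fraction(
            profile, {"chr1": 10_000}, max_copies=7
        )
        assert summary.fractions[7] == 0.0

    def test_monotone_nonincreasing_in_k(self):
        profile = self._profile([(1, 1001, 1), (500, 801, 3), (900, 951, 6)])
        summary = intro.genome_fraction(profile, {"chr1": 10_000})
        fr = [summary.fractions[k] for k in sorted(summary.fractions)]
        assert all(a >= b for a, b in zip(fr, fr[1:]))

    def test_sex_chromosomes_excluded_from_denominator(self):
        profile = self._profile([(1, 1001, 1)])
        summary = intro.genome_fraction(
            profile, {"chr1": 10_000, "chrX": 5_000}
        )
        assert summary.denominator_bp == 10_000

    def test_block_beyond_chromosome_end_rejected(self):
        profile = self._profile([(1, 20_002, 1)])
        with pytest.raises(ValueError, match="beyond"):
            intro.genome_fraction(profile, {"chr1": 20_000})


class TestFixedRegions:
    def test_full_copy_region_emitted(self):
        blocks = pd.DataFrame(
            [(ind, hap, "chr1", 5000, 8001) for ind, hap in ALL_SIX]
            + [("IND_1", 1, "chr1", 9000, 9501)],
            columns=["individual", "haplotype", "chrom", "start", "end"],
        )
        profile = intro.copy_count_profile(blocks)
        fixed = intro.fixed_regions(profile, total_haplotypes=6)
        assert list(fixed.itertuples(index=False, name=None)) == [
            ("chr1", 5000, 8001)
        ]

    def test_one_missing_haplotype_removes_region(self):
        blocks = pd.DataFrame(
            [(ind, hap, "chr1", 5000, 8001) for ind, hap in ALL_SIX[:-1]],
            columns=["individual", "haplotype", "chrom", "start", "end"],
        )
        profile = intro.copy_count_profile(blocks)
        assert len(intro.fixed_regions(profile, total_haplotypes=6)) == 0

    def test_bed_round_trip(self, tmp_path):
        from insula import io

        blocks = pd.DataFrame(
            [(ind, hap, "chr1", 5000, 8001) for ind, hap in ALL_SIX],
            columns=["individual", "haplotype", "chrom", "start", "end"],
        )
        fixed = intro.fixed_regions(
            intro.copy_count_profile(blocks), total_haplotypes=6
        )
        path = tmp_path / "fixed.bed"
        io.write_bed(intro.blocks_to_bed(fixed), path)
        assert io.read_bed(path) == [("chr1", 4999, 8000)]


def test_truth_block_recovered_for_whole_chromosome():
    """One block covering a whole chromosome for all six haplotypes is
    recovered exactly by the fixed-region caller."""
    truth = AncestrySimTruth(
        blocks=[("chr1", 0, 1_000_000, ALL_SIX)],
        chrom_lengths={"chr1": 1_000_000},
        n_individuals=3,
        noise_sd=0.0,
    )
    track = simulate_ancestry_tracks(truth, snp_spacing=1000, seed=1)
    calls = intro.call_introgressed_snps(track)
    blocks = intro.merge_blocks(calls)
    profile = intro.copy_count_profile(blocks)
    fixed = intro.fixed_regions(profile, total_haplotypes=6)
    assert len(fixed) == 1
    row = fixed.iloc[0]
    # first SNP at pos 1, last at 999001; end is last SNP + 1
    assert (row.chrom, row.start, row.end) == ("chr1", 1, 999_002)
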