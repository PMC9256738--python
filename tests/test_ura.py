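import numpy as np
import pytest

from _oracles import brute_unique_positions
from gutrefset.synthetic import simulate_genome, simulate_reads
from gutrefset.ura import (
    AlignmentRecord,
    UniquenessIndex,
    alignment_rates,
    build_uniqueness_index,
    classify_reads,
    exact_read_mapper,
    partition_windows,
    read_alignments_sam,
    read_alignments_tsv,
    ura_profile,
    write_alignments_tsv,
)

R = 100  # read length used throughout


class TestUniquenessIndex:
    def test_repeat_free_genome_fully_unique(self):
        g = {"a": simulate_genome(3000, 80).sequence}
        index = build_uniqueness_index(g, R)
        assert index.unique["a"].all()
        assert index.unique_counts["a"] == 3000 - R + 1

    def test_identical_genomes_share_everything(self):
        seq = simulate_genome(3000, 81).sequence
        index = build_uniqueness_index({"a": seq, "b": seq}, R)
        assert index.unique_counts == {"a": 0, "b": 0}

    def test_internal_duplication_matches_brute_force(self):
        rng = np.random.default_rng(82)
        parts = [simulate_genome(n, rng).sequence for n in (600, 500, 400)]
        dup = simulate_genome(200, rng).sequence
        seq = parts[0] + dup + parts[1] + dup + parts[2]
        genomes = {"a": seq, "b": simulate_genome(800, rng).sequence}
        index = build_uniqueness_index(genomes, R)
        oracle = brute_unique_positions(genomes, R)
        for gid in genomes:
            assert index.unique[gid].tolist() == oracle[gid]
        # positions fully inside either duplicate copy are non-unique
        start1 = 600
        inside = index.unique["a"][start1 : start1 + 200 - R + 1]
        assert not inside.any()

    def test_reverse_complement_copy_detected(self):
        from gutrefset.ura import reverse_complement

        seq = simulate_genome(1000, 83).sequence
        genomes = {"fwd": seq, "rev": reverse_complement(seq)}
        index = build_uniqueness_index(genomes, R)
        assert index.unique_counts == {"fwd": 0, "rev": 0}

    def test_removing_genome_never_decreases_uniqueness(self):
        seq = simulate_genome(2000, 84).sequence
        other = simulate_genome(2000, 85).sequence
        with_copy = build_uniqueness_index({"a": seq, "b": seq[:1200], "c": other}, R)
        without = build_uniqueness_index({"a": seq, "c": other}, R)
        assert without.unique_counts["a"] >= with_copy.unique_counts["a"]
        assert without.unique_counts["c"] >= with_copy.unique_counts["c"]

    def test_bad_read_length_rejected(self):
        with pytest.raises(ValueError):
            build_uniqueness_index({"a": "ACGT"}, 0)


def synthetic_index(unique_flags, read_length=1):
    """Index built directly from boolean position flags."""
    arrays = {g: np.asarray(f, dtype=bool) for g, f in unique_flags.items()}
    return UniquenessIndex(
        read_length=read_length,
        genome_lengths={g: len(a) for g, a in arrays.items()},
        unique=arrays,
    )


class TestWindowPartition:
    def test_all_unique_equal_windows(self):
        index = synthetic_index({"g": [True] * 1000})
        part = partition_windows(index, 100)
        assert part.windows["g"] == [(i * 100, (i + 1) * 100) for i in range(10)]
        assert part.expected_unique["g"] == [100] * 10

    def test_alternating_uniqueness_doubles_window_length(self):
        index = synthetic_index({"g": [True, False] * 500})
        part = partition_windows(index, 100)
        widths = [e - s for s, e in part.windows["g"]]
        assert widths[:4] == [200, 200, 200, 200]
        assert part.expected_unique["g"][:4] == [100] * 4

    def test_window_larger_than_total_gives_single_window(self):
        index = synthetic_index({"g": [True] * 30})
        part = partition_windows(index, 100)
        assert part.windows["g"] == [(0, 30)]
        assert part.expected_unique["g"] == [30]

    def test_zero_unique_genome_excluded_and_flagged(self):
        index = synthetic_index({"g": [False] * 50, "ok": [True] * 50})
        part = partition_windows(index, 10)
        assert "g" not in part.windows
        assert part.skipped == ["g"]

    def test_windows_tile_without_overlap(self):
        rng = np.random.default_rng(86)
        index = synthetic_index({"g": rng.random(5000) < 0.3})
        part = partition_windows(index, 50)
        win = part.windows["g"]
        assert win[0][0] == 0
        assert win[-1][1] == 5000
        for (s1, e1), (s2, e2) in zip(win, win[1:]):
            assert e1 == s2
        full = [e for e in part.expected_unique["g"][:-1]]
        assert all(e == 50 for e in full)


class TestClassifyReads:
    def test_single_placement_is_unique(self):
        calls = classify_reads([AlignmentRecord("r1", "g", 10, -5.0)])
        assert calls["r1"].mapped and calls["r1"].unique
        assert calls["r1"].best.position == 10

    def test_best_score_tie_is_not_unique(self):
        calls = classify_reads(
            [AlignmentRecord("r1", "g", 10, -5.0), AlignmentRecord("r1", "g", 50, -5.0)]
        )
        assert calls["r1"].mapped and not calls["r1"].unique
        assert calls["r1"].best is None

    def test_strict_maximum_selects_best(self):
        calls = classify_reads(
            [AlignmentRecord("r1", "g", 10, -10.0), AlignmentRecord("r1", "g2", 3, -30.0)]
        )
        assert calls["r1"].unique
        assert calls["r1"].best.genome_id == "g"


class TestAlignmentRates:
    def test_counting(self):
        records = [AlignmentRecord(f"r{i}", "g", i, 0.0) for i in range(5)]
        records += [AlignmentRecord("r5", "g", 0, 0.0), AlignmentRecord("r5", "g", 9, 0.0)]
        rates = alignment_rates(classify_reads(records), total_reads=10)
        assert rates == {"mapped_fraction": 0.6, "unique_fraction": 0.5}

    def test_unique_never_exceeds_mapped(self, rng):
        records = []
        for i in range(30):
            n_placements = int(rng.integers(1, 4))
            for j in range(n_placements):
                records.append(AlignmentRecord(f"r{i}", "g", j * 10, -float(rng.integers(0, 3))))
        rates = alignment_rates(classify_reads(records), total_reads=40)
        assert rates["unique_fraction"] <= rates["mapped_fraction"] <= 1.0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError, match="zero reads"):
            alignment_rates({})


class TestExactMapper:
    def test_error_free_reads_all_map(self):
        genomes = {"a": simulate_genome(5000, 87).sequence}
        reads, truth = simulate_reads(genomes, {"a": 1.0}, R, depth=1.0, seed=88)
        calls = classify_reads(exact_read_mapper(reads, genomes))
        rates = alignment_rates(calls, total_reads=len(reads))
        assert rates["mapped_fraction"] == 1.0

    def test_read_from_duplicated_region_not_unique(self):
        dup = simulate_genome(300, 89).sequence
        seq = dup + simulate_genome(500, 90).sequence + dup
        read = seq[50 : 50 + R]  # fully inside the first duplicate copy
        calls = classify_reads(exact_read_mapper([("r1", read)], {"a": seq}))
        assert calls["r1"].mapped and not calls["r1"].unique

    def test_reverse_strand_leftmost_coordinates(self):
        from gutrefset.ura import reverse_complement

        seq = simulate_genome(1000, 91).sequence
        read = reverse_complement(seq[200 : 200 + R])
        calls = classify_reads(exact_read_mapper([("r1", read)], {"a": seq}))
        assert calls["r1"].unique
        assert calls["r1"].best.position == 200
        assert calls["r1"].best.strand == "-"


@pytest.fixture(scope="module")
def two_species():
    return {
        "spA": simulate_genome(40_000, 92).sequence,
        "spB": simulate_genome(40_000, 93).sequence,
    }


@pytest.fixture(scope="module")
def two_species_setup(two_species):
    index = build_uniqueness_index(two_species, R)
    partition = partition_windows(index, 4000)
    return index, partition


class TestUraProfile:
    def test_single_species_sample(self, two_species, two_species_setup):
        index, partition = two_species_setup
        reads, _ = simulate_reads(two_species, {"spA": 1.0, "spB": 0.0}, R, depth=0.5, seed=94)
        calls = classify_reads(exact_read_mapper(reads, two_species))
        profiles = ura_profile(partition, calls, index)
        assert profiles["spA"].present
        assert profiles["spA"].relative_abundance == pytest.approx(1.0)
        assert not profiles["spB"].present
        assert profiles["spB"].relative_abundance == 0.0

    def test_three_to_one_mixture_recovered(self, two_species, two_species_setup):
        index, partition = two_species_setup
        reads, _ = simulate_reads(
            two_species, {"spA": 0.75, "spB": 0.25}, R, depth=3.0, seed=95
        )
        calls = classify_reads(exact_read_mapper(reads, two_species))
        profiles = ura_profile(partition, calls, index)
        n = len(reads)
        se = np.sqrt(0.75 * 0.25 / n)
        assert profiles["spA"].present and profiles["spB"].present
        assert abs(profiles["spA"].relative_abundance - 0.75) <= 3 * se
        assert abs(profiles["spB"].relative_abundance - 0.25) <= 3 * se
        total = sum(p.relative_abundance for p in profiles.values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_reads_piled_in_one_window_called_absent(self, two_species, two_species_setup):
        index, partition = two_species_setup
        start, end = partition.windows["spA"][0]
        seq = two_species["spA"]
        reads = [(f"r{i}", seq[start + i : start + i + R]) for i in range(20)]
        calls = classify_reads(exact_read_mapper(reads, two_species))
        with pytest.warns(UserWarning):  # no species ends up present
            profiles = ura_profile(partition, calls, index, min_reads=10)
        assert profiles["spA"].unique_read_count == 20
        assert profiles["spA"].uniformity_p < 0.05
        assert not profiles["spA"].present

    def test_presence_invariant_to_read_order(self, two_species, two_species_setup):
        index, partition = two_species_setup
        reads, _ = simulate_reads(two_species, {"spA": 0.5, "spB": 0.5}, R, depth=1.0, seed=96)
        records = exact_read_mapper(reads, two_species)
        fwd = ura_profile(partition, classify_reads(records), index)
        rev = ura_profile(partition, classify_reads(records[::-1]), index)
        for g in fwd:
            assert fwd[g].present == rev[g].present
            assert fwd[g].relative_abundance == pytest.approx(rev[g].relative_abundance)

    def test_no_present_genomes_warns(self, two_species, two_species_setup):
        index, partition = two_species_setup
        seq = two_species["spA"]
        calls = classify_reads(exact_read_mapper([("r0", seq[:R])], two_species))
        with pytest.warns(UserWarning, match="presence"):
            profiles = ura_profile(partition, calls, index, min_reads=50)
        assert all(p.relative_abundance == 0.0 for p in profiles.values())


class TestAlignmentIO:
    def test_tsv_roundtrip(self, tmp_path):
        records = [
            AlignmentRecord("r1", "gA", 5, -10.0, "+"),
            AlignmentRecord("r1", "gB", 9, -20.0, "-"),
            AlignmentRecord("r2", "gA", 0, 0.0, "+"),
        ]
        p = tmp_path / "aln.tsv"
        write_alignments_tsv(records, p)
        assert read_alignments_tsv(p) == records

    def test_malformed_tsv_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("r1\tgA\t5\n")
        with pytest.raises(ValueError, match="5 columns"):
            read_alignments_tsv(p)

    def test_sam_subset_parsed(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:gA\tLN:1000\n"
            "@SQ\tSN:gB\tLN:1000\n"
            "r1\t0\tgA\t6\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\tAS:i:-5\n"
            "r1\t272\tgB\t11\t60\t10M\t*\t0\t0\t*\t*\tAS:i:-9\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\t*\n"
        )
        records = read_alignments_sam(sam)
        assert len(records) == 2  # unmapped r2 skipped
        assert records[0] == AlignmentRecord("r1", "gA", 5, -5.0, "+", 0)
        assert records[1].strand == "-"
        assert records[1].position == 10
        calls = classify_reads(records)
        assert calls["r1"].unique and calls["r1"].best.genome_id == "gA"
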