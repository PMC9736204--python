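"""Copy-number calling, binned frequencies, MCR detection and group tests."""

import numpy as np
import pandas as pd
import pytest

from hgblkit.cna import (
    alteration_frequency,
    bin_genome,
    call_cna_states,
    compare_cna_groups,
    find_mcrs,
    label_cytoband,
)
from hgblkit.synthetic import TOY_GENOME, default_cytobands

MB = 1_000_000


def seg_df(rows):
    """rows: (sample, chrom, start, end, value) tuples."""
    return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# per-base counting oracle: an explicit per-base coverage-set array
# ---------------------------------------------------------------------------

def mcr_oracle(calls, direction, min_freq, samples, genome):
    """Brute-force MCRs by painting sample bitmasks onto per-base arrays."""
    out = []
    n = len(samples)
    bit = {s: 1 << i for i, s in enumerate(samples)}
    min_count = min_freq * n - 1e-9
    for chrom, length in genome:
        paint = np.zeros(length, dtype=np.int64)
        sub = calls[
            (calls["chrom"] == chrom)
            & (calls["call"] == direction)
            & calls["sample"].isin(samples)
        ]
        for _, r in sub.iterrows():
            paint[int(r["start"]): int(r["end"])] |= bit[r["sample"]]
        # maximal runs of identical coverage sets
        change = np.flatnonzero(np.diff(paint)) + 1
        bounds = np.concatenate([[0], change, [length]])
        runs = [
            (int(s), int(e), int(paint[s]))
            for s, e in zip(bounds[:-1], bounds[1:])
            if paint[s] != 0
        ]
        popcount = lambda m: bin(m).count("1")
        # above-threshold runs grouped into coordinate-contiguous blocks
        blocks, cur = [], []
        for i, (s, e, m) in enumerate(runs):
            if popcount(m) < min_count:
                if cur:
                    blocks.append(cur)
                cur = []
                continue
            if cur and runs[cur[-1]][1] == s:
                cur.append(i)
            else:
                if cur:
                    blocks.append(cur)
                cur = [i]
        if cur:
            blocks.append(cur)
        for block in blocks:
            for i in block:
                s, e, m = runs[i]
                c = popcount(m)
                lc = popcount(runs[i - 1][2]) if i > 0 and runs[i - 1][1] == s else 0
                rc = (
                    popcount(runs[i + 1][2])
                    if i + 1 < len(runs) and runs[i + 1][0] == e
                    else 0
                )
                if c > lc and c > rc:
                    out.append((chrom, s, e, direction, c, True))
            if len(block) > 1:
                s = runs[block[0]][0]
                e = runs[block[-1]][1]
                common = runs[block[0]][2]
                for i in block[1:]:
                    common &= runs[i][2]
                if popcount(common) >= min_count:
                    out.append((chrom, s, e, direction, popcount(common), False))
    return sorted(out, key=lambda r: (r[0], r[1], -(r[2] - r[1])))


def random_instance(rng, n_samples, genome, direction="gain"):
    rows = []
    for s in range(n_samples):
        sample = f"S{s}"
        for chrom, length in genome:
            for _ in range(rng.integers(0, 4)):
                a = int(rng.integers(0, length - 10))
                b = int(rng.integers(a + 10, min(a + length // 2, length) + 1))
                value = 0.5 if direction == "gain" else -0.5
                rows.append((sample, chrom, a, b, value))
    return call_cna_states(seg_df(rows))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestCallStates:
    def test_log2_thresholds(self):
        calls = call_cna_states(
            seg_df([("S", "chrA", 0, 10, 0.58), ("S", "chrA", 10, 20, 0.0),
                    ("S", "chrA", 20, 30, -0.45)])
        )
        assert list(calls["call"]) == ["gain", "neutral", "loss"]

    def test_integer_cn_thresholds(self):
        calls = call_cna_states(
            seg_df([("S", "chrA", 0, 10, 1), ("S", "chrA", 10, 20, 2),
                    ("S", "chrA", 20, 30, 4)]),
            integer_cn=True,
        )
        assert list(calls["call"]) == ["loss", "neutral", "gain"]

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValueError):
            call_cna_states(seg_df([("S", "chrA", 0, 10, float("nan"))]))


class TestBinGenome:
    def test_exact_tiling(self):
        bins = bin_genome([("chr1", 100 * MB)], bin_size=MB)
        assert len(bins) == 100
        assert bins.iloc[0]["start"] == 0 and bins.iloc[-1]["end"] == 100 * MB

    def test_truncated_last_bin(self):
        bins = bin_genome([("chr1", 2_500_000)], bin_size=MB)
        sizes = (bins["end"] - bins["start"]).tolist()
        assert sizes == [MB, MB, 500_000]

    def test_bins_disjoint_and_covering(self):
        bins = bin_genome(TOY_GENOME, bin_size=777)
        for chrom, length in TOY_GENOME:
            sub = bins[bins["chrom"] == chrom].sort_values("start")
            assert sub.iloc[0]["start"] == 0
            assert sub.iloc[-1]["end"] == length
            assert (sub["start"].values[1:] == sub["end"].values[:-1]).all()


class TestAlterationFrequency:
    def test_fraction_of_overlapping_samples(self):
        calls = call_cna_states(
            seg_df([("A", "chrA", 0, 1000, 0.5), ("B", "chrA", 500, 1500, 0.5)])
        )
        bins = bin_genome([("chrA", 2000)], bin_size=1000)
        freq = alteration_frequency(calls, bins, ["A", "B", "C"], "gain")
        assert freq["frequency"].tolist() == pytest.approx([2 / 3, 1 / 3])

    def test_invariant_to_splitting_a_segment(self):
        whole = call_cna_states(seg_df([("A", "chrA", 100, 900, 0.5)]))
        split = call_cna_states(
            seg_df([("A", "chrA", 100, 400, 0.5), ("A", "chrA", 400, 900, 0.5)])
        )
        bins = bin_genome([("chrA", 1000)], bin_size=250)
        f1 = alteration_frequency(whole, bins, ["A"], "gain")
        f2 = alteration_frequency(split, bins, ["A"], "gain")
        assert f1["frequency"].tolist() == f2["frequency"].tolist()

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            alteration_frequency(
                call_cna_states(seg_df([])), bin_genome(TOY_GENOME), [], "gain"
            )


class TestFindMcrs:
    def test_pairwise_intersection_is_peak(self):
        calls = call_cna_states(
            seg_df([("A", "chrA", 100, 300, 0.5), ("B", "chrA", 200, 400, 0.5)])
        )
        regions = find_mcrs(calls, "gain", min_freq=0.5)
        peak = [r for r in regions if r.is_peak]
        assert len(peak) == 1
        assert (peak[0].start, peak[0].end) == (200, 300)
        assert peak[0].frequency == 1.0

    def test_single_sample_recovers_its_own_segment(self):
        calls = call_cna_states(seg_df([("A", "chrA", 50, 150, 0.5)]))
        regions = find_mcrs(calls, "gain", min_freq=1.0)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (50, 150)

    def test_broad_region_with_interior_peak(self):
        # three samples span the whole region, two more stack on the middle
        rows = [(f"S{i}", "chrA", 0, 3000, 0.5) for i in range(3)]
        rows += [(f"P{i}", "chrA", 1000, 2000, 0.5) for i in range(2)]
        calls = call_cna_states(seg_df(rows))
        regions = find_mcrs(calls, "gain", min_freq=0.3)
        broad = [r for r in regions if not r.is_peak]
        peaks = [r for r in regions if r.is_peak]
        assert len(broad) == 1 and len(peaks) == 1
        assert (broad[0].start, broad[0].end, broad[0].n_samples) == (0, 3000, 3)
        assert (peaks[0].start, peaks[0].end, peaks[0].n_samples) == (1000, 2000, 5)

    def test_min_freq_validation(self):
        calls = call_cna_states(seg_df([("A", "chrA", 0, 10, 0.5)]))
        with pytest.raises(ValueError):
            find_mcrs(calls, "gain", min_freq=0.0)

    def test_matches_per_base_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(2, 7))
            samples = [f"S{i}" for i in range(n)]
            calls = random_instance(rng, n, TOY_GENOME)
            got = [
                (r.chrom, r.start, r.end, r.direction, r.n_samples, r.is_peak)
                for r in find_mcrs(calls, "gain", min_freq=0.3,
                                   group_samples=samples)
            ]
            expected = mcr_oracle(calls, "gain", 0.3, samples, TOY_GENOME)
            assert got == expected

    def test_every_mcr_contained_in_contributing_samples(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            samples = [f"S{i}" for i in range(n)]
            calls = random_instance(rng, n, TOY_GENOME)
            for r in find_mcrs(calls, "gain", min_freq=0.3, group_samples=samples):
                covering = 0
                for s in samples:
                    sub = calls[
                        (calls["sample"] == s)
                        & (calls["chrom"] == r.chrom)
                        & (calls["call"] == "gain")
                    ]
                    base = np.zeros(dict(TOY_GENOME)[r.chrom], dtype=bool)
                    for _, row in sub.iterrows():
                        base[int(row["start"]): int(row["end"])] = True
                    if base[r.start: r.end].all():
                        covering += 1
                assert covering == r.n_samples


class TestCytobandLabels:
    def test_gain_and_loss_prefixes(self):
        cyto = default_cytobands()
        assert label_cytoband("chr1", 62 * MB, 70 * MB, "gain", cyto) == "+1q25.2"
        assert label_cytoband("chr1", 0, 4 * MB, "loss", cyto) == "-1p36.32"

    def test_spanning_region_hyphenated(self):
        cyto = default_cytobands()
        label = label_cytoband("chr1", 0, 55 * MB, "loss", cyto)
        assert label == "-1p36.32-q21.1"

    def test_uncovered_chromosome_is_error(self):
        with pytest.raises(ValueError):
            label_cytoband("chr99", 0, 100, "gain", default_cytobands())


class TestCompareGroups:
    def test_identical_groups_all_p_one(self):
        rows = [(f"A{i}", "chrA", 0, 1000, 0.5) for i in range(3)]
        rows_b = [(f"B{i}", "chrA", 0, 1000, 0.5) for i in range(3)]
        bins = bin_genome([("chrA", 2000)], bin_size=1000)
        per_bin, regions = compare_cna_groups(
            call_cna_states(seg_df(rows)), call_cna_states(seg_df(rows_b)), bins
        )
        assert (per_bin["p"] == 1.0).all()
        assert regions.empty

    def test_five_vs_zero_of_five(self):
        rows = [(f"A{i}", "chrA", 0, 1000, 0.5) for i in range(5)]
        rows_b = [(f"B{i}", "chrA", 0, 1000, 0.0) for i in range(5)]
        bins = bin_genome([("chrA", 1000)], bin_size=1000)
        per_bin, regions = compare_cna_groups(
            call_cna_states(seg_df(rows)), call_cna_states(seg_df(rows_b)), bins
        )
        gain = per_bin[per_bin["direction"] == "gain"]
        assert gain["p"].iloc[0] == pytest.approx(2 / 252)  # hypergeometric
        assert not regions.empty

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(3)
        calls_a = random_instance(rng, 4, [("chrA", 2000)])
        calls_b = random_instance(rng, 5, [("chrA", 2000)])
        bins = bin_genome([("chrA", 2000)], bin_size=500)
        pa, _ = compare_cna_groups(calls_a, calls_b, bins)
        pb, _ = compare_cna_groups(calls_b, calls_a, bins)
        assert pa["p"].tolist() == pytest.approx(pb["p"].tolist())
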