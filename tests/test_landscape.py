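"""K2P divergence, substitution counting, pairwise alignment and the
accumulation landscape."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cqkit import (
    GenomeSpec,
    TEPlantSpec,
    align_copy_to_consensus,
    build_landscape,
    count_substitutions,
    k2p_distance,
    plant_te_copies,
    repeat_fraction,
    simulate_genome,
)
from cqkit.landscape import RepeatAlignment, parse_align_tsv, write_align_tsv
from cqkit.simulate import random_te_library


class TestK2PDistance:
    def test_zero_for_identical_sequences(self):
        assert k2p_distance(0.0, 0.0) == 0.0

    def test_reference_value(self):
        # independent evaluation of -1/2 ln((1-2P-Q) sqrt(1-2Q))
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert expected == pytest.approx(0.1701812, abs=1e-7)
        assert k2p_distance(0.1, 0.05) == pytest.approx(expected, abs=1e-12)

    def test_saturation_returns_nan(self):
        assert math.isnan(k2p_distance(0.5, 0.0))
        assert math.isnan(k2p_distance(0.1, 0.5))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            k2p_distance(-0.1, 0.0)
        with pytest.raises(ValueError):
            k2p_distance(0.8, 0.4)

    @given(
        st.floats(0.001, 0.35),
        st.floats(0.001, 0.35),
    )
    @settings(deadline=None, max_examples=200)
    def test_exceeds_raw_mismatch_fraction(self, p, q):
        k = k2p_distance(p, q)
        if not math.isnan(k):
            assert k > p + q

    def test_monotone_in_each_argument_on_grid(self):
        grid = np.arange(0.0, 0.30, 0.02)
        for q in grid:
            values = [k2p_distance(p, q) for p in grid]
            values = [v for v in values if not math.isnan(v)]
            assert all(b > a for a, b in zip(values, values[1:]))
        for p in grid:
            values = [k2p_distance(p, q) for q in grid]
            values = [v for v in values if not math.isnan(v)]
            assert all(b > a for a, b in zip(values, values[1:]))

    def test_q_zero_closed_form_and_small_p_series(self):
        for p in (0.01, 0.05, 0.1, 0.2):
            assert k2p_distance(p, 0.0) == pytest.approx(-0.5 * math.log(1 - 2 * p))
        # series: -1/2 ln(1-2p) = p + p^2 + O(p^3)
        p = 1e-3
        assert k2p_distance(p, 0.0) == pytest.approx(p + p * p, abs=1e-8)


class TestCountSubstitutions:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", (4, 0.0, 0.0)),
            ("AGGT", "ACGT", (4, 0.0, 0.25)),  # G vs C: purine vs pyrimidine
            ("GCGT", "ACGT", (4, 0.25, 0.0)),  # G vs A: transition
            ("A-GT", "ACGT", (3, 0.0, 0.0)),  # gap column excluded
            ("ANGT", "ACGT", (3, 0.0, 0.0)),  # N column excluded
        ],
    )
    def test_hand_classified_columns(self, a, b, expected):
        n, p, q = count_substitutions(a, b)
        assert (n, p, q) == expected

    def test_no_countable_columns(self):
        n, p, q = count_substitutions("--", "AC")
        assert n == 0 and math.isnan(p) and math.isnan(q)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_substitutions("ACG", "AC")


def gotoh_score(a: str, b: str, match=2.0, mismatch=-2.0, open_=-6.0, ext=-1.0) -> float:
    """Independent quadratic-space affine-gap global alignment score."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = open_ + ext * (i - 1)
    for j in range(1, m + 1):
        Iy[0][j] = open_ + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + open_, Ix[i - 1][j] + ext, Iy[i - 1][j] + open_)
            Iy[i][j] = max(M[i][j - 1] + open_, Iy[i][j - 1] + ext, Ix[i][j - 1] + open_)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def alignment_score(row_a: str, row_b: str, match=2.0, mismatch=-2.0, open_=-6.0, ext=-1.0) -> float:
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-":
            score += ext if in_gap_a else open_
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += ext if in_gap_b else open_
            in_gap_b, in_gap_a = True, False
        else:
            score += match if x == y else mismatch
            in_gap_a = in_gap_b = False
    return score


class TestAlignment:
    def test_identical_sequences_align_gapless(self):
        a, b = align_copy_to_consensus("ACGTACGTGG", "ACGTACGTGG")
        assert a == b == "ACGTACGTGG"
        assert alignment_score(a, b) == 2.0 * 10

    def test_single_substitution_gives_one_mismatch_no_gaps(self):
        a, b = align_copy_to_consensus("ACGTTCGTGG", "ACGTACGTGG")
        assert "-" not in a and "-" not in b
        assert sum(x != y for x, y in zip(a, b)) == 1

    def test_score_matches_independent_dp_on_random_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(12):
            n = int(rng.integers(30, 180))
            a = "".join(rng.choice(list("ACGT"), size=n))
            b = list(a)
            for _ in range(int(rng.integers(0, 10))):  # substitutions
                b[int(rng.integers(len(b)))] = "ACGT"[int(rng.integers(4))]
            for _ in range(int(rng.integers(0, 3))):  # indels
                pos = int(rng.integers(1, len(b)))
                if rng.random() < 0.5:
                    del b[pos : pos + int(rng.integers(1, 4))]
                else:
                    b[pos:pos] = rng.choice(list("ACGT"), size=int(rng.integers(1, 4)))
            b = "".join(b)
            row_a, row_b = align_copy_to_consensus(a, b)
            assert alignment_score(row_a, row_b) == pytest.approx(gotoh_score(a, b))

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            align_copy_to_consensus("", "ACGT")


class TestLandscape:
    def test_single_insertion_lands_in_expected_bin(self):
        aln = RepeatAlignment("c", 1, 500, "TE", "LINE", 500, 0.05, 0.021, 0.073)
        table = build_landscape([aln], bin_width=1.0)
        assert table.table.loc[7.0, "LINE"] == 500
        assert table.total_bp == 500

    def test_empty_input_gives_empty_table(self):
        table = build_landscape([])
        assert table.total_bp == 0
        assert table.saturated_bp == 0

    def test_bin_totals_conserve_aligned_bp(self):
        rng = np.random.default_rng(5)
        alignments = []
        expected = 0
        for i in range(300):
            p = float(rng.uniform(0, 0.4))
            q = float(rng.uniform(0, 0.3))
            bp = int(rng.integers(50, 2000))
            k = k2p_distance(p, q) if p + q <= 1 else float("nan")
            alignments.append(
                RepeatAlignment("c", 1, bp, f"TE{i % 7}", "DNA" if i % 2 else "LTR", bp, p, q, k)
            )
            if not math.isnan(k):
                expected += bp
        table = build_landscape(alignments, bin_width=1.0, cap=55.0)
        assert table.total_bp == expected
        assert table.total_bp + table.saturated_bp == sum(a.aligned_columns for a in alignments)

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            build_landscape([], bin_width=0)

    def test_planted_copies_recover_target_divergence(self):
        contigs, truth = simulate_genome(
            GenomeSpec(8, 0, 0, contig_length_range=(40_000, 60_000), seed=91)
        )
        lib = random_te_library([("TEfam", 5000)], seed=92)
        contigs, truth = plant_te_copies(
            contigs, lib, TEPlantSpec("TEfam", n_copies=20, target_divergence=0.20, seed=93), truth
        )
        alignments = [
            RepeatAlignment.from_gapped(
                ins.contig_id, ins.start, ins.end, "TEfam", "LINE",
                contigs[ins.contig_id][ins.start - 1 : ins.end], lib["TEfam"],
            )
            for ins in truth.insertions
        ]
        ks = np.array([a.k2p for a in alignments])
        bps = np.array([a.aligned_columns for a in alignments])
        weighted_mean = float((ks * bps).sum() / bps.sum())
        assert weighted_mean == pytest.approx(0.20, abs=0.02)
        # the realized divergences recorded at planting time agree
        recorded = [ins.divergence for ins in truth.insertions]
        assert np.allclose(sorted(recorded), sorted(ks))


class TestRepeatFraction:
    def test_simple_fraction(self):
        bp, frac = repeat_fraction([("c", 1, 100)], {"c": 1000})
        assert (bp, frac) == (100, 0.1)

    def test_overlapping_intervals_merge(self):
        bp, _ = repeat_fraction([("c", 1, 100), ("c", 51, 150)], {"c": 1000})
        assert bp == 150

    def test_random_intervals_equal_bitmap_oracle(self):
        rng = np.random.default_rng(8)
        lengths = {f"s{i}": int(rng.integers(200, 2000)) for i in range(6)}
        annotations = []
        bitmaps = {s: np.zeros(n, dtype=bool) for s, n in lengths.items()}
        for _ in range(200):
            s = f"s{int(rng.integers(6))}"
            start = int(rng.integers(1, lengths[s]))
            end = min(int(start + rng.integers(0, 100)), lengths[s])
            annotations.append((s, start, end))
            bitmaps[s][start - 1 : end] = True
        bp, frac = repeat_fraction(annotations, lengths)
        expected = sum(int(b.sum()) for b in bitmaps.values())
        assert bp == expected
        assert frac == pytest.approx(expected / sum(lengths.values()))

    def test_out_of_bounds_interval_names_offender(self):
        with pytest.raises(ValueError, match="c:5-2000"):
            repeat_fraction([("c", 5, 2000)], {"c": 1000})


def test_align_tsv_round_trip(tmp_path):
    rows = [
        {
            "contig_id": "c1", "start": 10, "end": 13, "te_name": "TE1",
            "te_class": "LINE", "aligned_insertion": "AC-GT", "aligned_consensus": "ACAGT",
        }
    ]
    path = tmp_path / "aln.tsv"
    write_align_tsv(path, rows)
    (aln,) = parse_align_tsv(path)
    assert aln.te_class == "LINE"
    assert aln.aligned_columns == 4
    assert aln.k2p == 0.0
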