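"""Insulation-score TAD borders: calling, alignment, dynamics."""

import numpy as np
import pytest

from tempo3d.grid import GenomeGrid
from tempo3d.matrix import ContactMatrix
from tempo3d.tads import (
    InsulationProfile,
    TadBorder,
    align_borders,
    border_dynamics,
    call_borders,
    insulation_score,
    sigmoid_insulation,
)

BINSIZE = 50_000


def make_matrix(vals, valid=None):
    vals = np.asarray(vals, dtype=float)
    grid = GenomeGrid({"chrT": vals.shape[0] * BINSIZE}, BINSIZE)
    return ContactMatrix(grid, "chrT", vals, valid=valid, stage="iced")


def brute_force_raw_insulation(vals, valid, b, w=8, dmin_bins=1):
    """Independent window-mean oracle for one bin boundary."""
    n = vals.shape[0]
    if b - w + 1 < 0 or b + w >= n:
        return np.nan
    acc = []
    for i in range(b - w + 1, b + 1):
        for j in range(b + 1, b + w + 1):
            if j - i >= dmin_bins and valid[i] and valid[j]:
                acc.append(vals[i, j])
    return np.mean(acc) if acc else np.nan


class TestInsulationScore:
    def test_uniform_matrix_has_zero_log_insulation(self):
        p = insulation_score(make_matrix(np.full((30, 30), 4.0)))
        finite = np.isfinite(p.insulation)
        assert finite.sum() == 15  # windows truncate within 8 bins of both ends
        assert np.allclose(p.insulation[finite], 0.0, atol=1e-12)

    def test_two_tad_matrix_has_unique_minimum_at_junction(self):
        n = 30
        block = np.array([0] * 15 + [1] * 15)
        vals = np.where(np.equal.outer(block, block), 4.0, 0.0)
        m = make_matrix(vals)
        p = insulation_score(m)
        # oracle: brute-force window means, minimum must sit at boundary 14
        raw_oracle = np.array(
            [brute_force_raw_insulation(vals, m.valid, b) for b in range(n)]
        )
        assert np.allclose(p.raw, raw_oracle, equal_nan=True)
        finite = np.flatnonzero(np.isfinite(p.insulation))
        assert finite[np.argmin(p.insulation[finite])] == 14
        borders = call_borders(p)
        assert [b.bin_index for b in borders] == [14]

    def test_all_masked_window_is_missing(self):
        vals = np.full((30, 30), 4.0)
        valid = np.ones(30, dtype=bool)
        valid[6:23] = False
        p = insulation_score(make_matrix(vals, valid=valid))
        assert np.isnan(p.raw[14])

    def test_log_track_is_centred_to_zero_mean(self):
        rng = np.random.default_rng(0)
        v = rng.poisson(20.0, size=(40, 40)).astype(float) + 1
        p = insulation_score(make_matrix(np.triu(v) + np.triu(v, 1).T))
        finite = np.isfinite(p.insulation)
        assert p.insulation[finite].mean() == pytest.approx(0.0, abs=1e-9)

    def test_invalid_distance_range_is_rejected(self):
        m = make_matrix(np.full((30, 30), 1.0))
        with pytest.raises(ValueError):
            insulation_score(m, d_min=400_000, d_max=50_000)
        with pytest.raises(ValueError):
            insulation_score(m, d_min=30_000, d_max=400_000)  # not a bin multiple


def profile_from_track(smoothed, d_max=400_000, delta=2):
    smoothed = np.asarray(smoothed, dtype=float)
    return InsulationProfile(
        chrom="chrT", binsize=BINSIZE, raw=np.exp2(smoothed),
        insulation=smoothed, smoothed=smoothed,
        d_min=50_000, d_max=d_max, delta=delta,
    )


class TestCallBorders:
    def test_strong_and_weak_minima_separate_by_decile_score(self):
        track = np.zeros(40)
        track[10] = -1.0    # strong border: strength 1.0 -> score 10
        track[25] = -0.35   # weak border: strength 0.35 -> score 4, excluded
        p = profile_from_track(track)
        borders = call_borders(p, min_score=4)
        assert [(b.bin_index, b.score) for b in borders] == [(10, 10)]
        all_cands = call_borders(p, min_score=0)
        assert [(b.bin_index, b.score) for b in all_cands] == [(10, 10), (25, 4)]

    def test_score_four_is_excluded_strictly(self):
        track = np.zeros(40)
        track[10] = -1.0
        track[25] = -0.4  # ceil(10*0.4) = 4: not strictly above 4
        assert [b.bin_index for b in call_borders(profile_from_track(track))] == [10]

    def test_equal_strength_candidates_share_the_top_decile(self):
        track = np.zeros(40)
        track[10] = track[25] = -0.8
        borders = call_borders(profile_from_track(track), min_score=0)
        assert [b.score for b in borders] == [10, 10]
        assert call_borders(profile_from_track(track), min_score=10) == []

    def test_plateau_resolves_to_leftmost_bin(self):
        track = np.zeros(40)
        track[10] = track[11] = -1.0
        borders = call_borders(profile_from_track(track))
        assert [b.bin_index for b in borders] == [10]

    def test_flat_track_has_no_borders(self):
        assert call_borders(profile_from_track(np.zeros(40))) == []


def borders_at(bins, sample="."):
    return [TadBorder("chrT", b, 1.0, 10, sample) for b in bins]


class TestAlignBorders:
    def test_two_bins_apart_is_homologous(self):
        out = align_borders({"s1": borders_at([100]), "s2": borders_at([102])})
        assert len(out.groups) == 1
        assert set(out.groups[0]) == {"s1", "s2"}

    def test_three_bins_apart_stays_separate(self):
        out = align_borders({"s1": borders_at([100]), "s2": borders_at([103])})
        assert len(out.groups) == 2

    def test_chain_of_three_samples_forms_single_group(self):
        out = align_borders(
            {"s1": borders_at([100]), "s2": borders_at([101]), "s3": borders_at([102])}
        )
        assert len(out.groups) == 1
        assert set(out.groups[0]) == {"s1", "s2", "s3"}

    def test_one_border_per_sample_per_group(self):
        out = align_borders({"s1": borders_at([100, 102]), "s2": borders_at([101])})
        sizes = sorted(len(g) for g in out.groups)
        assert sizes == [1, 2]
        paired = next(g for g in out.groups if len(g) == 2)
        assert paired["s1"].bin_index == 100  # nearest-first, leftmost tie-break

    def test_symmetric_in_sample_order(self):
        a = {"s1": borders_at([10, 50, 90]), "s2": borders_at([11, 52, 89])}
        b = dict(reversed(list(a.items())))
        ga = [frozenset((s, br.bin_index) for s, br in g.items()) for g in align_borders(a).groups]
        gb = [frozenset((s, br.bin_index) for s, br in g.items()) for g in align_borders(b).groups]
        assert sorted(ga, key=sorted) == sorted(gb, key=sorted)

    def test_exhaustive_grouping_matches_pairwise_rule_on_tiny_inputs(self):
        # every pair in a group must be <= 2 bins apart; singletons otherwise
        cases = [
            ({"s1": [100], "s2": [102], "s3": [104]}, 2),  # 100-104 too far: chain splits
            ({"s1": [100], "s2": [101], "s3": [103]}, 2),
            ({"s1": [100], "s2": [200]}, 2),
            ({"s1": [100], "s2": [100]}, 1),
        ]
        for sets, n_expected in cases:
            out = align_borders({s: borders_at(v) for s, v in sets.items()})
            assert len(out.groups) == n_expected
            for g in out.groups:
                idx = [b.bin_index for b in g.values()]
                assert max(idx) - min(idx) <= 2


class TestBorderDynamics:
    def test_present_everywhere_is_invariant(self):
        sets = {f"t{i}": borders_at([100], f"t{i}") for i in range(6)}
        table, counts = border_dynamics(align_borders(sets), [f"t{i}" for i in range(6)])
        assert table[0]["dynamics"] == "invariant"
        assert all(v == {"gained": 0, "lost": 0} for v in counts.values())

    def test_loss_at_first_transition(self):
        sets = {"t0": borders_at([100], "t0"), "t1": [], "t2": []}
        table, counts = border_dynamics(align_borders(sets), ["t0", "t1", "t2"])
        assert table[0]["events"] == [("lost", "t1")]
        assert counts[("t0", "t1")]["lost"] == 1

    def test_planted_losses_are_counted_exactly(self):
        keep = [10 * k for k in range(1, 41)]
        lost = keep[:20]
        sets = {
            "t0": borders_at(keep, "t0"),
            "t1": borders_at([b for b in keep if b not in lost], "t1"),
        }
        _, counts = border_dynamics(align_borders(sets), ["t0", "t1"])
        assert counts[("t0", "t1")] == {"gained": 0, "lost": 20}


class TestSigmoidInsulation:
    def test_zero_maps_to_zero_and_order_is_preserved(self):
        track = np.array([0.0, -0.5, -1.5, 0.8, np.nan])
        p = profile_from_track(track)
        s = sigmoid_insulation(p)
        assert s[0] == 0.0
        assert s[2] < s[1] < 0 < s[3]  # deeper insulation stays more negative
        assert np.isnan(s[4])

    def test_two_sigma_maps_to_tanh_one(self):
        a = 1 / np.sqrt(6)
        p = profile_from_track(np.array([a, -a, 2.0]))
        assert sigmoid_insulation(p)[2] == pytest.approx(np.tanh(1.0))
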