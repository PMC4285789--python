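"""Kink-relative numbering, propensities, motifs, length matching, KS,
wheel summaries and hydrogen-bond break rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinkscan import (
    HelixSpec,
    MotifSpec,
    aa_propensity,
    build_ideal_helix,
    compare_angle_distributions,
    hbond_break_rates,
    kink_window_from_sequence,
    kink_windows,
    length_matched_samples,
    motif_enrichment,
    motif_match,
    wheel_summary,
)
from kinkscan.constants import AMINO_ACIDS, INSIDE_OFFSETS, OUTSIDE_OFFSETS
from kinkscan.errors import LengthMatchError, MotifParseError
from kinkscan.helix_extraction import Helix
from kinkscan.kink_detection import HelixClassification, KinkCall
from kinkscan.synthetic import random_helix_sequences
from tests.conftest import as_helix


def make_call(helix, kink_idx):
    return KinkCall(
        helix_ref=helix, peak_idx=kink_idx, kink_idx=kink_idx, angle=30.0,
        wobble_at_kink=0.0,
    )


class TestKinkWindows:
    def test_interior_kink_has_all_offsets(self, ideal_chain):
        helix = as_helix(ideal_chain)
        (w,) = kink_windows([make_call(helix, 8)])
        assert sorted(w.positions) == list(range(-6, 7))

    def test_edge_kink_clipped(self, ideal_chain):
        helix = as_helix(ideal_chain, 0, 12)  # 13 residues
        (w,) = kink_windows([make_call(helix, 6)])
        assert sorted(w.positions) == list(range(-6, 7))
        (w2,) = kink_windows([make_call(helix, 3)])
        assert min(w2.positions) == -3

    def test_inside_outside_bookkeeping(self):
        assert INSIDE_OFFSETS == (-4, -3, 0, 3, 4)
        assert OUTSIDE_OFFSETS == (-5, -2, 2, 5)


class TestPropensity:
    def test_hand_computed_planted_proline(self):
        """P at offset +2 in half the windows vs a 5% background is
        log2(0.5/0.05) = log2(10)."""
        windows = []
        for k in range(1000):
            seq = list("A" * 13)
            seq[8] = "P" if k < 500 else "G"  # offset +2 from center 6
            windows.append(kink_window_from_sequence("".join(seq), 6))
        background = ["A" * 19 + "P"] * 500  # exactly 5% Proline
        table = aa_propensity(windows, background)
        assert table.score.loc["P", 2] == pytest.approx(np.log2(10.0), abs=1e-9)
        assert table.ratio.loc["P", 2] == pytest.approx(10.0, abs=1e-9)

    def test_absent_amino_acid_gets_finite_pseudocounted_score(self):
        windows = [kink_window_from_sequence("A" * 13, 6) for _ in range(50)]
        table = aa_propensity(windows, ["ACDEFGHIKLMNPQRSTVWY" * 5])
        assert np.isfinite(table.score.loc["W", 0])
        assert table.score.loc["W", 0] < 0
        assert table.pseudocounted.loc["W", 0]

    def test_null_corpus_scores_near_zero(self):
        kinked, straight = random_helix_sequences(3000, length_dist=13, seed=7)
        windows = [kink_window_from_sequence(s, p) for s, p in kinked]
        table = aa_propensity(windows, straight)
        assert np.nanmax(np.abs(table.score.values)) < 0.5

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            aa_propensity([], [])


class TestMotifs:
    @pytest.mark.parametrize(
        "motif,segment,expected",
        [
            ("xxxxP", ("AAAAAAPAAAAAA", 6), True),
            ("xxxxP", ("PAAAAAAAAAAAA", 6), False),
            ("[ST]P", ("AAASPAAAAAAAA", 6), True),
            ("[ST]P", ("AAAAPAAAAAAAA", 6), False),
            ("P", ("AAAAAAAAAAAAA", 6), False),
            ("G_0 or G_+1", ("AAAAAAGAAAAAA", 6), True),
            ("G_0 or G_+1", ("AAAAAAAGAAAAA", 6), True),
            ("G_0 or G_+1", ("AAAAAAAAAGAAA", 6), False),
        ],
    )
    def test_match_semantics(self, motif, segment, expected):
        assert motif_match(MotifSpec.parse(motif), segment) is expected

    @pytest.mark.parametrize("bad", ["[ST", "zP", "", "P]"])
    def test_parse_errors(self, bad):
        with pytest.raises(MotifParseError):
            MotifSpec.parse(bad)

    @pytest.mark.parametrize(
        "text", ["xxxxP", "[ST]P", "[AVILMFYW]xP", "P", "G_0 or G_+1"]
    )
    def test_text_roundtrip(self, text):
        assert MotifSpec.parse(text).to_text() == text

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_pattern_containment_monotonicity(self, seed):
        """P is at least as frequent as xP, which beats xxxxP, in any
        fixed-length window corpus."""
        rng = np.random.default_rng(seed)
        segs = [
            (
                "".join(rng.choice(list(AMINO_ACIDS), size=13)),
                6,
            )
            for _ in range(60)
        ]
        counts = [
            sum(motif_match(MotifSpec.parse(m), s) for s in segs)
            for m in ("P", "xP", "xxxxP")
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestEnrichment:
    def test_planted_ratio_recovered(self):
        rng = np.random.default_rng(0)
        kinked, straight = [], []
        for k in range(2000):
            seq = list("".join(rng.choice(list("ACDEFHIKLMNQRSTVY"), size=13)))
            if k < 1200:  # 60% of kink segments carry the motif
                seq[5:7] = "WP"
            kinked.append(("".join(seq), 6))
        for k in range(4000):
            seq = list("".join(rng.choice(list("ACDEFHIKLMNQRSTVY"), size=13)))
            if k < 240:  # 6% of straight helices
                seq[5:7] = "WP"
            straight.append("".join(seq))
        (row,) = motif_enrichment(["WP"], kinked, straight, seed=1)
        assert row.pct_kink == pytest.approx(60.0, abs=0.5)
        assert row.pct_straight_mean == pytest.approx(6.0, abs=0.5)
        assert row.ratio == pytest.approx(10.0, abs=1.0)

    def test_absent_motif_gives_zero_and_nan_ratio(self):
        kinked = [("A" * 13, 6)] * 10
        straight = ["A" * 20] * 10
        (row,) = motif_enrichment(["W"], kinked, straight, seed=0)
        assert row.pct_kink == 0.0
        assert np.isnan(row.ratio)

    def test_deterministic_under_seed(self):
        kinked, straight = random_helix_sequences(200, length_dist=20, seed=4)
        segs = [(s[:13], 6) for s, _ in kinked]
        a = motif_enrichment(["P", "xP"], segs, straight, seed=11)
        b = motif_enrichment(["P", "xP"], segs, straight, seed=11)
        assert [(r.pct_straight_mean, r.pct_straight_sd) for r in a] == [
            (r.pct_straight_mean, r.pct_straight_sd) for r in b
        ]

    def test_short_straight_helices_excluded(self):
        kinked = [("A" * 13, 6)]
        with pytest.warns(UserWarning):
            motif_enrichment(["A"], kinked, ["A" * 12, "A" * 13], seed=0)


class FakeHelix:
    def __init__(self, length):
        self.length = length


class TestLengthMatching:
    def test_pool_equals_target_gives_permutations(self):
        target = [FakeHelix(L) for L in (15, 15, 20, 25)]
        samples = length_matched_samples(target, target, n_samples=5, seed=0)
        for s in samples:
            assert sorted(h.length for h in s) == [15, 15, 20, 25]

    def test_histograms_match_exactly_every_sample(self):
        rng = np.random.default_rng(2)
        pool = [FakeHelix(int(L)) for L in rng.integers(13, 40, 2000)]
        target = [FakeHelix(int(L)) for L in rng.choice([15, 20, 20, 30], 60)]
        samples = length_matched_samples(pool, target, n_samples=50, seed=3)
        want = sorted(h.length for h in target)
        assert all(sorted(h.length for h in s) == want for s in samples)

    def test_within_sample_draws_without_replacement(self):
        pool = [FakeHelix(20) for _ in range(10)]
        target = [FakeHelix(20) for _ in range(10)]
        (sample,) = length_matched_samples(pool, target, n_samples=1, seed=0)
        assert len({id(h) for h in sample}) == 10

    def test_deficient_pool_names_length(self):
        pool = [FakeHelix(20)] * 3
        target = [FakeHelix(20)] * 2 + [FakeHelix(35)]
        with pytest.raises(LengthMatchError, match="35"):
            length_matched_samples(pool, target)


class TestCompareAngles:
    def test_identical_sets_give_zero_D(self):
        angles = [5.0, 10.0, 15.0, 25.0]
        df = compare_angle_distributions(angles, angles)
        assert df.loc[0, "D"] == 0.0

    def test_disjoint_supports_give_D_one(self):
        df = compare_angle_distributions([1.0, 2.0, 3.0], [50.0, 60.0, 70.0])
        assert df.loc[0, "D"] == 1.0

    def test_null_rejection_rate_controlled(self):
        """Same-distribution samples: p ≥ 0.05 in ≥ 90% of repeats."""
        rng = np.random.default_rng(8)
        ok = 0
        for _ in range(100):
            a = rng.gamma(2.0, 6.0, 200)
            b = rng.gamma(2.0, 6.0, 200)
            if compare_angle_distributions(a, b).loc[0, "pvalue"] >= 0.05:
                ok += 1
        assert ok >= 90

    def test_per_length_stratification(self):
        a = [(20, 5.0), (20, 9.0), (25, 30.0), (25, 31.0), (30, 4.0)]
        b = [(20, 5.0), (20, 9.0), (25, 2.0), (25, 3.0), (30, 9.0)]
        df = compare_angle_distributions(a, b, per_length=True)
        # stratum 30 skipped (n < 2 per side)
        assert set(df["stratum"]) == {20, 25}
        assert df.set_index("stratum").loc[20, "D"] == 0.0
        assert df.set_index("stratum").loc[25, "D"] == 1.0


class TestWheelSummary:
    def test_constant_scalar(self, ideal_chain):
        helix = as_helix(ideal_chain)
        windows = kink_windows([make_call(helix, 10), make_call(helix, 12)])
        df = wheel_summary(windows, lambda w, off: 1.0)
        assert np.allclose(df["mean"], 1.0)
        assert np.allclose(df["two_sd"], 0.0)

    def test_inside_outside_pattern_recovered(self, ideal_chain):
        helix = as_helix(ideal_chain)
        windows = kink_windows([make_call(helix, 10)])

        def val(w, off):
            return 1.0 if off in INSIDE_OFFSETS else -1.0

        df = wheel_summary(windows, val).set_index("offset")
        for off in INSIDE_OFFSETS:
            assert df.loc[off, "mean"] == 1.0
        for off in OUTSIDE_OFFSETS:
            assert df.loc[off, "mean"] == -1.0

    def test_empty_windows(self):
        df = wheel_summary([], lambda w, off: 1.0)
        assert (df["n"] == 0).all()


class TestBreakRates:
    def _setup(self, n_break=2):
        chain = build_ideal_helix(HelixSpec(length=28))
        helix = as_helix(chain)
        from kinkscan.residue_annotation import backbone_hbonds

        records = [r for r in backbone_hbonds(chain) if r.kind == "bb_i4"]
        acceptors = sorted(r.acceptor_idx for r in records)
        removed = set(acceptors[:n_break])
        records = [r for r in records if r.acceptor_idx not in removed]
        cls = HelixClassification(
            helix_ref=helix, max_angle=30.0, label="kinked",
            kinks=[make_call(helix, 14)],
        )
        chains = {helix.chain_ref: chain}
        hbonds = {helix.chain_ref: records}
        return cls, chains, hbonds

    def test_all_bonds_present_gives_zero(self):
        cls, chains, hbonds = self._setup(n_break=0)
        out = hbond_break_rates([cls], chains, hbonds)
        assert out["broken_i4_fraction"] == 0.0

    def test_fraction_is_broken_over_assessable(self):
        cls, chains, hbonds = self._setup(n_break=2)
        out = hbond_break_rates([cls], chains, hbonds)
        assert out["broken_i4_fraction"] == pytest.approx(2 / out["n_assessed"])

    def test_kink_window_scope_clips_at_edges(self):
        cls, chains, hbonds = self._setup(n_break=0)
        cls.kinks = [make_call(cls.helix_ref, 2)]  # kink near the N-terminus
        out = hbond_break_rates([cls], chains, hbonds, scope="kink_window")
        by = out["by_offset"].set_index("offset")
        assert by.loc[-6, "n"] == 0  # offset falls outside the helix
        assert by.loc[3, "n"] == 1

    def test_straight_helices_ignored(self):
        cls, chains, hbonds = self._setup(n_break=2)
        cls.label = "straight"
        out = hbond_break_rates([cls], chains, hbonds)
        assert out["n_assessed"] == 0
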