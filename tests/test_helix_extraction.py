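"""Merging, splitting, seed trimming, membrane trimming and orchestration."""

import numpy as np
import pytest

from kinkscan import (
    HelixSpec,
    MembraneAnnotation,
    build_helix,
    build_ideal_helix,
    extract_helices,
    is_helical_seed,
    merge_helical_segments,
    split_on_large_kink,
    trim_helix_ends,
    trim_to_membrane,
)
from kinkscan.helix_extraction import (
    SEED_ANGLE_RANGES,
    SEED_IDEAL_DISTANCES,
)
from kinkscan.synthetic import build_backbone, _solve_phi_psi
from kinkscan.errors import LengthMatchError
from tests.conftest import as_helix, mark_all_helical


def chain_with_states(states: str):
    """Ideal helix chain with an explicit per-residue state string."""
    chain = build_ideal_helix(HelixSpec(length=len(states)))
    for r, s in zip(chain.residues, states):
        r.ss_state = "H" if s == "H" else "-"
    return chain


class TestMerging:
    @pytest.mark.parametrize(
        "states,expected_spans",
        [
            ("HHHHHH--HHHHHH", [(0, 13)]),  # gap 2 → one 14-residue candidate
            ("HHHHHH-HHHHHHH", [(0, 13)]),  # gap 1
            ("HHHHHH---HHHHH", [(0, 5), (9, 13)]),  # gap 3 → two candidates
            ("H-------------", [(0, 0)]),  # singleton run
            ("--------------", []),
            ("HH-HH--HH-----", [(0, 8)]),  # transitive left-to-right
        ],
    )
    def test_gap_rules(self, states, expected_spans):
        chain = chain_with_states(states)
        helices = merge_helical_segments(chain)
        assert [(h.start_idx, h.end_idx) for h in helices] == expected_spans

    def test_empty_chain(self):
        from kinkscan.structure_model import ChainModel

        assert merge_helical_segments(ChainModel("x", "A")) == []


class TestSplitting:
    def test_large_kink_splits_at_max_angle(self):
        chain = build_helix(HelixSpec(length=30, kinks=[(15, 80.0, 0.0)]))
        frags = split_on_large_kink(as_helix(chain))
        assert len(frags) == 2
        assert abs(frags[1].start_idx - 15) <= 1
        assert frags[0].end_idx + 1 == frags[1].start_idx  # no residues lost

    def test_straight_helix_unchanged(self, ideal_chain):
        helix = as_helix(ideal_chain)
        assert split_on_large_kink(helix) == [helix]

    def test_below_threshold_unchanged(self):
        chain = build_helix(HelixSpec(length=30, kinks=[(15, 40.0, 0.0)]))
        assert len(split_on_large_kink(as_helix(chain))) == 1

    def test_short_helix_returned_unchanged(self, ideal_chain):
        helix = as_helix(ideal_chain, 0, 10)
        assert split_on_large_kink(helix) == [helix]


class TestHelicalSeed:
    def test_ideal_helix_start_is_seed(self, ideal_chain):
        assert is_helical_seed(ideal_chain.residues[:5])

    def test_ideal_values_inside_printed_ranges(self, ideal_chain):
        """The ideal parametrization lands comfortably inside the seed
        windows: angles ≈ 44.8°/73.8°/54.4°, distances ≈ 5.40/5.05/6.20 Å."""
        cas = [r.coords_CA for r in ideal_chain.residues[:5]]
        v1 = cas[1] - cas[0]
        for x in (2, 3, 4):
            vx = cas[x] - cas[0]
            cosang = np.dot(v1, vx) / np.linalg.norm(v1) / np.linalg.norm(vx)
            ang = np.degrees(np.arccos(cosang))
            lo, hi = SEED_ANGLE_RANGES[x]
            assert lo < ang < hi
            assert abs(np.linalg.norm(vx) - SEED_IDEAL_DISTANCES[x]) < 0.5

    def test_displaced_ca_fails(self, ideal_chain):
        import copy

        chain = copy.deepcopy(ideal_chain)
        # push Cα(3) 1.5 Å further from Cα(1): distance leaves the 0.5 Å band
        v = chain.residues[2].coords_CA - chain.residues[0].coords_CA
        chain.residues[2].coords_CA = (
            chain.residues[2].coords_CA + 1.5 * v / np.linalg.norm(v)
        )
        assert not is_helical_seed(chain.residues[:5])

    def test_extended_strand_fails(self):
        chain = build_backbone([180.0] * 5, [180.0] * 5)
        assert not is_helical_seed(chain.residues[:5])

    def test_missing_ca_fails_with_warning(self, ideal_chain):
        import copy

        chain = copy.deepcopy(ideal_chain)
        chain.residues[1].coords_CA = None
        with pytest.warns(UserWarning):
            assert not is_helical_seed(chain.residues[:5])

    def test_wrong_length_raises(self, ideal_chain):
        with pytest.raises(ValueError):
            is_helical_seed(ideal_chain.residues[:4])


def coil_capped_chain(n_coil=2, n_helix=25):
    """Chain with polyproline-II-like coil residues prepended to a helix."""
    phi_a, psi_a, tau = _solve_phi_psi(1.5, 100.0)
    phi = [-75.0] * n_coil + [phi_a] * n_helix
    psi = [145.0] * n_coil + [psi_a] * n_helix
    return build_backbone(phi, psi, tau=tau)


class TestTrimEnds:
    def test_coil_cap_removed(self):
        chain = coil_capped_chain(n_coil=2, n_helix=25)
        trimmed = trim_helix_ends(as_helix(chain))
        assert trimmed.start_idx == 2
        assert trimmed.end_idx == 26

    def test_clean_helix_unchanged(self, ideal_chain):
        helix = as_helix(ideal_chain)
        trimmed = trim_helix_ends(helix)
        assert (trimmed.start_idx, trimmed.end_idx) == (0, 29)

    def test_short_fragment_empties(self, ideal_chain):
        assert trim_helix_ends(as_helix(ideal_chain, 0, 3)).is_empty()

    def test_all_coil_empties(self):
        chain = build_backbone([180.0] * 8, [180.0] * 8)
        assert trim_helix_ends(as_helix(chain)).is_empty()


def annotate_regions(chain, labels):
    return MembraneAnnotation(
        labels={
            (chain.pdb_id, r.chain_id, r.seq_num, r.insertion_code): lab
            for r, lab in zip(chain.residues, labels)
        }
    )


class TestMembraneTrim:
    def test_excess_outside_trimmed(self, ideal_chain):
        labels = ["outside"] * 8 + ["tail"] * 22
        ann = annotate_regions(ideal_chain, labels)
        out = trim_to_membrane(as_helix(ideal_chain), ann)
        assert out.start_idx == 3  # 8 outside → keep at most 5
        assert out.end_idx == 29

    def test_fully_outside_rejected(self, ideal_chain):
        ann = annotate_regions(ideal_chain, ["outside"] * 30)
        assert trim_to_membrane(as_helix(ideal_chain), ann).is_empty()

    def test_fully_inside_unchanged(self, ideal_chain):
        ann = annotate_regions(ideal_chain, ["tail"] * 30)
        out = trim_to_membrane(as_helix(ideal_chain), ann)
        assert (out.start_idx, out.end_idx) == (0, 29)

    def test_no_tail_residues_rejected(self, ideal_chain):
        ann = annotate_regions(ideal_chain, ["head"] * 30)
        assert trim_to_membrane(as_helix(ideal_chain), ann).is_empty()

    def test_unknown_counts_as_outside(self, ideal_chain):
        labels = ["unknown"] * 8 + ["tail"] * 22
        ann = annotate_regions(ideal_chain, labels)
        assert trim_to_membrane(as_helix(ideal_chain), ann).start_idx == 3

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            MembraneAnnotation(labels={("x", "A", 1, ""): "lipid"})


class TestExtractHelices:
    def test_clean_helix_extracted_whole(self):
        chain = mark_all_helical(build_ideal_helix(HelixSpec(length=25)))
        (helix,) = extract_helices(chain)
        assert helix.length == 25

    def test_twelve_residue_helix_removed(self):
        chain = mark_all_helical(build_ideal_helix(HelixSpec(length=12)))
        assert extract_helices(chain) == []

    def test_thirteen_residue_helix_kept(self):
        chain = mark_all_helical(build_ideal_helix(HelixSpec(length=13)))
        assert len(extract_helices(chain)) == 1

    def test_sharply_kinked_helix_splits_in_two(self):
        chain = mark_all_helical(
            build_helix(HelixSpec(length=40, kinks=[(20, 80.0, 0.0)]))
        )
        helices = extract_helices(chain)
        assert len(helices) == 2
        assert all(h.length >= 13 for h in helices)

    def test_outputs_pass_seed_and_length_invariants(self):
        for spec in (
            HelixSpec(length=30, noise_sd=0.1, seed=1),
            HelixSpec(length=40, kinks=[(20, 80.0, 120.0)], noise_sd=0.1, seed=2),
        ):
            chain = mark_all_helical(build_helix(spec))
            for h in extract_helices(chain):
                assert h.length >= 13
                assert is_helical_seed(h.residues[:5])
                assert is_helical_seed(h.residues[-5:])

    def test_idempotent(self):
        from kinkscan.structure_model import ChainModel

        chain = mark_all_helical(
            build_helix(HelixSpec(length=40, kinks=[(20, 80.0, 0.0)]))
        )
        first = extract_helices(chain)
        for h in first:
            sub = ChainModel(pdb_id="x", chain_id="A", residues=list(h.residues))
            again = extract_helices(sub)
            assert len(again) == 1
            assert again[0].length == h.length
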