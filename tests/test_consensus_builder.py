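"""Reference mapping, conservation profile, and degenerate consensus."""

import numpy as np
import pytest

from oligofish.consensus_builder import (
    ConservationProfile,
    build_consensus,
    build_profile,
    map_homolog,
)
from oligofish.iupac_seq import FixedSeq, revcomp
from oligofish.synthetic_data import FamilySpec, simulate_family

from conftest import random_fixed


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(11)
    return FixedSeq(random_fixed(rng, 200))


class TestMapHomolog:
    def test_exact_substring_accepted_with_coordinates(self, reference):
        hom = str(reference)[20:80]  # columns 21..80
        res = map_homolog(hom, reference, min_match=50)
        assert res.accepted
        assert res.matched_nt == 60
        assert (res.ref_start, res.ref_end) == (21, 80)
        assert res.strand == "+"

    def test_below_min_match_rejected(self, reference):
        res49 = map_homolog(str(reference)[50:99], reference, min_match=50)
        res50 = map_homolog(str(reference)[50:100], reference, min_match=50)
        assert not res49.accepted and res49.matched_nt == 49
        assert res50.accepted and res50.matched_nt == 50

    def test_substitutions_reduce_matched_nt(self, reference):
        hom = list(str(reference)[20:80])
        for pos in (5, 17, 29, 41, 53):  # well-separated: no gap can help
            hom[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[hom[pos]]
        res = map_homolog("".join(hom), reference, min_match=50)
        assert res.accepted
        assert res.matched_nt == 55

    def test_reverse_orientation_detected(self, reference):
        hom = str(revcomp(str(reference)[20:80]))
        res = map_homolog(hom, reference, min_match=50)
        assert res.accepted and res.strand == "-"
        assert res.matched_nt == 60
        assert (res.ref_start, res.ref_end) == (21, 80)

    def test_acceptance_monotone_in_min_match(self, reference):
        hom = str(reference)[30:90]
        accepted = [
            map_homolog(hom, reference, min_match=m).accepted
            for m in (40, 55, 60, 61, 80)
        ]
        # once rejected at some threshold, never re-accepted at a higher one
        assert accepted == sorted(accepted, reverse=True)


class TestBuildProfile:
    def test_identical_copies_give_uniform_depth(self, reference):
        profile = build_profile([str(reference)] * 10, reference)
        assert (profile.depth == 10).all()
        assert (profile.counts.max(axis=1) == 10).all()  # single-base columns
        assert profile.acceptance_fraction == 1.0

    def test_partial_span_homolog(self, reference):
        hom = str(reference)[10:70]  # columns 11..70
        profile = build_profile([hom], reference)
        depth = profile.depth
        assert (depth[10:70] == 1).all()
        assert depth[:10].sum() == 0 and depth[70:].sum() == 0

    def test_rejected_homologs_contribute_nothing(self, reference):
        profile = build_profile([str(reference)[:49]], reference, min_match=50)
        assert profile.depth.sum() == 0
        assert profile.acceptance_fraction == 0.0

    def test_empty_homolog_list_errors(self, reference):
        with pytest.raises(ValueError):
            build_profile([], reference)

    def test_depth_recount_matches_stored_mappings(self):
        """Column depth totals equal an independent recount from the
        per-homolog mapping extents (ungapped family: blocks are exact)."""
        spec = FamilySpec(
            ancestor_length=300, indel_rate=0.0, n_lineages=2,
            n_homologs_per_lineage=10, conserved_windows=((101, 130),), seed=5,
        )
        ancestor, homologs, _ = simulate_family(spec)
        profile = build_profile(homologs, ancestor)
        recount = np.zeros(len(ancestor), dtype=int)
        for m in profile.mappings:
            if m.accepted:
                recount[m.ref_start - 1 : m.ref_end] += 1
        assert (profile.depth == recount).all()

    def test_tsv_round_trip(self, reference, tmp_path):
        profile = build_profile([str(reference)] * 3, reference)
        path = tmp_path / "p.tsv"
        profile.to_tsv(path)
        back = ConservationProfile.from_tsv(path)
        assert (back.counts == profile.counts).all()

    def test_bedgraph_is_zero_based_half_open(self, reference, tmp_path):
        hom = str(reference)[10:70]
        profile = build_profile([hom], reference)
        path = tmp_path / "d.bedgraph"
        profile.depth_to_bedgraph(path)
        lines = [l.split("\t") for l in path.read_text().splitlines()]
        assert lines[1] == ["consensus", "10", "70", "1"]


class TestBuildConsensus:
    def _profile(self, columns):
        """Build a profile from {col(1-based): {base: count}}."""
        length = max(columns)
        prof = ConservationProfile(length)
        order = "ACGT"
        for col, counts in columns.items():
            for base, n in counts.items():
                prof.counts[col - 1, order.index(base)] = n
        return prof

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 5, "G": 5}, "R"),  # even two-base split
            ({"A": 19, "G": 1}, "A"),  # minor base below threshold
            ({"A": 7, "C": 2, "G": 1}, "M"),  # G at 0.1 excluded
        ],
    )
    def test_column_letter(self, counts, expected):
        prof = self._profile({1: counts, 2: counts})
        res = build_consensus(prof, freq_threshold=0.2, min_depth=2)
        assert str(res.consensus)[0] == expected

    def test_flanks_trimmed_internal_gap_is_n(self):
        prof = self._profile({1: {"A": 1}, 3: {"A": 5}, 5: {"C": 5}, 7: {"A": 1}})
        res = build_consensus(prof, min_depth=2)
        assert (res.span_start, res.span_end) == (3, 5)
        assert str(res.consensus) == "ANC"

    def test_all_below_min_depth_errors(self):
        prof = self._profile({1: {"A": 1}, 2: {"C": 1}})
        with pytest.raises(ValueError, match="no covered span"):
            build_consensus(prof, min_depth=2)

    def test_degeneracy_monotone_in_freq_threshold(self):
        rng = np.random.default_rng(3)
        prof = ConservationProfile(50, rng.integers(0, 8, (50, 4)))
        prev = None
        for thr in (0.05, 0.1, 0.2, 0.35, 0.5):
            res = build_consensus(prof, freq_threshold=thr, min_depth=1)
            deg = res.consensus.degeneracy
            if prev is not None:
                assert deg <= prev
            prev = deg

    def test_planted_conserved_window_recovered_exactly(self, family):
        spec, ancestor, homologs, _ = family
        profile = build_profile(homologs, ancestor)
        res = build_consensus(profile)
        (w_start, w_end), = spec.conserved_windows
        i0, i1 = w_start - res.span_start, w_end - res.span_start + 1
        window = res.consensus[i0:i1]
        assert str(window) == str(ancestor)[w_start - 1 : w_end]
        assert window.degeneracy == 1
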