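"""Probe scanning on a consensus and tandem-repeat probe construction."""

from math import prod

import numpy as np
import pytest

from oligofish.consensus_builder import ConsensusResult, ConservationProfile
from oligofish.iupac_seq import IUPAC_BASES, DegenerateSeq
from oligofish.probe_designer import (
    DesignConstraints,
    TandemMonomer,
    build_tandem_probe,
    pick_tandem_length,
    scan_probes,
)
from oligofish.thermo import HybridizationConditions, tm_range

COND = HybridizationConditions()


def _uniform_profile(length, depth=10):
    counts = np.zeros((length, 4), dtype=np.int64)
    counts[:, 2] = depth  # all-G placeholder; only depth matters for the scan
    return ConservationProfile(length, counts)


class TestScanProbes:
    def test_single_legal_window_is_found(self):
        # one 30-nt GC-balanced window with in-range Tm, flanked by N
        core = "GCAT" * 7 + "GC"
        letters = "N" * 40 + core + "N" * 40
        cons = ConsensusResult(DegenerateSeq(letters), 1, len(letters))
        profile = _uniform_profile(len(letters))
        cands = scan_probes(cons, profile, DesignConstraints(), COND)
        assert len(cands) == 1
        assert (cands[0].start, cands[0].end) == (41, 70)
        assert str(cands[0].sequence) == core

    def test_no_depth_gives_empty_list(self):
        cons = ConsensusResult(DegenerateSeq("GCAT" * 20), 1, 80)
        profile = ConservationProfile(80)
        assert scan_probes(cons, profile, DesignConstraints(), COND) == []

    def test_matches_exhaustive_oracle(self, rng):
        """Selected set equals an independent brute-force enumeration with
        the same ranking and greedy spacing rule."""
        letters = "".join(
            "ACGTRY"[i] for i in rng.choice(6, size=150, p=[0.24, 0.24, 0.24, 0.24, 0.02, 0.02])
        )
        cons = ConsensusResult(DegenerateSeq(letters), 1, 150)
        counts = np.zeros((150, 4), dtype=np.int64)
        counts[:, 0] = rng.integers(5, 11, 150)
        profile = ConservationProfile(150, counts)
        cstr = DesignConstraints(min_depth_frac=0.6, min_spacing=10)

        # oracle: enumerate every window, filter, rank, greedily select
        depth = profile.depth.astype(float)
        md = depth.max()
        pool = []
        for s in range(150):
            for L in range(cstr.len_min, cstr.len_max + 1):
                if s + L > 150:
                    break
                w = letters[s : s + L]
                if "N" in w:
                    continue
                if prod(len(IUPAC_BASES[c]) for c in w) > cstr.max_degeneracy:
                    continue
                r = tm_range(w, COND)
                if r.tm_min < cstr.tm_min or r.tm_max > cstr.tm_max:
                    continue
                frac = depth[s : s + L].mean() / md
                if frac < cstr.min_depth_frac:
                    continue
                pool.append((s + 1, s + L, frac, r))
        pool.sort(key=lambda t: (-t[2], -t[3].tm_min, t[0], t[1]))
        chosen = []
        for s, e, frac, r in pool:
            if all(s > ce + cstr.min_spacing or e < cs - cstr.min_spacing for cs, ce in chosen):
                chosen.append((s, e))
        chosen.sort()

        got = [(c.start, c.end) for c in scan_probes(cons, profile, cstr, COND)]
        assert got == chosen

    def test_every_candidate_satisfies_all_constraints(self, family):
        spec, ancestor, homologs, _ = family
        from oligofish.consensus_builder import build_consensus, build_profile

        profile = build_profile(homologs, ancestor)
        cons = build_consensus(profile)
        cstr = DesignConstraints()
        cands = scan_probes(cons, profile, cstr, COND)
        assert cands
        md = profile.depth.max()
        for c in cands:
            assert cstr.len_min <= c.length <= cstr.len_max
            assert c.end - c.start + 1 == c.length
            assert c.sequence.degeneracy <= cstr.max_degeneracy
            assert "N" not in str(c.sequence)
            assert c.tm.tm_min >= cstr.tm_min and c.tm.tm_max <= cstr.tm_max
            ref_lo = cons.span_start - 1 + c.start - 1
            frac = profile.depth[ref_lo : ref_lo + c.length].mean() / md
            assert frac == pytest.approx(c.mean_depth_frac)
            assert frac >= cstr.min_depth_frac
        # pairwise spacing
        for a, b in zip(cands, cands[1:]):
            assert b.start > a.end + cstr.min_spacing

    @pytest.mark.parametrize(
        "relax",
        [
            {"len_min": 20},
            {"len_max": 33},
            {"tm_min": 35.0},
            {"tm_max": 60.0},
            {"max_degeneracy": 4096},
            {"min_depth_frac": 0.2},
        ],
    )
    def test_relaxing_a_constraint_never_shrinks_the_pool(self, family, relax):
        spec, ancestor, homologs, _ = family
        from oligofish.consensus_builder import build_consensus, build_profile

        from oligofish.probe_designer import enumerate_candidates

        profile = build_profile(homologs, ancestor)
        cons = build_consensus(profile)
        base = {(c.start, c.end) for c in enumerate_candidates(cons, profile, DesignConstraints(), COND)}
        relaxed = {
            (c.start, c.end)
            for c in enumerate_candidates(cons, profile, DesignConstraints(**relax), COND)
        }
        assert base <= relaxed


class TestTandemProbes:
    @pytest.mark.parametrize(
        "unit,phase,length,expected",
        [
            ("TTTAGGG", 0, 29, "TTTAGGGTTTAGGGTTTAGGGTTTAGGGT"),
            ("ACATTCTTGAT", 0, 30, "ACATTCTTGATACATTCTTGATACATTCTT"),
            ("A", 0, 5, "AAAAA"),
            ("TTTAGGG", 3, 10, "AGGGTTTAGG"),
        ],
    )
    def test_phase_truncated_concatemer(self, unit, phase, length, expected):
        assert str(build_tandem_probe(unit, phase, length)) == expected

    def test_output_chunks_are_copies_of_unit(self):
        unit = "ACATTCTTGAT"
        probe = str(build_tandem_probe(unit, 0, 47))
        k = len(unit)
        for i in range(0, len(probe), k):
            chunk = probe[i : i + k]
            assert unit.startswith(chunk) or chunk == unit

    def test_non_primitive_monomer_rejected(self):
        with pytest.raises(ValueError, match="repetition"):
            TandemMonomer("ATAT")

    def test_bad_phase_and_length_rejected(self):
        with pytest.raises(ValueError):
            build_tandem_probe("TTTAGGG", 7, 29)
        with pytest.raises(ValueError):
            build_tandem_probe("TTTAGGG", 0, 5)


class TestPickTandemLength:
    def test_at_only_monomer_is_infeasible_with_report(self):
        scan = pick_tandem_length("TTA", COND)
        assert not scan.feasible
        assert set(scan.per_length_tm) == set(range(24, 32))
        assert all(tm < 39.0 for tm in scan.per_length_tm.values())

    def test_gc_monomer_shortest_feasible_length(self):
        scan = pick_tandem_length("GC", COND)
        expected = None
        for L in range(24, 32):
            tm = scan.per_length_tm[L]
            if expected is None and 39.0 <= tm <= 53.0:
                expected = L
        assert scan.feasible == (expected is not None)
        assert scan.target_len == expected

    def test_telomere_monomer_matches_direct_scan(self):
        from oligofish.thermo import tm_fixed

        scan = pick_tandem_length("TTTAGGG", COND)
        direct = {
            L: tm_fixed(build_tandem_probe("TTTAGGG", 0, L), COND)
            for L in range(24, 32)
        }
        assert scan.per_length_tm == pytest.approx(direct)
        feasible = [L for L, tm in direct.items() if 39.0 <= tm <= 53.0]
        assert scan.feasible == bool(feasible)
        if feasible:
            assert scan.target_len == min(feasible)
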