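import re

import numpy as np
import pytest

import dropmicro as dm
from dropmicro._util import random_dna, revcomp
from dropmicro.dash import GuideCandidate, GuideSet, parse_templates
from dropmicro.io import read_fasta, write_fasta


def brute_force_windows(seq):
    """Oracle: all N20-NGG protospacers on both strands via regex."""
    out = set()
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for m in re.finditer(r"(?=([ACGT]{20}[ACGT]GG))", s):
            out.add((strand, m.group(1)[:20], m.group(1)[20:]))
    return out


class TestEnumerateGuides:
    def test_matches_regex_oracle_on_random_sequences(self):
        for seed in range(10):
            seq = random_dna(np.random.default_rng(seed), 2000)
            cands = dm.enumerate_guides({"t": seq})
            got = {(c.strand, c.spacer, c.pam) for c in cands}
            assert got == brute_force_windows(seq)

    def test_single_forward_site(self):
        seq = "A" * 20 + "AGG"  # no CC anywhere: nothing on the minus strand
        cands = dm.enumerate_guides({"t": seq})
        assert len(cands) == 1
        c = cands[0]
        assert (c.strand, c.spacer, c.pam) == ("+", "A" * 20, "AGG")
        assert c.cut_position == 17

    def test_no_gg_or_cc_yields_nothing(self):
        seq = ("AT" * 40)
        assert dm.enumerate_guides({"t": seq}) == []

    def test_short_target_yields_nothing(self):
        assert dm.enumerate_guides({"t": "ACGTACGTACGTACGTACGTAG"}) == []

    def test_cut_positions_inside_target(self):
        seq = random_dna(np.random.default_rng(3), 500)
        for c in dm.enumerate_guides({"t": seq}):
            assert 1 <= c.cut_position < len(seq)


class TestFilterGuides:
    def _cand(self, spacer, pam="AGG"):
        return GuideCandidate(spacer, pam, "t", "+", 17, gc_fraction=(
            (spacer.count("G") + spacer.count("C")) / len(spacer)
        ))

    def test_extreme_gc_removed(self):
        low = self._cand("ATATATATATATATATATGC")  # GC 0.10
        mid = self._cand("ACGTACGTACGTACGTACGT")
        kept = dm.filter_guides([low, mid])
        assert kept == [mid] and "gc" in low.flags

    def test_tttt_always_removed(self):
        cand = self._cand("ACGTTTTACGCACGCACGCA")
        assert dm.filter_guides([cand]) == []
        assert "homopolymer" in cand.flags

    def test_long_homopolymer_removed(self):
        cand = self._cand("ACGGGGGCACGCATGCATGC")
        assert dm.filter_guides([cand]) == []

    def test_offtarget_seed_removed_vs_substring_oracle(self):
        rng = np.random.default_rng(4)
        offtarget = {"m1": random_dna(rng, 1500)}
        index = dm.build_offtarget_index(offtarget)
        cands = dm.filter_guides(dm.enumerate_guides({"t": random_dna(rng, 2000)}))
        kept = dm.filter_guides(list(cands), offtarget_index=index)
        for c in cands:
            hit = False
            for s in (offtarget["m1"], revcomp(offtarget["m1"])):
                for m in re.finditer(r"(?=([ACGT]{12}[ACGT]GG))", s):
                    if m.group(1)[:12] == c.seed:
                        hit = True
            assert (c in kept) == (not hit)


class TestTileGuides:
    def _cands(self, cuts, gene="t"):
        return [
            GuideCandidate("ACGT" * 5, "AGG", gene, "+", c, 0.5) for c in cuts
        ]

    @staticmethod
    def minimal_picks_reaching(cuts, max_gap, reach):
        """DP oracle: fewest picks, each within max_gap of the previous one
        (the first within max_gap of position 0), whose last pick is exactly
        ``reach``."""
        import math

        cuts = sorted(cuts)
        f: list[float] = []
        for i, c in enumerate(cuts):
            best = 1.0 if c <= max_gap else math.inf
            for j in range(i):
                if cuts[j] < c <= cuts[j] + max_gap:
                    best = min(best, f[j] + 1)
            f.append(best)
        return min(f[i] for i, c in enumerate(cuts) if c == reach)

    def test_regular_candidates_match_minimal_cover(self):
        cuts = list(range(10, 500, 10))
        gs = dm.tile_guides(self._cands(cuts), max_gap=50, target_lengths={"t": 500})
        picked = [g.cut_position for g in gs.selected]
        assert picked[-1] == 490  # greedy reaches the last reachable cut
        assert len(picked) == self.minimal_picks_reaching(cuts, 50, picked[-1])
        assert all(b - a <= 50 for a, b in zip(picked, picked[1:]))
        assert picked[0] <= 50

    def test_single_candidate_selected(self):
        gs = dm.tile_guides(self._cands([30]), max_gap=50)
        assert [g.cut_position for g in gs.selected] == [30]

    def test_empty_candidates_full_uncovered_interval(self):
        gs = dm.tile_guides([], max_gap=50, target_lengths={"t": 400})
        assert gs.selected == []
        assert gs.uncovered == [("t", 1, 400)]

    def test_gap_without_candidates_recorded(self):
        cuts = [20, 40, 300, 320]
        gs = dm.tile_guides(self._cands(cuts), max_gap=50, target_lengths={"t": 340})
        assert any(start > 40 and end < 300 for _, start, end in gs.uncovered)
        assert {g.cut_position for g in gs.selected} >= {40, 320}

    def test_no_shared_cut_sites(self):
        cands = self._cands([20, 20, 40])
        gs = dm.tile_guides(cands, max_gap=50)
        picked = [g.cut_position for g in gs.selected]
        assert len(picked) == len(set(picked))


def _tiled_target(seed=5, length=1500):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, length)
    cands = dm.filter_guides(dm.enumerate_guides({"rrna": seq}))
    gs = dm.tile_guides(cands, max_gap=50, target_lengths={"rrna": length})
    return seq, gs


class TestDigest:
    def test_composition_formula_endpoints(self):
        assert dm.predict_post_rrna_fraction(0.83, 0.904) == pytest.approx(
            0.32, abs=0.005
        )
        assert dm.predict_post_rrna_fraction(0.83, 0.0) == pytest.approx(0.83)
        assert dm.predict_post_rrna_fraction(0.83, 1.0) == 0.0

    def test_fully_tiled_molecules_all_depleted(self):
        seq, gs = _tiled_target()
        mols = []
        for i, g in enumerate(gs.selected):
            s = max(0, g.cut_position - 60)
            mols.append(
                dm.Amplicon(f"m{i}", "AD" + seq[s : s + 150] + "AD", True, 2, 2)
            )
        report = dm.digest_in_silico(mols, gs)
        assert report.depleted_fraction_rrna == 1.0

    def test_no_cut_leaves_composition_unchanged(self):
        _, gs = _tiled_target()
        mols = [dm.Amplicon("m", "AD" + "AT" * 60 + "AD", True, 2, 2)]
        report = dm.digest_in_silico(mols, GuideSet([], max_gap=50))
        assert report.observed_post_rrna_fraction == report.initial_rrna_fraction

    def test_non_rrna_molecules_conserved_exactly(self):
        seq, gs = _tiled_target()
        rng = np.random.default_rng(6)
        other = random_dna(rng, 1000)
        mols = [
            dm.Amplicon(f"n{i}", "AD" + other[i : i + 200] + "AD", False, 2, 2)
            for i in range(0, 400, 20)
        ]
        patterns = gs.protospacer_patterns()
        clean = [m for m in mols if not any(p in m.insert for p in patterns)]
        report = dm.digest_in_silico(clean, gs)
        assert report.surviving_non_rrna == len(clean)

    def test_depletion_monotone_in_max_gap(self):
        seq = random_dna(np.random.default_rng(7), 2000)
        cands = dm.filter_guides(dm.enumerate_guides({"t": seq}))
        rng = np.random.default_rng(8)
        starts = rng.integers(0, 1800, size=300)
        mols = [
            dm.Amplicon(f"m{i}", "AD" + seq[s : s + 200] + "AD", True, 2, 2)
            for i, s in enumerate(starts)
        ]
        fractions = []
        for gap in (30, 60, 120, 300):
            gs = dm.tile_guides(cands, max_gap=gap, target_lengths={"t": 2000})
            fractions.append(dm.digest_in_silico(mols, gs).depleted_fraction_rrna)
        assert all(a >= b - 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_cut_site_between_adapters_only(self):
        _, gs = _tiled_target()
        pattern = sorted(gs.protospacer_patterns())[0]
        # the full protospacer+PAM sits inside the adapter -> no depletion
        mol = dm.Amplicon("m", pattern + "AT" * 60, True, len(pattern), 0)
        report = dm.digest_in_silico([mol], gs)
        assert report.depleted_fraction_rrna == 0.0


class TestTemplates:
    def test_lengths_and_g_prepend(self):
        a = GuideCandidate("G" + "ACGT" * 4 + "CAT", "AGG", "t", "+", 17, 0.5)
        b = GuideCandidate("A" + "ACGT" * 4 + "CAT", "TGG", "t", "+", 30, 0.5)
        gs = GuideSet([a, b], max_gap=50)
        t7, scaf = "TAATACGACTCACTATAG", "GTTTTAGAGC"
        recs = dm.emit_templates(gs, t7, scaf)
        assert len(recs[0]) == len(t7) + 20 + len(scaf)
        assert len(recs[1]) == len(t7) + 21 + len(scaf)
        assert recs[1].sequence[len(t7)] == "G"

    def test_fasta_roundtrip_recovers_spacers(self, tmp_path):
        _, gs = _tiled_target()
        recs = dm.emit_templates(gs)
        path = str(tmp_path / "templates.fasta")
        write_fasta(recs, path)
        spacers = parse_templates(read_fasta(path))
        assert spacers == [g.spacer for g in gs.selected]
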