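import math

import numpy as np
import pytest

from sigpep.cleavage import (
    CleavageModel,
    DEFAULT_POSITIONS,
    EUKARYOTE_RULES,
    PROKARYOTE_RULES,
    build_weight_matrix,
    extract_window,
    get_rules,
    residue_background,
    rule_check,
    scan_cleavage,
    window_score,
    windows_from_sites,
)
from sigpep.data import SyntheticSpec, generate_synthetic
from sigpep.encoder import ProteinSequence
from sigpep.properties import ALPHABET, INDEX

UNIFORM_BG = {res: 1.0 / 20 for res in ALPHABET}


class TestBuildWeightMatrix:
    def test_single_window_uniform_background_no_pseudocount(self):
        model = build_weight_matrix(["AAA"], UNIFORM_BG, pseudocount=0.0, positions=(-2, -1, 1))
        a = INDEX["A"]
        assert np.allclose(model.Q[a], math.log(20.0))
        other = np.delete(model.Q, a, axis=0)
        assert np.all(np.isneginf(other))

    def test_counts_matching_background_give_zero_matrix(self):
        # 20 windows whose columns are permutations of the alphabet: every
        # positional frequency equals the uniform background exactly
        rng = np.random.default_rng(0)
        cols = [rng.permutation(list(ALPHABET)) for _ in range(3)]
        windows = ["".join(cols[j][i] for j in range(3)) for i in range(20)]
        model = build_weight_matrix(windows, UNIFORM_BG, pseudocount=0.0, positions=(-2, -1, 1))
        assert np.allclose(model.Q, 0.0, atol=1e-12)

    def test_ragged_windows_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_weight_matrix(["AAA", "AA"], UNIFORM_BG, positions=(-2, -1, 1))

    def test_background_validation(self):
        bad = dict(UNIFORM_BG)
        bad["A"] = 0.0
        with pytest.raises(ValueError, match="background"):
            build_weight_matrix(["AAA"], bad, positions=(-2, -1, 1))

    def test_window_order_irrelevant(self, rng):
        windows = ["".join(rng.choice(list(ALPHABET), size=15)) for _ in range(30)]
        m1 = build_weight_matrix(windows, UNIFORM_BG)
        m2 = build_weight_matrix(windows[::-1], UNIFORM_BG)
        assert np.array_equal(m1.Q, m2.Q)

    def test_profile_recovery_from_sampled_windows(self):
        # each column allows 5 residues at probability 0.2 -> expected count
        # ~100 of 500, so the log-ratio is recoverable to ~0.1 on average
        rng = np.random.default_rng(42)
        width = len(DEFAULT_POSITIONS)
        support = [rng.choice(20, size=5, replace=False) for _ in range(width)]
        windows = []
        for _ in range(500):
            chars = [ALPHABET[rng.choice(support[i])] for i in range(width)]
            windows.append("".join(chars))
        model = build_weight_matrix(windows, UNIFORM_BG, pseudocount=1.0)
        errors = []
        for i in range(width):
            for a in support[i]:
                true_log_ratio = math.log(0.2 / (1.0 / 20))
                errors.append(abs(model.Q[a, i] - true_log_ratio))
        assert np.mean(errors) <= 0.1


class TestRuleCheck:
    def _seq(self, signal_tail, mature="MDE"):
        # pad the front so the candidate site lands at a fixed position
        prefix = "MKLLLLLLLL"
        residues = prefix + signal_tail + mature
        site = len(prefix) + len(signal_tail) + 1
        return ProteinSequence("x", residues), site

    def test_eukaryotic_minus3_set_excludes_alanine(self):
        # -3 = A is NOT in the eukaryotic -3 set (charged/polar residues only)
        seq, site = self._seq("ASA")  # -3 A, -2 S, -1 A
        assert rule_check(seq, site, EUKARYOTE_RULES) is False

    def test_eukaryotic_compliant_site(self):
        seq, site = self._seq("NSA")  # -3 N (allowed), -1 A (allowed), no P
        assert rule_check(seq, site, EUKARYOTE_RULES) is True

    def test_proline_anywhere_in_window_fails(self):
        seq, site = self._seq("NPA")  # P at -2
        assert rule_check(seq, site, EUKARYOTE_RULES) is False
        seq, site = self._seq("NSA", mature="PDE")  # P at +1
        assert rule_check(seq, site, EUKARYOTE_RULES) is False

    def test_prokaryotic_minus3_accepts_valine(self):
        seq, site = self._seq("VSG")  # -3 V, -1 G, no P
        assert rule_check(seq, site, PROKARYOTE_RULES) is True

    def test_site_out_of_range_rejected(self):
        seq = ProteinSequence("x", "MKLLLNSAMDE")
        with pytest.raises(ValueError, match="outside"):
            rule_check(seq, 3, EUKARYOTE_RULES)
        with pytest.raises(ValueError, match="outside"):
            rule_check(seq, seq.N, EUKARYOTE_RULES)

    def test_get_rules_variants(self):
        assert get_rules("eukaryote") is EUKARYOTE_RULES
        assert get_rules("prokaryote") is PROKARYOTE_RULES
        classic = get_rules("eukaryote", classic_von_heijne=True)
        assert "A" in classic.allowed_minus3
        with pytest.raises(ValueError):
            get_rules("archaea")


class TestScan:
    def _uniform_model(self):
        Q = np.zeros((20, len(DEFAULT_POSITIONS)))
        return CleavageModel(
            Q=Q, positions=DEFAULT_POSITIONS, pseudocount=1.0, background=UNIFORM_BG
        )

    def test_no_compliant_position_returns_none(self):
        # tryptophan-only sequence: no allowed -1 residue anywhere
        seq = ProteinSequence("x", "W" * 30)
        assert scan_cleavage(seq, self._uniform_model(), EUKARYOTE_RULES) is None

    def test_tie_breaks_to_most_n_terminal_site(self):
        # two compliant sites, uniform (all-zero) matrix -> equal scores
        seq = ProteinSequence("x", "MKLLLLLLLLNSAMDENSAMDELLL")
        hit = scan_cleavage(seq, self._uniform_model(), EUKARYOTE_RULES)
        assert hit is not None
        site, score = hit
        compliant = [
            s for s in range(4, seq.N)
            if rule_check(seq, s, EUKARYOTE_RULES)
        ]
        assert site == min(compliant)
        assert score == 0.0

    def test_with_uniform_matrix_scan_reduces_to_rule_filter(self, rng):
        model = self._uniform_model()
        for _ in range(20):
            seq = ProteinSequence(
                "x", "".join(rng.choice(list(ALPHABET), size=int(rng.integers(20, 80))))
            )
            hit = scan_cleavage(seq, model, EUKARYOTE_RULES)
            compliant = [
                s for s in range(4, min(60, seq.N - 1) + 1)
                if rule_check(seq, s, EUKARYOTE_RULES)
            ]
            if not compliant:
                assert hit is None
            else:
                assert hit[0] == compliant[0]

    def test_never_returns_rule_violating_site(self, rng, small_dataset):
        positives, sites, _ = small_dataset
        windows = windows_from_sites(positives, sites)
        bg = residue_background(positives)
        model = build_weight_matrix(windows, bg)
        for seq in positives[:20]:
            hit = scan_cleavage(seq, model, EUKARYOTE_RULES)
            assert hit is not None
            assert rule_check(seq, hit[0], EUKARYOTE_RULES)

    def test_planted_sites_recovered(self, small_dataset):
        # matrix from the annotated windows of the same generated set
        # (self-consistency style), then every planted site rescanned
        positives, sites, _ = small_dataset
        windows = windows_from_sites(positives, sites)
        bg = residue_background(positives)
        model = build_weight_matrix(windows, bg)
        hits = [scan_cleavage(seq, model, EUKARYOTE_RULES) for seq in positives]
        correct = sum(
            1 for hit, true_site in zip(hits, sites)
            if hit is not None and hit[0] == true_site
        )
        assert correct / len(hits) >= 0.9

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            scan_cleavage(ProteinSequence("x", "MKLA"), self._uniform_model(), EUKARYOTE_RULES)


class TestWindowHandling:
    def test_extract_window_positions(self):
        seq = ProteinSequence("x", "ACDEFGHIKLMNPQRSTVWY")
        w = extract_window(seq, 15, positions=(-3, -2, -1, 1, 2))
        # site 15 -> -3..-1 are residues 12..14 (N,P,Q), +1/+2 are 15,16 (R,S)
        assert w == "NPQRS"
        assert extract_window(seq, 2, positions=(-3, -2, -1, 1, 2)) is None

    def test_partial_windows_score_in_bounds_positions_only(self):
        rng = np.random.default_rng(1)
        Q = rng.normal(size=(20, len(DEFAULT_POSITIONS)))
        model = CleavageModel(
            Q=Q, positions=DEFAULT_POSITIONS, pseudocount=1.0, background=UNIFORM_BG
        )
        seq = ProteinSequence("x", "MKLLLLNSAMDELLL")
        site = 10
        expected = 0.0
        for col, rel in enumerate(DEFAULT_POSITIONS):
            idx = (site - 1) + (rel - 1 if rel > 0 else rel)
            if 0 <= idx < seq.N:
                expected += Q[INDEX[seq.residues[idx]], col]
        assert window_score(seq, site, model) == pytest.approx(expected)

    def test_matrix_tsv_round_trip(self, tmp_path, rng):
        windows = ["".join(rng.choice(list(ALPHABET), size=15)) for _ in range(25)]
        model = build_weight_matrix(windows, UNIFORM_BG, pseudocount=0.5)
        path = tmp_path / "pwm.tsv"
        model.save_tsv(path)
        loaded = CleavageModel.load_tsv(path)
        assert loaded.positions == model.positions
        assert loaded.pseudocount == model.pseudocount
        assert np.allclose(loaded.Q, model.Q, atol=1e-9)
        assert loaded.background == pytest.approx(model.background, abs=1e-5)
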