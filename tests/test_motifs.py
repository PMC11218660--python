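"""PWM scanning, exact p-values, gain/loss calls and the signed OR."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cardmpra import motifs


def strict_pwm(consensus, motif_id="m", background=None):
    mat = np.zeros((len(consensus), 4))
    for i, c in enumerate(consensus):
        mat[i, "ACGT".index(c)] = 1.0
    kw = {} if background is None else {"background": np.asarray(background)}
    return motifs.PWM(motif_id, mat, **kw)


def mixed_pwm(n_strict=5, n_moderate=5):
    """Alternating strict and moderately informative positions; consensus
    is all-A."""
    rows = []
    for i in range(n_strict + n_moderate):
        if i % 2 == 0 and i // 2 < n_strict:
            rows.append([1.0, 0.0, 0.0, 0.0])
        else:
            rows.append([0.55, 0.15, 0.15, 0.15])
    return motifs.PWM("mixed", np.array(rows))


class TestExactPValues:
    @pytest.mark.parametrize("length", [4, 5, 6])
    def test_dp_matches_enumeration_bit_for_bit(self, length):
        """Tail probabilities from the integer DP equal exhaustive
        enumeration over all k-mers at the same discretization."""
        rng = np.random.default_rng(length)
        mat = rng.dirichlet(np.ones(4) * 0.7, size=length)
        bg = rng.dirichlet(np.ones(4) * 10)
        pwm = motifs.PWM("t", mat, background=bg)
        s = pwm.int_scores()
        q = np.maximum(np.round(bg * (1 << 20)).astype(np.int64), 1)
        table = {}
        for kmer in itertools.product(range(4), repeat=length):
            sc = int(sum(s[i, b] for i, b in enumerate(kmer)))
            w = 1
            for b in kmer:
                w *= int(q[b])
            table[sc] = table.get(sc, 0) + w
        total = sum(table.values())
        acc = 0
        for sc in sorted(table, reverse=True):
            acc += table[sc]
            assert pwm.match_p(sc) == acc / total

    def test_consensus_p_is_background_product(self):
        bg = [0.4, 0.3, 0.2, 0.1]
        pwm = strict_pwm("ACGTA", background=bg)
        hit = motifs.scan_pwm("TT" + "ACGTA" + "GG", pwm, window=(2, 7))
        expected = 0.4 * 0.3 * 0.2 * 0.1 * 0.4
        assert hit.p == pytest.approx(expected, rel=1e-5)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        pwm = motifs.PWM("s", rng.dirichlet(np.ones(4), size=6))
        seq = "".join(rng.choice(list("ACGT"), 50))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        h1 = motifs.scan_pwm(seq, pwm)
        h2 = motifs.scan_pwm(rc, pwm)
        assert h1.int_score == h2.int_score
        assert h1.p == h2.p

    def test_short_sequence_gives_no_hit(self):
        pwm = strict_pwm("ACGTAC")
        assert motifs.scan_pwm("ACG", pwm) is None
        assert motifs.motif_score(None) == 0.0


class TestScoreSemantics:
    def test_score_is_minus_log10_p(self):
        assert motifs.score_from_p(1e-3) == pytest.approx(3.0)
        assert motifs.p_from_score(3.0) == pytest.approx(1e-3)

    def test_delta_two_is_hundredfold(self):
        for s in (2.5, 4.0, 7.3):
            assert motifs.p_from_score(s) / motifs.p_from_score(s + 2.0) \
                == pytest.approx(100.0)


class TestClassifyChanges:
    def _pair_frame(self, ref_seq, alt_seq, center, cls="MPRA-DA"):
        return pd.DataFrame([{
            "pair_id": "p0", "ref_seq": ref_seq, "alt_seq": alt_seq,
            "ref_center": center, "alt_center": center, "class": cls}])

    def test_identical_sequences_no_calls(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 171))
        pairs = self._pair_frame(seq, seq, 85)
        out = motifs.classify_changes(pairs, [mixed_pwm()], window=8)
        assert (out["delta"] == 0).all()
        assert (out["call"] == "none").all()

    def test_snv_destroying_planted_motif_is_lom(self):
        """An SNV at a strict position of a planted motif drops the match
        p-value >= 100-fold; cross-checked against exhaustive enumeration."""
        pwm = mixed_pwm()
        rng = np.random.default_rng(2)
        flank = "".join(rng.choice(list("CGT"), 80))
        flank2 = "".join(rng.choice(list("CGT"), 81))
        ref = flank + "A" * 10 + flank2  # planted all-A site at 80..90
        alt = ref[:84] + "C" + ref[85:]  # SNV at a strict position (84)
        pairs = self._pair_frame(ref, alt, 85)
        out = motifs.classify_changes(pairs, [pwm], window=8)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["call"] == "LoM"
        assert row["category"] == "MPRA-DA_LoM"
        # enumeration oracle over all 10-mers (uniform background: p = count/4^10)
        s = pwm.int_scores()
        grids = np.indices((4,) * 10).reshape(10, -1)
        all_scores = s[np.arange(10)[:, None], grids].sum(axis=0)
        def oracle_p(int_score):
            return int((all_scores >= int_score).sum()) / 4 ** 10
        hit_ref = motifs.scan_pwm(ref, pwm, (77, 94))
        hit_alt = motifs.scan_pwm(alt, pwm, (77, 94))
        assert hit_ref.p == oracle_p(hit_ref.int_score)
        assert hit_alt.p == oracle_p(hit_alt.int_score)
        assert row["score_ref"] - row["score_alt"] >= 2.0

    def test_below_threshold_delta_not_called(self):
        changes = pd.DataFrame([{"pair_id": "p", "motif_id": "m",
                                 "score_ref": 5.0, "score_alt": 3.1,
                                 "delta": -1.9}])
        # direct check of the rule: |delta| = 1.9 < 2 is no call
        assert abs(changes["delta"].iloc[0]) < motifs.DELTA_THRESHOLD

    def test_weak_matches_filtered_by_p_gate(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 60))
        pairs = self._pair_frame(seq, seq, 30)
        pwm = strict_pwm("ACGTACGTAC")
        out = motifs.classify_changes(pairs, [pwm], window=8)
        if len(out):
            assert (np.maximum(out["score_ref"], out["score_alt"]) > 3.0).all()


class TestOddsRatio:
    def _changes(self, n_eff_changed, n_eff, n_ns_changed, n_ns,
                 cls="MPRA-IA", delta=3.0):
        rows = []
        for i in range(n_eff):
            rows.append(("e%d" % i, "m", cls,
                         "GoM" if i < n_eff_changed else "none",
                         delta if i < n_eff_changed else 0.0))
        for i in range(n_ns):
            rows.append(("n%d" % i, "m", "MPRA-NS",
                         "GoM" if i < n_ns_changed else "none",
                         delta if i < n_ns_changed else 0.0))
        return pd.DataFrame(rows, columns=["pair_id", "motif_id",
                                           "activity_class", "call", "delta"])

    def test_hand_example(self):
        # P_mc = 0.5, P_mn = 0.1, activator pattern: OR = (0.5*0.9)/(0.1*0.5) = 9
        ch = self._changes(5, 10, 1, 10)
        row = motifs.motif_odds_ratio(ch, "m", "MPRA-IA")
        assert row["or_value"] == pytest.approx(9.0)
        assert row["n_sign"] == 1

    def test_no_association_gives_unit_or(self):
        ch = self._changes(3, 10, 3, 10)
        row = motifs.motif_odds_ratio(ch, "m", "MPRA-IA")
        assert abs(row["or_value"]) == pytest.approx(1.0)

    def test_repressor_pattern_negative(self):
        # motif GAINED in MPRA-DA pairs -> repressor, n = -1, OR negative
        ch = self._changes(5, 10, 1, 10, cls="MPRA-DA", delta=3.0)
        row = motifs.motif_odds_ratio(ch, "m", "MPRA-DA")
        assert row["n_sign"] == -1
        assert row["or_value"] < 0

    def test_swapping_groups_inverts_unsigned_or(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a, b = rng.integers(1, 9, 2)
            ch = self._changes(int(a), 10, int(b), 10)
            fwd = motifs.motif_odds_ratio(ch, "m", "MPRA-IA")
            # swap: treat NS as effect and effect as NS
            sw = ch.copy()
            sw["activity_class"] = sw["activity_class"].map(
                {"MPRA-IA": "MPRA-NS", "MPRA-NS": "MPRA-IA"})
            rev = motifs.motif_odds_ratio(sw, "m", "MPRA-IA")
            assert abs(fwd["or_value"]) == pytest.approx(1 / abs(rev["or_value"]))

    def test_zero_cell_smoothing_flagged(self):
        ch = self._changes(10, 10, 1, 10)
        row = motifs.motif_odds_ratio(ch, "m", "MPRA-IA")
        assert row["smoothed"]
        assert 0 < row["P_mc"] < 1 and 0 < row["P_mn"] < 1


class TestFrequencyRanking:
    def _table(self, causal_rate, decoy_rate, n_eff=50, n_ns=50, n_decoys=50,
               seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cls, n, tag in (("MPRA-DA", n_eff, "e"), ("MPRA-NS", n_ns, "n")):
            for i in range(n):
                pid = f"{tag}{i}"
                rate = causal_rate if cls == "MPRA-DA" else 0.05
                call = "LoM" if rng.random() < rate else "none"
                rows.append((pid, "causal", cls, call, -3.0 if call != "none" else 0))
                for d in range(n_decoys):
                    call = "LoM" if rng.random() < decoy_rate else "none"
                    rows.append((pid, f"decoy{d:02d}", cls, call,
                                 -3.0 if call != "none" else 0))
        return pd.DataFrame(rows, columns=["pair_id", "motif_id",
                                           "activity_class", "call", "delta"])

    def test_planted_causal_motif_ranks_high(self):
        ranked = motifs.motif_frequency_ranking(self._table(0.6, 0.05))
        causal_rank = ranked.set_index("motif_id").loc["causal", "rank"]
        assert causal_rank <= 5

    def test_never_perturbed_motif_excluded(self):
        ranked = motifs.motif_frequency_ranking(self._table(0.0, 0.05, seed=1))
        assert "causal" not in set(ranked["motif_id"])

    def test_equal_frequencies_give_unit_ratio(self):
        rows = []
        for cls, tag in (("MPRA-DA", "e"), ("MPRA-NS", "n")):
            for i in range(20):
                rows.append((f"{tag}{i}", "m", cls,
                             "LoM" if i < 10 else "none", -3.0))
        ch = pd.DataFrame(rows, columns=["pair_id", "motif_id",
                                         "activity_class", "call", "delta"])
        ranked = motifs.motif_frequency_ranking(ch)
        assert ranked["ratio"].iloc[0] == pytest.approx(1.0)


def test_meme_round_trip(tmp_path):
    rng = np.random.default_rng(11)
    pwms = [motifs.PWM(f"mot{i}", rng.dirichlet(np.ones(4), size=8))
            for i in range(3)]
    path = tmp_path / "motifs.meme"
    motifs.write_meme(pwms, path)
    back = motifs.read_meme(path)
    assert [p.motif_id for p in back] == ["mot0", "mot1", "mot2"]
    for a, b in zip(pwms, back):
        assert np.allclose(a.matrix, b.matrix, atol=1e-5)
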