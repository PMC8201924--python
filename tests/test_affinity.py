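import math

import numpy as np
import pytest

from nuchmm.affinity import (LinkerScorer, compute_hba, compute_local_hba,
                             prob_linker, prob_nucleosome)
from nuchmm.fixtures import iid_model
from nuchmm.model import SEGMENTS, LinkerModel, encode_sequence
from nuchmm.training import estimate_nucleosome_model

ODD_SEGMENTS = ["A", "C", "E", "G", "I", "K", "M"]


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.2, 0.3]))


class TestProbNucleosome:
    def test_uniform_model_is_sequence_independent(self, uniform_tm):
        expected = -147 * math.log(4)
        for seed in (0, 1):
            seq = _random_seq(147, seed)
            assert prob_nucleosome(seq, uniform_tm) == pytest.approx(expected)

    def test_point_mass_model_scores_training_sequence_zero(self):
        seq = _random_seq(147, 5)
        nuc = estimate_nucleosome_model([seq], pseudocount=False,
                                        smoothing=False)
        assert prob_nucleosome(seq, nuc) == pytest.approx(0.0, abs=1e-12)

    def test_iid_closed_form(self):
        m = iid_model([0.5, 1 / 6, 1 / 6, 1 / 6], [0.25] * 4)
        assert prob_nucleosome("A" * 147, m) == pytest.approx(
            147 * math.log(0.5))

    def test_wrong_length_rejected(self, uniform_tm):
        with pytest.raises(ValueError):
            prob_nucleosome("ACGT", uniform_tm)

    def test_n_gives_missing_by_default_finite_under_uniform_policy(
            self, uniform_tm):
        seq = "A" * 73 + "N" + "A" * 73
        assert math.isnan(prob_nucleosome(seq, uniform_tm))
        v = prob_nucleosome(seq, uniform_tm, n_policy="uniform")
        assert v == pytest.approx(-147 * math.log(4))


class TestProbLinker:
    def test_uniform_any_length(self, uniform_tm):
        for n in (1, 3, 5, 21, 147):
            assert prob_linker(_random_seq(n, n), uniform_tm) == \
                pytest.approx(-n * math.log(4))

    def test_length_one_uses_freqL_only(self):
        m = iid_model([0.25] * 4, [0.4, 0.2, 0.2, 0.2])
        assert prob_linker("A", m) == pytest.approx(math.log(0.4))

    def test_hand_built_order_ramp_on_acgta(self):
        rng = np.random.default_rng(9)

        def rows(k):
            r = rng.dirichlet([1.0] * 4, size=4 ** k)
            return r

        link = LinkerModel(freqL=rng.dirichlet([1.0] * 4), tranL=rows(1),
                           tranL2=rows(2), tranL3=rows(3), tranL4=rows(4))
        a, c, g, t = 0, 1, 2, 3
        expected = (math.log(link.freqL[a])
                    + math.log(link.tranL[a, c])
                    + math.log(link.tranL2[a * 4 + c, g])
                    + math.log(link.tranL3[(a * 4 + c) * 4 + g, t])
                    + math.log(link.tranL4[((a * 4 + c) * 4 + g) * 4 + t, a]))
        assert prob_linker("ACGTA", link) == pytest.approx(expected)


class TestComputeHBA:
    def test_identical_laws_give_zero_everywhere(self):
        m = iid_model([0.25] * 4, [0.25] * 4)
        prof = compute_hba(_random_seq(400, 2), m)
        assert np.allclose(prof.scores[prof.defined], 0.0, atol=1e-10)
        assert prof.defined.sum() == 400 - 146

    def test_iid_worked_case(self):
        m = iid_model([0.25] * 4, [0.4, 0.2, 0.2, 0.2])
        prof = compute_hba("A" * 147, m)
        assert prof.scores[73] == pytest.approx(147 * math.log(0.625))
        assert prof.defined.sum() == 1

    def test_centered_mode_sums_to_zero(self, trained_model):
        prof = compute_hba(_random_seq(500, 3), trained_model,
                           mode="centered")
        assert np.nansum(prof.scores) == pytest.approx(0.0, abs=1e-8)

    def test_short_query_empty_profile_with_warning(self, uniform_tm):
        with pytest.warns(UserWarning):
            prof = compute_hba("ACGT" * 30, uniform_tm)
        assert prof.defined.sum() == 0

    def test_window_overlapping_n_is_missing(self, trained_model):
        seq = _random_seq(400, 4)
        seq = seq[:200] + "N" + seq[201:]
        prof = compute_hba(seq, trained_model)
        # every dyad whose 147-bp window covers position 201 is undefined
        assert np.isnan(prof.scores[127:274]).all()
        assert prof.defined.sum() == (400 - 146) - 147

    def test_translation_equivariance(self, trained_model):
        core = _random_seq(300, 6)
        base = compute_hba(core, trained_model).scores
        for offset in (10, 57):
            padded = _random_seq(offset, 7) + core + _random_seq(40, 8)
            shifted = compute_hba(padded, trained_model).scores
            np.testing.assert_allclose(
                shifted[offset + 73 : offset + 300 - 73],
                base[73 : 300 - 73], atol=1e-10)

    def test_per_base_accumulation_oracle(self, trained_model):
        """Direct per-base log accumulation reproduces the vectorized a_i."""
        seq = _random_seq(250, 12)
        codes = encode_sequence(seq)
        prof = compute_hba(seq, trained_model)
        nuc, link = trained_model.nucleosome, trained_model.linker
        for s in (0, 37, 103):                     # window starts, 0-based
            num = math.log(nuc.freqN4[int(
                "".join(str(c) for c in codes[s:s + 4]), 4)])
            for t in range(5, 148):
                ctx = 0
                for j in range(t - 5, t - 1):
                    ctx = ctx * 4 + int(codes[s + j])
                num += math.log(nuc.tranN4[t - 5][ctx][int(codes[s + t - 1])])
            den = math.log(link.freqL[int(codes[s])])
            for i in range(1, 147):
                order = min(i, 4)
                ctx = 0
                for j in range(i - order, i):
                    ctx = ctx * 4 + int(codes[s + j])
                table = [link.tranL, link.tranL2, link.tranL3,
                         link.tranL4][order - 1]
                den += math.log(table[ctx][int(codes[s + i])])
            assert prof.scores[s + 73] == pytest.approx(num - den, abs=1e-10)


class TestLocalHBA:
    def test_identical_laws_all_zero(self):
        m = iid_model([0.25] * 4, [0.25] * 4)
        prof = compute_local_hba(_random_seq(300, 2), m)
        defined = ~np.isnan(prof.scores)
        assert np.allclose(prof.scores[defined], 0.0, atol=1e-10)

    def test_iid_closed_forms_per_segment_length(self):
        m = iid_model([0.25] * 4, [0.4, 0.2, 0.2, 0.2])
        prof = compute_local_hba("A" * 147, m)
        assert prof.track("A")[73] == pytest.approx(21 * math.log(0.625))
        assert prof.track("B")[73] == pytest.approx(20 * math.log(0.625))
        for seg, (p, q) in SEGMENTS.items():
            assert prof.track(seg)[73] == pytest.approx(
                (q - p + 1) * math.log(0.625))

    def test_odd_segments_telescope_exactly_under_iid(self):
        m = iid_model([0.3, 0.2, 0.3, 0.2], [0.4, 0.2, 0.2, 0.2])
        seq = _random_seq(400, 11)
        hba = compute_hba(seq, m)
        local = compute_local_hba(seq, m)
        total = sum(local.track(s) for s in ODD_SEGMENTS)
        defined = hba.defined
        np.testing.assert_allclose(total[defined], hba.scores[defined],
                                   atol=1e-9)

    def test_near_additivity_identity_under_trained_model(self,
                                                          trained_model):
        """Sum over the non-overlapping segments minus HBA equals exactly the
        six boundary corrections (joint 4-mer start vs chained conditionals,
        and linker-chain restart vs continuation)."""
        seq = _random_seq(200, 13)
        codes = encode_sequence(seq)
        hba = compute_hba(seq, trained_model)
        local = compute_local_hba(seq, trained_model)
        nuc, link = trained_model.nucleosome, trained_model.linker
        lsc = LinkerScorer(codes, link, n_policy="uniform")
        seg_keys = list(SEGMENTS)
        for w in (0, 20, 53):                       # window start, 0-based
            corrections = 0.0
            for seg in ODD_SEGMENTS[1:]:            # C,E,G,I,K,M boundaries
                p, _q = SEGMENTS[seg]
                a = w + p - 1
                k = seg_keys.index(seg)
                ctx4 = 0
                for j in range(a, a + 4):
                    ctx4 = ctx4 * 4 + int(codes[j])
                start_term = math.log(nuc.freqN4S[k][ctx4])
                chained = 0.0
                for t in range(p, p + 4):
                    ctx = 0
                    for j in range(t - 5, t - 1):
                        ctx = ctx * 4 + int(codes[w + j])
                    chained += math.log(
                        nuc.tranN4[t - 5][ctx][int(codes[w + t - 1])])
                num_corr = start_term - chained
                den_restart = float(lsc.score(a, a + 3))
                den_continued = float(lsc.cum5[a + 4] - lsc.cum5[a])
                corrections += num_corr - (den_restart - den_continued)
            total = sum(local.track(s)[w + 73] for s in ODD_SEGMENTS)
            assert total - hba.scores[w + 73] == pytest.approx(
                corrections, abs=1e-9)
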