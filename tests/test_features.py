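"""Profiles, mutual information, coevolution input, pair potential,
and the 51-channel tensor assembly."""

import numpy as np
import pytest

from contactnet.core import CONTACT, ContactMap, ProteinRecord
from contactnet.features import (ACC_I, ACC_J, COEV, MUTUAL_INFO, N_CHANNELS,
                                 PAIR_POTENTIAL, PROFILE_I, PROFILE_J, SS_I,
                                 SS_J, Alignment, PairPotentialTable,
                                 assemble_features,
                                 compute_mutual_information, compute_profile,
                                 derive_pair_potential,
                                 load_coevolution_matrix)
from contactnet.core import AMINO_ACIDS, AA_INDEX


def _random_alignment(rng, depth, width, gap_rate=0.1):
    letters = list(AMINO_ACIDS)
    target = "".join(rng.choice(letters, width))
    rows = [target]
    for _ in range(depth - 1):
        row = ["-" if rng.random() < gap_rate else rng.choice(letters)
               for _ in range(width)]
        rows.append("".join(row))
    return Alignment(rows=rows)


class TestProfile:
    def test_single_sequence_is_one_hot(self):
        aln = Alignment(rows=["ACD"])
        prof = compute_profile(aln, pseudocount=0.0)
        expected = np.zeros((3, 20))
        for i, a in enumerate("ACD"):
            expected[i, AA_INDEX[a]] = 1.0
        assert np.allclose(prof, expected)

    def test_conserved_column_frequency_one(self):
        aln = Alignment(rows=["A", "A", "A"])
        prof = compute_profile(aln, pseudocount=0.0)
        assert prof[0, AA_INDEX["A"]] == pytest.approx(1.0)

    @pytest.mark.parametrize("pseudocount", [0.0, 1.0])
    def test_matches_naive_counting(self, pseudocount):
        rng = np.random.default_rng(2)
        aln = _random_alignment(rng, depth=50, width=30)
        prof = compute_profile(aln, pseudocount=pseudocount)
        for col in range(30):
            counts = np.zeros(20)
            for row in aln.rows:
                k = AA_INDEX.get(row[col])
                if k is not None:
                    counts[k] += 1
            counts += pseudocount / 20
            assert np.allclose(prof[col], counts / counts.sum())

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        prof = compute_profile(_random_alignment(rng, 20, 15))
        assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-9)


class TestMutualInformation:
    def test_identical_sequences_zero(self):
        aln = Alignment(rows=["ACDE"] * 10)
        mi = compute_mutual_information(aln, pseudocount=0.0)
        assert np.allclose(mi, 0.0, atol=1e-12)

    def test_perfect_two_letter_covariation_is_ln2(self):
        # two joint states AC / CA, equally frequent, perfectly covarying
        rows = ["AC", "CA"] * 5
        mi = compute_mutual_information(Alignment(rows=rows),
                                        pseudocount=0.0)
        assert mi[0, 1] == pytest.approx(np.log(2.0))

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(5)
        aln = _random_alignment(rng, depth=40, width=10)
        enc = aln.encoded()
        mi = compute_mutual_information(aln, pseudocount=0.0)
        for i in range(10):
            for j in range(i + 1, 10):
                both = (enc[:, i] < 20) & (enc[:, j] < 20)
                n = both.sum()
                joint = np.zeros((20, 20))
                for a, b in zip(enc[both, i], enc[both, j]):
                    joint[a, b] += 1
                joint /= n
                fi, fj = joint.sum(1), joint.sum(0)
                expected = sum(
                    joint[a, b] * np.log(joint[a, b] / (fi[a] * fj[b]))
                    for a in range(20) for b in range(20) if joint[a, b] > 0
                )
                assert mi[i, j] == pytest.approx(expected, abs=1e-10)

    def test_symmetric_nonnegative_zero_diagonal(self):
        rng = np.random.default_rng(7)
        mi = compute_mutual_information(_random_alignment(rng, 25, 12))
        assert np.allclose(mi, mi.T)
        assert (mi >= -1e-12).all()
        assert np.allclose(np.diag(mi), 0.0)


class TestCoevolutionInput:
    def test_zero_file(self, tmp_path):
        path = tmp_path / "zero.mat"
        np.savetxt(path, np.zeros((4, 4)))
        assert np.array_equal(load_coevolution_matrix(path, 4),
                              np.zeros((4, 4)))

    def test_asymmetric_entries_averaged(self, tmp_path):
        m = np.zeros((3, 3))
        m[1, 2], m[2, 1] = 0.4, 0.2
        path = tmp_path / "asym.mat"
        np.savetxt(path, m)
        out = load_coevolution_matrix(path)
        assert out[1, 2] == pytest.approx(0.3)
        assert out[2, 1] == pytest.approx(0.3)

    def test_round_trip_bit_equal_after_symmetrisation(self, tmp_path,
                                                       toy_target):
        from contactnet.io import write_flat_matrix

        path = tmp_path / "coev.mat"
        write_flat_matrix(path, toy_target.coevolution)
        back = load_coevolution_matrix(path, toy_target.length)
        assert np.array_equal(back, toy_target.coevolution)


class TestPairPotential:
    def _corpus(self, rng, n=30, L=25, only_pair=None):
        corpus = []
        for _ in range(n):
            seq = "".join(rng.choice(list(AMINO_ACIDS), L))
            states = np.zeros((L, L), dtype=np.int8)
            iu, ju = np.triu_indices(L, k=1)
            pick = rng.random(len(iu)) < 0.05
            for i, j in zip(iu[pick], ju[pick]):
                if only_pair and {seq[i], seq[j]} != set(only_pair):
                    continue
                states[i, j] = states[j, i] = CONTACT
            corpus.append((seq, ContactMap(states=states)))
        return corpus

    def test_exclusive_contact_pair_is_minimum(self):
        rng = np.random.default_rng(1)
        corpus = self._corpus(rng, only_pair="AA")
        pot = derive_pair_potential(corpus, smoothing=0.5)
        a = AA_INDEX["A"]
        assert pot.table[a, a] == pot.table.min()

    def test_uniform_contacts_approach_zero(self):
        rng = np.random.default_rng(2)
        corpus = self._corpus(rng, n=400, L=40)
        pot = derive_pair_potential(corpus, smoothing=1.0)
        assert np.abs(pot.table).max() < 0.35
        assert np.abs(pot.table).mean() < 0.1

    def test_symmetry_and_no_contact_error(self):
        rng = np.random.default_rng(3)
        pot = derive_pair_potential(self._corpus(rng))
        assert np.array_equal(pot.table, pot.table.T)
        empty = [("ACD", ContactMap(states=np.zeros((3, 3), dtype=np.int8)))]
        with pytest.raises(ValueError, match="no contacts"):
            derive_pair_potential(empty)

    def test_unknown_letter_gets_mean(self):
        table = PairPotentialTable(np.ones((20, 20)))
        assert table.lookup("X", "A") == pytest.approx(1.0)


class TestAssembly:
    def _inputs(self, rng, L):
        target = ProteinRecord("t", "".join(rng.choice(list(AMINO_ACIDS), L)))
        profile = rng.random((L, 20))
        profile /= profile.sum(1, keepdims=True)
        ss3 = rng.random((L, 3))
        ss3 /= ss3.sum(1, keepdims=True)
        acc = rng.random(L)
        coev = rng.random((L, L))
        coev = (coev + coev.T) / 2
        mi = rng.random((L, L))
        mi = (mi + mi.T) / 2
        pot = PairPotentialTable(np.zeros((20, 20)))
        return target, profile, ss3, acc, coev, mi, pot

    def test_channel_count_and_small_shape(self):
        rng = np.random.default_rng(0)
        T = assemble_features(*self._inputs(rng, 2))
        assert T.shape == (2, 2, N_CHANNELS) == (2, 2, 51)

    def test_layout_and_symmetries(self):
        rng = np.random.default_rng(4)
        target, profile, ss3, acc, coev, mi, pot = self._inputs(rng, 9)
        T = assemble_features(target, profile, ss3, acc, coev, mi, pot)
        # 2D channels are symmetric
        for ch in (COEV, MUTUAL_INFO, PAIR_POTENTIAL):
            assert np.array_equal(T[:, :, ch], T[:, :, ch].T)
        # concatenated 1D blocks swap under transposition
        assert np.array_equal(T[:, :, PROFILE_I],
                              T.transpose(1, 0, 2)[:, :, PROFILE_J])
        assert np.array_equal(T[:, :, SS_I], T.transpose(1, 0, 2)[:, :, SS_J])
        assert np.array_equal(T[:, :, ACC_I], T[:, :, ACC_J].T)
        assert np.array_equal(T[3, 5, PROFILE_I], profile[3])
        assert np.array_equal(T[3, 5, PROFILE_J], profile[5])

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        inputs = self._inputs(rng, 6)
        assert np.array_equal(assemble_features(*inputs),
                              assemble_features(*inputs))

    def test_length_mismatch_names_feature(self):
        rng = np.random.default_rng(1)
        target, profile, ss3, acc, coev, mi, pot = self._inputs(rng, 7)
        with pytest.raises(ValueError, match="ss3"):
            assemble_features(target, profile, ss3[:-1], acc, coev, mi, pot)
        with pytest.raises(ValueError, match="coevolution"):
            assemble_features(target, profile, ss3, acc, coev[:-1, :-1], mi, pot)
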