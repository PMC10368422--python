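"""PWM scanning, motif enrichment, sharing matrices and density profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from clonatlas.motifs import (
    MotifPWM,
    density_profile,
    enrich,
    read_pwms,
    scan,
    share_matrix,
    write_pwms_jaspar,
)
from oracles import brute_scan, hypergeom_sf_exact


def deterministic_pwm(consensus: str, name: str = "M") -> MotifPWM:
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 1.0
    return MotifPWM(name, mat)


def soft_pwm(consensus: str, p: float = 0.91, name: str = "M") -> MotifPWM:
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = p
    return MotifPWM(name, mat)


RC = str.maketrans("ACGT", "TGCA")


class TestScan:
    def test_consensus_scores_two_bits_per_position(self):
        pwm = deterministic_pwm("ACGTAC")
        hits = scan("ACGTAC", pwm)
        assert len(hits) == 1
        assert hits.score[0] == pytest.approx(2.0 * 6)

    def test_strand_symmetry(self):
        pwm = soft_pwm("ACGGTACA")
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 300)) + "ACGGTACA"
        rc = seq.translate(RC)[::-1]
        assert len(scan(seq, pwm)) == len(scan(rc, pwm))

    def test_motif_longer_than_sequence_zero_hits(self):
        assert len(scan("ACG", deterministic_pwm("ACGTACGT"))) == 0

    def test_n_bases_score_as_background(self):
        pwm = soft_pwm("ACGG")  # not reverse-complement palindromic
        # an N position contributes 0 bits instead of its match score
        full = scan("ACGG", pwm)
        with_n = scan("ANGG", pwm)
        assert len(full) == 1
        assert len(with_n) == 0 or with_n.score.max() < full.score[0]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_position_by_position_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pwm = soft_pwm("ACGGTA", p=0.7)
        seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        got = sorted(zip(scan(seq, pwm).position, scan(seq, pwm).strand))
        expected = brute_scan(seq, pwm.matrix, pwm.background,
                              pwm.effective_threshold)
        assert got == expected


class TestEnrich:
    def _peaks(self, n, prefix, start=0):
        return pd.DataFrame({
            "chrom": ["chr1"] * n,
            "start": [start + i * 100 for i in range(n)],
            "end": [start + i * 100 + 80 for i in range(n)],
            "peak_id": [f"{prefix}{i}" for i in range(n)],
        })

    def test_extreme_enrichment_equals_exact_tail(self):
        pwm = deterministic_pwm("ACGTACGTAA")
        n_t, n_b = 10, 90
        seq_len = (n_t + n_b) * 100 + 100
        rng = np.random.default_rng(1)
        seq = list("".join(rng.choice(list("CT"), seq_len)))  # no A/G: no chance hits
        tgt = self._peaks(n_t, "t")
        bg = self._peaks(n_b, "b", start=n_t * 100)
        for r in tgt.itertuples(index=False):  # plant in every target peak
            seq[r.start: r.start + 10] = "ACGTACGTAA"
        table = enrich(tgt, bg, {"chr1": "".join(seq)}, [pwm])
        expected = float(hypergeom_sf_exact(10, 100, 10, 10))
        assert table.p_value[0] == pytest.approx(expected, rel=1e-10)

    def test_p_value_equals_scipy_survival_function(self):
        # direct check of the hypergeometric parameterization
        for (N, K, n, k) in [(100, 30, 20, 10), (50, 5, 5, 2), (40, 40, 10, 10)]:
            exact = float(hypergeom_sf_exact(k, N, K, n))
            assert hypergeom.sf(k - 1, N, K, n) == pytest.approx(exact, rel=1e-10)

    def test_empty_target_is_error(self):
        with pytest.raises(ValueError, match="empty target"):
            enrich(self._peaks(0, "t"), self._peaks(5, "b"), {"chr1": "A" * 1000},
                   [deterministic_pwm("ACGT")])

    def test_null_composition_rarely_flagged(self):
        """Identical target/background composition: no BH 0.05 call in >=95% of seeds."""
        pwm = soft_pwm("ACGTTGCA", p=0.85)
        flagged = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            seq = "".join(rng.choice(list("ACGT"), 10_100))
            tgt = self._peaks(20, "t")
            bg = self._peaks(60, "b", start=2_000)
            table = enrich(tgt, bg, {"chr1": seq}, [pwm])
            flagged += int((table.p_adj < 0.05).any())
        assert flagged <= max(1, int(0.05 * n_rep))


class TestShareMatrix:
    def test_known_intersection(self):
        m = share_matrix({"x": {"A", "B", "C"}}, {"y": {"B", "C", "D"}})
        assert m.loc["x", "y"] == 2

    def test_disjoint_zero(self):
        m = share_matrix({"x": {"A"}}, {"y": {"B"}})
        assert m.loc["x", "y"] == 0

    def test_transpose_symmetry_and_brute_force(self):
        rng = np.random.default_rng(3)
        names = [f"M{i}" for i in range(12)]
        A = {f"a{i}": set(rng.choice(names, rng.integers(1, 8), replace=False))
             for i in range(4)}
        B = {f"b{i}": set(rng.choice(names, rng.integers(1, 8), replace=False))
             for i in range(3)}
        ab = share_matrix(A, B)
        ba = share_matrix(B, A)
        pd.testing.assert_frame_equal(ab, ba.T, check_names=False)
        for a, sa in A.items():
            for b, sb in B.items():
                assert ab.loc[a, b] == sum(1 for m in sa if m in sb)


class TestDensityProfile:
    def test_no_hits_all_zero(self):
        pwm = deterministic_pwm("ACGTACGTAC")
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [4_000], "end": [4_500]})
        prof = density_profile(peaks, pwm, {"chr1": "T" * 10_000})
        assert (prof == 0).all()
        assert len(prof) == 100  # 2000 / 20 bins

    def test_integrates_to_hits_per_peak(self):
        pwm = deterministic_pwm("ACGTACGTAC")
        rng = np.random.default_rng(4)
        seq = list("".join(rng.choice(list("CT"), 20_000)))
        starts = [3_000, 8_000, 13_000]
        for s in starts[:2]:  # plant in 2 of 3 windows
            seq[s + 250 - 5: s + 250 + 5] = "ACGTACGTAC"
        peaks = pd.DataFrame({"chrom": ["chr1"] * 3, "start": starts,
                              "end": [s + 500 for s in starts]})
        prof = density_profile(peaks, pwm, {"chr1": "".join(seq)})
        assert prof.sum() == pytest.approx(2 / 3)

    def test_window_must_be_multiple_of_bin(self):
        pwm = deterministic_pwm("ACGT")
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        with pytest.raises(ValueError):
            density_profile(peaks, pwm, {"chr1": "A" * 1000}, window=2000,
                            bin_size=30)


class TestPwmIO:
    def test_jaspar_round_trip(self, tmp_path):
        pwms = [soft_pwm("ACGGTACA", name="MOTIF_A"),
                deterministic_pwm("TTGACA", name="MOTIF_B")]
        path = tmp_path / "lib.jaspar"
        write_pwms_jaspar(pwms, path)
        loaded = read_pwms(path)
        assert [m.name for m in loaded] == ["MOTIF_A", "MOTIF_B"]
        np.testing.assert_allclose(loaded[0].matrix, pwms[0].matrix, atol=1e-3)
        assert loaded[1].consensus == "TTGACA"

    def test_invalid_probability_rows_rejected(self):
        with pytest.raises(ValueError):
            MotifPWM("bad", np.full((4, 4), 0.3))
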