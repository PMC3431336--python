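"""Information vectors, core finding, window scoring, scanning, file I/O."""

import math

import numpy as np
import pytest

from trireg import synthetic
from trireg.errors import ParameterError, UndefinedScoreError
from trireg.pwm import (
    ALPHABET,
    PWM,
    ScanConfig,
    edge_set,
    find_core,
    information_vector,
    predict_tf_targets,
    read_matrix_tsv,
    read_transfac,
    scan_sequence,
    score_window,
    write_transfac,
)


# ---------------------------------------------------------------------------
# Naive all-window re-scorer: the independent oracle
# ---------------------------------------------------------------------------

def naive_info(pwm):
    out = []
    for i in range(pwm.length):
        s = 0.0
        for b in range(4):
            f = pwm.matrix[b, i]
            if f > 0:
                s += f * math.log(4 * f)
        out.append(s)
    return out


def naive_core(pwm):
    info = naive_info(pwm)
    best, best_sum = 0, -1.0
    for off in range(pwm.length - 4):
        s = sum(info[off:off + 5])
        if s > best_sum + 1e-15:
            best, best_sum = off, s
    return best


def naive_score(pwm, window, positions):
    info = naive_info(pwm)
    cur = lo = hi = 0.0
    for i in positions:
        col = [pwm.matrix[b, i] for b in range(4)]
        cur += info[i] * col[ALPHABET.index(window[i])]
        lo += info[i] * min(col)
        hi += info[i] * max(col)
    return (cur - lo) / (hi - lo)


def _revcomp(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def naive_scan(seq, pwm, config):
    """All windows, both strands, pure-python scoring."""
    hits = []
    L = pwm.length
    for strand in ("+", "-") if config.both_strands else ("+",):
        mat = pwm if strand == "+" else pwm.reverse_complement()
        core = naive_core(mat)
        for pos in range(len(seq) - L + 1):
            window = seq[pos:pos + L]
            if "N" in window:
                continue  # "skip" policy
            cs = naive_score(mat, window, range(core, core + 5))
            ms = naive_score(mat, window, range(L))
            if cs >= config.core_threshold and ms >= config.matrix_threshold:
                hits.append((pos, strand, cs, ms))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def random_pwm(rng, length=None):
    length = length or int(rng.integers(5, 13))
    counts = rng.gamma(1.0, 1.0, size=(4, length)) + 0.05
    # Sharpen a random consensus so thresholded hits are possible.
    for i in range(length):
        counts[rng.integers(4), i] += rng.uniform(2, 15)
    return PWM(counts, name=f"R{length}")


def random_seq(rng, length):
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# information_vector / find_core
# ---------------------------------------------------------------------------

class TestInformationVector:
    def test_uniform_column_is_zero(self):
        pwm = PWM(np.ones((4, 3)), pseudocount=0.0)
        assert information_vector(pwm) == pytest.approx([0, 0, 0], abs=1e-12)

    def test_point_mass_is_ln4(self):
        counts = np.zeros((4, 1))
        counts[2, 0] = 10.0
        pwm = PWM(counts, pseudocount=0.0)
        assert information_vector(pwm)[0] == pytest.approx(math.log(4))

    def test_half_half_column_is_ln2(self):
        counts = np.zeros((4, 1))
        counts[0, 0] = counts[1, 0] = 5.0
        pwm = PWM(counts, pseudocount=0.0)
        assert information_vector(pwm)[0] == pytest.approx(math.log(2))

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            info = information_vector(random_pwm(rng))
            assert (info >= 0).all() and (info <= math.log(4) + 1e-12).all()


class TestFindCore:
    def test_length_five_motif(self):
        pwm = synthetic.generate_pwm("ACGTA", concentration=10)
        assert find_core(pwm) == 0

    def test_unique_max_window(self):
        # Informative positions 2..6 of an 8-position matrix.
        counts = np.ones((4, 8))
        for i in range(2, 7):
            counts[0, i] = 1000.0
        assert find_core(PWM(counts)) == 2

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError):
            find_core(synthetic.generate_pwm("ACGT", concentration=10))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_window_oracle(self, seed):
        pwm = random_pwm(np.random.default_rng(seed))
        assert find_core(pwm) == naive_core(pwm)


# ---------------------------------------------------------------------------
# score_window
# ---------------------------------------------------------------------------

class TestScoreWindow:
    def test_consensus_scores_exactly_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pwm = random_pwm(rng)
            assert score_window(pwm, pwm.consensus) == 1.0

    def test_anti_consensus_scores_exactly_zero(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng)
        anti = "".join(ALPHABET[i] for i in np.argmin(pwm.matrix, axis=0))
        assert score_window(pwm, anti) == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        pwm = random_pwm(rng)
        window = random_seq(rng, pwm.length)
        assert score_window(pwm, window) == pytest.approx(
            naive_score(pwm, window, range(pwm.length)), abs=1e-12
        )

    def test_uniform_pwm_is_undefined(self):
        pwm = PWM(np.ones((4, 6)), pseudocount=0.0)
        with pytest.raises(UndefinedScoreError):
            score_window(pwm, "ACGTAC")


# ---------------------------------------------------------------------------
# scan_sequence
# ---------------------------------------------------------------------------

class TestScanSequence:
    def test_planted_consensus_found_at_position(self):
        pwm = synthetic.generate_pwm("ACGTACGTAA", concentration=math.inf)
        seq = "T" * 17 + pwm.consensus + "T" * 20
        hits = scan_sequence(seq, pwm, ScanConfig())
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].position == 17
        assert plus[0].core_score == 1.0 and plus[0].matrix_score == 1.0

    def test_palindrome_hits_both_strands(self):
        pwm = synthetic.generate_pwm("ACGCGT", concentration=math.inf)  # palindromic
        seq = "TTTTT" + "ACGCGT" + "TTTTT"
        hits = scan_sequence(seq, pwm, ScanConfig())
        assert {(h.position, h.strand) for h in hits} == {(5, "+"), (5, "-")}

    def test_windows_with_n_skipped_by_default(self):
        pwm = synthetic.generate_pwm("ACGTACG", concentration=math.inf)
        seq = "ACGTACG".replace("T", "N") + "ACGTACG"
        hits = scan_sequence(seq, pwm, ScanConfig())
        assert all(h.position == 7 for h in hits)

    def test_min_frequency_policy_still_scores_n_windows(self):
        pwm = synthetic.generate_pwm("ACGTACG", concentration=5.0)
        config = ScanConfig(
            core_threshold=0.0, matrix_threshold=0.0,
            ambiguity_policy="min-frequency", both_strands=False,
        )
        hits = scan_sequence("ANGTACG", pwm, config)
        assert len(hits) == 1
        assert hits[0].matrix_score < 1.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        pwm = random_pwm(rng, 8)
        seq = random_seq(rng, 500)
        loose = scan_sequence(seq, pwm, ScanConfig(0.8, 0.8))
        tight = scan_sequence(seq, pwm, ScanConfig(0.9, 0.9))
        loose_keys = {(h.position, h.strand) for h in loose}
        tight_keys = {(h.position, h.strand) for h in tight}
        assert tight_keys <= loose_keys

    def test_strand_convention_mirror(self):
        # Scanning the reverse complement with the same PWM mirrors hits.
        rng = np.random.default_rng(8)
        pwm = random_pwm(rng, 7)
        seq = random_seq(rng, 300)
        config = ScanConfig(0.85, 0.85)
        fwd = scan_sequence(seq, pwm, config)
        rev = scan_sequence(_revcomp(seq), pwm, config)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (len(seq) - h.position - pwm.length, flip[h.strand]) for h in rev
        }
        assert {(h.position, h.strand) for h in fwd} == mirrored

    @pytest.mark.parametrize("thresholds", [(1.0, 0.95), (0.85, 0.8)])
    def test_matches_naive_all_window_scorer(self, thresholds):
        rng = np.random.default_rng(11)
        config = ScanConfig(*thresholds)
        for _ in range(60):
            pwm = random_pwm(rng)
            seq = random_seq(rng, 200)
            got = [
                (h.position, h.strand, h.core_score, h.matrix_score)
                for h in scan_sequence(seq, pwm, config)
            ]
            expected = naive_scan(seq, pwm, config)
            assert [(p, s) for p, s, *_ in got] == [(p, s) for p, s, *_ in expected]
            for g, e in zip(got, expected):
                assert g[2] == pytest.approx(e[2], abs=1e-12)
                assert g[3] == pytest.approx(e[3], abs=1e-12)


# ---------------------------------------------------------------------------
# predict_tf_targets
# ---------------------------------------------------------------------------

class TestPredictTargets:
    def test_no_promoters_no_edges(self):
        pwm = synthetic.generate_pwm("ACGTACGT", concentration=10)
        out = predict_tf_targets({}, {pwm.name: pwm}, {"TF1": [pwm.name]})
        assert out.empty

    def test_planted_consensus_edges_recovered(self, small_world):
        out = predict_tf_targets(
            small_world.promoters, small_world.pwms,
            small_world.tf_to_matrix, ScanConfig(),
        )
        edges = edge_set(out)
        planted = small_world.ground_truth.planted_pairs
        assert planted <= edges

    def test_stricter_matrix_threshold_shrinks_edges(self, small_world):
        loose = edge_set(
            predict_tf_targets(
                small_world.promoters, small_world.pwms,
                small_world.tf_to_matrix, ScanConfig(1.0, 0.95),
            )
        )
        tight = edge_set(
            predict_tf_targets(
                small_world.promoters, small_world.pwms,
                small_world.tf_to_matrix, ScanConfig(1.0, 1.0),
            )
        )
        assert tight <= loose

    def test_unmapped_tf_rejected(self):
        with pytest.raises(ParameterError):
            predict_tf_targets({"g": "ACGT"}, {}, {"TF1": []})


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

class TestMatrixIO:
    def test_transfac_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        pwms = [random_pwm(rng, 6), random_pwm(rng, 9)]
        path = tmp_path / "lib.transfac"
        write_transfac(pwms, path)
        back = read_transfac(path)
        assert set(back) == {p.name for p in pwms}
        for p in pwms:
            assert np.allclose(back[p.name].counts, p.counts, atol=1e-4)

    def test_matrix_tsv_reader(self, tmp_path):
        path = tmp_path / "m.tsv"
        lines = ["matrix\tposition\tA\tC\tG\tT"]
        for i, row in enumerate([(10, 1, 1, 1), (1, 10, 1, 1)], start=1):
            lines.append("M1\t%d\t%d\t%d\t%d\t%d" % (i, *row))
        path.write_text("\n".join(lines) + "\n")
        pwms = read_matrix_tsv(path)
        assert pwms["M1"].consensus == "AC"
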