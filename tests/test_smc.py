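"""Sequential Monte Carlo motif discovery."""

import math

import numpy as np
import pytest

from regulonkit.core import BASES, encode, revcomp
from regulonkit.motif import block_dissimilarity
from regulonkit.simulate import make_pwm, make_planted_sequences
from regulonkit.smc import (
    SMCParams,
    discover_motif,
    estimate_width,
    export_particle,
    max_weight_particle,
    posterior_mean_theta,
    run_family,
    site_posteriors,
    smc_init,
    smc_step,
)

UNIFORM = np.full(4, 0.25)


def seq_ids(seqs):
    return [s for s, _ in seqs]


class TestInit:
    def test_population_shape_and_uniform_weights(self):
        st = smc_init(10, 500, SMCParams(n_particles=500), seed=0)
        assert st.counts.shape == (500, 10, 4)
        np.testing.assert_allclose(st.weights, 1 / 500)
        assert st.offsets == []

    def test_prior_pwm_pseudocounts_column_sums(self):
        prior = make_pwm(10, "palindromic", 0.8, seed=1).theta
        st = smc_init(10, 50, prior_theta=prior, prior_strength=10.0, seed=0)
        np.testing.assert_allclose(st.counts[0].sum(axis=1), 10.0)
        np.testing.assert_allclose(st.nsites, 10.0)

    def test_same_seed_same_stream(self):
        a = smc_init(8, 10, seed=42).rng.random(5)
        b = smc_init(8, 10, seed=42).rng.random(5)
        np.testing.assert_array_equal(a, b)

    def test_mismatched_prior_width_rejected(self):
        with pytest.raises(ValueError):
            smc_init(8, 10, prior_theta=np.full((10, 4), 0.25), seed=0)


class TestStep:
    def test_weights_sum_to_one_after_each_step(self, planted16):
        _, seqs, _ = planted16
        params = SMCParams(n_particles=200)
        st = smc_init(16, 200, params, seed=0)
        for _, seq in seqs[:5]:
            smc_step(st, seq)
            assert st.weights.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(st.weights >= 0)

    def test_systematic_resample_restores_full_ess(self):
        st = smc_init(8, 100, SMCParams(n_particles=100), seed=1)
        smc_step(st, "ACGTACGTACGTACGT")
        st.weights = np.zeros(100)
        st.weights[:3] = [0.5, 0.3, 0.2]
        st._systematic_resample()
        assert st.ess() == pytest.approx(100.0)
        np.testing.assert_allclose(st.weights, 0.01)

    def test_zero_presence_prior_places_nothing(self):
        params = SMCParams(n_particles=100, pi=0.0)
        st = smc_init(8, 100, params, seed=2)
        for seq in ("ACGTACGTACGT", "TTTTACGTACGT"):
            smc_step(st, seq)
        assert all((off == -1).all() for off in st.offsets)

    def test_sequence_shorter_than_width_forced_absent(self):
        params = SMCParams(n_particles=50)
        st = smc_init(8, 50, params, seed=3)
        smc_step(st, "ACGT")
        assert (st.offsets[0] == -1).all()

    def test_deterministic_under_seed(self, planted16):
        _, seqs, _ = planted16
        params = SMCParams(n_particles=100)
        runs = []
        for _ in range(2):
            st = smc_init(16, 100, params, seed=11)
            for _, seq in seqs[:6]:
                smc_step(st, seq)
            runs.append((np.array(st.offsets), st.weights.copy()))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        np.testing.assert_allclose(runs[0][1], runs[1][1])


def oracle_joint_posterior(seqs, w, params):
    """Exhaustive enumeration of the sequential two-sequence joint model.

    Candidate priors, Dirichlet-multinomial likelihood ratios, and the
    two-block symmetry factor are recomputed here with plain Python
    arithmetic, independently of the sampler's vectorised path.
    """
    alpha, pi, lam = params.alpha, params.pi, params.lam_sym
    bg = params.background
    c = w // 2

    def candidates(seq):
        L = len(seq)
        cands = [None]
        for o in range(L - w + 1):
            cands.append((o, "+"))
            cands.append((o, "-"))
        return cands

    def word_of(seq, cand):
        o, s = cand
        word = seq[o : o + w]
        return revcomp(word) if s == "-" else word

    def dmin_bits(counts, n):
        theta = [
            [(counts[j][b] + alpha) / (n + 4 * alpha) for b in range(4)]
            for j in range(w)
        ]
        best = None
        for sym in ("palindromic", "direct_repeat", "inverted_repeat"):
            total = 0.0
            for j in range(c):
                p = theta[j]
                if sym == "palindromic":
                    q = [theta[w - 1 - j][3 - b] for b in range(4)]
                elif sym == "direct_repeat":
                    q = theta[w - c + j]
                else:
                    q = theta[w - 1 - j]
                total += sum(
                    (p[b] - q[b]) * (math.log2(p[b]) - math.log2(q[b]))
                    for b in range(4)
                )
            d = total / (2 * c)
            best = d if best is None else min(best, d)
        return best

    def factor(counts, n, seq, cand):
        mv = len(seq) - w + 1
        if cand is None:
            prior = 1 - pi
            lik = 1.0
            d = dmin_bits(counts, n)
        else:
            prior = pi / (2 * mv)
            word = word_of(seq, cand)
            codes = [BASES.index(ch) for ch in word]
            lik = 1.0
            for j, b in enumerate(codes):
                lik *= (counts[j][b] + alpha) / (n + 4 * alpha) / bg[b]
            new = [row[:] for row in counts]
            for j, b in enumerate(codes):
                new[j][b] += 1
            d = dmin_bits(new, n + 1)
        return prior * lik * math.exp(-lam * d)

    def updated(counts, n, seq, cand):
        if cand is None:
            return counts, n
        new = [row[:] for row in counts]
        for j, ch in enumerate(word_of(seq, cand)):
            new[j][BASES.index(ch)] += 1
        return new, n + 1

    zero = [[0.0] * 4 for _ in range(w)]
    joint = {}
    for c1 in candidates(seqs[0]):
        f1 = factor(zero, 0.0, seqs[0], c1)
        counts1, n1 = updated(zero, 0.0, seqs[0], c1)
        for c2 in candidates(seqs[1]):
            f2 = factor(counts1, n1, seqs[1], c2)
            joint[(c1, c2)] = f1 * f2
    total = sum(joint.values())
    return {k: v / total for k, v in joint.items()}


def smc_joint_distribution(seqs, w, params, seed):
    st = smc_init(w, params.n_particles, params, seed=seed)
    for seq in seqs:
        smc_step(st, seq)
    dist = {}
    for i in range(st.n):
        key = []
        for off, strd in zip(st.offsets, st.strands):
            if off[i] < 0:
                key.append(None)
            else:
                key.append((int(off[i]), "+-"[int(strd[i])]))
        key = tuple(key)
        dist[key] = dist.get(key, 0.0) + float(st.weights[i])
    return dist


class TestOracleEquivalence:
    def test_two_sequence_posterior_matches_enumeration(self):
        """SMC placement posterior vs exhaustive enumeration (small n)."""
        seqs = ["ACGTTGCACGTA", "TTGCACGTAAGT"]
        params = SMCParams(n_particles=20000, pi=0.8)
        oracle = oracle_joint_posterior(seqs, 8, params)
        got = smc_joint_distribution(seqs, 8, params, seed=12)
        keys = set(oracle) | set(got)
        tv = 0.5 * sum(abs(oracle.get(k, 0.0) - got.get(k, 0.0)) for k in keys)
        assert tv <= 0.08


class TestEstimateWidth:
    def test_single_width_forced(self, planted16):
        _, seqs, _ = planted16
        params = SMCParams(n_particles=100)
        table, best, _ = estimate_width(
            [s for _, s in seqs[:6]], [14], params, seed=0
        )
        assert best == 14
        assert len(table) == 1

    def test_table_has_one_row_per_width(self, planted16):
        _, seqs, _ = planted16
        params = SMCParams(n_particles=60)
        table, best, _ = estimate_width(
            [s for _, s in seqs[:5]], [12, 14, 16], params, seed=0
        )
        assert [row[0] for row in table] == [12, 14, 16]
        assert best in {12, 14, 16}

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            estimate_width(["ACGTACGTACGTACGT"], [], SMCParams(), seed=0)


class TestDiscoverMotif:
    def test_uniform_background_yields_no_or_weak_motif(self):
        seqs, _ = make_planted_sequences(8, 200, pwm=None, seed=9)
        params = SMCParams(n_particles=200)
        res = discover_motif(seqs, params=params, seed=9, w_range=[12, 16])
        assert (
            res.status == "no motif found"
            or res.motif.information_content() < 8.0
        )

    def test_requires_minimum_sequences(self):
        seqs, _ = make_planted_sequences(3, 100, pwm=None, seed=1)
        with pytest.raises(ValueError):
            discover_motif(seqs, params=SMCParams(n_particles=50), seed=0)

    def test_presence_prior_zero_reports_no_motif(self, planted16):
        _, seqs, _ = planted16
        params = SMCParams(n_particles=100, pi=0.0)
        res = discover_motif(seqs[:6], params=params, seed=0, w_range=[16])
        assert res.status == "no motif found"

    def test_prior_pwm_does_not_hurt_site_recall(self, planted16):
        pwm, seqs, truth = planted16
        params = SMCParams(n_particles=300)
        truth_offs = {s[0]: s[2] for s in truth.site_loci}

        def recall(res):
            hit = sum(
                1
                for sid, off, _strand, _p in res.site_calls
                if sid in truth_offs and off is not None
                and abs(off - truth_offs[sid]) <= 3
            )
            return hit / len(truth_offs)

        plain = discover_motif(seqs, params=params, seed=5, w_range=[16])
        primed = discover_motif(
            seqs, params=params, prior_theta=pwm.theta, prior_strength=20.0,
            seed=5, w_range=[16],
        )
        assert recall(primed) >= recall(plain)

    def test_lambda_zero_disables_symmetry_prior(self, planted16):
        _, seqs, _ = planted16
        params = SMCParams(n_particles=150, lam_sym=0.0)
        res = discover_motif(seqs[:8], params=params, seed=3, w_range=[16])
        assert res.status in {"ok", "no motif found"}

    def test_site_posteriors_are_probabilities(self, planted16):
        _, seqs, _ = planted16
        params = SMCParams(n_particles=150)
        res = discover_motif(seqs[:8], params=params, seed=4, w_range=[16])
        for _sid, _off, _strand, prob in res.site_calls:
            assert 0.0 <= prob <= 1.0


def test_export_particle_counts_match_placements(planted16):
    _, seqs, _ = planted16
    params = SMCParams(n_particles=100)
    st = run_family([s for _, s in seqs[:6]], 16, params, seed=2)
    p = export_particle(st, max_weight_particle(st))
    n_placed = sum(1 for pl in p.placements if pl is not None)
    np.testing.assert_allclose(p.counts.sum(axis=1), n_placed)
    assert p.w == 16
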