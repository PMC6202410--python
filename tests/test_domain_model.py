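"""The three-level domain-model simulator and its Markov machinery."""

import numpy as np
import pytest
from scipy import stats

from dnasym.domain_model import (
    M_I,
    M_II,
    DomainModelConfig,
    MarkovProcess,
    generate_chunk,
    generate_genome,
    generate_macrostructure,
    second_eigenvalue_modulus,
    stationary_distribution,
)

# the shipped transition matrices, frozen entry-for-entry (rows/cols A,C,G,T)
M_I_LITERAL = [
    [0.2, 0.1, 0.2, 0.5],
    [0.01, 0.84, 0.01, 0.14],
    [0.4, 0.1, 0.4, 0.1],
    [0.3, 0.15, 0.25, 0.3],
]
M_II_LITERAL = [
    [0.1, 0.2, 0.1, 0.6],
    [0.1, 0.75, 0.1, 0.05],
    [0.1, 0.4, 0.1, 0.4],
    [0.1, 0.35, 0.45, 0.1],
]


def dinuc_freqs(codes: np.ndarray) -> np.ndarray:
    counts = np.zeros((4, 4))
    np.add.at(counts, (codes[:-1], codes[1:]), 1)
    return counts / counts.sum()


class TestStationaryDistribution:
    def test_uniform_matrix(self):
        mu = stationary_distribution(np.full((4, 4), 0.25))
        assert mu == pytest.approx([0.25] * 4)

    def test_shipped_matrices_violate_chargaff(self):
        for M in (M_I, M_II):
            mu = stationary_distribution(M)
            assert mu @ M == pytest.approx(mu, abs=1e-10)
            assert mu.sum() == pytest.approx(1.0)
            assert abs(mu[0] - mu[3]) > 0.01  # mu(A) != mu(T)
            assert abs(mu[1] - mu[2]) > 0.01  # mu(C) != mu(G)

    def test_identity_matrix_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.eye(4))

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.full((4, 4), 0.3))


class TestShippedMatrices:
    def test_printed_fidelity(self):
        assert np.array_equal(M_I, np.array(M_I_LITERAL))
        assert np.array_equal(M_II, np.array(M_II_LITERAL))
        assert M_I.sum(axis=1) == pytest.approx([1, 1, 1, 1], abs=1e-12)
        assert M_II.sum(axis=1) == pytest.approx([1, 1, 1, 1], abs=1e-12)

    def test_mixing_proxy_in_unit_interval(self):
        for M in (M_I, M_II):
            assert 0 < second_eigenvalue_modulus(M) < 1


class TestGenerateChunk:
    def test_length_one_matches_stationary(self, rng):
        p = MarkovProcess.from_matrix(M_I)
        draws = np.array([generate_chunk(p, 1, rng).codes[0] for _ in range(10_000)])
        observed = np.bincount(draws, minlength=4)
        res = stats.chisquare(observed, 10_000 * p.stationary)
        assert res.pvalue > 1e-3

    def test_deterministic_matrix_gives_cycle(self, rng):
        M = np.zeros((4, 4))
        for i in range(4):
            M[i, (i + 1) % 4] = 1.0
        p = MarkovProcess.from_matrix(M)
        codes = generate_chunk(p, 20, rng).codes.astype(int)
        assert all((b - a) % 4 == 1 for a, b in zip(codes[:-1], codes[1:]))

    def test_dinucleotide_frequencies_match_closed_form(self, rng):
        p = MarkovProcess.from_matrix(M_I)
        codes = generate_chunk(p, 100_000, rng).codes
        expected = p.stationary[:, None] * M_I
        observed = dinuc_freqs(codes)
        se = np.sqrt(expected * (1 - expected) / (len(codes) - 1))
        assert (np.abs(observed - expected) < 5 * np.maximum(se, 1e-12)).all()

    def test_bad_length_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_chunk(MarkovProcess.from_matrix(M_I), 0, rng)


class TestReverseComplementProcess:
    def test_hat_process_structure(self):
        p = MarkovProcess.from_matrix(M_I)
        q = p.reverse_complement()
        assert q.matrix.sum(axis=1) == pytest.approx([1, 1, 1, 1])
        # stationary law maps through the complement: mu_hat(x) = mu(comp(x))
        assert q.stationary == pytest.approx(p.stationary[::-1])


class TestGenerateMacrostructure:
    CFG = DomainModelConfig(macrostructure_length=200_000)

    def test_whole_chunks_and_target_overshoot(self, rng):
        p = MarkovProcess.from_matrix(M_I)
        seq, log = generate_macrostructure(p, self.CFG, rng)
        lengths = [l for l, _ in log]
        assert sum(lengths) == len(seq)
        assert 200_000 <= len(seq) < 200_000 + 170
        assert all(130 <= l <= 170 for l in lengths)
        # dropping the last chunk leaves the total below target
        assert sum(lengths[:-1]) < 200_000

    def test_mirrored_fraction_near_half(self, rng):
        p = MarkovProcess.from_matrix(M_I)
        cfg = DomainModelConfig(macrostructure_length=10**6)
        _, log = generate_macrostructure(p, cfg, rng)
        flips = np.array([m for _, m in log])
        se = 0.5 / np.sqrt(len(flips))
        assert abs(flips.mean() - 0.5) < 3 * se

    def test_chunk_lengths_uniform(self, rng):
        p = MarkovProcess.from_matrix(M_I)
        cfg = DomainModelConfig(macrostructure_length=1_600_000)
        _, log = generate_macrostructure(p, cfg, rng)
        lengths = np.array([l for l, _ in log])
        assert len(lengths) > 10_000
        observed = np.bincount(lengths - 130, minlength=41)
        res = stats.chisquare(observed)
        assert res.pvalue > 0.01

    @pytest.mark.parametrize("prob,conjugate", [(0.0, False), (1.0, True)])
    def test_orientation_extremes_match_closed_forms(self, rng, prob, conjugate):
        """p_rc = 0 reproduces p's dinucleotide law; p_rc = 1 reproduces the
        reverse-complement process p-hat (hat-conjugated closed form)."""
        p = MarkovProcess.from_matrix(M_I)
        cfg = DomainModelConfig(macrostructure_length=400_000, revcomp_probability=prob)
        seq, log = generate_macrostructure(p, cfg, rng)
        assert all(m == conjugate for _, m in log)
        ref = p.reverse_complement() if conjugate else p
        expected = ref.stationary[:, None] * ref.matrix
        observed = dinuc_freqs(seq.codes)
        # chunk junctions perturb ~1/150 of windows; allow 5 SE + junction slack
        se = np.sqrt(expected * (1 - expected) / len(seq))
        assert (np.abs(observed - expected) < 5 * se + 2 / 150).all()


class TestGenerateGenome:
    def test_default_structure(self):
        genome, gt = generate_genome(DomainModelConfig(seed=3))
        assert 2_000_000 <= genome.N < 2_000_000 + 2 * 170
        assert genome.is_clean()
        assert gt["boundaries"][0] == 0 and gt["boundaries"][-1] == genome.N
        assert len(gt["chunk_logs"]) == 2
        assert gt["scales"]["L_S"] == 300
        assert gt["scales"]["L_M"] == 10**6
        assert all(0 < s < 1 for s in gt["scales"]["slem"])

    def test_reproducible_and_seed_sensitive(self):
        g1, _ = generate_genome(DomainModelConfig(seed=9, macrostructure_length=50_000))
        g2, _ = generate_genome(DomainModelConfig(seed=9, macrostructure_length=50_000))
        g3, _ = generate_genome(DomainModelConfig(seed=10, macrostructure_length=50_000))
        assert g1.symbols == g2.symbols
        assert g1.symbols != g3.symbols

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chunk_length_range": (0, 10)},
            {"chunk_length_range": (50, 40)},
            {"revcomp_probability": 1.5},
            {"matrices": ()},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DomainModelConfig(**kwargs)
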