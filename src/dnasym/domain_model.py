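"""Three-level domain model: a generative DNA simulator with known symmetry.

The model mimics the mosaic organisation of real chromosomes and, by
construction, the nested symmetry hierarchy:

1. *Domains*: order-1 Markov chains over [A, C, G, T] whose stationary
   distributions deliberately violate Chargaff's rule (mu(A) != mu(T),
   mu(C) != mu(G)), so that a single domain carries no reverse-complement
   symmetry.  The exponential decay of Markov correlations sets the domain
   correlation scale L_D (about 10 bp for the shipped matrices).
2. *Macrostructures*: chunks with length uniform in [130, 170] (mean 150)
   are drawn from one process and, with probability 1/2 each, reverse
   complemented before concatenation — the in-silico analogue of mobile
   elements inserting on either strand.  Same-orientation runs are
   geometric with mean 2 chunks, so the same-type cluster scale is
   L_S ~ 2 * 150 = 300 bp.  Chunks accumulate until the macrostructure
   reaches its target length L_M ~ 1e6.
3. *Genome*: macrostructures generated by different matrices (shipped
   M_I and M_II, analogous to isochores of different composition) are
   concatenated.

All randomness flows from one numpy Generator: a macrostructure draws the
chunk lengths first, then the orientations, then the symbols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import Sequence

#: transition matrices of the two shipped domain processes, rows/cols [A,C,G,T]
M_I = np.array(
    [
        [0.2, 0.1, 0.2, 0.5],
        [0.01, 0.84, 0.01, 0.14],
        [0.4, 0.1, 0.4, 0.1],
        [0.3, 0.15, 0.25, 0.3],
    ]
)

M_II = np.array(
    [
        [0.1, 0.2, 0.1, 0.6],
        [0.1, 0.75, 0.1, 0.05],
        [0.1, 0.4, 0.1, 0.4],
        [0.1, 0.35, 0.45, 0.1],
    ]
)


def stationary_distribution(M: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Unique left fixed probability vector of a row-stochastic matrix.

    Raises ``ValueError`` when the chain has no unique stationary
    distribution (e.g. a reducible matrix such as the identity).
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4) or (M < 0).any() or not np.allclose(M.sum(axis=1), 1, atol=1e-12):
        raise ValueError("M must be a 4x4 row-stochastic matrix")
    eigvals, eigvecs = np.linalg.eig(M.T)
    at_one = np.abs(eigvals - 1.0) < tol
    if at_one.sum() != 1:
        raise ValueError("no unique stationary distribution (reducible chain?)")
    mu = np.real(eigvecs[:, np.argmax(at_one)])
    mu = mu / mu.sum()
    if (mu < -tol).any():
        raise ValueError("stationary vector not nonnegative")
    return np.clip(mu, 0.0, None) / np.clip(mu, 0.0, None).sum()


def second_eigenvalue_modulus(M: np.ndarray) -> float:
    """Modulus of the second-largest eigenvalue: the Markov mixing proxy
    for the domain correlation scale L_D (decay length -1/ln(slem))."""
    eigvals = np.sort(np.abs(np.linalg.eigvals(M)))[::-1]
    return float(eigvals[1])


@dataclass(frozen=True, eq=False)
class MarkovProcess:
    """An order-1 nucleotide process: transition matrix plus stationary law."""

    matrix: np.ndarray
    stationary: np.ndarray

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "MarkovProcess":
        M = np.array(M, dtype=float)
        M.setflags(write=False)
        mu = stationary_distribution(M)
        mu.setflags(write=False)
        return cls(M, mu)

    def reverse_complement(self) -> "MarkovProcess":
        """The process generating reverse-complemented realizations.

        With complement map c(A)=T etc. (code c(x) = 3 - x), a realization of
        this process read backwards and complemented is a realization of the
        chain  M_hat[x, y] = mu(c(y)) M[c(y), c(x)] / mu(c(x)),  whose
        stationary law is mu_hat(x) = mu(c(x)).
        """
        M, mu = self.matrix, self.stationary
        comp = np.array([3, 2, 1, 0])
        M_hat = np.empty_like(M)
        for x in range(4):
            for y in range(4):
                M_hat[x, y] = mu[comp[y]] * M[comp[y], comp[x]] / mu[comp[x]]
        return MarkovProcess.from_matrix(M_hat)


@dataclass(frozen=True, eq=False)
class DomainModelConfig:
    """All simulator parameters.

    Defaults are the reference study conditions: processes M_I and M_II,
    chunk lengths uniform in [130, 170], reverse-complement probability 1/2,
    macrostructures of 1e6 bp.
    """

    matrices: tuple = (M_I, M_II)
    chunk_length_range: tuple[int, int] = (130, 170)
    revcomp_probability: float = 0.5
    macrostructure_length: int = 10**6
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.chunk_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid chunk_length_range")
        if not 0.0 <= self.revcomp_probability <= 1.0:
            raise ValueError("revcomp_probability must be in [0, 1]")
        if len(self.matrices) < 1:
            raise ValueError("need at least one process matrix")

    @property
    def processes(self) -> tuple[MarkovProcess, ...]:
        return tuple(MarkovProcess.from_matrix(M) for M in self.matrices)


def _sample_start(mu: np.ndarray, u: float) -> int:
    return int(np.searchsorted(np.cumsum(mu), u, side="right"))


def generate_chunk(p: MarkovProcess, length: int, rng: np.random.Generator) -> Sequence:
    """One realization of the process: first symbol from mu, then M rows."""
    if length < 1:
        raise ValueError("length must be >= 1")
    cum = np.cumsum(p.matrix, axis=1)
    rows = [tuple(cum[i, :3]) for i in range(4)]
    us = rng.random(length).tolist()
    out = bytearray(length)
    s = _sample_start(p.stationary, us[0])
    out[0] = s
    for i in range(1, length):
        u = us[i]
        r = rows[s]
        if u < r[0]:
            s = 0
        elif u < r[1]:
            s = 1
        elif u < r[2]:
            s = 2
        else:
            s = 3
        out[i] = s
    return Sequence.from_codes(np.frombuffer(bytes(out), dtype=np.uint8))


def _batch_chunks(p: MarkovProcess, lengths: np.ndarray,
                  rng: np.random.Generator) -> list[np.ndarray]:
    """Independent chunk realizations, generated column-parallel.

    One uniform matrix of shape (n_chunks, max_length) is drawn; chunk i
    uses the first lengths[i] columns of row i.
    """
    n, max_len = len(lengths), int(lengths.max())
    u = rng.random((n, max_len))
    cum = np.cumsum(p.matrix, axis=1)[:, :3]
    states = np.empty((n, max_len), dtype=np.uint8)
    states[:, 0] = np.searchsorted(np.cumsum(p.stationary), u[:, 0], side="right")
    for j in range(1, max_len):
        states[:, j] = (u[:, j, None] > cum[states[:, j - 1]]).sum(axis=1)
    return [states[i, : lengths[i]] for i in range(n)]


def generate_macrostructure(p: MarkovProcess, config: DomainModelConfig,
                            rng: np.random.Generator):
    """Concatenate reverse-complement-mirrored chunks up to the target length.

    Chunks are independent realizations of ``p`` (each starts fresh from the
    stationary law); each is reverse complemented with probability
    ``config.revcomp_probability`` before concatenation.  Generation stops at
    the first chunk whose addition reaches or exceeds
    ``config.macrostructure_length``, so whole chunks are kept and the final
    length lies in [L_M, L_M + max_chunk).  Returns the sequence and a chunk
    log (list of (length, mirrored) tuples) for ground-truth checks.
    """
    lo, hi = config.chunk_length_range
    target = config.macrostructure_length
    n_max = target // lo + 2
    lengths = rng.integers(lo, hi + 1, size=n_max)
    total = np.cumsum(lengths)
    n_chunks = int(np.searchsorted(total, target, side="left")) + 1
    n_chunks = min(n_chunks, n_max)
    lengths = lengths[:n_chunks]
    mirrored = rng.random(n_chunks) < config.revcomp_probability
    chunks = _batch_chunks(p, lengths, rng)
    parts = [3 - c[::-1] if m else c for c, m in zip(chunks, mirrored)]
    codes = np.concatenate(parts).astype(np.uint8)
    chunk_log = [(int(l), bool(m)) for l, m in zip(lengths, mirrored)]
    return Sequence.from_codes(codes), chunk_log


def generate_genome(config: DomainModelConfig):
    """One macrostructure per configured process, concatenated in order.

    Returns the genome and a ground-truth dict with macrostructure
    boundaries, per-macrostructure chunk logs, and the model scales: the
    second-eigenvalue mixing proxy for L_D, the cluster scale
    L_S = 2 * mean chunk length, and L_M = macrostructure_length.
    """
    rng = np.random.default_rng(config.seed)
    parts, logs, boundaries = [], [], [0]
    for p in config.processes:
        seq, chunk_log = generate_macrostructure(p, config, rng)
        parts.append(seq.codes)
        logs.append(chunk_log)
        boundaries.append(boundaries[-1] + len(seq))
    genome = Sequence.from_codes(np.concatenate(parts), label=f"domain-model-seed{config.seed}")
    lo, hi = config.chunk_length_range
    slems = [second_eigenvalue_modulus(M) for M in config.matrices]
    ground_truth = {
        "boundaries": boundaries,
        "chunk_logs": logs,
        "seed": config.seed,
        "scales": {
            "slem": slems,
            "L_D": [-1.0 / np.log(s) if 0 < s < 1 else float("inf") for s in slems],
            "L_S": 2 * (lo + hi) / 2,
            "L_M": config.macrostructure_length,
        },
    }
    return genome, ground_truth
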