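"""Self-supervised corruption of the denoised matrix.

Each gene's values are shuffled independently across cells (preserving every
per-gene marginal), a Bernoulli mask with per-gene probability p_j selects
which entries to replace, and the corrupted matrix is composed elementwise:

    X_M = X′ ⊙ M + X_z ⊙ (1 − M)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MaskedBatch:
    corrupted: np.ndarray        # X_M
    true_mask: np.ndarray        # M, binary, 1 = entry replaced
    shuffled_source: np.ndarray  # X′
    mask_probs: np.ndarray       # per-gene p_j

    def __post_init__(self) -> None:
        if not (self.corrupted.shape == self.true_mask.shape
                == self.shuffled_source.shape):
            raise ValueError("MaskedBatch component shapes must match")


def shuffle_within_genes(Xz: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each gene column independently across cells."""
    Xz = np.asarray(Xz)
    out = np.empty_like(Xz)
    n = Xz.shape[0]
    for j in range(Xz.shape[1]):
        out[:, j] = Xz[rng.permutation(n), j]
    return out


def sample_mask(shape: tuple[int, int], p, rng: np.random.Generator) -> np.ndarray:
    """Binary mask with independent Bernoulli(p_j) draws in column j.

    `p` may be a scalar or a per-gene vector of length shape[1].
    """
    p = np.broadcast_to(np.asarray(p, dtype=float), (shape[1],))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("mask probabilities must lie in [0, 1]")
    return (rng.random(shape) < p[None, :]).astype(float)


def compose_masked(X_prime: np.ndarray, Xz: np.ndarray,
                   M: np.ndarray) -> np.ndarray:
    """Elementwise composition X_M = X′⊙M + X_z⊙(1−M)."""
    X_prime, Xz, M = (np.asarray(a) for a in (X_prime, Xz, M))
    if not (X_prime.shape == Xz.shape == M.shape):
        raise ValueError("shapes must match")
    if not np.all((M == 0) | (M == 1)):
        raise ValueError("mask must be binary")
    return X_prime * M + Xz * (1.0 - M)


def corrupt(Xz: np.ndarray, mask_probs, rng: np.random.Generator) -> MaskedBatch:
    """Draw one full corruption: shuffle, mask, compose."""
    Xz = np.asarray(Xz, dtype=float)
    X_prime = shuffle_within_genes(Xz, rng)
    p = np.broadcast_to(np.asarray(mask_probs, dtype=float), (Xz.shape[1],))
    M = sample_mask(Xz.shape, p, rng)
    return MaskedBatch(corrupted=compose_masked(X_prime, Xz, M),
                       true_mask=M, shuffled_source=X_prime, mask_probs=p)
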