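"""Equal-rates amino-acid substitution model.

The placement likelihood and the sequence simulator share one model: a
Poisson-type (20-state Jukes--Cantor-like) process with equal
exchangeabilities and uniform stationary frequencies.  Branch lengths are
measured in expected substitutions per site, so with substitution rate
``alpha`` off-diagonal and ``19*alpha`` total leaving rate, time is scaled
by ``alpha = 1/19``:

    P(same,  t) = 1/20 + (19/20) * exp(-lambda * t)
    P(other, t) = 1/20 - (1/20)  * exp(-lambda * t)

with ``lambda = 20/19``.  The closed form keeps the per-edge placement
likelihood cheap (no eigendecompositions) and makes an exact brute-force
oracle easy to write.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_STATES = 20
GAP_CODE = -1

# lambda in the closed-form transition probability
_LAM = N_STATES / (N_STATES - 1.0)

_AA_TO_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_aa(seq: str) -> np.ndarray:
    """Encode an amino-acid string as integer states; gaps/unknowns -> -1."""
    return np.array([_AA_TO_CODE.get(c, GAP_CODE) for c in seq.upper()],
                    dtype=np.int64)


def decode_aa(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[c] if c >= 0 else "-" for c in codes)


def p_same(t: np.ndarray | float) -> np.ndarray | float:
    """Probability of observing the same residue after branch length t."""
    return 1.0 / N_STATES + (N_STATES - 1.0) / N_STATES * np.exp(-_LAM * t)


def p_diff(t: np.ndarray | float) -> np.ndarray | float:
    """Probability of one specific different residue after branch length t."""
    return 1.0 / N_STATES - 1.0 / N_STATES * np.exp(-_LAM * t)


def transition_matrix(t: float) -> np.ndarray:
    """Full 20x20 transition-probability matrix P(t)."""
    P = np.full((N_STATES, N_STATES), p_diff(t))
    np.fill_diagonal(P, p_same(t))
    return P


def evolve_states(states: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve integer state array along a branch of length t (vectorized).

    Each site independently stays with probability p_same(t); otherwise it
    jumps to one of the 19 other states uniformly.
    """
    out = states.copy()
    stay = 1.0 / N_STATES + (N_STATES - 1.0) / N_STATES * np.exp(-_LAM * t)
    change = rng.random(states.shape) >= stay
    n_change = int(change.sum())
    if n_change:
        # uniform over the 19 non-identical states
        shift = rng.integers(1, N_STATES, size=n_change)
        out[change] = (out[change] + shift) % N_STATES
    return out


def stationary_states(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. states from the (uniform) stationary distribution."""
    return rng.integers(0, N_STATES, size=n)
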