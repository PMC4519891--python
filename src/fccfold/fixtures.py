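"""Synthetic test data: random sequences and random lattice walks.

Everything is generated from a seed, so test inputs never need to be
downloaded or stored.
"""

from __future__ import annotations

import numpy as np

from .energy import AMINO_ACIDS, HYDROPHOBIC
from .lattice import Conformation, random_saw

__all__ = ["random_sequence", "random_hp_sequence", "random_conformation"]


def _rng(rng: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng


def random_sequence(
    n: int, rng: np.random.Generator | int, hydrophobic_fraction: float = 0.4
) -> str:
    """Random 20-letter sequence with a target hydrophobic fraction.

    0.4 is typical of globular proteins under the 8-letter hydrophobic
    class used by the HP model.
    """
    rng = _rng(rng)
    h_letters = sorted(HYDROPHOBIC)
    p_letters = sorted(set(AMINO_ACIDS) - HYDROPHOBIC)
    out = []
    for _ in range(n):
        if rng.random() < hydrophobic_fraction:
            out.append(h_letters[int(rng.integers(len(h_letters)))])
        else:
            out.append(p_letters[int(rng.integers(len(p_letters)))])
    return "".join(out)


def random_hp_sequence(
    n: int, rng: np.random.Generator | int, hydrophobic_fraction: float = 0.4
) -> str:
    """Random sequence reported directly in the two-letter H/P alphabet."""
    rng = _rng(rng)
    return "".join(
        "H" if rng.random() < hydrophobic_fraction else "P" for _ in range(n)
    )


def random_conformation(
    n: int, rng: np.random.Generator | int, sequence: str | None = None
) -> Conformation:
    """Random self-avoiding walk carrying a random sequence."""
    rng = _rng(rng)
    if sequence is None:
        sequence = random_sequence(n, rng)
    return random_saw(n, rng, sequence)
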