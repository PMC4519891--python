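"""Contact-based statistical energy objectives.

Two contact energies are supported, both summed over topological contacts
(chain-separated residue pairs sitting on neighbouring lattice sites):

* E_HP — the hydrophobic-polar model: minus the number of contacts whose
  residues are both hydrophobic (C, F, I, L, M, V, W, Y; everything else,
  including histidine, is polar).
* E_CP — a general contact potential: minus the sum of a symmetric 20x20
  residue-pair potential over all contacts.  The matrix is user-supplied
  (e.g. Berrera or Miyazawa-Jernigan); no specific published table is
  bundled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import Conformation, contact_pairs

__all__ = [
    "AMINO_ACIDS",
    "HYDROPHOBIC",
    "ContactMatrix",
    "classify_hp",
    "hp_energy",
    "cp_energy",
    "load_contact_matrix",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = frozenset("CFILMVWY")

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def classify_hp(sequence: str) -> str:
    """Map a 20-letter sequence to its H/P string."""
    out = []
    for ch in sequence:
        if ch not in _AA_INDEX:
            raise ValueError(f"unknown amino-acid letter {ch!r}")
        out.append("H" if ch in HYDROPHOBIC else "P")
    return "".join(out)


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric 20x20 residue-pair contact potential."""

    values: np.ndarray  # (20, 20), indexed by AMINO_ACIDS order
    name: str = "user"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (20, 20):
            raise ValueError("contact matrix must be 20x20")
        if not np.allclose(v, v.T):
            raise ValueError("contact matrix must be symmetric")
        object.__setattr__(self, "values", v)
        v.setflags(write=False)

    def pair(self, a: str, b: str) -> float:
        try:
            return float(self.values[_AA_INDEX[a], _AA_INDEX[b]])
        except KeyError as exc:
            raise KeyError(f"no contact-matrix entry for letter {exc.args[0]!r}")

    @classmethod
    def hp_indicator(cls) -> "ContactMatrix":
        """1 for H-H pairs, 0 otherwise; reduces E_CP to E_HP."""
        v = np.zeros((20, 20))
        for a in HYDROPHOBIC:
            for b in HYDROPHOBIC:
                v[_AA_INDEX[a], _AA_INDEX[b]] = 1.0
        return cls(v, name="hp-indicator")


def load_contact_matrix(path) -> ContactMatrix:
    """Read a contact-potential TSV: header row/column of one-letter codes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.str.upper()
    df.columns = df.columns.str.upper()
    missing = set(AMINO_ACIDS) - set(df.index) | set(AMINO_ACIDS) - set(df.columns)
    if missing:
        raise ValueError(f"contact matrix missing letters: {sorted(missing)}")
    ordered = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
    return ContactMatrix(ordered.to_numpy(dtype=np.float64), name=str(path))


def hp_energy(conformation: Conformation) -> int:
    """E_HP: minus the count of hydrophobic-hydrophobic contacts."""
    hp = classify_hp(conformation.sequence)
    return -sum(
        1 for i, j in contact_pairs(conformation) if hp[i] == "H" and hp[j] == "H"
    )


def cp_energy(conformation: Conformation, matrix: ContactMatrix) -> float:
    """E_CP: minus the summed pair potential over all contacts."""
    seq = conformation.sequence
    # sorted iteration keeps the float sum bit-reproducible
    return -sum(
        matrix.pair(seq[i], seq[j]) for i, j in sorted(contact_pairs(conformation))
    )
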