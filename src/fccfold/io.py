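"""File formats: FASTA, Cα-only PDB, move-string tables, and the packaged
benchmark identifier list.

The move-string format is one record per line:

    <id> <TAB> <sequence> <TAB> <moves as space-separated labels 1..12>

Cα PDB output writes one ATOM record per residue (chain A, residue numbers
1..n, occupancy 1.00, element C), which round-trips through any standard
PDB reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1, seq3

from .energy import AMINO_ACIDS
from .lattice import Conformation, decode_moves, format_moves

__all__ = [
    "BenchmarkEntry",
    "read_fasta",
    "read_ca_pdb",
    "write_ca_pdb",
    "read_move_strings",
    "write_move_strings",
    "load_benchmark_list",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA records as (id, uppercased sequence) pairs.

    Raises ``ValueError`` on letters outside the 20 standard codes.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"record {rec.id!r}: invalid amino-acid letters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def read_ca_pdb(path, chain: str | None = None) -> tuple[np.ndarray, str]:
    """Extract the Cα trace of one chain from a PDB file.

    Returns (coords in Å as an (n, 3) array, one-letter sequence).  With
    ``chain=None`` a single-chain file is accepted; otherwise the chain id
    must be given.  Alternate locations resolve to the highest-occupancy
    conformer (Bio.PDB's default selection).
    """
    structure = PDBParser(QUIET=True).get_structure("ref", str(path))
    models = list(structure.get_models())
    if not models:
        raise ValueError(f"no coordinate records in {path}")
    model = models[0]
    chains = {c.id: c for c in model.get_chains()}
    if chain is None:
        if len(chains) != 1:
            raise ValueError(
                f"file has chains {sorted(chains)}; specify one explicitly"
            )
        chain = next(iter(chains))
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available: {sorted(chains)}")
    coords, letters = [], []
    for residue in chains[chain]:
        if "CA" not in residue:
            continue
        coords.append(residue["CA"].get_coord())
        try:
            letters.append(seq1(residue.get_resname()))
        except KeyError:
            letters.append("X")
    if not coords:
        raise ValueError(f"no Cα atoms found in chain {chain!r}")
    return np.asarray(coords, dtype=np.float64), "".join(letters)


def write_ca_pdb(path, sequence: str, coords: np.ndarray, chain: str = "A") -> None:
    """Write a Cα-only PDB file (one ATOM record per residue)."""
    coords = np.asarray(coords, dtype=np.float64)
    if len(sequence) != len(coords):
        raise ValueError("sequence and coordinates differ in length")
    lines = []
    for i, (aa, (x, y, z)) in enumerate(zip(sequence, coords), start=1):
        resname = seq3(aa).upper()
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:>3s} {chain}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_move_strings(path) -> list[tuple[str, Conformation]]:
    """Read move-string records; each is decoded and SAW-validated."""
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
        rec_id, sequence, moves = parts
        out.append((rec_id, decode_moves(sequence.upper(), moves)))
    return out


def write_move_strings(path, records: list[tuple[str, Conformation]]) -> None:
    lines = [
        f"{rec_id}\t{conf.sequence}\t{format_moves(conf.moves)}"
        for rec_id, conf in records
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class BenchmarkEntry:
    """One benchmark identifier: 4-char PDB code plus chain char or '-'.

    Sequences and native structures are not bundled; users supply them as
    FASTA / PDB files when evaluating against natives.
    """

    pdb_id: str

    @property
    def pdb_code(self) -> str:
        return self.pdb_id[:4]

    @property
    def chain(self) -> str | None:
        suffix = self.pdb_id[4:5]
        return suffix if suffix and suffix != "-" else None


def load_benchmark_list() -> list[BenchmarkEntry]:
    """The 75 CB513-derived benchmark identifiers, in published order."""
    text = (
        resources.files("fccfold.data").joinpath("cb513_benchmark_ids.txt").read_text()
    )
    return [BenchmarkEntry(line.strip()) for line in text.splitlines() if line.strip()]
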