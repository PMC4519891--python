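"""Backbone virtual-bond angles on the FCC lattice and their preferences.

Two Cα-trace angles describe local backbone geometry:

* κ (kappa): the bend angle at residue i formed by the Cα atoms of residues
  i-2, i and i+2, in [0°, 180°].
* α (alpha): the signed virtual dihedral of the Cα atoms of residues i-1,
  i, i+1 and i+2, in (-180°, 180°].

On the FCC lattice both angles take a small discrete set of values.
Exhaustive enumeration of all self-avoiding 5-point fragments shows the
non-degenerate κ range is exactly 30°–150° and the α magnitudes fall into
six clusters.  An empirical 13x6 preference matrix (κ bins 30°..150° in 10°
steps crossed with six α bins labelled 60, 80, 180, -130, -110, -10
degrees, derived from a non-redundant PDB survey) scores each (κ, α) pair;
the angle objective K_KA is minus the summed preference, so lower is
better, matching the free-energy convention.  Conformations containing a
degenerate fragment or a zero-preference pair are rejected by the angle
constraint used in the multi-objective search.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .lattice import DIRECTION_ARRAY, Conformation

__all__ = [
    "KAPPA_BIN_CENTERS",
    "ALPHA_BIN_CENTERS",
    "PreferenceMatrix",
    "load_preference_matrix",
    "kappa_angle",
    "alpha_angle",
    "angle_pairs",
    "bin_pair",
    "preference",
    "ka_energy",
    "check_angle_constraint",
    "enumerate_feasible_pairs",
    "feasible_angle_table",
    "alpha_magnitude_clusters",
]

KAPPA_BIN_CENTERS: tuple[int, ...] = tuple(range(30, 151, 10))
ALPHA_BIN_CENTERS: tuple[float, ...] = (60.0, 80.0, 180.0, -130.0, -110.0, -10.0)


@dataclass(frozen=True)
class PreferenceMatrix:
    """13x6 binned (κ, α) preference values.

    Rows are κ bin centers 30°..150° (step 10°); columns are the six α bin
    labels.  All entries are non-negative; the 30° row is all zero.
    """

    values: np.ndarray  # (13, 6) float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (len(KAPPA_BIN_CENTERS), len(ALPHA_BIN_CENTERS)):
            raise ValueError("preference matrix must be 13x6")
        if (v < 0).any():
            raise ValueError("preference values must be non-negative")
        object.__setattr__(self, "values", v)
        v.setflags(write=False)

    def cell(self, kappa_bin: int, alpha_bin: float) -> float:
        i = KAPPA_BIN_CENTERS.index(kappa_bin)
        j = ALPHA_BIN_CENTERS.index(alpha_bin)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(KAPPA_BIN_CENTERS, name="kappa"),
            columns=[f"{int(a)}" for a in ALPHA_BIN_CENTERS],
        )


def load_preference_matrix() -> PreferenceMatrix:
    """Load the packaged (κ, α) preference table."""
    with resources.files("fccfold.data").joinpath("ka_preferences.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if tuple(df.index) != KAPPA_BIN_CENTERS:
        raise ValueError("unexpected kappa bins in packaged preference table")
    if tuple(float(c) for c in df.columns) != ALPHA_BIN_CENTERS:
        raise ValueError("unexpected alpha bins in packaged preference table")
    return PreferenceMatrix(df.to_numpy(dtype=np.float64))


def _as_int_coords(coords) -> np.ndarray:
    return np.asarray(coords, dtype=np.int64)


def kappa_angle(coords, i: int) -> float:
    """Bend angle at position ``i`` between positions ``i-2`` and ``i+2``.

    Exactly 0.0 or 180.0 for colinear arms (detected with integer cross
    products, so degeneracy is decided exactly, not by a float tolerance).
    """
    coords = _as_int_coords(coords)
    n = len(coords)
    if not 2 <= i <= n - 3:
        raise IndexError(f"kappa undefined at position {i} for chain of length {n}")
    u = coords[i - 2] - coords[i]
    v = coords[i + 2] - coords[i]
    if not np.cross(u, v).any():
        return 180.0 if int(u @ v) < 0 else 0.0
    c = float(u @ v) / math.sqrt(float(u @ u) * float(v @ v))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def alpha_angle(coords, i: int) -> float:
    """Signed dihedral of positions ``i-1, i, i+1, i+2`` (right-hand rule).

    Returns NaN when either bond-plane normal vanishes (three colinear
    points), which excludes the position from scoring.
    """
    coords = _as_int_coords(coords)
    n = len(coords)
    if not 1 <= i <= n - 3:
        raise IndexError(f"alpha undefined at position {i} for chain of length {n}")
    b1 = coords[i] - coords[i - 1]
    b2 = coords[i + 1] - coords[i]
    b3 = coords[i + 2] - coords[i + 1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if not n1.any() or not n2.any():
        return math.nan
    # IUPAC sign: atan2((n1 x n2) . b2_hat, n1 . n2), as in DSSP
    y = float(np.cross(n1, n2) @ b2) / math.sqrt(float(b2 @ b2))
    a = math.degrees(math.atan2(y, float(n1 @ n2)))
    return 180.0 if a <= -180.0 else a


def angle_pairs(coords) -> list[tuple[int, float, float]]:
    """All (i, κ_i, α_i) with both angles defined: 2 <= i <= n-3 (0-based).

    κ is 0/180 for degenerate bends and α is NaN for degenerate dihedrals;
    callers decide how to treat those.
    """
    coords = _as_int_coords(coords)
    return [
        (i, kappa_angle(coords, i), alpha_angle(coords, i))
        for i in range(2, len(coords) - 2)
    ]


def bin_pair(kappa: float, alpha: float) -> tuple[int | None, float]:
    """Assign (κ, α) to bin centers.

    κ is rounded to the nearest 10° center; values rounding below 30° or
    above 150° are unbinnable and yield ``None``.  α goes to the nearest of
    the six centers by circular distance.
    """
    k = int(round(kappa / 10.0)) * 10  # half-to-even, like np.rint
    kappa_bin = k if 30 <= k <= 150 else None
    diffs = [abs((alpha - c + 180.0) % 360.0 - 180.0) for c in ALPHA_BIN_CENTERS]
    alpha_bin = ALPHA_BIN_CENTERS[int(np.argmin(diffs))]
    return kappa_bin, alpha_bin


def preference(
    kappa_bin: int | None, alpha_bin: float, matrix: PreferenceMatrix
) -> float:
    """Preference value for a binned pair; unbinnable κ scores 0."""
    if kappa_bin is None:
        return 0.0
    return matrix.cell(kappa_bin, alpha_bin)


def _angle_table(coords) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (κ_i, α_i, degenerate_i) for all i in 2..n-3 at once.

    Degeneracy (colinear arms or vanishing dihedral plane) is decided with
    exact integer cross products.  Equivalent to calling
    :func:`kappa_angle` / :func:`alpha_angle` position by position, but one
    numpy pass — this is the hot path of the evolutionary search.
    """
    c = _as_int_coords(coords)
    n = len(c)
    if n < 5:
        empty = np.empty(0)
        return empty, empty, np.empty(0, dtype=bool)
    center = c[2 : n - 2]
    u = c[0 : n - 4] - center
    v = c[4:n] - center
    deg_k = ~np.cross(u, v).any(axis=1)
    uv = np.einsum("ij,ij->i", u, v).astype(np.float64)
    norm2 = np.einsum("ij,ij->i", u, u) * np.einsum("ij,ij->i", v, v)
    cosk = np.clip(uv / np.sqrt(norm2.astype(np.float64)), -1.0, 1.0)
    kappa = np.degrees(np.arccos(cosk))
    kappa[deg_k] = np.where(uv[deg_k] < 0, 180.0, 0.0)
    b1 = c[2 : n - 2] - c[1 : n - 3]
    b2 = c[3 : n - 1] - c[2 : n - 2]
    b3 = c[4:n] - c[3 : n - 1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    deg_a = ~n1.any(axis=1) | ~n2.any(axis=1)
    b2n = b2 / np.sqrt(np.einsum("ij,ij->i", b2, b2).astype(np.float64))[:, None]
    x = np.einsum("ij,ij->i", n1, n2).astype(np.float64)
    y = np.einsum("ij,ij->i", np.cross(n1, n2).astype(np.float64), b2n)
    alpha = np.degrees(np.arctan2(y, x))
    alpha = np.where(alpha <= -180.0, alpha + 360.0, alpha)
    alpha[deg_a] = math.nan
    degenerate = deg_k | deg_a
    return kappa, alpha, degenerate


def _preference_table(
    kappa: np.ndarray, alpha: np.ndarray, matrix: PreferenceMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bin lookup: (preference values, κ-binnable mask)."""
    kb = (np.rint(kappa / 10.0) * 10).astype(np.int64)
    k_ok = (kb >= 30) & (kb <= 150)
    centers = np.asarray(ALPHA_BIN_CENTERS)
    diffs = np.abs((alpha[:, None] - centers[None, :] + 180.0) % 360.0 - 180.0)
    aj = np.argmin(np.nan_to_num(diffs, nan=np.inf), axis=1)
    ki = np.clip((kb - 30) // 10, 0, len(KAPPA_BIN_CENTERS) - 1)
    values = np.where(k_ok, matrix.values[ki, aj], 0.0)
    return values, k_ok


def ka_energy(conformation: Conformation, matrix: PreferenceMatrix) -> float:
    """Angle-preference objective K_KA = -Σ preference(κ_i, α_i).

    Sums over every position with both angles defined and non-degenerate;
    degenerate fragments contribute 0.  Always <= 0; chains shorter than 5
    residues have no defined pairs and score 0.
    """
    coords = conformation.coords if isinstance(conformation, Conformation) else conformation
    if len(coords) < 5:
        warnings.warn(
            f"chain of length {len(coords)} defines no (kappa, alpha) pairs",
            stacklevel=2,
        )
        return 0.0
    kappa, alpha, degenerate = _angle_table(coords)
    values, _ = _preference_table(kappa, alpha, matrix)
    return -float(values[~degenerate].sum())


def check_angle_constraint(
    conformation: Conformation, matrix: PreferenceMatrix
) -> bool:
    """Angle-legality rule for the constrained (FCC') search.

    True iff every defined (κ, α) pair is non-degenerate and bins to a cell
    with strictly positive preference.  Chains too short to define any pair
    pass vacuously.
    """
    coords = conformation.coords if isinstance(conformation, Conformation) else conformation
    kappa, alpha, degenerate = _angle_table(coords)
    if not len(kappa):
        return True
    if degenerate.any():
        return False
    values, k_ok = _preference_table(kappa, alpha, matrix)
    return bool(k_ok.all() and (values > 0.0).all())


def _pair_is_feasible(coords, i: int, matrix: PreferenceMatrix) -> bool:
    kappa = kappa_angle(coords, i)
    if kappa in (0.0, 180.0):
        return False
    alpha = alpha_angle(coords, i)
    if math.isnan(alpha):
        return False
    kb, ab = bin_pair(kappa, alpha)
    return preference(kb, ab, matrix) > 0.0


def enumerate_feasible_pairs() -> list[tuple[float, float]]:
    """Exhaustively enumerate realizable (κ, α) pairs on the lattice.

    Generates every self-avoiding 5-point FCC fragment with the first point
    at the origin and the first move fixed (the lattice rotation group acts
    transitively on the 12 directions, so fixing it only removes a 12-fold
    multiplicity), computes κ at the center and α at the last four points,
    and returns the raw values for every fragment where both are defined
    and κ is non-degenerate.  Multiplicities are preserved.
    """
    pairs: list[tuple[float, float]] = []
    dirs = DIRECTION_ARRAY
    first = dirs[0]
    for combo in itertools.product(range(12), repeat=3):
        steps = np.vstack([first, dirs[list(combo)]])
        pts = np.zeros((5, 3), dtype=np.int64)
        pts[1:] = np.cumsum(steps, axis=0)
        if len({tuple(p) for p in pts.tolist()}) < 5:
            continue
        kappa = kappa_angle(pts, 2)
        if kappa in (0.0, 180.0):
            continue
        alpha = alpha_angle(pts, 2)
        if math.isnan(alpha):
            continue
        pairs.append((kappa, alpha))
    return pairs


def _cluster_1d(values: list[float], tol: float) -> list[list[float]]:
    clusters: list[list[float]] = []
    for v in sorted(values):
        if clusters and v - clusters[-1][-1] <= tol:
            clusters[-1].append(v)
        else:
            clusters.append([v])
    return clusters


def alpha_magnitude_clusters(
    pairs: list[tuple[float, float]] | None = None, tol: float = 5.0
) -> list[float]:
    """Cluster centers of |α| over the realizable pairs (merge radius tol).

    The lattice is mirror-symmetric, so realizable α values come in ±
    pairs; the six discrete α spaces correspond to the magnitudes.
    """
    if pairs is None:
        pairs = enumerate_feasible_pairs()
    clusters = _cluster_1d([abs(a) for _, a in pairs], tol)
    return [float(np.mean(c)) for c in clusters]


def feasible_angle_table() -> pd.DataFrame:
    """Realized (κ, α) value table with multiplicities, for reporting.

    One row per distinct (κ, α) value pair (0.01° rounding), with the
    fragment count and the bin assignment.
    """
    rows: dict[tuple[float, float], int] = {}
    for kappa, alpha in enumerate_feasible_pairs():
        key = (round(kappa, 2), round(alpha, 2))
        rows[key] = rows.get(key, 0) + 1
    records = []
    for (kappa, alpha), count in sorted(rows.items()):
        kb, ab = bin_pair(kappa, alpha)
        records.append(
            {
                "kappa": kappa,
                "alpha": alpha,
                "count": count,
                "kappa_bin": kb,
                "alpha_bin": ab,
            }
        )
    return pd.DataFrame.from_records(records)
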