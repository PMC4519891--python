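"""Distance-matrix RMSD (dRMSD) between two Cα traces.

dRMSD compares the two intramolecular distance matrices rather than
superposed coordinates:

    dRMSD = sqrt( sum_{i<j} (d_ij^model - d_ij^ref)^2 / C(n, 2) )

over all C(n,2) residue pairs, in Å.  Being built from internal distances
it is invariant under rigid motion and reflection of either structure and
needs no superposition step.  Lattice models should be scaled to Å first
(3.8 Å Cα step; see :func:`fccfold.lattice.scale_coordinates`).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist

__all__ = ["drmsd"]


def drmsd(model_coords, ref_coords) -> float:
    """Distance-matrix RMSD in Å between equal-length coordinate sets."""
    model = np.asarray(model_coords, dtype=np.float64)
    ref = np.asarray(ref_coords, dtype=np.float64)
    if model.shape != ref.shape or model.ndim != 2 or model.shape[1] != 3:
        raise ValueError(
            f"coordinate sets must both be (n, 3); got {model.shape} and {ref.shape}"
        )
    if len(model) < 2:
        raise ValueError("dRMSD needs at least 2 points")
    diff = pdist(model) - pdist(ref)
    return float(np.sqrt(np.mean(diff**2)))
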