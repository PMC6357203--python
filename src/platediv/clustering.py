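"""Single-link proximity grouping of point sets.

Used both by the spatial simulator (to derive ground-truth cluster labels)
and by the imaging front-end (to group detected spots), so that "in contact"
means exactly the same thing on both sides of a round trip.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


def single_link_labels(xy: np.ndarray, threshold: float) -> np.ndarray:
    """Connected components of the graph joining points at distance <= threshold.

    Parameters
    ----------
    xy : (n, 2) array of coordinates.
    threshold : contact distance in the same units as ``xy``; must be >= 0.

    Returns
    -------
    (n,) integer labels; label numbering is deterministic (ordered by the
    first member index of each component).
    """
    if threshold < 0:
        raise ValueError("contact distance must be non-negative")
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if n == 0:
        return np.zeros(0, dtype=int)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be an (n, 2) array")
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    # renumber so labels appear in order of first occurrence (determinism)
    _, first_index, inverse = np.unique(labels, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_index))
    return order[inverse]
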