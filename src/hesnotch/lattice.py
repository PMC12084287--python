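"""Cell-connectivity lattices and the neighbour-averaged Dll1 signal.

Cells sit on a regular hexagonal grid indexed by axial (rhombic) lattice
coordinates ``(row, col)``: the six neighbours of a node are obtained by the
offsets ``(0, +-1)``, ``(+-1, 0)`` and ``(+1, +1)/(-1, -1)``.  This indexing
makes the periodic wrap an exact hexagonal torus for any grid size and is
the coordinate system in which the Fourier dispersion analysis of the
package is phrased.

The incoming signal a cell receives is the weighted average
``<D_in>_i = sum_j W[i, j] D_j`` with weights summing to (at most) one.
Two boundary conventions are supported for finite grids:

* ``"zero"`` (default reading): every existing neighbour keeps weight 1/6
  and missing neighbours contribute zero signal, so boundary cells receive
  a weaker total input.  Pass ``normalise_boundary=True`` for the
  alternative reading in which boundary weights are renormalised to one.
* ``"periodic"``: both lattice directions wrap; every node of a grid with
  at least three rows and columns has exactly six distinct neighbours of
  weight 1/6.  For degenerate sizes (the one- and two-cell systems) the
  wrap produces repeated neighbours; self-loops are dropped and the
  remaining multiplicities renormalised, which reproduces the classical
  two-cell mutual coupling and the all-to-all three-cell system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "HexLattice",
    "build_hex_lattice",
    "coupling_lattice",
    "neighbour_average",
    "W2",
    "W3",
]

#: Axial-coordinate offsets of the six hexagonal neighbours.
HEX_OFFSETS = ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (-1, -1))

#: Two-cell coupling of the idealised period-3 pattern: the minority fate
#: (row 0) sees only the majority fate, the majority fate sees both in
#: equal measure.
W2 = np.array([[0.0, 1.0], [0.5, 0.5]])

#: All-to-all three-cell coupling, the smallest faithful model of the
#: period-3 pattern on the hexagonal tiling.
W3 = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])


@dataclass
class HexLattice:
    """A weighted cell-connectivity graph.

    ``weights`` is a K-by-K sparse matrix with ``weights[i, j]`` the weight
    of the signal node ``i`` receives from node ``j``.  ``rows``/``cols``
    record the generating grid shape when applicable, and ``coords`` the
    per-node axial coordinates.
    """

    weights: sp.csr_matrix
    bc: str
    rows: int | None = None
    cols: int | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = sp.csr_matrix(self.weights)
        if self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weight matrix must be square")
        if (self.weights.data < 0).any():
            raise ValueError("neighbour weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def neighbours(self, i: int) -> np.ndarray:
        """Indices of the nodes whose signal reaches node ``i`` (self excluded)."""
        row = self.weights.getrow(i)
        idx = row.indices[row.data > 0]
        return idx[idx != i]

    @property
    def degrees(self) -> np.ndarray:
        """In-degree of every node, self-loops excluded."""
        return np.array([len(self.neighbours(i)) for i in range(self.n_nodes)])

    def weight_sums(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel()

    def neighbour_average(self, values: np.ndarray) -> np.ndarray:
        """Weighted average of ``values`` over each node's neighbours."""
        values = np.asarray(values, dtype=float)
        if values.shape[0] != self.n_nodes:
            raise ValueError(
                f"field has {values.shape[0]} entries but lattice has {self.n_nodes} nodes"
            )
        return self.weights @ values

    def adjacency_symmetric(self) -> bool:
        pattern = (self.weights != 0).astype(np.int8)
        return (pattern != pattern.T).nnz == 0

    # -- plain-text interchange ------------------------------------------------

    def to_csv(self, edge_path, node_path=None) -> None:
        """Write the edge list (source, target, weight) and optional node table."""
        coo = self.weights.tocoo()
        pd.DataFrame(
            {"source": coo.col, "target": coo.row, "weight": coo.data}
        ).to_csv(edge_path, index=False)
        if node_path is not None:
            coords = self.coords
            if coords is None:
                coords = np.full((self.n_nodes, 2), -1)
            pd.DataFrame(
                {"id": np.arange(self.n_nodes), "row": coords[:, 0], "col": coords[:, 1]}
            ).to_csv(node_path, index=False)

    @classmethod
    def from_csv(cls, edge_path, node_path=None, bc: str = "imported") -> "HexLattice":
        edges = pd.read_csv(edge_path)
        n = int(max(edges["source"].max(), edges["target"].max())) + 1
        coords = None
        if node_path is not None:
            nodes = pd.read_csv(node_path)
            n = max(n, int(nodes["id"].max()) + 1)
            coords = np.column_stack([nodes["row"].to_numpy(), nodes["col"].to_numpy()])
        weights = sp.csr_matrix(
            (edges["weight"], (edges["target"], edges["source"])), shape=(n, n)
        )
        return cls(weights=weights, bc=bc, coords=coords)


def build_hex_lattice(
    rows: int,
    cols: int,
    bc: str = "zero",
    *,
    normalise_boundary: bool = False,
) -> HexLattice:
    """Construct a ``rows``-by-``cols`` hexagonal grid.

    Parameters
    ----------
    bc : {"zero", "periodic"}
        Boundary handling, see the module docstring.
    normalise_boundary : bool
        Only meaningful for ``bc="zero"``: renormalise boundary weights to
        sum to one instead of letting missing neighbours contribute zero.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if bc not in ("zero", "periodic"):
        raise ValueError(f"unknown boundary condition {bc!r}; expected 'zero' or 'periodic'")

    n = rows * cols
    coords = np.array([(r, c) for r in range(rows) for c in range(cols)])
    data, rows_i, cols_j = [], [], []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if bc == "periodic":
                targets: dict[int, int] = {}
                for dr, dc in HEX_OFFSETS:
                    j = ((r + dr) % rows) * cols + (c + dc) % cols
                    if j == i:
                        continue  # degenerate wrap: drop self-signal
                    targets[j] = targets.get(j, 0) + 1
                total = sum(targets.values())
                for j, mult in targets.items():
                    rows_i.append(i)
                    cols_j.append(j)
                    data.append(mult / total)
            else:
                present = []
                for dr, dc in HEX_OFFSETS:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols:
                        present.append(rr * cols + cc)
                w = (1.0 / len(present)) if (normalise_boundary and present) else (1.0 / 6.0)
                for j in present:
                    rows_i.append(i)
                    cols_j.append(j)
                    data.append(w)
    weights = sp.csr_matrix((data, (rows_i, cols_j)), shape=(n, n))
    return HexLattice(weights=weights, bc=bc, rows=rows, cols=cols, coords=coords)


def coupling_lattice(which: str) -> HexLattice:
    """The idealised pattern-coupling systems ``"W2"`` and ``"W3"``."""
    key = which.upper()
    if key == "W2":
        return HexLattice(weights=sp.csr_matrix(W2), bc="coupling")
    if key == "W3":
        return HexLattice(weights=sp.csr_matrix(W3), bc="coupling")
    raise ValueError(f"unknown coupling lattice {which!r}; expected 'W2' or 'W3'")


def neighbour_average(lattice: HexLattice, values: np.ndarray) -> np.ndarray:
    """Module-level convenience wrapper for :meth:`HexLattice.neighbour_average`."""
    return lattice.neighbour_average(values)
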