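"""Labelled tetrahedral meshes.

The analysis operates on 4-node tetrahedral volume meshes in a mm / N / MPa
unit system with anatomical axes ``+x`` subject-left, ``+y`` anterior,
``+z`` superior.  Every element carries exactly one region label (a named
bone plate or suture band); named node sets mark landmarks, bite points,
temporomandibular-joint (TMJ) nodes, facial probe points and the zygomatic
arch mid-span control nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

#: Bone-plate region labels.
BONE_LABELS = (
    "frontal",
    "parietal",
    "occipital",
    "facial",
    "zygomatic_arch_L",
    "zygomatic_arch_R",
    "skull_base",
)

#: Compliant-joint (suture / fontanelle / synchondrosis) region labels.
SUTURE_LABELS = (
    "metopic",
    "coronal",
    "sagittal",
    "lambdoid",
    "facial_suture",
    "base_joint",
    "anterior_fontanelle",
)

REGION_LABELS = BONE_LABELS + SUTURE_LABELS


class MeshError(ValueError):
    """Raised for structurally invalid meshes (inverted/mislabelled elements)."""


@dataclass
class LabelledTetMesh:
    """Tetrahedral mesh with per-element region labels and named node sets.

    Attributes
    ----------
    nodes : (n, 3) float array
        Node coordinates in mm.
    tets : (m, 4) int array
        Node indices of each tetrahedron, positively oriented.
    region : (m,) int array
        Index into :data:`REGION_LABELS` per element.
    node_sets : dict
        Named node-index arrays (``bite_incisor``, ``bite_molar_L`` ...).
    landmarks : (42, 3) float array
        Anatomical landmark coordinates (1-based ids 1..42 -> rows 0..41).
        Insertion-side landmarks sit on the (unmodelled) mandible and are
        not mesh nodes.
    landmark_nodes : (42,) int array
        Nearest mesh node for on-skull landmarks, -1 for off-mesh ones.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    landmarks: np.ndarray | None = None
    landmark_nodes: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    # -- basic derived quantities -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.tets.shape[0])

    def element_coords(self) -> np.ndarray:
        """(m, 4, 3) coordinates of element corners."""
        return self.nodes[self.tets]

    def volumes(self) -> np.ndarray:
        """Signed element volumes in mm^3 (positive for valid orientation)."""
        x = self.element_coords()
        a = x[:, 1] - x[:, 0]
        b = x[:, 2] - x[:, 0]
        c = x[:, 3] - x[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def region_names(self) -> np.ndarray:
        return np.asarray(REGION_LABELS, dtype=object)[self.region]

    def elements_with_label(self, *labels: str) -> np.ndarray:
        codes = [REGION_LABELS.index(lb) for lb in labels]
        return np.flatnonzero(np.isin(self.region, codes))

    def is_suture(self) -> np.ndarray:
        """Boolean per-element mask of compliant-joint elements."""
        first_suture = len(BONE_LABELS)
        return self.region >= first_suture

    # -- validation ---------------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`MeshError` on failure."""
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= self.n_nodes:
            raise MeshError("tetrahedron references a node out of range")
        vol = self.volumes()
        bad = np.flatnonzero(vol <= 0)
        if bad.size:
            raise MeshError(f"{bad.size} non-positive-volume elements, first={bad[0]}")
        if self.region.shape[0] != self.n_elements:
            raise MeshError("one region label per element required")
        if self.region.min() < 0 or self.region.max() >= len(REGION_LABELS):
            raise MeshError("region code out of range")
        for name, idx in self.node_sets.items():
            idx = np.asarray(idx)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise MeshError(f"node set {name!r} has out-of-range indices")
        ncomp, _ = connected_components(self.node_adjacency(), directed=False)
        if ncomp != 1:
            raise MeshError(f"mesh is disconnected ({ncomp} components)")

    # -- connectivity helpers -----------------------------------------------------

    def edges(self) -> np.ndarray:
        """(e, 2) unique undirected node-pair edges of the tetrahedra."""
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        e = np.vstack([self.tets[:, p] for p in pairs])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def node_adjacency(self):
        """Sparse symmetric node adjacency with edge lengths as weights."""
        e = self.edges()
        w = np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)
        n = self.n_nodes
        m = coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return m.tocsr()

    def mirror_node_map(self) -> np.ndarray:
        """Map each node to its mirror image under x-negation.

        The surrogate generator builds one half and reflects it, so the map
        is exact.  Raises :class:`MeshError` when a node has no mirror twin.
        """
        order = np.lexsort((self.nodes[:, 2], self.nodes[:, 1], self.nodes[:, 0]))
        mirrored = self.nodes.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        order_m = np.lexsort((mirrored[:, 2], mirrored[:, 1], mirrored[:, 0]))
        if not np.array_equal(self.nodes[order], mirrored[order_m]):
            raise MeshError("mesh nodes are not mirror-symmetric about x=0")
        out = np.empty(self.n_nodes, dtype=np.int64)
        out[order_m] = order
        return out

    def nearest_node(self, point, labels: tuple[str, ...] | None = None) -> int:
        """Index of the mesh node closest to ``point``.

        With ``labels`` given the search is restricted to nodes of elements
        carrying one of those region labels.  Ties break on node index.
        """
        point = np.asarray(point, dtype=float)
        if labels is None:
            cand = np.arange(self.n_nodes)
        else:
            els = self.elements_with_label(*labels)
            cand = np.unique(self.tets[els])
        d = np.linalg.norm(self.nodes[cand] - point, axis=1)
        return int(cand[np.argmin(d)])
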