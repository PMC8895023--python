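"""Quaternion utilities, the octahedral rotation group and uniform SO(3) grids.

Quaternions are stored scalar-first, ``(w, x, y, z)``, with ``q`` and ``-q``
identified (both represent the same rotation).  Uniform orientation grids are
built by refining the 600-cell, the regular 4-polytope whose 120 vertices are
the binary icosahedral unit quaternions: each of its 600 tetrahedral cells is
subdivided barycentrically at level ``n`` and the points are radially
projected onto the unit 3-sphere.  The number of distinct rotations at level
``n`` is ``10 (5 n^3 + n)``.

For particles with octahedral symmetry the grid is reduced to a fundamental
domain of SO(3)/O by keeping one canonical representative per orbit under the
24 proper rotations of the octahedral group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "quat_multiply",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_angle",
    "octahedral_group_matrices",
    "octahedral_group_quats",
    "cell600_vertices",
    "so3_grid",
    "reduce_to_fundamental_domain",
    "canonical_representatives",
    "QuaternionGrid",
    "build_quaternion_grid",
]

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product of scalar-first quaternions (broadcasting)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (or stack of matrices) for scalar-first quaternions."""
    return Rotation.from_quat(np.asarray(q, dtype=float), scalar_first=True).as_matrix()


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    """Scalar-first quaternion(s) for rotation matrices, w >= 0 convention."""
    q = Rotation.from_matrix(np.asarray(m, dtype=float)).as_quat(scalar_first=True)
    q = np.atleast_2d(q)
    flip = q[:, 0] < 0
    q[flip] = -q[flip]
    return q if q.shape[0] > 1 else q[0]


def quat_angle(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Geodesic rotation angle (radians) between two rotations."""
    d = np.abs(np.sum(np.asarray(q1, float) * np.asarray(q2, float), axis=-1))
    return 2.0 * np.arccos(np.clip(d, -1.0, 1.0))


def octahedral_group_matrices() -> np.ndarray:
    """The 24 proper rotation matrices of the octahedral group O.

    These are the signed permutation matrices with determinant +1; they map
    the cubic grid onto itself exactly.
    """
    mats = []
    for perm in permutations(range(3)):
        for signs in product((1, -1), repeat=3):
            m = np.zeros((3, 3))
            for i, (p, s) in enumerate(zip(perm, signs)):
                m[i, p] = s
            if np.isclose(np.linalg.det(m), 1.0):
                mats.append(m)
    out = np.array(mats)
    assert out.shape == (24, 3, 3)
    return out


def octahedral_group_quats() -> np.ndarray:
    """The 24 group rotations as scalar-first unit quaternions (w >= 0)."""
    return matrix_to_quat(octahedral_group_matrices())


def cell600_vertices() -> np.ndarray:
    """The 120 unit-quaternion vertices of the 600-cell."""
    verts = []
    # 8 permutations of (+-1, 0, 0, 0)
    for i in range(4):
        for s in (1.0, -1.0):
            v = np.zeros(4)
            v[i] = s
            verts.append(v)
    # 16 of (+-1/2, +-1/2, +-1/2, +-1/2)
    for signs in product((0.5, -0.5), repeat=4):
        verts.append(np.array(signs))
    # 96 even permutations of (+-phi, +-1, +-1/phi, 0) / 2
    base = (_PHI / 2.0, 0.5, 1.0 / (2.0 * _PHI), 0.0)
    even_perms = [p for p in permutations(range(4)) if _perm_parity(p) == 0]
    for perm in even_perms:
        for signs in product((1.0, -1.0), repeat=4):
            v = np.array([signs[i] * base[perm[i]] for i in range(4)])
            verts.append(v)
    verts = np.unique(np.round(np.array(verts), 12), axis=0)
    assert verts.shape == (120, 4)
    return verts


def _perm_parity(perm) -> int:
    inv = sum(
        1
        for i in range(len(perm))
        for j in range(i + 1, len(perm))
        if perm[i] > perm[j]
    )
    return inv % 2


def _cell600_cells(verts: np.ndarray) -> np.ndarray:
    """Vertex index quadruples of the 600 tetrahedral cells."""
    # Adjacent vertices subtend 36 degrees: dot product phi/2.
    dots = verts @ verts.T
    adj = np.abs(dots - _PHI / 2.0) < 1e-9
    n = len(verts)
    neighbours = [np.nonzero(adj[i])[0] for i in range(n)]
    cells = set()
    for i in range(n):
        ni = neighbours[i]
        ni = ni[ni > i]
        for a_idx in range(len(ni)):
            j = ni[a_idx]
            common_ij = ni[adj[j, ni]]
            common_ij = common_ij[common_ij > j]
            for b_idx in range(len(common_ij)):
                k = common_ij[b_idx]
                common = common_ij[adj[k, common_ij]]
                for m in common[common > k]:
                    cells.add((i, j, k, int(m)))
    cells = np.array(sorted(cells))
    assert cells.shape == (600, 4), cells.shape
    return cells


def so3_grid(level: int) -> np.ndarray:
    """Uniform SO(3) sampling by barycentric refinement of the 600-cell.

    Returns ``10 (5 n^3 + n)`` scalar-first unit quaternions with w >= 0
    (one representative per antipodal pair; boundary w == 0 broken by the
    first nonzero component being positive).
    """
    if level < 1:
        raise ValueError("refinement level must be >= 1")
    verts = cell600_vertices()
    cells = _cell600_cells(verts)
    n = level
    # barycentric integer weights (i, j, k, l), sum n
    weights = np.array(
        [
            (i, j, k, n - i - j - k)
            for i in range(n + 1)
            for j in range(n + 1 - i)
            for k in range(n + 1 - i - j)
        ],
        dtype=float,
    )
    pts = np.einsum("cvd,pv->cpd", verts[cells], weights / n).reshape(-1, 4)
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts = _canonical_sign(pts)
    pts = np.unique(np.round(pts, 9), axis=0)
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    expected = 10 * (5 * n**3 + n)
    assert len(pts) == expected, (len(pts), expected)
    return pts


def _canonical_sign(q: np.ndarray) -> np.ndarray:
    """Pick the representative of each antipodal pair with first nonzero > 0."""
    q = np.array(q, dtype=float)
    key = np.where(np.abs(q) > 1e-10, q, 0.0)
    first = np.zeros(len(q))
    for c in range(4):
        col = key[:, c]
        undecided = first == 0
        first[undecided] = np.sign(col[undecided])
    q[first < 0] *= -1
    return q


def reduce_to_fundamental_domain(
    quats: np.ndarray, group_quats: np.ndarray | None = None
) -> np.ndarray:
    """Map each rotation to its canonical representative under a point group.

    A slice of a group-symmetric intensity volume at orientation ``q`` is
    identical to the slice at ``g q`` for every group rotation ``g`` (the
    symmetry acts on the left), so orientations are identified along the
    orbit ``{g q : g in group} x {+-1}``.  The representative is the
    lexicographically largest quaternion (compared componentwise w, x, y, z
    after rounding).  Duplicate orbits are removed.
    """
    reps = canonical_representatives(quats, group_quats)
    uniq = np.unique(np.round(np.atleast_2d(reps), 8), axis=0)
    uniq /= np.linalg.norm(uniq, axis=1)[:, None]
    return uniq


def canonical_representatives(
    quats: np.ndarray, group_quats: np.ndarray | None = None
) -> np.ndarray:
    """Per-rotation canonical orbit representative (row-aligned with input)."""
    if group_quats is None:
        group_quats = octahedral_group_quats()
    quats = np.atleast_2d(np.asarray(quats, dtype=float))
    reps = np.empty_like(quats)
    chunk = 65536
    for lo in range(0, len(quats), chunk):
        block = quats[lo : lo + chunk]
        images = quat_multiply(group_quats[None, :, :], block[:, None, :])
        images = np.concatenate([images, -images], axis=1)  # (B, 48, 4)
        qi = np.round(images, 9)
        # lexicographic argmax over the 48 images via two packed integer keys
        ints = np.round(qi * 1e9).astype(np.int64)
        key_a = ints[..., 0] * (1 << 32) + ints[..., 1] // 1
        key_b = ints[..., 2] * (1 << 32) + ints[..., 3] // 1
        best_a = key_a.max(axis=1, keepdims=True)
        tie = key_a == best_a
        key_b_masked = np.where(tie, key_b, np.iinfo(np.int64).min)
        idx = key_b_masked.argmax(axis=1)
        reps[lo : lo + chunk] = qi[np.arange(len(block)), idx]
    return reps


_KNOWN_GROUPS = {"O": octahedral_group_quats, "1": lambda: np.array([[1.0, 0, 0, 0]])}

# The refined 600-cell is itself invariant under the binary tetrahedral
# subgroup, so octahedral orbits would intersect the grid 12 times instead of
# the generic 24 and the reduced grid would double-sample the fundamental
# domain.  A fixed generic left rotation de-tunes the grid from the group
# while preserving its uniformity.
_DETUNE = np.array([0.969, 0.171, 0.146, 0.089])
_DETUNE = _DETUNE / np.linalg.norm(_DETUNE)


@dataclass
class QuaternionGrid:
    """Uniform orientation grid, optionally reduced to a symmetry fundamental domain."""

    quats: np.ndarray
    level: int
    symmetry: str

    def __len__(self) -> int:
        return len(self.quats)


def build_quaternion_grid(level: int, symmetry: str = "O") -> QuaternionGrid:
    """Refined 600-cell SO(3) grid reduced by a point group.

    ``symmetry="O"`` keeps one representative per orbit of the 24 octahedral
    rotations; ``symmetry="1"`` keeps the full grid.  Level 20 gives a
    reduced count close to the 16.4k-orientation grids used for cube-like
    particles; small levels suffice for tests.
    """
    fn = _KNOWN_GROUPS.get(symmetry)
    if fn is None:
        raise ValueError(f"unknown point group {symmetry!r}; known: {sorted(_KNOWN_GROUPS)}")
    full = so3_grid(level)
    if symmetry == "1":
        reduced = full
    else:
        detuned = _canonical_sign(quat_multiply(_DETUNE[None, :], full))
        reps = canonical_representatives(detuned, fn())
        in_domain = np.abs(reps - np.round(detuned, 9)).max(axis=1) < 1e-7
        reduced = detuned[in_domain]
    return QuaternionGrid(quats=reduced, level=level, symmetry=symmetry)
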