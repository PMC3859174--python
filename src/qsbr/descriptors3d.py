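"""The six 3D molecular descriptors of the final bitterness model.

Computed from a conformer (elements, coordinates in Angstrom, bond graph)
following the standard handbook definitions of the descriptor families:

SPAN
    Size: radius of the smallest centroid-centered sphere enclosing all
    atoms, i.e. the maximum distance from the unweighted geometric center
    to any atom.
MSD
    Balaban's mean-square-distance topological index: the square root of
    the sum of squared topological distances over ordered atom pairs,
    divided by A(A-1).  Decreases with branching and with atom count.
Mor11v (3D-MoRSE)
    Electron-diffraction scattering sum over atom pairs,
    sum w_i w_j sin(s r_ij)/(s r_ij), at s = 10 / Angstrom with
    van-der-Waals-volume weights.  The family is indexed Mor01..Mor32 with
    Mor01 corresponding to s = 0 (where the kernel is defined as 1), so
    MorK uses s = K - 1; an off-by-one here silently changes results.
E3s, G3p (WHIM)
    Weighted holistic invariant descriptors from the weighted-covariance
    PCA of the centered coordinates: E3s is the third-axis accessibility
    (inverse kurtosis of the axis scores) under electrotopological-state
    weights; G3p the third-axis symmetry under polarizability weights.
HATS8u (GETAWAY)
    Leverage autocorrelation at topological lag 8, unweighted: leverages
    are the diagonal of the molecular influence matrix
    H = M (M'M)^-1 M' of the centered coordinates M.

All six are invariant under rigid rotation/translation of the coordinates
and under atom relabeling.  Exact numerical compatibility with the
proprietary Dragon implementation is not promised (its weight tables and
normalizations are not fully published); the definitions here are the
open literature ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "Conformer",
    "DescriptorVector",
    "WhimAxes",
    "atomic_weights",
    "span",
    "msd_index",
    "morse",
    "mor_descriptor",
    "whim_directional",
    "hats",
    "compute_six",
    "read_xyz",
    "read_sdf",
]

# --------------------------------------------------------------------------
# atomic weight tables, scaled relative to carbon
#
# 'u' unit weights; 'v' van der Waals volumes from Bondi radii (volume
# ratio (r/r_C)^3, r_C = 1.70 A); 'p' static dipole polarizabilities in
# 1e-24 cm^3 relative to carbon (1.76).  The electrotopological scheme 's'
# is computed per atom from the graph (Kier-Hall intrinsic states), not
# from a table -- see _estate_weights.

_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
_POLARIZABILITY = {
    "H": 0.667, "C": 1.76, "N": 1.10, "O": 0.802, "F": 0.557,
    "P": 3.63, "S": 2.90, "Cl": 2.18, "Br": 3.05, "I": 5.35,
}
#: valence electrons and principal quantum number, for intrinsic states
_VALENCE = {
    "H": (1, 1), "C": (4, 2), "N": (5, 2), "O": (6, 2), "F": (7, 2),
    "P": (5, 3), "S": (6, 3), "Cl": (7, 3), "Br": (7, 4), "I": (7, 5),
}

WEIGHT_SCHEMES = ("u", "v", "p", "s")


class DisconnectedGraphError(ValueError):
    """Topological descriptors need a connected bond graph."""


@dataclass
class Conformer:
    """A single conformer: elements, coordinates (n x 3, Angstrom), bonds.

    Bonds are undirected (i, j) index pairs, 0-based, no self-loops.
    Hydrogens are used if present and never added implicitly.
    """

    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be ({n}, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-loop bond ({i}, {j})")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_atoms, self.n_atoms), dtype=int)
        for i, j in self.bonds:
            A[i, j] = A[j, i] = 1
        return A

    def topological_distances(self) -> np.ndarray:
        """All-pairs shortest-path matrix of the bond graph.

        Raises :class:`DisconnectedGraphError` if any pair is unreachable.
        """
        D = shortest_path(csr_matrix(self.adjacency()), unweighted=True)
        if np.isinf(D).any():
            raise DisconnectedGraphError("bond graph is disconnected")
        return D.astype(int)


@dataclass
class DescriptorVector:
    """The six descriptors of the bitterness model for one conformer."""

    SPAN: float
    MSD: float
    E3s: float
    G3p: float
    HATS8u: float
    Mor11v: float
    degenerate_axis3: bool = field(default=False, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {
            "SPAN": self.SPAN,
            "Mor11v": self.Mor11v,
            "MSD": self.MSD,
            "HATS8u": self.HATS8u,
            "G3p": self.G3p,
            "E3s": self.E3s,
        }


def _estate_weights(conformer: Conformer) -> np.ndarray:
    """Kier-Hall intrinsic states on the hydrogen-depleted graph, C-scaled.

    I = ((2/L)^2 dv + 1) / d with L the principal quantum number, dv the
    valence-electron count minus attached hydrogens, d the heavy-atom
    degree; explicit hydrogens get weight 0.  Scaled by the sp3-CH2
    carbon value 1.25 so a chain carbon weighs ~1.  This approximates the
    (unpublished) electrotopological weighting of commercial descriptor
    software by the intrinsic-state part of the E-state formalism.
    """
    n = conformer.n_atoms
    heavy = [i for i, e in enumerate(conformer.elements) if e != "H"]
    A = conformer.adjacency()
    w = np.zeros(n)
    for i in heavy:
        zv, L = _VALENCE[conformer.elements[i]]
        nbrs = np.flatnonzero(A[i])
        n_h = sum(1 for j in nbrs if conformer.elements[j] == "H")
        d = len([j for j in nbrs if conformer.elements[j] != "H"])
        dv = zv - n_h
        if d == 0:
            d = 1  # isolated heavy atom: treat as monovalent
        w[i] = ((2.0 / L) ** 2 * dv + 1.0) / d
    return w / 1.25


def atomic_weights(conformer: Conformer, scheme: str) -> np.ndarray:
    """Per-atom weights for a scheme in ``{'u', 'v', 'p', 's'}``."""
    if scheme == "u":
        return np.ones(conformer.n_atoms)
    if scheme == "s":
        return _estate_weights(conformer)
    if scheme == "v":
        table = {e: (r / _VDW_RADII["C"]) ** 3 for e, r in _VDW_RADII.items()}
    elif scheme == "p":
        table = {e: p / _POLARIZABILITY["C"] for e, p in _POLARIZABILITY.items()}
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    missing = sorted({e for e in conformer.elements if e not in table})
    if missing:
        raise KeyError(f"no {scheme!r} weights for element(s) {missing}")
    return np.array([table[e] for e in conformer.elements])


def span(conformer: Conformer) -> float:
    """Radius of the smallest centroid-centered enclosing sphere (Angstrom)."""
    centroid = conformer.coords.mean(axis=0)
    return float(np.linalg.norm(conformer.coords - centroid, axis=1).max())


def msd_index(conformer: Conformer) -> float:
    """Balaban mean-square-distance index of the bond graph.

    sqrt( sum_{i != j} d_ij^2 / (A (A - 1)) ) over ordered atom pairs.
    """
    n = conformer.n_atoms
    if n < 2:
        raise ValueError("MSD needs at least 2 atoms")
    D = conformer.topological_distances()
    return float(math.sqrt((D.astype(float) ** 2).sum() / (n * (n - 1))))


def morse(conformer: Conformer, s: float, weight: str = "u") -> float:
    """3D-MoRSE scattering sum at scattering parameter ``s`` (1/Angstrom).

    sum over unordered atom pairs of w_i w_j sin(s r_ij)/(s r_ij); the
    s = 0 kernel is defined as 1, so Mor01 is the sum of weight products.
    """
    n = conformer.n_atoms
    if n < 2:
        return 0.0
    w = atomic_weights(conformer, weight)
    diff = conformer.coords[:, None, :] - conformer.coords[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    if s == 0:
        kernel = np.ones_like(rij)
    else:
        sr = s * rij
        kernel = np.where(sr == 0, 1.0, np.sin(sr) / np.where(sr == 0, 1.0, sr))
    return float(np.sum(w[iu[0]] * w[iu[1]] * kernel))


def mor_descriptor(conformer: Conformer, index: int, weight: str = "u") -> float:
    """MorK by its conventional 1-based name: MorK uses s = K - 1 (1/A).

    ``mor_descriptor(c, 11, 'v')`` is Mor11v (s = 10 / Angstrom).
    """
    if not 1 <= index <= 32:
        raise ValueError("3D-MoRSE index must be in 1..32")
    return morse(conformer, float(index - 1), weight)


@dataclass
class WhimAxes:
    """Directional WHIM indices from weighted-covariance PCA.

    ``eigenvalues`` are the axis variances (descending); ``proportions``
    their shares; ``accessibility`` the per-axis inverse kurtosis of the
    scores (E indices); ``symmetry`` the per-axis information-theoretic
    symmetry (G indices, in (0, 1]).  A rank-deficient third axis is
    reported as 0 with ``degenerate_axis3`` set.
    """

    eigenvalues: np.ndarray
    proportions: np.ndarray
    accessibility: np.ndarray
    symmetry: np.ndarray
    degenerate_axis3: bool


def _axis_symmetry(t: np.ndarray, tol: float) -> float:
    """Information-theoretic symmetry of scores along one axis.

    Atoms with a mirror partner (another atom at the opposite projection,
    or themselves on the axis plane) are 'symmetric'; each unsymmetric
    atom forms its own class.  gamma = 1 / (1 + I) with I the mean
    information content of that partition; gamma = 1 for a fully
    symmetric distribution.
    """
    n = len(t)
    n_s = 0
    for i in range(n):
        if abs(t[i]) <= tol or np.any(np.abs(t + t[i]) <= tol):
            n_s += 1
    n_a = n - n_s
    info = 0.0
    if n_s:
        info -= (n_s / n) * math.log2(n_s / n)
    if n_a:
        info -= n_a * (1.0 / n) * math.log2(1.0 / n)
    return 1.0 / (1.0 + info)


def whim_directional(
    conformer: Conformer, weight: str = "u", symmetry_tol: float = 0.15
) -> WhimAxes:
    """Directional WHIM indices under the chosen atomic-weight scheme.

    The weighted covariance of the centered coordinates is
    diagonalized; scores are the projections of the atoms on its
    eigenvectors.  Eigenvalues below 1e-10 (planar/linear geometries)
    yield accessibility and symmetry 0 on that axis with the degenerate
    flag set rather than an exception, so batch runs survive flat
    molecules.
    """
    n = conformer.n_atoms
    w = atomic_weights(conformer, weight)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError(f"weight scheme {weight!r} has zero total weight")
    mean = (w[:, None] * conformer.coords).sum(axis=0) / wsum
    X = conformer.coords - mean
    S = (w[:, None] * X).T @ X / wsum
    lams, V = np.linalg.eigh(S)
    order = np.argsort(lams)[::-1]
    lams, V = np.clip(lams[order], 0.0, None), V[:, order]
    T = X @ V
    total = lams.sum()
    props = lams / total if total > 0 else np.zeros(3)
    access = np.zeros(3)
    sym = np.zeros(3)
    degenerate = bool(lams[2] <= 1e-10)
    for m in range(3):
        if lams[m] <= 1e-10:
            continue
        q4 = np.sum(T[:, m] ** 4)
        access[m] = float(lams[m] ** 2 * n / q4) if q4 > 0 else 0.0
        sym[m] = _axis_symmetry(T[:, m], symmetry_tol * math.sqrt(lams[m]))
    return WhimAxes(
        eigenvalues=lams,
        proportions=props,
        accessibility=access,
        symmetry=sym,
        degenerate_axis3=degenerate,
    )


def leverages(conformer: Conformer) -> np.ndarray:
    """Diagonal of the molecular influence matrix H = M (M'M)^+ M'.

    M is the matrix of centered coordinates; the pseudo-inverse handles
    planar/linear geometries.  Leverages sum to rank(M) (3 for non-planar
    conformers).
    """
    M = conformer.coords - conformer.coords.mean(axis=0)
    H = M @ np.linalg.pinv(M.T @ M, rcond=1e-10) @ M.T
    return np.clip(np.diag(H), 0.0, None)


def hats(conformer: Conformer, lag: int, weight: str = "u") -> float:
    """GETAWAY leverage autocorrelation HATSk(w) at topological lag k.

    sum over unordered atom pairs at topological distance k of
    (h_i w_i)(h_j w_j); lag 0 sums the squared terms.  HATS8u is lag 8
    with unit weights; it is 0 whenever the graph diameter is below 8.
    """
    if lag < 0:
        raise ValueError("lag must be >= 0")
    h = leverages(conformer) * atomic_weights(conformer, weight)
    D = conformer.topological_distances()
    if lag == 0:
        return float(np.sum(h**2))
    i, j = np.nonzero(np.triu(D == lag, k=1))
    return float(np.sum(h[i] * h[j]))


def compute_six(conformer: Conformer) -> DescriptorVector:
    """Assemble the six descriptors of the bitterness model."""
    whim_s = whim_directional(conformer, "s")
    whim_p = whim_directional(conformer, "p")
    return DescriptorVector(
        SPAN=span(conformer),
        MSD=msd_index(conformer),
        E3s=float(whim_s.accessibility[2]),
        G3p=float(whim_p.symmetry[2]),
        HATS8u=hats(conformer, 8, "u"),
        Mor11v=mor_descriptor(conformer, 11, "v"),
        degenerate_axis3=whim_s.degenerate_axis3 or whim_p.degenerate_axis3,
    )


# --------------------------------------------------------------------------
# conformer readers


def read_xyz(path: str | Path, bonds_path: str | Path | None = None) -> Conformer:
    """Read an XYZ file, with bonds from a sidecar list of 1-based pairs.

    If no sidecar is given, chain connectivity in file order is assumed.
    """
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    elements, coords = [], []
    for line in lines[2 : 2 + n]:
        parts = line.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    if bonds_path is not None:
        bonds = []
        for line in Path(bonds_path).read_text().splitlines():
            parts = line.split()
            if parts:
                bonds.append((int(parts[0]) - 1, int(parts[1]) - 1))
    else:
        bonds = [(i, i + 1) for i in range(n - 1)]
    return Conformer(elements=elements, coords=np.array(coords), bonds=bonds)


def write_xyz(
    conformer: Conformer, path: str | Path, bonds_path: str | Path | None = None
) -> None:
    """Write an XYZ file and, optionally, the sidecar bond list (1-based)."""
    lines = [str(conformer.n_atoms), "generated by qsbr"]
    for e, (x, y, z) in zip(conformer.elements, conformer.coords):
        lines.append(f"{e} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
    if bonds_path is not None:
        Path(bonds_path).write_text(
            "".join(f"{i + 1} {j + 1}\n" for i, j in conformer.bonds)
        )


def read_sdf(path: str | Path) -> list[Conformer]:
    """Read all molecules of an SDF file (coordinates + bonds) via RDKit."""
    from rdkit import Chem  # deferred: only needed for SDF input

    out = []
    for mol in Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False):
        if mol is None:
            continue
        conf = mol.GetConformer()
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        coords = np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        )
        bonds = [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
        ]
        out.append(Conformer(elements=elements, coords=coords, bonds=bonds))
    return out
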