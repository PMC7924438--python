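"""Synthetic imbalanced datasets and toy antigen structures.

The generators here emulate the statistical structure that cluster-based
hybrid resampling assumes: a majority (non-epitope) class spread over
several density modes of unequal size, and a rare minority (epitope)
class, part of whose mass may sit inside majority modes — the hard
boundary regime where plain undersampling loses information and plain
oversampling amplifies ambiguous points.  The default imbalance ratio is
10:1, matching the class ratio observed in surface-residue epitope data.

Toy structures are minimal single-chain PDB files (Cα traces; the
sphere-surface geometry also carries pseudo-side-chain heavy atoms for
contact tests) so the structural feature module is testable without any
external download.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of an imbalanced two-class Gaussian-mixture dataset.

    majority count = round(imbalance_ratio * n_minority).  Majority
    cluster centers are pairwise separated by ``cluster_separation``
    within-cluster standard deviations; ``overlap`` is the fraction of
    minority mass relocated into majority components.
    """

    n_minority: int = 50
    imbalance_ratio: float = 10.0
    n_majority_clusters: int = 3
    dim: int = 12
    cluster_separation: float = 5.0
    overlap: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_minority <= 0:
            raise ValueError("n_minority must be positive")
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1")
        if self.n_majority_clusters <= 0:
            raise ValueError("n_majority_clusters must be positive")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be >= 0")
        if not 0 <= self.overlap <= 1:
            raise ValueError("overlap must lie in [0, 1]")

    @property
    def n_majority(self) -> int:
        return int(round(self.imbalance_ratio * self.n_minority))


@dataclass(frozen=True)
class ToyStructureSpec:
    """Parameters of a toy single-chain antigen structure."""

    n_residues: int = 20
    epitope_fraction: float = 0.2
    geometry: str = "helix"  # helix | sphere_surface | random_coil
    seed: int = 0

    def validate(self) -> None:
        if self.n_residues < 5:
            raise ValueError("n_residues must be >= 5")
        if not 0 < self.epitope_fraction < 1:
            raise ValueError("epitope_fraction must lie in (0, 1)")
        if self.geometry not in ("helix", "sphere_surface", "random_coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _cluster_centers(rng: np.random.Generator, k: int, dim: int,
                     separation: float) -> np.ndarray:
    """k centers with pairwise distance >= separation (unit within-cluster sd)."""
    centers = [np.zeros(dim)]
    while len(centers) < k:
        cand = rng.normal(scale=max(separation, 1.0) * 1.5, size=dim)
        if all(np.linalg.norm(cand - c) >= separation for c in centers):
            centers.append(cand)
    return np.vstack(centers)


def make_imbalanced(spec: SyntheticSpec) -> LabeledDataset:
    """Generate an imbalanced dataset from a multi-modal majority mixture.

    Majority rows are drawn from ``n_majority_clusters`` unit-variance
    Gaussians with Dirichlet(2) mixture weights (unequal cluster sizes,
    so proportional quotas differ across clusters).  Minority rows come
    from a single Gaussian offset from every majority center, except for
    an ``overlap`` fraction relocated into majority components.  The
    generating component id of every majority row is stored in
    ``attrs["majority_component"]`` for cluster-recovery tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_maj = spec.n_majority
    k = spec.n_majority_clusters

    centers = _cluster_centers(rng, k, spec.dim, spec.cluster_separation)
    weights = rng.dirichlet(np.full(k, 2.0))
    comp = rng.choice(k, size=n_maj, p=weights)
    X_maj = centers[comp] + rng.normal(size=(n_maj, spec.dim))

    # minority center: offset from all majority centers
    sep = max(spec.cluster_separation, 1.0)
    while True:
        min_center = centers.mean(axis=0) + rng.normal(scale=1.5 * sep,
                                                       size=spec.dim)
        if all(np.linalg.norm(min_center - c) >= spec.cluster_separation
               for c in centers):
            break
    n_over = int(round(spec.overlap * spec.n_minority))
    n_own = spec.n_minority - n_over
    X_min_own = min_center + rng.normal(size=(n_own, spec.dim))
    over_comp = rng.choice(k, size=n_over, p=weights)
    X_min_over = centers[over_comp] + rng.normal(size=(n_over, spec.dim))

    X = np.vstack([X_min_own, X_min_over, X_maj])
    y = np.concatenate([np.ones(spec.n_minority, dtype=int),
                        np.zeros(n_maj, dtype=int)])
    ds = LabeledDataset(X=X, y=y)
    ds.attrs["majority_component"] = comp
    ds.attrs["spec"] = spec
    return ds


def make_grouped(spec: SyntheticSpec, n_groups: int) -> LabeledDataset:
    """Generate an imbalanced dataset with group ids (pseudo-complexes).

    Rows of each class are dealt round-robin across groups after a
    seeded shuffle, so every group contains at least one positive and
    one negative (requires n_groups <= n_minority).
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if n_groups > spec.n_minority:
        raise ValueError("n_groups cannot exceed n_minority")
    ds = make_imbalanced(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 7919)))
    group = np.empty(len(ds), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(ds.y == cls)
        rng.shuffle(idx)
        group[idx] = 1 + (np.arange(len(idx)) % n_groups)
    ds.group = group
    return ds


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def _helix_ca(n: int) -> np.ndarray:
    # ideal alpha-helix Calpha trace: r=2.3 A, 100 deg/residue, 1.5 A rise
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])


def _sphere_ca(n: int) -> np.ndarray:
    # Fibonacci lattice on a sphere sized so neighbor spacing ~ 5-6 A
    radius = 3.0 * np.sqrt(n)
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5.0)) * i
    return radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _coil_ca(n: int, rng: np.random.Generator) -> np.ndarray:
    # self-avoiding-ish random walk with 3.8 A steps
    pts = [np.zeros(3)]
    while len(pts) < n:
        step = rng.normal(size=3)
        step *= 3.8 / np.linalg.norm(step)
        cand = pts[-1] + step
        if all(np.linalg.norm(cand - p) > 3.0 for p in pts[:-1]):
            pts.append(cand)
    return np.vstack(pts)


def _format_atom(serial: int, name: str, resname: str, resnum: int,
                 xyz: np.ndarray, bfac: float, element: str) -> str:
    return (
        f"ATOM  {serial:5d} {name:^4s}{resname:>4s} A{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{bfac:6.2f}"
        f"          {element:>2s}"
    )


def make_toy_structure(spec: ToyStructureSpec):
    """Build a toy antigen: a ResidueTable and the matching PDB text.

    The epitope is a spatially contiguous patch: the residue farthest
    from the centroid seeds the patch and its round(fraction * n) - 1
    nearest residues (by Cα distance) complete it.  Coordinates and B
    factors are pre-rounded to PDB column precision so re-parsing the
    emitted file reproduces the table exactly.
    """
    from .features import ResidueTable  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.geometry == "helix":
        ca = _helix_ca(n)
    elif spec.geometry == "sphere_surface":
        ca = _sphere_ca(n)
    else:
        ca = _coil_ca(n, rng)
    ca = np.round(ca, 3)

    aa = rng.choice(list(_AA20), size=n)
    bfac = np.round(rng.uniform(10.0, 50.0, size=n), 2)
    rsa = np.round(rng.uniform(0.05, 1.0, size=n), 3)

    # contiguous epitope patch
    n_epi = int(round(spec.epitope_fraction * n))
    seed_res = int(np.argmax(np.linalg.norm(ca - ca.mean(axis=0), axis=1)))
    order = np.argsort(np.linalg.norm(ca - ca[seed_res], axis=1))
    epitope = np.zeros(n, dtype=bool)
    epitope[order[:n_epi]] = True

    heavy: list[np.ndarray] = []
    lines = []
    serial = 1
    b_mean = np.empty(n)
    for i in range(n):
        atoms = [("CA", ca[i], "C")]
        if spec.geometry == "sphere_surface":
            # pseudo side chain pointing outward from the sphere center
            u = ca[i] / np.linalg.norm(ca[i])
            atoms.append(("CB", np.round(ca[i] + 1.5 * u, 3), "C"))
            atoms.append(("CG", np.round(ca[i] + 3.0 * u, 3), "C"))
        coords = np.vstack([a[1] for a in atoms])
        heavy.append(coords)
        b_mean[i] = round(float(bfac[i]), 2)  # all atoms share the residue B
        for name, xyz, elem in atoms:
            lines.append(_format_atom(serial, name, _THREE[aa[i]], i + 1,
                                      xyz, bfac[i], elem))
            serial += 1
    lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    rt = ResidueTable(
        chain=np.full(n, "A", dtype=object),
        resnum=np.arange(1, n + 1),
        aa=aa.astype(object),
        ca=ca,
        b_ca=bfac,
        b_mean=b_mean,
        heavy=heavy,
        rsa=rsa,
        exposed=np.ones(n, dtype=bool),
        epitope=epitope,
    )
    return rt, pdb_text


def write_toy_structure(spec: ToyStructureSpec, path) -> None:
    _, text = make_toy_structure(spec)
    with io.open(path, "w") as fh:
        fh.write(text)
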