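"""Per-residue structural features for conformational epitope prediction.

Works from antigen structures (PDB format) and computes, per surface
residue:

* **CN** — contact number: count of other Cα atoms within a microsphere
  of radius ``radius`` (default 13 Å, the customary half-sphere-exposure
  radius) centered on the residue's Cα.
* **HSE** — half-sphere exposure: the same neighbors split into an
  "up" and a "down" hemisphere by the Cα-only pseudo-side-chain vector
  u_i = (Cα_i − Cα_{i−1}) + (Cα_i − Cα_{i+1}); a neighbor is "up" iff
  its displacement has positive dot product with u_i (ties go down).
* **QSE** — quadrant-sphere exposure: the neighbors split into eight
  octants of a local right-handed frame (e1 along u_i, e2 the chain
  direction Cα_{i+1} − Cα_{i−1} orthogonalized to e1, e3 = e1 × e2);
  sign patterns with zeros resolve to the negative side.
* B factors (Cα and all-atom mean), physicochemical AAindex values,
  and an amino-acid log-odds score contrasting epitope-centered
  9-residue sequence windows against non-epitope windows.

Surface residues are those with relative solvent accessibility (RSA,
supplied as a precomputed column) above 0.01.  Epitope labels come from
antigen–antibody atomic contacts: an antigen residue is an epitope
residue iff any of its heavy atoms lies within 4 Å of any antibody
heavy atom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dataset import LabeledDataset

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 13.0
DEFAULT_RSA_THRESHOLD = 0.01
DEFAULT_CONTACT_DIST = 4.0

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # AAindex1 row order


class PDBParseError(ValueError):
    pass


@dataclass
class ResidueTable:
    """Per-residue structural records for one or more chains."""

    chain: np.ndarray      # chain id, str
    resnum: np.ndarray     # author residue number, int
    aa: np.ndarray         # one-letter amino acid, str
    ca: np.ndarray         # (n, 3) Cα coordinates, Å
    b_ca: np.ndarray       # B factor of Cα
    b_mean: np.ndarray     # mean B over all residue atoms
    heavy: list | None = None    # per-residue (m_i, 3) heavy-atom coords
    rsa: np.ndarray | None = None
    exposed: np.ndarray | None = None
    epitope: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.resnum)
        if not (len(self.chain) == len(self.aa) == len(self.ca) == n):
            raise ValueError("column length mismatch")
        if not np.isfinite(self.ca).all():
            raise ValueError("non-finite coordinates")
        for ch in np.unique(self.chain):
            nums = self.resnum[self.chain == ch]
            if len(np.unique(nums)) != len(nums):
                raise ValueError(f"duplicate residue numbers in chain {ch}")

    def __len__(self) -> int:
        return len(self.resnum)

    def subset(self, mask: np.ndarray) -> "ResidueTable":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return ResidueTable(
            chain=self.chain[idx], resnum=self.resnum[idx], aa=self.aa[idx],
            ca=self.ca[idx], b_ca=self.b_ca[idx], b_mean=self.b_mean[idx],
            heavy=None if self.heavy is None else [self.heavy[i] for i in idx],
            rsa=None if self.rsa is None else self.rsa[idx],
            exposed=None if self.exposed is None else self.exposed[idx],
            epitope=None if self.epitope is None else self.epitope[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "chain": self.chain, "resnum": self.resnum, "aa": self.aa,
            "x": self.ca[:, 0], "y": self.ca[:, 1], "z": self.ca[:, 2],
            "b_ca": self.b_ca, "b_mean": self.b_mean,
        })
        if self.rsa is not None:
            df["rsa"] = self.rsa
        if self.exposed is not None:
            df["exposed"] = self.exposed
        if self.epitope is not None:
            df["epitope"] = self.epitope
        return df


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def parse_pdb(path, chains: list[str] | None = None) -> ResidueTable:
    """Parse ATOM records of the first model into a ResidueTable.

    Alternate locations resolve to the highest-occupancy conformer
    (Biopython's default selection).  Residues without a Cα atom are
    skipped with a log message.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("antigen", path)
    except (PDBConstructionException, ValueError) as exc:
        raise PDBParseError(f"malformed PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise PDBParseError(f"no ATOM records found in {path}")
    model = models[0]  # first model only

    rows: dict[str, list] = {k: [] for k in
                             ("chain", "resnum", "aa", "b_ca", "b_mean")}
    cas, heavies = [], []
    for chain in model:
        if chains is not None and chain.id not in chains:
            continue
        for res in chain:
            if res.id[0].strip():  # skip HETATM / water
                continue
            if "CA" not in res:
                logger.info("residue %s%s lacks a CA atom; skipped",
                            chain.id, res.id[1])
                continue
            atoms = [a for a in res.get_atoms() if a.element != "H"]
            rows["chain"].append(chain.id)
            rows["resnum"].append(res.id[1])
            rows["aa"].append(_THREE_TO_ONE.get(res.get_resname(), "X"))
            # PDB columns carry 2 (B) / 3 (xyz) decimals; round the float32
            # values back to column precision so parsing is exact
            rows["b_ca"].append(round(float(res["CA"].get_bfactor()), 2))
            rows["b_mean"].append(
                round(float(np.mean([a.get_bfactor() for a in atoms])), 2))
            cas.append(np.round(res["CA"].get_coord().astype(float), 3))
            heavies.append(np.round(np.array([a.get_coord() for a in atoms],
                                             dtype=float), 3))
    if not cas:
        raise PDBParseError(f"no parsable residues in {path}")
    return ResidueTable(
        chain=np.array(rows["chain"], dtype=object),
        resnum=np.array(rows["resnum"], dtype=int),
        aa=np.array(rows["aa"], dtype=object),
        ca=np.vstack(cas),
        b_ca=np.array(rows["b_ca"]),
        b_mean=np.array(rows["b_mean"]),
        heavy=heavies,
    )


# ---------------------------------------------------------------------------
# surface filter and microsphere features
# ---------------------------------------------------------------------------

def surface_filter(rt: ResidueTable,
                   threshold: float = DEFAULT_RSA_THRESHOLD) -> ResidueTable:
    """Keep residues with RSA strictly above ``threshold`` (exposed)."""
    if rt.rsa is None:
        raise ValueError("RSA column required for surface filtering")
    keep = rt.rsa > threshold
    out = rt.subset(keep)
    out.exposed = np.ones(len(out), dtype=bool)
    return out


def contact_number(rt: ResidueTable,
                   radius: float = DEFAULT_RADIUS) -> np.ndarray:
    """CN(i) = number of other Cα within ``radius`` Å (inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    tree = cKDTree(rt.ca)
    counts = np.array([len(tree.query_ball_point(p, radius)) - 1
                       for p in rt.ca])
    return counts


def _pseudo_cb(rt: ResidueTable) -> tuple[np.ndarray, np.ndarray]:
    """Cα-only pseudo-side-chain direction per residue; validity mask.

    u_i = (Cα_i − Cα_{i−1}) + (Cα_i − Cα_{i+1}) using sequence
    neighbors within the same chain; termini are invalid.
    """
    n = len(rt)
    u = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    for ch in np.unique(rt.chain):
        idx = np.flatnonzero(rt.chain == ch)
        idx = idx[np.argsort(rt.resnum[idx])]
        if len(idx) < 3:
            continue
        for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
            vec = (rt.ca[b] - rt.ca[a]) + (rt.ca[b] - rt.ca[c])
            if np.linalg.norm(vec) > 1e-9:
                u[b] = vec
                valid[b] = True
    return u, valid


def half_sphere_exposure(rt: ResidueTable, radius: float = DEFAULT_RADIUS
                         ) -> tuple[np.ndarray, np.ndarray]:
    """(up, down) neighbor counts per residue; NaN where no direction.

    up + down = CN at the same radius for every valid residue.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    u, valid = _pseudo_cb(rt)
    tree = cKDTree(rt.ca)
    up = np.full(len(rt), np.nan)
    down = np.full(len(rt), np.nan)
    for i in range(len(rt)):
        if not valid[i]:
            continue
        nbrs = [j for j in tree.query_ball_point(rt.ca[i], radius) if j != i]
        d = rt.ca[nbrs] - rt.ca[i] if nbrs else np.empty((0, 3))
        # ties (dot == 0) count down; the tolerance keeps exact-plane
        # neighbors on the same side after a rigid motion of the input
        above = (d @ (u[i] / np.linalg.norm(u[i]))) > 1e-6
        up[i] = int(above.sum())
        down[i] = len(nbrs) - up[i]
    return up, down


def _local_frame(rt: ResidueTable) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed (e1, e2, e3) frame per residue; validity mask."""
    u, valid = _pseudo_cb(rt)
    n = len(rt)
    frames = np.full((n, 3, 3), np.nan)
    ok = np.zeros(n, dtype=bool)
    for ch in np.unique(rt.chain):
        idx = np.flatnonzero(rt.chain == ch)
        idx = idx[np.argsort(rt.resnum[idx])]
        for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
            if not valid[b]:
                continue
            e1 = u[b] / np.linalg.norm(u[b])
            t = rt.ca[c] - rt.ca[a]
            t = t - (t @ e1) * e1
            nt = np.linalg.norm(t)
            if nt < 1e-9:  # collinear: no well-defined frame
                continue
            e2 = t / nt
            e3 = np.cross(e1, e2)
            frames[b] = np.vstack([e1, e2, e3])
            ok[b] = True
    return frames, ok


def quadrant_sphere_exposure(rt: ResidueTable, radius: float = DEFAULT_RADIUS
                             ) -> np.ndarray:
    """(n, 8) octant neighbor counts; NaN rows where the frame is degenerate.

    Octant index packs the sign bits of the neighbor's (e1, e2, e3)
    coordinates — bit 2 for e1 > 0, bit 1 for e2 > 0, bit 0 for e3 > 0;
    exact zeros resolve to the negative side.  Row sums equal CN.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    frames, ok = _local_frame(rt)
    tree = cKDTree(rt.ca)
    out = np.full((len(rt), 8), np.nan)
    for i in range(len(rt)):
        if not ok[i]:
            continue
        nbrs = [j for j in tree.query_ball_point(rt.ca[i], radius) if j != i]
        counts = np.zeros(8)
        for j in nbrs:
            coords = frames[i] @ (rt.ca[j] - rt.ca[i])
            # zeros resolve to the negative side, with the same
            # rigid-motion-stable tolerance as the hemisphere split
            octant = ((coords[0] > 1e-6) << 2) | ((coords[1] > 1e-6) << 1) \
                | (coords[2] > 1e-6)
            counts[octant] += 1
        out[i] = counts
    return out


# ---------------------------------------------------------------------------
# epitope annotation
# ---------------------------------------------------------------------------

def annotate_epitopes(antigen: ResidueTable, antibody_atoms: np.ndarray,
                      max_dist: float = DEFAULT_CONTACT_DIST) -> np.ndarray:
    """Boolean epitope flag per antigen residue from heavy-atom contacts.

    A residue is an epitope residue iff any of its heavy atoms lies
    within ``max_dist`` Å of any antibody heavy atom.
    """
    if antigen.heavy is None:
        raise ValueError("antigen heavy-atom coordinates required")
    antibody_atoms = np.asarray(antibody_atoms, dtype=float)
    if antibody_atoms.size == 0:
        raise ValueError("antibody atom set is empty")
    tree = cKDTree(antibody_atoms)
    flags = np.zeros(len(antigen), dtype=bool)
    for i, atoms in enumerate(antigen.heavy):
        if len(atoms) == 0:
            continue
        d, _ = tree.query(atoms)
        flags[i] = bool((d <= max_dist).any())
    return flags


# ---------------------------------------------------------------------------
# AAindex physicochemical features
# ---------------------------------------------------------------------------

@dataclass
class AAIndexTable:
    """Physicochemical indices parsed from an AAindex1 flat file."""

    indices: dict[str, dict[str, float]]
    imputed: dict[str, list[str]] = field(default_factory=dict)

    def __getitem__(self, index_id: str) -> dict[str, float]:
        return self.indices[index_id]


def parse_aaindex1(path) -> AAIndexTable:
    """Parse AAindex1 'H' (accession) and 'I' (value) blocks.

    The I block lists 20 values in the canonical two-row layout
    (A R N D C Q E G H I / L K M F P S T W Y V).  'NA' entries are
    imputed with the index mean and recorded in ``imputed``.
    """
    indices: dict[str, dict[str, float]] = {}
    imputed: dict[str, list[str]] = {}
    acc = None
    values: list[float | None] = []
    in_i = False

    def _commit():
        nonlocal acc, values, in_i
        if acc is None or len(values) != 20:
            acc, values, in_i = None, [], False
            return
        present = [v for v in values if v is not None]
        mean = float(np.mean(present)) if present else 0.0
        table = {}
        missing = []
        for aa, v in zip(AA_ORDER, values):
            if v is None:
                table[aa] = mean
                missing.append(aa)
            else:
                table[aa] = v
        indices[acc] = table
        if missing:
            imputed[acc] = missing
        acc, values, in_i = None, [], False

    with open(path) as fh:
        for line in fh:
            if line.startswith("H "):
                acc = line.split()[1]
            elif line.startswith("I "):
                in_i = True
            elif in_i and line.startswith(" "):
                for tok in line.split():
                    values.append(None if tok == "NA" else float(tok))
            elif line.startswith("//"):
                _commit()
    _commit()
    if not indices:
        raise ValueError(f"no AAindex1 entries found in {path}")
    return AAIndexTable(indices=indices, imputed=imputed)


def aaindex_features(rt: ResidueTable, table: AAIndexTable,
                     index_ids: list[str]) -> pd.DataFrame:
    """Per-residue lookup of the selected physicochemical indices."""
    cols = {}
    for idx in index_ids:
        if idx not in table.indices:
            raise KeyError(f"unknown AAindex id {idx!r}")
        mapping = table.indices[idx]
        mean = float(np.mean(list(mapping.values())))
        vals = np.empty(len(rt))
        for i, aa in enumerate(rt.aa):
            if aa in mapping:
                vals[i] = mapping[aa]
            else:
                warnings.warn(f"unknown amino acid {aa!r}; imputing "
                              f"{idx} with the index mean")
                vals[i] = mean
        cols[f"aaindex_{idx}"] = vals
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# sequence log-odds
# ---------------------------------------------------------------------------

@dataclass
class LogOddsModel:
    """Per-amino-acid log2 odds of epitope-window vs background enrichment."""

    scores: dict[str, float]
    window: int = 9
    center: int = 5  # 1-based position within the window
    pseudocount: float = 1.0


def fit_log_odds(sequences: list[str], epitope_labels: list[np.ndarray],
                 exposed_flags: list[np.ndarray], window: int = 9,
                 center: int = 5, pseudocount: float = 1.0) -> LogOddsModel:
    """Amino-acid log-odds from epitope-centered vs non-epitope windows.

    A sliding window of ``window`` residues runs over each sequence;
    a window enters the counts only if its center residue (1-based
    position ``center``) is exposed, and is classed epitope or
    non-epitope by the center's label.  For amino acid a,

        score(a) = log2 p_epi(a) − log2 p_non(a)

    with Laplace-smoothed frequencies p(a) = (count + pc) / (total + 20 pc).
    """
    if window % 2 != 1:
        raise ValueError("window length must be odd")
    if not 1 <= center <= window:
        raise ValueError("center must lie within the window")
    epi_counts = {aa: 0 for aa in AA_ORDER}
    non_counts = {aa: 0 for aa in AA_ORDER}
    n_epi = n_non = 0
    for seq, lab, exp in zip(sequences, epitope_labels, exposed_flags):
        lab = np.asarray(lab, dtype=bool)
        exp = np.asarray(exp, dtype=bool)
        if not (len(seq) == len(lab) == len(exp)):
            raise ValueError("sequence/label/exposure length mismatch")
        for start in range(len(seq) - window + 1):
            c = start + center - 1
            if not exp[c]:
                continue
            counts = epi_counts if lab[c] else non_counts
            for aa in seq[start:start + window]:
                if aa in counts:
                    counts[aa] += 1
            if lab[c]:
                n_epi += 1
            else:
                n_non += 1
    if n_epi == 0 or n_non == 0:
        raise ValueError("need at least one eligible window of each class")
    tot_epi = sum(epi_counts.values())
    tot_non = sum(non_counts.values())
    pc = pseudocount
    scores = {
        aa: float(np.log2((epi_counts[aa] + pc) / (tot_epi + 20 * pc))
                  - np.log2((non_counts[aa] + pc) / (tot_non + 20 * pc)))
        for aa in AA_ORDER
    }
    return LogOddsModel(scores=scores, window=window, center=center,
                        pseudocount=pc)


def score_log_odds(model: LogOddsModel, sequence: str) -> np.ndarray:
    """Map each residue of a sequence to its amino-acid log-odds score."""
    return np.array([model.scores.get(aa, 0.0) for aa in sequence])


# ---------------------------------------------------------------------------
# feature table assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureOptions:
    include_cn: bool = True
    include_hse: bool = True
    include_qse: bool = True
    include_bfactor: bool = True
    radius: float = DEFAULT_RADIUS
    aaindex_ids: tuple[str, ...] = ()
    aaindex_table: AAIndexTable | None = None
    log_odds: LogOddsModel | None = None
    psaia: pd.DataFrame | None = None  # precomputed, keyed (chain, resnum)


def build_feature_table(rt: ResidueTable,
                        options: FeatureOptions = FeatureOptions()
                        ) -> LabeledDataset:
    """Assemble the per-residue feature matrix with epitope labels.

    Expects a surface-filtered table; residues whose HSE/QSE is
    undefined (termini, degenerate frames) get zero in those columns.
    Precomputed solvent-accessibility/geometry columns (e.g. ASA, RSA,
    depth and protrusion indices) are passed through by (chain, resnum).
    """
    if rt.epitope is None:
        raise ValueError("epitope labels required (run annotate_epitopes)")
    cols: dict[str, np.ndarray] = {}
    if options.include_cn:
        cols["cn"] = contact_number(rt, options.radius).astype(float)
    if options.include_hse:
        up, down = half_sphere_exposure(rt, options.radius)
        cols["hse_up"] = np.nan_to_num(up)
        cols["hse_down"] = np.nan_to_num(down)
    if options.include_qse:
        qse = quadrant_sphere_exposure(rt, options.radius)
        for k in range(8):
            cols[f"qse_{k + 1}"] = np.nan_to_num(qse[:, k])
    if options.include_bfactor:
        cols["b_ca"] = rt.b_ca.astype(float)
        cols["b_mean"] = rt.b_mean.astype(float)
    if options.aaindex_ids:
        if options.aaindex_table is None:
            raise ValueError("aaindex_table required with aaindex_ids")
        aai = aaindex_features(rt, options.aaindex_table,
                               list(options.aaindex_ids))
        for c in aai.columns:
            cols[c] = aai[c].to_numpy()
    if options.log_odds is not None:
        cols["log_odds"] = score_log_odds(options.log_odds, "".join(rt.aa))
    if options.psaia is not None:
        merged = pd.DataFrame({"chain": rt.chain, "resnum": rt.resnum}).merge(
            options.psaia, on=["chain", "resnum"], how="left", validate="1:1")
        extra = [c for c in options.psaia.columns
                 if c not in ("chain", "resnum")]
        if merged[extra].isna().any().any():
            raise ValueError("precomputed table does not cover all residues")
        for c in extra:
            cols[c] = merged[c].to_numpy(dtype=float)
    if not cols:
        raise ValueError("no features selected")
    X = np.column_stack(list(cols.values()))
    return LabeledDataset(X=X, y=rt.epitope.astype(int),
                          group=rt.chain.copy(),
                          feature_names=list(cols.keys()))
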