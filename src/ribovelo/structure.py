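"""Per-residue protein structure features from predicted 3D models.

Four features drive the downstream association analysis:

* 3-class secondary structure (H/E/C) from Kabsch--Sander hydrogen-bond
  energies (the algorithm at the core of DSSP), collapsed 8-to-3.
* Solvent accessible surface area (Shrake--Rupley with deterministic
  golden-spiral sphere points) and its relative form rASA.
* A per-residue disorder score in [0, 1], by default a smoothed
  transform of pLDDT (AlphaFold-style models store pLDDT in the
  B-factor column), optionally replaced by external predictor output.
* Local absolute contact order: the mean absolute sequence separation
  of a residue's 3D contacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .constants import AA1_TO_AA3, AA3_TO_AA1, MAX_ASA, VDW_RADII

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Kabsch-Sander electrostatic H-bond model constants
_KS_Q1Q2_F = 0.084 * 332.0  # = 27.888 kcal/mol * A
_KS_CUTOFF = -0.5  # kcal/mol
_PEPTIDE_BOND_MAX = 2.5  # A; C(i-1)-N(i) farther than this is a chain break


class StructureError(ValueError):
    """Raised for malformed or unsupported structure files."""


@dataclass
class ProteinStructure:
    """A single-chain protein model: residues, heavy atoms, pLDDT.

    Atoms are stored in flat arrays; ``atom_res_index`` maps each atom to
    its 0-based residue position. ``res_ids`` are the (1-based, strictly
    increasing) author residue numbers.
    """

    gene_id: str
    res_ids: np.ndarray          # (R,) int
    res_names: np.ndarray        # (R,) 1-letter amino-acid codes
    plddt: np.ndarray            # (R,) float in [0, 100]
    atom_res_index: np.ndarray   # (A,) int, 0-based into residues
    atom_names: np.ndarray       # (A,) str
    elements: np.ndarray         # (A,) str
    coords: np.ndarray           # (A, 3) float, Angstrom
    radii: np.ndarray = field(default=None)  # (A,) vdW radii, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.radii is None:
            self.radii = np.array(
                [VDW_RADII.get(e, 1.70) for e in self.elements], dtype=float
            )
        if len(self.res_ids) == 0:
            raise StructureError(f"{self.gene_id}: structure has no residues")
        if not np.all(np.diff(self.res_ids) > 0):
            raise StructureError(f"{self.gene_id}: residue ids not strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"{self.gene_id}: non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)

    def sequence(self) -> str:
        return "".join(self.res_names)

    def backbone_coords(self, atom_name: str, required: bool = False) -> np.ndarray:
        """(R, 3) coordinates of one backbone atom type; NaN where absent."""
        out = np.full((self.n_residues, 3), np.nan)
        mask = self.atom_names == atom_name
        out[self.atom_res_index[mask]] = self.coords[mask]
        if required:
            missing = np.where(np.isnan(out[:, 0]))[0]
            if missing.size:
                rid = self.res_ids[missing[0]]
                raise StructureError(
                    f"{self.gene_id}: residue {rid} lacks backbone atom {atom_name}"
                )
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Rigidly transformed copy (used for invariance checks)."""
        return ProteinStructure(
            gene_id=self.gene_id,
            res_ids=self.res_ids.copy(),
            res_names=self.res_names.copy(),
            plddt=self.plddt.copy(),
            atom_res_index=self.atom_res_index.copy(),
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            radii=self.radii.copy(),
        )


# ---------------------------------------------------------------------------
# File I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _from_atom_array(gene_id: str, array) -> ProteinStructure:
    import biotite.structure as bst

    array = array[array.element != "H"]
    chains = np.unique(array.chain_id)
    if len(chains) > 1:
        raise StructureError(
            f"{gene_id}: multi-chain file not supported (chains {list(chains)})"
        )
    res_starts = bst.get_residue_starts(array)
    res_ids = array.res_id[res_starts].astype(int)
    res_names3 = array.res_name[res_starts]
    try:
        res_names = np.array([AA3_TO_AA1[n] for n in res_names3])
    except KeyError as exc:
        raise StructureError(f"{gene_id}: unknown residue name {exc}") from exc
    plddt = array.b_factor[res_starts].astype(float)
    atom_res_index = np.repeat(
        np.arange(len(res_starts)),
        np.diff(np.append(res_starts, len(array))),
    )
    struct = ProteinStructure(
        gene_id=gene_id,
        res_ids=res_ids,
        res_names=res_names,
        plddt=plddt,
        atom_res_index=atom_res_index,
        atom_names=array.atom_name.copy(),
        elements=array.element.copy(),
        coords=array.coord.copy(),
    )
    # fail early on incomplete backbones; O checked at H-bond time
    for name in ("N", "CA", "C"):
        struct.backbone_coords(name, required=True)
    return struct


def load_structure(path: str | Path, gene_id: str | None = None) -> ProteinStructure:
    """Read a single-chain PDB or mmCIF model; pLDDT from the B-factor column."""
    import biotite.structure.io.pdb as pdbio
    import biotite.structure.io.pdbx as pdbxio

    path = Path(path)
    gene_id = gene_id or path.stem
    if path.suffix.lower() in (".cif", ".mmcif"):
        cif = pdbxio.CIFFile.read(str(path))
        array = pdbxio.get_structure(cif, model=1, extra_fields=["b_factor"])
    else:
        pdb = pdbio.PDBFile.read(str(path))
        array = pdb.get_structure(model=1, extra_fields=["b_factor"])
    return _from_atom_array(gene_id, array)


def write_structure(struct: ProteinStructure, path: str | Path) -> None:
    """Write as PDB with per-residue pLDDT in the B-factor column."""
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdbio

    n = len(struct.atom_names)
    array = bst.AtomArray(n)
    array.coord = struct.coords.astype(np.float32)
    array.chain_id = np.full(n, "A")
    array.res_id = struct.res_ids[struct.atom_res_index]
    array.res_name = np.array(
        [AA1_TO_AA3[struct.res_names[i]] for i in struct.atom_res_index]
    )
    array.atom_name = struct.atom_names
    array.element = struct.elements
    array.hetero = np.zeros(n, dtype=bool)
    array.set_annotation("b_factor", struct.plddt[struct.atom_res_index])
    pdb = pdbio.PDBFile()
    pdb.set_structure(array)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander)
# ---------------------------------------------------------------------------

def _hbond_matrix(struct: ProteinStructure) -> np.ndarray:
    """don_acc[d, a]: backbone N-H of residue d donates to C=O of residue a.

    E = 27.888 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol, bond iff
    E < -0.5.  The amide H is placed 1.0 A from N along the previous
    residue's C=O direction (O->C); the chain's first residue, residues
    after a chain break, and prolines have no donor H.
    """
    N = struct.backbone_coords("N", required=True)
    C = struct.backbone_coords("C", required=True)
    O = struct.backbone_coords("O", required=True)
    R = struct.n_residues

    seq_break = np.zeros(R, dtype=bool)
    seq_break[0] = True
    if R > 1:
        gap = struct.res_ids[1:] - struct.res_ids[:-1] != 1
        far = np.linalg.norm(N[1:] - C[:-1], axis=1) > _PEPTIDE_BOND_MAX
        seq_break[1:] = gap | far

    H = np.full((R, 3), np.nan)
    ok = ~seq_break
    co_dir = C[:-1] - O[:-1]
    co_dir /= np.linalg.norm(co_dir, axis=1, keepdims=True)
    H[1:][ok[1:]] = N[1:][ok[1:]] + co_dir[ok[1:]]
    H[struct.res_names == "P"] = np.nan  # proline has no amide H

    with np.errstate(divide="ignore", invalid="ignore"):
        r_on = cdist(O, N)
        r_cn = cdist(C, N)
        r_oh = cdist(O, H)
        r_ch = cdist(C, H)
        energy = _KS_Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    energy = np.nan_to_num(energy, nan=0.0, posinf=0.0, neginf=0.0)
    # energy[a, d] currently indexed acceptor-first; transpose to don_acc
    don_acc = (energy.T < _KS_CUTOFF)
    # exclude self and directly bonded neighbours
    idx = np.arange(R)
    near = np.abs(idx[:, None] - idx[None, :]) < 2
    don_acc[near] = False
    return don_acc


def assign_secondary_structure(struct: ProteinStructure) -> np.ndarray:
    """Per-residue 3-class secondary structure (H/E/C).

    Helix: two consecutive i -> i+n turns (n = 4, with 3_10 and pi
    turns collapsed in) mark residues i..i+n-1. Strand: Kabsch-Sander
    parallel/antiparallel bridge patterns. H takes precedence over E;
    everything else is coil.
    """
    R = struct.n_residues
    ss = np.full(R, "C", dtype="<U1")
    if R < 5:
        return ss
    hb = _hbond_matrix(struct)  # hb[donor, acceptor]

    is_e = np.zeros(R, dtype=bool)
    is_h = np.zeros(R, dtype=bool)

    # turns: C=O of i accepts from N-H of i+n  ->  hb[i+n, i]
    for n in (4, 3, 5):
        turn = np.zeros(R, dtype=bool)
        valid = np.arange(R - n)
        turn[valid] = hb[valid + n, valid]
        for i in range(1, R - n):
            if turn[i - 1] and turn[i]:
                is_h[i : i + n] = True

    # bridges: stretches i-1,i,i+1 and j-1,j,j+1, |i-j| >= 3
    for i in range(1, R - 1):
        for j in range(i + 3, R - 1):
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            antipar = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or antipar:
                is_e[i] = True
                is_e[j] = True

    ss[is_e] = "E"
    ss[is_h] = "H"  # H wins over E
    return ss


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _golden_spiral_points(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (deterministic)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_asa(
    struct: ProteinStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-residue solvent accessible surface area (A^2).

    Each atom's sphere of radius (vdW + probe) is sampled at ``n_points``
    golden-spiral points; a point is exposed if it lies outside every
    other atom's augmented sphere. Residue ASA sums its atoms.
    """
    if n_points < 10:
        raise ValueError(f"n_points must be >= 10, got {n_points}")
    sphere = _golden_spiral_points(n_points)
    aug = struct.radii + probe_radius
    coords = struct.coords
    n_atoms = len(coords)
    tree = cKDTree(coords)
    max_aug = aug.max()

    atom_area = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + aug[i] * sphere
        neighbors = tree.query_ball_point(coords[i], aug[i] + max_aug)
        neighbors = [j for j in neighbors if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(pts - coords[j], axis=1)
            exposed &= d >= aug[j]
            if not exposed.any():
                break
        atom_area[i] = exposed.sum() / n_points * 4.0 * np.pi * aug[i] ** 2

    asa = np.zeros(struct.n_residues)
    np.add.at(asa, struct.atom_res_index, atom_area)
    return asa


def relative_asa(asa: float | np.ndarray, amino_acid: str | np.ndarray) -> np.ndarray:
    """rASA = ASA / max-ASA(aa), clipped to [0, 1]."""
    aas = np.atleast_1d(np.asarray(amino_acid))
    unknown = [a for a in np.unique(aas) if a not in MAX_ASA]
    if unknown:
        raise ValueError(f"unknown amino-acid code(s): {unknown}")
    maxima = np.array([MAX_ASA[a] for a in aas])
    out = np.clip(np.atleast_1d(np.asarray(asa, dtype=float)) / maxima, 0.0, 1.0)
    return out if out.size > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Disorder and contact order
# ---------------------------------------------------------------------------

def disorder_scores(
    struct: ProteinStructure,
    external_scores: np.ndarray | None = None,
    window: int = 15,
) -> np.ndarray:
    """Per-residue disorder score in [0, 1].

    External predictor scores pass through unchanged (after a range
    check). Otherwise the score is a centered moving average (window
    truncated at the termini) of 1 - pLDDT/100: low-confidence stretches
    of predicted models behave like disordered segments.
    """
    if external_scores is not None:
        scores = np.asarray(external_scores, dtype=float)
        if len(scores) != struct.n_residues:
            raise ValueError("external score length does not match residue count")
        if np.any((scores < 0) | (scores > 1)) or not np.all(np.isfinite(scores)):
            raise ValueError("external disorder scores must lie in [0, 1]")
        return scores
    raw = 1.0 - struct.plddt / 100.0
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    n = len(raw)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def local_absolute_contact_order(
    struct: ProteinStructure,
    cutoff: float = 6.0,
    min_separation: int = 2,
) -> np.ndarray:
    """Mean |i - j| over residues j contacting residue i; NaN if none.

    A contact is any heavy-atom pair within ``cutoff`` A between residues
    at least ``min_separation`` apart in sequence. "Absolute": not
    normalized by chain length.
    """
    tree = cKDTree(struct.coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    laco = np.full(struct.n_residues, np.nan)
    if len(pairs) == 0:
        return laco
    ri = struct.atom_res_index[pairs[:, 0]]
    rj = struct.atom_res_index[pairs[:, 1]]
    keep = np.abs(ri - rj) >= min_separation
    if not keep.any():
        return laco
    contact = np.unique(np.sort(np.column_stack([ri[keep], rj[keep]]), axis=1), axis=0)
    seps = np.abs(contact[:, 0] - contact[:, 1]).astype(float)
    sums = np.zeros(struct.n_residues)
    counts = np.zeros(struct.n_residues)
    for col in (0, 1):
        np.add.at(sums, contact[:, col], seps)
        np.add.at(counts, contact[:, col], 1.0)
    has = counts > 0
    laco[has] = sums[has] / counts[has]
    return laco


# ---------------------------------------------------------------------------
# Feature table
# ---------------------------------------------------------------------------

def residue_feature_table(
    struct: ProteinStructure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    contact_cutoff: float = 6.0,
    min_separation: int = 2,
    idr_window: int = 15,
    external_idr: np.ndarray | None = None,
) -> pd.DataFrame:
    """All four per-residue features for one structure, as a tidy frame."""
    ss3 = assign_secondary_structure(struct)
    asa = shrake_rupley_asa(struct, probe_radius=probe_radius, n_points=n_points)
    rasa = np.asarray(
        [relative_asa(a, aa) for a, aa in zip(asa, struct.res_names)], dtype=float
    )
    idr = disorder_scores(struct, external_scores=external_idr, window=idr_window)
    laco = local_absolute_contact_order(
        struct, cutoff=contact_cutoff, min_separation=min_separation
    )
    return pd.DataFrame(
        {
            "gene_id": struct.gene_id,
            "residue_index": struct.res_ids,
            "aa": struct.res_names,
            "ss3": ss3,
            "asa": asa,
            "rasa": rasa,
            "idr": idr,
            "laco": laco,
        }
    )
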