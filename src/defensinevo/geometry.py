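"""Dimer-interface superposition and flexibility metrics.

α-defensin dimers are held together by four intermolecular backbone hydrogen
bonds between residues 18 and 20 of each chain (HNP4 numbering). Structures
are therefore superposed on the backbone atoms of those interface residues,
and per-frame flexibility is summarized by two Cα distances and one Cα
dihedral involving the distal loop residues 11 and 22:

* d22 = |A22Cα - B22Cα|   (interface separation; stable in a intact dimer)
* d11 = |A11Cα - B11Cα|   (loop-tip separation; reports loop flexibility)
* dihedral A11Cα-A22Cα-B22Cα-B11Cα  (relative twist of the two monomers)

Structures may carry a numbering map translating their own residue numbers
onto the HNP4 reference numbering used by these definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

BACKBONE_ATOMS = ("N", "CA", "C", "O")
INTERFACE_RESIDUES = (18, 20)


class MissingAtomsError(KeyError):
    """Raised when required atoms are absent; lists every absence."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        super().__init__("missing atoms: " + ", ".join(self.missing))


@dataclass
class DimerStructure:
    """Two-chain coordinate set with optional HNP4 numbering maps.

    ``chains`` maps chain id -> residue number -> atom name -> xyz (Å).
    The first two chain ids in ``chain_order`` play the roles of A and B.
    ``numbering_map`` (per chain) translates reference (HNP4) residue
    numbers to structure residue numbers; identity when omitted.
    """

    chains: dict[str, dict[int, dict[str, np.ndarray]]]
    chain_order: tuple[str, str]
    numbering_map: Optional[dict[str, dict[int, int]]] = None
    frame: int = 1

    def __post_init__(self) -> None:
        if len(self.chain_order) != 2:
            raise ValueError("a dimer needs exactly two chains")
        for cid in self.chain_order:
            if cid not in self.chains:
                raise ValueError(f"chain {cid!r} not present in structure")

    def _struct_resnum(self, chain_id: str, ref_resnum: int) -> int:
        if self.numbering_map and chain_id in self.numbering_map:
            try:
                return self.numbering_map[chain_id][ref_resnum]
            except KeyError:
                raise MissingAtomsError(
                    [f"{chain_id}:{ref_resnum} (no numbering-map entry)"]
                ) from None
        return ref_resnum

    def atom(self, role: str, ref_resnum: int, atom_name: str) -> np.ndarray:
        """Coordinates of an atom addressed by dimer role 'A'/'B', HNP4
        residue number and atom name."""
        chain_id = self.chain_order[0 if role == "A" else 1]
        resnum = self._struct_resnum(chain_id, ref_resnum)
        try:
            return self.chains[chain_id][resnum][atom_name]
        except KeyError:
            raise MissingAtomsError([f"{role}{ref_resnum}:{atom_name}"]) from None

    def selection_coords(
        self,
        residues: Sequence[int] = INTERFACE_RESIDUES,
        atoms: Sequence[str] = BACKBONE_ATOMS,
    ) -> np.ndarray:
        """Stacked coordinates of the given residues/atoms in both chains, in
        a fixed (role, residue, atom) order."""
        coords = []
        missing = []
        for role in ("A", "B"):
            for res in residues:
                for name in atoms:
                    try:
                        coords.append(self.atom(role, res, name))
                    except MissingAtomsError as err:
                        missing.extend(err.missing)
        if missing:
            raise MissingAtomsError(missing)
        return np.array(coords)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "DimerStructure":
        """Copy with every atom mapped to R·x + t."""
        new_chains = {
            cid: {
                res: {name: rotation @ xyz + translation for name, xyz in atoms.items()}
                for res, atoms in residues.items()
            }
            for cid, residues in self.chains.items()
        }
        return DimerStructure(new_chains, self.chain_order, self.numbering_map, self.frame)

    def with_jitter(
        self, rng: np.random.Generator, sigma_of_residue, frame: int
    ) -> "DimerStructure":
        """Copy with isotropic Gaussian jitter; per-residue σ from callable."""
        new_chains = {}
        for cid, residues in self.chains.items():
            new_res = {}
            for res, atoms in residues.items():
                sigma = sigma_of_residue(cid, res)
                new_res[res] = {
                    name: xyz + rng.normal(0.0, sigma, size=3) if sigma > 0 else xyz.copy()
                    for name, xyz in atoms.items()
                }
            new_chains[cid] = new_res
        return DimerStructure(new_chains, self.chain_order, self.numbering_map, frame)


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, structure: DimerStructure) -> DimerStructure:
        return structure.transformed(self.rotation, self.translation)


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Optimal rigid-body fit of ``mobile`` onto ``reference`` (orthogonal
    Procrustes via SVD, proper rotation enforced)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = (R @ mobile.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return Superposition(R, t, rmsd)


def superpose_interface(
    mobile: DimerStructure,
    reference: DimerStructure,
    residues: Sequence[int] = INTERFACE_RESIDUES,
    atoms: Sequence[str] = BACKBONE_ATOMS,
) -> Superposition:
    """Rigid-body fit of ``mobile`` onto ``reference`` over the dimer
    interface (default: backbone N, CA, C, O of residues 18 and 20 in both
    chains, HNP4 numbering)."""
    P = mobile.selection_coords(residues, atoms)
    Q = reference.selection_coords(residues, atoms)
    return kabsch(P, Q)


def torsion_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral (degrees, in (-180, 180]) of four points using the
    standard atan2 torsion formula."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


@dataclass(frozen=True)
class DimerFrameMetrics:
    """Flexibility metrics of one trajectory frame."""

    frame: int
    d22: float
    d11: float
    dihedral: float


def frame_metrics(structure: DimerStructure) -> DimerFrameMetrics:
    """Extract d22, d11 and the A11-A22-B22-B11 Cα dihedral from a frame."""
    a11 = structure.atom("A", 11, "CA")
    a22 = structure.atom("A", 22, "CA")
    b22 = structure.atom("B", 22, "CA")
    b11 = structure.atom("B", 11, "CA")
    d22 = float(np.linalg.norm(a22 - b22))
    d11 = float(np.linalg.norm(a11 - b11))
    dih = torsion_angle(a11, a22, b22, b11)
    return DimerFrameMetrics(structure.frame, d22, d11, dih)


def trajectory_metrics(frames: Iterable[DimerStructure]) -> pd.DataFrame:
    """Per-frame metrics table with columns frame, d22, d11, dihedral."""
    rows = [frame_metrics(s) for s in frames]
    if not rows:
        raise ValueError("empty trajectory")
    return pd.DataFrame(
        {
            "frame": [r.frame for r in rows],
            "d22": [r.d22 for r in rows],
            "d11": [r.d11 for r in rows],
            "dihedral": [r.dihedral for r in rows],
        }
    )


def trajectory_summary(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD, min and max per metric over a trajectory.

    The dihedral is summarized on its absolute value (the per-frame signed
    values stay in the frame table); a single-frame trajectory has SD 0.
    """
    if len(metrics) == 0:
        raise ValueError("empty trajectory")
    cols = {"d22": metrics["d22"], "d11": metrics["d11"],
            "abs_dihedral": metrics["dihedral"].abs()}
    rows = []
    for name, series in cols.items():
        sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
        rows.append(
            {
                "metric": name,
                "mean": float(series.mean()),
                "sd": sd,
                "min": float(series.min()),
                "max": float(series.max()),
            }
        )
    return pd.DataFrame(rows)
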