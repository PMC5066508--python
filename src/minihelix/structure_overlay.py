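"""Rigid superposition of tRNA arm backbones (Kabsch) from PDB coordinates.

The anticodon arm and the T arm of cloverleaf tRNA are both 17-residue
stem-loops; superposing their backbones measures their structural homology.
Backbone point sets are read from PDB files (default atom set P, O5', C5',
C4', C3', O3' -- six atoms per residue), matched ordinally (i-th point to
i-th point, stem on stem and loop on loop), and superposed by the Kabsch
algorithm: the least-squares optimal proper rotation is obtained from the
SVD of the cross-covariance of the centered point sets, with a sign
correction that forbids reflections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "BackboneSelection",
    "SuperpositionResult",
    "ATOM_SETS",
    "read_backbone",
    "kabsch_superpose",
    "overlay_ac_vs_t",
]

ATOM_SETS = {
    "backbone6": ("P", "O5'", "C5'", "C4'", "C3'", "O3'"),
    "p": ("P",),
}


@dataclass(frozen=True)
class BackboneSelection:
    """Ordered backbone points for a contiguous residue range of one chain."""

    points: np.ndarray = field(repr=False)  # shape (n, 3), Angstrom
    labels: tuple[tuple[int, str], ...]     # (residue number, atom name) per point
    chain: str
    residue_range: tuple[int, int]
    atom_names: tuple[str, ...]
    missing: tuple[tuple[int, str], ...] = ()

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_residues(self) -> int:
        return len({r for r, _ in self.labels})

    def drop_residues(self, residues: set[int]) -> "BackboneSelection":
        keep = [i for i, (r, _) in enumerate(self.labels) if r not in residues]
        return BackboneSelection(
            self.points[keep],
            tuple(self.labels[i] for i in keep),
            self.chain,
            self.residue_range,
            self.atom_names,
            self.missing,
        )


def read_backbone(
    pdb_path: str | Path,
    chain: str,
    residue_range: tuple[int, int],
    atom_set: str | tuple[str, ...] = "backbone6",
) -> BackboneSelection:
    """Extract ordered backbone coordinates for a residue range of a chain.

    Points are ordered by residue number, then by the atom set's fixed order.
    Missing residues in the range raise an error listing them; atoms missing
    from a present residue are recorded in ``missing`` (the overlay drops
    such residues pairwise). Altloc conflicts resolve to highest occupancy
    (Biopython's default ordering).
    """
    atoms = ATOM_SETS[atom_set] if isinstance(atom_set, str) else tuple(atom_set)
    start, end = residue_range
    if end < start:
        raise ValueError("residue range end before start")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(f"chain {chain!r} not found in {pdb_path}")
    residues = {}
    for res in model[chain]:
        hetflag, resseq, _icode = res.id
        if hetflag.strip():
            continue
        residues[resseq] = res
    wanted = list(range(start, end + 1))
    absent = [r for r in wanted if r not in residues]
    if absent:
        raise ValueError(
            f"residues missing from chain {chain!r}: {absent} "
            f"(requested {start}-{end})"
        )
    points, labels, missing = [], [], []
    for resseq in wanted:
        res = residues[resseq]
        for name in atoms:
            if name in res:
                atom = res[name]
                if atom.is_disordered():
                    atom = sorted(
                        atom.disordered_get_list(),
                        key=lambda a: a.get_occupancy() or 0.0,
                    )[-1]
                points.append(atom.get_coord())
                labels.append((resseq, name))
            else:
                missing.append((resseq, name))
    return BackboneSelection(
        np.asarray(points, dtype=float),
        tuple(labels),
        chain,
        (start, end),
        atoms,
        tuple(missing),
    )


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid map of P onto Q: q ~= rotation @ p + translation."""

    rotation: np.ndarray = field(repr=False)  # (3, 3), proper orthonormal
    translation: np.ndarray = field(repr=False)  # (3,)
    rmsd: float
    n_atoms: int

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
            "n_atoms": self.n_atoms,
        }


def _as_points(x: BackboneSelection | np.ndarray) -> np.ndarray:
    return x.points if isinstance(x, BackboneSelection) else np.asarray(x, dtype=float)


def kabsch_superpose(
    P: BackboneSelection | np.ndarray, Q: BackboneSelection | np.ndarray
) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation mapping P onto Q.

    Correspondence is ordinal. When both arguments are backbone selections
    their atom-name sequences must match. Degenerate inputs (< 3 points, or
    effectively collinear sets, for which the rotation is not unique) are
    rejected.
    """
    if isinstance(P, BackboneSelection) and isinstance(Q, BackboneSelection):
        if tuple(a for _, a in P.labels) != tuple(a for _, a in Q.labels):
            raise ValueError("atom-name sequences of the two selections differ")
    p = _as_points(P)
    q = _as_points(Q)
    if p.shape != q.shape:
        raise ValueError(f"point counts differ: {p.shape[0]} vs {q.shape[0]}")
    n = p.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    # collinear sets leave a free rotation about the common axis
    if min(np.linalg.matrix_rank(pc, tol=1e-8), np.linalg.matrix_rank(qc, tol=1e-8)) < 2:
        raise ValueError("degenerate (collinear) point set: rotation not determined")
    H = pc.T @ qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q.mean(axis=0) - R @ p.mean(axis=0)
    diff = (pc @ R.T) - qc
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return SuperpositionResult(R, t, rmsd, n)


def overlay_ac_vs_t(
    pdb_path: str | Path,
    ac_range: tuple[int, int],
    t_range: tuple[int, int],
    chain: str = "A",
    atom_set: str | tuple[str, ...] = "backbone6",
) -> SuperpositionResult:
    """Superpose the anticodon-arm backbone onto the T-arm backbone.

    Both ranges must span 17 residues; correspondence is ordinal (stem on
    stem, loop on loop). Residues missing any atom of the set in either arm
    are dropped pairwise from both selections (with a warning) so the point
    sets stay matched.
    """
    for label, rng in (("anticodon arm", ac_range), ("T arm", t_range)):
        if rng[1] - rng[0] + 1 != 17:
            raise ValueError(f"{label} range must span 17 residues, got {rng}")
    ac = read_backbone(pdb_path, chain, ac_range, atom_set)
    t = read_backbone(pdb_path, chain, t_range, atom_set)

    # pairwise-complete: residue k of one arm pairs with residue k of the other
    def incomplete(sel: BackboneSelection) -> set[int]:
        return {r - sel.residue_range[0] for r, _ in sel.missing}

    bad = incomplete(ac) | incomplete(t)
    if bad:
        warnings.warn(
            f"dropping residue offsets {sorted(bad)} missing backbone atoms "
            f"in one of the arms",
            stacklevel=2,
        )
        ac = ac.drop_residues({ac.residue_range[0] + k for k in bad})
        t = t.drop_residues({t.residue_range[0] + k for k in bad})
    return kabsch_superpose(ac, t)
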