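"""Rigid-body superposition and RMSD statistics over coordinate ensembles.

Optimal least-squares superposition of corresponded C-alpha point sets by
the Kabsch algorithm (SVD with reflection correction), plus min/mean/max
RMSD summaries over a conformational ensemble.  Correspondence is
positional (point i of the mobile set pairs with point i of the reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CoordSet",
    "SuperpositionResult",
    "read_ca_coords",
    "read_xyz_tsv",
    "kabsch_superpose",
    "ensemble_rmsd_stats",
]


@dataclass
class CoordSet:
    """An ordered set of 3-D points (Angstrom) with an optional residue list."""

    label: str
    points: np.ndarray                       # (n, 3)
    residue_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if self.residue_ids is not None and len(self.residue_ids) != len(self.points):
            raise ValueError("residue_ids length mismatch")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SuperpositionResult:
    """Optimal rigid motion (proper rotation + translation) and its RMSD."""

    rotation: np.ndarray     # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def __post_init__(self) -> None:
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(r), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def read_ca_coords(pdb_path: str | Path, chain: Optional[str] = None) -> CoordSet:
    """C-alpha coordinates from PDB ATOM records, one point per residue.

    For residues with alternate locations the first-listed altloc is taken.
    Raises an error when the requested chain is absent (listing available
    chains) or when no CA atoms are found.
    """
    pdb_path = Path(pdb_path)
    points: list[list[float]] = []
    residue_ids: list[str] = []
    seen: set[tuple[str, str, str]] = set()
    chains: set[str] = set()
    for line in pdb_path.read_text().splitlines():
        if not line.startswith("ATOM"):
            continue
        atom_name = line[12:16].strip()
        if atom_name != "CA":
            continue
        chain_id = line[21]
        chains.add(chain_id)
        if chain is not None and chain_id != chain:
            continue
        res_key = (chain_id, line[22:26].strip(), line[26])
        if res_key in seen:
            continue  # later altloc of the same residue
        seen.add(res_key)
        points.append([float(line[30:38]), float(line[38:46]),
                       float(line[46:54])])
        residue_ids.append(f"{chain_id}:{line[17:20].strip()}{line[22:26].strip()}")
    if chain is not None and chain not in chains:
        raise ValueError(
            f"chain {chain!r} not found; available chains: {sorted(chains)}"
        )
    if not points:
        raise ValueError(f"no CA ATOM records in {pdb_path}")
    return CoordSet(label=pdb_path.stem, points=np.array(points),
                    residue_ids=residue_ids)


def read_xyz_tsv(path: str | Path, label: Optional[str] = None) -> CoordSet:
    """Plain coordinate table: one x<TAB>y<TAB>z row per point; a header
    line is permitted."""
    path = Path(path)
    rows = []
    for line in path.read_text().splitlines():
        parts = line.split("\t")
        if not line.strip():
            continue
        try:
            rows.append([float(v) for v in parts[:3]])
        except ValueError:
            if rows:
                raise
            continue  # header
    return CoordSet(label=label or path.stem, points=np.array(rows))


def kabsch_superpose(reference: CoordSet, mobile: CoordSet) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Kabsch algorithm: SVD of the cross-covariance of the centered point
    sets, with the smallest singular vector sign-flipped when needed so the
    rotation is proper (no reflection).  Requires >= 3 corresponded,
    non-collinear points.
    """
    a = reference.points
    b = mobile.points
    if len(a) != len(b):
        raise ValueError(f"point counts differ: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise ValueError("superposition needs at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = ca - rotation @ cb
    moved = b @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation,
                               rmsd=rmsd)


def ensemble_rmsd_stats(
    reference: CoordSet, ensemble: Sequence[CoordSet]
) -> dict:
    """Per-member Kabsch RMSDs against a reference, with min/max/mean.

    The summary values are also reported rounded to 0.1 Angstrom, the
    customary precision for structure-comparison tables.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    rmsds = [kabsch_superpose(reference, member).rmsd for member in ensemble]
    arr = np.array(rmsds)
    return {
        "labels": [m.label for m in ensemble],
        "rmsds": rmsds,
        "min": float(arr.min()),
        "max": float(arr.max()),
        "mean": float(arr.mean()),
        "summary_0.1A": {
            "min": round(float(arr.min()), 1),
            "max": round(float(arr.max()), 1),
            "mean": round(float(arr.mean()), 1),
        },
    }
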