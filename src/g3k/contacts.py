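"""Monosaccharide/atom distance maps and inter-conformer contact variability.

Distance maps are symmetric all-pairs matrices within one conformer
(residue level: heavy-atom centroid distance by default, minimum atom
distance optionally). Variability maps aggregate across conformers as the
conformer-weighted standard deviation of each pairwise distance: near-zero
entries mark stable contacts, large entries mark rearranging pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import ConformerEnsemble, Model


class ContactsError(ValueError):
    pass


@dataclass
class DistanceMap:
    level: str            # atom | residue
    labels: list[str]
    matrix: np.ndarray    # distances (A) or variability scores (A)
    mode: str = "distance"  # distance | variability
    weights: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def _points_and_labels(model: Model, level: str, residue_mode: str) -> tuple[np.ndarray, list[str]]:
    if level == "atom":
        atoms = model.atoms
        return (
            np.array([a.position for a in atoms]),
            [f"{a.chain}{a.residue_seq}:{a.name}" for a in atoms],
        )
    if level != "residue":
        raise ContactsError(f"unknown level {level!r}")
    labels = [f"{r.chain}{r.seq}:{r.monosaccharide or r.code}" for r in model.residues]
    if residue_mode == "centroid":
        return np.array([r.centroid() for r in model.residues]), labels
    return None, labels  # min-distance mode computes pairwise below


def distance_map(model: Model, level: str = "residue", residue_mode: str = "centroid") -> DistanceMap:
    """Symmetric all-pairs distance matrix for one conformer."""
    pts, labels = _points_and_labels(model, level, residue_mode)
    if pts is not None:
        mat = cdist(pts, pts)
    else:
        n = len(model.residues)
        mat = np.zeros((n, n))
        coords = [r.coords() for r in model.residues]
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = cdist(coords[i], coords[j]).min()
    np.fill_diagonal(mat, 0.0)
    return DistanceMap(level=level, labels=labels, matrix=mat, mode="distance")


def variability_map(
    ensemble: ConformerEnsemble, level: str = "residue", residue_mode: str = "centroid",
    statistic: str = "std",
) -> DistanceMap:
    """Weighted spread of each pairwise distance across conformers.

    Entry (i, j) is the conformer-weighted standard deviation (or MAD with
    ``statistic="mad"``) of distance(i, j); zero iff the distance is
    constant across the ensemble.
    """
    if ensemble.n_conformers < 2:
        raise ContactsError("variability map needs >= 2 conformers")
    maps = [distance_map(m, level, residue_mode) for m in ensemble.conformers]
    stack = np.stack([m.matrix for m in maps])  # (n_conf, n, n)
    w = ensemble.weights[:, None, None]
    mean = (stack * w).sum(axis=0)
    if statistic == "std":
        var = (w * (stack - mean) ** 2).sum(axis=0)
        spread = np.sqrt(np.maximum(var, 0.0))
    elif statistic == "mad":
        spread = (w * np.abs(stack - mean)).sum(axis=0)
    else:
        raise ContactsError(f"unknown statistic {statistic!r}")
    np.fill_diagonal(spread, 0.0)
    return DistanceMap(
        level=level, labels=maps[0].labels, matrix=spread,
        mode="variability", weights=ensemble.weights,
    )
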