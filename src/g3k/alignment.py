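"""Rigid superposition of glycan point clouds.

SVD-based Kabsch superposition over known correspondences, iterative
closest-point (ICP) alignment with k-d-tree correspondences for unequal
point sets, optional Nelder-Mead refinement of the six rigid-motion
parameters, best-conformer-pair search between ensembles, and pairwise
best-pair RMSD matrices.

The reported RMSD is asymmetric as defined here: it runs over mobile
points and their nearest reference points (``symmetric=True`` averages
both directions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .model import ConformerEnsemble, Model

MAIN_CHAIN_ATOMS = {"C1", "C2", "C3", "C4", "C5", "O5"}


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentResult:
    rotation: np.ndarray          # 3x3 proper rotation
    translation: np.ndarray       # 3-vector, A
    rmsd: float
    correspondences: list[tuple[int, int]] = field(default_factory=list)
    mode: str = "all_heavy"
    iterations: int = 0

    def transform(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def _selection(model: Model, mode: str) -> np.ndarray:
    if mode in ("all", "all_heavy"):
        pts = model.coords()
    elif mode in ("mainchain", "main_chain"):
        pts = np.array(
            [a.position for a in model.atoms if a.name in MAIN_CHAIN_ATOMS], dtype=float
        ).reshape(-1, 3)
    else:
        raise AlignmentError(f"unknown selection mode {mode!r}")
    if len(pts) == 0:
        raise AlignmentError(f"empty atom selection under mode {mode!r}")
    return pts


def kabsch(P: np.ndarray, Q: np.ndarray) -> AlignmentResult:
    """Optimal proper rotation + translation mapping P onto Q (matched sets).

    Reflection cases (det < 0 from the raw SVD) are corrected by flipping
    the smallest singular direction, so the rotation is always proper.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or len(P) < 3:
        raise AlignmentError("kabsch needs matched point sets with >= 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    if np.linalg.matrix_rank(H) < 2:
        raise AlignmentError("rank-deficient (collinear) point sets")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return AlignmentResult(
        rotation=R, translation=t, rmsd=rmsd,
        correspondences=[(i, i) for i in range(len(P))], iterations=1,
    )


def _nn_rmsd(moved: np.ndarray, tree: cKDTree) -> tuple[float, np.ndarray]:
    d, idx = tree.query(moved)
    return float(np.sqrt(np.mean(d**2))), idx


def icp_align(
    mobile: Model | np.ndarray,
    reference: Model | np.ndarray,
    mode: str = "all_heavy",
    max_iter: int = 50,
    tol: float = 1e-4,
    fast: bool = False,
    symmetric: bool = False,
) -> AlignmentResult:
    """Iterative closest-point alignment of possibly unequal point sets.

    Alternates k-d-tree nearest-neighbor correspondence (mobile ->
    reference) with Kabsch superposition until the RMSD improves by less
    than ``tol`` A or ``max_iter`` rounds. ``fast=True`` runs a single
    correspondence + Kabsch pass.
    """
    P = mobile if isinstance(mobile, np.ndarray) else _selection(mobile, mode)
    Q = reference if isinstance(reference, np.ndarray) else _selection(reference, mode)
    if len(P) < 3 or len(Q) < 3:
        raise AlignmentError("need >= 3 points on both sides")
    tree = cKDTree(Q)
    # initialize from centroid superposition and principal-axes candidates,
    # keeping the start with the lowest nearest-neighbor RMSD
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    starts = [np.eye(3)]
    if len(P) >= 3 and len(Q) >= 3:
        _, vp = np.linalg.eigh(np.cov((P - pc).T))
        _, vq = np.linalg.eigh(np.cov((Q - qc).T))
        if np.linalg.det(vp) < 0:
            vp[:, 0] = -vp[:, 0]
        if np.linalg.det(vq) < 0:
            vq[:, 0] = -vq[:, 0]
        for s1 in (1.0, -1.0):
            for s2 in (1.0, -1.0):
                flip = np.diag([s1, s2, s1 * s2])  # proper rotations only
                starts.append(vq @ flip @ vp.T)
    R, t, rmsd, idx = None, None, np.inf, None
    for R0 in starts:
        t0 = qc - R0 @ pc
        r0, i0 = _nn_rmsd(P @ R0.T + t0, tree)
        if r0 < rmsd:
            R, t, rmsd, idx = R0, t0, r0, i0
    iters = 0
    for _ in range(1 if fast else max_iter):
        iters += 1
        step = kabsch(P, Q[idx])
        moved = step.transform(P)
        new_rmsd, new_idx = _nn_rmsd(moved, tree)
        if new_rmsd <= rmsd + 1e-12:
            R, t = step.rotation, step.translation
            improved = rmsd - new_rmsd
            rmsd, idx = new_rmsd, new_idx
            if improved < tol:
                break
        else:
            break
    if symmetric:
        back, _ = cKDTree(moved).query(Q)
        rmsd = 0.5 * (rmsd + float(np.sqrt(np.mean(back**2))))
    return AlignmentResult(
        rotation=R, translation=t, rmsd=rmsd,
        correspondences=list(enumerate(idx.tolist())), mode=mode, iterations=iters,
    )


def refine_nelder_mead(
    result: AlignmentResult,
    mobile: Model | np.ndarray,
    reference: Model | np.ndarray,
    mode: str = "all_heavy",
    symmetric: bool = False,
) -> AlignmentResult:
    """Nelder-Mead simplex refinement over the 6 rigid-motion parameters.

    Never worse than the starting alignment: a non-improving search
    returns the input result unchanged.
    """
    P = mobile if isinstance(mobile, np.ndarray) else _selection(mobile, mode)
    Q = reference if isinstance(reference, np.ndarray) else _selection(reference, mode)
    tree = cKDTree(Q)

    def objective(x: np.ndarray) -> float:
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        moved = P @ R.T + x[3:]
        r, _ = _nn_rmsd(moved, tree)
        if symmetric:
            back, _ = cKDTree(moved).query(Q)
            r = 0.5 * (r + float(np.sqrt(np.mean(back**2))))
        return r

    x0 = np.concatenate([Rotation.from_matrix(result.rotation).as_rotvec(), result.translation])
    opt = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
    if opt.fun >= result.rmsd:
        return result
    R = Rotation.from_rotvec(opt.x[:3]).as_matrix()
    moved = P @ R.T + opt.x[3:]
    _, idx = _nn_rmsd(moved, tree)
    return AlignmentResult(
        rotation=R, translation=opt.x[3:], rmsd=float(opt.fun),
        correspondences=list(enumerate(idx.tolist())), mode=result.mode,
        iterations=result.iterations + int(opt.nit),
    )


def best_conformer_alignment(
    a: ConformerEnsemble, b: ConformerEnsemble, mode: str = "all_heavy", fast: bool = False
) -> tuple[tuple[int, int], AlignmentResult]:
    """Exhaustive conformer-pair search; the lowest-RMSD pair wins.

    Ties are broken lexicographically by conformer indices.
    """
    best_pair, best_result = None, None
    for i, ma in enumerate(a.conformers):
        for j, mb in enumerate(b.conformers):
            res = icp_align(ma, mb, mode=mode, fast=fast)
            if best_result is None or res.rmsd < best_result.rmsd - 1e-12:
                best_pair, best_result = (i, j), res
    return best_pair, best_result


def pairwise_alignment_matrix(
    ensembles: list[ConformerEnsemble], mode: str = "all_heavy", fast: bool = True
) -> np.ndarray:
    """Symmetric matrix of best-conformer-pair RMSDs (computed once per pair)."""
    if len(ensembles) < 2:
        raise AlignmentError("need >= 2 ensembles")
    n = len(ensembles)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, res = best_conformer_alignment(ensembles[i], ensembles[j], mode=mode, fast=fast)
            mat[i, j] = mat[j, i] = res.rmsd
    return mat
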