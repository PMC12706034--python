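"""Three glycan flexibility measures on a common RMSF-like scale.

* B-factor RMSF (X-ray): RMSF = sqrt(3 B / (8 pi^2)), per atom.
* Distance flexibility (conformer ensembles): per-axis mean absolute
  deviation (MAD) of atomic positions from the weighted-mean structure,
  averaged over the three axes, converted via RMSF = MAD * sqrt(pi/2)
  (exact for Gaussian displacements per axis).
* Torsion flexibility: circular standard deviation of phi/psi/omega per
  linkage, averaged over the available angles, then over a residue's
  incident linkages; rotation-invariant, in degrees.

All measures are conformer-weight aware. B-factor-derived profiles are
only comparable within one crystal structure; combining across files
triggers a warning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ConformerEnsemble, warn

MAD_TO_RMSF = math.sqrt(math.pi / 2.0)

#: cap for fully dispersed angles: the circular std at mean resultant
#: length 0.2, ~102.79 deg, avoids unbounded values poisoning averages
DISPERSED_CAP_DEG = math.degrees(math.sqrt(-2.0 * math.log(0.2)))


class FlexibilityError(ValueError):
    pass


@dataclass
class FlexibilityProfile:
    """Per-atom/per-residue flexibility of one ensemble or structure."""

    kind: str  # bfactor | distance | torsion
    atom_values: np.ndarray | None = None           # A (bfactor/distance)
    residue_values: dict = field(default_factory=dict)  # A, or deg for torsion
    weights: np.ndarray | None = None
    atom_mad: np.ndarray | None = None              # intermediate, distance kind


def rmsf_from_bfactor(b) -> float | np.ndarray:
    """RMSF (A) from a crystallographic temperature factor (A^2)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise FlexibilityError("negative B-factor")
    out = np.sqrt(3.0 * b / (8.0 * math.pi**2))
    return float(out) if out.ndim == 0 else out


def bfactor_flexibility(model, source: str | None = None, _seen: set = set()) -> FlexibilityProfile:
    """Per-atom/per-residue RMSF from B-factors of one structure."""
    if source is not None:
        if _seen and source not in _seen:
            warn("combining B-factor flexibility across different structures; "
                 "values are only comparable within one crystal structure")
        _seen.add(source)
    values = rmsf_from_bfactor(np.array([a.b_factor for a in model.atoms]))
    res_vals, i = {}, 0
    for res in model.residues:
        res_vals[res.key] = float(values[i : i + len(res.atoms)].mean())
        i += len(res.atoms)
    return FlexibilityProfile(kind="bfactor", atom_values=values, residue_values=res_vals)


def distance_flexibility(ensemble: ConformerEnsemble) -> FlexibilityProfile:
    """MAD-based RMSF across conformers (requires pre-aligned conformers)."""
    if ensemble.n_conformers < 2:
        raise FlexibilityError(
            "distance flexibility needs >= 2 conformers; use torsion flexibility "
            "for single structures"
        )
    xyz = ensemble.coords()  # (n_conf, n_atoms, 3)
    w = ensemble.weights[:, None, None]
    mean = (xyz * w).sum(axis=0)
    mad_axis = (np.abs(xyz - mean) * w).sum(axis=0)  # (n_atoms, 3)
    mad = mad_axis.mean(axis=1)
    rmsf = mad * MAD_TO_RMSF
    res_vals, i = {}, 0
    for res in ensemble.conformers[0].residues:
        res_vals[res.key] = float(rmsf[i : i + len(res.atoms)].mean())
        i += len(res.atoms)
    return FlexibilityProfile(
        kind="distance", atom_values=rmsf, residue_values=res_vals,
        weights=ensemble.weights, atom_mad=mad,
    )


def circular_std(angles_deg, weights=None) -> tuple[float, bool]:
    """Weighted circular standard deviation in degrees.

    Returns (spread, dispersed). When the mean resultant length is
    numerically zero the spread is capped at ~102.8 deg (its value at
    Rbar = 0.2) and flagged dispersed.
    """
    theta = np.radians(np.asarray(angles_deg, dtype=float))
    if theta.size < 2:
        raise FlexibilityError("circular std needs >= 2 angles")
    if weights is None:
        w = np.full(theta.size, 1.0 / theta.size)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    rbar = min(1.0, float(np.hypot((w * np.sin(theta)).sum(), (w * np.cos(theta)).sum())))
    if rbar < 1e-12:
        return DISPERSED_CAP_DEG, True
    if rbar == 1.0:
        return 0.0, False
    s = math.degrees(math.sqrt(-2.0 * math.log(rbar)))
    return min(s, DISPERSED_CAP_DEG), s > DISPERSED_CAP_DEG or False


def torsion_flexibility(torsion_table: pd.DataFrame) -> FlexibilityProfile:
    """Circular spread of glycosidic torsions, per linkage and per residue.

    Expects the long table from :func:`g3k.geometry.glycosidic_torsions`
    over an ensemble. Per-linkage score = mean of the circular standard
    deviations of the available angles (phi, psi and, for x-6 linkages,
    omega); per-residue score = mean over the linkages the residue is
    involved in. A residue in no linkage has no value.
    """
    linkage_scores: dict[tuple[str, str], float] = {}
    for (donor, acceptor), grp in torsion_table.groupby(["donor", "acceptor"], sort=False):
        spreads = []
        for col in ("phi", "psi", "omega"):
            vals = grp[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if ok.sum() >= 2:
                s, _ = circular_std(vals[ok], grp["weight"].to_numpy()[ok])
                spreads.append(s)
        if spreads:
            linkage_scores[(donor, acceptor)] = float(np.mean(spreads))
    residue_scores: dict[str, list[float]] = {}
    for (donor, acceptor), score in linkage_scores.items():
        residue_scores.setdefault(donor, []).append(score)
        residue_scores.setdefault(acceptor, []).append(score)
    res_vals = {rid: float(np.mean(v)) for rid, v in residue_scores.items()}
    prof = FlexibilityProfile(kind="torsion", residue_values=res_vals)
    prof.linkage_values = linkage_scores  # type: ignore[attr-defined]
    return prof


def flexibility_table(profile: FlexibilityProfile) -> pd.DataFrame:
    unit = "deg" if profile.kind == "torsion" else "A"
    rows = [
        {"residue": k if isinstance(k, str) else f"{k[0]}{k[1]}",
         "kind": profile.kind, "value": round(v, 4), "unit": unit}
        for k, v in profile.residue_values.items()
    ]
    return pd.DataFrame(rows)
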