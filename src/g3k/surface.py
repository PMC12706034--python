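"""Shrake-Rupley solvent-accessible surface area (SASA).

Atom-level SASA with a rolling probe (default 1.4 A, a water molecule) over
van-der-Waals spheres, using a fixed golden-spiral point set so results are
deterministic. Residue-level values sum constituent atoms, with covalent
modification groups (sulfate, acetyl, phosphocholine, ...) attributed to
their parent monosaccharide; a glycoprotein's linker amino acid is reported
as its own entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import (
    MODIFICATION_CODES,
    SUGAR_CODES,
    ConformerEnsemble,
    GlycanComponent,
    Model,
    warn,
)

#: Bondi-style van-der-Waals radii (A), heavy atoms only
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


class SasaError(ValueError):
    pass


@dataclass
class SasaProfile:
    """Per-atom and per-residue solvent accessibility in A^2."""

    atom_area: np.ndarray
    residue_area: dict[tuple[str, int], float]
    probe_radius: float = DEFAULT_PROBE
    n_sphere_points: int = DEFAULT_POINTS
    weighted: bool = False
    normalized: dict[tuple[str, int], float] = field(default_factory=dict)

    def normalize(self) -> "SasaProfile":
        """Min-max normalize residue areas to [0, 1] (0.5 on a constant profile)."""
        vals = np.array(list(self.residue_area.values()))
        lo, hi = vals.min(), vals.max()
        if hi - lo < 1e-12:
            self.normalized = {k: 0.5 for k in self.residue_area}
        else:
            self.normalized = {k: (v - lo) / (hi - lo) for k, v in self.residue_area.items()}
        return self


def golden_spiral(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points via the golden-angle spiral."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def compute_sasa(
    coords: np.ndarray,
    elements: list[str],
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Shrake-Rupley per-atom areas (A^2).

    For each atom, the fraction of ``n_points`` quasi-uniform points on the
    sphere of radius (vdW + probe) not inside any neighbor's expanded
    sphere, times that sphere's area.
    """
    radii = radii or VDW_RADII
    coords = np.asarray(coords, dtype=float)
    try:
        r = np.array([radii[e] for e in elements]) + probe_radius
    except KeyError as exc:
        raise SasaError(f"unknown element {exc.args[0]!r}: no vdW radius") from None
    n = len(coords)
    sphere = golden_spiral(n_points)
    tree = cKDTree(coords)
    rmax = r.max()
    areas = np.empty(n)
    for i in range(n):
        neigh = [j for j in tree.query_ball_point(coords[i], r[i] + rmax) if j != i]
        pts = coords[i] + r[i] * sphere
        if neigh:
            diff = pts[:, None, :] - coords[neigh][None, :, :]
            buried = (np.einsum("pjk,pjk->pj", diff, diff) < (r[neigh] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r[i] ** 2
    return areas


def _model_sasa(model: Model, probe_radius: float, n_points: int) -> np.ndarray:
    atoms = model.atoms
    return compute_sasa(
        np.array([a.position for a in atoms]), [a.element for a in atoms],
        probe_radius, n_points,
    )


def residue_sasa(
    model: Model,
    component: GlycanComponent | None = None,
    atom_areas: np.ndarray | None = None,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    bond_cutoff: float = 1.8,
) -> SasaProfile:
    """Residue-level SASA with modification attribution.

    Sugar residues receive the summed area of their own atoms plus the
    atoms of covalently bonded non-sugar modification groups; a linker
    amino acid (glycoproteins) appears as its own entry. A modification
    bonded to no sugar is reported separately with a warning.
    """
    if atom_areas is None:
        atom_areas = _model_sasa(model, probe_radius, n_points)
    atoms = model.atoms
    if len(atom_areas) != len(atoms):
        raise SasaError("per-atom areas do not match the model's atoms")
    area_by_key: dict[tuple[str, int], float] = {}
    offsets = {}
    i = 0
    for res in model.residues:
        offsets[res.key] = slice(i, i + len(res.atoms))
        area_by_key[res.key] = float(atom_areas[i : i + len(res.atoms)].sum())
        i += len(res.atoms)

    sugar_keys = {r.key for r in model.residues if r.code in SUGAR_CODES or r.monosaccharide}
    keep: dict[tuple[str, int], float] = {}
    for res in model.residues:
        if res.key in sugar_keys:
            keep[res.key] = area_by_key[res.key]
    # attribute modifications to their nearest covalently-bonded sugar
    for res in model.residues:
        if res.key in sugar_keys or res.is_amino_acid:
            continue
        if res.code not in MODIFICATION_CODES:
            continue
        parent, best = None, bond_cutoff
        for sres in model.residues:
            if sres.key not in sugar_keys:
                continue
            d = np.sqrt(
                ((res.coords()[:, None, :] - sres.coords()[None, :, :]) ** 2).sum(-1)
            ).min()
            if d <= best:
                parent, best = sres.key, d
        if parent is None:
            warn(f"modification {res.code}{res.seq} bonded to no sugar; reported separately")
            keep[res.key] = area_by_key[res.key]
        else:
            keep[parent] += area_by_key[res.key]
    # linker amino acid of a glycoprotein gets its own entry
    if component is not None and component.attachment is not None:
        aa, _site = component.attachment
        if aa.key in area_by_key:
            keep[aa.key] = area_by_key[aa.key]
    return SasaProfile(
        atom_area=atom_areas, residue_area=keep,
        probe_radius=probe_radius, n_sphere_points=n_points,
    )


def weighted_sasa(profiles: list[SasaProfile], weights) -> SasaProfile:
    """Conformer-weighted mean of per-residue SASA profiles."""
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    if len(profiles) != len(weights):
        raise SasaError("one weight per profile required")
    keys = set(profiles[0].residue_area)
    for p in profiles[1:]:
        if set(p.residue_area) != keys:
            raise SasaError("profiles do not share a residue set")
    residue = {
        k: float(sum(w * p.residue_area[k] for w, p in zip(weights, profiles)))
        for k in profiles[0].residue_area
    }
    atom = np.sum([w * p.atom_area for w, p in zip(weights, profiles)], axis=0)
    return SasaProfile(
        atom_area=atom, residue_area=residue,
        probe_radius=profiles[0].probe_radius,
        n_sphere_points=profiles[0].n_sphere_points, weighted=True,
    )


def ensemble_sasa(
    ensemble: ConformerEnsemble,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> SasaProfile:
    """Weighted residue SASA across an ensemble's conformers."""
    profiles = [
        residue_sasa(m, ensemble.glycan, probe_radius=probe_radius, n_points=n_points)
        for m in ensemble.conformers
    ]
    return weighted_sasa(profiles, ensemble.weights)


def sasa_table(profile: SasaProfile, component: GlycanComponent | None = None) -> pd.DataFrame:
    """Residue, monosaccharide, raw, and min-max-normalized SASA (TSV-ready)."""
    profile.normalize()
    rows = []
    for key, area in profile.residue_area.items():
        mono = ""
        if component is not None:
            try:
                mono = component.residue(key).monosaccharide
            except KeyError:
                pass
        rows.append(
            {"residue": f"{key[0]}{key[1]}", "monosaccharide": mono,
             "sasa_A2": round(area, 3), "sasa_norm": round(profile.normalized[key], 4)}
        )
    return pd.DataFrame(rows)
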