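"""Glycan geometry: dihedrals, glycosidic torsions, ring puckering and
conformation labels, hydroxyl orientation, torsion-torsion correlation.

Conventions
-----------
* Angles are degrees in (-180, 180]; reported torsions are rounded to two
  decimal places.
* phi = ringO-Canomeric-Ox-Cx (ring oxygen of the donor: O5 for pyranoses,
  O4 for furanoses, O6 for sialic acids), psi = Canomeric-Ox-Cx-Cy with Cy
  the next ring carbon after Cx (wrapping back when C(x+1) is not a ring
  atom), omega = O6-C6-C5-O5 of the acceptor for x-6 linkages.
* Ring puckering follows the Cremer-Pople construction about the geometric
  center, with the mean-plane normal oriented so a counterclockwise-ordered
  flat ring has a +z normal; theta = atan2(q2, q3) in [0, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ConformerEnsemble, GlycanComponent, Model, Residue, anomeric_carbon, warn

__all__ = [
    "dihedral_angle",
    "glycosidic_torsions",
    "ring_puckering",
    "classify_conformation",
    "hydroxyl_orientation",
    "torsion_torsion_correlation",
    "PuckeringParameters",
]


class GeometryError(ValueError):
    pass


def _wrap_deg(a):
    """Map angle(s) to the half-open interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    out = np.where(out == -180.0, 180.0, out)
    return float(out) if out.ndim == 0 else out


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral in degrees via the four-quadrant arctangent.

    With bond vectors v1 = p2-p1, v2 = p3-p2, v3 = p4-p3 and plane normals
    n1 = v1 x v2, n2 = v2 x v3, the angle is
    atan2((n1 x n2) . v2/|v2|, n1 . n2), in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    v1, v2, v3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(v1, v2), np.cross(v2, v3)
    norm2 = np.linalg.norm(v2)
    if norm2 < 1e-9 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("degenerate geometry: collinear or coincident points")
    y = np.dot(np.cross(n1, n2), v2 / norm2)
    x = np.dot(n1, n2)
    return _wrap_deg(math.degrees(math.atan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D so |CD| = bond, angle(B,C,D) = angle, dihedral(A,B,C,D) = dihedral."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise GeometryError("cannot place atom from collinear reference frame")
    n /= nn
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(dih),
            bond * math.sin(ang) * math.sin(dih),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotate_about_axis(points: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of points about an axis through ``origin``."""
    points = np.asarray(points, dtype=float)
    origin = np.asarray(origin, dtype=float)
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    t = math.radians(angle_deg)
    rel = points - origin
    rot = (
        rel * math.cos(t)
        + np.cross(k, rel) * math.sin(t)
        + np.outer(rel @ k, k) * (1 - math.cos(t))
    )
    return rot + origin


# ---------------------------------------------------------------------------
# glycosidic torsions


def _next_ring_carbon(acceptor: Residue, x: int) -> str:
    ring = acceptor.ring_atoms
    nxt = f"C{x + 1}"
    if nxt in ring:
        return nxt
    prev = f"C{x - 1}"
    if prev in ring:
        return prev
    # exocyclic acceptor carbon (e.g. C6 of a pyranose): wrap to the last ring carbon
    carbons = [n for n in ring if n.startswith("C")]
    return carbons[-1]


def _linkage_torsions(model: Model, comp: GlycanComponent, linkage) -> dict:
    donor = model.residue(*linkage.donor)
    acceptor = model.residue(*linkage.acceptor)
    ring_o = donor.ring_atoms[-1]  # O5 / O4 / O6
    c_anomeric = f"C{linkage.anomeric_carbon}"
    ox, cx = f"O{linkage.x}", f"C{linkage.x}"
    cy = _next_ring_carbon(acceptor, linkage.x)
    for res, name in ((donor, ring_o), (donor, c_anomeric), (acceptor, ox), (acceptor, cx), (acceptor, cy)):
        if not res.has_atom(name):
            raise GeometryError(
                f"missing atom {name} in residue {res.code}{res.seq} for linkage "
                f"{linkage.donor}->{linkage.acceptor}"
            )
    phi = dihedral_angle(
        donor.atom(ring_o).position,
        donor.atom(c_anomeric).position,
        acceptor.atom(ox).position,
        acceptor.atom(cx).position,
    )
    psi = dihedral_angle(
        donor.atom(c_anomeric).position,
        acceptor.atom(ox).position,
        acceptor.atom(cx).position,
        acceptor.atom(cy).position,
    )
    omega = np.nan
    if linkage.x == 6:
        omega = dihedral_angle(
            acceptor.atom("O6").position,
            acceptor.atom("C6").position,
            acceptor.atom("C5").position,
            acceptor.atom("O5").position,
        )
    return {"phi": round(phi, 2), "psi": round(psi, 2), "omega": round(omega, 2) if np.isfinite(omega) else np.nan}


_LINKER_ATOMS = {
    "ASN": ("ND2", "CG", "CB"),
    "SER": ("OG", "CB", "CA"),
    "THR": ("OG1", "CB", "CA"),
}


def _attachment_torsions(model: Model, comp: GlycanComponent) -> dict | None:
    aa_res, site = comp.attachment
    aa = model.residue(aa_res.chain, aa_res.seq)
    root = model.residue(*comp.root)
    names = _LINKER_ATOMS.get(aa.code)
    if names is None:
        warn(f"no linker-torsion convention for {aa.code}; skipped")
        return None
    site_atom, c1_next, c2_next = names
    ring_o = root.ring_atoms[-1]
    c_anomeric = f"C{anomeric_carbon(root.monosaccharide)}"
    phi = dihedral_angle(
        root.atom(ring_o).position,
        root.atom(c_anomeric).position,
        aa.atom(site_atom).position,
        aa.atom(c1_next).position,
    )
    psi = dihedral_angle(
        root.atom(c_anomeric).position,
        aa.atom(site_atom).position,
        aa.atom(c1_next).position,
        aa.atom(c2_next).position,
    )
    return {"phi": round(phi, 2), "psi": round(psi, 2), "omega": np.nan}


def glycosidic_torsions(
    target: Model | ConformerEnsemble, component: GlycanComponent | None = None
) -> pd.DataFrame:
    """Per-linkage (phi, psi, omega) for each conformer.

    Returns a long-format table with one row per linkage per conformer
    (columns: conformer, weight, donor, acceptor, donor_name, acceptor_name,
    x, anomer, context, phi, psi, omega). Linkages with missing atoms are
    reported as warnings and skipped; other linkages are still computed.
    """
    if isinstance(target, ConformerEnsemble):
        models = target.conformers
        labels = target.labels
        weights = target.weights
        component = component or target.glycan
    else:
        models, labels, weights = [target], ["conf0"], np.array([1.0])
    if component is None:
        raise ValueError("a GlycanComponent is required for a bare Model")

    rows = []
    for model, label, weight in zip(models, labels, weights):
        for lk in component.linkages:
            donor = component.residue(lk.donor)
            acceptor = component.residue(lk.acceptor)
            try:
                tors = _linkage_torsions(model, component, lk)
            except GeometryError as exc:
                warn(str(exc))
                continue
            rows.append(
                {
                    "conformer": label,
                    "weight": float(weight),
                    "donor": f"{lk.donor[0]}{lk.donor[1]}",
                    "acceptor": f"{lk.acceptor[0]}{lk.acceptor[1]}",
                    "donor_name": donor.monosaccharide or donor.code,
                    "acceptor_name": acceptor.monosaccharide or acceptor.code,
                    "x": lk.x,
                    "anomer": donor.anomer,
                    "context": "sugar-sugar",
                    **tors,
                }
            )
        if component.attachment is not None:
            aa_res, _site = component.attachment
            tors = _attachment_torsions(model, component)
            if tors is not None:
                root = component.residue(component.root)
                rows.append(
                    {
                        "conformer": label,
                        "weight": float(weight),
                        "donor": f"{component.root[0]}{component.root[1]}",
                        "acceptor": f"{aa_res.chain}{aa_res.seq}",
                        "donor_name": root.monosaccharide or root.code,
                        "acceptor_name": aa_res.code,
                        "x": 0,
                        "anomer": root.anomer,
                        "context": "sugar-aminoacid",
                        **tors,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "conformer", "weight", "donor", "acceptor", "donor_name",
            "acceptor_name", "x", "anomer", "context", "phi", "psi", "omega",
        ],
    )


# ---------------------------------------------------------------------------
# Cremer-Pople ring puckering


@dataclass
class PuckeringParameters:
    """Cremer-Pople puckering of one 5- or 6-membered ring."""

    n: int
    q: dict[int, float] = field(default_factory=dict)        # amplitudes, A
    phi: dict[int, float] = field(default_factory=dict)      # phases, deg [0, 360)
    Q: float = 0.0
    theta: float | None = None                               # deg [0, 180], 6-rings
    planar: bool = False

    @property
    def q2(self) -> float:
        return self.q.get(2, 0.0)

    @property
    def q3(self) -> float:
        return self.q.get(3, 0.0)

    @property
    def phi2(self) -> float | None:
        return self.phi.get(2)


def cp_displacements(n: int, q: dict[int, float], phi: dict[int, float]) -> np.ndarray:
    """Out-of-plane displacements z_j synthesized from puckering amplitudes.

    Inverse of :func:`ring_puckering`: z_j = sqrt(2/n) sum_m q_m cos(phi_m +
    2 pi m j / n) plus, for even n, n^{-1/2} q_{n/2} (-1)^j.
    """
    j = np.arange(n)
    z = np.zeros(n)
    for m in range(2, (n - 1) // 2 + 1):
        qm = q.get(m, 0.0)
        pm = math.radians(phi.get(m, 0.0))
        z += math.sqrt(2.0 / n) * qm * np.cos(pm + 2 * math.pi * m * j / n)
    if n % 2 == 0:
        z += q.get(n // 2, 0.0) * ((-1.0) ** j) / math.sqrt(n)
    return z


def ring_puckering(coords: np.ndarray, planar_tol: float = 1e-6) -> PuckeringParameters:
    """Cremer-Pople parameters for an ordered ring of 5 or 6 atoms."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n not in (5, 6):
        raise GeometryError(f"ring size {n} unsupported (need 5 or 6)")
    rel = coords - coords.mean(axis=0)
    j = np.arange(n)
    ang = 2 * math.pi * j / n
    r1 = (rel * np.sin(ang)[:, None]).sum(axis=0)
    r2 = (rel * np.cos(ang)[:, None]).sum(axis=0)
    normal = np.cross(r2, r1)
    nn = np.linalg.norm(normal)
    if nn < 1e-12:
        raise GeometryError("degenerate ring geometry")
    z = rel @ (normal / nn)

    params = PuckeringParameters(n=n)
    total = 0.0
    for m in range(2, (n - 1) // 2 + 1):
        a = math.sqrt(2.0 / n) * float(np.sum(z * np.cos(m * ang)))
        b = -math.sqrt(2.0 / n) * float(np.sum(z * np.sin(m * ang)))
        qm = math.hypot(a, b)
        params.q[m] = qm
        params.phi[m] = math.degrees(math.atan2(b, a)) % 360.0
        total += qm * qm
    q_half = None
    if n % 2 == 0:
        q_half = float(np.sum(z * ((-1.0) ** j))) / math.sqrt(n)
        params.q[n // 2] = q_half  # signed
        total += q_half * q_half
    params.Q = math.sqrt(total)
    if params.Q < planar_tol:
        params.planar = True
        params.theta = None
        return params
    if n == 6:
        params.theta = math.degrees(math.atan2(params.q[2], q_half))
    return params


# phi2 -> label lookup tables (ring indexed from the anomeric carbon;
# "6" denotes the ring oxygen, following common usage for pyranoses)
BOAT_LABELS = {0: "1,4B", 60: "B2,5", 120: "3,6B", 180: "B1,4", 240: "2,5B", 300: "B3,6"}
SKEW_LABELS = {30: "1S5", 90: "6S2", 150: "3S1", 210: "5S1", 270: "2S6", 330: "1S3"}
ENVELOPE_LABELS = {0: "C1-endo", 72: "C3-endo", 144: "O4-endo", 216: "C2-endo", 288: "C4-endo"}
TWIST_LABELS = {36: "3T2", 108: "OT4", 180: "2T1", 252: "4T3", 324: "1TO"}


def _nearest_anchor(phi2: float, anchors: dict[int, str], tol: float) -> str | None:
    for anchor, label in anchors.items():
        d = abs((phi2 - anchor + 180.0) % 360.0 - 180.0)
        if d <= tol:
            return label
    return None


def classify_conformation(
    p: PuckeringParameters, ring_kind: str = "pyranose", chirality: str = "D"
) -> str:
    """Conformation label from puckering parameters.

    Six-membered rings: chairs for theta < 45 or theta > 135 (4C1/1C4 for D,
    inverted for L; 2C5/5C2 for sialic acids), otherwise boats at phi2
    multiples of 60 deg (+-15) and skew-boats 30 deg off. Five-membered
    rings: envelopes at phi2 multiples of 72 deg (+-18), twists 36 deg off.
    """
    if p.planar:
        return "planar"
    if p.n == 5:
        phi2 = p.phi2 or 0.0
        label = _nearest_anchor(phi2, ENVELOPE_LABELS, 18.0)
        return label if label is not None else _nearest_anchor(phi2, TWIST_LABELS, 18.0)
    if p.theta is None:
        return "planar"
    sialic = ring_kind == "sialic"
    if p.theta < 45.0:
        if sialic:
            return "2C5"
        return "4C1" if chirality == "D" else "1C4"
    if p.theta > 135.0:
        if sialic:
            return "5C2"
        return "1C4" if chirality == "D" else "4C1"
    phi2 = p.phi2 or 0.0
    boat = _nearest_anchor(phi2, BOAT_LABELS, 15.0)
    if sialic:
        return "boat" if boat is not None else "skew"
    if boat is not None:
        return boat
    return _nearest_anchor(phi2, SKEW_LABELS, 15.0)


def residue_puckering(residue: Residue) -> PuckeringParameters:
    """Puckering of a sugar residue's ring atoms."""
    if not residue.monosaccharide:
        raise GeometryError(f"residue {residue.code}{residue.seq} has no assigned monosaccharide")
    names = residue.ring_atoms
    missing = [n for n in names if not residue.has_atom(n)]
    if missing:
        raise GeometryError(f"missing ring atoms {missing} in {residue.code}{residue.seq}")
    return ring_puckering(residue.coords(names))


# ---------------------------------------------------------------------------
# hydroxyl orientation


def hydroxyl_orientation(residue: Residue, p: PuckeringParameters | None = None) -> dict[str, str]:
    """Axial/equatorial assignment of ring-carbon hydroxyl (and amine) groups.

    Only defined for chair-like rings (theta < 45 or theta > 135); other
    states return "undetermined" for every group.
    """
    if p is None:
        p = residue_puckering(residue)
    ring_names = residue.ring_atoms
    coords = residue.coords(ring_names)
    rel = coords - coords.mean(axis=0)
    n = len(coords)
    ang = 2 * math.pi * np.arange(n) / n
    normal = np.cross((rel * np.cos(ang)[:, None]).sum(0), (rel * np.sin(ang)[:, None]).sum(0))
    normal /= np.linalg.norm(normal)

    chair = p.theta is not None and (p.theta < 45.0 or p.theta > 135.0)
    out: dict[str, str] = {}
    ring_carbons = [nme for nme in ring_names if nme.startswith("C")]
    for atom in residue.atoms:
        if atom.name in ring_names or atom.element not in ("O", "N"):
            continue
        # attach to the nearest ring carbon; skip if not covalently close
        dists = [np.linalg.norm(atom.position - residue.atom(c).position) for c in ring_carbons]
        i = int(np.argmin(dists))
        if dists[i] > 1.65:
            continue
        if not chair:
            out[atom.name] = "undetermined"
            continue
        v = atom.position - residue.atom(ring_carbons[i]).position
        v /= np.linalg.norm(v)
        tilt = math.degrees(math.acos(min(1.0, abs(float(v @ normal)))))
        out[atom.name] = "axial" if tilt < 45.0 else "equatorial"
    if not chair and out:
        warn(f"residue {residue.code}{residue.seq} not in a chair state; orientations undetermined")
    return out


# ---------------------------------------------------------------------------
# torsion-torsion correlation


def torsion_wide(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Pivot a long torsion table to conformers x angle-columns (degrees)."""
    angles = table.melt(
        id_vars=["conformer", "weight", "donor", "acceptor", "x"],
        value_vars=["phi", "psi", "omega"],
        var_name="angle",
        value_name="value",
    ).dropna(subset=["value"])
    angles["column"] = angles["donor"] + "-" + angles["acceptor"] + ":" + angles["angle"]
    wide = angles.pivot_table(index="conformer", columns="column", values="value", sort=False)
    w = angles.drop_duplicates("conformer").set_index("conformer")["weight"]
    w = w.reindex(wide.index).to_numpy()
    return wide, w / w.sum()


def _circular_mean_rad(theta: np.ndarray, w: np.ndarray) -> float:
    return math.atan2(float(np.sum(w * np.sin(theta))), float(np.sum(w * np.cos(theta))))


def circular_correlation(a_deg, b_deg, weights=None) -> float:
    """Jammalamadaka-SenGupta circular-circular correlation coefficient."""
    a = np.radians(np.asarray(a_deg, dtype=float))
    b = np.radians(np.asarray(b_deg, dtype=float))
    w = np.full(len(a), 1.0 / len(a)) if weights is None else np.asarray(weights, float) / np.sum(weights)
    sa = np.sin(a - _circular_mean_rad(a, w))
    sb = np.sin(b - _circular_mean_rad(b, w))
    denom = math.sqrt(float(np.sum(w * sa**2)) * float(np.sum(w * sb**2)))
    if denom < 1e-12:
        return 0.0
    return float(np.sum(w * sa * sb) / denom)


def binned_mutual_information(a_deg, b_deg, weights=None, bins: int = 8) -> float:
    """Weighted mutual information (nats) of two angles binned over (-180, 180]."""
    a = _wrap_deg(np.asarray(a_deg, dtype=float))
    b = _wrap_deg(np.asarray(b_deg, dtype=float))
    w = np.full(len(a), 1.0 / len(a)) if weights is None else np.asarray(weights, float) / np.sum(weights)
    edges = np.linspace(-180.0, 180.0, bins + 1)
    joint, _, _ = np.histogram2d(a, b, bins=[edges, edges], weights=w)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / np.outer(pa, pb)[mask])))


def torsion_torsion_correlation(
    table_or_wide: pd.DataFrame, weights=None, bins: int = 8
) -> dict[str, pd.DataFrame]:
    """Pairwise circular correlation and binned mutual information matrices.

    Accepts either the long table from :func:`glycosidic_torsions` or an
    already-wide conformers-by-angles frame plus explicit weights. Requires
    at least 3 conformers.
    """
    if "phi" in table_or_wide.columns and "conformer" in table_or_wide.columns:
        wide, w = torsion_wide(table_or_wide)
    else:
        wide = table_or_wide
        w = (
            np.full(len(wide), 1.0 / len(wide))
            if weights is None
            else np.asarray(weights, float) / np.sum(weights)
        )
    if len(wide) < 3:
        raise GeometryError("torsion-torsion correlation needs at least 3 conformers")
    cols = list(wide.columns)
    k = len(cols)
    rmat = np.eye(k)
    mimat = np.zeros((k, k))
    for i in range(k):
        mimat[i, i] = binned_mutual_information(wide[cols[i]], wide[cols[i]], w, bins)
        for jj in range(i + 1, k):
            a, b = wide[cols[i]].to_numpy(), wide[cols[jj]].to_numpy()
            rmat[i, jj] = rmat[jj, i] = circular_correlation(a, b, w)
            mimat[i, jj] = mimat[jj, i] = binned_mutual_information(a, b, w, bins)
    return {
        "circular_r": pd.DataFrame(rmat, index=cols, columns=cols),
        "mutual_information": pd.DataFrame(mimat, index=cols, columns=cols),
    }
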