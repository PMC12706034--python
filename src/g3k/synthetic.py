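"""Ground-truth fixture generation: idealized rings, glycans with prescribed
torsions, conformer ensembles, protein-glycan scenes, and binding tables.

Geometry is idealized (C-C 1.53 A, C-O 1.43 A, tetrahedral substituents)
rather than force-field minimized: every prescribed quantity (puckering
amplitudes, glycosidic torsions, contact distances) is imposed analytically
so the analysis modules can be checked against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import iupac
from .geometry import (
    GeometryError,
    _next_ring_carbon,
    cp_displacements,
    dihedral_angle,
    place_atom,
    rotate_about_axis,
)
from .model import (
    MONOSACCHARIDES,
    AtomRecord,
    ConformerEnsemble,
    GlycanComponent,
    Linkage,
    Model,
    Residue,
    anomeric_carbon,
    ring_atom_names,
    warn,
)

BOND_CC = 1.53
BOND_CO = 1.43
BOND_CN = 1.45
TET = 109.47


@dataclass
class GlycanBuildSpec:
    """Recipe for one glycan conformer with exact prescribed geometry.

    ``torsions`` maps the donor residue number (tree order, root = 1) to
    (phi, psi) or (phi, psi, omega) in degrees; ``puckering`` maps residue
    numbers to (Q, theta, phi2) for 6-rings or (Q, phi2) for 5-rings.
    Unspecified linkages/rings fall back to the defaults.
    """

    sequence: str
    torsions: dict[int, tuple] = field(default_factory=dict)
    puckering: dict[int, tuple] = field(default_factory=dict)
    default_phi: float = -70.0
    default_psi: float = 120.0
    default_omega: float = -60.0
    root_anomer: str = "b"
    bond_co: float = BOND_CO


@dataclass
class EnsembleSpec:
    """Recipe for a conformer ensemble around one glycan topology.

    ``kappa`` is the von Mises concentration of the torsion noise (None =
    no torsion noise); ``jitter_sigma`` is per-coordinate Gaussian noise in
    A. The first ``n_anchor`` residues (tree order) receive neither, which
    emulates conformers aligned along their leading residues. By default
    the anchor covers the first five residues when the glycan is that large.
    """

    n_conformers: int = 10
    kappa: float | dict[int, float] | None = 20.0
    jitter_sigma: float = 0.0
    weights: np.ndarray | None = None
    seed: int = 0
    n_anchor: int | None = None


# ---------------------------------------------------------------------------
# ring templates


def _hexagon_radius() -> float:
    return BOND_CC  # regular hexagon: side length equals radius


def _pentagon_radius() -> float:
    return 1.45 / (2 * math.sin(math.pi / 5))


def build_ring(
    monosaccharide: str,
    Q: float = 0.57,
    theta: float = 0.0,
    phi2: float = 0.0,
) -> dict[str, np.ndarray]:
    """Ring-atom coordinates with exact Cremer-Pople puckering.

    Atoms sit on a regular polygon in the xy-plane with out-of-plane
    displacements synthesized from the CP basis, so that
    :func:`g3k.geometry.ring_puckering` recovers (Q, theta, phi2). For
    5-membered rings ``theta`` is ignored (Q is the single m=2 amplitude).
    """
    if Q < 0 or Q > 1.0:
        raise GeometryError(f"infeasible puckering amplitude Q={Q}")
    names = ring_atom_names(monosaccharide)
    n = len(names)
    if n == 6:
        q = {2: Q * math.sin(math.radians(theta)), 3: Q * math.cos(math.radians(theta))}
        phases = {2: phi2}
    else:
        q = {2: Q}
        phases = {2: phi2}
    z = cp_displacements(n, q, phases)
    radius = _hexagon_radius() if n == 6 else _pentagon_radius()
    ang = 2 * math.pi * np.arange(n) / n
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), z])
    return dict(zip(names, coords))


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    rel = coords - coords.mean(axis=0)
    ang = 2 * math.pi * np.arange(len(coords)) / len(coords)
    normal = np.cross((rel * np.cos(ang)[:, None]).sum(0), (rel * np.sin(ang)[:, None]).sum(0))
    return normal / np.linalg.norm(normal)


def _substituent_dirs(a, prev, nxt) -> tuple[np.ndarray, np.ndarray]:
    """Two exocyclic tetrahedral directions at ring atom ``a``."""
    u1 = (prev - a) / np.linalg.norm(prev - a)
    u2 = (nxt - a) / np.linalg.norm(nxt - a)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    half = math.acos(max(-1.0, min(1.0, float(u1 @ u2)))) / 2.0
    cosb = max(-1.0, min(1.0, (1.0 / 3.0) / max(math.cos(half), 1e-6)))
    sinb = math.sqrt(max(0.0, 1.0 - cosb * cosb))
    return bis * cosb + perp * sinb, bis * cosb - perp * sinb


def _axial_equatorial(a, prev, nxt, normal) -> tuple[np.ndarray, np.ndarray]:
    d1, d2 = _substituent_dirs(a, prev, nxt)
    if abs(float(d1 @ normal)) >= abs(float(d2 @ normal)):
        return d1, d2  # axial, equatorial
    return d2, d1


def build_residue(
    monosaccharide: str,
    anomer: str = "b",
    puckering: tuple | None = None,
    omega: float = -60.0,
) -> Residue:
    """A full idealized residue (ring + exocyclic substituents) in a local frame."""
    info = MONOSACCHARIDES[monosaccharide]
    names = ring_atom_names(monosaccharide)
    if puckering is None:
        puck = (0.57, 0.0 if info["chirality"] == "D" else 180.0, 0.0)
    elif len(puckering) == 2:
        puck = (puckering[0], 0.0, puckering[1])
    else:
        puck = tuple(puckering)
    ring = build_ring(monosaccharide, *puck)
    ring_coords = np.array([ring[nm] for nm in names])
    normal = _ring_normal(ring_coords)

    atoms: dict[str, np.ndarray] = dict(ring)
    carbons = [nm for nm in names if nm.startswith("C")]

    def _place(carbon: str, sub: str, bond: float, axial: bool):
        i = names.index(carbon)
        prev_a, nxt_a = ring[names[i - 1]], ring[names[(i + 1) % len(names)]]
        ax, eq = _axial_equatorial(ring[carbon], prev_a, nxt_a, normal)
        atoms[sub] = ring[carbon] + bond * (ax if axial else eq)

    axial_set = info["axial"]
    kind = info["ring"]
    ac = info["anomeric"]
    if kind in ("pyranose", "furanose"):
        _place("C1", "O1", BOND_CO, axial=(anomer == "a"))
        if info.get("n_acetyl"):
            _place("C2", "N2", BOND_CN, axial="O2" in axial_set)
        else:
            _place("C2", "O2", BOND_CO, axial="O2" in axial_set)
        _place("C3", "O3", BOND_CO, axial="O3" in axial_set)
        if kind == "pyranose":
            _place("C4", "O4", BOND_CO, axial="O4" in axial_set)
            if not info.get("no_c6"):
                _place("C5", "C6", BOND_CC, axial=False)
                if not info.get("deoxy6"):
                    atoms["O6"] = place_atom(atoms["O5"], atoms["C5"], atoms["C6"], BOND_CO, TET, omega)
        else:  # furanose: exocyclic C5-O5 arm on C4
            _place("C4", "C5", BOND_CC, axial=False)
            atoms["O5"] = place_atom(atoms["O4"], atoms["C4"], atoms["C5"], BOND_CO, TET, omega)
    else:  # sialic: ring C2..C6 + O6; C2 carries the anomeric O2 and carboxyl C1
        _place("C2", "O2", BOND_CO, axial=(anomer == "a"))
        i = names.index("C2")
        prev_a, nxt_a = ring[names[i - 1]], ring[names[(i + 1) % len(names)]]
        ax, eq = _axial_equatorial(ring["C2"], prev_a, nxt_a, normal)
        atoms["C1"] = ring["C2"] + BOND_CC * (eq if anomer == "a" else ax)
        _place("C4", "O4", BOND_CO, axial=False)
        _place("C5", "N5", BOND_CN, axial=False)
        _place("C6", "C7", BOND_CC, axial=False)
        atoms["O7"] = place_atom(atoms["O6"], atoms["C6"], atoms["C7"], BOND_CO, TET, -60.0)

    order = names + [nm for nm in atoms if nm not in names]
    res = Residue(code="", seq=0, chain="A", monosaccharide=monosaccharide, anomer=anomer)
    for nm in order:
        res.atoms.append(
            AtomRecord(
                serial=0,
                name=nm,
                element=nm[0],
                residue_code="",
                residue_seq=0,
                chain="A",
                position=atoms[nm],
                b_factor=20.0,
            )
        )
    return res


# ---------------------------------------------------------------------------
# glycan assembly


def _rigid_map(points: np.ndarray, src_o: np.ndarray, src_c: np.ndarray,
               dst_o: np.ndarray, dst_c: np.ndarray) -> np.ndarray:
    """Rigidly move points so src_o -> dst_o and src_c aligns along dst_c."""
    v_src = src_c - src_o
    v_dst = dst_c - dst_o
    a = v_src / np.linalg.norm(v_src)
    b = v_dst / np.linalg.norm(v_dst)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else -np.eye(3) + 2 * np.outer(a, a)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
    return (points - src_o) @ rot.T + dst_o


def _spin_to_dihedral(points: np.ndarray, origin, axis, current: float, target: float) -> np.ndarray:
    delta = target - current
    return rotate_about_axis(points, origin, axis, delta)


def _set_group_dihedral(group: np.ndarray, origin, axis, measure, target: float) -> np.ndarray:
    """Rotate ``group`` about axis until ``measure(group)`` equals target (deg)."""
    cur = measure(group)
    out = rotate_about_axis(group, origin, axis, target - cur)
    if abs((measure(out) - target + 180.0) % 360.0 - 180.0) > 1e-6:
        out = rotate_about_axis(group, origin, axis, -(target - cur) * 2.0)
    return out


def build_glycan(spec: GlycanBuildSpec | str) -> tuple[Model, GlycanComponent, dict]:
    """Assemble a glycan conformer with exact prescribed torsions.

    Residues are numbered 1..n in tree order (reducing end first); each
    donor subtree is rigidly rotated about its glycosidic bonds so that the
    extracted (phi, psi, omega) equal the prescribed values. Returns the
    coordinate model, the ground-truth topology, and a ground-truth record
    of the imposed torsions and puckering.
    """
    if isinstance(spec, str):
        spec = GlycanBuildSpec(sequence=spec)
    tree = iupac.parse(spec.sequence)
    nodes = list(tree.walk())
    for i, node in enumerate(nodes, start=1):
        node.seq = i  # type: ignore[attr-defined]
    tree.anomer = tree.anomer or spec.root_anomer

    residues: dict[int, Residue] = {}
    linkages: list[Linkage] = []
    truth_torsions: dict[int, tuple] = {}
    truth_puckering: dict[int, tuple] = {}

    def _target_torsions(seq: int, x: int) -> tuple[float, float, float]:
        t = spec.torsions.get(seq, ())
        phi = t[0] if len(t) > 0 else spec.default_phi
        psi = t[1] if len(t) > 1 else spec.default_psi
        omega = t[2] if len(t) > 2 else spec.default_omega
        return float(phi), float(psi), float(omega)

    def _make_residue(node) -> Residue:
        puck = spec.puckering.get(node.seq)
        res = build_residue(node.name, anomer=node.anomer or "b", puckering=puck)
        res.seq = node.seq
        res.code = node.name
        for a in res.atoms:
            a.residue_seq = node.seq
            a.residue_code = node.name
        info = MONOSACCHARIDES[node.name]
        if puck is None:
            puck = (0.57, 0.0 if info["chirality"] == "D" else 180.0, 0.0)
        elif len(puck) == 2:
            puck = (puck[0], None, puck[1])
        truth_puckering[node.seq] = tuple(puck)
        return res

    root_res = _make_residue(tree)
    residues[tree.seq] = root_res

    def _attach(parent_node, child_node):
        acceptor = residues[parent_node.seq]
        x = child_node.link_x
        if x is None:
            raise iupac.SequenceError("cannot build a glycan from a wildcard linkage")
        ox, cx = f"O{x}", f"C{x}"
        cy = _next_ring_carbon(acceptor, x)
        for nm in (ox, cx, cy):
            if not acceptor.has_atom(nm):
                raise iupac.SequenceError(
                    f"{acceptor.monosaccharide} has no position {x} to accept a linkage"
                )
        phi_t, psi_t, omega_t = _target_torsions(child_node.seq, x)

        if x == 6 and acceptor.has_atom("O6") and acceptor.has_atom("O5"):
            # impose omega on the acceptor's exocyclic arm before attaching
            o6 = acceptor.atom("O6")
            group = o6.position[None, :]
            def _measure(g):
                return dihedral_angle(g[0], acceptor.atom("C6").position,
                                      acceptor.atom("C5").position, acceptor.atom("O5").position)
            group = _set_group_dihedral(
                group, acceptor.atom("C6").position,
                acceptor.atom("C6").position - acceptor.atom("C5").position,
                _measure, omega_t,
            )
            o6.position = group[0]

        child = _make_residue(child_node)
        ac = anomeric_carbon(child_node.name)
        c_anom, o_anom = f"C{ac}", f"O{ac}"
        ring_o = child.ring_atoms[-1]

        target_c = place_atom(
            acceptor.atom(cy).position, acceptor.atom(cx).position,
            acceptor.atom(ox).position, spec.bond_co, 115.0, psi_t,
        )
        pts = child.coords()
        pts = _rigid_map(pts, child.atom(o_anom).position, child.atom(c_anom).position,
                         acceptor.atom(ox).position, target_c)
        # spin about the glycosidic C-O bond to impose phi
        names_idx = {a.name: i for i, a in enumerate(child.atoms)}
        def _measure_phi(g):
            return dihedral_angle(g[names_idx[ring_o]], g[names_idx[c_anom]],
                                  acceptor.atom(ox).position, acceptor.atom(cx).position)
        pts = _set_group_dihedral(
            pts, acceptor.atom(ox).position,
            pts[names_idx[c_anom]] - acceptor.atom(ox).position, _measure_phi, phi_t,
        )
        for a, pos in zip(child.atoms, pts):
            a.position = pos
        # the anomeric oxygen is the acceptor's Ox after condensation
        child.atoms = [a for a in child.atoms if a.name != o_anom]
        residues[child_node.seq] = child
        linkages.append(
            Linkage(donor=("A", child_node.seq), acceptor=("A", parent_node.seq), x=x,
                    anomeric_carbon=ac)
        )
        record = (phi_t, psi_t, omega_t) if x == 6 else (phi_t, psi_t)
        truth_torsions[child_node.seq] = record

    def _walk_attach(node):
        for child in node.children:
            _attach(node, child)
            _walk_attach(child)

    _walk_attach(tree)

    ordered = [residues[i] for i in sorted(residues)]
    serial = 1
    for res in ordered:
        from .model import CODES_BY_SUGAR
        res.code = CODES_BY_SUGAR.get((res.monosaccharide, res.anomer or "b"), res.code)
        for a in res.atoms:
            a.serial = serial
            a.residue_code = res.code
            serial += 1
    model = Model(residues=list(ordered))
    component = GlycanComponent(
        residues=list(ordered), linkages=linkages, root=("A", tree.seq), attachment=None
    )
    _steric_check(model)
    truth = {
        "sequence": iupac.emit(tree),
        "torsions": truth_torsions,
        "puckering": truth_puckering,
    }
    return model, component, truth


def _steric_check(model: Model) -> None:
    xyz = model.coords()
    if len(xyz) < 2:
        return
    from scipy.spatial.distance import pdist

    if float(pdist(xyz).min()) < 0.8:
        warn("steric collapse: non-bonded atoms closer than 0.8 A")


# ---------------------------------------------------------------------------
# conformer ensembles


def make_ensemble(
    build: GlycanBuildSpec | str, spec: EnsembleSpec | None = None
) -> tuple[ConformerEnsemble, dict]:
    """Conformer ensemble by von Mises torsion perturbation + positional jitter.

    The first ``n_anchor`` residues keep their exact build geometry in every
    conformer. Returns (ensemble, ground truth of the unperturbed build).
    """
    if isinstance(build, str):
        build = GlycanBuildSpec(sequence=build)
    spec = spec or EnsembleSpec()
    rng = np.random.default_rng(spec.seed)
    base_model, component, truth = build_glycan(build)
    n_res = len(component.residues)
    n_anchor = spec.n_anchor if spec.n_anchor is not None else (5 if n_res >= 5 else 1)

    def _kappa_for(seq: int) -> float | None:
        if spec.kappa is None:
            return None
        if isinstance(spec.kappa, dict):
            return spec.kappa.get(seq)
        return spec.kappa

    acceptor_of = {lk.donor[1]: lk.acceptor[1] for lk in component.linkages}
    conformers: list[Model] = []
    for _ in range(spec.n_conformers):
        torsions = {}
        for seq, base in truth["torsions"].items():
            kappa = _kappa_for(seq)
            vals = list(base)
            if kappa is not None and seq > n_anchor:
                noise = np.degrees(rng.vonmises(0.0, kappa, size=len(vals)))
                vals = [v + d for v, d in zip(vals, noise)]
                # omega rotates the acceptor's own exocyclic arm: keep it
                # fixed when the acceptor residue is anchored
                if len(vals) > 2 and acceptor_of.get(seq, 0) <= n_anchor:
                    vals[2] = base[2]
            torsions[seq] = tuple(vals)
        pspec = GlycanBuildSpec(
            sequence=build.sequence, torsions=torsions, puckering=build.puckering,
            default_phi=build.default_phi, default_psi=build.default_psi,
            default_omega=build.default_omega, root_anomer=build.root_anomer,
        )
        model, _, _ = build_glycan(pspec)
        if spec.jitter_sigma > 0:
            for res in model.residues:
                if res.seq > n_anchor:
                    for a in res.atoms:
                        a.position = a.position + rng.normal(0.0, spec.jitter_sigma, 3)
        conformers.append(model)

    weights = spec.weights
    ens = ConformerEnsemble(
        glycan=component, conformers=conformers, weights=weights,
        labels=[f"cluster{i}" for i in range(spec.n_conformers)], source_kind="md",
    )
    return ens, truth


# ---------------------------------------------------------------------------
# protein scenes

_AA_TEMPLATES: dict[str, list[tuple[str, str]]] = {
    # (atom name, element); chained along +x with ~1.5 A spacing, side chain last
    "TRP": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"), ("CD1", "C"), ("NE1", "N")],
    "ASN": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"), ("OD1", "O"), ("ND2", "N")],
    "SER": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O")],
    "THR": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG1", "O"), ("CG2", "C")],
    "TYR": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("CG", "C"), ("OH", "O")],
    "ALA": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")],
}


def _amino_acid(code: str, seq: int, chain: str = "P") -> Residue:
    if code not in _AA_TEMPLATES:
        raise ValueError(f"no template for amino acid {code}")
    res = Residue(code=code, seq=seq, chain=chain)
    # zig-zag chain so no two atoms coincide; side-chain tip has the largest x
    for i, (nm, el) in enumerate(_AA_TEMPLATES[code]):
        pos = np.array([1.45 * i, 0.5 * (i % 2), 0.0])
        res.atoms.append(
            AtomRecord(serial=0, name=nm, element=el, residue_code=code,
                       residue_seq=seq, chain=chain, position=pos, b_factor=15.0, het=False)
        )
    return res


def make_complex(
    build: GlycanBuildSpec | str,
    pocket: list[tuple[str, float]] = (("TRP", 3.5),),
) -> tuple[Model, GlycanComponent, dict]:
    """A free glycan plus protein residues at prescribed minimum distances."""
    model, component, truth = build_glycan(build)
    gly_xyz = model.coords()
    rng_dirs = _unit_directions(len(pocket))
    placed = {}
    for i, ((code, dist), u) in enumerate(zip(pocket, rng_dirs)):
        if dist < 2.0:
            raise ValueError(f"requested contact distance {dist} A < 2 A")
        res = _amino_acid(code, seq=101 + i)
        # orient template tip (last atom) toward the glycan, body away
        tip = res.atoms[-1].position
        body = res.coords().mean(axis=0)
        pts = _rigid_map(res.coords(), tip, body, np.zeros(3), u)
        proj = gly_xyz @ u
        anchor = gly_xyz[int(np.argmax(proj))]
        pts = pts + (anchor + dist * u)
        for a, p in zip(res.atoms, pts):
            a.position = p
        # trim to the exact minimum distance (two corrective steps)
        for _ in range(3):
            d = np.sqrt(((pts[:, None, :] - gly_xyz[None, :, :]) ** 2).sum(-1)).min()
            pts = pts + (dist - d) * u
        for a, p in zip(res.atoms, pts):
            a.position = p
        placed[res.key] = round(float(np.sqrt(((pts[:, None, :] - gly_xyz[None, :, :]) ** 2).sum(-1)).min()), 4)
        model.residues.append(res)
    truth = dict(truth, pocket={k: v for k, v in placed.items()})
    return model, component, truth


def _unit_directions(k: int) -> list[np.ndarray]:
    dirs = [np.array([1.0, 0, 0]), np.array([-1.0, 0, 0]), np.array([0, 1.0, 0]),
            np.array([0, -1.0, 0]), np.array([0, 0, 1.0]), np.array([0, 0, -1.0])]
    if k > len(dirs):
        raise ValueError("at most 6 pocket residues supported")
    return dirs[:k]


def make_glycopeptide(
    build: GlycanBuildSpec | str,
    site: str = "ASN",
    linker_phi: float = -97.0,
    linker_psi: float = 178.0,
) -> tuple[Model, GlycanComponent, dict]:
    """A glycan covalently attached to an Asn (N-linked) or Ser/Thr (O-linked)."""
    model, component, truth = build_glycan(build)
    aa = _amino_acid(site, seq=100)
    site_atom = {"ASN": "ND2", "SER": "OG", "THR": "OG1"}[site]
    prev1 = {"ASN": "CG", "SER": "CB", "THR": "CB"}[site]
    prev2 = {"ASN": "CB", "SER": "CA", "THR": "CA"}[site]

    root = model.residue(*component.root)
    ac = anomeric_carbon(root.monosaccharide)
    c_anom = f"C{ac}"
    ring_o = root.ring_atoms[-1]
    target_c = place_atom(
        aa.atom(prev2).position, aa.atom(prev1).position, aa.atom(site_atom).position,
        BOND_CN, 115.0, linker_psi,
    )
    gly_atoms = model.atoms
    pts = np.array([a.position for a in gly_atoms])
    # map the whole glycan: anomeric O1 condenses onto the side-chain site atom
    o1 = root.atom("O1").position if root.has_atom("O1") else root.atom(f"O{ac}").position
    pts = _rigid_map(pts, o1, root.atom(c_anom).position, aa.atom(site_atom).position, target_c)
    idx = {id(a): i for i, a in enumerate(gly_atoms)}
    def _measure_phi(g):
        return dihedral_angle(g[idx[id(root.atom(ring_o))]], g[idx[id(root.atom(c_anom))]],
                              aa.atom(site_atom).position, aa.atom(prev1).position)
    pts = _set_group_dihedral(
        pts, aa.atom(site_atom).position,
        pts[idx[id(root.atom(c_anom))]] - aa.atom(site_atom).position, _measure_phi, linker_phi,
    )
    for a, p in zip(gly_atoms, pts):
        a.position = p
    anomeric_o = f"O{ac}"
    root.atoms = [a for a in root.atoms if a.name != anomeric_o]
    model.residues.insert(0, aa)
    component.attachment = (aa, site_atom)
    truth = dict(truth, linker=(linker_phi, linker_psi), site=(site, site_atom))
    return model, component, truth


# ---------------------------------------------------------------------------
# binding tables


def simulate_binding(
    properties: dict[str, float] | pd.Series,
    slope: float = 0.05,
    noise_sd: float = 0.5,
    protein: str = "lectin1",
    seed: int = 0,
) -> pd.DataFrame:
    """Binding z-scores linear in a structural property plus Gaussian noise."""
    if len(properties) < 3:
        raise ValueError("need at least 3 glycans")
    if noise_sd <= 0:
        raise ValueError("noise sd must be positive")
    ser = pd.Series(properties, dtype=float)
    rng = np.random.default_rng(seed)
    z = slope * ser.to_numpy() + rng.normal(0.0, noise_sd, len(ser))
    return pd.DataFrame({"glycan": ser.index, "protein": protein, "z": z})
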