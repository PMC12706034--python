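"""PDB reading/writing, glycan detection, and conformer-ensemble assembly.

File structure is inferred automatically: a file is treated as glycan-only
(MD/X-ray style), a protein-glycan complex, or a glycosylated protein,
depending on the presence of amino acids and of covalent glycan-protein
bonds. Glycosidic bonds are detected geometrically (anomeric carbon to an
oxygen/nitrogen of another residue within ``BOND_CUTOFF``).
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import networkx as nx
import numpy as np
import pandas as pd

from . import iupac
from .geometry import dihedral_angle
from .model import (
    MODIFICATION_CODES,
    SUGAR_CODES,
    AtomRecord,
    ConformerEnsemble,
    GlycanComponent,
    Linkage,
    Model,
    Residue,
    anomeric_carbon,
    warn,
)

#: covalent glycosidic-bond cutoff in A (C-O covalent bonds are ~1.4 A;
#: the margin tolerates model strain without bridging packing contacts)
BOND_CUTOFF = 1.8

_WATER = {"HOH", "WAT", "DOD"}


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parsing


def _validate_coordinate_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: malformed {what} coordinate field {fieldtxt!r}"
                    ) from None


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep the highest-occupancy alternative per atom name (tie -> 'A')."""
    by_name: dict[str, list[AtomRecord]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name, group in by_name.items():
        if len(group) == 1:
            out.append(group[0])
        else:
            group.sort(key=lambda a: (-a.occupancy, a.alt_loc or "A"))
            out.append(group[0])
    out.sort(key=lambda a: a.serial)
    return out


def _anomer_from_geometry(res: Residue) -> str:
    """Anomer from the sign of the improper dihedral C2-C1-O5-O1.

    Calibrated on ideal 4C1 D-pyranose templates: a negative improper
    corresponds to an axial anomeric oxygen (alpha for D-sugars).
    """
    ac = anomeric_carbon(res.monosaccharide) if res.monosaccharide else 1
    names = (f"C{ac + 1}", f"C{ac}", res.ring_atoms[-1] if res.ring_atoms else "O5", f"O{ac}")
    if not all(res.has_atom(n) for n in names):
        return ""
    try:
        improper = dihedral_angle(*(res.atom(n).position for n in names))
    except Exception:
        return ""
    return "a" if improper < 0 else "b"


def parse_structure(path_or_text: str | os.PathLike) -> tuple[list[Model], dict]:
    """Parse PDB text (or a path to it) into coordinate models + metadata.

    Returns one :class:`Model` per MODEL block (one if absent). Hydrogens
    are dropped and alternative locations resolved to the best-occupancy
    conformer. Metadata reports the inferred ``source_kind``.
    """
    text = None
    if isinstance(path_or_text, (str, os.PathLike)):
        p = Path(path_or_text)
        if isinstance(path_or_text, os.PathLike) or (
            len(str(path_or_text)) < 4096 and "\n" not in str(path_or_text) and p.suffix
        ):
            try:
                if p.exists():
                    text = p.read_text()
            except OSError:
                text = None
    if text is None:
        text = str(path_or_text)
    if not text.strip():
        raise ParseError("empty PDB input")
    _validate_coordinate_lines(text)
    st = gemmi.read_pdb_string(text)
    if sum(len(ch) for mdl in st for ch in mdl) == 0:
        raise ParseError("no atoms found in PDB input")

    models: list[Model] = []
    for gm in st:
        model = Model()
        serial = 0
        for chain in gm:
            for gres in chain:
                res = Residue(code=gres.name.strip(), seq=gres.seqid.num, chain=chain.name or "A")
                raw = []
                for ga in gres:
                    el = ga.element.name
                    if el in ("H", "D"):
                        continue
                    serial += 1
                    raw.append(
                        AtomRecord(
                            serial=ga.serial or serial,
                            name=ga.name,
                            element=el,
                            residue_code=res.code,
                            residue_seq=res.seq,
                            chain=res.chain,
                            position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            b_factor=max(ga.b_iso, 0.0),
                            occupancy=ga.occ,
                            alt_loc=ga.altloc.strip() if isinstance(ga.altloc, str) else (ga.altloc or ""),
                            het=gres.het_flag == "H",
                        )
                    )
                res.atoms = _resolve_altlocs(raw)
                if not res.atoms:
                    continue
                if res.code in SUGAR_CODES:
                    res.monosaccharide, res.anomer = SUGAR_CODES[res.code]
                    if not res.anomer:
                        res.anomer = _anomer_from_geometry(res)
                model.residues.append(res)
        if model.residues:
            models.append(model)
    if not models:
        raise ParseError("no coordinate models found")

    metadata = {"n_models": len(models), "source_kind": _infer_source_kind(models[0])}
    return models, metadata


def _infer_source_kind(model: Model) -> str:
    has_protein = any(r.is_amino_acid for r in model.residues)
    sugars = [r for r in model.residues if r.code in SUGAR_CODES]
    if not sugars:
        return "protein" if has_protein else "empty"
    if not has_protein:
        return "md"
    # covalent bond between any sugar anomeric carbon and a protein N/O?
    for res in sugars:
        ac = anomeric_carbon(res.monosaccharide)
        if not res.has_atom(f"C{ac}"):
            continue
        cpos = res.atom(f"C{ac}").position
        for other in model.residues:
            if not other.is_amino_acid:
                continue
            for a in other.atoms:
                if a.element in ("N", "O") and np.linalg.norm(a.position - cpos) <= BOND_CUTOFF:
                    return "glycoprotein"
    return "complex"


# ---------------------------------------------------------------------------
# glycan detection


def detect_glycans(model: Model, bond_cutoff: float = BOND_CUTOFF) -> list[GlycanComponent]:
    """Group sugar residues into rooted glycan components via bond detection.

    The root of each component is the residue whose anomeric carbon is free
    or protein-linked. A cyclic bond graph raises an error naming the
    residues involved; an unrecognized code bonded into a component is kept
    with an empty monosaccharide and a warning.
    """
    sugars = [r for r in model.residues if r.code in SUGAR_CODES]
    if not sugars:
        return []
    graph = nx.DiGraph()
    for r in sugars:
        graph.add_node(r.key, residue=r)

    for donor in sugars:
        ac = anomeric_carbon(donor.monosaccharide)
        if not donor.has_atom(f"C{ac}"):
            continue
        cpos = donor.atom(f"C{ac}").position
        best = None
        for acceptor in sugars:
            if acceptor.key == donor.key:
                continue
            for a in acceptor.atoms:
                if a.element != "O" or a.name in donor.ring_atoms:
                    continue
                d = float(np.linalg.norm(a.position - cpos))
                if d <= bond_cutoff and (best is None or d < best[0]):
                    digits = "".join(ch for ch in a.name if ch.isdigit())
                    if digits:
                        best = (d, acceptor, int(digits))
        if best is not None:
            _, acceptor, x = best
            graph.add_edge(donor.key, acceptor.key, x=x, anomeric_carbon=ac)

    try:
        cycle = nx.find_cycle(graph.to_undirected())
        names = sorted({f"{model.residue(*k).code}{k[1]}" for edge in cycle for k in edge[:2]})
        raise ParseError(f"cyclic glycosidic bond graph involving residues {names}")
    except nx.NetworkXNoCycle:
        pass

    components = []
    for comp_keys in nx.connected_components(graph.to_undirected()):
        residues = [model.residue(*k) for k in sorted(comp_keys, key=lambda k: (k[0], k[1]))]
        linkages = [
            Linkage(donor=u, acceptor=v, x=d["x"], anomeric_carbon=d["anomeric_carbon"])
            for u, v, d in graph.edges(data=True)
            if u in comp_keys
        ]
        roots = [r.key for r in residues if graph.out_degree(r.key) == 0]
        root = roots[0] if roots else residues[0].key
        attachment = _find_attachment(model, model.residue(*root), bond_cutoff)
        comp = GlycanComponent(residues=residues, linkages=linkages, root=root, attachment=attachment)
        _warn_unknown_neighbors(model, comp, bond_cutoff)
        components.append(comp)
    components.sort(key=lambda c: c.root)
    return components


def _find_attachment(model: Model, root: Residue, cutoff: float):
    ac = anomeric_carbon(root.monosaccharide)
    if not root.has_atom(f"C{ac}"):
        return None
    cpos = root.atom(f"C{ac}").position
    for other in model.residues:
        if not other.is_amino_acid:
            continue
        for a in other.atoms:
            if a.element in ("N", "O") and a.name not in ("N", "O") and (
                np.linalg.norm(a.position - cpos) <= cutoff
            ):
                return (other, a.name)
    return None


def _warn_unknown_neighbors(model: Model, comp: GlycanComponent, cutoff: float) -> None:
    comp_xyz = np.vstack([r.coords() for r in comp.residues])
    for other in model.residues:
        if other.is_amino_acid or other.code in SUGAR_CODES or other.code in _WATER:
            continue
        if other.code in MODIFICATION_CODES:
            continue
        d = np.sqrt(((other.coords()[:, None, :] - comp_xyz[None, :, :]) ** 2).sum(-1)).min()
        if d <= cutoff:
            warn(f"unrecognized residue code {other.code!r} bonded to a glycan; kept unassigned")
            comp.residues.append(other)


# ---------------------------------------------------------------------------
# IUPAC emission


def to_iupac(component: GlycanComponent) -> str:
    """Canonical IUPAC-condensed sequence of a detected component."""
    unknown = sorted({r.code for r in component.residues if not r.monosaccharide})
    if unknown:
        raise ValueError(f"unknown monosaccharide codes in component: {unknown}")

    def _node(key) -> iupac.SeqNode:
        res = component.residue(key)
        node = iupac.SeqNode(name=res.monosaccharide, anomer=res.anomer or "?")
        for lk in component.donors_of(key):
            child = _node(lk.donor)
            child.link_x = lk.x
            node.children.append(child)
        return node

    return iupac.emit(_node(component.root))


# ---------------------------------------------------------------------------
# conformer selection & pockets


def infer_glycan_class(component: GlycanComponent) -> str:
    """Heuristic glycan class from the reducing-end residue."""
    root = component.residue(component.root)
    names = [r.monosaccharide for r in component.residues]
    if root.monosaccharide == "GalNAc":
        return "O"
    if root.monosaccharide == "GlcNAc" and names.count("Man") >= 2:
        return "N"
    if root.monosaccharide in ("Glc", "Gal"):
        return "lipid"
    return "free"


def select_physiological_conformers(
    ensembles_by_anomer: dict[str, ConformerEnsemble], glycan_class: str
) -> ConformerEnsemble:
    """Pick the physiologically relevant reducing-end anomer group.

    O-glycans and glycolipids occur with alpha reducing ends, N-glycans
    with beta; if the requested group is absent the other is returned with
    a warning. Weights are renormalized over the selected group.
    """
    if not ensembles_by_anomer:
        raise ValueError("no anomeric groups supplied")
    wanted = "b" if glycan_class == "N" else "a"
    if wanted not in ensembles_by_anomer:
        other = next(iter(ensembles_by_anomer))
        warn(f"no {wanted}-anomer conformers for class {glycan_class}; using {other} group")
        wanted = other
    ens = ensembles_by_anomer[wanted]
    return ConformerEnsemble(
        glycan=ens.glycan, conformers=ens.conformers,
        weights=np.asarray(ens.weights) / np.sum(ens.weights),
        labels=list(ens.labels), source_kind=ens.source_kind,
    )


def get_binding_pocket(
    model: Model, component: GlycanComponent, cutoff: float = 5.0
) -> pd.DataFrame:
    """Protein residues/atoms within ``cutoff`` A of any glycan heavy atom.

    Returns one row per contacting protein atom (chain, seq, code, atom,
    distance), sorted by each residue's minimum distance.
    """
    glycan_xyz = np.vstack([r.coords() for r in component.residues])
    rows = []
    protein = [r for r in model.residues if r.is_amino_acid]
    if not protein:
        warn("no protein residues present; empty binding pocket")
        return pd.DataFrame(columns=["chain", "seq", "code", "atom", "distance", "residue_min"])
    for res in protein:
        for a in res.atoms:
            d = float(np.sqrt(((glycan_xyz - a.position) ** 2).sum(-1)).min())
            if d <= cutoff:
                rows.append({"chain": res.chain, "seq": res.seq, "code": res.code,
                             "atom": a.name, "distance": round(d, 4)})
    df = pd.DataFrame(rows, columns=["chain", "seq", "code", "atom", "distance"])
    if df.empty:
        df["residue_min"] = []
        return df
    df["residue_min"] = df.groupby(["chain", "seq"])["distance"].transform("min")
    return df.sort_values(["residue_min", "distance"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# writing


def write_pdb(models: Model | list[Model], path: str | os.PathLike | None = None) -> str:
    """Fixed-column PDB text (MODEL/ENDMDL framing for multi-model input)."""
    if isinstance(models, Model):
        models = [models]
    st = gemmi.Structure()
    st.name = "g3k"
    for i, model in enumerate(models, start=1):
        gm = gemmi.Model(i)
        chains: dict[str, gemmi.Chain] = {}
        for res in model.residues:
            ch = chains.get(res.chain)
            if ch is None:
                ch = gemmi.Chain(res.chain or "A")
                chains[res.chain] = ch
                gm.add_chain(ch)
                ch = gm[-1]
                chains[res.chain] = ch
            gres = gemmi.Residue()
            gres.name = res.code or "UNK"
            gres.seqid = gemmi.SeqId(res.seq, " ")
            gres.het_flag = "H" if not res.is_amino_acid else "A"
            for a in res.atoms:
                if np.any(np.abs(a.position) >= 10000.0):
                    raise ValueError(
                        f"coordinate overflow of the PDB 8.3 field for atom {a.name}"
                    )
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.b_iso = a.b_factor
                ga.occ = a.occupancy
                gres.add_atom(ga)
            ch.add_residue(gres)
        st.add_model(gm)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_weights(path: str | os.PathLike) -> list[tuple[str, float]]:
    """Sidecar conformer-weight table: two TSV columns (label, fraction)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, frac = line.split("\t")[:2]
        rows.append((label, float(frac)))
    return rows


def write_weights(labels: list[str], weights, path: str | os.PathLike) -> None:
    lines = [f"{lb}\t{float(w):.6f}" for lb, w in zip(labels, weights)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_ensemble(
    path: str | os.PathLike,
    weights_path: str | os.PathLike | None = None,
    source_kind: str | None = None,
) -> ConformerEnsemble:
    """Read a (multi-model) PDB plus optional weight sidecar into an ensemble."""
    models, meta = parse_structure(path)
    comps = detect_glycans(models[0])
    if not comps:
        raise ParseError("no glycan component detected")
    comp = max(comps, key=lambda c: len(c.residues))
    labels = [f"model{i + 1}" for i in range(len(models))]
    weights = None
    if weights_path is not None:
        rows = read_weights(weights_path)
        if len(rows) != len(models):
            raise ValueError("weight sidecar length does not match model count")
        labels = [r[0] for r in rows]
        weights = np.array([r[1] for r in rows])
    return ConformerEnsemble(
        glycan=comp, conformers=models, weights=weights, labels=labels,
        source_kind=source_kind or meta["source_kind"],
    )
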