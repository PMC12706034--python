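"""Shared domain types for glycan 3D analysis.

The unit of analysis is a :class:`ConformerEnsemble`: one glycan topology
(:class:`GlycanComponent`) carried by one or more coordinate conformers,
each with a cluster-proportion weight (e.g. representatives of MD clusters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# chemistry tables

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: ring chemistry per canonical monosaccharide name
#: ring kinds: pyranose (C1..C5+O5), furanose (C1..C4+O4), sialic (C2..C6+O6)
MONOSACCHARIDES: dict[str, dict] = {
    "Glc":     {"ring": "pyranose", "anomeric": 1, "chirality": "D", "axial": set()},
    "Gal":     {"ring": "pyranose", "anomeric": 1, "chirality": "D", "axial": {"O4"}},
    "Man":     {"ring": "pyranose", "anomeric": 1, "chirality": "D", "axial": {"O2"}},
    "GlcNAc":  {"ring": "pyranose", "anomeric": 1, "chirality": "D", "axial": set(), "n_acetyl": True},
    "GalNAc":  {"ring": "pyranose", "anomeric": 1, "chirality": "D", "axial": {"O4"}, "n_acetyl": True},
    "Fuc":     {"ring": "pyranose", "anomeric": 1, "chirality": "L", "axial": {"O2"}, "deoxy6": True},
    "Xyl":     {"ring": "pyranose", "anomeric": 1, "chirality": "D", "axial": set(), "no_c6": True},
    "Neu5Ac":  {"ring": "sialic",   "anomeric": 2, "chirality": "D", "axial": set()},
    "Neu5Gc":  {"ring": "sialic",   "anomeric": 2, "chirality": "D", "axial": set()},
    "Araf":    {"ring": "furanose", "anomeric": 1, "chirality": "L", "axial": set()},
}

#: PDB chemical-component codes -> (canonical monosaccharide, anomer or "")
#: anomer "" means the code does not pin it and geometry must decide.
SUGAR_CODES: dict[str, tuple[str, str]] = {
    "NAG": ("GlcNAc", "b"), "NDG": ("GlcNAc", "a"),
    "MAN": ("Man", "a"), "BMA": ("Man", "b"),
    "GAL": ("Gal", "b"), "GLA": ("Gal", "a"),
    "GLC": ("Glc", "a"), "BGC": ("Glc", "b"),
    "FUC": ("Fuc", "a"), "FUL": ("Fuc", "b"),
    "XYS": ("Xyl", "a"), "XYP": ("Xyl", "b"),
    "A2G": ("GalNAc", "a"), "NGA": ("GalNAc", "b"),
    "SIA": ("Neu5Ac", "a"), "SLB": ("Neu5Ac", "b"),
    "NGC": ("Neu5Gc", "a"),
    "AHR": ("Araf", "a"), "BXX": ("Araf", "b"),
}

#: inverse map: (monosaccharide, anomer) -> PDB code, for writing
CODES_BY_SUGAR: dict[tuple[str, str], str] = {v: k for k, v in reversed(list(SUGAR_CODES.items()))}

#: residue codes of covalent sugar modifications handled by SASA attribution
MODIFICATION_CODES = {"SO4", "SO3", "ACE", "ACY", "PCH", "PC", "MEX", "PO4"}

GREEK = {"a": "α", "b": "β"}


def ring_atom_names(monosaccharide: str) -> list[str]:
    """Ordered ring-atom names for a canonical monosaccharide."""
    kind = MONOSACCHARIDES[monosaccharide]["ring"]
    if kind == "pyranose":
        return ["C1", "C2", "C3", "C4", "C5", "O5"]
    if kind == "furanose":
        return ["C1", "C2", "C3", "C4", "O4"]
    return ["C2", "C3", "C4", "C5", "C6", "O6"]  # sialic


def anomeric_carbon(monosaccharide: str) -> int:
    return MONOSACCHARIDES[monosaccharide]["anomeric"]


# ---------------------------------------------------------------------------
# coordinate records


@dataclass
class AtomRecord:
    """One heavy atom of a PDB-style record."""

    serial: int
    name: str
    element: str
    residue_code: str
    residue_seq: int
    chain: str
    position: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    alt_loc: str = ""
    het: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.name}")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")


@dataclass
class Residue:
    """A residue (sugar, amino acid or modification) with its atoms."""

    code: str
    seq: int
    chain: str
    atoms: list[AtomRecord] = field(default_factory=list)
    monosaccharide: str = ""
    anomer: str = ""  # "a", "b" or ""

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.seq)

    @property
    def ring_atoms(self) -> list[str]:
        if not self.monosaccharide:
            return []
        return ring_atom_names(self.monosaccharide)

    @property
    def is_sugar(self) -> bool:
        return bool(self.monosaccharide) or self.code in SUGAR_CODES

    @property
    def is_amino_acid(self) -> bool:
        return self.code in AMINO_ACIDS

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.code}{self.seq}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def coords(self, names: list[str] | None = None) -> np.ndarray:
        if names is None:
            return np.array([a.position for a in self.atoms], dtype=float)
        return np.array([self.atom(n).position for n in names], dtype=float)

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)


@dataclass
class Model:
    """One coordinate model: an ordered collection of residues."""

    residues: list[Residue] = field(default_factory=list)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        atoms = self.atoms
        if len(atoms) != len(xyz):
            raise ValueError("coordinate array does not match atom count")
        for a, p in zip(atoms, xyz):
            a.position = np.asarray(p, dtype=float)

    def residue(self, chain: str, seq: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.seq == seq:
                return r
        raise KeyError(f"residue {chain}/{seq} not found")

    def copy(self) -> "Model":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# glycan topology


@dataclass(frozen=True)
class Linkage:
    """A glycosidic linkage: ``donor`` provides the anomeric carbon, bonded to
    O``x`` of ``acceptor`` (the residue nearer the reducing end)."""

    donor: tuple[str, int]
    acceptor: tuple[str, int]
    x: int
    anomeric_carbon: int = 1

    def __post_init__(self):
        if not 1 <= self.x <= 9:
            raise ValueError(f"linkage position {self.x} outside 1..9")


@dataclass
class GlycanComponent:
    """Connected sugar component: residues + rooted linkage tree.

    ``root`` is the reducing-end residue (free or protein-linked anomeric
    carbon); ``attachment`` records a covalent protein anchor when present.
    """

    residues: list[Residue]
    linkages: list[Linkage]
    root: tuple[str, int] | None = None
    attachment: tuple[Residue, str] | None = None  # (amino acid, site atom)

    def residue(self, key: tuple[str, int]) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"residue {key} not in component")

    def donors_of(self, key: tuple[str, int]) -> list[Linkage]:
        """Linkages whose acceptor is ``key`` (i.e. branches hanging off it)."""
        return [l for l in self.linkages if l.acceptor == key]

    def linkage_to_acceptor(self, donor_key: tuple[str, int]) -> Linkage | None:
        for l in self.linkages:
            if l.donor == donor_key:
                return l
        return None

    @property
    def residue_keys(self) -> list[tuple[str, int]]:
        return [r.key for r in self.residues]


@dataclass
class ConformerEnsemble:
    """One glycan's conformers with cluster-proportion weights."""

    glycan: GlycanComponent
    conformers: list[Model]
    weights: np.ndarray | None = None
    labels: list[str] | None = None
    source_kind: str = "md"  # md | xray | complex | glycoprotein

    def __post_init__(self):
        n = len(self.conformers)
        if n == 0:
            raise ValueError("ensemble needs at least one conformer")
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != n:
            raise ValueError("one weight per conformer required")
        if np.any(self.weights < 0):
            raise ValueError("conformer weights must be non-negative")
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("conformer weights sum to zero")
        if abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total
        if self.labels is None:
            self.labels = [f"conf{i}" for i in range(n)]
        counts = {len(m.atoms) for m in self.conformers}
        if len(counts) != 1:
            raise ValueError("conformers must share atom count and ordering")

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_conformers, n_atoms, 3)."""
        return np.stack([m.coords() for m in self.conformers])


def warn(message: str) -> None:
    warnings.warn(message, stacklevel=3)
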