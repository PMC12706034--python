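"""IUPAC-condensed glycan sequence parsing and emission.

Dialect: linkages written inline (``Galb1-4GlcNAc``), branches in
parentheses (``Galb1-4(Fuca1-3)GlcNAc``), reducing end rightmost. Anomers
are ``a``/``b``; motifs may use ``?`` for an unknown anomer or linkage
position and may end in a dangling linkage (``Fuca1-6``) meaning "attached
at that position to an unspecified acceptor".

Canonical emission rule: at every acceptor the main chain continues through
the donor with the deepest subtree (ties broken by lower linkage position,
then name); remaining donors are parenthesized branches ordered by
ascending linkage position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import MONOSACCHARIDES, anomeric_carbon

_LINK_RE = re.compile(r"([ab?])([12])-([1-9?])$")
_NAMES = sorted(MONOSACCHARIDES, key=len, reverse=True)


class SequenceError(ValueError):
    pass


@dataclass
class SeqNode:
    """One residue in a parsed sequence tree (children are donor branches)."""

    name: str
    anomer: str = ""          # anomer of this residue's own anomeric carbon
    link_x: int | None = None  # acceptor position this node is attached at
    children: list["SeqNode"] = field(default_factory=list)

    @property
    def anomeric(self) -> int:
        return anomeric_carbon(self.name)

    def depth(self) -> int:
        return 1 + max((c.depth() for c in self.children), default=0)

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def walk(self):
        """Yield nodes depth-first, acceptor before donors."""
        yield self
        for c in self.children:
            yield from c.walk()


def _strip_name(s: str) -> tuple[str, str]:
    for name in _NAMES:
        if s.endswith(name):
            return s[: -len(name)], name
    raise SequenceError(f"no monosaccharide name at the end of {s!r}")


def _parse_unit(s: str) -> SeqNode:
    """Parse one unit: optional donor chain/branches followed by a residue."""
    s = s.strip()
    rest, name = _strip_name(s)
    node = SeqNode(name=name)
    branches: list[SeqNode] = []
    # peel trailing parenthesized branches
    while rest.endswith(")"):
        depth, i = 0, len(rest) - 1
        while i >= 0:
            if rest[i] == ")":
                depth += 1
            elif rest[i] == "(":
                depth -= 1
                if depth == 0:
                    break
            i -= 1
        if depth != 0:
            raise SequenceError(f"unbalanced parentheses in {s!r}")
        branches.append(_parse_dangling(rest[i + 1 : -1]))
        rest = rest[:i]
    if rest:
        branches.append(_parse_dangling(rest))
    # parsed right-to-left; restore written order
    node.children = list(reversed(branches))
    return node


def _parse_dangling(s: str) -> SeqNode:
    """Parse a donor subtree ending in a linkage, e.g. ``Neu5Aca2-3``."""
    m = _LINK_RE.search(s.strip())
    if not m:
        raise SequenceError(f"expected trailing linkage in {s!r}")
    anomer, ac, x = m.groups()
    child = _parse_unit(s.strip()[: m.start()])
    if int(ac) != child.anomeric:
        raise SequenceError(
            f"linkage {m.group(0)!r} uses carbon {ac} but {child.name} "
            f"links through C{child.anomeric}"
        )
    child.anomer = anomer
    child.link_x = None if x == "?" else int(x)
    return child


def parse(sequence: str) -> SeqNode:
    """Parse an IUPAC-condensed sequence into a tree rooted at the reducing end."""
    if not sequence or not sequence.strip():
        raise SequenceError("empty sequence")
    node = _parse_unit(sequence)
    if node.anomer == "" and node.children is not None:
        # root anomer unstated in plain sequences; callers may set it
        pass
    return node


def parse_motif(motif: str) -> tuple[SeqNode, int | None]:
    """Parse a motif which may end in a dangling linkage.

    Returns ``(tree, attach_x)`` where ``attach_x`` is the acceptor position
    of a dangling linkage (None when the motif ends in a residue, or when
    the dangling position is the wildcard ``?``... the wildcard also returns
    None but with ``tree.link_x`` left unset).
    """
    motif = motif.strip()
    if _LINK_RE.search(motif):
        node = _parse_dangling(motif)
        return node, node.link_x
    return parse(motif), None


def _sort_children(node: SeqNode) -> tuple[SeqNode | None, list[SeqNode]]:
    if not node.children:
        return None, []
    ordered = sorted(
        node.children,
        key=lambda c: (-c.depth(), c.link_x if c.link_x is not None else 99, c.name),
    )
    return ordered[0], sorted(
        ordered[1:], key=lambda c: (c.link_x if c.link_x is not None else 99, c.name)
    )


def _link_str(node: SeqNode) -> str:
    x = "?" if node.link_x is None else str(node.link_x)
    anomer = node.anomer or "?"
    return f"{anomer}{node.anomeric}-{x}"


def emit(node: SeqNode) -> str:
    """Emit the canonical IUPAC-condensed string for a sequence tree."""
    main, branches = _sort_children(node)
    parts = []
    if main is not None:
        parts.append(emit(main) + _link_str(main))
    for b in branches:
        parts.append("(" + emit(b) + _link_str(b) + ")")
    parts.append(node.name)
    return "".join(parts)


def canonicalize(sequence: str) -> str:
    return emit(parse(sequence))
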