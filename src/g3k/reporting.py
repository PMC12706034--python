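"""Tabular export, run metadata, and basic plots.

Every numeric output file carries a commented metadata header (tool
version, input hashes, parameters) so runs are reproducible and
self-describing; re-running with identical inputs and parameters yields
identical numeric content.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .model import GlycanComponent, warn


@dataclass
class RunMetadata:
    tool_version: str = __version__
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    parameters: dict = field(default_factory=dict)
    timestamp: str = ""

    def add_input(self, path) -> None:
        p = Path(path)
        self.inputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]

    def stamp(self) -> "RunMetadata":
        self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        return self

    def header_lines(self) -> list[str]:
        lines = [f"# g3k {self.tool_version}"]
        if self.timestamp:
            lines.append(f"# run: {self.timestamp}")
        for path, digest in self.inputs.items():
            lines.append(f"# input: {path} sha256:{digest}")
        if self.parameters:
            lines.append(f"# params: {json.dumps(self.parameters, sort_keys=True)}")
        return lines


def write_table(
    df: pd.DataFrame, path, metadata: RunMetadata | None = None, sep: str = "\t",
    as_json: bool = False,
) -> None:
    """Write a table as TSV/CSV with a metadata header, or as JSON."""
    path = Path(path)
    if as_json:
        payload = {"metadata": metadata.__dict__ if metadata else {}, "rows": df.to_dict("records")}
        path.write_text(json.dumps(payload, indent=1, default=str))
        return
    header = "\n".join(metadata.header_lines()) + "\n" if metadata else ""
    path.write_text(header + df.to_csv(sep=sep, index=False))


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------------------
# report tables


def ramachandran_table(
    torsions: pd.DataFrame, disaccharide: str | None = None
) -> pd.DataFrame:
    """(phi, psi) rows, optionally filtered to one disaccharide.

    ``disaccharide`` uses the sequence dialect, e.g. ``Galb1-4GlcNAc``;
    the anomer or position may be ``?`` wildcards. An absent linkage
    yields an empty table with a warning.
    """
    df = torsions[torsions["context"] == "sugar-sugar"].copy()
    if disaccharide is not None:
        from . import iupac

        node = iupac.parse(disaccharide)
        if len(node.children) != 1:
            raise ValueError(f"{disaccharide!r} is not a single linkage")
        donor = node.children[0]
        keep = df["donor_name"] == donor.name
        keep &= df["acceptor_name"] == node.name
        if donor.link_x is not None:
            keep &= df["x"] == donor.link_x
        if donor.anomer and donor.anomer != "?":
            keep &= df["anomer"] == donor.anomer
        df = df[keep]
        if df.empty:
            warn(f"no linkage matching {disaccharide!r} in torsion table")
    return df[["conformer", "donor", "acceptor", "x", "anomer", "phi", "psi"]].reset_index(drop=True)


def glycan_score_table(
    values: dict, component: GlycanComponent
) -> pd.DataFrame:
    """Residue-annotated score table for external renderers.

    Values are keyed by residue key (chain, seq); each row reports the raw
    value plus its min-max normalization within the glycan (a constant
    profile normalizes to 0.5 everywhere).
    """
    keys = set(component.residue_keys)
    unknown = set(values) - keys
    if unknown:
        raise ValueError(f"profile keys {sorted(unknown)} not in component")
    vals = {k: float(v) for k, v in values.items()}
    lo, hi = min(vals.values()), max(vals.values())
    rows = []
    for k, v in vals.items():
        norm = 0.5 if hi - lo < 1e-12 else (v - lo) / (hi - lo)
        rows.append(
            {"residue": f"{k[0]}{k[1]}",
             "monosaccharide": component.residue(k).monosaccharide,
             "value": v, "normalized": round(norm, 6)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plots (optional conveniences; analyses are always table-based)


def plot_contact_map(dmap, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(dmap.matrix, cmap="viridis")
    ax.set_xticks(range(len(dmap.labels)), dmap.labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(dmap.labels)), dmap.labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="A" if dmap.mode == "distance" else "spread (A)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ramachandran(table: pd.DataFrame, path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.4, 4.4))
    ax.scatter(table["phi"], table["psi"], s=12, alpha=0.7)
    ax.set_xlim(-180, 180)
    ax.set_ylim(-180, 180)
    ax.set_xlabel("phi (deg)")
    ax.set_ylabel("psi (deg)")
    ax.set_title(title)
    ax.axhline(0, lw=0.3, color="gray")
    ax.axvline(0, lw=0.3, color="gray")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
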