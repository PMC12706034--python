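"""Structure-function statistics for glycan motifs.

Twin analysis (pairs of sequences differing only by one motif, compared
with the motif and its attachment site excluded), motif-level property
aggregation (averaging within and across motif occurrences), regression of
lectin binding z-scores on motif structure, class comparisons (one-way
ANOVA + Tukey HSD), and the shared statistical toolkit (paired t,
Mann-Whitney U, Benjamini-Hochberg, Cohen's d_z).

Residues are addressed by their position in the sequence tree's
depth-first walk (reducing end = 1), matching the numbering used by the
synthetic builder and PDB emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import iupac
from .iupac import SeqNode
from .model import warn


class MotifError(ValueError):
    pass


# ---------------------------------------------------------------------------
# binding tables


def validate_binding_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the (glycan, protein, z) long-format contract."""
    required = {"glycan", "protein", "z"}
    if not required.issubset(df.columns):
        raise MotifError(f"binding table needs columns {sorted(required)}")
    if df.duplicated(["glycan", "protein"]).any():
        raise MotifError("duplicate (glycan, protein) pairs in binding table")
    if not np.all(np.isfinite(df["z"].to_numpy(dtype=float))):
        raise MotifError("non-finite z-scores in binding table")
    return df


def read_binding_table(path) -> pd.DataFrame:
    return validate_binding_table(pd.read_csv(path))


# ---------------------------------------------------------------------------
# motif matching on sequence trees


def _walk_ids(tree: SeqNode) -> dict[int, SeqNode]:
    return {i: node for i, node in enumerate(tree.walk(), start=1)}


def _link_matches(motif: SeqNode, node: SeqNode) -> bool:
    if motif.link_x is not None and motif.link_x != node.link_x:
        return False
    if motif.anomer and motif.anomer != "?" and node.anomer and motif.anomer != node.anomer:
        return False
    return True


def _match_subtree(motif: SeqNode, node: SeqNode, terminal: bool, exact: bool):
    """All ways motif's subtree maps onto node's subtree.

    ``exact`` requires the match to consume every glycan descendant
    (pendant match, used for deletions); otherwise extra glycan branches
    are allowed. ``terminal`` requires motif leaves to map to glycan
    leaves. Yields lists of matched glycan nodes.
    """
    if motif.name != node.name:
        return
    if not motif.children:
        if terminal and node.children:
            return
        if exact and node.children:
            return
        yield [node]
        return
    if exact and len(motif.children) != len(node.children):
        return
    # assign each motif child to a distinct glycan child
    def _assign(mchildren, available):
        if not mchildren:
            yield []
            return
        first, rest = mchildren[0], mchildren[1:]
        for i, cand in enumerate(available):
            if not _link_matches(first, cand):
                continue
            for sub in _match_subtree(first, cand, terminal, exact):
                for tail in _assign(rest, available[:i] + available[i + 1 :]):
                    yield sub + tail

    for assignment in _assign(motif.children, list(node.children)):
        yield [node] + assignment


def find_motif(
    sequence: str, motif: str, terminal: bool = False
) -> list[list[int]]:
    """Occurrences of a motif in a sequence, as lists of residue ids.

    A motif ending in a dangling linkage (e.g. ``Fuca1-6``) must match a
    complete pendant subtree attached at that position; a plain motif may
    match anywhere in the tree, with extra glycan branches permitted.
    """
    try:
        mtree, _ = iupac.parse_motif(motif)
    except iupac.SequenceError as exc:
        raise MotifError(f"malformed motif {motif!r}: {exc}") from None
    pendant = _is_dangling(motif)
    tree = iupac.parse(sequence)
    ids = {id(node): i for i, node in enumerate(tree.walk(), start=1)}
    out = []
    for node in tree.walk():
        if pendant:
            if node is tree:
                continue  # a dangling motif needs an acceptor
            if not _link_matches(mtree, node):
                continue
            for match in _match_subtree(mtree, node, terminal, exact=True):
                out.append(sorted(ids[id(m)] for m in match))
        else:
            for match in _match_subtree(mtree, node, terminal, exact=False):
                out.append(sorted(ids[id(m)] for m in match))
    # de-duplicate occurrences that differ only in assignment order
    seen, unique = set(), []
    for occ in out:
        key = tuple(occ)
        if key not in seen:
            seen.add(key)
            unique.append(occ)
    return unique


def _is_dangling(motif: str) -> bool:
    import re

    return re.search(r"[ab?][12]-[1-9?]\s*$", motif) is not None


# ---------------------------------------------------------------------------
# twins


@dataclass
class TwinPair:
    """A pair of sequences differing only by one motif occurrence."""

    with_motif: str
    without_motif: str
    motif: str
    excluded_with: set[int] = field(default_factory=set)     # motif + attachment site
    excluded_without: set[int] = field(default_factory=set)  # attachment site


def _canonical_order(node: SeqNode) -> list[SeqNode]:
    main, branches = iupac._sort_children(node)
    out: list[SeqNode] = []
    if main is not None:
        out += _canonical_order(main)
    for b in branches:
        out += _canonical_order(b)
    out.append(node)
    return out


def find_twins(sequences: list[str], motif: str) -> list[TwinPair]:
    """All pairs (s, s') where deleting one motif occurrence from s gives s'.

    The motif must describe a pendant subtree (it usually ends in a
    dangling linkage, e.g. ``Fuca1-6`` for core fucose). The excluded sets
    cover the motif residues plus the attachment-site residue on the
    with-motif side, and the corresponding attachment residue on the
    without-motif side.
    """
    if not _is_dangling(motif):
        raise MotifError(
            f"twin motif {motif!r} must end in a dangling linkage (e.g. 'Fuca1-6')"
        )
    canon = {}
    for s in sequences:
        try:
            canon[s] = iupac.canonicalize(s)
        except iupac.SequenceError as exc:
            raise MotifError(f"cannot parse sequence {s!r}: {exc}") from None
    by_canon = {}
    for s, c in canon.items():
        by_canon.setdefault(c, s)

    pairs = []
    for s in sequences:
        tree = iupac.parse(s)
        ids = {id(node): i for i, node in enumerate(tree.walk(), start=1)}
        parents = {}
        for node in tree.walk():
            for child in node.children:
                parents[id(child)] = node
        for occ in find_motif(s, motif):
            occ_nodes = [n for n in tree.walk() if ids[id(n)] in set(occ)]
            roots = [n for n in occ_nodes if id(n) in parents and parents[id(n)] not in occ_nodes]
            if len(roots) != 1:
                continue
            attach = parents[id(roots[0])]
            attach.children = [c for c in attach.children if c is not roots[0]]
            deleted_canon = iupac.emit(tree)
            partner = by_canon.get(deleted_canon)
            if partner is not None and canon[s] != deleted_canon:
                order_deleted = _canonical_order(tree)
                partner_tree = iupac.parse(partner)
                order_partner = _canonical_order(partner_tree)
                pids = {id(n): i for i, n in enumerate(partner_tree.walk(), start=1)}
                pos = order_deleted.index(attach)
                attach_partner = pids[id(order_partner[pos])]
                pairs.append(
                    TwinPair(
                        with_motif=s, without_motif=partner, motif=motif,
                        excluded_with=set(occ) | {ids[id(attach)]},
                        excluded_without={attach_partner},
                    )
                )
            attach.children.append(roots[0])  # restore
    # one twin per unordered sequence pair
    seen, unique = set(), []
    for p in pairs:
        key = (p.with_motif, p.without_motif)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


def cohens_dz(diffs: np.ndarray) -> float:
    sd = float(np.std(diffs, ddof=1))
    if sd < 1e-12:
        return math_inf_signed(float(np.mean(diffs)))
    return float(np.mean(diffs) / sd)


def math_inf_signed(mean: float) -> float:
    if mean == 0:
        return 0.0
    return float("inf") if mean > 0 else float("-inf")


@dataclass
class TwinTestResult:
    n_pairs: int
    mean_with: float
    mean_without: float
    t_statistic: float
    p_value: float
    d_z: float
    degenerate: bool = False
    per_pair: pd.DataFrame | None = None


def twin_difference_test(
    pairs: list[TwinPair], profiles: dict[str, dict[int, float]]
) -> TwinTestResult:
    """Paired two-tailed t-test + Cohen's d_z over twin property profiles.

    ``profiles`` maps each sequence to {residue id: property value}
    (residue ids in tree-walk order). Motif residues and attachment sites
    are excluded per pair before averaging.
    """
    rows = []
    for p in pairs:
        prof_w = profiles.get(p.with_motif)
        prof_wo = profiles.get(p.without_motif)
        if prof_w is None or prof_wo is None:
            continue
        vals_w = [v for rid, v in prof_w.items() if rid not in p.excluded_with]
        vals_wo = [v for rid, v in prof_wo.items() if rid not in p.excluded_without]
        if not vals_w or not vals_wo:
            continue
        rows.append(
            {"with": p.with_motif, "without": p.without_motif,
             "mean_with": float(np.mean(vals_w)), "mean_without": float(np.mean(vals_wo))}
        )
    if len(rows) < 3:
        raise MotifError("twin test needs >= 3 pairs with the property computed")
    table = pd.DataFrame(rows)
    diffs = (table["mean_with"] - table["mean_without"]).to_numpy()
    sd = float(np.std(diffs, ddof=1))
    if sd < 1e-12:
        dz = math_inf_signed(float(np.mean(diffs)))
        t_stat, pval = (0.0, 1.0) if dz == 0.0 else (np.sign(dz) * np.inf, 0.0)
        return TwinTestResult(
            n_pairs=len(table), mean_with=table["mean_with"].mean(),
            mean_without=table["mean_without"].mean(), t_statistic=float(t_stat),
            p_value=float(pval), d_z=dz, degenerate=True, per_pair=table,
        )
    t_stat, pval = stats.ttest_rel(table["mean_with"], table["mean_without"])
    return TwinTestResult(
        n_pairs=len(table), mean_with=float(table["mean_with"].mean()),
        mean_without=float(table["mean_without"].mean()),
        t_statistic=float(t_stat), p_value=float(pval),
        d_z=float(np.mean(diffs) / sd), per_pair=table,
    )


# ---------------------------------------------------------------------------
# motif properties & binding correlation


def motif_property(
    profile: dict[int, float], sequence: str, motif: str,
    aggregate: str = "mean", terminal: bool = False,
) -> float | None:
    """Property of a motif in one glycan: aggregate within each occurrence
    (mean, or sum for the summed-exposure variant), then mean across
    occurrences. Returns None when the motif is absent."""
    occurrences = find_motif(sequence, motif, terminal=terminal)
    if not occurrences:
        return None
    per_occ = []
    for occ in occurrences:
        vals = [profile[rid] for rid in occ if rid in profile]
        if not vals:
            continue
        per_occ.append(float(np.sum(vals)) if aggregate == "sum" else float(np.mean(vals)))
    return float(np.mean(per_occ)) if per_occ else None


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


def lectin_structure_correlation(
    binding: pd.DataFrame, lectin: str, motif: str,
    profiles: dict[str, dict[int, float]],
    aggregate: str = "mean", terminal: bool = False,
) -> RegressionResult:
    """Least-squares regression of z-scored binding on a motif property.

    Uses every glycan that both carries the motif and has a binding row
    for ``lectin``; needs >= 3 such glycans and a non-constant predictor.
    """
    validate_binding_table(binding)
    sub = binding[binding["protein"] == lectin]
    xs, zs = [], []
    for _, row in sub.iterrows():
        prof = profiles.get(row["glycan"])
        if prof is None:
            continue
        val = motif_property(prof, row["glycan"], motif, aggregate=aggregate, terminal=terminal)
        if val is None:
            continue
        xs.append(val)
        zs.append(float(row["z"]))
    if len(xs) < 3:
        raise MotifError(f"fewer than 3 glycans with motif {motif!r} and binding for {lectin!r}")
    xs = np.asarray(xs)
    if float(np.std(xs)) < 1e-12:
        raise MotifError("constant predictor: motif property has zero variance")
    res = stats.linregress(xs, np.asarray(zs))
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        pearson_r=float(res.rvalue), p_value=float(res.pvalue), n=len(xs),
    )


# ---------------------------------------------------------------------------
# class comparisons & toolkit


@dataclass
class ClassComparison:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame
    groups: list[str]


def class_comparison(values_by_group: dict[str, np.ndarray]) -> ClassComparison:
    """One-way ANOVA + Tukey HSD over glycan-class groups.

    Groups with fewer than 2 observations are dropped with a warning.
    """
    groups = {}
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            warn(f"group {name!r} has n < 2; dropped from class comparison")
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise MotifError("class comparison needs >= 2 groups with n >= 2")
    names = list(groups)
    f_stat, pval = stats.f_oneway(*groups.values())
    tk = stats.tukey_hsd(*groups.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {"group_a": names[i], "group_b": names[j],
                 "mean_diff": float(np.mean(groups[names[i]]) - np.mean(groups[names[j]])),
                 "p_adj": float(tk.pvalue[i, j])}
            )
    return ClassComparison(
        f_statistic=float(f_stat), p_value=float(pval),
        tukey=pd.DataFrame(rows), groups=names,
    )


def unpaired_test(a, b) -> tuple[float, float]:
    """Mann-Whitney U for unpaired group comparison (two-sided)."""
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def bh_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise MotifError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
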