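"""Per-window trees, topology classes and the genealogical sorting index.

Window trees are built by neighbor joining on pairwise per-site
haplotype differences and rooted on the outgroup; this trades the
likelihood search a full phylogenomic analysis would use for a fast,
self-contained distance method, while the downstream classification is
method-agnostic.

Topology classes for the three ingroup lineages (Japan Sea ``JS``,
Pacific ``PO``, Atlantic ``AT``):

* ``species``   — JS, PO and AT are each monophyletic;
* ``geography`` — JS and PO jointly form a clade (to the exclusion of AT);
* ``ancestral`` — JS and AT jointly form a clade;
* ``unresolved``— anything else.

Precedence is species > geography > ancestral.

The genealogical sorting index (gsi) measures the degree of exclusive
ancestry of a labelled group: ``gs = (n - 1) / sum_u (c_u - 1)`` over
the internal nodes ``u`` on the paths from the group's MRCA to its
tips (``c_u`` = child count), rescaled between its minimum on the tree
and 1, so gsi = 1 iff the group is monophyletic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gio import MISSING, HaplotypeMatrix, WindowConfig, iter_windows

__all__ = [
    "TreeRecord",
    "distance_matrix",
    "nj_tree",
    "window_tree",
    "classify_topology",
    "gsi",
    "window_tree_scan",
    "TOPO_CLASSES",
]

TOPO_CLASSES = ("species", "geography", "ancestral", "unresolved")
INGROUP_LINEAGES = ("JS", "PO", "AT")


@dataclass
class TreeRecord:
    chrom: str
    start: int
    end: int
    tree: object = None                       # rooted skbio TreeNode
    topo_class: str = "unresolved"
    gsi_by_pop: dict = field(default_factory=dict)
    flag: str = ""


# ---------------------------------------------------------------------------
# distances and tree building
# ---------------------------------------------------------------------------

def distance_matrix(haps: HaplotypeMatrix, window=None):
    """Pairwise per-site difference proportions between haplotypes.

    Pairwise deletion of missing data; zero usable sites for any pair is
    an error.  Returns ``(matrix, tip_names)`` where tip names are
    ``sample#column``.
    """
    if window is not None:
        haps = haps.slice_window(window)
    A = haps.alleles
    if A.shape[0] == 0:
        raise ValueError("zero usable sites in window")
    ok = A != MISSING
    both = ok[:, :, None] & ok[:, None, :]
    diff = (A[:, :, None] != A[:, None, :]) & both
    denom = haps.length - (~both).sum(axis=0)
    if np.any(denom <= 0):
        raise ValueError("a haplotype pair has zero usable sites")
    d = diff.sum(axis=0) / denom
    names = [f"{s}#{i}" for i, s in enumerate(haps.sample_of_haplotype)]
    return d, names


def nj_tree(dist: np.ndarray, names):
    """Neighbor joining; returns an unrooted skbio TreeNode.

    Negative branch lengths produced by the NJ formulas are clamped to
    zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(dist, ids=list(names))
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def root_on_outgroup(tree, outgroup_names):
    """Root an unrooted tree on the edge leading to the outgroup.

    With several outgroup tips, roots above their LCA when they are
    monophyletic in the unrooted sense; otherwise above the first tip.
    """
    tips = [tree.find(n) for n in outgroup_names]
    if len(tips) == 1:
        target = tips[0]
    else:
        target = tree.lca(tips)
        if target is tree.root():
            target = tips[0]
    rooted = tree.root_at(
        target, above=True, branch_attrs=[], root_name=None
    )
    return rooted


def window_tree(haps: HaplotypeMatrix, outgroup_pop: str = "OUT",
                window=None):
    """NJ tree over a window's haplotypes, rooted on the outgroup.

    Returns ``(tree, flag)``; ``flag`` is ``"star"`` when all ingroup
    haplotypes are identical (the tree is still returned).
    """
    if window is not None:
        haps = haps.slice_window(window)
    d, names = distance_matrix(haps)
    pops = haps.pop_of_haplotype
    out_names = [n for n, p in zip(names, pops) if p == outgroup_pop]
    if not out_names:
        raise ValueError(f"no outgroup haplotypes ({outgroup_pop!r}) present")
    in_idx = [i for i, p in enumerate(pops) if p != outgroup_pop]
    if len(in_idx) < 3:
        raise ValueError("need at least three ingroup haplotypes")
    flag = ""
    if np.allclose(d[np.ix_(in_idx, in_idx)], 0):
        flag = "star"
    tree = nj_tree(d, names)
    return root_on_outgroup(tree, out_names), flag


# ---------------------------------------------------------------------------
# monophyly, classification, gsi
# ---------------------------------------------------------------------------

def _tips_by_pop(tree, pop_of_tip: dict):
    groups: dict = {}
    for tip in tree.tips():
        pop = pop_of_tip.get(tip.name)
        groups.setdefault(pop, []).append(tip.name)
    return groups


def _is_monophyletic(tree, names) -> bool:
    names = set(names)
    if not names:
        return False
    tips = [tree.find(n) for n in names]
    if len(tips) == 1:
        return True
    lca = tree.lca(tips)
    under = {t.name for t in lca.tips()}
    return under == names


def classify_topology(tree, pop_of_tip: dict, outgroup_pop: str = "OUT"
                      ) -> str:
    """Classify a rooted window tree into species/geography/ancestral.

    Requires all three ingroup lineages among the tips; otherwise
    returns ``unresolved``.
    """
    groups = _tips_by_pop(tree, pop_of_tip)
    if any(lin not in groups for lin in INGROUP_LINEAGES):
        return "unresolved"
    js, po, at = (groups[lin] for lin in INGROUP_LINEAGES)
    if all(_is_monophyletic(tree, g) for g in (js, po, at)):
        return "species"
    if _is_monophyletic(tree, js + po):
        return "geography"
    if _is_monophyletic(tree, js + at):
        return "ancestral"
    return "unresolved"


def gsi(tree, group_names) -> float:
    """Genealogical sorting index of a group of tips on a rooted tree.

    1 for a monophyletic group, approaching 0 as uniting the group
    requires traversing the whole tree.  Defined as 1 when the group
    spans all tips.
    """
    group = set(group_names)
    if not group:
        raise ValueError("group must be non-empty")
    all_tips = [t.name for t in tree.tips()]
    if not group <= set(all_tips):
        raise ValueError("group contains unknown tip names")
    n = len(group)
    N = len(all_tips)
    if n == N:
        return 1.0
    if n == 1:
        return 1.0

    def denom_over(nodes):
        return sum(len(u.children) - 1 for u in nodes)

    tips = [tree.find(name) for name in group]
    mrca = tree.lca(tips)
    # uniting nodes: internal nodes under (and including) the MRCA whose
    # subtree contains at least one group tip
    uniting = [
        u for u in mrca.traverse(include_self=True)
        if u.children and any(t.name in group for t in u.tips())
    ]
    gs = (n - 1) / denom_over(uniting)
    internals = [u for u in tree.traverse(include_self=True) if u.children]
    gs_min = (n - 1) / denom_over(internals)
    if gs_min >= 1.0:
        return 1.0
    return float((gs - gs_min) / (1.0 - gs_min))


# ---------------------------------------------------------------------------
# windowed driver
# ---------------------------------------------------------------------------

def window_tree_scan(haps: HaplotypeMatrix, cfg: WindowConfig | None = None,
                     outgroup_pop: str = "OUT") -> pd.DataFrame:
    """Build, classify and score a tree for every window with data."""
    cfg = cfg or WindowConfig(min_usable_sites=1)
    pop_of_tip = {
        f"{s}#{i}": haps.pop_of_sample[s]
        for i, s in enumerate(haps.sample_of_haplotype)
    }
    rows = []
    for win in iter_windows(haps.length, cfg):
        rec = TreeRecord(haps.chrom, win[0], win[1])
        try:
            tree, flag = window_tree(haps, outgroup_pop, win)
        except ValueError as exc:
            rec.flag = str(exc)
            rows.append(rec)
            continue
        rec.tree, rec.flag = tree, flag
        rec.topo_class = classify_topology(tree, pop_of_tip, outgroup_pop)
        groups = _tips_by_pop(tree, pop_of_tip)
        for lin in INGROUP_LINEAGES:
            if lin in groups:
                rec.gsi_by_pop[lin] = gsi(tree, groups[lin])
        rows.append(rec)
    out = pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "topo_class": r.topo_class, "flag": r.flag,
        **{f"gsi_{k}": v for k, v in r.gsi_by_pop.items()},
        "newick": (str(r.tree).strip() if r.tree is not None else ""),
    } for r in rows])
    return out
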