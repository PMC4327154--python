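"""Rooted tree construction from polarized haploid SNP haplotypes.

Non-recombining haploid data are near-perfectly tree-like: almost every
site's derived-carrier set is a clade. The builder therefore constructs a
rooted perfect phylogeny from the sites whose carrier sets form a laminar
family (pairwise nested or disjoint), and places the residue — recurrent
sites — on the fixed tree by two-state minimum-change (Fitch/Hartigan)
parsimony. The whole procedure is deterministic.

Site patterns are weighted by how many sites share them when choosing the
laminar family greedily, so a clade supported by many mutations always
beats a conflicting one-off homoplasy pattern.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (MISSING, FormatError, HaplotypeMatrix, Mutation,
                      MutationTree, Node, STRProfileTable)

__all__ = [
    "MutationTree", "Node", "Mutation", "SiteCompatibilityReport",
    "polarize", "build_tree", "place_recurrent", "mutations_to_root",
    "identical_groups", "IdentityReport",
]


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def polarize(matrix: HaplotypeMatrix,
             ancestral_source: str | Mapping[str, str] = "ref-is-ancestral"
             ) -> HaplotypeMatrix:
    """Recode calls so that 1 always means the derived state.

    ``ancestral_source`` is one of

    * ``"ref-is-ancestral"`` — trust the reference allele;
    * ``"outgroup:<sample_id>"`` — the named sample (e.g. a great-ape
      genome sequenced alongside) carries the ancestral allele; it is
      removed from the returned matrix;
    * a mapping ``site_id -> ancestral base``.

    Sites whose ancestral allele cannot be resolved are flagged
    ``ancestral_known=False`` (tree building skips them by default).
    """
    calls = matrix.calls.copy()
    known = np.ones(matrix.n_sites, dtype=bool)
    sample_ids = list(matrix.sample_ids)

    if isinstance(ancestral_source, str) and \
            ancestral_source.startswith("outgroup:"):
        og = ancestral_source.split(":", 1)[1]
        og_i = matrix.sample_index(og)
        anc_alleles = []
        for j, site in enumerate(matrix.sites):
            c = calls[og_i, j]
            if c == MISSING:
                anc_alleles.append(None)
                known[j] = False
            else:
                anc_alleles.append(site.ref if c == 0 else site.alt)
        keep = [i for i in range(matrix.n_samples) if i != og_i]
        calls = calls[keep]
        sample_ids = [sample_ids[i] for i in keep]
        lookup = {s.site_id: a for s, a in zip(matrix.sites, anc_alleles)}
    elif isinstance(ancestral_source, str):
        if ancestral_source != "ref-is-ancestral":
            raise ValueError(
                f"unknown ancestral source {ancestral_source!r}")
        lookup = {s.site_id: s.ref for s in matrix.sites}
    else:
        lookup = dict(ancestral_source)

    for j, site in enumerate(matrix.sites):
        anc = lookup.get(site.site_id)
        if anc is None:
            known[j] = False
            continue
        if anc == site.ref:
            pass
        elif anc == site.alt:
            obs = calls[:, j]
            flipped = np.where(obs == MISSING, MISSING, 1 - obs)
            calls[:, j] = flipped
        else:
            known[j] = False
    return HaplotypeMatrix(sample_ids, matrix.sites, calls, known)


# ---------------------------------------------------------------------------
# Compatibility report
# ---------------------------------------------------------------------------

@dataclass
class SiteCompatibilityReport:
    """Per-site tree-compatibility: ``compatible`` iff the derived-carrier
    set maps to a single branch; recurrent sites need >=2 events."""
    table: pd.DataFrame  # index site_id; columns: compatible, n_events

    @property
    def n_recurrent(self) -> int:
        return int((~self.table["compatible"]).sum())

    @property
    def total_events(self) -> int:
        return int(self.table["n_events"].sum())

    @property
    def recurrent_sites(self) -> list[str]:
        return list(self.table.index[~self.table["compatible"]])


# ---------------------------------------------------------------------------
# Tree building
# ---------------------------------------------------------------------------

def _laminar(a: frozenset, b: frozenset) -> bool:
    return a.isdisjoint(b) or a <= b or b <= a


def build_tree(matrix: HaplotypeMatrix, use_unresolved: bool = False
               ) -> tuple[MutationTree, SiteCompatibilityReport]:
    """Build the rooted mutation tree from a derived-coded matrix.

    Sites flagged ``ancestral_known=False`` are excluded unless
    ``use_unresolved`` is set. Missing calls among used sites are an error.
    Tips with identical haplotypes attach to a shared node via zero-length
    terminal branches.
    """
    if matrix.n_samples == 0 or matrix.n_sites == 0:
        raise FormatError("empty matrix")
    use = (np.ones(matrix.n_sites, bool) if use_unresolved
           else matrix.ancestral_known.copy())
    if not use.any():
        raise FormatError("no sites with known ancestral state")
    cols = np.flatnonzero(use)
    sub = matrix.calls[:, cols]
    if (sub == MISSING).any():
        raise FormatError("missing calls among sites used for tree building")

    n = matrix.n_samples
    universe = frozenset(range(n))

    # group sites by derived-carrier pattern
    by_pattern: dict[frozenset[int], list[int]] = {}
    for j in cols:
        carr = matrix.carriers(j)
        if not carr:
            raise FormatError(
                f"site {matrix.sites[j].site_id} has no derived carriers")
        by_pattern.setdefault(carr, []).append(j)

    # greedy laminar family: weight (support) first, then size, then tips
    patterns = sorted(
        by_pattern,
        key=lambda p: (-len(by_pattern[p]), -len(p), sorted(p)))
    accepted: list[frozenset[int]] = []
    rejected: list[frozenset[int]] = []
    for p in patterns:
        if p == universe or all(_laminar(p, q) for q in accepted):
            accepted.append(p)
        else:
            rejected.append(p)

    tree = _tree_from_laminar(matrix, accepted, by_pattern, universe)

    # place recurrent sites by fixed-root (ancestral) minimum change
    rows = []
    for p in accepted:
        for j in by_pattern[p]:
            rows.append((matrix.sites[j].site_id, True, 1))
    for p in sorted(rejected, key=lambda q: (len(q), sorted(q))):
        carriers = {matrix.sample_ids[i] for i in p}
        for j in by_pattern[p]:
            sid = matrix.sites[j].site_id
            count, placement = _min_change_place(tree, carriers,
                                                 root_state=0)
            for node_id, back in placement:
                node = tree.nodes[node_id]
                node.mutations.append(Mutation(sid, back))
                node.n_mut += 1
            rows.append((sid, False, count))
    site_order = {s: k for k, s in enumerate(matrix.site_ids)}
    rows.sort(key=lambda r: site_order[r[0]])
    report = SiteCompatibilityReport(pd.DataFrame(
        rows, columns=["site_id", "compatible", "n_events"]
    ).set_index("site_id"))
    return tree, report


def _tree_from_laminar(matrix: HaplotypeMatrix,
                       accepted: list[frozenset[int]],
                       by_pattern: dict[frozenset[int], list[int]],
                       universe: frozenset[int]) -> MutationTree:
    n = matrix.n_samples
    # unique clade sets, largest first; universe handled as the root
    clades = sorted({p for p in accepted if p != universe and len(p) > 1},
                    key=lambda p: (-len(p), sorted(p)))
    nodes: dict[str, Node] = {"ROOT": Node(id="ROOT")}
    clade_id: dict[frozenset[int], str] = {universe: "ROOT"}
    for k, c in enumerate(clades, 1):
        cid = f"N{k}"
        clade_id[c] = cid
        # parent: smallest strictly-containing accepted clade (or root)
        parent = "ROOT"
        best = universe
        for q in clades:
            if len(q) > len(c) and c < q and len(q) < len(best):
                best, parent = q, clade_id[q]
        nodes[cid] = Node(id=cid, parent=parent)
        nodes[parent].children.append(cid)
    # tips under their smallest containing clade
    for i, sid in enumerate(matrix.sample_ids):
        parent, best = "ROOT", universe
        for q in clades:
            if i in q and len(q) < len(best):
                best, parent = q, clade_id[q]
        nodes[sid] = Node(id=sid, parent=parent, sample_id=sid)
        nodes[parent].children.append(sid)
    # mutations for accepted patterns (singletons map onto terminal branches)
    site_order = {s: k for k, s in enumerate(matrix.site_ids)}
    for p in accepted:
        if len(p) == 1:
            target = matrix.sample_ids[next(iter(p))]
        else:
            target = clade_id[p]
        node = nodes[target]
        for j in sorted(by_pattern[p]):
            node.mutations.append(Mutation(matrix.sites[j].site_id))
        node.n_mut = len(node.mutations)
    # deterministic child order: internal nodes by id then tips
    for node in nodes.values():
        node.children.sort(key=lambda c: (nodes[c].is_tip, c))
        node.mutations.sort(key=lambda m: site_order.get(m.site_id, 1 << 30))
    return MutationTree(nodes, "ROOT")


# ---------------------------------------------------------------------------
# Two-state minimum-change placement (Fitch/Hartigan as a DP)
# ---------------------------------------------------------------------------

def place_recurrent(tree: MutationTree, carriers: Iterable[str],
                    root_state: int | None = 0
                    ) -> tuple[int, list[tuple[str, bool]], bool]:
    """Minimum mutational events for a derived-carrier set on a fixed tree.

    Returns ``(n_events, placement, back_mutation)`` where ``placement``
    lists ``(branch node id, is_back_mutation)`` for one optimal
    assignment. ``root_state=None`` lets the root state be inferred freely
    (a derived root is then flagged as a possible back-mutation pattern);
    the default fixes the root ancestral, as polarized data warrant.

    Ties among optimal placements break deterministically: a child keeps
    its parent's state whenever that is cost-neutral, deferring changes
    toward the terminal branches.
    """
    carriers = set(carriers)
    count, placement, root_derived = _min_change(tree, carriers, root_state)
    back = root_derived or any(b for _, b in placement)
    return count, placement, back


def _min_change(tree: MutationTree, carriers: set[str],
                root_state: int | None):
    tip_names = {(n.sample_id or n.id) for n in tree.tips()}
    unknown = carriers - tip_names
    if unknown:
        raise KeyError(f"carrier set references unknown tips: "
                       f"{sorted(unknown)}")
    if not carriers:
        raise ValueError("carrier set is empty")
    INF = 1 << 30
    cost: dict[str, list[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            s = 1 if (node.sample_id or node.id) in carriers else 0
            cost[node.id] = [INF, INF]
            cost[node.id][s] = 0
        else:
            c0 = c1 = 0
            for ch in node.children:
                c0 += min(cost[ch][0], cost[ch][1] + 1)
                c1 += min(cost[ch][1], cost[ch][0] + 1)
            cost[node.id] = [c0, c1]
    rc = cost[tree.root]
    if root_state is None:
        root_assign = 0 if rc[0] <= rc[1] else 1
    else:
        root_assign = root_state
    total = rc[root_assign]
    # backtrack: keep parent state when cost-equal
    placement: list[tuple[str, bool]] = []
    state = {tree.root: root_assign}
    for node in tree.preorder():
        s = state[node.id]
        for ch in node.children:
            keep, flip = cost[ch][s], cost[ch][1 - s] + 1
            if keep <= flip:
                state[ch] = s
            else:
                state[ch] = 1 - s
                placement.append((ch, s == 1))  # 1 -> 0 is a back-mutation
    return total, placement, root_assign == 1


def _min_change_place(tree: MutationTree, carriers: set[str],
                      root_state: int = 0):
    count, placement, _ = _min_change(tree, carriers, root_state)
    return count, placement


# ---------------------------------------------------------------------------
# Per-sample mutation paths and identity structure
# ---------------------------------------------------------------------------

def mutations_to_root(tree: MutationTree) -> pd.Series:
    """Mutation count from each tip up to the tree root (stem excluded).

    The mean over tips equals rho of the whole tree.
    """
    counts = {}
    # accumulate top-down: depth(node) = depth(parent) + n_mut
    depth: dict[str, int] = {tree.root: 0}
    for node in tree.preorder():
        if node.parent is not None:
            depth[node.id] = depth[node.parent] + node.n_mut
        if node.is_tip:
            counts[node.sample_id or node.id] = depth[node.id]
    return pd.Series(counts, name="mutations_to_root")


@dataclass
class IdentityReport:
    """Partition of samples into identity classes under a marker set."""
    groups: list[list[str]]  # classes with >=2 members, deterministic order
    n_classes: int           # total classes incl. singletons
    snp_differences: dict[tuple[str, str], int] | None = None

    @property
    def n_pairs(self) -> int:
        return sum(1 for g in self.groups if len(g) == 2)

    @property
    def n_trios(self) -> int:
        return sum(1 for g in self.groups if len(g) == 3)


def identical_groups(data: HaplotypeMatrix | STRProfileTable,
                     subset: str | Sequence[str] | None = None,
                     matrix: HaplotypeMatrix | None = None
                     ) -> IdentityReport:
    """Group samples indistinguishable under the chosen markers.

    For an STR table, ``subset`` selects the marker subset; supplying the
    SNP ``matrix`` additionally reports pairwise SNP differences within
    each STR-identical group.
    """
    if isinstance(data, HaplotypeMatrix):
        keys = [tuple(row) for row in data.calls]
        ids = data.sample_ids
    else:
        loci = list(data.resolve_subset(subset if subset is not None
                                        else "set21"))
        sub = data.profiles[loci]
        keys = [tuple(row) for row in sub.to_numpy()]
        ids = data.sample_ids
    classes: dict[tuple, list[str]] = {}
    for sid, key in zip(ids, keys):
        classes.setdefault(key, []).append(sid)
    groups = sorted((g for g in classes.values() if len(g) >= 2),
                    key=lambda g: g[0])
    snp_diffs = None
    if matrix is not None and not isinstance(data, HaplotypeMatrix):
        snp_diffs = {}
        for g in groups:
            for a_i in range(len(g)):
                for b_i in range(a_i + 1, len(g)):
                    a, b = g[a_i], g[b_i]
                    ra = matrix.calls[matrix.sample_index(a)]
                    rb = matrix.calls[matrix.sample_index(b)]
                    snp_diffs[(a, b)] = int((ra != rb).sum())
    return IdentityReport(groups=groups, n_classes=len(classes),
                          snp_differences=snp_diffs)
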