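"""Synthetic male genealogies with SNP and STR mutation processes.

The generator emulates the statistical structure the analyses assume: a
nonrecombining haploid genealogy (constant-size coalescent, fixed-depth
star, or user-supplied Newick), Poisson SNP mutations at a per-year rate
over a fixed nucleotide target, strict single-step STR mutations at
per-locus per-generation rates, optional finite-sites recurrence with a
CpG-elevated rate class, and tissue-source labels with optional extra
somatic singletons for cell-line (LCL) samples.

Defaults mirror the study conditions the analyses were designed for:
SNP rate 1.0e-9 /bp/year over 3,724,156 bp, generation time 30 years,
STR rate 6.9e-4 /locus/generation on the 21-locus dating panel, tissue
fractions 152:208:88 (LCL:blood:saliva). The haploid effective size
(default 2,100 generations) puts coalescent tree depths in the range of
the real tree (~126 ka at 30 y/generation).

Every operation is a pure function of (config, seed): each draws its
random stream from the config seed plus a fixed per-operation tag.
Truth logs (per-event branch and site) make downstream inference
checkable against the simulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .formats import (HaplotypeMatrix, MutationTree, Mutation, Node,
                      STRProfileTable, SampleMeta, Site, STR_SUBSETS,
                      read_newick)

__all__ = ["SimConfig", "sim_genealogy", "sim_snps", "sim_strs",
           "sim_metadata", "simulate_dataset", "SimulatedDataset"]

_TISSUE_DEFAULT = {"LCL": 152 / 448, "blood": 208 / 448, "saliva": 88 / 448}


@dataclass
class SimConfig:
    """All knobs of the generator; ``seed`` is mandatory."""
    seed: int
    n: int = 60
    genealogy: str = "coalescent"          # coalescent | star | newick
    effective_size: float = 2100.0         # haploid Ne, in generations
    star_depth_years: float = 125_826.0
    newick: str | None = None
    snp_rate: float = 1.0e-9               # per bp per year
    target_length: int = 3_724_156
    sites_model: str = "infinite"          # infinite | finite
    finite_sites: int = 1000
    cpg_fraction: float = 0.02
    cpg_multiplier: float = 10.0
    str_loci: tuple[str, ...] = STR_SUBSETS["set21"]
    str_rate: float | Mapping[str, float] = 6.9e-4  # per locus per gen
    str_root_allele: int = 14
    generation_time: float = 30.0
    tissue_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_TISSUE_DEFAULT))
    lcl_extra_rate: float = 0.0            # mean somatic singletons per LCL

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.genealogy not in ("coalescent", "star", "newick"):
            raise ValueError(f"unknown genealogy model {self.genealogy!r}")
        if self.sites_model not in ("infinite", "finite"):
            raise ValueError(f"unknown sites model {self.sites_model!r}")
        if abs(sum(self.tissue_probs.values()) - 1.0) > 1e-9:
            raise ValueError("tissue probabilities must sum to 1")
        for name, v in (("snp_rate", self.snp_rate),
                        ("cpg_fraction", self.cpg_fraction),
                        ("lcl_extra_rate", self.lcl_extra_rate)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    def locus_rate(self, locus: str) -> float:
        if isinstance(self.str_rate, Mapping):
            return float(self.str_rate[locus])
        return float(self.str_rate)

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), tag])


# ---------------------------------------------------------------------------
# Genealogy
# ---------------------------------------------------------------------------

def sim_genealogy(config: SimConfig) -> MutationTree:
    """Time-annotated tree skeleton (node times in years before present)."""
    if config.n < 2:
        raise ValueError("need n >= 2 tips")
    tip_ids = [f"S{i + 1:03d}" for i in range(config.n)]
    if config.genealogy == "star":
        nodes = {"ROOT": Node(id="ROOT", time=config.star_depth_years)}
        for t in tip_ids:
            nodes[t] = Node(id=t, parent="ROOT", sample_id=t, time=0.0)
            nodes["ROOT"].children.append(t)
        return MutationTree(nodes, "ROOT")
    if config.genealogy == "newick":
        if not config.newick:
            raise ValueError("genealogy='newick' needs config.newick")
        return _times_from_lengths(read_newick(config.newick))
    # Kingman coalescent with haploid effective size Ne (generations):
    # while k lineages remain, the wait to the next merger is
    # Exp(mean Ne / C(k,2)).
    rng = config.rng(1)
    nodes = {t: Node(id=t, sample_id=t, time=0.0) for t in tip_ids}
    lineages = list(tip_ids)
    t_gen = 0.0
    k_int = 0
    while len(lineages) > 1:
        k = len(lineages)
        t_gen += rng.exponential(config.effective_size / (k * (k - 1) / 2))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        k_int += 1
        nid = f"I{k_int}"
        a, b = lineages[i], lineages[j]
        nodes[nid] = Node(id=nid, children=[a, b],
                          time=t_gen * config.generation_time)
        nodes[a].parent = nodes[b].parent = nid
        lineages = [x for x in lineages if x not in (a, b)] + [nid]
    root = lineages[0]
    return MutationTree(nodes, root)


def _times_from_lengths(tree: MutationTree) -> MutationTree:
    """Interpret Newick branch lengths as years and convert to node times."""
    depth = {tree.root: 0.0}
    for n in tree.preorder():
        if n.parent is not None:
            depth[n.id] = depth[n.parent] + n.n_mut
        n.n_mut, n.mutations = 0, []
    max_d = max(depth[t.id] for t in tree.tips())
    for n in tree.nodes.values():
        n.time = max_d - depth[n.id]
    return tree


def _branch_years(tree: MutationTree, node: Node) -> float:
    return tree.nodes[node.parent].time - node.time


def _draw_unique(rng: np.random.Generator, high: int,
                 size: int) -> np.ndarray:
    """``size`` distinct integers in [0, high); rejection-sampled, cheap
    while size << high."""
    if size > high:
        raise ValueError("more events than available positions")
    out = np.unique(rng.integers(0, high, size=size))
    while out.size < size:
        extra = rng.integers(0, high, size=2 * (size - out.size))
        out = np.unique(np.concatenate([out, extra]))
    if out.size > size:
        out = rng.choice(out, size=size, replace=False)
    return out


# ---------------------------------------------------------------------------
# SNP mutations
# ---------------------------------------------------------------------------

def sim_snps(tree: MutationTree, config: SimConfig
             ) -> tuple[HaplotypeMatrix, pd.DataFrame, dict[str, str]]:
    """Drop Poisson SNP mutations on the genealogy.

    Returns (derived-coded matrix, truth event log, per-site trinucleotide
    context). Under the infinite-sites model every event founds a new
    site; under finite sites events land on a fixed set of positions (a
    CpG class carrying a rate multiplier) and may recur, toggling the
    allelic state. Sites left unobservable (all tips ancestral) appear in
    the log flagged ``observed=False`` but not in the matrix.
    """
    rng = config.rng(2)
    branches = sorted((n for n in tree.preorder() if n.parent is not None),
                      key=lambda n: n.id)
    mu_site = config.snp_rate  # per bp per year
    n_ev = rng.poisson([mu_site * config.target_length
                        * _branch_years(tree, b) for b in branches])
    total = int(n_ev.sum())
    if config.sites_model == "infinite":
        L = config.target_length
        positions = _draw_unique(rng, L, total)
        pos_is_cpg = dict(zip(positions.tolist(),
                              (rng.random(total)
                               < config.cpg_fraction).tolist()))
    else:
        L = config.finite_sites
        n_cpg = int(round(config.cpg_fraction * L))
        cpg_sites = set(rng.choice(L, size=n_cpg, replace=False).tolist())
        w = np.ones(L)
        w[list(cpg_sites)] = config.cpg_multiplier
        positions = rng.choice(L, size=total, p=w / w.sum())
        pos_is_cpg = {int(p): (int(p) in cpg_sites) for p in positions}
    branch_of_event = np.repeat([b.id for b in branches], n_ev)

    by_pos: dict[int, list[str]] = {}
    for pos, bid in zip(positions.tolist(), branch_of_event):
        by_pos.setdefault(int(pos), []).append(bid)

    # per-branch descendant-tip masks, for vectorized tip states
    tip_ids = [n.sample_id or n.id for n in tree.tips()]
    tip_index = {t: i for i, t in enumerate(tip_ids)}
    mask: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            m = np.zeros(len(tip_ids), dtype=bool)
            m[tip_index[node.sample_id or node.id]] = True
        else:
            m = np.zeros(len(tip_ids), dtype=bool)
            for c in node.children:
                m |= mask[c]
        mask[node.id] = m

    sorted_pos = sorted(by_pos)
    cols = np.zeros((len(sorted_pos), len(tip_ids)), dtype=bool)
    single = [j for j, p in enumerate(sorted_pos) if len(by_pos[p]) == 1]
    if single:
        bidx = {b.id: k for k, b in enumerate(branches)}
        mask_mat = np.stack([mask[b.id] for b in branches])
        cols[single] = mask_mat[[bidx[by_pos[sorted_pos[j]][0]]
                                 for j in single]]
    for j, pos in enumerate(sorted_pos):
        bids = by_pos[pos]
        if len(bids) > 1:  # recurrent: tip state is event parity on path
            col = np.zeros(len(tip_ids), dtype=bool)
            for bid in bids:
                col ^= mask[bid]
            cols[j] = col

    sites: list[Site] = []
    keep: list[int] = []
    context: dict[str, str] = {}
    log_rows = []
    for j, pos in enumerate(sorted_pos):
        cpg = pos_is_cpg[pos]
        ref, alt, ctx = ("C", "T", "ACG") if cpg else ("A", "G", "TAT")
        site = Site("Y", pos + 1, ref, alt)
        observed = bool(cols[j].any())
        for bid in by_pos[pos]:
            log_rows.append({"site_id": site.site_id, "chrom": "Y",
                             "pos": pos + 1, "branch": bid, "cpg": cpg,
                             "observed": observed})
        if observed:
            sites.append(site)
            keep.append(j)
            context[site.site_id] = ctx
    calls = cols[keep].T.astype(np.int8) if keep else \
        np.zeros((len(tip_ids), 0), dtype=np.int8)
    matrix = HaplotypeMatrix(tip_ids, sites, calls,
                             np.ones(len(sites), dtype=bool))
    log = pd.DataFrame(
        log_rows, columns=["site_id", "chrom", "pos", "branch", "cpg",
                           "observed"])
    return matrix, log, context


# ---------------------------------------------------------------------------
# STR mutations
# ---------------------------------------------------------------------------

def sim_strs(tree: MutationTree, config: SimConfig
             ) -> tuple[STRProfileTable, dict[str, int]]:
    """Strict symmetric single-step STR evolution along the genealogy.

    Per branch and locus the number of steps is Poisson with mean
    rate x branch-length-in-generations; each step is +/-1 with equal
    probability. Returns the tip table and the true root haplotype.
    """
    rng = config.rng(3)
    g = config.generation_time
    branches = sorted((n for n in tree.preorder() if n.parent is not None),
                      key=lambda n: n.id)
    loci = list(config.str_loci)
    root_hap = {l: int(config.str_root_allele) for l in loci}
    allele: dict[str, np.ndarray] = {
        tree.root: np.array([root_hap[l] for l in loci], dtype=np.int64)}
    for node in tree.preorder():
        if node.parent is None:
            continue
        gens = _branch_years(tree, node) / g
        steps = rng.poisson([config.locus_rate(l) * gens for l in loci])
        delta = np.zeros(len(loci), dtype=np.int64)
        for k, m in enumerate(steps):
            if m:
                delta[k] = rng.choice([-1, 1], size=m).sum()
        allele[node.id] = allele[node.parent] + delta
    rows = {n.sample_id or n.id: allele[n.id] for n in tree.tips()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=loci)
    df.index.name = "sample_id"
    if (df.to_numpy() < 0).any():
        raise ValueError(
            "simulated repeat count went negative; raise str_root_allele")
    return STRProfileTable(df), root_hap


# ---------------------------------------------------------------------------
# Metadata and somatic (LCL) singletons
# ---------------------------------------------------------------------------

def sim_metadata(tree: MutationTree, config: SimConfig,
                 matrix: HaplotypeMatrix | None = None
                 ) -> tuple[list[SampleMeta], HaplotypeMatrix | None,
                            pd.DataFrame]:
    """Tissue-source labels and optional extra somatic singletons.

    Haplogroup labels follow the root's child clades (HG1, HG2, ...).
    Each LCL tip receives a Poisson(``lcl_extra_rate``) number of private
    singleton variants, appended to the matrix (always on terminal
    branches, mirroring somatic cell-line artefacts). Returns (metadata,
    augmented matrix or None, extra-singleton log).
    """
    rng = config.rng(4)
    tips = tree.tips()
    tip_ids = [n.sample_id or n.id for n in tips]
    hg_of: dict[str, str] = {}
    for k, child in enumerate(tree.nodes[tree.root].children, 1):
        for s in tree.clade_samples(child):
            hg_of[s] = f"HG{k}"
    names = list(config.tissue_probs)
    probs = np.array([config.tissue_probs[t] for t in names])
    draws = rng.choice(len(names), size=len(tip_ids), p=probs)
    meta = [SampleMeta(sample_id=s, population=hg_of.get(s, "HG0"),
                       region="SIM", tissue_source=names[d],
                       haplogroup=hg_of.get(s, "HG0"))
            for s, d in zip(tip_ids, draws)]
    extra_rows = []
    out_matrix = matrix
    if matrix is not None and config.lcl_extra_rate > 0:
        used = {s.pos for s in matrix.sites}
        new_sites: list[Site] = []
        new_cols: list[np.ndarray] = []
        order = {s: i for i, s in enumerate(matrix.sample_ids)}
        for m in meta:
            if m.tissue_source != "LCL":
                continue
            for _ in range(rng.poisson(config.lcl_extra_rate)):
                pos = int(rng.integers(1, config.target_length + 1))
                while pos in used:
                    pos = int(rng.integers(1, config.target_length + 1))
                used.add(pos)
                site = Site("Y", pos, "A", "G")
                col = np.zeros(matrix.n_samples, dtype=np.int8)
                col[order[m.sample_id]] = 1
                new_sites.append(site)
                new_cols.append(col)
                extra_rows.append({"sample_id": m.sample_id,
                                   "site_id": site.site_id})
        if new_sites:
            sites = list(matrix.sites) + new_sites
            calls = np.concatenate(
                [matrix.calls, np.stack(new_cols, axis=1)], axis=1)
            idx = sorted(range(len(sites)), key=lambda j: sites[j].pos)
            out_matrix = HaplotypeMatrix(
                matrix.sample_ids, [sites[j] for j in idx], calls[:, idx],
                np.ones(len(sites), dtype=bool))
    extra = pd.DataFrame(extra_rows, columns=["sample_id", "site_id"])
    return meta, out_matrix, extra


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    tree: MutationTree
    matrix: HaplotypeMatrix
    event_log: pd.DataFrame
    context: dict[str, str]
    strs: STRProfileTable
    str_root: dict[str, int]
    meta: list[SampleMeta]
    lcl_extra_log: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: genealogy, SNPs, STRs, metadata."""
    tree = sim_genealogy(config)
    matrix, log, context = sim_snps(tree, config)
    strs, str_root = sim_strs(tree, config)
    meta, matrix2, extra = sim_metadata(tree, config, matrix)
    return SimulatedDataset(config=config, tree=tree,
                            matrix=matrix2 if matrix2 is not None else matrix,
                            event_log=log, context=context, strs=strs,
                            str_root=str_root, meta=meta,
                            lcl_extra_log=extra)
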