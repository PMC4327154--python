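"""Domain containers and file formats.

The pipeline works on three tabular objects — a haploid SNP haplotype
matrix, an STR repeat-count table and per-sample metadata — plus a rooted
mutation-annotated tree. This module defines those containers, validates
their invariants strictly, and reads/writes the standard interchange
formats (VCF 4.x via pysam, Newick via dendropy, tab-delimited tables via
pandas).

Coordinates follow the VCF convention (1-based). Haplotype calls are coded
0 = reference (or ancestral after polarization), 1 = alternate/derived,
-1 = missing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam

MISSING = -1

TISSUE_SOURCES = frozenset({"LCL", "blood", "saliva", "unknown"})

#: The 23-marker forensic panel. DYS385 is bilocal (two co-amplified copies)
#: and is excluded from every dating subset.
PANEL_LOCI = (
    "DYS19", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392", "DYS393",
    "DYS385a", "DYS385b", "DYS437", "DYS438", "DYS439", "DYS448", "DYS456",
    "DYS458", "DYS635", "GATAH4", "DYS481", "DYS533", "DYS549", "DYS570",
    "DYS576", "DYS643",
)

BILOCAL_LOCI = frozenset({"DYS385a", "DYS385b"})

#: Dating subsets: the maximal usable 21 (all single-copy loci), 17 (dropping
#: the rapidly mutating DYS570/DYS576 and the complex-repeat DYS389II/DYS448),
#: and the minimal 13 (Yfiler panel minus the bilocal and complex loci).
_SET21 = tuple(l for l in PANEL_LOCI if l not in BILOCAL_LOCI)
_SET17 = tuple(l for l in _SET21
               if l not in {"DYS570", "DYS576", "DYS389II", "DYS448"})
_SET13 = tuple(l for l in _SET17
               if l not in {"DYS481", "DYS533", "DYS549", "DYS643"})
STR_SUBSETS: dict[str, tuple[str, ...]] = {
    "set21": _SET21, "set17": _SET17, "set13": _SET13,
}

assert len(_SET21) == 21 and len(_SET17) == 17 and len(_SET13) == 13


class FormatError(ValueError):
    """Malformed or invariant-violating input."""


class NonHaploidCallError(FormatError):
    """A genotype that is neither haploid nor homozygous-diploid."""


class Site(NamedTuple):
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


# ---------------------------------------------------------------------------
# Haplotype matrix
# ---------------------------------------------------------------------------

class HaplotypeMatrix:
    """Samples x biallelic SNP sites, haploid calls in {0, 1, missing}.

    After :func:`ychron.phylogeny.polarize`, 1 always means the derived
    state; ``ancestral_known`` records, per site, whether the ancestral
    allele was resolved.
    """

    def __init__(self, sample_ids: Sequence[str], sites: Sequence[Site],
                 calls: np.ndarray,
                 ancestral_known: np.ndarray | None = None) -> None:
        self.sample_ids = list(sample_ids)
        self.sites = [Site(*s) for s in sites]
        self.calls = np.asarray(calls, dtype=np.int8)
        if ancestral_known is None:
            ancestral_known = np.zeros(len(self.sites), dtype=bool)
        self.ancestral_known = np.asarray(ancestral_known, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise FormatError("calls must be 0, 1 or missing (-1)")
        if self.ancestral_known.shape != (len(self.sites),):
            raise FormatError("ancestral_known length mismatch")
        seen: dict[tuple[str, int], Site] = {}
        last: dict[str, int] = {}
        for s in self.sites:
            if len(s.ref) != 1 or len(s.alt) != 1 or s.ref == s.alt:
                raise FormatError(f"site {s.site_id} is not a biallelic SNP")
            if (s.chrom, s.pos) in seen:
                raise FormatError(f"duplicate position {s.chrom}:{s.pos}")
            seen[(s.chrom, s.pos)] = s
            if s.pos <= last.get(s.chrom, 0):
                raise FormatError(
                    f"positions not strictly increasing at {s.chrom}:{s.pos}")
            last[s.chrom] = s.pos

    # -- basic accessors ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def carriers(self, j: int) -> frozenset[int]:
        """Indices of samples carrying allele 1 at site column ``j``."""
        return frozenset(np.flatnonzero(self.calls[:, j] == 1).tolist())

    def drop_incomplete_sites(self) -> tuple["HaplotypeMatrix", int]:
        """Remove any site with >=1 missing call; returns (matrix, n_dropped)."""
        keep = ~(self.calls == MISSING).any(axis=0)
        dropped = int((~keep).sum())
        return self.subset_sites(np.flatnonzero(keep)), dropped

    def subset_sites(self, idx: Iterable[int]) -> "HaplotypeMatrix":
        idx = list(idx)
        return HaplotypeMatrix(
            self.sample_ids, [self.sites[j] for j in idx],
            self.calls[:, idx], self.ancestral_known[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.sites == other.sites
                and np.array_equal(self.calls, other.calls))

    def __repr__(self) -> str:
        return (f"HaplotypeMatrix({self.n_samples} samples x "
                f"{self.n_sites} sites)")


# ---------------------------------------------------------------------------
# STR profile table
# ---------------------------------------------------------------------------

class STRProfileTable:
    """Samples x STR loci integer repeat counts with a marker-subset registry.

    Bilocal loci (the two DYS385 copies) are parsed and retained but flagged
    and excluded from every dating subset.
    """

    def __init__(self, profiles: pd.DataFrame,
                 subsets: Mapping[str, Sequence[str]] | None = None,
                 bilocal: Iterable[str] | None = None) -> None:
        if profiles.index.has_duplicates:
            raise FormatError("duplicate sample ids in STR table")
        try:
            profiles = profiles.astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-integer STR allele: {exc}") from None
        if (profiles.to_numpy() < 0).any():
            raise FormatError("negative repeat count")
        self.profiles = profiles
        self.bilocal = frozenset(
            BILOCAL_LOCI & set(profiles.columns)
            if bilocal is None else bilocal)
        self.subsets: dict[str, tuple[str, ...]] = {}
        base = dict(STR_SUBSETS) if subsets is None else dict(subsets)
        for name, loci in base.items():
            self.register_subset(name, loci, strict=subsets is not None)

    def register_subset(self, name: str, loci: Sequence[str],
                        strict: bool = True) -> None:
        loci = tuple(loci)
        missing = [l for l in loci if l not in self.profiles.columns]
        if missing and strict:
            raise FormatError(f"subset {name!r} references unknown loci "
                              f"{missing}")
        loci = tuple(l for l in loci if l in self.profiles.columns)
        bad = [l for l in loci if l in self.bilocal]
        if bad:
            raise FormatError(f"bilocal loci {bad} cannot enter a dating "
                              f"subset")
        if loci:
            self.subsets[name] = loci

    def resolve_subset(self, subset: str | Sequence[str]) -> tuple[str, ...]:
        if isinstance(subset, str):
            if subset not in self.subsets:
                raise FormatError(f"unknown subset {subset!r}")
            return self.subsets[subset]
        unknown = [l for l in subset if l not in self.profiles.columns]
        if unknown:
            raise FormatError(f"unknown loci in subset: {unknown}")
        return tuple(subset)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def loci(self) -> list[str]:
        return list(self.profiles.columns)

    def __repr__(self) -> str:
        return (f"STRProfileTable({len(self.profiles)} samples x "
                f"{len(self.profiles.columns)} loci)")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    population: str = "unknown"
    region: str = "unknown"
    tissue_source: str = "unknown"
    haplogroup: str | None = None

    def __post_init__(self) -> None:
        if self.tissue_source not in TISSUE_SOURCES:
            raise FormatError(
                f"tissue source {self.tissue_source!r} not in "
                f"{sorted(TISSUE_SOURCES)}")


def read_metadata(path: str, matrix: HaplotypeMatrix | None = None
                  ) -> list[SampleMeta]:
    """Read a tab-delimited metadata table (sample_id, population, region,
    tissue_source, haplogroup)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise FormatError("metadata table needs a 'sample_id' column")
    out = []
    for _, row in df.iterrows():
        out.append(SampleMeta(
            sample_id=row["sample_id"],
            population=row.get("population", "") or "unknown",
            region=row.get("region", "") or "unknown",
            tissue_source=row.get("tissue_source", "") or "unknown",
            haplogroup=row.get("haplogroup", "") or None))
    if matrix is not None:
        known = set(matrix.sample_ids)
        stray = [m.sample_id for m in out if m.sample_id not in known]
        if stray:
            raise FormatError(f"metadata samples absent from matrix: {stray}")
    return out


def write_metadata(meta: Sequence[SampleMeta], path: str) -> None:
    pd.DataFrame([{
        "sample_id": m.sample_id, "population": m.population,
        "region": m.region, "tissue_source": m.tissue_source,
        "haplogroup": m.haplogroup or "",
    } for m in meta]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutation-annotated rooted tree
# ---------------------------------------------------------------------------

class Mutation(NamedTuple):
    site_id: str
    back: bool = False  # derived -> ancestral reversion


@dataclass
class Node:
    """Tree node; the branch *above* the node carries its mutations.

    ``n_mut`` is the branch length in mutation events; it equals
    ``len(mutations)`` whenever per-event detail is known (a tree read back
    from bare Newick knows only the counts).
    """
    id: str
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    sample_id: str | None = None
    mutations: list[Mutation] = field(default_factory=list)
    n_mut: int = 0
    time: float | None = None  # years before present

    @property
    def is_tip(self) -> bool:
        return not self.children


class MutationTree:
    """Rooted tree whose branches carry SNP mutation events.

    Mutations recorded on the root node itself sit on the stem above the
    most recent common ancestor of the sample (shared by every tip) and are
    excluded from within-tree statistics.
    """

    def __init__(self, nodes: dict[str, Node], root: str) -> None:
        self.nodes = nodes
        self.root = root
        if root not in nodes:
            raise FormatError("root id not among nodes")
        n_roots = sum(1 for n in nodes.values() if n.parent is None)
        if n_roots != 1 or nodes[root].parent is not None:
            raise FormatError("tree must have exactly one root")
        for n in nodes.values():
            if n.mutations and n.n_mut != len(n.mutations):
                raise FormatError(f"node {n.id}: n_mut != len(mutations)")
        self._n_desc: dict[str, int] | None = None

    # -- traversal ----------------------------------------------------------
    def postorder(self, start: str | None = None) -> Iterator[Node]:
        start = self.root if start is None else start
        stack, out = [start], []
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.nodes[nid].children)
        for nid in reversed(out):
            yield self.nodes[nid]

    def preorder(self, start: str | None = None) -> Iterator[Node]:
        start = self.root if start is None else start
        stack = [start]
        while stack:
            nid = stack.pop()
            yield self.nodes[nid]
            stack.extend(reversed(self.nodes[nid].children))

    def tips(self, start: str | None = None) -> list[Node]:
        return [n for n in self.preorder(start) if n.is_tip]

    def clade_samples(self, node_id: str) -> list[str]:
        if node_id not in self.nodes:
            raise KeyError(f"unknown node {node_id!r}")
        return [n.sample_id or n.id for n in self.tips(node_id)]

    def n_descendant_tips(self, node_id: str) -> int:
        if self._n_desc is None:
            nd: dict[str, int] = {}
            for n in self.postorder():
                nd[n.id] = 1 if n.is_tip else sum(
                    nd[c] for c in n.children)
            self._n_desc = nd
        return self._n_desc[node_id]

    @property
    def n_tips(self) -> int:
        return self.n_descendant_tips(self.root)

    def path_to_root(self, node_id: str) -> list[Node]:
        """Nodes from ``node_id`` up to (excluding) the root."""
        out = []
        nid = node_id
        while self.nodes[nid].parent is not None:
            out.append(self.nodes[nid])
            nid = self.nodes[nid].parent
        return out

    def tip_by_sample(self, sample_id: str) -> Node:
        for n in self.nodes.values():
            if n.is_tip and (n.sample_id or n.id) == sample_id:
                return n
        raise KeyError(f"no tip for sample {sample_id!r}")

    def total_events(self) -> int:
        return sum(n.n_mut for n in self.nodes.values()
                   if n.parent is not None)


# ---------------------------------------------------------------------------
# Newick IO (dendropy-backed)
# ---------------------------------------------------------------------------

def write_newick(tree: MutationTree) -> str:
    """Serialize; branch lengths are integer mutation counts, internal node
    labels are preserved. Per-mutation site detail goes in the events
    sidecar (:func:`write_events`)."""
    dt = dendropy.Tree()
    taxa = dt.taxon_namespace

    def build(nid: str, parent_dnode):
        n = tree.nodes[nid]
        dnode = dendropy.Node()
        if n.is_tip:
            dnode.taxon = taxa.new_taxon(label=(n.sample_id or n.id))
        else:
            dnode.label = n.id
        dnode.edge.length = n.n_mut
        if parent_dnode is None:
            dt.seed_node = dnode
        else:
            parent_dnode.add_child(dnode)
        for c in n.children:
            build(c, dnode)

    build(tree.root, None)
    return dt.as_string(schema="newick", suppress_rooting=True,
                        suppress_internal_node_labels=False,
                        real_value_format_specifier=".0f").strip()


def read_newick(text: str) -> MutationTree:
    """Parse Newick back into a :class:`MutationTree` (counts only; use
    :func:`read_events` to restore per-site detail)."""
    try:
        dt = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise FormatError(f"malformed Newick: {exc}") from None
    nodes: dict[str, Node] = {}
    counter = [0]

    def walk(dnode, parent_id: str | None) -> str:
        if dnode.taxon is not None:
            nid = dnode.taxon.label
            sample = dnode.taxon.label
        elif dnode.label:
            nid = dnode.label
            sample = None
        else:
            counter[0] += 1
            nid = f"N{counter[0]}"
            sample = None
        if nid in nodes:
            raise FormatError(f"duplicate node label {nid!r}")
        bl = dnode.edge.length or 0
        nodes[nid] = Node(id=nid, parent=parent_id, sample_id=sample,
                          n_mut=int(round(bl)))
        for child in dnode.child_nodes():
            cid = walk(child, nid)
            nodes[nid].children.append(cid)
        return nid

    root_id = walk(dt.seed_node, None)
    return MutationTree(nodes, root_id)


def write_events(tree: MutationTree, path_or_buf) -> pd.DataFrame:
    """Sidecar TSV: one row per mutation event (site id, branch, direction)."""
    rows = [
        {"site_id": m.site_id, "branch": n.id,
         "direction": "back" if m.back else "forward"}
        for n in tree.preorder() for m in n.mutations
    ]
    df = pd.DataFrame(rows, columns=["site_id", "branch", "direction"])
    if path_or_buf is not None:
        df.to_csv(path_or_buf, sep="\t", index=False)
    return df


def read_events(tree: MutationTree, path) -> MutationTree:
    """Attach per-site events from a sidecar TSV onto ``tree`` in place."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    for n in tree.nodes.values():
        n.mutations = []
    for _, row in df.iterrows():
        n = tree.nodes.get(row["branch"])
        if n is None:
            raise FormatError(f"events reference unknown branch "
                              f"{row['branch']!r}")
        n.mutations.append(Mutation(row["site_id"],
                                    row["direction"] == "back"))
    for n in tree.nodes.values():
        if n.mutations:
            n.n_mut = len(n.mutations)
    return tree


# ---------------------------------------------------------------------------
# VCF IO (pysam-backed)
# ---------------------------------------------------------------------------

def read_haploid_vcf(path: str, require_complete: bool = True,
                     on_invalid: str = "error") -> HaplotypeMatrix:
    """Read biallelic SNPs with haploid (or homozygous-diploid) genotypes.

    Parameters
    ----------
    require_complete
        If true (default), any missing genotype is an error; otherwise
        sites with missing calls are retained with calls coded missing.
    on_invalid
        "error" rejects multiallelic/indel records; "skip" drops them.
    """
    if on_invalid not in ("error", "skip"):
        raise ValueError("on_invalid must be 'error' or 'skip'")
    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    sites: list[Site] = []
    cols: list[np.ndarray] = []
    seen_pos: set[tuple[str, int]] = set()
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            if on_invalid == "skip":
                continue
            raise FormatError(
                f"record {rec.chrom}:{rec.pos} is not a biallelic SNP")
        if (rec.chrom, rec.pos) in seen_pos:
            raise FormatError(f"duplicate position {rec.chrom}:{rec.pos}")
        seen_pos.add((rec.chrom, rec.pos))
        col = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            alleles = tuple(a for a in gt if a is not None)
            if not alleles:
                if require_complete:
                    raise FormatError(
                        f"missing call for sample {s} at "
                        f"{rec.chrom}:{rec.pos} (require_complete)")
                col[i] = MISSING
            elif len(set(alleles)) > 1:
                raise NonHaploidCallError(
                    f"non-haploid call {gt} for sample {s} at "
                    f"{rec.chrom}:{rec.pos}")
            elif alleles[0] not in (0, 1):
                raise FormatError(
                    f"allele index {alleles[0]} out of range at "
                    f"{rec.chrom}:{rec.pos}")
            else:
                col[i] = alleles[0]
        sites.append(Site(rec.chrom, rec.pos, rec.ref, alts[0]))
        cols.append(col)
    order = sorted(range(len(sites)), key=lambda j: (sites[j].chrom,
                                                     sites[j].pos))
    calls = (np.stack([cols[j] for j in order], axis=1)
             if cols else np.zeros((len(samples), 0), dtype=np.int8))
    return HaplotypeMatrix(samples, [sites[j] for j in order], calls)


def write_haploid_vcf(matrix: HaplotypeMatrix, path: str,
                      contig_length: int = 60_000_000) -> None:
    """Write the matrix as an uncompressed haploid VCF."""
    header = pysam.VariantHeader()
    header.add_meta("FILTER", items=[("ID", "PASS"),
                                     ("Description", "All filters passed")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Genotype")])
    for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
        header.contigs.add(chrom, length=contig_length)
    if not matrix.sites:
        header.contigs.add("Y", length=contig_length)
    for s in matrix.sample_ids:
        header.add_sample(s)
    out = pysam.VariantFile(path, "w", header=header)
    for j, site in enumerate(matrix.sites):
        rec = out.new_record(contig=site.chrom, start=site.pos - 1,
                             stop=site.pos, alleles=(site.ref, site.alt))
        rec.filter.add("PASS")
        for i, s in enumerate(matrix.sample_ids):
            call = int(matrix.calls[i, j])
            rec.samples[s]["GT"] = (None,) if call == MISSING else (call,)
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# STR table IO
# ---------------------------------------------------------------------------

def read_str_table(path) -> STRProfileTable:
    """Tab-delimited table: first column sample ids, remaining columns loci."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise FormatError(
                f"non-integer allele at locus {col}, sample {bad}")
        if not np.allclose(vals, np.round(vals)):
            raise FormatError(f"non-integer allele at locus {col}")
        df[col] = vals.astype(np.int64)
    return STRProfileTable(df)


def write_str_table(table: STRProfileTable, path) -> None:
    table.profiles.to_csv(path, sep="\t", index_label="sample_id")
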