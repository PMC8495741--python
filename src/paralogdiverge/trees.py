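"""Gene/domain trees on a shared species topology.

Branch identity is by leaf bipartition, so rooting never affects
matching: every branch of a tree is represented by the canonical side of
its leaf split (the side *not* containing the alphabetically first
taxon).  A gene tree missing some taxa is matched against the master
topology pruned to the taxa present; master branches fused by pruning
are represented by one member of the fused path.

Newick parsing is delegated to dendropy; this module only adds the
bipartition bookkeeping that aligns branch-length vectors across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .errors import FormatError, TopologyError, ValidationError

#: Canonical bipartition identifier: the frozenset of taxon labels on the
#: side of the split not containing the reference (minimum) taxon.
BranchId = frozenset


def parse_tree(source: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(source, dendropy.Tree):
        return source
    return dendropy.Tree.get(data=source, schema="newick",
                             preserve_underscores=True)


def _canonical(side: frozenset, taxa: frozenset) -> frozenset:
    ref = min(taxa)
    return frozenset(side) if ref not in side else taxa - side


def branch_lengths(tree: dendropy.Tree) -> tuple[frozenset, dict]:
    """Map every branch of ``tree`` to (canonical bipartition -> length).

    For a rooted binary tree the two edges incident to the root describe
    the same split; their lengths are summed, which is the standard
    unrooted reading.  Missing branch lengths raise :class:`FormatError`,
    negative ones :class:`ValidationError`.
    """
    taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    if len(taxa) < 3:
        raise FormatError("trees must have at least 3 taxa")
    out: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if not side or side == taxa:
            continue
        if node.edge.length is None:
            raise FormatError(f"missing branch length above {sorted(side)[:3]}")
        if node.edge.length < 0:
            raise ValidationError("negative branch length")
        key = _canonical(side, taxa)
        out[key] = out.get(key, 0.0) + float(node.edge.length)
    return taxa, out


def restrict_branches(master_branches: dict, taxa: frozenset,
                      subset: frozenset) -> dict:
    """Group master branch ids by their bipartition restricted to ``subset``.

    Returns ``{restricted canonical id: [master branch ids...]}``; branches
    whose split becomes trivial on ``subset`` are dropped.  A group with
    more than one member is a path of master branches fused by pruning.
    """
    groups: dict = {}
    for key in master_branches:
        # ``key`` is one side of the split over the full taxon set.
        inter = key & subset
        if not inter or inter == subset:
            continue
        rkey = _canonical(inter, subset)
        groups.setdefault(rkey, []).append(key)
    return groups


def _representative(group: list) -> frozenset:
    return min(group, key=lambda s: (len(s), tuple(sorted(s))))


@dataclass
class GeneTreeSet:
    """Branch-length vectors for many genes on one master topology."""

    taxa: frozenset
    master_branches: dict  # BranchId -> length on the master tree
    genes: dict = field(default_factory=dict)       # name -> {BranchId: length}
    taxa_present: dict = field(default_factory=dict)  # name -> frozenset
    master_tree: dendropy.Tree | None = field(default=None, repr=False)

    def add_gene(self, name: str, tree: dendropy.Tree) -> None:
        gtaxa, gbranches = branch_lengths(tree)
        extra = gtaxa - self.taxa
        if extra:
            raise TopologyError(f"gene {name!r} has taxa not in master: "
                                f"{sorted(extra)}")
        self.genes[name] = match_to_master(self.master_branches, self.taxa,
                                           gbranches, gtaxa, name)
        self.taxa_present[name] = gtaxa

    def add_gene_branches(self, name: str, branches: dict,
                          taxa_present: frozenset | None = None) -> None:
        """Register a gene already keyed by master branch ids."""
        unknown = set(branches) - set(self.master_branches)
        if unknown:
            raise TopologyError(f"gene {name!r}: {len(unknown)} branch ids "
                                "not on the master topology")
        self.genes[name] = dict(branches)
        self.taxa_present[name] = taxa_present or self.taxa


def match_to_master(master_branches: dict, taxa: frozenset,
                    gene_branches: dict, gene_taxa: frozenset,
                    name: str = "?") -> dict:
    """Align one gene's branches to master branch identifiers.

    With all taxa present this is exact bipartition lookup.  With taxa
    missing, the master is pruned to the gene's taxon set; a fused path of
    master branches receives the gene branch length (the sum of the merged
    branches on the gene side) under one representative master id.
    """
    if gene_taxa == taxa:
        groups = {key: [key] for key in master_branches}
    else:
        groups = restrict_branches(master_branches, taxa, gene_taxa)
    out: dict = {}
    for key, length in gene_branches.items():
        if key not in groups:
            raise TopologyError(
                f"gene {name!r}: branch {tuple(sorted(key))[:3]}... conflicts "
                "with the master topology after pruning")
        out[_representative(groups[key])] = length
    return out


def read_newick_trees(path, master: str | dendropy.Tree) -> GeneTreeSet:
    """Read one newick tree per line into a :class:`GeneTreeSet`.

    Lines may be plain newick strings (genes auto-named ``gene_1``, ...)
    or ``name<TAB>newick``.
    """
    mtree = parse_tree(master)
    taxa, mbranches = branch_lengths(mtree)
    ts = GeneTreeSet(taxa=taxa, master_branches=mbranches, master_tree=mtree)
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if "\t" in line:
                name, newick = line.split("\t", 1)
            else:
                name, newick = f"gene_{i}", line
            ts.add_gene(name, parse_tree(newick))
    if not ts.genes:
        raise FormatError(f"no trees in {path}")
    return ts


def write_gene_trees(ts: GeneTreeSet, path) -> None:
    """Write full-taxon genes back to ``name<TAB>newick`` lines.

    Branch lengths are painted onto a clone of the master tree, so only
    genes observed in every taxon can be written.
    """
    if ts.master_tree is None:
        raise ValueError("GeneTreeSet carries no master tree to clone")
    with open(path, "w") as fh:
        for name, branches in ts.genes.items():
            if ts.taxa_present[name] != ts.taxa:
                raise ValueError(f"gene {name!r} is missing taxa; cannot be "
                                 "written on the master topology")
            clone = ts.master_tree.clone(depth=1)
            painted: set = set()
            for node in clone.preorder_node_iter():
                if node.parent_node is None:
                    continue
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if not side or side == ts.taxa:
                    continue
                key = _canonical(side, ts.taxa)
                if key in branches:
                    # a rooted-binary master shows the root split twice;
                    # assign the fused length once, zero on the twin edge
                    node.edge.length = branches[key] if key not in painted \
                        else 0.0
                    painted.add(key)
            newick = clone.as_string(schema="newick",
                                     suppress_rooting=True).strip()
            fh.write(f"{name}\t{newick}\n")
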