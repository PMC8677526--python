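"""Time-tree data model and I/O.

Trees are rooted and measured in absolute time: node ages are in Ma before
present, with extant samples anchored at age 0.  Two departures from the
ultrametric binary trees of classical phylogenetics are supported, because
serially sampled (fossil) data require them:

* **fossil tips** -- leaves with age > 0;
* **sampled ancestors** -- degree-2 *sampled* internal nodes, representing a
  fossil that lies on a lineage with later sampled descendants.

Ages are primary; branch lengths are derived as ``parent.age - child.age``.
On disk, sampled ancestors use the common tree-log convention of a
zero-length-branch tip, which is converted to/from the in-memory degree-2
representation on parse/write.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field

import dendropy

AGE_TOL = 1e-6

_VERSION_COUNTER = itertools.count(1)


class TreeParseError(ValueError):
    pass


class TreeValidationError(ValueError):
    pass


class TimeTreeNode:
    """Node of a :class:`TimeTree`.

    Attributes
    ----------
    label : str
        Taxon name for sampled nodes, "" otherwise.
    age : float
        Ma before present (>= 0).
    children : list[TimeTreeNode]
        0 (tip), 1 (sampled ancestor) or 2 children.
    is_sample : bool
        True for every tip and for sampled-ancestor internal nodes.
    branch_index : int
        Stable integer identifying the branch above this node.
    """

    __slots__ = ("label", "age", "children", "parent", "is_sample",
                 "branch_index", "meta")

    def __init__(self, label="", age=0.0, children=None, is_sample=False,
                 branch_index=-1):
        self.label = label
        self.age = float(age)
        self.children = children if children is not None else []
        self.parent = None
        self.is_sample = is_sample
        self.branch_index = branch_index
        self.meta = None  # optional annotation dict (posterior, HPDs, ...)
        for c in self.children:
            c.parent = self

    # -- structure helpers -------------------------------------------------
    def add_child(self, child):
        child.parent = self
        self.children.append(child)

    def remove_child(self, child):
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self):
        return not self.children

    @property
    def is_sampled_ancestor(self):
        return self.is_sample and len(self.children) == 1

    @property
    def is_extant(self):
        return self.is_leaf and self.age <= AGE_TOL

    @property
    def is_fossil(self):
        return self.is_sample and self.age > AGE_TOL

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = ("SA" if self.is_sampled_ancestor
                else "tip" if self.is_leaf else "int")
        return f"<{kind} {self.label or '*'} age={self.age:.4g}>"


class TimeTree:
    """Rooted time tree; species trees may carry an origin age (> root age)."""

    def __init__(self, root: TimeTreeNode, origin_age: float | None = None):
        self.root = root
        self.origin_age = origin_age
        self.version = 0      # bumped on every structural change
        self._flat = {}       # flattening caches keyed by partition id
        self._nodes_cache = None
        self._assign_branch_indices()

    # -- traversal ----------------------------------------------------------
    def bump_version(self):
        """Mark a structural change; returns the previous version so a
        rejected proposal can restore it (stamps are never reused, so a
        cache built against the transient structure can never collide)."""
        old = self.version
        self.version = next(_VERSION_COUNTER)
        return old

    def node_list(self):
        """All nodes (preorder), cached until the structure changes."""
        cache = self._nodes_cache
        if cache is None or cache[0] != self.version:
            cache = (self.version, list(self.preorder()))
            self._nodes_cache = cache
        return cache[1]

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def postorder(self):
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self):
        return [n for n in self.preorder() if n.is_leaf]

    def samples(self):
        return [n for n in self.preorder() if n.is_sample]

    @property
    def taxa(self):
        return {n.label for n in self.samples()}

    def node_count(self):
        return sum(1 for _ in self.preorder())

    def extant_tips(self):
        return [n for n in self.leaves() if n.is_extant]

    def fossil_samples(self):
        return [n for n in self.samples() if n.age > AGE_TOL]

    def sampled_ancestors(self):
        return [n for n in self.preorder() if n.is_sampled_ancestor]

    def bifurcations(self):
        return [n for n in self.preorder() if len(n.children) == 2]

    def find(self, label):
        for n in self.preorder():
            if n.label == label:
                return n
        raise KeyError(label)

    def mrca(self, labels):
        """Most recent common ancestor of the named samples."""
        want = set(labels)
        best = None
        for node in self.postorder():
            below = {m.label for m in _subtree_samples(node)}
            if want <= below and (best is None or node.age < best.age):
                best = node
        if best is None:
            raise KeyError(f"taxa {want} not all present")
        return best

    def _assign_branch_indices(self):
        used = {n.branch_index for n in self.preorder() if n.branch_index >= 0}
        counter = itertools.count()
        for node in self.preorder():
            if node.branch_index < 0:
                idx = next(counter)
                while idx in used:
                    idx = next(counter)
                used.add(idx)
                node.branch_index = idx

    def copy(self):
        def rec(node):
            new = TimeTreeNode(node.label, node.age,
                               [rec(c) for c in node.children],
                               node.is_sample, node.branch_index)
            if node.meta:
                new.meta = dict(node.meta)
            return new
        return TimeTree(rec(self.root), self.origin_age)

    def __repr__(self):  # pragma: no cover
        return (f"<TimeTree {len(self.leaves())} leaves, "
                f"{len(self.sampled_ancestors())} SAs>")


def _subtree_samples(node):
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_sample:
            out.append(n)
        stack.extend(n.children)
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_time_tree(tree: TimeTree) -> list[str]:
    """Return a list of invariant violations (empty iff the tree is valid).

    Diagnostics, not exceptions: each entry names the offending node and the
    rule it breaks.
    """
    problems = []
    for node in tree.preorder():
        name = node.label or f"branch#{node.branch_index}"
        if node.age < -AGE_TOL:
            problems.append(f"negative age at {name}")
        if len(node.children) > 2:
            problems.append(f"multifurcation at {name}")
        if len(node.children) == 1:
            if not node.is_sample:
                problems.append(f"unsampled degree-2 node at {name}")
            child = node.children[0]
            if child.age > node.age + AGE_TOL:
                problems.append(f"age order violated at {name}")
            if abs(child.age - node.age) <= AGE_TOL and not child.is_sample:
                problems.append(
                    f"age tie between sampled ancestor {name} and unsampled "
                    f"node (warning)")
        if len(node.children) == 2:
            if node.is_sample:
                problems.append(f"sampled bifurcation at {name}")
            for child in node.children:
                if child.age >= node.age - AGE_TOL:
                    problems.append(f"age order violated at {name}")
        if node.is_leaf and not node.is_sample:
            problems.append(f"unsampled tip at {name}")
        if node.is_leaf and not node.label:
            problems.append(f"unlabeled tip at branch#{node.branch_index}")
    labels = [n.label for n in tree.samples()]
    if len(labels) != len(set(labels)):
        problems.append("duplicate sample labels")
    if tree.origin_age is not None and tree.origin_age <= tree.root.age:
        problems.append("origin age not above root age")
    indices = [n.branch_index for n in tree.preorder()]
    if len(indices) != len(set(indices)):
        problems.append("duplicate branch indices")
    return problems


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_tree(text: str, dialect: str = "plain",
               tip_ages: dict[str, float] | None = None,
               schema: str | None = None) -> TimeTree:
    """Parse a Newick or NEXUS tree into a :class:`TimeTree`.

    Branch lengths are required and converted to ages with the deepest tips
    anchored at age 0, unless ``tip_ages`` pins named tips to known ages (a
    mismatch between table and Newick-implied ages beyond 1e-6 Ma is an
    error).  Zero-length tip branches are interpreted as sampled ancestors.

    ``dialect`` may be ``plain`` or ``beast-metadata`` (``[&...]`` comments
    are tolerated and stripped in both cases).
    """
    if dialect not in ("plain", "beast-metadata"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if schema is None:
        schema = "nexus" if text.lstrip()[:6].upper() == "#NEXUS" else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text, schema=schema,
            suppress_internal_node_taxa=False,
            terminating_semicolon_required=False,
            preserve_underscores=True,
            rooting="force-rooted")
    except Exception as exc:
        raise TreeParseError(f"malformed tree text: {exc}") from exc
    return _from_dendropy(dtree, tip_ages)


def parse_trees(text: str, schema: str = "nexus") -> list[TimeTree]:
    """Parse every tree in a NEXUS TREES block (or multi-line Newick)."""
    tl = dendropy.TreeList.get(data=text, schema=schema,
                               preserve_underscores=True,
                               rooting="force-rooted")
    return [_from_dendropy(t, None) for t in tl]


def _from_dendropy(dtree, tip_ages):
    # TimeTreeNode has __slots__; keep scratch branch lengths in a side table.
    lengths = {}

    def build2(dnode):
        label = ""
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            length = 0.0
        if length < 0:
            raise TreeValidationError(
                f"negative branch length at {label or '(internal)'}")
        node = TimeTreeNode(label=label)
        lengths[id(node)] = float(length)
        for dc in dnode.child_nodes():
            node.add_child(build2(dc))
        return node

    root = build2(dtree.seed_node)

    # depths
    depth = {id(root): 0.0}
    order = []
    stack = [root]
    while stack:
        n = stack.pop()
        order.append(n)
        for c in n.children:
            depth[id(c)] = depth[id(n)] + lengths[id(c)]
            stack.append(c)
    leaves = [n for n in order if not n.children]
    if not leaves:
        raise TreeParseError("tree has no tips")

    # root age: anchored so deepest tip sits at 0, unless a tip-age table
    # pins tips explicitly.
    root_age = max(depth[id(l)] for l in leaves)
    if tip_ages:
        anchors = [(l, tip_ages[l.label]) for l in leaves
                   if l.label in tip_ages]
        if anchors:
            cands = [depth[id(l)] + a for l, a in anchors]
            root_age = cands[0]
            for c in cands[1:]:
                if abs(c - root_age) > AGE_TOL:
                    raise TreeValidationError(
                        "tip-age table inconsistent with branch lengths "
                        f"(implied root ages {root_age:.8g} vs {c:.8g})")
            # all unpinned tips must land at non-negative ages
            for l in leaves:
                if root_age - depth[id(l)] < -AGE_TOL:
                    raise TreeValidationError(
                        f"tip {l.label} would have negative age")
    for n in order:
        n.age = max(0.0, root_age - depth[id(n)])
        if tip_ages and not n.children and n.label in tip_ages:
            n.age = tip_ages[n.label]

    root = _absorb_sampled_ancestors(root)
    for n in _preorder_from(root):
        if not n.children:
            n.is_sample = True
    return TimeTree(root)


def _preorder_from(node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


def _absorb_sampled_ancestors(root):
    """Convert zero-length-branch tip children into degree-2 sampled nodes."""
    def rec(node):
        node.children = [rec(c) for c in node.children]
        for c in node.children:
            c.parent = node
        if len(node.children) == 2:
            for sa_child in list(node.children):
                if (not sa_child.children
                        and abs(sa_child.age - node.age) <= AGE_TOL
                        and sa_child.age > AGE_TOL):
                    other = [c for c in node.children if c is not sa_child][0]
                    sa = TimeTreeNode(label=sa_child.label, age=node.age,
                                      children=[other], is_sample=True)
                    sa.parent = node.parent
                    return sa
        return node
    return rec(root)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_tree(tree: TimeTree, with_metadata: bool = False,
               precision: int = 12) -> str:
    """Serialize to Newick.

    Branch lengths are ``parent.age - child.age``; sampled ancestors are
    re-encoded as zero-length tip branches.  With ``with_metadata`` any
    node ``meta`` dict is written as a ``[&key=value,...]`` comment, and the
    origin age (if set) is recorded on the root.
    """
    def fmt(x):
        return f"{x:.{precision}g}"

    def meta_str(node):
        if not with_metadata or not node.meta:
            return ""
        parts = []
        for k, v in node.meta.items():
            if isinstance(v, (tuple, list)):
                parts.append(f"{k}={{{','.join(fmt(x) for x in v)}}}")
            else:
                parts.append(f"{k}={fmt(v)}" if isinstance(v, float)
                             else f"{k}={v}")
        return "[&" + ",".join(parts) + "]"

    def quote(label):
        if label and any(ch in label for ch in " ()[]:;,'"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def rec(node, parent_age):
        if node.is_sampled_ancestor:
            # re-expand: bifurcation at node.age with zero-length tip
            inner = rec(node.children[0], node.age)
            core = (f"({inner},{quote(node.label)}{meta_str(node)}"
                    f":0.0)")
        elif node.is_leaf:
            core = quote(node.label) + meta_str(node)
        else:
            inner = ",".join(rec(c, node.age) for c in node.children)
            core = f"({inner})" + (quote(node.label) if node.label else "") \
                + meta_str(node)
        if parent_age is None:
            return core
        return core + ":" + fmt(parent_age - node.age)

    out = rec(tree.root, None)
    if with_metadata and tree.origin_age is not None:
        out += f"[&origin={fmt(tree.origin_age)}]"
    return out + ";"


def write_nexus(trees, names=None, with_metadata=False) -> str:
    """NEXUS TREES block with a translate table."""
    taxa = sorted(trees[0].taxa)
    index = {t: i + 1 for i, t in enumerate(taxa)}
    buf = io.StringIO()
    buf.write("#NEXUS\n\nBegin taxa;\n")
    buf.write(f"    Dimensions ntax={len(taxa)};\n    Taxlabels\n")
    for t in taxa:
        buf.write(f"        {_nexus_quote(t)}\n")
    buf.write("        ;\nEnd;\n\nBegin trees;\n    Translate\n")
    buf.write(",\n".join(f"        {i} {_nexus_quote(t)}"
                         for t, i in index.items()))
    buf.write("\n        ;\n")
    for k, tree in enumerate(trees):
        relab = tree.copy()
        for n in relab.preorder():
            if n.is_sample:
                n.label = str(index[n.label])
        name = names[k] if names else f"STATE_{k}"
        buf.write(f"tree {name} = "
                  + write_tree(relab, with_metadata=with_metadata) + "\n")
    buf.write("End;\n")
    return buf.getvalue()


def _nexus_quote(label):
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_nexus_trees(text: str) -> list[TimeTree]:
    return parse_trees(text, schema="nexus")


# ---------------------------------------------------------------------------
# tree-set utilities
# ---------------------------------------------------------------------------

def prune_taxa(trees, drop) -> list[TimeTree]:
    """Restrict each tree to the taxa not in ``drop``.

    Degree-2 unsampled nodes left behind are suppressed; every surviving
    node keeps its age, so divergence times among the remaining taxa are
    untouched.
    """
    drop = set(drop)
    out = []
    for tree in trees:
        if not (tree.taxa - drop):
            raise ValueError("pruning would remove every taxon")
        out.append(_prune_one(tree, drop))
    return out


def _prune_one(tree, drop):
    tree = tree.copy()

    def rec(node):
        kept = []
        for c in node.children:
            r = rec(c)
            if r is not None:
                kept.append(r)
        keep_self = node.is_sample and node.label not in drop
        if not kept and not keep_self:
            return None
        if len(kept) == 1 and not keep_self:
            return kept[0]  # suppress unsampled degree-2 node
        node.children = kept
        for c in kept:
            c.parent = node
        if not keep_self:
            node.is_sample = False
            node.label = ""
        return node

    new_root = rec(tree.root)
    if new_root is None:
        raise ValueError("pruning would remove every taxon")
    new_root.parent = None
    return TimeTree(new_root, tree.origin_age)


# ---------------------------------------------------------------------------
# tip dates
# ---------------------------------------------------------------------------

def tip_date_from_range(first: float, last: float, grid: float = 0.05
                        ) -> float:
    """Tip date from a stratigraphic range: the range midpoint rounded to the
    nearest ``grid`` Ma; a range reaching the present yields 0."""
    if first < last:
        raise ValueError("range first occurrence must be >= last occurrence")
    if last < 0:
        raise ValueError("ages must be non-negative")
    if last == 0:
        return 0.0
    mid = (first + last) / 2.0
    return round(round(mid / grid) * grid, 10)


def read_tip_age_table(text: str) -> dict[str, float]:
    """Two-column TSV ``taxon<TAB>age_Ma``."""
    ages = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"bad tip-age line: {line!r}")
        ages[parts[0]] = float(parts[1])
    return ages


# ---------------------------------------------------------------------------
# TaxonMap
# ---------------------------------------------------------------------------

@dataclass
class TaxonMap:
    """Maps each gene-tree tip label to (species name, individual id)."""
    mapping: dict[str, tuple[str, str]] = field(default_factory=dict)

    def species_of(self, gene_tip: str) -> str:
        return self.mapping[gene_tip][0]

    def tips_for_species(self, species: str):
        return [g for g, (s, _) in self.mapping.items() if s == species]

    @classmethod
    def from_suffix(cls, gene_tips, sep="_"):
        """Build from labels of the form ``species_individual``."""
        m = {}
        for tip in gene_tips:
            if sep in tip:
                sp, ind = tip.rsplit(sep, 1)
            else:
                sp, ind = tip, "0"
            m[tip] = (sp, ind)
        return cls(m)

    def validate(self, species_tree: TimeTree):
        species = species_tree.taxa
        for tip, (sp, _) in self.mapping.items():
            if sp not in species:
                raise ValueError(
                    f"gene tip {tip} maps to unknown species {sp}")
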