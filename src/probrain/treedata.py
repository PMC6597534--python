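"""Calibrated trees and specimen tables.

The analysis runs on a rooted, time-calibrated phylogeny (branch lengths in
Ma) whose tips are individual specimens, and on a trait table with one row per
specimen (endocast volume, brain mass, body mass, encephalization quotient).
Fossil tips make the tree non-ultrametric.  Newick reading and writing is
delegated to dendropy; :class:`CalibratedTree` is a light preorder-array
representation convenient for covariance algebra.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "TreeError",
    "NewickParseError",
    "CalibratedTree",
    "parse_newick",
    "write_newick",
    "resolve_polytomies",
    "prune_tips",
    "attach_specimens",
    "SpecimenTable",
    "load_specimen_table",
    "read_calibrations",
]

SPECIMEN_COLUMNS = ("specimen_id", "taxon", "endocast_cm3", "brain_g", "body_g", "eq", "group")


class TreeError(ValueError):
    """Invalid tree structure or tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input."""


class CalibratedTree:
    """Rooted tree with branch lengths in Ma.

    Nodes are integer ids in preorder (root = 0, so ``parent[v] < v`` for every
    non-root node).  ``labels[v]`` is the tip label for leaves and an optional
    clade name for internal nodes.  ``blen[v]`` is the length of the branch
    above ``v``; the root's entry stores the (usually zero) root edge, which
    does not contribute to node depths.
    """

    def __init__(self, parent: Sequence[int], blen: Sequence[float], labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = list(labels)
        self._children: list[list[int]] | None = None
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "CalibratedTree":
        parent, blen, labels = [], [], []
        index: dict[int, int] = {}
        for node in dtree.preorder_node_iter():
            idx = len(parent)
            index[id(node)] = idx
            parent.append(index[id(node.parent_node)] if node.parent_node is not None else -1)
            blen.append(node.edge.length if node.edge.length is not None else 0.0)
            if node.is_leaf():
                labels.append(node.taxon.label if node.taxon is not None else node.label)
            else:
                labels.append(node.label)
        return cls(parent, blen, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            nodes[v].edge.length = float(self.blen[v])
            if self.is_tip(v):
                nodes[v].taxon = taxa.new_taxon(self.labels[v])
            else:
                nodes[v].label = self.labels[v]
            if self.parent[v] >= 0:
                nodes[self.parent[v]].add_child(nodes[v])
        dtree.seed_node = nodes[0]
        return dtree

    def copy(self) -> "CalibratedTree":
        return CalibratedTree(self.parent.copy(), self.blen.copy(), list(self.labels))

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.parent)
        if n == 0:
            raise TreeError("empty tree")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise TreeError("exactly one root (node 0) is required")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeError("nodes must be in preorder (parent before child)")
        if np.any(self.blen < 0) or not np.all(np.isfinite(self.blen)):
            raise TreeError("all branch lengths must be finite and >= 0")
        tips = [self.labels[v] for v in range(n) if self.is_tip(v)]
        if any(t is None for t in tips):
            raise TreeError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for v in range(1, self.n_nodes):
                ch[self.parent[v]].append(v)
            self._children = ch
        return self._children

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    @property
    def tips(self) -> list[int]:
        return [v for v in range(self.n_nodes) if self.is_tip(v)]

    @property
    def internal_nodes(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.is_tip(v)]

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[v] for v in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def node_by_label(self, label: str) -> int:
        for v, lab in enumerate(self.labels):
            if lab == label:
                return v
        raise TreeError(f"no node labelled {label!r}")

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths in Ma (root depth 0; root edge ignored)."""
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.blen[v]
        return d

    def ancestor_sets(self) -> list[set[int]]:
        """For each node, the set of its ancestors including itself."""
        anc: list[set[int]] = []
        for v in range(self.n_nodes):
            if self.parent[v] < 0:
                anc.append({v})
            else:
                anc.append(anc[self.parent[v]] | {v})
        return anc

    def clade_tips(self, v: int) -> list[int]:
        """Tip ids descending from node v (v itself if it is a tip)."""
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(u)
            else:
                stack.extend(self.children[u])
        return sorted(out)

    def mrca(self, v: int, w: int) -> int:
        anc = self.ancestor_sets()
        # common ancestors form a chain; preorder ids grow down the chain
        return max(anc[v] & anc[w])

    # -- covariance support ------------------------------------------------

    def shared_path_matrix(self, tip_order: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Matrix S with S_ij = root-to-MRCA path length for tips i, j (Ma).

        The diagonal holds root-to-tip depths.  This is the unit-rate Brownian
        motion covariance of the tip states.
        """
        depths = self.depths()
        anc = self.ancestor_sets()
        tips = self.tips
        labels = [self.labels[v] for v in tips]
        if tip_order is not None:
            pos = {lab: i for i, lab in enumerate(labels)}
            missing = [t for t in tip_order if t not in pos]
            if missing:
                raise TreeError(f"tips not in tree: {missing}")
            tips = [tips[pos[t]] for t in tip_order]
            labels = list(tip_order)
        k = len(tips)
        S = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                common = anc[tips[i]] & anc[tips[j]]
                S[i, j] = S[j, i] = max(depths[u] for u in common)
        return S, labels

    def node_tip_distances(self) -> np.ndarray:
        """Patristic distance from every node to every tip, shape (n_nodes, n_tips)."""
        depths = self.depths()
        anc = self.ancestor_sets()
        tips = self.tips
        D = np.empty((self.n_nodes, len(tips)))
        for v in range(self.n_nodes):
            for j, t in enumerate(tips):
                m = max(depths[u] for u in (anc[v] & anc[t]))
                D[v, j] = depths[v] + depths[t] - 2.0 * m
        return D


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> CalibratedTree:
    """Parse a Newick string into a :class:`CalibratedTree`.

    Raises :class:`NewickParseError` (with dendropy's positional message) for
    malformed input and :class:`TreeError` for structural problems such as
    duplicate tip labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except TreeError:
        raise
    except Exception as exc:  # dendropy raises several tokenizer error types
        raise NewickParseError(f"malformed Newick: {exc}") from None
    return CalibratedTree.from_dendropy(dtree)


def _fmt_len(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: CalibratedTree) -> str:
    """Serialize to Newick, writing every branch length (zeros explicitly)."""
    ch = tree.children

    def rec(v: int) -> str:
        lab = tree.labels[v] or ""
        if ch[v]:
            return "(" + ",".join(rec(c) for c in ch[v]) + f"){lab}:{_fmt_len(tree.blen[v])}"
        return f"{lab}:{_fmt_len(tree.blen[v])}"

    return rec(0) + ";"


# ---------------------------------------------------------------------------
# Nested-list rebuilding helpers (used by structural edits)
# ---------------------------------------------------------------------------

def _to_nested(tree: CalibratedTree, v: int = 0):
    """Node as [label, blen, children]."""
    return [tree.labels[v], float(tree.blen[v]), [_to_nested(tree, c) for c in tree.children[v]]]


def _from_nested(root) -> CalibratedTree:
    parent, blen, labels = [], [], []

    def walk(node, par: int) -> None:
        idx = len(parent)
        parent.append(par)
        labels.append(node[0])
        blen.append(node[1])
        for c in node[2]:
            walk(c, idx)

    walk(root, -1)
    return CalibratedTree(parent, blen, labels)


def resolve_polytomies(tree: CalibratedTree) -> CalibratedTree:
    """Return a strictly bifurcating tree, inserting zero-length branches.

    Polytomies are resolved left-to-right ((c1,c2):0, c3, ...), which leaves
    the induced tip covariance matrix unchanged.
    """
    root = _to_nested(tree)

    def resolve(node) -> None:
        while len(node[2]) > 2:
            grouped = [None, 0.0, node[2][:2]]
            node[2] = [grouped] + node[2][2:]
        for c in node[2]:
            resolve(c)

    resolve(root)
    return _from_nested(root)


def prune_tips(tree: CalibratedTree, drop: Iterable[str]) -> CalibratedTree:
    """Remove the named tips.

    Internal unifurcations are collapsed by summing branch lengths, so
    root-to-tip depths — and hence Brownian covariances among retained tips —
    are exactly preserved.  A root left with a single child is kept (the stem
    remains part of every retained tip's shared path).
    """
    drop = set(drop)
    present = set(tree.tip_labels)
    missing = drop - present
    if missing:
        raise TreeError(f"cannot prune tips not in tree: {sorted(missing)}")
    if len(present - drop) < 1:
        raise TreeError("pruning would remove every tip")
    root = _to_nested(tree)

    def walk(node):
        if not node[2]:  # tip
            return None if node[0] in drop else node
        kept = [w for w in (walk(c) for c in node[2]) if w is not None]
        if not kept:
            return None
        if len(kept) == 1 and node is not root:
            child = kept[0]
            child[1] += node[1]
            return child
        node[2] = kept
        return node

    out = walk(root)
    return _from_nested(out)


def attach_specimens(
    tree: CalibratedTree,
    table: "SpecimenTable",
    taxon_map: Mapping[str, str] | None = None,
    epsilon: float = 0.01,
) -> CalibratedTree:
    """Replace each species tip with its specimen tips.

    A species observed once keeps its branch and is renamed to the specimen
    id.  A species with n > 1 specimens becomes a shallow polytomy: the
    species tip turns into an internal node (keeping the species name as its
    label) whose branch is shortened by ``epsilon`` and which carries n
    specimen tips of length ``epsilon``, so root-to-tip depths are preserved
    and conspecific specimens share all but the last ``epsilon`` Ma of path.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    df = table.df[table.df["group"] == "proboscidean"]
    taxon_map = dict(taxon_map) if taxon_map else {}
    tip_set = set(tree.tip_labels)
    groups: dict[str, list[str]] = {}
    orphans: list[str] = []
    for _, row in df.iterrows():
        tip = taxon_map.get(row["taxon"], str(row["taxon"]).replace(" ", "_"))
        if tip not in tip_set:
            orphans.append(row["specimen_id"])
            continue
        groups.setdefault(tip, []).append(row["specimen_id"])
    if orphans:
        raise TreeError(f"specimen records with no matching tip: {orphans}")

    root = _to_nested(tree)

    def walk(node) -> None:
        if not node[2]:
            ids = groups.get(node[0])
            if ids is None:
                log.warning("tip %s has no specimen records; left unchanged", node[0])
            elif len(ids) == 1:
                node[0] = ids[0]
            else:
                node[1] = max(node[1] - epsilon, 0.0)
                node[2] = [[sid, epsilon, []] for sid in ids]
            return
        for c in node[2]:
            walk(c)

    walk(root)
    return _from_nested(root)


# ---------------------------------------------------------------------------
# Specimen table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecimenRecord:
    """One measured individual."""

    specimen_id: str
    taxon: str
    body_g: float
    endocast_cm3: float | None = None
    brain_g: float | None = None
    eq: float | None = None
    group: str = "proboscidean"


@dataclass
class SpecimenTable:
    """Ordered specimen records, held as a pandas DataFrame.

    Columns: ``specimen_id, taxon, endocast_cm3, brain_g, body_g, eq, group``
    (plus any recomputed columns added downstream).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPECIMEN_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"specimen table missing columns: {missing}")
        ids = self.df["specimen_id"]
        if ids.duplicated().any():
            raise ValueError(f"duplicate specimen ids: {sorted(ids[ids.duplicated()])}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def proboscideans(self) -> "SpecimenTable":
        return SpecimenTable(self.df[self.df["group"] == "proboscidean"].copy())

    def outgroups(self) -> "SpecimenTable":
        return SpecimenTable(self.df[self.df["group"] == "outgroup"].copy())

    def subset(self, specimen_ids: Iterable[str]) -> "SpecimenTable":
        keep = set(specimen_ids)
        return SpecimenTable(self.df[self.df["specimen_id"].isin(keep)].copy())

    def exclude(self, specimen_ids: Iterable[str]) -> "SpecimenTable":
        drop = set(specimen_ids)
        return SpecimenTable(self.df[~self.df["specimen_id"].isin(drop)].copy())

    def records(self) -> list[SpecimenRecord]:
        out = []
        for _, r in self.df.iterrows():
            out.append(
                SpecimenRecord(
                    specimen_id=r["specimen_id"],
                    taxon=r["taxon"],
                    body_g=float(r["body_g"]),
                    endocast_cm3=None if pd.isna(r["endocast_cm3"]) else float(r["endocast_cm3"]),
                    brain_g=None if pd.isna(r["brain_g"]) else float(r["brain_g"]),
                    eq=None if pd.isna(r["eq"]) else float(r["eq"]),
                    group=r["group"],
                )
            )
        return out

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def _normalize_decimal_commas(s: pd.Series) -> pd.Series:
    return pd.to_numeric(s.astype(str).str.strip().str.replace(",", ".", regex=False).replace({"": None, "nan": None}), errors="raise")


def load_specimen_table(source: str | Path | io.IOBase) -> SpecimenTable:
    """Read a specimen CSV (decimal commas in numeric columns are normalized).

    Row-level problems (missing/non-positive body mass, no size measurement at
    all, unparseable numbers) are collected and raised together.
    """
    df = pd.read_csv(source, dtype=str)
    if df.empty:
        log.warning("specimen table is empty")
        return SpecimenTable(pd.DataFrame(columns=list(SPECIMEN_COLUMNS)))
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"specimen CSV missing columns: {missing}")
    errors: list[str] = []
    for col in ("endocast_cm3", "brain_g", "body_g", "eq"):
        try:
            df[col] = _normalize_decimal_commas(df[col])
        except (ValueError, TypeError):
            # fall back row by row to report the offender
            vals = []
            for i, raw in df[col].items():
                try:
                    vals.append(_normalize_decimal_commas(pd.Series([raw])).iloc[0])
                except (ValueError, TypeError):
                    errors.append(f"row {i} ({df['specimen_id'][i]}): non-numeric {col}={raw!r}")
                    vals.append(np.nan)
            df[col] = vals
    bad_body = df["body_g"].isna() | (df["body_g"] <= 0)
    for i in df.index[bad_body]:
        errors.append(f"row {i} ({df['specimen_id'][i]}): body mass missing or non-positive")
    no_size = df["endocast_cm3"].isna() & df["brain_g"].isna()
    for i in df.index[no_size]:
        errors.append(f"row {i} ({df['specimen_id'][i]}): neither endocast volume nor brain mass present")
    bad_group = ~df["group"].isin(["proboscidean", "outgroup"])
    for i in df.index[bad_group]:
        errors.append(f"row {i} ({df['specimen_id'][i]}): group must be proboscidean|outgroup, got {df['group'][i]!r}")
    if errors:
        raise ValueError("invalid specimen table:\n  " + "\n  ".join(errors))
    return SpecimenTable(df)


def read_calibrations(source: str | Path | io.IOBase) -> dict[str, float]:
    """Read a ``name=age`` calibration file (ages in Ma; # comments allowed)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    out: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"calibration line {lineno}: expected name=age, got {line!r}")
        name, val = line.split("=", 1)
        out[name.strip()] = float(val)
    return out
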