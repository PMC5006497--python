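"""Tree and trait-table I/O, and collapsing of poorly supported branches.

Trees are held as rooted dendropy trees with per-internal-branch Bayesian
support values parsed from internal node labels (or NEXUS comment
metadata).  Branches whose support falls at or below a threshold are
collapsed into "twigs": the entire clade is replaced by a single terminal
coded with the union of the member species' states, so topological
uncertainty is converted into trait ambiguity rather than trusted structure.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import pandas as pd

from .states import FULL_SET, StateSet, normalize_label, state_set_label
from .traits import TraitColumn

logger = logging.getLogger(__name__)


class TreeParseError(ValueError):
    pass


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths and optional branch supports.

    Supports live on internal nodes as ``node.support`` (float in [0, 1]
    or ``None`` when the source annotated nothing — absence is recorded as
    absence, never coerced to 1.0).
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeParseError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeParseError(f"negative branch length {edge.length}")
        for node in self.tree.preorder_node_iter():
            if not hasattr(node, "support"):
                node.support = None

    # -- basic queries -------------------------------------------------
    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def internal_nodes(self, exclude_root: bool = True):
        root = self.tree.seed_node
        for node in self.tree.preorder_internal_node_iter():
            if exclude_root and node is root:
                continue
            yield node

    def supports(self) -> list[float | None]:
        return [n.support for n in self.internal_nodes()]

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter()
        )

    # -- serialization -------------------------------------------------
    @classmethod
    def from_string(cls, text: str, schema: str | None = None) -> "Phylogeny":
        """Parse a Newick or NEXUS tree; supports read from internal labels."""
        if schema is None:
            schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema=schema,
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeParseError(f"could not parse {schema} tree: {exc}") from exc
        tree.is_rooted = True
        _parse_supports(tree)
        return cls(tree)

    @classmethod
    def from_path(cls, path: str) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_string(fh.read())

    def to_newick(self) -> str:
        """Newick string with supports written as internal node labels."""
        for node in self.tree.preorder_internal_node_iter():
            sup = getattr(node, "support", None)
            node.label = _format_support(sup) if sup is not None else None
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip() + "\n"

    def clone(self) -> "Phylogeny":
        other = Phylogeny.from_string(self.to_newick())
        return other


def _format_support(value: float) -> str:
    text = f"{value:.6f}".rstrip("0").rstrip(".")
    return text if text else "0"


def _parse_supports(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf():
            continue
        label = node.label
        if label is None:
            # some writers stash posterior support in comments/annotations
            ann = node.annotations.get_value("posterior", None)
            if ann is not None:
                label = str(ann)
        if label is None:
            continue
        try:
            value = float(label)
        except ValueError:
            continue
        if 0.0 <= value <= 1.0:
            node.support = value


# ---------------------------------------------------------------------
# twig collapsing


@dataclass
class TwigMap:
    """Mapping from twig label to the original taxa it replaces."""

    members: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, taxa in self.members.items():
            if len(taxa) < 2:
                raise ValueError(f"twig {label!r} has fewer than 2 members")
            if seen & taxa:
                raise ValueError("twig member sets overlap")
            seen |= taxa

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, label: str) -> frozenset[str]:
        return self.members[label]


def collapse_low_support(
    tree: Phylogeny,
    threshold: float = 0.95,
    twig_prefix: str = "twig",
) -> tuple[Phylogeny, TwigMap]:
    """Replace maximal low-support clades by single "twig" terminals.

    Every maximal clade whose subtending branch carries support <=
    ``threshold`` becomes one terminal (outermost-first, so nested
    low-support structure inside an already-collapsed clade is absorbed).
    Branches without annotated support are retained as trusted; consensus
    trees commonly annotate only uncertain nodes.

    The twig terminal's branch length is the subtending branch length plus
    the mean root-to-tip path length within the collapsed clade, preserving
    the expected tip depth.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    work = tree.clone()
    t = work.tree
    to_collapse: list[dendropy.Node] = []
    stack = [t.seed_node]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            continue
        sup = getattr(node, "support", None)
        if node is not t.seed_node and sup is not None and sup <= threshold:
            to_collapse.append(node)  # maximal: do not descend further
            continue
        stack.extend(node.child_nodes())

    members: dict[str, frozenset[str]] = {}
    for i, node in enumerate(to_collapse, start=1):
        leaves = [l for l in node.leaf_iter()]
        labels = frozenset(l.taxon.label for l in leaves)
        depths = []
        for leaf in leaves:
            d, cur = 0.0, leaf
            while cur is not node:
                d += cur.edge.length or 0.0
                cur = cur.parent_node
            depths.append(d)
        mean_depth = sum(depths) / len(depths)
        label = f"{twig_prefix}{i}"
        node.set_child_nodes([])
        node.support = None
        node.label = None
        node.taxon = t.taxon_namespace.new_taxon(label)
        node.edge.length = (node.edge.length or 0.0) + mean_depth
        members[label] = labels
    t.purge_taxon_namespace()
    return Phylogeny(work.tree), TwigMap(members)


def twig_state_set(member_states: list[StateSet]) -> StateSet:
    """Union coding of a twig: all pattern states of its member species."""
    if not member_states:
        raise ValueError("twig with no member states")
    out: set[str] = set()
    for s in member_states:
        out |= s
    return frozenset(out)


def apply_twig_coding(column: TraitColumn, twigs: TwigMap) -> TraitColumn:
    """Rewrite a trait column after collapsing: twigs get union state sets."""
    assignments = dict(column.assignments)
    for label, taxa in twigs.members.items():
        member_states = [assignments.pop(t) for t in taxa if t in assignments]
        if not member_states:
            raise ValueError(f"no trait data for any member of {label!r}")
        assignments[label] = twig_state_set(member_states)
    return TraitColumn(assignments, name=column.name)


# ---------------------------------------------------------------------
# trait tables


def read_trait_table(source: str) -> dict[str, TraitColumn]:
    """Read trait columns from TSV/CSV text, a NEXUS DATA block, or a path.

    Long layout (``taxon<TAB>state``) yields one column named after the
    state header; wide layout (``taxon`` plus one column per patch) yields
    one :class:`TraitColumn` per patch.  Multi-state cells use ``|`` and
    ``mottled``/``unknown`` map to the full ambiguity set.  NEXUS standard
    matrices use symbols 0-3 in canonical state order with ``?``/``-`` as
    full ambiguity and ``{..}`` polymorphism sets.
    """
    text = source
    if "\n" not in source and ("\t" not in source):
        try:
            with open(source) as fh:
                text = fh.read()
        except OSError:
            pass
    if text.lstrip().lower().startswith("#nexus"):
        return _read_nexus_traits(text)
    first = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("trait table needs a taxon column plus >=1 state column")
    taxon_col = df.columns[0]
    out: dict[str, TraitColumn] = {}
    for col in df.columns[1:]:
        assignments: dict[str, StateSet] = {}
        for taxon, raw in zip(df[taxon_col], df[col]):
            if pd.isna(raw):
                assignments[str(taxon)] = FULL_SET
            else:
                assignments[str(taxon)] = normalize_label(str(raw))
        out[str(col)] = TraitColumn(assignments, name=str(col))
    return out


def _read_nexus_traits(text: str) -> dict[str, TraitColumn]:
    from .states import STATE_ORDER

    matrix = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    n_chars = max(len(seq) for seq in matrix.values())
    columns: dict[str, dict[str, StateSet]] = {
        f"char{i + 1}": {} for i in range(n_chars)
    }
    for taxon, seq in matrix.items():
        for i, cell in enumerate(seq):
            fundamentals = getattr(cell, "fundamental_states", None) or [cell]
            symbols = {s.symbol for s in fundamentals}
            states = {
                STATE_ORDER[int(sym)] for sym in symbols if sym.isdigit()
            }
            columns[f"char{i + 1}"][taxon.label] = (
                frozenset(states) if states else FULL_SET
            )
    return {
        name: TraitColumn(assignments, name=name)
        for name, assignments in columns.items()
    }


def write_trait_table(columns: Mapping[str, TraitColumn], path: str) -> None:
    patches = list(columns)
    taxa = columns[patches[0]].taxa
    rows = []
    for taxon in taxa:
        row = {"taxon": taxon}
        for p in patches:
            row[p] = state_set_label(columns[p][taxon])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def reconcile(
    tree: Phylogeny,
    column: TraitColumn,
    on_missing_taxon: str = "prune",
) -> TraitColumn:
    """Align a trait column with a tree's tip set.

    Trait taxa absent from the tree are pruned with a warning (or raise,
    with ``on_missing_taxon="error"``); tree tips without trait data are
    coded as fully ambiguous with a warning.
    """
    tips = set(tree.taxa)
    extra = [t for t in column.taxa if t not in tips]
    if extra:
        if on_missing_taxon == "error":
            raise ValueError(f"trait taxa not on tree: {extra}")
        logger.warning("pruning %d trait taxa not on tree: %s", len(extra), extra)
    assignments = {t: s for t, s in column.assignments.items() if t in tips}
    for tip in tree.taxa:
        if tip not in assignments:
            logger.warning("tip %r has no trait data; coding as unknown", tip)
            assignments[tip] = FULL_SET
    return TraitColumn(assignments, name=column.name)
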