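"""Gene-tree, taxonomy, and orthogroup input/output.

Gene trees are maximum-likelihood trees over mixed host/prokaryote/eukaryote
sequence sets, carrying ultrafast-bootstrap (UFBOOT) support percentages on
internal branches.  Trees are treated as unrooted: the unit of interest is the
bipartition (split) of the leaf set induced by each edge, and a "clade" means
one side of a bipartition.

Support-label dialects: IQ-TREE writes either a bare integer per internal node
or an ``aLRT/UFBOOT`` slash pair; in the latter case the *last* slash-separated
field is the UFBOOT value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import dendropy
import pandas as pd

DOMAIN_CLASSES = frozenset(
    {"host_query", "eukaryote", "prokaryote", "virus", "unknown"}
)

#: Conventional order of lineage ranks as stored in semicolon-joined strings.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


class TreeParseError(ValueError):
    """Malformed newick or invalid support label."""


class TaxonomyError(ValueError):
    """Invalid or incomplete taxonomy table."""


def _parse_support_label(label: Optional[str]) -> Optional[int]:
    """Parse an internal-node label into a UFBOOT support percentage.

    ``None``/empty -> absent; ``"95"`` -> 95; ``"88.1/97"`` -> 97 (last field).
    """
    if label is None or label == "":
        return None
    last = label.split("/")[-1]
    try:
        value = float(last)
    except ValueError:
        raise TreeParseError(f"unparseable support label {label!r}") from None
    if not 0.0 <= value <= 100.0:
        raise TreeParseError(f"support {value} outside [0, 100] in label {label!r}")
    return int(round(value))


@dataclass
class GeneTree:
    """An unrooted gene tree with per-bipartition support values.

    ``bipartitions`` maps one side of each internal edge (the leaf set "below"
    the edge in the parsed representation) to its support, or ``None`` when the
    newick carried no label for that edge.  Trivial (single-leaf) bipartitions
    are not stored: terminal edges carry no support.
    """

    leaves: frozenset
    bipartitions: dict  # frozenset[str] -> Optional[int]
    n_sites: Optional[int] = None
    _dendropy: Optional[dendropy.Tree] = field(default=None, repr=False, compare=False)

    def sides(self) -> Iterator[tuple]:
        """Yield every non-trivial bipartition side with its support.

        Each internal edge contributes both of its sides (the stored side and
        its complement), sharing the edge's support.  Trivial sides (single
        leaves and their complements) are also yielded with support ``None``,
        so callers see every side of every edge.
        """
        for side, support in self.bipartitions.items():
            yield side, support
            yield self.leaves - side, support
        for leaf in self.leaves:
            side = frozenset({leaf})
            yield side, None
            yield self.leaves - side, None

    def support_of(self, side: frozenset) -> Optional[int]:
        if side in self.bipartitions:
            return self.bipartitions[side]
        return self.bipartitions.get(self.leaves - side)


def _tree_from_dendropy(tree: dendropy.Tree, n_sites: Optional[int]) -> GeneTree:
    leaves = frozenset(t.label for t in tree.taxon_namespace)
    if len(leaves) != len(tree.taxon_namespace):
        raise TreeParseError("duplicate leaf labels")
    bipartitions: dict = {}
    seed = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is seed or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(leaves - below) == 0:
            continue
        support = _parse_support_label(node.label)
        prev = bipartitions.get(below)
        if prev is None:
            bipartitions[below] = support
    # children of the seed node in an unrooted newick with a bifurcating root
    # describe the same edge twice; dendropy keeps them distinct nodes, and the
    # dict above keeps the first labelled value.
    return GeneTree(leaves=leaves, bipartitions=bipartitions, n_sites=n_sites, _dendropy=tree)


def read_gene_tree_string(newick: str, n_sites: Optional[int] = None) -> GeneTree:
    """Parse a newick string into a :class:`GeneTree`."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed newick: {exc}") from exc
    return _tree_from_dendropy(tree, n_sites)


def read_gene_tree(path, n_sites: Optional[int] = None) -> GeneTree:
    """Read a newick file; see :func:`read_gene_tree_string` for dialects."""
    with open(path) as fh:
        return read_gene_tree_string(fh.read(), n_sites=n_sites)


def write_gene_tree(tree: GeneTree, path) -> None:
    """Write a tree back to newick, supports as internal-node labels."""
    if tree._dendropy is None:
        raise ValueError("tree has no topology attached")
    out = tree._dendropy.clone(depth=1)
    leaves = tree.leaves
    for node in out.preorder_node_iter():
        if node is out.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(leaves - below) == 0:
            node.label = None
            continue
        support = tree.support_of(below)
        node.label = None if support is None else str(support)
    with open(path, "w") as fh:
        fh.write(
            out.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
        )


@dataclass(frozen=True)
class TaxonEntry:
    domain_class: str
    lineage: tuple
    source: str = ""

    def rank(self, rank) -> str:
        """Lineage label at ``rank`` (name from RANKS or integer depth)."""
        idx = RANKS.index(rank) if isinstance(rank, str) else int(rank)
        if idx >= len(self.lineage):
            raise TaxonomyError(
                f"rank {rank!r} absent from lineage {';'.join(self.lineage)!r}"
            )
        return self.lineage[idx]


class TaxonomyMap:
    """Sequence-ID -> domain class + ranked lineage.

    Every leaf of any tree passed downstream must have an entry; lookups of
    unknown sequence IDs raise :class:`TaxonomyError`.
    """

    def __init__(self, entries: Mapping[str, TaxonEntry]):
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._entries

    def __getitem__(self, seq_id: str) -> TaxonEntry:
        try:
            return self._entries[seq_id]
        except KeyError:
            raise TaxonomyError(f"sequence {seq_id!r} missing from taxonomy map") from None

    def domain_class(self, seq_id: str) -> str:
        return self[seq_id].domain_class

    def is_host(self, seq_id: str) -> bool:
        return self[seq_id].domain_class == "host_query"

    def is_prok_or_virus(self, seq_id: str) -> bool:
        return self[seq_id].domain_class in ("prokaryote", "virus")

    def rank(self, seq_id: str, rank) -> str:
        return self[seq_id].rank(rank)

    def items(self):
        return self._entries.items()

    def validate_leaves(self, leaves: Iterable[str]) -> None:
        missing = sorted(l for l in leaves if l not in self._entries)
        if missing:
            raise TaxonomyError(f"leaves missing from taxonomy: {missing}")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a taxonomy TSV with columns seq_id, domain_class, lineage, source.

    Lineage is a semicolon-joined ranked string (domain;phylum;...).  Duplicate
    seq_id rows and unknown domain_class tokens are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"seq_id", "domain_class", "lineage"}
    if not required.issubset(df.columns):
        raise TaxonomyError(f"taxonomy table must have columns {sorted(required)}")
    dup = df["seq_id"][df["seq_id"].duplicated()]
    if len(dup):
        raise TaxonomyError(f"duplicate seq_id rows: {sorted(set(dup))}")
    bad = df.loc[~df["domain_class"].isin(DOMAIN_CLASSES)]
    if len(bad):
        rows = [f"{r.seq_id}:{r.domain_class}" for r in bad.itertuples()]
        raise TaxonomyError(f"unknown domain_class token(s): {rows}")
    entries = {}
    for r in df.itertuples():
        lineage = tuple(x.strip() for x in r.lineage.split(";") if x.strip())
        source = getattr(r, "source", "")
        entries[r.seq_id] = TaxonEntry(r.domain_class, lineage, source)
    return TaxonomyMap(entries)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    rows = [
        {
            "seq_id": sid,
            "domain_class": e.domain_class,
            "lineage": ";".join(e.lineage),
            "source": e.source,
        }
        for sid, e in sorted(taxonomy.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class Orthogroup:
    """A cluster of putative orthologs/paralogs across species."""

    group_id: str
    members: list
    species: dict  # member seq_id -> species label
    cog: Optional[str] = None
    annotation: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"orthogroup {self.group_id} has no members")


def read_orthogroups(path) -> dict:
    """Read an orthogroup membership TSV into {group_id: Orthogroup}.

    Columns: orthogroup, seq_id, species, optional cog, annotation (long
    format, one member per row).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"orthogroup", "seq_id", "species"}
    if not required.issubset(df.columns):
        raise ValueError(f"orthogroup table must have columns {sorted(required)}")
    groups: dict = {}
    for gid, sub in df.groupby("orthogroup", sort=True):
        cogs = [c for c in sub.get("cog", pd.Series(dtype=str)).tolist() if c]
        ann = [a for a in sub.get("annotation", pd.Series(dtype=str)).tolist() if a]
        groups[gid] = Orthogroup(
            group_id=gid,
            members=sub["seq_id"].tolist(),
            species=dict(zip(sub["seq_id"], sub["species"])),
            cog=cogs[0] if cogs else None,
            annotation=ann[0] if ann else "",
        )
    return groups


def write_orthogroups(groups: Mapping[str, Orthogroup], path) -> None:
    rows = []
    for gid in sorted(groups):
        og = groups[gid]
        for m in og.members:
            rows.append(
                {
                    "orthogroup": gid,
                    "seq_id": m,
                    "species": og.species.get(m, ""),
                    "cog": og.cog or "",
                    "annotation": og.annotation,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def reduce_redundancy(
    tree: GeneTree,
    taxonomy: TaxonomyMap,
    keep_per_clade: int = 1,
    rank="genus",
) -> frozenset:
    """Thin taxonomically redundant leaves from a gene tree.

    Within every maximal monophyletic group of leaves sharing the same lineage
    label at ``rank`` (monophyletic = one side of some bipartition of the
    unrooted tree), at most ``keep_per_clade`` non-host representatives are
    retained, preferring longer sequence IDs (ties broken lexicographically).
    Host (host_query) leaves are always retained.

    Returns the retained leaf-ID set.
    """
    if keep_per_clade < 1:
        raise ValueError("keep_per_clade must be >= 1")
    taxonomy.validate_leaves(tree.leaves)

    def label(leaf: str) -> Optional[str]:
        e = taxonomy[leaf]
        try:
            return e.rank(rank)
        except TaxonomyError:
            return None  # lineage too shallow: never grouped

    # candidate groups: sides whose leaves all share the same rank label
    candidates = []
    seen = set()
    for side, _ in tree.sides():
        if side in seen:
            continue
        seen.add(side)
        labels = {label(l) for l in side}
        if len(labels) == 1 and None not in labels:
            candidates.append(side)
    # maximal candidates first; assign each leaf to the largest group
    candidates.sort(key=lambda s: (-len(s), sorted(s)))
    assigned: dict = {}
    groups: list = []
    for cand in candidates:
        fresh = [l for l in cand if l not in assigned]
        if not fresh:
            continue
        group = frozenset(fresh)
        groups.append(group)
        for l in fresh:
            assigned[l] = group

    retained = set()
    for group in groups:
        hosts = [l for l in group if taxonomy.is_host(l)]
        others = sorted(
            (l for l in group if not taxonomy.is_host(l)),
            key=lambda l: (-len(l), l),
        )
        retained.update(hosts)
        retained.update(others[:keep_per_clade])
    return frozenset(retained)
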