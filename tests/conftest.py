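"""Shared helpers: taxonomy builders, random annotated trees, and an
independent brute-force LGT oracle built on Bio.Phylo (a different newick
parser than the implementation uses)."""

from __future__ import annotations

import io
import itertools

import numpy as np
import pytest
from Bio import Phylo

from symbio.trees import TaxonEntry, TaxonomyMap

HOST_LINEAGE = ("Eukaryota", "Metamonada", "Anaeramoebidae")


def make_taxonomy(spec: dict) -> TaxonomyMap:
    """Build a TaxonomyMap from {seq_id: (domain_class, phylum)}.

    The phylum lands at lineage index 1 so donor inference at rank 'phylum'
    sees it; deeper ranks are synthesised from it.
    """
    entries = {}
    for sid, (cls, phylum) in spec.items():
        if cls == "host_query":
            lineage = HOST_LINEAGE + ("Anaeramoebida", "fam", "Anaeramoeba")
        else:
            domain = "Bacteria" if cls == "prokaryote" else (
                "Viruses" if cls == "virus" else "Eukaryota"
            )
            lineage = (domain, phylum, f"{phylum}_cl", f"{phylum}_ord",
                       f"{phylum}_fam", f"{phylum}_{sid}")
        entries[sid] = TaxonEntry(cls, lineage, "test")
    return TaxonomyMap(entries)


def random_annotated_tree(rng: np.random.Generator, max_leaves: int = 12):
    """Random unrooted (trifurcating-root) newick with random supports and a
    random host/prokaryote/eukaryote/virus leaf composition.

    Returns (newick, classes) with classes mapping seq_id -> (domain_class,
    phylum).  Exactly one host leaf; supports are drawn in [0, 100] or
    omitted.
    """
    n = int(rng.integers(4, max_leaves + 1))
    classes = {"host": ("host_query", "")}
    leaves = ["host"]
    phyla = ("Proteobacteria", "Firmicutes", "Bacteroidota")
    euk_groups = ("Amoebozoa", "Opisthokonta")
    for i in range(n - 1):
        r = rng.random()
        if r < 0.55:
            cls = ("prokaryote", phyla[rng.integers(0, len(phyla))])
        elif r < 0.65:
            cls = ("virus", "Naldaviricetes")
        else:
            cls = ("eukaryote", euk_groups[rng.integers(0, len(euk_groups))])
        name = f"x{i:02d}"
        classes[name] = cls
        leaves.append(name)

    def subtree(items) -> str:
        if len(items) == 1:
            return items[0]
        k = int(rng.integers(1, len(items)))
        left, right = items[:k], items[k:]
        label = "" if rng.random() < 0.25 else str(int(rng.integers(0, 101)))
        return f"({subtree(left)},{subtree(right)}){label}"

    order = [leaves[i] for i in rng.permutation(len(leaves))]
    a = max(1, int(rng.integers(1, len(order) - 1)))
    b = int(rng.integers(a + 1, len(order)))
    parts = [order[:a], order[a:b], order[b:]]  # all non-empty for n >= 4
    newick = "(" + ",".join(subtree(p) for p in parts) + ");"
    return newick, classes


def _phylo_sides(newick: str):
    """All bipartition sides of a newick tree via Bio.Phylo: {side: support}."""
    tree = Phylo.read(io.StringIO(newick), "newick")
    all_leaves = frozenset(t.name for t in tree.get_terminals())
    sides: dict = {}

    def visit(clade, is_root):
        below = frozenset(t.name for t in clade.get_terminals())
        if not is_root and 0 < len(below) < len(all_leaves):
            support = None if clade.confidence is None else int(round(clade.confidence))
            comp = all_leaves - below
            if below not in sides or sides[below] is None:
                sides[below] = support
            if comp not in sides or sides[comp] is None:
                sides[comp] = support
        for child in clade.clades:
            visit(child, False)

    visit(tree.root, True)
    for leaf in all_leaves:
        sides.setdefault(frozenset({leaf}), None)
        sides.setdefault(all_leaves - {leaf}, None)
    return all_leaves, sides


def oracle_classify(newick: str, classes: dict, support_threshold=70,
                    composition_fraction=0.95, max_stray=1):
    """Literal brute-force application of the clade and composition criteria.

    Enumerates every side of every bipartition and checks: support at or
    above threshold (missing counts 0), host inside, at least one
    prokaryote/virus, at most ``max_stray`` non-host eukaryotes.  Smallest
    qualifying side wins (ties: higher support, then lexicographic leaves).
    Falls back to the whole-tree composition fraction.
    """
    all_leaves, sides = _phylo_sides(newick)
    host = next(l for l, (c, _) in classes.items() if c == "host_query")
    prok = {l for l, (c, _) in classes.items() if c in ("prokaryote", "virus")}

    qualifying = []
    for side, support in sides.items():
        eff = support if support is not None else 0
        if host not in side or eff < support_threshold:
            continue
        if not side & prok:
            continue
        strays = sum(1 for l in side if l != host and l not in prok
                     and classes[l][0] != "host_query")
        if strays > max_stray:
            continue
        qualifying.append((side, eff))
    if qualifying:
        side, support = min(qualifying,
                            key=lambda q: (len(q[0]), -q[1], tuple(sorted(q[0]))))
        return True, "clade", side, support
    if len(prok) / len(all_leaves) >= composition_fraction:
        return True, "composition", all_leaves, None
    return False, "none", None, None


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
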