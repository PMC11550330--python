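"""Phylogeny-based lateral-gene-transfer (LGT) classification.

A host (query) gene is called an LGT candidate when its position in a gene
tree places it among prokaryotic and/or viral sequences:

* criterion ``clade`` — some side of a well-supported bipartition (UFBOOT
  >= ``support_threshold``, default 70%) contains the host gene together with
  at least one prokaryote/virus sequence and at most
  ``max_stray_eukaryotes`` (default 1) other eukaryote sequences;
* criterion ``composition`` — no such clade exists, but at least
  ``composition_fraction`` (default 95%) of the sequences in the tree are
  prokaryotic and/or viral;
* criterion ``short_cluster`` — the alignment is too short for a tree
  (< ``min_sites_for_tree`` sites, default 80) and every non-host member of
  the sequence cluster is prokaryotic or viral.

Donor taxonomy is inferred from the qualifying clade: the taxonomic group at
the requested rank whose share of non-host clade members *strictly* exceeds
``donor_majority`` (default 50%); otherwise the donor is unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pandas as pd

from .trees import GeneTree, Orthogroup, TaxonomyMap

UNASSIGNED = "unassigned"

#: How the composition criterion is gated on clade support:
#: "no_qualifying_clade" — fires only when no bipartition satisfies the clade
#: criterion (default); "no_supported_clade" — fires only when no bipartition
#: anywhere in the tree reaches the support threshold.
COMPOSITION_GATES = ("no_qualifying_clade", "no_supported_clade")


@dataclass(frozen=True)
class LgtParams:
    """Thresholds of the four-criterion LGT screen (defaults as published)."""

    support_threshold: int = 70
    composition_fraction: float = 0.95
    donor_majority: float = 0.50
    max_stray_eukaryotes: int = 1
    min_sites_for_tree: int = 80
    donor_rank: str = "phylum"
    include_host_in_denominator: bool = True
    composition_gate: str = "no_qualifying_clade"

    def __post_init__(self):
        if not 0 <= self.support_threshold <= 100:
            raise ValueError("support_threshold must be in [0, 100]")
        for name in ("composition_fraction", "donor_majority"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.max_stray_eukaryotes < 0:
            raise ValueError("max_stray_eukaryotes must be >= 0")
        if self.composition_gate not in COMPOSITION_GATES:
            raise ValueError(f"composition_gate must be one of {COMPOSITION_GATES}")


@dataclass(frozen=True)
class LgtCall:
    """Per-gene LGT classification."""

    gene_id: str
    is_lgt: bool
    criterion: str  # clade | composition | short_cluster | none
    clade_leaves: Optional[frozenset] = None
    support: Optional[int] = None
    donor: str = UNASSIGNED
    orthogroup: Optional[str] = None

    def __post_init__(self):
        if self.criterion == "clade" and self.support is None:
            raise ValueError("clade call must carry a support value")
        if self.criterion == "none" and self.is_lgt:
            raise ValueError("criterion 'none' implies is_lgt False")


def _side_supports(tree: GeneTree) -> dict:
    """Every side of every edge -> support (missing label or terminal -> None)."""
    out: dict = {}
    for side, _ in tree.sides():
        if side not in out:
            out[side] = tree.support_of(side)
    return out


def infer_donor(
    clade_leaves: Iterable[str],
    taxonomy: TaxonomyMap,
    rank: str = "phylum",
    params: Optional[LgtParams] = None,
) -> str:
    """Strict-majority donor inference over the non-host leaves of a clade.

    Returns the lineage label at ``rank`` whose share of non-host leaves
    strictly exceeds ``params.donor_majority``; :data:`UNASSIGNED` when no
    group does (in particular on exact ties at the default 0.5).
    """
    params = params or LgtParams()
    leaves = list(clade_leaves)
    if not leaves:
        raise ValueError("empty clade")
    non_host = [l for l in leaves if not taxonomy.is_host(l)]
    if not non_host:
        return UNASSIGNED
    counts: dict = {}
    for leaf in non_host:
        counts[taxonomy.rank(leaf, rank)] = counts.get(taxonomy.rank(leaf, rank), 0) + 1
    total = len(non_host)
    best = max(counts, key=lambda g: (counts[g], g))
    if counts[best] / total > params.donor_majority:
        return best
    return UNASSIGNED


def classify_tree(
    tree: GeneTree,
    taxonomy: TaxonomyMap,
    params: Optional[LgtParams] = None,
) -> list:
    """Classify every host gene in a tree; returns one :class:`LgtCall` each.

    For each host leaf the clade criterion is checked over every bipartition
    side containing it; among qualifying sides the smallest is kept for donor
    inference (ties: higher support, then lexicographic leaf set).  Missing
    supports count as 0, so unlabelled edges never satisfy the clade
    criterion.  When no side qualifies, the whole-tree composition criterion
    is evaluated.
    """
    params = params or LgtParams()
    taxonomy.validate_leaves(tree.leaves)
    hosts = sorted(l for l in tree.leaves if taxonomy.is_host(l))
    if not hosts:
        raise ValueError("tree contains no host_query leaf")

    sides = _side_supports(tree)
    n_prok = sum(1 for l in tree.leaves if taxonomy.is_prok_or_virus(l))
    denom = (
        len(tree.leaves)
        if params.include_host_in_denominator
        else len(tree.leaves) - len(hosts)
    )
    composition_ok = denom > 0 and n_prok / denom >= params.composition_fraction
    any_supported = any(
        (s or 0) >= params.support_threshold for s in sides.values()
    )

    calls = []
    for host in hosts:
        qualifying = []
        for side, support in sides.items():
            if host not in side:
                continue
            eff = support if support is not None else 0
            if eff < params.support_threshold:
                continue
            if not any(taxonomy.is_prok_or_virus(l) for l in side):
                continue
            strays = sum(
                1
                for l in side
                if not taxonomy.is_host(l) and not taxonomy.is_prok_or_virus(l)
            )
            if strays > params.max_stray_eukaryotes:
                continue
            qualifying.append((side, eff))
        if qualifying:
            side, support = min(
                qualifying, key=lambda q: (len(q[0]), -q[1], tuple(sorted(q[0])))
            )
            calls.append(
                LgtCall(
                    gene_id=host,
                    is_lgt=True,
                    criterion="clade",
                    clade_leaves=side,
                    support=support,
                    donor=infer_donor(side, taxonomy, params.donor_rank, params),
                )
            )
            continue
        gate_open = (
            not any_supported
            if params.composition_gate == "no_supported_clade"
            else True
        )
        if gate_open and composition_ok:
            calls.append(
                LgtCall(
                    gene_id=host,
                    is_lgt=True,
                    criterion="composition",
                    clade_leaves=tree.leaves,
                    support=None,
                    donor=infer_donor(tree.leaves, taxonomy, params.donor_rank, params),
                )
            )
        else:
            calls.append(LgtCall(gene_id=host, is_lgt=False, criterion="none"))
    return calls


def classify_short_cluster(
    members: Orthogroup,
    taxonomy: TaxonomyMap,
    n_sites: int,
    params: Optional[LgtParams] = None,
) -> list:
    """Classify a short cluster (alignment below the tree-building cutoff).

    The cluster is an LGT when *every* non-host member is prokaryotic or
    viral.  Host-only clusters yield negative calls with a warning — there is
    nothing to compare against.
    """
    params = params or LgtParams()
    if n_sites >= params.min_sites_for_tree:
        raise ValueError(
            f"cluster has {n_sites} sites >= {params.min_sites_for_tree}; "
            "use classify_tree on its gene tree"
        )
    hosts = [m for m in members.members if taxonomy.is_host(m)]
    non_host = [m for m in members.members if not taxonomy.is_host(m)]
    if not hosts:
        raise ValueError(f"cluster {members.group_id} has no host member")
    if not non_host:
        warnings.warn(
            f"cluster {members.group_id} contains only host sequences; "
            "nothing to compare",
            stacklevel=2,
        )
        return [
            LgtCall(gene_id=h, is_lgt=False, criterion="none", orthogroup=members.group_id)
            for h in sorted(hosts)
        ]
    is_lgt = all(taxonomy.is_prok_or_virus(m) for m in non_host)
    donor = (
        infer_donor(members.members, taxonomy, params.donor_rank, params)
        if is_lgt
        else UNASSIGNED
    )
    return [
        LgtCall(
            gene_id=h,
            is_lgt=is_lgt,
            criterion="short_cluster" if is_lgt else "none",
            clade_leaves=frozenset(members.members) if is_lgt else None,
            donor=donor,
            orthogroup=members.group_id,
        )
        for h in sorted(hosts)
    ]


def calls_to_frame(calls: Iterable[LgtCall]) -> pd.DataFrame:
    """Flatten calls into the output table (one row per host gene)."""
    rows = []
    for c in calls:
        rows.append(
            {
                "gene_id": c.gene_id,
                "orthogroup": c.orthogroup or "",
                "is_lgt": int(c.is_lgt),
                "criterion": c.criterion,
                "support": "" if c.support is None else c.support,
                "clade_size": "" if c.clade_leaves is None else len(c.clade_leaves),
                "donor": c.donor,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "orthogroup",
            "is_lgt",
            "criterion",
            "support",
            "clade_size",
            "donor",
        ],
    )


def frame_to_calls(df: pd.DataFrame) -> list:
    calls = []
    for r in df.itertuples():
        calls.append(
            LgtCall(
                gene_id=str(r.gene_id),
                is_lgt=bool(int(r.is_lgt)),
                criterion=str(r.criterion),
                support=None if str(r.support) in ("", "nan") else int(float(r.support)),
                donor=str(r.donor),
                orthogroup=str(r.orthogroup) or None,
            )
        )
    return calls
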