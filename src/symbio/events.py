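"""Collapse gene-level LGT calls into acquisition events on the host tree.

Each orthogroup containing at least one LGT-positive gene is treated as one
acquisition event (gene duplications after acquisition inflate gene counts
but not event counts).  Events are placed on the fixed three-taxon host
phylogeny ((BUSSELTON2, SCHOONER1), BMAN) by Dollo-style parsimony: a single
acquisition on the stem of the smallest clade containing every species that
possesses the gene; differential loss is not modelled, so patterns spanning
the root map to the stem of the whole genus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional

import pandas as pd

from .lgt import UNASSIGNED, LgtCall
from .trees import Orthogroup

HOST_SPECIES = ("BUSSELTON2", "SCHOONER1", "BMAN")

BRANCHES = (
    "anaeramoeba_stem",
    "flamelloides_stem",
    "buss2_terminal",
    "sch1_terminal",
    "bman_terminal",
)

_TERMINAL = {
    "BUSSELTON2": "buss2_terminal",
    "SCHOONER1": "sch1_terminal",
    "BMAN": "bman_terminal",
}


class HostTree:
    """The fixed rooted host topology ((BUSSELTON2, SCHOONER1), BMAN).

    Exposes only branch assignment; the topology is immutable.
    """

    species = HOST_SPECIES
    branches = BRANCHES

    def mrca_branch(self, present: Iterable[str]) -> str:
        """Stem branch of the smallest clade containing all present species."""
        present = frozenset(present)
        unknown = present - set(HOST_SPECIES)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        if not present:
            raise ValueError("at least one species must be present")
        if len(present) == 1:
            return _TERMINAL[next(iter(present))]
        if present == {"BUSSELTON2", "SCHOONER1"}:
            return "flamelloides_stem"
        # any pattern including BMAN plus a flamelloides strain spans the root
        return "anaeramoeba_stem"


def map_event_to_branch(
    presence: Mapping[str, bool], host_tree: Optional[HostTree] = None
) -> str:
    """Dollo single-acquisition branch for a per-species presence pattern."""
    host_tree = host_tree or HostTree()
    present = [sp for sp in HOST_SPECIES if presence.get(sp)]
    return host_tree.mrca_branch(present)


@dataclass(frozen=True)
class LgtEvent:
    """One inferred acquisition (one orthogroup with LGT-positive genes)."""

    orthogroup: str
    genes_per_species: tuple  # ((species, n_genes), ...) over HOST_SPECIES
    branch: str
    donor: str = UNASSIGNED
    cog: Optional[str] = None

    @property
    def n_genes(self) -> int:
        return sum(n for _, n in self.genes_per_species)


def collapse_to_events(
    calls: Iterable[LgtCall],
    orthogroups: Mapping[str, Orthogroup],
    host_tree: Optional[HostTree] = None,
) -> list:
    """Group LGT-positive gene calls into per-orthogroup acquisition events.

    Every positive gene must belong to exactly one orthogroup.  The event
    donor is the plurality of assigned member-call donors (ties or no
    assignments -> unassigned); per-species gene counts are preserved so the
    events' gene totals sum to the number of LGT-positive genes.
    """
    host_tree = host_tree or HostTree()
    gene_to_group: Dict[str, str] = {}
    for gid, og in orthogroups.items():
        for m in og.members:
            if m in gene_to_group and gene_to_group[m] != gid:
                raise ValueError(
                    f"gene {m} belongs to orthogroups {gene_to_group[m]} and {gid}"
                )
            gene_to_group[m] = gid

    by_group: Dict[str, list] = {}
    for call in calls:
        if not call.is_lgt:
            continue
        gid = call.orthogroup or gene_to_group.get(call.gene_id)
        if gid is None:
            raise ValueError(f"LGT-positive gene {call.gene_id} not in any orthogroup")
        by_group.setdefault(gid, []).append(call)

    events = []
    for gid in sorted(by_group):
        group_calls = by_group[gid]
        og = orthogroups[gid]
        counts = Counter(og.species[c.gene_id] for c in group_calls)
        donors = Counter(c.donor for c in group_calls if c.donor != UNASSIGNED)
        if donors:
            top = donors.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                donor = UNASSIGNED
            else:
                donor = top[0][0]
        else:
            donor = UNASSIGNED
        presence = {sp: counts.get(sp, 0) > 0 for sp in HOST_SPECIES}
        events.append(
            LgtEvent(
                orthogroup=gid,
                genes_per_species=tuple((sp, counts.get(sp, 0)) for sp in HOST_SPECIES),
                branch=map_event_to_branch(presence, host_tree),
                donor=donor,
                cog=og.cog,
            )
        )
    return events


def tally(events: Iterable[LgtEvent], by: str) -> dict:
    """Count events by donor, branch, or COG functional category.

    The counts partition the event set; events lacking the attribute fall in
    an ``unassigned`` bin.
    """
    if by not in ("donor", "branch", "cog"):
        raise ValueError("by must be one of donor, branch, cog")
    out: Counter = Counter()
    for ev in events:
        value = getattr(ev, by)
        out[value if value else UNASSIGNED] += 1
    return dict(sorted(out.items()))


def events_to_frame(events: Iterable[LgtEvent]) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        counts = dict(ev.genes_per_species)
        rows.append(
            {
                "event_id": f"E{i + 1:05d}",
                "orthogroup": ev.orthogroup,
                "branch": ev.branch,
                "donor": ev.donor,
                "n_genes_BUSS2": counts.get("BUSSELTON2", 0),
                "n_genes_SCH1": counts.get("SCHOONER1", 0),
                "n_genes_BMAN": counts.get("BMAN", 0),
                "cog": ev.cog or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "orthogroup",
            "branch",
            "donor",
            "n_genes_BUSS2",
            "n_genes_SCH1",
            "n_genes_BMAN",
            "cog",
        ],
    )
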