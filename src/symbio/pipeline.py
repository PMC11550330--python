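"""End-to-end demo pipeline: simulate -> classify -> collapse -> map -> tally.

The pipeline drives the library stages from a single flat-key config, writes
per-stage TSV/JSON outputs, and finishes with a manifest recording the full
parameter set and a SHA-256 checksum of every output so reruns are provably
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import events as ev
from . import lgt, simulate, trees

STAGES = ("simulate", "classify", "collapse", "tally")


@dataclass
class RunConfig:
    """Flat-key pipeline configuration; every threshold defaults to the
    published value so deviations are always explicit in the manifest."""

    outdir: str = "symbio_run"
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    # simulation block
    n_orthogroups: int = 10
    n_prok: int = 10
    n_euk: int = 6
    lgt_fraction: float = 0.5
    planted_support: int = 95
    # classifier thresholds
    support_threshold: int = 70
    composition_fraction: float = 0.95
    donor_majority: float = 0.50
    max_stray_eukaryotes: int = 1
    min_sites_for_tree: int = 80
    donor_rank: str = "phylum"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.lgt_params()  # validate thresholds eagerly

    def lgt_params(self) -> lgt.LgtParams:
        return lgt.LgtParams(
            support_threshold=self.support_threshold,
            composition_fraction=self.composition_fraction,
            donor_majority=self.donor_majority,
            max_stray_eukaryotes=self.max_stray_eukaryotes,
            min_sites_for_tree=self.min_sites_for_tree,
            donor_rank=self.donor_rank,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    The simulate stage plants ``n_orthogroups`` three-species orthogroups
    (one gene tree per member gene); a fraction of orthogroups carries a
    nested-in-prokaryotes host gene in each member tree.  Downstream stages
    classify every tree, collapse positive calls to per-orthogroup events
    with a host-tree branch, and tally events by donor and branch.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": [], "outputs": {}}
    species = list(ev.HOST_SPECIES)

    trees_dir = out / "trees"
    taxonomy_path = out / "taxonomy.tsv"
    og_path = out / "orthogroups.tsv"
    calls_path = out / "calls.tsv"
    events_path = out / "events.tsv"
    tallies_path = out / "tallies.json"

    if "simulate" in config.stages:
        trees_dir.mkdir(exist_ok=True)
        entries: dict = {}
        og_rows: Dict[str, trees.Orthogroup] = {}
        n_lgt = int(round(config.lgt_fraction * config.n_orthogroups))
        for g in range(config.n_orthogroups):
            gid = f"OG{g + 1:04d}"
            scenario = "lgt_nested" if g < n_lgt else "vertical"
            members, sp_map = [], {}
            for s, sp in enumerate(species):
                gene = f"{sp}_g{g + 1:04d}"
                tree, taxonomy, _truth = simulate.simulate_gene_tree(
                    scenario,
                    n_prok=config.n_prok,
                    n_euk=config.n_euk,
                    planted_support=config.planted_support,
                    seed=config.seed * 1_000 + g * 10 + s,
                    host_name=gene,
                    host_source=sp,
                )
                trees.write_gene_tree(tree, trees_dir / f"{gene}.nwk")
                for sid, entry in taxonomy.items():
                    entries.setdefault(sid, entry)
                members.append(gene)
                sp_map[gene] = sp
            og_rows[gid] = trees.Orthogroup(
                group_id=gid, members=members, species=sp_map
            )
        trees.write_taxonomy(trees.TaxonomyMap(entries), taxonomy_path)
        trees.write_orthogroups(og_rows, og_path)
        manifest["stages"].append("simulate")

    if "classify" in config.stages:
        tree_files = sorted(trees_dir.glob("*.nwk"))
        if not tree_files:
            raise FileNotFoundError(
                f"no newick trees in {trees_dir} (produced by the simulate stage)"
            )
        taxonomy = trees.read_taxonomy(taxonomy_path)
        params = config.lgt_params()
        groups = trees.read_orthogroups(og_path)
        gene_to_og = {
            m: gid for gid, og in groups.items() for m in og.members
        }
        calls: list = []
        for tf in tree_files:
            tree = trees.read_gene_tree(tf)
            for call in lgt.classify_tree(tree, taxonomy, params):
                calls.append(
                    lgt.LgtCall(
                        gene_id=call.gene_id,
                        is_lgt=call.is_lgt,
                        criterion=call.criterion,
                        clade_leaves=call.clade_leaves,
                        support=call.support,
                        donor=call.donor,
                        orthogroup=gene_to_og.get(call.gene_id),
                    )
                )
        lgt.calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
        manifest["stages"].append("classify")

    if "collapse" in config.stages:
        if not calls_path.exists():
            raise FileNotFoundError(
                f"{calls_path} missing (produced by the classify stage)"
            )
        calls = lgt.frame_to_calls(pd.read_csv(calls_path, sep="\t"))
        groups = trees.read_orthogroups(og_path)
        event_list = ev.collapse_to_events(calls, groups)
        ev.events_to_frame(event_list).to_csv(events_path, sep="\t", index=False)
        manifest["stages"].append("collapse")
    else:
        event_list = None

    if "tally" in config.stages:
        if event_list is None:
            raise FileNotFoundError(
                "events unavailable (produced by the collapse stage)"
            )
        tallies = {
            "by_donor": ev.tally(event_list, "donor"),
            "by_branch": ev.tally(event_list, "branch"),
            "by_cog": ev.tally(event_list, "cog"),
            "n_events": len(event_list),
            "n_lgt_genes": sum(e.n_genes for e in event_list),
        }
        tallies_path.write_text(json.dumps(tallies, indent=2, sort_keys=True) + "\n")
        manifest["stages"].append("tally")

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
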