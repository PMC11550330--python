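"""Gene-family expansion/contraction scoring from per-species family counts.

The pipeline follows a median-based comparative procedure: families that are
taxon-specific, exclusive to one of the compared groups, or have a zero count
median in any group are excluded; within-group outliers (|population z-score|
above 1.5) are replaced by the group median; counts are normalised by their
family's median; and a family is flagged expanded or contracted when the
absolute log2 fold-change between group medians of normalised counts reaches
2.35 (a five-fold change, log2 5 ~ 2.32).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DynamicsParams:
    """Thresholds of the expansion/contraction screen (published defaults)."""

    z_threshold: float = 1.5
    log2fc_threshold: float = 2.35
    fold_equivalent: float = 5.0
    group_agg: str = "median"  # aggregation of normalised counts per group

    def __post_init__(self):
        if self.z_threshold <= 0 or self.log2fc_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.group_agg not in ("median", "mean"):
            raise ValueError("group_agg must be 'median' or 'mean'")


@dataclass
class FamilyCountMatrix:
    """Families x species protein counts with a species -> group assignment.

    ``exclusions`` maps excluded family IDs to a machine-readable reason;
    excluded families stay in ``counts`` (flagged, not deleted) but are
    ignored by downstream scoring.
    """

    counts: pd.DataFrame  # index: family IDs, columns: species, int counts
    groups: Dict[str, str]  # species -> group label
    exclusions: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"species without group assignment: {sorted(missing)}")

    @property
    def group_labels(self) -> Tuple[str, ...]:
        seen: list = []
        for sp in self.counts.columns:
            g = self.groups[sp]
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def species_of(self, group: str) -> list:
        return [sp for sp in self.counts.columns if self.groups[sp] == group]

    def included(self) -> pd.DataFrame:
        return self.counts.loc[~self.counts.index.isin(self.exclusions)]


def read_count_matrix(counts_path, groups_path) -> FamilyCountMatrix:
    """Read a families x species counts TSV and a (species, group) TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    gdf = pd.read_csv(groups_path, sep="\t", dtype=str)
    if not {"species", "group"}.issubset(gdf.columns):
        raise ValueError("groups table must have columns species, group")
    return FamilyCountMatrix(counts=counts, groups=dict(zip(gdf["species"], gdf["group"])))


def filter_families(
    matrix: FamilyCountMatrix,
    extra_exclusions: Optional[Dict[str, str]] = None,
) -> FamilyCountMatrix:
    """Flag families unusable for group comparison.

    Flags (without deleting) families that are taxon-specific (non-zero in a
    single species), exclusive to one compared group, or have a zero median
    count in any compared group.  ``extra_exclusions`` lets the caller flag
    additional families (e.g. lineages known to carry idiosyncratic
    expansions) with a stated reason.
    """
    labels = matrix.group_labels
    if len(labels) < 2:
        raise ValueError("need at least two groups to compare")
    exclusions = dict(matrix.exclusions)
    counts = matrix.counts
    present = counts > 0
    group_cols = {g: matrix.species_of(g) for g in labels}

    n_species_present = present.sum(axis=1)
    group_presence = pd.DataFrame(
        {g: present[cols].any(axis=1) for g, cols in group_cols.items()}
    )
    group_medians = pd.DataFrame(
        {g: counts[cols].median(axis=1) for g, cols in group_cols.items()}
    )
    for fam in counts.index:
        if fam in exclusions:
            continue
        if n_species_present[fam] <= 1:
            exclusions[fam] = "taxon_specific"
        elif group_presence.loc[fam].sum() <= 1:
            exclusions[fam] = "group_exclusive"
        elif (group_medians.loc[fam] == 0).any():
            exclusions[fam] = "zero_group_median"
    for fam, reason in (extra_exclusions or {}).items():
        exclusions.setdefault(fam, reason)
    return replace(matrix, exclusions=exclusions)


def _replace_once(values: np.ndarray, z_threshold: float) -> np.ndarray:
    sd = values.std()  # population standard deviation
    if sd == 0:
        return values
    z = (values - values.mean()) / sd
    mask = np.abs(z) > z_threshold
    if not mask.any():
        return values
    out = values.copy()
    out[mask] = np.median(values)
    return out


def replace_outliers(
    matrix: FamilyCountMatrix, params: Optional[DynamicsParams] = None
) -> FamilyCountMatrix:
    """Replace within-group outlier counts by their group median.

    A value is an outlier when its population z-score within the (family,
    group) vector exceeds the threshold in absolute value.  Replacement is
    iterated to a fixed point (replacing a gross outlier can expose a milder
    one), which makes the operation idempotent.  Constant vectors (zero
    standard deviation) and single-member groups are passed through, the
    latter with a warning.
    """
    params = params or DynamicsParams()
    counts = matrix.counts.astype(float).copy()
    for g in matrix.group_labels:
        cols = matrix.species_of(g)
        if len(cols) < 2:
            warnings.warn(
                f"group {g!r} has a single member; outlier replacement skipped",
                stacklevel=2,
            )
            continue
        block = counts[cols].to_numpy()
        for i in range(block.shape[0]):
            vec = block[i]
            for _ in range(100):
                new = _replace_once(vec, params.z_threshold)
                if np.array_equal(new, vec):
                    break
                vec = new
            block[i] = vec
        counts[cols] = block
    return replace(matrix, counts=counts)


def score_families(
    matrix: FamilyCountMatrix,
    params: Optional[DynamicsParams] = None,
    group_pairs: Optional[Iterable[Tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Per-family log2 fold-changes between groups, on filtered counts.

    Counts are first normalised by the family median across all included
    species; log2FC = log2(agg of normalised counts in A) - log2(agg in B)
    for each ordered group pair (agg = group median by default).  A family is
    flagged ``expanded`` (log2FC >= threshold) or ``contracted``
    (log2FC <= -threshold).

    Returns a DataFrame with columns family, group_a, group_b, log2fc, flag.
    """
    params = params or DynamicsParams()
    labels = matrix.group_labels
    if group_pairs is None:
        group_pairs = [
            (a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]
        ]
    counts = matrix.included().astype(float)
    fam_median = counts.median(axis=1)
    if (fam_median <= 0).any():
        bad = list(counts.index[fam_median <= 0])
        raise RuntimeError(
            f"zero family median reached scoring (filter should exclude): {bad}"
        )
    norm = counts.div(fam_median, axis=0)
    agg = np.median if params.group_agg == "median" else np.mean

    rows = []
    for a, b in group_pairs:
        cols_a, cols_b = matrix.species_of(a), matrix.species_of(b)
        agg_a = norm[cols_a].apply(agg, axis=1)
        agg_b = norm[cols_b].apply(agg, axis=1)
        for label, series in ((a, agg_a), (b, agg_b)):
            if (series <= 0).any():
                bad = list(series.index[series <= 0])
                raise RuntimeError(
                    f"zero {label!r} group aggregate reached scoring "
                    f"(filter should exclude): {bad}"
                )
        log2fc = np.log2(agg_a) - np.log2(agg_b)
        for fam in counts.index:
            fc = log2fc[fam]
            if fc >= params.log2fc_threshold:
                flag = "expanded"
            elif fc <= -params.log2fc_threshold:
                flag = "contracted"
            else:
                flag = "none"
            rows.append(
                {"family": fam, "group_a": a, "group_b": b, "log2fc": fc, "flag": flag}
            )
    return pd.DataFrame(rows, columns=["family", "group_a", "group_b", "log2fc", "flag"])


def core_accessory(matrix: FamilyCountMatrix) -> pd.Series:
    """Label each family core (present in every species) or accessory."""
    present = matrix.counts > 0
    all_zero = ~present.any(axis=1)
    if all_zero.any():
        warnings.warn(
            f"{int(all_zero.sum())} families have zero counts everywhere",
            stacklevel=2,
        )
    labels = np.where(present.all(axis=1), "core", "accessory")
    return pd.Series(labels, index=matrix.counts.index, name="core_accessory")
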