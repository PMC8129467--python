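"""Per-cell species richness (SR) and weighted endemism (WE).

SR is the number of species present in a cell. WE is the sum over species
present in the cell of 1/R_s, where R_s is the number of cells the species
occupies; a species confined to a single cell contributes a full unit to that
cell, a widespread species is diluted across its range. Summed over all
cells, each species contributes exactly R_s * (1/R_s) = 1, so the total WE of
a presence matrix equals its species count — a conservation identity used as
a built-in check.

Trait-group subsets (the alpine special-morphology syndromes: greenhouse
bracts, woolly indumentum, cushion habit, stemless rosettes) restrict the
presence matrix to the group *first* and recount R_s within the subset, so
group WE measures endemism of the group's own distribution.
"""

from __future__ import annotations

import pandas as pd

from .grids import GridSpec
from .occurrences import range_sizes

SMT_GROUPS = ("greenhouse", "woolly", "cushion", "stemless")
SMT_POOLED = "SMT-pooled"


def species_richness(P: pd.DataFrame) -> pd.Series:
    """SR per cell: row sums of the binary incidence."""
    if P.empty:
        raise ValueError("empty presence matrix")
    return P.sum(axis=1).astype(int).rename("SR")


def weighted_endemism(P: pd.DataFrame) -> pd.Series:
    """WE per cell: sum of reciprocal range sizes of the species present."""
    if P.empty:
        raise ValueError("empty presence matrix")
    R = range_sizes(P)
    if (R == 0).any():
        dead = R.index[R == 0].tolist()
        raise ValueError(f"species with zero occupied cells: {dead[:5]}")
    return (P / R).sum(axis=1).rename("WE")


def validate_trait_groups(groups: pd.DataFrame, species: pd.Index) -> pd.DataFrame:
    """Species -> membership table with one boolean column per SMT group.

    Accepts either boolean columns named after the groups, or a two-column
    (species, group) long table. Unknown species names are rejected.
    """
    if set(SMT_GROUPS) & set(groups.columns):
        g = groups.set_index("species") if "species" in groups.columns else groups.copy()
        for name in SMT_GROUPS:
            if name not in g.columns:
                g[name] = False
        g = g[list(SMT_GROUPS)].astype(bool)
    else:
        long = groups.rename(columns=str.lower)
        if not {"species", "group"} <= set(long.columns):
            raise ValueError("trait table needs boolean group columns or (species, group)")
        bad_groups = set(long["group"]) - set(SMT_GROUPS)
        if bad_groups:
            raise ValueError(f"unknown trait groups: {sorted(bad_groups)}")
        g = (
            long.assign(v=True)
            .pivot_table(index="species", columns="group", values="v",
                         fill_value=False, aggfunc="any")
            .reindex(columns=list(SMT_GROUPS), fill_value=False)
            .astype(bool)
        )
    unknown = g.index.difference(species)
    if len(unknown):
        raise ValueError(f"trait table names species absent from the data: {list(unknown[:5])}")
    return g


def subset_presence(P: pd.DataFrame, groups: pd.DataFrame, which: str) -> pd.DataFrame:
    """Presence matrix restricted to one trait group (or the pooled set)."""
    g = validate_trait_groups(groups, P.columns)
    if which == SMT_POOLED:
        members = g.index[g.any(axis=1)]
    elif which in SMT_GROUPS:
        members = g.index[g[which]]
    else:
        raise ValueError(f"unknown group {which!r}; expected one of {SMT_GROUPS + (SMT_POOLED,)}")
    if len(members) == 0:
        raise ValueError(f"trait group {which!r} is empty")
    sub = P[P.columns.intersection(members)]
    sub = sub.loc[sub.sum(axis=1) > 0]  # drop cells emptied by the restriction
    return sub


def subset_diversity(P: pd.DataFrame, groups: pd.DataFrame, which: str) -> pd.DataFrame:
    """SR and WE of one trait group, with R_s recounted within the subset."""
    sub = subset_presence(P, groups, which)
    return diversity_table(sub, group=which)


def diversity_table(P: pd.DataFrame, grid: GridSpec | None = None,
                    group: str = "all") -> pd.DataFrame:
    """Tidy per-cell table: cell_id [, lon_center, lat_center], group, SR, WE."""
    out = pd.DataFrame({
        "cell_id": P.index,
        "group": group,
        "SR": species_richness(P).to_numpy(),
        "WE": weighted_endemism(P).to_numpy(),
    })
    if grid is not None:
        lon, lat = grid.cell_center(out["cell_id"].to_numpy())
        out.insert(1, "lon_center", lon)
        out.insert(2, "lat_center", lat)
    return out
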