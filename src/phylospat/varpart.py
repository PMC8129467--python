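"""Three-set variance partitioning by partial regression.

The seven environmental predictors fall into three factor groups — geology
(Alt, Alt_SD), modern climate (MAT, MAP) and glacial-interglacial climate
stability (MAT_ano, MAP_ano, Vel). Fitting the seven OLS models formed by
every union of the groups and applying inclusion-exclusion to their R^2
values decomposes the explained variance into the fractions

    a, b, c   unique to geology / climate / stability
    d, e, f   shared pairwise (geology&climate, climate&stability,
              geology&stability)
    g         shared by all three
    residual  1 - R^2(all predictors)

Shared fractions are differences of R^2 values and can legitimately be
negative (suppression); they are reported as computed, because clipping
would break the exact identity a+b+c+d+e+f+g = R^2(all). Collinearity
*within* a group is harmless here — only whole-group R^2 values enter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VarpartResult", "partition_three", "DEFAULT_GROUPS"]

DEFAULT_GROUPS = {
    "geology": ["Alt", "Alt_SD"],
    "climate": ["MAT", "MAP"],
    "stability": ["MAT_ano", "MAP_ano", "Vel"],
}


@dataclass
class VarpartResult:
    fractions: pd.Series     # a..g + residual
    r2_models: pd.Series     # R^2 of the 7 fitted models, keys like "G", "GC"
    adjusted: bool
    group_names: tuple[str, str, str]

    def table(self) -> pd.DataFrame:
        g1, g2, g3 = self.group_names
        desc = {
            "a": f"{g1} unique", "b": f"{g2} unique", "c": f"{g3} unique",
            "d": f"{g1} & {g2} shared", "e": f"{g2} & {g3} shared",
            "f": f"{g1} & {g3} shared", "g": "three-way shared",
            "residual": "unexplained",
        }
        return pd.DataFrame({
            "fraction": self.fractions.index,
            "component": [desc[k] for k in self.fractions.index],
            "value": self.fractions.to_numpy(),
        })


def _r2(y: np.ndarray, X: np.ndarray, adjusted: bool) -> float:
    n = len(y)
    M = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    e = y - M @ beta
    yc = y - y.mean()
    r2 = 1.0 - (e @ e) / (yc @ yc)
    if adjusted:
        p = np.linalg.matrix_rank(M) - 1
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return float(r2)


def partition_three(y: pd.Series, X_geo: pd.DataFrame, X_clim: pd.DataFrame,
                    X_stab: pd.DataFrame, adjusted: bool = True,
                    group_names: tuple[str, str, str] = ("geology", "climate", "stability"),
                    ) -> VarpartResult:
    """Decompose R^2 of y over three predictor groups by inclusion-exclusion."""
    groups = [X_geo, X_clim, X_stab]
    for name, g in zip(group_names, groups):
        if g is None or g.shape[1] == 0:
            raise ValueError(f"predictor group {name!r} is empty")
    cols = [set(g.columns) for g in groups]
    for i in range(3):
        for j in range(i + 1, 3):
            overlap = cols[i] & cols[j]
            if overlap:
                raise ValueError(f"groups {group_names[i]!r} and {group_names[j]!r} "
                                 f"share predictors: {sorted(overlap)}")
    yv = np.asarray(y, dtype=float)
    G, C, S = (np.asarray(g, dtype=float) for g in groups)

    def r2(*mats):
        return _r2(yv, np.column_stack(mats), adjusted)

    R = pd.Series({
        "G": r2(G), "C": r2(C), "S": r2(S),
        "GC": r2(G, C), "GS": r2(G, S), "CS": r2(C, S),
        "GCS": r2(G, C, S),
    })
    a = R["GCS"] - R["CS"]
    b = R["GCS"] - R["GS"]
    c = R["GCS"] - R["GC"]
    g3 = R["G"] + R["C"] + R["S"] - R["GC"] - R["GS"] - R["CS"] + R["GCS"]
    d = R["GCS"] - R["S"] - a - b
    e = R["GCS"] - R["G"] - b - c
    f = R["GCS"] - R["C"] - a - c
    fractions = pd.Series(
        {"a": a, "b": b, "c": c, "d": d, "e": e, "f": f, "g": g3,
         "residual": 1.0 - R["GCS"]})
    return VarpartResult(fractions, R, adjusted, group_names)
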