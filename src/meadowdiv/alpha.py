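"""Per-unit alpha diversity: Margalef richness, Shannon-Wiener, Pielou
evenness, and Simpson (as 1 - dominance), stratified by trophic guild.

All logarithms are natural.  Conventions for degenerate communities:
a monoculture (S = 1) has MR = 0, H = 0, J = 0 and D = 0; J is defined
as 0 rather than 0/0 so guild tables stay dense.  Zero-count species
never enter the proportion sums (0 * ln 0 := 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import GUILD_CODES, CommunityMatrix, GuildTable, subset_by_guild


class EmptyCommunityError(ValueError):
    """Raised when an index is requested for an all-zero count vector."""


@dataclass(frozen=True)
class AlphaRecord:
    """Alpha indices for one sampling unit (optionally one guild).

    Attributes
    ----------
    S, N : int
        Species count and individual count.
    MR : float
        Margalef richness (S - 1) / ln N; 0 for S = 1 (and for N = 1 by
        the limit convention).
    H : float
        Shannon-Wiener index in nats.
    J : float
        Pielou evenness H / ln S in [0, 1]; 0 for monocultures.
    D : float
        Simpson diversity 1 - sum(p_i^2) in [0, 1).
    """

    unit_id: str
    guild: str | None
    S: int
    N: int
    MR: float
    H: float
    J: float
    D: float


def alpha_indices(counts, unit_id: str = "", guild: str | None = None) -> AlphaRecord:
    """Compute MR, H, J, D (plus S and N) from a count vector."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise EmptyCommunityError("cannot compute alpha indices for an empty community")
    n = float(c.sum())
    s = int(c.size)
    p = c / n
    h = float(-np.sum(p * np.log(p)))
    d = float(1.0 - np.sum(p**2))
    mr = 0.0 if s == 1 or n <= 1 else (s - 1) / np.log(n)
    j = 0.0 if s == 1 else h / np.log(s)
    return AlphaRecord(unit_id, guild, s, int(n), float(mr), h, float(j), d)


def alpha_table(cm: CommunityMatrix, gt: GuildTable | None = None, guilds=None) -> pd.DataFrame:
    """One row of alpha indices per (unit, guild) with >= 1 individual.

    Unit x guild cells with zero individuals are omitted (missing, not
    zero).  With ``gt`` None the whole community is summarised per unit
    under guild label ``"all"``.
    """
    strata: list[tuple[str, CommunityMatrix]] = []
    if gt is None:
        strata.append(("all", cm))
    else:
        gt.check_covers(cm.species_ids)
        for g in guilds or GUILD_CODES:
            strata.append((g, subset_by_guild(cm, gt, g)))
    records = []
    for g, sub in strata:
        for i, unit in enumerate(sub.unit_ids):
            row = sub.counts[i]
            if row.sum() == 0:
                continue
            rec = alpha_indices(row, unit_id=unit, guild=g)
            records.append(
                {
                    "unit": unit,
                    "guild": g,
                    "treatment": cm.metadata.loc[unit, "treatment"],
                    "S": rec.S,
                    "N": rec.N,
                    "MR": rec.MR,
                    "H": rec.H,
                    "J": rec.J,
                    "D": rec.D,
                }
            )
    return pd.DataFrame(
        records, columns=["unit", "guild", "treatment", "S", "N", "MR", "H", "J", "D"]
    )


def minmax_normalize(values) -> np.ndarray:
    """Scale a vector to [0, 1]; a constant vector maps to all 0.5."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty vector")
    if not np.isfinite(x).any():
        raise ValueError("need at least one finite value")
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)
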