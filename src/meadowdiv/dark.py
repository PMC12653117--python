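"""Beals-smoothing dark diversity, potential distribution probability (PDD),
and the Community Completeness Index (CCI).

Dark diversity is the set of species absent from a site yet belonging to
its site-specific species pool.  It is operationalised here through Beals
smoothing: the probability of finding species ``j`` at unit ``k`` is the
mean, over the other species ``i`` present at ``k``, of the conditional
co-occurrence frequency M_ij / n_i estimated from a reference incidence
matrix.  A species absent at a unit whose Beals probability exceeds a
per-species threshold (a low quantile of its probabilities at the units
where it IS present) is counted as dark there.

From the dark sets follow two summary statistics: per species
PDD = ND / NP (occurrences in dark diversity over occurrences in the
species pool = present-or-dark units), and per unit CCI = SR / (SR + PR)
(observed richness over observed-plus-dark richness; 1 means no
detectable recovery deficit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import (
    CommunityMatrix,
    ConsistencyError,
    GuildTable,
    IncidenceMatrix,
    aggregate_units,
    subset_by_guild,
    to_incidence,
)

DEFAULT_QUANTILE = 0.01


@dataclass
class BealsMatrix:
    """Per-unit, per-species Beals presence probabilities.

    The probability for species ``j`` at unit ``k`` never uses ``j``'s own
    presence at ``k`` (self-exclusion).
    """

    unit_ids: list[str]
    species_ids: list[str]
    p: np.ndarray
    reference: str = "self"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.unit_ids, columns=self.species_ids)


@dataclass
class DarkDiversityResult:
    """Dark sets, thresholds, PDD and CCI for one analysis stratum."""

    beals: BealsMatrix
    thresholds: pd.Series
    dark: pd.DataFrame  # bool, units x species
    pdd: pd.DataFrame  # species, ND, NP, PDD
    cci: pd.DataFrame  # unit, SR, PR, CCI
    q: float
    skipped_species: list[str] = field(default_factory=list)
    incidence: IncidenceMatrix | None = None

    @property
    def dark_sets(self) -> dict[str, set[str]]:
        return {
            u: set(self.dark.columns[self.dark.loc[u].to_numpy()]) for u in self.dark.index
        }


def beals_matrix(inc: IncidenceMatrix, reference: IncidenceMatrix | None = None) -> BealsMatrix:
    """Beals smoothing probabilities for every (unit, species) pair.

    P_kj = (1/S'_k) * sum over species i present at k, i != j, of
    M_ij / n_i, where M_ij counts reference units containing both i and j
    and n_i counts reference units containing i.  S'_k is the number of
    species present at k excluding j itself; P_kj = 0 when S'_k = 0.
    """
    ref = inc if reference is None else reference
    if ref.species_ids != inc.species_ids:
        raise ConsistencyError("reference and target matrices must share the species list")
    X = inc.presence.astype(float)
    R = ref.presence.astype(float)
    M = R.T @ R  # co-occurrence counts in the reference
    n = R.sum(axis=0)  # occurrence frequency per species in the reference
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(n[:, None] > 0, M / n[:, None], 0.0)  # row i: M_ij / n_i
    raw = X @ cond  # includes the i = j term for species present at k
    # self-exclusion: subtract M_jj / n_j = 1 where j itself is present at k
    self_term = X * np.where(n > 0, 1.0, 0.0)
    richness = X.sum(axis=1, keepdims=True)
    s_prime = richness - X  # species present at k excluding j
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(s_prime > 0, (raw - self_term) / np.maximum(s_prime, 1), 0.0)
    p = np.clip(p, 0.0, 1.0)  # guard round-off at the boundaries
    return BealsMatrix(
        list(inc.unit_ids), list(inc.species_ids), p, "self" if reference is None else "external"
    )


def species_thresholds(bm: BealsMatrix, inc: IncidenceMatrix, q: float = DEFAULT_QUANTILE):
    """Per-species dark-membership thresholds from presence units.

    threshold_j is the q-quantile (linear interpolation) of the Beals
    values of species j at the units where j is present; q = 0 gives the
    strict minimum.  Species with zero occurrences, or present in every
    unit (no absences to classify), get NaN and are reported as skipped.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if bm.species_ids != inc.species_ids or bm.unit_ids != inc.unit_ids:
        raise ConsistencyError("Beals matrix and incidence matrix must match")
    thresholds = np.full(len(bm.species_ids), np.nan)
    skipped = []
    occ = inc.occupancy
    for j, sp in enumerate(bm.species_ids):
        if occ[j] == 0 or occ[j] == inc.n_units:
            skipped.append(sp)
            continue
        vals = bm.p[inc.presence[:, j] == 1, j]
        thresholds[j] = np.quantile(vals, q)
    return pd.Series(thresholds, index=bm.species_ids, name="threshold"), skipped


def dark_sets(bm: BealsMatrix, inc: IncidenceMatrix, thresholds: pd.Series) -> pd.DataFrame:
    """Boolean units x species table: absent and strictly above threshold."""
    thr = thresholds.reindex(bm.species_ids).to_numpy()
    absent = inc.presence == 0
    with np.errstate(invalid="ignore"):
        above = bm.p > thr  # NaN threshold -> False
    return pd.DataFrame(absent & above, index=bm.unit_ids, columns=bm.species_ids)


def pdd(dark: pd.DataFrame, inc: IncidenceMatrix) -> pd.DataFrame:
    """Potential distribution probability PDD = ND / NP per species.

    ND is the number of units where the species is dark; NP the number of
    units where it is in the species pool (present or dark).  Species with
    NP = 0 are reported with NaN (not applicable).
    """
    nd = dark.to_numpy().sum(axis=0)
    np_pool = nd + inc.occupancy
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(np_pool > 0, nd / np.maximum(np_pool, 1), np.nan)
    return pd.DataFrame(
        {"species": dark.columns, "ND": nd, "NP": np_pool, "PDD": ratio}
    )


def cci(sr, pr):
    """Community Completeness Index SR / (SR + PR); NaN when SR + PR = 0."""
    sr = np.asarray(sr, dtype=float)
    pr = np.asarray(pr, dtype=float)
    if (sr < 0).any() or (pr < 0).any():
        raise ValueError("SR and PR must be non-negative")
    tot = sr + pr
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(tot > 0, sr / np.maximum(tot, 1e-300), np.nan)
    return out if out.ndim else float(out)


def dark_diversity(
    cm: CommunityMatrix,
    gt: GuildTable | None = None,
    guild: str | None = None,
    level: str = "plot",
    q: float = DEFAULT_QUANTILE,
    reference: IncidenceMatrix | None = None,
) -> DarkDiversityResult:
    """Run the full Beals dark-diversity workflow on one stratum.

    The matrix is optionally restricted to one guild, aggregated to the
    requested unit level (plot by default), binarised, and smoothed; dark
    sets, PDD and CCI follow.  ``reference`` optionally supplies an
    external co-occurrence pool at the same level and species list.
    """
    if guild is not None:
        if gt is None:
            raise ValueError("a GuildTable is required to stratify by guild")
        cm = subset_by_guild(cm, gt, guild)
    cm = aggregate_units(cm, level)
    inc = to_incidence(cm)
    bm = beals_matrix(inc, reference)
    thresholds, skipped = species_thresholds(bm, inc, q)
    dk = dark_sets(bm, inc, thresholds)
    pdd_tab = pdd(dk, inc)
    sr = inc.presence.sum(axis=1)
    pr = dk.to_numpy().sum(axis=1)
    cci_tab = pd.DataFrame(
        {
            "unit": cm.unit_ids,
            "treatment": cm.metadata["treatment"].to_numpy(),
            "SR": sr,
            "PR": pr,
            "CCI": cci(sr, pr),
        }
    )
    return DarkDiversityResult(bm, thresholds, dk, pdd_tab, cci_tab, q, skipped, inc)
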