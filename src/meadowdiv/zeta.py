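"""Multi-order zeta diversity: the expected number of species shared by
``i`` sites drawn at random from an assemblage.

The expectation has an exact closed form in terms of species occupancies:
for a species present in ``o`` of ``n`` units, the probability that all
``i`` sampled units contain it is C(o, i) / C(n, i), so

    zeta_i = sum_s C(occupancy_s, i) / C(n, i).

zeta_1 is mean per-unit richness; zeta_n counts species with full
occupancy; the sequence is nonincreasing in the order.  Consecutive
ratios zeta_{i+1}/zeta_i measure the retention probability of shared
species as one more site is added — near 1 means widespread-species
dominance, a fast fall means rare-species-driven turnover.

Per-order dispersion (sd across site combinations) is enumerated exactly
when the number of combinations is modest and sampled otherwise; the
expectation itself is always exact in ``exact`` mode.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .community import IncidenceMatrix

#: above this many combinations the per-order sd is estimated from a sample
ENUMERATION_CAP = 100_000
SD_SAMPLES = 10_000


@dataclass
class ZetaDecline:
    """Zeta decline curve for one stratum (treatment x guild)."""

    orders: np.ndarray
    zeta: np.ndarray
    sd: np.ndarray
    mode: str
    n_samples: int | None = None
    seed: int | None = None

    @property
    def ratios(self) -> np.ndarray:
        """zeta[i+1] / zeta[i]; NaN (missing) where the denominator is 0."""
        return zeta_ratios(self)


def zeta_exact(inc: IncidenceMatrix, order: int) -> float:
    """Closed-form expected shared-species count over all combinations of
    ``order`` units."""
    n = inc.n_units
    if not 1 <= order <= n:
        raise ValueError(f"order must be in [1, {n}], got {order}")
    denom = math.comb(n, order)
    total = sum(math.comb(int(o), order) for o in inc.occupancy)
    return total / denom


def _shared_counts(presence: np.ndarray, combos) -> np.ndarray:
    """Number of species present in every unit of each combination."""
    return np.array([presence[list(c)].all(axis=0).sum() for c in combos], dtype=float)


def zeta_decline(
    inc: IncidenceMatrix,
    max_order: int | None = None,
    mode: str = "exact",
    n_samples: int | None = None,
    seed: int | None = None,
    sd: bool = True,
) -> ZetaDecline:
    """Zeta decline curve over orders 1..max_order.

    ``exact`` mode uses the occupancy closed form for every expectation;
    the per-order sd is enumerated over all combinations when there are at
    most :data:`ENUMERATION_CAP`, otherwise estimated from
    :data:`SD_SAMPLES` sampled combinations.  ``monte_carlo`` mode
    estimates both from ``n_samples`` uniformly drawn combinations (units
    without replacement within a draw) and requires a seed.
    """
    n = inc.n_units
    if max_order is None:
        max_order = min(10, n)
    if not 1 <= max_order <= n:
        raise ValueError(f"max_order must be in [1, {n}], got {max_order}")
    if mode not in ("exact", "monte_carlo"):
        raise ValueError(f"mode must be 'exact' or 'monte_carlo', got {mode!r}")
    orders = np.arange(1, max_order + 1)
    zetas = np.empty(max_order)
    sds = np.full(max_order, np.nan)
    presence = inc.presence
    rng = None
    if mode == "monte_carlo" or (sd and any(math.comb(n, int(i)) > ENUMERATION_CAP for i in orders)):
        if seed is None:
            raise ValueError("a seed is required when combinations are sampled")
        rng = np.random.default_rng(seed)
    if mode == "monte_carlo" and (n_samples is None or n_samples < 1):
        raise ValueError("monte_carlo mode requires n_samples >= 1")

    for k, i in enumerate(orders):
        i = int(i)
        n_comb = math.comb(n, i)
        if mode == "exact":
            zetas[k] = zeta_exact(inc, i)
            if not sd:
                continue
            if n_comb <= ENUMERATION_CAP:
                shared = _shared_counts(presence, itertools.combinations(range(n), i))
            else:
                combos = [rng.choice(n, size=i, replace=False) for _ in range(SD_SAMPLES)]
                shared = _shared_counts(presence, combos)
            sds[k] = shared.std(ddof=1) if shared.size > 1 else 0.0
        else:
            combos = [rng.choice(n, size=i, replace=False) for _ in range(n_samples)]
            shared = _shared_counts(presence, combos)
            zetas[k] = shared.mean()
            sds[k] = shared.std(ddof=1) if shared.size > 1 else 0.0
    return ZetaDecline(orders, zetas, sds, mode, n_samples if mode == "monte_carlo" else None, seed)


def zeta_ratios(decline: ZetaDecline) -> np.ndarray:
    """Consecutive ratios zeta[i+1]/zeta[i], NaN where undefined (zeta[i]=0)."""
    z = decline.zeta
    out = np.full(len(z) - 1, np.nan)
    nz = z[:-1] > 0
    out[nz] = z[1:][nz] / z[:-1][nz]
    return out


def terminal_ratio(decline: ZetaDecline) -> float:
    """Last defined consecutive ratio of a decline curve (NaN if none)."""
    r = zeta_ratios(decline)
    defined = r[~np.isnan(r)]
    return float(defined[-1]) if defined.size else float("nan")


def _zeta_curve(presence: np.ndarray, orders: np.ndarray) -> np.ndarray:
    n = presence.shape[0]
    occ = presence.sum(axis=0)
    return np.array(
        [sum(math.comb(int(o), int(i)) for o in occ) / math.comb(n, int(i)) for i in orders]
    )


def zeta_permutation_test(
    incA: IncidenceMatrix,
    incB: IncidenceMatrix,
    max_order: int | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Permutation test for a difference in zeta decline between two strata.

    Units are pooled and randomly reassigned to the two strata (group
    sizes preserved).  The per-order statistic is |zeta_A(i) - zeta_B(i)|;
    the global statistic is the maximum over orders.  p-values use the
    add-one rule p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if incA.n_units < 2 or incB.n_units < 2:
        raise ValueError("each stratum needs at least 2 units")
    if incA.species_ids != incB.species_ids:
        raise ValueError("strata must share the same species list")
    nA, nB = incA.n_units, incB.n_units
    if max_order is None:
        max_order = min(10, nA, nB)
    if max_order > min(nA, nB):
        raise ValueError("max_order exceeds the smaller stratum size")
    orders = np.arange(1, max_order + 1)
    pooled = np.vstack([incA.presence, incB.presence])
    obs = np.abs(_zeta_curve(incA.presence, orders) - _zeta_curve(incB.presence, orders))
    obs_global = obs.max()
    rng = np.random.default_rng(seed)
    exceed = np.zeros(max_order)
    exceed_global = 0
    for _ in range(n_perm):
        perm = rng.permutation(nA + nB)
        d = np.abs(
            _zeta_curve(pooled[perm[:nA]], orders) - _zeta_curve(pooled[perm[nA:]], orders)
        )
        exceed += d >= obs
        exceed_global += d.max() >= obs_global
    return {
        "orders": orders,
        "observed": obs,
        "p_per_order": (1 + exceed) / (n_perm + 1),
        "p_global": (1 + exceed_global) / (n_perm + 1),
        "n_perm": n_perm,
    }
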