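"""Synthetic community generator emulating a nested grassland sampling design.

The generator produces site-by-species count matrices with the hierarchy
4 treatments x 3 plots x 4 transects (48 sampling units) over a pool of
88 species in four trophic guilds, with controllable assembly structure:

* each treatment has an occupancy profile — ``widespread_dominated``
  draws per-species unit-occupancy probabilities from a Beta skewed high
  (Beta(5, 2)), ``rare_dominated`` skewed low (Beta(1, 6)), ``mixed``
  balanced (Beta(2, 2));
* presence at each unit is an independent Bernoulli draw from that
  probability; abundance conditional on presence is zero-truncated
  negative binomial, so incidence structure and abundance are decoupled;
* with probability ``dark_withhold_rate``, an occurrence of a suitable
  species (occupancy probability >= 0.5, i.e. a species-pool member) is
  deleted after generation and recorded — these withheld occurrences are
  planted ground truth for the dark-diversity machinery.

Default profiles mimic a restoration gradient in which exclusion fencing
(FE) and no-till reseeding (FR) assemble widespread-dominated
communities while planted grass (GC) and grazed control (CK) are
rare-dominated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityMatrix, ConsistencyError, GuildTable, GUILD_CODES
from .dark import DarkDiversityResult

#: Beta(a, b) shapes for the per-species occupancy probability per profile
OCCUPANCY_PRESETS = {
    "widespread_dominated": (5.0, 2.0),
    "rare_dominated": (1.0, 6.0),
    "mixed": (2.0, 2.0),
}

#: latent suitability at/above this makes a species a pool member of the treatment
SUITABILITY_THRESHOLD = 0.5

DEFAULT_TREATMENTS = ("FE", "GC", "FR", "CK")
DEFAULT_PROFILES = {
    "FE": "widespread_dominated",
    "GC": "rare_dominated",
    "FR": "widespread_dominated",
    "CK": "rare_dominated",
}
DEFAULT_GUILD_FRACTIONS = {"Ph": 0.40, "Pr": 0.25, "Sa": 0.20, "Om": 0.15}


@dataclass
class SyntheticDesign:
    """Parameters of one simulated study.

    Defaults reproduce the emulated design: 4 treatments x 3 plots x
    4 transects, 88 species, guild mix 40/25/20/15 % (Ph/Pr/Sa/Om), mean
    abundance 6 individuals per occurrence with negative-binomial
    dispersion 0.8, and 10 % of suitable occurrences withheld as planted
    dark diversity.
    """

    n_treatments: int = 4
    plots_per_treatment: int = 3
    transects_per_plot: int = 4
    n_species: int = 88
    guild_fractions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GUILD_FRACTIONS))
    occupancy_profile: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    abundance_dispersion: float = 0.8
    mean_abundance: float = 6.0
    dark_withhold_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_treatments, self.plots_per_treatment, self.transects_per_plot) < 1:
            raise ValueError("design must have at least one treatment, plot and transect")
        if self.n_species < 1:
            raise ValueError("design must have at least one species")
        if abs(sum(self.guild_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("guild_fractions must sum to 1")
        if set(self.guild_fractions) - set(GUILD_CODES):
            raise ValueError(f"guild codes must be among {GUILD_CODES}")
        if not 0.0 <= self.dark_withhold_rate <= 1.0:
            raise ValueError("dark_withhold_rate must be in [0, 1]")
        if self.mean_abundance <= 0 or self.abundance_dispersion <= 0:
            raise ValueError("mean_abundance and abundance_dispersion must be positive")
        for t, prof in self.occupancy_profile.items():
            if prof not in OCCUPANCY_PRESETS:
                raise ValueError(f"unknown occupancy profile {prof!r} for treatment {t!r}")

    @property
    def treatments(self) -> list[str]:
        names = list(self.occupancy_profile)
        if len(names) != self.n_treatments:
            names = [f"T{i + 1}" for i in range(self.n_treatments)]
        return names

    def profile_of(self, treatment: str) -> str:
        return self.occupancy_profile.get(treatment, "mixed")

    @property
    def n_units(self) -> int:
        return self.n_treatments * self.plots_per_treatment * self.transects_per_plot


@dataclass
class SyntheticTruth:
    """Ground truth recorded during generation.

    ``withheld`` holds (unit_id, species_id) pairs whose occurrence was
    deleted after generation — the planted dark-diversity members.
    ``pools`` maps each treatment to its species pool (suitability >=
    0.5); ``occupancy_class`` labels each species widespread /
    intermediate / rare from its mean suitability across treatments.
    """

    occupancy_class: dict[str, str]
    withheld: set[tuple[str, str]]
    pools: dict[str, set[str]]
    suitability: pd.DataFrame  # treatments x species latent occupancy probability
    unit_treatment: dict[str, str]


def _allocate_guilds(design: SyntheticDesign, rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of species counts to guilds, then a
    seeded shuffle of which species index carries which guild."""
    fracs = [design.guild_fractions.get(g, 0.0) for g in GUILD_CODES]
    raw = [f * design.n_species for f in fracs]
    counts = [int(np.floor(r)) for r in raw]
    rema = np.argsort([c - r for c, r in zip(counts, raw)])  # most negative remainder first
    for i in range(design.n_species - sum(counts)):
        counts[rema[i % len(counts)]] += 1
    labels = [g for g, c in zip(GUILD_CODES, counts) for _ in range(c)]
    return [labels[i] for i in rng.permutation(design.n_species)]


def _truncated_nb(rng: np.random.Generator, size: int, mean: float, k: float) -> np.ndarray:
    """Zero-truncated negative binomial: NB(mean, size=k) resampled at zero."""
    p = k / (k + mean)
    out = rng.negative_binomial(k, p, size=size)
    for _ in range(1000):
        zero = out == 0
        if not zero.any():
            break
        out[zero] = rng.negative_binomial(k, p, size=int(zero.sum()))
    out[out == 0] = 1  # pathological tail guard; practically unreachable
    return out


def simulate_community(design: SyntheticDesign) -> tuple[CommunityMatrix, SyntheticTruth]:
    """Draw one community matrix and its ground truth, reproducibly.

    A single seed sequence drives the whole simulation; per-treatment
    sub-streams are spawned deterministically so each treatment block is
    independent of the others' parameter order.
    """
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(1 + design.n_treatments)
    global_rng = np.random.default_rng(children[0])
    guild_labels = _allocate_guilds(design, global_rng)
    width = max(2, len(str(design.n_species)))
    species = [f"sp{i + 1:0{width}d}" for i in range(design.n_species)]

    units: list[str] = []
    meta: list[dict[str, str]] = []
    counts_rows: list[np.ndarray] = []
    withheld: set[tuple[str, str]] = set()
    pools: dict[str, set[str]] = {}
    suitability = {}
    unit_treatment: dict[str, str] = {}

    for t_idx, treat in enumerate(design.treatments):
        rng = np.random.default_rng(children[1 + t_idx])
        a, b = OCCUPANCY_PRESETS[design.profile_of(treat)]
        suit = rng.beta(a, b, size=design.n_species)
        suitability[treat] = suit
        pools[treat] = {s for s, v in zip(species, suit) if v >= SUITABILITY_THRESHOLD}
        eligible = suit >= SUITABILITY_THRESHOLD
        for p_idx in range(design.plots_per_treatment):
            for x_idx in range(design.transects_per_plot):
                unit = f"{treat}-P{p_idx + 1}-T{x_idx + 1}"
                present = rng.random(design.n_species) < suit
                row = np.zeros(design.n_species, dtype=np.int64)
                n_pres = int(present.sum())
                if n_pres:
                    row[present] = _truncated_nb(
                        rng, n_pres, design.mean_abundance, design.abundance_dispersion
                    )
                if design.dark_withhold_rate > 0:
                    drop = present & eligible & (rng.random(design.n_species) < design.dark_withhold_rate)
                    for j in np.flatnonzero(drop):
                        row[j] = 0
                        withheld.add((unit, species[j]))
                units.append(unit)
                meta.append({"treatment": treat, "plot": f"P{p_idx + 1}", "transect": f"T{x_idx + 1}"})
                counts_rows.append(row)
                unit_treatment[unit] = treat

    cm = CommunityMatrix(units, species, np.vstack(counts_rows), pd.DataFrame(meta, index=units))
    suit_df = pd.DataFrame(suitability, index=species).T
    mean_suit = suit_df.mean(axis=0)
    occ_class = {
        s: ("widespread" if m >= 0.6 else "rare" if m <= 0.25 else "intermediate")
        for s, m in mean_suit.items()
    }
    truth = SyntheticTruth(occ_class, withheld, pools, suit_df, unit_treatment)
    return cm, GuildTable(dict(zip(species, guild_labels))), truth


def evaluate_dark_recovery(truth: SyntheticTruth, result: DarkDiversityResult) -> dict:
    """Score a dark-diversity result against planted withheld occurrences.

    Returns sensitivity (withheld pairs flagged as dark / withheld),
    precision (flagged-and-withheld / flagged among pool-eligible
    absences), and the flag rates on eligible vs never-suitable absences
    used as the chance baseline.  Requires a transect-level result so the
    units match the truth's.
    """
    if result.incidence is None:
        raise ConsistencyError("result carries no incidence matrix")
    inc = result.incidence
    missing = [u for u in inc.unit_ids if u not in truth.unit_treatment]
    if missing:
        raise ConsistencyError(f"result units unknown to the truth: {missing[:3]}")
    dark = result.dark
    species = list(dark.columns)
    sp_idx = {s: j for j, s in enumerate(species)}
    pres = inc.presence
    darr = dark.to_numpy()

    eligible = np.zeros_like(pres, dtype=bool)
    for i, u in enumerate(inc.unit_ids):
        pool = truth.pools[truth.unit_treatment[u]]
        for s in pool:
            if s in sp_idx:
                eligible[i, sp_idx[s]] = True
    absent = pres == 0
    elig_abs = absent & eligible
    inelig_abs = absent & ~eligible

    withheld_mask = np.zeros_like(pres, dtype=bool)
    u_idx = {u: i for i, u in enumerate(inc.unit_ids)}
    n_withheld = 0
    for u, s in truth.withheld:
        if u in u_idx and s in sp_idx:
            withheld_mask[u_idx[u], sp_idx[s]] = True
            n_withheld += 1

    hit = int((darr & withheld_mask).sum())
    flagged_elig = int((darr & elig_abs).sum())
    sensitivity = hit / n_withheld if n_withheld else float("nan")
    precision = hit / flagged_elig if flagged_elig else float("nan")
    rate_elig = flagged_elig / elig_abs.sum() if elig_abs.sum() else float("nan")
    rate_inelig = (
        int((darr & inelig_abs).sum()) / inelig_abs.sum() if inelig_abs.sum() else float("nan")
    )
    return {
        "n_withheld": n_withheld,
        "sensitivity": sensitivity,
        "precision": precision,
        "flag_rate_eligible_absences": float(rate_elig),
        "flag_rate_ineligible_absences": float(rate_inelig),
    }
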