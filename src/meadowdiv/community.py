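"""Site-by-species community matrices with sample metadata and guild annotations.

The data model mirrors a hierarchical sweep-net sampling design: sampling
units (transects) nested in plots nested in treatments.  A
:class:`CommunityMatrix` holds integer abundance counts; an
:class:`IncidenceMatrix` is its binary (presence/absence) reduction; a
:class:`GuildTable` maps each species to one of four trophic guilds
(phytophagous ``Ph``, predatory ``Pr``, saprophagous ``Sa``, omnivorous
``Om``).  Every downstream analysis consumes these three objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GUILD_CODES = ("Ph", "Pr", "Sa", "Om")
METADATA_COLUMNS = ("treatment", "plot", "transect")
AGGREGATION_LEVELS = ("transect", "plot", "treatment")


class FormatError(ValueError):
    """A delimited-text input violates the expected layout."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (matrix/metadata/guilds) do not."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = [x for x in labels if x in seen or seen.add(x)]  # type: ignore[func-returns-value]
    if dups:
        raise FormatError(f"duplicate {what} label(s): {sorted(set(dups))}")


@dataclass
class CommunityMatrix:
    """Sampling-unit x species abundance counts plus per-unit metadata.

    Parameters
    ----------
    unit_ids : list of str
        Sampling-unit labels (rows), unique.
    species_ids : list of str
        Species labels (columns), unique.
    counts : ndarray of int, shape (n_units, n_species)
        Non-negative integer abundances.
    metadata : DataFrame
        Indexed by unit label with columns ``treatment``, ``plot``,
        ``transect``; one row per unit.
    """

    unit_ids: list[str]
    species_ids: list[str]
    counts: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.unit_ids = [str(u) for u in self.unit_ids]
        self.species_ids = [str(s) for s in self.species_ids]
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.unit_ids), len(self.species_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.unit_ids)} units x {len(self.species_ids)} species"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise FormatError("counts must be integers; real-valued abundances are rejected")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise FormatError("negative counts are not allowed")
        self.counts = counts
        _check_unique(self.unit_ids, "unit")
        _check_unique(self.species_ids, "species")
        md = self.metadata
        if not isinstance(md, pd.DataFrame):
            raise ConsistencyError("metadata must be a DataFrame")
        missing_cols = [c for c in METADATA_COLUMNS if c not in md.columns]
        if missing_cols:
            raise ConsistencyError(f"metadata missing column(s): {missing_cols}")
        md = md.loc[:, list(METADATA_COLUMNS)].copy()
        md.index = md.index.astype(str)
        absent = [u for u in self.unit_ids if u not in md.index]
        if absent:
            raise ConsistencyError(f"unit(s) without metadata: {absent}")
        md = md.loc[self.unit_ids]
        md.index.name = None
        for col in METADATA_COLUMNS:
            md[col] = md[col].astype(str)
            if (md[col].str.len() == 0).any() or md[col].isin(["nan", "None"]).any():
                raise ConsistencyError(f"empty {col} label in metadata")
        self.metadata = md

    # -- convenience views -------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def treatments(self) -> list[str]:
        """Treatment labels in first-appearance order."""
        return list(dict.fromkeys(self.metadata["treatment"]))

    @property
    def empty_species(self) -> list[str]:
        """Species present in no unit (retained in the matrix, flagged here)."""
        mask = self.counts.sum(axis=0) == 0
        return [s for s, m in zip(self.species_ids, mask) if m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.unit_ids, columns=self.species_ids)

    def select_units(self, units: Iterable[str]) -> "CommunityMatrix":
        units = [str(u) for u in units]
        idx = {u: i for i, u in enumerate(self.unit_ids)}
        missing = [u for u in units if u not in idx]
        if missing:
            raise ConsistencyError(f"unknown unit(s): {missing}")
        rows = [idx[u] for u in units]
        return CommunityMatrix(units, list(self.species_ids), self.counts[rows], self.metadata.loc[units])


@dataclass
class IncidenceMatrix:
    """Binary presence/absence matrix derived from a :class:`CommunityMatrix`."""

    unit_ids: list[str]
    species_ids: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.presence)
        if p.shape != (len(self.unit_ids), len(self.species_ids)):
            raise FormatError("presence shape mismatch")
        if p.size and not np.isin(p, (0, 1)).all():
            raise FormatError("presence entries must be 0 or 1")
        self.presence = p.astype(np.int8)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def occupancy(self) -> np.ndarray:
        """Per-species count of units where the species is present."""
        return self.presence.sum(axis=0).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.unit_ids, columns=self.species_ids)


@dataclass
class GuildTable:
    """Species -> trophic guild mapping with optional taxonomy.

    ``guilds`` maps every species label to one of ``Ph``, ``Pr``, ``Sa``,
    ``Om``; ``taxonomy`` optionally carries order/family labels.
    """

    guilds: dict[str, str]
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.guilds = {str(k): str(v) for k, v in self.guilds.items()}
        bad = {g for g in self.guilds.values() if g not in GUILD_CODES}
        if bad:
            raise FormatError(f"unknown guild code(s): {sorted(bad)}; allowed: {GUILD_CODES}")

    def guild_of(self, species: str) -> str:
        try:
            return self.guilds[species]
        except KeyError:
            raise ConsistencyError(f"species {species!r} has no guild annotation") from None

    def members(self, guild: str) -> list[str]:
        if guild not in GUILD_CODES:
            raise ValueError(f"unknown guild code {guild!r}; allowed: {GUILD_CODES}")
        return [s for s, g in self.guilds.items() if g == guild]

    def check_covers(self, species_ids: Sequence[str]) -> None:
        missing = [s for s in species_ids if s not in self.guilds]
        if missing:
            raise ConsistencyError(f"species without guild annotation: {missing}")


# ---------------------------------------------------------------------------
# Readers / writers.  Delimited text, comma default, tab accepted; the first
# column holds unit labels, the header holds species labels.
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_community(matrix_path: str | Path, metadata_path: str | Path) -> CommunityMatrix:
    """Read a community matrix and its sample metadata from delimited text.

    The matrix file is wide format (units x species); the metadata file has
    columns ``unit,treatment,plot,transect`` and must key every unit label.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    sep = _sniff_sep(matrix_path)
    with open(matrix_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(header) != len(set(header)):  # pandas would silently mangle these
        raise FormatError(f"duplicate species column(s) in {matrix_path.name}")
    df = pd.read_csv(matrix_path, sep=sep, index_col=0, dtype=str)
    if df.index.duplicated().any():
        raise FormatError(f"duplicate unit row(s) in {matrix_path.name}")
    try:
        counts = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {matrix_path.name}: {exc}") from exc
    if np.isnan(counts).any():
        raise FormatError(f"missing count value in {matrix_path.name}")
    md = pd.read_csv(metadata_path, sep=_sniff_sep(metadata_path), dtype=str)
    if "unit" not in md.columns:
        raise FormatError(f"metadata {metadata_path.name} lacks a 'unit' column")
    md = md.set_index("unit")
    return CommunityMatrix(
        [str(u) for u in df.index], [str(s) for s in df.columns], counts, md
    )


def write_community(cm: CommunityMatrix, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Write matrix and metadata as CSV, inverse of :func:`read_community`."""
    cm.to_frame().rename_axis("unit").to_csv(matrix_path)
    cm.metadata.rename_axis("unit").to_csv(metadata_path)


def read_guilds(path: str | Path) -> GuildTable:
    """Read a species annotation table with columns ``species,guild[,order,family]``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    for col in ("species", "guild"):
        if col not in df.columns:
            raise FormatError(f"guild table {path.name} lacks a '{col}' column")
    if df["species"].duplicated().any():
        raise FormatError(f"duplicate species in guild table {path.name}")
    taxonomy = None
    extra = [c for c in ("order", "family") if c in df.columns]
    if extra:
        taxonomy = df.set_index("species")[extra]
    return GuildTable(dict(zip(df["species"], df["guild"])), taxonomy)


def write_guilds(gt: GuildTable, path: str | Path) -> None:
    df = pd.DataFrame({"species": list(gt.guilds), "guild": list(gt.guilds.values())})
    if gt.taxonomy is not None:
        df = df.join(gt.taxonomy, on="species")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------


def to_incidence(cm: CommunityMatrix) -> IncidenceMatrix:
    """Binary transformation: presence = (count > 0)."""
    return IncidenceMatrix(list(cm.unit_ids), list(cm.species_ids), (cm.counts > 0).astype(np.int8))


def subset_by_guild(cm: CommunityMatrix, gt: GuildTable, guild: str) -> CommunityMatrix:
    """Restrict the matrix to the species of one trophic guild.

    All sampling units are retained, even those whose row sum becomes zero:
    an empty guild sample is an observation, not missing data.
    """
    if guild not in GUILD_CODES:
        raise ValueError(f"unknown guild code {guild!r}; allowed: {GUILD_CODES}")
    gt.check_covers(cm.species_ids)
    cols = [i for i, s in enumerate(cm.species_ids) if gt.guilds[s] == guild]
    species = [cm.species_ids[i] for i in cols]
    counts = cm.counts[:, cols] if cols else np.zeros((cm.n_units, 0), dtype=np.int64)
    return CommunityMatrix(list(cm.unit_ids), species, counts, cm.metadata)


def _group_key(md: pd.Series, level: str) -> str:
    if level == "treatment":
        return str(md["treatment"])
    if level == "plot":
        return f"{md['treatment']}-{md['plot']}"
    return str(md.name)


def aggregate_units(cm: CommunityMatrix, level: str) -> CommunityMatrix:
    """Sum counts within transect/plot/treatment groups.

    ``transect`` is the identity (each row already is one transect).  Finer
    metadata levels collapsed by the aggregation are recorded as ``"all"``.
    """
    if level not in AGGREGATION_LEVELS:
        raise ValueError(f"unknown aggregation level {level!r}; allowed: {AGGREGATION_LEVELS}")
    if level == "transect":
        return CommunityMatrix(list(cm.unit_ids), list(cm.species_ids), cm.counts.copy(), cm.metadata)
    keys = [_group_key(cm.metadata.loc[u], level) for u in cm.unit_ids]
    order = list(dict.fromkeys(keys))
    counts = np.zeros((len(order), cm.n_species), dtype=np.int64)
    meta_rows = {}
    for u, k in zip(cm.unit_ids, keys):
        i = order.index(k)
        counts[i] += cm.counts[cm.unit_ids.index(u)]
        row = cm.metadata.loc[u]
        meta_rows[k] = {
            "treatment": row["treatment"],
            "plot": row["plot"] if level == "plot" else "all",
            "transect": "all",
        }
    md = pd.DataFrame([meta_rows[k] for k in order], index=order)
    return CommunityMatrix(order, list(cm.species_ids), counts, md)
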