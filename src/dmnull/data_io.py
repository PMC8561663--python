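"""Count-table I/O and host/species filtering.

The universal input of the package is a per-host species count table: one row
per individual host (here, an individual worm), one column per bacterial
species, integer CFU counts, plus a lineage label per host (e.g. ``"N2"`` or
``"daf-2"``).  Hosts with very low total colonization are removed before
analysis because plate counts at low CFU are unreliable; the threshold may
differ between host lineages.  Individual species may additionally be dropped
from a table (e.g. a near-absent species that would otherwise dominate an
ordination through rare-presence noise).

Host filtering is applied *before* species dropping: low-count hosts are
judged on the total CFU of the full community, and species removal is a
subsequent analysis step.  :func:`filter_low_count_hosts` therefore always
sees original totals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "LineageFilterPolicy",
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "filter_low_count_hosts",
    "drop_species",
]

logger = logging.getLogger(__name__)

HOST_COL = "host_id"
LINEAGE_COL = "lineage"


class CountTableError(ValueError):
    """Raised for malformed count tables (parse errors, bad labels)."""


@dataclass(frozen=True)
class CommunityMatrix:
    """Hosts x species integer count table with a lineage label per host.

    Parameters
    ----------
    host_ids : sequence of str
        Unique identifier per host (row).
    lineage : sequence of str
        Host-lineage label per row, aligned with ``host_ids``.
    species_names : sequence of str
        Unique species label per column.
    counts : (n_hosts, n_species) integer array
        Nonnegative CFU counts.
    """

    host_ids: tuple[str, ...]
    lineage: tuple[str, ...]
    species_names: tuple[str, ...]
    counts: np.ndarray

    def __init__(self, host_ids, lineage, species_names, counts):
        object.__setattr__(self, "host_ids", tuple(str(h) for h in host_ids))
        object.__setattr__(self, "lineage", tuple(str(g) for g in lineage))
        object.__setattr__(
            self, "species_names", tuple(str(s) for s in species_names)
        )
        arr = np.asarray(counts)
        if arr.ndim != 2:
            raise CountTableError("counts must be a 2-D hosts x species array")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise CountTableError("counts must be finite integers")
            arr = arr.astype(np.int64)
        arr = arr.astype(np.int64, copy=True)
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        self._validate()

    def _validate(self) -> None:
        n, k = self.counts.shape
        if len(self.host_ids) != n:
            raise CountTableError(
                f"{len(self.host_ids)} host ids for {n} count rows"
            )
        if len(self.lineage) != n:
            raise CountTableError(
                f"{len(self.lineage)} lineage labels for {n} count rows"
            )
        if len(self.species_names) != k:
            raise CountTableError(
                f"{len(self.species_names)} species names for {k} count columns"
            )
        if len(set(self.host_ids)) != n:
            raise CountTableError("duplicate host ids")
        if len(set(self.species_names)) != k:
            raise CountTableError("duplicate species names")
        if self.counts.size and self.counts.min() < 0:
            i, j = np.argwhere(self.counts < 0)[0]
            raise CountTableError(
                f"negative count at host {self.host_ids[i]!r}, "
                f"species {self.species_names[j]!r}"
            )

    @property
    def n_hosts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Total CFU per host (row sums)."""
        return self.counts.sum(axis=1)

    def lineages(self) -> tuple[str, ...]:
        """Distinct lineage labels in first-appearance order."""
        return tuple(dict.fromkeys(self.lineage))

    def select_hosts(self, mask: np.ndarray) -> "CommunityMatrix":
        mask = np.asarray(mask, dtype=bool)
        return CommunityMatrix(
            [h for h, m in zip(self.host_ids, mask) if m],
            [g for g, m in zip(self.lineage, mask) if m],
            self.species_names,
            self.counts[mask],
        )

    def subset_lineage(self, lineage: str) -> "CommunityMatrix":
        """Rows belonging to one host lineage."""
        mask = np.array([g == lineage for g in self.lineage])
        if not mask.any():
            raise CountTableError(f"no hosts with lineage {lineage!r}")
        return self.select_hosts(mask)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: host_id, lineage, then one column per species."""
        df = pd.DataFrame(self.counts, columns=list(self.species_names))
        df.insert(0, LINEAGE_COL, list(self.lineage))
        df.insert(0, HOST_COL, list(self.host_ids))
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        host_col: str = HOST_COL,
        lineage_col: str = LINEAGE_COL,
    ) -> "CommunityMatrix":
        if df.empty and df.columns.empty:
            raise CountTableError("empty table")
        for col in (host_col, lineage_col):
            if col not in df.columns:
                raise CountTableError(f"missing required column {col!r}")
        species = [c for c in df.columns if c not in (host_col, lineage_col)]
        if not species:
            raise CountTableError("no species columns found")
        counts = np.empty((len(df), len(species)), dtype=np.int64)
        for j, sp in enumerate(species):
            col = pd.to_numeric(df[sp], errors="coerce")
            bad = col.isna() | (col != np.floor(col.fillna(0))) | (col < 0)
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise CountTableError(
                    f"non-integer, negative or missing count at row "
                    f"{df.index[i]}, column {sp!r}: {df[sp].iloc[i]!r}"
                )
            counts[:, j] = col.astype(np.int64)
        return cls(
            df[host_col].astype(str).tolist(),
            df[lineage_col].astype(str).tolist(),
            species,
            counts,
        )


@dataclass(frozen=True)
class LineageFilterPolicy:
    """Per-lineage minimum-total thresholds and species-removal lists.

    ``min_total_by_lineage`` maps a lineage label to its minimum total CFU
    per host; lineages not listed fall back to ``default_min_total``.  The
    defaults encode the filtering convention of the source experiments:
    hosts of the immuno-derepressed *daf-2* lineage (small communities) are
    kept at >=100 CFU, all other lineages at >=1,000 CFU.
    """

    min_total_by_lineage: Mapping[str, int] = field(
        default_factory=lambda: {"daf-2": 100}
    )
    default_min_total: int | None = 1000
    species_to_drop_by_lineage: Mapping[str, tuple[str, ...]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        for lin, t in self.min_total_by_lineage.items():
            if t < 0:
                raise ValueError(f"negative threshold for lineage {lin!r}")
        if self.default_min_total is not None and self.default_min_total < 0:
            raise ValueError("negative default threshold")

    def threshold(self, lineage: str) -> int:
        if lineage in self.min_total_by_lineage:
            return int(self.min_total_by_lineage[lineage])
        if self.default_min_total is None:
            raise KeyError(
                f"no threshold for lineage {lineage!r} and no default set"
            )
        return int(self.default_min_total)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv", "xlsx"):
        return suffix
    raise CountTableError(f"cannot infer format from {path.name!r}")


def read_count_table(
    path,
    fmt: str | None = None,
    host_col: str = HOST_COL,
    lineage_col: str = LINEAGE_COL,
    sheet: str | int = 0,
) -> CommunityMatrix:
    """Read a count table from CSV, TSV or XLSX.

    The header row must give species names; one column gives the host id and
    one the lineage label.  XLSX reading targets the first sheet unless
    ``sheet`` names another; column-name matching is case-sensitive.

    Raises
    ------
    CountTableError
        On missing file, malformed header, or negative/NaN/non-integer
        counts (the error names the offending row and column).
    """
    path = Path(path)
    if not path.exists():
        raise CountTableError(f"no such file: {path}")
    fmt = _infer_format(path, fmt)
    try:
        if fmt == "csv":
            df = pd.read_csv(path)
        elif fmt == "tsv":
            df = pd.read_csv(path, sep="\t")
        elif fmt == "xlsx":
            df = pd.read_excel(path, sheet_name=sheet)
        else:
            raise CountTableError(f"unknown format {fmt!r}")
    except pd.errors.EmptyDataError as exc:
        raise CountTableError(f"empty file: {path}") from exc
    return CommunityMatrix.from_frame(df, host_col=host_col, lineage_col=lineage_col)


def write_count_table(m: CommunityMatrix, path, fmt: str | None = None) -> None:
    """Write a count table; inverse of :func:`read_count_table`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    df = m.to_frame()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise CountTableError(f"unknown format {fmt!r}")


def filter_low_count_hosts(
    m: CommunityMatrix, policy: LineageFilterPolicy | None = None
) -> CommunityMatrix:
    """Remove hosts whose total CFU falls below their lineage threshold.

    Row order is preserved; the number of hosts removed per lineage is
    logged.  An empty result is permitted (with a warning).
    """
    if policy is None:
        policy = LineageFilterPolicy()
    totals = m.totals
    keep = np.array(
        [t >= policy.threshold(g) for t, g in zip(totals, m.lineage)]
    )
    removed: dict[str, int] = {}
    for g, k in zip(m.lineage, keep):
        if not k:
            removed[g] = removed.get(g, 0) + 1
    for g, cnt in removed.items():
        logger.info("filter_low_count_hosts: removed %d host(s) of lineage %s", cnt, g)
    if not keep.any():
        warnings.warn("all hosts removed by low-count filter", stacklevel=2)
    return m.select_hosts(keep)


def drop_species(m: CommunityMatrix, species: Iterable[str]) -> CommunityMatrix:
    """Remove species columns; totals are recomputed from the remainder."""
    species = list(species)
    unknown = [s for s in species if s not in m.species_names]
    if unknown:
        raise CountTableError(f"species not in table: {unknown}")
    if not species:
        return m
    keep = [j for j, s in enumerate(m.species_names) if s not in species]
    return CommunityMatrix(
        m.host_ids,
        m.lineage,
        [m.species_names[j] for j in keep],
        m.counts[:, keep],
    )


def apply_filter_policy(
    m: CommunityMatrix, policy: LineageFilterPolicy
) -> CommunityMatrix:
    """Host filtering first, then species removal for a single-lineage table.

    Species-removal lists are per-lineage; applying them to a multi-lineage
    table would produce ragged columns, so this helper requires that any
    listed lineage be the only one present.
    """
    m = filter_low_count_hosts(m, policy)
    to_drop: set[str] = set()
    for lin in m.lineages():
        to_drop.update(policy.species_to_drop_by_lineage.get(lin, ()))
    if to_drop and len(m.lineages()) > 1:
        raise CountTableError(
            "per-lineage species removal on a multi-lineage table would "
            "produce ragged columns; subset lineages first"
        )
    return drop_species(m, sorted(to_drop)) if to_drop else m
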