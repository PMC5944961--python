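"""Abundance tables and Preston octave binning.

A community layer is a list of per-species integer abundances.  Before any
model is fitted the abundances are grouped into log2 abundance classes
("octaves").  Two binning dialects are provided:

``halfopen``
    Octave ``R >= 1`` holds species with abundance ``r`` in the half-open
    interval ``(2**(R-1), 2**R]``, so octave 1 holds {1, 2}, octave 2 holds
    {3, 4}, octave 3 holds {5..8} and so on.  Counts are integers and the
    whole community is retained.

``preston_halving``
    Class boundaries sit at the powers of two.  A species with abundance
    strictly between ``2**R`` and ``2**(R+1)`` is counted in octave ``R``
    (classes are indexed at their lower boundary); a species whose abundance
    is exactly a boundary ``2**R`` contributes one half to octave ``R - 1``
    and one half to octave ``R``.  The half of the singletons that falls
    below the smallest boundary lies below the sampling veil; it is dropped
    from the histogram and reported, never redistributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceRecord",
    "LayerDataset",
    "OctaveHistogram",
    "DIALECTS",
    "read_abundance_table",
    "descriptive_stats",
    "bin_octaves",
    "modal_octave",
]

DIALECTS = ("halfopen", "preston_halving")

#: default column names expected in long-format input tables (case-insensitive)
DEFAULT_COLUMNS = {
    "community": "community",
    "layer": "layer",
    "species": "species",
    "abundance": "abundance",
}


class FormatError(ValueError):
    """Input table does not have the expected columns or file type."""


class ValidationError(ValueError):
    """A data value violates an invariant (e.g. non-positive abundance)."""


@dataclass(frozen=True)
class AbundanceRecord:
    """One species with its abundance (number of individuals), ``r >= 1``."""

    species_id: str
    abundance: int

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValidationError("species_id must be non-empty")
        if not float(self.abundance).is_integer() or self.abundance < 1:
            raise ValidationError(
                f"abundance must be a positive integer, got {self.abundance!r} "
                f"for species {self.species_id!r}"
            )


@dataclass
class LayerDataset:
    """Per-species abundances of one community layer (the unit of analysis)."""

    community: str
    layer: str
    records: list[AbundanceRecord]
    area_m2: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValidationError("LayerDataset needs at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.species_id in seen:
                raise ValidationError(f"duplicate species_id {rec.species_id!r}")
            seen.add(rec.species_id)

    @property
    def S(self) -> int:
        """Observed species richness."""
        return len(self.records)

    @property
    def N(self) -> int:
        """Total number of individuals."""
        return int(sum(rec.abundance for rec in self.records))

    @property
    def abundances(self) -> np.ndarray:
        return np.array([rec.abundance for rec in self.records], dtype=int)

    @property
    def label(self) -> str:
        return f"{self.layer}, {self.community}"


@dataclass
class OctaveHistogram:
    """Species counts per octave, ``S_obs(R)``, for one layer dataset.

    ``counts`` may hold half-integers under the ``preston_halving`` dialect.
    Interior zero-count octaves are retained: they are observations of zero
    species in an abundance class, and the octave axis must stay contiguous
    for the regression.
    """

    octaves: np.ndarray
    counts: np.ndarray
    dialect: str
    below_veil: float = 0.0
    source_label: str = ""

    def __post_init__(self) -> None:
        self.octaves = np.asarray(self.octaves, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.octaves.size == 0:
            raise ValidationError("histogram must have at least one octave")
        if self.octaves.size != self.counts.size:
            raise ValidationError("octaves and counts must have equal length")
        if np.any(np.diff(self.octaves) != 1):
            raise ValidationError("octaves must be contiguous integers")
        if np.any(self.counts < 0):
            raise ValidationError("species counts must be non-negative")

    @property
    def n(self) -> int:
        """Number of octaves spanning [R_min, R_max], zeros included."""
        return int(self.octaves.size)

    @property
    def N_oct(self) -> float:
        """Total individuals after octave transformation, sum of 2^R * S_obs(R)."""
        return float(np.sum(np.exp2(self.octaves) * self.counts))

    @property
    def R_max(self) -> int:
        """Largest octave with a positive species count."""
        return int(self.octaves[self.counts > 0].max())

    @property
    def total_species(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"octave": self.octaves, "species_count": self.counts})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _normalise_columns(
    df: pd.DataFrame, columns: Mapping[str, str] | None
) -> pd.DataFrame:
    mapping = dict(DEFAULT_COLUMNS)
    if columns:
        mapping.update(columns)
    lower = {str(c).strip().lower(): c for c in df.columns}
    resolved = {}
    for role, name in mapping.items():
        key = name.strip().lower()
        if key not in lower:
            raise FormatError(
                f"missing column {name!r} (for {role}); found {list(df.columns)}"
            )
        resolved[lower[key]] = role
    return df.rename(columns=resolved)[list(mapping)]


def read_abundance_table(
    path: str | Path,
    format: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> list[LayerDataset]:
    """Read a long-format abundance table into one dataset per (community, layer).

    Parameters
    ----------
    path
        CSV/TSV file or spreadsheet with columns community, layer, species,
        abundance (configurable through ``columns``, case-insensitive).
    format
        One of ``csv``, ``tsv``, ``xls``/``xlsx``; inferred from the file
        suffix when omitted.  Spreadsheets are read sheet by sheet and the
        sheets concatenated.
    columns
        Optional role-to-header mapping overriding the default names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("csv", "tsv", "txt"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, comment="#")
    elif fmt in ("xls", "xlsx"):
        sheets = pd.read_excel(path, sheet_name=None)
        df = pd.concat(sheets.values(), ignore_index=True)
    else:
        raise FormatError(f"unsupported format {fmt!r}")
    df = _normalise_columns(df, columns)

    datasets: list[LayerDataset] = []
    for (community, layer), group in df.groupby(["community", "layer"], sort=True):
        records = []
        for row in group.itertuples(index=True):
            r = row.abundance
            if pd.isna(r) or float(r) != int(float(r)) or int(float(r)) < 1:
                raise ValidationError(
                    f"row {row.Index}: abundance must be a positive integer, "
                    f"got {r!r} (community={community!r}, layer={layer!r}, "
                    f"species={row.species!r})"
                )
            records.append(AbundanceRecord(str(row.species), int(float(r))))
        datasets.append(LayerDataset(str(community), str(layer), records))
    return datasets


def descriptive_stats(ds: LayerDataset) -> dict:
    """Richness, total abundance and abundance range of one layer."""
    r = ds.abundances
    return {
        "community": ds.community,
        "layer": ds.layer,
        "S": ds.S,
        "N": ds.N,
        "min_abundance": int(r.min()),
        "max_abundance": int(r.max()),
    }


def _halfopen_octave(r: int) -> int:
    # octave R >= 1 holds r in (2**(R-1), 2**R]; (r-1).bit_length() realises
    # ceil(log2(r)) for integer r, floored at 1 so that {1, 2} share octave 1
    return max(1, int(r - 1).bit_length())


def bin_octaves(ds: LayerDataset, dialect: str = "halfopen") -> OctaveHistogram:
    """Group a layer's abundances into Preston octaves.

    Species totals are conserved: the histogram counts plus the reported
    below-veil mass (``preston_halving`` only) always sum to ``S``.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    abundances = ds.abundances
    contrib: dict[int, float] = {}
    below_veil = 0.0
    if dialect == "halfopen":
        for r in abundances:
            R = _halfopen_octave(int(r))
            contrib[R] = contrib.get(R, 0.0) + 1.0
    else:
        for r in map(int, abundances):
            if r & (r - 1) == 0:  # exact power of two: split across the boundary
                R = r.bit_length() - 1
                if R == 0:
                    below_veil += 0.5
                else:
                    contrib[R - 1] = contrib.get(R - 1, 0.0) + 0.5
                contrib[R] = contrib.get(R, 0.0) + 0.5
            else:
                R = r.bit_length() - 1  # floor(log2 r), strictly inside the class
                contrib[R] = contrib.get(R, 0.0) + 1.0
    R_min, R_max = min(contrib), max(contrib)
    octaves = np.arange(R_min, R_max + 1)
    counts = np.array([contrib.get(int(R), 0.0) for R in octaves])
    return OctaveHistogram(
        octaves, counts, dialect, below_veil=below_veil, source_label=ds.label
    )


def modal_octave(h: OctaveHistogram) -> int:
    """Octave with the maximal species count; ties go to the smaller octave."""
    return int(h.octaves[int(np.argmax(h.counts))])
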