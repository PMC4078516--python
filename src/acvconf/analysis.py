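"""Table-level conformer analytics.

Operates on tables of conformer (or tautomer) records carrying the eight
chain-placement descriptors plus relative energies: A/B and syn/anti
classification from the sign of phi1, circular torsion-range binning,
energy-band statistics and Boltzmann populations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ConformerRecord",
    "ConformerTable",
    "PopulationConfig",
    "TorsionBin",
    "BinReport",
    "BandStats",
    "SchemaError",
    "UnclassifiableError",
    "read_conformer_table",
    "classify_conformer",
    "bin_torsions",
    "boltzmann_populations",
    "energy_band_stats",
]

#: kcal/(mol K); the per-mole reading of kT in the Boltzmann weight.
GAS_CONSTANT_KCAL = 1.98720425e-3

REQUIRED_COLUMNS = ("name", "R", "beta", "Phi",
                    "phi1", "phi2", "phi3", "phi4", "phi5", "dE")
NUMERIC_COLUMNS = ("R", "beta", "Phi", "phi1", "phi2", "phi3", "phi4",
                   "phi5", "mu", "dE", "dG")

# characters normalized away when parsing transcribed tables
_CHAR_FIXES = str.maketrans({
    "−": "-",   # unicode minus
    "–": "-",   # en dash
    " ": "",    # thin space
    " ": "",    # nbsp
    "*": "",
    "_": "",
})


class SchemaError(ValueError):
    """Raised when a conformer table lacks mandatory columns or rows."""


class UnclassifiableError(ValueError):
    """Raised when phi1 is exactly zero and no class can be assigned."""


@dataclass
class ConformerRecord:
    """One table row: identity, descriptors, and input energies."""

    name: str
    phi1: float
    phi2: float
    phi3: float
    phi4: float
    phi5: float
    R: float = math.nan
    beta: float = math.nan
    Phi: float = math.nan
    mu: float = math.nan
    dE: float = math.nan
    dG: float = math.nan
    level: str = ""

    def energy(self, column: str) -> float:
        if column not in ("dE", "dG"):
            raise ValueError(f"unknown energy column {column!r}")
        return getattr(self, column)


class ConformerTable:
    """A collection of ConformerRecords backed by a DataFrame."""

    def __init__(self, frame: pd.DataFrame, provenance: str = "") -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        self.frame = frame.reset_index(drop=True)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> list[ConformerRecord]:
        fields = set(ConformerRecord.__dataclass_fields__)
        out = []
        for _, row in self.frame.iterrows():
            data = {k: row[k] for k in self.frame.columns if k in fields}
            if "level" in data and not isinstance(data["level"], str):
                data["level"] = ""
            out.append(ConformerRecord(**data))
        return out

    def require_nonempty(self) -> None:
        if len(self.frame) == 0:
            raise SchemaError("operation requires a non-empty table")

    @classmethod
    def from_records(cls, records: Sequence[ConformerRecord],
                     provenance: str = "") -> "ConformerTable":
        rows = [vars(r) for r in records]
        frame = pd.DataFrame(rows) if rows else pd.DataFrame(
            columns=list(REQUIRED_COLUMNS) + ["mu", "dG", "level"])
        return cls(frame, provenance=provenance)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _clean_cell(value: str) -> str:
    return value.translate(_CHAR_FIXES).strip().strip('"').strip("'")


def read_conformer_table(path: str | Path, level: str | None = None,
                         sep: str | None = None) -> ConformerTable:
    """Read a delimited conformer/tautomer table (UTF-8, comma or tab).

    Unicode minus signs, thin spaces and stray transcription markup are
    normalized before numeric parsing.  If ``level`` is given and the table
    has a ``level`` column, rows of other levels are dropped with a logged
    warning.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise SchemaError(f"{path}: empty table")
    if sep is None:
        header = text.splitlines()[0]
        sep = "\t" if "\t" in header else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    frame.columns = [c.strip() for c in frame.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns: {missing}")
    for col in frame.columns:
        frame[col] = frame[col].map(
            lambda v: _clean_cell(v) if isinstance(v, str) else v)
    for col in NUMERIC_COLUMNS:
        if col not in frame.columns:
            continue
        try:
            frame[col] = pd.to_numeric(frame[col].replace("", np.nan))
        except (ValueError, TypeError):
            for i, v in enumerate(frame[col]):
                try:
                    if isinstance(v, str) and v != "":
                        float(v)
                except ValueError:
                    raise SchemaError(
                        f"{path}: line {i + 2}: unparseable numeric "
                        f"{v!r} in column {col!r}") from None
            raise
    if level is not None and "level" in frame.columns:
        skipped = int((frame["level"] != level).sum())
        if skipped:
            logger.warning("%s: skipping %d rows not at level %s",
                           path, skipped, level)
        frame = frame[frame["level"] == level]
        if frame.empty:
            raise SchemaError(f"{path}: no rows at level {level!r}")
    return ConformerTable(frame.reset_index(drop=True), provenance=str(path))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_conformer(record: ConformerRecord | float) -> tuple[str, str]:
    """Class A (anti) iff phi1 < 0, class B (syn) iff phi1 > 0.

    phi1 == 0 exactly is flagged as unclassifiable rather than guessed.
    """
    phi1 = record.phi1 if isinstance(record, ConformerRecord) else float(record)
    if math.isnan(phi1):
        raise UnclassifiableError("phi1 is undefined")
    if phi1 < 0:
        return ("A", "anti")
    if phi1 > 0:
        return ("B", "syn")
    raise UnclassifiableError("phi1 is exactly zero: orientation ambiguous")


def _classes(frame: pd.DataFrame) -> pd.Series:
    if (frame["phi1"] == 0).any():
        raise UnclassifiableError("table contains phi1 == 0 rows")
    return pd.Series(np.where(frame["phi1"] < 0, "A", "B"), index=frame.index)


# ---------------------------------------------------------------------------
# torsion binning
# ---------------------------------------------------------------------------

@dataclass
class TorsionBin:
    """A closed circular interval on (-180, 180]; lo > hi wraps through 180."""

    lo: float
    hi: float

    def contains(self, value: float) -> bool:
        if self.lo <= self.hi:
            return self.lo <= value <= self.hi
        return value >= self.lo or value <= self.hi

    def overlaps(self, other: "TorsionBin") -> bool:
        probes = (self.lo, self.hi, other.lo, other.hi)
        return any(self.contains(p) and other.contains(p) for p in probes)

    def label(self) -> str:
        return f"[{self.lo:g},{self.hi:g}]"


def _round_half_away(value: float, decimals: int = 0) -> float:
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


@dataclass
class BinReport:
    torsion: str
    bins: list[TorsionBin]
    counts: list[dict]
    unbinned: dict

    def totals(self) -> list[int]:
        return [c["total"] for c in self.counts]

    def to_dict(self) -> dict:
        return {
            "torsion": self.torsion,
            "bins": [dict(interval=b.label(), **c)
                     for b, c in zip(self.bins, self.counts)],
            "unbinned": self.unbinned,
        }


def bin_torsions(table: ConformerTable, torsion: str,
                 bins: Sequence[TorsionBin | tuple[float, float]],
                 edge_decimals: int = 0) -> BinReport:
    """Count records per circular torsion bin, split by class A/B.

    Bin edges transcribed from printed range summaries are rounded extremes,
    so membership is tested after rounding each observed value to
    ``edge_decimals`` decimals (half away from zero).  Pass
    ``edge_decimals=None`` to compare raw values.  Records outside every bin
    fall into an explicit unbinned bucket, so bin totals plus the unbinned
    total always equal the table size.
    """
    if torsion not in ("phi1", "phi2", "phi3", "phi4", "phi5"):
        raise ValueError(f"unknown torsion {torsion!r}")
    bins = [b if isinstance(b, TorsionBin) else TorsionBin(*b) for b in bins]
    for i, b1 in enumerate(bins):
        for b2 in bins[i + 1:]:
            if b1.overlaps(b2):
                raise ValueError(f"overlapping bins {b1.label()} and {b2.label()}")
    frame = table.frame
    classes = _classes(frame) if len(frame) else pd.Series(dtype=str)
    counts = [{"total": 0, "A": 0, "B": 0} for _ in bins]
    unbinned = {"total": 0, "A": 0, "B": 0, "names": []}
    for idx, value in frame[torsion].items():
        v = value if edge_decimals is None else _round_half_away(value, edge_decimals)
        cls = classes[idx]
        for b, c in zip(bins, counts):
            if b.contains(v):
                c["total"] += 1
                c[cls] += 1
                break
        else:
            unbinned["total"] += 1
            unbinned[cls] += 1
            unbinned["names"].append(str(frame["name"][idx]))
    return BinReport(torsion=torsion, bins=bins, counts=counts,
                     unbinned=unbinned)


# ---------------------------------------------------------------------------
# Boltzmann populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Temperature and energy-column choice for Boltzmann weighting.

    The published headline populations are reproduced by the relative
    electronic energies (dE, which include the zero-point correction), so
    dE is the default; the Gibbs column dG is selectable.
    """

    temperature: float = 298.15
    gas_constant: float = GAS_CONSTANT_KCAL
    energy_column: str = "dE"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.energy_column not in ("dE", "dG"):
            raise ValueError("energy_column must be 'dE' or 'dG'")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


def boltzmann_populations(table: ConformerTable,
                          config: PopulationConfig | None = None) -> pd.DataFrame:
    """Per-record populations p_i = exp(-E_i/RT) / sum_j exp(-E_j/RT), in %.

    Percentages sum to 100 within 1e-9.  Reference-shift invariant: adding a
    constant to every energy leaves the populations unchanged.
    """
    config = config or PopulationConfig()
    table.require_nonempty()
    energies = table.frame[config.energy_column].to_numpy(dtype=float)
    if np.isnan(energies).any():
        bad = table.frame["name"][np.isnan(energies)].tolist()
        raise ValueError(f"records missing {config.energy_column}: {bad}")
    shifted = energies - energies.min()
    weights = np.exp(-shifted / config.rt)
    populations = 100.0 * weights / weights.sum()
    return pd.DataFrame({
        "name": table.frame["name"],
        "energy": energies,
        "population_pct": populations,
    })


# ---------------------------------------------------------------------------
# energy bands
# ---------------------------------------------------------------------------

@dataclass
class BandStats:
    lo: float
    hi: float
    energy_column: str
    count: int
    count_A: int
    count_B: int
    ratio: float | None          # count_A / count_B, raw
    ratio_rounded: float | None  # one decimal, matching printed precision

    def to_dict(self) -> dict:
        return vars(self).copy()


def energy_band_stats(table: ConformerTable, band: tuple[float, float],
                      energy_column: str = "dE",
                      include_upper: bool = False) -> BandStats:
    """Counts and A/B ratio for records with lo <= E < hi (kcal/mol).

    ``include_upper=True`` closes the band at ``hi`` (used for a terminal
    band so that consecutive bands partition the table).  An empty B class
    yields an undefined (None) ratio rather than an exception.
    """
    lo, hi = band
    if lo > hi:
        raise ValueError("band lower bound exceeds upper bound")
    frame = table.frame
    energies = frame[energy_column]
    mask = (energies >= lo) & ((energies <= hi) if include_upper
                               else (energies < hi))
    sel = frame[mask]
    classes = _classes(sel) if len(sel) else pd.Series(dtype=str)
    count_a = int((classes == "A").sum())
    count_b = int((classes == "B").sum())
    ratio = (count_a / count_b) if count_b else None
    return BandStats(
        lo=lo, hi=hi, energy_column=energy_column,
        count=int(mask.sum()), count_A=count_a, count_B=count_b,
        ratio=ratio,
        ratio_rounded=None if ratio is None else _round_half_away(ratio, 1),
    )
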