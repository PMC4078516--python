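"""Exhaustive torsion-grid conformational search with local relaxation.

Enumerates a regular grid over the selected chain torsions of a template,
relaxes each start in torsion space under a pluggable energy model,
deduplicates the resulting minima by circular torsion distance, and ranks
the survivors into the A#/B# naming scheme (class by sign of phi1, numbered
by ascending energy within each class).

Relaxation is deliberately restricted to the driven torsions (bond lengths
and angles stay fixed): the energy model is a surrogate standing in for the
externally supplied energies, and keeping the engine in torsion space keeps
it exact, fast and testable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.optimize import minimize

from .analysis import ConformerRecord, ConformerTable
from .descriptors import TORSION_NAMES, descriptor_set, wrap_angle
from .model import Conformation
from .synthetic import set_chain_torsions

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyModel",
    "SearchConfig",
    "SearchResult",
    "grid_search",
    "deduplicate_and_rank",
    "enumerate_starts",
    "circular_distance",
]


@runtime_checkable
class EnergyModel(Protocol):
    """Pure mapping Conformation -> scalar energy (kcal/mol).

    Implementations may advertise ``per_torsion_analytic = True`` and provide
    ``torsion_energy(torsions: dict) -> float`` for a fast torsion-space path.
    """

    def energy(self, conf: Conformation) -> float: ...


@dataclass
class SearchConfig:
    """Grid, minimizer and deduplication settings."""

    step: float = 60.0
    torsions: tuple[str, ...] = TORSION_NAMES
    energy_tolerance: float = 1e-8    # kcal/mol, minimizer ftol
    angle_tolerance: float = 1e-4     # degrees, minimizer xtol
    dedup_tolerance: float = 20.0     # degrees, circular, per torsion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0 or 360.0 % self.step != 0:
            raise ValueError("step must divide 360")
        unknown = set(self.torsions) - set(TORSION_NAMES)
        if unknown:
            raise ValueError(f"unknown torsions {sorted(unknown)}")
        if self.dedup_tolerance <= 0 or self.energy_tolerance <= 0 \
                or self.angle_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SearchResult:
    """One convergent start: relaxed conformation, energy, grid origin."""

    conformation: Conformation
    energy: float               # relative to the run's global minimum
    start: tuple[float, ...]    # grid values of the driven torsions

    def torsions(self) -> dict[str, float]:
        return descriptor_set(self.conformation).torsions()


class SearchError(RuntimeError):
    """Raised when no grid start converges or a model returns non-finite."""


def enumerate_starts(config: SearchConfig) -> list[tuple[float, ...]]:
    """Grid start points: Cartesian product of [0, 360) in ``step`` steps."""
    values = [wrap_angle(v) for v in np.arange(0.0, 360.0, config.step)]
    return list(itertools.product(values, repeat=len(config.torsions)))


def circular_distance(a: float, b: float) -> float:
    """Shortest angular distance in degrees, in [0, 180]."""
    return abs(wrap_angle(a - b))


def _objective(template: Conformation, model: EnergyModel,
               torsions: Sequence[str]):
    fast = getattr(model, "per_torsion_analytic", False) and \
        hasattr(model, "torsion_energy")

    def f(x: np.ndarray) -> float:
        values = {name: wrap_angle(v) for name, v in zip(torsions, x)}
        if fast:
            return model.torsion_energy(values)
        conf = set_chain_torsions(template, values)
        return model.energy(conf)

    return f


def grid_search(template: Conformation, model: EnergyModel,
                config: SearchConfig | None = None) -> list[SearchResult]:
    """One relaxed local minimum per convergent grid start.

    Starts where the model is non-finite (clashes) are skipped with a log
    message; a NaN model value raises naming the start.  Energies are
    reported relative to the global minimum found.  Deterministic.
    """
    config = config or SearchConfig()
    from .model import validate_topology

    violations = validate_topology(template.graph)
    if violations:
        raise ValueError(f"template fails topology validation: {violations}")

    f = _objective(template, model, config.torsions)
    raw: list[tuple[np.ndarray, float, tuple[float, ...]]] = []
    for start in enumerate_starts(config):
        e0 = f(np.asarray(start, dtype=float))
        if math.isnan(e0):
            raise SearchError(f"model returned NaN at grid start {start}")
        if math.isinf(e0):
            logger.info("skipping clashing grid start %s", start)
            continue
        res = minimize(f, np.asarray(start, dtype=float), method="Powell",
                       options={"xtol": config.angle_tolerance,
                                "ftol": config.energy_tolerance,
                                "maxiter": 10000})
        x, e = res.x, float(res.fun)
        if not math.isfinite(e) or e > e0:
            x, e = np.asarray(start, dtype=float), e0  # never worse than start
        raw.append((x, e, start))
    if not raw:
        raise SearchError("no convergent grid start")

    e_min = min(e for (_x, e, _s) in raw)
    results = []
    for x, e, start in raw:
        values = {name: wrap_angle(v) for name, v in zip(config.torsions, x)}
        conf = set_chain_torsions(template, values)
        conf.provenance = f"grid_search:start={start}"
        results.append(SearchResult(conformation=conf, energy=e - e_min,
                                    start=start))
    return results


def deduplicate_and_rank(results: Sequence[SearchResult],
                         config: SearchConfig | None = None) -> ConformerTable:
    """Merge near-identical minima and rank survivors into A#/B# names.

    Minima whose five torsions agree within the circular dedup tolerance
    (max over torsions) merge, keeping the lowest energy.  Survivors are
    split by the sign of phi1 and numbered by ascending energy within each
    class; phi1 == 0 routes to an 'U' (unclassified) bucket with a warning.
    Idempotent and independent of input order.
    """
    if not results:
        raise ValueError("no search results to deduplicate")
    config = config or SearchConfig()

    def sort_key(r: SearchResult):
        tors = r.torsions()
        return (r.energy,) + tuple(round(tors[n], 1) for n in TORSION_NAMES)

    ordered = sorted(results, key=sort_key)
    survivors: list[SearchResult] = []
    for cand in ordered:
        tors = cand.torsions()
        merged = False
        for kept in survivors:
            kept_tors = kept.torsions()
            dist = max(circular_distance(tors[n], kept_tors[n])
                       for n in TORSION_NAMES)
            if dist <= config.dedup_tolerance:
                merged = True
                break
        if not merged:
            survivors.append(cand)

    e0 = min(s.energy for s in survivors)
    by_class: dict[str, list[SearchResult]] = {"A": [], "B": [], "U": []}
    for s in survivors:
        phi1 = s.torsions()["phi1"]
        if abs(phi1) < 1e-9:  # numerically zero: ambiguous, do not guess
            phi1 = 0.0
        if phi1 < 0:
            by_class["A"].append(s)
        elif phi1 > 0:
            by_class["B"].append(s)
        else:
            logger.warning("minimum with phi1 == 0 routed to bucket 'U'")
            by_class["U"].append(s)

    records = []
    for cls in ("A", "B", "U"):
        for i, s in enumerate(by_class[cls], start=1):
            ds = descriptor_set(s.conformation)
            records.append(ConformerRecord(
                name=f"{cls}{i}", **ds.torsions(),
                R=ds.R, beta=ds.beta, Phi=ds.Phi,
                mu=math.nan, dE=s.energy - e0, dG=math.nan,
                level=f"search:{type(s).__name__}"))
    table = ConformerTable.from_records(
        records, provenance=f"grid_search step={config.step} "
                            f"dedup={config.dedup_tolerance}")
    return table
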