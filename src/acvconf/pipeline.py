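"""End-to-end report pipeline: descriptors -> classification -> populations
-> H-bonds -> search, with a versioned JSON summary.

All angles are degrees, energies kcal/mol, distances Angstrom; the summary
header states the unit conventions and records every parameter that
overrides a default.  Output is reproducible byte-for-byte except for the
single timestamp header field.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, descriptors, hbonds, search
from .analysis import (BandStats, ConformerTable, PopulationConfig,
                       TorsionBin, bin_torsions, boltzmann_populations,
                       classify_conformer, energy_band_stats,
                       read_conformer_table)
from .hbonds import HBondSpec, classify_intramolecular_type, detect_hbonds
from .model import Conformation, read_xyz, validate_topology
from .search import SearchConfig
from .synthetic import EnsembleSpec, ToyEnergyModel, build_template

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "SUMMARY_SCHEMA_VERSION",
           "DEFAULT_BINS"]

SUMMARY_SCHEMA_VERSION = "1.0"

#: Default circular torsion bins (the published modal ranges).
DEFAULT_BINS = {
    "phi2": [(65.0, 180.0), (-180.0, -66.0)],
    "phi3": [(58.0, 180.0), (-180.0, -58.0)],
    "phi4": [(175.0, -173.0), (41.0, 118.0), (-75.0, -45.0)],
    "phi5": [(165.0, -166.0), (39.0, 123.0), (-120.0, -46.0)],
}

#: Default energy bands (kcal/mol); the last one is upper-inclusive.
DEFAULT_BANDS = [(0.0, 1.0), (1.0, 3.0), (3.0, 8.5)]


@dataclass
class PipelineConfig:
    """Stage configuration for :func:`run_pipeline`."""

    temperatures: tuple[float, ...] = (298.15, 273.15)
    energy_column: str = "dE"
    bins: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_BINS.items()})
    bands: list = field(default_factory=lambda: list(DEFAULT_BANDS))
    hbond_spec: HBondSpec = field(default_factory=HBondSpec)
    search_config: SearchConfig | None = None
    output_dir: Path = Path("acvconf-report")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        overridden = []
        if "temperatures" in raw:
            kwargs["temperatures"] = tuple(float(t) for t in raw["temperatures"])
        if "energy_column" in raw:
            kwargs["energy_column"] = str(raw["energy_column"])
        if "bins" in raw:
            kwargs["bins"] = {k: [tuple(b) for b in v]
                              for k, v in raw["bins"].items()}
        if "bands" in raw:
            kwargs["bands"] = [tuple(b) for b in raw["bands"]]
        if "hbond" in raw:
            kwargs["hbond_spec"] = HBondSpec(**raw["hbond"])
        if "search" in raw:
            kwargs["search_config"] = SearchConfig(**raw["search"])
        if "output_dir" in raw:
            kwargs["output_dir"] = Path(raw["output_dir"])
        for key in kwargs:
            overridden.append(key)
        if overridden:
            logger.info("config overrides defaults for: %s",
                        ", ".join(sorted(overridden)))
        return cls(**kwargs)


def _table_stage(table: ConformerTable, config: PipelineConfig) -> dict:
    out: dict = {"n_records": len(table), "provenance": table.provenance}

    classes = {"A": 0, "B": 0}
    for record in table.records:
        cls, _orient = classify_conformer(record)
        classes[cls] += 1
    out["class_counts"] = classes

    populations = {}
    for temperature in config.temperatures:
        pop_config = PopulationConfig(temperature=temperature,
                                      energy_column=config.energy_column)
        frame = boltzmann_populations(table, pop_config)
        populations[f"{temperature:g}K"] = {
            str(n): round(float(p), 4)
            for n, p in zip(frame["name"], frame["population_pct"])}
    out["populations_pct"] = populations
    out["population_config"] = {
        "energy_column": config.energy_column,
        "gas_constant_kcal_mol_K": analysis.GAS_CONSTANT_KCAL,
        "temperatures_K": list(config.temperatures),
    }

    out["torsion_bins"] = {
        torsion: bin_torsions(table, torsion,
                              [TorsionBin(*b) for b in bins]).to_dict()
        for torsion, bins in config.bins.items()}

    bands = []
    for i, band in enumerate(config.bands):
        stats = energy_band_stats(table, band,
                                  energy_column=config.energy_column,
                                  include_upper=(i == len(config.bands) - 1))
        bands.append(stats.to_dict())
    out["energy_bands"] = bands
    return out


def _coordinate_stage(conf: Conformation, config: PipelineConfig) -> dict:
    out: dict = {"provenance": conf.provenance,
                 "n_atoms": len(conf.graph.atoms),
                 "molecule_ids": conf.graph.molecule_ids()}
    violations = validate_topology(conf.graph)
    out["topology_violations"] = violations
    if not violations:
        per_molecule = {}
        for mol in conf.graph.molecule_ids():
            ds = descriptors.descriptor_set(conf, molecule_id=mol)
            planarity = descriptors.base_nonplanarity(conf, molecule_id=mol)
            per_molecule[str(mol)] = {
                "descriptors": {k: round(v, 4) for k, v in ds.to_dict().items()},
                "ring_max_abs_nu": round(planarity.max_abs, 4),
                "ring_flagged": list(planarity.flagged),
            }
        out["molecules"] = per_molecule
    bonds = detect_hbonds(conf, config.hbond_spec)
    out["hbonds"] = [b.to_dict() for b in bonds]
    intra = [b for b in bonds if b.scope == "intra" and b.hydrogen == "H5'"]
    out["intramolecular_type"] = classify_intramolecular_type(intra)
    return out


def run_pipeline(inputs: dict, config: PipelineConfig | None = None) -> dict:
    """Run every applicable stage and write a report bundle.

    ``inputs`` maps input kinds to paths or objects:
    ``tautomer_table`` / ``conformer_table`` (path or ConformerTable),
    ``coordinates`` (list of XYZ paths or Conformations), ``search``
    (truthy: run the toy-model grid search).  Returns the summary dict;
    writes ``summary.json`` plus per-stage delimited outputs under
    ``config.output_dir``.  Raises ValueError if no input is given; stage
    errors are reported in the summary and the pipeline continues.
    """
    config = config or PipelineConfig()
    if not inputs:
        raise ValueError("no inputs: provide a table, coordinates, or search")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "units": {"angle": "degree", "energy": "kcal/mol",
                  "distance": "Angstrom", "population": "percent"},
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "errors": {},
    }

    for key in ("tautomer_table", "conformer_table"):
        if key not in inputs:
            continue
        value = inputs[key]
        try:
            table = value if isinstance(value, ConformerTable) else \
                read_conformer_table(value, level=inputs.get(f"{key}_level"))
            stage = _table_stage(table, config)
            summary["stages"][key] = stage
            pops = []
            for temperature, mapping in stage["populations_pct"].items():
                for name, pct in mapping.items():
                    pops.append({"temperature": temperature, "name": name,
                                 "population_pct": pct})
            pd.DataFrame(pops).to_csv(outdir / f"{key}_populations.tsv",
                                      sep="\t", index=False)
        except Exception as exc:  # reported, pipeline continues per-stage
            logger.error("stage %s failed: %s", key, exc)
            summary["errors"][key] = str(exc)

    if "coordinates" in inputs:
        coordinate_stages = []
        for item in inputs["coordinates"]:
            try:
                conf = item if isinstance(item, Conformation) else read_xyz(item)
                coordinate_stages.append(_coordinate_stage(conf, config))
            except Exception as exc:
                logger.error("coordinate stage failed for %s: %s", item, exc)
                summary["errors"][f"coordinates:{item}"] = str(exc)
        summary["stages"]["coordinates"] = coordinate_stages
        rows = []
        for stage in coordinate_stages:
            rows.extend(stage["hbonds"])
        pd.DataFrame(rows).to_csv(outdir / "hbonds.tsv", sep="\t", index=False)

    if inputs.get("search"):
        try:
            template = build_template("N1")
            search_config = config.search_config or SearchConfig(
                step=120.0, torsions=("phi1", "phi4", "phi5"))
            results = search.grid_search(template, ToyEnergyModel(),
                                         search_config)
            table = search.deduplicate_and_rank(results, search_config)
            table.to_tsv(outdir / "search_minima.tsv")
            summary["stages"]["search"] = {
                "n_starts": len(search.enumerate_starts(search_config)),
                "n_minima": len(table),
                "config": {
                    "step": search_config.step,
                    "torsions": list(search_config.torsions),
                    "dedup_tolerance": search_config.dedup_tolerance,
                    "seed": search_config.seed,
                },
            }
        except Exception as exc:
            logger.error("search stage failed: %s", exc)
            summary["errors"]["search"] = str(exc)

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
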