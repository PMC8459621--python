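"""End-to-end analysis runs: records in, report bundle out.

A run reads (or receives) the cage records and a composition table, computes
per-cage mass balances and performance metrics, the cross-cage aggregate
table and the standard regressions, and writes the bundle to an output
directory:

- ``balances.csv``    one row per cage x nutrient with component masses,
  loss and per-tonne loading
- ``metrics.csv``     one row per cage with the seven performance metrics
- ``aggregate.json``  cross-cage mean/SD/min/max per nutrient and component
- ``regressions.csv`` slope, intercept, r² and n per fitted pair
- ``run.log``         the basis/mode decisions and per-stage progress

All inputs are read and all numbers computed before anything is written, so
a failing run leaves no partial bundle.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .balance import (
    MassBasis,
    NUTRIENTS,
    aggregate_balances,
    balances_to_frame,
    cage_nutrient_loss,
)
from .metrics import FEEDING_MODES, LOG_BASES, compute_metrics
from .records import (
    CageRecord,
    NutrientComposition,
    default_composition,
    read_composition,
    read_records,
)
from .regression import DEFAULT_PAIRS, cage_table, relationship_report

__all__ = ["RunConfig", "load_config", "run_pipeline"]

logger = logging.getLogger("cageload")


class RunConfig(BaseModel):
    """Configuration of one analysis run."""

    model_config = ConfigDict(frozen=True)

    records: Path
    composition: Path | None = None  # None -> bundled study composition
    basis: MassBasis = MassBasis.AS_RECORDED
    log_base: str = "natural"
    feeding_mode: str = "total_gain"
    pairs: tuple[tuple[str, str, str], ...] = DEFAULT_PAIRS
    out_dir: Path = Field(default=Path("cageload-out"))

    def model_post_init(self, _ctx) -> None:
        if self.log_base not in LOG_BASES:
            raise ValueError(f"log_base must be one of {LOG_BASES}")
        if self.feeding_mode not in FEEDING_MODES:
            raise ValueError(f"feeding_mode must be one of {FEEDING_MODES}")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML or JSON run configuration, with keyword overrides."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute a full run; returns the paths of the written bundle."""
    records = read_records(config.records)
    if not records:
        raise ValueError(f"no cage records in {config.records}")
    comp = (
        read_composition(config.composition)
        if config.composition is not None
        else default_composition()
    )

    results = [cage_nutrient_loss(r, comp, config.basis) for r in records]
    balances = balances_to_frame(results)
    aggregate = aggregate_balances(results)
    metrics = pd.DataFrame(
        [
            {"cage_id": r.cage_id}
            | compute_metrics(
                r, log_base=config.log_base, feeding_mode=config.feeding_mode
            ).__dict__
            for r in records
        ]
    )
    table = cage_table(
        records, comp, config.basis, config.log_base, config.feeding_mode
    )
    regressions = relationship_report(table, config.pairs) if len(records) >= 2 else None

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("records=%s n_cages=%d", config.records, len(records))
        logger.info(
            "composition=%s basis=%s log_base=%s feeding_mode=%s",
            config.composition or "<bundled study composition>",
            config.basis.value,
            config.log_base,
            config.feeding_mode,
        )
        paths = {"log": log_path}
        paths["balances"] = out / "balances.csv"
        balances.to_csv(paths["balances"], index=False)
        paths["metrics"] = out / "metrics.csv"
        metrics.to_csv(paths["metrics"], index=False)
        paths["aggregate"] = out / "aggregate.json"
        _write_aggregate(aggregate, len(records), paths["aggregate"])
        if regressions is not None:
            paths["regressions"] = out / "regressions.csv"
            regressions.to_csv(paths["regressions"], index=False)
            for _, row in regressions.iterrows():
                logger.info(
                    "fit %s: slope=%.6g intercept=%.6g r2=%.4f n=%d",
                    row["pair_name"], row["slope"], row["intercept"],
                    row["r_squared"], row["n"],
                )
        logger.info("wrote %d output files to %s", len(paths), out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return paths


def _write_aggregate(aggregate: pd.DataFrame, n_cages: int, path: Path) -> None:
    """Aggregate table as nested JSON: nutrient -> component -> stats."""
    fields = ("input_feed", "input_juvenile", "output_harvest", "output_dead", "loss")
    block: dict = {"n_cages": n_cages, "units": "kg/cage/cycle"}
    for nutrient in NUTRIENTS:
        block[nutrient] = {
            field: {
                stat: float(aggregate.loc[nutrient, f"{field}_{stat}"])
                for stat in ("mean", "std", "min", "max")
            }
            for field in fields
        }
    with open(path, "w") as handle:
        json.dump(block, handle, indent=2)
        handle.write("\n")
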