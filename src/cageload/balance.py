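"""C/N/P mass balances for floating-cage fish culture.

The nutrient load a cage releases to the waterbody over one production cycle
is estimated by mass balance: everything that entered (feed supplied F and
stocked juveniles J) minus everything retained in fish biomass taken out
(harvest H and dead fish M), each mass multiplied by the material's nutrient
fraction.  For carbon::

    C_loss = (F * C_feed + J * C_fish) - (H * C_fish + M * C_fish)

and analogously for nitrogen and phosphorus, with a single fish composition
applied to juveniles, harvested and dead fish.

The composition fractions are measured on dry weight.  Two bases are
offered for the masses they multiply:

``as_recorded`` (default)
    fractions applied directly to the recorded wet / as-fed masses.  This is
    the basis that reproduces the published per-cage budgets for this system
    (e.g. 1226 kg harvested x 0.1656 = 203.0 kg C).
``dry_matter``
    masses first converted to dry matter via the moisture fraction — the
    literal dry-weight reading of the balance equations.

Losses can come out negative when the bookkeeping is inconsistent (more
nutrient in the harvested fish than entered); this warns rather than errors
so the analyst sees the cage rather than losing the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from types import MappingProxyType
from typing import Iterable, Mapping

import pandas as pd

from .records import BookkeepingWarning, CageRecord, NutrientComposition

__all__ = [
    "MassBasis",
    "NUTRIENTS",
    "NutrientBalance",
    "MassBalanceResult",
    "to_dry_mass",
    "component_nutrient_mass",
    "nutrient_loss",
    "cage_nutrient_loss",
    "loading_per_tonne_feed",
    "balances_to_frame",
    "aggregate_balances",
]

#: Nutrients tracked by the balance, in reporting order.
NUTRIENTS = ("C", "N", "P")

_FRACTION_ATTR = {"C": "c_frac", "N": "n_frac", "P": "p_frac"}


class MassBasis(str, Enum):
    """Whether composition fractions multiply recorded or dry masses."""

    AS_RECORDED = "as_recorded"
    DRY_MATTER = "dry_matter"


def to_dry_mass(mass_kg: float, moisture_frac: float) -> float:
    """Convert an as-recorded mass to dry matter: ``mass * (1 - moisture)``."""
    if mass_kg < 0:
        raise ValueError("mass must be non-negative")
    if not 0.0 <= moisture_frac < 1.0:
        raise ValueError("moisture_frac must be in [0, 1); 1 leaves no dry matter")
    return mass_kg * (1.0 - moisture_frac)


def component_nutrient_mass(
    mass_kg: float,
    nutrient_frac: float,
    basis: MassBasis = MassBasis.AS_RECORDED,
    moisture_frac: float = 0.0,
) -> float:
    """Nutrient mass (kg) carried by one balance component.

    ``as_recorded`` returns ``mass * nutrient_frac``; ``dry_matter`` first
    removes moisture.
    """
    if mass_kg < 0:
        raise ValueError("mass must be non-negative")
    if not 0.0 <= nutrient_frac <= 1.0:
        raise ValueError("nutrient_frac must be in [0, 1]")
    basis = MassBasis(basis)
    if basis is MassBasis.DRY_MATTER:
        mass_kg = to_dry_mass(mass_kg, moisture_frac)
    return mass_kg * nutrient_frac


def nutrient_loss(
    input_feed: float,
    input_juvenile: float,
    output_harvest: float,
    output_dead: float,
) -> float:
    """Balance arithmetic: inputs minus retained outputs, in kg of nutrient."""
    return (input_feed + input_juvenile) - (output_harvest + output_dead)


@dataclass(frozen=True)
class NutrientBalance:
    """Component nutrient masses (kg) and the resulting loss for one nutrient."""

    input_feed: float
    input_juvenile: float
    output_harvest: float
    output_dead: float
    loss: float


@dataclass(frozen=True)
class MassBalanceResult:
    """Per-cage C/N/P balance plus the feed mass the loadings are scaled by."""

    cage_id: str
    basis: MassBasis
    feed_mass_basis: float  # kg of feed on the chosen basis
    nutrients: Mapping[str, NutrientBalance]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nutrients", MappingProxyType(dict(self.nutrients)))


def cage_nutrient_loss(
    record: CageRecord,
    comp: NutrientComposition,
    basis: MassBasis = MassBasis.AS_RECORDED,
) -> MassBalanceResult:
    """Full C/N/P balance for one cage.

    A negative loss raises :class:`~cageload.records.BookkeepingWarning`
    (inconsistent records), never an error.
    """
    basis = MassBasis(basis)
    balances: dict[str, NutrientBalance] = {}
    for nutrient in NUTRIENTS:
        attr = _FRACTION_ATTR[nutrient]
        feed_frac = getattr(comp.feed, attr)
        fish_frac = getattr(comp.fish, attr)
        input_feed = component_nutrient_mass(
            record.feed_supplied_kg, feed_frac, basis, comp.feed.moisture_frac
        )
        input_juvenile = component_nutrient_mass(
            record.stock_total_weight_kg, fish_frac, basis, comp.fish.moisture_frac
        )
        output_harvest = component_nutrient_mass(
            record.harvest_total_weight_kg, fish_frac, basis, comp.fish.moisture_frac
        )
        output_dead = component_nutrient_mass(
            record.dead_total_weight_kg, fish_frac, basis, comp.fish.moisture_frac
        )
        loss = nutrient_loss(input_feed, input_juvenile, output_harvest, output_dead)
        if loss < 0:
            warnings.warn(
                f"cage {record.cage_id}: negative {nutrient} loss ({loss:g} kg) — "
                "outputs exceed inputs; check the cage's bookkeeping",
                BookkeepingWarning,
                stacklevel=2,
            )
        balances[nutrient] = NutrientBalance(
            input_feed, input_juvenile, output_harvest, output_dead, loss
        )
    feed_mass = record.feed_supplied_kg
    if basis is MassBasis.DRY_MATTER:
        feed_mass = to_dry_mass(feed_mass, comp.feed.moisture_frac)
    return MassBalanceResult(record.cage_id, basis, feed_mass, balances)


def loading_per_tonne_feed(result: MassBalanceResult) -> dict[str, float]:
    """Nutrient loss per tonne of feed supplied, kg/tonne per nutrient."""
    if result.feed_mass_basis <= 0:
        raise ValueError("feed mass must be positive to scale per tonne")
    tonnes = result.feed_mass_basis / 1000.0
    return {nutrient: bal.loss / tonnes for nutrient, bal in result.nutrients.items()}


_FIELDS = ("input_feed", "input_juvenile", "output_harvest", "output_dead", "loss")


def balances_to_frame(results: Iterable[MassBalanceResult]) -> pd.DataFrame:
    """Tidy per-cage table: one row per cage x nutrient, plus per-tonne loading."""
    rows = []
    for result in results:
        per_tonne = loading_per_tonne_feed(result)
        for nutrient, bal in result.nutrients.items():
            rows.append(
                {
                    "cage_id": result.cage_id,
                    "nutrient": nutrient,
                    **{field: getattr(bal, field) for field in _FIELDS},
                    "loading_per_tonne": per_tonne[nutrient],
                    "feed_mass_basis": result.feed_mass_basis,
                    "basis": result.basis.value,
                }
            )
    if not rows:
        raise ValueError("no balance results given")
    return pd.DataFrame(rows)


def aggregate_balances(results: Iterable[MassBalanceResult]) -> pd.DataFrame:
    """Cross-cage summary per nutrient and component: mean, sd, min, max.

    Sample SD (n-1 denominator).  With a single cage SD is undefined and is
    reported as 0 alongside a warning.
    """
    frame = balances_to_frame(results)
    n_cages = frame["cage_id"].nunique()
    stats = (
        frame.groupby("nutrient")[list(_FIELDS)]
        .agg(["mean", "std", "min", "max"])
        .reindex(list(NUTRIENTS))
    )
    if n_cages < 2:
        warnings.warn(
            "SD is undefined for a single cage; reporting 0", UserWarning, stacklevel=2
        )
        stats.loc[:, (slice(None), "std")] = 0.0
    stats.columns = [f"{field}_{stat}" for field, stat in stats.columns]
    return stats
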