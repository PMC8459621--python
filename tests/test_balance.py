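"""Mass-balance arithmetic: worked budget values, conservation, bases."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cageload import (
    CageRecord,
    MassBasis,
    aggregate_balances,
    cage_nutrient_loss,
    component_nutrient_mass,
    loading_per_tonne_feed,
    nutrient_loss,
    to_dry_mass,
)
from cageload.balance import MassBalanceResult, NutrientBalance
from cageload.records import BookkeepingWarning

# Published 20-cage component means (kg/cage/cycle): feed, juvenile,
# harvest, dead — the worked example every balance must reproduce.
WORKED_MEANS = {
    "C": (412.19, 44.49, 203.01, 17.40, 236.27),
    "N": (121.93, 8.39, 41.06, 4.73, 84.53),
    "P": (14.38, 1.11, 6.25, 0.53, 8.71),
}


def _record(**overrides) -> CageRecord:
    base = dict(
        cage_id="t", volume_m3=75, stock_count=5625, stock_mean_weight_g=50,
        stock_total_weight_kg=281.25, feed_supplied_kg=2023, dead_count=625,
        dead_total_weight_kg=76.6, harvest_count=5000,
        harvest_total_weight_kg=1226, cycle_days=170,
    )
    base.update(overrides)
    return CageRecord(**base)


class TestDryMass:
    def test_moisture_removal(self):
        assert to_dry_mass(1226, 0.689) == pytest.approx(381.29, abs=0.005)

    def test_zero_moisture_is_identity(self):
        assert to_dry_mass(123.4, 0.0) == 123.4

    def test_zero_mass(self):
        assert to_dry_mass(0, 0.5) == 0

    @pytest.mark.parametrize("mass,moist", [(1, 1.0), (-1, 0.5), (1, 1.2)])
    def test_invalid_inputs(self, mass, moist):
        with pytest.raises(ValueError):
            to_dry_mass(mass, moist)


class TestComponentMass:
    def test_harvest_carbon(self):
        assert component_nutrient_mass(1226, 0.1656) == pytest.approx(203.03, abs=0.005)

    def test_zero_mass(self):
        assert component_nutrient_mass(0, 0.5) == 0

    def test_feed_mass_inversion(self):
        # feed mass implied by the published feed-P mean and feed P fraction
        feed = 14.38 / 0.0071
        assert feed == pytest.approx(2025.35, abs=0.005)
        assert component_nutrient_mass(feed, 0.0071) == pytest.approx(14.38)

    def test_dry_basis_scales_by_moisture(self):
        wet = component_nutrient_mass(1000, 0.1656, MassBasis.AS_RECORDED)
        dry = component_nutrient_mass(1000, 0.1656, MassBasis.DRY_MATTER, 0.689)
        assert dry == pytest.approx(wet * (1 - 0.689))


@pytest.mark.parametrize("nutrient", ["C", "N", "P"])
def test_worked_example_losses(nutrient):
    """The published component means reproduce the published losses.

    C is exact at two decimals; N and P land within 0.02 of the printed
    values (the printed losses aggregate before rounding).
    """
    feed, juv, harv, dead, expected = WORKED_MEANS[nutrient]
    loss = nutrient_loss(feed, juv, harv, dead)
    assert loss == pytest.approx(expected, abs=1e-9)


def test_cage_balance_matches_published_harvest_carbon(mean_cage, composition):
    result = cage_nutrient_loss(mean_cage, composition)
    assert result.nutrients["C"].output_harvest == pytest.approx(203.03, abs=0.01)
    assert result.nutrients["C"].input_feed == pytest.approx(2023 * 0.2023)


def test_zero_outputs_means_loss_equals_inputs(composition):
    record = _record(harvest_count=0, dead_count=5625, harvest_total_weight_kg=0,
                     dead_total_weight_kg=0)
    result = cage_nutrient_loss(record, composition)
    for bal in result.nutrients.values():
        assert bal.loss == pytest.approx(bal.input_feed + bal.input_juvenile)


def test_negative_loss_warns_not_errors(composition):
    record = _record(harvest_total_weight_kg=99999, feed_supplied_kg=1)
    with pytest.warns(BookkeepingWarning):
        result = cage_nutrient_loss(record, composition)
    assert result.nutrients["C"].loss < 0


class TestPerTonneLoading:
    def test_published_phosphorus_loading(self):
        feed_mass = 14.38 / 0.0071  # kg feed implied by the feed-P budget
        result = MassBalanceResult(
            "x", MassBasis.AS_RECORDED, feed_mass,
            {"P": NutrientBalance(14.38, 1.11, 6.25, 0.53, 8.70)},
        )
        loading = loading_per_tonne_feed(result)["P"]
        assert 4.29 <= round(loading, 2) <= 4.30

    def test_unit_identity(self):
        result = MassBalanceResult(
            "x", MassBasis.AS_RECORDED, 1000.0,
            {"C": NutrientBalance(5, 0, 0, 0, 5)},
        )
        assert loading_per_tonne_feed(result)["C"] == 5.0

    def test_zero_loss(self):
        result = MassBalanceResult(
            "x", MassBasis.AS_RECORDED, 500.0, {"C": NutrientBalance(1, 0, 1, 0, 0)}
        )
        assert loading_per_tonne_feed(result)["C"] == 0.0

    def test_zero_feed_mass_errors(self):
        result = MassBalanceResult(
            "x", MassBasis.AS_RECORDED, 0.0, {"C": NutrientBalance(0, 1, 0, 0, 1)}
        )
        with pytest.raises(ValueError):
            loading_per_tonne_feed(result)


class TestAggregate:
    def test_cohort_summary_shape(self, cohort, composition):
        records, _ = cohort
        results = [cage_nutrient_loss(r, composition) for r in records]
        table = aggregate_balances(results)
        assert list(table.index) == ["C", "N", "P"]
        assert {"loss_mean", "loss_std", "loss_min", "loss_max"} <= set(table.columns)

    def test_single_cage_sd_reported_zero_with_warning(self, mean_cage, composition):
        result = cage_nutrient_loss(mean_cage, composition)
        with pytest.warns(UserWarning, match="SD"):
            table = aggregate_balances([result])
        assert (table.filter(like="_std") == 0).all().all()

    def test_identical_cages_have_zero_spread(self, mean_cage, composition):
        results = [cage_nutrient_loss(mean_cage, composition) for _ in range(3)]
        # identical cage ids collapse to one cage: rebuild with unique ids
        results = [
            MassBalanceResult(f"c{i}", r.basis, r.feed_mass_basis, dict(r.nutrients))
            for i, r in enumerate(results)
        ]
        table = aggregate_balances(results)
        assert (table.filter(like="_std").round(12) == 0).all().all()
        assert (table["loss_min"] == table["loss_max"]).all()

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            aggregate_balances([])


masses = st.floats(min_value=0, max_value=1e5)


@settings(max_examples=150, derandomize=True)
@given(feed=masses, stock=masses, harvest=masses, dead=masses)
def test_conservation_is_exact(composition, feed, stock, harvest, dead):
    """inputs - outputs - loss == 0 for every nutrient, to the last bit."""
    record = _record(
        feed_supplied_kg=feed, stock_total_weight_kg=stock, stock_mean_weight_g=0,
        harvest_total_weight_kg=harvest, dead_total_weight_kg=dead,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BookkeepingWarning)
        result = cage_nutrient_loss(record, composition)
    for bal in result.nutrients.values():
        assert (bal.input_feed + bal.input_juvenile) - (
            bal.output_harvest + bal.output_dead
        ) - bal.loss == 0.0


@settings(max_examples=100, derandomize=True)
@given(feed=st.floats(min_value=1, max_value=1e5))
def test_doubling_feed_adds_exactly_the_feed_increment(composition, feed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BookkeepingWarning)
        base = cage_nutrient_loss(_record(feed_supplied_kg=feed), composition)
        doubled = cage_nutrient_loss(_record(feed_supplied_kg=2 * feed), composition)
    for nutrient in "CNP":
        a, b = base.nutrients[nutrient], doubled.nutrients[nutrient]
        assert b.input_feed == pytest.approx(2 * a.input_feed, rel=1e-12)
        assert b.loss - a.loss == pytest.approx(a.input_feed, rel=1e-9)


def test_bases_are_proportional_per_component(mean_cage, composition):
    wet = cage_nutrient_loss(mean_cage, composition, MassBasis.AS_RECORDED)
    dry = cage_nutrient_loss(mean_cage, composition, MassBasis.DRY_MATTER)
    feed_scale = 1 - composition.feed.moisture_frac
    fish_scale = 1 - composition.fish.moisture_frac
    for nutrient in "CNP":
        w, d = wet.nutrients[nutrient], dry.nutrients[nutrient]
        assert d.input_feed == pytest.approx(w.input_feed * feed_scale)
        assert d.input_juvenile == pytest.approx(w.input_juvenile * fish_scale)
        assert d.output_harvest == pytest.approx(w.output_harvest * fish_scale)
        assert d.output_dead == pytest.approx(w.output_dead * fish_scale)


def test_longhand_oracle_matches_cage_balance(cohort, composition):
    """Element-wise longhand sums equal the packaged computation."""
    records, _ = cohort
    attr = {"C": "c_frac", "N": "n_frac", "P": "p_frac"}
    for record in records:
        result = cage_nutrient_loss(record, composition)
        for nutrient in "CNP":
            expected = (
                record.feed_supplied_kg * getattr(composition.feed, attr[nutrient])
                + record.stock_total_weight_kg * getattr(composition.fish, attr[nutrient])
                - record.harvest_total_weight_kg * getattr(composition.fish, attr[nutrient])
                - record.dead_total_weight_kg * getattr(composition.fish, attr[nutrient])
            )
            assert result.nutrients[nutrient].loss == pytest.approx(expected, rel=1e-12)
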