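"""Stage machine: rates, conversions, stochastic steps, the diapause gate."""

import numpy as np
import pytest

from marshsim.constants import CELL_AREA_M2
from marshsim.lifecycle import (
    STAGE_ORDER,
    Influence,
    Population,
    Rates,
    StageSpec,
    diapause_gate,
    dump_stage_table,
    effective_rates,
    lmg_default,
    load_stage_table,
    reproduce,
    step_population,
    step_stage,
    to_count,
    to_density,
)


def _plain_stage(name="larva", **kw):
    defaults = dict(aboveground=name in ("larva", "imago"), mortality=0.0)
    defaults.update(kw)
    return StageSpec(name=name, **defaults)


def _pop_with(stage, density, n_cohorts=1):
    pop = Population(0)
    for _ in range(n_cohorts):
        pop.stages[stage].add(density / n_cohorts)
    return pop


class TestEffectiveRates:
    def test_no_influences_returns_base(self):
        stage = _plain_stage(mortality=0.02, development=0.05)
        r = effective_rates(stage, {"temperature": 15, "contact_water": 3, "humidity": 80})
        assert (r.mortality, r.development, r.fecundity) == (0.02, 0.05, 0.0)

    def test_response_clamps_beyond_boundary_nodes(self):
        infl = Influence("temperature", "development", [(10.0, 0.5), (20.0, 2.0)])
        stage = _plain_stage(development=0.1, influences=[infl])
        hot = effective_rates(stage, {"temperature": 35, "contact_water": 0, "humidity": 0})
        cold = effective_rates(stage, {"temperature": -5, "contact_water": 0, "humidity": 0})
        assert hot.development == pytest.approx(0.2)
        assert cold.development == pytest.approx(0.05)

    def test_multipliers_combine_as_product(self):
        i1 = Influence("temperature", "mortality", [(0.0, 1.5)])
        i2 = Influence("humidity", "mortality", [(0.0, 0.5)])
        stage = _plain_stage(mortality=0.02, influences=[i1, i2])
        r = effective_rates(stage, {"temperature": 5, "contact_water": 0, "humidity": 50})
        assert r.mortality == pytest.approx(0.015)

    def test_persistence_window_gates_multiplier(self):
        infl = Influence(
            "contact_water", "mortality", [(0.0, 8.0)],
            persistence_days=14, persistence_below=1.0,
        )
        stage = _plain_stage(mortality=0.01, influences=[infl])
        drivers = {"temperature": 10, "contact_water": 0.5, "humidity": 50}
        early = effective_rates(stage, drivers, {"contact_water": 5})
        held = effective_rates(stage, drivers, {"contact_water": 14})
        assert early.mortality == pytest.approx(0.01)
        assert held.mortality == pytest.approx(0.08)

    def test_mortality_clipped_to_one(self):
        infl = Influence("temperature", "mortality", [(0.0, 100.0)])
        stage = _plain_stage(mortality=0.5, influences=[infl])
        r = effective_rates(stage, {"temperature": 0, "contact_water": 0, "humidity": 0})
        assert r.mortality == 1.0


class TestDensityCountConversion:
    @pytest.mark.parametrize(
        "density,expected",
        [(0.002, 125), (0.0, 0), (0.725, 45_313)],  # 45312.5 rounds half-up
    )
    def test_to_count_examples(self, density, expected):
        assert to_count(density, CELL_AREA_M2) == expected

    def test_roundtrip(self):
        assert to_count(to_density(125), CELL_AREA_M2) == 125

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            to_count(-0.1)


class TestStepStage:
    def test_zero_rates_only_age_advances(self):
        pop = _pop_with("larva", 0.5, n_cohorts=3)
        before = [c for c in pop.stages["larva"].count]
        rng = np.random.default_rng(0)
        moved, _ = step_stage(pop, _plain_stage(), Rates(0.0, 0.0, 0.0), rng)
        assert moved == 0
        assert list(pop.stages["larva"].count) == before
        assert (pop.stages["larva"].age == 1).all()

    def test_total_mortality_empties_stage(self):
        pop = _pop_with("larva", 0.5, n_cohorts=2)
        rng = np.random.default_rng(0)
        step_stage(pop, _plain_stage(mortality=1.0), Rates(1.0, 0.0, 0.0), rng)
        assert len(pop.stages["larva"]) == 0

    def test_binomial_death_moments(self):
        # n = 1e4, p = 0.1: mean deaths within 3 * sd of 1000 over 500 draws
        deaths = []
        rng = np.random.default_rng(42)
        for _ in range(500):
            pop = Population(0)
            pop.stages["larva"].add_count(10_000)
            step_stage(pop, _plain_stage(mortality=0.1), Rates(0.1, 0.0, 0.0), rng)
            deaths.append(10_000 - pop.stages["larva"].total_count())
        sd = np.sqrt(10_000 * 0.1 * 0.9)
        se = sd / np.sqrt(500)
        assert abs(np.mean(deaths) - 1000) < 4 * se

    def test_transfer_waits_for_development_completion(self):
        stage = _plain_stage(development=0.25, transfer=1.0)
        pop = _pop_with("larva", 0.4)
        rng = np.random.default_rng(1)
        moved_by_day = []
        for _ in range(4):
            moved, _ = step_stage(pop, stage, Rates(0.0, 0.25, 0.0), rng)
            moved_by_day.append(moved)
        assert moved_by_day[:3] == [0, 0, 0]
        assert moved_by_day[3] == to_count(0.4)  # dev reaches 1.0 on day 4

    def test_dev_fraction_is_monotone_along_cohort_array(self):
        stage = _plain_stage(development=0.1, transfer=0.5)
        pop = Population(0)
        rng = np.random.default_rng(2)
        for day in range(12):
            pop.stages["larva"].add_count(1000)
            step_stage(pop, stage, Rates(0.01, 0.1, 0.0), rng)
            dev = pop.stages["larva"].dev
            assert (np.diff(dev) <= 1e-12).all()


class TestReproduce:
    def test_no_imagos_no_eggs(self):
        assert reproduce(Population(0), 2.0, np.random.default_rng(0)) == 0

    def test_zero_fecundity_no_eggs(self):
        pop = _pop_with("imago", 0.1)
        assert reproduce(pop, 0.0, np.random.default_rng(0)) == 0

    def test_poisson_moments(self):
        pop = Population(0)
        pop.stages["imago"].add_count(1000)
        rng = np.random.default_rng(7)
        eggs = [reproduce(pop, 2.0, rng) for _ in range(500)]
        se = np.sqrt(2000) / np.sqrt(500)
        assert abs(np.mean(eggs) - 2000) < 4 * se


class TestDiapauseGate:
    def test_midwinter_is_dormant(self):
        assert not diapause_gate(15, (61, 300))  # mid-January

    def test_spring_develops(self):
        assert diapause_gate(105, (61, 300))  # mid-April

    def test_boundaries_inclusive(self):
        assert diapause_gate(61, (61, 300))
        assert diapause_gate(300, (61, 300))
        assert not diapause_gate(60, (61, 300))
        assert not diapause_gate(301, (61, 300))

    def test_wraparound_window(self):
        assert diapause_gate(350, (330, 30))
        assert diapause_gate(10, (330, 30))
        assert not diapause_gate(100, (330, 30))

    def test_out_of_range_day_errors(self):
        with pytest.raises(ValueError):
            diapause_gate(0, None)
        with pytest.raises(ValueError):
            diapause_gate(365, None)


class TestStepPopulation:
    def _zero_mortality_table(self):
        table = lmg_default()
        for spec in table.values():
            spec.mortality = 0.0
            spec.influences = [
                i for i in spec.influences if i.target != "mortality"
            ]
        table["imago"].fecundity = 0.0
        return table

    def test_density_conservation_without_mortality(self):
        table = self._zero_mortality_table()
        pop = Population(0)
        pop.stages["diapause"].add(0.725)
        start = pop.total_count()
        rng = np.random.default_rng(3)
        rates = {
            name: Rates(0.0, spec.development, 0.0)
            for name, spec in table.items()
        }
        for day in range(1, 2 * 364 + 1):
            step_population(pop, table, rates, (day - 1) % 364 + 1, rng)
        assert pop.total_count() == start

    def test_stage_ordering_no_skipping(self):
        # seed only the embryo stage; larva must appear before imago does
        table = self._zero_mortality_table()
        pop = Population(0)
        pop.stages["embryo"].add(0.1)
        rng = np.random.default_rng(4)
        rates = {n: Rates(0.0, 0.05, 0.0) for n in STAGE_ORDER}
        seen_imago_before_larva = False
        larva_seen = False
        for day in range(1, 200):
            step_population(pop, table, rates, day, rng)
            if pop.stages["larva"].total_count() > 0:
                larva_seen = True
            if pop.stages["imago"].total_count() > 0 and not larva_seen:
                seen_imago_before_larva = True
        assert not seen_imago_before_larva
        assert larva_seen

    def test_flow_events_record_transfers(self):
        table = self._zero_mortality_table()
        pop = Population(0)
        pop.stages["larva"].add(0.2, dev=1.0)
        rng = np.random.default_rng(5)
        rates = {n: Rates(0.0, 0.0, 0.0) for n in STAGE_ORDER}
        flows = step_population(pop, table, rates, 180, rng, collect_flows=True)
        transfer = [f for f in flows if f.sink_stage == "imago"]
        assert len(transfer) == 1
        assert transfer[0].density <= 0.2


class TestStageTableIO:
    def test_roundtrip(self, tmp_path):
        table = lmg_default()
        path = tmp_path / "stages.json"
        dump_stage_table(table, path)
        back = load_stage_table(path)
        for name in STAGE_ORDER:
            assert back[name] == table[name]

    def test_missing_stage_rejected(self, tmp_path):
        import json

        table = lmg_default()
        path = tmp_path / "stages.json"
        dump_stage_table(table, path)
        with open(path) as fh:
            raw = json.load(fh)
        del raw["larva"]
        with open(path, "w") as fh:
            json.dump(raw, fh)
        with pytest.raises(ValueError, match="missing stages"):
            load_stage_table(path)

    def test_bad_rate_names_stage(self, tmp_path):
        import json

        table = lmg_default()
        path = tmp_path / "stages.json"
        dump_stage_table(table, path)
        with open(path) as fh:
            raw = json.load(fh)
        raw["embryo"]["mortality"] = 1.5
        with open(path, "w") as fh:
            json.dump(raw, fh)
        with pytest.raises(ValueError, match="embryo"):
            load_stage_table(path)

    def test_aboveground_stages_must_be_larva_and_imago(self):
        import json

        table = lmg_default()
        raw = {}
        for name, s in table.items():
            raw[name] = {
                "aboveground": name == "imago",  # larva wrongly belowground
                "mortality": s.mortality,
                "development": s.development,
                "transfer": s.transfer,
                "fecundity": s.fecundity,
                "dispersal": s.dispersal,
                "influences": [],
                "active_window": None,
            }
        import tempfile, os

        with tempfile.NamedTemporaryFile("w", suffix=".json", delete=False) as fh:
            json.dump(raw, fh)
            path = fh.name
        try:
            with pytest.raises(ValueError, match="aboveground"):
                load_stage_table(path)
        finally:
            os.unlink(path)
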