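"""Scheduler behavior: each model step's contract, order, and conservation."""

from archmatnet import Trait, init_world, run_model, step
from archmatnet import dynamics
from archmatnet.dynamics import (
    TickReport,
    do_hunt,
    do_visit,
    form_alliance,
    step_environment,
    step_loss,
    trade,
    transmit,
)
from archmatnet.world_model import ArtifactObject

from conftest import quiet_config, small_config


def total_held(world):
    return sum(len(p.pot_inv) + len(p.point_inv) for p in world.people)


def total_deposited(world):
    return sum(len(c.assemblage) for c in world.camps)


# ---------------------------------------------------------------------
# the scheduler
# ---------------------------------------------------------------------

class TestScheduler:
    def test_noop_world_reports_all_zero(self, quiet_world):
        for _ in range(5):
            report = step(quiet_world)
            assert report.as_tuple()[1:] == (0,) * 14

    def test_tick_and_population_conserved(self):
        world = init_world(small_config(nTicks=150))
        n = len(world.people)
        for _ in range(150):
            step(world)
        assert world.tick == 150
        assert len(world.people) == n
        assert len(world.camps) == 6
        assert all(len(b.camp_ids) == 3 for b in world.bands)

    def test_seed_determinism_of_full_run(self):
        cfg = small_config(nTicks=120, randomSeed=99)
        runs = []
        for _ in range(2):
            world = init_world(cfg)
            runs.append(([step(world).as_tuple() for _ in range(120)],
                         world.serialize()))
        assert runs[0] == runs[1]

    def test_steps_execute_in_fixed_order(self, monkeypatch, quiet_world):
        trace = []
        order = ["step_environment", "step_innovation", "step_activities",
                 "step_loss", "step_transmission", "step_deposition",
                 "step_migration"]
        for name in order:
            real = getattr(dynamics, name)
            monkeypatch.setattr(
                dynamics, name,
                (lambda nm, fn: lambda w, r: (trace.append(nm), fn(w, r)))(
                    name, real))
        step(quiet_world)
        assert trace == order


# ---------------------------------------------------------------------
# step 1: environment + alliance trim
# ---------------------------------------------------------------------

class TestEnvironment:
    def test_no_change_when_probability_zero(self):
        world = init_world(quiet_config(pEnvChange=0.0, nTicks=50))
        for _ in range(50):
            step(world)
        assert world.current_env == 0

    def test_changes_every_tick_when_certain(self):
        world = init_world(quiet_config(pEnvChange=1.0))
        seen = {world.current_env}
        for _ in range(5):
            step(world)
            assert world.current_env not in seen
            seen.add(world.current_env)

    def test_zoned_mode_never_mutates(self):
        world = init_world(quiet_config(envMode="zoned", pEnvChange=1.0))
        env0 = [world.environment_at(c.loc) for c in world.camps]
        for _ in range(5):
            step(world)
        assert [world.environment_at(c.loc) for c in world.camps] == env0
        # one zone per band territory
        assert len(set(env0)) == len(world.bands)

    def test_alliance_trim_to_maximum(self, quiet_world):
        person = quiet_world.people[0]
        others = [p for p in quiet_world.people if p.id != 0][:7]
        for o in others:
            person.allies.add(o.id)
            o.allies.add(0)
        step_environment(quiet_world, TickReport())
        assert len(person.allies) == 5
        assert person.allies <= {o.id for o in others}
        # trimming is mutual
        for o in others:
            assert (0 in o.allies) == (o.id in person.allies)


# ---------------------------------------------------------------------
# step 2: innovation
# ---------------------------------------------------------------------

class TestInnovation:
    def test_new_point_trait_carries_current_environment(self):
        world = init_world(quiet_config(pLuckyLeap=1.0, pEnvChange=0.0))
        world.current_env = 42
        step(world)
        for p in world.people:
            new = [t for t in p.pot_traits | p.point_traits
                   if t.innovation_tick == 1]
            assert len(new) == 1
            if new[0].domain == "point":
                assert new[0].innovation_env == 42
            else:
                assert new[0].innovation_env is None

    def test_no_object_from_empty_repertoire(self):
        world = init_world(quiet_config(pNewObject=1.0))
        world.people[0].point_traits = set()
        step(world)
        assert world.people[0].point_inv == []
        assert len(world.people[0].pot_inv) == 1

    def test_inventory_cap_blocks_creation(self):
        world = init_world(quiet_config(pNewObject=1.0))
        for _ in range(15):
            step(world)
        for p in world.people:
            assert len(p.pot_inv) == 10
            assert len(p.point_inv) == 10

    def test_new_variant_extends_known_type(self):
        world = init_world(quiet_config(pNewVariant=1.0))
        known_types = {t.type_id for t in world.people[0].pot_traits
                       | world.people[0].point_traits}
        step(world)
        for p in world.people:
            added = [t for t in p.pot_traits | p.point_traits
                     if t.innovation_tick == 1]
            assert len(added) == 1
            assert added[0].type_id in known_types


# ---------------------------------------------------------------------
# step 3: aggregation
# ---------------------------------------------------------------------

class TestAggregation:
    def test_no_aggregation_when_probability_zero(self):
        world = init_world(quiet_config(aggregationFreq=0.0, nTicks=30))
        for _ in range(30):
            step(world)
        assert world.ledger.total("visiting") == 0

    def test_pairwise_visiting_counts_per_aggregated_tick(self):
        cfg = quiet_config(nBands=1, campPopulation=4, aggregationFreq=1.0,
                           aggregationDuration=3)
        world = init_world(cfg)
        for _ in range(3):
            step(world)
        members = [p.id for p in world.people]
        n_pairs = len(members) * (len(members) - 1) // 2
        assert n_pairs == 66
        for i in members:
            for j in members[i + 1:]:
                assert world.ledger.count(i, j, "visiting") == 3

    def test_duration_countdown_returns_home(self):
        cfg = quiet_config(aggregationFreq=1.0, aggregationDuration=1)
        world = init_world(cfg)
        step(world)  # aggregation starts, lasts this tick
        assert any(b.aggregating for b in world.bands)
        was = [b.aggregating for b in world.bands]
        step(world)  # countdown expires before a new draw can start it again
        # each band alternates: aggregating one tick, home the next
        assert [b.aggregating for b in world.bands] == [not w for w in was]


# ---------------------------------------------------------------------
# hunting
# ---------------------------------------------------------------------

class TestHunting:
    def test_no_hunts_without_probability(self):
        world = init_world(small_config(pHunting=0.0, nTicks=100))
        for _ in range(100):
            step(world)
        assert world.ledger.total("hunting") == 0

    def test_single_hunt_pair_enumeration(self, quiet_world):
        cfg = quiet_config(huntingGroupSize=4)
        world = init_world(cfg)
        do_hunt(world, world.people[0])
        counts = [(k, v) for k, v in world.ledger.pair_counts.items()
                  if k[2] == "hunting"]
        assert len(counts) == 6  # C(4,2) pairs
        assert all(v == 1 for _, v in counts)
        party = {a for (a, b, _), _ in counts} | {b for (a, b, _), _ in counts}
        assert 0 in party
        assert all(world.people[i].band_id == 0 for i in party)

    def test_party_capped_by_band_size(self):
        cfg = quiet_config(nBands=1, campPopulation=2, huntingGroupSize=6)
        world = init_world(cfg)
        do_hunt(world, world.people[0])
        pairs = [k for k in world.ledger.pair_counts if k[2] == "hunting"]
        assert len(pairs) == 15  # whole band of 6 hunts together

    def test_hunt_success_raises_every_participants_prestige(self):
        cfg = quiet_config(huntingGroupSize=3)
        world = init_world(cfg)
        for _ in range(200):
            do_hunt(world, world.people[0])
        party_prestige = world.people[0].hunt_success
        assert 0 < party_prestige < 200  # success is a per-hunt coin


# ---------------------------------------------------------------------
# visiting and alliances
# ---------------------------------------------------------------------

class TestVisiting:
    def test_no_allies_no_visit(self, quiet_world):
        do_visit(quiet_world, quiet_world.people[0])
        assert quiet_world.ledger.total("visiting") == 0

    def test_visit_drops_two_pots(self):
        cfg = quiet_config(pDropPot=1.0)
        world = init_world(cfg)
        a, b = world.people[0], world.people[12]  # different camps
        a.allies.add(b.id)
        b.allies.add(a.id)
        trait = next(iter(a.pot_traits))
        a.pot_inv.append(ArtifactObject("pot", trait, 0, a.id))
        b.pot_inv.append(ArtifactObject("pot", trait, 0, b.id))
        do_visit(world, a)
        camp = world.camps[b.camp_id]
        assert len(camp.assemblage) == 2
        assert all(o.kind == "pot" for o, _ in camp.assemblage)

    def test_visiting_counts_symmetric_after_run(self):
        world = run_model(small_config(nTicks=150))
        for (a, b, kind), v in world.ledger.pair_counts.items():
            assert world.ledger.count(a, b, kind) == \
                world.ledger.count(b, a, kind) == v

    def test_zero_max_allies_means_no_visits(self):
        world = run_model(small_config(nTicks=100, maximumAlliesN=0,
                                       pVisiting=1.0, pNewAlliance=1.0,
                                       aggregationFreq=0.0))
        assert world.ledger.total("visiting") == 0


class TestAlliances:
    def test_no_growth_without_probability(self):
        world = run_model(small_config(nTicks=100, pNewAlliance=0.0))
        assert all(not p.allies for p in world.people)

    def test_mutual_and_never_own_camp_or_self(self):
        world = init_world(quiet_config())
        for _ in range(60):
            for person in world.people:
                form_alliance(world, person)
        for p in world.people:
            assert p.id not in p.allies
            for a in p.allies:
                assert p.id in world.people[a].allies
                # no migration happened, so residence camps are unchanged
                # since formation time
                assert world.people[a].camp_id != p.camp_id


# ---------------------------------------------------------------------
# step 5: loss
# ---------------------------------------------------------------------

class TestLoss:
    def test_no_loss_at_zero(self):
        world = run_model(small_config(nTicks=80, pLoss=0.0,
                                       transmissionRate=0.0))
        base = init_world(small_config(nTicks=80, pLoss=0.0,
                                       transmissionRate=0.0))
        for p, q in zip(world.people, base.people):
            assert p.pot_traits >= q.pot_traits
            assert p.point_traits >= q.point_traits

    def test_certain_loss_can_empty_a_domain(self):
        world = init_world(quiet_config(pLoss=1.0))
        person = world.people[0]
        only = next(iter(person.pot_traits))
        person.pot_traits = {only}
        person.point_traits = set()
        step_loss(world, TickReport())
        assert person.pot_traits == set() or person.point_traits == set()

    def test_distinct_traits_non_increasing_under_pure_loss(self):
        cfg = quiet_config(pLoss=0.3, nTicks=60)
        world = init_world(cfg)
        from archmatnet.metrics import distinct_traits
        prev = distinct_traits(world, "pot") + distinct_traits(world, "point")
        for _ in range(60):
            step(world)
            cur = distinct_traits(world, "pot") + distinct_traits(world, "point")
            assert cur <= prev
            prev = cur


# ---------------------------------------------------------------------
# transmission
# ---------------------------------------------------------------------

def _lone_world(**overrides):
    return init_world(quiet_config(**overrides))


class TestTransmission:
    def test_known_trait_counts_interaction_without_change(self):
        world = _lone_world()
        learner, model = world.people[0], world.people[1]
        # same camp: identical starting repertoires
        before = set(learner.pot_traits)
        assert transmit(world, learner, [model], "pot")
        assert learner.pot_traits == before
        assert world.ledger.count(learner.id, model.id, "learning") == 1

    def test_conformist_adopts_clear_majority(self):
        world = _lone_world(learningMethod="conformist")
        t_major = Trait("pot", 900, "a", "high", None, 0)
        pool = [world.people[i] for i in (1, 2, 3, 4)]
        for i, p in enumerate(pool):
            p.pot_traits = {t_major} if i < 3 else \
                {Trait("pot", 901 + i, "b", "low", None, 0)}
        learner = world.people[0]
        learner.pot_traits = set()
        for _ in range(20):
            learner.pot_traits.clear()
            assert transmit(world, learner, pool, "pot")
            assert learner.pot_traits == {t_major}

    def test_prestige_copies_from_most_successful_hunter(self):
        world = _lone_world()
        pool = [world.people[i] for i in (1, 2, 3)]
        star = pool[1]
        star.hunt_success = 10
        marker = Trait("point", 950, "c", "high", 0, 0)
        star.point_traits = {marker}
        learner = world.people[0]
        learner.point_traits = set()
        assert transmit(world, learner, pool, "point")
        assert learner.point_traits == {marker}
        assert world.ledger.count(learner.id, star.id, "learning") == 1

    def test_new_trait_triggers_object_creation(self):
        world = _lone_world()
        model = world.people[1]
        marker = Trait("pot", 960, "d", "high", None, 0)
        model.pot_traits = {marker}
        learner = world.people[0]
        learner.pot_traits = set()
        transmit(world, learner, [model], "pot")
        assert len(learner.pot_inv) == 1
        assert learner.pot_inv[0].trait == marker

    def test_empty_pool_no_transmission(self):
        world = _lone_world()
        assert not transmit(world, world.people[0], [], "pot")

    def test_visibility_off_selects_classes_uniformly(self):
        world = _lone_world(visibility=False)
        hi = Trait("pot", 970, "a", "high", None, 0)
        lo = Trait("pot", 971, "b", "low", None, 0)
        model = world.people[1]
        model.pot_traits = {hi, lo}
        learner = world.people[0]
        n_hi = 0
        n = 10_000
        for _ in range(n):
            learner.pot_traits = set()
            transmit(world, learner, [model], "pot")
            n_hi += hi in learner.pot_traits
        from scipy.stats import chisquare
        _, p = chisquare([n_hi, n - n_hi])
        assert p > 0.01

    def test_visibility_on_prefers_high_class(self):
        world = _lone_world(visibility=True)
        hi = Trait("pot", 972, "a", "high", None, 0)
        lo = Trait("pot", 973, "b", "low", None, 0)
        model = world.people[1]
        model.pot_traits = {hi, lo}
        learner = world.people[0]
        n_hi = 0
        for _ in range(2000):
            learner.pot_traits = set()
            transmit(world, learner, [model], "pot")
            n_hi += hi in learner.pot_traits
        assert n_hi / 2000 > 0.8  # ~0.9 by design

    def test_visibility_gate_can_block_transmission(self):
        world = _lone_world(visibility=True)
        lo = Trait("pot", 974, "b", "low", None, 0)
        model = world.people[1]
        model.pot_traits = {lo}
        learner = world.people[0]
        outcomes = []
        for _ in range(500):
            learner.pot_traits = set()
            outcomes.append(transmit(world, learner, [model], "pot"))
        assert any(outcomes) and not all(outcomes)

    def test_adapted_point_variants_preferred(self):
        world = _lone_world()
        world.current_env = 5
        adapted = Trait("point", 980, "a", "high", 5, 0)
        foreign = Trait("point", 981, "b", "high", 3, 0)
        model = world.people[1]
        model.point_traits = {adapted, foreign}
        model.hunt_success = 10
        learner = world.people[0]
        n_adapted = 0
        n = 2000
        for _ in range(n):
            learner.point_traits = set()
            transmit(world, learner, [model], "point")
            n_adapted += adapted in learner.point_traits
        # 0.9 restricted-to-adapted + 0.1 uniform over both -> ~0.95
        assert n_adapted / n > 0.85


# ---------------------------------------------------------------------
# trading
# ---------------------------------------------------------------------

class TestTrading:
    def test_empty_inventories_no_trade(self, quiet_world):
        a, b = quiet_world.people[0], quiet_world.people[1]
        assert not trade(quiet_world, a, b, ("pot", "point"))
        assert quiet_world.ledger.total("trading") == 0

    def test_swap_preserves_sizes_and_multiset(self, quiet_world):
        a, b = quiet_world.people[0], quiet_world.people[1]
        t = next(iter(a.pot_traits))
        objs = [ArtifactObject("point", t, 0, i) for i in range(4)]
        a.point_inv = [objs[0]]
        b.point_inv = objs[1:]
        before = {o for o in a.point_inv + b.point_inv}
        assert trade(quiet_world, a, b, ("point",))
        assert len(a.point_inv) == 1 and len(b.point_inv) == 3
        assert {o for o in a.point_inv + b.point_inv} == before
        assert quiet_world.ledger.count(a.id, b.id, "trading") == 1


# ---------------------------------------------------------------------
# step 7: deposition
# ---------------------------------------------------------------------

class TestDeposition:
    def test_nothing_deposited_without_drop_probabilities(self):
        world = run_model(small_config(nTicks=100, pDropPot=0.0,
                                       pDropPoint=0.0, pHunting=0.0,
                                       pVisiting=0.0))
        assert total_deposited(world) == 0

    def test_global_object_conservation(self):
        world = run_model(small_config(nTicks=300))
        assert world.objects_created == total_held(world) + total_deposited(world)
        assert world.objects_deposited == total_deposited(world)

    def test_deposition_respects_causality(self):
        world = run_model(small_config(nTicks=200))
        for camp in world.camps:
            for obj, dep_tick in camp.assemblage:
                assert obj.creation_tick <= dep_tick


# ---------------------------------------------------------------------
# step 8: migration
# ---------------------------------------------------------------------

class TestMigration:
    def test_migration_disabled_before_onset(self):
        world = init_world(quiet_config(pMigration=1.0, migrationOnsetTick=40))
        for _ in range(40):
            step(world)
        assert world.migration_log == []
        step(world)
        assert world.migration_log  # first possible migration at onset + 1

    def test_camp_sizes_conserved_through_migration(self):
        world = run_model(small_config(nTicks=150, pMigration=0.2,
                                       migrationOnsetTick=10))
        assert world.migration_log
        for camp in world.camps:
            assert len(camp.residents) == 4
            assert all(world.people[i].camp_id == camp.id
                       for i in camp.residents)

    def test_gendered_migration_restricts_movers(self):
        world = run_model(small_config(nTicks=120, pMigration=0.3,
                                       migrationOnsetTick=10,
                                       genderedMigration=True))
        assert world.migration_log
        moved = {m for _, m, p in world.migration_log} | \
                {p for _, m, p in world.migration_log}
        assert all(world.people[i].gender == "A" for i in moved)

    def test_residence_bookkeeping_consistent_after_migration(self):
        world = init_world(quiet_config(pMigration=1.0, migrationOnsetTick=1))
        step(world)
        step(world)
        assert world.migration_log
        for camp in world.camps:
            assert all(world.people[i].camp_id == camp.id
                       for i in camp.residents)
        for p in world.people:
            assert p.band_id == world.camps[p.camp_id].band_id
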