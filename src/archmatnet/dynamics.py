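"""Per-tick scheduler: the eight model steps, executed in fixed order.

Each tick (one simulated month) runs, in order:

1. environmental change (mutating mode) and alliance trimming,
2. innovation (new trait types, new variants, object creation),
3. activities — seasonal aggregation bookkeeping plus, for people who are
   not aggregating, alliance formation, visiting and hunting (aggregating
   people may still hunt from the aggregation site),
4. (activities continue; hunting/visiting consequences happen inline),
5. cultural loss (forgetting one trait),
6. camp-internal cultural transmission and trading,
7. deposition into camp assemblages (the archaeological record),
8. migration (residence-camp swaps), enabled only after the onset tick.

People are always processed in id order so that a run is reproducible from
the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .world_model import (
    INVENTORY_CAP,
    REPERTOIRE_CAP,
    VARIANT_LETTERS,
    ArtifactObject,
    ModelConfig,
    Person,
    Trait,
    WorldState,
    sorted_traits,
    init_world,
)

#: strength of the preference for high-visibility traits when the
#: visibility switch is on (most transmission picks the high class)
HIGH_VISIBILITY_PREFERENCE = 0.9

#: probability a hunt succeeds (drawn once per hunt)
HUNT_SUCCESS_P = 0.5

#: when a point-trait transmission offers environment-adapted candidates,
#: probability the copy is restricted to the adapted ones (functional
#: variants of subsistence tools are preferentially copied)
ADAPTED_PREFERENCE = 0.9

#: the gender allowed to move when gendered migration is on
MIGRATING_GENDER = "A"


@dataclass
class TickReport:
    """Per-tick activity counts (debug/trace plumbing)."""

    tick: int = 0
    env_changes: int = 0
    new_types: int = 0
    new_variants: int = 0
    objects_created: int = 0
    aggregations_started: int = 0
    aggregations_ended: int = 0
    hunts: int = 0
    visits: int = 0
    alliances_formed: int = 0
    traits_lost: int = 0
    transmissions: int = 0
    trades: int = 0
    deposits: int = 0
    migrations: int = 0

    def as_tuple(self) -> tuple:
        return (self.tick, self.env_changes, self.new_types, self.new_variants,
                self.objects_created, self.aggregations_started,
                self.aggregations_ended, self.hunts, self.visits,
                self.alliances_formed, self.traits_lost, self.transmissions,
                self.trades, self.deposits, self.migrations)


# ---------------------------------------------------------------------
# step 1: environment + alliance trim
# ---------------------------------------------------------------------

def step_environment(world: WorldState, report: TickReport) -> None:
    cfg = world.config
    rng = world.rng
    if cfg.envMode == "mutating" and rng.random() < cfg.pEnvChange:
        world.current_env = world.fresh_environment()
        report.env_changes += 1
    cap = cfg.maximumAlliesN
    for p in world.people:
        excess = len(p.allies) - cap
        if excess > 0:
            dropped = rng.sample(sorted(p.allies), excess)
            for d in dropped:
                p.allies.discard(d)
                world.people[d].allies.discard(p.id)


# ---------------------------------------------------------------------
# step 2: innovation
# ---------------------------------------------------------------------

def _person_env(world: WorldState, person: Person) -> int:
    band = world.bands[person.band_id]
    loc = band.aggregation_site if band.aggregating else world.camps[person.camp_id].loc
    return world.environment_at(loc)


def _acquire_trait(world: WorldState, person: Person, trait: Trait) -> bool:
    """Add a trait to the matching repertoire under the memory bound.

    Returns True when the trait was genuinely acquired.  A full repertoire
    rejects new traits: only forgetting (step 5) frees a slot, so with
    zero loss a society's culture freezes once memories fill, while any
    loss sustains turnover - trait extinction and with it cultural
    differentiation between groups.
    """
    repertoire = person.traits(trait.domain)
    if trait in repertoire or len(repertoire) >= REPERTOIRE_CAP:
        return False
    repertoire.add(trait)
    return True


def _create_object(world: WorldState, person: Person, kind: str,
                   report: TickReport) -> bool:
    """Make one object from a random repertoire trait, if possible."""
    repertoire = person.traits(kind)
    inv = person.inventory(kind)
    if not repertoire or len(inv) >= INVENTORY_CAP:
        return False
    trait = world.rng.choice(sorted_traits(repertoire))
    inv.append(ArtifactObject(kind, trait, world.tick, person.id))
    world.objects_created += 1
    report.objects_created += 1
    return True


def step_innovation(world: WorldState, report: TickReport) -> None:
    cfg = world.config
    rng = world.rng
    p_leap, p_var, p_obj = cfg.pLuckyLeap, cfg.pNewVariant, cfg.pNewObject
    for person in world.people:
        if p_leap and rng.random() < p_leap:
            domain = "pot" if rng.random() < 0.5 else "point"
            env = _person_env(world, person) if domain == "point" else None
            trait = Trait(domain, world.fresh_type_id(),
                          rng.choice(VARIANT_LETTERS),
                          "high" if rng.random() < 0.5 else "low",
                          env, world.tick)
            _acquire_trait(world, person, trait)
            report.new_types += 1
            world.trace(person.id, "lucky_leap", (), f"{domain}:{trait.style}")
        if p_var and rng.random() < p_var:
            domain = "pot" if rng.random() < 0.5 else "point"
            repertoire = person.traits(domain)
            if repertoire:
                base = rng.choice(sorted_traits(repertoire))
                held = {t.variant for t in repertoire if t.type_id == base.type_id}
                free = [v for v in VARIANT_LETTERS if v not in held]
                if free:
                    env = _person_env(world, person) if domain == "point" else None
                    trait = Trait(domain, base.type_id, rng.choice(free),
                                  "high" if rng.random() < 0.5 else "low",
                                  env, world.tick)
                    _acquire_trait(world, person, trait)
                    report.new_variants += 1
                    world.trace(person.id, "new_variant", (), f"{domain}:{trait.style}")
        if p_obj:
            if rng.random() < p_obj:
                _create_object(world, person, "pot", report)
            if rng.random() < p_obj:
                _create_object(world, person, "point", report)


# ---------------------------------------------------------------------
# transmission and trading primitives (used by steps 3, 4 and 6)
# ---------------------------------------------------------------------

def transmit(world: WorldState, learner: Person, pool: list[Person],
             domain: str, report: TickReport | None = None) -> bool:
    """One social-learning event; returns True if a transmission happened.

    Prestige mode copies a random trait from the most prestigious pool
    member (points: successful-hunt count; pots: the pottery-prestige
    value), ties broken uniformly.  Conformist mode adopts the modal style
    in the pool, ties broken uniformly.  With the visibility switch on, a
    visibility class is drawn first (high with probability 0.9); if no
    candidate trait belongs to the drawn class nothing is transmitted.
    A realized transmission always increments the learning counter, even
    when the learner already held the trait; a genuinely new trait also
    prompts the learner to make one object of it if the inventory allows.
    """
    if not pool:
        return False
    cfg = world.config
    rng = world.rng

    wanted_class = None
    if cfg.visibility:
        wanted_class = ("high" if rng.random() < HIGH_VISIBILITY_PREFERENCE
                        else "low")
    # subsistence-tool selection: prefer point variants adapted to the
    # environment where the learner currently is
    prefer_adapted = (domain == "point"
                      and rng.random() < ADAPTED_PREFERENCE)
    local_env = _person_env(world, learner) if prefer_adapted else None

    def _filter(traits):
        if wanted_class is not None:
            traits = [t for t in traits if t.visibility == wanted_class]
        if prefer_adapted:
            adapted = [t for t in traits if t.innovation_env == local_env]
            if adapted:
                return adapted
        return list(traits)

    if cfg.learningMethod == "prestige":
        if domain == "point":
            best = max(p.hunt_success for p in pool)
            models = [p for p in pool if p.hunt_success == best]
        else:
            best = max(p.pot_prestige for p in pool)
            models = [p for p in pool if p.pot_prestige == best]
        model = models[0] if len(models) == 1 else rng.choice(models)
        candidates = _filter(model.traits(domain))
        if not candidates:
            return False
        trait = rng.choice(sorted_traits(candidates))
        partner = model
    else:  # conformist: adopt the modal style in the pool
        counts: dict[Trait, int] = {}
        for p in pool:
            for t in p.traits(domain):
                if wanted_class is not None and t.visibility != wanted_class:
                    continue
                counts[t] = counts.get(t, 0) + 1
        if prefer_adapted:
            adapted = {t: c for t, c in counts.items()
                       if t.innovation_env == local_env}
            if adapted:
                counts = adapted
        if not counts:
            return False
        best = max(counts.values())
        modal = sorted_traits(t for t, c in counts.items() if c == best)
        trait = modal[0] if len(modal) == 1 else rng.choice(modal)
        holders = [p for p in pool if trait in p.traits(domain)]
        partner = holders[0] if len(holders) == 1 else rng.choice(holders)

    novel = _acquire_trait(world, learner, trait)
    world.ledger.record(learner, partner, "learning")
    if report is not None:
        report.transmissions += 1
    world.trace(learner.id, "learn", (partner.id,), f"{domain}:{trait.style}")
    if novel:
        inv = learner.inventory(domain)
        if len(inv) < INVENTORY_CAP:
            inv.append(ArtifactObject(domain, trait, world.tick, learner.id))
            world.objects_created += 1
            if report is not None:
                report.objects_created += 1
    return True


def trade(world: WorldState, a: Person, b: Person, kinds: tuple[str, ...],
          report: TickReport | None = None) -> bool:
    """One-for-one object swap between two people.

    A kind with stock on both sides is drawn (fair coin when both kinds
    qualify) and one uniformly random object of that kind changes hands in
    each direction, so per-kind inventory sizes are unchanged and the cap
    holds trivially.  Trading fails silently when no kind has stock on both
    sides.
    """
    rng = world.rng
    tradable = [k for k in kinds if a.inventory(k) and b.inventory(k)]
    if not tradable:
        return False
    kind = tradable[0] if len(tradable) == 1 else rng.choice(tradable)
    inv_a, inv_b = a.inventory(kind), b.inventory(kind)
    ia = rng.randrange(len(inv_a))
    ib = rng.randrange(len(inv_b))
    inv_a[ia], inv_b[ib] = inv_b[ib], inv_a[ia]
    world.ledger.record(a, b, "trading")
    if report is not None:
        report.trades += 1
    world.trace(a.id, "trade", (b.id,), kind)
    world.trace(b.id, "trade", (a.id,), kind)
    return True


def _deposit(world: WorldState, person: Person, kind: str, camp_id: int,
             report: TickReport | None = None) -> bool:
    """Move one uniformly random object of *kind* into a camp assemblage."""
    inv = person.inventory(kind)
    if not inv:
        return False
    obj = inv.pop(world.rng.randrange(len(inv)))
    world.camps[camp_id].assemblage.append((obj, world.tick))
    world.objects_deposited += 1
    if report is not None:
        report.deposits += 1
    world.trace(person.id, "drop", (), f"{kind}@camp{camp_id}")
    return True


# ---------------------------------------------------------------------
# steps 3-4: activities (aggregation, alliances, visiting, hunting)
# ---------------------------------------------------------------------

def _nearest_band_camp(world: WorldState, band_id: int,
                       loc: tuple[int, int]) -> int:
    """Nearest camp of the territory-owning band; ties broken uniformly."""
    band = world.bands[band_id]
    dists = []
    for cid in band.camp_ids:
        cx, cy = world.camps[cid].loc
        dists.append(((cx - loc[0]) ** 2 + (cy - loc[1]) ** 2, cid))
    best = min(d for d, _ in dists)
    nearest = [cid for d, cid in dists if d == best]
    return nearest[0] if len(nearest) == 1 else world.rng.choice(nearest)


def do_hunt(world: WorldState, initiator: Person,
            report: TickReport | None = None) -> None:
    """A group hunt within the initiator's band territory.

    The initiator recruits band-mates (co-aggregated members while
    aggregating) up to the hunting group size and the party moves to a
    random cell in the band territory (next to the aggregation site during
    aggregations).  Success is drawn once per hunt; on success every
    participant's successful-hunt count
    (point prestige) increments.  Hunting pair counters increment for every
    participant pair regardless of success.  Each participant may then drop
    a point (credited to the nearest camp of the territory-owning band),
    trade points with a random co-hunter, or receive one point-trait
    transmission from the party.
    """
    cfg = world.config
    rng = world.rng
    band = world.bands[initiator.band_id]
    mates = [p for p in world.band_members(band.id) if p.id != initiator.id]
    k = min(cfg.huntingGroupSize - 1, len(mates))
    party = [initiator] + (rng.sample(mates, k) if k else [])
    if report is not None:
        report.hunts += 1

    x0, y0, x1, y1 = band.territory
    if band.aggregating:
        ax, ay = band.aggregation_site
        loc = (min(max(ax + rng.choice((-1, 0, 1)), x0), x1 - 1),
               min(max(ay + rng.choice((-1, 0, 1)), y0), y1 - 1))
    else:
        loc = (rng.randrange(x0, x1), rng.randrange(y0, y1))
    success = rng.random() < HUNT_SUCCESS_P
    if success:
        for p in party:
            p.hunt_success += 1

    ledger = world.ledger
    for i, pi in enumerate(party):
        for pj in party[i + 1:]:
            ledger.record(pi, pj, "hunting")
    world.trace(initiator.id, "hunt",
                (p.id for p in party[1:]), f"success={success}")

    drop_camp = _nearest_band_camp(world, band.id, loc)
    for p in party:
        if rng.random() < cfg.pDropPoint:
            _deposit(world, p, "point", drop_camp, report)
        if len(party) > 1 and rng.random() < cfg.pTrading:
            others = [q for q in party if q.id != p.id]
            trade(world, p, rng.choice(others), ("point",), report)
        if rng.random() < cfg.transmissionRate:
            transmit(world, p, [q for q in party if q.id != p.id],
                     "point", report)


def do_visit(world: WorldState, visitor: Person,
             report: TickReport | None = None) -> None:
    """Visit one randomly chosen ally at that ally's residence camp.

    The visitor interacts with every one of their allies currently present
    at that camp (allies away aggregating are missed).  Visiting pair
    counters increment between the visitor and each present ally; every
    participant may drop a pot and/or a point into the visited camp's
    assemblage, trade objects, or receive one transmission (domain by fair
    coin).  The visitor then returns home.
    """
    if not visitor.allies:
        return
    cfg = world.config
    rng = world.rng
    ally_id = rng.choice(sorted(visitor.allies))
    ally = world.people[ally_id]
    camp_id = ally.camp_id
    present = [world.people[i] for i in sorted(visitor.allies)
               if world.people[i].camp_id == camp_id
               and not world.bands[world.people[i].band_id].aggregating]
    if not present:
        return
    if report is not None:
        report.visits += 1
    for p in present:
        world.ledger.record(visitor, p, "visiting")
    world.trace(visitor.id, "visit", (p.id for p in present), f"camp{camp_id}")

    participants = [visitor] + present
    for p in participants:
        if rng.random() < cfg.pDropPot:
            _deposit(world, p, "pot", camp_id, report)
        if rng.random() < cfg.pDropPoint:
            _deposit(world, p, "point", camp_id, report)
        if len(participants) > 1 and rng.random() < cfg.pTrading:
            others = [q for q in participants if q.id != p.id]
            trade(world, p, rng.choice(others), ("pot", "point"), report)
        if rng.random() < cfg.transmissionRate:
            domain = "pot" if rng.random() < 0.5 else "point"
            transmit(world, p, [q for q in participants if q.id != p.id],
                     domain, report)


def form_alliance(world: WorldState, person: Person,
                  report: TickReport | None = None) -> None:
    """Create a mutual alliance with a random person from another camp."""
    if world.config.maximumAlliesN == 0:
        return  # no alliance can be maintained
    candidates = [p.id for p in world.people if p.camp_id != person.camp_id]
    if not candidates:
        return
    other = world.people[world.rng.choice(candidates)]
    if other.id in person.allies:
        return  # duplicate alliance is a no-op
    person.allies.add(other.id)
    other.allies.add(person.id)
    if report is not None:
        report.alliances_formed += 1
    world.trace(person.id, "alliance", (other.id,))


def step_activities(world: WorldState, report: TickReport) -> None:
    cfg = world.config
    rng = world.rng
    ledger = world.ledger

    # aggregation state machine
    for band in world.bands:
        if band.aggregating:
            band.aggregation_ticks_remaining -= 1
            if band.aggregation_ticks_remaining <= 0:
                band.aggregating = False
                report.aggregations_ended += 1
        elif cfg.aggregationFreq and rng.random() < cfg.aggregationFreq:
            band.aggregating = True
            band.aggregation_ticks_remaining = cfg.aggregationDuration
            report.aggregations_started += 1

    # while aggregating, every co-aggregated pair is recorded as visiting
    for band in world.bands:
        if not band.aggregating:
            continue
        members = world.band_members(band.id)
        for i, pi in enumerate(members):
            for pj in members[i + 1:]:
                ledger.record(pi, pj, "visiting")

    p_ally, p_visit, p_hunt = cfg.pNewAlliance, cfg.pVisiting, cfg.pHunting
    for person in world.people:
        if world.bands[person.band_id].aggregating:
            # hunts can still start from the aggregation site
            if p_hunt and rng.random() < p_hunt:
                do_hunt(world, person, report)
            continue
        if p_ally and rng.random() < p_ally:
            form_alliance(world, person, report)
        if p_visit and rng.random() < p_visit:
            do_visit(world, person, report)
        if p_hunt and rng.random() < p_hunt:
            do_hunt(world, person, report)


# ---------------------------------------------------------------------
# step 5: cultural loss
# ---------------------------------------------------------------------

def step_loss(world: WorldState, report: TickReport) -> None:
    cfg = world.config
    rng = world.rng
    p_loss = cfg.pLoss
    if not p_loss:
        return
    for person in world.people:
        if rng.random() < p_loss:
            pooled = sorted_traits(person.pot_traits) + sorted_traits(person.point_traits)
            if not pooled:
                continue
            lost = rng.choice(pooled)
            person.traits(lost.domain).discard(lost)
            report.traits_lost += 1
            world.trace(person.id, "loss", (), f"{lost.domain}:{lost.style}")


# ---------------------------------------------------------------------
# step 6: camp-internal transmission and trading
# ---------------------------------------------------------------------

def step_transmission(world: WorldState, report: TickReport) -> None:
    cfg = world.config
    rng = world.rng
    p_learn, p_trade = cfg.transmissionRate, cfg.pTrading
    if not (p_learn or p_trade):
        return
    for person in world.people:
        pool: list[Person] | None = None
        if p_learn and rng.random() < p_learn:
            pool = world.co_located(person)
            domain = "pot" if rng.random() < 0.5 else "point"
            transmit(world, person, pool, domain, report)
        if p_trade and rng.random() < p_trade:
            if pool is None:
                pool = world.co_located(person)
            if pool:
                trade(world, person, rng.choice(pool), ("pot", "point"), report)


# ---------------------------------------------------------------------
# step 7: deposition (the archaeological record)
# ---------------------------------------------------------------------

def _deposit_camp_for(world: WorldState, person: Person) -> int:
    band = world.bands[person.band_id]
    if band.aggregating:
        # drops at the aggregation site are credited to the nearest band
        # camp (ties uniform)
        return _nearest_band_camp(world, band.id, band.aggregation_site)
    return person.camp_id


def step_deposition(world: WorldState, report: TickReport) -> None:
    cfg = world.config
    rng = world.rng
    p_pot, p_point = cfg.pDropPot, cfg.pDropPoint
    if not (p_pot or p_point):
        return
    for person in world.people:
        if p_pot and rng.random() < p_pot and person.pot_inv:
            _deposit(world, person, "pot", _deposit_camp_for(world, person),
                     report)
        if p_point and rng.random() < p_point and person.point_inv:
            _deposit(world, person, "point", _deposit_camp_for(world, person),
                     report)


# ---------------------------------------------------------------------
# step 8: migration
# ---------------------------------------------------------------------

def step_migration(world: WorldState, report: TickReport) -> None:
    cfg = world.config
    if world.tick <= cfg.migrationOnsetTick or not cfg.pMigration:
        return
    rng = world.rng
    for person in world.people:
        if rng.random() >= cfg.pMigration:
            continue
        if cfg.genderedMigration and person.gender != MIGRATING_GENDER:
            continue
        candidates = [p for p in world.people
                      if p.camp_id != person.camp_id
                      and (not cfg.genderedMigration
                           or p.gender == MIGRATING_GENDER)]
        if not candidates:
            continue
        partner = rng.choice(candidates)
        ca, cb = person.camp_id, partner.camp_id
        world.camps[ca].residents.discard(person.id)
        world.camps[cb].residents.discard(partner.id)
        person.camp_id, partner.camp_id = cb, ca
        person.band_id = world.camps[cb].band_id
        partner.band_id = world.camps[ca].band_id
        world.camps[cb].residents.add(person.id)
        world.camps[ca].residents.add(partner.id)
        world.migration_log.append((world.tick, person.id, partner.id))
        report.migrations += 1
        world.trace(person.id, "migrate", (partner.id,), f"->camp{cb}")


# ---------------------------------------------------------------------
# the scheduler
# ---------------------------------------------------------------------

def step(world: WorldState) -> TickReport:
    """Advance the world by one tick, running steps 1-8 in order."""
    world.tick += 1
    report = TickReport(tick=world.tick)
    step_environment(world, report)
    step_innovation(world, report)
    step_activities(world, report)
    step_loss(world, report)
    step_transmission(world, report)
    step_deposition(world, report)
    step_migration(world, report)
    return report


def run_model(config: ModelConfig,
              snapshot_hook=None,
              trace_person: int | None = None) -> WorldState:
    """Initialize a world and run it for ``config.nTicks`` ticks.

    ``snapshot_hook(world)`` is called whenever the tick is a positive
    multiple of ``config.snapshotInterval`` (the high-resolution export
    cadence).  ``trace_person`` enables the per-person activity trace.
    """
    world = init_world(config)
    if trace_person is not None:
        world.trace_person = trace_person
    interval = config.snapshotInterval
    for _ in range(config.nTicks):
        step(world)
        if snapshot_hook is not None and interval and world.tick % interval == 0:
            snapshot_hook(world)
    return world
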