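"""Domain types, run configuration, and deterministic world initialization.

The simulated world is a square-ish grid partitioned into band territories.
Each band owns three residential camps and one aggregation site; each camp
houses a fixed number of people.  People carry cultural trait repertoires
(pot traits and point traits), bounded object inventories (at most 10 pots
and 10 points), alliance ties, and prestige counters.  Camps accumulate the
simulated archaeological record: every object dropped at a camp stays there.

All randomness flows through a single ``random.Random`` stream owned by the
:class:`WorldState`; stochastic draws consume it in a fixed documented order
(people are always processed in id order), so a run is fully reproducible
from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import random
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import yaml

VARIANT_LETTERS = "abcdefghijklmno"  # variants are discrete letters a-o only

#: grid cells per band territory side
TERRITORY_SIDE = 10

#: starting repertoire size per person, per domain (shared within a camp)
INITIAL_TRAITS_PER_DOMAIN = 5

#: hard cap on objects of each kind a person can carry
INVENTORY_CAP = 10

#: bounded cultural memory: traits of each domain a person can maintain.
#: Acquiring a new trait at the cap evicts a random held trait, so traits
#: can go extinct at the camp level - the motor of cultural
#: differentiation between groups.
REPERTOIRE_CAP = 10


class ConfigurationError(ValueError):
    """Raised when a run configuration violates its invariants."""


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration.

    Field names mirror the simulator's published parameter names.  Every
    ``p*`` field is a per-tick (or per-event, where noted) probability in
    [0, 1]; one tick represents a month.
    """

    nTicks: int = 2000
    nBands: int = 3
    campPopulation: int = 10
    pEnvChange: float = 0.05
    envMode: str = "mutating"  # "zoned" | "mutating"
    aggregationFreq: float = 0.02
    aggregationDuration: int = 5
    pHunting: float = 0.05
    huntingGroupSize: int = 5
    pVisiting: float = 0.05
    pNewAlliance: float = 0.05
    maximumAlliesN: int = 5
    pMigration: float = 0.002
    genderedMigration: bool = False
    pTrading: float = 0.1  # per event
    transmissionRate: float = 0.1  # per event
    learningMethod: str = "prestige"  # "prestige" | "conformist"
    pLuckyLeap: float = 0.005
    pNewVariant: float = 0.01
    pNewObject: float = 0.1
    pLoss: float = 0.01
    potteryPrestige: str = "random_values"  # "random_values" | "single_random_person"
    uniqueTraits: bool = False
    visibility: bool = False
    pDropPot: float = 0.05
    pDropPoint: float = 0.05
    migrationOnsetTick: int = 1000
    snapshotInterval: int = 1000
    randomSeed: int = 42

    _PROB_FIELDS = (
        "pEnvChange", "aggregationFreq", "pHunting", "pVisiting",
        "pNewAlliance", "pMigration", "pTrading", "transmissionRate",
        "pLuckyLeap", "pNewVariant", "pNewObject", "pLoss",
        "pDropPot", "pDropPoint",
    )
    _COUNT_FIELDS = (
        "nTicks", "nBands", "campPopulation", "aggregationDuration",
        "huntingGroupSize",
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in self._PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} outside [0, 1]")
        for name in self._COUNT_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ConfigurationError(f"{name}={v!r} must be a positive integer")
        if self.maximumAlliesN < 0:
            raise ConfigurationError("maximumAlliesN must be >= 0")
        if self.huntingGroupSize > 3 * self.campPopulation:
            raise ConfigurationError(
                "huntingGroupSize cannot exceed band size (3 x campPopulation)"
            )
        if self.envMode not in ("zoned", "mutating"):
            raise ConfigurationError(f"unknown envMode {self.envMode!r}")
        if self.learningMethod not in ("prestige", "conformist"):
            raise ConfigurationError(f"unknown learningMethod {self.learningMethod!r}")
        if self.potteryPrestige not in ("random_values", "single_random_person"):
            raise ConfigurationError(
                f"unknown potteryPrestige {self.potteryPrestige!r}"
            )

    def replace(self, **changes) -> "ModelConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


class Trait(NamedTuple):
    """A transmissible cultural unit.

    ``(type_id, variant)`` is the stylistic identity used by the assemblage
    metrics; ``visibility`` gates transmission when the visibility switch is
    on; ``innovation_env`` records, for point traits only, the environment
    where the trait was innovated (points are adaptive there and nowhere
    else).  Pot traits carry ``innovation_env=None``.
    """

    domain: str  # "pot" | "point"
    type_id: int
    variant: str
    visibility: str  # "high" | "low"
    innovation_env: int | None
    innovation_tick: int

    @property
    def style(self) -> tuple[int, str]:
        return (self.type_id, self.variant)

    def sort_key(self) -> tuple:
        # innovation_env is None for pots; map to -1 so keys are orderable
        return (self.domain, self.type_id, self.variant, self.visibility,
                -1 if self.innovation_env is None else self.innovation_env,
                self.innovation_tick)


def sorted_traits(traits: Iterable["Trait"]) -> list["Trait"]:
    """Deterministic ordering of a trait collection (for seeded sampling)."""
    return sorted(traits, key=Trait.sort_key)


class ArtifactObject(NamedTuple):
    kind: str  # "pot" | "point"
    trait: Trait
    creation_tick: int
    maker_id: int


class Person:
    __slots__ = (
        "id", "gender", "camp_id", "band_id", "pot_traits", "point_traits",
        "pot_inv", "point_inv", "allies", "hunt_success", "pot_prestige",
    )

    def __init__(self, pid: int, gender: str, camp_id: int, band_id: int):
        self.id = pid
        self.gender = gender
        self.camp_id = camp_id
        self.band_id = band_id
        self.pot_traits: set[Trait] = set()
        self.point_traits: set[Trait] = set()
        self.pot_inv: list[ArtifactObject] = []
        self.point_inv: list[ArtifactObject] = []
        self.allies: set[int] = set()
        self.hunt_success = 0
        self.pot_prestige = 0.0

    def traits(self, domain: str) -> set[Trait]:
        return self.pot_traits if domain == "pot" else self.point_traits

    def inventory(self, kind: str) -> list[ArtifactObject]:
        return self.pot_inv if kind == "pot" else self.point_inv

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"Person({self.id}, camp={self.camp_id}, band={self.band_id}, "
                f"|pot|={len(self.pot_traits)}, |point|={len(self.point_traits)})")


class Camp:
    __slots__ = ("id", "band_id", "loc", "residents", "assemblage")

    def __init__(self, cid: int, band_id: int, loc: tuple[int, int]):
        self.id = cid
        self.band_id = band_id
        self.loc = loc
        self.residents: set[int] = set()
        #: archaeological record: (object, deposition tick); only ever grows
        self.assemblage: list[tuple[ArtifactObject, int]] = []


class Band:
    __slots__ = (
        "id", "camp_ids", "territory", "aggregation_site",
        "aggregating", "aggregation_ticks_remaining",
    )

    def __init__(self, bid: int, camp_ids: list[int],
                 territory: tuple[int, int, int, int],
                 aggregation_site: tuple[int, int]):
        self.id = bid
        self.camp_ids = camp_ids  # exactly 3
        self.territory = territory  # (x0, y0, x1, y1), half-open
        self.aggregation_site = aggregation_site
        self.aggregating = False
        self.aggregation_ticks_remaining = 0


class InteractionLedger:
    """Symmetric weighted edge counts per interaction kind.

    Person-pair counts are stored once per unordered pair.  Because people
    migrate, each event is *also* tallied against the camp and band the two
    participants belonged to at event time; these event-time tallies are
    what the migration-safe aggregation uses.
    """

    KINDS = ("hunting", "visiting", "learning", "trading")

    __slots__ = ("pair_counts", "camp_counts", "band_counts")

    def __init__(self):
        self.pair_counts: dict[tuple[int, int, str], int] = {}
        self.camp_counts: dict[tuple[int, int, str], int] = {}
        self.band_counts: dict[tuple[int, int, str], int] = {}

    def record(self, pi: Person, pj: Person, kind: str) -> None:
        a, b = (pi.id, pj.id) if pi.id <= pj.id else (pj.id, pi.id)
        key = (a, b, kind)
        pc = self.pair_counts
        pc[key] = pc.get(key, 0) + 1
        ca, cb = pi.camp_id, pj.camp_id
        if ca > cb:
            ca, cb = cb, ca
        ckey = (ca, cb, kind)
        cc = self.camp_counts
        cc[ckey] = cc.get(ckey, 0) + 1
        ba, bb = pi.band_id, pj.band_id
        if ba > bb:
            ba, bb = bb, ba
        bkey = (ba, bb, kind)
        bc = self.band_counts
        bc[bkey] = bc.get(bkey, 0) + 1

    def count(self, i: int, j: int, kind: str) -> int:
        a, b = (i, j) if i <= j else (j, i)
        return self.pair_counts.get((a, b, kind), 0)

    def total(self, kind: str) -> int:
        return sum(v for (_, _, k), v in self.pair_counts.items() if k == kind)


class WorldState:
    __slots__ = (
        "tick", "config", "rng", "people", "camps", "bands", "ledger",
        "current_env", "_next_type_id", "_next_env_id",
        "pot_prestige_person", "objects_created", "objects_deposited",
        "migration_log", "trace_person", "person_trace",
    )

    def __init__(self, config: ModelConfig):
        self.tick = 0
        self.config = config
        self.rng = random.Random(config.randomSeed)
        self.people: list[Person] = []
        self.camps: list[Camp] = []
        self.bands: list[Band] = []
        self.ledger = InteractionLedger()
        self.current_env = 0  # mutating mode: global environment id
        self._next_type_id = 0
        self._next_env_id = 1
        self.pot_prestige_person: int | None = None
        self.objects_created = 0
        self.objects_deposited = 0
        self.migration_log: list[tuple[int, int, int]] = []  # (tick, mover, partner)
        self.trace_person: int | None = None
        self.person_trace: list[tuple[int, int, str, str, str]] = []

    # -- environment ---------------------------------------------------

    def environment_at(self, loc: tuple[int, int]) -> int:
        """Environment id at a grid cell.

        Zoned mode: one environment per vertical territory strip (so each
        band territory is its own ecological zone).  Mutating mode: a single
        global environment id that may be replaced each tick.
        """
        if self.config.envMode == "zoned":
            return loc[0] // TERRITORY_SIDE
        return self.current_env

    def fresh_environment(self) -> int:
        env = self._next_env_id
        self._next_env_id += 1
        return env

    def fresh_type_id(self) -> int:
        tid = self._next_type_id
        self._next_type_id += 1
        return tid

    # -- location ------------------------------------------------------

    def location_of(self, person: Person):
        """Current residence location: the aggregation site while the
        person's band aggregates, otherwise the residence camp."""
        band = self.bands[person.band_id]
        if band.aggregating:
            return ("aggregation", band.id)
        return ("camp", person.camp_id)

    def co_located(self, person: Person) -> list[Person]:
        """People at the person's current location, excluding the person.

        While the band aggregates this is the whole band; otherwise the
        person's camp co-residents (minus band members away aggregating,
        which cannot happen for one's own camp)."""
        band = self.bands[person.band_id]
        if band.aggregating:
            return [p for p in self.people
                    if p.band_id == band.id and p.id != person.id]
        camp = self.camps[person.camp_id]
        return [self.people[i] for i in sorted(camp.residents) if i != person.id]

    def band_members(self, band_id: int) -> list[Person]:
        return [p for p in self.people if p.band_id == band_id]

    def trace(self, pid: int, activity: str, partners: Iterable[int] = (),
              detail: str = "") -> None:
        if self.trace_person is not None and pid == self.trace_person:
            self.person_trace.append(
                (self.tick, pid, activity,
                 ";".join(str(x) for x in partners), detail))

    # -- serialization helpers ----------------------------------------

    def serialize(self) -> str:
        """Deterministic textual snapshot of the full state (for
        reproducibility checks)."""
        parts = [f"tick={self.tick}", f"env={self.current_env}"]
        for p in self.people:
            parts.append(
                f"P{p.id}|{p.gender}|c{p.camp_id}|b{p.band_id}"
                f"|pot={[t.sort_key() for t in sorted_traits(p.pot_traits)]!r}"
                f"|point={[t.sort_key() for t in sorted_traits(p.point_traits)]!r}"
                f"|inv={sorted(o[:1] + (o.trait.style,) + o[2:] for o in p.pot_inv + p.point_inv)!r}"
                f"|allies={sorted(p.allies)}"
                f"|hs={p.hunt_success}|pp={p.pot_prestige!r}")
        for c in self.camps:
            parts.append(
                f"C{c.id}|b{c.band_id}|res={sorted(c.residents)}"
                f"|asm={sorted((o.kind, o.trait.style, o.creation_tick, o.maker_id, t) for o, t in c.assemblage)!r}")
        return "\n".join(parts)


def _make_initial_pool(world: WorldState, domain: str) -> list[tuple[int, str, str]]:
    """Draw (type_id, variant, visibility) templates for a starting pool."""
    rng = world.rng
    pool = []
    for _ in range(INITIAL_TRAITS_PER_DOMAIN):
        pool.append((
            world.fresh_type_id(),
            rng.choice(VARIANT_LETTERS),
            "high" if rng.random() < 0.5 else "low",
        ))
    return pool


def init_world(config: ModelConfig) -> WorldState:
    """Build the initial world deterministically from the configuration.

    Layout: band ``b`` owns the vertical strip ``[b*10, (b+1)*10) x [0, 10)``
    with three camps placed symmetrically around the territory center, which
    hosts the aggregation site.  Camps are populated with ``campPopulation``
    people of alternating gender.  Every person in a camp starts with that
    camp's shared starting repertoire (5 pot and 5 point traits); with
    ``uniqueTraits`` the camps' starting type ids are mutually disjoint,
    otherwise all camps share one pool of styles (point traits are
    instantiated per camp so that they are adaptive in the camp's own
    environment).
    """
    config.validate()
    world = WorldState(config)
    rng = world.rng

    shared_pools = None
    if not config.uniqueTraits:
        shared_pools = {
            "pot": _make_initial_pool(world, "pot"),
            "point": _make_initial_pool(world, "point"),
        }

    pid = 0
    for b in range(config.nBands):
        x0 = b * TERRITORY_SIDE
        cx = x0 + TERRITORY_SIDE // 2
        cy = TERRITORY_SIDE // 2
        camp_locs = [(cx - 3, cy), (cx + 3, cy), (cx, cy + 3)]
        camp_ids = []
        for loc in camp_locs:
            cid = len(world.camps)
            world.camps.append(Camp(cid, b, loc))
            camp_ids.append(cid)
        world.bands.append(
            Band(b, camp_ids, (x0, 0, x0 + TERRITORY_SIDE, TERRITORY_SIDE),
                 (cx, cy)))

        for cid in camp_ids:
            camp = world.camps[cid]
            camp_env = world.environment_at(camp.loc)
            if config.uniqueTraits:
                pools = {
                    "pot": _make_initial_pool(world, "pot"),
                    "point": _make_initial_pool(world, "point"),
                }
            else:
                pools = shared_pools
            camp_traits = {
                "pot": {Trait("pot", t, v, vis, None, 0)
                        for t, v, vis in pools["pot"]},
                "point": {Trait("point", t, v, vis, camp_env, 0)
                          for t, v, vis in pools["point"]},
            }
            for n in range(config.campPopulation):
                person = Person(pid, "A" if n % 2 == 0 else "B", cid, b)
                person.pot_traits = set(camp_traits["pot"])
                person.point_traits = set(camp_traits["point"])
                camp.residents.add(pid)
                world.people.append(person)
                pid += 1

    if config.potteryPrestige == "random_values":
        for p in world.people:
            p.pot_prestige = rng.random()
    else:  # single_random_person
        chosen = rng.randrange(len(world.people))
        world.pot_prestige_person = chosen
        world.people[chosen].pot_prestige = 1.0

    return world
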