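"""Run serialization: the four result CSVs, migration-safe adjacency
aggregation, and high-resolution snapshots.

All CSVs are comma-separated UTF-8 with a header row and a deterministic
row sort, so a re-run with the same configuration and seed reproduces them
byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from .metrics import assemblage_counts, jaccard_distance_matrix
from .world_model import WorldState

ASSEMBLAGE_COLUMNS = ["camp", "band", "kind", "typeId", "variant",
                      "creationTick", "depositionTick", "makerId"]
INTERACTION_COLUMNS = ["personA", "personB", "kind", "count"]
PERSON_COLUMNS = ["personId", "gender", "campId", "bandId"]
PARAMETER_COLUMNS = ["name", "value"]


@dataclass
class RunArtifacts:
    """Paths of the files written for one run."""

    assemblages: str
    interactions: str
    persons: str
    parameters: str
    snapshots: list[str]
    person_trace: str | None = None

    def core_files(self) -> list[str]:
        return [self.assemblages, self.interactions, self.persons,
                self.parameters]


def assemblages_frame(world: WorldState) -> pd.DataFrame:
    rows = []
    for camp in world.camps:
        for obj, dep_tick in camp.assemblage:
            rows.append((camp.id, camp.band_id, obj.kind, obj.trait.type_id,
                         obj.trait.variant, obj.creation_tick, dep_tick,
                         obj.maker_id))
    df = pd.DataFrame(rows, columns=ASSEMBLAGE_COLUMNS)
    return df.sort_values(ASSEMBLAGE_COLUMNS, kind="mergesort",
                          ignore_index=True)


def interactions_frame(world: WorldState) -> pd.DataFrame:
    rows = [(a, b, kind, count)
            for (a, b, kind), count in world.ledger.pair_counts.items()]
    df = pd.DataFrame(rows, columns=INTERACTION_COLUMNS)
    return df.sort_values(INTERACTION_COLUMNS, kind="mergesort",
                          ignore_index=True)


def persons_frame(world: WorldState) -> pd.DataFrame:
    rows = [(p.id, p.gender, p.camp_id, p.band_id) for p in world.people]
    return pd.DataFrame(rows, columns=PERSON_COLUMNS)


def parameters_frame(world: WorldState) -> pd.DataFrame:
    cfg = world.config.to_dict()
    rows = [(name, cfg[name]) for name in sorted(cfg)]
    return pd.DataFrame(rows, columns=PARAMETER_COLUMNS)


def write_results(world: WorldState, out_dir: str) -> RunArtifacts:
    """Write the four result CSVs: assemblages, interactions, person
    metadata and run parameters (including the seed)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, frame in (
        ("assemblages", assemblages_frame(world)),
        ("interactions", interactions_frame(world)),
        ("persons", persons_frame(world)),
        ("parameters", parameters_frame(world)),
    ):
        path = os.path.join(out_dir, f"{name}.csv")
        frame.to_csv(path, index=False)
        paths[name] = path
    trace_path = None
    if world.trace_person is not None:
        trace_path = os.path.join(out_dir, "person_trace.csv")
        pd.DataFrame(world.person_trace,
                     columns=["tick", "personId", "activity", "partnerIds",
                              "detail"]).to_csv(trace_path, index=False)
    return RunArtifacts(paths["assemblages"], paths["interactions"],
                        paths["persons"], paths["parameters"], [],
                        trace_path)


# ---------------------------------------------------------------------
# adjacency aggregation
# ---------------------------------------------------------------------

def _counts_to_matrix(counts: dict[tuple[int, int, str], int],
                      entities: list[int],
                      kind: str | None) -> pd.DataFrame:
    mat = pd.DataFrame(0, index=entities, columns=entities)
    for (a, b, k), c in counts.items():
        if kind is not None and k != kind:
            continue
        mat.loc[a, b] += c
        if a != b:
            mat.loc[b, a] += c
    return mat


def aggregate_adjacency(world: WorldState,
                        level: str = "camp",
                        kind: str | None = None) -> pd.DataFrame:
    """Migration-safe adjacency table between camps or bands.

    Every interaction was tallied against the camp/band membership of both
    participants *at event time*, so the table is accurate even when people
    migrated afterwards.  ``kind`` restricts to one interaction kind
    (hunting/visiting/learning/trading); None sums all kinds.
    """
    ledger = world.ledger
    if level == "camp":
        return _counts_to_matrix(ledger.camp_counts,
                                 [c.id for c in world.camps], kind)
    if level == "band":
        return _counts_to_matrix(ledger.band_counts,
                                 [b.id for b in world.bands], kind)
    raise ValueError(f"unknown level {level!r}")


def naive_adjacency(world: WorldState,
                    level: str = "camp",
                    kind: str | None = None) -> pd.DataFrame:
    """Adjacency table built from final memberships (inaccurate after
    migration; kept for comparison with :func:`aggregate_adjacency`)."""
    if level == "camp":
        entities = [c.id for c in world.camps]
        member = {p.id: p.camp_id for p in world.people}
    elif level == "band":
        entities = [b.id for b in world.bands]
        member = {p.id: p.band_id for p in world.people}
    else:
        raise ValueError(f"unknown level {level!r}")
    counts: dict[tuple[int, int, str], int] = {}
    for (i, j, k), c in world.ledger.pair_counts.items():
        a, b = sorted((member[i], member[j]))
        key = (a, b, k)
        counts[key] = counts.get(key, 0) + c
    return _counts_to_matrix(counts, entities, kind)


# ---------------------------------------------------------------------
# high-resolution snapshots
# ---------------------------------------------------------------------

def highres_snapshot(world: WorldState, out_dir: str) -> list[str]:
    """Write interaction adjacency tables and pot/point weighted-Jaccard
    matrices (camp and band level) suffixed with the current tick."""
    os.makedirs(out_dir, exist_ok=True)
    t = world.tick
    written = []
    for level in ("camp", "band"):
        path = os.path.join(out_dir, f"interactions_{level}_tick{t}.csv")
        aggregate_adjacency(world, level).to_csv(path)
        written.append(path)
        for kind in ("pot", "point"):
            vectors = assemblage_counts(world, kind, level, max_tick=t)
            path = os.path.join(out_dir, f"jaccard_{kind}_{level}_tick{t}.csv")
            jaccard_distance_matrix(vectors).to_csv(path)
            written.append(path)
    return written
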