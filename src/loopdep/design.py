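"""Experimental design: multi-element events, encoding and retrieval schedules.

Events associate one element from each of several semantic categories.  The
three analysis categories are ``location``, ``people`` and ``object``; the
object category merges a literal-object and an animal stimulus pool, with an
``animal_flag`` retained because one scheduling constraint and lure selection
distinguish the two pools.

Closed-loop events bind 3 elements with all 3 pairwise associations
(AB-BC-CA, a cycle); open-loop events bind 4 elements with 3 chained
associations (AB-BC-CD).  Encoding presents one association of each event per
block over 3 blocks; retrieval probes every association of every event in
both cue->target directions over 6 blocks of 4-alternative forced choice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("location", "people", "object")

#: short labels used in trial_type strings, e.g. "loc-obj"
CATEGORY_ABBREV = {"location": "loc", "people": "peo", "object": "obj"}

# timing constants (seconds)
ENCODING_STIM_DURATION = 6.0
RETRIEVAL_MAX_DURATION = 6.0
CONFIDENCE_WINDOW = 6.0
ISI = 1.5
FIXATION = 0.5


@dataclass(frozen=True)
class Element:
    """A single event element: an opaque token with an analysis category."""

    element_id: str
    category: str
    animal_flag: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.animal_flag and self.category != "object":
            raise ValueError("animal_flag only applies to object elements")


@dataclass
class EventStructure:
    """One multi-element event and its encoded associations.

    ``associations`` is ordered by encoding block: ``associations[b]`` is the
    pair presented in block ``b + 1``.  Closed events have 3 elements whose
    associations form a cycle; open events have 4 elements chained A-B-C-D.
    """

    event_id: str
    loop_type: str  # "closed" | "open"
    elements: list[Element]
    associations: list[tuple[str, str]]

    def element(self, element_id: str) -> Element:
        for el in self.elements:
            if el.element_id == element_id:
                return el
        raise KeyError(element_id)

    def validate(self) -> None:
        n_expected = 3 if self.loop_type == "closed" else 4
        if self.loop_type not in ("closed", "open"):
            raise ValueError(f"bad loop_type {self.loop_type!r}")
        if len(self.elements) != n_expected:
            raise ValueError(
                f"{self.loop_type} event {self.event_id} has "
                f"{len(self.elements)} elements, expected {n_expected}"
            )
        if len(self.associations) != 3:
            raise ValueError("every event has exactly 3 associations")
        ids = [el.element_id for el in self.elements]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate element in event")
        degree: dict[str, int] = {i: 0 for i in ids}
        seen = set()
        for a, b in self.associations:
            if a not in degree or b not in degree:
                raise ValueError("association references unknown element")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError("duplicate association")
            seen.add(key)
            degree[a] += 1
            degree[b] += 1
        if self.loop_type == "closed":
            if any(d != 2 for d in degree.values()):
                raise ValueError("closed event associations must form a cycle")
        else:
            if sorted(degree.values()) != [1, 1, 2, 2]:
                raise ValueError("open event associations must form a chain")


@dataclass
class EventSet:
    """The full collection of events for one participant/session."""

    events: list[EventStructure]

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    @property
    def closed(self) -> list[EventStructure]:
        return [e for e in self.events if e.loop_type == "closed"]

    @property
    def open(self) -> list[EventStructure]:
        return [e for e in self.events if e.loop_type == "open"]

    def elements_by_pool(self) -> dict[tuple[str, bool], list[Element]]:
        pools: dict[tuple[str, bool], list[Element]] = {}
        for ev in self.events:
            for el in ev.elements:
                pools.setdefault((el.category, el.animal_flag), []).append(el)
        return pools

    def event(self, event_id: str) -> EventStructure:
        for ev in self.events:
            if ev.event_id == event_id:
                return ev
        raise KeyError(event_id)


@dataclass
class DesignConfig:
    """Counts and timing of the default experiment.

    Defaults reproduce the canonical design: 36 events total, 18 closed-loop
    (9 with a literal object, 9 with an animal) and 18 open-loop 4-element
    chains containing both an object and an animal.
    """

    n_closed: int = 18
    n_open: int = 18
    pool_sizes: dict = field(
        default_factory=lambda: {
            "location": 40,
            "people": 40,
            "object": 40,
            "animal": 40,
        }
    )
    shared_event_set: bool = False  # one fixed set reused across participants
    encoding_stim_duration: float = ENCODING_STIM_DURATION
    retrieval_max_duration: float = RETRIEVAL_MAX_DURATION
    confidence_window: float = CONFIDENCE_WINDOW
    isi: float = ISI
    fixation: float = FIXATION


def _make_pools(config: DesignConfig) -> dict[str, list[Element]]:
    """Build fresh element pools; ids are category-prefixed tokens."""
    pools = {}
    for name, size in config.pool_sizes.items():
        if name == "animal":
            pools[name] = [
                Element(f"ani_{i:03d}", "object", animal_flag=True)
                for i in range(size)
            ]
        else:
            abbrev = CATEGORY_ABBREV.get(name, name[:3])
            pools[name] = [Element(f"{abbrev}_{i:03d}", name) for i in range(size)]
    return pools


def _draw(pools: dict[str, list[Element]], name: str) -> Element:
    if not pools.get(name):
        raise ValueError(f"element pool exhausted for category {name!r}")
    return pools[name].pop()


def _order_closed(elements: list[Element], rng: np.random.Generator) -> list[tuple[str, str]]:
    """Order a closed event's 3 associations over encoding blocks.

    All 3 pairwise associations of {L, O, P} are encoded; block 3 must pair
    the object/animal element with either the location or the people element.
    """
    by_cat = {el.category: el for el in elements}
    obj = by_cat["object"]
    partner = by_cat[["location", "people"][rng.integers(2)]]
    block3 = (partner.element_id, obj.element_id)
    others = [
        tuple(sorted((a.element_id, b.element_id)))
        for a, b in itertools.combinations(elements, 2)
        if frozenset((a.element_id, b.element_id)) != frozenset(block3)
    ]
    if rng.integers(2):
        others = others[::-1]
    return [others[0], others[1], block3]


def _order_open(elements: list[Element], rng: np.random.Generator) -> list[tuple[str, str]]:
    """Choose a chain ordering A-B-C-D for an open event.

    The block-3 association is the chain's final pair (C, D); it must combine
    an object-pool or animal-pool element with a location or people element.
    """
    valid = []
    for perm in itertools.permutations(elements):
        c, d = perm[2], perm[3]
        cats = {c.category, d.category}
        if cats == {"object"} or "object" not in cats:
            continue
        valid.append(perm)
    if not valid:
        raise ValueError("no chain ordering satisfies the block-3 constraint")
    perm = valid[rng.integers(len(valid))]
    ids = [el.element_id for el in perm]
    return [(ids[0], ids[1]), (ids[1], ids[2]), (ids[2], ids[3])]


def build_event_set(config: DesignConfig | None = None, rng=None) -> EventSet:
    """Generate the event set: closed-loop triads and open-loop chains.

    Closed events split into two sub-pools by category composition
    (location-object-people vs location-animal-people); open events draw one
    element from each of the four stimulus pools.  No element is reused
    across events.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(rng)
    pools = _make_pools(config)
    for p in pools.values():
        rng.shuffle(p)

    events: list[EventStructure] = []
    n_animal_closed = config.n_closed // 2
    for i in range(config.n_closed):
        obj_pool = "animal" if i < n_animal_closed else "object"
        elements = [
            _draw(pools, "location"),
            _draw(pools, obj_pool),
            _draw(pools, "people"),
        ]
        ev = EventStructure(
            event_id=f"ev{i:02d}c",
            loop_type="closed",
            elements=elements,
            associations=_order_closed(elements, rng),
        )
        ev.validate()
        events.append(ev)
    for i in range(config.n_open):
        elements = [
            _draw(pools, "location"),
            _draw(pools, "object"),
            _draw(pools, "animal"),
            _draw(pools, "people"),
        ]
        ev = EventStructure(
            event_id=f"ev{i:02d}o",
            loop_type="open",
            elements=elements,
            associations=_order_open(elements, rng),
        )
        ev.validate()
        events.append(ev)
    return EventSet(events)


def _trial_type(ev: EventStructure, first: str, second: str) -> str:
    c1 = CATEGORY_ABBREV[ev.element(first).category]
    c2 = CATEGORY_ABBREV[ev.element(second).category]
    return f"{c1}-{c2}"


def build_encoding_schedule(
    event_set: EventSet, config: DesignConfig | None = None, rng=None
) -> pd.DataFrame:
    """Schedule encoding: 3 blocks, one association of each event per block.

    Within each block the order of events is randomised.  Onsets lie on a
    regular grid (fixation + stimulus + inter-stimulus interval per slot).
    Returns a tidy DataFrame, one row per encoding trial.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(rng)
    slot = config.fixation + config.encoding_stim_duration + config.isi
    rows = []
    trial_index = 0
    for block in range(1, 4):
        order = np.arange(len(event_set.events))
        rng.shuffle(order)
        for k in order:
            ev = event_set.events[k]
            a, b = ev.associations[block - 1]
            if block == 3:
                cats = {ev.element(a).category, ev.element(b).category}
                if "object" not in cats or cats == {"object"}:
                    raise ValueError(
                        f"event {ev.event_id}: block-3 pair violates the "
                        "location/people-with-object constraint"
                    )
            rows.append(
                {
                    "onset": trial_index * slot + config.fixation,
                    "duration": config.encoding_stim_duration,
                    "trial_type": _trial_type(ev, a, b),
                    "block": block,
                    "event_id": ev.event_id,
                    "loop_type": ev.loop_type,
                    "elem1_id": a,
                    "elem2_id": b,
                }
            )
            trial_index += 1
    return pd.DataFrame(rows)


def _lures(
    event_set: EventSet,
    ev: EventStructure,
    target: Element,
    rng: np.random.Generator,
) -> list[str]:
    """3 lures sharing the target's stimulus pool, drawn from other events."""
    candidates = [
        el.element_id
        for other in event_set.events
        if other.event_id != ev.event_id
        for el in other.elements
        if el.category == target.category and el.animal_flag == target.animal_flag
    ]
    if len(candidates) < 3:
        raise ValueError(
            f"fewer than 3 lure candidates for category {target.category!r} "
            f"(animal_flag={target.animal_flag})"
        )
    pick = rng.choice(len(candidates), size=3, replace=False)
    return [candidates[i] for i in sorted(pick)]


def build_retrieval_schedule(
    event_set: EventSet, config: DesignConfig | None = None, rng=None
) -> pd.DataFrame:
    """Schedule retrieval: 6 blocks, every association probed bidirectionally.

    Each event contributes 6 trials (3 associations x 2 cue->target
    directions) placed one per block in a random per-event permutation.
    Lures share the target's stimulus pool and come from other events.
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(rng)
    slot = (
        config.fixation
        + config.retrieval_max_duration
        + config.confidence_window
        + config.isi
    )
    per_event_trials = {}
    for ev in event_set.events:
        directed = []
        for a, b in ev.associations:
            directed.append((a, b))
            directed.append((b, a))
        order = np.arange(6)
        rng.shuffle(order)
        per_event_trials[ev.event_id] = [directed[i] for i in order]

    rows = []
    trial_index = 0
    for block in range(1, 7):
        order = np.arange(len(event_set.events))
        rng.shuffle(order)
        for k in order:
            ev = event_set.events[k]
            cue_id, target_id = per_event_trials[ev.event_id][block - 1]
            target = ev.element(target_id)
            lures = _lures(event_set, ev, target, rng)
            rows.append(
                {
                    "onset": trial_index * slot + config.fixation,
                    "duration": config.retrieval_max_duration,
                    "trial_type": _trial_type(ev, cue_id, target_id),
                    "block": block,
                    "event_id": ev.event_id,
                    "loop_type": ev.loop_type,
                    "cue_id": cue_id,
                    "cue_category": ev.element(cue_id).category,
                    "target_id": target_id,
                    "target_category": target.category,
                    "lure1": lures[0],
                    "lure2": lures[1],
                    "lure3": lures[2],
                }
            )
            trial_index += 1
    return pd.DataFrame(rows)
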