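"""Domain types and construction of grooming / aggression networks from event records.

The central object is :class:`SocialNetwork`, a thin wrapper around a
:mod:`networkx` graph whose edge weights are hourly interaction rates
(grooming seconds per hour, or aggressive acts per hour).  Networks are
built from plain delimited-text tables: a roster of individuals, a table
of focal observation hours, and a table of dyadic interaction events.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "AgeClass",
    "Sex",
    "Behaviour",
    "AgeSexClass",
    "Individual",
    "Roster",
    "ObservationEffort",
    "InteractionEvent",
    "SocialNetwork",
    "Normalization",
    "merge_grooming_bouts",
    "build_grooming_network",
    "build_aggression_network",
    "symmetrise",
    "read_roster",
    "write_roster",
    "read_effort",
    "write_effort",
    "read_events",
    "write_events",
    "write_network",
    "read_network",
    "DEFAULT_BOUT_GAP_S",
]

#: Maximum pause (seconds) between two same-dyad, same-direction grooming
#: events for them to count as one continuous bout.
DEFAULT_BOUT_GAP_S = 30.0


class AgeClass(str, enum.Enum):
    INFANT = "infant"
    JUVENILE = "juvenile"
    SUBADULT = "subadult"
    ADULT = "adult"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Behaviour(str, enum.Enum):
    GROOMING = "grooming"
    AGGRESSION = "aggression"


@dataclass(frozen=True)
class AgeSexClass:
    """An (age class, sex) pair, the unit of class-level comparison."""

    age_class: AgeClass
    sex: Sex

    @property
    def label(self) -> str:
        return f"{self.age_class.value}_{self.sex.value}"

    @classmethod
    def from_label(cls, label: str) -> "AgeSexClass":
        age, _, sex = label.rpartition("_")
        return cls(AgeClass(age), Sex(sex))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class Individual:
    id: str
    age_sex: AgeSexClass
    is_study_subject: bool = True

    @property
    def age_class(self) -> AgeClass:
        return self.age_sex.age_class

    @property
    def sex(self) -> Sex:
        return self.age_sex.sex


class Roster:
    """Ordered collection of individuals with unique ids."""

    def __init__(self, individuals: Iterable[Individual]):
        self._individuals = list(individuals)
        if not self._individuals:
            raise ValueError("roster must not be empty")
        seen: set[str] = set()
        for ind in self._individuals:
            if ind.id in seen:
                raise ValueError(f"duplicate id in roster: {ind.id!r}")
            seen.add(ind.id)
        self._by_id = {ind.id: ind for ind in self._individuals}

    def __len__(self) -> int:
        return len(self._individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._individuals)

    def __contains__(self, id_: str) -> bool:
        return id_ in self._by_id

    def __getitem__(self, id_: str) -> Individual:
        try:
            return self._by_id[id_]
        except KeyError:
            raise KeyError(f"unknown individual id: {id_!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Roster):
            return NotImplemented
        return self._individuals == other._individuals

    @property
    def individuals(self) -> list[Individual]:
        return list(self._individuals)

    @property
    def study_subjects(self) -> list[Individual]:
        return [i for i in self._individuals if i.is_study_subject]

    @property
    def study_ids(self) -> list[str]:
        return [i.id for i in self.study_subjects]

    def ids_in_class(
        self,
        age_class: AgeClass | str | None = None,
        sex: Sex | str | None = None,
        study_only: bool = True,
    ) -> list[str]:
        """Ids of (study) individuals matching an age class and/or sex."""
        age_class = AgeClass(age_class) if age_class is not None else None
        sex = Sex(sex) if sex is not None else None
        out = []
        for ind in self._individuals:
            if study_only and not ind.is_study_subject:
                continue
            if age_class is not None and ind.age_class != age_class:
                continue
            if sex is not None and ind.sex != sex:
                continue
            out.append(ind.id)
        return out

    def class_map(self, study_only: bool = True) -> dict[str, str]:
        """Mapping id -> age-sex label (e.g. ``\"adult_female\"``)."""
        inds = self.study_subjects if study_only else self._individuals
        return {i.id: i.age_sex.label for i in inds}


@dataclass
class ObservationEffort:
    """Focal observation hours per individual."""

    hours: dict[str, float]

    def __post_init__(self) -> None:
        for id_, h in self.hours.items():
            if not h > 0:
                raise ValueError(f"focal hours must be > 0 (id {id_!r}: {h})")

    def __getitem__(self, id_: str) -> float:
        try:
            return self.hours[id_]
        except KeyError:
            raise KeyError(f"no observation effort recorded for id {id_!r}") from None

    def __contains__(self, id_: str) -> bool:
        return id_ in self.hours

    @property
    def total(self) -> float:
        return float(sum(self.hours.values()))


@dataclass(frozen=True)
class InteractionEvent:
    """One observed dyadic behaviour.

    Grooming events carry a duration in seconds; aggression events are
    point events with an implicit count of one.  ``start_time_s`` is only
    required for grooming when bout merging is requested.
    """

    actor: str
    recipient: str
    behaviour: Behaviour
    start_time_s: float | None = None
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.actor == self.recipient:
            raise ValueError(f"self-interaction not allowed (id {self.actor!r})")
        if self.behaviour is Behaviour.GROOMING:
            if self.duration_s is None or self.duration_s < 0:
                raise ValueError("grooming events require a non-negative duration_s")
        elif self.duration_s is not None:
            raise ValueError("aggression events must not carry a duration")

    @property
    def end_time_s(self) -> float | None:
        if self.start_time_s is None or self.duration_s is None:
            return None
        return self.start_time_s + self.duration_s


class Normalization(str, enum.Enum):
    """Denominator used to turn dyadic totals into hourly rates."""

    DYAD_HOURS = "dyad_hours"      # hours(actor) + hours(recipient)
    ACTOR_HOURS = "actor_hours"    # hours(actor)
    TOTAL_HOURS = "total_hours"    # sum of hours over all study subjects


@dataclass
class SocialNetwork:
    """Weighted social network over rostered study subjects.

    ``graph`` is a :class:`networkx.DiGraph` for directed networks and a
    :class:`networkx.Graph` after symmetrisation.  Nodes carry
    ``age_class``, ``sex`` and ``age_sex`` attributes; edges carry a
    positive ``weight`` (hourly rate).  Absent edges mean rate zero.
    """

    graph: nx.DiGraph | nx.Graph
    behaviour: str = "interaction"

    @property
    def directed(self) -> bool:
        return self.graph.is_directed()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        data = self.graph.get_edge_data(u, v)
        return float(data["weight"]) if data else 0.0

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def copy(self) -> "SocialNetwork":
        return SocialNetwork(self.graph.copy(), self.behaviour)

    def without_nodes(self, ids: Iterable[str]) -> "SocialNetwork":
        """New network with the given nodes (and incident edges) deleted."""
        ids = set(ids)
        missing = ids - set(self.graph.nodes)
        if missing:
            raise KeyError(f"nodes not in network: {sorted(missing)}")
        g = self.graph.copy()
        g.remove_nodes_from(ids)
        return SocialNetwork(g, self.behaviour)

    def node_class(self, id_: str) -> str:
        return self.graph.nodes[id_]["age_sex"]

    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {(u, v): float(d["weight"]) for u, v, d in self.graph.edges(data=True)}

    @classmethod
    def empty(cls, roster: Roster, behaviour: str = "interaction",
              directed: bool = True) -> "SocialNetwork":
        g: nx.DiGraph | nx.Graph = nx.DiGraph() if directed else nx.Graph()
        for ind in roster.study_subjects:
            g.add_node(
                ind.id,
                age_class=ind.age_class.value,
                sex=ind.sex.value,
                age_sex=ind.age_sex.label,
            )
        return cls(g, behaviour)


# ---------------------------------------------------------------------------
# bout merging
# ---------------------------------------------------------------------------

def merge_grooming_bouts(
    events: Sequence[InteractionEvent],
    max_gap_s: float = DEFAULT_BOUT_GAP_S,
) -> list[InteractionEvent]:
    """Merge grooming events interrupted for at most ``max_gap_s`` seconds.

    Events must be sorted by (actor, recipient, start_time) and all be
    grooming.  Consecutive events of the same directed dyad whose pause
    (gap between the end of one event and the start of the next) is at
    most ``max_gap_s`` are merged into a single bout whose duration is the
    sum of the component durations.  A change of partner or of direction
    always starts a new bout.
    """
    for ev in events:
        if ev.behaviour is not Behaviour.GROOMING:
            raise ValueError("merge_grooming_bouts accepts grooming events only")
        if ev.start_time_s is None:
            raise ValueError("bout merging requires start_time_s on every event")
    key = [(ev.actor, ev.recipient, ev.start_time_s) for ev in events]
    if key != sorted(key):
        raise ValueError("events must be sorted by (actor, recipient, start_time)")

    merged: list[InteractionEvent] = []
    last_end = 0.0  # true end of the previous component (pauses included)
    for ev in events:
        if merged:
            prev = merged[-1]
            same_dyad = (prev.actor, prev.recipient) == (ev.actor, ev.recipient)
            if same_dyad and ev.start_time_s - last_end <= max_gap_s:
                merged[-1] = replace(
                    prev, duration_s=prev.duration_s + ev.duration_s
                )
                last_end = ev.end_time_s
                continue
        merged.append(ev)
        last_end = ev.end_time_s
    return merged


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _rate_denominator(
    actor: str,
    recipient: str,
    effort: ObservationEffort,
    normalization: Normalization,
) -> float:
    if normalization is Normalization.DYAD_HOURS:
        h = effort[actor] + effort[recipient]
    elif normalization is Normalization.ACTOR_HOURS:
        h = effort[actor]
    else:
        h = effort.total
    if not h > 0:
        raise ValueError(f"non-positive rate denominator for dyad {actor}->{recipient}")
    return h


def _check_events(events: Sequence[InteractionEvent], roster: Roster,
                  effort: ObservationEffort, behaviour: Behaviour) -> None:
    subjects = set(roster.study_ids)
    for ev in events:
        if ev.behaviour is not behaviour:
            raise ValueError(
                f"expected only {behaviour.value} events, got {ev.behaviour.value}"
            )
        for id_ in (ev.actor, ev.recipient):
            if id_ not in subjects:
                raise ValueError(f"event references non-study individual {id_!r}")
            if id_ not in effort:
                raise ValueError(f"individual {id_!r} missing from effort table")


def build_grooming_network(
    events: Sequence[InteractionEvent],
    effort: ObservationEffort,
    roster: Roster,
    normalization: Normalization | str = Normalization.DYAD_HOURS,
) -> SocialNetwork:
    """Directed grooming network; edge weights are seconds groomed per hour.

    ``events`` should already be merged bouts (see
    :func:`merge_grooming_bouts`); weights only depend on per-dyad total
    seconds, so merging does not change them.
    """
    normalization = Normalization(normalization)
    _check_events(events, roster, effort, Behaviour.GROOMING)
    net = SocialNetwork.empty(roster, behaviour="grooming")
    totals: dict[tuple[str, str], float] = {}
    for ev in events:
        totals[(ev.actor, ev.recipient)] = (
            totals.get((ev.actor, ev.recipient), 0.0) + ev.duration_s
        )
    for (a, r), seconds in sorted(totals.items()):
        if seconds > 0:
            h = _rate_denominator(a, r, effort, normalization)
            net.graph.add_edge(a, r, weight=seconds / h)
    return net


def build_aggression_network(
    events: Sequence[InteractionEvent],
    effort: ObservationEffort,
    roster: Roster,
    normalization: Normalization | str = Normalization.DYAD_HOURS,
) -> SocialNetwork:
    """Directed aggression network; edge weights are aggressive acts per hour."""
    normalization = Normalization(normalization)
    _check_events(events, roster, effort, Behaviour.AGGRESSION)
    net = SocialNetwork.empty(roster, behaviour="aggression")
    counts: dict[tuple[str, str], int] = {}
    for ev in events:
        counts[(ev.actor, ev.recipient)] = counts.get((ev.actor, ev.recipient), 0) + 1
    for (a, r), c in sorted(counts.items()):
        h = _rate_denominator(a, r, effort, normalization)
        net.graph.add_edge(a, r, weight=c / h)
    return net


def symmetrise(network: SocialNetwork) -> SocialNetwork:
    """Undirected equivalent with w(i,j) = w(i->j) + w(j->i).

    An already-undirected network is returned as a copy (idempotent).
    """
    if not network.directed:
        return network.copy()
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes(data=True))
    for u, v, d in network.graph.edges(data=True):
        w = d["weight"]
        if g.has_edge(u, v):
            g[u][v]["weight"] += w
        else:
            g.add_edge(u, v, weight=w)
    return SocialNetwork(g, network.behaviour)


# ---------------------------------------------------------------------------
# file I/O  (plain delimited text; see README for the column dialects)
# ---------------------------------------------------------------------------

def read_roster(path: str | Path) -> Roster:
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "sex", "age_class", "is_study_subject"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"roster file missing columns: {sorted(missing)}")
    individuals = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        if str(row.id) in seen:
            raise ValueError(f"{path}, row {row_no}: duplicate id {row.id!r}")
        seen.add(str(row.id))
        try:
            individuals.append(
                Individual(
                    id=str(row.id),
                    age_sex=AgeSexClass(AgeClass(row.age_class), Sex(row.sex)),
                    is_study_subject=_parse_bool(row.is_study_subject),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, row {row_no}: {exc}") from exc
    try:
        return Roster(individuals)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def write_roster(roster: Roster, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [i.id for i in roster],
            "sex": [i.sex.value for i in roster],
            "age_class": [i.age_class.value for i in roster],
            "is_study_subject": [i.is_study_subject for i in roster],
        }
    ).to_csv(path, index=False)


def read_effort(path: str | Path, roster: Roster | None = None) -> ObservationEffort:
    df = pd.read_csv(path, dtype={"id": str})
    if {"id", "hours"} - set(df.columns):
        raise ValueError(f"effort file must have columns id,hours: {path}")
    hours: dict[str, float] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        id_ = str(row.id)
        if id_ in hours:
            raise ValueError(f"{path}, row {row_no}: duplicate id {id_!r}")
        if roster is not None and id_ not in roster:
            raise ValueError(f"{path}, row {row_no}: unknown id {id_!r}")
        hours[id_] = float(row.hours)
    return ObservationEffort(hours)


def write_effort(effort: ObservationEffort, path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(effort.hours), "hours": list(effort.hours.values())}
    ).to_csv(path, index=False)


def read_events(path: str | Path, roster: Roster | None = None) -> list[InteractionEvent]:
    df = pd.read_csv(path, dtype={"actor": str, "recipient": str})
    required = {"actor", "recipient", "behaviour"}
    if required - set(df.columns):
        raise ValueError(f"events file missing columns {sorted(required)}: {path}")
    events = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            behaviour = Behaviour(row.behaviour)
            start = getattr(row, "start_time_s", None)
            start = None if start is None or pd.isna(start) else float(start)
            dur = getattr(row, "duration_s", None)
            dur = None if dur is None or pd.isna(dur) else float(dur)
            ev = InteractionEvent(
                actor=str(row.actor),
                recipient=str(row.recipient),
                behaviour=behaviour,
                start_time_s=start,
                duration_s=dur,
            )
        except ValueError as exc:
            raise ValueError(f"{path}, row {row_no}: {exc}") from exc
        if roster is not None:
            for id_ in (ev.actor, ev.recipient):
                if id_ not in roster:
                    raise ValueError(f"{path}, row {row_no}: unknown id {id_!r}")
        events.append(ev)
    return events


def write_events(events: Sequence[InteractionEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "actor": [e.actor for e in events],
            "recipient": [e.recipient for e in events],
            "behaviour": [e.behaviour.value for e in events],
            "start_time_s": [e.start_time_s for e in events],
            "duration_s": [e.duration_s for e in events],
        }
    ).to_csv(path, index=False)


def write_network(network: SocialNetwork, path: str | Path) -> None:
    """Write a network as an edge-list CSV or GraphML (by extension)."""
    path = Path(path)
    if path.suffix == ".graphml":
        g = network.graph.copy()
        g.graph["behaviour"] = network.behaviour
        nx.write_graphml(g, path)
        return
    rows = [
        {"source": u, "target": v, "weight": d["weight"]}
        for u, v, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)


def read_network(
    path: str | Path,
    roster: Roster,
    behaviour: str = "interaction",
    directed: bool = True,
) -> SocialNetwork:
    """Read an edge-list CSV written by :func:`write_network`."""
    df = pd.read_csv(path, dtype={"source": str, "target": str})
    net = SocialNetwork.empty(roster, behaviour=behaviour, directed=directed)
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        for id_ in (row.source, row.target):
            if id_ not in roster:
                raise ValueError(f"{path}, row {row_no}: unknown id {id_!r}")
        net.graph.add_edge(row.source, row.target, weight=float(row.weight))
    return net
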