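from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from troopnet.data_model import (
    AgeClass,
    AgeSexClass,
    Behaviour,
    InteractionEvent,
    Normalization,
    ObservationEffort,
    Roster,
    Sex,
    build_aggression_network,
    build_grooming_network,
    merge_grooming_bouts,
    read_effort,
    read_events,
    read_network,
    read_roster,
    symmetrise,
    write_effort,
    write_events,
    write_network,
    write_roster,
)

from conftest import make_individual, make_roster, network_from_edges, uniform_effort


def groom(actor, recipient, start, duration):
    return InteractionEvent(actor, recipient, Behaviour.GROOMING,
                            start_time_s=start, duration_s=duration)


def aggress(actor, recipient, start=None):
    return InteractionEvent(actor, recipient, Behaviour.AGGRESSION, start_time_s=start)


class TestDomainTypes:
    def test_roster_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            Roster([make_individual("A"), make_individual("A")])

    def test_roster_rejects_empty(self):
        with pytest.raises(ValueError):
            Roster([])

    def test_roster_lookup(self):
        r = make_roster(3)
        assert r["N0"].id == "N0"
        with pytest.raises(KeyError, match="unknown"):
            r["missing"]

    def test_effort_rejects_nonpositive_hours(self):
        with pytest.raises(ValueError):
            ObservationEffort({"A": 0.0})

    def test_event_rejects_self_interaction(self):
        with pytest.raises(ValueError, match="self"):
            groom("A", "A", 0, 10)

    def test_grooming_requires_duration(self):
        with pytest.raises(ValueError, match="duration"):
            InteractionEvent("A", "B", Behaviour.GROOMING, start_time_s=0)

    def test_aggression_rejects_duration(self):
        with pytest.raises(ValueError):
            InteractionEvent("A", "B", Behaviour.AGGRESSION, duration_s=5.0)

    def test_age_sex_label_round_trip(self):
        c = AgeSexClass(AgeClass.SUBADULT, Sex.FEMALE)
        assert AgeSexClass.from_label(c.label) == c


class TestMergeGroomingBouts:
    def test_gap_at_threshold_merges(self):
        # 60 s bout ending at t=60, next starts at t=80 (20 s gap) -> one 90 s bout
        events = [groom("A", "B", 0, 60), groom("A", "B", 80, 30)]
        merged = merge_grooming_bouts(events)
        assert len(merged) == 1
        assert merged[0].duration_s == pytest.approx(90.0)

    def test_gap_above_threshold_keeps_bouts(self):
        events = [groom("A", "B", 0, 60), groom("A", "B", 91, 30)]  # 31 s gap
        merged = merge_grooming_bouts(events)
        assert len(merged) == 2

    def test_gap_exactly_threshold_merges(self):
        events = [groom("A", "B", 0, 60), groom("A", "B", 90, 30)]  # 30 s gap
        assert len(merge_grooming_bouts(events)) == 1

    def test_direction_change_starts_new_bout(self):
        events = sorted(
            [groom("A", "B", 0, 60), groom("B", "A", 65, 30)],
            key=lambda e: (e.actor, e.recipient, e.start_time_s),
        )
        assert len(merge_grooming_bouts(events)) == 2

    def test_rejects_unsorted(self):
        events = [groom("A", "B", 100, 10), groom("A", "B", 0, 10)]
        with pytest.raises(ValueError, match="sorted"):
            merge_grooming_bouts(events)

    def test_rejects_aggression(self):
        with pytest.raises(ValueError, match="grooming"):
            merge_grooming_bouts([aggress("A", "B", 0)])

    def test_custom_threshold(self):
        events = [groom("A", "B", 0, 60), groom("A", "B", 80, 30)]
        assert len(merge_grooming_bouts(events, max_gap_s=10)) == 2

    @given(st.lists(st.floats(min_value=1, max_value=100), min_size=1, max_size=8),
           st.floats(min_value=0, max_value=30))
    def test_total_duration_invariant_under_splitting(self, durations, gap):
        # one long bout split into sub-events with gaps <= 30 s merges back
        events, t = [], 0.0
        for d in durations:
            events.append(groom("A", "B", t, d))
            t += d + gap
        merged = merge_grooming_bouts(events)
        assert len(merged) == 1
        assert merged[0].duration_s == pytest.approx(sum(durations))


class TestNetworkConstruction:
    def setup_method(self):
        self.roster = make_roster(4)
        self.effort = uniform_effort(self.roster, hours=5.0)

    def test_grooming_weight_dyad_hours(self):
        events = [groom("N0", "N1", 0, 300)]
        net = build_grooming_network(events, self.effort, self.roster)
        assert net.weight("N0", "N1") == pytest.approx(300 / (5 + 5))

    def test_grooming_weight_actor_hours(self):
        events = [groom("N0", "N1", 0, 300)]
        net = build_grooming_network(events, self.effort, self.roster,
                                     normalization="actor_hours")
        assert net.weight("N0", "N1") == pytest.approx(60.0)

    def test_grooming_weight_total_hours(self):
        events = [groom("N0", "N1", 0, 300)]
        net = build_grooming_network(events, self.effort, self.roster,
                                     normalization=Normalization.TOTAL_HOURS)
        assert net.weight("N0", "N1") == pytest.approx(300 / 20.0)

    def test_no_events_gives_all_nodes_no_edges(self):
        net = build_grooming_network([], self.effort, self.roster)
        assert net.n_nodes == 4
        assert net.n_edges == 0

    def test_aggression_rate(self):
        roster = make_roster(2)
        effort = uniform_effort(roster, hours=4.0)
        events = [aggress("N0", "N1") for _ in range(4)]
        net = build_aggression_network(events, effort, roster)
        assert net.weight("N0", "N1") == pytest.approx(0.5)

    def test_aggression_asymmetry_preserved(self):
        events = [aggress("N0", "N1"), aggress("N1", "N0")]
        net = build_aggression_network(events, self.effort, self.roster)
        assert net.weight("N0", "N1") > 0
        assert net.weight("N1", "N0") > 0
        assert net.n_edges == 2

    def test_rejects_individual_missing_from_effort(self):
        effort = ObservationEffort({"N0": 5.0, "N1": 5.0, "N2": 5.0})
        with pytest.raises(ValueError, match="effort"):
            build_grooming_network([groom("N0", "N3", 0, 10)], effort, self.roster)

    def test_rejects_non_study_subject(self):
        roster = Roster([make_individual("A"), make_individual("B"),
                         make_individual("C", is_study_subject=False)])
        effort = ObservationEffort({"A": 5.0, "B": 5.0, "C": 5.0})
        with pytest.raises(ValueError, match="non-study"):
            build_grooming_network([groom("A", "C", 0, 10)], effort, roster)

    def test_order_independence(self):
        events = [groom("N0", "N1", 0, 100), groom("N2", "N3", 0, 50),
                  groom("N0", "N2", 0, 25)]
        a = build_grooming_network(events, self.effort, self.roster)
        b = build_grooming_network(events[::-1], self.effort, self.roster)
        assert a.edge_weights() == b.edge_weights()

    def test_merge_then_rate_equals_rate_of_merged(self):
        split = [groom("N0", "N1", 0, 40), groom("N0", "N1", 50, 60)]
        whole = [groom("N0", "N1", 0, 100)]
        net_a = build_grooming_network(merge_grooming_bouts(split), self.effort, self.roster)
        net_b = build_grooming_network(whole, self.effort, self.roster)
        assert net_a.weight("N0", "N1") == pytest.approx(net_b.weight("N0", "N1"))


class TestSymmetrise:
    def test_adds_both_directions(self):
        net = network_from_edges({("A", "B"): 2.0, ("B", "A"): 3.0})
        sym = symmetrise(net)
        assert sym.weight("A", "B") == pytest.approx(5.0)

    def test_single_direction_kept(self):
        net = network_from_edges({("A", "B"): 2.0})
        assert symmetrise(net).weight("A", "B") == pytest.approx(2.0)

    def test_idempotent(self):
        net = network_from_edges({("A", "B"): 2.0, ("B", "A"): 3.0, ("B", "C"): 1.0})
        once = symmetrise(net)
        twice = symmetrise(once)
        assert once.edge_weights() == twice.edge_weights()

    def test_total_weight_conserved(self):
        rng = np.random.default_rng(0)
        from conftest import random_network

        net = random_network(8, 0.4, rng)
        assert symmetrise(net).total_weight() == pytest.approx(net.total_weight())


class TestFileIO:
    def test_roster_round_trip(self, tmp_path):
        roster = Roster([
            make_individual("A", "adult_male"),
            make_individual("B", "juvenile_female"),
            make_individual("C", "subadult_female", is_study_subject=False),
        ])
        path = tmp_path / "roster.csv"
        write_roster(roster, path)
        assert read_roster(path) == roster

    def test_roster_of_three_rows(self, tmp_path):
        path = tmp_path / "roster.csv"
        path.write_text(
            "id,sex,age_class,is_study_subject\n"
            "A,male,adult,true\nB,female,juvenile,true\nC,male,subadult,false\n"
        )
        assert len(read_roster(path)) == 3

    def test_malformed_roster_row_reports_row_number(self, tmp_path):
        path = tmp_path / "roster.csv"
        path.write_text("id,sex,age_class,is_study_subject\nA,male,wrong,true\n")
        with pytest.raises(ValueError, match="row 2"):
            read_roster(path)

    def test_effort_round_trip(self, tmp_path):
        effort = ObservationEffort({"A": 7.5, "B": 8.25})
        path = tmp_path / "effort.csv"
        write_effort(effort, path)
        assert read_effort(path).hours == effort.hours

    def test_events_round_trip(self, tmp_path):
        events = [groom("A", "B", 0.0, 60.0), aggress("B", "A", 5.0)]
        path = tmp_path / "events.csv"
        write_events(events, path)
        assert read_events(path) == events

    def test_event_with_unknown_id_rejected(self, tmp_path):
        roster = make_roster(2)
        path = tmp_path / "events.csv"
        write_events([groom("N0", "GHOST", 0, 10)], path)
        with pytest.raises(ValueError, match="GHOST"):
            read_events(path, roster)

    def test_network_round_trip(self, troop_data, troop_networks, tmp_path):
        roster, _, _ = troop_data
        net = troop_networks["grooming"]
        path = tmp_path / "net.csv"
        write_network(net, path)
        back = read_network(path, roster, behaviour="grooming")
        assert back.edge_weights() == pytest.approx(net.edge_weights())
        assert back.n_nodes == net.n_nodes

    def test_graphml_export(self, troop_networks, tmp_path):
        import networkx as nx

        path = tmp_path / "net.graphml"
        write_network(troop_networks["grooming"], path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == troop_networks["grooming"].n_edges


def test_duplicate_roster_id_reports_row_number(tmp_path):
    path = tmp_path / "roster.csv"
    path.write_text("id,sex,age_class,is_study_subject\n"
                    "A,male,adult,true\nA,male,adult,true\n")
    with pytest.raises(ValueError, match="row 3"):
        read_roster(path)
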