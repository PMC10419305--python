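"""Emergent-network mechanics, derived metrics and their brute-force oracle."""

import itertools

import numpy as np
import pytest
from scipy import stats

import obesnet as ob
from obesnet.errors import ConfigurationError
from obesnet.network import (
    CandidateIndex,
    NetworkState,
    bmi_colour_class,
    build_graph,
    read_edge_list,
)


def grid_population(coords, bmi=25.0, gender=0):
    agents = []
    for i, (x, y) in enumerate(coords):
        agents.append(ob.Agent(
            id=i, age=40.0, gender=ob.Gender(gender), height=1.75,
            weight=bmi * 1.75**2, education=3, pal_category=1, pos_x=x, pos_y=y,
        ))
    return ob.Population.from_agents(agents)


class TestPropinquity:
    def test_single_agent_has_empty_set(self):
        pop = grid_population([(0, 0)])
        assert ob.propinquity_set(pop[0], pop.agents(), ra=5.0) == set()

    def test_colocated_pair_within_tiny_range(self):
        pop = grid_population([(1, 1), (1, 1)])
        agents = pop.agents()
        assert ob.propinquity_set(agents[0], agents, ra=0.1) == {1}
        assert ob.propinquity_set(agents[1], agents, ra=0.1) == {0}

    def test_unit_grid_centre_sees_all_eight(self):
        coords = [(x, y) for x in range(3) for y in range(3)]
        pop = grid_population(coords)
        centre = next(a for a in pop.agents() if (a.pos_x, a.pos_y) == (1, 1))
        neighbours = ob.propinquity_set(centre, pop.agents(), ra=1.5)
        assert len(neighbours) == 8  # diagonal sqrt(2) < 1.5

    def test_dead_agents_excluded(self):
        pop = grid_population([(0, 0), (0.5, 0)])
        pop.alive[1] = False
        assert ob.propinquity_set(pop[0], pop.agents(), ra=2.0) == set()


class TestHomophily:
    def test_equal_bmis_always_pass(self, agent_factory):
        p = agent_factory(0, bmi=31.0)
        q = agent_factory(1, bmi=31.0, gender=ob.Gender.FEMALE)
        assert ob.homophily_indicator(p, q, theta_trigger=0.0, theta_bmiadj=[5, 5, 5, 5]) == 1

    def test_zero_weight_disables_homophily(self, agent_factory):
        p = agent_factory(0, bmi=20.0)
        q = agent_factory(1, bmi=45.0)
        assert ob.homophily_indicator(p, q, theta_trigger=1.0, theta_bmiadj=[0, 0, 0, 0]) == 1

    def test_weighted_gap_above_trigger_blocks(self, agent_factory):
        p = agent_factory(0, bmi=30.0)
        q = agent_factory(1, bmi=36.0)
        assert ob.homophily_indicator(p, q, theta_trigger=5.0, theta_bmiadj=[1, 1, 1, 1]) == 0

    def test_directional_weights_break_symmetry(self, agent_factory):
        p = agent_factory(0, bmi=25.0, gender=ob.Gender.MALE)
        q = agent_factory(1, bmi=30.0, gender=ob.Gender.FEMALE)
        weights = [1.0, 0.1, 1.0, 2.0]  # mm, mf, ff, fm
        assert ob.homophily_indicator(p, q, 2.0, weights) == 1  # 0.1 * 5 <= 2
        assert ob.homophily_indicator(q, p, 2.0, weights) == 0  # 2.0 * 5 > 2


class TestMemoryProbability:
    def test_no_contacts_gives_baseline(self):
        state = NetworkState(3, memory_window=4)
        assert ob.memory_probability(0, 1, state, theta_mem=2.0, baseline_prob=0.3) == 0.3

    def test_saturates_at_one(self):
        state = NetworkState.from_interactions(2, 4, [[(0, 1)]] * 4)
        assert ob.memory_probability(0, 1, state, theta_mem=50.0, baseline_prob=0.1) == 1.0

    def test_formula_value(self):
        # alpha = 2 contacts / window 4 = 0.5
        state = NetworkState.from_interactions(2, 4, [[(0, 1)], [(1, 0)], [], []])
        pi = ob.memory_probability(0, 1, state, theta_mem=0.6, baseline_prob=0.1)
        assert pi == pytest.approx(0.4)

    def test_monotone_in_contact_count(self):
        probs = []
        for contacts in range(4):
            slots = [[(0, 1)]] * contacts + [[]] * (4 - contacts)
            state = NetworkState.from_interactions(2, 4, slots)
            probs.append(ob.memory_probability(0, 1, state, 1.0, 0.1))
        assert probs == sorted(probs)


class TestStepNetwork:
    def params(self, **kw):
        base = dict(ra=5.0, s_max=2, memory_window=6, z=10.0, offers_per_step=2,
                    theta_trigger=100.0, theta_mem=1.0, baseline_prob=1.0)
        return ob.NetworkParams(**{**base, **kw})

    def test_zero_capacity_records_nothing(self, rng):
        pop = grid_population([(0, 0), (1, 0), (0, 1)])
        state = NetworkState(3, 6)
        src, dst = ob.step_network(pop, self.params(s_max=0), state, rng)
        assert len(src) == 0 and state.counts.sum() == 0

    def test_out_of_range_pairs_never_interact(self, rng):
        pop = grid_population([(0, 0), (9, 9)])
        state = NetworkState(2, 6)
        src, _ = ob.step_network(pop, self.params(ra=1.0), state, rng)
        assert len(src) == 0

    def test_forced_acceptance_recorded_for_both(self, rng):
        pop = grid_population([(0, 0), (1, 0)])
        state = NetworkState(2, 6)
        ob.step_network(pop, self.params(offers_per_step=1), state, rng)
        assert state.counts[0, 1] >= 1
        assert state.counts[0, 1] == state.counts[1, 0]
        assert state.history(0)[-1].tolist().count(1) >= 1

    def test_capacity_never_exceeded_in_any_slot(self, rng, profile):
        pop = ob.generate_population(120, seed=3, profile=profile)
        params = self.params(ra=50.0, s_max=2, offers_per_step=4, z=profile.map_size)
        state = NetworkState(len(pop), 6)
        for _ in range(5):
            src, dst = ob.step_network(pop, params, state, rng)
            if len(dst):
                _, counts = np.unique(dst, return_counts=True)
                assert counts.max() <= params.s_max

    def test_recorded_pairs_respect_range_and_homophily(self, rng, profile):
        pop = ob.generate_population(120, seed=4, profile=profile)
        params = self.params(ra=6.0, theta_trigger=3.0, offers_per_step=3,
                             z=profile.map_size)
        state = NetworkState(len(pop), 6)
        for _ in range(4):
            src, dst = ob.step_network(pop, params, state, rng)
            d = np.hypot(pop.pos_x[src] - pop.pos_x[dst], pop.pos_y[src] - pop.pos_y[dst])
            assert np.all(d < params.ra)
            gaps = np.abs(pop.bmi[src] - pop.bmi[dst])
            assert np.all(gaps <= params.theta_trigger + 1e-12)

    def test_edge_set_is_dynamic_not_frozen(self, profile):
        from obesnet.presets import fingerprint_network

        pop = ob.generate_population(500, seed=6, profile=profile)
        # fingerprint dynamics at half density: double the homophily window
        params = fingerprint_network().model_copy(update={"theta_trigger": 0.174})
        state = NetworkState(len(pop), params.memory_window)
        rng = np.random.default_rng(0)
        index = CandidateIndex(pop, params.ra)
        edge_sets = []
        for step in range(30):
            ob.step_network(pop, params, state, rng, index)
            if step >= 26:
                g = build_graph(pop, state)
                edge_sets.append(set(map(tuple, map(sorted, g.edges()))))
        changed = [len(a ^ b) for a, b in zip(edge_sets, edge_sets[1:])]
        assert all(c > 0 for c in changed)

    def test_average_degree_reaches_plateau(self, profile):
        pop = ob.generate_population(300, seed=8, profile=profile)
        params = ob.NetworkParams(z=profile.map_size)
        state = NetworkState(len(pop), params.memory_window)
        rng = np.random.default_rng(5)
        index = CandidateIndex(pop, params.ra)
        degrees = []
        for _ in range(80):
            ob.step_network(pop, params, state, rng, index)
            g = build_graph(pop, state)
            degrees.append(2 * g.number_of_edges() / g.number_of_nodes())
        fit = stats.linregress(np.arange(50), degrees[-50:])
        assert fit.pvalue > 0.01 or abs(fit.slope) < 0.01


class TestNeighbourhood:
    def test_empty_history_empty_set(self):
        state = NetworkState(4, 3)
        assert ob.neighbourhood(0, state) == set()

    def test_recent_partner_included(self):
        state = NetworkState.from_interactions(4, 3, [[(0, 2)]])
        assert ob.neighbourhood(0, state) == {2}

    def test_partner_beyond_window_excluded(self):
        slots = [[(0, 2)]] + [[]] * 3  # window 3: first slot rolls off
        state = NetworkState.from_interactions(4, 3, slots)
        assert ob.neighbourhood(0, state) == set()

    def test_dead_partner_excluded(self):
        state = NetworkState.from_interactions(4, 3, [[(0, 2)]])
        alive = np.array([True, True, False, True])
        assert ob.neighbourhood(0, state, alive=alive) == set()


def brute_force_metrics(n, edges, bmi):
    """Independent implementation by exhaustive enumeration (small graphs)."""
    adj = {i: set() for i in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    deg = {i: len(adj[i]) for i in range(n)}
    nan = float("nan")
    # mean local clustering over nodes with >= 2 neighbours
    locals_ = []
    for i in range(n):
        if deg[i] < 2:
            continue
        links = sum(1 for u, v in itertools.combinations(sorted(adj[i]), 2) if v in adj[u])
        locals_.append(links / (deg[i] * (deg[i] - 1) / 2))
    clustering = float(np.mean(locals_)) if locals_ else nan
    closed = open_ = 0
    for i in range(n):
        for u, v in itertools.combinations(sorted(adj[i]), 2):
            if v in adj[u]:
                closed += 1
            else:
                open_ += 1
    transitivity = closed / (closed + open_) if (closed + open_) else 0.0
    ends = [(deg[u], deg[v]) for u, v in edges]
    if ends:
        x = np.array([a for a, b in ends] + [b for a, b in ends], dtype=float)
        y = np.array([b for a, b in ends] + [a for a, b in ends], dtype=float)
        deg_assort = nan if x.std() == 0 or y.std() == 0 else float(np.corrcoef(x, y)[0, 1])
        bx = np.array([bmi[u] for u, v in edges] + [bmi[v] for u, v in edges])
        by = np.array([bmi[v] for u, v in edges] + [bmi[u] for u, v in edges])
        bmi_assort = nan if bx.std() == 0 or by.std() == 0 else float(np.corrcoef(bx, by)[0, 1])
    else:
        deg_assort = bmi_assort = nan
    return {
        "clustering": clustering,
        "transitivity": float(transitivity),
        "degree_assortativity": deg_assort,
        "bmi_assortativity": bmi_assort,
        "average_degree": 2 * len(edges) / n,
    }


def state_from_edges(n, edges, bmi):
    pop = grid_population([(i, 0) for i in range(n)])
    pop.weight = np.asarray(bmi) * pop.height**2
    state = NetworkState.from_interactions(n, 1, [list(edges)])
    return pop, state


class TestComputeMetrics:
    def test_triangle(self):
        pop, state = state_from_edges(3, [(0, 1), (1, 2), (0, 2)], [22, 24, 26])
        m = ob.compute_metrics(pop, state)
        assert m.clustering == pytest.approx(1.0)
        assert m.transitivity == pytest.approx(1.0)
        assert m.average_degree == pytest.approx(2.0)

    def test_three_node_path(self):
        pop, state = state_from_edges(3, [(0, 1), (1, 2)], [22, 24, 26])
        m = ob.compute_metrics(pop, state)
        assert m.transitivity == pytest.approx(0.0)
        assert m.average_degree == pytest.approx(4.0 / 3.0)

    def test_four_node_star_degree_assortativity(self):
        pop, state = state_from_edges(4, [(0, 1), (0, 2), (0, 3)], [22, 24, 26, 28])
        m = ob.compute_metrics(pop, state)
        assert m.degree_assortativity == pytest.approx(-1.0)

    def test_fewer_than_two_nodes_undefined(self):
        pop, state = state_from_edges(1, [], [25])
        m = ob.compute_metrics(pop, state)
        assert np.isnan(m.average_degree) and np.isnan(m.clustering)

    def test_zero_variance_assortativity_flagged_undefined(self):
        # 4-cycle: every degree 2, every BMI equal
        pop, state = state_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)], [25] * 4)
        m = ob.compute_metrics(pop, state)
        assert np.isnan(m.degree_assortativity)
        assert np.isnan(m.bmi_assortativity)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(3, 13))
            p_edge = rng.uniform(0.15, 0.7)
            edges = [(u, v) for u in range(n) for v in range(u + 1, n)
                     if rng.random() < p_edge]
            bmi = rng.uniform(18, 40, size=n)
            pop, state = state_from_edges(n, edges, bmi)
            ours = ob.compute_metrics(pop, state).as_dict()
            ref = brute_force_metrics(n, edges, bmi)
            for key, expected in ref.items():
                if np.isnan(expected):
                    assert np.isnan(ours[key]), key
                else:
                    assert ours[key] == pytest.approx(expected, abs=1e-12), key


class TestExport:
    def test_triangle_edge_list_rows_and_round_trip(self, tmp_path):
        pop, state = state_from_edges(3, [(0, 1), (1, 2), (0, 2)], [22, 24, 26])
        path = tmp_path / "edges.tsv"
        ob.export_network(pop, state, path, "edgelist")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4  # header + 3 edges
        g = read_edge_list(path)
        original = build_graph(pop, state)
        assert set(g.edges()) == set(original.edges())
        for u, v in g.edges():
            assert g[u][v]["weight"] == pytest.approx(original[u][v]["weight"])

    def test_morbidly_obese_node_is_black(self, tmp_path):
        assert bmi_colour_class(42.0) == "black"
        assert bmi_colour_class(33.0) == "red"
        assert bmi_colour_class(27.0) == "orange"
        assert bmi_colour_class(22.0) == "green"
        pop, state = state_from_edges(2, [(0, 1)], [42, 22])
        path = tmp_path / "net.graphml"
        ob.export_network(pop, state, path, "graphml")
        import networkx as nx

        g = nx.read_graphml(path)
        classes = {data["bmi_class"] for _, data in g.nodes(data=True)}
        assert classes == {"black", "green"}

    def test_unknown_format_rejected(self, tmp_path):
        pop, state = state_from_edges(2, [(0, 1)], [22, 24])
        with pytest.raises(ConfigurationError):
            ob.export_network(pop, state, tmp_path / "x", "dot")
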