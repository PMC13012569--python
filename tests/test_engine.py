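"""Simulation loop: stochastic event semantics, motility/mechanics, clocks,
and reproducibility."""

import math

import numpy as np
import pytest

from cellgrammar.cells import APOPTOTIC, LIVE, NECROTIC, CellType
from cellgrammar.engine import Schedule, Simulation, rate_to_probability
from cellgrammar.grammar import parse_rules_csv, Vocabulary
from cellgrammar.microenv import Domain


def simple_sim(types, schedule=None, seed=0, size=2000.0, substrates=None, rules=None):
    dom = Domain(-size, size, -size, size, voxel_size=50.0)
    ruleset = None
    if rules:
        vocab = Vocabulary(substrates=[s["name"] for s in (substrates or [])],
                           cell_types=[t.name for t in types])
        ruleset = parse_rules_csv(rules, vocab)
    return Simulation(dom, types, ruleset=ruleset, substrates=substrates,
                      schedule=schedule or Schedule(6, 6, 6, 720, 720), seed=seed)


class TestRateToProbability:
    def test_closed_forms(self):
        assert rate_to_probability(0.0, 5.0) == 0.0
        assert rate_to_probability(math.log(2) / 6.0, 6.0) == pytest.approx(0.5)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-1.0, 1.0)
        with pytest.raises(ValueError):
            rate_to_probability(1.0, 0.0)

    def test_monte_carlo_frequency(self):
        r, dt, n = 0.01, 6.0, 100_000
        rng = np.random.default_rng(7)
        p = rate_to_probability(r, dt)
        hits = (rng.random(n) < p).sum()
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


class TestPhenotypeSweep:
    def test_all_rates_zero_no_events(self):
        sim = simple_sim([CellType("c")])
        sim.add_agents("c", np.zeros((50, 2)))
        sim.refresh_rules()
        sim.phenotype_sweep(6.0)
        assert len(sim.events.records) == 0
        assert len(sim.population) == 50

    def test_pure_birth_matches_exponential_growth(self):
        r, T, n0, reps = 0.001, 720.0, 1000, 20
        finals = []
        for seed in range(reps):
            ct = CellType("c", phenotype={"cycle entry": r, "migration speed": 0.0})
            sim = simple_sim([ct], seed=seed)
            pts = np.random.default_rng(seed).random((n0, 2)) * 3800 - 1900
            sim.add_agents("c", pts)
            snaps, _ = sim.run()
            finals.append(len(snaps[-1].ids))
        expected = n0 * math.exp(r * T)
        se = np.std(finals, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(finals) - expected) < 3 * se + 1e-9

    def test_asymmetric_division_daughter_fates(self):
        stem = CellType("stem", phenotype={"cycle entry": 0.05},
                        fate_table=[(0.0, float("inf"), "neuron")])
        neuron = CellType("neuron")
        sim = simple_sim([stem, neuron])
        sim.add_agents("stem", np.random.default_rng(0).random((30, 2)) * 1000)
        snaps, events = sim.run()
        divisions = [r for r in events.records if r[1] == "division"]
        assert divisions
        assert all(d[2]["cell_type"] == "stem" for d in divisions)
        assert all(d[2]["daughter_type"] == "neuron" for d in divisions)
        final = snaps[-1]
        assert final.count("stem") == 30  # every division kept one stem daughter
        assert final.count("neuron") == len(divisions)

    def test_bookkeeping_matches_event_log(self):
        ct = CellType("c", phenotype={"cycle entry": 0.002, "apoptosis": 0.001},
                      apoptosis_duration=60.0)
        sim = simple_sim([ct], seed=3)
        sim.add_agents("c", np.random.default_rng(1).random((500, 2)) * 3000 - 1500)
        snaps, ev = sim.run()
        assert len(snaps[-1].ids) == 500 + ev.births - ev.removals


class TestDeathAndClearance:
    def test_necrotic_lysis_clock(self):
        ct = CellType("c", necrosis_lysis_duration=100.0)
        sim = simple_sim([ct], schedule=Schedule(6, 6, 6, 200, 10))
        sim.add_agents("c", np.zeros((1, 2)))
        sim.population.state[0] = NECROTIC
        sim.population.death_clock[0] = 100.0
        snaps, _ = sim.run()
        for s in snaps:
            assert len(s.ids) == (1 if s.time < 100.0 else 0)

    def test_live_cells_never_phagocytosed_without_live_rate(self):
        eater = CellType("m", phenotype={"phagocytose dead cell": 10.0})
        prey = CellType("t")
        sim = simple_sim([eater, prey], schedule=Schedule(6, 6, 6, 120, 120))
        sim.add_agents("m", np.zeros((1, 2)))
        sim.add_agents("t", np.array([[10.0, 0.0]]))
        snaps, ev = sim.run()
        assert snaps[-1].count("t") == 1
        assert ev.count("phagocytosed") == 0

    def test_dead_cell_phagocytosis_rate_semantics(self):
        # empirical removal frequency over many one-step trials
        r, dt, trials = 0.02, 6.0, 2000
        removed = 0
        eater = CellType("m", phenotype={"phagocytose dead cell": r})
        prey = CellType("t")
        sim = simple_sim([eater, prey], seed=11)
        for _ in range(trials):
            sim.population = type(sim.population)(sim.population.cell_types)
            sim.add_agents("m", np.zeros((1, 2)))
            sim.add_agents("t", np.array([[10.0, 0.0]]))
            sim.population.state[1] = NECROTIC
            sim.population.death_clock[1] = np.inf
            sim.refresh_rules()
            sim.death_and_clearance(dt)
            if len(sim.population) == 1:
                removed += 1
        p = rate_to_probability(r, dt)
        se = math.sqrt(p * (1 - p) / trials)
        assert abs(removed / trials - p) < 3 * se


class TestAttack:
    def _pair(self, attack_rate, damage_rate, seed=0):
        atk = CellType("killer", phenotype={"attack tumor": attack_rate,
                                            "damage rate": damage_rate})
        tgt = CellType("tumor")
        sim = simple_sim([atk, tgt], seed=seed)
        sim.add_agents("killer", np.zeros((1, 2)))
        sim.add_agents("tumor", np.array([[10.0, 0.0]]))
        sim.refresh_rules()
        return sim

    def test_zero_attack_rate_no_damage(self):
        sim = self._pair(0.0, 5.0)
        for _ in range(20):
            sim.attack_sweep(6.0)
        assert sim.population.damage[1] == 0.0

    def test_locked_attacker_deterministic_accrual(self):
        sim = self._pair(1e9, 0.05)  # engagement certain on first sweep
        T, dt = 60.0, 6.0
        for _ in range(int(T / dt)):
            sim.attack_sweep(dt)
        assert sim.population.damage[1] == pytest.approx(0.05 * T)

    def test_damage_feeds_apoptosis_rule_to_saturation(self):
        rules = "tumor,damage,increases,apoptosis,0.05,30,4,0\n"
        atk = CellType("killer", phenotype={"attack tumor": 1e9, "damage rate": 10.0})
        tgt = CellType("tumor")
        sim = simple_sim([atk, tgt], rules=rules,
                         schedule=Schedule(6, 6, 6, 600, 600), seed=4)
        sim.add_agents("killer", np.zeros((1, 2)))
        sim.add_agents("tumor", np.array([[10.0, 0.0]]))
        for _ in range(30):
            sim.refresh_rules()
            sim.attack_sweep(6.0)
        sim.refresh_rules()
        assert sim.population.behaviors["apoptosis"][1] == pytest.approx(0.05, rel=1e-3)


class TestMotilityMechanics:
    def test_pure_chemotaxis_moves_up_gradient(self):
        ct = CellType("c", phenotype={"migration speed": 1.0, "migration bias": 1.0,
                                      "migration persistence time": 5.0},
                      chemotaxis_substrate="attractant", chemotaxis_direction=1)
        sub = [dict(name="attractant", diffusion_coefficient=0.0)]
        sim = simple_sim([ct], substrates=sub, size=200.0,
                         schedule=Schedule(0.1, 0.1, 6, 60, 60))
        xs, _ = sim.domain.voxel_centers()
        sim.microenv["attractant"].values = np.tile(
            0.01 * (xs[None, :] + 200.0), (sim.domain.ny, 1))
        sim.add_agents("c", np.array([[-150.0, 0.0]]))
        snaps, _ = sim.run()
        disp = snaps[-1].positions[0] - np.array([-150.0, 0.0])
        assert disp[0] == pytest.approx(60.0, rel=0.05)  # speed * time along +x
        assert abs(disp[1]) < 1e-6

    def test_overlapping_agents_separate_monotonically(self):
        ct = CellType("c", phenotype={"migration speed": 0.0,
                                      "cell-cell adhesion strength": 0.0})
        sim = simple_sim([ct], size=200.0, schedule=Schedule(0.1, 0.1, 6, 30, 30))
        sim.add_agents("c", np.array([[0.0, 0.0], [4.0, 0.0]]))
        sim.refresh_rules()
        dists = [4.0]
        for _ in range(200):
            sim.motility_mechanics_sweep(0.1)
            dists.append(np.linalg.norm(sim.population.position[0]
                                        - sim.population.position[1]))
        assert all(b >= a - 1e-12 for a, b in zip(dists, dists[1:]))
        assert dists[-1] >= 2 * ct.radius * 0.95

    def test_unbiased_walk_mean_displacement_zero(self):
        ct = CellType("c", phenotype={"migration speed": 1.0, "migration bias": 0.0,
                                      "migration persistence time": 5.0})
        sim = simple_sim([ct], size=5000.0, schedule=Schedule(1, 1, 6, 120, 120),
                         seed=9)
        n = 1000
        sim.add_agents("c", np.zeros((n, 2)))
        snaps, _ = sim.run()
        disp = snaps[-1].positions
        se = disp.std(axis=0, ddof=1) / math.sqrt(n)
        assert np.all(np.abs(disp.mean(axis=0)) < 3 * se)


class TestRunSimulation:
    def test_zero_total_time_single_snapshot(self):
        sim = simple_sim([CellType("c")], schedule=Schedule(6, 6, 6, 0, 6))
        sim.add_agents("c", np.zeros((5, 2)))
        snaps, _ = sim.run()
        assert len(snaps) == 1 and snaps[0].time == 0.0

    def test_same_seed_byte_identical(self):
        def run(seed):
            ct = CellType("c", phenotype={"cycle entry": 0.002, "apoptosis": 0.0005,
                                          "migration speed": 0.5})
            sim = simple_sim([ct], seed=seed, schedule=Schedule(1, 1, 6, 240, 60))
            sim.add_agents("c", np.random.default_rng(0).random((100, 2)) * 500)
            snaps, _ = sim.run()
            return "".join(s.to_csv() for s in snaps)

        assert run(5) == run(5)
        assert run(5) != run(6)

    def test_no_rules_matches_base_phenotype_dynamics(self):
        # a ruleset whose rules never fire (zero-signal substrate) reproduces
        # the dynamics of an empty ruleset, draw for draw
        ct = CellType("c", phenotype={"cycle entry": 0.003})
        sub = [dict(name="ghost", diffusion_coefficient=0.0)]
        rules = "c,ghost,increases,cycle entry,0.003,10,4,0\n"
        sims = []
        for rs in (None, rules):
            sim = simple_sim([ct], substrates=sub, rules=rs, seed=2,
                             schedule=Schedule(6, 6, 6, 360, 360))
            sim.add_agents("c", np.random.default_rng(3).random((200, 2)) * 1000)
            snaps, _ = sim.run()
            sims.append(len(snaps[-1].ids))
        assert sims[0] == sims[1]

    def test_schedule_violations_rejected(self):
        with pytest.raises(ValueError):
            Schedule(dt_diffusion=1.0, dt_mechanics=0.5, dt_phenotype=6.0)
        with pytest.raises(ValueError):
            Schedule(dt_diffusion=0.4, dt_mechanics=1.0, dt_phenotype=6.0)
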