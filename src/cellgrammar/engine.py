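"""Simulation loop: stochastic cell events, motility, mechanics, and
substrate coupling on a layered timestep schedule.

Time advances on three nested steps: diffusion (default 0.01 min), mechanics
(default 0.1 min), and phenotype (default 6 min); each coarser step is an
integer multiple of the finer one.  Within a phenotype step the order is
fixed: signals are read, rules applied, then per agent the mutually
exclusive events are drawn in the order death -> transformation -> division,
followed by the attack sweep, phagocytosis, and clearance of dead cells
whose clocks expired.

All randomness comes from one numpy Generator seeded by the run seed; the
draw order is fixed (death uniforms, transformation uniforms and priorities,
division uniforms, division directions, fate draws, motility directions,
attack draws, phagocytosis draws), so identical seeds give byte-identical
trajectories.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .cells import LIVE, APOPTOTIC, NECROTIC, CellType, Population, apply_rules, compute_signals
from .grammar import RuleSet, compile_ruleset
from .microenv import Domain, Microenvironment

__all__ = [
    "Schedule",
    "EventLog",
    "Snapshot",
    "Simulation",
    "rate_to_probability",
    "run_simulation",
]

#: per-minute rate at which cell volume relaxes back to the type's target
VOLUME_RELAXATION_RATE = 0.05


def rate_to_probability(r: float, dt: float):
    """Probability that a Poisson event with rate ``r`` fires within ``dt``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    out = 1.0 - np.exp(-r * dt)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Schedule:
    """Layered timestep schedule (all times in minutes)."""

    dt_diffusion: float = 0.01
    dt_mechanics: float = 0.1
    dt_phenotype: float = 6.0
    total_time: float = 1440.0
    snapshot_interval: float = 60.0

    def __post_init__(self):
        if not (0 < self.dt_diffusion <= self.dt_mechanics <= self.dt_phenotype):
            raise ValueError("need 0 < dt_diffusion <= dt_mechanics <= dt_phenotype")
        for coarse, fine, names in (
            (self.dt_mechanics, self.dt_diffusion, "mechanics/diffusion"),
            (self.dt_phenotype, self.dt_mechanics, "phenotype/mechanics"),
        ):
            ratio = coarse / fine
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"{names} steps must be integer multiples")

    @property
    def diffusion_substeps(self) -> int:
        return int(round(self.dt_mechanics / self.dt_diffusion))

    @property
    def mechanics_per_phenotype(self) -> int:
        return int(round(self.dt_phenotype / self.dt_mechanics))


@dataclass
class EventLog:
    """Timestamped record of discrete cell events."""

    records: list[tuple] = field(default_factory=list)
    births: int = 0
    removals: int = 0

    def log(self, time: float, kind: str, **detail):
        self.records.append((time, kind, detail))
        if kind == "division":
            self.births += 1
        elif kind in ("cleared", "lysed", "phagocytosed"):
            self.removals += 1

    def count(self, kind: str) -> int:
        return sum(1 for r in self.records if r[1] == kind)


@dataclass
class Snapshot:
    """Cell table plus substrate arrays at one time point."""

    time: float
    ids: np.ndarray
    positions: np.ndarray
    cell_types: list[str]
    states: list[str]
    volumes: np.ndarray
    damage: np.ndarray
    speeds: np.ndarray
    substrates: dict[str, np.ndarray]

    def count(self, cell_type: str | None = None, state: str | None = None) -> int:
        n = len(self.ids)
        mask = np.ones(n, dtype=bool)
        if cell_type is not None:
            mask &= np.array([ct == cell_type for ct in self.cell_types])
        if state is not None:
            mask &= np.array([s == state for s in self.states])
        return int(mask.sum())

    def to_csv(self) -> str:
        out = io.StringIO()
        out.write("time_min,id,x_um,y_um,cell_type,state,volume_um3,damage,speed_um_min\n")
        for k in range(len(self.ids)):
            out.write(
                f"{self.time:g},{self.ids[k]},{self.positions[k, 0]:.4f},"
                f"{self.positions[k, 1]:.4f},{self.cell_types[k]},{self.states[k]},"
                f"{self.volumes[k]:.4f},{self.damage[k]:.6g},{self.speeds[k]:.6g}\n"
            )
        return out.getvalue()


class Simulation:
    """One runnable model: domain + substrates + cell types + compiled rules."""

    def __init__(
        self,
        domain: Domain,
        cell_types: list[CellType],
        ruleset: RuleSet | None = None,
        substrates: list[dict] | None = None,
        schedule: Schedule | None = None,
        seed: int = 0,
    ):
        self.domain = domain
        self.schedule = schedule or Schedule()
        self.rng = np.random.default_rng(seed)
        self.microenv = Microenvironment(domain)
        for spec in substrates or []:
            self.microenv.add_substrate(**spec)
        self.population = Population(cell_types)
        self.events = EventLog()
        self.time = 0.0
        self.ruleset = ruleset or RuleSet()
        phenos = {}
        for ct in cell_types:
            behaviors = {r.behavior for r in self.ruleset if r.cell_type == ct.name}
            phenos[ct.name] = {b: ct.base_value(b) for b in behaviors}
        self.compiled = compile_ruleset(self.ruleset, phenos) if len(self.ruleset) else {}
        self._speeds = np.zeros(0)

    # -- seeding -----------------------------------------------------------

    def add_agents(self, type_name: str, positions) -> np.ndarray:
        return self.population.add_agents(type_name, positions)

    # -- per-sweep operations ------------------------------------------------

    def _behavior(self, name: str) -> np.ndarray:
        pop = self.population
        if name in pop.behaviors:
            return pop.behaviors[name]
        per_type = np.array([ct.base_value(name) for ct in pop.cell_types])
        return per_type[pop.type] if len(pop) else np.zeros(0)

    def phenotype_sweep(self, dt: float) -> None:
        """Mutually exclusive stochastic events: death, transformation,
        division (in that order), from the current behaviour vectors."""
        pop = self.population
        n = len(pop)
        if n == 0:
            return
        live = pop.state == LIVE
        busy = np.zeros(n, dtype=bool)  # got an event already this sweep

        # 1. death
        for kind, state_code, duration_attr in (
            ("apoptosis", APOPTOTIC, "apoptosis_duration"),
            ("necrosis", NECROTIC, "necrosis_lysis_duration"),
        ):
            rate = self._behavior(kind)
            u = self.rng.random(n)
            hit = live & ~busy & (u < rate_to_probability(rate, dt))
            for row in np.where(hit)[0]:
                ct = pop.cell_types[pop.type[row]]
                pop.state[row] = state_code
                pop.death_clock[row] = self.time + getattr(ct, duration_attr)
                pop.attack_target[row] = -1
                self.events.log(self.time, "death", mode=kind, id=int(pop.id[row]),
                                cell_type=ct.name)
            busy |= hit

        # 2. transformation (first success in randomized target order)
        transform_behaviors = sorted(
            b for b in pop.behaviors if b.startswith("transform to ")
        )
        if transform_behaviors:
            targets = [b[len("transform to "):] for b in transform_behaviors]
            probs = np.stack(
                [rate_to_probability(pop.behaviors[b], dt) for b in transform_behaviors],
                axis=1,
            )
            u = self.rng.random(probs.shape)
            prio = self.rng.random(probs.shape)
            success = u < probs
            success[~(live & ~busy), :] = False
            keyed = np.where(success, prio, np.inf)
            winner = np.argmin(keyed, axis=1)
            has = success.any(axis=1)
            for row in np.where(has)[0]:
                tgt = targets[winner[row]]
                if tgt not in pop.type_index:
                    continue
                old = pop.type_name(row)
                k = pop.type_index[tgt]
                pop.type[row] = k
                ct = pop.cell_types[k]
                pop.radius[row] = ct.radius
                self.events.log(self.time, "transformation", id=int(pop.id[row]),
                                from_type=old, to_type=tgt)
            busy |= has

        # 3. division
        rate = self._behavior("cycle entry")
        u = self.rng.random(n)
        divide = live & ~busy & (u < rate_to_probability(rate, dt))
        rows = np.where(divide)[0]
        if len(rows):
            theta = self.rng.random(len(rows)) * 2.0 * math.pi
            direction = np.stack([np.cos(theta), np.sin(theta)], axis=1)
            for idx, row in enumerate(rows):
                ct = pop.cell_types[pop.type[row]]
                half_v = pop.volume[row] / 2.0
                new_r = pop.radius[row] / 2.0 ** (1.0 / 3.0)
                offset = direction[idx] * (pop.radius[row] / 2.0)
                parent_pos = pop.position[row].copy()
                daughter_type = ct.name
                if ct.fate_table:
                    daughter_type = self._fate_lookup(ct) or ct.name
                d_pos = self._clamp(parent_pos + offset)
                pop.position[row] = self._clamp(parent_pos - offset)
                pop.volume[row] = half_v
                pop.radius[row] = new_r
                new_ids = pop.add_agents(daughter_type, d_pos[None, :])
                pop.volume[-1] = half_v
                pop.radius[-1] = new_r
                self.events.log(self.time, "division", parent=int(pop.id[row]),
                                daughter=int(new_ids[0]), cell_type=ct.name,
                                daughter_type=daughter_type)
            # population arrays changed size; behaviour vectors were reset
            # by add_agents and are refreshed at the next phenotype step

    def _fate_lookup(self, ct: CellType) -> str | None:
        for t0, t1, name in ct.fate_table:
            if t0 <= self.time < t1:
                return name
        return None

    def attack_sweep(self, dt: float) -> None:
        """Effector attack: engagement is stochastic per the attack rate;
        an engaged attacker deals damage_rate*dt per sweep while contact
        with a live target persists.  Attack is non-exclusive: several
        attackers may damage one target."""
        pop = self.population
        n = len(pop)
        if n == 0:
            return
        attack_behaviors = [b for b in pop.behaviors if b.startswith("attack ")]
        if not attack_behaviors:
            return
        pairs = pop.neighbor_pairs()
        contacts: dict[int, list[int]] = {}
        for a, b in pairs:
            contacts.setdefault(int(a), []).append(int(b))
            contacts.setdefault(int(b), []).append(int(a))
        id_to_row = {int(pop.id[r]): r for r in range(n)}
        damage_rate = self._behavior("damage rate")
        live = pop.state == LIVE
        order = np.argsort(pop.id)
        for row in order:
            if not live[row]:
                continue
            rates = {}
            for beh in attack_behaviors:
                target_type = beh[len("attack "):]
                r = float(pop.behaviors[beh][row])
                if r > 0 and target_type in pop.type_index:
                    rates[pop.type_index[target_type]] = r
            if not rates:
                continue
            eligible = [
                c for c in contacts.get(int(row), [])
                if live[c] and int(pop.type[c]) in rates
            ]
            tgt_row = id_to_row.get(int(pop.attack_target[row]), -1)
            engaged = tgt_row >= 0 and tgt_row in eligible
            if not engaged:
                pop.attack_target[row] = -1
                if eligible:
                    pick = eligible[int(self.rng.integers(len(eligible)))]
                    rate = rates[int(pop.type[pick])]
                    if self.rng.random() < rate_to_probability(rate, dt):
                        pop.attack_target[row] = pop.id[pick]
                        tgt_row = pick
                        engaged = True
                        self.events.log(self.time, "attack", attacker=int(pop.id[row]),
                                        target=int(pop.id[pick]))
            if engaged:
                pop.damage[tgt_row] += damage_rate[row] * dt

    def death_and_clearance(self, dt: float) -> None:
        """Phagocytosis of dead (and flagged live) targets, then removal of
        dead cells whose apoptosis/lysis clocks expired."""
        pop = self.population
        n = len(pop)
        if n == 0:
            return
        remove = np.zeros(n, dtype=bool)
        phag_behaviors = [
            b for b in pop.behaviors
            if b == "phagocytose dead cell" or b.startswith("phagocytose ")
        ]
        if phag_behaviors:
            pairs = pop.neighbor_pairs()
            live = pop.state == LIVE
            for a, b in pairs:
                for eater, prey in ((int(a), int(b)), (int(b), int(a))):
                    if not live[eater] or remove[prey]:
                        continue
                    rate = 0.0
                    if not live[prey]:
                        rate = float(self._behavior("phagocytose dead cell")[eater])
                    else:
                        beh = f"phagocytose {pop.type_name(prey)}"
                        if beh in pop.behaviors:
                            rate = float(pop.behaviors[beh][eater])
                    if rate > 0 and self.rng.random() < rate_to_probability(rate, dt):
                        remove[prey] = True
                        self.events.log(self.time, "phagocytosed",
                                        eater=int(pop.id[eater]), prey=int(pop.id[prey]))
        expired = (pop.state != LIVE) & (self.time >= pop.death_clock) & ~remove
        for row in np.where(expired)[0]:
            kind = "cleared" if pop.state[row] == APOPTOTIC else "lysed"
            self.events.log(self.time, kind, id=int(pop.id[row]))
        remove |= expired
        if remove.any():
            pop.remove(remove)
            self._speeds = np.zeros(len(pop))

    def motility_mechanics_sweep(self, dt: float) -> None:
        """Biased random motility plus pairwise repulsion/adhesion forces,
        overdamped position update, positions clamped to the domain."""
        pop = self.population
        n = len(pop)
        if n == 0:
            return
        live = pop.state == LIVE
        inert = np.array([pop.cell_types[k].inert for k in pop.type])
        speed = self._behavior("migration speed") * live * ~inert
        bias = self._behavior("migration bias")
        persistence = np.maximum(self._behavior("migration persistence time"), 1e-9)

        # redraw motility direction when the persistence timer expires
        pop.persistence_timer -= dt
        expired = (pop.persistence_timer <= 0) & live & ~inert
        theta = self.rng.random(n) * 2.0 * math.pi  # fixed-size draw for determinism
        if expired.any():
            rand_dir = np.stack([np.cos(theta), np.sin(theta)], axis=1)
            grad_dir = np.zeros((n, 2))
            for k, ct in enumerate(pop.cell_types):
                if ct.chemotaxis_substrate and ct.chemotaxis_substrate in self.microenv:
                    rows = np.where((pop.type == k) & expired)[0]
                    if len(rows):
                        g = self.microenv[ct.chemotaxis_substrate].gradient_many(
                            pop.position[rows]
                        )
                        norm = np.linalg.norm(g, axis=1, keepdims=True)
                        g = np.where(norm > 0, g / np.maximum(norm, 1e-300), 0.0)
                        grad_dir[rows] = ct.chemotaxis_direction * g
            mix = bias[:, None] * grad_dir + (1.0 - bias[:, None]) * rand_dir
            norm = np.linalg.norm(mix, axis=1, keepdims=True)
            mix = np.where(norm > 0, mix / np.maximum(norm, 1e-300), rand_dir)
            pop.motility_dir[expired] = mix[expired]
            pop.persistence_timer[expired] = persistence[expired]

        velocity = speed[:, None] * pop.motility_dir

        # pairwise mechanics: quadratic repulsion on overlap, adhesion within
        # the interaction distance
        pairs = pop.neighbor_pairs()
        if len(pairs):
            a, b = pairs[:, 0], pairs[:, 1]
            delta = pop.position[a] - pop.position[b]
            d = np.linalg.norm(delta, axis=1)
            d = np.maximum(d, 1e-9)
            unit = delta / d[:, None]
            rsum = pop.radius[a] + pop.radius[b]
            cr = 0.5 * (self._behavior("cell-cell repulsion strength")[a]
                        + self._behavior("cell-cell repulsion strength")[b])
            ca = 0.5 * (self._behavior("cell-cell adhesion strength")[a]
                        + self._behavior("cell-cell adhesion strength")[b])
            overlap = np.maximum(1.0 - d / rsum, 0.0)
            rep = cr * overlap ** 2
            r_adh = 1.25 * rsum
            adh_term = np.maximum(1.0 - d / r_adh, 0.0)
            adh = ca * adh_term ** 2
            f = (rep - adh)[:, None] * unit
            np.add.at(velocity, a, f)
            np.add.at(velocity, b, -f)

        pop.position = self._clamp(pop.position + velocity * dt)
        self._speeds = np.linalg.norm(velocity, axis=1)

    def _clamp(self, positions: np.ndarray) -> np.ndarray:
        d = self.domain
        return np.clip(positions, [d.x_min, d.y_min], [d.x_max, d.y_max])

    def _exchange(self, dt: float) -> None:
        """Aggregate per-voxel secretion/uptake from all live agents (one
        implicit update per voxel per substrate)."""
        pop = self.population
        n = len(pop)
        if n == 0 or not self.microenv.fields:
            return
        live = pop.state == LIVE
        ii, jj = self.domain.voxel_indices(pop.position)
        Vv = self.domain.voxel_volume
        for name, fld in self.microenv.fields.items():
            S = self._behavior(f"{name} secretion") * live
            U = self._behavior(f"{name} uptake") * live
            if not (S.any() or U.any()):
                continue
            f = dt * pop.volume / Vv
            num = np.zeros(self.domain.shape)
            den = np.zeros(self.domain.shape)
            np.add.at(num, (ii, jj), f * S * fld.saturation_density)
            np.add.at(den, (ii, jj), f * (S + U))
            fld.values = (fld.values + num) / (1.0 + den)

    # -- main loop -----------------------------------------------------------

    def refresh_rules(self) -> None:
        signals = compute_signals(self.population, self.microenv, self.time)
        apply_rules(self.population, self.compiled, signals)

    def run(self, progress: bool = False) -> tuple[list[Snapshot], EventLog]:
        sched = self.schedule
        snapshots = [self.snapshot()]
        if sched.total_time <= 0:
            return snapshots, self.events
        n_mech = int(round(sched.total_time / sched.dt_mechanics))
        next_snap = sched.snapshot_interval
        self.refresh_rules()
        for step in range(1, n_mech + 1):
            for _ in range(sched.diffusion_substeps):
                self._exchange(sched.dt_diffusion)
                self.microenv.step(sched.dt_diffusion)
            self.motility_mechanics_sweep(sched.dt_mechanics)
            self.time = step * sched.dt_mechanics
            if step % sched.mechanics_per_phenotype == 0:
                self.refresh_rules()
                self.phenotype_sweep(sched.dt_phenotype)
                self.attack_sweep(sched.dt_phenotype)
                self.death_and_clearance(sched.dt_phenotype)
                self._relax_volumes(sched.dt_phenotype)
            if self.time >= next_snap - 1e-9:
                snapshots.append(self.snapshot())
                next_snap += sched.snapshot_interval
        if snapshots[-1].time < self.time:
            snapshots.append(self.snapshot())
        return snapshots, self.events

    def _relax_volumes(self, dt: float) -> None:
        pop = self.population
        if len(pop) == 0:
            return
        target_v = np.array([ct.volume for ct in pop.cell_types])[pop.type]
        target_r = np.array([ct.radius for ct in pop.cell_types])[pop.type]
        frac = 1.0 - math.exp(-VOLUME_RELAXATION_RATE * dt)
        pop.volume += (target_v - pop.volume) * frac
        pop.radius = target_r * (pop.volume / target_v) ** (1.0 / 3.0)

    def snapshot(self) -> Snapshot:
        pop = self.population
        n = len(pop)
        speeds = self._speeds if len(self._speeds) == n else np.zeros(n)
        return Snapshot(
            time=self.time,
            ids=pop.id.copy(),
            positions=pop.position.copy(),
            cell_types=[pop.type_name(r) for r in range(n)],
            states=[pop.state_name(r) for r in range(n)],
            volumes=pop.volume.copy(),
            damage=pop.damage.copy(),
            speeds=speeds.copy(),
            substrates={k: f.values.copy() for k, f in self.microenv.fields.items()},
        )


def run_simulation(scenario, seed: int = 0, **overrides) -> tuple[list[Snapshot], EventLog]:
    """Build and run a scenario (see :mod:`cellgrammar.scenarios`)."""
    sim = scenario.build(seed=seed, **overrides)
    return sim.run()
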