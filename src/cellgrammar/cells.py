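"""Cell types, agent population state, signal readout, and rule application.

Agents are off-lattice circles with position, volume, live/dead substate and
accumulated damage.  Population state is stored as flat numpy arrays (one
row per agent) for speed; :class:`CellAgent` is a lightweight per-agent view
used by the single-agent API and the tests.

Signals read by the rules for each agent:

* ``<substrate>``          concentration in the containing voxel
* ``<substrate> gradient`` magnitude of the voxel-centred gradient
* ``pressure``             dimensionless crowding score
  sum over overlapping neighbours of (1 - d/(r_i+r_j))^2
* ``contact with <type>``  neighbours of that type within the interaction
  distance 1.25*(r_i+r_j)
* ``contact with dead cell``, ``damage``, ``volume``, ``time``, ``dead``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .grammar import CORE_BEHAVIORS
from .responses import BehaviorResponse, aggregate_response

__all__ = ["CellType", "CellAgent", "Population", "LIVE", "APOPTOTIC", "NECROTIC",
           "CONTACT_MULTIPLIER", "read_signals", "apply_rules"]

LIVE, APOPTOTIC, NECROTIC = 0, 1, 2
_STATE_NAMES = {LIVE: "live", APOPTOTIC: "apoptotic", NECROTIC: "necrotic"}

#: neighbours within CONTACT_MULTIPLIER*(r_i+r_j) count as "in contact"
CONTACT_MULTIPLIER = 1.25


@dataclass
class CellType:
    """A named cell kind with its base behavioural phenotype.

    ``phenotype`` maps behavior identifier -> base value b0 (e.g. "cycle
    entry" in 1/min, "migration speed" in um/min).  Behaviours absent from
    the map default to 0 except persistence time (1 min) and mechanics
    strengths.  ``chemotaxis`` optionally names a substrate and a direction
    (+1 up-gradient, -1 down-gradient).  ``fate_table`` enables asymmetric
    division: a list of (t_start_min, t_end_min, daughter_type) windows; the
    non-stem daughter's type is looked up at division time.
    """

    name: str
    phenotype: dict[str, float] = field(default_factory=dict)
    radius: float = 8.4  # um; default gives ~2494 um^3, a typical cell volume
    chemotaxis_substrate: str | None = None
    chemotaxis_direction: int = 1
    fate_table: list[tuple[float, float, str]] | None = None
    apoptosis_duration: float = 516.0   # min until an apoptotic cell is cleared
    necrosis_lysis_duration: float = 1440.0  # min until a necrotic cell lyses
    inert: bool = False                 # mechanics-only scaffold cells

    _DEFAULTS = {
        "migration persistence time": 1.0,
        "migration bias": 0.0,
        "cell-cell repulsion strength": 10.0,
        "cell-cell adhesion strength": 0.4,
    }

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        for k, v in self.phenotype.items():
            if k == "migration bias" and not (0.0 <= v <= 1.0):
                raise ValueError("migration bias must lie in [0, 1]")

    def base_value(self, behavior: str) -> float:
        if behavior in self.phenotype:
            return float(self.phenotype[behavior])
        return float(self._DEFAULTS.get(behavior, 0.0))

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius ** 3


class Population:
    """Struct-of-arrays store for all agents in a simulation."""

    def __init__(self, cell_types: list[CellType]):
        self.cell_types = list(cell_types)
        self.type_index = {ct.name: k for k, ct in enumerate(self.cell_types)}
        n = 0
        self.id = np.zeros(n, dtype=np.int64)
        self.position = np.zeros((n, 2))
        self.type = np.zeros(n, dtype=np.int32)
        self.state = np.zeros(n, dtype=np.int8)
        self.volume = np.zeros(n)
        self.radius = np.zeros(n)
        self.damage = np.zeros(n)
        self.motility_dir = np.zeros((n, 2))
        self.persistence_timer = np.zeros(n)
        self.death_clock = np.full(n, np.inf)
        self.attack_target = np.full(n, -1, dtype=np.int64)  # id of locked target
        self._next_id = 0
        #: behaviour vectors refreshed each phenotype sweep: behavior -> array
        self.behaviors: dict[str, np.ndarray] = {}

    # -- bookkeeping -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.id)

    def add_agents(self, type_name: str, positions: np.ndarray) -> np.ndarray:
        """Append agents of one type; returns their ids."""
        k = self.type_index[type_name]
        ct = self.cell_types[k]
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        n = len(positions)
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.id = np.concatenate([self.id, ids])
        self.position = np.vstack([self.position, positions])
        self.type = np.concatenate([self.type, np.full(n, k, dtype=np.int32)])
        self.state = np.concatenate([self.state, np.zeros(n, dtype=np.int8)])
        self.volume = np.concatenate([self.volume, np.full(n, ct.volume)])
        self.radius = np.concatenate([self.radius, np.full(n, ct.radius)])
        self.damage = np.concatenate([self.damage, np.zeros(n)])
        self.motility_dir = np.vstack([self.motility_dir, np.zeros((n, 2))])
        self.persistence_timer = np.concatenate([self.persistence_timer, np.zeros(n)])
        self.death_clock = np.concatenate([self.death_clock, np.full(n, np.inf)])
        self.attack_target = np.concatenate(
            [self.attack_target, np.full(n, -1, dtype=np.int64)]
        )
        # extend current behaviour vectors with the new agents' base values
        self.behaviors = {
            beh: np.concatenate([arr, np.full(n, ct.base_value(beh))])
            for beh, arr in self.behaviors.items()
        }
        return ids

    def remove(self, mask: np.ndarray) -> None:
        keep = ~mask
        self.id = self.id[keep]
        self.position = self.position[keep]
        self.type = self.type[keep]
        self.state = self.state[keep]
        self.volume = self.volume[keep]
        self.radius = self.radius[keep]
        self.damage = self.damage[keep]
        self.motility_dir = self.motility_dir[keep]
        self.persistence_timer = self.persistence_timer[keep]
        self.death_clock = self.death_clock[keep]
        self.attack_target = self.attack_target[keep]
        self.behaviors = {k: v[keep] for k, v in self.behaviors.items()}

    def type_name(self, row: int) -> str:
        return self.cell_types[self.type[row]].name

    def state_name(self, row: int) -> str:
        return _STATE_NAMES[int(self.state[row])]

    def agent(self, row: int) -> "CellAgent":
        return CellAgent(self, row)

    def counts_by_type(self, live_only: bool = False) -> dict[str, int]:
        out = {ct.name: 0 for ct in self.cell_types}
        for k, ct in enumerate(self.cell_types):
            mask = self.type == k
            if live_only:
                mask &= self.state == LIVE
            out[ct.name] = int(mask.sum())
        return out

    # -- neighbour queries -------------------------------------------------

    def neighbor_pairs(self) -> np.ndarray:
        """All pairs (row_i, row_j) within the contact distance.

        Uses a k-d tree over positions; the query radius is the largest
        possible interaction distance, pairs are then filtered by the exact
        per-pair criterion d <= CONTACT_MULTIPLIER*(r_i+r_j).
        """
        if len(self) < 2:
            return np.empty((0, 2), dtype=np.intp)
        rmax = float(self.radius.max())
        tree = cKDTree(self.position)
        pairs = tree.query_pairs(r=2.0 * rmax * CONTACT_MULTIPLIER, output_type="ndarray")
        if len(pairs) == 0:
            return pairs
        d = np.linalg.norm(self.position[pairs[:, 0]] - self.position[pairs[:, 1]], axis=1)
        rsum = self.radius[pairs[:, 0]] + self.radius[pairs[:, 1]]
        return pairs[d <= CONTACT_MULTIPLIER * rsum]


class CellAgent:
    """A view onto one row of a :class:`Population`."""

    def __init__(self, population: Population, row: int):
        self._pop = population
        self._row = row

    id = property(lambda self: int(self._pop.id[self._row]))
    position = property(lambda self: self._pop.position[self._row])
    cell_type = property(lambda self: self._pop.type_name(self._row))
    state = property(lambda self: self._pop.state_name(self._row))
    volume = property(lambda self: float(self._pop.volume[self._row]))
    radius = property(lambda self: float(self._pop.radius[self._row]))
    damage = property(lambda self: float(self._pop.damage[self._row]))

    @property
    def is_dead(self) -> bool:
        return int(self._pop.state[self._row]) != LIVE

    def behavior(self, name: str) -> float:
        if name in self._pop.behaviors:
            return float(self._pop.behaviors[name][self._row])
        return self._pop.cell_types[self._pop.type[self._row]].base_value(name)


# -- signal extraction ------------------------------------------------------


def compute_signals(pop: Population, microenv, time: float) -> dict[str, np.ndarray]:
    """Vectorized signal readout for every agent.

    Returns a map signal identifier -> array over agents.  Substrate
    concentrations/gradients are sampled at the containing voxel (positions
    clamped at the boundary); contact counts use the exact pairwise contact
    criterion; pressure is the crowding score over overlapping neighbours.
    """
    n = len(pop)
    signals: dict[str, np.ndarray] = {}
    if microenv is not None:
        for name, fld in microenv.fields.items():
            signals[name] = fld.sample_many(pop.position) if n else np.zeros(0)
            g = fld.gradient_many(pop.position) if n else np.zeros((0, 2))
            signals[f"{name} gradient"] = np.linalg.norm(g, axis=1)
    pressure = np.zeros(n)
    contact = {ct.name: np.zeros(n) for ct in pop.cell_types}
    contact_dead = np.zeros(n)
    pairs = pop.neighbor_pairs()
    if len(pairs):
        a, b = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(pop.position[a] - pop.position[b], axis=1)
        rsum = pop.radius[a] + pop.radius[b]
        overlap = d < rsum
        score = np.where(overlap, (1.0 - d / rsum) ** 2, 0.0)
        np.add.at(pressure, a, score)
        np.add.at(pressure, b, score)
        for k, ct in enumerate(pop.cell_types):
            np.add.at(contact[ct.name], a, (pop.type[b] == k).astype(float))
            np.add.at(contact[ct.name], b, (pop.type[a] == k).astype(float))
        dead = pop.state != LIVE
        np.add.at(contact_dead, a, dead[b].astype(float))
        np.add.at(contact_dead, b, dead[a].astype(float))
    signals["pressure"] = pressure
    for name, arr in contact.items():
        signals[f"contact with {name}"] = arr
    signals["contact with dead cell"] = contact_dead
    signals["damage"] = pop.damage.copy()
    signals["volume"] = pop.volume.copy()
    signals["time"] = np.full(n, float(time))
    signals["dead"] = (pop.state != LIVE).astype(float)
    return signals


def read_signals(agent: CellAgent, microenv, time: float) -> dict[str, float]:
    """Single-agent signal vector (scalar values)."""
    pop = agent._pop
    all_sig = compute_signals(pop, microenv, time)
    return {k: float(v[agent._row]) for k, v in all_sig.items()}


# -- rule application -------------------------------------------------------


def apply_rules(
    pop: Population,
    compiled: dict[str, dict[str, BehaviorResponse]],
    signals: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Evaluate every compiled behaviour response for every agent.

    Behaviours without rules keep base phenotype values.  Dead agents only
    feel rule terms flagged applies-to-dead; when none apply the behaviour
    falls back to the base value.  Results are written to ``pop.behaviors``
    and returned.
    """
    n = len(pop)
    behaviors: dict[str, np.ndarray] = {}
    needed = set(CORE_BEHAVIORS)
    for per_type in compiled.values():
        needed.update(per_type)
    for ct in pop.cell_types:
        needed.update(ct.phenotype)
    for beh in sorted(needed):
        per_type = np.array([ct.base_value(beh) for ct in pop.cell_types])
        behaviors[beh] = per_type[pop.type] if n else np.zeros(0)
    dead = pop.state != LIVE
    for ct_name, per_behavior in compiled.items():
        if ct_name not in pop.type_index:
            continue
        k = pop.type_index[ct_name]
        rows = np.where(pop.type == k)[0]
        if len(rows) == 0:
            continue
        sub = {name: arr[rows] for name, arr in signals.items()}
        for beh, resp in per_behavior.items():
            live_rows = rows[~dead[rows]]
            dead_rows = rows[dead[rows]]
            if len(live_rows):
                sub_live = {name: arr[~dead[rows]] for name, arr in sub.items()}
                behaviors[beh][live_rows] = _evaluate(resp, sub_live, dead=False)
            if len(dead_rows):
                sub_dead = {name: arr[dead[rows]] for name, arr in sub.items()}
                behaviors[beh][dead_rows] = _evaluate(resp, sub_dead, dead=True)
    pop.behaviors = behaviors
    return behaviors


def _evaluate(resp: BehaviorResponse, signals, *, dead: bool):
    U = aggregate_response(resp.up_terms, signals, dead=dead)
    D = aggregate_response(resp.down_terms, signals, dead=dead)
    b0 = resp.base_value
    bM = resp.max_value if resp.max_value is not None else b0
    bm = resp.min_value if resp.min_value is not None else b0
    return (1.0 - D) * ((1.0 - U) * b0 + U * bM) + D * bm
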