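"""Bundled scenario models and synthetic-data fixture generators.

Each scenario packages a rules file (CSV text), substrate definitions, cell
types with base phenotypes, an initial seeding, and a timestep schedule.
Scenarios are self-contained — no external data needed — and validate
against the signal/behavior dictionaries on construction.  ``build`` yields
a runnable :class:`~cellgrammar.engine.Simulation`; ``reduced=True``
switches to the desk-scale variant (smaller domain and counts at the same
cell density, shorter horizon) used for quick qualitative runs.

Numeric parameters that the underlying studies do not print (most rates and
half-maxes) are package defaults chosen for biological plausibility; they
are annotated "unstated" in each scenario's notes.  Where a reduced-scale
variant rescales a parameter (e.g. oxygen uptake, so the smaller tumor
spans the same number of oxygen penetration depths as the full one), the
override is listed explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cells import CellType
from .engine import Schedule, Simulation
from .grammar import RuleSet, Vocabulary, parse_rules_csv
from .initialization import SeedingSpec, seed_disk, seed_ring
from .metrics import PopulationSeries, population_auc
from .microenv import Boundary, Domain
from .sensitivity import PARAM_FIELDS, biphasic_hill

__all__ = ["Scenario", "build_scenario", "available_scenarios",
           "FixtureGenerator", "generate_fixture"]

#: physioxic far-field oxygen, mmHg
PHYSIOXIA = 38.0

OXYGEN = dict(name="oxygen", diffusion_coefficient=1.0e5, decay_rate=0.1,
              initial_value=PHYSIOXIA, boundary=Boundary.DIRICHLET,
              boundary_value=PHYSIOXIA, saturation_density=PHYSIOXIA)


def _factor(name, **kw):
    """A secreted, diffusing signalling factor (dimensionless, rho* = 1)."""
    base = dict(name=name, diffusion_coefficient=1.0e4, decay_rate=0.01,
                initial_value=0.0, boundary=Boundary.NO_FLUX, saturation_density=1.0)
    base.update(kw)
    return base


ECM = dict(name="ecm", diffusion_coefficient=0.0, decay_rate=0.0,
           initial_value=0.0, boundary=Boundary.NO_FLUX, saturation_density=1.0)


@dataclass
class Scenario:
    """A fully specified, runnable model."""

    name: str
    description: str
    domain: Domain
    substrates: list[dict]
    cell_types: list[CellType]
    rules_csv: str
    seedings: list[SeedingSpec]
    schedule: Schedule
    #: desk-scale variant: overrides for domain/seedings/schedule/phenotypes
    reduced_overrides: dict = field(default_factory=dict)
    #: provenance notes: rule or parameter -> origin ("stated" / "unstated")
    notes: dict[str, str] = field(default_factory=dict)
    #: optional initial substrate values: name -> array or callable(domain)
    initial_fields: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- validation ---------------------------------------------------------

    def vocabulary(self) -> Vocabulary:
        return Vocabulary(
            substrates=[s["name"] for s in self.substrates],
            cell_types=[ct.name for ct in self.cell_types],
        )

    def rules(self) -> RuleSet:
        return parse_rules_csv(self.rules_csv, self.vocabulary())

    def validate(self) -> None:
        rs = self.rules()
        type_names = {ct.name for ct in self.cell_types}
        for spec in self.seedings:
            unknown = set(spec.counts) - type_names
            if unknown:
                raise ValueError(f"{self.name}: seeding uses unknown types {sorted(unknown)}")
        assert len(rs) >= 0  # parse succeeded

    # -- construction -------------------------------------------------------

    def build(self, seed: int = 0, reduced: bool = False,
              param_factors: dict[str, float] | None = None,
              total_time: float | None = None,
              snapshot_interval: float | None = None) -> Simulation:
        domain = self.reduced_overrides.get("domain", self.domain) if reduced else self.domain
        schedule = self.reduced_overrides.get("schedule", self.schedule) if reduced \
            else self.schedule
        seedings = self.reduced_overrides.get("seedings", self.seedings) if reduced \
            else self.seedings
        if total_time is not None or snapshot_interval is not None:
            schedule = replace(
                schedule,
                total_time=total_time if total_time is not None else schedule.total_time,
                snapshot_interval=snapshot_interval if snapshot_interval is not None
                else schedule.snapshot_interval,
            )
        cell_types = [replace(ct, phenotype=dict(ct.phenotype)) for ct in self.cell_types]
        if reduced:
            for (tname, beh), value in self.reduced_overrides.get("phenotypes", {}).items():
                for ct in cell_types:
                    if ct.name == tname:
                        ct.phenotype[beh] = value
        ruleset = self.rules()
        if param_factors:
            ruleset, cell_types = _apply_param_factors(ruleset, cell_types, param_factors)
        sim = Simulation(
            domain=domain,
            cell_types=cell_types,
            ruleset=ruleset,
            substrates=self.substrates,
            schedule=schedule,
            seed=seed,
        )
        for name, init in self.initial_fields.items():
            values = init(domain) if callable(init) else np.asarray(init, dtype=float)
            sim.microenv[name].values = values.copy()
        for spec in seedings:
            _seed_spec(sim, spec)
        return sim

    # -- sensitivity hooks ---------------------------------------------------

    def parameter_ids(self) -> list[str]:
        """Addressable rule parameters, ruleN_{base,sat,hfm,hp}."""
        out = []
        for n, _ in enumerate(self.rules(), start=1):
            out.extend(f"rule{n}_{f}" for f in PARAM_FIELDS)
        return out

    def qoi_runner(self, total_time: float | None = None):
        """Runner for sensitivity sweeps: live-population AUC per cell type
        on the reduced variant."""

        def run(factors: dict[str, float], seed: int) -> dict[str, float]:
            sim = self.build(seed=seed, reduced=True, param_factors=factors,
                             total_time=total_time)
            snaps, _ = sim.run()
            series = PopulationSeries.from_snapshots(snaps, live_only=True)
            return {f"auc_{t}": population_auc(series, t) for t in series.counts}

        return run


def _seed_spec(sim: Simulation, spec: SeedingSpec) -> None:
    if spec.mode == "disk":
        for tname, count in spec.counts.items():
            pts, _ = seed_disk(count, spec.radius, spec.center, tname, rng=sim.rng)
            sim.add_agents(tname, pts)
    elif spec.mode == "ring":
        pts, labels = seed_ring(spec.counts, spec.inner_radius, spec.outer_radius,
                                spec.center, rng=sim.rng)
        start = 0
        for tname, count in spec.counts.items():
            sim.add_agents(tname, pts[start:start + count])
            start += count
    elif spec.mode == "box":
        # counts seeded uniformly in the rectangle (center, radius) interpreted
        # as (center, half-extents): used by the layered-growth scenario
        half = np.asarray(spec.radius)
        for tname, count in spec.counts.items():
            u = sim.rng.random((int(count), 2)) * 2.0 - 1.0
            pts = np.asarray(spec.center) + u * half
            sim.add_agents(tname, pts)
    else:
        raise ValueError(f"unsupported seeding mode {spec.mode!r}")


def _apply_param_factors(ruleset: RuleSet, cell_types: list[CellType], factors):
    rules = list(ruleset.rules)
    cell_types = [replace(ct, phenotype=dict(ct.phenotype)) for ct in cell_types]
    by_name = {ct.name: ct for ct in cell_types}
    for pid, f in factors.items():
        try:
            rule_part, fld = pid.rsplit("_", 1)
            n = int(rule_part.removeprefix("rule"))
            rule = rules[n - 1]
        except (ValueError, IndexError):
            raise KeyError(f"unaddressable parameter id {pid!r}") from None
        if fld == "base":
            ct = by_name[rule.cell_type]
            ct.phenotype[rule.behavior] = ct.base_value(rule.behavior) * f
        elif fld == "sat":
            rules[n - 1] = replace(rule, saturation_value=rule.saturation_value * f)
        elif fld == "hfm":
            rules[n - 1] = replace(rule, half_max=rule.half_max * f)
        elif fld == "hp":
            rules[n - 1] = replace(rule, hill_power=rule.hill_power * f)
        else:
            raise KeyError(f"unaddressable parameter id {pid!r}")
    return RuleSet(rules=rules, source=ruleset.source), cell_types


# ---------------------------------------------------------------------------
# scenario definitions
# ---------------------------------------------------------------------------


def _tumor_base(**extra) -> dict:
    pheno = {
        "cycle entry": 0.0,           # driven by the oxygen rule
        "apoptosis": 5.3e-5,
        "necrosis": 0.0028,           # anoxic rate; oxygen rule suppresses it
        "oxygen uptake": 10.0,
        "migration speed": 0.0,
    }
    pheno.update(extra)
    return pheno


def _hypoxia() -> Scenario:
    """Oxygen-limited tumor growth with a transient post-hypoxic motile
    phenotype: low oxygen triggers necrosis and conversion to a motile type;
    reoxygenation reverts motile cells."""
    rules = "\n".join([
        "tumor,oxygen,increases,cycle entry,0.00072,21.5,4,0",
        "tumor,oxygen,decreases,necrosis,0,5,8,0",
        "tumor,oxygen,decreases,transform to motile tumor,0,8,8,0",
        "motile tumor,oxygen,increases,cycle entry,0.00072,21.5,4,0",
        "motile tumor,oxygen,decreases,necrosis,0,5,8,0",
        "motile tumor,oxygen,increases,transform to tumor,0.01,12,8,0",
    ]) + "\n"
    tumor = CellType("tumor", phenotype=_tumor_base(**{
        "transform to motile tumor": 0.005,  # anoxic rate, suppressed by oxygen
    }))
    motile = CellType("motile tumor", phenotype=_tumor_base(**{
        "migration speed": 0.75,
        "migration bias": 0.25,
        "migration persistence time": 15.0,
        "transform to tumor": 0.0,  # reversion driven up by oxygen
    }), chemotaxis_substrate="oxygen", chemotaxis_direction=1)
    full_seed = [SeedingSpec(mode="disk", counts={"tumor": 2000}, radius=400.0)]
    reduced = dict(
        domain=Domain(-500, 500, -500, 500, voxel_size=20.0),
        seedings=[SeedingSpec(mode="disk", counts={"tumor": 500}, radius=200.0)],
        schedule=Schedule(dt_diffusion=0.05, dt_mechanics=0.1, dt_phenotype=6.0,
                          total_time=720.0, snapshot_interval=120.0),
        # oxygen uptake raised so the desk-scale tumor spans the same number
        # of oxygen penetration depths as the grown full-scale tumor
        phenotypes={("tumor", "oxygen uptake"): 80.0,
                    ("motile tumor", "oxygen uptake"): 80.0},
    )
    return Scenario(
        name="hypoxia",
        description="oxygen-dependent tumor growth with post-hypoxic migration",
        domain=Domain(-1000, 1000, -1000, 1000, voxel_size=20.0),
        substrates=[dict(OXYGEN)],
        cell_types=[tumor, motile],
        rules_csv=rules,
        seedings=full_seed,
        schedule=Schedule(total_time=7200.0, snapshot_interval=360.0),
        reduced_overrides=reduced,
        notes={
            "oxygen decreases necrosis": "stated rule",
            "oxygen decreases transformation to motile tumor cells": "stated rule",
            "2,000 cells, 400 um disk, 38 mmHg": "stated initial condition",
            "rates and half-maxes": "unstated; package defaults",
        },
    )


def _pdac_caf() -> Scenario:
    """Fibroblast/ECM-driven EMT in pancreatic cancer: fibroblasts deposit
    ECM; ECM density drives the epithelial-to-mesenchymal transformation
    (rate rising from 0 to 0.01/min) and biphasically modulates mesenchymal
    migration speed."""
    rules = "\n".join([
        "epithelial tumor,ecm,increases,transform to mesenchymal tumor,0.01,0.5,4,0",
        "epithelial tumor,inflammatory factor,increases,cycle entry,0.001,0.25,2,0",
        "epithelial tumor,oxygen,decreases,necrosis,0,5,8,0",
        "mesenchymal tumor,ecm,increases,migration speed,1.5,0.25,4,0",
        "mesenchymal tumor,ecm,decreases,migration speed,0,0.85,8,0",
        "mesenchymal tumor,inflammatory factor,increases,transform to epithelial tumor,0.002,0.25,2,0",
        "mesenchymal tumor,oxygen,decreases,necrosis,0,5,8,0",
    ]) + "\n"
    epithelial = CellType("epithelial tumor", phenotype=_tumor_base(**{
        "cycle entry": 0.0005,
    }))
    mesenchymal = CellType("mesenchymal tumor", phenotype=_tumor_base(**{
        "cycle entry": 0.0,              # EMT phenotype does not proliferate
        "migration speed": 0.0,          # driven by the biphasic ECM rules
        "migration persistence time": 15.0,
        "transform to epithelial tumor": 0.0,
    }))
    fibroblast = CellType("fibroblast", phenotype={
        "ecm secretion": 0.02,
        "inflammatory factor secretion": 0.5,
        "oxygen uptake": 2.0,
        "migration speed": 0.1,
    })
    full_seed = [SeedingSpec(mode="disk",
                             counts={"epithelial tumor": 833, "fibroblast": 167},
                             radius=400.0)]  # 1,000 cells at a 5:1 PANC:CAF ratio
    reduced = dict(
        domain=Domain(-500, 500, -500, 500, voxel_size=20.0),
        seedings=[SeedingSpec(mode="disk",
                              counts={"epithelial tumor": 208, "fibroblast": 42},
                              radius=200.0)],
        schedule=Schedule(dt_diffusion=0.05, dt_mechanics=0.1, dt_phenotype=6.0,
                          total_time=720.0, snapshot_interval=120.0),
    )
    return Scenario(
        name="pdac_caf",
        description="fibroblast-driven EMT and biphasic ECM motility in PDAC",
        domain=Domain(-1000, 1000, -1000, 1000, voxel_size=20.0),
        substrates=[dict(OXYGEN), dict(ECM), _factor("inflammatory factor")],
        cell_types=[epithelial, mesenchymal, fibroblast],
        rules_csv=rules,
        seedings=full_seed,
        schedule=Schedule(total_time=10080.0, snapshot_interval=720.0),
        reduced_overrides=reduced,
        notes={
            "EMT rate 0 to 0.01/min with ECM density": "stated",
            "biphasic motility via two Hill terms on ECM": "stated",
            "1,000 cells at PANC:CAF ratios": "stated",
            "other rates": "unstated; package defaults",
        },
    )


def _macrophage(name: str, secretes: dict[str, float], extra=None) -> CellType:
    pheno = {
        "migration speed": 1.0,
        "migration bias": 0.75,
        "migration persistence time": 10.0,
        "phagocytose dead cell": 0.02,
        "oxygen uptake": 1.0,
    }
    for sub, rate in secretes.items():
        pheno[f"{sub} secretion"] = rate
    pheno.update(extra or {})
    return CellType(name, phenotype=pheno,
                    chemotaxis_substrate="oxygen", chemotaxis_direction=-1)


def _immune_base() -> Scenario:
    """Tumor clearance by CD8 T cells with a plastic M1/M2 macrophage axis:
    oxygenation polarizes macrophages; pro-/anti-inflammatory factors
    modulate T-cell attack; damage kills tumor cells."""
    rules = "\n".join([
        "tumor,oxygen,increases,cycle entry,0.00072,21.5,4,0",
        "tumor,oxygen,decreases,necrosis,0,5,8,0",
        "tumor,damage,increases,apoptosis,0.05,30,4,0",
        "M1 macrophage,oxygen,decreases,transform to M2 macrophage,0,10,4,0",
        "M2 macrophage,oxygen,increases,transform to M1 macrophage,0.002,10,4,0",
        "CD8 T cell,pro-inflammatory factor,increases,attack tumor,0.1,0.2,2,0",
        "CD8 T cell,anti-inflammatory factor,decreases,attack tumor,0,0.2,2,0",
    ]) + "\n"
    tumor = CellType("tumor", phenotype=_tumor_base())
    m1 = _macrophage("M1 macrophage", {"pro-inflammatory factor": 1.0},
                     {"transform to M2 macrophage": 0.002})
    m2 = _macrophage("M2 macrophage", {"anti-inflammatory factor": 1.0},
                     {"transform to M1 macrophage": 0.0})
    cd8 = CellType("CD8 T cell", phenotype={
        "migration speed": 1.0,
        "migration bias": 0.5,
        "migration persistence time": 10.0,
        "attack tumor": 0.01,
        "damage rate": 0.1,
        "oxygen uptake": 1.0,
    }, chemotaxis_substrate="pro-inflammatory factor", chemotaxis_direction=1)
    full_seed = [
        SeedingSpec(mode="disk", counts={"tumor": 2000}, radius=400.0),
        SeedingSpec(mode="ring",
                    counts={"M1 macrophage": 100, "M2 macrophage": 100, "CD8 T cell": 100},
                    inner_radius=450.0, outer_radius=600.0),
    ]
    reduced = dict(
        domain=Domain(-500, 500, -500, 500, voxel_size=20.0),
        seedings=[
            SeedingSpec(mode="disk", counts={"tumor": 500}, radius=200.0),
            SeedingSpec(mode="ring",
                        counts={"M1 macrophage": 25, "M2 macrophage": 25, "CD8 T cell": 25},
                        inner_radius=225.0, outer_radius=300.0),
        ],
        schedule=Schedule(dt_diffusion=0.05, dt_mechanics=0.1, dt_phenotype=6.0,
                          total_time=720.0, snapshot_interval=120.0),
        phenotypes={("tumor", "oxygen uptake"): 80.0},
    )
    return Scenario(
        name="immune_base",
        description="tumor-immune clearance with plastic M1/M2 macrophages",
        domain=Domain(-1000, 1000, -1000, 1000, voxel_size=20.0),
        substrates=[dict(OXYGEN), _factor("pro-inflammatory factor"),
                    _factor("anti-inflammatory factor")],
        cell_types=[tumor, m1, m2, cd8],
        rules_csv=rules,
        seedings=full_seed,
        schedule=Schedule(total_time=7200.0, snapshot_interval=360.0),
        reduced_overrides=reduced,
        notes={
            "ring of immune cells, 100 of each non-tumor type": "stated",
            "oxygen-dependent macrophage polarization": "stated",
            "rates and half-maxes": "unstated; package defaults",
        },
    )


def _immune_extended() -> Scenario:
    """Extended immune model: M0/M1/M2 macrophages and naive/activated/
    exhausted CD8 T cells.  IFN-gamma activates naive T cells (IL-10
    inhibits activation); IL-10 exhausts activated T cells; hypoxia and
    IL-10 polarize macrophages toward M2."""
    rules = "\n".join([
        "tumor,oxygen,increases,cycle entry,0.00072,21.5,4,0",
        "tumor,oxygen,decreases,necrosis,0,5,8,0",
        "tumor,damage,increases,apoptosis,0.05,30,4,0",
        "M0 macrophage,contact with dead cell,increases,transform to M1 macrophage,0.1,0.5,4,0",
        "M1 macrophage,oxygen,decreases,transform to M2 macrophage,0,15,4,0",
        "M1 macrophage,IL-10,increases,transform to M2 macrophage,0.02,0.1,2,0",
        "naive CD8 T cell,IFN-gamma,increases,transform to activated CD8 T cell,0.05,0.05,2,0",
        "naive CD8 T cell,IL-10,decreases,transform to activated CD8 T cell,0,0.5,2,0",
        "activated CD8 T cell,IFN-gamma,increases,cycle entry,0.002,0.1,2,0",
        "activated CD8 T cell,IL-10,increases,transform to exhausted CD8 T cell,0.02,0.1,2,0",
        "activated CD8 T cell,IFN-gamma,increases,attack tumor,0.1,0.1,2,0",
    ]) + "\n"
    tumor = CellType("tumor", phenotype=_tumor_base())
    m0 = _macrophage("M0 macrophage", {}, {"transform to M1 macrophage": 0.0})
    m1 = _macrophage("M1 macrophage", {"IFN-gamma": 1.0},
                     {"transform to M2 macrophage": 0.005})
    m2 = _macrophage("M2 macrophage", {"IL-10": 1.0})

    def t_cell(name, extra=None):
        pheno = {
            "migration speed": 1.0,
            "migration bias": 0.5,
            "migration persistence time": 10.0,
            "oxygen uptake": 1.0,
        }
        pheno.update(extra or {})
        return CellType(name, phenotype=pheno,
                        chemotaxis_substrate="IFN-gamma", chemotaxis_direction=1)

    naive = t_cell("naive CD8 T cell", {"transform to activated CD8 T cell": 0.0})
    activated = t_cell("activated CD8 T cell", {
        "attack tumor": 0.0,  # driven by the IFN-gamma rule
        "damage rate": 0.1,
        "transform to exhausted CD8 T cell": 0.0,
    })
    exhausted = t_cell("exhausted CD8 T cell", {"migration speed": 0.2})
    full_seed = [
        SeedingSpec(mode="disk", counts={"tumor": 2000}, radius=400.0),
        SeedingSpec(mode="ring",
                    counts={"M0 macrophage": 400, "naive CD8 T cell": 400},
                    inner_radius=450.0, outer_radius=600.0),
    ]
    reduced = dict(
        domain=Domain(-500, 500, -500, 500, voxel_size=20.0),
        seedings=[
            SeedingSpec(mode="disk", counts={"tumor": 500}, radius=200.0),
            SeedingSpec(mode="ring",
                        counts={"M0 macrophage": 100, "naive CD8 T cell": 100},
                        inner_radius=225.0, outer_radius=300.0),
        ],
        schedule=Schedule(dt_diffusion=0.05, dt_mechanics=0.1, dt_phenotype=6.0,
                          total_time=1440.0, snapshot_interval=240.0),
        phenotypes={("tumor", "oxygen uptake"): 80.0},
    )
    return Scenario(
        name="immune_extended",
        description="immune activation then macrophage-mediated exhaustion",
        domain=Domain(-1000, 1000, -1000, 1000, voxel_size=20.0),
        substrates=[dict(OXYGEN), _factor("IFN-gamma"), _factor("IL-10")],
        cell_types=[tumor, m0, m1, m2, naive, activated, exhausted],
        rules_csv=rules,
        seedings=full_seed,
        schedule=Schedule(total_time=7200.0, snapshot_interval=360.0),
        reduced_overrides=reduced,
        notes={
            "2,000 tumor in a disc; 400 M0 + 400 naive CD8 in a ring": "stated",
            "IFN-gamma promotes / IL-10 inhibits activation": "stated",
            "IL-10 promotes exhaustion; hypoxia promotes M2": "stated",
            "rates and half-maxes": "unstated; package defaults",
        },
    )


def _tam_egf(variant: str = "go_and_grow") -> Scenario:
    """Macrophage-driven invasion in a breast-cancer spheroid: M2-like
    macrophages secrete EGF; the 'grow' variant couples EGF to tumor cycle
    entry, 'go' to migration speed, 'go_and_grow' to both.  IL-4 polarizes
    macrophages toward M2 and drives their proliferation; IFN-gamma
    repolarizes toward M1; Th2 CD4 T cells are a cellular IL-4 source."""
    egf_rules = {
        "grow": ["tumor,EGF,increases,cycle entry,0.0015,0.25,2,0"],
        "go": ["tumor,EGF,increases,migration speed,1.0,0.25,2,0"],
        "go_and_grow": [
            "tumor,EGF,increases,cycle entry,0.0015,0.25,2,0",
            "tumor,EGF,increases,migration speed,1.0,0.25,2,0",
        ],
    }
    if variant not in egf_rules:
        raise ValueError(f"unknown tam_egf variant {variant!r}; "
                         f"choose from {sorted(egf_rules)}")
    rules = "\n".join([
        "tumor,oxygen,increases,cycle entry,0.00072,21.5,4,0",
        "tumor,oxygen,decreases,necrosis,0,5,8,0",
        *egf_rules[variant],
        "M1 macrophage,IL-4,increases,transform to M2 macrophage,0.01,0.25,2,0",
        "M2 macrophage,IFN-gamma,increases,transform to M1 macrophage,0.01,0.25,2,0",
        "M2 macrophage,IL-4,increases,cycle entry,0.001,0.25,2,0",
    ]) + "\n"
    tumor = CellType("tumor", phenotype=_tumor_base(**{
        "migration persistence time": 15.0,
    }))
    m1 = _macrophage("M1 macrophage", {"IFN-gamma": 0.5},
                     {"transform to M2 macrophage": 0.0})
    m2 = _macrophage("M2 macrophage", {"EGF": 1.0},
                     {"transform to M1 macrophage": 0.0})
    cd4 = CellType("Th2 CD4 T cell", phenotype={
        "IL-4 secretion": 1.0,
        "migration speed": 0.5,
        "migration persistence time": 10.0,
    })
    full_seed = [
        SeedingSpec(mode="disk", counts={"tumor": 200}, radius=150.0),
        SeedingSpec(mode="ring",
                    counts={"M1 macrophage": 10, "M2 macrophage": 10, "Th2 CD4 T cell": 10},
                    inner_radius=175.0, outer_radius=300.0),
    ]
    reduced = dict(
        domain=Domain(-400, 400, -400, 400, voxel_size=20.0),
        seedings=full_seed,  # already desk scale (230 agents)
        schedule=Schedule(dt_diffusion=0.05, dt_mechanics=0.1, dt_phenotype=6.0,
                          total_time=720.0, snapshot_interval=120.0),
    )
    sc = Scenario(
        name="tam_egf",
        description=f"macrophage EGF-driven invasion ({variant} hypothesis)",
        domain=Domain(-600, 600, -600, 600, voxel_size=20.0),
        substrates=[dict(OXYGEN), _factor("EGF"), _factor("IL-4"), _factor("IFN-gamma")],
        cell_types=[tumor, m1, m2, cd4],
        rules_csv=rules,
        seedings=full_seed,
        schedule=Schedule(total_time=7200.0, snapshot_interval=360.0),
        reduced_overrides=reduced,
        notes={
            "200 tumor cells + 10 of each immune type": "stated",
            "grow/go/go-and-grow EGF hypotheses": "stated",
            "rates and half-maxes": "unstated; package defaults",
        },
    )
    return sc


COMBO_T_SUBTYPES = [
    f"{lineage} {pd1} {cd137}"
    for lineage in ("CD8 T cell", "CD4 T cell")
    for pd1 in ("PD-1hi", "PD-1lo")
    for cd137 in ("CD137lo", "CD137hi")
]
COMBO_TUMOR_TYPES = ["tumor PD-L1hi", "tumor PD-L1lo"]


def _combo_therapy(cohort_counts: dict[str, int] | None = None,
                   pdl1_hi_fraction: float = 0.25) -> Scenario:
    """Virtual-trial model: T-cell subtypes stratified by PD-1 and CD137
    status attack PD-L1 hi/lo tumor cells.  CD137hi effectors kill faster
    and independently of PD-L1; PD-1hi effectors cannot kill PD-L1hi tumor
    cells.  CD137hi agents secrete inflammatory factor; CD4 cells secrete
    the chemokine attracting CD8 cells."""
    kill_lo, kill_hi = 0.005, 0.02  # CD137lo vs CD137hi attack rates, 1/min
    types: list[CellType] = []
    rules_rows: list[str] = []
    for tt in COMBO_TUMOR_TYPES:
        types.append(CellType(tt, phenotype=_tumor_base(**{"cycle entry": 0.0003})))
        rules_rows.append(f"{tt},damage,increases,apoptosis,0.05,30,4,0")
        rules_rows.append(f"{tt},oxygen,decreases,necrosis,0,5,8,0")
    for name in COMBO_T_SUBTYPES:
        is_cd8 = name.startswith("CD8")
        cd137hi = "CD137hi" in name
        pd1hi = "PD-1hi" in name
        rate = kill_hi if cd137hi else kill_lo
        pheno = {
            "migration speed": 1.0,
            "migration bias": 0.5,
            "migration persistence time": 10.0,
            "oxygen uptake": 1.0,
        }
        if is_cd8:
            pheno["damage rate"] = 0.1
            pheno["attack tumor PD-L1lo"] = rate
            # PD-1hi effectors are checkpoint-blocked on PD-L1hi tumor unless CD137hi
            pheno["attack tumor PD-L1hi"] = rate if (cd137hi or not pd1hi) else 0.0
        else:
            pheno["pro-inflammatory factor secretion"] = 0.5
        if cd137hi:
            pheno["pro-inflammatory factor secretion"] = 1.0
        types.append(CellType(
            name, phenotype=pheno,
            chemotaxis_substrate="pro-inflammatory factor" if is_cd8 else None,
        ))
    types.append(_macrophage("macrophage", {"anti-inflammatory factor": 0.5}))
    rules = "\n".join(rules_rows) + "\n"
    if cohort_counts is None:
        cohort_counts = {  # a representative synthetic tissue composition
            "CD8 T cell PD-1hi CD137lo": 60,
            "CD8 T cell PD-1lo CD137lo": 40,
            "CD8 T cell PD-1hi CD137hi": 10,
            "CD8 T cell PD-1lo CD137hi": 10,
            "CD4 T cell PD-1hi CD137lo": 80,
            "CD4 T cell PD-1lo CD137lo": 60,
            "CD4 T cell PD-1hi CD137hi": 10,
            "CD4 T cell PD-1lo CD137hi": 10,
            "macrophage": 120,
        }
    from .initialization import composition_from_counts

    spec = composition_from_counts(cohort_counts, tumor_total=1000,
                                   pdl1_hi_fraction=pdl1_hi_fraction,
                                   tumor_hi_type="tumor PD-L1hi",
                                   tumor_lo_type="tumor PD-L1lo")
    spec.radius = 400.0
    reduced_counts = {k: max(1, v // 4) if v else 0 for k, v in spec.counts.items()}
    reduced = dict(
        domain=Domain(-500, 500, -500, 500, voxel_size=20.0),
        seedings=[SeedingSpec(mode="disk", counts=reduced_counts, radius=200.0)],
        schedule=Schedule(dt_diffusion=0.05, dt_mechanics=0.1, dt_phenotype=6.0,
                          total_time=720.0, snapshot_interval=120.0),
    )
    return Scenario(
        name="combo_therapy",
        description="virtual clinical trial of GVAX/nivolumab/urelumab combinations",
        domain=Domain(-1000, 1000, -1000, 1000, voxel_size=20.0),
        substrates=[dict(OXYGEN), _factor("pro-inflammatory factor"),
                    _factor("anti-inflammatory factor")],
        cell_types=types,
        rules_csv=rules,
        seedings=[spec],
        schedule=Schedule(total_time=10080.0, snapshot_interval=720.0),
        reduced_overrides=reduced,
        notes={
            "1,000 tumor agents, PD-L1 hi/lo split from cohort data": "stated",
            "CD137hi kill faster, PD-L1-independent": "stated ordering, magnitudes unstated",
        },
    )


CORTICAL_LAYERS = ["layer 6 neuron", "layer 5 neuron", "layer 4 neuron",
                   "layer 2/3 neuron"]


def _cortex(fate_switch_times: tuple[float, ...] = (150.0, 300.0, 450.0),
            stem_cycle_rate: float = 0.02) -> Scenario:
    """Cortical layer formation by asymmetric stem-cell division: each
    division keeps one stem daughter while the other adopts the layer fate
    scheduled for the current simulation time (deep layers first); fated
    neurons migrate toward the pial surface and stop on contact with it,
    and stem cycling slows as time elapses."""
    t1, t2, t3 = fate_switch_times
    fate = [(0.0, t1, "layer 6 neuron"), (t1, t2, "layer 5 neuron"),
            (t2, t3, "layer 4 neuron"), (t3, float("inf"), "layer 2/3 neuron")]
    # stem cycling slows as simulated developmental time elapses
    rules_rows = ["stem cell,time,decreases,cycle entry,0,450,8,0"]
    # migrating neurons slow to a stop on contact with the pial surface;
    # cohorts rise in birth order and stack beneath it by crowding
    for layer in CORTICAL_LAYERS:
        rules_rows.append(
            f"{layer},contact with pial cell,decreases,migration speed,0,0.5,8,0"
        )
    rules = "\n".join(rules_rows) + "\n"
    stem = CellType("stem cell", phenotype={"cycle entry": stem_cycle_rate},
                    fate_table=fate, radius=6.0)

    def neuron(name):
        # fated neurons migrate straight up the pial cue and stop on contact
        # with the pial surface; cohorts stack beneath it in arrival order
        return CellType(name, phenotype={
            "migration speed": 2.0,
            "migration bias": 1.0,
            "migration persistence time": 2.0,
            "cell-cell adhesion strength": 0.1,
        }, chemotaxis_substrate="pial cue", chemotaxis_direction=1, radius=6.0)

    pial = CellType("pial cell", inert=True, radius=6.0,
                    phenotype={"cell-cell repulsion strength": 30.0})
    domain = Domain(-100, 100, 0, 400, voxel_size=20.0)

    def ramp(dom: Domain) -> np.ndarray:
        _, ys = dom.voxel_centers()
        return np.tile(((ys - dom.y_min) / (dom.y_max - dom.y_min))[:, None],
                       (1, dom.nx))

    seedings = [
        SeedingSpec(mode="box", counts={"stem cell": 30},
                    center=(0.0, 10.0), radius=(95.0, 8.0)),
        SeedingSpec(mode="box", counts={"pial cell": 30},
                    center=(0.0, 394.0), radius=(95.0, 4.0)),
    ]
    schedule = Schedule(dt_diffusion=0.5, dt_mechanics=0.5, dt_phenotype=6.0,
                        total_time=840.0, snapshot_interval=210.0)
    return Scenario(
        name="cortex",
        description="laminar cortical development via asymmetric division",
        domain=domain,
        substrates=[dict(name="pial cue", diffusion_coefficient=0.0, decay_rate=0.0,
                         initial_value=0.0, boundary=Boundary.NO_FLUX,
                         saturation_density=1.0)],
        cell_types=[stem, *(neuron(n) for n in CORTICAL_LAYERS), pial],
        rules_csv=rules,
        seedings=seedings,
        schedule=schedule,
        reduced_overrides={},  # already desk scale
        initial_fields={"pial cue": ramp},
        notes={
            "asymmetric division, one stem daughter": "stated",
            "fate sequence controlled by simulation time": "stated",
            "cycling slows as time elapses": "stated",
            "switch times and rates": "unstated; calibrated to layer data",
        },
    )


_BUILDERS = {
    "hypoxia": _hypoxia,
    "pdac_caf": _pdac_caf,
    "immune_base": _immune_base,
    "immune_extended": _immune_extended,
    "tam_egf": _tam_egf,
    "combo_therapy": _combo_therapy,
    "cortex": _cortex,
}


def available_scenarios() -> list[str]:
    return sorted(_BUILDERS)


def build_scenario(name: str, **kwargs) -> Scenario:
    """Construct one of the bundled scenario models by name."""
    if name not in _BUILDERS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(available_scenarios())}"
        )
    return _BUILDERS[name](**kwargs)


# ---------------------------------------------------------------------------
# synthetic fixture generators
# ---------------------------------------------------------------------------


@dataclass
class FixtureGenerator:
    """Deterministic synthetic stand-ins for the omics-derived inputs."""

    kind: str  # spot_table | cohort_counts | motility_dataset | layer_reference
    seed: int = 0
    params: dict = field(default_factory=dict)


def generate_fixture(gen: FixtureGenerator):
    fn = {
        "spot_table": _gen_spot_table,
        "cohort_counts": _gen_cohort_counts,
        "motility_dataset": _gen_motility_dataset,
        "layer_reference": _gen_layer_reference,
    }.get(gen.kind)
    if fn is None:
        raise ValueError(f"unknown fixture kind {gen.kind!r}")
    return fn(np.random.default_rng(gen.seed), **gen.params)


def _gen_spot_table(rng, n_spots: int = 500, pitch: float = 100.0) -> pd.DataFrame:
    """Synthetic annotated spot table on a hexagonal lattice: a central
    tumor blob (epithelial core, mesenchymal fringe), a fibroblast collar
    with dense ECM, and inert scaffold tissue outside."""
    cols = int(math.ceil(math.sqrt(n_spots)))
    pts = []
    k = 0
    row = 0
    while k < n_spots:
        for c in range(cols):
            if k >= n_spots:
                break
            x = c * pitch + (pitch / 2.0 if row % 2 else 0.0)
            y = row * pitch * math.sqrt(3.0) / 2.0
            pts.append((x, y))
            k += 1
        row += 1
    pts = np.array(pts)
    center = pts.mean(axis=0)
    d = np.linalg.norm(pts - center, axis=1)
    r_tumor = np.percentile(d, 30)
    r_fringe = np.percentile(d, 45)
    r_fibro = np.percentile(d, 65)
    labels = np.where(d < r_tumor, "epithelial tumor",
                      np.where(d < r_fringe, "mesenchymal tumor",
                               np.where(d < r_fibro, "fibroblast", "inert")))
    # a little annotation noise inside the tumor blob
    flip = (d < r_tumor) & (rng.random(len(d)) < 0.1)
    labels = labels.copy()
    labels[flip] = "mesenchymal tumor"
    ecm = np.where(labels == "fibroblast", 0.8, np.where(labels == "inert", 0.5, 0.1))
    ecm = np.clip(ecm + rng.normal(0.0, 0.05, len(d)), 0.0, 1.0)
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1],
                         "cell_type": labels, "ecm_density": ecm})


def _gen_cohort_counts(rng, n_patients: int = 12, library_size: int = 400,
                       concentration: float = 2.0) -> pd.DataFrame:
    """Per-patient immune composition over the trial taxonomy, drawn from a
    Dirichlet-multinomial; rows sum exactly to the library size.  A PD-L1hi
    tumor fraction column accompanies the immune counts."""
    taxonomy = COMBO_T_SUBTYPES + ["macrophage"]
    alpha = np.full(len(taxonomy), concentration)
    rows = []
    for p in range(n_patients):
        probs = rng.dirichlet(alpha)
        counts = rng.multinomial(library_size, probs)
        rows.append({"patient": f"P{p + 1:02d}",
                     **dict(zip(taxonomy, counts.tolist())),
                     "pdl1_hi_fraction": float(rng.beta(2.0, 5.0))})
    return pd.DataFrame(rows)


def _gen_motility_dataset(rng, n_points: int = 40, noise: float = 0.0,
                          b_max: float = 0.8, up_half_max: float = 0.3,
                          up_power: float = 2.0, down_half_max: float = 1.2,
                          down_power: float = 4.0,
                          density_range: tuple[float, float] = (0.05, 4.0)) -> pd.DataFrame:
    """(ECM density, mean speed) pairs from a known biphasic combined-Hill
    curve, optionally with multiplicative lognormal noise."""
    density = np.geomspace(density_range[0], density_range[1], n_points)
    speed = biphasic_hill(density, b_max, up_half_max, up_power,
                          down_half_max, down_power)
    if noise > 0:
        speed = speed * np.exp(rng.normal(0.0, noise, n_points))
    return pd.DataFrame({"density": density, "speed": speed})


def _gen_layer_reference(rng, thicknesses: dict[str, float] | None = None,
                         jitter: float = 0.0) -> dict[str, float]:
    """Reference per-layer thicknesses (um) with the deep-to-superficial
    ordering of a mouse cortical column."""
    base = thicknesses or {"layer 6 neuron": 90.0, "layer 5 neuron": 70.0,
                           "layer 4 neuron": 50.0, "layer 2/3 neuron": 60.0}
    if jitter > 0:
        base = {k: float(v * math.exp(rng.normal(0.0, jitter))) for k, v in base.items()}
    return dict(base)
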