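"""Parameter sensitivity sweeps and the two calibration procedures.

Sensitivity uses multiplicative perturbations: a parameter value theta is
replaced by theta*(1 +/- level) for levels such as 1%, 5%, 10%, 20%, with
perturbed and reference runs sharing the replicate's RNG seed so the index
reflects the parameter and not sampling noise.  The sensitivity index is a
normalized central-difference elasticity

    index(theta, level) = |QoI(theta*(1+level)) - QoI(theta*(1-level))|
                          / (2 * level * |QoI_ref|)

averaged over replicates; per parameter the mean and standard deviation of
the index across QoIs summarize its influence.

Rule parameters are addressed as ``rule<N>_<field>`` with N the 1-based rule
insertion order and field one of ``base`` (the phenotype base value b0),
``sat`` (saturation), ``hfm`` (half-max), ``hp`` (Hill power).

Calibration: (a) a biphasic combined-Hill fit of migration speed versus ECM
density, with density feeding one increasing and one decreasing term; (b) a
grid search minimizing the layer-thickness residual sum of squares of a
layered-growth simulation against reference thicknesses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .metrics import layer_rss
from .responses import hill

__all__ = [
    "SweepSpec",
    "SensitivityResult",
    "run_sweep",
    "fit_biphasic_hill",
    "biphasic_hill",
    "calibrate_layers",
]

PARAM_FIELDS = ("base", "sat", "hfm", "hp")


@dataclass
class SweepSpec:
    """What to perturb, by how much, and how often."""

    parameters: list[str]
    levels: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20)
    replicates: int = 3
    qois: tuple[str, ...] = ()
    base_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for lv in self.levels:
            if not (0.0 <= lv < 1.0):
                raise ValueError("perturbation levels must lie in [0, 1)")


@dataclass
class SensitivityResult:
    """Tidy sweep records plus per-parameter index summaries."""

    records: list[dict] = field(default_factory=list)
    #: parameter -> (mean index across QoIs, SD across QoIs)
    summary: dict[str, tuple[float, float]] = field(default_factory=dict)

    def index(self, parameter: str) -> float:
        return self.summary[parameter][0]

    def to_csv(self) -> str:
        lines = ["parameter,level,replicate,qoi,value_plus,value_minus,value_ref,index"]
        for r in self.records:
            lines.append(
                f"{r['parameter']},{r['level']},{r['replicate']},{r['qoi']},"
                f"{r['value_plus']:.8g},{r['value_minus']:.8g},"
                f"{r['value_ref']:.8g},{r['index']:.8g}"
            )
        return "\n".join(lines) + "\n"


def run_sweep(runner, spec: SweepSpec) -> SensitivityResult:
    """Run a multiplicative-perturbation sweep.

    ``runner(factors, seed)`` must run the model with each addressed
    parameter multiplied by its factor and return a map QoI name -> value.
    ``runner`` may be a scenario object exposing ``qoi_runner()``.
    """
    if hasattr(runner, "qoi_runner"):
        runner = runner.qoi_runner()
    result = SensitivityResult()
    seeds = [spec.base_seed + 1000 * k for k in range(spec.replicates)]
    ref_cache = {s: runner({}, s) for s in seeds}
    qois = list(spec.qois) or sorted(ref_cache[seeds[0]])
    per_param_qoi: dict[str, dict[str, list[float]]] = {}
    for param in spec.parameters:
        per_param_qoi[param] = {q: [] for q in qois}
        for level in spec.levels:
            for rep, seed in enumerate(seeds):
                if level == 0.0:
                    plus = minus = ref_cache[seed]
                else:
                    plus = runner({param: 1.0 + level}, seed)
                    minus = runner({param: 1.0 - level}, seed)
                ref = ref_cache[seed]
                for q in qois:
                    denom = 2.0 * level * abs(ref[q])
                    idx = abs(plus[q] - minus[q]) / denom if denom > 0 else 0.0
                    per_param_qoi[param][q].append(idx)
                    result.records.append(dict(
                        parameter=param, level=level, replicate=rep, qoi=q,
                        value_plus=plus[q], value_minus=minus[q],
                        value_ref=ref[q], index=idx,
                    ))
        means = [float(np.mean(v)) for v in per_param_qoi[param].values()]
        result.summary[param] = (float(np.mean(means)), float(np.std(means)))
    return result


# -- biphasic Hill calibration -------------------------------------------------


def biphasic_hill(x, b_max, up_half_max, up_power, down_half_max, down_power):
    """Combined response with the same signal feeding one up and one down
    term (base and minimum values 0):

        b(x) = (1 - D(x)) * U(x) * b_max

    Biphasic (rises then falls) when the down half-max exceeds the up one.
    """
    U = hill(x, up_half_max, up_power)
    D = hill(x, down_half_max, down_power)
    return (1.0 - D) * U * b_max


def fit_biphasic_hill(density, speed, n_starts: int = 12, seed: int = 0) -> dict:
    """Bounded nonlinear least squares of the biphasic combined-Hill model.

    Uses multi-start (Latin-hypercube initials, half-maxes sampled in log
    space) to avoid the model's local minima.  Returns the fitted parameters
    and the residual sum of squares.
    """
    x = np.asarray(density, dtype=float)
    y = np.asarray(speed, dtype=float)
    if len(x) < 6:
        raise ValueError("need at least 6 (density, speed) points")
    xpos = x[x > 0]
    x_lo, x_hi = float(xpos.min()), float(x.max())
    lb = np.array([1e-6 * max(y.max(), 1e-12), x_lo / 10.0, 0.25, x_lo / 10.0, 0.25])
    ub = np.array([10.0 * max(y.max(), 1e-12), x_hi * 10.0, 10.0, x_hi * 10.0, 10.0])

    def residuals(p):
        return biphasic_hill(x, *p) - y

    sampler = qmc.LatinHypercube(d=5, seed=seed)
    unit = sampler.random(n_starts)
    log_lb, log_ub = np.log(lb), np.log(ub)
    starts = np.exp(log_lb + unit * (log_ub - log_lb))
    best = None
    for p0 in starts:
        try:
            sol = least_squares(residuals, p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("biphasic Hill fit failed from every start")
    rss, p = best
    return {
        "base_value": 0.0,
        "max_value": float(p[0]),
        "up_half_max": float(p[1]),
        "up_power": float(p[2]),
        "down_half_max": float(p[3]),
        "down_power": float(p[4]),
        "rss": rss,
    }


# -- layer calibration ---------------------------------------------------------


def calibrate_layers(runner, reference: dict[str, float], search_space: dict[str, list],
                     replicates: int = 3, base_seed: int = 0):
    """Grid search minimizing mean layer-thickness RSS against a reference.

    ``runner(params, seed)`` must run the layered-growth model and return a
    map layer -> thickness (um).  Every grid point is evaluated with the
    same ``replicates`` seeds; returns (best_params, best_rss, table) where
    the table lists every evaluated point.
    """
    names = list(search_space)
    grids = [list(search_space[n]) for n in names]
    if not names or any(len(g) == 0 for g in grids):
        raise ValueError("search space must be non-empty")
    table = []
    best = None
    for combo in itertools.product(*grids):
        params = dict(zip(names, combo))
        rss_values = []
        for rep in range(replicates):
            thick = runner(params, base_seed + 1000 * rep)
            rss_values.append(layer_rss(thick, reference))
        mean_rss = float(np.mean(rss_values))
        table.append({**params, "rss": mean_rss})
        if best is None or mean_rss < best[1]:
            best = (params, mean_rss)
    return best[0], best[1], table
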