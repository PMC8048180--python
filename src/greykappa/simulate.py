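"""Paired Monte Carlo accuracy study.

For every scenario — a (table structure, sample size, category count,
agreement level, measure, weight) combination — two streams of tables are
sampled: simulation I from the latent-model joint probabilities ``p`` and
simulation II from the grey-zone table ``p_hat`` produced by the CP search
at matched true agreement.  Estimator accuracy is summarised against the
population coefficient ``kappa`` of ``p`` by

    MAE  = (1/r) sum |kappa - kappa_hat_i|
    MSE  = (1/r) sum (kappa - kappa_hat_i)^2
    MAPE = (100/r) sum |kappa - kappa_hat_i| / |kappa|

over r replications; the paired difference MAE_II - MAE_I quantifies the
damage a grey zone does to each coefficient.  The full factorial design
crosses 3 structures x 5 sample sizes x 4 table sizes x 3 agreement levels
x 5 measures x 5 weights (4500 measure-weight-scenario combinations).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import UndefinedCoefficientError, UndefinedMAPEError
from .greyzone import SearchResult, cp_search
from .measures import MEASURES, ProbabilityTable, coefficient
from .tablegen import joint_probabilities, make_cutoffs, true_coefficient
from .weights import SCHEMES

#: Agreement levels and the latent correlations they denote.
LEVEL_RHO = {"L": 0.1, "M": 0.6, "H": 0.9}

#: Factor levels of the full study design.
FULL_GRID = {
    "structure": ("BL", "UB1", "UB2"),
    "n": (50, 100, 200, 500, 1000),
    "q": (3, 4, 5, 6),
    "level": ("L", "M", "H"),
    "measure": MEASURES,
    "scheme": SCHEMES,
}

def mae(true_value: float, estimates) -> float:
    """Mean absolute error of the estimates against the true coefficient."""
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be non-empty")
    return float(np.abs(true_value - est).mean())


def mse_mape(true_value: float, estimates) -> tuple[float, float]:
    """Mean squared error and mean absolute percentage error (in percent)."""
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be non-empty")
    mse = float(((true_value - est) ** 2).mean())
    if true_value == 0.0:
        raise UndefinedMAPEError("MAPE undefined for a true coefficient of 0")
    mape = float(100.0 * (np.abs(true_value - est) / abs(true_value)).mean())
    return mse, mape


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation design."""

    structure: str  # BL, UB1, UB2
    n: int
    q: int
    level: str  # L, M, H
    measure: str
    scheme: str
    replications: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in FULL_GRID["structure"]:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.level not in LEVEL_RHO:
            raise ValueError(f"unknown agreement level {self.level!r}")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def rho(self) -> float:
        return LEVEL_RHO[self.level]


@dataclass(frozen=True)
class AccuracyResult:
    """Paired error summaries of one scenario (I: no grey zone, II: grey zone)."""

    scenario: Scenario
    true_kappa: float
    mae1: float
    mae2: float
    mse1: float
    mse2: float
    mape1: float | None
    mape2: float | None
    dropped1: int
    dropped2: int
    r_effective1: int
    r_effective2: int
    search_achieved: float
    search_converged: bool


def scenario_tables(
    structure: str, q: int, level: str, epsilon: float = 0.01
) -> tuple[ProbabilityTable, SearchResult]:
    """The paired (p, grey-zone search result) for a design triple."""
    cuts = make_cutoffs(structure, q)
    p = joint_probabilities(LEVEL_RHO[level], cuts, cuts)
    search = cp_search(p, epsilon=epsilon)
    return p, search


def _estimate_streams(
    p: ProbabilityTable,
    p_hat: ProbabilityTable,
    scenario: Scenario,
) -> tuple[list[float], list[float], int, int]:
    """Estimate streams of simulations I and II over r replicates each.

    The two streams are sampled independently (each from its own generator
    spawned off the scenario seed), mirroring how the paired study draws its
    tables.  Degenerate replicates (an undefined coefficient) are dropped
    and counted.
    """
    child1, child2 = np.random.SeedSequence(scenario.seed).spawn(2)
    streams = []
    drops = []
    for p_use, child in ((p, child1), (p_hat, child2)):
        rng = np.random.default_rng(child)
        est: list[float] = []
        dropped = 0
        flat = p_use.p.ravel()
        for _ in range(scenario.replications):
            counts = rng.multinomial(scenario.n, flat).reshape(p_use.q, p_use.q)
            try:
                cv = coefficient(ProbabilityTable(counts / scenario.n),
                                 scenario.measure, scenario.scheme, n=scenario.n)
            except UndefinedCoefficientError:
                dropped += 1
                continue
            est.append(cv.value)
        streams.append(est)
        drops.append(dropped)
    return streams[0], streams[1], drops[0], drops[1]


def run_scenario(
    scenario: Scenario,
    tables: tuple[ProbabilityTable, SearchResult] | None = None,
    epsilon: float = 0.01,
) -> AccuracyResult:
    """Run both paired simulations for one scenario.

    ``tables`` allows the (p, p_hat) pair to be shared across the 25
    measure/weight scenarios of a (structure, q, level) triple, as the grey-
    zone search is common to all of them.
    """
    if tables is None:
        tables = scenario_tables(scenario.structure, scenario.q, scenario.level, epsilon)
    p, search = tables
    kappa = true_coefficient(p, scenario.measure, scenario.scheme).value
    est1, est2, dropped1, dropped2 = _estimate_streams(p, search.p_hat, scenario)
    mae1 = mae(kappa, est1)
    mae2 = mae(kappa, est2)
    try:
        mse1, mape1 = mse_mape(kappa, est1)
        mse2, mape2 = mse_mape(kappa, est2)
    except UndefinedMAPEError:
        mse1 = float(((kappa - np.asarray(est1)) ** 2).mean())
        mse2 = float(((kappa - np.asarray(est2)) ** 2).mean())
        mape1 = mape2 = None
    return AccuracyResult(
        scenario=scenario, true_kappa=kappa,
        mae1=mae1, mae2=mae2, mse1=mse1, mse2=mse2, mape1=mape1, mape2=mape2,
        dropped1=dropped1, dropped2=dropped2,
        r_effective1=len(est1), r_effective2=len(est2),
        search_achieved=search.achieved, search_converged=search.converged,
    )


def expand_grid(config: dict | None = None, replications: int = 1000) -> list[Scenario]:
    """Enumerate scenarios for a (sub)grid of the study design.

    ``config`` maps any of the factor names in :data:`FULL_GRID` to a list of
    levels; missing factors default to the full set.  Ordering is the
    deterministic nested-loop order of :data:`FULL_GRID`.
    """
    cfg = dict(FULL_GRID)
    if config:
        for key, levels in config.items():
            if key not in FULL_GRID:
                raise ValueError(f"unknown design factor {key!r}")
            levels = tuple(levels)
            bad = set(levels) - set(FULL_GRID[key])
            if bad:
                raise ValueError(f"invalid levels for {key!r}: {sorted(bad)}")
            cfg[key] = levels
    out = []
    for structure in cfg["structure"]:
        for n in cfg["n"]:
            for q in cfg["q"]:
                for level in cfg["level"]:
                    for measure in cfg["measure"]:
                        for scheme in cfg["scheme"]:
                            out.append(Scenario(
                                structure=structure, n=n, q=q, level=level,
                                measure=measure, scheme=scheme,
                                replications=replications,
                            ))
    return out


def run_grid(
    config: dict | None = None,
    seed: int = 0,
    replications: int = 1000,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Run a (sub)grid and return the long-format results table.

    Per-scenario seeds are spawned deterministically from ``seed``; the
    (p, p_hat) pair is computed once per (structure, q, level) triple.  One
    output row per (scenario, grey-status) with columns structure, n, q,
    level, rho, measure, scheme, grey, true_kappa, mae, mse, mape,
    r_effective, dropped, seed — the data behind the study's comparisons.
    """
    scenarios = expand_grid(config, replications)
    seeds = np.random.SeedSequence(seed).generate_state(len(scenarios)) % (2**31)
    cache: dict[tuple, tuple] = {}
    rows = []
    for scn, s in zip(scenarios, seeds):
        scn = Scenario(**{**asdict(scn), "seed": int(s)})
        triple = (scn.structure, scn.q, scn.level)
        if triple not in cache:
            cache[triple] = scenario_tables(*triple, epsilon)
        res = run_scenario(scn, tables=cache[triple], epsilon=epsilon)
        base = {
            "structure": scn.structure, "n": scn.n, "q": scn.q,
            "level": scn.level, "rho": scn.rho,
            "measure": scn.measure, "scheme": scn.scheme,
            "true_kappa": res.true_kappa, "seed": scn.seed,
        }
        rows.append({**base, "grey": False, "mae": res.mae1, "mse": res.mse1,
                     "mape": res.mape1, "r_effective": res.r_effective1,
                     "dropped": res.dropped1})
        rows.append({**base, "grey": True, "mae": res.mae2, "mse": res.mse2,
                     "mape": res.mape2, "r_effective": res.r_effective2,
                     "dropped": res.dropped2})
    return pd.DataFrame(rows)
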