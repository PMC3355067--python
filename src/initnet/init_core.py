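"""Evidence-maximizing subnetwork extraction as a mixed-integer program.

Given a flux-consistent template, per-reaction evidence weights w and an
optional set of metabolites known to be present in the tissue, pick binary
inclusions y maximizing

    sum_i w_i * y_i  +  delta * sum_j x_j

subject to a relaxed steady state S v = b with b >= 0 on internal
metabolites (net accumulation permitted), flux coupling

    y_i = 1  =>  |v_i| >= eps_flux      (one direction binary per
    y_i = 0  =>   v_i  = 0               reversible reaction rules out
                                          forward/backward cancellation)

and production indicators x_j = 1 => b_j >= eps_production.  Metabolites
with presence evidence have x_j fixed to 1, forcing the network to achieve
a positive net production of them.  Exchange reactions carry no binary and
no weight: they are always permitted.

The big-M constants, epsilons and the production reward delta live in
:class:`INITConfig`; an exhaustive subset-enumeration oracle
(:func:`brute_force_oracle`) certifies the encoding on small instances.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from ._lp import solve_lp
from .evidence import WeightVector
from .model_core import MetabolicModel, stoichiometric_matrix

__all__ = [
    "INITConfig",
    "INITProblem",
    "INITSolution",
    "build_problem",
    "solve",
    "extract_network",
    "brute_force_oracle",
    "weight_sensitivity",
]

_FEAS_TOL = 1e-6


@dataclass
class INITConfig:
    epsilon_flux: float = 1.0
    epsilon_production: float = 1.0
    big_M: float = 1000.0
    production_reward: float = 0.1
    solver_gap_tolerance: float = 1e-6
    random_seed: int = 0

    def __post_init__(self):
        if not (0 < self.epsilon_flux < self.big_M):
            raise ValueError("require 0 < epsilon_flux < big_M")
        if self.epsilon_production <= 0 or self.production_reward <= 0:
            raise ValueError("epsilon_production and production_reward must be > 0")


@dataclass
class INITProblem:
    template: MetabolicModel
    weights: Dict[str, float]
    present_metabolites: FrozenSet[str]
    config: INITConfig
    # variable index maps (into one flat vector)
    rxn_ids: List[str] = field(default_factory=list)
    internal_met_ids: List[str] = field(default_factory=list)
    v_index: Dict[str, int] = field(default_factory=dict)
    b_index: Dict[str, int] = field(default_factory=dict)
    y_index: Dict[str, int] = field(default_factory=dict)
    d_index: Dict[str, int] = field(default_factory=dict)
    x_index: Dict[str, int] = field(default_factory=dict)
    n_vars: int = 0


@dataclass
class INITSolution:
    y: Dict[str, int]
    v: Dict[str, float]
    b: Dict[str, float]
    x: Dict[str, int]
    objective: float
    solver_status: str  # optimal | infeasible | error
    wall_time: float = 0.0

    @property
    def included_reactions(self) -> Set[str]:
        return {r for r, yi in self.y.items() if yi == 1}

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "solver_status": self.solver_status,
            "wall_time": self.wall_time,
            "y": self.y,
            "v": self.v,
            "b": self.b,
            "x": self.x,
        }


def build_problem(
    template: MetabolicModel,
    weights: "WeightVector | Dict[str, float]",
    present_metabolites: Iterable[str] = (),
    config: Optional[INITConfig] = None,
) -> INITProblem:
    """Index variables and validate inputs; constraint assembly happens at solve."""
    config = config or INITConfig()
    wmap = weights.weights if isinstance(weights, WeightVector) else dict(weights)
    missing = [r.id for r in template.non_exchange_reactions if r.id not in wmap]
    if missing:
        raise ValueError(f"weights missing for reactions: {missing}")
    internal = [m.id for m in template.internal_metabolites]
    present = frozenset(present_metabolites)
    unknown = present - set(internal)
    if unknown:
        raise ValueError(f"present metabolites not internal to template: {sorted(unknown)}")

    problem = INITProblem(
        template=template,
        weights={r.id: float(wmap[r.id]) for r in template.non_exchange_reactions},
        present_metabolites=present,
        config=config,
    )
    idx = 0
    for r in template.reactions:
        problem.v_index[r.id] = idx
        idx += 1
    for m in internal:
        problem.b_index[m] = idx
        idx += 1
    for r in template.non_exchange_reactions:
        problem.y_index[r.id] = idx
        idx += 1
    for r in template.non_exchange_reactions:
        if r.reversible:
            problem.d_index[r.id] = idx
            idx += 1
    for m in internal:
        problem.x_index[m] = idx
        idx += 1
    problem.n_vars = idx
    problem.rxn_ids = [r.id for r in template.reactions]
    problem.internal_met_ids = internal
    return problem


def _assemble(problem: INITProblem):
    """Build (c, constraints, bounds, integrality) for scipy.optimize.milp."""
    cfg = problem.config
    template = problem.template
    M, eps, eps_b, delta = (
        cfg.big_M,
        cfg.epsilon_flux,
        cfg.epsilon_production,
        cfg.production_reward,
    )
    n = problem.n_vars
    lb = np.full(n, -np.inf)
    ub = np.full(n, np.inf)
    integrality = np.zeros(n)
    c = np.zeros(n)

    for r in template.reactions:
        i = problem.v_index[r.id]
        lb[i] = -M if r.reversible else 0.0
        ub[i] = M
    for m in problem.internal_met_ids:
        j = problem.b_index[m]
        lb[j], ub[j] = 0.0, M
    for rid, k in problem.y_index.items():
        lb[k], ub[k] = 0, 1
        integrality[k] = 1
        c[k] = problem.weights[rid]
    for rid, k in problem.d_index.items():
        lb[k], ub[k] = 0, 1
        integrality[k] = 1
    for m, k in problem.x_index.items():
        lb[k], ub[k] = 0, 1
        integrality[k] = 1
        c[k] = delta
        if m in problem.present_metabolites:
            lb[k] = 1

    rows, cols, vals, cl, cu = [], [], [], [], []
    row = 0

    def add(entries, lo, hi):
        nonlocal row
        for col, val in entries:
            rows.append(row)
            cols.append(col)
            vals.append(val)
        cl.append(lo)
        cu.append(hi)
        row += 1

    # mass balance: S v - b = 0 per internal metabolite
    S, met_ids, rxn_ids = stoichiometric_matrix(template, internal_only=True)
    S = S.tocoo()
    balance_entries: Dict[str, list] = {m: [] for m in met_ids}
    for j, i, val in zip(S.row, S.col, S.data):
        balance_entries[met_ids[j]].append((problem.v_index[rxn_ids[i]], float(val)))
    for m in met_ids:
        entries = balance_entries[m] + [(problem.b_index[m], -1.0)]
        add(entries, 0.0, 0.0)

    for r in template.non_exchange_reactions:
        i, k = problem.v_index[r.id], problem.y_index[r.id]
        # |v| <= M y
        add([(i, 1.0), (k, -M)], -np.inf, 0.0)
        if r.reversible:
            add([(i, -1.0), (k, -M)], -np.inf, 0.0)
            d = problem.d_index[r.id]
            # y=1, d=1 => v >= eps ; y=1, d=0 => v <= -eps ; y=0 => slack
            add([(i, 1.0), (d, -M), (k, -M)], eps - 2 * M, np.inf)
            add([(i, 1.0), (d, -M), (k, M)], -np.inf, M - eps)
        else:
            # v >= eps y
            add([(i, 1.0), (k, -eps)], 0.0, np.inf)

    for m in problem.internal_met_ids:
        # b_j >= eps_b x_j
        add([(problem.b_index[m], 1.0), (problem.x_index[m], -eps_b)], 0.0, np.inf)

    A = sparse.csc_matrix((vals, (rows, cols)), shape=(row, n))
    constraints = LinearConstraint(A, np.asarray(cl), np.asarray(cu))
    return c, constraints, Bounds(lb, ub), integrality


def _check_solution(problem: INITProblem, sol: INITSolution) -> None:
    """Hard feasibility certificate; raises AssertionError on violation."""
    cfg = problem.config
    S, met_ids, rxn_ids = stoichiometric_matrix(problem.template, internal_only=True)
    v = np.array([sol.v[r] for r in rxn_ids])
    b = S @ v
    for j, m in enumerate(met_ids):
        assert abs(b[j] - sol.b[m]) < _FEAS_TOL * max(1.0, abs(b[j])), (
            f"S·v disagrees with b for {m}"
        )
        assert sol.b[m] >= -_FEAS_TOL, f"negative accumulation for {m}"
    for rid, yi in sol.y.items():
        if yi == 1:
            assert abs(sol.v[rid]) >= cfg.epsilon_flux - 1e-5, (
                f"included reaction {rid} carries |v|={abs(sol.v[rid])} < eps"
            )
        else:
            assert abs(sol.v[rid]) <= 1e-5, f"excluded reaction {rid} carries flux"
    for m in problem.present_metabolites:
        assert sol.x[m] == 1, f"present metabolite {m} has x=0"
        assert sol.b[m] >= cfg.epsilon_production - 1e-5, (
            f"present metabolite {m} not produced"
        )


def solve(problem: INITProblem, config: Optional[INITConfig] = None) -> INITSolution:
    """Solve to proven optimality (within the configured gap) with HiGHS."""
    cfg = config or problem.config
    c, constraints, bounds, integrality = _assemble(problem)
    start = time.perf_counter()
    res = milp(
        -c,  # milp minimizes
        constraints=constraints,
        bounds=bounds,
        integrality=integrality,
        options={"mip_rel_gap": cfg.solver_gap_tolerance, "presolve": True},
    )
    elapsed = time.perf_counter() - start
    if res.status == 2:
        return INITSolution(
            y={}, v={}, b={}, x={}, objective=float("nan"),
            solver_status="infeasible", wall_time=elapsed,
        )
    if res.status != 0 or res.x is None:
        return INITSolution(
            y={}, v={}, b={}, x={}, objective=float("nan"),
            solver_status="error", wall_time=elapsed,
        )
    xvec = res.x
    sol = INITSolution(
        y={rid: int(round(xvec[k])) for rid, k in problem.y_index.items()},
        v={rid: float(xvec[problem.v_index[rid]]) for rid in problem.rxn_ids},
        b={m: float(xvec[problem.b_index[m]]) for m in problem.internal_met_ids},
        x={m: int(round(xvec[k])) for m, k in problem.x_index.items()},
        objective=float(-res.fun),
        solver_status="optimal",
        wall_time=elapsed,
    )
    # tiny fluxes on excluded reactions are solver noise; snap them
    for rid, yi in sol.y.items():
        if yi == 0 and abs(sol.v[rid]) < 1e-6:
            sol.v[rid] = 0.0
    _check_solution(problem, sol)
    return sol


def extract_network(
    template: MetabolicModel,
    solution: INITSolution,
    gene_scores: Optional[Dict[str, float]] = None,
    flux_tolerance: float = 1e-6,
    id: Optional[str] = None,
) -> MetabolicModel:
    """Model with the y=1 reactions plus the exchange reactions actually used.

    GPRs are pruned to positive-evidence genes; a reaction kept despite all
    its genes scoring non-positive retains an empty GPR.
    """
    from .evidence import prune_gpr

    keep = set(solution.included_reactions)
    for r in template.exchange_reactions:
        if abs(solution.v.get(r.id, 0.0)) > flux_tolerance:
            keep.add(r.id)
    sub = template.subset(keep, id=id or f"{template.id}_extracted")
    if gene_scores is not None:
        for r in sub.reactions:
            r.gpr = prune_gpr(r.gpr, gene_scores)
        genes = set()
        for r in sub.reactions:
            genes |= r.genes
        sub.genes = sorted(genes)
        sub.validate()
    return sub


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

class OracleCapError(ValueError):
    pass


def _subset_lp(
    template: MetabolicModel,
    v_bounds: Dict[str, Tuple[float, float]],
    forced_production: Set[str],
    cfg: INITConfig,
    S,
    met_ids: List[str],
    rxn_ids: List[str],
    objective_row: Optional[np.ndarray] = None,
):
    """LP over (v, b): S v = b, b in [0, M] (present rows in [eps_b, M])."""
    n, m = len(rxn_ids), len(met_ids)
    bounds = [v_bounds[r] for r in rxn_ids]
    for met in met_ids:
        lo = cfg.epsilon_production if met in forced_production else 0.0
        bounds.append((lo, cfg.big_M))
    A_eq = sparse.hstack([S, -sparse.identity(m, format="csr")], format="csr")
    c = np.zeros(n + m) if objective_row is None else objective_row
    return solve_lp(c, A_eq, np.zeros(m), bounds, maximize=objective_row is not None)


def _max_reward_count(
    template, v_bounds, present, candidates, cfg, S, met_ids, rxn_ids
) -> int:
    """Largest set of candidate metabolites jointly producible at >= eps_b.

    Producibility is downward closed, so test the full candidate set first
    and only fall back to a decreasing-size exhaustive search on failure.
    """
    candidates = list(candidates)

    def feasible(extra: Iterable[str]) -> bool:
        res = _subset_lp(
            template, v_bounds, present | set(extra), cfg, S, met_ids, rxn_ids
        )
        return res.status == 0

    if feasible(candidates):
        return len(candidates)
    for size in range(len(candidates) - 1, 0, -1):
        for combo in itertools.combinations(candidates, size):
            if feasible(combo):
                return size
    return 0


def brute_force_oracle(
    template: MetabolicModel,
    weights: "WeightVector | Dict[str, float]",
    present_metabolites: Iterable[str] = (),
    config: Optional[INITConfig] = None,
    cap: int = 12,
) -> Tuple[Optional[Set[str]], float]:
    """Exhaustive search over inclusion subsets and flux directions.

    Returns (best reaction set, best objective); (None, nan) if no feasible
    subset exists (a present metabolite cannot be produced).  Refuses
    templates with more than ``cap`` non-exchange reactions.
    """
    cfg = config or INITConfig()
    wmap = weights.weights if isinstance(weights, WeightVector) else dict(weights)
    non_ex = template.non_exchange_reactions
    if len(non_ex) > cap:
        raise OracleCapError(
            f"{len(non_ex)} non-exchange reactions exceed oracle cap {cap}"
        )
    present = set(present_metabolites)
    S, met_ids, rxn_ids = stoichiometric_matrix(template, internal_only=True)
    delta = cfg.production_reward
    exchange_bounds = {
        r.id: (-cfg.big_M if r.reversible else 0.0, cfg.big_M)
        for r in template.exchange_reactions
    }
    n_internal = len(met_ids)

    best_obj = -np.inf
    best_set: Optional[Set[str]] = None
    ids = [r.id for r in non_ex]
    subsets = sorted(
        (frozenset(combo) for k in range(len(ids) + 1) for combo in itertools.combinations(ids, k)),
        key=lambda s: -sum(wmap[r] for r in s),
    )
    rev_map = {r.id: r.reversible for r in non_ex}
    for included in subsets:
        w_sum = sum(wmap[r] for r in included)
        if w_sum + delta * n_internal <= best_obj + 1e-12:
            continue  # cannot beat the incumbent even with every reward
        rev_included = [r for r in included if rev_map[r]]
        for directions in itertools.product((1, -1), repeat=len(rev_included)):
            v_bounds: Dict[str, Tuple[float, float]] = dict(exchange_bounds)
            for r in non_ex:
                if r.id not in included:
                    v_bounds[r.id] = (0.0, 0.0)
                elif not r.reversible:
                    v_bounds[r.id] = (cfg.epsilon_flux, cfg.big_M)
            for r, sign in zip(rev_included, directions):
                v_bounds[r] = (
                    (cfg.epsilon_flux, cfg.big_M)
                    if sign > 0
                    else (-cfg.big_M, -cfg.epsilon_flux)
                )
            base = _subset_lp(template, v_bounds, present, cfg, S, met_ids, rxn_ids)
            if base.status != 0:
                continue
            # candidates: metabolites individually producible at >= eps_b
            candidates = []
            for j, met in enumerate(met_ids):
                if met in present:
                    continue
                obj = np.zeros(len(rxn_ids) + n_internal)
                obj[len(rxn_ids) + j] = 1.0
                res = _subset_lp(
                    template, v_bounds, present, cfg, S, met_ids, rxn_ids,
                    objective_row=obj,
                )
                if res.status == 0 and res.fun >= cfg.epsilon_production - 1e-9:
                    candidates.append(met)
            count = _max_reward_count(
                template, v_bounds, present, candidates, cfg, S, met_ids, rxn_ids
            )
            obj_val = w_sum + delta * (count + len(present))
            if obj_val > best_obj + 1e-12:
                best_obj = obj_val
                best_set = set(included)
    if best_set is None:
        return None, float("nan")
    return best_set, float(best_obj)


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------

def _jaccard(a: Set[str], b: Set[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


@dataclass
class SensitivityReport:
    baseline_reactions: Set[str]
    similarities: List[float]
    perturbations: List[Dict[str, float]]

    @property
    def mean_jaccard(self) -> float:
        return float(np.mean(self.similarities)) if self.similarities else 1.0

    @property
    def min_jaccard(self) -> float:
        return float(np.min(self.similarities)) if self.similarities else 1.0


def weight_sensitivity(
    template: MetabolicModel,
    model_for_weights: MetabolicModel,
    evidence,
    tissue: str,
    present_metabolites: Iterable[str] = (),
    config: Optional[INITConfig] = None,
    weight_config=None,
    perturbation: float = 0.20,
    n_draws: int = 8,
    seed: int = 0,
) -> SensitivityReport:
    """Re-solve with the four staining weights perturbed by ±``perturbation``.

    Draws random up/down combinations (all 16 sign patterns when
    ``n_draws`` >= 16) and reports Jaccard similarity of the perturbed
    reaction sets against the unperturbed solution.
    """
    from .evidence import HPA_LEVELS, WeightConfig, reaction_weights

    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    cfg = config or INITConfig()
    wcfg = weight_config or WeightConfig()
    present = frozenset(present_metabolites)

    def run(wc) -> Set[str]:
        wv = reaction_weights(model_for_weights, evidence, tissue, wc)
        problem = build_problem(template, wv, present, cfg)
        sol = solve(problem)
        if sol.solver_status != "optimal":
            raise RuntimeError(f"solver status {sol.solver_status}")
        return sol.included_reactions

    baseline = run(wcfg)
    patterns = list(itertools.product((1 + perturbation, 1 - perturbation), repeat=4))
    rng = np.random.default_rng(seed)
    if n_draws >= len(patterns):
        chosen = patterns
    else:
        chosen = [patterns[i] for i in rng.choice(len(patterns), n_draws, replace=False)]
    sims, perts = [], []
    for factors in chosen:
        hpa = {
            level: wcfg.hpa_weights[level] * f
            for level, f in zip(HPA_LEVELS, factors)
        }
        wc = WeightConfig(
            hpa_weights=hpa,
            no_evidence_weight=wcfg.no_evidence_weight,
            expression_scale=wcfg.expression_scale,
            expression_log_base=wcfg.expression_log_base,
            expression_pseudocount=wcfg.expression_pseudocount,
        )
        sims.append(_jaccard(baseline, run(wc)))
        perts.append(dict(zip(HPA_LEVELS, [float(f) for f in factors])))
    return SensitivityReport(
        baseline_reactions=baseline, similarities=sims, perturbations=perts
    )
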