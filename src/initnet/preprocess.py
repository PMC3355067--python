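"""Template curation: turn a raw merged model into a connected,
flux-consistent template network.

The pipeline applies, in order: removal of reactions touching blacklisted
generic metabolites and elementally unbalanced reactions; removal of
reactions lacking directionality information; iterative removal of
reactions with unproducible substrates (dead ends); and removal of
reactions that cannot carry flux with all exchanges open.  The last two
stages are iterated to a joint fixed point, since a flux-inconsistency
removal can create new dead ends.

Mass-balance checking tolerates hydrogen imbalance (free proton exchange is
assumed); any other element with nonzero net count marks a reaction as
unbalanced.  Reactions with a formula-less metabolite are reported as
uncheckable, never as unbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import sparse

from ._lp import DEFAULT_BOUND, flux_bounds, solve_lp
from .model_core import MetabolicModel, Reaction, stoichiometric_matrix

__all__ = [
    "StageRecord",
    "CurationReport",
    "TemplateConfig",
    "MassBalanceReport",
    "remove_blacklisted",
    "check_mass_balance",
    "leak_test",
    "remove_no_directionality",
    "remove_unconnected",
    "flux_consistent",
    "build_template",
]

#: Minimum flux treated as "can carry flux".
DEFAULT_FLUX_THRESHOLD = 1e-4

REASONS = (
    "generic_metabolite",
    "unbalanced",
    "no_directionality",
    "unconnected",
    "flux_inconsistent",
)


@dataclass
class StageRecord:
    stage: str
    removed: Dict[str, str]  # reaction id -> reason code
    n_reactions: int
    n_metabolites: int
    n_genes: int


@dataclass
class CurationReport:
    stages: List[StageRecord] = field(default_factory=list)
    #: LP flux certificates from the consistency stage: rid -> flux dict.
    certificates: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def add_stage(self, stage: str, removed: Dict[str, str], model: MetabolicModel):
        genes = set()
        for r in model.reactions:
            genes |= r.genes
        self.stages.append(
            StageRecord(
                stage=stage,
                removed=dict(removed),
                n_reactions=len(model.reactions),
                n_metabolites=len(model.metabolites),
                n_genes=len(genes),
            )
        )

    @property
    def removed(self) -> Dict[str, str]:
        out: Dict[str, str] = {}
        for s in self.stages:
            out.update(s.removed)
        return out

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "removed": s.removed,
                    "n_reactions": s.n_reactions,
                    "n_metabolites": s.n_metabolites,
                    "n_genes": s.n_genes,
                }
                for s in self.stages
            ]
        }


@dataclass
class TemplateConfig:
    blacklist: Set[str] = field(default_factory=set)
    #: Reaction ids with known directionality; None = all known.
    directionality_known: Optional[Set[str]] = None
    remove_unbalanced: bool = True
    flux_threshold: float = DEFAULT_FLUX_THRESHOLD
    big_m: float = DEFAULT_BOUND


def _drop_dangling(model: MetabolicModel, keep_rxns: Iterable[str]) -> MetabolicModel:
    return model.subset(keep_rxns)


def remove_blacklisted(
    model: MetabolicModel, blacklist: Iterable[str]
) -> Tuple[MetabolicModel, Dict[str, str]]:
    """Drop reactions touching blacklisted metabolites (matched by id or
    case-insensitive name), then dangling metabolites."""
    terms = {b.lower() for b in blacklist}
    if not terms:
        return model, {}
    bad_mets = {
        m.id
        for m in model.metabolites
        if m.id.lower() in terms or (m.name and m.name.lower() in terms)
    }
    removed = {
        r.id: "generic_metabolite"
        for r in model.reactions
        if set(r.stoichiometry) & bad_mets
    }
    keep = [r.id for r in model.reactions if r.id not in removed]
    return _drop_dangling(model, keep), removed


@dataclass
class MassBalanceReport:
    unbalanced: List[str]
    uncheckable: List[str]


def check_mass_balance(model: MetabolicModel) -> MassBalanceReport:
    """Elemental balance per non-exchange reaction; H imbalance is tolerated."""
    formulas = {m.id: m.formula for m in model.metabolites}
    unbalanced, uncheckable = [], []
    for rxn in model.reactions:
        if rxn.is_exchange:
            continue
        if any(formulas[m] is None for m in rxn.stoichiometry):
            uncheckable.append(rxn.id)
            continue
        net: Dict[str, float] = {}
        for met, coeff in rxn.stoichiometry.items():
            for element, count in formulas[met].items():
                net[element] = net.get(element, 0.0) + coeff * count
        if any(abs(v) > 1e-9 for e, v in net.items() if e != "H"):
            unbalanced.append(rxn.id)
    return MassBalanceReport(unbalanced=unbalanced, uncheckable=uncheckable)


def remove_no_directionality(
    model: MetabolicModel, directionality_known: Optional[Iterable[str]] = None
) -> Tuple[MetabolicModel, Dict[str, str]]:
    if directionality_known is None:
        return model, {}
    known = set(directionality_known)
    removed = {r.id: "no_directionality" for r in model.reactions if r.id not in known}
    keep = [r.id for r in model.reactions if r.id not in removed]
    return _drop_dangling(model, keep), removed


def _producible_metabolites(reactions: Sequence[Reaction]) -> Set[str]:
    """Metabolites producible by some reaction or exchangeable."""
    out: Set[str] = set()
    for r in reactions:
        if r.is_exchange:
            # an exchange makes its metabolite available regardless of sign
            out |= set(r.stoichiometry)
        else:
            out |= set(r.products)
            if r.reversible:
                out |= set(r.reactants)
    return out


def _substrates(rxn: Reaction) -> Set[str]:
    subs = set(rxn.reactants)
    if rxn.reversible:
        subs |= set(rxn.products)
    return subs


def remove_unconnected(
    model: MetabolicModel,
) -> Tuple[MetabolicModel, Dict[str, str]]:
    """Iteratively drop reactions whose substrates no other reaction can supply.

    A substrate counts as supplied if it has an exchange reaction or is
    producible by at least one *other* retained reaction (either side of a
    reversible reaction counts as producible).  Runs to a fixed point.
    """
    retained = list(model.reactions)
    removed: Dict[str, str] = {}
    changed = True
    while changed:
        changed = False
        produced_by: Dict[str, Set[str]] = {}
        for r in retained:
            if r.is_exchange:
                for m in r.stoichiometry:
                    produced_by.setdefault(m, set()).add(r.id)
            else:
                mets = set(r.products) | (set(r.reactants) if r.reversible else set())
                for m in mets:
                    produced_by.setdefault(m, set()).add(r.id)
        next_retained = []
        for r in retained:
            if r.is_exchange:
                next_retained.append(r)
                continue
            dead = any(
                not (produced_by.get(s, set()) - {r.id}) for s in _substrates(r)
            )
            if dead:
                removed[r.id] = "unconnected"
                changed = True
            else:
                next_retained.append(r)
        retained = next_retained
    return _drop_dangling(model, [r.id for r in retained]), removed


def flux_consistent(
    model: MetabolicModel,
    flux_threshold: float = DEFAULT_FLUX_THRESHOLD,
    big_m: float = DEFAULT_BOUND,
    report: Optional[CurationReport] = None,
) -> Tuple[MetabolicModel, Dict[str, str]]:
    """Keep exactly the reactions able to carry |v| ≥ threshold at steady
    state with all exchanges open.

    Per-reaction flux maximization; reactions already carrying flux in a
    previous LP certificate are skipped (results identical to the plain
    per-reaction scan, which serves as the test oracle).
    """
    if not model.reactions:
        return model, {}
    S, _, rxn_ids = stoichiometric_matrix(model, internal_only=True)
    n = len(rxn_ids)
    bounds = [flux_bounds(r.reversible, big_m) for r in model.reactions]
    b_eq = np.zeros(S.shape[0])
    consistent: Set[str] = set()
    certificates: Dict[str, Dict[str, float]] = {}

    def record(v: np.ndarray):
        for k, rid in enumerate(rxn_ids):
            if abs(v[k]) >= flux_threshold and rid not in consistent:
                consistent.add(rid)
                certificates[rid] = {
                    rj: float(v[j]) for j, rj in enumerate(rxn_ids) if v[j] != 0.0
                }

    for i, rxn in enumerate(model.reactions):
        if rxn.id in consistent:
            continue
        c = np.zeros(n)
        c[i] = 1.0
        res = solve_lp(c, S, b_eq, bounds, maximize=True)
        if res.status == 0 and res.fun >= flux_threshold:
            record(res.x)
            continue
        if rxn.reversible:
            res = solve_lp(c, S, b_eq, bounds, maximize=False)
            if res.status == 0 and res.fun <= -flux_threshold:
                record(res.x)
    removed = {rid: "flux_inconsistent" for rid in rxn_ids if rid not in consistent}
    out = _drop_dangling(model, sorted(consistent, key=rxn_ids.index))
    if report is not None:
        report.certificates.update(certificates)
    return out, removed


def leak_test(
    model: MetabolicModel,
    test_metabolites: Iterable[str],
    tolerance: float = 1e-6,
    big_m: float = DEFAULT_BOUND,
) -> Dict[str, float]:
    """Maximal free production of each test metabolite with all uptakes closed.

    Returns metabolite id → maximal production rate; entries above
    ``tolerance`` indicate the network can create the quantity from nothing
    (a leak).  Exchange reactions are restricted to secretion only.
    """
    S, met_ids, rxn_ids = stoichiometric_matrix(model, internal_only=True)
    row_of = {m: j for j, m in enumerate(met_ids)}
    bounds = []
    for rxn in model.reactions:
        lo, hi = flux_bounds(rxn.reversible, big_m)
        if rxn.is_exchange:
            met, coeff = next(iter(rxn.stoichiometry.items()))
            # secretion = flux direction that consumes the metabolite
            if coeff < 0:
                lo = 0.0
            else:
                hi = 0.0
                if not rxn.reversible:
                    lo = 0.0  # irreversible pure-uptake exchange: fully closed
        bounds.append((lo, hi))
    results: Dict[str, float] = {}
    n = len(rxn_ids)
    for met in test_metabolites:
        if met not in row_of:
            raise KeyError(f"unknown internal metabolite {met!r}")
        j = row_of[met]
        keep = [k for k in range(len(met_ids)) if k != j]
        A_eq = S[keep, :]
        c = np.asarray(S[j, :].todense()).ravel()
        res = solve_lp(c, A_eq, np.zeros(len(keep)), bounds, maximize=True)
        if res.status == 3:  # unbounded production
            results[met] = float("inf")
        elif res.status == 0:
            results[met] = float(res.fun)
        else:
            raise RuntimeError(f"leak LP failed for {met!r}: status {res.status}")
        _ = n
    return results


def build_template(
    model: MetabolicModel, config: Optional[TemplateConfig] = None
) -> Tuple[MetabolicModel, CurationReport]:
    """Apply the four curation stages; stages 3–4 iterate to a joint fixed point.

    Idempotent: running the pipeline on its own output changes nothing.
    """
    config = config or TemplateConfig()
    report = CurationReport()

    model, removed = remove_blacklisted(model, config.blacklist)
    if config.remove_unbalanced:
        balance = check_mass_balance(model)
        removed_bal = {rid: "unbalanced" for rid in balance.unbalanced}
        model = model.subset(
            [r.id for r in model.reactions if r.id not in removed_bal]
        )
        removed.update(removed_bal)
    report.add_stage("blacklist_balance", removed, model)

    model, removed = remove_no_directionality(model, config.directionality_known)
    report.add_stage("directionality", removed, model)

    removed_unconnected: Dict[str, str] = {}
    removed_inconsistent: Dict[str, str] = {}
    while True:
        model, removed = remove_unconnected(model)
        removed_unconnected.update(removed)
        model, removed = flux_consistent(
            model, config.flux_threshold, config.big_m, report=report
        )
        removed_inconsistent.update(removed)
        if not removed:
            break
    report.add_stage("unconnected", removed_unconnected, model)
    report.add_stage("flux_consistency", removed_inconsistent, model)
    return model, report
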