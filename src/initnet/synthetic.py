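"""Random connected stoichiometric networks with planted active subnetworks
and simulated evidence, so the whole pipeline is testable offline.

The generator grows a bipartite metabolite–reaction graph outward from a
set of exchanged seed metabolites, so every reaction's substrates are
producible by construction; dead-end products receive secretion exchanges.
The planted subnetwork is grown first and is verified to be flux-consistent
on its own (with exchanges open) before the decoy reactions are added.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .evidence import EvidenceTable
from .gpr import Gene
from .model_core import MetabolicModel, Metabolite, Reaction

__all__ = [
    "SyntheticSpec",
    "generate_network",
    "simulate_evidence",
    "simulate_network_groups",
]


@dataclass
class SyntheticSpec:
    n_metabolites: int = 20
    n_reactions: int = 30
    reversible_fraction: float = 0.2
    exchange_fraction: float = 0.2
    planted_fraction: float = 0.5
    hpa_noise_rate: float = 0.0
    expression_lognormal_sigma: float = 0.5
    n_tissues: int = 5
    seed: int = 0
    #: mixture over (high, medium, low) labels for planted genes
    hpa_level_mixture: Tuple[float, float, float] = (0.5, 0.3, 0.2)
    target_tissue: str = "t0"

    def __post_init__(self):
        for name in (
            "reversible_fraction",
            "exchange_fraction",
            "planted_fraction",
            "hpa_noise_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_reactions < self.n_metabolites / 3:
            raise ValueError("need n_reactions >= n_metabolites / 3 for connectivity")
        if self.n_tissues < 1:
            raise ValueError("n_tissues must be >= 1")
        if abs(sum(self.hpa_level_mixture) - 1.0) > 1e-9:
            raise ValueError("hpa_level_mixture must sum to 1")

    @property
    def tissues(self) -> List[str]:
        return [f"t{i}" for i in range(self.n_tissues)]


def _grow_reactions(
    rng: np.random.Generator,
    count: int,
    prefix: str,
    producible: Set[str],
    unused: List[str],
    spec: SyntheticSpec,
) -> List[Reaction]:
    reactions = []
    for k in range(count):
        rid = f"{prefix}{k}"
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        pool = sorted(producible)
        subs = list(rng.choice(pool, size=min(n_sub, len(pool)), replace=False))
        prods: List[str] = []
        for _ in range(n_prod):
            if unused:
                met = unused.pop(int(rng.integers(0, len(unused))))
            else:
                choices = [m for m in sorted(producible) if m not in subs]
                if not choices:
                    break
                met = choices[int(rng.integers(0, len(choices)))]
            if met not in prods and met not in subs:
                prods.append(met)
        if not prods:  # degenerate draw; force a fresh product from producible
            choices = [m for m in sorted(producible) if m not in subs]
            prods = [choices[0]] if choices else []
        stoich: Dict[str, float] = {}
        for met in subs:
            stoich[met] = -float(rng.integers(1, 3))
        for met in prods:
            stoich[met] = float(rng.integers(1, 3))
        reversible = bool(rng.random() < spec.reversible_fraction)
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=reversible,
                gpr=Gene(f"g_{rid}"),
            )
        )
        producible.update(prods)
    return reactions


def _assemble_model(
    spec: SyntheticSpec, rng: np.random.Generator
) -> Tuple[MetabolicModel, Set[str]]:
    met_ids = [f"m{i}[c]" for i in range(spec.n_metabolites)]
    n_exchange = max(2, round(spec.exchange_fraction * spec.n_reactions))
    n_internal_rxns = max(1, spec.n_reactions - n_exchange)
    n_planted = round(spec.planted_fraction * n_internal_rxns)

    n_seed = max(1, n_exchange // 2)
    seed_mets = list(rng.choice(met_ids, size=min(n_seed, len(met_ids)), replace=False))
    producible: Set[str] = set(seed_mets)
    unused = [m for m in met_ids if m not in producible]

    exchanges = [
        Reaction(id=f"EX_{met}", stoichiometry={met: 1.0}, reversible=True)
        for met in seed_mets
    ]
    planted_rxns = _grow_reactions(rng, n_planted, "P", producible, unused, spec)
    decoy_rxns = _grow_reactions(
        rng, n_internal_rxns - n_planted, "D", producible, unused, spec
    )

    internal = planted_rxns + decoy_rxns
    # Secretion outlets: a metabolite only counts as drained if an
    # irreversible reaction consumes it (a reversible consumer may be forced
    # backwards and is not a reliable sink).  The planted subnetwork must be
    # flux-capable on its own, so drainage is assessed against planted
    # reactions for planted metabolites and against all reactions otherwise.
    def _drained(reactions: Sequence[Reaction]) -> Set[str]:
        out: Set[str] = set()
        for r in reactions:
            if not r.reversible:
                out |= set(r.reactants)
        return out

    consumed_planted = _drained(planted_rxns)
    consumed_all = _drained(internal)
    # metabolites touched by a reversible reaction need an outlet too: the
    # dead-end removal step treats either side of a reversible reaction as a
    # substrate, so such metabolites must be exchangeable to survive curation
    reversible_touched: Set[str] = set()
    for r in internal:
        if r.reversible:
            reversible_touched |= set(r.stoichiometry)
    consumed_planted -= reversible_touched
    consumed_all -= reversible_touched
    exchanged = {next(iter(r.stoichiometry)) for r in exchanges}
    used: Set[str] = set()
    used_planted: Set[str] = set()
    for r in internal:
        used |= set(r.stoichiometry)
    for r in planted_rxns:
        used_planted |= set(r.stoichiometry)
    for met in met_ids:
        if met in exchanged:
            continue
        planted_dead_end = met in used_planted and met not in consumed_planted
        dead_end = met in used and met not in consumed_all
        if planted_dead_end or dead_end:
            exchanges.append(
                Reaction(id=f"EX_{met}", stoichiometry={met: -1.0}, reversible=False)
            )
    metabolites = [
        Metabolite(id=m, name=m.split("[")[0], compartment="cytosol")
        for m in met_ids
        if m in used or m in exchanged
    ]
    reactions = exchanges + internal
    genes = sorted(set().union(*(r.genes for r in reactions)))
    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        id=f"synthetic_seed{spec.seed}",
    )
    return model, {r.id for r in planted_rxns}


def generate_network(
    spec: SyntheticSpec, max_retries: int = 20
) -> Tuple[MetabolicModel, Set[str]]:
    """Generate a model plus its planted reaction-id set.

    Retries with derived sub-seeds until both the full model and the planted
    subnetwork (with its exchanges) are flux-consistent.
    """
    from .preprocess import flux_consistent

    for attempt in range(max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        model, planted = _assemble_model(spec, rng)
        _, removed_full = flux_consistent(model)
        if removed_full:
            continue
        sub_ids = planted | {r.id for r in model.exchange_reactions}
        sub = model.subset(sub_ids)
        _, removed_planted = flux_consistent(sub)
        if set(removed_planted) - {r.id for r in model.exchange_reactions}:
            continue
        return model, planted
    raise RuntimeError(
        "could not generate a flux-consistent network; try a larger "
        "exchange_fraction or more reactions per metabolite"
    )


def simulate_evidence(
    model: MetabolicModel,
    planted_set: Set[str],
    spec: SyntheticSpec,
) -> EvidenceTable:
    """Noisy staining labels plus lognormal expression signals.

    Genes of planted reactions are labeled high/medium/low (per the spec's
    mixture) in the target tissue and absent otherwise; labels flip with
    ``hpa_noise_rate``.  Expression signals are lognormal across tissues,
    with a four-fold elevated mean for planted genes in the target tissue.
    """
    unknown = planted_set - {r.id for r in model.reactions}
    if unknown:
        raise ValueError(f"planted reactions not in model: {sorted(unknown)}")
    rng = np.random.default_rng([spec.seed, 10_007])
    planted_genes: Set[str] = set()
    for r in model.reactions:
        if r.id in planted_set:
            planted_genes |= r.genes
    levels = ("high", "medium", "low")
    rows = []
    for gene in sorted(model.genes):
        is_planted = gene in planted_genes
        if is_planted:
            label = levels[int(rng.choice(3, p=list(spec.hpa_level_mixture)))]
            if rng.random() < spec.hpa_noise_rate:
                label = "absent"
        else:
            label = "absent"
            if rng.random() < spec.hpa_noise_rate:
                label = levels[int(rng.choice(3, p=list(spec.hpa_level_mixture)))]
        signals = np.exp(rng.normal(0.0, spec.expression_lognormal_sigma, spec.n_tissues))
        if is_planted:
            signals[0] *= 4.0
        for t, tissue in enumerate(spec.tissues):
            rows.append(
                {
                    "gene": gene,
                    "tissue": tissue,
                    # staining is only simulated for the target tissue; other
                    # tissues carry expression evidence alone
                    "hpa_level": label if tissue == spec.target_tissue else np.nan,
                    "expression_signal": float(signals[t]),
                }
            )
    return EvidenceTable(pd.DataFrame(rows))


def simulate_network_groups(
    spec: SyntheticSpec,
    n_group_a: int,
    n_group_b: int,
    n_differential_features: int,
    decoy_inclusion_rate: float = 0.5,
) -> Tuple[List[MetabolicModel], Dict[str, str], Dict[str, List[str]]]:
    """Two groups of extracted-style networks sharing a core.

    Group-a networks carry ``n_differential_features`` planted reactions that
    group-b networks lack; remaining decoy reactions are included at random
    per network.  Returns (models, label→group map, truth dict with the
    differential reaction and gene ids).
    """
    model, planted = generate_network(spec)
    if n_differential_features > len(planted):
        raise ValueError("n_differential_features exceeds the planted set size")
    rng = np.random.default_rng([spec.seed, 20_011])
    planted_sorted = sorted(planted)
    differential = [
        planted_sorted[i]
        for i in rng.choice(len(planted_sorted), n_differential_features, replace=False)
    ]
    core = [r for r in planted_sorted if r not in differential]
    decoys = sorted(
        r.id for r in model.non_exchange_reactions if r.id not in planted
    )
    exchanges = [r.id for r in model.exchange_reactions]
    models: List[MetabolicModel] = []
    groups: Dict[str, str] = {}
    for group, count in (("a", n_group_a), ("b", n_group_b)):
        for i in range(count):
            label = f"{group}{i}"
            chosen = [d for d in decoys if rng.random() < decoy_inclusion_rate]
            keep = set(exchanges) | set(core) | set(chosen)
            if group == "a":
                keep |= set(differential)
            models.append(model.subset(keep, id=label))
            groups[label] = group
    truth_genes = sorted(
        set().union(*(model.reaction_map[r].genes for r in differential))
        if differential
        else set()
    )
    return models, groups, {"reactions": sorted(differential), "genes": truth_genes}
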