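"""Per-gene evidence → per-reaction weights for one tissue.

Protein-staining categories map to fixed scores (high/medium/low/absent →
20/15/10/−8 by default).  Numeric expression evidence is scored as a scaled
log-ratio of the tissue signal to the gene's cross-tissue mean, so that a
signal equal to the mean scores zero and a two-fold change scores like the
"low" staining category.  A reaction takes the highest score over its GPR
genes; staining evidence takes precedence over expression for the same gene.
Reactions with no gene, or no scored gene, get the no-evidence default (−2);
exchange reactions are never penalized and get weight 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gpr import GPRNode, gpr_genes
from .gpr import prune_gpr as _prune_gpr_tree
from .model_core import MetabolicModel

__all__ = [
    "HPA_LEVELS",
    "WeightConfig",
    "EvidenceTable",
    "WeightVector",
    "hpa_gene_weight",
    "expression_gene_weight",
    "gene_score",
    "reaction_weights",
    "prune_gpr",
]

HPA_LEVELS = ("high", "medium", "low", "absent")


@dataclass
class WeightConfig:
    """Scoring parameters; defaults follow the published weight scheme."""

    hpa_weights: Dict[str, float] = field(
        default_factory=lambda: {"high": 20.0, "medium": 15.0, "low": 10.0, "absent": -8.0}
    )
    no_evidence_weight: float = -2.0
    expression_scale: float = 10.0
    expression_log_base: float = 2.0
    #: None → auto: half the smallest positive signal (0 if no zeros present).
    expression_pseudocount: Optional[float] = None

    def __post_init__(self):
        missing = set(HPA_LEVELS) - set(self.hpa_weights)
        if missing:
            raise ValueError(f"hpa_weights missing levels: {sorted(missing)}")
        w = self.hpa_weights
        # sign constraints only: independent +/-20% perturbations of the four
        # category weights (sensitivity analysis) may break strict ordering
        if not (w["high"] > 0 and w["medium"] > 0 and w["low"] > 0 > w["absent"]):
            raise ValueError("require high, medium, low > 0 > absent")
        if not self.no_evidence_weight < 0:
            raise ValueError("no_evidence_weight must be negative")
        if self.expression_scale <= 0 or self.expression_log_base <= 1:
            raise ValueError("expression_scale > 0 and expression_log_base > 1 required")

    def scaled(self, factor: float) -> "WeightConfig":
        """Copy with every categorical weight multiplied by ``factor``."""
        return WeightConfig(
            hpa_weights={k: v * factor for k, v in self.hpa_weights.items()},
            no_evidence_weight=self.no_evidence_weight * factor,
            expression_scale=self.expression_scale * factor,
            expression_log_base=self.expression_log_base,
            expression_pseudocount=self.expression_pseudocount,
        )


class EvidenceTable:
    """Rows keyed by (gene, tissue) holding staining level and/or signal."""

    def __init__(self, frame: Optional[pd.DataFrame] = None):
        if frame is None:
            frame = pd.DataFrame(
                columns=["gene", "tissue", "hpa_level", "expression_signal"]
            )
        frame = frame.copy()
        for col in ("hpa_level", "expression_signal"):
            if col not in frame.columns:
                frame[col] = np.nan
        bad = frame["hpa_level"].dropna()
        bad = bad[~bad.isin(HPA_LEVELS)]
        if len(bad):
            raise ValueError(f"unknown HPA levels: {sorted(bad.unique())}")
        signals = pd.to_numeric(frame["expression_signal"], errors="coerce")
        if (signals.dropna() < 0).any():
            raise ValueError("expression signals must be nonnegative")
        frame["expression_signal"] = signals
        no_data = frame["hpa_level"].isna() & frame["expression_signal"].isna()
        if no_data.any():
            raise ValueError("every evidence row needs an HPA level or a signal")
        self.frame = frame[["gene", "tissue", "hpa_level", "expression_signal"]]
        self._hpa = {
            (r.gene, r.tissue): r.hpa_level
            for r in frame.itertuples()
            if isinstance(r.hpa_level, str)
        }
        expr = frame[~frame["expression_signal"].isna()]
        self._signal = {
            (r.gene, r.tissue): float(r.expression_signal) for r in expr.itertuples()
        }
        self._signals_by_gene: Dict[str, Dict[str, float]] = {}
        for (gene, tissue), sig in self._signal.items():
            self._signals_by_gene.setdefault(gene, {})[tissue] = sig

    @property
    def tissues(self) -> list:
        return sorted(self.frame["tissue"].unique())

    @property
    def genes(self) -> list:
        return sorted(self.frame["gene"].unique())

    def hpa_level(self, gene: str, tissue: str) -> Optional[str]:
        return self._hpa.get((gene, tissue))

    def expression_signals(self, gene: str) -> Dict[str, float]:
        """All per-tissue signals available for a gene."""
        return dict(self._signals_by_gene.get(gene, {}))

    @classmethod
    def from_tsv(cls, path) -> "EvidenceTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"gene": str, "tissue": str}))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class WeightVector:
    """Per-reaction weights w_i for one tissue, with provenance."""

    weights: Dict[str, float]
    source_type: Dict[str, str] = field(default_factory=dict)  # hpa|expression|none
    source_gene: Dict[str, Optional[str]] = field(default_factory=dict)
    tissue: str = ""

    def __getitem__(self, reaction_id: str) -> float:
        return self.weights[reaction_id]

    def to_frame(self) -> pd.DataFrame:
        rids = list(self.weights)
        return pd.DataFrame(
            {
                "reaction": rids,
                "weight": [self.weights[r] for r in rids],
                "source_gene": [self.source_gene.get(r) or "" for r in rids],
                "source_type": [self.source_type.get(r, "none") for r in rids],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hpa_gene_weight(level: str, config: Optional[WeightConfig] = None) -> float:
    """Score of one staining category."""
    config = config or WeightConfig()
    if level not in config.hpa_weights:
        raise ValueError(f"unknown HPA level {level!r}")
    return config.hpa_weights[level]


def expression_gene_weight(
    signal: float,
    all_tissue_signals: Sequence[float],
    config: Optional[WeightConfig] = None,
) -> float:
    """Scaled log of signal over cross-tissue mean (positive above the mean)."""
    config = config or WeightConfig()
    signals = np.asarray(list(all_tissue_signals), dtype=float)
    if signals.size == 0:
        raise ValueError("all_tissue_signals must be non-empty")
    if signal < 0 or (signals < 0).any():
        raise ValueError("signals must be nonnegative")
    pseudo = config.expression_pseudocount
    if pseudo is None:
        positive = signals[signals > 0]
        needs = signal == 0 or (signals == 0).any()
        pseudo = float(positive.min()) / 2.0 if (needs and positive.size) else 0.0
    mean = float(signals.mean())
    if mean + pseudo <= 0 or signal + pseudo <= 0:
        raise ValueError("zero signals with zero pseudocount: ratio undefined")
    ratio = (signal + pseudo) / (mean + pseudo)
    return config.expression_scale * math.log(ratio, config.expression_log_base)


def gene_score(
    gene: str,
    tissue: str,
    evidence: EvidenceTable,
    config: Optional[WeightConfig] = None,
) -> Tuple[Optional[float], str]:
    """(score, source) for one gene in one tissue; source in {hpa, expression, none}.

    Staining evidence takes precedence over expression when both exist.
    """
    config = config or WeightConfig()
    level = evidence.hpa_level(gene, tissue)
    if level is not None:
        return hpa_gene_weight(level, config), "hpa"
    signals = evidence.expression_signals(gene)
    if tissue in signals:
        return (
            expression_gene_weight(signals[tissue], list(signals.values()), config),
            "expression",
        )
    return None, "none"


def reaction_weights(
    model: MetabolicModel,
    evidence: EvidenceTable,
    tissue: str,
    config: Optional[WeightConfig] = None,
) -> WeightVector:
    """Weight per reaction: max gene score, or the no-evidence default.

    Exchange reactions get weight 0 (never penalized, never rewarded).
    """
    config = config or WeightConfig()
    weights: Dict[str, float] = {}
    source_type: Dict[str, str] = {}
    source_gene: Dict[str, Optional[str]] = {}
    score_cache: Dict[str, Tuple[Optional[float], str]] = {}
    for rxn in model.reactions:
        if rxn.is_exchange:
            weights[rxn.id] = 0.0
            source_type[rxn.id] = "none"
            source_gene[rxn.id] = None
            continue
        best: Optional[Tuple[float, str, str]] = None
        for gene in sorted(rxn.genes):
            if gene not in score_cache:
                score_cache[gene] = gene_score(gene, tissue, evidence, config)
            score, source = score_cache[gene]
            if score is None:
                continue
            if best is None or score > best[0]:
                best = (score, source, gene)
        if best is None:
            weights[rxn.id] = config.no_evidence_weight
            source_type[rxn.id] = "none"
            source_gene[rxn.id] = None
        else:
            weights[rxn.id], source_type[rxn.id], source_gene[rxn.id] = best
    return WeightVector(
        weights=weights, source_type=source_type, source_gene=source_gene, tissue=tissue
    )


def gene_scores_for_tissue(
    genes,
    tissue: str,
    evidence: EvidenceTable,
    config: Optional[WeightConfig] = None,
) -> Dict[str, float]:
    """Score map over ``genes`` (scored genes only)."""
    config = config or WeightConfig()
    out: Dict[str, float] = {}
    for gene in genes:
        score, _ = gene_score(gene, tissue, evidence, config)
        if score is not None:
            out[gene] = score
    return out


def prune_gpr(
    gpr: Optional[GPRNode], gene_scores: Mapping[str, float]
) -> Optional[GPRNode]:
    """Keep only genes with positive evidence; empty expression if none remain."""
    return _prune_gpr_tree(gpr, gene_scores)
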