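"""Comparative analysis across sets of extracted networks.

Covers binary presence matrices (genes or reactions × networks),
hypergeometric group enrichment, reporter-metabolite scoring, average-linkage
clustering with bootstrap support, core/unique feature statistics and
set-overlap tests against reference gene lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .model_core import MetabolicModel

__all__ = [
    "PresenceMatrix",
    "presence_matrix",
    "group_enrichment",
    "reporter_metabolites",
    "cluster_networks",
    "core_unique_stats",
    "overlap_test",
]


@dataclass
class PresenceMatrix:
    frame: pd.DataFrame  # features × networks, {0,1}
    feature_kind: str  # gene | reaction
    groups: Dict[str, str] = field(default_factory=dict)  # network label -> group tag

    def __post_init__(self):
        values = self.frame.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0/1")
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate network labels")
        if self.frame.index.duplicated().any():
            raise ValueError("duplicate feature ids")

    @property
    def features(self) -> List[str]:
        return list(self.frame.index)

    @property
    def networks(self) -> List[str]:
        return list(self.frame.columns)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, feature_kind: str = "gene") -> "PresenceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame=frame.astype(int), feature_kind=feature_kind)


def presence_matrix(
    models: Sequence[MetabolicModel],
    feature_kind: str = "gene",
    labels: Optional[Sequence[str]] = None,
    groups: Optional[Dict[str, str]] = None,
) -> PresenceMatrix:
    """Binary feature × network membership matrix."""
    if not models:
        raise ValueError("need at least one model")
    if feature_kind not in ("gene", "reaction"):
        raise ValueError("feature_kind must be 'gene' or 'reaction'")
    labels = list(labels) if labels is not None else [m.id for m in models]
    if len(labels) != len(models):
        raise ValueError("labels/models length mismatch")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate network labels")
    feature_sets = [
        set(m.genes) if feature_kind == "gene" else {r.id for r in m.reactions}
        for m in models
    ]
    features = sorted(set().union(*feature_sets))
    data = np.zeros((len(features), len(models)), dtype=int)
    for col, fs in enumerate(feature_sets):
        for row, f in enumerate(features):
            if f in fs:
                data[row, col] = 1
    frame = pd.DataFrame(data, index=features, columns=labels)
    return PresenceMatrix(frame=frame, feature_kind=feature_kind, groups=groups or {})


def group_enrichment(
    matrix: PresenceMatrix,
    group_a_labels: Sequence[str],
    group_b_labels: Sequence[str],
    alternative: str = "greater",
    threshold: float = 1e-4,
) -> pd.DataFrame:
    """Per-feature hypergeometric test for over-representation in group a.

    The tail probability is that of observing >= k_a presences among the
    n_a group-a networks, given k_a + k_b presences across all n_a + n_b
    networks.  Columns: counts, p_value, q_value (Benjamini–Hochberg) and a
    boolean ``significant`` at the raw threshold.
    """
    a, b = list(group_a_labels), list(group_b_labels)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    missing = (set(a) | set(b)) - set(matrix.networks)
    if missing:
        raise ValueError(f"unknown network labels: {sorted(missing)}")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if alternative == "less":
        a, b = b, a
    n_a, n_b = len(a), len(b)
    k_a = matrix.frame[a].sum(axis=1).to_numpy()
    k_b = matrix.frame[b].sum(axis=1).to_numpy()
    total = k_a + k_b
    # P(X >= k_a), X ~ Hypergeom(N = n_a + n_b, K = total, n = n_a)
    p = stats.hypergeom.sf(k_a - 1, n_a + n_b, total, n_a)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = _bh_qvalues(p)
    return pd.DataFrame(
        {
            "count_in_group_a": k_a,
            "count_in_group_b": k_b,
            "p_value": p,
            "q_value": q,
            "significant": p < threshold,
        },
        index=matrix.frame.index,
    )


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def reporter_metabolites(
    template: MetabolicModel,
    gene_pvalues: Dict[str, float],
    n_null_samples: int = 1000,
    seed: int = 0,
    p_floor: float = 1e-15,
) -> pd.DataFrame:
    """Aggregate gene-level p-values onto metabolites of the template.

    For each internal metabolite with k >= 1 scored neighbor genes (genes of
    any reaction touching it, direction-agnostic): z_g = Phi^-1(1 - p_g),
    Z = sum(z)/sqrt(k), corrected by the mean/sd of Z over random size-k
    gene draws from the scored gene pool, and converted to a one-sided p.
    """
    if not gene_pvalues:
        raise ValueError("gene_pvalues is empty")
    clipped = {}
    for gene, p in gene_pvalues.items():
        if not (0 < p < 1):
            warnings.warn(f"p-value for {gene} clamped into ({p_floor}, {1 - p_floor})")
            p = min(max(p, p_floor), 1 - p_floor)
        clipped[gene] = p
    zmap = {g: stats.norm.isf(p) for g, p in clipped.items()}
    scored = sorted(zmap)
    zpool = np.array([zmap[g] for g in scored])

    neighbors: Dict[str, Set[str]] = {m.id: set() for m in template.internal_metabolites}
    for rxn in template.reactions:
        genes = rxn.genes & set(scored)
        if not genes:
            continue
        for met in rxn.stoichiometry:
            if met in neighbors:
                neighbors[met] |= genes

    rng = np.random.default_rng(seed)
    null_cache: Dict[int, Tuple[float, float]] = {}

    def null_moments(k: int) -> Tuple[float, float]:
        if k not in null_cache:
            if k >= len(zpool):
                # only one possible draw: degenerate null
                mu = float(zpool.sum() / np.sqrt(k))
                null_cache[k] = (mu, 1.0)
            else:
                draws = np.empty(n_null_samples)
                for i in range(n_null_samples):
                    draws[i] = zpool[
                        rng.choice(len(zpool), size=k, replace=False)
                    ].sum() / np.sqrt(k)
                sd = float(draws.std(ddof=1))
                # degenerate null (all gene z equal) -> sd is numerically zero
                null_cache[k] = (float(draws.mean()), sd if sd > 1e-12 else 1.0)
        return null_cache[k]

    rows = []
    for met in sorted(neighbors):
        genes = neighbors[met]
        k = len(genes)
        if k < 1:
            continue
        z_raw = sum(zmap[g] for g in genes) / np.sqrt(k)
        mu, sd = null_moments(k)
        z_corr = (z_raw - mu) / sd
        rows.append(
            {
                "metabolite": met,
                "k": k,
                "z_raw": z_raw,
                "z_corrected": z_corr,
                "p_value": float(stats.norm.sf(z_corr)),
            }
        )
    return pd.DataFrame(rows).set_index("metabolite")


@dataclass
class ClusteringResult:
    labels: List[str]
    linkage: np.ndarray
    supports: Dict[FrozenSet[str], float]

    def clades(self) -> List[FrozenSet[str]]:
        return _clades_from_linkage(self.linkage, self.labels)

    def to_newick(self) -> str:
        """Newick with bootstrap support as internal node labels."""
        n = len(self.labels)
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = render(node.get_left()), render(node.get_right())
            clade = frozenset(
                self.labels[i] for i in node.pre_order(lambda leaf: leaf.id)
            )
            support = self.supports.get(clade)
            label = "" if support is None or len(clade) == n else f"{support:.3f}"
            return f"({left},{right}){label}:{node.dist:.6g}"

        body = render(tree)
        return f"{body};"


def _clades_from_linkage(Z: np.ndarray, labels: Sequence[str]) -> List[FrozenSet[str]]:
    n = len(labels)
    members: Dict[int, FrozenSet[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    clades = []
    for i, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        clades.append(merged)
    return clades


def cluster_networks(
    matrix: PresenceMatrix, n_bootstrap: int = 1000, seed: int = 0
) -> ClusteringResult:
    """Average-linkage tree on Jaccard distance between network columns,
    with ordinary feature-resampling bootstrap support per internal clade."""
    labels = matrix.networks
    if len(labels) < 3:
        raise ValueError("need at least three networks to cluster")
    X = matrix.frame.to_numpy().T.astype(bool)  # networks × features

    def tree(data: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-zero rows give 0/0 -> 0
            d = pdist(data, metric="jaccard")
        return hierarchy.linkage(np.nan_to_num(d), method="average")

    Z = tree(X)
    reference = _clades_from_linkage(Z, labels)
    counts = {clade: 0 for clade in reference}
    rng = np.random.default_rng(seed)
    n_features = X.shape[1]
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_features, size=n_features)
        boot = set(_clades_from_linkage(tree(X[:, idx]), labels))
        for clade in reference:
            if clade in boot:
                counts[clade] += 1
    supports = {c: counts[c] / n_bootstrap for c in reference}
    return ClusteringResult(labels=labels, linkage=Z, supports=supports)


def core_unique_stats(matrix: PresenceMatrix) -> Dict[str, float]:
    """Counts/fractions of features present in all networks vs exactly one."""
    sums = matrix.frame.sum(axis=1)
    n_networks = len(matrix.networks)
    total = len(matrix.features)
    n_core = int((sums == n_networks).sum())
    n_unique = int((sums == 1).sum())
    return {
        "n_features": total,
        "n_core": n_core,
        "n_unique": n_unique,
        "frac_core": n_core / total if total else 0.0,
        "frac_unique": n_unique / total if total else 0.0,
    }


def overlap_test(
    model_genes: Iterable[str],
    reference_genes: Iterable[str],
    universe_size: int,
) -> Tuple[int, float]:
    """One-sided hypergeometric p for the observed gene-set overlap.

    p = P(overlap >= observed) drawing |model| genes from a universe
    containing |reference| marked genes.
    """
    model = set(model_genes)
    reference = set(reference_genes)
    if not reference:
        raise ValueError("reference set is empty")
    if universe_size < len(model | reference):
        raise ValueError("universe smaller than the union of the sets")
    overlap = len(model & reference)
    if overlap > min(len(model), len(reference)):
        raise ValueError("impossible overlap")  # unreachable with true sets
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, len(reference), len(model)))
    return overlap, min(p, 1.0)
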