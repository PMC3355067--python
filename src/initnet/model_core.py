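"""Data model and I/O for constraint-based metabolic networks.

Provides the in-memory model types (metabolites, reactions, GPR trees),
stoichiometric-matrix assembly, and readers/writers for SBML (via cobra)
and a simple two-file TSV dialect:

* ``<stem>_reactions.tsv``: columns ``id``, ``equation``, ``gpr``,
  ``subsystem``; equations use ``=>`` (irreversible) or ``<=>``
  (reversible), e.g. ``a[c] + 2 b[c] => c[c]``.  An empty side denotes an
  exchange reaction.
* ``<stem>_metabolites.tsv``: columns ``id``, ``name``, ``compartment``,
  ``formula``.

Metabolite ids carry a ``[c]``-style compartment suffix in the TSV dialect;
ids are otherwise opaque strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import sparse

from .gpr import GPRNode, gpr_genes, gpr_to_string, parse_gpr

__all__ = [
    "COMPARTMENTS",
    "COMPARTMENT_TAGS",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "FormatError",
    "parse_formula",
    "format_formula",
    "stoichiometric_matrix",
    "read_model",
    "write_model",
]

#: The eight compartments of the compartmentalized human template.
COMPARTMENTS = (
    "nucleus",
    "cytosol",
    "er",
    "golgi",
    "peroxisome",
    "lysosome",
    "mitochondria",
    "extracellular",
)

#: Short tags used in ``[c]``-style id suffixes and SBML compartment ids.
COMPARTMENT_TAGS = {
    "nucleus": "n",
    "cytosol": "c",
    "er": "r",
    "golgi": "g",
    "peroxisome": "p",
    "lysosome": "l",
    "mitochondria": "m",
    "extracellular": "e",
}
_TAG_TO_COMPARTMENT = {v: k for k, v in COMPARTMENT_TAGS.items()}


class ModelValidationError(ValueError):
    pass


class FormatError(ValueError):
    pass


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse ``C6H12O6``-style elemental formulas into element→count maps."""
    if not formula:
        return {}
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise FormatError(f"malformed formula {formula!r}")
        element, digits = match.groups()
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        raise FormatError(f"malformed formula {formula!r}")
    return counts


def format_formula(counts: Dict[str, int]) -> str:
    parts = []
    for element in sorted(counts):
        n = counts[element]
        if n:
            parts.append(element + (str(n) if n != 1 else ""))
    return "".join(parts)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    formula: Optional[Dict[str, int]] = None
    external_ids: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.formula is not None:
            for element, count in self.formula.items():
                if not (isinstance(count, int) and count >= 0):
                    raise ModelValidationError(
                        f"metabolite {self.id!r}: bad count for element {element!r}"
                    )

    @property
    def is_extracellular(self) -> bool:
        return self.compartment == "extracellular"


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    reversible: bool = False
    gpr: Optional[GPRNode] = None
    subsystem: Optional[str] = None

    def __post_init__(self):
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        for met, coeff in self.stoichiometry.items():
            if coeff == 0:
                raise ModelValidationError(
                    f"reaction {self.id!r}: zero coefficient for {met!r}"
                )

    @property
    def is_exchange(self) -> bool:
        """An exchange touches exactly one metabolite (system boundary)."""
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> set:
        return gpr_genes(self.gpr)

    @property
    def reactants(self) -> List[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> List[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class MetabolicModel:
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: List[str] = field(default_factory=list)
    id: str = "model"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        gene_set = set(self.genes)
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in known:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                    )
            missing = rxn.genes - gene_set
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} GPR references unknown genes {sorted(missing)}"
                )

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_map(self) -> Dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_map(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def internal_metabolites(self) -> List[Metabolite]:
        return [m for m in self.metabolites if not m.is_extracellular]

    @property
    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def non_exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if not r.is_exchange]

    def subset(self, reaction_ids, id: Optional[str] = None) -> "MetabolicModel":
        """Submodel keeping the given reactions and the metabolites they touch."""
        keep = set(reaction_ids)
        unknown = keep - {r.id for r in self.reactions}
        if unknown:
            raise ModelValidationError(f"unknown reaction ids: {sorted(unknown)}")
        reactions = [r for r in self.reactions if r.id in keep]
        used = set()
        for r in reactions:
            used |= set(r.stoichiometry)
        metabolites = [m for m in self.metabolites if m.id in used]
        genes = sorted(set().union(*(r.genes for r in reactions)) if reactions else set())
        return MetabolicModel(
            metabolites=metabolites,
            reactions=reactions,
            genes=genes,
            id=id or self.id,
        )


def stoichiometric_matrix(
    model: MetabolicModel, internal_only: bool = False
) -> Tuple[sparse.csr_matrix, List[str], List[str]]:
    """Assemble S as a sparse matrix with row/column id lists.

    Entry (j, i) is the signed coefficient of metabolite j in reaction i.
    With ``internal_only`` the extracellular rows are dropped.
    """
    mets = model.internal_metabolites if internal_only else model.metabolites
    met_ids = [m.id for m in mets]
    row_of = {m: j for j, m in enumerate(met_ids)}
    rxn_ids = [r.id for r in model.reactions]
    rows, cols, vals = [], [], []
    for i, rxn in enumerate(model.reactions):
        for met, coeff in rxn.stoichiometry.items():
            j = row_of.get(met)
            if j is not None:
                rows.append(j)
                cols.append(i)
                vals.append(float(coeff))
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids)), dtype=float
    )
    return S, met_ids, rxn_ids


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _format_side(items: List[Tuple[str, float]]) -> str:
    parts = []
    for met, coeff in items:
        coeff = abs(coeff)
        if coeff == 1:
            parts.append(met)
        else:
            text = f"{coeff:g}"
            parts.append(f"{text} {met}")
        parts.append("+")
    return " ".join(parts[:-1]) if parts else ""


def _equation_string(rxn: Reaction) -> str:
    lhs = _format_side([(m, c) for m, c in rxn.stoichiometry.items() if c < 0])
    rhs = _format_side([(m, c) for m, c in rxn.stoichiometry.items() if c > 0])
    arrow = "<=>" if rxn.reversible else "=>"
    return f"{lhs} {arrow} {rhs}".strip()


_NUM_RE = re.compile(r"^\d+(\.\d+)?$")


def _parse_side(text: str, sign: int, stoich: Dict[str, float], rxn_id: str) -> None:
    text = text.strip()
    if not text:
        return
    for term in text.split("+"):
        tokens = term.strip().split()
        if len(tokens) == 1:
            coeff, met = 1.0, tokens[0]
        elif len(tokens) == 2 and _NUM_RE.match(tokens[0]):
            coeff, met = float(tokens[0]), tokens[1]
        else:
            raise FormatError(f"reaction {rxn_id!r}: cannot parse term {term.strip()!r}")
        stoich[met] = stoich.get(met, 0.0) + sign * coeff


def parse_equation(equation: str, rxn_id: str = "?") -> Tuple[Dict[str, float], bool]:
    if "<=>" in equation:
        lhs, rhs = equation.split("<=>", 1)
        reversible = True
    elif "=>" in equation:
        lhs, rhs = equation.split("=>", 1)
        reversible = False
    else:
        raise FormatError(f"reaction {rxn_id!r}: no arrow in equation {equation!r}")
    stoich: Dict[str, float] = {}
    _parse_side(lhs, -1, stoich, rxn_id)
    _parse_side(rhs, +1, stoich, rxn_id)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise FormatError(f"reaction {rxn_id!r}: empty equation {equation!r}")
    return stoich, reversible


def _tsv_paths(path) -> Tuple[Path, Path]:
    path = Path(path)
    stem = path.parent / path.name.replace(".tsv", "")
    return (
        Path(f"{stem}_reactions.tsv"),
        Path(f"{stem}_metabolites.tsv"),
    )


def _read_tsv(path) -> MetabolicModel:
    rxn_path, met_path = _tsv_paths(path)
    for p in (rxn_path, met_path):
        if not p.exists():
            raise FileNotFoundError(p)
    met_df = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
    rxn_df = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")
    metabolites = []
    for row in met_df.itertuples(index=False):
        formula = parse_formula(row.formula) if getattr(row, "formula", "") else None
        metabolites.append(
            Metabolite(
                id=row.id, name=row.name, compartment=row.compartment, formula=formula
            )
        )
    reactions = []
    for row in rxn_df.itertuples(index=False):
        stoich, reversible = parse_equation(row.equation, row.id)
        reactions.append(
            Reaction(
                id=row.id,
                stoichiometry=stoich,
                reversible=reversible,
                gpr=parse_gpr(getattr(row, "gpr", "")),
                subsystem=getattr(row, "subsystem", "") or None,
            )
        )
    genes = sorted(set().union(*(r.genes for r in reactions)) if reactions else set())
    name = Path(path).name.replace(".tsv", "")
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, genes=genes, id=name
    )


def _write_tsv(model: MetabolicModel, path) -> None:
    rxn_path, met_path = _tsv_paths(path)
    met_df = pd.DataFrame(
        {
            "id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
            "formula": [
                format_formula(m.formula) if m.formula is not None else ""
                for m in model.metabolites
            ],
        }
    )
    rxn_df = pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "equation": [_equation_string(r) for r in model.reactions],
            "gpr": [gpr_to_string(r.gpr) for r in model.reactions],
            "subsystem": [r.subsystem or "" for r in model.reactions],
        }
    )
    met_df.to_csv(met_path, sep="\t", index=False)
    rxn_df.to_csv(rxn_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML via cobra
# ---------------------------------------------------------------------------

_SBML_BOUND = 1000.0
_SID_OK_RE = re.compile(r"[A-Za-z0-9_]")


def _encode_sid(raw: str) -> str:
    """Encode arbitrary ids as valid SBML SIds (``[`` → ``__91__`` etc.)."""
    out = []
    for ch in raw:
        out.append(ch if _SID_OK_RE.match(ch) else f"__{ord(ch)}__")
    return "".join(out)


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(_encode_sid(model.id))
    cmets = {}
    for met in model.metabolites:
        c = cobra.Metabolite(
            _encode_sid(met.id),
            name=met.name,
            compartment=COMPARTMENT_TAGS[met.compartment],
            formula=format_formula(met.formula) if met.formula is not None else None,
        )
        for db, ident in met.external_ids.items():
            c.annotation[db] = ident
        cmets[met.id] = c
    crxns = []
    for rxn in model.reactions:
        c = cobra.Reaction(_encode_sid(rxn.id))
        c.add_metabolites({cmets[m]: coeff for m, coeff in rxn.stoichiometry.items()})
        c.bounds = (-_SBML_BOUND if rxn.reversible else 0.0, _SBML_BOUND)
        if rxn.subsystem:
            c.subsystem = rxn.subsystem
        crxns.append(c)
    cm.add_reactions(crxns)
    # gene_reaction_rule must be set after add_reactions so genes register
    for rxn, c in zip(model.reactions, crxns):
        rule = gpr_to_string(rxn.gpr)
        if rule:
            c.gene_reaction_rule = rule
    return cm


def _from_cobra(cm) -> MetabolicModel:
    metabolites = []
    for cmet in cm.metabolites:
        compartment = _TAG_TO_COMPARTMENT.get(cmet.compartment)
        if compartment is None:
            raise FormatError(
                f"metabolite {cmet.id!r}: unknown compartment tag {cmet.compartment!r}"
            )
        formula = parse_formula(cmet.formula) if cmet.formula else None
        external = {
            db: v if isinstance(v, str) else v[0]
            for db, v in cmet.annotation.items()
            if db != "sbo"
        }
        metabolites.append(
            Metabolite(
                id=cmet.id,
                name=cmet.name or "",
                compartment=compartment,
                formula=formula,
                external_ids=external,
            )
        )
    reactions = []
    for crxn in cm.reactions:
        stoich = {m.id: float(c) for m, c in crxn.metabolites.items()}
        reactions.append(
            Reaction(
                id=crxn.id,
                stoichiometry=stoich,
                reversible=crxn.lower_bound < 0,
                gpr=parse_gpr(crxn.gene_reaction_rule),
                subsystem=crxn.subsystem or None,
            )
        )
    genes = sorted(set().union(*(r.genes for r in reactions)) if reactions else set())
    return MetabolicModel(
        metabolites=metabolites, reactions=reactions, genes=genes, id=cm.id
    )


def _read_sbml(path) -> MetabolicModel:
    import logging

    import cobra

    logging.getLogger("cobra").setLevel(logging.ERROR)
    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises CobraSBMLError on parse failure
        raise FormatError(f"cannot parse SBML file {path}: {exc}") from exc
    try:
        return _from_cobra(cm)
    except ModelValidationError:
        raise
    except FormatError:
        raise


def _write_sbml(model: MetabolicModel, path) -> None:
    import cobra

    cobra.io.write_sbml_model(_to_cobra(model), str(path))


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def _infer_format(path, format: Optional[str]) -> str:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".tsv":
        return "tsv"
    raise FormatError(f"cannot infer format from {path}; pass format=...")


def read_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Read a model from SBML or the TSV dialect; validates on load."""
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        return _read_sbml(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise FormatError(f"unknown format {fmt!r}")


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "tsv":
        _write_tsv(model, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
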