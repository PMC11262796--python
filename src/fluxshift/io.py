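"""Model input/output: SBML reading and the native two-table text format.

Two SBML dialects are accepted for gene associations: the modern L3 ``fbc``
gene-product associations and the legacy ``GENE_ASSOCIATION:`` notes field
used by older COBRA-style files.  Which dialect supplied the rules is logged
in the model's provenance.

The native format is two UTF-8 tab-separated tables, designed to round-trip
a model exactly (ids, stoichiometry, bounds, GPR strings):

``reactions.tsv``
    columns ``id  equation  lb  ub  gpr  subsystem``; the equation string is
    ``coef met + coef met <=> coef met ...`` with either side possibly empty
    (exchange reactions).
``metabolites.tsv``
    columns ``id  compartment  name``.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Tuple, Union

import libsbml

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
)

__all__ = [
    "SBMLFormatError",
    "NativeFormatError",
    "read_sbml",
    "read_native",
    "write_native",
    "format_equation",
    "parse_equation",
]

ARROW = "<=>"


class SBMLFormatError(ValueError):
    """SBML file could not be parsed into a valid model."""


class NativeFormatError(ValueError):
    """Native-format table is malformed; message carries the line number."""


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _fbc_association_to_gpr(assoc) -> str:
    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return assoc.getGeneProduct()
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [
            _fbc_association_to_gpr(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [
            _fbc_association_to_gpr(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    raise SBMLFormatError(f"unsupported fbc association node: {assoc}")


def _notes_gpr(reaction) -> str:
    notes = reaction.getNotesString() if reaction.isSetNotes() else ""
    for line in notes.splitlines():
        text = line.strip()
        # strip surrounding html tags like <p>...</p> or <html:p>
        while text.startswith("<") and ">" in text:
            text = text[text.index(">") + 1 :].strip()
        while text.endswith(">") and "<" in text:
            text = text[: text.rindex("<")].strip()
        for key in ("GENE_ASSOCIATION:", "GENE ASSOCIATION:"):
            if text.upper().startswith(key):
                return text[len(key) :].strip()
    return ""


def _reaction_bounds(reaction, sbml_model) -> Tuple[float, float]:
    fbc_r = reaction.getPlugin("fbc")
    if fbc_r is not None and (
        fbc_r.isSetLowerFluxBound() or fbc_r.isSetUpperFluxBound()
    ):
        def param_value(pid, default):
            p = sbml_model.getParameter(pid) if pid else None
            return p.getValue() if p is not None else default

        lb = param_value(
            fbc_r.getLowerFluxBound() if fbc_r.isSetLowerFluxBound() else "",
            -DEFAULT_BOUND,
        )
        ub = param_value(
            fbc_r.getUpperFluxBound() if fbc_r.isSetUpperFluxBound() else "",
            DEFAULT_BOUND,
        )
        return lb, ub
    # legacy: kinetic-law parameters
    kl = reaction.getKineticLaw()
    if kl is not None:
        lb = ub = None
        for i in range(kl.getNumParameters()):
            p = kl.getParameter(i)
            if p.getId() == "LOWER_BOUND":
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND":
                ub = p.getValue()
        if lb is not None or ub is not None:
            rev_default = -DEFAULT_BOUND if reaction.getReversible() else 0.0
            return (lb if lb is not None else rev_default,
                    ub if ub is not None else DEFAULT_BOUND)
    if reaction.getReversible():
        return -DEFAULT_BOUND, DEFAULT_BOUND
    return 0.0, DEFAULT_BOUND


def read_sbml(path: Union[str, os.PathLike]) -> MetabolicModel:
    """Read an SBML (L2 or L3, with or without fbc) file into a model.

    Bounds missing from the file default to ±1000 for reversible reactions
    and [0, 1000] for irreversible ones.  GPRs are taken from fbc
    gene-product associations when present, otherwise from the
    ``GENE_ASSOCIATION`` notes field.
    """
    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLFormatError(
            f"{path}: SBML parse error at line {err.getLine()}: "
            f"{err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLFormatError(f"{path}: file contains no <model> element")

    metabolites = []
    species_ids = set()
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are outside the mass balance
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                compartment=sp.getCompartment() or "c",
                name=sp.getName() or "",
            )
        )
        species_ids.add(sp.getId())

    fbc_plugin = sbml_model.getPlugin("fbc")
    gene_dialects = set()
    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            sid = ref.getSpecies()
            if not sbml_model.getSpecies(sid):
                raise SBMLFormatError(
                    f"{path}: reaction {rx.getId()!r} references undeclared "
                    f"species {sid!r}"
                )
            if sid in species_ids:
                stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            sid = ref.getSpecies()
            if not sbml_model.getSpecies(sid):
                raise SBMLFormatError(
                    f"{path}: reaction {rx.getId()!r} references undeclared "
                    f"species {sid!r}"
                )
            if sid in species_ids:
                stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()

        gpr = ""
        fbc_r = rx.getPlugin("fbc")
        if fbc_r is not None and fbc_r.getGeneProductAssociation() is not None:
            gpr = _fbc_association_to_gpr(
                fbc_r.getGeneProductAssociation().getAssociation()
            )
            gene_dialects.add("fbc")
        else:
            gpr = _notes_gpr(rx)
            if gpr:
                gene_dialects.add("notes")
        # fbc gene products may use labels distinct from ids; map ids -> labels
        lb, ub = _reaction_bounds(rx, sbml_model)
        reactions.append(
            Reaction(id=rx.getId(), stoich=stoich, lb=lb, ub=ub, gpr=gpr)
        )

    objective = None
    if fbc_plugin is not None and fbc_plugin.getNumObjectives() > 0:
        obj = fbc_plugin.getActiveObjective() or fbc_plugin.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            objective = obj.getFluxObjective(0).getReaction()

    try:
        model = MetabolicModel(
            metabolites=metabolites, reactions=reactions, objective=objective
        )
    except ModelValidationError as exc:
        raise SBMLFormatError(f"{path}: {exc}") from exc
    model.log(f"read_sbml: {path.name}, level {sbml_model.getLevel()}")
    model.log(
        "read_sbml: gene rules from "
        + (", ".join(sorted(gene_dialects)) if gene_dialects else "none")
    )
    return model


# ---------------------------------------------------------------------------
# native format
# ---------------------------------------------------------------------------

def format_equation(reaction: Reaction) -> str:
    """Render stoichiometry as ``a A + b B <=> c C``; empty sides allowed."""
    lhs, rhs = [], []
    for mid in sorted(reaction.stoich):
        coef = reaction.stoich[mid]
        side = lhs if coef < 0 else rhs
        mag = abs(coef)
        term = mid if mag == 1 else f"{mag:g} {mid}"
        side.append(term)
    return f"{' + '.join(lhs)} {ARROW} {' + '.join(rhs)}".strip()


def parse_equation(text: str) -> Dict[str, float]:
    if ARROW not in text:
        raise NativeFormatError(f"equation missing {ARROW!r} arrow: {text!r}")
    lhs_text, rhs_text = text.split(ARROW, 1)
    stoich: Dict[str, float] = {}

    def add_side(side_text: str, sign: float) -> None:
        side_text = side_text.strip()
        if not side_text:
            return
        for term in side_text.split(" + "):
            parts = term.strip().split()
            if len(parts) == 1:
                coef, mid = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError as exc:
                    raise NativeFormatError(
                        f"bad coefficient in equation term {term!r}"
                    ) from exc
                mid = parts[1]
            else:
                raise NativeFormatError(f"malformed equation term: {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add_side(lhs_text, -1.0)
    add_side(rhs_text, +1.0)
    return stoich


_REACTION_COLUMNS = ["id", "equation", "lb", "ub", "gpr", "subsystem"]
_METABOLITE_COLUMNS = ["id", "compartment", "name"]


def write_native(model: MetabolicModel, directory: Union[str, os.PathLike]) -> Path:
    """Write ``reactions.tsv`` and ``metabolites.tsv`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "metabolites.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_METABOLITE_COLUMNS) + "\n")
        for m in model.metabolites:
            fh.write(f"{m.id}\t{m.compartment}\t{m.name}\n")
    with open(directory / "reactions.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(_REACTION_COLUMNS) + "\n")
        for r in model.reactions:
            fh.write(
                f"{r.id}\t{format_equation(r)}\t{r.lb:.10g}\t{r.ub:.10g}"
                f"\t{r.gpr}\t{r.subsystem}\n"
            )
    return directory


def _read_table(path: Path, columns: List[str]) -> List[Dict[str, str]]:
    if not path.exists():
        raise NativeFormatError(f"missing table: {path}")
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in columns if c not in header]
        if missing:
            raise NativeFormatError(
                f"{path}, line 1: missing required columns {missing}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise NativeFormatError(
                    f"{path}, line {lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            rows.append(dict(zip(header, fields)))
    return rows


def read_native(directory: Union[str, os.PathLike]) -> MetabolicModel:
    """Read a model written by :func:`write_native`; exact round trip."""
    directory = Path(directory)
    met_rows = _read_table(directory / "metabolites.tsv", _METABOLITE_COLUMNS)
    rxn_rows = _read_table(directory / "reactions.tsv", _REACTION_COLUMNS)
    metabolites = [
        Metabolite(id=row["id"], compartment=row["compartment"], name=row["name"])
        for row in met_rows
    ]
    reactions = []
    for lineno, row in enumerate(rxn_rows, start=2):
        try:
            stoich = parse_equation(row["equation"])
            lb, ub = float(row["lb"]), float(row["ub"])
        except (NativeFormatError, ValueError) as exc:
            raise NativeFormatError(
                f"{directory / 'reactions.tsv'}, line {lineno}: {exc}"
            ) from exc
        reactions.append(
            Reaction(
                id=row["id"],
                stoich=stoich,
                lb=lb,
                ub=ub,
                gpr=row["gpr"],
                subsystem=row["subsystem"],
            )
        )
    model = MetabolicModel(metabolites=metabolites, reactions=reactions)
    model.log(f"read_native: {directory}")
    return model
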