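"""Data model and I/O for SBGN-style disease maps.

A disease map is stored here as a :class:`RegulatoryMap`: a set of species
(proteins, genes, RNAs, complexes, phenotypes, degradation sinks) joined by
signed reactions (state transitions, complex associations, dissociations,
transports, unknown transitions, logical activations).  Two file views are
supported: a SIF-like signed edge table (CSV/TSV) and CellDesigner-dialect
SBML.  The two views of a published map may disagree on node counts (complex
expansion, phenotype handling differ between tools); they are treated as
independent inputs with independent censuses.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

SPECIES_KINDS = ("protein", "gene", "rna", "complex", "phenotype", "degradation", "unknown")
COMPARTMENTS = ("cytoplasm", "nucleus", "extracellular", "membrane")
INTERACTION_CATEGORIES = (
    "state_transition",
    "complex_association",
    "dissociation",
    "transport",
    "unknown_transition",
    "logical_activation",
)
SIGNS = ("activation", "inhibition", "neutral")

#: Documented mapping from sign tokens found in files to the canonical sign
#: vocabulary.  Unknown tokens fail loudly: a silently flipped sign corrupts
#: every downstream Boolean rule.
SIGN_TOKENS = {
    "activation": "activation",
    "activate": "activation",
    "activates": "activation",
    "positive": "activation",
    "positive_influence": "activation",
    "state_transition": "activation",
    "transcription": "activation",
    "translation": "activation",
    "catalysis": "activation",
    "trigger": "activation",
    "physical_stimulation": "activation",
    "1": "activation",
    "+": "activation",
    "->": "activation",
    "inhibition": "inhibition",
    "inhibit": "inhibition",
    "inhibits": "inhibition",
    "negative": "inhibition",
    "negative_influence": "inhibition",
    "unknown_negative_influence": "inhibition",
    "repression": "inhibition",
    "-1": "inhibition",
    "-": "inhibition",
    "-|": "inhibition",
    "neutral": "neutral",
    "transport": "neutral",
    "translocation": "neutral",
    "dissociation": "neutral",
    "0": "neutral",
}


class MapFormatError(ValueError):
    """Raised when an input file violates the map format contract."""


class MapParseError(MapFormatError):
    """Raised when an input file is not even well-formed (XML etc.)."""


@dataclass(frozen=True)
class SpeciesNode:
    """One molecular entity (or phenotype / sink) of a disease map."""

    id: str
    name: str = ""
    kind: str = "unknown"
    compartment: str = "cytoplasm"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("species id must be non-empty")
        if self.kind not in SPECIES_KINDS:
            raise ValueError(f"unknown species kind {self.kind!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class Interaction:
    """One signed reaction: sources act on a single target."""

    id: str
    sources: tuple[str, ...]
    target: str
    category: str = "state_transition"
    sign: str = "activation"
    mechanism_note: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("interaction id must be non-empty")
        if not self.sources:
            raise ValueError(f"interaction {self.id}: needs at least one source")
        if self.category not in INTERACTION_CATEGORIES:
            raise ValueError(f"interaction {self.id}: unknown category {self.category!r}")
        if self.sign not in SIGNS:
            raise ValueError(f"interaction {self.id}: unknown sign {self.sign!r}")
        object.__setattr__(self, "sources", tuple(self.sources))


@dataclass
class RegulatoryMap:
    """Species plus signed reactions of a disease map."""

    species: list[SpeciesNode] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)
    provenance: str = ""

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_interactions(self) -> int:
        return len(self.interactions)

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_by_id(self) -> dict[str, SpeciesNode]:
        return {s.id: s for s in self.species}

    def regulators_of(self, target: str) -> list[Interaction]:
        return [i for i in self.interactions if i.target == target]

    def copy(self) -> "RegulatoryMap":
        return RegulatoryMap(list(self.species), list(self.interactions), self.provenance)


@dataclass
class MapSummary:
    """Census of a map: totals plus per-kind and per-category tallies."""

    n_species: int
    n_interactions: int
    species_by_kind: dict[str, int]
    interactions_by_category: dict[str, int]
    n_compartments: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


@dataclass(frozen=True)
class ValidationIssue:
    rule: str
    offender: str
    message: str


# ---------------------------------------------------------------------------
# edge-table I/O


@dataclass(frozen=True)
class EdgeTableDialect:
    """Column-name configuration for SIF-like edge tables."""

    source: str = "source"
    sign: str = "sign"
    target: str = "target"
    kind: str = "kind"
    compartment: str = "compartment"


def _canonical_sign(token: str, row_no: int) -> str:
    key = token.strip().lower()
    if key not in SIGN_TOKENS:
        raise MapFormatError(f"row {row_no}: unresolvable sign token {token!r}")
    return SIGN_TOKENS[key]


def read_edge_table(
    path: str | Path,
    dialect: EdgeTableDialect | None = None,
    sep: str | None = None,
) -> RegulatoryMap:
    """Read a signed edge table into a :class:`RegulatoryMap`.

    One species per distinct endpoint label, one interaction per row.  The
    sign column is mapped through :data:`SIGN_TOKENS`; unknown tokens raise
    :class:`MapFormatError` with the offending row number.
    """
    path = Path(path)
    dialect = dialect or EdgeTableDialect()
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".sif") else ","
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None:
            raise MapFormatError(f"{path}: empty file, no header row")
        for col in (dialect.source, dialect.sign, dialect.target):
            if col not in reader.fieldnames:
                raise MapFormatError(f"{path}: missing mandatory column {col!r}")
        has_kind = dialect.kind in reader.fieldnames
        has_comp = dialect.compartment in reader.fieldnames

        species: dict[str, SpeciesNode] = {}
        interactions: list[Interaction] = []
        for row_no, row in enumerate(reader, start=2):  # 1 = header line
            src = (row[dialect.source] or "").strip()
            tgt = (row[dialect.target] or "").strip()
            if not src:
                raise MapFormatError(f"row {row_no}: blank source")
            sign_token = (row[dialect.sign] or "").strip()
            if not tgt and not sign_token:
                # species-only row: declares an isolated node
                kind = (row.get(dialect.kind) or "unknown").strip() if has_kind else "unknown"
                comp = (row.get(dialect.compartment) or "cytoplasm").strip() if has_comp else "cytoplasm"
                if kind not in SPECIES_KINDS:
                    kind = "unknown"
                if comp not in COMPARTMENTS:
                    comp = "cytoplasm"
                species.setdefault(src, SpeciesNode(src, src, kind, comp))
                continue
            if not tgt:
                raise MapFormatError(f"row {row_no}: blank target")
            sign = _canonical_sign(row[dialect.sign] or "", row_no)
            for label in (src, tgt):
                if label not in species:
                    kind = (row.get(dialect.kind) or "unknown").strip() if has_kind else "unknown"
                    comp = (
                        (row.get(dialect.compartment) or "cytoplasm").strip()
                        if has_comp
                        else "cytoplasm"
                    )
                    # kind/compartment columns describe the *target* on most
                    # exports; only trust them for the target endpoint.
                    if label == tgt and kind in SPECIES_KINDS and comp in COMPARTMENTS:
                        species[label] = SpeciesNode(label, label, kind, comp)
                    else:
                        species.setdefault(label, SpeciesNode(label, label))
            if has_kind:
                # upgrade a previously defaulted target node
                kind = (row.get(dialect.kind) or "").strip()
                if kind in SPECIES_KINDS and species[tgt].kind == "unknown" and kind != "unknown":
                    species[tgt] = replace(species[tgt], kind=kind)
            interactions.append(
                Interaction(
                    id=f"e{row_no - 1}",
                    sources=(src,),
                    target=tgt,
                    category="state_transition",
                    sign=sign,
                )
            )
    return RegulatoryMap(list(species.values()), interactions, provenance=str(path))


def write_edge_table(map_: RegulatoryMap, path: str | Path, sep: str = ",") -> Path:
    """Write the map as a signed edge table, one row per (source, target).

    Rows are sorted by interaction id (natural order of the id string) so two
    writes of the same map are byte-identical.
    """
    path = Path(path)
    kinds = {s.id: s for s in map_.species}
    covered = {e for i in map_.interactions for e in (*i.sources, i.target)}
    rows = []
    # isolated species first, as species-only rows (blank sign and target)
    for s in sorted(map_.species, key=lambda s: s.id):
        if s.id not in covered:
            rows.append((s.id, "", "", s.kind, s.compartment))
    for inter in sorted(map_.interactions, key=lambda i: i.id):
        for src in inter.sources:
            tgt = kinds.get(inter.target)
            rows.append(
                (
                    src,
                    inter.sign,
                    inter.target,
                    tgt.kind if tgt else "unknown",
                    tgt.compartment if tgt else "cytoplasm",
                )
            )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(["source", "sign", "target", "kind", "compartment"])
        writer.writerows(rows)
    return path


# ---------------------------------------------------------------------------
# CellDesigner-dialect SBML


_CD_CLASS_TO_KIND = {
    "PROTEIN": "protein",
    "RECEPTOR": "protein",
    "ION_CHANNEL": "protein",
    "TRUNCATED": "protein",
    "GENERIC": "protein",
    "GENE": "gene",
    "RNA": "rna",
    "ANTISENSE_RNA": "rna",
    "COMPLEX": "complex",
    "PHENOTYPE": "phenotype",
    "DEGRADED": "degradation",
    "UNKNOWN": "unknown",
    "DRUG": "unknown",
    "ION": "unknown",
    "SIMPLE_MOLECULE": "unknown",
}

_CD_REACTION_TO_CATEGORY = {
    "STATE_TRANSITION": "state_transition",
    "KNOWN_TRANSITION_OMITTED": "state_transition",
    "TRANSCRIPTION": "state_transition",
    "TRANSLATION": "state_transition",
    "HETERODIMER_ASSOCIATION": "complex_association",
    "DISSOCIATION": "dissociation",
    "TRUNCATION": "dissociation",
    "TRANSPORT": "transport",
    "TRANSLOCATION": "transport",
    "UNKNOWN_TRANSITION": "unknown_transition",
    "UNKNOWN_POSITIVE_INFLUENCE": "unknown_transition",
    "UNKNOWN_NEGATIVE_INFLUENCE": "unknown_transition",
    "REDUCED_PHYSICAL_STIMULATION": "logical_activation",
    "PHYSICAL_STIMULATION": "logical_activation",
    "POSITIVE_INFLUENCE": "logical_activation",
    "NEGATIVE_INFLUENCE": "logical_activation",
    "TRIGGER": "logical_activation",
    "INHIBITION": "state_transition",
}

_CD_NEGATIVE_REACTIONS = {
    "INHIBITION",
    "NEGATIVE_INFLUENCE",
    "UNKNOWN_NEGATIVE_INFLUENCE",
    "UNKNOWN_INHIBITION",
}

_COMPARTMENT_ALIASES = {
    "cytoplasm": "cytoplasm",
    "cytosol": "cytoplasm",
    "default": "cytoplasm",
    "nucleus": "nucleus",
    "extracellular": "extracellular",
    "extracellular_space": "extracellular",
    "membrane": "membrane",
    "plasma_membrane": "membrane",
}


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


def _first_text(parent: etree._Element, localname: str) -> str | None:
    for el in parent.iter():
        if _localname(el) == localname:
            return el.text
    return None


def read_celldesigner_sbml(path: str | Path) -> RegulatoryMap:
    """Read a CellDesigner-dialect SBML file into a :class:`RegulatoryMap`.

    Species kind comes from the CellDesigner ``class`` annotation when
    present (plain SBML degrades to ``unknown``).  Each SBML reaction becomes
    one interaction: reactants are the sources, the first product the target,
    the reaction-type annotation sets category and sign.  Reactions without
    reactants fall back to their modifiers as sources.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise MapParseError(f"{path}: not well-formed XML ({exc})") from exc
    root = tree.getroot()
    if _localname(root) != "sbml":
        raise MapFormatError(f"{path}: root element is not <sbml>")

    compartments: dict[str, str] = {}
    for el in root.iter():
        if _localname(el) == "compartment":
            cid = el.get("id", "")
            name = (el.get("name") or cid).strip().lower().replace(" ", "_")
            compartments[cid] = _COMPARTMENT_ALIASES.get(name, "cytoplasm")

    species: dict[str, SpeciesNode] = {}
    for el in root.iter():
        if _localname(el) != "species":
            continue
        sid = el.get("id")
        if sid is None:
            continue
        cd_class = _first_text(el, "class")
        kind = _CD_CLASS_TO_KIND.get((cd_class or "").strip().upper(), "unknown")
        comp = compartments.get(el.get("compartment", ""), "cytoplasm")
        species[sid] = SpeciesNode(sid, el.get("name") or sid, kind, comp)
    if not species:
        raise MapFormatError(f"{path}: SBML model declares no species")

    interactions: list[Interaction] = []
    for el in root.iter():
        if _localname(el) != "reaction":
            continue
        rid = el.get("id") or f"re{len(interactions) + 1}"
        sources: list[str] = []
        products: list[str] = []
        modifiers: list[str] = []
        for sub in el.iter():
            ln = _localname(sub)
            if ln == "speciesReference" or ln == "modifierSpeciesReference":
                ref = sub.get("species")
                if ref is None:
                    continue
                parent = sub.getparent()
                pname = _localname(parent) if parent is not None else ""
                if pname == "listOfReactants":
                    sources.append(ref)
                elif pname == "listOfProducts":
                    products.append(ref)
                elif pname == "listOfModifiers":
                    modifiers.append(ref)
        rtype = (_first_text(el, "reactionType") or "STATE_TRANSITION").strip().upper()
        category = _CD_REACTION_TO_CATEGORY.get(rtype, "state_transition")
        if not sources:
            sources = modifiers
        if not sources or not products:
            continue  # boundary production/consumption carries no regulation
        if rtype in _CD_NEGATIVE_REACTIONS:
            sign = "inhibition"
        elif category in ("transport", "dissociation"):
            sign = "neutral"
        else:
            sign = "activation"
        for ref in sources + products:
            if ref not in species:
                raise MapFormatError(f"{path}: reaction {rid} references undeclared species {ref}")
        interactions.append(
            Interaction(
                id=rid,
                sources=tuple(sources),
                target=products[0],
                category=category,
                sign=sign,
            )
        )
    return RegulatoryMap(list(species.values()), interactions, provenance=str(path))


# ---------------------------------------------------------------------------
# census and validation


def summarize_map(map_: RegulatoryMap) -> MapSummary:
    """Exact census of a map; unused kinds/categories tally as zero."""
    by_kind = {k: 0 for k in SPECIES_KINDS}
    for s in map_.species:
        by_kind[s.kind] += 1
    by_cat = {c: 0 for c in INTERACTION_CATEGORIES}
    for i in map_.interactions:
        by_cat[i.category] += 1
    return MapSummary(
        n_species=map_.n_species,
        n_interactions=map_.n_interactions,
        species_by_kind=by_kind,
        interactions_by_category=by_cat,
        n_compartments=len({s.compartment for s in map_.species}),
    )


def validate_map(map_: RegulatoryMap) -> list[ValidationIssue]:
    """Check type invariants; reports problems, never raises on content."""
    issues: list[ValidationIssue] = []
    seen_species: set[str] = set()
    for s in map_.species:
        if s.id in seen_species:
            issues.append(ValidationIssue("duplicate_species_id", s.id, f"species id {s.id!r} occurs more than once"))
        seen_species.add(s.id)
    seen_inter: set[str] = set()
    ids = {s.id for s in map_.species}
    for i in map_.interactions:
        if i.id in seen_inter:
            issues.append(ValidationIssue("duplicate_interaction_id", i.id, f"interaction id {i.id!r} occurs more than once"))
        seen_inter.add(i.id)
        for endpoint in (*i.sources, i.target):
            if endpoint not in ids:
                issues.append(
                    ValidationIssue(
                        "referential_integrity",
                        i.id,
                        f"interaction {i.id} references unknown species {endpoint!r}",
                    )
                )
        if i.category == "complex_association" and len(i.sources) < 2:
            issues.append(
                ValidationIssue("complex_arity", i.id, f"complex association {i.id} has fewer than 2 sources")
            )
        if i.category == "dissociation" and len(i.sources) != 1:
            issues.append(ValidationIssue("dissociation_arity", i.id, f"dissociation {i.id} must have exactly 1 source"))
        if i.sign == "neutral" and i.category not in ("transport", "dissociation"):
            issues.append(
                ValidationIssue("neutral_sign", i.id, f"interaction {i.id} is neutral but not transport/dissociation")
            )
    # phenotype sinks: phenotype nodes should have no outgoing reactions
    phenos = {s.id for s in map_.species if s.kind == "phenotype"}
    for i in map_.interactions:
        for src in i.sources:
            if src in phenos:
                issues.append(
                    ValidationIssue("phenotype_outgoing", src, f"phenotype {src} is a source of interaction {i.id}")
                )
    return issues
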