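"""Variant-mask grammar: parsing, harmonization, evaluation, and categorization.

A *mask* is a boolean filter over annotated variants, written as an infix
expression whose leaves are annotation atoms (consequence tokens, predictor
calls, score thresholds) and minor-allele-frequency tokens.  Masks select the
variants whose dosages are collapsed into a per-gene burden, so their exact
semantics — including how heterogeneous published definitions are harmonized
into one vocabulary — determine everything downstream.

Grammar
-------
``expr := term ('|' term)* ; term := factor ('&' factor)* ; factor := atom | '(' expr ')'``

``&`` binds tighter than ``|``.  Atom tokens:

* consequence tokens — ``stop_gained``, ``missense``, ``synonymous``, ... ;
  ``essential_splice`` is a macro for splice donor or acceptor.
* ``LoF_HC`` / ``LoF_LC`` — LOFTEE loss-of-function confidence.
* ``IMPACT_HIGH`` etc. — VEP impact class.
* ``indel`` — ref/alt length difference.
* categorical predictor calls — ``<Algorithm>_pred_<CALL>``
  (e.g. ``Polyphen2_HDIV_pred_D``).
* score thresholds — ``<Algorithm>_score_<x>`` / ``CADD_phred_<x>`` meaning
  *score at least x* on the native scale (``REVEL_score_0_55`` = REVEL >= 0.55).
* composite-score thresholds — ``combo_og25`` etc., composite score >= 0.25.
* MAF tokens — ``maf1`` = MAF < 1%, ``maf0_1`` = MAF < 0.1%,
  ``maf_gt_5`` = MAF > 5%; ``maf_le_*`` and reference-panel-prefixed MAF
  tokens are accepted on input and rewritten during normalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "And",
    "Or",
    "Node",
    "MaskParseError",
    "MaskEvaluationError",
    "MaskDefinition",
    "MaskCatalog",
    "VariantRecord",
    "parse_mask",
    "parse_expression",
    "serialize",
    "normalize_mask",
    "canonicalize",
    "evaluate_mask",
    "evaluate_expression",
    "dedupe_catalog",
    "categorize_mask",
    "truth_table_equivalent",
    "collect_atoms",
    "variants_to_frame",
    "CONSEQUENCES",
    "ANNOTATION_CLASSES",
    "MAXMAF_CLASSES",
]


# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "stop_lost",
        "frameshift",
        "splice_donor",
        "splice_acceptor",
        "splice_region",
        "missense",
        "synonymous",
        "inframe_indel",
        "start_retained",
        "stop_retained",
        "incomplete_terminal_codon",
        "other",
    }
)

#: consequence atoms counted as putative loss of function
PLOF_ATOMS = frozenset(
    {"stop_gained", "stop_lost", "frameshift", "splice_donor", "splice_acceptor",
     "essential_splice", "LoF_HC", "LoF_LC", "IMPACT_HIGH"}
)

#: consequence atoms that widen a mask beyond missense/pLoF/indel territory
BROAD_CODING_ATOMS = frozenset(
    {"synonymous", "splice_region", "start_retained", "stop_retained",
     "incomplete_terminal_codon", "other", "IMPACT_MODERATE", "IMPACT_LOW",
     "IMPACT_MODIFIER"}
)

IMPACTS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})

#: predictor algorithms with a numeric score column (column ``<name>_<kind>``)
SCORE_ALGORITHMS: Mapping[str, str] = {
    "REVEL": "score",
    "CADD": "phred",
    "MPC": "score",
    "PrimateAI": "score",
}

#: predictor algorithms with a categorical call column (column ``<name>_pred``)
CATEGORICAL_ALGORITHMS = frozenset(
    {"SIFT", "Polyphen2_HDIV", "Polyphen2_HVAR", "MutationTaster", "ClinVar"}
)

#: reference-panel prefixes on MAF tokens, rewritten to cohort MAF
_REF_PANEL_PREFIXES = ("gnomad_", "exac_", "esp_", "1kg_", "kg1_", "control_", "ref_")

ANNOTATION_CLASSES = ("pLoF", "damMis", "pLoFdamMis", "pLoFmis", "misIndels", "coding")
MAXMAF_CLASSES = ("common", "low-frequency", "rare", "ultra-rare")


class MaskParseError(ValueError):
    """Raised for unknown tokens or malformed mask expressions."""


class MaskEvaluationError(KeyError):
    """Raised when an atom references a predictor the annotation table lacks."""


# --------------------------------------------------------------------------
# AST
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    token: str


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]


Node = Union[Atom, And, Or]

_NUM_RE = r"\d+(?:_\d+)?"


def _parse_number(text: str) -> float:
    """Underscore-decimal numbers: ``0_55`` -> 0.55, ``20`` -> 20.0."""
    return float(text.replace("_", "."))


@dataclass(frozen=True)
class AtomSemantics:
    """Resolved meaning of an atom token."""

    kind: str  # consequence | essential_splice | lof | impact | indel |
    #            categorical | score | combo | maf_lt | maf_gt
    algorithm: str | None = None
    call: str | None = None
    threshold: float | None = None


def classify_token(token: str) -> AtomSemantics:
    """Resolve ``token`` to its semantics, or raise :class:`MaskParseError`."""
    if token in CONSEQUENCES:
        return AtomSemantics("consequence", call=token)
    if token == "essential_splice":
        return AtomSemantics("essential_splice")
    if token in ("LoF_HC", "LoF_LC"):
        return AtomSemantics("lof", call=token.split("_")[1])
    if token.startswith("IMPACT_"):
        impact = token[len("IMPACT_"):]
        if impact in IMPACTS:
            return AtomSemantics("impact", call=impact)
        raise MaskParseError(f"unknown impact token: {token!r}")
    if token == "indel":
        return AtomSemantics("indel")

    m = re.fullmatch(rf"combo_(og|pc|ic)(\d+)", token)
    if m:
        return AtomSemantics("combo", algorithm=f"combo_{m.group(1)}",
                             threshold=int(m.group(2)) / 100.0)
    m = re.fullmatch(rf"maf({_NUM_RE})", token)
    if m:
        return AtomSemantics("maf_lt", threshold=_parse_number(m.group(1)) / 100.0)
    m = re.fullmatch(rf"maf_gt_({_NUM_RE})", token)
    if m:
        return AtomSemantics("maf_gt", threshold=_parse_number(m.group(1)) / 100.0)

    for alg, kind in SCORE_ALGORITHMS.items():
        m = re.fullmatch(rf"{re.escape(alg)}_{kind}_({_NUM_RE})", token)
        if m:
            return AtomSemantics("score", algorithm=f"{alg}_{kind}",
                                 threshold=_parse_number(m.group(1)))
    for alg in CATEGORICAL_ALGORITHMS:
        m = re.fullmatch(rf"{re.escape(alg)}_pred_([A-Za-z]+)", token)
        if m:
            return AtomSemantics("categorical", algorithm=alg, call=m.group(1))

    raise MaskParseError(f"unknown atom token: {token!r}")


def _is_input_only_token(token: str) -> bool:
    """Tokens accepted by the parser but rewritten away by normalization."""
    if token in ("nonsynonymous", "splice"):
        return True
    if re.fullmatch(rf"maf_le_{_NUM_RE}", token):
        return True
    if re.fullmatch(rf"Polyphen2_pred_[A-Za-z]+", token):
        return True
    if any(token.startswith(p) for p in _REF_PANEL_PREFIXES):
        rest = token[token.index("_") + 1:]
        if re.fullmatch(rf"maf(?:_le|_gt)?_?{_NUM_RE}", rest):
            return True
    return False


# --------------------------------------------------------------------------
# Parser / serializer
# --------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|\||&|[A-Za-z0-9_.]+)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    out, pos = [], 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            rest = expression[pos:].strip()
            if not rest:
                break
            raise MaskParseError(
                f"cannot tokenize {rest[:20]!r} at position {pos}")
        out.append((m.group(1), m.start(1)))
        pos = m.end()
    return out


def parse_expression(expression: str) -> Node:
    """Parse a mask expression string into an AST.

    Unknown atoms raise :class:`MaskParseError` naming the token; unbalanced
    parentheses raise with the offending position.
    """
    tokens = _tokenize(expression)
    idx = 0

    def peek():
        return tokens[idx][0] if idx < len(tokens) else None

    def expr() -> Node:
        nonlocal idx
        parts = [term()]
        while peek() == "|":
            idx += 1
            parts.append(term())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def term() -> Node:
        nonlocal idx
        parts = [factor()]
        while peek() == "&":
            idx += 1
            parts.append(factor())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def factor() -> Node:
        nonlocal idx
        if idx >= len(tokens):
            raise MaskParseError(
                f"unexpected end of expression in {expression!r}")
        tok, pos = tokens[idx]
        if tok == "(":
            idx += 1
            inner = expr()
            if peek() != ")":
                raise MaskParseError(
                    f"unbalanced parenthesis at position {pos} in {expression!r}")
            idx += 1
            return inner
        if tok in ("|", "&", ")"):
            raise MaskParseError(
                f"unexpected {tok!r} at position {pos} in {expression!r}")
        idx += 1
        if not _is_input_only_token(tok):
            classify_token(tok)  # raises on unknown atoms
        return Atom(tok)

    node = expr()
    if idx != len(tokens):
        tok, pos = tokens[idx]
        raise MaskParseError(
            f"unexpected {tok!r} at position {pos} in {expression!r}")
    return node


def serialize(node: Node, *, _parent: str | None = None) -> str:
    """Render an AST back to the infix grammar with minimal parentheses."""
    if isinstance(node, Atom):
        return node.token
    if isinstance(node, Or):
        text = " | ".join(serialize(c, _parent="|") for c in node.children)
        return f"({text})" if _parent == "&" else text
    text = " & ".join(serialize(c, _parent="&") for c in node.children)
    return f"({text})" if _parent == "|" else text


def collect_atoms(node: Node) -> set[str]:
    if isinstance(node, Atom):
        return {node.token}
    out: set[str] = set()
    for child in node.children:
        out |= collect_atoms(child)
    return out


# --------------------------------------------------------------------------
# Normalization / canonical form
# --------------------------------------------------------------------------


def _rewrite_atom(token: str) -> Node:
    """Harmonization rewrites for tokens carried over from heterogeneous
    published definitions."""
    if token == "nonsynonymous":
        return Atom("missense")
    if token == "splice":
        return Or((Atom("splice_acceptor"), Atom("splice_donor")))
    m = re.fullmatch(r"Polyphen2_pred_([A-Za-z]+)", token)
    if m:  # unversioned PolyPhen2: include both HDIV and HVAR models
        call = m.group(1)
        return Or((Atom(f"Polyphen2_HDIV_pred_{call}"),
                   Atom(f"Polyphen2_HVAR_pred_{call}")))
    for prefix in _REF_PANEL_PREFIXES:
        if token.startswith(prefix):  # reference-panel MAF -> cohort MAF
            return _rewrite_atom(token[len(prefix):])
    m = re.fullmatch(rf"maf_le_({_NUM_RE})", token)
    if m:  # MAF <= t harmonized to MAF < t
        return Atom(f"maf{m.group(1)}")
    return Atom(token)


def _rewrite(node: Node) -> Node:
    if isinstance(node, Atom):
        return _rewrite_atom(node.token)
    cls = type(node)
    return cls(tuple(_rewrite(c) for c in node.children))


def canonicalize(node: Node) -> Node:
    """Flattened, lexicographically sorted n-ary AND/OR with duplicate leaves
    removed.  Logically equivalent expressions over the same atoms that differ
    only in ordering, grouping, or repetition share one canonical form."""
    if isinstance(node, Atom):
        return node
    cls = type(node)
    flat: list[Node] = []
    for child in node.children:
        child = canonicalize(child)
        if isinstance(child, cls):
            flat.extend(child.children)
        else:
            flat.append(child)
    seen: dict[str, Node] = {}
    for child in flat:
        seen.setdefault(serialize(child), child)
    ordered = tuple(seen[k] for k in sorted(seen))
    if len(ordered) == 1:
        return ordered[0]
    return cls(ordered)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant (coordinates 1-based, as in VCF)."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    lof_confidence: str = "none"  # HC | LC | none
    impact: str = "MODIFIER"
    predictor_categorical: Mapping[str, str] = field(default_factory=dict)
    predictor_scores: Mapping[str, float] = field(default_factory=dict)
    maf: float = 0.0
    mac: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf out of range: {self.maf}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence: {self.consequence!r}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def variants_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Flatten :class:`VariantRecord` objects into the annotation table."""
    rows = []
    for r in records:
        row: dict = {
            "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
            "ref": r.ref, "alt": r.alt, "gene": r.gene,
            "consequence": r.consequence, "is_indel": r.is_indel,
            "lof_confidence": r.lof_confidence, "impact": r.impact,
            "maf": r.maf, "mac": r.mac,
        }
        for alg, call in r.predictor_categorical.items():
            row[f"{alg}_pred"] = call
        for col, value in r.predictor_scores.items():
            row[col] = value
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MaskDefinition:
    mask_id: str
    predicate: Node
    source: str = ""

    @property
    def expression(self) -> str:
        return serialize(self.predicate)

    @property
    def category(self) -> tuple[str, str]:
        return categorize_mask(self)


@dataclass
class MaskCatalog:
    masks: list[MaskDefinition]

    def __post_init__(self) -> None:
        ids = [m.mask_id for m in self.masks]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate mask ids: {dup}")

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def get(self, mask_id: str) -> MaskDefinition:
        for m in self.masks:
            if m.mask_id == mask_id:
                return m
        raise KeyError(mask_id)

    @property
    def mask_ids(self) -> list[str]:
        return [m.mask_id for m in self.masks]

    def membership(self, variants: pd.DataFrame) -> pd.DataFrame:
        """masks x variants binary inclusion matrix."""
        data = {m.mask_id: evaluate_mask(m, variants) for m in self.masks}
        return pd.DataFrame(data, index=variants["variant_id"]).T.astype(int)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def parse_mask(expression: str, mask_id: str = "", source: str = "") -> MaskDefinition:
    return MaskDefinition(mask_id=mask_id, predicate=parse_expression(expression),
                          source=source)


def normalize_mask(mask: MaskDefinition) -> MaskDefinition:
    """Apply harmonization rewrites, then canonicalize.  Idempotent."""
    return replace(mask, predicate=canonicalize(_rewrite(mask.predicate)))


def _atom_vector(sem: AtomSemantics, token: str, variants: pd.DataFrame) -> np.ndarray:
    if sem.kind == "consequence":
        return (variants["consequence"] == sem.call).to_numpy()
    if sem.kind == "essential_splice":
        return variants["consequence"].isin(["splice_donor", "splice_acceptor"]).to_numpy()
    if sem.kind == "lof":
        return (variants["lof_confidence"] == sem.call).to_numpy()
    if sem.kind == "impact":
        return (variants["impact"] == sem.call).to_numpy()
    if sem.kind == "indel":
        return variants["is_indel"].fillna(False).to_numpy(dtype=bool)
    if sem.kind == "maf_lt":
        return (variants["maf"].to_numpy() < sem.threshold)
    if sem.kind == "maf_gt":
        return (variants["maf"].to_numpy() > sem.threshold)
    if sem.kind in ("score", "combo"):
        col = sem.algorithm
        if col not in variants.columns:
            raise MaskEvaluationError(
                f"annotation table has no column {col!r} required by atom {token!r}")
        vals = pd.to_numeric(variants[col], errors="coerce").to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            return vals >= sem.threshold  # NaN (missing score) -> False
    if sem.kind == "categorical":
        col = f"{sem.algorithm}_pred"
        if col not in variants.columns:
            raise MaskEvaluationError(
                f"annotation table has no column {col!r} required by atom {token!r}")
        return (variants[col] == sem.call).to_numpy()
    raise AssertionError(f"unhandled atom kind {sem.kind}")  # pragma: no cover


def evaluate_expression(node: Node, variants: pd.DataFrame) -> np.ndarray:
    """Vectorized evaluation of an AST over the annotation table.

    A score or categorical atom on a variant missing that predictor's value
    evaluates False: an unscored variant cannot satisfy a score threshold.
    """
    if isinstance(node, Atom):
        return _atom_vector(classify_token(node.token), node.token, variants)
    parts = [evaluate_expression(c, variants) for c in node.children]
    return np.logical_and.reduce(parts) if isinstance(node, And) \
        else np.logical_or.reduce(parts)


def evaluate_mask(mask: MaskDefinition, variants: pd.DataFrame) -> np.ndarray:
    return evaluate_expression(mask.predicate, variants)


def dedupe_catalog(catalog: MaskCatalog) -> MaskCatalog:
    """One representative per canonical form; merged provenance retained.

    Masks are normalized first, so textual variants of the same harmonized
    definition collapse.  The representative keeps the lexicographically
    smallest mask id of its class.
    """
    classes: dict[str, list[MaskDefinition]] = {}
    for mask in catalog:
        norm = normalize_mask(mask)
        classes.setdefault(norm.expression, []).append(norm)
    unique = []
    for members in classes.values():
        members.sort(key=lambda m: m.mask_id)
        rep = members[0]
        sources = sorted({m.source for m in members if m.source})
        unique.append(replace(rep, source=";".join(sources)))
    unique.sort(key=lambda m: m.mask_id)
    return MaskCatalog(unique)


def truth_table_equivalent(a: Node, b: Node, max_atoms: int = 20) -> bool:
    """Exhaustive logical equivalence over all assignments of the joint atom
    set (atoms treated as free boolean variables)."""
    atoms = sorted(collect_atoms(a) | collect_atoms(b))
    if len(atoms) > max_atoms:
        raise ValueError(f"too many atoms for truth-table check: {len(atoms)}")

    def ev(node: Node, assign: Mapping[str, bool]) -> bool:
        if isinstance(node, Atom):
            return assign[node.token]
        values = (ev(c, assign) for c in node.children)
        return all(values) if isinstance(node, And) else any(values)

    for bits in range(1 << len(atoms)):
        assign = {atom: bool(bits >> i & 1) for i, atom in enumerate(atoms)}
        if ev(a, assign) != ev(b, assign):
            return False
    return True


# ---- categorization -------------------------------------------------------


def _maxmaf_class(node: Node) -> str:
    thresholds = [classify_token(t).threshold for t in collect_atoms(node)
                  if classify_token(t).kind == "maf_lt"]
    if not thresholds:
        return "common"
    t = min(thresholds)
    if t <= 1e-4:
        return "ultra-rare"
    if t <= 1e-3:
        return "rare"
    if t <= 1e-2:
        return "low-frequency"
    return "common"


def _strip_maf(node: Node) -> Node | None:
    if isinstance(node, Atom):
        kind = classify_token(node.token).kind
        return None if kind in ("maf_lt", "maf_gt") else node
    kept = [c for c in (_strip_maf(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    return type(node)(tuple(kept))


def _branch_flags(branch: Node) -> dict:
    atoms = collect_atoms(branch)
    sems = {t: classify_token(t) for t in atoms}
    has_pred = any(s.kind in ("score", "combo", "categorical") for s in sems.values())
    return {
        "broad": bool(atoms & BROAD_CODING_ATOMS),
        "plof": bool(atoms & PLOF_ATOMS) and not (atoms - PLOF_ATOMS),
        "dam_mis": "missense" in atoms and has_pred,
        "plain_mis": "missense" in atoms and not has_pred,
        "indel": bool(atoms & {"inframe_indel", "indel"}),
    }


def _annotation_class(node: Node) -> str:
    stripped = _strip_maf(node)
    if stripped is None:
        return "coding"  # pure-MAF mask keeps every coding variant supplied
    branches = stripped.children if isinstance(stripped, Or) else (stripped,)
    flags = [_branch_flags(b) for b in branches]
    if any(f["broad"] for f in flags):
        return "coding"
    has_plof = any(f["plof"] for f in flags)
    has_dam = any(f["dam_mis"] for f in flags)
    has_plain = any(f["plain_mis"] for f in flags)
    has_indel = any(f["indel"] and not f["plof"] for f in flags)
    if has_plof and not (has_dam or has_plain or has_indel):
        return "pLoF"
    if has_dam and not has_plof and not has_plain and not has_indel:
        return "damMis"
    if has_plof and has_dam and not has_plain:
        return "pLoFdamMis"
    if has_plof and (has_plain or has_indel):
        return "pLoFmis"
    return "misIndels"


def categorize_mask(mask: MaskDefinition) -> tuple[str, str]:
    """(annotation_class, maxmaf_class) for a normalized mask.

    The maxMAF class comes from the tightest ``maf<`` token (none -> common);
    the annotation class from the leaf composition of the MAF-stripped
    predicate, with pLoF / damMis / pLoFdamMis / pLoFmis / misIndels / coding
    resolved in that precedence order.
    """
    node = canonicalize(_rewrite(mask.predicate))
    return _annotation_class(node), _maxmaf_class(node)
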