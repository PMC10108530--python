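"""Parsing and evaluation of KEGG-style metabolic module definitions.

A module definition is a boolean/sequential expression over KEGG Orthologs
(KOs, ``K#####``) following the KEGG flat-file DEFINITION convention:

* a **space** separates sequential reaction steps (logical AND along a route),
* a **comma** separates alternative branches (logical OR),
* ``+`` joins subunits of an enzyme complex (all required),
* ``-`` marks a non-essential component of a complex,
* ``--`` on its own is a reaction step with no KO assigned (a gap),
* parentheses group sub-expressions,
* an ``M#####`` token references another module, expanded in place.

*Pathwise completeness* of a definition, given the set of KOs annotated in a
genome, is the maximum over all alternative routes through the definition of
the mean per-step completeness along that route. An atomic step scores 1 if
its KO is annotated; an enzyme complex scores the fraction of its essential
subunits annotated (configurable to all-or-nothing); a gap step scores 0 by
default (configurable to be excluded from route length).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import ValidationError

__all__ = [
    "Atom",
    "Gap",
    "Complex",
    "NestedModule",
    "Alternatives",
    "Step",
    "ModuleDefinition",
    "GenomeAnnotations",
    "CompletenessPolicy",
    "ModuleParseError",
    "ModuleCycleError",
    "PathCapacityError",
    "parse_definition",
    "render",
    "enumerate_paths",
    "count_paths",
    "step_completeness",
    "pathwise_completeness",
    "completeness_matrix",
]

KO_RE = re.compile(r"K\d{5}")
MODULE_RE = re.compile(r"M\d{5}")


class ModuleParseError(ValueError):
    """Raised when a definition string cannot be parsed.

    Carries the character ``position`` (in the normalized definition) at
    which parsing failed, when known.
    """

    def __init__(self, message: str, position: Optional[int] = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ModuleCycleError(RuntimeError):
    """Nested module references form a cycle (or exceed the depth cap)."""


class PathCapacityError(RuntimeError):
    """The number of alternative routes exceeds the configured cap."""


# ---------------------------------------------------------------------------
# step algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """A single-KO reaction step."""

    ko: str


@dataclass(frozen=True)
class Gap:
    """A reaction step with no KO assigned (``--``)."""


@dataclass(frozen=True)
class Complex:
    """An enzyme complex; components are ``(ko, essential)`` pairs."""

    components: tuple  # tuple[tuple[str, bool], ...]

    def __post_init__(self):
        if len(self.components) < 2:
            raise ValidationError("a complex needs at least 2 components")
        if not any(essential for _, essential in self.components):
            raise ValidationError("a complex needs at least 1 essential component")

    @property
    def essential_kos(self) -> tuple:
        return tuple(ko for ko, essential in self.components if essential)


@dataclass(frozen=True)
class NestedModule:
    """A reference to another module, expanded in place during evaluation."""

    module_id: str


@dataclass(frozen=True)
class Alternatives:
    """Mutually exclusive branches; each branch is a sequence of steps."""

    branches: tuple  # tuple[tuple[Step, ...], ...]

    def __post_init__(self):
        if len(self.branches) < 2:
            raise ValidationError("alternatives need at least 2 branches")
        if any(len(b) == 0 for b in self.branches):
            raise ValidationError("alternative branches must be non-empty")


Step = Union[Atom, Gap, Complex, NestedModule, Alternatives]
AtomicStep = Union[Atom, Gap, Complex]


@dataclass(frozen=True)
class ModuleDefinition:
    """A parsed module definition: an ordered sequence of steps."""

    module_id: str
    steps: tuple  # tuple[Step, ...]
    raw_text: str = ""

    def __post_init__(self):
        if not MODULE_RE.fullmatch(self.module_id):
            raise ValidationError(f"bad module id {self.module_id!r} (want M#####)")
        if len(self.steps) == 0:
            raise ValidationError(f"{self.module_id}: definition has no steps")


@dataclass(frozen=True)
class GenomeAnnotations:
    """The set of KOs annotated in one genome, plus optional genome stats."""

    genome_id: str
    kos: frozenset
    genome_length_bp: Optional[int] = None
    completion_pct: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "kos", frozenset(k.upper() for k in self.kos))
        for ko in self.kos:
            if not KO_RE.fullmatch(ko):
                raise ValidationError(f"{self.genome_id}: bad KO accession {ko!r}")
        if self.genome_length_bp is not None and self.genome_length_bp < 0:
            raise ValidationError(f"{self.genome_id}: negative genome length")
        if self.completion_pct is not None and not 0 <= self.completion_pct <= 100:
            raise ValidationError(f"{self.genome_id}: completion_pct outside [0,100]")


@dataclass(frozen=True)
class CompletenessPolicy:
    """Evaluation knobs for pathwise completeness.

    complex_all_or_none
        Score a complex 1 only when every essential subunit is annotated,
        instead of the default fractional rule.
    exclude_gap_steps
        Drop ``--`` steps from route length instead of counting them as
        always-absent steps (the conservative default).
    path_cap
        Hard cap on the number of enumerated routes; exceeding it raises
        :class:`PathCapacityError` rather than silently truncating.
    max_nesting_depth
        Cap on recursive nested-module expansion.
    """

    complex_all_or_none: bool = False
    exclude_gap_steps: bool = False
    path_cap: int = 100_000
    max_nesting_depth: int = 10


DEFAULT_POLICY = CompletenessPolicy()


# ---------------------------------------------------------------------------
# tokenizer / parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"K\d{5}|M\d{5}|--|[(),+\-]| +")


def _tokenize(text: str):
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ModuleParseError(f"unknown token {text[pos:pos + 8]!r}", pos)
        tok = m.group(0)
        if tok[0] == " ":
            kind = "SPACE"
        elif tok == "--":
            kind = "GAP"
        elif tok[0] == "K":
            kind = "KO"
        elif tok[0] == "M":
            kind = "MOD"
        else:
            kind = tok
        tokens.append((kind, tok, pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens, text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise ModuleParseError("unexpected end of definition", len(self.text))
        self.i += 1
        return tok

    def _expect(self, kind: str):
        tok = self._peek()
        if tok is None or tok[0] != kind:
            pos = tok[2] if tok else len(self.text)
            raise ModuleParseError(f"expected {kind!r}", pos)
        return self._next()

    def parse_seq(self) -> list:
        steps = list(self.parse_alt())
        while True:
            tok = self._peek()
            if tok is None or tok[0] != "SPACE":
                return steps
            self._next()
            steps.extend(self.parse_alt())

    def parse_alt(self) -> list:
        branches = [self.parse_term()]
        while True:
            tok = self._peek()
            if tok is None or tok[0] != ",":
                break
            self._next()
            branches.append(self.parse_term())
        if len(branches) == 1:
            return branches[0]
        return [Alternatives(tuple(tuple(b) for b in branches))]

    def parse_term(self) -> list:
        tok = self._peek()
        if tok is None:
            raise ModuleParseError("unexpected end of definition", len(self.text))
        kind, value, pos = tok
        if kind == "(":
            self._next()
            steps = self.parse_seq()
            self._expect(")")
            after = self._peek()
            if after is not None and after[0] in ("+", "-"):
                raise ModuleParseError(
                    "parenthesized groups cannot be complex components", after[2]
                )
            return steps
        if kind == "GAP":
            self._next()
            return [Gap()]
        if kind == "MOD":
            self._next()
            return [NestedModule(value)]
        if kind == "KO":
            self._next()
            components = [(value, True)]
            while True:
                after = self._peek()
                if after is None or after[0] not in ("+", "-"):
                    break
                sign = self._next()
                unit = self._peek()
                if unit is None or unit[0] != "KO":
                    upos = unit[2] if unit else len(self.text)
                    raise ModuleParseError(
                        "complex components must be KO accessions", upos
                    )
                self._next()
                components.append((unit[1], sign[0] == "+"))
            if len(components) == 1:
                return [Atom(value)]
            return [Complex(tuple(components))]
        raise ModuleParseError(f"unexpected {value!r}", pos)


def parse_definition(
    module_id: str,
    text: str,
    registry: Optional[Mapping[str, "ModuleDefinition"]] = None,
) -> ModuleDefinition:
    """Parse a definition string into a :class:`ModuleDefinition`.

    ``registry`` is accepted for interface symmetry with the evaluation
    functions; nested module ids are resolved lazily at evaluation time, so
    parsing never requires it.
    """
    if text is None or not text.strip():
        raise ModuleParseError(f"{module_id}: empty definition")
    normalized = " ".join(text.strip().upper().split())
    tokens = _tokenize(normalized)
    parser = _Parser(tokens, normalized)
    steps = parser.parse_seq()
    leftover = parser._peek()
    if leftover is not None:
        raise ModuleParseError(f"unexpected {leftover[1]!r}", leftover[2])
    return ModuleDefinition(module_id=module_id, steps=tuple(steps), raw_text=text)


# ---------------------------------------------------------------------------
# rendering (parse/render round-trip)
# ---------------------------------------------------------------------------


def _render_step(step: Step) -> str:
    if isinstance(step, Atom):
        return step.ko
    if isinstance(step, Gap):
        return "--"
    if isinstance(step, NestedModule):
        return step.module_id
    if isinstance(step, Complex):
        out = step.components[0][0]
        for ko, essential in step.components[1:]:
            out += ("+" if essential else "-") + ko
        return out
    if isinstance(step, Alternatives):
        inner = ",".join(
            _render_branch(branch) for branch in step.branches
        )
        return f"({inner})"
    raise TypeError(f"not a step: {step!r}")


def _render_branch(branch: Sequence[Step]) -> str:
    text = " ".join(_render_step(s) for s in branch)
    if len(branch) > 1:
        return f"({text})"
    return text


def render(obj: Union[ModuleDefinition, Sequence[Step]]) -> str:
    """Render a parsed definition back to a normalized definition string."""
    steps = obj.steps if isinstance(obj, ModuleDefinition) else obj
    return " ".join(_render_step(s) for s in steps)


# ---------------------------------------------------------------------------
# path enumeration
# ---------------------------------------------------------------------------


def _lookup(module_id: str, registry, stack, depth: int, max_depth: int):
    if module_id in stack:
        raise ModuleCycleError(f"cyclic nested module reference via {module_id}")
    if depth + 1 > max_depth:
        raise ModuleCycleError(f"nested module depth exceeds {max_depth}")
    if registry is None or module_id not in registry:
        raise ValidationError(f"nested module {module_id} not found in registry")
    return registry[module_id]


def _count(steps, registry, stack, depth, max_depth) -> int:
    total = 1
    for step in steps:
        if isinstance(step, Alternatives):
            total *= sum(
                _count(branch, registry, stack, depth, max_depth)
                for branch in step.branches
            )
        elif isinstance(step, NestedModule):
            sub = _lookup(step.module_id, registry, stack, depth, max_depth)
            total *= _count(
                sub.steps, registry, stack | {step.module_id}, depth + 1, max_depth
            )
    return total


def _expand(steps, registry, stack, depth, max_depth):
    paths = [()]
    for step in steps:
        if isinstance(step, Alternatives):
            choices = []
            for branch in step.branches:
                choices.extend(_expand(branch, registry, stack, depth, max_depth))
            paths = [p + c for p in paths for c in choices]
        elif isinstance(step, NestedModule):
            sub = _lookup(step.module_id, registry, stack, depth, max_depth)
            choices = _expand(
                sub.steps, registry, stack | {step.module_id}, depth + 1, max_depth
            )
            paths = [p + c for p in paths for c in choices]
        else:
            paths = [p + (step,) for p in paths]
    return paths


def count_paths(
    defn: ModuleDefinition,
    registry: Optional[Mapping[str, ModuleDefinition]] = None,
    max_depth: int = 10,
) -> int:
    """Number of alternative routes through ``defn`` (nested modules expanded)."""
    return _count(defn.steps, registry, frozenset({defn.module_id}), 0, max_depth)


def enumerate_paths(
    defn: ModuleDefinition,
    registry: Optional[Mapping[str, ModuleDefinition]] = None,
    path_cap: int = 100_000,
    max_depth: int = 10,
) -> list:
    """Enumerate every route through a definition.

    Each route is a tuple of atomic steps (:class:`Atom`, :class:`Complex`
    or :class:`Gap`); nested modules are expanded in place. The number of
    routes equals the product over Alternatives of their branch counts.
    """
    if path_cap < 1:
        raise ValidationError("path_cap must be >= 1")
    n = count_paths(defn, registry, max_depth)
    if n > path_cap:
        raise PathCapacityError(
            f"{defn.module_id}: {n} paths exceed the cap of {path_cap}"
        )
    return _expand(defn.steps, registry, frozenset({defn.module_id}), 0, max_depth)


# ---------------------------------------------------------------------------
# completeness
# ---------------------------------------------------------------------------


def step_completeness(
    step: AtomicStep,
    kos: Iterable[str],
    policy: CompletenessPolicy = DEFAULT_POLICY,
) -> float:
    """Completeness of a single atomic step given an annotated KO set."""
    koset = kos if isinstance(kos, (set, frozenset)) else set(kos)
    if isinstance(step, Atom):
        return 1.0 if step.ko in koset else 0.0
    if isinstance(step, Gap):
        return 0.0
    if isinstance(step, Complex):
        essential = step.essential_kos
        present = sum(1 for ko in essential if ko in koset)
        if policy.complex_all_or_none:
            return 1.0 if present == len(essential) else 0.0
        return present / len(essential)
    raise ValidationError(f"not an atomic step: {step!r}")


def pathwise_completeness(
    defn: ModuleDefinition,
    kos: Iterable[str],
    registry: Optional[Mapping[str, ModuleDefinition]] = None,
    policy: CompletenessPolicy = DEFAULT_POLICY,
) -> float:
    """Max over routes of the mean per-step completeness along the route."""
    koset = frozenset(k.upper() for k in kos)
    paths = enumerate_paths(
        defn, registry, path_cap=policy.path_cap, max_depth=policy.max_nesting_depth
    )
    best = 0.0
    for path in paths:
        steps = [
            s
            for s in path
            if not (policy.exclude_gap_steps and isinstance(s, Gap))
        ]
        if not steps:
            value = 0.0
        else:
            value = sum(step_completeness(s, koset, policy) for s in steps) / len(steps)
        if value > best:
            best = value
    return best


def completeness_matrix(
    genomes: Sequence[GenomeAnnotations],
    modules: Sequence[ModuleDefinition],
    policy: CompletenessPolicy = DEFAULT_POLICY,
    registry: Optional[Mapping[str, ModuleDefinition]] = None,
) -> pd.DataFrame:
    """Genome x module pathwise-completeness grid (rows genomes, cols modules)."""
    genome_ids = [g.genome_id for g in genomes]
    module_ids = [m.module_id for m in modules]
    if len(set(genome_ids)) != len(genome_ids):
        raise ValidationError("duplicate genome ids")
    if len(set(module_ids)) != len(module_ids):
        raise ValidationError("duplicate module ids")
    if registry is None:
        registry = {m.module_id: m for m in modules}
    data = {
        m.module_id: [
            pathwise_completeness(m, g.kos, registry, policy) for g in genomes
        ]
        for m in modules
    }
    return pd.DataFrame(data, index=pd.Index(genome_ids, name="genome"), dtype=float)
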