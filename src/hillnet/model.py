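"""Domain types and rule grammar for logic-based network models.

A model is a list of *species* (genes, proteins or processes carrying a
continuous normalized activity) and a list of *reactions* (directed
activating or inhibiting influences onto a single target species).
Reactions are written in a small rule language::

    rule := [term ("&" term)*] "=>" target
    term := ["!"] ID

``A & !B => E`` reads "A activates and B inhibits E".  A rule with an
empty antecedent (``=> A``) is an *input reaction*: an environmental
stimulus whose flux is just its weight.  Several reactions sharing one
target are OR-combined by the dynamics layer, so OR never appears in the
grammar itself.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Species",
    "RuleTerm",
    "Reaction",
    "NetworkModel",
    "ValidationIssue",
    "RuleParseError",
    "ModelError",
    "parse_rule",
    "render_rule",
    "validate_model",
    "apply_knockout",
    "set_reaction_weight",
    "set_species_params",
    "DEFAULT_TAU",
    "DEFAULT_YMAX",
    "DEFAULT_YINIT",
    "DEFAULT_WEIGHT",
    "DEFAULT_N",
    "DEFAULT_EC50",
]

# Parameter defaults of the workbook dialect: tau=1, yinit=0, ymax=1 for
# species; w=1, n=1.4, EC50=0.5 for reactions.
DEFAULT_TAU = 1.0
DEFAULT_YMAX = 1.0
DEFAULT_YINIT = 0.0
DEFAULT_WEIGHT = 1.0
DEFAULT_N = 1.4
DEFAULT_EC50 = 0.5

_TOKEN_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class RuleParseError(ValueError):
    """A reaction rule string does not match the grammar."""


class ModelError(ValueError):
    """A model operation referenced an unknown id or an out-of-range value."""


def is_token(s: str) -> bool:
    """True if ``s`` is a valid species/reaction identifier token."""
    return bool(_TOKEN_RE.match(s))


@dataclass(frozen=True)
class Species:
    """A network node with a continuous activity state in [0, y_max].

    tau is the relaxation time constant (arbitrary time units), y_init
    the activity at simulation start and y_max the maximal attainable
    activity; setting y_max to 0 models a knockout.
    """

    id: str
    name: str = ""
    y_init: float = DEFAULT_YINIT
    y_max: float = DEFAULT_YMAX
    tau: float = DEFAULT_TAU
    module_tag: str = ""
    notes: str = ""
    refs: str = ""
    extra: tuple[tuple[str, str], ...] = ()  # unrecognized workbook columns, verbatim


@dataclass(frozen=True)
class RuleTerm:
    """One antecedent of a rule: a source species and its sign."""

    species_id: str
    sign: int  # +1 activation, -1 inhibition

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")


@dataclass(frozen=True)
class Reaction:
    """A parsed regulatory rule with its Hill parameters.

    w is the reaction weight in [0, 1] (0 disables the reaction), n the
    Hill coefficient and ec50 the source activity giving half-maximal
    activation.  ``terms`` is empty exactly for input reactions.
    """

    id: str
    rule_text: str
    terms: tuple[RuleTerm, ...]
    target_id: str
    w: float = DEFAULT_WEIGHT
    n: float = DEFAULT_N
    ec50: float = DEFAULT_EC50
    module_tag: str = ""
    notes: str = ""
    refs: str = ""
    extra: tuple[tuple[str, str], ...] = ()

    @property
    def is_input(self) -> bool:
        return not self.terms


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    location: str  # e.g. "species[ISL1]", "reactions[r7]"
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.severity.upper()} at {self.location}: {self.message}"


@dataclass(frozen=True)
class NetworkModel:
    """A complete parsed network: species, reactions and lookup indices.

    Species order defines the state-vector index order everywhere, so a
    model is deterministic down to column ordering of every output.
    """

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction]):
        object.__setattr__(self, "species", tuple(species))
        object.__setattr__(self, "reactions", tuple(reactions))

    # -- lookups ------------------------------------------------------
    @property
    def species_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.species)

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise ModelError(f"unknown species id {species_id!r}") from None

    def get_species(self, species_id: str) -> Species:
        return self.species[self.species_index(species_id)]

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise ModelError(f"unknown reaction id {reaction_id!r}")

    @property
    def incoming_index(self) -> dict[str, tuple[Reaction, ...]]:
        """Map target species id -> reactions producing that target."""
        idx: dict[str, list[Reaction]] = {s.id: [] for s in self.species}
        for r in self.reactions:
            idx.setdefault(r.target_id, []).append(r)
        return {k: tuple(v) for k, v in idx.items()}

    @property
    def input_reactions(self) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.is_input)


# ---------------------------------------------------------------------
# rule grammar
# ---------------------------------------------------------------------

def parse_rule(rule_text: str) -> tuple[tuple[RuleTerm, ...], str]:
    """Parse a rule string into signed terms and a target token.

    A single leading apostrophe (the spreadsheet text marker placed
    before ``=``) is stripped before parsing.  Whitespace around tokens
    is ignored.  An empty antecedent yields an input reaction.
    """
    text = rule_text.strip()
    if text.startswith("'"):
        text = text[1:].strip()
    if "=>" not in text:
        raise RuleParseError(f"rule {rule_text!r} has no '=>'")
    lhs, sep, rhs = text.partition("=>")
    if "=>" in rhs:
        raise RuleParseError(f"rule {rule_text!r} has more than one '=>'")
    target = rhs.strip()
    if not target:
        raise RuleParseError(f"rule {rule_text!r} has an empty target")
    if not is_token(target):
        raise RuleParseError(f"rule {rule_text!r}: target {target!r} is not a valid identifier")

    terms: list[RuleTerm] = []
    lhs = lhs.strip()
    if lhs:
        for raw in lhs.split("&"):
            tok = raw.strip()
            if not tok:
                raise RuleParseError(f"rule {rule_text!r} has a dangling '&'")
            sign = +1
            if tok.startswith("!"):
                sign = -1
                tok = tok[1:].strip()
            if not tok:
                raise RuleParseError(f"rule {rule_text!r} has a '!' without an identifier")
            if not is_token(tok):
                raise RuleParseError(f"rule {rule_text!r}: term {tok!r} is not a valid identifier")
            terms.append(RuleTerm(tok, sign))
    return tuple(terms), target


def render_rule(terms: Iterable[RuleTerm], target_id: str) -> str:
    """Inverse of :func:`parse_rule` up to whitespace."""
    lhs = " & ".join(("!" if t.sign < 0 else "") + t.species_id for t in terms)
    return f"{lhs} => {target_id}" if lhs else f"=> {target_id}"


def reaction_from_rule(
    reaction_id: str, rule_text: str, **params: object
) -> Reaction:
    """Build a :class:`Reaction` by parsing ``rule_text``."""
    terms, target = parse_rule(rule_text)
    text = rule_text.strip()
    if text.startswith("'"):
        text = text[1:].strip()
    return Reaction(id=reaction_id, rule_text=text, terms=terms, target_id=target, **params)  # type: ignore[arg-type]


# ---------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------

def validate_model(model: NetworkModel) -> list[ValidationIssue]:
    """Collect every invariant violation; an empty list means valid.

    Errors: invalid/duplicate ids, unresolved rule references, parameter
    domain violations (tau <= 0, y_max < 0, w outside [0,1], n <= 0,
    ec50 outside (0,1), ec50**n >= 1/2 which breaks the normalized-Hill
    parameterization).  y_init > y_max is a warning only.
    """
    issues: list[ValidationIssue] = []
    err = lambda loc, msg: issues.append(ValidationIssue("error", loc, msg))
    warn = lambda loc, msg: issues.append(ValidationIssue("warning", loc, msg))

    seen_sp: set[str] = set()
    for s in model.species:
        loc = f"species[{s.id}]"
        if not is_token(s.id):
            err(loc, f"id {s.id!r} is not a valid identifier token")
        if s.id in seen_sp:
            err(loc, f"duplicate species id {s.id!r}")
        seen_sp.add(s.id)
        if not s.tau > 0:
            err(loc, f"tau must be > 0, got {s.tau}")
        if s.y_max < 0:
            err(loc, f"y_max must be >= 0, got {s.y_max}")
        if s.y_init < 0:
            err(loc, f"y_init must be >= 0, got {s.y_init}")
        elif s.y_init > s.y_max:
            warn(loc, f"y_init ({s.y_init}) exceeds y_max ({s.y_max})")

    seen_rx: set[str] = set()
    for r in model.reactions:
        loc = f"reactions[{r.id}]"
        if not is_token(r.id):
            err(loc, f"id {r.id!r} is not a valid identifier token")
        if r.id in seen_rx:
            err(loc, f"duplicate reaction id {r.id!r}")
        seen_rx.add(r.id)
        if r.target_id not in seen_sp:
            err(loc, f"rule {r.rule_text!r} targets unknown species {r.target_id!r}")
        for t in r.terms:
            if t.species_id not in seen_sp:
                err(loc, f"rule {r.rule_text!r} references unknown species {t.species_id!r}")
        if not 0.0 <= r.w <= 1.0:
            err(loc, f"weight must be in [0, 1], got {r.w}")
        if not r.n > 0:
            err(loc, f"Hill coefficient must be > 0, got {r.n}")
        if not 0.0 < r.ec50 < 1.0:
            err(loc, f"ec50 must be in (0, 1), got {r.ec50}")
        elif not r.ec50 ** r.n < 0.5:
            err(
                loc,
                f"ec50**n = {r.ec50 ** r.n:.6g} must be < 1/2 for the "
                "normalized Hill parameterization to exist",
            )
    return issues


# ---------------------------------------------------------------------
# perturbation constructors (never mutate their input)
# ---------------------------------------------------------------------

def apply_knockout(model: NetworkModel, species_id: str) -> NetworkModel:
    """Return a copy of ``model`` with ``species_id``'s y_max set to 0.

    Setting the maximal activity to zero removes the species from the
    network dynamically: its activity decays to zero and its outgoing
    activations vanish while its outgoing inhibitions are released.
    """
    i = model.species_index(species_id)
    species = list(model.species)
    species[i] = dataclasses.replace(species[i], y_max=0.0)
    return NetworkModel(species, model.reactions)


def set_reaction_weight(model: NetworkModel, reaction_id: str, w: float) -> NetworkModel:
    """Return a copy with reaction ``reaction_id``'s weight set to ``w``."""
    if not 0.0 <= w <= 1.0:
        raise ModelError(f"reaction weight must be in [0, 1], got {w}")
    reactions = list(model.reactions)
    for i, r in enumerate(reactions):
        if r.id == reaction_id:
            reactions[i] = dataclasses.replace(r, w=float(w))
            return NetworkModel(model.species, reactions)
    raise ModelError(f"unknown reaction id {reaction_id!r}")


def set_species_params(
    model: NetworkModel,
    species_id: str,
    *,
    y_max: float | None = None,
    tau: float | None = None,
) -> NetworkModel:
    """Return a copy with a species' y_max and/or tau overridden."""
    i = model.species_index(species_id)
    changes: dict[str, float] = {}
    if y_max is not None:
        if y_max < 0:
            raise ModelError(f"y_max must be >= 0, got {y_max}")
        changes["y_max"] = float(y_max)
    if tau is not None:
        if not tau > 0:
            raise ModelError(f"tau must be > 0, got {tau}")
        changes["tau"] = float(tau)
    if not changes:
        return model
    species = list(model.species)
    species[i] = dataclasses.replace(species[i], **changes)
    return NetworkModel(species, model.reactions)
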