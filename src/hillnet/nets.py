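"""Programmatically constructed networks: two tutorial models and a
random-model generator for property testing.

``build_examplenet`` is the classic five-species teaching network with
two environmental inputs; ``build_cardiacdevnet`` is a small gene
regulatory network of cardiac outflow-tract development (GATA6 driving
NKX2-5/TBX1/PITX2 while NKX2-5 represses ISL1).  Both are built from
their published descriptions with the dialect's default parameters
(tau=1, ymax=1, n=1.4, EC50=0.5) — nothing tuned.
"""

from __future__ import annotations

import numpy as np

from .model import NetworkModel, Species, reaction_from_rule, validate_model

__all__ = ["build_examplenet", "build_cardiacdevnet", "random_network"]


def build_examplenet() -> NetworkModel:
    """Five species A-E, six reactions, both input weights 0 at build time.

    A and B are stimulus-driven inputs; A activates C and E, B activates
    D and inhibits E, and E feeds back onto C — so C is the OR of two
    routes and E is an AND of activation by A with absence of B.
    """
    species = [Species(id=s, name=s) for s in "ABCDE"]
    reactions = [
        reaction_from_rule("r1", "=> A", w=0.0),
        reaction_from_rule("r2", "=> B", w=0.0),
        reaction_from_rule("r3", "A => C"),
        reaction_from_rule("r4", "B => D"),
        reaction_from_rule("r5", "A & !B => E"),
        reaction_from_rule("r6", "E => C"),
    ]
    return NetworkModel(species, reactions)


def build_cardiacdevnet() -> NetworkModel:
    """Cardiac-development transcription factor network, 5 species / 7 reactions.

    ISL1 starts at activity 1: anterior second heart field progenitors
    express ISL1 highly until NKX2-5 rises and represses it.  The single
    input reaction (GATA6 expression) starts off (w=0).
    """
    species = [
        Species(id="GATA6", name="GATA6"),
        Species(id="NKX25", name="NKX2-5"),
        Species(id="TBX1", name="TBX1"),
        Species(id="ISL1", name="ISL1", y_init=1.0),
        Species(id="PITX2", name="PITX2"),
    ]
    reactions = [
        reaction_from_rule("r1", "=> GATA6", w=0.0),
        reaction_from_rule("r2", "GATA6 => NKX25"),
        reaction_from_rule("r3", "GATA6 => TBX1"),
        reaction_from_rule("r4", "NKX25 => TBX1"),
        reaction_from_rule("r5", "TBX1 => PITX2"),
        reaction_from_rule("r6", "NKX25 => PITX2"),
        reaction_from_rule("r7", "!NKX25 => ISL1"),
    ]
    return NetworkModel(species, reactions)


def random_network(
    n_species: int,
    n_reactions: int,
    p_input: float = 0.25,
    p_inhib: float = 0.3,
    seed: int = 0,
) -> NetworkModel:
    """A reproducible random valid model for property tests.

    The first reaction is always an input so some drive exists; the rest
    are inputs with probability ``p_input`` or rules with 1-3 source
    terms, each inhibiting with probability ``p_inhib``.  Isolated
    species are allowed (they exercise zero-drive decay).  Parameters
    stay at the dialect defaults except weights, drawn uniform in [0,1].
    """
    if n_species < 1 or n_reactions < 1:
        raise ValueError("need at least one species and one reaction")
    rng = np.random.default_rng(seed)
    ids = [f"S{i}" for i in range(n_species)]
    species = [Species(id=s, y_init=float(rng.uniform(0, 1))) for s in ids]
    reactions = []
    for i in range(n_reactions):
        target = ids[int(rng.integers(n_species))]
        if i == 0 or rng.uniform() < p_input:
            rule = f"=> {target}"
        else:
            k = int(rng.integers(1, 4))
            sources = [ids[int(rng.integers(n_species))] for _ in range(k)]
            terms = [
                ("!" if rng.uniform() < p_inhib else "") + s for s in sources
            ]
            rule = " & ".join(terms) + f" => {target}"
        reactions.append(
            reaction_from_rule(f"r{i + 1}", rule, w=float(rng.uniform(0, 1)))
        )
    mdl = NetworkModel(species, reactions)
    assert not [i for i in validate_model(mdl) if i.severity == "error"]
    return mdl
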