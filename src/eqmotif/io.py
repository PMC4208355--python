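"""Plain-text reaction network format and distribution serialization.

Network format, one reaction per line::

    # comment
    2 M + 0 D -> 1 D ; k=1e3
    G + D <-> Gs ; kf=1 ; kr=2      # reversible shorthand
    0 -> S ; k=1                     # empty side = 0 (or blank)
    init: M=100 D=0 G=1 Gs=0

Integer coefficients default to 1; species are declared implicitly by first
occurrence; the ``init:`` line fixes the stoichiometric compatibility class.
Duplicate reactions (same reactant and product complexes) are merged by
summing their rate constants.
"""

from __future__ import annotations

import json
import re

import numpy as np

from .network import Reaction, ReactionNetwork
from .solvers import EquilibriumDistribution

__all__ = [
    "ParseError",
    "parse_network",
    "write_network",
    "write_distribution",
    "read_distribution",
]


class ParseError(ValueError):
    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_*']*)\s*$")


def _parse_side(text: str, species_order: list, line_no: int) -> dict:
    text = text.strip()
    counts: dict = {}
    if text in ("", "0"):
        return counts
    for term in text.split("+"):
        term = term.strip()
        if term in ("", "0"):
            continue
        m = _TERM_RE.match(term)
        if not m:
            # allow "2M" style (coefficient glued to the name)
            m2 = re.match(r"^\s*(\d+)\s*([A-Za-z_][A-Za-z0-9_*']*)\s*$", term)
            if not m2:
                raise ParseError(f"cannot parse term {term!r}", line_no)
            coeff, name = int(m2.group(1)), m2.group(2)
        else:
            coeff = int(m.group(1)) if m.group(1) else 1
            name = m.group(2)
        if name not in species_order:
            species_order.append(name)
        counts[name] = counts.get(name, 0) + coeff
    return counts


def _rate_of(part: str, key: str, line_no: int) -> float:
    m = re.match(rf"^\s*{key}\s*=\s*([^\s]+)\s*$", part)
    if not m:
        raise ParseError(f"expected '{key}=<float>', got {part!r}", line_no)
    try:
        val = float(m.group(1))
    except ValueError:
        raise ParseError(f"invalid rate constant {m.group(1)!r}", line_no) from None
    if val <= 0:
        raise ParseError(f"rate constant must be positive, got {val}", line_no)
    return val


def parse_network(text: str) -> tuple[ReactionNetwork, tuple]:
    """Parse the plain-text format; returns (network, initial state)."""
    species_order: list = []
    raw: list = []  # (reactants dict, products dict, rate)
    init: dict = {}
    saw_init = False
    for line_no, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("init:"):
            saw_init = True
            for item in line[5:].split():
                if "=" not in item:
                    raise ParseError(f"bad init entry {item!r}", line_no)
                name, val = item.split("=", 1)
                try:
                    count = int(val)
                except ValueError:
                    raise ParseError(f"bad init count {val!r}", line_no) from None
                if count < 0:
                    raise ParseError("initial counts must be non-negative", line_no)
                if name not in species_order:
                    species_order.append(name)
                init[name] = count
            continue
        parts = [p.strip() for p in line.split(";")]
        head = parts[0]
        if "<->" in head:
            lhs, rhs = head.split("<->", 1)
            if len(parts) != 3:
                raise ParseError("reversible reaction needs ';kf=..;kr=..'", line_no)
            kf = _rate_of(parts[1], "kf", line_no)
            kr = _rate_of(parts[2], "kr", line_no)
            a = _parse_side(lhs, species_order, line_no)
            b = _parse_side(rhs, species_order, line_no)
            raw.append((a, b, kf))
            raw.append((b, a, kr))
        elif "->" in head:
            lhs, rhs = head.split("->", 1)
            if len(parts) != 2:
                raise ParseError("reaction needs exactly one ';k=<float>'", line_no)
            k = _rate_of(parts[1], "k", line_no)
            a = _parse_side(lhs, species_order, line_no)
            b = _parse_side(rhs, species_order, line_no)
            raw.append((a, b, k))
        else:
            raise ParseError("expected '->' or '<->'", line_no)
    if not raw:
        raise ParseError("no reactions found")
    n = len(species_order)
    reactions = []
    for a, b, k in raw:
        alpha = tuple(a.get(s, 0) for s in species_order)
        beta = tuple(b.get(s, 0) for s in species_order)
        reactions.append(Reaction(alpha, beta, k))
    net = ReactionNetwork(species_order, reactions)
    if saw_init:
        X0 = tuple(init.get(s, 0) for s in species_order)
    else:
        X0 = tuple(0 for _ in range(n))
    return net, X0


def _side_str(coeffs, species) -> str:
    terms = []
    for c, s in zip(coeffs, species):
        if c == 0:
            continue
        terms.append(s if c == 1 else f"{c} {s}")
    return " + ".join(terms) if terms else "0"


def write_network(network: ReactionNetwork, X0=None) -> str:
    """Serialize in the plain-text format (canonical ordering: species in
    declaration order, one irreversible reaction per line)."""
    lines = []
    for r in network.reactions:
        lines.append(
            f"{_side_str(r.reactants, network.species)} -> "
            f"{_side_str(r.products, network.species)} ; k={r.rate:.17g}"
        )
    if X0 is not None:
        lines.append("init: " + " ".join(
            f"{s}={int(x)}" for s, x in zip(network.species, X0)
        ))
    return "\n".join(lines) + "\n"


def write_distribution(
    dist: EquilibriumDistribution, format: str = "tsv", species=None
) -> str:
    """TSV: one column per species count plus 'probability' (17 significant
    digits); JSON mirrors the same content.  Row order = enumeration order."""
    if dist.space is None:
        raise ValueError("distribution has no state space attached")
    n_sp = len(dist.space.states[0])
    names = list(species) if species is not None else [f"x{i}" for i in range(n_sp)]
    if format == "tsv":
        lines = ["\t".join(names + ["probability"])]
        for state, p in zip(dist.space.states, dist.probs):
            lines.append("\t".join(str(int(v)) for v in state) + f"\t{p:.17e}")
        return "\n".join(lines) + "\n"
    if format == "json":
        return json.dumps(
            {
                "species": names,
                "states": [list(map(int, s)) for s in dist.space.states],
                "probabilities": [float(f"{p:.17e}") for p in dist.probs],
            },
            indent=2,
        ) + "\n"
    raise ValueError(f"unknown format {format!r}")


def read_distribution(text: str) -> EquilibriumDistribution:
    """Round-trip reader for both serialization formats."""
    from .network import StateSpace

    text = text.strip()
    if text.startswith("{"):
        obj = json.loads(text)
        states = [tuple(s) for s in obj["states"]]
        probs = np.array(obj["probabilities"], dtype=float)
    else:
        lines = text.splitlines()
        states, probs_list = [], []
        for line in lines[1:]:
            cells = line.split("\t")
            states.append(tuple(int(v) for v in cells[:-1]))
            probs_list.append(float(cells[-1]))
        probs = np.array(probs_list)
    return EquilibriumDistribution(probs / probs.sum(), StateSpace(states))
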