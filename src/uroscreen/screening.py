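"""Bacteria-count banding, the legacy culture trigger, and a reflex-rule grammar.

The analyzer's bacteria channel is banded into three semi-quantitative groups:
below 130 bacteria/µL reports *negative*, 130–330 reports *+*, above 330
reports *++*; the bands partition [0, ∞).  Under the legacy policy a sample is
reflexed to culture when the bacteria band is + or higher, or leukocytes
exceed 50/µL.

Candidate cut-off rules are expressed in a small grammar over three
quantities — ``leuk`` (leukocytes/µL), ``bact`` (bacteria/µL) and ``band``
(the banded bacteria result) — combined with AND/OR and parentheses, e.g.::

    leuk>20 OR band>=++
    (leuk>20 AND band>=+) OR (leuk>100 AND band==neg)

A rule evaluating True on a sediment result means "reflex to culture".
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Union

from .cohort_model import SedimentResult
from .exceptions import InputError, RuleSyntaxError

__all__ = [
    "BacteriaBand",
    "Atom",
    "Group",
    "ScreeningRule",
    "bacteria_band",
    "legacy_trigger",
    "parse_rule",
    "rule_applies",
    "ADOPTED_RULE_TEXT",
    "EXAMPLE_RULE_TEXTS",
]


class BacteriaBand(enum.IntEnum):
    """Semi-quantitative bacteria result; ordered negative < plus < plusplus."""

    NEGATIVE = 0
    PLUS = 1
    PLUSPLUS = 2

    @property
    def symbol(self) -> str:
        return {0: "neg", 1: "+", 2: "++"}[int(self)]

    @classmethod
    def from_symbol(cls, sym: str) -> "BacteriaBand":
        table = {"neg": cls.NEGATIVE, "negative": cls.NEGATIVE, "+": cls.PLUS, "++": cls.PLUSPLUS}
        try:
            return table[sym]
        except KeyError:
            raise InputError(f"unknown band symbol {sym!r}") from None


#: Band boundaries in bacteria/µL: [0, 130) -> negative, [130, 330] -> +, (330, ∞) -> ++.
BAND_LOW = 130.0
BAND_HIGH = 330.0

#: Legacy trigger leukocyte arm: leukocytes strictly above this reflex to culture.
LEGACY_LEUKOCYTE_THRESHOLD = 50.0


def bacteria_band(count: float) -> BacteriaBand:
    """Band a bacteria count (per µL) into negative / + / ++."""
    if count < 0:
        raise InputError(f"bacteria count must be >= 0, got {count!r}")
    if count < BAND_LOW:
        return BacteriaBand.NEGATIVE
    if count <= BAND_HIGH:
        return BacteriaBand.PLUS
    return BacteriaBand.PLUSPLUS


def legacy_trigger(sediment: SedimentResult) -> bool:
    """Legacy culture-trigger policy: band + or higher, or leukocytes > 50/µL.

    The bacteria arm is implemented as band >= + (count >= 130) so banding and
    triggering share a single boundary.
    """
    return (
        bacteria_band(sediment.bacteria) >= BacteriaBand.PLUS
        or sediment.leukocytes > LEGACY_LEUKOCYTE_THRESHOLD
    )


_COMPARATORS = {
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
}

_QUANTITIES = ("leuk", "bact", "band")


@dataclass(frozen=True)
class Atom:
    """One atomic condition: quantity, comparator, threshold.

    ``band`` atoms compare in band order; ``leuk``/``bact`` compare raw counts.
    """

    quantity: str
    comparator: str
    threshold: Union[float, BacteriaBand]

    def __post_init__(self):
        if self.quantity not in _QUANTITIES:
            raise InputError(f"unknown quantity {self.quantity!r}")
        if self.comparator not in _COMPARATORS:
            raise InputError(f"unknown comparator {self.comparator!r}")
        if self.quantity == "band":
            object.__setattr__(self, "threshold", BacteriaBand(self.threshold))
        else:
            t = float(self.threshold)
            if t < 0:
                raise InputError("thresholds must be non-negative")
            object.__setattr__(self, "threshold", t)

    def applies(self, sediment: SedimentResult) -> bool:
        if self.quantity == "leuk":
            value: Union[float, BacteriaBand] = sediment.leukocytes
        elif self.quantity == "bact":
            value = sediment.bacteria
        else:
            value = bacteria_band(sediment.bacteria)
        return _COMPARATORS[self.comparator](value, self.threshold)

    def canonical(self) -> str:
        if self.quantity == "band":
            thr = self.threshold.symbol
        else:
            thr = f"{self.threshold:g}"
        return f"{self.quantity}{self.comparator}{thr}"


@dataclass(frozen=True)
class Group:
    """AND/OR combination of atoms and nested groups."""

    combinator: str  # "AND" | "OR"
    clauses: tuple  # of Atom | Group

    def __post_init__(self):
        if self.combinator not in ("AND", "OR"):
            raise InputError(f"combinator must be AND or OR, got {self.combinator!r}")
        object.__setattr__(self, "clauses", tuple(self.clauses))
        if not self.clauses:
            raise InputError("a rule group needs at least one clause")

    def applies(self, sediment: SedimentResult) -> bool:
        op = all if self.combinator == "AND" else any
        return op(c.applies(sediment) for c in self.clauses)

    def canonical(self) -> str:
        parts = []
        for c in self.clauses:
            text = c.canonical()
            if isinstance(c, Group):
                text = f"({text})"
            parts.append(text)
        return f" {self.combinator} ".join(parts)


@dataclass(frozen=True)
class ScreeningRule:
    """A reflex-screening cut-off rule; True means reflex to culture."""

    root: Union[Atom, Group]

    def applies(self, sediment: SedimentResult) -> bool:
        return self.root.applies(sediment)

    @property
    def text(self) -> str:
        return self.root.canonical()

    def __str__(self) -> str:
        return self.text


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<op>>=|<=|==|>|<)"
    r"|(?P<band>\+\+|\+)|(?P<word>[A-Za-z_]+)|(?P<num>\d+(?:\.\d+)?))"
)

_WORD_ALIASES = {
    "leuk": "leuk",
    "leukocytes": "leuk",
    "bact": "bact",
    "bacteria": "bact",
    "band": "band",
}


def _tokenize(text: str):
    pos = 0
    tokens: list[tuple[str, str, int]] = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise RuleSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of rule", len(self.text))
        self.i += 1
        return tok

    def expect_word(self, *values):
        tok = self.peek()
        if tok and tok[0] == "word" and tok[1].upper() in values:
            self.i += 1
            return tok[1].upper()
        return None

    def parse(self) -> Union[Atom, Group]:
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise RuleSyntaxError(f"trailing input {tok[1]!r}", tok[2])
        return node

    def expr(self) -> Union[Atom, Group]:
        terms = [self.term()]
        while self.expect_word("OR"):
            terms.append(self.term())
        if len(terms) == 1:
            return terms[0]
        return Group("OR", tuple(terms))

    def term(self) -> Union[Atom, Group]:
        factors = [self.factor()]
        while self.expect_word("AND"):
            factors.append(self.factor())
        if len(factors) == 1:
            return factors[0]
        return Group("AND", tuple(factors))

    def factor(self) -> Union[Atom, Group]:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of rule", len(self.text))
        if tok[0] == "lparen":
            self.next()
            node = self.expr()
            closing = self.peek()
            if closing is None or closing[0] != "rparen":
                raise RuleSyntaxError("missing closing parenthesis", len(self.text))
            self.next()
            return node
        return self.atom()

    def atom(self) -> Atom:
        kind, value, pos = self.next()
        if kind != "word" or value.lower() not in _WORD_ALIASES:
            raise RuleSyntaxError(f"expected a quantity name, got {value!r}", pos)
        quantity = _WORD_ALIASES[value.lower()]
        kind, op, pos = self.next()
        if kind != "op":
            raise RuleSyntaxError(f"expected a comparator, got {op!r}", pos)
        kind, thr, pos = self.next()
        if quantity == "band":
            if kind == "band":
                threshold: Union[float, BacteriaBand] = BacteriaBand.from_symbol(thr)
            elif kind == "word" and thr.lower() in ("neg", "negative"):
                threshold = BacteriaBand.NEGATIVE
            else:
                raise RuleSyntaxError(f"expected a band value (neg/+/++), got {thr!r}", pos)
        else:
            if kind != "num":
                raise RuleSyntaxError(f"expected a numeric threshold, got {thr!r}", pos)
            threshold = float(thr)
        return Atom(quantity, op, threshold)


def parse_rule(text: str) -> ScreeningRule:
    """Parse a rule expression; formatting a parsed rule round-trips.

    Raises :class:`RuleSyntaxError` with the offending position on bad input.
    """
    if not text or not text.strip():
        raise RuleSyntaxError("empty rule expression", 0)
    return ScreeningRule(_Parser(text).parse())


def rule_applies(rule: Union[ScreeningRule, str], sediment: SedimentResult) -> bool:
    """Evaluate a rule (object or expression text) on a sediment result."""
    if isinstance(rule, str):
        rule = parse_rule(rule)
    return rule.applies(sediment)


#: The adopted reflex cut-off: leukocytes > 20/µL OR bacteria band ++ (> 330/µL).
ADOPTED_RULE_TEXT = "leuk>20 OR band>=++"

#: The candidate cut-off rules evaluated in the sweep, strictest leukocyte
#: threshold first; the adopted rule is the fifth.
EXAMPLE_RULE_TEXTS = (
    "leuk>75 OR band>=+",
    "leuk>50 OR band>=++",
    "leuk>30 OR band>=++",
    "leuk>25 OR band>=++",
    "leuk>20 OR band>=++",
    "(leuk>20 AND band>=+) OR (leuk>100 AND band==neg)",
    "(leuk>20 AND band>=+) OR (leuk>50 AND band==neg)",
)
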