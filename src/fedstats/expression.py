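"""Restricted R-style expression language for the researcher session.

The evaluation vocabulary is deliberately tiny — exactly the shapes that
appear in a federated session transcript::

    tm <- load("DS1", "munich_site")
    freq(c(tm$gender, tr$gender))
    quantile(c(tm$age, tr$age))
    freq(c(subset(tm, event_death == 0)$follow_up, ...))
    length(tm$age)

Grammar (conjunctions only; no disjunction, no arithmetic)::

    statement  := IDENT '<-' expr | expr
    expr       := call | postfix
    postfix    := primary ('$' IDENT)?
    primary    := IDENT | call
    call       := FUNC '(' args ')'
    predicate  := clause ('&' clause)*
    clause     := IDENT REL literal         REL in == != < <= > >=
    literal    := NUMBER | STRING | IDENT   (bare idents name category labels)

Every parse is deterministic; evaluation touches only share-level
operations, and the only values a statement may return to the researcher
are aggregate results.  A bare table or column as the final value is a
policy refusal: row-level output is impossible by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import ring as R
from .stats import AggregateResult, SecureStats
from .table import (CATEGORICAL, Clause, PrivateColumn, PrivateTable,
                    SelectionMask, build_mask, concat_columns, concat_masks,
                    mask_and)


class ParseError(ValueError):
    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


class PolicyError(PermissionError):
    """The expression requests something other than an aggregate."""


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<arrow><-)|(?P<rel>==|!=|<=|>=|<|>)|(?P<amp>&)|(?P<dollar>\$)"
    r"|(?P<lpar>\()|(?P<rpar>\))|(?P<comma>,)"
    r"|(?P<number>-?\d+(?:\.\d+)?)"
    r"|(?P<string>\"[^\"]*\"|'[^']*')"
    r"|(?P<ident>[A-Za-z_][A-Za-z0-9_.]*))"
)

FUNCTIONS = ("load", "c", "subset", "freq", "mean", "median", "quantile",
             "min", "max", "length", "survival_table")


@dataclass
class _Token:
    kind: str
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens, i = [], 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if m is None or m.end() == i:
            if text[i:].strip() == "":
                break
            raise ParseError(f"unexpected character {text[i]!r}", i)
        for kind, val in m.groupdict().items():
            if val is not None:
                tokens.append(_Token(kind, val, m.start()))
                break
        i = m.end()
    tokens.append(_Token("eof", "", len(text)))
    return tokens


# -- AST --------------------------------------------------------------------

@dataclass
class Name:
    name: str


@dataclass
class Dollar:
    obj: object
    column: str


@dataclass
class Call:
    func: str
    args: list


@dataclass
class Pred:
    clauses: list[tuple[str, str, object]]


@dataclass
class Assign:
    name: str
    expr: object


class _Parser:
    def __init__(self, text: str) -> None:
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> _Token:
        return self.tokens[self.i]

    def next(self) -> _Token:
        t = self.tokens[self.i]
        self.i += 1
        return t

    def expect(self, kind: str) -> _Token:
        t = self.next()
        if t.kind != kind:
            raise ParseError(f"expected {kind}, found {t.text!r}", t.pos)
        return t

    def parse(self):
        if (self.peek().kind == "ident"
                and self.tokens[self.i + 1].kind == "arrow"):
            name = self.next().text
            self.next()
            node = Assign(name, self.expr())
        else:
            node = self.expr()
        t = self.peek()
        if t.kind != "eof":
            raise ParseError(f"trailing input {t.text!r}", t.pos)
        return node

    def expr(self):
        return self.postfix()

    def postfix(self):
        node = self.primary()
        while self.peek().kind == "dollar":
            self.next()
            col = self.expect("ident").text
            node = Dollar(node, col)
        return node

    def primary(self):
        t = self.next()
        if t.kind != "ident":
            raise ParseError(f"expected identifier, found {t.text!r}", t.pos)
        if self.peek().kind == "lpar":
            if t.text not in FUNCTIONS:
                raise ParseError(f"unknown function {t.text!r}", t.pos)
            self.next()
            args = self.call_args(t.text)
            self.expect("rpar")
            return Call(t.text, args)
        return Name(t.text)

    def call_args(self, func: str) -> list:
        args: list = []
        if self.peek().kind == "rpar":
            return args
        while True:
            if func == "subset" and args:  # second arg is the predicate
                args.append(self.predicate())
            elif self.peek().kind == "string":
                tok = self.next()
                args.append(tok.text[1:-1])
            else:
                args.append(self.expr())
            if self.peek().kind == "comma":
                self.next()
                continue
            return args

    def predicate(self) -> Pred:
        clauses = [self.clause()]
        while self.peek().kind == "amp":
            self.next()
            clauses.append(self.clause())
        return Pred(clauses)

    def clause(self) -> tuple[str, str, object]:
        col = self.expect("ident").text
        rel = self.expect("rel").text
        t = self.next()
        if t.kind == "number":
            const: object = float(t.text) if "." in t.text else int(t.text)
        elif t.kind == "string":
            const = t.text[1:-1]
        elif t.kind == "ident":
            const = t.text
        else:
            raise ParseError(f"expected a constant, found {t.text!r}", t.pos)
        return (col, rel, const)


def parse(text: str):
    """Parse a session statement; raises :class:`ParseError` with position."""
    return _Parser(text).parse()


# -- evaluation -------------------------------------------------------------

@dataclass
class _TableVal:
    table: PrivateTable
    mask: SelectionMask | None = None


@dataclass
class _ColumnVal:
    column: PrivateColumn
    mask: SelectionMask | None = None
    label: str = ""


class Evaluator:
    """Evaluate parsed statements against a cluster's private tables.

    ``tables`` maps public labels to ingested :class:`PrivateTable`s;
    ``env`` holds the researcher's session bindings (``tm``, ``tr``...).
    All evaluation runs in the share domain through ``engine``.
    """

    def __init__(self, tables: dict[str, PrivateTable], engine: SecureStats,
                 env: dict | None = None) -> None:
        self.tables = tables
        self.engine = engine
        self.env: dict[str, object] = env if env is not None else {}

    def evaluate(self, text: str):
        node = parse(text)
        if isinstance(node, Assign):
            value = self._eval(node.expr)
            if isinstance(value, AggregateResult):
                raise PolicyError("aggregate results are public; bind tables "
                                  "or subsets, not results")
            self.env[node.name] = value
            kind = "table" if isinstance(value, _TableVal) else "column"
            return {"assigned": node.name, "kind": kind}
        value = self._eval(node)
        if isinstance(value, AggregateResult):
            return value
        raise PolicyError(
            "only aggregate statistics may be released; a raw "
            f"{'table' if isinstance(value, _TableVal) else 'column'} "
            "is not a permitted result")

    # -- helpers -------------------------------------------------------------

    def _eval(self, node):
        if isinstance(node, Name):
            if node.name not in self.env:
                raise ParseError(f"unknown name {node.name!r}", 0)
            return self.env[node.name]
        if isinstance(node, Dollar):
            base = self._eval(node.obj)
            if not isinstance(base, _TableVal):
                raise PolicyError("'$' selects a column from a table")
            col = base.table.column(node.column)
            return _ColumnVal(column=col, mask=base.mask,
                              label=f"{base.table.site_label}${node.column}")
        if isinstance(node, Call):
            return getattr(self, f"_fn_{node.func}")(node.args)
        raise TypeError(f"cannot evaluate node {node!r}")

    def _fn_load(self, args):
        if not args:
            raise ParseError("load() needs a table label", 0)
        label = args[-1]
        if not isinstance(label, str):
            raise ParseError("load() takes string arguments", 0)
        if label not in self.tables:
            raise KeyError(f"no uploaded table {label!r}")
        return _TableVal(self.tables[label])

    def _ones_mask(self, n: int, ring) -> SelectionMask:
        bits = R.public_share(np.ones(n, dtype=np.int64), ring=ring, kind=R.BIT)
        return SelectionMask(bits=bits, source="all", description="all rows")

    def _fn_c(self, args):
        vals = [self._eval(a) for a in args]
        if not vals or not all(isinstance(v, _ColumnVal) for v in vals):
            raise PolicyError("c() concatenates column expressions")
        col = vals[0].column
        mask = vals[0].mask
        any_mask = any(v.mask is not None for v in vals)
        if any_mask and mask is None:
            mask = self._ones_mask(len(col), col.values.ring)
        for v in vals[1:]:
            col = concat_columns(col, v.column)
            if any_mask:
                m = v.mask or self._ones_mask(len(v.column), v.column.values.ring)
                mask = concat_masks(mask, m)
        return _ColumnVal(column=col, mask=mask,
                          label="c(" + ", ".join(v.label for v in vals) + ")")

    def _fn_subset(self, args):
        if len(args) != 2 or not isinstance(args[1], Pred):
            raise ParseError("subset(table, predicate) expects a predicate", 0)
        base = self._eval(args[0])
        if not isinstance(base, _TableVal):
            raise PolicyError("subset() filters a table")
        clauses = []
        for colname, rel, const in args[1].clauses:
            spec = base.table.dictionary[colname] if colname in base.table.dictionary \
                else base.table.column(colname).spec
            if spec.kind == CATEGORICAL and isinstance(const, (int, float)):
                const = str(int(const))  # numeric literals name category labels
            clauses.append(Clause(colname, rel, const))
        mask = build_mask(base.table, clauses, self.engine.store)
        if base.mask is not None:
            mask = mask_and(base.mask, mask, self.engine.store)
        return _TableVal(base.table, mask)

    def _column_arg(self, args, fn):
        if len(args) != 1:
            raise ParseError(f"{fn}() takes one column expression", 0)
        v = self._eval(args[0])
        if not isinstance(v, _ColumnVal):
            raise PolicyError(f"{fn}() applies to a column expression")
        return v

    def _fn_freq(self, args):
        v = self._column_arg(args, "freq")
        return self.engine.freq(v.column, v.mask)

    def _fn_mean(self, args):
        v = self._column_arg(args, "mean")
        return self.engine.mean(v.column, v.mask)

    def _masked_refusal(self, fn):
        raise PolicyError(f"{fn}() over a subset is not part of the agreed "
                          "statistics vocabulary")

    def _fn_quantile(self, args):
        v = self._column_arg(args, "quantile")
        if v.mask is not None:
            self._masked_refusal("quantile")
        return self.engine.quantile(v.column)

    def _fn_median(self, args):
        v = self._column_arg(args, "median")
        if v.mask is not None:
            self._masked_refusal("median")
        return self.engine.median(v.column)

    def _fn_min(self, args):
        v = self._column_arg(args, "min")
        if v.mask is not None:
            self._masked_refusal("min")
        return self.engine.minimum(v.column)

    def _fn_max(self, args):
        v = self._column_arg(args, "max")
        if v.mask is not None:
            self._masked_refusal("max")
        return self.engine.maximum(v.column)

    def _fn_length(self, args):
        v = self._column_arg(args, "length")
        return self.engine.length(v.column, v.mask)

    def _fn_survival_table(self, args):
        if len(args) != 2:
            raise ParseError("survival_table(time_column, event_column)", 0)
        tv = self._eval(args[0])
        ev = self._eval(args[1])
        if not (isinstance(tv, _ColumnVal) and isinstance(ev, _ColumnVal)):
            raise PolicyError("survival_table() applies to column expressions")
        mask = tv.mask or ev.mask
        return self.engine.survival_table(tv.column, ev.column, mask)
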