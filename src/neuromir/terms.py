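"""Model-term specification and design-matrix construction for cohort tables.

A :class:`TermSpec` is an ordered list of main effects and pairwise
interactions over cohort columns, written in the compact CLI syntax
``"log(mir20b),apoe_e4,region,log(mir20b):apoe_e4"``.  Continuous columns may
be wrapped in ``log(...)``; categorical columns are dummy-encoded against
their first level (the cutpoints absorb the reference level, so no explicit
intercept column is ever built).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import RankDeficiencyError, SchemaError


@dataclass(frozen=True)
class Factor:
    """A single predictor reference, optionally log-transformed."""

    column: str
    log: bool = False

    @property
    def label(self) -> str:
        return f"log({self.column})" if self.log else self.column

    @classmethod
    def parse(cls, text: str) -> "Factor":
        text = text.strip()
        if text.startswith("log(") and text.endswith(")"):
            return cls(text[4:-1].strip(), log=True)
        return cls(text)


@dataclass(frozen=True)
class Term:
    """A main effect (one factor) or a pairwise interaction (two factors)."""

    factors: tuple[Factor, ...]

    @property
    def name(self) -> str:
        return ":".join(f.label for f in self.factors)

    @property
    def is_interaction(self) -> bool:
        return len(self.factors) > 1

    @property
    def columns(self) -> frozenset[str]:
        return frozenset(f.column for f in self.factors)

    @classmethod
    def parse(cls, text: str) -> "Term":
        parts = [Factor.parse(p) for p in text.split(":") if p.strip()]
        if not 1 <= len(parts) <= 2:
            raise SchemaError(f"term {text!r}: only main effects and pairwise "
                              "interactions are supported")
        return cls(tuple(parts))


class TermSpec:
    """Ordered, unique collection of model terms."""

    def __init__(self, terms: list[Term] | tuple[Term, ...]):
        names = [t.name for t in terms]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate terms in specification: {names}")
        self.terms = tuple(terms)

    @classmethod
    def parse(cls, text: str) -> "TermSpec":
        """Parse the CLI syntax, e.g. ``"log(mir20b),apoe_e4,region"``."""
        return cls([Term.parse(t) for t in text.split(",") if t.strip()])

    def __iter__(self):
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __repr__(self) -> str:
        return f"TermSpec({', '.join(t.name for t in self.terms)})"

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def drop(self, name: str) -> "TermSpec":
        """Return the spec without the named term.

        Marginality is respected: dropping a main effect also drops every
        interaction that involves its column.  Dropping an interaction
        leaves its parents in place.
        """
        target = next((t for t in self.terms if t.name == name), None)
        if target is None:
            raise SchemaError(f"term {name!r} not in specification")
        if target.is_interaction:
            keep = [t for t in self.terms if t.name != name]
        else:
            col = next(iter(target.columns))
            keep = [t for t in self.terms
                    if t.name != name and col not in t.columns]
        return TermSpec(keep)


def _encode_factor(data: pd.DataFrame, factor: Factor) -> pd.DataFrame:
    if factor.column not in data.columns:
        raise SchemaError(f"predictor column {factor.column!r} missing from data")
    col = data[factor.column]
    if col.isna().any():
        raise SchemaError(f"column {factor.column!r} contains missing values")
    if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
        levels = (list(col.cat.categories)
                  if isinstance(col.dtype, pd.CategoricalDtype)
                  else sorted(col.unique()))
        if factor.log:
            raise SchemaError(f"log() applied to categorical column {factor.column!r}")
        # reference level absorbed by the cutpoints
        out = {}
        for lev in levels[1:]:
            out[f"{factor.column}[{lev}]"] = (col == lev).astype(float).to_numpy()
        return pd.DataFrame(out, index=data.index)
    values = col.to_numpy(dtype=float)
    if factor.log:
        if np.any(values <= 0):
            raise SchemaError(f"log({factor.column}) requires strictly positive values")
        values = np.log(values)
    return pd.DataFrame({factor.label: values}, index=data.index)


def build_design(data: pd.DataFrame, spec: TermSpec,
                 check_rank: bool = True) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Build the encoded design matrix (no intercept column).

    Returns the design frame and a map from term name to the design columns
    it produced.  With ``check_rank`` (used at fit time, not for prediction
    frames) a :class:`RankDeficiencyError` is raised when the columns,
    together with an implicit constant, are collinear.
    """
    blocks: list[pd.DataFrame] = []
    term_columns: dict[str, list[str]] = {}
    for term in spec:
        encoded = [_encode_factor(data, f) for f in term.factors]
        block = encoded[0]
        for other in encoded[1:]:
            prod = {}
            for a in block.columns:
                for b in other.columns:
                    prod[f"{a}:{b}"] = block[a].to_numpy() * other[b].to_numpy()
            block = pd.DataFrame(prod, index=data.index)
        term_columns[term.name] = list(block.columns)
        blocks.append(block)
    design = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=data.index)
    if check_rank and len(design.columns):
        with_const = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
        rank = np.linalg.matrix_rank(with_const)
        if rank < with_const.shape[1]:
            raise RankDeficiencyError(
                "design matrix is rank deficient (collinear or duplicated "
                f"predictors) for terms {spec.names}")
    return design, term_columns
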