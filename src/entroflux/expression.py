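"""Mapping gene expression onto reactions through GPR rules.

The inference objective needs one abundance per (split) reaction.  Gene-level
abundances (FPKM-like, nonnegative) are pushed through each reaction's
gene-protein-reaction (GPR) boolean rule:

* ``AND`` — enzyme complex: limited by the scarcest subunit, evaluates to the
  **minimum** of its children;
* ``OR`` — isozymes: capacities add, evaluates to the **sum** of its children
  (a ``max`` convention is also offered, see ``or_mode``).

Genes absent from the profile are dropped from their node; a node whose
children are all missing is itself missing.  Reactions whose rule is empty or
evaluates to missing receive the **median** of the GPR-derived values, and
every value is floored at ``epsilon`` so that log terms downstream are
defined.  Forward and reverse copies of a reversible reaction share the same
abundance (one enzyme catalyzes both directions).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ExpressionParseError, GPRSyntaxError, MappingError
from .network import SplitNetwork

__all__ = [
    "ExpressionProfile",
    "ReactionExpression",
    "load_expression",
    "evaluate_gpr",
    "map_expression",
]


@dataclass
class ExpressionProfile:
    """Gene-level abundances for one sample.

    ``values`` maps gene identifier to a nonnegative abundance; identifiers
    are unique by construction of the dict.
    """

    values: dict[str, float]
    sample_id: str = ""

    def __post_init__(self):
        for gene, val in self.values.items():
            if val < 0:
                raise ExpressionParseError(
                    f"negative abundance {val} for gene {gene!r}"
                )

    def __len__(self) -> int:
        return len(self.values)

    def scaled(self, c: float) -> "ExpressionProfile":
        """Profile with every abundance multiplied by ``c > 0``."""
        if c <= 0:
            raise ValueError("scale factor must be positive")
        return ExpressionProfile(
            {g: v * c for g, v in self.values.items()}, self.sample_id
        )


@dataclass
class ReactionExpression:
    """Per-split-reaction expression vector ``g`` (strictly positive).

    Attributes
    ----------
    g : ndarray over split reactions
        Abundance per split reaction; both directions of a reversible
        reaction carry the same value; floored at the mapping ``epsilon``.
    imputed : frozenset of str
        Original reaction ids whose value came from median imputation.
    split_reaction_ids : list of str
        Alignment reference (same order as ``g``).
    """

    g: np.ndarray
    imputed: frozenset
    split_reaction_ids: list[str]

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g <= 0):
            raise MappingError("reaction expression must be strictly positive")

    @property
    def G(self) -> float:
        """Total expression, the normalizer of Q(g_i) = g_i / G."""
        return float(self.g.sum())


def load_expression(path, gene_col: str | int = 0,
                    value_col: str | int = 1,
                    sep: str | None = None,
                    sample_id: str | None = None) -> ExpressionProfile:
    """Read a two-column delimited expression table (header required).

    ``gene_col``/``value_col`` may be column names or positions; the
    delimiter is sniffed (TSV/CSV) unless given.
    """
    import csv

    try:
        table = pd.read_csv(path, sep=sep, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise ExpressionParseError(f"{path}: empty expression file") from None
    if table.shape[0] == 0:
        raise ExpressionParseError(f"{path}: no data rows")
    genes = table.iloc[:, gene_col] if isinstance(gene_col, int) \
        else table[gene_col]
    vals = table.iloc[:, value_col] if isinstance(value_col, int) \
        else table[value_col]
    vals = pd.to_numeric(vals, errors="coerce")
    if vals.isna().any():
        bad = int(vals.index[vals.isna()][0])
        raise ExpressionParseError("non-numeric abundance", line=bad + 2)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ExpressionParseError(f"duplicate gene identifier {dup!r}")
    neg = vals < 0
    if neg.any():
        bad = int(vals.index[neg][0])
        raise ExpressionParseError(
            f"negative abundance {vals.iloc[bad]}", line=bad + 2
        )
    return ExpressionProfile(
        dict(zip(genes.astype(str), vals.astype(float))),
        sample_id=sample_id or str(path),
    )


def _parse_gpr(rule: str) -> ast.AST | None:
    import warnings

    from cobra.core.gene import GPR

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # cobra warns before failing
            tree = GPR.from_string(rule)
    except Exception as exc:
        raise GPRSyntaxError(f"cannot parse GPR rule {rule!r}: {exc}") from exc
    if tree.body is None:
        raise GPRSyntaxError(f"cannot parse GPR rule {rule!r}")
    return tree.body


def _eval_node(node: ast.AST, values: dict[str, float], or_mode: str):
    if isinstance(node, ast.Name):
        return values.get(node.id)
    if isinstance(node, ast.BoolOp):
        children = [_eval_node(c, values, or_mode) for c in node.values]
        present = [c for c in children if c is not None]
        if not present:
            return None
        if isinstance(node.op, ast.And):
            return min(present)
        return sum(present) if or_mode == "sum" else max(present)
    raise GPRSyntaxError(f"unsupported GPR node {ast.dump(node)}")


def evaluate_gpr(rule: str, profile: ExpressionProfile,
                 or_mode: str = "sum") -> float | None:
    """Evaluate a GPR rule against a profile; ``None`` means missing.

    ``or_mode`` selects the isozyme convention: ``"sum"`` (capacities add,
    the default) or ``"max"``.
    """
    if or_mode not in ("sum", "max"):
        raise ValueError("or_mode must be 'sum' or 'max'")
    if not rule or not rule.strip():
        return None
    body = _parse_gpr(rule)
    return _eval_node(body, profile.values, or_mode)


def map_expression(split: SplitNetwork, profile: ExpressionProfile,
                   epsilon: float = 1e-8,
                   or_mode: str = "sum") -> ReactionExpression:
    """Build the per-split-reaction expression vector ``g``.

    Each reaction with a GPR evaluating to a value receives it; reactions
    with an empty or fully-missing rule receive the median of the
    GPR-derived values; every value is floored at ``epsilon > 0``.

    Raises
    ------
    MappingError
        If no reaction receives a GPR-derived value (median undefined).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    base = split.base
    assigned: dict[str, float] = {}
    for rid, rule in zip(base.reaction_ids, base.gpr_rules):
        val = evaluate_gpr(rule, profile, or_mode=or_mode)
        if val is not None:
            assigned[rid] = float(val)
    if not assigned:
        raise MappingError(
            "no reaction has a GPR evaluating against this profile; "
            "median imputation is undefined"
        )
    median = float(np.median(list(assigned.values())))
    imputed = frozenset(rid for rid in base.reaction_ids
                        if rid not in assigned)
    g = np.empty(split.n_split)
    for rid in base.reaction_ids:
        value = max(assigned.get(rid, median), epsilon)
        f, r = split.pairing[rid]
        g[f] = value
        if r is not None:
            g[r] = value
    return ReactionExpression(
        g=g, imputed=imputed,
        split_reaction_ids=list(split.split_reaction_ids),
    )
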