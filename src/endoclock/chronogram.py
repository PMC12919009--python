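"""Relative chronograms and their scaling to absolute time.

A relative chronogram is a rooted ultrametric tree whose root age is fixed
to 1; internal node ages are fractions of the crown age. Scaling to
absolute time multiplies every node age either by a known crown age in
years, or by the tree depth in substitutions/site divided by a substitution
rate — with per-node uncertainty intervals propagated from a lognormal
rate multiplier by Monte Carlo.

Polytomies are accepted (poorly supported nodes are commonly collapsed);
the MRCA of tips inside a polytomy is the polytomy node itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .calibration import LognormalRatePrior

__all__ = [
    "RelativeChronogram",
    "AbsoluteChronogram",
    "UltrametricityError",
    "read_newick",
    "chronogram_from_string",
    "mrca_age",
    "scale_by_crown_age",
    "scale_by_rate",
]

DEFAULT_ULTRAMETRIC_TOL = 1e-6


class UltrametricityError(ValueError):
    """Raised when tip depths disagree beyond tolerance."""


def _node_key(node: dendropy.Node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


@dataclass
class RelativeChronogram:
    """Rooted ultrametric tree with root age 1.

    ``node_ages`` maps a frozenset of descendant tip labels (the clade
    identity, robust to rotation) to the node's relative age in [0, 1].
    """

    tree: dendropy.Tree
    node_ages: dict[frozenset[str], float]
    node_hpd: dict[frozenset[str], tuple[float, float]] | None = None

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tree.taxon_namespace)

    @property
    def root_age(self) -> float:
        return 1.0


@dataclass
class AbsoluteChronogram:
    """Node ages in years, optionally with per-node intervals."""

    tree: dendropy.Tree
    node_ages: dict[frozenset[str], float]
    node_intervals: dict[frozenset[str], tuple[float, float]] | None = None

    def age_table(self) -> pd.DataFrame:
        rows = []
        for i, (clade, age) in enumerate(
            sorted(self.node_ages.items(), key=lambda kv: kv[1])
        ):
            lo, hi = (
                self.node_intervals[clade]
                if self.node_intervals is not None
                else (float("nan"), float("nan"))
            )
            rows.append(
                {
                    "node": i,
                    "tips": ";".join(sorted(clade)),
                    "age": age,
                    "lower": lo,
                    "upper": hi,
                }
            )
        return pd.DataFrame(rows)


def _build(tree: dendropy.Tree, tol: float) -> RelativeChronogram:
    tree.is_rooted = True
    root = tree.seed_node
    if len(root.child_nodes()) < 2:
        raise ValueError("tree root must have at least two children")
    # depth of each node from the root
    depths: dict[dendropy.Node, float] = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise ValueError("newick tree must have branch lengths")
        depths[node] = depths[node.parent_node] + node.edge.length
    tip_depths = {lf.taxon.label: depths[lf] for lf in tree.leaf_node_iter()}
    max_depth = max(tip_depths.values())
    if max_depth <= 0:
        raise ValueError("tree has zero depth")
    for label, depth in tip_depths.items():
        if abs(depth - max_depth) > tol * max_depth:
            raise UltrametricityError(
                f"tip {label!r} has depth {depth:.6g}, expected {max_depth:.6g} "
                f"(tolerance {tol:g} relative)"
            )
    node_ages: dict[frozenset[str], float] = {}
    for node in tree.preorder_node_iter():
        age = (max_depth - depths[node]) / max_depth
        if node.is_leaf():
            age = 0.0
        node_ages[_node_key(node)] = age
    return RelativeChronogram(tree=tree, node_ages=node_ages)


def read_newick(
    path: str | Path, tol: float = DEFAULT_ULTRAMETRIC_TOL
) -> RelativeChronogram:
    """Read a rooted ultrametric newick tree; normalize the root age to 1.

    Non-ultrametric trees (tip depths differing by more than ``tol`` relative
    to the root depth) are rejected, naming the offending tip.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="force-rooted")
    return _build(tree, tol)


def chronogram_from_string(
    newick: str, tol: float = DEFAULT_ULTRAMETRIC_TOL
) -> RelativeChronogram:
    """As :func:`read_newick`, from an in-memory newick string."""
    tree = dendropy.Tree.get(
        file=io.StringIO(newick), schema="newick", rooting="force-rooted"
    )
    return _build(tree, tol)


def mrca_age(chron: RelativeChronogram, tips: Sequence[str]) -> float:
    """Relative age of the most recent common ancestor of ``tips``."""
    tips = set(tips)
    unknown = tips - chron.taxa
    if unknown:
        raise KeyError(f"unknown tips: {sorted(unknown)}")
    if len(tips) == 1:
        return 0.0
    best: tuple[int, float] | None = None
    for clade, age in chron.node_ages.items():
        if tips <= clade:
            if best is None or len(clade) < best[0]:
                best = (len(clade), age)
    assert best is not None  # the root contains every tip set
    return best[1]


def scale_by_crown_age(
    chron: RelativeChronogram, crown_age: float
) -> AbsoluteChronogram:
    """Multiply every relative node age (and HPD) by the crown age in years."""
    if crown_age <= 0:
        raise ValueError(f"crown_age must be positive, got {crown_age}")
    ages = {clade: age * crown_age for clade, age in chron.node_ages.items()}
    intervals = None
    if chron.node_hpd is not None:
        intervals = {
            clade: (lo * crown_age, hi * crown_age)
            for clade, (lo, hi) in chron.node_hpd.items()
        }
    tree = chron.tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= crown_age
    return AbsoluteChronogram(tree=tree, node_ages=ages, node_intervals=intervals)


def scale_by_rate(
    chron: RelativeChronogram,
    tree_depth_subs: float,
    prior: LognormalRatePrior,
    n_draws: int = 100_000,
    seed: int = 0,
) -> AbsoluteChronogram:
    """Scale by a substitution rate with lognormal uncertainty.

    Point ages are ``relative age * tree_depth_subs / point_rate``; per-node
    95% intervals come from the 2.5/97.5 percentiles of ages under draws of
    rate * X, X the prior's lognormal multiplier. Because age ∝ 1/rate, the
    draws divide the point age by the multiplier.
    """
    if tree_depth_subs <= 0:
        raise ValueError("tree_depth_subs must be positive")
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    if prior.point_rate <= 0:
        raise ValueError("prior has a degenerate point rate")
    depth_years = tree_depth_subs / prior.point_rate
    rng = np.random.default_rng(seed)
    multipliers = prior.sample_rates(n_draws, rng) / prior.point_rate
    inv = 1.0 / multipliers
    lo_f, hi_f = np.percentile(inv, [2.5, 97.5])
    ages = {c: a * depth_years for c, a in chron.node_ages.items()}
    intervals = {c: (a * lo_f, a * hi_f) for c, a in ages.items()}
    tree = chron.tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= depth_years
    return AbsoluteChronogram(tree=tree, node_ages=ages, node_intervals=intervals)
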