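"""Phylogenies, Felsenstein independent contrasts and the randomization test.

A trait measured across species is pseudo-replicated by shared ancestry:
close relatives resemble each other regardless of any causal link between
the trait and, say, habitat temperature.  Felsenstein's independent
contrasts remove that structure under a Brownian-motion model: at each
internal node of a bifurcating tree the difference between the two child
values, divided by the square root of the summed (variance-extended) branch
lengths, is one independent draw.  Association between two traits is then
measured by the through-origin correlation of their contrasts, and its
significance by a permutation test that shuffles the pairing between the two
contrast vectors.

Newick parsing is delegated to dendropy; the contrast recursion, the
through-origin correlation and the randomization estimator are implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as _ss

from . import stats as tb_stats
from .composition import AMINO_ACIDS, proteome_frequencies


class NewickError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A rooted dendropy tree with branch lengths on every non-root edge."""

    tree: dendropy.Tree
    has_polytomy: bool

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True)
            .strip()
            .replace("'", "")
        )

    def clone(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1), self.has_polytomy)


def _check(tree: dendropy.Tree) -> Phylogeny:
    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise NewickError("unlabeled leaf")
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise NewickError(f"duplicate leaf name {dup!r}")
    root = tree.seed_node
    has_polytomy = False
    for node in tree.preorder_node_iter():
        if node is not root and node.edge.length is None:
            raise NewickError(f"missing branch length above node {node}")
        if node is not root and node.edge.length < 0:
            raise NewickError("negative branch length")
        if len(node.child_nodes()) > 2:
            has_polytomy = True
    return Phylogeny(tree, has_polytomy)


def parse_newick(text: str) -> Phylogeny:
    """Parse a rooted newick string; polytomies are flagged, missing branch
    lengths and duplicate leaf names are errors."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"malformed newick: {exc}") from exc
    return _check(tree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def adjust_zero_branches(
    phy: Phylogeny,
    policy: Literal["half_min_positive", "fixed"] = "half_min_positive",
    value: float | None = None,
) -> Phylogeny:
    """Replace zero-length branches.

    The default policy sets each zero branch to half the minimum positive
    branch length; ``fixed`` sets them to ``value``.
    """
    out = phy.clone()
    root = out.tree.seed_node
    lengths = [
        n.edge.length for n in out.tree.preorder_node_iter() if n is not root
    ]
    positive = [b for b in lengths if b > 0]
    if not positive:
        raise ValueError("all branch lengths are zero; cannot adjust")
    if policy == "half_min_positive":
        repl = min(positive) / 2.0
    elif policy == "fixed":
        if value is None or value <= 0:
            raise ValueError("fixed policy needs a positive value")
        repl = float(value)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    for node in out.tree.preorder_node_iter():
        if node is not root and node.edge.length == 0:
            node.edge.length = repl
    return out


def resolve_polytomies(phy: Phylogeny) -> Phylogeny:
    """Arbitrarily resolve polytomies into zero-length branches, then apply
    the half-min zero-branch adjustment."""
    out = phy.clone()
    out.tree.resolve_polytomies()
    out.has_polytomy = False
    return adjust_zero_branches(out)


@dataclass(frozen=True)
class ContrastSet:
    """Standardized independent contrasts, one per internal node (postorder)."""

    node_ids: tuple[str, ...]
    values: np.ndarray
    trait: str

    def __len__(self) -> int:
        return len(self.values)


def independent_contrasts(
    phy: Phylogeny, trait: Mapping[str, float], trait_name: str = "trait"
) -> ContrastSet:
    """Felsenstein's recursion on a bifurcating tree.

    At each internal node with child values x1, x2 on (variance-extended)
    branches v1, v2: contrast = (x1-x2)/sqrt(v1+v2); the node's value is the
    branch-weighted mean (x1/v1+x2/v2)/(1/v1+1/v2) and its parent branch is
    extended by v1*v2/(v1+v2).  Child order follows the newick order, so
    contrast signs are reproducible (and arbitrary, as always with PIC).
    """
    if phy.has_polytomy:
        raise ValueError(
            "tree contains polytomies; resolve_polytomies() before computing contrasts"
        )
    root = phy.tree.seed_node
    values: dict = {}
    lengths: dict = {}
    node_ids: list[str] = []
    contrasts: list[float] = []
    counter = 0
    for node in phy.tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            label = node.taxon.label
            if label not in trait:
                raise KeyError(f"no trait value for species {label!r}")
            values[node] = float(trait[label])
            lengths[node] = float(node.edge.length)
            continue
        if len(children) != 2:
            raise ValueError("tree is not bifurcating")
        c1, c2 = children
        v1, v2 = lengths[c1], lengths[c2]
        if v1 <= 0 or v2 <= 0:
            raise ValueError(
                "non-positive branch length in contrast computation; "
                "apply adjust_zero_branches first"
            )
        counter += 1
        node_ids.append(f"n{counter}")
        contrasts.append((values[c1] - values[c2]) / np.sqrt(v1 + v2))
        values[node] = (values[c1] / v1 + values[c2] / v2) / (1 / v1 + 1 / v2)
        extension = v1 * v2 / (v1 + v2)
        lengths[node] = (float(node.edge.length) if node is not root else 0.0) + extension
    return ContrastSet(tuple(node_ids), np.asarray(contrasts, dtype=float), trait_name)


def positivize(cx: ContrastSet, cy: ContrastSet) -> tuple[np.ndarray, np.ndarray]:
    """Flip each (x, y) pair so that x >= 0; a diagnostic convention only —
    the through-origin correlation is invariant to pairwise sign flips."""
    sign = np.where(cx.values < 0, -1.0, 1.0)
    return cx.values * sign, cy.values * sign


def contrast_correlation(cx: ContrastSet, cy: ContrastSet) -> float:
    """Through-origin correlation R = sum(x*y)/sqrt(sum(x^2)*sum(y^2))."""
    if cx.node_ids != cy.node_ids:
        raise ValueError("contrast sets are not over the same nodes in the same order")
    x, y = cx.values, cy.values
    if len(x) < 2:
        raise ValueError("need at least 2 contrasts")
    sx, sy = float(np.dot(x, x)), float(np.dot(y, y))
    if sx == 0 or sy == 0:
        raise ValueError("all-zero contrast vector; correlation undefined")
    return float(np.dot(x, y) / np.sqrt(sx * sy))


def contrast_correlation_pvalue(r: float, n_contrasts: int) -> float:
    """Two-sided p for a through-origin correlation of n contrasts, from the
    t distribution with n-1 degrees of freedom."""
    df = n_contrasts - 1
    if df < 1:
        raise ValueError("need at least 2 contrasts")
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * _ss.t.sf(abs(t), df))


@dataclass(frozen=True)
class RandomizationResult:
    r_observed: float
    n_permutations: int
    exceedances: int
    pvalue: float
    seed: int


def exceedance_pvalue(exceedances: int, n_permutations: int) -> float:
    """Permutation p-value (k+1)/(N+1), the observed data counting as one
    additional randomization."""
    if not 0 <= exceedances <= n_permutations:
        raise ValueError("exceedance count outside [0, N]")
    return (exceedances + 1) / (n_permutations + 1)


def randomization_pvalue(
    cx: ContrastSet,
    cy: ContrastSet,
    n_permutations: int = 9999,
    seed: int = 0,
    null: Literal["permutation", "signflip"] = "permutation",
    alternative: Literal["greater", "less", "observed"] = "greater",
) -> RandomizationResult:
    """Permutation test for the through-origin contrast correlation.

    The pairing between the two contrast vectors is shuffled
    ``n_permutations`` times and p = (k+1)/(N+1) with k the exceedance
    count.  The default alternative tests positive association (k counts
    R_rand >= R_obs), which is uniform under the null; ``less`` counts
    R_rand <= R_obs; ``observed`` picks the tail from the sign of the
    observed R (anticonservative under the null, provided for completeness).
    The ``signflip`` null flips random pair signs instead of permuting, for
    users who prefer a reflection-based null.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if alternative not in ("greater", "less", "observed"):
        raise ValueError(f"unknown alternative {alternative!r}")
    r_obs = contrast_correlation(cx, cy)
    rng = np.random.default_rng(seed)
    x, y = cx.values, cy.values
    sx = float(np.dot(x, x))
    sy = float(np.dot(y, y))
    denom = np.sqrt(sx * sy)
    k = 0
    for _ in range(n_permutations):
        if null == "permutation":
            y_r = rng.permutation(y)
        elif null == "signflip":
            y_r = y * rng.choice([-1.0, 1.0], size=len(y))
        else:
            raise ValueError(f"unknown null {null!r}")
        r_rand = float(np.dot(x, y_r) / denom)
        if alternative == "greater":
            hit = r_rand >= r_obs
        elif alternative == "less":
            hit = r_rand <= r_obs
        else:  # tail chosen by the observed sign
            hit = r_rand >= r_obs if r_obs >= 0 else r_rand <= r_obs
        if hit:
            k += 1
    return RandomizationResult(
        r_obs, n_permutations, k, exceedance_pvalue(k, n_permutations), seed
    )


def per_aa_temperature_profile(
    proteomes: Mapping[str, Sequence],
    traits: Mapping[str, float] | pd.DataFrame,
    tree: Phylogeny | None = None,
    randomization: bool = False,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-amino-acid correlation with temperature, naive and comparative.

    Naive columns (R, p) are ordinary Pearson correlations of species-level
    amino-acid fractions against temperature.  When a tree is supplied, the
    comparative columns (R_comp, p_comp) are through-origin correlations of
    independent contrasts, with p from the t distribution on n_contrasts - 1
    degrees of freedom (or from the randomization test when requested).
    """
    if isinstance(traits, pd.DataFrame):
        traits = dict(zip(traits["species"], traits["temperature"]))
    species = sorted(proteomes)
    missing = [s for s in species if s not in traits]
    if missing:
        raise ValueError(f"species without temperature: {missing}")
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    freqs = {s: proteome_frequencies(proteomes[s]) for s in species}
    temps = np.array([traits[s] for s in species])
    if tree is not None:
        extra = set(tree.leaf_labels) ^ set(species)
        if extra:
            raise ValueError(f"tree/panel species mismatch: {sorted(extra)}")
        ct = independent_contrasts(tree, {s: traits[s] for s in species}, "temperature")
    rows = []
    for aa in AMINO_ACIDS:
        fr = np.array([freqs[s][aa] for s in species])
        naive = tb_stats.pearson(fr, temps)
        row = {"amino_acid": aa, "R": naive.statistic, "p": naive.pvalue}
        if tree is not None:
            ca = independent_contrasts(tree, {s: freqs[s][aa] for s in species}, aa)
            r_comp = contrast_correlation(ct, ca)
            if randomization:
                p_comp = randomization_pvalue(
                    ct, ca, n_permutations=n_permutations, seed=seed
                ).pvalue
            else:
                p_comp = contrast_correlation_pvalue(r_comp, len(ct))
            row.update({"R_comp": r_comp, "p_comp": p_comp})
        rows.append(row)
    return pd.DataFrame(rows)
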