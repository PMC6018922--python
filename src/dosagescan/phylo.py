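"""Phylogenetic generalized least squares under Brownian-motion covariance.

Gene copies within a family are related by duplication and speciation, so
per-tip observations are not independent. Under Brownian trait evolution on
a rooted tree with branch lengths, the covariance between tips i and j is
proportional to the shared path length from the root to their most recent
common ancestor, and the variance of tip i is its root-to-tip distance.
The regression of log10 transcript abundance on gene copy number is then
fitted by GLS with that covariance:

    beta_hat = (X' C^-1 X)^-1 X' C^-1 y,   X = [1, x]

with residual variance sigma2_hat = r' C^-1 r / (n - 2), slope standard
error from sigma2_hat (X' C^-1 X)^-1, and a two-sided t test on n - 2
degrees of freedom. The slope is invariant to rescaling C by a positive
scalar (sigma2_hat absorbs it), so branch-length units are immaterial.
Implemented from matrix first principles via Cholesky factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import linalg, stats

from dosagescan.io import read_newick


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian tip covariance of a rooted tree with branch lengths."""

    tip_labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        c = self.matrix
        if c.shape != (len(self.tip_labels), len(self.tip_labels)):
            raise ValueError("matrix shape does not match tip labels")
        if not np.allclose(c, c.T):
            raise ValueError("covariance matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(c)) < -1e-8:
            raise ValueError("covariance matrix is not positive semi-definite")


@dataclass(frozen=True)
class PGLSResult:
    """Copy-number -> log-abundance regression for one gene family."""

    family_id: str
    n_tips: int
    slope: float
    intercept: float
    slope_se: float
    t_stat: float
    df: int
    p_value: float
    p_bonferroni: float | None = None


class UntestableFamilyError(ValueError):
    """Raised when the predictor is constant (no copy-number variation)."""


def brownian_covariance(tree: dendropy.Tree | str) -> PhyloCovariance:
    """Tip covariance C with C[i,j] = depth of MRCA(i, j), C[i,i] = tip depth.

    Accepts a dendropy tree, a Newick string, or a path to a Newick file.
    The tree must be rooted with branch lengths everywhere; ultrametricity is
    not required.
    """
    if not isinstance(tree, dendropy.Tree):
        tree = read_newick(tree)
    leaves = tree.leaf_nodes()
    if len(leaves) < 3:
        raise ValueError("need at least 3 tips")
    if tree.is_rooted is False:
        raise ValueError(
            "tree is explicitly unrooted; root it upstream (midpoint or "
            "outgroup) before computing Brownian covariance")
    root = tree.seed_node

    depth: dict[dendropy.Node, float] = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise ValueError(
                "unrooted/lengthless edge encountered; root the tree "
                "(midpoint or outgroup) and supply branch lengths upstream")
        depth[node] = depth[node.parent_node] + node.edge.length

    labels = tuple(
        lf.taxon.label if lf.taxon is not None else str(id(lf))
        for lf in leaves)
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)
    c = np.zeros((n, n))
    for lf in leaves:
        c[index[lf], index[lf]] = depth[lf]
    # for each internal node, tip pairs split across its children share
    # exactly its depth
    for node in tree.postorder_internal_node_iter():
        kids = node.child_nodes()
        tips_per_kid = [[index[lf] for lf in kid.leaf_iter()] for kid in kids]
        d = depth[node]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in tips_per_kid[a]:
                    for j in tips_per_kid[b]:
                        c[i, j] = c[j, i] = d
    return PhyloCovariance(tip_labels=labels, matrix=c)


def log_transform_abundance(rpkm: Sequence[float]) -> np.ndarray:
    """log10(RPKM + 1); the unit offset anchors zero abundance at zero."""
    arr = np.asarray(rpkm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("RPKM values must be non-negative")
    return np.log10(arr + 1.0)


def pgls_fit(
    x: Sequence[float],
    y: Sequence[float],
    cov: PhyloCovariance | np.ndarray,
    family_id: str = "",
) -> PGLSResult:
    """GLS regression of y on x with phylogenetic error covariance.

    ``x`` and ``y`` must be aligned to the covariance's tip order. With the
    identity covariance this reduces exactly to ordinary least squares.
    """
    c = cov.matrix if isinstance(cov, PhyloCovariance) else np.asarray(cov)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 tips")
    if len(y) != n or c.shape != (n, n):
        raise ValueError("x, y and covariance dimensions disagree")
    if np.ptp(x) == 0:
        raise UntestableFamilyError(
            f"family {family_id or '<unnamed>'}: constant copy number; "
            "no variation to regress on")

    design = np.column_stack([np.ones(n), x])
    try:
        chol = linalg.cho_factor(c, lower=True)
        ci_x = linalg.cho_solve(chol, design)
        ci_y = linalg.cho_solve(chol, y)
    except linalg.LinAlgError:
        warnings.warn("singular covariance; using pseudo-inverse",
                      stacklevel=2)
        pinv = np.linalg.pinv(c)
        ci_x = pinv @ design
        ci_y = pinv @ y
    xtcx = design.T @ ci_x
    xtcy = design.T @ ci_y
    beta = np.linalg.solve(xtcx, xtcy)
    resid = y - design @ beta
    try:
        ci_r = linalg.cho_solve(chol, resid)
    except NameError:  # pragma: no cover - pseudo-inverse branch
        ci_r = pinv @ resid
    dof = n - 2
    sigma2 = float(resid @ ci_r) / dof
    cov_beta = sigma2 * np.linalg.inv(xtcx)
    se = float(np.sqrt(max(cov_beta[1, 1], 0.0)))
    if se == 0.0:
        t_stat = np.inf if beta[1] != 0 else 0.0
        p = 0.0 if beta[1] != 0 else 1.0
    else:
        t_stat = float(beta[1] / se)
        p = float(2.0 * stats.t.sf(abs(t_stat), dof))
    return PGLSResult(
        family_id=family_id, n_tips=n,
        slope=float(beta[1]), intercept=float(beta[0]),
        slope_se=se, t_stat=t_stat, df=dof, p_value=p,
    )


def run_family_scan(
    families: Mapping[str, tuple[dendropy.Tree | str, Sequence[float],
                                 Sequence[float]]],
    extra_trees: Mapping[str, Sequence[dendropy.Tree | str]] | None = None,
) -> tuple[list[PGLSResult], dict[str, str], dict[str, list[float]]]:
    """PGLS across gene families with Bonferroni adjustment.

    ``families`` maps family id to ``(tree, copy_numbers, log_abundances)``
    with traits in the tree's tip order (as returned by
    :func:`brownian_covariance`). Families with constant copy number are
    untestable and reported with a reason instead of a result; the Bonferroni
    factor is the number of testable families. ``extra_trees`` optionally
    supplies alternative trees per family (e.g. posterior samples); their
    per-tree p-values are returned untouched as a robustness report.
    """
    results: list[PGLSResult] = []
    untestable: dict[str, str] = {}
    for fam, (tree, x, y) in families.items():
        cov = brownian_covariance(tree)
        try:
            results.append(pgls_fit(x, y, cov, family_id=fam))
        except UntestableFamilyError as exc:
            untestable[fam] = str(exc)
    m = len(results)
    results = [
        PGLSResult(
            family_id=r.family_id, n_tips=r.n_tips, slope=r.slope,
            intercept=r.intercept, slope_se=r.slope_se, t_stat=r.t_stat,
            df=r.df, p_value=r.p_value,
            p_bonferroni=min(1.0, r.p_value * m),
        )
        for r in results
    ]
    per_tree: dict[str, list[float]] = {}
    if extra_trees:
        for fam, trees in extra_trees.items():
            if fam not in families:
                continue
            _, x, y = families[fam]
            pvals = []
            for t in trees:
                try:
                    pvals.append(
                        pgls_fit(x, y, brownian_covariance(t),
                                 family_id=fam).p_value)
                except UntestableFamilyError:
                    pvals.append(float("nan"))
            per_tree[fam] = pvals
    return results, untestable, per_tree
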