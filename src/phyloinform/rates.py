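"""Per-site substitution-rate estimation on a fixed time tree.

Each alignment column gets its own rate lambda (substitutions/site/Ma),
estimated by maximising the Felsenstein pruning likelihood under JC69
with uniform root frequencies. Branch lengths are in Ma, so a branch of
length t contributes an expected distance d = lambda * t. Because the
tree is fixed and JC69 has no free nuisance parameters, the profile over
lambda is a clean 1-D optimisation, solved per site by a coarse grid
scan followed by golden-section refinement of the bracketing interval
(the scan guards against occasional multi-modality of single-site
likelihood surfaces).

Degenerate columns - constant, all-missing, or with fewer than two
non-missing taxa - carry no rate information; they are assigned
lambda = 0 with the boundary flag set so that downstream
informativeness sums stay defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import MISSING_CODE, SeqMatrix
from .partitions import PartitionScheme
from .substmodel import jc_prob
from .tree import PhyloTree

__all__ = [
    "jc_prob",
    "site_loglik",
    "estimate_site_rate",
    "estimate_all_rates",
    "SiteRateTable",
    "default_lambda_max",
]

#: expected root-to-tip substitutions allowed at the rate ceiling
_LAMBDA_MAX_DEPTH = 20.0
_GRID_POINTS = 65
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def default_lambda_max(tree: PhyloTree) -> float:
    """Rate ceiling: 20 expected substitutions root-to-tip (far beyond
    saturation for any usable marker)."""
    T = tree.root_age
    if T <= 0:
        raise ValueError("tree has zero depth; cannot set a rate ceiling")
    return _LAMBDA_MAX_DEPTH / T


@dataclass
class SiteRateTable:
    """Per-site rate estimates as a tidy frame.

    Columns: site (1-based), partition, lambda, loglik, boundary.
    """

    frame: pd.DataFrame

    COLUMNS = ("site", "partition", "lambda", "loglik", "boundary")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"rate table missing columns: {sorted(missing)}")
        lam = self.frame["lambda"].to_numpy(dtype=float)
        if np.any(lam < 0):
            raise ValueError("negative rate in table")

    def rates_for_sites(self, sites_1based: np.ndarray) -> np.ndarray:
        """Rates for the given 1-based site indices; raises listing any
        site without a rate."""
        lookup = pd.Series(
            self.frame["lambda"].to_numpy(), index=self.frame["site"]
        )
        sites = np.asarray(sites_1based)
        missing = [int(s) for s in sites if s not in lookup.index]
        if missing:
            raise KeyError(f"no rate for sites: {missing[:20]}")
        return lookup.loc[sites].to_numpy(dtype=float)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SiteRateTable":
        """Read a rate table in the package layout; externally produced
        tables (e.g. from another rate estimator) are accepted as long as
        they carry the same columns."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if "boundary" in df.columns:
            df["boundary"] = df["boundary"].astype(bool)
        return cls(df)


# -- pruning engine ---------------------------------------------------------


def _tree_arrays(tree: PhyloTree):
    post = tree.postorder()
    return post, tree.children, tree.blen


def _pruning_loglik(tree: PhyloTree, codes: np.ndarray, lam) -> np.ndarray:
    """Log-likelihood of each column under JC69 at per-site rates.

    codes: (n_tree_tips, n_sites) uint8 in tip order ``tree.tip_ids``;
    lam: scalar or (n_sites,) array. Returns (n_sites,).
    """
    n_sites = codes.shape[1]
    lam = np.broadcast_to(np.asarray(lam, dtype=float), (n_sites,))
    post, children, blen = _tree_arrays(tree)
    tip_row = {node: r for r, node in enumerate(tree.tip_ids)}

    partial = {}
    logscale = np.zeros(n_sites)
    for node in post:
        if not children[node]:
            row = codes[tip_row[node]]
            p = np.zeros((n_sites, 4))
            obs = row != MISSING_CODE
            p[~obs] = 1.0
            p[np.flatnonzero(obs), row[obs]] = 1.0
            partial[node] = p
            continue
        p = np.ones((n_sites, 4))
        for child in children[node]:
            d = lam * blen[child]
            e = np.exp(-4.0 * d / 3.0)
            p_same = 0.25 + 0.75 * e
            p_diff = 0.25 - 0.25 * e
            v = partial.pop(child)
            s = v.sum(axis=1, keepdims=True)
            p *= (p_same - p_diff)[:, None] * v + p_diff[:, None] * s
        scale = p.max(axis=1)
        ok = scale > 0
        p[ok] /= scale[ok, None]
        with np.errstate(divide="ignore"):
            logscale += np.where(ok, np.log(np.where(ok, scale, 1.0)), -np.inf)
        partial[node] = p
    root = partial[post[-1]]
    with np.errstate(divide="ignore"):
        return np.log(0.25 * root.sum(axis=1)) + logscale


def _codes_for_tree(matrix: SeqMatrix, tree: PhyloTree) -> np.ndarray:
    """Reorder matrix rows to the tree's tip order; taxa present in the
    tree but absent from the matrix contribute missing data."""
    tip_labels = tree.tip_labels
    row_of = {lab: i for i, lab in enumerate(matrix.labels)}
    absent = [lab for lab in matrix.labels if lab not in set(tip_labels)]
    if absent:
        raise KeyError(f"matrix taxa not in tree: {absent}")
    codes = np.full((len(tip_labels), matrix.n_sites), MISSING_CODE, np.uint8)
    mcodes = matrix.codes()
    for r, lab in enumerate(tip_labels):
        if lab in row_of:
            codes[r] = mcodes[row_of[lab]]
    return codes


def site_loglik(tree: PhyloTree, column, lam: float) -> float:
    """Pruning log-likelihood of a single column at rate *lam*.

    *column* maps taxon label -> symbol (tree tips absent from the map
    are treated as missing data).
    """
    if lam < 0:
        raise ValueError("rate must be >= 0")
    labels = list(column)
    matrix = SeqMatrix.from_strings(labels, [str(column[t]) for t in labels])
    codes = _codes_for_tree(matrix, tree)
    return float(_pruning_loglik(tree, codes, float(lam))[0])


# -- optimisation -----------------------------------------------------------


def _degenerate_mask(codes: np.ndarray) -> np.ndarray:
    """Columns that carry no rate information (<=1 distinct observed state
    or <2 non-missing taxa)."""
    obs = codes != MISSING_CODE
    n_obs = obs.sum(axis=0)
    n_states = np.zeros(codes.shape[1], dtype=int)
    for k in range(4):
        n_states += (codes == k).any(axis=0)
    return (n_obs < 2) | (n_states <= 1)


def _optimize_columns(tree, codes, lam_max, tol):
    """Vectorised per-column MLE of lambda on [0, lam_max]."""
    n = codes.shape[1]
    grid = np.linspace(0.0, lam_max, _GRID_POINTS)
    ll = np.stack([_pruning_loglik(tree, codes, g) for g in grid])  # (G, n)
    best = np.argmax(ll, axis=0)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, len(grid) - 1)]

    a, b = lo.copy(), hi.copy()
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1 = _pruning_loglik(tree, codes, x1)
    f2 = _pruning_loglik(tree, codes, x2)
    span = float((hi - lo).max(initial=tol))
    n_iter = int(np.ceil(np.log(max(span, tol) / tol) / -np.log(_GOLDEN))) + 1
    for _ in range(n_iter):
        up = f1 < f2  # maximum lies in [x1, b]
        a = np.where(up, x1, a)
        b = np.where(up, b, x2)
        old_x1, old_f1, old_f2 = x1, f1, f2
        x1 = np.where(up, x2, b - _GOLDEN * (b - a))
        x2 = np.where(up, a + _GOLDEN * (b - a), old_x1)
        x_eval = np.where(up, x2, x1)
        f_eval = _pruning_loglik(tree, codes, x_eval)
        f1 = np.where(up, old_f2, f_eval)
        f2 = np.where(up, f_eval, old_f1)
    lam = np.where(f1 > f2, x1, x2)
    loglik = _pruning_loglik(tree, codes, lam)
    at_zero = _pruning_loglik(tree, codes, np.zeros(n))
    take_zero = at_zero >= loglik
    lam = np.where(take_zero, 0.0, lam)
    loglik = np.where(take_zero, at_zero, loglik)
    at_max = ll[-1]
    take_max = at_max >= loglik
    lam = np.where(take_max, lam_max, lam)
    loglik = np.where(take_max, at_max, loglik)
    return lam, loglik


def estimate_site_rate(tree: PhyloTree, column, lam_max=None, tol=1e-8):
    """MLE of the substitution rate for one column.

    Returns (lambda_hat, loglik, boundary). *column* maps taxon -> symbol.
    """
    labels = list(column)
    matrix = SeqMatrix.from_strings(labels, [str(column[t]) for t in labels])
    table = estimate_all_rates(matrix, tree, scheme=None, lam_max=lam_max, tol=tol)
    row = table.frame.iloc[0]
    return float(row["lambda"]), float(row["loglik"]), bool(row["boundary"])


def estimate_all_rates(
    matrix: SeqMatrix,
    tree: PhyloTree,
    scheme: PartitionScheme | None = None,
    lam_max: float | None = None,
    tol: float = 1e-8,
) -> SiteRateTable:
    """Per-site rate MLEs for every column of the alignment.

    Duplicate column patterns are collapsed before optimisation, so wide
    alignments with many shared patterns cost little extra. Column order
    is preserved in the output.
    """
    if not tree.is_ultrametric():
        warnings.warn(
            "tree is not ultrametric; rates are still per unit branch "
            "length but the time axis of downstream profiles is suspect",
            stacklevel=2,
        )
    if lam_max is None:
        lam_max = default_lambda_max(tree)
    codes = _codes_for_tree(matrix, tree)

    uniq, inverse = np.unique(codes, axis=1, return_inverse=True)
    lam_u = np.zeros(uniq.shape[1])
    ll_u = np.zeros(uniq.shape[1])
    degen = _degenerate_mask(uniq)
    if degen.any():
        ll_u[degen] = _pruning_loglik(tree, uniq[:, degen], 0.0)
    live = ~degen
    if live.any():
        lam_u[live], ll_u[live] = _optimize_columns(
            tree, uniq[:, live], lam_max, tol
        )
    lam = lam_u[inverse]
    ll = ll_u[inverse]
    btol = max(tol, 1e-4 * lam_max)
    boundary = (lam <= btol) | (lam >= lam_max - btol)

    n = matrix.n_sites
    part_of = np.full(n, "", dtype=object)
    if scheme is not None:
        for name, cols0 in scheme.items0():
            part_of[cols0] = name
    frame = pd.DataFrame(
        {
            "site": np.arange(1, n + 1),
            "partition": part_of,
            "lambda": lam,
            "loglik": ll,
            "boundary": boundary,
        }
    )
    return SiteRateTable(frame)
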