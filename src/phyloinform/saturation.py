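"""Substitution-saturation tables: uncorrected p-distances against
patristic distances on a reference tree.

Saturation shows up as a plateau of the pairwise p-distance as the tree
distance between taxa grows: once multiple hits accumulate, the observed
difference stalls near the stationary ceiling (3/4 under JC with equal
base frequencies). Missing data are handled by pairwise deletion, so
taxon pairs sharing only part of a fragment still contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import MISSING_CODE, SeqMatrix
from .partitions import PartitionScheme
from .tree import PhyloTree

__all__ = ["p_distance", "saturation_table", "SaturationTable"]


def p_distance(seq_a: str, seq_b: str):
    """Uncorrected p-distance with pairwise deletion.

    Returns (proportion differing, n compared); positions where either
    symbol is missing (gap, '?', 'N', ambiguity code) are excluded.
    Raises ValueError when no position is comparable.
    """
    m = SeqMatrix.from_strings(["a", "b"], [seq_a, seq_b])
    codes = m.codes()
    return _p_distance_codes(codes[0], codes[1])


def _p_distance_codes(a: np.ndarray, b: np.ndarray):
    both = (a != MISSING_CODE) & (b != MISSING_CODE)
    n = int(both.sum())
    if n == 0:
        raise ValueError("no comparable (both non-missing) positions")
    diff = int((a[both] != b[both]).sum())
    return diff / n, n


@dataclass
class SaturationTable:
    """Pairwise rows plus per-partition OLS summaries.

    pairs: partition, taxon_a, taxon_b, n_compared, p_distance,
    tree_distance. summary: partition, slope, intercept, pearson_r.
    """

    pairs: pd.DataFrame
    summary: pd.DataFrame

    def write_tsv(self, pairs_path, summary_path) -> None:
        self.pairs.to_csv(pairs_path, sep="\t", index=False)
        self.summary.to_csv(summary_path, sep="\t", index=False)


def saturation_table(
    matrix: SeqMatrix, tree: PhyloTree, scheme: PartitionScheme
) -> SaturationTable:
    """One row per unordered taxon pair per partition.

    Tree distances are patristic distances on the supplied tree (any
    rooted Newick: a chronogram, a consensus phylogram, or a single-gene
    tree). Pairs with zero comparable sites are dropped with a warning.
    """
    tree_tips = set(tree.tip_labels)
    absent = [t for t in matrix.labels if t not in tree_tips]
    if absent:
        raise KeyError(f"matrix taxa absent from tree: {absent}")

    labels, dmat = tree.tip_distance_matrix()
    tpos = {lab: i for i, lab in enumerate(labels)}
    codes = matrix.codes()

    rows = []
    dropped = 0
    for name, cols0 in scheme.items0():
        sub = codes[:, cols0]
        for ia, ib in combinations(range(matrix.n_taxa), 2):
            a, b = matrix.labels[ia], matrix.labels[ib]
            try:
                p, n = _p_distance_codes(sub[ia], sub[ib])
            except ValueError:
                dropped += 1
                continue
            rows.append(
                {
                    "partition": name,
                    "taxon_a": a,
                    "taxon_b": b,
                    "n_compared": n,
                    "p_distance": p,
                    "tree_distance": dmat[tpos[a], tpos[b]],
                }
            )
    if dropped:
        warnings.warn(
            f"dropped {dropped} taxon pair(s) with zero comparable sites",
            stacklevel=2,
        )
    pairs = pd.DataFrame(rows)

    summaries = []
    for name in scheme.names:
        sub = pairs[pairs["partition"] == name]
        if len(sub) < 2 or sub["tree_distance"].nunique() < 2:
            slope = intercept = r = float("nan")
        else:
            fit = stats.linregress(sub["tree_distance"], sub["p_distance"])
            slope, intercept, r = fit.slope, fit.intercept, fit.rvalue
        summaries.append(
            {
                "partition": name,
                "slope": slope,
                "intercept": intercept,
                "pearson_r": r,
            }
        )
    return SaturationTable(pairs=pairs, summary=pd.DataFrame(summaries))


def plot_saturation(table: SaturationTable, path) -> None:
    """Scatter of p-distance vs tree distance, one panel per partition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(table.summary["partition"])
    ncol = min(4, max(1, len(names)))
    nrow = (len(names) + ncol - 1) // ncol
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False
    )
    for k, name in enumerate(names):
        ax = axes[k // ncol][k % ncol]
        sub = table.pairs[table.pairs["partition"] == name]
        ax.scatter(sub["tree_distance"], sub["p_distance"], s=4, alpha=0.5)
        ax.set_title(name, fontsize=8)
        ax.set_ylim(0, 1)
    for k in range(len(names), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.supxlabel("patristic distance (Ma)")
    fig.supylabel("uncorrected p-distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
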