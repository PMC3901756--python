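"""Classification of alignment columns: conserved, variable but
parsimony-uninformative, or parsimony-informative.

Missing symbols (gaps, '?', 'N', ambiguity codes) are ignored when
counting states. A column is conserved when at most one distinct state
remains, parsimony-informative when at least two states each occur in at
least two taxa, and variable-uninformative otherwise. "Variable" counts
reported by :func:`summarize` include the parsimony-informative sites
(the stacked-proportion convention used in marker comparisons).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .alignment import MISSING_CODE, SeqMatrix
from .partitions import PartitionScheme

__all__ = ["classify_site", "classify_columns", "summarize"]

CONSERVED = "conserved"
VARIABLE = "variable_uninformative"
INFORMATIVE = "parsimony_informative"


def classify_columns(codes: np.ndarray):
    """Vectorised classification of every column of a coded matrix.

    Returns (classes, all_missing): an array of class strings per column
    and a boolean mask of columns with no non-missing symbol at all
    (those are counted as conserved).
    """
    counts = np.stack([(codes == k).sum(axis=0) for k in range(4)])  # (4, n)
    n_present = (counts > 0).sum(axis=0)
    n_doubled = (counts >= 2).sum(axis=0)
    classes = np.where(
        n_present <= 1,
        CONSERVED,
        np.where(n_doubled >= 2, INFORMATIVE, VARIABLE),
    )
    all_missing = counts.sum(axis=0) == 0
    return classes, all_missing


def classify_site(column) -> str:
    """Classify one alignment column (sequence of one symbol per taxon)."""
    symbols = list(column)
    codes = np.array(
        [_SYMBOL_CODES.get(s.upper(), MISSING_CODE) for s in symbols],
        dtype=np.uint8,
    ).reshape(-1, 1)
    classes, _ = classify_columns(codes)
    return str(classes[0])


_SYMBOL_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def summarize(matrix: SeqMatrix, scheme: PartitionScheme) -> pd.DataFrame:
    """Per-partition site-class counts and proportions.

    Columns: partition, n_sites, n_conserved, n_variable,
    n_parsimony_informative, n_all_missing, prop_conserved, prop_variable,
    prop_parsimony_informative. n_variable includes informative sites, so
    n_conserved + n_variable = n_sites.
    """
    codes = matrix.codes()
    classes, all_missing = classify_columns(codes)
    rows = []
    for name, cols0 in scheme.items0():
        if cols0.size == 0:
            warnings.warn(f"partition {name!r} is empty", stacklevel=2)
        cls = classes[cols0]
        n = int(cols0.size)
        n_cons = int((cls == CONSERVED).sum())
        n_inf = int((cls == INFORMATIVE).sum())
        n_var = n - n_cons  # variable includes informative
        rows.append(
            {
                "partition": name,
                "n_sites": n,
                "n_conserved": n_cons,
                "n_variable": n_var,
                "n_parsimony_informative": n_inf,
                "n_all_missing": int(all_missing[cols0].sum()),
                "prop_conserved": n_cons / n if n else 0.0,
                "prop_variable": n_var / n if n else 0.0,
                "prop_parsimony_informative": n_inf / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)
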