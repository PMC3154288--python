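"""Equal-frequency discretization of numeric attributes.

Entropy-, chi-squared- and Gini-based weightings (and the OneR rule learner)
need categorical views of numeric attributes; values are cut at the
empirical quantiles so each bin holds roughly the same number of records.
Duplicate quantile edges collapse, so heavily tied attributes may end up
with fewer than the requested number of bins (down to a single bin for a
constant attribute).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DiscretizationConfig:
    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def equal_frequency_codes(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Integer bin codes in [0, n_bins) under equal-frequency cutting.

    An attribute with at most n_bins distinct values is passed through as-is
    (one bin per value): quantile cutting would otherwise merge the sparse
    levels of skewed binary/ternary attributes into a single bin. Otherwise
    edges are interior quantiles; a value equal to an edge goes to the lower
    bin, which keeps the coding deterministic under ties.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D attribute")
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
    edges = np.unique(np.quantile(x, qs))
    return np.digitize(x, edges, right=True)
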