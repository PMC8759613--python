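"""Natural cubic spline design basis for the study-time trend.

The long-run drift of a participant's pain reports over time since study
entry is modelled nonparametrically with a natural cubic spline in ``t``
(days since first pain entry).  The basis below follows the classical
``ns()``-style construction: boundary knots at the range of the observed
times, interior knots at quantiles, truncated-power differences that enforce
linearity beyond the boundary knots, and no intercept column.  Columns are
mean-centered so the basis carries no location information (the ordinal
cutpoints own the location of the latent scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class SplineBasis:
    """A fitted natural-cubic-spline basis that can be re-applied to new times."""

    knots: np.ndarray          # all knots, boundary included, ascending
    col_means: np.ndarray      # means subtracted from each column
    df: int                    # number of columns actually produced

    def transform(self, t_values: np.ndarray) -> np.ndarray:
        raw = _natural_spline_raw(np.asarray(t_values, dtype=float), self.knots)
        return raw - self.col_means


def _truncated_cubic(x: np.ndarray, knot: float) -> np.ndarray:
    return np.clip(x - knot, 0.0, None) ** 3


def _natural_spline_raw(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Uncentered natural cubic spline basis: [x, d_1-d_{K-1}, ..., d_{K-2}-d_{K-1}]."""
    kn = np.asarray(knots, dtype=float)
    K = kn.size
    if K < 2:
        # only a linear column is available
        return x[:, None].copy()

    xmax = kn[-1]

    def d(k: int) -> np.ndarray:
        return (_truncated_cubic(x, kn[k]) - _truncated_cubic(x, xmax)) / (xmax - kn[k])

    cols = [x]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)


def spline_basis(t_values: np.ndarray, df: int = 5,
                 knots: np.ndarray | None = None) -> tuple[np.ndarray, SplineBasis]:
    """Build a centered natural cubic spline basis over observed times.

    Parameters
    ----------
    t_values : array of non-negative times (days since entry).
    df : requested number of basis columns (>= 3).  ``df + 1`` knots are
        placed: boundary knots at min/max of ``t_values``, ``df - 1`` interior
        knots at quantiles of the distinct observed times.
    knots : optional explicit knot vector (ascending, boundary included);
        overrides the quantile rule.

    Returns
    -------
    (basis, SplineBasis) — basis has shape ``(len(t_values), df_eff)`` with
    mean-centered columns; ``df_eff`` may be smaller than ``df`` when there
    are too few distinct times to support the requested knots (a warning is
    logged).
    """
    t = np.asarray(t_values, dtype=float)
    if df < 3:
        raise ConfigurationError(f"spline df must be >= 3, got {df}")
    if t.size and t.min() < 0:
        raise ConfigurationError("spline times must be non-negative")

    if knots is None:
        distinct = np.unique(t)
        n_knots = df + 1
        if distinct.size < n_knots:
            n_knots = max(2, distinct.size)
            logger.warning(
                "only %d distinct time values; reducing spline knots to %d "
                "(df %d -> %d)", distinct.size, n_knots, df, n_knots - 1)
        qs = np.linspace(0, 1, n_knots)
        kn = np.quantile(distinct, qs)
        kn = np.unique(kn)
    else:
        kn = np.unique(np.asarray(knots, dtype=float))

    raw = _natural_spline_raw(t, kn)
    col_means = raw.mean(axis=0)
    basis = raw - col_means
    return basis, SplineBasis(knots=kn, col_means=col_means, df=basis.shape[1])
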