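"""Collinearity screening for candidate environmental variables.

Pairwise Pearson correlations are computed on values extracted at the
occurrence points (whole-raster correlation is available via
``pearson_matrix`` on any table).  Pairs with ``|r| >= threshold``
(default 0.8) are resolved greedily in descending ``|r|``, keeping the
member with the higher percent contribution from a preliminary
full-variable model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError

__all__ = [
    "CorrelationMatrix",
    "pearson_matrix",
    "prune",
    "two_pass_selection",
]


@dataclass
class CorrelationMatrix:
    names: list[str]
    r: np.ndarray
    constant: list[str]  # variables with zero variance, r defined as 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.names, columns=self.names)


def pearson_matrix(values, names=None) -> CorrelationMatrix:
    """Pearson correlation matrix of a points x variables table.

    Constant columns get r = 0 against every other variable (diagonal
    stays 1) and are flagged.  Requires at least 3 rows with no missing
    values.
    """
    if isinstance(values, pd.DataFrame):
        names = list(values.columns) if names is None else list(names)
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        if names is None:
            names = [f"v{i}" for i in range(x.shape[1])]
    if x.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 rows for a correlation matrix, got {x.shape[0]}"
        )
    if np.isnan(x).any():
        raise InsufficientDataError("correlation input contains missing values")
    sd = x.std(axis=0)
    const = sd == 0
    xc = x - x.mean(axis=0)
    sd_safe = np.where(const, 1.0, sd)
    z = xc / sd_safe
    r = (z.T @ z) / x.shape[0]
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMatrix(list(names), r, [n for n, c in zip(names, const) if c])


def prune(
    corr: CorrelationMatrix,
    contributions: dict[str, float],
    threshold: float = 0.8,
):
    """Drop one member of every surviving pair with ``|r| >= threshold``.

    Offending pairs are visited in descending ``|r|`` (ties broken by
    variable-name order); within a pair still alive, the lower-contribution
    member is dropped (contribution tie: the alphabetically later name).
    Returns ``(kept_names, drop_log)`` where drop_log rows are dicts with
    kept/dropped/r and both contributions.
    """
    missing = [n for n in corr.names if n not in contributions]
    if missing:
        raise ConfigError(f"contribution table missing variables: {missing}")

    n = len(corr.names)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr.r[i, j]) >= threshold:
                pairs.append((i, j))
    pairs.sort(key=lambda ij: (-abs(corr.r[ij[0], ij[1]]), corr.names[ij[0]], corr.names[ij[1]]))

    alive = set(corr.names)
    drop_log = []
    for i, j in pairs:
        a, b = corr.names[i], corr.names[j]
        if a not in alive or b not in alive:
            continue
        ca, cb = contributions[a], contributions[b]
        if ca > cb:
            keep, drop = a, b
        elif cb > ca:
            keep, drop = b, a
        else:
            keep, drop = sorted((a, b))  # tie: drop the later name
        alive.discard(drop)
        drop_log.append(
            {
                "kept": keep,
                "dropped": drop,
                "r": float(corr.r[i, j]),
                "contribution_kept": float(contributions[keep]),
                "contribution_dropped": float(contributions[drop]),
            }
        )
    kept = [name for name in corr.names if name in alive]

    # no surviving pair may still offend
    idx = [corr.names.index(k) for k in kept]
    sub = corr.r[np.ix_(idx, idx)]
    off = np.abs(sub - np.eye(len(idx)))
    assert (off < threshold).all() or not len(idx)
    return kept, drop_log


def two_pass_selection(
    values,
    params=None,
    threshold: float = 0.8,
    correlation_scope: str = "background",
):
    """Contribution-informed pruning.

    Pass 1 fits a preliminary maximum-entropy model on all candidate
    variables to obtain percent contributions; pass 2 prunes collinear
    pairs with :func:`prune`.  ``values`` is a dict with keys ``presence``
    and ``background``: DataFrames of raw variable values (same columns).

    ``correlation_scope`` selects the sample the correlations are computed
    on: ``"background"`` (default; a uniform sample of the study region,
    reflecting environmental collinearity) or ``"occurrences"`` (values at
    the presence points, which understates collinearity for
    range-restricted species through restriction-of-range attenuation).
    Returns ``(kept_names, drop_log, contributions)``.
    """
    from .maxent import MaxentParams, build_features, fit, percent_contribution

    params = params or MaxentParams()
    pres = values["presence"]
    bg = values["background"]
    Fp, Fb, expansion = build_features(pres, bg, params)
    model = fit(Fp, Fb, expansion, params)
    contrib = percent_contribution(model)
    if correlation_scope == "occurrences":
        corr_table = pres
    elif correlation_scope == "background":
        corr_table = bg[list(pres.columns)]
    else:
        raise ConfigError(f"unknown correlation scope {correlation_scope!r}")
    corr = pearson_matrix(corr_table)
    kept, drop_log = prune(corr, contrib, threshold=threshold)
    return kept, drop_log, contrib
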