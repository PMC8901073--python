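"""Alpha and beta diversity.

Alpha indices follow the conventions of the amplicon toolchain this package
mirrors: Shannon entropy in bits (log base 2), Pielou's evenness
H / log2(S_obs), Simpson as 1 - sum(p^2), bias-corrected Chao1, ACE with
rare-taxon cutoff 10, and Fisher's alpha solving S = a*ln(1 + N/a).
Richness estimators require integer raw counts (their formulas use
frequencies of frequencies); Shannon/Simpson-family indices may be computed
from CSS-normalized values, which only enter through proportions.

Beta diversity is Bray-Curtis, embedded by non-metric MDS and tested by
PERMANOVA with seeded label permutations (optionally restricted within
strata, e.g. pigs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.diversity import alpha as skalpha
from sklearn.manifold import smacof

from .config import substream
from .containers import NormalizedTable, OtuTable

RICHNESS_INDICES = ("observed_otus", "chao1", "ACE", "fisher_alpha")
PROPORTION_INDICES = ("shannon", "simpson", "equitability", "simpson_e")
ALL_INDICES = RICHNESS_INDICES + PROPORTION_INDICES


def _values(table) -> pd.DataFrame:
    return table.counts if isinstance(table, OtuTable) else table.values


def alpha_indices(table: OtuTable | NormalizedTable,
                  indices=ALL_INDICES, base: float = 2.0) -> pd.DataFrame:
    """Per-sample alpha-diversity indices (samples as rows).

    Raises if a richness estimator (chao1/ACE/fisher_alpha) is requested on
    non-integer values: those formulas need raw integer counts.
    """
    values = _values(table)
    arr = values.to_numpy(dtype=float)
    integral = np.allclose(arr, np.round(arr))
    needs_int = [i for i in indices if i in RICHNESS_INDICES and i !=
                 "observed_otus"]
    if needs_int and not integral:
        raise ValueError(
            f"indices {needs_int} require integer raw counts; "
            "compute them on the unnormalized table"
        )
    rows = {}
    for sample in values.columns:
        col = arr[:, values.columns.get_loc(sample)]
        col = col[col > 0]
        icol = np.round(col).astype(np.int64) if integral else None
        out = {}
        for name in indices:
            if name == "observed_otus":
                out[name] = float(col.size)
            elif name == "chao1":
                out[name] = float(skalpha.chao1(icol, bias_corrected=True))
            elif name == "ACE":
                # undefined when every rare taxon is a singleton
                try:
                    out[name] = float(skalpha.ace(icol, rare_threshold=10))
                except ValueError:
                    out[name] = float("nan")
            elif name == "fisher_alpha":
                try:
                    out[name] = float(skalpha.fisher_alpha(icol))
                except (ValueError, RuntimeError):
                    out[name] = float("nan")
            elif name == "shannon":
                out[name] = float(skalpha.shannon(col, base=base))
            elif name == "simpson":
                out[name] = float(skalpha.simpson(col))
            elif name == "equitability":
                out[name] = float(skalpha.pielou_e(col))
            elif name == "simpson_e":
                out[name] = float(skalpha.simpson_e(col))
            else:
                raise ValueError(f"unknown alpha index {name!r}")
        rows[sample] = out
    return pd.DataFrame.from_dict(rows, orient="index")[list(indices)]


def alpha_table(raw: OtuTable,
                normalized: NormalizedTable | None = None) -> pd.DataFrame:
    """Study convention: richness from raw counts, diversity/evenness from
    the CSS-normalized table (falling back to raw when not given)."""
    rich = alpha_indices(raw, indices=RICHNESS_INDICES)
    div = alpha_indices(normalized if normalized is not None else raw,
                        indices=PROPORTION_INDICES)
    return pd.concat([rich, div], axis=1)


def baseline_adjust(alpha: pd.DataFrame, metadata: pd.DataFrame,
                    baseline: str = "T0",
                    group_col: str = "treatment") -> pd.DataFrame:
    """Remove each treatment group's mean day-1 value from its series.

    After adjustment every group's mean at the baseline timepoint is exactly
    zero, removing between-group differences already present at birth;
    within-group differences between later timepoints are unchanged.
    """
    meta = metadata.loc[alpha.index]
    adjusted = alpha.copy().astype(float)
    for group, members in meta.groupby(group_col).groups.items():
        base_samples = members[meta.loc[members, "timepoint"] == baseline]
        if len(base_samples) == 0:
            raise ValueError(
                f"group {group!r} has no samples at baseline {baseline!r}")
        offsets = alpha.loc[base_samples].mean(axis=0)
        adjusted.loc[members] = alpha.loc[members] - offsets
    return adjusted


def bray_curtis(table: OtuTable | NormalizedTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix between samples:
    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    values = _values(table)
    if values.shape[1] < 2:
        raise ValueError("need at least two samples")
    dist = pdist(values.T.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(dist), ids=list(values.columns))


def _classical_mds(d2: np.ndarray, k: int) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    w = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w)


def nmds(dist: DistanceMatrix, k: int = 2, seed: int = 0,
         max_iter: int = 300) -> tuple[pd.DataFrame, float]:
    """Non-metric MDS of a distance matrix by iterative majorization.

    Starts from the classical (metric) scaling solution and minimizes
    Kruskal stress-1 over monotone transformations of the input distances.
    Returns the k-dimensional coordinates and the final stress.
    """
    d = dist.data
    n = d.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    init = _classical_mds(d ** 2, k)
    coords, stress = smacof(
        d, metric=False, n_components=k, init=init, n_init=1,
        max_iter=max_iter, eps=1e-9, normalized_stress=True,
        random_state=int(seed) % (2 ** 32),
    )
    return (pd.DataFrame(coords, index=list(dist.ids),
                         columns=[f"NMDS{i + 1}" for i in range(k)]),
            float(stress))


def _pseudo_f(d2: np.ndarray, labels: np.ndarray,
              groups: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    k = groups.size
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(dist: DistanceMatrix, grouping, n_perm: int = 999,
              seed: int = 0, strata=None) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F compares among-group to within-group sums of squared
    distances; the p-value is (#{permuted F >= observed} + 1)/(n_perm + 1),
    with labels shuffled freely or within ``strata`` when given (e.g.
    restrict to permutations within pigs for repeated measures).
    """
    labels = np.asarray(pd.Series(grouping).to_numpy())
    d2 = dist.data.astype(float) ** 2
    n = d2.shape[0]
    if labels.size != n:
        raise ValueError("grouping length does not match distance matrix")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two groups")
    observed = _pseudo_f(d2, labels, groups)
    rng = substream(seed, "permanova")
    if strata is None:
        strata_idx = [np.arange(n)]
    else:
        strata = np.asarray(pd.Series(strata).to_numpy())
        strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    # permuted labels, one row per permutation
    perm_labels = np.tile(labels, (n_perm, 1))
    for idx in strata_idx:
        for row in perm_labels:
            row[idx] = row[idx[rng.permutation(idx.size)]]
    # vectorized SS_within across permutations
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = np.zeros(n_perm)
    for g in groups:
        m = (perm_labels == g).astype(float)
        n_g = m[0].sum()
        if n_g > 0:
            quad = np.einsum("pi,ij,pj->p", m, d2, m) / 2.0
            ss_within += quad / n_g
    k = groups.size
    perm_f = ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))
    p = (np.count_nonzero(perm_f >= observed) + 1) / (n_perm + 1)
    return {"pseudo_F": float(observed), "p_value": float(p),
            "n_perm": int(n_perm)}
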