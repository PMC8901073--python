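"""Repeated-measures linear models for longitudinal microbiome responses.

The model for a per-sample response y (an alpha-diversity index, a
normalized OTU count, or the F:B ratio) is

    y = X beta + pig + e

with fixed effects of diet treatment and timepoint (optionally their
interaction), a random intercept per pig with variance sigma2_pig, and
residuals correlated within pig across the four sampling timepoints by a
stationary first-order autoregression with parameter rho (correlation
rho**lag on the timepoint order; the uneven day spacing 1/12/26/58 is not
used). Variance parameters are estimated by REML with the residual scale
profiled out, fixed effects by generalized least squares at the optimum,
and each fixed term is tested with a Wald F using containment denominator
degrees of freedom n_obs - n_pigs - rank(X) + 1.

The Firmicutes:Bacteroidetes (F:B) ratio utilities and its stratified
bootstrap (resampling samples with replacement within treatment x
timepoint cells, replicate refits of the interaction model) live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import substream
from .containers import (NormalizedTable, TIMEPOINTS, TREATMENTS)

logger = logging.getLogger(__name__)

_CANONICAL_LEVELS = {
    "treatment": list(TREATMENTS),
    "timepoint": list(TIMEPOINTS),
    "period": ["pre", "post"],
}

_RHO_CAP = 0.999


# ------------------------------------------------------------- design

def _levels(meta: pd.DataFrame, factor: str) -> list:
    observed = list(pd.unique(meta[factor]))
    canonical = _CANONICAL_LEVELS.get(factor)
    if canonical and set(observed) <= set(canonical):
        return [l for l in canonical if l in observed]
    return sorted(observed)


def build_design(meta: pd.DataFrame, factors, interaction: bool = False):
    """Reference-cell design matrix with named term blocks.

    Returns (X, term_columns, column_names) where term_columns maps each
    fixed term (factor name or 'a:b') to its column indices in X.
    """
    n = len(meta)
    cols = [np.ones(n)]
    names = ["intercept"]
    term_columns: dict[str, list[int]] = {}
    factor_dummies = {}
    for f in factors:
        levels = _levels(meta, f)
        dummies = []
        idxs = []
        for level in levels[1:]:
            cols.append((meta[f] == level).to_numpy(dtype=float))
            names.append(f"{f}[{level}]")
            idxs.append(len(cols) - 1)
            dummies.append((level, cols[-1]))
        factor_dummies[f] = dummies
        term_columns[f] = idxs
    if interaction:
        if len(factors) != 2:
            raise ValueError("interaction requires exactly two factors")
        a, b = factors
        idxs = []
        for la, ca in factor_dummies[a]:
            for lb, cb in factor_dummies[b]:
                cols.append(ca * cb)
                names.append(f"{a}[{la}]:{b}[{lb}]")
                idxs.append(len(cols) - 1)
        term_columns[f"{a}:{b}"] = idxs
    X = np.column_stack(cols)
    return X, term_columns, names


def _blocks(meta: pd.DataFrame, X: np.ndarray, y: np.ndarray,
            pig_col: str, timepoint_col: str):
    """Group observations by pig, pigs by identical timepoint pattern.

    Returns a list of (t_indices, X3, Y2) with X3 of shape
    (n_pigs_in_pattern, n_times, p) ready for vectorized block algebra.
    """
    order = {t: i for i, t in enumerate(TIMEPOINTS)}
    t_idx = meta[timepoint_col].map(order).to_numpy()
    pigs = meta[pig_col].to_numpy()
    by_pattern: dict[tuple, list[tuple[np.ndarray, np.ndarray]]] = {}
    for pig in pd.unique(pigs):
        rows = np.flatnonzero(pigs == pig)
        rows = rows[np.argsort(t_idx[rows], kind="stable")]
        pattern = tuple(t_idx[rows])
        by_pattern.setdefault(pattern, []).append(rows)
    out = []
    for pattern, row_groups in by_pattern.items():
        idx = np.array(row_groups)  # (m, nt)
        t = np.asarray(pattern, dtype=float)
        X3, Y2 = X[idx], y[idx]
        p = X.shape[1]
        # precomputed pieces reused at every likelihood evaluation
        out.append({
            "lag": np.abs(t[:, None] - t[None, :]),
            "X3": X3,
            "Xflat": X3.reshape(-1, p),
            "Y2": Y2,
            "m": X3.shape[0],
        })
    return out


# --------------------------------------------------------------- REML

def _gls_pieces(blocks, gamma: float, rho: float):
    """Sum of per-pig block quadratic forms under W = gamma*J + AR1(rho)."""
    p = blocks[0]["Xflat"].shape[1]
    xtwix = np.zeros((p, p))
    xtwiy = np.zeros(p)
    ytwiy = 0.0
    sum_logdet = 0.0
    for blk in blocks:
        lag = blk["lag"]
        W = gamma + np.where(lag == 0, 1.0, rho ** lag)
        sign, logdet = np.linalg.slogdet(W)
        if sign <= 0:
            return None
        Wi = np.linalg.inv(W)
        sum_logdet += blk["m"] * logdet
        WiX = np.matmul(Wi, blk["X3"])          # (m, nt, p)
        WiY = blk["Y2"] @ Wi.T                   # (m, nt)
        xtwix += blk["Xflat"].T @ WiX.reshape(-1, p)
        xtwiy += blk["Xflat"].T @ WiY.reshape(-1)
        ytwiy += float((blk["Y2"] * WiY).sum())
    return xtwix, xtwiy, ytwiy, sum_logdet


def _profiled_neg2(blocks, n: int, p: int, gamma: float, rho: float):
    pieces = _gls_pieces(blocks, gamma, rho)
    if pieces is None:
        return np.inf, None
    xtwix, xtwiy, ytwiy, sum_logdet = pieces
    sign, logdet_x = np.linalg.slogdet(xtwix)
    if sign <= 0:
        return np.inf, None
    beta = np.linalg.solve(xtwix, xtwiy)
    ypy = ytwiy - float(xtwiy @ beta)
    if ypy <= 0:
        return np.inf, None
    neg2 = (n - p) * np.log(ypy) + sum_logdet + logdet_x
    return neg2, (beta, xtwix, ypy)


def reml_loglik(response: pd.Series, metadata: pd.DataFrame,
                sigma2_pig: float, sigma2_e: float, rho: float,
                factors=("treatment", "timepoint"),
                interaction: bool = False,
                pig_col: str = "pig",
                timepoint_col: str = "timepoint") -> float:
    """Restricted log-likelihood at arbitrary admissible variance
    parameters (used for local-optimum sanity checks)."""
    meta = metadata.loc[response.index]
    X, _, _ = build_design(meta, factors, interaction)
    y = response.to_numpy(dtype=float)
    blocks = _blocks(meta, X, y, pig_col, timepoint_col)
    n, p = X.shape
    gamma = sigma2_pig / sigma2_e
    pieces = _gls_pieces(blocks, gamma, rho)
    if pieces is None:
        return -np.inf
    xtwix, xtwiy, ytwiy, sum_logdet = pieces
    sign, logdet_x = np.linalg.slogdet(xtwix)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtwix, xtwiy)
    ypy = ytwiy - float(xtwiy @ beta)
    # V = sigma2_e * W; translate W-scale pieces to V scale
    return -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + n * np.log(sigma2_e) + sum_logdet
        + logdet_x - p * np.log(sigma2_e)
        + ypy / sigma2_e
    )


@dataclass
class ModelFit:
    """REML fit: variance components, GLS fixed effects, per-term F tests."""

    coefficients: pd.Series
    cov: pd.DataFrame
    sigma2_pig: float
    sigma2_e: float
    rho: float
    terms: pd.DataFrame  # index: term; columns: F, p_value, df_num, df_den
    n_obs: int
    n_pigs: int
    converged: bool = True
    rho_at_boundary: bool = False
    reml: float = float("nan")


def fit_repeated_model(response: pd.Series, metadata: pd.DataFrame,
                       factors=("treatment", "timepoint"),
                       interaction: bool = False,
                       pig_col: str = "pig",
                       timepoint_col: str = "timepoint",
                       fix_rho: float | None = None,
                       fix_gamma: float | None = None) -> ModelFit:
    """Fit the AR(1) + random-pig-intercept model by REML.

    ``fix_rho``/``fix_gamma`` pin the autocorrelation or the variance ratio
    sigma2_pig/sigma2_e (0 reduces the fit to ordinary least squares when
    both are pinned to 0).
    """
    meta = metadata.loc[response.index]
    X, term_columns, names = build_design(meta, factors, interaction)
    y = response.to_numpy(dtype=float)
    n, p = X.shape
    n_pigs = meta[pig_col].nunique()
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient fixed-effect design")
    df_den = max(n - n_pigs - p + 1, 1)

    if np.allclose(y, y[0]):
        # constant response: no information on any term
        terms = pd.DataFrame(
            {"F": 0.0, "p_value": 1.0,
             "df_num": [len(v) for v in term_columns.values()],
             "df_den": df_den},
            index=list(term_columns),
        )
        coef = pd.Series(np.zeros(p), index=names)
        coef["intercept"] = y[0]
        return ModelFit(coef, pd.DataFrame(np.zeros((p, p)), index=names,
                                           columns=names),
                        0.0, 0.0, 0.0, terms, n, n_pigs)

    blocks = _blocks(meta, X, y, pig_col, timepoint_col)

    free = []
    if fix_rho is None:
        free.append("rho")
    if fix_gamma is None:
        free.append("gamma")

    def unpack(theta):
        i = 0
        if fix_rho is None:
            rho = _RHO_CAP * np.tanh(theta[i]); i += 1
        else:
            rho = fix_rho
        if fix_gamma is None:
            gamma = np.exp(np.clip(theta[i], -15, 15))
        else:
            gamma = fix_gamma
        return gamma, rho

    converged = True
    if free:
        def objective(theta):
            gamma, rho = unpack(theta)
            return _profiled_neg2(blocks, n, p, gamma, rho)[0]

        x0 = np.zeros(len(free))
        if fix_gamma is None:
            x0[-1] = np.log(0.5)
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-7,
                                         "maxiter": 1000})
        converged = bool(res.success)
        theta = res.x
    else:
        theta = np.zeros(0)

    gamma, rho = unpack(theta)
    neg2, payload = _profiled_neg2(blocks, n, p, gamma, rho)
    if payload is None:
        raise RuntimeError(
            f"REML optimization failed at gamma={gamma}, rho={rho}")
    beta, xtwix, ypy = payload
    sigma2_e = ypy / (n - p)
    sigma2_pig = gamma * sigma2_e
    cov = sigma2_e * np.linalg.inv(xtwix)

    rows = {}
    for term, idx in term_columns.items():
        q = len(idx)
        b = beta[idx]
        sub = cov[np.ix_(idx, idx)]
        f_stat = float(b @ np.linalg.solve(sub, b)) / q
        rows[term] = {"F": f_stat,
                      "p_value": float(stats.f.sf(f_stat, q, df_den)),
                      "df_num": q, "df_den": df_den}
    terms = pd.DataFrame.from_dict(rows, orient="index")

    reml = reml_loglik(response, metadata, max(sigma2_pig, 1e-300),
                       sigma2_e, rho, factors, interaction,
                       pig_col, timepoint_col) if sigma2_e > 0 else np.nan
    return ModelFit(
        coefficients=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        sigma2_pig=float(sigma2_pig), sigma2_e=float(sigma2_e),
        rho=float(rho), terms=terms, n_obs=n, n_pigs=n_pigs,
        converged=converged,
        rho_at_boundary=bool(abs(rho) >= 0.99), reml=float(reml),
    )


# ------------------------------------------------- per-OTU differential

def per_otu_tests(norm: NormalizedTable, alpha: float = 0.05,
                  factors=("treatment", "timepoint"),
                  level: str = "otu") -> pd.DataFrame:
    """Fit the repeated-measures model to each taxon's normalized counts.

    Returns per-taxon F and p for every fixed term plus a ``significant``
    flag for the treatment term at the given alpha (no multiplicity
    correction, matching the study's raw p < 0.05 cutoff). Taxa that are
    all-zero within some treatment x timepoint cell, or constant overall,
    are skipped and logged.
    """
    meta = norm.metadata
    cell = meta["treatment"].astype(str) + "/" + meta["timepoint"].astype(str)
    rows = []
    for taxon, values in norm.values.iterrows():
        v = values.astype(float)
        zero_cell = (v.groupby(cell).apply(lambda s: (s == 0).all())).any()
        if zero_cell or np.allclose(v, v.iloc[0]):
            logger.info("skipping degenerate taxon %s at level %s",
                        taxon, level)
            continue
        fit = fit_repeated_model(v, meta, factors=factors)
        row = {"taxon": taxon, "level": level}
        for term in fit.terms.index:
            row[f"F_{term}"] = fit.terms.loc[term, "F"]
            row[f"p_{term}"] = fit.terms.loc[term, "p_value"]
        row["significant"] = bool(row.get("p_treatment", 1.0) < alpha)
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------ F:B ratio

def fb_ratio(norm: NormalizedTable) -> pd.DataFrame:
    """Per-sample Firmicutes:Bacteroidetes ratio from normalized counts.

    Samples with a zero Bacteroidetes sum are excluded (undefined ratio)
    with a warning in the log.
    """
    phylum = norm.lineages["phylum"]
    firm = norm.values.loc[phylum == "Firmicutes"].sum(axis=0)
    bact = norm.values.loc[phylum == "Bacteroidetes"].sum(axis=0)
    out = pd.DataFrame({"firmicutes_sum": firm, "bacteroidetes_sum": bact})
    bad = out["bacteroidetes_sum"] <= 0
    if bad.any():
        logger.warning("excluding %d sample(s) with zero Bacteroidetes: %s",
                       bad.sum(), list(out.index[bad]))
        out = out.loc[~bad]
    out["ratio"] = out["firmicutes_sum"] / out["bacteroidetes_sum"]
    return out


def fb_cell_medians(fb: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Median F:B per treatment x period cell."""
    meta = metadata.loc[fb.index]
    med = fb["ratio"].groupby(
        [meta["treatment"], meta["period"]]).median()
    out = med.rename("median_FB").reset_index()
    return out


def fb_model(fb: pd.DataFrame, metadata: pd.DataFrame,
             interaction: bool = True) -> ModelFit:
    """Repeated-measures model of the F:B ratio on period (pre/post
    weaning), treatment and, by default, their interaction."""
    return fit_repeated_model(fb["ratio"], metadata,
                              factors=("period", "treatment"),
                              interaction=interaction)


# ------------------------------------------------------------ bootstrap

@dataclass
class BootstrapResult:
    """Replicate-level and summarized bootstrap output for the F:B model."""

    n_boot: int
    seed: int
    replicate_terms: pd.DataFrame   # replicate x (term stat/p columns)
    term_summary: pd.DataFrame      # per term: statistic_bstr, p_value_bstr
    cell_summary: pd.DataFrame      # treatment, period, median_FB, Q1, Q3
    n_redrawn: int = 0


def bootstrap_fb(norm: NormalizedTable, n_boot: int = 1000, seed: int = 0,
                 unit: str = "sample", interaction: bool = True,
                 max_redraws: int = 100) -> BootstrapResult:
    """Bootstrap the F:B analysis.

    Each replicate resamples with replacement within treatment x timepoint
    cells (``unit="sample"``; drawn samples are placed onto the cell's
    original pig/timepoint design slots so the repeated-measures model stays
    estimable) or resamples whole pigs within treatment (``unit="pig"``),
    recomputes every sample's F:B ratio and refits the model. Summaries are
    the per-term medians of the replicate statistics/p-values and, per
    treatment x period cell, the observed median F:B with the first and
    third quartiles of the bootstrapped per-sample F:B distribution (all
    replicate samples in the cell pooled).
    """
    if unit not in ("sample", "pig", "identity"):
        raise ValueError(f"unknown bootstrap unit {unit!r}")
    rng = substream(seed, "bootstrap_fb")
    meta = norm.metadata
    fb_obs = fb_ratio(norm)
    observed_cells = fb_cell_medians(fb_obs, meta)

    cell = meta["treatment"].astype(str) + "/" + meta["timepoint"].astype(str)
    cell_slots = {c: list(idx) for c, idx in
                  meta.groupby(cell).groups.items()}
    pigs_by_treatment = {
        t: list(pd.unique(meta.loc[meta["treatment"] == t, "pig"]))
        for t in pd.unique(meta["treatment"])
    }
    samples_of_pig = {p: list(idx) for p, idx in
                      meta.groupby("pig").groups.items()}
    tp_of_sample = meta["timepoint"]

    replicate_rows = []
    cell_rows = []
    n_redrawn = 0
    for b in range(n_boot):
        for _attempt in range(max_redraws):
            mapping = {}
            if unit == "identity":  # degenerate resample: each sample once
                mapping = {s: s for s in meta.index}
            elif unit == "sample":
                for c, slots in cell_slots.items():
                    draws = rng.choice(slots, size=len(slots), replace=True)
                    mapping.update(dict(zip(slots, draws)))
            else:
                for t, pigs in pigs_by_treatment.items():
                    draws = rng.choice(pigs, size=len(pigs), replace=True)
                    for slot_pig, drawn_pig in zip(pigs, draws):
                        drawn = {tp_of_sample[s]: s
                                 for s in samples_of_pig[drawn_pig]}
                        for s in samples_of_pig[slot_pig]:
                            mapping[s] = drawn.get(tp_of_sample[s], s)
            resampled = norm.values[[mapping[s] for s in meta.index]]
            resampled.columns = meta.index
            boot = NormalizedTable(
                values=resampled, scaling_factors=norm.scaling_factors,
                scale_constant=norm.scale_constant, lineages=norm.lineages,
                metadata=meta[["pig", "treatment", "timepoint"]],
                quantile=norm.quantile)
            fb = fb_ratio(boot)
            # a replicate must keep every design cell populated
            if len(fb) < len(meta) and (
                fb_cell_medians(fb, meta).shape[0]
                < observed_cells.shape[0]
            ):
                n_redrawn += 1
                logger.info("redrawing degenerate bootstrap replicate %d", b)
                continue
            break
        else:
            raise RuntimeError(f"replicate {b}: too many degenerate redraws")
        fit = fb_model(fb, meta, interaction=interaction)
        row = {"replicate": b}
        for term in fit.terms.index:
            row[f"{term}_statistic"] = fit.terms.loc[term, "F"]
            row[f"{term}_p"] = fit.terms.loc[term, "p_value"]
        replicate_rows.append(row)
        cells = pd.DataFrame({
            "ratio": fb["ratio"],
            "treatment": meta.loc[fb.index, "treatment"],
            "period": meta.loc[fb.index, "period"],
        })
        cell_rows.append(cells)

    replicate_terms = pd.DataFrame(replicate_rows).set_index("replicate")
    terms = sorted({c[:-len("_statistic")] for c in replicate_terms.columns
                    if c.endswith("_statistic")})
    term_summary = pd.DataFrame({
        "statistic_bstr": [replicate_terms[f"{t}_statistic"].median()
                           for t in terms],
        "p_value_bstr": [replicate_terms[f"{t}_p"].median() for t in terms],
    }, index=terms)

    all_cells = pd.concat(cell_rows, ignore_index=True)
    q = all_cells.groupby(["treatment", "period"])["ratio"].quantile(
        [0.25, 0.75]).unstack()
    q.columns = ["Q1_bstr", "Q3_bstr"]
    cell_summary = observed_cells.merge(q.reset_index(),
                                        on=["treatment", "period"])
    return BootstrapResult(
        n_boot=n_boot, seed=seed, replicate_terms=replicate_terms,
        term_summary=term_summary, cell_summary=cell_summary,
        n_redrawn=n_redrawn,
    )
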