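"""Downstream single-cell analyses.

Once each cell carries its own parameter estimates, cell-to-cell
variability becomes a measurement channel in its own right:

* ``perceived_shock`` scores how strongly each cell experienced the
  osmotic shocks (time-averaged relative volume drop after shock
  onsets);
* ``correlate_features`` relates parameters to physiological features
  via Spearman rank correlations;
* ``pca_rank`` decomposes the multivariate parameter variability into
  principal components and ranks features by their variance-weighted
  average correlation with the PCs;
* ``inheritance_test`` asks whether mother/daughter (MD) parameter
  pairs are closer than non-related mother/daughter (nMD) pairs, via a
  bootstrap over resampled pair sets;
* ``md_feature_comparison`` compares a feature between daughters and
  their mothers (mean relative difference + rank correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .input_model import ShockSchedule

__all__ = ["PcaSummary", "InheritanceReport", "perceived_shock",
           "correlate_features", "pca_rank", "inheritance_test",
           "md_feature_comparison"]


def perceived_shock(trace_times: np.ndarray, trace_values: np.ndarray,
                    schedule: ShockSchedule, post_window_min: float = 12.0,
                    pre_window_min: float = 6.0) -> float:
    """Time-averaged relative volume (or size) reduction following shocks.

    For each shock whose onset the trace covers, the relative drop is
    (V_pre − V_post)/V_pre with V_pre the mean over ``pre_window_min``
    before onset and V_post the minimum within ``post_window_min`` after
    onset.  Returns the mean over observed shocks, or NaN when the trace
    covers none.
    """
    t = np.asarray(trace_times, dtype=float)
    v = np.asarray(trace_values, dtype=float)
    drops = []
    for start, _end in schedule.intervals:
        pre = v[(t >= start - pre_window_min) & (t < start)]
        post = v[(t >= start) & (t <= start + post_window_min)]
        if len(pre) == 0 or len(post) == 0:
            continue
        v_pre = float(np.mean(pre))
        if v_pre <= 0:
            continue
        drops.append((v_pre - float(np.min(post))) / v_pre)
    return float(np.mean(drops)) if drops else float("nan")


def correlate_features(params: pd.DataFrame, features: pd.DataFrame,
                       min_pairs: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlation of every parameter (or PC) column with
    every feature column, with two-tailed p-values.

    Rows with missing entries are dropped pairwise; constant columns
    yield NaN.  Returns (rho, p) DataFrames indexed by parameter.
    """
    common = params.index.intersection(features.index)
    if len(common) < min_pairs:
        raise ValueError(f"need >= {min_pairs} paired rows, got {len(common)}")
    P = params.loc[common]
    F = features.loc[common]
    rho = pd.DataFrame(index=P.columns, columns=F.columns, dtype=float)
    pval = pd.DataFrame(index=P.columns, columns=F.columns, dtype=float)
    for pc in P.columns:
        for fc in F.columns:
            x = P[pc].to_numpy(dtype=float)
            y = F[fc].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_pairs or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rho.loc[pc, fc] = np.nan
                pval.loc[pc, fc] = np.nan
                continue
            r, p = stats.spearmanr(x[ok], y[ok])
            rho.loc[pc, fc] = r
            pval.loc[pc, fc] = p
    return rho, pval


@dataclass
class PcaSummary:
    """PCA of the standardized log-parameters with feature ranking."""

    loadings: np.ndarray            # (4, k) orthonormal columns
    variance_fractions: np.ndarray  # (k,) non-negative, sums to 1
    pc_scores: pd.DataFrame         # per-cell PC coordinates
    feature_correlations: pd.DataFrame  # (PC x feature) Spearman rho
    feature_pvalues: pd.DataFrame
    feature_scores: pd.Series       # weighted average |rho| per feature

    @property
    def ranked_features(self) -> list[str]:
        return list(self.feature_scores.sort_values(ascending=False).index)


def pca_rank(log_params: pd.DataFrame, features: pd.DataFrame | None = None,
             min_cells: int = 10) -> PcaSummary:
    """Principal-component analysis of the per-cell log-parameters and
    variance-weighted feature ranking.

    Parameters are standardized before the PCA.  Each feature's score
    is Σ_c varfrac_c · |ρ(PC_c, feature)| — its average correlation
    with the parameter variability, weighted by how much variability
    each component carries.  Components beyond the matrix rank get zero
    variance fraction.
    """
    X = log_params.to_numpy(dtype=float)
    n, d = X.shape
    if n < min_cells or d < 2:
        raise ValueError("need >= 10 cells and >= 2 parameters")
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - X.mean(axis=0)) / sd_safe
    pca = PCA(n_components=d)
    scores = pca.fit_transform(Xs)
    frac = pca.explained_variance_ratio_.copy()
    frac[frac < 1e-12] = 0.0
    frac = frac / frac.sum()
    pc_names = [f"PC{i+1}" for i in range(d)]
    pc_scores = pd.DataFrame(scores, index=log_params.index, columns=pc_names)

    if features is not None and len(features.columns) > 0:
        rho, pval = correlate_features(pc_scores, features, min_pairs=min_cells)
        weighted = (np.abs(rho).T * frac).T.sum(axis=0)
    else:
        rho = pd.DataFrame(index=pc_names)
        pval = pd.DataFrame(index=pc_names)
        weighted = pd.Series(dtype=float)
    return PcaSummary(loadings=pca.components_.T, variance_fractions=frac,
                      pc_scores=pc_scores, feature_correlations=rho,
                      feature_pvalues=pval, feature_scores=weighted)


@dataclass
class InheritanceReport:
    """Bootstrap comparison of MD vs nMD parameter distances."""

    per_parameter: pd.DataFrame  # mean_md, mean_nmd, closeness_pct, p_value
    n_pairs: int
    n_boot: int
    distance: str = "abs_log_diff"


def _md_pairs(params: pd.DataFrame, lineage: pd.DataFrame):
    """Indices of (mother, daughter) pairs present in the params table."""
    pairs = []
    for _, row in lineage.iterrows():
        d, m = row["daughter_id"], row["mother_id"]
        if d in params.index and m in params.index:
            pairs.append((m, d))
    return pairs


def inheritance_test(
    params: pd.DataFrame,
    lineage: pd.DataFrame,
    n_pairs: int = 40,
    n_boot: int = 50000,
    rng: np.random.Generator | int | None = None,
    distance: str = "abs_log_diff",
    columns: tuple[str, ...] | None = None,
) -> InheritanceReport:
    """Bootstrap test of parameter inheritance from mother to daughter.

    Per parameter, the pair distance is |ln θ_daughter − ln θ_mother|.
    The observed statistic is the mean distance over all available MD
    pairs; its null reference distribution is built from ``n_boot``
    random *rematchings*: each null set permutes the daughters across
    the mothers (assignments pairing a mother with her own daughter are
    rejected and redrawn), so every null set is a full nMD matching
    with the same structure as the observed MD matching — each mother
    and each daughter used exactly once.  The one-sided p-value is the
    (add-one corrected) fraction of null matchings whose mean distance
    is <= the observed MD mean, i.e. the probability that non-related
    mother/daughter pairings look at least as close as the true ones.
    This permutation construction is exactly calibrated when daughters
    are exchangeable across mothers (no inheritance).  The closeness
    percentage is 100·(1 − mean(MD)/mean(nMD)) with mean(nMD) taken
    over every valid non-related pairing.

    ``n_pairs`` is the minimum number of MD pairs required for the test
    to run.
    """
    if distance != "abs_log_diff":
        raise ValueError(f"unknown distance {distance!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cols = list(columns) if columns is not None else list(params.columns)
    pairs = _md_pairs(params, lineage)
    if len(pairs) < n_pairs:
        raise ValueError(f"need >= {n_pairs} MD pairs, got {len(pairs)}")
    mothers = [m for m, _ in pairs]
    daughters = [d for _, d in pairs]
    mother_of = {d: m for m, d in pairs}
    logs = np.log(params[cols].to_numpy(dtype=float))
    row = {cid: i for i, cid in enumerate(params.index)}
    mi = np.array([row[m] for m in mothers])
    di = np.array([row[d] for d in daughters])

    md_dist = np.abs(logs[di] - logs[mi])  # (n_md, n_cols)

    # nMD distance matrix: every mother x every non-own daughter
    n_md = len(pairs)
    D = np.abs(logs[di][None, :, :] - logs[mi][:, None, :])  # (mother, daughter, col)
    own = np.array([[mother_of[daughters[j]] == mothers[i] for j in range(n_md)]
                    for i in range(n_md)])
    valid = ~own
    if not valid.any(axis=1).all():
        raise ValueError("some mother has no non-related daughter available")

    obs_md = md_dist.mean(axis=0)  # (n_cols,)

    # null reference: random daughter-permutations without own-mother
    # assignments (rows with clashes are re-permuted until clean);
    # processed in chunks to bound memory
    null_means = np.empty((n_boot, len(cols)))
    rows = np.arange(n_md)
    chunk = max(1, min(n_boot, 4_000_000 // max(n_md, 1)))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        perms = rng.permuted(np.tile(rows, (b, 1)), axis=1)
        bad = np.flatnonzero(~valid[rows[None, :], perms].all(axis=1))
        for _ in range(10_000):
            if len(bad) == 0:
                break
            perms[bad] = rng.permuted(perms[bad], axis=1)
            bad = bad[~valid[rows[None, :], perms[bad]].all(axis=1)]
        else:  # pragma: no cover - only reachable for pathological lineages
            raise RuntimeError("could not draw clash-free daughter permutations")
        null_means[done:done + b] = D[rows[None, :], perms].mean(axis=1)
        done += b

    flat_nmd = np.array([D[:, :, c][valid].mean() for c in range(len(cols))])

    records = []
    for c, col in enumerate(cols):
        mean_md = float(obs_md[c])
        mean_nmd = float(flat_nmd[c])
        p = float((1 + np.sum(null_means[:, c] <= mean_md)) / (n_boot + 1))
        closeness = 100.0 * (1.0 - mean_md / mean_nmd) if mean_nmd > 0 else np.nan
        records.append({"parameter": col, "mean_md": mean_md, "mean_nmd": mean_nmd,
                        "closeness_pct": closeness, "p_value": p})
    table = pd.DataFrame(records).set_index("parameter")
    return InheritanceReport(per_parameter=table, n_pairs=n_pairs, n_boot=n_boot,
                             distance=distance)


def md_feature_comparison(features: pd.DataFrame, lineage: pd.DataFrame,
                          column: str, min_pairs: int = 10) -> dict:
    """Daughter-vs-mother comparison of one feature.

    Returns the mean relative difference mean((f_d − f_m)/f_m) — e.g.
    +0.14 means daughters are on average 14% higher — and the Spearman
    correlation between mothers' and daughters' values with its p-value
    (negative rho: the feature is anti-inherited).  Pairs whose mother
    value is zero are dropped with a warning count.
    """
    pairs = _md_pairs(features[[column]].dropna(), lineage)
    f = features[column]
    fm = np.array([f[m] for m, _ in pairs], dtype=float)
    fd = np.array([f[d] for _, d in pairs], dtype=float)
    nonzero = fm != 0
    n_dropped = int((~nonzero).sum())
    fm, fd = fm[nonzero], fd[nonzero]
    if len(fm) < min_pairs:
        raise ValueError(f"need >= {min_pairs} MD pairs with nonzero mother "
                         f"feature, got {len(fm)}")
    rel_diff = float(np.mean((fd - fm) / fm))
    rho, p = stats.spearmanr(fm, fd)
    return {"mean_relative_difference": rel_diff, "spearman_rho": float(rho),
            "p_value": float(p), "n_pairs": int(len(fm)),
            "n_dropped_zero_mother": n_dropped}
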