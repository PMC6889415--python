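"""Statistics for redox-, total- and phospho-proteome matrices.

The pipeline order mirrors how multiplexed redox/phospho intensity data
are processed in practice: per-sample log2/median/SD normalization within
each treatment-time condition; protein-abundance correction of late
(24 h) redox values; missing-value imputation (k-nearest-neighbour for
sporadic missingness, random-tail draws for condition-structured
missingness); empirical-Bayes moderated two-sample tests with
Benjamini-Hochberg control; direction-based integration of two contrasts
via rotated signed z-scores; kinase-substrate fidelity statistics
(one-sided Bartlett variance and one-sided t); probabilistic PCA by EM
with missing-data support; and per-group median coefficient of variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .matrix import OmicsMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def log2_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Log2-transform without centring or scaling.

    For data already on a common scale across samples (e.g. generated
    matrices without sample-loading effects), where median centring would
    only inject bias when regulation is one-sided. Real acquisitions with
    per-sample loading/labelling offsets need :func:`normalize` instead.
    """
    if matrix.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    out = matrix.copy()
    out.values = np.log2(out.values)
    out.scale = "log2-normalized"
    return out


def normalize(matrix: OmicsMatrix, scale_estimator: str = "sd") -> OmicsMatrix:
    """Log2-transform, median-centre and scale each sample column.

    Centring and scaling use the observed values of each column; columns
    are processed within their (treatment, time) condition, and the scale
    statistic is per-sample (``sd``, default, ddof=1) or ``mad``
    (normalized median absolute deviation).
    """
    if matrix.scale != "linear":
        raise ValueError("matrix is already normalized (scale flag is not 'linear')")
    if scale_estimator not in ("sd", "mad"):
        raise ValueError(f"unknown scale estimator {scale_estimator!r}")
    out = matrix.copy()
    vals = np.log2(out.values.to_numpy(dtype=float))
    for _, group in out.samples.groupby(["treatment", "time"], sort=False):
        for sid in group["sample_id"]:
            j = out.sample_ids.index(sid)
            col = vals[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                continue
            centred = col - np.median(obs)
            if scale_estimator == "sd":
                s = np.std(obs - np.median(obs), ddof=1) if obs.size > 1 else 0.0
            else:
                s = sps.median_abs_deviation(obs, scale="normal")
            if s == 0:
                warnings.warn(
                    f"sample {sid!r}: degenerate scale (all observed values equal); "
                    "returning zeros",
                    stacklevel=2,
                )
                vals[:, j] = np.where(np.isnan(col), np.nan, 0.0)
            else:
                vals[:, j] = centred / s
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    out.scale = "log2-normalized"
    return out


def normalize_redox_by_protein(
    redox: OmicsMatrix,
    proteome: OmicsMatrix,
    mapping: dict,
    late_time: str = "24 h",
    drop_unmatched: bool = False,
) -> OmicsMatrix:
    """Correct late-time redox values for protein-abundance changes.

    On the log2 scale, the matched protein's level (same treatment, late
    time point) is subtracted from each late-time redox value; early
    time points pass through unchanged because protein abundance barely
    moves on that timescale. Peptides without a quantified matching
    protein are left unadjusted and flagged (or dropped when
    ``drop_unmatched``).
    """
    if redox.scale != "log2-normalized" or proteome.scale != "log2-normalized":
        raise ValueError("both matrices must be normalized first")
    out = redox.copy()
    unmatched: list[str] = []
    late_cols = out.samples["time"] == late_time
    for feat in out.feature_ids:
        prot = mapping.get(feat)
        if prot is None or prot not in proteome.values.index:
            unmatched.append(feat)
            continue
        for _, row in out.samples.loc[late_cols].iterrows():
            prot_cols = proteome.sample_ids_for(row["treatment"], late_time)
            if not prot_cols:
                unmatched.append(feat)
                break
            level = proteome.values.loc[prot, prot_cols].mean(skipna=True)
            if np.isnan(level):
                unmatched.append(feat)
                break
            out.values.loc[feat, row["sample_id"]] -= level
    unmatched = sorted(set(unmatched))
    if unmatched:
        logger.info("%d redox peptides lack a quantified protein match", len(unmatched))
    if drop_unmatched and unmatched:
        out.values = out.values.drop(index=unmatched)
    out.flags["protein_corrected"] = True
    out.flags["unmatched_peptides"] = unmatched
    return out


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_knn(
    matrix: OmicsMatrix,
    k: int = 10,
    max_missing_fraction: float = 0.5,
    standardize_rows: bool = False,
) -> OmicsMatrix:
    """k-nearest-neighbour imputation over feature rows.

    Features with missing fraction below ``max_missing_fraction`` have
    each missing cell replaced by the unweighted mean, over the ``k``
    nearest feature rows (per-column-normalized Euclidean distance on
    jointly observed columns), of that column's observed values.
    Features at or above the threshold are untouched. Distance ties
    break by feature id for determinism.

    Distances use the rows as-is by default, so neighbours share the
    feature's intensity level and the borrowed values are on the right
    scale (the convention of the standard expression-matrix kNN
    imputers); ``standardize_rows`` switches to z-scored rows, which
    matches on profile shape regardless of level.
    """
    if matrix.scale != "log2-normalized":
        raise ValueError("impute_knn expects a normalized matrix")
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float)
    n_feat, n_samp = vals.shape
    obs = ~np.isnan(vals)
    if standardize_rows:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            row_mean = np.nanmean(vals, axis=1, keepdims=True)
            row_sd = np.nanstd(vals, axis=1, keepdims=True, ddof=0)
        row_sd[row_sd == 0] = 1.0
        z = (vals - row_mean) / row_sd
    else:
        z = vals

    feature_ids = np.array(out.feature_ids)
    frac_missing = 1.0 - obs.mean(axis=1)
    targets = np.flatnonzero((frac_missing > 0) & (frac_missing < max_missing_fraction))
    for i in targets:
        for j in np.flatnonzero(~obs[i]):
            donors = np.flatnonzero(obs[:, j])
            donors = donors[donors != i]
            joint = obs[donors] & obs[i]
            n_joint = joint.sum(axis=1)
            donors = donors[n_joint > 0]
            if donors.size == 0:
                continue
            diff = z[donors] - z[i]
            diff[~(obs[donors] & obs[i])] = 0.0
            d2 = (diff**2).sum(axis=1) / joint[n_joint > 0].sum(axis=1)
            order = np.lexsort((feature_ids[donors], np.sqrt(d2)))
            if donors.size < k:
                logger.warning(
                    "feature %s sample %s: only %d eligible neighbours (< k=%d)",
                    feature_ids[i], out.sample_ids[j], donors.size, k,
                )
            chosen = donors[order[:k]]
            vals[i, j] = vals[chosen, j].mean()
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out


def impute_random_tail(
    matrix: OmicsMatrix,
    group_key: str = "treatment",
    group_pair: tuple = ("basal", "insulin"),
    width: float = 0.3,
    downshift: float = 1.8,
    min_present: int = 2,
    seed: int = 0,
) -> OmicsMatrix:
    """Random-tail imputation for condition-structured (on/off) missingness.

    Within each treatment arm, a feature quantified in at least
    ``min_present`` replicates of one condition and in none of the other
    has the all-missing condition's cells drawn from
    ``N(mu_s - downshift*sigma_s, (width*sigma_s)^2)`` where ``mu_s`` and
    ``sigma_s`` are the observed mean/SD of that sample column — the low
    tail of the intensity distribution. Applied symmetrically in both
    directions.
    """
    if matrix.scale != "log2-normalized":
        raise ValueError("impute_random_tail expects a normalized matrix")
    labels = set(matrix.samples[group_key])
    missing_labels = [g for g in group_pair if g not in labels]
    if missing_labels:
        raise ValueError(f"sample metadata lacks {group_key} label(s) {missing_labels}")
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    vals = out.values.to_numpy(dtype=float)
    col_of = {s: j for j, s in enumerate(out.sample_ids)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_mean = np.nanmean(vals, axis=0)
        col_sd = np.nanstd(vals, axis=0, ddof=1)

    other_key = "treatment" if group_key != "treatment" else "time"
    for _, arm in out.samples.groupby(other_key, sort=False):
        cols = {
            g: [col_of[s] for s in arm.loc[arm[group_key] == g, "sample_id"]]
            for g in group_pair
        }
        if not all(cols.values()):
            continue
        for a, b in ((0, 1), (1, 0)):
            present, absent = cols[group_pair[a]], cols[group_pair[b]]
            n_obs_present = (~np.isnan(vals[:, present])).sum(axis=1)
            n_obs_absent = (~np.isnan(vals[:, absent])).sum(axis=1)
            qualify = np.flatnonzero((n_obs_present >= min_present) & (n_obs_absent == 0))
            for i in qualify:
                for j in absent:
                    vals[i, j] = rng.normal(
                        col_mean[j] - downshift * col_sd[j], width * col_sd[j]
                    )
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out


# ---------------------------------------------------------------------------
# moderated two-sample test
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    """Per-feature results of one group-vs-group moderated comparison."""

    table: pd.DataFrame  # feature, logFC, s2, df, t, p, adj_p
    d0: float
    s0_sq: float
    contrast: tuple = ("", "")

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior df must be >= 0")

    @property
    def features(self) -> pd.Index:
        return self.table.index


def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y for x by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior to sample variances.

    Models s2 ~ s0^2 * F(df, d0) via the log-variance moments: returns
    (d0, s0_sq), with d0 = inf when the log-variances are underdispersed
    relative to pure chi-squared sampling noise.
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - digamma(d / 2) + np.log(d / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    if np.ptp(z) < 1e-10:
        # degenerate: every feature reports the same variance — the prior
        # is a point mass on that common value
        return np.inf, float(np.exp(np.mean(z)))
    resid_var = e_var - np.mean(polygamma(1, d / 2))
    if resid_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2 * _trigamma_inverse(resid_var)
    s0_sq = np.exp(e_mean + digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s0_sq)


def moderated_test(
    matrix: OmicsMatrix,
    contrast: tuple,
    group_key: str = "treatment",
    min_per_group: int = 2,
    d0_override: float | None = None,
) -> ContrastResult:
    """Empirical-Bayes moderated two-sample t-test per feature.

    ``contrast`` is ``(test_label, reference_label)`` over ``group_key``
    values; logFC is test minus reference of group means on the log2
    scale. Per-feature pooled variances are shrunk toward the
    method-of-moments prior (d0, s0^2); p-values come from a t
    distribution on ``d0 + df`` degrees of freedom, adjusted by
    Benjamini-Hochberg. ``d0_override`` forces the prior df (0 recovers
    the ordinary pooled t-test).
    """
    test_label, ref_label = contrast
    cols = {}
    for label in contrast:
        sel = matrix.samples[group_key] == label
        if not sel.any():
            raise ValueError(f"no samples with {group_key} == {label!r}")
        cols[label] = [matrix.sample_ids.index(s) for s in matrix.samples.loc[sel, "sample_id"]]
    vals = matrix.values.to_numpy(dtype=float)
    a = vals[:, cols[test_label]]
    b = vals[:, cols[ref_label]]
    na = (~np.isnan(a)).sum(axis=1)
    nb = (~np.isnan(b)).sum(axis=1)
    keep = (na >= min_per_group) & (nb >= min_per_group) & (na + nb > 2)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("moderated_test: dropped %d features with insufficient replication", dropped)
    if not keep.any():
        raise ValueError("no feature has enough replicates in both groups")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_a = np.nanmean(a[keep], axis=1)
        mean_b = np.nanmean(b[keep], axis=1)
        var_a = np.nanvar(a[keep], axis=1, ddof=1)
        var_b = np.nanvar(b[keep], axis=1, ddof=1)
    na_k, nb_k = na[keep], nb[keep]
    df_g = na_k + nb_k - 2.0
    s2_g = ((na_k - 1) * np.where(na_k > 1, var_a, 0) + (nb_k - 1) * np.where(nb_k > 1, var_b, 0)) / df_g
    logfc = mean_a - mean_b

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2_g)) if d0 > 0 else 0.0
    else:
        d0, s0_sq = fit_f_dist(s2_g, df_g)
    if np.isinf(d0):
        s2_post = np.full_like(s2_g, s0_sq)
        df_total = np.full_like(df_g, np.inf)
    else:
        s2_post = (d0 * s0_sq + df_g * s2_g) / (d0 + df_g)
        df_total = d0 + df_g
    se = np.sqrt(s2_post * (1.0 / na_k + 1.0 / nb_k))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    p = np.where(
        np.isinf(df_total), 2 * sps.norm.sf(np.abs(t)), 2 * sps.t.sf(np.abs(t), df_total)
    )
    adj_p = bh_adjust(p)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2_g,
            "df": df_g,
            "t": t,
            "p": p,
            "adj_p": adj_p,
        },
        index=matrix.values.index[keep],
    )
    table.index.name = "feature"
    return ContrastResult(table=table, d0=d0, s0_sq=s0_sq, contrast=contrast)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# direction-based two-contrast integration
# ---------------------------------------------------------------------------

@dataclass
class DirectionResult:
    table: pd.DataFrame  # z1, z2, z_combined, p, label
    direction: tuple = (1, 1)


def _signed_z(result: ContrastResult) -> pd.Series:
    p = result.table["p"].to_numpy(dtype=float)
    tiny = np.finfo(float).tiny
    n_zero = int((p <= 0).sum())
    if n_zero:
        logger.info("clipping %d zero p-values to %.3g", n_zero, tiny)
    p = np.clip(p, tiny, 1.0)
    z = np.sign(result.table["logFC"].to_numpy()) * np.abs(sps.norm.ppf(p / 2))
    return pd.Series(z, index=result.features)


def direction_analysis(
    c1: ContrastResult, c2: ContrastResult, direction: tuple = (1, 1)
) -> DirectionResult:
    """Integrate two contrasts along a chosen direction.

    Each contrast is converted to a signed z-score
    ``z = sign(logFC) * |Phi^{-1}(p/2)|``; the combined statistic is the
    projection ``(d1*z1 + d2*z2)/sqrt(2)`` for direction
    ``(d1, d2) in {+1, -1}^2``, tested one-sided against its upper
    normal tail. Features concordant with the direction at small p form
    the concordantly regulated set.
    """
    if set(direction) - {1, -1}:
        raise ValueError("direction components must be +1 or -1")
    shared = c1.features.intersection(c2.features)
    if shared.empty:
        raise ValueError("contrasts share no features")
    z1 = _signed_z(c1).loc[shared]
    z2 = _signed_z(c2).loc[shared]
    zc = (direction[0] * z1 + direction[1] * z2) / np.sqrt(2.0)
    tiny = np.finfo(float).tiny
    p = np.clip(sps.norm.sf(zc), tiny, np.nextafter(1.0, 0.0))
    label = np.where(
        (np.sign(z1) == np.sign(z2)) & (z1 != 0),
        np.where(z1 > 0, "concordant-up", "concordant-down"),
        "discordant",
    )
    table = pd.DataFrame(
        {"z1": z1, "z2": z2, "z_combined": zc, "p": p, "label": label}, index=shared
    )
    table.index.name = "feature"
    return DirectionResult(table=table, direction=tuple(direction))


# ---------------------------------------------------------------------------
# kinase-substrate fidelity
# ---------------------------------------------------------------------------

@dataclass
class SubstrateSetStats:
    kinase: str
    substrates: list[str]
    bartlett_stat: float
    bartlett_p_one_sided: float
    t_stat: float
    t_p_one_sided: float


def substrate_fidelity(
    changes: pd.DataFrame,
    sets: dict,
    conditions: tuple,
) -> list[SubstrateSetStats]:
    """Variance and mean statistics of substrate phosphorylation changes.

    ``changes`` holds per-feature log2 changes with one column per
    condition label; ``sets`` maps kinase id to substrate feature ids;
    ``conditions = (early, later)``. Per kinase:

    * one-sided Bartlett test of whether the later condition's variance
      across substrates exceeds the earlier one's — the omnibus Bartlett
      p is halved when the later sample variance is indeed larger,
      otherwise reported as ``1 - p/2``;
    * a one-sided one-sample t-test of whether the later condition's
      mean change is below zero (signalling attenuation).

    Singleton sets are skipped with a log entry.
    """
    early, later = conditions
    out = []
    for kinase, members in sets.items():
        members = [m for m in members if m in changes.index]
        if len(members) < 2:
            logger.info("kinase %s: fewer than 2 quantified substrates; skipped", kinase)
            continue
        x_early = changes.loc[members, early].dropna().to_numpy(dtype=float)
        x_later = changes.loc[members, later].dropna().to_numpy(dtype=float)
        if len(x_early) < 2 or len(x_later) < 2:
            logger.info("kinase %s: insufficient quantification in a condition; skipped", kinase)
            continue
        stat, p_omni = sps.bartlett(x_later, x_early)
        if np.var(x_later, ddof=1) > np.var(x_early, ddof=1):
            p_one = p_omni / 2
        else:
            p_one = 1 - p_omni / 2
        t_res = sps.ttest_1samp(x_later, 0.0, alternative="less")
        out.append(
            SubstrateSetStats(
                kinase=kinase,
                substrates=members,
                bartlett_stat=float(stat),
                bartlett_p_one_sided=float(p_one),
                t_stat=float(t_res.statistic),
                t_p_one_sided=float(t_res.pvalue),
            )
        )
    return out


# ---------------------------------------------------------------------------
# probabilistic PCA (EM, missing-data capable)
# ---------------------------------------------------------------------------

@dataclass
class PPCAResult:
    scores: np.ndarray       # n_samples x q latent posterior means
    loadings: np.ndarray     # n_features x q
    noise_variance: float
    mean: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool


def ppca(
    matrix: OmicsMatrix | np.ndarray,
    n_components: int,
    max_iter: int = 1000,
    rel_tol: float = 1e-8,
    seed: int = 0,
) -> PPCAResult:
    """Probabilistic PCA fitted by expectation-maximisation.

    Model: for each sample column y (length p), y = W x + mu + eps with
    x ~ N(0, I_q) and isotropic noise eps ~ N(0, sigma^2 I). Missing
    entries are handled exactly in the E-step by restricting to each
    sample's observed coordinates. Convergence: relative log-likelihood
    change below ``rel_tol`` (or ``max_iter``).
    """
    if isinstance(matrix, OmicsMatrix):
        y = matrix.values.to_numpy(dtype=float).T  # samples x features
    else:
        y = np.asarray(matrix, dtype=float).T
    n, p = y.shape
    q = int(n_components)
    if q >= min(n, p):
        raise ValueError(f"n_components={q} must be < min(n_samples, n_features)={min(n, p)}")
    obs = ~np.isnan(y)
    if not obs.any(axis=0).all():
        raise ValueError("some feature has no observed value")

    rng = np.random.default_rng(seed)
    mu = np.nanmean(y, axis=0)
    w = rng.standard_normal((p, q)) * 0.1
    sigma2 = float(np.nanvar(y - mu)) or 1.0

    ll_old = -np.inf
    converged = False
    complete = obs.all()
    it = 0
    for it in range(1, max_iter + 1):
        if complete:
            yc = y - mu
            m = w.T @ w + sigma2 * np.eye(q)
            m_inv = np.linalg.inv(m)
            ex = yc @ w @ m_inv                       # n x q
            exx_sum = n * sigma2 * m_inv + ex.T @ ex  # q x q
            w_new = (yc.T @ ex) @ np.linalg.inv(exx_sum)
            sigma2_new = (
                np.sum(yc**2) - 2 * np.sum((ex @ w_new.T) * yc) + np.trace(exx_sum @ (w_new.T @ w_new))
            ) / (n * p)
            mu_new = y.mean(axis=0)
            # marginal Gaussian log-likelihood via the determinant lemma:
            # C = W W' + s2 I_p; logdet C = (p-q) log s2 + logdet(W'W + s2 I_q)
            yc = y - mu_new
            m2 = w_new.T @ w_new + sigma2_new * np.eye(q)
            _, logdet_m = np.linalg.slogdet(m2)
            logdet_c = (p - q) * np.log(sigma2_new) + logdet_m
            yw = yc @ w_new
            quad = (np.sum(yc**2) - np.sum((yw @ np.linalg.inv(m2)) * yw)) / sigma2_new
            ll = -0.5 * (n * (p * np.log(2 * np.pi) + logdet_c) + quad)
        else:
            ex = np.zeros((n, q))
            exx_sum = np.zeros((q, q))
            ll = 0.0
            stats_rows = []
            for i in range(n):
                o = obs[i]
                wo = w[o]
                yo = y[i, o] - mu[o]
                m = wo.T @ wo + sigma2 * np.eye(q)
                m_inv = np.linalg.inv(m)
                ex[i] = m_inv @ wo.T @ yo
                cov_x = sigma2 * m_inv
                exx_sum += cov_x + np.outer(ex[i], ex[i])
                stats_rows.append((o, yo, cov_x))
                po = int(o.sum())
                _, logdet_m = np.linalg.slogdet(m)
                logdet_c = (po - q) * np.log(sigma2) + logdet_m
                wy = wo.T @ yo
                quad = (yo @ yo - wy @ m_inv @ wy) / sigma2
                ll += -0.5 * (po * np.log(2 * np.pi) + logdet_c + quad)
            # M-step per feature row (only samples observing that feature)
            w_new = np.zeros_like(w)
            mu_new = mu.copy()
            for jf in range(p):
                rows = np.flatnonzero(obs[:, jf])
                a = np.zeros((q, q))
                b = np.zeros(q)
                resid = y[rows, jf]
                mu_new[jf] = np.mean(resid - ex[rows] @ w[jf])
                for i in rows:
                    o, yo, cov_x = stats_rows[i]
                    a += cov_x + np.outer(ex[i], ex[i])
                    b += (y[i, jf] - mu_new[jf]) * ex[i]
                w_new[jf] = np.linalg.solve(a, b)
            num = 0.0
            denom = 0
            for i in range(n):
                o, yo, cov_x = stats_rows[i]
                wo = w_new[o]
                r = (y[i, o] - mu_new[o]) - wo @ ex[i]
                num += r @ r + np.trace(wo @ cov_x @ wo.T)
                denom += int(o.sum())
            sigma2_new = num / denom
        w, sigma2, mu = w_new, max(sigma2_new, 1e-12), mu_new
        if np.isfinite(ll_old) and abs(ll - ll_old) <= rel_tol * abs(ll_old):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    # orthogonalise the principal subspace for reporting
    u, s, _ = np.linalg.svd(w, full_matrices=False)
    loadings = u * s
    if complete:
        yc = y - mu
        m = loadings.T @ loadings + sigma2 * np.eye(q)
        scores = yc @ loadings @ np.linalg.inv(m)
    else:
        scores = np.zeros((n, q))
        for i in range(n):
            o = obs[i]
            wo = loadings[o]
            m = wo.T @ wo + sigma2 * np.eye(q)
            scores[i] = np.linalg.solve(m, wo.T @ (y[i, o] - mu[o]))
    return PPCAResult(
        scores=scores,
        loadings=loadings,
        noise_variance=float(sigma2),
        mean=mu,
        log_likelihood=float(ll_old),
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# replicate precision
# ---------------------------------------------------------------------------

def median_cv(matrix: OmicsMatrix, treatment: str, time: str | None = None) -> float:
    """Median per-feature coefficient of variation within one group.

    CV = sd/mean on linear intensities over the group's replicates;
    the median is taken over features observed in every replicate.
    """
    if matrix.scale != "linear":
        raise ValueError("median_cv expects linear-scale intensities")
    sel = matrix.samples["treatment"] == treatment
    if time is not None:
        sel &= matrix.samples["time"] == time
    ids = list(matrix.samples.loc[sel, "sample_id"])
    if len(ids) < 2:
        raise ValueError("need at least 2 replicates in the group")
    sub = matrix.values[ids].to_numpy(dtype=float)
    complete = ~np.isnan(sub).any(axis=1)
    if not complete.any():
        raise ValueError("no feature observed in all replicates of the group")
    sub = sub[complete]
    cv = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    return float(np.median(cv))
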