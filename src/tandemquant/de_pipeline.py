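"""Label-free differential-expression pipeline for knockout-vs-WT proteomics.

The workflow mirrors the standard transcriptomics-style treatment of
label-free protein abundance matrices:

1. top-N roll-up of peptide intensities to protein level (N = 3);
2. removal of uninformative features (zero condition means, near-zero
   variance);
3. midpoint imputation of remaining zeros;
4. TMM (trimmed mean of M-values) between-sample normalisation;
5. removal of run-order batch effects by an ANOVA simultaneous-component
   decomposition that preserves the genotype contrast;
6. voom-style precision weights from a fitted mean–variance trend;
7. per-protein linear models (genotype + age + sex) with empirical-Bayes
   moderated t-statistics;
8. Benjamini–Hochberg FDR adjustment and fold-change calling.

Stages are exposed both as scikit-learn style transformers/estimators
(operating on a samples × proteins orientation so they compose with
sklearn pipelines) and as thin module-level functions operating on
:class:`AbundanceMatrix` (proteins × samples, the orientation label-free
quantitation exports use).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GENOTYPES = ("KO", "WT")


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """Protein × sample intensity matrix with sample metadata.

    Parameters
    ----------
    values
        Non-negative intensities, rows indexed by unique protein
        accessions, columns by sample ids.
    samples
        Metadata indexed by sample id with columns ``genotype`` (KO/WT),
        ``age`` (weeks), ``sex`` (M/F), ``run_order`` (positive int) and
        optionally ``tissue``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.samples = pd.DataFrame(self.samples)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.values.index.has_duplicates:
            raise ValueError("protein ids must be unique")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)}")
        required = {"genotype", "age", "sex", "run_order"}
        absent = required - set(self.samples.columns)
        if absent:
            raise ValueError(f"metadata columns missing: {sorted(absent)}")
        bad = set(self.samples["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")
        # align metadata to column order; normalise axis names so text
        # round-trips compare equal
        self.samples = self.samples.loc[self.values.columns]
        self.values.index.name = "accession"
        self.values.columns.name = None
        self.samples.index.name = "sample"

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def genotype(self) -> pd.Series:
        return self.samples["genotype"]

    def with_values(self, values: pd.DataFrame) -> "AbundanceMatrix":
        return AbundanceMatrix(values, self.samples.loc[values.columns])

    # -- text I/O ----------------------------------------------------------

    def to_csv(self, values_path, samples_path, sep: str = ",") -> None:
        self.values.to_csv(values_path, sep=sep, index_label="accession")
        self.samples.to_csv(samples_path, sep=sep, index_label="sample")

    @classmethod
    def from_csv(cls, values_path, samples_path, sep: str = ",") -> "AbundanceMatrix":
        values = pd.read_csv(values_path, sep=sep, index_col=0)
        samples = pd.read_csv(samples_path, sep=sep, index_col=0)
        return cls(values, samples)


# ---------------------------------------------------------------------------
# top-N roll-up
# ---------------------------------------------------------------------------


def topn_protein_quant(
    peptide_intensities: pd.DataFrame,
    protein_map: pd.Series | dict,
    n: int = 3,
) -> pd.DataFrame:
    """Roll peptide intensities up to protein level by the top-N rule.

    For each protein the ``n`` peptides with the highest mean intensity
    across samples are selected once, and their intensities summed per
    sample — so every sample uses the same peptide set.  Proteins with
    fewer than ``n`` peptides use all of theirs.

    Parameters
    ----------
    peptide_intensities
        Peptide × sample intensities.
    protein_map
        Peptide id → protein accession (each peptide maps to one protein).
    n
        Number of top peptides to sum (default 3).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    protein_map = pd.Series(protein_map)
    if protein_map.empty:
        raise ValueError("empty peptide→protein mapping")
    unmapped = peptide_intensities.index.difference(protein_map.index)
    if len(unmapped):
        raise ValueError(f"peptides without protein mapping: {list(unmapped)[:5]}")
    means = peptide_intensities.mean(axis=1)
    rows = {}
    for protein, peptides in protein_map.loc[peptide_intensities.index].groupby(
        protein_map
    ):
        top = means.loc[peptides.index].nlargest(n).index
        rows[protein] = peptide_intensities.loc[top].sum(axis=0)
    return pd.DataFrame(rows).T.rename_axis("accession")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


class UninformativeFilter(BaseEstimator, TransformerMixin):
    """Drop features with zero condition means or near-zero variance.

    A feature is removed when its mean intensity is ≤ 0 in *every*
    condition (a feature present in only one genotype is kept — that is
    exactly the biology a knockout comparison is looking for), or when it
    has near-zero variance: the most frequent value accounts for at least
    ``unique_cut`` percent of samples *and* the ratio of the most frequent
    to the second most frequent value count exceeds ``freq_cut``.

    X is samples × features (sklearn orientation); ``y`` gives the
    condition label of each sample.
    """

    def __init__(self, freq_cut: float = 95.0 / 5.0, unique_cut: float = 90.0):
        self.freq_cut = freq_cut
        self.unique_cut = unique_cut

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples × features)")
        conditions = np.unique(y)
        if any((y == c).sum() < 2 for c in conditions):
            raise ValueError("need >= 2 samples per condition")
        n, p = X.shape
        cond_means = np.vstack([X[y == c].mean(axis=0) for c in conditions])
        zero_mean = (cond_means <= 0).all(axis=0)
        nzv = np.zeros(p, dtype=bool)
        for j in range(p):
            _vals, counts = np.unique(X[:, j], return_counts=True)
            counts = np.sort(counts)[::-1]
            top_pct = 100.0 * counts[0] / n
            ratio = counts[0] / counts[1] if len(counts) > 1 else np.inf
            nzv[j] = top_pct >= self.unique_cut and ratio > self.freq_cut
        self.support_ = ~(zero_mean | nzv)
        self.n_removed_zero_mean_ = int(zero_mean.sum())
        self.n_removed_nzv_ = int((nzv & ~zero_mean).sum())
        if not self.support_.any():
            raise ValueError("all features removed by filtering")
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return X[:, self.support_]


def filter_uninformative(
    matrix: AbundanceMatrix,
    freq_cut: float = 95.0 / 5.0,
    unique_cut: float = 90.0,
) -> AbundanceMatrix:
    """Apply :class:`UninformativeFilter` to an :class:`AbundanceMatrix`."""
    f = UninformativeFilter(freq_cut=freq_cut, unique_cut=unique_cut)
    f.fit(matrix.values.T.to_numpy(), matrix.genotype.to_numpy())
    kept = matrix.values.loc[f.support_]
    logger.info(
        "filter_uninformative: %d -> %d proteins (%d zero-mean, %d near-zero-variance)",
        len(matrix.values),
        len(kept),
        f.n_removed_zero_mean_,
        f.n_removed_nzv_,
    )
    return matrix.with_values(kept)


# ---------------------------------------------------------------------------
# midpoint zero imputation
# ---------------------------------------------------------------------------


class MidpointZeroImputer(BaseEstimator, TransformerMixin):
    """Replace zeros with the midpoint between 0 and the feature's
    smallest non-zero value.

    The "next non-zero value" is resolved within the feature (protein) so
    the result does not depend on arbitrary sample ordering.
    X is samples × features.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if (X == 0).all(axis=0).any():
            raise ValueError(
                "all-zero feature: filtering must precede imputation"
            )
        with np.errstate(invalid="ignore"):
            masked = np.where(X > 0, X, np.nan)
        self.min_nonzero_ = np.nanmin(masked, axis=0)
        return self

    def transform(self, X):
        was_df = isinstance(X, pd.DataFrame)
        arr = np.asarray(X, dtype=float).copy()
        fill = np.broadcast_to(self.min_nonzero_ / 2.0, arr.shape)
        arr[arr == 0] = fill[arr == 0]
        if was_df:
            return pd.DataFrame(arr, index=X.index, columns=X.columns)
        return arr


def impute_zeros_midpoint(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Row-wise midpoint imputation of zeros on an :class:`AbundanceMatrix`."""
    imp = MidpointZeroImputer()
    out = imp.fit(matrix.values.T).transform(matrix.values.T).T
    n_imputed = int((matrix.values.to_numpy() == 0).sum())
    logger.info("impute_zeros_midpoint: %d zeros imputed", n_imputed)
    return matrix.with_values(out)


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------


def _tmm_pairwise(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Two-sided trimmed, precision-weighted mean of M-values (log2)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    m = np.log2((obs / lib_obs) / (ref / lib_ref))
    a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    # asymptotic (delta-method) variance of M under count-like sampling
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if len(m) == 0:
        return 0.0
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Trimmed-mean-of-M-values between-sample normalisation.

    For each sample a scaling factor is the precision-weighted, doubly
    trimmed mean of the log2 ratios (M-values) of its features against a
    reference sample, on library-size-scaled intensities.  The reference
    is the sample whose upper quartile is closest to the mean upper
    quartile.  TMM factors are rescaled to have geometric mean 1; the
    effective per-sample divisor combines the library size and the TMM
    factor (also rescaled to geometric mean 1 so the overall intensity
    scale is preserved).

    X is samples × features with strictly positive entries (imputation
    must precede).  Attributes after ``fit``: ``lib_size_``,
    ``tmm_factors_`` (product 1), ``scaling_factors_`` (effective
    divisors, product 1).
    """

    def __init__(self, trim_m: float = 0.30, trim_a: float = 0.05):
        self.trim_m = trim_m
        self.trim_a = trim_a

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if (X <= 0).any():
            raise ValueError("TMM requires strictly positive intensities")
        lib = X.sum(axis=1)
        scaled_uq = np.quantile(X / lib[:, None], 0.75, axis=1)
        self.ref_index_ = int(np.argmin(np.abs(scaled_uq - scaled_uq.mean())))
        log_f = np.array(
            [
                _tmm_pairwise(
                    X[k],
                    X[self.ref_index_],
                    lib[k],
                    lib[self.ref_index_],
                    self.trim_m,
                    self.trim_a,
                )
                for k in range(X.shape[0])
            ]
        )
        f = 2.0**log_f
        f /= np.exp(np.mean(np.log(f)))
        self.lib_size_ = lib
        self.tmm_factors_ = f
        eff = lib * f
        self.scaling_factors_ = eff / np.exp(np.mean(np.log(eff)))
        return self

    def transform(self, X):
        was_df = isinstance(X, pd.DataFrame)
        arr = np.asarray(X, dtype=float) / self.scaling_factors_[:, None]
        if was_df:
            return pd.DataFrame(arr, index=X.index, columns=X.columns)
        return arr


def tmm_factors(
    matrix: AbundanceMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> tuple[pd.DataFrame, AbundanceMatrix]:
    """TMM factors and the normalised matrix.

    Returns a per-sample table (``lib_size``, ``tmm``, ``scaling`` — the
    effective divisor, product 1) and the normalised
    :class:`AbundanceMatrix`.
    """
    norm = TMMNormalizer(trim_m=trim_m, trim_a=trim_a)
    Xt = matrix.values.T
    norm.fit(Xt)
    factors = pd.DataFrame(
        {
            "lib_size": norm.lib_size_,
            "tmm": norm.tmm_factors_,
            "scaling": norm.scaling_factors_,
        },
        index=matrix.values.columns,
    )
    out = norm.transform(Xt).T
    logger.info("tmm_factors: reference sample %s", matrix.values.columns[norm.ref_index_])
    return factors, matrix.with_values(out)


# ---------------------------------------------------------------------------
# batch-effect removal (ANOVA simultaneous-component style)
# ---------------------------------------------------------------------------


class BatchEffectRemover(BaseEstimator, TransformerMixin):
    """Remove run-order batch structure while preserving the condition
    contrast.

    On the log2 matrix, the condition-mean structure is set aside, batch
    means of the remainder are computed, and the principal components of
    that batch-mean submatrix that cumulatively explain at least
    ``variance_threshold`` of its variance are subtracted.  Because the
    subtracted signal is built from condition-centred data, condition
    means are untouched by construction (up to design imbalance).

    X is samples × features on the log2 scale; ``y`` is the condition
    label, ``batch`` the batch label, both per sample.
    """

    def __init__(self, variance_threshold: float = 0.95):
        self.variance_threshold = variance_threshold

    def fit(self, X, y, batch=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if batch is None:
            raise ValueError("batch labels are required")
        batch = np.asarray(batch)
        batches = np.unique(batch)
        if len(batches) < 2:
            raise ValueError("need >= 2 batches")
        # confounding check: within every batch both conditions must not
        # collapse to a single condition for ALL batches simultaneously
        table = pd.crosstab(pd.Series(batch), pd.Series(y))
        if (table.astype(bool).sum(axis=1) == 1).all():
            raise ValueError(
                "batch is confounded with condition: every batch contains a "
                "single condition, so batch and condition effects cannot be "
                "separated"
            )
        cond_means = np.zeros_like(X)
        for c in np.unique(y):
            cond_means[y == c] = X[y == c].mean(axis=0)
        resid = X - cond_means
        batch_means = np.zeros_like(X)
        for b in batches:
            batch_means[batch == b] = resid[batch == b].mean(axis=0)
        self.batch_signal_ = self._low_rank(batch_means)
        return self

    def _low_rank(self, M: np.ndarray) -> np.ndarray:
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        var = s**2
        total = var.sum()
        if total <= 1e-30:
            return np.zeros_like(M)
        cum = np.cumsum(var) / total
        k = int(np.searchsorted(cum, self.variance_threshold) + 1)
        k = min(k, len(s))
        return (u[:, :k] * s[:k]) @ vt[:k]

    def transform(self, X):
        was_df = isinstance(X, pd.DataFrame)
        arr = np.asarray(X, dtype=float) - self.batch_signal_
        if was_df:
            return pd.DataFrame(arr, index=X.index, columns=X.columns)
        return arr


def assign_batches(run_order: Sequence[int], n_batches: int) -> np.ndarray:
    """Group acquisition run order into equal-sized consecutive blocks."""
    run_order = np.asarray(run_order)
    ranks = stats.rankdata(run_order, method="ordinal") - 1
    return np.floor(ranks * n_batches / len(run_order)).astype(int)


def remove_batch_arsyn(
    matrix: AbundanceMatrix,
    n_batches: int = 3,
    variance_threshold: float = 0.95,
    batch: Sequence | None = None,
) -> AbundanceMatrix:
    """ANOVA simultaneous-component batch removal on the log2 scale.

    The matrix must be strictly positive (normalised, post-imputation);
    correction happens in log2 space and the corrected matrix is returned
    on the original linear scale.  Batch blocks default to equal-sized
    consecutive groups of the ``run_order`` metadata column.
    """
    if batch is None:
        batch = assign_batches(matrix.samples["run_order"].to_numpy(), n_batches)
    vals = matrix.values.to_numpy()
    if (vals <= 0).any():
        raise ValueError("batch removal requires a strictly positive matrix")
    logX = np.log2(vals.T)
    remover = BatchEffectRemover(variance_threshold=variance_threshold)
    remover.fit(logX, matrix.genotype.to_numpy(), batch=batch)
    corrected = remover.transform(logX)
    out = pd.DataFrame(
        2.0**corrected.T, index=matrix.values.index, columns=matrix.values.columns
    )
    logger.info(
        "remove_batch_arsyn: %d batches, threshold %.2f",
        len(np.unique(batch)),
        variance_threshold,
    )
    return matrix.with_values(out)


# ---------------------------------------------------------------------------
# voom-style precision weights
# ---------------------------------------------------------------------------


def _fit_ols(Y: np.ndarray, D: np.ndarray, W: np.ndarray | None = None):
    """Per-feature (weighted) least squares.

    Y is features × samples, D the samples × p design, W optional
    per-observation weights (features × samples).  Returns coefficients
    (features × p), unscaled standard errors of each coefficient, residual
    sd per feature, and residual df.
    """
    g, n = Y.shape
    p = D.shape[1]
    df = n - p
    if df <= 0:
        raise ValueError("fewer samples than design columns")
    beta = np.empty((g, p))
    se_unscaled = np.empty((g, p))
    sigma = np.empty(g)
    if W is None:
        W = np.ones_like(Y)
    for i in range(g):
        w = W[i]
        sw = np.sqrt(w)
        Dw = D * sw[:, None]
        yw = Y[i] * sw
        coef, _res, rank, _sv = np.linalg.lstsq(Dw, yw, rcond=None)
        if rank < p:
            beta[i] = np.nan
            se_unscaled[i] = np.nan
            sigma[i] = np.nan
            continue
        beta[i] = coef
        resid = yw - Dw @ coef
        rss = float(resid @ resid)
        sigma[i] = np.sqrt(rss / df)
        xtx_inv = np.linalg.inv(Dw.T @ Dw)
        se_unscaled[i] = np.sqrt(np.diag(xtx_inv))
    return beta, se_unscaled, sigma, df


def voom_weights(
    counts: np.ndarray | pd.DataFrame,
    design: np.ndarray,
    span: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Log2 transform with per-observation precision weights.

    Intensities are treated as count-like: ``y = log2((x + 0.5) /
    (lib + 1) * 1e6)`` with library sizes the column totals.  Residual
    square-root standard deviations from a preliminary fit are smoothed
    against mean log2 intensity by lowess; each observation's weight is
    the inverse fourth power of the trend value at its fitted
    log-intensity.

    Parameters
    ----------
    counts
        features × samples positive matrix.
    design
        samples × p design matrix.

    Returns
    -------
    (log2 intensities, weights), both features × samples.
    """
    X = np.asarray(counts, dtype=float)
    if (X < 0).any():
        raise ValueError("negative intensities")
    lib = X.sum(axis=0)
    Y = np.log2((X + 0.5) / (lib + 1.0) * 1e6)
    beta, _se, sigma, _df = _fit_ols(Y, np.asarray(design, dtype=float))
    fitted = beta @ np.asarray(design, dtype=float).T
    amean = Y.mean(axis=1)
    sx = amean + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    ok = np.isfinite(sx) & np.isfinite(sy)
    lo = _lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
    lx, ly = lo[:, 0], lo[:, 1]
    # piecewise-linear interpolation of the trend, constant beyond range
    fitted_counts = fitted + (np.mean(np.log2(lib + 1.0)) - np.log2(1e6))
    trend = np.interp(fitted_counts, lx, ly)
    trend = np.clip(trend, 1e-6, None)
    w = trend**-4
    return Y, w


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------


@dataclass
class ModerationParams:
    """Empirical-Bayes variance-shrinkage hyperparameters.

    ``prior_var`` (s0²) and ``prior_df`` (d0) define the scaled inverse
    chi-square prior on per-feature residual variances; ``prior_df`` may
    be ``inf`` (complete pooling) or 0 (no moderation).
    """

    prior_var: float
    prior_df: float

    def __post_init__(self) -> None:
        if self.prior_var <= 0:
            raise ValueError("prior variance must be positive")
        if self.prior_df < 0:
            raise ValueError("prior df must be >= 0")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_moderation_params(sigma2: np.ndarray, df: float) -> ModerationParams:
    """Fit the scaled-F hyperparameters (d0, s0²) by moment matching.

    Works on log residual variances: the mean and excess variance of
    ``log(s²)`` relative to their known chi-square contributions identify
    the prior degrees of freedom and prior variance.
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) == 0:
        raise ValueError("no positive residual variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0 = np.exp(emean)
    return ModerationParams(prior_var=float(s0), prior_df=float(d0))


def moderated_t(
    beta: np.ndarray,
    se_unscaled: np.ndarray,
    sigma: np.ndarray,
    df: float,
    params: ModerationParams | None = None,
) -> pd.DataFrame:
    """Moderated t-statistics for one coefficient across features.

    The posterior variance shrinks each feature's residual variance
    toward the prior: ``s̃² = (d0·s0² + d·s²) / (d0 + d)``; the moderated
    t is the coefficient over ``se_unscaled · s̃`` with ``d0 + d`` degrees
    of freedom.

    Parameters
    ----------
    beta, se_unscaled
        Per-feature coefficient and its unscaled standard error (the
        standard error divided by the residual sd).
    sigma
        Per-feature residual standard deviations.
    df
        Residual degrees of freedom of the fit.
    params
        Hyperparameters; estimated from ``sigma`` when omitted.
    """
    sigma = np.asarray(sigma, dtype=float)
    if params is None:
        params = estimate_moderation_params(sigma**2, df)
    d0, s02 = params.prior_df, params.prior_var
    if np.isinf(d0):
        post_var = np.full_like(sigma, s02)
        df_total = np.inf
    else:
        post_var = (d0 * s02 + df * sigma**2) / (d0 + df)
        df_total = d0 + df
    t = np.asarray(beta) / (np.asarray(se_unscaled) * np.sqrt(post_var))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {
            "t": t,
            "p_value": p,
            "posterior_var": post_var,
            "df_total": df_total,
        }
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame, fc_cut: float = 1.5, fdr_cut: float = 0.05
) -> pd.DataFrame:
    """Significance calls at FDR and linear fold-change thresholds.

    A feature is significant iff ``adj_p < fdr_cut`` (strict) and
    ``|log2FC| > log2(fc_cut)``; direction is the sign of the log fold
    change.
    """
    if fc_cut <= 0 or fdr_cut <= 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    sig = (out["adj_p"] < fdr_cut) & (out["log2fc"].abs() > np.log2(fc_cut))
    out["significant"] = sig
    out["direction"] = np.where(
        ~sig, "ns", np.where(out["log2fc"] > 0, "up", "down")
    )
    return out


# ---------------------------------------------------------------------------
# the fit/test estimator
# ---------------------------------------------------------------------------


class ModeratedDE(BaseEstimator):
    """Precision-weighted moderated-t differential expression.

    Fits per-feature linear models ``log2 intensity ~ condition +
    covariates`` with voom precision weights, applies empirical-Bayes
    variance moderation, BH adjustment, and FC/FDR calling.

    X is samples × features (positive intensities, normalised and
    batch-corrected); ``y`` is the condition label (the contrast is the
    first level of ``contrast`` minus the second).  Covariates are passed
    to ``fit``.

    Attributes after ``fit``: ``results_`` (per-feature table),
    ``params_`` (:class:`ModerationParams`), ``df_residual_``.
    """

    def __init__(
        self,
        fc_cut: float = 1.5,
        fdr_cut: float = 0.05,
        contrast: tuple[str, str] = ("KO", "WT"),
        use_voom: bool = True,
        moderation: ModerationParams | None = None,
    ):
        self.fc_cut = fc_cut
        self.fdr_cut = fdr_cut
        self.contrast = contrast
        self.use_voom = use_voom
        self.moderation = moderation

    def fit(self, X, y, covariates: pd.DataFrame | np.ndarray | None = None):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        arr = Xdf.to_numpy(dtype=float).T  # features × samples
        y = np.asarray(y)
        test, refl = self.contrast
        if not set(y) <= {test, refl}:
            raise ValueError(f"labels {set(y)} do not match contrast {self.contrast}")
        cond = (y == test).astype(float)
        cols = [np.ones(len(y)), cond]
        names = ["intercept", "condition"]
        if covariates is not None:
            cov = pd.DataFrame(covariates)
            for name in cov.columns:
                col = cov[name]
                if col.dtype == object or str(col.dtype) == "category":
                    levels = pd.unique(col)
                    for lev in levels[1:]:
                        cols.append((col == lev).astype(float).to_numpy())
                        names.append(f"{name}[{lev}]")
                else:
                    cols.append(col.to_numpy(dtype=float))
                    names.append(str(name))
        D = np.column_stack(cols)
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("aliased design: some coefficients not estimable")
        if self.use_voom:
            Y, W = voom_weights(arr, D)
        else:
            if (arr <= 0).any():
                raise ValueError("intensities must be positive for log transform")
            Y, W = np.log2(arr), None
        beta, se_u, sigma, df = _fit_ols(Y, D, W)
        self.df_residual_ = df
        j = names.index("condition")
        self.params_ = (
            self.moderation
            if self.moderation is not None
            else estimate_moderation_params(sigma**2, df)
        )
        mod = moderated_t(beta[:, j], se_u[:, j], sigma, df, self.params_)
        res = pd.DataFrame(
            {
                "log2fc": beta[:, j],
                "t": mod["t"].to_numpy(),
                "p_value": mod["p_value"].to_numpy(),
            },
            index=Xdf.columns,
        )
        res["adj_p"] = bh_adjust(res["p_value"].to_numpy())
        self.results_ = call_de(res, fc_cut=self.fc_cut, fdr_cut=self.fdr_cut)
        self.design_names_ = names
        return self

    def summary(self) -> dict:
        r = self.results_
        return {
            "n_proteins": int(len(r)),
            "n_significant": int(r["significant"].sum()),
            "n_up": int((r["direction"] == "up").sum()),
            "n_down": int((r["direction"] == "down").sum()),
        }


# ---------------------------------------------------------------------------
# PCA scores
# ---------------------------------------------------------------------------


def pca_scores(
    matrix: AbundanceMatrix, k: int = 3, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the top-k principal components of log2 intensities.

    Returns the scores (samples × k) and the per-component explained
    variance ratios.
    """
    vals = matrix.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("PCA on log scale requires positive intensities")
    X = np.log2(vals).T  # samples × proteins
    if k > min(X.shape):
        raise ValueError("k exceeds matrix rank bound")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    df = pd.DataFrame(
        scores,
        index=matrix.values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return df, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# the full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything the DE workflow produces for one tissue dataset."""

    results: pd.DataFrame
    summary: dict
    pca_scores: pd.DataFrame
    pca_variance: np.ndarray
    factors: pd.DataFrame
    stages: list = field(default_factory=list)
    estimator: ModeratedDE | None = None


def run_de_pipeline(
    matrix: AbundanceMatrix,
    fc_cut: float = 1.5,
    fdr_cut: float = 0.05,
    n_batches: int = 3,
    variance_threshold: float = 0.95,
    freq_cut: float = 95.0 / 5.0,
    unique_cut: float = 90.0,
    use_voom: bool = True,
    correct_batch: bool = True,
) -> PipelineResult:
    """Filter → impute → TMM → batch removal → weights → moderated test.

    Stage order matches the label-free workflow narrative; each stage's
    input/output dimensions are logged and recorded in ``stages``.
    """
    stages = []

    def log_stage(name: str, m: AbundanceMatrix) -> None:
        stages.append({"stage": name, "proteins": len(m.values), "samples": m.values.shape[1]})
        logger.info("%s: %d proteins × %d samples", name, *m.values.shape)

    log_stage("input", matrix)
    m = filter_uninformative(matrix, freq_cut=freq_cut, unique_cut=unique_cut)
    log_stage("filter", m)
    m = impute_zeros_midpoint(m)
    log_stage("impute", m)
    factors, m = tmm_factors(m)
    log_stage("tmm", m)
    if correct_batch:
        m = remove_batch_arsyn(
            m, n_batches=n_batches, variance_threshold=variance_threshold
        )
        log_stage("batch", m)
    est = ModeratedDE(fc_cut=fc_cut, fdr_cut=fdr_cut, use_voom=use_voom)
    covariates = m.samples[["age", "sex"]]
    est.fit(m.values.T, m.genotype.to_numpy(), covariates=covariates)
    scores, varshare = pca_scores(m, k=min(3, min(m.values.shape) - 1))
    return PipelineResult(
        results=est.results_,
        summary=est.summary(),
        pca_scores=scores,
        pca_variance=varshare,
        factors=factors,
        stages=stages,
        estimator=est,
    )
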