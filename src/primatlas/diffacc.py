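"""Differential accessibility: QC, normalization, and NB species tests.

The count model is a negative-binomial GLM with a log link, per-sample
size-factor offsets, and species as the only design factor
(Var = mu + alpha * mu^2). Because the factor is categorical, the GLM
maximum likelihood reduces to independent per-group mean estimates; we
exploit that for a fast, fully vectorized fit across all OCRs at once.
The species effect is assessed by a likelihood-ratio test of the
species model against the intercept-only model; pairwise contrasts are
Wald tests on the difference of group coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8
_POISSON_CUTOFF = 1e-6  # below this dispersion the NB is numerically Poisson


@dataclass
class NormalizationResult:
    """Median-of-ratios size factors and the normalized count matrix."""

    size_factors: pd.Series
    normalized: pd.DataFrame


def size_factors(counts: pd.DataFrame) -> NormalizationResult:
    """Median-of-ratios normalization.

    s_j = median_i( count_ij / geometric_mean_i ), with the geometric mean
    taken across samples within each OCR row. Requires strictly positive
    counts, i.e. the zero-count filter must already have run.
    """
    if (counts <= 0).any().any():
        raise ValueError(
            "counts contain zeros; apply atlas.filter_zero_count before normalizing"
        )
    logc = np.log(counts.to_numpy(dtype=float))
    log_geomean = logc.mean(axis=1, keepdims=True)
    ratios = np.exp(logc - log_geomean)
    s = pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")
    normalized = counts / s
    return NormalizationResult(size_factors=s, normalized=normalized)


def replicate_qc(
    counts: pd.DataFrame, meta: pd.DataFrame, r_threshold: float = 0.85
) -> tuple[list[str], pd.DataFrame]:
    """Correlation-based replicate QC.

    Pearson correlations are computed on log2(normalized count + 1). A
    sample is retained iff its best correlation with another sample of
    the same species exceeds ``r_threshold``. A species with a single
    sample is retained with a warning (nothing to compare against).
    """
    if counts.shape[1] < 2:
        raise ValueError("replicate QC needs at least two samples")
    norm = size_factors(counts)
    logn = np.log2(norm.normalized + 1)
    corr = logn.corr(method="pearson")
    retained: list[str] = []
    for sample in counts.columns:
        species = meta.loc[sample, "species"]
        peers = [
            s
            for s in counts.columns
            if s != sample and meta.loc[s, "species"] == species
        ]
        if not peers:
            logger.warning("sample %s has no same-species peer; retained", sample)
            retained.append(sample)
        elif corr.loc[sample, peers].max() > r_threshold:
            retained.append(sample)
        else:
            logger.info(
                "excluding %s: max within-species r = %.3f <= %.2f",
                sample,
                corr.loc[sample, peers].max(),
                r_threshold,
            )
    return retained, corr


def estimate_dispersion(
    counts: pd.DataFrame,
    norm: NormalizationResult,
    meta: pd.DataFrame,
    moderate: bool = True,
) -> pd.Series:
    """Per-OCR NB dispersion by pooled within-species method of moments.

    For each species group: alpha_hat = (var - mean) / mean^2 on
    normalized counts; group estimates are pooled with (n_g - 1) weights
    and floored at a small positive value. Single-replicate groups
    contribute nothing.

    With ``moderate=True`` (default) each per-OCR estimate is
    additionally floored at the dataset-wide median of the raw
    estimates. With the few replicates typical of cross-species designs
    the raw moment estimator is noisy, and OCRs whose dispersion is
    underestimated by chance inflate the likelihood-ratio statistic;
    the median floor restores type-I calibration at the cost of some
    power on genuinely low-dispersion OCRs.
    """
    num = np.zeros(len(counts))
    den = 0.0
    for species, sub in meta.groupby("species"):
        cols = [c for c in sub["sample_id"] if c in counts.columns]
        if len(cols) < 2:
            continue
        x = norm.normalized[cols].to_numpy()
        mu = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - mu) / mu**2
        num += (len(cols) - 1) * np.nan_to_num(a)
        den += len(cols) - 1
    alpha = num / den if den > 0 else np.zeros(len(counts))
    alpha = np.maximum(alpha, ALPHA_FLOOR)
    if moderate and len(alpha):
        alpha = np.maximum(alpha, np.median(alpha))
    return pd.Series(alpha, index=counts.index, name="alpha")


# ---------------------------------------------------------------------------
# vectorized NB group fits


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of NB(mu, alpha) log likelihood; Poisson limit for tiny alpha.

    y, mu: (n, k); alpha: (n, 1). Returns (n,).
    """
    pois = y * np.log(mu) - mu - gammaln(y + 1)
    a = np.maximum(alpha, _POISSON_CUTOFF)
    inv_a = 1.0 / a
    nb = (
        gammaln(y + inv_a)
        - gammaln(inv_a)
        - gammaln(y + 1)
        + y * (np.log(a * mu) - np.log1p(a * mu))
        - inv_a * np.log1p(a * mu)
    )
    out = np.where(alpha < _POISSON_CUTOFF, pois, nb)
    return out.sum(axis=1)


def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """MLE of the group mean m for y_j ~ NB(s_j * m, alpha), vectorized.

    The score f(m) = sum_j (y_j - s_j m) / (1 + alpha s_j m) is strictly
    decreasing in m, so the root is found by bisection. y: (n, k);
    s: (k,); alpha: (n, 1). Returns (n,).
    """

    def score(m):
        mu = s[None, :] * m[:, None]
        return ((y - mu) / (1.0 + alpha * mu)).sum(axis=1)

    lo = np.full(y.shape[0], 1e-9)
    hi = (y / s[None, :]).max(axis=1) + 1.0
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        pos = score(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


def _group_arrays(counts: pd.DataFrame, norm: NormalizationResult, meta: pd.DataFrame):
    samples = list(counts.columns)
    sf = norm.size_factors.loc[samples].to_numpy()
    y = counts.to_numpy(dtype=float)
    groups = {
        sp: [i for i, c in enumerate(samples) if meta.loc[c, "species"] == sp]
        for sp in meta.loc[samples, "species"].unique()
    }
    return y, sf, groups


def fit_species_model(
    counts: pd.DataFrame,
    norm: NormalizationResult,
    alpha: pd.Series,
    meta: pd.DataFrame,
) -> dict:
    """Fit per-species NB group means and the intercept-only model.

    Returns per-species mean estimates m_s, their Fisher information,
    and the log likelihood of both models, all vectorized over OCRs.
    """
    y, sf, groups = _group_arrays(counts, norm, meta)
    a = alpha.loc[counts.index].to_numpy()[:, None]
    means, infos = {}, {}
    ll_species = np.zeros(len(counts))
    for sp, idx in groups.items():
        m = _fit_group_mean(y[:, idx], sf[idx], a)
        mu = sf[idx][None, :] * m[:, None]
        means[sp] = m
        # Fisher information for beta = log m under the log link
        infos[sp] = (mu / (1.0 + a * mu)).sum(axis=1)
        ll_species += _nb_loglik(y[:, idx], mu, a)
    m0 = _fit_group_mean(y, sf, a)
    mu0 = sf[None, :] * m0[:, None]
    ll_null = _nb_loglik(y, mu0, a)
    return {
        "means": means,
        "info": infos,
        "ll_species": ll_species,
        "ll_null": ll_null,
        "n_species": len(groups),
    }


def test_species_effect(
    counts: pd.DataFrame,
    norm: NormalizationResult,
    alpha: pd.Series,
    meta: pd.DataFrame,
    fit: dict | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of the species model against intercept-only.

    The statistic 2*(l_species - l_null) is referred to chi-square with
    (n_species - 1) degrees of freedom; q is BH-adjusted across OCRs.
    """
    if fit is None:
        fit = fit_species_model(counts, norm, alpha, meta)
    if fit["n_species"] < 2:
        raise ValueError("species-effect test needs at least two species")
    stat = np.maximum(2.0 * (fit["ll_species"] - fit["ll_null"]), 0.0)
    p = stats.chi2.sf(stat, df=fit["n_species"] - 1)
    q = bh_adjust(p)
    return pd.DataFrame({"lrt_stat": stat, "p": p, "q": q}, index=counts.index)


def pairwise_contrast(
    counts: pd.DataFrame,
    norm: NormalizationResult,
    alpha: pd.Series,
    meta: pd.DataFrame,
    species_a: str,
    species_b: str,
    pseudocount: float = 0.5,
    fit: dict | None = None,
) -> pd.DataFrame:
    """Wald contrast of species_a vs species_b.

    The reported fold change is log2((mean_a + c) / (mean_b + c)) of the
    normalized group means with pseudocount c; the Wald test uses the
    GLM coefficient difference (no pseudocount) with its standard error
    from the Fisher information of the independent group fits.
    """
    if fit is None:
        fit = fit_species_model(counts, norm, alpha, meta)
    for sp in (species_a, species_b):
        if sp not in fit["means"]:
            raise ValueError(f"species {sp!r} absent from the fitted model")
    ma, mb = fit["means"][species_a], fit["means"][species_b]
    log2fc = np.log2((ma + pseudocount) / (mb + pseudocount))
    se_ln = np.sqrt(1.0 / fit["info"][species_a] + 1.0 / fit["info"][species_b])
    z = (np.log(ma) - np.log(mb)) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_adjust(p)
    return pd.DataFrame(
        {"log2fc": log2fc, "se": se_ln / np.log(2), "p": p, "q": q},
        index=counts.index,
    )


def pca_qc(
    norm: NormalizationResult, meta: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(normalized + 1); OCRs are the variables."""
    x = np.log2(norm.normalized + 1).to_numpy().T
    if x.shape[0] < 3:
        raise ValueError("PCA QC needs at least three samples")
    pca = PCA()
    coords = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    df = pd.DataFrame(coords, index=norm.normalized.columns, columns=cols)
    df["species"] = meta.loc[df.index, "species"].to_numpy()
    return df, pca.explained_variance_ratio_


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    q = multipletests(p, method="fdr_bh")[1]
    return q
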