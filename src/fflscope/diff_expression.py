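"""Simplified negative-binomial Wald differential expression.

Two-group (tumor vs normal) testing on raw counts: median-of-ratios size
factors, method-of-moments gene-wise dispersion, a delta-method standard
error on the log2 fold change and a normal Wald p-value. Deliberately
lighter than a full DESeq2-style engine — no dispersion shrinkage, no LFC
moderation, no independent filtering — but sharing its normalization and
its NB mean-variance model Var = mu + alpha * mu^2. The pipeline can also
ingest an externally produced DE table verbatim (``read_external_de_table``)
so downstream stages may run against a full DESeq2 output.

Calling conventions: log2fc is tumor over normal; features are called
``up`` / ``down`` at |log2fc| > 0.58 with raw Wald p < 0.05 (both
configurable), matching the thresholds the rest of the pipeline assumes.
BH q-values are reported alongside for the record but play no role in the
default status call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, SampleSheet, ValidationError, _read_tsv

logger = logging.getLogger(__name__)

#: pseudo-count added to normalized group means before taking log2
EPSILON = 0.5

#: dispersion floor (method-of-moments estimates can go negative)
MIN_DISPERSION = 1e-8


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Uses features with positive counts in every sample; if none exist,
    falls back to features positive in >= 90% of samples (geometric mean
    and per-sample median then taken over the positive entries only).
    """
    mat = counts.data.to_numpy(dtype=float)
    n_features, n_samples = mat.shape
    all_pos = (mat > 0).all(axis=1)
    if all_pos.any():
        sub = mat[all_pos]
        loggeo = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - loggeo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        frac_pos = (mat > 0).mean(axis=1)
        keep = frac_pos >= 0.9
        if not keep.any():
            raise ValidationError(
                "cannot estimate size factors: no feature positive in >= 90% of samples"
            )
        sub = mat[keep]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(np.maximum(sub, 1e-300)), np.nan)
        loggeo = np.nanmean(logs, axis=1)
        ratios = logs - loggeo[:, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalized_counts(counts: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    f = factors.reindex(counts.sample_ids)
    if f.isna().any():
        raise ValidationError("size factors missing for some samples")
    return counts.data / f.to_numpy()[None, :]


def log_expression(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(normalized count + 1), the expression scale used for pairing
    and correlation throughout the pipeline."""
    if factors is None:
        factors = estimate_size_factors(counts)
    return np.log2(normalized_counts(counts, factors) + 1.0)


def nb_wald_test(
    counts: CountMatrix,
    sheet: SampleSheet,
    factors: pd.Series | None = None,
    lfc_cut: float = 0.58,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Per-feature NB Wald test of tumor vs normal.

    Returns a DataFrame indexed by feature with columns baseMean, log2fc,
    se, wald_p, qvalue, status. All-zero features are reported with status
    ``ns`` and NaN statistics.
    """
    if factors is None:
        factors = estimate_size_factors(counts)
    tumor = [s for s in sheet.samples("tumor") if s in counts.data.columns]
    normal = [s for s in sheet.samples("normal") if s in counts.data.columns]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValidationError("need >= 2 samples per group for the Wald test")

    norm = normalized_counts(counts, factors)
    xt = norm[tumor].to_numpy()
    xn = norm[normal].to_numpy()
    nt, nn = xt.shape[1], xn.shape[1]

    mt = xt.mean(axis=1)
    mn = xn.mean(axis=1)
    vt = xt.var(axis=1, ddof=1)
    vn = xn.var(axis=1, ddof=1)

    # method-of-moments dispersion from the NB model Var = mu + alpha mu^2,
    # pooled across the two groups and floored
    num = (nt - 1) * (vt - mt) + (nn - 1) * (vn - mn)
    den = (nt - 1) * mt**2 + (nn - 1) * mn**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    alpha = np.maximum(alpha, MIN_DISPERSION)

    log2fc = np.log2(mt + EPSILON) - np.log2(mn + EPSILON)
    ln2sq = np.log(2.0) ** 2
    var_lfc = (
        (mt + alpha * mt**2) / (nt * (mt + EPSILON) ** 2)
        + (mn + alpha * mn**2) / (nn * (mn + EPSILON) ** 2)
    ) / ln2sq
    se = np.sqrt(var_lfc)

    all_zero = (mt == 0) & (mn == 0)
    n_zero = int(all_zero.sum())
    if n_zero:
        logger.warning("nb_wald_test: %d all-zero features reported as ns", n_zero)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    wald_p = np.where(all_zero, np.nan, wald_p)

    finite = ~np.isnan(wald_p)
    qvalue = np.full_like(wald_p, np.nan)
    if finite.any():
        qvalue[finite] = multipletests(wald_p[finite], method="fdr_bh")[1]

    status = np.full(len(log2fc), "ns", dtype=object)
    sig = finite & (wald_p < p_cut)
    status[sig & (log2fc > lfc_cut)] = "up"
    status[sig & (log2fc < -lfc_cut)] = "down"
    status[all_zero] = "ns"

    base_mean = np.concatenate([xt, xn], axis=1).mean(axis=1)
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2fc": np.where(all_zero, np.nan, log2fc),
            "se": np.where(all_zero, np.nan, se),
            "wald_p": wald_p,
            "qvalue": qvalue,
            "status": status,
        },
        index=pd.Index(counts.feature_ids, name="feature"),
    )
    return out


def read_external_de_table(path) -> pd.DataFrame:
    """Load an externally produced DE table (e.g. from DESeq2).

    Required columns: feature, log2fc, wald_p, status. Extra columns are
    carried through untouched.
    """
    df = _read_tsv(path, ["feature", "log2fc", "wald_p", "status"])
    df = df.set_index("feature")
    df["log2fc"] = df["log2fc"].astype(float)
    df["wald_p"] = df["wald_p"].astype(float)
    bad = set(df["status"]) - {"up", "down", "ns"}
    if bad:
        raise ValidationError(f"external DE table has unknown status labels: {sorted(bad)}")
    return df


def de_features(de: pd.DataFrame, direction: str | None = None) -> set[str]:
    """Features called differential; optionally restricted to up or down."""
    if direction is None:
        return set(de.index[de["status"] != "ns"])
    return set(de.index[de["status"] == direction])
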