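"""Dataset-level QC analytics: rank correlations, PCA, aggregation profiles,
and distribution comparisons of melting parameters.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ProfilesQCError",
    "spearman_matrix",
    "PCAResult",
    "pca_variance",
    "MannWhitneyResult",
    "compare_param_distributions",
    "AggregatedProfile",
    "aggregated_fraction_profile",
    "parameter_distribution_tests",
]


class ProfilesQCError(ValueError):
    """Invalid input to a QC analytic."""


def spearman_matrix(expr: pd.DataFrame, min_overlap: int = 3) -> pd.DataFrame:
    """Pairwise Spearman rank correlations between samples (columns).

    ``expr`` is proteins × samples.  Each pair uses its pairwise-complete
    observations; pairs sharing fewer than ``min_overlap`` finite values get
    NaN with a warning.  Ties are handled by average ranks (scipy).  The
    result is symmetric with a unit diagonal.
    """
    samples = list(expr.columns)
    n = len(samples)
    if n < 2:
        raise ProfilesQCError("need at least 2 samples for pairwise correlation")
    out = pd.DataFrame(np.eye(n), index=samples, columns=samples, dtype=float)
    values = expr.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.isfinite(values[:, i]) & np.isfinite(values[:, j])
            if int(mask.sum()) < min_overlap:
                log.warning(
                    "samples %s/%s share only %d finite observations; correlation omitted",
                    samples[i], samples[j], int(mask.sum()),
                )
                rho = np.nan
            else:
                rho = stats.spearmanr(values[mask, i], values[mask, j]).statistic
            out.iat[i, j] = rho
            out.iat[j, i] = rho
    return out


@dataclasses.dataclass
class PCAResult:
    """PCA of samples (observations) in protein space (variables).

    ``fractions`` are variance-explained fractions summing to 1, components
    ordered by decreasing variance.  Sign convention: within each loading
    vector the entry of largest magnitude is positive.  ``scores`` is
    samples × components, ``loadings`` components × proteins;
    ``scores @ loadings`` reconstructs the centered matrix.
    """

    fractions: np.ndarray
    scores: pd.DataFrame
    loadings: np.ndarray
    n_proteins_used: int


def pca_variance(expr: pd.DataFrame) -> PCAResult:
    """Principal component decomposition of sample expression profiles.

    Proteins (rows) with any missing value are dropped (complete-case).
    Rank deficiency after centering yields trailing zero-variance components
    rather than an error.
    """
    complete = expr.dropna(axis=0, how="any")
    if complete.shape[0] < 2 or complete.shape[1] < 2:
        raise ProfilesQCError(
            "need ≥ 2 proteins and ≥ 2 samples after dropping missing rows"
        )
    x = complete.to_numpy(dtype=float).T  # samples × proteins
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(vt.shape[0]):
        jmax = int(np.argmax(np.abs(vt[k])))
        if vt[k, jmax] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    var = s**2
    total = float(var.sum())
    fractions = var / total if total > 0 else np.full_like(var, np.nan)
    scores = pd.DataFrame(
        u * s,
        index=list(expr.columns),
        columns=[f"PC{k + 1}" for k in range(len(s))],
    )
    return PCAResult(
        fractions=fractions,
        scores=scores,
        loadings=vt,
        n_proteins_used=complete.shape[0],
    )


@dataclasses.dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    n_a: int
    n_b: int
    method: str


def compare_param_distributions(
    values_a, values_b, alternative: str = "two-sided"
) -> MannWhitneyResult:
    """Mann–Whitney U comparison of two parameter distributions.

    Uses exact enumeration for small tie-free samples (both n ≤ 8) and the
    tie-corrected normal approximation otherwise.  U is reported for the
    first sample.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ProfilesQCError("both samples must contain at least one value")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return MannWhitneyResult(
        u=float(res.statistic), p=float(res.pvalue), n_a=int(a.size), n_b=int(b.size),
        method=method,
    )


@dataclasses.dataclass
class AggregatedProfile:
    """Mean aggregated/denatured fraction at each gradient temperature.

    ``aggregated`` clips each protein's 1 − FC into [0, 1] before averaging
    (over-recovered points contribute 0); ``raw`` is the unclipped mean.
    """

    temperatures: np.ndarray
    aggregated: np.ndarray
    raw: np.ndarray


def aggregated_fraction_profile(
    fold_changes, temperatures=None
) -> AggregatedProfile:
    """Per-temperature mean aggregated fraction 1 − FC across proteins.

    ``fold_changes`` is proteins × temperatures, already normalized so the
    reference (lowest-temperature) column equals 1; the profile there is 0.
    """
    fc = np.asarray(fold_changes, dtype=float)
    if fc.ndim == 1:
        fc = fc[None, :]
    if temperatures is None:
        temps = np.arange(fc.shape[1], dtype=float)
    else:
        temps = np.asarray(temperatures, dtype=float)
    ref = fc[:, int(np.argmin(temps))] if temperatures is not None else fc[:, 0]
    ref = ref[np.isfinite(ref)]
    if ref.size and not np.allclose(ref, 1.0):
        log.warning("fold changes do not equal 1 at the reference temperature")
    agg = 1.0 - fc
    with np.errstate(invalid="ignore"):
        clipped = np.clip(agg, 0.0, 1.0)
    return AggregatedProfile(
        temperatures=temps,
        aggregated=np.nanmean(clipped, axis=0),
        raw=np.nanmean(agg, axis=0),
    )


def parameter_distribution_tests(
    fits: pd.DataFrame,
    control_condition: str = "control",
    parameters: tuple[str, ...] = ("tm", "slope", "plateau"),
) -> pd.DataFrame:
    """Mann–Whitney comparison of fitted-parameter distributions, each
    treatment against the control, restricted to QC-passing fits."""
    ok = fits[fits["qc_pass"].astype(bool)]
    ctrl = ok[ok["condition"] == control_condition]
    if ctrl.empty:
        raise ProfilesQCError(f"no QC-passing control fits ({control_condition!r})")
    rows = []
    for treatment in pd.unique(ok["condition"]):
        if treatment == control_condition:
            continue
        sub = ok[ok["condition"] == treatment]
        for param in parameters:
            res = compare_param_distributions(sub[param], ctrl[param])
            rows.append(
                {
                    "condition": treatment,
                    "parameter": param,
                    "u": res.u,
                    "p": res.p,
                    "n_treatment": res.n_a,
                    "n_control": res.n_b,
                    "median_difference": float(
                        np.nanmedian(sub[param]) - np.nanmedian(ctrl[param])
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "condition", "parameter", "u", "p", "n_treatment", "n_control",
            "median_difference",
        ],
    )
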