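"""Paired differential expression between iPSC and MK lines.

The analysis chain: retain transcripts whose raw-FPKM interquartile
range across all samples exceeds a threshold; form the per-subject
paired difference Delta = mean over technical replicates of
log2(FPKM_iPSC + 1) - log2(FPKM_MK + 1); take the first two principal
components of Delta as nuisance covariates; fit, per transcript,

    Delta_ij = beta0_i + beta1_i * PC1_j + beta2_i * PC2_j + eps_ij

and test beta0_i (the cell-type contrast) with an empirical-Bayes
moderated t-statistic, converting p-values to Storey q-values.  A
negative beta0 means the transcript is higher in MK.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .datatypes import ExpressionStudy

__all__ = [
    "iqr_filter",
    "build_delta",
    "DeltaMatrix",
    "compute_pcs",
    "PCScores",
    "fit_moderated",
    "DEResult",
    "qvalues",
]


def iqr_filter(study: ExpressionStudy, threshold: float = 1.0) -> list[str]:
    """Transcripts whose raw-FPKM IQR across ALL samples exceeds ``threshold``.

    The IQR keeps transcripts absent in one cell type but modestly
    expressed in the other (the signal of interest here) while dropping
    single-sample outliers that a mean or variance filter would keep.
    Quartiles use linear interpolation between order statistics.
    """
    if study.n_samples < 4:
        raise ValueError("IQR filter needs at least 4 samples")
    vals = study.fpkm.to_numpy(float)
    q75, q25 = np.percentile(vals, [75, 25], axis=1)
    keep = (q75 - q25) > threshold
    return [str(t) for t in study.fpkm.index[keep]]


@dataclass
class DeltaMatrix:
    """Per-subject averaged paired log2 differences, iPSC minus MK."""

    delta: pd.DataFrame  # transcripts x subjects
    provenance: dict[str, list[str]]  # subject -> replicates used


def build_delta(
    study: ExpressionStudy,
    transcripts: Optional[Sequence[str]] = None,
    offset: float = 1.0,
) -> DeltaMatrix:
    """Paired log-difference construction with technical-replicate averaging.

    For each subject and replicate r with both cell types present,
    d_r = log2(FPKM_iPSC,r + offset) - log2(FPKM_MK,r + offset); the
    subject's column is the mean of its available d_r.  Subjects with a
    single complete replicate use it alone (flagged via a warning and
    the provenance record); subjects with none are excluded.
    """
    fpkm = study.fpkm if transcripts is None else study.fpkm.loc[list(transcripts)]
    log2 = np.log2(fpkm.to_numpy(float) + offset)
    log2 = pd.DataFrame(log2, index=fpkm.index, columns=fpkm.columns)
    cols: dict[str, np.ndarray] = {}
    provenance: dict[str, list[str]] = {}
    for subject in dict.fromkeys(study.samples["subject"]):
        diffs, reps = [], []
        for rep in ("A", "B"):
            ipsc = study.sample_id(subject, "iPSC", rep)
            mk = study.sample_id(subject, "MK", rep)
            if ipsc is None or mk is None:
                continue
            diffs.append(log2[ipsc].to_numpy() - log2[mk].to_numpy())
            reps.append(rep)
        if not diffs:
            warnings.warn(f"subject {subject}: no complete iPSC/MK pair; excluded")
            continue
        if len(diffs) == 1:
            warnings.warn(f"subject {subject}: single technical replicate {reps[0]}")
        cols[subject] = np.mean(diffs, axis=0)
        provenance[subject] = reps
    if not cols:
        raise ValueError("no subject has a complete iPSC/MK pair")
    delta = pd.DataFrame(cols, index=fpkm.index)
    return DeltaMatrix(delta=delta, provenance=provenance)


@dataclass
class PCScores:
    scores: pd.DataFrame  # subjects x k
    variance_fractions: np.ndarray


def compute_pcs(delta: DeltaMatrix, k: int = 2) -> PCScores:
    """Subject-level scores of the top-k principal components of Delta.

    Each subject's column is centered (its mean over transcripts
    removed); no scaling.  Column centering lets the scores retain
    subject-level offsets, so a batch factor that shifts whole subjects
    can be absorbed by the regression instead of leaking into the
    intercept.  Components whose subject profile is statistically
    constant (|score mean| > 5 x score sd) are skipped: such a
    component is the transcript-mean direction, collinear with the
    fitted intercept, and would render the cell-type contrast
    unidentifiable.  The sign of each kept component is fixed so its
    largest-magnitude transcript loading is positive.
    """
    X = delta.delta.to_numpy(float)
    n_subjects = X.shape[1]
    if k >= n_subjects:
        raise ValueError(f"k={k} requires more than {k} subjects")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    chosen: list[int] = []
    for j in range(S.size):
        if len(chosen) == k:
            break
        sc = Vt[j] * S[j]
        sd = sc.std()
        if sd > 0 and abs(sc.mean()) > 5.0 * sd:
            continue  # intercept-collinear component
        chosen.append(j)
    if len(chosen) < k:  # degenerate input: fall back to leading components
        chosen = list(range(k))
    for j in chosen:
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    scores = np.column_stack([Vt[j] * S[j] for j in chosen])
    var = S**2
    fractions = var[chosen] / var.sum() if var.sum() > 0 else np.zeros(k)
    return PCScores(
        scores=pd.DataFrame(
            scores, index=delta.delta.columns,
            columns=[f"PC{i + 1}" for i in range(len(chosen))],
        ),
        variance_fractions=fractions,
    )


@dataclass
class DEResult:
    """Per-transcript moderated inference on the cell-type contrast."""

    table: pd.DataFrame  # beta0, s2, s2_post, t, p, q, direction, log2fc_mk
    d0: float  # prior degrees of freedom
    s0_sq: float  # prior variance
    residual_df: int


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, monotone decreasing)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled F to the log residual variances (eBayes).

    log s2 - digamma(df/2) + log(df/2) has mean digamma(d0/2) - log(d0/2)
    + log s0^2 and excess variance trigamma(d0/2); invert the trigamma
    to get the prior df d0 and back out the prior variance s0^2.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    evar = e.var(ddof=1)
    excess = evar - polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(ebar))
    half_d0 = _trigamma_inverse(float(excess))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(ebar + digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def fit_moderated(
    delta: DeltaMatrix,
    pcs: Optional[PCScores] = None,
    d0_override: Optional[float] = None,
    s0_sq_override: Optional[float] = None,
    sig_q: float = 0.05,
) -> DEResult:
    """Per-transcript OLS of Delta on [1, PC1, PC2] with moderated t.

    Empirical-Bayes hyperparameters (d0, s0^2) are estimated from the
    ensemble of residual variances by moment matching on the log scale;
    the posterior variance s2_post = (d0*s0^2 + df*s2) / (d0 + df)
    shrinks each transcript toward the pooled prior, and the moderated
    t = beta0 / (sqrt(s2_post) * c) is referred to a t distribution
    with df + d0 degrees of freedom.  ``d0_override=0`` recovers the
    ordinary per-transcript t exactly.

    The ``direction`` label and user-facing ``log2fc_mk`` report the MK
    minus iPSC orientation (= -beta0), so "up in MK" is positive.
    """
    D = delta.delta.to_numpy(float)
    n_tx, n_subjects = D.shape
    if pcs is None:
        X = np.ones((n_subjects, 1))
    else:
        X = np.column_stack([np.ones(n_subjects), pcs.scores.to_numpy(float)])
    p = X.shape[1]
    df = n_subjects - p
    if df < 1:
        raise ValueError(f"need more than {p} subjects for residual df >= 1")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = D @ X @ XtX_inv  # n_tx x p
    resid = D - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df
    if (s2 == 0).all():
        raise ValueError("all residual variances are zero: degenerate input")
    c = float(np.sqrt(XtX_inv[0, 0]))  # intercept SE factor

    if d0_override is not None or s0_sq_override is not None:
        d0_est, s0_est = _estimate_prior(s2, df)
        d0 = float(d0_override) if d0_override is not None else d0_est
        s0_sq = float(s0_sq_override) if s0_sq_override is not None else s0_est
    else:
        d0, s0_sq = _estimate_prior(s2, df)
    if not np.isfinite(d0) and d0_override is None and not np.isfinite(s0_sq):
        warnings.warn("prior df estimate non-finite; falling back to ordinary t")
        d0, s0_sq = 0.0, 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        total_df: float = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 0] / (np.sqrt(s2_post) * c)
    if np.isinf(total_df):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), total_df)
    q = qvalues(pvals)
    beta0 = beta[:, 0]
    direction = np.where(beta0 < 0, "up_in_MK", "down_in_MK")
    table = pd.DataFrame(
        {
            "beta0": beta0,
            "s2": s2,
            "s2_post": s2_post,
            "t": t,
            "p": pvals,
            "q": q,
            "direction": direction,
            "log2fc_mk": -beta0,
            "significant": q < sig_q,
        },
        index=delta.delta.index,
    )
    return DEResult(table=table, d0=d0, s0_sq=s0_sq, residual_df=df)


def qvalues(
    pvals: np.ndarray,
    pi0: Optional[float] = None,
    lambdas: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Storey q-values with a smoothed pi0 estimate.

    pi0 is estimated by fitting a cubic trend to pi0(lambda) =
    #{p > lambda} / (m (1 - lambda)) over lambda = 0.05..0.95 and
    evaluating at the largest lambda; pass ``pi0=1`` for plain
    Benjamini-Hochberg behaviour.  Output is monotone in p and <= 1.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        lams = np.arange(0.05, 0.96, 0.05) if lambdas is None else np.asarray(lambdas)
        pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in lams])
        if m < 100 or np.ptp(pi0_lam) == 0:
            pi0_est = float(min(pi0_lam[-1], 1.0))
        else:
            coeffs = np.polyfit(lams, pi0_lam, 3)
            pi0_est = float(np.polyval(coeffs, lams[-1]))
        pi0 = float(np.clip(pi0_est, 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
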