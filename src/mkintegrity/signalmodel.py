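"""SNP-array signal model shared by the simulator and the CNV caller.

Per probe, the array reports a Log R Ratio (LRR, total-intensity log2
ratio whose mean shifts with copy number) and a B allele frequency
(BAF in [0, 1] whose band structure reflects the allelic copy state).
Copy number c places BAF bands at k/c for k = 0..c B alleles, weighted
by Hardy-Weinberg at the probe's population B-allele frequency; copy
number 0 has no allelic signal and the BAF is uniform noise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import comb

#: default per-state LRR emission means for copy numbers 0..4
LRR_MEANS = (-3.5, -0.66, 0.0, 0.40, 0.68)

#: fraction of probes whose BAF is an outlier drawn uniformly on [0, 1]
BAF_OUTLIER_FRACTION = 0.01

COPY_NUMBERS = (0, 1, 2, 3, 4)


def baf_bands(copy_number: int, maf: float) -> tuple[np.ndarray, np.ndarray]:
    """BAF band positions and Hardy-Weinberg weights for one copy state.

    Returns (bands, weights); for copy number 0 both are empty (the BAF
    is pure uniform noise).
    """
    if copy_number == 0:
        return np.empty(0), np.empty(0)
    c = copy_number
    k = np.arange(c + 1)
    bands = k / c
    weights = comb(c, k) * maf**k * (1.0 - maf) ** (c - k)
    return bands, weights / weights.sum()


def sample_baf(
    copy_number: int | np.ndarray,
    maf: np.ndarray,
    baf_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw BAFs for probes sharing one copy state.

    Band membership is Hardy-Weinberg at each probe's MAF; Gaussian
    jitter is added and the result truncated (clipped) to [0, 1], which
    reproduces the mass real arrays pile at the homozygous rails.  A
    small outlier fraction is drawn uniformly.
    """
    maf = np.atleast_1d(np.asarray(maf, float))
    n = maf.shape[0]
    if np.isscalar(copy_number) or np.ndim(copy_number) == 0:
        cn = np.full(n, int(copy_number))
    else:
        cn = np.asarray(copy_number, int)
    out = np.empty(n)
    for c in np.unique(cn):
        idx = np.flatnonzero(cn == c)
        if c == 0:
            out[idx] = rng.uniform(0.0, 1.0, idx.size)
            continue
        k = rng.binomial(c, maf[idx])
        vals = k / c + rng.normal(0.0, baf_sd, idx.size)
        out[idx] = np.clip(vals, 0.0, 1.0)
    outlier = rng.uniform(0.0, 1.0, n) < BAF_OUTLIER_FRACTION
    out[outlier] = rng.uniform(0.0, 1.0, int(outlier.sum()))
    return out


def _truncnorm_logpdf(x: np.ndarray, loc: float, sd: float) -> np.ndarray:
    a, b = (0.0 - loc) / sd, (1.0 - loc) / sd
    return stats.truncnorm.logpdf(x, a, b, loc=loc, scale=sd)


def baf_loglik(
    baf: np.ndarray,
    maf: np.ndarray,
    copy_number: int,
    baf_sd: float,
    outlier_fraction: float = BAF_OUTLIER_FRACTION,
) -> np.ndarray:
    """Log-density of observed BAFs under one copy state.

    Mixture of [0,1]-truncated Gaussians centred on the state's bands
    (Hardy-Weinberg weights at each probe's MAF) plus a uniform outlier
    component.
    """
    baf = np.asarray(baf, float)
    maf = np.asarray(maf, float)
    if copy_number == 0:
        return np.zeros_like(baf)  # log uniform density on [0,1]
    c = copy_number
    k = np.arange(c + 1)
    # per-probe HW weights, shape (n, c+1)
    w = comb(c, k)[None, :] * maf[:, None] ** k * (1 - maf[:, None]) ** (c - k)
    w /= w.sum(axis=1, keepdims=True)
    dens = np.zeros_like(baf)
    for j, band in enumerate(k / c):
        dens += w[:, j] * np.exp(_truncnorm_logpdf(baf, band, baf_sd))
    dens = (1.0 - outlier_fraction) * dens + outlier_fraction * 1.0
    return np.log(dens)
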