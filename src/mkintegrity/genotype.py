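"""Genotype fidelity across the MNC -> iPSC -> MK lineage.

Four operations: sliding-window LD pruning of the marker set, pairwise
identity-by-descent (IBD) estimation by the method of moments, pairwise
genotype discordance counting, and the transmitted-discordance "mutation
rate" (MNC vs iPSC mismatches that the paired MK inherited, interpreted
as reprogramming-era somatic mutations).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .datatypes import MISSING, GenotypePanel

__all__ = [
    "IBDEstimate",
    "DiscordanceReport",
    "TransmittedReport",
    "ld_prune",
    "estimate_ibd",
    "count_discordances",
    "transmitted_discordance",
    "round_sigfig",
]


@dataclass
class IBDEstimate:
    sample_a: str
    sample_b: str
    z0: float
    z1: float
    z2: float
    relationship: str  # within-subject | between-subject
    n_markers: int
    flagged: bool = False


@dataclass
class DiscordanceReport:
    sample_a: str
    sample_b: str
    n_compared: int
    n_discordant: int

    @property
    def rate(self) -> float:
        return self.n_discordant / self.n_compared if self.n_compared else float("nan")


@dataclass
class TransmittedReport:
    subject: str
    replicate: str
    n_snps_compared: int  # all three calls non-missing
    n_mnc_ipsc_discordant: int
    n_transmitted: int  # MNC != iPSC and iPSC == MK

    @property
    def transmitted_rate_percent(self) -> float:
        if not self.n_snps_compared:
            return float("nan")
        return 100.0 * self.n_transmitted / self.n_snps_compared


def round_sigfig(x: float, digits: int = 1) -> float:
    """Round to a number of significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage columns over jointly
    non-missing samples (composite LD)."""
    k = calls.shape[1]
    if (calls == MISSING).any():
        r2 = np.zeros((k, k))
        for i, j in combinations(range(k), 2):
            gi, gj = calls[:, i], calls[:, j]
            ok = (gi != MISSING) & (gj != MISSING)
            if ok.sum() < 2:
                continue
            xi, xj = gi[ok].astype(float), gj[ok].astype(float)
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            r2[i, j] = r2[j, i] = r * r
        return r2
    X = calls.astype(float)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    np.fill_diagonal(r, 0.0)
    return r * r


def _mafs(calls: np.ndarray) -> np.ndarray:
    """Per-SNP minor-allele frequency from observed dosages."""
    miss = calls == MISSING
    n_called = (~miss).sum(axis=0)
    total = np.where(miss, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, total / (2.0 * n_called), 0.0)
    return np.minimum(p, 1.0 - p)


def ld_prune(
    panel: GenotypePanel,
    window: int = 50,
    step: int = 5,
    r2_threshold: float = 0.3,
) -> list[int]:
    """Greedy sliding-window LD pruning; returns retained SNP indices.

    Within each ``window``-SNP window (advanced by ``step``, restarted
    per chromosome), while any retained pair has dosage-correlation
    r^2 above the threshold, one member of the worst pair is removed:
    the SNP with the lower MAF, or on ties the later-positioned one.
    """
    if window < 2:
        raise ValueError("window must span at least 2 SNPs")
    if not 0.0 < r2_threshold < 1.0:
        raise ValueError("r2_threshold must lie in (0, 1)")
    calls = panel.calls.T  # SNPs x samples -> work column-wise below
    maf = _mafs(panel.calls)
    if (maf == 0).all():
        warnings.warn("panel has no polymorphic SNPs; nothing to prune")
        return list(range(panel.n_snps))
    keep = np.ones(panel.n_snps, dtype=bool)
    chroms = panel.snps["chrom"].to_numpy()
    for chrom in dict.fromkeys(chroms):
        idx_chr = np.flatnonzero(chroms == chrom)
        n = idx_chr.size
        for w0 in range(0, max(n - 1, 1), step):
            widx = idx_chr[w0 : w0 + window]
            live = widx[keep[widx]]
            if live.size >= 2:
                # removing a SNP never changes the r^2 of remaining pairs,
                # so one matrix per window suffices
                r2 = _pairwise_r2(panel.calls[:, live])
                alive = np.ones(live.size, dtype=bool)
                while alive.sum() >= 2:
                    sub = np.where(np.outer(alive, alive), r2, 0.0)
                    worst = np.unravel_index(np.argmax(sub), sub.shape)
                    if sub[worst] <= r2_threshold:
                        break
                    a, b = live[worst[0]], live[worst[1]]
                    if maf[a] < maf[b]:
                        drop_local, drop = worst[0], a
                    elif maf[b] < maf[a]:
                        drop_local, drop = worst[1], b
                    else:  # positions increase with index
                        drop_local, drop = max(worst), max(a, b)
                    keep[drop] = False
                    alive[drop_local] = False
            if w0 + window >= n:
                break
    return [int(i) for i in np.flatnonzero(keep)]


# ---------------------------------------------------------------------------
# IBD estimation (method of moments)
# ---------------------------------------------------------------------------


def _falling(x: np.ndarray, k: int) -> np.ndarray:
    out = np.ones_like(x, dtype=float)
    for i in range(k):
        out *= x - i
    return out


def _ibs_expectations(
    founder_calls: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker P(IBS=i | IBD=z) with finite-sample bias correction.

    Allele frequencies are estimated from founder samples; each
    polynomial in the true frequency (p^a q^b) is replaced by its
    unbiased factorial-moment estimator from the founder allele counts,
    the standard small-sample correction for method-of-moments IBD.
    Returns (P0|0, P1|0, P2|0, P1|1, P2|1) arrays over markers.
    """
    miss = founder_calls == MISSING
    X = np.where(miss, 0, founder_calls).sum(axis=0).astype(float)  # B-allele counts
    Na = 2.0 * (~miss).sum(axis=0)  # called allele counts
    Y = Na - X

    def mono(a: int, b: int) -> np.ndarray:
        """Unbiased estimate of p^a q^b per marker."""
        num = _falling(X, a) * _falling(Y, b)
        den = _falling(Na, a + b)
        with np.errstate(invalid="ignore", divide="ignore"):
            est = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return np.clip(est, 0.0, 1.0)

    p2q2 = mono(2, 2)
    p00 = 2.0 * p2q2
    p10 = 4.0 * mono(3, 1) + 4.0 * mono(1, 3)
    p20 = mono(4, 0) + mono(0, 4) + 4.0 * p2q2
    p11 = 2.0 * mono(2, 1) + 2.0 * mono(1, 2)
    p21 = mono(3, 0) + mono(0, 3) + mono(2, 1) + mono(1, 2)
    return p00, p10, p20, p11, p21


def estimate_ibd(
    panel: GenotypePanel,
    markers: Optional[Sequence[int]] = None,
    min_markers: int = 100,
    min_informative: int = 50,
) -> list[IBDEstimate]:
    """Method-of-moments IBD sharing (Z0, Z1, Z2) for all sample pairs.

    Observed identity-by-state (IBS) counts are matched to their
    expectations given IBD state; allele frequencies come from the
    founder-like samples (one MNC per subject, or all samples if no MNC
    is present).  Estimates are clipped to [0, 1] and renormalized to
    sum to one.  Pairs with fewer than ``min_informative`` jointly
    non-missing markers are flagged, not estimated.
    """
    idx = np.arange(panel.n_snps) if markers is None else np.asarray(markers, int)
    if idx.size < min_markers:
        raise ValueError(f"need at least {min_markers} markers, got {idx.size}")
    calls = panel.calls[:, idx]
    founders = [i for i, s in enumerate(panel.samples) if s.cell_type == "MNC"]
    founder_calls = calls[founders] if founders else calls
    p00, p10, p20, p11, p21 = _ibs_expectations(founder_calls)

    results = []
    for ia, ib in combinations(range(panel.n_samples), 2):
        sa, sb = panel.samples[ia], panel.samples[ib]
        ga, gb = calls[ia], calls[ib]
        ok = (ga != MISSING) & (gb != MISSING)
        rel = "within-subject" if sa.subject == sb.subject else "between-subject"
        m = int(ok.sum())
        if m < min_informative:
            results.append(
                IBDEstimate(sa.sample_id, sb.sample_id, float("nan"), float("nan"),
                            float("nan"), rel, m, flagged=True)
            )
            continue
        ibs = 2 - np.abs(ga[ok].astype(int) - gb[ok].astype(int))
        n0 = float((ibs == 0).sum())
        n1 = float((ibs == 1).sum())
        n2 = float((ibs == 2).sum())
        e00, e10, e20 = p00[ok].sum(), p10[ok].sum(), p20[ok].sum()
        e11, e21 = p11[ok].sum(), p21[ok].sum()
        z0 = n0 / e00 if e00 > 0 else 0.0
        z1 = (n1 - z0 * e10) / e11 if e11 > 0 else 0.0
        z2 = (n2 - z0 * e20 - z1 * e21) / m
        z = np.clip([z0, z1, z2], 0.0, 1.0)
        z = z / z.sum() if z.sum() > 0 else np.array([0.0, 0.0, 1.0])
        results.append(
            IBDEstimate(sa.sample_id, sb.sample_id, float(z[0]), float(z[1]),
                        float(z[2]), rel, m)
        )
    return results


# ---------------------------------------------------------------------------
# discordance
# ---------------------------------------------------------------------------


def count_discordances(panel: GenotypePanel, pair: tuple[str, str]) -> DiscordanceReport:
    """Count genotype mismatches between two lines, missing calls excluded."""
    a, b = pair
    if a == b:
        raise ValueError("cannot compare a sample with itself")
    ga, gb = panel.row(a), panel.row(b)
    ok = (ga != MISSING) & (gb != MISSING)
    return DiscordanceReport(a, b, int(ok.sum()), int((ga[ok] != gb[ok]).sum()))


def transmitted_discordance(
    panel: GenotypePanel, subject: str, replicate: str
) -> TransmittedReport:
    """Transmitted discordances for one subject's lineage replicate.

    A transmitted discordance is a SNP (all three calls non-missing)
    where the MNC and iPSC disagree but the MK matches the iPSC — the
    signature of a mutation arising at reprogramming and carried into
    the differentiated line.
    """
    ids = {}
    for cell_type, rep in (("MNC", ""), ("iPSC", replicate), ("MK", replicate)):
        sid = panel.find(subject, cell_type, rep)
        if sid is None:
            raise ValueError(
                f"subject {subject}: no {cell_type}"
                + (f" replicate {rep}" if rep else "")
                + " line in panel"
            )
        ids[cell_type] = sid
    mnc = panel.row(ids["MNC"])
    ipsc = panel.row(ids["iPSC"])
    mk = panel.row(ids["MK"])
    ok = (mnc != MISSING) & (ipsc != MISSING) & (mk != MISSING)
    disc = ok & (mnc != ipsc)
    transmitted = disc & (ipsc == mk)
    return TransmittedReport(
        subject, replicate, int(ok.sum()), int(disc.sum()), int(transmitted.sum())
    )
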