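"""Copy-number calling from SNP-array LRR/BAF tracks.

A five-state hidden Markov model over copy numbers 0-4 emits, per probe,
a Gaussian Log R Ratio and a genotype-band-mixture B allele frequency
(conditionally independent given the state).  Decoding is exact Viterbi
in log space, per chromosome.  Maximal runs of a constant non-diploid
state with at least ``min_probes`` probes become called segments; parent
and daughter call sets are compared by reciprocal overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CNVSegment, IntensityTrack
from .signalmodel import BAF_OUTLIER_FRACTION, COPY_NUMBERS, LRR_MEANS, baf_loglik

__all__ = [
    "HMMModel",
    "emission_loglik",
    "viterbi_decode",
    "call_segments",
    "compare_cnv_sets",
    "CNVComparison",
    "evidence_extract",
]


@dataclass
class HMMModel:
    """Parameters of the copy-number HMM.

    ``state_change_prob`` is the total per-step probability of leaving
    the current state, split evenly among the four other states;
    distance between probes is not modelled.
    """

    lrr_means: tuple[float, ...] = LRR_MEANS
    lrr_sds: tuple[float, ...] = (0.25,) * 5
    baf_sd: float = 0.03
    baf_outlier_fraction: float = BAF_OUTLIER_FRACTION
    state_change_prob: float = 1e-4
    initial: tuple[float, ...] = (0.2,) * 5

    def __post_init__(self) -> None:
        if len(self.lrr_means) != 5 or len(self.lrr_sds) != 5:
            raise ValueError("model needs parameters for copy numbers 0..4")
        if any(s <= 0 for s in self.lrr_sds) or self.baf_sd <= 0:
            raise ValueError("emission standard deviations must be positive")
        if not 0.0 <= self.baf_outlier_fraction < 1.0:
            raise ValueError("outlier fraction must lie in [0, 1)")
        if not 0.0 < self.state_change_prob < 1.0:
            raise ValueError("state change probability must lie in (0, 1)")

    @property
    def log_transition(self) -> np.ndarray:
        t = np.full((5, 5), self.state_change_prob / 4.0)
        np.fill_diagonal(t, 1.0 - self.state_change_prob)
        return np.log(t)

    @property
    def log_initial(self) -> np.ndarray:
        return np.log(np.asarray(self.initial) / np.sum(self.initial))


def emission_loglik(
    model: HMMModel,
    lrr: np.ndarray,
    baf: np.ndarray,
    maf: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-probe, per-state emission log-likelihoods, shape (n, 5).

    The LRR term is Gaussian around the state mean; the BAF term is the
    state's Hardy-Weinberg band mixture (uniform for copy number 0) with
    truncated-Gaussian jitter and a uniform outlier component.  ``maf``
    defaults to 0.5 when the track carries no population frequencies.
    """
    lrr = np.atleast_1d(np.asarray(lrr, float))
    baf = np.atleast_1d(np.asarray(baf, float))
    if not (np.isfinite(lrr).all() and np.isfinite(baf).all()):
        raise ValueError("non-finite LRR/BAF input")
    if ((baf < 0) | (baf > 1)).any():
        raise ValueError("BAF outside [0, 1]")
    maf = np.full_like(baf, 0.5) if maf is None else np.atleast_1d(np.asarray(maf, float))
    out = np.empty((lrr.size, 5))
    for s, cn in enumerate(COPY_NUMBERS):
        lrr_term = (
            -0.5 * ((lrr - model.lrr_means[s]) / model.lrr_sds[s]) ** 2
            - np.log(model.lrr_sds[s] * np.sqrt(2 * np.pi))
        )
        baf_term = baf_loglik(baf, maf, cn, model.baf_sd, model.baf_outlier_fraction)
        out[:, s] = lrr_term + baf_term
    return out


def viterbi_decode(
    model: HMMModel, track: IntensityTrack, sample_id: str
) -> pd.DataFrame:
    """Maximum a posteriori copy-number path for one sample.

    Decodes each chromosome independently (no transitions across
    chromosome boundaries).  Returns a frame with chrom, pos, and the
    decoded ``copy_number`` per probe, in track order.
    """
    sub = track.sample(sample_id)
    frames = []
    for chrom, grp in sub.groupby("chrom", sort=False):
        if grp.empty:
            warnings.warn(f"chromosome {chrom}: no probes, skipped")
            continue
        maf = grp["maf"].to_numpy() if "maf" in grp.columns else None
        ll = emission_loglik(
            model, grp["lrr"].to_numpy(), grp["baf"].to_numpy(), maf
        )
        path = _viterbi(ll, model.log_transition, model.log_initial)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": grp["pos"].to_numpy(),
                    "lrr": grp["lrr"].to_numpy(),
                    "copy_number": path,
                }
            )
        )
    if not frames:
        raise ValueError(f"sample {sample_id}: empty track")
    return pd.concat(frames, ignore_index=True)


def _viterbi(ll: np.ndarray, log_trans: np.ndarray, log_init: np.ndarray) -> np.ndarray:
    n, k = ll.shape
    delta = log_init + ll[0]
    back = np.zeros((n, k), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + log_trans  # (from, to)
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(k)] + ll[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def call_segments(
    decoded: pd.DataFrame,
    sample_id: str,
    min_probes: int = 10,
) -> list[CNVSegment]:
    """Turn a decoded path into called segments.

    Maximal runs of a constant non-diploid state with at least
    ``min_probes`` supporting probes become segments; shorter aberrant
    runs are dropped.
    """
    segments: list[CNVSegment] = []
    for chrom, grp in decoded.groupby("chrom", sort=False):
        states = grp["copy_number"].to_numpy()
        pos = grp["pos"].to_numpy()
        lrr = grp["lrr"].to_numpy()
        n = states.size
        start = 0
        for i in range(1, n + 1):
            if i == n or states[i] != states[start]:
                run = i - start
                if states[start] != 2 and run >= min_probes:
                    segments.append(
                        CNVSegment(
                            sample_id=sample_id,
                            chrom=str(chrom),
                            start=int(pos[start]),
                            end=int(pos[i - 1]),
                            copy_number=int(states[start]),
                            n_probes=run,
                            mean_lrr=float(lrr[start:i].mean()),
                        )
                    )
                start = i
    return segments


@dataclass
class CNVComparison:
    """Parent/daughter CNV call comparison.

    Daughter segments matching a parent segment (same chromosome, same
    gain/loss direction, reciprocal overlap >= threshold) are shared;
    the rest are candidate introduced CNVs.
    """

    parent: str
    daughter: str
    shared: list[tuple[CNVSegment, CNVSegment]] = field(default_factory=list)
    daughter_only: list[CNVSegment] = field(default_factory=list)
    parent_only: list[CNVSegment] = field(default_factory=list)


def _reciprocal_overlap(a: CNVSegment, b: CNVSegment) -> float:
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a.end - a.start + 1), inter / (b.end - b.start + 1))


def compare_cnv_sets(
    parent: Sequence[CNVSegment],
    daughter: Sequence[CNVSegment],
    min_reciprocal_overlap: float = 0.5,
) -> CNVComparison:
    """Match daughter CNV calls against the parent line's calls."""
    parent_id = parent[0].sample_id if parent else ""
    daughter_id = daughter[0].sample_id if daughter else ""
    cmp = CNVComparison(parent_id, daughter_id)
    matched_parent: set[int] = set()
    for d in daughter:
        best, best_ov = None, 0.0
        for i, p in enumerate(parent):
            if i in matched_parent or p.chrom != d.chrom:
                continue
            if (p.copy_number > 2) != (d.copy_number > 2):
                continue
            ov = _reciprocal_overlap(p, d)
            if ov > best_ov:
                best, best_ov = i, ov
        if best is not None and best_ov >= min_reciprocal_overlap:
            cmp.shared.append((parent[best], d))
            matched_parent.add(best)
        else:
            cmp.daughter_only.append(d)
    cmp.parent_only = [p for i, p in enumerate(parent) if i not in matched_parent]
    return cmp


def evidence_extract(
    track: IntensityTrack,
    segment: CNVSegment,
    samples: Sequence[str],
    flank_probes: int = 20,
) -> pd.DataFrame:
    """LRR/BAF window around a candidate CNV for visual review.

    Returns the probes spanning the segment plus ``flank_probes`` on
    each side, for every requested sample, so a parent/daughter pair can
    be contrasted the way candidate calls are adjudicated by eye.
    """
    frames = []
    for sid in samples:
        sub = track.sample(sid)
        sub = sub[sub["chrom"] == segment.chrom].reset_index(drop=True)
        inside = (sub["pos"] >= segment.start) & (sub["pos"] <= segment.end)
        if not inside.any():
            continue
        lo = max(int(np.flatnonzero(inside)[0]) - flank_probes, 0)
        hi = min(int(np.flatnonzero(inside)[-1]) + flank_probes, len(sub) - 1)
        frames.append(sub.iloc[lo : hi + 1].assign(segment_sample=segment.sample_id))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
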