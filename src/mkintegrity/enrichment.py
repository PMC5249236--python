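"""Direction-split gene-set enrichment with a Kolmogorov-Smirnov score test.

Differential-expression results are first split by direction (up in MK
versus down in MK); each gene's score for a direction is the minimum
p-value over its transcripts whose effect sign matches, with genes
lacking a matching transcript scored 1.  Per term, a one-sided
two-sample KS test asks whether member-gene scores are stochastically
smaller (more significant) than non-member scores.

This is the classic flat-set KS test: no gene-ontology DAG
decorrelation is applied, so overlapping ancestor terms of a true
signal will co-rank with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import GeneSetCatalog
from .de import DEResult, qvalues

__all__ = ["gene_scores", "ks_enrichment", "ks_statistic", "EnrichmentResult"]


def gene_scores(
    de: DEResult,
    transcript_to_gene: Mapping[str, str],
    direction: str,
) -> pd.Series:
    """Per-gene scores in [0, 1] for one direction; lower = more significant.

    A gene's score is the minimum p over its transcripts whose beta0
    sign matches ``direction`` (up_in_MK: beta0 < 0); genes with no
    matching transcript score 1.
    """
    if direction not in ("up_in_MK", "down_in_MK"):
        raise ValueError(f"unknown direction {direction!r}")
    if not transcript_to_gene:
        raise ValueError("empty transcript-to-gene mapping")
    tab = de.table
    genes = pd.Series(
        [transcript_to_gene.get(t) for t in tab.index], index=tab.index, dtype=object
    )
    if genes.isna().any():
        missing = tab.index[genes.isna()][0]
        raise ValueError(f"transcript {missing} has no gene mapping")
    match = tab["direction"] == direction
    scores = pd.Series(1.0, index=pd.unique(genes))
    matched = tab.loc[match, "p"].groupby(genes[match].to_numpy()).min()
    scores.loc[matched.index] = matched
    return scores


def ks_statistic(member_scores: np.ndarray, other_scores: np.ndarray) -> float:
    """One-sided two-sample KS statistic D+ = sup_x [F_members - F_others].

    Positive when member scores sit to the left of (are smaller than)
    non-member scores.
    """
    member_scores = np.sort(np.asarray(member_scores, float))
    other_scores = np.sort(np.asarray(other_scores, float))
    grid = np.concatenate([member_scores, other_scores])
    f_m = np.searchsorted(member_scores, grid, side="right") / member_scores.size
    f_o = np.searchsorted(other_scores, grid, side="right") / other_scores.size
    return float(np.max(f_m - f_o))


def _ks_pvalue_asymptotic(d: float, m: int, n: int) -> float:
    """Asymptotic one-sided two-sample KS p-value exp(-2 m n d^2 / (m+n))."""
    if d <= 0:
        return 1.0
    en = m * n / (m + n)
    return float(min(1.0, np.exp(-2.0 * en * d * d)))


@dataclass
class EnrichmentResult:
    term_id: str
    name: str
    annotated: int  # member genes in the scored universe
    significant: int  # members whose best matching-direction transcript q < threshold
    expected: float  # annotated x universe significant fraction
    d_statistic: float
    p: float
    q: float = float("nan")
    flagged: bool = False


def ks_enrichment(
    scores: pd.Series,
    catalog: GeneSetCatalog,
    de: Optional[DEResult] = None,
    transcript_to_gene: Optional[Mapping[str, str]] = None,
    direction: Optional[str] = None,
    sig_q_threshold: float = 0.05,
    min_term_size: int = 2,
    method: str = "asymptotic",
    n_perm: int = 9999,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Per-term KS enrichment over a scored gene universe.

    For each term with at least ``min_term_size`` members and 2
    non-members in the universe, tests whether member scores are
    stochastically smaller than non-member scores.  ``method`` selects
    the asymptotic one-sided KS p-value or a label-permutation p-value.
    A term covering the whole universe has no complement; it is reported
    with p = 1 and flagged.

    The "significant" column counts member genes whose best
    matching-direction transcript reaches q < ``sig_q_threshold`` (when
    ``de`` and the mapping are supplied); "expected" scales the
    universe-wide significant fraction by the term's annotated count, so
    expected/annotated is constant across terms.
    """
    universe = np.asarray(scores.index, dtype=object)
    vals = scores.to_numpy(float)
    rng = np.random.default_rng(seed)

    sig_genes: set[str] = set()
    if de is not None and transcript_to_gene is not None and direction is not None:
        tab = de.table
        match = (tab["direction"] == direction) & (tab["q"] < sig_q_threshold)
        sig_genes = {transcript_to_gene[t] for t in tab.index[match]}
        sig_genes &= set(universe)
    universe_sig_fraction = len(sig_genes) / universe.size if universe.size else 0.0

    results = []
    for term_id, (name, members) in catalog.terms.items():
        mask = np.isin(universe, list(members))
        m = int(mask.sum())
        if m < min_term_size:
            continue
        annotated = m
        significant = len(sig_genes & set(universe[mask]))
        expected = annotated * universe_sig_fraction
        n_other = universe.size - m
        if n_other < 2:
            results.append(
                EnrichmentResult(term_id, name, annotated, significant, expected,
                                 0.0, 1.0, flagged=True)
            )
            continue
        d = ks_statistic(vals[mask], vals[~mask])
        if method == "asymptotic":
            p = _ks_pvalue_asymptotic(d, m, n_other)
        elif method == "permutation":
            hits = 0
            for _ in range(n_perm):
                perm = rng.permutation(universe.size)
                d_perm = ks_statistic(vals[perm[:m]], vals[perm[m:]])
                if d_perm >= d - 1e-12:
                    hits += 1
            p = (1.0 + hits) / (n_perm + 1.0)
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append(EnrichmentResult(term_id, name, annotated, significant, expected, d, p))
    if not results:
        return results
    qs = qvalues(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
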