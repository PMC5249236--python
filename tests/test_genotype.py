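"""Genotype fidelity: LD pruning, IBD method of moments, discordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mkintegrity as mk
from mkintegrity.datatypes import MISSING
from mkintegrity.genotype import (
    count_discordances,
    estimate_ibd,
    ld_prune,
    round_sigfig,
    transmitted_discordance,
)

from conftest import make_panel


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _reference_prune(calls, positions, window, step, thr):
    """Independent re-implementation of the greedy windowed rule."""
    n = calls.shape[1]
    maf = []
    for j in range(n):
        g = calls[:, j][calls[:, j] != MISSING]
        p = g.mean() / 2 if g.size else 0.0
        maf.append(min(p, 1 - p))
    keep = set(range(n))
    for w0 in range(0, max(n - 1, 1), step):
        while True:
            live = [j for j in range(w0, min(w0 + window, n)) if j in keep]
            worst, worst_r2 = None, thr
            for ai in range(len(live)):
                for bi in range(ai + 1, len(live)):
                    a, b = live[ai], live[bi]
                    ga, gb = calls[:, a].astype(float), calls[:, b].astype(float)
                    ok = (calls[:, a] != MISSING) & (calls[:, b] != MISSING)
                    if ok.sum() < 2 or ga[ok].std() == 0 or gb[ok].std() == 0:
                        continue
                    r2 = np.corrcoef(ga[ok], gb[ok])[0, 1] ** 2
                    if r2 > worst_r2:
                        worst, worst_r2 = (a, b), r2
            if worst is None:
                break
            a, b = worst
            if maf[a] < maf[b]:
                keep.discard(a)
            elif maf[b] < maf[a]:
                keep.discard(b)
            else:
                keep.discard(max(a, b))
        if w0 + window >= n:
            break
    return sorted(keep)


def test_perfectly_correlated_pair_prunes_to_one():
    rng = np.random.default_rng(1)
    col = rng.integers(0, 3, 40)
    panel = make_panel(np.column_stack([col, col]))
    kept = ld_prune(panel, window=2, step=1, r2_threshold=0.3)
    assert len(kept) == 1


def test_prune_matches_reference_implementation_on_fixtures():
    rng = np.random.default_rng(7)
    for trial in range(20):
        calls = rng.integers(0, 3, size=(12, 10)).astype(np.int8)
        # inject some hard LD by copying columns
        calls[:, 3] = calls[:, 2]
        if trial % 2:
            calls[:, 8] = 2 - calls[:, 7]
        panel = make_panel(calls)
        got = ld_prune(panel, window=5, step=2, r2_threshold=0.3)
        want = _reference_prune(calls, panel.snps["pos"].to_numpy(), 5, 2, 0.3)
        assert got == want


def test_independent_snps_mostly_retained_with_many_samples():
    rng = np.random.default_rng(11)
    maf = rng.uniform(0.2, 0.5, 200)
    calls = rng.binomial(2, maf, size=(5000, 200)).astype(np.int8)
    panel = make_panel(calls)
    kept = ld_prune(panel)
    assert len(kept) == 200  # r^2 noise vanishes at n=5000


def test_retained_set_has_no_high_r2_pair_within_window():
    panel, _ = mk.simulate_genotype_lineage(4, 800, error_rate=0.001, seed=13)
    kept = ld_prune(panel, window=50, step=5, r2_threshold=0.3)
    kept_arr = np.array(kept)
    for w0 in range(0, 800, 5):
        live = kept_arr[(kept_arr >= w0) & (kept_arr < w0 + 50)]
        if live.size < 2:
            continue
        X = panel.calls[:, live].astype(float)
        sd = X.std(axis=0)
        X = X[:, sd > 0]
        if X.shape[1] < 2:
            continue
        r = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(r, 0.0)
        assert (r**2).max() <= 0.3 + 1e-12


def test_monomorphic_panel_returns_all_with_warning():
    panel = make_panel(np.zeros((6, 5), dtype=np.int8))
    with pytest.warns(UserWarning):
        kept = ld_prune(panel)
    assert kept == list(range(5))


# ---------------------------------------------------------------------------
# IBD
# ---------------------------------------------------------------------------


def _mom_oracle(ga, gb, freqs):
    """Direct evaluation of the method-of-moments equations with known
    (plug-in) allele frequencies — no bias correction."""
    ibs = 2 - np.abs(ga - gb)
    n0, n1, n2 = (ibs == 0).sum(), (ibs == 1).sum(), (ibs == 2).sum()
    p, q = freqs, 1 - freqs
    e00 = (2 * p**2 * q**2).sum()
    e10 = (4 * p**3 * q + 4 * p * q**3).sum()
    e20 = (p**4 + q**4 + 4 * p**2 * q**2).sum()
    e11 = (2 * p**2 * q + 2 * p * q**2).sum()
    e21 = (p**3 + q**3 + p**2 * q + p * q**2).sum()
    z0 = n0 / e00
    z1 = (n1 - z0 * e10) / e11
    z2 = (n2 - z0 * e20 - z1 * e21) / len(ga)
    z = np.clip([z0, z1, z2], 0, 1)
    return z / z.sum()


def test_small_case_matches_direct_formula_oracle():
    """With a large founder pool the bias correction is negligible and the
    estimator must match the plug-in moment equations."""
    rng = np.random.default_rng(17)
    n_snps = 20
    freqs = rng.uniform(0.2, 0.5, n_snps)
    founders = rng.binomial(2, freqs, size=(500, n_snps)).astype(np.int8)
    panel = make_panel(founders)
    est = estimate_ibd(panel, min_markers=20, min_informative=10)
    lookup = {(e.sample_a, e.sample_b): e for e in est}
    obs_freq = founders.mean(axis=0) / 2
    for (a, b), e in list(lookup.items())[:30]:
        ga = panel.row(a).astype(int)
        gb = panel.row(b).astype(int)
        want = _mom_oracle(ga, gb, obs_freq)
        np.testing.assert_allclose([e.z0, e.z1, e.z2], want, atol=0.02)


def test_duplicates_and_unrelated_patterns():
    panel, _ = mk.simulate_genotype_lineage(
        8, 20000, error_rate=0.0, n_mutations_per_ipsc=0, n_lines=1, seed=19
    )
    est = estimate_ibd(panel)
    for e in est:
        assert not e.flagged
        assert abs(e.z0 + e.z1 + e.z2 - 1.0) < 1e-12
        if e.relationship == "within-subject":
            assert e.z2 >= 0.99 and e.z0 <= 0.01
        else:
            assert e.z2 <= 0.05 and e.z0 >= 0.9


def test_sparse_pair_flagged_not_estimated():
    rng = np.random.default_rng(23)
    calls = rng.integers(0, 3, size=(3, 200)).astype(np.int8)
    calls[2, 40:] = MISSING  # only 40 informative markers vs others
    panel = make_panel(calls)
    est = estimate_ibd(panel, min_markers=100, min_informative=50)
    flags = {(e.sample_a, e.sample_b): e.flagged for e in est}
    assert flags[("S0", "S2")] and flags[("S1", "S2")]
    assert not flags[("S0", "S1")]


# ---------------------------------------------------------------------------
# discordance
# ---------------------------------------------------------------------------


def test_hand_counted_discordance_excludes_missing():
    panel = make_panel([[0, 1, 2, -1, 2], [0, 2, 2, 1, 2]])
    r = count_discordances(panel, ("S0", "S1"))
    assert (r.n_compared, r.n_discordant) == (4, 1)
    assert r.rate == 0.25


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_discordance_is_symmetric(seed):
    rng = np.random.default_rng(seed)
    calls = rng.integers(-1, 3, size=(2, 50)).astype(np.int8)
    panel = make_panel(calls)
    a = count_discordances(panel, ("S0", "S1"))
    b = count_discordances(panel, ("S1", "S0"))
    assert (a.n_compared, a.n_discordant) == (b.n_compared, b.n_discordant)


def test_same_sample_comparison_rejected():
    panel = make_panel([[0, 1], [1, 2]])
    with pytest.raises(ValueError):
        count_discordances(panel, ("S0", "S0"))


# ---------------------------------------------------------------------------
# transmitted discordance
# ---------------------------------------------------------------------------


def _lineage_panel(mnc, ipsc, mkv):
    import pandas as pd

    from mkintegrity.datatypes import GenotypePanel, SampleLineage

    calls = np.array([mnc, ipsc, mkv], dtype=np.int8)
    n = calls.shape[1]
    snps = pd.DataFrame(
        {
            "name": [f"rs{i}" for i in range(n)],
            "chrom": "1",
            "pos": np.arange(1, n + 1),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = [
        SampleLineage("P1", "P1", "MNC", ""),
        SampleLineage("IP1A", "P1", "iPSC", "A"),
        SampleLineage("MP1A", "P1", "MK", "A"),
    ]
    return GenotypePanel(calls, snps, samples)


def test_reverted_mutation_is_discordant_but_not_transmitted():
    panel = _lineage_panel([0, 0, 0], [1, 0, 0], [0, 0, 0])
    t = transmitted_discordance(panel, "P1", "A")
    assert t.n_mnc_ipsc_discordant == 1
    assert t.n_transmitted == 0


def test_transmitted_subset_of_discordant_and_missing_line_rejected():
    panel = _lineage_panel([0, 1, 0, 2], [1, 0, 0, 2], [1, 1, 0, 2])
    t = transmitted_discordance(panel, "P1", "A")
    assert t.n_transmitted <= t.n_mnc_ipsc_discordant
    assert (t.n_mnc_ipsc_discordant, t.n_transmitted) == (2, 1)
    with pytest.raises(ValueError, match="iPSC"):
        transmitted_discordance(
            make_panel([[0, 1]], subjects=["P1"]), "P1", "A"
        )


def test_noiseless_simulation_recovers_planted_truth_exactly():
    panel, truth = mk.simulate_genotype_lineage(
        2, 5000, error_rate=0.0, n_mutations_per_ipsc=8, seed=29
    )
    for subject in ("P001", "P002"):
        for rep in ("A", "B"):
            t = transmitted_discordance(panel, subject, rep)
            assert t.n_mnc_ipsc_discordant == 8
            assert t.n_transmitted == 8


def test_transmitted_rate_under_pure_error_matches_enumeration():
    """With no planted mutations, transmitted events arise only from
    miscall coincidences; their frequency must match the enumerated
    three-line model over many replicates."""
    e = 0.01
    maf = 0.3
    # brute-force P(MNC != iPSC and iPSC == MK) for one SNP
    p_g = {0: (1 - maf) ** 2, 1: 2 * maf * (1 - maf), 2: maf**2}
    p_event = 0.0
    for g, pg in p_g.items():
        obs = {x: e / 2 for x in (0, 1, 2) if x != g}
        obs[g] = 1 - e
        for a, pa in obs.items():  # iPSC call
            for m, pm in obs.items():  # MNC call
                for k, pk in obs.items():  # MK call
                    if m != a and a == k:
                        p_event += pg * pa * pm * pk
    n_snps, n_rep = 500, 200
    total = 0
    for i in range(n_rep):
        panel, _ = mk.simulate_genotype_lineage(
            1, n_snps, error_rate=e, n_mutations_per_ipsc=0, n_lines=1,
            maf_sampler=lambda rng, n: np.full(n, maf), seed=1000 + i,
        )
        total += transmitted_discordance(panel, "P001", "A").n_transmitted
    n_trials = n_snps * n_rep
    expect = n_trials * p_event
    sd = np.sqrt(n_trials * p_event * (1 - p_event))
    assert abs(total - expect) <= 3 * sd


def test_rate_rounding_convention():
    assert round_sigfig(100 * 8 / 946674, 1) == 0.0008
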