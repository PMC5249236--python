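"""Paired DE: IQR filter, delta construction, PCA, moderated t, q-values."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mkintegrity as mk
from mkintegrity.datatypes import ExpressionStudy
from mkintegrity.de import (
    DeltaMatrix,
    build_delta,
    compute_pcs,
    fit_moderated,
    iqr_filter,
    qvalues,
)


def _study_from_matrix(fpkm_rows, n_subjects):
    """FPKM rows (transcripts) over n_subjects x {iPSC, MK} x {A, B}."""
    rows = []
    for s in range(n_subjects):
        subject = f"P{s + 1:03d}"
        for ct, prefix in (("iPSC", "I"), ("MK", "M")):
            for rep in ("A", "B"):
                rows.append(
                    {"sample_id": f"{prefix}{subject}{rep}", "subject": subject,
                     "cell_type": ct, "replicate": rep}
                )
    samples = pd.DataFrame(rows)
    fpkm = pd.DataFrame(
        np.asarray(fpkm_rows, float),
        index=[f"T{i}" for i in range(len(fpkm_rows))],
        columns=samples["sample_id"],
    )
    transcripts = pd.DataFrame(
        {"transcript_id": fpkm.index, "gene": fpkm.index, "chrom": "1",
         "start": np.arange(1, len(fpkm) + 1) * 1000,
         "end": np.arange(1, len(fpkm) + 1) * 1000 + 100}
    )
    return ExpressionStudy(fpkm, transcripts, samples)


# ---------------------------------------------------------------------------
# IQR filter
# ---------------------------------------------------------------------------


def test_iqr_keeps_celltype_split_and_drops_single_outlier():
    n_subjects = 14  # 56 samples
    off_on = []  # 0 in all iPSC, 2 in all MK -> IQR 2, retained
    for s in range(n_subjects):
        off_on += [0, 0, 2, 2]  # iPSC A, iPSC B, MK A, MK B per subject
    # single-sample spike: 100 once, 0 elsewhere -> IQR 0, excluded
    spike = [0.0] * 56
    spike[17] = 100.0
    constant = [5.0] * 56
    rows = [off_on, spike, constant]
    # sample order above is per-subject blocks; rebuild to the study layout
    study = _study_from_matrix(rows, n_subjects)
    kept = iqr_filter(study, threshold=1.0)
    assert "T0" in kept  # cell-type split survives
    assert "T1" not in kept  # one-sample outlier excluded
    assert "T2" not in kept  # constant excluded


def test_iqr_threshold_is_strict():
    study = _study_from_matrix([[0, 0, 1, 1] * 14], 14)
    assert iqr_filter(study, threshold=1.0) == []  # IQR == 1, not > 1


# ---------------------------------------------------------------------------
# delta construction
# ---------------------------------------------------------------------------


def test_delta_arithmetic_with_replicate_averaging():
    # log2-scale targets: iPSC_A=4, MK_A=2, iPSC_B=6, MK_B=2 -> delta 3
    f = lambda v: 2.0**v - 1.0
    study = _study_from_matrix([[f(4), f(6), f(2), f(2)] * 2], 2)
    delta = build_delta(study)
    assert np.allclose(delta.delta.to_numpy(), 3.0)
    assert delta.provenance["P001"] == ["A", "B"]


def test_zero_fpkm_maps_to_zero_log():
    study = _study_from_matrix([[0.0, 0.0, 0.0, 0.0] * 3], 3)
    delta = build_delta(study)
    assert np.allclose(delta.delta.to_numpy(), 0.0)


def test_identical_celltype_matrices_give_null_delta(paired_study):
    study, *_ = paired_study
    fpkm = study.fpkm.copy()
    for subject in study.samples["subject"].unique():
        for rep in ("A", "B"):
            fpkm[study.sample_id(subject, "MK", rep)] = fpkm[
                study.sample_id(subject, "iPSC", rep)
            ]
    null_study = ExpressionStudy(fpkm, study.transcripts, study.samples)
    assert np.allclose(build_delta(null_study).delta.to_numpy(), 0.0)


def test_single_replicate_subject_used_alone_with_flag():
    study = _study_from_matrix([[4, 6, 1, 3] * 2], 2)
    keep = [s for s in study.samples["sample_id"] if s not in ("IP001B", "MP001B")]
    sub = study.subset_samples(keep)
    with pytest.warns(UserWarning, match="single technical replicate"):
        delta = build_delta(sub)
    assert delta.provenance["P001"] == ["A"]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_rank_one_delta_concentrates_variance_on_pc1():
    u = np.array([1.0, 2.0, -1.0, 0.5, 3.0])
    v = np.array([1.0, -1.0, 2.0, 0.0])
    delta = DeltaMatrix(pd.DataFrame(np.outer(u, v)), {})
    pcs = compute_pcs(delta, k=2)
    assert pcs.variance_fractions[0] == pytest.approx(1.0)


def test_scores_match_direct_eigendecomposition_on_fixture():
    rng = np.random.default_rng(43)
    X = rng.normal(size=(5, 4))
    delta = DeltaMatrix(pd.DataFrame(X), {})
    pcs = compute_pcs(delta, k=2)
    Xc = X - X.mean(axis=0, keepdims=True)
    evals, evecs = np.linalg.eigh(Xc.T @ Xc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(2):
        got = pcs.scores.iloc[:, j].to_numpy()
        want = evecs[:, j] * np.sqrt(evals[j])
        assert np.allclose(np.abs(got), np.abs(want), atol=1e-8)
    assert np.allclose(
        pcs.variance_fractions, evals[:2] / evals.sum(), atol=1e-10
    )


def test_planted_orthogonal_factors_recovered_in_ratio():
    rng = np.random.default_rng(47)
    n_tx, n_sub = 2000, 16
    f1 = np.tile([1.0, -1.0], n_sub // 2) * 2.0  # variance 4
    f2 = np.repeat([1.0, -1.0], n_sub // 2) * 1.0  # variance 1
    X = np.outer(rng.normal(size=n_tx), f1) + np.outer(rng.normal(size=n_tx), f2)
    X += rng.normal(0, 0.01, X.shape)
    pcs = compute_pcs(DeltaMatrix(pd.DataFrame(X), {}), k=2)
    ratio = pcs.variance_fractions[0] / pcs.variance_fractions[1]
    assert ratio == pytest.approx(4.0, rel=0.15)


def test_k_must_be_below_subject_count():
    delta = DeltaMatrix(pd.DataFrame(np.zeros((10, 3))), {})
    with pytest.raises(ValueError):
        compute_pcs(delta, k=3)


# ---------------------------------------------------------------------------
# moderated fit
# ---------------------------------------------------------------------------


def _random_delta(n_tx=400, n_sub=14, seed=51, effects=None, het=True):
    rng = np.random.default_rng(seed)
    sd = rng.uniform(0.3, 1.2, n_tx) if het else np.full(n_tx, 0.5)
    X = rng.normal(0, 1, (n_tx, n_sub)) * sd[:, None]
    if effects is not None:
        X += np.asarray(effects)[:, None]
    return DeltaMatrix(pd.DataFrame(X, index=[f"T{i}" for i in range(n_tx)]), {})


def test_zero_prior_df_recovers_ordinary_t():
    delta = _random_delta()
    pcs = compute_pcs(delta, k=2)
    fit = fit_moderated(delta, pcs, d0_override=0.0)
    # ordinary OLS t for the intercept, computed independently
    D = delta.delta.to_numpy()
    X = np.column_stack([np.ones(14), pcs.scores.to_numpy()])
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = D @ X @ XtX_inv
    resid = D - beta @ X.T
    s2 = (resid**2).sum(axis=1) / (14 - 3)
    t_ols = beta[:, 0] / np.sqrt(s2 * XtX_inv[0, 0])
    assert np.allclose(fit.table["t"].to_numpy(), t_ols, atol=1e-8)


def test_posterior_variance_plug_in_arithmetic():
    delta = _random_delta(n_tx=50, n_sub=7)  # df = 7 - 3 = 4
    pcs = compute_pcs(delta, k=2)
    fit = fit_moderated(delta, pcs, d0_override=4.0, s0_sq_override=1.0)
    s2 = fit.table["s2"].to_numpy()
    want = (4.0 * 1.0 + 4.0 * s2) / 8.0
    assert np.allclose(fit.table["s2_post"].to_numpy(), want)
    i = np.argmin(np.abs(s2 - 3.0))  # d0=4, s0^2=1, d=4, s^2=3 -> 2
    assert fit.table["s2_post"].to_numpy()[i] == pytest.approx(
        (4 + 4 * s2[i]) / 8.0
    )


def test_shrinkage_bounded_between_sample_and_prior_variance():
    delta = _random_delta(seed=53)
    fit = fit_moderated(delta, compute_pcs(delta, k=2))
    s2 = fit.table["s2"].to_numpy()
    post = fit.table["s2_post"].to_numpy()
    lo = np.minimum(s2, fit.s0_sq) - 1e-12
    hi = np.maximum(s2, fit.s0_sq) + 1e-12
    assert ((post >= lo) & (post <= hi)).all()


def test_global_null_p_uniform_and_no_discoveries():
    pooled = []
    for seed in (61, 62, 63):
        delta = _random_delta(n_tx=5000, seed=seed)
        fit = fit_moderated(delta, compute_pcs(delta, k=2))
        pooled.append(fit.table["p"].to_numpy())
        assert (fit.table["q"] < 0.05).mean() < 0.002
    ks = stats.kstest(np.concatenate(pooled), "uniform")
    assert ks.pvalue > 0.01


def test_direction_labels_flip_when_celltypes_swap(paired_study):
    study, *_ = paired_study
    fit = fit_moderated(build_delta(study), None)
    swapped = study.samples.copy()
    swapped["cell_type"] = swapped["cell_type"].map({"iPSC": "MK", "MK": "iPSC"})
    study2 = ExpressionStudy(study.fpkm, study.transcripts, swapped)
    fit2 = fit_moderated(build_delta(study2), None)
    sig = fit.table["q"] < 0.01
    assert (
        fit.table.loc[sig, "direction"].to_numpy()
        != fit2.table.loc[sig, "direction"].to_numpy()
    ).all()


def test_pc_adjustment_removes_planted_batch_bias():
    """A batch factor loading on the top PC of delta biases the naive
    intercept; including the PCs must remove that bias."""
    rng = np.random.default_rng(67)
    n_tx, n_sub = 3000, 14
    batch = np.where(np.arange(n_sub) < 7, 1.0, -1.0)
    batch = batch - batch.mean()  # unbalanced designs keep a mean offset
    batch[0] = 2.0  # break exact balance so the intercept is biased
    loadings = rng.normal(1.0, 0.3, n_tx)
    X = np.outer(loadings, batch) + rng.normal(0, 0.3, (n_tx, n_sub))
    delta = DeltaMatrix(pd.DataFrame(X, index=[f"T{i}" for i in range(n_tx)]), {})
    naive = fit_moderated(delta, None)
    adjusted = fit_moderated(delta, compute_pcs(delta, k=2))
    bias_naive = abs(naive.table["beta0"].mean())
    bias_adj = abs(adjusted.table["beta0"].mean())
    assert bias_naive > 0.05
    assert bias_adj < 0.01


def test_fit_is_deterministic(paired_study):
    study, *_ = paired_study
    delta = build_delta(study)
    a = fit_moderated(delta, compute_pcs(delta))
    b = fit_moderated(delta, compute_pcs(delta))
    pd.testing.assert_frame_equal(a.table, b.table)
    assert a.d0 == b.d0 and a.s0_sq == b.s0_sq


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_moderated_statistics_agree_with_limma(tmp_path):
    """Independent oracle: the same model fit with R limma's lmFit/eBayes."""
    delta = _random_delta(n_tx=300, n_sub=14, seed=71, het=True)
    pcs = compute_pcs(delta, k=2)
    fit = fit_moderated(delta, pcs)
    delta.delta.to_csv(tmp_path / "delta.tsv", sep="\t")
    pcs.scores.to_csv(tmp_path / "pcs.tsv", sep="\t")
    script = tmp_path / "oracle.R"
    script.write_text(
        """
        suppressMessages(library(limma))
        d <- as.matrix(read.delim(commandArgs(TRUE)[1], row.names=1))
        pc <- as.matrix(read.delim(commandArgs(TRUE)[2], row.names=1))
        design <- cbind(Intercept=1, pc)
        f <- eBayes(lmFit(d, design))
        out <- data.frame(beta0=f$coefficients[,1], t=f$t[,1],
                          p=f$p.value[,1], d0=f$df.prior, s0=f$s2.prior)
        write.table(out, commandArgs(TRUE)[3], sep="\t", quote=FALSE)
        """
    )
    out = tmp_path / "limma.tsv"
    subprocess.run(
        ["Rscript", str(script), str(tmp_path / "delta.tsv"),
         str(tmp_path / "pcs.tsv"), str(out)],
        check=True, capture_output=True,
    )
    ref = pd.read_csv(out, sep="\t")
    assert np.allclose(fit.table["beta0"], ref["beta0"], atol=1e-8)
    assert fit.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-4)
    assert fit.s0_sq == pytest.approx(float(ref["s0"].iloc[0]), rel=1e-4)
    assert np.allclose(fit.table["t"], ref["t"], rtol=1e-6)
    assert np.allclose(fit.table["p"], ref["p"], rtol=1e-5)


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------


def test_all_unit_pvalues_give_unit_qvalues():
    assert np.allclose(qvalues(np.ones(20)), 1.0)


def test_bh_oracle_at_forced_pi0():
    q = qvalues(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
    assert np.allclose(q, 0.04)


def test_pi0_estimate_consistent_under_uniform_null():
    rng = np.random.default_rng(73)
    p = rng.uniform(size=10_000)
    q = qvalues(p)
    # back out pi0 from the largest q-value: q_(m) = pi0 * p_(m) ~ pi0
    assert q.max() >= 0.9
    ratio = q[np.argmax(p)] / p.max()
    assert abs(ratio - 1.0) < 0.05


def test_qvalues_monotone_in_p():
    rng = np.random.default_rng(79)
    p = rng.uniform(size=500)
    q = qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_qvalues_reject_invalid_input():
    with pytest.raises(ValueError):
        qvalues(np.array([]))
    with pytest.raises(ValueError):
        qvalues(np.array([0.5, 1.5]))
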