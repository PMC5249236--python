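"""Synthetic-data generators for every input the pipeline consumes.

Each generator emulates one observable of the study design — a genotyped
MNC -> iPSC -> MK lineage, a SNP-array LRR/BAF track, a paired iPSC/MK
FPKM study, a gene-set catalog — and returns the corresponding planted
ground truth so that recovery can be tested exactly.

Defaults reflect the study design: up to two iPSC/MK technical-replicate
lines per subject, 14 subjects in the expression study with 2 technical
replicates per cell type, and a single-replicate chromosome-arm
duplication as the structural event of interest.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ArmMap,
    CNVTruth,
    ExpressionStudy,
    ExpressionTruth,
    GeneSetCatalog,
    GenotypePanel,
    GenotypeTruth,
    SampleLineage,
)
from .signalmodel import LRR_MEANS, sample_baf

__all__ = [
    "simulate_genotype_lineage",
    "simulate_probe_map",
    "simulate_lrr_baf",
    "simulate_transcript_annotation",
    "default_armmap",
    "make_expression_truth",
    "simulate_expression_study",
    "simulate_geneset_catalog",
]


# ---------------------------------------------------------------------------
# genotype lineage
# ---------------------------------------------------------------------------


def _miscall(calls: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Replace each flagged call by one of the two other genotype codes."""
    for j in positions:
        others = [g for g in (0, 1, 2) if g != calls[j]]
        calls[j] = others[rng.integers(2)]


def simulate_genotype_lineage(
    n_subjects: int,
    n_snps: int,
    error_rate: float = 0.0037,
    n_mutations_per_ipsc: int = 0,
    maf_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    n_lines: int = 2,
    seed: int = 0,
) -> tuple[GenotypePanel, GenotypeTruth]:
    """Simulate genotyped MNC -> iPSC -> MK lineages for several subjects.

    Per subject, a germline (MNC) dosage vector is drawn under
    Hardy-Weinberg from per-SNP minor-allele frequencies.  Each iPSC line
    is the germline plus ``n_mutations_per_ipsc`` planted somatic
    mutations plus independent per-call miscalls at ``error_rate``; the
    paired MK inherits the iPSC's planted mutations (they are
    "transmitted") but receives fresh independent miscalls.  Miscalls are
    symmetric: an erroneous call becomes one of the two other codes with
    equal probability.

    Parameters
    ----------
    maf_sampler
        Callable ``(rng, n) -> MAF array in (0, 0.5]``; defaults to
        uniform on [0.05, 0.5].
    n_lines
        Number of iPSC/MK technical-replicate pairs per subject (1 or 2).

    Returns the panel plus a :class:`GenotypeTruth` listing every planted
    mutation and every random miscall.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be positive")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    if n_lines not in (1, 2):
        raise ValueError("n_lines must be 1 or 2")
    rng = np.random.default_rng(seed)
    if maf_sampler is None:
        maf = rng.uniform(0.05, 0.5, n_snps)
    else:
        maf = np.asarray(maf_sampler(rng, n_snps), float)
        if ((maf <= 0) | (maf > 0.5)).any():
            raise ValueError("MAFs must lie in (0, 0.5]")

    snps = pd.DataFrame(
        {
            "name": [f"rs{i:07d}" for i in range(n_snps)],
            "chrom": "1",
            "pos": np.arange(1, n_snps + 1) * 1000,
            "allele_a": "A",
            "allele_b": "B",
            "maf": maf,
        }
    )

    samples: list[SampleLineage] = []
    rows: list[np.ndarray] = []
    truth = GenotypeTruth(per_call_error_rate=error_rate)
    replicates = ["A", "B"][:n_lines]

    for s in range(n_subjects):
        subject = f"P{s + 1:03d}"
        germline = rng.binomial(2, maf).astype(np.int8)
        samples.append(SampleLineage(subject, subject, "MNC", ""))
        mnc = germline.copy()
        err = np.flatnonzero(rng.random(n_snps) < error_rate)
        _miscall(mnc, err, rng)
        truth.error_positions.extend((subject, int(j)) for j in err)
        rows.append(mnc)

        for rep in replicates:
            ipsc_id, mk_id = f"I{subject}{rep}", f"M{subject}{rep}"
            ipsc = germline.copy()
            # planted mutations: away from this sample's future error sites
            mut_pos = rng.choice(n_snps, size=n_mutations_per_ipsc, replace=False)
            for j in mut_pos:
                others = [g for g in (0, 1, 2) if g != germline[j]]
                new = others[rng.integers(2)]
                ipsc[j] = new
                truth.planted_mutations.append((subject, rep, int(j), int(new)))
            mk = ipsc.copy()
            for sid, vec in ((ipsc_id, ipsc), (mk_id, mk)):
                ok = np.setdiff1d(np.arange(n_snps), mut_pos, assume_unique=False)
                err = ok[rng.random(ok.size) < error_rate]
                _miscall(vec, err, rng)
                truth.error_positions.extend((sid, int(j)) for j in err)
            samples.append(SampleLineage(ipsc_id, subject, "iPSC", rep))
            rows.append(ipsc)
            samples.append(SampleLineage(mk_id, subject, "MK", rep))
            rows.append(mk)

    panel = GenotypePanel(np.vstack(rows), snps, samples)
    return panel, truth


# ---------------------------------------------------------------------------
# LRR / BAF intensity tracks
# ---------------------------------------------------------------------------


def simulate_probe_map(
    n_probes: int,
    chroms: Sequence[str] = ("1",),
    spacing: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Evenly spaced probe positions with random MAFs, split over chromosomes."""
    rng = np.random.default_rng(seed)
    per = np.full(len(chroms), n_probes // len(chroms))
    per[: n_probes % len(chroms)] += 1
    frames = []
    for chrom, n in zip(chroms, per):
        frames.append(
            pd.DataFrame(
                {
                    "snp": [f"cnv_{chrom}_{i}" for i in range(n)],
                    "chrom": chrom,
                    "pos": np.arange(1, n + 1) * spacing,
                    "maf": rng.uniform(0.05, 0.5, n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_lrr_baf(
    probe_map: pd.DataFrame,
    cnv_truth: CNVTruth,
    lrr_sd: float = 0.2,
    baf_sd: float = 0.03,
    samples: Optional[Sequence[str]] = None,
    lrr_means: Sequence[float] = LRR_MEANS,
    seed: int = 0,
) -> tuple["IntensityTrack", CNVTruth]:
    """Simulate per-probe LRR/BAF observations with planted CNV segments.

    LRR is Gaussian around the copy-state mean; BAF follows the state's
    Hardy-Weinberg genotype-band mixture with truncated Gaussian jitter.
    Truth segments index probes within their chromosome (inclusive).
    """
    from .datatypes import IntensityTrack  # local to avoid cycle at import time

    if lrr_sd <= 0 or baf_sd <= 0:
        raise ValueError("noise standard deviations must be positive")
    rng = np.random.default_rng(seed)
    if samples is None:
        carriers = list(dict.fromkeys(seg[4] for seg in cnv_truth.segments))
        samples = carriers or ["S1"]

    chrom_groups = {
        chrom: grp.reset_index(drop=True) for chrom, grp in probe_map.groupby("chrom", sort=False)
    }
    for chrom, s, e, cn, sample in cnv_truth.segments:
        if chrom not in chrom_groups or e >= len(chrom_groups[chrom]):
            raise ValueError(f"truth segment outside probe map: {chrom}:{s}-{e}")

    frames = []
    for sample in samples:
        for chrom, grp in chrom_groups.items():
            n = len(grp)
            cn_path = np.full(n, 2, dtype=int)
            for tchrom, s, e, cn, carrier in cnv_truth.segments:
                if carrier == sample and tchrom == chrom:
                    cn_path[s : e + 1] = cn
            means = np.asarray(lrr_means)[cn_path]
            lrr = means + rng.normal(0.0, lrr_sd, n)
            baf = sample_baf(cn_path, grp["maf"].to_numpy(), baf_sd, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "snp": grp["snp"],
                        "chrom": chrom,
                        "pos": grp["pos"],
                        "lrr": lrr,
                        "baf": baf,
                        "maf": grp["maf"],
                    }
                )
            )
    return IntensityTrack(pd.concat(frames, ignore_index=True)), cnv_truth


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

#: synthetic genome used by the expression simulator: chrom -> (length, centromere)
SYNTHETIC_GENOME = {
    "1": (200_000_000, 100_000_000),
    "2": (180_000_000, 90_000_000),
    "3": (160_000_000, 80_000_000),
    "4": (140_000_000, 70_000_000),
}


def default_armmap() -> ArmMap:
    """Arm map of the synthetic genome the expression simulator uses."""
    return ArmMap({c: cen for c, (_, cen) in SYNTHETIC_GENOME.items()})


def simulate_transcript_annotation(
    n_transcripts: int,
    seed: int = 0,
    transcripts_per_gene: int = 1,
) -> pd.DataFrame:
    """Random transcript coordinates over the synthetic genome.

    Genes group ``transcripts_per_gene`` consecutive transcripts; all
    transcripts of a gene share its locus.
    """
    rng = np.random.default_rng(seed)
    chroms = list(SYNTHETIC_GENOME)
    n_genes = int(np.ceil(n_transcripts / transcripts_per_gene))
    gene_chrom = rng.choice(len(chroms), n_genes)
    gene_start = np.array(
        [rng.integers(1, SYNTHETIC_GENOME[chroms[c]][0] - 100_000) for c in gene_chrom]
    )
    rows = []
    for t in range(n_transcripts):
        g = t // transcripts_per_gene
        start = int(gene_start[g])
        rows.append(
            {
                "transcript_id": f"TX{t:06d}",
                "gene": f"G{g:06d}",
                "chrom": chroms[gene_chrom[g]],
                "start": start,
                "end": start + int(rng.integers(1_000, 100_000)),
            }
        )
    return pd.DataFrame(rows)


def make_expression_truth(
    transcripts: pd.DataFrame,
    catalog: Optional[GeneSetCatalog] = None,
    n_de: int = 0,
    de_effect: float = 2.0,
    enriched_terms: Optional[dict[str, tuple[str, float]]] = None,
    loading_sd: float = 0.0,
    arm_duplication: Optional[tuple[str, str, str, str, str, float]] = None,
    seed: int = 0,
) -> ExpressionTruth:
    """Assemble a planted truth record for :func:`simulate_expression_study`.

    ``n_de`` transcripts get a cell-type effect of ``de_effect`` (MK minus
    iPSC log2 units, random sign per transcript).  If ``enriched_terms``
    maps term ids of ``catalog`` to (direction, effect), every transcript
    of a member gene receives an effect of the stated sign instead, so the
    term carries a coherent directional signal.
    """
    rng = np.random.default_rng(seed)
    n = len(transcripts)
    effects = np.zeros(n)
    if n_de:
        idx = rng.choice(n, n_de, replace=False)
        effects[idx] = de_effect * rng.choice((-1.0, 1.0), n_de)
    enriched = dict(enriched_terms or {})
    if enriched:
        if catalog is None:
            raise ValueError("enriched_terms requires a catalog")
        gene_of = transcripts["gene"].to_numpy()
        for term_id, (direction, effect) in enriched.items():
            members = catalog.members(term_id)
            mask = np.isin(gene_of, list(members))
            sign = 1.0 if direction == "up_in_MK" else -1.0
            effects[mask] = sign * effect
    loadings = rng.normal(0.0, loading_sd, n) if loading_sd > 0 else None
    return ExpressionTruth(
        celltype_effects=effects,
        loadings=loadings,
        arm_duplication=arm_duplication,
        enriched_terms=enriched,
    )


def simulate_expression_study(
    n_subjects: int,
    truth: ExpressionTruth,
    transcripts: Optional[pd.DataFrame] = None,
    noise_sd: float | np.ndarray = 0.5,
    baseline_mean: float = 2.5,
    baseline_sd: float = 1.5,
    armmap: Optional[ArmMap] = None,
    seed: int = 0,
) -> tuple[ExpressionStudy, ExpressionTruth]:
    """Simulate a paired iPSC/MK FPKM study with technical replicates.

    Each subject contributes four samples (iPSC and MK, replicates A and
    B).  On the log2 scale a transcript's value is baseline + cell-type
    effect (MK only) + covariate loading x batch covariate + replicate
    noise (``noise_sd`` may be per-transcript); FPKM = 2^value - 1
    floored at zero.  An optional planted arm
    duplication multiplies the FPKM of that arm's transcripts in exactly
    one designated sample.
    """
    rng = np.random.default_rng(seed)
    if transcripts is None:
        n_tx = len(truth.celltype_effects)
        transcripts = simulate_transcript_annotation(n_tx, seed=seed)
    n_tx = len(transcripts)
    if len(truth.celltype_effects) != n_tx:
        raise ValueError("truth effects do not match the transcript table")
    if armmap is None:
        armmap = default_armmap()
    if truth.arm_duplication is not None and truth.arm_duplication[5] <= 0:
        raise ValueError("duplication factor must be positive")

    rows = []
    for s in range(n_subjects):
        subject = f"P{s + 1:03d}"
        batch = 1 if s < (n_subjects + 1) // 2 else 2
        for cell_type in ("iPSC", "MK"):
            prefix = "I" if cell_type == "iPSC" else "M"
            for rep in ("A", "B"):
                rows.append(
                    {
                        "sample_id": f"{prefix}{subject}{rep}",
                        "subject": subject,
                        "cell_type": cell_type,
                        "replicate": rep,
                        "batch": batch,
                        "lane": 1 + (s + (rep == "B")) % 2,
                        "pct_cd41_cd42a": round(
                            float(rng.uniform(40, 95)) if cell_type == "MK" else 0.0, 1
                        ),
                    }
                )
    samples = pd.DataFrame(rows)
    covariate = np.where(samples["batch"].to_numpy() == 1, 1.0, -1.0)

    baseline = rng.normal(baseline_mean, baseline_sd, n_tx)
    is_mk = (samples["cell_type"] == "MK").to_numpy()
    log2_mean = baseline[:, None] + np.outer(truth.celltype_effects, is_mk.astype(float))
    if truth.loadings is not None:
        log2_mean = log2_mean + np.outer(truth.loadings, covariate)
    sd = np.broadcast_to(np.asarray(noise_sd, float).reshape(-1, 1), (n_tx, 1)) \
        if np.ndim(noise_sd) else float(noise_sd)
    values = log2_mean + rng.normal(0.0, 1.0, (n_tx, len(samples))) * sd
    fpkm = np.maximum(np.exp2(values) - 1.0, 0.0)

    if truth.arm_duplication is not None:
        subject, rep, cell_type, chrom, arm, factor = truth.arm_duplication
        prefix = "I" if cell_type == "iPSC" else "M"
        target = f"{prefix}{subject}{rep}"
        col = samples.index[samples["sample_id"] == target]
        if col.empty:
            raise ValueError(f"duplication carrier {target} not simulated")
        on_arm = np.array(
            [
                transcripts["chrom"].iloc[t] == chrom
                and armmap.arm_of(chrom, int(transcripts["start"].iloc[t])) == arm
                for t in range(n_tx)
            ]
        )
        fpkm[np.ix_(on_arm, col)] *= factor

    fpkm_df = pd.DataFrame(
        fpkm, index=transcripts["transcript_id"], columns=samples["sample_id"]
    )
    study = ExpressionStudy(fpkm_df, transcripts, samples)
    truth.covariates = covariate
    return study, truth


# ---------------------------------------------------------------------------
# gene-set catalogs
# ---------------------------------------------------------------------------

UMBRELLA_TERM = ("GO:0008150", "biological_process")


def simulate_geneset_catalog(
    n_genes: int,
    n_terms: int,
    term_size_sampler: int | Callable[[np.random.Generator], int] = 25,
    seed: int = 0,
) -> GeneSetCatalog:
    """Random flat gene-set catalog over genes G000000..G{n_genes-1}.

    The first of the ``n_terms`` terms is always the umbrella term
    containing every gene (the "biological_process" root); the remaining
    terms' members are sampled without replacement at sizes from
    ``term_size_sampler`` (an int for fixed sizes, or a callable).
    """
    if n_terms < 1:
        raise ValueError("need at least the umbrella term")
    rng = np.random.default_rng(seed)
    genes = np.array([f"G{i:06d}" for i in range(n_genes)])
    terms: dict[str, tuple[str, frozenset]] = {
        UMBRELLA_TERM[0]: (UMBRELLA_TERM[1], frozenset(genes))
    }
    for t in range(n_terms - 1):
        size = term_size_sampler if isinstance(term_size_sampler, int) else int(
            term_size_sampler(rng)
        )
        if size > n_genes:
            raise ValueError(f"term size {size} exceeds the {n_genes}-gene universe")
        members = rng.choice(genes, size, replace=False)
        terms[f"GO:{7000000 + t}"] = (f"synthetic term {t}", frozenset(members))
    return GeneSetCatalog(terms)
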