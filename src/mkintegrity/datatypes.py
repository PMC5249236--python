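"""Shared data containers for the integrity pipeline.

The pipeline follows a cell lineage per donor subject: peripheral-blood
mononuclear cells (MNC) are reprogrammed into up to two induced pluripotent
stem-cell lines (iPSC, technical replicates A and B), each differentiated
into a megakaryocyte line (MK).  Genotype calls, SNP-array intensities
(LRR/BAF) and transcript FPKM matrices all hang off this lineage metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel for a no-call

CELL_TYPES = ("MNC", "iPSC", "MK")
REPLICATES = ("A", "B", "")  # MNC carries no replicate


@dataclass(frozen=True)
class SampleLineage:
    """Identity of one cell line: who it came from and what it is."""

    sample_id: str
    subject: str
    cell_type: str  # MNC | iPSC | MK
    replicate: str  # A | B | "" (MNC)

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if self.replicate not in REPLICATES:
            raise ValueError(f"unknown replicate {self.replicate!r}")
        if self.cell_type == "MNC" and self.replicate:
            raise ValueError("MNC samples carry no replicate label")


class GenotypePanel:
    """Samples x SNPs dosage matrix with lineage metadata.

    Dosages are alt-allele counts in {0, 1, 2}; -1 marks a missing call and
    is excluded from every pairwise comparison downstream.
    """

    def __init__(
        self,
        calls: np.ndarray,
        snps: pd.DataFrame,
        samples: list[SampleLineage],
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2:
            raise ValueError("calls must be a 2-D samples x SNPs matrix")
        if calls.shape[0] != len(samples):
            raise ValueError(
                f"{calls.shape[0]} call rows but {len(samples)} samples"
            )
        if calls.shape[1] != len(snps):
            raise ValueError(
                f"{calls.shape[1]} call columns but {len(snps)} SNPs"
            )
        bad = ~np.isin(calls, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {calls[i, j]} at sample {samples[i].sample_id}, "
                f"SNP row {j}"
            )
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in panel")
        required = {"name", "chrom", "pos"}
        if not required.issubset(snps.columns):
            raise ValueError(f"snps table needs columns {sorted(required)}")
        self.calls = calls
        self.snps = snps.reset_index(drop=True)
        self.samples = list(samples)
        self._index = {s.sample_id: i for i, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def row(self, sample_id: str) -> np.ndarray:
        return self.calls[self._index[sample_id]]

    def lineage(self, sample_id: str) -> SampleLineage:
        return self.samples[self._index[sample_id]]

    def find(
        self, subject: str, cell_type: str, replicate: str = ""
    ) -> Optional[str]:
        """Return the sample id matching a lineage slot, or None."""
        for s in self.samples:
            if (
                s.subject == subject
                and s.cell_type == cell_type
                and s.replicate == replicate
            ):
                return s.sample_id
        return None


@dataclass
class IntensityTrack:
    """Per-probe Log R Ratio / B allele frequency observations.

    ``data`` columns: sample_id, snp, chrom, pos, lrr, baf and optionally
    maf (population B-allele frequency used by the HMM emission model).
    Rows are sorted by (sample, chromosome, position).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "snp", "chrom", "pos", "lrr", "baf"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"intensity table missing columns {sorted(missing)}")
        baf = self.data["baf"].to_numpy(float)
        bad = (baf < 0) | (baf > 1) | ~np.isfinite(baf)
        if bad.any():
            raise ValueError(
                f"BAF outside [0,1] at row {int(np.argwhere(bad)[0][0])}"
            )
        if not np.isfinite(self.data["lrr"].to_numpy(float)).all():
            raise ValueError("non-finite LRR values")
        self.data = (
            self.data.sort_values(["sample_id", "chrom", "pos"], kind="stable")
            .reset_index(drop=True)
        )

    def sample(self, sample_id: str) -> pd.DataFrame:
        sub = self.data[self.data["sample_id"] == sample_id]
        if sub.empty:
            raise KeyError(f"sample {sample_id!r} not in track")
        return sub

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))


class ExpressionStudy:
    """Transcript x sample FPKM matrix with coordinates and a sample sheet.

    ``fpkm``: DataFrame indexed by transcript id, one column per sample.
    ``transcripts``: transcript id, gene, chrom, start, end (1-based).
    ``samples``: sample_id, subject, cell_type in {iPSC, MK}, replicate,
    plus free-form covariate columns (batch, lane, pct_cd41_cd42a, ...).
    """

    def __init__(
        self,
        fpkm: pd.DataFrame,
        transcripts: pd.DataFrame,
        samples: pd.DataFrame,
    ) -> None:
        required = {"transcript_id", "gene", "chrom", "start", "end"}
        if not required.issubset(transcripts.columns):
            raise ValueError(f"transcripts table needs columns {sorted(required)}")
        req_s = {"sample_id", "subject", "cell_type", "replicate"}
        if not req_s.issubset(samples.columns):
            raise ValueError(f"sample sheet needs columns {sorted(req_s)}")
        transcripts = transcripts.reset_index(drop=True)
        samples = samples.reset_index(drop=True)
        if not set(samples["cell_type"]).issubset({"iPSC", "MK"}):
            raise ValueError("expression cell types must be iPSC or MK")
        if list(fpkm.index) != list(transcripts["transcript_id"]):
            fpkm = fpkm.loc[transcripts["transcript_id"]]
        if set(fpkm.columns) != set(samples["sample_id"]):
            raise ValueError("FPKM columns do not match the sample sheet")
        fpkm = fpkm[list(samples["sample_id"])]
        vals = fpkm.to_numpy(float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("FPKM values must be finite and non-negative")
        self.fpkm = fpkm
        self.transcripts = transcripts
        self.samples = samples

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_id(self, subject: str, cell_type: str, replicate: str) -> Optional[str]:
        m = self.samples
        hit = m[
            (m["subject"] == subject)
            & (m["cell_type"] == cell_type)
            & (m["replicate"] == replicate)
        ]
        return None if hit.empty else str(hit["sample_id"].iloc[0])

    def subset_samples(self, keep: list[str]) -> "ExpressionStudy":
        mask = self.samples["sample_id"].isin(keep)
        return ExpressionStudy(
            self.fpkm[list(self.samples.loc[mask, "sample_id"])],
            self.transcripts,
            self.samples.loc[mask].reset_index(drop=True),
        )


class ArmMap:
    """Chromosome arm lookup from cytoband centromere boundaries.

    ``centromeres`` maps chromosome -> first 1-based position of the q arm;
    positions strictly below it belong to p.
    """

    def __init__(self, centromeres: dict[str, int]) -> None:
        if not centromeres:
            raise ValueError("empty arm map")
        self.centromeres = dict(centromeres)

    def arm_of(self, chrom: str, pos: int) -> str:
        if chrom not in self.centromeres:
            raise KeyError(f"chromosome {chrom!r} not in arm map")
        return "p" if pos < self.centromeres[chrom] else "q"

    @property
    def chromosomes(self) -> list[str]:
        return list(self.centromeres)


@dataclass
class GeneSetCatalog:
    """Flat term -> gene-member sets (GMT semantics)."""

    terms: dict[str, tuple[str, frozenset]]  # id -> (name, members)

    def members(self, term_id: str) -> frozenset:
        return self.terms[term_id][1]

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def __len__(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# Ground-truth records emitted by the simulators
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTruth:
    """Planted truth of a simulated genotype lineage."""

    per_call_error_rate: float
    # (subject, replicate, snp index, new genotype), introduced in the iPSC
    # and copied to its paired MK
    planted_mutations: list[tuple[str, str, int, int]] = field(default_factory=list)
    # (sample_id, snp index) independent miscalls
    error_positions: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class CNVTruth:
    """Planted copy-number segments; baseline copy number is 2 elsewhere.

    Segments are (chrom, start probe index, end probe index, copy number,
    carrier sample id) with inclusive probe indices local to the chromosome.
    """

    segments: list[tuple[str, int, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_sample: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for chrom, s, e, cn, sample in self.segments:
            if s > e:
                raise ValueError(f"segment start {s} > end {e}")
            if cn not in (0, 1, 2, 3, 4):
                raise ValueError(f"copy number {cn} outside 0..4")
            by_sample.setdefault((sample, chrom), []).append((s, e))
        for key, ivs in by_sample.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping truth segments for {key}")


@dataclass
class ExpressionTruth:
    """Planted truth of a simulated expression study."""

    # per-transcript log2 mean difference, MK minus iPSC
    celltype_effects: np.ndarray
    # per-sample covariate values and per-transcript loadings
    covariates: Optional[np.ndarray] = None  # shape (n_samples,)
    loadings: Optional[np.ndarray] = None  # shape (n_transcripts,)
    # (subject, replicate, cell_type, chrom, arm, multiplicative factor)
    arm_duplication: Optional[tuple[str, str, str, str, str, float]] = None
    # term id -> (direction in {up_in_MK, down_in_MK}, effect size)
    enriched_terms: dict[str, tuple[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class CNVSegment:
    """A called copy-number segment (copy number != 2)."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive position
    end: int
    copy_number: int
    n_probes: int
    mean_lrr: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("segment start > end")
        if self.n_probes < 1:
            raise ValueError("segment must have at least one probe")
        if self.copy_number == 2:
            raise ValueError("diploid runs are not segments")
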