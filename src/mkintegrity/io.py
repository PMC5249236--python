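"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain TSV; coordinates are 1-based inclusive
internally, with UCSC cytoband input (0-based half-open) converted at the
boundary.  Every reader validates strictly — no malformed record passes
silently — and every writer emits files its reader round-trips.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    ArmMap,
    CNVTruth,
    ExpressionStudy,
    GeneSetCatalog,
    GenotypePanel,
    GenotypeTruth,
    IntensityTrack,
    SampleLineage,
)

_LINEAGE_RE = re.compile(r"^([IM])(.+?)([AB])$")


def parse_lineage_name(sample_id: str) -> SampleLineage:
    """Parse lineage metadata from the study's naming convention.

    Prefix I or M marks an iPSC or MK line and the trailing A/B its
    technical replicate (e.g. ``MP030A`` is subject P030's MK line A);
    anything else is taken as a donor MNC whose subject is the name.
    """
    m = _LINEAGE_RE.match(sample_id)
    if m:
        prefix, subject, rep = m.groups()
        cell_type = "iPSC" if prefix == "I" else "MK"
        return SampleLineage(sample_id, subject, cell_type, rep)
    return SampleLineage(sample_id, sample_id, "MNC", "")


def _read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "subject", "cell_type", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    sheet["replicate"] = sheet["replicate"].fillna("")
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in sample sheet")
    return sheet


def _lineages_for(ids: list[str], sheet: Optional[pd.DataFrame]) -> list[SampleLineage]:
    """Sample-sheet metadata overrides name-convention parsing."""
    if sheet is None:
        return [parse_lineage_name(i) for i in ids]
    lookup = sheet.set_index("sample_id")
    out = []
    for i in ids:
        if i in lookup.index:
            row = lookup.loc[i]
            out.append(SampleLineage(i, row["subject"], row["cell_type"], row["replicate"]))
        else:
            out.append(parse_lineage_name(i))
    return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_GENO_META = ["name", "chrom", "pos", "allele_a", "allele_b"]


def read_genotypes(
    path: str | Path,
    dialect: str = "tsv",
    sample_sheet: Optional[str | Path] = None,
) -> GenotypePanel:
    """Read a genotype call matrix.

    ``dialect='tsv'``: header row ``name chrom pos allele_a allele_b``
    followed by one dosage column per sample, one row per SNP.
    ``dialect='pedigree'``: a PLINK text ``.ped`` file (``path``) with its
    ``.map`` alongside; dosages count the lexicographically later allele.
    Missing calls are -1.  Input unsorted within a chromosome is sorted
    with a warning.
    """
    sheet = _read_sample_sheet(sample_sheet) if sample_sheet else None
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        missing = set(_GENO_META) - set(df.columns)
        if missing:
            raise ValueError(f"genotype TSV missing columns {sorted(missing)}")
        sample_ids = [c for c in df.columns if c not in _GENO_META and c != "maf"]
        if not sample_ids:
            raise ValueError("genotype TSV has no sample columns")
        calls = df[sample_ids].to_numpy()
        if not np.issubdtype(calls.dtype, np.number):
            bad = df[sample_ids].map(lambda v: not str(v).lstrip("-").isdigit())
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric dosage {calls[r, c]!r} at line {r + 2}, sample {sample_ids[c]}"
            )
        bad = ~np.isin(calls, (-1, 0, 1, 2))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {calls[r, c]} at line {r + 2}, sample {sample_ids[c]}"
            )
        snps = df[_GENO_META].copy()
        if "maf" in df.columns:
            snps["maf"] = df["maf"]
        calls = calls.T  # -> samples x SNPs
    elif dialect == "pedigree":
        snps, calls, sample_ids = _read_ped(Path(path))
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")

    order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].astype(str).to_numpy()))
    if not np.array_equal(order, np.arange(len(snps))):
        warnings.warn("genotype input not position-sorted; sorting")
        snps = snps.iloc[order].reset_index(drop=True)
        calls = calls[:, order]
    snps["chrom"] = snps["chrom"].astype(str)
    return GenotypePanel(calls, snps, _lineages_for(list(sample_ids), sheet))


def _read_ped(ped_path: Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise FileNotFoundError(f"no .map companion for {ped_path}")
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "name", "cm", "pos"], dtype=str
    )
    n_snps = len(mp)
    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path} line {ln}: expected {6 + 2 * n_snps} fields, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])
    alleles = np.array(allele_rows).reshape(len(sample_ids), n_snps, 2)
    allele_a = np.empty(n_snps, dtype=object)
    allele_b = np.empty(n_snps, dtype=object)
    calls = np.full((len(sample_ids), n_snps), -1, dtype=np.int8)
    for j in range(n_snps):
        obs = sorted(set(alleles[:, j, :].ravel()) - {"0"})
        if len(obs) > 2:
            raise ValueError(f"SNP {mp['name'][j]} has >2 alleles: {obs}")
        a = obs[0] if obs else "A"
        b = obs[1] if len(obs) > 1 else a
        allele_a[j], allele_b[j] = a, b
        present = (alleles[:, j, 0] != "0") & (alleles[:, j, 1] != "0")
        calls[present, j] = (alleles[present, j, :] == b).sum(axis=1)
    snps = pd.DataFrame(
        {
            "name": mp["name"],
            "chrom": mp["chrom"],
            "pos": mp["pos"].astype(int),
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    return snps, calls, sample_ids


def write_genotypes(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel in the TSV dialect :func:`read_genotypes` reads."""
    df = panel.snps[_GENO_META].copy()
    if "maf" in panel.snps.columns:
        df["maf"] = panel.snps["maf"]
    for i, sid in enumerate(panel.sample_ids):
        df[sid] = panel.calls[i]
    df.to_csv(path, sep="\t", index=False)


def write_sample_sheet(samples: list[SampleLineage] | pd.DataFrame, path: str | Path) -> None:
    if isinstance(samples, pd.DataFrame):
        samples.to_csv(path, sep="\t", index=False)
        return
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "subject": s.subject,
                "cell_type": s.cell_type,
                "replicate": s.replicate,
            }
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LRR/BAF intensity (GenomeStudio final-report style)
# ---------------------------------------------------------------------------

_INTENSITY_COLS = {
    "Sample ID": "sample_id",
    "SNP Name": "snp",
    "Chr": "chrom",
    "Position": "pos",
    "Log R Ratio": "lrr",
    "B Allele Freq": "baf",
}


def read_intensity(path: str | Path) -> IntensityTrack:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_INTENSITY_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity file missing columns {sorted(missing)}")
    df = df.rename(columns=_INTENSITY_COLS)
    if df.empty:
        raise ValueError("empty intensity file")
    for col in ("lrr", "baf", "pos"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"non-numeric {col} at data row {row + 1}")
        df[col] = vals
    baf = df["baf"].to_numpy(float)
    bad = (baf < 0) | (baf > 1)
    if bad.any():
        raise ValueError(f"BAF outside [0,1] at data row {int(np.argwhere(bad)[0][0]) + 1}")
    df["chrom"] = df["chrom"].astype(str)
    if "MAF" in df.columns:
        df = df.rename(columns={"MAF": "maf"})
    return IntensityTrack(df)


def write_intensity(track: IntensityTrack, path: str | Path) -> None:
    inv = {v: k for k, v in _INTENSITY_COLS.items()}
    df = track.data.rename(columns=inv)
    if "maf" in df.columns:
        df = df.rename(columns={"maf": "MAF"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_EXPR_META = ["transcript_id", "gene", "chrom", "start", "end"]


def read_expression(path: str | Path, sample_sheet: str | Path) -> ExpressionStudy:
    """Read a transcript FPKM TSV plus its sample sheet.

    FPKM columns follow the five transcript-annotation columns; the
    sample sheet carries lineage metadata and covariates (batch, lane,
    percent CD41+CD42a+, ...).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_EXPR_META) - set(df.columns)
    if missing:
        raise ValueError(f"expression file missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError("empty expression file")
    sheet = pd.read_csv(sample_sheet, sep="\t")
    req = {"sample_id", "subject", "cell_type", "replicate"}
    if not req.issubset(sheet.columns):
        raise ValueError(f"sample sheet missing columns {sorted(req - set(sheet.columns))}")
    sheet["replicate"] = sheet["replicate"].fillna("").astype(str)
    sample_ids = [c for c in df.columns if c not in _EXPR_META]
    fpkm = df[sample_ids].apply(pd.to_numeric, errors="coerce")
    if fpkm.isna().any().any():
        col = fpkm.columns[fpkm.isna().any()][0]
        row = int(fpkm.index[fpkm[col].isna()][0])
        raise ValueError(f"non-numeric FPKM at data row {row + 1}, sample {col}")
    transcripts = df[_EXPR_META].copy()
    transcripts["chrom"] = transcripts["chrom"].astype(str)
    fpkm.index = transcripts["transcript_id"]
    return ExpressionStudy(fpkm, transcripts, sheet)


def write_expression(study: ExpressionStudy, path: str | Path, sheet_path: str | Path) -> None:
    df = study.transcripts[_EXPR_META].copy()
    fpkm = study.fpkm.reset_index(drop=True)
    out = pd.concat([df, fpkm], axis=1)
    out.to_csv(path, sep="\t", index=False)
    study.samples.to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cytoband arm map
# ---------------------------------------------------------------------------


def read_armmap(path: str | Path) -> ArmMap:
    """Build an arm map from a UCSC cytoBand-style file.

    Columns: chrom, 0-based start, end, band name (e.g. ``p36.33``),
    stain.  The centromere is the boundary between the last p band and
    the first q band; acen bands count toward their lettered arm.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str},
    )
    if df.empty:
        raise ValueError("empty cytoband file")
    df["chrom"] = df["chrom"].str.replace("^chr", "", regex=True)
    centromeres: dict[str, int] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        arms = grp["band"].str[0]
        if not set(arms).issubset({"p", "q"}):
            bad = grp["band"][~arms.isin(["p", "q"])].iloc[0]
            raise ValueError(f"unparseable band name {bad!r} on chromosome {chrom}")
        q = grp[arms == "q"]
        if q.empty:
            raise ValueError(f"chromosome {chrom} has no q bands")
        # first q-band 0-based start -> first 1-based q position
        centromeres[chrom] = int(q["start"].min()) + 1
    return ArmMap(centromeres)


def write_armmap(armmap: ArmMap, path: str | Path, length_pad: int = 100_000_000) -> None:
    """Write a minimal two-band cytoband file reproducing the arm map."""
    rows = []
    for chrom, cen in armmap.centromeres.items():
        rows.append((chrom, 0, cen - 1, "p11", "acen"))
        rows.append((chrom, cen - 1, cen - 1 + length_pad, "q11", "acen"))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_genesets(path: str | Path) -> GeneSetCatalog:
    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {ln}: need id, name and at least one gene")
            term_id, name, genes = fields[0], fields[1], fields[2:]
            if term_id in terms:
                raise ValueError(f"GMT line {ln}: duplicate term {term_id}")
            if len(set(genes)) != len(genes):
                warnings.warn(f"GMT line {ln}: duplicate genes in {term_id}; deduplicated")
            terms[term_id] = (name, frozenset(genes))
    if not terms:
        raise ValueError("empty GMT file")
    return GeneSetCatalog(terms)


def write_genesets(catalog: GeneSetCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, members) in catalog.terms.items():
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# planted-truth records
# ---------------------------------------------------------------------------


def write_genotype_truth(truth: GenotypeTruth, path: str | Path) -> None:
    rows = [("error_rate", "", "", "", truth.per_call_error_rate)]
    rows += [
        ("mutation", subj, rep, j, g) for subj, rep, j, g in truth.planted_mutations
    ]
    rows += [("error", sid, "", j, "") for sid, j in truth.error_positions]
    pd.DataFrame(rows, columns=["kind", "who", "replicate", "snp_index", "value"]).to_csv(
        path, sep="\t", index=False
    )


def write_cnv_truth(truth: CNVTruth, path: str | Path) -> None:
    pd.DataFrame(
        truth.segments,
        columns=["chrom", "start_probe", "end_probe", "copy_number", "sample_id"],
    ).to_csv(path, sep="\t", index=False)
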