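"""End-to-end orchestration of the integrity assessment.

``run_pipeline`` executes, in order: synthetic-data generation (or
loading of user files), genotype fidelity (LD pruning, IBD, pairwise
and transmitted discordance), structural integrity (HMM CNV calls and
parent/daughter comparison), transcriptomic integrity (IQR filter,
paired differences, PC-adjusted moderated DE, direction-split KS
enrichment) and expression-based arm CNV detection.  Every stage writes
machine-readable TSVs under the output directory and contributes to a
plain-text report; all randomness derives from one master seed, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnvmod
from . import de as demod
from . import enrichment as enrmod
from . import expr_cnv as xcnvmod
from . import genotype as genomod
from . import io as iomod
from . import simulate as simmod
from .datatypes import CNVTruth

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "simulate": {
        "genotype": {
            "n_subjects": 6,
            "n_snps": 20000,
            "error_rate": 2.5e-5,
            "n_mutations_per_ipsc": 8,
            "n_lines": 2,
        },
        "cnv": {
            "n_probes": 6000,
            "chroms": ["1", "2"],
            "spacing": 66666,
            "lrr_sd": 0.2,
            "baf_sd": 0.03,
            # local probe index ranges; chr1 q arm spans indices 1500..2999
            "shared_deletion": {"chrom": "2", "start": 1000, "end": 1099, "cn": 1},
            "arm_duplication": {"chrom": "1", "start": 1500, "end": 2999, "cn": 3},
        },
        "expression": {
            "n_subjects": 14,
            "n_transcripts": 3000,
            "transcripts_per_gene": 2,
            "n_de": 300,
            "de_effect": 2.0,
            "noise_sd": 0.5,
            "catalog": {"n_genes": 1500, "n_terms": 40, "term_size": 25},
            "enriched_terms": {
                "GO:7000000": ["up_in_MK", 2.0],
                "GO:7000001": ["down_in_MK", 2.0],
            },
            "arm_duplication": {
                "subject": "P001",
                "replicate": "A",
                "cell_type": "MK",
                "chrom": "1",
                "arm": "q",
                "factor": 2.0,
            },
        },
    },
    "genotype_qc": {
        "window": 50,
        "step": 5,
        "r2": 0.3,
        "min_informative": 50,
        "platform_error_rate_percent": 0.37,
    },
    "cnv": {"min_probes": 10, "min_reciprocal_overlap": 0.5},
    "de": {"iqr_threshold": 1.0, "offset": 1.0, "n_pcs": 2, "sig_q": 0.05,
           "exclude_samples": []},
    "enrichment": {"sig_q": 0.05, "min_term_size": 5},
    "expr_cnv": {
        "chrom": "1",
        "target_arm": "q",
        "n_perm": 9999,
        "sample_a": "MP001A",
        "sample_b": "MP001B",
    },
    "plots": False,
}


def _merge(base: dict, override: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return copy.deepcopy(out)


def load_config(path: Optional[str | Path] = None, **overrides: Any) -> dict:
    """Default configuration, optionally merged with a YAML file and overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return _merge(cfg, overrides)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class IntegrityReport:
    """Aggregated results of all pipeline stages, with file provenance."""

    config: dict
    config_hash: str
    genotype: dict = field(default_factory=dict)
    structural: dict = field(default_factory=dict)
    transcriptomic: dict = field(default_factory=dict)
    expression_cnv: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "genotype": self.genotype,
            "structural": self.structural,
            "transcriptomic": self.transcriptomic,
            "expression_cnv": self.expression_cnv,
            "outputs": self.outputs,
        }


def run_pipeline(
    config: Optional[dict | str | Path] = None,
    outdir: str | Path = "mkintegrity_out",
    seed: Optional[int] = None,
) -> IntegrityReport:
    """Run the full integrity assessment; returns the combined report.

    ``config`` may be a configuration dict (see ``DEFAULT_CONFIG``) or a
    YAML path; ``seed`` overrides the configured master seed.
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = _merge(DEFAULT_CONFIG, config)
    if seed is not None:
        cfg["seed"] = int(seed)
    master = int(cfg["seed"])
    out = Path(outdir)
    for sub in ("inputs", "genotype", "cnv", "de", "enrichment", "expr_cnv"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    report = IntegrityReport(config=cfg, config_hash=config_hash(cfg))

    # ---- stage 0: synthetic inputs -------------------------------------
    sim = cfg["simulate"]
    gcfg = sim["genotype"]
    panel, gtruth = simmod.simulate_genotype_lineage(
        n_subjects=gcfg["n_subjects"],
        n_snps=gcfg["n_snps"],
        error_rate=gcfg["error_rate"],
        n_mutations_per_ipsc=gcfg["n_mutations_per_ipsc"],
        n_lines=gcfg["n_lines"],
        seed=master,
    )
    iomod.write_genotypes(panel, out / "inputs" / "genotypes.tsv")
    iomod.write_sample_sheet(panel.samples, out / "inputs" / "samples.tsv")
    iomod.write_genotype_truth(gtruth, out / "inputs" / "genotype_truth.tsv")

    ccfg = sim["cnv"]
    probe_map = simmod.simulate_probe_map(
        ccfg["n_probes"], chroms=ccfg["chroms"], spacing=ccfg["spacing"], seed=master + 1
    )
    track_samples = ["P001", "IP001A", "MP001A"]
    segments = []
    sd = ccfg["shared_deletion"]
    for s in track_samples:
        segments.append((sd["chrom"], sd["start"], sd["end"], sd["cn"], s))
    ad = ccfg["arm_duplication"]
    segments.append((ad["chrom"], ad["start"], ad["end"], ad["cn"], "MP001A"))
    cnv_truth = CNVTruth(segments)
    track, _ = simmod.simulate_lrr_baf(
        probe_map, cnv_truth, lrr_sd=ccfg["lrr_sd"], baf_sd=ccfg["baf_sd"],
        samples=track_samples, seed=master + 2,
    )
    iomod.write_intensity(track, out / "inputs" / "intensity.tsv")
    iomod.write_cnv_truth(cnv_truth, out / "inputs" / "cnv_truth.tsv")

    ecfg = sim["expression"]
    transcripts = simmod.simulate_transcript_annotation(
        ecfg["n_transcripts"], seed=master + 3,
        transcripts_per_gene=ecfg["transcripts_per_gene"],
    )
    cat_cfg = ecfg["catalog"]
    catalog = simmod.simulate_geneset_catalog(
        cat_cfg["n_genes"], cat_cfg["n_terms"], cat_cfg["term_size"], seed=master + 4
    )
    dup = ecfg["arm_duplication"]
    etruth = simmod.make_expression_truth(
        transcripts,
        catalog=catalog,
        n_de=ecfg["n_de"],
        de_effect=ecfg["de_effect"],
        enriched_terms={k: tuple(v) for k, v in ecfg["enriched_terms"].items()},
        arm_duplication=(
            dup["subject"], dup["replicate"], dup["cell_type"],
            dup["chrom"], dup["arm"], dup["factor"],
        ),
        seed=master + 5,
    )
    study, etruth = simmod.simulate_expression_study(
        ecfg["n_subjects"], etruth, transcripts=transcripts,
        noise_sd=ecfg["noise_sd"], seed=master + 6,
    )
    armmap = simmod.default_armmap()
    iomod.write_expression(
        study, out / "inputs" / "expression.tsv", out / "inputs" / "expr_samples.tsv"
    )
    iomod.write_armmap(armmap, out / "inputs" / "cytoband.txt")
    iomod.write_genesets(catalog, out / "inputs" / "genesets.gmt")

    # ---- stage 1: genotype integrity -----------------------------------
    qc = cfg["genotype_qc"]
    pruned = genomod.ld_prune(panel, qc["window"], qc["step"], qc["r2"])
    ibd = genomod.estimate_ibd(panel, pruned, min_informative=qc["min_informative"])
    ibd_df = pd.DataFrame(
        [
            {
                "sample_a": e.sample_a, "sample_b": e.sample_b, "z0": e.z0,
                "z1": e.z1, "z2": e.z2, "relationship": e.relationship,
                "n_markers": e.n_markers, "flagged": e.flagged,
            }
            for e in ibd
        ]
    )
    ibd_df.to_csv(out / "genotype" / "ibd.tsv", sep="\t", index=False)

    disc_rows, trans_rows = [], []
    for s in panel.samples:
        if s.cell_type == "iPSC":
            mnc = panel.find(s.subject, "MNC")
            if mnc:
                r = genomod.count_discordances(panel, (mnc, s.sample_id))
                disc_rows.append(("MNC->iPSC", r))
            mk = panel.find(s.subject, "MK", s.replicate)
            if mk:
                r = genomod.count_discordances(panel, (s.sample_id, mk))
                disc_rows.append(("iPSC->MK", r))
                t = genomod.transmitted_discordance(panel, s.subject, s.replicate)
                trans_rows.append(t)
    disc_df = pd.DataFrame(
        [
            {
                "comparison": kind, "sample_a": r.sample_a, "sample_b": r.sample_b,
                "n_compared": r.n_compared, "n_discordant": r.n_discordant,
                "rate_percent": 100.0 * r.rate,
            }
            for kind, r in disc_rows
        ]
    )
    disc_df.to_csv(out / "genotype" / "discordance.tsv", sep="\t", index=False)
    trans_df = pd.DataFrame(
        [
            {
                "subject": t.subject, "replicate": t.replicate,
                "n_snps_compared": t.n_snps_compared,
                "n_mnc_ipsc_discordant": t.n_mnc_ipsc_discordant,
                "n_transmitted": t.n_transmitted,
                "transmitted_rate_percent": t.transmitted_rate_percent,
            }
            for t in trans_rows
        ]
    )
    trans_df.to_csv(out / "genotype" / "transmitted.tsv", sep="\t", index=False)
    report.genotype = {
        "n_snps": panel.n_snps,
        "n_pruned_markers": len(pruned),
        "within_subject_min_z2": float(
            ibd_df.loc[~ibd_df.flagged & (ibd_df.relationship == "within-subject"), "z2"].min()
        ),
        "between_subject_max_z2": float(
            ibd_df.loc[~ibd_df.flagged & (ibd_df.relationship == "between-subject"), "z2"].max()
        ),
        "max_discordance_rate_percent": float(disc_df["rate_percent"].max()),
        "platform_error_rate_percent": qc["platform_error_rate_percent"],
        "max_transmitted": int(trans_df["n_transmitted"].max()),
        "max_transmitted_rate_percent_1sf": genomod.round_sigfig(
            float(trans_df["transmitted_rate_percent"].max()), 1
        ),
    }

    # ---- stage 2: structural integrity ---------------------------------
    model = cnvmod.HMMModel(baf_sd=ccfg["baf_sd"])
    seg_by_sample: dict[str, list] = {}
    seg_rows = []
    for sid in track.sample_ids:
        decoded = cnvmod.viterbi_decode(model, track, sid)
        segs = cnvmod.call_segments(decoded, sid, cfg["cnv"]["min_probes"])
        seg_by_sample[sid] = segs
        for g in segs:
            seg_rows.append(
                {
                    "sample_id": g.sample_id, "chrom": g.chrom, "start": g.start,
                    "end": g.end, "copy_number": g.copy_number,
                    "n_probes": g.n_probes, "mean_lrr": g.mean_lrr,
                }
            )
    pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "copy_number",
                           "n_probes", "mean_lrr"],
    ).to_csv(out / "cnv" / "segments.tsv", sep="\t", index=False)

    comp_rows = []
    extracts = []
    pairs = [("P001", "IP001A"), ("IP001A", "MP001A")]
    for parent, daughter in pairs:
        if parent not in seg_by_sample or daughter not in seg_by_sample:
            continue
        comparison = cnvmod.compare_cnv_sets(
            seg_by_sample[parent], seg_by_sample[daughter],
            cfg["cnv"]["min_reciprocal_overlap"],
        )
        for seg in comparison.daughter_only:
            comp_rows.append(
                {"parent": parent, "daughter": daughter, "class": "daughter_only",
                 "chrom": seg.chrom, "start": seg.start, "end": seg.end,
                 "copy_number": seg.copy_number, "n_probes": seg.n_probes}
            )
            extracts.append(cnvmod.evidence_extract(track, seg, [parent, daughter]))
        for pseg, dseg in comparison.shared:
            comp_rows.append(
                {"parent": parent, "daughter": daughter, "class": "shared",
                 "chrom": dseg.chrom, "start": dseg.start, "end": dseg.end,
                 "copy_number": dseg.copy_number, "n_probes": dseg.n_probes}
            )
        for seg in comparison.parent_only:
            comp_rows.append(
                {"parent": parent, "daughter": daughter, "class": "parent_only",
                 "chrom": seg.chrom, "start": seg.start, "end": seg.end,
                 "copy_number": seg.copy_number, "n_probes": seg.n_probes}
            )
    comp_df = pd.DataFrame(
        comp_rows, columns=["parent", "daughter", "class", "chrom", "start", "end",
                            "copy_number", "n_probes"],
    )
    comp_df.to_csv(out / "cnv" / "comparisons.tsv", sep="\t", index=False)
    if extracts:
        pd.concat(extracts, ignore_index=True).to_csv(
            out / "cnv" / "extracts.tsv", sep="\t", index=False
        )
    report.structural = {
        "n_segments": len(seg_rows),
        "daughter_only": int((comp_df["class"] == "daughter_only").sum()) if not comp_df.empty else 0,
        "shared": int((comp_df["class"] == "shared").sum()) if not comp_df.empty else 0,
        "mk_has_1q_gain": bool(
            any(
                g.chrom == ad["chrom"] and g.copy_number > 2
                for g in seg_by_sample.get("MP001A", [])
            )
        ),
    }

    # ---- stage 3: transcriptomic integrity -----------------------------
    decfg = cfg["de"]
    transcript_to_gene = dict(
        zip(study.transcripts["transcript_id"], study.transcripts["gene"])
    )

    def de_chain(current_study):
        retained = demod.iqr_filter(current_study, decfg["iqr_threshold"])
        delta = demod.build_delta(current_study, retained, decfg["offset"])
        pcs = demod.compute_pcs(delta, decfg["n_pcs"])
        fit = demod.fit_moderated(delta, pcs, sig_q=decfg["sig_q"])
        return retained, delta, pcs, fit

    retained, delta, pcs, fit = de_chain(study)
    pcs.scores.to_csv(out / "de" / "pc_scores.tsv", sep="\t")
    ann = study.transcripts.set_index("transcript_id")
    for direction, fname in (("up_in_MK", "results_up_in_mk.tsv"),
                             ("down_in_MK", "results_down_in_mk.tsv")):
        sub = fit.table[fit.table["direction"] == direction]
        out_df = pd.DataFrame(
            {
                "transcript_id": sub.index,
                "gene": ann.loc[sub.index, "gene"].to_numpy(),
                "chrom": ann.loc[sub.index, "chrom"].to_numpy(),
                "start": ann.loc[sub.index, "start"].to_numpy(),
                "end": ann.loc[sub.index, "end"].to_numpy(),
                "log2_fold_change_mk": sub["log2fc_mk"].to_numpy(),
                "fold_change_mk": np.exp2(sub["log2fc_mk"].to_numpy()),
                "p": sub["p"].to_numpy(),
                "q": sub["q"].to_numpy(),
            }
        ).sort_values("q", kind="stable")
        out_df.to_csv(out / "de" / fname, sep="\t", index=False)

    enc = cfg["enrichment"]
    top_terms: dict[str, list[str]] = {}
    sig_terms: dict[str, set] = {}
    for direction, fname in (("up_in_MK", "up_in_mk.tsv"), ("down_in_MK", "down_in_mk.tsv")):
        scores = enrmod.gene_scores(fit, transcript_to_gene, direction)
        res = enrmod.ks_enrichment(
            scores, catalog, de=fit, transcript_to_gene=transcript_to_gene,
            direction=direction, sig_q_threshold=enc["sig_q"],
            min_term_size=enc["min_term_size"],
        )
        df = pd.DataFrame(
            [
                {
                    "GO.ID": r.term_id, "Term": r.name, "Annotated": r.annotated,
                    "Significant": r.significant, "Expected": round(r.expected, 2),
                    "p-value": r.p, "q-value": r.q,
                }
                for r in res
            ]
        ).sort_values(["q-value", "p-value"], kind="stable")
        df.to_csv(out / "enrichment" / fname, sep="\t", index=False)
        top_terms[direction] = list(df["GO.ID"].head(5))
        sig_terms[direction] = set(df.loc[df["q-value"] < 1e-3, "GO.ID"])

    sig = fit.table["q"] < decfg["sig_q"]
    report.transcriptomic = {
        "n_transcripts": study.n_transcripts,
        "n_retained": len(retained),
        "pc_variance_fractions": [round(float(f), 4) for f in pcs.variance_fractions],
        "n_up_in_mk": int((sig & (fit.table["direction"] == "up_in_MK")).sum()),
        "n_down_in_mk": int((sig & (fit.table["direction"] == "down_in_MK")).sum()),
        "d0": float(fit.d0),
        "top_terms": top_terms,
    }

    # sensitivity mode: full rerun without the excluded samples + partners
    excluded = list(decfg["exclude_samples"])
    if excluded:
        drop = set(excluded)
        for sid in excluded:
            row = study.samples[study.samples["sample_id"] == sid]
            if not row.empty:
                r = row.iloc[0]
                partner_type = "iPSC" if r["cell_type"] == "MK" else "MK"
                partner = study.sample_id(r["subject"], partner_type, r["replicate"])
                if partner:
                    drop.add(partner)
        keep = [s for s in study.samples["sample_id"] if s not in drop]
        sub_study = study.subset_samples(keep)
        _, _, _, fit_x = de_chain(sub_study)
        top_x: dict[str, list[str]] = {}
        sig_x: dict[str, set] = {}
        for direction in ("up_in_MK", "down_in_MK"):
            scores = enrmod.gene_scores(fit_x, transcript_to_gene, direction)
            res = enrmod.ks_enrichment(
                scores, catalog, de=fit_x, transcript_to_gene=transcript_to_gene,
                direction=direction, sig_q_threshold=enc["sig_q"],
                min_term_size=enc["min_term_size"],
            )
            df = pd.DataFrame(
                [{"GO.ID": r.term_id, "q": r.q, "p": r.p} for r in res]
            ).sort_values(["q", "p"], kind="stable")
            df.to_csv(
                out / "enrichment" / f"sensitivity_{direction.lower()}.tsv",
                sep="\t", index=False,
            )
            top_x[direction] = list(df["GO.ID"].head(5))
            sig_x[direction] = set(df.loc[df["q"] < 1e-3, "GO.ID"])
        # agreement on the highly significant (q < 0.001) term lists
        report.transcriptomic["sensitivity"] = {
            "excluded": sorted(drop),
            "top_terms": top_x,
            "top_terms_agree": {
                d: sig_terms[d] == sig_x[d] for d in sig_terms
            },
        }

    # ---- stage 4: expression-based arm CNV -----------------------------
    xc = cfg["expr_cnv"]
    fc = xcnvmod.replicate_fold_change(
        study, xc["sample_a"], xc["sample_b"], transcripts=retained,
        offset=decfg["offset"],
    )
    fc.to_csv(out / "expr_cnv" / "fold_changes.tsv", sep="\t")
    contrast = xcnvmod.arm_contrast(
        fc, armmap, xc["chrom"], xc["target_arm"], n_perm=xc["n_perm"],
        seed=master + 7,
    )
    pd.DataFrame(
        [
            {
                "chrom": contrast.chrom, "target_arm": contrast.target_arm,
                "target_mean_log2fc": contrast.target_mean,
                "target_n": contrast.target_n,
                "reference_mean_log2fc": contrast.reference_mean,
                "reference_n": contrast.reference_n,
                "observed_contrast": contrast.observed, "p": contrast.p,
            }
        ]
    ).to_csv(out / "expr_cnv" / "arm_contrast.tsv", sep="\t", index=False)
    report.expression_cnv = {
        "target_mean_log2fc": round(contrast.target_mean, 4),
        "reference_mean_log2fc": round(contrast.reference_mean, 4),
        "p": contrast.p,
        "detected": contrast.p < 0.01,
    }

    if cfg.get("plots"):
        from . import plots as plotmod

        chrom1 = track.sample("MP001A")
        chrom1 = chrom1[chrom1["chrom"] == ad["chrom"]]
        plotmod.plot_lrr_baf(
            chrom1, out / "cnv" / "mp001a_chr1.png", title="MP001A chr1"
        )
        plotmod.plot_arm_contrast(contrast, out / "expr_cnv" / "arm_contrast.png")

    # relative paths so machine outputs are location-independent
    report.outputs = {
        sub: sub for sub in ("inputs", "genotype", "cnv", "de", "enrichment", "expr_cnv")
    }
    _write_report(report, out)
    return report


def _write_report(report: IntegrityReport, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True, default=str)
    g, s, t, x = report.genotype, report.structural, report.transcriptomic, report.expression_cnv
    lines = [
        "mkintegrity combined report",
        f"config hash: {report.config_hash}",
        "",
        "GENOTYPE INTEGRITY",
        f"  SNPs: {g['n_snps']}; LD-pruned markers: {g['n_pruned_markers']}",
        f"  within-subject min Z2: {g['within_subject_min_z2']:.4f}",
        f"  between-subject max Z2: {g['between_subject_max_z2']:.4f}",
        f"  max pairwise discordance: {g['max_discordance_rate_percent']:.4g}% "
        f"(platform error benchmark {g['platform_error_rate_percent']}%)",
        f"  max transmitted discordances: {g['max_transmitted']} "
        f"(rate {g['max_transmitted_rate_percent_1sf']:.4g}%)",
        "",
        "STRUCTURAL INTEGRITY",
        f"  segments called: {s['n_segments']}; shared parent/daughter: {s['shared']}; "
        f"daughter-only: {s['daughter_only']}",
        f"  MK-line chr1 gain detected: {s['mk_has_1q_gain']}",
        "",
        "TRANSCRIPTOMIC INTEGRITY",
        f"  transcripts: {t['n_transcripts']}; IQR-retained: {t['n_retained']}",
        f"  PC variance fractions: {t['pc_variance_fractions']}",
        f"  significant transcripts (q<0.05): {t['n_up_in_mk']} up in MK, "
        f"{t['n_down_in_mk']} down in MK",
        f"  top enriched terms up_in_MK: {', '.join(t['top_terms']['up_in_MK'])}",
        f"  top enriched terms down_in_MK: {', '.join(t['top_terms']['down_in_MK'])}",
        "",
        "EXPRESSION-BASED CNV",
        f"  target arm mean log2 FC: {x['target_mean_log2fc']} "
        f"(reference arm {x['reference_mean_log2fc']})",
        f"  permutation p: {x['p']:.3g}; detected: {x['detected']}",
        "",
    ]
    if "sensitivity" in t:
        lines.insert(-1, "SENSITIVITY (sample exclusion rerun)")
        lines.insert(-1, f"  excluded: {', '.join(t['sensitivity']['excluded'])}")
        lines.insert(-1, f"  top-term agreement: {t['sensitivity']['top_terms_agree']}")
        lines.insert(-1, "")
    (out / "report.txt").write_text("\n".join(lines))
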