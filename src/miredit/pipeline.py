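"""End-to-end synthetic study: simulate -> genotype -> fold -> discover -> quantify.

Runs the full analysis on simulated transgenic lines and produces a per-line
report table: genotype summary (mutated clones / total, mutation spectrum),
trace-deconvolution editing rate, impaired-processing tally over genotyped
precursors, relative miRNA and target-transcript abundance, and the variants
discovered from simulated sRNA reads.  All randomness flows from a single
top-level seed through named per-stage children; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotyping as gt
from .quantify import correlate, fit_curves, quantify
from .simulate import (
    EditProfile,
    PrecursorSpec,
    ReadSimConfig,
    SampleSpec,
    make_locus,
    simulate_amplicon_clones,
    simulate_edits,
    simulate_qpcr,
    simulate_sanger_trace,
    simulate_srna_reads,
)
from .simulate.qpcr import CurveSpec
from .structure import analyze_precursor
from .types import PremiRNALocus
from .variants import call_variants, preprocess, specificity_filter

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "n_loci": 2,
    "n_alleles": 4,
    "snp_rate": 0.01,
    "n_lines": 8,
    "clones_per_line": 10,
    "nt_clones": 12,
    "mosaicism": 3,
    "edit_probabilities": None,  # EditProfile defaults
    "depth": 10_000,
    "tailing_prob": 0.1,
    "impaired_leak": 0.0,
    "qpcr_noise_sd": 0.1,
    "trace_noise": 0.02,
}


@dataclass
class LineReport:
    line_id: str
    locus_id: str
    genotype: gt.LineGenotype
    editing_rate: float
    impaired: int
    n_genotyped: int
    mirna_rel_abundance: float | None = None
    target_rel_abundance: float | None = None
    variants: list = field(default_factory=list)
    processable_fraction_truth: float = 0.0


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage integer seed below 2^31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:12]


def project_pos(ops: list[gt.DiffOp], pos: int) -> int:
    """Map a reference coordinate through difference ops to clone coords."""
    shift = 0
    for op in ops:
        if op.kind == "ins" and op.pos <= pos:
            shift += op.length
        elif op.kind == "del":
            if op.pos + op.length <= pos:
                shift -= op.length
            elif op.pos <= pos:
                shift -= pos - op.pos
    return pos + shift


def edited_precursor(
    clone: str, ops: list[gt.DiffOp], locus: PremiRNALocus
) -> tuple[str, tuple[int, int]]:
    """Precursor subsequence of an edited clone and its mature span.

    Reference precursor and miR-5p spans are projected through the clone's
    difference operations; an excised precursor comes back empty or with a
    collapsed mature span.
    """
    p_lo, p_hi = locus.precursor_span
    m_lo, m_hi = locus.mir5p_amplicon_span()
    c_lo, c_hi = project_pos(ops, p_lo), project_pos(ops, p_hi)
    cm_lo, cm_hi = project_pos(ops, m_lo), project_pos(ops, m_hi)
    prec = clone[c_lo:c_hi]
    return prec, (cm_lo - c_lo, cm_hi - c_lo)


def _provenance(config: dict) -> str:
    return f"seed={config['seed']} config={_config_hash(config)} miredit=0.1.0"


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def run(config: dict | None = None, outdir: str | Path | None = None) -> list[LineReport]:
    """Run all stages in dependency order; see module docstring."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    _validate_config(cfg)
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    stage = "setup"
    try:
        return _run_stages(cfg, out, prov)
    except Exception as exc:
        if out:
            (out / "failure_manifest.json").write_text(
                json.dumps({"stage": stage, "error": str(exc)}, indent=2)
            )
        raise


class ConfigError(ValueError):
    pass


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("n_loci", "n_lines", "clones_per_line", "depth", "mosaicism"):
        if not isinstance(cfg[key], int) or cfg[key] < 1:
            raise ConfigError(f"{key} must be a positive integer")
    if not 0 <= cfg["snp_rate"] <= 0.05:
        raise ConfigError("snp_rate must be in [0, 0.05]")


def _run_stages(cfg: dict, out: Path | None, prov: str) -> list[LineReport]:
    master = cfg["seed"]

    # --- loci -------------------------------------------------------------
    loci = [
        make_locus(
            seed=_stage_seed(master, f"locus{k}"),
            n_alleles=cfg["n_alleles"],
            snp_rate=cfg["snp_rate"],
            locus_id=f"locus{k + 1}",
        )
        for k in range(cfg["n_loci"])
    ]

    # --- simulate lines (mosaic edit outcomes per line) --------------------
    lines: list[dict] = []
    probs = cfg["edit_probabilities"]
    for i in range(cfg["n_lines"]):
        locus = loci[i % len(loci)]
        profile = EditProfile(
            **({"probabilities": probs} if probs else {}),
            seed=_stage_seed(master, f"line{i}-edits"),
        )
        outcomes = simulate_edits(locus, profile, cfg["mosaicism"])
        prop = 1.0 / len(outcomes)
        lines.append(
            {
                "line_id": f"line{i + 1}",
                "locus": locus,
                "outcomes": outcomes,
                "truth": [(o.edited_seq, prop) for o in outcomes],
            }
        )

    # --- NT panels and genotyping ------------------------------------------
    nt_panels: dict[str, set] = {}
    nt_clone_store: dict[str, list[str]] = {}
    for locus in loci:
        nt_clones, _ = simulate_amplicon_clones(
            [(a, 1.0 / len(locus.allele_seqs)) for a in locus.allele_seqs],
            cfg["nt_clones"],
            seed=_stage_seed(master, f"{locus.locus_id}-nt"),
        )
        nt_clone_store[locus.locus_id] = nt_clones
        nt_panels[locus.locus_id] = gt.build_nt_panel(
            [
                gt.align_clone(c, locus, f"nt{i}", allele_index=0)
                for i, c in enumerate(nt_clones)
            ]
        )

    clone_rows = []
    reports: list[LineReport] = []
    mutated_precursors: dict[str, dict[str, tuple[str, tuple[int, int], bool]]] = {
        locus.locus_id: {} for locus in loci
    }
    for line in lines:
        locus: PremiRNALocus = line["locus"]
        clones, _idx = simulate_amplicon_clones(
            line["truth"],
            cfg["clones_per_line"],
            seed=_stage_seed(master, f"{line['line_id']}-clones"),
        )
        calls_per_clone = []
        impaired_n = 0
        for ci, clone in enumerate(clones):
            aln = gt.align_clone(clone, locus, f"{line['line_id']}.{ci}")
            ops = gt.mask_polymorphism(aln, nt_panels[locus.locus_id])
            calls = gt.classify_mutation(ops, locus.guides, locus)
            calls_per_clone.append(calls)
            prec, mspan = edited_precursor(clone, ops, locus)
            *_, pcall = analyze_precursor(prec, mspan)
            if pcall.impaired:
                impaired_n += 1
            if any(c.is_edit for c in calls):
                pid = f"{line['line_id']}-{locus.locus_id}-c{ci}"
                mutated_precursors[locus.locus_id][pid] = (
                    prec,
                    mspan,
                    pcall.impaired,
                )
            for call in calls:
                clone_rows.append(
                    {
                        "line": line["line_id"],
                        "locus": locus.locus_id,
                        "clone": aln.clone_id,
                        "best_allele": aln.best_allele_index + 1,
                        "type": call.type,
                        "span": f"{call.span[0]}-{call.span[1]}",
                        "inserted_base": call.inserted_base or "",
                        "distance_to_cut": call.distance_to_cut,
                        "overlaps_mir5p": call.overlaps_mir5p,
                        "precursor_impaired": pcall.impaired,
                        "impaired_reasons": ",".join(sorted(pcall.reasons)),
                    }
                )
        genotype = gt.summarize_line(line["line_id"], calls_per_clone)

        # trace deconvolution over a window downstream of the first cut
        c1, _c2 = locus.cut_positions
        trace = simulate_sanger_trace(
            line["truth"],
            (c1 - 20, c1 + 120),
            noise=cfg["trace_noise"],
            seed=_stage_seed(master, f"{line['line_id']}-trace"),
        )
        score = gt.ko_score(trace, locus)

        # processing truth for abundance simulation
        frac = 0.0
        for outcome, (_seq, p) in zip(line["outcomes"], line["truth"]):
            prec, mspan = _truth_precursor(outcome, locus)
            *_, pcall = analyze_precursor(prec, mspan)
            frac += p * (cfg["impaired_leak"] if pcall.impaired else 1.0)
        reports.append(
            LineReport(
                line_id=line["line_id"],
                locus_id=locus.locus_id,
                genotype=genotype,
                editing_rate=score.editing_rate,
                impaired=impaired_n,
                n_genotyped=len(clones),
                processable_fraction_truth=frac,
            )
        )

    # --- sRNA simulation and variant discovery -----------------------------
    read_cfg = ReadSimConfig(
        depth=cfg["depth"],
        tailing_prob=cfg["tailing_prob"],
        impaired_leak=cfg["impaired_leak"],
    )
    samples = _build_samples(cfg, loci, lines, reports)
    reads, _truth = simulate_srna_reads(
        samples, read_cfg, seed=_stage_seed(master, "srna")
    )
    reads_by_sample = {
        s.sample_id: preprocess(reads[s.sample_id], s.sample_id, read_cfg.adapter)
        for s in samples
    }
    precursors, canonical = _reference_sets(loci, mutated_precursors)
    all_variants = call_variants(reads_by_sample, precursors, canonical)

    groups: dict[str, set[str]] = {}
    for s in samples:
        groups.setdefault(s.group, set()).add(s.sample_id)
    for report in reports:
        test = groups.get(report.line_id, set())
        controls = [g for name, g in groups.items() if name != report.line_id]
        # only variants originating from the line's own (edited) locus count
        own = lambda src: src == f"{report.locus_id}-wt" or f"-{report.locus_id}-" in src
        report.variants = [
            v
            for v in specificity_filter(all_variants, test, controls)
            if v.var_class != "canonical" and any(own(s) for s in v.sources)
        ]

    # --- qPCR simulation and quantification --------------------------------
    abundance_truth: dict[str, dict[str, float]] = {}
    floor = 1e-3
    for k in range(3):  # NT baseline plants
        abundance_truth[f"NT{k + 1}"] = {
            "mir": 1.0,
            "target": 1.0,
            "control": 1.0,
        }
    for report in reports:
        f = max(report.processable_fraction_truth, floor)
        abundance_truth[report.line_id] = {
            "mir": f,
            "target": 1.6 - 0.6 * f,  # repression relief when miRNA drops
            "control": 1.0,
        }
    curve_specs = [
        CurveSpec("mir", noise_sd=cfg["qpcr_noise_sd"]),
        CurveSpec("target", slope=-3.45, intercept=30.0, noise_sd=cfg["qpcr_noise_sd"]),
        CurveSpec("control", slope=-3.35, intercept=28.0, noise_sd=cfg["qpcr_noise_sd"]),
    ]
    cq_table, series = simulate_qpcr(
        abundance_truth, curve_specs, seed=_stage_seed(master, "qpcr")
    )
    curves = fit_curves(series)
    quant = quantify(
        cq_table, curves, "control", {f"NT{k + 1}" for k in range(3)}
    )
    rel = {(a.sample_id, a.assay): a.relative_to_nt for a in quant.abundances}
    for report in reports:
        report.mirna_rel_abundance = rel.get((report.line_id, "mir"))
        report.target_rel_abundance = rel.get((report.line_id, "target"))

    # --- artifacts ----------------------------------------------------------
    if out:
        _write_tsv(pd.DataFrame(clone_rows), out / "clone_calls.tsv", prov)
        _write_tsv(_report_frame(reports), out / "line_reports.tsv", prov)
        _write_tsv(_variant_frame(reports), out / "variants.tsv", prov)
        _write_tsv(quant.to_frame(), out / "abundance.tsv", prov)
        corr = _correlations(reports)
        (out / "correlations.json").write_text(json.dumps(corr, indent=2))
    return reports


def _truth_precursor(outcome, locus: PremiRNALocus) -> tuple[str, tuple[int, int]]:
    """Edited precursor straight from simulator ground truth."""
    call = outcome.call
    if call.type == "none":
        lo, hi = locus.precursor_span
        src = locus.allele_seqs[outcome.allele_index]
        return src[lo:hi], locus.mir5p_span
    if call.type == "insertion":
        op = gt.DiffOp("ins", call.span[0], 1, alt=call.inserted_base)
    else:
        op = gt.DiffOp(
            "del", call.span[0], call.span[1] - call.span[0]
        )
    src = locus.allele_seqs[outcome.allele_index]
    clone = gt.apply_ops(src, [op])
    return edited_precursor(clone, [op], locus)


def _build_samples(cfg, loci, lines, reports) -> list[SampleSpec]:
    wt_specs = [
        PrecursorSpec(
            precursor_id=f"{locus.locus_id}-wt",
            sequence=locus.precursor_seq,
            mature_span=locus.mir5p_span,
            impaired=False,
        )
        for locus in loci
    ]
    samples = [
        SampleSpec(sample_id=f"NT{k + 1}", group="NT", precursors=tuple(wt_specs))
        for k in range(3)
    ]
    for line, report in zip(lines, reports):
        locus = line["locus"]
        specs = [s for s in wt_specs if s.precursor_id != f"{locus.locus_id}-wt"]
        for j, outcome in enumerate(line["outcomes"]):
            prec, mspan = _truth_precursor(outcome, locus)
            if mspan[1] - mspan[0] < 18 or not prec:
                continue  # excised: contributes no reads at all
            *_, pcall = analyze_precursor(prec, mspan)
            specs.append(
                PrecursorSpec(
                    precursor_id=f"{line['line_id']}-{locus.locus_id}-o{j}",
                    sequence=prec,
                    mature_span=mspan,
                    impaired=pcall.impaired,
                    weight=line["truth"][j][1],
                )
            )
        samples.append(
            SampleSpec(
                sample_id=f"{line['line_id']}-s1",
                group=line["line_id"],
                precursors=tuple(specs),
            )
        )
    return samples


def _reference_sets(loci, mutated_precursors):
    precursors: dict[str, str] = {}
    canonical: dict[str, tuple[int, int]] = {}
    for locus in loci:
        precursors[f"{locus.locus_id}-wt"] = locus.precursor_seq
        canonical[f"{locus.locus_id}-wt"] = locus.mir5p_span
        for pid, (prec, mspan, _imp) in mutated_precursors[locus.locus_id].items():
            if prec and mspan[1] - mspan[0] >= 10:
                precursors[pid] = prec
                canonical[pid] = mspan
    return precursors, canonical


def _report_frame(reports: list[LineReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "line": r.line_id,
                "locus": r.locus_id,
                "genotyped": f"{r.genotype.n_mutated}/{r.genotype.n_clones}",
                "mutated_fraction": r.genotype.mutated_fraction,
                "spectrum": ";".join(
                    f"{k}:{v}" for k, v in sorted(r.genotype.spectrum.items())
                ),
                "all_alleles_mutated": r.genotype.all_alleles_mutated,
                "knockout_score": round(r.editing_rate, 4),
                "impaired_processing": f"{r.impaired}/{r.n_genotyped}",
                "mirna_rel_abundance": r.mirna_rel_abundance,
                "target_rel_abundance": r.target_rel_abundance,
                "n_line_specific_variants": len(r.variants),
            }
            for r in reports
        ]
    )


def _variant_frame(reports: list[LineReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for v in r.variants:
            rows.append(
                {
                    "line": r.line_id,
                    "sequence": v.sequence,
                    "class": v.var_class,
                    "sources": ";".join(v.sources),
                    "unambiguous": v.unambiguous,
                    "offset5": v.offset5,
                    "offset3": v.offset3,
                    "tail": v.tail,
                    "tail_end": v.tail_end,
                    "total_count": sum(v.counts.values()),
                    "low_abundance": v.low_abundance,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "line", "sequence", "class", "sources", "unambiguous",
            "offset5", "offset3", "tail", "tail_end", "total_count",
            "low_abundance",
        ],
    )


def _correlations(reports: list[LineReport]) -> dict:
    """Impaired-allele count vs miRNA abundance; miRNA vs target abundance."""
    usable = [
        r
        for r in reports
        if r.mirna_rel_abundance is not None and r.target_rel_abundance is not None
    ]
    out: dict = {"n_lines": len(usable)}
    if len(usable) >= 3:
        impaired = [r.impaired / r.n_genotyped for r in usable]
        mir = [r.mirna_rel_abundance for r in usable]
        tgt = [r.target_rel_abundance for r in usable]
        out["impaired_vs_mirna"] = correlate(impaired, mir)
        out["mirna_vs_target"] = correlate(mir, tgt)
    return out
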