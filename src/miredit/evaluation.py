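"""Self-contained benchmark measurements over synthetic ground truth.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage and measures performance against the simulator's truth tables.  Used by
the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from . import genotyping as gt
from .fold import brute_force_mfe, fold
from .pipeline import _truth_precursor, run
from .quantify import correlate
from .simulate import (
    EditProfile,
    PrecursorSpec,
    ReadSimConfig,
    SampleSpec,
    make_locus,
    simulate_amplicon_clones,
    simulate_edits,
    simulate_sanger_trace,
    simulate_srna_reads,
)
from .structure import analyze_precursor
from .variants import call_variants, preprocess, specificity_filter


def folding_oracle_agreement(n_seqs: int = 200, max_len: int = 14, seed: int = 0):
    """Fraction of random short sequences where DP MFE == exhaustive minimum."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_seqs):
        length = int(rng.integers(10, max_len + 1))
        seq = "".join(rng.choice(list("ACGU"), length))
        _, best = brute_force_mfe(seq)
        if abs(fold(seq).mfe_kcal_mol - best) < 1e-9:
            agree += 1
    return agree, n_seqs


EDIT_CLASS_TO_CALL = {
    "short_deletion": "short_deletion",
    "insertion_T": "insertion",
    "insertion_G": "insertion",
    "inter_guide_excision": "inter_guide_excision",
    "large_deletion": "large_deletion",
}


def genotyping_recovery(n_per_class: int = 1000, seed: int = 0):
    """Per-class classification accuracy on simulated single-edit clones."""
    locus = make_locus(seed=seed + 1, n_alleles=4, snp_rate=0.01)
    nt_clones, _ = simulate_amplicon_clones(
        [(a, 0.25) for a in locus.allele_seqs], 24, seed=seed + 2
    )
    panel = gt.build_nt_panel(
        [gt.align_clone(c, locus, allele_index=0) for c in nt_clones]
    )
    accuracy: dict[str, float] = {}
    for cls in ("short_deletion", "insertion_T", "inter_guide_excision",
                "large_deletion"):
        profile = EditProfile(probabilities={cls: 1.0}, seed=seed + 10)
        edits = simulate_edits(locus, profile, n_per_class)
        correct = 0
        for e in edits:
            aln = gt.align_clone(e.edited_seq, locus)
            ops = gt.mask_polymorphism(aln, panel)
            calls = gt.classify_mutation(ops, locus.guides, locus)
            types = [c.type for c in calls if c.is_edit]
            if types == [e.call.type]:
                correct += 1
        accuracy[cls] = correct / n_per_class
    return accuracy


def snp_false_edit_calls(n_clones: int = 1000, seed: int = 0) -> int:
    """Edit calls produced by natural SNPs alone (should be zero)."""
    locus = make_locus(seed=seed + 1, n_alleles=4, snp_rate=0.01)
    nt_clones, _ = simulate_amplicon_clones(
        [(a, 0.25) for a in locus.allele_seqs], 24, seed=seed + 2
    )
    panel = gt.build_nt_panel(
        [gt.align_clone(c, locus, allele_index=0) for c in nt_clones]
    )
    clones, _ = simulate_amplicon_clones(
        [(a, 0.25) for a in locus.allele_seqs], n_clones, seed=seed + 3
    )
    false_calls = 0
    for clone in clones:
        aln = gt.align_clone(clone, locus)
        ops = gt.mask_polymorphism(aln, panel)
        calls = gt.classify_mutation(ops, locus.guides, locus)
        false_calls += sum(1 for c in calls if c.is_edit)
    return false_calls


def ko_mixture_grid(noise: float = 0.02, seed: int = 0):
    """Worst-case recovery error of trace deconvolution over a proportion grid.

    Traces are built from known mixtures of the wild type with deletions,
    an insertion and the inter-guide excision; recovered indel-signature
    spectra are compared to truth.  Returns (max L-inf over the grid,
    max |editing-rate error|).
    """
    locus = make_locus(seed=seed + 1, n_alleles=4, snp_rate=0.01)
    c1, c2 = locus.cut_positions
    ref = locus.allele_seqs[0]
    window = (c1 - 20, c1 + 120)
    components = {
        "wt": (ref, "wt"),
        "del2": (ref[: c1 - 1] + ref[c1 + 1 :], "del2"),
        "del5": (ref[: c2 - 2] + ref[c2 + 3 :], "del5"),
        "ins1": (ref[:c1] + "T" + ref[c1:], "ins1"),
        "exc": (ref[:c1] + ref[c2:], f"del{c2 - c1}"),
    }
    max_linf = 0.0
    max_rate_err = 0.0
    for k, wt_prop in enumerate((0.0, 0.2, 0.5, 0.7, 0.9, 1.0)):
        rest = 1.0 - wt_prop
        mixture = [
            (components["wt"][0], wt_prop),
            (components["del2"][0], rest * 0.4),
            (components["del5"][0], rest * 0.3),
            (components["ins1"][0], rest * 0.2),
            (components["exc"][0], rest * 0.1),
        ]
        truth = {
            "wt": wt_prop,
            "del2": rest * 0.4,
            "del5": rest * 0.3,
            "ins1": rest * 0.2,
            components["exc"][1]: rest * 0.1,
        }
        trace = simulate_sanger_trace(mixture, window, noise=noise, seed=seed + 20 + k)
        score = gt.ko_score(trace, locus)
        spectrum = dict(score.signature_spectrum)
        spectrum["wt"] = 1.0 - score.editing_rate
        keys = set(truth) | set(spectrum)
        linf = max(abs(truth.get(s, 0.0) - spectrum.get(s, 0.0)) for s in keys)
        max_linf = max(max_linf, linf)
        max_rate_err = max(max_rate_err, abs(score.editing_rate - (1.0 - wt_prop)))
    return max_linf, max_rate_err


def variant_discovery_metrics(depth: int = 100_000, tailing: float = 0.1,
                              seed: int = 0):
    """Count-weighted precision/recall of variant discovery vs simulator truth.

    One test line carrying processable mutated precursors, two NT samples and
    one reciprocal-locus line serve as controls; the exclusion guarantee is
    verified exactly (returned as the number of control-sample leaks among
    reported line-specific variants).
    """
    locus_a = make_locus(seed=seed + 1, n_alleles=4, snp_rate=0.01, locus_id="locA")
    locus_b = make_locus(seed=seed + 2, n_alleles=4, snp_rate=0.01, locus_id="locB")

    profile = EditProfile(
        probabilities={"short_deletion": 0.5, "insertion_T": 0.5}, seed=seed + 3
    )
    precursors = {
        "locA-wt": locus_a.precursor_seq,
        "locB-wt": locus_b.precursor_seq,
    }
    canonical = {"locA-wt": locus_a.mir5p_span, "locB-wt": locus_b.mir5p_span}

    def line_specs(locus, edits, prefix):
        specs = []
        for j, e in enumerate(edits):
            prec, mspan = _truth_precursor(e, locus)
            if mspan[1] - mspan[0] < 18:
                continue
            *_, pcall = analyze_precursor(prec, mspan)
            pid = f"{prefix}-o{j}"
            precursors[pid] = prec
            canonical[pid] = mspan
            specs.append(
                PrecursorSpec(pid, prec, mspan, impaired=pcall.impaired,
                              weight=1.0 / len(edits))
            )
        return specs

    edits_a = simulate_edits(locus_a, profile, 3)
    edits_b = simulate_edits(
        locus_b,
        EditProfile(probabilities={"short_deletion": 1.0}, seed=seed + 4),
        3,
    )
    wt_a = PrecursorSpec("locA-wt", locus_a.precursor_seq, locus_a.mir5p_span)
    wt_b = PrecursorSpec("locB-wt", locus_b.precursor_seq, locus_b.mir5p_span)
    samples = [
        SampleSpec("NT1", "NT", (wt_a, wt_b)),
        SampleSpec("NT2", "NT", (wt_a, wt_b)),
        SampleSpec("lineA-s1", "lineA",
                   tuple(line_specs(locus_a, edits_a, "lineA-locA")) + (wt_b,)),
        SampleSpec("lineB-s1", "lineB",
                   tuple(line_specs(locus_b, edits_b, "lineB-locB")) + (wt_a,)),
    ]
    cfg = ReadSimConfig(depth=depth, tailing_prob=tailing)
    reads, truth = simulate_srna_reads(samples, cfg, seed=seed + 5)

    reads_by_sample = {
        s.sample_id: preprocess(reads[s.sample_id], s.sample_id, cfg.adapter)
        for s in samples
    }
    variants = call_variants(reads_by_sample, precursors, canonical)

    # count-weighted precision / recall per sample, pooled
    tp = fp = fn = 0
    for sample in reads_by_sample:
        truth_counts = dict(
            truth.loc[truth["sample"] == sample, ["variant", "count"]].itertuples(
                index=False, name=None
            )
        )
        discovered = {
            v.sequence: v.counts[sample] for v in variants if v.counts.get(sample)
        }
        for seq, count in discovered.items():
            if seq in truth_counts:
                tp += count
            else:
                fp += count
        for seq, count in truth_counts.items():
            if seq not in discovered:
                fn += count
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)

    groups = {"NT": {"NT1", "NT2"}, "lineA": {"lineA-s1"}, "lineB": {"lineB-s1"}}
    reported = specificity_filter(
        variants, groups["lineA"], [groups["NT"], groups["lineB"]]
    )
    leaks = sum(
        1
        for v in reported
        for s in groups["NT"] | groups["lineB"]
        if v.counts.get(s, 0) > 0
    )
    return precision, recall, leaks


def pipeline_correlations(seed: int = 1, n_lines: int = 8, depth: int = 1000):
    """Rank correlations across simulated lines: impairment vs abundance."""
    reports = run({"seed": seed, "n_lines": n_lines, "depth": depth})
    usable = [r for r in reports if r.mirna_rel_abundance is not None]
    impaired = [r.impaired / r.n_genotyped for r in usable]
    mir = [r.mirna_rel_abundance for r in usable]
    tgt = [r.target_rel_abundance for r in usable]
    return (
        correlate(impaired, mir)["spearman"],
        correlate(mir, tgt)["spearman"],
        len(usable),
    )


def mfei_threshold_value() -> float:
    """(|-45.9| / 108 * 100) / 50 — the hand-checkable MFEI arithmetic."""
    from .fold import FoldResult
    from .structure import mfei

    seq = ("GC" + "AT") * 27  # 108 nt, 50% GC
    return mfei(FoldResult(seq.replace("T", "U"), "." * 108, -45.9)).mfei


def efficiency_percent(slope: float = -3.3219) -> float:
    """Amplification efficiency (%) from a standard-curve slope."""
    from .quantify import StandardCurve

    return StandardCurve("a", slope, 35.0, 1.0).efficiency * 100.0
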