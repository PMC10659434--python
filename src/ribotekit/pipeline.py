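"""One-command reproducible run: simulate -> analyse -> report.

``run`` drives the whole desk-scale study: it generates a synthetic
transcriptome and count data, tests differential TE across the four
genotype x treatment contrasts, classifies conditional-dependence
genes, quantifies uORF occupancy and its changes, computes tripeptide
pause scores, estimates polysome-gradient TEs, and writes a directory
of inputs, result tables, figures and a machine-readable summary.
Identical config + seed gives identical tables and summary JSON.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pause as pause_mod
from . import plots
from .annotation import write_annotation, write_counts, write_wiggle
from .polysome import estimate_te_table, delta_te_with_sem, pm_ratio
from .simulate import (
    CONDITIONS,
    GradientSimConfig,
    SimConfig,
    generate_transcriptome,
    simulate_counts,
    simulate_gradient,
    simulate_tracks,
)
from .te import classify_conditional_dependence, correlate_delta_te, delta_te_test
from .uorf import (
    compute_rro,
    delta_rro_test,
    enrichment_test,
    filter_uorfs,
    subset_by_fold,
    summarize_uorf_classes,
    venn_counts,
)

__all__ = ["RunConfig", "PipelineError", "run", "paper_analog_config"]

WT_U = ("WT", "untreated")
WT_T = ("WT", "treated")
MUT_U = ("mutant", "untreated")
MUT_T = ("mutant", "treated")

#: the four contrasts of the conditional-dependence analysis, in the
#: order the classifier expects
CONTRASTS: dict[str, tuple] = {
    "mutT_vs_WTT": (MUT_T, WT_T),
    "mutT_vs_mut": (MUT_T, MUT_U),
    "WTT_vs_WT": (WT_T, WT_U),
    "mut_vs_WT": (MUT_U, WT_U),
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and partial-output list."""

    def __init__(self, stage: str, cause: BaseException, outputs: list[str]):
        self.stage = stage
        self.outputs = outputs
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Everything one run needs; defaults are the study's constants
    (FDR 0.25/0.01 for TE, 0.5 for RRO, 1.41-fold, 18-nt offset, ±50 nt
    window, 100-occurrence motif floor, uORF/CDS count filters 2/32)."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    gradient: GradientSimConfig = field(default_factory=GradientSimConfig)
    fdr_te: float = 0.25
    fdr_te_strict: float = 0.01
    fdr_rro: float = 0.5
    fold: float = 1.41
    offset_nt: int = 18
    window_nt: int = 50
    min_occurrence: int = 100
    min_uorf_mean: float = 2.0
    min_cds_mean: float = 32.0
    t_down: float = 0.5
    t_tol: float = 0.25
    sf_method: str = "total-count"
    make_tracks: bool = True
    make_figures: bool = True
    polysome_targets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # one seed governs every stage
        self.sim.seed = self.seed
        self.gradient.seed = self.seed

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = SimConfig(**_tuplify(data.pop("sim", {})))
        gradient = GradientSimConfig(**_tuplify(data.pop("gradient", {})))
        return cls(sim=sim, gradient=gradient, **data)


def _tuplify(d: dict) -> dict:
    """YAML has no tuples; effect maps arrive keyed by 'genotype:treatment'."""
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        elif k in ("te_effects", "rro_effects") and isinstance(v, dict):
            out[k] = {
                g: {tuple(c.split(":")): float(x) for c, x in m.items()}
                for g, m in v.items()
            }
        else:
            out[k] = v
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def paper_analog_config(seed: int = 0, n_genes: int = 2000) -> RunConfig:
    """The full study-analog scenario: one GCN4-like ~40-fold TE
    induction under treatment, CPA1/CAD1-like 2.0- and 2.6-fold
    inductions, twenty genes losing TE only under the double
    perturbation, and valine A-site pausing under treatment."""
    cfg = RunConfig(seed=seed)
    cfg.sim.n_genes = n_genes
    n = cfg.sim.n_genes
    width = len(str(n))
    gid = lambda i: f"g{i:0{width}d}"
    te_effects: dict = {}
    # GCN4 analog: strong treatment induction in both genotypes
    te_effects[gid(0)] = {WT_T: float(np.log2(40.0)), MUT_T: float(np.log2(40.0))}
    # CPA1/CAD1 analogs: ~2-fold and 2.6-fold induction by treatment
    te_effects[gid(1)] = {WT_T: 1.0, MUT_T: 1.0}
    te_effects[gid(2)] = {WT_T: float(np.log2(2.6)), MUT_T: float(np.log2(2.6))}
    # conditional genes: TE loss only when mutation and treatment combine
    conditional = [gid(i) for i in range(10, 30)]
    for g in conditional:
        te_effects[g] = {MUT_T: -1.5}
    cfg.sim.te_effects = te_effects
    # starvation slows decoding of every Val codon: all motifs with
    # Val in the A site dwell longer
    from .annotation import AA_ALPHABET

    cfg.sim.dwell_factors = {
        f"{a}{b}V": 3.0 for a in AA_ALPHABET for b in AA_ALPHABET
    }
    cfg.sim.dwell_conditions = (WT_T,)
    cfg.polysome_targets = {
        "HKR1like": {WT_U: 3.0, WT_T: 2.4, MUT_U: 3.0, MUT_T: 1.2},
        "ACT1like": {c: 4.0 for c in CONDITIONS},
    }
    return cfg


def run(config: RunConfig, outdir) -> dict:
    """Execute the full pipeline into ``outdir``; returns the summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    log: list[dict] = []

    def emit(path: Path) -> None:
        written.append(str(path.relative_to(out)))

    def stage(name):
        def deco(fn):
            def wrapper():
                try:
                    result = fn()
                except Exception as exc:  # noqa: BLE001 - rethrown with stage name
                    manifest = out / "partial_outputs.json"
                    manifest.write_text(json.dumps(written, indent=1))
                    raise PipelineError(name, exc, written) from exc
                log.append({"stage": name, "outputs": list(written)})
                return result
            return wrapper
        return deco

    summary: dict = {"seed": config.seed}

    @stage("simulate")
    def _sim():
        tx = generate_transcriptome(config.sim)
        sim = simulate_counts(tx, config.sim)
        write_annotation(tx, out / "annotation.gff3")
        emit(out / "annotation.gff3")
        write_counts(sim.rpf, out / "rpf_counts.tsv", out / "samples_rpf.tsv")
        write_counts(sim.rna, out / "rna_counts.tsv", out / "samples_rna.tsv")
        write_counts(sim.uorf_rpf, out / "uorf_rpf_counts.tsv")
        for p in ("rpf_counts.tsv", "samples_rpf.tsv", "rna_counts.tsv",
                  "samples_rna.tsv", "uorf_rpf_counts.tsv"):
            emit(out / p)
        (out / "sim_truth.json").write_text(
            json.dumps(sim.truth.to_json_dict(), sort_keys=True)
        )
        emit(out / "sim_truth.json")
        return tx, sim

    tx, sim = _sim()

    @stage("te")
    def _te():
        results = {}
        for name, contrast in CONTRASTS.items():
            res = delta_te_test(sim.rpf, sim.rna, contrast,
                                sf_method=config.sf_method)
            res.table.to_csv(out / f"te_{name}.tsv", sep="\t")
            emit(out / f"te_{name}.tsv")
            results[name] = res
        delta = pd.DataFrame(
            {name: res.table["log2fc"] for name, res in results.items()}
        ).dropna()
        # the conditional-dependence pattern is read within the set of
        # genes with significant TE reductions in the double-vs-single
        # perturbation contrast, as in the study's 32-gene set
        sig_down = results["mutT_vs_WTT"].discoveries(config.fdr_te, "down")
        labels = classify_conditional_dependence(
            delta.loc[delta.index.intersection(sig_down)],
            t_down=config.t_down, t_tol=config.t_tol,
        )
        labels.labels.to_frame().to_csv(out / "conditional_labels.tsv", sep="\t")
        emit(out / "conditional_labels.tsv")
        r, p = correlate_delta_te(results["WTT_vs_WT"], results["mutT_vs_mut"])
        summary["te"] = {
            name: {
                "tested": int(res.table.shape[0]),
                f"q<{config.fdr_te:g}": int(len(res.discoveries(config.fdr_te))),
                f"q<{config.fdr_te_strict:g}": int(
                    len(res.discoveries(config.fdr_te_strict))
                ),
            }
            for name, res in results.items()
        }
        summary["te"]["treatment_response_correlation"] = {"r": r, "p": p}
        summary["te"]["conditional_genes"] = sorted(labels.conditional_genes)
        return results, delta, labels

    te_results, delta, labels = _te()

    @stage("uorf")
    def _uorf():
        if sim.uorf_rpf.counts.shape[0] == 0:
            summary["uorf"] = {"n_uorfs": 0}
            return None
        eligibility = filter_uorfs(sim.uorf_rpf, sim.rpf,
                                   config.min_uorf_mean, config.min_cds_mean)
        eligibility.to_csv(out / "uorf_eligibility.tsv", sep="\t")
        emit(out / "uorf_eligibility.tsv")
        rro = compute_rro(sim.uorf_rpf, sim.rpf, eligibility)
        rro.to_csv(out / "uorf_rro.tsv", sep="\t")
        emit(out / "uorf_rro.tsv")
        rro_test = delta_rro_test(sim.uorf_rpf, sim.rpf, (MUT_T, WT_T),
                                  config.min_uorf_mean, config.min_cds_mean)
        rro_test.table.to_csv(out / "rro_mutT_vs_WTT.tsv", sep="\t")
        emit(out / "rro_mutT_vs_WTT.tsv")
        class_summary = summarize_uorf_classes(te_results["WTT_vs_WT"], tx)
        class_summary.to_csv(out / "uorf_class_summary.tsv", sep="\t",
                             index=False)
        emit(out / "uorf_class_summary.tsv")

        universe = set(te_results["mutT_vs_WTT"].table.index)
        hits = set(labels.conditional_genes) & universe
        functional = {
            t.id for t in tx
            if any(u.source == "functional" for u in t.uorfs)
        } & universe
        p_enrich = enrichment_test(hits, functional, universe)
        venn = venn_counts(hits, functional)
        (out / "venn_counts.json").write_text(json.dumps(venn, sort_keys=True))
        emit(out / "venn_counts.json")
        induced = subset_by_fold(te_results["WTT_vs_WT"], config.fold, "up")
        summary["uorf"] = {
            "n_uorfs": int(sim.uorf_rpf.counts.shape[0]),
            "n_eligible": int(eligibility["eligible"].sum()),
            f"rro_q<{config.fdr_rro:g}": int(
                len(rro_test.discoveries(config.fdr_rro))
            ),
            "enrichment_p": p_enrich,
            "venn": venn,
            f"induced>{config.fold:g}x": len(induced),
        }
        return rro_test

    _uorf()

    @stage("pause")
    def _pause():
        if not config.make_tracks:
            summary["pause"] = {"skipped": True}
            return None
        tables = {}
        for cond, tag in ((WT_U, "WT_untr"), (WT_T, "WT_SM")):
            reads = sim.rpf.counts[sim.rpf.columns_for(cond)].sum(axis=1)
            tracks, _truth = simulate_tracks(tx, config.sim, cond, reads,
                                             config.offset_nt)
            write_wiggle(list(tracks.values()), out / f"occupancy_{tag}.wig")
            emit(out / f"occupancy_{tag}.wig")
            profiles = [
                pause_mod.assign_codon_occupancy(tracks[t.id], t,
                                                 config.offset_nt)
                for t in tx
            ]
            tables[tag] = pause_mod.motif_pause_table(
                profiles, tx, config.window_nt, config.min_occurrence
            )
            tables[tag].to_csv(out / f"pause_{tag}.tsv", sep="\t")
            emit(out / f"pause_{tag}.tsv")
        cmp = pause_mod.compare_pause_tables(tables["WT_untr"],
                                             tables["WT_SM"], "V")
        summary["pause"] = {
            "n_motifs": int(cmp["pairs"].shape[0]),
            "n_val_a_site": cmp["n_group"],
            "val_group_median_ratio": cmp["group_median_ratio"],
            "other_median_ratio": cmp["other_median_ratio"],
            "mannwhitney_p": cmp["mannwhitney_p"],
        }
        return cmp

    pause_cmp = _pause()

    @stage("polysome")
    def _poly():
        if not config.polysome_targets:
            summary["polysome"] = {"skipped": True}
            return None
        gradients = simulate_gradient(config.polysome_targets, config.gradient)
        te_table = estimate_te_table(gradients)
        te_table.to_csv(out / "polysome_te.tsv", sep="\t")
        emit(out / "polysome_te.tsv")
        g0 = gradients[0].fractions
        mono = float(g0.loc[g0["multiplier"] == 1, "a260_area"].sum())
        poly = float(g0.loc[g0["multiplier"] >= 2, "a260_area"].sum())
        summary["polysome"] = {
            "pm_ratio_first_gradient": pm_ratio(mono, poly),
            "delta_te": {},
        }
        for target in sorted(config.polysome_targets):
            d = delta_te_with_sem(te_table, target)
            d.to_csv(out / f"polysome_delta_te_{target}.tsv", sep="\t")
            emit(out / f"polysome_delta_te_{target}.tsv")
            summary["polysome"]["delta_te"][target] = {
                g: {"mean_ratio": float(row["mean_ratio"]),
                    "sem": float(row["sem"])}
                for g, row in d.iterrows()
            }
        return te_table

    _poly()

    @stage("figures")
    def _figs():
        if not config.make_figures:
            return None
        plots.volcano(te_results["mutT_vs_WTT"].table, config.fdr_te,
                      out / "volcano_mutT_vs_WTT.png",
                      "mutant+SM vs WT+SM")
        emit(out / "volcano_mutT_vs_WTT.png")
        plots.notched_box(
            {name: res.table["log2fc"].to_numpy()
             for name, res in te_results.items()},
            out / "boxplot_contrasts.png",
        )
        emit(out / "boxplot_contrasts.png")
        sig = delta.index[
            (te_results["mutT_vs_WTT"].table["qvalue"] < config.fdr_te)
            .reindex(delta.index).fillna(False)
        ]
        if len(sig) >= 3:
            order = classify_conditional_dependence(
                delta.loc[sig], config.t_down, config.t_tol
            ).cluster_order
            plots.delta_heatmap(delta.loc[sig], order, out / "heatmap.png")
            emit(out / "heatmap.png")
        if pause_cmp is not None:
            pairs = pause_cmp["pairs"]
            plots.pause_scatter(
                pairs, pairs.index.str.endswith("V"),
                out / "pause_scatter.png", ("WT", "WT+SM"),
            )
            emit(out / "pause_scatter.png")
        return None

    _figs()

    @stage("summary")
    def _summary():
        for rel in sorted(written):
            p = out / rel
            if p.suffix in (".tsv", ".gff3", ".wig", ".json"):
                log.append({"file": rel, "sha256_16": _checksum(p)})
        (out / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=1, default=float)
        )
        (out / "run_log.json").write_text(
            json.dumps(log, sort_keys=True, indent=1)
        )
        return None

    _summary()
    return summary
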