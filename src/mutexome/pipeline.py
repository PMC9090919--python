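"""End-to-end orchestration of the synthetic analysis chain.

Stages (synth -> mutex -> er -> signatures -> mirna -> regulome) communicate
through plain files in the output directory; a run writes per-stage TSV/JSON
outputs, a summary JSON with the headline quantities, and a manifest listing
every output with its sha256 checksum. A run is deterministic given
(config, seed); a failing stage is recorded and does not corrupt the outputs
of completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from . import mirna as mmirna
from . import mutex_stats as mstats
from . import regulome as mreg
from . import signatures as msig
from . import synth as msynth
from .containers import SignatureSet
from .expression import calibrate_er_cutoff, predict_er_status

logger = logging.getLogger(__name__)

ALL_STAGES = ("synth", "mutex", "er", "signatures", "mirna", "regulome")


@dataclass
class RunConfig:
    """Pipeline configuration; thresholds default to the published values."""

    synth: msynth.SynthConfig = field(default_factory=msynth.SynthConfig)
    stages: tuple[str, ...] = ALL_STAGES
    fdr: float = 0.01
    window: int = 100_000
    min_targets: int = 1000
    er_grid_step: float = 0.1
    alpha: float = 0.05
    n_random_sets: int = 100
    # synthetic regulome scale
    n_peaks: int = 800
    peak_overlap: float = 0.25
    n_chroms: int = 8
    chrom_length: int = 80_000_000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = mio.read_yaml(path)
        synth_cfg = msynth.SynthConfig(**raw.pop("synth", {}))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(synth=synth_cfg, **raw)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return float(f"{obj:.{ndigits}g}")  # significant digits: keeps tiny p-values
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run the enabled stages, returning (and writing) the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.synth.seed, "stages": list(cfg.stages)}
    errors: dict[str, str] = {}
    scfg = cfg.synth

    # ---- synth ------------------------------------------------------------
    genotypes = expr1 = expr2 = planted = universe = None
    mirna_out = reg_out = None
    if "synth" in cfg.stages:
        genotypes = msynth.gen_genotypes(scfg)
        expr1, planted = msynth.gen_expression(scfg, genotypes)
        scfg2 = dataclasses.replace(scfg, seed=scfg.seed + 1_000_003)
        genotypes2 = msynth.gen_genotypes(scfg2, cohort="synthetic2")
        expr2, _ = msynth.gen_expression(scfg2, genotypes2)
        universe = msynth.universe_signature(scfg)
        mio.write_genotypes(genotypes, out / "genotypes.tsv")
        mio.write_matrix(expr1, out / "expression_cohort1.tsv")
        mio.write_gmt(
            {planted.name: list(planted.members), universe.name: list(universe.members)},
            out / "planted_sets.gmt",
        )

    # ---- mutual exclusivity ------------------------------------------------
    if "mutex" in cfg.stages and genotypes is not None:
        try:
            global_res = mstats.evaluate_contingency(
                mstats.build_contingency(genotypes), alpha=cfg.alpha
            )
            strata = {}
            for col in ("histology", "met_site", "TP53_class"):
                for level in sorted(genotypes[col].astype(str).unique()):
                    if not level:
                        continue
                    strata[f"{col}={level}"] = (
                        lambda df, c=col, v=level: df[c].astype(str) == v
                    )
            results = mstats.stratified_screen(genotypes, strata, alpha=cfg.alpha)
            mstats.results_to_frame([global_res, *results]).to_csv(
                out / "mutex_strata.tsv", sep="\t", index=False
            )
            r_size, p_size, flag_size = mstats.size_significance_correlation(results)
            enrich, enrich_flag = mstats.dual_mutant_enrichment(genotypes, "met_site")
            if not enrich_flag:
                enrich.to_csv(out / "dual_mutant_enrichment.tsv", sep="\t", index=False)
            vaf = mstats.compare_vaf(genotypes)
            summary["mutex"] = {
                "counts": dict(zip("abcd", global_res.counts())),
                "odds_ratio": global_res.odds_ratio,
                "ci_low": global_res.ci_low,
                "ci_high": global_res.ci_high,
                "p": global_res.p,
                "size_significance_r": r_size,
                "size_significance_flag": flag_size or None,
                "vaf_p": vaf.p,
                "vaf_median_esr1_wt": vaf.median_esr1_wt,
                "vaf_median_esr1_mut": vaf.median_esr1_mut,
            }
        except Exception as exc:  # stage isolation
            errors["mutex"] = repr(exc)
            logger.exception("mutex stage failed")

    # ---- ER calibration ----------------------------------------------------
    if "er" in cfg.stages:
        try:
            ref_vals, ref_labels = msynth.gen_er_cohort(scfg, 1000)
            target_cfg = dataclasses.replace(scfg, seed=scfg.seed + 2_000_003)
            target_vals, _ = msynth.gen_er_cohort(target_cfg, 500)
            cal = calibrate_er_cutoff(ref_vals, ref_labels, target_vals, step=cfg.er_grid_step)
            cal.table.to_csv(out / "er_calibration.tsv", sep="\t", index=False)
            n_pos = int((predict_er_status(target_vals, cal.chosen_cutoff) == "pos").sum())
            summary["er"] = {
                "chosen_cutoff": cal.chosen_cutoff,
                "concordance": cal.concordance,
                "n_target_positive": n_pos,
                "n_reference": cal.n_reference,
            }
        except Exception as exc:
            errors["er"] = repr(exc)
            logger.exception("er stage failed")

    # ---- signatures ----------------------------------------------------------
    tp53_er = None
    if "signatures" in cfg.stages and expr1 is not None:
        try:
            labels1 = (genotypes["TP53_status"] == "Mut").tolist()
            scfg2 = dataclasses.replace(scfg, seed=scfg.seed + 1_000_003)
            genotypes2 = msynth.gen_genotypes(scfg2, cohort="synthetic2")
            labels2 = (genotypes2["TP53_status"] == "Mut").tolist()
            res1 = msig.de_screen(expr1, labels1, universe, fdr=cfg.fdr)
            res2 = msig.de_screen(expr2, labels2, universe, fdr=cfg.fdr)
            tp53_er, non_tp53_er = msig.derive_signatures(
                res1, res2, universe, ("synthetic", "synthetic2"), fdr=cfg.fdr
            )
            mio.write_gmt(
                {tp53_er.name: list(tp53_er.members),
                 non_tp53_er.name: list(non_tp53_er.members)},
                out / "derived_signatures.gmt",
            )
            scores = msig.gsva_score(expr1, [universe, tp53_er, non_tp53_er])
            scores.rename_axis("set").to_csv(out / "enrichment_scores.tsv", sep="\t")
            mut = np.asarray(labels1)
            mw = stats.mannwhitneyu(
                scores.loc[tp53_er.name].to_numpy()[mut],
                scores.loc[tp53_er.name].to_numpy()[~mut],
                alternative="two-sided",
            )
            planted_set = set(planted.members)
            summary["signatures"] = {
                "n_tp53_er": len(tp53_er),
                "n_non_tp53_er": len(non_tp53_er),
                "recall_vs_planted": len(set(tp53_er.members) & planted_set) / len(planted_set),
                "false_positives": len(set(tp53_er.members) - planted_set),
                "tp53_er_score_p": float(mw.pvalue),
            }
        except Exception as exc:
            errors["signatures"] = repr(exc)
            logger.exception("signatures stage failed")

    # ---- miRNA screen ----------------------------------------------------------
    mirna_targets: set[str] = set()
    if "mirna" in cfg.stages and expr1 is not None:
        try:
            mirna_out = msynth.gen_mirna(scfg, expr1)
            sites = mmirna.site_table(mirna_out.mature_seqs, mirna_out.transcript)
            esr1 = expr1.row("ESR1")
            screen = mmirna.screen_mirnas(mirna_out.expr, esr1, sites)
            screen.to_csv(out / "mirna_screen.tsv", sep="\t", index=False)
            selected = screen.loc[screen["selected"], "mirna_id"].tolist()
            set_scores = mmirna.mirna_set_score(mirna_out.expr, selected)
            mut = (genotypes["TP53_status"] == "Mut").to_numpy()
            mw = stats.mannwhitneyu(
                set_scores.to_numpy()[mut], set_scores.to_numpy()[~mut],
                alternative="two-sided",
            )
            target_table = msynth.gen_mirna_targets(
                scfg, list(mirna_out.expr.features), msynth.gene_names(scfg)
            )
            mirna_targets = set(
                target_table.loc[target_table["mirna_id"].isin(selected), "gene"]
            )
            summary["mirna"] = {
                "n_candidates": int(len(screen)),
                "n_selected": int(len(selected)),
                "set_score_p": float(mw.pvalue),
                "n_target_genes": len(mirna_targets),
            }
        except Exception as exc:
            errors["mirna"] = repr(exc)
            logger.exception("mirna stage failed")

    # ---- regulome --------------------------------------------------------------
    if "regulome" in cfg.stages:
        try:
            reg_out = msynth.gen_regulome(
                scfg, n_peaks=cfg.n_peaks, overlap=cfg.peak_overlap,
                n_chroms=cfg.n_chroms, chrom_length=cfg.chrom_length,
                gene_ids=msynth.gene_names(scfg), window=cfg.window,
            )
            mio.write_bed(reg_out.peaks_a, out / "p53_peaks.bed")
            mio.write_bed(reg_out.peaks_b, out / "er_peaks.bed")
            annotated = mreg.annotate_genes_near_peaks(
                reg_out.peaks_a, reg_out.gene_model, window=cfg.window
            )
            ann = mreg.filter_union_targets(
                {"p53_synth": annotated}, min_targets=cfg.min_targets, window=cfg.window
            )
            ov = mreg.overlap_significance(
                reg_out.peaks_a, reg_out.peaks_b, reg_out.chrom_sizes,
                n_sets=cfg.n_random_sets, seed=scfg.seed,
            )
            signature = tp53_er if tp53_er is not None else (
                planted if planted is not None else None
            )
            reg_summary = {
                "n_annotated": len(annotated),
                "union_flag": ann.flag or None,
                "overlap_fraction": ov.overlap_fraction,
                "overlap_p": ov.p,
                "overlap_p_empirical": ov.p_empirical,
            }
            if signature is not None:
                report = mreg.dual_mechanism_classify(
                    signature, ann.union_genes, mirna_targets
                )
                _write_json(
                    {**report.counts(), "union_count": report.union_count,
                     "union_pct": report.union_pct, "both_pct": report.both_pct},
                    out / "dual_mechanism.json",
                )
                reg_summary.update({
                    "dual_counts": report.counts(),
                    "union_pct": report.union_pct,
                    "both_pct": report.both_pct,
                })
            summary["regulome"] = reg_summary
        except Exception as exc:
            errors["regulome"] = repr(exc)
            logger.exception("regulome stage failed")

    if errors:
        summary["errors"] = errors
    summary = _round_floats(summary)
    _write_json(summary, out / "summary.json")

    manifest = {
        "config": _round_floats({
            **{k: v for k, v in dataclasses.asdict(cfg).items() if k != "synth"},
            "synth": dataclasses.asdict(cfg.synth),
        }),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write_json(manifest, out / "manifest.json")
    return summary
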