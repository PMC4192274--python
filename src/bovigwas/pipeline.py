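"""End-to-end driver: QC -> kinship -> SSR -> q-values -> BayesB ensemble ->
convergence -> QTL selection -> pathway enrichment, for one or more traits.

Each stage is the corresponding module's public surface; this module only
sequences them and writes the declared output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bayesb as bb
from . import convergence as cv
from . import enrich as en
from . import fdr, qc, qtl_ensemble, ssr
from .genio import GeneSet, GenotypeSet, OrthologMap, PathwayDB, Pedigree, PhenotypeTable
from .kinship import build_amatrix

__all__ = ["PipelineConfig", "TraitResult", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    min_maf: float = 0.05
    max_missing: float = 0.05
    mendel_max_error_rate: float = 0.0
    min_adj_rel: float = 0.70
    fdr_alpha: float = 0.05
    bayes_iterations: int = 20_000
    bayes_thin: int = 100
    mh_inner: int = 10
    window: int = 5
    pp_threshold: float = 0.5
    flank_bp: int = 500_000
    seed: int = 0


@dataclass
class TraitResult:
    trait: str
    ssr_result: ssr.SsrResult
    qvalue_result: fdr.QvalueResult
    ssr_qtl: list[fdr.QtlCall]
    prior_grid: qtl_ensemble.PriorGrid
    ensemble: qtl_ensemble.EnsembleResult
    final_qtl: list[fdr.QtlCall]
    convergence: list[cv.ConvergenceReport]
    hit_set: en.GeneHitSet | None = None
    pathway_results: list[en.PathwayResult] = field(default_factory=list)


@dataclass
class PipelineResult:
    genotypes_qc: GenotypeSet
    qc_report: qc.QcReport
    traits: dict[str, TraitResult]
    combined_pathways: list[en.PathwayResult] = field(default_factory=list)


def run_pipeline(
    genotypes: GenotypeSet,
    pedigree: Pedigree,
    phenotypes: PhenotypeTable,
    genes: GeneSet | None = None,
    orthologs: OrthologMap | None = None,
    pathways: PathwayDB | None = None,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    gs, qc_report = qc.run_snp_qc(
        genotypes,
        pedigree,
        mendel_max_error_rate=cfg.mendel_max_error_rate,
        min_maf=cfg.min_maf,
        max_missing=cfg.max_missing,
    )
    pheno, animal_report = qc.filter_animals(phenotypes, pedigree, cfg.min_adj_rel)
    qc_report.stages += animal_report.stages
    if out is not None:
        (out / "qc_report.json").write_text(json.dumps(qc_report.to_dict(), indent=1))

    amatrix = build_amatrix(pedigree)
    all_positions = {
        str(c): np.sort(gs.pos[gs.chrom == c]) for c in dict.fromkeys(gs.chrom)
    }
    snp_positions = dict(zip(gs.snp_ids, (int(p) for p in gs.pos)))

    traits: dict[str, TraitResult] = {}
    hit_sets: list[en.GeneHitSet] = []
    for t_i, trait in enumerate(pheno.traits):
        y = pheno.for_trait(trait)
        vc = ssr.estimate_varcomp(y, amatrix)
        scan = ssr.ssr_scan(gs, y, amatrix, vc)
        pi0 = fdr.estimate_pi0(scan.p)
        qres = fdr.qvalues(scan.p, pi0)
        ssr_qtl = fdr.call_ssr_qtl(qres, scan.snp_ids, scan.chrom, scan.pos, cfg.fdr_alpha)
        grid = qtl_ensemble.build_prior_grid(qres.p_ssr)

        per_analysis: list[list[fdr.QtlCall]] = []
        reports: list[cv.ConvergenceReport] = []
        for a_i, one_minus_pi in enumerate(grid.values):
            bcfg = bb.BayesBConfig(
                one_minus_pi=one_minus_pi,
                n_iterations=cfg.bayes_iterations,
                thin=cfg.bayes_thin,
                mh_inner=cfg.mh_inner,
                seed=cfg.seed + 1000 * t_i + a_i,
            )
            chain = bb.run_bayesb(gs, y, bcfg)
            report = cv.assess_convergence(chain, scan)
            burn = report.burn_in if report.converged else chain.n_records // 2
            burn = min(burn, chain.n_records - 1)
            pp = bb.compute_pp(chain, burn, cfg.window)
            per_analysis.append(
                qtl_ensemble.call_high_pp_qtl(pp, gs.snp_ids, gs.pos, cfg.pp_threshold)
            )
            reports.append(report)
            if out is not None:
                bb.save_chain(chain, out / f"chain_{trait}_{a_i:02d}.h5")

        ensemble = qtl_ensemble.EnsembleResult(priors=grid.values, qtl_per_analysis=per_analysis)
        try:
            selected = qtl_ensemble.select_analysis(ensemble)
            final_qtl = ensemble.qtl_per_analysis[selected]
        except ValueError:
            final_qtl = []

        tr = TraitResult(
            trait=trait,
            ssr_result=scan,
            qvalue_result=qres,
            ssr_qtl=ssr_qtl,
            prior_grid=grid,
            ensemble=ensemble,
            final_qtl=final_qtl,
            convergence=reports,
        )
        if genes is not None and orthologs is not None and pathways is not None:
            tr.hit_set = en.build_hit_set(
                trait, final_qtl, genes, orthologs, snp_positions, all_positions, cfg.flank_bp
            )
            if tr.hit_set.background:
                tr.pathway_results = en.enrichment_test(tr.hit_set, pathways)
            hit_sets.append(tr.hit_set)
        traits[trait] = tr

        if out is not None:
            ssr.write_ssr(scan, out / f"ssr_{trait}.tsv")
            fdr.write_qvalues(qres, scan.snp_ids, out / f"qvalues_{trait}.tsv")
            fdr.write_qtl_bed(ssr_qtl, out / f"ssr_qtl_{trait}.bed")
            fdr.write_qtl_bed(final_qtl, out / f"bayes_qtl_{trait}.bed")
            _write_ensemble_tsv(tr, out / f"ensemble_{trait}.tsv")
            cv.write_report(reports[0], out / f"convergence_{trait}.json")
            cv.write_trace_plots(reports[0], out / f"plots_{trait}")
            if tr.pathway_results:
                en.write_results(
                    en.results_to_frame(tr.pathway_results, trait),
                    out / f"pathways_{trait}.tsv",
                )

    result = PipelineResult(genotypes_qc=gs, qc_report=qc_report, traits=traits)
    if hit_sets:
        combined = en.combined_trait_set(hit_sets)
        if combined.background and pathways is not None:
            result.combined_pathways = en.enrichment_test(combined, pathways)
            if out is not None:
                en.write_results(
                    en.results_to_frame(result.combined_pathways, "combined"),
                    out / "pathways_combined.tsv",
                )
    return result


def _write_ensemble_tsv(tr: TraitResult, path: Path) -> None:
    rows = []
    for a_i, (prior, qtls) in enumerate(
        zip(tr.ensemble.priors, tr.ensemble.qtl_per_analysis)
    ):
        for q in qtls:
            rows.append(
                {
                    "analysis": a_i,
                    "one_minus_pi": prior,
                    "chrom": q.chrom,
                    "start": q.start,
                    "end": q.end,
                    "window_pp": q.score,
                    "occurrence_rate": q.occurrence_rate,
                    "selected": a_i == tr.ensemble.selected,
                    "snp_ids": ",".join(q.snp_ids),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "analysis", "one_minus_pi", "chrom", "start", "end",
            "window_pp", "occurrence_rate", "selected", "snp_ids",
        ],
    ).to_csv(path, sep="\t", index=False)
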