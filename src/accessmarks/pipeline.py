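"""End-to-end orchestration of the analysis stages on a synthetic study.

The stages mirror the analysis order: replicate intersection per genotype,
consensus merge, accessibility matrix + noise and confidence filters, mark
distance association and co-localization, TFBS Monte Carlo enrichment, gene
level classification, expression classification, and the three-way
marks/accessibility/expression integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import association, consensus as cns, enrichment, genes as gn, integration as intg
from .simulate import H2A, K27, SimSpec, SyntheticStudy, simulate_study

CATEGORY_PRIMARY_MARK = {
    "only-H2AK121ub": H2A,
    "H2AK121ub/H3K27me3": H2A,
    "only-H3K27me3": K27,
}


@dataclass
class AnalysisResults:
    genotype_ths: dict
    consensus: list
    matrix: pd.DataFrame
    filter_threshold: float
    confident: list
    confident_matrix: pd.DataFrame
    distance_summaries: dict
    venn: pd.DataFrame
    tss_distribution: pd.DataFrame
    enrichment: Optional[enrichment.EnrichmentResult]
    pairing: intg.GeneTHSPairing
    level_classes: dict = field(default_factory=dict)       # (mutant, mark) -> df
    accessibility_calls: dict = field(default_factory=dict)  # mutant -> df
    expression_classes: dict = field(default_factory=dict)   # mutant -> df
    categories: Optional[pd.Series] = None
    integration_tables: dict = field(default_factory=dict)   # (mutant, category) -> df


def analyze_study(
    study: SyntheticStudy,
    n_sets: int = 200,
    run_enrichment: bool = True,
    venn_d: int = 2000,
) -> AnalysisResults:
    spec = study.spec
    sample_genotypes = study.sample_genotypes

    genotype_ths = {
        g: cns.replicate_consensus(reps[0], reps[1])
        for g, reps in study.replicate_peaks.items()
    }
    consensus = cns.build_consensus(genotype_ths)
    qpass = cns.genotype_qpass(consensus, study.replicate_peaks)
    matrix = cns.build_matrix(consensus, study.tracks)
    filtered, threshold = cns.filter_matrix(matrix)
    confident = cns.confidence_filter(
        consensus, filtered, qpass, sample_genotypes, min_cpm=3.0
    )
    confident_matrix = filtered.loc[[c.region_id for c in confident]]
    confident_intervals = [c.interval for c in confident]

    distance_summaries = {
        mark: association.distance_bin_percentages(confident_intervals, peaks)
        for mark, peaks in study.mark_peaks.items()
    }
    venn = association.colocalization_venn(
        confident_intervals, study.mark_peaks[K27], study.mark_peaks[H2A], d=venn_d
    )
    tss_dist = cns.tss_distribution(confident, study.genes)

    enr = None
    if run_enrichment:
        enr = enrichment.mc_enrichment_test(
            confident_intervals, list(study.tfbs), study.genome,
            n_sets=n_sets, seed=study.seed,
        )

    pairing = intg.gene_ths_pairing(study.genes, confident, confident_matrix,
                                    genome=study.genome)

    results = AnalysisResults(
        genotype_ths=genotype_ths, consensus=consensus, matrix=matrix,
        filter_threshold=threshold, confident=confident,
        confident_matrix=confident_matrix, distance_summaries=distance_summaries,
        venn=venn, tss_distribution=tss_dist, enrichment=enr, pairing=pairing,
        categories=study.categories,
    )

    wt_chip = [f"WT_rep{r + 1}" for r in range(spec.n_chip_replicates)]
    wt_rna = [f"WT_rep{r + 1}" for r in range(spec.n_rna_replicates)]
    acc_samples = {s: g for s, g in sample_genotypes.items()}
    for mutant in spec.focal_mutants:
        acc = cns.differential_accessibility(
            pairing.accessibility, acc_samples, mutant, reference="WT"
        )
        results.accessibility_calls[mutant] = acc
        mut_rna = [f"{mutant}_rep{r + 1}" for r in range(spec.n_rna_replicates)]
        results.expression_classes[mutant] = gn.classify_expression(
            study.expression, mut_rna, wt_rna
        )
        mut_chip = [f"{mutant}_rep{r + 1}" for r in range(spec.n_chip_replicates)]
        for mark, table in study.mark_tables.items():
            results.level_classes[(mutant, mark)] = gn.classify_levels(
                table, mut_chip, wt_chip
            )
        for category, mark in CATEGORY_PRIMARY_MARK.items():
            results.integration_tables[(mutant, category)] = intg.integrate(
                results.level_classes[(mutant, mark)],
                acc["direction"],
                results.expression_classes[mutant]["class"],
                study.categories,
                category,
            )
    return results


def run_synthetic_analysis(
    spec: Optional[SimSpec] = None, seed: int = 0, **kwargs
) -> tuple[SyntheticStudy, AnalysisResults]:
    """Generate a synthetic study and run the full analysis over it."""
    spec = spec or SimSpec()
    study = simulate_study(spec, seed)
    return study, analyze_study(study, **kwargs)
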