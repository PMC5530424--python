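"""End-to-end orchestration: learners from data, replicate studies.

Ties the modules together: per pathway, the SNP-gene mapping is built, the
network is pruned/rewired/symmetrized/PSD-shifted, the kernel computed and
repaired, and a df-calibrated base-learner produced.  The replicate studies
reproduce the two simulation designs the method was evaluated on -- a null
scenario measuring false selections and an effect scenario measuring power
against the single-pathway LKMT comparator.
"""

from __future__ import annotations

import numpy as np

from .boosting import (
    DF_TARGET,
    NU,
    KernelBaseLearner,
    kernel_boost,
    selected_pathways,
)
from .evaluate import ReplicateResults
from .kernel import TOL_REL, GenotypeMatrix, KernelMatrix, ensure_psd_kernel, network_kernel
from .lkmt import lkmt_score_test
from .pathway_graph import (
    GeneAnnotation,
    SignedGeneNetwork,
    build_mapping_matrix,
    prepare_network,
)
from .simulate import (
    SimulationScenario,
    assign_phenotype_null,
    layout_annotation,
    make_toy_networks,
    plan_effects,
    scenario_gene_layout,
    simulate_effect_replicate,
    simulate_genotypes,
)


def build_base_learners(
    geno: GenotypeMatrix,
    annotation: GeneAnnotation,
    networks: list[SignedGeneNetwork],
    df_target: float = DF_TARGET,
    tol_rel: float = TOL_REL,
) -> list[KernelBaseLearner]:
    """One calibrated kernel base-learner per pathway.

    Pathways without any represented gene are rejected; each learner stores
    the SNP-side weight matrix A N A' and its training genotypes so that
    prediction kernels for new individuals can be formed later.
    """
    learners = []
    for net in networks:
        gene_set = set(net.genes)
        snps = [s for s in geno.snp_ids if gene_set.intersection(annotation.genes_of(s))]
        if not snps:
            raise ValueError(f"pathway {net.name!r}: no SNP maps to its genes")
        first_map = build_mapping_matrix(annotation, net, snps)
        prepared, _rho = prepare_network(net, first_map.represented_genes)
        A = build_mapping_matrix(annotation, prepared, snps)
        Zp = geno.subset_snps(snps)
        K = network_kernel(Zp, A, prepared)
        bl = KernelBaseLearner(
            net.name, K.K, df_target=df_target, tol_rel=tol_rel,
            max_rank=min(prepared.n_genes, Zp.n),
        )
        bl.attach_genotype_map(snps, A.A @ prepared.adjacency @ A.A.T, Zp.Z)
        learners.append(bl)
    return learners


def _lkmt_row(
    y: np.ndarray,
    learners: list[KernelBaseLearner],
    X: np.ndarray | None = None,
) -> np.ndarray:
    pvals = np.empty(len(learners))
    for j, bl in enumerate(learners):
        kern = ensure_psd_kernel(KernelMatrix(bl.K_raw, bl.pathway_id))
        pvals[j] = lkmt_score_test(y, X, kern).p_value
    return pvals


def null_selection_study(
    n_replicates: int = 20,
    n_pathways: int = 10,
    genes_per_pathway: int = 30,
    n: int = 400,
    m_max: int = 100,
    n_folds: int = 10,
    seed: int = 1,
    nu: float = NU,
    df_target: float = DF_TARGET,
    subsample_fraction: float = 0.5,
    compute_lkmt: bool = False,
    scenario: SimulationScenario | None = None,
) -> ReplicateResults:
    """Replicated null scenario: genotype data with a Bernoulli(0.5) phenotype.

    Pathway topologies are generated once and held fixed; every replicate
    draws fresh genotypes and an independent random disease status, fits the
    subsampling-tuned boosting model and records which pathways entered it.
    """
    if scenario is None:
        scenario = SimulationScenario(
            n_cases=n // 2, n_controls=n - n // 2, rr_per_allele=1.0,
            n_pathways=n_pathways, genes_per_pathway=genes_per_pathway,
        )
    root = np.random.default_rng(seed)
    networks = make_toy_networks(
        scenario.n_pathways, scenario.genes_per_pathway, scenario.density,
        scenario.inhibition_fraction, seed=root,
        overlap_fraction=scenario.overlap_fraction,
    )
    layout = scenario_gene_layout(scenario, networks)
    annotation = layout_annotation(layout)
    rep_seeds = [int(root.integers(2**31)) for _ in range(n_replicates)]
    selected = np.zeros((n_replicates, len(networks)), dtype=bool)
    lkmt_p = np.zeros_like(selected, dtype=float) if compute_lkmt else None
    m_stops: list[int] = []
    for r, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(rs)
        geno = simulate_genotypes(
            scenario.n, layout, scenario.maf_range, scenario.ld_rho, seed=rng
        )
        y = assign_phenotype_null(scenario.n, seed=rng)
        learners = build_base_learners(geno, annotation, networks, df_target)
        fit = kernel_boost(
            y, learners, nu=nu, m_max=m_max, n_folds=n_folds,
            subsample_fraction=subsample_fraction, seed=int(rng.integers(2**31)),
        )
        chosen = selected_pathways(fit)
        selected[r] = [net.name in chosen for net in networks]
        m_stops.append(fit.m_stop)
        if compute_lkmt:
            lkmt_p[r] = _lkmt_row(y, learners)
    return ReplicateResults(
        pathway_ids=[net.name for net in networks],
        selected=selected,
        lkmt_p=lkmt_p,
        seeds=rep_seeds,
        m_stops=m_stops,
    )


def power_study(
    n_replicates: int = 20,
    rr_per_allele: float = 1.5,
    n_cases: int = 500,
    n_controls: int = 500,
    n_pathways: int = 10,
    genes_per_pathway: int = 30,
    m_max: int = 100,
    n_folds: int = 10,
    seed: int = 1,
    nu: float = NU,
    df_target: float = DF_TARGET,
    subsample_fraction: float = 0.5,
    compute_lkmt: bool = True,
) -> ReplicateResults:
    """Replicated effect scenario with fixed causal placement.

    Two causal pathways receive three interconnected effect genes with two
    influential SNPs each; networks and effect placement are fixed across
    replicates, matching how the evaluation design reuses its pathway and
    effect-gene choices while regenerating genotypes per replicate.
    """
    scenario = SimulationScenario(
        n_cases=n_cases, n_controls=n_controls, rr_per_allele=rr_per_allele,
        n_pathways=n_pathways, genes_per_pathway=genes_per_pathway,
    )
    root = np.random.default_rng(seed)
    networks = make_toy_networks(
        scenario.n_pathways, scenario.genes_per_pathway, scenario.density,
        scenario.inhibition_fraction, seed=root,
        overlap_fraction=scenario.overlap_fraction,
    )
    layout = scenario_gene_layout(scenario, networks)
    annotation = layout_annotation(layout)
    causal, _genes, effect_snps = plan_effects(networks, scenario, root)
    rep_seeds = [int(root.integers(2**31)) for _ in range(n_replicates)]
    selected = np.zeros((n_replicates, len(networks)), dtype=bool)
    lkmt_p = np.zeros_like(selected, dtype=float) if compute_lkmt else None
    m_stops: list[int] = []
    for r, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(rs)
        geno, y = simulate_effect_replicate(scenario, layout, effect_snps, seed=rng)
        learners = build_base_learners(geno, annotation, networks, df_target)
        fit = kernel_boost(
            y, learners, nu=nu, m_max=m_max, n_folds=n_folds,
            subsample_fraction=subsample_fraction, seed=int(rng.integers(2**31)),
        )
        chosen = selected_pathways(fit)
        selected[r] = [net.name in chosen for net in networks]
        m_stops.append(fit.m_stop)
        if compute_lkmt:
            lkmt_p[r] = _lkmt_row(y, learners)
    return ReplicateResults(
        pathway_ids=[net.name for net in networks],
        selected=selected,
        lkmt_p=lkmt_p,
        causal_pathways=causal,
        seeds=rep_seeds,
        m_stops=m_stops,
    )
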