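"""Synthetic data for the kernel boosting study conditions.

Emulates the simulation architecture of the evaluation study without any
external haplotype engine: every gene is a *pseudogene* of (by default) five
SNPs with within-gene linkage disequilibrium generated by a Gaussian copula
with AR(1) correlation, genes are mutually independent (the stand-in for the
>= 100 kb spacing of sampled segments), phenotypes are either pure-noise
Bernoulli(0.5) draws (null scenario) or follow an additive per-allele
relative-risk model on two SNPs in each of three interconnected genes per
causal pathway, sampled to an exact 1:1 case-control quota.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .kernel import GenotypeMatrix
from .pathway_graph import GeneAnnotation, SignedGeneNetwork


@dataclass(frozen=True)
class SimulationScenario:
    """Parameters of one simulation condition.

    ``rr_per_allele = 1.0`` is the null scenario (phenotype independent of
    genotype); otherwise two causal pathways receive three interconnected
    effect genes with two influential SNPs each.
    """

    n_cases: int = 500
    n_controls: int = 500
    rr_per_allele: float = 1.0
    n_pathways: int = 10
    genes_per_pathway: int = 30
    snps_per_gene: int = 5
    n_causal_pathways: int = 2
    effect_genes_per_pathway: int = 3
    effect_snps_per_gene: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.5
    density: float = 0.1
    inhibition_fraction: float = 0.1
    overlap_fraction: float = 0.0
    prevalence: float = 0.1

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


def _validate_maf_ld(maf_range: tuple[float, float], ld_rho: float) -> None:
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5], got {maf_range}")
    if not 0 <= ld_rho < 1:
        raise ValueError(f"ld_rho must be in [0, 1), got {ld_rho}")


def simulate_genotypes(
    n: int,
    gene_layout: dict[str, int],
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_rho: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Pseudogene genotypes with within-gene LD and independent genes.

    Per gene, per-SNP minor allele frequencies are drawn uniformly from
    ``maf_range``; two haplotypes per individual come from a Gaussian copula
    with AR(1) correlation ``ld_rho`` inside the gene, thresholded at the
    MAF quantile, and are summed to 0/1/2 minor-allele counts.
    """
    _validate_maf_ld(maf_range, ld_rho)
    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    snp_ids: list[str] = []
    for gene, m in gene_layout.items():
        mafs = rng.uniform(maf_range[0], maf_range[1], size=m)
        ii = np.arange(m)
        corr = ld_rho ** np.abs(ii[:, None] - ii[None, :])
        L = np.linalg.cholesky(corr)
        latent = rng.standard_normal((2 * n, m)) @ L.T
        alleles = (latent < norm.ppf(mafs)[None, :]).astype(np.int64)
        blocks.append(alleles[:n] + alleles[n:])
        snp_ids.extend(f"{gene}_s{k + 1}" for k in range(m))
    Z = np.concatenate(blocks, axis=1)
    sample_ids = [f"ind{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(Z, sample_ids, snp_ids)


def layout_annotation(gene_layout: dict[str, int]) -> GeneAnnotation:
    """SNP-gene annotation matching :func:`simulate_genotypes` SNP ids."""
    records = [
        (f"{gene}_s{k + 1}", gene)
        for gene, m in gene_layout.items()
        for k in range(m)
    ]
    return GeneAnnotation.from_records(records)


def sample_effect_genes(
    network: SignedGeneNetwork,
    n_neighbours: int = 2,
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Draw a seed effect gene plus adjacent neighbours from a pathway.

    The seed gene is sampled with probability proportional to its betweenness
    centrality (genes in topologically central positions are preferred;
    uniform fallback when all centralities vanish), restricted to genes with
    at least ``n_neighbours`` neighbours; the neighbours are then drawn
    uniformly without replacement from its adjacency.
    """
    rng = np.random.default_rng(seed)
    g = network.to_graph()
    eligible = [v for v in network.genes if g.degree(v) >= n_neighbours]
    if not eligible:
        raise ValueError(
            f"no gene in {network.name!r} has >= {n_neighbours} neighbours"
        )
    centrality = nx.betweenness_centrality(g)
    weights = np.array([centrality[v] for v in eligible])
    if weights.sum() > 0:
        probs = weights / weights.sum()
    else:
        probs = np.full(len(eligible), 1.0 / len(eligible))
    seed_gene = eligible[rng.choice(len(eligible), p=probs)]
    nbrs = sorted(g.neighbors(seed_gene))
    chosen = list(rng.choice(len(nbrs), size=n_neighbours, replace=False))
    return [seed_gene] + [nbrs[i] for i in chosen]


def assign_phenotype_null(
    n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """I.i.d. Bernoulli(0.5) case status, independent of all genotypes."""
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    return (rng.random(n) < 0.5).astype(np.int64)


def assign_phenotype_effect(
    Z: GenotypeMatrix,
    effect_snps: list[str],
    rr_per_allele: float,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator | None = None,
    genotype_sampler=None,
    prevalence: float = 0.1,
    max_batches: int = 200,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Case-control sample with additive per-allele effects and exact quotas.

    Individuals are assigned case probability
    ``expit(alpha + log(rr) * burden)`` where the burden is the minor-allele
    count summed over the effect SNPs; ``alpha`` anchors the marginal
    prevalence near ``prevalence`` (per-allele odds ratio approximates the
    relative risk at low prevalence).  Individuals are drawn from ``Z`` (and,
    when the pool is exhausted, from ``genotype_sampler(n, rng)``) until
    exactly ``n_cases`` cases and ``n_controls`` controls are retained.
    """
    if rr_per_allele <= 0:
        raise ValueError("rr_per_allele must be positive")
    rng = np.random.default_rng(seed)
    snp_pos = {s: i for i, s in enumerate(Z.snp_ids)}
    missing = [s for s in effect_snps if s not in snp_pos]
    if missing:
        raise KeyError(f"effect SNPs absent from genotypes: {missing}")
    cols = [snp_pos[s] for s in effect_snps]
    beta = np.log(rr_per_allele)
    alpha = logit(prevalence) - beta * float(Z.Z[:, cols].sum(axis=1).mean())

    kept_rows: list[np.ndarray] = []
    kept_y: list[int] = []
    quota = {1: n_cases, 0: n_controls}
    pool = Z
    for _ in range(max_batches):
        burden = pool.Z[:, cols].sum(axis=1)
        prob = expit(alpha + beta * burden)
        status = (rng.random(pool.n) < prob).astype(np.int64)
        for i, s in enumerate(status):
            if quota[int(s)] > 0:
                quota[int(s)] -= 1
                kept_rows.append(pool.Z[i])
                kept_y.append(int(s))
        if quota[1] == 0 and quota[0] == 0:
            break
        if genotype_sampler is None:
            raise ValueError(
                "genotype pool exhausted before quotas were met; provide a "
                "genotype_sampler to draw additional individuals"
            )
        pool = genotype_sampler(max(quota[1] + quota[0], 64) * 8, rng)
    else:
        raise RuntimeError("case/control quota not attainable (degenerate model)")
    order = rng.permutation(len(kept_y))
    Z_out = np.asarray(kept_rows, dtype=np.int64)[order]
    y_out = np.asarray(kept_y, dtype=np.int64)[order]
    sample_ids = [f"ind{i + 1:05d}" for i in range(len(y_out))]
    return GenotypeMatrix(Z_out, sample_ids, list(Z.snp_ids)), y_out


def make_toy_networks(
    n_pathways: int,
    genes_per_pathway: int,
    density: float = 0.1,
    inhibition_fraction: float = 0.1,
    seed: int | np.random.Generator | None = None,
    overlap_fraction: float = 0.0,
) -> list[SignedGeneNetwork]:
    """Random signed pathway networks (Erdos-Renyi with signed edges).

    Gene ids are globally unique except for an optional shared fraction:
    each pathway after the first reuses ``round(overlap_fraction * G)`` genes
    drawn from the previous pathway, emulating gene overlap between real
    pathways.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if not 0 <= inhibition_fraction <= 1:
        raise ValueError("inhibition_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(overlap_fraction * genes_per_pathway))
    networks: list[SignedGeneNetwork] = []
    prev_genes: list[str] = []
    for q in range(n_pathways):
        own = [
            f"pw{q + 1}g{j + 1}"
            for j in range(genes_per_pathway - (n_shared if q > 0 else 0))
        ]
        shared: list[str] = []
        if q > 0 and n_shared > 0:
            idx = rng.choice(len(prev_genes), size=n_shared, replace=False)
            shared = [prev_genes[i] for i in idx]
        genes = shared + own
        G = len(genes)
        adj = np.zeros((G, G))
        iu, ju = np.triu_indices(G, 1)
        present = rng.random(len(iu)) < density
        signs = np.where(rng.random(len(iu)) < inhibition_fraction, -1.0, 1.0)
        adj[iu[present], ju[present]] = signs[present]
        adj[ju[present], iu[present]] = signs[present]
        networks.append(SignedGeneNetwork(genes, adj, name=f"pathway{q + 1:02d}"))
        prev_genes = genes
    return networks


@dataclass
class SimulatedDataset:
    """One simulated replicate: genotypes, networks, annotation, phenotype."""

    genotypes: GenotypeMatrix
    phenotype: np.ndarray
    networks: list[SignedGeneNetwork]
    annotation: GeneAnnotation
    gene_layout: dict[str, int]
    causal_pathways: list[str] = field(default_factory=list)
    effect_genes: dict[str, list[str]] = field(default_factory=dict)
    effect_snps: list[str] = field(default_factory=list)


def scenario_gene_layout(
    scenario: SimulationScenario, networks: list[SignedGeneNetwork]
) -> dict[str, int]:
    layout: dict[str, int] = {}
    for net in networks:
        for g in net.genes:
            layout.setdefault(g, scenario.snps_per_gene)
    return layout


def plan_effects(
    networks: list[SignedGeneNetwork],
    scenario: SimulationScenario,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[str], dict[str, list[str]], list[str]]:
    """Choose causal pathways, effect genes and effect SNPs for a scenario.

    Causal pathways are drawn at random; within each, one seed gene is
    sampled with betweenness-centrality weighting and completed with
    adjacent neighbours, then a fixed number of SNPs per effect gene are
    drawn.  Studies call this once so the placement stays fixed across
    replicates.
    """
    rng = np.random.default_rng(seed)
    need = scenario.effect_genes_per_pathway - 1
    feasible = [
        q for q, net in enumerate(networks)
        if (np.abs(np.sign(net.adjacency)).sum(axis=1) >= need).any()
    ]
    if len(feasible) < scenario.n_causal_pathways:
        raise ValueError(
            f"only {len(feasible)} pathways can host {need + 1} interconnected "
            "effect genes; increase density or pathway size"
        )
    causal_idx = rng.choice(feasible, size=scenario.n_causal_pathways, replace=False)
    causal: list[str] = []
    effect_genes: dict[str, list[str]] = {}
    effect_snps: list[str] = []
    for q in sorted(causal_idx):
        net = networks[q]
        genes = sample_effect_genes(
            net, n_neighbours=scenario.effect_genes_per_pathway - 1, seed=rng
        )
        causal.append(net.name)
        effect_genes[net.name] = genes
        for g in genes:
            picked = rng.choice(
                scenario.snps_per_gene, size=scenario.effect_snps_per_gene,
                replace=False,
            )
            effect_snps.extend(f"{g}_s{k + 1}" for k in sorted(picked))
    return causal, effect_genes, sorted(set(effect_snps))


def simulate_effect_replicate(
    scenario: SimulationScenario,
    gene_layout: dict[str, int],
    effect_snps: list[str],
    seed: int | np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """One case-control replicate under the additive relative-risk model."""
    ss_rng = np.random.default_rng(seed)
    rng_geno = np.random.default_rng(ss_rng.integers(2**31))
    rng_pheno = np.random.default_rng(ss_rng.integers(2**31))

    def sampler(n_new: int, rng: np.random.Generator) -> GenotypeMatrix:
        return simulate_genotypes(
            n_new, gene_layout, scenario.maf_range, scenario.ld_rho, seed=rng
        )

    pool = sampler(int(np.ceil(scenario.n / scenario.prevalence / 2)), rng_geno)
    return assign_phenotype_effect(
        pool,
        effect_snps,
        scenario.rr_per_allele,
        scenario.n_cases,
        scenario.n_controls,
        seed=rng_pheno,
        genotype_sampler=sampler,
        prevalence=scenario.prevalence,
    )


def simulate_scenario(
    scenario: SimulationScenario,
    seed: int,
    networks: list[SignedGeneNetwork] | None = None,
) -> SimulatedDataset:
    """Generate one full replicate of a scenario.

    Networks may be supplied (the study keeps pathway topologies fixed
    across replicates); otherwise they are generated from the same seed
    stream.  Under ``rr_per_allele = 1.0`` the phenotype is a pure
    Bernoulli(0.5) draw; otherwise effect genes are placed by betweenness-
    weighted sampling and the case-control quota model applies.
    """
    ss = np.random.SeedSequence(seed)
    rng_net, rng_geno, rng_pheno, rng_place = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    if networks is None:
        networks = make_toy_networks(
            scenario.n_pathways,
            scenario.genes_per_pathway,
            scenario.density,
            scenario.inhibition_fraction,
            seed=rng_net,
            overlap_fraction=scenario.overlap_fraction,
        )
    gene_layout = scenario_gene_layout(scenario, networks)
    annotation = layout_annotation(gene_layout)
    n = scenario.n

    if scenario.rr_per_allele == 1.0:
        geno = simulate_genotypes(
            n, gene_layout, scenario.maf_range, scenario.ld_rho, seed=rng_geno
        )
        y = assign_phenotype_null(n, seed=rng_pheno)
        return SimulatedDataset(geno, y, networks, annotation, gene_layout)

    causal, effect_genes, effect_snps = plan_effects(networks, scenario, rng_place)

    def sampler(n_new: int, rng: np.random.Generator) -> GenotypeMatrix:
        return simulate_genotypes(
            n_new, gene_layout, scenario.maf_range, scenario.ld_rho, seed=rng
        )

    pool = sampler(int(np.ceil(n / scenario.prevalence / 2)), rng_geno)
    geno, y = assign_phenotype_effect(
        pool,
        effect_snps,
        scenario.rr_per_allele,
        scenario.n_cases,
        scenario.n_controls,
        seed=rng_pheno,
        genotype_sampler=sampler,
        prevalence=scenario.prevalence,
    )
    return SimulatedDataset(
        geno, y, networks, annotation, gene_layout,
        causal_pathways=causal, effect_genes=effect_genes, effect_snps=effect_snps,
    )
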