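"""Pathway network structures: SNP-gene mapping, adjacency repair, descriptors.

A pathway is represented as a signed gene-interaction network (activation +1,
inhibition -1).  Before a genetic similarity kernel can be built from it, the
adjacency matrix has to be restricted to genes that are actually represented
by SNPs in the study (with multiplicative rewiring of indirect links), made
symmetric, and shifted to be positive semidefinite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

#: absolute tolerance below which eigenvalues count as non-negative
EPS_NUM = 1e-8


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """SNP-to-gene assignment, optionally with gene coordinates.

    Parameters
    ----------
    snp_to_genes
        Mapping from SNP id to the tuple of gene ids it is annotated to.
        A SNP may map to multiple overlapping genes.
    gene_coords
        Optional mapping ``gene_id -> (chromosome, start, end)`` with
        1-based inclusive base-pair coordinates.
    """

    snp_to_genes: dict[str, tuple[str, ...]]
    gene_coords: dict[str, tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if self.gene_coords is not None:
            for g, (_, start, end) in self.gene_coords.items():
                if start > end:
                    raise ValueError(f"gene {g}: start {start} > end {end}")

    def genes_of(self, snp_id: str) -> tuple[str, ...]:
        return self.snp_to_genes.get(snp_id, ())

    @classmethod
    def from_records(cls, records) -> "GeneAnnotation":
        """Build from an iterable of ``(snp_id, gene_id)`` pairs."""
        mapping: dict[str, list[str]] = {}
        for snp, gene in records:
            lst = mapping.setdefault(str(snp), [])
            if gene not in lst:
                lst.append(str(gene))
        return cls({s: tuple(gs) for s, gs in mapping.items()})

    @classmethod
    def from_positions(cls, snp_positions, gene_coords, flank: int = 0) -> "GeneAnnotation":
        """Annotate SNPs to genes by physical position.

        ``snp_positions`` is an iterable of ``(snp_id, chrom, pos)``;
        ``gene_coords`` maps gene id to ``(chrom, start, end)``.  A SNP is
        assigned to every gene whose (flank-extended) interval covers its
        position; coordinates are 1-based inclusive.  ``flank`` extends the
        gene boundaries on both sides by the given number of base pairs,
        standing in for LD-block extension of gene regions.
        """
        if flank < 0:
            raise ValueError("flank must be non-negative")
        by_chrom: dict[str, list[tuple[str, int, int]]] = {}
        for g, (chrom, start, end) in gene_coords.items():
            if start > end:
                raise ValueError(f"gene {g}: start {start} > end {end}")
            by_chrom.setdefault(str(chrom), []).append((g, start - flank, end + flank))
        mapping: dict[str, tuple[str, ...]] = {}
        for snp, chrom, pos in snp_positions:
            hits = tuple(
                g for g, lo, hi in by_chrom.get(str(chrom), []) if lo <= int(pos) <= hi
            )
            if hits:
                mapping[str(snp)] = hits
        return cls(mapping, gene_coords=dict(gene_coords))


@dataclass
class SignedGeneNetwork:
    """A pathway as a signed gene adjacency matrix.

    ``adjacency[i, j]`` carries the interaction weight between ``genes[i]``
    and ``genes[j]``; canonically +1 (activation) or -1 (inhibition), although
    rewired links may carry products of such weights.  The diagonal of a raw
    network is zero.
    """

    genes: list[str]
    adjacency: np.ndarray
    name: str = "pathway"
    directed_input: bool = False

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.genes)
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match {n} genes"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def is_symmetric(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.adjacency - self.adjacency.T) <= tol))

    def to_graph(self) -> nx.Graph:
        """Undirected networkx view with a ``sign`` attribute per edge."""
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        idx_i, idx_j = np.nonzero(np.triu(self.adjacency, 1))
        lower = np.nonzero(np.tril(self.adjacency, -1))
        for i, j in zip(*lower):
            if self.adjacency[j, i] == 0:  # only-lower entries
                g.add_edge(self.genes[i], self.genes[j], sign=self.adjacency[i, j])
        for i, j in zip(idx_i, idx_j):
            g.add_edge(self.genes[i], self.genes[j], sign=self.adjacency[i, j])
        return g


@dataclass(frozen=True)
class MappingMatrix:
    """SNP-to-gene design matrix A (n_snps x n_genes), size-adjusted."""

    A: np.ndarray
    snp_order: list[str]
    gene_order: list[str]
    represented_genes: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class NetworkSummary:
    nodes: int
    links: int
    inhibition_links: int
    average_degree: float
    density: float
    inhibition_degree: float
    transitivity: float
    signed_transitivity: float
    diameter: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_mapping_matrix(
    annotation: GeneAnnotation,
    network: SignedGeneNetwork,
    snp_order: list[str],
) -> MappingMatrix:
    """SNP-gene mapping matrix with gene-size adjustment 1/sqrt(m_g).

    ``A[s, g] = 1/sqrt(m_g)`` when SNP ``s`` is annotated to gene ``g``,
    where ``m_g`` is the number of SNPs in ``snp_order`` annotated to ``g``.
    The adjustment gives every represented gene a unit-norm column, so genes
    contribute equally to the kernel regardless of how many SNPs they span.
    Genes without any annotated SNP get an all-zero column and are reported
    in ``represented_genes``'s complement (remove them with
    :func:`prune_and_rewire` before building the kernel).
    """
    if not snp_order:
        raise ValueError("snp_order must be non-empty")
    if not network.genes:
        raise ValueError("network has no genes")
    gene_idx = {g: j for j, g in enumerate(network.genes)}
    n_s, n_g = len(snp_order), len(network.genes)
    hits = np.zeros((n_s, n_g), dtype=bool)
    for i, snp in enumerate(snp_order):
        for g in annotation.genes_of(snp):
            j = gene_idx.get(g)
            if j is not None:
                hits[i, j] = True
    m_g = hits.sum(axis=0)
    if not m_g.any():
        raise ValueError(
            "no SNP maps to any gene of the network (empty overlap)"
        )
    A = np.zeros((n_s, n_g))
    nz = m_g > 0
    A[:, nz] = hits[:, nz] / np.sqrt(m_g[nz])
    represented = frozenset(g for g, m in zip(network.genes, m_g) if m > 0)
    return MappingMatrix(A, list(snp_order), list(network.genes), represented)


def prune_and_rewire(
    network: SignedGeneNetwork, represented_genes: set[str] | frozenset[str]
) -> SignedGeneNetwork:
    """Remove unrepresented genes, rewiring their neighbours multiplicatively.

    Genes not represented by any SNP are eliminated one at a time, in input
    gene order.  When gene ``g`` is removed, every pair of its current
    neighbours ``(a, b)`` obtains a direct link with weight
    ``w(a, g) * w(g, b)`` unless a direct ``a-b`` link already exists;
    existing links are never overwritten.  This preserves the sign of
    indirect interactions mediated by the dropped gene.
    """
    unknown = set(represented_genes) - set(network.genes)
    if unknown:
        raise ValueError(f"represented genes not in network: {sorted(unknown)}")
    adj = network.adjacency.copy()
    genes = network.genes
    active = np.ones(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        if g in represented_genes:
            continue
        nbrs = [j for j in np.flatnonzero(active) if j != i and adj[i, j] != 0]
        for a, b in itertools.combinations(nbrs, 2):
            if adj[a, b] == 0:
                w = adj[a, i] * adj[i, b]
                adj[a, b] = adj[b, a] = w
        adj[i, :] = 0.0
        adj[:, i] = 0.0
        active[i] = False
    keep = np.flatnonzero(active)
    return SignedGeneNetwork(
        [genes[k] for k in keep],
        adj[np.ix_(keep, keep)],
        name=network.name,
        directed_input=network.directed_input,
    )


def symmetrize_adjacency(network: SignedGeneNetwork) -> SignedGeneNetwork:
    """Mirror the adjacency along its diagonal.

    Edges present in only one direction are mirrored.  If both directions
    carry conflicting non-zero weights, the upper-triangle entry (i < j)
    wins -- a deterministic, documented tie rule.
    """
    N = network.adjacency
    upper = np.triu(N, 1)
    lower_t = np.tril(N, -1).T
    combined = np.where(upper != 0, upper, lower_t)
    sym = combined + combined.T + np.diag(np.diag(N))
    return replace(network, adjacency=sym)


def psd_shift_matrix(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigenvalue-shift a symmetric matrix onto the PSD cone.

    Returns ``(rho * M + (1 - rho) * I, rho)`` with
    ``rho = 1 / (1 - lambda_min)`` when the smallest eigenvalue is negative,
    else ``rho = 1`` and ``M`` unchanged.  This is the largest shrinkage
    weight that makes the result PSD: the smallest eigenvalue maps exactly
    to zero while the original structure is preserved as far as possible.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(M, M.T, atol=EPS_NUM):
        raise ValueError("input must be symmetric")
    lam_min = float(np.linalg.eigvalsh(M)[0])
    if lam_min >= 0:
        return M, 1.0
    rho = 1.0 / (1.0 - lam_min)
    out = rho * M + (1.0 - rho) * np.eye(M.shape[0])
    return out, rho


def prepare_network(
    network: SignedGeneNetwork, represented_genes: set[str] | frozenset[str]
) -> tuple[SignedGeneNetwork, float]:
    """Full preparation chain: prune/rewire, symmetrize, PSD shift."""
    pruned = prune_and_rewire(network, represented_genes)
    if pruned.n_genes == 0:
        raise ValueError(f"pathway {network.name!r}: no represented genes left")
    sym = symmetrize_adjacency(pruned)
    shifted, rho = psd_shift_matrix(sym.adjacency)
    return replace(sym, adjacency=shifted), rho


def network_summary(network: SignedGeneNetwork) -> NetworkSummary:
    """Topology descriptors of a prepared (symmetric) pathway network.

    ``transitivity`` is the global clustering coefficient (closed over
    connected triplets); ``signed_transitivity`` weights each closed triplet
    by the product of its three edge signs, so it may be negative when
    inhibition dominates triangles.  The diameter is computed on the largest
    connected component.
    """
    if network.n_genes == 0:
        raise ValueError("empty network")
    if not network.is_symmetric(tol=1e-12):
        raise ValueError("network_summary expects a symmetric network")
    S = network.adjacency.copy()
    np.fill_diagonal(S, 0.0)
    signs = np.sign(S)
    A = np.abs(signs)
    n = network.n_genes
    deg = A.sum(axis=1)
    links = int(A.sum() / 2)
    inhibition = int((signs < 0).sum() / 2)
    triplets = float(np.sum(deg * (deg - 1)))  # 2x the connected triplets
    closed = float(np.trace(A @ A @ A))  # 6x the triangles
    signed_closed = float(np.trace(signs @ signs @ signs))
    transitivity = closed / triplets if triplets > 0 else 0.0
    signed_transitivity = signed_closed / triplets if triplets > 0 else 0.0
    g = network.to_graph()
    if n >= 2:
        largest = max(nx.connected_components(g), key=len)
        diameter = int(nx.diameter(g.subgraph(largest))) if len(largest) > 1 else 0
    else:
        diameter = 0
    return NetworkSummary(
        nodes=n,
        links=links,
        inhibition_links=inhibition,
        average_degree=float(deg.mean()),
        density=float(links / (n * (n - 1) / 2)) if n > 1 else 0.0,
        inhibition_degree=float(2 * inhibition / n),
        transitivity=transitivity,
        signed_transitivity=signed_transitivity,
        diameter=diameter,
    )
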