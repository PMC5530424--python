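"""Network-based genetic similarity kernels.

The kernel K = Z A N A' Z' turns minor-allele-count genotypes into an
n x n similarity matrix that respects the pathway's interaction topology:
Z are the genotypes, A the size-adjusted SNP-gene mapping and N the prepared
(signed, symmetric, PSD-shifted) gene adjacency.  This module also repairs
numerical PSD violations of K, computes the inverse matrix square root used
to reformulate the penalized base-learner, and builds the rectangular
prediction kernel between new and training individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .pathway_graph import EPS_NUM, MappingMatrix, SignedGeneNetwork

#: default relative eigenvalue cutoff for pseudo square-root inversion
TOL_REL = 1e-10


@dataclass(frozen=True)
class GenotypeMatrix:
    """Genotypes as minor-allele counts, n individuals x n_snps SNPs."""

    Z: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        Z = np.asarray(self.Z)
        if Z.ndim != 2:
            raise ValueError("Z must be a 2-d matrix")
        if Z.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"Z shape {Z.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if not np.isin(Z, (0, 1, 2)).all():
            bad = np.argwhere(~np.isin(Z, (0, 1, 2)))[0]
            raise ValueError(
                f"genotype entries must be minor-allele counts 0/1/2; "
                f"offending entry at sample {self.sample_ids[bad[0]]}, "
                f"SNP {self.snp_ids[bad[1]]}"
            )
        object.__setattr__(self, "Z", np.asarray(Z, dtype=float))

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in idx]
        if missing:
            raise KeyError(f"SNPs not in genotype matrix: {missing[:5]}")
        cols = [idx[s] for s in snp_ids]
        return GenotypeMatrix(self.Z[:, cols], list(self.sample_ids), list(snp_ids))

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        return GenotypeMatrix(
            self.Z[rows], [self.sample_ids[i] for i in rows], list(self.snp_ids)
        )


@dataclass(frozen=True)
class KernelMatrix:
    """A pathway kernel with a record of any PSD repair applied."""

    K: np.ndarray
    pathway_id: str = "pathway"
    rho_applied: float = 1.0


@dataclass(frozen=True)
class KernelSqrtInv:
    """Pseudo inverse square root K^(-1/2) on the retained eigen-rank."""

    M: np.ndarray
    rank: int
    tol_rel: float
    eigenvalues: np.ndarray  # retained, ascending
    eigenvectors: np.ndarray  # n x rank, aligned with eigenvalues


def _check_conformable(Z: GenotypeMatrix, A: MappingMatrix, N: SignedGeneNetwork) -> None:
    n_s, n_g = A.A.shape
    if len(Z.snp_ids) != n_s:
        raise ValueError(
            f"genotype matrix has {len(Z.snp_ids)} SNPs but mapping matrix {n_s}"
        )
    if Z.snp_ids != A.snp_order:
        raise ValueError("SNP order of genotypes and mapping matrix disagree")
    if N.n_genes != n_g:
        raise ValueError(
            f"network has {N.n_genes} genes but mapping matrix {n_g} columns"
        )
    if not N.is_symmetric(tol=EPS_NUM):
        raise ValueError("network adjacency must be symmetric (prepare it first)")


def network_kernel(
    Z: GenotypeMatrix, A: MappingMatrix, N: SignedGeneNetwork
) -> KernelMatrix:
    """K = Z A N A' Z', the network-based similarity of all pairs."""
    _check_conformable(Z, A, N)
    R = Z.Z @ A.A
    K = R @ N.adjacency @ R.T
    K = (K + K.T) / 2.0  # enforce exact symmetry against rounding
    return KernelMatrix(K, pathway_id=N.name)


def ensure_psd_kernel(kernel: KernelMatrix) -> KernelMatrix:
    """Repair small numerical PSD violations of K by the eigenvalue shift.

    Applies the same transformation used on the adjacency matrix,
    rho*K + (1-rho)*I with rho = 1/(1-lambda_min), but only when the
    smallest eigenvalue actually undershoots -EPS_NUM; a theoretically PSD
    kernel passes through unchanged (rho = 1), which also makes the repair
    idempotent.
    """
    K = kernel.K
    if not np.allclose(K, K.T, atol=EPS_NUM):
        raise ValueError("kernel must be symmetric")
    lam_min = float(scipy.linalg.eigvalsh(K, subset_by_index=[0, 0])[0])
    if lam_min >= -EPS_NUM:
        return kernel
    rho = 1.0 / (1.0 - lam_min)
    repaired = rho * K + (1.0 - rho) * np.eye(K.shape[0])
    return KernelMatrix(repaired, kernel.pathway_id, rho_applied=rho * kernel.rho_applied)


def kernel_sqrt_inv(
    kernel: KernelMatrix, tol_rel: float = TOL_REL, max_rank: int | None = None
) -> KernelSqrtInv:
    """Pseudo inverse square root of a PSD kernel via eigendecomposition.

    Eigenvalues at or below ``tol_rel`` times the largest one are treated as
    zero and dropped, so rank-deficient kernels (the common case: the rank
    is bounded by the number of genes) are handled without forming explicit
    inverses.  ``max_rank`` is an optional hint bounding the number of
    eigenpairs that need computing.
    """
    K = kernel.K
    n = K.shape[0]
    if max_rank is not None and max_rank < n:
        d, V = scipy.linalg.eigh(K, subset_by_index=[n - max_rank, n - 1])
    else:
        d, V = scipy.linalg.eigh(K)
    d_max = float(d.max(initial=0.0))
    if d_max <= 0:
        raise ValueError(
            f"kernel {kernel.pathway_id!r} is degenerate (no positive eigenvalues)"
        )
    keep = d > tol_rel * d_max
    if not keep.any():
        raise ValueError(f"kernel {kernel.pathway_id!r} has no retained eigenvalues")
    d_r, V_r = d[keep], V[:, keep]
    M = (V_r / np.sqrt(d_r)) @ V_r.T
    return KernelSqrtInv(M=M, rank=int(keep.sum()), tol_rel=tol_rel,
                         eigenvalues=d_r, eigenvectors=V_r)


def prediction_kernel(
    Z_new: GenotypeMatrix,
    Z_train: GenotypeMatrix,
    A: MappingMatrix,
    N: SignedGeneNetwork,
) -> np.ndarray:
    """K* = Z_new A N A' Z_train', the similarity of new to training samples.

    The result is rectangular (n_new x n_train) and carries no PSD
    requirement; it is only used to transport fitted pathway effects onto
    new individuals.
    """
    if Z_new.snp_ids != Z_train.snp_ids:
        raise ValueError("new and training genotypes must share the SNP order")
    _check_conformable(Z_train, A, N)
    W = A.A @ N.adjacency @ A.A.T
    return Z_new.Z @ W @ Z_train.Z.T
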