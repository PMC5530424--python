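"""File formats: genotypes, networks, annotations, gene sets, fitted models.

Genotypes are read either from the PLINK ``.raw`` dialect (header
``FID IID PAT MAT SEX PHENOTYPE snp_A ...`` with allele-count columns) or
from a plain delimited matrix with a header row of SNP ids.  Networks are
signed edge lists, gene sets GMT, annotations tab-delimited tables.  Fitted
boosting models serialize to a checksummed JSON document whose per-pathway
effect reduces to a per-SNP weight vector, so prediction needs no kernels.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .boosting import BoostFit
from .kernel import GenotypeMatrix
from .pathway_graph import GeneAnnotation, SignedGeneNetwork

MODEL_FORMAT_VERSION = 1
_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _validate_genotype_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    values = df.to_numpy()
    mask = pd.isna(df).to_numpy()
    if mask.any():
        r, c = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: missing genotype at row {df.index[r]}, column "
            f"{df.columns[c]!r}; impute missing values upstream"
        )
    arr = np.asarray(values, dtype=float)
    if not np.isin(arr, (0, 1, 2)).all():
        r, c = np.argwhere(~np.isin(arr, (0, 1, 2)))[0]
        raise ValueError(
            f"{path}: entry {arr[r, c]!r} at row {df.index[r]}, column "
            f"{df.columns[c]!r} is not a minor-allele count 0/1/2"
        )
    return arr.astype(np.int64)


def read_genotypes(path: str | Path, dialect: str = "plink-raw") -> GenotypeMatrix:
    """Read a 0/1/2 genotype matrix; rejects missing values explicitly."""
    path = Path(path)
    if dialect == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing_meta = [c for c in _PLINK_META if c not in df.columns]
        if missing_meta:
            raise ValueError(f"{path}: not PLINK .raw (missing {missing_meta})")
        sample_ids = df["IID"].astype(str).tolist()
        geno = df.drop(columns=_PLINK_META)
        snp_ids = [c.rsplit("_", 1)[0] for c in geno.columns]
    elif dialect == "delimited":
        df = pd.read_csv(path, sep="\t", dtype=str)
        first = df.columns[0]
        if first.upper() in {"IID", "ID", "SAMPLE", "SAMPLE_ID"}:
            sample_ids = df[first].astype(str).tolist()
            geno = df.drop(columns=[first])
        else:
            sample_ids = [f"ind{i + 1:05d}" for i in range(len(df))]
            geno = df
        snp_ids = list(geno.columns)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    geno = geno.apply(pd.to_numeric, errors="coerce")
    geno.index = sample_ids
    Z = _validate_genotype_frame(geno, str(path))
    return GenotypeMatrix(Z, sample_ids, snp_ids)


def write_genotypes(
    geno: GenotypeMatrix,
    path: str | Path,
    dialect: str = "plink-raw",
    phenotype: np.ndarray | None = None,
) -> None:
    path = Path(path)
    Z = geno.Z.astype(int)
    if dialect == "plink-raw":
        pheno = (
            np.asarray(phenotype, dtype=int) + 1  # PLINK 1=control 2=case
            if phenotype is not None
            else np.full(geno.n, -9, dtype=int)
        )
        cols = {
            "FID": geno.sample_ids,
            "IID": geno.sample_ids,
            "PAT": 0, "MAT": 0, "SEX": 0,
            "PHENOTYPE": pheno,
        }
        snp_cols = pd.DataFrame(
            Z, columns=[f"{s}_A" for s in geno.snp_ids]
        )
        df = pd.concat([pd.DataFrame(cols), snp_cols], axis=1)
        df.to_csv(path, sep=" ", index=False)
    elif dialect == "delimited":
        df = pd.DataFrame(Z, columns=geno.snp_ids)
        df.insert(0, "IID", geno.sample_ids)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def read_phenotype(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Two-column table ``IID<TAB>phenotype`` with 0/1 status."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    ids = df.iloc[:, 0].astype(str).tolist()
    y = pd.to_numeric(df.iloc[:, 1]).to_numpy()
    if set(np.unique(y)) - {0, 1}:
        raise ValueError(f"{path}: phenotype must be coded 0/1")
    return ids, y.astype(np.int64)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Covariate table with an IID first column; returns IID-indexed frame."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index(df.columns[0])


# ---------------------------------------------------------------------------
# networks / annotation / gene sets
# ---------------------------------------------------------------------------

def read_network(path: str | Path, name: str | None = None) -> SignedGeneNetwork:
    """Signed edge list ``gene_a<TAB>gene_b<TAB>sign`` (# comments allowed)."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    with open(path, newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            a, b, tok = parts
            tok = tok.replace("−", "-").replace("+", "")
            try:
                sign = float(tok)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad sign token {parts[2]!r}") from exc
            edges.append((a, b, sign))
    genes = sorted({g for a, b, _ in edges for g in (a, b)})
    idx = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((len(genes), len(genes)))
    directed = False
    for a, b, sign in edges:
        adj[idx[a], idx[b]] = sign
    # links listed in one direction only are undirected; mirror them
    one_way = (adj != 0) & (adj.T == 0)
    if np.any((adj != adj.T) & (adj != 0) & (adj.T != 0)):
        directed = True
    adj = np.where(one_way.T, adj.T, adj)
    return SignedGeneNetwork(
        genes, adj, name=name or path.stem, directed_input=directed
    )


def write_network(network: SignedGeneNetwork, path: str | Path) -> None:
    """Canonical sorted edge list of the upper triangle (plus asymmetric links)."""
    lines = []
    N = network.adjacency
    for i in range(network.n_genes):
        for j in range(network.n_genes):
            if i == j or N[i, j] == 0:
                continue
            if N[j, i] == N[i, j] and j < i:
                continue  # symmetric pair already written
            lines.append((network.genes[i], network.genes[j], N[i, j]))
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tsign\n")
        for a, b, s in sorted(lines):
            fh.write(f"{a}\t{b}\t{s:g}\n")


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Tab-delimited SNP annotation ``snp_id chrom pos gene_id``."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        names=["snp_id", "chrom", "pos", "gene_id"], header=0,
    )
    return GeneAnnotation.from_records(zip(df["snp_id"], df["gene_id"]))


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchrom\tpos\tgene_id\n")
        for snp in sorted(annotation.snp_to_genes):
            for gene in annotation.snp_to_genes[snp]:
                fh.write(f"{snp}\t.\t0\t{gene}\n")


def read_gene_table(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Gene coordinate table ``gene_id chrom start end`` (1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str,
        names=["gene_id", "chrom", "start", "end"], header=0,
    )
    return {
        str(r.gene_id): (str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    }


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, list[str]] = {}
    with open(path, newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, genes = parts[0], parts[2:]
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < len([g for g in genes if g]):
                warnings.warn(f"{path}:{lineno}: duplicate genes in set {name!r} removed")
            sets[name] = deduped
    return sets


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def _snp_weights(fit: BoostFit) -> list[dict]:
    out = []
    for j, bl in enumerate(fit.base_learners):
        gamma = fit.gamma_agg[j]
        if bl.snp_ids is None:
            raise ValueError(
                f"base-learner {bl.pathway_id!r} lacks genotype data; cannot serialize"
            )
        if np.any(gamma):
            alpha = bl.V @ ((bl.V.T @ gamma) / np.sqrt(bl.d))
            w = bl.snp_weight_matrix @ (bl.Z_train.T @ alpha)
        else:
            w = np.zeros(len(bl.snp_ids))
        out.append({
            "pathway_id": bl.pathway_id,
            "snp_ids": list(bl.snp_ids),
            "snp_weights": [float(v) for v in w],
        })
    return out


def _checksum(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def save_model(fit: BoostFit, path: str | Path, config: dict | None = None) -> None:
    """Serialize a fitted model to checksummed JSON.

    Pathway effects are stored as per-SNP weight vectors
    ``w_p = A N A' Z_train' K^(-1/2) gamma_p``, so a prediction is the plain
    linear form ``eta = X beta + sum_p Z_new w_p`` -- identical to evaluating
    the prediction kernel, without shipping training kernels.
    """
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "offset": {
            "beta": [float(b) for b in fit.offset.beta],
            "covariate_names": list(fit.offset.covariate_names),
        },
        "nu": fit.nu,
        "m_stop": fit.m_stop,
        "selection_path": [int(j) for j in fit.selection_path],
        "pathway_ids": list(fit.pathway_ids),
        "pathways": _snp_weights(fit),
        "config": config or {},
    }
    doc = {"payload": payload, "checksum": _checksum(payload)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


@dataclass
class LoadedModel:
    """Deserialized boosting model supporting prediction only."""

    offset_beta: np.ndarray
    covariate_names: tuple[str, ...]
    nu: float
    m_stop: int
    selection_path: list[int]
    pathway_ids: list[str]
    pathway_snp_ids: list[list[str]]
    pathway_snp_weights: list[np.ndarray]
    config: dict

    def linear_predictor(
        self, geno: GenotypeMatrix, X: np.ndarray | None = None
    ) -> np.ndarray:
        if self.covariate_names:
            if X is None:
                raise ValueError(
                    f"model was fitted with covariates {list(self.covariate_names)}; "
                    "supply a covariate matrix for prediction"
                )
            eta = self.offset_beta[0] + np.asarray(X, float) @ self.offset_beta[1:]
        else:
            eta = np.full(geno.n, self.offset_beta[0])
        for snps, w in zip(self.pathway_snp_ids, self.pathway_snp_weights):
            if np.any(w):
                eta = eta + geno.subset_snps(snps).Z @ w
        return eta

    def predict_proba(
        self, geno: GenotypeMatrix, X: np.ndarray | None = None
    ) -> np.ndarray:
        return expit(self.linear_predictor(geno, X))


def load_model(path: str | Path) -> LoadedModel:
    with open(path) as fh:
        doc = json.load(fh)
    payload = doc.get("payload")
    if payload is None or "checksum" not in doc:
        raise ValueError(f"{path}: not a kernboost model file")
    if _checksum(payload) != doc["checksum"]:
        raise ValueError(f"{path}: checksum mismatch (file corrupted or edited)")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: model format {payload['format_version']} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    return LoadedModel(
        offset_beta=np.asarray(payload["offset"]["beta"], dtype=float),
        covariate_names=tuple(payload["offset"]["covariate_names"]),
        nu=float(payload["nu"]),
        m_stop=int(payload["m_stop"]),
        selection_path=[int(j) for j in payload["selection_path"]],
        pathway_ids=list(payload["pathway_ids"]),
        pathway_snp_ids=[list(p["snp_ids"]) for p in payload["pathways"]],
        pathway_snp_weights=[
            np.asarray(p["snp_weights"], dtype=float) for p in payload["pathways"]
        ],
        config=payload.get("config", {}),
    )
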