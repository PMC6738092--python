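"""Two-way hierarchical clustering on signature genes and two-subtype assignment.

The conventional configuration is gene-wise z-scoring, 1 - Pearson correlation
distance and average linkage; the sample tree is cut into k = 2 clusters and
the cluster with the higher mean signature score (mean z of up genes minus
mean z of down genes) is labelled genomic subtype 2, i.e. the adverse,
LVI-enriched subtype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import CoverageError, DomainError
from .io import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)

_DISTANCES = {"one-minus-pearson": "correlation", "euclidean": "euclidean"}
_LINKAGES = {"average", "complete", "ward"}


@dataclass
class ClusteringParams:
    standardize: str = "zscore"          # {"zscore", "none"}
    distance: str = "one-minus-pearson"  # {"one-minus-pearson", "euclidean"}
    linkage: str = "average"             # {"average", "complete", "ward"}
    n_subtypes: int = 2

    def validate(self) -> None:
        if self.standardize not in {"zscore", "none"}:
            raise DomainError(f"unknown standardization {self.standardize!r}")
        if self.distance not in _DISTANCES:
            raise DomainError(f"unknown distance {self.distance!r}")
        if self.linkage not in _LINKAGES:
            raise DomainError(f"unknown linkage {self.linkage!r}")
        if self.n_subtypes < 2:
            raise DomainError("n_subtypes must be >= 2")


@dataclass
class SubtypeAssignment:
    """Per-sample subtype labels plus the dendrograms that produced them."""

    labels: pd.Series                 # values in {1, 2} once labelled
    scores: pd.Series                 # per-sample signature score
    sample_linkage: np.ndarray        # scipy linkage matrix, (n-1) x 4
    gene_linkage: np.ndarray | None = None
    labelled: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


def standardize_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Gene-wise z-score (sample sd, n-1 denominator); zero-variance rows dropped."""
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = values.index[~keep].tolist()
        logger.warning("standardize_rows: dropped %d constant rows: %s",
                       len(dropped), dropped[:5])
    arr = arr[keep]
    centred = arr - arr.mean(axis=1, keepdims=True)
    z = centred / arr.std(axis=1, ddof=1, keepdims=True)
    return pd.DataFrame(z, index=values.index[keep], columns=values.columns)


def restrict_to_signature(matrix: ExpressionMatrix,
                          signature: GeneSignature) -> pd.DataFrame:
    """Signature-gene submatrix; requires >= 50% of signature genes present."""
    present = [g for g in signature.genes if g in matrix.values.index]
    missing_frac = 1.0 - len(present) / len(signature)
    if missing_frac > 0:
        logger.info("restrict_to_signature: %.1f%% of signature genes missing",
                    100 * missing_frac)
    if missing_frac > 0.5:
        raise CoverageError(
            f"only {len(present)}/{len(signature)} signature genes present "
            f"({100 * (1 - missing_frac):.0f}% coverage; >= 50% required)")
    return matrix.values.loc[present]


def signature_scores(z_values: pd.DataFrame, signature: GeneSignature) -> pd.Series:
    """Per-sample score: mean z of up genes minus mean z of down genes."""
    up = [g for g in signature.up if g in z_values.index]
    down = [g for g in signature.down if g in z_values.index]
    score = pd.Series(0.0, index=z_values.columns)
    if up:
        score = score + z_values.loc[up].mean(axis=0)
    if down:
        score = score - z_values.loc[down].mean(axis=0)
    score.name = "score"
    return score


def cluster_samples(values: pd.DataFrame,
                    params: ClusteringParams | None = None,
                    cluster_genes: bool = True) -> SubtypeAssignment:
    """Agglomerative clustering of samples on a signature-gene submatrix.

    Returns an *unlabelled* assignment: cluster ids are arbitrary {1, 2}
    (ordered by first occurrence); ``label_subtypes`` applies the score rule.
    Scores are computed on the z-scored matrix regardless of the distance used.
    """
    params = params if params is not None else ClusteringParams()
    params.validate()
    if values.shape[1] < 2:
        raise DomainError("need >= 2 samples to cluster")
    if values.shape[0] < 2:
        raise DomainError("need >= 2 genes to cluster")
    z = standardize_rows(values)
    work = z if params.standardize == "zscore" else values.loc[z.index]
    dist = pdist(work.to_numpy(dtype=float).T, metric=_DISTANCES[params.distance])
    sample_z = linkage(dist, method=params.linkage)
    flat = fcluster(sample_z, t=params.n_subtypes, criterion="maxclust")
    # renumber clusters by first occurrence so the raw ids are input-order stable
    seen: dict[int, int] = {}
    ids = []
    for c in flat:
        if c not in seen:
            seen[c] = len(seen) + 1
        ids.append(seen[c])
    labels = pd.Series(ids, index=values.columns, name="subtype")
    gene_z = None
    if cluster_genes and work.shape[0] > 2:
        gene_dist = pdist(work.to_numpy(dtype=float), metric=_DISTANCES[params.distance])
        gene_z = linkage(gene_dist, method=params.linkage)
    return SubtypeAssignment(labels=labels, scores=pd.Series(np.nan, index=values.columns),
                             sample_linkage=sample_z, gene_linkage=gene_z, labelled=False)


def label_subtypes(assignment: SubtypeAssignment, scores: pd.Series) -> SubtypeAssignment:
    """Label the higher-scoring cluster subtype 2; ties label the smaller cluster 2."""
    labels = assignment.labels
    clusters = sorted(labels.unique())
    if len(clusters) != 2:
        raise DomainError(f"label_subtypes needs exactly 2 clusters, got {len(clusters)}")
    scores = scores.loc[labels.index]
    means = {c: float(scores[labels == c].mean()) for c in clusters}
    sizes = {c: int((labels == c).sum()) for c in clusters}
    a, b = clusters
    if means[a] > means[b]:
        adverse = a
    elif means[b] > means[a]:
        adverse = b
    else:
        adverse = a if sizes[a] < sizes[b] else b
    relabelled = labels.map(lambda c: 2 if c == adverse else 1)
    return replace(assignment, labels=relabelled, scores=scores, labelled=True)


def assign_subtypes(matrix: ExpressionMatrix, signature: GeneSignature,
                    params: ClusteringParams | None = None) -> SubtypeAssignment:
    """Restrict to signature genes, cluster, score and label in one call."""
    values = restrict_to_signature(matrix, signature)
    assignment = cluster_samples(values, params)
    scores = signature_scores(standardize_rows(values), signature)
    return label_subtypes(assignment, scores)


def project_centroids(matrix: ExpressionMatrix, signature: GeneSignature,
                      reference_values: pd.DataFrame,
                      reference_assignment: SubtypeAssignment) -> pd.Series:
    """Nearest-centroid subtype assignment for prospective cohorts.

    Centroids are the mean z-profiles of the two reference clusters; new
    samples take the label of the closer centroid (Euclidean on z-scores).
    """
    z_ref = standardize_rows(reference_values)
    genes = [g for g in z_ref.index if g in matrix.values.index]
    z_new = standardize_rows(matrix.values.loc[genes])
    genes = [g for g in genes if g in z_new.index]
    labels = reference_assignment.labels
    centroids = {c: z_ref.loc[genes, labels[labels == c].index].mean(axis=1)
                 for c in sorted(labels.unique())}
    out = {}
    for s in z_new.columns:
        v = z_new.loc[genes, s]
        out[s] = min(centroids, key=lambda c: float(((v - centroids[c]) ** 2).sum()))
    return pd.Series(out, name="subtype")


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree with branch lengths."""
    n = len(leaf_names)

    def _height(node: int) -> float:
        return 0.0 if node < n else float(z[node - n, 2])

    def build(node: int, branch_len: float) -> str:
        if node < n:
            return f"{leaf_names[node]}:{branch_len:.6g}"
        left, right, height, _ = z[node - n]
        inner = ",".join([build(int(left), height - _height(int(left))),
                          build(int(right), height - _height(int(right)))])
        return f"({inner}):{max(branch_len, 0.0):.6g}"

    return build(2 * n - 2, 0.0).rsplit(":", 1)[0] + ";"
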