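"""Gene signatures: clustering, extraction, scoring and centroid correlation.

Hierarchical clustering follows the Eisen convention used for two-color
arrays: similarity is the *uncentered* correlation
``sum(x*y) / sqrt(sum(x^2) * sum(y^2))`` (a cosine without mean
subtraction), distance ``1 - similarity``, average linkage.

A :class:`GeneSignature` is an ordered list of ``(gene_id, direction)``
members.  Mapped onto a tumor cohort it is scored per sample as the signed
sum of log2 expression ratios; cohorts are stratified either by the top
split of the sample dendrogram or by the sign of the score, and signatures
are compared through their *centroids* — the per-patient mean expression of
the mapped genes — with Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .io import ExperimentDesign

__all__ = [
    "GeneSignature",
    "ClusterTree",
    "TwoGroupSplit",
    "ScoreResult",
    "uncentered_correlation",
    "uncentered_correlation_matrix",
    "hierarchical_cluster",
    "cut_two_groups",
    "extract_induced_genes",
    "map_signature",
    "signature_score",
    "split_by_score_sign",
    "split_by_gene_threshold",
    "centroid_values",
    "correlate_signatures",
]


@dataclass
class GeneSignature:
    """A named, ordered gene set with per-gene direction (+1 up, -1 down)."""

    name: str
    members: list[tuple[str, int]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique: list[tuple[str, int]] = []
        for gene, direction in self.members:
            if direction not in (-1, 1):
                raise ValueError(f"direction must be +-1, got {direction} for {gene!r}")
            if gene not in seen:
                seen.add(gene)
                unique.append((gene, direction))
        if not unique:
            raise ValueError(f"signature {self.name!r} has no members")
        self.members = unique

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_genes(cls, name: str, genes: Iterable[str], direction: int = 1) -> "GeneSignature":
        return cls(name, [(g, direction) for g in genes])

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "GeneSignature":
        """Load from a TSV with columns gene_id[, gene_symbol][, direction]."""
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        if "gene_id" not in df.columns:
            raise ValueError("signature TSV needs a gene_id column")
        directions = (
            df["direction"].astype(int)
            if "direction" in df.columns
            else pd.Series(1, index=df.index)
        )
        return cls(name or Path(path).stem, list(zip(df["gene_id"], directions)))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.members, columns=["gene_id", "direction"]).to_csv(
            path, sep="\t", index=False
        )


def uncentered_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Uncentered (cosine-like) correlation over pairwise-valid entries.

    Defined as 0 when either vector is all zeros on the shared support.
    Requires at least two jointly valid entries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("need at least 2 paired valid entries")
    xs, ys = x[ok], y[ok]
    denom = np.sqrt(np.sum(xs * xs) * np.sum(ys * ys))
    if denom == 0:
        return 0.0
    return float(np.clip(np.sum(xs * ys) / denom, -1.0, 1.0))


def uncentered_correlation_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise uncentered correlations between rows, missing-aware.

    For each pair the sums run over jointly valid entries only; pairs whose
    shared support gives a zero norm get similarity 0.
    """
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v).astype(float)
    x = np.where(np.isfinite(v), v, 0.0)
    xy = x @ x.T
    x2 = x * x
    # sum of x^2 over entries valid in both rows of the pair
    nx = x2 @ mask.T
    ny = mask @ x2.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = xy / np.sqrt(nx * ny)
    sim[~np.isfinite(sim)] = 0.0
    return np.clip(sim, -1.0, 1.0)


@dataclass
class ClusterTree:
    """Average-linkage dendrogram over genes or samples of a matrix.

    ``linkage`` is a scipy linkage matrix over ``items`` (ids in input
    order); ``item_values`` keeps the clustered value rows for labeling
    group splits by expression level.
    """

    linkage: np.ndarray
    items: list[str]
    item_values: np.ndarray
    axis: str

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_merges(self) -> int:
        return self.linkage.shape[0]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.items[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.items[node.id]}:{length:.6f}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(
    matrix: pd.DataFrame, axis: Literal["genes", "samples"] = "genes"
) -> ClusterTree:
    """Average-linkage clustering with uncentered-correlation distance.

    Items (rows for ``axis='genes'``, columns for ``axis='samples'``) with
    fewer than two valid values are excluded with a warning.  Deterministic
    for a given input order; scipy breaks distance ties by item index.
    """
    if axis == "genes":
        values = matrix.to_numpy(dtype=float)
        ids = list(matrix.index.astype(str))
    elif axis == "samples":
        values = matrix.to_numpy(dtype=float).T
        ids = list(matrix.columns.astype(str))
    else:
        raise ValueError("axis must be 'genes' or 'samples'")
    valid_counts = np.isfinite(values).sum(axis=1)
    usable = valid_counts >= 2
    if not usable.all():
        dropped = [i for i, u in zip(ids, usable) if not u]
        warnings.warn(
            f"excluding {len(dropped)} item(s) with <2 valid values from clustering",
            stacklevel=2,
        )
        values = values[usable]
        ids = [i for i, u in zip(ids, usable) if u]
    if len(ids) < 2:
        raise ValueError("need at least 2 items to cluster")
    sim = uncentered_correlation_matrix(values)
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return ClusterTree(linkage=z, items=ids, item_values=values, axis=axis)


class TwoGroupSplit(NamedTuple):
    """Top dendrogram split with the higher-expressing branch labeled 'high'."""

    high: list[str]
    low: list[str]
    high_mean: float
    low_mean: float


def cut_two_groups(tree: ClusterTree) -> TwoGroupSplit:
    """Cut the dendrogram at its root into two groups labeled high/low.

    The branch with the larger mean value (over its items' valid entries) is
    labeled 'high'.
    """
    labels = hierarchy.fcluster(tree.linkage, t=2, criterion="maxclust")
    if len(set(labels)) < 2:  # all distances tied at root; fall back to last merge
        raise ValueError("dendrogram could not be cut into two groups")
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(lab, []).append(idx)
    (la, ia), (lb, ib) = sorted(groups.items())
    mean_a = float(np.nanmean(tree.item_values[ia]))
    mean_b = float(np.nanmean(tree.item_values[ib]))
    items = tree.items
    if mean_a >= mean_b:
        return TwoGroupSplit([items[i] for i in ia], [items[i] for i in ib], mean_a, mean_b)
    return TwoGroupSplit([items[i] for i in ib], [items[i] for i in ia], mean_b, mean_a)


def extract_induced_genes(
    matrix: pd.DataFrame,
    design: ExperimentDesign,
    delta: float = 0.0,
    name: str = "coculture_induced",
) -> GeneSignature:
    """Genes consistently induced in co-culture over both monocultures.

    A gene is included when its *minimum* log2 ratio across all co-culture
    replicates exceeds its *maximum* across all monoculture replicates of
    both cell types by at least ``delta``.  Genes with missing values in any
    involved sample are skipped.
    """
    design.require_all_roles()
    co_cols = design.samples("coculture")
    mono_cols = design.samples("monoculture_A") + design.samples("monoculture_B")
    co = matrix[co_cols]
    mono = matrix[mono_cols]
    complete = co.notna().all(axis=1) & mono.notna().all(axis=1)
    induced = complete & (co.min(axis=1) > mono.max(axis=1) + delta)
    genes = list(matrix.index[induced].astype(str))
    if not genes:
        raise ValueError("no induced genes found")
    return GeneSignature.from_genes(name, genes)


def map_signature(
    signature: GeneSignature,
    cohort_matrix: pd.DataFrame,
    id_map: pd.DataFrame,
) -> tuple[GeneSignature, dict]:
    """Map a signature's gene ids onto cohort probes through a two-column table.

    ``id_map`` must have columns ``gene_id`` and ``probe_id``.  Each unique
    signature gene contributes at most one probe (first mapping wins); a
    probe claimed by an earlier gene is not reused.  The report records
    unmapped members, probes absent from the cohort matrix and the full
    multimap for transparency.
    """
    for col in ("gene_id", "probe_id"):
        if col not in id_map.columns:
            raise ValueError(f"id_map needs a {col!r} column")
    lookup: dict[str, list[str]] = {}
    for gene, probe in zip(id_map["gene_id"].astype(str), id_map["probe_id"].astype(str)):
        lookup.setdefault(gene, []).append(probe)
    mapped: list[tuple[str, int]] = []
    used: set[str] = set()
    unmapped: list[str] = []
    absent: list[str] = []
    multimap: dict[str, list[str]] = {}
    for gene, direction in signature.members:
        probes = lookup.get(gene, [])
        if probes:
            multimap[gene] = probes
        chosen = None
        for p in probes:
            if p in used:
                continue
            if p not in cohort_matrix.index:
                absent.append(p)
                continue
            chosen = p
            break
        if chosen is None:
            unmapped.append(gene)
        else:
            used.add(chosen)
            mapped.append((chosen, direction))
    report = {
        "n_input": len(signature),
        "n_mapped": len(mapped),
        "unmapped": unmapped,
        "probes_absent_from_cohort": absent,
        "multimap": multimap,
    }
    if not mapped:
        raise ValueError(f"no member of signature {signature.name!r} could be mapped")
    return GeneSignature(f"{signature.name}_mapped", mapped), report


class ScoreResult(NamedTuple):
    scores: pd.Series
    n_genes: pd.Series


def signature_score(matrix: pd.DataFrame, signature: GeneSignature) -> ScoreResult:
    """Per-sample signed sum of log2 ratios over the signature's genes.

    Missing entries contribute 0 so scores stay comparable as sums; the
    per-sample count of contributing (valid) genes is returned alongside.
    """
    present = [(g, d) for g, d in signature.members if g in matrix.index]
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} present in matrix")
    genes = [g for g, _ in present]
    dirs = np.array([d for _, d in present], dtype=float)
    sub = matrix.loc[genes]
    contrib = sub.mul(dirs, axis=0)
    scores = contrib.fillna(0.0).sum(axis=0)
    scores.name = f"{signature.name}_score"
    n = sub.notna().sum(axis=0)
    n.name = "n_genes"
    return ScoreResult(scores, n)


class SignSplit(NamedTuple):
    below: list[str]
    above: list[str]

    @property
    def counts(self) -> tuple[int, int]:
        """(below, above) group sizes."""
        return (len(self.below), len(self.above))


def split_by_score_sign(scores: pd.Series) -> SignSplit:
    """Split samples at the reference zero: score < 0 below, >= 0 above."""
    below = list(scores.index[scores < 0].astype(str))
    above = list(scores.index[scores >= 0].astype(str))
    return SignSplit(below, above)


def split_by_gene_threshold(matrix: pd.DataFrame, gene_id: str) -> SignSplit:
    """Split samples by a single gene's raw log2 ratio against the reference.

    Values < 0 are "below reference", >= 0 "above".  The matrix must be
    un-centered for the reference-pool threshold to be meaningful.
    """
    if gene_id not in matrix.index:
        raise KeyError(f"gene {gene_id!r} not present in matrix")
    row = matrix.loc[gene_id]
    valid = row.dropna()
    split = SignSplit(
        list(valid.index[valid < 0].astype(str)),
        list(valid.index[valid >= 0].astype(str)),
    )
    if not split.below or not split.above:
        warnings.warn(f"gene {gene_id!r} splits all samples to one side", stacklevel=2)
    return split


def centroid_values(signature: GeneSignature, matrix: pd.DataFrame) -> pd.Series:
    """Per-patient centroid: mean expression of the signature's mapped genes."""
    genes = [g for g in signature.gene_ids if g in matrix.index]
    if not genes:
        raise ValueError(f"no gene of signature {signature.name!r} present in matrix")
    centroid = matrix.loc[genes].mean(axis=0, skipna=True)
    centroid.name = f"{signature.name}_centroid"
    return centroid


def correlate_signatures(p1: pd.Series, p2: pd.Series) -> float:
    """Signed Pearson correlation of two centroid profiles over shared patients."""
    joined = pd.concat([p1, p2], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 patients with both profiles valid")
    a, b = joined.iloc[:, 0], joined.iloc[:, 1]
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        warnings.warn("zero-variance centroid profile; correlation undefined", stacklevel=2)
        return float("nan")
    return float(pearsonr(a, b)[0])
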