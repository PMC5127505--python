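"""Mutant-class discovery and downstream class/residue-level analyses.

Variants are clustered by the shape of their phenotype profile across
conditions using centred-correlation distance (1 - Pearson r over jointly
measured conditions) with average-linkage agglomeration — the convention of
expression-style clustering tools.  The number of classes is selected by
mean silhouette width over a k range, and classes are named from spike-in
anchors: loss-of-function spike-ins mark Class 1 and gain-of-function
spike-ins mark Class 3.

Also here: the classical unpaired two-sample t-test used for
class-vs-class condition contrasts, transcription-start-site bin-profile
deltas, and the helical-propensity-change regression for the trigger-loop
tip region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .synthetic_data import GOF_SPIKE_IDS, LOF_SPIKE_IDS, parse_variant_id

__all__ = [
    "ClusterResult",
    "ClassAssignment",
    "TTestResult",
    "TSSBinProfile",
    "RegressionResult",
    "centered_correlation_distance",
    "pairwise_distances",
    "hier_cluster",
    "assign_classes",
    "dendrogram_to_newick",
    "class_condition_test",
    "tss_fraction_change",
    "helical_propensity_regression",
    "EXAMPLE_HELIX_PROPENSITY",
    "DEFAULT_ANCHORS",
]

DEFAULT_ANCHORS = {"Class 1": LOF_SPIKE_IDS, "Class 3": GOF_SPIKE_IDS}


def centered_correlation_distance(x, y) -> float:
    """1 - Pearson r over jointly measured (non-NaN) conditions.

    Returns NaN when fewer than two conditions are jointly measured or
    either vector is constant over the shared support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0.0 or ys.std() == 0.0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(1.0 - r)


def pairwise_distances(scores: pd.DataFrame) -> pd.DataFrame:
    """Variant x variant centred-correlation distances, pairwise-complete."""
    corr = scores.T.corr(method="pearson", min_periods=2)
    return (1.0 - corr).clip(lower=0.0)


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    ids: list[str]
    distances: pd.DataFrame  # square, over the clustered ids
    dropped: tuple[str, ...] = ()


def hier_cluster(
    scores: pd.DataFrame,
    linkage: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of variant profiles.

    Variants whose distance to some other variant is undefined (fewer than
    two shared conditions, or a constant profile) are excluded with a
    warning; the tree is deterministic given the input order, and the
    distance matrix itself is order-independent.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    scores = scores.sort_index()
    D = pairwise_distances(scores)
    np.fill_diagonal(D.values, 0.0)
    dropped: list[str] = []
    while len(D) >= 2 and np.isnan(D.values).any():
        n_bad = D.isna().sum(axis=1)
        worst = n_bad.sort_values(ascending=False, kind="stable").index[0]
        dropped.append(str(worst))
        D = D.drop(index=worst, columns=worst)
    if dropped:
        warnings.warn(
            f"{len(dropped)} variant(s) excluded from clustering "
            f"(undefined correlation distance): {dropped[:5]}...",
            stacklevel=2,
        )
    if len(D) < 3:
        raise ValueError("need at least 3 clusterable variants")
    condensed = squareform(D.values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return ClusterResult(
        linkage_matrix=Z, ids=list(D.index), distances=D, dropped=tuple(dropped)
    )


@dataclass
class ClassAssignment:
    """Variant -> class labels cut from the dendrogram.

    ``k`` is selected by mean silhouette width; class names come from
    spike-in anchors where present (otherwise by cluster size).  Variants
    excluded from clustering are labelled ``unassigned``.
    """

    labels: pd.Series
    k: int
    silhouette_by_k: dict[int, float]
    cluster_result: ClusterResult
    anchor_consistent: bool
    anchors: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _candidate_partitions(result: ClusterResult, min_class_size: int):
    """Flat partitions from every distinct tree cut height, with clusters
    below ``min_class_size`` collapsed to debris (label 0)."""
    Z = result.linkage_matrix
    heights = np.unique(Z[:, 2])
    cuts = np.concatenate([[heights[0] / 2 if heights[0] > 0 else -1.0],
                           (heights[:-1] + heights[1:]) / 2])
    seen = set()
    out = []
    for t in cuts:
        flat = hierarchy.fcluster(Z, t=t, criterion="distance")
        labels, sizes = np.unique(flat, return_counts=True)
        keep = {int(l) for l, c in zip(labels, sizes) if c >= min_class_size}
        collapsed = np.where(np.isin(flat, sorted(keep)), flat, 0)
        key = tuple(collapsed)
        if key in seen:
            continue
        seen.add(key)
        out.append((float(t), collapsed, len(keep)))
    return out


def assign_classes(
    result: ClusterResult,
    k_range=range(2, 9),
    anchors: dict[str, tuple[str, ...]] | None = None,
    min_class_frac: float = 0.05,
) -> ClassAssignment:
    """Cut the tree at the silhouette-optimal height and name the classes.

    Every distinct cut height of the dendrogram is a candidate partition;
    clusters smaller than ``min_class_frac`` of the clustered variants are
    treated as unassigned debris (profile outliers — e.g. variants with no
    coherent phenotype — detach near the top of a correlation-distance
    tree and would otherwise absorb the cut).  Among candidates whose
    substantive class count lies in ``k_range``, the partition maximising
    the mean silhouette width is selected, where debris variants
    contribute a silhouette of zero (the singleton convention), so a cut
    cannot improve its score by discarding variants.  The class count is
    an output, not an assumption.

    Anchors only *name* classes (majority vote per anchor group); they
    never move a variant.  ``anchor_consistent`` records whether each
    anchor group fell wholly in one class and the groups fell in distinct
    classes.
    """
    if anchors is None:
        anchors = dict(DEFAULT_ANCHORS)
    D = result.distances.values
    n = len(result.ids)
    min_size = max(2, int(np.ceil(min_class_frac * n)))
    best, best_s, sil_by_k = None, -np.inf, {}
    for t, flat, k_eff in _candidate_partitions(result, min_size):
        if k_eff not in k_range:
            continue
        member = flat != 0
        if member.sum() <= k_eff:
            continue
        per_member = silhouette_samples(
            D[np.ix_(member, member)], flat[member], metric="precomputed"
        )
        s = float(per_member.sum() / n)  # debris contributes 0
        if s > sil_by_k.get(k_eff, -np.inf):
            sil_by_k[k_eff] = s
        # ties resolve to the simpler partition (fewer classes)
        if s > best_s or (s == best_s and best is not None and k_eff < best[2]):
            best, best_s = (t, flat, k_eff), s
    if best is None:
        raise ValueError("silhouette undefined over the requested class range")
    _, flat, best_k = best
    ids = pd.Index(result.ids)

    # name substantive clusters from anchors, then by size
    cluster_of = pd.Series(flat, index=ids)
    name_of: dict[int, str] = {0: "unassigned"}
    anchor_consistent = True
    claimed: set[int] = set()
    for class_name in sorted(anchors):
        members = [v for v in anchors[class_name] if v in ids]
        if not members:
            continue
        homes = cluster_of[members]
        homes = homes[homes != 0]
        if homes.empty:
            anchor_consistent = False
            continue
        top = int(homes.mode().iloc[0])
        if homes.nunique() > 1 or top in claimed:
            anchor_consistent = False
        if top not in name_of:
            name_of[top] = class_name
        claimed.add(top)
    sizes = cluster_of[cluster_of != 0].value_counts()
    taken = set(name_of.values())
    next_num = 1
    for cl in sizes.sort_values(ascending=False).index:
        if int(cl) in name_of:
            continue
        while f"Class {next_num}" in taken:
            next_num += 1
        name_of[int(cl)] = f"Class {next_num}"
        taken.add(f"Class {next_num}")
    labels = cluster_of.map(lambda c: name_of[int(c)]).rename("class")
    for vid in result.dropped:
        labels[vid] = "unassigned"
    return ClassAssignment(
        labels=labels,
        k=int(best_k),
        silhouette_by_k=sil_by_k,
        cluster_result=result,
        anchor_consistent=anchor_consistent,
        anchors=anchors,
    )


def dendrogram_to_newick(Z: np.ndarray, ids: list[str]) -> str:
    """Newick export of a scipy linkage matrix, branch lengths = height gaps."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


# --------------------------------------------------------------------------
# Class-level and residue-level analyses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float


def class_condition_test(
    scores: pd.DataFrame,
    labels: pd.Series,
    condition: str,
    class_a: str,
    class_b: str,
) -> TTestResult:
    """Classical (pooled-variance) two-tailed unpaired t-test between two
    classes' scores in one condition."""
    col = scores[condition]
    a = col[labels.reindex(col.index) == class_a].dropna()
    b = col[labels.reindex(col.index) == class_b].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both classes need >= 2 measured scores")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(t), p=float(p), n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
    )


@dataclass(frozen=True)
class TSSBinProfile:
    """Transcription-start-site usage split into ordered positional bins
    (upstream to downstream); fractions sum to 1."""

    fractions: tuple[float, ...]
    sample: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if (f < 0).any():
            raise ValueError("bin fractions must be >= 0")
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError("bin fractions must sum to 1")


def tss_fraction_change(mutant: TSSBinProfile, wt: TSSBinProfile) -> np.ndarray:
    """Per-bin change in TSS fraction relative to the WT distribution."""
    if len(mutant.fractions) != len(wt.fractions):
        raise ValueError("bin count mismatch")
    return np.asarray(mutant.fractions) - np.asarray(wt.fractions)


# Example alpha-helical propensity scale (free energies, kcal/mol, relative
# to alanine; larger = more helix-destabilising), in the style of published
# host-guest scales.  It is a replaceable input table, not a result of this
# package: pass your preferred literature scale to
# :func:`helical_propensity_regression`.
EXAMPLE_HELIX_PROPENSITY = {
    "A": 0.00, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26, "Q": 0.39,
    "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50, "Y": 0.53, "F": 0.54,
    "H": 0.61, "V": 0.61, "N": 0.65, "T": 0.66, "C": 0.68, "D": 0.69,
    "G": 1.00, "P": 3.16,
}


@dataclass(frozen=True)
class RegressionResult:
    r: float
    slope: float
    intercept: float
    n: int


def helical_propensity_regression(
    scores: pd.Series,
    propensity_scale: dict[str, float],
    residues=range(1090, 1097),
    exclude=(),
) -> RegressionResult:
    """Regress a condition score on the helical-propensity change.

    ``scores`` maps single-substitution variant ids (e.g. ``V1094I``) to
    phenotypic scores (typically the MPA condition, a proxy for altered
    catalytic activity).  x is propensity(mutant) - propensity(WT) for
    variants in the tip region; ``exclude`` drops residue numbers (e.g.
    ``{1094}``).  Returns Pearson r (NaN when y is constant), least-squares
    slope and the n used.
    """
    residues = set(residues)
    exclude = set(exclude)
    xs, ys = [], []
    for vid, score in scores.dropna().items():
        try:
            parts = parse_variant_id(str(vid))
        except ValueError:
            continue  # not a substitution id (e.g. WT)
        if len(parts) != 1:
            continue
        wt_aa, res, mut_aa = parts[0]
        if res not in residues or res in exclude:
            continue
        if wt_aa not in propensity_scale or mut_aa not in propensity_scale:
            continue
        xs.append(propensity_scale[mut_aa] - propensity_scale[wt_aa])
        ys.append(float(score))
    if len(xs) < 3:
        raise ValueError("need at least 3 scored variants in the region")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if y.std() == 0.0:
        return RegressionResult(r=float("nan"), slope=0.0,
                                intercept=float(y.mean()), n=len(y))
    fit = stats.linregress(x, y)
    return RegressionResult(
        r=float(fit.rvalue), slope=float(fit.slope),
        intercept=float(fit.intercept), n=len(y),
    )
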