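"""Response-signature discovery: Ward clustering of coinhibition profiles,
dynamic branch cutting, median profiles, characteristic gene signatures and
gene-set enrichment.

Screens are clustered hierarchically on the distance ``1 − coinhibition``
with Ward agglomeration.  Discrete clusters come from a dynamic branch cut:
instead of slicing the dendrogram at one fixed height, branches are split
recursively wherever the merge height jumps by more than a gap threshold,
with the aggressiveness of splitting controlled by ``deep_split`` (0–4) or
an explicit ``min_gap``.  Each cluster's *median profile* (per-gene median
FD over member screens) defines its *characteristic gene signature*: the
genes whose median FD passes the positive-tail standard-normal rule
(P < 0.001 within one dataset, P < 0.05 for the combined dataset).
Signatures with fewer than two genes and no enriched gene set are dropped.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io import AnalysisConfig, ScreenMatrix
from .scoring import fd_significance_threshold
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

# default relative gap threshold per deep_split level (fraction of the
# dendrogram height range); smaller = more aggressive splitting
DEEP_SPLIT_GAP = {0: 0.45, 1: 0.35, 2: 0.25, 3: 0.15, 4: 0.05}


@dataclass
class ClusterParams:
    """Dynamic branch cutting parameters.

    ``deep_split`` (0–4) sets the split aggressiveness; ``min_gap``
    overrides the implied relative gap threshold (fraction of the tree
    height range in (0,1)); ``cut_height`` is an absolute ceiling on the
    dendrogram height scale above which branches are never clustered
    (default: the 99th percentile of merge heights).
    """

    deep_split: int = 2
    min_cluster_size: int = 3
    cut_height: float | None = None
    min_gap: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.deep_split <= 4:
            raise ValueError("deep_split must be in 0..4")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.min_gap is not None and not 0 < self.min_gap < 1:
            raise ValueError("min_gap must be in (0,1)")

    @property
    def gap_threshold(self) -> float:
        return self.min_gap if self.min_gap is not None else DEEP_SPLIT_GAP[self.deep_split]


@dataclass
class Dendrogram:
    """Ward merge tree over screen leaves.

    ``linkage_matrix`` is in scipy format but with heights on the
    Lance–Williams "Ward.D" scale for the supplied dissimilarity (see
    :func:`ward_dendrogram`).  Heights are nondecreasing along any
    leaf-to-root path.
    """

    linkage_matrix: np.ndarray
    leaf_ids: list[str]
    method: str = "ward"

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Serialize as a Newick string with branch lengths from merge heights."""
        Z = self.linkage_matrix
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(Z):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + k] = h
        return node[n + len(Z) - 1] + ";"


def ward_dendrogram(sim: SimilarityMatrix) -> Dendrogram:
    """Ward agglomeration on the distance d = 1 − coinhibition.

    Missing similarity pairs are placed at distance 1 (zero similarity).
    The Lance–Williams Ward update is applied to the dissimilarity itself
    (the "Ward.D" convention): scipy's Ward routine runs the update on
    squared distances, so it is fed sqrt(d) and the resulting heights are
    squared back.  Deterministic given the input; ties follow the
    nearest-neighbor-chain visit order.
    """
    if sim.axis != "screens":
        raise ValueError("ward_dendrogram clusters screens; got axis=genes")
    d = sim.distance(missing_value=1.0)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 screens to cluster")
    arr = d.to_numpy(dtype=float)
    arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 0.0)
    arr = np.clip(arr, 0.0, None)
    condensed = squareform(arr, checks=False)
    Z = linkage(np.sqrt(condensed), method="ward")
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2
    return Dendrogram(Z, [str(i) for i in d.index])


@dataclass
class ClusterAssignment:
    """screen → cluster id; positive integers are clusters, 0 = unassigned."""

    labels: pd.Series

    @property
    def n_clusters(self) -> int:
        return int((pd.unique(self.labels) > 0).sum())

    def members(self, cluster_id: int) -> list[str]:
        return [str(s) for s in self.labels.index[self.labels == cluster_id]]

    def clusters(self) -> dict[int, list[str]]:
        return {int(c): self.members(int(c))
                for c in sorted(pd.unique(self.labels)) if c > 0}


def dynamic_cut(dend: Dendrogram, params: ClusterParams | None = None) -> ClusterAssignment:
    """Adaptive cluster extraction from the dendrogram height profile.

    Branches entirely below ``cut_height`` (default: 99th percentile of merge
    heights, which detaches the topmost join) form candidate clusters.  A
    candidate whose internal height is below ``gap_threshold`` × its
    detachment height is already one tight cluster and is emitted whole.
    Any other candidate is dissected: it is emitted as one cluster when no
    merge inside it jumps by more than ``gap_threshold`` × (the candidate
    branch's own height) above its children, and otherwise split at its top
    merge with the parts processed recursively under the same absolute
    threshold.  Normalizing by the candidate branch rather than the whole
    tree keeps a single outlier screen that joins far above everything else
    from masking the real cluster boundaries, while the tight-branch guard
    keeps within-cluster noise from being dissected at its own scale.
    Parts smaller than ``min_cluster_size`` are
    unassigned (label 0) — the outlier screens hanging off an otherwise
    tight branch.  Lower thresholds (higher ``deep_split``) split more
    aggressively.  Deterministic; cluster ids are assigned in dendrogram
    leaf order.
    """
    params = params or ClusterParams()
    Z = dend.linkage_matrix
    n = dend.n_leaves
    heights = dend.heights
    if len(heights) == 0:
        return ClusterAssignment(pd.Series(0, index=dend.leaf_ids))
    cut_h = params.cut_height if params.cut_height is not None \
        else float(np.percentile(heights, 99.0))

    children = {n + k: (int(Z[k, 0]), int(Z[k, 1])) for k in range(len(Z))}
    height_of = {i: 0.0 for i in range(n)}
    height_of.update({n + k: float(Z[k, 2]) for k in range(len(Z))})

    size: dict[int, int] = {}
    def _size(node: int) -> int:
        if node not in size:
            size[node] = 1 if node < n else sum(_size(c) for c in children[node])
        return size[node]

    def _leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return _leaves(a) + _leaves(b)

    # candidate roots: maximal subtrees whose top height <= cut_height,
    # together with the height of the merge that detached them
    candidates: list[tuple[int, float]] = []
    def _collect(node: int, parent_height: float) -> None:
        if height_of[node] <= cut_h:
            candidates.append((node, parent_height))
        elif node >= n:
            for c in children[node]:
                _collect(c, height_of[node])
    _collect(n + len(Z) - 1, np.inf)

    max_gap: dict[int, float] = {}
    def _max_internal_gap(node: int) -> float:
        if node < n:
            return 0.0
        if node not in max_gap:
            a, b = children[node]
            here = height_of[node] - max(height_of[a], height_of[b])
            max_gap[node] = max(here, _max_internal_gap(a), _max_internal_gap(b))
        return max_gap[node]

    clusters: list[list[int]] = []
    def _split(node: int, gap_abs: float) -> None:
        if node < n or _max_internal_gap(node) <= gap_abs:
            clusters.append(_leaves(node))
            return
        a, b = children[node]
        ok_a = _size(a) >= params.min_cluster_size
        ok_b = _size(b) >= params.min_cluster_size
        if ok_a and ok_b:
            _split(a, gap_abs)
            _split(b, gap_abs)
        elif ok_a:
            _split(a, gap_abs)   # b too small: its leaves stay unassigned
        elif ok_b:
            _split(b, gap_abs)
        else:
            clusters.append(_leaves(node))  # indivisible: keep whole branch

    tau = params.gap_threshold
    for cand, parent_h in candidates:
        if _size(cand) < params.min_cluster_size:
            continue  # members stay unassigned
        if np.isfinite(parent_h) and height_of[cand] <= tau * parent_h:
            # branch far tighter than its detachment height: one cluster
            clusters.append(_leaves(cand))
        else:
            span = height_of[cand]
            _split(cand, tau * span if span > 0 else np.inf)

    labels = pd.Series(0, index=dend.leaf_ids, dtype=int)
    kept = [c for c in clusters if len(c) >= params.min_cluster_size]
    # deterministic ids: order clusters by their smallest dendrogram leaf position
    order = dict(zip(_leaves(n + len(Z) - 1) if len(Z) else range(n),
                     itertools.count()))
    kept.sort(key=lambda c: min(order[i] for i in c))
    for cid, leaf_idx in enumerate(kept, start=1):
        labels.iloc[leaf_idx] = cid
    return ClusterAssignment(labels)


# ---------------------------------------------------------------------------
# signatures

@dataclass
class ResponseSignature:
    """A cluster of screens plus its characteristic gene signature."""

    cluster_id: int
    members: list[str]
    median_profile: pd.Series
    signature_genes: list[str]
    enrichments: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["set_name", "overlap", "set_size", "p", "adj_p"]))

    def enriched_sets(self, alpha: float = 0.05) -> list[str]:
        if self.enrichments.empty:
            return []
        hit = self.enrichments["adj_p"] <= alpha
        return self.enrichments.loc[hit, "set_name"].tolist()

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "members": list(self.members),
            "signature_genes": list(self.signature_genes),
            "enriched_sets": self.enriched_sets(),
        }


def median_profile(members: list[str], fd: ScreenMatrix) -> pd.Series:
    """Per-gene median FD over the member screens (pairwise-complete)."""
    if not members:
        raise ValueError("median_profile needs a nonempty cluster")
    return fd.values[list(members)].median(axis=1, skipna=True)


def signature_genes(profile: pd.Series, alpha: float = 0.001) -> list[str]:
    """Genes whose median FD passes the positive-tail normal rule at *alpha*.

    Threshold is Φ⁻¹(1−alpha) (3.0902 at 0.001, 1.6449 at 0.05), inclusive;
    requires ``sensitivity_positive`` values.  Monotone in alpha.
    """
    thr = fd_significance_threshold(alpha)
    hit = profile[profile >= thr]
    return [str(g) for g in hit.index]


def enrich(gene_set: list[str], universe: list[str],
           gmt_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of *gene_set* in each GMT set.

    Sets are intersected with *universe* first.  For a set of size K in a
    universe of size M with a query of size N and overlap k, the upper-tail
    P is ``hypergeom.sf(k−1, M, K, N)``; Benjamini–Hochberg adjustment is
    applied across sets.
    """
    uni = set(map(str, universe))
    if not uni:
        raise ValueError("empty universe")
    query = set(map(str, gene_set)) & uni
    rows = []
    for name, genes in gmt_sets.items():
        members = set(map(str, genes)) & uni
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(members), len(query))) \
            if members else 1.0
        rows.append((name, k, len(members), p))
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p"])
    if len(df):
        df["adj_p"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    else:
        df["adj_p"] = []
    return df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)


def extract_signatures(assignment: ClusterAssignment, fd: ScreenMatrix,
                       alpha: float = 0.001,
                       gmt_sets: dict[str, list[str]] | None = None
                       ) -> list[ResponseSignature]:
    """Build a :class:`ResponseSignature` for every cluster of *assignment*."""
    if fd.orientation != "sensitivity_positive":
        raise ValueError("signatures require sensitivity_positive FDs")
    universe = fd.row_ids
    out = []
    for cid, members in assignment.clusters().items():
        prof = median_profile(members, fd)
        genes = signature_genes(prof, alpha)
        sig = ResponseSignature(cluster_id=cid, members=members,
                                median_profile=prof, signature_genes=genes)
        if gmt_sets:
            sig.enrichments = enrich(genes, universe, gmt_sets)
        out.append(sig)
    return out


def filter_signatures(signatures: list[ResponseSignature],
                      enrichment_alpha: float = 0.05) -> list[ResponseSignature]:
    """Drop signatures with fewer than two genes and no enriched gene set."""
    kept = []
    for sig in signatures:
        if len(sig.signature_genes) >= 2 or sig.enriched_sets(enrichment_alpha):
            kept.append(sig)
    return kept
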