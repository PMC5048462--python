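"""Hierarchical clustering of per-gene fold-change profiles.

Genes are clustered on their log2 fold-change profile across comparisons,
by default with Pearson correlation distance (1 - r) and average linkage —
the distance that groups co-regulated genes regardless of amplitude.
Clusters containing designated marker genes can be extracted and gene
membership tallied across several datasets' marker-anchored clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .comparisons import normalize_agi

__all__ = [
    "ProfileMatrix",
    "MarkerSet",
    "ClusterConfig",
    "DEFAULT_MARKERS",
    "cluster_profiles",
    "marker_anchored_clusters",
    "cross_membership_tally",
]

logger = logging.getLogger(__name__)

#: confirmed and proposed iron-deficiency marker genes (IRT1, FRO2, F6'H1-like,
#: kelch-repeat AT3G07720, MTPA2, COPT2)
DEFAULT_MARKERS = (
    "AT4G19690",  # IRT1
    "AT1G01580",  # FRO2
    "AT3G13610",
    "AT3G07720",
    "AT3G58810",  # MTPA2
    "AT3G46900",  # COPT2
)


@dataclass
class ProfileMatrix:
    """Gene x comparison log2 fold changes; NaN marks unmeasured cells."""

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueError("profile matrix needs at least 2 comparisons")
        self.values.index = pd.Index(
            [normalize_agi(g) for g in self.values.index], name="gene_id"
        )
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene rows in profile matrix")
        self.values = self.values.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass(frozen=True)
class MarkerSet:
    markers: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker set must be non-empty")
        object.__setattr__(
            self, "markers", tuple(normalize_agi(m) for m in self.markers)
        )


@dataclass(frozen=True)
class ClusterConfig:
    """Distance/linkage/cut configuration.

    ``cut`` is either ``("maxclust", k)`` for a fixed cluster count or
    ``("height_fraction", f)`` to cut at fraction ``f`` of the maximum merge
    height (default 0.5).
    """

    distance: str = "pearson_correlation"
    linkage: str = "average"
    cut: tuple[str, float] = ("height_fraction", 0.5)

    def __post_init__(self) -> None:
        if self.distance not in ("pearson_correlation", "euclidean"):
            raise ValueError(f"unsupported distance {self.distance!r}")
        if self.linkage not in ("average", "complete", "ward"):
            raise ValueError(f"unsupported linkage {self.linkage!r}")
        mode, value = self.cut
        if mode not in ("maxclust", "height_fraction"):
            raise ValueError(f"unsupported cut mode {mode!r}")
        if mode == "maxclust" and (int(value) != value or value < 1):
            raise ValueError("maxclust cut requires a positive integer")
        if mode == "height_fraction" and not (0 < value <= 1):
            raise ValueError("height_fraction must be in (0, 1]")


def _correlation_distances(profiles: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distances; constant profiles get the maximal
    distance (2.0) to every other gene rather than raising."""
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    dist = 1.0 - corr
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def cluster_profiles(
    matrix: ProfileMatrix,
    config: ClusterConfig = ClusterConfig(),
    seed: int = 0,
) -> pd.Series:
    """Deterministic gene -> cluster-id assignment.

    Genes are sorted before linkage so the partition is invariant to input
    order; missing values are imputed as 0 (no change), consistent with the
    ternary treatment of unmeasured cells. ``seed`` is accepted for
    interface symmetry; the procedure is fully deterministic.
    """
    del seed  # deterministic procedure
    if len(matrix.genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    values = matrix.values.sort_index().fillna(0.0)
    profiles = values.to_numpy()

    if config.distance == "pearson_correlation":
        condensed = _correlation_distances(profiles)
        method = config.linkage
        if method == "ward":
            raise ValueError("ward linkage requires euclidean distance")
        Z = linkage(condensed, method=method)
    else:
        Z = linkage(profiles, method=config.linkage, metric="euclidean")

    mode, value = config.cut
    if mode == "maxclust":
        labels = fcluster(Z, t=int(value), criterion="maxclust")
    else:
        max_height = Z[:, 2].max() if len(Z) else 0.0
        labels = fcluster(Z, t=value * max_height, criterion="distance")
    return pd.Series(labels, index=values.index, name="cluster")


def marker_anchored_clusters(
    assignment: pd.Series, markers: MarkerSet = MarkerSet()
) -> dict[int, frozenset]:
    """Whole clusters that contain at least one marker gene.

    Returns ``{cluster_id: gene set}``. Markers absent from the assignment
    are logged, not fatal; with no marker present the result is empty.
    """
    present = [m for m in markers.markers if m in assignment.index]
    missing = [m for m in markers.markers if m not in assignment.index]
    if missing:
        logger.warning("marker gene(s) not in assignment: %s", ", ".join(missing))
    if not present:
        logger.warning("no marker gene present; returning no clusters")
        return {}
    anchor_ids = sorted(set(assignment.loc[present]))
    return {
        cid: frozenset(assignment.index[assignment == cid]) for cid in anchor_ids
    }


def cross_membership_tally(collections: Mapping[str, Iterable[str]]) -> pd.Series:
    """For each gene in the union, in how many collections it appears.

    ``collections`` maps dataset name -> marker-anchored gene set. Counts
    are bounded by the number of collections.
    """
    if len(collections) < 2:
        raise ValueError("need at least 2 collections to tally")
    sets = {name: {normalize_agi(g) for g in genes} for name, genes in collections.items()}
    union = sorted(set().union(*sets.values())) if sets else []
    counts = [sum(g in s for s in sets.values()) for g in union]
    return pd.Series(counts, index=pd.Index(union, name="gene_id"), name="n_datasets")
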