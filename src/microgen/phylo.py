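"""Phylum clustering and correlation-based OTU ordering.

Taxa are partitioned by phylum and, within each cluster, sorted by the
geometric mean of the absolute Spearman correlations with every cluster
member (self-correlation included).  The resulting order places strongly
co-varying OTUs next to each other so a 1-D convolution along the taxon
axis sees locally coherent signal.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from scipy import stats

from .datasets import ClrDataset, LongitudinalDataset, MicrogenError

__all__ = [
    "PhylumClusterMap",
    "cluster_by_phylum",
    "spearman_matrix",
    "geometric_mean_rho",
    "order_otus",
    "build_cluster_map",
]


@dataclasses.dataclass
class PhylumClusterMap:
    """Partition of taxa into phylum clusters with within-cluster ordering.

    ``clusters`` is a list of (phylum name, ordered taxon-index array);
    ``rho_bar`` holds each taxon's geometric-mean |Spearman| score.
    The concatenation of all cluster orders is a permutation of 0..n-1.
    """

    clusters: list
    rho_bar: np.ndarray
    taxon_ids: list

    @property
    def permutation(self) -> np.ndarray:
        return np.concatenate([idx for _, idx in self.clusters])

    def validate(self) -> None:
        perm = np.sort(self.permutation)
        if not np.array_equal(perm, np.arange(len(self.taxon_ids))):
            raise MicrogenError("cluster orders do not form a permutation of all taxa")
        for _, idx in self.clusters:
            rb = self.rho_bar[idx]
            if np.any(np.diff(rb) > 1e-12):
                raise MicrogenError("rho_bar must be non-increasing within a cluster")

    def to_json(self) -> str:
        return json.dumps({
            "clusters": [
                {"phylum": name, "taxa": [self.taxon_ids[i] for i in idx]}
                for name, idx in self.clusters
            ],
            "rho_bar": {self.taxon_ids[i]: float(r) for i, r in enumerate(self.rho_bar)},
        }, indent=2)

    @classmethod
    def from_json(cls, text: str, taxon_ids: list) -> "PhylumClusterMap":
        obj = json.loads(text)
        pos = {t: i for i, t in enumerate(taxon_ids)}
        clusters = [
            (c["phylum"], np.array([pos[t] for t in c["taxa"]], dtype=int))
            for c in obj["clusters"]
        ]
        rho_bar = np.ones(len(taxon_ids))
        for t, r in obj["rho_bar"].items():
            rho_bar[pos[t]] = r
        return cls(clusters=clusters, rho_bar=rho_bar, taxon_ids=list(taxon_ids))


def cluster_by_phylum(ds: LongitudinalDataset) -> dict:
    """Group taxon indices by phylum label; singleton phyla are allowed."""
    out: dict[str, list] = {}
    for i, (taxon, phylum) in enumerate(zip(ds.taxon_ids, ds.phylum)):
        if not str(phylum).strip():
            raise MicrogenError(f"taxon {taxon!r} has no phylum label")
        out.setdefault(str(phylum), []).append(i)
    return {p: np.array(idx, dtype=int) for p, idx in sorted(out.items())}


def spearman_matrix(clr: ClrDataset, cluster: np.ndarray) -> np.ndarray:
    """Spearman correlations between cluster members over all observed samples.

    Samples are pooled across subjects and observed timepoints.  A taxon
    that is constant across all observed samples has undefined rank
    correlation; its off-diagonal entries are set to 0 with a warning.
    """
    obs = clr.mask == 1
    pooled = clr.clr_values[obs][:, cluster]  # (n_obs_samples, p)
    p = len(cluster)
    if p == 1:
        return np.ones((1, 1))
    if pooled.shape[0] < 3:
        raise MicrogenError("need at least 3 observed samples for rank correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(pooled, axis=0).statistic
    rho = np.asarray(rho, dtype=float)
    if rho.ndim == 0:  # scipy collapses the two-column case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    if rho.shape != (p, p):  # fully degenerate input (e.g. all columns constant)
        rho = np.full((p, p), np.nan)
    constant = pooled.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            "constant taxa in cluster; their correlations are set to 0",
            RuntimeWarning,
        )
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    rho = np.nan_to_num(rho)
    np.fill_diagonal(rho, 1.0)
    return rho


def geometric_mean_rho(rho_row: np.ndarray) -> float:
    """Geometric mean of |rho| over ALL p entries of a correlation-matrix row.

    The product runs over every cluster member including the
    self-correlation (= 1); a single zero correlation annihilates it.
    """
    row = np.abs(np.asarray(rho_row, dtype=float))
    if row.size == 0:
        raise MicrogenError("empty correlation row")
    prod = float(np.prod(row))
    return prod ** (1.0 / row.size)


def order_otus(cluster: np.ndarray, rho_bar: np.ndarray, taxon_ids: list) -> np.ndarray:
    """Sort cluster members by rho_bar descending; ties by taxon id (lexicographic)."""
    keyed = sorted(
        range(len(cluster)),
        key=lambda j: (-rho_bar[j], str(taxon_ids[cluster[j]])),
    )
    return cluster[np.array(keyed, dtype=int)]


def build_cluster_map(clr: ClrDataset) -> PhylumClusterMap:
    """Cluster by phylum and order each cluster by geometric-mean |Spearman|."""
    ds = clr.source
    groups = cluster_by_phylum(ds)
    rho_bar = np.ones(ds.n_taxa)
    clusters = []
    for phylum, idx in groups.items():
        rho = spearman_matrix(clr, idx)
        scores = np.array([geometric_mean_rho(rho[j]) for j in range(len(idx))])
        rho_bar[idx] = scores
        clusters.append((phylum, order_otus(idx, scores, ds.taxon_ids)))
    cmap = PhylumClusterMap(clusters=clusters, rho_bar=rho_bar,
                            taxon_ids=list(ds.taxon_ids))
    cmap.validate()
    return cmap
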