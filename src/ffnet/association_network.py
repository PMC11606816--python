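"""Thresholded Spearman association and co-occurrence networks.

An edge is retained between two features when the tie-aware Spearman rank
correlation of their across-sample profiles satisfies |rho| > rho_threshold
(strict) and its two-sided p-value is below alpha (strict). Two network shapes
are supported: a microbe-volatile bipartite network and a microbe-microbe
co-occurrence network (positive edges = co-occurrence, negative = co-exclusion).

p-values
--------
``asymptotic_t`` (default): two-sided p from t = rho*sqrt((n-2)/(1-rho^2)) with
n-2 degrees of freedom; |rho| = 1 maps to p = 0. ``exact_permutation``: the
two-sided tail fraction of the full n! permutation null (n <= 8; Monte-Carlo
sampling beyond), computed on untied ranks. With very short series the exact
null is coarse — at n = 4 its smallest two-sided p is 2/24 ~ 0.083, which can
never clear alpha = 0.05; only the asymptotic convention can reproduce
significance calls from 4-timepoint designs, hence the default.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .tabular_io import AbundanceTable, FeatureAnnotation, annotation_index

_EXACT_MAX_N = 8
_TIE_EPS = 1e-12


@dataclasses.dataclass
class NetworkConfig:
    """Thresholds governing edge retention and hub calls."""

    rho_threshold: float = 0.6
    alpha: float = 0.05
    p_method: str = "asymptotic_t"
    min_hub_degree: int = 10
    fdr_bh: bool = False  # optional Benjamini-Hochberg over all tested pairs
    mc_permutations: int = 20000
    mc_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rho_threshold < 1:
            raise ConfigurationError("rho_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.p_method not in ("asymptotic_t", "exact_permutation"):
            raise ConfigurationError(f"unknown p_method {self.p_method!r}")
        if self.min_hub_degree < 0:
            raise ConfigurationError("min_hub_degree must be nonnegative")


@dataclasses.dataclass(frozen=True)
class CorrelationEdge:
    """A retained pairwise association."""

    feature_a: str
    feature_b: str
    rho: float
    p: float
    sign: int


@dataclasses.dataclass
class IncidenceSummary:
    """Within- vs cross-phylum composition of a co-occurrence edge set."""

    fraction_within_phylum: float
    fraction_cross_phylum: float
    pair_fractions: dict[tuple[str, str], float]
    n_edges: int


class AssociationNetwork:
    """A thresholded correlation graph with role-annotated nodes.

    Nodes are feature ids that have at least one retained edge (degree-0
    features never enter the graph). Edge attributes: rho, p, sign. Node
    attributes: role, and species/genus/phylum/category when annotations are
    supplied.
    """

    def __init__(self, graph: nx.Graph, bipartite: bool):
        self.graph = graph
        self.bipartite = bipartite

    @property
    def edges(self) -> list[CorrelationEdge]:
        return [
            CorrelationEdge(u, v, d["rho"], d["p"], d["sign"])
            for u, v, d in self.graph.edges(data=True)
        ]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((u, v))) for u, v in self.graph.edges()}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        kind = "bipartite" if self.bipartite else "co-occurrence"
        return f"AssociationNetwork({kind}, {self.n_nodes} nodes, {self.n_edges} edges)"


# ---------------------------------------------------------------------------
# Spearman statistics
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ValidationError("Spearman correlation needs n >= 3 samples")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    nx_ = np.sqrt((sx**2).sum())
    ny_ = np.sqrt((sy**2).sum())
    if nx_ == 0 or ny_ == 0:
        raise ValidationError("correlation undefined for a constant vector")
    rho = float(np.clip(sx @ sy / (nx_ * ny_), -1.0, 1.0))
    # snap roundoff at the boundary: identical/reversed ranks are exactly +/-1
    if 1.0 - abs(rho) < _TIE_EPS:
        rho = math.copysign(1.0, rho)
    return rho


@lru_cache(maxsize=None)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| values over all n! permutations of untied ranks (n <= 8)."""
    base = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(base)))
    c = base - base.mean()
    denom = (c**2).sum()
    rhos = (perms - base.mean()) @ c / denom
    return np.sort(np.abs(rhos))


def _mc_null_abs_rho(n: int, n_perm: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    base = np.arange(1, n + 1, dtype=float)
    c = base - base.mean()
    denom = (c**2).sum()
    perms = np.array([rng.permutation(base) for _ in range(n_perm)])
    rhos = (perms - base.mean()) @ c / denom
    return np.sort(np.abs(rhos))


def _p_from_null(abs_rho: np.ndarray, null_abs: np.ndarray) -> np.ndarray:
    """Two-sided tail fraction P(|rho_null| >= |rho_obs|), with a numerical
    guard so equalities count into the tail."""
    idx = np.searchsorted(null_abs, abs_rho - _TIE_EPS, side="left")
    return (len(null_abs) - idx) / len(null_abs)


def spearman_pvalue(
    rho: float,
    n: int,
    method: str = "asymptotic_t",
    mc_permutations: int = 20000,
    mc_seed: int = 0,
) -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n."""
    if n < 3:
        raise ValidationError("p-value needs n >= 3")
    abs_rho = min(abs(float(rho)), 1.0)
    if method == "asymptotic_t":
        if abs_rho >= 1.0 - _TIE_EPS:
            return 0.0
        t = abs_rho * math.sqrt((n - 2) / (1.0 - abs_rho**2))
        return float(2.0 * stats.t.sf(t, df=n - 2))
    if method == "exact_permutation":
        if n <= _EXACT_MAX_N:
            null = _exact_null_abs_rho(n)
        else:
            null = _mc_null_abs_rho(n, mc_permutations, mc_seed)
        return float(_p_from_null(np.array([abs_rho]), null)[0])
    raise ConfigurationError(f"unknown p_method {method!r}")


def _rank_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise average ranks, standardized; returns (standardized ranks,
    boolean mask of constant rows)."""
    ranks = stats.rankdata(values, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    norms_safe = np.where(constant, 1.0, norms)
    return centered / norms_safe[:, None], constant


def spearman_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs tie-aware Spearman rho between rows of ``a`` and rows of ``b``.

    Returns (rho matrix, constant-row mask of a, constant-row mask of b);
    entries involving a constant row are NaN.
    """
    ra, ca = _rank_rows(a)
    rb, cb = _rank_rows(b)
    rho = np.clip(ra @ rb.T, -1.0, 1.0)
    snap = 1.0 - np.abs(rho) < _TIE_EPS
    rho[snap] = np.sign(rho[snap])
    rho[ca, :] = np.nan
    rho[:, cb] = np.nan
    return rho, ca, cb


def _pvalue_matrix(rho: np.ndarray, n: int, config: NetworkConfig) -> np.ndarray:
    abs_rho = np.abs(rho)
    p = np.full_like(abs_rho, np.nan, dtype=float)
    ok = ~np.isnan(abs_rho)
    if config.p_method == "asymptotic_t":
        r = np.minimum(abs_rho[ok], 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
        pv = 2.0 * stats.t.sf(t, df=n - 2)
        pv[r >= 1.0 - _TIE_EPS] = 0.0
        p[ok] = pv
    else:
        if n <= _EXACT_MAX_N:
            null = _exact_null_abs_rho(n)
        else:
            null = _mc_null_abs_rho(n, config.mc_permutations, config.mc_seed)
        p[ok] = _p_from_null(abs_rho[ok], null)
    return p


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _attach_annotations(graph: nx.Graph, annotations) -> None:
    if annotations is None:
        return
    idx = annotation_index(annotations)
    for node in graph.nodes:
        ann = idx.get(node)
        if ann is None:
            continue
        for field in ("role", "species", "genus", "phylum", "category"):
            val = getattr(ann, field)
            if val:
                graph.nodes[node][field] = val


def _finalize(graph: nx.Graph, bipartite: bool, annotations) -> AssociationNetwork:
    _attach_annotations(graph, annotations)
    for node in graph.nodes:
        graph.nodes[node]["degree"] = graph.degree(node)
    return AssociationNetwork(graph, bipartite=bipartite)


def _warn_constant(ids: Sequence[str], mask: np.ndarray, label: str) -> None:
    if mask.any():
        skipped = [ids[i] for i in np.flatnonzero(mask)]
        warnings.warn(f"skipping constant {label} feature(s): {skipped}")


def build_bipartite(
    microbes: AbundanceTable,
    volatiles: AbundanceTable,
    config: NetworkConfig | None = None,
    annotations: Iterable[FeatureAnnotation] | None = None,
) -> AssociationNetwork:
    """Microbe-volatile network over all cross-role pairs passing both thresholds."""
    config = config or NetworkConfig()
    if microbes.sample_ids != volatiles.sample_ids:
        raise ValidationError(
            "microbe and volatile tables must share the identical ordered sample list"
        )
    n = microbes.n_samples
    if n < 3:
        raise ValidationError("association networks need at least 3 samples")
    rho, cm, cv = spearman_matrix(microbes.values, volatiles.values)
    _warn_constant(microbes.feature_ids, cm, "microbe")
    _warn_constant(volatiles.feature_ids, cv, "volatile")
    p = _pvalue_matrix(rho, n, config)
    p = _maybe_bh(p, config)
    keep = (np.abs(rho) > config.rho_threshold) & (p < config.alpha)
    keep &= ~np.isnan(rho)

    graph = nx.Graph()
    mids, vids = microbes.feature_ids, volatiles.feature_ids
    for i, j in zip(*np.nonzero(keep)):
        r = float(rho[i, j])
        graph.add_node(mids[i], role="microbe")
        graph.add_node(vids[j], role="volatile")
        graph.add_edge(
            mids[i], vids[j], rho=r, p=float(p[i, j]), sign=1 if r > 0 else -1
        )
    return _finalize(graph, bipartite=True, annotations=annotations)


def build_cooccurrence(
    microbes: AbundanceTable,
    config: NetworkConfig | None = None,
    annotations: Iterable[FeatureAnnotation] | None = None,
) -> AssociationNetwork:
    """Microbe-microbe co-occurrence/co-exclusion network (no self-edges)."""
    config = config or NetworkConfig()
    n = microbes.n_samples
    if n < 3:
        raise ValidationError("association networks need at least 3 samples")
    rho, cm, _ = spearman_matrix(microbes.values, microbes.values)
    _warn_constant(microbes.feature_ids, cm, "microbe")
    p = _pvalue_matrix(rho, n, config)
    iu = np.triu_indices(len(microbes.feature_ids), k=1)
    if config.fdr_bh:
        flat = p[iu]
        adj = _bh_adjust(flat)
        p = p.copy()
        p[iu] = adj
    keep = (np.abs(rho) > config.rho_threshold) & (p < config.alpha)
    keep &= ~np.isnan(rho)

    graph = nx.Graph()
    ids = microbes.feature_ids
    for i, j in zip(*keep.nonzero()):
        if i >= j:
            continue
        r = float(rho[i, j])
        graph.add_node(ids[i], role="microbe")
        graph.add_node(ids[j], role="microbe")
        graph.add_edge(ids[i], ids[j], rho=r, p=float(p[i, j]), sign=1 if r > 0 else -1)
    return _finalize(graph, bipartite=False, annotations=annotations)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-preserving)."""
    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    q = p[ok]
    m = len(q)
    if m == 0:
        return out
    order = np.argsort(q)
    adj = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _maybe_bh(p: np.ndarray, config: NetworkConfig) -> np.ndarray:
    if not config.fdr_bh:
        return p
    flat = p.ravel()
    return _bh_adjust(flat).reshape(p.shape)


# ---------------------------------------------------------------------------
# network summaries
# ---------------------------------------------------------------------------

def split_by_sign(
    network: AssociationNetwork,
) -> tuple[AssociationNetwork, AssociationNetwork]:
    """Partition edges into positive and negative subnetworks.

    Node sets are recomputed (degree-0 nodes dropped); edge counts are
    conserved: |positive| + |negative| = |total|.
    """
    parts = []
    for wanted in (1, -1):
        g = nx.Graph()
        for u, v, d in network.graph.edges(data=True):
            if d["sign"] == wanted:
                for node in (u, v):
                    g.add_node(node, **{
                        k: val for k, val in network.graph.nodes[node].items()
                        if k != "degree"
                    })
                g.add_edge(u, v, **d)
        for node in g.nodes:
            g.nodes[node]["degree"] = g.degree(node)
        parts.append(AssociationNetwork(g, bipartite=network.bipartite))
    return parts[0], parts[1]


def find_hubs(network: AssociationNetwork, min_degree: int = 10) -> list[str]:
    """Nodes with degree >= min_degree, sorted by degree descending then id."""
    hubs = [(n, d) for n, d in network.graph.degree() if d >= min_degree]
    hubs.sort(key=lambda nd: (-nd[1], nd[0]))
    return [n for n, _ in hubs]


def cooccurrence_incidence(
    network: AssociationNetwork,
    annotations: Iterable[FeatureAnnotation],
) -> IncidenceSummary:
    """Within- vs cross-phylum fractions over all retained edges.

    Every node must carry a phylum annotation; raises on an empty network.
    """
    if network.n_edges == 0:
        raise ValidationError("incidence undefined: network has no edges")
    idx = annotation_index(annotations)
    pair_counts: dict[tuple[str, str], int] = {}
    within = 0
    for u, v in network.graph.edges():
        phyla = []
        for node in (u, v):
            ann = idx.get(node)
            phylum = ann.phylum if ann is not None else None
            if not phylum:
                raise ValidationError(f"node {node!r} has no phylum annotation")
            phyla.append(phylum)
        key = tuple(sorted(phyla))
        pair_counts[key] = pair_counts.get(key, 0) + 1
        if phyla[0] == phyla[1]:
            within += 1
    n_edges = network.n_edges
    pair_fractions = {k: c / n_edges for k, c in sorted(pair_counts.items())}
    return IncidenceSummary(
        fraction_within_phylum=within / n_edges,
        fraction_cross_phylum=(n_edges - within) / n_edges,
        pair_fractions=pair_fractions,
        n_edges=n_edges,
    )
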