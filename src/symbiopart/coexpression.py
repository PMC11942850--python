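"""Per-caste weighted co-expression networks and host-flagellate strong pairs.

For each caste the TMM expression of that caste's samples (log2(TMM+1) by
default) gives a Pearson correlation matrix, soft-thresholded into an
unsigned adjacency a_ij = |cor_ij|^beta (beta = 12 by default), from which
the topological overlap measure (TOM) is computed:

    TOM_ij = (sum_u a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with k_i the connectivity sum_u a_iu and TOM_ii = 1.  A consensus TOM
(quantile-scaled element-wise minimum of the caste TOMs) supports joint
module detection by average-linkage clustering with a static tree cut.

The headline comparison extracts "strong pairs": transcript pairs with
per-caste edge weight (TOM) >= 0.5 where one member is classified as
flagellate and the other is anything else — host, unclear, or a
flagellate of unresolved order.  Worker and soldier pair lists are
compared directly and via their intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .source_classifier import FLAGELLATE, SourceCall

UNASSIGNED = 0  # module label for below-min-size clusters ("grey")


def correlation_matrix(tmm_subset: pd.DataFrame,
                       transform: str = "log2p1") -> pd.DataFrame:
    """Pearson correlation of transcripts across one caste's samples.

    Constant transcripts get correlation 0 with everything (they carry no
    co-expression information); the diagonal stays 1.
    """
    if tmm_subset.shape[1] < 3:
        raise ValueError("need >=3 samples for correlation")
    x = tmm_subset.to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=tmm_subset.index,
                        columns=tmm_subset.index)


def soft_adjacency(cor: pd.DataFrame, beta: float = 12.0) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency |cor|^beta, zero diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = np.abs(cor.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a symmetric zero-diagonal adjacency."""
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    shared = a @ a                       # sum_u a_iu * a_uj
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index,
                        columns=adjacency.columns)


def consensus_tom(tom_a: pd.DataFrame, tom_b: pd.DataFrame,
                  scale_quantile: float = 0.95) -> pd.DataFrame:
    """Quantile-scaled element-wise minimum of two TOMs.

    The second TOM is power-transformed so its off-diagonal
    *scale_quantile* quantile matches the first's, then the element-wise
    minimum is taken.  Node sets and order must agree.
    """
    if not tom_a.index.equals(tom_b.index):
        raise ValueError("TOMs must share the same node set and order")
    if not 0 < scale_quantile < 1:
        raise ValueError("scale_quantile must be in (0, 1)")
    a = tom_a.to_numpy(dtype=float)
    b = tom_b.to_numpy(dtype=float)
    off = ~np.eye(a.shape[0], dtype=bool)
    qa = np.quantile(a[off], scale_quantile)
    qb = np.quantile(b[off], scale_quantile)
    if 0 < qb < 1 and 0 < qa < 1:
        b = b ** (np.log(qa) / np.log(qb))
    cons = np.minimum(a, b)
    return pd.DataFrame(cons, index=tom_a.index, columns=tom_a.columns)


def detect_modules(tom: pd.DataFrame, cut_height: float = 0.995,
                   min_size: int = 10) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than *min_size* are labelled 0 (unassigned / grey);
    real modules get labels 1, 2, ... in decreasing size order.
    """
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, None)
    labels = fcluster(average(squareform(d, checks=False)),
                      t=cut_height, criterion="distance")
    out = np.zeros(len(labels), dtype=int)
    sizes = pd.Series(labels).value_counts()
    next_label = 1
    for cluster, size in sizes.items():
        if size >= min_size:
            out[labels == cluster] = next_label
            next_label += 1
    return pd.Series(out, index=tom.index, name="module")


@dataclass(frozen=True)
class StrongPair:
    """A flagellate x other transcript pair with edge weight >= threshold."""

    flagellate: str
    partner: str
    partner_class: str      # termite | unclear | flagellate-unclassified
    weight: float

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.flagellate, self.partner)))


def _partner_class(call: SourceCall | None) -> str:
    if call is None:
        return "unclear"
    if call.source == FLAGELLATE:
        return "flagellate-unclassified"
    return call.source


def strong_pairs(tom_caste: pd.DataFrame,
                 calls: dict[str, SourceCall],
                 threshold: float = 0.5) -> list[StrongPair]:
    """Extract flagellate x other pairs with weight >= threshold (inclusive).

    One member must carry a FLAGELLATE call; the partner may be termite,
    unclear, or another flagellate whose order is unresolved (matching
    how the partner classes are reported).  Flagellate x flagellate pairs
    where both have a resolved order are the within-symbiont network and
    are excluded.  When both members qualify as the "flagellate side",
    the lexicographically smaller id takes that role.
    """
    nodes = list(tom_caste.index)
    is_flag = np.array([calls[n].source == FLAGELLATE if n in calls else False
                        for n in nodes])
    has_order = np.array([
        (n in calls and calls[n].source == FLAGELLATE
         and calls[n].order is not None) for n in nodes])
    w = tom_caste.to_numpy(dtype=float)
    pairs: list[StrongPair] = []
    ii, jj = np.where(np.triu(w >= threshold, k=1))
    for i, j in zip(ii, jj):
        fi, fj = is_flag[i], is_flag[j]
        if not (fi or fj):
            continue
        if fi and fj:
            if has_order[i] and has_order[j]:
                continue  # both order-resolved: within-symbiont edge
            # flagellate side = the order-resolved one, else smaller id
            if has_order[i]:
                a, b = i, j
            elif has_order[j]:
                a, b = j, i
            else:
                a, b = (i, j) if nodes[i] < nodes[j] else (j, i)
        else:
            a, b = (i, j) if fi else (j, i)
        pairs.append(StrongPair(nodes[a], nodes[b],
                                _partner_class(calls.get(nodes[b])),
                                float(w[i, j])))
    return pairs


def shared_pairs(worker_list: list[StrongPair],
                 soldier_list: list[StrongPair]) -> list[StrongPair]:
    """Pairs strong in both castes (intersection on unordered id pairs);
    the returned records carry the worker-side weights."""
    soldier_keys = {p.key for p in soldier_list}
    return [p for p in worker_list if p.key in soldier_keys]


def pairs_table(pairs: list[StrongPair],
                calls: dict[str, SourceCall]) -> pd.DataFrame:
    rows = [{
        "node1": p.flagellate, "node2": p.partner, "weight": p.weight,
        "source1": calls[p.flagellate].source if p.flagellate in calls
        else "unclear",
        "source2": p.partner_class,
    } for p in pairs]
    return pd.DataFrame(rows, columns=["node1", "node2", "weight",
                                       "source1", "source2"])


def build_caste_networks(tmm: pd.DataFrame, castes: pd.Series,
                         calls: dict[str, SourceCall],
                         beta: float = 12.0, threshold: float = 0.5,
                         transform: str = "log2p1",
                         scale_quantile: float = 0.95,
                         cut_height: float = 0.995, min_size: int = 10
                         ) -> dict:
    """End-to-end network stage for both castes.

    Returns per-caste TOMs, the consensus TOM, module assignments, and
    worker/soldier/shared strong-pair lists.
    """
    from .expression import SOLDIER, WORKER

    toms = {}
    for caste in (WORKER, SOLDIER):
        samples = [s for s in tmm.columns if castes[s] == caste]
        cor = correlation_matrix(tmm[samples], transform=transform)
        toms[caste] = topological_overlap(soft_adjacency(cor, beta=beta))
    cons = consensus_tom(toms[WORKER], toms[SOLDIER],
                         scale_quantile=scale_quantile)
    modules = detect_modules(cons, cut_height=cut_height, min_size=min_size)
    pw = strong_pairs(toms[WORKER], calls, threshold=threshold)
    ps = strong_pairs(toms[SOLDIER], calls, threshold=threshold)
    return {
        "tom_worker": toms[WORKER],
        "tom_soldier": toms[SOLDIER],
        "consensus": cons,
        "modules": modules,
        "pairs_worker": pw,
        "pairs_soldier": ps,
        "pairs_shared": shared_pairs(pw, ps),
    }
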