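"""Sex assortment and centrality tests by node-label permutation.

The null model holds the edge structure fixed and permutes the sex
labels over nodes (attribute permutation, not edge rewiring): under the
null, which individuals are male or female is unrelated to who roosts
with whom.  Join counts classify every association as male-male,
female-female or intersex; the degree test compares mean degree
centrality between the sexes with a t statistic referred to its
permutation distribution.

p-values use the add-one estimator (1 + #extreme) / (n_perm + 1), which
can never return 0 from a finite number of permutations.  Both tails are
always computed for the join counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

CATEGORIES = ("MM", "FF", "MF")


def _edge_index(G: nx.Graph):
    nodes = sorted(G.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    sexes = np.array([G.nodes[n]["sex"] for n in nodes])
    edges = np.array([[idx[u], idx[v]] for u, v in G.edges], dtype=int)
    return nodes, sexes, edges


def _join_counts(sexes: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """(MM, FF, MF) counts for one labelling."""
    su, sv = sexes[edges[:, 0]], sexes[edges[:, 1]]
    mm = int(np.sum((su == "M") & (sv == "M")))
    ff = int(np.sum((su == "F") & (sv == "F")))
    return np.array([mm, ff, len(edges) - mm - ff])


@dataclass
class JoinCountResult:
    observed: dict[str, int]
    perm_mean: dict[str, float]
    p_greater: dict[str, float | None]   # observed count larger than chance
    p_less: dict[str, float | None]
    n_perm: int
    seed: int | None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def join_count_test(G: nx.Graph, n_perm: int = 10000, seed: int | None = None) -> JoinCountResult:
    """Join-count permutation test of sex assortment.

    Every node must carry a ``sex`` attribute.  MM + FF + MF equals the
    edge count in the observed data and every permutation.  If only one
    sex is present the test is degenerate and all p-values are None.
    """
    if G.number_of_edges() == 0:
        raise ValueError("join-count test requires at least one edge")
    _nodes, sexes, edges = _edge_index(G)
    obs = _join_counts(sexes, edges)
    degenerate = len(set(sexes)) < 2
    rng = np.random.default_rng(seed)
    ge = np.zeros(3, dtype=int)
    le = np.zeros(3, dtype=int)
    total = np.zeros(3, dtype=float)
    if not degenerate:
        for _ in range(n_perm):
            perm = rng.permutation(sexes)
            cnt = _join_counts(perm, edges)
            ge += cnt >= obs
            le += cnt <= obs
            total += cnt
    mk = lambda arr: {c: (None if degenerate else float(arr[i])) for i, c in enumerate(CATEGORIES)}
    return JoinCountResult(
        observed={c: int(obs[i]) for i, c in enumerate(CATEGORIES)},
        perm_mean={c: (None if degenerate else float(total[i] / n_perm)) for i, c in enumerate(CATEGORIES)},
        p_greater=mk((1 + ge) / (n_perm + 1)),
        p_less=mk((1 + le) / (n_perm + 1)),
        n_perm=n_perm,
        seed=seed,
    )


def _t_statistic(deg: np.ndarray, is_f: np.ndarray) -> float:
    """Pooled two-sample t for mean degree, F minus M.  Zero-variance
    samples with equal means give t = 0 (no signal)."""
    f, m = deg[is_f], deg[~is_f]
    diff = f.mean() - m.mean()
    nf, nm = len(f), len(m)
    sp2 = (((nf - 1) * f.var(ddof=1) if nf > 1 else 0.0)
           + ((nm - 1) * m.var(ddof=1) if nm > 1 else 0.0)) / (nf + nm - 2)
    se = np.sqrt(sp2 * (1 / nf + 1 / nm))
    if se == 0:
        return 0.0 if diff == 0 else np.sign(diff) * np.inf
    return float(diff / se)


@dataclass
class DegreeTestResult:
    degrees: dict[str, int]
    mean_f: float
    mean_m: float
    t_stat: float
    p_value: float
    tail: str
    n_perm: int
    seed: int | None
    null_t: list[float] = field(default_factory=list, repr=False)

    def to_json(self, path: str | Path) -> None:
        d = {k: v for k, v in self.__dict__.items() if k != "null_t"}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def degree_permutation_test(
    G: nx.Graph, tail: str = "greater", n_perm: int = 10000, seed: int | None = None
) -> DegreeTestResult:
    """Permutation test of sex differences in degree centrality.

    ``tail='greater'`` tests whether females are more central (mean
    female degree exceeds mean male degree); ``'less'`` the reverse.
    Degrees are fixed; sex labels are shuffled.
    """
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    nodes = sorted(G.nodes)
    sexes = np.array([G.nodes[n]["sex"] for n in nodes])
    if not (np.any(sexes == "F") and np.any(sexes == "M")):
        raise ValueError("degree test requires both sexes in the network")
    deg = np.array([G.degree(n) for n in nodes], dtype=float)
    is_f = sexes == "F"
    t_obs = _t_statistic(deg, is_f)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _t_statistic(deg, rng.permutation(is_f))
    if tail == "greater":
        extreme = int(np.sum(null >= t_obs))
    else:
        extreme = int(np.sum(null <= t_obs))
    return DegreeTestResult(
        degrees={n: int(d) for n, d in zip(nodes, deg)},
        mean_f=float(deg[is_f].mean()),
        mean_m=float(deg[~is_f].mean()),
        t_stat=t_obs,
        p_value=(1 + extreme) / (n_perm + 1),
        tail=tail,
        n_perm=n_perm,
        seed=seed,
        null_t=null.tolist(),
    )
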