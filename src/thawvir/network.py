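"""Gene-sharing network construction and viral-cluster assignment.

Genomes are profiled by their protein-cluster (PC) content; a pair of
genomes with ``a`` and ``b`` PCs sharing ``c`` of them, drawn from a
universe of ``n`` PCs, is scored by the hypergeometric tail probability
of sharing at least ``c``.  The similarity score is

    S = -log10(P * T),   T = N * (N - 1)

a Bonferroni-style correction by the number of ordered genome
comparisons; pairs with S >= 1 become weighted edges.  Markov clustering
(MCL) of the thresholded network yields viral clusters (VCs),
approximately genus-level groups; the inflation parameter is scanned over
a 21-value grid (1.0 to 5.0, step 0.2) and the partition maximising
weighted modularity is selected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

DEFAULT_INFLATION_GRID = tuple(round(1.0 + 0.2 * i, 1) for i in range(21))  # 1.0 .. 5.0


@dataclass
class ProteinCluster:
    """A protein family spanning >=2 genomes (the unit of gene sharing)."""

    id: str
    members: list[tuple[str, str]]  # (genome id, protein id)

    @property
    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}


@dataclass
class GenomeProfile:
    """PC content of one genome; singletons are proteins in no retained PC."""

    genome: str
    pc_set: frozenset[str]
    singleton_count: int = 0


@dataclass(frozen=True)
class SimilarityEdge:
    genome_a: str
    genome_b: str
    shared_pcs: int  # c
    p_value: float
    score: float  # S = -log10(p * T)


@dataclass
class ViralClusterAssignment:
    membership: dict[str, str]  # genome -> VC / doubleton / singleton label
    classes: dict[str, str]  # genome -> {"clustered", "doubleton", "singleton"}
    inflation: float  # selected optimum
    partitions: dict[float, list[frozenset[str]]]  # every grid value
    modularity: dict[float, float]
    edges: list[SimilarityEdge]


# ---------------------------------------------------------------------------
# hypergeometric scoring


def _check_hypergeom_args(a: int, b: int, c: int, n: int) -> None:
    if not (0 <= c <= min(a, b) and max(a, b) <= n and n > 0):
        raise ValueError(
            f"invalid hypergeometric arguments: a={a}, b={b}, c={c}, n={n} "
            "(require 0 <= c <= min(a,b) and a,b <= n)"
        )


def log_hypergeom_tail(a: int, b: int, c: int, n: int) -> float:
    """Natural-log upper-tail probability P(X >= c), X ~ Hypergeom(n, a, b).

    Computed by log-space summation of the pmf for numerical stability --
    tail probabilities underflow double precision long before the scores
    they feed stop being meaningful.
    """
    _check_hypergeom_args(a, b, c, n)
    if c == 0:
        return 0.0
    i = np.arange(c, min(a, b) + 1)
    return float(min(0.0, logsumexp(hypergeom.logpmf(i, n, a, b))))


def hypergeom_shared_pc_pvalue(a: int, b: int, c: int, n: int) -> float:
    """Probability of sharing >= c PCs by chance; symmetric in (a, b)."""
    return float(math.exp(log_hypergeom_tail(a, b, c, n)))


def similarity_score(
    p_value: float | None,
    n_genomes: int,
    *,
    log10_p: float | None = None,
) -> float:
    """S = -log10(P * T) with T = n_genomes * (n_genomes - 1) ordered pairs.

    Pass ``log10_p`` for tail probabilities that underflow to literal zero;
    a literal ``p_value == 0`` is rejected rather than silently producing
    an infinite score.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    T = n_genomes * (n_genomes - 1)
    if log10_p is None:
        if p_value is None or not (0 < p_value <= 1):
            raise ValueError(
                "p_value must be in (0, 1]; for underflowed tails pass log10_p "
                "from the log-space computation instead"
            )
        log10_p = math.log10(p_value)
    return -(log10_p + math.log10(T))


# ---------------------------------------------------------------------------
# Markov clustering


def mcl(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[frozenset[int]]:
    """Markov clustering of a weighted symmetric adjacency matrix.

    Self-loops are added internally with the column-maximum weight (floored
    at 1), the usual MCL convention: with weaker loops the diagonal of the
    expanded matrix exceeds the off-diagonals by (p_loop - p_edge)^2, so a
    high enough inflation shatters even a perfect clique into singletons,
    which makes the upper end of an inflation scan meaningless.  Columns
    are normalised to stochastic, and expansion (matrix squaring)
    alternates with inflation (elementwise power + renormalisation) and
    pruning until the matrix stops changing.  Clusters are read from the
    attractor rows of the limit matrix.  Deterministic.
    """
    A = np.array(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, rtol=1e-8, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency weights must be non-negative")
    n = A.shape[0]
    if n == 0:
        return []
    np.fill_diagonal(A, 0.0)
    np.fill_diagonal(A, np.maximum(A.max(axis=0), 1.0))
    M = A / A.sum(axis=0)
    for _ in range(max_iter):
        E = M @ M
        E = np.power(E, inflation)
        E[E < prune] = 0.0
        colsum = E.sum(axis=0)
        colsum[colsum == 0] = 1.0
        E /= colsum
        diff = np.abs(E - M).max()
        M = E
        if diff < tol:
            break
    # attractors: rows with mass on the diagonal; their support defines clusters
    eps = 1e-9
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for i in range(n):
        if M[i, i] > eps:
            for j in np.nonzero(M[i] > eps)[0]:
                union(i, int(j))
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=lambda s: min(s))


def _components(A: np.ndarray) -> list[list[int]]:
    """Connected components of a (symmetric) adjacency matrix, by min index."""
    n = A.shape[0]
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(A[i] > 0)[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        comps.append(sorted(comp))
    return comps


def cluster_graph(A: np.ndarray, inflation: float = 2.0) -> list[frozenset[int]]:
    """Partition a weighted graph: MCL within each connected component.

    Components of one or two nodes are their own clusters outright -- MCL
    on an isolated pair is degenerate (the column-stochastic matrix is
    nearly a permutation, whose powers oscillate toward the identity and
    split the pair) -- and larger components are partitioned by MCL on
    their submatrix.
    """
    clusters: list[frozenset[int]] = []
    for comp in _components(A):
        if len(comp) <= 2:
            clusters.append(frozenset(comp))
        else:
            sub = A[np.ix_(comp, comp)]
            for grp in mcl(sub, inflation=inflation):
                clusters.append(frozenset(comp[i] for i in grp))
    return sorted(clusters, key=min)


# ---------------------------------------------------------------------------
# protein clusters


def build_protein_clusters(
    protein_edges: pd.DataFrame,
    protein_genome: Mapping[str, str],
    min_bitscore: float = 50.0,
    max_evalue: float = 1e-4,
    inflation: float = 2.0,
) -> tuple[list[ProteinCluster], list[GenomeProfile]]:
    """MCL protein clustering of an all-vs-all similarity edge table.

    ``protein_edges`` needs columns query / subject / bitscore / evalue.
    Edges failing either threshold are dropped; self-edges are ignored with
    a warning.  Edges that pass contribute unit weight to the protein graph:
    the thresholds decide family membership, and residual bitscore variation
    (largely alignment-length noise) is not treated as affinity structure.
    PCs whose members span fewer than two genomes are demoted to singleton
    proteins and excluded from gene-sharing scoring.
    """
    required = {"query", "subject", "bitscore", "evalue"}
    missing = required - set(protein_edges.columns)
    if missing:
        raise ValueError(f"protein edge table missing columns: {sorted(missing)}")
    self_edges = protein_edges["query"] == protein_edges["subject"]
    if self_edges.any():
        warnings.warn(f"{int(self_edges.sum())} self-edges ignored")
    keep = (
        ~self_edges
        & (protein_edges.bitscore >= min_bitscore)
        & (protein_edges.evalue <= max_evalue)
    )
    edges = protein_edges[keep]

    proteins = sorted(protein_genome)
    pidx = {p: i for i, p in enumerate(proteins)}
    A = np.zeros((len(proteins), len(proteins)))
    for q, s in zip(edges["query"], edges["subject"]):
        if q not in pidx or s not in pidx:
            raise KeyError(f"edge references unknown protein: {q!r} / {s!r}")
        i, j = pidx[q], pidx[s]
        A[i, j] = A[j, i] = 1.0
    clusters = cluster_graph(A, inflation=inflation)

    pcs: list[ProteinCluster] = []
    clustered: dict[str, str] = {}
    serial = 0
    for grp in clusters:
        members = sorted(proteins[i] for i in grp)
        genomes = {protein_genome[p] for p in members}
        if len(members) >= 2 and len(genomes) >= 2:
            serial += 1
            pc_id = f"PC_{serial:04d}"
            pcs.append(ProteinCluster(id=pc_id, members=[(protein_genome[p], p) for p in members]))
            for p in members:
                clustered[p] = pc_id

    profiles: dict[str, dict] = {}
    for p in proteins:
        g = protein_genome[p]
        prof = profiles.setdefault(g, {"pcs": set(), "singletons": 0})
        if p in clustered:
            prof["pcs"].add(clustered[p])
        else:
            prof["singletons"] += 1
    genome_profiles = [
        GenomeProfile(genome=g, pc_set=frozenset(v["pcs"]), singleton_count=v["singletons"])
        for g, v in sorted(profiles.items())
    ]
    return pcs, genome_profiles


# ---------------------------------------------------------------------------
# viral clusters


def shared_pc_edges(
    profiles: Sequence[GenomeProfile],
    n_genomes: int | None = None,
    score_threshold: float = 1.0,
) -> list[SimilarityEdge]:
    """Hypergeometric-scored edges between genome profiles, thresholded at S."""
    if n_genomes is None:
        n_genomes = len(profiles)
    universe: set[str] = set()
    for p in profiles:
        universe |= p.pc_set
    n = len(universe)
    edges: list[SimilarityEdge] = []
    if n == 0 or n_genomes < 2:
        return edges
    ordered = sorted(profiles, key=lambda p: p.genome)
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            pi, pj = ordered[i], ordered[j]
            c = len(pi.pc_set & pj.pc_set)
            if c == 0:
                continue
            logp = log_hypergeom_tail(len(pi.pc_set), len(pj.pc_set), c, n)
            log10_p = logp / math.log(10)
            s = similarity_score(None, n_genomes, log10_p=log10_p)
            if s >= score_threshold:
                edges.append(
                    SimilarityEdge(
                        genome_a=pi.genome,
                        genome_b=pj.genome,
                        shared_pcs=c,
                        p_value=float(math.exp(logp)),
                        score=s,
                    )
                )
    return edges


def assign_viral_clusters(
    genome_profiles: Sequence[GenomeProfile],
    n_genomes: int | None = None,
    inflation_grid: Sequence[float] = DEFAULT_INFLATION_GRID,
    score_threshold: float = 1.0,
    min_cluster_size: int = 3,
) -> ViralClusterAssignment:
    """Build the S>=1 network, scan MCL inflation, and classify genomes.

    The optimum inflation is the grid value maximising weighted modularity
    of the resulting partition on the thresholded network (ties go to the
    smallest inflation); all partitions are retained so a user can pin a
    specific inflation instead.  Genomes in clusters of >= ``min_cluster_size``
    are "clustered" (assigned a VC id); exactly-two groups are doubletons;
    isolated genomes are singletons.
    """
    if not genome_profiles:
        raise ValueError("genome_profiles is empty")
    genomes = sorted(p.genome for p in genome_profiles)
    gidx = {g: i for i, g in enumerate(genomes)}
    edges = shared_pc_edges(genome_profiles, n_genomes, score_threshold)

    A = np.zeros((len(genomes), len(genomes)))
    G = nx.Graph()
    G.add_nodes_from(genomes)
    for e in edges:
        i, j = gidx[e.genome_a], gidx[e.genome_b]
        A[i, j] = A[j, i] = e.score
        G.add_edge(e.genome_a, e.genome_b, weight=e.score)

    partitions: dict[float, list[frozenset[str]]] = {}
    modularity: dict[float, float] = {}
    if not edges:
        warnings.warn("empty gene-sharing network: all genomes are singletons")
        part = [frozenset([g]) for g in genomes]
        for inf in inflation_grid:
            partitions[inf] = part
            modularity[inf] = 0.0
        best = inflation_grid[0]
    else:
        for inf in inflation_grid:
            clusters = cluster_graph(A, inflation=inf)
            part = [frozenset(genomes[i] for i in grp) for grp in clusters]
            partitions[inf] = part
            modularity[inf] = nx.community.modularity(G, part, weight="weight")
        best = max(inflation_grid, key=lambda inf: (modularity[inf], -inf))

    membership: dict[str, str] = {}
    classes: dict[str, str] = {}
    vc_serial = 0
    for grp in sorted(partitions[best], key=lambda s: sorted(s)[0]):
        if len(grp) >= min_cluster_size:
            vc_serial += 1
            label = f"VC_{vc_serial:03d}"
            cls = "clustered"
        elif len(grp) == 2:
            label = "doubleton_" + "_".join(sorted(grp))
            cls = "doubleton"
        else:
            label = f"singleton_{sorted(grp)[0]}"
            cls = "singleton"
        for g in grp:
            membership[g] = label
            classes[g] = cls
    return ViralClusterAssignment(
        membership=membership,
        classes=classes,
        inflation=float(best),
        partitions=partitions,
        modularity=modularity,
        edges=edges,
    )
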