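"""Two-step protein-family clustering.

Step one groups proteins into subfamilies by greedy set cover on a
filtered all-vs-all similarity graph (E-value <= 1e-3, coverage >= 0.5):
the node covering the most uncovered nodes (itself plus neighbours)
becomes a representative and claims them, ties broken by node id.

Step two clusters subfamilies into families by Markov clustering (MCL)
of a profile-profile similarity network: edges with probability >= 95%
and coverage >= 0.50 are kept, weighted probability/100 x coverage, and
MCL is run with inflation 2.0. Families are the MCL clusters; subfamilies
left out of the profile graph become families of their own. Families
always partition the input proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SimilarityEdge:
    query: str
    target: str
    evalue: float | None = None
    coverage: float = 0.0
    probability: float | None = None  # percent, profile edges only

    @property
    def weight(self) -> float:
        if self.probability is None:
            raise ValueError("weight defined for profile edges only")
        return (self.probability / 100.0) * self.coverage


@dataclass
class ProteinFamily:
    family_id: str
    subfamilies: list
    members: list
    singleton: bool = False


# ---------------------------------------------------------------------------
# Step 1: greedy set cover subfamilies
# ---------------------------------------------------------------------------

def subfamily_setcover(proteins: list, edges: list[SimilarityEdge],
                       evalue_max: float = 1e-3,
                       cov_min: float = 0.5) -> dict:
    """Greedy set-cover assignment of proteins to subfamily representatives.

    Edges failing the E-value or coverage filter are ignored. Repeatedly
    the node covering the most uncovered nodes (itself + neighbours) is
    selected as representative, ties by lexicographically smallest id;
    covered nodes are assigned to it. Isolated proteins become singleton
    subfamilies. Returns protein -> representative id.
    """
    adj: dict[str, set] = {p: set() for p in proteins}
    for e in edges:
        if e.query not in adj or e.target not in adj:
            raise ValueError(f"edge references unknown protein {e.query!r}/{e.target!r}")
        if e.evalue is not None and e.evalue > evalue_max:
            continue
        if e.coverage < cov_min:
            continue
        if e.query != e.target:
            adj[e.query].add(e.target)
            adj[e.target].add(e.query)
    uncovered = set(proteins)
    assignment: dict[str, str] = {}
    while uncovered:
        best = min(
            uncovered,
            key=lambda p: (-len(({p} | adj[p]) & uncovered), p))
        claimed = ({best} | adj[best]) & uncovered
        for p in claimed:
            assignment[p] = best
        uncovered -= claimed
    return assignment


# ---------------------------------------------------------------------------
# Step 2: Markov clustering
# ---------------------------------------------------------------------------

@dataclass
class MCLResult:
    clusters: list  # list of node-id lists
    converged: bool
    n_iter: int
    column_sum_error: float  # max |column sum - 1| observed after normalizations


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0] = 1.0
    return m / sums


def mcl(nodes: list, edges: list[SimilarityEdge], inflation: float = 2.0,
        prob_min: float = 95.0, cov_min: float = 0.5,
        max_iter: int = 100, tol: float = 1e-6,
        prune: float = 1e-5, add_self_loops: bool = True) -> MCLResult:
    """Markov clustering of the subfamily profile-similarity network.

    Profile edges with probability >= ``prob_min`` (percent) and coverage
    >= ``cov_min`` enter the graph weighted probability/100 x coverage.
    Self-loops are added with each node's maximum incident weight (1.0
    for isolated nodes). The column-stochastic matrix is alternately
    expanded (squared) and inflated (element-wise power then
    renormalized), with entries below ``prune`` dropped, until the matrix
    changes by less than ``tol`` or ``max_iter`` is reached. Clusters are
    read from attractor rows; nodes claimed by several attractors go to
    the one with the larger mass (ties: lower row index).
    """
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for e in edges:
        if e.probability is None:
            continue
        if e.probability < prob_min or e.coverage < cov_min:
            continue
        i, j = idx[e.query], idx[e.target]
        w = e.weight
        m[i, j] = max(m[i, j], w)
        m[j, i] = max(m[j, i], w)
    if add_self_loops:
        for i in range(n):
            inc = m[i].max()
            m[i, i] = inc if inc > 0 else 1.0
    m = _normalize_columns(m)
    col_err = float(np.abs(m.sum(axis=0) - 1.0).max()) if n else 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = m @ m  # expansion
        m = np.power(m, inflation)  # inflation
        m[m < prune] = 0.0
        m = _normalize_columns(m)
        col_err = max(col_err, float(np.abs(m.sum(axis=0) - 1.0).max()))
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged and n:
        import warnings

        warnings.warn(f"MCL did not converge in {max_iter} iterations")
    # attractors: rows with a positive diagonal entry
    attractors = [i for i in range(n) if m[i, i] > 0]
    owner = {}
    for i in attractors:
        for j in np.flatnonzero(m[i] > 0):
            j = int(j)
            cur = owner.get(j)
            if cur is None or m[i, j] > m[cur, j] or (
                    m[i, j] == m[cur, j] and i < cur):
                owner[j] = i
    clusters_by_attr: dict[int, list] = {}
    for j in range(n):
        a = owner.get(j, j)  # unclaimed nodes (fully pruned) stand alone
        clusters_by_attr.setdefault(a, []).append(j)
    clusters = sorted(
        (sorted(nodes[j] for j in members) for members in clusters_by_attr.values()),
        key=lambda c: c[0])
    return MCLResult(clusters=clusters, converged=converged, n_iter=it,
                     column_sum_error=col_err)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_families(subfamilies: dict, mcl_clusters: list) -> list[ProteinFamily]:
    """Merge co-clustered subfamilies into protein families.

    ``subfamilies`` maps protein -> subfamily representative;
    ``mcl_clusters`` is a list of lists of subfamily representatives.
    Every subfamily must occur in at most one cluster; representatives
    absent from all clusters become families of their own. The resulting
    families partition the proteins exactly.
    """
    members_by_rep: dict[str, list] = {}
    for prot, rep in subfamilies.items():
        members_by_rep.setdefault(rep, []).append(prot)
    seen: dict[str, int] = {}
    for ci, cluster in enumerate(mcl_clusters):
        for rep in cluster:
            if rep in seen:
                raise ValueError(
                    f"subfamily {rep!r} appears in clusters {seen[rep]} and {ci}; "
                    "families must partition proteins")
            seen[rep] = ci
    families = []
    used_reps = set()
    for ci, cluster in enumerate(mcl_clusters):
        reps = [r for r in cluster if r in members_by_rep]
        if not reps:
            continue
        members = sorted(p for r in reps for p in members_by_rep[r])
        used_reps.update(reps)
        families.append(ProteinFamily(
            family_id=f"fam_{min(reps)}", subfamilies=sorted(reps),
            members=members, singleton=len(members) == 1))
    for rep in sorted(set(members_by_rep) - used_reps):
        members = sorted(members_by_rep[rep])
        families.append(ProteinFamily(
            family_id=f"fam_{rep}", subfamilies=[rep], members=members,
            singleton=len(members) == 1))
    families.sort(key=lambda f: f.family_id)
    all_members = [p for f in families for p in f.members]
    if len(all_members) != len(set(all_members)) or set(all_members) != set(subfamilies):
        raise AssertionError("families do not partition the input proteins")
    return families


def cluster_proteins(proteins: list, protein_edges: list[SimilarityEdge],
                     profile_edges: list[SimilarityEdge],
                     inflation: float = 2.0, evalue_max: float = 1e-3,
                     cov_min: float = 0.5, prob_min: float = 95.0):
    """Run the full two-step procedure; returns (families, subfamilies, mcl)."""
    sub = subfamily_setcover(proteins, protein_edges, evalue_max, cov_min)
    reps = sorted(set(sub.values()))
    res = mcl(reps, profile_edges, inflation=inflation, prob_min=prob_min,
              cov_min=cov_min)
    fams = assemble_families(sub, res.clusters)
    return fams, sub, res


# ---------------------------------------------------------------------------
# Edge-table I/O
# ---------------------------------------------------------------------------

def edges_from_table(df: pd.DataFrame) -> list[SimilarityEdge]:
    """Build edges from a TSV-backed table with columns
    query, target, evalue, coverage, probability (extra columns ignored;
    missing evalue/probability allowed)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(SimilarityEdge(
            query=str(row.query), target=str(row.target),
            evalue=None if pd.isna(getattr(row, "evalue", np.nan)) else float(row.evalue),
            coverage=float(row.coverage),
            probability=None if pd.isna(getattr(row, "probability", np.nan))
            else float(row.probability)))
    return out
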