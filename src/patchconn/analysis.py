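"""Downstream group analyses on connectivity networks.

Three complementary views of group differences:

* projection of individual node patterns onto the healthy-group mean
  connectome (scores c_i(u), far from 1 = altered) with one-sided rank-sum
  tests, Bonferroni-corrected over the node family;
* comparison of per-subject network strength (mean |entry|) between a
  reference group and each other group, one-sided rank-sum;
* classical (Torgerson) multidimensional scaling of group-mean
  (sub)connectomes under the mean-absolute-difference matrix distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from patchconn.errors import DesignError, ValidationError
from patchconn.mdmr import _as_stack, pattern_rows
from patchconn.network import ConnectivityMatrix

#: Combined sample size up to which the rank-sum null is enumerated exactly.
EXACT_RANKSUM_LIMIT = 25


def group_mean_connectome(connectomes) -> np.ndarray:
    """Entry-wise mean of the group's connectivity matrices."""
    stack = _as_stack(connectomes)
    if stack.shape[0] < 1:
        raise ValidationError("need at least one subject")
    return stack.mean(axis=0)


def projection_scores(
    connectomes, reference: np.ndarray, node: int,
    include_diagonal: bool = True,
) -> np.ndarray:
    """Pearson correlation c_i(u) of each subject's node pattern with the
    reference (healthy mean) pattern h for that node.

    Scores near 1 mean the subject's connectivity map of this node looks
    healthy; the farther from 1, the more altered.
    """
    reference = np.asarray(reference, dtype=float)
    rows = pattern_rows(connectomes, node, include_diagonal)
    h = reference[node, :]
    if not include_diagonal:
        h = np.delete(h, node)
    if rows.shape[1] != h.shape[0]:
        raise ValidationError("reference connectome size does not match subjects")
    h_c = h - h.mean()
    h_norm = np.linalg.norm(h_c)
    if h_norm == 0.0:
        raise ValidationError(f"node {node}: constant reference pattern")
    z = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    if (norms == 0.0).any():
        bad = int(np.flatnonzero(norms == 0.0)[0])
        raise ValidationError(
            f"subject {bad}, node {node}: constant connectivity pattern"
        )
    return np.clip(z @ h_c / (norms * h_norm), -1.0, 1.0)


def rank_sum_one_sided(x, y) -> float:
    """One-sided Wilcoxon rank-sum p against 'median of x > median of y'.

    Exact null enumeration when the combined sample is small and tie-free,
    otherwise the normal approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DesignError("each group needs >= 2 values for the rank-sum test")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact" if (x.size + y.size) <= EXACT_RANKSUM_LIMIT and not has_ties
        else "asymptotic"
    )
    return float(mannwhitneyu(x, y, alternative="greater", method=method).pvalue)


def compare_projection(
    scores_a, scores_b, n_nodes_family: int, alpha: float = 0.01,
) -> pd.DataFrame:
    """Node-wise one-sided rank-sum test on projection scores.

    ``scores_a`` / ``scores_b`` are (n_nodes, n_subjects) arrays (or lists of
    per-node score vectors). The alternative is that group A's scores are
    stochastically larger (A = the less-altered group, e.g. the MCI
    non-converters). A node is significant iff p <= alpha / n_nodes_family
    (Bonferroni over the full node family, by default the grid's N).
    """
    sa = [np.asarray(s, float) for s in scores_a]
    sb = [np.asarray(s, float) for s in scores_b]
    if len(sa) != len(sb):
        raise ValidationError("score sets cover different node counts")
    if n_nodes_family < 1:
        raise ValidationError("n_nodes_family must be positive")
    p = np.array([rank_sum_one_sided(a, b) for a, b in zip(sa, sb)])
    thresh = alpha / n_nodes_family
    return pd.DataFrame({
        "node": np.arange(len(sa)),
        "p": p,
        "significant": p <= thresh,
    })


def compare_strength(
    strengths_by_group: dict, reference_group: str,
) -> pd.DataFrame:
    """One-sided rank-sum of per-subject network strength.

    Tests, for each non-reference group, the alternative that the reference
    group's strengths come from a distribution with higher median.
    """
    if reference_group not in strengths_by_group:
        raise ValidationError(f"reference group {reference_group!r} not present")
    ref = np.asarray(strengths_by_group[reference_group], dtype=float)
    rows = []
    for group, values in strengths_by_group.items():
        if group == reference_group:
            continue
        rows.append({
            "group": group,
            "n_ref": ref.size,
            "n_group": np.asarray(values).size,
            "p": rank_sum_one_sided(ref, values),
        })
    return pd.DataFrame(rows)


def matrix_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute entry-wise difference between two (sub)matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def classical_mds(
    distances: np.ndarray, n_dims: int = 2,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and embeds on the
    top ``n_dims`` non-negative eigenvalues. Returns (coordinates centered at
    the origin, all eigenvalues in descending order, strain). Strain is the
    fraction of total |eigenvalue| mass not captured by the used axes; it is
    0 exactly when the configuration is Euclidean-embeddable in n_dims.
    """
    D = np.asarray(distances, dtype=float)
    m = D.shape[0]
    if D.ndim != 2 or D.shape[1] != m:
        raise ValidationError(f"distance matrix must be square, got {D.shape}")
    if m < 2:
        raise DesignError("need at least 2 points for an MDS layout")
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    used = np.maximum(eigval[:n_dims], 0.0)
    coords = eigvec[:, :n_dims] * np.sqrt(used)[None, :]
    total = np.abs(eigval).sum()
    strain = float(1.0 - used.sum() / total) if total > 0 else 0.0
    return coords, eigval, strain


def groups_mds(
    mean_matrices: dict, node_subset=None, n_dims: int = 2,
) -> tuple[pd.DataFrame, float]:
    """Embed group-mean (sub)connectomes in n_dims by classical MDS.

    ``mean_matrices`` maps group label -> N x N mean connectome. If
    ``node_subset`` is given, each matrix is restricted to those rows (a
    k x N submatrix) before computing the pairwise mean-absolute-difference
    distances. Orientation is fixed by requiring the first group's coordinate
    to be non-negative on every axis.
    """
    groups = list(mean_matrices)
    if len(groups) < 2:
        raise DesignError("need at least 2 groups for an MDS layout")
    mats = []
    for g in groups:
        M = np.asarray(mean_matrices[g], dtype=float)
        if node_subset is not None:
            M = M[np.asarray(sorted(node_subset), dtype=int), :]
        mats.append(M)
    m = len(groups)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = matrix_distance(mats[i], mats[j])
    coords, _, strain = classical_mds(D, n_dims=n_dims)
    for axis in range(coords.shape[1]):  # deterministic sign convention
        if coords[0, axis] < 0:
            coords[:, axis] = -coords[:, axis]
    table = pd.DataFrame(coords, columns=[f"dim{k + 1}" for k in range(n_dims)])
    table.insert(0, "group", groups)
    return table, strain


def overlap_report(significant_sets: dict) -> dict:
    """Set-algebra bookkeeping over named significant-node sets.

    Reports per-set counts, all pairwise intersections and differences, and
    the global union/intersection — the usual summary when several pairwise
    group comparisons are read together.
    """
    sets = {name: set(int(i) for i in s) for name, s in significant_sets.items()}
    names = list(sets)
    report: dict = {
        "counts": {name: len(s) for name, s in sets.items()},
        "pairwise": {},
    }
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            report["pairwise"][f"{a} & {b}"] = {
                "intersection": sorted(sets[a] & sets[b]),
                "n_intersection": len(sets[a] & sets[b]),
                f"only_{a}": sorted(sets[a] - sets[b]),
                f"only_{b}": sorted(sets[b] - sets[a]),
            }
    if names:
        union = set().union(*sets.values())
        common = set(sets[names[0]])
        for name in names[1:]:
            common &= sets[name]
    else:
        union, common = set(), set()
    report["union"] = sorted(union)
    report["common_to_all"] = sorted(common)
    return report


def strengths_by_group(connectomes, labels) -> dict:
    """Per-subject mean strength grouped by label (helper for the pipeline)."""
    from patchconn.network import mean_strength

    stack = _as_stack(connectomes)
    out: dict = {}
    for mat, lab in zip(stack, labels):
        out.setdefault(lab, []).append(mean_strength(mat))
    return {k: np.asarray(v) for k, v in out.items()}
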