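"""Node-wise multivariate distance matrix regression (MDMR).

For each network node i, the "connectivity pattern" of a subject is row i of
their N x N connectivity matrix. Subjects u, v are compared through

    d_uv = sqrt(2 * (1 - r_uv))

where r_uv is the Pearson (or Spearman) correlation of the two patterns.
This distance is exactly the Euclidean distance between the z-scored,
sqrt(length)-normalized pattern vectors, so the ANOVA-like decomposition
below is a genuine sum-of-squares partition:

    SST = (1/n)   * sum_{u<v} d_uv^2
    SSW = sum_g (1/n_g) * sum_{u<v in g} d_uv^2
    SSA = SST - SSW
    F   = (n - 1) * SSA / SSW

F is not Fisher-F distributed; significance comes from a label-permutation
null, and the node family is corrected with Benjamini-Hochberg FDR.

The (n - 1) scaling differs from the conventional PERMANOVA normalization
F' = [SSA/(k-1)] / [SSW/(n-k)] only by a constant given n and k, and F is a
strictly decreasing function of SSW at fixed SST, so permutation p-values
under either scaling are identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from patchconn._util import as_seed_sequence
from patchconn.errors import (
    DegenerateDataError,
    DesignError,
    ParameterError,
    ValidationError,
)
from patchconn.network import ConnectivityMatrix

_KINDS = ("pearson", "spearman")

#: Relative tolerance used when counting permutation statistics >= observed;
#: guards against float round-off when permuted designs tie the observed one.
_F_TIE_RTOL = 1e-10


def _as_stack(connectomes) -> np.ndarray:
    """Stack connectomes into an (n_subjects, N, N) array."""
    if isinstance(connectomes, np.ndarray) and connectomes.ndim == 3:
        return np.asarray(connectomes, dtype=float)
    mats = [
        c.values if isinstance(c, ConnectivityMatrix) else np.asarray(c, float)
        for c in connectomes
    ]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValidationError(f"connectomes have mixed shapes: {sorted(shapes)}")
    return np.stack(mats)


def _group_index(labels) -> tuple[np.ndarray, list]:
    """Integer group codes (in order of first appearance) and group names."""
    labels = list(labels)
    names: list = []
    codes = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in names:
            names.append(lab)
        codes[i] = names.index(lab)
    return codes, names


@dataclass
class NodeDistanceMatrix:
    """Inter-subject distance matrix for one node's connectivity patterns."""

    node: int
    values: np.ndarray  # (n, n), symmetric, zero diagonal, entries in [0, 2]
    kind: str = "pearson"

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def pattern_rows(
    connectomes, node: int, include_diagonal: bool = True
) -> np.ndarray:
    """Each subject's node-``node`` connectivity pattern as a row.

    The pattern is row ``node`` of the subject's matrix, over all N columns.
    The own diagonal entry (always 1) is included by default; since it is the
    same constant for every subject it barely moves the correlations, but an
    exclude option is provided.
    """
    stack = _as_stack(connectomes)
    rows = stack[:, node, :]
    if not include_diagonal:
        rows = np.delete(rows, node, axis=1)
    return rows


def node_distance_matrix(
    connectomes,
    node: int,
    kind: str = "pearson",
    include_diagonal: bool = True,
) -> NodeDistanceMatrix:
    """Pairwise subject distances d = sqrt(2(1 - r)) for one node.

    ``kind`` selects Pearson correlation of the raw patterns or Spearman rank
    correlation (average ranks for ties).
    """
    if kind not in _KINDS:
        raise ParameterError(f"kind must be one of {_KINDS}, got {kind!r}")
    rows = pattern_rows(connectomes, node, include_diagonal)
    if rows.shape[0] < 2:
        raise DesignError("need at least 2 subjects")
    if kind == "spearman":
        rows = rankdata(rows, axis=1)
    sd = rows.std(axis=1)
    if (sd == 0.0).any():
        bad = int(np.flatnonzero(sd == 0.0)[0])
        raise DegenerateDataError(
            f"subject {bad}, node {node}: constant connectivity pattern, "
            f"correlation undefined"
        )
    z = rows - rows.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    r = np.clip(z @ z.T, -1.0, 1.0)
    d = np.sqrt(np.maximum(2.0 * (1.0 - r), 0.0))
    np.fill_diagonal(d, 0.0)
    return NodeDistanceMatrix(node=node, values=d, kind=kind)


def _d2(D) -> np.ndarray:
    values = D.values if isinstance(D, NodeDistanceMatrix) else np.asarray(D, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"distance matrix must be square, got {values.shape}")
    return values ** 2


def total_sum_squares(D) -> float:
    """SST = (1/n) * sum over unordered subject pairs of squared distance."""
    d2 = _d2(D)
    n = d2.shape[0]
    return float(d2.sum() / 2.0 / n)


def _check_design(codes: np.ndarray) -> np.ndarray:
    sizes = np.bincount(codes)
    if len(sizes) < 2:
        raise DesignError("need at least 2 groups")
    if (sizes < 2).any():
        raise DesignError(
            f"every group needs >= 2 subjects (pseudo-F undefined); "
            f"got sizes {sizes.tolist()}"
        )
    return sizes


def within_sum_squares(D, labels) -> float:
    """SSW = sum over groups g of (1/n_g) * sum of within-g squared distances."""
    d2 = _d2(D)
    codes, _ = _group_index(labels)
    if len(codes) != d2.shape[0]:
        raise ValidationError("labels length does not match distance matrix")
    sizes = _check_design(codes)
    ssw = 0.0
    for g, n_g in enumerate(sizes):
        member = codes == g
        ssw += d2[np.ix_(member, member)].sum() / 2.0 / n_g
    return float(ssw)


def pseudo_f(D, labels) -> tuple[float, float, float, float]:
    """Sum-of-squares decomposition and pseudo-F for a categorical design.

    Returns (SST, SSW, SSA, F) with SSA = SST - SSW and F = (n-1)*SSA/SSW.
    A perfectly separated design (SSW = 0, SSA > 0) returns F = +inf; an
    all-zero distance matrix is a degenerate design.
    """
    d2 = _d2(D)
    n = d2.shape[0]
    sst = total_sum_squares(d2 ** 0.5)
    ssw = within_sum_squares(d2 ** 0.5, labels)
    ssa = sst - ssw
    if abs(ssa) < 1e-12 * max(sst, 1.0):
        ssa = max(ssa, 0.0)
    if ssw == 0.0:
        if ssa > 0.0:
            return sst, ssw, ssa, float("inf")
        raise DegenerateDataError(
            "all distances are zero: pseudo-F undefined"
        )
    return sst, ssw, ssa, float((n - 1) * ssa / ssw)


def _ssw_for_codes(d2: np.ndarray, code_rows: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Vectorized SSW for many label assignments.

    ``code_rows`` is (m, n) of integer group codes; returns (m,) SSW values.
    Uses SSW = sum_g (1/n_g) * (x_g^T d2 x_g) / 2 with x_g the 0/1 member
    indicator of group g.
    """
    m = code_rows.shape[0]
    ssw = np.zeros(m)
    for g, n_g in enumerate(sizes):
        member = (code_rows == g).astype(float)  # (m, n)
        ssw += np.einsum("pi,ij,pj->p", member, d2, member) / (2.0 * n_g)
    return ssw


def permutation_test(
    D,
    labels,
    n_perm: int = 9999,
    seed=None,
    add_one: bool = True,
) -> tuple[float, float]:
    """Permutation p-value of the pseudo-F statistic.

    Subject labels are shuffled uniformly at random ``n_perm`` times; SST is
    permutation-invariant so only SSW is recomputed. By default the p-value
    uses the add-one, >= convention p = (1 + #{F_perm >= F_obs}) / (1 + n_perm),
    which is a valid p in (0, 1]. ``add_one=False`` gives the plain
    #{F_perm > F_obs} / n_perm count instead.

    Returns (F_obs, p).
    """
    if n_perm < 99:
        raise ParameterError(f"n_perm must be >= 99, got {n_perm}")
    d2 = _d2(D)
    n = d2.shape[0]
    codes, _ = _group_index(labels)
    if len(codes) != n:
        raise ValidationError("labels length does not match distance matrix")
    sizes = _check_design(codes)

    sst = float(d2.sum() / 2.0 / n)
    if sst == 0.0:
        raise DegenerateDataError("all distances are zero: pseudo-F undefined")

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_codes = codes[order]
    all_codes = np.vstack([codes[None, :], perm_codes])
    ssw = _ssw_for_codes(d2, all_codes, sizes)
    ssa = sst - ssw
    with np.errstate(divide="ignore"):
        f_all = np.where(ssw > 0.0, (n - 1) * ssa / np.where(ssw > 0, ssw, 1.0), np.inf)
    f_obs, f_perm = f_all[0], f_all[1:]

    tol = _F_TIE_RTOL * max(abs(f_obs), 1.0) if np.isfinite(f_obs) else 0.0
    if add_one:
        k = int(np.sum(f_perm >= f_obs - tol))
        p = (1.0 + k) / (1.0 + n_perm)
    else:
        k = int(np.sum(f_perm > f_obs + tol))
        p = k / n_perm
    return float(f_obs), float(p)


def fdr_correct(p_values, alpha: float = 0.01):
    """Benjamini-Hochberg step-up over the node family.

    Returns (q_values, significant_mask) with significance at q <= alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class MdmrResult:
    """Per-node MDMR table plus the run's settings."""

    table: pd.DataFrame  # node, SST, SSW, SSA, F, p, q, significant
    kind: str
    n_perm: int
    alpha: float
    seed: object

    @property
    def significant_nodes(self) -> set[int]:
        return set(self.table.loc[self.table["significant"], "node"].astype(int))


def run_mdmr(
    connectomes,
    labels,
    kind: str = "pearson",
    n_perm: int = 9999,
    alpha: float = 0.01,
    seed=None,
    include_diagonal: bool = True,
    n_jobs: int = 1,
) -> MdmrResult:
    """Full node-wise MDMR: distances -> permutation p per node -> FDR.

    Each node draws its permutations from an independent stream spawned from
    the master seed, so results are reproducible and independent of the
    number of workers.
    """
    stack = _as_stack(connectomes)
    n, N, _ = stack.shape
    codes, _ = _group_index(labels)
    if len(codes) != n:
        raise ValidationError("labels length does not match number of subjects")
    _check_design(codes)

    node_seeds = as_seed_sequence(seed).spawn(N)

    def one_node(i: int):
        D = node_distance_matrix(stack, i, kind=kind,
                                 include_diagonal=include_diagonal)
        sst, ssw, ssa, f = pseudo_f(D, labels)
        if ssa < -1e-9 * max(sst, 1.0):  # Euclidean embeddability guarantee
            raise DegenerateDataError(
                f"node {i}: negative between-group sum of squares ({ssa})"
            )
        _, p = permutation_test(D, labels, n_perm=n_perm, seed=node_seeds[i])
        return sst, ssw, ssa, f, p

    if n_jobs != 1:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=n_jobs)(
            delayed(one_node)(i) for i in range(N)
        )
    else:
        records = [one_node(i) for i in range(N)]

    table = pd.DataFrame(
        records, columns=["SST", "SSW", "SSA", "F", "p"]
    )
    table.insert(0, "node", np.arange(N))
    q, reject = fdr_correct(table["p"].to_numpy(), alpha=alpha)
    table["q"] = q
    table["significant"] = reject
    return MdmrResult(table=table, kind=kind, n_perm=n_perm, alpha=alpha,
                      seed=seed)
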