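"""Group-level inference: GLM contrasts, NBS, Yeo summaries, clinical association.

All edge-wise and feature-wise models are ordinary least squares with
the group contrast plus protected covariates; NBS controls the
familywise error of connected suprathreshold components by permuting
group labels and recording the maximal component size per permutation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from iscn.cohort import NetworkAssignment, YEO_LABELS


def _covariate_design(phenotype: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = []
    for c in covariates:
        v = phenotype[c]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(float)[:, None])
        else:
            cols.append(pd.get_dummies(v, drop_first=True).to_numpy(float))
    if not cols:
        return np.empty((len(phenotype), 0))
    return np.hstack(cols)


def _group_design(phenotype: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """[intercept, patient indicator, covariates...]"""
    n = len(phenotype)
    group = (phenotype["group"].to_numpy() == "patient").astype(float)
    x = np.hstack([np.ones((n, 1)), group[:, None], _covariate_design(phenotype, covariates)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear design: group/covariates are confounded")
    return x


def _ols_group_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized OLS of every column of y on x; returns the group
    (column 1) estimate, its t statistic, the residual SD, and the dof."""
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * xtx_inv[1, 1])
        t = np.where(se > 0, beta[1] / se, np.nan)
    return beta[1], t, np.sqrt(sigma2), dof


def glm_compare(
    features: pd.DataFrame,
    phenotype: pd.DataFrame,
    covariates: Sequence[str] = ("age", "gender"),
    family: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Case-control GLM per feature with Bonferroni correction.

    Fits feature ~ group + covariates by OLS; reports the patient-minus-
    control contrast, its t and two-tailed p, Cohen's d (contrast divided
    by the residual SD), and the Bonferroni flag p < alpha / family.
    ``family`` defaults to the number of features tested.  Constant
    features get NaN statistics rather than a spurious p.
    """
    x = _group_design(phenotype, covariates)
    y = features.to_numpy(float)
    est, t, resid_sd, dof = _ols_group_t(x, y)
    degenerate = y.std(axis=0) == 0
    est = np.where(degenerate, np.nan, est)
    t = np.where(degenerate, np.nan, t)
    resid_sd = np.where(degenerate, np.nan, resid_sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = 2 * stats.t.sf(np.abs(t), dof)
        d = np.where(resid_sd > 0, est / resid_sd, np.nan)
    fam = family if family is not None else features.shape[1]
    out = pd.DataFrame(
        {
            "estimate": est,
            "t": t,
            "p": p,
            "cohens_d": d,
            "bonferroni_family": fam,
            "significant": p < alpha / fam,
        },
        index=features.columns,
    )
    out.index.name = "feature"
    return out


@dataclasses.dataclass
class NbsComponent:
    nodes: list[int]          # region labels
    edges: list[tuple[int, int]]
    size: int                 # edge count (component extent)
    p: float
    significant: bool


@dataclasses.dataclass
class NbsResult:
    direction: str            # "increased" or "decreased"
    components: list[NbsComponent]
    null_max_sizes: np.ndarray
    edge_p: float
    alpha: float

    @property
    def significant_components(self) -> list[NbsComponent]:
        return [c for c in self.components if c.significant]


def _components_from_edges(mask: np.ndarray, iu: np.ndarray, ju: np.ndarray, r: int):
    """Connected components (BFS on the sparse graph) of suprathreshold
    edges; returns (component label per edge, sizes as edge counts)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None, np.array([], dtype=int)
    a = csr_matrix(
        (np.ones(idx.size), (iu[idx], ju[idx])), shape=(r, r)
    )
    _, node_labels = connected_components(a + a.T, directed=False)
    edge_labels = node_labels[iu[idx]]
    sizes = np.bincount(edge_labels, minlength=node_labels.max() + 1)
    return (idx, edge_labels), sizes


def nbs(
    edges: pd.DataFrame,
    phenotype: pd.DataFrame,
    covariates: Sequence[str] = ("age", "gender"),
    region_ids: Sequence[int] | None = None,
    edge_p: float = 0.001,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    scheme: str = "labels",
) -> dict[str, NbsResult]:
    """Network-based statistics on the R(R-1)/2 harmonized edge features.

    (1) edge-wise OLS t statistics for the patient-control contrast with
    covariates; (2) suprathreshold edges taken separately for positive
    and negative t beyond the two-tailed ``edge_p`` critical value;
    (3) connected components of each suprathreshold graph; (4) the null
    is built from ``n_perm`` permutations (the first is the identity, so
    corrected p >= 1/n_perm), recording the maximal component size per
    direction; (5) components whose size ranks in the top ``alpha`` of
    the max-size null reported significant.

    ``scheme="labels"`` (classic) permutes group labels only, covariates
    staying attached to subjects; ``scheme="freedman-lane"`` permutes the
    residuals of the covariate-only model and adds back its fitted
    values before recomputing the statistics.

    Returns one :class:`NbsResult` per direction ("increased" = patient
    > control).
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is too small for stable NBS p-values", stacklevel=2)
    y = edges.to_numpy(float)
    n, n_edges = y.shape
    r = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if r * (r - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} edge columns is not R(R-1)/2 for integer R")
    if region_ids is None:
        region_ids = list(range(1, r + 1))
    iu, ju = np.triu_indices(r, 1)

    if scheme not in ("labels", "freedman-lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    x = _group_design(phenotype, covariates)
    _, t_obs, _, dof = _ols_group_t(x, y)
    crit = stats.t.ppf(1 - edge_p / 2, dof)

    if scheme == "freedman-lane":
        # reduced model: intercept + covariates (group column dropped)
        z = np.delete(x, 1, axis=1)
        proj = z @ np.linalg.solve(z.T @ z, z.T)
        fitted = proj @ y
        resid = y - fitted

    rng = np.random.default_rng(seed)
    group = x[:, 1].copy()
    null_max = {"increased": np.zeros(n_perm, dtype=int), "decreased": np.zeros(n_perm, dtype=int)}
    for b in range(n_perm):
        if b == 0:
            t_b = t_obs  # identity permutation
        elif scheme == "labels":
            xp = x.copy()
            xp[:, 1] = group[rng.permutation(n)]
            _, t_b, _, _ = _ols_group_t(xp, y)
        else:
            y_b = fitted + resid[rng.permutation(n)]
            _, t_b, _, _ = _ols_group_t(x, y_b)
        for direction, mask in (("increased", t_b > crit), ("decreased", t_b < -crit)):
            _, sizes = _components_from_edges(mask, iu, ju, r)
            null_max[direction][b] = sizes.max() if sizes.size else 0

    results = {}
    for direction, mask in (("increased", t_obs > crit), ("decreased", t_obs < -crit)):
        comp, sizes = _components_from_edges(mask, iu, ju, r)
        comps: list[NbsComponent] = []
        if comp is not None:
            idx, edge_labels = comp
            for lab in np.unique(edge_labels):
                e_idx = idx[edge_labels == lab]
                e_list = [(region_ids[iu[e]], region_ids[ju[e]]) for e in e_idx]
                nodes = sorted({v for e in e_list for v in e})
                size = len(e_list)
                p = float(np.mean(null_max[direction] >= size))
                comps.append(
                    NbsComponent(nodes, e_list, size, p, significant=p <= alpha)
                )
        comps.sort(key=lambda c: (-c.size, c.nodes))
        results[direction] = NbsResult(direction, comps, null_max[direction], edge_p, alpha)
    return results


def summarize_networks(
    component: NbsComponent,
    assignment: NetworkAssignment,
) -> dict[str, pd.DataFrame | pd.Series]:
    """Yeo-network connection weights of one significant component.

    weight(A, B) = (# component edges joining networks A and B) divided
    by the maximum possible number of such connections given the full
    parcellation: n_A * n_B between distinct networks and
    n_A (n_A - 1) / 2 within a network.  Also returns the per-network
    weight sums (row sums including the within-network cell).
    """
    for node in component.nodes:
        if node not in assignment:
            raise ValueError(f"component node {node} has no network assignment")
    labels = list(YEO_LABELS)
    n_per = {lab: sum(1 for v in assignment.mapping.values() if v == lab) for lab in labels}
    counts = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in component.edges:
        la, lb = assignment[a], assignment[b]
        counts.loc[la, lb] += 1
        if la != lb:
            counts.loc[lb, la] += 1
    weights = counts.copy()
    for la in labels:
        for lb in labels:
            if la == lb:
                denom = n_per[la] * (n_per[la] - 1) / 2
            else:
                denom = n_per[la] * n_per[lb]
            weights.loc[la, lb] = counts.loc[la, lb] / denom if denom > 0 else 0.0
    return {"weights": weights, "network_sums": weights.sum(axis=1)}


def clinical_association(
    features: pd.DataFrame,
    phenotype: pd.DataFrame,
    score: str = "hamd17",
    covariates: Sequence[str] = ("age", "gender"),
    family: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial Pearson correlation of each feature with a clinical score.

    Both feature and score are residualized on the covariates (with
    intercept); r is the Pearson correlation of the residuals, with
    two-tailed p on n - k - 2 degrees of freedom (k = number of
    covariate regressors) and a Bonferroni flag over ``family``
    (defaults to the number of features).
    """
    s = phenotype[score].to_numpy(float)
    keep = ~np.isnan(s)
    s = s[keep]
    y = features.to_numpy(float)[keep]
    cov = _covariate_design(phenotype.loc[keep].reset_index(drop=True), covariates)
    n, k = cov.shape
    if n <= k + 2:
        raise ValueError(f"n={n} too small for partial correlation with {k} covariates")
    x = np.hstack([np.ones((n, 1)), cov])
    proj = x @ np.linalg.solve(x.T @ x, x.T)
    ry = y - proj @ y
    rs = s - proj @ s
    rs_norm = np.sqrt((rs**2).sum())
    ry_norm = np.sqrt((ry**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ry.T @ rs) / (ry_norm * rs_norm)
    r = np.clip(r, -1.0, 1.0)
    dof = n - k - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(dof / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), dof)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    fam = family if family is not None else features.shape[1]
    out = pd.DataFrame(
        {
            "partial_r": r,
            "p": p,
            "n": n,
            "bonferroni_family": fam,
            "significant": p < alpha / fam,
        },
        index=features.columns,
    )
    out.index.name = "feature"
    return out
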