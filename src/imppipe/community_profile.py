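"""Community profiling: MGS abundance, genus collapse, DMM enterotypes.

Metagenomic species (MGS) are co-abundant gene clusters quantified by the
mean FPKM of a 50-gene marker panel, with a detection guard: the abundance
is reported only when strictly more than 10% of the markers give a positive
signal, otherwise it is zero. MGS abundances are collapsed to genus-level
pseudo-counts and community types (enterotypes) are fit with a Dirichlet
multinomial mixture (DMM) by expectation-maximization, with BIC for model
selection. The component that combines a Bacteroides-like dominant genus
with the lowest member gene richness is tagged as the analog of the
low-richness "Bacteroides 2" community type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "MGSDefinition",
    "DMMModel",
    "EnterotypeAssignment",
    "compute_mgs_abundance",
    "collapse_to_genus",
    "dmm_loglik",
    "fit_dmm",
    "select_n_components",
    "assign_enterotypes",
]

ALPHA_FLOOR = 1e-6


@dataclass
class MGSDefinition:
    """A metagenomic species: member genes, marker panel, genus label."""

    mgs_id: str
    member_genes: list[str]
    marker_genes: list[str]
    genus: str

    def __post_init__(self):
        if not set(self.marker_genes) <= set(self.member_genes):
            raise ValueError(f"{self.mgs_id}: markers must be a subset of members")


def mgs_definitions_to_tsv(defs: Sequence[MGSDefinition], path) -> None:
    pd.DataFrame(
        {
            "mgs_id": [d.mgs_id for d in defs],
            "genus": [d.genus for d in defs],
            "member_genes": [",".join(d.member_genes) for d in defs],
            "marker_genes": [",".join(d.marker_genes) for d in defs],
        }
    ).to_csv(path, sep="\t", index=False)


def mgs_definitions_from_tsv(path) -> list[MGSDefinition]:
    df = pd.read_csv(path, sep="\t")
    return [
        MGSDefinition(
            mgs_id=row["mgs_id"],
            member_genes=row["member_genes"].split(","),
            marker_genes=row["marker_genes"].split(","),
            genus=row["genus"],
        )
        for _, row in df.iterrows()
    ]


def compute_mgs_abundance(
    fpkm: pd.DataFrame, defs: Sequence[MGSDefinition], detection_fraction: float = 0.10
) -> pd.DataFrame:
    """MGS abundance = mean marker FPKM if > detection_fraction of the panel
    is positive, else exactly 0."""
    cols = {}
    for d in defs:
        missing = [g for g in d.marker_genes if g not in fpkm.columns]
        if missing:
            raise KeyError(f"{d.mgs_id}: marker gene(s) absent from table: {missing[:5]}")
        markers = fpkm[d.marker_genes].to_numpy()
        detected = (markers > 0).mean(axis=1)
        mean_ab = markers.mean(axis=1)
        cols[d.mgs_id] = np.where(detected > detection_fraction, mean_ab, 0.0)
    return pd.DataFrame(cols, index=fpkm.index)


def collapse_to_genus(
    mgs: pd.DataFrame, defs: Sequence[MGSDefinition], total: int = 10_000
) -> pd.DataFrame:
    """Sum MGS abundance by genus and scale each sample to integer
    pseudo-counts (default 1e4) for multinomial modeling."""
    genus_of = {d.mgs_id: d.genus for d in defs}
    missing = [m for m in mgs.columns if m not in genus_of]
    if missing:
        raise KeyError(f"MGS without genus label: {missing[:5]}")
    summed = mgs.T.groupby(mgs.columns.map(genus_of)).sum().T
    row_sums = summed.sum(axis=1)
    props = summed.div(row_sums.where(row_sums > 0, 1.0), axis=0)
    return (props * total).round().astype(np.int64)


@dataclass
class DMMModel:
    """A fitted Dirichlet multinomial mixture over genus pseudo-counts."""

    K: int
    alpha: np.ndarray  # (K, J), all > 0
    pi: np.ndarray  # (K,), sums to 1
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    loglik: float
    n_iter: int
    converged: bool
    genus_names: list[str] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.alpha <= 0):
            raise ValueError("Dirichlet parameters must be positive")
        if abs(self.pi.sum() - 1) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    @property
    def bic(self) -> float:
        n = self.responsibilities.shape[0]
        p = self.K * self.alpha.shape[1] + (self.K - 1)
        return -2.0 * self.loglik + p * np.log(n)


def _as_matrix(counts) -> tuple[np.ndarray, list[str], list]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.columns), list(counts.index)
    X = np.asarray(counts, dtype=float)
    return X, [f"g{j}" for j in range(X.shape[1])], list(range(X.shape[0]))


def _dm_logpmf(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Coefficient-free Dirichlet-multinomial log pmf per sample.

    log DM(x|a) = logG(A) - logG(N+A) + sum_j [logG(x_j+a_j) - logG(a_j)],
    with the multinomial coefficient omitted (constant per sample).
    """
    A = alpha.sum()
    N = X.sum(axis=1)
    return (
        gammaln(A)
        - gammaln(N + A)
        + (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1)
    )


def dmm_loglik(counts, model: DMMModel) -> float:
    """Mixture log-likelihood sum_s log sum_k pi_k DM(x_s | alpha_k)."""
    X, _, _ = _as_matrix(counts)
    if np.any(model.alpha <= 0):
        raise ValueError("Dirichlet parameters must be positive")
    log_parts = np.stack(
        [np.log(model.pi[k]) + _dm_logpmf(X, model.alpha[k]) for k in range(model.K)],
        axis=1,
    )
    return float(logsumexp(log_parts, axis=1).sum())


def _optimize_alpha(X: np.ndarray, weights: np.ndarray, alpha0: np.ndarray) -> np.ndarray:
    """Maximize the weighted DM log-likelihood over alpha, in log space."""
    N = X.sum(axis=1)

    def neg(logc):
        a = np.exp(logc)
        A = a.sum()
        val = weights.sum() * gammaln(A) - (weights * gammaln(N + A)).sum()
        val += (weights[:, None] * (gammaln(X + a) - gammaln(a))).sum()
        return -val

    def grad(logc):
        a = np.exp(logc)
        A = a.sum()
        g = weights.sum() * digamma(A) - (weights * digamma(N + A)).sum()
        g = g + (weights[:, None] * (digamma(X + a) - digamma(a))).sum(axis=0)
        return -g * a

    x0 = np.log(np.maximum(alpha0, ALPHA_FLOOR))
    bounds = [(np.log(ALPHA_FLOOR), np.log(1e6))] * x0.size
    res = minimize(neg, x0, jac=grad, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 100})
    # guard EM monotonicity: never accept a worse alpha than the start
    if res.fun <= neg(x0):
        return np.maximum(np.exp(res.x), ALPHA_FLOOR)
    return np.maximum(alpha0, ALPHA_FLOOR)


def _fit_dmm_once(
    X: np.ndarray, K: int, max_iter: int, tol: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    from sklearn.cluster import KMeans

    n, J = X.shape
    totals = X.sum(axis=1)
    props = X / np.where(totals > 0, totals, 1.0)[:, None]
    if K == 1:
        labels = np.zeros(n, dtype=int)
    else:
        labels = KMeans(n_clusters=K, n_init=3, random_state=seed).fit_predict(props)
    alpha = np.empty((K, J))
    pi = np.empty(K)
    for k in range(K):
        members = props[labels == k]
        mean_p = members.mean(axis=0) if members.size else np.full(J, 1.0 / J)
        alpha[k] = np.maximum(mean_p * 50.0, ALPHA_FLOOR)
        pi[k] = max((labels == k).mean(), 1e-6)
    pi /= pi.sum()

    prev_ll = -np.inf
    converged = False
    it = 0
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        log_parts = np.stack(
            [np.log(pi[k]) + _dm_logpmf(X, alpha[k]) for k in range(K)], axis=1
        )
        norm = logsumexp(log_parts, axis=1)
        ll = float(norm.sum())
        trace.append(ll)
        resp = np.exp(log_parts - norm[:, None])
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        pi = np.maximum(resp.mean(axis=0), 1e-12)
        pi /= pi.sum()
        for k in range(K):
            alpha[k] = _optimize_alpha(X, resp[:, k], alpha[k])
    # final responsibilities under the last parameters
    log_parts = np.stack(
        [np.log(pi[k]) + _dm_logpmf(X, alpha[k]) for k in range(K)], axis=1
    )
    norm = logsumexp(log_parts, axis=1)
    resp = np.exp(log_parts - norm[:, None])
    trace.append(float(norm.sum()))
    return alpha, pi, resp, float(norm.sum()), it, converged, trace


def fit_dmm(
    counts,
    K: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    n_init: int = 5,
) -> DMMModel:
    """Fit a K-component DMM by EM (k-means init, best of n_init restarts).

    The E-step computes responsibilities proportional to pi_k DM(x|alpha_k);
    the M-step updates pi by responsibility means and each alpha_k by
    bounded quasi-Newton ascent in log-alpha space. The log-likelihood is
    non-decreasing across iterations (up to 1e-8).
    """
    X, genus_names, _ = _as_matrix(counts)
    if X.size == 0:
        raise ValueError("empty count matrix")
    if K < 1 or X.shape[0] < K:
        raise ValueError("need K >= 1 and at least K samples")
    best = None
    for r in range(n_init):
        out = _fit_dmm_once(X, K, max_iter, tol, seed + 1000 * r)
        if best is None or out[3] > best[3]:
            best = out
    alpha, pi, resp, ll, n_iter, converged, trace = best
    return DMMModel(
        K=K,
        alpha=alpha,
        pi=pi,
        responsibilities=resp,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        genus_names=genus_names,
        loglik_trace=trace,
    )


def select_n_components(
    counts, K_range: Sequence[int], seed: int = 0, **fit_kwargs
) -> int:
    """K minimizing BIC = -2 loglik + [K J + (K-1)] log n over K_range."""
    if not len(K_range):
        raise ValueError("K_range must be non-empty")
    best_k, best_bic = None, np.inf
    for K in K_range:
        model = fit_dmm(counts, K, seed=seed, **fit_kwargs)
        if model.bic < best_bic:
            best_k, best_bic = K, model.bic
    return best_k


@dataclass
class EnterotypeAssignment:
    """Per-sample component labels (1..K) and per-component descriptors."""

    labels: pd.Series  # sample -> 1-based component label
    components: pd.DataFrame  # component, dominant_genus, mean_richness, n_members
    bacteroides2_analog: int | None  # 1-based component label or None


def assign_enterotypes(
    model: DMMModel,
    counts,
    richness: pd.Series | None = None,
    bacteroides_genus: str = "Bacteroides",
) -> EnterotypeAssignment:
    """Label samples by argmax responsibility; describe each component by its
    dominant genus (largest alpha share) and the mean gene richness of its
    members. Among components dominated by the configured Bacteroides-like
    genus, the one with the lowest mean richness is tagged as the
    Bacteroides-2 analog."""
    _, _, sample_index = _as_matrix(counts)
    labels = pd.Series(
        np.argmax(model.responsibilities, axis=1) + 1, index=sample_index, name="enterotype"
    )
    rows = []
    for k in range(model.K):
        share = model.alpha[k] / model.alpha[k].sum()
        dom = model.genus_names[int(np.argmax(share))]
        members = labels.index[labels == k + 1]
        mean_rich = (
            float(richness.loc[members].mean()) if richness is not None and len(members) else np.nan
        )
        rows.append(
            {
                "component": k + 1,
                "dominant_genus": dom,
                "dominant_share": float(share.max()),
                "mean_richness": mean_rich,
                "n_members": int(len(members)),
            }
        )
    components = pd.DataFrame(rows).set_index("component")
    b2 = None
    bact = components[components["dominant_genus"] == bacteroides_genus]
    if len(bact) and richness is not None and bact["mean_richness"].notna().any():
        b2 = int(bact["mean_richness"].idxmin())
    elif len(bact):
        b2 = int(bact.index[0])
    return EnterotypeAssignment(labels=labels, components=components, bacteroides2_analog=b2)
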