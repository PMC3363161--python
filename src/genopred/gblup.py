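"""GBLUP: genomic relationship matrices, REML variance components, BLUP
solutions and marker-effect backsolving.

Three animal models are supported:

* G1 — additive genomic relationship G (VanRaden method 1):
  ``G = M M' / (2 sum p_i(1-p_i))`` with M the dosage matrix column-centered
  by twice the observed allele frequency;
* G2 — G1 plus a dominance relationship built from the heterozygote
  indicator centered by its expectation 2pq;
* G3 — G1 plus an additive-by-additive epistatic relationship, by default
  the Hadamard square G∘G (a matrix-square option exists).

Variance components are estimated by restricted maximum likelihood with an
EM warm start and average-information updates; GEBV come from the mixed
model equations; allele substitution effects are backsolved through
``alpha = Z_c' G^{-1} a_hat / (2 sum p_i(1-p_i))``, which satisfies the
reconstruction identity ``Z_c alpha = a_hat``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

log = logging.getLogger(__name__)

__all__ = [
    "GenomicRelationship",
    "VarianceComponents",
    "MmeSolution",
    "BacksolvedEffects",
    "build_grm",
    "build_dominance_rm",
    "build_epistasis_rm",
    "reml",
    "solve_mme",
    "backsolve_effects",
    "run_gblup",
]

DEFAULT_RIDGE = 1e-6


@dataclass
class GenomicRelationship:
    """A relationship matrix with its construction metadata."""

    matrix: np.ndarray
    kind: str  # additive | dominance | epistatic
    allele_freqs: np.ndarray | None = None
    denominator: float | None = None
    ridge: float = 0.0

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VarianceComponents:
    """REML estimates for one of the models G1-G3.

    ``h2`` is additive variance over the sum of all components; boundary
    flags mark components pinned at the small positive floor.
    """

    model: str
    sigma2_a: float
    sigma2_e: float
    sigma2_d: float | None = None
    sigma2_aa: float | None = None
    loglik: float = np.nan
    n_iter: int = 0
    boundary: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.sigma2_a + (self.sigma2_d or 0.0) + \
            (self.sigma2_aa or 0.0) + self.sigma2_e

    @property
    def h2(self) -> float:
        return self.sigma2_a / self.total


@dataclass
class MmeSolution:
    """Fixed-effect estimate and BLUPs for all genotyped individuals."""

    mu_hat: float
    a_hat: np.ndarray
    d_hat: np.ndarray | None = None
    aa_hat: np.ndarray | None = None

    @property
    def gebv(self) -> np.ndarray:
        return self.a_hat


@dataclass
class BacksolvedEffects:
    """Allele substitution effects recovered from GEBV."""

    alpha: np.ndarray
    sigma2_alpha: float
    denominator: float


# ---------------------------------------------------------------------------
# relationship matrices


def build_grm(X: np.ndarray, ridge: float = DEFAULT_RIDGE) -> GenomicRelationship:
    """Additive genomic relationship, VanRaden method 1.

    Frequencies are observed from ``X``; monomorphic SNPs are centered to
    zero and contribute nothing.  ``ridge`` (default 1e-6) is added to the
    diagonal for invertibility.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 individuals")
    p = X.mean(axis=0) / 2.0
    denom = float(2.0 * np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: zero scaling denominator")
    M = X - 2.0 * p
    G = (M @ M.T) / denom
    if ridge:
        G[np.diag_indices_from(G)] += ridge
        log.debug("GRM ridge %.1e added to diagonal", ridge)
    return GenomicRelationship(G, "additive", allele_freqs=p,
                               denominator=denom, ridge=ridge)


def build_dominance_rm(X: np.ndarray,
                       ridge: float = DEFAULT_RIDGE) -> GenomicRelationship:
    """Dominance relationship from the heterozygote indicator.

    Heterozygotes are coded 1, both homozygotes 0; columns are centered by
    the expected heterozygosity 2pq and the cross-product is scaled by
    ``sum 2 p_i q_i (1 - 2 p_i q_i)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 individuals")
    H = (X == 1.0).astype(float)
    if H.sum() == 0:
        raise ValueError("no heterozygous genotypes: dominance matrix undefined")
    p = X.mean(axis=0) / 2.0
    twopq = 2.0 * p * (1.0 - p)
    denom = float(np.sum(twopq * (1.0 - twopq)))
    if denom <= 0.0:
        raise ValueError("zero dominance scaling denominator")
    Hc = H - twopq
    D = (Hc @ Hc.T) / denom
    if ridge:
        D[np.diag_indices_from(D)] += ridge
    return GenomicRelationship(D, "dominance", allele_freqs=p,
                               denominator=denom, ridge=ridge)


def build_epistasis_rm(G: GenomicRelationship,
                       mode: str = "hadamard") -> GenomicRelationship:
    """Additive-by-additive epistatic relationship from an additive G.

    ``hadamard`` (default) returns the element-wise square G∘G, the standard
    additive-by-additive covariance; ``matrix-square`` returns the literal
    matrix product G·G.
    """
    if G.kind != "additive":
        raise ValueError("epistatic matrix is built from an additive G")
    if mode == "hadamard":
        E = G.matrix * G.matrix
    elif mode == "matrix-square":
        E = G.matrix @ G.matrix
    else:
        raise ValueError(f"unknown epistasis mode {mode!r}")
    return GenomicRelationship(E, "epistatic", allele_freqs=G.allele_freqs,
                               denominator=G.denominator)


# ---------------------------------------------------------------------------
# REML

_MODEL_TERMS = {"G1": ("additive",), "G2": ("additive", "dominance"),
                "G3": ("additive", "epistatic")}


def _loglik(Vc: np.ndarray, ones: np.ndarray, y: np.ndarray):
    """Restricted log-likelihood pieces from a Cholesky factor of V."""
    L = Vc
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_y = sla.cho_solve((L, True), y)
    Vi_1 = sla.cho_solve((L, True), ones)
    xvx = float(ones @ Vi_1)
    beta = float(ones @ Vi_y) / xvx
    Py = Vi_y - Vi_1 * beta
    ll = -0.5 * (logdetV + np.log(xvx) + float(y @ Py))
    return ll, Py, Vi_1, xvx


def reml(
    y: np.ndarray,
    relationships: list[GenomicRelationship],
    model: str = "G1",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarianceComponents:
    """Restricted maximum likelihood for models G1-G3.

    ``y`` may contain NaN (unphenotyped individuals); relationship matrices
    cover all individuals and are subset to the phenotyped rows here.  Five
    EM fixed-point iterations warm-start average-information updates;
    components driven negative are pinned at a floor of 1e-8 * Var(y) and
    flagged.  Convergence: |change in restricted log-likelihood| < tol.
    """
    if model not in _MODEL_TERMS:
        raise ValueError(f"unknown model {model!r}")
    terms = _MODEL_TERMS[model]
    by_kind = {r.kind: r for r in relationships}
    missing = [t for t in terms if t not in by_kind]
    if missing:
        raise ValueError(f"model {model} needs relationship(s): {missing}")
    y = np.asarray(y, dtype=float).ravel()
    obs = ~np.isnan(y)
    yo = y[obs]
    n = len(yo)
    if n < len(terms) + 2:
        raise ValueError("too few phenotyped records for the model")
    Ks = [np.ascontiguousarray(by_kind[t].matrix[np.ix_(obs, obs)])
          for t in terms]
    Ks.append(np.eye(n))  # residual
    t_all = len(Ks)
    vary = float(np.var(yo))
    floor = 1e-8 * vary
    theta = np.full(t_all, vary / t_all)
    ones = np.ones(n)

    def build_V(th):
        V = np.zeros((n, n))
        for c, K in zip(th, Ks):
            V += c * K
        return V

    def pieces(th):
        V = build_V(th)
        try:
            L = sla.cholesky(V, lower=True)
        except sla.LinAlgError as exc:
            raise ValueError("variance matrix not positive definite") from exc
        return _loglik(L, ones, yo) + (L,)

    ll, Py, Vi_1, xvx, L = pieces(theta)
    pinned = np.zeros(t_all, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        # P K_i P y and traces
        KPy = [K @ Py for K in Ks]
        yPKPy = np.array([float(Py @ kpy) for kpy in KPy])
        Vi_K = [sla.cho_solve((L, True), K) for K in Ks]
        # tr(P K) = tr(V^-1 K) - 1' V^-1 K V^-1 1 / (1' V^-1 1)
        trPK = np.array([
            float(np.trace(vk)) - float(Vi_1 @ (K @ Vi_1)) / xvx
            for vk, K in zip(Vi_K, Ks)
        ])
        score_all = 0.5 * (yPKPy - trPK)
        if it <= 5:
            new = theta * np.where(trPK > 0, yPKPy / np.maximum(trPK, 1e-300), 1.0)
        else:
            # average information on the free components; a component at the
            # floor re-enters only while its score points inward
            free = (theta > floor * (1 + 1e-9)) | (score_all > 0)
            free[-1] = True
            idx = np.flatnonzero(free)
            PKPy = []
            for j in idx:
                v = sla.cho_solve((L, True), KPy[j])
                v -= Vi_1 * (float(ones @ v) / xvx)
                PKPy.append(v)
            AI = np.empty((len(idx), len(idx)))
            for ai, j in enumerate(idx):
                for bi in range(ai, len(idx)):
                    AI[ai, bi] = AI[bi, ai] = 0.5 * float(KPy[j] @ PKPy[bi])
            try:
                step = np.linalg.solve(AI, score_all[idx])
            except np.linalg.LinAlgError:
                step = None
            new = theta.copy()
            if step is not None:
                new[idx] = theta[idx] + step  # negatives clamp to the floor
            else:
                # EM fallback for this iteration
                new = theta * np.where(trPK > 0, yPKPy / np.maximum(trPK, 1e-300),
                                       1.0)
        new = np.maximum(new, floor)
        pinned = new <= floor * (1 + 1e-12)
        pinned[-1] = False  # residual never pinned
        try:
            ll_new, Py, Vi_1, xvx, L = pieces(new)
        except ValueError:
            # retreat halfway toward the previous point
            new = 0.5 * (new + theta)
            ll_new, Py, Vi_1, xvx, L = pieces(new)
        # step-halving if the likelihood dropped (AI overshoot)
        halvings = 0
        while ll_new < ll - 1e-10 and halvings < 20 and it > 5:
            new = 0.5 * (new + theta)
            ll_new, Py, Vi_1, xvx, L = pieces(new)
            halvings += 1
        converged = abs(ll_new - ll) < tol
        theta, ll = new, ll_new
        if converged and it > 5:
            break
    else:
        raise RuntimeError(
            f"REML did not converge in {max_iter} iterations; "
            f"last theta={theta.tolist()}, loglik={ll}"
        )

    comp = dict(zip(terms, theta[:-1]))
    boundary = {t: bool(pinned[i]) for i, t in enumerate(terms)}
    return VarianceComponents(
        model=model,
        sigma2_a=float(comp["additive"]),
        sigma2_d=float(comp["dominance"]) if "dominance" in comp else None,
        sigma2_aa=float(comp["epistatic"]) if "epistatic" in comp else None,
        sigma2_e=float(theta[-1]),
        loglik=float(ll),
        n_iter=it,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# BLUP and backsolving


def solve_mme(
    y: np.ndarray,
    varcomp: VarianceComponents,
    relationships: list[GenomicRelationship],
) -> MmeSolution:
    """BLUP solutions of the mixed model equations for models G1-G3.

    Solved in the equivalent variance form: the GLS intercept from
    ``V = sum_c sigma2_c K_c[obs, obs] + sigma2_e I`` and random-effect
    predictions ``u_c = sigma2_c K_c[:, obs] V^{-1} (y - mu)``, which also
    yields predictions for unphenotyped (validation) individuals and does
    not require inverting a possibly singular K.  Identical (to numerical
    precision) to Henderson's equations when K is invertible.
    """
    terms = _MODEL_TERMS[varcomp.model]
    by_kind = {r.kind: r for r in relationships}
    y = np.asarray(y, dtype=float).ravel()
    obs = ~np.isnan(y)
    yo = y[obs]
    n = len(yo)
    sig = {"additive": varcomp.sigma2_a, "dominance": varcomp.sigma2_d,
           "epistatic": varcomp.sigma2_aa}
    V = varcomp.sigma2_e * np.eye(n)
    for t in terms:
        V += sig[t] * by_kind[t].matrix[np.ix_(obs, obs)]
    try:
        L = sla.cholesky(V, lower=True)
    except sla.LinAlgError as exc:
        raise ValueError("singular coefficient matrix in the MME") from exc
    ones = np.ones(n)
    Vi_y = sla.cho_solve((L, True), yo)
    Vi_1 = sla.cho_solve((L, True), ones)
    mu_hat = float(ones @ Vi_y) / float(ones @ Vi_1)
    resid = sla.cho_solve((L, True), yo - mu_hat)
    sol = {}
    for t in terms:
        sol[t] = sig[t] * (by_kind[t].matrix[:, obs] @ resid)
    return MmeSolution(
        mu_hat=mu_hat,
        a_hat=sol["additive"],
        d_hat=sol.get("dominance"),
        aa_hat=sol.get("epistatic"),
    )


def backsolve_effects(
    a_hat: np.ndarray,
    X: np.ndarray,
    G: GenomicRelationship,
    sigma2_a: float,
) -> BacksolvedEffects:
    """Allele substitution effects from GEBV.

    ``alpha = Z_c' G^{-1} a_hat / (2 sum p_i(1-p_i))`` with Z_c the centered
    dosage matrix used to build G.  This scaling makes the reconstruction
    ``Z_c alpha = a_hat`` an identity whenever a_hat lies in the row space
    of Z_c (the printed literature form with a leading sigma2_alpha instead
    of 1/denominator differs by the constant sigma2_a; relative magnitudes,
    hence QTL calls, are unchanged — both scalings are logged).
    ``sigma2_alpha = sigma2_a / denominator`` is reported alongside.
    """
    if G.kind != "additive":
        raise ValueError("backsolving requires the additive G")
    X = np.asarray(X, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float).ravel()
    if X.shape[0] != len(a_hat) or X.shape[0] != G.n:
        raise ValueError("X, a_hat and G must cover the same individuals")
    p_now = X.mean(axis=0) / 2.0
    denom_now = float(2.0 * np.sum(p_now * (1.0 - p_now)))
    if G.denominator is not None and abs(denom_now - G.denominator) > 1e-6 * max(
            denom_now, 1.0):
        raise ValueError(
            "G was not built from this X (scaling denominators disagree: "
            f"{G.denominator} vs {denom_now})"
        )
    Zc = X - 2.0 * p_now
    Gi_a = sla.lstsq(G.matrix, a_hat, lapack_driver="gelsd")[0]
    alpha = (Zc.T @ Gi_a) / denom_now
    sigma2_alpha = sigma2_a / denom_now
    log.debug(
        "backsolve scalings: 1/denominator=%.6g, sigma2_alpha=%.6g",
        1.0 / denom_now, sigma2_alpha,
    )
    return BacksolvedEffects(alpha=alpha, sigma2_alpha=sigma2_alpha,
                             denominator=denom_now)


def run_gblup(
    y: np.ndarray,
    X: np.ndarray,
    model: str = "G1",
    epistasis_mode: str = "hadamard",
    tol: float = 1e-8,
    max_iter: int = 200,
    ridge: float = DEFAULT_RIDGE,
):
    """Convenience wrapper: build matrices, estimate REML components, solve
    the MME and backsolve marker effects.  Returns
    (VarianceComponents, MmeSolution, BacksolvedEffects, relationships)."""
    G = build_grm(X, ridge=ridge)
    rels = [G]
    if model == "G2":
        rels.append(build_dominance_rm(X, ridge=ridge))
    elif model == "G3":
        rels.append(build_epistasis_rm(G, mode=epistasis_mode))
    vc = reml(y, rels, model=model, tol=tol, max_iter=max_iter)
    sol = solve_mme(y, vc, rels)
    eff = backsolve_effects(sol.a_hat, X, G, vc.sigma2_a)
    return vc, sol, eff, rels
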