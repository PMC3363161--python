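"""Bayesian whole-genome regression: BayesB, BayesCpi, and a joint
additive + dominance BayesCpi model.

The phenotype model is

    y_i = mu + sum_j (X_ij a_j + W_ij d_j) + e_i

with X the allele dosage (0/1/2), W the heterozygote indicator, a_j the
additive effect (half the homozygote difference) and d_j the dominance
deviation.  SNP effects carry spike-and-slab (mixture of a point mass at
zero and a normal) priors: BayesCpi uses one common effect variance and
samples the exclusion probability pi; BayesB fixes pi and gives every
included SNP its own scaled-inverse-chi-square-distributed variance.
Dosage columns are centered by twice the allele frequency (and W by its
column mean) before sampling; the intercept absorbs the shift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _samplers

__all__ = [
    "McmcConfig",
    "PriorSpec",
    "PosteriorSummary",
    "run_bayescpi",
    "run_bayesb",
    "run_bayescpi_dominance",
    "model_frequencies",
    "gebv_from_effects",
    "save_posterior_samples",
    "load_posterior_samples",
]


@dataclass(frozen=True)
class McmcConfig:
    """Chain length controls.  Defaults: 41,000 iterations, 1,000 burn-in,
    thinning 10 (4,000 retained samples)."""

    n_iter: int = 41_000
    burn_in: int = 1_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass(frozen=True)
class PriorSpec:
    """Mixture-prior hyperparameters.

    ``pi`` is the prior probability that a SNP has *no* effect (fixed at
    0.995 for BayesB; the BayesCpi starting value).  ``nu_*`` are the
    degrees of freedom of the scaled-inverse-chi-square priors on the effect
    and residual variances.  Scale parameters left as None are derived from
    the data: the effect-variance scale from an assumed genetic variance
    split over the expected number of included SNPs
    (genvar / ((1-pi) * sum_j 2 p_j q_j)), the residual scale from an
    assumed residual variance; both multiplied by (nu-2)/nu so the prior
    mean equals the assumption.  By default the assumed split is half the
    phenotypic variance to each side — weakly informative.
    """

    pi: float = 0.995
    pi_d: float = 0.995
    nu_a: float = 4.2
    nu_d: float = 4.2
    nu_e: float = 4.0
    s2_a: float | None = None
    s2_d: float | None = None
    s2_e: float | None = None
    genetic_var_guess: float | None = None
    residual_var_guess: float | None = None

    def __post_init__(self):
        for p in (self.pi, self.pi_d):
            if not (0.0 <= p <= 1.0):
                raise ValueError("pi must be in [0, 1]")
        for nu in (self.nu_a, self.nu_d, self.nu_e):
            if nu <= 0:
                raise ValueError("prior degrees of freedom must be > 0")


@dataclass
class PosteriorSummary:
    """Posterior summaries and retained samples from one chain.

    ``effect_mean_a``/``model_freq_a`` (and ``*_d`` for the dominance model)
    are per-SNP posterior means and inclusion probabilities.  Variance
    components are posterior means; the genetic components are the variance
    of the genomic values (X_c a, and W_c d) across the phenotyped
    individuals per retained sample.  ``gebv`` is for the rows of the
    training X, centered; use :func:`gebv_from_effects` for other panels.
    ``a_samples`` (n_retained x k) retains the sampled effects for
    window-variance computation; excluded SNPs are exactly 0.
    """

    effect_mean_a: np.ndarray
    model_freq_a: np.ndarray
    var_additive: float
    var_residual: float
    pi_mean: float
    gebv: np.ndarray
    allele_freq: np.ndarray
    a_samples: np.ndarray
    method: str
    effect_mean_d: np.ndarray | None = None
    model_freq_d: np.ndarray | None = None
    var_dominance: float = 0.0
    pi_d_mean: float | None = None
    d_samples: np.ndarray | None = None
    mu_samples: np.ndarray | None = None
    sigma2_e_samples: np.ndarray | None = None
    sigma2_a_samples: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def var_genetic(self) -> float:
        return self.var_additive + self.var_dominance

    @property
    def var_total(self) -> float:
        return self.var_genetic + self.var_residual

    @property
    def h2(self) -> float:
        return self.var_genetic / self.var_total


def _check_inputs(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D and row-matched to y")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 phenotyped records")
    if np.any(np.isnan(y)) or np.any(np.isnan(X)):
        raise ValueError("missing values not allowed in y or X")
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype vector")
    return y, X


def _center_dosage(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                           np.ndarray]:
    """Center columns by 2p; returns (Xc, xtx, active mask, freqs)."""
    p = X.mean(axis=0) / 2.0
    Xc = X - 2.0 * p
    xtx = np.einsum("ij,ij->j", Xc, Xc)
    active = xtx > 1e-12
    if not active.all():
        warnings.warn(
            f"{int((~active).sum())} zero-variance SNP columns skipped "
            "(effects fixed at 0)"
        )
    return np.ascontiguousarray(Xc.T), xtx, active, p


def _derive_scales(prior: PriorSpec, y: np.ndarray, p: np.ndarray,
                   pi: float) -> tuple[float, float, float]:
    """Fill in effect/dominance/residual prior scales (see PriorSpec)."""
    vary = float(np.var(y))
    gv = prior.genetic_var_guess if prior.genetic_var_guess is not None else 0.5 * vary
    rv = prior.residual_var_guess if prior.residual_var_guess is not None else 0.5 * vary
    sum2pq = float(np.sum(2.0 * p * (1.0 - p)))
    n_incl = max((1.0 - pi) * len(p), 1.0)
    denom = max(sum2pq * n_incl / len(p), 1e-8)
    s2_a = prior.s2_a if prior.s2_a is not None else \
        gv / denom * (prior.nu_a - 2.0) / prior.nu_a
    s2_d = prior.s2_d if prior.s2_d is not None else \
        gv / denom * (prior.nu_d - 2.0) / prior.nu_d
    s2_e = prior.s2_e if prior.s2_e is not None else \
        rv * (prior.nu_e - 2.0) / prior.nu_e
    return max(s2_a, 1e-10), max(s2_d, 1e-10), max(s2_e, 1e-10)


def run_bayescpi(
    y: np.ndarray,
    X: np.ndarray,
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    *,
    sample_pi: bool = True,
    fix_sigma2_a: float | None = None,
    fix_sigma2_e: float | None = None,
    fix_mu: float | None = None,
) -> PosteriorSummary:
    """BayesCpi Gibbs sampler (additive model).

    ``sample_pi=False`` keeps pi at ``prior.pi``; the ``fix_*`` keywords pin
    the corresponding parameter (used by the closed-form oracle checks, e.g.
    pi=0 with both variances fixed reduces the posterior mean to ridge
    regression / SNP-BLUP).
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcConfig()
    y, X = _check_inputs(y, X)
    Xt, xtx, active, p = _center_dosage(X)
    s2_a, _, s2_e = _derive_scales(prior, y, p, prior.pi)
    out = _samplers.bayescpi_chain(
        y, Xt, xtx, active, mcmc.n_iter, mcmc.burn_in, mcmc.thin,
        prior.pi, sample_pi, prior.nu_a, s2_a, prior.nu_e, s2_e,
        fix_sigma2_a is not None, fix_sigma2_a or 0.0,
        fix_sigma2_e is not None, fix_sigma2_e or 0.0,
        fix_mu is not None, fix_mu or 0.0,
        int(mcmc.seed) % (2**31),
    )
    a_samp, mu_s, s2a_s, s2e_s, pi_s, genvar_s = out
    a_mean = a_samp.mean(axis=0)
    gebv = Xt.T @ a_mean
    gebv -= gebv.mean()
    return PosteriorSummary(
        effect_mean_a=a_mean,
        model_freq_a=(a_samp != 0.0).mean(axis=0),
        var_additive=float(genvar_s.mean()),
        var_residual=float(s2e_s.mean()),
        pi_mean=float(pi_s.mean()),
        gebv=gebv,
        allele_freq=p,
        a_samples=a_samp,
        method="bayesCpi",
        mu_samples=mu_s,
        sigma2_e_samples=s2e_s,
        sigma2_a_samples=s2a_s,
        extras={"genvar_samples": genvar_s, "pi_samples": pi_s},
    )


def run_bayesb(
    y: np.ndarray,
    X: np.ndarray,
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    *,
    fix_sigma2_e: float | None = None,
    fix_mu: float | None = None,
) -> PosteriorSummary:
    """BayesB Gibbs sampler: pi fixed (default 0.995), per-locus effect
    variances updated jointly with the inclusion indicator by a
    Metropolis-Hastings step on the marginal likelihood.  The ``fix_*``
    keywords pin the residual variance or intercept (oracle checks)."""
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcConfig()
    y, X = _check_inputs(y, X)
    Xt, xtx, active, p = _center_dosage(X)
    s2_a, _, s2_e = _derive_scales(prior, y, p, prior.pi)
    a_samp, mu_s, s2e_s, genvar_s = _samplers.bayesb_chain(
        y, Xt, xtx, active, mcmc.n_iter, mcmc.burn_in, mcmc.thin,
        prior.pi, prior.nu_a, s2_a, prior.nu_e, s2_e,
        fix_sigma2_e is not None, fix_sigma2_e or 0.0,
        fix_mu is not None, fix_mu or 0.0,
        int(mcmc.seed) % (2**31),
    )
    a_mean = a_samp.mean(axis=0)
    gebv = Xt.T @ a_mean
    gebv -= gebv.mean()
    return PosteriorSummary(
        effect_mean_a=a_mean,
        model_freq_a=(a_samp != 0.0).mean(axis=0),
        var_additive=float(genvar_s.mean()),
        var_residual=float(s2e_s.mean()),
        pi_mean=prior.pi,
        gebv=gebv,
        allele_freq=p,
        a_samples=a_samp,
        method="bayesB",
        mu_samples=mu_s,
        sigma2_e_samples=s2e_s,
        extras={"genvar_samples": genvar_s},
    )


def run_bayescpi_dominance(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    prior: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorSummary:
    """Joint additive + dominance BayesCpi.

    Additive effects act on centered dosage, dominance deviations on the
    centered heterozygote indicator; each class has its own inclusion
    indicators, common variance and sampled pi (pi_a, pi_d).
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcConfig()
    y, X = _check_inputs(y, X)
    W = np.asarray(W, dtype=float)
    if W.shape != X.shape:
        raise ValueError("W must match X in shape")
    Xt, xtx, active_a, p = _center_dosage(X)
    wbar = W.mean(axis=0)
    Wc = W - wbar
    wtw = np.einsum("ij,ij->j", Wc, Wc)
    Wt = np.ascontiguousarray(Wc.T)
    active_d = wtw > 1e-12
    if not active_d.any():
        warnings.warn("no heterozygotes anywhere: dominance effects fixed at 0")
    s2_a, s2_d, s2_e = _derive_scales(prior, y, p, prior.pi)
    out = _samplers.bayescpi_dominance_chain(
        y, Xt, Wt, xtx, wtw, active_a, active_d,
        mcmc.n_iter, mcmc.burn_in, mcmc.thin, prior.pi, prior.pi_d,
        prior.nu_a, s2_a, prior.nu_d, s2_d, prior.nu_e, s2_e,
        int(mcmc.seed) % (2**31),
    )
    (a_samp, d_samp, mu_s, s2a_s, s2d_s, s2e_s, pia_s, pid_s,
     gva_s, gvd_s) = out
    a_mean = a_samp.mean(axis=0)
    d_mean = d_samp.mean(axis=0)
    alpha = a_mean + d_mean * (1.0 - 2.0 * p)
    gebv = Xt.T @ alpha
    gebv -= gebv.mean()
    return PosteriorSummary(
        effect_mean_a=a_mean,
        model_freq_a=(a_samp != 0.0).mean(axis=0),
        var_additive=float(gva_s.mean()),
        var_residual=float(s2e_s.mean()),
        pi_mean=float(pia_s.mean()),
        gebv=gebv,
        allele_freq=p,
        a_samples=a_samp,
        method="bayesCpi-dom",
        effect_mean_d=d_mean,
        model_freq_d=(d_samp != 0.0).mean(axis=0),
        var_dominance=float(gvd_s.mean()),
        pi_d_mean=float(pid_s.mean()),
        d_samples=d_samp,
        mu_samples=mu_s,
        sigma2_e_samples=s2e_s,
        sigma2_a_samples=s2a_s,
        extras={"genvar_a_samples": gva_s, "genvar_d_samples": gvd_s,
                "pi_samples": pia_s, "pi_d_samples": pid_s,
                "sigma2_d_samples": s2d_s},
    )


def save_posterior_samples(summary: PosteriorSummary, path) -> None:
    """Write the retained samples of a chain to an HDF5 store."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["method"] = summary.method
        fh.create_dataset("a_samples", data=summary.a_samples,
                          compression="gzip")
        if summary.d_samples is not None:
            fh.create_dataset("d_samples", data=summary.d_samples,
                              compression="gzip")
        for name in ("mu_samples", "sigma2_e_samples", "sigma2_a_samples"):
            arr = getattr(summary, name)
            if arr is not None:
                fh.create_dataset(name, data=arr)


def load_posterior_samples(path) -> dict:
    """Read a retained-sample store back as a dict of arrays."""
    import h5py

    out = {}
    with h5py.File(path, "r") as fh:
        out["method"] = fh.attrs["method"]
        for name in fh:
            out[name] = fh[name][...]
    return out


def model_frequencies(retained_samples: np.ndarray) -> np.ndarray:
    """Posterior inclusion probability per SNP.

    ``retained_samples`` is (n_retained x k) of sampled effects (excluded
    SNPs are exactly zero) or of 0/1 indicators; the model frequency is the
    fraction of retained samples in which the SNP is in the model.
    """
    s = np.asarray(retained_samples)
    if s.ndim != 2 or s.shape[0] < 1:
        raise ValueError("need a non-empty (n_samples x k) array")
    return (s != 0.0).mean(axis=0)


def gebv_from_effects(
    X: np.ndarray,
    effect_a: np.ndarray,
    effect_d: np.ndarray | None = None,
    allele_freq: np.ndarray | None = None,
    W: np.ndarray | None = None,
) -> np.ndarray:
    """GEBV as the linear combination of SNP substitution effects.

    Additive models: ``GEBV_i = sum_j X_ij a_j``.  With dominance effects the
    substitution effect ``alpha_j = a_j + d_j (1 - 2 p_j)`` is applied to the
    dosage.  Dosages are centered by 2p (frequency from ``allele_freq`` or
    observed) so the output is reported centered to mean zero.
    """
    X = np.asarray(X, dtype=float)
    effect_a = np.asarray(effect_a, dtype=float).ravel()
    if X.shape[1] != effect_a.shape[0]:
        raise ValueError("column count of X does not match effects")
    p = (np.asarray(allele_freq, dtype=float) if allele_freq is not None
         else X.mean(axis=0) / 2.0)
    alpha = effect_a.copy()
    if effect_d is not None:
        effect_d = np.asarray(effect_d, dtype=float).ravel()
        if effect_d.shape != effect_a.shape:
            raise ValueError("effect_d shape does not match effect_a")
        alpha = alpha + effect_d * (1.0 - 2.0 * p)
    g = (X - 2.0 * p) @ alpha
    return g - g.mean()
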