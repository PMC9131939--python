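"""First-order dynamic network inference by Gibbs variable selection.

Each gene i is modelled as a linear autoregression on the previous time
point of every other gene:

    x[t+1, i] = Mu_i + sum_j Gamma_ij * B_ij * x[t, j] + eps_i,
    eps_i ~ Normal(0, 1/Lambda_i)

with spike-and-slab priors: Gamma_ij ~ Bernoulli(rho), B_ij ~ Normal(0,
slab_var) given inclusion, Lambda_i ~ Gamma(shape, rate), Mu_i ~ Normal(0,
mu_var).  Self-links are excluded (Gamma_ii = 0).  Data are standardized
per gene before sampling.  The sampler integrates B_ij out of the
inclusion update (conditional Bayes factor), then draws B_ij from its
Gaussian full conditional when included; Mu and Lambda follow conjugate
updates.  The posterior link probability P_ij is the post-burn-in mean of
Gamma_ij, reported per chain and pooled; chains differ only by seed stream
and convergence is declared when the largest absolute pairwise difference
of link probabilities falls below a tolerance.

A target gene whose (centered) response has zero variance carries no
information about its regulators; its Gamma row is drawn from the prior, so
its link probabilities equal rho, and a warning is emitted.  A tiny ridge
jitter (1e-8) on the X'X scalars guards against exactly collinear
deterministic series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RIDGE_JITTER = 1e-8


@dataclass(frozen=True)
class Priors:
    rho: float | None = None        # None -> 1/n_genes
    slab_var: float = 2.0
    lambda_shape: float = 2.0
    lambda_rate: float = 0.01
    mu_var: float = 10.0


@dataclass
class ChainResult:
    prob: np.ndarray                      # (G, G) posterior mean of Gamma
    gamma_trace: np.ndarray               # (n_kept, G, G) uint8
    b_trace: np.ndarray                   # thinned (n_thin, G, G)
    lambda_trace: np.ndarray              # thinned (n_thin, G)
    mu_trace: np.ndarray                  # thinned (n_thin, G)


@dataclass
class PosteriorNetwork:
    genes: list[str]
    prob: np.ndarray                      # pooled (G, G), prob[j, i] = P(j -> i)
    chains: list[ChainResult]
    priors: Priors
    n_iter: int
    burn_in: int
    metadata: dict = field(default_factory=dict)

    def link_probability(self, regulator: str, target: str) -> float:
        j, i = self.genes.index(regulator), self.genes.index(target)
        return float(self.prob[j, i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.prob, index=self.genes, columns=self.genes)


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    informative = sd > 1e-12 * np.maximum(1.0, np.abs(mu))
    z = np.zeros_like(x)
    z[:, informative] = (x[:, informative] - mu[informative]) / sd[informative]
    return z, informative


def _run_chain(z: np.ndarray, informative: np.ndarray, priors: Priors, rho: float,
               n_iter: int, burn_in: int, rng: np.random.Generator,
               fixed_gamma: np.ndarray | None, thin: int) -> ChainResult:
    T, G = z.shape
    X = z[:-1]                      # (T-1, G) regressors
    Y = z[1:]                       # (T-1, G) responses
    n_obs = T - 1

    xtx = X.T @ X                   # needed only on the diagonal per predictor
    gamma = np.zeros((G, G), dtype=np.uint8)
    b = np.zeros((G, G))
    lam = np.ones(G)
    mu = np.zeros(G)

    preds = {i: [j for j in range(G) if j != i and informative[j]] for i in range(G)}
    log_prior_odds = np.log(rho) - np.log1p(-rho)
    inv_slab = 1.0 / priors.slab_var

    n_keep = n_iter - burn_in
    gamma_trace = np.zeros((n_keep, G, G), dtype=np.uint8)
    n_thin = max(n_keep // thin, 1)
    b_trace = np.zeros((n_thin, G, G))
    lam_trace = np.zeros((n_thin, G))
    mu_trace = np.zeros((n_thin, G))

    resid = Y - mu[None, :]         # residual per target, updated in place

    for i in range(G):
        if not informative[i]:
            continue
        resid[:, i] = Y[:, i] - mu[i]

    kept = 0
    thin_kept = 0
    for it in range(n_iter):
        for i in range(G):
            if not informative[i]:
                # no likelihood: Gamma row from the prior
                for j in range(G):
                    if j != i:
                        gamma[j, i] = 1 if rng.random() < rho else 0
                continue
            r = resid[:, i]
            li = lam[i]
            for j in preds[i]:
                if fixed_gamma is not None:
                    include = bool(fixed_gamma[j, i])
                else:
                    include = None
                if gamma[j, i]:
                    r = r + b[j, i] * X[:, j]
                v = inv_slab + li * (xtx[j, j] + RIDGE_JITTER)
                m = li * (X[:, j] @ r) / v
                if include is None:
                    log_odds = (log_prior_odds
                                + 0.5 * np.log(inv_slab / v)
                                + 0.5 * m * m * v)
                    include = rng.random() < 1.0 / (1.0 + np.exp(-log_odds))
                if include:
                    gamma[j, i] = 1
                    b[j, i] = m + rng.standard_normal() / np.sqrt(v)
                    r = r - b[j, i] * X[:, j]
                else:
                    gamma[j, i] = 0
                    b[j, i] = 0.0
            # intercept
            r = r + mu[i]
            prec = 1.0 / priors.mu_var + li * n_obs
            mean = li * r.sum() / prec
            mu[i] = mean + rng.standard_normal() / np.sqrt(prec)
            r = r - mu[i]
            # precision
            sse = float(r @ r)
            lam[i] = rng.gamma(priors.lambda_shape + 0.5 * n_obs,
                               1.0 / (priors.lambda_rate + 0.5 * sse))
            resid[:, i] = r
        if it >= burn_in:
            gamma_trace[kept] = gamma
            if kept % thin == 0 and thin_kept < n_thin:
                b_trace[thin_kept] = b
                lam_trace[thin_kept] = lam
                mu_trace[thin_kept] = mu
                thin_kept += 1
            kept += 1

    prob = gamma_trace.mean(axis=0)
    np.fill_diagonal(prob, 0.0)
    return ChainResult(prob=prob, gamma_trace=gamma_trace,
                       b_trace=b_trace[:thin_kept],
                       lambda_trace=lam_trace[:thin_kept],
                       mu_trace=mu_trace[:thin_kept])


def gibbs_infer(series: pd.DataFrame | np.ndarray, *, n_iter: int = 20000,
                burn_in: int | None = None, n_chains: int = 2, seed: int = 0,
                priors: Priors = Priors(), gene_names: Sequence[str] | None = None,
                fixed_gamma: np.ndarray | None = None, thin: int = 10) -> PosteriorNetwork:
    """Spike-and-slab Gibbs inference of the lag-1 regulatory network.

    ``series`` is (time x genes).  Returns pooled and per-chain posterior
    link-probability matrices with Gamma/B/Lambda/Mu traces.  ``fixed_gamma``
    clamps the inclusion indicators (used to validate the conjugate B
    update against the closed-form Bayesian regression posterior).
    """
    if isinstance(series, pd.DataFrame):
        names = [str(c) for c in series.columns]
        x = series.to_numpy(float)
    else:
        x = np.asarray(series, float)
        names = [f"g{j}" for j in range(x.shape[1])]
    if gene_names is not None:
        names = list(gene_names)
    T, G = x.shape
    if T < 10:
        raise ValueError("series must have at least 10 time points")
    if len(np.unique(x, axis=0)) < 2:
        raise ValueError("degenerate series: fewer than 2 distinct time points")
    if burn_in is None:
        burn_in = n_iter // 2
    if not 0 <= burn_in < n_iter:
        raise ValueError("need n_iter > burn_in >= 0")

    z, informative = _standardize(x)
    for name, ok in zip(names, informative):
        if not ok:
            warnings.warn(f"gene {name!r} is constant: excluded as regulator, "
                          "prior-only as target", stacklevel=2)

    rho = priors.rho if priors.rho is not None else 1.0 / G
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chains = [
        _run_chain(z, informative, priors, rho, n_iter, burn_in,
                   np.random.default_rng(s), fixed_gamma, thin)
        for s in seeds
    ]
    pooled = np.mean([c.prob for c in chains], axis=0)
    np.fill_diagonal(pooled, 0.0)
    return PosteriorNetwork(genes=names, prob=pooled, chains=chains,
                            priors=priors, n_iter=n_iter, burn_in=burn_in,
                            metadata={"rho": rho, "n_chains": n_chains,
                                      "seed": seed, "ridge_jitter": RIDGE_JITTER})


def convergence(post: PosteriorNetwork, tolerance: float = 0.05) -> tuple[float, bool]:
    """Largest absolute pairwise difference of per-chain link probabilities,
    and whether it is below ``tolerance``."""
    if len(post.chains) < 2:
        raise ValueError("convergence needs at least 2 chains")
    shapes = {c.prob.shape for c in post.chains}
    if len(shapes) != 1:
        raise ValueError("chains have mismatched dimensions")
    diag = 0.0
    for a in range(len(post.chains)):
        for b in range(a + 1, len(post.chains)):
            diag = max(diag, float(np.max(np.abs(post.chains[a].prob - post.chains[b].prob))))
    return diag, diag < tolerance


def network_uncertainty(post: PosteriorNetwork) -> dict:
    """Posterior distribution of each target's regulator count, plus top
    regulators ranked by pooled link probability."""
    if not post.chains or post.chains[0].gamma_trace.size == 0:
        raise ValueError("posterior carries no Gamma traces")
    traces = np.concatenate([c.gamma_trace for c in post.chains], axis=0)
    out: dict[str, dict] = {}
    G = len(post.genes)
    for i, gene in enumerate(post.genes):
        counts = traces[:, :, i].sum(axis=1)      # regulators of gene i per sample
        hist = np.bincount(counts, minlength=G)
        regs = sorted(((post.genes[j], float(post.prob[j, i]))
                       for j in range(G) if j != i), key=lambda t: (-t[1], t[0]))
        out[gene] = {
            "regulator_count_distribution": (hist / hist.sum()).tolist(),
            "top_regulators": regs,
        }
    return out


def top_regulators(post: PosteriorNetwork, k: int = 2) -> list[tuple[str, float]]:
    """Genes ranked by their strongest outgoing link probability."""
    strength = post.prob.max(axis=1)
    order = sorted(range(len(post.genes)), key=lambda j: (-strength[j], post.genes[j]))
    return [(post.genes[j], float(strength[j])) for j in order[:k]]
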