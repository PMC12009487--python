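"""Hierarchical Bayesian space-time models for count panels.

Six model variants for observed counts ``Y_ij ~ Poisson(E_ij * theta_ij)``:

* nonparametric, no interaction:  ``log theta_ij = a + v_i + u_i + g_j + f_j``
* nonparametric with a Knorr-Held interaction delta_ij of type I-IV:
  ``log theta_ij = a + v_i + u_i + g_j + f_j + d_ij``
* parametric trend:  ``log theta_ij = a + u_i + v_i + (b + s_i) * t_j``

with v_i iid normal (unstructured space), u_i intrinsic CAR (structured
space), g_j a second-order random walk (structured time), f_j iid normal
(unstructured time), b a global linear slope and s_i region-specific slope
deviations.  Interaction types cross the unstructured/structured space and
time components: I = iid, II = region-wise random walks, III = year-wise
ICAR, IV = ICAR (x) walk (Kronecker).

Inference is by MCMC: random effects are parametrized in the eigenbasis of
their structure matrices (see :mod:`stsir.gmrf`), which makes every prior a
diagonal Gaussian and enforces sum-to-zero / margin constraints exactly; the
latent field is updated jointly by MALA (preconditioned Langevin proposals
with dual-averaging step-size adaptation) and the random-effect precisions
by conjugate Gibbs steps.  Precisions carry Gamma(1, 5e-5) priors, the
common vague default for disease-mapping software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import poisson as _poisson

from . import gmrf
from .panel_io import AdjacencyGraph, CountPanel
from .standardization import ExpectedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "McmcConfig",
    "PosteriorFit",
    "MODEL_VARIANTS",
    "icar_log_prior",
    "rw2_log_prior",
    "interaction_log_prior",
    "fit",
    "adjusted_sir_table",
]

INTERACTION_TYPES = ("none", "I", "II", "III", "IV")


@dataclass(frozen=True)
class ModelSpec:
    """One of the six space-time model variants."""

    kind: str = "nonparametric"           # "nonparametric" | "parametric"
    interaction: str = "none"             # "none" | "I" | "II" | "III" | "IV"
    interaction_walk_order: int = 1       # RW order inside type II/IV
    temporal_walk_order: int = 2          # main temporal effect is RW2
    slope_prior: str = "iid"              # parametric region slopes: "iid" | "icar"

    def __post_init__(self):
        if self.kind not in ("nonparametric", "parametric"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.interaction not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.interaction!r}")
        if self.interaction_walk_order not in (1, 2):
            raise ValueError("interaction_walk_order must be 1 or 2")
        if self.temporal_walk_order != 2:
            raise ValueError("the structured temporal effect is fixed at RW2")
        if self.slope_prior not in ("iid", "icar"):
            raise ValueError("slope_prior must be 'iid' or 'icar'")

    @property
    def label(self) -> str:
        if self.kind == "parametric":
            return "parametric"
        return "nonparametric" if self.interaction == "none" else f"type_{self.interaction}"


#: The six variants compared in the analysis, in canonical order.
MODEL_VARIANTS = (
    ModelSpec("nonparametric", "none"),
    ModelSpec("nonparametric", "I"),
    ModelSpec("nonparametric", "II"),
    ModelSpec("nonparametric", "III"),
    ModelSpec("nonparametric", "IV"),
    ModelSpec("parametric"),
)


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    target_accept: float = 0.574
    mala_steps: int = 3
    # Gamma prior on every random-effect precision
    precision_shape: float = 1.0
    precision_rate: float = 5e-5
    # fixed prior standard deviation for alpha, beta and the free RW2
    # null-space (linear) direction
    fixed_effect_sd: float = 10.0
    rhat_limit: float = 1.05


# ---------------------------------------------------------------------------
# log-prior kernels (the quadratic forms behind the eigenbasis parametrization)
# ---------------------------------------------------------------------------

def icar_log_prior(u, graph: AdjacencyGraph, precision: float) -> float:
    """Joint ICAR kernel ``-tau/2 * sum_{i~j} (u_i - u_j)^2``.

    Consistent with full conditionals u_i | u_-i ~ N(mean of neighbours,
    1/(tau * n_i)); the improper normalizing constant is dropped.
    """
    u = np.asarray(u, dtype=float)
    if graph.n_regions == 0:
        raise ValueError("empty graph")
    if u.shape != (graph.n_regions,):
        raise ValueError("effect vector length does not match graph")
    L = graph.laplacian()
    return float(-0.5 * precision * u @ L @ u)


def rw2_log_prior(gamma, precision: float) -> float:
    """RW2 kernel ``-tau/2 * sum_j (gamma_j - 2 gamma_{j-1} + gamma_{j-2})^2``."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size < 3:
        raise ValueError("RW2 needs at least 3 time points")
    d2 = np.diff(gamma, n=2)
    return float(-0.5 * precision * np.sum(d2 ** 2))


def interaction_log_prior(delta, itype: str, graph: AdjacencyGraph,
                          walk_order: int, precision: float) -> float:
    """Quadratic-form kernel of a Knorr-Held interaction matrix (region x year)."""
    D = np.asarray(delta, dtype=float)
    n, T = D.shape
    if n != graph.n_regions:
        raise ValueError("interaction rows do not match graph")
    if itype == "I":
        q = np.sum(D ** 2)
    elif itype == "II":
        q = np.sum(np.diff(D, n=walk_order, axis=1) ** 2)
    elif itype == "III":
        L = graph.laplacian()
        q = float(np.sum(D * (L @ D)))
    elif itype == "IV":
        L = graph.laplacian()
        K = gmrf.rw_structure(T, walk_order)
        q = float(np.sum(D * (L @ D @ K)))
    else:
        raise ValueError(f"unknown interaction type {itype!r}")
    return float(-0.5 * precision * q)


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    name: str
    sl: slice
    eigenvalues: np.ndarray | None   # hyper-precision block if not None
    fixed_prec: float = 0.0
    basis: np.ndarray | None = None  # maps coefficients to the natural effect
    shape: tuple = ()                # natural-scale shape for reporting


class _Design:
    """Flat design matrix over cells plus per-block prior bookkeeping."""

    def __init__(self, panel: CountPanel, graph: AdjacencyGraph, spec: ModelSpec,
                 cfg: McmcConfig):
        n, T = panel.n_regions, panel.n_years
        self.n, self.T = n, T
        fixed_prec = 1.0 / cfg.fixed_effect_sd ** 2
        cols, blocks = [], []
        pos = 0

        def add(name, mat, eig=None, fprec=0.0, basis=None, shape=()):
            nonlocal pos
            cols.append(mat)
            blocks.append(_Block(name, slice(pos, pos + mat.shape[1]), eig,
                                 fprec, basis, shape))
            pos += mat.shape[1]

        ones_T = np.ones((T, 1))
        add("alpha", np.ones((n * T, 1)), fprec=fixed_prec)

        vb = gmrf.iid_contrast_basis(n)
        add("v", np.kron(vb.basis, ones_T), eig=vb.eigenvalues,
            basis=vb.basis, shape=(n,))
        ub = gmrf.penalized_basis(gmrf.icar_structure(graph))
        add("u", np.kron(ub.basis, ones_T), eig=ub.eigenvalues,
            basis=ub.basis, shape=(n,))

        if spec.kind == "nonparametric":
            gb = gmrf.penalized_basis(gmrf.rw_structure(T, spec.temporal_walk_order))
            add("gamma", np.kron(np.ones((n, 1)), gb.basis), eig=gb.eigenvalues,
                basis=gb.basis, shape=(T,))
            lin = gmrf.linear_trend_direction(T)[:, None]
            add("gamma_lin", np.kron(np.ones((n, 1)), lin), fprec=fixed_prec,
                basis=lin, shape=(T,))
            pb = gmrf.iid_contrast_basis(T)
            add("phi", np.kron(np.ones((n, 1)), pb.basis), eig=pb.eigenvalues,
                basis=pb.basis, shape=(T,))
            if spec.interaction != "none":
                ib = gmrf.interaction_basis(spec.interaction, graph, T,
                                            spec.interaction_walk_order)
                add("delta", ib.basis, eig=ib.eigenvalues,
                    basis=ib.basis, shape=(n, T))
        else:
            t = np.arange(T, dtype=float)
            t -= t.mean()
            self.t = t
            add("beta", np.kron(np.ones((n, 1)), t[:, None]), fprec=fixed_prec)
            if spec.slope_prior == "icar":
                sb = gmrf.penalized_basis(gmrf.icar_structure(graph))
            else:
                sb = gmrf.iid_contrast_basis(n)
            add("delta_i", np.kron(sb.basis, t[:, None]), eig=sb.eigenvalues,
                basis=sb.basis, shape=(n,))

        self.B = np.ascontiguousarray(np.hstack(cols))
        self.blocks = {b.name: b for b in blocks}
        self.p = pos
        self.hyper_blocks = [b for b in blocks if b.eigenvalues is not None]
        self.fixed_prec_vec = np.zeros(self.p)
        for b in blocks:
            if b.eigenvalues is None:
                self.fixed_prec_vec[b.sl] = b.fixed_prec
        self.pairs = self._build_pairs(spec)

    def _cols(self, names):
        return np.concatenate([np.arange(self.blocks[n].sl.start,
                                         self.blocks[n].sl.stop) for n in names])

    def _build_pairs(self, spec: ModelSpec) -> list:
        """Precompute shared-subspace geometry for the split-Gibbs moves.

        Effects whose design columns span overlapping subspaces of cell space
        (v and u; phi and the structured temporal effect; interactions and
        the main effects they contain) are only jointly identified; the
        split of the shared component is resampled from its exact Gaussian
        conditional each iteration, which the gradient sampler alone
        traverses too slowly.
        """
        pair_names = [(("v",), ("u",), ("v", "u"))]
        if "phi" in self.blocks:
            pair_names.append((("phi",), ("gamma", "gamma_lin"), ("phi", "gamma")))
        if "delta" in self.blocks:
            it = spec.interaction
            if it in ("I", "III"):
                pair_names += [(("delta",), ("v",), None), (("delta",), ("u",), None)]
            if it in ("I", "II"):
                pair_names += [(("delta",), ("phi",), None),
                               (("delta",), ("gamma", "gamma_lin"), None)]
            if it == "I":
                pair_names.append((("delta",), ("alpha",), None))
        pairs = []
        for namesA, namesB, swap in pair_names:
            pair = self._overlap_pair(namesA, namesB)
            if pair is not None:
                pair["swap_taus"] = swap
                pairs.append(pair)
        return pairs

    def _overlap_pair(self, namesA, namesB):
        idxA, idxB = self._cols(namesA), self._cols(namesB)
        Ba, Bb = self.B[:, idxA], self.B[:, idxB]
        Qa = Ba / np.linalg.norm(Ba, axis=0)
        Qb = Bb / np.linalg.norm(Bb, axis=0)
        u_sv, s_sv, vt_sv = np.linalg.svd(Qa.T @ Qb)
        m = int(np.sum(s_sv > 1 - 1e-8))
        if m == 0:
            return None
        W = Qa @ u_sv[:, :m]                       # orthonormal overlap basis
        na = np.sum(Ba ** 2, axis=0)
        nb = np.sum(Bb ** 2, axis=0)
        Ua = (Ba.T @ W) / na[:, None]              # Ba @ Ua = W
        Ub = (Bb.T @ W) / nb[:, None]
        WtBa = W.T @ Ba                            # overlap coords of an effect
        WtBb = W.T @ Bb
        return {"idxA": idxA, "idxB": idxB, "Ua": Ua, "Ub": Ub,
                "WtBa": WtBa, "WtBb": WtBb}

    def prior_precision(self, taus: dict) -> np.ndarray:
        prec = self.fixed_prec_vec.copy()
        for b in self.hyper_blocks:
            prec[b.sl] = taus[b.name] * b.eigenvalues
        return prec


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorFit:
    """MCMC output for one model variant.

    ``theta_draws`` holds posterior draws of the relative-risk surface
    (draws x regions x years); ``loglik_draws`` the matching per-cell Poisson
    log-likelihoods (draws x cells, cells flattened region-major).
    """

    model: ModelSpec
    region_ids: list
    years: list
    observed: np.ndarray
    expected: np.ndarray
    draws: dict
    theta_draws: np.ndarray
    loglik_draws: np.ndarray
    diagnostics: pd.DataFrame
    converged: bool
    accept_rate: float = float("nan")

    @property
    def theta_mean(self) -> np.ndarray:
        return self.theta_draws.mean(axis=0)

    def theta_ci(self, level: float = 0.95) -> tuple:
        lo = (1 - level) / 2
        return (np.quantile(self.theta_draws, lo, axis=0),
                np.quantile(self.theta_draws, 1 - lo, axis=0))

    @property
    def n_draws(self) -> int:
        return self.theta_draws.shape[0]


def _dual_averaging_init(eps0):
    return {"mu": np.log(10 * eps0), "log_eps": np.log(eps0),
            "log_eps_bar": 0.0, "H": 0.0, "m": 0}


def _dual_averaging_update(st, accept_prob, target):
    st["m"] += 1
    m = st["m"]
    st["H"] = (1 - 1 / (m + 10)) * st["H"] + (target - accept_prob) / (m + 10)
    st["log_eps"] = st["mu"] - np.sqrt(m) / 0.05 * st["H"]
    w = m ** -0.75
    st["log_eps_bar"] = w * st["log_eps"] + (1 - w) * st["log_eps_bar"]


def _run_chain(design: _Design, Yf, Ef, cfg: McmcConfig, rng):
    """One chain of the MALA-within-Gibbs sampler.

    Each iteration does (a) conjugate Gibbs updates of the random-effect
    precisions, (b) a few preconditioned MALA updates of the whole latent
    vector, and (c) one joint rescaling move per random effect that multiplies
    the effect by c and its precision by 1/c^2 — the move travels along the
    funnel between an effect's scale and its precision, which neither Gibbs
    nor MALA alone traverses efficiently.
    """
    B, p = design.B, design.p
    a0, b0 = cfg.precision_shape, cfg.precision_rate
    x = np.zeros(p)
    x[design.blocks["alpha"].sl] = np.log(max(Yf.sum(), 1.0) / Ef.sum())
    taus = {b.name: 10.0 for b in design.hyper_blocks}

    def loglik_parts(x):
        eta = B @ x
        lam = Ef * np.exp(np.clip(eta, -30, 30))
        return eta, lam, Yf @ eta - lam.sum()

    def logpost_grad(x, prec):
        eta, lam, lik = loglik_parts(x)
        lp = lik - 0.5 * np.sum(prec * x * x)
        grad = B.T @ (Yf - lam) - prec * x
        return lp, grad

    from scipy.linalg import cho_solve, cholesky, solve_triangular

    # fixed Gauss-Newton reference curvature of the Poisson likelihood;
    # the full (dense) metric H = G0 + diag(prior precision) captures the
    # exact linear ridges between effects sharing a column space, which a
    # diagonal preconditioner cannot represent
    lam_ref = np.maximum(Yf, 0.5)
    G0 = B.T @ (B * lam_ref[:, None])

    da = _dual_averaging_init(1.0)
    eps = np.exp(da["log_eps"])

    n_iter = cfg.warmup + cfg.draws
    keep_x = np.empty((cfg.draws, p))
    keep_tau = {b.name: np.empty(cfg.draws) for b in design.hyper_blocks}
    acc_count = 0
    acc_total = 0

    for it in range(n_iter):
        # (a) conjugate Gibbs update of each random-effect precision
        for b in design.hyper_blocks:
            z = x[b.sl]
            q = np.sum(b.eigenvalues * z * z)
            taus[b.name] = rng.gamma(a0 + 0.5 * b.eigenvalues.size,
                                     1.0 / (b0 + 0.5 * q))
        prec = design.prior_precision(taus)
        H = G0 + np.diag(prec)
        L = cholesky(H, lower=True)
        lp, grad = logpost_grad(x, prec)

        # (b) preconditioned MALA sweeps with metric H
        for _ in range(cfg.mala_steps):
            mean_fwd = x + 0.5 * eps ** 2 * cho_solve((L, True), grad)
            prop = mean_fwd + eps * solve_triangular(
                L, rng.standard_normal(p), lower=True, trans="T")
            lp_p, grad_p = logpost_grad(prop, prec)
            mean_rev = prop + 0.5 * eps ** 2 * cho_solve((L, True), grad_p)
            d_fwd = prop - mean_fwd
            d_rev = x - mean_rev
            log_q = (d_fwd @ H @ d_fwd - d_rev @ H @ d_rev) / (2 * eps ** 2)
            log_alpha = min(0.0, lp_p - lp + log_q)
            if np.log(rng.uniform()) < log_alpha:
                x, lp, grad = prop, lp_p, grad_p
                if it >= cfg.warmup:
                    acc_count += 1
            if it >= cfg.warmup:
                acc_total += 1
            if it < cfg.warmup:
                _dual_averaging_update(da, np.exp(log_alpha), cfg.target_accept)
                eps = np.exp(da["log_eps"])

        # (c) joint (effect, precision) rescaling move per random effect
        eta, lam, lik = loglik_parts(x)
        for b in design.hyper_blocks:
            z = x[b.sl]
            if not np.any(z):
                continue
            c = np.exp(0.3 * rng.standard_normal())
            delta_eta = (c - 1.0) * (design.B[:, b.sl] @ z)
            eta_p = eta + delta_eta
            lam_p = Ef * np.exp(np.clip(eta_p, -30, 30))
            lik_p = Yf @ eta_p - lam_p.sum()
            tau_p = taus[b.name] / c ** 2
            # z-prior normalization (tau'/tau)^{r/2} = c^{-r} cancels the
            # c^{r} part of the Jacobian c^{r-2}; the Gaussian kernel is
            # invariant under the move by construction
            log_prior = ((a0 - 1.0) * np.log(tau_p / taus[b.name])
                         - b0 * (tau_p - taus[b.name]))
            log_jac = -2.0 * np.log(c)
            if np.log(rng.uniform()) < lik_p - lik + log_prior + log_jac:
                x = x.copy()
                x[b.sl] = c * z
                taus[b.name] = tau_p
                eta, lam, lik = eta_p, lam_p, lik_p
        prec = design.prior_precision(taus)

        # (d) exact Gibbs resampling of shared-subspace splits
        for pr in design.pairs:
            zA, zB = x[pr["idxA"]], x[pr["idxB"]]
            pA, pB = prec[pr["idxA"]], prec[pr["idxB"]]
            cA = pr["WtBa"] @ zA
            cB = pr["WtBb"] @ zB
            s = cA + cB
            zresA = zA - pr["Ua"] @ cA
            zresB = zB - pr["Ub"] @ cB
            QA = pr["Ua"].T @ (pA[:, None] * pr["Ua"])
            QB = pr["Ub"].T @ (pB[:, None] * pr["Ub"])
            gA = pr["Ua"].T @ (pA * zresA)
            gB = pr["Ub"].T @ (pB * zresB)
            Q = QA + QB
            Lq = np.linalg.cholesky(Q)
            mean = np.linalg.solve(Q, QB @ s + gB - gA)
            cA_new = mean + np.linalg.solve(Lq.T, rng.standard_normal(len(s)))
            x[pr["idxA"]] = zresA + pr["Ua"] @ cA_new
            x[pr["idxB"]] = zresB + pr["Ub"] @ (s - cA_new)

        # (e) mode-swap move for fully overlapping pairs: exchange the shared
        # component and the two precisions (likelihood-invariant), jumping
        # between the "A explains the field" and "B explains it" modes
        for pr in design.pairs:
            if pr["swap_taus"] is None:
                continue
            nameA, nameB = pr["swap_taus"]
            idxA, idxB = pr["idxA"], pr["idxB"]
            zA, zB = x[idxA], x[idxB]
            cA = pr["WtBa"] @ zA
            cB = pr["WtBb"] @ zB
            zA_p = (zA - pr["Ua"] @ cA) + pr["Ua"] @ cB
            zB_p = (zB - pr["Ub"] @ cB) + pr["Ub"] @ cA
            taus_p = dict(taus)
            taus_p[nameA], taus_p[nameB] = taus[nameB], taus[nameA]
            prec_p = design.prior_precision(taus_p)

            def _logprior(zA_, zB_, pv):
                pa, pb = pv[idxA], pv[idxB]
                return 0.5 * (np.sum(np.log(pa)) + np.sum(np.log(pb))
                              - pa @ (zA_ * zA_) - pb @ (zB_ * zB_))

            if np.log(rng.uniform()) < (_logprior(zA_p, zB_p, prec_p)
                                        - _logprior(zA, zB, prec)):
                x[idxA], x[idxB] = zA_p, zB_p
                taus.update({nameA: taus_p[nameA], nameB: taus_p[nameB]})
                prec = prec_p

        if it < cfg.warmup:
            if it + 1 == cfg.warmup:
                eps = np.exp(da["log_eps_bar"])
        else:
            k = it - cfg.warmup
            keep_x[k] = x
            for b in design.hyper_blocks:
                keep_tau[b.name][k] = taus[b.name]

    return keep_x, keep_tau, acc_count / max(acc_total, 1)


def fit(panel: CountPanel, expected: ExpectedMatrix, graph: AdjacencyGraph,
        spec: ModelSpec = ModelSpec(), mcmc: McmcConfig = McmcConfig()) -> PosteriorFit:
    """Sample the posterior of one model variant.

    Returns a :class:`PosteriorFit` with draws of every model parameter,
    the relative-risk surface theta and per-cell log-likelihoods.  Split
    chains are checked with the rank-normalized scale-reduction statistic;
    a fit with any scalar's R-hat above the configured limit is flagged
    ``converged=False`` (downstream consumers should refuse it unless
    forced).
    """
    E = np.asarray(expected.expected, dtype=float)
    if np.any(E <= 0):
        raise ValueError("all expected counts must be positive for model fitting")
    if panel.observed.shape != E.shape:
        raise ValueError("panel and expected matrix shapes differ")
    design = _Design(panel, graph, spec, mcmc)
    Yf = panel.observed.ravel().astype(float)
    Ef = E.ravel()

    xs, tau_draws, acc = [], [], []
    for chain in range(mcmc.chains):
        rng = np.random.default_rng([int(mcmc.seed) % (2 ** 31), chain])
        kx, kt, a = _run_chain(design, Yf, Ef, mcmc, rng)
        xs.append(kx)
        tau_draws.append(kt)
        acc.append(a)

    X = np.concatenate(xs, axis=0)              # (chains*draws, p)
    S = X.shape[0]
    n, T = design.n, design.T

    draws: dict = {}
    bl = design.blocks
    draws["alpha"] = X[:, bl["alpha"].sl][:, 0]
    for name in ("v", "u", "gamma", "phi", "delta", "delta_i"):
        if name in bl and bl[name].basis is not None:
            eff = X[:, bl[name].sl] @ bl[name].basis.T
            if name == "delta":
                eff = eff.reshape(S, n, T)
            draws[name] = eff
    if "gamma" in draws and "gamma_lin" in bl:
        draws["gamma"] = draws["gamma"] + X[:, bl["gamma_lin"].sl] @ bl["gamma_lin"].basis.T
    if "beta" in bl:
        draws["beta"] = X[:, bl["beta"].sl][:, 0]
    for b in design.hyper_blocks:
        tau = np.concatenate([td[b.name] for td in tau_draws])
        draws[f"sd_{b.name}"] = 1.0 / np.sqrt(tau)

    eta = X @ design.B.T                        # (S, cells)
    theta_draws = np.exp(eta).reshape(S, n, T)
    lam = Ef[None, :] * np.exp(eta)
    loglik = _poisson.logpmf(panel.observed.ravel()[None, :], lam)

    diagnostics, converged = _convergence(draws, mcmc)
    fit_obj = PosteriorFit(
        model=spec, region_ids=list(panel.region_ids), years=list(panel.years),
        observed=panel.observed.copy(), expected=E.copy(), draws=draws,
        theta_draws=theta_draws, loglik_draws=loglik,
        diagnostics=diagnostics, converged=converged,
        accept_rate=float(np.mean(acc)),
    )
    if not converged:
        logger.warning("fit of %s flagged as not converged (max R-hat %.3f)",
                       spec.label, diagnostics["rhat"].max())
    return fit_obj


def _convergence(draws: dict, cfg: McmcConfig):
    """Split-chain R-hat / ESS for the scalar summaries, via arviz."""
    import arviz as az

    scalars = {}
    for name, arr in draws.items():
        if arr.ndim == 1:
            scalars[name] = arr
    rows = []
    ok = True
    for name, arr in scalars.items():
        a = np.asarray(arr).reshape(cfg.chains, -1)
        rhat = float(az.rhat(a))
        ess = float(az.ess(a))
        rows.append((name, rhat, ess))
        if not np.isfinite(rhat) or rhat > cfg.rhat_limit:
            ok = False
    return pd.DataFrame(rows, columns=["param", "rhat", "ess"]), ok


def adjusted_sir_table(fit_result: PosteriorFit, level: float = 0.95,
                       force: bool = False) -> pd.DataFrame:
    """Posterior-mean smoothed SIR per cell with a credible interval.

    Refuses fits flagged as not converged unless ``force=True``.
    """
    if not fit_result.converged and not force:
        raise RuntimeError("fit flagged as not converged; pass force=True to override")
    mean = fit_result.theta_mean
    lo, hi = fit_result.theta_ci(level)
    rows = []
    for i, r in enumerate(fit_result.region_ids):
        for j, y in enumerate(fit_result.years):
            rows.append((r, y, mean[i, j], lo[i, j], hi[i, j]))
    return pd.DataFrame(rows, columns=["region", "year", "sir_smoothed", "ci_low", "ci_high"])
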