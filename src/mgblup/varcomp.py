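"""AI-REML variance components for kernel mixed models.

The univariate model is

    y = 1*mu + sum_k u_k + e,    u_k ~ N(0, K_k sigma2_k),  e ~ N(0, I sigma2_e)

with K_k an individual-by-individual similarity kernel (genomic G and/or
microbial O) and the overall mean the sole fixed effect.  Restricted maximum
likelihood

    l_R = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ],
    V = sum_k sigma2_k K_k + sigma2_e I,
    P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1,

is maximised by average-information updates: the score for component k is
s_k = -1/2 [tr(P K_k) - y'P K_k P y] and the AI matrix is
A_ij = 1/2 y'P K_i P K_j P y.  Steps are halved whenever the likelihood would
decrease, an EM-REML step is the fallback when the AI proposal leaves the
parameter space, and components are pinned at a small floor when they
collapse.  The bivariate model stacks two traits with an unstructured 2x2
genetic block (Kronecker with G) and an unstructured 2x2 residual block,
giving the genetic correlation r_g = sigma_u12 / sqrt(sigma2_u1 sigma2_u2).

Standard errors of heritability, microbiability and r_g are obtained by
Monte Carlo: variance-component vectors are drawn from the asymptotic normal
N(theta_hat, AI^-1), negative variance draws are truncated at zero, the
ratio is evaluated per draw, and the sample SD is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .kernels import KernelMatrix

__all__ = [
    "KernelMixedModel",
    "KernelMixedResults",
    "BivariateKernelModel",
    "BivariateResults",
    "REMLError",
    "reml_loglik",
    "fit_reml",
    "fit_bivariate_reml",
    "derive_ratios",
    "monte_carlo_se",
]

log = logging.getLogger(__name__)

FLOOR_FRACTION = 1e-6  # variance floor as a fraction of Var(y)


class REMLError(ValueError):
    pass


# ----------------------------------------------------------------- likelihood

def _loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """REML log-likelihood (constant terms dropped); -inf when V is not PD."""
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = y @ Vi_y - (X.T @ Vi_y) @ beta
    return float(-0.5 * (logdet_v + logdet_x + yPy))


def reml_loglik(
    y: np.ndarray, kernels: list[np.ndarray], sigma2: np.ndarray,
    X: np.ndarray | None = None,
) -> float:
    """REML log-likelihood at sigma2 = (components..., residual).

    ``kernels`` excludes the residual identity; ``X`` defaults to the
    intercept-only design.
    """
    y = np.asarray(y, float)
    n = y.size
    sigma2 = np.asarray(sigma2, float)
    if len(sigma2) != len(kernels) + 1:
        raise REMLError("sigma2 must have one entry per kernel plus residual")
    if (sigma2 <= 0).any():
        raise REMLError("sigma2 must be positive")
    if X is None:
        X = np.ones((n, 1))
    V = sigma2[-1] * np.eye(n)
    for s, K in zip(sigma2[:-1], kernels):
        V = V + s * np.asarray(K, float)
    ll = _loglik(y, X, V)
    if not np.isfinite(ll):
        raise REMLError("V is singular at the supplied sigma2")
    return ll


# ------------------------------------------------------------------ AI engine

def _pmat(y, X, V):
    """Return (P, Py, loglik) or None when V / X'V^-1 X is not PD."""
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    n = V.shape[0]
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    Vi_X = Vi @ X
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return None
    P = Vi - Vi_X @ np.linalg.solve(XtViX, Vi_X.T)
    Py = P @ y
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    ll = float(-0.5 * (logdet_v + logdet_x + y @ Py))
    return P, Py, ll


class _DenseEvaluator:
    """REML likelihood, score and AI matrix on explicit n x n kernels."""

    def __init__(self, y, X, kernels):
        self.y = y
        self.X = X
        self.kernels = kernels
        self.n = y.size

    def loglik(self, theta):
        V = np.zeros((self.n, self.n))
        for t, K in zip(theta, self.kernels):
            V += t * K
        res = _pmat(self.y, self.X, V)
        if res is None:
            return None
        P, Py, ll = res
        return ll, (P, Py)

    def score_ai(self, theta, state):
        P, Py = state
        U = np.column_stack([K @ Py for K in self.kernels])
        PU = P @ U
        score = np.array(
            [-0.5 * (np.sum(P * K) - Py @ (K @ Py)) for K in self.kernels]
        )
        ai = 0.5 * (U.T @ PU)
        return score, ai

    def em_denominator(self):
        return self.n


class _BlockEvaluator:
    """REML quantities for kernels that share one eigenbasis.

    After rotating by the kernel eigenvectors, V falls apart into n
    independent d x d blocks (d = 1 for a single-trait single-kernel model,
    d = 2 for the bivariate model sharing one G), so every likelihood,
    score and AI evaluation is O(n) instead of O(n^3).  The rotation is an
    orthogonal transform of the data, leaving the REML likelihood exactly
    unchanged.

    Parameters
    ----------
    yt : (n, d) rotated responses.
    Xt : (n, d, p) rotated fixed-effect design per block.
    Kblocks : list of (n, d, d) per-block kernel contributions.
    """

    def __init__(self, yt, Xt, Kblocks):
        self.yt = yt
        self.Xt = Xt
        self.Kblocks = Kblocks
        self.n_blocks, self.d = yt.shape
        self.n = self.n_blocks * self.d

    def loglik(self, theta):
        V = np.zeros_like(self.Kblocks[0])
        for t, K in zip(theta, self.Kblocks):
            V = V + t * K
        try:
            np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        sign, logdet = np.linalg.slogdet(V)
        if (sign <= 0).any():
            return None
        Vi = np.linalg.inv(V)
        # S = X'V^-1X, b = X'V^-1y over blocks
        ViX = np.einsum("nij,njp->nip", Vi, self.Xt)
        S = np.einsum("nip,niq->pq", self.Xt, ViX)
        u = np.einsum("nij,nj->ni", Vi, self.yt)
        b = np.einsum("nip,ni->p", self.Xt, u)
        sign_s, logdet_s = np.linalg.slogdet(S)
        if sign_s <= 0:
            return None
        beta = np.linalg.solve(S, b)
        w = u - np.einsum("nip,p->ni", ViX, beta)  # Py in rotated coordinates
        yPy = float(np.einsum("ni,ni->", self.yt, u) - b @ beta)
        ll = float(-0.5 * (logdet.sum() + logdet_s + yPy))
        return ll, (Vi, ViX, S, w)

    def score_ai(self, theta, state):
        Vi, ViX, S, w = state
        Sinv = np.linalg.inv(S)
        k = len(self.Kblocks)
        score = np.empty(k)
        v = []  # K_k @ Py per parameter, rotated
        for idx, K in enumerate(self.Kblocks):
            # tr(P K) = tr(V^-1 K) - tr(S^-1 X'V^-1 K V^-1 X)
            tr_vik = np.einsum("nij,nji->", Vi, K)
            XtViK = np.einsum("nip,nij->npj", ViX, K)
            corr = np.einsum("npj,njq->pq", XtViK, ViX)
            tr_pk = tr_vik - np.trace(Sinv @ corr)
            Kw = np.einsum("nij,nj->ni", K, w)
            score[idx] = -0.5 * (tr_pk - float(np.einsum("ni,ni->", w, Kw)))
            v.append(Kw)
        # AI_ij = 0.5 * v_i' P v_j with P applied blockwise
        ai = np.empty((k, k))
        Viv = [np.einsum("nij,nj->ni", Vi, vk) for vk in v]
        c = [np.einsum("nip,ni->p", self.Xt, vv) for vv in Viv]
        for i in range(k):
            for j in range(i, k):
                term = float(np.einsum("ni,ni->", v[i], Viv[j]))
                term -= float(c[i] @ Sinv @ c[j])
                ai[i, j] = ai[j, i] = 0.5 * term
        return score, ai

    def em_denominator(self):
        return self.n


def _ai_reml(
    evaluator,
    theta0: np.ndarray,
    floor: np.ndarray,
    constrain,
    variance_mask: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
):
    """Generic AI-REML over theta with V = sum_k theta_k * K_k.

    ``evaluator`` supplies the likelihood and the score/AI quantities (dense
    or eigen-rotated), ``floor`` gives per-parameter lower bounds (-inf for
    covariances), ``constrain`` maps a proposal back into the feasible set,
    and ``variance_mask`` flags pure variance parameters (eligible for the
    EM fallback and floor pinning).

    Returns a dict with theta, ai (final AI matrix), llf trace, convergence
    flag, iteration count and a reason string.
    """
    n = evaluator.em_denominator()
    theta = constrain(np.asarray(theta0, float).copy())
    trace: list[float] = []
    converged = False
    reason = "max_iter"
    ai = np.eye(len(theta))
    at_floor_streak = np.zeros(len(theta), dtype=int)

    res = evaluator.loglik(theta)
    if res is None:
        raise REMLError("initial V is not positive definite")
    ll, state = res
    trace.append(ll)

    for it in range(1, max_iter + 1):
        score, ai = evaluator.score_ai(theta, state)

        # pin collapsed variance components pushed further down
        pinned = (
            variance_mask
            & (theta <= floor * (1 + 1e-9))
            & (score < 0)
            & (at_floor_streak >= 2)
        )
        free = ~pinned

        if np.linalg.norm(score[free]) < 1e-6 and len(trace) > 1 \
                and abs(trace[-1] - trace[-2]) < tol:
            converged, reason = True, "gradient"
            break

        delta = np.zeros_like(theta)
        try:
            a_free = ai[np.ix_(free, free)]
            ridge = 1e-8 * max(np.diag(a_free).max(), 1e-300)
            delta[free] = np.linalg.solve(
                a_free + ridge * np.eye(free.sum()), score[free])
        except np.linalg.LinAlgError:
            delta[free] = score[free]  # gradient fallback

        # trust region: a near-singular AI matrix can propose absurd steps
        scale = np.maximum(np.abs(theta), 0.1 * np.abs(theta).max() + 1e-300)
        worst = np.max(np.abs(delta) / scale)
        if worst > 5.0:
            delta *= 5.0 / worst

        def try_direction(direction):
            step = 1.0
            for _ in range(30):
                cand = constrain(theta + step * direction)
                res = evaluator.loglik(cand)
                if res is not None and res[0] >= ll - 1e-12 \
                        and not np.allclose(cand, theta):
                    return cand, res
                step /= 2.0
            return None

        hit = try_direction(delta)
        if hit is None:
            # EM-REML step for the variance parameters:
            # theta + theta^2 (y'PKPy - tr(PK)) / n = theta + 2 theta^2 s / n
            cand = theta.copy()
            for k in np.where(variance_mask & free)[0]:
                cand[k] = theta[k] + 2.0 * theta[k] ** 2 * score[k] / n
            cand = constrain(cand)
            res = evaluator.loglik(cand)
            if res is not None and res[0] >= ll - 1e-12 \
                    and not np.allclose(cand, theta):
                hit = cand, res
        if hit is None:
            # scaled-gradient fallback (moves covariances when AI/EM cannot)
            grad = score.copy()
            grad[~free] = 0.0
            gw = np.max(np.abs(grad) / scale)
            if gw > 0:
                hit = try_direction(grad * (1.0 / gw))

        if hit is not None:
            theta, (ll, state) = hit
            rejected_streak = 0
            trace.append(ll)
            at_floor_streak = np.where(
                variance_mask & (theta <= floor * (1 + 1e-9)),
                at_floor_streak + 1,
                0,
            )
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged, reason = True, "loglik"
                break
        else:
            # no feasible direction improves the likelihood by more than the
            # acceptance tolerance: a constrained (possibly boundary)
            # optimum within numerical precision
            converged, reason = True, "stationary"
            break

    return {
        "theta": theta,
        "ai": ai,
        "llf_trace": trace,
        "converged": converged,
        "n_iter": len(trace) - 1,
        "reason": reason,
    }


# ------------------------------------------------------------ univariate model

@dataclass
class VarCompEstimate:
    """Variance components with their asymptotic covariance (inverse AI)."""

    sigma2: np.ndarray
    labels: list[str]
    cov: np.ndarray

    def as_series(self) -> pd.Series:
        return pd.Series(self.sigma2, index=self.labels)


class KernelMixedModel:
    """Mixed model with an overall mean and kernel random effects.

    Parameters
    ----------
    y : phenotype Series indexed by individual id (missing allowed; the fit
        is on complete cases), or a plain array when ``ids`` is given.
    kernels : one or two :class:`KernelMatrix` objects (G and/or O); their
        kinds label the components.  Duplicated kinds are rejected.
    """

    def __init__(self, y, kernels: list[KernelMatrix], ids=None):
        if isinstance(y, pd.Series):
            s = y.astype(float)
        else:
            if ids is None:
                ids = kernels[0].ids
            s = pd.Series(np.asarray(y, float), index=[str(i) for i in ids])
        if not kernels:
            raise REMLError("at least one kernel is required")
        kinds = [k.kind for k in kernels]
        if len(set(kinds)) != len(kinds):
            raise REMLError(f"duplicated kernel kinds: {kinds}")
        s = s.dropna()
        keep = [i for i in s.index.astype(str) if all(i in k.ids for k in kernels)]
        if len(keep) < len(s):
            missing = len(s) - len(keep)
            raise REMLError(f"{missing} phenotyped ids absent from a kernel")
        self.ids = keep
        self.y = s.loc[keep].to_numpy()
        self.kernels = [k.subset(keep) for k in kernels]
        for k in self.kernels:
            k.check_psd()
        self.labels = kinds + ["residual"]

    def fit(self, tol: float = 1e-8, max_iter: int = 200) -> "KernelMixedResults":
        n = self.y.size
        vary = float(np.var(self.y, ddof=1))
        if vary <= 0:
            raise REMLError("phenotype has zero variance")
        jitter = 1e-8
        mats = [k.values + jitter * np.eye(n) for k in self.kernels]
        mats.append(np.eye(n))
        p = len(mats)
        theta0 = np.full(p, vary / p)
        floor = np.full(p, FLOOR_FRACTION * vary)

        def constrain(th):
            return np.maximum(th, floor)

        if len(self.kernels) == 1:
            # single kernel: rotate to its eigenbasis, V becomes diagonal
            w, E = np.linalg.eigh(mats[0])
            yt = (E.T @ self.y)[:, None]
            Xt = (E.T @ np.ones(n))[:, None, None]
            Kblocks = [w[:, None, None], np.ones((n, 1, 1))]
            evaluator = _BlockEvaluator(yt, Xt, Kblocks)
        else:
            evaluator = _DenseEvaluator(self.y, np.ones((n, 1)), mats)

        out = _ai_reml(
            evaluator, theta0, floor, constrain,
            variance_mask=np.ones(p, dtype=bool), tol=tol, max_iter=max_iter,
        )
        try:
            cov = np.linalg.inv(out["ai"])
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(out["ai"])
        est = VarCompEstimate(out["theta"], list(self.labels), (cov + cov.T) / 2)
        return KernelMixedResults(
            model=self,
            estimate=est,
            converged=out["converged"],
            n_iter=out["n_iter"],
            llf_trace=out["llf_trace"],
            reason=out["reason"],
        )


@dataclass
class KernelMixedResults:
    """Fit results: components, AI covariance, derived ratios, diagnostics."""

    model: KernelMixedModel
    estimate: VarCompEstimate
    converged: bool
    n_iter: int
    llf_trace: list[float]
    reason: str = ""

    @property
    def params(self) -> pd.Series:
        return self.estimate.as_series()

    @property
    def llf(self) -> float:
        return self.llf_trace[-1]

    @property
    def nobs(self) -> int:
        return len(self.model.ids)

    def _ratio_defs(self):
        """Map ratio name -> numerator component index.

        Single-kernel fits use sigma2_k/(sigma2_k + sigma2_e) (total h2 or
        m2); joint fits partition against everything (direct h2-bar, m2-bar).
        """
        labels = self.estimate.labels[:-1]
        joint = len(labels) > 1
        names = {}
        for i, lab in enumerate(labels):
            base = "h2" if lab == "genomic" else "m2"
            names[f"{base}_bar" if joint else base] = i
        return names, joint

    @property
    def ratios(self) -> dict[str, float] | None:
        """h2 / m2 (single kernel) or h2_bar / m2_bar (joint); None if not converged."""
        if not self.converged:
            return None
        s = self.estimate.sigma2
        names, joint = self._ratio_defs()
        total_all = s.sum()
        out = {}
        for name, i in names.items():
            denom = total_all if joint else s[i] + s[-1]
            out[name] = float(s[i] / denom)
        return out

    def monte_carlo_se(self, n_draws: int = 10000, seed: int = 0) -> dict[str, float]:
        """Monte-Carlo SEs of the ratio parameters (see module docstring)."""
        if not self.converged:
            raise REMLError("SEs undefined for a non-converged fit")
        draws = _mc_draws(self.estimate.sigma2, self.estimate.cov, n_draws, seed)
        names, joint = self._ratio_defs()
        s = draws  # (n_draws, p)
        out = {}
        for name, i in names.items():
            denom = s.sum(axis=1) if joint else s[:, i] + s[:, -1]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, s[:, i] / denom, 0.0)
            out[name] = float(np.std(r, ddof=1))
        return out

    def summary(self) -> str:
        lines = [
            "Kernel mixed model (AI-REML)",
            f"  n = {self.nobs}, components = {self.estimate.labels}",
            f"  converged = {self.converged} ({self.reason}), "
            f"iterations = {self.n_iter}, REML loglik = {self.llf:.4f}",
            "",
            "  Variance components:",
        ]
        se = np.sqrt(np.maximum(np.diag(self.estimate.cov), 0.0))
        for lab, v, s in zip(self.estimate.labels, self.estimate.sigma2, se):
            lines.append(f"    {lab:<10} {v:>12.6g}  (SE {s:.3g})")
        if self.converged:
            mcse = self.monte_carlo_se(n_draws=2000, seed=0)
            lines.append("  Ratios:")
            for name, val in self.ratios.items():
                lines.append(f"    {name:<10} {val:>8.3f}  (MC SE {mcse[name]:.3f})")
        else:
            lines.append("  Ratios: — (not converged)")
        return "\n".join(lines)


def _mc_draws(theta, cov, n_draws, seed):
    """Draws from N(theta, cov) with negative variance draws truncated at 0."""
    rng = np.random.default_rng(seed)
    cov = (np.asarray(cov) + np.asarray(cov).T) / 2
    w, V = np.linalg.eigh(cov)
    if w.min() < 0:
        log.warning("asymptotic covariance not PSD; projecting (min eig %.2e)",
                    w.min())
        w = np.maximum(w, 0.0)
    L = V * np.sqrt(w)
    z = rng.standard_normal((n_draws, len(theta)))
    draws = theta + z @ L.T
    return np.maximum(draws, 0.0)


# ------------------------------------------------------------- bivariate model

def _project_psd_2x2(block: np.ndarray, floor: float) -> np.ndarray:
    """Nearest PSD 2x2 (eigenvalue clip) with diagonal floored."""
    b = (block + block.T) / 2
    w, V = np.linalg.eigh(b)
    w = np.maximum(w, 0.0)
    b = V @ np.diag(w) @ V.T
    b[0, 0] = max(b[0, 0], floor)
    b[1, 1] = max(b[1, 1], floor)
    # keep |corr| <= 1 after flooring
    lim = np.sqrt(b[0, 0] * b[1, 1])
    b[0, 1] = b[1, 0] = np.clip(b[0, 1], -lim, lim)
    return b


class BivariateKernelModel:
    """Two-trait animal model sharing one genomic kernel.

    The stacked covariance is  V = Ku (x) G + Ke (x) I  with unstructured
    2x2 genetic (Ku) and residual (Ke) blocks estimated by AI-REML; each
    block is projected to PSD after every accepted step.  Complete cases
    (both traits observed) only.
    """

    PARAM_LABELS = ["su2_1", "su_12", "su2_2", "se2_1", "se_12", "se2_2"]

    def __init__(self, y1: pd.Series, y2: pd.Series, G: KernelMatrix):
        y1 = y1.astype(float).dropna()
        y2 = y2.astype(float).dropna()
        keep = [i for i in y1.index.astype(str) if i in set(y2.index.astype(str))
                and i in set(G.ids)]
        if len(keep) < 10:
            raise REMLError(f"only {len(keep)} complete cases; need >= 10")
        self.ids = keep
        self.y1 = y1.loc[keep].to_numpy()
        self.y2 = y2.loc[keep].to_numpy()
        self.G = G.subset(keep)
        self.G.check_psd()

    def fit(self, tol: float = 1e-8, max_iter: int = 200) -> "BivariateResults":
        n = len(self.ids)
        Gm = self.G.values + 1e-8 * np.eye(n)
        v1 = float(np.var(self.y1, ddof=1))
        v2 = float(np.var(self.y2, ddof=1))
        floor1, floor2 = FLOOR_FRACTION * v1, FLOOR_FRACTION * v2

        basis = [
            np.array([[1.0, 0], [0, 0]]),
            np.array([[0, 1.0], [1.0, 0]]),
            np.array([[0, 0], [0, 1.0]]),
        ]
        # rotate by G's eigenbasis: V splits into n independent 2x2 blocks
        w, E = np.linalg.eigh(Gm)
        yt = np.column_stack([E.T @ self.y1, E.T @ self.y2])
        a = E.T @ np.ones(n)
        Xt = np.einsum("n,jp->njp", a, np.eye(2))
        Kblocks = [B[None, :, :] * w[:, None, None] for B in basis]
        Kblocks += [np.broadcast_to(B, (n, 2, 2)).copy() for B in basis]
        evaluator = _BlockEvaluator(yt, Xt, Kblocks)

        theta0 = np.array([v1 / 2, 0.0, v2 / 2, v1 / 2, 0.0, v2 / 2])
        floor = np.array([floor1, -np.inf, floor2, floor1, -np.inf, floor2])
        variance_mask = np.array([True, False, True, True, False, True])

        def constrain(th):
            out = th.copy()
            ug = _project_psd_2x2(
                np.array([[th[0], th[1]], [th[1], th[2]]]),
                floor=min(floor1, floor2),
            )
            ue = _project_psd_2x2(
                np.array([[th[3], th[4]], [th[4], th[5]]]),
                floor=min(floor1, floor2),
            )
            out[:3] = ug[0, 0], ug[0, 1], ug[1, 1]
            out[3:] = ue[0, 0], ue[0, 1], ue[1, 1]
            return out

        out = _ai_reml(
            evaluator, theta0, floor, constrain, variance_mask,
            tol=tol, max_iter=max_iter,
        )
        try:
            cov = np.linalg.inv(out["ai"])
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(out["ai"])
        return BivariateResults(
            model=self,
            params=pd.Series(out["theta"], index=self.PARAM_LABELS),
            cov_params=(cov + cov.T) / 2,
            converged=out["converged"],
            n_iter=out["n_iter"],
            llf_trace=out["llf_trace"],
            reason=out["reason"],
        )


@dataclass
class BivariateResults:
    """Bivariate fit: 2x2 genetic/residual blocks and the genetic correlation."""

    model: BivariateKernelModel
    params: pd.Series
    cov_params: np.ndarray
    converged: bool
    n_iter: int
    llf_trace: list[float]
    reason: str = ""

    @property
    def llf(self) -> float:
        return self.llf_trace[-1]

    @property
    def rg(self) -> float | None:
        """Genetic correlation sigma_u12 / sqrt(sigma2_u1 sigma2_u2)."""
        if not self.converged:
            return None
        t = self.params.to_numpy()
        denom = np.sqrt(t[0] * t[2])
        if denom <= 0:
            return None
        return float(np.clip(t[1] / denom, -1.0, 1.0))

    def monte_carlo_se(self, n_draws: int = 10000, seed: int = 0) -> float:
        """Monte-Carlo SE of r_g from the asymptotic normal of the components."""
        if not self.converged:
            raise REMLError("SE undefined for a non-converged fit")
        rng = np.random.default_rng(seed)
        cov = (self.cov_params + self.cov_params.T) / 2
        w, V = np.linalg.eigh(cov)
        w = np.maximum(w, 0.0)
        L = V * np.sqrt(w)
        z = rng.standard_normal((n_draws, 6))
        draws = self.params.to_numpy() + z @ L.T
        su1 = np.maximum(draws[:, 0], 0.0)
        su2 = np.maximum(draws[:, 2], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = draws[:, 1] / np.sqrt(su1 * su2)
        r = np.clip(r[np.isfinite(r)], -1.0, 1.0)
        if r.size < 2:
            return float("nan")
        return float(np.std(r, ddof=1))

    def summary(self) -> str:
        lines = [
            "Bivariate kernel mixed model (AI-REML)",
            f"  n = {len(self.model.ids)} complete cases",
            f"  converged = {self.converged} ({self.reason}), "
            f"iterations = {self.n_iter}, REML loglik = {self.llf:.4f}",
            "  Components: " + ", ".join(
                f"{k}={v:.4g}" for k, v in self.params.items()
            ),
        ]
        if self.converged:
            lines.append(
                f"  r_g = {self.rg:.3f}  "
                f"(MC SE {self.monte_carlo_se(n_draws=2000, seed=0):.3f})"
            )
        else:
            lines.append("  r_g = — (not converged)")
        return "\n".join(lines)


# -------------------------------------------------------- functional wrappers

def fit_reml(y, kernels: list[KernelMatrix], ids=None,
             tol: float = 1e-8, max_iter: int = 200) -> KernelMixedResults:
    """Fit the univariate kernel mixed model (GBLUP / MBLUP / MGBLUP)."""
    return KernelMixedModel(y, kernels, ids=ids).fit(tol=tol, max_iter=max_iter)


def fit_bivariate_reml(y1: pd.Series, y2: pd.Series, G: KernelMatrix,
                       tol: float = 1e-8, max_iter: int = 200) -> BivariateResults:
    """Fit the two-trait model and estimate the genetic correlation."""
    return BivariateKernelModel(y1, y2, G).fit(tol=tol, max_iter=max_iter)


def derive_ratios(fit: KernelMixedResults, n_draws: int = 10000,
                  seed: int = 0) -> pd.DataFrame | None:
    """Ratio parameters (h2, m2 or h2_bar, m2_bar) with Monte-Carlo SEs."""
    if not fit.converged:
        return None
    ratios = fit.ratios
    ses = fit.monte_carlo_se(n_draws=n_draws, seed=seed)
    return pd.DataFrame(
        {"estimate": pd.Series(ratios), "se": pd.Series(ses)}
    )


def monte_carlo_se(fit, n_draws: int = 10000, seed: int = 0):
    """Monte-Carlo SEs for the fit's ratio parameters (dispatches on type)."""
    return fit.monte_carlo_se(n_draws=n_draws, seed=seed)
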