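"""Ordinal bud-set phenology: cumulative link mixed model and D50% timing.

The model is a proportional-odds (cumulative logit) regression of the
seven-level bud-set score, ordered from 3 (growing apical meristem) down to
0 (bud fully set), with day of year, home site (categorical) and the ramet
carbon:nitrogen ratio as fixed effects and random intercepts for donor tree
and for ramet (ramets nested in donors):

    logit P(score among the first j levels)
        = alpha_j - beta_D * day - beta_S(site) - beta_CN * CN
          - u_tree - u_ramet,
    u_tree ~ N(0, sigma_T^2),  u_ramet ~ N(0, sigma_R^2).

The marginal likelihood integrates the random intercepts out by a Laplace
approximation that exploits the nested block structure: the joint mode of
(u_tree, u_ramets) is found by damped Newton steps solved in closed form per
donor via the arrowhead structure of the Hessian, and the log-determinant
uses the same Schur complement.  The ordinal logistic log-likelihood is
log-concave in the linear predictor, so the inner problem is globally
concave.  The outer maximization runs L-BFGS-B on (alpha_1, log threshold
increments, betas, log sigmas) with central-difference gradients.

From a fit, D50% is the day of year at which a donor's ramets have 50%
probability of having at most reached score 1.5:

    D50 = (alpha_(1.5) - beta_CN * CN_ref - beta_S(site) - u_tree) / beta_D

with CN_ref = 12 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "SCORE_LEVELS",
    "cumulative_logit_probs",
    "BudSetClmm",
    "BudSetClmmResults",
    "fit_clmm",
    "category_probabilities",
    "d50",
    "pearson_climate",
]

#: Bud-set scoring levels in modelling order (least to most advanced).
SCORE_LEVELS: tuple[float, ...] = (3.0, 2.5, 2.0, 1.5, 1.0, 0.5, 0.0)

_LOG_SIGMA_MIN = -10.0
_LOG_SIGMA_MAX = 3.0
_P_FLOOR = 1e-300


def cumulative_logit_probs(alphas: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-category probabilities of the cumulative-logit model.

    ``alphas`` are the K-1 increasing thresholds; ``z`` the linear predictor
    (fixed effects plus random intercepts, entering with a minus sign).
    Returns an array of shape ``z.shape + (K,)`` summing to 1 over the last
    axis.
    """
    alphas = np.asarray(alphas, dtype=float)
    z = np.asarray(z, dtype=float)
    cum = expit(alphas - z[..., None])
    ones = np.ones(z.shape + (1,))
    zeros = np.zeros(z.shape + (1,))
    return np.diff(np.concatenate([zeros, cum, ones], axis=-1), axis=-1)


def _logistic_pdf(f_cum: np.ndarray) -> np.ndarray:
    return f_cum * (1.0 - f_cum)


@dataclass
class _Design:
    y: np.ndarray                 # category index per observation (0..K-1)
    X: np.ndarray                 # fixed-effect design (n_obs, p)
    exog_names: list[str]
    ramet_of_obs: np.ndarray
    donor_of_obs: np.ndarray
    donor_of_ramet: np.ndarray
    donor_ids: list[str]
    ramet_ids: list[str]
    levels: list[float]           # observed score levels in modelling order
    site_of_donor: pd.Series
    site_levels: list[str]
    centers: np.ndarray = None  # fixed-effect column means, removed for conditioning
    warnings_: list[str] = field(default_factory=list)


class BudSetClmm:
    """Cumulative link mixed model for ordinal bud-set observations.

    Parameters
    ----------
    data : DataFrame
        Long-format observations with one row per ramet and day.
    score_col, day_col, site_col, cn_col, donor_col, ramet_col : str
        Column names; defaults match the package's bud-set CSV schema.
    """

    def __init__(self, data: pd.DataFrame, *, score_col: str = "score",
                 day_col: str = "day", site_col: str = "site_id",
                 cn_col: str = "cn", donor_col: str = "donor_id",
                 ramet_col: str = "ramet_id") -> None:
        self.data = data.reset_index(drop=True)
        self._cols = dict(score=score_col, day=day_col, site=site_col,
                          cn=cn_col, donor=donor_col, ramet=ramet_col)
        self.design = self._build_design()
        self._mode_cache: tuple[np.ndarray, np.ndarray] | None = None

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "BudSetClmm":
        return cls(data, **kwargs)

    # ------------------------------------------------------------------ setup
    def _build_design(self) -> _Design:
        c = self._cols
        df = self.data
        scores = df[c["score"]].astype(float)
        unknown = set(np.round(scores, 3)) - set(SCORE_LEVELS)
        if unknown:
            raise ValueError(f"scores outside the 7-level scale: {sorted(unknown)}")
        levels = [s for s in SCORE_LEVELS if (scores == s).any()]
        warns: list[str] = []
        if len(levels) < len(SCORE_LEVELS):
            missing = sorted(set(SCORE_LEVELS) - set(levels), reverse=True)
            warns.append(f"unobserved score levels collapsed: {missing}")
        if len(levels) < 2:
            raise ValueError("need at least 2 observed score categories")
        y = scores.map({s: i for i, s in enumerate(levels)}).to_numpy(int)

        site_levels = sorted(df[c["site"]].astype(str).unique())
        cols = {"day": df[c["day"]].to_numpy(float)}
        for s in site_levels[1:]:
            cols[f"site[{s}]"] = (df[c["site"]].astype(str) == s).astype(float).to_numpy()
        cols["cn"] = df[c["cn"]].to_numpy(float)
        X = np.column_stack(list(cols.values()))
        exog_names = list(cols)
        # centre columns for optimizer conditioning; thresholds are shifted
        # back to the raw-covariate scale on reporting
        centers = X.mean(axis=0)
        X = X - centers

        ramet_ids = list(pd.unique(df[c["ramet"]].astype(str)))
        donor_ids = list(pd.unique(df[c["donor"]].astype(str)))
        r_index = {r: i for i, r in enumerate(ramet_ids)}
        d_index = {d: i for i, d in enumerate(donor_ids)}
        ramet_of_obs = df[c["ramet"]].astype(str).map(r_index).to_numpy(int)
        donor_of_obs = df[c["donor"]].astype(str).map(d_index).to_numpy(int)
        pair = df[[c["ramet"], c["donor"]]].astype(str).drop_duplicates()
        if pair[c["ramet"]].duplicated().any():
            raise ValueError("a ramet maps to more than one donor")
        donor_of_ramet = np.empty(len(ramet_ids), dtype=int)
        for r, d in pair.itertuples(index=False):
            donor_of_ramet[r_index[r]] = d_index[d]

        site_of_donor = (df[[c["donor"], c["site"]]].astype(str)
                         .drop_duplicates().set_index(c["donor"])[c["site"]])
        donors_per_site = site_of_donor.groupby(site_of_donor).size()
        lonely = donors_per_site[donors_per_site == 1]
        if len(lonely) and len(site_levels) > 1:
            warns.append(
                "site effect confounded with donor intercept at single-donor "
                f"sites: {sorted(lonely.index)}")
        return _Design(y, X, exog_names, ramet_of_obs, donor_of_obs,
                       donor_of_ramet, donor_ids, ramet_ids, levels,
                       site_of_donor, site_levels, centers, warns)

    @property
    def k_levels(self) -> int:
        return len(self.design.levels)

    @property
    def n_params(self) -> int:
        return (self.k_levels - 1) + self.design.X.shape[1] + 2

    # ------------------------------------------------------- parameter packing
    def unpack(self, params: np.ndarray):
        K = self.k_levels
        p = self.design.X.shape[1]
        a1 = params[0]
        alphas = a1 + np.concatenate([[0.0], np.cumsum(np.exp(params[1:K - 1]))])
        beta = params[K - 1:K - 1 + p]
        sig_t = float(np.exp(params[K - 1 + p]))
        sig_r = float(np.exp(params[K + p]))
        return alphas, beta, sig_t, sig_r

    def pack(self, alphas, beta, sigma_tree: float, sigma_ramet: float) -> np.ndarray:
        alphas = np.asarray(alphas, dtype=float)
        if np.any(np.diff(alphas) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        return np.concatenate([
            [alphas[0]], np.log(np.diff(alphas)), np.asarray(beta, dtype=float),
            [np.log(max(sigma_tree, np.exp(_LOG_SIGMA_MIN))),
             np.log(max(sigma_ramet, np.exp(_LOG_SIGMA_MIN)))]])

    # --------------------------------------------------------------- likelihood
    @property
    def _obs_idx(self):
        """Cached per-observation threshold indices and boundary masks."""
        if not hasattr(self, "_obs_idx_cache"):
            d = self.design
            K = self.k_levels
            self._obs_idx_cache = (np.minimum(d.y, K - 2),
                                   np.maximum(d.y - 1, 0),
                                   d.y == K - 1, d.y == 0)
        return self._obs_idx_cache

    def _obs_logp_derivs(self, alphas: np.ndarray, z: np.ndarray):
        """Per-observation log p and its first/second derivatives in z."""
        hi_idx, lo_idx, top, bot = self._obs_idx
        F_hi = expit(alphas[hi_idx] - z)
        F_lo = expit(alphas[lo_idx] - z)
        F_hi[top] = 1.0   # open upper boundary; logistic pdf vanishes there
        F_lo[bot] = 0.0
        f_hi = F_hi * (1.0 - F_hi)
        f_lo = F_lo * (1.0 - F_lo)
        p = np.maximum(F_hi - F_lo, _P_FLOOR)
        g = (f_lo - f_hi) / p
        d2p = f_hi * (1.0 - 2.0 * F_hi) - f_lo * (1.0 - 2.0 * F_lo)
        h = d2p / p - g * g
        return np.log(p), g, h

    def _inner_objective(self, alphas, eta, u_t, u_r, sig_t, sig_r) -> float:
        d = self.design
        z = eta + u_t[d.donor_of_obs] + u_r[d.ramet_of_obs]
        logp, _, _ = self._obs_logp_derivs(alphas, z)
        return (logp.sum()
                - 0.5 * np.sum(u_t**2) / sig_t**2
                - 0.5 * np.sum(u_r**2) / sig_r**2)

    def _laplace(self, params: np.ndarray, *, tol: float = 1e-9,
                 max_newton: int = 100):
        """Laplace-approximate marginal log-likelihood and random-effect modes."""
        d = self.design
        alphas, beta, sig_t, sig_r = self.unpack(params)
        eta = d.X @ beta
        n_t = len(d.donor_ids)
        n_r = len(d.ramet_ids)
        if self._mode_cache is not None:
            u_t, u_r = (a.copy() for a in self._mode_cache)
        else:
            u_t = np.zeros(n_t)
            u_r = np.zeros(n_r)
        inv_t = 1.0 / sig_t**2
        inv_r = 1.0 / sig_r**2

        def state(u_t, u_r):
            z = eta + u_t[d.donor_of_obs] + u_r[d.ramet_of_obs]
            logp, g, h = self._obs_logp_derivs(alphas, z)
            obj = (logp.sum() - 0.5 * np.sum(u_t**2) * inv_t
                   - 0.5 * np.sum(u_r**2) * inv_r)
            return logp, g, h, obj

        logp, g, h, obj = state(u_t, u_r)
        for _ in range(max_newton):
            grad_t = np.bincount(d.donor_of_obs, g, n_t) - u_t * inv_t
            grad_r = np.bincount(d.ramet_of_obs, g, n_r) - u_r * inv_r
            gmax = max(np.abs(grad_t).max(initial=0.0),
                       np.abs(grad_r).max(initial=0.0))
            if gmax < tol:
                break
            W_r = np.bincount(d.ramet_of_obs, -h, n_r)
            H_rr = W_r + inv_r
            H_tt = np.bincount(d.donor_of_ramet, W_r, n_t) + inv_t
            S_t = H_tt - np.bincount(d.donor_of_ramet, W_r**2 / H_rr, n_t)
            rhs_t = grad_t - np.bincount(d.donor_of_ramet, W_r * grad_r / H_rr, n_t)
            dt = rhs_t / S_t
            dr = (grad_r - W_r * dt[d.donor_of_ramet]) / H_rr
            step = 1.0
            improved = False
            for _ in range(25):
                ut_try = u_t + step * dt
                ur_try = u_r + step * dr
                logp, g, h, cand = state(ut_try, ur_try)
                if cand >= obj - 1e-12:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                # floating-point limit (e.g. probability floor kink); restore
                # the derivatives at the current iterate and stop
                logp, g, h, obj = state(u_t, u_r)
                break
            u_t, u_r, obj = ut_try, ur_try, cand
        # curvature at the mode for the determinant
        W_r = np.bincount(d.ramet_of_obs, -h, n_r)
        H_rr = W_r + inv_r
        H_tt = np.bincount(d.donor_of_ramet, W_r, n_t) + inv_t
        S_t = H_tt - np.bincount(d.donor_of_ramet, W_r**2 / H_rr, n_t)
        logdet = np.log(H_rr).sum() + np.log(S_t).sum()
        joint = (logp.sum()
                 - 0.5 * np.sum(u_t**2) * inv_t - n_t * np.log(sig_t)
                 - 0.5 * np.sum(u_r**2) * inv_r - n_r * np.log(sig_r)
                 - 0.5 * (n_t + n_r) * np.log(2.0 * np.pi))
        loglik = joint + 0.5 * (n_t + n_r) * np.log(2.0 * np.pi) - 0.5 * logdet
        self._mode_cache = (u_t, u_r)
        return loglik, u_t, u_r

    def loglike(self, params: np.ndarray) -> float:
        """Laplace-approximate marginal log-likelihood at a packed parameter
        vector (alpha_1, log threshold increments, betas, log sigma_T,
        log sigma_R)."""
        return self._laplace(np.asarray(params, dtype=float))[0]

    @property
    def _sorted_obs(self):
        """Observation/ramet orderings for segment sums in the quadrature."""
        if not hasattr(self, "_sorted_obs_cache"):
            d = self.design
            obs_order = np.argsort(d.ramet_of_obs, kind="stable")
            ramet_sorted = d.ramet_of_obs[obs_order]
            obs_starts = np.searchsorted(ramet_sorted,
                                         np.arange(len(d.ramet_ids)))
            ramet_order = np.argsort(d.donor_of_ramet, kind="stable")
            donor_sorted = d.donor_of_ramet[ramet_order]
            ramet_starts = np.searchsorted(donor_sorted,
                                           np.arange(len(d.donor_ids)))
            self._sorted_obs_cache = (obs_order, obs_starts, ramet_order,
                                      ramet_starts)
        return self._sorted_obs_cache

    def _agq_grid(self, params: np.ndarray, n_quad: int) -> dict:
        """Quadrature grid centred on the joint Laplace modes at ``params``
        and scaled by the curvature of the penalized log-likelihood; the
        ramet-level centres track the donor node through the
        cross-derivative of the arrowhead Hessian."""
        params = np.asarray(params, dtype=float)
        d = self.design
        alphas, beta, sig_t, sig_r = self.unpack(params)
        eta = d.X @ beta
        n_t = len(d.donor_ids)
        n_r = len(d.ramet_ids)
        _, u_t, u_r = self._laplace(params)
        z = eta + u_t[d.donor_of_obs] + u_r[d.ramet_of_obs]
        _, _, h = self._obs_logp_derivs(alphas, z)
        W_r = np.bincount(d.ramet_of_obs, -h, n_r)
        H_rr = W_r + 1.0 / sig_r**2
        H_tt = np.bincount(d.donor_of_ramet, W_r, n_t) + 1.0 / sig_t**2
        S_t = H_tt - np.bincount(d.donor_of_ramet, W_r**2 / H_rr, n_t)

        x, w = np.polynomial.hermite.hermgauss(n_quad)
        logw = np.log(w) + x**2  # GH weights against a unit integrand
        scale_t = np.sqrt(2.0 / S_t)
        ut_nodes = u_t[:, None] + scale_t[:, None] * x[None, :]
        slope_r = -(W_r / H_rr)
        scale_r = np.sqrt(2.0 / H_rr)
        dt_nodes = (ut_nodes - u_t[:, None])[d.donor_of_ramet]  # (n_r, A)
        ur_centres = u_r[:, None] + slope_r[:, None] * dt_nodes
        ur_nodes = (ur_centres[:, :, None]
                    + scale_r[:, None, None] * x[None, None, :])
        return {"logw": logw, "ut_nodes": ut_nodes, "ur_nodes": ur_nodes,
                "log_scale_t": np.log(scale_t), "log_scale_r": np.log(scale_r),
                "z_ranef": (ut_nodes[d.donor_of_obs][:, :, None]
                            + ur_nodes[d.ramet_of_obs])}

    def _loglike_on_grid(self, params: np.ndarray, grid: dict) -> float:
        """Marginal log-likelihood by Gauss-Hermite quadrature on a fixed
        node grid (grid need not be re-adapted for nearby parameters)."""
        d = self.design
        alphas, beta, sig_t, sig_r = self.unpack(np.asarray(params, float))
        inv_t = 1.0 / sig_t**2
        inv_r = 1.0 / sig_r**2
        eta = d.X @ beta
        z_obs = eta[:, None, None] + grid["z_ranef"]
        hi_idx, lo_idx, top, bot = self._obs_idx
        F_hi = expit(alphas[hi_idx][:, None, None] - z_obs)
        F_lo = expit(alphas[lo_idx][:, None, None] - z_obs)
        F_hi[top] = 1.0
        F_lo[bot] = 0.0
        logp = np.log(np.maximum(F_hi - F_lo, _P_FLOOR))
        obs_order, obs_starts, ramet_order, ramet_starts = self._sorted_obs
        logp_r = np.add.reduceat(logp[obs_order], obs_starts, axis=0)
        logw = grid["logw"]
        # inner integral per (ramet, A) by log-sum-exp over the B nodes
        log_int = (logw[None, None, :]
                   - 0.5 * grid["ur_nodes"]**2 * inv_r
                   - 0.5 * np.log(2.0 * np.pi * sig_r**2)
                   + grid["log_scale_r"][:, None, None]
                   + logp_r)
        mx = log_int.max(axis=2, keepdims=True)
        log_I = mx[:, :, 0] + np.log(np.exp(log_int - mx).sum(axis=2))
        # product over ramets within each donor, then the donor integral
        log_I_d = np.add.reduceat(log_I[ramet_order], ramet_starts, axis=0)
        log_out = (logw[None, :]
                   - 0.5 * grid["ut_nodes"]**2 * inv_t
                   - 0.5 * np.log(2.0 * np.pi * sig_t**2)
                   + grid["log_scale_t"][:, None]
                   + log_I_d)
        mx = log_out.max(axis=1, keepdims=True)
        return float((mx[:, 0] + np.log(np.exp(log_out - mx).sum(axis=1))).sum())

    def loglike_agq(self, params: np.ndarray, n_quad: int = 7) -> float:
        """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

        Nodes are centred on the joint Laplace modes, so a small ``n_quad``
        already corrects most of the Laplace error.  Cost grows with
        ``n_quad**2`` times the data size.
        """
        params = np.asarray(params, dtype=float)
        return self._loglike_on_grid(params, self._agq_grid(params, n_quad))

    def loglike_quadrature(self, params: np.ndarray, n_nodes: int = 25) -> float:
        """Marginal log-likelihood by nested Gauss-Hermite quadrature.

        Exact up to quadrature error; intended as an independent check of the
        Laplace approximation on small instances (cost grows with
        ``n_nodes**2`` times the data size).
        """
        d = self.design
        alphas, beta, sig_t, sig_r = self.unpack(np.asarray(params, float))
        eta = d.X @ beta
        nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
        wts = wts / np.sqrt(np.pi)
        t_nodes = np.sqrt(2.0) * sig_t * nodes
        r_nodes = np.sqrt(2.0) * sig_r * nodes
        total = 0.0
        for t in range(len(d.donor_ids)):
            donor_obs = d.donor_of_obs == t
            ramets = np.nonzero(d.donor_of_ramet == t)[0]
            lik_t = np.zeros(n_nodes)
            for a, ut in enumerate(t_nodes):
                log_prod = 0.0
                for r in ramets:
                    m = donor_obs & (d.ramet_of_obs == r)
                    # (n_nodes, n_obs_r): log p at each u_r node
                    z = eta[m][None, :] + ut + r_nodes[:, None]
                    probs = cumulative_logit_probs(alphas, z)
                    pk = np.take_along_axis(
                        probs, d.y[m][None, :, None], axis=2)[:, :, 0]
                    log_by_node = np.log(np.maximum(pk, _P_FLOOR)).sum(axis=1)
                    mx = log_by_node.max()
                    lik_r = np.dot(wts, np.exp(log_by_node - mx))
                    log_prod += mx + np.log(max(lik_r, _P_FLOOR))
                lik_t[a] = log_prod
            mx = lik_t.max()
            total += mx + np.log(max(np.dot(wts, np.exp(lik_t - mx)), _P_FLOOR))
        return total

    # --------------------------------------------------------------------- fit
    def _start_params(self) -> np.ndarray:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        d = self.design
        endog = pd.Series(pd.Categorical(d.y, categories=range(self.k_levels),
                                         ordered=True))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                om = OrderedModel(endog, d.X, distr="logit")
                res = om.fit(method="bfgs", disp=False, maxiter=200)
            p = d.X.shape[1]
            beta = res.params[:p]
            cuts = om.transform_threshold_params(res.params)[1:-1]
            if not np.all(np.isfinite(cuts)) or np.any(np.diff(cuts) <= 0):
                raise ValueError
        except Exception:
            freqs = np.bincount(d.y, minlength=self.k_levels) / len(d.y)
            cum = np.clip(np.cumsum(freqs)[:-1], 1e-3, 1 - 1e-3)
            cuts = np.log(cum / (1 - cum))
            cuts = np.sort(cuts) + 1e-6 * np.arange(len(cuts))
            beta = np.zeros(d.X.shape[1])
        return self.pack(cuts, beta, 0.5, 0.5)

    def fit(self, start_params: np.ndarray | None = None, *, se: bool = False,
            method: str = "laplace", n_quad: int = 7,
            gtol: float | None = None, ftol: float = 1e-10,
            maxiter: int = 200, fd_step: float = 1e-4) -> "BudSetClmmResults":
        """Maximize the Laplace marginal likelihood.

        Parameters
        ----------
        start_params : packed vector, optional
            Defaults to a fixed-effects proportional-odds fit with both
            random-effect SDs started at 0.5.
        se : bool
            Compute standard errors from the numerical Hessian (adds an
            O(n_params^2) number of likelihood evaluations).
        method : {"laplace", "agq"}
            "laplace" maximizes the Laplace marginal likelihood; "agq"
            additionally polishes the optimum under the adaptive
            Gauss-Hermite likelihood with ``n_quad`` nodes per level,
            reducing the small bias of the Laplace variance estimates.
        gtol : float, optional
            Max-norm gradient tolerance of the outer optimizer; defaults to
            the central-difference noise floor for the data size.
        fd_step : float
            Central-difference step of the outer gradient; the default
            balances truncation against roundoff for log-likelihoods of
            magnitude 1e3-1e4.
        """
        self._mode_cache = None
        x0 = self._start_params() if start_params is None else np.asarray(
            start_params, dtype=float)
        K, p = self.k_levels, self.design.X.shape[1]
        bounds = ([(None, None)] * (K - 1 + p)
                  + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)] * 2)
        if gtol is None:
            # roundoff of the central difference: eps*|loglik| / step
            gtol = max(1e-4, 10.0 * 2.2e-16 * (1.0 + len(self.design.y)) / fd_step)

        def nll(x):
            return -self.loglike(x)

        def grad(x):
            g = np.empty_like(x)
            for i in range(len(x)):
                xp = x.copy(); xp[i] += fd_step
                xm = x.copy(); xm[i] -= fd_step
                g[i] = (nll(xp) - nll(xm)) / (2 * fd_step)
            return g

        if method not in ("laplace", "agq"):
            raise ValueError(f"unknown method {method!r}")
        res = optimize.minimize(nll, x0, jac=grad, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": maxiter, "gtol": gtol,
                                         "ftol": ftol})
        success = bool(res.success)
        xhat = res.x
        if method == "agq":
            # polish on a node grid frozen at the Laplace optimum; the grid
            # re-adaptation changes the optimum by <1e-3, so one round
            # suffices (the reported loglik is re-adapted)
            for round_maxiter in (60,):
                grid = self._agq_grid(xhat, n_quad)

                def nll_q(x, _grid=grid):
                    return -self._loglike_on_grid(x, _grid)

                def grad_q(x, _grid=grid):
                    g = np.empty_like(x)
                    for i in range(len(x)):
                        xp = x.copy(); xp[i] += fd_step
                        xm = x.copy(); xm[i] -= fd_step
                        g[i] = (nll_q(xp) - nll_q(xm)) / (2 * fd_step)
                    return g

                res = optimize.minimize(nll_q, xhat, jac=grad_q,
                                        method="L-BFGS-B", bounds=bounds,
                                        options={"maxiter": round_maxiter,
                                                 "gtol": gtol, "ftol": 1e-9})
                xhat = res.x
            success = success and bool(res.success)
            loglik = self.loglike_agq(xhat, n_quad=n_quad)
            _, u_t, u_r = self._laplace(xhat)
        else:
            loglik, u_t, u_r = self._laplace(xhat)
        cov = None
        if se:
            cov = self._param_cov(xhat)
        return BudSetClmmResults(self, xhat, loglik, success,
                                 u_t, u_r, cov, method=method,
                                 optimizer_message=str(res.message))

    def _param_cov(self, params: np.ndarray, h: float = 1e-4) -> np.ndarray:
        n = len(params)
        H = np.empty((n, n))
        f0 = -self.loglike(params)
        for i in range(n):
            for j in range(i, n):
                xi = params.copy()
                if i == j:
                    xi[i] += h; fpp = -self.loglike(xi)
                    xi = params.copy(); xi[i] -= h; fmm = -self.loglike(xi)
                    H[i, i] = (fpp - 2 * f0 + fmm) / h**2
                else:
                    vals = []
                    for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                        x = params.copy()
                        x[i] += si * h; x[j] += sj * h
                        vals.append(-self.loglike(x))
                    H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * h**2)
        try:
            return np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return np.full((n, n), np.nan)


class BudSetClmmResults:
    """Results of a :class:`BudSetClmm` fit: estimates, random-effect modes,
    diagnostics, and derived D50% timing."""

    def __init__(self, model: BudSetClmm, params: np.ndarray, loglik: float,
                 converged: bool, u_tree: np.ndarray, u_ramet: np.ndarray,
                 cov_params: np.ndarray | None = None, method: str = "laplace",
                 optimizer_message: str = "") -> None:
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.loglik = float(loglik)
        self.converged = converged
        self.method = method
        self.optimizer_message = optimizer_message
        d = model.design
        alphas_c, self._beta, self.sigma_tree, self.sigma_ramet = \
            model.unpack(self.params)
        # undo the design-column centring: alpha_nat = alpha_c + beta @ centers
        self.thresholds = alphas_c + float(self._beta @ d.centers)
        self.beta = pd.Series(self._beta, index=d.exog_names, name="coef")
        self.ranef_tree = pd.Series(u_tree, index=d.donor_ids, name="ranef_tree")
        self.ranef_ramet = pd.Series(u_ramet, index=d.ramet_ids,
                                     name="ranef_ramet")
        self.cov_params = cov_params
        self.warnings = list(d.warnings_)

    # ------------------------------------------------------------- accessors
    @property
    def beta_day(self) -> float:
        return float(self.beta["day"])

    @property
    def beta_cn(self) -> float:
        return float(self.beta["cn"])

    def beta_site(self, site_id: str) -> float:
        key = f"site[{site_id}]"
        if key in self.beta.index:
            return float(self.beta[key])
        if str(site_id) in self.model.design.site_levels:
            return 0.0  # reference site
        raise KeyError(f"unknown site {site_id!r}")

    @property
    def bse(self) -> pd.Series | None:
        """Standard errors on the natural scale (delta method for sigmas)."""
        if self.cov_params is None:
            return None
        K = self.model.k_levels
        p = len(self._beta)
        se_packed = np.sqrt(np.maximum(np.diag(self.cov_params), 0.0))
        # thresholds: alpha_j = a1 + sum exp(g); delta method via Jacobian
        J = np.zeros((K - 1, len(self.params)))
        J[:, 0] = 1.0
        incr = np.exp(self.params[1:K - 1])
        for j in range(1, K - 1):
            J[j, 1:1 + j] = incr[:j]
        J[:, K - 1:K - 1 + p] = self.model.design.centers[None, :]
        var_alpha = np.einsum("ij,jk,ik->i", J, self.cov_params, J)
        names = ([f"alpha[{self.model.design.levels[j]}|"
                  f"{self.model.design.levels[j + 1]}]" for j in range(K - 1)]
                 + list(self.beta.index) + ["sigma_tree", "sigma_ramet"])
        vals = np.concatenate([
            np.sqrt(np.maximum(var_alpha, 0.0)),
            se_packed[K - 1:K - 1 + p],
            [self.sigma_tree * se_packed[K - 1 + p],
             self.sigma_ramet * se_packed[K + p]]])
        return pd.Series(vals, index=names, name="se")

    # ------------------------------------------------------------ computations
    def category_probabilities(self, day, site_id, cn, ranef_tree: float = 0.0,
                               ranef_ramet: float = 0.0) -> pd.Series:
        """Probabilities of each observed score level at the given covariates."""
        z = (self.beta_day * float(day) + self.beta_site(site_id)
             + self.beta_cn * float(cn) + ranef_tree + ranef_ramet)
        probs = cumulative_logit_probs(self.thresholds, np.array(z))
        return pd.Series(probs, index=self.model.design.levels, name="prob")

    def _alpha_at(self, level: float) -> float:
        levels = self.model.design.levels
        if level not in levels:
            raise ValueError(f"score level {level} not observed in the data")
        j = levels.index(level)
        if j >= len(self.thresholds):
            raise ValueError(f"no threshold below score level {level}")
        return float(self.thresholds[j])

    def d50(self, cn_ref: float = 12.0, level: float = 1.5) -> pd.DataFrame:
        """Per-donor day of year at which P(score at most advanced to
        ``level``) = 50%, at the reference C:N."""
        if self.beta_day == 0:
            raise ValueError("beta_day is zero; D50 undefined")
        alpha = self._alpha_at(level)
        d = self.model.design
        rows = []
        for donor in d.donor_ids:
            site = d.site_of_donor[donor]
            val = ((alpha - self.beta_cn * cn_ref - self.beta_site(site)
                    - self.ranef_tree[donor]) / self.beta_day)
            rows.append((donor, site, val))
        out = pd.DataFrame(rows, columns=["donor_id", "site_id", "d50"])
        out["cn_reference"] = cn_ref
        return out

    def summary(self) -> str:
        d = self.model.design
        bse = self.bse
        lines = ["Cumulative link mixed model (logit), Laplace approximation",
                 "=" * 60,
                 f"observations: {len(d.y)}   donors: {len(d.donor_ids)}   "
                 f"ramets: {len(d.ramet_ids)}",
                 f"log-likelihood: {self.loglik:.3f}   "
                 f"converged: {self.converged}", "-" * 60]
        rows = []
        K = self.model.k_levels
        for j in range(K - 1):
            rows.append((f"alpha[{d.levels[j]}|{d.levels[j + 1]}]",
                         self.thresholds[j]))
        for name, val in self.beta.items():
            rows.append((name, val))
        rows.append(("sigma_tree", self.sigma_tree))
        rows.append(("sigma_ramet", self.sigma_ramet))
        for name, val in rows:
            se = "" if bse is None or name not in bse.index else \
                f"  (se {bse[name]:.4f})"
            lines.append(f"{name:>24s} {val:12.4f}{se}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = self.model.design
        return {
            "thresholds": list(map(float, self.thresholds)),
            "levels": d.levels,
            "beta": {k: float(v) for k, v in self.beta.items()},
            "sigma_tree": self.sigma_tree,
            "sigma_ramet": self.sigma_ramet,
            "loglik": self.loglik,
            "converged": self.converged,
            "method": self.method,
            "warnings": self.warnings,
        }


# ------------------------------------------------------------ module surface
def fit_clmm(obs: pd.DataFrame, **fit_kwargs) -> BudSetClmmResults:
    """Fit the bud-set cumulative link mixed model to a long-format table."""
    return BudSetClmm.from_dataframe(obs).fit(**fit_kwargs)


def category_probabilities(fit: BudSetClmmResults, day, site_id, cn,
                           ranef_tree: float = 0.0,
                           ranef_ramet: float = 0.0) -> pd.Series:
    return fit.category_probabilities(day, site_id, cn, ranef_tree, ranef_ramet)


def d50(fit: BudSetClmmResults, cn_ref: float = 12.0) -> pd.DataFrame:
    return fit.d50(cn_ref=cn_ref)


def pearson_climate(d50_table: pd.DataFrame, climate: pd.DataFrame,
                    variables: tuple[str, ...] = ("t_jan", "t_jul", "pet"),
                    ) -> pd.DataFrame:
    """Pearson correlation of per-donor D50% with site climate variables.

    Returns one row per variable with r, the two-sided t-based p-value and n.
    """
    merged = d50_table.merge(climate, on="site_id", how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 donors with climate data")
    rows = []
    for var in variables:
        x = merged[var].to_numpy(float)
        y = merged["d50"].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero variance for {var!r} or d50")
        r, p = stats.pearsonr(x, y)
        rows.append((var, r, p, len(merged)))
    return pd.DataFrame(rows, columns=["variable", "r", "p_value", "n"])
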