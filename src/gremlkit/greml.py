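"""Multi-trait GREML (average-information REML) and GBLUP prediction.

The model, for traits t = 1..T measured on *disjoint* sample sets:

    y_t = X_t b_t + Z_t g_t + e_t,
    Cov(g_t, g_t') = sigma_g(t,t') * G_block,   e_t ~ N(0, I sigma_e_t^2)

with G the genomic relationship matrix over the union of samples.  Because
the sample sets are disjoint, residual cross-trait covariances are
structurally zero and only the genetic covariances are estimable — the key
identifiability property of the split-cohort design (a case-control cohort
and phenotype strata of an independent quantitative cohort).

Estimation is average-information REML: quasi-Newton updates using the
averaged observed/expected information, with damped early iterations and
step-halving whenever a proposal leaves the feasible region.  The sampling
covariance of the estimates is the inverse AI matrix at the optimum;
genetic correlations get delta-method standard errors from the full
sampling covariance (including the covariance between variance terms).

A binary trait is analysed on the observed 0/1 scale; the liability-scale
transformation is available separately (:func:`observed_to_liability_h2`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .grm import GRMatrix

logger = logging.getLogger(__name__)

#: variance proposals below this fraction of the phenotypic variance are
#: clamped to the boundary (and flagged)
VARIANCE_FLOOR_FRACTION = 1e-6


# ---------------------------------------------------------------------------
# Small reusable pieces
# ---------------------------------------------------------------------------

def residualize(y: np.ndarray, X: np.ndarray | None, add_intercept: bool = True) -> np.ndarray:
    """Ordinary least-squares residuals of ``y`` on covariates ``X``.

    Collinear columns are dropped with a warning; an intercept is included
    by default so the residuals have mean exactly zero.
    """
    y = np.asarray(y, dtype=float)
    cols = [np.ones((len(y), 1))] if add_intercept else []
    if X is not None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != len(y):
            X = X.T
        cols.append(X)
    if not cols:
        return y.copy()
    M = np.column_stack(cols)
    M = _drop_collinear(M)
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    resid = y - M @ beta
    if add_intercept:
        resid -= resid.mean()
    return resid


def _drop_collinear(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Keep a maximal linearly independent subset of columns (order kept)."""
    q, r, piv = linalg.qr(M, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * (diag[0] if diag.size else 1.0)).sum())
    if rank < M.shape[1]:
        warnings.warn(f"dropping {M.shape[1] - rank} collinear column(s)")
        keep = np.sort(piv[:rank])
        return M[:, keep]
    return M


def wald_test(
    estimate: float, se: float, null_value: float = 0.0, tail: str = "two"
) -> float:
    """Wald p-value for (estimate - null)/se against the standard normal.

    ``tail`` is ``"two"``, ``"upper"`` (H1: estimate > null) or ``"lower"``.
    """
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    z = (estimate - null_value) / se
    if tail == "two":
        return float(2.0 * stats.norm.sf(abs(z)))
    if tail == "upper":
        return float(stats.norm.sf(z))
    if tail == "lower":
        return float(stats.norm.cdf(z))
    raise ValueError(f"unknown tail {tail!r}")


def observed_to_liability_h2(h2_obs: float, prevalence: float, case_fraction: float) -> float:
    """Transform an observed-scale (0/1) SNP-heritability to the liability scale.

    Standard threshold-model correction for ascertained case-control data:

        h2_lia = h2_obs * K^2 (1-K)^2 / (P (1-P) phi(t)^2),  t = Phi^-1(1-K)

    with ``K`` the population prevalence and ``P`` the sample case fraction.
    """
    K, P = prevalence, case_fraction
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("prevalence and case fraction must be in (0,1)")
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    return float(h2_obs * K**2 * (1 - K) ** 2 / (P * (1 - P) * z**2))


# ---------------------------------------------------------------------------
# Model inputs
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeBlock:
    """One trait measured on one set of samples.

    ``y`` may be binary 0/1 (case-control, analysed on the observed scale)
    or continuous.  Covariates, if any, enter the fixed-effect design; the
    usual workflow pre-adjusts phenotypes with :func:`residualize` so the
    design reduces to a per-trait intercept.
    """

    trait: str
    sample_ids: list[str]
    y: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None
    fixed_effects: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != len(self.sample_ids):
            raise ValueError(f"{self.trait}: y length != sample count")

    def design(self) -> np.ndarray:
        X = np.ones((len(self.y), 1))
        if self.covariates is not None:
            C = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if C.shape[0] != len(self.y):
                C = C.T
            X = np.column_stack([X, C])
        return _drop_collinear(X)


@dataclass
class BlupSolution:
    """Predicted genetic values (the PRS-GBLUP) and fixed-effect estimates."""

    sample_ids: list[str]
    u: np.ndarray                 # predicted genetic value per sample
    prediction_error_variance: np.ndarray
    fixed_effects: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "u": self.u,
             "pev": self.prediction_error_variance}
        )


@dataclass
class GeneticCorrelation:
    """rg between two traits with its delta-method standard error."""

    traits: tuple[str, str]
    rg: float                      # clamped to [-1, 1]
    se: float
    raw_rg: float                  # unclamped estimate, used in Wald tests

    def wald_p(self, null_value: float = 0.0, tail: str = "two") -> float:
        return wald_test(self.raw_rg, self.se, null_value, tail)


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class GREML:
    """Average-information REML on a GRM for 1–3 phenotype blocks.

    Parameters
    ----------
    grm
        Genomic relationship matrix covering every phenotyped sample.
    blocks
        Phenotype blocks with pairwise-disjoint sample sets.
    """

    def __init__(self, grm: GRMatrix, blocks: list[PhenotypeBlock]):
        if not 1 <= len(blocks) <= 3:
            raise ValueError("1 to 3 phenotype blocks supported")
        seen: set[str] = set()
        index = {s: i for i, s in enumerate(grm.sample_ids)}
        for b in blocks:
            missing = [s for s in b.sample_ids if s not in index]
            if missing:
                raise ValueError(f"{b.trait}: {len(missing)} samples not in GRM")
            dup = seen & set(b.sample_ids)
            if dup:
                raise ValueError(f"sample(s) in more than one block: {sorted(dup)[:5]}")
            seen |= set(b.sample_ids)
        self.grm = grm
        self.blocks = blocks
        self.T = len(blocks)

        # stacked order: block 0 samples, then block 1, ...
        self._grm_rows = [np.array([index[s] for s in b.sample_ids]) for b in blocks]
        sizes = [len(b.sample_ids) for b in blocks]
        starts = np.concatenate([[0], np.cumsum(sizes)])
        self._slices = [slice(starts[t], starts[t + 1]) for t in range(self.T)]
        self.n = int(starts[-1])
        self._G = {}
        for t in range(self.T):
            for s in range(t, self.T):
                self._G[(t, s)] = grm.values[np.ix_(self._grm_rows[t], self._grm_rows[s])]
        self.y = np.concatenate([b.y for b in blocks])
        designs = [b.design() for b in blocks]
        self.X = linalg.block_diag(*designs)
        # parameter layout: sigma_g^2 per trait, sigma_g(t,t') pairs, sigma_e^2
        self.param_names = (
            [f"V(G)_{b.trait}" for b in blocks]
            + [f"C(G)_{blocks[t].trait}_{blocks[s].trait}"
               for t in range(self.T) for s in range(t + 1, self.T)]
            + [f"V(e)_{b.trait}" for b in blocks]
        )
        self._pairs = [(t, s) for t in range(self.T) for s in range(t + 1, self.T)]

    # -- V and derivative bookkeeping -----------------------------------

    def _build_V(self, theta: np.ndarray) -> np.ndarray:
        T = self.T
        V = np.zeros((self.n, self.n))
        for t in range(T):
            sl = self._slices[t]
            V[sl, sl] += theta[t] * self._G[(t, t)]
            V[sl, sl] += theta[T + len(self._pairs) + t] * np.eye(sl.stop - sl.start)
        for k, (t, s) in enumerate(self._pairs):
            slt, sls = self._slices[t], self._slices[s]
            V[slt, sls] += theta[T + k] * self._G[(t, s)]
            V[sls, slt] += theta[T + k] * self._G[(t, s)].T
        return V

    def _trace_PA(self, P: np.ndarray, i: int) -> float:
        T = self.T
        if i < T:
            sl = self._slices[i]
            return float(np.sum(P[sl, sl] * self._G[(i, i)]))
        if i < T + len(self._pairs):
            t, s = self._pairs[i - T]
            slt, sls = self._slices[t], self._slices[s]
            return float(2.0 * np.sum(P[slt, sls] * self._G[(t, s)]))
        t = i - T - len(self._pairs)
        sl = self._slices[t]
        return float(np.trace(P[sl, sl]))

    def _A_dot(self, i: int, v: np.ndarray) -> np.ndarray:
        """A_i @ v for the i-th parameter's derivative matrix."""
        T = self.T
        out = np.zeros_like(v)
        if i < T:
            sl = self._slices[i]
            out[sl] = self._G[(i, i)] @ v[sl]
        elif i < T + len(self._pairs):
            t, s = self._pairs[i - T]
            slt, sls = self._slices[t], self._slices[s]
            out[slt] = self._G[(t, s)] @ v[sls]
            out[sls] = self._G[(t, s)].T @ v[slt]
        else:
            t = i - T - len(self._pairs)
            sl = self._slices[t]
            out[sl] = v[sl]
        return out

    def _feasible(self, theta: np.ndarray) -> tuple[np.ndarray, list[int]]:
        """Clamp variances to the floor and covariances inside the cone."""
        T, npair = self.T, len(self._pairs)
        theta = theta.copy()
        flagged = []
        for t in range(T):
            floor = VARIANCE_FLOOR_FRACTION * self._vary[t]
            for idx in (t, T + npair + t):
                if theta[idx] < floor:
                    theta[idx] = floor
                    flagged.append(idx)
        for k, (t, s) in enumerate(self._pairs):
            # loose rail well outside the correlation cone: the restricted
            # likelihood itself diverges to -inf as V approaches singularity,
            # so estimates near |rg| = 1 stay unconstrained and Wald tests
            # of rg = 1 keep their two-sided behaviour
            cap = 1.5 * np.sqrt(theta[t] * theta[s])
            if abs(theta[T + k]) > cap:
                theta[T + k] = np.sign(theta[T + k]) * cap
                flagged.append(T + k)
        return theta, flagged

    def _reml_loglik(self, V: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        """Return (restricted logL, P, Py); raises LinAlgError if V not PD."""
        L = linalg.cholesky(V, lower=True)
        Vinv = linalg.cho_solve((L, True), np.eye(self.n))
        W = Vinv @ self.X
        M = self.X.T @ W
        Mchol = linalg.cho_factor(M)
        P = Vinv - W @ linalg.cho_solve(Mchol, W.T)
        P = (P + P.T) / 2.0
        Py = P @ self.y
        logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
        logdet_M = 2.0 * np.sum(np.log(np.diag(Mchol[0])))
        ll = -0.5 * (logdet_V + logdet_M + float(self.y @ Py))
        return ll, P, Py

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        tol: float = 1e-6,
        max_iter: int = 100,
        start: np.ndarray | None = None,
        n_damped: int = 3,
        damping: float = 0.3,
        verbose: bool = False,
    ) -> "GREMLResults":
        """Run AI-REML to convergence.

        Starting values: half the (adjusted) phenotypic variance for each
        genetic and residual variance, zero covariances.  The first
        ``n_damped`` iterations take damped steps; afterwards full AI steps
        with step-halving on infeasible or likelihood-decreasing proposals.
        Convergence: maximum relative parameter change below ``tol``.
        """
        T, npair = self.T, len(self._pairs)
        q = 2 * T + npair
        self._vary = np.array([np.var(b.y) for b in self.blocks])
        if np.any(self._vary <= 0):
            raise ValueError("a phenotype block has zero variance")
        if start is None:
            theta = np.concatenate(
                [0.5 * self._vary, np.zeros(npair), 0.5 * self._vary]
            )
        else:
            theta = np.asarray(start, dtype=float).copy()
        theta, _ = self._feasible(theta)

        trajectory = []
        self._ridge_flag = False
        converged = False
        clamped: set[int] = set()
        stalled = 0
        stall_tol = 1e-7 * max(self.n, 100)
        ll, P, Py = self._loglik_with_ridge(theta)
        for it in range(max_iter):
            grad = np.empty(q)
            Wmat = np.empty((self.n, q))
            for i in range(q):
                w = self._A_dot(i, Py)
                Wmat[:, i] = w
                grad[i] = -0.5 * (self._trace_PA(P, i) - float(Py @ w))
            PW = P @ Wmat
            AI = 0.5 * (Wmat.T @ PW)
            AI = (AI + AI.T) / 2.0

            # release floored variances whose gradient points back into the
            # interior (covariances never join the active set: their rail is
            # a projection, not an attractor — see _boundary_delta)
            clamped = {i for i in clamped if grad[i] <= 0}

            # active-set update: a component that leaves the feasible region
            # steps TO its boundary and is pinned there; the AI system is
            # re-solved for the free components conditional on that move
            # (cross-curvature term included), keeping the restricted step
            # an ascent direction
            def _boundary_delta(active: set[int]) -> np.ndarray:
                # variance floors are genuine boundary optima, so a clamped
                # variance steps exactly onto its floor; covariances never
                # appear here
                dlt = np.zeros(q)
                for i in active:
                    t_i = i if i < T else i - T - npair
                    dlt[i] = VARIANCE_FLOOR_FRACTION * self._vary[t_i] - theta[i]
                return dlt

            delta = np.zeros(q)
            for _ in range(q + 1):
                free = np.array([i not in clamped for i in range(q)])
                delta = _boundary_delta(clamped)
                if free.any():
                    sub = np.ix_(free, free)
                    rhs = grad[free] - AI[np.ix_(free, ~free)] @ delta[~free]
                    try:
                        delta[free] = np.linalg.solve(AI[sub], rhs)
                    except np.linalg.LinAlgError:
                        delta[free] = np.linalg.lstsq(AI[sub], rhs, rcond=None)[0]
                prop, flagged = self._feasible(theta + delta)
                newly = {i for i in flagged
                         if i not in clamped and (i < T or i >= T + npair)}
                if not newly:
                    break
                clamped |= newly

            # trust region: early AI proposals can be wildly out of scale
            # while the variance estimates are far from the optimum, so each
            # component's move is capped at one phenotypic-variance unit
            step_cap = np.empty(q)
            step_cap[:T] = self._vary
            step_cap[T + npair:] = self._vary
            for k2, (t2, s2) in enumerate(self._pairs):
                step_cap[T + k2] = np.sqrt(self._vary[t2] * self._vary[s2])
            step_cap = np.maximum(step_cap, 2.0 * np.abs(theta))
            over = np.abs(delta) / step_cap
            if over.max() > 1.0:
                delta = delta / over.max()

            scale = damping if it < n_damped else 1.0
            accepted = False
            for _ in range(12):
                prop, flagged = self._feasible(theta + scale * delta)
                try:
                    # no ridge here: a proposal that makes V indefinite
                    # (e.g. a jointly infeasible covariance pattern) must be
                    # rejected, not silently regularized
                    ll_new, P_new, Py_new = self._reml_loglik(self._build_V(prop))
                except (np.linalg.LinAlgError, linalg.LinAlgError):
                    scale /= 2.0
                    continue
                if ll_new < ll - 1e-8 * max(1.0, abs(ll)):
                    scale /= 2.0
                    continue
                accepted = True
                break
            if not accepted:
                # no uphill move exists along the restricted AI direction:
                # we are at a (possibly constrained) optimum
                converged = True
                trajectory.append({"iter": it, "loglik": ll, "theta": theta.copy(),
                                   "scale": 0.0, "flagged": sorted(clamped)})
                break

            step = prop - theta
            rel_change = np.abs(step) / np.maximum(np.abs(theta), self._vary.mean())
            dll = ll_new - ll
            theta, ll, P, Py = prop, ll_new, P_new, Py_new
            trajectory.append({"iter": it, "loglik": ll, "theta": theta.copy(),
                               "scale": scale, "flagged": sorted(set(flagged))})
            if verbose:
                logger.info("iter %d  logL=%.6f  theta=%s", it, ll, np.round(theta, 6))
            if it >= n_damped and rel_change.max() < tol:
                converged = True
                break
            # stagnation at a boundary-constrained optimum: the projected
            # step can crawl along a moving constraint, so treat two
            # consecutive near-zero likelihood gains as converged — but only
            # while a constraint is active (interior optima keep iterating
            # to full parameter precision)
            at_boundary = bool(clamped) or bool(flagged)
            if it >= n_damped and at_boundary and dll < stall_tol:
                stalled += 1
                if stalled >= 2:
                    converged = True
                    break
            else:
                stalled = 0
        if not converged:
            err = RuntimeError(f"AI-REML did not converge in {max_iter} iterations")
            err.trajectory = trajectory  # type: ignore[attr-defined]
            raise err

        # refresh AI and gradient at the optimum for the sampling covariance
        grad = np.empty(q)
        Wmat = np.empty((self.n, q))
        for i in range(q):
            w = self._A_dot(i, Py)
            Wmat[:, i] = w
            grad[i] = -0.5 * (self._trace_PA(P, i) - float(Py @ w))
        AI = 0.5 * (Wmat.T @ (P @ Wmat))
        AI = (AI + AI.T) / 2.0
        try:
            sampling_cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            sampling_cov = np.linalg.pinv(AI)
        natural_step = np.linalg.lstsq(AI, grad, rcond=None)[0]

        return GREMLResults(
            model=self,
            params=theta,
            param_names=list(self.param_names),
            sampling_cov=sampling_cov,
            loglik=ll,
            gradient=grad,
            natural_step=natural_step,
            trajectory=trajectory,
            ridge_used=self._ridge_flag,
            boundary_flags=sorted({i for rec in trajectory[-1:] for i in rec["flagged"]}),
        )

    def _loglik_with_ridge(self, theta: np.ndarray):
        try:
            return self._reml_loglik(self._build_V(theta))
        except np.linalg.LinAlgError:
            warnings.warn("V not positive definite; adding 1e-6 ridge")
            self._ridge_flag = True
            V = self._build_V(theta) + 1e-6 * np.eye(self.n)
            return self._reml_loglik(V)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class GREMLResults:
    """Variance components with their AI sampling covariance.

    ``params`` holds genetic variances (one per trait), genetic covariances
    (one per trait pair) and residual variances, in that order; the spec of
    each element is in ``param_names``.
    """

    model: GREML
    params: np.ndarray
    param_names: list[str]
    sampling_cov: np.ndarray
    loglik: float
    gradient: np.ndarray
    natural_step: np.ndarray
    trajectory: list[dict]
    ridge_used: bool = False
    boundary_flags: list[int] = field(default_factory=list)

    # -- indexing helpers -------------------------------------------------

    def _trait_index(self, trait: str) -> int:
        for i, b in enumerate(self.model.blocks):
            if b.trait == trait:
                return i
        raise KeyError(trait)

    def sigma_g2(self, trait: str) -> float:
        return float(self.params[self._trait_index(trait)])

    def sigma_e2(self, trait: str) -> float:
        T, npair = self.model.T, len(self.model._pairs)
        return float(self.params[T + npair + self._trait_index(trait)])

    def sigma_g(self, t1: str, t2: str) -> float:
        i, j = sorted((self._trait_index(t1), self._trait_index(t2)))
        k = self.model._pairs.index((i, j))
        return float(self.params[self.model.T + k])

    def param_se(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(max(self.sampling_cov[i, i], 0.0)))

    # -- derived quantities -----------------------------------------------

    def h2(self, trait: str) -> tuple[float, float]:
        """SNP-heritability (observed scale) and its delta-method SE."""
        i = self._trait_index(trait)
        T, npair = self.model.T, len(self.model._pairs)
        j = T + npair + i
        vg, ve = self.params[i], self.params[j]
        vp = vg + ve
        h2 = vg / vp
        grad = np.zeros(len(self.params))
        grad[i] = ve / vp**2
        grad[j] = -vg / vp**2
        se = float(np.sqrt(max(grad @ self.sampling_cov @ grad, 0.0)))
        return float(h2), se

    def genetic_correlation(self, t1: str, t2: str) -> GeneticCorrelation:
        """rg between two traits with delta-method SE from the full AI covariance."""
        i, j = sorted((self._trait_index(t1), self._trait_index(t2)))
        T = self.model.T
        k = T + self.model._pairs.index((i, j))
        vg1, vg2, cov = self.params[i], self.params[j], self.params[k]
        if vg1 <= 0 or vg2 <= 0:
            raise ValueError(
                f"genetic correlation undefined: non-positive genetic variance "
                f"({t1}: {vg1:.3g}, {t2}: {vg2:.3g})"
            )
        rg = cov / np.sqrt(vg1 * vg2)
        grad = np.zeros(len(self.params))
        grad[k] = 1.0 / np.sqrt(vg1 * vg2)
        grad[i] = -rg / (2.0 * vg1)
        grad[j] = -rg / (2.0 * vg2)
        se = float(np.sqrt(max(grad @ self.sampling_cov @ grad, 0.0)))
        clamped = float(np.clip(rg, -1.0, 1.0))
        if clamped != rg:
            logger.info("rg %.4f clamped to %+.1f (raw kept for tests)", rg, clamped)
        return GeneticCorrelation(traits=(t1, t2), rg=clamped, se=se, raw_rg=float(rg))

    # -- presentation ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.maximum(np.diag(self.sampling_cov), 0.0))
        return pd.DataFrame(
            {"component": self.param_names, "estimate": self.params, "se": se}
        )

    def summary(self) -> str:
        lines = [
            "GREML variance components (AI-REML)",
            f"  traits: {', '.join(b.trait for b in self.model.blocks)}",
            f"  n = {self.model.n}, logL = {self.loglik:.4f}, "
            f"iterations = {len(self.trajectory)}",
            "",
            self.to_frame().to_string(index=False, float_format=lambda x: f"{x: .6f}"),
            "",
        ]
        for b in self.model.blocks:
            h2, se = self.h2(b.trait)
            lines.append(f"  h2({b.trait}) = {h2:.4f} (SE {se:.4f})")
        for t, s in self.model._pairs:
            a, c = self.model.blocks[t].trait, self.model.blocks[s].trait
            try:
                g = self.genetic_correlation(a, c)
                lines.append(
                    f"  rg({a}, {c}) = {g.rg:+.4f} (SE {g.se:.4f}), "
                    f"p[rg=0] = {g.wald_p(0.0):.3g}, p[rg=1] = {g.wald_p(1.0):.3g}"
                )
            except ValueError:
                lines.append(f"  rg({a}, {c}) undefined (boundary genetic variance)")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------

def gblup_predict(
    results: GREMLResults | tuple[float, float],
    grm: GRMatrix,
    block: PhenotypeBlock,
    target_ids: list[str],
) -> BlupSolution:
    """Predict genetic values for phenotype-missing individuals.

    Single-trait GBLUP: with V = G_obs * sigma_u^2 + I * sigma_e^2 on the
    observed samples and GLS fixed effects b,

        u_hat = sigma_u^2 * G_{target,obs} V^{-1} (y_obs - X_obs b)

    The reliability proxy returned is the prediction error variance
    PEV_j = sigma_u^2 G_jj - sigma_u^4 G_{j,obs} P_obs G_{obs,j}.
    ``results`` may be a fitted single-trait :class:`GREMLResults` or a
    plain ``(sigma_u2, sigma_e2)`` pair.
    """
    if isinstance(results, GREMLResults):
        trait = block.trait
        su2, se2 = results.sigma_g2(trait), results.sigma_e2(trait)
    else:
        su2, se2 = map(float, results)

    index = {s: i for i, s in enumerate(grm.sample_ids)}
    obs = np.array([index[s] for s in block.sample_ids])
    tgt = np.array([index[s] for s in target_ids])
    G_oo = grm.values[np.ix_(obs, obs)]
    G_to = grm.values[np.ix_(tgt, obs)]
    X = block.design()

    if su2 <= 0:
        warnings.warn("sigma_u^2 = 0: all GBLUP predictions are zero")
        beta, *_ = np.linalg.lstsq(X, block.y, rcond=None)
        return BlupSolution(list(target_ids), np.zeros(len(tgt)),
                            np.zeros(len(tgt)), beta)

    V = su2 * G_oo + se2 * np.eye(len(obs))
    try:
        L = linalg.cho_factor(V)
    except np.linalg.LinAlgError:
        warnings.warn("observed V not positive definite; adding 1e-6 ridge")
        L = linalg.cho_factor(V + 1e-6 * np.eye(len(obs)))
    VinvX = linalg.cho_solve(L, X)
    M = X.T @ VinvX
    beta = np.linalg.solve(M, VinvX.T @ block.y)
    resid = block.y - X @ beta
    Vinv_resid = linalg.cho_solve(L, resid)
    u = su2 * (G_to @ Vinv_resid)

    # PEV via P_obs = Vinv - Vinv X (X' Vinv X)^-1 X' Vinv
    Vinv_Got = linalg.cho_solve(L, G_to.T)
    quad = np.einsum("ij,ji->i", G_to, Vinv_Got)
    XtVG = VinvX.T @ G_to.T
    quad_fix = np.einsum("ij,ji->i", XtVG.T, np.linalg.solve(M, XtVG))
    G_tt = np.diag(grm.values)[tgt]
    pev = su2 * G_tt - su2**2 * (quad - quad_fix)
    return BlupSolution(list(target_ids), u, np.maximum(pev, 0.0), beta)


def henderson_mme(
    su2: float,
    se2: float,
    grm_values: np.ndarray,
    obs_idx: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the full mixed-model equations (Henderson system) directly.

    Random effects are carried for *every* GRM sample; observations only for
    ``obs_idx``.  Returns (beta, u_all).  This is the slow reference solver
    used to validate :func:`gblup_predict`.
    """
    n_all = grm_values.shape[0]
    Z = np.zeros((len(obs_idx), n_all))
    Z[np.arange(len(obs_idx)), obs_idx] = 1.0
    lam = se2 / su2
    Ginv = np.linalg.inv(grm_values)
    top = np.hstack([X.T @ X, X.T @ Z])
    bottom = np.hstack([Z.T @ X, Z.T @ Z + lam * Ginv])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[: X.shape[1]], sol[X.shape[1]:]
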