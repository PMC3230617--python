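"""Two-component normal mixture modelling of O/E distributions.

A gene set whose CpG O/E values split into a low population (historically
methylated, CpG-depleted) and a high population (near the value expected by
chance) produces a bimodal O/E distribution.  This module fits one- and
two-component normal mixtures by EM, tests departure from unimodality with a
parametric-bootstrap likelihood-ratio test (the classical chi-square null
does not apply to mixture-order tests), and classifies genes into low/high
classes by posterior membership in the lower-mean component.

The API follows the model/results idiom: build a
:class:`GaussianMixtureModel` from the values, call :meth:`fit` for a
:class:`MixtureResults`, and :meth:`test_unimodality` for a
:class:`BimodalityTest`.  The functions ``fit_mixture``,
``unimodality_test``, ``class_boundary`` and ``classify_genes`` are thin
wrappers over the same objects.

Three guards, all from the commingling-analysis tradition, keep the test
honest on realistic O/E data.  First, the components share a common variance
by default: O/E values pooled over genes of very different lengths have
length-dependent sampling variance, and a free-variance two-component fit
absorbs that excess kurtosis as spurious "bimodality" even when the location
structure is unimodal.  Second, each component's mixing weight is floored at
5%: a gene *population* must hold a non-negligible fraction of genes, and
without the floor the likelihood rewards a degenerate sliver component
parked on the right tail.  Third, the unimodality test runs on Yeo-Johnson
transformed values (λ by normal MLE): O/E ratios of short genes are
right-skewed, skewness is the classic mimic of a second component, and
power-transforming before testing for commingled distributions is the
established cure.  A monotone transform cannot merge two genuine modes, so
power against real bimodality is retained.  All guards apply identically to
the observed fit and to every bootstrap refit, so the test compares like
with like.  ``equal_var=False``, ``min_weight=0`` and ``transform=None``
restore the unconstrained raw-scale test.  Fits used for gene
classification (:func:`fit_mixture`, :func:`classify_genes`) always work on
the raw O/E scale, where the component means are interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqstats import OERecord

__all__ = [
    "GaussianMixtureModel",
    "MixtureResults",
    "BimodalityTest",
    "GeneClassAssignment",
    "fit_mixture",
    "unimodality_test",
    "class_boundary",
    "classify_genes",
]

VAR_FLOOR = 1e-6
_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# batched EM core
# ---------------------------------------------------------------------------


def _loglik_k1(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MLE mean, variance (divisor n, floored) and loglik per row of X (m, n)."""
    n = X.shape[1]
    mu = X.mean(axis=1)
    var = np.maximum(X.var(axis=1), VAR_FLOOR)
    ll = -0.5 * n * (_LOG2PI + np.log(var) + 1.0)
    # exact loglik when the variance hits the floor (var != MLE there)
    floored = X.var(axis=1) < VAR_FLOOR
    if np.any(floored):
        dev = ((X[floored] - mu[floored, None]) ** 2).sum(axis=1)
        ll[floored] = -0.5 * n * (_LOG2PI + np.log(VAR_FLOOR)) - dev / (2 * VAR_FLOOR)
    return mu, var, ll


def _em_k2_batch(
    X: np.ndarray,
    w: np.ndarray,
    mu: np.ndarray,
    var: np.ndarray,
    equal_var: bool,
    tol: float = 1e-8,
    max_iter: int = 300,
    min_weight: float = 0.05,
):
    """Run k=2 EM on each row of X (m chains, n observations per chain).

    Parameters are (m, 2) arrays; copies are returned.  Convergence per
    chain at relative loglik change <= tol.  Returns
    (w, mu, var, loglik, n_iter, converged), all per chain.

    The M-step maximizes over mixing weights within [min_weight,
    1 - min_weight]; for two components the constrained maximizer is the
    clipped proportion, so this is a generalized EM and the per-iteration
    loglik is still non-decreasing.  The variance floor keeps components
    non-singular.  The equal-variance path runs on sufficient statistics
    (responsibilities are a logistic function of x when variances match),
    which is what makes the bootstrap test affordable.
    """
    from scipy.special import expit

    m, n = X.shape
    w = w.copy()
    mu = mu.copy()
    var = np.maximum(var.copy(), VAR_FLOOR)
    ll_prev = np.full(m, -np.inf)
    ll = np.full(m, -np.inf)
    n_iter = np.zeros(m, dtype=int)
    converged = np.zeros(m, dtype=bool)
    active = np.arange(m)
    Xa = X
    Sx = Xa.sum(axis=1)
    Sxx = (Xa * Xa).sum(axis=1)

    for it in range(1, max_iter + 1):
        w0 = w[active, 0]
        w1 = w[active, 1]
        mu0 = mu[active, 0]
        mu1 = mu[active, 1]
        if equal_var:
            v = var[active, 0]
            lw0 = np.log(w0)
            lw1 = np.log(w1)
            # log-odds of component 0 are linear in x under a shared variance
            alpha = (mu0 - mu1) / v
            beta = (mu1 * mu1 - mu0 * mu0) / (2.0 * v) + lw0 - lw1
            delta = alpha[:, None] * Xa + beta[:, None]
            r0 = expit(delta)
            sum_lp1 = (
                n * (lw1 - 0.5 * (_LOG2PI + np.log(v)))
                - (Sxx - 2.0 * mu1 * Sx + n * mu1 * mu1) / (2.0 * v)
            )
            ll_new = sum_lp1 + np.logaddexp(0.0, delta).sum(axis=1)
            r0x = r0 * Xa
            A0 = r0.sum(axis=1)
            B0 = r0x.sum(axis=1)
            C0 = (r0x * Xa).sum(axis=1)
            A1 = n - A0
            B1 = Sx - B0
            C1 = Sxx - C0
            A0c = np.maximum(A0, 1e-12)
            A1c = np.maximum(A1, 1e-12)
            new_mu0 = B0 / A0c
            new_mu1 = B1 / A1c
            dev = (C0 - B0 * B0 / A0c) + (C1 - B1 * B1 / A1c)
            new_v = np.maximum(dev / n, VAR_FLOOR)
            var0 = var1 = new_v
        else:
            v0 = var[active, 0]
            v1 = var[active, 1]
            lp0 = (
                np.log(w0)[:, None]
                - 0.5 * (_LOG2PI + np.log(v0))[:, None]
                - (Xa - mu0[:, None]) ** 2 / (2.0 * v0[:, None])
            )
            lp1 = (
                np.log(w1)[:, None]
                - 0.5 * (_LOG2PI + np.log(v1))[:, None]
                - (Xa - mu1[:, None]) ** 2 / (2.0 * v1[:, None])
            )
            mx = np.maximum(lp0, lp1)
            lse = mx + np.log(np.exp(lp0 - mx) + np.exp(lp1 - mx))
            ll_new = lse.sum(axis=1)
            r0 = np.exp(lp0 - lse)
            A0 = r0.sum(axis=1)
            A1 = n - A0
            A0c = np.maximum(A0, 1e-12)
            A1c = np.maximum(A1, 1e-12)
            new_mu0 = (r0 * Xa).sum(axis=1) / A0c
            new_mu1 = ((1.0 - r0) * Xa).sum(axis=1) / A1c
            dev0 = (r0 * (Xa - new_mu0[:, None]) ** 2).sum(axis=1)
            dev1 = ((1.0 - r0) * (Xa - new_mu1[:, None]) ** 2).sum(axis=1)
            var0 = np.maximum(dev0 / A0c, VAR_FLOOR)
            var1 = np.maximum(dev1 / A1c, VAR_FLOOR)

        new_w0 = np.clip(A0 / n, min_weight, 1.0 - min_weight)
        w[active, 0] = new_w0
        w[active, 1] = 1.0 - new_w0
        mu[active, 0] = new_mu0
        mu[active, 1] = new_mu1
        var[active, 0] = var0
        var[active, 1] = var1
        ll[active] = ll_new
        n_iter[active] = it

        done = np.abs(ll_new - ll_prev[active]) <= tol * (1.0 + np.abs(ll_new))
        if np.any(done):
            converged[active[done]] = True
            keep = ~done
            active = active[keep]
            Xa = Xa[keep]
            Sx = Sx[keep]
            Sxx = Sxx[keep]
            if active.size == 0:
                break
            ll_prev[active] = ll[active]
        else:
            ll_prev[active] = ll_new

    # order components by ascending mean
    swap = mu[:, 0] > mu[:, 1]
    for arr in (w, mu, var):
        arr[swap] = arr[swap][:, ::-1]
    return w, mu, var, ll, n_iter, converged


def _k2_inits(
    values: np.ndarray, n_restarts: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quantile-seeded restart grid: means at the 25th/75th percentiles,
    jittered per restart; the last restart is an epsilon-split of the single
    Gaussian fit, guaranteeing the k=2 likelihood dominates k=1."""
    q25, q75 = np.quantile(values, [0.25, 0.75])
    sd = max(float(values.std()), math.sqrt(VAR_FLOOR))
    mean = float(values.mean())
    mus = np.empty((n_restarts, 2))
    mus[0] = (q25, q75)
    for r in range(1, n_restarts - 1):
        mus[r] = np.sort((q25, q75) + rng.normal(0.0, 0.25 * sd, size=2))
    mus[n_restarts - 1] = (mean - 1e-3 * sd, mean + 1e-3 * sd)
    ws = np.full((n_restarts, 2), 0.5)
    vs = np.full((n_restarts, 2), sd * sd)
    return ws, mus, vs


# ---------------------------------------------------------------------------
# results objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixtureResults:
    """A fitted k-component normal mixture (k = 1 or 2).

    Means ascend for k=2; weights sum to 1; sds are floored away from zero.
    Equal by construction under the common-variance default.
    """

    k: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    loglik: float
    n_iter: int
    converged: bool
    seed: int
    n_obs: int
    equal_var: bool = True

    def posterior_low(self, values) -> np.ndarray:
        """Posterior probability of the lower-mean component per value."""
        if self.k != 2:
            raise ValueError("posterior_low requires a k=2 fit")
        x = np.asarray(values, dtype=float)
        lp = []
        for c in range(2):
            v = self.sds[c] ** 2
            lp.append(
                math.log(self.weights[c])
                - 0.5 * (_LOG2PI + math.log(v))
                - (x - self.means[c]) ** 2 / (2 * v)
            )
        mx = np.maximum(lp[0], lp[1])
        denom = mx + np.log(np.exp(lp[0] - mx) + np.exp(lp[1] - mx))
        return np.exp(lp[0] - denom)

    def boundary(self) -> float:
        """Low/high class boundary: the point between the component means
        where the weighted component densities are equal (posterior 0.5),
        located by bisection to 1e-10."""
        if self.k != 2:
            raise ValueError("class boundary requires a k=2 fit")
        if not self.converged:
            raise ValueError("class boundary requires a converged fit")

        def g(x: float) -> float:
            out = []
            for c in range(2):
                v = self.sds[c] ** 2
                out.append(
                    math.log(self.weights[c])
                    - 0.5 * math.log(v)
                    - (x - self.means[c]) ** 2 / (2 * v)
                )
            return out[0] - out[1]

        lo, hi = self.means
        if lo == hi:
            return lo
        glo, ghi = g(lo), g(hi)
        if glo <= 0 or ghi >= 0:
            raise ValueError("no posterior-0.5 crossing between the means")
        while hi - lo > 1e-10:
            mid = 0.5 * (lo + hi)
            if g(mid) > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def summary(self) -> str:
        lines = [
            f"Normal mixture fit (k={self.k}, n={self.n_obs}, "
            f"{'common' if self.equal_var else 'free'} variance)",
            f"{'comp':>4} {'weight':>10} {'mean':>10} {'sd':>10}",
        ]
        for c in range(self.k):
            lines.append(
                f"{c + 1:>4} {self.weights[c]:>10.4f} "
                f"{self.means[c]:>10.4f} {self.sds[c]:>10.4f}"
            )
        lines.append(
            f"loglik {self.loglik:.4f}  iterations {self.n_iter}  "
            f"converged {self.converged}  seed {self.seed}"
        )
        if self.k == 2 and self.converged:
            try:
                lines.append(f"class boundary (posterior 0.5): {self.boundary():.4f}")
            except ValueError:
                pass
        return "\n".join(lines)


@dataclass(frozen=True)
class BimodalityTest:
    """Parametric-bootstrap likelihood-ratio test of one vs two components.

    ``fit1``/``fit2`` are the fits on the (transformed) testing scale;
    ``transform_lambda`` is the Yeo-Johnson parameter used, or None for a
    raw-scale test.
    """

    lrt_stat: float
    p_value: float
    n_bootstrap: int
    seed: int
    alpha: float
    reject_unimodal: bool
    fit1: MixtureResults
    fit2: MixtureResults
    transform_lambda: float | None = None

    def summary(self) -> str:
        verdict = "rejected" if self.reject_unimodal else "not rejected"
        scale = (
            f"Yeo-Johnson scale, lambda = {self.transform_lambda:.3f}"
            if self.transform_lambda is not None
            else "raw scale"
        )
        return (
            f"Bootstrap LRT of unimodality ({scale}): LRT = {self.lrt_stat:.4f}, "
            f"p = {self.p_value:.4f} ({self.n_bootstrap} bootstrap replicates, "
            f"seed {self.seed})\n"
            f"Unimodality {verdict} at alpha = {self.alpha}"
        )


@dataclass(frozen=True)
class GeneClassAssignment:
    """Low/high CpG O/E class call for one gene (tie at 0.5 goes to low)."""

    gene_id: str
    oe: float
    posterior_low: float
    label: str


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class GaussianMixtureModel:
    """One- or two-component normal mixture model for a vector of O/E values.

    Parameters
    ----------
    values : array-like
        Finite observations (defined O/E ratios).
    equal_var : bool
        Share one variance across components (default True; see module
        docstring for why).
    min_weight : float
        Lower bound on each component's mixing proportion (default 0.05);
        excludes degenerate sliver components that model tail skew rather
        than a gene population.
    """

    N_RESTARTS = 10
    TOL = 1e-8
    MAX_ITER = 300

    def __init__(self, values, equal_var: bool = True, min_weight: float = 0.05):
        arr = np.asarray(values, dtype=float).ravel()
        if not np.all(np.isfinite(arr)):
            raise ValueError("values must be finite; filter undefined O/E first")
        if not 0.0 <= min_weight < 0.5:
            raise ValueError("min_weight must lie in [0, 0.5)")
        self.values = arr
        self.equal_var = equal_var
        self.min_weight = min_weight

    def fit(self, k: int = 2, seed: int = 1) -> MixtureResults:
        """Maximum-likelihood fit; deterministic given (values, k, seed).

        k=1 is the closed-form Gaussian MLE.  k=2 runs EM from 10
        quantile-seeded restarts (jitter drawn from ``seed``) and returns the
        best-loglik solution.
        """
        x = self.values
        if x.size < 10:
            raise ValueError("mixture fit requires at least 10 values")
        if k == 1:
            mu, var, ll = _loglik_k1(x[None, :])
            return MixtureResults(
                k=1,
                weights=(1.0,),
                means=(float(mu[0]),),
                sds=(float(math.sqrt(var[0])),),
                loglik=float(ll[0]),
                n_iter=0,
                converged=True,
                seed=seed,
                n_obs=x.size,
                equal_var=self.equal_var,
            )
        if k != 2:
            raise ValueError("only k=1 and k=2 are supported")
        if np.unique(x).size < 2:
            raise ValueError("k=2 requires at least 2 distinct values")
        rng = np.random.default_rng(seed)
        ws, mus, vs = _k2_inits(x, self.N_RESTARTS, rng)
        X = np.broadcast_to(x, (self.N_RESTARTS, x.size))
        w, mu, var, ll, n_iter, conv = _em_k2_batch(
            X, ws, mus, vs, self.equal_var, self.TOL, self.MAX_ITER, self.min_weight
        )
        best = int(np.argmax(np.where(conv, ll, ll - 1e9)))
        if not conv.any():
            best = int(np.argmax(ll))
        return MixtureResults(
            k=2,
            weights=(float(w[best, 0]), float(w[best, 1])),
            means=(float(mu[best, 0]), float(mu[best, 1])),
            sds=(float(math.sqrt(var[best, 0])), float(math.sqrt(var[best, 1]))),
            loglik=float(ll[best]),
            n_iter=int(n_iter[best]),
            converged=bool(conv[best]),
            seed=seed,
            n_obs=x.size,
            equal_var=self.equal_var,
        )

    def test_unimodality(
        self,
        n_bootstrap: int = 199,
        seed: int = 1,
        alpha: float = 0.05,
        transform: str | None = "yeo-johnson",
    ) -> BimodalityTest:
        """Parametric-bootstrap LRT of k=1 against k=2.

        Values are first symmetrized by a Yeo-Johnson transform (λ chosen by
        normal MLE) so that skewness cannot mimic a second component
        (``transform=None`` tests the raw values).  The observed statistic
        is 2*(loglik2 - loglik1) on the testing scale.  The null
        distribution is built by simulating ``n_bootstrap`` datasets of the
        same size from the fitted single Gaussian and refitting both models;
        p = (1 + #{boot >= observed}) / (n_bootstrap + 1).
        """
        x = self.values
        if x.size < 50:
            raise ValueError("unimodality test requires at least 50 values")
        if n_bootstrap < 99:
            raise ValueError("use at least 99 bootstrap replicates")
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        lam: float | None = None
        model = self
        if transform is not None:
            if transform != "yeo-johnson":
                raise ValueError("transform must be 'yeo-johnson' or None")
            from scipy import stats as _stats

            lam = float(_stats.yeojohnson_normmax(x))
            x = _stats.yeojohnson(x, lam)
            model = GaussianMixtureModel(
                x, equal_var=self.equal_var, min_weight=self.min_weight
            )
        fit1 = model.fit(k=1, seed=seed)
        fit2 = model.fit(k=2, seed=seed)
        # nested models: the epsilon-split restart guarantees ll2 >= ll1 up
        # to EM tolerance; clamp the residual rounding
        lrt = max(0.0, 2.0 * (fit2.loglik - fit1.loglik))

        rng = np.random.default_rng(seed)
        n = x.size
        B = n_bootstrap
        boot = rng.normal(fit1.means[0], fit1.sds[0], size=(B, n))
        _, _, ll1_b = _loglik_k1(boot)
        best_ll2 = np.full(B, -np.inf)
        # one EM batch per restart index; per-replicate inits from each
        # replicate's own quantiles
        q = np.quantile(boot, [0.25, 0.75], axis=1).T  # (B, 2)
        sd_b = np.maximum(boot.std(axis=1), math.sqrt(VAR_FLOOR))
        mean_b = boot.mean(axis=1)
        for r in range(self.N_RESTARTS):
            mus = q.copy()
            if r == self.N_RESTARTS - 1:
                mus[:, 0] = mean_b - 1e-3 * sd_b
                mus[:, 1] = mean_b + 1e-3 * sd_b
            elif r > 0:
                mus = np.sort(q + rng.normal(0.0, 0.25, size=(B, 2)) * sd_b[:, None], axis=1)
            ws = np.full((B, 2), 0.5)
            vs = np.tile((sd_b * sd_b)[:, None], (1, 2))
            _, _, _, ll, _, _ = _em_k2_batch(
                boot, ws, mus, vs, self.equal_var, self.TOL, self.MAX_ITER,
                self.min_weight,
            )
            best_ll2 = np.maximum(best_ll2, ll)
        boot_lrt = np.maximum(0.0, 2.0 * (best_ll2 - ll1_b))
        p = (1.0 + float(np.sum(boot_lrt >= lrt))) / (B + 1.0)
        return BimodalityTest(
            lrt_stat=lrt,
            p_value=p,
            n_bootstrap=B,
            seed=seed,
            alpha=alpha,
            reject_unimodal=p <= alpha,
            fit1=fit1,
            fit2=fit2,
            transform_lambda=lam,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def fit_mixture(
    values, k: int, seed: int = 1, equal_var: bool = True, min_weight: float = 0.05
) -> MixtureResults:
    """Fit a k-component (k = 1 or 2) normal mixture to the values."""
    return GaussianMixtureModel(
        values, equal_var=equal_var, min_weight=min_weight
    ).fit(k=k, seed=seed)


def unimodality_test(
    values,
    n_bootstrap: int = 199,
    seed: int = 1,
    alpha: float = 0.05,
    equal_var: bool = True,
    min_weight: float = 0.05,
) -> BimodalityTest:
    """Bootstrap LRT of a single Gaussian against a two-component mixture."""
    return GaussianMixtureModel(
        values, equal_var=equal_var, min_weight=min_weight
    ).test_unimodality(n_bootstrap=n_bootstrap, seed=seed, alpha=alpha)


def class_boundary(fit: MixtureResults) -> float:
    """Posterior-0.5 boundary between the low and high components."""
    return fit.boundary()


def classify_genes(
    oe_records: Sequence[OERecord], fit: MixtureResults
) -> list[GeneClassAssignment]:
    """Assign each defined-O/E gene to the low or high component.

    Genes with undefined O/E are omitted (their count is reported via the
    module logger by callers that care).  Posterior of the lower-mean
    component >= 0.5 labels a gene "low".
    """
    defined = [r for r in oe_records if r.defined]
    if not defined:
        raise ValueError("no defined O/E values to classify")
    values = np.array([r.oe for r in defined])
    post = fit.posterior_low(values)
    return [
        GeneClassAssignment(
            gene_id=r.gene_id,
            oe=float(r.oe),
            posterior_low=float(p),
            label="low" if p >= 0.5 else "high",
        )
        for r, p in zip(defined, post)
    ]


def plot_fit(values, fit: MixtureResults, path=None):
    """Histogram of O/E values with the fitted component densities overlaid.

    Bin width 0.05 over [0, 3]; values above 3 are not displayed (they remain
    in every computation).  Cosmetic output; returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(values, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.arange(0.0, 3.0 + 0.05, 0.05)
    ax.hist(x[(x >= 0) & (x <= 3)], bins=bins, color="0.7", edgecolor="0.4")
    grid = np.linspace(0, 3, 601)
    binw = 0.05
    for c in range(fit.k):
        dens = (
            fit.weights[c]
            / (fit.sds[c] * math.sqrt(2 * math.pi))
            * np.exp(-((grid - fit.means[c]) ** 2) / (2 * fit.sds[c] ** 2))
        )
        ax.plot(grid, dens * x.size * binw, lw=1.5)
    ax.set_xlabel("O/E ratio")
    ax.set_ylabel("number of genes")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
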