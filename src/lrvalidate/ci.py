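"""Standard errors and confidence intervals for the validation statistics.

Three modes are supported, mirroring the validated tool's OPTION ``se``:

``exact``
    asymptotic variances built from the focal-set covariance blocks
    (G22, Cp22, Cw22) under the joint distribution of the whole- and
    partial-data predictions,

        [u_w, u_p] ~ MVN(0, [[G - Cw22, G - Cp22], [G - Cp22, G - Cp22]]),

``approx``
    the same variances approximated from per-individual reliabilities only
    (diagonal prediction-error covariance, proportional whole/partial
    reliabilities),

``boot``
    percentile bootstrap over focal individuals (paired rows), 10,000
    resamples by default.

Writing K = G - Cp22 (the covariance of u_p), D = Cp22 - Cw22 (the
covariance of u_w - u_p, uncorrelated with u_p) and S = I - 11'/n, the
implemented variances are:

* bias  mean(u_p - u_w):      Var = 1'D1 / n^2                       (exact)
* reliability  u_p'Su_w/((n-1)s_gi2):
                              Var = [tr(SDSK) + 2tr(SKSK)] / ((n-1)^2 s_gi4)
                              (exact: variance of a Gaussian bilinear form)
* dispersion  u_p'Su_w / u_p'Su_p = 1 + u_p'Sd/u_p'Su_p with d ⊥ u_p:
                              Var = E[ w'Dw / (w'w)^2 ],  w = S u_p,
  evaluated exactly by eigendecomposition of SKS and one-dimensional
  quadrature (see docs/methods.md for the derivation and why the popular
  closed forms tr(SDSK)/tr(SK)^2 are biased at small n);
* correlation-type statistics use the Fisher z interval with variance
  1/(n-3); predictivity applies it to the raw correlation corr(y*, u_p)
  and scales the bounds by 1/h.

``mc_oracle`` draws from the joint distribution above and is the
ground-truth validator for every closed form; agreement is enforced by the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.linalg import eigh
from scipy.stats import norm

from .errors import InvariantError, LRValidationError
from .io import CovBlocks, ReliabilityTable
from .stats import FocalBlock

__all__ = [
    "CiSpec",
    "IntervalResult",
    "ci_bias_exact",
    "ci_bias_approx",
    "ci_dispersion_exact",
    "ci_dispersion_approx",
    "ci_correlation",
    "ci_reliability_exact",
    "ci_reliability_approx",
    "ci_predictivity",
    "ci_boot",
    "mc_oracle",
    "McResult",
]


@dataclass
class CiSpec:
    """Confidence-interval configuration (alpha, mode, bootstrap size, seed)."""

    alpha: float = 0.05
    mode: str = "exact"
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise LRValidationError("alpha must lie in (0, 1)")
        if self.mode not in ("exact", "approx", "boot"):
            raise LRValidationError("mode must be exact|approx|boot")
        if self.n_boot < 1:
            raise LRValidationError("n_boot must be positive")

    @property
    def z(self) -> float:
        """Standard-normal quantile z_{1 - alpha/2}."""
        return float(norm.ppf(1.0 - self.alpha / 2.0))


@dataclass
class IntervalResult:
    estimate: float
    lower: float
    upper: float
    mode: str
    se: float | None = None

    def __post_init__(self) -> None:
        if not (self.lower <= self.estimate + 1e-12 and
                self.estimate - 1e-12 <= self.upper):
            raise LRValidationError(
                f"interval [{self.lower}, {self.upper}] does not bracket "
                f"the estimate {self.estimate}"
            )

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


# ---------------------------------------------------------------------------
# trace helpers (S applied implicitly; S = I - 11'/n is never materialised)
# ---------------------------------------------------------------------------

def _sms(M: np.ndarray) -> np.ndarray:
    """S M S via row/column/grand-mean sweeps."""
    rm = M.mean(axis=0, keepdims=True)
    cm = M.mean(axis=1, keepdims=True)
    return M - rm - cm + M.mean()

def _tr_s(M: np.ndarray) -> float:
    """tr(SM) = tr(M) - mean of all entries * ... = tr(M) - 1'M1/n."""
    n = M.shape[0]
    return float(np.trace(M) - M.sum() / n)

def _tr_ss(A: np.ndarray, B: np.ndarray) -> float:
    """tr(S A S B)."""
    return float(np.sum(_sms(A) * B.T))


def _symmetric_interval(est: float, se: float, z: float, mode: str) -> IntervalResult:
    return IntervalResult(
        estimate=est, lower=est - z * se, upper=est + z * se, mode=mode, se=se
    )


# ---------------------------------------------------------------------------
# bias
# ---------------------------------------------------------------------------

def ci_bias_exact(mu_wp: float, blocks: CovBlocks, spec: CiSpec) -> IntervalResult:
    """Exact interval: Var(mean(u_p - u_w)) = 1'(Cp22 - Cw22)1 / n^2."""
    n = blocks.n
    delta = blocks.Cp22 - blocks.Cw22
    quad_sum = float(delta.sum())
    if quad_sum < -1e-8 * max(1.0, abs(delta).max()) * n * n:
        raise InvariantError("1'(Cp22 - Cw22)1 < 0: inconsistent PEV blocks")
    se = float(np.sqrt(max(quad_sum, 0.0)) / n)
    return _symmetric_interval(mu_wp, se, spec.z, "exact")


def ci_bias_approx(
    mu_wp: float, rels: ReliabilityTable, sigma_g2: float, spec: CiSpec
) -> IntervalResult:
    """Approximated interval: Var = sigma_g2 (rel_w_bar - rel_p_bar)/n."""
    rw = float(rels.rel_whole.mean())
    rp = float(rels.rel_partial.mean())
    n = len(rels.table)
    if rw < rp - 1e-12:
        raise InvariantError(
            "mean whole reliability below mean partial reliability — "
            "the whole and partial reliability files are likely swapped"
        )
    se = float(np.sqrt(max(sigma_g2 * (rw - rp), 0.0) / n))
    return _symmetric_interval(mu_wp, se, spec.z, "approx")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _dispersion_var_quadrature(K: np.ndarray, delta: np.ndarray) -> float:
    """Var(b) = E[w' D w / (w'w)^2] with w ~ N(0, SKS), by 1-D quadrature.

    With SKS = Q diag(lam) Q' and d_i = (Q'DQ)_ii,

        Var(b) = int_0^inf t * prod_k (1+2t lam_k)^{-1/2}
                            * sum_i d_i lam_i / (1+2t lam_i) dt.
    """
    SKS = _sms(K)
    SKS = 0.5 * (SKS + SKS.T)
    lam, Q = eigh(SKS)
    keep = lam > 1e-12 * max(lam.max(), 1e-300)
    lam = lam[keep]
    Q = Q[:, keep]
    if lam.size < 3:
        raise InvariantError(
            "partial predictions carry too little variance for the "
            "dispersion interval (rank of SKS below 3)"
        )
    d = np.einsum("ji,jk,ki->i", Q, delta, Q)
    if np.abs(d).max() <= 0.0:
        return 0.0

    # substitute t = tau / mean(lam) so the integrand's scale is O(1)
    scale = float(lam.mean())

    def integrand(tau: float) -> float:
        t = tau / scale
        u = 2.0 * t * lam
        return t * np.exp(-0.5 * np.sum(np.log1p(u))) * float(np.sum(d * lam / (1.0 + u)))

    var, _ = integrate.quad(integrand, 0.0, np.inf, limit=400)
    return max(float(var) / scale, 0.0)


def ci_dispersion_exact(b_wp: float, blocks: CovBlocks, spec: CiSpec) -> IntervalResult:
    """Exact interval for the slope of u_w on u_p.

    The regression residual d = u_w - u_p is uncorrelated with u_p under the
    joint distribution, so conditionally on u_p the slope error is Gaussian
    with variance u_p'S D S u_p / (u_p'S u_p)^2; the marginal variance is its
    expectation, evaluated exactly by quadrature.
    """
    K = blocks.G22 - blocks.Cp22
    delta = blocks.Cp22 - blocks.Cw22
    t3 = _tr_s(K)
    if t3 <= 0.0:
        raise InvariantError("tr(S(G22 - Cp22)) <= 0: partial predictions carry no variance")
    se = float(np.sqrt(_dispersion_var_quadrature(K, delta)))
    return _symmetric_interval(b_wp, se, spec.z, "exact")


def ci_dispersion_approx(
    b_wp: float, rels: ReliabilityTable, spec: CiSpec
) -> IntervalResult:
    """Approximated interval from reliabilities only.

    Diagonal-PEC reduction of the exact variance with rel_w ~ c * rel_p,
    c = rel_w_bar / rel_p_bar:

        Var(b) ~ (c-1)(var(rel_p) + rel_p_bar^2)
                 / (2(var(rel_p) + rel_p_bar^2) + n rel_p_bar^2).
    """
    rp = rels.rel_partial
    rw = rels.rel_whole
    n = rp.size
    rp_bar = float(rp.mean())
    rw_bar = float(rw.mean())
    if rp_bar <= 0.0:
        raise InvariantError("mean partial reliability is zero")
    if rw_bar < rp_bar - 1e-12:
        raise InvariantError(
            "mean whole reliability below mean partial reliability — "
            "the whole and partial reliability files are likely swapped"
        )
    c = rw_bar / rp_bar
    m2 = float(np.var(rp, ddof=1)) + rp_bar**2 if n > 1 else rp_bar**2
    var = (c - 1.0) * m2 / (2.0 * m2 + n * rp_bar**2)
    se = float(np.sqrt(max(var, 0.0)))
    return _symmetric_interval(b_wp, se, spec.z, "approx")


# ---------------------------------------------------------------------------
# correlation-type statistics (Fisher z)
# ---------------------------------------------------------------------------

def ci_correlation(rho: float, n: int, spec: CiSpec) -> IntervalResult:
    """Fisher z interval: tanh(atanh(rho) +/- z/sqrt(n-3))."""
    if n <= 3:
        raise LRValidationError("the Fisher interval needs n >= 4")
    if abs(rho) >= 1.0:
        warnings.warn("correlation is +/-1; interval degenerates", stacklevel=2)
        return IntervalResult(estimate=rho, lower=rho, upper=rho,
                              mode=spec.mode, se=None)
    half = spec.z / np.sqrt(n - 3)
    zr = np.arctanh(rho)
    return IntervalResult(
        estimate=rho,
        lower=float(np.tanh(zr - half)),
        upper=float(np.tanh(zr + half)),
        mode=spec.mode,
        se=None,
    )


def ci_predictivity(
    pred: float, h: float, n: int, spec: CiSpec
) -> IntervalResult:
    """Fisher interval of the raw correlation corr(y*, u_p) = h * pred,
    with the bounds scaled back by 1/h.  Reduces to ``ci_correlation`` at
    h = 1."""
    if h <= 0.0:
        raise LRValidationError("predictivity interval requires h > 0")
    raw = h * pred
    inner = ci_correlation(raw, n, spec)
    return IntervalResult(
        estimate=pred,
        lower=inner.lower / h,
        upper=inner.upper / h,
        mode=spec.mode,
        se=None,
    )


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def ci_reliability_exact(
    rel_stat: float, blocks: CovBlocks, sigma_gi2: float, spec: CiSpec
) -> IntervalResult:
    """Exact interval: the statistic is the bilinear form u_p'Su_w/((n-1)s_gi2),
    whose variance is [tr(SDSK) + 2 tr(SKSK)] / ((n-1)^2 s_gi4) exactly."""
    if sigma_gi2 <= 0.0:
        raise LRValidationError("sigma_gi2 must be positive")
    n = blocks.n
    K = blocks.G22 - blocks.Cp22
    delta = blocks.Cp22 - blocks.Cw22
    t1 = _tr_ss(delta, K)
    t2 = _tr_ss(K, K)
    var_num = t1 + 2.0 * t2
    if var_num < -1e-8 * max(1.0, abs(var_num)):
        raise InvariantError("tr(SDSK) + 2tr(SKSK) < 0: inconsistent PEV blocks")
    se = float(np.sqrt(max(var_num, 0.0)) / ((n - 1) * sigma_gi2))
    return _symmetric_interval(rel_stat, se, spec.z, "exact")


def ci_reliability_approx(
    rel_stat: float,
    rels: ReliabilityTable,
    sigma_g2: float,
    sigma_gi2: float,
    spec: CiSpec,
) -> IntervalResult:
    """Approximated interval:
    Var ~ (1+c) sigma_g4 (var(rel_p) + rel_p_bar^2) / (n sigma_gi4)."""
    if sigma_gi2 <= 0.0:
        raise LRValidationError("sigma_gi2 must be positive")
    rp = rels.rel_partial
    n = rp.size
    rp_bar = float(rp.mean())
    rw_bar = float(rels.rel_whole.mean())
    if rp_bar <= 0.0:
        raise InvariantError("mean partial reliability is zero")
    c = rw_bar / rp_bar
    m2 = float(np.var(rp, ddof=1)) + rp_bar**2 if n > 1 else rp_bar**2
    var = (1.0 + c) * sigma_g2**2 * m2 / (n * sigma_gi2**2)
    se = float(np.sqrt(max(var, 0.0)))
    return _symmetric_interval(rel_stat, se, spec.z, "approx")


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

_BOOT_STATS = ("bias", "dispersion", "ratio_of_accuracies", "reliability", "predictivity")


def ci_boot(
    block: FocalBlock,
    statistic: str,
    spec: CiSpec,
    sigma_gi2: float | None = None,
    h: float | None = None,
) -> IntervalResult:
    """Percentile bootstrap over focal individuals (paired rows).

    Resamples (u_w, u_p[, y*]) rows with replacement ``spec.n_boot`` times;
    the SE is the standard deviation of the bootstrap statistics and the
    interval is the [alpha/2, 1-alpha/2] percentile interval.  Deterministic
    given ``spec.seed``.
    """
    if statistic not in _BOOT_STATS:
        raise LRValidationError(f"unknown bootstrap statistic {statistic!r}")
    n = block.n
    min_n = 4 if statistic in ("ratio_of_accuracies", "predictivity") else 2
    if n < min_n:
        raise LRValidationError(f"bootstrap of {statistic} needs n >= {min_n}")
    if statistic == "reliability" and (sigma_gi2 is None or sigma_gi2 <= 0):
        raise LRValidationError("bootstrap of reliability needs sigma_gi2 > 0")
    if statistic == "predictivity":
        if h is None or h <= 0:
            raise LRValidationError("bootstrap of predictivity needs h > 0")
        if block.ystar is None:
            raise LRValidationError("bootstrap of predictivity needs y*")

    rng = np.random.default_rng(spec.seed)
    needs_var = statistic != "bias"
    vals = np.empty(spec.n_boot)
    filled = 0
    for _attempt in range(100):
        if filled == spec.n_boot:
            break
        todo = spec.n_boot - filled
        idx = rng.integers(0, n, size=(todo, n))
        uw = block.u_w[idx]
        up = block.u_p[idx]
        if statistic == "bias":
            batch = (up - uw).mean(axis=1)
            ok = np.ones(todo, dtype=bool)
        else:
            upc = up - up.mean(axis=1, keepdims=True)
            varp = (upc**2).sum(axis=1) / (n - 1)
            if statistic == "predictivity":
                ys = block.ystar[idx]
                ysc = ys - ys.mean(axis=1, keepdims=True)
                vary = (ysc**2).sum(axis=1) / (n - 1)
                cov = (ysc * upc).sum(axis=1) / (n - 1)
                ok = (varp > 0) & (vary > 0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    batch = cov / np.sqrt(varp * vary) / h
            else:
                uwc = uw - uw.mean(axis=1, keepdims=True)
                cov = (upc * uwc).sum(axis=1) / (n - 1)
                if statistic == "dispersion":
                    ok = varp > 0
                    with np.errstate(divide="ignore", invalid="ignore"):
                        batch = cov / varp
                elif statistic == "ratio_of_accuracies":
                    varw = (uwc**2).sum(axis=1) / (n - 1)
                    ok = (varp > 0) & (varw > 0)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        batch = cov / np.sqrt(varp * varw)
                else:  # reliability
                    ok = varp >= 0
                    batch = cov / sigma_gi2
        if not needs_var:
            ok = np.isfinite(batch)
        else:
            ok &= np.isfinite(batch)
        good = batch[ok]
        take = min(good.size, todo)
        vals[filled:filled + take] = good[:take]
        filled += take
    if filled < spec.n_boot:
        raise LRValidationError(
            f"bootstrap of {statistic}: too many degenerate resamples "
            f"({spec.n_boot - filled} of {spec.n_boot} unresolved); "
            "the focal predictions carry almost no variation"
        )
    point = _point_statistic(block, statistic, sigma_gi2, h)
    lo, hi = np.quantile(vals, [spec.alpha / 2.0, 1.0 - spec.alpha / 2.0])
    lo = min(float(lo), point)
    hi = max(float(hi), point)
    return IntervalResult(
        estimate=point, lower=lo, upper=hi, mode="boot", se=float(vals.std(ddof=1))
    )


def _point_statistic(
    block: FocalBlock, statistic: str, sigma_gi2: float | None, h: float | None
) -> float:
    from . import stats as _stats

    if statistic == "bias":
        return _stats.bias(block)
    if statistic == "dispersion":
        return _stats.dispersion(block)
    if statistic == "ratio_of_accuracies":
        return _stats.ratio_of_accuracies(block)
    if statistic == "reliability":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _stats.reliability(block, sigma_gi2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _stats.predictivity(block, h)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

@dataclass
class McResult:
    """Per-draw statistics sampled from the joint whole/partial distribution."""

    bias: np.ndarray
    dispersion: np.ndarray
    ratio_of_accuracies: np.ndarray
    reliability: np.ndarray
    u_w: np.ndarray | None = None
    u_p: np.ndarray | None = None

    def sd(self, statistic: str) -> float:
        return float(getattr(self, statistic).std(ddof=1))


def mc_oracle(
    blocks: CovBlocks,
    n_draws: int,
    seed: int = 0,
    sigma_gi2: float | None = None,
    keep_draws: bool = False,
) -> McResult:
    """Sample (u_w, u_p) jointly and return per-draw validation statistics.

    The joint covariance [[G-Cw22, G-Cp22], [G-Cp22, G-Cp22]] must be PSD
    (eigenvalue tolerance -1e-8 relative); this operation is the ground
    truth for every closed-form standard error in this module.
    """
    n = blocks.n
    A = blocks.G22 - blocks.Cw22
    K = blocks.G22 - blocks.Cp22
    joint = np.block([[A, K], [K, K]])
    joint = 0.5 * (joint + joint.T)
    lam, Q = eigh(joint)
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        raise InvariantError(
            "joint whole/partial covariance is not PSD: inconsistent CovBlocks"
        )
    root = Q * np.sqrt(np.clip(lam, 0.0, None))
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_draws, 2 * n)) @ root.T
    uw = draws[:, :n]
    up = draws[:, n:]

    if sigma_gi2 is None:
        sigma_gi2 = float(np.mean(np.diag(blocks.G22)))
    upc = up - up.mean(axis=1, keepdims=True)
    uwc = uw - uw.mean(axis=1, keepdims=True)
    cov = (upc * uwc).sum(axis=1) / (n - 1)
    varp = (upc**2).sum(axis=1) / (n - 1)
    varw = (uwc**2).sum(axis=1) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = cov / varp
        ratio = cov / np.sqrt(varp * varw)
    return McResult(
        bias=(up - uw).mean(axis=1),
        dispersion=disp,
        ratio_of_accuracies=ratio,
        reliability=cov / sigma_gi2,
        u_w=uw if keep_draws else None,
        u_p=up if keep_draws else None,
    )
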