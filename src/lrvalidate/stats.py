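"""Point estimates of the LR-method validation statistics.

The LR method compares two sets of breeding-value predictions for the same
focal individuals: ``u_w`` obtained from the whole dataset and ``u_p`` from a
partial dataset in which the focal phenotypes were removed.  Five statistics
summarise the comparison:

bias
    ``mean(u_p - u_w)`` — expected 0 for unbiased predictions.
dispersion (inflation)
    slope of the regression of ``u_w`` on ``u_p``,
    ``cov(u_p, u_w) / var(u_p)`` — expected 1; values below 1 indicate
    inflated (over-dispersed) partial predictions.
ratio of accuracies
    Pearson correlation ``corr(u_p, u_w)`` — the relative accuracy gain from
    adding the focal phenotypes.
reliability
    ``cov(u_p, u_w) / sigma_gi2`` where ``sigma_gi2`` is the genetic variance
    of the focal individuals — estimates the squared accuracy of ``u_p``.
predictivity
    ``corr(y*, u_p) / h`` where ``y*`` are phenotypes adjusted for all model
    effects except the validated one and ``h`` is the square root of the
    heritability.

All sample moments use the n-1 denominator; the choice cancels in every
ratio except reliability, whose confidence-interval formulas in :mod:`.ci`
are written consistently with n-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import LRValidationError

__all__ = [
    "FocalBlock",
    "ValidationStatistics",
    "bias",
    "dispersion",
    "ratio_of_accuracies",
    "reliability",
    "predictivity",
    "focal_genetic_variance",
    "compute_statistics",
]


@dataclass
class FocalBlock:
    """Aligned prediction vectors for the focal individuals of one trait.

    Row order follows the focal ID list exactly; ``ystar`` (adjusted
    phenotypes) is optional and only required for predictivity.
    """

    trait: int
    ids: np.ndarray
    u_w: np.ndarray
    u_p: np.ndarray
    ystar: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.u_w = np.asarray(self.u_w, dtype=float)
        self.u_p = np.asarray(self.u_p, dtype=float)
        if self.ystar is not None:
            self.ystar = np.asarray(self.ystar, dtype=float)
            if self.ystar.shape != self.ids.shape:
                raise LRValidationError(
                    "adjusted phenotypes do not align with the focal ids"
                )
        if not (self.ids.shape == self.u_w.shape == self.u_p.shape):
            raise LRValidationError("focal block vectors have mismatched lengths")
        if len(np.unique(self.ids)) != self.ids.size:
            raise LRValidationError("duplicate ids in focal block")

    @property
    def n(self) -> int:
        return int(self.ids.size)


@dataclass
class ValidationStatistics:
    """Point estimates for one trait."""

    bias: float
    dispersion: float
    ratio_of_accuracies: float
    reliability: float
    n: int
    sigma_gi2: float
    predictivity: float | None = None
    trait: int = 1
    warnings: list[str] = field(default_factory=list)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise LRValidationError(msg)


def bias(block: FocalBlock) -> float:
    """Mean difference partial minus whole, ``mean(u_p - u_w)``."""
    _require(block.n >= 1, "bias needs at least one focal individual")
    return float(np.mean(block.u_p - block.u_w))


def dispersion(block: FocalBlock) -> float:
    """Slope of the regression of u_w on u_p: cov(u_p,u_w)/var(u_p)."""
    _require(block.n >= 2, "dispersion needs at least two focal individuals")
    vp = float(np.var(block.u_p, ddof=1))
    _require(vp > 0.0, "no variation in partial predictions")
    cov = float(np.cov(block.u_p, block.u_w, ddof=1)[0, 1])
    return cov / vp


def ratio_of_accuracies(block: FocalBlock) -> float:
    """Pearson correlation between u_p and u_w."""
    _require(block.n >= 3, "correlation needs at least three focal individuals")
    vp = float(np.var(block.u_p, ddof=1))
    vw = float(np.var(block.u_w, ddof=1))
    _require(vp > 0.0 and vw > 0.0, "zero variance in predictions")
    cov = float(np.cov(block.u_p, block.u_w, ddof=1)[0, 1])
    return cov / np.sqrt(vp * vw)


def reliability(block: FocalBlock, sigma_gi2: float) -> float:
    """cov(u_p, u_w) divided by the focal genetic variance.

    Not clamped: values outside [0, 1] are diagnostic of model
    misspecification and are reported with a warning.
    """
    _require(block.n >= 2, "reliability needs at least two focal individuals")
    _require(sigma_gi2 > 0.0, "focal genetic variance must be positive")
    cov = float(np.cov(block.u_p, block.u_w, ddof=1)[0, 1])
    value = cov / sigma_gi2
    if not 0.0 <= value <= 1.0:
        warnings.warn(
            f"reliability estimate {value:.4g} outside [0, 1]; "
            "check the model or the focal genetic variance",
            stacklevel=2,
        )
    return value


def predictivity(block: FocalBlock, h: float) -> float:
    """corr(y*, u_p) divided by the square root of heritability ``h``."""
    _require(block.ystar is not None, "predictivity requires adjusted phenotypes")
    _require(h > 0.0, "predictivity requires a positive square-root heritability")
    _require(block.n >= 3, "correlation needs at least three focal individuals")
    ys = block.ystar
    vy = float(np.var(ys, ddof=1))
    vp = float(np.var(block.u_p, ddof=1))
    _require(vy > 0.0 and vp > 0.0, "zero variance in y* or partial predictions")
    corr = float(np.cov(ys, block.u_p, ddof=1)[0, 1]) / np.sqrt(vy * vp)
    value = corr / h
    if abs(value) > 1.0:
        warnings.warn(
            f"predictivity estimate {value:.4g} outside [-1, 1] "
            "(correlation divided by h may exceed 1)",
            stacklevel=2,
        )
    return value


def focal_genetic_variance(
    mode: str = "from_parfile",
    *,
    G22: np.ndarray | None = None,
    sigma_g2: float | None = None,
    user_value: float | None = None,
) -> float:
    """Genetic variance of the focal individuals, sigma_gi2.

    mode ``from_G22``
        mean of the diagonal of the focal genetic covariance block (already
        in trait-variance units; accounts for inbreeding/relationships).
    mode ``from_parfile``
        the base genetic variance from the variance components.
    mode ``user``
        a value supplied by the user.
    """
    if mode == "from_G22":
        _require(G22 is not None, "mode from_G22 requires the G22 block")
        return float(np.mean(np.diag(G22)))
    if mode == "from_parfile":
        _require(sigma_g2 is not None, "mode from_parfile requires sigma_g2")
        return float(sigma_g2)
    if mode == "user":
        _require(user_value is not None, "mode user requires a value")
        _require(user_value >= 0.0, "focal genetic variance cannot be negative")
        return float(user_value)
    raise LRValidationError(f"unknown focal-variance mode {mode!r}")


def compute_statistics(
    block: FocalBlock,
    sigma_gi2: float,
    h: float | None = None,
    want_predictivity: bool = False,
) -> ValidationStatistics:
    """All point estimates for one focal block."""
    pred = None
    if want_predictivity:
        if h is None:
            raise LRValidationError("predictivity requires the heritability")
        pred = predictivity(block, h)
    return ValidationStatistics(
        bias=bias(block),
        dispersion=dispersion(block),
        ratio_of_accuracies=ratio_of_accuracies(block),
        reliability=reliability(block, sigma_gi2),
        predictivity=pred,
        n=block.n,
        sigma_gi2=float(sigma_gi2),
        trait=block.trait,
    )
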