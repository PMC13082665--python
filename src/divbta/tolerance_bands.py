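"""Reference distribution of variance differences and outlier tolerance bands.

Under ordinary trial dynamics the lnCVRs of a body of comparable trials are
exchangeable draws around a common mean with modest between-trial spread. A
random-effects meta-analysis of a reference set yields the pooled mean M*,
the between-trial variance tau^2 of the true effects, and the variance V_M*
of the pooled mean; a new trial's true lnCVR is then expected inside the
meta-analytic prediction interval

    M* +/- t_df(alpha) * sqrt(tau^2 + V_M*)

with alpha chosen on the k-sigma scale (3-sigma: alpha ~ 0.0027). Trials
outside the band are "outliers" in the screening rule. A non-parametric
alternative builds Tukey inner/outer fences from per-trial median lnCVRs.

When a trial contributes several estimates (multi-arm, multiple time points)
the estimates are correlated; the pooled-mean variance is then estimated with
a CR2 small-sample cluster-robust sandwich and Satterthwaite degrees of
freedom, with the trial as the cluster.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .exceptions import InsufficientDataError, InvalidInputError
from .summary_stats import DivbtaEstimate

__all__ = [
    "MetaFit",
    "ToleranceBand",
    "random_effects_meta",
    "prediction_interval",
    "tukey_fences",
    "bootstrap_bands",
    "BootstrapBands",
    "select_reference_set",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaFit:
    """Random-effects meta-analysis summary of a reference set.

    mean_effect is M*, tau2 the between-trial variance of true effects,
    var_mean the variance of M*, k the number of independent units (trials),
    df the degrees of freedom used for the prediction-interval t quantile.
    """

    mean_effect: float
    tau2: float
    var_mean: float
    k: int
    df: float
    method: str  # "standard" | "cluster_robust"
    tau2_method: str = "reml"

    def __post_init__(self) -> None:
        if self.tau2 < 0 or self.var_mean < 0:
            raise InvalidInputError("tau2 and var_mean must be >= 0")


@dataclass(frozen=True)
class ToleranceBand:
    """An interval of lnCVR values consistent with ordinary trial dynamics."""

    lower: float
    upper: float
    sigma_level: Optional[float] = None
    kind: str = "prediction_interval"  # | "tukey_inner" | "tukey_outer"
    provenance: Optional[object] = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise InvalidInputError(f"lower ({self.lower}) exceeds upper ({self.upper})")

    def contains(self, value: float) -> bool:
        """Closed-interval membership; boundary values count as inside."""
        return self.lower <= value <= self.upper


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    # DerSimonian-Laird moment estimator.
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu) ** 2)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (len(y) - 1)) / c)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    # Profile restricted log-likelihood, maximised over tau2 >= 0.
    def nll(t2: float) -> float:
        tot = v + t2
        w = 1.0 / tot
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (np.sum(np.log(tot)) + math.log(np.sum(w)) + np.sum(w * (y - mu) ** 2))

    hi = max(10.0 * float(np.var(y, ddof=1)) if len(y) > 1 else 0.0, 10.0 * float(np.max(v)), 1e-6)
    res = minimize_scalar(nll, bounds=(0.0, hi), method="bounded", options={"xatol": 1e-10})
    t2 = float(res.x)
    return t2 if nll(t2) <= nll(0.0) else 0.0


def _cr2_sandwich(
    y: np.ndarray, v: np.ndarray, tau2: float, clusters: np.ndarray
) -> tuple[float, float]:
    """CR2 cluster-robust variance of the pooled mean, with Satterthwaite df.

    For the intercept-only weighted model the CR2 adjustment matrix
    (I - H_jj)^(-1/2) acts on the cluster weight vector as the scalar
    (1 - h_j)^(-1/2), where h_j is the cluster leverage; the Satterthwaite
    df uses the Bell-McCaffrey trace formula evaluated in observation space.
    """
    w = 1.0 / (v + tau2)
    m = 1.0 / np.sum(w)
    mu = m * np.sum(w * y)
    e = y - mu
    labels = np.unique(clusters)
    n = len(y)
    var = 0.0
    z_vectors = []
    for lab in labels:
        idx = clusters == lab
        s_j = np.sum(w[idx])
        h_j = m * s_j
        adj = 1.0 / math.sqrt(max(1.0 - h_j, 1e-12))
        u_j = adj * np.sum(w[idx] * e[idx])
        var += (m * u_j) ** 2
        g = np.zeros(n)
        g[idx] = m * adj * w[idx]
        # z_j = (I - H)' g_j with H' g = m * w * sum(g)
        z_vectors.append(g - m * w * np.sum(g))
    z = np.array(z_vectors)
    omega = z @ z.T
    tr = np.trace(omega)
    df = tr**2 / np.sum(omega * omega)
    return float(var), float(df)


def random_effects_meta(
    estimates: Sequence[DivbtaEstimate],
    tau2_method: str = "reml",
    clusters: Optional[Sequence[object]] = None,
) -> MetaFit:
    """Inverse-variance random-effects fit of a set of lnCVR estimates.

    Parameters
    ----------
    estimates
        At least 3 estimates with finite positive sampling variances.
    tau2_method
        ``"reml"`` (default) or ``"dl"`` (DerSimonian-Laird).
    clusters
        Cluster labels (one per estimate); defaults to each estimate's
        ``trial_id`` (or its index when unlabeled). When any cluster
        contributes more than one estimate, ``var_mean`` switches to the CR2
        cluster-robust sandwich with Satterthwaite df; otherwise it is the
        model-based ``1 / sum(w)`` with ``df = k - 2``.
    """
    y = np.array([e.estimate for e in estimates], dtype=float)
    v = np.array([e.sampling_variance for e in estimates], dtype=float)
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise InvalidInputError("all estimates need finite values and sampling_variance > 0")
    if clusters is None:
        clusters = [
            e.trial_id if e.trial_id is not None else f"__unit{i}" for i, e in enumerate(estimates)
        ]
    clusters = np.asarray(clusters, dtype=object)
    k = len(np.unique(clusters))
    if k < 3:
        raise InsufficientDataError(
            f"need >= 3 independent trials for a usable prediction interval, got k={k}"
        )

    if np.ptp(y) == 0.0:
        warnings.warn("all estimates identical; tau2 = 0", stacklevel=2)
        tau2 = 0.0
    elif tau2_method == "reml":
        tau2 = _reml_tau2(y, v)
    elif tau2_method == "dl":
        tau2 = _dl_tau2(y, v)
    else:
        raise InvalidInputError(f"unknown tau2_method {tau2_method!r}")

    w = 1.0 / (v + tau2)
    mean_effect = float(np.sum(w * y) / np.sum(w))
    counts = {lab: int(np.sum(clusters == lab)) for lab in np.unique(clusters)}
    if max(counts.values()) > 1:
        var_mean, df = _cr2_sandwich(y, v, tau2, clusters)
        method = "cluster_robust"
    else:
        var_mean = float(1.0 / np.sum(w))
        df = float(k - 2)
        method = "standard"
    return MetaFit(
        mean_effect=mean_effect,
        tau2=float(tau2),
        var_mean=var_mean,
        k=k,
        df=df,
        method=method,
        tau2_method=tau2_method,
    )


def sigma_alpha(sigma_level: float) -> float:
    """Two-sided tail probability of a k-sigma band: ``2 (1 - Phi(k))``."""
    return 2.0 * stats.norm.sf(sigma_level)


def prediction_interval(fit: MetaFit, sigma_level: float = 3.0) -> ToleranceBand:
    """k-sigma prediction interval ``M* +/- t_df(alpha) sqrt(tau2 + V_M*)``.

    The df comes from the fit (k - 2 for independent estimates, Satterthwaite
    for cluster-robust fits).
    """
    if fit.df < 1:
        raise InsufficientDataError(f"prediction interval needs df >= 1, got {fit.df}")
    alpha = sigma_alpha(sigma_level)
    hw = stats.t.ppf(1.0 - alpha / 2.0, fit.df) * math.sqrt(fit.tau2 + fit.var_mean)
    return ToleranceBand(
        lower=fit.mean_effect - hw,
        upper=fit.mean_effect + hw,
        sigma_level=sigma_level,
        kind="prediction_interval",
        provenance=fit,
    )


def _tukey_hinges(values: np.ndarray) -> tuple[float, float]:
    # Tukey hinges: medians of the lower/upper halves, halves sharing the
    # middle observation when n is odd.
    s = np.sort(values)
    n = len(s)
    lower = s[: (n + 1) // 2]
    upper = s[n // 2 :]
    return float(np.median(lower)), float(np.median(upper))


def tukey_fences(trial_median_estimates: Iterable[float]) -> tuple[ToleranceBand, ToleranceBand]:
    """Tukey inner (1.5 IQR) and outer (3 IQR) fences of per-trial medians.

    Quartiles are Tukey hinges (median-of-halves). Returns (inner, outer).
    """
    vals = np.asarray(list(trial_median_estimates), dtype=float)
    if len(vals) < 4:
        raise InsufficientDataError(f"Tukey fences need >= 4 trial medians, got {len(vals)}")
    q1, q3 = _tukey_hinges(vals)
    iqr = q3 - q1
    quartiles = {"q1": q1, "q3": q3, "iqr": iqr}
    inner = ToleranceBand(q1 - 1.5 * iqr, q3 + 1.5 * iqr, kind="tukey_inner", provenance=quartiles)
    outer = ToleranceBand(q1 - 3.0 * iqr, q3 + 3.0 * iqr, kind="tukey_outer", provenance=quartiles)
    return inner, outer


@dataclass(frozen=True)
class BootstrapBands:
    """Percentile CIs for prediction-interval bounds under trial resampling."""

    lower_ci: tuple[float, float]
    upper_ci: tuple[float, float]
    n_boot: int
    seed: Optional[int]
    full_band: ToleranceBand


def bootstrap_bands(
    estimates: Sequence[DivbtaEstimate],
    sigma_level: float = 3.0,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    tau2_method: str = "reml",
    clusters: Optional[Sequence[object]] = None,
) -> BootstrapBands:
    """Cluster bootstrap of the tolerance band (resampling unit = trial).

    Each resampled trial becomes an independent pseudo-cluster, so the
    refitted k equals the original k. Returns 95% percentile intervals of
    each bound; fully reproducible from ``seed``.
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100; bootstrap CIs will be unstable", stacklevel=2)
    if clusters is None:
        clusters = [
            e.trial_id if e.trial_id is not None else f"__unit{i}" for i, e in enumerate(estimates)
        ]
    clusters = np.asarray(clusters, dtype=object)
    labels = np.unique(clusters)
    by_cluster = {lab: [e for e, c in zip(estimates, clusters) if c == lab] for lab in labels}

    full_fit = random_effects_meta(estimates, tau2_method=tau2_method, clusters=clusters)
    full_band = prediction_interval(full_fit, sigma_level)

    rng = np.random.default_rng(seed)
    lowers = np.empty(n_boot)
    uppers = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.choice(labels, size=len(labels), replace=True)
        ests: list[DivbtaEstimate] = []
        labs: list[str] = []
        for j, lab in enumerate(draw):
            for e in by_cluster[lab]:
                ests.append(e)
                labs.append(f"bs{j}")
        fit = random_effects_meta(ests, tau2_method=tau2_method, clusters=labs)
        band = prediction_interval(fit, sigma_level)
        lowers[b], uppers[b] = band.lower, band.upper
    return BootstrapBands(
        lower_ci=(float(np.percentile(lowers, 2.5)), float(np.percentile(lowers, 97.5))),
        upper_ci=(float(np.percentile(uppers, 2.5)), float(np.percentile(uppers, 97.5))),
        n_boot=n_boot,
        seed=seed,
        full_band=full_band,
    )


def select_reference_set(
    estimates: Sequence[DivbtaEstimate],
    baseline_p: Mapping[str, Optional[float]],
    low: float = 0.025,
    high: float = 0.975,
) -> list[DivbtaEstimate]:
    """Drop trials with implausible or missing baseline screens before fitting.

    ``baseline_p`` maps trial_id to a combined one-sided baseline-plausibility
    p-value (or None when missing). Trials with p < ``low``, p > ``high`` or
    a missing p are excluded from the reference set.
    """
    kept = []
    dropped = 0
    for e in estimates:
        p = baseline_p.get(e.trial_id)
        if p is None or p < low or p > high:
            dropped += 1
            continue
        kept.append(e)
    if dropped:
        logger.info("reference-set filter: excluded %d estimate(s) by baseline screen", dropped)
    return kept
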