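"""Probabilistic layer: distribution fitting, Monte Carlo, sensitivity.

Concentration variability is propagated through the deterministic
exposure→risk pipeline by Monte Carlo simulation (default 10,000
iterations).  Each stochastic variable is described by a parametric
distribution selected from the candidate set {normal, lognormal, gamma,
Weibull, uniform, triangular} by minimum Anderson–Darling statistic, with a
chi-square statistic recorded as a secondary diagnostic; small or
degenerate samples fall back to an empirical (resampling) distribution or a
point mass.

Non-detect zeros are handled with a zero-inflated mixture for the
positive-support families (lognormal, gamma, Weibull): the point mass at
zero gets the observed zero fraction and the parametric family is fitted to
the positive part by maximum likelihood.

Outputs per target are percentile vectors, the mean, and the exceedance
probability — the fraction of simulated individuals whose risk crosses its
acceptability threshold (HQ > 1, CR > 10⁻⁶, AR > 1); ``certainty`` is its
complement.  Variance attribution uses normalized squared Spearman rank
correlations between each input and the output ("contribution to
variance"), expressed as percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .risk import THRESHOLDS

__all__ = [
    "FAMILIES",
    "PERCENTILES",
    "GofStats",
    "FittedDistribution",
    "RiskDistribution",
    "SensitivityReport",
    "anderson_darling",
    "chi_square_gof",
    "fit_family",
    "fit_distribution",
    "point_mass",
    "monte_carlo",
    "summarize_draws",
    "exceedance_probability",
    "sensitivity",
    "probabilistic_assessment",
]

FAMILIES = ("normal", "lognormal", "gamma", "weibull", "uniform", "triangular")
_POSITIVE_FAMILIES = frozenset({"lognormal", "gamma", "weibull"})

_SCIPY_DIST = {
    "normal": stats.norm,
    "lognormal": stats.lognorm,
    "gamma": stats.gamma,
    "weibull": stats.weibull_min,
    "uniform": stats.uniform,
    "triangular": stats.triang,
}

_N_PARAMS = {
    "normal": 2, "lognormal": 2, "gamma": 2, "weibull": 2,
    "uniform": 2, "triangular": 3,
}

PERCENTILES = (1, 5, 25, 50, 75, 95, 99)

_EPS = 1e-12


@dataclass(frozen=True)
class GofStats:
    """Goodness-of-fit diagnostics for one fitted candidate."""

    ad: float
    chisq: float
    chisq_p: float
    chisq_dof: int


@dataclass
class FittedDistribution:
    """A fitted marginal distribution for one stochastic variable.

    ``params`` are scipy shape/loc/scale parameters for parametric
    families, the retained sample for ``empirical``, and ``(value,)`` for
    ``point_mass``.  ``zero_weight`` is the point mass at zero of the
    zero-inflated mixture (0 for families fitted to the full sample).
    """

    variable: str
    family: str
    params: tuple
    zero_weight: float = 0.0
    gof: GofStats | None = None
    n: int = 0
    candidates: Mapping[str, GofStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES + ("empirical", "point_mass"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 0 <= self.zero_weight < 1:
            raise ValueError("zero_weight must be in [0, 1)")

    def _frozen(self):
        return _SCIPY_DIST[self.family](*self.params)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.family == "point_mass":
            return (x >= self.params[0]).astype(float)
        if self.family == "empirical":
            sample = np.sort(np.asarray(self.params))
            return np.searchsorted(sample, x, side="right") / len(sample)
        base = self._frozen().cdf(x)
        if self.zero_weight > 0:
            return np.where(x >= 0, self.zero_weight + (1 - self.zero_weight) * base,
                            0.0)
        return base

    def mean(self) -> float:
        if self.family == "point_mass":
            return float(self.params[0])
        if self.family == "empirical":
            return float(np.mean(self.params))
        return float((1 - self.zero_weight) * self._frozen().mean())

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point_mass":
            return np.full(size, float(self.params[0]))
        if self.family == "empirical":
            return rng.choice(np.asarray(self.params, dtype=float), size=size)
        draws = self._frozen().rvs(size=size, random_state=rng)
        if self.zero_weight > 0:
            draws = np.where(rng.random(size) < self.zero_weight, 0.0, draws)
        return draws


def point_mass(value: float, variable: str = "x") -> FittedDistribution:
    """A degenerate distribution concentrated at one value."""
    return FittedDistribution(variable, "point_mass", (float(value),), n=1)


def anderson_darling(values: Sequence[float], cdf: Callable) -> float:
    """Anderson–Darling statistic of a sample against a fitted CDF:

    A² = −n − (1/n) Σᵢ (2i−1) [ln F(x₍ᵢ₎) + ln(1 − F(x₍n+1−i₎))]

    CDF values are clipped away from {0, 1} so that atoms (e.g. a zero
    point mass) and extreme tails stay finite.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    u = np.clip(np.asarray(cdf(x), dtype=float), _EPS, 1 - _EPS)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log(1 - u[::-1]))))


def chi_square_gof(
    values: Sequence[float], cdf: Callable, n_params: int
) -> tuple[float, float, int]:
    """Chi-square goodness of fit on near-equiprobable empirical-quantile
    bins; returns (statistic, p-value, degrees of freedom)."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    k = max(4, min(int(math.sqrt(n)), 30))
    edges = np.unique(np.quantile(x, np.linspace(0, 1, k + 1)[1:-1]))
    edges = np.concatenate(([-np.inf], edges, [np.inf]))
    observed, _ = np.histogram(x, bins=np.concatenate(
        ([x[0] - 1], edges[1:-1], [x[-1] + 1])))
    cum = np.clip(np.asarray(cdf(edges[1:-1]), dtype=float), 0, 1)
    probs = np.diff(np.concatenate(([0.0], cum, [1.0])))
    expected = n * np.clip(probs, _EPS, None)
    statistic = float(np.sum((observed - expected) ** 2 / expected))
    dof = max(len(observed) - 1 - n_params, 1)
    return statistic, float(stats.chi2.sf(statistic, dof)), dof


def fit_family(values: Sequence[float], family: str) -> tuple[tuple, float]:
    """Maximum-likelihood fit of one candidate family.

    Positive-support families are fitted to the positive part with the
    location pinned at 0 and a zero point-mass weight equal to the observed
    zero fraction; the remaining families are fitted to the full sample.
    Returns ``(scipy_params, zero_weight)``.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if family in _POSITIVE_FAMILIES:
        pos = x[x > 0]
        if len(pos) < 2 or np.ptp(pos) == 0:
            raise ValueError(f"{family}: not enough positive spread to fit")
        zero_weight = 1 - len(pos) / len(x)
        dist = _SCIPY_DIST[family]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = dist.fit(pos, floc=0)
        return tuple(params), float(zero_weight)
    if family == "normal":
        return tuple(stats.norm.fit(x)), 0.0
    if family == "uniform":
        lo, span = x[0], float(np.ptp(x))
        if span == 0:
            raise ValueError("uniform: zero range")
        return (float(lo), span), 0.0
    if family == "triangular":
        lo, hi = x[0], x[-1]
        span = hi - lo
        if span == 0:
            raise ValueError("triangular: zero range")
        c0 = float(np.clip((3 * np.mean(x) - lo - hi) / span, 0.05, 0.95))
        pad = 1e-9 * span
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = stats.triang.fit(x, c0, loc=lo - pad, scale=span + 2 * pad)
        return tuple(params), 0.0
    raise ValueError(f"unknown family {family!r}")


def fit_distribution(
    values: Sequence[float],
    variable: str = "x",
    families: Iterable[str] = FAMILIES,
) -> FittedDistribution:
    """Fit candidate families and select the best by Anderson–Darling.

    Requires ≥ 8 observations with ≥ 2 distinct values for parametric
    fitting; smaller well-behaved samples fall back to an empirical
    distribution, and all-identical samples collapse to a point mass (with
    a warning).  Fewer than 2 observations is a hard error.  The input
    order never matters: values are sorted before fitting.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if len(x) < 2:
        raise ValueError("need at least 2 samples to fit a distribution")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite and >= 0")
    if np.ptp(x) == 0:
        warnings.warn(f"{variable}: all samples identical; using a point mass",
                      stacklevel=2)
        return FittedDistribution(variable, "point_mass", (float(x[0]),), n=len(x))
    if len(x) < 8:
        return FittedDistribution(variable, "empirical", tuple(x), n=len(x))

    fits: dict[str, tuple[tuple, float, GofStats]] = {}
    for family in families:
        try:
            params, zero_weight = fit_family(x, family)
        except (ValueError, RuntimeError):
            continue
        probe = FittedDistribution(variable, family, params, zero_weight, n=len(x))
        if not np.all(np.isfinite(probe.cdf(x))):
            continue
        ad = anderson_darling(x, probe.cdf)
        chisq, p, dof = chi_square_gof(x, probe.cdf, _N_PARAMS[family])
        fits[family] = (params, zero_weight, GofStats(ad, chisq, p, dof))
    if not fits:
        return FittedDistribution(variable, "empirical", tuple(x), n=len(x))

    best = min(fits, key=lambda f: fits[f][2].ad)
    params, zero_weight, gof = fits[best]
    return FittedDistribution(
        variable, best, params, zero_weight, gof=gof, n=len(x),
        candidates={f: g for f, (_, _, g) in fits.items()},
    )


@dataclass(frozen=True)
class RiskDistribution:
    """Monte Carlo output for one target quantity."""

    target: str
    n_iter: int
    seed: int
    mean: float
    percentiles: Mapping[int, float]
    threshold: float | None
    exceedance: float | None
    certainty: float | None

    def __post_init__(self) -> None:
        pct = [self.percentiles[p] for p in sorted(self.percentiles)]
        if any(b < a - 1e-12 for a, b in zip(pct, pct[1:])):
            raise ValueError("percentiles must be non-decreasing")
        if self.exceedance is not None and not 0 <= self.exceedance <= 1:
            raise ValueError("exceedance must be a probability")


def exceedance_probability(draws: np.ndarray, threshold: float) -> tuple[float, float]:
    """Fraction of draws strictly above the threshold, and its complement
    (the "certainty" that the individual stays within the acceptable range)."""
    draws = np.asarray(draws, dtype=float)
    exceedance = float(np.mean(draws > threshold))
    return exceedance, 1.0 - exceedance


def summarize_draws(
    target: str,
    draws: np.ndarray,
    threshold: float | None,
    seed: int,
) -> RiskDistribution:
    draws = np.asarray(draws, dtype=float)
    pct = {p: float(np.percentile(draws, p)) for p in PERCENTILES}
    if threshold is None:
        exc = cert = None
    else:
        exc, cert = exceedance_probability(draws, threshold)
    return RiskDistribution(
        target, len(draws), seed, float(np.mean(draws)), pct, threshold, exc, cert
    )


def monte_carlo(
    pipeline: Callable[[Mapping[str, np.ndarray]], Mapping[str, np.ndarray]],
    fitted: Mapping[str, FittedDistribution],
    n_iter: int = 10_000,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Draw every stochastic variable and evaluate the pipeline per draw.

    ``pipeline`` maps a dict of per-variable draw vectors to a dict of
    per-target output vectors.  Negative draws are truncated at 0.  A fixed
    seed fixes every reported number; variables are drawn in sorted name
    order from a single generator.  Returns ``(outputs, input_draws)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_iter < 1000:
        warnings.warn(
            f"n_iter={n_iter} < 1000: percentile and exceedance estimates "
            "will be unstable", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    draws = {
        name: np.maximum(fitted[name].sample(rng, n_iter), 0.0)
        for name in sorted(fitted)
    }
    outputs = {k: np.asarray(v, dtype=float) for k, v in pipeline(draws).items()}
    for name, out in outputs.items():
        if out.shape != (n_iter,):
            raise ValueError(f"pipeline output {name!r} has shape {out.shape}")
    return outputs, draws


@dataclass(frozen=True)
class SensitivityReport:
    """Percentage contribution of each input to one output's variance."""

    target: str
    contributions: Mapping[str, float]
    method: str = "spearman_r2_normalized"

    def __post_init__(self) -> None:
        total = sum(self.contributions.values())
        if self.contributions and total > 0 and abs(total - 100.0) > 0.1:
            raise ValueError(f"contributions sum to {total}, expected 100")


def sensitivity(
    inputs: Mapping[str, np.ndarray], output: np.ndarray, target: str = "output"
) -> SensitivityReport:
    """Attribute output variance to inputs by normalized squared Spearman
    rank correlation.  Constant inputs contribute 0 %; a constant output
    yields all-zero contributions with a warning."""
    output = np.asarray(output, dtype=float)
    if len(output) < 2:
        raise ValueError("need at least 2 draws")
    if np.ptp(output) == 0:
        warnings.warn(f"{target}: output is constant; contributions undefined",
                      stacklevel=2)
        return SensitivityReport(target, {k: 0.0 for k in inputs})
    r2: dict[str, float] = {}
    for name, x in inputs.items():
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            r2[name] = 0.0
            continue
        rho = stats.spearmanr(x, output).statistic
        r2[name] = float(rho**2) if np.isfinite(rho) else 0.0
    total = sum(r2.values())
    if total == 0:
        warnings.warn(f"{target}: no input correlates with the output", stacklevel=2)
        return SensitivityReport(target, {k: 0.0 for k in r2})
    return SensitivityReport(target, {k: 100.0 * v / total for k, v in r2.items()})


def _assessment_pipeline(refs, scenario, mode, keys):
    """Build the vectorized draws→risks closure for the packaged assessment."""
    from .exposure import acute_intake, dd_dermal, dd_inhalation, dd_oral
    from .registry import NoReferenceAvailable, noncancer_reference_dose

    def pipeline(draws: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        totals: dict[str, np.ndarray] = {}

        def accumulate(total_key: str, values: np.ndarray) -> None:
            totals[total_key] = totals.get(total_key, 0.0) + values

        for chem, matrix in keys:
            ref = refs.get(chem)
            if ref is None:
                continue
            p = draws[f"{chem}|{matrix}"]
            if matrix == "aerosol":
                dose = dd_inhalation(p, scenario, chem).value
                if ref.cpv_inh is not None:
                    out[f"CR|{chem}|inhalation"] = ref.cpv_inh * dose
                    accumulate("CR_total|inhalation", ref.cpv_inh * dose)
                try:
                    rd = noncancer_reference_dose(chem, "inhalation", ref, scenario)
                    out[f"HQ|{chem}|inhalation"] = dose / rd.value
                    accumulate("HI|inhalation", dose / rd.value)
                except NoReferenceAvailable:
                    pass
            else:
                oral = dd_oral(p, scenario, chem).value
                derm = dd_dermal(p, chem, scenario, mode).value
                if ref.cpv_oral is not None:
                    out[f"CR|{chem}|oral"] = ref.cpv_oral * oral
                    accumulate("CR_total|oral", ref.cpv_oral * oral)
                if ref.sf_derm is not None:
                    out[f"CR|{chem}|dermal"] = ref.sf_derm * derm
                    accumulate("CR_total|dermal", ref.sf_derm * derm)
                for route, dose in (("oral", oral), ("dermal", derm)):
                    try:
                        rd = noncancer_reference_dose(chem, route, ref, scenario)
                        out[f"HQ|{chem}|{route}"] = dose / rd.value
                        accumulate(f"HI|{route}", dose / rd.value)
                    except NoReferenceAvailable:
                        pass
                intake = acute_intake(p, scenario, chem).value
                for route, ld50 in (("oral", ref.ld50_oral), ("dermal", ref.ld50_derm)):
                    if ld50 is not None:
                        out[f"AR|{chem}|{route}"] = intake / ld50
                        accumulate(f"AR_total|{route}", intake / ld50)
        out.update(totals)
        return out

    return pipeline


_TARGET_THRESHOLD = {"CR": THRESHOLDS["cancer"], "HQ": THRESHOLDS["noncancer"],
                     "AR": THRESHOLDS["acute"], "HI": THRESHOLDS["noncancer"],
                     "CR_total": THRESHOLDS["cancer"], "AR_total": THRESHOLDS["acute"]}


def probabilistic_assessment(
    fitted: Mapping[tuple[str, str], FittedDistribution],
    refs=None,
    scenario=None,
    mode: str = "paper_replication",
    n_iter: int = 10_000,
    seed: int = 0,
) -> dict:
    """Monte Carlo risk assessment over fitted concentration distributions.

    ``fitted`` maps (chemical, matrix) to a fitted marginal distribution.
    Returns a dict with per-target :class:`RiskDistribution` objects,
    per-total :class:`SensitivityReport` objects (contributions of the
    concentration inputs), and the raw output draws.
    """
    from .exposure import ExposureScenario
    from .registry import load_packaged_references

    if refs is None:
        refs = load_packaged_references()
    if scenario is None:
        scenario = ExposureScenario.paper_default()

    keys = sorted(fitted)
    named = {f"{c}|{m}": d for (c, m), d in fitted.items()}
    pipeline = _assessment_pipeline(refs, scenario, mode, keys)
    outputs, input_draws = monte_carlo(pipeline, named, n_iter, seed)

    distributions = {}
    for target, vec in outputs.items():
        kind = target.split("|")[0]
        distributions[target] = summarize_draws(
            target, vec, _TARGET_THRESHOLD.get(kind), seed
        )

    sensitivities = {}
    for target, vec in outputs.items():
        if target.split("|")[0] in ("HI", "CR_total", "AR_total"):
            route = target.split("|")[1]
            matrix = "aerosol" if route == "inhalation" else "e-liquid"
            relevant = {k: v for k, v in input_draws.items() if k.endswith(matrix)}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sensitivities[target] = sensitivity(relevant, vec, target)

    return {
        "distributions": distributions,
        "sensitivities": sensitivities,
        "outputs": outputs,
        "inputs": input_draws,
        "n_iter": n_iter,
        "seed": seed,
        "mode": mode,
    }
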