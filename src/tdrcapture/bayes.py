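"""Bayesian linear regression of blood chemistry on capture duration and SST.

A Gibbs sampler for the normal linear model with vague zero-mean normal
priors on coefficients (precision 1e-6 by default) and a vague
inverse-gamma prior on the residual variance. Lactate is modelled on the
natural-log scale. Significance follows the credibility-interval rule: a
quantity is significant when its central 95% interval (2.5–97.5%) excludes
zero. A BEST-style normal two-group model estimates differences between
group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BloodRecord",
    "McmcConfig",
    "CoefficientSummary",
    "PosteriorSummary",
    "PredictedMean",
    "GroupDifferenceResult",
    "BLOOD_VARIABLES",
    "LOG_RESPONSES",
    "read_blood_table",
    "write_blood_table",
    "fit_additive_regression",
    "predict_mean",
    "extrapolate_mean",
    "two_group_difference",
    "significance",
    "quadratic_term_check",
]

BLOOD_VARIABLES = ("ph", "lactate", "glucose", "potassium", "osmolality", "haematocrit")
#: responses fitted on the natural-log scale
LOG_RESPONSES = frozenset({"lactate"})


@dataclass(frozen=True)
class BloodRecord:
    """One animal's blood panel with capture covariates."""

    animal_id: str
    ph: float
    lactate: float
    glucose: float
    potassium: float
    osmolality: float
    haematocrit: float
    capture_duration_min: float
    sst_c: float
    alive: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.sst_c <= 35:
            raise ValueError(f"{self.animal_id}: SST {self.sst_c} outside 0-35 C")
        if self.capture_duration_min <= 0:
            raise ValueError(f"{self.animal_id}: capture duration must be > 0")
        for name in ("lactate", "glucose", "potassium", "osmolality", "haematocrit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.animal_id}: {name} must be >= 0")


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings; defaults follow the analysis protocol."""

    iterations: int = 50_000
    burn_in: int = 2_000
    thinning: int = 10
    prior_precision: float = 1e-6
    sigma_prior_shape: float = 1e-3
    sigma_prior_rate: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.prior_precision <= 0:
            raise ValueError("prior_precision must be > 0")


@dataclass(frozen=True)
class CoefficientSummary:
    mean: float
    sd: float
    ci_lo: float
    ci_hi: float
    significant: bool


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior of one additive regression fit, with retained draws."""

    response: str
    transform: str  # "identity" | "log"
    predictors: tuple[str, ...]
    coefficients: dict[str, CoefficientSummary]
    sigma_mean: float
    n: int
    draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    sigma_draws: np.ndarray = field(repr=False, default=None)
    sst_range: tuple[float, float] = (-np.inf, np.inf)
    diagnostics: dict[str, float] = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        ess = [v for k, v in self.diagnostics.items() if k.startswith("ess_")]
        return bool(ess) and min(ess) >= 200


@dataclass(frozen=True)
class PredictedMean:
    mean: float
    ci_lo: float
    ci_hi: float


@dataclass(frozen=True)
class GroupDifferenceResult:
    """Posterior of mean(a) - mean(b)."""

    mean: float
    ci_lo: float
    ci_hi: float
    significant: bool


def significance(ci_lo: float, ci_hi: float) -> bool:
    """True when the credibility interval excludes zero."""
    if ci_lo > ci_hi:
        raise ValueError("ci_lo must not exceed ci_hi")
    return ci_lo > 0 or ci_hi < 0


def _summarize(draws: np.ndarray) -> CoefficientSummary:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return CoefficientSummary(
        mean=float(draws.mean()),
        sd=float(draws.std(ddof=1)),
        ci_lo=float(lo),
        ci_hi=float(hi),
        significant=significance(float(lo), float(hi)),
    )


def _ess(x: np.ndarray) -> float:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x[np.newaxis, :]))


def _gibbs_linear(
    X: np.ndarray,
    y: np.ndarray,
    mcmc: McmcConfig,
    rng: np.random.Generator,
    fixed_sigma2: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gibbs draws for beta (k columns) and sigma of y = X beta + eps."""
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    tau = mcmc.prior_precision
    a0, b0 = mcmc.sigma_prior_shape, mcmc.sigma_prior_rate

    # Work in the eigenbasis of X'X: the conditional precision is
    # Q (lam/sigma2 + tau) Q', so each sweep is O(p^2) with no
    # per-iteration factorization.
    lam, Q = np.linalg.eigh(XtX)
    b_eig = Q.T @ Xty

    sigma2 = fixed_sigma2 if fixed_sigma2 is not None else float(np.var(y) or 1.0)
    n_keep = -(-(mcmc.iterations - mcmc.burn_in) // mcmc.thinning)
    betas = np.empty((n_keep, p))
    sigmas = np.empty(n_keep)
    z_all = rng.standard_normal((mcmc.iterations, p))
    # the gamma shape is constant, so the shape-1 variates can be batched
    g_all = rng.gamma(a0 + n / 2.0, 1.0, size=mcmc.iterations)
    kept = 0
    for it in range(mcmc.iterations):
        d = lam / sigma2 + tau
        beta_eig = b_eig / (sigma2 * d) + z_all[it] / np.sqrt(d)
        beta = Q @ beta_eig
        if fixed_sigma2 is None:
            resid = y - X @ beta
            sigma2 = (b0 + 0.5 * float(resid @ resid)) / g_all[it]
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            betas[kept] = beta
            sigmas[kept] = np.sqrt(sigma2)
            kept += 1
    return betas[:kept], sigmas[:kept]


def fit_additive_regression(
    records: list[BloodRecord],
    response: str,
    include_interaction: bool = False,
    mcmc: McmcConfig | None = None,
    *,
    transform: str | None = None,
    fixed_sigma2: float | None = None,
    diagnostics: bool = True,
) -> PosteriorSummary:
    """Fit one blood variable on capture duration and SST.

    ``transform`` defaults to "log" for lactate and "identity" otherwise;
    log responses are natural-log transformed before fitting.
    ``fixed_sigma2`` pins the residual variance (conjugate-check hook).
    ``diagnostics=False`` skips effective-sample-size computation (useful
    inside large simulation studies).
    """
    mcmc = mcmc or McmcConfig()
    live = [r for r in records if r.alive]
    if not live:
        raise ValueError("no live animals in input")
    if len(live) < 4:
        raise ValueError(f"need >= 4 live records, got {len(live)}")
    if response not in BLOOD_VARIABLES:
        raise ValueError(f"unknown response {response!r}")
    if transform is None:
        transform = "log" if response in LOG_RESPONSES else "identity"
    if transform not in ("identity", "log"):
        raise ValueError(f"unknown transform {transform!r}")

    y = np.array([getattr(r, response) for r in live], dtype=float)
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive response")
        y = np.log(y)
    dur = np.array([r.capture_duration_min for r in live])
    sst = np.array([r.sst_c for r in live])
    for name, x in (("capture_duration_min", dur), ("sst_c", sst)):
        if np.ptp(x) == 0:
            raise ValueError(f"predictor {name} is constant")
    cols = [np.ones_like(dur), dur, sst]
    names = ["intercept", "capture_duration_min", "sst_c"]
    if include_interaction:
        cols.append(dur * sst)
        names.append("capture_duration_min:sst_c")
    X = np.column_stack(cols)
    if np.linalg.cond(X) > 1e8:
        raise ValueError("predictors are (near-)collinear")

    rng = np.random.default_rng(mcmc.seed)
    betas, sigmas = _gibbs_linear(X, y, mcmc, rng, fixed_sigma2=fixed_sigma2)
    draws = {name: betas[:, j] for j, name in enumerate(names)}
    coefficients = {name: _summarize(d) for name, d in draws.items()}
    diag: dict[str, float] = {}
    if diagnostics:
        diag = {f"ess_{name}": _ess(d) for name, d in draws.items()}
        half = betas.shape[0] // 2
        for j, name in enumerate(names):
            post_sd = max(coefficients[name].sd, 1e-12)
            diag[f"split_shift_{name}"] = float(
                abs(betas[:half, j].mean() - betas[half:, j].mean()) / post_sd
            )
    return PosteriorSummary(
        response=response,
        transform=transform,
        predictors=tuple(names[1:]),
        coefficients=coefficients,
        sigma_mean=float(sigmas.mean()),
        n=len(live),
        draws=draws,
        sigma_draws=sigmas,
        sst_range=(float(sst.min()), float(sst.max())),
        diagnostics=diag,
    )


def predict_mean(
    fit: PosteriorSummary, sst_c: float, duration_min: float = 0.0
) -> PredictedMean:
    """Posterior predicted mean of the response at given covariates.

    For log-transformed responses each draw's linear predictor is
    exponentiated before summarising, so the reported mean is the
    posterior mean on the response scale.
    """
    lo, hi = fit.sst_range
    if not lo <= sst_c <= hi:
        warnings.warn(
            f"SST {sst_c} C outside fitted range [{lo}, {hi}] C; extrapolating",
            stacklevel=2,
        )
    eta = fit.draws["intercept"].copy()
    eta += fit.draws["capture_duration_min"] * duration_min
    eta += fit.draws["sst_c"] * sst_c
    if "capture_duration_min:sst_c" in fit.draws:
        eta += fit.draws["capture_duration_min:sst_c"] * duration_min * sst_c
    vals = np.exp(eta) if fit.transform == "log" else eta
    ci_lo, ci_hi = np.percentile(vals, [2.5, 97.5])
    return PredictedMean(mean=float(vals.mean()), ci_lo=float(ci_lo), ci_hi=float(ci_hi))


def extrapolate_mean(
    mean_at_ref: float, slope: float, delta_x: float, transform: str = "identity"
) -> float:
    """Shift a predicted mean along one covariate by ``delta_x``.

    Identity responses move additively; log responses multiplicatively
    (slope on the natural-log scale).
    """
    if transform == "identity":
        return mean_at_ref + slope * delta_x
    if transform == "log":
        return mean_at_ref * float(np.exp(slope * delta_x))
    raise ValueError(f"unknown transform {transform!r}")


def two_group_difference(
    a, b, mcmc: McmcConfig | None = None
) -> GroupDifferenceResult:
    """BEST-style normal estimate of mean(a) - mean(b).

    Independent normal likelihoods per group with group-specific
    variances, vague normal priors on the means and vague inverse-gamma
    priors on the variances.
    """
    mcmc = mcmc or McmcConfig()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(mcmc.seed)
    draws = []
    for g in (a, b):
        if np.ptp(g) == 0:
            warnings.warn(
                "zero-variance group; posterior is regularized by the variance prior",
                stacklevel=2,
            )
        X = np.ones((g.size, 1))
        betas, _ = _gibbs_linear(X, g, mcmc, rng)
        draws.append(betas[:, 0])
    diff = draws[0] - draws[1]
    s = _summarize(diff)
    return GroupDifferenceResult(
        mean=s.mean, ci_lo=s.ci_lo, ci_hi=s.ci_hi, significant=s.significant
    )


def quadratic_term_check(
    records: list[BloodRecord],
    response: str,
    predictor: str,
    mcmc: McmcConfig | None = None,
) -> CoefficientSummary:
    """Linearity screen: posterior of a centred quadratic term.

    Adds (x - mean(x))^2 for the chosen predictor to the additive model
    and reports its coefficient; a non-significant quadratic supports the
    linear specification.
    """
    if predictor not in ("capture_duration_min", "sst_c"):
        raise ValueError("predictor must be capture_duration_min or sst_c")
    mcmc = mcmc or McmcConfig()
    live = [r for r in records if r.alive]
    if len(live) < 5:
        raise ValueError("need >= 5 live records for the quadratic screen")
    transform = "log" if response in LOG_RESPONSES else "identity"
    y = np.array([getattr(r, response) for r in live], dtype=float)
    if transform == "log":
        y = np.log(y)
    dur = np.array([r.capture_duration_min for r in live])
    sst = np.array([r.sst_c for r in live])
    x = dur if predictor == "capture_duration_min" else sst
    X = np.column_stack([np.ones_like(dur), dur, sst, (x - x.mean()) ** 2])
    rng = np.random.default_rng(mcmc.seed)
    betas, _ = _gibbs_linear(X, y, mcmc, rng)
    return _summarize(betas[:, 3])


def read_blood_table(path, *, delimiter: str = ",") -> list[BloodRecord]:
    """Read a delimited blood table; columns named as BloodRecord fields."""
    df = pd.read_csv(path, delimiter=delimiter)
    required = {"animal_id", "capture_duration_min", "sst_c", *BLOOD_VARIABLES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df["animal_id"][df["animal_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate animal_id {dup.iloc[0]!r}")
    if "alive" not in df.columns:
        df = df.assign(alive=True)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            BloodRecord(
                animal_id=str(row.animal_id),
                ph=float(row.ph),
                lactate=float(row.lactate),
                glucose=float(row.glucose),
                potassium=float(row.potassium),
                osmolality=float(row.osmolality),
                haematocrit=float(row.haematocrit),
                capture_duration_min=float(row.capture_duration_min),
                sst_c=float(row.sst_c),
                alive=bool(row.alive),
            )
        )
    return records


def write_blood_table(records: list[BloodRecord], path, *, delimiter: str = ",") -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep=delimiter, index=False)
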