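"""Bayesian cubic tail model for log mortality rates.

Each tail of a region's binned temperature-mortality curve is modelled as

    y_k ~ Normal(alpha + b1*u_k + b2*u_k^2 + b3*u_k^3, sigma^2),

where ``y_k`` is the log interval-mean mortality rate, ``u_k = x_k - c`` is
the interval-mean apparent temperature centred at the comfort temperature
``c``, and the warm and cold tails are fitted independently. The prior is
conjugate Normal-Inverse-Gamma,

    beta | sigma^2 ~ Normal(m0, sigma^2 * diag(s0^2)),
    sigma^2 ~ InvGamma(a0, b0),

so the joint posterior is available in closed form and is sampled exactly
(no MCMC): sigma^2 from its marginal Inverse-Gamma, then beta from the
conditional multivariate Normal. With a flat coefficient prior the
posterior mean of beta is exactly the ordinary-least-squares solution.

The public surface follows the Model/Results convention:
:class:`BayesianCubicTailModel` holds the data and prior,
``fit()`` returns a :class:`CubicTailResults` carrying the posterior draws,
their summaries and prediction methods. :func:`fit_tail` is the functional
shorthand used by the pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

from .curves import TailDataset

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "BayesianCubicTailModel",
    "CubicTailResults",
    "CurvePrediction",
    "fit_tail",
    "predict_mean_curve",
]

N_COEF = 4  # intercept + three polynomial terms


@dataclass
class PriorSpec:
    """Normal-Inverse-Gamma prior for one tail fit.

    ``coef_sd=None`` marks an improper flat prior on the coefficients, under
    which the posterior mean equals the least-squares estimate. The
    coefficient prior scale is relative to sigma (standard conjugate
    coupling). Defaults are weakly informative: the predictors are centred
    at the comfort temperature, so an SD of 100 is vague on every term.
    """

    coef_mean: np.ndarray = field(default_factory=lambda: np.zeros(N_COEF))
    coef_sd: np.ndarray | None = field(
        default_factory=lambda: np.full(N_COEF, 100.0)
    )
    sigma_shape: float = 0.01  # Inverse-Gamma a0
    sigma_scale: float = 0.01  # Inverse-Gamma b0

    def __post_init__(self) -> None:
        self.coef_mean = np.asarray(self.coef_mean, dtype=float)
        if self.coef_mean.shape != (N_COEF,):
            raise ValueError("coef_mean must have length 4")
        if self.coef_sd is not None:
            self.coef_sd = np.asarray(self.coef_sd, dtype=float)
            if self.coef_sd.shape != (N_COEF,):
                raise ValueError("coef_sd must have length 4")
            if (self.coef_sd <= 0).any():
                raise ValueError("coef_sd must be positive (or None for flat)")
        if self.sigma_shape < 0 or self.sigma_scale < 0:
            raise ValueError("sigma prior hyperparameters must be >= 0")

    @classmethod
    def flat(cls, sigma_shape: float = 0.0, sigma_scale: float = 0.0) -> "PriorSpec":
        """Improper flat prior on coefficients; Jeffreys-type on sigma^2."""
        return cls(coef_sd=None, sigma_shape=sigma_shape, sigma_scale=sigma_scale)

    def to_dict(self) -> dict:
        return {
            "coef_mean": self.coef_mean.tolist(),
            "coef_sd": None if self.coef_sd is None else self.coef_sd.tolist(),
            "sigma_shape": self.sigma_shape,
            "sigma_scale": self.sigma_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(
            coef_mean=np.asarray(d["coef_mean"], dtype=float),
            coef_sd=None if d["coef_sd"] is None else np.asarray(d["coef_sd"], float),
            sigma_shape=float(d["sigma_shape"]),
            sigma_scale=float(d["sigma_scale"]),
        )


@dataclass
class PosteriorDraws:
    """Joint posterior samples of one tail's model parameters.

    Coefficients are expressed on temperature centred at ``centering``
    (the comfort temperature at fit time); :meth:`recenter` re-expands the
    cubic about a different origin exactly, which is how fitted
    coefficients are compared with truths defined about another centre.
    """

    region_id: str
    tail: str  # "warm" | "cold"
    alpha: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray
    sigma: np.ndarray
    centering: float
    seed: int

    def __post_init__(self) -> None:
        n = len(self.alpha)
        for name in ("beta1", "beta2", "beta3", "sigma"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != n_samples")
        if (self.sigma <= 0).any():
            raise ValueError("sigma draws must be strictly positive")

    @property
    def n_samples(self) -> int:
        return len(self.alpha)

    def coef_matrix(self) -> np.ndarray:
        """(n_samples, 4) array of (alpha, beta1, beta2, beta3) draws."""
        return np.column_stack([self.alpha, self.beta1, self.beta2, self.beta3])

    def polyval(self, x) -> np.ndarray:
        """Per-draw cubic evaluated at temperatures ``x`` -> (n_samples, len(x))."""
        u = np.atleast_1d(np.asarray(x, dtype=float)) - self.centering
        return (
            self.alpha[:, None]
            + self.beta1[:, None] * u
            + self.beta2[:, None] * u**2
            + self.beta3[:, None] * u**3
        )

    def recenter(self, new_center: float) -> "PosteriorDraws":
        """Re-express every draw's cubic about ``new_center`` (exact)."""
        d = self.centering - new_center
        a, b1, b2, b3 = self.alpha, self.beta1, self.beta2, self.beta3
        return PosteriorDraws(
            region_id=self.region_id,
            tail=self.tail,
            alpha=a - b1 * d + b2 * d**2 - b3 * d**3,
            beta1=b1 - 2 * b2 * d + 3 * b3 * d**2,
            beta2=b2 - 3 * b3 * d,
            beta3=b3.copy(),
            sigma=self.sigma.copy(),
            centering=new_center,
            seed=self.seed,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alpha,
                "beta1": self.beta1,
                "beta2": self.beta2,
                "beta3": self.beta3,
                "sigma": self.sigma,
            }
        )

    def save(self, draws_path, meta_path=None) -> None:
        """Write draws as delimited text plus JSON metadata."""
        self.to_frame().to_csv(draws_path, index=False)
        if meta_path is not None:
            meta = {
                "region_id": self.region_id,
                "tail": self.tail,
                "n_samples": self.n_samples,
                "centering": self.centering,
                "seed": self.seed,
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, draws_path, meta_path) -> "PosteriorDraws":
        df = pd.read_csv(draws_path)
        with open(meta_path) as fh:
            meta = json.load(fh)
        return cls(
            region_id=meta["region_id"],
            tail=meta["tail"],
            alpha=df["alpha"].to_numpy(),
            beta1=df["beta1"].to_numpy(),
            beta2=df["beta2"].to_numpy(),
            beta3=df["beta3"].to_numpy(),
            sigma=df["sigma"].to_numpy(),
            centering=float(meta["centering"]),
            seed=int(meta["seed"]),
        )


@dataclass
class CurvePrediction:
    """Posterior curve on a temperature grid: per-draw values and summaries."""

    x_grid: np.ndarray
    draws: np.ndarray  # (n_samples, len(x_grid)) log rates
    mean: np.ndarray
    q025: np.ndarray
    q975: np.ndarray
    extrapolated: np.ndarray  # bool mask per grid point


class BayesianCubicTailModel:
    """Conjugate Bayesian cubic regression for one region-tail.

    Parameters
    ----------
    data : TailDataset
        Interval points (x in degC, y in log rate) of one tail.
    centering : float
        Temperature subtracted from x before fitting — the comfort
        temperature. Stored on the results so predictions are
        representation-invariant.
    prior : PriorSpec, optional
        Defaults to the weakly informative Normal-Inverse-Gamma prior.
    weighted : bool
        If True, weight each interval by its day count. Default False: the
        model treats interval means homoskedastically, one point each.
    """

    def __init__(
        self,
        data: TailDataset,
        centering: float,
        prior: PriorSpec | None = None,
        weighted: bool = False,
    ) -> None:
        self.data = data
        self.centering = float(centering)
        self.prior = prior if prior is not None else PriorSpec()
        self.weighted = weighted

        x = np.asarray(data.x, dtype=float)
        y = np.asarray(data.y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("tail data contain non-finite values")
        self._x = x
        self._y = y
        u = x - self.centering
        self._design = np.column_stack([np.ones_like(u), u, u**2, u**3])
        # Column scaling for conditioning only; posterior is mapped back.
        scale = np.sqrt(np.mean(self._design**2, axis=0))
        scale[scale == 0] = 1.0
        self._col_scale = scale

    @property
    def nobs(self) -> int:
        return len(self._y)

    def fit(self, n_samples: int = 1000, seed: int = 0) -> "CubicTailResults":
        """Draw ``n_samples`` exact joint posterior samples.

        Deterministic given ``seed``. Raises on a rank-deficient design
        (e.g. fewer distinct temperatures than parameters).
        """
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        X = self._design / self._col_scale
        y = self._y
        n = len(y)
        if self.weighted and self.data.weights is not None:
            w = np.sqrt(np.asarray(self.data.weights, dtype=float))
            X = X * w[:, None]
            y = y * w

        prior = self.prior
        m0 = prior.coef_mean * self._col_scale
        if prior.coef_sd is None:
            v0inv = np.zeros(N_COEF)
        else:
            sd_scaled = prior.coef_sd * self._col_scale
            v0inv = 1.0 / sd_scaled**2

        xtx = X.T @ X
        prec = xtx + np.diag(v0inv)
        try:
            cf = cho_factor(prec)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError(
                f"region {self.data.region_id!r} {self.data.tail} tail: "
                "rank-deficient design matrix"
            ) from exc
        # Cholesky also fails silently on near-singular matrices only via
        # huge condition numbers; check rank explicitly.
        if np.linalg.matrix_rank(X) < N_COEF:
            raise ValueError(
                f"region {self.data.region_id!r} {self.data.tail} tail: "
                "design matrix not full rank (too few distinct temperatures)"
            )
        rhs = X.T @ y + v0inv * m0
        mn = cho_solve(cf, rhs)

        a_n = prior.sigma_shape + 0.5 * n
        ssq = float(y @ y + m0 @ (v0inv * m0) - mn @ (prec @ mn))
        b_n = prior.sigma_scale + 0.5 * max(ssq, 0.0)
        if b_n <= 0:
            # Degenerate exact-fit data under a fully flat prior.
            b_n = np.finfo(float).tiny

        rng = np.random.default_rng(seed)
        sigma2 = b_n / rng.gamma(shape=a_n, scale=1.0, size=n_samples)
        sigma = np.sqrt(sigma2)
        # beta | sigma^2 ~ N(mn, sigma^2 * prec^{-1})
        l_cov = cholesky(np.linalg.inv(prec), lower=True)
        z = rng.standard_normal((n_samples, N_COEF))
        coefs = mn[None, :] + sigma[:, None] * (z @ l_cov.T)
        coefs = coefs / self._col_scale[None, :]  # back to natural units

        draws = PosteriorDraws(
            region_id=self.data.region_id,
            tail=self.data.tail,
            alpha=coefs[:, 0],
            beta1=coefs[:, 1],
            beta2=coefs[:, 2],
            beta3=coefs[:, 3],
            sigma=sigma,
            centering=self.centering,
            seed=seed,
        )
        return CubicTailResults(self, draws)


class CubicTailResults:
    """Posterior of one tail fit: draws, summaries and curve prediction."""

    def __init__(self, model: BayesianCubicTailModel, draws: PosteriorDraws) -> None:
        self.model = model
        self.draws = draws

    PARAM_NAMES = ("alpha", "beta1", "beta2", "beta3", "sigma")

    @property
    def params(self) -> pd.Series:
        """Posterior means."""
        return pd.Series(
            {p: float(np.mean(getattr(self.draws, p))) for p in self.PARAM_NAMES}
        )

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Equal-tailed posterior credible intervals."""
        lo = (1 - level) / 2
        rows = {}
        for p in self.PARAM_NAMES:
            v = getattr(self.draws, p)
            rows[p] = [float(np.quantile(v, lo)), float(np.quantile(v, 1 - lo))]
        return pd.DataFrame(rows, index=["lower", "upper"]).T

    def predict(self, x_grid) -> CurvePrediction:
        """Posterior curve (log rate) on a temperature grid; see
        :func:`predict_mean_curve`."""
        return predict_mean_curve(self.draws, x_grid, fitted_range=(
            float(self.model._x.min()), float(self.model._x.max())
        ))

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Bayesian cubic tail model — region {self.draws.region_id}, "
            f"{self.draws.tail} tail",
            f"n intervals: {self.model.nobs}   posterior draws: "
            f"{self.draws.n_samples}   centering: {self.draws.centering:.3f} degC",
            f"{'param':>6} {'mean':>12} {'sd':>12} {'2.5%':>12} {'97.5%':>12}",
        ]
        for p in self.PARAM_NAMES:
            v = getattr(self.draws, p)
            lines.append(
                f"{p:>6} {np.mean(v):>12.5g} {np.std(v):>12.5g} "
                f"{ci.loc[p, 'lower']:>12.5g} {ci.loc[p, 'upper']:>12.5g}"
            )
        return "\n".join(lines)


def fit_tail(
    data: TailDataset,
    centering: float,
    prior: PriorSpec | None = None,
    n_samples: int = 1000,
    seed: int = 0,
    weighted: bool = False,
) -> PosteriorDraws:
    """Fit one tail and return its posterior draws (functional shorthand)."""
    model = BayesianCubicTailModel(data, centering=centering, prior=prior,
                                   weighted=weighted)
    return model.fit(n_samples=n_samples, seed=seed).draws


def predict_mean_curve(
    draws: PosteriorDraws,
    x_grid,
    fitted_range: tuple[float, float] | None = None,
) -> CurvePrediction:
    """Per-draw log-rate curves on a grid plus mean and 95% band.

    Grid points outside ``fitted_range`` are permitted but flagged in
    ``extrapolated`` (and trigger a warning): a cubic is untrustworthy
    beyond the temperatures that informed it.
    """
    x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
    if x_grid.size == 0:
        raise ValueError("empty prediction grid")
    mat = draws.polyval(x_grid)
    if fitted_range is not None:
        extrapolated = (x_grid < fitted_range[0]) | (x_grid > fitted_range[1])
        if extrapolated.any():
            warnings.warn(
                f"region {draws.region_id!r} {draws.tail} tail: "
                f"{int(extrapolated.sum())} grid point(s) outside the fitted "
                f"range {fitted_range}; extrapolating the cubic",
                stacklevel=2,
            )
    else:
        extrapolated = np.zeros(x_grid.shape, dtype=bool)
    return CurvePrediction(
        x_grid=x_grid,
        draws=mat,
        mean=mat.mean(axis=0),
        q025=np.quantile(mat, 0.025, axis=0),
        q975=np.quantile(mat, 0.975, axis=0),
        extrapolated=extrapolated,
    )
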