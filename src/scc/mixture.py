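"""Three-component mixture model for one gene's values across neighbor cells.

The density is

    f(x) = lam1 * Normal(x; mu, sigma) + lam2 * Binomial(round(x); N, p)
           + lam3 * 1{x == 0},

with lam1 + lam2 + lam3 = 1. The Normal component carries genuinely
high-expression genes, the Binomial component low-expression genes whose
zeros are capture failures (p is the per-molecule detection probability,
N the total transcript count, constrained to 1..9), and the point mass at
zero carries truly silent genes. Parameters are estimated by EM; the
dominant weight then classifies the query cell's observed value as
keep / impute-N*p / true zero.

Two surfaces are provided: a vectorized kernel (`batch_fit`, one EM over a
genes x neighbors value matrix — the workhorse of the imputer) and a
statsmodels-style pair `DropoutMixture` / `MixtureFitResult` for fitting
and inspecting a single gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import gammaln

__all__ = [
    "MixtureParams",
    "EMConfig",
    "BatchParams",
    "mixture_density",
    "em_init",
    "em_estep",
    "em_mstep",
    "fit_mixture",
    "batch_fit",
    "DropoutMixture",
    "MixtureFitResult",
]


@dataclass
class EMConfig:
    """EM controls: 100 iterations max, stop when no tracked parameter
    (lambdas, mu, sigma, p; N is integer-valued and excluded) moves by
    more than ``tol``. Floors keep the Normal sd and detection
    probability away from degenerate values."""

    max_iter: int = 100
    tol: float = 0.01
    # sigma_floor keeps the Normal peak density below the zero point mass
    # (1/(sqrt(2*pi)*0.5) ~= 0.80 < 1); with a smaller floor the Normal
    # collapses onto the zero spike and claims the zeros it is not meant for.
    sigma_floor: float = 0.5
    p_floor: float = 0.01
    zero_tol: float = 1e-8
    component_eps: float = 1e-300
    weight_eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        for name in ("tol", "sigma_floor", "p_floor", "zero_tol", "component_eps", "weight_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MixtureParams:
    """Weights and component parameters of one fitted mixture."""

    lambda1: float
    lambda2: float
    lambda3: float
    mu: float
    sigma: float
    N: int
    p: float

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])

    def validate(self) -> None:
        if abs(self.lambda1 + self.lambda2 + self.lambda3 - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if min(self.lambda1, self.lambda2, self.lambda3) < -1e-12:
            raise ValueError("mixture weights must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie in (0, 1)")
        if not (1 <= int(self.N) <= 9):
            raise ValueError("N must be an integer in [1, 9]")


@dataclass
class BatchParams:
    """Per-gene parameter arrays for a batch of mixtures (shape (G,) each;
    ``lam`` is (G, 3))."""

    lam: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    N: np.ndarray
    p: np.ndarray

    def row(self, g: int) -> MixtureParams:
        return MixtureParams(
            lambda1=float(self.lam[g, 0]),
            lambda2=float(self.lam[g, 1]),
            lambda3=float(self.lam[g, 2]),
            mu=float(self.mu[g]),
            sigma=float(self.sigma[g]),
            N=int(self.N[g]),
            p=float(self.p[g]),
        )

    def copy(self) -> "BatchParams":
        return BatchParams(self.lam.copy(), self.mu.copy(), self.sigma.copy(), self.N.copy(), self.p.copy())


# ---------------------------------------------------------------------------
# densities


def _normal_pdf(x, mu, sigma):
    z = (x - mu) / sigma
    return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sigma)


def _binom_pmf(x, N, p):
    """pmf of Binomial(N, p) evaluated at round(x); 0 outside [0, N]."""
    k = np.rint(x)
    valid = (k >= 0) & (k <= N)
    ks = np.where(valid, k, 0.0)
    logpmf = (
        gammaln(N + 1.0)
        - gammaln(ks + 1.0)
        - gammaln(N - ks + 1.0)
        + ks * np.log(p)
        + (N - ks) * np.log1p(-p)
    )
    return np.where(valid, np.exp(logpmf), 0.0)


def mixture_density(x, params: MixtureParams, zero_tol: float = 1e-8):
    """Evaluate the three-component mixture density/mass at ``x``.

    The zero component is a point mass contributing only at x = 0 (within
    ``zero_tol``).
    """
    params.validate()
    x = np.asarray(x, dtype=float)
    f = (
        params.lambda1 * _normal_pdf(x, params.mu, params.sigma)
        + params.lambda2 * _binom_pmf(x, params.N, params.p)
        + params.lambda3 * (np.abs(x) <= zero_tol)
    )
    return float(f) if f.ndim == 0 else f


# ---------------------------------------------------------------------------
# batch EM kernel (G mixtures fitted simultaneously on a (G, n) value array)


def _batch_init(Z: np.ndarray, cfg: EMConfig) -> BatchParams:
    G, n = Z.shape
    mu = Z.mean(axis=1)
    sd = Z.std(axis=1, ddof=1)
    sigma = np.maximum(sd, cfg.sigma_floor)
    p = np.full(G, 0.1)
    nz_count = (Z > 0).sum(axis=1)
    nz_mean = np.where(nz_count > 0, Z.sum(axis=1) / np.maximum(nz_count, 1), 0.0)
    N = np.where(nz_count > 0, np.clip(np.rint(nz_mean / 0.1), 1, 9), 1.0)
    lam = np.full((G, 3), 1.0 / 3.0)
    return BatchParams(lam=lam, mu=mu, sigma=sigma, N=N.astype(float), p=p)


def _batch_estep(Z: np.ndarray, params: BatchParams, cfg: EMConfig) -> np.ndarray:
    """Responsibilities, shape (G, n, 3): lam_j * f_j(x) + eps, row-normalized."""
    f1 = _normal_pdf(Z, params.mu[:, None], params.sigma[:, None])
    f2 = _binom_pmf(Z, params.N[:, None], params.p[:, None])
    f3 = (np.abs(Z) <= cfg.zero_tol).astype(float)
    r = np.stack(
        [params.lam[:, 0, None] * f1, params.lam[:, 1, None] * f2, params.lam[:, 2, None] * f3],
        axis=2,
    )
    r += cfg.component_eps
    r /= r.sum(axis=2, keepdims=True)
    return r


def _batch_mstep(Z: np.ndarray, resp: np.ndarray, params: BatchParams, cfg: EMConfig) -> BatchParams:
    """Closed-form updates from the component-wise weighted moments.

    For each component j: P1 = sum_i Pro[i,j], lam_j = P1 / n,
    Mean_j = P2 / P1 with P2 = sum_i Pro[i,j] * x_i, and
    Dev_j = sqrt(P3 / P1) with P3 = sum_i Pro[i,j] * (x_i - Mean_j)^2.
    The Normal takes (Mean_1, Dev_1) directly; the Binomial recovers
    (N, p) from (Mean_2, Dev_2) by the method of moments with N clamped to
    1..9 and p re-solved from the mean so the component mean survives the
    integer rounding. A component with negligible total responsibility
    keeps its previous parameters.
    """
    G, n = Z.shape
    P1 = resp.sum(axis=1)  # (G, 3)
    lam = P1 / n
    P2 = np.einsum("gnj,gn->gj", resp, Z)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(P1 > 0, P2 / np.maximum(P1, cfg.weight_eps), 0.0)
    dev2 = np.empty((G, 2))
    for j in range(2):  # Dev only needed for Normal and Binomial components
        P3 = (resp[:, :, j] * (Z - mean[:, j, None]) ** 2).sum(axis=1)
        dev2[:, j] = P3 / np.maximum(P1[:, j], cfg.weight_eps)

    new = params.copy()
    new.lam = lam

    ok1 = P1[:, 0] >= cfg.weight_eps
    new.mu = np.where(ok1, mean[:, 0], params.mu)
    new.sigma = np.where(ok1, np.maximum(np.sqrt(dev2[:, 0]), cfg.sigma_floor), params.sigma)

    ok2 = (P1[:, 1] >= cfg.weight_eps) & (mean[:, 1] > 0)
    m2 = np.where(ok2, mean[:, 1], 1.0)  # placeholder where not updated
    p_mm = np.clip(1.0 - dev2[:, 1] / m2, cfg.p_floor, 1.0 - cfg.p_floor)
    N_new = np.clip(np.rint(m2 / p_mm), 1, 9)
    p_new = np.clip(m2 / N_new, cfg.p_floor, 1.0 - cfg.p_floor)
    new.N = np.where(ok2, N_new, params.N)
    new.p = np.where(ok2, p_new, params.p)
    return new


def batch_fit(Z: np.ndarray, cfg: EMConfig | None = None) -> tuple[BatchParams, np.ndarray, np.ndarray]:
    """Fit G mixtures at once on a (G, n) value matrix.

    Returns ``(params, n_iter, converged)`` where ``n_iter`` counts E+M
    sweeps per gene and ``converged`` marks genes whose tracked-parameter
    change fell below ``cfg.tol``. Genes that converge drop out of the
    active set, so mixed batches stay cheap.
    """
    cfg = cfg or EMConfig()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 2:
        raise ValueError("need a (G, n) value matrix with n >= 2")
    G = Z.shape[0]
    params = _batch_init(Z, cfg)
    n_iter = np.zeros(G, dtype=int)
    converged = np.zeros(G, dtype=bool)
    active = np.arange(G)
    for _ in range(cfg.max_iter):
        if active.size == 0:
            break
        sub = BatchParams(
            params.lam[active], params.mu[active], params.sigma[active], params.N[active], params.p[active]
        )
        resp = _batch_estep(Z[active], sub, cfg)
        new = _batch_mstep(Z[active], resp, sub, cfg)
        delta = np.max(
            np.stack(
                [
                    np.abs(new.lam - sub.lam).max(axis=1),
                    np.abs(new.mu - sub.mu),
                    np.abs(new.sigma - sub.sigma),
                    np.abs(new.p - sub.p),
                ]
            ),
            axis=0,
        )
        params.lam[active] = new.lam
        params.mu[active] = new.mu
        params.sigma[active] = new.sigma
        params.N[active] = new.N
        params.p[active] = new.p
        n_iter[active] += 1
        done = delta < cfg.tol
        converged[active[done]] = True
        active = active[~done]
    return params, n_iter, converged


# ---------------------------------------------------------------------------
# scalar API (single gene)


def em_init(values, cfg: EMConfig | None = None) -> MixtureParams:
    """Initial parameters: mu/sigma from the neighbor values, p = 0.1
    (detection rates run 5-15%), N from the nonzero mean at that rate,
    equal weights of one third."""
    cfg = cfg or EMConfig()
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two neighbor values")
    return _batch_init(values[None, :], cfg).row(0)


def em_estep(values, params: MixtureParams, cfg: EMConfig | None = None) -> np.ndarray:
    """Posterior component responsibilities, shape (n, 3), rows sum to 1."""
    cfg = cfg or EMConfig()
    params.validate()
    values = np.asarray(values, dtype=float)
    bp = BatchParams(
        lam=params.weights[None, :],
        mu=np.array([params.mu]),
        sigma=np.array([params.sigma]),
        N=np.array([float(params.N)]),
        p=np.array([params.p]),
    )
    return _batch_estep(values[None, :], bp, cfg)[0]


def em_mstep(
    values, resp: np.ndarray, params: MixtureParams | None = None, cfg: EMConfig | None = None
) -> MixtureParams:
    """One M step from responsibilities; ``params`` supplies carry-over
    values for components with no responsibility mass."""
    cfg = cfg or EMConfig()
    values = np.asarray(values, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if resp.shape != (values.size, 3):
        raise ValueError("responsibilities must have shape (n, 3)")
    if params is None:
        params = em_init(values, cfg)
    bp = BatchParams(
        lam=params.weights[None, :],
        mu=np.array([params.mu]),
        sigma=np.array([params.sigma]),
        N=np.array([float(params.N)]),
        p=np.array([params.p]),
    )
    return _batch_mstep(values[None, :], resp[None, :, :], bp, cfg).row(0)


def fit_mixture(values, cfg: EMConfig | None = None) -> tuple[MixtureParams, int, bool]:
    """Fit one mixture by EM; returns (params, iterations, converged)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two neighbor values")
    params, n_iter, converged = batch_fit(values[None, :], cfg)
    return params.row(0), int(n_iter[0]), bool(converged[0])


# ---------------------------------------------------------------------------
# model / results objects


class DropoutMixture:
    """Mixture model for one gene's expression across a cell's neighbors.

    Parameters
    ----------
    endog : array-like
        Nonnegative expression values of one gene in the neighbor cells.

    Examples
    --------
    >>> res = DropoutMixture([0, 0, 1, 2, 0, 1]).fit()
    >>> res.dominant_component in (0, 1, 2)
    True
    """

    def __init__(self, endog):
        self.endog = np.asarray(endog, dtype=float).ravel()
        if self.endog.size < 2:
            raise ValueError("need at least two neighbor values")
        if np.any(self.endog < 0) or not np.all(np.isfinite(self.endog)):
            raise ValueError("values must be nonnegative and finite")
        self.nobs = self.endog.size

    def fit(self, config: EMConfig | None = None) -> "MixtureFitResult":
        cfg = config or EMConfig()
        params, n_iter, converged = fit_mixture(self.endog, cfg)
        resp = em_estep(self.endog, params, cfg)
        return MixtureFitResult(self, params, cfg, n_iter, converged, resp)

    def density(self, x, params: MixtureParams, zero_tol: float = 1e-8):
        return mixture_density(x, params, zero_tol=zero_tol)


@dataclass
class MixtureFitResult:
    """Fitted mixture: parameters, responsibilities and diagnostics."""

    model: DropoutMixture
    params: MixtureParams
    config: EMConfig
    n_iter: int
    converged: bool
    responsibilities: np.ndarray = field(repr=False, default=None)

    @property
    def dominant_component(self) -> int:
        """0 = Normal (high expression), 1 = Binomial (dropout-prone low
        expression), 2 = zero point mass; ties go to the lower index."""
        return int(np.argmax(self.params.weights))

    @property
    def imputed_value(self) -> float:
        """Expectation N*p of the Binomial component."""
        return float(self.params.N * self.params.p)

    def predict_density(self, x):
        return mixture_density(x, self.params, zero_tol=self.config.zero_tol)

    def summary(self) -> str:
        p = self.params
        comp = ["Normal (high expression)", "Binomial (dropout)", "Zero point mass"][
            self.dominant_component
        ]
        lines = [
            "Dropout mixture fit",
            "=" * 46,
            f"n neighbors        {self.model.nobs:>10d}",
            f"iterations         {self.n_iter:>10d}   converged: {self.converged}",
            f"lambda1 (Normal)   {p.lambda1:>10.4f}",
            f"lambda2 (Binomial) {p.lambda2:>10.4f}",
            f"lambda3 (zero)     {p.lambda3:>10.4f}",
            f"mu                 {p.mu:>10.4f}",
            f"sigma              {p.sigma:>10.4f}",
            f"N                  {p.N:>10d}",
            f"p                  {p.p:>10.4f}",
            f"N*p (imputation)   {self.imputed_value:>10.4f}",
            f"dominant component {comp}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = asdict(self.params)
        d.update(n_iter=self.n_iter, converged=self.converged)
        return d
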