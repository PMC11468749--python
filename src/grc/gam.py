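"""Generalized additive (mixed) models for compression-ratio regression.

The scientific design: a genome's compression ratio is regressed on
smooth functions of AT content, (log) genome size and OUV, with genus as
a grouped random effect — a random slope of genome size, optionally a
random intercept — so that phylogenetically clustered genomes do not
masquerade as independent evidence.  Models are compared with AIC from
maximum-likelihood fits; final reported fits use REML.

Implementation: penalized cubic regression splines (B-spline basis,
knots at covariate quantiles, second-derivative roughness penalty,
sum-to-zero constraint absorbed by reparameterization).  Random effects
are realized through the standard penalized-regression equivalence: the
per-genus slope (and intercept) columns form a block with a shared ridge
penalty whose smoothing parameter is estimated together with the spline
penalties by minimizing the marginal ML or REML criterion of the
Gaussian model.  Effective degrees of freedom (edf) are traces of the
influence decomposition, AIC is the conditional Gaussian log-likelihood
penalized by edf, and per-smooth p-values are approximate Wald tests.

Usage follows the statsmodels convention::

    model = CompressibilityGAM.from_dataframe(df, spec)
    res = model.fit()            # GAMResults
    print(res.summary())
    curve = res.partial_effect("ouv")
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.interpolate import BSpline

__all__ = [
    "SmoothTerm",
    "RandomEffect",
    "ModelSpec",
    "CubicSplineBasis",
    "CompressibilityGAM",
    "GAMResults",
    "ModelComparison",
    "build_smooth_basis",
    "fit_gam",
    "compare_models",
    "fit_difference_model",
]

_LOG2PI = np.log(2.0 * np.pi)


class GAMError(ValueError):
    pass


@dataclass(frozen=True)
class SmoothTerm:
    covariate: str
    basis_dim: int = 10

    def __post_init__(self):
        if self.basis_dim < 4:
            raise GAMError("basis_dim must be >= 4 for a cubic spline basis")


@dataclass(frozen=True)
class RandomEffect:
    """Grouped random effect: per-group slope in ``slope_covariate`` (z-scored
    internally), optionally a per-group intercept, each with its own shared
    ridge penalty."""

    group: str
    slope_covariate: str | None = None
    include_intercept: bool = False

    def __post_init__(self):
        if self.slope_covariate is None and not self.include_intercept:
            raise GAMError("random effect needs a slope covariate or an intercept")


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    smooth_terms: tuple[SmoothTerm, ...] = ()
    linear_terms: tuple[str, ...] = ()
    random_effect: RandomEffect | None = None
    estimation: str = "REML"

    def __post_init__(self):
        smooths = tuple(
            SmoothTerm(t) if isinstance(t, str) else t for t in self.smooth_terms
        )
        object.__setattr__(self, "smooth_terms", smooths)
        object.__setattr__(self, "linear_terms", tuple(self.linear_terms))
        covs = [t.covariate for t in smooths] + list(self.linear_terms)
        if self.outcome in covs:
            raise GAMError("outcome must not appear among covariates")
        if len(set(covs)) != len(covs):
            raise GAMError("duplicate covariate in model spec")
        if self.estimation not in ("ML", "REML"):
            raise GAMError("estimation must be 'ML' or 'REML'")


# --- spline basis -----------------------------------------------------------


class CubicSplineBasis:
    """Penalized cubic regression spline basis for one covariate.

    ``basis_dim`` B-spline columns (cubic, interior knots at quantiles of
    the training values) with the integrated-squared-second-derivative
    penalty; a sum-to-zero constraint over the training points is absorbed
    by an orthonormal reparameterization, leaving ``basis_dim - 1``
    identifiable columns whose fitted curve is centered.
    """

    def __init__(self, x: np.ndarray, basis_dim: int = 10):
        x = np.asarray(x, dtype=float)
        if np.unique(x).size < basis_dim:
            raise GAMError(
                f"need >= {basis_dim} distinct covariate values, "
                f"got {np.unique(x).size}"
            )
        self.basis_dim = basis_dim
        self.xmin, self.xmax = float(x.min()), float(x.max())
        n_interior = basis_dim - 4
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(np.unique(x), qs)
        else:
            interior = np.array([])
        self.knots = np.concatenate(
            [[self.xmin] * 4, interior, [self.xmax] * 4]
        )
        self._penalty_raw = self._second_derivative_gram()
        F = self._raw_design(x)
        # null space of the sum-to-zero constraint 1'Fb = 0
        c = F.sum(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(c)
        self.Z = vt[1:].T  # basis_dim x (basis_dim - 1), orthonormal
        penalty = self.Z.T @ self._penalty_raw @ self.Z
        # normalize the penalty so smoothing parameters are scale-free
        # (the raw second-derivative Gram varies as 1/range(x)^3)
        norm = np.abs(penalty).max()
        self.penalty = penalty / norm if norm > 0 else penalty
        self.design_train = F @ self.Z

    def _second_derivative_gram(self) -> np.ndarray:
        t, k = self.knots, 3
        nb = self.basis_dim
        edges = np.unique(t)
        # 2-point Gauss-Legendre per knot span: exact for the piecewise
        # quadratic integrand (product of two piecewise-linear 2nd derivs)
        offs = 0.5 / np.sqrt(3.0)
        pts, wts = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            mid, half = 0.5 * (a + b), 0.5 * (b - a)
            pts += [mid - 2 * half * offs, mid + 2 * half * offs]
            wts += [half, half]
        pts = np.array(pts)
        d2 = BSpline(t, np.eye(nb), k).derivative(2)(pts)
        return (d2 * np.array(wts)[:, None]).T @ d2

    def _raw_design(self, x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, self.xmin, self.xmax)
        return BSpline.design_matrix(xc, self.knots, 3).toarray()

    def design(self, x: np.ndarray) -> np.ndarray:
        """Centered design at new points (values clamped to training range)."""
        return self._raw_design(np.asarray(x, dtype=float)) @ self.Z

    def extrapolated(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x < self.xmin) | (x > self.xmax)


def build_smooth_basis(x: np.ndarray, basis_dim: int = 10) -> CubicSplineBasis:
    """Build a penalized, centered cubic regression spline basis."""
    return CubicSplineBasis(np.asarray(x, dtype=float), basis_dim)


# --- model ------------------------------------------------------------------


@dataclass
class _Block:
    kind: str  # intercept | linear | smooth | random_intercept | random_slope
    name: str
    sl: slice
    penalty: np.ndarray | None = None  # within-block penalty, None = unpenalized
    basis: CubicSplineBasis | None = None


class CompressibilityGAM:
    """Gaussian additive mixed model for genome compressibility.

    Built from an analysis table (one row per genome) and a
    :class:`ModelSpec`; ``fit()`` selects all smoothing parameters —
    spline penalties and random-effect ridges — by the spec's marginal
    criterion and returns a :class:`GAMResults`.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        self.data = data
        cols = [spec.outcome] + [t.covariate for t in spec.smooth_terms]
        cols += list(spec.linear_terms)
        if spec.random_effect is not None:
            cols.append(spec.random_effect.group)
            if spec.random_effect.slope_covariate is not None:
                cols.append(spec.random_effect.slope_covariate)
        missing = [c for c in dict.fromkeys(cols) if c not in data.columns]
        if missing:
            raise GAMError(f"missing column(s): {missing}")
        sub = data[list(dict.fromkeys(cols))]
        numeric = sub.drop(
            columns=[spec.random_effect.group] if spec.random_effect else []
        )
        if numeric.isna().any().any():
            bad = numeric.columns[numeric.isna().any()].tolist()
            raise GAMError(
                f"missing values in column(s) {bad}; complete cases required"
            )
        self.y = data[spec.outcome].to_numpy(dtype=float)
        self.nobs = len(self.y)
        self._build_design()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec) -> "CompressibilityGAM":
        return cls(data, spec)

    def _build_design(self) -> None:
        spec, data, n = self.spec, self.data, self.nobs
        cols: list[np.ndarray] = [np.ones((n, 1))]
        blocks: list[_Block] = [_Block("intercept", "intercept", slice(0, 1))]
        p = 1
        for name in spec.linear_terms:
            cols.append(data[name].to_numpy(dtype=float).reshape(-1, 1))
            blocks.append(_Block("linear", name, slice(p, p + 1)))
            p += 1
        for term in spec.smooth_terms:
            basis = CubicSplineBasis(
                data[term.covariate].to_numpy(dtype=float), term.basis_dim
            )
            X = basis.design_train
            blocks.append(
                _Block(
                    "smooth",
                    term.covariate,
                    slice(p, p + X.shape[1]),
                    penalty=basis.penalty,
                    basis=basis,
                )
            )
            cols.append(X)
            p += X.shape[1]
        self.group_levels: list[str] = []
        if spec.random_effect is not None:
            re = spec.random_effect
            groups = data[re.group].astype(str)
            self.group_levels = sorted(groups.unique())
            if len(self.group_levels) < 2:
                raise GAMError("random effect needs >= 2 groups")
            dummies = (
                groups.to_numpy()[:, None] == np.array(self.group_levels)[None, :]
            ).astype(float)
            if re.include_intercept:
                G = dummies.shape[1]
                blocks.append(
                    _Block(
                        "random_intercept",
                        f"{re.group} (intercept)",
                        slice(p, p + G),
                        penalty=np.eye(G),
                    )
                )
                cols.append(dummies)
                p += G
            if re.slope_covariate is not None:
                z = data[re.slope_covariate].to_numpy(dtype=float)
                sd = z.std()
                if sd == 0:
                    raise GAMError("random-slope covariate is constant")
                zstd = (z - z.mean()) / sd
                G = dummies.shape[1]
                blocks.append(
                    _Block(
                        "random_slope",
                        f"{re.group} x {re.slope_covariate}",
                        slice(p, p + G),
                        penalty=np.eye(G),
                    )
                )
                cols.append(dummies * zstd[:, None])
                p += G
        self.X = np.hstack(cols)
        self.blocks = blocks
        self.penalized = [b for b in blocks if b.penalty is not None]
        self.p = p
        if self.p >= self.nobs:
            raise GAMError(
                f"more coefficients ({self.p}) than observations ({self.nobs})"
            )
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        S_total = np.zeros((p, p))
        for b in self.penalized:
            S_total[b.sl, b.sl] += b.penalty / max(1.0, np.abs(b.penalty).max())
        evals, evecs = np.linalg.eigh(S_total)
        keep = evals > 1e-10 * max(evals.max(), 1.0)
        self.V_range = evecs[:, keep]  # orthonormal basis of the penalized space
        self.n_nullspace = int((~keep).sum())

    # -- criterion ----------------------------------------------------------

    def _assemble(self, lam: np.ndarray) -> np.ndarray:
        A = self.XtX.copy()
        for lam_j, b in zip(lam, self.penalized):
            A[b.sl, b.sl] += lam_j * b.penalty
        return A

    def _solve(self, A: np.ndarray) -> np.ndarray:
        try:
            c, low = linalg.cho_factor(A)
            return linalg.cho_solve((c, low), self.Xty)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * (np.trace(A) / self.p + 1.0)
            for _ in range(6):
                try:
                    c, low = linalg.cho_factor(A + jitter * np.eye(self.p))
                    return linalg.cho_solve((c, low), self.Xty)
                except np.linalg.LinAlgError:
                    jitter *= 100.0
            raise GAMError("design is rank deficient; model cannot be fitted")

    def _criterion(self, rho: np.ndarray, method: str) -> float:
        # beyond exp(+-25) the criterion is flat in rho; a tiny quadratic
        # pull-back keeps the simplex from drifting along those directions
        overshoot = np.maximum(0.0, np.abs(rho) - 25.0)
        boundary_nudge = 1e-4 * float(overshoot @ overshoot)
        lam = np.exp(np.clip(rho, -25.0, 25.0))
        A = self._assemble(lam)
        theta = self._solve(A)
        rss = max(self.yty - 2 * theta @ self.Xty + theta @ (self.XtX @ theta), 0.0)
        pen = sum(
            lam_j * float(theta[b.sl] @ b.penalty @ theta[b.sl])
            for lam_j, b in zip(lam, self.penalized)
        )
        n, M = self.nobs, self.n_nullspace
        floor = 1e-12 * (self.yty / n + 1.0)
        S_lam = np.zeros((self.p, self.p))
        for lam_j, b in zip(lam, self.penalized):
            S_lam[b.sl, b.sl] += lam_j * b.penalty
        V = self.V_range
        if method == "REML":
            sig2 = max((rss + pen) / (n - M), floor)
            score = (n - M) * (_LOG2PI + np.log(sig2) + 1.0)
            score += np.linalg.slogdet(A)[1]
            if V.shape[1]:
                score -= np.linalg.slogdet(V.T @ S_lam @ V)[1]
        else:  # ML
            sig2 = max((rss + pen) / n, floor)
            score = n * (_LOG2PI + np.log(sig2) + 1.0)
            if V.shape[1]:
                score += np.linalg.slogdet(V.T @ A @ V)[1]
                score -= np.linalg.slogdet(V.T @ S_lam @ V)[1]
        if not np.isfinite(score):
            return 1e30
        return float(score) + boundary_nudge

    def fit(self, method: str | None = None, maxiter: int = 500) -> "GAMResults":
        """Select smoothing parameters by the marginal criterion and fit.

        ``method`` overrides the spec's estimation ("ML" or "REML").
        """
        method = method or self.spec.estimation
        if method not in ("ML", "REML"):
            raise GAMError("method must be 'ML' or 'REML'")
        n_pen = len(self.penalized)
        if n_pen:
            x0 = np.zeros(n_pen)
            res = optimize.minimize(
                self._criterion,
                x0,
                args=(method,),
                method="Nelder-Mead",
                options={
                    "maxiter": maxiter * max(1, n_pen),
                    "maxfev": maxiter * max(1, n_pen),
                    # rho precision of 0.05 bounds lambda error at ~5%, far
                    # below the sampling noise of any edf or AIC reported
                    "xatol": 5e-2,
                    "fatol": 1e-6,
                },
            )
            rho = np.clip(res.x, -25.0, 25.0)
            converged = bool(res.success)
            score = float(res.fun)
        else:
            rho = np.zeros(0)
            converged = True
            score = self._criterion(rho, method)
        lam = np.exp(rho)
        A = self._assemble(lam)
        theta = self._solve(A)
        Ainv = np.linalg.inv(A)
        B = Ainv @ self.XtX
        edf_by_term = {
            b.name: float(np.trace(B[b.sl, b.sl])) for b in self.blocks
        }
        edf_total = float(np.trace(B))
        fitted = self.X @ theta
        rss = float(np.sum((self.y - fitted) ** 2))
        resid_df = max(self.nobs - edf_total, 1.0)
        scale = rss / resid_df
        cov = scale * Ainv  # Bayesian posterior covariance
        sig2_ml = max(rss / self.nobs, 1e-300)
        aic = self.nobs * (_LOG2PI + np.log(sig2_ml) + 1.0) + 2.0 * (edf_total + 1.0)
        random_variances = {
            b.name: scale / lam_j
            for lam_j, b in zip(lam, self.penalized)
            if b.kind in ("random_intercept", "random_slope")
        }
        return GAMResults(
            model=self,
            method=method,
            params=theta,
            cov_params=cov,
            lambdas={b.name: float(l) for l, b in zip(lam, self.penalized)},
            edf_by_term=edf_by_term,
            edf_total=edf_total,
            rss=rss,
            scale=scale,
            score=score,
            aic=float(aic),
            random_variances=random_variances,
            fitted_values=fitted,
            converged=converged,
        )


# --- results ----------------------------------------------------------------


@dataclass
class GAMResults:
    """Fit results: estimates, uncertainties, diagnostics and summaries."""

    model: CompressibilityGAM
    method: str
    params: np.ndarray
    cov_params: np.ndarray
    lambdas: dict[str, float]
    edf_by_term: dict[str, float]
    edf_total: float
    rss: float
    scale: float
    score: float  # the minimized -2 marginal (ML or REML) criterion
    aic: float
    random_variances: dict[str, float]
    fitted_values: np.ndarray
    converged: bool
    _term_tests: dict | None = field(default=None, repr=False)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def reml_score(self) -> float | None:
        return self.score if self.method == "REML" else None

    @property
    def deviance(self) -> float:
        return self.rss

    def _block(self, name: str) -> _Block:
        for b in self.model.blocks:
            if b.name == name:
                return b
        raise GAMError(f"unknown term {name!r}")

    def coefficient(self, name: str) -> float:
        """Coefficient of the intercept or a linear term."""
        b = self._block(name)
        if b.kind not in ("intercept", "linear"):
            raise GAMError(f"{name!r} is not a parametric term")
        return float(self.params[b.sl][0])

    def coefficient_se(self, name: str) -> float:
        b = self._block(name)
        return float(np.sqrt(self.cov_params[b.sl, b.sl][0, 0]))

    def term_test(self, name: str) -> tuple[float, float, float]:
        """(statistic, edf, p) — Wald test of a smooth/random term, z-test of
        a linear term.  P-values are approximate."""
        b = self._block(name)
        beta = self.params[b.sl]
        Vb = self.cov_params[b.sl, b.sl]
        if b.kind in ("intercept", "linear"):
            z = beta[0] / np.sqrt(Vb[0, 0])
            return float(z), 1.0, float(2.0 * stats.norm.sf(abs(z)))
        edf = max(self.edf_by_term[name], 1e-8)
        rank = max(1, int(np.ceil(edf - 1e-8)))
        stat = float(beta @ np.linalg.pinv(Vb, rcond=1e-10) @ beta)
        # rank-limited pseudo-inverse when the smooth is heavily penalized
        if rank < len(beta):
            evals, evecs = np.linalg.eigh(Vb)
            idx = np.argsort(evals)[::-1][:rank]
            proj = evecs[:, idx]
            stat = float(
                (proj.T @ beta)
                @ np.linalg.solve(proj.T @ Vb @ proj, proj.T @ beta)
            )
        return stat, edf, float(stats.chi2.sf(stat, edf))

    def partial_effect(
        self, term: str, grid: np.ndarray | None = None, n_grid: int = 100
    ) -> pd.DataFrame:
        """Centered partial effect of one term on a grid, with +-2 SE bands.

        Grid values outside the training range are flagged ``extrapolated``
        (spline values are clamped to the boundary there).
        """
        b = self._block(term)
        if b.kind == "smooth":
            basis = b.basis
            if grid is None:
                grid = np.linspace(basis.xmin, basis.xmax, n_grid)
            grid = np.asarray(grid, dtype=float)
            D = basis.design(grid)
            est = D @ self.params[b.sl]
            se = np.sqrt(
                np.maximum(np.einsum("ij,jk,ik->i", D, self.cov_params[b.sl, b.sl], D), 0)
            )
            extrap = basis.extrapolated(grid)
        elif b.kind == "linear":
            x = self.model.data[term].to_numpy(dtype=float)
            if grid is None:
                grid = np.linspace(x.min(), x.max(), n_grid)
            grid = np.asarray(grid, dtype=float)
            coef = self.params[b.sl][0]
            centered = grid - x.mean()
            est = coef * centered
            se = np.abs(centered) * np.sqrt(self.cov_params[b.sl, b.sl][0, 0])
            extrap = (grid < x.min()) | (grid > x.max())
        else:
            raise GAMError(f"partial effects are defined for smooth/linear terms, "
                           f"not {b.kind!r}")
        return pd.DataFrame(
            {
                "x": grid,
                "effect": est,
                "se": se,
                "lower": est - 2 * se,
                "upper": est + 2 * se,
                "extrapolated": extrap,
            }
        )

    def summary(self) -> str:
        lines = [
            "Compressibility GAM results",
            "=" * 64,
            f"outcome: {self.model.spec.outcome:<24s} n_obs: {self.nobs}",
            f"estimation: {self.method:<21s} converged: {self.converged}",
            f"AIC (conditional, edf-penalized): {self.aic:.2f}",
            f"-2 {self.method} criterion: {self.score:.2f}",
            f"scale estimate: {self.scale:.6g}   total edf: {self.edf_total:.2f}",
            "",
            "Parametric terms",
            f"{'term':<28s}{'coef':>12s}{'se':>12s}{'p':>10s}",
        ]
        for b in self.model.blocks:
            if b.kind in ("intercept", "linear"):
                _, _, p = self.term_test(b.name)
                lines.append(
                    f"{b.name:<28s}{self.coefficient(b.name):>12.4g}"
                    f"{self.coefficient_se(b.name):>12.4g}{_fmt_p(p):>10s}"
                )
        smooths = [b for b in self.model.blocks if b.kind == "smooth"]
        if smooths:
            lines += ["", "Smooth terms",
                      f"{'term':<28s}{'edf':>8s}{'chi2':>12s}{'p':>10s}"]
            for b in smooths:
                stat, edf, p = self.term_test(b.name)
                lines.append(
                    f"{'s(' + b.name + ')':<28s}{edf:>8.2f}{stat:>12.3f}{_fmt_p(p):>10s}"
                )
        rand = [b for b in self.model.blocks
                if b.kind in ("random_intercept", "random_slope")]
        if rand:
            lines += ["", "Random effects (variance components)"]
            for b in rand:
                lines.append(
                    f"{b.name:<36s} var={self.random_variances[b.name]:.4g}"
                    f"  edf={self.edf_by_term[b.name]:.2f}"
                )
        return "\n".join(lines)

    def plot_partials(self, path=None):
        """Diagnostic partial-effect panels (one per smooth/linear term)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        terms = [b.name for b in self.model.blocks if b.kind in ("smooth", "linear")]
        if not terms:
            raise GAMError("no smooth or linear terms to plot")
        fig, axes = plt.subplots(1, len(terms), figsize=(4 * len(terms), 3.2))
        axes = np.atleast_1d(axes)
        for ax, term in zip(axes, terms):
            pe = self.partial_effect(term)
            ax.fill_between(pe["x"], pe["lower"], pe["upper"], alpha=0.25)
            ax.plot(pe["x"], pe["effect"])
            ax.set_xlabel(term)
            ax.set_ylabel("partial effect")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _fmt_p(p: float) -> str:
    return "<1e-4" if p < 1e-4 else f"{p:.4f}"


# --- model comparison and convenience wrappers ------------------------------


@dataclass
class ModelComparison:
    """Labeled ML fits and their AIC table; best = minimum AIC."""

    fits: dict[str, GAMResults]
    aic: dict[str, float]
    best: str

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "model": label,
                "aic": self.aic[label],
                "edf": self.fits[label].edf_total,
                "deviance": self.fits[label].deviance,
            }
            for label in self.fits
        ]
        return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)


def fit_gam(data: pd.DataFrame, spec: ModelSpec, method: str | None = None) -> GAMResults:
    """Fit one additive model; see :class:`CompressibilityGAM`."""
    return CompressibilityGAM(data, spec).fit(method=method)


def compare_models(
    data: pd.DataFrame, specs: dict[str, ModelSpec] | Sequence[tuple[str, ModelSpec]]
) -> ModelComparison:
    """Fit every labeled spec by ML on the same rows and rank by AIC."""
    if not isinstance(specs, dict):
        specs = dict(specs)
    if not specs:
        raise GAMError("no model specs given")
    fits = {label: fit_gam(data, spec, method="ML") for label, spec in specs.items()}
    aic = {label: fit.aic for label, fit in fits.items()}
    best = min(aic, key=aic.get)
    return ModelComparison(fits=fits, aic=aic, best=best)


def standard_specs(
    outcome: str,
    smooth_covariates: Sequence[str] = ("at", "log10_size", "ouv"),
    group: str = "genus",
    slope_covariate: str = "log10_size",
    basis_dim: int = 10,
    linear_terms: Sequence[str] = (),
    random_intercept: bool = False,
) -> dict[str, ModelSpec]:
    """The full / no-random-effects / null model triple for AIC comparison."""
    smooths = tuple(SmoothTerm(c, basis_dim) for c in smooth_covariates)
    full = ModelSpec(
        outcome=outcome,
        smooth_terms=smooths,
        linear_terms=tuple(linear_terms),
        random_effect=RandomEffect(
            group=group,
            slope_covariate=slope_covariate,
            include_intercept=random_intercept,
        ),
    )
    return {
        "full": full,
        "no_random_effects": replace(full, random_effect=None),
        "null": ModelSpec(outcome=outcome),
    }


def fit_difference_model(
    data: pd.DataFrame,
    outcome: str = "ratio_ctx_rc",
    baseline: str = "ratio_ctx",
    smooth_covariates: Sequence[str] = ("at", "log10_size", "ouv"),
    group: str | None = "genus",
    slope_covariate: str = "log10_size",
    basis_dim: int = 10,
    method: str = "REML",
) -> GAMResults:
    """Regress one backend's ratio on another's plus the composition smooths.

    The baseline ratio enters linearly; the fitted intercept is the mean
    ratio improvement of the outcome backend over the baseline at equal
    covariates, and the remaining smooths show where along AT content,
    genome size and OUV the two backends disagree.
    """
    for col in (outcome, baseline):
        if col not in data.columns:
            raise GAMError(f"missing ratio column {col!r}")
    re = (
        RandomEffect(group=group, slope_covariate=slope_covariate)
        if group is not None
        else None
    )
    spec = ModelSpec(
        outcome=outcome,
        smooth_terms=tuple(SmoothTerm(c, basis_dim) for c in smooth_covariates),
        linear_terms=(baseline,),
        random_effect=re,
        estimation=method,
    )
    return fit_gam(data, spec)
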