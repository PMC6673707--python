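"""Log-distance linear mixed models for the shell-record table.

Two model families:

* gradient: outcome ~ 1 + log(distance_mm + 1) on tract-WMH records
  (distance 0 = the lesion itself), random intercept and log-distance
  slope for participant and - in all-tracts scope - for tract.
* comparison: outcome ~ 1 + log(distance_mm) + type [+ log(distance) x
  type], on 2-10 mm records of both WMH types, with the interaction kept
  only when it lowers the BIC (ML refits for the comparison, REML for
  the reported fit).

The engine is a variance-components REML/ML fit: y = Xb + Zu + e with
independent variance components per random term (crossed groupings
supported), optimized over log variance ratios with a Woodbury-based
profiled likelihood. Marginal (Type III) Wald F tests are computed per
fixed term with Satterthwaite or residual denominator df; every term
here is single-df, so F = (estimate/SE)^2 holds exactly.

MD is rescaled by 1e4 before fitting (mm^2/s values are ~1e-4-1e-3,
which makes variance components ill-conditioned); estimates are reported
on the rescaled scale and the factor is recorded in the result.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .volume_io import ShellRecord

__all__ = [
    "MD_FIT_SCALE",
    "TermResult",
    "FitResult",
    "UnsupportedDfMethodError",
    "MissingLevelError",
    "VarianceComponentsLMM",
    "LMMFit",
    "records_frame",
    "fit_gradient_model",
    "fit_type_comparison_model",
    "type3_wald_f",
    "report_tables",
]

MD_FIT_SCALE = 1e4
_GAMMA_ACTIVE = 1e-6  # variance ratio below which a component is on the boundary


class UnsupportedDfMethodError(ValueError):
    pass


class MissingLevelError(ValueError):
    pass


@dataclass(frozen=True)
class TermResult:
    term: str
    estimate: float
    se: float
    f_stat: float
    df_num: int
    df_den: float
    p_value: float


@dataclass(frozen=True)
class FitResult:
    """Summary of one fitted mixed model (one table row family)."""

    outcome: str
    family: str  # {'gradient', 'comparison'}
    scope: str  # 'all' or a tract name
    terms: tuple[TermResult, ...]
    n_observations: int
    converged: bool
    singular: bool
    degenerate: bool
    df_method: str
    random_effect_variances: dict[str, float]
    residual_variance: float
    loglike: float
    bic: float | None
    outcome_scale: float
    interaction_included: bool | None = None
    bic_with_interaction: float | None = None
    bic_without_interaction: float | None = None
    message: str = ""
    _fit: "LMMFit | None" = field(default=None, repr=False, compare=False)

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)


# ---------------------------------------------------------------------------
# variance-components engine


class VarianceComponentsLMM:
    """REML/ML fit of y = Xb + Zu + e with independent variance components.

    Each random term contributes a block of Z columns sharing one
    variance; groupings may be crossed. The likelihood is profiled over
    b and the residual variance and optimized over log variance ratios.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        term_names: Sequence[str],
        z_blocks: dict[str, np.ndarray],
    ) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y are inconsistent")
        if len(term_names) != X.shape[1]:
            raise ValueError("term_names must match X columns")
        self.X, self.y = X, y
        self.term_names = list(term_names)
        self.block_names = list(z_blocks)
        self.n, self.p = X.shape
        if z_blocks:
            self.Z = np.hstack([z_blocks[k] for k in self.block_names])
            self.block_slices = {}
            start = 0
            for k in self.block_names:
                w = z_blocks[k].shape[1]
                self.block_slices[k] = slice(start, start + w)
                start += w
            self.q = start
            self.ZtZ = self.Z.T @ self.Z
            self.ZtX = self.Z.T @ X
            self.Zty = self.Z.T @ y
        else:
            self.Z = None
            self.q = 0
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.m = len(self.block_names)

    # -- core profiled quantities -------------------------------------

    def _col_gamma(self, gamma: np.ndarray) -> np.ndarray:
        out = np.empty(self.q)
        for g, name in zip(gamma, self.block_names):
            out[self.block_slices[name]] = g
        return out

    def _profile(self, gamma: np.ndarray):
        """GLS pieces for W = I + Z diag(col_gamma) Z'."""
        if self.q == 0 or (gamma <= 0).all():
            XtWX, XtWy, yWy, logdetW = self.XtX, self.Xty, self.yty, 0.0
        else:
            s = np.sqrt(self._col_gamma(np.maximum(gamma, 0.0)))
            M = np.eye(self.q) + (s[:, None] * s[None, :]) * self.ZtZ
            L = np.linalg.cholesky(M)
            Ax = solve_triangular(L, s[:, None] * self.ZtX, lower=True)
            by = solve_triangular(L, s * self.Zty, lower=True)
            XtWX = self.XtX - Ax.T @ Ax
            XtWy = self.Xty - Ax.T @ by
            yWy = self.yty - float(by @ by)
            logdetW = 2.0 * float(np.log(np.diag(L)).sum())
        beta = np.linalg.solve(XtWX, XtWy)
        rss = max(yWy - float(beta @ XtWy), 0.0)
        return beta, rss, XtWX, logdetW

    def neg2_reml(self, gamma: np.ndarray) -> float:
        beta, rss, XtWX, logdetW = self._profile(gamma)
        n, p = self.n, self.p
        if rss <= 0:
            return -np.inf
        sigma2 = rss / (n - p)
        sign, logdetXtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return (
            (n - p) * math.log(2.0 * math.pi * sigma2)
            + logdetW
            + logdetXtWX
            + (n - p)
        )

    def neg2_ml(self, gamma: np.ndarray) -> float:
        _, rss, _, logdetW = self._profile(gamma)
        n = self.n
        if rss <= 0:
            return -np.inf
        sigma2 = rss / n
        return n * math.log(2.0 * math.pi * sigma2) + logdetW + n

    # -- fitting -------------------------------------------------------

    def fit(self, reml: bool = True) -> "LMMFit":
        # degenerate zero-residual data: exact line fit, no variance left
        beta_ols = np.linalg.lstsq(self.X, self.y, rcond=None)[0]
        rss_ols = float(np.sum((self.y - self.X @ beta_ols) ** 2))
        scale = max(self.yty / max(self.n, 1), 1e-30)
        if rss_ols <= 1e-18 * scale * self.n:
            cov = np.zeros((self.p, self.p))
            return LMMFit(
                model=self,
                beta=beta_ols,
                cov_beta=cov,
                gamma=np.zeros(self.m),
                sigma2=0.0,
                loglike=math.inf,
                reml=reml,
                converged=True,
                singular=True,
                degenerate=True,
            )

        objective = self.neg2_reml if reml else self.neg2_ml
        if self.m == 0:
            val = objective(np.zeros(0))
            beta, rss, XtWX, _ = self._profile(np.zeros(0))
            dof = self.n - self.p if reml else self.n
            sigma2 = rss / dof
            return LMMFit(
                model=self,
                beta=beta,
                cov_beta=rss / (self.n - self.p) * np.linalg.inv(XtWX),
                gamma=np.zeros(0),
                sigma2=sigma2,
                loglike=-0.5 * val,
                reml=reml,
                converged=True,
                singular=False,
                degenerate=False,
            )

        def obj(rho: np.ndarray) -> float:
            val = objective(np.exp(rho))
            return val if np.isfinite(val) else 1e12

        candidates = []
        for start in (np.full(self.m, -1.0), np.full(self.m, -5.0), np.full(self.m, 1.0)):
            candidates.append(
                optimize.minimize(
                    obj,
                    start,
                    method="L-BFGS-B",
                    bounds=[(-16.0, 12.0)] * self.m,
                    options={"maxiter": 300, "ftol": 1e-12},
                )
            )
        best = min(candidates, key=lambda r: r.fun)
        # L-BFGS-B reports ABNORMAL line-search exits on the flat boundary
        # (gamma -> 0); accept if any successful start reached the same value,
        # else polish with Nelder-Mead and accept if it cannot improve
        converged = bool(
            any(c.success and c.fun < best.fun + 1e-6 for c in candidates)
        )
        if not converged:
            polish = optimize.minimize(
                obj,
                best.x,
                method="Nelder-Mead",
                options={"maxiter": 400, "fatol": 1e-10, "xatol": 1e-8},
            )
            if polish.fun < best.fun:
                best = polish
            converged = bool(polish.success or abs(polish.fun - best.fun) < 1e-6)
        gamma = np.exp(best.x)
        gamma[gamma < 1e-12] = 0.0
        beta, rss, XtWX, _ = self._profile(gamma)
        dof = self.n - self.p if reml else self.n
        sigma2 = rss / dof
        cov_beta = sigma2 * np.linalg.inv(XtWX)
        singular = bool((gamma < _GAMMA_ACTIVE).any())
        return LMMFit(
            model=self,
            beta=beta,
            cov_beta=cov_beta,
            gamma=gamma,
            sigma2=sigma2,
            loglike=-0.5 * float(best.fun),
            reml=reml,
            converged=converged,
            singular=singular,
            degenerate=False,
        )


@dataclass
class LMMFit:
    """Raw fit output of :class:`VarianceComponentsLMM`."""

    model: VarianceComponentsLMM
    beta: np.ndarray
    cov_beta: np.ndarray
    gamma: np.ndarray
    sigma2: float
    loglike: float
    reml: bool
    converged: bool
    singular: bool
    degenerate: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))

    @property
    def component_variances(self) -> dict[str, float]:
        return {
            name: float(g * self.sigma2)
            for name, g in zip(self.model.block_names, self.gamma)
        }

    @property
    def n_parameters(self) -> int:
        # fixed effects + active variance components + residual variance
        n_active = int((self.gamma >= _GAMMA_ACTIVE).sum())
        return self.model.p + n_active + 1

    def bic(self) -> float:
        if not math.isfinite(self.loglike):
            return -math.inf
        return -2.0 * self.loglike + self.n_parameters * math.log(self.model.n)


# ---------------------------------------------------------------------------
# denominator degrees of freedom


def _satterthwaite_df(fit: LMMFit, c: np.ndarray) -> float:
    """Satterthwaite denominator df for the contrast c'beta.

    Differentiates f(theta) = c' Cov(beta|theta) c and the REML
    information in log-variance coordinates (invariant to first order).
    """
    model = fit.model
    resid_df = max(model.n - model.p, 1)
    active = [i for i, g in enumerate(fit.gamma) if g >= _GAMMA_ACTIVE]
    theta = np.array(
        [fit.gamma[i] * fit.sigma2 for i in active] + [fit.sigma2], dtype=float
    )
    if (theta <= 0).any():
        return float(resid_df)

    def f_of(u: np.ndarray) -> float:
        th = np.exp(u)
        sigma2 = th[-1]
        gamma = np.zeros(model.m)
        for j, i in enumerate(active):
            gamma[i] = th[j] / sigma2
        _, _, XtWX, _ = model._profile(gamma)
        cov = sigma2 * np.linalg.inv(XtWX)
        return float(c @ cov @ c)

    def neg2_of(u: np.ndarray) -> float:
        th = np.exp(u)
        sigma2 = th[-1]
        gamma = np.zeros(model.m)
        for j, i in enumerate(active):
            gamma[i] = th[j] / sigma2
        beta, rss, XtWX, logdetW = model._profile(gamma)
        sign, logdetXtWX = np.linalg.slogdet(XtWX)
        if sign <= 0 or sigma2 <= 0 or rss <= 0:
            return np.inf
        n, p = model.n, model.p
        # -2 REML loglik in raw-variance form:
        #   n log s2 + log|W| + (log|XtWX| - p log s2) + rss/s2 + (n-p) log 2pi
        return (
            (n - p) * math.log(sigma2)
            + (n - p) * math.log(2.0 * math.pi)
            + logdetW
            + logdetXtWX
            + rss / sigma2
        )

    u0 = np.log(theta)
    k = len(u0)
    h = 1e-4

    grad = np.zeros(k)
    for i in range(k):
        up, dn = u0.copy(), u0.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (f_of(up) - f_of(dn)) / (2 * h)

    H = np.zeros((k, k))
    base = neg2_of(u0)
    if not np.isfinite(base):
        return float(resid_df)
    for i in range(k):
        for j in range(i, k):
            upp, upm, ump, umm = (u0.copy() for _ in range(4))
            upp[i] += h
            upp[j] += h
            upm[i] += h
            upm[j] -= h
            ump[i] -= h
            ump[j] += h
            umm[i] -= h
            umm[j] -= h
            val = (neg2_of(upp) - neg2_of(upm) - neg2_of(ump) + neg2_of(umm)) / (4 * h * h)
            H[i, j] = H[j, i] = val
    if not np.isfinite(H).all():
        return float(resid_df)
    # Cov(u_hat) ~ 2 H^{-1}; use pseudo-inverse for boundary-flat directions
    try:
        A = 2.0 * np.linalg.pinv(H)
    except np.linalg.LinAlgError:
        return float(resid_df)
    denom = float(grad @ A @ grad)
    f0 = f_of(u0)
    if denom <= 0 or f0 <= 0:
        return float(resid_df)
    df = 2.0 * f0 * f0 / denom
    return float(min(max(df, 1.0), resid_df))


def type3_wald_f(fit: LMMFit, df_method: str = "satterthwaite") -> tuple[TermResult, ...]:
    """Marginal Wald F test per fixed term (all terms here are single-df)."""
    if df_method not in ("satterthwaite", "residual"):
        raise UnsupportedDfMethodError(
            f"df method {df_method!r} is not implemented; use 'satterthwaite' or 'residual'"
        )
    model = fit.model
    resid_df = max(model.n - model.p, 1)
    out = []
    for i, name in enumerate(model.term_names):
        est = float(fit.beta[i])
        se = float(fit.se[i])
        if se == 0.0:
            # zero-residual degenerate fit: the estimate is exact
            is_zero = abs(est) < 1e-10
            f_stat = 0.0 if is_zero else math.inf
            out.append(
                TermResult(name, est, 0.0, f_stat, 1, float(resid_df), 1.0 if is_zero else 0.0)
            )
            continue
        f_stat = (est / se) ** 2
        if df_method == "residual" or fit.degenerate:
            df_den = float(resid_df)
        else:
            c = np.zeros(model.p)
            c[i] = 1.0
            df_den = _satterthwaite_df(fit, c)
        p = float(stats.f.sf(f_stat, 1, df_den))
        out.append(TermResult(name, est, se, f_stat, 1, df_den, p))
    return tuple(out)


# ---------------------------------------------------------------------------
# model families on the record table


def records_frame(records: Sequence[ShellRecord], outcome: str) -> pd.DataFrame:
    """Model-ready frame: CSF-excluded and empty records dropped."""
    if outcome not in ("fa", "md"):
        raise ValueError("outcome must be 'fa' or 'md'")
    rows = []
    for r in records:
        if r.excluded_csf or r.n_voxels == 0:
            continue
        y = r.mean_fa if outcome == "fa" else r.mean_md
        if y is None:
            continue
        if outcome == "md":
            y = y * MD_FIT_SCALE
        rows.append(
            {
                "participant": r.participant,
                "tract": r.tract,
                "wmh_type": r.wmh_type,
                "distance_mm": float(r.distance_mm),
                "y": float(y),
            }
        )
    return pd.DataFrame(rows)


def _indicator(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = sorted(labels.unique())
    mat = np.zeros((len(labels), len(levels)))
    for j, lev in enumerate(levels):
        mat[:, j] = (labels == lev).to_numpy(dtype=float)
    return mat, levels


def _random_blocks(
    df: pd.DataFrame, x: np.ndarray, include_tract: bool
) -> dict[str, np.ndarray]:
    blocks: dict[str, np.ndarray] = {}
    pmat, plevels = _indicator(df["participant"])
    if len(plevels) > 1:
        blocks["participant_intercept"] = pmat
        blocks["participant_slope"] = pmat * x[:, None]
    if include_tract:
        tmat, tlevels = _indicator(df["tract"])
        if len(tlevels) > 1:
            blocks["tract_intercept"] = tmat
            blocks["tract_slope"] = tmat * x[:, None]
    return blocks


def fit_gradient_model(
    records: Sequence[ShellRecord],
    outcome: str,
    scope: str = "all",
    df_method: str = "satterthwaite",
) -> FitResult:
    """outcome ~ 1 + log(distance+1) on tract-WMH records (0-10 mm).

    ``scope='all'`` fits the crossed participant-and-tract model; a tract
    name fits that tract alone with participant random effects.
    """
    df = records_frame(records, outcome)
    df = df[df["wmh_type"] == "tract_wmh"]
    if scope != "all":
        df = df[df["tract"] == scope]
    if df.empty:
        raise ValueError(f"no usable records for outcome={outcome}, scope={scope}")
    if df["distance_mm"].nunique() < 2:
        raise ValueError("need records at >= 2 distinct distances")
    x = np.log1p(df["distance_mm"].to_numpy())
    X = np.column_stack([np.ones(len(df)), x])
    blocks = _random_blocks(df, x, include_tract=(scope == "all"))
    model = VarianceComponentsLMM(X, df["y"].to_numpy(), ["intercept", "log_dist_plus1"], blocks)
    fit = model.fit(reml=True)
    terms = type3_wald_f(fit, df_method)
    ml_fit = model.fit(reml=False) if not fit.degenerate else fit
    return FitResult(
        outcome=outcome,
        family="gradient",
        scope=scope,
        terms=terms,
        n_observations=model.n,
        converged=fit.converged,
        singular=fit.singular,
        degenerate=fit.degenerate,
        df_method=df_method,
        random_effect_variances=fit.component_variances,
        residual_variance=fit.sigma2,
        loglike=fit.loglike,
        bic=None if fit.degenerate else ml_fit.bic(),
        outcome_scale=MD_FIT_SCALE if outcome == "md" else 1.0,
        _fit=fit,
    )


def _comparison_design(
    df: pd.DataFrame, interaction: bool
) -> tuple[np.ndarray, list[str], np.ndarray]:
    x = np.log(df["distance_mm"].to_numpy())
    nearby = (df["wmh_type"] == "nearby").to_numpy(dtype=float)
    cols = [np.ones(len(df)), x, nearby]
    names = ["intercept", "log_dist", "wmh_type_nearby"]
    if interaction:
        cols.append(x * nearby)
        names.append("log_dist:wmh_type_nearby")
    return np.column_stack(cols), names, x


def fit_type_comparison_model(
    records: Sequence[ShellRecord],
    outcome: str,
    scope: str = "all",
    df_method: str = "satterthwaite",
) -> FitResult:
    """Tract-WMH vs nearby trajectories over 2-10 mm with a BIC-gated interaction.

    The interaction log(distance) x type enters only if it lowers the BIC
    of an ML fit; ties keep the simpler model. The reported fit is REML.
    Type is coded with tract-WMH as reference, so the nearby coefficient
    is the nearby-minus-intersecting offset.
    """
    df = records_frame(records, outcome)
    df = df[df["distance_mm"] > 0]
    if scope != "all":
        df = df[df["tract"] == scope]
    present = set(df["wmh_type"].unique())
    for level in ("tract_wmh", "nearby"):
        if level not in present:
            raise MissingLevelError(
                f"wmh_type level {level!r} absent for outcome={outcome}, scope={scope}"
            )

    bics = {}
    for interaction in (False, True):
        X, names, x = _comparison_design(df, interaction)
        blocks = _random_blocks(df, x, include_tract=(scope == "all"))
        model = VarianceComponentsLMM(X, df["y"].to_numpy(), names, blocks)
        mlfit = model.fit(reml=False)
        bics[interaction] = mlfit.bic() if not mlfit.degenerate else math.inf
    if not math.isfinite(bics[False]) and not math.isfinite(bics[True]):
        use_interaction = False  # degenerate both ways: keep the simpler model
    else:
        use_interaction = bics[True] < bics[False]  # tie -> simpler

    X, names, x = _comparison_design(df, use_interaction)
    blocks = _random_blocks(df, x, include_tract=(scope == "all"))
    model = VarianceComponentsLMM(X, df["y"].to_numpy(), names, blocks)
    fit = model.fit(reml=True)
    terms = type3_wald_f(fit, df_method)
    return FitResult(
        outcome=outcome,
        family="comparison",
        scope=scope,
        terms=terms,
        n_observations=model.n,
        converged=fit.converged,
        singular=fit.singular,
        degenerate=fit.degenerate,
        df_method=df_method,
        random_effect_variances=fit.component_variances,
        residual_variance=fit.sigma2,
        loglike=fit.loglike,
        bic=min(b for b in bics.values()),
        outcome_scale=MD_FIT_SCALE if outcome == "md" else 1.0,
        interaction_included=use_interaction,
        bic_with_interaction=None if not math.isfinite(bics[True]) else bics[True],
        bic_without_interaction=None if not math.isfinite(bics[False]) else bics[False],
        _fit=fit,
    )


# ---------------------------------------------------------------------------
# reporting


_REPORT_COLUMNS = [
    "outcome",
    "scope",
    "term",
    "estimate",
    "std_error",
    "df_res",
    "f_stat",
    "p_value",
    "n_obs",
    "converged",
    "singular",
    "df_method",
    "outcome_scale",
    "interaction_included",
]


def _fit_rows(fit: FitResult) -> list[dict]:
    rows = []
    for t in fit.terms:
        rows.append(
            {
                "outcome": fit.outcome,
                "scope": fit.scope,
                "term": t.term,
                "estimate": t.estimate,
                "std_error": t.se,
                "df_res": t.df_den,
                "f_stat": t.f_stat,
                "p_value": t.p_value,
                "n_obs": fit.n_observations,
                "converged": fit.converged,
                "singular": fit.singular,
                "df_method": fit.df_method,
                "outcome_scale": fit.outcome_scale,
                "interaction_included": fit.interaction_included,
            }
        )
    return rows


def report_tables(
    fits: Sequence[FitResult],
    out_dir: str | os.PathLike,
    manifest_extra: dict | None = None,
) -> dict[str, Path]:
    """Write one CSV per (family, scope-kind) plus a JSON run manifest.

    Estimates, SEs, F, denominator df and p-values per term; the 0.01
    interpretive threshold is annotated in the manifest only - no row is
    filtered by significance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = {
        "gradient_all_tracts": [],
        "gradient_per_tract": [],
        "comparison_all_tracts": [],
        "comparison_per_tract": [],
    }
    for fit in fits:
        key = f"{fit.family}_{'all_tracts' if fit.scope == 'all' else 'per_tract'}"
        groups[key].extend(_fit_rows(fit))
    paths = {}
    for key, rows in groups.items():
        path = out / f"{key}.csv"
        pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, index=False)
        paths[key] = path
    manifest = {
        "n_fits": len(fits),
        "interpretive_alpha": 0.01,
        "md_fit_scale": MD_FIT_SCALE,
        "bic_choices": {
            f"{f.outcome}/{f.scope}": {
                "interaction_included": f.interaction_included,
                "bic_with_interaction": f.bic_with_interaction,
                "bic_without_interaction": f.bic_without_interaction,
            }
            for f in fits
            if f.family == "comparison"
        },
        "df_methods": sorted({f.df_method for f in fits}),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    mpath = out / "fit_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mpath
    return paths
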