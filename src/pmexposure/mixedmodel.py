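"""Random-intercept linear mixed models: fitting, profiling, EMMs, ICC.

The main fit is REML via statsmodels MixedLM. Profile-likelihood confidence
intervals for fixed effects are computed with a dedicated maximum-likelihood
engine for the single-random-intercept Gaussian model: for a given variance
ratio lambda = var_between/var_resid the GLS solution has a closed form in
group-level sufficient statistics, so the profile deviance of any fixed
coefficient (fit with that coefficient pinned, which is equivalent to
regressing ``y - c*x_j`` on the reduced design) is cheap enough for exact
root finding. ML, not REML, is used for the profile because the REML
criterion is not comparable across fixed-effect specifications.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from pmexposure.design import Design, DesignError, build_design, emm_table

_LOG2PI = np.log(2 * np.pi)


class RandomInterceptML:
    """Closed-form ML likelihood engine for y = X b + u_group + e."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        codes, _ = pd.factorize(groups)
        self.codes = codes
        self.n_groups = int(codes.max()) + 1
        self.N, self.p = self.X.shape
        # group-level sufficient statistics
        self.n_i = np.bincount(codes, minlength=self.n_groups).astype(float)
        self.S = np.zeros((self.n_groups, self.p))  # group sums of X rows
        np.add.at(self.S, codes, self.X)
        self.t = np.bincount(codes, weights=self.y, minlength=self.n_groups)
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    # -- likelihood ---------------------------------------------------------
    def _solve(self, lam: float, XtX, Xty, yty, S, t):
        c = lam / (1.0 + self.n_i * lam)
        A = XtX - (S * c[:, None]).T @ S
        b = Xty - S.T @ (c * t)
        q = yty - float(c @ (t * t))
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ b)
        return beta, rss, A

    def loglike(self, lam: float, stats_=None) -> float:
        XtX, Xty, yty, S, t = stats_ or (self.XtX, self.Xty, self.yty, self.S, self.t)
        try:
            _, rss, _ = self._solve(lam, XtX, Xty, yty, S, t)
        except np.linalg.LinAlgError:
            return -np.inf
        if rss <= 0:
            return -np.inf
        sigma2 = rss / self.N
        return float(
            -0.5 * self.N * (_LOG2PI + np.log(sigma2) + 1.0)
            - 0.5 * np.sum(np.log1p(self.n_i * lam))
        )

    def _max_loglike(self, stats_=None) -> tuple[float, float]:
        obj = lambda u: -self.loglike(np.exp(u), stats_)
        res = optimize.minimize_scalar(obj, bounds=(-16.0, 12.0), method="bounded",
                                       options={"xatol": 1e-8})
        lam = float(np.exp(res.x))
        ll = -float(res.fun)
        ll0 = self.loglike(0.0, stats_)  # boundary: no between-group variance
        return (0.0, ll0) if ll0 >= ll else (lam, ll)

    def fit(self):
        lam, ll = self._max_loglike()
        beta, rss, A = self._solve(lam, self.XtX, self.Xty, self.yty, self.S, self.t)
        sigma2 = rss / self.N
        cov = sigma2 * np.linalg.inv(A)
        return {"lam": lam, "loglike": ll, "beta": beta, "sigma2": sigma2,
                "se": np.sqrt(np.diag(cov))}

    # -- profiling ----------------------------------------------------------
    def _reduced_stats(self, j: int, c: float):
        keep = np.arange(self.p) != j
        xj_col = self.XtX[:, j]
        XtX = self.XtX[np.ix_(keep, keep)]
        Xty = (self.Xty - c * xj_col)[keep]
        yty = self.yty - 2.0 * c * self.Xty[j] + c * c * self.XtX[j, j]
        S = self.S[:, keep]
        t = self.t - c * self.S[:, j]
        return XtX, Xty, yty, S, t

    def profile_loglike(self, j: int, c: float) -> float:
        _, ll = self._max_loglike(self._reduced_stats(j, c))
        return ll

    def profile_ci(self, j: int, level: float = 0.95, fit: dict | None = None):
        """Profile-likelihood CI for coefficient j via deviance inversion."""
        fit = fit or self.fit()
        target = stats.chi2.ppf(level, 1)
        bhat = float(fit["beta"][j])
        step = float(fit["se"][j]) if np.isfinite(fit["se"][j]) else 0.1 * abs(bhat) + 0.1
        step = max(step, 1e-8)
        llmax = fit["loglike"]

        def dev(c: float) -> float:
            return 2.0 * (llmax - self.profile_loglike(j, c)) - target

        bounds = []
        for sign in (-1.0, 1.0):
            hi = step
            for _ in range(60):
                if dev(bhat + sign * hi) > 0:
                    break
                hi *= 2.0
            else:
                bounds.append(sign * np.inf)
                continue
            lo = hi / 2.0 if hi > step else 0.0
            root = optimize.brentq(
                lambda d: dev(bhat + sign * d), lo, hi, xtol=1e-6 * step
            )
            bounds.append(sign * root)
        return bhat + bounds[0], bhat + bounds[1]


# ---------------------------------------------------------------------------
# Model fit result


@dataclass
class FitResult:
    names: list[str]
    coefs: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    p_bh: dict[str, float]  # BH-adjusted, non-intercept family
    ci: dict[str, tuple[float, float]]  # profile-likelihood 95% CIs
    re_var: float
    resid_var: float
    icc: float
    emm: pd.DataFrame
    idw_mean: float
    n_obs: int
    n_groups: int
    converged: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefs": self.coefs,
                "se": self.se,
                "pvalues": self.pvalues,
                "p_bh": self.p_bh,
                "ci": {k: list(v) for k, v in self.ci.items()},
                "re_var": self.re_var,
                "resid_var": self.resid_var,
                "icc": self.icc,
                "idw_mean": self.idw_mean,
                "n_obs": self.n_obs,
                "n_groups": self.n_groups,
                "converged": self.converged,
            },
            indent=2,
        )

    def table(self) -> pd.DataFrame:
        """Coefficient/EMM table, one row per factor level plus covariates."""
        rows = []
        for _, r in self.emm.iterrows():
            f, lev = r["factor"], r["level"]
            name = None
            if f == "indoor":
                name = "indoor" if lev == "indoor" else None
            else:
                cand = f"{f}[{lev}]"
                name = cand if cand in self.coefs else None
            rows.append(
                {
                    "variable": f,
                    "level": lev,
                    "emm": r["emm"],
                    "coefficient": self.coefs.get(name, 0.0) if name else 0.0,
                    "ci_low": self.ci.get(name, (np.nan, np.nan))[0] if name else np.nan,
                    "ci_high": self.ci.get(name, (np.nan, np.nan))[1] if name else np.nan,
                    "p": self.pvalues.get(name, np.nan) if name else np.nan,
                    "p_bh": self.p_bh.get(name, np.nan) if name else np.nan,
                    "reference": name is None and lev == self.emm[self.emm["factor"] == f]["level"].iloc[0],
                }
            )
        for name in ("idw", "indoor:idw"):
            if name in self.coefs:
                rows.append(
                    {
                        "variable": name,
                        "level": "",
                        "emm": np.nan,
                        "coefficient": self.coefs[name],
                        "ci_low": self.ci.get(name, (np.nan, np.nan))[0],
                        "ci_high": self.ci.get(name, (np.nan, np.nan))[1],
                        "p": self.pvalues.get(name, np.nan),
                        "p_bh": self.p_bh.get(name, np.nan),
                        "reference": False,
                    }
                )
        return pd.DataFrame(rows)


def _bh(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def fit_model(
    df: pd.DataFrame,
    response: str = "y",
    demographics: str = "full",
    hour_col: str = "hour",
    ci_coefs: list[str] | str | None = "all",
    ci_level: float = 0.95,
) -> FitResult:
    """REML fit of the exposure mixed model with profile CIs, BH, and EMMs.

    ``ci_coefs`` selects which coefficients get profile-likelihood CIs
    ("all" non-intercept, a list of names, or None to skip).
    """
    design = build_design(df, response=response, demographics=demographics, hour_col=hour_col)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(design.y, design.X, groups=design.groups)
        res = md.fit(reml=True)
    coefs = dict(zip(design.names, np.asarray(res.fe_params)))
    se = dict(zip(design.names, np.asarray(res.bse_fe)))
    pvals = dict(zip(design.names, np.asarray(res.pvalues)[: len(design.names)]))

    family = [n for n in design.names if n != "intercept"]
    adj = _bh(np.array([pvals[n] for n in family]))
    p_bh = dict(zip(family, adj))

    ci: dict[str, tuple[float, float]] = {}
    if ci_coefs:
        wanted = family if ci_coefs == "all" else [c for c in ci_coefs if c in design.names]
        engine = RandomInterceptML(design.X, design.y, design.groups)
        efit = engine.fit()
        for name in wanted:
            j = design.names.index(name)
            ci[name] = engine.profile_ci(j, level=ci_level, fit=efit)

    re_var = float(np.asarray(res.cov_re)[0, 0])
    resid_var = float(res.scale)
    icc = re_var / (re_var + resid_var) if re_var + resid_var > 0 else 0.0
    emm = emm_table(coefs, design.factor_levels, design.idw_mean)
    return FitResult(
        names=design.names,
        coefs=coefs,
        se=se,
        pvalues=pvals,
        p_bh=p_bh,
        ci=ci,
        re_var=re_var,
        resid_var=resid_var,
        icc=icc,
        emm=emm,
        idw_mean=design.idw_mean,
        n_obs=len(design.y),
        n_groups=int(pd.unique(design.groups).size),
        converged=bool(res.converged),
    )


def indoor_slope(fit: FitResult | dict[str, float]) -> float:
    """Indoor-stratum slope of exposure on home background concentration.

    The background main effect is the outdoor-stratum slope; adding the
    indoor-by-background interaction gives the indoor-stratum slope.
    """
    coefs = fit.coefs if isinstance(fit, FitResult) else fit
    if "idw" not in coefs or "indoor:idw" not in coefs:
        raise KeyError("fit lacks the background main effect or its indoor interaction")
    return float(coefs["idw"] + coefs["indoor:idw"])


def variance_components_icc(
    df: pd.DataFrame, response: str = "y", group_col: str = "studyid"
) -> tuple[float, bool]:
    """ICC from an intercept-only random-intercept model.

    Returns (ICC, singular_flag); a singular fit reports ICC 0 with the
    flag set.
    """
    y = df[response].astype(float).to_numpy()
    groups = df[group_col].astype(str).to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, np.ones((len(y), 1)), groups=groups)
            res = md.fit(reml=True)
        re_var = float(np.asarray(res.cov_re)[0, 0])
        resid = float(res.scale)
    except Exception:  # noqa: BLE001
        return 0.0, True
    if not np.isfinite(re_var) or re_var < 1e-12:
        return 0.0, True
    return re_var / (re_var + resid), False


def sensitivity_suite(
    df: pd.DataFrame,
    response: str = "y",
    hour_col: str = "hour",
    n_groups: int = 10,
    seed: int = 0,
) -> dict:
    """Nested-model comparison plus leave-one-group-out refits.

    Model 1 drops all demographics, Model 2 keeps age and sex, Model 3 is
    fully adjusted. The leave-one-group-out pass splits participants into
    ``n_groups`` seeded groups and refits the full model on each 9/10
    subset, reporting the per-coefficient range; a refit that loses a
    factor level flags its coefficients as non-estimable.
    """
    nested = {}
    for label, demo in (("model1", "none"), ("model2", "age_sex"), ("model3", "full")):
        fit = fit_model(df, response=response, demographics=demo, hour_col=hour_col,
                        ci_coefs=None)
        nested[label] = fit
    spat = [n for n in nested["model3"].names
            if n.split("[")[0] in {"landuse", "season", "hour"}
            or n in {"indoor", "idw", "indoor:idw"}]
    nested_table = pd.DataFrame(
        {label: {n: fit.coefs.get(n, np.nan) for n in spat} for label, fit in nested.items()}
    ).rename_axis("coefficient").reset_index()

    rng = np.random.default_rng(seed)
    pids = np.array(sorted(df["studyid"].astype(str).unique()))
    perm = rng.permutation(len(pids))
    assignment = {pid: int(k % n_groups) for pid, k in zip(pids[perm], range(len(pids)))}
    logo_rows = {}
    flagged = []
    for g in range(n_groups):
        keep = ~df["studyid"].astype(str).map(assignment).eq(g)
        sub = df.loc[keep]
        try:
            fit = fit_model(sub, response=response, demographics="full",
                            hour_col=hour_col, ci_coefs=None)
            logo_rows[f"drop_group_{g}"] = {n: fit.coefs.get(n, np.nan) for n in spat}
        except DesignError:
            flagged.append(g)
            logo_rows[f"drop_group_{g}"] = {n: np.nan for n in spat}
    logo = pd.DataFrame(logo_rows).rename_axis("coefficient")
    logo_summary = pd.DataFrame(
        {
            "coefficient": logo.index,
            "min": logo.min(axis=1).to_numpy(),
            "max": logo.max(axis=1).to_numpy(),
            "range": (logo.max(axis=1) - logo.min(axis=1)).to_numpy(),
            "n_refits": logo.notna().sum(axis=1).to_numpy(),
        }
    )
    return {
        "nested": nested_table,
        "nested_fits": nested,
        "logo": logo.reset_index(),
        "logo_summary": logo_summary,
        "assignment": assignment,
        "flagged_refits": flagged,
    }
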