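"""Mixed-model inference and temporal cluster-based permutation testing.

Two model objects carry the statistics:

* :class:`EyeLMM` — a linear mixed model for a trial- or participant-level
  gaze measure with the full z-AQ x z-SPIN x emotion factorial as fixed
  effects, sex as a covariate, and a random intercept per participant.
  ``fit()`` returns :class:`EyeLMMResults` with REML estimates, Type III
  F tests (sum-to-zero factor coding) with Satterthwaite denominator
  degrees of freedom, and simple slopes of social anxiety at chosen levels
  of the autistic-trait moderator.

* :class:`ClusterPermutationTest` — compares two participant groups' mean
  eye-looking time courses epoch by epoch (Welch t), forms contiguous
  supra-threshold clusters of same sign, and evaluates each cluster's summed
  t mass against the permutation distribution of the maximum cluster mass
  under random relabelling of participants.

Point estimation of the mixed model is delegated to statsmodels ``MixedLM``;
the Satterthwaite layer (restricted-likelihood curvature of the two variance
components and per-contrast degrees of freedom) is computed here because
statsmodels does not provide it.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import comb

import statsmodels.formula.api as smf


@dataclass
class LMMSpec:
    """Model specification for :class:`EyeLMM`."""

    response: str
    fixed: str = "C(sex, Sum) + z_aq4 * z_spin * C(emotion, Sum)"
    groups: str = "participant_id"
    df_method: str = "satterthwaite"  # 'satterthwaite' | 'residual'

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


class _RandomInterceptREML:
    """Closed-form REML quantities for a Gaussian random-intercept model.

    The marginal covariance of group i is sigma2*I + tau2*J; all quantities
    use the Woodbury identity, so cost is linear in the number of rows.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, group_codes: np.ndarray):
        self.X = X
        self.y = y
        order = np.argsort(group_codes, kind="stable")
        self.X = X[order]
        self.y = y[order]
        codes = group_codes[order]
        _, starts = np.unique(codes, return_index=True)
        bounds = np.append(starts, len(codes))
        self.slices = [slice(bounds[k], bounds[k + 1]) for k in range(len(starts))]
        self.n, self.p = X.shape

    def beta_cov(self, tau2: float, sigma2: float,
                 X: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
        """GLS fixed effects and their covariance at given variance components."""
        X = self.X if X is None else X
        XtViX = np.zeros((X.shape[1], X.shape[1]))
        XtViy = np.zeros(X.shape[1])
        for sl in self.slices:
            Xi, yi = X[sl], self.y[sl]
            ni = Xi.shape[0]
            ci = tau2 / (sigma2 + ni * tau2)
            sx = Xi.sum(axis=0)
            sy = yi.sum()
            XtViX += (Xi.T @ Xi - ci * np.outer(sx, sx)) / sigma2
            XtViy += (Xi.T @ yi - ci * sx * sy) / sigma2
        C = np.linalg.inv(XtViX)
        beta = C @ XtViy
        return beta, C

    def m2ll(self, tau2: float, sigma2: float) -> float:
        """-2 x restricted log-likelihood (REML deviance)."""
        beta, _ = self.beta_cov(tau2, sigma2)
        r = self.y - self.X @ beta
        logdetV = 0.0
        quad = 0.0
        XtViX = np.zeros((self.p, self.p))
        for sl in self.slices:
            Xi, ri = self.X[sl], r[sl]
            ni = Xi.shape[0]
            ci = tau2 / (sigma2 + ni * tau2)
            logdetV += (ni - 1) * math.log(sigma2) + math.log(sigma2 + ni * tau2)
            quad += (ri @ ri - ci * ri.sum() ** 2) / sigma2
            sx = Xi.sum(axis=0)
            XtViX += (Xi.T @ Xi - ci * np.outer(sx, sx)) / sigma2
        sign, logdet = np.linalg.slogdet(XtViX)
        return ((self.n - self.p) * math.log(2 * math.pi)
                + logdetV + logdet + quad)

    def profile_fit(self) -> tuple[float, float]:
        """Robust REML fit by profiling: 1-D search over the variance ratio.

        For a random-intercept model the REML criterion depends on
        lambda = tau2/sigma2 only, with sigma2 profiled out in closed form,
        so a bounded scalar minimization cannot fail at the boundary.
        Used as a fallback when the general-purpose optimizer breaks down
        (typically when tau2 is at or near zero).
        """
        from scipy.optimize import minimize_scalar

        n, p = self.n, self.p

        def crit(lam: float) -> tuple[float, float]:
            XtWX = np.zeros((p, p))
            XtWy = np.zeros(p)
            logdet_corr = 0.0
            for sl in self.slices:
                Xi, yi = self.X[sl], self.y[sl]
                ni = Xi.shape[0]
                ci = lam / (1.0 + ni * lam)
                sx = Xi.sum(axis=0)
                XtWX += Xi.T @ Xi - ci * np.outer(sx, sx)
                XtWy += Xi.T @ yi - ci * sx * yi.sum()
                logdet_corr += math.log(1.0 + ni * lam)
            beta = np.linalg.solve(XtWX, XtWy)
            rss_w = 0.0
            r = self.y - self.X @ beta
            for sl in self.slices:
                ri = r[sl]
                ni = len(ri)
                ci = lam / (1.0 + ni * lam)
                rss_w += ri @ ri - ci * ri.sum() ** 2
            sigma2 = rss_w / (n - p)
            _, logdet_xwx = np.linalg.slogdet(XtWX)
            val = ((n - p) * math.log(sigma2) + logdet_corr + logdet_xwx
                   + (n - p))
            return val, sigma2

        res = minimize_scalar(lambda u: crit(math.exp(u))[0],
                              bounds=(-30.0, 10.0), method="bounded",
                              options={"xatol": 1e-10})
        lam = math.exp(res.x)
        v_int, s_int = crit(lam)
        v_zero, s_zero = crit(0.0)
        if v_zero <= v_int:
            return 0.0, s_zero
        return lam * s_int, s_int

    # -- Satterthwaite machinery -------------------------------------------

    def _vc_cov(self, tau2: float, sigma2: float) -> np.ndarray:
        """Asymptotic covariance of (tau2, sigma2) from the REML curvature."""
        h = np.array([max(1e-4 * tau2, 1e-6 * sigma2),
                      max(1e-4 * sigma2, 1e-8)])
        th = np.array([tau2, sigma2])

        def f(v: np.ndarray) -> float:
            return self.m2ll(max(v[0], 0.0), max(v[1], 1e-12))

        H = np.zeros((2, 2))
        f0 = f(th)
        for a in range(2):
            ea = np.zeros(2)
            ea[a] = h[a]
            H[a, a] = (f(th + ea) - 2 * f0 + f(th - ea)) / h[a] ** 2
        ea, eb = np.array([h[0], 0.0]), np.array([0.0, h[1]])
        H[0, 1] = H[1, 0] = (
            f(th + ea + eb) - f(th + ea - eb) - f(th - ea + eb) + f(th - ea - eb)
        ) / (4 * h[0] * h[1])
        # Var(theta) = [0.5 * H]^{-1}; guard boundary/non-PD cases
        try:
            A = np.linalg.inv(0.5 * H)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(0.5 * H)
        return A

    def contrast_df(self, ell: np.ndarray, tau2: float, sigma2: float,
                    A: np.ndarray | None = None) -> float:
        """Satterthwaite df of a single contrast l'beta: 2 f^2 / Var(f)."""
        if A is None:
            A = self._vc_cov(tau2, sigma2)
        h = np.array([max(1e-4 * tau2, 1e-6 * sigma2),
                      max(1e-4 * sigma2, 1e-8)])

        def f(t2: float, s2: float) -> float:
            _, C = self.beta_cov(max(t2, 0.0), max(s2, 1e-12))
            return float(ell @ C @ ell)

        f0 = f(tau2, sigma2)
        g = np.array([
            (f(tau2 + h[0], sigma2) - f(max(tau2 - h[0], 0.0), sigma2))
            / (h[0] + min(tau2, h[0])),
            (f(tau2, sigma2 + h[1]) - f(tau2, sigma2 - h[1])) / (2 * h[1]),
        ])
        var_f = float(g @ A @ g)
        if var_f <= 0 or not np.isfinite(var_f):
            return float(self.n - self.p)
        df = 2.0 * f0 ** 2 / var_f
        return float(np.clip(df, 1.0, 1e7))


@dataclass
class SimpleSlope:
    """Conditional slope of z-SPIN at a fixed z-AQ moderator level."""

    level: float  # z-AQ at which the slope is evaluated
    label: str  # low / medium / high autistic traits
    B: float  # unstandardized slope
    se: float
    t: float
    df: float
    beta: float  # standardized: B * SD(z_spin) / SD(response)
    p: float


class EyeLMMResults:
    """REML fit of an :class:`EyeLMM` with Type III tests and simple slopes."""

    def __init__(self, model: "EyeLMM", tau2: float, sigma2: float,
                 converged: bool):
        self.model = model
        self.tau2 = tau2
        self.sigma2 = sigma2
        self.converged = converged
        self._reml = model._reml
        self.fe_params, self.cov_fe = self._reml.beta_cov(tau2, sigma2)
        self._A = None

    # lazily computed: the variance-component covariance needs ~9 REML
    # deviance evaluations
    @property
    def vc_cov(self) -> np.ndarray:
        if self._A is None:
            self._A = self._reml._vc_cov(self.tau2, self.sigma2)
        return self._A

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    def _term_slices(self) -> dict[str, list[int]]:
        di = self.model.design_info
        out = {}
        for name in di.term_names:
            sl = di.term_name_slices[name]
            out[name] = list(range(sl.start, sl.stop))
        return out

    def _contrast_df(self, ell: np.ndarray) -> float:
        if self.model.spec.df_method == "residual":
            return float(self._reml.n - self._reml.p)
        if self.model.spec.df_method == "satterthwaite":
            return self._reml.contrast_df(ell, self.tau2, self.sigma2, self.vc_cov)
        raise NotImplementedError(
            f"df_method {self.model.spec.df_method!r} not implemented; "
            "use 'satterthwaite' or 'residual'")

    def anova(self, terms: Sequence[str] | None = None) -> pd.DataFrame:
        """Type III F tests for fixed-effect terms (intercept omitted).

        With sum-to-zero factor coding the Type III test of a term is the
        Wald F test of its coefficient block. Multi-df denominator df follow
        the eigencontrast-averaging rule: each orthonormal contrast of the
        block gets its own Satterthwaite df, combined through their harmonic
        aggregate. ``terms`` restricts the table to the named terms.
        """
        rows = []
        for term, idx in self._term_slices().items():
            if term == "Intercept" or (terms is not None and term not in terms):
                continue
            q = len(idx)
            L = np.zeros((q, len(self.fe_params)))
            for r, c in enumerate(idx):
                L[r, c] = 1.0
            Lb = L @ self.fe_params
            M = L @ self.cov_fe @ L.T
            F = float(Lb @ np.linalg.solve(M, Lb)) / q
            if q == 1:
                ddf = self._contrast_df(L[0])
            else:
                evals, evecs = np.linalg.eigh(M)
                nus = []
                for k in range(q):
                    ell = evecs[:, k] @ L
                    nus.append(self._contrast_df(ell))
                good = [nu for nu in nus if nu > 2]
                if good:
                    E = sum(nu / (nu - 2) for nu in good)
                    ddf = 2 * E / (E - q) if E > q else float(min(nus))
                else:
                    ddf = float(min(nus))
            p = float(st.f.sf(F, q, ddf))
            rows.append({"term": term, "F": F, "num_df": q, "den_df": ddf, "p": p})
        return pd.DataFrame(rows).set_index("term")

    def _slope_contrast(self, level: float) -> np.ndarray:
        names = self.exog_names
        try:
            i_spin = names.index("z_spin")
            i_int = names.index("z_aq4:z_spin")
        except ValueError as exc:
            raise ValueError(
                "model must contain z_spin and z_aq4:z_spin terms") from exc
        ell = np.zeros(len(names))
        ell[i_spin] = 1.0
        ell[i_int] = level
        return ell

    def simple_slopes(self, levels: Sequence[float] = (-1.0, 0.0, 1.0),
                      ) -> list[SimpleSlope]:
        """Slope of z-SPIN at fixed z-AQ levels, marginal over emotion.

        With sum-to-zero emotion coding the emotion-specific slope terms
        average out across levels, so the marginal slope is
        b_spin + level * b_interaction.
        """
        frame = self.model.frame
        sd_x = frame["z_spin"].std(ddof=1)
        sd_y = frame[self.model.spec.response].std(ddof=1)
        labels = {-1.0: "low", 0.0: "medium", 1.0: "high"}
        out = []
        for a in levels:
            ell = self._slope_contrast(a)
            B = float(ell @ self.fe_params)
            se = float(np.sqrt(ell @ self.cov_fe @ ell))
            df = self._contrast_df(ell)
            tval = B / se
            out.append(SimpleSlope(
                level=a, label=labels.get(a, f"z={a:g}"), B=B, se=se, t=tval,
                df=df, beta=B * sd_x / sd_y,
                p=float(2 * st.t.sf(abs(tval), df))))
        return out

    def slope_difference_tests(self, levels: Sequence[float] = (-1.0, 0.0, 1.0),
                               ) -> pd.DataFrame:
        """Pairwise Wald tests comparing the SPIN slope across z-AQ levels.

        The slope difference between levels a and b is (a-b) times the
        interaction coefficient, so all pairs share the interaction's t
        statistic; the table makes the comparisons explicit.
        """
        rows = []
        for a, b in itertools.combinations(levels, 2):
            ell = self._slope_contrast(a) - self._slope_contrast(b)
            d = float(ell @ self.fe_params)
            se = float(np.sqrt(ell @ self.cov_fe @ ell))
            df = self._contrast_df(ell)
            tval = d / se
            rows.append({"level_a": a, "level_b": b, "diff": d, "se": se,
                         "t": tval, "df": df,
                         "p": float(2 * st.t.sf(abs(tval), df))})
        return pd.DataFrame(rows)

    def recentered_spin_coef(self, level: float) -> float:
        """z-SPIN coefficient after recentring z-AQ at ``level``.

        The recentred design is refit by GLS at the fitted variance
        components (an exact linear reparameterization), so this equals the
        simple slope to machine precision.
        """
        names = self.exog_names
        # substituting z_aq4 -> (z_aq4 - level) rewrites each column that
        # contains z_aq4 as itself minus `level` times its reduced-order
        # column (z_aq4 alone reduces to the intercept); columns without
        # z_aq4 are untouched, so sources are always original columns
        X = self.model.exog
        Xc = X.copy()
        for j, name in enumerate(names):
            parts = name.split(":")
            if "z_aq4" not in parts:
                continue
            rest = [p for p in parts if p != "z_aq4"]
            if not rest:
                target = "Intercept"
            else:
                target = next(nm for nm in names
                              if sorted(nm.split(":")) == sorted(rest))
            k = names.index(target)
            Xc[:, j] = X[:, j] - level * X[:, k]
        reml = self._reml
        Xc_ordered = Xc[np.argsort(self.model.group_codes, kind="stable")]
        beta, _ = reml.beta_cov(self.tau2, self.sigma2, X=Xc_ordered)
        return float(beta[names.index("z_spin")])

    def summary(self) -> str:
        lines = [
            f"Linear mixed model (REML): {self.model.spec.formula}",
            f"groups: {self.model.spec.groups} "
            f"(n_groups={len(self._reml.slices)}, n_obs={self._reml.n})",
            f"random-intercept var tau2={self.tau2:.5g}, "
            f"residual var sigma2={self.sigma2:.5g}, "
            f"converged={self.converged}",
            "",
            "Type III tests "
            f"({self.model.spec.df_method} denominator df):",
            self.anova().to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            "Simple slopes of z_spin by autistic-trait level:",
        ]
        for s in self.simple_slopes():
            lines.append(
                f"  {s.label:>6} (z_aq={s.level:+.0f}): B={s.B:+.4f} "
                f"SE={s.se:.4f} t({s.df:.1f})={s.t:+.3f} "
                f"beta={s.beta:+.3f} p={s.p:.4f}")
        return "\n".join(lines)


class EyeLMM:
    """Random-intercept LMM for one eye-looking measure.

    Parameters
    ----------
    data : tidy table with one row per analysis unit (trial or
        participant x emotion cell), carrying the response, ``z_aq4``,
        ``z_spin``, ``emotion``, ``sex`` and the grouping column.
    spec : model specification; defaults to the full factorial of
        z-AQ x z-SPIN x emotion plus a sex covariate.
    """

    def __init__(self, data: pd.DataFrame, spec: LMMSpec):
        self.spec = spec
        frame = data.dropna(subset=[spec.response]).reset_index(drop=True)
        if frame[spec.groups].nunique() < 2:
            raise ValueError("need at least 2 participants")
        self.frame = frame
        self._sm_model = smf.mixedlm(spec.formula, frame,
                                     groups=frame[spec.groups])
        self.design_info = self._sm_model.data.design_info
        self.exog = np.asarray(self._sm_model.exog, dtype=float)
        self.endog = np.asarray(self._sm_model.endog, dtype=float)
        self.exog_names = list(self._sm_model.exog_names)
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            _, R = np.linalg.qr(self.exog)
            diag = np.abs(np.diag(R))
            aliased = [self.exog_names[j] for j in np.where(
                diag < 1e-8 * diag.max())[0]]
            raise ValueError(f"design matrix is rank deficient; aliased "
                             f"columns: {aliased}")
        self.group_codes = pd.factorize(frame[spec.groups], sort=True)[0]
        self._reml = _RandomInterceptREML(self.exog, self.endog,
                                          self.group_codes)

    @classmethod
    def from_metrics(cls, data: pd.DataFrame, response: str,
                     df_method: str = "satterthwaite") -> "EyeLMM":
        return cls(data, LMMSpec(response=response, df_method=df_method))

    def fit(self) -> EyeLMMResults:
        """REML fit; non-convergence is flagged on the results, not hidden.

        When the general optimizer fails outright (a known failure mode at
        the tau2 = 0 boundary) the closed-form profiled REML search takes
        over; that path cannot fail for this model class.
        """
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = self._sm_model.fit(reml=True)
            tau2 = float(np.asarray(res.cov_re)[0, 0])
            sigma2 = float(res.scale)
            converged = bool(getattr(res, "converged", True))
        except (np.linalg.LinAlgError, ValueError):
            tau2, sigma2 = self._reml.profile_fit()
            converged = True
        return EyeLMMResults(self, max(tau2, 0.0), sigma2, converged)


def fit_lmm(data: pd.DataFrame, spec: LMMSpec) -> EyeLMMResults:
    """Convenience wrapper: build and fit an :class:`EyeLMM`."""
    return EyeLMM(data, spec).fit()


def simple_slopes(fit: EyeLMMResults,
                  levels: Sequence[float] = (-1.0, 0.0, 1.0)) -> list[SimpleSlope]:
    return fit.simple_slopes(levels)


# ---------------------------------------------------------------------------
# temporal cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start: int  # epoch index, inclusive
    end: int  # epoch index, inclusive
    mass: float  # sum of t values inside the cluster
    p: float


@dataclass
class ClusterPermutationResult:
    t_obs: np.ndarray
    t_crit: np.ndarray
    clusters: list[Cluster]
    n_perm: int
    exact: bool
    cluster_alpha: float
    epoch_times: np.ndarray | None = None

    def summary(self) -> str:
        lines = [f"Cluster permutation test: {len(self.clusters)} cluster(s), "
                 f"{'exact enumeration' if self.exact else f'{self.n_perm} permutations'}"]
        for c in self.clusters:
            span = (f"epochs {c.start}..{c.end}" if self.epoch_times is None
                    else f"{self.epoch_times[c.start]:.0f}-"
                         f"{self.epoch_times[c.end]:.0f} ms")
            lines.append(f"  {span}: mass={c.mass:+.2f}, p={c.p:.4f}")
        if not self.clusters:
            lines.append("  no supra-threshold clusters")
        return "\n".join(lines)


def _welch_t(curves: np.ndarray, in_g1: np.ndarray,
             ) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware per-epoch Welch t and its per-epoch df.

    Epochs with no face-looking for a participant are NaN in that
    participant's curve and are dropped pairwise.
    """
    g1 = curves[in_g1]
    g2 = curves[~in_g1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        n1 = np.sum(~np.isnan(g1), axis=0).astype(float)
        n2 = np.sum(~np.isnan(g2), axis=0).astype(float)
        m1, m2 = np.nanmean(g1, axis=0), np.nanmean(g2, axis=0)
        v1, v2 = np.nanvar(g1, axis=0, ddof=1), np.nanvar(g2, axis=0, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(t)
    t = np.where(bad, np.nan, t)
    df = np.where(bad, np.nan, df)
    return t, df


def _find_clusters(t: np.ndarray, crit: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal contiguous runs of same-sign supra-threshold t values."""
    out = []
    n = len(t)
    i = 0
    while i < n:
        if not np.isfinite(t[i]) or abs(t[i]) <= crit[i]:
            i += 1
            continue
        sign = np.sign(t[i])
        j = i
        while (j + 1 < n and np.isfinite(t[j + 1])
               and abs(t[j + 1]) > crit[j + 1] and np.sign(t[j + 1]) == sign):
            j += 1
        out.append((i, j, float(np.nansum(t[i:j + 1]))))
        i = j + 1
    return out


def _max_cluster_mass(curves: np.ndarray, in_g1: np.ndarray,
                      alpha: float) -> float:
    t, df = _welch_t(curves, in_g1)
    crit = st.t.ppf(1 - alpha / 2, df)
    clusters = _find_clusters(t, crit)
    return max((abs(m) for _, _, m in clusters), default=0.0)


class ClusterPermutationTest:
    """Two-group comparison of eye-looking time courses.

    Parameters
    ----------
    curves : participants x epochs array (or DataFrame from
        :func:`traitgaze.metrics.participant_epoch_curves`), one averaged
        curve per participant.
    labels : group label per participant (exactly two distinct values,
        each with at least two members).
    """

    def __init__(self, curves: pd.DataFrame | np.ndarray, labels: Sequence):
        if isinstance(curves, pd.DataFrame):
            self.epoch_times = curves.columns.to_numpy(dtype=float)
            self.curves = curves.to_numpy(dtype=float)
        else:
            self.epoch_times = None
            self.curves = np.asarray(curves, dtype=float)
        labels = np.asarray(labels)
        if len(labels) != self.curves.shape[0]:
            raise ValueError("one label per participant curve required")
        uniq = np.unique(labels)
        if len(uniq) != 2:
            raise ValueError(f"exactly two groups required, got {list(uniq)}")
        self.in_g1 = labels == uniq[0]
        n1, n2 = int(self.in_g1.sum()), int((~self.in_g1).sum())
        if min(n1, n2) < 2:
            raise ValueError("each group needs at least 2 participants")
        self.group_labels = (uniq[0], uniq[1])

    def fit(self, n_perm: int = 1000, cluster_alpha: float = 0.05,
            seed: int | None = None, exact_limit: int = 100_000,
            ) -> ClusterPermutationResult:
        """Run the test.

        When the number of distinct relabellings C(n, n1) is at most
        ``exact_limit`` the permutation distribution is enumerated exactly
        (p = share of relabellings, including the identity, whose maximum
        cluster mass reaches the observed one); otherwise ``n_perm`` random
        relabellings give Monte-Carlo p = (1 + #exceedances) / (1 + n_perm).
        """
        if n_perm < 100:
            warnings.warn("n_perm < 100 gives a very coarse permutation p",
                          stacklevel=2)
        curves = self.curves
        n = curves.shape[0]
        n1 = int(self.in_g1.sum())
        t_obs, df_obs = _welch_t(curves, self.in_g1)
        crit = st.t.ppf(1 - cluster_alpha / 2, df_obs)
        found = _find_clusters(t_obs, crit)

        n_combos = int(comb(n, n1, exact=True))
        exact = n_combos <= exact_limit
        null_max: list[float] = []
        if exact:
            for combo in itertools.combinations(range(n), n1):
                mask = np.zeros(n, dtype=bool)
                mask[list(combo)] = True
                null_max.append(_max_cluster_mass(curves, mask, cluster_alpha))
            null_max_arr = np.array(null_max)
            n_eff = n_combos
        else:
            rng = np.random.default_rng(seed)
            for _ in range(n_perm):
                mask = np.zeros(n, dtype=bool)
                mask[rng.choice(n, size=n1, replace=False)] = True
                null_max.append(_max_cluster_mass(curves, mask, cluster_alpha))
            null_max_arr = np.array(null_max)
            n_eff = n_perm

        clusters = []
        for (i, j, mass) in found:
            exceed = int(np.sum(null_max_arr >= abs(mass) - 1e-12))
            if exact:
                p = exceed / n_eff
            else:
                p = (1 + exceed) / (1 + n_eff)
            clusters.append(Cluster(start=i, end=j, mass=mass, p=p))
        return ClusterPermutationResult(
            t_obs=t_obs, t_crit=crit, clusters=clusters,
            n_perm=n_eff, exact=exact, cluster_alpha=cluster_alpha,
            epoch_times=self.epoch_times)


def cluster_permutation(curves: pd.DataFrame | np.ndarray, labels: Sequence,
                        n_perm: int = 1000, cluster_alpha: float = 0.05,
                        seed: int | None = None) -> ClusterPermutationResult:
    """Convenience wrapper around :class:`ClusterPermutationTest`."""
    return ClusterPermutationTest(curves, labels).fit(
        n_perm=n_perm, cluster_alpha=cluster_alpha, seed=seed)
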