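"""L1-penalized stratified Cox proportional-hazards regression.

Mortality-signature extraction: an L1 (LASSO) penalty is applied to the
protein covariates while adjustment covariates (sex) stay unpenalized and
the baseline hazard is stratified by participant group, so each stratum
keeps its own unspecified baseline. The optimizer is glmnet-style cyclic
coordinate descent on the quadratic (IRLS) approximation of the stratified
Breslow partial likelihood:

    minimize  -(1/n) l(beta, gamma) + lambda * sum_j |beta_j|

with warm starts along a decreasing log-spaced lambda grid. The penalty
weight is chosen by 10-fold cross-validation on the Verweij-van Houwelingen
partial-likelihood deviance (both the minimizing lambda and the 1-SE rule
are reported), and selection robustness is assessed by rerunning the whole
cross-validated selection on stratified bootstrap resamples: proteins
selected in at least half the resamples are "robustly selected".

Young Controls are excluded from these analyses upstream (no events).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .containers import NPXMatrix, ValidationError

logger = logging.getLogger(__name__)

_WEIGHT_FLOOR = 1e-10


@njit(cache=True)
def _cd_sweeps(G, cvec, theta, Gq, diag, lam, m, n_sweeps, inner_tol):
    """Run up to ``n_sweeps`` cyclic coordinate-descent sweeps in place on
    (1/2) t'Gt - c't + lam*|t_1..m|; returns the last sweep's max update."""
    maxd = 0.0
    for _ in range(n_sweeps):
        maxd = 0.0
        for j in range(theta.shape[0]):
            dj = diag[j]
            if dj <= 0.0:
                continue
            num = cvec[j] - Gq[j] + dj * theta[j]
            if j < m:
                if num > lam:
                    new = (num - lam) / dj
                elif num < -lam:
                    new = (num + lam) / dj
                else:
                    new = 0.0
            else:
                new = num / dj
            d = new - theta[j]
            if d != 0.0:
                for i in range(Gq.shape[0]):
                    Gq[i] += G[i, j] * d
                theta[j] = new
                if abs(d) > maxd:
                    maxd = abs(d)
        if maxd < inner_tol:
            break
    return maxd


@njit(cache=True)
def _breslow_quantities_kernel(eta, event, firstpos, d, ndb):
    """Breslow log-likelihood, per-observation gradient and IRLS weight for
    one stratum, observations sorted ascending by time."""
    n = eta.shape[0]
    K = firstpos.shape[0]
    mx = eta[0]
    for i in range(1, n):
        if eta[i] > mx:
            mx = eta[i]
    e = np.exp(eta - mx)
    s0k = np.zeros(K)
    s0 = 0.0
    k = K - 1
    for i in range(n - 1, -1, -1):
        s0 += e[i]
        while k >= 0 and firstpos[k] == i:
            s0k[k] = s0
            k -= 1
    ll = 0.0
    cuma = np.zeros(K + 1)
    cumb = np.zeros(K + 1)
    for kk in range(K):
        cuma[kk + 1] = cuma[kk] + d[kk] / s0k[kk]
        cumb[kk + 1] = cumb[kk] + d[kk] / (s0k[kk] * s0k[kk])
        ll -= d[kk] * np.log(s0k[kk])
    g = np.empty(n)
    w = np.empty(n)
    for i in range(n):
        Ai = cuma[ndb[i]]
        Bi = cumb[ndb[i]]
        if event[i]:
            ll += eta[i] - mx
            g[i] = 1.0 - e[i] * Ai
        else:
            g[i] = -e[i] * Ai
        w[i] = e[i] * Ai - e[i] * e[i] * Bi
    return ll, g, w


@njit(cache=True)
def _breslow_hessian_kernel(e, C, firstpos, d):
    """Negative Hessian of the Breslow log-likelihood wrt the coefficients
    of the (sorted) covariate columns ``C``; one stratum."""
    n, m = C.shape
    K = firstpos.shape[0]
    H = np.zeros((m, m))
    s0 = 0.0
    s1 = np.zeros(m)
    s2 = np.zeros((m, m))
    k = K - 1
    for i in range(n - 1, -1, -1):
        ei = e[i]
        s0 += ei
        for a in range(m):
            va = ei * C[i, a]
            s1[a] += va
            for b in range(m):
                s2[a, b] += va * C[i, b]
        while k >= 0 and firstpos[k] == i:
            dk = d[k]
            for a in range(m):
                mua = s1[a] / s0
                for b in range(m):
                    H[a, b] += dk * (s2[a, b] / s0 - mua * s1[b] / s0)
            k -= 1
    return H


class _Stratum:
    """Static per-stratum structures for the Breslow partial likelihood."""

    def __init__(self, idx: np.ndarray, time: np.ndarray, event: np.ndarray):
        self.idx = idx  # positions in the full data
        order = np.argsort(time, kind="stable")
        self.sort = order
        self.pos = idx[order]  # full-data positions in sorted order
        self.time = time[order]
        self.event = event[order].astype(np.bool_)
        # a stratum without events contributes exactly zero to the partial
        # likelihood; it is kept but inert (relevant for CV training folds)
        death_times = self.time[self.event]
        self.ud, d = np.unique(death_times, return_counts=True)
        self.d = d.astype(np.float64)
        # first sorted position whose time >= each unique death time
        self.firstpos = np.searchsorted(self.time, self.ud, side="left")
        # for each observation: number of unique death times <= its time
        self.n_deaths_before = np.searchsorted(self.ud, self.time, side="right")

    def quantities(self, eta_full: np.ndarray):
        """(loglik, per-obs gradient, per-obs IRLS weight) in full-data order."""
        eta = np.ascontiguousarray(eta_full[self.pos])
        ll, g, w = _breslow_quantities_kernel(
            eta, self.event, self.firstpos, self.d, self.n_deaths_before
        )
        g_full = np.zeros_like(eta_full)
        w_full = np.zeros_like(eta_full)
        g_full[self.pos] = g
        w_full[self.pos] = w
        return float(ll), g_full, w_full

    def hessian(self, eta_full: np.ndarray, C_full: np.ndarray) -> np.ndarray:
        """Negative Hessian of the Breslow log-likelihood wrt the linear
        predictor coefficients of the columns in ``C_full`` (m x m)."""
        eta = eta_full[self.pos]
        e = np.exp(eta - eta.max())
        C = np.ascontiguousarray(C_full[self.pos])
        return _breslow_hessian_kernel(e, C, self.firstpos, self.d)


@dataclass
class SignatureResults:
    """Coefficient path, CV curve, and the selected protein sets."""

    protein_ids: list[str]
    unpenalized_names: list[str]
    lambdas: np.ndarray
    coef_path: pd.DataFrame  # proteins x lambdas (standardized scale)
    gamma_path: pd.DataFrame  # unpenalized covariates x lambdas
    cv_table: pd.DataFrame | None = None  # lambda, mean deviance, se
    lambda_min: float | None = None
    lambda_1se: float | None = None
    selection_rule: str = "lambda_min"

    def coefficients(self, lam: float) -> pd.Series:
        j = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.coef_path.iloc[:, j]

    def selected(self, rule: str | None = None) -> set[str]:
        rule = rule or self.selection_rule
        lam = {"lambda_min": self.lambda_min, "lambda_1se": self.lambda_1se}[rule]
        if lam is None:
            raise ValidationError("cross-validation has not been run")
        coefs = self.coefficients(lam)
        return set(coefs.index[coefs != 0.0])

    def summary(self) -> str:
        lines = [
            "Stratified Cox-LASSO mortality signature",
            f"  proteins (penalized)     {len(self.protein_ids)}",
            f"  unpenalized covariates   {self.unpenalized_names}",
            f"  lambda grid              {len(self.lambdas)} values "
            f"[{self.lambdas.min():.4g}, {self.lambdas.max():.4g}]",
        ]
        if self.lambda_min is not None:
            for rule in ("lambda_min", "lambda_1se"):
                lam = getattr(self, rule)
                sel = sorted(self.selected(rule))
                lines.append(f"  {rule} = {lam:.4g}: {len(sel)} proteins {sel}")
            lines.append(f"  selection rule in force: {self.selection_rule}")
        return "\n".join(lines)


@dataclass
class BootstrapResults:
    """Stability-selection frequencies across stratified bootstrap resamples."""

    frequencies: pd.Series  # protein -> fraction of resamples selected
    threshold: float
    n_bootstrap: int
    n_redraws: int = 0
    selection_rule: str = "lambda_min"

    @property
    def robust(self) -> set[str]:
        return set(self.frequencies.index[self.frequencies >= self.threshold])

    def summary(self) -> str:
        top = self.frequencies.sort_values(ascending=False).head(10)
        lines = [
            f"Bootstrap stability selection ({self.n_bootstrap} stratified "
            f"resamples, rule={self.selection_rule})",
            f"  robust proteins (frequency >= {self.threshold:g}): "
            f"{sorted(self.robust)}",
            f"  degenerate resamples redrawn: {self.n_redraws}",
            "  top selection frequencies:",
        ]
        lines += [f"    {p}: {f:.3f}" for p, f in top.items()]
        return "\n".join(lines)


class CoxLassoSignature:
    """Stratified Cox model with an L1 penalty on the protein covariates.

    Parameters
    ----------
    X : DataFrame, samples x proteins
        Penalized covariates; standardized to mean 0 / SD 1 internally
        (coefficients are then log hazard ratios per SD of NPX).
    time, event : array-like
        Follow-up time (years) and event indicator.
    strata : array-like
        Stratum label per sample (baseline hazard is separate per level).
    unpenalized : DataFrame or None
        Adjustment covariates estimated without penalty (e.g. a 0/1 sex
        indicator).
    """

    def __init__(
        self,
        X: pd.DataFrame,
        time,
        event,
        strata,
        unpenalized: pd.DataFrame | None = None,
        standardize: bool = True,
    ):
        self.protein_ids = list(X.columns)
        Xv = X.to_numpy(dtype=float)
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        self.strata = np.asarray(strata)
        if not (len(Xv) == len(self.time) == len(self.event) == len(self.strata)):
            raise ValidationError("X, time, event and strata must align")
        if not np.isfinite(Xv).all() or not np.isfinite(self.time).all():
            raise ValidationError("non-finite inputs")
        if self.event.sum() == 0:
            raise ValidationError("no events in the data")
        if standardize:
            mu = Xv.mean(axis=0)
            sd = Xv.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xv = (Xv - mu) / sd
        self.X = Xv
        if unpenalized is not None and unpenalized.shape[1] > 0:
            self.unpenalized_names = list(unpenalized.columns)
            self.U = unpenalized.to_numpy(dtype=float)
        else:
            self.unpenalized_names = []
            self.U = np.empty((len(self.time), 0))
        self.n = len(self.time)
        self._strata = [
            _Stratum(np.flatnonzero(self.strata == s), self.time[self.strata == s],
                     self.event[self.strata == s])
            for s in np.unique(self.strata)
        ]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_cohort(
        cls,
        matrix: NPXMatrix,
        cohort: pd.DataFrame,
        proteins: list[str] | None = None,
        groups: tuple[str, ...] = ("OC", "OP"),
        standardize: bool = True,
    ) -> "CoxLassoSignature":
        """Build the survival model from a cohort, excluding Young Controls."""
        keep = cohort.index[cohort["group"].isin(groups)]
        keep = [s for s in keep if s in matrix.sample_ids]
        sub = cohort.loc[keep]
        X = matrix.data.loc[keep, proteins or matrix.protein_ids]
        unpen = pd.DataFrame({"sex_male": (sub["sex"] == "M").astype(float)},
                             index=keep)
        return cls(
            X,
            sub["survival_time"],
            sub["event"],
            sub["group"],
            unpenalized=unpen,
            standardize=standardize,
        )

    # -- likelihood machinery ----------------------------------------------

    def _quantities(self, eta: np.ndarray):
        loglik, g, w = 0.0, np.zeros(self.n), np.zeros(self.n)
        for st in self._strata:
            ll_s, g_s, w_s = st.quantities(eta)
            loglik += ll_s
            g += g_s
            w += w_s
        return loglik, g, w

    def loglik(self, beta: np.ndarray, gamma: np.ndarray | None = None) -> float:
        eta = self.X @ beta
        if gamma is not None and self.U.shape[1]:
            eta = eta + self.U @ gamma
        return self._quantities(eta)[0]

    def score(self, beta: np.ndarray, gamma: np.ndarray | None = None) -> np.ndarray:
        """(1/n) gradient of the log partial likelihood wrt beta."""
        eta = self.X @ beta
        if gamma is not None and self.U.shape[1]:
            eta = eta + self.U @ gamma
        _, g, _ = self._quantities(eta)
        return self.X.T @ g / self.n

    # -- fitting -------------------------------------------------------------

    def _fit_unpenalized(self, tol: float = 1e-9, max_iter: int = 200) -> np.ndarray:
        """Newton fit of the unpenalized covariates alone (diagonal-Hessian CD)."""
        q = self.U.shape[1]
        gamma = np.zeros(q)
        if q == 0:
            return gamma
        for _ in range(max_iter):
            eta = self.U @ gamma
            _, g, w = self._quantities(eta)
            pos = w > _WEIGHT_FLOOR
            z = np.where(pos, eta + g / np.where(pos, w, 1.0), eta)
            wn = w / self.n
            new = gamma.copy()
            r = z - eta
            for j in range(q):
                denom = wn @ self.U[:, j] ** 2
                if denom <= 0:
                    continue
                num = denom * new[j] + self.U[:, j] @ (wn * r)
                nj = num / denom
                r -= self.U[:, j] * (nj - new[j])
                new[j] = nj
            delta = np.abs(new - gamma).max()
            gamma = new
            if delta < tol:
                break
        return gamma

    def lambda_max(self) -> float:
        """Smallest lambda that zeroes every penalized coefficient.

        Computed from the score at beta = 0 with the unpenalized covariates
        at their own partial-likelihood fit.
        """
        gamma = self._fit_unpenalized()
        return float(np.abs(self.score(np.zeros(len(self.protein_ids)), gamma)).max())

    def lambda_grid(self, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
        lmax = self.lambda_max()
        if lmax <= 0:
            lmax = 1e-3
        return np.geomspace(lmax, lmax * min_ratio, n_lambda)

    @staticmethod
    def _cd_quadratic(G, cvec, theta0, lam, m, inner_tol=1e-10, max_sweeps=10000):
        """Cyclic coordinate descent on (1/2) t'Gt - c't + lam*|t_1..m|;
        coordinates beyond ``m`` are unpenalized.

        On strongly correlated designs plain CD converges slowly, so every
        few sweeps the linear system implied by the current support and sign
        pattern is solved directly and accepted if it satisfies the KKT
        conditions of the quadratic subproblem.
        """
        theta = theta0.copy()
        Gq = G @ theta
        diag = np.diag(G)
        n_all = len(theta)

        def try_direct():
            nz = [j for j in range(n_all) if j >= m or theta[j] != 0.0]
            if not nz:
                return None
            sgn = np.array([np.sign(theta[j]) if j < m else 0.0 for j in nz])
            A = G[np.ix_(nz, nz)]
            b = cvec[nz] - lam * sgn
            try:
                sol = np.linalg.solve(A + 1e-12 * np.eye(len(nz)), b)
            except np.linalg.LinAlgError:
                return None
            if np.any(sol * sgn < 0.0):  # sign pattern inconsistent
                return None
            cand = np.zeros(n_all)
            cand[nz] = sol
            resid = cvec - G @ cand
            pen = resid[:m]
            zero_pen = cand[:m] == 0.0
            if np.any(np.abs(pen[zero_pen]) > lam + 1e-9):
                return None
            if np.any(np.abs(pen[~zero_pen] - lam * np.sign(cand[:m][~zero_pen]))
                      > 1e-8):
                return None
            if m < n_all and np.any(np.abs(resid[m:]) > 1e-8):
                return None
            return cand

        G = np.ascontiguousarray(G)
        diag = np.ascontiguousarray(diag)
        for _round in range(max_sweeps // 3 + 1):
            maxd = _cd_sweeps(G, cvec, theta, Gq, diag, lam, m, 3, inner_tol)
            if maxd < inner_tol:
                break
            if _round >= 1:
                cand = try_direct()
                if cand is not None:
                    return cand
        return theta

    def _penalized_obj(self, eta, beta, lam) -> float:
        return -self._quantities(eta)[0] / self.n + lam * np.abs(beta).sum()

    def _fit_one(self, lam, beta, gamma, tol=1e-7, max_iter=100):
        """Fit one lambda by proximal Newton steps (full Breslow Hessian on
        the active columns, coordinate descent on the penalized quadratic)
        with vectorized KKT screening of the zero coordinates."""
        X, U = self.X, self.U
        q = U.shape[1]
        eta = X @ beta + (U @ gamma if q else 0.0)
        active = list(np.flatnonzero(beta))
        ll, g, _ = self._quantities(eta)
        for _screen in range(len(beta) + 1):
            for _ in range(max_iter):
                m = len(active)
                C = np.concatenate([X[:, active], U], axis=1) if q else X[:, active]
                grad = C.T @ g / self.n
                H = sum(st.hessian(eta, C) for st in self._strata) / self.n
                theta = np.concatenate([beta[active], gamma])
                cvec = grad + H @ theta
                new_theta = self._cd_quadratic(H, cvec, theta, lam, m)
                # step-halving safeguard on the penalized objective
                obj0 = -ll / self.n + lam * np.abs(beta).sum()
                step = 1.0
                for _half in range(30):
                    cand = theta + step * (new_theta - theta)
                    beta_c = beta.copy()
                    beta_c[active] = cand[:m]
                    eta_c = X @ beta_c + (U @ cand[m:] if q else 0.0)
                    ll_c, g_c, _ = self._quantities(eta_c)
                    if -ll_c / self.n + lam * np.abs(beta_c).sum() <= obj0 + 1e-12:
                        break
                    step /= 2.0
                delta = float(np.abs(cand - theta).max(initial=0.0))
                beta, gamma, eta, ll, g = beta_c, cand[m:], eta_c, ll_c, g_c
                if delta < tol:
                    break
            # KKT screening over all penalized coordinates (reuses the
            # gradient already evaluated at the current coefficients)
            score = X.T @ g / self.n
            active_set = set(active)
            new = [j for j in
                   np.flatnonzero((np.abs(score) > lam + 1e-10) & (beta == 0.0))
                   if j not in active_set]
            if not new:
                break
            active.extend(new)
        return beta, gamma

    def fit(
        self,
        lambdas: np.ndarray | None = None,
        n_lambda: int = 100,
        min_ratio: float = 0.01,
    ) -> SignatureResults:
        """Fit the full coefficient path with warm starts."""
        if lambdas is None:
            lambdas = self.lambda_grid(n_lambda, min_ratio)
        lambdas = np.asarray(lambdas, dtype=float)
        if np.any(np.diff(lambdas) > 0):
            raise ValidationError("lambda grid must be decreasing")
        p, q = len(self.protein_ids), self.U.shape[1]
        beta = np.zeros(p)
        gamma = self._fit_unpenalized() if q else np.zeros(0)
        coef = np.zeros((p, len(lambdas)))
        gam = np.zeros((q, len(lambdas)))
        for i, lam in enumerate(lambdas):
            beta, gamma = self._fit_one(lam, beta, gamma)
            coef[:, i] = beta
            gam[:, i] = gamma
        return SignatureResults(
            protein_ids=self.protein_ids,
            unpenalized_names=self.unpenalized_names,
            lambdas=lambdas,
            coef_path=pd.DataFrame(coef, index=self.protein_ids, columns=lambdas),
            gamma_path=pd.DataFrame(gam, index=self.unpenalized_names, columns=lambdas),
        )

    def kkt_violations(
        self, beta: np.ndarray, gamma: np.ndarray, lam: float, tol: float = 1e-5
    ) -> int:
        """Count KKT violations at a solution: |score_j| <= lam for zero
        coefficients, score_j = lam * sign(beta_j) for active ones."""
        s = self.score(beta, gamma if len(gamma) else None)
        viol = 0
        for j, b in enumerate(beta):
            if b == 0.0:
                viol += abs(s[j]) > lam + tol
            else:
                viol += abs(s[j] - lam * np.sign(b)) > tol
        return int(viol)

    # -- cross-validation ----------------------------------------------------

    def _fold_assignment(self, n_folds: int, rng: np.random.Generator) -> np.ndarray:
        """Folds stratified jointly by (stratum, event status)."""
        folds = np.zeros(self.n, dtype=int)
        for s in np.unique(self.strata):
            for e in (0, 1):
                idx = np.flatnonzero((self.strata == s) & (self.event == e))
                rng.shuffle(idx)
                folds[idx] = np.arange(len(idx)) % n_folds
        return folds

    def _submodel(self, mask: np.ndarray) -> "CoxLassoSignature":
        X = pd.DataFrame(self.X[mask], columns=self.protein_ids)
        U = (
            pd.DataFrame(self.U[mask], columns=self.unpenalized_names)
            if self.U.shape[1]
            else None
        )
        # X is already on the standardized scale; do not re-center subsets
        return CoxLassoSignature(
            X, self.time[mask], self.event[mask], self.strata[mask],
            unpenalized=U, standardize=False,
        )

    def cross_validate(
        self,
        n_folds: int = 10,
        seed: int = 0,
        lambdas: np.ndarray | None = None,
        n_lambda: int = 100,
        min_ratio: float = 0.01,
        selection_rule: str = "lambda_min",
    ) -> SignatureResults:
        """Choose lambda by K-fold CV on the partial-likelihood deviance.

        The held-out deviance uses the Verweij-van Houwelingen contrast:
        for fold k with coefficients fitted on the complement,
        dev_k = -2 * (l_full(beta) - l_train(beta)). Both the minimizing
        lambda and the largest lambda within one SE of the minimum are
        recorded.
        """
        if selection_rule not in {"lambda_min", "lambda_1se"}:
            raise ValidationError("selection_rule must be lambda_min or lambda_1se")
        if lambdas is None:
            lambdas = self.lambda_grid(n_lambda, min_ratio)
        rng = np.random.default_rng(seed)
        folds = self._fold_assignment(n_folds, rng)
        dev = np.zeros((n_folds, len(lambdas)))
        for k in range(n_folds):
            train = folds != k
            if self.event[~train].sum() == 0:
                raise ValidationError(f"fold {k} holds out no events")
            sub = self._submodel(train)
            path = sub.fit(lambdas=lambdas)
            for i in range(len(lambdas)):
                beta = path.coef_path.iloc[:, i].to_numpy()
                gamma = path.gamma_path.iloc[:, i].to_numpy()
                ll_full = self.loglik(beta, gamma if len(gamma) else None)
                ll_train = sub.loglik(beta, gamma if len(gamma) else None)
                dev[k, i] = -2.0 * (ll_full - ll_train)
        mean = dev.mean(axis=0)
        se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        i_min = int(np.argmin(mean))
        lambda_min = float(lambdas[i_min])
        within = mean <= mean[i_min] + se[i_min]
        lambda_1se = float(lambdas[np.flatnonzero(within).min()])

        path = self.fit(lambdas=lambdas)
        path.cv_table = pd.DataFrame(
            {"lambda": lambdas, "mean_deviance": mean, "se_deviance": se}
        )
        path.lambda_min = lambda_min
        path.lambda_1se = lambda_1se
        path.selection_rule = selection_rule
        return path

    # -- bootstrap stability -------------------------------------------------

    def bootstrap_stability(
        self,
        n_bootstrap: int = 1000,
        threshold: float = 0.5,
        n_folds: int = 10,
        n_lambda: int = 100,
        selection_rule: str = "lambda_min",
        seed: int = 0,
        max_redraws: int = 1000,
    ) -> BootstrapResults:
        """Rerun the full CV selection on stratified bootstrap resamples.

        Each resample draws every stratum's samples with replacement at the
        original stratum size; resamples where a stratum loses all its
        events are redrawn (logged) so the resample count stays exact.
        """
        if not 0 < threshold <= 1:
            raise ValidationError("threshold must be in (0, 1]")
        rng = np.random.default_rng(seed)
        counts = pd.Series(0, index=self.protein_ids, dtype=float)
        n_redraws = 0
        stratum_idx = {s: np.flatnonzero(self.strata == s)
                       for s in np.unique(self.strata)}
        # the redraw rule only applies to strata that have events at all;
        # an event-free stratum is inert in the partial likelihood
        needs_events = {s: self.event[ix].sum() > 0 for s, ix in stratum_idx.items()}
        for b in range(n_bootstrap):
            for attempt in range(max_redraws):
                draws = {s: rng.choice(ix, size=len(ix), replace=True)
                         for s, ix in stratum_idx.items()}
                if all(self.event[d].sum() > 0
                       for s, d in draws.items() if needs_events[s]):
                    idx = np.concatenate(list(draws.values()))
                    break
                n_redraws += 1
            else:
                raise ValidationError("could not draw a non-degenerate resample")
            X = pd.DataFrame(self.X[idx], columns=self.protein_ids)
            U = (
                pd.DataFrame(self.U[idx], columns=self.unpenalized_names)
                if self.U.shape[1]
                else None
            )
            model = CoxLassoSignature(
                X, self.time[idx], self.event[idx], self.strata[idx],
                unpenalized=U, standardize=True,
            )
            res = model.cross_validate(
                n_folds=n_folds,
                seed=int(rng.integers(2**31)),
                n_lambda=n_lambda,
                selection_rule=selection_rule,
            )
            for protein in res.selected(selection_rule):
                counts[protein] += 1
        if n_redraws:
            logger.info("redrew %d degenerate bootstrap resamples", n_redraws)
        return BootstrapResults(
            frequencies=counts / n_bootstrap,
            threshold=threshold,
            n_bootstrap=n_bootstrap,
            n_redraws=n_redraws,
            selection_rule=selection_rule,
        )
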