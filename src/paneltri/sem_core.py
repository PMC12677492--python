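"""Maximum-likelihood covariance-structure (SEM) engine.

Models are written in RAM form.  Let ``A`` collect directed paths
(``A[i, j]`` = path from variable *j* to variable *i*), ``S`` the
covariances among exogenous parts/disturbances, and ``F`` the selection
matrix picking the observed rows.  The model-implied covariance of the
observed variables is::

    Sigma(theta) = F (I - A)^{-1} S (I - A)^{-T} F^T

Free parameters are string labels placed in the templates; repeating a
label imposes an equality constraint.  Estimation minimises the normal-
theory ML discrepancy

    F_ML = ln|Sigma| + tr(S_sample Sigma^{-1}) - ln|S_sample| - p

(optionally plus the mean term) with an analytic gradient; the model
chi-square is ``(n - 1) * F_ML`` and standard errors come from the inverse
observed information.  Standardization uses model-implied variances of all
variables (the "std.all" convention), with delta-method standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

Entry = float | str  # fixed value or free-parameter label

_PENALTY = 1e12


class IdentificationError(ValueError):
    """Raised when a model cannot be estimated (df < 0, bad layout)."""


class NonRecursiveError(np.linalg.LinAlgError):
    """Raised when (I - A) is singular, i.e. a feedback loop with unit gain."""


# ---------------------------------------------------------------------------
# sample moments
# ---------------------------------------------------------------------------

@dataclass
class SampleMoments:
    """Covariance matrix, mean vector and sample size summarising a dataset."""

    cov: np.ndarray
    mean: np.ndarray
    n: int
    var_names: list[str]

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        p = self.cov.shape[0]
        if self.cov.shape != (p, p):
            raise ValueError("cov must be square")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)
        if self.mean.shape != (p,):
            raise ValueError("mean length must match cov")
        if len(self.var_names) != p:
            raise ValueError("var_names length must match cov")
        if self.n < p + 1:
            raise ValueError(f"n={self.n} too small for p={p} variables")

    @property
    def p(self) -> int:
        return self.cov.shape[0]

    def is_pd(self) -> bool:
        try:
            np.linalg.cholesky(self.cov)
            return True
        except np.linalg.LinAlgError:
            return False

    @classmethod
    def from_data(cls, df: pd.DataFrame, columns: Sequence[str] | None = None) -> "SampleMoments":
        """Listwise-complete moments (denominator n - 1) from a wide frame."""
        if columns is not None:
            df = df[list(columns)]
        df = df.dropna()
        n = len(df)
        x = df.to_numpy(dtype=float)
        return cls(cov=np.cov(x, rowvar=False, ddof=1), mean=x.mean(axis=0),
                   n=n, var_names=list(df.columns))

    def reorder(self, names: Sequence[str]) -> "SampleMoments":
        idx = [self.var_names.index(v) for v in names]
        return SampleMoments(self.cov[np.ix_(idx, idx)], self.mean[idx], self.n, list(names))

    def to_csv(self, path) -> None:
        out = pd.DataFrame(self.cov, index=self.var_names, columns=self.var_names)
        out.insert(0, "mean", self.mean)
        out.insert(0, "n", self.n)
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "SampleMoments":
        df = pd.read_csv(path, index_col=0)
        names = list(df.index)
        return cls(cov=df[names].to_numpy(), mean=df["mean"].to_numpy(),
                   n=int(df["n"].iloc[0]), var_names=names)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class SemModelSpec:
    """Parameter-matrix template defining one structural model.

    ``paths[(target, source)]`` holds directed paths (``target ~ source``),
    ``covs[(a, b)]`` symmetric (co)variances (``a ~~ b``), ``means[v]``
    intercepts (``v ~ 1``, optional).  Entries are either a fixed float or a
    free-parameter label; repeated labels are equality constraints.
    Unlisted covariances are fixed to zero.
    """

    variables: list[str]
    observed: list[str]
    paths: dict[tuple[str, str], Entry] = field(default_factory=dict)
    covs: dict[tuple[str, str], Entry] = field(default_factory=dict)
    means: dict[str, Entry] | None = None
    starts: dict[str, float] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        unknown = set(self.observed) - set(self.variables)
        if unknown:
            raise ValueError(f"observed variables {sorted(unknown)} not declared")
        for (i, j) in list(self.paths) + list(self.covs):
            for v in (i, j):
                if v not in self.variables:
                    raise ValueError(f"undeclared variable {v!r} in template")
        for key, val in {**self.paths, **self.covs}.items():
            if isinstance(val, str):
                continue
            if not math.isfinite(float(val)):
                raise ValueError(f"non-finite fixed entry at {key}")
        # canonicalise symmetric keys
        covs: dict[tuple[str, str], Entry] = {}
        order = {v: i for i, v in enumerate(self.variables)}
        for (a, b), v in self.covs.items():
            key = (a, b) if order[a] <= order[b] else (b, a)
            if key in covs and covs[key] != v:
                raise ValueError(f"conflicting entries for covariance {key}")
            covs[key] = v
        self.covs = covs

    @property
    def latent(self) -> list[str]:
        return [v for v in self.variables if v not in self.observed]

    @property
    def free_labels(self) -> list[str]:
        """Distinct free-parameter labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for container in (self.paths, self.covs, self.means or {}):
            for val in container.values():
                if isinstance(val, str):
                    seen.setdefault(val)
        return list(seen)

    @property
    def k(self) -> int:
        """Free-parameter count after equality-constraint de-duplication."""
        return len(self.free_labels)

    @property
    def has_means(self) -> bool:
        return self.means is not None

    @property
    def n_moments(self) -> int:
        p = len(self.observed)
        m = p * (p + 1) // 2
        if self.has_means:
            m += p
        return m

    @property
    def df_on_full_moments(self) -> int:
        """Model degrees of freedom against full-rank sample moments."""
        return self.n_moments - self.k

    # -- numeric assembly -------------------------------------------------
    def _index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variables)}

    def build_matrices(self, theta: np.ndarray):
        """Numeric (A, S, mu_all) at parameter vector ``theta``."""
        labels = self.free_labels
        if len(theta) != len(labels):
            raise ValueError(f"theta length {len(theta)} != k={len(labels)}")
        val = dict(zip(labels, np.asarray(theta, dtype=float)))
        idx = self._index()
        m = len(self.variables)
        A = np.zeros((m, m))
        S = np.zeros((m, m))
        for (tgt, src), e in self.paths.items():
            A[idx[tgt], idx[src]] = val[e] if isinstance(e, str) else float(e)
        for (a, b), e in self.covs.items():
            v = val[e] if isinstance(e, str) else float(e)
            S[idx[a], idx[b]] = v
            S[idx[b], idx[a]] = v
        mu = np.zeros(m)
        if self.means is not None:
            for v, e in self.means.items():
                mu[idx[v]] = val[e] if isinstance(e, str) else float(e)
        return A, S, mu

    def start_vector(self, scale: float = 1.0) -> np.ndarray:
        """Heuristic start values: variances at 0.5*scale, other entries 0.1/0."""
        kind: dict[str, float] = {}
        for (a, b), e in self.covs.items():
            if isinstance(e, str) and e not in kind:
                kind[e] = 0.5 * scale if a == b else 0.0
        for key, e in self.paths.items():
            if isinstance(e, str) and e not in kind:
                kind[e] = 0.1
        if self.means is not None:
            for v, e in self.means.items():
                if isinstance(e, str) and e not in kind:
                    kind[e] = 0.0
        theta = np.array([self.starts.get(l, kind[l]) for l in self.free_labels])
        return theta

    # -- serialization -----------------------------------------------------
    def to_syntax(self) -> str:
        """Human-readable model syntax, one line per entry.

        Ops: ``~`` directed path, ``~~`` covariance, ``~1`` intercept.
        Fixed entries print their value, free entries their label.
        """
        lines = [f"# {self.name}", f"observed: {' '.join(self.observed)}",
                 f"latent: {' '.join(self.latent)}"]
        fmt = lambda e: e if isinstance(e, str) else f"{float(e):g}"
        for (tgt, src), e in sorted(self.paths.items()):
            lines.append(f"{tgt} ~ {src} {fmt(e)}")
        for (a, b), e in sorted(self.covs.items()):
            lines.append(f"{a} ~~ {b} {fmt(e)}")
        if self.means is not None:
            for v, e in sorted(self.means.items()):
                lines.append(f"{v} ~1 {fmt(e)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_syntax(cls, text: str, name: str = "model") -> "SemModelSpec":
        observed: list[str] = []
        latent: list[str] = []
        paths: dict[tuple[str, str], Entry] = {}
        covs: dict[tuple[str, str], Entry] = {}
        means: dict[str, Entry] | None = None
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("observed:"):
                observed = line.split(":", 1)[1].split()
                continue
            if line.startswith("latent:"):
                latent = line.split(":", 1)[1].split()
                continue
            parts = line.split()
            if parts[1] == "~1":
                v, entry = parts[0], parts[2]
                means = means or {}
                means[v] = _parse_entry(entry)
            elif parts[1] == "~":
                paths[(parts[0], parts[2])] = _parse_entry(parts[3])
            elif parts[1] == "~~":
                covs[(parts[0], parts[2])] = _parse_entry(parts[3])
            else:
                raise ValueError(f"cannot parse model-syntax line: {raw!r}")
        return cls(variables=observed + latent, observed=observed,
                   paths=paths, covs=covs, means=means, name=name)


def _parse_entry(tok: str) -> Entry:
    try:
        return float(tok)
    except ValueError:
        return tok


def saturated_spec(var_names: Sequence[str], means: bool = False) -> SemModelSpec:
    """All variances, covariances (and optionally means) free."""
    covs: dict[tuple[str, str], Entry] = {}
    for i, a in enumerate(var_names):
        for b in list(var_names)[i:]:
            covs[(a, b)] = f"s_{a}_{b}"
    mean_t = {v: f"m_{v}" for v in var_names} if means else None
    return SemModelSpec(variables=list(var_names), observed=list(var_names),
                        covs=covs, means=mean_t, name="saturated")


def independence_spec(var_names: Sequence[str], means: bool = False) -> SemModelSpec:
    """Baseline model: free variances (and optionally means) only."""
    covs = {(v, v): f"s_{v}" for v in var_names}
    mean_t = {v: f"m_{v}" for v in var_names} if means else None
    return SemModelSpec(variables=list(var_names), observed=list(var_names),
                        covs=covs, means=mean_t, name="independence")


# ---------------------------------------------------------------------------
# implied moments and discrepancy
# ---------------------------------------------------------------------------

def implied_moments(spec: SemModelSpec, theta: np.ndarray):
    """Model-implied (Sigma, mu) for the observed variables at ``theta``."""
    A, S, mu_all = spec.build_matrices(theta)
    m = len(spec.variables)
    IA = np.eye(m) - A
    if abs(np.linalg.det(IA)) < 1e-12:
        cycle = _find_cycle(spec)
        raise NonRecursiveError(
            "singular (I - A): the path structure contains a feedback loop with "
            f"unit gain{'' if cycle is None else ' through ' + ' -> '.join(cycle)}")
    B = np.linalg.inv(IA)
    V = B @ S @ B.T
    obs_idx = [spec.variables.index(v) for v in spec.observed]
    Sigma = V[np.ix_(obs_idx, obs_idx)]
    mu = (B @ mu_all)[obs_idx]
    return 0.5 * (Sigma + Sigma.T), mu


def implied_full_cov(spec: SemModelSpec, theta: np.ndarray) -> np.ndarray:
    """Implied covariance among ALL variables (latent included)."""
    A, S, _ = spec.build_matrices(theta)
    B = np.linalg.inv(np.eye(len(spec.variables)) - A)
    V = B @ S @ B.T
    return 0.5 * (V + V.T)


def _find_cycle(spec: SemModelSpec) -> list[str] | None:
    # DFS over the directed-path graph, purely for error messages
    graph: dict[str, list[str]] = {}
    for (tgt, src) in spec.paths:
        graph.setdefault(src, []).append(tgt)
    color: dict[str, int] = {}
    stack: list[str] = []

    def visit(v: str) -> list[str] | None:
        color[v] = 1
        stack.append(v)
        for w in graph.get(v, []):
            if color.get(w, 0) == 1:
                return stack[stack.index(w):] + [w]
            if color.get(w, 0) == 0:
                found = visit(w)
                if found:
                    return found
        stack.pop()
        color[v] = 2
        return None

    for v in spec.variables:
        if color.get(v, 0) == 0:
            found = visit(v)
            if found:
                return found
    return None


def fml_discrepancy(S: np.ndarray, mu_s: np.ndarray | None,
                    Sigma: np.ndarray, mu: np.ndarray | None,
                    p: int) -> float:
    """Normal-theory ML discrepancy; penalised (not raised) for non-PD Sigma."""
    S = np.asarray(S, dtype=float).reshape(p, p)
    Sigma = np.asarray(Sigma, dtype=float).reshape(p, p)
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        # barrier for the optimizer: large, increasing with non-PD severity
        w = np.linalg.eigvalsh(0.5 * (Sigma + Sigma.T))
        return _PENALTY * (1.0 + float(np.clip(-w.min(), 0, None)))
    logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("sample covariance matrix is not positive definite")
    Sigma_inv = np.linalg.inv(Sigma)
    f = logdet_sigma + float(np.trace(S @ Sigma_inv)) - logdet_s - p
    if mu_s is not None and mu is not None:
        d = np.asarray(mu_s, dtype=float) - np.asarray(mu, dtype=float)
        f += float(d @ Sigma_inv @ d)
    return max(f, 0.0) if f > -1e-8 else f


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class SemFit:
    """Estimates, uncertainty, standardized solution and fit for one model."""

    spec: SemModelSpec
    moments: SampleMoments
    theta_hat: np.ndarray
    se: np.ndarray
    chi2: float
    df: int
    p_chi2: float
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    rmsea_df0: bool
    converged: bool
    n_iter: int
    fmin: float
    grad_norm: float
    theta_cov: np.ndarray
    standardized: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return self.spec.free_labels

    def estimate(self, label: str) -> float:
        return float(self.theta_hat[self.labels.index(label)])

    def se_of(self, label: str) -> float:
        return float(self.se[self.labels.index(label)])

    def param_table(self) -> pd.DataFrame:
        z = np.where(self.se > 0, self.theta_hat / self.se, np.nan)
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "label": self.labels, "estimate": self.theta_hat, "se": self.se,
            "z": z, "p_value": p,
            "ci_lo": self.theta_hat - 1.959963984540054 * self.se,
            "ci_hi": self.theta_hat + 1.959963984540054 * self.se,
        })

    def std_path(self, target: str, source: str) -> tuple[float, float]:
        """(standardized estimate, delta-method SE) for a directed path."""
        return self.standardized[("~", target, source)]

    def std_cov(self, a: str, b: str) -> tuple[float, float]:
        order = {v: i for i, v in enumerate(self.spec.variables)}
        key = (a, b) if order[a] <= order[b] else (b, a)
        return self.standardized[("~~",) + key]

    def implied(self):
        return implied_moments(self.spec, self.theta_hat)


# ---------------------------------------------------------------------------
# gradient of F_ML
# ---------------------------------------------------------------------------

def _fml_and_grad(spec: SemModelSpec, theta: np.ndarray, S: np.ndarray,
                  mu_s: np.ndarray | None, obs_idx: np.ndarray,
                  deriv_masks) -> tuple[float, np.ndarray]:
    A, Smat, mu_all = spec.build_matrices(theta)
    m = len(spec.variables)
    p = len(obs_idx)
    IA = np.eye(m) - A
    try:
        B = np.linalg.inv(IA)
    except np.linalg.LinAlgError:
        return _PENALTY, np.zeros_like(theta)
    V = B @ Smat @ B.T
    Sigma = V[np.ix_(obs_idx, obs_idx)]
    Sigma = 0.5 * (Sigma + Sigma.T)
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(Sigma)
        g = _numeric_grad_penalty(spec, theta, obs_idx)
        return _PENALTY * (1.0 + float(np.clip(-w.min(), 0, None))), g
    f = fml_discrepancy(S, mu_s, Sigma, (B @ mu_all)[obs_idx] if mu_s is not None else None, p)
    Sigma_inv = np.linalg.inv(Sigma)
    # dF/dSigma = Sigma^-1 - Sigma^-1 S Sigma^-1  (covariance part)
    W = Sigma_inv - Sigma_inv @ S @ Sigma_inv
    if mu_s is not None:
        mu = (B @ mu_all)[obs_idx]
        d = mu_s - mu
        q = Sigma_inv @ d
        W = W - np.outer(q, q)
    grad = np.zeros(len(theta))
    BS = B @ Smat
    for j, (dA, dS, dmu) in enumerate(deriv_masks):
        # dSigma = F [ B dA B S B^T + B dS B^T + (B dA B S B^T)^T ] F^T
        term = np.zeros((m, m))
        if dA is not None:
            C = B @ dA @ BS @ B.T
            term += C + C.T
        if dS is not None:
            term += B @ dS @ B.T
        dSig = term[np.ix_(obs_idx, obs_idx)]
        g = float(np.sum(W * dSig))
        if mu_s is not None:
            dmu_obs = np.zeros(p)
            if dmu is not None:
                dmu_obs = (B @ dmu)[obs_idx]
            if dA is not None:
                dmu_obs = dmu_obs + (B @ dA @ B @ mu_all)[obs_idx]
            g += float(-2.0 * q @ dmu_obs)
        grad[j] = g
    return f, grad


def _numeric_grad_penalty(spec, theta, obs_idx):
    # crude downhill direction out of the non-PD region
    eps = 1e-5
    g = np.zeros(len(theta))
    for j in range(len(theta)):
        tp = theta.copy(); tp[j] += eps
        tm = theta.copy(); tm[j] -= eps
        wp = np.linalg.eigvalsh(_sigma_of(spec, tp, obs_idx)).min()
        wm = np.linalg.eigvalsh(_sigma_of(spec, tm, obs_idx)).min()
        g[j] = -(wp - wm) / (2 * eps) * _PENALTY
    return g


def _sigma_of(spec, theta, obs_idx):
    A, Smat, _ = spec.build_matrices(theta)
    m = len(spec.variables)
    try:
        B = np.linalg.inv(np.eye(m) - A)
    except np.linalg.LinAlgError:
        return np.eye(len(obs_idx))
    V = B @ Smat @ B.T
    return V[np.ix_(obs_idx, obs_idx)]


def _deriv_masks(spec: SemModelSpec):
    """Per-free-label indicator matrices (dA, dS, dmu)."""
    idx = spec._index()
    m = len(spec.variables)
    masks = []
    for label in spec.free_labels:
        dA = np.zeros((m, m)); useA = False
        dS = np.zeros((m, m)); useS = False
        dmu = np.zeros(m); useM = False
        for (tgt, src), e in spec.paths.items():
            if e == label:
                dA[idx[tgt], idx[src]] = 1.0
                useA = True
        for (a, b), e in spec.covs.items():
            if e == label:
                dS[idx[a], idx[b]] += 1.0
                if a != b:
                    dS[idx[b], idx[a]] += 1.0
                useS = True
        if spec.means is not None:
            for v, e in spec.means.items():
                if e == label:
                    dmu[idx[v]] = 1.0
                    useM = True
        masks.append((dA if useA else None, dS if useS else None, dmu if useM else None))
    return masks


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit(spec: SemModelSpec, moments: SampleMoments, *, n_starts: int = 5,
        seed: int = 0, gtol: float = 1e-8, max_iter: int = 2000,
        chi2_scale: str = "n-1", compute_se: bool = True,
        standardized: bool = True) -> SemFit:
    """Fit ``spec`` to ``moments`` by minimising the ML discrepancy.

    Quasi-Newton (BFGS) with an analytic gradient, from a heuristic start
    plus ``n_starts - 1`` jittered restarts; deterministic given ``seed``.
    """
    moments = moments.reorder(spec.observed)
    if not moments.is_pd():
        raise ValueError("sample covariance matrix is not positive definite")
    df = spec.df_on_full_moments
    if df < 0:
        raise IdentificationError(
            f"model has k={spec.k} free parameters but only {spec.n_moments} "
            "distinct sample moments (df < 0)")
    S = moments.cov
    mu_s = moments.mean if spec.has_means else None
    obs_idx = np.array([spec.variables.index(v) for v in spec.observed])
    masks = _deriv_masks(spec)

    def objective(theta):
        return _fml_and_grad(spec, theta, S, mu_s, obs_idx, masks)

    scale = float(np.mean(np.diag(S)))
    base = spec.start_vector(scale=scale)
    rng = np.random.default_rng(seed)
    # loose box keeps the first pass away from runaway ridges (e.g. a trait
    # factor trading off against a unit-gain residual chain); the second,
    # unbounded pass polishes to the gradient tolerance
    is_var = [any(isinstance(e, str) and e == lab and a == b
                  for (a, b), e in spec.covs.items())
              for lab in spec.free_labels]
    bounds = [(-10.0 * scale, 50.0 * scale) if v else (-10.0, 10.0) for v in is_var]
    best = None
    n_iter_total = 0
    for s in range(max(1, n_starts)):
        x0 = base if s == 0 else base + rng.normal(0, 0.3, size=base.shape) * np.maximum(1.0, np.abs(base))
        pre = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": max_iter, "ftol": 1e-14,
                                         "gtol": gtol})
        res = optimize.minimize(objective, pre.x, jac=True, method="BFGS",
                                options={"gtol": gtol, "maxiter": max_iter})
        n_iter_total += pre.nit + res.nit
        f, g = objective(res.x)
        cand = (f, float(np.max(np.abs(g))) if len(g) else 0.0, res.x)
        agree = best is not None and abs(cand[0] - best[0]) < 1e-9
        if best is None or cand[0] < best[0] - 1e-12 or (
                cand[0] < best[0] + 1e-10 and cand[1] < best[1]):
            best = cand
        # a perfect fit, or two independent starts landing on the same
        # minimum, is enough evidence that the optimum is global
        if best[0] < 1e-10 and best[1] < gtol * 10:
            break
        if agree and best[1] < 1e-5:
            break
    fmin, gnorm, theta_hat = best
    converged = bool(fmin < _PENALTY / 2 and gnorm < 1e-4)
    fmin = max(fmin, 0.0)

    n = moments.n
    scale_factor = (n - 1) if chi2_scale == "n-1" else n
    chi2 = float(scale_factor * fmin)

    # standard errors from the observed information of the scaled discrepancy
    k = spec.k
    theta_cov = np.full((k, k), np.nan)
    se = np.full(k, np.nan)
    if compute_se and converged and k > 0:
        H = _hessian(objective, theta_hat)
        info = (scale_factor / 2.0) * H  # observed information of the scaled discrepancy
        try:
            theta_cov = np.linalg.inv(info)
            d = np.diag(theta_cov)
            se = np.sqrt(np.where(d > 0, d, np.nan))
        except np.linalg.LinAlgError:
            pass

    # baseline (independence) model for incremental indices
    if df > 0:
        base_spec = independence_spec(spec.observed, means=spec.has_means)
        base_fit_f = _independence_fmin(S, mu_s)
        chi2_b = float(scale_factor * base_fit_f)
        df_b = base_spec.df_on_full_moments
        cfi, tli, rmsea, rmsea_ci, p_chi2, df0flag = fit_indices(chi2, df, chi2_b, df_b, n)
    else:
        cfi, tli, rmsea, rmsea_ci, p_chi2, df0flag = 1.0, 1.0, 0.0, (0.0, 0.0), 1.0, True

    fit_obj = SemFit(spec=spec, moments=moments, theta_hat=theta_hat, se=se,
                     chi2=chi2, df=df, p_chi2=p_chi2, cfi=cfi, tli=tli,
                     rmsea=rmsea, rmsea_ci90=rmsea_ci, rmsea_df0=df0flag,
                     converged=converged, n_iter=n_iter_total, fmin=fmin,
                     grad_norm=gnorm, theta_cov=theta_cov)
    if standardized and converged:
        fit_obj.standardized = standardize(fit_obj, spec)
    return fit_obj


def _independence_fmin(S: np.ndarray, mu_s) -> float:
    """Closed-form ML minimum of the independence model: -ln|R|.

    The diagonal model's ML solution is Sigma = diag(S) (and mu = mu_s when
    means are modeled), giving F = sum(ln s_ii) - ln|S| = -ln|R|.
    """
    d = np.diag(S)
    sign, logdet = np.linalg.slogdet(S)
    return float(np.sum(np.log(d)) - logdet)


def _hessian(objective, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from the analytic gradient."""
    k = len(theta)
    H = np.zeros((k, k))
    for j in range(k):
        step = eps * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += step
        tm = theta.copy(); tm[j] -= step
        _, gp = objective(tp)
        _, gm = objective(tm)
        H[:, j] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def fit_indices(chi2: float, df: int, chi2_baseline: float, df_baseline: int,
                n: int, rmsea_denominator: str = "n-1"):
    """CFI, TLI, RMSEA with 90% noncentral-chi-square CI, and the chi2 p.

    TLI is not clamped and may exceed 1; RMSEA with df=0 is reported as 0
    with a flag.  The RMSEA denominator is (n - 1) by default.
    """
    nn = (n - 1) if rmsea_denominator == "n-1" else n
    d = max(chi2 - df, 0.0)
    d_b = max(chi2_baseline - df_baseline, 0.0)
    cfi = 1.0 - (d / max(d_b, d, np.finfo(float).tiny)) if max(d_b, d) > 0 else 1.0
    if df_baseline > 0 and df > 0:
        ratio_b = chi2_baseline / df_baseline
        tli = (ratio_b - chi2 / df) / (ratio_b - 1.0) if abs(ratio_b - 1.0) > 1e-12 else 1.0
    else:
        tli = 1.0
    df0 = df == 0
    if df0:
        rmsea, ci = 0.0, (0.0, 0.0)
        p_chi2 = 1.0
    else:
        rmsea = math.sqrt(d / (df * nn))
        ci = _rmsea_ci(chi2, df, nn)
        p_chi2 = float(stats.chi2.sf(chi2, df))
    return float(cfi), float(tli), float(rmsea), ci, p_chi2, df0


def _rmsea_ci(chi2: float, df: int, nn: int, level: float = 0.90):
    """90% CI by root-finding on the noncentral chi-square distribution."""
    alpha = (1.0 - level) / 2.0

    def ncp_for(prob_target):
        # find lambda with P(X_{df,lambda} <= chi2) = prob_target
        f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob_target
        if f(0.0) < 0:
            return 0.0
        hi = max(chi2, 1.0)
        while f(hi) > 0 and hi < 1e7:
            hi *= 2.0
        if f(hi) > 0:
            return hi
        return float(optimize.brentq(f, 0.0, hi, xtol=1e-10))

    lam_lo = ncp_for(1.0 - alpha)
    lam_hi = ncp_for(alpha)
    lo = math.sqrt(lam_lo / (df * nn))
    hi = math.sqrt(lam_hi / (df * nn))
    if lo > hi:
        lo, hi = hi, lo
    return (lo, hi)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(fit_obj: SemFit, spec: SemModelSpec | None = None):
    """Standardized solution with delta-method SEs ("std.all" convention).

    Every path ``j -> i`` is rescaled by ``sd(j)/sd(i)`` using model-implied
    standard deviations of ALL variables (latent included); covariances
    become correlations.  Returns a dict keyed by ("~", target, source) and
    ("~~", a, b) with (estimate, se) values.
    """
    spec = spec or fit_obj.spec
    if not fit_obj.converged:
        raise ValueError("cannot standardize a non-converged fit")

    def std_vector(theta):
        A, Smat, _ = spec.build_matrices(theta)
        m = len(spec.variables)
        B = np.linalg.inv(np.eye(m) - A)
        V = B @ Smat @ B.T
        sd = np.sqrt(np.clip(np.diag(V), 0.0, None))
        idx = spec._index()
        out = []
        for (tgt, src) in path_keys:
            si, sj = sd[idx[src]], sd[idx[tgt]]
            out.append(A[idx[tgt], idx[src]] * si / sj if sj > 0 else np.nan)
        for (a, b) in cov_keys:
            ia, ib = idx[a], idx[b]
            if a == b:
                # standardized variance: share of total implied variance
                out.append(Smat[ia, ia] / V[ia, ia] if V[ia, ia] > 0 else np.nan)
            else:
                denom = sd[ia] * sd[ib]
                out.append(V[ia, ib] / denom if denom > 0 else np.nan)
        return np.array(out)

    path_keys = list(spec.paths)
    cov_keys = list(spec.covs)
    theta = fit_obj.theta_hat
    vals = std_vector(theta)
    k = len(theta)
    ses = np.full(len(vals), np.nan)
    if k > 0 and np.all(np.isfinite(np.diag(fit_obj.theta_cov))):
        J = np.zeros((len(vals), k))
        for j in range(k):
            step = 1e-5 * max(1.0, abs(theta[j]))
            tp = theta.copy(); tp[j] += step
            tm = theta.copy(); tm[j] -= step
            J[:, j] = (std_vector(tp) - std_vector(tm)) / (2 * step)
        cov_std = J @ fit_obj.theta_cov @ J.T
        d = np.diag(cov_std)
        ses = np.sqrt(np.where(d > 0, d, np.nan))
    out: dict[tuple[str, str, str], tuple[float, float]] = {}
    for key, v, s in zip(path_keys, vals[:len(path_keys)], ses[:len(path_keys)]):
        out[("~",) + key] = (float(v), float(s))
    for key, v, s in zip(cov_keys, vals[len(path_keys):], ses[len(path_keys):]):
        out[("~~",) + key] = (float(v), float(s))
    return out
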