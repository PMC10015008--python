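"""Binomial GAMM: shrinkage cubic regression splines + random intercepts.

The model for runner i is

    logit P(EHI_i = 1) = Xb_i + sum_j f_j(x_ij) + b_horse(i) + b_meet(i)

with f_j penalised cubic regression splines whose penalty is modified so a
large enough smoothing parameter shrinks the whole term to the zero
function, and zero-mean random intercepts represented as penalised (ridge)
dummy-coefficient blocks — the standard penalised-regression representation
of a mixed model.  Fitting maximises the penalised binomial log-likelihood
by iteratively reweighted least squares; each smoothing parameter (one per
smooth, one per random-effect block) is updated by the Fellner-Schall
marginal-likelihood (REML-type) step, so random-effect variances and smooth
wiggliness are estimated on the same footing.

Also here: rare-event control down-sampling and the prior-correction
("class adjustment") that maps model-scale probabilities from the enriched
fitting sample back to absolute probabilities at the true prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import splu
from scipy.special import expit, logit

__all__ = [
    "SmoothTerm", "ModelSpec", "SamplingInfo", "FittedGAMM",
    "fit_gamm", "predict_probability", "downsample_controls",
    "adjust_probability", "DEFAULT_SPEC", "FULL_SPEC",
]

_DENSE_LIMIT = 1200  # switch to sparse normal-equation solves above this p


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class SmoothTerm:
    var: str
    k: int = 10  # basis dimension (number of knots)

    @property
    def name(self) -> str:
        return f"s({self.var})"


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the binomial logit GAMM."""

    smooth: tuple = ()
    categorical: tuple = ()
    random: tuple = ()

    def __post_init__(self):
        names = [t.name for t in self.smooth] + list(self.categorical) + list(self.random)
        if len(set(names)) != len(names):
            raise ValueError("duplicated model terms")

    @property
    def removable(self) -> tuple:
        """Names of terms that backward selection may drop (never random)."""
        return tuple(t.name for t in self.smooth) + tuple(self.categorical)

    def drop(self, name: str) -> "ModelSpec":
        if name in self.categorical:
            return replace(self, categorical=tuple(c for c in self.categorical if c != name))
        if name in (t.name for t in self.smooth):
            return replace(self, smooth=tuple(t for t in self.smooth if t.name != name))
        raise KeyError(f"term {name!r} not removable")

    def describe(self) -> str:
        parts = [t.name for t in self.smooth] + list(self.categorical)
        parts += [f"re({r})" for r in self.random]
        return "ehi ~ " + " + ".join(parts) if parts else "ehi ~ 1"


def FULL_SPEC(knots: int = 10) -> ModelSpec:
    """The maximal model: all proposed explanatory factors."""
    return ModelSpec(
        smooth=tuple(SmoothTerm(v, knots) for v in ("age", "distance", "wbgt", "prev5")),
        categorical=("going5", "prev_incident", "year", "race_type", "off_band", "sex"),
        random=("horse_id", "meet_id"),
    )


def DEFAULT_SPEC(knots: int = 10) -> ModelSpec:
    """The selected model: maximal model minus sex and race type."""
    return FULL_SPEC(knots).drop("sex").drop("race_type")


# ---------------------------------------------------------------------------
# cubic regression spline basis (Wood's value-at-knots parameterisation)

def _crs_matrices(knots: np.ndarray):
    h = np.diff(knots)
    k = len(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i < k - 3:
            B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
    F = np.zeros((k, k))
    F[1:-1] = np.linalg.solve(B, D)  # second derivatives at knots from values
    S = D.T @ np.linalg.solve(B, D)  # integrated squared second derivative
    return F, S


def _crs_design(x: np.ndarray, knots: np.ndarray, F: np.ndarray) -> np.ndarray:
    x = np.clip(x, knots[0], knots[-1])
    j = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, len(knots) - 2)
    h = knots[j + 1] - knots[j]
    am = (knots[j + 1] - x) / h
    ap = (x - knots[j]) / h
    cm = ((knots[j + 1] - x) ** 3 / h - h * (knots[j + 1] - x)) / 6.0
    cp = ((x - knots[j]) ** 3 / h - h * (x - knots[j])) / 6.0
    n, k = len(x), len(knots)
    X = np.zeros((n, k))
    rows = np.arange(n)
    X[rows, j] += am
    X[rows, j + 1] += ap
    X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
    return X


@dataclass
class _SmoothInfo:
    var: str
    knots: np.ndarray
    F: np.ndarray
    Z: np.ndarray        # sum-to-zero constraint null-space basis, k x (k-1)
    S: np.ndarray        # constrained penalty with shrinkage modification
    xmin: float
    xmax: float

    def design(self, x, clamp_warn=True):
        x = np.asarray(x, dtype=float)
        if clamp_warn and (np.any(x < self.xmin) or np.any(x > self.xmax)):
            warnings.warn(
                f"{self.var}: values outside training range clamped to "
                f"[{self.xmin:g}, {self.xmax:g}]",
                stacklevel=2,
            )
        return _crs_design(x, self.knots, self.F) @ self.Z


def _build_smooth(x: np.ndarray, var: str, k: int) -> _SmoothInfo:
    qs = np.quantile(x, np.linspace(0, 1, k))
    knots = np.unique(qs)
    if len(knots) < 4:
        # fall back to an even grid over the observed range (ties in x)
        knots = np.linspace(x.min(), x.max(), max(4, min(k, 6)))
        if knots[0] == knots[-1]:
            raise ValueError(f"smooth covariate {var!r} is constant")
    F, S = _crs_matrices(knots)
    X = _crs_design(x, knots, F)
    c = X.mean(axis=0)
    # null space of the sum-to-zero constraint c'beta = 0
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(len(c))[:, :-1]]))
    Z = q[:, 1:]
    Sc = Z.T @ S @ Z
    Sc = 0.5 * (Sc + Sc.T)
    # normalise to unit spectral norm so smoothing parameters are
    # dimensionless and comparable across covariate scales
    vals, vecs = np.linalg.eigh(Sc)
    Sc = Sc / vals.max()
    # shrinkage: give the penalty null space (linear component) a small
    # positive eigenvalue so lambda -> inf shrinks the whole term to zero
    vals, vecs = np.linalg.eigh(Sc)
    pos = vals[vals > vals.max() * 1e-10]
    # small enough that estimable linear trends are essentially unshrunk,
    # large enough that a lambda at its cap shrinks the whole term to zero
    eps = 1e-2 * pos.min()
    vals = np.where(vals > vals.max() * 1e-10, vals, eps)
    Sc = (vecs * vals) @ vecs.T
    return _SmoothInfo(var, knots, F, Z, 0.5 * (Sc + Sc.T), float(x.min()), float(x.max()))


# ---------------------------------------------------------------------------
# design assembly

@dataclass
class _Design:
    spec: ModelSpec
    cat_levels: dict
    smooths: dict
    random_levels: dict
    slices: dict      # term name -> column slice in the full design
    p_fixed: int      # columns of the dense (intercept+categorical+smooth) block
    p: int

    def fixed_matrix(self, frame: pd.DataFrame, clamp_warn=True) -> np.ndarray:
        n = len(frame)
        X = np.zeros((n, self.p_fixed))
        X[:, 0] = 1.0
        for var in self.spec.categorical:
            sl = self.slices[var]
            levels = self.cat_levels[var]
            codes = pd.Categorical(frame[var].astype(str), categories=levels).codes
            if np.any(codes < 0):
                bad = sorted(set(frame[var].astype(str)) - set(levels))
                raise ValueError(f"unseen level(s) {bad} for categorical term {var!r}")
            for j in range(1, len(levels)):  # treatment coding
                X[:, sl.start + j - 1] = codes == j
        for t in self.spec.smooth:
            sl = self.slices[t.name]
            X[:, sl] = self.smooths[t.var].design(frame[t.var].to_numpy(float), clamp_warn)
        return X

    def random_codes(self, frame: pd.DataFrame) -> dict:
        """Level code per row for each random term; -1 for unseen levels."""
        out = {}
        for var in self.spec.random:
            out[var] = self.random_levels[var].get_indexer(frame[var].astype(str))
        return out

    def matrix(self, frame: pd.DataFrame, clamp_warn=True) -> sparse.csr_matrix:
        Xf = self.fixed_matrix(frame, clamp_warn)
        blocks = [sparse.csr_matrix(Xf)]
        codes = self.random_codes(frame)
        n = len(frame)
        for var in self.spec.random:
            c = codes[var]
            m = len(self.random_levels[var])
            rows = np.flatnonzero(c >= 0)
            Z = sparse.csr_matrix(
                (np.ones(len(rows)), (rows, c[rows])), shape=(n, m)
            )
            blocks.append(Z)
        return sparse.hstack(blocks, format="csr")


def _build_design(frame: pd.DataFrame, spec: ModelSpec,
                  cat_levels: dict | None = None) -> _Design:
    slices = {}
    col = 1  # intercept at column 0
    given = cat_levels or {}
    cat_levels = {}
    for var in spec.categorical:
        levels = given.get(var) or sorted(frame[var].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"categorical term {var!r} has a single level")
        cat_levels[var] = list(levels)
        slices[var] = slice(col, col + len(levels) - 1)
        col += len(levels) - 1
    smooths = {}
    for t in spec.smooth:
        info = _build_smooth(frame[t.var].to_numpy(float), t.var, t.k)
        smooths[t.var] = info
        d = info.S.shape[0]
        slices[t.name] = slice(col, col + d)
        col += d
    p_fixed = col
    random_levels = {}
    for var in spec.random:
        idx = pd.Index(sorted(frame[var].astype(str).unique()))
        random_levels[var] = idx
        slices[f"re({var})"] = slice(col, col + len(idx))
        col += len(idx)
    return _Design(spec, cat_levels, smooths, random_levels, slices, p_fixed, col)


# ---------------------------------------------------------------------------
# fitted model container

@dataclass
class FittedGAMM:
    design: _Design
    beta: np.ndarray
    lambdas: dict                 # penalty name -> smoothing parameter
    cov_fixed: np.ndarray         # posterior covariance of the dense block
    edf: dict                     # term name -> effective degrees of freedom
    convergence: dict
    term_mean_contrib: dict       # mean fitted contribution per term (training)
    fitted_values: np.ndarray

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    def linear_predictor(self, frame: pd.DataFrame, include_random: bool = True,
                         clamp_warn: bool = True) -> np.ndarray:
        Xf = self.design.fixed_matrix(frame, clamp_warn)
        eta = Xf @ self.beta[: self.design.p_fixed]
        if include_random:
            codes = self.design.random_codes(frame)
            for var in self.spec.random:
                sl = self.design.slices[f"re({var})"]
                b = self.beta[sl]
                c = codes[var]
                eta += np.where(c >= 0, b[np.clip(c, 0, None)], 0.0)
        return eta

    def to_json_dict(self) -> dict:
        return {
            "formula": self.spec.describe(),
            "coefficients": self.beta.tolist(),
            "lambdas": {k: float(v) for k, v in self.lambdas.items()},
            "edf": {k: float(v) for k, v in self.edf.items()},
            "convergence": self.convergence,
            "smooths": {
                v: {"knots": s.knots.tolist(), "range": [s.xmin, s.xmax]}
                for v, s in self.design.smooths.items()
            },
            "categorical_levels": self.design.cat_levels,
        }


class _Solver:
    """Cholesky (dense) or LU (sparse) solver for the normal-equation matrix."""

    def __init__(self, A):
        self.p = A.shape[0]
        if self.p <= _DENSE_LIMIT:
            self.dense = True
            self.fac = cho_factor(np.asarray(A.todense()) if sparse.issparse(A) else A)
        else:
            self.dense = False
            self.fac = splu(sparse.csc_matrix(A), permc_spec="COLAMD")

    def solve(self, b):
        return cho_solve(self.fac, b) if self.dense else self.fac.solve(b)


def _penalty_blocks(design: _Design) -> dict:
    """Penalty name -> (slice, matrix-or-None, rank); None means identity."""
    out = {}
    for t in design.spec.smooth:
        sl = design.slices[t.name]
        out[t.name] = (sl, design.smooths[t.var].S, sl.stop - sl.start)
    for var in design.spec.random:
        name = f"re({var})"
        sl = design.slices[name]
        out[name] = (sl, None, sl.stop - sl.start)
    return out


def _S_lambda(design: _Design, penalties: dict, lambdas: dict) -> sparse.csr_matrix:
    p = design.p
    rows, cols, vals = [], [], []
    for name, (sl, S, _) in penalties.items():
        lam = lambdas[name]
        if S is None:
            idx = np.arange(sl.start, sl.stop)
            rows.append(idx); cols.append(idx); vals.append(np.full(len(idx), lam))
        else:
            d = sl.stop - sl.start
            r, c = np.meshgrid(np.arange(d), np.arange(d), indexing="ij")
            rows.append((r + sl.start).ravel())
            cols.append((c + sl.start).ravel())
            vals.append((lam * S).ravel())
    if not rows:
        return sparse.csr_matrix((p, p))
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(p, p)
    )


def _block_traces(solver: "_Solver", penalties: dict, probes: dict, p: int) -> dict:
    """tr(A^{-1} S_j) per penalty block, via one batched multi-RHS solve.

    Small blocks are solved exactly against identity columns; large
    random-intercept blocks use fixed Rademacher probes (Hutchinson
    estimator) so the cost stays at a few dozen solves."""
    cols = {}
    total = 0
    for name, (sl, S, _) in penalties.items():
        d = sl.stop - sl.start
        width = probes[name].shape[1] if name in probes else d
        cols[name] = (total, total + width)
        total += width
    rhs = np.zeros((p, total))
    for name, (sl, S, _) in penalties.items():
        c0, c1 = cols[name]
        if name in probes:
            rhs[sl, c0:c1] = probes[name]
        else:
            rhs[sl.start:sl.stop, c0:c1] = np.eye(sl.stop - sl.start)
    sol = solver.solve(rhs)
    out = {}
    for name, (sl, S, _) in penalties.items():
        c0, c1 = cols[name]
        block = sol[sl.start:sl.stop, c0:c1]
        if name in probes:
            out[name] = float(np.mean(np.sum(block * probes[name], axis=0)))
        elif S is None:
            out[name] = float(np.trace(block))
        else:
            out[name] = float(np.sum(block * S.T))
    return out


def fit_gamm(
    frame: pd.DataFrame,
    spec: ModelSpec,
    y_col: str = "ehi",
    max_outer: int = 20,
    max_pirls: int = 30,
    tol: float = 1e-7,
    lam_tol: float = 0.02,
    n_probe: int = 32,
    trace_seed: int = 0,
    offset: np.ndarray | None = None,
    fixed_lambdas: dict | None = None,
    init_lambdas: dict | None = None,
    cat_levels: dict | None = None,
) -> FittedGAMM:
    """Fit the binomial logit GAMM by penalised IRLS with Fellner-Schall
    smoothing-parameter updates.

    Raises on non-convergence of the inner IRLS; warns when coefficients
    grow beyond a separation cap.
    """
    y = frame[y_col].to_numpy(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("response has a single class")

    design = _build_design(frame, spec, cat_levels=cat_levels)
    X = design.matrix(frame, clamp_warn=False)
    Xcsc = X.tocsc()
    # categorical levels supplied from a parent frame may have no rows here;
    # pin their (structurally empty) columns at zero so the normal matrix
    # stays positive definite and the level predicts like the reference
    col_nnz = np.asarray(np.abs(Xcsc).sum(axis=0)).ravel()
    # ... plus a negligible fixed ridge (1e-8) so separation-flattened
    # weights can never make the factorisation numerically indefinite
    empty_guard = sparse.diags((col_nnz == 0).astype(float) + 1e-8)
    penalties = _penalty_blocks(design)
    fixed_lambdas = fixed_lambdas or {}
    unknown = set(fixed_lambdas) - set(penalties)
    if unknown:
        raise ValueError(f"fixed_lambdas for unknown penalties: {sorted(unknown)}")
    # start penalties at moderate shrinkage rather than sigma ~ 1 /
    # near-unpenalised wiggliness: group effects otherwise soak up covariate
    # signal, and smooths start overfit, before the Fellner-Schall iteration
    # has a chance to tighten them (the converged optimum is unaffected)
    init_lambdas = init_lambdas or {}
    lambdas = {
        name: fixed_lambdas.get(
            name, init_lambdas.get(name, 10.0 if penalties[name][1] is None else 100.0))
        for name in penalties
    }
    p = design.p

    beta = np.zeros(p)
    beta[0] = float(np.clip(logit(y.mean()), -10, 10))

    rng = np.random.default_rng(trace_seed)
    probes = {}
    for name, (sl, S, _) in penalties.items():
        if S is None:  # Hutchinson probes for big identity blocks
            d = sl.stop - sl.start
            if d > 64:
                probes[name] = rng.choice([-1.0, 1.0], size=(d, n_probe))

    def pen_dev(eta, beta):
        # penalised deviance: -2 loglik + beta' S_lambda beta
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        pen = 0.0
        for name, (sl, S, _) in penalties.items():
            b = beta[sl]
            pen += lambdas[name] * (b @ b if S is None else b @ S @ b)
        return -2.0 * ll + pen

    o = np.zeros(len(y)) if offset is None else np.asarray(offset, dtype=float)
    eta = np.asarray(X @ beta) + o
    history = []
    n_factor = 0
    solver = None
    w = None
    for outer in range(max_outer):
        S_l = _S_lambda(design, penalties, lambdas)
        current = pen_dev(eta, beta)
        for it in range(max_pirls):
            mu = expit(eta)
            w = np.maximum(mu * (1 - mu), 1e-10)
            z = eta + (y - mu) / w
            A = (Xcsc.T.multiply(w) @ Xcsc) + S_l + empty_guard
            solver = _Solver(A)
            n_factor += 1
            rhs = Xcsc.T @ (w * (z - o))
            beta_new = solver.solve(rhs)
            eta_new = np.clip(np.asarray(X @ beta_new) + o, -30.0, 30.0)
            new = pen_dev(eta_new, beta_new)
            step = 1.0
            while new > current + 1e-8 and step > 1e-3:  # step halving
                step *= 0.5
                beta_new = beta + step * (beta_new - beta)
                eta_new = np.clip(np.asarray(X @ beta_new) + o, -30.0, 30.0)
                new = pen_dev(eta_new, beta_new)
            beta, eta = beta_new, eta_new
            done = abs(current - new) < tol * (abs(new) + 0.1)
            current = new
            if done:
                break
        else:
            raise RuntimeError(
                f"IRLS failed to converge within {max_pirls} iterations "
                f"(outer {outer}); penalised deviance trace: {history[-5:]}"
            )
        history.append(current)

        # Fellner-Schall update for every smoothing parameter (all trace
        # solves batched into one multi-RHS solve)
        traces = _block_traces(solver, penalties, probes, p)
        max_dlog = 0.0
        new_lambdas = {}
        for name, (sl, S, rank) in penalties.items():
            lam = lambdas[name]
            if name in fixed_lambdas:
                new_lambdas[name] = lam
                continue
            b = beta[sl]
            bSb = float(b @ b) if S is None else float(b @ S @ b)
            trA = traces[name]
            num = max(rank / lam - trA, 1e-10)
            lam_new = lam * num / max(bSb, 1e-12)
            lam_new = float(np.clip(lam_new, lam * np.exp(-4), lam * np.exp(4)))
            lam_new = float(np.clip(lam_new, 1e-7, 1e7))
            max_dlog = max(max_dlog, abs(np.log(lam_new) - np.log(lam)))
            new_lambdas[name] = lam_new
        lambdas = new_lambdas
        if max_dlog < lam_tol:
            break

    if np.max(np.abs(beta)) > 25:
        warnings.warn("possible separation: coefficient magnitude exceeds 25")

    # posterior covariance of the dense block and per-term edf
    S_l = _S_lambda(design, penalties, lambdas)
    mu = expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    A = (Xcsc.T.multiply(w) @ Xcsc) + S_l + empty_guard
    solver = _Solver(A)
    pf = design.p_fixed
    E = np.zeros((p, pf)); E[:pf] = np.eye(pf)
    cov_cols = solver.solve(E)
    cov_fixed = 0.5 * (cov_cols[:pf] + cov_cols[:pf].T)

    traces = _block_traces(solver, penalties, probes, p)
    edf = {}
    for name, (sl, S, rank) in penalties.items():
        d = sl.stop - sl.start
        base = rank if S is None else d
        edf[name] = base - lambdas[name] * traces[name]
    for var in spec.categorical:
        sl = design.slices[var]
        edf[var] = sl.stop - sl.start

    Xf = design.fixed_matrix(frame, clamp_warn=False)
    term_mean = {"intercept": float(beta[0])}
    for name, sl in design.slices.items():
        if not name.startswith("re(") and sl.stop <= pf:
            term_mean[name] = float(Xf[:, sl].mean(axis=0) @ beta[sl])

    return FittedGAMM(
        design=design,
        beta=beta,
        lambdas=lambdas,
        cov_fixed=cov_fixed,
        edf=edf,
        convergence={
            "outer_iterations": outer + 1,
            "factorizations": n_factor,
            "penalised_deviance": history[-1],
            "max_dlog_lambda": max_dlog,
        },
        term_mean_contrib=term_mean,
        fitted_values=expit(eta),
    )


def predict_probability(fitted: FittedGAMM, newdata: pd.DataFrame,
                        include_random: bool = True) -> np.ndarray:
    """Predicted probabilities on the fitted (possibly down-sampled) scale.

    Random intercepts of horses/meets unseen in training contribute zero;
    with ``include_random=False`` all random effects are zeroed.  Smooth
    covariates outside the training range are clamped (with a warning).
    Unseen categorical levels raise.
    """
    eta = fitted.linear_predictor(newdata, include_random=include_random)
    return expit(eta)


# ---------------------------------------------------------------------------
# rare-event down-sampling and prior correction

@dataclass(frozen=True)
class SamplingInfo:
    """Case fractions of the fitted (down-sampled) and source data."""

    q: float      # case fraction in the down-sampled fitting data
    pi: float     # case fraction in the source data
    ratio: float  # controls retained per case
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.pi <= self.q < 1.0):
            raise ValueError(f"need 0 < pi <= q < 1, got pi={self.pi}, q={self.q}")


def downsample_controls(frame: pd.DataFrame, ratio: float, rng, y_col: str = "ehi",
                        pi: float | None = None):
    """Keep all cases and a simple random sample of round(ratio * n_cases)
    controls.

    ``pi`` overrides the source-data case fraction recorded in the returned
    :class:`SamplingInfo` (useful when ``frame`` is itself a subset of a
    larger population).  If fewer controls exist than requested, all are
    kept with a warning.
    """
    if isinstance(rng, (int, np.integer)):
        seed, rng = int(rng), np.random.default_rng(rng)
    else:
        seed = None
    is_case = frame[y_col].to_numpy() == 1
    n_cases = int(is_case.sum())
    if n_cases == 0:
        raise ValueError("cannot down-sample a frame with no cases")
    controls = np.flatnonzero(~is_case)
    n_keep = int(round(ratio * n_cases))
    if n_keep >= len(controls):
        warnings.warn("requested more controls than available; keeping all rows")
        chosen = controls
    else:
        chosen = rng.choice(controls, size=n_keep, replace=False)
    idx = np.sort(np.concatenate([np.flatnonzero(is_case), chosen]))
    out = frame.iloc[idx].reset_index(drop=True)
    info = SamplingInfo(
        q=n_cases / len(idx),
        pi=float(pi) if pi is not None else n_cases / len(frame),
        ratio=ratio,
        seed=seed,
    )
    return out, info


def adjust_probability(p, sampling: SamplingInfo):
    """Map model-scale probabilities from the enriched sample to absolute
    probabilities at the true prevalence (odds-scale prior correction):

        odds_adj = [p / (1-p)] * [pi (1-q)] / [q (1-pi)]

    Strictly increasing in p; maps 0 to 0 and 1 to 1.
    """
    p = np.asarray(p, dtype=float)
    factor = (sampling.pi * (1 - sampling.q)) / (sampling.q * (1 - sampling.pi))
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = p / (1 - p) * factor
        out = np.where(p >= 1.0, 1.0, odds / (1 + odds))
    return float(out) if out.ndim == 0 else out
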