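"""Binomial and Poisson mixed models with crossed random effects.

The per-cell fixation indicator (or count) is modelled as

    g(E[y]) = X beta + Z b,    b ~ N(0, Sigma),

with a logit link for binary responses and a log link for counts.  The
grouping factors — subject and scene item — are crossed, not nested:
every subject contributes observations for every item.  ``Sigma`` is
block diagonal with one (possibly correlated) covariance matrix per
grouping factor, replicated over its levels.

Estimation maximizes the Laplace approximation to the marginal
likelihood.  The random-effect covariances are parameterized by the
elements of their lower-triangular Cholesky factors (``theta``); for a
given ``theta`` the spherical random effects ``u`` (``b = Lambda u``)
and the fixed effects are obtained jointly by penalized iteratively
reweighted least squares (PIRLS), and a quasi-Newton optimizer moves
``theta`` to minimize the Laplace deviance

    dev(theta) = sum dev_i(y, mu) + ||u||^2 + log det(Lt Zt W Z L + I).

Optimization is deterministic: fixed starting values (zero fixed effects
except the intercept at the empirical link-scale mean, identity-scaled
Cholesky factors), no randomness anywhere in the fit.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, stats
from scipy.special import expit, gammaln

__all__ = [
    "RandomEffects",
    "ModelSpec",
    "GLMMFit",
    "parse_formula",
    "fit",
    "wald_table",
    "lrt",
    "information_criteria",
    "count_parameters",
    "marginal_conditional_r2",
    "conditional_mode_intervals",
    "individual_coefficients",
    "derived_fixed_coefficient",
    "partial_effects",
    "comparison_spec",
    "enumerate_control_specs",
    "propose_simplification",
]

# Boundary-fit thresholds (standardized-predictor scale).
SINGULAR_VARIANCE = 1e-8
SINGULAR_CORRELATION = 1.0 - 1e-4

_MU_EPS = 1e-10


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomEffects:
    """Random-effect terms for one grouping factor.

    ``terms`` always includes the intercept ("1"); ``correlated`` selects
    the maximal structure (all correlations estimated) versus the
    zero-correlation-parameter (zcp) structure.  An intercept-only
    structure is ``terms=("1",)``.  Arbitrary term subsets express
    "parsimonious" models.
    """

    factor: str
    terms: tuple[str, ...] = ("1",)
    correlated: bool = True

    def __post_init__(self) -> None:
        if "1" not in self.terms:
            object.__setattr__(self, "terms", ("1",) + tuple(self.terms))

    @property
    def structure(self) -> str:
        if len(self.terms) == 1:
            return "intercept"
        return "maximal" if self.correlated else "zcp"


@dataclass(frozen=True)
class ModelSpec:
    """A GLMM specification.

    ``fixed`` and random ``terms`` use a small Wilkinson-style term
    grammar: "1" (intercept), a numeric column name, a categorical column
    name (expanded to treatment-contrast dummies against the reference
    level), or an interaction "a:b".  ``factor_levels`` fixes level order
    and reference for categorical columns, e.g.
    ``{"map": (("AWS", "IKN98", "GBVS"), "AWS")}``.
    """

    response: str
    family: str = "binomial"  # binomial (logit) | poisson (log)
    fixed: tuple[str, ...] = ("1",)
    random: tuple[RandomEffects, ...] = ()
    factor_levels: tuple[tuple[str, tuple[tuple[str, ...], str]], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "poisson"):
            raise ValueError(f"unsupported family {self.family!r}")
        if "1" not in self.fixed:
            object.__setattr__(self, "fixed", ("1",) + tuple(self.fixed))
        for col, (levels, ref) in self.factor_levels:
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not among levels of {col!r}")
        for re_ in self.random:
            for t in re_.terms:
                if t != "1" and t not in self.fixed:
                    raise ValueError(
                        f"random slope {t!r} for factor {re_.factor!r} is not a fixed term"
                    )

    @property
    def factor_level_map(self) -> dict[str, tuple[tuple[str, ...], str]]:
        return dict(self.factor_levels)

    def formula(self) -> str:
        parts = list(self.fixed)
        for re_ in self.random:
            bar = "|" if re_.correlated or len(re_.terms) == 1 else "||"
            parts.append(f"({' + '.join(re_.terms)} {bar} {re_.factor})")
        return f"{self.response} ~ {' + '.join(parts)}"


_RANDOM_RE = re.compile(r"\(([^|()]+)(\|\||\|)([^|()]+)\)")


def parse_formula(formula: str, family: str = "binomial",
                  factor_levels: Mapping[str, tuple[Sequence[str], str]] | None = None) -> ModelSpec:
    """Parse ``response ~ terms + (terms | factor) + (terms || factor)``.

    ``||`` denotes the zero-correlation structure.  The intercept is
    implicit in both the fixed and random parts.
    """
    if "~" not in formula:
        raise ValueError("formula must contain '~'")
    lhs, rhs = formula.split("~", 1)
    response = lhs.strip()
    if not response:
        raise ValueError("formula has no response")
    random: list[RandomEffects] = []

    def _grab(m: re.Match) -> str:
        terms = tuple(t.strip() for t in m.group(1).split("+") if t.strip())
        random.append(
            RandomEffects(
                factor=m.group(3).strip(),
                terms=terms if terms else ("1",),
                correlated=m.group(2) == "|",
            )
        )
        return ""

    rest = _RANDOM_RE.sub(_grab, rhs)
    fixed = tuple(t.strip() for t in rest.split("+") if t.strip())
    fl = tuple(
        (c, (tuple(levels), ref)) for c, (levels, ref) in (factor_levels or {}).items()
    )
    return ModelSpec(response=response, family=family, fixed=fixed,
                     random=tuple(random), factor_levels=fl)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _is_categorical(table: pd.DataFrame, col: str) -> bool:
    return not pd.api.types.is_numeric_dtype(table[col])


def _levels_for(spec: ModelSpec, table: pd.DataFrame | None, col: str) -> tuple[tuple[str, ...], str]:
    fl = spec.factor_level_map
    if col in fl:
        return fl[col]
    if table is None:
        raise ValueError(f"levels for factor {col!r} not declared in the model spec")
    levels = tuple(sorted(map(str, pd.unique(table[col]))))
    return levels, levels[0]


def _expand_atom(spec: ModelSpec, table: pd.DataFrame, atom: str) -> tuple[np.ndarray, list[str]]:
    """Expand one non-interaction atom to design columns."""
    n = len(table)
    if atom == "1":
        return np.ones((n, 1)), ["intercept"]
    if atom not in table.columns:
        raise KeyError(f"column {atom!r} not found in the observation table")
    if atom in spec.factor_level_map or _is_categorical(table, atom):
        levels, ref = _levels_for(spec, table, atom)
        vals = table[atom].astype(str).to_numpy()
        unknown = set(np.unique(vals)) - set(levels)
        if unknown:
            raise ValueError(f"column {atom!r} has undeclared levels {sorted(unknown)}")
        cols = [(vals == lv).astype(float) for lv in levels if lv != ref]
        names = [f"{atom}[{lv}]" for lv in levels if lv != ref]
        return np.column_stack(cols), names
    x = table[atom].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"column {atom!r} contains non-finite values")
    return x[:, None], [atom]


def build_design(spec: ModelSpec, table: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the given terms (columns in term order)."""
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for term in terms:
        atoms = [a.strip() for a in term.split(":")]
        mat, nm = _expand_atom(spec, table, atoms[0])
        for a in atoms[1:]:
            m2, n2 = _expand_atom(spec, table, a)
            mat = np.einsum("ni,nj->nij", mat, m2).reshape(len(table), -1)
            nm = [f"{x}:{y}" for x in nm for y in n2]
        blocks.append(mat)
        names.extend(nm)
    X = np.column_stack(blocks)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate design columns: {names}")
    return X, names


def _term_ncols(spec: ModelSpec, term: str) -> int:
    n = 1
    for a in term.split(":"):
        a = a.strip()
        if a != "1" and a in spec.factor_level_map:
            n *= len(spec.factor_level_map[a][0]) - 1
    return n


def count_parameters(spec: ModelSpec) -> tuple[int, int, int]:
    """(fixed, variance, correlation) parameter counts for a spec.

    Per grouping factor with m expanded random terms the maximal
    structure has m variances and m(m-1)/2 correlations; zcp has m
    variances; intercept-only has one variance.
    """
    k_fixed = sum(_term_ncols(spec, t) for t in spec.fixed)
    k_var = 0
    k_corr = 0
    for re_ in spec.random:
        m = sum(_term_ncols(spec, t) for t in re_.terms)
        k_var += m
        if re_.correlated:
            k_corr += m * (m - 1) // 2
    return k_fixed, k_var, k_corr


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

class _Family:
    name: str

    @staticmethod
    def make(name: str) -> "_Family":
        return {"binomial": _Binomial, "poisson": _Poisson}[name]()


class _Binomial(_Family):
    name = "binomial"

    def check_response(self, y: np.ndarray) -> None:
        if not np.isin(y, (0, 1)).all():
            raise ValueError("binomial responses must be 0/1")

    def linkinv(self, eta: np.ndarray) -> np.ndarray:
        return np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)

    def weights(self, mu: np.ndarray) -> np.ndarray:
        return mu * (1.0 - mu)

    def deviance(self, y: np.ndarray, mu: np.ndarray) -> float:
        return -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))

    def loglik(self, y: np.ndarray, mu: np.ndarray) -> float:
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))

    def start_intercept(self, y: np.ndarray) -> float:
        p = np.clip(y.mean(), 1e-3, 1 - 1e-3)
        return float(np.log(p / (1 - p)))

    resid_variance = np.pi**2 / 3.0  # logit-scale residual for R^2


class _Poisson(_Family):
    name = "poisson"

    def check_response(self, y: np.ndarray) -> None:
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("poisson responses must be non-negative integers")

    def linkinv(self, eta: np.ndarray) -> np.ndarray:
        return np.clip(np.exp(np.clip(eta, -30, 30)), _MU_EPS, None)

    def weights(self, mu: np.ndarray) -> np.ndarray:
        return mu

    def deviance(self, y: np.ndarray, mu: np.ndarray) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
        return 2.0 * float(np.sum(ylogy - (y - mu)))

    def loglik(self, y: np.ndarray, mu: np.ndarray) -> float:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))

    def start_intercept(self, y: np.ndarray) -> float:
        return float(np.log(max(y.mean(), 1e-3)))


# ---------------------------------------------------------------------------
# Random-effect bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class _FactorBlock:
    name: str
    levels: np.ndarray  # level labels in code order
    codes: np.ndarray  # (n,) int
    C: np.ndarray  # (n, k) random-effect design
    term_names: list[str]
    correlated: bool
    offset: int = 0  # start of this factor's block in the stacked u vector

    @property
    def q(self) -> int:
        return len(self.levels)

    @property
    def k(self) -> int:
        return self.C.shape[1]

    @property
    def n_theta(self) -> int:
        return self.k * (self.k + 1) // 2 if self.correlated else self.k

    def lam(self, th: np.ndarray) -> np.ndarray:
        """Lower-triangular Cholesky factor from its theta slice."""
        k = self.k
        L = np.zeros((k, k))
        if self.correlated:
            idx = np.tril_indices(k)
            L[idx] = th  # row-major lower triangle, diagonal included
        else:
            L[np.diag_indices(k)] = th
        return L

    def theta_bounds(self) -> list[tuple[float, float]]:
        k = self.k
        if not self.correlated:
            return [(0.0, 50.0)] * k
        bounds = []
        for i, j in zip(*np.tril_indices(k)):
            bounds.append((0.0, 50.0) if i == j else (-50.0, 50.0))
        return bounds

    def theta_start(self) -> np.ndarray:
        k = self.k
        if not self.correlated:
            return np.ones(k)
        i, j = np.tril_indices(k)
        return (i == j).astype(float)


def _make_blocks(spec: ModelSpec, table: pd.DataFrame) -> list[_FactorBlock]:
    blocks: list[_FactorBlock] = []
    offset = 0
    for re_ in spec.random:
        if re_.factor not in table.columns:
            raise KeyError(f"grouping factor {re_.factor!r} not in table")
        labels = table[re_.factor].astype(str).to_numpy()
        levels, codes = np.unique(labels, return_inverse=True)
        C, names = build_design(spec, table, list(re_.terms))
        fb = _FactorBlock(
            name=re_.factor, levels=levels, codes=codes.astype(np.intp),
            C=C, term_names=names, correlated=re_.correlated, offset=offset,
        )
        blocks.append(fb)
        offset += fb.q * fb.k
    return blocks


class _Workspace:
    """Precomputed group-sum operators for fast cross-product assembly.

    For every grouping factor a sparse indicator matrix sums arbitrary
    per-row quantities into per-level totals in one pass; a second
    indicator per factor pair handles the cross blocks of Zt W Z.
    """

    def __init__(self, X: np.ndarray, blocks: list[_FactorBlock]):
        n, p = X.shape
        self.X = X
        self.blocks = blocks
        self.qr = sum(b.q * b.k for b in blocks)
        ones = np.ones(n)
        indptr = np.arange(n + 1)
        # Group-sum operators as CSC with exactly one entry per observation
        # (column); data is replaced by the IRLS weights each iteration so
        # the weighting happens inside the single sparse pass.
        self.S = [
            sparse.csc_matrix((ones.copy(), b.codes.copy(), indptr), shape=(b.q, n))
            for b in blocks
        ]
        self.pairs = [
            (f, g) for f in range(len(blocks)) for g in range(f + 1, len(blocks))
        ]
        self.pair_S = {}
        for f, g in self.pairs:
            bf, bg = blocks[f], blocks[g]
            pc = bf.codes * bg.q + bg.codes
            self.pair_S[(f, g)] = sparse.csc_matrix(
                (ones.copy(), pc.astype(np.int32), indptr.astype(np.int32)),
                shape=(bf.q * bg.q, n),
            )
        # One stacked matrix of all weight-independent per-row products:
        # per factor [C_a*C_b (tril pairs) | C_a*X_j | C_a], then per factor
        # pair [Cf_a*Cg_b].  Per iteration it is scaled by w once and summed
        # into per-level / per-level-pair totals by sparse indicator matmuls.
        self.Uf: list[np.ndarray] = []
        self.pair_idx = []
        for b in blocks:
            ii, jj = np.tril_indices(b.k)
            self.pair_idx.append((ii, jj))
            block = np.concatenate(
                [
                    b.C[:, ii] * b.C[:, jj],
                    (b.C[:, :, None] * X[:, None, :]).reshape(n, -1),
                ],
                axis=1,
            )
            self.Uf.append(np.ascontiguousarray(block))
        self.Up: dict[tuple[int, int], np.ndarray] = {}
        for f, g in self.pairs:
            bf, bg = blocks[f], blocks[g]
            self.Up[(f, g)] = np.ascontiguousarray(
                (bf.C[:, :, None] * bg.C[:, None, :]).reshape(n, -1)
            )
        self.XXp = np.ascontiguousarray(
            (X[:, :, None] * X[:, None, :]).reshape(n, -1)
        )
        # Precomputed scatter indices into the dense A.
        self._within_scatter = []
        for f, b in enumerate(blocks):
            lev = b.offset + np.arange(b.q) * b.k
            ii, jj = self.pair_idx[f]
            self._within_scatter.append(
                [(lev + a_, lev + b_) for a_, b_ in zip(ii, jj)]
            )
        self._cross_scatter = {}
        for f, g in self.pairs:
            bf, bg = blocks[f], blocks[g]
            ridx = bf.offset + (np.arange(bf.q) * bf.k)[:, None, None, None] + np.arange(bf.k)[None, None, :, None]
            cidx = bg.offset + (np.arange(bg.q) * bg.k)[None, :, None, None] + np.arange(bg.k)[None, None, None, :]
            self._cross_scatter[(f, g)] = (
                np.broadcast_to(ridx, (bf.q, bg.q, bf.k, bg.k)).reshape(-1),
                np.broadcast_to(cidx, (bf.q, bg.q, bf.k, bg.k)).reshape(-1),
            )

    def assemble(self, w: np.ndarray, ztilde: np.ndarray):
        """Weighted cross products: A = ZtWZ, ZX = ZtWX, zr = ZtWz, plus X parts."""
        X = self.X
        n, p = X.shape
        qr = self.qr
        A = np.zeros((qr, qr))
        ZX = np.empty((qr, p))
        zr = np.empty(qr)
        wz = w * ztilde
        for f, b in enumerate(self.blocks):
            S = self.S[f]
            S.data[:] = w
            G = S @ self.Uf[f]  # (q, npair + k*p), weighted inside the pass
            npair = len(self.pair_idx[f][0])
            for c, (ridx, cidx) in enumerate(self._within_scatter[f]):
                A[ridx, cidx] = G[:, c]
                A[cidx, ridx] = G[:, c]
            ZX[b.offset : b.offset + b.q * b.k] = G[:, npair:].reshape(b.q * b.k, p)
            S.data[:] = wz
            zr[b.offset : b.offset + b.q * b.k] = (S @ b.C).reshape(-1)
        for f, g in self.pairs:
            S = self.pair_S[(f, g)]
            S.data[:] = w
            P = (S @ self.Up[(f, g)]).reshape(-1)
            ridx, cidx = self._cross_scatter[(f, g)]
            A[ridx, cidx] = P
            A[cidx, ridx] = P
        XtWX = (w @ self.XXp).reshape(p, p)
        Xtz = self.X.T @ wz
        return A, ZX, zr, XtWX, Xtz

    def eta_random(self, u: np.ndarray, lams: list[np.ndarray]) -> np.ndarray:
        out = np.zeros(self.X.shape[0])
        for b, L in zip(self.blocks, lams):
            B = u[b.offset : b.offset + b.q * b.k].reshape(b.q, b.k) @ L.T
            out += np.einsum("nk,nk->n", b.C, B[b.codes])
        return out


def _apply_lambda(A: np.ndarray, ZX: np.ndarray, zr: np.ndarray,
                  blocks: list[_FactorBlock], lams: list[np.ndarray]):
    """Transform Z-side cross products by the block-diagonal Lambda."""
    qr = A.shape[0]
    At = A.copy()
    for b, L in zip(blocks, lams):  # left-multiply rows by Lambda^T
        sl = slice(b.offset, b.offset + b.q * b.k)
        At[sl] = np.einsum("ij,qjr->qir", L.T, At[sl].reshape(b.q, b.k, qr)).reshape(
            b.q * b.k, qr
        )
    for b, L in zip(blocks, lams):  # right-multiply columns by Lambda
        sl = slice(b.offset, b.offset + b.q * b.k)
        At[:, sl] = (At[:, sl].reshape(qr, b.q, b.k) @ L).reshape(qr, b.q * b.k)
    ZXt = ZX.copy()
    zrt = zr.copy()
    for b, L in zip(blocks, lams):
        sl = slice(b.offset, b.offset + b.q * b.k)
        ZXt[sl] = np.einsum("ij,qjp->qip", L.T, ZXt[sl].reshape(b.q, b.k, -1)).reshape(
            b.q * b.k, -1
        )
        zrt[sl] = (L.T @ zrt[sl].reshape(b.q, b.k).T).T.reshape(-1)
    return At, ZXt, zrt


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class GLMMFit:
    """A fitted GLMM.

    ``fixed`` has one row per fixed-effect design column (estimate ``b``,
    ``se``, ``z``, ``p``); ``random_cov[factor]`` is the estimated
    covariance matrix of that factor's random effects (DataFrame indexed
    and labelled by term); ``cond_modes[factor]`` holds per-level
    conditional modes and ``cond_var[factor]`` the matching conditional
    variances.  ``loglik`` is the Laplace log-likelihood, ``n_params``
    counts fixed effects plus variance and correlation parameters.
    """

    spec: ModelSpec
    fixed: pd.DataFrame
    random_cov: dict[str, pd.DataFrame]
    theta: np.ndarray
    loglik: float
    deviance: float
    n_obs: int
    n_params: int
    cond_modes: dict[str, pd.DataFrame]
    cond_var: dict[str, pd.DataFrame]
    converged: bool
    singular: bool
    singular_flags: list[str]
    opt_message: str
    n_outer_evals: int
    fitted_linear: np.ndarray = field(repr=False)
    fitted_fixed_linear: np.ndarray = field(repr=False)
    fitted_mean: np.ndarray = field(repr=False)
    random_design_var: dict[str, float] = field(default_factory=dict)
    y_digest: str = ""

    @property
    def coef(self) -> pd.Series:
        return self.fixed["b"]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _pirls(fam, y, ws: _Workspace, blocks, lams, u, beta, *, tol=1e-11, max_iter=80):
    """Penalized IRLS for (u, beta) at fixed Lambda.

    Minimizes deviance(y, mu) + ||u||^2.  Returns the converged state and
    the log-determinant of the u-block of the weighted system at the
    final weights (the Laplace curvature term).
    """
    X = ws.X
    p = X.shape[1]
    qr = ws.qr
    # Per-row random contribution is rowdot(C Lambda, u_by_level[codes]);
    # C Lambda is fixed within a call and the gather is linear in u, so
    # step-halving interpolates gathers instead of re-gathering.
    CL = [b.C @ L for b, L in zip(blocks, lams)]

    def _gather(uvec):
        return [
            uvec[b.offset : b.offset + b.q * b.k].reshape(b.q, b.k)[b.codes]
            for b in blocks
        ]

    def _eta(bvec, gathers):
        e = X @ bvec
        for cl, g in zip(CL, gathers):
            e += np.einsum("nk,nk->n", cl, g)
        return e

    G = _gather(u)
    eta = _eta(beta, G)
    mu = fam.linkinv(eta)
    pdev = fam.deviance(y, mu) + float(u @ u)
    logdet = 0.0
    for _ in range(max_iter):
        w = np.clip(fam.weights(mu), 1e-12, None)
        ztilde = eta + (y - mu) / w
        A, ZX, zr, XtWX, Xtz = ws.assemble(w, ztilde)
        At, ZXt, zrt = _apply_lambda(A, ZX, zr, blocks, lams)
        M = np.empty((qr + p, qr + p))
        M[:qr, :qr] = At
        M[np.diag_indices(qr)[0], np.diag_indices(qr)[1]] += 1.0
        M[:qr, qr:] = ZXt
        M[qr:, :qr] = ZXt.T
        M[qr:, qr:] = XtWX
        rhs = np.concatenate([zrt, Xtz])
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0])[:qr])))
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        u_new, beta_new = sol[:qr], sol[qr:]
        G_new = _gather(u_new)
        # step-halving on the penalized deviance; a step that cannot
        # improve even after halving means we are at the (numerical)
        # optimum for this Lambda, so stop rather than drift
        step = 1.0
        improved = False
        for _half in range(10):
            u_try = u + step * (u_new - u)
            beta_try = beta + step * (beta_new - beta)
            G_try = [g + step * (gn - g) for g, gn in zip(G, G_new)]
            eta_try = _eta(beta_try, G_try)
            mu_try = fam.linkinv(eta_try)
            pdev_try = fam.deviance(y, mu_try) + float(u_try @ u_try)
            # a step saturating the linear predictor is in the flat,
            # clipped-likelihood region; reject it like a non-improvement
            if (
                np.isfinite(pdev_try)
                and np.abs(eta_try).max() < 1e2
                and pdev_try <= pdev + 1e-10 * (abs(pdev) + 1.0)
            ):
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        delta = pdev - pdev_try
        u, beta, G, eta, mu, pdev = u_try, beta_try, G_try, eta_try, mu_try, pdev_try
        if abs(delta) < tol * (abs(pdev) + 1.0):
            break
    return u, beta, eta, mu, pdev, logdet


def fit(
    spec: ModelSpec,
    table: pd.DataFrame,
    *,
    fix_theta: np.ndarray | None = None,
    start_theta: np.ndarray | None = None,
    outer_maxiter: int = 500,
    outer_ftol: float = 1e-10,
    outer_eps: float = 1e-5,
    pirls_tol: float = 1e-11,
) -> GLMMFit:
    """Fit a GLMM by Laplace-approximated maximum likelihood.

    ``fix_theta`` pins the covariance parameters (no outer optimization);
    useful for degenerate-structure checks against a plain GLM.  Boundary
    fits (a variance near zero, a correlation near +-1) are flagged, not
    errors; non-convergence of the outer optimizer is reported in
    ``converged`` / ``opt_message`` and never silent.
    """
    if spec.response not in table.columns:
        raise KeyError(f"response column {spec.response!r} not in table")
    fam = _Family.make(spec.family)
    y = table[spec.response].to_numpy(dtype=float)
    fam.check_response(y)
    X, fixed_names = build_design(spec, table, list(spec.fixed))
    blocks = _make_blocks(spec, table)
    if not blocks:
        raise ValueError("at least one random grouping factor is required")
    ws = _Workspace(X, blocks)
    p = X.shape[1]
    qr = ws.qr

    th_slices: list[slice] = []
    start = []
    bounds = []
    pos = 0
    for b in blocks:
        th_slices.append(slice(pos, pos + b.n_theta))
        start.append(b.theta_start())
        bounds.extend(b.theta_bounds())
        pos += b.n_theta
    theta0 = np.concatenate(start)
    if start_theta is not None:
        start_theta = np.asarray(start_theta, dtype=float)
        if start_theta.shape != theta0.shape:
            raise ValueError(f"start_theta must have {theta0.size} elements")
        theta0 = np.clip(start_theta, [b[0] for b in bounds], [b[1] for b in bounds])

    beta0 = np.zeros(p)
    if "intercept" in fixed_names:
        beta0[fixed_names.index("intercept")] = fam.start_intercept(y)
    state = {"u": np.zeros(qr), "beta": beta0.copy(), "evals": 0}

    def lams_of(th: np.ndarray) -> list[np.ndarray]:
        return [b.lam(th[sl]) for b, sl in zip(blocks, th_slices)]

    def _solve(lams, u_start, beta_start, tol=None, max_iter=80):
        """PIRLS from a warm start, falling back to the cold start if the
        warm trajectory degenerates (non-finite or runaway estimates)."""
        out = _pirls(
            fam, y, ws, blocks, lams, u_start.copy(), beta_start.copy(),
            tol=pirls_tol if tol is None else tol, max_iter=max_iter,
        )
        bad = not np.isfinite(out[4]) or np.abs(out[1]).max() > 1e3
        if bad and (np.any(u_start) or np.any(beta_start != beta0)):
            out = _pirls(
                fam, y, ws, blocks, lams, np.zeros(qr), beta0.copy(),
                tol=pirls_tol if tol is None else tol, max_iter=max_iter,
            )
        return out

    def objective(th: np.ndarray) -> float:
        lams = lams_of(th)
        u, beta, eta, mu, pdev, logdet = _solve(lams, state["u"], state["beta"])
        state["evals"] += 1
        obj = pdev + logdet
        if not np.isfinite(obj) or np.abs(beta).max() > 1e3:
            return 1e12  # keep the previous warm state
        state["u"], state["beta"] = u, beta
        return obj

    if fix_theta is not None:
        theta = np.asarray(fix_theta, dtype=float)
        if theta.shape != theta0.shape:
            raise ValueError(f"fix_theta must have {theta0.size} elements")
        converged, message = True, "theta fixed by caller"
    else:
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": outer_maxiter,
                "ftol": outer_ftol,
                "gtol": 1e-6,
                "eps": outer_eps,
            },
        )
        theta = res.x
        converged = bool(res.success)
        message = str(res.message)

    # Final converged state and curvature at the optimum.
    lams = lams_of(theta)
    u, beta, eta, mu, pdev, logdet = _solve(
        lams, state["u"], state["beta"], tol=1e-13, max_iter=120
    )
    w = np.clip(fam.weights(mu), 1e-12, None)
    ztilde = eta + (y - mu) / w
    A, ZX, zr, XtWX, Xtz = ws.assemble(w, ztilde)
    At, ZXt, _ = _apply_lambda(A, ZX, zr, blocks, lams)
    M_uu = At + np.eye(qr)
    cf_uu = linalg.cho_factor(M_uu, lower=True, check_finite=False)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf_uu[0]))))
    # Profiled fixed-effect covariance: Schur complement of the u block.
    AinvB = linalg.cho_solve(cf_uu, ZXt, check_finite=False)
    info_beta = XtWX - ZXt.T @ AinvB
    vcov_beta = np.linalg.inv(info_beta)
    se = np.sqrt(np.clip(np.diag(vcov_beta), 0, None))

    zval = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pval = 2.0 * stats.norm.sf(np.abs(zval))
    fixed = pd.DataFrame({"b": beta, "se": se, "z": zval, "p": pval}, index=fixed_names)

    loglik = fam.loglik(y, mu) - 0.5 * float(u @ u) - 0.5 * logdet
    deviance = fam.deviance(y, mu) + float(u @ u) + logdet
    kf, kv, kc = count_parameters(spec)
    n_params = kf + kv + kc

    # Random-effect summaries.
    Minv_uu = linalg.cho_solve(cf_uu, np.eye(qr), check_finite=False)
    random_cov: dict[str, pd.DataFrame] = {}
    cond_modes: dict[str, pd.DataFrame] = {}
    cond_var: dict[str, pd.DataFrame] = {}
    random_design_var: dict[str, float] = {}
    singular_flags: list[str] = []
    for b, L in zip(blocks, lams):
        Sigma = L @ L.T
        random_cov[b.name] = pd.DataFrame(Sigma, index=b.term_names, columns=b.term_names)
        var = np.diag(Sigma)
        sd = np.sqrt(np.clip(var, 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = Sigma / np.outer(sd, sd)
        for i, t in enumerate(b.term_names):
            if var[i] < SINGULAR_VARIANCE:
                singular_flags.append(f"{b.name}:{t} variance ~ 0")
        if b.correlated:
            for i in range(b.k):
                for j in range(i):
                    if np.isfinite(corr[i, j]) and abs(corr[i, j]) > SINGULAR_CORRELATION:
                        singular_flags.append(
                            f"{b.name}:({b.term_names[i]},{b.term_names[j]}) |corr| ~ 1"
                        )
        B = u[b.offset : b.offset + b.q * b.k].reshape(b.q, b.k) @ L.T
        cond_modes[b.name] = pd.DataFrame(B, index=b.levels, columns=b.term_names)
        cv = np.empty((b.q, b.k))
        for l in range(b.q):
            sl = slice(b.offset + l * b.k, b.offset + (l + 1) * b.k)
            cv[l] = np.diag(L @ Minv_uu[sl, sl] @ L.T)
        cond_var[b.name] = pd.DataFrame(cv, index=b.levels, columns=b.term_names)
        random_design_var[b.name] = float(np.mean(np.einsum("nk,kj,nj->n", b.C, Sigma, b.C)))

    return GLMMFit(
        spec=spec,
        fixed=fixed,
        random_cov=random_cov,
        theta=theta,
        loglik=loglik,
        deviance=deviance,
        n_obs=len(y),
        n_params=n_params,
        cond_modes=cond_modes,
        cond_var=cond_var,
        converged=converged,
        singular=bool(singular_flags),
        singular_flags=singular_flags,
        opt_message=message,
        n_outer_evals=state["evals"],
        fitted_linear=eta,
        fitted_fixed_linear=X @ beta,
        fitted_mean=mu,
        random_design_var=random_design_var,
        y_digest=hashlib.sha1(np.ascontiguousarray(y).tobytes()).hexdigest(),
    )


# ---------------------------------------------------------------------------
# Inference toolkit
# ---------------------------------------------------------------------------

def wald_table(fit_: GLMMFit) -> pd.DataFrame:
    """Per-term Wald summary: estimate, SE, z = b/SE, two-sided normal p."""
    out = fit_.fixed.copy()
    se = out["se"].to_numpy()
    b = out["b"].to_numpy()
    z = np.divide(b, se, out=np.zeros_like(b), where=se > 0)
    out["z"] = z
    out["p"] = 2.0 * stats.norm.sf(np.abs(z))
    return out


def _expanded_random_terms(fit_: GLMMFit) -> dict[str, set[str]]:
    return {f: set(cov.index) for f, cov in fit_.random_cov.items()}


def lrt(fit_nested: GLMMFit, fit_full: GLMMFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a full model.

    chi2 = 2 (l_full - l_nested), df = difference in parameter counts,
    p from the chi-square distribution (no boundary correction).
    """
    if fit_nested.n_obs != fit_full.n_obs or fit_nested.y_digest != fit_full.y_digest:
        raise ValueError("LRT requires both models fitted to the same data")
    if fit_nested.spec.family != fit_full.spec.family:
        raise ValueError("LRT requires the same family")
    if not set(fit_nested.fixed.index) <= set(fit_full.fixed.index):
        raise ValueError("fixed effects of the nested model are not a subset")
    full_rand = _expanded_random_terms(fit_full)
    for f, terms in _expanded_random_terms(fit_nested).items():
        if f not in full_rand or not terms <= full_rand[f]:
            raise ValueError(f"random terms for {f!r} are not nested")
    df = fit_full.n_params - fit_nested.n_params
    if df < 0:
        raise ValueError("nested model has more parameters than the full model")
    chi2 = 2.0 * (fit_full.loglik - fit_nested.loglik)
    if df == 0:
        return chi2, 0, 1.0 if abs(chi2) < 1e-8 else 0.0
    return chi2, df, float(stats.chi2.sf(max(chi2, 0.0), df))


def information_criteria(fit_: GLMMFit) -> tuple[float, float]:
    """(AIC, BIC): -2l + 2k and -2l + k ln N."""
    k = fit_.n_params
    aic = -2.0 * fit_.loglik + 2.0 * k
    bic = -2.0 * fit_.loglik + k * np.log(fit_.n_obs)
    return float(aic), float(bic)


def marginal_conditional_r2(fit_: GLMMFit) -> tuple[float, float]:
    """Variance explained by fixed effects alone vs fixed plus random.

    R2_m = s2_f / (s2_f + s2_r + s2_d); R2_c adds s2_r to the numerator.
    s2_f is the variance of the fixed-effect linear predictor over the
    data; s2_r sums, per grouping factor, the mean over observations of
    the random-effect design variance z' Sigma z (which reduces to the
    intercept variance for intercept-only structures); s2_d is the
    link-scale residual variance, pi^2/3 for the logit and
    ln(1 + 1/mean(mu)) for the Poisson log link.
    """
    if not fit_.converged:
        raise ValueError("R^2 is undefined for a non-converged fit")
    s2_f = float(np.var(fit_.fitted_fixed_linear))
    s2_r = float(sum(fit_.random_design_var.values()))
    if fit_.spec.family == "binomial":
        s2_d = _Binomial.resid_variance
    else:
        s2_d = float(np.log1p(1.0 / np.mean(fit_.fitted_mean)))
    denom = s2_f + s2_r + s2_d
    return s2_f / denom, (s2_f + s2_r) / denom


def conditional_mode_intervals(fit_: GLMMFit, factor: str) -> pd.DataFrame:
    """Per-level conditional modes with 95% prediction intervals.

    interval = mode +- 1.96 sqrt(conditional variance); the data product
    behind caterpillar plots.  Long format: level, term, mode, lower,
    upper.
    """
    modes = fit_.cond_modes[factor]
    cv = fit_.cond_var[factor]
    rows = []
    for term in modes.columns:
        half = 1.96 * np.sqrt(np.clip(cv[term].to_numpy(), 0, None))
        rows.append(
            pd.DataFrame(
                {
                    "level": modes.index,
                    "term": term,
                    "mode": modes[term].to_numpy(),
                    "lower": modes[term].to_numpy() - half,
                    "upper": modes[term].to_numpy() + half,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def individual_coefficients(fit_: GLMMFit, factor: str, term: str) -> pd.Series:
    """Per-level coefficient = fixed estimate + conditional mode."""
    if term == "1":
        term = "intercept"
    if term not in fit_.fixed.index:
        raise KeyError(f"{term!r} is not a fixed effect")
    modes = fit_.cond_modes[factor]
    if term not in modes.columns:
        raise KeyError(f"{term!r} has no random component for factor {factor!r}")
    return fit_.fixed.loc[term, "b"] + modes[term]


def derived_fixed_coefficient(fit_: GLMMFit, base_term: str, interaction_term: str) -> float:
    """Simple-effect + interaction coefficient (treatment coding).

    E.g. the central-bias slope for a non-reference saliency map is the
    reference slope plus the map-difference interaction.
    """
    return float(fit_.fixed.loc[base_term, "b"] + fit_.fixed.loc[interaction_term, "b"])


def partial_effects(
    fit_: GLMMFit,
    keep_fixed_terms: Sequence[str],
    values: pd.DataFrame,
) -> np.ndarray:
    """Linear predictor (link scale) from a subset of fixed effects.

    All other fixed effects and every random effect are removed.  The
    kept terms are design-column names of the fit; ``values`` supplies
    the predictor columns needed to rebuild them.
    """
    keep = list(keep_fixed_terms)
    unknown = [t for t in keep if t not in fit_.fixed.index]
    if unknown:
        raise KeyError(f"unknown fixed terms: {unknown}")
    table = values.copy()
    # Rebuild the full fixed design on the supplied values; fill columns the
    # kept terms do not touch with zeros so build_design succeeds.
    spec = fit_.spec
    needed = set()
    for term in spec.fixed:
        for a in term.split(":"):
            a = a.strip()
            if a != "1":
                needed.add(a)
    for col in needed:
        if col not in table.columns:
            if col in spec.factor_level_map:
                table[col] = spec.factor_level_map[col][1]  # reference level
            else:
                table[col] = 0.0
    Xv, names = build_design(spec, table, list(spec.fixed))
    b = fit_.fixed["b"].reindex(names).to_numpy()
    mask = np.array([nm in keep for nm in names], dtype=float)
    return Xv @ (b * mask)


def comparison_spec(
    maps: Sequence[str],
    reference: str,
    *,
    response: str = "fixated",
    cb: str = "cb_z",
    sal: str = "sal_z",
    map_column: str = "map",
    subject: str = "subject",
    item: str = "image",
    structure: str = "maximal",
    family: str = "binomial",
) -> ModelSpec:
    """GLMM comparing saliency maps via a treatment-coded map factor.

    Fixed part: intercept, central bias and saliency simple effects for
    the reference map, and map x central-bias plus map x saliency
    interactions (for three maps: seven fixed effects).  The random part
    carries the same non-intercept terms per grouping factor.
    """
    maps = list(maps)
    if reference not in maps:
        raise ValueError(f"reference {reference!r} not among maps {maps}")
    if len(maps) < 2:
        raise ValueError("need at least two maps to compare")
    fixed = ("1", cb, sal, f"{map_column}:{cb}", f"{map_column}:{sal}")
    if structure == "intercept":
        rterms: tuple[str, ...] = ("1",)
    else:
        rterms = fixed
    correlated = structure == "maximal"
    return ModelSpec(
        response=response,
        family=family,
        fixed=fixed,
        random=(
            RandomEffects(factor=subject, terms=rterms, correlated=correlated),
            RandomEffects(factor=item, terms=rterms, correlated=correlated),
        ),
        factor_levels=((map_column, (tuple(maps), reference)),),
    )


def enumerate_control_specs(
    maps: Sequence[str],
    cb_names: Sequence[str],
    grids: Sequence[tuple[int, int]],
    *,
    response: str = "fixated",
    subject: str = "subject",
    item: str = "image",
    family: str = "binomial",
) -> list[dict]:
    """Enumerate the control-analysis grid of two-predictor GLMM specs.

    One spec per (saliency map x central-bias predictor x grid geometry x
    random structure in {maximal, zcp, intercept}); three maps, seven
    central-bias predictors and three grids give 189 models.
    """
    out = []
    for map_name in maps:
        for cb_name in cb_names:
            for grid in grids:
                for structure in ("maximal", "zcp", "intercept"):
                    terms = ("1",) if structure == "intercept" else ("1", f"{cb_name}_z", f"{map_name}_z")
                    spec = ModelSpec(
                        response=response,
                        family=family,
                        fixed=("1", f"{cb_name}_z", f"{map_name}_z"),
                        random=(
                            RandomEffects(subject, terms, structure == "maximal"),
                            RandomEffects(item, terms, structure == "maximal"),
                        ),
                    )
                    out.append(
                        {
                            "map": map_name,
                            "central_bias": cb_name,
                            "grid": grid,
                            "structure": structure,
                            "spec": spec,
                        }
                    )
    return out


def propose_simplification(fit_: GLMMFit) -> list[str]:
    """Parsimony heuristic: parameters whose estimates sit on the boundary.

    Returns the singularity flags (variances ~ 0, correlations ~ +-1)
    collected at fit time; dropping exactly these is the conventional
    first simplification step.
    """
    return list(fit_.singular_flags)
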