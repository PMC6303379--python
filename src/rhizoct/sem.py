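"""Recursive path analysis: standardized coefficients and covariance fit indices.

A recursive path model (a DAG over observed variables with uncorrelated
equation errors) is fitted by maximum likelihood on the sample covariance
matrix. For this model class the ML estimates coincide with equation-wise
least squares, which is used as the closed-form estimator; the implied
covariance Σ̂ = (I−B)⁻¹ Ψ (I−B)⁻ᵀ then yields the usual discrepancy-based
fit statistics:

    F_ML  = log|Σ̂| + tr(S Σ̂⁻¹) − log|S| − p
    χ²    = (n − 1) · F_ML,   df = p(p+1)/2 − free parameters
    GFI   = 1 − tr[(Σ̂⁻¹ (S − Σ̂))²] / tr[(Σ̂⁻¹ S)²]
    RMSEA = sqrt(max(χ² − df, 0) / (df · (n − 1)))   (0 when df = 0)

All variables are standardized internally, so reported coefficients are
standardized path weights (χ² is invariant to this rescaling). Carbon
treatment enters as an ordinal 1/2/3 score by default; a two-column 0/1
dummy coding is available via :func:`carbon_dummies`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

CARBON_SCORE = {"none": 1, "moderate": 2, "high": 3}


class PathModelError(ValueError):
    pass


def code_carbon(level: str) -> int:
    """Ordinal 1/2/3 coding of the carbon treatment."""
    try:
        return CARBON_SCORE[level]
    except KeyError:
        raise PathModelError(f"unknown carbon level {level!r}; expected one of {sorted(CARBON_SCORE)}") from None


def carbon_dummies(levels: pd.Series) -> pd.DataFrame:
    """Two-indicator 0/1 dummy coding (moderate, high) vs the no-carbon base."""
    return pd.DataFrame(
        {"carbon_moderate": (levels == "moderate").astype(float), "carbon_high": (levels == "high").astype(float)}
    )


@dataclass
class PathModelSpec:
    """Directed edges (cause → effect) over named observed variables.

    ``exogenous`` defaults to the parentless variables. Declaring it
    explicitly matters for nested-model tests: a parentless variable *not*
    declared exogenous is treated as endogenous with all its incoming paths
    fixed at zero (so its covariance with the rest of the system is a model
    constraint rather than a free parameter).
    """

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    exogenous: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for cause, effect in self.edges:
            for v in (cause, effect):
                if v not in self.variables:
                    raise PathModelError(f"edge endpoint {v!r} not among declared variables {self.variables}")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise PathModelError("edge set contains a cycle; only recursive (DAG) models are supported")
        g = self.graph()
        if self.exogenous is None:
            self.exogenous = tuple(v for v in self.variables if g.in_degree(v) == 0)
        else:
            self.exogenous = tuple(self.exogenous)
            for v in self.exogenous:
                if v not in self.variables:
                    raise PathModelError(f"declared exogenous variable {v!r} not among variables")
                if g.in_degree(v) > 0:
                    raise PathModelError(f"declared exogenous variable {v!r} has incoming edges")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    @property
    def endogenous(self) -> tuple[str, ...]:
        return tuple(v for v in self.variables if v not in self.exogenous)

    @classmethod
    def from_text(cls, text: str) -> "PathModelSpec":
        """Parse a model from ``effect <- cause`` lines (one edge per line)."""
        edges = []
        variables: list[str] = []
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "<-" not in line:
                raise PathModelError(f"line {lineno}: expected 'effect <- cause', got {raw!r}")
            effect, cause = (s.strip() for s in line.split("<-", 1))
            if not effect or not cause:
                raise PathModelError(f"line {lineno}: empty endpoint in {raw!r}")
            edges.append((cause, effect))
            for v in (cause, effect):
                if v not in variables:
                    variables.append(v)
        if not edges:
            raise PathModelError("model text contains no edges")
        return cls(variables=tuple(variables), edges=tuple(edges))


@dataclass
class PathModelFit:
    spec: PathModelSpec
    coefficients: pd.DataFrame  # per edge: estimate, se, z, p
    residual_variances: dict[str, float]
    implied_cov: pd.DataFrame
    sample_cov: pd.DataFrame
    chi_square: float
    df: int
    p_chi: float
    gfi: float
    rmsea: float
    n: int

    @property
    def acceptable(self) -> bool:
        """Non-significant χ² (p > 0.05), the conventional acceptance flag."""
        return self.df == 0 or self.p_chi > 0.05

    def summary(self) -> str:
        lines = [f"Recursive path model, n={self.n}"]
        for _, r in self.coefficients.iterrows():
            stars = "***" if r.p < 0.001 else "**" if r.p < 0.01 else "*" if r.p < 0.05 else ""
            lines.append(f"  {r.effect} <- {r.cause}: {r.estimate:+.3f} (se {r.se:.3f}){stars}")
        lines.append(
            f"  fit: chi2={self.chi_square:.3f} df={self.df} p={self.p_chi:.3f} GFI={self.gfi:.3f} RMSEA={self.rmsea:.3f}"
        )
        return "\n".join(lines)


def _free_parameters(spec: PathModelSpec) -> int:
    n_exo = len(spec.exogenous)
    return len(spec.edges) + len(spec.endogenous) + n_exo + n_exo * (n_exo - 1) // 2


def fit_path_model(table: pd.DataFrame, spec: PathModelSpec) -> PathModelFit:
    """Fit a recursive path model by ML on the sample covariance.

    Variables are standardized internally; coefficients are standardized
    path weights with normal-theory SEs and two-sided normal p-values.
    """
    missing = [v for v in spec.variables if v not in table.columns]
    if missing:
        raise PathModelError(f"table lacks model variables {missing}")
    n = len(table)
    p = len(spec.variables)
    if n <= p:
        raise PathModelError(f"n={n} must exceed the number of variables ({p})")

    X = table.loc[:, list(spec.variables)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        flat = [v for v, s in zip(spec.variables, sd) if s == 0]
        raise PathModelError(f"variables with zero variance: {flat}")
    Z = (X - X.mean(axis=0)) / sd
    S = np.cov(Z, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(S) < p:
        raise PathModelError("singular sample covariance matrix")

    idx = {v: i for i, v in enumerate(spec.variables)}
    g = spec.graph()
    B = np.zeros((p, p))
    psi = np.zeros(p)
    rows = []
    for v in spec.variables:
        i = idx[v]
        parents = list(g.predecessors(v))
        if not parents:
            psi[i] = S[i, i]
            continue
        pj = [idx[u] for u in parents]
        Sxx = S[np.ix_(pj, pj)]
        Sxy = S[pj, i]
        b = np.linalg.solve(Sxx, Sxy)
        B[i, pj] = b
        resid_var = float(S[i, i] - Sxy @ b)
        psi[i] = max(resid_var, 1e-12)
        # normal-theory OLS standard errors on the standardized data
        sigma2 = psi[i] * (n - 1) / max(n - 1 - len(parents), 1)
        cov_b = sigma2 * np.linalg.inv(Sxx) / (n - 1)
        se = np.sqrt(np.diag(cov_b))
        for u, bj, sej in zip(parents, b, se):
            z = bj / sej if sej > 0 else np.inf
            rows.append({"cause": u, "effect": v, "estimate": float(bj), "se": float(sej),
                         "z": float(z), "p": float(2 * norm.sf(abs(z)))})

    # exogenous covariances are free (saturated block)
    exo = [idx[v] for v in spec.exogenous]
    Psi = np.diag(psi)
    for a in exo:
        for b_ in exo:
            if a != b_:
                Psi[a, b_] = S[a, b_]

    Iminus = np.eye(p) - B
    inv = np.linalg.inv(Iminus)
    sigma = inv @ Psi @ inv.T

    free = _free_parameters(spec)
    df = p * (p + 1) // 2 - free
    if df < 0:
        raise PathModelError(f"model has negative degrees of freedom ({df}): too many free parameters")

    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise PathModelError("non-positive-definite covariance matrix in fit")
    sigma_inv = np.linalg.inv(sigma)
    f_ml = float(logdet_m + np.trace(S @ sigma_inv) - logdet_s - p)
    chi2 = max((n - 1) * f_ml, 0.0)
    if df == 0:
        chi2 = 0.0
        p_chi = 1.0
        rmsea = 0.0
    else:
        from scipy.stats import chi2 as chi2_dist

        p_chi = float(chi2_dist.sf(chi2, df))
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    diff = S - sigma
    gfi = float(1.0 - np.trace(sigma_inv @ diff @ sigma_inv @ diff) / np.trace(sigma_inv @ S @ sigma_inv @ S))

    if n < 5 * free:
        warnings.warn(
            f"small sample: n={n} < 5x free parameters ({free}); SEM fit indices are unreliable", stacklevel=2
        )

    cols = list(spec.variables)
    return PathModelFit(
        spec=spec,
        coefficients=pd.DataFrame(rows),
        residual_variances={v: float(psi[idx[v]]) for v in spec.endogenous},
        implied_cov=pd.DataFrame(sigma, index=cols, columns=cols),
        sample_cov=pd.DataFrame(S, index=cols, columns=cols),
        chi_square=float(chi2),
        df=int(df),
        p_chi=float(p_chi),
        gfi=gfi,
        rmsea=rmsea,
        n=n,
    )


def compare_models(fits: list[PathModelFit]) -> pd.DataFrame:
    """Rank candidate fits by acceptability.

    Ordered by χ² p-value descending, then RMSEA ascending, then GFI
    descending; ``acceptable`` flags χ² p > 0.05 (or a saturated model).
    All fits must share the variables and sample size.
    """
    if not fits:
        raise PathModelError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if set(f.spec.variables) != set(ref.spec.variables) or f.n != ref.n:
            raise PathModelError("model comparison requires fits on the same variables and sample")
    rows = [
        {
            "model": i,
            "edges": len(f.spec.edges),
            "chi_square": f.chi_square,
            "df": f.df,
            "p_chi": f.p_chi,
            "gfi": f.gfi,
            "rmsea": f.rmsea,
            "acceptable": f.acceptable,
        }
        for i, f in enumerate(fits)
    ]
    out = pd.DataFrame(rows).sort_values(
        by=["p_chi", "rmsea", "gfi"], ascending=[False, True, False], kind="mergesort"
    )
    return out.reset_index(drop=True)
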