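"""Two-group recursive path analysis by maximum likelihood.

Fits a directed system of linear structural equations to per-group sample
covariance matrices.  The canonical model here is the herbivory ->
biomass -> nodulation diagram: herbivory may affect nodule number directly
and indirectly via root and shoot biomass, the root and shoot errors are
allowed to covary (shared micro-environment), and that error covariance
can be constrained equal across the two light-treatment groups.

For a recursive model with coefficient matrix B (``B[to, from]``) and
error/exogenous covariance Psi, the implied covariance is

    Sigma(theta) = (I - B)^-1  Psi  (I - B)^-T .

Estimation minimises the pooled ML discrepancy

    F = sum_g (n_g / N) [ log|Sigma_g| + tr(S_g Sigma_g^-1) - log|S_g| - p ]

with chi2 = (N - G) F_min (G groups).  Standard errors come from the
inverse observed information; cross-group differences in a coefficient are
judged by the critical ratio z = (b1 - b2) / sqrt(SE1^2 + SE2^2).  Means
are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covmatrix import CovMatrix

__all__ = [
    "PathModelSpec",
    "GroupSample",
    "PathModel",
    "PathResults",
    "parse_model",
    "herbivory_nodulation_spec",
    "fit_multigroup",
    "implied_covariance",
    "total_effects",
    "fit_indices",
    "simulate_group",
]


# ----------------------------------------------------------------------
# specification
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class PathModelSpec:
    """A recursive path diagram with error covariances and constraints."""

    variables: tuple[str, ...]
    directed_edges: tuple[tuple[str, str], ...]
    error_covariances: tuple[tuple[str, str], ...] = ()
    cross_group_equal: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        vs = set(self.variables)
        for a, b in list(self.directed_edges) + list(self.error_covariances):
            if a not in vs or b not in vs:
                raise ValueError(f"edge references unknown variable: {a!r}/{b!r}")
        # acyclicity via Kahn's algorithm
        indeg = {v: 0 for v in self.variables}
        for a, b in self.directed_edges:
            indeg[b] += 1
        queue = [v for v, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for a, b in self.directed_edges:
                if a == v:
                    indeg[b] -= 1
                    if indeg[b] == 0:
                        queue.append(b)
        if seen != len(self.variables):
            raise ValueError("path diagram contains a cycle; only recursive models are supported")
        names = set(self.param_names())
        for c in self.cross_group_equal:
            if c not in names:
                raise ValueError(f"cross-group constraint on unknown parameter {c!r}")

    @property
    def endogenous(self) -> tuple[str, ...]:
        targets = {b for _, b in self.directed_edges}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        targets = {b for _, b in self.directed_edges}
        return tuple(v for v in self.variables if v not in targets)

    def param_names(self) -> list[str]:
        """Within-group parameter names in canonical order."""
        names = [f"{a}->{b}" for a, b in self.directed_edges]
        names += [f"{v}~~{v}" for v in self.variables]
        names += [f"{a}~~{b}" for a, b in self.error_covariances]
        return names


def parse_model(text: str) -> PathModelSpec:
    """Parse the small text model format.

    One statement per line: ``a -> b`` (directed path), ``a ~~ b`` (error
    covariance), ``equal_across_groups: a~~b`` (cross-group equality
    constraint).  Variables are collected in order of first appearance.
    ``#`` starts a comment.
    """
    variables: list[str] = []
    edges: list[tuple[str, str]] = []
    covs: list[tuple[str, str]] = []
    equal: set[str] = set()

    def _seen(v: str) -> None:
        if v not in variables:
            variables.append(v)

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("equal_across_groups:"):
            equal.add(line.split(":", 1)[1].strip().replace(" ", ""))
        elif "->" in line:
            a, b = (s.strip() for s in line.split("->"))
            _seen(a), _seen(b)
            edges.append((a, b))
        elif "~~" in line:
            a, b = (s.strip() for s in line.split("~~"))
            _seen(a), _seen(b)
            covs.append((a, b))
        else:
            raise ValueError(f"cannot parse model line: {raw!r}")
    return PathModelSpec(tuple(variables), tuple(edges), tuple(covs), frozenset(equal))


def herbivory_nodulation_spec() -> PathModelSpec:
    """The herbivory -> biomass -> nodulation two-group diagram."""
    return parse_model(
        """
        herbivory -> root
        herbivory -> shoot
        herbivory -> nodules
        root -> nodules
        shoot -> nodules
        root ~~ shoot
        equal_across_groups: root~~shoot
        """
    )


@dataclass
class GroupSample:
    """One group's sample covariance matrix and sample size."""

    group: str
    cov: CovMatrix
    n: int

    def __post_init__(self) -> None:
        if self.n < self.cov.dim + 1:
            raise ValueError(
                f"group {self.group!r}: n={self.n} too small for {self.cov.dim} variables"
            )
        if np.linalg.eigvalsh(self.cov.values).min() <= 0:
            raise ValueError(
                f"group {self.group!r}: sample covariance is not positive definite; "
                "consider a ridge or more data"
            )


# ----------------------------------------------------------------------
# implied covariance
# ----------------------------------------------------------------------


def _matrices_from_params(
    values: dict[str, float], spec: PathModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    B = np.zeros((p, p))
    for a, b in spec.directed_edges:
        B[idx[b], idx[a]] = values[f"{a}->{b}"]
    Psi = np.zeros((p, p))
    for v in spec.variables:
        Psi[idx[v], idx[v]] = values[f"{v}~~{v}"]
    for a, b in spec.error_covariances:
        Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = values[f"{a}~~{b}"]
    return B, Psi


def implied_covariance(values: dict[str, float], spec: PathModelSpec) -> CovMatrix:
    """Sigma(theta) for a recursive model via the reduced form."""
    B, Psi = _matrices_from_params(values, spec)
    C = np.linalg.inv(np.eye(len(spec.variables)) - B)
    Sigma = C @ Psi @ C.T
    return CovMatrix(list(spec.variables), 0.5 * (Sigma + Sigma.T))


# ----------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------


class PathModel:
    """Multi-group path model fitted to sample covariance matrices."""

    def __init__(self, samples: list[GroupSample], spec: PathModelSpec) -> None:
        if not samples:
            raise ValueError("at least one group sample is required")
        for s in samples:
            if list(s.cov.labels) != list(spec.variables):
                # accept any order but require the same variable set, then align
                if set(s.cov.labels) != set(spec.variables):
                    raise ValueError(
                        f"group {s.group!r} variables {s.cov.labels} do not match "
                        f"model variables {list(spec.variables)}"
                    )
        self.spec = spec
        self.samples = samples
        self.groups = [s.group for s in samples]
        self.p = len(spec.variables)
        order = list(spec.variables)
        self.S = []
        for s in samples:
            perm = [s.cov.labels.index(v) for v in order]
            self.S.append(s.cov.values[np.ix_(perm, perm)])
        self.n = np.array([s.n for s in samples], dtype=float)
        self.N = float(self.n.sum())
        self._build_params()

    # -- parameter bookkeeping -----------------------------------------

    def _build_params(self) -> None:
        base = self.spec.param_names()
        self.free_names: list[str] = []
        self.slot: dict[tuple[str, str], int] = {}  # (group, base name) -> free index
        for name in base:
            if name in self.spec.cross_group_equal:
                fi = len(self.free_names)
                self.free_names.append(name)
                for g in self.groups:
                    self.slot[(g, name)] = fi
            else:
                for g in self.groups:
                    fi = len(self.free_names)
                    self.free_names.append(f"{g}:{name}" if len(self.groups) > 1 else name)
                    self.slot[(g, name)] = fi
        self.n_free = len(self.free_names)
        self.df = int(len(self.groups) * self.p * (self.p + 1) // 2 - self.n_free)

    def _group_values(self, theta: np.ndarray, g: str) -> dict[str, float]:
        return {name: theta[self.slot[(g, name)]] for name in self.spec.param_names()}

    # -- objective -------------------------------------------------------

    def _F(self, theta: np.ndarray, want_grad: bool = True):
        spec = self.spec
        idx = {v: i for i, v in enumerate(spec.variables)}
        F = 0.0
        grad = np.zeros(self.n_free)
        for g, Sg, ng in zip(self.groups, self.S, self.n):
            vals = self._group_values(theta, g)
            B, Psi = _matrices_from_params(vals, spec)
            C = np.linalg.inv(np.eye(self.p) - B)
            Sigma = C @ Psi @ C.T
            Sigma = 0.5 * (Sigma + Sigma.T)
            w, v = np.linalg.eigh(Sigma)
            wt = ng / self.N
            floor = 1e-10 * max(abs(w).max(), 1.0)
            if w.min() < floor:
                # inadmissible region: flooring + C1 penalty toward feasibility
                bad = w < floor
                gap = (floor - w[bad]) / floor
                F += wt * float((gap**2).sum()) * 1e6
                if want_grad:
                    U = v[:, bad]
                    dPen = -1e6 * wt * (U * (2 * gap / floor)) @ U.T
                    grad += self._chain(dPen, B, Psi, C, Sigma, g)
                w = np.maximum(w, floor)
            Sinv = (v / w) @ v.T
            _, ldS = np.linalg.slogdet(Sg)
            F += wt * (
                float(np.log(w).sum()) + float(np.sum(Sinv * Sg)) - ldS - self.p
            )
            if want_grad:
                W = Sinv - Sinv @ Sg @ Sinv
                grad += wt * self._chain(W, B, Psi, C, Sigma, g)
        return (F, grad) if want_grad else (F, None)

    def _chain(self, W, B, Psi, C, Sigma, g) -> np.ndarray:
        """Gradient of tr(W dSigma) wrt the free parameters of group g."""
        spec = self.spec
        idx = {v: i for i, v in enumerate(spec.variables)}
        out = np.zeros(self.n_free)
        Ct_W_C = C.T @ W @ C
        SWC = Sigma @ W @ C
        for a, b in spec.directed_edges:
            i, j = idx[b], idx[a]  # B[to, from]
            out[self.slot[(g, f"{a}->{b}")]] += 2.0 * SWC[j, i]
        for vname in spec.variables:
            i = idx[vname]
            out[self.slot[(g, f"{vname}~~{vname}")]] += Ct_W_C[i, i]
        for a, b in spec.error_covariances:
            i, j = idx[a], idx[b]
            out[self.slot[(g, f"{a}~~{b}")]] += Ct_W_C[i, j] + Ct_W_C[j, i]
        return out

    # -- starting values --------------------------------------------------

    def _start(self) -> np.ndarray:
        theta = np.zeros(self.n_free)
        counts = np.zeros(self.n_free)
        spec = self.spec
        idx = {v: i for i, v in enumerate(spec.variables)}
        for g, Sg in zip(self.groups, self.S):
            # OLS per structural equation
            resid_var = {}
            coefs = {}
            for y in spec.variables:
                parents = [a for a, b in spec.directed_edges if b == y]
                iy = idx[y]
                if not parents:
                    resid_var[y] = Sg[iy, iy]
                    continue
                ip = [idx[a] for a in parents]
                bvec = np.linalg.solve(Sg[np.ix_(ip, ip)], Sg[ip, iy])
                for a, bv in zip(parents, bvec):
                    coefs[(a, y)] = bv
                resid_var[y] = max(Sg[iy, iy] - float(Sg[ip, iy] @ bvec), 1e-3 * Sg[iy, iy])
            for (a, y), bv in coefs.items():
                fi = self.slot[(g, f"{a}->{y}")]
                theta[fi] += bv
                counts[fi] += 1
            for vname, vv in resid_var.items():
                fi = self.slot[(g, f"{vname}~~{vname}")]
                theta[fi] += vv
                counts[fi] += 1
            for a, b in spec.error_covariances:
                # residual covariance of a and b given their parents (crude)
                fi = self.slot[(g, f"{a}~~{b}")]
                theta[fi] += 0.5 * Sg[idx[a], idx[b]]
                counts[fi] += 1
        counts[counts == 0] = 1.0
        return theta / counts

    # -- fitting ----------------------------------------------------------

    def fit(self, maxiter: int = 2000) -> "PathResults":
        theta0 = self._start()
        res = optimize.minimize(
            lambda th: self._F(th),
            theta0,
            jac=True,
            method="BFGS",
            options={"gtol": 1e-9, "maxiter": maxiter},
        )
        theta = res.x
        F_min, gfin = self._F(theta)
        converged = bool(res.success or np.max(np.abs(gfin)) < 1e-6)
        chi2 = max((self.N - len(self.groups)) * F_min, 0.0)
        se = self._standard_errors(theta)
        return PathResults(self, theta, float(F_min), float(chi2), se, converged)

    def _standard_errors(self, theta: np.ndarray) -> np.ndarray:
        # observed information = Hessian of (N-G)/2 * F, by central FD of the
        # analytic gradient
        scale = 0.5 * (self.N - len(self.groups))
        k = self.n_free
        H = np.zeros((k, k))
        eps = 1e-5 * np.maximum(np.abs(theta), 1.0)
        for i in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps[i]
            tm[i] -= eps[i]
            gp = self._F(tp)[1]
            gm = self._F(tm)[1]
            H[:, i] = scale * (gp - gm) / (2 * eps[i])
        H = 0.5 * (H + H.T)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d)


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------


@dataclass
class PathResults:
    model: PathModel
    theta: np.ndarray
    F_min: float
    chi2: float
    se: np.ndarray
    converged: bool

    # -- basic accessors -------------------------------------------------

    @property
    def spec(self) -> PathModelSpec:
        return self.model.spec

    @property
    def df(self) -> int:
        return self.model.df

    @property
    def p_value(self) -> float:
        if self.df <= 0:
            return 1.0
        return float(stats.chi2.sf(self.chi2, self.df))

    @property
    def estimates(self) -> dict[str, dict[str, float]]:
        return {
            g: self.model._group_values(self.theta, g) for g in self.model.groups
        }

    @property
    def standard_errors(self) -> dict[str, dict[str, float]]:
        out = {}
        for g in self.model.groups:
            out[g] = {
                name: float(self.se[self.model.slot[(g, name)]])
                for name in self.spec.param_names()
            }
        return out

    # -- derived quantities ----------------------------------------------

    def implied(self, group: str) -> CovMatrix:
        return implied_covariance(
            self.model._group_values(self.theta, group), self.spec
        )

    def _std_B(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        vals = self.model._group_values(self.theta, group)
        B, _ = _matrices_from_params(vals, self.spec)
        sd = np.sqrt(np.diag(self.implied(group).values))
        Bstd = B * np.outer(1.0 / sd, sd)
        return B, Bstd

    @property
    def standardized(self) -> dict[str, dict[str, float]]:
        """Standardised coefficients via model-implied SDs."""
        idx = {v: i for i, v in enumerate(self.spec.variables)}
        out: dict[str, dict[str, float]] = {}
        for g in self.model.groups:
            vals = self.model._group_values(self.theta, g)
            _, Bstd = self._std_B(g)
            sd = np.sqrt(np.diag(self.implied(g).values))
            d = {}
            for a, b in self.spec.directed_edges:
                d[f"{a}->{b}"] = float(Bstd[idx[b], idx[a]])
            for a, b in self.spec.error_covariances:
                d[f"{a}~~{b}"] = float(vals[f"{a}~~{b}"] / (sd[idx[a]] * sd[idx[b]]))
            out[g] = d
        return out

    @property
    def r_squared(self) -> dict[str, dict[str, float]]:
        idx = {v: i for i, v in enumerate(self.spec.variables)}
        out: dict[str, dict[str, float]] = {}
        for g in self.model.groups:
            vals = self.model._group_values(self.theta, g)
            var = np.diag(self.implied(g).values)
            out[g] = {
                y: float(1.0 - vals[f"{y}~~{y}"] / var[idx[y]])
                for y in self.spec.endogenous
            }
        return out

    def total_effects(self) -> dict[str, pd.DataFrame]:
        """Standardised total effects (direct + all indirect paths).

        Entry [to, from] of each group's matrix.
        """
        out = {}
        for g in self.model.groups:
            _, Bstd = self._std_B(g)
            T = np.linalg.inv(np.eye(self.model.p) - Bstd) - np.eye(self.model.p)
            out[g] = pd.DataFrame(
                T, index=self.spec.variables, columns=self.spec.variables
            )
        return out

    def critical_ratios(self) -> pd.DataFrame:
        """z statistics for cross-group differences in unconstrained parameters."""
        if len(self.model.groups) != 2:
            raise ValueError("critical ratios are defined for exactly two groups")
        g1, g2 = self.model.groups
        rows = []
        for name in self.spec.param_names():
            if name in self.spec.cross_group_equal:
                continue
            i1, i2 = self.model.slot[(g1, name)], self.model.slot[(g2, name)]
            b1, b2 = self.theta[i1], self.theta[i2]
            s1, s2 = self.se[i1], self.se[i2]
            z = (b1 - b2) / np.sqrt(s1**2 + s2**2)
            rows.append(
                {
                    "parameter": name,
                    g1: b1,
                    g2: b2,
                    "z": float(z),
                    "p": float(2.0 * stats.norm.sf(abs(z))),
                }
            )
        return pd.DataFrame(rows)

    def fit_indices(self) -> tuple[float, float | None]:
        return fit_indices(
            self.chi2, self.df, self.model.S, self.model.n, len(self.model.groups)
        )

    def summary(self) -> str:
        cfi, rmsea = self.fit_indices()
        lines = [
            "Multi-group path model (ML, covariance structure only)",
            f"  groups: {', '.join(self.model.groups)} "
            f"(n = {', '.join(str(int(n)) for n in self.model.n)})",
            f"  chi2 = {self.chi2:.4f}, df = {self.df}, p = {self.p_value:.4f}",
            f"  CFI = {cfi:.4f}, RMSEA = "
            + (f"{rmsea:.4f}" if rmsea is not None else "n/a (df = 0)"),
            f"  converged: {self.converged}",
        ]
        std = self.standardized
        r2 = self.r_squared
        for g in self.model.groups:
            lines.append(f"  [{g}] standardised coefficients:")
            for k, v in std[g].items():
                lines.append(f"    {k:24s} {v:+.3f}")
            lines.append(
                "    R^2: "
                + ", ".join(f"{y}={v:.3f}" for y, v in r2[g].items())
            )
        if len(self.model.groups) == 2:
            cr = self.critical_ratios()
            sig = cr[cr["p"] < 0.05]
            if len(sig):
                lines.append("  cross-group differences (p < 0.05):")
                for _, row in sig.iterrows():
                    lines.append(
                        f"    {row['parameter']:24s} z = {row['z']:+.3f}, p = {row['p']:.4g}"
                    )
        return "\n".join(lines)


# ----------------------------------------------------------------------
# module-level helpers
# ----------------------------------------------------------------------


def fit_multigroup(samples: list[GroupSample], spec: PathModelSpec) -> PathResults:
    """Fit the multi-group path model (thin functional wrapper)."""
    return PathModel(samples, spec).fit()


def total_effects(fit: PathResults) -> dict[str, pd.DataFrame]:
    return fit.total_effects()


def fit_indices(
    chi2: float,
    df: int,
    S: list[np.ndarray],
    n: np.ndarray,
    n_groups: int,
) -> tuple[float, float | None]:
    """(CFI, RMSEA) against the per-group independence baseline.

    CFI = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0);
    RMSEA = sqrt(G) * sqrt(max(chi2 - df, 0) / (df (N - G))), the
    multi-group convention with the sqrt(G) factor; None when df = 0.
    """
    N = float(np.sum(n))
    p = S[0].shape[0]
    Fb = 0.0
    for Sg, ng in zip(S, n):
        Fb += (ng / N) * (
            float(np.log(np.diag(Sg)).sum()) - float(np.linalg.slogdet(Sg)[1])
        )
    chi2_b = (N - n_groups) * Fb
    df_b = n_groups * p * (p - 1) // 2
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df <= 0:
        return cfi, None
    rmsea = float(np.sqrt(n_groups) * np.sqrt(num / (df * (N - n_groups))))
    return cfi, rmsea


def simulate_group(
    values: dict[str, float],
    spec: PathModelSpec,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw individual-level data from the structural equations.

    Exogenous variables and errors are Gaussian with the specified
    (co)variances; endogenous variables are generated equation by equation
    in topological order.  Used as an independent simulation oracle and for
    power/recovery studies.
    """
    rng = np.random.default_rng(rng)
    _, Psi = _matrices_from_params(values, spec)
    w = np.linalg.eigvalsh(Psi)
    if w.min() < -1e-10:
        raise ValueError("error covariance structure is not PSD")
    wE, vE = np.linalg.eigh(Psi)
    errors = rng.standard_normal((n, len(spec.variables))) @ (
        vE * np.sqrt(np.clip(wE, 0, None))
    ).T
    idx = {v: i for i, v in enumerate(spec.variables)}
    data = np.zeros((n, len(spec.variables)))
    remaining = list(spec.variables)
    done: set[str] = set()
    while remaining:
        progressed = False
        for v in list(remaining):
            parents = [a for a, b in spec.directed_edges if b == v]
            if all(a in done for a in parents):
                col = errors[:, idx[v]].copy()
                for a in parents:
                    col += values[f"{a}->{v}"] * data[:, idx[a]]
                data[:, idx[v]] = col
                done.add(v)
                remaining.remove(v)
                progressed = True
        if not progressed:  # pragma: no cover - spec guarantees acyclicity
            raise RuntimeError("cyclic dependency while simulating")
    return pd.DataFrame(data, columns=list(spec.variables))
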