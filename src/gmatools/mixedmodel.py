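"""Multivariate REML estimation of environment-specific G matrices.

The model treats the k traits measured on one plant as repeated measures:
stacking them gives a k-vector per plant whose mean is a trait-specific
fixed-effect combination (trait x environment, trait x population, trait x
population-x-environment, trait x block-within-environment) and whose
covariance decomposes into an among-family component G (broad-sense
genetic, families being inbred lines) and a within-plant residual R.  With
``grouping="by_env"`` separate unstructured G and R matrices are estimated
for each environment; family effects are independent across environments,
so the marginal covariance is block diagonal over family-x-environment
cells:

    V_cell = J_n (x) G_e  +  I_n (x) R_e ,      J_n = 1 1'.

REML maximises the restricted likelihood with fixed effects profiled out.
The implementation exploits the cell structure throughout: with
H_n = (R + n G)^-1 and M_n = (R^-1 - H_n)/n,

    V_cell^-1 = I (x) R^-1  -  J (x) M_n ,
    log|V_cell| = (n-1) log|R| + log|R + nG| ,

so the whole objective and its analytic gradient reduce to a handful of
k x k operations on per-(environment, cell-size) data aggregates that are
precomputed once.  Family matrices are parameterised unconstrained-symmetric
by default (boundary estimates -- zero variances with nonzero covariances --
are admissible, as unconstrained-structure REML produces them); residual
matrices use a log-Cholesky parameterisation and stay positive definite.
A strict-PSD mode for the family matrices is available.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covmatrix import CovMatrix

__all__ = [
    "MixedModelSpec",
    "MultiTraitMixedModel",
    "MixedModelResults",
    "LRTResult",
    "fit_multitrait_reml",
    "lrt",
    "scale_traits",
    "filter_families",
    "family_mean_covariance",
    "DEFAULT_TRAITS",
]

DEFAULT_TRAITS = ["nodules", "herbivory", "root", "shoot"]


# ----------------------------------------------------------------------
# data preparation
# ----------------------------------------------------------------------


def scale_traits(
    table: pd.DataFrame, trait_names: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Scale every trait to an experiment-wide mean of 1.

    Each trait column is divided by its grand mean pooled over *both*
    environments (not per-environment means, so environment differences in
    scaled means are preserved).  Returns the scaled table and the scaling
    factors for back-transformation.
    """
    trait_names = trait_names or DEFAULT_TRAITS
    out = table.copy()
    factors: dict[str, float] = {}
    for t in trait_names:
        gm = float(out[t].mean())
        if gm == 0.0 or not np.isfinite(gm):
            raise ValueError(f"trait {t!r} has zero or non-finite grand mean; cannot scale")
        out[t] = out[t] / gm
        factors[t] = gm
    return out, factors


def filter_families(table: pd.DataFrame, min_per_env: int = 2) -> pd.DataFrame:
    """Keep families with at least ``min_per_env`` plants in every environment.

    Mirrors the usual convergence filter for family-structured field data
    (>= 2 survivors per treatment, i.e. >= 4 replicates overall), which also
    guarantees every retained family is represented in both environments.
    Retained/dropped counts are reported in ``attrs``.
    """
    envs = sorted(table["env"].unique())
    counts = table.groupby(["family", "env"]).size().unstack(fill_value=0)
    for e in envs:
        if e not in counts.columns:
            counts[e] = 0
    ok = counts.index[(counts[envs] >= min_per_env).all(axis=1)]
    out = table[table["family"].isin(ok)].reset_index(drop=True)
    if len(out) == 0:
        raise ValueError(
            f"no family has >= {min_per_env} plants in every environment; nothing retained"
        )
    out.attrs["families_retained"] = len(ok)
    out.attrs["families_dropped"] = counts.shape[0] - len(ok)
    return out


def family_mean_covariance(
    table: pd.DataFrame, env: str, trait_names: list[str] | None = None
) -> CovMatrix:
    """Covariance of family mean trait vectors within one environment.

    A fast method-of-moments G estimate: upwardly biased for the diagonal by
    the residual attenuation term R/n (n = plants per family), with the bias
    shrinking as within-family replication grows.  Used as the default
    estimator inside randomisation loops and as CPC input.
    """
    trait_names = trait_names or DEFAULT_TRAITS
    sub = table[table["env"] == env]
    means = sub.groupby("family")[trait_names].mean()
    if means.shape[0] < 3:
        raise ValueError(
            f"need >= 3 families with data in {env!r}, found {means.shape[0]}"
        )
    vals = np.cov(means.to_numpy(dtype=float), rowvar=False, ddof=1)
    return CovMatrix(list(trait_names), np.atleast_2d(vals), n_effective=means.shape[0])


# ----------------------------------------------------------------------
# model specification
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class MixedModelSpec:
    """Random-structure specification of the multi-trait mixed model.

    grouping : ``"by_env"`` estimates one unstructured family matrix and one
        unstructured residual matrix per environment; ``"none"`` pools both
        across environments.
    constraint : optional trait pair whose *family* covariance is constrained
        equal across environments (only meaningful with ``grouping="by_env"``).
    family_structure : ``"unstructured"`` (default; symmetric, possibly
        non-PSD) or ``"psd"`` (log-Cholesky, strictly PD).
    """

    grouping: str = "by_env"
    constraint: tuple[str, str] | None = None
    family_structure: str = "unstructured"

    def __post_init__(self) -> None:
        if self.grouping not in ("none", "by_env"):
            raise ValueError(f"grouping must be 'none' or 'by_env', got {self.grouping!r}")
        if self.constraint is not None and self.grouping != "by_env":
            raise ValueError("a cross-environment covariance constraint requires grouping='by_env'")
        if self.family_structure not in ("unstructured", "psd"):
            raise ValueError("family_structure must be 'unstructured' or 'psd'")


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_chi2: float
    full_params: int
    reduced_params: int


# ----------------------------------------------------------------------
# internal helpers
# ----------------------------------------------------------------------


def _vech_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(k)


def _sym_from_vech(v: np.ndarray, k: int) -> np.ndarray:
    m = np.zeros((k, k))
    i, j = _vech_indices(k)
    m[i, j] = v
    m[j, i] = v
    return m


def _vech_grad(dM: np.ndarray, k: int) -> np.ndarray:
    """Gradient wrt vech parameters from a full symmetric matrix gradient."""
    i, j = _vech_indices(k)
    g = dM[i, j] + dM[j, i]
    g[i == j] = np.diag(dM)  # diagonal entries appear once, not twice
    return g


def _chol_from_params(v: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    i, j = _vech_indices(k)
    L[i, j] = v
    d = np.diag_indices(k)
    L[d] = np.exp(np.clip(np.diag(L), -30.0, 30.0))
    return L


def _chol_params_from_matrix(m: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(m)
    i, j = _vech_indices(m.shape[0])
    P = L.copy()
    d = np.diag_indices(m.shape[0])
    P[d] = np.log(np.diag(L))
    return P[i, j]


def _chol_grad(dR: np.ndarray, L: np.ndarray, k: int) -> np.ndarray:
    """Gradient wrt log-Cholesky parameters from symmetric dR (R = L L')."""
    G = 2.0 * dR @ L
    d = np.diag_indices(k)
    G[d] = G[d] * np.diag(L)
    i, j = _vech_indices(k)
    return G[i, j]


def _sequential_independent_columns(X: np.ndarray, tol: float = 1e-9) -> list[int]:
    """Indices of columns kept by a deterministic left-to-right rank filter."""
    keep: list[int] = []
    Q: list[np.ndarray] = []
    for c in range(X.shape[1]):
        v = X[:, c].astype(float)
        nrm0 = np.linalg.norm(v)
        if nrm0 == 0:
            continue
        for q in Q:
            v = v - (q @ v) * q
        # re-orthogonalise once for stability
        for q in Q:
            v = v - (q @ v) * q
        nrm = np.linalg.norm(v)
        if nrm > tol * max(nrm0, 1.0):
            Q.append(v / nrm)
            keep.append(c)
    return keep


# ----------------------------------------------------------------------
# the model
# ----------------------------------------------------------------------


class MultiTraitMixedModel:
    """REML model for k traits with family-level and residual covariance.

    Parameters
    ----------
    table : DataFrame
        Long trait table (one row per plant) with ``family``, ``population``,
        ``block``, ``env`` columns and one column per trait.  Should already
        be mean-scaled and family-filtered.
    spec : MixedModelSpec
    trait_names : list of str, optional
    fixed : {"full", "env_only"}
        "full" is the field-design mean structure (trait x [env + population
        + env:population + block(env)]); "env_only" keeps only trait x env
        means (useful for designs simulated without populations or blocks).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        spec: MixedModelSpec,
        trait_names: list[str] | None = None,
        fixed: str = "full",
    ) -> None:
        self.spec = spec
        self.trait_names = list(trait_names or DEFAULT_TRAITS)
        self.k = len(self.trait_names)
        self.envs = sorted(table["env"].unique())
        if fixed not in ("full", "env_only"):
            raise ValueError("fixed must be 'full' or 'env_only'")
        self.fixed = fixed
        self._table = table.reset_index(drop=True)
        self._build_design()
        self._build_aggregates()
        self._build_param_map()

    # -- design ---------------------------------------------------------

    def _plant_design(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        n = len(df)
        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["intercept"]
        env = df["env"].to_numpy()
        for e in self.envs[1:]:
            cols.append((env == e).astype(float))
            names.append(f"env[{e}]")
        if self.fixed == "full":
            pops = sorted(df["population"].unique())
            pop = df["population"].to_numpy()
            for p in pops[1:]:
                cols.append((pop == p).astype(float))
                names.append(f"pop[{p}]")
            for e in self.envs[1:]:
                for p in pops[1:]:
                    cols.append(((env == e) & (pop == p)).astype(float))
                    names.append(f"env[{e}]:pop[{p}]")
            block = df["block"].to_numpy()
            self._blocks_by_env = {}
            for e in self.envs:
                blocks = sorted(df.loc[df["env"] == e, "block"].unique())
                self._blocks_by_env[e] = blocks
                for b in blocks[1:]:
                    cols.append(((env == e) & (block == b)).astype(float))
                    names.append(f"block[{b}]")
        else:
            self._blocks_by_env = {e: [] for e in self.envs}
        D = np.column_stack(cols)
        keep = _sequential_independent_columns(D)
        if len(keep) < D.shape[1]:
            dropped = [names[c] for c in range(D.shape[1]) if c not in keep]
            warnings.warn(
                f"dropping {len(dropped)} aliased fixed-effect column(s): {dropped}",
                stacklevel=2,
            )
        return D[:, keep], [names[c] for c in keep]

    def _build_design(self) -> None:
        df = self._table
        D, names = self._plant_design(df)
        self.D = D
        self.design_names = names
        self.m = D.shape[1]
        self.p_fixed = self.k * self.m
        Y = df[self.trait_names].to_numpy(dtype=float)
        # internal per-trait standardisation: conditions the optimisation and
        # makes results exactly invariant to the input's measurement scale;
        # all reported quantities are transformed back
        sd = Y.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.trait_scale = sd
        self.Y = Y / sd
        self.n_plants = len(df)
        self.n_obs = self.k * self.n_plants
        # REML log-likelihood shift from the internal standardisation
        self._ll_shift = -(self.n_plants - self.m) * float(np.log(sd).sum())
        self.fixed_names = [
            f"trait[{t}]:{c}" for t in self.trait_names for c in names
        ]
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.Y).tobytes())
        h.update(np.ascontiguousarray(self.D).tobytes())
        self.data_hash = h.hexdigest()

    def _build_aggregates(self) -> None:
        """Per-environment and per-(environment, cell-size) data sums."""
        df = self._table
        self.agg_env: dict[str, dict] = {}
        self.agg_en: dict[tuple[str, int], dict] = {}
        self.n_families: dict[str, int] = {}
        for e in self.envs:
            idx = np.flatnonzero((df["env"] == e).to_numpy())
            Ye, De = self.Y[idx], self.D[idx]
            fams = df["family"].to_numpy()[idx]
            order = np.argsort(fams, kind="stable")
            Ye, De, fams = Ye[order], De[order], fams[order]
            uniq, starts = np.unique(fams, return_index=True)
            bounds = np.append(starts, len(fams))
            self.n_families[e] = len(uniq)
            self.agg_env[e] = {
                "Q": De.T @ De,
                "U": Ye.T @ De,
                "W": Ye.T @ Ye,
                "n_plants": len(idx),
                "n_cells": len(uniq),
            }
            by_n: dict[int, list] = {}
            for c in range(len(uniq)):
                sl = slice(bounds[c], bounds[c + 1])
                n = bounds[c + 1] - bounds[c]
                s = De[sl].sum(axis=0)
                t = Ye[sl].sum(axis=0)
                by_n.setdefault(int(n), []).append((s, t))
            for n, pairs in by_n.items():
                S = np.array([s for s, _ in pairs])   # (cells, m)
                T = np.array([t for _, t in pairs])   # (cells, k)
                self.agg_en[(e, n)] = {
                    "count": len(pairs),
                    "SS": S.T @ S,       # m x m
                    "TS": T.T @ S,       # k x m
                    "TT": T.T @ T,       # k x k
                    "S": S,
                    "T": T,
                }

    # -- parameterisation ------------------------------------------------

    def _build_param_map(self) -> None:
        k = self.k
        self.nv = k * (k + 1) // 2
        groups = self.envs if self.spec.grouping == "by_env" else ["__pooled__"]
        self.groups = groups
        nz = 2 * self.nv * len(groups)  # internal vector: per group [G block, R block]
        # map internal z index -> free parameter index
        z_to_free = np.arange(nz)
        if self.spec.constraint is not None:
            a = self.trait_names.index(self.spec.constraint[0])
            b = self.trait_names.index(self.spec.constraint[1])
            if a == b:
                raise ValueError("constraint must name two distinct traits")
            i, j = max(a, b), min(a, b)
            ii, jj = _vech_indices(k)
            pos = int(np.flatnonzero((ii == i) & (jj == j))[0])
            # tie the G element of every group after the first to the first's
            first = pos
            for g in range(1, len(groups)):
                z_to_free[2 * self.nv * g + pos] = first
        # renumber free indices consecutively
        uniq, inv = np.unique(z_to_free, return_inverse=True)
        self.z_to_free = inv
        self.n_cov_params = len(uniq)
        # mark log-diagonal Cholesky parameters (box-bounded during fitting)
        i, j = _vech_indices(k)
        diag_in_block = i == j
        logdiag_z = np.zeros(nz, dtype=bool)
        for g in range(len(groups)):
            if self.spec.family_structure == "psd":
                logdiag_z[2 * self.nv * g : 2 * self.nv * g + self.nv] = diag_in_block
            logdiag_z[2 * self.nv * g + self.nv : 2 * self.nv * (g + 1)] = diag_in_block
        self.logdiag_free = np.zeros(self.n_cov_params, dtype=bool)
        self.logdiag_free[inv[logdiag_z]] = True

    def _unpack(self, theta: np.ndarray) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
        z = theta[self.z_to_free]
        k, nv = self.k, self.nv
        G: dict[str, np.ndarray] = {}
        R: dict[str, np.ndarray] = {}
        Lr: dict[str, np.ndarray] = {}
        for gi, g in enumerate(self.groups):
            gv = z[2 * nv * gi : 2 * nv * gi + nv]
            rv = z[2 * nv * gi + nv : 2 * nv * (gi + 1)]
            if self.spec.family_structure == "psd":
                Lg = _chol_from_params(gv, k)
                Gg = Lg @ Lg.T
            else:
                Gg = _sym_from_vech(gv, k)
            L = _chol_from_params(rv, k)
            G[g], R[g], Lr[g] = Gg, L @ L.T, L
        if self.spec.grouping == "none":
            g = self.groups[0]
            G = {e: G[g] for e in self.envs}
            R = {e: R[g] for e in self.envs}
            Lr = {e: Lr[g] for e in self.envs}
        return G, R, Lr

    def _pack_grad(
        self, theta: np.ndarray, dG: dict[str, np.ndarray], dR: dict[str, np.ndarray]
    ) -> np.ndarray:
        z = theta[self.z_to_free]
        k, nv = self.k, self.nv
        gz = np.zeros_like(z)
        for gi, g in enumerate(self.groups):
            if self.spec.grouping == "none":
                dGg = sum(dG[e] for e in self.envs)
                dRg = sum(dR[e] for e in self.envs)
            else:
                dGg, dRg = dG[g], dR[g]
            gv = z[2 * nv * gi : 2 * nv * gi + nv]
            if self.spec.family_structure == "psd":
                Lg = _chol_from_params(gv, k)
                gz[2 * nv * gi : 2 * nv * gi + nv] = _chol_grad(dGg, Lg, k)
            else:
                gz[2 * nv * gi : 2 * nv * gi + nv] = _vech_grad(dGg, k)
            rv = z[2 * nv * gi + nv : 2 * nv * (gi + 1)]
            L = _chol_from_params(rv, k)
            gz[2 * nv * gi + nv : 2 * nv * (gi + 1)] = _chol_grad(dRg, L, k)
        grad = np.zeros_like(theta)
        np.add.at(grad, self.z_to_free, gz)
        return grad

    # -- objective -------------------------------------------------------

    def _neg2_restricted(self, theta: np.ndarray, want_grad: bool = True):
        """log|V| + log|X'V^-1 X| + y'Py and its gradient, or a penalty."""
        k, m = self.k, self.m
        G, R, _ = self._unpack(theta)
        pieces: dict = {}
        logdetV = 0.0
        penalty = 0.0
        pgrad_G = {e: np.zeros((k, k)) for e in self.envs}
        pgrad_R = {e: np.zeros((k, k)) for e in self.envs}
        for e in self.envs:
            _, ld = np.linalg.slogdet(R[e])
            Rinv = np.linalg.inv(R[e])
            ae = self.agg_env[e]
            logdetV += (ae["n_plants"] - ae["n_cells"]) * ld
            pieces[e] = {"Rinv": Rinv, "logdetR": ld}
            scale_e = max(np.trace(R[e]) / k, 1e-12)
            floor = 1e-8 * scale_e
            for (ee, n), agg in self.agg_en.items():
                if ee != e:
                    continue
                Sig = R[e] + n * G[e]
                w, v = np.linalg.eigh(Sig)
                # continuous eigenvalue floor: below `floor` the likelihood is
                # computed at the floor and a C^1 quadratic penalty (on the
                # typical-eigenvalue scale, so line searches can interpolate
                # across it) pushes back toward the feasible region
                bad = w < floor
                if bad.any():
                    gap = (floor - w[bad]) / scale_e
                    penalty += 1e4 * float((gap**2).sum())
                    U = v[:, bad]
                    pg = (U * (2e4 * gap / scale_e)) @ U.T
                    pgrad_G[e] += -n * pg
                    pgrad_R[e] += -pg
                wf = np.maximum(w, floor)
                H = (v / wf) @ v.T
                M = (Rinv - H) / n
                logdetV += agg["count"] * np.log(wf).sum()
                pieces[(e, n)] = {"H": H, "M": M}

        # assemble C = X'V^-1X, b = X'V^-1 y, yVy
        C = np.zeros((k * m, k * m))
        b = np.zeros(k * m)
        yVy = 0.0
        for e in self.envs:
            Rinv = pieces[e]["Rinv"]
            ae = self.agg_env[e]
            C += np.kron(Rinv, ae["Q"])
            b += (Rinv @ ae["U"]).ravel()
            yVy += float(np.sum(Rinv * ae["W"]))
        for (e, n), agg in self.agg_en.items():
            M = pieces[(e, n)]["M"]
            C += -np.kron(M, agg["SS"])
            b += -(M @ agg["TS"]).ravel()
            yVy += -float(np.sum(M * agg["TT"]))
        C = 0.5 * (C + C.T)
        try:
            cF = np.linalg.cholesky(C)
            logdetC = 2.0 * np.log(np.diag(cF)).sum()
            beta = np.linalg.solve(C, b)
        except np.linalg.LinAlgError:
            # C can lose numerical definiteness during extreme excursions;
            # continue with floored eigenvalues there
            wC, vC = np.linalg.eigh(C)
            fC = 1e-12 * max(float(wC.max()), 1.0)
            wC = np.maximum(wC, fC)
            logdetC = float(np.log(wC).sum())
            beta = (vC / wC) @ (vC.T @ b)
        # y'Py >= 0 in exact arithmetic; the clamp only removes numerical junk
        yPy = max(yVy - float(b @ beta), 0.0)
        f = logdetV + logdetC + yPy + penalty
        self._last_beta = beta
        self._last_penalty = penalty
        if not want_grad:
            return f, None

        Bmat = beta.reshape(k, m)
        Cinv = np.linalg.inv(C).reshape(k, m, k, m)
        dG = {e: np.zeros((k, k)) for e in self.envs}
        dR = {e: np.zeros((k, k)) for e in self.envs}
        for e in self.envs:
            Rinv = pieces[e]["Rinv"]
            ae = self.agg_env[e]
            # residual aggregates: E1 = sum_j e_j e_j'
            E1 = (
                ae["W"]
                - ae["U"] @ Bmat.T
                - Bmat @ ae["U"].T
                + Bmat @ ae["Q"] @ Bmat.T
            )
            TQ = np.einsum("tuqv,uv->tq", Cinv, ae["Q"])
            B2 = Rinv @ TQ @ Rinv
            B3 = Rinv @ E1 @ Rinv
            B1 = np.zeros((k, k))
            for (ee, n), agg in self.agg_en.items():
                if ee != e:
                    continue
                H, M = pieces[(e, n)]["H"], pieces[(e, n)]["M"]
                cnt = agg["count"]
                K = np.einsum("tuqv,uv->tq", Cinv, agg["SS"])
                # E2 = sum_cells (t - B s)(t - B s)'
                E2 = (
                    agg["TT"]
                    - agg["TS"] @ Bmat.T
                    - Bmat @ agg["TS"].T
                    + Bmat @ agg["SS"] @ Bmat.T
                )
                # family-matrix gradient: tr(P dV) - r' dV r pieces
                A1 = cnt * n * H
                A2 = H @ K @ H
                A3 = H @ E2 @ H
                dG[e] += A1 - A2 - A3
                # residual-matrix gradient pieces depending on n
                B1 += cnt * n * (Rinv - M)
                B2 += -(M @ K @ Rinv + Rinv @ K @ M - n * M @ K @ M)
                B3 += -(Rinv @ E2 @ M + M @ E2 @ Rinv - n * M @ E2 @ M)
            dR[e] = B1 - B2 - B3 + pgrad_R[e]
            dG[e] = dG[e] + pgrad_G[e]
            dG[e] = 0.5 * (dG[e] + dG[e].T)
            dR[e] = 0.5 * (dR[e] + dR[e].T)
        return f, self._pack_grad(theta, dG, dR)

    # -- starting values ---------------------------------------------------

    def _start(self) -> np.ndarray:
        k = self.k
        df = self._table.copy()
        df[self.trait_names] = self.Y  # internal (standardised) scale
        start_G: dict[str, np.ndarray] = {}
        start_R: dict[str, np.ndarray] = {}
        for e in self.envs:
            sub = df[df["env"] == e]
            Ye = sub[self.trait_names].to_numpy(dtype=float)
            fams = sub["family"].to_numpy()
            means = sub.groupby("family")[self.trait_names].transform("mean").to_numpy()
            resid = Ye - means
            cells = len(np.unique(fams))
            dof = max(len(sub) - cells, k + 1)
            R0 = resid.T @ resid / dof
            R0 += 1e-8 * np.trace(R0) / k * np.eye(k)
            fam_means = sub.groupby("family")[self.trait_names].mean().to_numpy()
            Sm = np.cov(fam_means, rowvar=False, ddof=1) if len(fam_means) > 2 else R0.copy()
            Sm = np.atleast_2d(Sm)
            nbar = len(sub) / cells
            ns = [n for (ee, n) in self.agg_en if ee == e]
            for G0 in (Sm - R0 / nbar, Sm, 0.5 * np.diag(np.diag(Sm)), 0.01 * np.trace(R0) / k * np.eye(k)):
                if all(np.linalg.eigvalsh(R0 + n * G0).min() > 1e-10 for n in ns):
                    break
            start_G[e], start_R[e] = G0, R0
        if self.spec.grouping == "none":
            Gp = sum(start_G[e] for e in self.envs) / len(self.envs)
            Rp = sum(start_R[e] for e in self.envs) / len(self.envs)
            start_G = {"__pooled__": Gp}
            start_R = {"__pooled__": Rp}
        nv = self.nv
        z = np.zeros(2 * nv * len(self.groups))
        ii, jj = _vech_indices(k)
        for gi, g in enumerate(self.groups):
            if self.spec.family_structure == "psd":
                Gpos = start_G[g] + 1e-6 * np.eye(k) * max(np.trace(start_R[g]) / k, 1e-6)
                w, v = np.linalg.eigh(Gpos)
                Gpos = (v * np.clip(w, 1e-8 * np.trace(start_R[g]), None)) @ v.T
                z[2 * nv * gi : 2 * nv * gi + nv] = _chol_params_from_matrix(Gpos)
            else:
                z[2 * nv * gi : 2 * nv * gi + nv] = start_G[g][ii, jj]
            z[2 * nv * gi + nv : 2 * nv * (gi + 1)] = _chol_params_from_matrix(start_R[g])
        theta = np.zeros(self.n_cov_params)
        # scatter/average: assign z entries to free slots (ties get the first value)
        for zi, fi in enumerate(self.z_to_free):
            theta[fi] = z[zi]
        return theta

    # -- fitting -----------------------------------------------------------

    def fit(self, maxiter: int = 2000, gtol: float = 1e-7) -> "MixedModelResults":
        theta0 = self._start()

        def fun(th):
            f, g = self._neg2_restricted(th)
            return f, g

        bounds = [(-12.0, 12.0) if ld else (None, None) for ld in self.logdiag_free]
        res = optimize.minimize(
            fun,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": maxiter,
                "ftol": 1e-14,
                "gtol": gtol,
                "maxcor": 30,
                "maxls": 60,
            },
        )
        # BFGS polish: the bounded line search can stall near the floored
        # region; a dense quasi-Newton pass from the same point is robust on
        # this 20-40 parameter problem
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            polish = optimize.minimize(
                fun,
                res.x,
                jac=True,
                method="BFGS",
                options={"gtol": gtol, "maxiter": maxiter},
            )
        if polish.fun <= res.fun and np.all(
            np.abs(polish.x[self.logdiag_free]) <= 12.0
        ):
            res = polish
        # convergence = no further progress achievable (robust on flat,
        # weakly identified likelihoods where the gradient cannot vanish
        # to machine precision)
        converged = False
        for _ in range(3):
            f_cur = float(res.fun)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                extra = optimize.minimize(
                    fun, res.x, jac=True, method="BFGS",
                    options={"gtol": gtol, "maxiter": 50},
                )
            ok_bounds = np.all(np.abs(extra.x[self.logdiag_free]) <= 12.0)
            if ok_bounds and extra.fun <= f_cur:
                res = extra
            if not (ok_bounds and extra.fun < f_cur - 1e-7 * max(1.0, abs(f_cur))):
                converged = True
                break
        theta = res.x
        f, g = self._neg2_restricted(theta)
        if not converged:
            warnings.warn(
                f"REML optimisation did not converge: {res.message}", stacklevel=2
            )
        G, R, _ = self._unpack(theta)
        reml_ll = (
            -0.5 * (f + (self.n_obs - self.p_fixed) * np.log(2.0 * np.pi))
            + self._ll_shift
        )
        s = self.trait_scale
        back = np.outer(s, s)
        Bmat = self._last_beta.reshape(self.k, self.m) * s[:, None]
        fixed = pd.Series(Bmat.ravel(), index=self.fixed_names)
        G_by_env = {
            e: CovMatrix(self.trait_names, G[e] * back, n_effective=self.n_families[e])
            for e in self.envs
        }
        R_by_env = {
            e: CovMatrix(
                self.trait_names, R[e] * back, n_effective=self.agg_env[e]["n_plants"]
            )
            for e in self.envs
        }
        return MixedModelResults(
            model=self,
            spec=self.spec,
            theta=theta,
            reml_loglik=float(reml_ll),
            n_cov_params=self.n_cov_params,
            fixed_effects=fixed,
            G_by_env=G_by_env,
            R_by_env=R_by_env,
            converged=converged,
            n_obs=self.n_obs,
        )

    # -- least-squares means ----------------------------------------------

    def lsmeans_rows(self) -> pd.DataFrame:
        """Design rows for population x environment least-squares means.

        Averages over block effects with equal weight per block within the
        focal environment (the reference block contributes zero).
        """
        if self.fixed != "full":
            raise ValueError("lsmeans require the full fixed-effect design")
        df = self._table
        pops = sorted(df["population"].unique())
        rows = []
        meta = []
        for e in self.envs:
            blocks = self._blocks_by_env[e]
            for p in pops:
                d = np.zeros(len(self.design_names))
                for ci, name in enumerate(self.design_names):
                    if name == "intercept":
                        d[ci] = 1.0
                    elif name == f"env[{e}]":
                        d[ci] = 1.0
                    elif name == f"pop[{p}]":
                        d[ci] = 1.0
                    elif name == f"env[{e}]:pop[{p}]":
                        d[ci] = 1.0
                    elif name.startswith("block[") and blocks:
                        bname = name[len("block[") : -1]
                        if bname in blocks:
                            d[ci] = 1.0 / len(blocks)
                rows.append(d)
                meta.append((p, e))
        out = pd.DataFrame(meta, columns=["population", "env"])
        out.attrs["design_rows"] = np.array(rows)
        return out


@dataclass
class MixedModelResults:
    """REML solution: covariance estimates, log-likelihood, fixed effects."""

    model: MultiTraitMixedModel
    spec: MixedModelSpec
    theta: np.ndarray
    reml_loglik: float
    n_cov_params: int
    fixed_effects: pd.Series
    G_by_env: dict[str, CovMatrix]
    R_by_env: dict[str, CovMatrix]
    converged: bool
    n_obs: int

    def population_lsmeans(self) -> pd.DataFrame:
        """Per population x environment least-squares trait means."""
        meta = self.model.lsmeans_rows()
        rows = meta.attrs["design_rows"]
        Bmat = self.fixed_effects.to_numpy().reshape(self.model.k, self.model.m)
        vals = rows @ Bmat.T
        out = meta.copy()
        for j, t in enumerate(self.model.trait_names):
            out[t] = vals[:, j]
        return out

    def summary(self) -> str:
        lines = [
            "Multivariate REML mixed model",
            f"  traits: {', '.join(self.model.trait_names)}",
            f"  grouping: {self.spec.grouping}"
            + (f", constraint: {self.spec.constraint}" if self.spec.constraint else ""),
            f"  n_obs: {self.n_obs} ({self.model.n_plants} plants x {self.model.k} traits)",
            f"  REML log-likelihood: {self.reml_loglik:.4f}",
            f"  covariance parameters: {self.n_cov_params}",
            f"  converged: {self.converged}",
        ]
        for e, M in self.G_by_env.items():
            lines.append(f"  G[{e}] (n_families={M.n_effective}, psd={M.psd}):")
            lines.append(M.to_dataframe().round(5).to_string())
        for e, M in self.R_by_env.items():
            lines.append(f"  R[{e}] (n_plants={M.n_effective}):")
            lines.append(M.to_dataframe().round(5).to_string())
        return "\n".join(lines)


def fit_multitrait_reml(
    table: pd.DataFrame,
    spec: MixedModelSpec,
    trait_names: list[str] | None = None,
    fixed: str = "full",
) -> MixedModelResults:
    """Fit the multi-trait REML mixed model (thin functional wrapper)."""
    return MultiTraitMixedModel(table, spec, trait_names=trait_names, fixed=fixed).fit()


def lrt(full: MixedModelResults, reduced: MixedModelResults, tol: float = 1e-6) -> LRTResult:
    """Likelihood-ratio test between two nested REML covariance structures.

    Both fits must use identical data and identical fixed effects (REML
    log-likelihoods are incomparable otherwise).  The statistic is referred
    to a plain chi-square with df equal to the parameter-count difference
    (no boundary mixture correction).
    """
    if full.model.data_hash != reduced.model.data_hash:
        raise ValueError("models were fitted to different data; LRT invalid")
    if full.model.fixed_names != reduced.model.fixed_names:
        raise ValueError("models have different fixed effects; REML LRT invalid")
    df = full.n_cov_params - reduced.n_cov_params
    if df <= 0:
        raise ValueError(
            f"reduced model must have fewer covariance parameters (df={df})"
        )
    stat = 2.0 * (full.reml_loglik - reduced.reml_loglik)
    if stat < -tol * max(1.0, abs(full.reml_loglik)):
        warnings.warn(
            f"negative LRT statistic ({stat:.4g}); the full model may not have converged",
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    return LRTResult(
        statistic=float(stat),
        df=int(df),
        p_chi2=float(stats.chi2.sf(stat, df)),
        full_params=full.n_cov_params,
        reduced_params=reduced.n_cov_params,
    )
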