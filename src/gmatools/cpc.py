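"""Flury common-principal-components (CPC) hierarchy for two groups.

The Flury hierarchy orders hypotheses about a pair of covariance matrices
from most to least constrained: equality, proportionality, full CPC
(shared eigenvectors, free eigenvalues), partial CPC(q) (q shared
components), and unrelated structure.  Each level is fitted by maximum
likelihood treating the two sample matrices as Wishart estimates with
their effective degrees of freedom; the full-CPC basis comes from the
Flury-Gautschi (FG) pairwise-rotation algorithm, which minimises

    Phi(B) = sum_g  n_g * log det diag(B' S_g B)

over orthogonal B, a quantity that never increases across FG sweeps.

Following the "jump-up" testing style, every level is compared directly
against the unrelated-structure null.  The chi-square reference df are
reported for bookkeeping, but inference uses a family-level randomisation:
under the null that both environments share one covariance structure, a
family's sun and shade data are exchangeable, so each randomisation
replicate swaps the environment labels of a random subset of families,
re-estimates both matrices and recomputes every LR statistic;
p = (1 + #{LR_rand >= LR_obs}) / (n_randomisations + 1).

Boundary (non-PD) inputs are "bent" by flooring eigenvalues at
1e-6 * trace/p before the log-det likelihoods are evaluated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .covmatrix import CovMatrix
from .mixedmodel import family_mean_covariance

__all__ = ["CPCResult", "fg_common_basis", "cpc_likelihood_ratios", "cpc_jump_up"]

LEVELS = ["equality", "proportionality", "full_CPC", "partial_CPC(2)", "partial_CPC(1)"]
#: the headline comparison levels (partial-CPC fits are much slower and are
#: computed for completeness outside randomisation loops)
HEADLINE_LEVELS = ["equality", "proportionality", "full_CPC"]


@dataclass
class CPCResult:
    level: str
    lr_statistic: float
    df_chi2: int
    p_randomization: float | None
    common_basis: np.ndarray | None
    n_randomizations: int


def _bend(S: np.ndarray, floor_frac: float = 1e-6) -> np.ndarray:
    """Floor eigenvalues at floor_frac * trace/p so log-det likelihoods exist."""
    p = S.shape[0]
    w, v = np.linalg.eigh(S)
    floor = floor_frac * max(np.trace(S), 1e-300) / p
    if w.min() >= floor:
        return S
    return (v * np.maximum(w, floor)) @ v.T


def _fix_signs(B: np.ndarray) -> np.ndarray:
    sign = np.sign(B[np.abs(B).argmax(axis=0), np.arange(B.shape[1])])
    sign[sign == 0] = 1.0
    return B * sign


def fg_common_basis(
    S1: CovMatrix | np.ndarray,
    S2: CovMatrix | np.ndarray,
    n: tuple[int, int] = (1, 1),
    tol: float = 1e-10,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Common eigenvector basis of two PD matrices by the FG algorithm.

    Returns the orthogonal matrix B minimising
    ``sum_g n_g log det diag(B' S_g B)``; converged when successive bases
    differ by less than ``tol`` in maximum column angle.  The objective is
    asserted non-increasing at every sweep.
    """
    mats = []
    for S in (S1, S2):
        m = S.values if isinstance(S, CovMatrix) else np.asarray(S, dtype=float)
        m = _bend(m)
        if np.linalg.eigvalsh(m).min() <= 0:
            raise ValueError("input matrix is not positive definite even after bending")
        mats.append(m)
    weights = np.asarray(n, dtype=float)
    p = mats[0].shape[0]

    # warm start at the pooled eigenvectors
    _, B = np.linalg.eigh(weights[0] * mats[0] + weights[1] * mats[1])

    def objective(Bc: np.ndarray) -> float:
        return float(
            sum(
                w * np.log(np.einsum("ij,jk,ki->i", Bc.T, S, Bc)).sum()
                for w, S in zip(weights, mats)
            )
        )

    prev_obj = objective(B)
    stable_sweeps = 0
    for _ in range(max_sweeps):
        B_old = B.copy()
        for i, j in itertools.combinations(range(p), 2):
            cols = B[:, [i, j]]
            T = [cols.T @ S @ cols for S in mats]
            Q = np.eye(2)
            for _inner in range(100):
                d = [np.einsum("ij,jk,ki->i", Q.T, t, Q) for t in T]
                Tstar = sum(
                    w * (dg[0] - dg[1]) / (dg[0] * dg[1]) * t
                    for w, dg, t in zip(weights, d, T)
                )
                Tstar = 0.5 * (Tstar + Tstar.T)
                _, vecs = np.linalg.eigh(Tstar)
                # take the eigenvector closest to the current first column
                q1 = vecs[:, int(np.argmax(np.abs(vecs.T @ Q[:, 0])))]
                if q1 @ Q[:, 0] < 0:
                    q1 = -q1
                Qnew = np.column_stack([q1, [-q1[1], q1[0]]])
                if np.abs(Qnew - Q).max() < 1e-14:
                    Q = Qnew
                    break
                Q = Qnew
            B[:, [i, j]] = cols @ Q
        obj = objective(B)
        assert obj <= prev_obj + 1e-8 * max(1.0, abs(prev_obj)), (
            f"FG objective increased: {prev_obj} -> {obj}"
        )
        # with (near-)degenerate eigenvalues the basis can keep rotating
        # inside a flat subspace, so a stabilised objective also counts as
        # convergence
        if abs(prev_obj - obj) < 1e-12 * max(1.0, abs(obj)):
            stable_sweeps += 1
        else:
            stable_sweeps = 0
        prev_obj = obj
        # max column angle between successive bases
        cosang = np.clip(np.abs(np.einsum("ij,ij->j", B, B_old)), 0.0, 1.0)
        if np.arccos(cosang).max() < tol or stable_sweeps >= 3:
            return _fix_signs(B)
    raise RuntimeError(
        f"FG iteration did not converge within {max_sweeps} sweeps "
        f"(last objective {prev_obj:.6g})"
    )


# ----------------------------------------------------------------------
# ML fits of the hierarchy levels
# ----------------------------------------------------------------------


def _discrepancy(S: list[np.ndarray], Shat: list[np.ndarray], n: np.ndarray) -> float:
    """X^2 = sum_g n_g [ log det(Shat_g) - log det(S_g) + tr(Shat_g^-1 S_g) - p ]."""
    p = S[0].shape[0]
    x2 = 0.0
    for Sg, Hg, ng in zip(S, Shat, n):
        x2 += ng * (
            float(np.linalg.slogdet(Hg)[1])
            - float(np.linalg.slogdet(Sg)[1])
            + float(np.trace(np.linalg.solve(Hg, Sg)))
            - p
        )
    return max(float(x2), 0.0)


def _fit_proportional(S: list[np.ndarray], n: np.ndarray, tol: float = 1e-12):
    """ML fit of S_g = rho_g * Sigma (rho_1 = 1), by alternating updates."""
    p = S[0].shape[0]
    rho = np.ones(len(S))
    Sigma = sum(ng * Sg for ng, Sg in zip(n, S)) / n.sum()
    for _ in range(500):
        Sigma_new = sum(ng / rg * Sg for ng, rg, Sg in zip(n, rho, S)) / n.sum()
        rho_new = np.array(
            [float(np.trace(np.linalg.solve(Sigma_new, Sg))) / p for Sg in S]
        )
        rho_new = rho_new / rho_new[0]
        if np.abs(rho_new - rho).max() < tol and np.abs(Sigma_new - Sigma).max() < tol:
            rho, Sigma = rho_new, Sigma_new
            break
        rho, Sigma = rho_new, Sigma_new
    return [rg * Sigma for rg in rho]


def _skew(x: np.ndarray, p: int) -> np.ndarray:
    A = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    A[iu] = x
    return A - A.T


def _fit_partial_cpc(S: list[np.ndarray], n: np.ndarray, q: int, B_full: np.ndarray):
    """ML fit with q common components, remaining components group-specific."""
    p = S[0].shape[0]
    nfree = p * (p - 1) // 2

    def neg_ll(x: np.ndarray, B0: np.ndarray) -> float:
        B = B0 @ linalg.expm(_skew(x, p))
        Bc, N = B[:, :q], B[:, q:]
        val = 0.0
        for Sg, ng in zip(S, n):
            lam = np.einsum("ij,jk,ki->i", Bc.T, Sg, Bc)
            W = N.T @ Sg @ N
            val += ng * (np.log(lam).sum() + float(np.linalg.slogdet(W)[1]))
        return float(val)

    best = None
    for subset in itertools.combinations(range(p), q):
        rest = [c for c in range(p) if c not in subset]
        B0 = B_full[:, list(subset) + rest]
        res = optimize.minimize(
            neg_ll, np.zeros(nfree), args=(B0,), method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, B0, res.x)
    _, B0, x = best
    B = B0 @ linalg.expm(_skew(x, p))
    Bc, N = B[:, :q], B[:, q:]
    Shat = []
    for Sg in S:
        lam = np.einsum("ij,jk,ki->i", Bc.T, Sg, Bc)
        W = N.T @ Sg @ N
        wl, wv = np.linalg.eigh(W)
        Bg = N @ wv
        Shat.append((Bc * lam) @ Bc.T + (Bg * wl) @ Bg.T)
    return Shat, _fix_signs(Bc)


def _level_df(level: str, p: int, k: int = 2) -> int:
    full = k * p * (p + 1) // 2
    if level == "equality":
        pars = p * (p + 1) // 2
    elif level == "proportionality":
        pars = p * (p + 1) // 2 + (k - 1)
    elif level == "full_CPC":
        pars = p * (p - 1) // 2 + k * p
    elif level.startswith("partial_CPC"):
        q = int(level[level.index("(") + 1 : -1])
        pars = (
            p * q - q * (q + 1) // 2
            + k * ((p - q) * (p - q - 1) // 2 + p)
        )
    else:
        raise ValueError(f"unknown level {level!r}")
    return full - pars


def cpc_likelihood_ratios(
    S1: CovMatrix, S2: CovMatrix, levels: list[str] | None = None
) -> dict[str, tuple[float, np.ndarray | None]]:
    """LR statistic of every hierarchy level against unrelated structure.

    Uses each matrix's ``n_effective`` minus one as its Wishart df.  Returns
    ``{level: (lr, common_basis or None)}`` ordered down the hierarchy.
    """
    S1.require_compatible(S2)
    p = S1.dim
    n = np.array([max(S1.n_effective - 1, 1), max(S2.n_effective - 1, 1)], dtype=float)
    S = [_bend(S1.values), _bend(S2.values)]
    levels = levels or LEVELS
    B = fg_common_basis(S[0], S[1], n=tuple(n))
    out: dict[str, tuple[float, np.ndarray | None]] = {}
    for level in levels:
        if level == "equality":
            pooled = sum(ng * Sg for ng, Sg in zip(n, S)) / n.sum()
            Shat, basis = [pooled, pooled], None
        elif level == "proportionality":
            Shat, basis = _fit_proportional(S, n), None
        elif level == "full_CPC":
            Shat = [(B * np.einsum("ij,jk,ki->i", B.T, Sg, B)) @ B.T for Sg in S]
            basis = B
        elif level.startswith("partial_CPC"):
            q = int(level[level.index("(") + 1 : -1])
            if not 1 <= q <= p - 2:
                raise ValueError(f"partial CPC order must be in [1, {p - 2}]")
            Shat, basis = _fit_partial_cpc(S, n, q, B)
        else:
            raise ValueError(f"unknown level {level!r}")
        out[level] = (_discrepancy(S, Shat, n), basis)
    return out


# ----------------------------------------------------------------------
# jump-up randomisation test
# ----------------------------------------------------------------------


def _swap_family_envs(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Randomly relabel environments within families (family-level null)."""
    envs = sorted(table["env"].unique())
    out = table.copy()
    fams = out["family"].unique()
    flip = set(fams[rng.random(len(fams)) < 0.5])
    mask = out["family"].isin(flip)
    swap = {envs[0]: envs[1], envs[1]: envs[0]}
    out.loc[mask, "env"] = out.loc[mask, "env"].map(swap)
    return out


def cpc_jump_up(
    S1: CovMatrix | None,
    S2: CovMatrix | None,
    table: pd.DataFrame,
    n_randomizations: int = 999,
    rng: np.random.Generator | int | None = None,
    estimator: Callable[[pd.DataFrame, str], CovMatrix] | None = None,
    trait_names: list[str] | None = None,
    levels: list[str] | None = None,
) -> list[CPCResult]:
    """Jump-up CPC tests with a family-reassignment randomisation null.

    ``S1``/``S2`` may be passed pre-estimated (they must then come from the
    same estimator) or left as None to be estimated from ``table``.  Whole
    families are the exchangeable unit: each replicate swaps the environment
    labels of a random subset of families before re-estimation.
    """
    rng = np.random.default_rng(rng)
    if estimator is None:
        estimator = lambda tab, env: family_mean_covariance(tab, env, trait_names)  # noqa: E731
    envs = sorted(table["env"].unique())
    if len(envs) != 2:
        raise ValueError(f"expected exactly 2 environments, found {envs}")
    for e in envs:
        if table.loc[table["env"] == e, "family"].nunique() < 4:
            raise ValueError("need >= 4 families per environment for CPC testing")
    if S1 is None or S2 is None:
        S1, S2 = estimator(table, envs[0]), estimator(table, envs[1])
    levels = levels or HEADLINE_LEVELS
    observed = cpc_likelihood_ratios(S1, S2, levels)

    exceed = {lv: 0 for lv in levels}
    n_done = 0
    n_failed = 0
    for _ in range(n_randomizations):
        shuffled = _swap_family_envs(table, rng)
        try:
            R1 = estimator(shuffled, envs[0])
            R2 = estimator(shuffled, envs[1])
            rand = cpc_likelihood_ratios(R1, R2, levels)
        except Exception:  # noqa: BLE001 - abort threshold checked below
            n_failed += 1
            continue
        n_done += 1
        for lv in levels:
            if rand[lv][0] >= observed[lv][0]:
                exceed[lv] += 1
    if n_randomizations > 0 and n_failed > 0.05 * n_randomizations:
        raise RuntimeError(
            f"{n_failed}/{n_randomizations} randomisation replicates failed to fit"
        )
    if n_randomizations > 0 and n_failed:
        warnings.warn(f"{n_failed} randomisation replicate(s) dropped", stacklevel=2)

    p = S1.dim
    results = []
    for lv in levels:
        lr, basis = observed[lv]
        p_rand = (1.0 + exceed[lv]) / (n_done + 1.0) if n_done else None
        results.append(
            CPCResult(
                level=lv,
                lr_statistic=lr,
                df_chi2=_level_df(lv, p),
                p_randomization=p_rand,
                common_basis=basis,
                n_randomizations=n_done,
            )
        )
    return results
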