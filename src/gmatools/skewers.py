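"""Random-skewers comparison of two covariance matrices.

The multivariate breeder's equation predicts the response to a selection
gradient beta as the response vector dz = G beta.  The random-skewers
method draws many random unit-length selection gradients ("skewers"),
applies them to both matrices, and summarises similarity as the average
vector correlation -- the cosine of the angle -- between the paired
response vectors.  Two proportional matrices score 1 regardless of scale;
matrices that channel selection in unrelated directions score near 0.

Significance against the null hypothesis of matrix *equality* is obtained
by randomisation: individuals are pooled across the two environments and
reassigned at random to the original environment-by-family cells (cell
sizes preserved), both matrices are re-estimated, and the skewers
statistic is recomputed.  Low observed similarity relative to this null
rejects equality; the test is one-tailed, with
p = (1 + #{null r <= observed r}) / (n_null + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .covmatrix import CovMatrix

__all__ = ["SkewersResult", "random_skewers_r", "skewers_equality_test"]


@dataclass
class SkewersResult:
    r_mean: float
    n_vectors: int
    p_value: float | None
    n_null: int
    n_failed: int = 0
    null_distribution: np.ndarray | None = None


def _unit_sphere(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n iid selection vectors uniform on the unit (k-1)-sphere."""
    b = rng.standard_normal((n, k))
    norms = np.linalg.norm(b, axis=1, keepdims=True)
    # a zero draw has probability zero; guard for pathological generators
    norms[norms == 0] = 1.0
    return b / norms


def _mean_response_cosine(V1: np.ndarray, V2: np.ndarray, B: np.ndarray) -> float:
    r1 = B @ V1.T
    r2 = B @ V2.T
    n1 = np.linalg.norm(r1, axis=1)
    n2 = np.linalg.norm(r2, axis=1)
    dot = np.einsum("ij,ij->i", r1, r2)
    ok = (n1 > 0) & (n2 > 0)
    cos = np.zeros(len(B))
    cos[ok] = dot[ok] / (n1[ok] * n2[ok])  # zero-length responses contribute 0
    return float(cos.mean())


def random_skewers_r(
    G1: CovMatrix,
    G2: CovMatrix,
    n_vectors: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean response-vector correlation over random unit-length skewers.

    Symmetric in its arguments and invariant to multiplying both matrices
    by a common positive scalar.  A skewer whose response vanishes under a
    singular matrix contributes correlation 0.
    """
    G1.require_compatible(G2)
    if n_vectors < 1:
        raise ValueError("n_vectors must be >= 1")
    rng = np.random.default_rng(rng)
    B = _unit_sphere(rng, n_vectors, G1.dim)
    return _mean_response_cosine(G1.values, G2.values, B)


def _null_reassign(
    table: pd.DataFrame, envs: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Pool individuals across environments, reshuffle into the original cells."""
    out = table.copy()
    perm = rng.permutation(len(out))
    # keep (env, family) cell labels fixed; permute which plant's trait rows
    # land in each cell slot
    cell_cols = ["env", "family"]
    cells = out[cell_cols].to_numpy()
    out = out.drop(columns=cell_cols).iloc[perm].reset_index(drop=True)
    out[cell_cols] = cells
    return out


class _FastFamilyMeanCovs:
    """Vectorised family-mean covariance pair under row permutations.

    Precomputes the fixed env-by-family cell layout once; each call
    evaluates both environments' family-mean covariance matrices for a
    permutation of the pooled trait rows (identity = observed data).
    """

    def __init__(self, table: pd.DataFrame, envs: list[str], traits: list[str]):
        self.X = table[traits].to_numpy(dtype=float)
        env_col = table["env"].to_numpy()
        fam_col = table["family"].to_numpy()
        self.slots = []
        for e in envs:
            idx = np.flatnonzero(env_col == e)
            codes, _ = pd.factorize(fam_col[idx])
            counts = np.bincount(codes).astype(float)
            if len(counts) < 3:
                raise ValueError(f"need >= 3 families with data in {e!r}")
            self.slots.append((idx, codes, counts))

    def __call__(self, perm: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
        V = self.X if perm is None else self.X[perm]
        out = []
        for idx, codes, counts in self.slots:
            k = self.X.shape[1]
            sums = np.zeros((len(counts), k))
            np.add.at(sums, codes, V[idx])
            means = sums / counts[:, None]
            out.append(np.cov(means, rowvar=False, ddof=1))
        return out[0], out[1]


def skewers_equality_test(
    table: pd.DataFrame,
    estimator: Callable[[pd.DataFrame, str], CovMatrix] | None = None,
    n_vectors: int = 1000,
    n_null: int = 999,
    rng: np.random.Generator | int | None = None,
    trait_names: list[str] | None = None,
    keep_null: bool = False,
) -> SkewersResult:
    """Randomisation test of covariance-matrix equality via random skewers.

    ``estimator`` maps (table, env) to a CovMatrix; the default is the
    family-mean covariance.  The same skewer set is used for the observed
    statistic and every null replicate, so replicate-to-replicate variation
    reflects only the reassignment.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1 to define a randomisation p-value")
    rng = np.random.default_rng(rng)
    envs = sorted(table["env"].unique())
    if len(envs) != 2:
        raise ValueError(f"expected exactly 2 environments, found {envs}")

    null = []
    n_failed = 0
    if estimator is None:
        # fast vectorised path for the default family-mean estimator
        from .mixedmodel import DEFAULT_TRAITS

        traits = list(trait_names or DEFAULT_TRAITS)
        fast = _FastFamilyMeanCovs(table, envs, traits)
        V1, V2 = fast(None)
        B = _unit_sphere(rng, n_vectors, V1.shape[0])
        observed = _mean_response_cosine(V1, V2, B)
        for _ in range(n_null):
            N1, N2 = fast(rng.permutation(len(table)))
            null.append(_mean_response_cosine(N1, N2, B))
    else:
        M1, M2 = estimator(table, envs[0]), estimator(table, envs[1])
        B = _unit_sphere(rng, n_vectors, M1.dim)
        observed = _mean_response_cosine(M1.values, M2.values, B)
        for _ in range(n_null):
            shuffled = _null_reassign(table, envs, rng)
            try:
                N1 = estimator(shuffled, envs[0])
                N2 = estimator(shuffled, envs[1])
            except Exception as err:  # noqa: BLE001 - estimator is user-pluggable
                n_failed += 1
                warnings.warn(f"null replicate dropped: {err}", stacklevel=2)
                continue
            null.append(_mean_response_cosine(N1.values, N2.values, B))
    null_arr = np.asarray(null)
    n_eff = len(null_arr)
    p = (1.0 + float((null_arr <= observed).sum())) / (n_eff + 1.0) if n_eff else None
    return SkewersResult(
        r_mean=observed,
        n_vectors=n_vectors,
        p_value=p,
        n_null=n_eff,
        n_failed=n_failed,
        null_distribution=null_arr if keep_null else None,
    )
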