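"""Phenome preparation and kinship-aware multi-trait imputation.

A phenome is an N x p matrix Y of accessions by traits with block-wise
missingness.  Preparation follows three steps: drop traits with excessive
missingness, drop one member of each highly correlated trait pair, and
center/scale each trait.  Missing values are then imputed under a
multiple-phenotype mixed model (MPMM)

    Y = U + eps,   U ~ MN(0, K, B),   eps ~ MN(0, I_N, E)

where K is the accession kinship matrix, B the genetic trait covariance
and E the residual trait covariance.  The genetic term is given a
low-rank parameterization U = S beta with

    S ~ MN(0, K, I_r),   beta ~ MN(0, I_r, tau^-1 I_p)

and the residual precision a conjugate Wishart prior

    E^-1 ~ Wishart(p + 5, (1/4) I_p).

The model is fitted with a deterministic block coordinate-ascent scheme on
the joint log posterior: each sweep solves exactly for S (a Sylvester
system in the kinship eigenbasis), beta (a second Sylvester system), E
(the conjugate Wishart mode) and the missing entries (within-row Gaussian
conditional means given the observed entries), so the tracked objective is
monotone non-decreasing by construction.  Missing entries are replaced by
their posterior-mean prediction; observed entries are never altered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitMatrix",
    "MPMMSpec",
    "MPMMFit",
    "FilterReport",
    "filter_traits",
    "drop_correlated",
    "standardize",
    "mpmm_impute",
]


class PhenomeError(ValueError):
    """Raised on invalid phenome inputs."""


@dataclass
class TraitMatrix:
    """Accessions x traits with an observation mask.

    ``values`` carries NaN at unobserved entries; ``mask`` is True where
    observed.  ``standardization`` maps trait name -> (mean, sd) once
    :func:`standardize` has run, enabling back-transformation.
    """

    values: np.ndarray
    mask: np.ndarray
    accession_ids: list[str]
    trait_names: list[str]
    standardization: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise PhenomeError("mask shape must equal values shape")
        if self.values.shape != (len(self.accession_ids), len(self.trait_names)):
            raise PhenomeError("identifier lengths must match matrix shape")
        # unobserved entries carry NaN so they can never silently leak into math
        self.values = np.where(self.mask, self.values, np.nan)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TraitMatrix":
        vals = df.to_numpy(dtype=float)
        return cls(
            values=vals,
            mask=~np.isnan(vals),
            accession_ids=[str(i) for i in df.index],
            trait_names=[str(c) for c in df.columns],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.accession_ids, columns=self.trait_names
        )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> float:
        return float((~self.mask).mean())

    def subset_traits(self, keep: list[int]) -> "TraitMatrix":
        std = None
        if self.standardization is not None:
            std = {self.trait_names[j]: self.standardization[self.trait_names[j]] for j in keep}
        return TraitMatrix(
            values=self.values[:, keep],
            mask=self.mask[:, keep],
            accession_ids=list(self.accession_ids),
            trait_names=[self.trait_names[j] for j in keep],
            standardization=std,
        )


@dataclass
class FilterReport:
    dropped: list[str]
    reason: dict[str, str]
    residual_missing_fraction: float


def _as_trait_matrix(Y) -> TraitMatrix:
    if isinstance(Y, TraitMatrix):
        return Y
    if isinstance(Y, pd.DataFrame):
        return TraitMatrix.from_dataframe(Y)
    raise PhenomeError(f"expected TraitMatrix or DataFrame, got {type(Y)!r}")


def filter_traits(Y_raw, max_missing_frac: float = 0.30) -> tuple[TraitMatrix, FilterReport]:
    """Drop traits whose missing fraction strictly exceeds ``max_missing_frac``."""
    tm = _as_trait_matrix(Y_raw)
    if tm.n < 1 or tm.p < 1:
        raise PhenomeError("phenome must have at least one accession and one trait")
    miss = (~tm.mask).mean(axis=0)
    keep = [j for j in range(tm.p) if miss[j] <= max_missing_frac]
    dropped = [tm.trait_names[j] for j in range(tm.p) if miss[j] > max_missing_frac]
    if not keep:
        raise PhenomeError(
            f"no traits survive filter at max_missing_frac={max_missing_frac}"
        )
    out = tm.subset_traits(keep)
    report = FilterReport(
        dropped=dropped,
        reason={
            name: f"missing fraction {miss[tm.trait_names.index(name)]:.3f} > {max_missing_frac}"
            for name in dropped
        },
        residual_missing_fraction=out.missing_fraction(),
    )
    return out, report


def drop_correlated(
    Y, r_threshold: float = 0.95, min_overlap: int = 3
) -> tuple[TraitMatrix, list[tuple[str, str, float]]]:
    """Greedy removal of traits highly correlated with an earlier-kept trait.

    Pairwise Pearson r is computed on pairwise-complete observations; pairs
    with fewer than ``min_overlap`` shared observations get r = 0 and a
    warning.  Scanning in column order, a later trait is dropped when its
    |r| with any already-retained trait exceeds ``r_threshold``.

    Returns the reduced matrix and a report of (dropped, kept, r) triples.
    """
    tm = _as_trait_matrix(Y)
    df = tm.to_dataframe()
    corr = df.corr(min_periods=min_overlap)
    # overlap counts to distinguish "no data" NaN from genuine NaN correlations
    obs = tm.mask.astype(float)
    overlap = obs.T @ obs
    if np.any((overlap < min_overlap) & ~np.eye(tm.p, dtype=bool)):
        warnings.warn(
            "some trait pairs share fewer than "
            f"{min_overlap} observations; their correlation is treated as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    r = corr.to_numpy()
    r = np.where(np.isfinite(r), r, 0.0)

    kept: list[int] = []
    report: list[tuple[str, str, float]] = []
    for j in range(tm.p):
        clash = None
        for k in kept:
            if abs(r[j, k]) > r_threshold:
                clash = k
                break
        if clash is None:
            kept.append(j)
        else:
            report.append((tm.trait_names[j], tm.trait_names[clash], float(r[j, clash])))
    return tm.subset_traits(kept), report


def standardize(Y) -> TraitMatrix:
    """Center and scale each trait to observed mean 0, sd 1 (n-1 denominator)."""
    tm = _as_trait_matrix(Y)
    out = tm.values.copy()
    record: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(tm.trait_names):
        col = tm.values[:, j]
        obs = col[tm.mask[:, j]]
        if obs.size < 2 or np.unique(obs).size < 2:
            raise PhenomeError(
                f"trait {name!r} is constant or has <2 observed values; cannot standardize"
            )
        mu = float(obs.mean())
        sd = float(obs.std(ddof=1))
        out[:, j] = (col - mu) / sd
        record[name] = (mu, sd)
    return TraitMatrix(
        values=out,
        mask=tm.mask.copy(),
        accession_ids=list(tm.accession_ids),
        trait_names=list(tm.trait_names),
        standardization=record,
    )


@dataclass
class MPMMSpec:
    """MPMM hyperparameters and fitting controls.

    rank : latent columns of S; None means min(N, ceil(p/2)).  Full rank is
        allowed but leaves the residual covariance poorly identified.
    tau : precision of the beta prior (regularization strength), default 1.
    wishart_df / wishart_scale : residual-precision prior; defaults p+5 and
        (1/4) I_p, set at fit time when None.
    """

    rank: int | None = None
    tau: float = 1.0
    wishart_df: float | None = None
    wishart_scale: np.ndarray | None = None
    max_iter: int = 1000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise PhenomeError("tau must be positive")
        if self.tol <= 0 or self.max_iter < 1:
            raise PhenomeError("tol must be > 0 and max_iter >= 1")


@dataclass
class MPMMFit:
    S_mean: np.ndarray
    beta_mean: np.ndarray
    E_mean: np.ndarray
    B_implied: np.ndarray
    imputed: np.ndarray
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0


def _check_kinship(K: np.ndarray, n: int, tol: float = 1e-8):
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise PhenomeError(f"kinship shape {K.shape} does not match N={n}")
    if not np.allclose(K, K.T, atol=1e-10):
        raise PhenomeError("kinship matrix is not symmetric")
    evals, evecs = np.linalg.eigh(K)
    if evals.min() < -tol * max(1.0, evals.max()):
        raise PhenomeError(
            f"kinship is not PSD: most negative eigenvalue {evals.min():.3e}"
        )
    return np.clip(evals, 0.0, None), evecs


def mpmm_impute(Y, K, spec: MPMMSpec | None = None) -> MPMMFit:
    """Fit the low-rank kinship MPMM and impute missing entries.

    ``K`` may be a KinshipMatrix or a raw N x N array aligned to Y's
    accession order.  Returns an :class:`MPMMFit` whose ``imputed`` matrix
    equals the input at every observed entry.
    """
    tm = _as_trait_matrix(Y)
    spec = spec or MPMMSpec()
    Kv = getattr(K, "values", K)
    evals, Q = _check_kinship(np.asarray(Kv, dtype=float), tm.n)

    N, p = tm.n, tm.p
    # default latent rank: half the trait count.  With rank == p the MAP
    # residuals pin E to the prior floor and masked-entry predictions become
    # unidentified; truncation keeps the residual covariance estimable.
    r = spec.rank or max(1, min(N, (p + 1) // 2))
    if not 1 <= r <= min(N, p):
        raise PhenomeError(f"rank must be in [1, min(N,p)]={min(N,p)}, got {r}")
    nu0 = spec.wishart_df if spec.wishart_df is not None else p + 5
    if nu0 <= p - 1:
        raise PhenomeError(f"Wishart df {nu0} must exceed p-1={p-1}")
    V0 = spec.wishart_scale if spec.wishart_scale is not None else 0.25 * np.eye(p)
    V0inv = np.linalg.inv(V0)

    mask = tm.mask
    Y0 = np.where(mask, tm.values, 0.0)
    fully_observed = bool(mask.all())

    # pseudo-inverse eigenvalues of K; zero modes of K force S rows to zero
    eps = 1e-10 * max(1.0, evals.max())
    inv_l = np.where(evals > eps, 1.0 / np.clip(evals, eps, None), np.inf)

    # deterministic start: truncated SVD of the zero-filled matrix
    U0, s0, Vt0 = np.linalg.svd(Y0, full_matrices=False)
    S = U0[:, :r] * s0[:r]
    # fix signs for reproducibility
    for a in range(S.shape[1]):
        k = np.argmax(np.abs(S[:, a]))
        if S[k, a] < 0:
            S[:, a] = -S[:, a]
    beta = np.zeros((r, p))
    E = np.eye(p)
    Ycur = Y0.copy()

    # group rows by missingness pattern for the E-step
    patterns: dict[bytes, list[int]] = {}
    for i in range(N):
        patterns.setdefault(mask[i].tobytes(), []).append(i)

    def penalties(S, beta, E):
        # quadratic S penalty in the kinship eigenbasis (zero modes excluded)
        St = Q.T @ S
        fin = np.isfinite(inv_l)
        s_pen = float(np.sum((St[fin] ** 2) * inv_l[fin, None]))
        sign, logdetE = np.linalg.slogdet(E)
        e_prior = -0.5 * (nu0 - p - 1) * logdetE - 0.5 * float(
            np.trace(np.linalg.solve(E, V0inv))
        )
        return -0.5 * s_pen - 0.5 * spec.tau * float(np.sum(beta**2)) + e_prior

    def observed_loglik(S, beta, E):
        """Observed-data log-likelihood: rows are N((S beta)_obs, E_oo)."""
        M = S @ beta
        total = 0.0
        for key, rows in patterns.items():
            obs = np.frombuffer(key, dtype=bool)
            if not obs.any():
                continue
            rows_a = np.array(rows)
            Eoo = E[np.ix_(obs, obs)]
            sign, logdet = np.linalg.slogdet(Eoo)
            Rm = Y0[np.ix_(rows_a, np.where(obs)[0])] - M[rows_a][:, obs]
            quad = float(np.sum(Rm * np.linalg.solve(Eoo, Rm.T).T))
            total += -0.5 * (len(rows) * logdet + quad)
        return total

    def e_step(S, beta, E):
        """Conditional means of the missing entries and their covariance mass."""
        Ynew = Y0.copy()
        Cmass = np.zeros((p, p))
        M = S @ beta
        for key, rows in patterns.items():
            obs = np.frombuffer(key, dtype=bool)
            mis = ~obs
            if not mis.any():
                continue
            rows_a = np.array(rows)
            mis_idx = np.where(mis)[0]
            if not obs.any():
                Ynew[np.ix_(rows_a, mis_idx)] = M[rows_a][:, mis]
                Cmass[np.ix_(mis_idx, mis_idx)] += len(rows) * E[np.ix_(mis, mis)]
                continue
            Eoo = E[np.ix_(obs, obs)]
            Emo = E[np.ix_(mis, obs)]
            solve_oo = np.linalg.solve(Eoo, Emo.T)  # |obs| x |mis|
            resid_obs = Y0[np.ix_(rows_a, np.where(obs)[0])] - M[rows_a][:, obs]
            Ynew[np.ix_(rows_a, mis_idx)] = M[rows_a][:, mis] + resid_obs @ solve_oo
            schur = E[np.ix_(mis, mis)] - Emo @ solve_oo
            Cmass[np.ix_(mis_idx, mis_idx)] += len(rows) * schur
        return Ynew, Cmass

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, spec.max_iter + 1):
        # --- E-step: fill missing entries with conditional means, keep the
        #     conditional covariance mass for the scatter update
        if fully_observed:
            Cmass = np.zeros((p, p))
        else:
            Ycur, Cmass = e_step(S, beta, E)

        Einv = np.linalg.inv(E)
        Einv = 0.5 * (Einv + Einv.T)

        # --- M-step for beta: Sylvester system G beta + tau beta E = S' Y
        G = S.T @ S
        gam2, P2 = np.linalg.eigh(0.5 * (G + G.T))
        om, W = np.linalg.eigh(E)
        rhs = P2.T @ (S.T @ Ycur) @ W
        beta = P2 @ (rhs / (gam2[:, None] + spec.tau * om[None, :])) @ W.T

        # --- M-step for S: solve S A + K^+ S = Y E^-1 beta' in the K eigenbasis
        A = beta @ Einv @ beta.T
        A = 0.5 * (A + A.T)
        gam, P = np.linalg.eigh(A)
        C = Q.T @ (Ycur @ Einv @ beta.T) @ P
        denom = gam[None, :] + inv_l[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            Shat = np.where(np.isfinite(denom) & (denom > 0), C / denom, 0.0)
        S = Q @ Shat @ P.T

        # --- M-step for E: Wishart-regularized expected scatter
        R = Ycur - S @ beta
        E = (R.T @ R + Cmass + V0inv) / (N + nu0 - p - 1)
        E = 0.5 * (E + E.T)

        J = observed_loglik(S, beta, E) + penalties(S, beta, E)
        trace.append(J)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1.0)
            if rel < spec.tol:
                converged = True
                break
    if not fully_observed:
        Ycur, _ = e_step(S, beta, E)

    if converged:
        logger.info("MPMM converged after %d iterations", it)
    else:
        logger.warning("MPMM reached max_iter=%d without converging", spec.max_iter)

    imputed = np.where(mask, tm.values, Ycur)
    return MPMMFit(
        S_mean=S,
        beta_mean=beta,
        E_mean=E,
        B_implied=beta.T @ beta,
        imputed=imputed,
        elbo_trace=trace,
        converged=converged,
        n_iter=it,
    )
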