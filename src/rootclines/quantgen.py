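"""Phenotype statistics: mixed-model BLUPs, broad-sense heritability, trait
PCA, and the Holm-adjusted PC-environment correlation screen.

The BLUP model is the replicated greenhouse design
``y = b0 + R0r + N0n + T0t + e`` with every grouping factor random and a
single fixed intercept.  Variance components are estimated by EM-REML on
Henderson's mixed-model equations: each iteration solves the MME at the
current variance ratios and updates ``sigma2_f`` from the random-effect
solutions plus the trace of the corresponding block of the inverse
coefficient matrix.  EM steps never decrease the REML likelihood, at the
price of slow terminal convergence — adequate at greenhouse scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ModelError, NumericError

DEFAULT_SCREEN_ENV = ("elevation", "annual_precipitation", "mean_temperature", "soil_ph")


@dataclass
class BlupModelSpec:
    """Random-intercept model: response ~ grand mean + one random effect per factor."""

    response: str
    factors: tuple[str, ...] = ("accession", "node", "tray")

    def __post_init__(self):
        if len(self.factors) < 1:
            raise ModelError("at least one random factor is required")


@dataclass
class VarianceComponents:
    components: dict[str, float]   # per-factor variance
    residual: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def H2(self) -> float:
        return heritability(self)


def heritability(vc: VarianceComponents, genotype_factor: str = "accession") -> float:
    """Broad-sense heritability: genotype variance over genotype + error variance."""
    if genotype_factor not in vc.components:
        raise ModelError(f"no {genotype_factor!r} factor in the fitted model")
    sg = vc.components[genotype_factor]
    return sg / (sg + vc.residual) if (sg + vc.residual) > 0 else 0.0


def fit_blups(observations: pd.DataFrame, spec: BlupModelSpec,
              max_iter: int = 500, tol: float = 1e-8, track_loglik: bool = False,
              ) -> tuple[VarianceComponents, dict[str, pd.Series]]:
    """EM-REML variance components and BLUPs for a multi-factor random model.

    Returns the variance components and, per factor, a Series of BLUPs
    indexed by level.  BLUPs of each factor sum to ~0.  ``track_loglik``
    records the REML log-likelihood per iteration (an O(n^3) diagnostic).
    """
    y = observations[spec.response].to_numpy(float)
    n = len(y)
    if n < 3:
        raise ModelError("need at least 3 observations")
    Zs, levels = [], {}
    for f in spec.factors:
        if f not in observations.columns:
            raise ModelError(f"observations lack factor column {f!r}")
        labels = observations[f].astype(str)
        if labels.isna().any():
            raise ModelError(f"factor {f!r} has missing labels")
        lev = sorted(labels.unique())
        if len(lev) < 2:
            raise ModelError(f"factor {f!r} is confounded with the mean (single level)")
        Z = pd.get_dummies(pd.Categorical(labels, categories=lev)).to_numpy(float)
        Zs.append(Z)
        levels[f] = lev
    X = np.ones((n, 1))
    Zall = np.hstack(Zs)
    q_sizes = [Z.shape[1] for Z in Zs]
    q_total = sum(q_sizes)
    offsets = np.cumsum([0] + q_sizes)

    XtX = X.T @ X
    XtZ = X.T @ Zall
    ZtZ = Zall.T @ Zall
    Xty = X.T @ y
    Zty = Zall.T @ y
    yty = float(y @ y)

    sigma = {f: float(np.var(y)) / (len(spec.factors) + 1) for f in spec.factors}
    sigma_e = float(np.var(y)) / (len(spec.factors) + 1)
    loglik_trace: list[float] = []
    converged = False
    b = u = None
    for it in range(1, max_iter + 1):
        lam = np.concatenate([
            np.full(q, sigma_e / max(sigma[f], 1e-12))
            for f, q in zip(spec.factors, q_sizes)
        ])
        C = np.block([[XtX, XtZ], [XtZ.T, ZtZ + np.diag(lam)]])
        rhs = np.concatenate([Xty, Zty])
        try:
            Cinv = np.linalg.inv(C)
        except np.linalg.LinAlgError as exc:
            raise ModelError("singular mixed-model equations") from exc
        sol = Cinv @ rhs
        b, u = sol[:1], sol[1:]

        new_sigma = {}
        for i, f in enumerate(spec.factors):
            s = slice(1 + offsets[i], 1 + offsets[i + 1])
            uf = sol[s]
            tr = np.trace(Cinv[s, s])
            new_sigma[f] = float((uf @ uf + sigma_e * tr) / q_sizes[i])
        resid_ss = yty - float(b @ Xty) - float(u @ Zty)
        new_sigma_e = float(resid_ss / (n - X.shape[1]))
        if new_sigma_e <= 0:
            raise NumericError("EM-REML produced non-positive residual variance")

        if track_loglik:
            loglik_trace.append(
                _reml_loglik(y, X, Zs, [new_sigma[f] for f in spec.factors], new_sigma_e))
        rel = max(
            [abs(new_sigma[f] - sigma[f]) / max(sigma[f], 1e-12) for f in spec.factors]
            + [abs(new_sigma_e - sigma_e) / max(sigma_e, 1e-12)]
        )
        sigma, sigma_e = new_sigma, new_sigma_e
        if rel < tol:
            converged = True
            break
    if not converged and max_iter >= 100:
        # EM converges slowly near boundary; report the trace rather than fail
        pass
    vc = VarianceComponents(components=dict(sigma), residual=sigma_e,
                            n_iter=it, converged=converged, loglik_trace=loglik_trace)
    blups = {}
    for i, f in enumerate(spec.factors):
        s = slice(offsets[i], offsets[i + 1])
        blups[f] = pd.Series(u[s], index=levels[f], name=f)
    return vc, blups


def _reml_loglik(y, X, Zs, sigmas, sigma_e) -> float:
    n = len(y)
    V = sigma_e * np.eye(n)
    for Z, s2 in zip(Zs, sigmas):
        V += s2 * (Z @ Z.T)
    sign, logdetV = np.linalg.slogdet(V)
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    sign2, logdetX = np.linalg.slogdet(XtVinvX)
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    r = y - X @ beta
    return float(-0.5 * (logdetV + logdetX + r @ Vinv @ r))


# ---------------------------------------------------------------------------
# Trait PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame          # accession x component
    loadings: pd.DataFrame        # trait x component
    explained_ratio: np.ndarray   # variance fraction per component


def trait_pca(traits: pd.DataFrame, center: bool = True, scale: bool = True,
              id_column: str = "accession") -> PcaResult:
    """PCA of the accession x trait table via SVD.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making reports reproducible across libraries.
    """
    if id_column in traits.columns:
        ids = traits[id_column].astype(str).tolist()
        X = traits.drop(columns=[id_column])
    else:
        ids = [str(i) for i in traits.index]
        X = traits
    X = X.select_dtypes(include=[np.number])
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise DataError("PCA needs at least 2 traits and 3 accessions")
    if X.isna().any().any():
        raise DataError("PCA input contains missing values")
    M = X.to_numpy(float)
    if center:
        M = M - M.mean(axis=0)
    if scale:
        sd = M.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if len(zero):
            raise DataError(f"zero-variance trait: {X.columns[zero[0]]!r}")
        M = M / sd
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    # deterministic sign: largest |loading| positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    comps = [f"PC{k + 1}" for k in range(len(S))]
    scores = pd.DataFrame(U * S, index=ids, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comps)
    explained = S ** 2 / np.sum(S ** 2)
    return PcaResult(scores=scores, loadings=loadings, explained_ratio=explained)


# ---------------------------------------------------------------------------
# PC-environment correlation screen
# ---------------------------------------------------------------------------

def pc_environment_screen(pca: PcaResult, descriptors: pd.DataFrame,
                          which_pcs=(1, 2, 3),
                          which_env=DEFAULT_SCREEN_ENV,
                          id_column: str = "accession") -> pd.DataFrame:
    """Pearson r of PC scores against named environmental descriptors, with a
    Holm step-down over the whole test family."""
    env = descriptors.set_index(descriptors[id_column].astype(str))
    shared = [a for a in pca.scores.index if a in env.index]
    if len(shared) < 3:
        raise DataError("fewer than 3 shared accessions between PCA and descriptors")
    rows = []
    for k in which_pcs:
        pc = f"PC{k}"
        if pc not in pca.scores.columns:
            continue
        x = pca.scores.loc[shared, pc].to_numpy(float)
        for name in which_env:
            ys = env.loc[shared, name].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(ys)
            if ok.sum() < 3:
                raise DataError(f"fewer than 3 complete pairs for {pc} vs {name}")
            r, p = stats.pearsonr(x[ok], ys[ok])
            rows.append({"pc": pc, "descriptor": name, "n": int(ok.sum()),
                         "r": r, "p": p})
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p"].to_numpy())
    return table


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down familywise adjustment (order-invariant)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def elevation_tercile_anova(pc_scores: pd.Series, elevation: pd.Series) -> dict:
    """Convenience wrapper: split PC scores into terciles (ties to the lower
    bin) and run a one-way ANOVA of elevation across the groups."""
    shared = pc_scores.index.intersection(elevation.index)
    x = pc_scores.loc[shared].to_numpy(float)
    e = elevation.loc[shared].to_numpy(float)
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    groups = np.where(x <= q1, 0, np.where(x <= q2, 1, 2))
    samples = [e[groups == g] for g in range(3) if np.any(groups == g)]
    if len(samples) < 2:
        raise DataError("tercile split produced fewer than 2 groups")
    F, p = stats.f_oneway(*samples)
    return {"F": float(F), "p": float(p),
            "group_means": [float(s.mean()) for s in samples]}
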