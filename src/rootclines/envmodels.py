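"""All-relevant environmental feature selection, ensemble-tree trait models,
out-of-bag evaluation, Shapley-style attributions, and projection of trait
models onto a genotyped target panel.

Feature selection follows the shadow-feature (Boruta) scheme: each iteration
appends a permuted copy of every descriptor, fits a random forest on the
augmented matrix, and scores a "hit" for every real descriptor whose
permutation importance exceeds the best shadow importance.  A two-sided
binomial test on the accumulated hit counts confirms or rejects descriptors;
survivors at ``max_runs`` are resolved by the median-importance rough fix.

Importances are permutation importances (mean increase in MSE when a column
is shuffled), matching the all-relevant selection literature; impurity
importances are biased toward high-cardinality features.  All seeds are
derived by hashing descriptor/trait *names*, so results are invariant to
column order and adding a trait does not perturb the others.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .errors import ConfigError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 5000
SELECTION_N_TREES = 500


def _name_seed(*parts) -> int:
    """Stable 31-bit seed from string parts (order-sensitive)."""
    h = 0
    for p in parts:
        h = zlib.crc32(str(p).encode(), h)
    return h & 0x7FFFFFFF


def _rng_for(master_seed: int, *parts) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), _name_seed(*parts)])


@dataclass
class FeatureSelection:
    trait: str
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]          # undecided by the binomial test, resolved by rough fix
    hits: dict[str, int]
    n_iter: int
    alpha: float
    max_runs: int


@dataclass
class TraitModel:
    trait: str
    descriptors: list[str]
    n_trees: int
    split_candidates: int
    seed: int
    oob_r2: float
    fit_r: float
    estimator: RandomForestRegressor
    training_range: pd.DataFrame   # min/max per descriptor
    training_X: pd.DataFrame = None
    training_y: np.ndarray = None


@dataclass
class ShapAttribution:
    base_value: float
    contributions: pd.DataFrame    # rows x descriptors
    method: str
    n_samples: int | None = None

    def predictions(self) -> np.ndarray:
        return self.base_value + self.contributions.sum(axis=1).to_numpy()


@dataclass
class ProjectionResult:
    values: pd.DataFrame               # accession x modeled traits
    extrapolation: pd.DataFrame        # accession x descriptors (bool, out of range)
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Permutation importance (stacked single predict keeps this fast)
# ---------------------------------------------------------------------------

def _permutation_importance(model, X: np.ndarray, y: np.ndarray,
                            col_rngs: list[np.random.Generator],
                            n_repeats: int = 3,
                            columns: list[int] | None = None) -> np.ndarray:
    """Increase in MSE when each scored column is shuffled (averaged over
    repeats).

    ``X``/``y`` should be rows the model did not see during fitting
    (held-out data), so importances measure generalizable signal rather
    than in-bag overfit.  ``columns`` selects which columns to score
    (default all); all shuffled copies are stacked into a single predict
    call.
    """
    n, p = X.shape
    if columns is None:
        columns = list(range(p))
    k = len(columns)
    base_mse = float(np.mean((model.predict(X) - y) ** 2))
    stacked = np.repeat(X[None, :, :], k * n_repeats, axis=0).reshape(n_repeats, k, n, p)
    for r in range(n_repeats):
        for jj, j in enumerate(columns):
            stacked[r, jj, :, j] = X[col_rngs[jj].permutation(n), j]
    preds = model.predict(stacked.reshape(-1, p)).reshape(n_repeats, k, n)
    mse = np.mean((preds - y[None, None, :]) ** 2, axis=2)
    return mse.mean(axis=0) - base_mse


# ---------------------------------------------------------------------------
# Shadow-feature selection
# ---------------------------------------------------------------------------

def boruta_select(y: np.ndarray, X: pd.DataFrame, trait: str = "trait",
                  alpha: float = 0.01, max_runs: int = 100,
                  n_trees: int = SELECTION_N_TREES, seed: int = 0) -> FeatureSelection:
    """All-relevant selection of descriptors for one trait.

    An empty confirmed set is a valid outcome (a trait not related to the
    environment), not an error.
    """
    if len(X) < 15:
        raise ConfigError("feature selection needs at least 15 accessions")
    if X.isna().any().any():
        raise ConfigError("descriptors must be complete for feature selection")
    names = sorted(X.columns.astype(str))
    Xfull = X[names].to_numpy(float)
    y = np.asarray(y, dtype=float)
    n, p_init = Xfull.shape

    hits = {f: 0 for f in names}
    trials = {f: 0 for f in names}
    undecided = set(names)
    confirmed: list[str] = []
    rejected: list[str] = []
    imp_history: dict[str, list[float]] = {f: [] for f in names}
    shadow_max_history: list[float] = []
    # the binomial test is Bonferroni-adjusted over the initial descriptor
    # count, and rejected descriptors leave the model (standard practice for
    # shadow-feature selection; keeps the familywise error and runtime down)
    alpha_adj = alpha / p_init

    stall_limit = 20  # undecided set unchanged this long -> hand over to rough fix
    stall = 0
    it = 0
    while undecided and it < max_runs:
        it += 1
        active = sorted(undecided | set(confirmed))
        cols = [names.index(f) for f in active]
        Xs = Xfull[:, cols]
        # only undecided descriptors need scoring; confirmed ones stay in
        # the model so the forest keeps competing against them
        eval_names = sorted(undecided)
        eval_idx = [active.index(f) for f in eval_names]
        pe = len(eval_names)
        # the shadow pool always covers every descriptor, so the importance
        # bar stays "max over p chance patterns" even late in the run
        shadow = np.empty((n, p_init))
        for j, f in enumerate(names):
            rng_j = _rng_for(seed, trait, "shadow", it, f)
            shadow[:, j] = Xfull[rng_j.permutation(n), j]
        aug = np.hstack([Xs, shadow])
        # cross-fit importance: fit on each half, permute-and-score on the
        # other, average.  Out-of-sample scoring measures generalizable
        # signal (not in-bag overfit); both halves contribute evaluations.
        split_rng = _rng_for(seed, trait, "split", it)
        perm = split_rng.permutation(n)
        halves = (perm[: n // 2], perm[n // 2:])
        eval_cols = eval_idx + list(range(len(active), aug.shape[1]))
        imps = []
        for side, (fit_rows, hold) in enumerate([(halves[0], halves[1]),
                                                 (halves[1], halves[0])]):
            model = RandomForestRegressor(
                n_estimators=n_trees // 2,
                max_features="sqrt",
                random_state=_name_seed(seed, trait, "fit", it, side),
                n_jobs=1,
            )
            model.fit(aug[fit_rows], y[fit_rows])
            col_rngs = [_rng_for(seed, trait, "perm", it, side, f) for f in eval_names] + \
                       [_rng_for(seed, trait, "perm", it, side, f, "shadow") for f in names]
            imps.append(_permutation_importance(model, aug[hold], y[hold],
                                                col_rngs, columns=eval_cols))
        imp = np.mean(imps, axis=0)
        real_imp, shadow_imp = imp[:pe], imp[pe:]
        shadow_max = float(shadow_imp.max())
        shadow_max_history.append(shadow_max)
        for j, f in enumerate(eval_names):
            imp_history[f].append(float(real_imp[j]))
            trials[f] += 1
            if real_imp[j] > shadow_max:
                hits[f] += 1
        changed = False
        for f in sorted(undecided):
            res = stats.binomtest(hits[f], trials[f], 0.5, alternative="two-sided")
            if res.pvalue < alpha_adj:
                if hits[f] > trials[f] / 2:
                    confirmed.append(f)
                else:
                    rejected.append(f)
                undecided.discard(f)
                changed = True
        stall = 0 if changed else stall + 1
        if stall >= stall_limit:
            break

    tentative = sorted(undecided)
    if tentative:
        # rough fix: a tentative descriptor is promoted only when its
        # importance history sits significantly above the max-shadow
        # history (paired one-sided Wilcoxon on the per-iteration
        # differences); straddling chance features are rejected
        sm = np.asarray(shadow_max_history)
        for f in tentative:
            diff = np.asarray(imp_history[f]) - sm[-len(imp_history[f]):]
            promote = False
            if np.median(diff) > 0 and np.any(diff != 0):
                res = stats.wilcoxon(diff, alternative="greater")
                promote = res.pvalue < alpha
            if promote:
                confirmed.append(f)
            else:
                rejected.append(f)
    return FeatureSelection(trait=trait, confirmed=sorted(confirmed),
                            rejected=sorted(rejected), tentative=tentative,
                            hits=hits, n_iter=it, alpha=alpha, max_runs=max_runs)


def select_features(traits: pd.DataFrame, descriptors: pd.DataFrame,
                    trait_columns: list[str] | None = None,
                    alpha: float = 0.01, max_runs: int = 100,
                    n_trees: int = SELECTION_N_TREES, seed: int = 0,
                    id_column: str = "accession") -> dict[str, FeatureSelection]:
    """Run shadow-feature selection for every trait column."""
    X = _descriptor_block(descriptors, id_column)
    merged = traits.merge(descriptors[[id_column]], on=id_column)
    if trait_columns is None:
        trait_columns = [c for c in traits.columns if c != id_column]
    out = {}
    for t in trait_columns:
        y = merged[t].to_numpy(float)
        out[t] = boruta_select(y, X, trait=t, alpha=alpha, max_runs=max_runs,
                               n_trees=n_trees, seed=seed)
        logger.info("selection %s: %d confirmed, %d rejected (%d iterations)",
                    t, len(out[t].confirmed), len(out[t].rejected), out[t].n_iter)
    return out


def _descriptor_block(descriptors: pd.DataFrame, id_column: str) -> pd.DataFrame:
    drop = {id_column, "panel", "longitude", "latitude"}
    cols = [c for c in descriptors.columns
            if c not in drop and pd.api.types.is_numeric_dtype(descriptors[c])]
    return descriptors[cols]


# ---------------------------------------------------------------------------
# Trait models
# ---------------------------------------------------------------------------

def fit_trait_model(y: np.ndarray, descriptors: pd.DataFrame,
                    selection: FeatureSelection | list[str],
                    trait: str = "trait", n_trees: int = DEFAULT_N_TREES,
                    seed: int = 0) -> TraitModel:
    """Random-forest regression on the confirmed descriptor set.

    Split candidates per node are floor(p/3) (minimum 1); model quality is
    reported as out-of-bag percent variance explained (may be negative) and
    the Pearson correlation of observed vs OOB-predicted values.
    """
    features = selection.confirmed if isinstance(selection, FeatureSelection) else list(selection)
    if not features:
        raise ConfigError(f"trait {trait!r} has an empty confirmed descriptor set "
                          "(trait not modeled)")
    features = sorted(features)
    missing = [f for f in features if f not in descriptors.columns]
    if missing:
        raise SchemaError(f"descriptor table lacks columns {missing}")
    X = descriptors[features].to_numpy(float)
    y = np.asarray(y, dtype=float)
    p = len(features)
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, p // 3),
        oob_score=True,
        random_state=_name_seed(seed, trait, "model"),
        n_jobs=1,
    )
    model.fit(X, y)
    oob = model.oob_prediction_
    var_y = float(np.var(y))
    oob_r2 = 1.0 - float(np.mean((y - oob) ** 2)) / var_y if var_y > 0 else 0.0
    fit_r = float(stats.pearsonr(y, oob)[0]) if np.std(oob) > 0 else 0.0
    rng_df = pd.DataFrame({"min": X.min(axis=0), "max": X.max(axis=0)}, index=features)
    return TraitModel(trait=trait, descriptors=features, n_trees=n_trees,
                      split_candidates=max(1, p // 3), seed=seed,
                      oob_r2=oob_r2, fit_r=fit_r, estimator=model,
                      training_range=rng_df,
                      training_X=descriptors[features].copy(), training_y=y.copy())


def project(models: list[TraitModel], target_descriptors: pd.DataFrame,
            id_column: str = "accession") -> ProjectionResult:
    """Apply fitted trait models to the target panel.

    A pure function of the stored models.  Accessions with descriptor values
    outside the training range are flagged in the extrapolation report, not
    dropped.
    """
    ids = target_descriptors[id_column].astype(str).tolist()
    values = pd.DataFrame(index=ids)
    all_feats = sorted({f for m in models for f in m.descriptors})
    missing = [f for f in all_feats if f not in target_descriptors.columns]
    if missing:
        raise SchemaError(f"target descriptor table lacks columns {missing}")
    extrap = pd.DataFrame(False, index=ids, columns=all_feats)
    for m in models:
        X = target_descriptors[m.descriptors].to_numpy(float)
        values[m.trait] = m.estimator.predict(X)
        lo = m.training_range["min"].to_numpy()
        hi = m.training_range["max"].to_numpy()
        out = (X < lo) | (X > hi)
        extrap.loc[:, m.descriptors] |= pd.DataFrame(out, index=ids, columns=m.descriptors)
    if not np.isfinite(values.to_numpy()).all():
        raise ConfigError("projection produced non-finite values")
    prov = {m.trait: {"n_trees": m.n_trees, "seed": m.seed,
                      "descriptors": m.descriptors} for m in models}
    return ProjectionResult(values=values, extrapolation=extrap, provenance=prov)


# ---------------------------------------------------------------------------
# Shapley attributions
# ---------------------------------------------------------------------------

MODEL_ARCHIVE_VERSION = 1


def save_models(models: list[TraitModel], path) -> None:
    """Serialize trait models (with provenance) to a joblib archive."""
    import joblib

    payload = {
        "version": MODEL_ARCHIVE_VERSION,
        "models": models,
        "provenance": {m.trait: {"descriptors": m.descriptors,
                                 "n_trees": m.n_trees, "seed": m.seed}
                       for m in models},
    }
    joblib.dump(payload, path)


def load_models(path) -> list[TraitModel]:
    import joblib

    payload = joblib.load(path)
    if payload.get("version") != MODEL_ARCHIVE_VERSION:
        raise ConfigError(f"unsupported model archive version "
                          f"{payload.get('version')!r}")
    return payload["models"]


def shap_attribute(model: TraitModel, rows: pd.DataFrame,
                   method: str = "exact_tree", background: pd.DataFrame | None = None,
                   n_samples: int = 200, max_background: int = 64,
                   seed: int = 0) -> ShapAttribution:
    """Additive per-descriptor attribution of model predictions.

    ``exact_tree`` enumerates all feature coalitions and computes exact
    Shapley values under the marginal (interventional) expectation over a
    background sample; feasible for the small descriptor sets these models
    use (p <= 14).  ``sampling`` is the Monte-Carlo permutation estimator.
    Both satisfy additivity: base value + row sum = model prediction.
    """
    feats = model.descriptors
    missing = [f for f in feats if f not in rows.columns]
    if missing:
        raise SchemaError(f"rows lack model descriptors {missing}")
    X = rows[feats].to_numpy(float)
    if background is None:
        background = model.training_X
    B = background[feats].to_numpy(float)
    rng = _rng_for(seed, model.trait, "shap")
    if len(B) > max_background:
        B = B[rng.choice(len(B), size=max_background, replace=False)]
    predict = model.estimator.predict
    p = len(feats)

    if method == "exact_tree":
        if p > 14:
            raise ConfigError("exact attribution limited to 14 descriptors; use sampling")
        contrib = _exact_shapley(predict, X, B, p)
        base = float(predict(B).mean())
    elif method == "sampling":
        contrib, base = _sampling_shapley(predict, X, B, p, n_samples, rng)
    else:
        raise ConfigError(f"unknown attribution method {method!r}")
    return ShapAttribution(base_value=base,
                           contributions=pd.DataFrame(contrib, columns=feats,
                                                      index=rows.index),
                           method=method,
                           n_samples=n_samples if method == "sampling" else None)


def _coalition_value(predict, X, B, mask) -> np.ndarray:
    """v(S): mean prediction with features in S from x, the rest from the
    background rows (marginal expectation)."""
    n, nb = len(X), len(B)
    hyb = np.repeat(B[None, :, :], n, axis=0)          # (n, nb, p)
    hyb[:, :, mask] = X[:, None, mask]
    return predict(hyb.reshape(n * nb, -1)).reshape(n, nb).mean(axis=1)


def _exact_shapley(predict, X, B, p) -> np.ndarray:
    from itertools import combinations
    from math import factorial

    n = len(X)
    values = {}
    for r in range(p + 1):
        for S in combinations(range(p), r):
            mask = np.zeros(p, dtype=bool)
            mask[list(S)] = True
            values[S] = _coalition_value(predict, X, B, mask)
    contrib = np.zeros((n, p))
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for r in range(p):
            w = factorial(r) * factorial(p - r - 1) / factorial(p)
            for S in combinations(others, r):
                Sj = tuple(sorted(S + (j,)))
                contrib[:, j] += w * (values[Sj] - values[S])
    return contrib


def _sampling_shapley(predict, X, B, p, n_samples, rng) -> tuple[np.ndarray, float]:
    """Permutation estimator; base value is the mean prediction over the
    sampled background rows so additivity holds exactly."""
    n = len(X)
    contrib = np.zeros((n, p))
    b_idx = rng.integers(0, len(B), size=n_samples)
    base_preds = np.zeros(n_samples)
    for s in range(n_samples):
        order = rng.permutation(p)
        current = np.repeat(B[b_idx[s]][None, :], n, axis=0)
        base_row = predict(B[b_idx[s]][None, :])[0]
        base_preds[s] = base_row
        prev = np.full(n, base_row)
        for j in order:
            current[:, j] = X[:, j]
            cur = predict(current)
            contrib[:, j] += cur - prev
            prev = cur
    return contrib / n_samples, float(base_preds.mean())
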