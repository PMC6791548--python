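"""Cross-validation of breeding-value predictions.

Genotyped animals are split into k mutually exclusive folds by K-means
clustering on their pedigree relationship coefficients (rows of A22),
so validation sets are whole family clusters rather than random
animals. Per fold, the validation animals' corrected phenotypes are
masked for all traits, each model is refit on the remaining records,
and three metrics are computed per trait:

* predictive ability r = cor(prediction, held-out corrected phenotype)
* accuracy = r / sqrt(h2), with h2 the stage-1 multi-trait posterior
  mean heritability, fixed across folds
* bias = OLS slope of the corrected phenotype on the prediction
  (1 = no over- or under-dispersion of predictions)

The reduced-records experiment subsamples the most-recorded trait's
training records down to the reference trait's count and recomputes all
metrics with the validation sets unchanged, quantifying what the extra
records were buying.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .mme import run_model
from .pedigree import Pedigree, RelationshipMatrixA


@dataclass
class FoldAssignment:
    animal_ids: list[str]
    fold: np.ndarray  # 1..k per animal
    k: int
    seed: int
    feature: str = "A22 rows"

    def __post_init__(self) -> None:
        sizes = np.bincount(self.fold, minlength=self.k + 1)[1:]
        if (sizes == 0).any():
            raise ValueError("empty fold")

    def ids_in_fold(self, f: int) -> list[str]:
        return [a for a, g in zip(self.animal_ids, self.fold) if g == f]


def kmeans_folds(A22: RelationshipMatrixA, k: int = 5, seed: int = 0,
                 n_restarts: int = 25) -> FoldAssignment:
    """K-means on rows of A22 (Euclidean, best of ``n_restarts``)."""
    n = len(A22.ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} genotyped animals")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(A22.values)
    return FoldAssignment(list(A22.ids), labels.astype(int) + 1, k, seed)


def _fold_metrics(pred: np.ndarray, y: np.ndarray, h2: float) -> dict:
    ok = np.isfinite(y) & np.isfinite(pred)
    if ok.sum() < 3 or np.std(pred[ok]) == 0 or np.std(y[ok]) == 0:
        return {"predictive_ability": np.nan, "accuracy": np.nan, "bias": np.nan,
                "n": int(ok.sum())}
    r = float(np.corrcoef(pred[ok], y[ok])[0, 1])
    slope = float(np.polyfit(pred[ok], y[ok], 1)[0])
    return {"predictive_ability": r, "accuracy": r / np.sqrt(h2), "bias": slope,
            "n": int(ok.sum())}


@dataclass
class ValidationMetrics:
    per_fold: pd.DataFrame  # trait, model, fold, predictive_ability, accuracy, bias
    h2: dict[str, float]
    folds: FoldAssignment | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        g = self.per_fold.groupby(["trait", "model"])[
            ["predictive_ability", "accuracy", "bias"]]
        mean = g.mean()
        se = g.sem(ddof=1)
        out = mean.join(se, lsuffix="_mean", rsuffix="_se").reset_index()
        return out

    def write_tsv(self, path) -> None:
        self.per_fold.to_csv(path, sep="\t", index=False)


def run_cross_validation(
    yc: pd.DataFrame,
    ped: Pedigree,
    kinships: dict[str, object],
    varcomp,
    folds: FoldAssignment,
    models: list[str],
    h2: dict[str, float] | None = None,
    traits: list[str] | None = None,
    scoring_yc: pd.DataFrame | None = None,
) -> ValidationMetrics:
    """K-fold cross-validation over genotyped animals.

    ``kinships`` maps "BLUP" -> SparseAInverse and "ssGBLUP" ->
    HInverse; ``h2`` defaults to the heritabilities in ``varcomp``.
    Validation animals have all trait records masked during refitting.
    ``scoring_yc`` lets the reduced-records experiment train on a
    thinned table while scoring against the original held-out values.
    """
    traits = list(traits or varcomp.traits)
    if h2 is None:
        h2 = dict(zip(varcomp.traits, np.asarray(varcomp.h2, dtype=float)))
    rows = []
    yc_idx = (scoring_yc if scoring_yc is not None else yc).set_index("animal")
    for f in range(1, folds.k + 1):
        val_ids = folds.ids_in_fold(f)
        train = yc.copy()
        mask = train["animal"].isin(val_ids)
        train.loc[mask, traits] = np.nan
        for model in models:
            kin = kinships["ssGBLUP" if model.endswith("ssGBLUP") else "BLUP"]
            res = run_model(train, ped, kin, varcomp, model, traits=traits)
            pred = res.frame().loc[val_ids]
            held = yc_idx.loc[val_ids, traits]
            for tr in traits:
                met = _fold_metrics(pred[tr].to_numpy(), held[tr].to_numpy(),
                                    h2[tr])
                if met["n"] < 3:
                    import warnings
                    warnings.warn(
                        f"fold {f}, trait {tr}: too few phenotyped validation "
                        "animals; metric missing")
                rows.append({"trait": tr, "model": model, "fold": f, **met})
    return ValidationMetrics(pd.DataFrame(rows), dict(h2), folds)


def reduced_data_experiment(
    yc: pd.DataFrame,
    ped: Pedigree,
    kinships: dict[str, object],
    varcomp,
    folds: FoldAssignment,
    models: list[str],
    target_trait: str = "yw",
    reference_trait: str = "cw",
    seed: int = 0,
    h2: dict[str, float] | None = None,
    traits: list[str] | None = None,
) -> tuple[ValidationMetrics, ValidationMetrics]:
    """Full-vs-reduced comparison: subsample the target trait's records
    to the reference trait's count (validation records untouched) and
    recompute all metrics. Returns (full, reduced) metric tables."""
    traits = list(traits or varcomp.traits)
    n_target = int(yc[target_trait].notna().sum())
    n_ref = int(yc[reference_trait].notna().sum())
    if n_ref > n_target:
        raise ValueError(
            f"reference trait has more records ({n_ref}) than target ({n_target})")
    full = run_cross_validation(yc, ped, kinships, varcomp, folds, models,
                                h2=h2, traits=traits)

    rng = np.random.default_rng(seed)
    has = yc[target_trait].notna().to_numpy()
    droppable = np.flatnonzero(has)
    n_drop = n_target - n_ref
    drop = rng.choice(droppable, size=n_drop, replace=False)
    reduced_yc = yc.copy()
    reduced_yc.loc[reduced_yc.index[drop], target_trait] = np.nan
    # train on the thinned records but score against the original
    # held-out values, so the validation sets are identical to the full run
    reduced = run_cross_validation(reduced_yc, ped, kinships, varcomp, folds,
                                   models, h2=h2, traits=traits, scoring_yc=yc)
    return full, reduced


def permutation_null(pred: np.ndarray, y: np.ndarray, n_perm: int = 200,
                     seed: int = 0) -> float:
    """Mean correlation of predictions with permuted phenotypes (should
    be ~0; a calibration check for the predictive-ability metric)."""
    rng = np.random.default_rng(seed)
    ok = np.isfinite(pred) & np.isfinite(y)
    pred, y = pred[ok], y[ok]
    rs = [np.corrcoef(pred, rng.permutation(y))[0, 1] for _ in range(n_perm)]
    return float(np.mean(rs))
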