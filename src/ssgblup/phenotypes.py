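"""Phenotype table handling, yearling-weight interpolation, fixed-effect
design construction, and corrected phenotypes.

Five traits are analysed: backfat thickness (BT, mm), carcass weight
(CW, kg), eye muscle area (EMA, cm^2), marbling score (MS, 9-point
scale treated as continuous), and yearling weight (YW, kg). YW is
recorded on all tested animals; carcass traits only on slaughtered
steers, so carcass records form a much smaller subset.

Fixed effects are trait-specific: YW uses batch-test-place-sex and
birth place; the carcass traits use batch-test-place-slaughter-date and
birth place, with slaughter age (days) as a covariate for CW, EMA and
MS (not BT). Identifiability is imposed by dropping the first level of
every factor against a per-trait intercept.

The corrected phenotype yc = u_hat + e_hat = y - X b_hat comes from the
stage-1 multi-trait fit and is the response for all later evaluation
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

TRAITS = ["bt", "cw", "ema", "ms", "yw"]

#: trait -> (factor columns, covariate column or None)
TRAIT_DESIGNS: dict[str, tuple[list[str], str | None]] = {
    "yw": (["cg_yw", "birth_place"], None),
    "bt": (["cg_carcass", "birth_place"], None),
    "cw": (["cg_carcass", "birth_place"], "slaughter_age"),
    "ema": (["cg_carcass", "birth_place"], "slaughter_age"),
    "ms": (["cg_carcass", "birth_place"], "slaughter_age"),
}


def compute_yw(w_t: float, t: float, w_t1: float, t1: float) -> float:
    """Yearling weight from two weighings by linear interpolation to day 365.

    YW = ((w_t - w_t1) / (t - t1)) * (365 - t1) + w_t1, with the final
    weighing at day ``t`` (~365) and the previous at day ``t1`` (~180).
    """
    if t1 <= 0 or t <= t1:
        raise ValueError(f"require t > t1 > 0, got t={t}, t1={t1}")
    if w_t <= 0 or w_t1 <= 0:
        raise ValueError("weights must be positive")
    return (w_t - w_t1) / (t - t1) * (365.0 - t1) + w_t1


@dataclass
class DesignSpec:
    """Fixed-effect design for one trait over the full record list."""

    trait: str
    X: np.ndarray          # (n_records, p) incl. intercept
    column_names: list[str]


def build_design(table: pd.DataFrame, trait: str) -> DesignSpec:
    """Trait-specific fixed-effect design matrix (drop-first coding).

    Rows follow ``table`` order; factor levels missing for a record are
    coded as their own "na" level so the matrix is defined for every
    animal (records with the trait unobserved still need a row during
    multi-trait missing-data augmentation). Single-level factors are
    dropped with a warning.
    """
    if trait not in TRAIT_DESIGNS:
        raise KeyError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    factors, covariate = TRAIT_DESIGNS[trait]
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for f in factors:
        if f not in table.columns:
            continue
        lv = table[f].astype(object).where(table[f].notna(), "na").astype(str)
        levels = sorted(lv.unique())
        if len(levels) < 2:
            warnings.warn(f"factor {f!r} has a single level; dropped for {trait}")
            continue
        for level in levels[1:]:  # drop first level
            cols.append((lv == level).to_numpy(dtype=float))
            names.append(f"{f}={level}")
    if covariate is not None and covariate in table.columns:
        x = table[covariate].to_numpy(dtype=float)
        x = np.where(np.isnan(x), np.nanmean(x), x)
        cols.append(x - x.mean())
        names.append(covariate)
    return DesignSpec(trait, np.column_stack(cols), names)


def build_designs(table: pd.DataFrame, traits: list[str] | None = None
                  ) -> dict[str, DesignSpec]:
    return {t: build_design(table, t) for t in (traits or TRAITS)}


def compute_corrected_phenotypes(fit, table: pd.DataFrame,
                                 traits: list[str] | None = None) -> pd.DataFrame:
    """yc = y - X b_hat per observed record (equivalently u_hat + e_hat).

    ``fit`` is a stage-1 posterior summary exposing ``b_hat`` (dict
    trait -> coefficient vector) and ``designs`` (dict trait ->
    DesignSpec) over the rows of ``table``.
    """
    traits = traits or [t for t in TRAITS if t in fit.b_hat]
    out = pd.DataFrame({"animal": table["animal"].to_numpy()})
    for t in traits:
        spec = fit.designs[t]
        if spec.X.shape[0] != len(table):
            raise ValueError("stage-1 fit and phenotype table have different rows")
        y = table[t].to_numpy(dtype=float)
        yc = y - spec.X @ fit.b_hat[t]
        out[t] = np.where(np.isnan(y), np.nan, yc)
    return out
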