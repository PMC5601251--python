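"""Within/among-individual decomposition of breeding success in early and late adulthood.

The population-level age trajectory confounds three things: genuine
within-individual change, the selective appearance of late recruits, and
the selective disappearance of short-lived birds.  Following the
within-group-centring approach, each species x sex dataset is split at the
population-level breakpoint and two Bernoulli GLMMs (individual + year
intercepts) are fitted:

* early adulthood (age <= cutoff), known recruits only::

      outcome ~ years_since_first + age_first + is_first_attempt

  ``years_since_first`` (age - age at first reproduction) captures
  within-individual improvement; ``age_first`` captures selective
  appearance (do late recruits perform differently?); the first-attempt
  flag captures the discontinuous penalty of inexperience.

* late adulthood (age > cutoff), presumed-dead birds only::

      outcome ~ years_before_death + age_last + is_last_attempt

  ``years_before_death`` (age at last reproduction - age) captures
  within-individual senescent decline -- by this coding a *positive*
  coefficient means success falls as death approaches; ``age_last``
  captures selective disappearance (a negative coefficient means good
  late-life breeders die younger); the last-attempt flag captures terminal
  effects.

Term importance is scored as the change in AIC when the term is removed and
the model refitted on identical data (positive = the term improves fit).
Optional robustness terms (partner change, years since the previous
attempt, its outcome, and their interaction) can be added to the late model
without altering the headline terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .age_models import make_age_basis, AgeFunctionSpec
from .glmm import fit_glmm, GlmmFit

__all__ = [
    "DecompositionResult",
    "split_at_threshold",
    "fit_early_model",
    "fit_late_model",
    "term_importance",
    "compare_sex_ages",
    "species_interaction_model",
]

EARLY_TERMS = ("years_since_first", "age_first", "is_first_attempt")
LATE_TERMS = ("years_before_death", "age_last", "is_last_attempt")
ROBUSTNESS_TERMS = ("partner_change", "years_since_last", "previous_outcome",
                    "years_since_last_x_previous_outcome")


@dataclass
class DecompositionResult:
    """Fitted early- or late-adulthood decomposition model.

    ``estimates`` maps term name -> (coefficient, SE, dAIC-on-removal);
    ``dropped`` lists terms removed from the design because their column was
    constant (degenerate data).
    """

    phase: str
    species: str | None
    sex: str | None
    fit: GlmmFit
    estimates: dict
    n_obs: int
    dropped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"phase": self.phase, "species": self.species, "sex": self.sex, "term": t,
             "estimate": est, "se": se, "delta_aic": d, "n": self.n_obs}
            for t, (est, se, d) in self.estimates.items()
        ]
        return pd.DataFrame(rows)


def split_at_threshold(records: pd.DataFrame, cutoff_age: int,
                       overrides: dict | None = None):
    """Partition attempts into early (age <= cutoff) and late (age > cutoff).

    ``overrides`` maps (species, sex) -> cutoff, replacing ``cutoff_age``
    for that subset (used e.g. to force the female wandering-albatross split
    to 18 so that all birds have started breeding in early adulthood).
    """
    df = records
    cut = pd.Series(int(cutoff_age), index=df.index)
    if overrides:
        for (sp, sex), c in overrides.items():
            cut[(df["species"] == sp) & (df["sex"] == sex)] = int(c)
    early = df[df["age"] <= cut].reset_index(drop=True)
    late = df[df["age"] > cut].reset_index(drop=True)
    if early.empty or late.empty:
        side = "early" if early.empty else "late"
        raise ValueError(f"cutoff {cutoff_age} leaves the {side} side empty")
    return early, late


def _build_design(df: pd.DataFrame, terms):
    """Centred design columns for the named covariates; constant columns are
    dropped (recorded) rather than fitted."""
    cols, names, dropped = [np.ones(len(df))], ["intercept"], []
    for t in terms:
        if t == "years_since_last_x_previous_outcome":
            x = (df["years_since_last"].to_numpy(dtype=float)
                 * df["previous_outcome"].to_numpy(dtype=float))
        else:
            x = df[t].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            dropped.append(t)
            continue
        if t in ("age_first", "age_last", "years_since_last"):
            x = x - x.mean()  # centring for conditioning; slope unchanged
        cols.append(x)
        names.append(t)
    return np.column_stack(cols), names, dropped


def _fit_with_importance(df, terms, phase, species=None, sex=None, importance=True):
    X, names, dropped = _build_design(df, terms)
    y = df["outcome"].to_numpy(dtype=float)
    ind = df["individual_id"].to_numpy()
    yr = df["season"].to_numpy()
    full = fit_glmm(y, X, ind, yr, terms=names)
    estimates = {}
    for t in names[1:]:
        j = names.index(t)
        if importance:
            reduced = fit_glmm(y, np.delete(X, j, axis=1), ind, yr,
                               terms=[n for n in names if n != t])
            d_aic = float(reduced.aic - full.aic)  # positive => term improves fit
        else:
            d_aic = float("nan")
        estimates[t] = (float(full.beta[j]), float(full.se[j]), d_aic)
    return DecompositionResult(
        phase=phase, species=species, sex=sex, fit=full, estimates=estimates,
        n_obs=len(df), dropped=dropped,
    )


def fit_early_model(early: pd.DataFrame, species=None, sex=None,
                    importance: bool = True) -> DecompositionResult:
    """Early-adulthood decomposition on known recruits.

    ``early`` must carry the derived covariates (see
    :func:`reproage.records.derive_covariates`); rows with
    ``known_recruit == 0`` are excluded because their age at first
    measurement is not their age at first reproduction.
    """
    df = early[early["known_recruit"] == 1].reset_index(drop=True)
    if df.empty:
        raise ValueError("no known recruits in the early-adulthood data")
    return _fit_with_importance(df, EARLY_TERMS, "early", species, sex, importance)


def fit_late_model(late: pd.DataFrame, robustness=(), species=None, sex=None,
                   importance: bool = True) -> DecompositionResult:
    """Late-adulthood decomposition on presumed-dead birds.

    Only birds whose disappearance satisfies the species gap rule
    (``presumed_dead == 1``) enter, so that age at last measurement is age
    at last reproduction.  ``robustness`` may add any of
    ``partner_change``, ``years_since_last``, ``previous_outcome``,
    ``years_since_last_x_previous_outcome``; these never displace the
    headline terms.  Rows missing a requested robustness covariate (first
    observed attempts) are dropped for that fit.
    """
    df = late[late["presumed_dead"] == 1].reset_index(drop=True)
    if df.empty:
        raise ValueError("no presumed-dead birds in the late-adulthood data")
    terms = list(LATE_TERMS)
    for t in robustness:
        if t not in ROBUSTNESS_TERMS:
            raise ValueError(f"unknown robustness term {t!r}")
        terms.append(t)
    if robustness:
        need = set(robustness) - {"partner_change"}
        if "years_since_last_x_previous_outcome" in need:
            need |= {"years_since_last", "previous_outcome"}
            need.discard("years_since_last_x_previous_outcome")
        for c in need:
            df = df[df[c].notna()]
        df = df.reset_index(drop=True)
    return _fit_with_importance(df, terms, "late", species, sex, importance)


def term_importance(result: DecompositionResult, term: str) -> float:
    """dAIC on removal for a fitted term (positive = term improves fit)."""
    if term not in result.estimates:
        raise KeyError(f"term {term!r} not in the fitted design")
    return result.estimates[term][2]


def compare_sex_ages(
    nests: pd.DataFrame,
    threshold_male: int,
    threshold_female: int,
    random_unit: str = "pair",
) -> dict:
    """Which parent's age explains more variation in nest success?

    ``nests`` has one row per nest x season with ``pair_id``, ``season``,
    ``male_age``, ``female_age``, ``outcome``.  Fits
    ``outcome ~ male hinge + female hinge`` with year and pair (or, with
    ``random_unit="none"``, year-only paired with a constant dummy) random
    intercepts, then drops each sex's pair of age columns in turn; the sex
    whose removal increases AIC more explains more variation.

    Returns a dict with the full fit, per-sex dAIC on dropping, and the
    winning sex.
    """
    for c in ("pair_id", "season", "male_age", "female_age", "outcome"):
        if c not in nests.columns:
            raise ValueError(f"nest table missing column {c!r}")
    if nests.empty:
        raise ValueError("no overlapping known-age pairs")
    Xm, _ = make_age_basis(AgeFunctionSpec("threshold1", (threshold_male,)),
                           nests["male_age"].to_numpy())
    Xf, _ = make_age_basis(AgeFunctionSpec("threshold1", (threshold_female,)),
                           nests["female_age"].to_numpy())
    X = np.column_stack([np.ones(len(nests)), Xm, Xf])
    names = ["intercept", "male_before", "male_after", "female_before", "female_after"]
    y = nests["outcome"].to_numpy(dtype=float)
    if random_unit == "pair":
        unit = nests["pair_id"].to_numpy()
    elif random_unit == "none":
        unit = np.zeros(len(nests), dtype=int)
    else:
        raise ValueError("random_unit must be 'pair' or 'none'")
    yr = nests["season"].to_numpy()
    full = fit_glmm(y, X, unit, yr, terms=names)
    drop = {}
    for sex, js in (("male", [1, 2]), ("female", [3, 4])):
        reduced = fit_glmm(y, np.delete(X, js, axis=1), unit, yr)
        drop[sex] = float(reduced.aic - full.aic)
    winner = max(drop, key=drop.get)
    return {"fit": full, "delta_aic_drop": drop, "more_variation": winner}


def species_interaction_model(
    records: pd.DataFrame, phase: str, reference: str = "BBA"
) -> pd.DataFrame:
    """Cross-species test: do the decomposition terms differ among species?

    Fits the phase model on all species together with treatment-coded
    species main effects and species x term interactions for each of the
    three phase terms, and scores each interaction *block* (both non-reference
    species contrasts for one term) by dAIC on removal.  Eligibility filters
    (known recruits / presumed dead) are applied as in the single-species
    models.

    Returns a tidy frame: term, interaction coefficient per species
    contrast, SE, and the block dAIC.
    """
    if phase == "early":
        terms, eligible = EARLY_TERMS, records["known_recruit"] == 1
    elif phase == "late":
        terms, eligible = LATE_TERMS, records["presumed_dead"] == 1
    else:
        raise ValueError("phase must be 'early' or 'late'")
    df = records[eligible].reset_index(drop=True)
    species = sorted(df["species"].unique())
    if len(species) < 2:
        raise ValueError("species interactions need at least two species present")
    others = [s for s in species if s != reference]
    if reference not in species:
        raise ValueError(f"reference species {reference!r} absent from the data")

    cols, names = [np.ones(len(df))], ["intercept"]
    base = {}
    for t in terms:
        x = df[t].to_numpy(dtype=float)
        if t in ("age_first", "age_last"):
            x = x - x.mean()
        base[t] = x
        cols.append(x)
        names.append(t)
    dummies = {}
    for s in others:
        d = (df["species"] == s).to_numpy(dtype=float)
        dummies[s] = d
        cols.append(d)
        names.append(f"species[{s}]")
    inter_blocks = {}
    for t in terms:
        js = []
        for s in others:
            cols.append(base[t] * dummies[s])
            names.append(f"species[{s}]:{t}")
            js.append(len(cols) - 1)
        inter_blocks[t] = js
    X = np.column_stack(cols)
    y = df["outcome"].to_numpy(dtype=float)
    ind = df["individual_id"].to_numpy()
    yr = df["season"].to_numpy()
    full = fit_glmm(y, X, ind, yr, terms=names)
    rows = []
    for t, js in inter_blocks.items():
        reduced = fit_glmm(y, np.delete(X, js, axis=1), ind, yr)
        d_aic = float(reduced.aic - full.aic)
        for j in js:
            rows.append(
                {"phase": phase, "interaction": names[j], "term": t,
                 "estimate": float(full.beta[j]), "se": float(full.se[j]),
                 "block_delta_aic": d_aic}
            )
    return pd.DataFrame(rows)
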