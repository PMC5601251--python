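"""Longitudinal breeding-attempt records: I/O, validation, filters, derived covariates.

The canonical in-memory container is a :class:`pandas.DataFrame` with one row
per breeding attempt (individual x season).  Required columns::

    individual_id  opaque string
    species        one of {"BBA", "GHA", "WA"}
    sex            one of {"M", "F"}
    season         integer year in which the chick would fledge
    age            integer age in years (>= 1)
    outcome        1 if the chick fledged, else 0

Optional columns: ``partner_id`` (opaque string) and ``known_recruit``
(1 if the first observed attempt is genuinely the bird's first breeding
attempt; assumed 1 when absent).

:func:`read_records` validates and derives the per-attempt bookkeeping
columns (``attempt_index``, ``years_since_last``, ``previous_outcome``,
``partner_change``); :func:`build_histories` collapses attempts into one row
per individual and applies the species-specific death proxy (a bird unseen
at the colony for 4 years for BBA, 5 years for GHA and WA, is presumed
dead); :func:`derive_covariates` adds the within-individual age clocks
(years since first breeding, years before death) used by the early/late
decomposition models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SPECIES = ("BBA", "GHA", "WA")
SEXES = ("M", "F")

#: Years a bird must go unseen after its last breeding season to be presumed
#: dead (established breeders are highly site-faithful; <1% of real gaps
#: exceed these values).
DEFAULT_GAP_RULE = {"BBA": 4, "GHA": 5, "WA": 5}

REQUIRED_COLUMNS = ("individual_id", "species", "sex", "season", "age", "outcome")


class RecordValidationError(ValueError):
    """Raised when a breeding-attempt table violates a structural invariant."""


def _as_frame(records) -> pd.DataFrame:
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(records)
    return records


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants; return the frame sorted by (individual, season).

    Raises
    ------
    RecordValidationError
        On a missing required column, non-binary outcome, duplicate
        (individual, season) pair, or ages that do not increase with season
        within an individual.
    """
    df = _as_frame(df)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"missing required column(s): {missing}")
    df = df.copy()
    df["season"] = df["season"].astype(int)
    df["age"] = df["age"].astype(int)
    out = df["outcome"]
    if not np.isin(np.asarray(out), (0, 1)).all():
        raise RecordValidationError("outcome must be binary (0/1)")
    df["outcome"] = out.astype(int)
    bad_sp = set(df["species"].unique()) - set(SPECIES)
    if bad_sp:
        raise RecordValidationError(f"unknown species code(s): {sorted(bad_sp)}")
    bad_sex = set(df["sex"].unique()) - set(SEXES)
    if bad_sex:
        raise RecordValidationError(f"unknown sex code(s): {sorted(bad_sex)}")
    if (df["age"] < 1).any():
        raise RecordValidationError("age must be >= 1")
    dup = df.duplicated(subset=["individual_id", "season"])
    if dup.any():
        pair = df.loc[dup, ["individual_id", "season"]].iloc[0]
        raise RecordValidationError(
            f"duplicate attempt for individual {pair['individual_id']!r} "
            f"in season {pair['season']}"
        )
    df = df.sort_values(["individual_id", "season"], kind="mergesort").reset_index(drop=True)
    # within an individual, age must be monotone increasing with season
    age_diff = df.groupby("individual_id", sort=False)["age"].diff()
    if (age_diff.dropna() <= 0).any():
        bad = df.loc[age_diff <= 0, "individual_id"].iloc[0]
        raise RecordValidationError(f"non-monotone ages within individual {bad!r}")
    return df


def annotate_attempts(df: pd.DataFrame) -> pd.DataFrame:
    """Derive attempt_index, years_since_last, previous_outcome, partner_change.

    ``years_since_last`` and ``previous_outcome`` refer to the bird's own
    previous attempt regardless of partner, and are missing (NaN) on the
    first observed attempt.  ``partner_change`` is 1 on the first attempt
    with a new partner (0 on the first attempt overall, and always 0 when
    no ``partner_id`` column is present).
    """
    df = df.copy()
    grp = df.groupby("individual_id", sort=False)
    df["attempt_index"] = grp.cumcount() + 1
    df["years_since_last"] = grp["season"].diff()
    df["previous_outcome"] = grp["outcome"].shift(1)
    if "partner_id" in df.columns:
        prev_partner = grp["partner_id"].shift(1)
        change = (df["partner_id"] != prev_partner) & prev_partner.notna()
        df["partner_change"] = change.astype(int)
    else:
        df["partner_change"] = 0
    return df


def read_records(path) -> pd.DataFrame:
    """Read a breeding-attempt CSV, validate it, and derive attempt covariates.

    The dialect is comma-separated UTF-8 with a mandatory header row, '.'
    decimal separator and empty strings for missing values.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "partner_id": str})
    return annotate_attempts(validate_records(df))


def write_records(df: pd.DataFrame, path) -> None:
    """Write breeding-attempt records in the CSV dialect read by :func:`read_records`."""
    _as_frame(df).to_csv(path, index=False)


def build_histories(records, study_end: int, gap_rule: dict | None = None) -> pd.DataFrame:
    """Collapse attempts into one row per individual and apply the death proxy.

    Parameters
    ----------
    records
        Validated attempt table (one row per individual x season).
    study_end
        Last monitored season.  A bird is presumed dead when
        ``study_end - last season >= gap_rule[species]``; birds failing the
        rule are censored (``presumed_dead = 0``), not imputed.
    gap_rule
        Species -> minimum unseen gap, default ``{"BBA": 4, "GHA": 5, "WA": 5}``.

    Returns
    -------
    DataFrame with one row per individual: species, sex, n_attempts,
    first_season, last_season, age_first, age_last, known_recruit,
    presumed_dead.
    """
    df = _as_frame(records)
    gap_rule = dict(DEFAULT_GAP_RULE if gap_rule is None else gap_rule)
    if int(study_end) < int(df["season"].max()):
        raise ValueError(
            f"study_end {study_end} earlier than the last observed season "
            f"{int(df['season'].max())}"
        )
    df = df.sort_values(["individual_id", "season"], kind="mergesort")
    grp = df.groupby("individual_id", sort=True)
    hist = grp.agg(
        species=("species", "first"),
        sex=("sex", "first"),
        n_attempts=("season", "size"),
        first_season=("season", "first"),
        last_season=("season", "last"),
        age_first=("age", "first"),
        age_last=("age", "last"),
    ).reset_index()
    if "known_recruit" in df.columns:
        hist["known_recruit"] = grp["known_recruit"].first().astype(int).values
    else:
        hist["known_recruit"] = 1
    gaps = hist["species"].map(gap_rule)
    hist["presumed_dead"] = (int(study_end) - hist["last_season"] >= gaps).astype(int)
    return hist


def filter_age_support(records, min_count: int = 5) -> pd.DataFrame:
    """Drop attempts at ages with fewer than ``min_count`` observations.

    Intended for a single species x sex dataset before population-level
    model fitting, so that thinly supported extreme ages do not drive the
    age-function fit.  The filter is applied once, not iterated.  (An
    alternative treatment -- pooling ages with <10 observations into their
    neighbour -- leaves the study's conclusions unchanged and is not
    implemented here.)
    """
    df = _as_frame(records)
    support = df.groupby("age")["age"].transform("size")
    out = df[support >= min_count].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no ages with >= {min_count} observations")
    return out


def derive_covariates(records, histories: pd.DataFrame) -> pd.DataFrame:
    """Attach within-individual age clocks and attempt flags.

    Adds, per attempt:

    - ``years_since_first`` = age - age_first (calendar years, so skipped
      seasons still advance the clock),
    - ``years_before_death`` = age_last - age,
    - ``is_first_attempt`` / ``is_last_attempt`` 0/1 flags,
    - the individual-level ``age_first``, ``age_last``, ``known_recruit``,
      ``presumed_dead`` columns from ``histories``.
    """
    df = _as_frame(records)
    cols = ["individual_id", "age_first", "age_last", "known_recruit", "presumed_dead"]
    drop = [c for c in cols[1:] if c in df.columns]
    merged = df.drop(columns=drop).merge(
        histories[cols], on="individual_id", how="left", validate="m:1"
    )
    if merged["age_first"].isna().any():
        bad = merged.loc[merged["age_first"].isna(), "individual_id"].iloc[0]
        raise ValueError(f"individual {bad!r} missing from histories")
    merged["years_since_first"] = merged["age"] - merged["age_first"]
    merged["years_before_death"] = merged["age_last"] - merged["age"]
    merged["is_first_attempt"] = (merged["years_since_first"] == 0).astype(int)
    merged["is_last_attempt"] = (merged["years_before_death"] == 0).astype(int)
    return merged


def summarize_life_history(histories: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE ages at first/last reproduction and reproductive lifespan.

    One row per species x sex.  The first-reproduction summary uses known
    recruits only; the last-reproduction summary uses presumed-dead birds
    only (their last observed attempt is their last reproduction).
    Reproductive lifespan is the difference of the two means -- a
    population-level quantity, not the mean of within-bird spans, because
    the two summaries draw on different (overlapping) sets of birds.
    SEs are sample SD / sqrt(n).
    """
    rows = []
    for (sp, sex), sub in histories.groupby(["species", "sex"]):
        first = sub.loc[sub["known_recruit"] == 1, "age_first"]
        last = sub.loc[sub["presumed_dead"] == 1, "age_last"]
        if len(first) == 0 or len(last) == 0:
            raise ValueError(f"empty summary cell for species={sp}, sex={sex}")
        rows.append(
            {
                "species": sp,
                "sex": sex,
                "n_first": len(first),
                "mean_age_first": first.mean(),
                "se_age_first": first.std(ddof=1) / np.sqrt(len(first)) if len(first) > 1 else np.nan,
                "n_last": len(last),
                "mean_age_last": last.mean(),
                "se_age_last": last.std(ddof=1) / np.sqrt(len(last)) if len(last) > 1 else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out["repro_lifespan"] = reproductive_lifespan(out["mean_age_first"], out["mean_age_last"])
    return out


def reproductive_lifespan(mean_age_first, mean_age_last):
    """Reproductive lifespan as the difference between mean ages at last and first reproduction."""
    return np.asarray(mean_age_last, dtype=float) - np.asarray(mean_age_first, dtype=float)
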