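"""Statistics over a table of surveyed studies (sample size vs accuracy).

The analyses mirror a common meta-survey recipe: test the sample-size column
for normality (raw and log10), correlate log10 sample size with reported
accuracy (Pearson) and raw sample size with accuracy (Spearman), report the
simple-regression R², and repeat the Pearson correlation inside each data
modality with at least 3 studies.

The real studies table is a supplementary artifact and is not shipped;
:func:`make_survey_fixture` generates a statistically similar stand-in
(positively skewed sample sizes, negatively correlated accuracy) for testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import InvalidArgumentError

__all__ = [
    "REQUIRED_COLUMNS",
    "SurveyStats",
    "load_survey",
    "survey_statistics",
    "make_survey_fixture",
]

REQUIRED_COLUMNS = ("study", "n", "accuracy", "year", "modality", "classifier")

MODALITIES = ("brain imaging", "motion tracking", "other")


@dataclass
class SurveyStats:
    n_studies: int
    ks_raw_d: float
    ks_raw_p: float
    ks_log_d: float
    ks_log_p: float
    pearson_r: float
    pearson_df: int
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    r_squared: float
    slope: float
    intercept: float
    median_n: float
    per_modality: dict[str, dict[str, Any]] = field(default_factory=dict)
    degenerate: bool = False
    ks_variant: str = "lilliefors"

    def to_json(self) -> str:
        return json.dumps(self.__dict__, default=float, indent=2)


def load_survey(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Load and validate a studies table (CSV path or DataFrame).

    Required columns: ``study,n,accuracy,year,modality,classifier``.
    Constraints: n >= 2, accuracy in (0, 100], unique study ids.  Violations
    raise with the offending rows listed.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidArgumentError(f"survey table is missing columns: {missing}")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    df["accuracy"] = pd.to_numeric(df["accuracy"], errors="coerce")
    bad_n = df.index[~(df["n"] >= 2)].tolist()
    if bad_n:
        raise InvalidArgumentError(f"rows with sample size < 2 or non-numeric: {bad_n}")
    bad_acc = df.index[~((df["accuracy"] > 0) & (df["accuracy"] <= 100))].tolist()
    if bad_acc:
        raise InvalidArgumentError(
            f"rows with accuracy outside (0, 100] or non-numeric: {bad_acc}"
        )
    dupes = df.index[df["study"].duplicated()].tolist()
    if dupes:
        raise InvalidArgumentError(f"duplicate study ids at rows: {dupes}")
    return df


def _ks_normality(x: np.ndarray, variant: str) -> tuple[float, float]:
    """One-sample KS test against a normal with estimated mean/SD.

    ``"lilliefors"`` corrects the p-value for the estimated parameters
    (default); ``"fitted"`` is the plain KS test against the fitted normal,
    which is anti-conservative but sometimes reported.  Degenerate input
    (fewer than 4 values, or zero spread) yields (nan, nan).
    """
    if len(x) < 4 or np.ptp(x) == 0:
        return float("nan"), float("nan")
    if variant == "lilliefors":
        d, p = lilliefors(x, dist="norm", pvalmethod="table")
        return float(d), float(p)
    if variant == "fitted":
        d, p = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
        return float(d), float(p)
    raise InvalidArgumentError(f"unknown KS variant {variant!r}")


def survey_statistics(
    table: pd.DataFrame, ks_variant: str = "lilliefors"
) -> SurveyStats:
    """Compute the full set of survey statistics from a validated table."""
    df = load_survey(table)
    if len(df) < 3:
        raise InvalidArgumentError("survey statistics need at least 3 studies")

    n = df["n"].to_numpy(dtype=float)
    acc = df["accuracy"].to_numpy(dtype=float)
    log_n = np.log10(n)

    degenerate = np.ptp(log_n) == 0 or np.ptp(acc) == 0
    if degenerate:
        pearson_r = pearson_p = spearman_rho = spearman_p = float("nan")
        slope = intercept = r_squared = float("nan")
    else:
        pearson_r, pearson_p = stats.pearsonr(log_n, acc)
        spearman_rho, spearman_p = stats.spearmanr(n, acc)
        slope, intercept = np.polyfit(log_n, acc, 1)
        r_squared = float(pearson_r) ** 2

    per_modality: dict[str, dict[str, Any]] = {}
    for modality, grp in df.groupby("modality"):
        if len(grp) < 3 or grp["accuracy"].nunique() == 1 or grp["n"].nunique() == 1:
            per_modality[str(modality)] = {"n_studies": len(grp), "skipped": True}
            continue
        r, p = stats.pearsonr(np.log10(grp["n"]), grp["accuracy"])
        per_modality[str(modality)] = {
            "n_studies": len(grp),
            "r": float(r),
            "df": len(grp) - 2,
            "p": float(p),
            "skipped": False,
        }

    ks_raw = _ks_normality(n, ks_variant)
    ks_log = _ks_normality(log_n, ks_variant)

    return SurveyStats(
        n_studies=len(df),
        ks_raw_d=ks_raw[0],
        ks_raw_p=ks_raw[1],
        ks_log_d=ks_log[0],
        ks_log_p=ks_log[1],
        pearson_r=float(pearson_r),
        pearson_df=len(df) - 2,
        pearson_p=float(pearson_p),
        spearman_rho=float(spearman_rho),
        spearman_p=float(spearman_p),
        r_squared=float(r_squared),
        slope=float(slope),
        intercept=float(intercept),
        median_n=float(np.median(n)),
        per_modality=per_modality,
        degenerate=bool(degenerate),
        ks_variant=ks_variant,
    )


def make_survey_fixture(
    n_studies: int = 55,
    slope: float = -15.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    intercept: float = 110.0,
) -> pd.DataFrame:
    """Generate a synthetic studies table emulating the survey's shape.

    Sample sizes are log-uniform on [20, 2000] (positively skewed on the raw
    scale); accuracy = intercept + slope * log10(N) + N(0, noise_sd), clipped
    to (50, 100].
    """
    if n_studies < 3:
        raise InvalidArgumentError(f"n_studies must be >= 3, got {n_studies}")
    rng = np.random.default_rng(seed)
    log_n = rng.uniform(np.log10(20), np.log10(2000), size=n_studies)
    n = np.round(10**log_n).astype(int)
    acc = intercept + slope * np.log10(n) + rng.normal(0.0, noise_sd, size=n_studies)
    acc = np.clip(acc, 50.0 + 1e-9, 100.0)
    modality = rng.choice(MODALITIES, size=n_studies, p=(0.7, 0.15, 0.15))
    classifier = rng.choice(
        ("SVM", "logistic regression", "random forest", "neural network"),
        size=n_studies,
    )
    year = rng.integers(2005, 2020, size=n_studies)
    return pd.DataFrame(
        {
            "study": [f"S{i + 1:03d}" for i in range(n_studies)],
            "n": n,
            "accuracy": np.round(acc, 2),
            "year": year,
            "modality": modality,
            "classifier": classifier,
        }
    )
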