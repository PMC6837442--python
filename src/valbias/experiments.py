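"""Sweep drivers: accuracy distributions across design points.

Each runner draws ``runs_per_point`` fresh datasets per design point, shares
every dataset across all compared schemes at that point (paired comparison),
and summarises the accuracy sample per (scheme, point): mean, 95% t-interval,
a one-sample t-test against the 50% chance level, and pairwise between-scheme
tests (unpaired, as reported in the source study, with the paired variant
emitted alongside).

Publication-scale presets encode the full settings; ``*-quick`` presets
downscale runs and points but never the protocol logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy import stats

from . import model_tuning as mt
from .exceptions import InvalidArgumentError
from .seeding import derive_seed
from .synthetic_data import Dataset, generate_discriminable, generate_noise
from .validation_schemes import PipelineSpec, preset, validate

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "summarize",
    "fit_trend",
    "run_sample_size_sweep",
    "run_feature_count_sweep",
    "run_grid_size_sweep",
    "run_folds_sweep",
    "run_ratio_sweep",
    "run_discriminable_sweep",
    "run_sweep",
    "experiment_preset",
    "PRESETS",
]

SWEEP_VARIABLES = (
    "sample_size",
    "n_features",
    "grid_size",
    "n_folds",
    "ratio",
    "discriminable_sample_size",
)

CHANCE_LEVEL = 50.0


@dataclass(frozen=True)
class ExperimentConfig:
    """One sweep: which variable to move, over which values, with what recipe."""

    variable: str
    values: tuple
    schemes: tuple[str, ...] = ("kfold",)
    pipeline: str | PipelineSpec = "logreg"
    runs_per_point: int = 50
    seed: int = 0
    n_samples: int = 100
    n_features: int = 50
    n_folds: int = 10
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.variable not in SWEEP_VARIABLES:
            raise InvalidArgumentError(
                f"unknown sweep variable {self.variable!r}; "
                f"expected one of {SWEEP_VARIABLES}"
            )
        if len(self.values) == 0:
            raise InvalidArgumentError("sweep values must be non-empty")
        if self.runs_per_point < 2:
            raise InvalidArgumentError(
                f"runs_per_point must be >= 2, got {self.runs_per_point}"
            )

    def resolved_pipeline(self) -> PipelineSpec:
        if isinstance(self.pipeline, PipelineSpec):
            return self.pipeline
        return preset(self.pipeline)


@dataclass
class SweepResult:
    """Raw per-run accuracies plus per-point summaries and pairwise tests."""

    raw: pd.DataFrame  # scheme, point, run, accuracy
    summary: pd.DataFrame
    pairwise: pd.DataFrame
    config: ExperimentConfig
    meta: dict[str, Any] = field(default_factory=dict)


def summarize(sample, chance: float = CHANCE_LEVEL) -> dict[str, float]:
    """Mean, 95% t-interval and a two-sided one-sample t-test vs ``chance``.

    CI = mean +/- t(0.975, R-1) * SD / sqrt(R).  A zero-variance sample gets
    CI width 0 and is flagged degenerate instead of a t statistic.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError("summarize needs a sample of size >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    r = x.size
    if sd == 0.0:
        return {
            "mean": mean,
            "ci_lo": mean,
            "ci_hi": mean,
            "ci_width": 0.0,
            "t": float("nan"),
            "p": float("nan"),
            "n_runs": r,
            "degenerate": True,
        }
    half = float(stats.t.ppf(0.975, r - 1) * sd / np.sqrt(r))
    t_stat, p = stats.ttest_1samp(x, chance)
    return {
        "mean": mean,
        "ci_lo": mean - half,
        "ci_hi": mean + half,
        "ci_width": 2 * half,
        "t": float(t_stat),
        "p": float(p),
        "n_runs": r,
        "degenerate": False,
    }


def fit_trend(x, y, order: int = 5):
    """Least-squares polynomial trend (plotting aid); coefficients lowest
    order first."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = min(order, x.size - 1)
    return np.polynomial.polynomial.polyfit(x, y, order)


# ---------------------------------------------------------------------------
# generic engine
# ---------------------------------------------------------------------------


def _run_points(
    config: ExperimentConfig,
    points: list[dict[str, Any]],
    dataset_factory: Callable[[dict[str, Any], int], Dataset],
    spec_factory: Callable[[dict[str, Any]], PipelineSpec],
) -> SweepResult:
    """Each ``point`` dict must carry a hashable ``label``; extra keys are
    copied into the raw table."""
    rows = []
    for pi, point in enumerate(points):
        spec = spec_factory(point)
        for run in range(config.runs_per_point):
            ds = dataset_factory(point, run)
            for scheme in config.schemes:
                res = validate(
                    scheme,
                    ds,
                    spec,
                    seed=derive_seed(config.seed, "validate", scheme, pi, run),
                    n_folds=config.n_folds,
                    test_fraction=config.test_fraction,
                )
                row = {k: v for k, v in point.items()}
                row.update(
                    scheme=scheme,
                    point=point["label"],
                    run=run,
                    accuracy=res.accuracy,
                )
                rows.append(row)
    raw = pd.DataFrame(rows)

    summaries = []
    for (scheme, label), grp in raw.groupby(["scheme", "point"], sort=False):
        s = summarize(grp["accuracy"].to_numpy())
        s.update(scheme=scheme, point=label)
        s["share_perfect"] = float(np.mean(grp["accuracy"].to_numpy() == 100.0))
        summaries.append(s)
    summary = pd.DataFrame(summaries)

    pairs = []
    schemes = list(config.schemes)
    for label, grp in raw.groupby("point", sort=False):
        for i in range(len(schemes)):
            for j in range(i + 1, len(schemes)):
                a = grp.loc[grp["scheme"] == schemes[i], "accuracy"].to_numpy()
                b = grp.loc[grp["scheme"] == schemes[j], "accuracy"].to_numpy()
                t_ind, p_ind = stats.ttest_ind(a, b)
                if np.all(a - b == (a - b)[0]):
                    t_rel, p_rel = float("nan"), float("nan")
                else:
                    t_rel, p_rel = stats.ttest_rel(a, b)
                pairs.append(
                    {
                        "point": label,
                        "scheme_a": schemes[i],
                        "scheme_b": schemes[j],
                        "mean_a": float(a.mean()),
                        "mean_b": float(b.mean()),
                        "t_unpaired": float(t_ind),
                        "p_unpaired": float(p_ind),
                        "t_paired": float(t_rel),
                        "p_paired": float(p_rel),
                    }
                )
    pairwise = pd.DataFrame(pairs)
    return SweepResult(raw=raw, summary=summary, pairwise=pairwise, config=config)


# ---------------------------------------------------------------------------
# the six sweeps
# ---------------------------------------------------------------------------


def run_sample_size_sweep(config: ExperimentConfig) -> SweepResult:
    """Noise data, p fixed (default 50), sample size varied; all requested
    schemes share each generated dataset."""
    for n in config.values:
        if n % 2 != 0:
            raise InvalidArgumentError(f"sample sizes must be even, got {n}")
    points = [{"label": int(n), "n_samples": int(n)} for n in config.values]
    spec = config.resolved_pipeline()
    return _run_points(
        config,
        points,
        lambda pt, run: generate_noise(
            pt["n_samples"],
            config.n_features,
            derive_seed(config.seed, "data", pt["label"], run),
        ),
        lambda pt: spec,
    )


def run_feature_count_sweep(config: ExperimentConfig) -> SweepResult:
    """Noise data, N fixed (default 100), feature count varied."""
    points = [{"label": int(p), "n_features": int(p)} for p in config.values]
    spec = config.resolved_pipeline()
    return _run_points(
        config,
        points,
        lambda pt, run: generate_noise(
            config.n_samples,
            pt["n_features"],
            derive_seed(config.seed, "data", pt["label"], run),
        ),
        lambda pt: spec,
    )


def run_grid_size_sweep(config: ExperimentConfig) -> SweepResult:
    """Noise data, N and p fixed; tuning grid built per point by
    :func:`valbias.model_tuning.make_grid`."""
    base = config.resolved_pipeline()
    points = [{"label": int(m), "grid_size": int(m)} for m in config.values]
    return _run_points(
        config,
        points,
        lambda pt, run: generate_noise(
            config.n_samples,
            config.n_features,
            derive_seed(config.seed, "data", pt["label"], run),
        ),
        lambda pt: replace(base, grid=mt.make_grid(base.classifier_kind, pt["grid_size"])),
    )


def run_folds_sweep(config: ExperimentConfig) -> SweepResult:
    """Noise data; the number of inner tuning folds varied (up to
    leave-one-out on the development rows)."""
    base = config.resolved_pipeline()
    points = [{"label": int(k), "inner_folds": int(k)} for k in config.values]
    return _run_points(
        config,
        points,
        lambda pt, run: generate_noise(
            config.n_samples,
            config.n_features,
            derive_seed(config.seed, "data", pt["label"], run),
        ),
        lambda pt: replace(base, inner_folds=pt["inner_folds"]),
    )


def run_ratio_sweep(config: ExperimentConfig) -> SweepResult:
    """Feature-to-sample ratio sweep: values are (ratio, n_samples) pairs and
    the feature count is ``round(ratio * n)`` per point."""
    points = []
    for ratio, n in config.values:
        if n % 2 != 0:
            raise InvalidArgumentError(f"sample sizes must be even, got {n}")
        p = max(1, int(round(ratio * n)))
        points.append(
            {
                "label": f"r={ratio:g},N={int(n)}",
                "ratio": float(ratio),
                "n_samples": int(n),
                "n_features": p,
            }
        )
    spec = config.resolved_pipeline()
    return _run_points(
        config,
        points,
        lambda pt, run: generate_noise(
            pt["n_samples"],
            pt["n_features"],
            derive_seed(config.seed, "data", pt["label"], run),
        ),
        lambda pt: spec,
    )


def run_discriminable_sweep(config: ExperimentConfig) -> SweepResult:
    """Discriminable generator (10 of 50 columns shifted by 0.5); summary
    includes CI widths and the share of perfect (100%) runs per point."""
    for n in config.values:
        if n % 2 != 0:
            raise InvalidArgumentError(f"sample sizes must be even, got {n}")
    points = [{"label": int(n), "n_samples": int(n)} for n in config.values]
    spec = config.resolved_pipeline()
    return _run_points(
        config,
        points,
        lambda pt, run: generate_discriminable(
            pt["n_samples"],
            derive_seed(config.seed, "data", pt["label"], run),
            n_features=config.n_features,
        ),
        lambda pt: spec,
    )


_RUNNERS = {
    "sample_size": run_sample_size_sweep,
    "n_features": run_feature_count_sweep,
    "grid_size": run_grid_size_sweep,
    "n_folds": run_folds_sweep,
    "ratio": run_ratio_sweep,
    "discriminable_sample_size": run_discriminable_sweep,
}


def run_sweep(config: ExperimentConfig) -> SweepResult:
    """Dispatch on ``config.variable``."""
    return _RUNNERS[config.variable](config)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_ALL_SCHEMES = ("split", "kfold", "nested", "fs_out", "tune_out")
_RATIOS = (1 / 3, 1 / 2, 1, 2, 3, 10, 20)
# caption range 14..446 (the body text says 42; the caption is followed here)
_RATIO_NS = (14, 42, 90, 150, 222, 300, 446)

PRESETS: dict[str, dict[str, Any]] = {
    # five-scheme sample-size sweeps, N = 20, 40, ... 1000
    "fig3-svm": dict(
        variable="sample_size",
        values=tuple(range(20, 1001, 20)),
        schemes=_ALL_SCHEMES,
        pipeline="svm",
        runs_per_point=50,
    ),
    "fig3-logreg": dict(
        variable="sample_size",
        values=tuple(range(20, 1001, 20)),
        schemes=_ALL_SCHEMES,
        pipeline="logreg",
        runs_per_point=50,
    ),
    "fig3-quick": dict(
        variable="sample_size",
        values=(20, 60, 100),
        schemes=_ALL_SCHEMES,
        pipeline="logreg",
        runs_per_point=10,
    ),
    # feature-count sweeps at N = 100
    "fig4a-svm": dict(
        variable="n_features",
        values=tuple(range(20, 201, 20)),
        schemes=("kfold",),
        pipeline="svm",
        runs_per_point=50,
    ),
    "fig5a-logreg": dict(
        variable="n_features",
        values=tuple(range(20, 201, 20)),
        schemes=("kfold",),
        pipeline="logreg",
        runs_per_point=50,
    ),
    "featcount-quick": dict(
        variable="n_features",
        values=(20, 60, 100),
        schemes=("kfold",),
        pipeline="logreg",
        runs_per_point=8,
        n_samples=40,
    ),
    # grid-size sweeps at N = 100
    "fig4b-svm": dict(
        variable="grid_size",
        values=tuple(range(2, 21)),
        schemes=("kfold",),
        pipeline="svm",
        runs_per_point=50,
    ),
    "fig5b-logreg": dict(
        variable="grid_size",
        values=(2, 25, 50, 100, 150, 200),
        schemes=("kfold",),
        pipeline="logreg",
        runs_per_point=50,
    ),
    "gridsize-quick": dict(
        variable="grid_size",
        values=(2, 6),
        schemes=("kfold",),
        pipeline="logreg",
        runs_per_point=8,
        n_samples=40,
    ),
    # tuning-fold sweeps at N = 100 (leave-one-out = 100)
    "fig4c-svm": dict(
        variable="n_folds",
        values=(2, 5, 10, 20, 40, 60, 80, 100),
        schemes=("kfold",),
        pipeline="svm",
        runs_per_point=50,
    ),
    "fig5c-logreg": dict(
        variable="n_folds",
        values=(2, 5, 10, 20, 40, 60, 80, 100),
        schemes=("kfold",),
        pipeline="logreg",
        runs_per_point=50,
    ),
    "folds-quick": dict(
        variable="n_folds",
        values=(2, 10),
        schemes=("kfold",),
        pipeline="logreg",
        runs_per_point=8,
        n_samples=40,
    ),
    # feature-to-sample ratios
    "fig6-svm": dict(
        variable="ratio",
        values=tuple((r, n) for r in _RATIOS for n in _RATIO_NS),
        schemes=("kfold",),
        pipeline="svm",
        runs_per_point=50,
    ),
    "fig6-logreg": dict(
        variable="ratio",
        values=tuple((r, n) for r in _RATIOS for n in _RATIO_NS),
        schemes=("kfold",),
        pipeline="logreg",
        runs_per_point=50,
    ),
    "ratio-quick": dict(
        variable="ratio",
        values=((1 / 3, 42), (1, 42), (3, 42)),
        schemes=("kfold",),
        pipeline="logreg",
        runs_per_point=8,
    ),
    # discriminable data
    "fig7-svm": dict(
        variable="discriminable_sample_size",
        values=tuple(range(20, 1001, 20)),
        schemes=("kfold", "nested", "split"),
        pipeline="svm",
        runs_per_point=50,
    ),
    "discriminable-quick": dict(
        variable="discriminable_sample_size",
        values=(40, 100),
        schemes=("kfold", "split"),
        pipeline="logreg",
        runs_per_point=5,
    ),
}


def experiment_preset(name: str, seed: int = 0, **overrides: Any) -> ExperimentConfig:
    """Instantiate a named preset, optionally overriding any field."""
    if name not in PRESETS:
        raise InvalidArgumentError(
            f"unknown experiment preset {name!r}; expected one of {sorted(PRESETS)}"
        )
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return ExperimentConfig(seed=seed, **kwargs)
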