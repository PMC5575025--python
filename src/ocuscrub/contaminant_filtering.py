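"""Negative-control regression filtering of low-biomass OTU tables.

The filter removes reagent/handling contaminants from an OTU count table in
nine ordered steps:

(a) drop samples sequenced below a minimum depth (default 10,000 reads);
(b) convert counts to within-sample relative abundances;
(c) weight each sample's relative abundances by its relative PCR band
    luminosity, a surrogate for target DNA concentration;
(d) average the weighted relative abundances per OTU within each of the
    three sample types (subject, blank-swab control, water control);
(e) drop OTUs whose share of the summed subject-sample means falls below a
    rare-OTU threshold (default 0.0001%);
(f) regress log subject-sample means on log blank-control means across
    OTUs (ordinary least squares, natural logs, with a pseudocount for
    zeros);
(g) retain the OTUs whose subject abundance exceeds the regression
    prediction by more than ``se_multiplier`` prediction standard errors —
    equivalently, by more than the factor exp(m * SE(x)) on the abundance
    scale;
(h) refit the blank-control regression from scratch on the retained OTUs
    and apply the same outlier rule again;
(i) run one further pass with the water-control means as the predictor.

The rationale: a reagent contaminant enters every reaction at a fixed
absolute amount, so its abundance in negative controls predicts its
abundance in subject samples; an OTU genuinely resident in the subjects
sits far above that prediction.  The threshold uses the per-point standard
error of the fitted value, se(x) = sigma_hat * sqrt(1/n + (x - x_bar)^2 / Sxx)
(what ``predict.lm(..., se.fit=TRUE)`` reports as the prediction standard
error), so the retention band tracks the uncertainty of the regression line
itself.  The scalar residual standard error sigma_hat = sqrt(RSS / (n - 2))
is exposed on every fit.

Every step logs its sample/OTU attrition into a :class:`FilterReport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import (
    BLANK_CONTROL,
    SAMPLE_TYPES,
    SUBJECT,
    WATER_CONTROL,
    CountTable,
    LuminosityTable,
    SampleMetadata,
    ValidationError,
    validate_experiment,
)

__all__ = [
    "FilterConfig",
    "FilterError",
    "RegressionFit",
    "FilterStep",
    "FilterReport",
    "PipelineResult",
    "filter_samples_by_depth",
    "to_relative",
    "relative_luminosity",
    "weight_by_luminosity",
    "sample_type_means",
    "remove_rare_otus",
    "default_pseudocount",
    "fit_control_regression",
    "regression_retain",
    "run_contaminant_pipeline",
]

LUMINOSITY_PROPORTIONAL = "proportional"
LUMINOSITY_LITERAL = "literal"


class FilterError(ValueError):
    """A pipeline stage cannot proceed (annotated with its step letter)."""


@dataclass(frozen=True)
class FilterConfig:
    """Tunable thresholds of the contaminant filter.

    ``min_depth`` and ``rare_fraction`` use strict "less than" removal, so a
    sample at exactly ``min_depth`` reads and an OTU at exactly the rare
    threshold are both retained.  ``rare_fraction`` is a proportion
    (1e-6 == 0.0001%).  All logs are natural.

    ``luminosity_mode`` selects how band luminosity L maps to a weight:
    ``"proportional"`` (default) uses L / L_max so the brightest band —
    the highest-biomass sample — carries full weight; ``"literal"`` uses
    (L_max - L) / L_max, which inverts the weighting and is provided only
    for comparison (see the methods note).
    """

    min_depth: int = 10_000
    rare_fraction: float = 1e-6
    se_multiplier: float = 5.0
    luminosity_mode: str = LUMINOSITY_PROPORTIONAL

    def validate(self) -> None:
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")
        if not (0.0 < self.rare_fraction < 1.0):
            raise ValidationError("rare_fraction must lie in (0, 1)")
        if self.se_multiplier <= 0:
            raise ValidationError("se_multiplier must be positive")
        if self.luminosity_mode not in (LUMINOSITY_PROPORTIONAL, LUMINOSITY_LITERAL):
            raise ValidationError(
                f"luminosity_mode must be {LUMINOSITY_PROPORTIONAL!r} or {LUMINOSITY_LITERAL!r}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "FilterConfig":
        known = {"min_depth", "rare_fraction", "se_multiplier", "luminosity_mode"}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown filter config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Steps (a)-(e)


def filter_samples_by_depth(counts: CountTable, min_depth: int) -> CountTable:
    """Step (a): drop samples with fewer than ``min_depth`` total reads."""
    totals = counts.sample_totals()
    keep = totals.index[totals >= min_depth]
    if len(keep) == 0:
        raise FilterError(
            f"step (a): every sample has fewer than {min_depth} reads; nothing to analyse"
        )
    return CountTable(counts.data.loc[keep])


def to_relative(counts: CountTable) -> pd.DataFrame:
    """Step (b): within-sample relative abundances (rows sum to one)."""
    totals = counts.sample_totals()
    if (totals == 0).any():
        sid = totals.index[totals == 0][0]
        raise FilterError(f"step (b): sample {sid!r} has zero total count")
    return counts.data.div(totals, axis=0)


def relative_luminosity(
    luminosity: LuminosityTable | pd.Series,
    mode: str = LUMINOSITY_PROPORTIONAL,
) -> pd.Series:
    """Step (c) weights: per-sample relative band luminosity in [0, 1].

    ``proportional`` returns L / L_max (brightest sample -> 1); ``literal``
    returns (L_max - L) / L_max (brightest sample -> 0).
    """
    values = luminosity.values if isinstance(luminosity, LuminosityTable) else luminosity.astype(float)
    l_max = values.max()
    if not l_max > 0:
        raise FilterError("step (c): all luminosities are zero; weights undefined")
    if mode == LUMINOSITY_PROPORTIONAL:
        weights = values / l_max
    elif mode == LUMINOSITY_LITERAL:
        weights = (l_max - values) / l_max
    else:
        raise ValidationError(f"unknown luminosity mode {mode!r}")
    weights.name = "relative_luminosity"
    return weights


def weight_by_luminosity(rel: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    """Step (c): multiply each sample's relative abundances by its weight.

    Samples with weight zero become all-zero rows; they stay in the table
    (and are flagged at the pipeline level) rather than being dropped.
    """
    missing = [sid for sid in rel.index if sid not in weights.index]
    if missing:
        raise FilterError(f"step (c): no luminosity weight for samples {missing[:5]}")
    return rel.mul(weights.reindex(rel.index), axis=0)


def sample_type_means(weighted: pd.DataFrame, metadata: SampleMetadata) -> pd.DataFrame:
    """Step (d): per-OTU mean weighted relative abundance per sample type.

    Means are arithmetic over all samples of the type, zeros included.
    Returns a DataFrame indexed by OTU (sorted) with one column per sample
    type.  Raises if any of the three types has no samples in ``weighted``.
    """
    table_ids = set(weighted.index)
    means = {}
    for stype in SAMPLE_TYPES:
        ids = sorted(s for s in metadata.samples_of_type(stype) if s in table_ids)
        if not ids:
            raise FilterError(
                f"step (d): no {stype} samples remain; cannot compute sample-type means"
            )
        means[stype] = weighted.loc[ids].mean(axis=0)
    out = pd.DataFrame(means)
    return out.sort_index()


def remove_rare_otus(subject_means: pd.Series, rare_fraction: float) -> pd.Index:
    """Step (e): retain OTUs holding at least ``rare_fraction`` of the total.

    The basis is each OTU's share of the *summed subject-sample* mean
    weighted relative abundances; removal is strict ("less than"), so a
    share exactly at the threshold is retained.
    """
    total = subject_means.sum()
    if not total > 0:
        raise FilterError("step (e): subject-sample means are all zero")
    share = subject_means / total
    retained = subject_means.index[share >= rare_fraction]
    if len(retained) == 0:
        raise FilterError("step (e): the rare-OTU filter removed every OTU")
    return retained


# ---------------------------------------------------------------------------
# Regression passes (f)-(i)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of log subject means on log control means across OTUs.

    ``residual_se`` is sqrt(RSS / (n - 2)).  ``x_mean`` and ``x_ss`` (the
    centred sum of squares of the predictor) allow the per-point standard
    error of the fitted value to be reconstructed:
    se(x) = residual_se * sqrt(1/n + (x - x_mean)^2 / x_ss).
    """

    slope: float
    intercept: float
    residual_se: float
    n_points: int
    x_mean: float
    x_ss: float
    pseudocount: float
    predictor_label: str

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError("regression requires at least 3 OTUs")
        if self.residual_se < 0:
            raise ValidationError("residual_se must be non-negative")

    def predict(self, x: np.ndarray | float):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def fit_standard_error(self, x: np.ndarray | float):
        """Standard error of the fitted mean at predictor value(s) ``x``."""
        x = np.asarray(x, dtype=float)
        leverage = 1.0 / self.n_points + (x - self.x_mean) ** 2 / self.x_ss
        return self.residual_se * np.sqrt(leverage)


def default_pseudocount(values: Iterable[float]) -> float:
    """Half the smallest non-zero value among ``values``.

    Used to take logs of tables containing zeros: applied to both axes of
    the regression, it keeps OTUs absent from the controls as extreme
    positive residuals (retainable) instead of undefined points.
    """
    arr = np.asarray(list(values), dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise FilterError("cannot derive a pseudocount: all abundances are zero")
    return float(positive.min() / 2.0)


def _aligned_log_xy(
    subject_means: pd.Series,
    control_means: pd.Series,
    otu_set: Iterable[str],
    pseudocount: float | None,
) -> tuple[np.ndarray, np.ndarray, list[str], float]:
    otus = sorted(set(otu_set))
    missing = [o for o in otus if o not in subject_means.index or o not in control_means.index]
    if missing:
        raise FilterError(f"OTUs missing from the means tables: {missing[:5]}")
    y_raw = subject_means.loc[otus].to_numpy(dtype=float)
    x_raw = control_means.loc[otus].to_numpy(dtype=float)
    if pseudocount is None:
        pseudocount = default_pseudocount(np.concatenate([y_raw, x_raw]))
    return np.log(x_raw + pseudocount), np.log(y_raw + pseudocount), otus, pseudocount


def fit_control_regression(
    subject_means: pd.Series,
    control_means: pd.Series,
    otu_set: Iterable[str],
    pseudocount: float | None = None,
    predictor_label: str = BLANK_CONTROL,
) -> RegressionFit:
    """Steps (f)/(h)/(i): OLS of log subject means on log control means.

    ``otu_set`` selects the OTUs entering the fit (at least three).  When
    ``pseudocount`` is None it defaults to half the smallest non-zero mean
    among the values being regressed, freshly computed for this fit.
    """
    otus = sorted(set(otu_set))
    if len(otus) < 3:
        raise FilterError(f"regression requires at least 3 OTUs, got {len(otus)}")
    x, y, otus, eps = _aligned_log_xy(subject_means, control_means, otus, pseudocount)
    x_mean = float(x.mean())
    x_ss = float(((x - x_mean) ** 2).sum())
    if x_ss <= 0 or not np.isfinite(x_ss):
        raise FilterError(
            "regression undefined: zero predictor variance (all control means identical)"
        )
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    rss = float(((y - (intercept + slope * x)) ** 2).sum())
    residual_se = math.sqrt(max(rss, 0.0) / (len(otus) - 2))
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        residual_se=residual_se,
        n_points=len(otus),
        x_mean=x_mean,
        x_ss=x_ss,
        pseudocount=eps,
        predictor_label=predictor_label,
    )


def regression_retain(
    fit: RegressionFit,
    subject_means: pd.Series,
    control_means: pd.Series,
    otu_set: Iterable[str],
    se_multiplier: float,
) -> list[str]:
    """Steps (g)/(h)/(i): keep OTUs in excess abundance over the prediction.

    An OTU is retained iff its log subject mean exceeds the regression
    prediction by strictly more than ``se_multiplier`` times the prediction
    standard error at its predictor value — on the abundance scale, iff the
    subject mean exceeds the predicted abundance by more than the factor
    exp(se_multiplier * se(x)).  Returns the retained OTU ids, sorted.
    """
    x, y, otus, _ = _aligned_log_xy(subject_means, control_means, otu_set, fit.pseudocount)
    residuals = y - fit.predict(x)
    threshold = se_multiplier * fit.fit_standard_error(x)
    return [otu for otu, r, t in zip(otus, residuals, threshold) if r > t]


# ---------------------------------------------------------------------------
# Report


@dataclass(frozen=True)
class FilterStep:
    """Attrition record for one pipeline step."""

    step: str
    description: str
    n_samples_removed: int
    n_samples_retained: int
    n_otus_removed: int
    n_otus_retained: int
    fit: RegressionFit | None = None
    threshold_factor: float | None = None
    notes: tuple[str, ...] = ()


@dataclass
class FilterReport:
    """Per-step ledger of samples and OTUs removed/retained.

    ``threshold_factor`` on regression steps is the multiplicative retention
    margin exp(se_multiplier * se(x_bar)) evaluated at the predictor mean,
    where the prediction standard error is smallest.
    """

    steps: list[FilterStep] = field(default_factory=list)

    def add(self, step: FilterStep) -> None:
        self.steps.append(step)

    def otu_counts(self) -> list[int]:
        return [s.n_otus_retained for s in self.steps]

    def otu_counts_monotone(self) -> bool:
        counts = self.otu_counts()
        return all(b <= a for a, b in zip(counts, counts[1:]))

    @property
    def final_otus_retained(self) -> int:
        return self.steps[-1].n_otus_retained if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            rows.append(
                {
                    "step": s.step,
                    "description": s.description,
                    "samples_removed": s.n_samples_removed,
                    "samples_retained": s.n_samples_retained,
                    "otus_removed": s.n_otus_removed,
                    "otus_retained": s.n_otus_retained,
                    "slope": s.fit.slope if s.fit else np.nan,
                    "intercept": s.fit.intercept if s.fit else np.nan,
                    "residual_se": s.fit.residual_se if s.fit else np.nan,
                    "n_regression_points": s.fit.n_points if s.fit else np.nan,
                    "threshold_factor": s.threshold_factor if s.threshold_factor else np.nan,
                    "notes": "; ".join(s.notes),
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["contaminant filter report", "========================="]
        for s in self.steps:
            lines.append(
                f"({s.step}) {s.description}: removed {s.n_samples_removed} samples, "
                f"{s.n_otus_removed} OTUs -> {s.n_samples_retained} samples, "
                f"{s.n_otus_retained} OTUs retained"
            )
            if s.fit is not None:
                lines.append(
                    f"      regression on {s.fit.predictor_label}: slope={s.fit.slope:.4f}, "
                    f"intercept={s.fit.intercept:.4f}, residual SE={s.fit.residual_se:.4f}, "
                    f"n={s.fit.n_points}, retention factor at the predictor mean="
                    f"{s.threshold_factor:.4f}"
                )
            for note in s.notes:
                lines.append(f"      note: {note}")
        return "\n".join(lines)


@dataclass
class PipelineResult:
    """Final retained OTU set, filtered table and per-step report."""

    retained_otus: tuple[str, ...]
    report: FilterReport
    filtered_counts: CountTable | None
    weights: pd.Series
    means: pd.DataFrame


# ---------------------------------------------------------------------------
# Full pipeline


def _regression_pass(
    step: str,
    description: str,
    subject_means: pd.Series,
    control_means: pd.Series,
    retained: list[str],
    config: FilterConfig,
    predictor_label: str,
    report: FilterReport,
    n_samples: int,
    fit_step: str | None = None,
) -> list[str]:
    """Run one fit+retain pass, logging attrition; returns the survivors.

    ``fit_step`` optionally logs the fit itself as a separate (no-attrition)
    record, used for the first pass where fitting and retention carry
    distinct step letters.
    """
    def _skip(notes: tuple[str, ...]) -> None:
        if fit_step is not None:
            report.add(FilterStep(fit_step, description + " (fit)", 0, n_samples,
                                  0, len(retained), notes=notes))
        report.add(FilterStep(step, description, 0, n_samples, 0, len(retained),
                              notes=notes))

    if len(retained) == 0:
        _skip(("skipped: no OTUs left",))
        return retained
    if len(retained) < 3:
        _skip((f"skipped: only {len(retained)} OTUs, regression needs 3",))
        return retained
    try:
        fit = fit_control_regression(
            subject_means, control_means, retained, predictor_label=predictor_label
        )
    except FilterError as exc:
        raise FilterError(f"step ({fit_step or step}): {exc}") from exc
    survivors = regression_retain(
        fit, subject_means, control_means, retained, config.se_multiplier
    )
    factor = float(
        np.exp(config.se_multiplier * fit.residual_se / math.sqrt(fit.n_points))
    )
    if fit_step is not None:
        report.add(
            FilterStep(fit_step, description + " (fit)", 0, n_samples,
                       0, len(retained), fit=fit, threshold_factor=factor)
        )
    report.add(
        FilterStep(
            step,
            description,
            0,
            n_samples,
            len(retained) - len(survivors),
            len(survivors),
            fit=fit,
            threshold_factor=factor,
        )
    )
    return survivors


def run_contaminant_pipeline(
    counts: CountTable,
    metadata: SampleMetadata,
    luminosity: LuminosityTable,
    config: FilterConfig | None = None,
) -> PipelineResult:
    """Run the full nine-step contaminant filter on a validated experiment.

    The input tables are canonicalised (sorted sample and OTU axes) first,
    so the result is invariant to the ordering of the input files.  Errors
    raised by a stage are annotated with the step letter.  An empty final
    set is a legitimate outcome (the report shows where attrition reached
    zero); it is not an error.
    """
    config = config or FilterConfig()
    config.validate()
    validate_experiment(counts, metadata, luminosity).raise_if_errors()

    counts = counts.sorted()
    n_otus_in = counts.n_otus
    report = FilterReport()

    # (a) depth filter
    deep = filter_samples_by_depth(counts, config.min_depth)
    removed_samples = counts.n_samples - deep.n_samples
    report.add(
        FilterStep(
            "a",
            f"remove samples with fewer than {config.min_depth} reads",
            removed_samples,
            deep.n_samples,
            0,
            n_otus_in,
        )
    )
    for stype in SAMPLE_TYPES:
        if not any(s in deep.data.index for s in metadata.samples_of_type(stype)):
            raise FilterError(
                f"step (a): the depth filter removed every {stype} sample; "
                "later steps cannot run"
            )

    # (b) relative abundances
    rel = to_relative(deep)
    report.add(
        FilterStep("b", "convert counts to within-sample relative abundances",
                   0, deep.n_samples, 0, n_otus_in)
    )

    # (c) luminosity weighting
    lum = luminosity.values.reindex(deep.data.index)
    missing = list(lum.index[lum.isna()])
    if missing:
        raise FilterError(f"step (c): no luminosity for samples {missing[:5]}")
    weights = relative_luminosity(lum, mode=config.luminosity_mode)
    weighted = weight_by_luminosity(rel, weights)
    zero_weight = tuple(weights.index[weights == 0])
    notes = (
        (f"samples with zero weight (all-zero rows retained): {list(zero_weight)}",)
        if zero_weight
        else ()
    )
    report.add(
        FilterStep("c", f"weight by relative band luminosity ({config.luminosity_mode})",
                   0, deep.n_samples, 0, n_otus_in, notes=notes)
    )

    # (d) sample-type means
    try:
        means = sample_type_means(weighted, metadata)
    except FilterError as exc:
        raise FilterError(str(exc)) from exc
    report.add(
        FilterStep("d", "mean weighted relative abundance per sample type",
                   0, deep.n_samples, 0, n_otus_in)
    )

    # (e) rare-OTU removal
    retained_idx = remove_rare_otus(means[SUBJECT], config.rare_fraction)
    retained = sorted(retained_idx)
    report.add(
        FilterStep(
            "e",
            f"remove OTUs below {config.rare_fraction:g} of total subject abundance",
            0,
            deep.n_samples,
            n_otus_in - len(retained),
            len(retained),
        )
    )

    # (f)-(g) blank-swab regression, first pass
    retained = _regression_pass(
        "g", "blank-control regression, first pass",
        means[SUBJECT], means[BLANK_CONTROL], retained, config,
        BLANK_CONTROL, report, deep.n_samples, fit_step="f",
    )
    # (h) blank-swab regression, second pass (fresh fit on the survivors)
    retained = _regression_pass(
        "h", "blank-control regression, second pass",
        means[SUBJECT], means[BLANK_CONTROL], retained, config,
        BLANK_CONTROL, report, deep.n_samples,
    )
    # (i) water-control regression pass
    retained = _regression_pass(
        "i", "water-control regression pass",
        means[SUBJECT], means[WATER_CONTROL], retained, config,
        WATER_CONTROL, report, deep.n_samples,
    )

    filtered = CountTable(deep.data.loc[:, retained]) if retained else None
    return PipelineResult(
        retained_otus=tuple(retained),
        report=report,
        filtered_counts=filtered,
        weights=weights,
        means=means,
    )
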