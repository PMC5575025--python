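"""Alpha/beta diversity, rarefaction and temporal-stability summaries.

Covers the community statistics of the downstream analysis: per-sample
richness and Shannon index (natural logs), pairwise Bray-Curtis
dissimilarity on relative abundances, Monte-Carlo rarefaction curves
(subsampling reads without replacement), and per-taxon coefficients of
variation of relative abundance across time points.  Results are plain
pandas objects, exported as TSV by the CLI so that mixed-model or
PERMANOVA-style testing can happen in external tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import distance
from scipy.stats import entropy

from .io_tables import (
    SUBJECT,
    CountTable,
    SampleMetadata,
    ValidationError,
)

__all__ = [
    "richness",
    "shannon",
    "alpha_diversity_table",
    "bray_curtis_pair",
    "bray_curtis",
    "rarefaction_curve",
    "time_point_mean_relative_abundance",
    "temporal_cv",
]


def _as_frame(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    return counts.data if isinstance(counts, CountTable) else counts


def richness(counts: CountTable | pd.DataFrame) -> pd.Series:
    """Number of OTUs with at least one read, per sample."""
    df = _as_frame(counts)
    out = (df >= 1).sum(axis=1)
    out.name = "richness"
    return out


def shannon(counts: CountTable | pd.DataFrame, base: float | None = None) -> pd.Series:
    """Shannon index H = -sum p_i log p_i per sample (natural log default)."""
    df = _as_frame(counts)
    totals = df.sum(axis=1)
    if (totals <= 0).any():
        sid = totals.index[totals <= 0][0]
        raise ValidationError(f"sample {sid!r} has zero total count; Shannon undefined")
    values = np.array([entropy(row, base=base) for row in df.to_numpy(dtype=float)])
    return pd.Series(values, index=df.index, name="shannon")


def alpha_diversity_table(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness and Shannon index as one table."""
    return pd.DataFrame({"richness": richness(counts), "shannon": shannon(counts)})


def bray_curtis_pair(u, v) -> float:
    """Bray-Curtis dissimilarity between two count/abundance vectors.

    Computed on relative abundances: BC = sum|p_i - q_i| / sum(p_i + q_i).
    0 for identical compositions, 1 for disjoint support.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.sum() <= 0 or v.sum() <= 0:
        raise ValidationError("Bray-Curtis undefined for a zero-total sample")
    return float(distance.braycurtis(u / u.sum(), v / v.sum()))


def bray_curtis(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Full symmetric Bray-Curtis matrix across samples (zero diagonal)."""
    df = _as_frame(counts)
    totals = df.sum(axis=1)
    if (totals <= 0).any():
        sid = totals.index[totals <= 0][0]
        raise ValidationError(f"sample {sid!r} has zero total count; Bray-Curtis undefined")
    rel = df.div(totals, axis=0).to_numpy(dtype=float)
    mat = distance.squareform(distance.pdist(rel, metric="braycurtis"))
    return pd.DataFrame(mat, index=df.index, columns=df.index)


def rarefaction_curve(
    sample_counts,
    depths,
    n_reps: int = 100,
    seed: int | None = None,
) -> pd.Series:
    """Expected richness under subsampling without replacement.

    For each depth in ``depths``, reads are drawn without replacement from
    the sample (a multivariate hypergeometric draw) ``n_reps`` times and the
    mean number of OTUs observed is reported.  Deterministic under a fixed
    ``seed``; a depth equal to the sample total returns the observed
    richness exactly.
    """
    vec = np.asarray(
        sample_counts.to_numpy() if isinstance(sample_counts, pd.Series) else sample_counts
    )
    if vec.ndim != 1:
        raise ValidationError("rarefaction expects a single sample vector")
    if np.any(vec < 0) or np.any(vec != np.floor(vec)):
        raise ValidationError("rarefaction requires non-negative integer counts")
    vec = vec.astype(np.int64)
    total = int(vec.sum())
    if total == 0:
        raise ValidationError("rarefaction undefined for an empty sample")
    depths = [int(d) for d in depths]
    for d in depths:
        if d < 1 or d > total:
            raise ValidationError(f"rarefaction depth {d} outside [1, {total}]")
    rng = np.random.default_rng(seed)
    means = {}
    for d in depths:
        draws = rng.multivariate_hypergeometric(vec, d, size=n_reps)
        means[d] = float((draws > 0).sum(axis=1).mean())
    out = pd.Series(means, name="expected_richness")
    out.index.name = "depth"
    return out


def time_point_mean_relative_abundance(
    counts: CountTable,
    metadata: SampleMetadata,
) -> pd.DataFrame:
    """Per-taxon mean relative abundance within each time point.

    Averages within-sample relative abundances over the subject samples of
    each time point (zeros included).  Returns taxa x time points; a time
    point with no samples yields a column of NaN.
    """
    df = counts.data
    subject_ids = [s for s in metadata.samples_of_type(SUBJECT) if s in set(counts.sample_ids)]
    if not subject_ids:
        raise ValidationError("no subject samples shared between counts and metadata")
    totals = df.loc[subject_ids].sum(axis=1)
    if (totals <= 0).any():
        sid = totals.index[totals <= 0][0]
        raise ValidationError(f"sample {sid!r} has zero total count")
    rel = df.loc[subject_ids].div(totals, axis=0)
    out = {}
    for time in metadata.time_points:
        ids = [s for s in subject_ids if metadata.subject_and_time(s)[1] == time]
        out[time] = rel.loc[ids].mean(axis=0) if ids else pd.Series(np.nan, index=df.columns)
    result = pd.DataFrame(out)
    result.index.name = "taxon_id"
    return result


def temporal_cv(per_time_means: pd.DataFrame) -> pd.Series:
    """Coefficient of variation of each taxon's abundance across time.

    CV = sample standard deviation (n-1 denominator) divided by the mean of
    the per-time values.  Taxa with fewer than two non-missing time points
    or a non-positive mean are reported as missing (NaN).
    """
    values = per_time_means.to_numpy(dtype=float)
    out = np.full(values.shape[0], np.nan)
    for i, row in enumerate(values):
        obs = row[~np.isnan(row)]
        if obs.size < 2:
            continue
        mean = obs.mean()
        if mean <= 0:
            continue
        out[i] = obs.std(ddof=1) / mean
    result = pd.Series(out, index=per_time_means.index, name="cv_over_time")
    return result
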