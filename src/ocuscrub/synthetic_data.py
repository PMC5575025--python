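"""Synthetic low-biomass amplicon experiments with known contamination.

The generator emulates a longitudinal conjunctival swab study: ~45 subjects
sampled at three time points, a handful of blank-swab and nuclease-free
water negative controls, sequencing depths of roughly 55k +/- 29k reads, and
10-40 resident OTUs per sample riding on top of a pool of reagent
contaminants.

The contamination model is the one under which negative-control regression
filtering is coherent:

* every *resident* (true) OTU's absolute abundance in a subject sample
  scales with that sample's target biomass (per-sample log-normal), with a
  per-subject stable core of OTUs present at every time point and the rest
  appearing sporadically;
* every *contaminant* OTU contributes a fixed absolute spike — its reagent
  concentration — shared by all samples including the controls, independent
  of sample biomass.  Relative contaminant abundance is therefore inversely
  related to biomass, which is exactly what makes control abundance a linear
  predictor of subject abundance on the log scale;
* negative controls carry only a small fraction of the mean subject target
  biomass (carry-over), so contaminant reads dominate them;
* observed counts are a multinomial draw of each sample's combined relative
  abundances at its sequencing depth, and PCR band luminosity is the
  sample's total target biomass up to multiplicative log-normal noise.

Ground truth (resident vs contaminant OTUs, per-subject core membership) is
returned alongside the tables so that filter performance can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import (
    BLANK_CONTROL,
    DEFAULT_TIME_POINTS,
    RANKS,
    SUBJECT,
    UNCLASSIFIED,
    WATER_CONTROL,
    CountTable,
    LuminosityTable,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
    read_count_table,
    read_luminosity,
    read_metadata,
    read_taxonomy,
    write_count_table,
    write_luminosity,
    write_metadata,
    write_taxonomy,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulationBundle",
    "ConfusionSummary",
    "generate_experiment",
    "truth_confusion",
    "write_bundle",
    "read_bundle",
]


# Lineages for recognisable genera reported from the ocular surface and its
# surroundings; assigned round-robin so taxon-level collapsing is testable.
_LINEAGES: tuple[tuple[str, ...], ...] = (
    ("Actinobacteria", "Actinomycetia", "Corynebacteriales", "Corynebacteriaceae", "Corynebacterium"),
    ("Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Acinetobacter"),
    ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"),
    ("Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    ("Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Oxalobacteraceae", "Massilia"),
    ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Rothia"),
    ("Firmicutes", "Clostridia", "Tissierellales", "Peptoniphilaceae", "Anaerococcus"),
    ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Micrococcus"),
    ("Actinobacteria", "Actinomycetia", "Propionibacteriales", "Propionibacteriaceae", "Propionibacterium"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Klebsiella"),
)


@dataclass
class SimulationConfig:
    """Study design and noise parameters of the synthetic experiment.

    Defaults mirror the emulated study: 45 subjects x 3 time points, nine
    blank-swab and three water controls, depths of 54,652 +/- 28,912 reads
    (truncated at 1,000), a 40-OTU resident pool against 150 reagent
    contaminants, and an 8-OTU stable core per subject with sporadic
    presence of the remaining residents.  Biomass and concentration scales
    are in arbitrary units; only ratios matter because counts are drawn
    from relative abundances.
    """

    n_subjects: int = 45
    n_times: int = 3
    n_blank_controls: int = 9
    n_water_controls: int = 3
    n_true_otus: int = 40
    n_contaminant_otus: int = 150
    core_size_per_subject: int = 8
    #: probability that a non-core resident OTU shows up in any given sample
    sporadic_presence: float = 0.3
    subject_biomass_log_mean: float = 0.0
    subject_biomass_log_sd: float = 0.5
    #: control target biomass as a fraction of the mean subject biomass
    control_biomass_fraction: float = 0.01
    contaminant_concentration_log_mean: float = -5.0
    contaminant_concentration_log_sd: float = 1.0
    #: sd of per-reaction log-normal variation around each contaminant's
    #: reagent concentration (lot-to-lot and pipetting variability; blank
    #: studies report order-of-magnitude spread between reactions)
    contaminant_noise_sd: float = 1.5
    depth_mean: float = 54652.0
    depth_sd: float = 28912.0
    min_depth: int = 1000
    #: sd of multiplicative log-normal noise on band luminosity
    luminosity_noise_sd: float = 0.2
    #: sd of per-subject, per-OTU log abundance (between-OTU evenness)
    abundance_log_sd: float = 1.0
    #: sd of the sample-to-sample log-normal wobble of OTU abundances
    temporal_noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_subjects",
            "n_times",
            "n_blank_controls",
            "n_water_controls",
            "n_true_otus",
            "n_contaminant_otus",
            "core_size_per_subject",
            "min_depth",
        ):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a positive count")
        if self.core_size_per_subject > self.n_true_otus:
            raise ValidationError("core_size_per_subject cannot exceed n_true_otus")
        if not (0.0 < self.control_biomass_fraction < 1.0):
            raise ValidationError("control_biomass_fraction must lie in (0, 1)")
        if not (0.0 <= self.sporadic_presence <= 1.0):
            raise ValidationError("sporadic_presence must lie in [0, 1]")
        for name in (
            "subject_biomass_log_sd",
            "contaminant_concentration_log_sd",
            "contaminant_noise_sd",
            "luminosity_noise_sd",
            "abundance_log_sd",
            "temporal_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.depth_mean <= 0 or self.depth_sd <= 0:
            raise ValidationError("depth_mean and depth_sd must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        return cls(**mapping)


@dataclass(eq=False)
class SyntheticTruth:
    """Ground-truth OTU partition and per-subject core membership."""

    true_otu_ids: frozenset[str]
    contaminant_otu_ids: frozenset[str]
    core_membership: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.true_otu_ids & self.contaminant_otu_ids:
            raise ValidationError("true and contaminant OTU sets must be disjoint")
        for subject, core in self.core_membership.items():
            if not core <= self.true_otu_ids:
                raise ValidationError(
                    f"core membership of subject {subject!r} includes non-resident OTUs"
                )

    @property
    def all_otu_ids(self) -> frozenset[str]:
        return self.true_otu_ids | self.contaminant_otu_ids

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return (
            self.true_otu_ids == other.true_otu_ids
            and self.contaminant_otu_ids == other.contaminant_otu_ids
            and self.core_membership == other.core_membership
        )


@dataclass(eq=False)
class SimulationBundle:
    """The five products of one synthetic experiment."""

    counts: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyMap
    luminosity: LuminosityTable
    truth: SyntheticTruth

    def __iter__(self) -> Iterator:
        yield self.counts
        yield self.metadata
        yield self.taxonomy
        yield self.luminosity
        yield self.truth

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationBundle):
            return NotImplemented
        return (
            self.counts == other.counts
            and self.metadata == other.metadata
            and self.taxonomy == other.taxonomy
            and self.luminosity == other.luminosity
            and self.truth == other.truth
        )


def _time_labels(n_times: int) -> tuple[str, ...]:
    if n_times == len(DEFAULT_TIME_POINTS):
        return DEFAULT_TIME_POINTS
    return tuple(f"time{i}" for i in range(n_times))


def generate_experiment(config: SimulationConfig) -> SimulationBundle:
    """Draw one complete synthetic experiment.

    The draw is fully determined by ``config`` (including its ``seed``):
    the same config yields a bit-identical bundle on every call.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_true = config.n_true_otus
    n_cont = config.n_contaminant_otus
    n_otus = n_true + n_cont
    otu_ids = np.array([f"OTU{i + 1:04d}" for i in range(n_otus)])
    true_cols = np.sort(rng.choice(n_otus, size=n_true, replace=False))
    cont_cols = np.setdiff1d(np.arange(n_otus), true_cols)

    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    times = _time_labels(config.n_times)
    subject_sample_ids = [f"{s}_{t}" for s in subjects for t in times]
    blank_ids = [f"BLANK{i + 1:02d}" for i in range(config.n_blank_controls)]
    water_ids = [f"WATER{i + 1:02d}" for i in range(config.n_water_controls)]
    sample_ids = subject_sample_ids + blank_ids + water_ids
    n_sub_samples = len(subject_sample_ids)
    n_controls = len(blank_ids) + len(water_ids)
    n_samples = len(sample_ids)

    # resident community: per-subject OTU propensities, stable core, sporadic rest
    weights = rng.lognormal(0.0, config.abundance_log_sd, (config.n_subjects, n_true))
    core_mask = np.zeros((config.n_subjects, n_true), dtype=bool)
    for s in range(config.n_subjects):
        core_mask[s, rng.choice(n_true, size=config.core_size_per_subject, replace=False)] = True
    sporadic = rng.random((config.n_subjects, config.n_times, n_true)) < config.sporadic_presence
    presence = core_mask[:, None, :] | sporadic

    biomass = rng.lognormal(
        config.subject_biomass_log_mean,
        config.subject_biomass_log_sd,
        (config.n_subjects, config.n_times),
    )
    wobble = rng.lognormal(0.0, config.temporal_noise_sd, (config.n_subjects, config.n_times, n_true))
    abs_true_subject = presence * biomass[:, :, None] * weights[:, None, :] * wobble
    abs_true_subject = abs_true_subject.reshape(n_sub_samples, n_true)

    # carry-over of resident material into negative controls: a small
    # fraction of the mean subject profile, wobbled per control sample
    mean_profile = abs_true_subject.mean(axis=0)
    carry_noise = rng.lognormal(0.0, config.temporal_noise_sd, (n_controls, n_true))
    abs_true_control = config.control_biomass_fraction * mean_profile[None, :] * carry_noise

    # reagent contaminants: one absolute concentration per OTU entering every
    # reaction regardless of its biomass, with per-reaction log-normal
    # variability around that concentration (reagent lots, pipetting)
    concentrations = rng.lognormal(
        config.contaminant_concentration_log_mean,
        config.contaminant_concentration_log_sd,
        n_cont,
    )
    reaction_noise = rng.lognormal(0.0, config.contaminant_noise_sd, (n_samples, n_cont))

    absolute = np.zeros((n_samples, n_otus))
    absolute[:n_sub_samples, true_cols] = abs_true_subject
    absolute[n_sub_samples:, true_cols] = abs_true_control
    absolute[:, cont_cols] = concentrations[None, :] * reaction_noise

    a_lo = (config.min_depth - config.depth_mean) / config.depth_sd
    depths = stats.truncnorm.rvs(
        a_lo, np.inf, loc=config.depth_mean, scale=config.depth_sd,
        size=n_samples, random_state=rng,
    )
    depths = np.maximum(np.round(depths).astype(np.int64), config.min_depth)

    rel = absolute / absolute.sum(axis=1, keepdims=True)
    counts = np.empty((n_samples, n_otus), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(depths[i], rel[i])

    target_biomass = absolute[:, true_cols].sum(axis=1)
    lum_noise = rng.normal(0.0, config.luminosity_noise_sd, n_samples)
    luminosity = target_biomass * np.exp(lum_noise)

    counts_df = pd.DataFrame(counts, index=sample_ids, columns=otu_ids)
    meta_df = pd.DataFrame(
        {
            "sample_type": [SUBJECT] * n_sub_samples
            + [BLANK_CONTROL] * len(blank_ids)
            + [WATER_CONTROL] * len(water_ids),
            "subject_id": [s for s in subjects for _ in times] + [pd.NA] * n_controls,
            "time_point": [t for _ in subjects for t in times] + [pd.NA] * n_controls,
        },
        index=sample_ids,
    )

    lineages = []
    for i in range(n_otus):
        lineage = list(_LINEAGES[i % len(_LINEAGES)])
        if i % 10 == 9:  # leave some OTUs unresolved below family, RDP-style
            lineage[4] = UNCLASSIFIED
        lineages.append(lineage)
    tax_df = pd.DataFrame(lineages, index=otu_ids, columns=list(RANKS))

    truth = SyntheticTruth(
        true_otu_ids=frozenset(otu_ids[true_cols]),
        contaminant_otu_ids=frozenset(otu_ids[cont_cols]),
        core_membership={
            subjects[s]: frozenset(otu_ids[true_cols[core_mask[s]]])
            for s in range(config.n_subjects)
        },
    )

    return SimulationBundle(
        counts=CountTable(counts_df),
        metadata=SampleMetadata(meta_df, times),
        taxonomy=TaxonomyMap(tax_df),
        luminosity=LuminosityTable(pd.Series(luminosity, index=sample_ids)),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Scoring


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion of a retained-OTU set against the simulation truth.

    Positives are resident OTUs; a contaminant that the filter removes is a
    true negative.  ``sensitivity`` is the fraction of residents retained,
    ``specificity`` the fraction of contaminants removed.
    """

    true_positives: int
    false_positives: int
    true_negatives: int
    false_negatives: int

    @property
    def total(self) -> int:
        return (
            self.true_positives
            + self.false_positives
            + self.true_negatives
            + self.false_negatives
        )

    @property
    def sensitivity(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.true_negatives + self.false_positives
        return self.true_negatives / denom if denom else float("nan")


def truth_confusion(retained_otus, truth: SyntheticTruth) -> ConfusionSummary:
    """Score a retained-OTU set against the ground-truth partition."""
    retained = set(retained_otus)
    unknown = retained - truth.all_otu_ids
    if unknown:
        raise ValidationError(f"retained OTUs unknown to truth: {sorted(unknown)[:5]}")
    tp = len(retained & truth.true_otu_ids)
    fp = len(retained & truth.contaminant_otu_ids)
    return ConfusionSummary(
        true_positives=tp,
        false_positives=fp,
        true_negatives=len(truth.contaminant_otu_ids) - fp,
        false_negatives=len(truth.true_otu_ids) - tp,
    )


# ---------------------------------------------------------------------------
# Bundle persistence

_BUNDLE_FILES = (
    "counts.tsv",
    "metadata.tsv",
    "taxonomy.tsv",
    "luminosity.tsv",
    "truth.tsv",
    "core_membership.tsv",
)


def write_bundle(bundle: SimulationBundle, directory, force: bool = False) -> list[Path]:
    """Write all five bundle tables as TSV into ``directory``.

    Refuses to overwrite existing files unless ``force`` is set.  Re-reading
    the directory with :func:`read_bundle` reproduces the bundle exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [directory / name for name in _BUNDLE_FILES]
    if not force:
        existing = [p.name for p in paths if p.exists()]
        if existing:
            raise FileExistsError(
                f"refusing to overwrite {existing} in {directory} (use force=True)"
            )
    write_count_table(bundle.counts, paths[0])
    write_metadata(bundle.metadata, paths[1])
    write_taxonomy(bundle.taxonomy, paths[2])
    write_luminosity(bundle.luminosity, paths[3])
    truth_df = pd.DataFrame(
        {
            "otu_id": bundle.counts.otu_ids,
            "role": [
                "true" if o in bundle.truth.true_otu_ids else "contaminant"
                for o in bundle.counts.otu_ids
            ],
        }
    )
    truth_df.to_csv(paths[4], sep="\t", index=False)
    with paths[5].open("w", encoding="utf-8") as fh:
        fh.write("subject_id\totu_id\n")
        for subject in sorted(bundle.truth.core_membership):
            for otu in sorted(bundle.truth.core_membership[subject]):
                fh.write(f"{subject}\t{otu}\n")
    return paths


def read_bundle(directory) -> SimulationBundle:
    """Re-read a bundle previously written by :func:`write_bundle`."""
    directory = Path(directory)
    counts = read_count_table(directory / "counts.tsv")
    metadata = read_metadata(directory / "metadata.tsv")
    taxonomy = read_taxonomy(directory / "taxonomy.tsv")
    luminosity = read_luminosity(directory / "luminosity.tsv")
    truth_df = pd.read_csv(directory / "truth.tsv", sep="\t", dtype=str)
    core_df = pd.read_csv(directory / "core_membership.tsv", sep="\t", dtype=str)
    true_ids = frozenset(truth_df.loc[truth_df["role"] == "true", "otu_id"])
    cont_ids = frozenset(truth_df.loc[truth_df["role"] == "contaminant", "otu_id"])
    membership: dict[str, frozenset[str]] = {
        subject: frozenset(group["otu_id"])
        for subject, group in core_df.groupby("subject_id")
    }
    truth = SyntheticTruth(true_ids, cont_ids, membership)
    return SimulationBundle(counts, metadata, taxonomy, luminosity, truth)
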