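"""Presence/absence and prevalence analysis across subjects and time.

A *core* taxon, in the strict sense used here, is one detected in every
subject at every time point.  Because almost no taxon meets that bar on a
sparse surface, the analysis also reports, per taxon, how many subjects
carried it at all time points and at any time point, and supports relaxed
cores (a fraction of subjects, any-time presence).

Presence is a thresholded reduction of counts (default: at least one read).
A (subject, time) cell with no underlying sample is *missing*, never
``False``; subjects with incomplete sampling are excluded from the
denominators, so a three-visit study with two drop-outs is summarised over
the subjects who completed all visits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import (
    RANKS,
    SUBJECT,
    CountTable,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
)

__all__ = [
    "PresenceTable",
    "CoreSummary",
    "CultureSummary",
    "collapse_taxonomy",
    "presence_table",
    "core_taxa",
    "prevalence_summary",
    "culture_presence_summary",
]


def collapse_taxonomy(counts: CountTable, taxonomy: TaxonomyMap, rank: str) -> CountTable:
    """Sum OTU counts into taxa at ``rank`` (phylum ... genus).

    OTUs unclassified at the rank are pooled into a single ``unclassified``
    taxon.  Total counts per sample are conserved exactly.
    """
    if rank not in RANKS:
        raise ValidationError(f"unknown rank {rank!r} (expected one of {RANKS})")
    missing = [o for o in counts.otu_ids if o not in taxonomy]
    if missing:
        raise ValidationError(f"OTUs missing from taxonomy: {missing[:5]}")
    labels = taxonomy.data.loc[counts.otu_ids, rank]
    collapsed = counts.data.T.groupby(labels).sum().T
    collapsed.columns.name = "taxon_id"
    return CountTable(collapsed)


@dataclass(eq=False)
class PresenceTable:
    """Boolean presence per (taxon, subject, time point).

    ``data`` is indexed by taxon with a (subject, time) MultiIndex on the
    columns, dtype ``boolean``; missing cells (no sample collected) are
    ``pd.NA``.
    """

    data: pd.DataFrame
    time_points: tuple[str, ...]

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    def complete_subjects(self) -> list[str]:
        """Subjects with a sample at every time point (no missing cells)."""
        out = []
        for subject in self.subjects:
            block = self.data[subject]
            if not block.isna().to_numpy().any():
                out.append(subject)
        return out


def presence_table(
    counts: CountTable,
    metadata: SampleMetadata,
    detection_threshold: int = 1,
) -> PresenceTable:
    """Reduce subject-sample counts to presence per (taxon, subject, time).

    A taxon is present in a cell when any sample of that (subject, time)
    reaches ``detection_threshold`` reads (duplicates are OR-combined); a
    cell with no sample is marked missing.
    """
    if detection_threshold < 1:
        raise ValidationError("detection_threshold must be at least 1 read")
    subject_samples = [s for s in metadata.samples_of_type(SUBJECT) if s in set(counts.sample_ids)]
    if not subject_samples:
        raise ValidationError("no subject samples shared between counts and metadata")

    cell_samples: dict[tuple[str, str], list[str]] = {}
    for sid in subject_samples:
        subject, time = metadata.subject_and_time(sid)
        cell_samples.setdefault((subject, time), []).append(sid)

    subjects = [s for s in metadata.subject_ids]
    times = metadata.time_points
    columns = pd.MultiIndex.from_product([subjects, times], names=["subject_id", "time_point"])
    detected = counts.data >= detection_threshold

    data = pd.DataFrame(index=counts.otu_ids, columns=columns, dtype="boolean")
    for subject in subjects:
        for time in times:
            ids = cell_samples.get((subject, time))
            if ids:
                data[(subject, time)] = detected.loc[ids].any(axis=0).to_numpy()
            # else: leave the cell as pd.NA (missing, never False)
    data.index.name = "taxon_id"
    return PresenceTable(data=data, time_points=tuple(times))


def _subject_presence_counts(presence: PresenceTable) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-taxon boolean frames (taxa x complete subjects): all-times, any-time."""
    complete = presence.complete_subjects()
    all_times = pd.DataFrame(index=presence.data.index)
    any_time = pd.DataFrame(index=presence.data.index)
    for subject in complete:
        block = presence.data[subject].astype(bool)
        all_times[subject] = block.all(axis=1)
        any_time[subject] = block.any(axis=1)
    return all_times, any_time, complete


def core_taxa(
    presence: PresenceTable,
    subject_fraction: float = 1.0,
    require_all_times: bool = True,
) -> set[str]:
    """Taxa present in at least ``subject_fraction`` of complete subjects.

    With ``subject_fraction=1`` and ``require_all_times=True`` this is the
    strict core: present in all subjects at all time points.  Subjects with
    missing cells are excluded from the denominator entirely.
    """
    if not (0.0 < subject_fraction <= 1.0):
        raise ValidationError("subject_fraction must lie in (0, 1]")
    all_times, any_time, complete = _subject_presence_counts(presence)
    if not complete:
        raise ValidationError("no subject was sampled at every time point")
    basis = all_times if require_all_times else any_time
    counts = basis.sum(axis=1)
    # integer comparison avoids float-threshold edge cases: need at least
    # ceil(fraction * n) subjects, with a tiny slack against representation error
    needed = math.ceil(subject_fraction * len(complete) - 1e-9)
    return set(counts.index[counts >= needed])


@dataclass
class CoreSummary:
    """Per-taxon prevalence across complete subjects, plus the strict core.

    ``table`` columns: ``n_subjects_all_times`` / ``frac_subjects_all_times``
    (taxon present at every time point) and ``n_subjects_any_time`` /
    ``frac_subjects_any_time`` (present at one or more time points), with
    the number of complete subjects as the denominator for both.
    """

    table: pd.DataFrame
    n_complete_subjects: int
    n_taxa_all_times_any_subject: int
    core: set[str]


def prevalence_summary(presence: PresenceTable) -> CoreSummary:
    """Summarise how consistently each taxon is carried across subjects."""
    all_times, any_time, complete = _subject_presence_counts(presence)
    if not complete:
        raise ValidationError("no subject was sampled at every time point")
    n = len(complete)
    n_all = all_times.sum(axis=1).astype(int)
    n_any = any_time.sum(axis=1).astype(int)
    table = pd.DataFrame(
        {
            "n_subjects_all_times": n_all,
            "frac_subjects_all_times": n_all / n,
            "n_subjects_any_time": n_any,
            "frac_subjects_any_time": n_any / n,
        }
    )
    table.index.name = "taxon_id"
    return CoreSummary(
        table=table,
        n_complete_subjects=n,
        n_taxa_all_times_any_subject=int((n_all >= 1).sum()),
        core=set(table.index[n_all == n]),
    )


@dataclass
class CultureSummary:
    """Per-taxon isolation proportions, overall and per time point."""

    proportions: pd.DataFrame  # taxa x ("overall", *time_points)
    n_samples: pd.Series  # column -> number of samples behind it


def culture_presence_summary(
    presence: pd.DataFrame,
    metadata: SampleMetadata,
) -> CultureSummary:
    """Proportion of samples from which each taxon was isolated.

    ``presence`` is a boolean taxa x samples table of culture results
    (isolated yes/no per plate/sample).  Proportions are reported over all
    samples and within each time point of the subject samples.
    """
    missing = [s for s in presence.columns if s not in set(metadata.sample_ids)]
    if missing:
        raise ValidationError(f"culture samples missing from metadata: {missing[:5]}")
    bool_presence = presence.astype(bool)
    out = pd.DataFrame(index=presence.index)
    n_samples = {}
    out["overall"] = bool_presence.mean(axis=1)
    n_samples["overall"] = presence.shape[1]
    for time in metadata.time_points:
        ids = [
            s
            for s in presence.columns
            if metadata.sample_type(s) == SUBJECT and metadata.subject_and_time(s)[1] == time
        ]
        out[time] = bool_presence[ids].mean(axis=1) if ids else np.nan
        n_samples[time] = len(ids)
    out.index.name = "taxon_id"
    return CultureSummary(proportions=out, n_samples=pd.Series(n_samples))
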