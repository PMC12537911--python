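"""Clone identity, cross-sample merging, corrected frequencies and state composition.

A clone is keyed by its TCRbeta (V, D, J, CDR3 nucleotide) rearrangement in
bulk data and by the CDR3beta nucleotide sequence alone in single-cell
data.  Bulk samples from one subject are merged into a :class:`CloneSet`;
read counts are aliquot-corrected, pooled frequencies and four-state
exhaustion compositions computed from the sorted-fraction datasets, and the
terminally-exhausted-read filter selects tumor-reactive clones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CLONE_KEY_COLS, ClonetrackError, RepertoireSample

logger = logging.getLogger(__name__)

CloneKey = tuple[str, str, str, str]

COMPOSITION_COLS = ("PD1neg", "precursor", "intermediate", "terminal")


class SubjectMismatchError(ClonetrackError):
    """Samples from multiple subjects were passed to a within-subject merge."""


class DegenerateFractionError(ClonetrackError):
    """All sorted cells were aliquoted away; no reads remain to correct."""


class UndefinedCompositionError(ClonetrackError):
    """Clone has no reads in any sorted fraction on the requested day."""


def corrected_counts(sample: RepertoireSample) -> pd.Series:
    """Aliquot-corrected read counts for one sample.

    Removing cells for single-cell sequencing before library preparation
    shrinks every clone's read count by the same factor; the correction
    ``raw * cells_sorted / (cells_sorted - cells_aliquoted_sc)`` restores
    the pre-aliquot cell scale.  With no aliquot the counts are unchanged.
    """
    raw = sample.clonotypes.set_index(list(CLONE_KEY_COLS))["read_count"].astype(float)
    if sample.cells_aliquoted_sc == 0 or sample.cells_sorted == 0:
        return raw
    if sample.cells_aliquoted_sc >= sample.cells_sorted:
        raise DegenerateFractionError(
            f"sample {sample.sample_id}: all {sample.cells_sorted} sorted cells aliquoted"
        )
    factor = sample.cells_sorted / (sample.cells_sorted - sample.cells_aliquoted_sc)
    return raw * factor


@dataclass
class CloneSet:
    """Merged clones of one subject across samples, days and fractions.

    ``counts`` is a long table with one row per (clone, sample) pairing:
    clone key columns, ``day``, ``site``, ``fraction``, raw ``count`` and
    aliquot-``corrected`` count.  ``cells`` (after :func:`attach_cells`)
    carries single-cell annotations with their link status.
    """

    subject_id: str
    counts: pd.DataFrame
    cells: pd.DataFrame | None = None

    @property
    def keys(self) -> list[CloneKey]:
        return sorted(
            self.counts[list(CLONE_KEY_COLS)].drop_duplicates().itertuples(index=False, name=None)
        )

    @property
    def n_clones(self) -> int:
        return len(self.counts[list(CLONE_KEY_COLS)].drop_duplicates())

    def days(self) -> list[int]:
        return sorted(self.counts["day"].unique())

    def subset(self, keys: Iterable[CloneKey]) -> "CloneSet":
        keyset = set(keys)
        idx = self.counts.set_index(list(CLONE_KEY_COLS)).index
        kept = self.counts[idx.isin(keyset)].reset_index(drop=True)
        cells = None
        if self.cells is not None:
            cells = self.cells.copy()
            linked = cells["clone_key"].isin(keyset)
            cells.loc[~linked & (cells["link_status"] == "linked"), "link_status"] = "unlinked"
            cells.loc[~linked & (cells["link_status"] == "linked"), "clone_key"] = None
        return CloneSet(subject_id=self.subject_id, counts=kept, cells=cells)

    def clone(self, key: CloneKey) -> "MergedClone":
        return MergedClone.from_cloneset(self, key)


def build_clones(samples: Sequence[RepertoireSample]) -> CloneSet:
    """Merge samples of one subject into a clone table.

    One merged clone per distinct (V, D, J, CDR3nt) key; clones absent from
    a sample implicitly have count 0 there.  Merging is within-subject only
    and associative: any sample order yields the identical table.
    """
    if not samples:
        raise ClonetrackError("no samples to merge")
    subjects = {s.subject_id for s in samples}
    if len(subjects) > 1:
        raise SubjectMismatchError(f"samples span multiple subjects: {sorted(subjects)}")
    frames = []
    for s in samples:
        corr = corrected_counts(s)
        df = s.clonotypes.copy()
        df["day"] = s.day
        df["site"] = s.site
        df["fraction"] = s.fraction
        df["count"] = df["read_count"]
        df["corrected"] = corr.to_numpy()
        frames.append(df.drop(columns=["read_count"]))
    counts = pd.concat(frames, ignore_index=True)
    counts = counts.sort_values(
        [*CLONE_KEY_COLS, "day", "site", "fraction"], kind="mergesort"
    ).reset_index(drop=True)
    return CloneSet(subject_id=samples[0].subject_id, counts=counts)


def clone_frequency(cloneset: CloneSet, day: int) -> pd.Series:
    """Per-clone frequency f_d: pooled corrected reads across that day's
    datasets divided by the day's total corrected reads.

    Indexed by clone key over *all* clones in the set (absent clones get 0);
    sums to 1.
    """
    day_rows = cloneset.counts[cloneset.counts["day"] == day]
    total = day_rows["corrected"].sum()
    if total <= 0:
        raise ClonetrackError(f"no reads on day {day}")
    per_clone = day_rows.groupby(list(CLONE_KEY_COLS))["corrected"].sum()
    all_keys = pd.MultiIndex.from_tuples(cloneset.keys, names=list(CLONE_KEY_COLS))
    return per_clone.reindex(all_keys, fill_value=0.0) / total


def clone_day_counts(cloneset: CloneSet, day: int) -> pd.Series:
    """Pooled corrected counts per clone for one day (all clones, 0 filled)."""
    day_rows = cloneset.counts[cloneset.counts["day"] == day]
    per_clone = day_rows.groupby(list(CLONE_KEY_COLS))["corrected"].sum()
    all_keys = pd.MultiIndex.from_tuples(cloneset.keys, names=list(CLONE_KEY_COLS))
    return per_clone.reindex(all_keys, fill_value=0.0)


def _composition_table(cloneset: CloneSet, day: int) -> pd.DataFrame:
    day_rows = cloneset.counts[cloneset.counts["day"] == day]
    present = set(day_rows["fraction"].unique())
    missing = [f for f in COMPOSITION_COLS if f not in present]
    if missing:
        raise ClonetrackError(
            f"phenotype_composition: day {day} lacks sorted fraction(s) {missing}"
        )
    pivot = day_rows.pivot_table(
        index=list(CLONE_KEY_COLS), columns="fraction", values="corrected", aggfunc="sum"
    ).reindex(columns=list(COMPOSITION_COLS), fill_value=0.0)
    pivot = pivot.fillna(0.0)
    return pivot


def phenotype_compositions(cloneset: CloneSet, day: int) -> pd.DataFrame:
    """Four-state composition per clone on one day, from corrected counts.

    Rows (clones with any reads that day) are fractions over
    (PD-1-, precursor, intermediate, terminal) summing to 1.
    """
    pivot = _composition_table(cloneset, day)
    totals = pivot.sum(axis=1)
    pivot = pivot[totals > 0]
    return pivot.div(totals[totals > 0], axis=0)


def phenotype_composition(cloneset: CloneSet, key: CloneKey, day: int) -> pd.Series:
    """Composition of a single clone; errors if it has no reads that day."""
    pivot = _composition_table(cloneset, day)
    if key not in pivot.index or pivot.loc[key].sum() <= 0:
        raise UndefinedCompositionError(f"clone {key} absent from all four fractions on day {day}")
    row = pivot.loc[key]
    return row / row.sum()


def attach_cells(cloneset: CloneSet, cell_annotations: pd.DataFrame) -> CloneSet:
    """Link single cells to bulk clones by shared CDR3beta nucleotide sequence.

    Cells whose CDR3beta matches multiple bulk clones (same CDR3, different
    V/D/J) are excluded (``link_status='ambiguous'``); cells with no bulk
    match are retained but flagged ``'unlinked'``.
    """
    keys = cloneset.counts[list(CLONE_KEY_COLS)].drop_duplicates()
    by_cdr3 = keys.groupby("cdr3_nt")
    mapping: dict[str, CloneKey | None] = {}
    for cdr3, grp in by_cdr3:
        if len(grp) == 1:
            mapping[cdr3] = tuple(grp.iloc[0][list(CLONE_KEY_COLS)])
        else:
            mapping[cdr3] = None  # ambiguous
    cells = cell_annotations.copy()
    cdr3s = cells["cdr3b_nt"].astype(str).str.upper()
    status = []
    clone_key = []
    for c in cdr3s:
        if c not in mapping:
            status.append("unlinked")
            clone_key.append(None)
        elif mapping[c] is None:
            status.append("ambiguous")
            clone_key.append(None)
        else:
            status.append("linked")
            clone_key.append(mapping[c])
    cells["clone_key"] = clone_key
    cells["link_status"] = status
    n_amb = status.count("ambiguous")
    if n_amb:
        logger.info("excluded %d cells matching multiple bulk clones", n_amb)
    return CloneSet(subject_id=cloneset.subject_id, counts=cloneset.counts, cells=cells)


def restrict_precursor_panel(
    cloneset: CloneSet, days: tuple[int, int] = (14, 21)
) -> CloneSet:
    """Keep clones seen in single-cell data on both days with consistent alpha chains.

    A clone qualifies when it has at least one linked cell on each of the
    two days and all its linked cells' non-missing TCRalpha CDR3 sequences
    are identical.
    """
    if cloneset.cells is None:
        raise ClonetrackError("attach_cells must run before restrict_precursor_panel")
    linked = cloneset.cells[cloneset.cells["link_status"] == "linked"]
    kept: list[CloneKey] = []
    for key, grp in linked.groupby("clone_key"):
        days_seen = set(grp["day"])
        if not all(d in days_seen for d in days):
            continue
        alphas = grp["cdr3a_nt"].dropna()
        alphas = alphas[alphas.astype(str).str.len() > 0]
        if alphas.nunique() > 1:
            continue
        kept.append(key)
    return cloneset.subset(kept)


def tumor_reactive_filter(
    cloneset: CloneSet,
    days: Iterable[int] | None = None,
    fractions: tuple[str, ...] = ("terminal",),
) -> CloneSet:
    """Keep clones with reads in the terminally exhausted dataset.

    Clones whose corrected terminal-fraction count is positive in at least
    one sample of ``days`` (default: all days) pass; this enriches for
    tumor-reactive clones.  ``fractions`` can be widened to
    ``("terminal", "intermediate")`` to admit any TIM-3+ dataset instead.
    Idempotent.
    """
    rows = cloneset.counts
    if days is not None:
        rows = rows[rows["day"].isin(list(days))]
    rows = rows[rows["fraction"].isin(fractions) & (rows["corrected"] > 0)]
    kept = rows[list(CLONE_KEY_COLS)].drop_duplicates().itertuples(index=False, name=None)
    return cloneset.subset(kept)


def detected(cloneset: CloneSet, key: CloneKey, day: int) -> bool:
    """A clone counts as detected on a day when any fraction has corrected reads."""
    rows = cloneset.counts
    sel = rows[
        (rows["day"] == day)
        & (rows["v_call"] == key[0])
        & (rows["d_call"] == key[1])
        & (rows["j_call"] == key[2])
        & (rows["cdr3_nt"] == key[3])
    ]
    return bool((sel["corrected"] > 0).any())


@dataclass
class MergedClone:
    """Convenience view of one clone across days: counts, frequencies, composition."""

    key: CloneKey
    counts: pd.DataFrame  # rows for this clone only
    frequencies: dict[int, float] = field(default_factory=dict)
    compositions: dict[int, pd.Series] = field(default_factory=dict)
    cell_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_cloneset(cls, cloneset: CloneSet, key: CloneKey) -> "MergedClone":
        rows = cloneset.counts[
            (cloneset.counts["v_call"] == key[0])
            & (cloneset.counts["d_call"] == key[1])
            & (cloneset.counts["j_call"] == key[2])
            & (cloneset.counts["cdr3_nt"] == key[3])
        ]
        freqs = {}
        comps = {}
        for day in cloneset.days():
            try:
                freqs[day] = float(clone_frequency(cloneset, day).loc[key])
            except ClonetrackError:
                pass
            try:
                comps[day] = phenotype_composition(cloneset, key, day)
            except ClonetrackError:
                pass
        cell_ids = []
        if cloneset.cells is not None:
            linked = cloneset.cells[
                (cloneset.cells["link_status"] == "linked")
                & (cloneset.cells["clone_key"] == key)
            ]
            cell_ids = linked["cell_id"].tolist()
        return cls(key=key, counts=rows.reset_index(drop=True), frequencies=freqs,
                   compositions=comps, cell_ids=cell_ids)


def export_clone_table(cloneset: CloneSet, path: str | Path) -> pd.DataFrame:
    """One row per clone-day: pooled counts, frequency and composition (if sorted)."""
    records = []
    for day in cloneset.days():
        freqs = clone_frequency(cloneset, day)
        counts = clone_day_counts(cloneset, day)
        try:
            comps = phenotype_compositions(cloneset, day)
        except ClonetrackError:
            comps = None
        for key in cloneset.keys:
            rec = {
                "v_call": key[0], "d_call": key[1], "j_call": key[2], "cdr3_nt": key[3],
                "day": day,
                "corrected_count": counts.loc[key],
                "frequency": freqs.loc[key],
            }
            if comps is not None and key in comps.index:
                for col in COMPOSITION_COLS:
                    rec[f"frac_{col}"] = comps.loc[key, col]
            records.append(rec)
    out = pd.DataFrame(records)
    out.to_csv(path, sep="\t", index=False)
    return out
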