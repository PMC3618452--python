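"""Bin selection, metabolite assignment and fold-change aggregation.

Buckets are flagged as treatment-related when their t-test q-value falls
strictly below ``q_cut`` (default 0.2) OR their VIP exceeds ``vip_cut``
(default 1.5).  Selected buckets are mapped to metabolites through a
chemical-shift library of ppm windows; a bucket whose center falls in
the windows of several metabolites is assigned to all of them and
flagged ambiguous rather than arbitrated.  Per metabolite, the selected
buckets are summed within each sample and the fold change is the ratio
of the treated-group mean of those sums to the control-group mean.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .bucketing import BucketTable
from .stats import BinStat

__all__ = [
    "ShiftLibrary",
    "BinAssignment",
    "MetaboliteResult",
    "load_shift_library",
    "select_bins",
    "assign_bins",
    "metabolite_fold_change",
]


@dataclass(frozen=True)
class LibraryEntry:
    metabolite: str
    kegg_id: str
    intervals: tuple[tuple[float, float], ...]


@dataclass
class ShiftLibrary:
    entries: list[LibraryEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("shift library is empty")
        for e in self.entries:
            for lo, hi in e.intervals:
                if not lo < hi:
                    raise ValueError(
                        f"{e.metabolite}: invalid interval [{lo}, {hi})"
                    )

    def kegg_of(self, metabolite: str) -> str:
        for e in self.entries:
            if e.metabolite == metabolite:
                return e.kegg_id
        raise KeyError(metabolite)

    def metabolites_at(self, ppm: float) -> list[str]:
        hits = []
        for e in self.entries:
            if any(lo <= ppm < hi for lo, hi in e.intervals):
                hits.append(e.metabolite)
        return hits


def load_shift_library(path=None) -> ShiftLibrary:
    """Load the packaged default (or a user-supplied) shift library TSV."""
    if path is None:
        text = resources.files("metabopls.data").joinpath("shift_library.tsv").read_text()
    else:
        text = Path(path).read_text()
    rows: dict[str, tuple[str, list[tuple[float, float]]]] = {}
    reader = csv.reader(
        (l for l in text.splitlines() if l.strip() and not l.startswith("#")),
        delimiter="\t",
    )
    header = next(reader)
    if header[0] != "metabolite":
        raise ValueError("shift library must have a 'metabolite' header column")
    for row in reader:
        name, kegg, lo, hi = row[:4]
        rows.setdefault(name, (kegg, []))[1].append((float(lo), float(hi)))
    return ShiftLibrary(
        entries=[
            LibraryEntry(name, kegg, tuple(ivs)) for name, (kegg, ivs) in rows.items()
        ]
    )


def select_bins(
    stats: list[BinStat], q_cut: float = 0.2, vip_cut: float = 1.5
) -> list[BinStat]:
    """Flag treatment-related buckets: q < q_cut OR VIP > vip_cut (strict)."""
    selected = []
    for s in stats:
        if np.isnan(s.q_value) or np.isnan(s.vip):
            raise ValueError(
                f"bin {s.bin_center_ppm}: q-value and VIP must be populated "
                "before selection"
            )
        s.selected = bool(s.q_value < q_cut or s.vip > vip_cut)
        if s.selected:
            selected.append(s)
    return selected


@dataclass
class BinAssignment:
    """Outcome of mapping selected buckets onto the shift library."""

    assignments: dict[str, list[BinStat]] = field(default_factory=dict)
    unassigned: list[BinStat] = field(default_factory=list)
    ambiguous_bins: list[BinStat] = field(default_factory=list)

    def is_ambiguous(self, metabolite: str) -> bool:
        amb = {id(b) for b in self.ambiguous_bins}
        return any(id(b) in amb for b in self.assignments.get(metabolite, []))


def assign_bins(selected: list[BinStat], library: ShiftLibrary) -> BinAssignment:
    """Map each selected bucket to every metabolite window containing it."""
    result = BinAssignment()
    for s in selected:
        names = library.metabolites_at(s.bin_center_ppm)
        if not names:
            result.unassigned.append(s)
            continue
        if len(names) > 1:
            result.ambiguous_bins.append(s)
        for name in names:
            result.assignments.setdefault(name, []).append(s)
    return result


@dataclass
class MetaboliteResult:
    metabolite: str
    kegg_id: str
    n_bins: int
    avg_fold_change: float
    direction: str
    ambiguous: bool = False


def metabolite_fold_change(
    table: BucketTable,
    assignment: BinAssignment,
    library: ShiftLibrary,
    treated_label: str = "treated",
    control_label: str = "control",
) -> list[MetaboliteResult]:
    """Aggregate selected buckets to metabolite-level fold changes.

    Per sample the metabolite's buckets are summed; the fold change is the
    treated-group mean of the sums over the control-group mean (which, by
    linearity of the mean, equals the ratio of summed group-mean bucket
    values).
    """
    if not table.normalized:
        raise ValueError("fold changes are defined on the normalized table")
    tmask = table.group_mask(treated_label)
    cmask = table.group_mask(control_label)
    center_to_col = {round(c, 6): j for j, c in enumerate(table.bin_centers_ppm)}
    results: list[MetaboliteResult] = []
    for name, bins in sorted(assignment.assignments.items()):
        cols = [center_to_col[round(b.bin_center_ppm, 6)] for b in bins]
        per_sample = table.matrix[:, cols].sum(axis=1)
        mean_c = float(per_sample[cmask].mean())
        if mean_c <= 0:
            raise ValueError(f"metabolite {name!r}: non-positive control mean")
        fc = float(per_sample[tmask].mean()) / mean_c
        results.append(
            MetaboliteResult(
                metabolite=name,
                kegg_id=library.kegg_of(name),
                n_bins=len(cols),
                avg_fold_change=fc,
                direction="up" if fc > 1 else "down",
                ambiguous=assignment.is_ambiguous(name),
            )
        )
    results.sort(key=lambda r: -r.avg_fold_change)
    return results
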