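"""TSS-window peak annotation and 2x2 Fisher exact enrichment testing.

A gene is "positive" for a ChIP-seq source when any peak interval intersects
the symmetric window around its transcription start site (TSS); promoter
enrichment between two gene sets (e.g. transactivated targets vs a repressed
module) is then tested with the two-sided Fisher exact test on the resulting
2x2 table.

Conventions, fixed bit-exactly:

* peaks and windows are 0-based half-open intervals;
* the TSS is a single base; a half-width ``w`` yields the window
  ``[tss - w, tss + w + 1)`` so the window covers the TSS base plus ``w``
  bases on each side regardless of strand (strand matters only when choosing
  the TSS coordinate upstream of this module);
* two-sided p sums the hypergeometric probabilities of all tables with the
  observed margins whose probability does not exceed the observed table's
  (the probability-at-most-observed rule used by R's fisher.test and
  scipy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import GeneSet, ParseError, ValidationError, normalize_symbol

# relative slack when comparing hypergeometric point masses, as in R/scipy:
# tables whose probability is <= p_obs * (1 + EPS) are counted
_REL_EPS = 1e-7


# ---------------------------------------------------------------------------
# genomic containers
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Peak intervals per chromosome, 0-based half-open, sorted by start."""

    intervals: dict[str, np.ndarray]  # chrom -> (n, 2) int array
    source: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            a = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if (a[:, 0] >= a[:, 1]).any():
                bad = a[a[:, 0] >= a[:, 1]][0]
                raise ValidationError(
                    f"interval start >= end on {chrom}: {bad[0]} >= {bad[1]}"
                )
            clean[chrom] = a[np.argsort(a[:, 0], kind="stable")]
        self.intervals = clean

    @classmethod
    def from_intervals(
        cls, triples: Iterable[tuple[str, int, int]], source: str = ""
    ) -> "PeakSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in triples:
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        return cls(
            intervals={c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()},
            source=source,
        )

    def __len__(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any peak intersecting the half-open query [start, end)?"""
        arr = self.intervals.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        return bool(((arr[:, 0] < end) & (arr[:, 1] > start)).any())


def read_bed(path: str | Path, source: str | None = None) -> PeakSet:
    """BED3+ reader; overlapping intervals are retained as-is (no merging)."""
    triples = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
        triples.append((chrom, start, end))
    return PeakSet.from_intervals(triples, source=source or Path(path).stem)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(peaks.intervals):
            for start, end in peaks.intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


@dataclass
class TssAnnotation:
    """gene -> (chrom, tss_position 0-based, strand). One TSS per gene."""

    table: pd.DataFrame  # index: gene; columns chrom, tss, strand

    def __post_init__(self) -> None:
        need = {"chrom", "tss", "strand"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"TSS table needs columns {sorted(need)}")
        if self.table.index.has_duplicates:
            raise ValidationError("multiple TSS rows for one gene")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise ValidationError("strand must be + or -")
        self.table = self.table.copy()
        self.table.index = [normalize_symbol(g) for g in self.table.index]

    @classmethod
    def from_records(cls, records: Mapping[str, tuple[str, int, str]]) -> "TssAnnotation":
        df = pd.DataFrame.from_dict(
            {g: {"chrom": c, "tss": int(t), "strand": s} for g, (c, t, s) in records.items()},
            orient="index",
        )
        return cls(table=df)

    def genes(self) -> set[str]:
        return set(self.table.index)


def read_tss_table(path: str | Path) -> TssAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    need = {"gene", "chrom", "tss_position", "strand"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: TSS TSV needs columns {sorted(need)}")
    df = df.rename(columns={"tss_position": "tss"}).set_index("gene")
    return TssAnnotation(table=df[["chrom", "tss", "strand"]])


def write_tss_table(tss: TssAnnotation, path: str | Path) -> None:
    out = tss.table.rename(columns={"tss": "tss_position"}).reset_index(names="gene")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TSS-window annotation
# ---------------------------------------------------------------------------

def annotate_tss_overlap(
    tss: TssAnnotation,
    peaks: PeakSet | Sequence[PeakSet],
    window_bp: int,
    combine: str = "any",
) -> pd.Series:
    """Per-gene boolean: does any peak intersect the +/- ``window_bp`` window
    around the TSS base?

    ``peaks`` may be one PeakSet or several ChIP-seq sources; with
    ``combine="any"`` a gene is positive if any source has a peak in the
    window, with ``"all"`` every source must.  Genes on chromosomes absent
    from a source are negative for that source.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    sources = [peaks] if isinstance(peaks, PeakSet) else list(peaks)
    if not sources:
        raise ValidationError("no peak sources supplied")
    if combine not in ("any", "all"):
        raise ValidationError("combine must be 'any' or 'all'")
    result = {}
    for gene, row in tss.table.iterrows():
        start = int(row.tss) - window_bp
        end = int(row.tss) + window_bp + 1  # half-open; covers the TSS base
        hits = [src.overlaps(row.chrom, start, end) for src in sources]
        result[gene] = all(hits) if combine == "all" else any(hits)
    return pd.Series(result, name=f"tss_overlap_{window_bp}bp", dtype=bool)


# ---------------------------------------------------------------------------
# 2x2 tables and the Fisher exact test
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = gene groups, columns = with/without
    the feature."""

    a: int
    b: int
    c: int
    d: int
    excluded_group1: list[str] = field(default_factory=list)
    excluded_group2: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValidationError(f"counts must be non-negative integers, got {v}")
        self.a, self.b, self.c, self.d = int(self.a), int(self.b), int(self.c), int(self.d)
        if self.total == 0:
            raise ValidationError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def percent_positive(self) -> tuple[float, float]:
        """Percentage of feature-positive genes per group, rounded to one
        decimal place (display convention)."""
        n1, n2 = self.a + self.b, self.c + self.d
        p1 = round(100.0 * self.a / n1, 1) if n1 else 0.0
        p2 = round(100.0 * self.c / n2, 1) if n2 else 0.0
        return p1, p2


def count_enrichment(
    group1: GeneSet, group2: GeneSet, overlaps: pd.Series | Mapping[str, bool]
) -> ContingencyTable2x2:
    """Build the 2x2 table (group x overlap) from per-gene overlap calls.

    Genes lacking a TSS annotation (absent from ``overlaps``) are excluded
    from the denominators and reported on the table.
    """
    if len(group2) == 0 or len(group1) == 0:
        raise ValidationError("both gene groups must be non-empty")
    calls = dict(overlaps.items()) if isinstance(overlaps, pd.Series) else dict(overlaps)
    calls = {normalize_symbol(g): bool(v) for g, v in calls.items()}

    def split(group: GeneSet) -> tuple[int, int, list[str]]:
        pos = neg = 0
        missing = []
        for g in sorted(group.members):
            if g not in calls:
                missing.append(g)
            elif calls[g]:
                pos += 1
            else:
                neg += 1
        return pos, neg, missing

    a, b, miss1 = split(group1)
    c, d, miss2 = split(group2)
    return ContingencyTable2x2(a, b, c, d, excluded_group1=miss1, excluded_group2=miss2)


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(A = a) for the central hypergeometric with margins r1, r2, c1."""
    lg = math.lgamma
    n = r1 + r2

    def lchoose(m: int, k: int) -> float:
        return lg(m + 1) - lg(k + 1) - lg(m - k + 1)

    return lchoose(r1, a) + lchoose(r2, c1 - a) - lchoose(n, c1)


def fisher_exact_two_sided(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table, computed in log space.

    Sums the hypergeometric point masses of every table with the observed
    margins whose probability is at most the observed table's (with a 1e-7
    relative guard against float ties).  A zero margin gives p = 1.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    log_obs = _log_hypergeom_pmf(a, r1, r2, c1)
    cutoff = log_obs + math.log1p(_REL_EPS)
    logps = [_log_hypergeom_pmf(k, r1, r2, c1) for k in range(lo, hi + 1)]
    selected = [x for x in logps if x <= cutoff]
    m = max(selected)
    p = math.exp(m) * sum(math.exp(x - m) for x in selected)
    return min(p, 1.0)


def fisher_exact_oracle(table: ContingencyTable2x2 | Sequence[Sequence[int]]):
    """Exact-arithmetic enumeration of the two-sided Fisher p.

    Enumerates every table with the observed margins, computing each point
    mass as an integer numerator over the common denominator C(n, c1), and
    sums the numerators that are <= the observed one — integer comparisons,
    so no floating-point tie ambiguity.  Returns a ``fractions.Fraction``.

    Independent of :func:`fisher_exact_two_sided`; intended for validation.
    """
    from fractions import Fraction

    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = table.total
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return Fraction(1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numerators = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    obs = numerators[a]
    total = sum(num for num in numerators.values() if num <= obs)
    return Fraction(total, math.comb(n, c1))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def enrichment_report(
    group1: GeneSet,
    group2: GeneSet,
    tss: TssAnnotation,
    peak_sources: Mapping[str, PeakSet],
    windows: Sequence[int] = (2000, 10000),
    combine: str = "any",
) -> pd.DataFrame:
    """Counts, percentages and two-sided Fisher p per (window, source set).

    Emits one row per window for the combined sources plus one row per
    individual source, so both the pooled and the per-dataset pictures are
    available.
    """
    if not peak_sources:
        raise ValidationError("no peak sources supplied")
    rows = []
    configs: list[tuple[str, PeakSet | list[PeakSet]]] = [
        ("combined", list(peak_sources.values()))
    ]
    configs += [(name, ps) for name, ps in peak_sources.items()]
    for window in windows:
        for label, src in configs:
            overlaps = annotate_tss_overlap(tss, src, window, combine=combine)
            tab = count_enrichment(group1, group2, overlaps)
            pct1, pct2 = tab.percent_positive()
            rows.append(
                {
                    "window_bp": window,
                    "source": label,
                    "group1": group1.name,
                    "group2": group2.name,
                    "a": tab.a,
                    "b": tab.b,
                    "c": tab.c,
                    "d": tab.d,
                    "group1_percent": pct1,
                    "group2_percent": pct2,
                    "p_two_sided": fisher_exact_two_sided(tab),
                    "n_excluded_group1": len(tab.excluded_group1),
                    "n_excluded_group2": len(tab.excluded_group2),
                }
            )
    return pd.DataFrame(rows)
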