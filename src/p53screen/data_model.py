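"""Shared domain types, readers/writers and validation.

Everything downstream of the raw assays is expressed in terms of a small set
of containers: an :class:`ExpressionMatrix` (probe- or gene-level abundances),
a :class:`SampleDesign` mapping samples onto experimental conditions, a
:class:`ProbeGeneMap`, an :class:`OrthologMap` for human/mouse set
intersection, and :class:`GeneSet`.

Condition codes
---------------
Each sample is assigned a condition code derived from its design row:

* time-course cell lines: ``W0/W12/W24/W48`` (p53 wild-type) and
  ``K0/K12/K24/K48`` (p53 null), by genotype and hours after genotoxic
  treatment;
* mouse tissues: ``W``/``WX`` (wild-type, un-/irradiated) and ``K``/``KX``
  (p53 null);
* tumor cohort: ``cohort_wt`` / ``cohort_mut`` by somatic p53 status.

The tissue field disambiguates the mouse arms from the cohort (mouse samples
carry a tissue label, cohort samples do not).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENOTYPES = ("p53_wt", "p53_null", "p53_mut")
TREATMENTS = ("none", "ADR", "irradiation")
TIMEPOINTS = (0, 12, 24, 48)


class ValidationError(ValueError):
    """Input violates a documented contract (values, not syntax)."""


class ParseError(ValueError):
    """Input file is syntactically malformed."""


# ---------------------------------------------------------------------------
# symbol normalization
# ---------------------------------------------------------------------------

def normalize_symbol(symbol: str, species: str = "human") -> str:
    """Case-normalize a gene symbol: upper case for human, capitalized for
    mouse (``Ccnb1`` style). Surrounding whitespace is stripped."""
    s = str(symbol).strip()
    if not s:
        raise ValidationError("empty gene symbol")
    if species == "human":
        return s.upper()
    if species == "mouse":
        return s[:1].upper() + s[1:].lower()
    raise ValidationError(f"unknown species {species!r}")


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Feature x sample abundance matrix.

    ``values`` is a float DataFrame indexed by feature id with sample ids as
    columns.  Units are whatever the upstream platform produced (array
    intensity, FPKM, normalized counts); all criteria downstream are ratio-
    or rank-based so no unit is enforced beyond non-negativity.
    """

    values: pd.DataFrame
    feature_kind: str  # {"probe", "gene"}

    def __post_init__(self) -> None:
        if self.feature_kind not in ("probe", "gene"):
            raise ValidationError(f"feature_kind must be probe|gene, got {self.feature_kind!r}")
        if not isinstance(self.values, pd.DataFrame):
            raise ValidationError("values must be a DataFrame")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicated sample ids")
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(
                f"missing value at feature {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value at feature {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression_table(path: str | Path, feature_kind: str) -> ExpressionMatrix:
    """Read a TSV expression table (header = sample ids, column 1 = feature
    ids) into a validated :class:`ExpressionMatrix`.

    Malformed numeric cells (including literal ``NA``) raise :class:`ParseError`
    naming the offending feature and sample.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, index_col=0)
    raw.index.name = None
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            feat = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric cell at feature {feat!r}, sample {col!r} "
                f"(value {raw.loc[feat, col]!r})"
            )
        numeric[col] = converted.to_numpy()
    try:
        return ExpressionMatrix(values=numeric, feature_kind=feature_kind)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV that :func:`read_expression_table` round-trips bit-identically
    (float repr preserves the value exactly)."""
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format=None)


# ---------------------------------------------------------------------------
# SampleDesign and condition codes
# ---------------------------------------------------------------------------

def condition_code(
    genotype: str,
    treatment: str,
    timepoint: int | float | None,
    tissue: str | None = None,
) -> str:
    """Map a sample's design onto its condition code (see module docstring).

    Total and deterministic over the supported designs; anything else raises
    :class:`ValidationError`.
    """
    if genotype not in GENOTYPES:
        raise ValidationError(f"unknown genotype {genotype!r}")
    if treatment not in TREATMENTS:
        raise ValidationError(f"unknown treatment {treatment!r}")
    has_time = timepoint is not None and not (isinstance(timepoint, float) and np.isnan(timepoint))
    has_tissue = tissue is not None and str(tissue) not in ("", "NA", "nan")

    if has_time:
        if genotype == "p53_mut":
            raise ValidationError("time-course design has no p53_mut arm")
        t = int(timepoint)
        if t not in TIMEPOINTS:
            raise ValidationError(f"unsupported timepoint {timepoint!r}")
        return ("W" if genotype == "p53_wt" else "K") + str(t)
    if has_tissue:
        if genotype == "p53_mut":
            raise ValidationError("mouse design has no p53_mut arm")
        base = "W" if genotype == "p53_wt" else "K"
        return base + ("X" if treatment == "irradiation" else "")
    if genotype == "p53_wt":
        return "cohort_wt"
    if genotype == "p53_mut":
        return "cohort_mut"
    raise ValidationError("cohort design has no p53_null arm")


@dataclass
class SampleDesign:
    """Per-sample design table with derived condition codes.

    ``table`` columns: sample_id, genotype, treatment, timepoint, tissue,
    condition_code (derived, never read from input).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "genotype", "treatment", "timepoint", "tissue"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValidationError("duplicated sample ids in design")
        codes = [
            condition_code(row.genotype, row.treatment, row.timepoint, row.tissue)
            for row in self.table.itertuples()
        ]
        self.table = self.table.assign(condition_code=codes).reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "SampleDesign":
        df = pd.DataFrame(records)
        if "timepoint" in df.columns:
            df["timepoint"] = pd.to_numeric(df["timepoint"], errors="coerce")
        if "tissue" in df.columns:
            df["tissue"] = df["tissue"].where(df["tissue"].notna(), None)
        return cls(table=df)

    def samples_for(self, *codes: str, tissue: str | None = None) -> list[str]:
        """Sample ids whose condition code is in ``codes`` (optionally
        restricted to one tissue)."""
        mask = self.table["condition_code"].isin(codes)
        if tissue is not None:
            mask &= self.table["tissue"] == tissue
        return self.table.loc[mask, "sample_id"].tolist()

    @property
    def codes(self) -> pd.Series:
        return self.table.set_index("sample_id")["condition_code"]


def read_sample_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    df["timepoint"] = pd.to_numeric(df.get("timepoint"), errors="coerce")
    df["tissue"] = df["tissue"].where(df["tissue"].notna(), None)
    return SampleDesign(table=df)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.table.drop(columns=["condition_code"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ProbeGeneMap / OrthologMap / GeneSet
# ---------------------------------------------------------------------------

@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene symbol map."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {str(p): normalize_symbol(g) for p, g in self.mapping.items()}

    def gene_of(self, probe: str) -> str:
        return self.mapping[probe]

    def probes_of(self, gene: str) -> list[str]:
        g = normalize_symbol(gene)
        return [p for p, q in self.mapping.items() if q == g]


@dataclass
class OrthologMap:
    """Human/mouse gene-symbol correspondence, case-normalized per species."""

    pairs: list[tuple[str, str]]  # (human_symbol, mouse_symbol)

    def __post_init__(self) -> None:
        self._mouse_to_human: dict[str, str] = {}
        norm_pairs = []
        for human, mouse in self.pairs:
            h = normalize_symbol(human, "human")
            m = normalize_symbol(mouse, "mouse")
            norm_pairs.append((h, m))
            self._mouse_to_human[m] = h
        self.pairs = norm_pairs

    def to_human(self, mouse_symbols: Iterable[str]) -> tuple[set[str], list[str]]:
        """Translate mouse symbols; returns (mapped human set, unmapped
        mouse symbols).  Unmapped symbols are reported, never dropped
        silently."""
        mapped: set[str] = set()
        unmapped: list[str] = []
        for sym in mouse_symbols:
            m = normalize_symbol(sym, "mouse")
            if m in self._mouse_to_human:
                mapped.add(self._mouse_to_human[m])
            else:
                unmapped.append(m)
        return mapped, sorted(unmapped)

    @classmethod
    def identity(cls, human_symbols: Iterable[str]) -> "OrthologMap":
        """Symbol-identity map (human FOO <-> mouse Foo); the common case for
        one-to-one named orthologs."""
        return cls(pairs=[(s, s) for s in human_symbols])


@dataclass
class GeneSet:
    """Named set of (case-normalized) gene symbols with free-text provenance."""

    name: str
    members: frozenset[str]
    provenance: str = ""

    @classmethod
    def from_iterable(
        cls, name: str, symbols: Iterable[str], species: str = "human", provenance: str = ""
    ) -> "GeneSet":
        return cls(
            name=name,
            members=frozenset(normalize_symbol(s, species) for s in symbols),
            provenance=provenance,
        )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members

    def __and__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(
            name=f"{self.name}&{other.name}",
            members=self.members & other.members,
            provenance="intersection",
        )


def read_gene_set(path: str | Path, name: str | None = None, species: str = "human") -> GeneSet:
    """One symbol per line; '#' starts a comment; blank lines ignored."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return GeneSet.from_iterable(name or Path(path).stem, symbols, species=species,
                                 provenance=str(path))


def write_gene_set(genes: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes.members)))


def read_bed_intervals(path: str | Path):
    """Read BED3 peaks into a PeakSet (see :mod:`p53screen.enrichment`)."""
    from .enrichment import read_bed  # deferred: enrichment imports this module

    return read_bed(path)
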