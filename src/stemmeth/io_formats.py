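"""On-disk formats and the in-memory containers built from them.

Coordinate conventions (applied *only* at this boundary):

* cytosine reports: 1-based positions, one row per strand-specific cytosine
  (the Bismark CX-report convention);
* BED: 0-based half-open;
* GFF3: 1-based inclusive, converted on load so that start ``s`` / end ``e``
  become ``(s - 1, e)``.

Chromosome names are matched as exact strings; no "chr"-prefix
normalization is performed, because silent renaming is a classic source of
off-by-one-chromosome bugs.

The ``context`` column of a cytosine report is advisory: the trinucleotide
is authoritative, and a context that disagrees with its trinucleotide is
recomputed with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._sequence import context_from_trinucleotide

logger = logging.getLogger(__name__)

CX_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]

STAGES = ("E", "D7", "D14", "D35", "S7", "S14")
FRACTIONS = ("stem", "nonstem", "seedling")

#: optional per-region statistic columns carried by DMR BED files, in the
#: on-disk column order after chrom/start/end
DMR_EXTRA_COLUMNS = ["context", "n_dmps", "mean_delta", "direction"]


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-specific cytosine with its methylation evidence."""

    chrom: str
    pos: int  # 1-based position of the cytosine on the reference
    strand: str  # '+' or '-'
    context: str  # CG / CHG / CHH
    trinucleotide: str  # 3-mer starting at the C, read 5'->3' on its strand
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("methylation counts must be non-negative")


@dataclass
class MethylomeSample:
    """A sample's cytosine records plus its stage/fraction metadata.

    ``records`` is a DataFrame with the :data:`CX_COLUMNS` columns, sorted
    by (chrom, pos, strand) and unique on that key.
    """

    sample_id: str
    stage: str
    fraction: str
    records: pd.DataFrame
    genome_id: str = ""

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.fraction not in FRACTIONS:
            raise ValueError(
                f"unknown fraction {self.fraction!r}; expected one of {FRACTIONS}"
            )
        df = self.records
        missing = [c for c in CX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"records missing columns {missing}")
        if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
            raise ValueError("negative methylation counts")
        df = df.astype({"pos": "int64", "n_meth": "int64", "n_unmeth": "int64"})
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) records within sample")
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    def subset_chrom(self, chrom: str) -> pd.DataFrame:
        return self.records[self.records["chrom"] == chrom]


@dataclass(frozen=True)
class AnnotationFeature:
    """A gene or transposable-element interval (0-based half-open)."""

    feature_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "TE"  # 'gene' or 'TE'
    family: str = ""
    superfamily: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"feature {self.feature_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DMRSet:
    """Called or externally supplied differentially methylated regions.

    ``regions`` holds chrom/start/end (0-based half-open) and, when known,
    the per-region statistic columns of :data:`DMR_EXTRA_COLUMNS`.
    """

    regions: pd.DataFrame
    set_id: str = ""

    def __post_init__(self) -> None:
        df = self.regions
        for c in ("chrom", "start", "end"):
            if c not in df.columns:
                raise ValueError(f"DMRSet regions missing column {c!r}")
        if len(df) and (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(f"region {bad['chrom']}:{bad['start']}-{bad['end']} is empty")
        self.regions = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class ExpressionMatrix:
    """Nonnegative feature x sample abundance table (TPM-like).

    ``feature_meta`` (indexed like ``values`` rows) carries ``class``
    ('protein_coding', 'TE' or 'housekeeping'), ``family`` and
    ``superfamily``; ``sample_meta`` (indexed like ``values`` columns)
    carries ``stage`` and ``fraction``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.values.index.equals(self.feature_meta.index):
            self.feature_meta = self.feature_meta.reindex(self.values.index)
        if self.feature_meta["class"].isna().any():
            raise ValueError("every feature needs a class")
        if not self.values.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.reindex(self.values.columns)

    def columns_for(self, stage: str, fraction: str) -> list[str]:
        m = self.sample_meta
        return list(m.index[(m["stage"] == stage) & (m["fraction"] == fraction)])


# ---------------------------------------------------------------------------
# cytosine reports


def read_cytosine_report(
    path: str | Path,
    sample_id: str | None = None,
    *,
    stage: str,
    fraction: str,
    genome_id: str = "",
) -> MethylomeSample:
    """Load a 7-column cytosine report into a :class:`MethylomeSample`.

    Columns: chrom, pos (1-based), strand, n_meth, n_unmeth, context,
    trinucleotide. A context that disagrees with its trinucleotide is
    recomputed from the trinucleotide with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CX_COLUMNS,
            dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            CX_COLUMNS, [str, "int64", str, "int64", "int64", str, str]
        )})
    for col in ("pos", "n_meth", "n_unmeth"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: unparseable {col!r} value on line {lineno}")
        df[col] = numeric.astype("int64")
    neg = (df["n_meth"] < 0) | (df["n_unmeth"] < 0)
    if neg.any():
        lineno = int(neg.idxmax()) + 1
        raise ValueError(f"{path}: negative count on line {lineno}")
    if len(df):
        expected = df["trinucleotide"].map(lambda t: context_from_trinucleotide(str(t)))
        fixable = expected.notna() & (expected != df["context"])
        if fixable.any():
            logger.warning(
                "%s: %d records had a context inconsistent with their trinucleotide; "
                "recomputed from the trinucleotide",
                path,
                int(fixable.sum()),
            )
            df.loc[fixable, "context"] = expected[fixable]
    return MethylomeSample(
        sample_id=sample_id or path.stem,
        stage=stage,
        fraction=fraction,
        records=df,
        genome_id=genome_id,
    )


def write_cytosine_report(sample: MethylomeSample, path: str | Path) -> None:
    """Write a sample as a header-free 7-column TSV, sorted and bit-stable."""
    df = sample.records.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    df.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


# ---------------------------------------------------------------------------
# annotations


def read_annotation(path: str | Path, dialect: str = "bed", *, default_kind: str = "TE") -> list[AnnotationFeature]:
    """Load gene/TE features from BED6(+3) or GFF3.

    The BED dialect reads columns chrom, start, end, name, score, strand
    and, when present, three extra columns kind, family, superfamily.
    The GFF3 dialect keeps ``gene`` features and anything whose type
    mentions a transposable element, reading ``Family``/``Superfamily``
    attributes when present.
    """
    dialect = dialect.lower()
    if dialect in ("bed", "bed6"):
        return _read_bed_features(path, default_kind=default_kind)
    if dialect == "gff3":
        return _read_gff3_features(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_bed_features(path: str | Path, *, default_kind: str) -> list[AnnotationFeature]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    feats = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = list(row) + [None] * (9 - len(row))
        chrom, start, end = r[0], int(r[1]), int(r[2])
        if end <= start:
            raise ValueError(f"{path} line {i}: end {end} <= start {start}")
        feats.append(
            AnnotationFeature(
                feature_id=r[3] if r[3] is not None else f"feat{i}",
                chrom=chrom,
                start=start,
                end=end,
                strand=r[5] if r[5] in ("+", "-") else ".",
                kind=r[6] if r[6] is not None else default_kind,
                family=r[7] if r[7] is not None and not pd.isna(r[7]) else "",
                superfamily=r[8] if r[8] is not None and not pd.isna(r[8]) else "",
            )
        )
    return feats


def _read_gff3_features(path: str | Path) -> list[AnnotationFeature]:
    from gffutils.iterators import DataIterator

    feats = []
    for f in DataIterator(str(path)):
        ftype = f.featuretype.lower()
        if ftype == "gene":
            kind = "gene"
        elif "transpos" in ftype:
            kind = "TE"
        else:
            continue
        start, end = f.start - 1, f.end  # 1-based inclusive -> 0-based half-open
        if end <= start:
            raise ValueError(f"{path}: feature {f.id} empty after coordinate conversion")
        attrs = {k.lower(): v for k, v in f.attributes.items()}
        feats.append(
            AnnotationFeature(
                feature_id=f.id or attrs.get("name", [""])[0] or f"{f.seqid}:{start}-{end}",
                chrom=f.seqid,
                start=start,
                end=end,
                strand=f.strand if f.strand in ("+", "-") else ".",
                kind=kind,
                family=attrs.get("family", [""])[0],
                superfamily=attrs.get("superfamily", [""])[0],
            )
        )
    return feats


def write_annotation(features: Sequence[AnnotationFeature], path: str | Path) -> None:
    """Write features as BED6+3 (kind, family, superfamily in columns 7-9)."""
    rows = [
        (f.chrom, f.start, f.end, f.feature_id, 0, f.strand, f.kind, f.family, f.superfamily)
        for f in sorted(features, key=lambda f: (f.chrom, f.start, f.end))
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# region sets


def read_region_set(path: str | Path, set_id: str | None = None) -> DMRSet:
    """Load a BED3+ region set; extra columns 4-7 are read back as
    context, n_dmps, mean_delta, direction when present."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=range(3))
    if len(df) and df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str) if len(df) else pd.Series(dtype=str),
            "start": df[1].astype("int64") if len(df) else pd.Series(dtype="int64"),
            "end": df[2].astype("int64") if len(df) else pd.Series(dtype="int64"),
        }
    )
    extra_types = {"context": str, "n_dmps": "int64", "mean_delta": float, "direction": "int64"}
    for j, name in enumerate(DMR_EXTRA_COLUMNS, start=3):
        if df.shape[1] > j and len(df):
            try:
                out[name] = df[j].astype(extra_types[name])
            except (ValueError, TypeError):
                break  # non-canonical extra columns: keep the parsed prefix
    return DMRSet(regions=out, set_id=set_id or path.stem)


def write_region_set(dmrset: DMRSet, path: str | Path) -> None:
    """Write a region set as BED3 plus any known statistic columns."""
    cols = ["chrom", "start", "end"] + [
        c for c in DMR_EXTRA_COLUMNS if c in dmrset.regions.columns
    ]
    dmrset.regions.to_csv(
        path, sep="\t", header=False, index=False, columns=cols, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    values_path: str | Path,
    feature_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> ExpressionMatrix:
    """Load a TSV expression matrix plus its feature and sample metadata."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    feature_meta = pd.read_csv(feature_meta_path, sep="\t", index_col=0, dtype=str)
    feature_meta = feature_meta.fillna("")
    sample_meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0, dtype=str)
    return ExpressionMatrix(values=values, feature_meta=feature_meta, sample_meta=sample_meta)


def write_expression_matrix(
    matrix: ExpressionMatrix,
    values_path: str | Path,
    feature_meta_path: str | Path,
    sample_meta_path: str | Path,
) -> None:
    matrix.values.to_csv(values_path, sep="\t", float_format="%.10g")
    matrix.feature_meta.to_csv(feature_meta_path, sep="\t")
    matrix.sample_meta.to_csv(sample_meta_path, sep="\t")


# ---------------------------------------------------------------------------
# genome sequences


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load chromosome sequences from a FASTA file (indexed via pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# record helpers


def records_to_dataframe(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records], columns=CX_COLUMNS)
    if not len(df):
        df = df.astype(
            {"pos": "int64", "n_meth": "int64", "n_unmeth": "int64"}, errors="ignore"
        )
    return df
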