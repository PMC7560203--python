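"""Weighted methylation levels, replicate pooling, conversion-rate QC and
chromosome-window tracks.

All level summaries use the *weighted* convention of WGBS practice:
total methylated read counts divided by total read counts over the
cytosines considered — never the unweighted mean of per-cytosine ratios,
which is dominated by low-coverage sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sequence import classify_context, context_from_trinucleotide  # noqa: F401  (re-export)
from .io_formats import CX_COLUMNS, MethylomeSample


@dataclass(frozen=True)
class LevelSummary:
    """Aggregate methylation over a set of cytosines.

    ``level`` is ``nan`` when no reads cover the set (missing, not zero).
    """

    context: str | None
    n_cytosines: int
    total_meth: int
    total_unmeth: int

    @property
    def level(self) -> float:
        denom = self.total_meth + self.total_unmeth
        if denom == 0:
            return float("nan")
        return self.total_meth / denom


def _records_of(sample_or_df) -> pd.DataFrame:
    if isinstance(sample_or_df, MethylomeSample):
        return sample_or_df.records
    return sample_or_df


def weighted_level(records, context: str | None = None) -> LevelSummary:
    """Count-sum methylation level over (optionally context-filtered) records."""
    df = _records_of(records)
    if context is not None:
        df = df[df["context"] == context]
    return LevelSummary(
        context=context,
        n_cytosines=int(len(df)),
        total_meth=int(df["n_meth"].sum()),
        total_unmeth=int(df["n_unmeth"].sum()),
    )


def pool_samples(samples: list[MethylomeSample], sample_id: str | None = None) -> MethylomeSample:
    """Sum counts per (chrom, pos, strand) across replicate samples.

    Replicates must share genome, stage and fraction; the pooled sample
    covers the union of their positions.
    """
    if not samples:
        raise ValueError("need at least one sample to pool")
    first = samples[0]
    for s in samples[1:]:
        if (s.genome_id, s.stage, s.fraction) != (first.genome_id, first.stage, first.fraction):
            raise ValueError(
                f"cannot pool {s.sample_id}: stage/fraction/genome mismatch with {first.sample_id}"
            )
    cat = pd.concat([s.records for s in samples], ignore_index=True)
    pooled = (
        cat.groupby(["chrom", "pos", "strand"], sort=True, as_index=False)
        .agg(
            n_meth=("n_meth", "sum"),
            n_unmeth=("n_unmeth", "sum"),
            context=("context", "first"),
            trinucleotide=("trinucleotide", "first"),
        )
        .loc[:, CX_COLUMNS]
    )
    return MethylomeSample(
        sample_id=sample_id or "+".join(s.sample_id for s in samples),
        stage=first.stage,
        fraction=first.fraction,
        records=pooled,
        genome_id=first.genome_id,
    )


def estimate_conversion_rate(sample: MethylomeSample, control_chrom: str) -> float:
    """Bisulfite conversion rate from an unmethylated control contig.

    The control (the chloroplast in plant WGBS) is assumed fully
    unmethylated, so every methylated call there is a conversion failure:
    rate = sum(n_unmeth) / sum(n_meth + n_unmeth) over the control.
    """
    ctrl = sample.subset_chrom(control_chrom)
    total = int(ctrl["n_meth"].sum() + ctrl["n_unmeth"].sum())
    if total == 0:
        raise ValueError(f"no covered cytosines on control contig {control_chrom!r}")
    return int(ctrl["n_unmeth"].sum()) / total


def correct_level(level: float, conversion_rate: float) -> float:
    """Subtract the conversion-failure floor: level' = max(0, (level - f)/(1 - f))
    with f = 1 - conversion_rate. Off by default in all summaries (QC only)."""
    f = 1.0 - conversion_rate
    if f >= 1.0:
        raise ValueError("conversion rate must be > 0")
    return max(0.0, (level - f) / (1.0 - f))


def window_track(
    sample: MethylomeSample,
    window: int,
    step: int,
    context: str | None = None,
    chrom_lengths: dict[str, int] | None = None,
    min_cov: int = 0,
) -> pd.DataFrame:
    """Sliding-window weighted levels per chromosome.

    Windows tile ``[0, chrom_len)`` at the given step; a window with no
    covered cytosines gets level ``nan`` (missing, not zero). Chromosome
    lengths default to the last covered position.
    """
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    df = _records_of(sample)
    if context is not None:
        df = df[df["context"] == context]
    if min_cov > 0:
        df = df[(df["n_meth"] + df["n_unmeth"]) >= min_cov]
    out = []
    chroms = sorted(chrom_lengths) if chrom_lengths is not None else sorted(df["chrom"].unique())
    for chrom in chroms:
        sub = df[df["chrom"] == chrom]
        pos0 = sub["pos"].to_numpy() - 1  # report positions are 1-based
        meth = sub["n_meth"].to_numpy()
        unmeth = sub["n_unmeth"].to_numpy()
        clen = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else (int(pos0[-1]) + 1 if len(pos0) else 0)
        )
        starts = np.arange(0, max(clen, 1), step, dtype="int64")
        ends = np.minimum(starts + window, clen)
        cmeth = np.concatenate([[0], np.cumsum(meth)])
        cunmeth = np.concatenate([[0], np.cumsum(unmeth)])
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        wmeth = cmeth[hi] - cmeth[lo]
        wunmeth = cunmeth[hi] - cunmeth[lo]
        denom = wmeth + wunmeth
        with np.errstate(invalid="ignore"):
            level = np.where(denom > 0, wmeth / np.maximum(denom, 1), np.nan)
        out.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "context": context if context is not None else "all",
                    "n_cytosines": hi - lo,
                    "level": level,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "context", "n_cytosines", "level"]
        )
    return pd.concat(out, ignore_index=True)
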