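"""Metagene/meta-TE methylation profiles and LOWESS of level versus
element length.

Metaplots average methylation over a set of features in three panels:
a fixed-bp upstream flank, the feature body rescaled to fractional
coordinates, and a fixed-bp downstream flank, all oriented 5'->3' by the
feature's strand (strandless features are treated as plus). Bin levels use
count-sum aggregation across *all* features (total methylated reads over
total reads per bin), so short or lowly covered features do not dominate.
A cytosine overlapping several features contributes to each of their
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io_formats import AnnotationFeature, MethylomeSample
from .methylation_core import weighted_level


@dataclass
class MetaProfile:
    """Aggregated methylation profile over features.

    ``upstream`` / ``body`` / ``downstream`` are per-bin weighted levels
    (``nan`` where no reads fell in a bin), already oriented 5'->3'.
    """

    context: str
    n_features: int
    flank: int
    flank_bins: int
    body_bins: int
    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    bin_meth: np.ndarray  # raw count sums, concatenated panels
    bin_total: np.ndarray

    @property
    def levels(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])

    def to_frame(self) -> pd.DataFrame:
        panel = (
            ["upstream"] * self.flank_bins
            + ["body"] * self.body_bins
            + ["downstream"] * self.flank_bins
        )
        return pd.DataFrame(
            {
                "panel": panel,
                "bin": list(range(self.flank_bins))
                + list(range(self.body_bins))
                + list(range(self.flank_bins)),
                "level": self.levels,
                "total_reads": self.bin_total,
            }
        )


def metaplot(
    sample: MethylomeSample,
    features: Sequence[AnnotationFeature],
    context: str,
    flank: int = 2000,
    flank_bins: int = 20,
    body_bins: int = 40,
) -> MetaProfile:
    """Count-sum metaplot of one context over features plus flanks.

    Flank bins are fixed-width (``flank / flank_bins`` bp); body bins are
    fractional. Flank bins never include cytosines from inside the body:
    the upstream panel covers exactly [start - flank, start) and the
    downstream panel [end, end + flank) in genomic coordinates (swapped
    and mirrored for minus-strand features).
    """
    if not features:
        raise ValueError("need at least one feature")
    n_bins = 2 * flank_bins + body_bins
    meth = np.zeros(n_bins)
    total = np.zeros(n_bins)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    recs = sample.records[sample.records["context"] == context]
    for chrom, g in recs.groupby("chrom"):
        pos0 = g["pos"].to_numpy() - 1
        order = np.argsort(pos0, kind="mergesort")
        pos0 = pos0[order]
        cm = np.concatenate([[0], np.cumsum(g["n_meth"].to_numpy()[order])])
        ct = np.concatenate([[0], np.cumsum((g["n_meth"] + g["n_unmeth"]).to_numpy()[order])])
        by_chrom[chrom] = (pos0, cm, ct)

    for f in features:
        if f.chrom not in by_chrom:
            continue
        pos0, cm, ct = by_chrom[f.chrom]
        # genomic bin edges: upstream flank, fractional body, downstream flank
        up = f.start - flank + np.arange(flank_bins + 1) * (flank / flank_bins)
        body = f.start + np.arange(body_bins + 1) * ((f.end - f.start) / body_bins)
        down = f.end + np.arange(flank_bins + 1) * (flank / flank_bins)
        edges = np.concatenate([up, body[1:], down[1:]])
        idx = np.searchsorted(pos0, np.ceil(edges).astype("int64"), side="left")
        bm = cm[idx[1:]] - cm[idx[:-1]]
        bt = ct[idx[1:]] - ct[idx[:-1]]
        if f.strand == "-":
            bm, bt = bm[::-1], bt[::-1]
        meth += bm
        total += bt

    with np.errstate(invalid="ignore"):
        levels = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    return MetaProfile(
        context=context,
        n_features=len(features),
        flank=flank,
        flank_bins=flank_bins,
        body_bins=body_bins,
        upstream=levels[:flank_bins],
        body=levels[flank_bins : flank_bins + body_bins],
        downstream=levels[flank_bins + body_bins :],
        bin_meth=meth,
        bin_total=total,
    )


def per_feature_level(
    sample: MethylomeSample,
    feature: AnnotationFeature,
    context: str,
    min_cov: int = 1,
) -> float:
    """Weighted level of one context inside one feature; ``nan`` when fewer
    than ``min_cov`` covered cytosines fall inside."""
    df = sample.subset_chrom(feature.chrom)
    df = df[(df["context"] == context) & (df["pos"] > feature.start) & (df["pos"] <= feature.end)]
    covered = df[(df["n_meth"] + df["n_unmeth"]) > 0]
    if len(covered) < min_cov:
        return float("nan")
    return weighted_level(covered).level


def lowess_length_fit(
    lengths: Sequence[float],
    levels: Sequence[float],
    frac: float = 0.3,
    iters: int = 2,
) -> pd.DataFrame:
    """LOWESS fit of per-feature methylation level versus feature length.

    Tricube-weighted local linear regression with bisquare robustifying
    iterations; undefined (nan) levels are dropped. Returns a DataFrame
    with columns ``length`` and ``level`` sorted by length, one row per
    distinct length.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(levels, dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(x)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError(f"need >= 10 features with defined levels, got {len(x)}")
    fit = _sm_lowess(y, x, frac=frac, it=iters, return_sorted=True)
    out = pd.DataFrame({"length": fit[:, 0], "level": fit[:, 1]})
    return out.drop_duplicates("length").reset_index(drop=True)
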