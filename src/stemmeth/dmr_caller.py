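"""Differential methylation: Fisher-exact DMP calling and 50-bp clustering
into DMRs.

A differentially methylated position (DMP) is a single cytosine whose
methylated/unmethylated counts differ between two samples by a two-sided
Fisher's exact test. DMPs on a chromosome are then clustered: consecutive
DMPs at most ``max_gap`` bp apart (default 50) join one differentially
methylated region (DMR); clusters with fewer than ``min_dmps`` members are
discarded.

The Fisher p-value is computed by exact integer-weight enumeration of the
hypergeometric distribution (rational-safe for the table totals seen in
WGBS), so it is reproducible to full precision and independent of any
statistics library's tie-handling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DMRSet, MethylomeSample
from .methylation_core import weighted_level

logger = logging.getLogger(__name__)

#: relative tolerance for the "probability <= observed" comparison when the
#: enumeration has to fall back to floating point (totals > 10,000)
_P_TOL = 1e-12


@dataclass(frozen=True)
class DMP:
    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    p_value: float
    level_a: float
    level_b: float

    @property
    def direction(self) -> int:
        return int(np.sign(self.level_b - self.level_a))


@lru_cache(maxsize=200_000)
def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is <= that of the observed table. For totals
    up to 10,000 the comparison and summation use exact integer weights
    C(r1, k) * C(r2, c1 - k); beyond that, floating-point hypergeometric
    pmfs with a 1e-12 relative tolerance on the comparison.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, r2, c1 = a + b, c + d, a + c
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    if n <= 10_000:
        weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)]
        w_obs = weights[a - kmin]
        num = sum(w for w in weights if w <= w_obs)
        return float(num / sum(weights))
    ks = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[a - kmin]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + _P_TOL)].sum()))


def _combine_cg_dyads(df: pd.DataFrame) -> pd.DataFrame:
    """Sum the two strands of each CG dyad (symmetric CG methylation).

    The dyad is keyed by the plus-strand C position: a minus-strand CG at
    position p pairs with the plus-strand C at p - 1.
    """
    df = df.copy()
    df["pos"] = np.where(df["strand"] == "-", df["pos"] - 1, df["pos"])
    out = (
        df.groupby(["chrom", "pos"], sort=True, as_index=False)
        .agg(n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum"))
    )
    out["strand"] = "+"
    out["context"] = "CG"
    return out


def call_dmps(
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    context: str,
    alpha: float = 0.01,
    min_cov: int = 4,
    mtc: str = "none",
    combine_cg_strands: bool | None = None,
) -> pd.DataFrame:
    """Call DMPs between two samples at cytosines of one context.

    Only cytosines covered by at least ``min_cov`` reads in *both* samples
    are tested. ``mtc`` selects multiple-testing handling: ``"none"``
    (raw p < alpha) or ``"BH"`` (Benjamini-Hochberg adjusted p < alpha).
    For CG, the two strands of each dyad are summed before testing by
    default (``combine_cg_strands``), halving the number of tests.

    Returns a DataFrame with columns chrom, pos, strand, context, p_value,
    level_a, level_b, direction, sorted by (chrom, pos).
    """
    if mtc not in ("none", "BH"):
        raise ValueError(f"unknown mtc mode {mtc!r}")
    if combine_cg_strands is None:
        combine_cg_strands = context == "CG"
    cols = ["chrom", "pos", "strand", "n_meth", "n_unmeth"]
    da = sample_a.records.loc[sample_a.records["context"] == context, cols]
    db = sample_b.records.loc[sample_b.records["context"] == context, cols]
    if combine_cg_strands and context == "CG":
        da = _combine_cg_dyads(da)[cols]
        db = _combine_cg_dyads(db)[cols]
    merged = da.merge(db, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    cov_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    cov_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    merged = merged[(cov_a >= min_cov) & (cov_b >= min_cov)].reset_index(drop=True)
    if not len(merged):
        logger.warning(
            "no shared covered %s cytosines between %s and %s",
            context, sample_a.sample_id, sample_b.sample_id,
        )
        return _empty_dmp_frame()
    p = np.fromiter(
        (
            fisher_exact_2x2(int(ma), int(ua), int(mb), int(ub))
            for ma, ua, mb, ub in zip(
                merged["n_meth_a"], merged["n_unmeth_a"],
                merged["n_meth_b"], merged["n_unmeth_b"],
            )
        ),
        dtype=float,
        count=len(merged),
    )
    if mtc == "BH":
        from statsmodels.stats.multitest import multipletests

        p_adj = multipletests(p, method="fdr_bh")[1]
    else:
        p_adj = p
    level_a = merged["n_meth_a"] / (merged["n_meth_a"] + merged["n_unmeth_a"])
    level_b = merged["n_meth_b"] / (merged["n_meth_b"] + merged["n_unmeth_b"])
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "strand": merged["strand"],
            "context": context,
            "p_value": p,
            "level_a": level_a,
            "level_b": level_b,
            "direction": np.sign(level_b - level_a).astype("int64"),
        }
    )
    out = out[p_adj < alpha]
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _empty_dmp_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype="int64"),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "p_value": pd.Series(dtype=float),
            "level_a": pd.Series(dtype=float),
            "level_b": pd.Series(dtype=float),
            "direction": pd.Series(dtype="int64"),
        }
    )


def cluster_dmps(dmps: pd.DataFrame, max_gap: int = 50, min_dmps: int = 2) -> DMRSet:
    """Cluster sorted DMPs into DMRs with the maximum-gap rule.

    Consecutive DMPs on the same chromosome join one cluster iff their
    positions differ by at most ``max_gap`` bp (a separation strictly
    greater than ``max_gap`` splits). Clusters with fewer than ``min_dmps``
    DMPs are discarded. Each DMR spans [min_pos - 1, max_pos) in 0-based
    half-open coordinates, so a single-DMP region spans 1 bp.
    """
    if len(dmps) == 0:
        return DMRSet(regions=pd.DataFrame(columns=[
            "chrom", "start", "end", "context", "n_dmps", "mean_delta", "direction"
        ]))
    by_chrom = dmps.groupby("chrom", sort=True)
    for _, g in by_chrom:
        if not g["pos"].is_monotonic_increasing:
            raise ValueError("DMPs must be sorted by (chrom, pos)")
    rows = []
    for (chrom, context), g in dmps.groupby(["chrom", "context"], sort=True):
        pos = g["pos"].to_numpy()
        delta = (g["level_b"] - g["level_a"]).to_numpy()
        new_cluster = np.concatenate([[True], np.diff(pos) > max_gap])
        cid = np.cumsum(new_cluster)
        for c in np.unique(cid):
            sel = cid == c
            if sel.sum() < min_dmps:
                continue
            p = pos[sel]
            mean_delta = float(delta[sel].mean())
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(p.min()) - 1,
                    "end": int(p.max()),
                    "context": context,
                    "n_dmps": int(sel.sum()),
                    "mean_delta": mean_delta,
                    "direction": int(np.sign(mean_delta)),
                }
            )
    return DMRSet(regions=pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "n_dmps", "mean_delta", "direction"]
    ))


def score_dmrs(
    dmrset: DMRSet, sample_a: MethylomeSample, sample_b: MethylomeSample
) -> DMRSet:
    """Attach the weighted-level difference (b - a) to each region.

    The delta is computed over cytosines of the region's context inside the
    region; a region with no covered cytosines in either sample gets a
    ``nan`` delta and ``covered=False``.
    """
    regions = dmrset.regions.copy()
    deltas, covered = [], []
    for row in regions.itertuples(index=False):
        context = getattr(row, "context", None)
        sub_a = _region_records(sample_a, row.chrom, row.start, row.end, context)
        sub_b = _region_records(sample_b, row.chrom, row.start, row.end, context)
        la = weighted_level(sub_a).level
        lb = weighted_level(sub_b).level
        ok = not (math.isnan(la) or math.isnan(lb))
        covered.append(ok)
        deltas.append(lb - la if ok else float("nan"))
    regions["delta"] = deltas
    regions["covered"] = covered
    return DMRSet(regions=regions, set_id=dmrset.set_id)


def _region_records(
    sample: MethylomeSample, chrom: str, start: int, end: int, context: str | None
) -> pd.DataFrame:
    df = sample.subset_chrom(chrom)
    # 1-based pos p lies in 0-based half-open [start, end) iff start < p <= end
    df = df[(df["pos"] > start) & (df["pos"] <= end)]
    if context:
        df = df[df["context"] == context]
    return df


def interval_jaccard(start_a: int, end_a: int, start_b: int, end_b: int) -> float:
    inter = max(0, min(end_a, end_b) - max(start_a, start_b))
    union = (end_a - start_a) + (end_b - start_b) - inter
    return inter / union if union else 0.0


def evaluate_against_truth(
    called: DMRSet, truth: DMRSet, min_jaccard: float = 0.5
) -> tuple[float, float]:
    """Region-level precision/recall of called DMRs against planted truth.

    A truth region is recovered if some called DMR on the same chromosome
    reaches the interval-Jaccard threshold with it; symmetrically for
    precision. With no called regions, precision is ``nan`` and recall 0.
    """
    cr, tr = called.regions, truth.regions
    def _hits(queries: pd.DataFrame, targets: pd.DataFrame) -> int:
        n = 0
        for q in queries.itertuples(index=False):
            cand = targets[targets["chrom"] == q.chrom]
            if any(
                interval_jaccard(q.start, q.end, t.start, t.end) >= min_jaccard
                for t in cand.itertuples(index=False)
            ):
                n += 1
        return n

    recall = _hits(tr, cr) / len(tr) if len(tr) else float("nan")
    precision = _hits(cr, tr) / len(cr) if len(cr) else float("nan")
    return precision, recall
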