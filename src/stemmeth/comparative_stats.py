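"""Permutation z-score enrichment of methylation differences within region
sets, and PCA-based sample relatedness over region-level methylation.

The enrichment procedure follows a four-step scheme: (1) take an external
region set (e.g. DMRs of a methylation mutant versus wild type); (2)
compute the mean per-cytosine methylation difference between two samples
over cytosines inside those regions; (3) draw ``n_perm`` random region
*sets* matched to the template in region count and lengths, placed
uniformly across the genome (chromosome chosen proportional to its length,
irrespective of TE overlap; the unmethylated control contig is excluded),
and recompute the same statistic for each; (4) report
``z = (observed - mean(permuted)) / sd(permuted)`` with sample standard
deviation. A positive z means the first-listed "b" sample (stem cells, in
the study design) is more methylated than "a" inside the set than expected
at random.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import DMRSet, MethylomeSample
from .synthetic_data import GenomeModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    region_set_id: str
    context: str
    observed_stat: float
    n_cytosines_observed: int
    perm_mean: float
    perm_sd: float
    z: float
    n_perm: int
    n_perm_used: int
    seed: int


@dataclass
class PCAResult:
    """Sample coordinates on principal components of a centered
    region-by-sample methylation matrix (no variance scaling).

    Coordinates are reproducible up to a per-axis sign flip.
    """

    coordinates: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray
    n_features: int

    def coords(self, sample: str, n_pcs: int | None = None) -> np.ndarray:
        if sample not in self.coordinates.index:
            raise KeyError(f"unknown sample {sample!r}")
        v = self.coordinates.loc[sample].to_numpy()
        return v[:n_pcs] if n_pcs is not None else v


# ---------------------------------------------------------------------------
# per-cytosine difference machinery


def _diff_tables(
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    context: str,
    min_cov: int,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: sorted 0-based positions of context cytosines covered
    >= min_cov in both samples, with per-cytosine level difference (b - a)."""
    cols = ["chrom", "pos", "strand", "n_meth", "n_unmeth"]
    da = sample_a.records.loc[sample_a.records["context"] == context, cols]
    db = sample_b.records.loc[sample_b.records["context"] == context, cols]
    m = da.merge(db, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    cov_a = m["n_meth_a"] + m["n_unmeth_a"]
    cov_b = m["n_meth_b"] + m["n_unmeth_b"]
    m = m[(cov_a >= max(min_cov, 1)) & (cov_b >= max(min_cov, 1))]
    diff = (
        m["n_meth_b"] / (m["n_meth_b"] + m["n_unmeth_b"])
        - m["n_meth_a"] / (m["n_meth_a"] + m["n_unmeth_a"])
    ).to_numpy()
    pos0 = m["pos"].to_numpy() - 1
    tables = {}
    for chrom in m["chrom"].unique():
        sel = (m["chrom"] == chrom).to_numpy()
        p = pos0[sel]
        d = diff[sel]
        order = np.argsort(p, kind="mergesort")
        p, d = p[order], d[order]
        tables[chrom] = (p, np.concatenate([[0.0], np.cumsum(d)]))
    return tables


def _region_sums(
    tables: Mapping[str, tuple[np.ndarray, np.ndarray]],
    chroms: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
) -> tuple[float, int]:
    total, n = 0.0, 0
    for chrom in np.unique(chroms):
        if chrom not in tables:
            continue
        pos0, cdiff = tables[chrom]
        sel = chroms == chrom
        lo = np.searchsorted(pos0, starts[sel], side="left")
        hi = np.searchsorted(pos0, ends[sel], side="left")
        total += float((cdiff[hi] - cdiff[lo]).sum())
        n += int((hi - lo).sum())
    return total, n


def region_methylation_difference(
    regions: DMRSet,
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    context: str,
    min_cov: int = 4,
) -> tuple[float, int]:
    """Mean per-cytosine level difference (b - a) over region cytosines.

    Uses every cytosine of the context inside any region that is covered by
    at least ``min_cov`` reads in both samples. Returns (stat, n_cytosines);
    the stat is ``nan`` when no cytosine qualifies.
    """
    tables = _diff_tables(sample_a, sample_b, context, min_cov)
    df = regions.regions
    total, n = _region_sums(
        tables,
        df["chrom"].to_numpy(),
        df["start"].to_numpy(),
        df["end"].to_numpy(),
    )
    if n == 0:
        logger.warning("no qualifying %s cytosines in region set %s", context, regions.set_id)
        return float("nan"), 0
    return total / n, n


# ---------------------------------------------------------------------------
# matched random regions


def _chrom_length_map(genome) -> dict[str, int]:
    if isinstance(genome, GenomeModel):
        return {c: genome.chrom_lengths[c] for c in genome.nuclear_chroms}
    return dict(genome)


def _sample_matched_arrays(
    chrom_lengths: dict[str, int],
    template_lengths: np.ndarray,
    n_perm: int,
    seed: int,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Core placement: for each permutation and template region, a random
    (chromosome, start) such that the region fits; chromosome probability
    proportional to its length among chromosomes long enough."""
    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype="int64")
    rng = np.random.default_rng(seed)
    R = len(template_lengths)
    chrom_idx = np.empty((n_perm, R), dtype="int64")
    starts = np.empty((n_perm, R), dtype="int64")
    for j, L in enumerate(template_lengths):
        elig = np.flatnonzero(lens >= L)
        if len(elig) == 0:
            raise ValueError(f"template region of {L} bp longer than every chromosome")
        p = lens[elig] / lens[elig].sum()
        ci = elig[rng.choice(len(elig), size=n_perm, p=p)]
        u = rng.random(n_perm)
        starts[:, j] = (u * (lens[ci] - L + 1)).astype("int64")
        chrom_idx[:, j] = ci
    return chroms, chrom_idx, starts


def sample_matched_regions(
    genome,
    template: DMRSet,
    n_perm: int,
    seed: int,
) -> list[DMRSet]:
    """Draw ``n_perm`` random region sets matched to the template.

    Each permuted set has the template's region count, with each region's
    length copied from the corresponding template region. The control
    contig is excluded when a :class:`GenomeModel` is given.
    """
    if len(template) == 0:
        raise ValueError("template region set is empty")
    chrom_lengths = _chrom_length_map(genome)
    tlen = (template.regions["end"] - template.regions["start"]).to_numpy()
    chroms, chrom_idx, starts = _sample_matched_arrays(chrom_lengths, tlen, n_perm, seed)
    names = np.array(chroms)
    out = []
    for i in range(n_perm):
        out.append(
            DMRSet(
                regions=pd.DataFrame(
                    {
                        "chrom": names[chrom_idx[i]],
                        "start": starts[i],
                        "end": starts[i] + tlen,
                    }
                ),
                set_id=f"perm{i}",
            )
        )
    return out


def permutation_zscore(
    regions: DMRSet,
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    context: str,
    genome,
    n_perm: int = 1000,
    min_cov: int = 4,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation z-score of the region-set methylation difference.

    Permuted sets whose statistic is undefined (no qualifying cytosines)
    are dropped; more than 50% undefined raises (the genome is too sparse
    for the template)."""
    tables = _diff_tables(sample_a, sample_b, context, min_cov)
    df = regions.regions
    obs_total, obs_n = _region_sums(
        tables, df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
    )
    if obs_n == 0:
        raise ValueError(
            f"observed statistic undefined: no qualifying {context} cytosines "
            f"in region set {regions.set_id!r}"
        )
    observed = obs_total / obs_n
    chrom_lengths = _chrom_length_map(genome)
    tlen = (df["end"] - df["start"]).to_numpy()
    chroms, chrom_idx, starts = _sample_matched_arrays(chrom_lengths, tlen, n_perm, seed)
    names = np.array(chroms)
    perm_vals = []
    for i in range(n_perm):
        total, n = _region_sums(tables, names[chrom_idx[i]], starts[i], starts[i] + tlen)
        if n > 0:
            perm_vals.append(total / n)
    if len(perm_vals) < n_perm / 2:
        raise ValueError(
            f"{n_perm - len(perm_vals)}/{n_perm} permuted statistics undefined; "
            "genome coverage too sparse for this template"
        )
    if len(perm_vals) < n_perm:
        logger.warning("dropped %d/%d undefined permuted sets", n_perm - len(perm_vals), n_perm)
    pv = np.asarray(perm_vals)
    perm_mean = float(pv.mean())
    perm_sd = float(pv.std(ddof=1))
    z = (observed - perm_mean) / perm_sd if perm_sd > 0 else float("nan")
    return EnrichmentResult(
        region_set_id=regions.set_id,
        context=context,
        observed_stat=observed,
        n_cytosines_observed=obs_n,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        z=float(z),
        n_perm=n_perm,
        n_perm_used=len(pv),
        seed=seed,
    )


def cell_seed(seed: int, set_name: str, contrast_name: str, context: str) -> int:
    """Stable per-cell seed for :func:`enrichment_matrix` (crc32-derived,
    < 2^31), so any matrix cell is reproducible standalone."""
    return zlib.crc32(f"{seed}:{set_name}:{contrast_name}:{context}".encode()) & 0x7FFFFFFF


def enrichment_matrix(
    mutant_dmr_sets: Mapping[str, DMRSet],
    contrasts: Sequence[tuple[str, MethylomeSample, MethylomeSample]],
    contexts: Sequence[str],
    genome,
    n_perm: int = 1000,
    min_cov: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """z for every (region set x contrast x context) cell.

    Rows are region-set names; columns a (contrast, context) MultiIndex.
    Positive z: the "b" sample of the contrast (stem) is more methylated
    inside the set than random expectation. Per-cell failures become NaN.
    """
    cols = pd.MultiIndex.from_product(
        [[name for name, _, _ in contrasts], list(contexts)],
        names=["contrast", "context"],
    )
    mat = pd.DataFrame(index=list(mutant_dmr_sets), columns=cols, dtype=float)
    for set_name, dmrset in mutant_dmr_sets.items():
        for contrast_name, a, b in contrasts:
            for context in contexts:
                try:
                    res = permutation_zscore(
                        dmrset, a, b, context, genome,
                        n_perm=n_perm, min_cov=min_cov,
                        seed=cell_seed(seed, set_name, contrast_name, context),
                    )
                    mat.loc[set_name, (contrast_name, context)] = res.z
                except (ValueError, KeyError) as exc:
                    logger.warning(
                        "cell (%s, %s, %s) failed: %s", set_name, contrast_name, context, exc
                    )
                    mat.loc[set_name, (contrast_name, context)] = float("nan")
    return mat


# ---------------------------------------------------------------------------
# region-level PCA


def assemble_region_feature_matrix(
    samples: Sequence[MethylomeSample],
    regions: DMRSet,
    context: str,
    min_cov: int = 4,
) -> pd.DataFrame:
    """Region x sample matrix of weighted methylation levels.

    A region must carry at least ``min_cov`` reads over its context
    cytosines in *every* sample, otherwise it is dropped (no imputation).
    Raises if fewer than 3 regions survive.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    df = regions.regions
    levels = np.empty((len(df), len(samples)))
    ok = np.ones(len(df), dtype=bool)
    for j, s in enumerate(samples):
        sub = s.records[s.records["context"] == context]
        for chrom in df["chrom"].unique():
            c = sub[sub["chrom"] == chrom]
            pos0 = c["pos"].to_numpy() - 1
            order = np.argsort(pos0, kind="mergesort")
            pos0 = pos0[order]
            cmeth = np.concatenate([[0], np.cumsum(c["n_meth"].to_numpy()[order])])
            ctot = np.concatenate(
                [[0], np.cumsum((c["n_meth"] + c["n_unmeth"]).to_numpy()[order])]
            )
            sel = (df["chrom"] == chrom).to_numpy()
            lo = np.searchsorted(pos0, df.loc[sel, "start"].to_numpy(), side="left")
            hi = np.searchsorted(pos0, df.loc[sel, "end"].to_numpy(), side="left")
            meth = cmeth[hi] - cmeth[lo]
            tot = ctot[hi] - ctot[lo]
            ok[sel] &= tot >= max(min_cov, 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                levels[sel, j] = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d/%d regions under-covered in at least one sample", n_dropped, len(df))
    idx = [f"{r.chrom}:{r.start}-{r.end}" for r in df.itertuples(index=False)]
    mat = pd.DataFrame(levels, index=idx, columns=[s.sample_id for s in samples])[ok]
    if len(mat) < 3:
        raise ValueError(f"only {len(mat)} regions covered in all samples; need >= 3")
    return mat


def pca(matrix: pd.DataFrame) -> PCAResult:
    """PCA of a feature x sample matrix by SVD of the feature-centered data.

    No variance scaling (all features share the [0, 1] level scale).
    Sample coordinates are the projections onto the principal axes;
    explained-variance fractions are normalized squared singular values.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 3:
        raise ValueError("need >= 2 samples and >= 3 features")
    x = matrix.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        ratio = np.zeros(len(s))
        coords = np.zeros((matrix.shape[1], len(s)))
    else:
        ratio = s**2 / total
        coords = (s[:, None] * vt).T  # samples x PCs
    return PCAResult(
        coordinates=pd.DataFrame(
            coords,
            index=matrix.columns,
            columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
        ),
        explained_variance_ratio=ratio,
        n_features=matrix.shape[0],
    )


def convergence_distance(
    pca_result: PCAResult,
    reference_sample: str,
    query_samples: Sequence[str],
    n_pcs: int = 2,
) -> pd.Series:
    """Euclidean distances from each query to the reference in the first
    ``n_pcs`` PCs, sorted ascending (smallest = most similar)."""
    ref = pca_result.coords(reference_sample, n_pcs)
    d = {q: float(np.linalg.norm(pca_result.coords(q, n_pcs) - ref)) for q in query_samples}
    return pd.Series(d, name="distance").sort_values()
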