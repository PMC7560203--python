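"""Synthetic genomes, methylomes and expression matrices with the
statistical structure the analysis assumes.

The generator emulates a small plant-like genome: AT-rich random sequence,
transposable elements clustered around the centromere (triangular placement
density), genes on the arms, and an extra fully unmethylated control contig
playing the role of the chloroplast for conversion-rate estimation. True
per-cytosine methylation probabilities follow context- and
feature-dependent means (high mCG at TEs and gene bodies, lower and more
dynamic mCHG/mCHH at TEs) with beta-distributed site-to-site
overdispersion. Observed counts arise per cytosine as Poisson coverage and
binomial methylated calls, with bisulfite conversion failure inflating the
apparent level by ``p_obs = p + (1 - p) * conversion_failure``.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._sequence import find_cytosines
from .io_formats import (
    CX_COLUMNS,
    AnnotationFeature,
    DMRSet,
    ExpressionMatrix,
    MethylomeSample,
)

CONTROL_CONTIG = "plastid"

_SUPERFAMILIES = ("LTR/COPIA", "LTR/GYPSY", "LINE/L1", "DNA/MuDR", "RC/Helitron")
_FAMILY_PREFIX = {
    "LTR/COPIA": "ATCOPIA",
    "LTR/GYPSY": "ATHILA",
    "LINE/L1": "ATLINE",
    "DNA/MuDR": "VANDAL",
    "RC/Helitron": "ATREP",
}


@dataclass
class GenomeModel:
    """A synthetic genome: sequences, feature annotation, centromeres and
    the unmethylated control contig."""

    chrom_lengths: dict[str, int]
    centromere_mid: dict[str, int]
    features: list[AnnotationFeature]
    control_contig: str
    seq: dict[str, str]
    _cytosine_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def nuclear_chroms(self) -> list[str]:
        return [c for c in self.chrom_lengths if c != self.control_contig]

    def cytosines(self, chrom: str) -> np.ndarray:
        """Structured array (pos, strand, context, trinucleotide) of every
        context-defined cytosine on both strands of `chrom`."""
        if chrom not in self._cytosine_cache:
            self._cytosine_cache[chrom] = find_cytosines(self.seq[chrom])
        return self._cytosine_cache[chrom]


@dataclass
class MethylationProfile:
    """Mean true methylation level per (feature kind, context).

    Defaults sketch an Arabidopsis-like landscape: TEs methylated in all
    three contexts (strongly in CG), gene bodies carrying moderate CG-only
    methylation, and a low genomic background. ``concentration`` is the
    beta concentration of per-cytosine levels around these means; ``None``
    disables site-to-site variation (every cytosine gets the mean exactly).
    """

    means: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("TE", "CG"): 0.85,
            ("TE", "CHG"): 0.35,
            ("TE", "CHH"): 0.10,
            ("gene", "CG"): 0.20,
            ("gene", "CHG"): 0.02,
            ("gene", "CHH"): 0.02,
            ("background", "CG"): 0.05,
            ("background", "CHG"): 0.02,
            ("background", "CHH"): 0.02,
        }
    )
    concentration: float | None = 50.0

    def __post_init__(self) -> None:
        for k, v in self.means.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"profile mean for {k} outside [0, 1]: {v}")


@dataclass
class TrueMethylome:
    """Latent per-cytosine methylation probabilities for one sample.

    ``per_chrom`` maps chromosome to a DataFrame with columns pos (1-based),
    strand, context, trinucleotide, p.
    """

    genome: GenomeModel
    per_chrom: dict[str, pd.DataFrame]
    label: str = ""

    def copy(self, label: str = "") -> "TrueMethylome":
        return TrueMethylome(
            genome=self.genome,
            per_chrom={c: df.copy() for c, df in self.per_chrom.items()},
            label=label or self.label,
        )


def generate_genome(
    n_chrom: int,
    chrom_len: int,
    n_te: int,
    n_gene: int,
    seed: int,
    *,
    control_len: int = 10_000,
    n_families: int | None = None,
) -> GenomeModel:
    """Generate a genome with centromere-clustered TEs and arm genes.

    TE midpoints follow a triangular density peaked at the centromere
    (chromosome midpoint); TE lengths mix short (<2.5 kb) and long
    (>2.5 kb) classes. Features never overlap. An unmethylated control
    contig is appended.
    """
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be at least 10 kb")
    if n_te < 0 or n_gene < 0:
        raise ValueError("feature counts must be non-negative")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_lengths = {c: int(chrom_len) for c in chroms}
    centromere_mid = {c: chrom_len // 2 for c in chroms}

    # AT-rich sequence (~36% GC, Arabidopsis-like)
    bases = np.array(list("ACGT"))
    probs = [0.32, 0.18, 0.18, 0.32]
    seq = {
        c: "".join(rng.choice(bases, size=chrom_len, p=probs))
        for c in chroms
    }
    seq[CONTROL_CONTIG] = "".join(rng.choice(bases, size=control_len, p=probs))
    chrom_lengths[CONTROL_CONTIG] = control_len

    # family pool
    if n_families is None:
        n_families = max(2, min(20, n_te // 2)) if n_te else 0
    fam_super = [
        _SUPERFAMILIES[i % len(_SUPERFAMILIES)] for i in range(n_families)
    ]
    families = [
        f"{_FAMILY_PREFIX[sf]}{i + 1}" for i, sf in enumerate(fam_super)
    ]

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def _place(length: int, centromeric: bool) -> tuple[str, int] | None:
        for _ in range(200):
            chrom = chroms[rng.integers(len(chroms))]
            clen = chrom_lengths[chrom]
            if length >= clen:
                continue
            if centromeric:
                mid = rng.triangular(0, centromere_mid[chrom], clen)
                start = int(np.clip(mid - length / 2, 0, clen - length))
            else:
                start = int(rng.integers(0, clen - length))
            end = start + length
            if all(e <= start or s >= end for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                return chrom, start
        return None

    features: list[AnnotationFeature] = []
    for i in range(n_te):
        if rng.random() < 0.6:
            length = int(rng.integers(300, 2_400))
        else:
            length = int(rng.integers(2_500, 8_000))
        placed = _place(length, centromeric=True)
        if placed is None:
            raise ValueError(
                f"infeasible packing: could not place TE {i + 1}/{n_te} of {length} bp"
            )
        chrom, start = placed
        fi = int(rng.integers(n_families)) if n_families else 0
        features.append(
            AnnotationFeature(
                feature_id=f"TE{i + 1:05d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                kind="TE",
                family=families[fi] if families else "",
                superfamily=fam_super[fi] if families else "",
            )
        )
    for i in range(n_gene):
        length = int(rng.integers(800, 4_000))
        placed = _place(length, centromeric=False)
        if placed is None:
            raise ValueError(
                f"infeasible packing: could not place gene {i + 1}/{n_gene} of {length} bp"
            )
        chrom, start = placed
        features.append(
            AnnotationFeature(
                feature_id=f"gene{i + 1:05d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
                kind="gene",
            )
        )
    features.sort(key=lambda f: (f.chrom, f.start))
    return GenomeModel(
        chrom_lengths=chrom_lengths,
        centromere_mid=centromere_mid,
        features=features,
        control_contig=CONTROL_CONTIG,
        seq=seq,
    )


def _feature_kind_per_cytosine(
    genome: GenomeModel, chrom: str, pos0: np.ndarray
) -> np.ndarray:
    """'TE' / 'gene' / 'background' for each 0-based cytosine position."""
    kinds = np.full(len(pos0), "background", dtype="U10")
    feats = [f for f in genome.features if f.chrom == chrom]
    if not feats:
        return kinds
    starts = np.array([f.start for f in feats])
    ends = np.array([f.end for f in feats])
    fkind = np.array([f.kind for f in feats], dtype="U10")
    idx = np.searchsorted(starts, pos0, side="right") - 1
    ok = (idx >= 0) & (pos0 < ends[np.maximum(idx, 0)])
    kinds[ok] = fkind[idx[ok]]
    return kinds


def generate_methylome(
    genome: GenomeModel,
    profile: MethylationProfile | None = None,
    seed: int = 0,
    label: str = "",
) -> TrueMethylome:
    """Draw per-cytosine true methylation probabilities from the profile.

    Each cytosine's p is beta-distributed around the mean for its
    (feature kind, context); the control contig is exactly 0 everywhere.
    """
    profile = profile or MethylationProfile()
    rng = np.random.default_rng(seed)
    per_chrom = {}
    for chrom in genome.chrom_lengths:
        cyt = genome.cytosines(chrom)
        df = pd.DataFrame(
            {
                "pos": cyt["pos"],
                "strand": cyt["strand"],
                "context": cyt["context"],
                "trinucleotide": cyt["trinucleotide"],
            }
        )
        if chrom == genome.control_contig:
            df["p"] = 0.0
        else:
            kinds = _feature_kind_per_cytosine(genome, chrom, cyt["pos"] - 1)
            means = np.zeros(len(df))
            for (kind, context), m in profile.means.items():
                means[(kinds == kind) & (cyt["context"] == context)] = m
            c = profile.concentration
            if c is None:
                p = means
            else:
                p = np.where(
                    (means > 0) & (means < 1),
                    rng.beta(np.maximum(means, 1e-9) * c, np.maximum(1 - means, 1e-9) * c),
                    means,
                )
            df["p"] = p
        per_chrom[chrom] = df
    return TrueMethylome(genome=genome, per_chrom=per_chrom, label=label)


def plant_dmrs(
    methylome: TrueMethylome,
    n_regions: int,
    length_range: tuple[int, int] = (300, 800),
    delta: float = 0.4,
    context: str = "CHG",
    seed: int = 0,
    label: str = "",
) -> tuple[TrueMethylome, DMRSet]:
    """Plant non-overlapping differential regions into a copy of a methylome.

    Returns a second methylome whose true p is shifted by ``delta``
    (clipped to [0, 1]) at cytosines of the given context inside each
    planted region, and the ground-truth region set (with ``context`` and
    ``delta`` columns). Cytosines of other contexts are untouched, as is
    everything on the control contig.
    """
    if abs(delta) > 1:
        raise ValueError("|delta| must be <= 1")
    rng = np.random.default_rng(seed)
    genome = methylome.genome
    chroms = genome.nuclear_chroms
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for i in range(n_regions):
        ok = False
        for _ in range(500):
            chrom = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            clen = genome.chrom_lengths[chrom]
            if length >= clen:
                continue
            start = int(rng.integers(0, clen - length))
            end = start + length
            if all(e <= start or s >= end for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                rows.append({"chrom": chrom, "start": start, "end": end,
                             "context": context, "delta": float(delta)})
                ok = True
                break
        if not ok:
            raise ValueError(f"cannot place {n_regions} non-overlapping regions")
    truth = DMRSet(regions=pd.DataFrame(rows), set_id="truth")
    shifted = methylome.copy(label=label or f"{methylome.label}+planted")
    for chrom, regs in truth.regions.groupby("chrom"):
        df = shifted.per_chrom[chrom]
        sel = np.zeros(len(df), dtype=bool)
        pos = df["pos"].to_numpy()
        for r in regs.itertuples(index=False):
            sel |= (pos > r.start) & (pos <= r.end)
        sel &= (df["context"] == context).to_numpy()
        df.loc[sel, "p"] = np.clip(df.loc[sel, "p"] + delta, 0.0, 1.0)
    return shifted, truth


def sample_counts(
    methylome: TrueMethylome,
    coverage_mean: float,
    conversion_failure: float = 0.005,
    seed: int = 0,
    *,
    sample_id: str = "sample",
    stage: str = "D7",
    fraction: str = "stem",
    drop_uncovered: bool = False,
) -> MethylomeSample:
    """Sample observed counts: Poisson coverage, binomial methylated calls.

    ``n ~ Poisson(coverage_mean)`` per cytosine and
    ``n_meth ~ Binomial(n, p + (1 - p) * conversion_failure)``: a
    conversion failure makes an unmethylated cytosine read as methylated,
    the direction a chloroplast-style control measures.
    """
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    if not 0 <= conversion_failure < 1:
        raise ValueError("conversion_failure must be in [0, 1)")
    rng = np.random.default_rng(seed)
    frames = []
    for chrom in methylome.genome.chrom_lengths:
        df = methylome.per_chrom[chrom]
        n = rng.poisson(coverage_mean, size=len(df))
        p_obs = df["p"].to_numpy() * (1 - conversion_failure) + conversion_failure
        n_meth = rng.binomial(n, p_obs)
        out = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": df["pos"].to_numpy(),
                "strand": df["strand"].to_numpy(),
                "n_meth": n_meth,
                "n_unmeth": n - n_meth,
                "context": df["context"].to_numpy(),
                "trinucleotide": df["trinucleotide"].to_numpy(),
            }
        )
        if drop_uncovered:
            out = out[n > 0]
        frames.append(out)
    records = pd.concat(frames, ignore_index=True)[CX_COLUMNS]
    return MethylomeSample(
        sample_id=sample_id,
        stage=stage,
        fraction=fraction,
        records=records,
        genome_id=methylome.label or "synthetic",
    )


def generate_expression(
    features: Sequence[AnnotationFeature],
    stages: Sequence[str] = ("E", "D7", "D14", "D35"),
    upregulated_families: Iterable[str] = (),
    fold: float = 4.0,
    up_stage: str = "D7",
    housekeeping_ids: Iterable[str] = (),
    noise_cv: float = 0.2,
    seed: int = 0,
) -> ExpressionMatrix:
    """Generate a TPM-like matrix with paired stem/non-stem columns.

    Members of ``upregulated_families`` are multiplied by ``fold`` in the
    stem column of ``up_stage`` only, mimicking stage-specific TE
    activation. Housekeeping features keep a single base mean in every
    column (only multiplicative noise with coefficient of variation
    ``noise_cv``); other features additionally get a per-stage
    developmental factor shared by the paired stem/non-stem columns.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    if up_stage not in stages:
        raise ValueError(f"up_stage {up_stage!r} not among stages {stages}")
    upregulated_families = set(upregulated_families)
    housekeeping_ids = set(housekeeping_ids)
    known_families = {f.family for f in features if f.kind == "TE"}
    unknown = upregulated_families - known_families
    if unknown:
        raise ValueError(f"unknown TE families: {sorted(unknown)}")
    unknown_hk = housekeeping_ids - {f.feature_id for f in features}
    if unknown_hk:
        raise ValueError(f"unknown housekeeping feature ids: {sorted(unknown_hk)}")

    rng = np.random.default_rng(seed)
    ids = [f.feature_id for f in features]
    classes = [
        "housekeeping" if f.feature_id in housekeeping_ids
        else ("TE" if f.kind == "TE" else "protein_coding")
        for f in features
    ]
    feature_meta = pd.DataFrame(
        {
            "class": classes,
            "family": [f.family for f in features],
            "superfamily": [f.superfamily for f in features],
        },
        index=pd.Index(ids, name="feature_id"),
    )
    base = rng.lognormal(mean=np.log(10.0), sigma=1.0, size=len(features))
    is_hk = feature_meta["class"].to_numpy() == "housekeeping"
    stage_factor = {
        s: np.where(is_hk, 1.0, rng.lognormal(0.0, 0.5, size=len(features)))
        for s in stages
    }
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    else:
        sigma = 0.0
    in_up_family = np.array(
        [f.kind == "TE" and f.family in upregulated_families for f in features]
    )
    cols, col_meta = {}, []
    for s in stages:
        for frac in ("stem", "nonstem"):
            v = base * stage_factor[s]
            if s == up_stage and frac == "stem":
                v = np.where(in_up_family, v * fold, v)
            if sigma > 0:
                v = v * rng.lognormal(-sigma**2 / 2, sigma, size=len(v))
            name = f"{s}_{frac}"
            cols[name] = v
            col_meta.append({"sample": name, "stage": s, "fraction": frac})
    values = pd.DataFrame(cols, index=feature_meta.index)
    sample_meta = pd.DataFrame(col_meta).set_index("sample")
    return ExpressionMatrix(values=values, feature_meta=feature_meta, sample_meta=sample_meta)


@dataclass
class SimulationConfig:
    """Default study conditions for the bundled synthetic experiment.

    Two nuclear chromosomes plus the control contig; stem vs non-stem
    nuclei at one stage with planted context-specific DMRs (the stem
    methylome is the shifted one), a seedling sample drawn from the
    non-stem methylome, and an expression matrix across four stages with
    a set of TE families activated in stem cells of one stage.
    """

    n_chrom: int = 2
    chrom_len: int = 200_000
    n_te: int = 30
    n_gene: int = 60
    coverage_mean: float = 20.0
    conversion_failure: float = 0.005
    n_dmrs: int = 50
    dmr_length: tuple[int, int] = (300, 800)
    dmr_delta: float = 0.4
    dmr_context: str = "CHG"
    stage: str = "D7"
    expression_stages: tuple[str, ...] = ("E", "D7", "D14", "D35")
    n_up_families: int = 12
    fold: float = 4.0
    noise_cv: float = 0.2
    n_housekeeping: int = 20


@dataclass
class SimulatedStudy:
    genome: GenomeModel
    methylome_nonstem: TrueMethylome
    methylome_stem: TrueMethylome
    truth_dmrs: DMRSet
    samples: dict[str, MethylomeSample]
    expression: ExpressionMatrix


def simulate_study(config: SimulationConfig, seed: int) -> SimulatedStudy:
    """Run the full generator chain under one master seed."""
    seeds = np.random.default_rng(seed).integers(2**31, size=8)
    genome = generate_genome(
        config.n_chrom, config.chrom_len, config.n_te, config.n_gene, int(seeds[0])
    )
    nonstem = generate_methylome(genome, seed=int(seeds[1]), label="nonstem")
    stem, truth = plant_dmrs(
        nonstem,
        config.n_dmrs,
        config.dmr_length,
        config.dmr_delta,
        config.dmr_context,
        seed=int(seeds[2]),
        label="stem",
    )
    samples = {}
    for name, meth, frac, s in (
        ("stem", stem, "stem", seeds[3]),
        ("nonstem", nonstem, "nonstem", seeds[4]),
        ("seedling", nonstem, "seedling", seeds[5]),
    ):
        sid = f"{config.stage}_{name}"
        samples[sid] = sample_counts(
            meth,
            config.coverage_mean,
            config.conversion_failure,
            seed=int(s),
            sample_id=sid,
            stage=config.stage,
            fraction=frac,
        )
    families = sorted({f.family for f in genome.features if f.kind == "TE" and f.family})
    genes = [f.feature_id for f in genome.features if f.kind == "gene"]
    expression = generate_expression(
        genome.features,
        stages=config.expression_stages,
        upregulated_families=families[: config.n_up_families],
        fold=config.fold,
        up_stage=config.stage if config.stage in config.expression_stages else config.expression_stages[0],
        housekeeping_ids=genes[: config.n_housekeeping],
        noise_cv=config.noise_cv,
        seed=int(seeds[6]),
    )
    return SimulatedStudy(
        genome=genome,
        methylome_nonstem=nonstem,
        methylome_stem=stem,
        truth_dmrs=truth,
        samples=samples,
        expression=expression,
    )


def write_genome_fasta(genome: GenomeModel, path, width: int = 70) -> None:
    """Write the genome sequences as uncompressed FASTA."""
    with open(path, "w") as fh:
        for chrom, s in genome.seq.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
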