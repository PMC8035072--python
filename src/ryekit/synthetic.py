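"""Seeded synthetic inputs with the statistical structure each stage assumes.

Every downstream operation in this package is testable without any download:
the generators here produce

* binned read-depth cohorts over a combined wheat+rye reference with planted
  karyotype classes (none / 1AL.1RS / 1BL.1RS / ambiguous),
* Hi-C intra-chromosomal link lists with power-law contact-distance decay
  and planted inversions,
* structured diploid genotype panels (k clusters around shared ancestral
  frequencies, optional gene-flow tracts, outgroup triples, effect labels,
  per-call depth and site quality), and
* forward/reverse alignment hit tables whose reciprocal best matches carry a
  planted segmental identity mosaic.

All generators take an explicit seed and are bit-reproducible; none keeps
hidden global state.  What the generators do and do not emulate about real
sequencing data is discussed in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .karyotype import KARYOTYPE_LABELS, BinnedDepthProfile
from .popgen import GenotypeMatrix

__all__ = [
    "DepthSimConfig",
    "SimulatedCohort",
    "simulate_depth_cohort",
    "simulate_reference_profile",
    "HiCSimConfig",
    "simulate_hic_links",
    "Tract",
    "PopSimConfig",
    "simulate_structured_genotypes",
    "simulate_rbh_mosaic",
]


# ---------------------------------------------------------------------------
# Depth cohorts
# ---------------------------------------------------------------------------

_DEFAULT_CHROM_LENGTHS = {"1A": 590_000_000, "1B": 690_000_000, "1R": 980_000_000}


@dataclass
class DepthSimConfig:
    """Knobs of the combined-reference depth simulator.

    ``introgression_fraction`` is the fraction of reference depth attained
    by present-but-foreign chromatin (rye reads in a wheat background map
    somewhat less efficiently); ``residual_fraction`` the small cross-mapping
    residual on absent chromatin; ``dispersion`` the negative-binomial
    overdispersion of per-bin counts (0 means deterministic expectations,
    for exact tests).  ``bias_loc``/``bias_scale`` control a per-sample
    protocol-bias coefficient multiplying a fixed distal-to-proximal
    mappability gradient (amplitude ``gradient_amplitude`` in log2 units);
    the normalization reference is generated bias-free, so this models the
    sample-consistent residual deviation from the reference that survives
    rpmm normalization in real panels.
    """

    n_per_class: int = 50
    bin_size: int = 1_000_000
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CHROM_LENGTHS)
    )
    total_reads: float = 2_000_000
    dispersion: float = 0.1
    introgression_fraction: float = 0.8
    residual_fraction: float = 0.01
    ambiguous_fraction: float = 0.15
    replaced_arm: int = 250_000_000
    introgressed_arm: int = 350_000_000
    bias_loc: float = 0.35
    bias_scale: float = 0.10
    gradient_amplitude: float = 0.5
    classes: Sequence[str] = KARYOTYPE_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.introgression_fraction <= 1:
            raise ValueError("introgression_fraction must be in [0, 1]")
        unknown = set(self.classes) - set(KARYOTYPE_LABELS)
        if unknown:
            raise ValueError(f"unknown karyotype class name(s): {sorted(unknown)}")
        for chrom in ("1A", "1B", "1R"):
            if chrom not in self.chrom_lengths:
                raise ValueError(f"chrom_lengths must include {chrom}")
        for chrom in ("1A", "1B"):
            if self.chrom_lengths[chrom] < 2 * self.replaced_arm:
                raise ValueError(f"{chrom} shorter than twice the replaced arm")
        if self.chrom_lengths["1R"] < 2 * self.introgressed_arm:
            raise ValueError("1R shorter than twice the introgressed arm")


@dataclass
class SimulatedCohort:
    profiles: list[BinnedDepthProfile]
    labels: list[str]
    truth_regions: list[list[tuple[str, int, int, str]]]

    def __post_init__(self) -> None:
        if not (len(self.profiles) == len(self.labels) == len(self.truth_regions)):
            raise ValueError("profiles, labels and truth_regions differ in length")


def _bin_frame(cfg: DepthSimConfig) -> pd.DataFrame:
    rows = []
    for chrom in sorted(cfg.chrom_lengths):
        length = int(cfg.chrom_lengths[chrom])
        for b in range(0, length, cfg.bin_size):
            rows.append(
                {
                    "chrom": chrom,
                    "bin_start": b,
                    "frac": min(cfg.bin_size, length - b) / cfg.bin_size,
                }
            )
    return pd.DataFrame(rows)


def _gradient(cfg: DepthSimConfig, bins: pd.DataFrame) -> np.ndarray:
    """Fixed distal-to-proximal mappability gradient, in log2 units.

    Runs linearly from +gradient_amplitude at the I end (chromosome start)
    to -gradient_amplitude at the opposite end of each chromosome.
    """
    h = np.zeros(len(bins))
    for chrom, length in cfg.chrom_lengths.items():
        mask = (bins["chrom"] == chrom).to_numpy()
        mids = bins.loc[mask, "bin_start"].to_numpy() + cfg.bin_size / 2
        h[mask] = cfg.gradient_amplitude * (1.0 - 2.0 * mids / length)
    return h


def _class_weights(cfg: DepthSimConfig, bins: pd.DataFrame, label: str) -> np.ndarray:
    """Relative expected depth per bin for one karyotype class (bias-free)."""
    chrom = bins["chrom"].to_numpy()
    start = bins["bin_start"].to_numpy()
    w = np.where(chrom == "1R", cfg.residual_fraction, 1.0)
    in_1r_arm = (chrom == "1R") & (start + cfg.bin_size <= cfg.introgressed_arm)
    if label in ("introgressed_1A1R", "introgressed_1B1R"):
        lost = "1A" if label == "introgressed_1A1R" else "1B"
        in_lost = (chrom == lost) & (start + cfg.bin_size <= cfg.replaced_arm)
        w = np.where(in_lost, cfg.residual_fraction, w)
        w = np.where(in_1r_arm, cfg.introgression_fraction, w)
    elif label == "ambiguous":
        w = np.where(in_1r_arm, cfg.ambiguous_fraction, w)
    elif label != "none":
        raise ValueError(f"unknown class name: {label!r}")
    return w * bins["frac"].to_numpy()


def _truth(cfg: DepthSimConfig, label: str) -> list[tuple[str, int, int, str]]:
    if label == "introgressed_1A1R":
        return [("1R", 0, cfg.introgressed_arm, "gain"), ("1A", 0, cfg.replaced_arm, "loss")]
    if label == "introgressed_1B1R":
        return [("1R", 0, cfg.introgressed_arm, "gain"), ("1B", 0, cfg.replaced_arm, "loss")]
    if label == "ambiguous":
        return [("1R", 0, cfg.introgressed_arm, "gain")]
    return []


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Overdispersed counts: var = mu * (1 + dispersion * mu).

    dispersion == 0 returns the rounded expectation (deterministic), for
    exact noise-free tests.
    """
    if dispersion == 0:
        return np.rint(mu).astype(np.int64)
    lam = rng.gamma(shape=1.0 / dispersion, scale=np.maximum(mu, 0) * dispersion)
    return rng.poisson(lam).astype(np.int64)


def simulate_depth_cohort(cfg: DepthSimConfig) -> SimulatedCohort:
    """Seeded cohort of binned depth profiles with planted karyotype labels."""
    rng = np.random.default_rng(cfg.seed)
    bins = _bin_frame(cfg)
    h = _gradient(cfg, bins)
    profiles, labels, truths = [], [], []
    for label in cfg.classes:
        base_w = _class_weights(cfg, bins, label)
        for i in range(cfg.n_per_class):
            bias = rng.normal(cfg.bias_loc, cfg.bias_scale)
            w = base_w * np.exp2(bias * h)
            mu = cfg.total_reads * w / w.sum()
            counts = _draw_counts(rng, mu, cfg.dispersion)
            frame = bins[["chrom", "bin_start"]].copy()
            frame["count"] = counts
            profiles.append(
                BinnedDepthProfile(
                    sample_id=f"{label}_{i:04d}", bins=frame, bin_size=cfg.bin_size
                )
            )
            labels.append(label)
            truths.append(_truth(cfg, label))
    return SimulatedCohort(profiles=profiles, labels=labels, truth_regions=truths)


def simulate_reference_profile(
    cfg: DepthSimConfig, depth_multiplier: float = 10.0
) -> BinnedDepthProfile:
    """The normalization reference: a deeply sequenced non-introgressed
    sample with zero protocol bias (its own stream off ``cfg.seed``)."""
    rng = np.random.default_rng((cfg.seed, 0x5EF))
    bins = _bin_frame(cfg)
    w = _class_weights(cfg, bins, "none")
    mu = cfg.total_reads * depth_multiplier * w / w.sum()
    counts = _draw_counts(rng, mu, cfg.dispersion)
    frame = bins[["chrom", "bin_start"]].copy()
    frame["count"] = counts
    return BinnedDepthProfile(sample_id="reference", bins=frame, bin_size=cfg.bin_size)


# ---------------------------------------------------------------------------
# Hi-C links
# ---------------------------------------------------------------------------


@dataclass
class HiCSimConfig:
    """Planted-inversion Hi-C link simulator for one chromosome.

    Links are generated in the sequenced genotype's own ("query")
    coordinates with power-law contact-distance decay p(d) ~ d^decay_exponent
    on [min_dist, chrom_length], then both ends are mapped through the truth
    inversions (coordinate reflection within each interval) into reference
    coordinates.  Overlapping truth intervals are unsupported.
    """

    chrom_length: int
    chrom: str = "5R"
    sv_set: Sequence[tuple[int, int]] = ()
    n_links: int = 500_000
    decay_exponent: float = -1.0
    min_dist: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_links <= 0:
            raise ValueError("n_links must be positive")
        if self.decay_exponent >= 0:
            raise ValueError("decay_exponent must be negative")
        if not 0 < self.min_dist < self.chrom_length:
            raise ValueError("min_dist must be in (0, chrom_length)")
        svs = sorted((int(s), int(e)) for s, e in self.sv_set)
        for s, e in svs:
            if not (0 <= s < e <= self.chrom_length):
                raise ValueError(f"SV interval ({s}, {e}) outside chromosome")
        for (s1, e1), (s2, e2) in zip(svs, svs[1:]):
            if s2 < e1:
                raise ValueError("overlapping truth SVs are unsupported")
        self.sv_set = svs


def _powerlaw(
    rng: np.random.Generator, n: int, a: float, d_min: float, d_max: float
) -> np.ndarray:
    """Inverse-CDF draws from p(d) ~ d^a on [d_min, d_max]."""
    u = rng.random(n)
    if a == -1.0:
        return d_min * (d_max / d_min) ** u
    k = a + 1.0
    return (u * (d_max**k - d_min**k) + d_min**k) ** (1.0 / k)


def _apply_inversions(coords: np.ndarray, sv_set: Sequence[tuple[int, int]]) -> np.ndarray:
    out = coords.copy()
    for s, e in sv_set:
        inside = (out >= s) & (out < e)
        out[inside] = s + (e - 1) - out[inside]
    return out


def simulate_hic_links(cfg: HiCSimConfig) -> pd.DataFrame:
    """Seeded intra-chromosomal link list in reference coordinates."""
    rng = np.random.default_rng(cfg.seed)
    L = cfg.chrom_length
    x = np.empty(cfg.n_links, dtype=np.int64)
    y = np.empty(cfg.n_links, dtype=np.int64)
    todo = np.arange(cfg.n_links)
    while todo.size:
        xs = rng.uniform(0, L, size=todo.size)
        d = _powerlaw(rng, todo.size, cfg.decay_exponent, cfg.min_dist, L)
        sign = rng.choice([-1.0, 1.0], size=todo.size)
        ys = xs + sign * d
        ok = (ys >= 0) & (ys < L)
        x[todo[ok]] = xs[ok].astype(np.int64)
        y[todo[ok]] = ys[ok].astype(np.int64)
        todo = todo[~ok]
    x = _apply_inversions(x, cfg.sv_set)
    y = _apply_inversions(y, cfg.sv_set)
    return pd.DataFrame(
        {"chrom1": cfg.chrom, "pos1": x, "chrom2": cfg.chrom, "pos2": y}
    )


# ---------------------------------------------------------------------------
# Structured genotypes
# ---------------------------------------------------------------------------


@dataclass
class Tract:
    """Gene-flow tract: within [start, end) on ``chrom`` the recipient
    cluster's allele frequencies copy the donor cluster's."""

    donor: int
    recipient: int
    chrom: str
    start: int
    end: int


@dataclass
class PopSimConfig:
    """Structured diploid panel around shared ancestral frequencies.

    Cluster allele frequencies follow a Balding-Nichols spread around each
    site's ancestral derived-allele frequency with drift parameter
    ``divergence`` (0 reproduces the ancestral frequencies exactly, the
    panmictic limit).  ``sel_differential`` in (0, 1] scales the derived
    frequency of nonsynonymous sites in cluster ``sel_group`` (values < 1
    emulate stronger purifying selection there).  The outgroup triple's
    majority equals the ancestral allele except at ``outgroup_error`` sites,
    where the triple carries three distinct alleles (no majority).
    """

    n_clusters: int = 7
    samples_per_cluster: int = 20
    n_sites: int = 2000
    divergence: float = 0.15
    tracts: Sequence[Tract] = ()
    prop_nonsyn: float = 0.4
    sel_differential: float = 1.0
    sel_group: int = 1
    outgroup_error: float = 0.05
    missing_rate: float = 0.08
    depth_mean: float = 12.0
    quality_range: tuple[float, float] = (50.0, 500.0)
    n_chroms: int = 2
    chrom_length: int = 100_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prop_nonsyn", "outgroup_error", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.sel_differential <= 1:
            raise ValueError("sel_differential must be in (0, 1]")
        if self.divergence < 0 or self.divergence >= 1:
            raise ValueError("divergence must be in [0, 1)")
        chrom_names = {f"chr{i + 1}" for i in range(self.n_chroms)}
        for t in self.tracts:
            if t.chrom not in chrom_names:
                raise ValueError(f"tract chromosome {t.chrom!r} not simulated")
            if not 0 <= t.start < t.end <= self.chrom_length:
                raise ValueError("tract outside the site coordinate range")
            if not (1 <= t.donor <= self.n_clusters and 1 <= t.recipient <= self.n_clusters):
                raise ValueError("tract cluster ids out of range")


_BASES = np.array(list("ACGT"))


def simulate_structured_genotypes(
    cfg: PopSimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.Series]:
    """Seeded (GenotypeMatrix, SiteAnnotation frame, truth cluster labels)."""
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.n_sites
    # site map: chromosomes filled round-robin, positions sorted uniform
    chrom_of = np.array([f"chr{(i % cfg.n_chroms) + 1}" for i in range(n_sites)])
    pos = np.empty(n_sites, dtype=np.int64)
    for c in np.unique(chrom_of):
        mask = chrom_of == c
        m = int(mask.sum())
        draws = np.unique(rng.integers(1, cfg.chrom_length, size=m))
        while draws.size < m:  # top up the rare collisions
            extra = rng.integers(1, cfg.chrom_length, size=m - draws.size)
            draws = np.unique(np.concatenate([draws, extra]))
        pos[mask] = np.sort(draws)
    order = np.lexsort((pos, chrom_of))
    chrom_of, pos = chrom_of[order], pos[order]

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref, alt = _BASES[ref_idx], _BASES[alt_idx]

    # ancestral derived-allele frequencies (derived == alt; ancestral == ref)
    q = rng.beta(0.8, 2.0, size=n_sites)
    q = np.clip(q, 0.02, 0.98)
    F = cfg.divergence
    if F == 0:
        p = np.tile(q, (cfg.n_clusters, 1))
    else:
        shape = (1 - F) / F
        p = rng.beta(
            np.tile(q * shape, (cfg.n_clusters, 1)),
            np.tile((1 - q) * shape, (cfg.n_clusters, 1)),
        )
    effect = np.where(
        rng.random(n_sites) < cfg.prop_nonsyn, "nonsynonymous", "synonymous"
    )
    if cfg.sel_differential < 1:
        sel_mask = effect == "nonsynonymous"
        p[cfg.sel_group - 1, sel_mask] *= cfg.sel_differential
    for t in cfg.tracts:
        in_tract = (chrom_of == t.chrom) & (pos >= t.start) & (pos < t.end)
        p[t.recipient - 1, in_tract] = p[t.donor - 1, in_tract]

    n_samples = cfg.n_clusters * cfg.samples_per_cluster
    labels = np.repeat(np.arange(1, cfg.n_clusters + 1), cfg.samples_per_cluster)
    samples = [f"c{k}_s{i:03d}" for k in range(1, cfg.n_clusters + 1) for i in range(cfg.samples_per_cluster)]
    calls = rng.binomial(2, p[labels - 1, :]).astype(np.int8)
    depth = rng.poisson(rng.gamma(4.0, cfg.depth_mean / 4.0, size=(n_samples, n_sites)))
    missing = (rng.random((n_samples, n_sites)) < cfg.missing_rate) | (depth == 0)
    calls[missing] = -1

    qual = rng.uniform(*cfg.quality_range, size=n_sites)
    sites = pd.DataFrame(
        {"chrom": chrom_of, "pos": pos, "ref": ref, "alt": alt, "qual": qual}
    )

    # outgroup triples: majority ancestral, except error sites (3 distinct)
    err = rng.random(n_sites) < cfg.outgroup_error
    all_anc = rng.random(n_sites) < 0.8
    # ref_idx/alt_idx differ; pick a third base different from both
    third_idx = np.zeros(n_sites, dtype=np.int64)
    for b in range(4):
        free = (third_idx == ref_idx) | (third_idx == alt_idx)
        third_idx[free] = b
    third = _BASES[third_idx]
    triples = np.where(
        err[:, None],
        np.column_stack([ref, alt, third]),
        np.where(
            all_anc[:, None],
            np.column_stack([ref, ref, ref]),
            np.column_stack([ref, ref, alt]),
        ),
    ).astype(object)
    # per-site random ordering of the triple
    perm = np.argsort(rng.random((n_sites, 3)), axis=1)
    triples = np.take_along_axis(triples, perm, axis=1)
    annotations = pd.DataFrame(
        {
            "chrom": chrom_of,
            "pos": pos,
            "effect": effect,
            "out1": triples[:, 0],
            "out2": triples[:, 1],
            "out3": triples[:, 2],
        }
    )
    gm = GenotypeMatrix(samples=samples, sites=sites, calls=calls, depth=depth)
    truth = pd.Series(labels, index=samples, name="cluster")
    return gm, annotations, truth


# ---------------------------------------------------------------------------
# RBH mosaic
# ---------------------------------------------------------------------------


def simulate_rbh_mosaic(
    n_genes: int,
    segments: Sequence[tuple[int, int]],
    identities: Mapping[str, Sequence[float]],
    seed: int = 0,
    identity_sd: float = 1.0,
    decoy_prob: float = 0.3,
    gene_spacing: int = 30_000,
    align_len: int = 1_000,
    chrom: str = "q1",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Forward/reverse hit tables with a planted segmental identity mosaic.

    ``segments`` must partition [0, n_genes) into half-open index ranges;
    ``identities[genome][k]`` is the mean percent identity of segment ``k``
    against that subject genome.  Every query gene gets one true hit per
    subject genome (and its mirror in the reverse table) plus, with
    probability ``decoy_prob``, a decoy secondary hit at lower bitscore and
    higher E-value that reciprocal-best selection must never pick.
    Returns (forward, reverse, gene positions).
    """
    segs = sorted((int(s), int(e)) for s, e in segments)
    if segs[0][0] != 0 or segs[-1][1] != n_genes or any(
        e1 != s2 for (_, e1), (s2, _) in zip(segs, segs[1:])
    ):
        raise ValueError("segments must partition [0, n_genes)")
    for genome, vals in identities.items():
        if len(vals) != len(segs):
            raise ValueError(f"identities[{genome!r}] needs one value per segment")
        if any(not 0 <= v <= 100 for v in vals):
            raise ValueError("identity must be within [0, 100]")
    rng = np.random.default_rng(seed)
    seg_of = np.empty(n_genes, dtype=int)
    for k, (s, e) in enumerate(segs):
        seg_of[s:e] = k
    positions = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "chrom": chrom,
            "pos": np.arange(n_genes, dtype=np.int64) * gene_spacing + 1,
        }
    )

    def hit_row(q, s, genome, ident, length, bitscore):
        evalue = float(length * 10.0 ** (-bitscore / 10.0))
        return {
            "qseqid": q,
            "sseqid": s,
            "pident": round(float(np.clip(ident, 0.0, 100.0)), 3),
            "length": int(length),
            "mismatch": int(round(length * (1 - ident / 100.0))),
            "gapopen": 0,
            "qstart": 1,
            "qend": int(length),
            "sstart": 1,
            "send": int(length),
            "evalue": evalue,
            "bitscore": round(float(bitscore), 1),
            "subject_genome": genome,
        }

    fwd_rows, rev_rows = [], []
    for genome in sorted(identities):
        planted = np.asarray(identities[genome], dtype=float)[seg_of]
        ident = np.clip(planted + rng.normal(0, identity_sd, size=n_genes), 0, 100)
        for i in range(n_genes):
            q = f"gene{i:05d}"
            s = f"{genome}:g{i:05d}"
            bits = 2.0 * align_len * ident[i] / 100.0
            fwd_rows.append(hit_row(q, s, genome, ident[i], align_len, bits))
            rev_rows.append(hit_row(s, q, genome, ident[i], align_len, bits))
            if rng.random() < decoy_prob:
                # secondary hit to a neighboring subject gene: worse E-value
                j = (i + 1) % n_genes
                d_ident = max(ident[i] - rng.uniform(5, 15), 0)
                d_bits = 2.0 * align_len * d_ident / 100.0 * 0.8
                fwd_rows.append(
                    hit_row(q, f"{genome}:g{j:05d}", genome, d_ident, align_len, d_bits)
                )
                rev_rows.append(
                    hit_row(f"{genome}:g{j:05d}", f"gene{(i + 2) % n_genes:05d}", genome, d_ident, align_len, d_bits)
                )
    return pd.DataFrame(fwd_rows), pd.DataFrame(rev_rows), positions
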