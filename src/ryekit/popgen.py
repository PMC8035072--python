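"""Filtering, clustering and windowed statistics over a genotype matrix.

Covers the statistics used to dissect reticulate evolution in a diversity
panel genotyped against a single reference line:

* two filter regimes (a lenient missing/MAF regime and a stringent
  depth/missing/quality regime),
* PCA + k-means cluster designation (k = 7 on the first three components by
  default),
* identity-by-state (IBS) to a focal sample in sliding windows of 100 SNP
  loci advanced by 25,
* the Weir & Hill (2002) variance-components Fst estimator in the same
  windows, as a ratio of sums over each window's sites,
* outgroup polarization by majority consensus of three outgroup
  (sub)genome alleles,
* windowed Pn/Ps of derived polymorphisms per group (reported only when
  Pn + Ps >= 10), and
* the allele-frequency ABBA-BABA D statistic with a weighted 5-Mb
  delete-one-block jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .windows import window_starts

__all__ = [
    "GenotypeMatrix",
    "ClusterModel",
    "DStatResult",
    "LENIENT_FILTERS",
    "STRINGENT_FILTERS",
    "filter_genotypes",
    "pca_and_kmeans",
    "windowed_ibs",
    "windowed_fst",
    "fst_components",
    "polarize_by_outgroup",
    "windowed_pnps",
    "patterson_d",
]

MISSING = -1

#: Panel-level regime: max 30% missing data, minor allele frequency >= 1%.
LENIENT_FILTERS = {"max_missing": 0.30, "maf": 0.01}
#: Stringent regime for IBS/Fst: depth >= 6, max 5% missing, call quality >= 250.
STRINGENT_FILTERS = {"min_depth": 6, "max_missing": 0.05, "min_quality": 250}


@dataclass
class GenotypeMatrix:
    """Biallelic samples x sites genotype calls with per-call depth.

    ``calls`` holds alt-allele dosage 0/1/2 with missing coded as -1;
    ``sites`` needs columns chrom, pos (1-based), ref, alt and optionally
    qual; ``depth`` (same shape as calls) may be None.
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls shape does not match samples x sites")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("calls must be 0/1/2 or -1 (missing)")
        if self.depth is not None and np.asarray(self.depth).shape != self.calls.shape:
            raise ValueError("depth shape does not match calls")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[s] for s in ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"sample {err.args[0]!r} not in matrix") from None

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def sort_by_position(self) -> "GenotypeMatrix":
        order = np.lexsort((self.sites["pos"].to_numpy(), self.sites["chrom"].to_numpy()))
        return self.take_sites(order)


def filter_genotypes(
    gm: GenotypeMatrix,
    max_missing: float,
    maf: float | None = None,
    min_depth: int | None = None,
    min_quality: float | None = None,
) -> tuple[GenotypeMatrix, int]:
    """Apply the enabled site/call filters; return (filtered matrix, #sites).

    The per-call depth filter marks calls missing *before* site-level
    missingness is computed.  Sites failing any enabled threshold are
    removed.  An empty result is a warning, not an error.  The operation is
    idempotent: filtering a filtered matrix changes nothing.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    if maf is not None and not 0 <= maf <= 0.5:
        raise ValueError("maf must be in [0, 0.5]")
    calls = gm.calls.copy()
    depth = None if gm.depth is None else np.asarray(gm.depth)
    if min_depth is not None:
        if depth is None:
            raise ValueError("min_depth filter requires per-call depth")
        calls[depth < min_depth] = MISSING
    keep = np.ones(gm.n_sites, dtype=bool)
    if min_quality is not None:
        if "qual" not in gm.sites.columns:
            raise ValueError("min_quality filter requires a qual column")
        keep &= gm.sites["qual"].to_numpy() >= min_quality
    miss_frac = (calls == MISSING).mean(axis=0)
    keep &= miss_frac <= max_missing
    if maf is not None:
        called = calls != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, calls, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        minor = np.minimum(p, 1 - p)
        keep &= np.nan_to_num(minor, nan=-1.0) >= maf
    idx = np.flatnonzero(keep)
    out = GenotypeMatrix(
        samples=list(gm.samples),
        sites=gm.sites.iloc[idx].reset_index(drop=True),
        calls=calls[:, idx],
        depth=None if depth is None else depth[:, idx],
    )
    if out.n_sites == 0:
        warnings.warn("all sites removed by filters", stacklevel=2)
    return out, out.n_sites


@dataclass
class ClusterModel:
    """PCA scores and k-means assignments for a panel."""

    pc_scores: pd.DataFrame  # samples x components
    assignments: pd.Series  # sample -> cluster in 1..k
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return int(self.assignments.nunique())


def _imputed_centered(gm: GenotypeMatrix) -> np.ndarray:
    X = gm.calls.astype(float)
    X[X == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    mean = np.nan_to_num(mean, nan=0.0)  # all-missing site -> contributes 0
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[1]]
    return X - mean


def pca_and_kmeans(
    gm: GenotypeMatrix,
    n_components: int = 3,
    k: int = 7,
    restarts: int = 25,
    seed: int = 0,
) -> ClusterModel:
    """Mean-imputed, centered PCA followed by k-means on the top scores.

    Defaults follow the analysis this package reproduces: seven clusters on
    the first three principal components, with 25 k-means restarts (a single
    restart is seed-fragile).
    """
    if k > gm.n_samples:
        raise ValueError("k exceeds the number of samples")
    X = _imputed_centered(gm)
    n_components = min(n_components, min(X.shape) - 1)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(scores)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return ClusterModel(
        pc_scores=pd.DataFrame(scores, index=gm.samples, columns=cols),
        assignments=pd.Series(labels + 1, index=gm.samples, name="cluster"),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def _window_frame(
    gm: GenotypeMatrix, window: int, step: int
) -> list[tuple[str, np.ndarray]]:
    """Per chromosome, index arrays of full windows (position-sorted sites)."""
    pos = gm.sites["pos"].to_numpy()
    chroms = gm.sites["chrom"].to_numpy()
    out = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        for s in window_starts(len(idx), window, step):
            out.append((chrom, idx[s : s + window]))
    return out


def windowed_ibs(
    gm: GenotypeMatrix,
    focal_sample: str,
    window: int = 100,
    step: int = 25,
) -> pd.DataFrame:
    """IBS of every sample to the focal sample in 100-SNP/step-25 windows.

    IBS at a co-called site is 1 - |dosage difference| / 2; the window value
    is the mean over co-called sites.  Windows where a pair shares no
    co-called site get NaN.  Window position is the mean position of the
    window's variant sites.
    """
    focal = gm.sample_index([focal_sample])[0]
    f = gm.calls[focal]
    pos = gm.sites["pos"].to_numpy()
    rows = []
    for chrom, idx in _window_frame(gm, window, step):
        fw = f[idx]
        cw = gm.calls[:, idx]
        both = (cw != MISSING) & (fw != MISSING)
        sim = 1.0 - np.abs(cw - fw) / 2.0
        with np.errstate(invalid="ignore"):
            val = np.where(
                both.sum(axis=1) > 0,
                np.where(both, sim, 0.0).sum(axis=1) / np.maximum(both.sum(axis=1), 1),
                np.nan,
            )
        mean_pos = float(pos[idx].mean())
        for s_i, sample in enumerate(gm.samples):
            rows.append(
                {
                    "chrom": chrom,
                    "mean_pos": mean_pos,
                    "sample": sample,
                    "value": val[s_i],
                    "n_sites": int(both[s_i].sum()),
                    "statistic": "ibs",
                }
            )
    return pd.DataFrame(rows)


def fst_components(
    counts: np.ndarray, freqs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator/denominator of the variance-components Fst.

    ``counts``: called allele counts per population (r x sites);
    ``freqs``: alt-allele frequencies per population (r x sites).
    Implements the two-level allele-count ANOVA with unequal sample sizes
    (the Weir & Hill 2002 generalization of the classic estimator):

        MSP = sum_i m_i (p_i - p_bar)^2 / (r - 1)
        MSG = sum_i m_i p_i (1 - p_i) / sum_i (m_i - 1)
        n_c = (M - sum_i m_i^2 / M) / (r - 1)
        Fst = (MSP - MSG) / (MSP + (n_c - 1) MSG)

    Sites where any population has zero called alleles yield NaN components.
    Window estimates are ratios of summed numerators and denominators.
    """
    m = np.asarray(counts, dtype=float)
    p = np.asarray(freqs, dtype=float)
    r = m.shape[0]
    if r < 2:
        raise ValueError("need at least two populations")
    M = m.sum(axis=0)
    valid = (m > 0).all(axis=0) & (m.sum(axis=0) > r)  # need sum(m_i - 1) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p_bar = (m * p).sum(axis=0) / M
        msp = (m * (p - p_bar) ** 2).sum(axis=0) / (r - 1)
        msg = (m * p * (1 - p)).sum(axis=0) / (M - r)
        n_c = (M - (m**2).sum(axis=0) / M) / (r - 1)
        num = msp - msg
        den = msp + (n_c - 1) * msg
    num = np.where(valid, num, np.nan)
    den = np.where(valid, den, np.nan)
    return num, den


def _group_freqs(
    gm: GenotypeMatrix, groups: Mapping[str, Sequence[str]]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = list(groups)
    counts = np.zeros((len(names), gm.n_sites))
    freqs = np.zeros((len(names), gm.n_sites))
    for i, name in enumerate(names):
        idx = gm.sample_index(groups[name])
        sub = gm.calls[idx]
        called = sub != MISSING
        m = 2.0 * called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs[i] = np.where(m > 0, alt / np.maximum(m, 1), np.nan)
        counts[i] = m
    return counts, freqs, names


def windowed_fst(
    gm: GenotypeMatrix,
    groups: Mapping[str, Sequence[str]],
    pairs: Sequence[tuple[str, str]] | None = None,
    window: int = 100,
    step: int = 25,
) -> pd.DataFrame:
    """Pairwise windowed Fst for designated sample groups.

    Each window value is sum(numerator)/sum(denominator) of the per-site
    variance components over the window's usable sites (ratio of sums, not
    a mean of per-site ratios).  Windows with no usable site get NaN.
    """
    for name, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"group {name!r} needs at least two samples")
    counts, freqs, names = _group_freqs(gm, groups)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    pos = gm.sites["pos"].to_numpy()
    rows = []
    for g1, g2 in pairs:
        i1, i2 = names.index(g1), names.index(g2)
        num, den = fst_components(counts[[i1, i2]], freqs[[i1, i2]])
        for chrom, idx in _window_frame(gm, window, step):
            nw, dw = num[idx], den[idx]
            usable = ~np.isnan(dw)
            value = float(nw[usable].sum() / dw[usable].sum()) if usable.any() else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "mean_pos": float(pos[idx].mean()),
                    "pair": f"{g1}~{g2}",
                    "value": value,
                    "n_sites": int(usable.sum()),
                    "statistic": "fst",
                }
            )
    return pd.DataFrame(rows)


def polarize_by_outgroup(
    sites: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Assign ancestral alleles by majority consensus of the outgroup triple.

    ``annotations`` needs chrom, pos and out1/out2/out3 (the three outgroup
    subgenome alleles).  The ancestral allele is the one occurring at least
    twice in the triple; sites whose triple has no majority, or whose
    majority allele matches neither ref nor alt, are flagged and omitted
    from polarized analyses.  Returns one row per site of ``sites`` with
    columns ancestral, derived and status in {ok, no_majority,
    allele_mismatch, unannotated}.
    """
    merged = sites[["chrom", "pos", "ref", "alt"]].merge(
        annotations[["chrom", "pos", "out1", "out2", "out3"]],
        on=["chrom", "pos"],
        how="left",
    )
    o1, o2, o3 = (merged[c].to_numpy(dtype=object) for c in ("out1", "out2", "out3"))
    # the majority allele of a triple, if any: the one equal to another
    major = np.select([o1 == o2, o1 == o3, o2 == o3], [o1, o1, o2], default=None)
    annotated = merged["out1"].notna().to_numpy()
    ref = merged["ref"].to_numpy(dtype=object)
    alt = merged["alt"].to_numpy(dtype=object)
    is_ref = annotated & (major == ref)
    is_alt = annotated & (major == alt)
    status = np.where(
        ~annotated,
        "unannotated",
        np.where(
            major == None,  # noqa: E711 -- elementwise against object array
            "no_majority",
            np.where(is_ref | is_alt, "ok", "allele_mismatch"),
        ),
    )
    ancestral = np.select([is_ref, is_alt], [ref, alt], default=None)
    derived = np.select([is_ref, is_alt], [alt, ref], default=None)
    return pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "ancestral": ancestral,
            "derived": derived,
            "status": status,
        }
    )


def _derived_freqs(
    gm: GenotypeMatrix, polarization: pd.DataFrame, sample_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(derived-allele frequency, called allele count) per site for a group.

    Sites not polarized (status != ok) get NaN frequency.  The derived
    allele is alt where ancestral == ref, else ref.
    """
    sub = gm.calls[sample_idx]
    called = sub != MISSING
    m = 2.0 * called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(m > 0, alt / np.maximum(m, 1), np.nan)
    derived_is_alt = polarization["derived"].to_numpy() == gm.sites["alt"].to_numpy()
    ok = (polarization["status"].to_numpy() == "ok")
    p = np.where(derived_is_alt, p_alt, 1.0 - p_alt)
    p = np.where(ok, p, np.nan)
    return p, m


def windowed_pnps(
    gm: GenotypeMatrix,
    annotations: pd.DataFrame,
    polarization: pd.DataFrame,
    group_samples: Sequence[str],
    window: int = 100,
    step: int = 25,
    min_total: int = 10,
    segregating: str = "polymorphic",
) -> pd.DataFrame:
    """Windowed ratio of nonsynonymous to synonymous derived polymorphisms.

    A site counts toward Pn (or Ps) when its effect is nonsynonymous
    (synonymous), its ancestral state is polarized, and the derived allele
    is present in the group -- by default additionally requiring the site to
    be polymorphic within the group (``segregating='polymorphic'``; pass
    ``'present'`` to count any derived occurrence).  Bins with
    Pn + Ps < ``min_total`` are suppressed (value NaN, ``reported`` False).
    Ps = 0 in a reported bin yields value inf with ``infinite`` True.
    """
    if len(group_samples) == 0:
        raise ValueError("empty group")
    if segregating not in ("polymorphic", "present"):
        raise ValueError("segregating must be 'polymorphic' or 'present'")
    idx_samples = gm.sample_index(group_samples)
    p, _m = _derived_freqs(gm, polarization, idx_samples)
    ann = annotations.set_index(["chrom", "pos"])
    eff = ann.reindex(
        pd.MultiIndex.from_frame(gm.sites[["chrom", "pos"]])
    )["effect"].to_numpy()
    if segregating == "polymorphic":
        seg = (p > 0) & (p < 1)
    else:
        seg = p > 0
    is_n = seg & (eff == "nonsynonymous")
    is_s = seg & (eff == "synonymous")
    pos = gm.sites["pos"].to_numpy()
    rows = []
    for chrom, idx in _window_frame(gm, window, step):
        pn = int(is_n[idx].sum())
        ps = int(is_s[idx].sum())
        reported = pn + ps >= min_total
        if not reported:
            value, infinite = np.nan, False
        elif ps == 0:
            value, infinite = np.inf, True
        else:
            value, infinite = pn / ps, False
        rows.append(
            {
                "chrom": chrom,
                "mean_pos": float(pos[idx].mean()),
                "pn": pn,
                "ps": ps,
                "value": value,
                "reported": reported,
                "infinite": infinite,
                "n_sites": len(idx),
                "statistic": "pnps",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DStatResult:
    d: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    se_defined: bool

    def __repr__(self) -> str:  # compact, for logs
        return (
            f"DStatResult(d={self.d:.4f}, se={self.se:.4f}, z={self.z:.2f}, "
            f"n_sites={self.n_sites}, n_blocks={self.n_blocks})"
        )


def patterson_d(
    gm: GenotypeMatrix,
    p1_samples: Sequence[str],
    p2_samples: Sequence[str],
    p3_samples: Sequence[str],
    polarization: pd.DataFrame,
    block_size: int = 5_000_000,
) -> DStatResult:
    """Allele-frequency ABBA-BABA D with a delete-one-block jackknife.

    With derived-allele frequencies p1, p2, p3 per group and the outgroup
    fixed ancestral,

        D = sum[(1-p1) p2 p3 - p1 (1-p2) p3] / sum[(1-p1) p2 p3 + p1 (1-p2) p3].

    The standard error comes from a weighted delete-one jackknife over
    contiguous ``block_size`` genomic intervals (weights = informative sites
    per block; blocks without informative sites are skipped).  With fewer
    than two informative blocks the s.e. is undefined and flagged.
    """
    sets = [set(p1_samples), set(p2_samples), set(p3_samples)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValueError("P1, P2, P3 must be disjoint sample groups")
    ps = []
    for group in (p1_samples, p2_samples, p3_samples):
        p, _ = _derived_freqs(gm, polarization, gm.sample_index(group))
        ps.append(p)
    p1, p2, p3 = ps
    abba = (1 - p1) * p2 * p3
    baba = p1 * (1 - p2) * p3
    usable = ~(np.isnan(abba) | np.isnan(baba))
    num_s = np.where(usable, abba - baba, 0.0)
    den_s = np.where(usable, abba + baba, 0.0)
    informative = usable & (den_s > 0)
    N, Dn = num_s.sum(), den_s.sum()
    if Dn <= 0:
        return DStatResult(np.nan, np.nan, np.nan, int(informative.sum()), 0, False)
    d_hat = N / Dn
    chrom_codes = pd.factorize(gm.sites["chrom"].to_numpy())[0].astype(np.int64)
    block_ids = chrom_codes * 1_000_000 + gm.sites["pos"].to_numpy(np.int64) // int(block_size)
    blocks = []
    for b in np.unique(block_ids):
        in_b = block_ids == b
        m_j = int(informative[in_b].sum())
        if m_j == 0:
            continue
        blocks.append((num_s[in_b].sum(), den_s[in_b].sum(), m_j))
    g = len(blocks)
    if g < 2:
        return DStatResult(float(d_hat), np.nan, np.nan, int(informative.sum()), g, False)
    n_tot = sum(m for _, _, m in blocks)
    theta_del = np.array([(N - nj) / (Dn - dj) for nj, dj, _ in blocks])
    m = np.array([mj for _, _, mj in blocks], dtype=float)
    h = n_tot / m
    theta_j = g * d_hat - float(((1 - m / n_tot) * theta_del).sum())
    var = float(
        (1.0 / g)
        * (((h * d_hat - (h - 1) * theta_del - theta_j) ** 2) / (h - 1)).sum()
    )
    se = np.sqrt(var)
    z = d_hat / se if se > 0 else np.nan
    return DStatResult(float(d_hat), float(se), float(z), int(informative.sum()), g, True)
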