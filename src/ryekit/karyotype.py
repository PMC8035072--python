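"""Combined-reference read-depth karyotyping of wheat-rye introgressions.

Wheat breeding programs screen germplasm for 1AL.1RS and 1BL.1RS Robertsonian
translocations, in which the short arm of wheat chromosome 1A or 1B is
replaced by the rye 1R short arm.  When a sample's reads are mapped to a
combined wheat+rye reference, the translocation appears as depletion of depth
over the replaced wheat arm and gain of depth over the rye arm.

This module turns per-bin read counts into

* ``rpmm``: log2 reads-per-bin per million mapped reads,
* ``r``: rpmm normalized by subtracting a designated reference sample's rpmm
  for the same bin (controls for bin-level mappability bias),
* two scalar features per sample built from window means of ``r`` over the
  "normally introgressed" (I) and "normally non-introgressed" (N) ends of
  chromosomes 1A/1B and 1R, and
* an RBF-kernel soft-margin SVM (cost C=1) that classifies samples into the
  closed karyotype vocabulary, with a train-size cross-validation experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "KARYOTYPE_LABELS",
    "BinnedDepthProfile",
    "ArmWindows",
    "ArmRegionSpec",
    "compute_rpmm",
    "normalize_to_reference",
    "extract_karyotype_features",
    "median_heuristic_gamma",
    "KaryotypeClassifier",
    "fit_karyotype_classifier",
    "cross_validate_classifier",
    "summarize_cv",
    "classify_karyotypes",
    "sqrt_diff_heatmap_matrix",
    "bin_counts_from_alignments",
]

#: Closed karyotype vocabulary.
KARYOTYPE_LABELS = ("none", "introgressed_1A1R", "introgressed_1B1R", "ambiguous")


@dataclass
class BinnedDepthProfile:
    """Per-chromosome 1-Mb (by default) binned read counts for one sample.

    ``bins`` holds columns ``chrom``, ``bin_start`` (0-based, half-open bins
    of width ``bin_size``) and ``count``, plus ``rpmm`` and ``r`` once
    computed.  ``total_mapped`` defaults to the sum of counts.
    """

    sample_id: str
    bins: pd.DataFrame
    bin_size: int = 1_000_000
    total_mapped: float | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "bin_start", "count"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"profile bins missing columns: {sorted(missing)}")
        if (self.bins["count"] < 0).any():
            raise ValueError("bin counts must be non-negative")
        if self.total_mapped is None:
            self.total_mapped = float(self.bins["count"].sum())

    def with_rpmm(self, pseudocount: float = 0.5) -> "BinnedDepthProfile":
        """Return a copy whose ``bins`` carry an ``rpmm`` column."""
        out = self.bins.copy()
        out["rpmm"] = compute_rpmm(out["count"].to_numpy(), self.total_mapped, pseudocount)
        return BinnedDepthProfile(self.sample_id, out, self.bin_size, self.total_mapped)


def compute_rpmm(
    counts: np.ndarray | Sequence[float],
    total_mapped: float,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """log2(reads mapped to bin per million reads mapped).

    Zero-count bins are replaced by ``pseudocount`` reads before the log so
    the track stays finite everywhere.
    """
    if total_mapped is None or total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    c = np.where(counts > 0, counts, pseudocount)
    return np.log2(c / (total_mapped / 1e6))


def normalize_to_reference(
    sample: BinnedDepthProfile, reference: BinnedDepthProfile
) -> BinnedDepthProfile:
    """Subtract the reference sample's rpmm bin-by-bin, yielding ``r``.

    Both profiles must carry ``rpmm`` on an identical binning (same
    chromosomes and bin starts, in the same order).
    """
    for prof in (sample, reference):
        if "rpmm" not in prof.bins.columns:
            raise ValueError(f"profile {prof.sample_id!r} lacks an rpmm column")
    same = (
        len(sample.bins) == len(reference.bins)
        and (sample.bins["chrom"].to_numpy() == reference.bins["chrom"].to_numpy()).all()
        and (sample.bins["bin_start"].to_numpy() == reference.bins["bin_start"].to_numpy()).all()
    )
    if not same:
        raise ValueError("sample and reference profiles are binned differently")
    out = sample.bins.copy()
    out["r"] = out["rpmm"].to_numpy() - reference.bins["rpmm"].to_numpy()
    return BinnedDepthProfile(sample.sample_id, out, sample.bin_size, sample.total_mapped)


@dataclass(frozen=True)
class ArmWindows:
    """I/N window geometry for one chromosome.

    ``i_end`` names the chromosome end that is "normally introgressed": the
    I window is the terminal ``introgressed_window`` bp at that end, the N
    window the terminal ``nonintrogressed_window`` bp at the opposite end.
    """

    chrom_length: int
    i_end: str = "start"
    introgressed_window: int = 200_000_000
    nonintrogressed_window: int = 300_000_000

    def __post_init__(self) -> None:
        if self.i_end not in ("start", "end"):
            raise ValueError("i_end must be 'start' or 'end'")
        if self.introgressed_window + self.nonintrogressed_window > self.chrom_length:
            raise ValueError("I and N windows overlap: chromosome too short")

    def window(self, which: str) -> tuple[int, int]:
        """(start, end) of the I or N window, 0-based half-open."""
        if which == "I":
            w = self.introgressed_window
            at_start = self.i_end == "start"
        elif which == "N":
            w = self.nonintrogressed_window
            at_start = self.i_end == "end"
        else:
            raise ValueError("which must be 'I' or 'N'")
        return (0, w) if at_start else (self.chrom_length - w, self.chrom_length)


@dataclass
class ArmRegionSpec:
    """I/N windows for the three translocation-relevant chromosomes."""

    arms: Mapping[str, ArmWindows] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in ("1A", "1B", "1R"):
            if chrom not in self.arms:
                raise ValueError(f"ArmRegionSpec must define windows for {chrom}")

    @classmethod
    def from_chrom_lengths(
        cls,
        chrom_lengths: Mapping[str, int],
        i_end: str | Mapping[str, str] = "start",
        introgressed_window: int = 200_000_000,
        nonintrogressed_window: int = 300_000_000,
    ) -> "ArmRegionSpec":
        arms = {}
        for chrom in ("1A", "1B", "1R"):
            end = i_end if isinstance(i_end, str) else i_end[chrom]
            arms[chrom] = ArmWindows(
                chrom_length=int(chrom_lengths[chrom]),
                i_end=end,
                introgressed_window=introgressed_window,
                nonintrogressed_window=nonintrogressed_window,
            )
        return cls(arms)


def _window_mean(profile: BinnedDepthProfile, chrom: str, lo: int, hi: int) -> float:
    """Mean ``r`` over bins wholly inside [lo, hi); error if no bin fits."""
    sub = profile.bins[profile.bins["chrom"] == chrom]
    starts = sub["bin_start"].to_numpy()
    inside = (starts >= lo) & (starts + profile.bin_size <= hi)
    if not inside.any():
        raise ValueError(
            f"no whole bin of {profile.sample_id!r} inside {chrom}:{lo}-{hi}"
        )
    return float(sub.loc[inside, "r"].mean())


def extract_karyotype_features(
    profiles: Iterable[BinnedDepthProfile],
    spec: ArmRegionSpec,
    log_base: float = math.e,
) -> pd.DataFrame:
    """Two introgression features per sample from window means of ``r``.

    featureA = -log[(mean(r^1A_I) - mean(r^1A_N)) * (mean(r^1R_I) - mean(r^1R_N))]
    featureB likewise with 1B in place of 1A.  Whenever the log argument is
    <= 0 the feature is undefined; such samples receive the minimum of the
    defined values of that feature across the cohort and are flagged in
    ``substitutedA``/``substitutedB``.  If a feature is undefined for every
    sample in the cohort this raises, since no substitution value exists.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty cohort")
    ln_base = math.log(log_base)
    rows = []
    for prof in profiles:
        if "r" not in prof.bins.columns:
            raise ValueError(f"profile {prof.sample_id!r} lacks an r column")
        wm = {}
        for chrom in ("1A", "1B", "1R"):
            arm = spec.arms[chrom]
            for which in ("I", "N"):
                lo, hi = arm.window(which)
                wm[chrom, which] = _window_mean(prof, chrom, lo, hi)
        rye = wm["1R", "I"] - wm["1R", "N"]
        arg_a = (wm["1A", "I"] - wm["1A", "N"]) * rye
        arg_b = (wm["1B", "I"] - wm["1B", "N"]) * rye
        rows.append(
            {
                "sample_id": prof.sample_id,
                "featureA": -math.log(arg_a) / ln_base if arg_a > 0 else np.nan,
                "featureB": -math.log(arg_b) / ln_base if arg_b > 0 else np.nan,
            }
        )
    feats = pd.DataFrame(rows)
    for name, flag in (("featureA", "substitutedA"), ("featureB", "substitutedB")):
        undefined = feats[name].isna()
        if undefined.all():
            raise ValueError(f"{name} undefined for every sample in the cohort")
        feats[flag] = undefined
        feats.loc[undefined, name] = feats.loc[~undefined, name].min()
    return feats


def median_heuristic_gamma(
    X: np.ndarray, max_points: int = 2000, seed: int = 0
) -> float:
    """RBF bandwidth gamma = 1 / median squared pairwise distance.

    Zero distances (exactly coincident points, common after the
    min-substitution rule) are excluded from the median.
    """
    X = np.asarray(X, dtype=float)
    if len(X) > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), max_points, replace=False)]
    diff = X[:, None, :] - X[None, :, :]
    sq = (diff**2).sum(axis=-1)
    iu = np.triu_indices(len(X), k=1)
    vals = sq[iu]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("all points coincide; RBF bandwidth undefined")
    return float(1.0 / np.median(vals))


@dataclass
class KaryotypeClassifier:
    """Fitted scaler + RBF SVM with the bandwidth used."""

    pipeline: Pipeline
    gamma: float

    @property
    def classes_(self) -> np.ndarray:
        return self.pipeline.named_steps["svc"].classes_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.asarray(X, dtype=float))


def _as_feature_array(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[["featureA", "featureB"]].to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def fit_karyotype_classifier(
    features,
    labels: Sequence[str],
    C: float = 1.0,
    gamma: float | None = None,
    seed: int = 0,
) -> KaryotypeClassifier:
    """Soft-margin RBF-kernel SVM with cost C=1 on the two features.

    Features are standardized; the kernel bandwidth defaults to the median
    heuristic on the standardized features (the original tool estimated its
    bandwidth internally, which is not specified further).
    """
    X = _as_feature_array(features)
    y = np.asarray(labels)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to fit a classifier")
    scaler = StandardScaler().fit(X)
    if gamma is None:
        gamma = median_heuristic_gamma(scaler.transform(X), seed=seed)
    pipe = Pipeline(
        [
            ("scale", scaler),
            ("svc", SVC(C=C, kernel="rbf", gamma=gamma, random_state=seed)),
        ]
    )
    pipe.fit(X, y)
    return KaryotypeClassifier(pipeline=pipe, gamma=gamma)


def cross_validate_classifier(
    features,
    labels: Sequence[str],
    train_sizes: Sequence[int] = tuple(range(50, 601, 50)),
    repeats: int = 100,
    seed: int = 0,
    C: float = 1.0,
) -> pd.DataFrame:
    """Train-size cross-validation: random train subsets, held-out accuracy.

    For each size, ``repeats`` random training subsets are drawn without
    replacement, a classifier fitted, and accuracy measured on the remaining
    samples.  Returns one row per (train_size, repeat).
    """
    X = _as_feature_array(features)
    y = np.asarray(labels)
    n = len(X)
    rng = np.random.default_rng(seed)
    rows = []
    for size in train_sizes:
        if size >= n:
            raise ValueError(f"train size {size} >= dataset size {n}")
        for rep in range(repeats):
            while True:
                idx = rng.choice(n, size=size, replace=False)
                if len(np.unique(y[idx])) >= 2:
                    break
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            model = fit_karyotype_classifier(X[mask], y[mask], C=C, seed=seed)
            acc = float((model.predict(X[~mask]) == y[~mask]).mean())
            rows.append({"train_size": int(size), "repeat": rep, "accuracy": acc})
    return pd.DataFrame(rows)


def summarize_cv(cv: pd.DataFrame) -> pd.DataFrame:
    """Per-size mean and quartiles of held-out accuracy."""
    g = cv.groupby("train_size")["accuracy"]
    out = g.agg(
        mean="mean",
        q1=lambda s: s.quantile(0.25),
        median="median",
        q3=lambda s: s.quantile(0.75),
        n="count",
    )
    return out.reset_index()


def classify_karyotypes(model: KaryotypeClassifier, features) -> np.ndarray:
    """Predict one closed-vocabulary label per sample."""
    X = _as_feature_array(features)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    return model.predict(X)


def sqrt_diff_heatmap_matrix(calls: np.ndarray) -> np.ndarray:
    """sqrt(percent differing calls) for all sample pairs.

    ``calls`` is samples x sites with missing coded as -1.  Entry (i, j) is
    sqrt(100 * fraction of co-called sites with differing calls); pairs with
    no co-called sites get NaN; the diagonal is 0.
    """
    calls = np.asarray(calls)
    n = calls.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            both = (calls[i] >= 0) & (calls[j] >= 0)
            if not both.any():
                out[i, j] = out[j, i] = np.nan
                continue
            frac = float((calls[i, both] != calls[j, both]).mean())
            out[i, j] = out[j, i] = math.sqrt(100.0 * frac)
    return out


def bin_counts_from_alignments(
    path: str,
    bin_size: int = 1_000_000,
    min_mapq: int = 20,
    exclude_flags: int = 3332,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Tabulate reads per non-overlapping bin from a SAM/BAM/CRAM file.

    Mirrors the usual quality filtering of combined-reference mapping
    (default: drop MAPQ < 20 and any read with flag bits in 3332, i.e.
    unmapped/secondary/QC-fail/duplicate/supplementary).  Returns a tidy
    frame with chrom, bin_start, count covering every bin of each reference
    sequence (or of ``chrom_lengths`` when given).
    """
    import pysam

    counts: dict[tuple[str, int], int] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        for read in fh:
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            if read.flag & exclude_flags:
                continue
            b = (read.reference_start // bin_size) * bin_size
            counts[read.reference_name, b] = counts.get((read.reference_name, b), 0) + 1
    if chrom_lengths is not None:
        lengths = dict(chrom_lengths)
    rows = []
    for chrom, length in lengths.items():
        for b in range(0, int(length), bin_size):
            rows.append(
                {"chrom": chrom, "bin_start": b, "count": counts.get((chrom, b), 0)}
            )
    return pd.DataFrame(rows)
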