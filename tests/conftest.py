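import numpy as np
import pandas as pd
import pytest

from ryekit.karyotype import (
    ArmRegionSpec,
    extract_karyotype_features,
    normalize_to_reference,
)
from ryekit.popgen import GenotypeMatrix
from ryekit.synthetic import (
    DepthSimConfig,
    simulate_depth_cohort,
    simulate_reference_profile,
)


def make_matrix(calls, depth=None, qual=None, chrom=None, pos=None):
    """GenotypeMatrix from a plain nested list of dosages (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    sites = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * n_sites,
            "pos": pos if pos is not None else np.arange(1, n_sites + 1) * 1000,
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
            "qual": qual if qual is not None else [300.0] * n_sites,
        }
    )
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        sites=sites,
        calls=calls,
        depth=None if depth is None else np.asarray(depth),
    )


@pytest.fixture(scope="session")
def depth_cohort():
    """A moderate 4-class depth cohort shared by the karyotype tests."""
    cfg = DepthSimConfig(n_per_class=50, seed=1)
    cohort = simulate_depth_cohort(cfg)
    return cfg, cohort


@pytest.fixture(scope="session")
def cohort_features(depth_cohort):
    """featureA/featureB + labels for the shared cohort."""
    cfg, cohort = depth_cohort
    ref = simulate_reference_profile(cfg).with_rpmm()
    tracks = [normalize_to_reference(p.with_rpmm(), ref) for p in cohort.profiles]
    spec = ArmRegionSpec.from_chrom_lengths(cfg.chrom_lengths)
    feats = extract_karyotype_features(tracks, spec)
    return feats, np.array(cohort.labels)
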