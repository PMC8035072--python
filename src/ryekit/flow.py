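"""Genome-size estimation from flow-cytometry G1 peak means.

Nuclear 2C DNA content is estimated against an internal standard of known
DNA amount co-chopped with the sample:

    2C (pg) = sample G1 peak mean x standard 2C DNA content (pg)
              / standard G1 peak mean

averaged over replicate runs, then converted with 1 pg = 0.978 Gb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

__all__ = ["PG_TO_GB", "FlowSample", "GenomeSizeEstimate", "estimate_genome_size"]

#: Conversion factor from picograms of DNA to gigabases.
PG_TO_GB = 0.978


@dataclass
class FlowSample:
    """Replicate G1 peak means for one accession against one standard."""

    standard_2c_pg: float
    replicates: Sequence[tuple[float, float]] = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.standard_2c_pg <= 0:
            raise ValueError("standard 2C DNA content must be positive")
        if not self.replicates:
            raise ValueError("need at least one (sample, standard) peak pair")
        for sample_mean, standard_mean in self.replicates:
            if sample_mean <= 0 or standard_mean <= 0:
                raise ValueError("peak means must be positive")


class GenomeSizeEstimate(NamedTuple):
    pg_2c: float
    gb_2c: float
    gb_1c: float


def estimate_genome_size(
    sample: FlowSample, aggregation: str = "mean_of_ratios"
) -> GenomeSizeEstimate:
    """2C pg / 2C Gb / 1C Gb from replicate peak-mean pairs.

    ``mean_of_ratios`` (default) averages the per-replicate 2C estimates,
    matching per-day replicate runs; ``ratio_of_means`` divides the mean
    peaks instead.  The estimate is invariant to rescaling both peak means
    of a replicate by the same factor.
    """
    if aggregation == "mean_of_ratios":
        pg = sum(
            s * sample.standard_2c_pg / st for s, st in sample.replicates
        ) / len(sample.replicates)
    elif aggregation == "ratio_of_means":
        mean_s = sum(s for s, _ in sample.replicates) / len(sample.replicates)
        mean_st = sum(st for _, st in sample.replicates) / len(sample.replicates)
        pg = mean_s * sample.standard_2c_pg / mean_st
    else:
        raise ValueError("aggregation must be 'mean_of_ratios' or 'ratio_of_means'")
    gb = pg * PG_TO_GB
    return GenomeSizeEstimate(pg_2c=pg, gb_2c=gb, gb_1c=gb / 2.0)
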