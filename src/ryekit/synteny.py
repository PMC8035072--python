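"""Reciprocal-best-hit selection and binned percent-identity profiles.

Given BLAST-tabular hit tables between one query gene set and the annotated
transcriptomes of one or more subject (sub)genomes, this module selects the
best hit per gene (lowest E-value, ties broken by highest bitscore then
longest alignment), keeps only reciprocal best matches per subject genome,
and summarizes mean percent identity in sliding bins of 100 consecutive
matches (advanced by 20) along each query chromosome -- a chromosome-scale
proxy for relative evolutionary distance that exposes phylogenomic mosaics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .windows import window_starts

__all__ = [
    "BLAST6_COLUMNS",
    "select_best_hit",
    "select_best_hits",
    "select_reciprocal_best",
    "binned_identity_profile",
]

#: Standard BLAST outfmt-6 column names.
BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def _best_order(hits: pd.DataFrame) -> pd.DataFrame:
    """Sort by the selection key: E-value asc, bitscore desc, length desc,
    then subject id lexicographically (residual tie-break, flagged)."""
    return hits.sort_values(
        ["evalue", "bitscore", "length", "sseqid"],
        ascending=[True, False, False, True],
        kind="stable",
    )


def select_best_hit(hits: pd.DataFrame) -> pd.Series | None:
    """Single best hit for one query against one subject genome.

    Returns None for an empty table.  The returned row carries
    ``tie_broken_by_id`` = True when E-value, bitscore and length were all
    tied and the subject id decided.
    """
    if len(hits) == 0:
        return None
    ordered = _best_order(hits)
    best = ordered.iloc[0].copy()
    tie = False
    if len(ordered) > 1:
        nxt = ordered.iloc[1]
        tie = (
            best["evalue"] == nxt["evalue"]
            and best["bitscore"] == nxt["bitscore"]
            and best["length"] == nxt["length"]
        )
    best["tie_broken_by_id"] = bool(tie)
    return best


def select_best_hits(hits: pd.DataFrame, by: str = "qseqid") -> pd.DataFrame:
    """Best hit per ``by`` group (vectorized version of select_best_hit)."""
    if len(hits) == 0:
        return hits.copy()
    ordered = _best_order(hits)
    return ordered.groupby(by, sort=False).head(1).reset_index(drop=True)


def select_reciprocal_best(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    genome_col: str = "subject_genome",
) -> tuple[pd.DataFrame, dict]:
    """Reciprocal best matches, computed separately per subject genome.

    ``forward`` maps query genes to subject-genome transcripts; ``reverse``
    maps subject transcripts back to query genes (its qseqid/sseqid are
    swapped relative to forward).  A pair (q, s) is kept iff s is q's best
    forward hit within that genome and q is s's best reverse hit.
    Non-reciprocal pairs are dropped silently; counts are reported in the
    returned stats dict.  Output is invariant to input row order.
    """
    stats = {"forward_best": 0, "reverse_best": 0, "reciprocal": 0, "dropped": 0}
    kept = []
    genomes = sorted(set(forward[genome_col]))
    for genome in genomes:
        fwd = select_best_hits(forward[forward[genome_col] == genome], by="qseqid")
        rev_pool = reverse[reverse[genome_col] == genome] if genome_col in reverse.columns else reverse
        rev = select_best_hits(rev_pool, by="qseqid")
        stats["forward_best"] += len(fwd)
        stats["reverse_best"] += len(rev)
        back = dict(zip(rev["qseqid"], rev["sseqid"]))
        mutual = fwd[fwd.apply(lambda h: back.get(h["sseqid"]) == h["qseqid"], axis=1)]
        stats["reciprocal"] += len(mutual)
        stats["dropped"] += len(fwd) - len(mutual)
        kept.append(mutual)
    out = pd.concat(kept, ignore_index=True) if kept else forward.iloc[0:0].copy()
    out = out.sort_values(["qseqid", genome_col]).reset_index(drop=True)
    return out, stats


def binned_identity_profile(
    rbh: pd.DataFrame,
    positions: pd.DataFrame | None = None,
    bin_matches: int = 100,
    step_matches: int = 20,
    genome_col: str = "subject_genome",
) -> pd.DataFrame:
    """Mean percent identity in sliding bins of consecutive RBH matches.

    Matches are ordered by query genomic position within each chromosome
    (gene start coordinate, joined from ``positions`` on qseqid when the
    rbh frame lacks chrom/pos columns); bins hold ``bin_matches`` matches
    and advance by ``step_matches``; trailing partial bins are dropped, and
    bins never span chromosomes.  Bin position = mean match position.
    """
    df = rbh.copy()
    if positions is not None:
        df = df.merge(
            positions.rename(columns={"gene_id": "qseqid"})[["qseqid", "chrom", "pos"]],
            on="qseqid",
            how="left",
        )
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"RBH records need a {col!r} column (pass positions)")
    if df["pos"].isna().any():
        raise ValueError("some RBH queries have no genomic position")
    rows = []
    for genome, sub in df.groupby(genome_col, sort=True):
        for chrom, cdf in sub.groupby("chrom", sort=True):
            cdf = cdf.sort_values(["pos", "qseqid"], kind="stable")
            ident = cdf["pident"].to_numpy(dtype=float)
            pos = cdf["pos"].to_numpy(dtype=float)
            for s in window_starts(len(cdf), bin_matches, step_matches):
                sl = slice(s, s + bin_matches)
                rows.append(
                    {
                        "chrom": chrom,
                        "mean_pos": float(pos[sl].mean()),
                        "subject_genome": genome,
                        "value": float(ident[sl].mean()),
                        "n_sites": bin_matches,
                        "statistic": "identity",
                    }
                )
    return pd.DataFrame(rows)
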