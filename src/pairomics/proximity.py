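"""Genome linearization and co-enrichment window scanning.

Features from all three omics layers are projected onto a single axis by
concatenating chromosomes in the fixed order 1..22, X, Y and placing each
feature at its interval midpoint. A fixed-width window (default 1 Mb) is
slid along the axis counting significant features per layer; windows holding
at least one significant miRNA, gene and protein and more than ten
significant features in total are merged into enriched regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CHROMOSOMES, FeatureAnnotation, OmicsKind

__all__ = [
    "chromosome_offsets",
    "linearize",
    "scan_windows",
    "select_regions",
    "manhattan_table",
]

#: More than 10 significant features required inside a region.
DEFAULT_MIN_TOTAL = 11


def chromosome_offsets(chrom_lengths: dict) -> dict[str, int]:
    """Cumulative offsets of the chromosomes, canonical order."""
    offsets: dict[str, int] = {}
    running = 0
    for chrom in CHROMOSOMES:
        if chrom in chrom_lengths:
            offsets[chrom] = running
            running += int(chrom_lengths[chrom])
    return offsets


def linearize(annotation: FeatureAnnotation, chrom_lengths: dict) -> pd.DataFrame:
    """Map features to global positions on the concatenated genome.

    Each feature sits at floor((start + end) / 2) within its chromosome;
    the global position adds the cumulative length of preceding chromosomes.
    """
    offsets = chromosome_offsets(chrom_lengths)
    t = annotation.table
    missing = set(t["chromosome"]) - set(offsets)
    if missing:
        raise ValueError(f"chromosomes without a known length: {sorted(missing)}")
    midpoint = (t["start"] + t["end"]) // 2
    lengths = t["chromosome"].map(lambda c: int(chrom_lengths[c]))
    beyond = t[midpoint > lengths]
    if len(beyond):
        raise ValueError(
            f"features beyond chromosome end: {beyond['feature_id'].tolist()[:10]}"
        )
    out = pd.DataFrame(
        {
            "feature_id": t["feature_id"],
            "omics_kind": t["omics_kind"],
            "chromosome": t["chromosome"],
            "midpoint": midpoint.astype(int),
            "global_position": (t["chromosome"].map(offsets) + midpoint).astype(int),
        }
    )
    return out.reset_index(drop=True)


def scan_windows(
    positions: pd.DataFrame,
    significant_ids,
    window_size: int = 1_000_000,
    step: int = 500_000,
    total_length: int | None = None,
) -> pd.DataFrame:
    """Count significant features per omics kind in sliding windows.

    Windows are half-open [w, w + window_size), starting at 1 and advancing
    by ``step``; a feature on the right-open boundary belongs to the next
    window. Counting is done with sorted-array bisection and is exactly
    equivalent to a per-window recount.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    sig = positions[positions["feature_id"].isin(set(significant_ids))]
    if total_length is None:
        total_length = int(positions["global_position"].max()) if len(positions) else 1
    starts = np.arange(1, total_length + 1, step, dtype=np.int64)
    counts = {}
    for kind in OmicsKind:
        pos = np.sort(
            sig.loc[sig["omics_kind"] == kind.value, "global_position"].to_numpy()
        )
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size, side="left")
        counts[kind.value] = hi - lo
    out = pd.DataFrame(
        {
            "window_start": starts,
            "window_end": starts + window_size,
            "n_mirna": counts[OmicsKind.MIRNA.value],
            "n_gene": counts[OmicsKind.MRNA.value],
            "n_protein": counts[OmicsKind.PROTEIN.value],
        }
    )
    out["n_total"] = out[["n_mirna", "n_gene", "n_protein"]].sum(axis=1)
    return out


def select_regions(
    windows: pd.DataFrame,
    positions: pd.DataFrame,
    significant_ids,
    chrom_lengths: dict,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Merge qualifying windows into maximal enriched regions.

    A window qualifies when it holds at least one significant feature of
    every omics kind and at least ``min_total`` significant features overall.
    Overlapping or touching qualifying windows merge; merged spans are cut at
    chromosome boundaries, member features and counts are recomputed per
    piece, and pieces that no longer meet the criteria are dropped.
    Coordinates in the result are chromosome-local, 1-based inclusive.
    """
    qual = windows[
        (windows["n_mirna"] >= 1)
        & (windows["n_gene"] >= 1)
        & (windows["n_protein"] >= 1)
        & (windows["n_total"] >= min_total)
    ]
    cols = [
        "chromosome",
        "start",
        "end",
        "n_mirna",
        "n_gene",
        "n_protein",
        "n_total",
        "feature_ids",
    ]
    if len(qual) == 0:
        return pd.DataFrame(columns=cols)

    # merge overlapping/adjacent half-open spans in global coordinates
    merged: list[list[int]] = []
    for start, end in zip(qual["window_start"], qual["window_end"]):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(end))
        else:
            merged.append([int(start), int(end)])

    offsets = chromosome_offsets(chrom_lengths)
    sig = positions[positions["feature_id"].isin(set(significant_ids))]
    records = []
    for gstart, gend in merged:
        for chrom, offset in offsets.items():
            chrom_span = (offset + 1, offset + int(chrom_lengths[chrom]) + 1)
            lo = max(gstart, chrom_span[0])
            hi = min(gend, chrom_span[1])
            if lo >= hi:
                continue
            members = sig[
                (sig["global_position"] >= lo) & (sig["global_position"] < hi)
            ]
            kind_counts = members["omics_kind"].value_counts()
            n_mir = int(kind_counts.get(OmicsKind.MIRNA.value, 0))
            n_gene = int(kind_counts.get(OmicsKind.MRNA.value, 0))
            n_prot = int(kind_counts.get(OmicsKind.PROTEIN.value, 0))
            total = n_mir + n_gene + n_prot
            if n_mir < 1 or n_gene < 1 or n_prot < 1 or total < min_total:
                continue
            records.append(
                {
                    "chromosome": chrom,
                    "start": lo - offset,
                    "end": hi - 1 - offset,  # inclusive end
                    "n_mirna": n_mir,
                    "n_gene": n_gene,
                    "n_protein": n_prot,
                    "n_total": total,
                    "feature_ids": ",".join(sorted(members["feature_id"])),
                }
            )
    return pd.DataFrame(records, columns=cols)


def manhattan_table(
    results_by_kind: dict, positions: pd.DataFrame, adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Plot-ready table of -log10 adjusted p against global position.

    ``results_by_kind`` maps omics kind to its differential result table.
    Adjusted p-values of exactly zero are clamped to the smallest positive
    float before taking the logarithm.
    """
    col = {"bonferroni": "p_bonferroni", "bh": "p_bh"}[adjust.lower()]
    tiny = np.finfo(float).tiny
    frames = []
    for kind, results in results_by_kind.items():
        kind = OmicsKind(kind).value
        pos = positions[positions["omics_kind"] == kind]
        merged = pos.merge(
            results[["feature_id", col]], on="feature_id", how="inner"
        )
        merged["neg_log10_adj_p"] = -np.log10(np.maximum(merged[col], tiny))
        frames.append(
            merged[["feature_id", "omics_kind", "global_position", "neg_log10_adj_p"]]
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["feature_id", "omics_kind", "global_position", "neg_log10_adj_p"]
    )
    return out.sort_values(["global_position", "feature_id"]).reset_index(drop=True)
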