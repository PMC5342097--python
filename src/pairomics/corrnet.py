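"""Ab-initio all-pairs correlation network across concatenated omics layers.

Every feature pair (within and between layers) is tested for Pearson
correlation across all samples; only pairs passing a family-wise Bonferroni
threshold become edges. The pair matrix is evaluated blockwise so the full
feature x feature correlation matrix is never materialized.
"""

from __future__ import annotations

import itertools
import logging
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ExpressionMatrix, OmicsKind
from .stats import PSEUDOCOUNT

logger = logging.getLogger("pairomics")

__all__ = ["family_alpha", "pairwise_correlation_edges", "pair_type_summary"]

_KIND_ORDER = [OmicsKind.MIRNA.value, OmicsKind.MRNA.value, OmicsKind.PROTEIN.value]


def pair_type(kind_a: str, kind_b: str) -> str:
    """Canonical unordered pair-type label, e.g. ``miRNA-mRNA``."""
    a, b = sorted((OmicsKind(kind_a).value, OmicsKind(kind_b).value),
                  key=_KIND_ORDER.index)
    return f"{a}-{b}"


def family_alpha(n_features: int, family_alpha_level: float = 0.05) -> float:
    """Bonferroni per-test threshold for testing all C(n, 2) feature pairs."""
    if n_features < 2:
        raise ValueError("need at least 2 features for pairwise testing")
    return family_alpha_level / comb(n_features, 2)


def _correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    # two-sided p from the t transform of r with n-2 df
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, np.finfo(float).tiny))
    return 2 * sps.t.sf(np.abs(t), df=n - 2)


def pairwise_correlation_edges(
    matrices: list[ExpressionMatrix],
    threshold: float,
    sample_ids: list[str] | None = None,
    max_block_size: int = 2000,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Significant Pearson correlations among all feature pairs.

    Correlations are computed on log2(x + 1) values over the pooled sample
    set (tumor and control together, or ``sample_ids`` if given). Constant
    features are excluded with a logged count. Returns one row per unordered
    pair with raw p below ``threshold``: feature_a, feature_b, kind_a,
    kind_b, pair_type, r, p_raw.
    """
    if sample_ids is None:
        sample_ids = matrices[0].sample_ids
    for m in matrices:
        if set(m.sample_ids) != set(sample_ids):
            raise ValueError("matrices must share the same sample set")
    n = len(sample_ids)
    if n < 3:
        raise ValueError("need >= 3 samples for correlation testing")

    feats, kinds, rows = [], [], []
    for m in matrices:
        log_vals = np.log2(m.data[sample_ids].to_numpy() + pseudocount)
        feats.extend(m.feature_ids)
        kinds.extend([m.omics_kind.value] * m.shape[0])
        rows.append(log_vals)
    x = np.vstack(rows)
    feats = np.array(feats)
    kinds = np.array(kinds)

    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    if constant.any():
        logger.info("excluding %d constant features", int(constant.sum()))
    z = centered[~constant] / norms[~constant, None]
    feats, kinds = feats[~constant], kinds[~constant]
    n_feat = len(feats)

    records = []
    block_starts = range(0, n_feat, max_block_size)
    for bi in block_starts:
        zi = z[bi : bi + max_block_size]
        for bj in range(bi, n_feat, max_block_size):
            zj = z[bj : bj + max_block_size]
            r_block = zi @ zj.T
            p_block = _correlation_pvalues(r_block, n)
            ii, jj = np.nonzero(p_block < threshold)
            gi, gj = ii + bi, jj + bj
            keep = gi < gj  # strict upper triangle of the global pair matrix
            for a, b in zip(gi[keep], gj[keep]):
                records.append(
                    (
                        feats[a],
                        feats[b],
                        kinds[a],
                        kinds[b],
                        pair_type(kinds[a], kinds[b]),
                        float(np.clip(r_block[a - bi, b - bj], -1, 1)),
                        float(p_block[a - bi, b - bj]),
                    )
                )
    edges = pd.DataFrame(
        records,
        columns=["feature_a", "feature_b", "kind_a", "kind_b", "pair_type", "r", "p_raw"],
    )
    return edges.sort_values(["feature_a", "feature_b"]).reset_index(drop=True)


def pair_type_summary(edges: pd.DataFrame, n_per_omics: dict) -> pd.DataFrame:
    """Observed vs expected edge fractions for the six unordered pair types.

    The expected fraction of pair type (A, B) under uniform pairing is
    n_A*n_B / C(N, 2) for A != B and C(n_A, 2) / C(N, 2) for A = B.
    """
    n_per = {OmicsKind(k).value: int(v) for k, v in n_per_omics.items()}
    total = sum(n_per.values())
    total_pairs = comb(total, 2)
    n_edges = len(edges)
    observed = edges["pair_type"].value_counts() if n_edges else pd.Series(dtype=int)
    records = []
    for a, b in itertools.combinations_with_replacement(_KIND_ORDER, 2):
        label = pair_type(a, b)
        n_a, n_b = n_per.get(a, 0), n_per.get(b, 0)
        expected = (comb(n_a, 2) if a == b else n_a * n_b) / total_pairs
        count = int(observed.get(label, 0))
        records.append(
            {
                "pair_type": label,
                "expected_fraction": expected,
                "observed_count": count,
                "observed_fraction": count / n_edges if n_edges else 0.0,
            }
        )
    return pd.DataFrame(records)
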