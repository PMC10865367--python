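"""Jaccard-index evaluation and multi-algorithm ranking tables.

JI(A, B) = |A intersect B| / |A union B|, on hole-filled regions: contours
are compared as the regions they enclose, because the index on 1-pixel rings
is near zero and carries no information about boundary agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import SegfuseError, ShapeMismatchError, UndefinedScoreError
from .fusion import FusionConfig, fuse
from .mask_io import BinaryMask, SegmentationSet


@dataclass(frozen=True)
class JaccardScore:
    value: float
    intersection_px: int
    union_px: int

    def __float__(self) -> float:
        return self.value


def jaccard(a, b) -> JaccardScore:
    """Jaccard index of two masks/contours, compared as filled regions."""
    pa = np.asarray(getattr(a, "pixels", a)).astype(bool)
    pb = np.asarray(getattr(b, "pixels", b)).astype(bool)
    if pa.shape != pb.shape:
        raise ShapeMismatchError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    pa = ndi.binary_fill_holes(pa)
    pb = ndi.binary_fill_holes(pb)
    union = int((pa | pb).sum())
    if union == 0:
        raise UndefinedScoreError("Jaccard index of two empty masks is undefined")
    inter = int((pa & pb).sum())
    return JaccardScore(value=inter / union, intersection_px=inter, union_px=union)


@dataclass(frozen=True)
class RankingTable:
    """One row per algorithm configuration, one JI column per case, plus the
    row mean and the 1-based rank by descending mean (ties keep input order).
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="algorithm")


def config_label(cfg: FusionConfig) -> str:
    label = cfg.algorithm
    if cfg.algorithm == "middle":
        label += f"-{cfg.middle_tiebreak}"
    if cfg.algorithm == "avg_target_input":
        label += f"-{cfg.target_index}"
    return label


def rank_algorithms(
    cases: list[tuple[SegmentationSet, BinaryMask]],
    configs: list[FusionConfig],
    labels: list[str] | None = None,
) -> RankingTable:
    """Run every config on every case and rank by mean Jaccard index.

    A fusion failure leaves a missing cell (NaN), excluded from that row's
    mean, and emits a warning.
    """
    if not cases or not configs:
        raise UndefinedScoreError("ranking needs at least one case and one config")
    if labels is None:
        labels = [config_label(c) for c in configs]
    case_cols = [f"case_{i}" for i in range(1, len(cases) + 1)]
    values = np.full((len(configs), len(cases)), np.nan)
    for r, cfg in enumerate(configs):
        for c, (segs, truth) in enumerate(cases):
            try:
                fused = fuse(segs, cfg)
                values[r, c] = jaccard(fused, truth).value
            except SegfuseError as exc:
                warnings.warn(
                    f"{labels[r]} failed on case {c + 1}: {exc}", stacklevel=2
                )
    df = pd.DataFrame(values, index=labels, columns=case_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        df["mean"] = np.nanmean(values, axis=1)
    order = np.argsort(-df["mean"].to_numpy(), kind="stable")
    ranks = np.empty(len(configs), dtype=int)
    ranks[order] = np.arange(1, len(configs) + 1)
    df["rank"] = ranks
    return RankingTable(table=df)


__all__ = ["JaccardScore", "RankingTable", "jaccard", "rank_algorithms", "config_label"]
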