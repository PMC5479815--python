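"""RPKM quantification, expression filtering, and profile normalization.

The filtering stage mirrors the dual trimming criteria used for the organoid
series: a gene is kept when (1) its day-14 RPKM is at or above a floor
(inclusive, default 0.2) and (2) its RPKM summed over all stages exceeds a
floor (strict, default 0.2).  By default criterion (1) is evaluated on
replicate A and criterion (2) on replicate B, matching the original
cross-comparison design; either criterion can be pointed at ``"A"``, ``"B"``
or ``"both"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import StageMatrix, stage_day
from .errors import InputError


def compute_rpkm(counts: StageMatrix) -> StageMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    rpkm_gj = 1e9 * count_gj / (mapped_total_j * length_g)

    Mapped totals are the per-stage genome-mapping totals carried in the
    matrix header, not column sums; use :func:`column_sum_totals` first if a
    column-sum fallback is wanted.
    """
    if counts.value_kind != "counts":
        raise InputError(f"expected counts, got {counts.value_kind!r}")
    if counts.mapped_totals is None:
        raise InputError("mapped totals missing; cannot compute RPKM")
    lengths = counts.lengths_bp.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise InputError("non-positive gene length")
    totals = counts.mapped_totals.to_numpy(dtype=float)
    rpkm = 1e9 * counts.values.to_numpy(dtype=float) / (totals[None, :] * lengths[:, None])
    return StageMatrix(
        values=pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.stages),
        lengths_bp=counts.lengths_bp,
        value_kind="rpkm",
        mapped_totals=counts.mapped_totals,
    )


def column_sum_totals(counts: StageMatrix) -> StageMatrix:
    """Replace mapped totals by column sums (fallback when totals are absent)."""
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        raise InputError("a stage column sums to zero; cannot use as total")
    return replace(counts, mapped_totals=totals.astype(float))


@dataclass
class FilterReport:
    """Outcome of the dual trimming criteria."""

    n_input: int
    n_kept: int
    kept_ids: list
    criteria: dict

    def __post_init__(self) -> None:
        assert self.n_kept == len(self.kept_ids) <= self.n_input

    def apply(self, sm: StageMatrix) -> StageMatrix:
        return sm.subset(self.kept_ids)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"n_input": self.n_input, "n_kept": self.n_kept,
                 "criteria": self.criteria},
                fh, indent=2, sort_keys=True,
            )

    def to_tsv(self, path) -> None:
        pd.Series(self.kept_ids, name="gene_id").to_csv(path, sep="\t", index=False)


def _criterion_mask(which: str, mask_a: pd.Series, mask_b: pd.Series) -> pd.Series:
    if which == "A":
        return mask_a
    if which == "B":
        return mask_b
    if which == "both":
        return mask_a & mask_b
    raise InputError(f"criterion target must be 'A', 'B' or 'both', got {which!r}")


def trim_genes(
    rpkm_a: StageMatrix,
    rpkm_b: StageMatrix,
    day14_min: float = 0.2,
    sum_min: float = 0.2,
    day14_on: str = "A",
    sum_on: str = "B",
) -> FilterReport:
    """Keep genes passing both trimming criteria; survivors in input order.

    Criterion (1): day-14 RPKM >= ``day14_min`` (inclusive).
    Criterion (2): sum of RPKM over all stages > ``sum_min`` (strict).
    """
    for sm in (rpkm_a, rpkm_b):
        if sm.value_kind != "rpkm":
            raise InputError("trim_genes expects RPKM matrices")
    if set(rpkm_a.gene_ids) != set(rpkm_b.gene_ids):
        raise InputError("replicates have different gene universes")
    rpkm_b = rpkm_b.subset(rpkm_a.gene_ids)

    day14_cols_a = [c for c in rpkm_a.stages if stage_day(c) == 14]
    day14_cols_b = [c for c in rpkm_b.stages if stage_day(c) == 14]
    if not day14_cols_a or not day14_cols_b:
        raise InputError("day-14 stage column missing")

    c1 = _criterion_mask(
        day14_on,
        rpkm_a.values[day14_cols_a[0]] >= day14_min,
        rpkm_b.values[day14_cols_b[0]] >= day14_min,
    )
    c2 = _criterion_mask(
        sum_on,
        rpkm_a.values.sum(axis=1) > sum_min,
        rpkm_b.values.sum(axis=1) > sum_min,
    )
    keep = c1 & c2
    kept_ids = list(rpkm_a.gene_ids[keep])
    return FilterReport(
        n_input=rpkm_a.n_genes,
        n_kept=len(kept_ids),
        kept_ids=kept_ids,
        criteria={"day14_min": day14_min, "sum_min": sum_min,
                  "day14_on": day14_on, "sum_on": sum_on},
    )


def log_transform(rpkm: StageMatrix) -> StageMatrix:
    """log2(RPKM + 1), the scale used for the stage dendrogram/heatmap."""
    if rpkm.value_kind != "rpkm":
        raise InputError(f"expected rpkm, got {rpkm.value_kind!r}")
    return replace(rpkm, values=np.log2(rpkm.values + 1.0), value_kind="log_rpkm")


def log_normalize(rpkm: StageMatrix, mode: str = "subtract_log_mean") -> StageMatrix:
    """Per-gene normalized profiles on the log2 scale.

    Default (``subtract_log_mean``): x = log2(rpkm + 1) then subtract the
    gene's mean over stages, so every output row has mean 0.  The alternative
    ``divide_linear_mean`` divides each row by its linear-scale stage average
    before the log transform.
    """
    if rpkm.value_kind != "rpkm":
        raise InputError(f"expected rpkm, got {rpkm.value_kind!r}")
    vals = rpkm.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise InputError("negative RPKM values")
    if mode == "subtract_log_mean":
        x = np.log2(vals + 1.0)
        out = x - x.mean(axis=1, keepdims=True)
    elif mode == "divide_linear_mean":
        means = vals.mean(axis=1, keepdims=True)
        means[means == 0] = 1.0
        out = np.log2(vals / means + 1.0)
    else:
        raise InputError(f"unknown normalization mode {mode!r}")
    return replace(
        rpkm,
        values=pd.DataFrame(out, index=rpkm.gene_ids, columns=rpkm.stages),
        value_kind="normalized",
    )
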