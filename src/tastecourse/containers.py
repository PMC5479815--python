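"""Core container for stage-series expression data.

A :class:`StageMatrix` holds one replicate's genes x stages table together
with the per-gene transcript lengths and (for raw counts) the per-stage
mapped-read totals needed to compute RPKM.  Stage columns are labelled
``d<day>`` (``d2`` ... ``d14``) and must be ordered by day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError

VALUE_KINDS = ("counts", "rpkm", "log_rpkm", "normalized")


def stage_day(label: str) -> int:
    """Day number encoded in a stage label such as ``d14``."""
    if not label.startswith("d"):
        raise InputError(f"stage label {label!r} is not of the form d<day>")
    try:
        return int(label[1:])
    except ValueError as exc:
        raise InputError(f"stage label {label!r} is not of the form d<day>") from exc


@dataclass
class StageMatrix:
    """Genes x ordered growth stages for a single replicate series.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per stage (``d2``...).
    lengths_bp
        Transcript length per gene, in base pairs (>= 1).
    value_kind
        One of ``counts``, ``rpkm``, ``log_rpkm``, ``normalized``.
    mapped_totals
        Per-stage total mapped reads; required when ``value_kind='counts'``.
    """

    values: pd.DataFrame
    lengths_bp: pd.Series
    value_kind: str
    mapped_totals: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise InputError(f"unknown value_kind {self.value_kind!r}")
        if self.values.index.duplicated().any():
            raise InputError("duplicate gene ids in StageMatrix")
        if self.values.shape[1] < 2:
            raise InputError("StageMatrix needs at least 2 stage columns")
        days = [stage_day(c) for c in self.values.columns]
        if days != sorted(days):
            raise InputError("stage columns must be ordered by day")
        self.lengths_bp = self.lengths_bp.reindex(self.values.index)
        if self.lengths_bp.isna().any() or (self.lengths_bp < 1).any():
            raise InputError("gene lengths must be >= 1 bp for every gene")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise InputError("non-finite expression values")
        if self.value_kind in ("counts", "rpkm") and (arr < 0).any():
            raise InputError(f"negative values not allowed for {self.value_kind}")
        if self.value_kind == "counts":
            if self.mapped_totals is None:
                raise InputError("mapped_totals required for count matrices")
            self.mapped_totals = self.mapped_totals.reindex(self.values.columns)
            if self.mapped_totals.isna().any() or (self.mapped_totals <= 0).any():
                raise InputError("mapped totals must be positive for every stage")

    # -- basic views ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> list[str]:
        return list(self.values.columns)

    @property
    def days(self) -> list[int]:
        return [stage_day(c) for c in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def subset(self, gene_ids) -> "StageMatrix":
        """Return a new matrix restricted to ``gene_ids`` (order preserved)."""
        idx = pd.Index(gene_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise InputError(f"{len(missing)} requested genes absent from matrix")
        return replace(
            self,
            values=self.values.loc[idx],
            lengths_bp=self.lengths_bp.loc[idx],
        )

    # -- text serialization ------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: gene_id, length_bp, one column per stage.

        Mapped totals (when present) are stored in a ``#mapped_totals`` header
        comment so a single file round-trips a count matrix.
        """
        with open(path, "w") as fh:
            fh.write(f"#value_kind\t{self.value_kind}\n")
            if self.mapped_totals is not None:
                vals = "\t".join(repr(float(v)) for v in self.mapped_totals)
                fh.write(f"#mapped_totals\t{vals}\n")
            out = self.values.copy()
            out.insert(0, "length_bp", self.lengths_bp)
            out.index.name = "gene_id"
            out.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "StageMatrix":
        value_kind = None
        totals_raw = None
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, *rest = line[1:].rstrip("\n").split("\t")
                if key == "value_kind":
                    value_kind = rest[0]
                elif key == "mapped_totals":
                    totals_raw = [float(v) for v in rest]
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", index_col="gene_id")
        if value_kind is None:
            raise InputError(f"{path}: missing #value_kind header")
        lengths = df.pop("length_bp")
        totals = None
        if totals_raw is not None:
            totals = pd.Series(totals_raw, index=df.columns, dtype=float)
        return cls(values=df, lengths_bp=lengths, value_kind=value_kind,
                   mapped_totals=totals)
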