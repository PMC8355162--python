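"""RPKM normalization, expressed-gene filtering and fold-change DE calling.

The differential-expression definition used throughout the pipeline is the
one used for the transfection transcriptomes: counts are normalized to RPKM
(reads per kilobase of exon model per million mapped reads), genes must
exceed an RPKM threshold in *both* the treatment and the control-mimic
column to count as expressed, and a gene is called differentially expressed
when its fold change versus the control exceeds a plain ratio cutoff
(default 1.3) in either direction.  There is no dispersion-modelling test:
the DE rule is a deterministic threshold on the observed fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cardiomir.exceptions import ConfigurationError, InputError

DEFAULT_RPKM_THRESHOLD = 2.00
DEFAULT_FC_CUTOFF = 1.3
DEFAULT_PSEUDOCOUNT = 0.25

DE_UP = "up"
DE_DOWN = "down"
DE_NOT_SIGNIFICANT = "not_significant"
DE_NOT_EXPRESSED = "not_expressed"


@dataclass
class GeneExpressionMatrix:
    """Gene-level counts for one control condition plus >=1 treatments.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes (index) x conditions (columns).
    lengths_bp
        Exon-model length per gene in base pairs, aligned to ``counts.index``.
    control
        Column label of the control condition (the control mimic).
    library_sizes
        Mapped-read totals per condition.  Defaults to the column sums of
        ``counts`` -- the mapped-read total is not recoverable from a count
        matrix alone, so the column sum is the standard stand-in.
    """

    counts: pd.DataFrame
    lengths_bp: pd.Series
    control: str
    library_sizes: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.lengths_bp = self.lengths_bp.reindex(self.counts.index)
        if self.lengths_bp.isna().any():
            raise InputError("every gene needs a length in lengths_bp")
        if (self.lengths_bp <= 0).any():
            raise InputError("gene lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts must be non-negative")
        if self.control not in self.counts.columns:
            raise InputError(
                f"control condition {self.control!r} not among columns "
                f"{list(self.counts.columns)}"
            )
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise InputError("library_sizes must cover every condition")
        if (self.library_sizes <= 0).any():
            raise InputError("library sizes must be positive")

    @property
    def treatments(self) -> list[str]:
        return [c for c in self.counts.columns if c != self.control]

    @classmethod
    def from_tsv(cls, path, control: str) -> "GeneExpressionMatrix":
        """Read a gene_id / length_bp / per-condition-columns TSV."""
        df = pd.read_csv(path, sep="\t")
        if "gene_id" not in df.columns or "length_bp" not in df.columns:
            raise InputError("counts TSV needs gene_id and length_bp columns")
        df = df.set_index("gene_id")
        lengths = df.pop("length_bp")
        return cls(counts=df, lengths_bp=lengths, control=control)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.lengths_bp)
        out.to_csv(path, sep="\t", index_label="gene_id")


def compute_rpkm(matrix: GeneExpressionMatrix) -> pd.DataFrame:
    """RPKM per gene and condition.

    rpkm[g, c] = counts[g, c] / ((length_bp[g] / 1e3) * (library_size[c] / 1e6))
    """
    kb = matrix.lengths_bp.to_numpy(dtype=float)[:, None] / 1e3
    per_million = matrix.library_sizes.to_numpy(dtype=float)[None, :] / 1e6
    values = matrix.counts.to_numpy(dtype=float) / (kb * per_million)
    return pd.DataFrame(values, index=matrix.counts.index, columns=matrix.counts.columns)


def flag_expressed(
    rpkm_control: pd.Series,
    rpkm_treatment: pd.Series,
    rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD,
) -> pd.Series:
    """True iff RPKM is strictly greater than the threshold in both conditions."""
    if rpkm_threshold < 0:
        raise ConfigurationError("rpkm_threshold must be non-negative")
    return (rpkm_control > rpkm_threshold) & (rpkm_treatment > rpkm_threshold)


def compute_fold_changes(
    rpkm: pd.DataFrame,
    control: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD,
) -> pd.DataFrame:
    """Long-form fold-change table: one row per (gene, treatment).

    log2fc = log2((rpkm_treatment + pseudocount) / (rpkm_control + pseudocount));
    the pseudocount guards against zeros and is irrelevant for genes passing
    the expressed filter at typical depths.
    """
    if control not in rpkm.columns:
        raise InputError(f"control column {control!r} missing from RPKM matrix")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be non-negative")
    ctrl = rpkm[control]
    frames = []
    for treatment in (c for c in rpkm.columns if c != control):
        trt = rpkm[treatment]
        with np.errstate(divide="ignore"):
            log2fc = np.log2((trt + pseudocount) / (ctrl + pseudocount))
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": rpkm.index,
                    "mirna": treatment,
                    "rpkm_control": ctrl.to_numpy(),
                    "rpkm_treatment": trt.to_numpy(),
                    "log2fc": log2fc.to_numpy(),
                    "expressed": flag_expressed(ctrl, trt, rpkm_threshold).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_de(records: pd.DataFrame, fc_cutoff: float = DEFAULT_FC_CUTOFF) -> pd.DataFrame:
    """Assign de_status from the fold-change threshold.

    Expressed genes with |log2fc| > log2(fc_cutoff) are 'up'/'down' by sign;
    the down direction is the symmetric FC < 1/fc_cutoff reading of the
    cutoff.  Unexpressed genes are 'not_expressed'.
    """
    if fc_cutoff <= 1:
        raise ConfigurationError("fc_cutoff must be > 1")
    out = records.copy()
    log_cut = np.log2(fc_cutoff)
    status = np.full(len(out), DE_NOT_SIGNIFICANT, dtype=object)
    status[(out["log2fc"] > log_cut).to_numpy()] = DE_UP
    status[(out["log2fc"] < -log_cut).to_numpy()] = DE_DOWN
    status[~out["expressed"].to_numpy()] = DE_NOT_EXPRESSED
    out["de_status"] = status
    return out


def quantify(
    matrix: GeneExpressionMatrix,
    rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Counts -> RPKM -> fold changes -> DE status, in one step."""
    rpkm = compute_rpkm(matrix)
    records = compute_fold_changes(
        rpkm, matrix.control, pseudocount=pseudocount, rpkm_threshold=rpkm_threshold
    )
    return call_de(records, fc_cutoff=fc_cutoff)


def de_gene_sets(records: pd.DataFrame, mirna: str) -> dict[str, set[str]]:
    """Up/down gene sets for one treatment from a long-form DE table."""
    sub = records[records["mirna"] == mirna]
    if sub.empty:
        raise InputError(f"treatment {mirna!r} absent from DE table")
    return {
        DE_UP: set(sub.loc[sub["de_status"] == DE_UP, "gene_id"]),
        DE_DOWN: set(sub.loc[sub["de_status"] == DE_DOWN, "gene_id"]),
    }
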