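"""RPKM expression quantification from per-stage read-count tables.

Read mapping itself is out of scope; the interface is a count table with one
row per transcript and one column per (stage, replicate) library, plus the
total mapped reads of each library (mapping to the whole reference
transcriptome, so the library total may exceed the catalog sum).

RPKM = counts / (length_kb * mapped_Mreads); developmental summaries are
means and standard deviations over replicates on the log2(RPKM + pseudocount)
scale, matching how stage expression profiles are usually displayed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_STAGES = ("embryo", "NI-II", "NV-VI", "CI-II", "CV", "adult_female")
DEFAULT_PSEUDOCOUNT = 1.0


def rpkm(counts: float, total_mapped: int, length_bp: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    if length_bp <= 0:
        raise ValueError("length_bp must be > 0")
    return counts / ((length_bp / 1e3) * (total_mapped / 1e6))


@dataclass
class CountTable:
    """Per-(transcript, stage, replicate) read counts with library sizes.

    ``counts`` is indexed by transcript id with a (stage, replicate)
    MultiIndex on the columns; ``total_mapped`` is indexed by the same
    (stage, replicate) pairs; ``lengths`` maps transcript id to length in bp.
    """

    counts: pd.DataFrame
    total_mapped: pd.Series
    lengths: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(pd.MultiIndex.from_tuples(
                list(self.total_mapped.index), names=self.counts.columns.names)):
            self.total_mapped = self.total_mapped.reindex(self.counts.columns)
        if self.total_mapped.isna().any():
            raise ValueError("total_mapped missing for some libraries")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        short = self.counts.sum(axis=0) > self.total_mapped
        if short.any():
            bad = list(self.counts.columns[short])
            raise ValueError(f"library total_mapped below catalog sum: {bad}")
        missing = set(self.counts.index) - set(self.lengths.index)
        if missing:
            raise ValueError(f"missing lengths for transcripts {sorted(missing)[:5]}")

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(s for s, _ in self.counts.columns))

    def replicates(self, stage: str) -> list:
        return [r for s, r in self.counts.columns if s == stage]

    def to_tsv(self, counts_path: str | Path, libsize_path: str | Path) -> None:
        flat = self.counts.copy()
        flat.columns = [f"{s}:{r}" for s, r in flat.columns]
        flat.insert(0, "length_bp", self.lengths.reindex(flat.index))
        flat.to_csv(counts_path, sep="\t", index_label="transcript_id")
        lib = self.total_mapped.copy()
        lib.index = [f"{s}:{r}" for s, r in lib.index]
        lib.rename("total_mapped").to_csv(libsize_path, sep="\t",
                                          index_label="library")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, libsize_path: str | Path) -> "CountTable":
        flat = pd.read_csv(counts_path, sep="\t", index_col="transcript_id")
        lengths = flat.pop("length_bp")
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split(":", 1)) for c in flat.columns],
            names=["stage", "replicate"])
        flat.columns = cols
        lib = pd.read_csv(libsize_path, sep="\t", index_col="library")["total_mapped"]
        lib.index = pd.MultiIndex.from_tuples(
            [tuple(c.split(":", 1)) for c in lib.index],
            names=["stage", "replicate"])
        return cls(flat, lib, lengths)


@dataclass
class ExpressionTable:
    """RPKM per library plus per-stage log2 summaries."""

    rpkm: pd.DataFrame        # (transcript, (stage, replicate))
    log2_rpkm: pd.DataFrame
    stage_mean: pd.DataFrame  # (transcript, stage), log2 scale
    stage_sd: pd.DataFrame
    pseudocount: float

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            {"mean_log2_rpkm": self.stage_mean, "sd_log2_rpkm": self.stage_sd},
            axis=1)
        out.columns = [f"{metric}:{stage}" for metric, stage in out.columns]
        out.to_csv(path, sep="\t", index_label="transcript_id")


def rpkm_table(ct: CountTable) -> pd.DataFrame:
    lengths_kb = ct.lengths.reindex(ct.counts.index) / 1e3
    mreads = ct.total_mapped / 1e6
    return ct.counts.div(mreads, axis=1).div(lengths_kb, axis=0)


def summarize_stages(ct: CountTable,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ExpressionTable:
    """RPKM, log2(RPKM + pseudocount), and per-stage replicate mean/SD.

    SD is the sample standard deviation over replicates (0 by definition for
    a single-replicate stage).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    rp = rpkm_table(ct)
    log2 = np.log2(rp + pseudocount)
    stage_mean = log2.T.groupby(level="stage", sort=False).mean().T
    stage_sd = log2.T.groupby(level="stage", sort=False).std(ddof=1).T.fillna(0.0)
    order = ct.stages
    return ExpressionTable(rp, log2, stage_mean[order], stage_sd[order],
                           pseudocount)


def plot_stage_expression(expr: ExpressionTable, transcript_ids: Sequence[str],
                          path: str | Path) -> None:
    """Simple per-stage bar plot of mean log2 RPKM with SD error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(transcript_ids)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.2 * n), squeeze=False)
    stages = list(expr.stage_mean.columns)
    x = np.arange(len(stages))
    for ax, tid in zip(axes.ravel(), transcript_ids):
        ax.bar(x, expr.stage_mean.loc[tid], yerr=expr.stage_sd.loc[tid],
               color="0.3", capsize=3)
        ax.set_xticks(x, stages, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel("log2 RPKM")
        ax.set_title(tid, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
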