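"""Pooled CRISPR suppressor-screen scoring.

Reads are trimmed at a constant prefix, the following 22-nt barcode is
matched exactly against the sgRNA library (perfect matches only — any
mismatch discards the read), counts are normalized to reads per million
mapped reads (RPM), and genes are scored by the median log2 fold change
of their guides between treated and control conditions.  Gene-level
abundance is the sum of the per-condition median guide RPMs, giving the
x-axis of the Bland-Altman MA table.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

BARCODE_LENGTH = 22
_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SgRNALibrary:
    """sgRNA library: one row per guide with its gene and 22-nt barcode."""

    table: pd.DataFrame  # columns: sgrna_id, gene, barcode

    def __post_init__(self):
        t = self.table
        required = {"sgrna_id", "gene", "barcode"}
        if not required.issubset(t.columns):
            raise ValueError(f"library table needs columns {sorted(required)}")
        if t.empty:
            raise ValueError("empty sgRNA library")
        barcodes = t["barcode"].astype(str)
        if barcodes.duplicated().any():
            dup = barcodes[barcodes.duplicated()].iloc[0]
            raise ValueError(f"duplicate barcode in library: {dup}")
        if t["sgrna_id"].duplicated().any():
            raise ValueError("duplicate sgrna_id in library")
        bad = barcodes[
            (barcodes.str.len() != BARCODE_LENGTH)
            | ~barcodes.map(lambda b: set(b) <= _VALID_BASES)
        ]
        if not bad.empty:
            raise ValueError(f"invalid barcode (need {BARCODE_LENGTH}-nt ACGT): {bad.iloc[0]}")

    @classmethod
    def from_csv(cls, path) -> "SgRNALibrary":
        return cls(pd.read_csv(path, dtype=str))

    @property
    def barcode_to_sgrna(self) -> dict[str, str]:
        return dict(zip(self.table["barcode"], self.table["sgrna_id"]))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ScreenCountTable:
    """Per-sgRNA read counts for the treated and control conditions."""

    counts: pd.DataFrame  # index sgrna_id, columns subset of {treated, control}
    library: SgRNALibrary

    @property
    def total_mapped(self) -> pd.Series:
        return self.counts.sum(axis=0)


def read_fastq_sequences(path):
    """Yield read sequences from a FASTQ file (gzip-aware)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq)


def trim_reads(reads, prefix: str):
    """Extract the 22-nt barcode that follows the constant prefix.

    The prefix is located by exact substring search (first occurrence);
    reads lacking the exact prefix, or with fewer than 22 bases after it,
    are dropped.  Returns (barcodes, n_dropped).
    """
    if not prefix:
        raise ValueError("prefix must be nonempty")
    barcodes: list[str] = []
    dropped = 0
    for read in reads:
        pos = read.find(prefix)
        if pos < 0:
            dropped += 1
            continue
        start = pos + len(prefix)
        barcode = read[start : start + BARCODE_LENGTH]
        if len(barcode) < BARCODE_LENGTH:
            dropped += 1
            continue
        barcodes.append(barcode)
    return barcodes, dropped


def count_barcodes(barcodes, library: SgRNALibrary) -> tuple[pd.Series, int]:
    """Count barcodes matching library entries exactly.

    Any barcode not identical to a library barcode (even a single
    mismatch) is discarded.  Returns (counts indexed by sgrna_id over the
    whole library, n_unmatched).
    """
    lookup = library.barcode_to_sgrna
    counts = dict.fromkeys(library.table["sgrna_id"], 0)
    unmatched = 0
    for bc in barcodes:
        sg = lookup.get(bc)
        if sg is None:
            unmatched += 1
        else:
            counts[sg] += 1
    return pd.Series(counts, name="count"), unmatched


def count_table_from_fastq(
    library: SgRNALibrary, prefix: str, treated_path, control_path
) -> ScreenCountTable:
    """Trim and count both conditions' FASTQ files into a ScreenCountTable."""
    cols = {}
    for name, path in (("treated", treated_path), ("control", control_path)):
        barcodes, _ = trim_reads(read_fastq_sequences(path), prefix)
        counts, _ = count_barcodes(barcodes, library)
        cols[name] = counts
    return ScreenCountTable(counts=pd.DataFrame(cols), library=library)


def normalize_rpm(table: ScreenCountTable) -> pd.DataFrame:
    """Reads per million mapped reads: count / total_mapped * 1e6 per condition."""
    totals = table.total_mapped
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero mapped reads in condition(s) {bad}")
    return table.counts / totals * 1e6


def sgrna_log2fc(rpm_treated, rpm_control, pseudocount: float = 0.5):
    """Per-guide log2((rpm_treated + pc) / (rpm_control + pc)).

    The symmetric pseudocount (default 0.5 RPM) keeps dropout guides —
    expected under a killed-control design — finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    t = np.asarray(rpm_treated, dtype=float)
    c = np.asarray(rpm_control, dtype=float)
    return np.log2((t + pseudocount) / (c + pseudocount))


def gene_median_log2fc(log2fcs_by_gene: pd.Series) -> pd.Series:
    """Median per-gene of its guides' log2 fold changes.

    `log2fcs_by_gene` is a Series of per-guide log2FCs indexed (or
    groupable) by gene; standard median (mean of the central pair for an
    even number of guides).
    """
    return log2fcs_by_gene.groupby(level="gene").median()


def score_screen(
    table: ScreenCountTable, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Full gene-level scoring of a two-condition screen count table.

    Returns a frame indexed by gene with columns median_log2fc (median of
    the per-guide log2FC of RPM between treated and control),
    abundance_rpm (median guide RPM in treated + median in control), and
    n_sgrnas, sorted by median_log2fc descending (ties broken by gene
    name).
    """
    rpm = normalize_rpm(table)
    genes = table.library.table.set_index("sgrna_id")["gene"]
    rpm = rpm.join(genes, how="left")

    lfc = sgrna_log2fc(rpm["treated"], rpm["control"], pseudocount)
    per_guide = pd.DataFrame(
        {"gene": rpm["gene"], "log2fc": lfc, "treated": rpm["treated"], "control": rpm["control"]}
    )
    g = per_guide.groupby("gene")
    out = pd.DataFrame(
        {
            "median_log2fc": g["log2fc"].median(),
            "abundance_rpm": g["treated"].median() + g["control"].median(),
            "n_sgrnas": g.size(),
        }
    )
    out = out.sort_index(kind="mergesort")
    return out.sort_values("median_log2fc", ascending=False, kind="mergesort")


def ma_table(gene_scores: pd.DataFrame) -> pd.DataFrame:
    """Bland-Altman MA table: (gene, abundance_rpm, median_log2fc).

    Sorted by median_log2fc descending; ties ordered by gene name
    (stable).  Raises on empty input.
    """
    if gene_scores.empty:
        raise ValueError("no gene scores")
    out = gene_scores.reset_index()[["gene", "abundance_rpm", "median_log2fc"]]
    out = out.sort_values("gene", kind="mergesort")
    return out.sort_values(
        "median_log2fc", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
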