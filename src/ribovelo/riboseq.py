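"""Ribosome-footprint processing: P-site calibration, codon occupancy,
periodicity QC, scaled footprints and the coverage filter.

Coordinates are CDS-local, 0-based, half-open throughout. Footprint
reads are rows of a DataFrame with columns ``gene_id``,
``five_prime_pos`` (nt offset of the read's 5' end within the CDS,
may be negative by up to the P-site offset) and ``length`` (nt).
Scaled footprints — per-codon counts divided by the gene's mean count
over the analyzed codon range — are the translation-velocity proxy:
larger values mean slower elongation (more ribosome dwell).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

READ_COLUMNS = ("gene_id", "five_prime_pos", "length")

# candidate P-site offsets scanned during start-codon calibration (nt)
DEFAULT_OFFSET_WINDOW = (8, 18)
# peak/mean ratio below which a length's calibration is flagged
LOW_CONFIDENCE_RATIO = 2.0


@dataclass
class OffsetTable:
    """Per-read-length P-site offsets plus calibration diagnostics."""

    offsets: dict[int, int]
    read_counts: dict[int, int] = field(default_factory=dict)
    low_confidence: set[int] = field(default_factory=set)
    dropped: set[int] = field(default_factory=set)

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length": sorted(self.offsets),
                "offset": [self.offsets[l] for l in sorted(self.offsets)],
                "n_reads": [self.read_counts.get(l, 0) for l in sorted(self.offsets)],
                "low_confidence": [
                    l in self.low_confidence for l in sorted(self.offsets)
                ],
            }
        )


@dataclass
class CodonOccupancy:
    gene_id: str
    counts: np.ndarray  # int, one entry per sense codon


@dataclass
class ScaledProfile:
    gene_id: str
    values: np.ndarray          # float, NaN outside analyzed range
    covered_fraction: float
    analyzed_range: tuple[int, int]
    zero_total: bool = False


def _check_reads(reads: pd.DataFrame) -> None:
    missing = set(READ_COLUMNS) - set(reads.columns)
    if missing:
        raise ValueError(f"read table lacks columns: {sorted(missing)}")


def protein_lengths(gene_table: pd.DataFrame) -> dict[str, int]:
    """CDS length (nt, incl. stop) -> protein length in codons."""
    return {
        row.gene_id: int(row.cds_length) // 3 - 1
        for row in gene_table.itertuples()
    }


# ---------------------------------------------------------------------------
# Length selection and calibration
# ---------------------------------------------------------------------------

def read_length_histogram(reads: pd.DataFrame) -> dict[int, int]:
    """Exact read counts per footprint length."""
    if len(reads) == 0:
        return {}
    _check_reads(reads)
    vc = reads["length"].value_counts()
    return {int(l): int(c) for l, c in sorted(vc.items())}


def select_abundant_lengths(
    histogram: dict[int, int], min_fraction: float = 0.5
) -> set[int]:
    """Lengths with at least ``min_fraction`` of the modal length's count."""
    if not histogram:
        raise ValueError("empty length histogram")
    peak = max(histogram.values())
    return {l for l, c in histogram.items() if c >= min_fraction * peak}


def calibrate_psite_offsets(
    reads: pd.DataFrame,
    gene_table: pd.DataFrame,
    lengths: set[int] | None = None,
    offset_window: tuple[int, int] = DEFAULT_OFFSET_WINDOW,
) -> OffsetTable:
    """Determine the per-length P-site offset from the start-codon peak.

    For each read length, the offset is the o in ``offset_window`` that
    maximizes, over all genes, the number of reads whose shifted 5' end
    (five_prime_pos + o) lands exactly on the first nucleotide of the
    start codon; ties break toward the smaller offset. Lengths with no
    reads near any start codon are dropped with a warning; a peak/mean
    ratio under 2 flags the length low-confidence.
    """
    _check_reads(reads)
    if lengths is None:
        lengths = set(read_length_histogram(reads))
    lo, hi = offset_window
    candidates = np.arange(lo, hi + 1)
    table = OffsetTable(offsets={})
    for length in sorted(lengths):
        sub = reads.loc[reads["length"] == length, "five_prime_pos"].to_numpy()
        table.read_counts[length] = len(sub)
        # count reads with pos + o == 0  <=>  pos == -o
        hits = np.array([(sub == -o).sum() for o in candidates])
        if hits.sum() == 0:
            warnings.warn(
                f"read length {length}: no reads near start codons; dropped",
                stacklevel=2,
            )
            table.dropped.add(length)
            continue
        best = int(candidates[np.argmax(hits)])  # argmax takes first => smaller o
        table.offsets[length] = best
        if hits.max() < LOW_CONFIDENCE_RATIO * hits.mean():
            table.low_confidence.add(length)
    return table


# ---------------------------------------------------------------------------
# Occupancy, QC, scaling, filtering
# ---------------------------------------------------------------------------

def codon_occupancy(
    reads: pd.DataFrame,
    offsets: OffsetTable | dict[int, int],
    gene_table: pd.DataFrame,
) -> tuple[dict[str, CodonOccupancy], int]:
    """Per-gene codon-resolution counts; returns (occupancies, n_discarded).

    Each read adds 1 to codon floor((five_prime_pos + offset)/3) when
    that index lies within the gene's sense codons; reads shifted out of
    range, or with lengths absent from the offset table, are discarded
    (and counted).
    """
    _check_reads(reads)
    offmap = offsets.offsets if isinstance(offsets, OffsetTable) else dict(offsets)
    plens = protein_lengths(gene_table)
    unknown = set(reads["gene_id"].unique()) - set(plens)
    if unknown:
        raise ValueError(f"reads reference unknown gene ids: {sorted(unknown)[:5]}")

    occ = {g: CodonOccupancy(g, np.zeros(L, dtype=int)) for g, L in plens.items()}
    discarded = 0
    lengths = reads["length"].to_numpy()
    known_len = np.isin(lengths, list(offmap))
    discarded += int((~known_len).sum())
    sub = reads[known_len]
    shift = sub["five_prime_pos"].to_numpy() + np.array(
        [offmap[l] for l in sub["length"]]
    )
    codon = np.floor_divide(shift, 3)
    for gene_id, grp_idx in sub.groupby("gene_id", sort=False).indices.items():
        L = plens[gene_id]
        c = codon[grp_idx]
        ok = (c >= 0) & (c < L)
        np.add.at(occ[gene_id].counts, c[ok], 1)
        discarded += int((~ok).sum())
    return occ, discarded


@dataclass
class FrameQC:
    frame_fractions: tuple[float, float, float]
    start_coverage: np.ndarray   # mean coverage at nt offsets -30..+60 from start
    stop_coverage: np.ndarray    # mean coverage at nt offsets -60..+30 from stop
    status: str                  # "pass" | "fail"

    def to_dict(self) -> dict:
        return {
            "frame_fractions": list(self.frame_fractions),
            "start_coverage": self.start_coverage.tolist(),
            "stop_coverage": self.stop_coverage.tolist(),
            "status": self.status,
        }


def frame_periodicity_qc(
    reads: pd.DataFrame,
    offsets: OffsetTable | dict[int, int],
    gene_table: pd.DataFrame,
    pass_threshold: float = 0.5,
) -> FrameQC:
    """Three-nucleotide periodicity report on calibrated read positions.

    Codon-resolution data concentrates shifted 5' ends in frame 0;
    the report also gives mean per-gene coverage around the start
    (-30..+60 nt) and stop (-60..+30 nt) codons. Status is "fail" when
    the frame-0 fraction drops below ``pass_threshold`` — reported,
    never enforced.
    """
    _check_reads(reads)
    offmap = offsets.offsets if isinstance(offsets, OffsetTable) else dict(offsets)
    plens = protein_lengths(gene_table)
    known = reads["length"].isin(offmap)
    sub = reads[known]
    shift = sub["five_prime_pos"].to_numpy() + np.array(
        [offmap[l] for l in sub["length"]]
    )
    frames = np.bincount(np.mod(shift, 3), minlength=3)
    total = frames.sum()
    fracs = tuple((frames / total) if total else np.zeros(3))

    start_cov = np.zeros(91)  # -30..+60
    stop_cov = np.zeros(91)   # -60..+30
    n_genes = 0
    for gene_id, grp_idx in sub.groupby("gene_id", sort=False).indices.items():
        if gene_id not in plens:
            continue
        n_genes += 1
        cds_len = 3 * (plens[gene_id] + 1)
        pos = shift[grp_idx]
        s = pos + 30
        ok = (s >= 0) & (s < 91)
        np.add.at(start_cov, s[ok], 1)
        e = pos - cds_len + 60
        ok = (e >= 0) & (e < 91)
        np.add.at(stop_cov, e[ok], 1)
    if n_genes:
        start_cov /= n_genes
        stop_cov /= n_genes
    status = "pass" if total and fracs[0] >= pass_threshold else "fail"
    return FrameQC(fracs, start_cov, stop_cov, status)


def scale_footprints(
    occupancy: CodonOccupancy,
    exclude_first: int = 5,
    exclude_last: int = 5,
) -> ScaledProfile:
    """Gene-mean-normalized profile over the analyzed codon range.

    values[i] = count[i] / mean(count over [exclude_first, L - exclude_last));
    zeros are included in the mean; codons outside the range are NaN.
    An all-zero analyzed range yields an all-NaN profile with
    ``zero_total`` set.
    """
    L = len(occupancy.counts)
    start, stop = exclude_first, L - exclude_last
    if stop <= start:
        raise ValueError(
            f"{occupancy.gene_id}: analyzed range empty "
            f"(length {L}, exclusions {exclude_first}+{exclude_last})"
        )
    window = occupancy.counts[start:stop].astype(float)
    values = np.full(L, np.nan)
    covered = float((window > 0).mean())
    if window.sum() == 0:
        return ScaledProfile(occupancy.gene_id, values, covered, (start, stop), True)
    values[start:stop] = window / window.mean()
    return ScaledProfile(occupancy.gene_id, values, covered, (start, stop), False)


def coverage_filter(
    occupancies: dict[str, CodonOccupancy],
    threshold: float = 0.6,
    exclude_first: int = 5,
    exclude_last: int = 5,
) -> list[str]:
    """Genes whose analyzed-range coverage is strictly above ``threshold``.

    Coverage = fraction of analyzed-range codons with at least one
    footprint; the strict inequality means exactly-60% genes are
    excluded at the 0.6 default.
    """
    kept = []
    for gene_id, occ in occupancies.items():
        L = len(occ.counts)
        start, stop = exclude_first, L - exclude_last
        if stop <= start:
            continue
        window = occ.counts[start:stop]
        if (window > 0).mean() > threshold:
            kept.append(gene_id)
    return kept


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_position_table(path: str | Path) -> pd.DataFrame:
    """Plain TSV read table: gene_id, five_prime_pos, length."""
    reads = pd.read_csv(path, sep="\t")
    _check_reads(reads)
    return reads.astype({"five_prime_pos": int, "length": int})


def read_alignments(
    path: str | Path,
    min_mapq: int = 10,
) -> pd.DataFrame:
    """Load unique single-end alignments from SAM/BAM against a CDS
    "transcriptome" (reference name = gene id, CDS-local coordinates).

    Multi-mapping reads are excluded by the mapping-quality threshold
    (uniquely mapped convention); secondary/supplementary alignments and
    reverse-strand reads are skipped. 1-based reference positions from
    the alignment become 0-based CDS offsets here, once, at this
    boundary.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    rows = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_reverse or aln.mapping_quality < min_mapq:
                continue
            rows.append(
                (aln.reference_name, aln.reference_start, aln.query_length)
            )
    return pd.DataFrame(rows, columns=list(READ_COLUMNS))


def occupancy_frame(occupancies: dict[str, CodonOccupancy],
                    profiles: dict[str, ScaledProfile] | None = None) -> pd.DataFrame:
    """Long-format table: gene_id, codon_index (0-based), count[, scaled_value]."""
    frames = []
    for gene_id in sorted(occupancies):
        occ = occupancies[gene_id]
        df = pd.DataFrame(
            {
                "gene_id": gene_id,
                "codon_index": np.arange(len(occ.counts)),
                "count": occ.counts,
            }
        )
        if profiles is not None and gene_id in profiles:
            df["scaled_value"] = profiles[gene_id].values
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
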