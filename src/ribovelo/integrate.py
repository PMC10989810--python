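"""Join codon-level velocity profiles with residue-level structure
features, attach codon usage frequencies, and label protein regions."""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd

from .constants import SENSE_CODONS, STOP_CODONS, translate
from .riboseq import ScaledProfile


def compute_codon_usage(cds_collection: dict[str, str]) -> dict[str, float]:
    """Fraction of each sense codon among all sense codons in the input.

    Stop codons are excluded from both numerator and denominator; the 61
    frequencies sum to 1.
    """
    counts: Counter[str] = Counter()
    for gene_id, cds in cds_collection.items():
        if len(cds) % 3 != 0:
            raise ValueError(f"{gene_id}: CDS length {len(cds)} not a multiple of 3")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3].upper()
            if codon not in STOP_CODONS:
                counts[codon] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no sense codons in input")
    return {c: counts[c] / total for c in SENSE_CODONS}


def rscu(cds_collection: dict[str, str]) -> dict[str, float]:
    """Relative synonymous codon usage (sensitivity-analysis alternative)."""
    from .constants import GENETIC_CODE

    usage = compute_codon_usage(cds_collection)
    fam: dict[str, list[str]] = {}
    for c in SENSE_CODONS:
        fam.setdefault(GENETIC_CODE[c], []).append(c)
    out = {}
    for aa, codons in fam.items():
        mean = sum(usage[c] for c in codons) / len(codons)
        for c in codons:
            out[c] = usage[c] / mean if mean > 0 else 0.0
    return out


def codon_residue_map(cds: str, protein_length: int) -> dict[int, int]:
    """codon i (0-based) -> residue i+1 (1-based); the stop codon is unmapped."""
    if len(cds) != 3 * (protein_length + 1):
        raise ValueError(
            f"CDS length {len(cds)} != 3*({protein_length}+1); "
            "expected exactly one stop codon"
        )
    protein = translate(cds)
    if "*" in protein[:-1] or protein[-1] != "*":
        raise ValueError("CDS must end with its only stop codon")
    return {i: i + 1 for i in range(protein_length)}


def segment_regions(protein_length: int) -> np.ndarray:
    """Per-residue N/M/C terciles; remainders go to the earlier segments."""
    if protein_length < 3:
        raise ValueError(f"protein too short to segment: {protein_length} residues")
    L = protein_length
    b1 = -(-L // 3)          # ceil(L/3)
    b2 = -(-2 * L // 3)      # ceil(2L/3)
    labels = np.empty(L, dtype="<U1")
    labels[:b1] = "N"
    labels[b1:b2] = "M"
    labels[b2:] = "C"
    return labels


def build_joint_table(
    scaled_profiles: dict[str, ScaledProfile],
    feature_tables: pd.DataFrame,
    usage: dict[str, float],
    retained_genes: list[str],
    cds_collection: dict[str, str] | None = None,
    residue_lag: int = 0,
) -> pd.DataFrame:
    """One row per (gene, codon) with velocity and structure features.

    Inner join of scaled profiles (codon-indexed) and feature tables
    (residue-indexed) on codon_index = residue_index - 1 (shifted by
    ``residue_lag`` codons if modelling ribosome-tunnel delay). Rows with
    a missing (ramp-excluded) scaled value are dropped; missing laco is
    kept as NaN and handled per analysis. Region labels are attached.
    """
    frames = []
    feature_tables = feature_tables.set_index(["gene_id", "residue_index"])
    for gene_id in retained_genes:
        if gene_id not in scaled_profiles:
            continue
        prof = scaled_profiles[gene_id]
        L = len(prof.values)
        try:
            feats = feature_tables.xs(gene_id, level="gene_id")
        except KeyError:
            warnings.warn(f"{gene_id}: no feature table; skipped", stacklevel=2)
            continue
        if feats.index.max() != L:
            warnings.warn(
                f"{gene_id}: protein length mismatch (profile {L} codons, "
                f"features to residue {feats.index.max()}); skipped",
                stacklevel=2,
            )
            continue
        codons = None
        if cds_collection is not None and gene_id in cds_collection:
            cds = cds_collection[gene_id]
            codons = [cds[3 * i : 3 * i + 3] for i in range(L)]
        regions = segment_regions(L)
        df = feats.reset_index()
        codon_index = df["residue_index"].to_numpy() - 1 + residue_lag
        ok = (codon_index >= 0) & (codon_index < L)
        df = df[ok]
        codon_index = codon_index[ok]
        df.insert(0, "gene_id", gene_id)
        df["codon_index"] = codon_index
        df["scaled_value"] = prof.values[codon_index]
        df["region"] = regions[df["residue_index"].to_numpy() - 1]
        if codons is not None:
            df["codon"] = [codons[i] for i in codon_index]
            df["codon_freq"] = [usage[c] for c in df["codon"]]
        elif "codon" in df.columns:
            df["codon_freq"] = [usage[c] for c in df["codon"]]
        frames.append(df[~df["scaled_value"].isna()])
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def per_gene_summary(joint: pd.DataFrame) -> pd.DataFrame:
    """Row counts and mean scaled values per gene (join bookkeeping)."""
    return (
        joint.groupby("gene_id")
        .agg(
            n_records=("scaled_value", "size"),
            mean_scaled=("scaled_value", "mean"),
            n_missing_laco=("laco", lambda s: int(s.isna().sum())),
        )
        .reset_index()
    )
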