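"""Statistical layer: per-gene partial Spearman correlations between
scaled footprints and structure features, the cross-gene one-sample
t-test with Bonferroni correction, the structured-vs-coil Wilcoxon
comparison, and metagene profiles around residue classes.

The aggregation follows the per-gene-then-test scheme: a correlation
coefficient is computed within each gene, and the deviation of the
cross-gene mean from zero is tested with a one-sample t-test, so every
gene carries equal weight regardless of length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_FEATURES = ("codon_freq", "rasa", "idr", "laco")
POSITIVE_CLASS = ("K", "R")

# significance bands on the Bonferroni-corrected p-value
_BANDS = ((2.2e-15, "****"), (2.2e-10, "***"), (2.2e-5, "**"), (0.05, "*"))


class DegenerateInputError(ValueError):
    pass


def significance_band(p: float) -> str:
    for cutoff, band in _BANDS:
        if p < cutoff:
            return band
    return "N.S"


# ---------------------------------------------------------------------------
# Correlation primitives
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Spearman correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance input")
    rx, ry = _midranks(x), _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def partial_spearman(x, y, z) -> float:
    """First-order partial Spearman correlation of x and y given z.

    All three vectors are rank-transformed (mid-ranks), then
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)) or len(x) < 4:
        raise ValueError("need three equal-length vectors with n >= 4")
    if np.ptp(z) == 0:
        raise DegenerateInputError("covariate z is constant")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance input")
    rx, ry, rz = (_midranks(v) for v in (x, y, z))
    r = np.corrcoef(np.vstack([rx, ry, rz]))
    r_xy, r_xz, r_yz = r[0, 1], r[0, 2], r[1, 2]
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise DegenerateInputError("covariate perfectly correlated with x or y")
    return float(
        (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    )


# ---------------------------------------------------------------------------
# Per-gene correlations and the cross-gene mean test
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrResult:
    gene_id: str
    feature_name: str
    rho: float
    n_positions: int


@dataclass
class MeanTestResult:
    feature_name: str
    mean_rho: float
    sd_rho: float
    n_genes: int
    t_statistic: float
    p_raw: float
    p_bonferroni: float
    significance_band: str


def per_gene_partial_correlations(
    joint: pd.DataFrame,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
    covariate: str = "codon_freq",
    min_positions: int = 30,
) -> tuple[list[PartialCorrResult], list[dict]]:
    """rho(scaled footprints, feature | codon usage) for every gene.

    The covariate's own row uses plain Spearman. Rows with a missing
    feature value are dropped pairwise; genes with fewer than
    ``min_positions`` valid rows for a feature are skipped and recorded
    in the returned skip ledger.
    """
    results: list[PartialCorrResult] = []
    skipped: list[dict] = []
    for gene_id, sub in joint.groupby("gene_id", sort=True):
        x_all = sub["scaled_value"].to_numpy(dtype=float)
        z_all = sub[covariate].to_numpy(dtype=float)
        for feat in feature_names:
            y_all = sub[feat].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all) & np.isfinite(z_all)
            n = int(ok.sum())
            if n < min_positions:
                skipped.append(
                    {"gene_id": gene_id, "feature": feat, "n_valid": n,
                     "reason": "below min_positions"}
                )
                continue
            try:
                if feat == covariate:
                    rho = spearman_rho(x_all[ok], y_all[ok])
                else:
                    rho = partial_spearman(x_all[ok], y_all[ok], z_all[ok])
            except DegenerateInputError as exc:
                skipped.append(
                    {"gene_id": gene_id, "feature": feat, "n_valid": n,
                     "reason": str(exc)}
                )
                continue
            results.append(PartialCorrResult(gene_id, feat, rho, n))
    return results, skipped


def cross_gene_mean_test(
    results: list[PartialCorrResult] | np.ndarray,
    feature_name: str = "",
    n_tests: int = 1,
) -> MeanTestResult:
    """One-sample t-test on the per-gene correlation coefficients.

    t = mean / (sd / sqrt(N)) with df = N - 1, two-sided p, Bonferroni
    p = min(1, p * n_tests), and the significance band assigned on the
    corrected p.
    """
    if len(results) and isinstance(results[0], PartialCorrResult):
        rhos = np.array([r.rho for r in results])
        feature_name = feature_name or results[0].feature_name
    else:
        rhos = np.asarray(results, dtype=float)
    n = len(rhos)
    if n < 2:
        raise ValueError(f"need >= 2 genes, got {n}")
    sd = float(rhos.std(ddof=1))
    if sd == 0:
        raise DegenerateInputError("zero variance across genes")
    mean = float(rhos.mean())
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    p_bonf = min(1.0, p * n_tests)
    return MeanTestResult(
        feature_name=feature_name,
        mean_rho=mean,
        sd_rho=sd,
        n_genes=n,
        t_statistic=float(t),
        p_raw=p,
        p_bonferroni=p_bonf,
        significance_band=significance_band(p_bonf),
    )


def association_summary(
    joint: pd.DataFrame,
    feature_names: tuple[str, ...] = DEFAULT_FEATURES,
    covariate: str = "codon_freq",
    min_positions: int = 30,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-feature mean correlation heat-map row: mean rho, t, p, band."""
    results, _ = per_gene_partial_correlations(
        joint, feature_names, covariate, min_positions
    )
    n_tests = n_tests if n_tests is not None else len(feature_names)
    rows = []
    for feat in feature_names:
        sub = [r for r in results if r.feature_name == feat]
        if len(sub) < 2:
            continue
        mt = cross_gene_mean_test(sub, feat, n_tests=n_tests)
        rows.append(vars(mt))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (structured vs coil)
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of a, p).

    Small tie-free samples (n_a + n_b <= 12) are tested by exact
    enumeration of all rank assignments; otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled, method="average")
    w = float(ranks[:na].sum())
    has_ties = len(np.unique(pooled)) < na + nb

    if mode == "exact" or (mode == "auto" and na + nb <= 12 and not has_ties):
        total = na + nb
        all_ranks = np.arange(1, total + 1)
        sums = np.fromiter(
            (sum(c) for c in combinations(all_ranks, na)),
            dtype=float,
            count=comb(total, na),
        )
        mean_w = na * (total + 1) / 2.0
        extreme = np.abs(sums - mean_w) >= abs(w - mean_w) - 1e-12
        return w, float(extreme.mean())

    n = na + nb
    mean_w = na * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var_w = na * nb / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    diff = abs(w - mean_w) - 0.5  # continuity correction
    z = max(diff, 0.0) / np.sqrt(var_w)
    return w, float(2.0 * sps.norm.sf(z))


@dataclass
class StructuredVsCoil:
    median_structured: float
    median_coil: float
    n_structured: int
    n_coil: int
    direction: str           # "coil_slower" | "structured_slower" | "none"
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return vars(self)


def structured_vs_coil(joint: pd.DataFrame) -> StructuredVsCoil:
    """Pool scaled footprints into structured (H+E) vs coil groups.

    Higher scaled footprints mean slower translation, so
    median_coil > median_structured reads as "coil slower".
    """
    vals = joint["scaled_value"].to_numpy(dtype=float)
    ss = joint["ss3"].to_numpy()
    ok = np.isfinite(vals)
    structured = vals[ok & np.isin(ss, ("H", "E"))]
    coil = vals[ok & (ss == "C")]
    if len(structured) == 0 or len(coil) == 0:
        raise ValueError("structured or coil group is empty")
    stat, p = wilcoxon_rank_sum(structured, coil)
    ms, mc = float(np.median(structured)), float(np.median(coil))
    direction = "coil_slower" if mc > ms else ("structured_slower" if ms > mc else "none")
    return StructuredVsCoil(ms, mc, len(structured), len(coil), direction, stat, p)


# ---------------------------------------------------------------------------
# Metagene and region-stratified analyses
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    residue_class: tuple[str, ...]
    offsets: np.ndarray
    mean_scaled: np.ndarray
    n_occurrences: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean_scaled": self.mean_scaled,
                "n_occurrences": self.n_occurrences,
            }
        )


def metagene_profile(
    joint: pd.DataFrame,
    residue_class: str | tuple[str, ...] = "P",
    window: int = 30,
) -> MetageneProfile:
    """Mean scaled footprint at offsets -window..+window around every
    occurrence of the residue class whose full window has data.

    Scaled profiles average to 1 per gene, so a stall appears as a peak
    above the ~1 baseline at offset 0.
    """
    classes = (residue_class,) if isinstance(residue_class, str) else tuple(residue_class)
    offsets = np.arange(-window, window + 1)
    sums = np.zeros(len(offsets))
    n_occ = 0
    for _, sub in joint.groupby("gene_id", sort=True):
        sub = sub.sort_values("codon_index")
        idx = sub["codon_index"].to_numpy()
        vals = sub["scaled_value"].to_numpy(dtype=float)
        aa = sub["aa"].to_numpy()
        # dense vector over codon positions (NaN where absent)
        L = int(idx.max()) + 1
        dense = np.full(L, np.nan)
        dense[idx] = vals
        hits = idx[np.isin(aa, classes)]
        for h in hits:
            if h - window < 0 or h + window >= L:
                continue
            seg = dense[h - window : h + window + 1]
            if np.isnan(seg).any():
                continue
            sums += seg
            n_occ += 1
    mean = sums / n_occ if n_occ else np.full(len(offsets), np.nan)
    return MetageneProfile(classes, offsets, mean, n_occ)


def region_stratified_correlations(
    joint: pd.DataFrame,
    feature: str = "idr",
    covariate: str = "codon_freq",
    min_positions: int = 10,
    n_tests: int = 3,
) -> dict[str, MeanTestResult]:
    """The per-gene correlation + mean test within each N/M/C tercile."""
    out: dict[str, MeanTestResult] = {}
    for region in ("N", "M", "C"):
        sub = joint[joint["region"] == region]
        if sub.empty:
            continue
        results, _ = per_gene_partial_correlations(
            sub, (feature,), covariate, min_positions
        )
        if len(results) < 2:
            continue
        out[region] = cross_gene_mean_test(results, feature, n_tests=n_tests)
    return out
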