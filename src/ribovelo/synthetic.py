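"""Synthetic CDSs, structures and ribosome footprints with planted effects.

The generator produces the three inputs of the pipeline — coding
sequences, AlphaFold-style structure models, and footprint reads — with
a *known* velocity model planted in the counts:

    lambda_i = exp(b0 + b_coil 1[ss_i=C] + b_pro 1[aa_i=P]
                   + b_pos 1[aa_i in {K,R}] + b_freq f(codon_i)
                   + b_rasa rASA_i)

one rate per sense codon. Per-codon counts are Poisson (optionally
negative-binomial) around mean_depth * lambda / mean(lambda), and reads
are the exact expansion of those counts, each 5' end displaced upstream
of its codon by a known per-length P-site offset. Every downstream
stage can therefore be tested against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import (
    GENETIC_CODE,
    SENSE_CODONS,
    START_CODON,
    STOP_CODONS,
    translate,
)
from .structure import ProteinStructure

DEFAULT_EFFECTS: dict[str, float] = {
    "intercept": 0.0,
    "coil": math.log(2.0),     # coil codons translated ~2x slower
    "proline": 0.4,            # P is a poor peptidyl donor/acceptor
    "positive": 0.5,           # K/R stall in the exit tunnel
    "codon_freq": -20.0,       # frequent codons faster (raw-frequency scale)
    "rasa": 0.5,               # exposed residues slower
}

DEFAULT_OFFSETS: dict[int, int] = {28: 12, 29: 13}
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {28: 0.6, 29: 0.4}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of one simulated Ribo-seq + structure dataset."""

    seed: int = 0
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (120, 300)   # protein length, codons
    codon_usage_bias: dict[str, float] | None = None  # per-sense-codon weights
    effect_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    mean_depth: float = 50.0                          # expected reads per codon
    offset_by_length: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    start_peak: float = 3.0       # initiation-peak multiplier on codon 0
    noise: str = "poisson"        # or "negative_binomial"
    nb_dispersion: float = 0.5    # var = mu + nb_dispersion * mu^2

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if lo < 10:
            raise ConfigError(f"gene_length_range minimum {lo} < 10 codons")
        if hi < lo:
            raise ConfigError("gene_length_range upper bound below lower bound")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        total = sum(self.length_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ConfigError(f"length_weights sum to {total}, expected 1")
        if set(self.length_weights) - set(self.offset_by_length):
            raise ConfigError("every read length needs an entry in offset_by_length")
        if any(o < 0 for o in self.offset_by_length.values()):
            raise ConfigError("offsets must be non-negative")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ConfigError(f"unknown noise model {self.noise!r}")

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent, reproducible RNG stream keyed by integers."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, *stream]))


@dataclass
class PlantedGene:
    gene_id: str
    cds_sequence: str
    protein_sequence: str
    ss_string: str
    true_lambda: np.ndarray | None = None

    def __post_init__(self) -> None:
        L = len(self.protein_sequence)
        if len(self.cds_sequence) != 3 * (L + 1):
            raise ValueError(f"{self.gene_id}: CDS length != 3*(protein_length+1)")
        if translate(self.cds_sequence) != self.protein_sequence + "*":
            raise ValueError(f"{self.gene_id}: CDS does not translate to protein")
        if len(self.ss_string) != L:
            raise ValueError(f"{self.gene_id}: ss_string length != protein length")

    @property
    def protein_length(self) -> int:
        return len(self.protein_sequence)

    def codons(self) -> list[str]:
        """Sense codons only (stop excluded)."""
        cds = self.cds_sequence
        return [cds[3 * i : 3 * i + 3] for i in range(self.protein_length)]


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

# secondary-structure run sampler: mean run lengths typical of globular folds
_SS_STATES = ("H", "E", "C")
_SS_MEAN_RUN = {"H": 10.0, "E": 5.0, "C": 6.0}
_SS_START_P = np.array([0.35, 0.2, 0.45])
_SS_NEXT = {
    "H": (("E", "C"), (0.3, 0.7)),
    "E": (("H", "C"), (0.2, 0.8)),
    "C": (("H", "E"), (0.55, 0.45)),
}


def _sample_ss_string(length: int, rng: np.random.Generator) -> str:
    out: list[str] = []
    state = _SS_STATES[rng.choice(3, p=_SS_START_P)]
    while len(out) < length:
        run = 1 + rng.geometric(1.0 / _SS_MEAN_RUN[state])
        out.extend(state * min(run, length - len(out)))
        nxt, probs = _SS_NEXT[state]
        state = nxt[rng.choice(len(nxt), p=np.array(probs))]
    return "".join(out)


def _default_bias(rng: np.random.Generator) -> dict[str, float]:
    """A mildly skewed codon-usage profile (log-normal weights)."""
    w = rng.lognormal(mean=0.0, sigma=0.5, size=len(SENSE_CODONS))
    return dict(zip(SENSE_CODONS, w / w.sum()))


def generate_cds_set(config: SimulationConfig) -> list[PlantedGene]:
    """Generate ``n_genes`` CDSs following the configured codon-usage bias.

    Each CDS is ATG + (L-1) sense codons + one stop codon; internal stops
    are impossible by construction. Deterministic under ``config.seed``.
    """
    rng = config.rng(0)
    bias = config.codon_usage_bias or _default_bias(rng)
    codons = [c for c in SENSE_CODONS if bias.get(c, 0.0) > 0]
    if not codons:
        raise ConfigError("codon_usage_bias has no positive-weight sense codon")
    weights = np.array([bias[c] for c in codons], dtype=float)
    weights = weights / weights.sum()
    lo, hi = config.gene_length_range

    genes: list[PlantedGene] = []
    for g in range(config.n_genes):
        L = int(rng.integers(lo, hi + 1))
        body_idx = rng.choice(len(codons), size=L - 1, p=weights)
        body = [codons[i] for i in body_idx]
        stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
        cds = START_CODON + "".join(body) + stop
        protein = translate(cds)[:-1]
        ss = _sample_ss_string(L, rng)
        genes.append(
            PlantedGene(
                gene_id=f"g{g:04d}",
                cds_sequence=cds,
                protein_sequence=protein,
                ss_string=ss,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Ideal structure builder (NeRF chain extension from canonical dihedrals)
# ---------------------------------------------------------------------------

_BOND = {"N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231}
_ANGLE = {"N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.8}
_DIHEDRALS = {"H": (-57.0, -47.0), "E": (-119.0, 113.0)}
_OMEGA = 180.0
_PLDDT = {"H": 90.0, "E": 90.0, "C": 40.0}


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.cos(dihedral) * math.sin(angle),
            bond * math.sin(dihedral) * math.sin(angle),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _coil_dihedrals(rng: np.random.Generator) -> tuple[float, float]:
    # broad allowed (extended/PPII-like) region, away from the helical basin
    phi = float(rng.uniform(-160.0, -55.0))
    psi = float(rng.uniform(60.0, 170.0))
    return phi, psi


def generate_ideal_structure(
    ss_string: str,
    seed: int = 0,
    gene_id: str = "ideal",
    sequence: str | None = None,
    res_id_start: int = 1,
) -> ProteinStructure:
    """Backbone (N, CA, C, O) built from canonical dihedrals per ss class.

    Helix phi/psi = -57/-47, strand -119/113, coil drawn from a wide
    allowed region (seeded). pLDDT is 90 in H/E runs and 40 in C runs.
    """
    if not ss_string:
        raise ValueError("ss_string is empty")
    if any(s not in "HEC" for s in ss_string):
        raise ValueError(f"ss_string must be over H/E/C, got {ss_string!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    L = len(ss_string)
    seq = sequence or "A" * L
    if len(seq) != L:
        raise ValueError("sequence length != ss_string length")

    phis = np.empty(L)
    psis = np.empty(L)
    for i, s in enumerate(ss_string):
        if s in _DIHEDRALS:
            phis[i], psis[i] = _DIHEDRALS[s]
        else:
            phis[i], psis[i] = _coil_dihedrals(rng)

    N = np.empty((L, 3))
    CA = np.empty((L, 3))
    C = np.empty((L, 3))
    O = np.empty((L, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND["N_CA"], 0.0, 0.0)
    ang = math.radians(_ANGLE["N_CA_C"])
    C[0] = CA[0] + _BOND["CA_C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, L):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1],
                     _BOND["C_N"], _ANGLE["CA_C_N"], psis[i - 1])
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i],
                      _BOND["N_CA"], _ANGLE["C_N_CA"], _OMEGA)
        C[i] = _nerf(C[i - 1], N[i], CA[i],
                     _BOND["CA_C"], _ANGLE["N_CA_C"], phis[i])
    for i in range(L):
        O[i] = _nerf(N[i], CA[i], C[i],
                     _BOND["C_O"], _ANGLE["CA_C_O"], psis[i] + 180.0)

    coords = np.empty((4 * L, 3))
    coords[0::4], coords[1::4], coords[2::4], coords[3::4] = N, CA, C, O
    plddt = np.array([_PLDDT[s] for s in ss_string])
    return ProteinStructure(
        gene_id=gene_id,
        res_ids=np.arange(res_id_start, res_id_start + L),
        res_names=np.array(list(seq)),
        plddt=plddt,
        atom_res_index=np.repeat(np.arange(L), 4),
        atom_names=np.tile(np.array(["N", "CA", "C", "O"]), L),
        elements=np.tile(np.array(["N", "C", "C", "O"]), L),
        coords=coords,
    )


def generate_antiparallel_sheet(
    n_per_strand: int = 8, gene_id: str = "sheet"
) -> ProteinStructure:
    """Two antiparallel strands in H-bonding register (one structure).

    The second strand is placed by a deterministic rigid-body fit that
    targets ideal N-H...O=C geometry (N...O around 2.9 A) between
    registered residue pairs, giving Kabsch-Sander antiparallel bridges
    on interior residues. The strands carry non-consecutive residue ids
    so no peptide bond links them.
    """
    n = n_per_strand
    a = generate_ideal_structure("E" * n, gene_id=gene_id, res_id_start=1)
    b0 = generate_ideal_structure("E" * n, gene_id=gene_id, res_id_start=n + 3)

    aN = a.backbone_coords("N")
    aO = a.backbone_coords("O")

    def residuals(params: np.ndarray) -> np.ndarray:
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        t = params[3:]
        coords = b0.coords @ rot.T + t
        bN = np.full((n, 3), np.nan)
        bO = np.full((n, 3), np.nan)
        names = b0.atom_names
        bN[b0.atom_res_index[names == "N"]] = coords[names == "N"]
        bO[b0.atom_res_index[names == "O"]] = coords[names == "O"]
        res = []
        for i in range(n):
            j = n - 1 - i  # antiparallel register
            if i % 2 == 0:  # narrow pairs carry the two H-bonds
                res.append(np.linalg.norm(aN[i] - bO[j]) - 2.9)
                res.append(np.linalg.norm(aO[i] - bN[j]) - 2.9)
        return np.asarray(res)

    from scipy.spatial.transform import Rotation

    x0 = np.concatenate(
        [Rotation.from_euler("x", 180, degrees=True).as_rotvec(), [0.0, 4.8, 0.0]]
    )
    fit = least_squares(residuals, x0, method="lm", max_nfev=2000)
    rot = Rotation.from_rotvec(fit.x[:3]).as_matrix()
    coords_b = b0.coords @ rot.T + fit.x[3:]

    return ProteinStructure(
        gene_id=gene_id,
        res_ids=np.concatenate([a.res_ids, b0.res_ids]),
        res_names=np.concatenate([a.res_names, b0.res_names]),
        plddt=np.concatenate([a.plddt, b0.plddt]),
        atom_res_index=np.concatenate([a.atom_res_index, b0.atom_res_index + n]),
        atom_names=np.concatenate([a.atom_names, b0.atom_names]),
        elements=np.concatenate([a.elements, b0.elements]),
        coords=np.vstack([a.coords, coords_b]),
    )


# ---------------------------------------------------------------------------
# Planted features / velocity model / counts / reads
# ---------------------------------------------------------------------------

# class-conditional rASA sampling: coil residues sit on the surface more often
_RASA_BETA = {"C": (4.0, 2.0), "H": (2.0, 4.0), "E": (1.5, 5.0)}


def synthetic_feature_table(
    gene: PlantedGene,
    config: SimulationConfig,
    codon_usage: dict[str, float],
    stream: int = 0,
) -> pd.DataFrame:
    """Fast per-residue feature table drawn from seeded class-conditional
    distributions (no 3D build) — for statistical simulations at scale.

    ss3 is the planted ss_string; rASA ~ Beta per class (coil more
    exposed); idr is the smoothed pLDDT transform (90 for H/E, 40 for C);
    laco ~ lognormal, larger in strands.
    """
    rng = config.rng(3, stream, int(gene.gene_id[1:], 10) if gene.gene_id[1:].isdigit() else 0)
    L = gene.protein_length
    ss = np.array(list(gene.ss_string))
    rasa = np.empty(L)
    for cls, (al, be) in _RASA_BETA.items():
        m = ss == cls
        rasa[m] = rng.beta(al, be, size=int(m.sum()))
    plddt = np.where(ss == "C", 40.0, 90.0)
    raw = 1.0 - plddt / 100.0
    half = 7
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    idx = np.arange(L)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, L)
    idr = (csum[hi] - csum[lo]) / (hi - lo)
    laco = rng.lognormal(mean=np.where(ss == "E", 2.5, 1.8), sigma=0.4)
    codons = gene.codons()
    return pd.DataFrame(
        {
            "gene_id": gene.gene_id,
            "residue_index": np.arange(1, L + 1),
            "aa": list(gene.protein_sequence),
            "ss3": ss,
            "rasa": rasa,
            "idr": idr,
            "laco": laco,
            "codon": codons,
            "codon_freq": [codon_usage[c] for c in codons],
        }
    )


def plant_velocity_model(
    gene: PlantedGene,
    features: pd.DataFrame,
    effects: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-codon expected occupancy from the log-linear planted model."""
    effects = dict(DEFAULT_EFFECTS) if effects is None else effects
    L = gene.protein_length
    if len(features) != L:
        raise ValueError(
            f"{gene.gene_id}: feature table has {len(features)} rows, expected {L}"
        )
    aa = features["aa"].to_numpy()
    ss = features["ss3"].to_numpy()
    log_lam = np.full(L, effects.get("intercept", 0.0))
    log_lam += effects.get("coil", 0.0) * (ss == "C")
    log_lam += effects.get("proline", 0.0) * (aa == "P")
    log_lam += effects.get("positive", 0.0) * np.isin(aa, ("K", "R"))
    log_lam += effects.get("codon_freq", 0.0) * features["codon_freq"].to_numpy()
    log_lam += effects.get("rasa", 0.0) * features["rasa"].to_numpy()
    lam = np.exp(log_lam)
    gene.true_lambda = lam
    return lam


def sample_counts(
    gene: PlantedGene,
    true_lambda: np.ndarray,
    config: SimulationConfig,
    stream: int = 0,
) -> np.ndarray:
    """Per-codon counts ~ Poisson(mean_depth * lambda / mean(lambda)).

    Codon 0 is additionally inflated by ``start_peak`` (initiation peak),
    which anchors start-codon P-site calibration as in real coverage.
    """
    rng = config.rng(1, stream, _gene_stream(gene.gene_id))
    mu = config.mean_depth * true_lambda / true_lambda.mean()
    mu = mu.copy()
    mu[0] *= config.start_peak
    if config.noise == "poisson":
        return rng.poisson(mu)
    # negative binomial: var = mu + a mu^2  ->  n = 1/a, p = n/(n+mu)
    a = config.nb_dispersion
    nshape = 1.0 / a
    return rng.negative_binomial(nshape, nshape / (nshape + mu))


def _gene_stream(gene_id: str) -> int:
    digits = "".join(ch for ch in gene_id if ch.isdigit())
    return int(digits) if digits else abs(hash(gene_id)) % (2**31)


def sample_reads(
    gene: PlantedGene,
    counts: np.ndarray,
    config: SimulationConfig,
    stream: int = 0,
) -> pd.DataFrame:
    """Expand per-codon counts into footprint reads.

    Each read's length is drawn from ``length_weights`` and its 5' end is
    3*i - offset_by_length[length] for codon i (CDS coordinate, 0-based;
    may be negative by at most the offset — the footprint overhangs the
    start codon, as real P-site-calibrated reads do).
    """
    rng = config.rng(2, stream, _gene_stream(gene.gene_id))
    codon_idx = np.repeat(np.arange(len(counts)), counts)
    lengths_avail = np.array(sorted(config.length_weights))
    probs = np.array([config.length_weights[l] for l in lengths_avail])
    lengths = lengths_avail[rng.choice(len(lengths_avail), size=len(codon_idx), p=probs)]
    offsets = np.array([config.offset_by_length[l] for l in lengths])
    return pd.DataFrame(
        {
            "gene_id": gene.gene_id,
            "five_prime_pos": 3 * codon_idx - offsets,
            "length": lengths,
        }
    )


# ---------------------------------------------------------------------------
# Whole-dataset convenience + writers
# ---------------------------------------------------------------------------

def compute_usage(genes: list[PlantedGene]) -> dict[str, float]:
    from collections import Counter

    counts: Counter[str] = Counter()
    for g in genes:
        counts.update(g.codons())
    total = sum(counts.values())
    return {c: counts[c] / total for c in SENSE_CODONS}


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[PlantedGene]
    features: pd.DataFrame           # per-residue planted features, all genes
    counts: dict[str, np.ndarray]    # planted per-codon counts
    reads: pd.DataFrame              # footprint reads, all genes
    usage: dict[str, float]

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "cds_length": [len(g.cds_sequence) for g in self.genes],
            }
        )


def simulate_dataset(
    config: SimulationConfig, with_reads: bool = True
) -> SyntheticDataset:
    """Generate genes, planted features, lambda, counts and (optionally) reads."""
    genes = generate_cds_set(config)
    usage = compute_usage(genes)
    feats = []
    counts: dict[str, np.ndarray] = {}
    read_frames = []
    for g in genes:
        ft = synthetic_feature_table(g, config, usage)
        lam = plant_velocity_model(g, ft, config.effect_coefficients)
        cnt = sample_counts(g, lam, config)
        counts[g.gene_id] = cnt
        feats.append(ft)
        if with_reads:
            read_frames.append(sample_reads(g, cnt, config))
    reads = (
        pd.concat(read_frames, ignore_index=True)
        if read_frames
        else pd.DataFrame(columns=["gene_id", "five_prime_pos", "length"])
    )
    return SyntheticDataset(
        config=config,
        genes=genes,
        features=pd.concat(feats, ignore_index=True),
        counts=counts,
        reads=reads,
        usage=usage,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path,
                  with_structures: bool = True) -> None:
    """Write FASTA, gene table, read table, ground truth and PDB models."""
    from .structure import write_structure

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "cds.fasta", "w") as fh:
        for g in ds.genes:
            fh.write(f">{g.gene_id}\n{g.cds_sequence}\n")
    ds.gene_table().to_csv(outdir / "genes.tsv", sep="\t", index=False)
    ds.reads.to_csv(outdir / "reads.tsv", sep="\t", index=False)

    truth = []
    for g in ds.genes:
        truth.append(
            pd.DataFrame(
                {
                    "gene_id": g.gene_id,
                    "codon_index": np.arange(g.protein_length),
                    "true_lambda": g.true_lambda,
                    "planted_count": ds.counts[g.gene_id],
                }
            )
        )
    pd.concat(truth, ignore_index=True).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(ds.config.effect_coefficients.items()), columns=["effect", "beta"]
    ).to_csv(outdir / "effects.tsv", sep="\t", index=False)

    if with_structures:
        sdir = outdir / "structures"
        sdir.mkdir(exist_ok=True)
        rows = []
        for g in ds.genes:
            struct = generate_ideal_structure(
                g.ss_string,
                seed=ds.config.seed + _gene_stream(g.gene_id),
                gene_id=g.gene_id,
                sequence=g.protein_sequence,
            )
            path = sdir / f"{g.gene_id}.pdb"
            write_structure(struct, path)
            rows.append({"gene_id": g.gene_id, "path": str(path)})
        pd.DataFrame(rows).to_csv(outdir / "structure_map.tsv", sep="\t", index=False)
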