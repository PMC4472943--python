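"""Ground-truth simulator for the four-genotype LPS epistasis experiment.

The generative model mirrors the factorial design of the study system: bone
marrow-derived macrophages of four genotypes (wild type, *Dusp1* knockout,
the phospho-dead *Zfp36aa* knock-in, and the double mutant), left untreated
or stimulated with LPS, measured in triplicate on a linear-intensity
expression platform.

Per gene, expression is log-normal around a condition mean built from

* a baseline ``mu`` (log2),
* an LPS induction ``lam`` (log2 fold change, induced genes only),
* a DUSP1 effect ``delta`` (log2 overexpression caused by *Dusp1* deletion,
  applied under LPS),
* a TTP-phosphorylation-mediated fraction ``phi`` in [0, 1]: in the
  *Zfp36aa* background the DUSP1 effect shrinks to ``(1 - phi) * delta``,
  because the share of the effect that runs through phosphorylation of TTP
  serines 52/178 is abolished when those serines are mutated,
* a *Zfp36aa* main effect ``zeta`` (log2 underexpression of direct TTP
  targets in either *Zfp36aa* background).

Replicate noise is additive Gaussian in log2 space (multiplicative on the
linear scale), the error structure implied by ratio-based analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "Dusp1KO", "Zfp36aa", "DoubleMut")
TREATMENTS = ("untreated", "LPS")

__all__ = [
    "GENOTYPES",
    "TREATMENTS",
    "TtpFractionDist",
    "SimulationParams",
    "DecaySeries",
    "simulate_experiment",
    "simulate_decay_series",
    "simulate_utr",
]


@dataclass(frozen=True)
class TtpFractionDist:
    """Mixture distribution for phi, the TTP-mediated fraction of delta.

    With probability ``point_mass_zero`` a gene is fully TTP-independent
    (phi = 0, the behaviour of cluster-1/2-like transcripts); otherwise phi
    is Beta(``beta_a``, ``beta_b``), so partially and fully TTP-dependent
    genes (cluster-3/4-like) both occur.
    """

    point_mass_zero: float = 0.3
    beta_a: float = 4.5
    beta_b: float = 5.5

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if not 0.0 <= self.point_mass_zero <= 1.0:
            raise ValueError("point_mass_zero must be in [0, 1]")
        if self.beta_a <= 0 or self.beta_b <= 0:
            raise ValueError("Beta shape parameters must be positive")
        phi = rng.beta(self.beta_a, self.beta_b, size=n)
        phi[rng.random(n) < self.point_mass_zero] = 0.0
        return phi


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the factorial expression simulation.

    All effect sizes are log2; ``noise_sd_log2`` is the replicate SD in
    log2 space. Defaults describe a moderately noisy two-colour array
    experiment with strong LPS inductions; they are fixtures, not estimates
    fitted to any real dataset.
    """

    n_genes: int = 1000
    frac_induced: float = 0.3
    induction_log2_mean: float = 2.5
    induction_log2_sd: float = 1.0
    frac_dusp1_responsive: float = 0.5
    dusp1_effect_log2_mean: float = 1.0
    dusp1_effect_log2_sd: float = 0.5
    ttp_fraction_dist: TtpFractionDist = field(default_factory=TtpFractionDist)
    zfp36aa_effect_log2: float = -0.5
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd_log2: float = 0.2
    n_replicates: int = 3
    timepoint: str = "1h"
    lps_only_effects: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("frac_induced", "frac_dusp1_responsive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be > 0")
        for name in ("induction_log2_sd", "dusp1_effect_log2_sd", "baseline_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _draw_truth(params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_genes
    mu = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n)
    induced = rng.random(n) < params.frac_induced
    lam = np.where(
        induced, rng.normal(params.induction_log2_mean, params.induction_log2_sd, n), 0.0
    )
    responsive = induced & (rng.random(n) < params.frac_dusp1_responsive)
    delta = np.where(
        responsive,
        rng.normal(params.dusp1_effect_log2_mean, params.dusp1_effect_log2_sd, n),
        0.0,
    )
    phi = np.where(responsive, params.ttp_fraction_dist.draw(n, rng), 0.0)
    # Direct TTP targets: genes whose DUSP1 effect runs (at least partly)
    # through TTP phosphorylation; only these feel the Zfp36aa main effect.
    direct = responsive & (phi > 0)
    zeta = np.where(direct, params.zfp36aa_effect_log2, 0.0)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "mu_log2": mu,
            "induction_log2": lam,
            "dusp1_effect_log2": delta,
            "ttp_fraction": phi,
            "zfp36aa_effect_log2": zeta,
            "induced": induced,
            "dusp1_responsive": responsive,
            "direct_ttp_target": direct,
        }
    ).set_index("gene_id")


def expected_log2(truth: pd.DataFrame, genotype: str, treatment: str,
                  lps_only_effects: bool = True) -> np.ndarray:
    """Noise-free expected log2 intensity for one condition.

    The double mutant combines the *Dusp1* deletion effect attenuated by the
    TTP-mediated fraction, ``(1 - phi) * delta``, with the *Zfp36aa* main
    effect ``zeta``.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    m = truth["mu_log2"].to_numpy().copy()
    lps = treatment == "LPS"
    if lps:
        m += truth["induction_log2"].to_numpy()
    if lps or not lps_only_effects:
        delta = truth["dusp1_effect_log2"].to_numpy()
        phi = truth["ttp_fraction"].to_numpy()
        zeta = truth["zfp36aa_effect_log2"].to_numpy()
        if genotype == "Dusp1KO":
            m += delta
        elif genotype == "Zfp36aa":
            m += zeta
        elif genotype == "DoubleMut":
            m += (1.0 - phi) * delta + zeta
    return m


def simulate_experiment(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the 4-genotype x 2-treatment x n-replicate experiment.

    Returns
    -------
    matrix : DataFrame, genes x samples
        Linear-scale intensities, strictly positive.
    design : DataFrame
        One row per sample: sample_id, genotype, treatment, timepoint,
        replicate.
    truth : DataFrame
        Per-gene generative parameters and flags (indexed by gene_id).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    truth = _draw_truth(params, rng)

    rows = []
    columns = {}
    for genotype in GENOTYPES:
        for treatment in TREATMENTS:
            mean = expected_log2(truth, genotype, treatment, params.lps_only_effects)
            for rep in range(1, params.n_replicates + 1):
                sid = f"{genotype}_{treatment}_{params.timepoint}_r{rep}"
                noise = rng.normal(0.0, params.noise_sd_log2, params.n_genes)
                columns[sid] = np.exp2(mean + noise)
                rows.append(
                    {
                        "sample_id": sid,
                        "genotype": genotype,
                        "treatment": treatment,
                        "timepoint": params.timepoint,
                        "replicate": rep,
                    }
                )
    matrix = pd.DataFrame(columns, index=truth.index)
    matrix.index.name = "probe_id"
    design = pd.DataFrame(rows)
    return matrix, design, truth


@dataclass(frozen=True)
class DecaySeries:
    """One transcription-shutoff chase: abundance (% of t=0) over time."""

    gene: str
    genotype: str
    timepoints_h: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError("timepoints and values must have equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("abundances must be strictly positive")


def simulate_decay_series(
    half_life: float,
    timepoints: list[float] | tuple[float, ...],
    noise_sd_log2: float = 0.0,
    seed: int = 0,
    gene: str = "sim",
    genotype: str = "WT",
) -> DecaySeries:
    """First-order decay chase: 100 * 2^(-t / half_life) * 2^N(0, noise).

    The series is normalized to 100 at t=0 before noise is applied, matching
    the convention of normalizing each chase to its own zero timepoint.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    t = np.asarray(sorted(timepoints), dtype=float)
    if 0.0 not in t:
        raise ValueError("timepoints must include 0")
    if noise_sd_log2 < 0:
        raise ValueError("noise_sd_log2 must be >= 0")
    rng = np.random.default_rng(seed)
    clean = 100.0 * np.exp2(-t / half_life)
    noise = rng.normal(0.0, noise_sd_log2, t.size) if noise_sd_log2 > 0 else 0.0
    values = clean * np.exp2(noise)
    return DecaySeries(gene, genotype, tuple(t), tuple(values))


_ARE = "UAUUUAU"
_RNA = np.array(list("ACGU"))


def simulate_utr(length: int, n_motifs: int, seed: int = 0) -> str:
    """Random RNA 3'UTR with exactly ``n_motifs`` planted UAUUUAU heptamers.

    Planted occurrences are non-overlapping; the finished sequence is
    rescanned and rejected (and redrawn) if random background produced any
    accidental extra occurrence, so the returned sequence contains exactly
    the requested count.
    """
    from .motif import scan_are  # local import: avoids cycle at module load

    m = len(_ARE)
    if n_motifs < 0:
        raise ValueError("n_motifs must be >= 0")
    if length < m * n_motifs:
        raise ValueError(f"length {length} cannot hold {n_motifs} motifs of {m} nt")
    rng = np.random.default_rng(seed)
    for _ in range(10000):
        seq = rng.choice(_RNA, size=length)
        if n_motifs > 0:
            # Sample non-overlapping start positions uniformly: choose
            # n sorted distinct values t_i, then s_i = t_i + i*(m-1).
            span = length - m - (n_motifs - 1) * (m - 1) + 1
            ts = np.sort(rng.choice(span, size=n_motifs, replace=False))
            starts = ts + np.arange(n_motifs) * (m - 1)
            for s in starts:
                seq[s : s + m] = list(_ARE)
        candidate = "".join(seq)
        if scan_are(candidate).count == n_motifs:
            return candidate
    raise RuntimeError("could not place motifs without accidental extras")
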