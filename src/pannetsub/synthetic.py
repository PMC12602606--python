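"""Synthetic multi-omic cohort generator with a recorded truth ledger.

Generates a toy autosomal genome, an array-style probe manifest with
chromatin-state annotations, a methylation beta matrix, an RNA-seq
count matrix, and a clinical sample sheet. Every planted effect —
two-level subtype structure (alpha-like vs ADM on methylation, ADM
transcriptomic subtypes on expression), differentially methylated
probes, sub-telomeric/peri-centromeric hypomethylation in ADM,
subtype-specific expression programs, an MLP1-style signature elevated
in two subtypes, promoter-methylation-coupled genes, and group-wise
survival hazards — is recorded in a :class:`GroundTruth` ledger so that
downstream recovery can be scored exactly.

All randomness flows from a single integer seed; sub-streams are
derived deterministically per component, so cohorts are byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as pio
from .methylation import beta_to_m

ALPHA_LIKE = "alpha_like"
ADM_SUBTYPES = ("ADM1", "ADM2", "ADM3", "ADM4")

DEFAULT_STATE_FRACTIONS = {
    "active_promoter": 0.15,
    "weak_promoter": 0.10,
    "enhancer": 0.20,
    "lowly_methylated": 0.15,
    "heterochromatin": 0.20,
    "other": 0.20,
}


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# toy genome


@dataclass(frozen=True)
class ToyGenome:
    """Small all-autosome genome: (name, length, centromere start/end) per
    chromosome; coordinates 1-based."""

    chromosomes: tuple

    def __post_init__(self):
        if len(self.chromosomes) < 2:
            raise ConfigurationError("need at least two chromosomes")
        for name, length, cs, ce in self.chromosomes:
            if not 0 < cs < ce < length:
                raise ConfigurationError(
                    f"chromosome {name}: need 0 < cen_start < cen_end < length"
                )
            if name.lower() in {"chrx", "chry", "chrm", "x", "y", "mt"}:
                raise ConfigurationError(f"non-autosomal chromosome {name!r}")

    @property
    def names(self):
        return [c[0] for c in self.chromosomes]


def default_genome(
    n_chromosomes: int = 6,
    length_bp: int = 50_000_000,
    centromere: tuple = (24_000_000, 26_000_000),
) -> ToyGenome:
    """Six 50 Mb autosomes with centromeres at 24-26 Mb by default."""
    return ToyGenome(
        tuple(
            (f"chr{i}", length_bp, centromere[0], centromere[1])
            for i in range(1, n_chromosomes + 1)
        )
    )


# ---------------------------------------------------------------------------
# ground truth ledger


@dataclass
class GroundTruth:
    """Ledger of every planted effect, keyed exactly once each."""

    sample_subtype: dict = field(default_factory=dict)
    dmp_probes: set = field(default_factory=set)
    dmp_delta: dict = field(default_factory=dict)  # probe -> signed delta-beta
    region_effect_delta: dict = field(default_factory=dict)
    de_genes: dict = field(default_factory=dict)  # subtype -> [(gene, log2fc)]
    signature_genes: set = field(default_factory=set)
    coupled_pairs: list = field(default_factory=list)  # (gene, probe, target_rho)
    hazards: dict = field(default_factory=dict)

    def validate(self, manifest: pd.DataFrame | None = None) -> None:
        de_all = {g for lst in self.de_genes.values() for g, _ in lst}
        for gene, probe, _rho in self.coupled_pairs:
            if gene not in de_all:
                raise ConfigurationError(
                    f"coupled gene {gene!r} not among planted DE genes"
                )
        if manifest is not None:
            probes = set(manifest["probe_id"])
            if not self.dmp_probes <= probes:
                raise ConfigurationError("dmp_probes not a subset of manifest")

    def to_json(self) -> str:
        payload = {
            "sample_subtype": self.sample_subtype,
            "dmp_probes": sorted(self.dmp_probes),
            "dmp_delta": {k: self.dmp_delta[k] for k in sorted(self.dmp_delta)},
            "region_effect_delta": self.region_effect_delta,
            "de_genes": {k: sorted(v) for k, v in self.de_genes.items()},
            "signature_genes": sorted(self.signature_genes),
            "coupled_pairs": sorted(self.coupled_pairs),
            "hazards": self.hazards,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# manifest


def make_manifest(
    genome: ToyGenome,
    n_probes: int,
    state_fractions: dict | None = None,
    seed: int = 0,
    gene_pool_factor: float = 0.8,
) -> pd.DataFrame:
    """Probe manifest with uniform placement and chromatin states.

    Probes are placed uniformly (chromosome chosen proportionally to
    length, position uniform along it) and assigned a chromatin state by
    the given fractions (must sum to 1 within 1e-9). Each active/weak
    promoter probe is linked to exactly one gene; the gene pool is
    ``gene_pool_factor`` times the promoter-probe count, so some genes
    carry several promoter probes. Deterministic under a fixed seed.
    """
    if state_fractions is None:
        state_fractions = dict(DEFAULT_STATE_FRACTIONS)
    if n_probes < 100:
        raise ConfigurationError("n_probes must be >= 100")
    total = sum(state_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"state fractions sum to {total}, expected 1")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 1])
    lengths = np.array([c[1] for c in genome.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(lengths), size=n_probes, p=lengths / lengths.sum())
    pos = np.array(
        [rng.integers(1, genome.chromosomes[i][1] + 1) for i in chrom_idx]
    )
    states = list(state_fractions)
    state_assign = rng.choice(len(states), size=n_probes,
                              p=np.array([state_fractions[s] for s in states]))
    df = pd.DataFrame(
        {
            "chrom": [genome.chromosomes[i][0] for i in chrom_idx],
            "pos": pos,
            "state": [states[i] for i in state_assign],
        }
    )
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df.insert(0, "probe_id", [f"cg{i:07d}" for i in range(len(df))])

    prom_mask = df["state"].isin(pio.PROMOTER_STATES)
    n_prom = int(prom_mask.sum())
    n_genes = max(1, int(round(gene_pool_factor * n_prom)))
    pool = [f"G{i:05d}" for i in range(n_genes)]
    # every gene gets at least one probe; leftovers reuse genes at random
    assign = pool[:n_prom]
    if n_prom > n_genes:
        assign = pool + list(rng.choice(pool, size=n_prom - n_genes, replace=True))
    df["gene"] = pd.Series(np.nan, index=df.index, dtype=object)
    df.loc[prom_mask, "gene"] = [str(g) for g in assign]
    return pio.validate_manifest(df)


# ---------------------------------------------------------------------------
# methylation


@dataclass
class MethylationEffects:
    """Planted methylation effects (all deltas on the beta scale).

    ``n_dmp`` probes get a signed delta of magnitude ``dmp_delta_beta``
    in ADM samples (sign positive with probability ``dmp_up_fraction``);
    candidate DMP probes are drawn with chromatin-state weights
    ``dmp_state_weights`` (default favors enhancers and lowly-methylated
    regions). Probes inside the sub-telomeric/peri-centromeric windows
    additionally shift by ``region_effect_delta`` in ADM samples.
    ``promoter_effects`` drives promoter hypomethylation of coupled
    genes in a single target subtype: (probe, target_subtype,
    beta_rest, beta_target).
    """

    n_dmp: int = 600
    dmp_delta_beta: float = 0.3
    dmp_up_fraction: float = 0.5
    dmp_state_weights: dict = field(
        default_factory=lambda: {"enhancer": 4.0, "lowly_methylated": 3.0}
    )
    region_effect_delta: dict = field(
        default_factory=lambda: {"subtelomeric": -0.15, "pericentromeric": -0.15}
    )
    tel_window_bp: int = 2_000_000
    cen_window_bp: int = 2_000_000
    promoter_effects: list = field(default_factory=list)


def _region_probe_mask(manifest: pd.DataFrame, genome: ToyGenome,
                       tel_window: int, cen_window: int):
    sub = np.zeros(len(manifest), dtype=bool)
    peri = np.zeros(len(manifest), dtype=bool)
    info = {c[0]: c[1:] for c in genome.chromosomes}
    for i, (chrom, pos) in enumerate(zip(manifest["chrom"], manifest["pos"])):
        length, cs, ce = info[chrom]
        if pos <= tel_window or pos > length - tel_window:
            sub[i] = True
        if cs - cen_window <= pos <= ce + cen_window:
            peri[i] = True
            sub[i] = False  # pericentromeric-first on overlap
    return sub, peri


def simulate_methylation(
    manifest: pd.DataFrame,
    n_per_group: dict,
    effects: MethylationEffects | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    genome: ToyGenome | None = None,
    truth: GroundTruth | None = None,
):
    """Simulate a beta matrix with planted group effects.

    Baseline probe methylation comes from the bimodal mixture
    Beta(0.5, 5) / Beta(5, 0.5) (unmethylated vs methylated modes, a
    stand-in for array-like bimodality). Noise is added on the logit
    scale and back-transformed; ``noise_sd`` is the approximate
    beta-scale standard deviation near mid-range (the logit-scale sd is
    4 * noise_sd, the inverse expit slope at 1/2), so medians of planted
    shifts are preserved exactly and means to second order.

    Returns (beta DataFrame probes x samples, GroundTruth).
    """
    if effects is None:
        effects = MethylationEffects()
    if genome is None:
        genome = default_genome()
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    if any(n < 2 for n in n_per_group.values()):
        raise ConfigurationError("every group needs >= 2 samples")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 2])
    n_probes = len(manifest)
    probe_ids = manifest["probe_id"].to_numpy()

    samples, subtypes = [], []
    i = 1
    for group, n in n_per_group.items():
        for _ in range(n):
            samples.append(f"S{i:03d}")
            subtypes.append(group)
            i += 1
    is_adm = np.array([s != ALPHA_LIKE for s in subtypes])

    # baseline bimodal mixture
    methylated_mode = rng.random(n_probes) < 0.5
    base = np.where(
        methylated_mode,
        rng.beta(5.0, 0.5, size=n_probes),
        rng.beta(0.5, 5.0, size=n_probes),
    )

    sub_mask, peri_mask = _region_probe_mask(
        manifest, genome, effects.tel_window_bp, effects.cen_window_bp
    )
    region_delta = np.zeros(n_probes)
    d_sub = float(effects.region_effect_delta.get("subtelomeric", 0.0))
    d_peri = float(effects.region_effect_delta.get("pericentromeric", 0.0))
    region_delta[sub_mask] = d_sub
    region_delta[peri_mask] = d_peri
    # keep the shifted value inside (0.03, 0.97): re-draw region baselines
    for mask, d in ((sub_mask, d_sub), (peri_mask, d_peri)):
        if mask.any() and d != 0.0:
            lo = 0.03 + max(0.0, -d)
            hi = 0.97 - max(0.0, d)
            base[mask] = rng.uniform(lo, hi, size=int(mask.sum()))

    # planted DMPs outside the structural regions and promoter-effect probes
    reserved = set(p for p, *_ in [(pe[0],) for pe in effects.promoter_effects])
    candidates = np.where(~sub_mask & ~peri_mask
                          & ~manifest["probe_id"].isin(reserved).to_numpy())[0]
    if effects.n_dmp > len(candidates):
        raise ConfigurationError("n_dmp exceeds available non-region probes")
    weights = np.array(
        [effects.dmp_state_weights.get(s, 1.0)
         for s in manifest["state"].to_numpy()[candidates]]
    )
    dmp_idx = rng.choice(candidates, size=effects.n_dmp, replace=False,
                         p=weights / weights.sum())
    signs = np.where(rng.random(effects.n_dmp) < effects.dmp_up_fraction, 1.0, -1.0)
    dmp_delta = signs * effects.dmp_delta_beta
    delta = np.zeros(n_probes)
    delta[dmp_idx] = dmp_delta
    for j, d in zip(dmp_idx, dmp_delta):
        lo = 0.03 + max(0.0, -d)
        hi = 0.97 - max(0.0, d)
        base[j] = rng.uniform(lo, hi)

    # probe x sample mean
    mean = base[:, None] + (delta + region_delta)[:, None] * is_adm[None, :]

    # subtype-targeted promoter effects (coupled genes)
    probe_pos = {p: k for k, p in enumerate(probe_ids)}
    for probe, target, beta_rest, beta_target in effects.promoter_effects:
        if probe not in probe_pos:
            raise ConfigurationError(f"promoter effect probe {probe!r} unknown")
        k = probe_pos[probe]
        tgt = np.array([s == target for s in subtypes])
        mean[k] = np.where(tgt, beta_target, beta_rest)

    # warn only when a *planted* effect pushes values out of range;
    # extreme baseline draws from the bimodal mixture are expected
    effect_probes = (delta != 0) | (region_delta != 0)
    clipped = (mean < 0.001) | (mean > 0.999)
    frac_clipped = np.where(effect_probes, clipped.mean(axis=1), 0.0)
    if (frac_clipped > 0.5).any():
        warnings.warn(
            f"{int((frac_clipped > 0.5).sum())} probes with planted effects "
            "clipped in >50% of draws"
        )
    mean = np.clip(mean, 0.001, 0.999)
    noise = rng.normal(0.0, 4.0 * noise_sd, size=mean.shape)
    beta = expit(logit(mean) + noise)

    if truth is None:
        truth = GroundTruth()
    truth.sample_subtype.update(dict(zip(samples, subtypes)))
    truth.dmp_probes |= set(probe_ids[dmp_idx])
    truth.dmp_delta.update(
        {probe_ids[j]: float(d) for j, d in zip(dmp_idx, dmp_delta)}
    )
    truth.region_effect_delta = {
        "subtelomeric": d_sub, "pericentromeric": d_peri,
        "tel_window_bp": effects.tel_window_bp,
        "cen_window_bp": effects.cen_window_bp,
    }
    return pd.DataFrame(beta, index=probe_ids, columns=samples), truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genes: list,
    sample_sheet: pd.DataFrame,
    truth: GroundTruth,
    nb_dispersion: float = 0.05,
    coupling: list | None = None,
    beta: pd.DataFrame | None = None,
    manifest: pd.DataFrame | None = None,
    seed: int = 0,
    base_mean_range: tuple = (20.0, 2000.0),
):
    """Simulate an NB count matrix with planted subtype programs.

    Counts are gamma-Poisson (negative binomial) with per-gene base
    means log-uniform over ``base_mean_range`` and subtype-specific
    means ``exp(base + ln2 * log2FC * indicator)`` from
    ``truth.de_genes``. For coupled (gene, probe, target_rho) triples
    the gene's log2 mean additionally decreases linearly in that
    sample's promoter-probe M-value, with slope calibrated against the
    NB noise so the realized Spearman correlation is close to
    ``target_rho``. The coupling is recorded in the truth ledger.
    """
    if nb_dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    coupling = list(coupling or [])
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 3])
    samples = list(sample_sheet["sample_id"])
    subtype = np.array([truth.sample_subtype[s] for s in samples])
    n_genes, n_samples = len(genes), len(samples)

    log2_base = rng.uniform(np.log2(base_mean_range[0]),
                            np.log2(base_mean_range[1]), size=n_genes)
    log2_mu = np.tile(log2_base[:, None], (1, n_samples))

    gene_pos = {g: i for i, g in enumerate(genes)}
    for st, pairs in truth.de_genes.items():
        ind = subtype == st
        for gene, lfc in pairs:
            if gene not in gene_pos:
                raise ConfigurationError(f"DE gene {gene!r} not in gene list")
            log2_mu[gene_pos[gene], ind] += lfc

    if coupling:
        if beta is None:
            raise ConfigurationError("coupling requires the beta matrix")
        if manifest is not None:
            prom = manifest.set_index("probe_id")
            for gene, probe, _rho in coupling:
                if probe not in prom.index or prom.loc[probe, "state"] not in pio.PROMOTER_STATES:
                    raise ConfigurationError(
                        f"coupled pair references non-promoter probe {probe!r}"
                    )
                if prom.loc[probe, "gene"] != gene:
                    raise ConfigurationError(
                        f"probe {probe!r} is not a promoter probe of {gene!r}"
                    )
        m_all = beta_to_m(beta[samples])
        for gene, probe, rho in coupling:
            if not -1.0 <= rho <= 1.0:
                raise ConfigurationError("target_rho must lie in [-1, 1]")
            gi = gene_pos[gene]
            m = m_all.loc[probe].to_numpy(dtype=float)
            sd_m = m.std()
            if sd_m == 0:
                raise ConfigurationError(f"probe {probe!r} has constant M-values")
            mu_bar = 2.0 ** log2_base[gi]
            cv2 = 1.0 / mu_bar + nb_dispersion
            sd_noise_log2 = np.sqrt(cv2) / np.log(2.0)
            k = sd_noise_log2 * abs(rho) / np.sqrt(max(1.0 - rho**2, 1e-6))
            slope = np.sign(rho) * k / sd_m
            log2_mu[gi] += slope * (m - m.mean())
            truth.coupled_pairs.append((gene, probe, float(rho)))

    mu = 2.0 ** log2_mu
    if nb_dispersion > 1e-12:
        lam = rng.gamma(shape=1.0 / nb_dispersion, scale=mu * nb_dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    return (
        pd.DataFrame(counts.astype(np.int64), index=list(genes), columns=samples),
        truth,
    )


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    sample_sheet: pd.DataFrame,
    hazard_by_group: dict,
    censor_rate: float = 0.2,
    seed: int = 0,
    group_column: str = "epigenetic_subtype",
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Exponential event times per group with independent censoring.

    Censoring times are exponential with the rate chosen so the
    expected censored fraction equals ``censor_rate``
    (c = h * r / (1 - r) for group hazard h); ``censor_rate = 0`` means
    every event is observed. Adds ``dfs_time``/``dfs_event`` columns.
    """
    if not 0 <= censor_rate < 1:
        raise ConfigurationError("censor_rate must lie in [0, 1)")
    if any(h <= 0 for h in hazard_by_group.values()):
        raise ConfigurationError("hazards must be positive")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 4])
    sheet = sample_sheet.copy()
    times = np.empty(len(sheet))
    events = np.empty(len(sheet), dtype=int)
    groups = sheet[group_column].to_numpy()
    for i, g in enumerate(groups):
        h = hazard_by_group[g]
        t_event = rng.exponential(1.0 / h)
        if censor_rate > 0:
            c_rate = h * censor_rate / (1.0 - censor_rate)
            t_cens = rng.exponential(1.0 / c_rate)
        else:
            t_cens = np.inf
        times[i] = min(t_event, t_cens)
        events[i] = int(t_event <= t_cens)
    sheet["dfs_time"] = times
    sheet["dfs_event"] = events
    if truth is not None:
        truth.hazards = {k: float(v) for k, v in hazard_by_group.items()}
    return sheet


# ---------------------------------------------------------------------------
# whole-cohort builder


@dataclass
class CohortConfig:
    """Study-scale defaults for the synthetic cohort.

    The defaults mirror the structure the pipeline must detect: ~100
    samples split into one alpha-like and four ADM transcriptomic
    subtypes (one of them deliberately tiny), 10k probes / 5k genes,
    ADM-specific DMPs and structural-region hypomethylation,
    subtype-specific expression programs, a two-subtype signature, and
    promoter-coupled genes in the hypoxia-like subtype.
    """

    n_per_group: dict = field(
        default_factory=lambda: {
            ALPHA_LIKE: 30, "ADM1": 25, "ADM2": 25, "ADM3": 18, "ADM4": 2
        }
    )
    n_probes: int = 10_000
    n_genes: int = 5_000
    noise_sd: float = 0.05
    n_dmp: int = 600
    dmp_delta_beta: float = 0.3
    region_effect_delta: dict = field(
        default_factory=lambda: {"subtelomeric": -0.15, "pericentromeric": -0.15}
    )
    tel_window_bp: int = 2_000_000
    cen_window_bp: int = 2_000_000
    n_de_per_subtype: int = 150
    de_log2fc_range: tuple = (1.5, 3.0)
    de_up_fraction: float = 0.7
    n_signature_genes: int = 30
    signature_subtypes: tuple = ("ADM1", "ADM3")
    n_coupled: int = 40
    target_rho: float = -0.85
    coupled_subtype: str = "ADM1"
    nb_dispersion: float = 0.05
    hazards: dict = field(
        default_factory=lambda: {
            ALPHA_LIKE: 0.05, "ADM1": 0.15, "ADM2": 0.15, "ADM3": 0.15,
            "ADM4": 0.15,
        }
    )
    censor_rate: float = 0.3
    state_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_STATE_FRACTIONS)
    )
    batch: str = "B1"

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("de_log2fc_range", "signature_subtypes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class Cohort:
    genome: ToyGenome
    manifest: pd.DataFrame
    beta: pd.DataFrame
    counts: pd.DataFrame
    sheet: pd.DataFrame
    truth: GroundTruth


def _clinical_annotations(rng, samples, subtypes, batch):
    is_adm = np.array([s != ALPHA_LIKE for s in subtypes])
    daxx = np.where(is_adm, rng.random(len(samples)) < 0.9,
                    rng.random(len(samples)) < 0.1)
    grade = [
        rng.choice(["G2", "G3"], p=[0.6, 0.4]) if adm
        else rng.choice(["G1", "G2"], p=[0.7, 0.3])
        for adm in is_adm
    ]
    alt = np.where(is_adm, rng.random(len(samples)) < 0.8,
                   rng.random(len(samples)) < 0.05)
    cna = np.where(is_adm, rng.random(len(samples)) < 0.75,
                   rng.random(len(samples)) < 0.1)
    functional = [
        rng.choice(["non_functioning", "insulinoma"], p=[0.92, 0.08])
        for _ in samples
    ]
    # ADM3 tumors are small (mostly < 2.5 cm); others larger
    size = np.array(
        [
            float(np.round(rng.lognormal(np.log(1.9), 0.25), 1))
            if st == "ADM3"
            else float(np.round(rng.lognormal(np.log(3.4), 0.35), 1))
            for st in subtypes
        ]
    )
    size = np.maximum(size, 0.3)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "batch": batch,
            "epigenetic_subtype": [
                "ADM" if s != ALPHA_LIKE else ALPHA_LIKE for s in subtypes
            ],
            "transcriptomic_subtype": subtypes,
            "menin_lost": True,
            "daxx_atrx_lost": daxx,
            "grade": grade,
            "alt_status": np.where(alt, "ALT_pos", "ALT_neg"),
            "cna_status": np.where(cna, "CNA_high", "CNA_low"),
            "functional_status": functional,
            "tumor_size_cm": size,
        }
    )


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Generate the full synthetic cohort with its truth ledger."""
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 5])
    genome = default_genome()
    manifest = make_manifest(
        genome, config.n_probes, config.state_fractions, seed=seed
    )

    # gene universe: promoter-linked genes first, filler genes after
    prom_genes = sorted(manifest["gene"].dropna().unique())
    if len(prom_genes) >= config.n_genes:
        genes = prom_genes[: config.n_genes]
    else:
        filler = [f"GX{i:05d}" for i in range(config.n_genes - len(prom_genes))]
        genes = prom_genes + filler

    truth = GroundTruth()

    # subtype-specific DE programs, preferring promoter-linked genes so
    # the integration screen has a realistic pair universe
    adm_subtypes = [s for s in config.n_per_group if s != ALPHA_LIKE]
    pool = [g for g in genes if g in set(prom_genes)] + \
           [g for g in genes if g not in set(prom_genes)]
    cursor = 0
    for st in adm_subtypes:
        chosen = pool[cursor:cursor + config.n_de_per_subtype]
        cursor += config.n_de_per_subtype
        lfc_mag = rng.uniform(*config.de_log2fc_range, size=len(chosen))
        signs = np.where(rng.random(len(chosen)) < config.de_up_fraction, 1.0, -1.0)
        truth.de_genes[st] = [
            (g, float(s * m)) for g, s, m in zip(chosen, signs, lfc_mag)
        ]
    # MLP1-like signature: same genes up in the designated subtypes
    sig_genes = pool[cursor:cursor + config.n_signature_genes]
    cursor += config.n_signature_genes
    for st in config.signature_subtypes:
        truth.de_genes.setdefault(st, [])
        truth.de_genes[st].extend(
            (g, float(rng.uniform(1.5, 2.5))) for g in sig_genes
        )
    truth.signature_genes = set(sig_genes)

    # coupled pairs: promoter probes of DE genes in the coupled subtype
    gene_to_probes = (
        manifest.dropna(subset=["gene"]).groupby("gene")["probe_id"].apply(list)
    )
    coupled_candidates = [
        (g, gene_to_probes[g][0])
        for g, _ in truth.de_genes.get(config.coupled_subtype, [])
        if g in gene_to_probes.index
    ]
    coupled = coupled_candidates[: config.n_coupled]
    if len(coupled) < config.n_coupled:
        warnings.warn(
            f"only {len(coupled)} promoter-linked DE genes available for "
            f"coupling (requested {config.n_coupled})"
        )
    promoter_effects = [
        (probe, config.coupled_subtype, 0.75, 0.25) for _, probe in coupled
    ]
    # the coupling replaces the additive DE program for those genes
    coupled_gene_set = {g for g, _ in coupled}
    truth.de_genes[config.coupled_subtype] = [
        (g, l) for g, l in truth.de_genes[config.coupled_subtype]
        if g not in coupled_gene_set
    ] + [(g, 2.0) for g in coupled_gene_set]

    effects = MethylationEffects(
        n_dmp=config.n_dmp,
        dmp_delta_beta=config.dmp_delta_beta,
        region_effect_delta=dict(config.region_effect_delta),
        tel_window_bp=config.tel_window_bp,
        cen_window_bp=config.cen_window_bp,
        promoter_effects=promoter_effects,
    )
    beta, truth = simulate_methylation(
        manifest, config.n_per_group, effects, noise_sd=config.noise_sd,
        seed=seed, genome=genome, truth=truth,
    )

    samples = list(beta.columns)
    subtypes = [truth.sample_subtype[s] for s in samples]
    sheet = _clinical_annotations(rng, samples, subtypes, config.batch)
    sheet = simulate_survival(
        sheet,
        {st: config.hazards[st] for st in config.n_per_group},
        censor_rate=config.censor_rate,
        seed=seed,
        group_column="transcriptomic_subtype",
        truth=truth,
    )
    sheet = sheet.set_index("sample_id", drop=False)

    counts, truth = simulate_expression(
        genes,
        sheet,
        truth,
        nb_dispersion=config.nb_dispersion,
        coupling=[(g, p, config.target_rho) for g, p in coupled],
        beta=beta,
        manifest=manifest,
        seed=seed,
    )
    truth.validate(manifest)
    return Cohort(genome=genome, manifest=manifest, beta=beta, counts=counts,
                  sheet=sheet, truth=truth)


def read_genome(path) -> ToyGenome:
    """Read a genome table TSV (chrom, length_bp, centromere start/end)."""
    df = pd.read_csv(path, sep="\t")
    return ToyGenome(
        tuple(
            (r.chrom, int(r.length_bp), int(r.centromere_start_bp),
             int(r.centromere_end_bp))
            for r in df.itertuples()
        )
    )


def write_genome(genome: ToyGenome, path) -> None:
    pd.DataFrame(
        genome.chromosomes,
        columns=["chrom", "length_bp", "centromere_start_bp",
                 "centromere_end_bp"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write genome, manifest, beta, counts, sample sheet and truth ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(cohort.genome, outdir / "genome.tsv")
    pio.write_manifest(cohort.manifest, outdir / "manifest.tsv")
    pio.write_matrix(cohort.beta, outdir / "beta.tsv")
    pio.write_matrix(cohort.counts, outdir / "counts.tsv")
    pio.write_sample_sheet(cohort.sheet, outdir / "sample_sheet.tsv")
    (outdir / "truth.json").write_text(cohort.truth.to_json())
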