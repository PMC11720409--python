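"""Synthetic two-platform CSF proteomics study generator.

Emulates the statistical structure the downstream pipeline assumes, with
known ground truth:

* a memory-clinic cohort with demographics, CSF biochemistry and AD
  biomarkers drawn from published summary distributions;
* a shared latent proteome: per (sample, protein) level carrying planted
  linear phenotype effects;
* reagents with bimodal binding fidelity α ∈ [0, 1] — a "good" class whose
  signal tracks the latent protein and a "poor" class dominated by noise —
  which produces the bimodal Spearman correlation distributions seen in
  real aptamer/antibody comparisons;
* multi-reagent-per-protein and multi-ID protein-complex annotations;
* plate structure with replicated calibrator samples whose between-plate
  variation exceeds their within-plate variation.

Signal model (log2 scale): for reagent r targeting protein p on sample s,

    y[r, s] = b_r + α_r · L[p, s] + sqrt(1 − α_r²) · e + δ[r, plate(s)]

with L the unit-variance latent level, e unit-variance reagent noise, b_r a
reagent baseline and δ a per-(reagent, plate) shift ~ N(0, τ_inter).
Calibrator columns replace the biological terms by one fixed latent vector
plus replicate noise ~ N(0, σ_intra), so their CV reflects technical noise
only.  The aptamer runs are exported on a positive linear RFU scale
(baseline × 2^y); the antibody run stays on its native log2 (NPX) scale.

The fidelity of an aptamer is shared between the two aptamer runs (it is
the same physical reagent) while antibody fidelity is drawn independently
per protein — so a reagent can be internally reproducible yet fail to
replicate cross-platform, as observed in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    PhenotypeTable,
    PlateMap,
    Platform,
    ReagentAnnotation,
    Scale,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def default_effect_map(n_proteins: int, n_signature: int = 30) -> dict:
    """Planted AD-endophenotype signature: the first ``n_signature`` proteins
    carry effects on p-tau, Aβ42 and MMSE simultaneously (shared biology),
    the substrate for top-K overlap enrichment."""
    n_signature = min(n_signature, n_proteins)
    effects = {}
    for i in range(n_signature):
        effects[f"PROT{i:04d}"] = {
            "csf_ptau": 0.5,
            "csf_ab42": -0.4,
            "mmse": -0.3,
        }
    return effects


@dataclass
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults echo the real study: a 264-sample cohort, about a third of
    aptamers in the high-fidelity class, two calibrators on each of 16
    plates, and between-plate technical noise (τ_inter) exceeding
    within-plate noise (σ_intra), both in log2 units.
    """

    n_samples: int = 264
    n_proteins: int = 1000
    n_soma_reagents: int = 1200
    n_olink_reagents: int = 350
    overlap_fraction: float = 0.30   # fraction of proteins also on the antibody panel
    multi_id_fraction: float = 0.05  # protein complexes with 2 UniProt IDs
    f_good: float = 0.33
    fidelity_good: tuple[float, float] = (0.75, 0.95)
    fidelity_poor: tuple[float, float] = (0.0, 0.25)
    plate_count: int = 16
    calibrators_per_plate: int = 2
    sigma_intra: float = 0.07
    tau_inter: float = 0.12
    baseline_rfu: float = 1000.0
    phenotype_effects: dict = field(default_factory=dict)  # protein -> {pheno: beta}
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.f_good <= 1:
            raise ValueError("f_good must lie in [0, 1]")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        for name in ("n_samples", "n_proteins", "n_soma_reagents",
                     "n_olink_reagents", "plate_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.calibrators_per_plate < 2:
            raise ValueError("calibrators_per_plate must be >= 2")
        if self.n_soma_reagents < self.n_proteins:
            raise ValueError("need at least one aptamer per protein")
        if not self.phenotype_effects:
            self.phenotype_effects = default_effect_map(self.n_proteins)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study.

    reagents: one row per (reagent, platform family) with target protein,
    fidelity α and planted class; effects: planted per-protein phenotype
    betas; latent: protein × sample latent levels (filled by
    :func:`generate_assays`).
    """

    reagents: pd.DataFrame  # reagent_id, family, protein, alpha, planted_class
    effects: dict
    latent: pd.DataFrame | None = None


GOOD_PLANTED = "GOOD-planted"
POOR_PLANTED = "POOR-planted"


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

# per-(diagnosis, technique) CSF biomarker means/SDs (pg/mL)
_AB42_PARAMS = {("HC", "CLEIA"): (1210, 121), ("MCI", "CLEIA"): (977, 393),
                ("HC", "ELISA"): (1080, 202), ("MCI", "ELISA"): (760, 323)}
_PTAU_PARAMS = {("HC", "CLEIA"): (33.7, 4.73), ("MCI", "CLEIA"): (54.2, 31.8),
                ("HC", "ELISA"): (43.3, 9.97), ("MCI", "ELISA"): (70.2, 36.6)}
_MMSE_PARAMS = {"HC": (29.6, 0.565), "MCI": (25.5, 3.44)}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, size: int) -> np.ndarray:
    """Rejection-sampled normal truncated below at ``low``."""
    out = rng.normal(mean, sd, size)
    bad = out <= low
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out <= low
    return out


def generate_cohort(config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Draw a memory-clinic cohort (HC + MCI) with clinical covariates.

    Marginals follow the real cohort's summary table: mean age 71.0 (SD
    8.28, truncated > 40), 55.7% female, 230/264 MCI, ~72% ELISA biomarker
    technique, MMSE per diagnosis clipped to [0, 30], and Aβ42/p-tau drawn
    per (diagnosis, technique) cell.
    """
    if config.n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    age = _truncated_normal(rng, 71.0, 8.28, 40.0, n)
    sex = (rng.random(n) < 0.557).astype(int)  # 1 = female
    diagnosis = np.where(rng.random(n) < 230 / 264, "MCI", "HC")
    technique = np.where(rng.random(n) < 190 / 264, "ELISA", "CLEIA")
    mmse = np.empty(n)
    ab42 = np.empty(n)
    ptau = np.empty(n)
    for i in range(n):
        mu, sd = _MMSE_PARAMS[diagnosis[i]]
        mmse[i] = np.clip(np.round(rng.normal(mu, sd)), 0, 30)
        key = (diagnosis[i], technique[i])
        ab42[i] = _truncated_normal(rng, *_AB42_PARAMS[key], 0.0, 1)[0]
        ptau[i] = _truncated_normal(rng, *_PTAU_PARAMS[key], 0.0, 1)[0]
    df = pd.DataFrame({
        "age": age,
        "sex": sex,
        "diagnosis": diagnosis,
        "csf_ab42": ab42,
        "csf_ptau": ptau,
        "csf_albumin": _truncated_normal(rng, 0.239, 0.0902, 0.0, n),
        "csf_globulins": _truncated_normal(rng, 0.191, 0.0616, 0.0, n),
        "csf_total_protein": _truncated_normal(rng, 0.453, 0.145, 0.0, n),
        "csf_rbc": np.maximum(rng.normal(53.9, 135, n), 0.0),
        "qalb": _truncated_normal(rng, 862, 100, 0.0, n),
        "mmse": mmse.astype(int),
        "technique": technique,
        "apoe_e4": (rng.random(n) < 0.295).astype(int),
        "storage_years": _truncated_normal(rng, 4.30, 0.768, 0.0, n),
    }, index=pd.Index(sample_ids, name="sample_id"))
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# Reagent panels
# ---------------------------------------------------------------------------


def _protein_uniprot_sets(config: SimulationConfig,
                          rng: np.random.Generator) -> dict[str, frozenset[str]]:
    """One UniProt accession per protein; a configured fraction are
    multi-ID complexes (two accessions), duplicated consistently across
    platforms because both annotate the same biology."""
    sets = {}
    n_complex = int(round(config.multi_id_fraction * config.n_proteins))
    complex_idx = set(rng.choice(config.n_proteins, size=n_complex,
                                 replace=False).tolist())
    for i in range(config.n_proteins):
        pid = f"PROT{i:04d}"
        ids = {f"P{i:05d}"}
        if i in complex_idx:
            ids.add(f"Q{i:05d}")
        sets[pid] = frozenset(ids)
    return sets


def generate_reagents(config: SimulationConfig,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[dict[Platform, list[ReagentAnnotation]],
                                 SyntheticTruth]:
    """Build the three reagent panels and the fidelity ground truth.

    Every protein gets at least one aptamer; surplus aptamers target random
    proteins (multiplicity).  A random ``overlap_fraction`` of proteins is
    also on the antibody panel; surplus antibody assays duplicate random
    panel proteins on a second subpanel.  Fidelity α is drawn from the
    two-class mixture: with probability ``f_good`` from the high range,
    else from the low range.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    uniprot = _protein_uniprot_sets(config, rng)
    proteins = list(uniprot)

    # aptamer panel: one per protein, then surplus on random proteins
    soma_targets = list(range(config.n_proteins))
    extra = config.n_soma_reagents - config.n_proteins
    soma_targets += rng.choice(config.n_proteins, size=extra,
                               replace=True).tolist()
    soma_alpha = _draw_fidelity(config, rng, config.n_soma_reagents)

    # antibody panel: subset of proteins, surplus duplicated on a 2nd subpanel
    n_olink_prot = int(round(config.overlap_fraction * config.n_proteins))
    n_olink_prot = min(n_olink_prot, config.n_olink_reagents)
    olink_prot = sorted(rng.choice(config.n_proteins, size=n_olink_prot,
                                   replace=False).tolist())
    olink_targets = list(olink_prot)
    extra_o = config.n_olink_reagents - n_olink_prot
    if extra_o > 0 and n_olink_prot > 0:
        olink_targets += rng.choice(olink_prot, size=extra_o,
                                    replace=True).tolist()
    # antibody fidelity is per protein (subpanel duplicates share it)
    olink_prot_alpha = dict(zip(
        olink_prot, _draw_fidelity(config, rng, len(olink_prot))))

    annotations: dict[Platform, list[ReagentAnnotation]] = {
        Platform.SOMA_A: [], Platform.SOMA_B: [], Platform.OLINK: []}
    truth_rows = []
    for j, tgt in enumerate(soma_targets):
        rid = f"soma.{j:05d}"
        pid = proteins[tgt]
        for plat in (Platform.SOMA_A, Platform.SOMA_B):
            annotations[plat].append(ReagentAnnotation(
                rid, plat, uniprot[pid], gene_symbol=pid))
        truth_rows.append({
            "reagent_id": rid, "family": "SOMA", "protein": pid,
            "alpha": soma_alpha[j],
            "planted_class": _class_of(config, soma_alpha[j])})
    seen_panel: dict[int, int] = {}
    for j, tgt in enumerate(olink_targets):
        k = seen_panel.get(tgt, 0)
        seen_panel[tgt] = k + 1
        rid = f"olink.{j:05d}"
        pid = proteins[tgt]
        alpha = olink_prot_alpha[tgt]
        annotations[Platform.OLINK].append(ReagentAnnotation(
            rid, Platform.OLINK, uniprot[pid], gene_symbol=pid,
            panel=f"panel{k + 1}"))
        truth_rows.append({
            "reagent_id": rid, "family": "OLINK", "protein": pid,
            "alpha": alpha, "planted_class": _class_of(config, alpha)})
    truth = SyntheticTruth(
        reagents=pd.DataFrame(truth_rows),
        effects=dict(config.phenotype_effects))
    return annotations, truth


def _draw_fidelity(config: SimulationConfig, rng: np.random.Generator,
                   n: int) -> np.ndarray:
    good = rng.random(n) < config.f_good
    lo_g, hi_g = config.fidelity_good
    lo_p, hi_p = config.fidelity_poor
    out = np.where(good, rng.uniform(lo_g, hi_g, n), rng.uniform(lo_p, hi_p, n))
    return out


def _class_of(config: SimulationConfig, alpha: float) -> str:
    lo_g, hi_g = config.fidelity_good
    return GOOD_PLANTED if lo_g <= alpha <= hi_g else POOR_PLANTED


# ---------------------------------------------------------------------------
# Assay matrices
# ---------------------------------------------------------------------------


def generate_assays(cohort: PhenotypeTable,
                    annotations: Mapping[Platform, list[ReagentAnnotation]],
                    truth: SyntheticTruth,
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[dict[Platform, ExpressionMatrix],
                               dict[Platform, PlateMap]]:
    """Render the three assay matrices plus per-run plate maps.

    Study samples follow the signal model in the module docstring;
    calibrator columns share a fixed latent vector and carry only the plate
    shift and replicate noise.  Aptamer runs are exported as positive
    linear RFU (baseline × 2^y), the antibody run as log2 NPX.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(cohort.sample_ids)
    if n != config.n_samples:
        raise ValueError("cohort size does not match config.n_samples")

    # latent proteome with planted phenotype effects, unit variance per protein
    pheno_num = cohort.numeric_frame()
    proteins = [f"PROT{i:04d}" for i in range(config.n_proteins)]
    latent = rng.standard_normal((config.n_proteins, n))
    for i, pid in enumerate(proteins):
        betas = truth.effects.get(pid)
        if not betas:
            continue
        signal = np.zeros(n)
        b2 = 0.0
        for pheno, beta in betas.items():
            x = pheno_num[pheno].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                continue
            signal += beta * (x - x.mean()) / sd
            b2 += beta * beta
        latent[i] = signal + np.sqrt(max(1.0 - b2, 0.05)) * latent[i]
    latent = (latent - latent.mean(axis=1, keepdims=True))
    latent /= latent.std(axis=1, ddof=1, keepdims=True)
    truth.latent = pd.DataFrame(latent, index=proteins,
                                columns=cohort.sample_ids)
    latent_cal = rng.standard_normal(config.n_proteins)  # shared by all runs

    tr = truth.reagents.set_index(["reagent_id", "family"])
    prot_index = {pid: i for i, pid in enumerate(proteins)}

    matrices: dict[Platform, ExpressionMatrix] = {}
    plate_maps: dict[Platform, PlateMap] = {}
    for plat in (Platform.SOMA_A, Platform.SOMA_B, Platform.OLINK):
        anns = annotations[plat]
        family = "OLINK" if plat is Platform.OLINK else "SOMA"
        rids = [a.reagent_id for a in anns]
        alpha = np.array([tr.loc[(r, family), "alpha"] for r in rids])
        tgt = np.array([prot_index[tr.loc[(r, family), "protein"]]
                        for r in rids])
        n_r = len(rids)
        baseline = rng.normal(0.0, 2.0, n_r)

        # plate layout: study samples round-robin, calibrators per plate
        plate_of_study = np.arange(n) % config.plate_count
        shift = rng.normal(0.0, config.tau_inter, (n_r, config.plate_count))

        noise = rng.standard_normal((n_r, n))
        y_study = (baseline[:, None]
                   + alpha[:, None] * latent[tgt, :]
                   + np.sqrt(1.0 - alpha**2)[:, None] * noise
                   + shift[:, plate_of_study])

        cal_ids, cal_plates = [], []
        for p in range(config.plate_count):
            for rep in range(config.calibrators_per_plate):
                cal_ids.append(f"CAL_{plat.value}_{p:02d}_{rep}")
                cal_plates.append(p)
        cal_plates_arr = np.array(cal_plates)
        rep_noise = rng.normal(0.0, config.sigma_intra,
                               (n_r, len(cal_ids)))
        y_cal = (baseline[:, None]
                 + alpha[:, None] * latent_cal[tgt, None]
                 + shift[:, cal_plates_arr]
                 + rep_noise)

        y = np.concatenate([y_study, y_cal], axis=1)
        cols = list(cohort.sample_ids) + cal_ids
        if plat is Platform.OLINK:
            values = pd.DataFrame(y, index=rids, columns=cols)
            matrices[plat] = ExpressionMatrix(values, Scale.NPX_LOG2, plat)
        else:
            values = pd.DataFrame(config.baseline_rfu * np.exp2(y),
                                  index=rids, columns=cols)
            matrices[plat] = ExpressionMatrix(values, Scale.LINEAR_RFU, plat)

        pm_rows = [{"sample_id": s, "plate_id": f"{plat.value}_P{p:02d}",
                    "role": "STUDY"}
                   for s, p in zip(cohort.sample_ids, plate_of_study)]
        pm_rows += [{"sample_id": s, "plate_id": f"{plat.value}_P{p:02d}",
                     "role": "CALIBRATOR"}
                    for s, p in zip(cal_ids, cal_plates)]
        plate_maps[plat] = PlateMap(pd.DataFrame(pm_rows))
    return matrices, plate_maps


# ---------------------------------------------------------------------------
# Convenience bundle + closed-form correlation oracle
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    cohort: PhenotypeTable
    annotations: dict[Platform, list[ReagentAnnotation]]
    truth: SyntheticTruth
    matrices: dict[Platform, ExpressionMatrix]
    plate_maps: dict[Platform, PlateMap]


def simulate_study(config: SimulationConfig | None = None,
                   seed: int | None = None) -> SimulatedStudy:
    """Generate a complete three-assay study (cohort, panels, matrices).

    ``seed`` overrides ``config.seed``.  Identical seeds give bit-identical
    outputs.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config.seed = seed
    ss = np.random.SeedSequence(config.seed)
    r_cohort, r_reag, r_assay = [np.random.default_rng(s)
                                 for s in ss.spawn(3)]
    cohort = generate_cohort(config, r_cohort)
    annotations, truth = generate_reagents(config, r_reag)
    matrices, plate_maps = generate_assays(cohort, annotations, truth,
                                           config, r_assay)
    return SimulatedStudy(config, cohort, annotations, truth, matrices,
                          plate_maps)


def expected_pair_correlation(alpha1: float, alpha2: float
                              ) -> tuple[float, float]:
    """Closed-form expected correlation between two reagents of fidelities
    α1, α2 reading the same unit-variance latent protein.

    Pearson r = α1·α2 (attenuation under the additive unit-variance noise
    model); Spearman follows from the bivariate-normal rank-correlation
    identity ρ_s = (6/π)·asin(r/2).
    """
    for a in (alpha1, alpha2):
        if not 0.0 <= a <= 1.0:
            raise ValueError("fidelity must lie in [0, 1]")
    r = alpha1 * alpha2
    return r, (6.0 / np.pi) * np.arcsin(r / 2.0)
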