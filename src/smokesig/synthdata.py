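"""Synthetic 450k-style data generation with known ground truth.

Everything downstream (preprocessing, EWAS, enrichment) is exercised on data
produced here: a probe annotation with CpG-island context, a tumour cohort
with smoking status and covariates, a map of planted methylation effects
(partly shared between the "lung" cohort and an external "blood"
meta-analysis), two-channel raw intensities following a
normal-background-plus-gamma-signal model, and blood-style summary
statistics. All randomness flows through a mandatory integer seed; a fixed
seed gives bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

REGIONS = ("island", "shore", "shelf", "open_sea")
#: Full-array proportions of the four collapsed CpG-island-context categories
#: (island, shore, shelf, open sea) on the 450k platform.
ARRAY_REGION_PROPS = (0.316, 0.233, 0.094, 0.357)

SMOKING_LEVELS = ("never", "current", "former_le15", "former_gt15")
#: Cohort smoking-group proportions (never / current / former<=15y / former>15y).
SMOKING_PROPS = (0.156, 0.233, 0.346, 0.264)
STAGES = ("I", "II", "III", "IV")
STAGE_PROPS = (0.554, 0.238, 0.159, 0.049)

#: Multiplicative attenuation of the planted lung effect in former smokers,
#: relative to current smokers (methylation changes fade with quitting time).
FORMER_ATTENUATION = {"never": 0.0, "current": 1.0, "former_le15": 0.6, "former_gt15": 0.3}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model.

    Intensity units are arbitrary fluorescence counts; methylation effects
    are on the beta (fraction) scale. ``signal_shape`` is the gamma shape of
    the per-observation signal (mean ``alpha*beta``); shape 1 is a pure
    exponential, the default 16 reflects averaging over bead replicates.
    """

    n_probes: int = 10_000
    n_samples: int = 390
    group_props: tuple = SMOKING_PROPS
    n_true_lung: int = 100
    n_true_blood: int = 200
    n_shared: int = 40
    effect_mean: float = 0.12      # mean |delta beta| of planted lung effects
    effect_sd: float = 0.04
    blood_effect_mean: float = 0.05  # mean |delta beta| in the blood study
    blood_effect_sd: float = 0.02
    sign_neg_prob: float = 0.8     # hypomethylation bias of planted effects
    mu_b: float = 500.0            # background mean
    sigma_b: float = 100.0         # background sd
    alpha: float = 4000.0          # signal mean at beta = 1
    signal_shape: float = 16.0
    noise_logit_sd: float = 0.15   # per-sample biological noise (logit beta)
    plate_sd: float = 0.05         # per plate x probe batch shift (logit beta)
    n_plates: int = 4
    gap_frac: float = 0.01
    gap_maf_range: tuple = (0.1, 0.5)
    dropout_frac: float = 0.002    # probe x sample pairs drawn background-only
    cross_reactive_frac: float = 0.06
    meta_n: float = 15_907.0       # effective blood meta-analysis size
    n_oob: int = 200
    n_neg_controls: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 0 or self.n_samples < 0:
            raise ValueError("n_probes and n_samples must be non-negative")
        if self.n_shared > min(self.n_true_lung, self.n_true_blood):
            raise ValueError("n_shared must not exceed min(n_true_lung, n_true_blood)")
        if max(self.n_true_lung, self.n_true_blood) > self.n_probes:
            raise ValueError("true-effect counts must not exceed n_probes")
        if self.sigma_b <= 0 or self.alpha <= 0:
            raise ValueError("sigma_b and alpha must be positive")
        if self.meta_n <= 0:
            raise ValueError("meta_n must be positive")


@dataclass
class RawIntensities:
    """Two-channel raw intensities plus background pools, one column per sample.

    ``M`` and ``U`` are probes x samples DataFrames; ``oob`` (out-of-band)
    and ``neg_M``/``neg_U`` (negative controls) are control x samples frames
    drawn from the background distribution only.
    """

    M: pd.DataFrame
    U: pd.DataFrame
    oob: pd.DataFrame
    neg_M: pd.DataFrame
    neg_U: pd.DataFrame

    @property
    def probe_ids(self):
        return self.M.index

    @property
    def sample_ids(self):
        return self.M.columns

    def subset_samples(self, sample_ids) -> "RawIntensities":
        sample_ids = list(sample_ids)
        return RawIntensities(
            M=self.M[sample_ids], U=self.U[sample_ids], oob=self.oob[sample_ids],
            neg_M=self.neg_M[sample_ids], neg_U=self.neg_U[sample_ids],
        )

    def subset_probes(self, probe_ids) -> "RawIntensities":
        probe_ids = list(probe_ids)
        return RawIntensities(
            M=self.M.loc[probe_ids], U=self.U.loc[probe_ids], oob=self.oob,
            neg_M=self.neg_M, neg_U=self.neg_U,
        )


def _check_props(props, what: str, tol: float = 1e-9) -> np.ndarray:
    props = np.asarray(props, dtype=float)
    if np.any(props < 0) or np.any(props > 1):
        raise ValueError(f"{what} must lie in [0, 1]")
    if abs(props.sum() - 1.0) > tol:
        raise ValueError(f"{what} must sum to 1 (got {props.sum()!r})")
    return props


def largest_remainder(n: int, props) -> np.ndarray:
    """Integer allocation of ``n`` among groups by largest-remainder rounding.

    Deterministic: floors first, then distributes the leftover units to the
    largest fractional remainders (first occurrence wins ties). Proportions
    may carry printed-rounding error (tolerance 0.005), as with percentages
    quoted to one decimal place.
    """
    props = _check_props(props, "proportions", tol=5e-3)
    raw = n * props
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        counts[idx] += 1
    return counts


def simulate_annotation(
    n_probes: int,
    region_props=ARRAY_REGION_PROPS,
    cross_reactive_frac: float = 0.06,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a probe annotation table.

    Regions are assigned multinomially with the given proportions
    (island/shore/shelf/open-sea); a random fraction of probes is flagged
    cross-reactive. Gene symbols are synthetic; positions are 1-based.
    """
    if n_probes < 0:
        raise ValueError("n_probes must be non-negative")
    props = _check_props(region_props, "region_props")
    if not 0 <= cross_reactive_frac <= 1:
        raise ValueError("cross_reactive_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    region = rng.choice(REGIONS, size=n_probes, p=props)
    chrom = rng.choice([f"chr{c}" for c in list(range(1, 23)) + ["X"]], size=n_probes)
    pos = rng.integers(1, 250_000_000, size=n_probes) if n_probes else np.array([], dtype=int)
    n_genes = rng.choice([0, 1, 2], size=n_probes, p=[0.25, 0.6, 0.15])
    genes = [
        ";".join(f"GENE{rng.integers(0, max(n_probes, 1))}" for _ in range(k))
        for k in n_genes
    ]
    design_type = rng.choice(["I", "II"], size=n_probes, p=[0.28, 0.72])
    cross_reactive = rng.random(n_probes) < cross_reactive_frac
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chrom,
            "pos": pos.astype(int),
            "genes": genes,
            "region": region,
            "design_type": design_type,
            "cross_reactive": cross_reactive,
        }
    )


def simulate_cohort(
    n_samples: int,
    group_props=SMOKING_PROPS,
    age_mean: float = 65.3,
    age_sd: float = 10.0,
    n_plates: int = 4,
    duplicate_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate sample metadata for a tumour cohort.

    Smoking groups are allocated by largest-remainder rounding of
    ``n_samples * group_props`` (so printed percentages reproduce printed
    counts exactly); sex, age, stage, plate and ten ancestry PCs are drawn
    independently. ``duplicate_frac`` adds extra aliquots for a random subset
    of subjects so the downstream duplicate-resolution path is exercised.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    counts = largest_remainder(n_samples, group_props)
    rng = np.random.default_rng(seed)
    smoking = np.repeat(SMOKING_LEVELS, counts)
    perm = rng.permutation(n_samples)
    smoking = np.asarray(smoking)[perm] if n_samples else np.array([], dtype=object)

    subject_ids = [f"SUBJ{i:05d}" for i in range(n_samples)]
    sample_ids = [f"{s}-01" for s in subject_ids]
    sex = rng.choice(["male", "female"], size=n_samples, p=[0.451, 0.549])
    age = rng.normal(age_mean, age_sd, size=n_samples)
    stage = rng.choice(STAGES, size=n_samples, p=STAGE_PROPS)
    plate = rng.choice([f"plate{p + 1}" for p in range(n_plates)], size=n_samples)
    pcs = rng.normal(0.0, 1.0, size=(n_samples, 10))
    pack_years = np.where(
        smoking == "never", np.nan, np.maximum(rng.normal(42.2, 20.0, size=n_samples), 0.5)
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": subject_ids,
            "smoking": smoking,
            "sex": sex,
            "age": age,
            "stage": stage,
            "plate": plate,
            "pack_years": pack_years,
        }
    )
    for j in range(10):
        meta[f"pc{j + 1}"] = pcs[:, j]

    if duplicate_frac > 0 and n_samples:
        n_dup = int(round(duplicate_frac * n_samples))
        dup_rows = meta.iloc[rng.choice(n_samples, size=n_dup, replace=False)].copy()
        dup_rows["sample_id"] = dup_rows["subject_id"] + "-02"
        meta = pd.concat([meta, dup_rows], ignore_index=True)
    return meta


def plant_effects(
    annotation: pd.DataFrame,
    config: SimulationConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant true methylation effects on a subset of non-cross-reactive probes.

    Draws ``n_shared`` probes with effects in both tissues (same sign),
    plus lung-only and blood-only sets, all disjoint. Signs follow the
    hypomethylation bias ``sign_neg_prob``; magnitudes are truncated-normal
    |delta beta| draws.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    eligible = annotation.loc[~annotation["cross_reactive"], "probe_id"].to_numpy()
    n_needed = config.n_true_lung + config.n_true_blood - config.n_shared
    if n_needed > eligible.size:
        raise ValueError("not enough non-cross-reactive probes for requested effects")
    chosen = rng.choice(eligible, size=n_needed, replace=False)
    shared = chosen[: config.n_shared]
    lung_only = chosen[config.n_shared: config.n_true_lung]
    blood_only = chosen[config.n_true_lung:]

    def magnitudes(n, mean, sd):
        return np.abs(rng.normal(mean, sd, size=n))

    signs = {}
    for pid in chosen:
        signs[pid] = -1.0 if rng.random() < config.sign_neg_prob else 1.0

    eff = pd.DataFrame(
        {
            "probe_id": annotation["probe_id"].to_numpy(),
            "true_effect_lung": 0.0,
            "true_effect_blood": 0.0,
            "shared": False,
            "null_probe": True,
        }
    ).set_index("probe_id")
    lung_set = np.concatenate([shared, lung_only])
    blood_set = np.concatenate([shared, blood_only])
    eff.loc[lung_set, "true_effect_lung"] = [
        signs[p] * m for p, m in zip(lung_set, magnitudes(lung_set.size, config.effect_mean, config.effect_sd))
    ]
    eff.loc[blood_set, "true_effect_blood"] = [
        signs[p] * m
        for p, m in zip(blood_set, magnitudes(blood_set.size, config.blood_effect_mean, config.blood_effect_sd))
    ]
    eff.loc[shared, "shared"] = True
    eff.loc[np.concatenate([lung_set, blood_set]), "null_probe"] = False
    return eff.reset_index()


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _truncated_normal(rng, mu, sigma, size):
    """Normal(mu, sigma^2) draws truncated at 0 (values clipped, the
    generative convention for background intensities)."""
    return np.maximum(rng.normal(mu, sigma, size=size), 0.0)


def simulate_intensities(
    annotation: pd.DataFrame,
    cohort: pd.DataFrame,
    effect_map: pd.DataFrame,
    config: SimulationConfig,
    seed: int = 0,
) -> RawIntensities:
    """Simulate two-channel intensities with planted smoking effects.

    Per probe a baseline beta is drawn from a bimodal mixture; smoking
    groups shift it by the probe's true lung effect (attenuated in former
    smokers), plate and biological noise act on the logit scale, and gap
    probes get three Hardy-Weinberg genotype modes. Channel signal is
    Gamma(shape k, mean alpha*beta) resp. alpha*(1-beta); background is
    Normal(mu_b, sigma_b^2) truncated at 0 and added to both channels.
    A ``dropout_frac`` fraction of probe x sample pairs is background-only.
    """
    config.validate()
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    if not annotation["probe_id"].equals(effect_map["probe_id"]):
        raise ValueError("annotation and effect_map must share probe ids (same order)")
    rng = np.random.default_rng(seed)
    G = len(annotation)
    n = len(cohort)
    probe_ids = annotation["probe_id"].to_numpy()
    sample_ids = cohort["sample_id"].to_numpy()

    # baseline methylation: bimodal across probes, as on the platform
    comp = rng.choice(3, size=G, p=[0.4, 0.4, 0.2])
    base = np.where(
        comp == 0, rng.beta(2, 10, size=G),
        np.where(comp == 1, rng.beta(10, 2, size=G), rng.beta(5, 5, size=G)),
    )
    base = np.clip(base, 0.02, 0.98)

    atten = cohort["smoking"].map(FORMER_ATTENUATION).to_numpy()
    delta = np.outer(effect_map["true_effect_lung"].to_numpy(), atten)  # G x n

    plates = cohort["plate"].to_numpy()
    plate_levels = pd.unique(plates)
    plate_fx = rng.normal(0.0, config.plate_sd, size=(G, plate_levels.size))
    plate_idx = pd.Categorical(plates, categories=plate_levels).codes
    lgt = _logit(base)[:, None] + plate_fx[:, plate_idx]
    lgt = lgt + rng.normal(0.0, config.noise_logit_sd, size=(G, n))
    beta = np.clip(_expit(lgt) + delta, 1e-3, 1.0 - 1e-3)

    # gap probes: three genotype-driven modes per subject (Hardy-Weinberg)
    n_gap = int(round(config.gap_frac * G))
    if n_gap:
        null_mask = effect_map["null_probe"].to_numpy()
        gap_pool = np.flatnonzero(null_mask)
        gap_rows = rng.choice(gap_pool, size=min(n_gap, gap_pool.size), replace=False)
        maf = rng.uniform(*config.gap_maf_range, size=gap_rows.size)
        for row, q in zip(gap_rows, maf):
            geno = rng.binomial(2, q, size=n)
            beta[row] = np.clip(0.15 + 0.3 * geno + rng.normal(0, 0.02, size=n), 1e-3, 1 - 1e-3)
        gap_flag = np.zeros(G, dtype=bool)
        gap_flag[gap_rows] = True
    else:
        gap_flag = np.zeros(G, dtype=bool)
    # recorded for ground-truth checks, without mutating the caller's frame
    effect_map.attrs["gap_truth"] = pd.Series(gap_flag, index=probe_ids)

    k = config.signal_shape
    sig_m = rng.gamma(k, config.alpha * beta / k)
    sig_u = rng.gamma(k, config.alpha * (1.0 - beta) / k)
    if config.dropout_frac > 0:
        drop = rng.random((G, n)) < config.dropout_frac
        sig_m[drop] = 0.0
        sig_u[drop] = 0.0
    M = sig_m + _truncated_normal(rng, config.mu_b, config.sigma_b, (G, n))
    U = sig_u + _truncated_normal(rng, config.mu_b, config.sigma_b, (G, n))

    oob = _truncated_normal(rng, config.mu_b, config.sigma_b, (config.n_oob, n))
    neg_m = _truncated_normal(rng, config.mu_b, config.sigma_b, (config.n_neg_controls, n))
    neg_u = _truncated_normal(rng, config.mu_b, config.sigma_b, (config.n_neg_controls, n))
    return RawIntensities(
        M=pd.DataFrame(M, index=probe_ids, columns=sample_ids),
        U=pd.DataFrame(U, index=probe_ids, columns=sample_ids),
        oob=pd.DataFrame(oob, columns=sample_ids),
        neg_M=pd.DataFrame(neg_m, columns=sample_ids),
        neg_U=pd.DataFrame(neg_u, columns=sample_ids),
    )


def simulate_summary_stats(
    effect_map: pd.DataFrame,
    annotation: pd.DataFrame,
    meta_n: float = 15_907.0,
    se_scale: float = 1.0,
    seed: int = 0,
    study: str = "blood",
) -> pd.DataFrame:
    """Simulate an external-study summary-statistics table.

    Per probe: estimate (in % methylation) = 100 * true blood effect +
    Normal(0, SE^2) with SE = 100 * se_scale / sqrt(meta_n); P is the
    two-sided normal tail of estimate/SE. Null probes therefore have
    uniform P. ``meta_n=inf`` is the noiseless limit: estimates equal the
    true effects and exact-zero z yields P = 1 (documented convention).
    """
    if not meta_n > 0:
        raise ValueError("meta_n must be positive")
    rng = np.random.default_rng(seed)
    true = 100.0 * effect_map["true_effect_blood"].to_numpy()
    if np.isinf(meta_n):
        est = true
        se = np.zeros_like(true)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(est == 0.0, 0.0, np.inf * np.sign(est))
    else:
        scale = 100.0 * se_scale / np.sqrt(meta_n)
        se = np.full_like(true, scale)
        est = true + rng.normal(0.0, scale, size=true.size)
        z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "probe_id": effect_map["probe_id"].to_numpy(),
            "estimate": est,
            "se": se,
            "p": p,
            "study": study,
        }
    )
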