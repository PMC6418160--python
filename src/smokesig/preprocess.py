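"""450k-style preprocessing: detection P, sample/probe QC, noob, gap probes.

The chain mirrors standard Infinium practice: detection P-values against the
negative-control background, sample-level intensity and detection QC,
one-sample-per-subject duplicate resolution, cross-reactive and
low-detection probe removal, normal-exponential out-of-band (noob)
background correction, beta computation, and gap-probe flagging.

A probe x sample observation counts as *failing* detection when its
detection P >= the cutoff (P < cutoff means confidently above background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import erfcx

from .synthdata import RawIntensities


def compute_detection_p(raw: RawIntensities) -> pd.DataFrame:
    """Detection P per probe x sample from the negative-control background.

    P = upper-tail probability of the total intensity M+U under
    Normal(m_neg, s_neg^2), with m_neg the per-sample median of
    negative-control totals and s_neg a robust scale (MAD x 1.4826).
    """
    totals = raw.neg_M.to_numpy() + raw.neg_U.to_numpy()
    if totals.shape[0] < 3:
        raise ValueError("need at least 3 negative controls per sample")
    m_neg = np.median(totals, axis=0)
    s_neg = stats.median_abs_deviation(totals, axis=0, scale="normal")
    if np.any(s_neg <= 0):
        raise ValueError("degenerate negative-control scale (MAD = 0)")
    x = raw.M.to_numpy() + raw.U.to_numpy()
    p = stats.norm.sf(x, loc=m_neg[None, :], scale=s_neg[None, :])
    return pd.DataFrame(p, index=raw.probe_ids, columns=raw.sample_ids)


@dataclass
class QCReport:
    """Per-sample QC metrics and keep/drop verdicts."""

    table: pd.DataFrame  # sample_id, log2_median_M, log2_median_U, fail_frac, kept, reason

    @property
    def kept_samples(self) -> list:
        return self.table.loc[self.table["kept"], "sample_id"].tolist()


def qc_samples(
    raw: RawIntensities,
    detp: pd.DataFrame,
    intensity_cut: float = 11.0,
    fail_frac: float = 0.01,
    detp_cut: float = 0.01,
    intensity_rule: str = "and",
) -> QCReport:
    """Flag low-quality samples.

    A sample is dropped when its log2 median M and log2 median U are both
    below ``intensity_cut`` (``intensity_rule="or"`` drops when either is),
    or when more than ``fail_frac`` of probes fail detection at
    ``detp_cut``. Both metrics are reported for every sample.
    """
    if len(raw.M.index) == 0:
        raise ValueError("empty probe set")
    if intensity_rule not in ("and", "or"):
        raise ValueError("intensity_rule must be 'and' or 'or'")
    log2_m = np.log2(raw.M.median(axis=0).to_numpy())
    log2_u = np.log2(raw.U.median(axis=0).to_numpy())
    frac_fail = (detp.to_numpy() >= detp_cut).mean(axis=0)
    if intensity_rule == "and":
        low_int = (log2_m < intensity_cut) & (log2_u < intensity_cut)
    else:
        low_int = (log2_m < intensity_cut) | (log2_u < intensity_cut)
    bad_det = frac_fail > fail_frac
    reasons = []
    for li, bd in zip(low_int, bad_det):
        parts = (["low intensity"] if li else []) + (["detection"] if bd else [])
        reasons.append("; ".join(parts))
    table = pd.DataFrame(
        {
            "sample_id": list(raw.sample_ids),
            "log2_median_M": log2_m,
            "log2_median_U": log2_u,
            "fail_frac": frac_fail,
            "kept": ~(low_int | bad_det),
            "reason": reasons,
        }
    )
    return QCReport(table=table)


def resolve_duplicates(
    metadata: pd.DataFrame, detp: pd.DataFrame, detp_cut: float = 0.01
) -> list:
    """Keep exactly one sample per subject.

    The retained sample minimises the fraction of probes failing detection;
    ties break to the lexicographically smallest sample_id.
    """
    meta = metadata[metadata["sample_id"].isin(detp.columns)]
    fail = (detp >= detp_cut).mean(axis=0)
    kept = []
    for _, grp in meta.groupby("subject_id", sort=True):
        ranked = sorted(grp["sample_id"], key=lambda s: (fail[s], s))
        kept.append(ranked[0])
    return sorted(kept)


@dataclass
class ProbeFilterResult:
    keep: list
    n_cross_reactive_removed: int
    n_low_detection_removed: int


def filter_probes(
    detp: pd.DataFrame,
    annotation: pd.DataFrame,
    detp_cut: float = 0.01,
    sample_frac: float = 0.10,
) -> ProbeFilterResult:
    """Remove cross-reactive probes, then probes failing detection in more
    than ``sample_frac`` of the retained samples."""
    ann = annotation.set_index("probe_id")
    cross = ann.loc[detp.index, "cross_reactive"].to_numpy(dtype=bool)
    fail_frac = (detp.to_numpy() >= detp_cut).mean(axis=1)
    low_det = fail_frac > sample_frac
    keep_mask = ~cross & ~low_det
    return ProbeFilterResult(
        keep=list(detp.index[keep_mask]),
        n_cross_reactive_removed=int(cross.sum()),
        n_low_detection_removed=int((low_det & ~cross).sum()),
    )


@dataclass(frozen=True)
class NoobParams:
    """Normal-exponential convolution parameters for one sample."""

    mu_b: float
    sigma_b: float
    alpha: float
    offset: float = 15.0

    def __post_init__(self):
        if self.sigma_b <= 0:
            raise ValueError("sigma_b must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


def normexp_signal(x, mu_b: float, sigma_b: float, alpha: float) -> np.ndarray:
    """Posterior mean E[S | X = x] under X = S + B, S ~ Exp(mean alpha),
    B ~ Normal(mu_b, sigma_b^2):

        mu_sf = x - mu_b - sigma_b^2 / alpha
        E[S|X] = mu_sf + sigma_b * phi(mu_sf/sigma_b) / Phi(mu_sf/sigma_b)

    Strictly positive for all x.
    """
    x = np.asarray(x, dtype=float)
    mu_sf = x - mu_b - sigma_b**2 / alpha
    z = mu_sf / sigma_b
    # phi(z)/Phi(z) via the scaled complementary error function: numerically
    # stable for z << 0 where both phi and Phi underflow
    mills = np.sqrt(2.0 / np.pi) / erfcx(-z / np.sqrt(2.0))
    return mu_sf + sigma_b * mills


def estimate_noob_params(raw: RawIntensities, offset: float = 15.0, alpha_floor: float = 1.0):
    """Per-sample noob parameters: background mean/sd from the out-of-band
    pool, signal mean alpha = mean in-band intensity minus mu_b (floored)."""
    params = {}
    for s in raw.sample_ids:
        oob = raw.oob[s].to_numpy()
        mu_b = float(np.mean(oob))
        sigma_b = float(np.std(oob, ddof=1))
        if sigma_b <= 0:
            raise ValueError(f"sample {s}: non-positive background sd estimate")
        inband = np.concatenate([raw.M[s].to_numpy(), raw.U[s].to_numpy()])
        alpha = max(float(np.mean(inband)) - mu_b, alpha_floor)
        params[s] = NoobParams(mu_b=mu_b, sigma_b=sigma_b, alpha=alpha, offset=offset)
    return params


def noob_correct(raw: RawIntensities, params=None, offset: float = 15.0) -> RawIntensities:
    """Noob background correction of both channels.

    ``params`` maps sample_id -> NoobParams; estimated from the out-of-band
    pool when omitted. Output intensities are strictly positive
    (posterior mean + offset).
    """
    if params is None:
        params = estimate_noob_params(raw, offset=offset)
    M = raw.M.copy()
    U = raw.U.copy()
    for s in raw.sample_ids:
        pp = params[s]
        M[s] = normexp_signal(M[s].to_numpy(), pp.mu_b, pp.sigma_b, pp.alpha) + pp.offset
        U[s] = normexp_signal(U[s].to_numpy(), pp.mu_b, pp.sigma_b, pp.alpha) + pp.offset
    return RawIntensities(M=M, U=U, oob=raw.oob, neg_M=raw.neg_M, neg_U=raw.neg_U)


def compute_beta(corrected: RawIntensities, beta_offset: float = 100.0) -> pd.DataFrame:
    """Beta values beta = M / (M + U + beta_offset), in [0, 1)."""
    m = corrected.M.to_numpy()
    u = corrected.U.to_numpy()
    beta = m / (m + u + beta_offset)
    return pd.DataFrame(beta, index=corrected.probe_ids, columns=corrected.sample_ids)


def gaphunter(
    beta: pd.DataFrame, gap_threshold: float = 0.05, out_cutoff: float = 0.01
) -> pd.DataFrame:
    """Flag probes whose beta distribution splits into separated clusters.

    Sorted betas are split wherever a consecutive difference exceeds
    ``gap_threshold``; a probe with >= 2 groups is a gap probe unless the
    combined size of all non-largest groups is below ``out_cutoff`` x n
    (then the split is outlier-driven and the gap flag is demoted).
    Deterministic and invariant to sample order.
    """
    n = beta.shape[1]
    if n < 2:
        raise ValueError("gaphunter needs at least 2 samples")
    vals = np.sort(beta.to_numpy(), axis=1)
    records = []
    for row in vals:
        cuts = np.flatnonzero(np.diff(row) > gap_threshold)
        sizes = np.diff(np.concatenate([[0], cuts + 1, [n]])).tolist()
        n_groups = len(sizes)
        is_gap = n_groups >= 2
        outlier = False
        if is_gap:
            minority = n - max(sizes)
            if minority < out_cutoff * n:
                outlier = True
                is_gap = False
        records.append((is_gap, n_groups, sizes, outlier))
    return pd.DataFrame(
        records,
        index=beta.index,
        columns=["is_gap", "n_groups", "group_sizes", "outlier_driven"],
    )


@dataclass
class PreprocessResult:
    """Analysis-ready betas plus the bookkeeping of every exclusion step."""

    beta: pd.DataFrame
    gap_flags: pd.DataFrame
    qc: QCReport
    kept_samples: list
    probe_filter: ProbeFilterResult
    noob_params: dict
    manifest: dict


def preprocess(
    raw: RawIntensities,
    metadata: pd.DataFrame,
    annotation: pd.DataFrame,
    detp_cut: float = 0.01,
    sample_fail_frac: float = 0.01,
    probe_sample_frac: float = 0.10,
    intensity_cut: float = 11.0,
    noob_offset: float = 15.0,
    beta_offset: float = 100.0,
    gap_threshold: float = 0.05,
    gap_out_cutoff: float = 0.01,
) -> PreprocessResult:
    """Full chain: detection P -> sample QC -> dedup -> probe filter ->
    noob -> beta -> gap flags, with a manifest of counts at every step."""
    detp = compute_detection_p(raw)
    qc = qc_samples(
        raw, detp, intensity_cut=intensity_cut, fail_frac=sample_fail_frac, detp_cut=detp_cut
    )
    qc_kept = qc.kept_samples
    kept = resolve_duplicates(
        metadata[metadata["sample_id"].isin(qc_kept)], detp[qc_kept], detp_cut=detp_cut
    )
    detp_kept = detp[kept]
    pf = filter_probes(detp_kept, annotation, detp_cut=detp_cut, sample_frac=probe_sample_frac)
    raw_kept = raw.subset_samples(kept).subset_probes(pf.keep)
    params = estimate_noob_params(raw_kept, offset=noob_offset)
    corrected = noob_correct(raw_kept, params=params)
    beta = compute_beta(corrected, beta_offset=beta_offset)
    gaps = gaphunter(beta, gap_threshold=gap_threshold, out_cutoff=gap_out_cutoff)
    manifest = {
        "n_samples_in": int(len(raw.sample_ids)),
        "n_samples_qc_removed": int(len(raw.sample_ids) - len(qc_kept)),
        "n_samples_duplicate_removed": int(len(qc_kept) - len(kept)),
        "n_samples_out": int(len(kept)),
        "n_probes_in": int(len(raw.probe_ids)),
        "n_probes_cross_reactive_removed": pf.n_cross_reactive_removed,
        "n_probes_low_detection_removed": pf.n_low_detection_removed,
        "n_probes_out": int(len(pf.keep)),
        "n_gap_probes": int(gaps["is_gap"].sum()),
        "detp_cut": detp_cut,
        "sample_fail_frac": sample_fail_frac,
        "probe_sample_frac": probe_sample_frac,
        "noob_offset": noob_offset,
        "beta_offset": beta_offset,
    }
    return PreprocessResult(
        beta=beta, gap_flags=gaps, qc=qc, kept_samples=kept, probe_filter=pf,
        noob_params=params, manifest=manifest,
    )
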