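"""Probewise EWAS: OLS on beta values with empirical-Bayes moderation.

Per CpG, methylation (beta) is regressed on smoking status (treatment-coded
against never smokers) adjusting for sex, age, stage, plate and ten ancestry
principal components. Residual variances are shrunk toward a common prior by
the standard moment-matched scaled-inverse-chi-square empirical Bayes
scheme, giving moderated t-statistics on d0 + d degrees of freedom.
Diagnostics: genomic inflation lambda, QQ data, BH q-values, and a
residual-SVD surrogate-variable sensitivity model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

CHI2_1_MEDIAN = 0.4549364231195724  # median of the chi-square(1) distribution

CONTRASTS = ("current", "former_le15", "former_gt15")

REQUIRED_COVARIATES = ["smoking", "sex", "age", "stage", "plate"] + [f"pc{i}" for i in range(1, 11)]


@dataclass
class DesignMatrix:
    X: np.ndarray                 # samples x covariates, full column rank
    columns: list
    contrasts: dict               # contrast name -> column index
    sample_ids: list
    n_dropped: int = 0

    @property
    def rank(self) -> int:
        return self.X.shape[1]


def build_design(metadata: pd.DataFrame, extra: np.ndarray | None = None) -> DesignMatrix:
    """Treatment-coded design: intercept, smoking dummies (never = reference),
    sex, age, stage, plate dummies, ten ancestry PCs.

    Rows with missing covariates are excluded (count recorded). Degenerate
    single-level factors emit no columns. Raises on rank deficiency, naming
    the collinear columns.
    """
    meta = metadata.dropna(subset=[c for c in REQUIRED_COVARIATES if c in metadata.columns])
    n_dropped = len(metadata) - len(meta)
    if len(meta) == 0:
        raise ValueError("no samples with complete covariates")
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    contrasts = {}

    def add_dummies(series, prefix, reference):
        levels = [l for l in pd.unique(series) if l != reference]
        for lev in sorted(levels):
            cols.append((series == lev).to_numpy(dtype=float))
            names.append(f"{prefix}_{lev}")

    smoking = meta["smoking"]
    for lev in CONTRASTS:
        if (smoking == lev).any():
            cols.append((smoking == lev).to_numpy(dtype=float))
            contrasts[lev] = len(names)
            names.append(f"smoking_{lev}")
    add_dummies(meta["sex"], "sex", reference="female")
    cols.append(meta["age"].to_numpy(dtype=float))
    names.append("age")
    add_dummies(meta["stage"], "stage", reference="I")
    add_dummies(meta["plate"], "plate", reference=sorted(pd.unique(meta["plate"]))[0])
    for j in range(1, 11):
        cols.append(meta[f"pc{j}"].to_numpy(dtype=float))
        names.append(f"pc{j}")
    X = np.column_stack(cols)
    if extra is not None:
        X = np.column_stack([X, extra])
        names = names + [f"sv{j + 1}" for j in range(extra.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns greedily by incremental rank
        bad = []
        kept = np.empty((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return DesignMatrix(
        X=X, columns=names, contrasts=contrasts,
        sample_ids=list(meta["sample_id"]), n_dropped=n_dropped,
    )


@dataclass
class ProbewiseFit:
    coef: np.ndarray        # G x p
    sigma2: np.ndarray      # G residual variances
    df: np.ndarray          # G residual degrees of freedom
    v: np.ndarray           # p unscaled variance factors diag((X'X)^-1)
    probe_ids: list
    design: DesignMatrix


def fit_probewise(beta: pd.DataFrame, design: DesignMatrix) -> ProbewiseFit:
    """Ordinary least squares per probe (vectorised across probes).

    Missing betas are handled probewise complete-case with per-probe df.
    SE of coefficient j is sqrt(sigma2 * v[j]).
    """
    Y = beta[design.sample_ids].to_numpy()
    X = design.X
    n, p = X.shape
    if n - p <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    v = np.diag(xtx_inv).copy()
    if not np.isnan(Y).any():
        coef = Y @ (xtx_inv @ X.T).T
        resid = Y - coef @ X.T
        rss = np.einsum("ij,ij->i", resid, resid)
        df = np.full(Y.shape[0], n - p, dtype=float)
        sigma2 = rss / df
    else:
        G = Y.shape[0]
        coef = np.full((G, p), np.nan)
        sigma2 = np.full(G, np.nan)
        df = np.full(G, np.nan)
        for g in range(G):
            ok = ~np.isnan(Y[g])
            dg = ok.sum() - p
            if dg <= 0:
                raise ValueError(f"probe {beta.index[g]}: non-positive residual df")
            Xg = X[ok]
            bg, rssg, *_ = np.linalg.lstsq(Xg, Y[g, ok], rcond=None)
            coef[g] = bg
            resid = Y[g, ok] - Xg @ bg
            sigma2[g] = resid @ resid / dg
            df[g] = dg
    return ProbewiseFit(
        coef=coef, sigma2=sigma2, df=df, v=v, probe_ids=list(beta.index), design=design
    )


@dataclass(frozen=True)
class EBayesPrior:
    d0: float       # prior degrees of freedom, may be inf
    s0_sq: float    # prior variance


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve psi'(x) = y for x > 0 by Newton iteration on 1/psi'."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s_sq: np.ndarray, df: np.ndarray) -> EBayesPrior:
    """Moment-matched prior (d0, s0^2) for the scaled-inverse-chi-square
    variance model, from the log-variance distribution across probes:

        e_g = ln s_g^2 - psi(d_g/2) + ln(d_g/2)
        psi'(d0/2) = max(0, var(e) - mean psi'(d_g/2));  d0 = inf if <= 0
        s0^2 = exp(mean(e) + psi(d0/2) - ln(d0/2))
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s_sq.shape)
    if s_sq.size < 10:
        raise ValueError("need at least 10 probes to estimate the prior")
    if np.all(s_sq == 0):
        raise ValueError("all residual variances are zero")
    if np.any(s_sq <= 0):
        floor = s_sq[s_sq > 0].min()
        s_sq = np.where(s_sq <= 0, floor, s_sq)
    half = df / 2.0
    e = np.log(s_sq) - polygamma(0, half) + np.log(half)
    evar = float(np.var(e, ddof=1))
    target = evar - float(np.mean(polygamma(1, half)))
    if target <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * trigamma_inverse(target)
        s0_sq = float(np.exp(np.mean(e) + _digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def _digamma(x):
    return float(polygamma(0, x))


def moderate_variances(s_sq: np.ndarray, df: np.ndarray, prior: EBayesPrior) -> np.ndarray:
    """Posterior variances s~^2 = (d0 s0^2 + d s^2) / (d0 + d)."""
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s_sq.shape)
    if np.isinf(prior.d0):
        return np.full_like(s_sq, prior.s0_sq)
    if prior.d0 == 0:
        return s_sq.copy()
    return (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)


def ebayes_moderate(fit: ProbewiseFit, contrast_col: int, prior: EBayesPrior | None = None):
    """Moderated t for one design column.

    Returns (prior, DataFrame with estimate, se, t, df_total, p). With
    ``prior=EBayesPrior(0, s0)`` the result is the ordinary OLS t exactly.
    """
    if prior is None:
        prior = estimate_prior(fit.sigma2, fit.df)
    s2_post = moderate_variances(fit.sigma2, fit.df, prior)
    b = fit.coef[:, contrast_col]
    se = np.sqrt(s2_post * fit.v[contrast_col])
    t = b / se
    df_total = fit.df + (0.0 if np.isinf(prior.d0) else prior.d0)
    if np.isinf(prior.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
        df_total = np.full_like(fit.df, np.inf)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = pd.DataFrame(
        {"estimate": b, "se": se, "t": t, "df_total": df_total, "p": p},
        index=fit.probe_ids,
    )
    return prior, out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, in [0, 1])."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genomic_inflation(p: np.ndarray):
    """Genomic inflation lambda and QQ data.

    lambda = median(qchisq1(1 - p)) / 0.4549364; returns (lambda, expected,
    observed) where expected/observed are sorted -log10 P for QQ plotting.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(p <= 0):
        raise ValueError("p = 0 encountered; floor p-values before computing lambda")
    if np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / CHI2_1_MEDIAN)
    obs = np.sort(-np.log10(p))[::-1]
    expected = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    return lam, expected, obs


def estimate_surrogates(beta: pd.DataFrame, design: DesignMatrix, n_sv: int = 10) -> np.ndarray:
    """Surrogate variables as the top left singular vectors (sample space) of
    the model residual matrix.

    Deterministic up to sign; the sign is fixed by making each vector's
    largest-magnitude entry positive. An exactly-zero residual matrix yields
    zero vectors (documented degenerate convention).
    """
    X = design.X
    n = X.shape[0]
    if n_sv >= n - design.rank:
        raise ValueError(f"n_sv={n_sv} too large for {n} samples and rank {design.rank}")
    Y = beta[design.sample_ids].to_numpy().T  # samples x probes
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    R = Y - H @ Y
    # numerically-zero residuals (beta exactly in the model span) yield the
    # documented degenerate convention: zero surrogate vectors
    if np.max(np.abs(R)) <= 1e-10 * max(1.0, np.max(np.abs(Y))):
        return np.zeros((n, n_sv))
    u, s, _ = np.linalg.svd(R, full_matrices=False)
    sv = u[:, :n_sv].copy()
    for j in range(sv.shape[1]):
        k = np.argmax(np.abs(sv[:, j]))
        if sv[k, j] < 0:
            sv[:, j] = -sv[:, j]
    return sv


def model_agreement(coef_a: np.ndarray, coef_b: np.ndarray) -> float:
    """Pearson correlation between two coefficient vectors."""
    a = np.asarray(coef_a, dtype=float)
    b = np.asarray(coef_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a coefficient vector")
    return float(stats.pearsonr(a, b)[0])


@dataclass
class EwasResult:
    """Per-contrast EWAS tables plus inflation diagnostics."""

    tables: dict            # contrast -> DataFrame (probe-indexed)
    prior: EBayesPrior
    lambdas: dict           # contrast -> lambda
    design: DesignMatrix


def run_ewas(
    beta: pd.DataFrame,
    metadata: pd.DataFrame,
    gap_flags: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
    extra_covariates: np.ndarray | None = None,
    exclude_gap_probes: bool = False,
) -> EwasResult:
    """Full EWAS: design, probewise OLS, moderation, FDR, lambda.

    Effect estimates are reported on the percent-methylation scale
    (100 x delta beta). Gap probes are flagged, not removed, unless
    ``exclude_gap_probes`` is set.
    """
    meta = metadata[metadata["sample_id"].isin(beta.columns)]
    design = build_design(meta, extra=extra_covariates)
    if exclude_gap_probes and gap_flags is not None:
        beta = beta.loc[~gap_flags["is_gap"].reindex(beta.index, fill_value=False)]
    fit = fit_probewise(beta, design)
    prior = estimate_prior(fit.sigma2, fit.df)
    avg_meth = 100.0 * beta.mean(axis=1)
    tables = {}
    lambdas = {}
    for name, col in design.contrasts.items():
        _, tab = ebayes_moderate(fit, col, prior=prior)
        tab = tab.copy()
        tab["estimate"] *= 100.0
        tab["se"] *= 100.0
        tab["q_fdr"] = bh_fdr(tab["p"].to_numpy())
        tab["avg_meth_pct"] = avg_meth
        if gap_flags is not None:
            tab["gap_probe"] = gap_flags["is_gap"].reindex(tab.index, fill_value=False)
        else:
            tab["gap_probe"] = False
        if annotation is not None:
            ann = annotation.set_index("probe_id")
            for c in ("chrom", "pos", "genes"):
                tab[c] = ann[c].reindex(tab.index)
        tab.index.name = "probe_id"
        tables[name] = tab
        lambdas[name] = genomic_inflation(np.clip(tab["p"].to_numpy(), 1e-300, 1.0))[0]
    return EwasResult(tables=tables, prior=prior, lambdas=lambdas, design=design)
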