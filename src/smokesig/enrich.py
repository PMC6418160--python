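"""Cross-study CpG signature enrichment.

Quantifies over-representation of one study's significant CpG set within
another's results over a shared probe universe: observed vs expected
(hypergeometric) overlap, Fisher exact tests, P-threshold sweeps,
permutation nulls built by reassigning P-values to probes, effect-direction
concordance, and the distribution of overlap sites across CpG-island
context regions (G-test plus per-region proportion tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import ARRAY_REGION_PROPS, REGIONS

#: Default signature inclusion threshold in both studies.
P_CUTOFF = 1e-4
#: Default threshold sweep grid, 1.0 down to 1e-10.
SWEEP_GRID = tuple(10.0 ** -np.arange(0, 10.5, 0.5))


def harmonize_universe(results_a: pd.DataFrame, results_b: pd.DataFrame):
    """Restrict study B to study A's analysed probe universe.

    The universe is the set of probes analysed in study A (after its
    filters); returns (universe_index, N, n_b_lost) where n_b_lost counts
    study-B probes absent from the universe.
    """
    ua = pd.Index(results_a["probe_id"]) if "probe_id" in results_a else results_a.index
    ub = pd.Index(results_b["probe_id"]) if "probe_id" in results_b else results_b.index
    common = ub.intersection(ua)
    if len(common) == 0:
        raise ValueError("probe universes of the two studies are disjoint")
    return ua, len(ua), len(ub) - len(common)


@dataclass
class EnrichmentResult:
    N: int
    n_a: int
    n_b: int
    k: int
    expected: float
    odds_ratio: float
    p_fisher: float
    threshold_a: float | None = None
    threshold_b: float | None = None
    sided: str = "greater"

    @property
    def expected_1dp(self) -> float:
        """Expected overlap at the reporting precision (1 decimal place)."""
        return round(self.expected, 1)


def overlap_enrichment(set_a, set_b, N: int, sided: str = "greater",
                       threshold_a=None, threshold_b=None) -> EnrichmentResult:
    """Enrichment of set B inside set A over a universe of N probes.

    k = |A n B|, expected = |A||B|/N; the 2x2 table is
    (k, |A|-k, |B|-k, N-|A|-|B|+k) with the sample odds ratio
    (k * (N-|A|-|B|+k)) / ((|A|-k) * (|B|-k)). ``sided="greater"`` gives the
    hypergeometric upper tail P(X >= k); ``"two-sided"`` the Fisher exact
    two-sided P.
    """
    sa, sb = set(set_a), set(set_b)
    n_a, n_b = len(sa), len(sb)
    if N < len(sa | sb):
        raise ValueError("universe size N smaller than |A u B|")
    k = len(sa & sb)
    expected = n_a * n_b / N if N else 0.0
    rest = N - n_a - n_b + k
    denom = (n_a - k) * (n_b - k)
    odds = (k * rest / denom) if denom > 0 else np.inf if k else np.nan
    if n_a == 0 or n_b == 0:
        p = 1.0
    elif sided == "greater":
        p = float(stats.hypergeom.sf(k - 1, N, n_b, n_a))
    elif sided == "two-sided":
        p = float(stats.fisher_exact([[k, n_a - k], [n_b - k, rest]], alternative="two-sided")[1])
    else:
        raise ValueError("sided must be 'greater' or 'two-sided'")
    return EnrichmentResult(
        N=N, n_a=n_a, n_b=n_b, k=k, expected=expected, odds_ratio=odds,
        p_fisher=min(p, 1.0), threshold_a=threshold_a, threshold_b=threshold_b, sided=sided,
    )


def _passing(p: pd.Series, threshold: float) -> pd.Index:
    """Probes passing a significance threshold (P < t; t >= 1 passes all)."""
    if threshold >= 1.0:
        return p.index
    return p.index[p.to_numpy() < threshold]


def threshold_sweep(results_a_p: pd.Series, set_b, N: int, thresholds=SWEEP_GRID) -> pd.DataFrame:
    """Enrichment of the fixed B set at a grid of study-A P cutoffs.

    Returns one row per threshold: (threshold_a, n_a, k, expected,
    odds_ratio, p_fisher). Overlap k is monotone non-decreasing in the
    threshold by construction.
    """
    set_b = set(set_b)
    rows = []
    for t in sorted(thresholds):
        res = overlap_enrichment(_passing(results_a_p, t), set_b, N, threshold_a=t)
        rows.append((t, res.n_a, res.k, res.expected, res.odds_ratio, res.p_fisher))
    return pd.DataFrame(
        rows, columns=["threshold_a", "n_a", "k", "expected", "odds_ratio", "p_fisher"]
    )


@dataclass
class PermutationNull:
    n_perm: int
    overlaps: np.ndarray      # per-rep overlap counts
    fisher_p: np.ndarray      # per-rep hypergeometric upper-tail p
    k_obs: int
    empirical_p: float
    min_fisher_p: float
    seed: int


def permutation_null(
    results_a_p: pd.Series, set_b, N: int, threshold: float = P_CUTOFF,
    n_perm: int = 10_000, seed: int = 0,
) -> PermutationNull:
    """Permutation null for the overlap: P-values are randomly reassigned to
    probes of the universe and the overlap with the fixed B set recomputed.

    empirical_p = (1 + #{k_perm >= k_obs}) / (n_perm + 1) (add-one
    estimator, never exactly zero).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    p = results_a_p.to_numpy()
    if N != p.size:
        raise ValueError("N must equal the universe size of results_a_p")
    b_mask = results_a_p.index.isin(set(set_b))
    n_b = int(b_mask.sum())
    pass_mask = p < threshold if threshold < 1.0 else np.ones_like(p, dtype=bool)
    n_a = int(pass_mask.sum())
    k_obs = int((pass_mask & b_mask).sum())
    overlaps = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        perm = rng.permutation(p)
        hits = perm < threshold if threshold < 1.0 else np.ones_like(p, dtype=bool)
        overlaps[r] = int(np.count_nonzero(hits & b_mask))
    # hypergeometric p per rep, computed once per distinct overlap count
    uniq, inv = np.unique(overlaps, return_inverse=True)
    p_uniq = stats.hypergeom.sf(uniq - 1, N, n_b, n_a) if n_a and n_b else np.ones_like(uniq, float)
    fisher_p = np.asarray(p_uniq)[inv]
    empirical_p = (1.0 + np.count_nonzero(overlaps >= k_obs)) / (n_perm + 1.0)
    return PermutationNull(
        n_perm=n_perm, overlaps=overlaps, fisher_p=fisher_p, k_obs=k_obs,
        empirical_p=float(empirical_p),
        min_fisher_p=float(fisher_p.min()) if n_perm else 1.0, seed=seed,
    )


@dataclass
class ConcordanceReport:
    n: int
    pearson_r: float | None
    n_same_sign: int
    fraction_same_sign: float
    n_larger_in_a: int
    spearman_rho: float | None = None


def effect_concordance(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame, overlap_set,
    full_universe_spearman: bool = False,
) -> ConcordanceReport:
    """Direction and magnitude concordance of effect estimates at the
    overlap sites.

    Sign agreement counts exact-zero estimates as discordant. Pearson r is
    omitted (None) for fewer than 3 overlap sites. With
    ``full_universe_spearman`` the Spearman rho of -log10 P ranks is
    computed across the full common probe universe instead of the overlap.
    """
    a = stats_a.set_index("probe_id") if "probe_id" in stats_a else stats_a
    b = stats_b.set_index("probe_id") if "probe_id" in stats_b else stats_b
    idx = pd.Index(sorted(overlap_set))
    if len(idx) == 0:
        raise ValueError("overlap set is empty")
    ea = a.loc[idx, "estimate"].to_numpy(dtype=float)
    eb = b.loc[idx, "estimate"].to_numpy(dtype=float)
    same = (np.sign(ea) == np.sign(eb)) & (ea != 0) & (eb != 0)
    r = float(stats.pearsonr(ea, eb)[0]) if len(idx) >= 3 else None
    rho = None
    if full_universe_spearman:
        common = a.index.intersection(b.index)
        la = -np.log10(np.clip(a.loc[common, "p"].to_numpy(dtype=float), 1e-300, None))
        lb = -np.log10(np.clip(b.loc[common, "p"].to_numpy(dtype=float), 1e-300, None))
        rho = float(stats.spearmanr(la, lb)[0])
    return ConcordanceReport(
        n=len(idx), pearson_r=r, n_same_sign=int(same.sum()),
        fraction_same_sign=float(same.mean()),
        n_larger_in_a=int((np.abs(ea) > np.abs(eb)).sum()), spearman_rho=rho,
    )


@dataclass
class RegionEnrichment:
    observed: dict          # region -> count
    expected: dict          # region -> expected count
    g_stat: float
    df: int
    p_g: float
    region_p: dict          # region -> two-sided continuity-corrected p


def region_distribution_test(
    overlap_set, annotation: pd.DataFrame, array_props=ARRAY_REGION_PROPS
) -> RegionEnrichment:
    """G-test of the overlap set's CpG-island-context distribution against
    the full-array proportions, plus per-region proportion tests.

    G = 2 sum O_r ln(O_r / E_r) with E_r = n * prop_r (zero observed counts
    contribute 0, the limit convention); df = regions - 1; P from
    chi-square. Per-region tests are two-sided one-sample z-tests with
    Yates continuity correction.
    """
    props = np.asarray(array_props, dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("array_props must sum to 1")
    ann = annotation.set_index("probe_id")
    idx = pd.Index(sorted(set(overlap_set)))
    regions = ann.loc[idx, "region"]
    n = len(idx)
    observed = {r: int((regions == r).sum()) for r in REGIONS}
    expected = {r: n * p for r, p in zip(REGIONS, props)}
    if any(e == 0 and observed[r] > 0 for r, e in expected.items()):
        raise ValueError("observed count in a region with zero expectation")
    g = 0.0
    for r in REGIONS:
        if observed[r] > 0:
            g += observed[r] * np.log(observed[r] / expected[r])
    g *= 2.0
    df = len(REGIONS) - 1
    p_g = float(stats.chi2.sf(g, df))
    region_p = {}
    for r, p0 in zip(REGIONS, props):
        phat = observed[r] / n
        num = max(abs(phat - p0) - 1.0 / (2 * n), 0.0)
        z = num / np.sqrt(p0 * (1 - p0) / n)
        region_p[r] = float(2.0 * stats.norm.sf(z))
    return RegionEnrichment(
        observed=observed, expected=expected, g_stat=float(g), df=df, p_g=p_g, region_p=region_p
    )


def stratified_enrichment(
    results_by_stratum: dict, set_b, N_by_stratum: dict | None = None,
    threshold: float = P_CUTOFF,
) -> dict:
    """Per-stratum enrichment: each stratum brings its own EWAS P-values
    (Series over its universe); the B set is intersected with each universe.

    A stratum with no passing probes yields a valid result with n_a = 0 and
    p_fisher = 1.
    """
    out = {}
    for name, p_series in results_by_stratum.items():
        N = N_by_stratum[name] if N_by_stratum else len(p_series)
        b_here = set(set_b) & set(p_series.index)
        out[name] = overlap_enrichment(
            _passing(p_series, threshold), b_here, N,
            threshold_a=threshold, threshold_b=None,
        )
    return out
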