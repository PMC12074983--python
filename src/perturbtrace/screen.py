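"""Per-perturbation phenotype aggregation and hit calling.

Each sgRNA's traces are compared against the pooled non-targeting control
traces across five chromatin phenotypes — adjacent-TAD distance, long-range
A-A / A-B / B-B contact frequency and overall inter-TAD distance — plus the
nuclear features computed elsewhere. Distance phenotypes use a two-sided
Wilcoxon signed-rank test paired by TAD pair; contact phenotypes a two-sided
Wilcoxon rank-sum test over per-trace frequencies; FDR is Benjamini-Hochberg
per phenotype across perturbations. Correlation analyses relate the 27x27
log2 fold-change matrices to each other and to the A/B compartment score
matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .traces import (
    CompartmentProfile,
    batch_adjacent_distances,
    batch_contact_frequencies,
    batch_pair_distances,
    condensed_pair_indices,
    warnings_ignore,
)

#: Default hit-calling thresholds.
FDR_THRESHOLD = 0.1
EFFECT_FLOOR = 0.05          # our floor, not printed by the study design
MIN_TRACES = 20
MIN_PAIR_TRACES = 5          # pair must be observed in >= this many traces per group
SHORT_RANGE_CUTOFF_BP = 3_000_000
CONTACT_PSEUDOCOUNT = 1e-3

#: Screen design bookkeeping: traced TADs plus cellular stains imaged per cell.
N_TADS = 27
N_CELLULAR_TARGETS = 3


def screen_design_summary(n_sgrnas: int = 420,
                          n_imaging_targets: int = N_TADS + N_CELLULAR_TARGETS) -> dict:
    """Imaging target x perturbation bookkeeping for the screen design
    (the default 420-sgRNA, 30-target design gives 12,600 combinations)."""
    return {
        "n_sgrnas": n_sgrnas,
        "n_imaging_targets": n_imaging_targets,
        "n_combinations": n_sgrnas * n_imaging_targets,
    }


# ---------------------------------------------------------------------------
# log2fc distance matrices
# ---------------------------------------------------------------------------

def _median_pair_distances(pair_d: np.ndarray, min_traces_per_pair: int):
    with warnings_ignore():
        med = np.nanmedian(pair_d, axis=0)
    n_obs = (~np.isnan(pair_d)).sum(axis=0)
    med[n_obs < min_traces_per_pair] = np.nan
    return med


def log2fc_distance_matrix(perturb_traces: np.ndarray, control_traces: np.ndarray,
                           min_traces: int = MIN_TRACES,
                           min_pair_traces: int = MIN_PAIR_TRACES) -> np.ndarray:
    """n_tad x n_tad matrix of log2(median pair distance, perturbation /
    control); entries observed in too few traces in either group are NaN,
    and the diagonal is undefined."""
    p = batch_pair_distances(perturb_traces)
    c = batch_pair_distances(control_traces)
    if len(p) < min_traces:
        raise ValueError(f"perturbation group has {len(p)} traces, need >= {min_traces}")
    fc = condensed_log2fc(p, c, min_pair_traces)
    n_tad = perturb_traces.shape[1]
    mat = np.full((n_tad, n_tad), np.nan)
    i, j = condensed_pair_indices(n_tad)
    mat[i, j] = fc
    mat[j, i] = fc
    return mat


def condensed_log2fc(perturb_pair_d: np.ndarray, control_pair_d: np.ndarray,
                     min_pair_traces: int = MIN_PAIR_TRACES) -> np.ndarray:
    mp = _median_pair_distances(perturb_pair_d, min_pair_traces)
    mc = _median_pair_distances(control_pair_d, min_pair_traces)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(mp / mc)


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    log2fc: float
    p: float
    n: int

    @property
    def insufficient_data(self) -> bool:
        return math.isnan(self.p)


def distance_test(perturb_pair_d: np.ndarray, control_pair_d: np.ndarray,
                  pair_mask: np.ndarray | None = None,
                  min_pairs: int = 6,
                  min_pair_traces: int = MIN_PAIR_TRACES) -> TestResult:
    """Two-sided Wilcoxon signed-rank test pairing the per-TAD-pair median
    distances of the perturbation against the control over ``pair_mask``
    (all pairs by default); log2fc is the mean per-pair log2 fold change."""
    mp = _median_pair_distances(perturb_pair_d, min_pair_traces)
    mc = _median_pair_distances(control_pair_d, min_pair_traces)
    if pair_mask is not None:
        mp, mc = mp[pair_mask], mc[pair_mask]
    ok = ~(np.isnan(mp) | np.isnan(mc))
    mp, mc = mp[ok], mc[ok]
    if len(mp) < min_pairs:
        return TestResult(float("nan"), float("nan"), int(len(mp)))
    log2fc = float(np.mean(np.log2(mp / mc)))
    diffs = mp - mc
    if np.allclose(diffs, 0):
        return TestResult(0.0, 1.0, int(len(mp)))
    p = stats.wilcoxon(mp, mc, alternative="two-sided", zero_method="wilcox").pvalue
    return TestResult(log2fc, float(p), int(len(mp)))


def contact_test(perturb_freqs: np.ndarray, control_freqs: np.ndarray,
                 min_traces: int = MIN_TRACES,
                 pseudocount: float = CONTACT_PSEUDOCOUNT) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test comparing per-trace
    contact frequencies; log2fc of group means with a pseudocount guarding
    zero means."""
    p_vals = np.asarray(perturb_freqs, dtype=float)
    c_vals = np.asarray(control_freqs, dtype=float)
    p_vals = p_vals[~np.isnan(p_vals)]
    c_vals = c_vals[~np.isnan(c_vals)]
    if len(p_vals) < min_traces or len(c_vals) < min_traces:
        return TestResult(float("nan"), float("nan"), int(len(p_vals)))
    log2fc = float(np.log2((p_vals.mean() + pseudocount) / (c_vals.mean() + pseudocount)))
    p = stats.mannwhitneyu(p_vals, c_vals, alternative="two-sided").pvalue
    return TestResult(log2fc, float(p), int(len(p_vals)))


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up over the non-missing p values; NaN
    entries stay NaN. Output satisfies FDR >= p elementwise."""
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def z_score(perturb_values: np.ndarray, control_values: np.ndarray) -> float:
    """(perturbation mean - control mean) / control SD of a per-trace or
    per-cell summary."""
    p = np.asarray(perturb_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    p, c = p[~np.isnan(p)], c[~np.isnan(c)]
    sd = c.std(ddof=1)
    if len(p) == 0 or len(c) < 2 or sd == 0:
        return float("nan")
    return float((p.mean() - c.mean()) / sd)


# ---------------------------------------------------------------------------
# Phenotype table and hit calling
# ---------------------------------------------------------------------------

CHROMATIN_PHENOTYPES = ("adjacent_tad", "freq_AA", "freq_AB", "freq_BB", "overall_distance")


def phenotype_table(traces_by_sgrna: dict, control_sgrnas,
                    profile: CompartmentProfile,
                    min_traces: int = MIN_TRACES) -> pd.DataFrame:
    """Multi-scale chromatin phenotype summary per sgRNA.

    ``traces_by_sgrna`` maps sgRNA id -> (m, n_tad, 3) trace stack (already
    QC-filtered); all traces of ``control_sgrnas`` are pooled as the
    reference. Returns one row per (sgRNA, phenotype) with log2fc, p, FDR
    (BH per phenotype across perturbations) and z.
    """
    control_sgrnas = [sg for sg in control_sgrnas if sg in traces_by_sgrna]
    if not control_sgrnas:
        raise ValueError("no control sgRNAs present in the trace groups")
    ctrl = np.concatenate([traces_by_sgrna[sg] for sg in control_sgrnas], axis=0)
    ctrl_pair_d = batch_pair_distances(ctrl)
    ctrl_freqs = batch_contact_frequencies(ctrl_pair_d, profile)
    with warnings_ignore():
        ctrl_adj = np.nanmean(batch_adjacent_distances(ctrl), axis=1)
        ctrl_all = np.nanmean(ctrl_pair_d, axis=1)

    i, j = condensed_pair_indices(profile.n_tad)
    adjacent_mask = (j - i) == 1

    rows = []
    for sg in sorted(traces_by_sgrna):
        grp = traces_by_sgrna[sg]
        is_ctrl = sg in control_sgrnas
        n = len(grp)
        if n < min_traces:
            for ph in CHROMATIN_PHENOTYPES:
                rows.append((sg, ph, n, np.nan, np.nan, np.nan, is_ctrl))
            continue
        pair_d = batch_pair_distances(grp)
        freqs = batch_contact_frequencies(pair_d, profile)
        with warnings_ignore():
            adj = np.nanmean(batch_adjacent_distances(grp), axis=1)
            overall = np.nanmean(pair_d, axis=1)

        res_adj = distance_test(pair_d, ctrl_pair_d, pair_mask=adjacent_mask)
        rows.append((sg, "adjacent_tad", n, res_adj.log2fc, res_adj.p,
                     z_score(adj, ctrl_adj), is_ctrl))
        for name in ("freq_AA", "freq_AB", "freq_BB"):
            res = contact_test(freqs[name], ctrl_freqs[name], min_traces=min_traces)
            rows.append((sg, name, n, res.log2fc, res.p,
                         z_score(freqs[name], ctrl_freqs[name]), is_ctrl))
        res_all = distance_test(pair_d, ctrl_pair_d)
        rows.append((sg, "overall_distance", n, res_all.log2fc, res_all.p,
                     z_score(overall, ctrl_all), is_ctrl))

    table = pd.DataFrame(
        rows, columns=["sgrna", "phenotype", "n_traces", "log2fc", "p", "z", "is_control"]
    )
    table["fdr"] = np.nan
    for ph, idx in table.groupby("phenotype").groups.items():
        table.loc[idx, "fdr"] = fdr_correct(table.loc[idx, "p"].to_numpy())
    return table


def call_hits(table: pd.DataFrame, fdr_threshold: float = FDR_THRESHOLD,
              effect_floor: float = EFFECT_FLOOR,
              top_k: int | None = None) -> pd.DataFrame:
    """Rank perturbations passing FDR and effect-size criteria per
    phenotype and direction; non-targeting controls are never listed."""
    ok = (
        (table["fdr"] < fdr_threshold)
        & (table["log2fc"].abs() >= effect_floor)
        & ~table["is_control"]
        & table["fdr"].notna()
    )
    hits = table[ok].copy()
    hits["direction"] = np.where(hits["log2fc"] > 0, "up", "down")
    hits = hits.sort_values(
        ["phenotype", "direction", "log2fc"],
        key=lambda s: s.abs() if s.name == "log2fc" else s,
        ascending=[True, True, False],
    )
    if top_k is not None:
        hits = hits.groupby(["phenotype", "direction"], group_keys=False).head(top_k)
    return hits.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Correlation analyses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci_low: float
    ci_high: float
    n_points: int
    fdr: float = float("nan")


def _pearson_with_ci(x: np.ndarray, y: np.ndarray, min_points: int = 10) -> CorrelationResult:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < min_points:
        return CorrelationResult(float("nan"), float("nan"), float("nan"), float("nan"), n)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    # Fisher-z 95% interval
    if abs(r) >= 1.0 or n <= 3:
        lo, hi = r, r
    else:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - 1.959963984540054 * se), math.tanh(z + 1.959963984540054 * se)
    return CorrelationResult(r, p, lo, hi, n)


def correlate_effect_matrices(m1: np.ndarray, m2: np.ndarray,
                              min_points: int = 10) -> CorrelationResult:
    """Pearson correlation over the paired non-missing upper-triangle
    entries of two symmetric effect matrices (351 points for the chr22
    design); two-sided t-test p and a Fisher-z 95% CI."""
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    if m1.shape != m2.shape:
        raise ValueError("matrices must share shape")
    i, j = condensed_pair_indices(m1.shape[0])
    return _pearson_with_ci(m1[i, j], m2[i, j], min_points)


def ab_score_matrix(profile: CompartmentProfile) -> np.ndarray:
    """Average A/B compartment score of every TAD pair: (s_i + s_j)/2."""
    s = profile.scores
    return (s[:, None] + s[None, :]) / 2.0


def short_long_range_split(log2fc_matrix: np.ndarray, profile: CompartmentProfile,
                           cutoff_bp: int = SHORT_RANGE_CUTOFF_BP) -> dict:
    """Mean log2fc over short-range (< cutoff genomic midpoint separation)
    and long-range (>= cutoff) TAD pairs; NaN for an empty class."""
    mat = np.asarray(log2fc_matrix, float)
    i, j = condensed_pair_indices(mat.shape[0])
    sep = np.abs(profile.midpoints_bp[j] - profile.midpoints_bp[i])
    vals = mat[i, j]
    out = {}
    for name, mask in (("short_range", sep < cutoff_bp), ("long_range", sep >= cutoff_bp)):
        v = vals[mask & ~np.isnan(vals)]
        out[name] = float(v.mean()) if v.size else float("nan")
    return out


def cluster_hits(matrices: dict) -> dict:
    """Hierarchical clustering of hits by the similarity of their log2fc
    distance matrices: pairwise Pearson r between vectorized upper
    triangles, distance 1 - r, average linkage, deterministic leaf order
    (inputs sorted by sgRNA id; zero-variance matrices excluded with a
    warning).

    Returns {"sgrnas", "corr", "linkage", "order", "newick"}.
    """
    names = sorted(matrices)
    vecs = {}
    for name in names:
        m = np.asarray(matrices[name], float)
        i, j = condensed_pair_indices(m.shape[0])
        v = m[i, j]
        if np.nanstd(v) == 0 or np.isnan(v).all():
            warnings.warn(f"excluding constant log2fc matrix for {name}", stacklevel=2)
            continue
        vecs[name] = v
    names = list(vecs)
    k = len(names)
    if k < 3:
        raise ValueError("need >= 3 usable hits to cluster")
    corr = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            corr[a, b] = corr[b, a] = _pearson_with_ci(vecs[names[a]], vecs[names[b]]).r
    dist = 1.0 - corr
    condensed = dist[np.triu_indices(k, 1)]
    link = hierarchy.average(condensed)
    order = list(hierarchy.leaves_list(link))
    tree = hierarchy.to_tree(link)

    def _newick(node):
        if node.is_leaf():
            return names[node.id]
        return f"({_newick(node.left)}:{node.dist / 2:.6g},{_newick(node.right)}:{node.dist / 2:.6g})"

    return {
        "sgrnas": names,
        "corr": corr,
        "linkage": link,
        "order": order,
        "newick": _newick(tree) + ";",
    }


def cross_feature_correlation(feature_table: pd.DataFrame,
                              min_points: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations between per-hit feature log2fc vectors
    (rows = hits, columns = features), pairwise-complete, with two-sided
    t-test p and BH FDR across feature pairs."""
    feats = list(feature_table.columns)
    if len(feature_table) < 3:
        raise ValueError("need >= 3 hits")
    rows = []
    for a in range(len(feats)):
        for b in range(a + 1, len(feats)):
            x = feature_table[feats[a]].to_numpy(float)
            y = feature_table[feats[b]].to_numpy(float)
            res = _pearson_with_ci(x, y, min_points=min_points)
            rows.append((feats[a], feats[b], res.r, res.p, res.n_points))
    out = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p", "n_points"])
    out["fdr"] = fdr_correct(out["p"].to_numpy())
    return out
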