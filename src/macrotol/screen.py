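"""Multivariate per-variant association screen on line-level survival.

The screen tests each biallelic variant of an inbred panel against the
vector of per-diet survival proportions: a MANOVA (Pillai's trace, with
Wolbachia infection status as an additive covariate) on the multivariate
response, two-sided Wilcoxon rank-sum tests per diet, and median
phenotype differences (alternate minus reference lines) as effect sizes.
A variant is selected when the MANOVA p-value, at least one per-diet
Wilcoxon p-value, and the median difference on that same diet all pass
their thresholds — by default the relaxed pre-screen cut-offs
(MANOVA p < 1e-5, Wilcoxon p < 0.01, |median difference| >= 0.3 on raw
proportions or 0.2 on reference-diet-normalized ones).  P-values are
deliberately unadjusted (the screen feeds a functional-validation stage);
a Benjamini-Hochberg column is emitted for information only.

Phenotypes are aggregated from vial counts as the unweighted mean of
per-vial proportions per line x diet, which equals pooled counts under
equal seeding.  Normalization subtracts each line's reference-diet value
and drops the reference column.  Variant filtering keeps a variant only
when at least ``min_per_group`` (default 5) phenotyped lines carry each
allele among non-missing calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import GenotypeMatrix

__all__ = [
    "LinePhenotypeMatrix",
    "ScreenThresholds",
    "aggregate_line_phenotypes",
    "normalize_phenotypes",
    "filter_variants",
    "manova_test",
    "pillai_trace_p",
    "ranksum_p",
    "wilcoxon_per_diet",
    "effect_sizes",
    "screen_variants",
]

_log = logging.getLogger(__name__)


@dataclass
class LinePhenotypeMatrix:
    """Line x diet survival proportions, raw or reference-normalized."""

    table: pd.DataFrame  # index: line id, columns: diet labels
    stage: str  # "pupation" | "eclosion"
    reference_diet: str
    normalized: bool = False

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        lo, hi = (-1.0, 1.0) if self.normalized else (0.0, 1.0)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < lo - 1e-9 or np.nanmax(vals) > hi + 1e-9:
                raise ValueError(
                    f"phenotype values outside [{lo}, {hi}] for "
                    f"normalized={self.normalized}"
                )
        if self.normalized and self.reference_diet in self.table.columns:
            raise ValueError("normalized matrix must not contain the reference diet")

    @property
    def diets(self) -> list[str]:
        return list(self.table.columns)

    @property
    def lines(self) -> list[str]:
        return list(self.table.index)


def aggregate_line_phenotypes(
    panel: pd.DataFrame,
    stage: str = "pupation",
    eclosion_denominator: str = "seeded",
) -> LinePhenotypeMatrix:
    """Aggregate vial counts to line x diet survival proportions.

    The per-cell value is the unweighted mean of vial proportions
    (pupated/seeded, or for eclosion either eclosed/seeded — the default,
    survival to adult — or eclosed/pupated).  Missing line x diet cells
    stay missing (NaN); they are never imputed.
    """
    if stage not in ("pupation", "eclosion"):
        raise ValueError("stage must be 'pupation' or 'eclosion'")
    df = panel.copy()
    if stage == "pupation":
        prop = df["n_pupated"] / df["n_seeded"]
    elif eclosion_denominator == "seeded":
        prop = df["n_eclosed"] / df["n_seeded"]
    elif eclosion_denominator == "pupae":
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(df["n_pupated"] > 0, df["n_eclosed"] / df["n_pupated"], np.nan)
    else:
        raise ValueError("eclosion_denominator must be 'seeded' or 'pupae'")
    df = df.assign(_prop=prop)
    diets = list(dict.fromkeys(df["diet"]))
    table = (
        df.groupby(["strain", "diet"], sort=False)["_prop"]
        .mean()
        .unstack("diet")
        .reindex(columns=diets)
    )
    table.index.name = "line"
    return LinePhenotypeMatrix(table, stage=stage, reference_diet=diets[0])


def normalize_phenotypes(m: LinePhenotypeMatrix) -> LinePhenotypeMatrix:
    """Subtract each line's reference-diet value; drop the reference column."""
    if m.normalized:
        raise ValueError("matrix is already normalized")
    if m.reference_diet not in m.table.columns:
        raise ValueError(f"reference diet {m.reference_diet!r} absent from matrix")
    ref = m.table[m.reference_diet]
    table = m.table.drop(columns=[m.reference_diet]).sub(ref, axis=0)
    return LinePhenotypeMatrix(
        table, stage=m.stage, reference_diet=m.reference_diet, normalized=True
    )


def filter_variants(
    g: GenotypeMatrix,
    phenotyped_lines: Sequence[str],
    min_per_group: int = 5,
) -> GenotypeMatrix:
    """Restrict to phenotyped lines and variants with enough lines per allele.

    A variant is kept iff, among non-missing calls of phenotyped lines, at
    least ``min_per_group`` lines carry the reference allele and at least
    ``min_per_group`` carry the alternate.  Variant order is preserved.
    """
    common = [l for l in g.lines if l in set(phenotyped_lines)]
    if not common:
        raise ValueError("no lines in common between genotypes and phenotypes")
    sub = g.subset(lines=common)
    n_ref = (sub.calls == 0).sum(axis=1)
    n_alt = (sub.calls == 1).sum(axis=1)
    keep = (n_ref >= min_per_group) & (n_alt >= min_per_group)
    return sub.subset(variant_mask=keep)


def pillai_trace_p(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    statistic: str = "pillai",
) -> float:
    """MANOVA p-value for the terms in X_full beyond X_reduced.

    Standard multivariate linear model machinery: hypothesis and error
    SSCP matrices from the two nested fits, then either Pillai's trace
    (default; most robust) or Wilks' lambda with the Rao F approximation.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    r_full = np.linalg.matrix_rank(X_full)
    r_red = np.linalg.matrix_rank(X_reduced)
    q = r_full - r_red
    df_e = n - r_full
    if q < 1:
        raise ValueError("hypothesis design adds no rank beyond the reduced design")
    if df_e < m:
        raise ValueError(
            f"rank deficiency: {n} observations cannot support a {m}-variate "
            f"response with {r_full} model terms"
        )

    def _resid_sscp(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        return R.T @ R

    E = _resid_sscp(X_full)
    H = _resid_sscp(X_reduced) - E
    s = min(q, m)
    if statistic == "pillai":
        V = float(np.trace(H @ np.linalg.inv(H + E)))
        mm = (abs(q - m) - 1) / 2.0
        nn = (df_e - m - 1) / 2.0
        df1 = s * (2 * mm + s + 1)
        df2 = s * (2 * nn + s + 1)
        V = min(max(V, 0.0), s - 1e-12)
        F = (df2 / df1) * V / (s - V)
        return float(stats.f.sf(F, df1, df2))
    if statistic == "wilks":
        lam = float(np.linalg.det(E) / np.linalg.det(H + E))
        r = df_e - (m - q + 1) / 2.0
        u = (m * q - 2) / 4.0
        t = (
            math.sqrt((m**2 * q**2 - 4) / (m**2 + q**2 - 5))
            if m**2 + q**2 - 5 > 0
            else 1.0
        )
        df1 = m * q
        df2 = r * t - 2 * u
        lam_t = lam ** (1.0 / t)
        F = (1 - lam_t) / lam_t * df2 / df1
        return float(stats.f.sf(F, df1, df2))
    raise ValueError(f"unknown MANOVA statistic {statistic!r}")


def manova_test(
    phenos: LinePhenotypeMatrix,
    genotype: pd.Series,
    wolbachia: pd.Series | None = None,
    statistic: str = "pillai",
) -> float:
    """MANOVA p-value for genotype on the per-diet phenotype vector.

    ``genotype`` holds 0 (reference) / 1 (alternate) calls by line id;
    lines with missing calls or any missing phenotype cell are excluded
    (complete-case).  Wolbachia status enters additively as a binary
    covariate, never interacting with genotype; a constant covariate is
    dropped with a log notice.
    """
    geno = genotype.reindex(phenos.lines)
    mask = geno.isin([0, 1]) & phenos.table.notna().all(axis=1)
    if wolbachia is not None:
        wolb = wolbachia.reindex(phenos.lines)
        mask &= wolb.notna()
    Y = phenos.table.loc[mask].to_numpy(dtype=float)
    gv = geno.loc[mask].to_numpy(dtype=float)
    n = len(gv)
    groups = np.unique(gv)
    if len(groups) < 2:
        raise ValueError("genotype vector is constant among complete-case lines")
    if min((gv == g).sum() for g in groups) < 2:
        raise ValueError("each allele group needs at least 2 lines")
    cols = [np.ones(n), gv]
    red_cols = [np.ones(n)]
    if wolbachia is not None:
        wv = wolb.loc[mask].to_numpy(dtype=float)
        if np.ptp(wv) > 0:
            cols.append(wv)
            red_cols.append(wv)
        else:
            _log.debug("constant Wolbachia covariate dropped from MANOVA design")
    X_full = np.column_stack(cols)
    X_red = np.column_stack(red_cols)
    return pillai_trace_p(Y, X_full, X_red, statistic=statistic)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _exact_ranksum_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration of group assignments.

    Ties are handled with midranks; the distribution of the rank sum over
    all C(N, n1) equally-likely assignments is built by subset-sum dynamic
    programming over doubled midranks (integers), and the two-sided
    p-value sums assignments at least as far from the null mean as the
    observed rank sum.
    """
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(int)
    n1, N = len(x), len(pooled)
    total = int(ranks2.sum())
    # dp[j, s] = number of ways to pick j observations with doubled-rank sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for j in range(min(n1, N) - 1, -1, -1):
            dp[j + 1, r:] += dp[j, : total + 1 - r]
    counts = dp[n1]
    sums = np.arange(total + 1)
    mu = n1 * ranks2.mean()
    obs = float(ranks2[:n1].sum())
    extreme = np.abs(sums - mu) >= abs(obs - mu) - 1e-9
    return float(counts[extreme].sum() / math.comb(N, n1))


def ranksum_p(x, y, method: str = "auto", exact_max_n: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    ``method`` is "exact" (enumeration, tie-aware), "approx"
    (tie-corrected, continuity-corrected normal approximation), or "auto"
    (exact when the combined sample size is <= ``exact_max_n``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if len(x) + len(y) <= exact_max_n else "approx"
    if method == "exact":
        return _exact_ranksum_two_sided(x, y)
    if method == "approx":
        return float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    raise ValueError(f"unknown method {method!r}")


def _split_groups(phenos: LinePhenotypeMatrix, genotype: pd.Series, diet: str):
    geno = genotype.reindex(phenos.lines)
    col = phenos.table[diet]
    mask = geno.isin([0, 1]) & col.notna()
    vals = col[mask]
    gv = geno[mask]
    return vals[gv == 1].to_numpy(), vals[gv == 0].to_numpy()  # alt, ref


def wilcoxon_per_diet(
    phenos: LinePhenotypeMatrix, genotype: pd.Series, exact_max_n: int = 20
) -> pd.Series:
    """Two-sided rank-sum p per diet (alt vs ref lines); NaN for empty groups."""
    out = {}
    for diet in phenos.diets:
        alt, ref = _split_groups(phenos, genotype, diet)
        out[diet] = (
            ranksum_p(alt, ref, method="auto", exact_max_n=exact_max_n)
            if len(alt) and len(ref)
            else np.nan
        )
    return pd.Series(out, name="wilcoxon_p")


def effect_sizes(phenos: LinePhenotypeMatrix, genotype: pd.Series) -> pd.Series:
    """Median difference in phenotype, alternate minus reference, per diet."""
    out = {}
    for diet in phenos.diets:
        alt, ref = _split_groups(phenos, genotype, diet)
        out[diet] = (
            float(np.median(alt) - np.median(ref)) if len(alt) and len(ref) else np.nan
        )
    return pd.Series(out, name="median_difference")


@dataclass(frozen=True)
class ScreenThresholds:
    """Selection cut-offs for the variant screen (defaults: the relaxed
    pre-validation cut-offs; effect threshold depends on normalization)."""

    manova_p: float = 1e-5
    wilcoxon_p: float = 0.01
    effect_raw: float = 0.3
    effect_normalized: float = 0.2

    def effect(self, normalized: bool) -> float:
        return self.effect_normalized if normalized else self.effect_raw


def screen_variants(
    g: GenotypeMatrix,
    phenos: LinePhenotypeMatrix,
    thresholds: ScreenThresholds | None = None,
) -> pd.DataFrame:
    """Run the full per-variant screen on a (filtered) genotype matrix.

    Returns one row per variant: MANOVA p, per-diet Wilcoxon p and median
    differences, allele-group sizes, BH-adjusted MANOVA p (informational),
    selection flag and per-diet selection reasons.  Per-variant test
    failures (e.g. a variant monomorphic among complete-case lines) are
    flagged in the ``error`` column, never aborting the screen.
    """
    thr = thresholds or ScreenThresholds()
    eff_thr = thr.effect(phenos.normalized)
    rows = []
    lines = pd.Index(phenos.lines)
    for i in range(g.n_variants):
        calls = pd.Series(g.calls[i], index=g.lines).replace(-1, np.nan)
        calls = calls.reindex(lines)
        rec: dict = {"variant_id": g.variants["id"].iloc[i]}
        rec["n_ref_lines"] = int((calls == 0).sum())
        rec["n_alt_lines"] = int((calls == 1).sum())
        try:
            rec["manova_p"] = manova_test(phenos, calls, g.wolbachia)
            rec["error"] = ""
        except (ValueError, np.linalg.LinAlgError) as exc:
            rec["manova_p"] = np.nan
            rec["error"] = str(exc)
        wilc = wilcoxon_per_diet(phenos, calls)
        eff = effect_sizes(phenos, calls)
        reasons = []
        for diet in phenos.diets:
            rec[f"wilcoxon_p[{diet}]"] = wilc[diet]
            rec[f"median_difference[{diet}]"] = eff[diet]
            hit = (
                np.isfinite(wilc[diet])
                and np.isfinite(eff[diet])
                and wilc[diet] < thr.wilcoxon_p
                and abs(eff[diet]) >= eff_thr
            )
            rec[f"diet_hit[{diet}]"] = bool(hit)
            if hit:
                reasons.append(diet)
        rec["selected"] = bool(
            np.isfinite(rec["manova_p"])
            and rec["manova_p"] < thr.manova_p
            and reasons
        )
        rec["selection_reasons"] = ",".join(reasons) if rec["selected"] else ""
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out):
        ok = out["manova_p"].notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(out.loc[ok, "manova_p"], method="fdr_bh")[1]
        out["manova_p_bh"] = adj
    return out
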