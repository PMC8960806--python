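"""Synthetic inbred-panel data generators.

Every downstream stage of the package (GxE mixed models, the variant
screen, pupation kinetics, calorimetry standardization) can be exercised
end to end on data produced here, with known ground truth.

The survival generator emulates a reference-panel diet screen: inbred
strains reared on a set of diets in replicate vials at controlled larval
density.  Vial-level pupation counts are binomial with a logit-scale
linear predictor composed of a fixed per-diet effect plus a strain-level
multivariate-normal random effect (intercept + one slope per
non-reference diet), i.e. exactly the generative structure assumed by the
random-slopes GLMM that tests for genotype-by-environment interaction.
Eclosion is a binomial thinning of pupation with a per-strain eclosion
probability, which guarantees eclosed <= pupated <= seeded in every vial.

The genotype generator produces biallelic variant-by-line calls with a
configurable minor-line-count distribution, per-line Wolbachia status,
and optional planted causal variants whose alternate-allele lines have
their diet-specific survival shifted on the proportion scale (clipped to
[0.01, 0.99]) — the scale on which the screen's effect-size filter
operates.

All generators are pure functions of their configuration including the
seed.  A single global seed is expanded into independent per-component
substreams via ``numpy.random.SeedSequence`` spawn keys, so adding a new
generator never perturbs existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimulationConfig",
    "CausalVariant",
    "GenotypeMatrix",
    "simulate_survival_panel",
    "simulate_genotypes",
    "causal_line_effects",
    "simulate_panel_with_genotypes",
    "simulate_pupation_timecourse",
    "simulate_respirometry",
    "DEFAULT_DIETS",
    "DEFAULT_DIET_EFFECTS",
]

# Stream ids for per-component seed substreams (counter-based: never reuse,
# never renumber).
_STREAM_SURVIVAL = 0
_STREAM_GENOTYPES = 1
_STREAM_PUPATION = 2
_STREAM_RESPIROMETRY = 3

#: The six screen diets; the high-protein base diet comes first and acts as
#: the reference diet everywhere.
DEFAULT_DIETS = ("HPD", "HSD", "HFDcoco", "HFDlard", "WD", "HStD")

#: Baseline log-odds of pupation per diet.  Chosen to put mean survival
#: near the values a diet screen of this design reports: ~0.90 on the
#: protein and starch diets, ~0.76 on high sugar, ~0.67 on coconut oil.
DEFAULT_DIET_EFFECTS = {
    "HPD": 2.2,
    "HSD": 1.15,
    "HFDcoco": 0.71,
    "HFDlard": 2.0,
    "WD": 1.4,
    "HStD": 2.2,
}

# Among-strain variances on the logit scale: intercept first, then one
# slope per non-reference diet in DEFAULT_DIETS order.  Larger slope
# variance on the sugar and coconut-oil diets mirrors where inbred panels
# show the most genetic variation in tolerance.
_DEFAULT_RE_VARIANCES = (0.6, 0.8, 0.8, 0.2, 0.4, 0.2)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class CausalVariant:
    """A planted causal variant.

    ``shifts`` maps diet label -> additive shift of the pupation
    proportion of alternate-allele lines on that diet.  ``n_alt_lines``
    optionally pins the number of alternate lines (otherwise drawn from
    the configured minor-line-count distribution).
    """

    index: int
    shifts: Mapping[str, float]
    n_alt_lines: int | None = None


@dataclass
class SimulationConfig:
    """Design of a synthetic diet-screen experiment.

    Defaults reproduce the panel design the package targets: 196 strains,
    six diets with the high-protein diet as reference, 4 replicate vials
    of 30 larvae per strain x diet.
    """

    n_strains: int = 196
    diets: Sequence[str] = DEFAULT_DIETS
    n_vials_per_diet: int = 4
    n_larvae_per_vial: int = 30
    fixed_diet_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIET_EFFECTS)
    )
    random_effect_covariance: np.ndarray | None = None
    eclosion_beta: tuple[float, float] = (27.0, 3.0)
    n_variants: int = 500
    minor_line_count_distribution: int | tuple[int, int] | Callable = None  # type: ignore[assignment]
    missing_call_rate: float = 0.02
    causal_variants: Sequence[CausalVariant] = ()
    wolbachia_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if len(self.diets) < 1:
            raise ValueError("at least one diet required")
        if len(set(self.diets)) != len(self.diets):
            raise ValueError("diet labels must be unique")
        if not 0.0 <= self.wolbachia_prevalence <= 1.0:
            raise ValueError("wolbachia_prevalence must be in [0, 1]")
        k = len(self.diets)
        if self.random_effect_covariance is None:
            var = np.asarray(_DEFAULT_RE_VARIANCES[:k], dtype=float)
            if var.size < k:  # more diets than defaults cover
                var = np.concatenate([var, np.full(k - var.size, 0.3)])
            self.random_effect_covariance = np.diag(var)
        cov = np.asarray(self.random_effect_covariance, dtype=float)
        if cov.shape != (k, k):
            raise ValueError(
                f"random_effect_covariance must be {k}x{k} "
                "(intercept + one slope per non-reference diet)"
            )
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("random_effect_covariance must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-8:
            raise ValueError(
                "random_effect_covariance is not positive semi-definite "
                f"(smallest eigenvalue {eig.min():.3g})"
            )
        self.random_effect_covariance = cov
        missing = [d for d in self.diets if d not in self.fixed_diet_effects]
        if missing:
            raise ValueError(f"fixed_diet_effects missing diets: {missing}")
        if self.minor_line_count_distribution is None:
            self.minor_line_count_distribution = (1, self.n_strains // 2)
        for cv in self.causal_variants:
            if not 0 <= cv.index < self.n_variants:
                raise ValueError(
                    f"causal variant index {cv.index} out of range "
                    f"[0, {self.n_variants})"
                )
        if len(self.causal_variants) > self.n_variants:
            raise ValueError("more causal variants than variants")

    @property
    def reference_diet(self) -> str:
        return self.diets[0]

    @property
    def strain_ids(self) -> list[str]:
        return [f"line_{i + 1:03d}" for i in range(self.n_strains)]


def _strain_random_effects(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    cov = config.random_effect_covariance
    k = cov.shape[0]
    # eigen-based sampling tolerates PSD (singular) covariances
    vals, vecs = np.linalg.eigh(cov)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((config.n_strains, k))
    return z @ root.T


def simulate_survival_panel(
    config: SimulationConfig,
    line_effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate a vial-level survival panel table.

    Returns one row per strain x diet x vial with columns
    ``strain, diet, vial, n_seeded, n_pupated, n_eclosed``.

    ``line_effects`` (strains x diets, proportion scale) optionally shifts
    each strain's expected pupation proportion, e.g. the output of
    :func:`causal_line_effects` for planted variants.  Shifted
    proportions are clipped to [0.01, 0.99].
    """
    rng = _rng(config.seed, _STREAM_SURVIVAL)
    strains = config.strain_ids
    diets = list(config.diets)
    u = _strain_random_effects(config, rng)  # (S, k): intercept + slopes
    ecl_a, ecl_b = config.eclosion_beta
    p_ecl = rng.beta(ecl_a, ecl_b, size=config.n_strains)

    eta = np.empty((config.n_strains, len(diets)))
    for j, d in enumerate(diets):
        eta[:, j] = config.fixed_diet_effects[d] + u[:, 0]
        if j > 0:
            eta[:, j] += u[:, j]
    p = expit(eta)
    if line_effects is not None:
        shift = line_effects.reindex(index=strains, columns=diets).fillna(0.0).to_numpy()
        p = np.clip(p + shift, 0.01, 0.99)

    n = config.n_larvae_per_vial
    v = config.n_vials_per_diet
    pup = rng.binomial(n, p[:, :, None], size=(config.n_strains, len(diets), v))
    ecl = rng.binomial(pup, p_ecl[:, None, None])

    s_idx, d_idx, v_idx = np.meshgrid(
        np.arange(config.n_strains), np.arange(len(diets)), np.arange(v), indexing="ij"
    )
    return pd.DataFrame(
        {
            "strain": np.array(strains)[s_idx.ravel()],
            "diet": np.array(diets)[d_idx.ravel()],
            "vial": v_idx.ravel() + 1,
            "n_seeded": n,
            "n_pupated": pup.ravel(),
            "n_eclosed": ecl.ravel(),
        }
    )


@dataclass
class GenotypeMatrix:
    """Biallelic variant x line calls with per-line Wolbachia status.

    ``calls`` is an int8 array of shape (n_variants, n_lines) with values
    0 (reference), 1 (alternate) and -1 (missing).  Lines are inbred, so
    calls are haploid-equivalent.
    """

    variants: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    calls: np.ndarray
    lines: list[str]
    wolbachia: pd.Series  # bool indexed by line id

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.lines)):
            raise ValueError("calls shape does not match variants x lines")
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("line ids must be unique")
        bad = set(np.unique(self.calls)) - {-1, 0, 1}
        if bad:
            raise ValueError(f"calls must be in {{-1, 0, 1}}, found {sorted(bad)}")
        self.wolbachia = self.wolbachia.reindex(self.lines)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, variant_mask=None, lines: Sequence[str] | None = None) -> "GenotypeMatrix":
        variants = self.variants
        calls = self.calls
        if variant_mask is not None:
            variants = variants.loc[np.asarray(variant_mask)].reset_index(drop=True)
            calls = calls[np.asarray(variant_mask)]
        if lines is not None:
            idx = [self.lines.index(l) for l in lines]
            calls = calls[:, idx]
        else:
            lines = self.lines
        return GenotypeMatrix(variants, calls.copy(), list(lines), self.wolbachia.reindex(lines))


def _draw_minor_counts(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    dist = config.minor_line_count_distribution
    size = config.n_variants
    if callable(dist):
        counts = np.asarray(dist(rng, size), dtype=int)
    elif isinstance(dist, tuple):
        lo, hi = dist
        counts = rng.integers(lo, hi + 1, size=size)
    else:
        counts = np.full(size, int(dist))
    if counts.min() < 0 or counts.max() > config.n_strains:
        raise ValueError("minor line counts must lie in [0, n_strains]")
    return counts


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a biallelic genotype matrix and the causal-variant truth table.

    Alternate-allele lines are drawn uniformly per variant; calls go
    missing independently at ``missing_call_rate``.  Returns the matrix
    and a truth table with one row per planted causal variant and shift.
    """
    rng = _rng(config.seed, _STREAM_GENOTYPES)
    n_var, n_lin = config.n_variants, config.n_strains
    lines = config.strain_ids
    counts = _draw_minor_counts(config, rng)
    forced = {cv.index: cv.n_alt_lines for cv in config.causal_variants if cv.n_alt_lines is not None}
    for i, c in forced.items():
        counts[i] = c

    calls = np.zeros((n_var, n_lin), dtype=np.int8)
    for i in range(n_var):
        if counts[i] > 0:
            alt = rng.choice(n_lin, size=counts[i], replace=False)
            calls[i, alt] = 1
    if config.missing_call_rate > 0:
        miss = rng.random((n_var, n_lin)) < config.missing_call_rate
        calls[miss] = -1

    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=n_var)
    alt = (ref + rng.integers(1, 4, size=n_var)) % 4
    variants = pd.DataFrame(
        {
            "id": [f"var_{i + 1:06d}" for i in range(n_var)],
            "chrom": "2L",
            "pos": np.arange(1, n_var + 1) * 100,
            "ref": bases[ref],
            "alt": bases[alt],
        }
    )
    wolb = pd.Series(
        rng.random(n_lin) < config.wolbachia_prevalence, index=lines, name="wolbachia"
    )
    g = GenotypeMatrix(variants, calls, lines, wolb)

    rows = []
    for cv in config.causal_variants:
        for diet, shift in cv.shifts.items():
            rows.append(
                {
                    "variant_id": variants["id"].iloc[cv.index],
                    "variant_index": cv.index,
                    "diet": diet,
                    "shift": shift,
                    "n_alt_lines": int((calls[cv.index] == 1).sum()),
                }
            )
    truth = pd.DataFrame(rows, columns=["variant_id", "variant_index", "diet", "shift", "n_alt_lines"])
    return g, truth


def causal_line_effects(
    config: SimulationConfig, genotypes: GenotypeMatrix
) -> pd.DataFrame:
    """Per-line, per-diet proportion shifts implied by planted causal variants.

    Shifts add over variants; lines with a missing call at a causal
    variant receive no shift from it.
    """
    shifts = pd.DataFrame(0.0, index=genotypes.lines, columns=list(config.diets))
    for cv in config.causal_variants:
        carriers = genotypes.calls[cv.index] == 1
        for diet, s in cv.shifts.items():
            shifts.loc[carriers, diet] += s
    return shifts


def simulate_panel_with_genotypes(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GenotypeMatrix, pd.DataFrame]:
    """Compose genotype and survival simulation: planted variants shape the panel."""
    genotypes, truth = simulate_genotypes(config)
    effects = causal_line_effects(config, genotypes)
    panel = simulate_survival_panel(config, line_effects=effects)
    return panel, genotypes, truth


def sigmoid_curve(t, i_max: float, a1: float, t_mid: float):
    """Logistic pupation curve: cumulative pupae at time ``t`` (dAEL)."""
    return i_max * expit(a1 * (np.asarray(t, dtype=float) - t_mid))


def simulate_pupation_timecourse(
    params: Sequence[Mapping],
    days: Sequence[float],
    noise: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate cumulative pupation time courses for a set of vials.

    ``params`` is a sequence of mappings with keys ``vial`` (label),
    ``i_max``, ``a1``, ``t_mid`` and optionally ``seeded`` (defaults to
    ``i_max``) plus passthrough labels ``strain``/``diet``.

    With ``noise=True`` each of the ``i_max`` larvae pupates at a time
    drawn from a logistic distribution with location ``t_mid`` and scale
    ``1/a1``, so the expected cumulative count is exactly the logistic
    curve and counts are non-decreasing integers by construction.  With
    ``noise=False`` the rounded deterministic curve is returned.
    """
    days = np.asarray(days, dtype=float)
    if days.size and np.any(np.diff(days) <= 0):
        raise ValueError("observation days must be strictly increasing")
    rng = _rng(seed, _STREAM_PUPATION)
    frames = []
    for p in params:
        i_max, a1, t_mid = float(p["i_max"]), float(p["a1"]), float(p["t_mid"])
        seeded = int(p.get("seeded", round(i_max)))
        if a1 <= 0:
            raise ValueError("a1 must be positive")
        if i_max > seeded:
            raise ValueError("i_max cannot exceed larvae seeded")
        if noise:
            times = rng.logistic(loc=t_mid, scale=1.0 / a1, size=int(round(i_max)))
            counts = (times[None, :] <= days[:, None]).sum(axis=1)
        else:
            counts = np.rint(sigmoid_curve(days, i_max, a1, t_mid)).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "vial": p["vial"],
                    "strain": p.get("strain", ""),
                    "diet": p.get("diet", ""),
                    "day": days,
                    "cumulative_pupae": counts,
                    "seeded": seeded,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_respirometry(
    n_flies: int,
    condition_means: Mapping[str, float],
    mass_slope: float,
    activity_slope: float,
    residual_sd: float,
    mass_mean: float = 0.8,
    mass_sd: float = 0.08,
    activity_rate: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-fly respirometry records with linear mass/activity effects.

    Metabolic rate (mJ h^-1) = condition mean + mass_slope * fresh_mass +
    activity_slope * activity + N(0, residual_sd).  Conditions (e.g.
    genotype x diet cells) are assigned round-robin.  Condition labels of
    the form "<genotype>:<diet>" populate the genotype/diet columns.
    """
    if residual_sd <= 0:
        raise ValueError("residual_sd must be positive (use a tiny value for near-noiseless data)")
    rng = _rng(seed, _STREAM_RESPIROMETRY)
    conditions = list(condition_means)
    if n_flies == 0:
        return pd.DataFrame(
            columns=["fly", "condition", "genotype", "diet", "fresh_mass", "activity", "mr_mj_per_h"]
        )
    cond = [conditions[i % len(conditions)] for i in range(n_flies)]
    mass = np.abs(rng.normal(mass_mean, mass_sd, size=n_flies))
    mass = np.clip(mass, 1e-3, None)
    activity = rng.poisson(activity_rate, size=n_flies).astype(float)
    mu = np.array([condition_means[c] for c in cond])
    mr = mu + mass_slope * mass + activity_slope * activity + rng.normal(0, residual_sd, n_flies)
    geno = [c.split(":")[0] if ":" in c else c for c in cond]
    diet = [c.split(":")[1] if ":" in c else "" for c in cond]
    return pd.DataFrame(
        {
            "fly": [f"fly_{i + 1:04d}" for i in range(n_flies)],
            "condition": cond,
            "genotype": geno,
            "diet": diet,
            "fresh_mass": mass,
            "activity": activity,
            "mr_mj_per_h": mr,
        }
    )
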