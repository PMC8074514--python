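"""Seeded synthetic-cohort generator with a single dominant wealth factor.

The generator emulates a six-wave household panel from a growing low-income
economy: a latent household wealth trait rises across waves, binary asset and
housing indicators follow a probit item-response model around it, items enter
and leave the instrument over time, and the final two waves carry an
urban/rural stratum with an urban wealth shift.  Thresholds are calibrated in
closed form so each item's per-wave ownership marginal matches its target.

Item response model.  Household h in wave t has latent wealth

    w_ht = mu_t + delta*(u_h - p_t) + sigma_t*(sqrt(icc)*b_h + sqrt(1-icc)*e_ht)

with persistent household component b_h (intraclass correlation ``icc``),
urban flag u_h, urban share p_t and urban shift delta (zero outside the
final two waves; the shift is centred so the wave mean stays mu_t).  Item j
is owned iff lambda_j*w_ht + u > tau_jt with u ~ N(0,1), so

    P(owned) = Phi((lambda_j*mu_t - tau_jt) / sqrt(lambda_j^2*var_t + 1)),

inverted exactly by ``calibrate_thresholds`` (strata enter as a two-component
normal mixture, solved numerically).  Crowding is integer rooms over integer
household members — the discreteness reproduces the score clumping real
early-wave data show.  True discriminations and latent draws are returned for
parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .asset_panel import AssetPanel, Codebook, ItemDef

__all__ = [
    "WaveSpec",
    "SyntheticSpec",
    "calibrate_thresholds",
    "simulate_panel",
    "simulate_external",
    "default_codebook",
    "default_paper_spec",
    "WAVES",
    "TARGET_MARGINALS",
]

WAVES = ("1967", "1975", "1987", "2002", "2015-16", "2017-18")
WAVE_NS = (547, 755, 617, 820, 1075, 1145)
URBAN_COUNTS = {"2015-16": (302, 1075), "2017-18": (329, 1145)}

# Per-wave ownership proportions used to calibrate the simulator; None = item
# not on that wave's instrument.  Exact 0.00 / 1.00 marginals yield constant
# columns (the item stays on the instrument but cannot enter that wave's fit).
TARGET_MARGINALS: dict[str, tuple] = {
    "radio": (0.32, 0.53, 0.58, 0.21, 0.30, 0.22),
    "record_player": (None, 0.02, 0.06, None, None, None),
    "sewing_machine": (None, 0.11, 0.10, 0.10, 0.19, 0.18),
    "refrigerator": (0.01, 0.02, 0.04, 0.27, 0.67, 0.71),
    "television": (None, 0.01, 0.22, 0.77, 0.92, 0.92),
    "bicycle": (0.01, 0.03, 0.11, 0.53, 0.51, 0.45),
    "motorcycle": (None, 0.00, 0.01, 0.01, 0.24, 0.31),
    "automobile": (None, 0.00, 0.01, 0.08, 0.27, 0.27),
    "video_player": (None, None, None, 0.09, 0.55, 0.47),
    "sound_system": (None, None, None, 0.38, 0.59, 0.57),
    "computer": (None, None, None, 0.01, 0.34, 0.30),
    "telephone": (None, None, None, 0.31, 0.95, 0.96),
    "washing_machine": (None, None, None, None, 0.19, 0.21),
    "owns_land": (None, 0.74, 0.80, 0.53, 0.73, 0.67),
    "owns_house": (0.84, 0.80, 0.82, 0.78, 0.81, 0.83),
    "floor": (0.04, 0.11, 0.37, 0.76, 0.90, 0.91),
    "roof": (0.73, 0.72, 0.89, 0.98, 0.99, 0.99),
    "walls": (0.46, 0.56, 0.81, 0.93, 0.98, 0.98),
    "separate_kitchen": (0.58, 0.73, 0.90, 0.91, 0.95, 0.97),
    "cooking_medium": (0.01, 0.46, 0.67, 0.83, 0.91, 0.87),
    "sanitary_installation": (0.05, 0.16, 0.57, 0.89, 0.98, 0.99),
    "electricity": (0.00, 0.11, 0.72, 0.96, 0.98, 0.97),
    "improved_water_source": (0.03, 0.10, 0.42, 1.00, 0.98, 0.97),
    "improved_sewage": (None, None, None, 0.11, 0.52, 0.54),
}

CROWDING_MEANS = (0.61, 0.61, 0.60, 0.77, 1.09, 1.13)
MEMBERS_MEANS = (5.0, 5.0, 5.0, 4.5, 3.6, 3.5)

# Stipulated item discriminations (loadings on the latent wealth factor).
# Radio gets a deliberately small discrimination: its ownership rises then
# falls across waves, so its pooled relevance is weak and data-dependent.
DISCRIMINATIONS: dict[str, float] = {
    "radio": 0.25,
    "record_player": 0.4,
    "sewing_machine": 0.6,
    "refrigerator": 1.2,
    "television": 1.5,
    "bicycle": 0.6,
    "motorcycle": 0.8,
    "automobile": 0.9,
    "video_player": 1.0,
    "sound_system": 0.8,
    "computer": 1.0,
    "telephone": 1.2,
    "washing_machine": 0.9,
    "owns_land": 0.4,
    "owns_house": 0.3,
    "floor": 1.4,
    "roof": 0.8,
    "walls": 1.0,
    "separate_kitchen": 0.8,
    "cooking_medium": 1.1,
    "sanitary_installation": 1.4,
    "electricity": 1.5,
    "improved_water_source": 1.0,
    "improved_sewage": 0.8,
}

# Items carrying a three-level low/medium/high quality grading.
ORDINAL_ITEMS = ("floor", "roof", "walls", "cooking_medium", "sanitary_installation")

# Zero-imputation rules: waves in which a not-asked item is read as "not owned".
IMPUTE_ZERO: dict[str, tuple[str, ...]] = {
    "owns_land": ("1967",),
    "record_player": ("1967", "2002", "2015-16", "2017-18"),
    "sewing_machine": ("1967",),
    "television": ("1967",),
    "motorcycle": ("1967",),
    "automobile": ("1967",),
    "video_player": ("1967", "1975", "1987"),
    "sound_system": ("1967", "1975", "1987"),
    "computer": ("1967", "1975", "1987"),
    "telephone": ("1967", "1975", "1987"),
    "washing_machine": ("1967", "1975", "1987", "2002"),
    "improved_sewage": ("1967", "1975", "1987"),
}


@dataclass
class WaveSpec:
    """One wave: size, latent moments, calibration targets and crowding model."""

    label: str
    n: int
    mu: float
    sigma: float
    marginals: dict[str, float | None]
    crowding_mean: float
    members_mean: float
    urban_share: float | None = None

    def __post_init__(self):
        if self.n <= 0 or self.sigma <= 0:
            raise ValueError(f"wave {self.label}: n and sigma must be positive")


@dataclass
class SyntheticSpec:
    """Full parameterization of the latent-wealth item-response simulator."""

    waves: list[WaveSpec]
    discriminations: dict[str, float]
    icc: float = 0.6
    urban_shift: float = 0.5
    ordinal_offset: float = 0.8
    rooms_slope: float = 0.8
    rooms_sd: float = 0.8
    schooling_corr: dict[str, float] = field(
        default_factory=lambda: {"maternal": 0.16, "paternal": 0.10, "attained": 0.35}
    )
    # stipulated share of within-wave latent-wealth SD the fitted index
    # composite captures; used only to calibrate the schooling copula so the
    # *measured* index-schooling correlations land on schooling_corr
    index_reliability: float = 0.8
    pool_size: int = 1400
    seed: int = 0

    def __post_init__(self):
        mus = [w.mu for w in self.waves]
        if any(b < a for a, b in zip(mus, mus[1:])):
            raise ValueError("wave latent means must be non-decreasing")
        if not 0 <= self.icc < 1:
            raise ValueError("icc must be in [0, 1)")
        for k, v in self.schooling_corr.items():
            if abs(v) >= 1:
                raise ValueError(f"schooling correlation {k}={v} must be in (-1, 1)")
        if self.pool_size < max(w.n for w in self.waves):
            raise ValueError("pool_size smaller than largest wave")

    @property
    def wave_labels(self) -> list[str]:
        return [w.label for w in self.waves]


def calibrate_thresholds(
    target: float, lam: float, mu: float, sigma: float
) -> float:
    """Threshold tau with P(lam*w + u > tau) = target for w ~ N(mu, sigma²).

    Closed form: tau = lam*mu + sqrt(lam²sigma² + 1)·Phi⁻¹(1 − target).
    Degenerate targets give ±inf (constant item).
    """
    if not 0 <= target <= 1:
        raise ValueError(f"marginal {target} outside [0, 1]")
    if target <= 0:
        return math.inf
    if target >= 1:
        return -math.inf
    s = math.sqrt(lam * lam * sigma * sigma + 1.0)
    return lam * mu + s * float(stats.norm.ppf(1.0 - target))


def _calibrate_mixture(
    target: float, lam: float, mus: list[float], sigmas: list[float], shares: list[float]
) -> float:
    """Threshold for a stratified wave: latent wealth is a normal mixture."""
    if target <= 0:
        return math.inf
    if target >= 1:
        return -math.inf

    def exceed(tau: float) -> float:
        return sum(
            pi * stats.norm.sf((tau - lam * m) / math.sqrt(lam * lam * s * s + 1.0))
            for pi, m, s in zip(shares, mus, sigmas)
        )

    lo, hi = -50.0, 50.0
    return float(optimize.brentq(lambda t: exceed(t) - target, lo, hi, xtol=1e-12))


def wave_thresholds(spec: SyntheticSpec, wave: WaveSpec) -> dict[str, float]:
    """Calibrated tau_jt for every item asked in the wave."""
    out = {}
    for item, p in wave.marginals.items():
        if p is None:
            continue
        lam = spec.discriminations[item]
        if wave.urban_share:
            q = wave.urban_share
            d = spec.urban_shift
            # urban mean shift centred so the wave mean stays mu_t
            mus = [wave.mu + d * (1 - q), wave.mu - d * q]
            out[item] = _calibrate_mixture(p, lam, mus, [wave.sigma] * 2, [q, 1 - q])
        else:
            out[item] = calibrate_thresholds(p, lam, wave.mu, wave.sigma)
    return out


def default_codebook() -> Codebook:
    """Codebook matching the benchmark instrument and harmonization rules."""
    items = []
    for name, margs in TARGET_MARGINALS.items():
        availability = frozenset(w for w, p in zip(WAVES, margs) if p is not None)
        if name in ORDINAL_ITEMS:
            binary = {"low": 0, "medium": 0, "high": 1}
            ordinal = {"low": 0, "medium": 1, "high": 2}
            kind = "housing"
        else:
            binary = {"no": 0, "yes": 1}
            ordinal = None
            kind = (
                "housing"
                if name
                in {
                    "owns_land",
                    "owns_house",
                    "separate_kitchen",
                    "electricity",
                    "improved_water_source",
                    "improved_sewage",
                }
                else "asset"
            )
        items.append(
            ItemDef(
                name=name,
                kind=kind,
                binary_recode=binary,
                ordinal_recode=ordinal,
                availability=availability,
                impute_zero_waves=IMPUTE_ZERO.get(name, ()),
            )
        )
    items.append(
        ItemDef(
            name="rooms_per_member",
            kind="crowding",
            availability=frozenset(WAVES),
        )
    )
    return Codebook(items=tuple(items), waves=WAVES)


def default_paper_spec(seed: int = 0) -> SyntheticSpec:
    """The study conditions: six waves with the printed household counts,
    instrument availability pattern, calibrated marginals and urban shares."""
    mus = (-1.5, -1.0, -0.2, 0.6, 1.0, 1.05)
    sigmas = (0.8, 0.9, 1.0, 0.85, 0.8, 0.8)
    waves = []
    for i, label in enumerate(WAVES):
        urban = URBAN_COUNTS.get(label)
        waves.append(
            WaveSpec(
                label=label,
                n=WAVE_NS[i],
                mu=mus[i],
                sigma=sigmas[i],
                marginals={k: v[i] for k, v in TARGET_MARGINALS.items()},
                crowding_mean=CROWDING_MEANS[i],
                members_mean=MEMBERS_MEANS[i],
                urban_share=(urban[0] / urban[1]) if urban else None,
            )
        )
    return SyntheticSpec(waves=waves, discriminations=dict(DISCRIMINATIONS), seed=seed)


# ---------------------------------------------------------------------------
# simulation


def simulate_panel(
    spec: SyntheticSpec,
    seed: int | None = None,
    codebook: Codebook | None = None,
    return_truth: bool = False,
):
    """Draw a panel from the spec; fully reproducible under the seed.

    With ``return_truth=True`` also returns the latent-wealth table
    (household_id, wave) → w used by parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cb = codebook or default_codebook()
    crowd_name = cb.crowding_item.name

    width = len(str(spec.pool_size))
    pool_ids = np.array([f"H{i:0{width}d}" for i in range(1, spec.pool_size + 1)])
    b = rng.standard_normal(spec.pool_size)  # persistent household component
    urban_flag = rng.random(spec.pool_size)  # uniform; thresholded per wave share

    frames, ordinal_frames, strata, truths = [], [], [], []
    for wave in spec.waves:
        take = np.sort(rng.choice(spec.pool_size, size=wave.n, replace=False))
        hh = pool_ids[take]
        e = rng.standard_normal(wave.n)
        w = wave.mu + wave.sigma * (
            math.sqrt(spec.icc) * b[take] + math.sqrt(1.0 - spec.icc) * e
        )
        stratum = None
        if wave.urban_share:
            is_urban = urban_flag[take] < wave.urban_share
            w = w + spec.urban_shift * (is_urban.astype(float) - wave.urban_share)
            stratum = np.where(is_urban, "urban", "rural")

        taus = wave_thresholds(spec, wave)
        idx = pd.MultiIndex.from_arrays(
            [hh, [wave.label] * wave.n], names=["household_id", "wave"]
        )
        vals = pd.DataFrame(index=idx, columns=cb.item_names, dtype=float)
        ords = pd.DataFrame(index=idx, columns=cb.item_names, dtype=float)
        for item in cb.item_names:
            if item == crowd_name:
                continue
            if item not in taus:
                continue  # NOT_ASKED stays NaN
            lam = spec.discriminations[item]
            tau = taus[item]
            y = lam * w + rng.standard_normal(wave.n)
            vals[item] = (y > tau).astype(float)
            if item in ORDINAL_ITEMS:
                # medium quality occupies a band below the high-quality cut
                ords[item] = np.select(
                    [y > tau, y > tau - spec.ordinal_offset], [2.0, 1.0], 0.0
                )
        # crowding: integer rooms over integer members
        lam_m = max(wave.members_mean - 1.0, 1e-9)
        members = 1 + rng.poisson(lam_m, size=wave.n)
        inv_members_mean = (1.0 - math.exp(-lam_m)) / lam_m
        rooms_mean = wave.crowding_mean / inv_members_mean
        rooms = np.clip(
            np.round(
                rooms_mean
                + spec.rooms_slope * (w - wave.mu)
                + spec.rooms_sd * rng.standard_normal(wave.n)
            ),
            1,
            12,
        )
        vals[crowd_name] = rooms / members

        frames.append(vals)
        ordinal_frames.append(ords)
        strata.append(
            pd.Series(stratum if stratum is not None else np.nan, index=idx, dtype=object)
        )
        truths.append(pd.Series(w, index=idx, name="latent_wealth"))

    values = pd.concat(frames)
    ordinal = pd.concat(ordinal_frames)
    stratum = pd.concat(strata)
    panel = AssetPanel(
        values=values,
        codebook=cb,
        ordinal=ordinal,
        stratum=stratum if stratum.notna().any() else None,
    )
    if return_truth:
        return panel, pd.concat(truths)
    return panel


def simulate_external(
    spec: SyntheticSpec,
    truth: pd.Series,
    seed: int | None = None,
) -> pd.DataFrame:
    """Schooling-like external measures with target latent correlations.

    For each household, parental schooling couples to standardized latent
    wealth at the household's earliest observed wave and attained schooling
    to the latest, through a Gaussian copula; the Gaussian score is then
    discretized onto a right-skewed grade distribution (monotone quantile
    map, which preserves ranks).  Discretizing attenuates the Pearson
    correlation by a factor k = corr(G⁻¹(Φ(X)), X) that depends only on the
    grade distribution; a binary-item index likewise captures only a share of
    within-wave latent variance (the stipulated ``index_reliability``).  The
    copula strength is divided by both so the *measured* index–schooling
    correlations land on the ``schooling_corr`` targets.
    """
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 104729)
    order = {w: i for i, w in enumerate(spec.wave_labels)}
    df = truth.rename("w").reset_index()
    df["order"] = df["wave"].map(order)
    df = df.sort_values("order")
    g = df.groupby("household_id", sort=True)
    first = g.first()
    last = g.last()

    # right-skewed grade distribution over 0..18 completed years
    grades = np.arange(19)
    pmf = 0.78**grades
    pmf[0] *= 2.2  # excess mass at zero schooling
    pmf /= pmf.sum()
    cum = np.cumsum(pmf)

    # attenuation of a Pearson correlation under the quantile discretization:
    # k = Cov(G, X)/sd(G) with G = G⁻¹(Φ(X)), X ~ N(0,1); grade g occupies
    # (z_{g-1}, z_g], so E[G·X] = Σ_g g·(φ(z_{g-1}) − φ(z_g))
    cuts = stats.norm.ppf(np.concatenate(([0.0], cum)))
    phi = stats.norm.pdf(np.clip(cuts, -40, 40))
    phi[np.isinf(cuts)] = 0.0
    cov_gx = float(np.sum(grades * (phi[:-1] - phi[1:])))
    g_mean = float(np.sum(grades * pmf))
    g_sd = math.sqrt(float(np.sum((grades - g_mean) ** 2 * pmf)))
    atten = cov_gx / g_sd

    def draw(latents: pd.Series, rho: float) -> pd.Series:
        rho_adj = max(min(rho / (atten * spec.index_reliability), 0.995), -0.995)
        z = (latents - latents.mean()) / latents.std(ddof=0)
        gstar = rho_adj * z + math.sqrt(1 - rho_adj * rho_adj) * rng.standard_normal(len(z))
        u = stats.norm.cdf(gstar)
        return pd.Series(grades[np.searchsorted(cum, u)], index=latents.index)

    out = pd.DataFrame(index=first.index)
    out["maternal_schooling"] = draw(first["w"], spec.schooling_corr["maternal"])
    out["paternal_schooling"] = draw(first["w"], spec.schooling_corr["paternal"])
    out["attained_schooling"] = draw(last["w"], spec.schooling_corr["attained"])
    out.index.name = "household_id"
    return out
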