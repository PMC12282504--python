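"""Synthetic cohorts with a planted low-rank cross-block covariance.

Each subject carries latent scores; brain and behavior blocks are noisy
projections of those scores onto fixed sparse unit direction vectors, plus
an age trend on the brain block. Cohort structure defaults to the study
shape: 91 ED (61 restricting + 30 binge-purge) and 48 HC, 65 brain columns,
38 behavior columns, follow-up severity for 72 of the 91 ED subjects.
Ground truth (directions, supports, latents) is returned for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .datamodel import BEHAVIOR_DOMAINS, StudyDataset
from .decomposition import PlsDecomposition


@dataclass
class SyntheticSpec:
    """Parameters of the planted latent model."""

    n_edr: int = 61
    n_edbp: int = 30
    n_hc: int = 48
    p: int = 65
    q: int = 38
    n_latent: int = 2
    effect_brain: tuple[float, ...] = (1.0, 0.6)  # a_l, latent-to-brain scale
    effect_behavior: tuple[float, ...] = (1.0, 0.6)  # b_l
    noise_sd: float = 1.0
    subtype_shift: float = 0.5  # latent-1 mean shift for EDbp
    age_slope_scale: float = 0.05  # SD of per-column age slopes
    followup_coupling: float = 0.3  # gamma: latent-1 -> follow-up severity
    baseline_autocorr: float = 0.5  # rho: baseline -> follow-up severity
    followup_fraction: float = 72 / 91
    brain_support: int | None = None  # nonzero entries per brain direction (default 20%)
    behavior_support: int | None = None
    heavy_tails: bool = False  # t(5) residuals instead of Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_edr", "n_edbp", "n_hc", "p", "q", "n_latent"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 < self.followup_fraction <= 1.0):
            raise ValueError("followup_fraction must be in (0, 1]")
        if len(self.effect_brain) < self.n_latent or len(self.effect_behavior) < self.n_latent:
            raise ValueError("need one effect scale per planted latent")

    @property
    def n_ed(self) -> int:
        return self.n_edr + self.n_edbp

    @property
    def n(self) -> int:
        return self.n_ed + self.n_hc

    def resolved_supports(self) -> tuple[int, int]:
        bs = self.brain_support if self.brain_support is not None else max(2, round(0.2 * self.p))
        qs = (
            self.behavior_support
            if self.behavior_support is not None
            else max(2, round(0.2 * self.q))
        )
        if bs * self.n_latent > self.p:
            raise ValueError(
                f"brain support {bs} x {self.n_latent} latents exceeds p = {self.p}"
            )
        if qs * self.n_latent > self.q:
            raise ValueError(
                f"behavior support {qs} x {self.n_latent} latents exceeds q = {self.q}"
            )
        return bs, qs


@dataclass
class GroundTruth:
    """Planted structure saved alongside a generated dataset."""

    u: np.ndarray  # (p, L) unit direction vectors, disjoint sparse supports
    v: np.ndarray  # (q, L)
    brain_support: list[np.ndarray]  # indices of nonzero u entries per latent
    behavior_support: list[np.ndarray]
    latent: np.ndarray  # (n, L) subject latent scores
    effect_brain: np.ndarray  # (L,)
    effect_behavior: np.ndarray  # (L,)
    noise_sd: float
    spec: SyntheticSpec


def _sparse_directions(
    rng: np.random.Generator, dim: int, n_latent: int, support: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Unit-norm directions with disjoint equal-magnitude sparse supports."""
    order = rng.permutation(dim)
    dirs = np.zeros((dim, n_latent))
    supports = []
    for l in range(n_latent):
        idx = np.sort(order[l * support : (l + 1) * support])
        signs = rng.choice([-1.0, 1.0], size=support)
        dirs[idx, l] = signs / np.sqrt(support)
        supports.append(idx)
    return dirs, supports


def _noise(rng: np.random.Generator, shape: tuple[int, ...], spec: SyntheticSpec) -> np.ndarray:
    if spec.heavy_tails:
        draws = rng.standard_t(df=5, size=shape)
        return draws / np.sqrt(5 / 3)  # unit variance
    return rng.standard_normal(shape)


def _names(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    if spec.p == 65:  # study layout: 35 white-matter tracts + 30 subcortical regions
        roi = [f"tract_{i+1:02d}" for i in range(35)] + [f"aseg_{i+1:02d}" for i in range(30)]
    else:
        roi = [f"roi_{i+1:03d}" for i in range(spec.p)]
    chunks = np.array_split(np.arange(spec.q), len(BEHAVIOR_DOMAINS))
    domains = []
    names = []
    for domain, idx in zip(BEHAVIOR_DOMAINS, chunks):
        for i, _ in enumerate(idx):
            names.append(f"{domain}_{i+1:02d}")
            domains.append(domain)
    return roi, names, domains


def generate_dataset(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[StudyDataset, GroundTruth]:
    """Draw one cohort from the planted latent model.

    Per subject i with latent scores z_il ~ Normal(shift, 1):
    brain_i = sum_l a_l z_il u_l + age_i * slope + noise,
    behavior_i = sum_l b_l z_il v_l + noise, with the subtype shift applied
    to latent 1 for binge-purge subjects. Baseline severity tracks latent 1;
    follow-up severity (for the follow-up subset of ED subjects) is
    rho * baseline + gamma * latent_1 + noise, clipped to the 0-6 scale.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    bs, qs = spec.resolved_supports()
    n, L = spec.n, spec.n_latent

    group = np.array(["ED"] * spec.n_ed + ["HC"] * spec.n_hc, dtype=object)
    subtype = np.array(
        ["EDr"] * spec.n_edr + ["EDbp"] * spec.n_edbp + ["NA"] * spec.n_hc, dtype=object
    )
    age = rng.uniform(13.1, 18.2, size=n)

    latent = rng.standard_normal((n, L))
    latent[subtype == "EDbp", 0] += spec.subtype_shift

    u, u_support = _sparse_directions(rng, spec.p, L, bs)
    v, v_support = _sparse_directions(rng, spec.q, L, qs)
    a = np.asarray(spec.effect_brain[:L], float)
    b = np.asarray(spec.effect_behavior[:L], float)

    slope = rng.normal(0.0, spec.age_slope_scale, size=spec.p)
    brain = (latent * a) @ u.T + np.outer(age, slope) + spec.noise_sd * _noise(rng, (n, spec.p), spec)
    behavior = (latent * b) @ v.T + spec.noise_sd * _noise(rng, (n, spec.q), spec)

    ed_mask = group == "ED"
    baseline = np.where(
        ed_mask,
        2.9 + 0.8 * latent[:, 0] + 0.4 * rng.standard_normal(n),
        0.1 + 0.15 * np.abs(rng.standard_normal(n)),
    )
    baseline = np.clip(baseline, 0.0, 6.0)

    followup = np.full(n, np.nan)
    ed_idx = np.nonzero(ed_mask)[0]
    n_follow = int(round(spec.followup_fraction * ed_idx.size))
    follow_idx = np.sort(rng.choice(ed_idx, size=n_follow, replace=False))
    followup[follow_idx] = np.clip(
        spec.baseline_autocorr * baseline[follow_idx]
        + spec.followup_coupling * latent[follow_idx, 0]
        + 0.5 * rng.standard_normal(n_follow),
        0.0,
        6.0,
    )

    roi_names, behavior_names, behavior_domains = _names(spec)
    ds = StudyDataset(
        subject_id=np.array([f"S{i+1:04d}" for i in range(n)], dtype=object),
        brain=brain,
        behavior=behavior,
        age=age,
        group=group,
        subtype=subtype,
        baseline_severity=baseline,
        followup_severity=followup,
        roi_names=roi_names,
        behavior_names=behavior_names,
        behavior_domains=behavior_domains,
    )
    gt = GroundTruth(
        u=u,
        v=v,
        brain_support=u_support,
        behavior_support=v_support,
        latent=latent,
        effect_brain=a,
        effect_behavior=b,
        noise_sd=spec.noise_sd,
        spec=spec,
    )
    return ds, gt


def generate_null_dataset(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[StudyDataset, GroundTruth]:
    """Same marginal structure with all cross-block effects set to zero."""
    null_spec = dataclasses.replace(
        spec,
        effect_brain=tuple(0.0 for _ in spec.effect_brain),
        effect_behavior=tuple(0.0 for _ in spec.effect_behavior),
    )
    return generate_dataset(null_spec, rng=rng)


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    """How well an estimated decomposition recovers the planted structure."""

    matched_lv: np.ndarray  # (L,) estimated LV index matched to each planted latent
    cos_u: np.ndarray  # (L,) |cosine| between true and matched brain directions
    cos_v: np.ndarray
    covexp_est: np.ndarray  # (L,) covariance-explained of the matched LVs
    covexp_expected: np.ndarray  # (L,) noiseless limit (a_l b_l)^2 / sum
    covexp_bias: np.ndarray
    brain_tpr: np.ndarray | None = None  # per latent, |BSR| flags vs planted support
    brain_fpr: np.ndarray | None = None
    behavior_tpr: np.ndarray | None = None
    behavior_fpr: np.ndarray | None = None


def recovery_report(
    gt: GroundTruth,
    dec: PlsDecomposition,
    inference=None,
) -> RecoveryMetrics:
    """Cosine similarity, covariance-explained bias, and (when inference
    results are supplied) true/false-positive rates of the bootstrap-ratio
    reliability flags against the planted sparse supports.

    On null data (all planted effects zero) TPR is undefined and reported
    as NaN; FPR is then the overall flagged fraction.
    """
    L = gt.u.shape[1]
    if dec.k < L:
        raise ValueError(f"decomposition has {dec.k} LVs, ground truth has {L}")

    # greedy matching of planted latents to estimated LVs by combined |cos|
    sim = np.abs(gt.u.T @ dec.U) + np.abs(gt.v.T @ dec.V)  # (L, k)
    matched = np.full(L, -1)
    used: set[int] = set()
    for l in range(L):
        order = np.argsort(-sim[l])
        matched[l] = next(int(j) for j in order if int(j) not in used)
        used.add(int(matched[l]))

    cos_u = np.array([abs(float(gt.u[:, l] @ dec.U[:, matched[l]])) for l in range(L)])
    cos_v = np.array([abs(float(gt.v[:, l] @ dec.V[:, matched[l]])) for l in range(L)])
    covexp_est = dec.covexp[matched]

    ab2 = (gt.effect_brain * gt.effect_behavior) ** 2
    total = ab2.sum()
    covexp_expected = ab2 / total if total > 0 else np.full(L, np.nan)

    metrics = RecoveryMetrics(
        matched_lv=matched,
        cos_u=cos_u,
        cos_v=cos_v,
        covexp_est=covexp_est,
        covexp_expected=covexp_expected,
        covexp_bias=covexp_est - covexp_expected,
    )

    if inference is not None:
        is_null = total == 0
        b_tpr, b_fpr, y_tpr, y_fpr = [], [], [], []
        for l in range(L):
            j = matched[l]
            for flags, support, dim, tprs, fprs in (
                (
                    np.asarray(inference.reliable_brain_weights)[:, j],
                    gt.brain_support[l],
                    gt.u.shape[0],
                    b_tpr,
                    b_fpr,
                ),
                (
                    np.asarray(inference.reliable_behavior_weights)[:, j],
                    gt.behavior_support[l],
                    gt.v.shape[0],
                    y_tpr,
                    y_fpr,
                ),
            ):
                non_support = np.setdiff1d(np.arange(dim), support)
                if is_null:
                    tprs.append(np.nan)
                    fprs.append(float(flags.mean()))
                else:
                    tprs.append(float(flags[support].mean()))
                    fprs.append(float(flags[non_support].mean()) if non_support.size else np.nan)
        metrics.brain_tpr = np.array(b_tpr)
        metrics.brain_fpr = np.array(b_fpr)
        metrics.behavior_tpr = np.array(y_tpr)
        metrics.behavior_fpr = np.array(y_fpr)
    return metrics
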