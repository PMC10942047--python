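"""Synthetic cohort generator: subjects, reader annotations, logits, toy images.

Emulates the statistical structure of a two-finding screening study so that
every downstream stage (calibration, evaluation, classifier training) can be
exercised without real data:

* each subject carries a per-finding severity ``s`` drawn from a two-component
  mixture (background vs affected) and a latent reader-positive probability
  ``p = σ(a·(s - s0))``;
* annotations are four independent Bernoulli(p) reader calls per finding
  (two first-stage readers merged by union, two recorded second-stage readers);
* classifier logits follow the scaled-logit model ``-λ_true · u = logit(p) + ε``
  with Gaussian noise ε, i.e. ``u = -(logit(p) + ε)/λ_true``;
* toy grayscale images show an apical band (finding 1) and a laterally
  displaced spine ridge (finding 2) whose salience grows with severity.

Default prevalences target merged first-stage positive rates of about 4.5%
(finding 1, "pleural_thickening") and 1.6% (finding 2, "scoliosis"),
mirroring the class imbalance of apical-cap and spinal-curvature findings in
large screening cohorts.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .posterior import DiagnosisGroup, logit, sigmoid

__all__ = [
    "DistributionSpec",
    "FindingConfig",
    "SimConfig",
    "ImageConfig",
    "SubjectTruth",
    "AnnotationRecord",
    "sample_subjects",
    "simulate_annotations",
    "simulate_logits",
    "ideal_prediction_logits",
    "render_images",
    "apex_mask",
    "spine_mask",
    "background_mask",
    "first_stage_positive_rate",
]

P_EPS = 1e-6  # latent-p clamp before taking logits


@dataclass(frozen=True)
class DistributionSpec:
    """A named scalar distribution with parameters, seedable via a Generator."""

    name: str  # "exponential" | "uniform" | "normal" | "constant"
    params: Tuple[float, ...]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.name == "exponential":
            (scale,) = self.params
            if scale <= 0:
                raise ValueError("exponential scale must be > 0")
            return rng.exponential(scale, n)
        if self.name == "uniform":
            low, high = self.params
            if high < low:
                raise ValueError("uniform requires high >= low")
            return rng.uniform(low, high, n)
        if self.name == "normal":
            mu, sd = self.params
            if sd < 0:
                raise ValueError("normal requires sd >= 0")
            return rng.normal(mu, sd, n)
        if self.name == "constant":
            (v,) = self.params
            return np.full(n, v)
        raise ValueError(f"unknown distribution {self.name!r}")

    def pdf_grid(self, s: np.ndarray) -> np.ndarray:
        """Density on a grid (used by quadrature oracles)."""
        if self.name == "exponential":
            (scale,) = self.params
            return np.where(s >= 0, np.exp(-s / scale) / scale, 0.0)
        if self.name == "uniform":
            low, high = self.params
            return np.where((s >= low) & (s <= high), 1.0 / (high - low), 0.0)
        if self.name == "normal":
            mu, sd = self.params
            return np.exp(-0.5 * ((s - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        raise ValueError(f"no closed-form pdf for {self.name!r}")


@dataclass(frozen=True)
class FindingConfig:
    """Latent severity mixture and reader-probability link for one finding."""

    name: str
    mixture_weight: float  # probability a subject is "affected"
    background: DistributionSpec
    affected: DistributionSpec
    link_slope: float  # a in p = sigmoid(a (s - s0))
    link_threshold: float  # s0
    lambda_true: float  # generative logit scale (λ in u = -(logit p + ε)/λ)
    logit_noise_sd: float  # ε standard deviation

    def __post_init__(self):
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must be in [0, 1]")
        if self.lambda_true <= 0:
            raise ValueError("lambda_true must be > 0")
        if self.logit_noise_sd < 0:
            raise ValueError("logit_noise_sd must be >= 0")

    def link(self, s: np.ndarray) -> np.ndarray:
        return sigmoid(self.link_slope * (np.asarray(s, dtype=float) - self.link_threshold))


def _default_findings() -> Tuple[FindingConfig, ...]:
    # Affected severities spread p over roughly (0.2, 0.95); background keeps
    # p near zero.  Mixture weights solved against the quadrature oracle
    # (first_stage_positive_rate) so the merged first-stage positive rate is
    # 4.46% and 1.58% — the class imbalance typical of these two findings.
    return (
        FindingConfig(
            name="pleural_thickening",
            mixture_weight=0.045476,
            background=DistributionSpec("exponential", (0.12,)),
            affected=DistributionSpec("uniform", (1.55, 3.0)),
            link_slope=3.0,
            link_threshold=2.0,
            lambda_true=0.79,
            logit_noise_sd=0.3,
        ),
        FindingConfig(
            name="scoliosis",
            mixture_weight=0.009999,
            background=DistributionSpec("exponential", (0.12,)),
            affected=DistributionSpec("uniform", (1.55, 3.0)),
            link_slope=3.0,
            link_threshold=2.0,
            lambda_true=0.22,
            logit_noise_sd=0.3,
        ),
    )


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings."""

    n_subjects: int = 1000
    seed: int = 0
    findings: Tuple[FindingConfig, ...] = field(default_factory=_default_findings)

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")

    @property
    def finding_names(self) -> List[str]:
        return [f.name for f in self.findings]


def uniform_latent_config(n_subjects: int, seed: int = 0,
                          lambdas: Sequence[float] = (0.79, 0.22),
                          noise_sd: float = 0.3) -> SimConfig:
    """Config whose latent p is exactly Uniform(0, 1) per finding.

    With a flat latent-p density the group-conditional distribution of p is
    the uniform-prior posterior, which makes this the matched condition for
    calibration-recovery and posterior-comparison checks.
    Severity s ~ U(0,1) is mapped through the identity-link trick
    p = σ(logit(s)) = s (slope 1, threshold 0 on the logit scale is emulated
    by sampling s already in probability units).
    """
    findings = []
    base = _default_findings()
    for f, lam in zip(base, lambdas):
        findings.append(
            FindingConfig(
                name=f.name,
                mixture_weight=1.0,
                background=DistributionSpec("constant", (0.5,)),
                affected=DistributionSpec("uniform", (P_EPS, 1.0 - P_EPS)),
                link_slope=0.0,  # sentinel: identity link (p = s), see sample_subjects
                link_threshold=0.0,
                lambda_true=lam,
                logit_noise_sd=noise_sd,
            )
        )
    return SimConfig(n_subjects=n_subjects, seed=seed, findings=tuple(findings))


def separable_config(n_subjects: int, seed: int = 0) -> SimConfig:
    """Classifier-benchmark config: balanced classes, image-predictable labels.

    Half the subjects are affected with high severity (latent p between about
    0.82 and 0.95) and half are clean background (p ≈ 0.002), so the merged
    first-stage label almost always reflects visible image content.  Used for
    classifier sanity benchmarks, not for prevalence-realistic simulations.
    """
    base = _default_findings()
    findings = tuple(
        FindingConfig(
            name=f.name,
            mixture_weight=0.5,
            background=DistributionSpec("constant", (0.0,)),
            affected=DistributionSpec("uniform", (2.5, 3.0)),
            link_slope=3.0,
            link_threshold=2.0,
            lambda_true=f.lambda_true,
            logit_noise_sd=f.logit_noise_sd,
        )
        for f in base
    )
    return SimConfig(n_subjects=n_subjects, seed=seed, findings=findings)


@dataclass(frozen=True)
class SubjectTruth:
    """Ground truth for one synthetic subject."""

    subject_id: str
    severity: Dict[str, float]  # per finding
    p: Dict[str, float]  # latent reader-positive probability per finding


@dataclass(frozen=True)
class AnnotationRecord:
    """Reader calls for one subject: two-stage, two readers per stage, per finding."""

    subject_id: str
    calls: Dict[str, Tuple[int, int, int, int]]  # finding -> (r1_s1, r2_s1, r1_s2, r2_s2)

    def merged_first(self, finding: str) -> str:
        r1, r2, _, _ = self.calls[finding]
        return "P" if (r1 or r2) else "N"

    def group(self, finding: str) -> DiagnosisGroup:
        return DiagnosisGroup.from_calls(*self.calls[finding])


def sample_subjects(config: SimConfig) -> List[SubjectTruth]:
    """Draw the cohort: severities from the mixture, p through the link."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    sev = {}
    prob = {}
    for f in config.findings:
        affected = rng.random(n) < f.mixture_weight
        s = f.background.sample(rng, n)
        s_aff = f.affected.sample(rng, n)
        s = np.where(affected, s_aff, s)
        p = s if f.link_slope == 0.0 else f.link(s)  # slope 0 => identity link
        sev[f.name] = s
        prob[f.name] = np.clip(p, 0.0, 1.0)
    width = max(6, len(str(max(n - 1, 0))))
    return [
        SubjectTruth(
            subject_id=f"S{i:0{width}d}",
            severity={k: float(sev[k][i]) for k in sev},
            p={k: float(prob[k][i]) for k in prob},
        )
        for i in range(n)
    ]


def simulate_annotations(truths: Sequence[SubjectTruth], seed: int) -> List[AnnotationRecord]:
    """Four independent Bernoulli(p) reader calls per subject and finding."""
    rng = np.random.default_rng(seed)
    if not truths:
        return []
    findings = list(truths[0].p)
    n = len(truths)
    draws = {}
    for name in findings:
        p = np.array([t.p[name] for t in truths])
        if np.any((p < 0) | (p > 1)):
            raise ValueError("latent probabilities must lie in [0, 1]")
        draws[name] = (rng.random((n, 4)) < p[:, None]).astype(int)
    return [
        AnnotationRecord(
            subject_id=t.subject_id,
            calls={name: tuple(int(v) for v in draws[name][i]) for name in findings},
        )
        for i, t in enumerate(truths)
    ]


def simulate_logits(truths: Sequence[SubjectTruth], lambda_true: float,
                    noise_sd: float, seed: int, finding: Optional[str] = None) -> np.ndarray:
    """Classifier-style raw logits u with -λ_true·u = logit(p) + Normal(0, σ²).

    Latent p is clamped to [ε, 1-ε] (ε = 1e-6) before the logit.  Returns one
    logit per subject for the given finding (default: the first).
    """
    if lambda_true <= 0:
        raise ValueError("lambda_true must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if not truths:
        return np.empty(0)
    finding = finding or next(iter(truths[0].p))
    p = np.clip(np.array([t.p[finding] for t in truths]), P_EPS, 1 - P_EPS)
    eps = rng.normal(0.0, noise_sd, len(p)) if noise_sd > 0 else 0.0
    return -(logit(p) + eps) / lambda_true


def ideal_prediction_logits(truths: Sequence[SubjectTruth], config: SimConfig,
                            seed: int, n_models: int = 10) -> "pd.DataFrame":
    """A K-model prediction grid from the generative logit model.

    Each of the ``n_models`` pseudo-CV-models gets an independent noise
    realization, emulating between-model output variability.  Returns a tidy
    frame (subject_id, finding, model_index, logit).
    """
    import pandas as pd

    rows = []
    for j, f in enumerate(config.findings):
        for m in range(1, n_models + 1):
            u = simulate_logits(truths, f.lambda_true, f.logit_noise_sd,
                                seed=seed + 7919 * m + 104729 * j, finding=f.name)
            for t, ui in zip(truths, u):
                rows.append((t.subject_id, f.name, m, float(ui)))
    return pd.DataFrame(rows, columns=["subject_id", "finding", "model_index", "logit"])


def first_stage_positive_rate(f: FindingConfig, n_grid: int = 20001) -> float:
    """Quadrature oracle for the merged first-stage positive rate E[1-(1-p)²]."""

    def component_rate(spec: DistributionSpec) -> float:
        if spec.name == "constant":
            p = f.link(spec.params[0]) if f.link_slope != 0.0 else spec.params[0]
            return 1 - (1 - p) ** 2
        if spec.name == "exponential":
            hi = spec.params[0] * 40
        elif spec.name == "uniform":
            hi = spec.params[1]
        else:
            hi = spec.params[0] + 10 * spec.params[1]
        lo = min(0.0, spec.params[0] if spec.name == "uniform" else 0.0)
        s = np.linspace(lo, hi, n_grid)
        w = spec.pdf_grid(s)
        p = s if f.link_slope == 0.0 else f.link(s)
        return float(np.trapezoid((1 - (1 - p) ** 2) * w, s))

    pi = f.mixture_weight
    return pi * component_rate(f.affected) + (1 - pi) * component_rate(f.background)


# ---------------------------------------------------------------------------
# toy image rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageConfig:
    """Geometry and contrast of the toy radiograph-like images."""

    side: int = 64
    background_level: float = 0.40
    apex_fraction: float = 0.15  # top rows carrying the apical band
    apex_contrast: float = 0.35  # added intensity at maximal severity
    spine_halfwidth_fraction: float = 0.04
    spine_amplitude_fraction: float = 0.10  # lateral sinusoid amplitude at max severity
    spine_contrast: float = 0.30
    noise_sd: float = 0.04
    severity_max: float = 3.0  # severity mapped to full contrast/displacement

    def __post_init__(self):
        if self.side < 32:
            raise ValueError("image side must be >= 32")


def apex_mask(cfg: ImageConfig) -> np.ndarray:
    """Apical band rows, excluding the spine column band."""
    m = np.zeros((cfg.side, cfg.side), dtype=bool)
    m[: int(round(cfg.apex_fraction * cfg.side)), :] = True
    m &= ~spine_mask(cfg)
    return m


def spine_mask(cfg: ImageConfig) -> np.ndarray:
    """Columns that the spine ridge can ever occupy (any displacement)."""
    half = int(np.ceil((cfg.spine_halfwidth_fraction + cfg.spine_amplitude_fraction) * cfg.side))
    c = cfg.side // 2
    m = np.zeros((cfg.side, cfg.side), dtype=bool)
    m[:, max(0, c - half) : min(cfg.side, c + half + 1)] = True
    return m


def background_mask(cfg: ImageConfig) -> np.ndarray:
    """Rows below the apex band, outside the spine band."""
    m = np.ones((cfg.side, cfg.side), dtype=bool)
    m[: int(round(cfg.apex_fraction * cfg.side)), :] = False
    m &= ~spine_mask(cfg)
    return m


def render_images(truths: Sequence[SubjectTruth], cfg: ImageConfig, seed: int) -> np.ndarray:
    """Render one grayscale image per subject, shape (n, side, side), values ~[0, 1].

    Finding 1 (first in the truth dict) brightens the apical band in
    proportion to severity; finding 2 displaces a bright vertical spine ridge
    laterally by a sinusoid with severity-proportional amplitude.  Additive
    Gaussian pixel noise on top.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = len(truths)
    S = cfg.side
    out = np.full((n, S, S), cfg.background_level, dtype=float)
    if n == 0:
        return out
    fnames = list(truths[0].severity)
    s1 = np.array([t.severity[fnames[0]] for t in truths])
    s2 = np.array([t.severity[fnames[1]] for t in truths]) if len(fnames) > 1 else np.zeros(n)

    apex_rows = int(round(cfg.apex_fraction * S))
    rows = np.arange(S)
    cols = np.arange(S)
    half = max(1, int(round(cfg.spine_halfwidth_fraction * S)))
    center = S // 2
    for i in range(n):
        # apical band
        c1 = cfg.apex_contrast * min(s1[i] / cfg.severity_max, 1.0)
        out[i, :apex_rows, :] += c1
        # spine ridge with sinusoidal lateral displacement
        amp = cfg.spine_amplitude_fraction * S * min(s2[i] / cfg.severity_max, 1.0)
        offset = np.rint(amp * np.sin(2 * np.pi * rows / S)).astype(int)
        for r in range(S):
            c = center + offset[r]
            lo, hi = max(0, c - half), min(S, c + half + 1)
            out[i, r, lo:hi] += cfg.spine_contrast
    if cfg.noise_sd > 0:
        out += rng.normal(0.0, cfg.noise_sd, out.shape)
    return out
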