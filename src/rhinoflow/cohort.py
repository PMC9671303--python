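"""Synthetic pre/post subject-pair generator.

Real septoturbinoplasty cohorts come from CT scans that are not public, so
this module generates virtual subjects carrying the same statistical
structure: a preoperatively more obstructed side whose cavity gap is
narrowed by a severity factor δ ∈ (0, 1), a mildly widened contralateral
side (compensatory mucosal decongestion), and a virtual surgery that moves
the narrowed gap back toward symmetric by a correction fraction ρ
(post-operative gap factor δ + ρ·(1 − δ)) while bilateral turbinate
reduction widens both cavities slightly.  Each subject then runs the full
matched-pressure protocol, and NOSE scores are drawn from a declared
linear-plus-noise generative model on unilateral MOS resistance:

    nose_pre    = clip(round(a + b·NR_mos_pre + ε₁), 0, 20)
    improvement = clip(round(c·(NR_mos_pre − NR_mos_post) + ε₂), 0, nose_pre)

The score model is an artifice for pipeline testing — it makes the
"symptom improvement tracks unilateral MOS resistance reduction" structure
recoverable by the statistics layer — not a claim about physiology.

Reproducibility contract: one integer seed defines the cohort bit-exactly,
and per-subject substreams are keyed by (seed, subject index) so a cohort is
a prefix-stable function of n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ambient import AmbientConditions
from .errors import CohortGenerationError, DomainError
from .geometry import (
    BilateralAirwayModel,
    Region,
    Side,
    SubjectState,
    default_template,
    scale_slit_gap,
    validate_airway,
)
from .protocol import extract_subject_metrics, run_subject_protocol
from .tables import CohortTable

__all__ = [
    "CohortConfig",
    "SubjectDraw",
    "draw_subject_parameters",
    "sample_preop_anatomy",
    "apply_virtual_surgery",
    "generate_nose_scores",
    "generate_cohort",
    "implied_improvement_correlation",
]


@dataclass(frozen=True)
class CohortConfig:
    """Sampling distributions and score-model constants for one cohort.

    Interval fields are (low, high) bounds of uniform draws.  Defaults give
    pre-op unilateral MOS resistances of roughly 0.08–0.31 Pa/(mL·s) and MOS
    flow partitions of roughly 16–45 % on the default template — the
    envelopes reported for symptomatic septal-deviation cohorts.
    """

    n_subjects: int = 8
    seed: int = 0
    deviation_severity: tuple[float, float] = (0.35, 0.75)  # δ, MOS gap factor
    compensatory_los_factor: tuple[float, float] = (1.0, 1.15)
    correction_fraction: tuple[float, float] = (0.6, 1.0)  # ρ
    turbinate_reduction_factor: tuple[float, float] = (1.05, 1.20)
    nose_intercept: float = 5.0  # a
    nose_slope_pre: float = 45.0  # b, (Pa/(mL·s))⁻¹
    nose_slope_improve: float = 60.0  # c, (Pa/(mL·s))⁻¹
    nose_noise_sd_pre: float = 2.5
    nose_noise_sd_improve: float = 3.5
    target_flow: float = 250e-6  # m³/s
    compute_transport: bool = True
    transport_steps: int = 100

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise DomainError("n_subjects must be ≥ 1")
        lo, hi = self.deviation_severity
        if not (0.0 < lo <= hi < 1.0):
            raise DomainError("deviation_severity bounds must satisfy 0 < lo ≤ hi < 1")
        lo, hi = self.correction_fraction
        if not (0.0 <= lo <= hi <= 1.0):
            raise DomainError("correction_fraction bounds must lie in [0, 1]")
        for name in ("compensatory_los_factor", "turbinate_reduction_factor"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi):
                raise DomainError(f"{name} bounds must be positive and ordered")


@dataclass(frozen=True)
class SubjectDraw:
    """All random draws for one subject, in a fixed order."""

    delta: float  # pre-op MOS cavity gap factor
    los_factor: float  # pre-op LOS compensatory gap factor
    rho: float  # surgical correction fraction
    turbinate_factor: float  # bilateral post-op gap multiplier
    mos_side: Side
    eps_pre: float  # score-model noise draws
    eps_improve: float


def subject_rng(seed: int, index: int) -> np.random.Generator:
    """Per-subject substream: stable under changes of cohort size."""
    return np.random.default_rng([seed, index])


def draw_subject_parameters(config: CohortConfig, rng: np.random.Generator) -> SubjectDraw:
    return SubjectDraw(
        delta=rng.uniform(*config.deviation_severity),
        los_factor=rng.uniform(*config.compensatory_los_factor),
        rho=rng.uniform(*config.correction_fraction),
        turbinate_factor=rng.uniform(*config.turbinate_reduction_factor),
        mos_side=Side.LEFT if rng.uniform() < 0.5 else Side.RIGHT,
        eps_pre=rng.normal(0.0, 1.0),
        eps_improve=rng.normal(0.0, 1.0),
    )


def sample_preop_anatomy(
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
    draw: SubjectDraw | None = None,
) -> tuple[BilateralAirwayModel, SubjectDraw]:
    """Sample one preoperative anatomy from the template.

    Returns the model together with the draw that produced it (the surgery
    step needs δ and ρ).  Generation never silently clips: a draw producing
    an invalid model raises :class:`CohortGenerationError`.
    """
    config.validate()
    if draw is None:
        draw = draw_subject_parameters(config, rng)
    gaps = {Side.LEFT: 1.0, Side.RIGHT: 1.0}
    gaps[draw.mos_side] = draw.delta
    gaps[draw.mos_side.other] = draw.los_factor
    model = default_template(
        subject_id=subject_id,
        state=SubjectState.PREOP,
        left_gap_factor=gaps[Side.LEFT],
        right_gap_factor=gaps[Side.RIGHT],
    )
    bad = validate_airway(model)
    if bad:
        raise CohortGenerationError(
            f"sampled anatomy invalid: {'; '.join(bad)}", stage="sample_preop_anatomy"
        )
    return model, draw


def _scale_cavities(model: BilateralAirwayModel, factors: dict[Side, float]) -> BilateralAirwayModel:
    def scaled(path, factor):
        return tuple(
            scale_slit_gap(s, factor) if s.region is Region.AREA2_CAVITY else s
            for s in path
        )

    return BilateralAirwayModel(
        subject_id=model.subject_id,
        state=SubjectState.POSTOP,
        left_path=scaled(model.left_path, factors[Side.LEFT]),
        right_path=scaled(model.right_path, factors[Side.RIGHT]),
        shared_path=model.shared_path,
    )


def apply_virtual_surgery(
    preop_model: BilateralAirwayModel, draw: SubjectDraw
) -> BilateralAirwayModel:
    """Septoplasty + bilateral turbinoplasty on a sampled preop model.

    The MOS cavity gap factor moves from δ to δ + ρ·(1 − δ); both cavities
    are then widened by the turbinate-reduction factor.  Vestibule and
    nasopharynx are untouched.  Because the gap never narrows, the post-op
    MOS resistance can only decrease (cubic-gap law).
    """
    corrected = draw.delta + draw.rho * (1.0 - draw.delta)
    factors = {
        draw.mos_side: (corrected / draw.delta) * draw.turbinate_factor,
        draw.mos_side.other: draw.turbinate_factor,
    }
    post = _scale_cavities(preop_model, factors)
    bad = validate_airway(post)
    if bad:
        raise CohortGenerationError(
            f"postoperative model invalid: {'; '.join(bad)}", stage="apply_virtual_surgery"
        )
    return post


def generate_nose_scores(
    nr_mos_pre: float,
    nr_mos_post: float,
    config: CohortConfig,
    draw: SubjectDraw,
) -> dict[str, int]:
    """NOSE scores (0–20 integers) from the linear-plus-noise score model."""
    a, b, c = config.nose_intercept, config.nose_slope_pre, config.nose_slope_improve
    nose_pre = int(
        np.clip(round(a + b * nr_mos_pre + config.nose_noise_sd_pre * draw.eps_pre), 0, 20)
    )
    improvement = int(
        np.clip(
            round(c * (nr_mos_pre - nr_mos_post) + config.nose_noise_sd_improve * draw.eps_improve),
            0,
            nose_pre,
        )
    )
    return {
        "nose_pre": nose_pre,
        "nose_post": nose_pre - improvement,
        "nose_improvement": improvement,
    }


def implied_improvement_correlation(
    dnr: np.ndarray, config: CohortConfig
) -> float:
    """Model-implied Pearson correlation of improvement with ΔNR.

    Attenuation of a noiseless linear relation by additive score noise:
    ρ = c·σ_ΔNR / √(c²·σ_ΔNR² + σ_ε²) (rounding and clipping perturb this
    only mildly at the default noise scale).
    """
    c, sd = config.nose_slope_improve, config.nose_noise_sd_improve
    s = float(np.std(dnr))
    return c * s / math.hypot(c * s, sd)


def generate_cohort(
    config: CohortConfig, ambient: AmbientConditions | None = None
) -> CohortTable:
    """Sample, operate, solve, and score ``n_subjects`` virtual subjects.

    Returns a :class:`CohortTable` with one PREOP and one POSTOP row per
    subject and a provenance block (config, seed, package version).
    """
    config.validate()
    ambient = ambient or AmbientConditions()
    rows: list[dict] = []
    for i in range(config.n_subjects):
        subject_id = f"V{i + 1}"
        rng = subject_rng(config.seed, i)
        stage = "draw"
        try:
            draw = draw_subject_parameters(config, rng)
            stage = "sample_preop_anatomy"
            preop, _ = sample_preop_anatomy(config, rng, subject_id, draw)
            stage = "apply_virtual_surgery"
            postop = apply_virtual_surgery(preop, draw)
            stage = "protocol"
            result = run_subject_protocol(
                preop,
                postop,
                ambient,
                target_flow=config.target_flow,
                compute_transport=config.compute_transport,
                n_steps=config.transport_steps,
            )
            stage = "metrics"
            pre_m = extract_subject_metrics(result, SubjectState.PREOP)
            post_m = extract_subject_metrics(result, SubjectState.POSTOP)
            stage = "nose_scores"
            scores = generate_nose_scores(
                pre_m.nr_unilateral_mos, post_m.nr_unilateral_mos, config, draw
            )
        except CohortGenerationError as exc:
            raise CohortGenerationError(
                f"subject {subject_id} failed at stage {exc.stage or stage}: {exc}",
                subject_index=i,
                stage=exc.stage or stage,
            ) from exc
        except Exception as exc:  # noqa: BLE001 - annotate subject and stage
            raise CohortGenerationError(
                f"subject {subject_id} failed at stage {stage}: {exc}",
                subject_index=i,
                stage=stage,
            ) from exc
        pre_row = pre_m.to_row()
        post_row = post_m.to_row()
        pre_row["nose"] = scores["nose_pre"]
        post_row["nose"] = scores["nose_post"]
        for row in (pre_row, post_row):
            row["delta"] = draw.delta
            row["rho"] = draw.rho
        rows.extend([pre_row, post_row])
    from . import __version__

    frame = pd.DataFrame(rows)
    provenance = {
        "source": "SYNTHETIC",
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "package_version": __version__,
    }
    return CohortTable(frame, provenance)
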