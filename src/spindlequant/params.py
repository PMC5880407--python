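"""Parameter models for simulation, measurement and classification.

All parameters are plain pydantic models so a run is fully described by one
serializable document (see :class:`RunConfig`).  Units are stated per field:
lengths in micrometres (μm), times in minutes, rates in μm/min, intensities in
camera counts.
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, model_validator

PHENOTYPE_CLASSES = ("normal", "immediate", "failed")


class PhenotypeParams(BaseModel):
    """Kinetic parameters of the three spindle-elongation phenotypes.

    Defaults describe a Securin-depleted (Pds1-AID + auxin) population: a large
    fraction of cells elongate the spindle continuously from the moment of SPB
    separation ("immediate"), the remainder either hold a short metaphase
    spindle before rapid anaphase elongation ("normal") or never elongate past
    6 μm within the hour of observation ("failed").

    Wild-type anchors: cells hold a short (~1–2 μm) metaphase spindle for
    22.4 min on average, lengthening from ~1 to ~2 μm over ~20 min
    (drift 0.05 μm/min) before fast anaphase elongation.
    """

    class_probs: dict[str, float] = Field(
        default_factory=lambda: {"normal": 0.50, "immediate": 0.40, "failed": 0.10},
        description="Mixture probabilities over {normal, immediate, failed}.",
    )
    metaphase_duration_mean: float = Field(22.4, description="Mean metaphase duration, min.")
    metaphase_duration_sd: float = Field(4.0, description="SD of metaphase duration, min.")
    metaphase_duration_min: float = Field(
        1.0, description="Lower truncation of the metaphase-duration distribution, min."
    )
    formation_length_mean: float = Field(1.0, description="Spindle length at formation, μm.")
    metaphase_drift_rate: float = Field(0.05, description="Slow metaphase elongation rate, μm/min.")
    anaphase_rate: float = Field(1.0, description="Fast anaphase elongation rate, μm/min.")
    immediate_rate_range: Tuple[float, float] = Field(
        (0.2, 0.6),
        description="Uniform range of continuous elongation rates for 'immediate' cells, μm/min; "
        "strictly between the metaphase drift rate and the anaphase rate.",
    )
    shortening_event_rate: float = Field(
        0.05, description="Rate of transient spindle-shortening events in 'immediate' cells, events/min."
    )
    shortening_depth: float = Field(0.5, description="Depth of a transient shortening dip, μm.")
    separation_offset_mean: float = Field(
        6.71, description="Mean sister-separation time relative to spindle formation, min (may be negative)."
    )
    separation_offset_sd: float = Field(3.0, description="SD of the separation offset, min.")
    missegregation_prob: float = Field(
        0.3, description="Probability that both sisters segregate to the same pole (fate = failed)."
    )
    length_noise_sd: float = Field(
        0.1, description="Gaussian measurement noise on spindle length, μm (localization error)."
    )
    anaphase_plateau: float = Field(
        8.0, description="Final anaphase spindle length at which elongation stops, μm."
    )
    failed_max_length: float = Field(
        4.0, description="Length ceiling for 'failed' cells, μm (kept well below the 6 μm rule)."
    )

    @model_validator(mode="after")
    def _check(self) -> "PhenotypeParams":
        if set(self.class_probs) - set(PHENOTYPE_CLASSES):
            raise ValueError(f"class_probs keys must be among {PHENOTYPE_CLASSES}")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_probs must sum to 1 (got {total})")
        for name, p in self.class_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"class_probs[{name}] outside [0, 1]")
        if not 0.0 <= self.missegregation_prob <= 1.0:
            raise ValueError("missegregation_prob outside [0, 1]")
        for name in (
            "metaphase_drift_rate",
            "anaphase_rate",
            "shortening_event_rate",
            "metaphase_duration_mean",
            "metaphase_duration_sd",
            "length_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.immediate_rate_range
        if not lo < hi:
            raise ValueError("immediate_rate_range must be increasing")
        if not (self.metaphase_drift_rate < lo and hi < self.anaphase_rate):
            raise ValueError(
                "immediate_rate_range must lie strictly between metaphase_drift_rate "
                "and anaphase_rate"
            )
        return self


class OpticsParams(BaseModel):
    """Acquisition geometry and noise of the (simulated) microscope.

    Defaults match the trajectory assay: 1-min sampling over 60 min, 17
    z-slices every 0.5 μm on a 60× / 1.4 NA widefield system.  Use
    :meth:`cohesin` for the Cohesin assay geometry (5 planes at 200 nm on a
    100× objective).
    """

    pixel_size_xy: float = Field(0.107, description="Lateral pixel size, μm.")
    z_step: float = Field(0.5, description="Axial slice spacing, μm.")
    n_slices: int = Field(17, ge=1, description="Number of z-slices per timepoint.")
    n_y: int = Field(96, ge=8, description="Field height, pixels.")
    n_x: int = Field(96, ge=8, description="Field width, pixels.")
    psf_sigma_xy: float = Field(0.10, gt=0, description="Lateral Gaussian PSF sigma, μm.")
    psf_sigma_z: float = Field(0.35, gt=0, description="Axial Gaussian PSF sigma, μm.")
    background_level: float = Field(50.0, ge=0, description="Uniform camera background, counts.")
    noise_model: Literal["poisson", "gaussian", "none"] = Field(
        "poisson", description="Pixel noise model applied to rendered counts."
    )
    gaussian_sd: float = Field(10.0, ge=0, description="SD for the gaussian noise model, counts.")
    frame_interval: float = Field(1.0, gt=0, description="Time between frames, min.")
    n_frames: int = Field(61, ge=1, description="Number of frames (61 → t = 0..60 min).")
    focus_counts: float = Field(4000.0, gt=0, description="Integrated counts per rendered focus.")

    @classmethod
    def cohesin(cls, **overrides) -> "OpticsParams":
        """Geometry of the pericentric-Cohesin assay: 5 planes at 200 nm, 100×."""
        defaults = dict(
            pixel_size_xy=0.0645,
            z_step=0.2,
            n_slices=5,
            n_y=64,
            n_x=64,
            background_level=20.0,
            n_frames=1,
        )
        defaults.update(overrides)
        return cls(**defaults)


class ClassifierConfig(BaseModel):
    """Thresholds of the three classification rules and the curation heuristics.

    The rules themselves (2 μm within 10 min, 2.5 μm within 15 min, 6 μm within
    60 min) are fixed by the scoring scheme; the inflection and shortening
    thresholds operationalize the visual criteria used for manual curation and
    are declared configuration, not facts about the assay.
    """

    thresh_10: float = Field(2.0, description="Length threshold for the 10-min rule, μm (strict >).")
    thresh_15: float = Field(2.5, description="Length threshold for the 15-min rule, μm (strict >).")
    thresh_reach: float = Field(6.0, description="Anaphase-completion threshold, μm (inclusive ≥).")
    t_rule10: float = Field(10.0, description="Horizon of the first rule, min.")
    t_rule15: float = Field(15.0, description="Horizon of the second rule, min.")
    t_end: float = Field(60.0, description="Observation window for the 6 μm rule, min.")
    slope_ratio_min: float = Field(
        3.0, description="Post/pre slope ratio required for a 'clear' inflection."
    )
    slope_floor: float = Field(
        0.05, description="Floor on the pre-slope used in the ratio test, μm/min."
    )
    sse_min: float = Field(
        0.5, description="Minimum fractional SSE reduction of the two-segment fit vs a single line."
    )
    shortening_min: float = Field(
        0.2, description="Minimum frame-to-frame decrease counted as spindle shortening, μm."
    )
    crossing_mode: Literal["transient", "step"] = Field(
        "transient",
        description="Reading of 'elongated past 2 μm in a single time point': a single-frame "
        "excursion above threshold ('transient') or a one-step jump of ≥ step_min μm ('step').",
    )
    step_min: float = Field(1.0, description="Jump size for the 'step' crossing reading, μm.")
    smooth_window: int = Field(
        3, description="Moving-median window applied inside inflection detection only, frames."
    )


class RunConfig(BaseModel):
    """Complete description of an end-to-end run (simulate → classify → stats)."""

    seed: int = Field(0, ge=0, description="Master seed; all per-cell seeds derive from it.")
    n_cells: int = Field(100, ge=0, description="Number of cells to simulate.")
    phenotype: PhenotypeParams = Field(default_factory=PhenotypeParams)
    optics: OpticsParams = Field(default_factory=OpticsParams)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    render_stacks: bool = Field(False, description="Also render image stacks for each cell.")
    make_plots: bool = Field(True, description="Render the per-cell trace figure.")

    def config_hash(self) -> str:
        """Stable SHA-256 over the serialized configuration (first 12 hex digits)."""
        import hashlib
        import json

        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DEFAULT_TRACE_COLORS = {"normal": "black", "immediate": "green", "failed": "red"}
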