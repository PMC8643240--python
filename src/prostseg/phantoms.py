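"""Synthetic T2WI-like prostate phantoms with ground-truth masks and case records.

The phantom is an axial 2D slice: an elliptical gland (transverse axis about
4 cm, antero-posterior axis about 2 cm — the textbook "flat chestnut"
dimensions) centred in the image, split into a concentric central zone
(class 1) and a surrounding marginal/peripheral zone (class 2), embedded in
surrounding tissue (class 0).  Intensities follow the T2WI convention: the
marginal zone is bright, the central zone intermediate, and cancerous lesions
are low-signal foci that replace gland tissue.  Gaussian noise is added on
top of the per-class mean intensities.

Every stochastic operation takes an explicit integer seed and derives its own
:class:`numpy.random.Generator`; nothing touches NumPy's global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "PhantomParams",
    "CaseRecord",
    "PhantomCase",
    "ParameterError",
    "PlacementError",
    "CLASS_SURROUNDING",
    "CLASS_CENTRAL",
    "CLASS_MARGINAL",
    "STAGES",
    "generate_phantom",
    "insert_lesion",
    "sample_case_record",
    "generate_cohort",
]

CLASS_SURROUNDING = 0
CLASS_CENTRAL = 1
CLASS_MARGINAL = 2

#: Clinical T-stage labels in increasing order of extent.
STAGES = ("T1", "T2a", "T2b", "T2c", "T3", "T4")


class ParameterError(ValueError):
    """Raised when phantom parameters are geometrically or numerically invalid."""


class PlacementError(ValueError):
    """Raised when a lesion centre falls outside the gland."""


# Default categorical / log-normal sampling regimes for clinical records.
# The cancer Gleason mix is weighted toward scores 6-7 with a tail to 10,
# PSA is log-normal around a median of 12 ng/mL, and stages span T1-T4;
# hyperplasia records sit at the benign floor (Gleason 1+1, PSA median 4).
GLEASON_SCORE_PROBS_CANCER: Mapping[int, float] = {6: 0.35, 7: 0.40, 8: 0.15, 9: 0.08, 10: 0.02}
STAGE_PROBS_CANCER: Mapping[str, float] = {
    "T1": 0.20, "T2a": 0.20, "T2b": 0.25, "T2c": 0.15, "T3": 0.15, "T4": 0.05,
}
PSA_MEDIAN_CANCER = 12.0
PSA_LOG_SD_CANCER = 0.6
PSA_MEDIAN_HYPERPLASIA = 4.0
PSA_LOG_SD_HYPERPLASIA = 0.5


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and noise parameters of the synthetic slice.

    Lengths are in millimetres; ``pixel_spacing`` converts to pixels.
    ``central_fraction`` scales the central-zone ellipse relative to the whole
    gland and must lie strictly inside (0, 1) so the marginal zone is
    non-empty.
    """

    image_height: int = 64
    image_width: int = 64
    pixel_spacing: float = 1.0  # mm per pixel
    gland_transverse_axis: float = 40.0  # mm, full axis (left-right)
    gland_ap_axis: float = 20.0  # mm, full axis (antero-posterior)
    central_fraction: float = 0.55
    intensity_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "surrounding": 90.0,
            "central": 140.0,
            "marginal": 190.0,
            "lesion": 70.0,
        }
    )
    noise_sd: float = 10.0
    lesion_probability_given_cancer: float = 1.0
    lesion_radius_range: tuple[int, int] = (3, 8)  # pixels
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ParameterError("image dimensions must be positive")
        if self.pixel_spacing <= 0:
            raise ParameterError("pixel_spacing must be positive")
        if self.gland_transverse_axis <= 0 or self.gland_ap_axis <= 0:
            raise ParameterError("gland axes must be positive")
        if not (0.0 < self.central_fraction < 1.0):
            raise ParameterError("central_fraction must lie strictly in (0, 1)")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if not (0.0 <= self.lesion_probability_given_cancer <= 1.0):
            raise ParameterError("lesion_probability_given_cancer must be in [0, 1]")
        a_px = self.gland_transverse_axis / self.pixel_spacing
        b_px = self.gland_ap_axis / self.pixel_spacing
        if a_px > self.image_width or b_px > self.image_height:
            raise ParameterError(
                f"gland ({a_px:.1f} x {b_px:.1f} px) exceeds the "
                f"{self.image_height} x {self.image_width} image extent"
            )
        required = {"surrounding", "central", "marginal", "lesion"}
        missing = required - set(self.intensity_means)
        if missing:
            raise ParameterError(f"intensity_means missing classes: {sorted(missing)}")


@dataclass
class CaseRecord:
    """One patient's diagnosis, histology grade, PSA and clinical stage.

    ``gleason_score`` is the sum of the two most prevalent pattern grades
    (each 1-5).  ``risk_group`` is assigned only for cancer cases.
    """

    case_id: str
    true_class: Literal["cancer", "hyperplasia"]
    gleason_primary: int
    gleason_secondary: int
    gleason_score: int
    psa: float
    clinical_stage: str
    risk_group: str | None = None

    def __post_init__(self) -> None:
        if self.true_class not in ("cancer", "hyperplasia"):
            raise ValueError(f"unknown true_class {self.true_class!r}")
        if not (1 <= self.gleason_primary <= 5 and 1 <= self.gleason_secondary <= 5):
            raise ValueError("Gleason pattern grades must be in 1-5")
        if self.gleason_score != self.gleason_primary + self.gleason_secondary:
            raise ValueError("gleason_score must equal primary + secondary")
        if self.psa < 0:
            raise ValueError("PSA must be non-negative")
        if self.clinical_stage not in STAGES:
            raise ValueError(f"unknown clinical stage {self.clinical_stage!r}")
        if self.risk_group is not None and self.true_class != "cancer":
            raise ValueError("risk_group may be set only for cancer cases")


@dataclass
class PhantomCase:
    """A cohort entry: image, ground-truth mask, lesion mask and case record."""

    image: np.ndarray
    mask: np.ndarray
    lesion_mask: np.ndarray
    record: CaseRecord


def _gland_geometry(params: PhantomParams) -> tuple[float, float, float, float]:
    """Return (row_center, col_center, semi_axis_rows_px, semi_axis_cols_px)."""
    cy = (params.image_height - 1) / 2.0
    cx = (params.image_width - 1) / 2.0
    # transverse axis runs left-right (columns), AP axis front-back (rows)
    a_col = (params.gland_transverse_axis / 2.0) / params.pixel_spacing
    b_row = (params.gland_ap_axis / 2.0) / params.pixel_spacing
    return cy, cx, b_row, a_col


def _make_mask(params: PhantomParams) -> np.ndarray:
    cy, cx, b_row, a_col = _gland_geometry(params)
    rows = np.arange(params.image_height)[:, None]
    cols = np.arange(params.image_width)[None, :]
    r2 = ((rows - cy) / b_row) ** 2 + ((cols - cx) / a_col) ** 2
    mask = np.zeros((params.image_height, params.image_width), dtype=np.uint8)
    mask[r2 <= 1.0] = CLASS_MARGINAL
    f = params.central_fraction
    r2c = ((rows - cy) / (f * b_row)) ** 2 + ((cols - cx) / (f * a_col)) ** 2
    mask[r2c <= 1.0] = CLASS_CENTRAL
    return mask


def _noiseless_image(params: PhantomParams, mask: np.ndarray) -> np.ndarray:
    means = params.intensity_means
    lut = np.array(
        [means["surrounding"], means["central"], means["marginal"]], dtype=np.float64
    )
    return lut[mask]


def generate_phantom(
    params: PhantomParams, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom slice and its three-class ground-truth mask.

    Returns ``(image, mask)`` with identical shapes; the image is the
    per-class mean intensity plus zero-mean Gaussian noise of standard
    deviation ``params.noise_sd``.  Identical ``(params, seed)`` pairs give
    bit-identical outputs.
    """
    params.validate()
    mask = _make_mask(params)
    image = _noiseless_image(params, mask)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    return image, mask


def insert_lesion(
    image: np.ndarray,
    mask: np.ndarray,
    center: tuple[int, int],
    radius: float,
    lesion_intensity: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint a low-signal lesion disc into the gland.

    Pixels within ``radius`` of ``center`` (row, col) that lie inside the
    gland (classes 1 or 2) are set to ``lesion_intensity``.  The tissue-class
    mask is left unchanged; the returned boolean lesion mask records exactly
    which pixels were painted.  ``seed`` is accepted for API symmetry but
    unused: the fill is deterministic.

    Raises :class:`PlacementError` if ``center`` is not a gland pixel.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    r0, c0 = int(center[0]), int(center[1])
    if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]):
        raise PlacementError(f"lesion centre {center} outside the image")
    if mask[r0, c0] == CLASS_SURROUNDING:
        raise PlacementError(f"lesion centre {center} outside the gland")
    rows = np.arange(mask.shape[0])[:, None]
    cols = np.arange(mask.shape[1])[None, :]
    disc = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2
    lesion = disc & (mask != CLASS_SURROUNDING)
    out = np.array(image, dtype=np.float64, copy=True)
    out[lesion] = lesion_intensity
    return out, lesion


def _split_gleason_score(score: int, rng: np.random.Generator) -> tuple[int, int]:
    """Pick a (primary, secondary) pattern pair summing to ``score``."""
    lo = max(1, score - 5)
    hi = min(5, score - 1)
    primary = int(rng.integers(lo, hi + 1))
    return primary, score - primary


def sample_case_record(
    true_class: Literal["cancer", "hyperplasia"],
    seed: int,
    case_id: str = "case",
) -> CaseRecord:
    """Draw one clinical record from the declared sampling regimes.

    Cancer: Gleason score categorical over 6-10, PSA log-normal (median 12
    ng/mL), stage categorical over T1-T4.  Hyperplasia: Gleason floor (1+1),
    PSA log-normal (median 4 ng/mL), stage T1.  Reproducible under ``seed``;
    the risk group is left unset (assigned later by the stratifier).
    """
    rng = np.random.default_rng(seed)
    if true_class == "cancer":
        scores = np.array(sorted(GLEASON_SCORE_PROBS_CANCER))
        probs = np.array([GLEASON_SCORE_PROBS_CANCER[s] for s in scores])
        score = int(rng.choice(scores, p=probs))
        primary, secondary = _split_gleason_score(score, rng)
        psa = float(rng.lognormal(np.log(PSA_MEDIAN_CANCER), PSA_LOG_SD_CANCER))
        stage_names = list(STAGE_PROBS_CANCER)
        stage = str(rng.choice(stage_names, p=[STAGE_PROBS_CANCER[s] for s in stage_names]))
    elif true_class == "hyperplasia":
        primary = secondary = 1
        score = 2
        psa = float(rng.lognormal(np.log(PSA_MEDIAN_HYPERPLASIA), PSA_LOG_SD_HYPERPLASIA))
        stage = "T1"
    else:
        raise ValueError(f"unknown true_class {true_class!r}")
    return CaseRecord(
        case_id=case_id,
        true_class=true_class,
        gleason_primary=primary,
        gleason_secondary=secondary,
        gleason_score=score,
        psa=psa,
        clinical_stage=stage,
        risk_group=None,
    )


def _case_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(master_seed).spawn(n)


def generate_cohort(
    n_cancer: int,
    n_hyperplasia: int,
    params: PhantomParams | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a full cohort of phantom cases with clinical records.

    Cancer cases receive a low-signal lesion with probability
    ``params.lesion_probability_given_cancer`` (centre uniform over gland
    pixels, radius uniform over ``params.lesion_radius_range``), painted on
    the noiseless image before noise is added.  Per-case seeds are derived
    deterministically from the master ``seed``, so two cohorts from the same
    master seed are identical case by case.
    """
    if n_cancer < 0 or n_hyperplasia < 0:
        raise ValueError("case counts must be non-negative")
    if params is None:
        params = PhantomParams()
    params.validate()

    labels = ["cancer"] * n_cancer + ["hyperplasia"] * n_hyperplasia
    base_mask = _make_mask(params)
    base_image = _noiseless_image(params, base_mask)
    gland_pixels = np.argwhere(base_mask != CLASS_SURROUNDING)
    cases: list[PhantomCase] = []
    for i, (true_class, ss) in enumerate(zip(labels, _case_seeds(seed, len(labels)))):
        rng = np.random.default_rng(ss)
        case_id = f"case_{i:03d}"
        image = base_image.copy()
        lesion_mask = np.zeros_like(base_mask, dtype=bool)
        if true_class == "cancer" and rng.random() < params.lesion_probability_given_cancer:
            center = gland_pixels[rng.integers(len(gland_pixels))]
            lo, hi = params.lesion_radius_range
            radius = int(rng.integers(lo, hi + 1))
            image, lesion_mask = insert_lesion(
                image, base_mask, tuple(center), radius,
                params.intensity_means["lesion"],
            )
        if params.noise_sd > 0:
            image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
        record = sample_case_record(
            true_class, seed=int(rng.integers(2**31)), case_id=case_id
        )
        cases.append(PhantomCase(image=image, mask=base_mask.copy(),
                                 lesion_mask=lesion_mask, record=record))
    return cases
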