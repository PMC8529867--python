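"""Synthetic texture phantoms and full synthetic study cohorts.

The private patient cohort behind the analysis is not available, so every
downstream stage is exercised on synthetic data with the same statistical
structure:

* **lesion phantoms** — a circular lesion on a uniform background whose
  heterogeneity is controlled by the three classic components of texture
  phantom studies: object size, object density (contrast) and object
  number, plus additive Gaussian noise;
* **paired timepoints** — a baseline/post-therapy phantom pair whose
  histogram entropy is nudged in a requested direction by scaling the noise
  level (a monotone lever on the entropy of the integer-binned histogram);
* **survival outcomes** — event times from an exponential proportional-
  hazards model ``h(t) = lambda0 * exp(beta' x_std)`` on standardized
  patient-level features, with independent exponential censoring.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import aggregate, texture
from .imaging import (
    BASELINE,
    HU_MAX,
    HU_MIN,
    POST,
    ImageSlice,
    LesionRecord,
    make_lesion_record,
)


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class TexturePhantomSpec:
    """Parameters of one lesion phantom.

    ``object_count`` discs of diameter ``object_diameter_mm`` at a uniform
    HU offset ``object_contrast_hu`` are dropped uniformly at random inside
    the lesion; overlapping discs add the contrast once (union, not sum).
    """

    lesion_diameter_mm: float = 15.0
    object_diameter_mm: float = 4.0
    object_count: int = 6
    object_contrast_hu: float = 60.0
    background_hu: float = 40.0
    noise_sd_hu: float = 10.0
    pixel_spacing_mm: float = 0.98
    grid_size_px: int = 48
    seed: int = 0
    allow_small_lesion: bool = False

    def validate(self) -> None:
        if self.lesion_diameter_mm < 5.0 and not self.allow_small_lesion:
            raise PhantomError(
                "lesion below the 5 mm analysis threshold; set allow_small_lesion "
                "to generate it deliberately"
            )
        if self.object_count > 0 and self.object_diameter_mm >= self.lesion_diameter_mm:
            raise PhantomError("objects must be smaller than the lesion")
        if self.object_count < 0:
            raise PhantomError("object_count must be non-negative")
        if self.noise_sd_hu < 0:
            raise PhantomError("noise SD must be non-negative")
        if self.pixel_spacing_mm <= 0 or self.grid_size_px <= 0:
            raise PhantomError("spacing and grid size must be positive")
        if self.grid_size_px * self.pixel_spacing_mm < 2.0 * self.lesion_diameter_mm:
            raise PhantomError(
                "grid extent must be at least twice the lesion diameter "
                "(room for the filter support)"
            )


def generate_lesion_image(
    spec: TexturePhantomSpec,
    patient_id: str = "",
    slice_id: str = "phantom",
    timepoint: str = BASELINE,
) -> tuple[ImageSlice, np.ndarray]:
    """Render one lesion phantom; returns the slice and the lesion mask."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = spec.grid_size_px
    s = spec.pixel_spacing_mm
    # pixel-center coordinates in mm; lesion centered on the grid
    coords = (np.arange(g) + 0.5) * s
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    cx = cy = g * s / 2.0
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    lesion_r = spec.lesion_diameter_mm / 2.0
    mask = r2 <= lesion_r**2

    hu = np.full((g, g), float(spec.background_hu))
    if spec.object_count > 0:
        covered = np.zeros((g, g), dtype=bool)
        obj_r = spec.object_diameter_mm / 2.0
        # uniform placement inside the lesion disc
        radii = lesion_r * np.sqrt(rng.random(spec.object_count))
        angles = rng.random(spec.object_count) * 2.0 * math.pi
        for rad, ang in zip(radii, angles):
            ox = cx + rad * math.cos(ang)
            oy = cy + rad * math.sin(ang)
            covered |= (xx - ox) ** 2 + (yy - oy) ** 2 <= obj_r**2
        hu[covered] += spec.object_contrast_hu
    if spec.noise_sd_hu > 0:
        hu += rng.normal(0.0, spec.noise_sd_hu, size=(g, g))

    pixels = np.clip(np.rint(hu), HU_MIN, HU_MAX).astype(np.int32)
    image = ImageSlice(
        pixels=pixels,
        pixel_spacing_mm=(s, s),
        slice_id=slice_id,
        patient_id=patient_id,
        timepoint=timepoint,
    )
    return image, mask


def measured_entropy(image: ImageSlice, mask: np.ndarray) -> float:
    """Unfiltered (SSF = 0) histogram entropy of the in-mask HU values, bits."""
    binned = texture.integer_bin(image.pixels[mask])
    return texture.compute_stats(binned).entropy


def _derived_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed & 0x7FFFFFFF, salt]).generate_state(1)[0] % (2**31))


@dataclass
class PairedLesion:
    """Baseline/post-therapy phantom pair sharing one lesion id."""

    baseline: LesionRecord
    post: LesionRecord
    requested_shift: float
    feasible: bool
    message: str = ""


def generate_paired_timepoints(
    spec: TexturePhantomSpec,
    entropy_shift: float,
    lesion_id: str = "L1",
    patient_id: str = "",
) -> PairedLesion:
    """Generate a baseline phantom and a post-therapy phantom whose measured
    SSF = 0 entropy moves by roughly ``entropy_shift`` (relative).

    The shift is realised by scaling the noise SD: for integer-binned
    Gaussian noise the entropy is approximately ``log2(sigma) + const``, so
    a relative target ``H1 = H0 * (1 + shift)`` maps to
    ``sigma_post = sigma * 2**(H0 * shift)``.  An unreachable request (no
    noise to scale, or entropy already zero with a decrease requested) is
    flagged on the output rather than silently ignored.
    """
    if abs(entropy_shift) >= 1:
        raise PhantomError("|entropy_shift| must be < 1")
    base_image, base_mask = generate_lesion_image(
        spec, patient_id=patient_id, slice_id=f"{lesion_id}_{BASELINE}", timepoint=BASELINE
    )
    baseline = make_lesion_record(base_image, base_mask, lesion_id)

    feasible, message = True, ""
    post_sigma = spec.noise_sd_hu
    if entropy_shift != 0.0:
        h0 = measured_entropy(base_image, base_mask)
        if spec.noise_sd_hu == 0.0:
            feasible = False
            message = "no noise to scale: entropy shift unreachable"
        elif h0 == 0.0 and entropy_shift < 0:
            feasible = False
            message = "baseline entropy already 0: negative shift unreachable"
        else:
            post_sigma = spec.noise_sd_hu * 2.0 ** (h0 * entropy_shift)

    post_spec = replace(
        spec, noise_sd_hu=post_sigma, seed=_derived_seed(spec.seed, 7919)
    )
    post_image, post_mask = generate_lesion_image(
        post_spec, patient_id=patient_id, slice_id=f"{lesion_id}_{POST}", timepoint=POST
    )
    flags = () if feasible else ("entropy_shift_unreachable",)
    post = make_lesion_record(post_image, post_mask, lesion_id, flags=flags)
    return PairedLesion(
        baseline=baseline,
        post=post,
        requested_shift=entropy_shift,
        feasible=feasible,
        message=message,
    )


# ---------------------------------------------------------------------------
# Survival generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Study-level parameters of a synthetic cohort.

    ``effect_coefficients`` are log-hazard coefficients per *standardized*
    feature unit in the data-generating hazard
    ``h(t) = baseline_hazard * exp(beta' x_std)``.  The defaults plant a
    protective baseline-kurtosis effect and a delta-entropy effect, the two
    marker families the analysis is built to detect.  PFS events are drawn
    from the same linear predictor with the hazard scaled by
    ``pfs_hazard_factor``.
    """

    n_patients: int = 150
    lesions_per_patient: tuple[int, int] = (1, 3)
    effect_coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"kurtosis_ssf2": -0.6, "perc_entropy_ssf4": 0.6}
    )
    baseline_hazard: float = math.log(2.0) / 30.0  # per month; median ~30 mo at x=0
    censoring_rate: float = math.log(2.0) / 60.0  # per month
    pfs_hazard_factor: float = 2.0
    entropy_shift_range: tuple[float, float] = (-0.15, 0.15)
    ldh_median: float = 389.0  # U/L
    ldh_log_sd: float = 0.35
    ldh_shift_sd: float = 0.18  # SD of the relative pre->post LDH change
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise PhantomError("a cohort needs at least 2 patients")
        lo, hi = self.lesions_per_patient
        if lo < 1 or hi < lo:
            raise PhantomError("lesions_per_patient must be a range with 1 <= lo <= hi")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise PhantomError("hazard and censoring rates must be positive")
        if not (-1 < self.entropy_shift_range[0] <= self.entropy_shift_range[1] < 1):
            raise PhantomError("entropy_shift_range must be within (-1, 1)")


def draw_survival(
    features: pd.DataFrame,
    coefficients: Mapping[str, float],
    baseline_hazard: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw right-censored exponential proportional-hazards outcomes.

    ``features`` is a patient-indexed table; each feature named in
    ``coefficients`` is standardized to zero mean / unit variance before
    entering the linear predictor.  Returns a frame with ``time_months``
    and ``event`` columns indexed like ``features``.
    """
    lp = np.zeros(len(features))
    for name, beta in coefficients.items():
        if name not in features.columns:
            raise PhantomError(f"effect feature {name!r} not in the feature table")
        col = features[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            bad = features.index[~np.isfinite(col)][0]
            raise PhantomError(f"non-finite value of {name!r} for patient {bad}")
        sd = col.std()
        if sd == 0:
            raise PhantomError(f"feature {name!r} has zero variance across patients")
        lp += beta * (col - col.mean()) / sd
    if not np.all(np.isfinite(lp)):
        bad = features.index[~np.isfinite(lp)][0]
        raise PhantomError(f"non-finite linear predictor for patient {bad}")
    event_t = rng.exponential(1.0 / (baseline_hazard * np.exp(lp)))
    if censoring_rate > 0:
        censor_t = rng.exponential(1.0 / censoring_rate, size=len(features))
    else:
        censor_t = np.full(len(features), np.inf)
    time = np.minimum(event_t, censor_t)
    return pd.DataFrame(
        {"time_months": time, "event": event_t <= censor_t}, index=features.index
    )


def generate_survival(
    features: pd.DataFrame,
    spec: CohortSpec,
    seed: int | None = None,
    hazard_scale: float = 1.0,
) -> pd.DataFrame:
    """Spec-driven wrapper around :func:`draw_survival`."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    return draw_survival(
        features,
        spec.effect_coefficients,
        spec.baseline_hazard * hazard_scale,
        spec.censoring_rate,
        rng,
    )


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A full synthetic study held in memory.

    ``lesions`` maps patient id to that patient's :class:`PairedLesion`
    list; ``patient_table`` is the analysis-ready wide table (baseline and
    delta features, clinical covariates, OS/PFS outcomes).
    """

    spec: CohortSpec
    lesions: dict[str, list[PairedLesion]]
    patient_table: pd.DataFrame


def _patient_phantom_specs(
    rng: np.random.Generator, spec: CohortSpec, patient_seed: int
) -> list[TexturePhantomSpec]:
    """Draw per-lesion phantom parameters for one patient.

    Parameter ranges are chosen to span visibly different heterogeneity:
    lesion diameters 10-22 mm, 0-12 objects of 2-6 mm at 30-90 HU contrast,
    noise 6-14 HU, on the scanner's 0.98 mm pixel grid.
    """
    lo, hi = spec.lesions_per_patient
    n_lesions = int(rng.integers(lo, hi + 1))
    specs = []
    for j in range(n_lesions):
        diameter = float(rng.uniform(10.0, 22.0))
        spacing = 0.98
        grid = int(math.ceil(2.2 * diameter / spacing / 2.0) * 2)
        specs.append(
            TexturePhantomSpec(
                lesion_diameter_mm=diameter,
                object_diameter_mm=float(rng.uniform(2.0, min(6.0, diameter / 2.0))),
                object_count=int(rng.integers(0, 13)),
                object_contrast_hu=float(rng.uniform(30.0, 90.0)),
                background_hu=40.0,
                noise_sd_hu=float(rng.uniform(6.0, 14.0)),
                pixel_spacing_mm=spacing,
                grid_size_px=grid,
                seed=_derived_seed(patient_seed, 100 + j),
            )
        )
    return specs


def generate_cohort(
    spec: CohortSpec,
    sign_convention: str = aggregate.AS_PRINTED,
) -> Cohort:
    """Generate a complete synthetic study with planted survival effects.

    Per patient: lesion phantoms with randomly drawn heterogeneity, a
    post-therapy twin of each lesion with a patient-level entropy shift,
    feature extraction and aggregation exactly as the analysis pipeline
    performs them, simulated LDH / metastatic-site counts, and OS / PFS
    outcomes drawn from the proportional-hazards model on the aggregated
    features.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lesions: dict[str, list[PairedLesion]] = {}
    rows = []
    for i in range(spec.n_patients):
        pid = f"P{i:03d}"
        patient_seed = _derived_seed(spec.seed, i)
        shift = float(rng.uniform(*spec.entropy_shift_range))
        pairs = []
        base_fvs, post_fvs = [], []
        for j, pspec in enumerate(_patient_phantom_specs(rng, spec, patient_seed)):
            pair = generate_paired_timepoints(
                pspec, shift, lesion_id=f"{pid}_L{j}", patient_id=pid
            )
            pairs.append(pair)
            base_fvs.append(texture.extract_features(pair.baseline))
            post_fvs.append(texture.extract_features(pair.post))
        lesions[pid] = pairs
        base_pf = aggregate.average_over_lesions(base_fvs)
        delta = aggregate.aggregate_delta(base_fvs, post_fvs, convention=sign_convention)

        ldh_pre = float(
            np.exp(rng.normal(math.log(spec.ldh_median), spec.ldh_log_sd))
        )
        ldh_post = float(ldh_pre * max(0.1, 1.0 + rng.normal(0.0, spec.ldh_shift_sd)))
        n_sites = int(1 + rng.poisson(0.7))
        row = {"patient_id": pid, "n_lesions": base_pf.n_lesions}
        row.update(base_pf.values.to_dict())
        row.update(delta.values.to_dict())
        row.update({"ldh_pre": ldh_pre, "ldh_post": ldh_post, "n_sites": n_sites})
        rows.append(row)

    table = pd.DataFrame(rows).set_index("patient_id")
    os_out = generate_survival(table, spec, seed=_derived_seed(spec.seed, 424242))
    pfs_out = generate_survival(
        table,
        spec,
        seed=_derived_seed(spec.seed, 515151),
        hazard_scale=spec.pfs_hazard_factor,
    )
    table["os_months"] = os_out["time_months"]
    table["os_event"] = os_out["event"].astype(int)
    table["pfs_months"] = pfs_out["time_months"]
    table["pfs_event"] = pfs_out["event"].astype(int)
    return Cohort(spec=spec, lesions=lesions, patient_table=table.reset_index())


def write_cohort(cohort: Cohort, out_dir, overwrite: bool = False) -> None:
    """Write a cohort to disk in the pipeline's expected input layout.

    ``images/`` text-grid HU files with JSON spacing sidecars, ``masks/``
    0/1 text grids, ``manifest.json`` listing every lesion/timepoint, and
    ``clinical.csv``.
    """
    import json
    from pathlib import Path

    from . import imaging

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise PhantomError(f"output directory {out} is not empty (use overwrite)")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    manifest = []
    for pid, pairs in sorted(cohort.lesions.items()):
        for pair in pairs:
            for rec in (pair.baseline, pair.post):
                stem = f"{rec.lesion_id}_{rec.timepoint}"
                img_path = out / "images" / f"{stem}.txt"
                mask_path = out / "masks" / f"{stem}.txt"
                imaging.write_slice(rec.image, img_path, fmt="text")
                imaging.write_mask(rec.mask, mask_path)
                manifest.append(
                    {
                        "patient_id": pid,
                        "lesion_id": rec.lesion_id,
                        "timepoint": rec.timepoint,
                        "image": str(img_path.relative_to(out)),
                        "roi": str(mask_path.relative_to(out)),
                    }
                )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    clinical_cols = [
        "patient_id",
        "ldh_pre",
        "ldh_post",
        "n_sites",
        "os_months",
        "os_event",
        "pfs_months",
        "pfs_event",
    ]
    cohort.patient_table[clinical_cols].to_csv(out / "clinical.csv", index=False)
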