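"""Synthetic test-retest cohort generator.

Emulates the statistical structure of a paired-scan PET study: a cohort of
patients each carrying several lesions, scanned twice a few days apart with
no biological change in between.  Observed test-retest differences are pure
measurement variability, generated here as

* a per-patient multiplicative bias on the retest scan (log-scale SD ``tau``,
  shared by all of a patient's lesions — scanner calibration, dose, uptake
  time), and
* independent per-lesion, per-feature, per-scan log-normal noise
  (log-scale SD ``sigma_w``).

True lesion volumes and uptakes are log-normal.  Two output modes:

``generate_paired_features``
    directly emits the matched test/retest feature table, plus a ground-truth
    record for parameter-recovery tests.

``generate_phantom_pair``
    voxelizes one patient's lesions as ellipsoidal uptake plateaus on a 3-D
    grid and perturbs the retest mask by random boundary-voxel flips, so that
    volume errors arise from segmentation jitter the way they do for real
    small lesions.

The log-ratio ln(retest/test) of a directly noised feature has standard
deviation sqrt(tau^2 + 2 sigma_w^2); this analytically known estimand is what
the repeatability statistics are validated against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError

__all__ = [
    "FEATURES",
    "CohortParams",
    "GroundTruth",
    "PhantomPair",
    "generate_paired_features",
    "generate_phantom_pair",
]

#: Canonical feature names, in report order.
FEATURES = ("suv_max", "suv_mean", "suv_total", "volume_cc")

# Features that receive their own independent measurement noise; suv_total is
# derived as suv_mean * volume_cc so the identity holds on both scans.
_NOISED = ("suv_max", "suv_mean", "volume_cc")

_BACKGROUND_SUV = 0.2
_PLACEMENT_ATTEMPTS = 500


@dataclass(frozen=True)
class CohortParams:
    """Generative knobs of the synthetic test-retest cohort.

    Defaults emulate a metastatic-prostate-cancer PSMA-PET cohort of 22
    patients with ~300 matched lesions in total.  The log-volume location and
    scale are set so that roughly 64% of lesions exceed 1 cm^3 and 54% exceed
    1.5 cm^3; bias and noise SDs are set so that SUV wCOV is on the order of
    9% and the 95% limits of agreement span roughly -25% to +35%.
    """

    n_patients: int = 22
    lesions_per_patient_mean: float = 13.5  # Poisson mean, min 1 enforced
    log_volume_mean: float = 0.56  # ln cm^3
    log_volume_sd: float = 1.57
    log_uptake_mean: float = 1.4  # ln SUV_mean
    log_uptake_sd: float = 0.6
    patient_bias_sd: float = 0.09  # tau, log scale
    lesion_noise_sd: float = 0.09  # sigma_w, log scale
    jitter_boundary_prob: float = 0.2
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if self.lesions_per_patient_mean <= 0:
            raise ParameterError("lesions_per_patient_mean must be positive")
        for name in ("log_volume_sd", "log_uptake_sd", "patient_bias_sd", "lesion_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if not 0.0 <= self.jitter_boundary_prob <= 1.0:
            raise ParameterError("jitter_boundary_prob must lie in [0, 1]")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ParameterError("voxel_size_mm entries must be positive")
        if any(int(s) < 1 for s in self.grid_shape):
            raise ParameterError("grid_shape entries must be >= 1")

    def with_(self, **kwargs) -> "CohortParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Per-lesion latent values behind a generated cohort.

    ``lesions`` has one row per lesion: patient_id, lesion_id, true_log_volume,
    true_log_uptake, true_log_suv_max, patient_bias.
    """

    lesions: pd.DataFrame
    params: CohortParams


@dataclass
class PhantomPair:
    """A voxelized test/retest scan pair for one patient.

    Labels use 0 for background and k >= 1 for lesion k; the same label
    denotes the same lesion on both time points (``truth`` records the
    correspondence explicitly for matching-recovery tests).
    """

    suv_test: np.ndarray
    suv_retest: np.ndarray
    labels_test: np.ndarray
    labels_retest: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    patient_id: str
    truth: pd.DataFrame = field(repr=False)  # test_label, retest_label, voxel volumes, plateau


def _patient_rng(params: CohortParams, patient_index: int) -> np.random.Generator:
    # One spawned stream per patient so that growing the cohort appends new
    # patients without perturbing earlier ones.
    child = np.random.SeedSequence(params.seed).spawn(patient_index + 1)[patient_index]
    return np.random.default_rng(child)


def _patient_id(i: int) -> str:
    return f"P{i + 1:03d}"


def _draw_patient(params: CohortParams, rng: np.random.Generator):
    """Shared latent draws for one patient: lesion count, bias, truths.

    Draw order is fixed (count, bias, volumes, uptakes, peak offsets) and is
    part of the reproducibility contract.
    """
    n_lesions = max(1, int(rng.poisson(params.lesions_per_patient_mean)))
    bias = rng.normal(0.0, params.patient_bias_sd) if params.patient_bias_sd > 0 else 0.0
    log_vol = rng.normal(params.log_volume_mean, params.log_volume_sd, n_lesions)
    log_upt = rng.normal(params.log_uptake_mean, params.log_uptake_sd, n_lesions)
    # SUV_max sits above SUV_mean by a per-lesion log offset (peak sharpness).
    peak = np.abs(rng.normal(0.35, 0.10, n_lesions))
    return n_lesions, bias, log_vol, log_upt, peak


def generate_paired_features(params: CohortParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the matched test/retest lesion feature table.

    Returns a wide pair table with one row per matched lesion and columns
    ``patient_id``, ``lesion_id`` and ``{feature}_test`` / ``{feature}_retest``
    for each of :data:`FEATURES`, together with the :class:`GroundTruth`.

    SUV_max, SUV_mean and volume each receive independent log-normal noise of
    SD ``lesion_noise_sd`` on each scan; the retest scan is additionally
    scaled by the patient's bias factor ``exp(b_i)``.  SUV_total is the
    product SUV_mean x volume on each scan, so it carries both noise terms
    and the bias factor squared — volumetric uptake inherits variability from
    both the intensity and the delineation, as it does in practice.
    """
    rows = []
    truth_rows = []
    for i in range(params.n_patients):
        rng = _patient_rng(params, i)
        pid = _patient_id(i)
        n_lesions, bias, log_vol, log_upt, peak = _draw_patient(params, rng)
        true_log = {
            "suv_max": log_upt + peak,
            "suv_mean": log_upt,
            "volume_cc": log_vol,
        }
        noise = {
            (f, tp): rng.normal(0.0, params.lesion_noise_sd, n_lesions)
            if params.lesion_noise_sd > 0
            else np.zeros(n_lesions)
            for f in _NOISED
            for tp in ("test", "retest")
        }
        for j in range(n_lesions):
            rec = {"patient_id": pid, "lesion_id": f"{pid}-L{j + 1:03d}"}
            for f in _NOISED:
                rec[f"{f}_test"] = math.exp(true_log[f][j] + noise[(f, "test")][j])
                rec[f"{f}_retest"] = math.exp(true_log[f][j] + bias + noise[(f, "retest")][j])
            for tp in ("test", "retest"):
                rec[f"suv_total_{tp}"] = rec[f"suv_mean_{tp}"] * rec[f"volume_cc_{tp}"]
            rows.append(rec)
            truth_rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": rec["lesion_id"],
                    "true_log_volume": log_vol[j],
                    "true_log_uptake": log_upt[j],
                    "true_log_suv_max": log_upt[j] + peak[j],
                    "patient_bias": bias,
                }
            )
    cols = ["patient_id", "lesion_id"] + [f"{f}_{tp}" for f in FEATURES for tp in ("test", "retest")]
    pairs = pd.DataFrame(rows, columns=cols)
    truth = GroundTruth(lesions=pd.DataFrame(truth_rows), params=params)
    return pairs, truth


# ---------------------------------------------------------------------------
# phantom mode


def _ellipsoid_semi_axes_mm(volume_cc: float, rng: np.random.Generator) -> np.ndarray:
    """Random mildly anisotropic semi-axes (mm) with the requested volume."""
    ratios = rng.uniform(0.7, 1.3, 3)
    ratios /= ratios.prod() ** (1.0 / 3.0)
    # volume_cc * 1000 = mm^3; equivalent-sphere radius in mm
    r_mm = (3.0 * volume_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return r_mm * ratios


def _voxelize_ellipsoid(center_mm, semi_mm, grid_shape, voxel_mm) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the ellipsoid."""
    lo = [max(0, int((center_mm[a] - semi_mm[a]) / voxel_mm[a]) - 1) for a in range(3)]
    hi = [
        min(grid_shape[a], int((center_mm[a] + semi_mm[a]) / voxel_mm[a]) + 2) for a in range(3)
    ]
    mask = np.zeros(grid_shape, dtype=bool)
    idx = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
    if any(x.size == 0 for x in idx):
        return mask
    dist2 = sum(
        (((idx[a] + 0.5) * voxel_mm[a] - center_mm[a]) / semi_mm[a]) ** 2 for a in range(3)
    )
    mask[idx[0], idx[1], idx[2]] = dist2 <= 1.0
    return mask


def _boundary_voxels(mask: np.ndarray):
    """(removable, addable) index arrays: 6-connectivity boundary of a mask."""
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    dilated = ndimage.binary_dilation(mask)
    removable = np.argwhere(mask & ~eroded)
    addable = np.argwhere(dilated & ~mask)
    return removable, addable


def generate_phantom_pair(
    params: CohortParams,
    patient_index: int,
    *,
    min_separation_mm: float = 30.0,
    smooth_sigma_mm: float | None = None,
) -> PhantomPair:
    """Voxelize one patient's lesions as a test/retest image/mask pair.

    Lesions are ellipsoidal plateaus of uniform SUV on a low constant
    background.  The retest mask is the test mask with every boundary voxel
    (6-connectivity, per lesion) independently flipped with probability
    ``jitter_boundary_prob``; because the flip count scales with surface area
    while volume scales with r^3, the *relative* volume perturbation grows as
    lesions shrink.  The retest plateau additionally carries the patient bias
    and per-lesion SUV noise.

    ``min_separation_mm`` is the minimum center-to-center distance enforced
    at placement (also at least the sum of the two bounding radii plus two
    voxels), so lesions never touch and centroid matching is unambiguous.
    ``smooth_sigma_mm`` optionally applies a Gaussian partial-volume blur to
    the SUV grids (masks untouched); it breaks the exact plateau/feature
    equality and is off by default.

    Raises :class:`PlacementError` if a lesion cannot be placed within a
    bounded number of attempts.
    """
    if patient_index < 0 or patient_index >= params.n_patients:
        raise ParameterError(
            f"patient_index {patient_index} out of range for {params.n_patients} patients"
        )
    rng = _patient_rng(params, patient_index)
    pid = _patient_id(patient_index)
    n_lesions, bias, log_vol, log_upt, peak = _draw_patient(params, rng)
    grid_shape = tuple(int(s) for s in params.grid_shape)
    voxel_mm = np.asarray(params.voxel_size_mm, dtype=float)
    extent_mm = np.array(grid_shape) * voxel_mm

    labels_test = np.zeros(grid_shape, dtype=np.int32)
    suv_test = np.full(grid_shape, _BACKGROUND_SUV, dtype=np.float64)
    centers, radii, masks = [], [], []
    for j in range(n_lesions):
        semi = _ellipsoid_semi_axes_mm(math.exp(log_vol[j]), rng)
        bound_r = float(np.max(semi))
        placed = False
        for _ in range(_PLACEMENT_ATTEMPTS):
            margin = semi + 2.0 * voxel_mm  # room for jitter growth
            if np.any(extent_mm - 2 * margin <= 0):
                break
            c = rng.uniform(margin, extent_mm - margin)
            ok = all(
                np.linalg.norm(c - centers[k])
                >= max(min_separation_mm, bound_r + radii[k] + 2 * float(voxel_mm.max()))
                for k in range(len(centers))
            )
            if ok:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place lesion {j + 1}/{n_lesions} (volume "
                f"{math.exp(log_vol[j]):.2f} cm^3) on grid {grid_shape} after "
                f"{_PLACEMENT_ATTEMPTS} attempts; enlarge the grid or reduce "
                f"lesion count/size/separation"
            )
        mask = _voxelize_ellipsoid(c, semi, grid_shape, voxel_mm)
        if not mask.any():  # tiny lesion below the voxel grid: keep one voxel
            ijk = tuple(np.minimum((c / voxel_mm).astype(int), np.array(grid_shape) - 1))
            mask[ijk] = True
        centers.append(c)
        radii.append(bound_r)
        masks.append(mask)
        labels_test[mask] = j + 1

    # retest mask: per-lesion boundary jitter
    labels_retest = labels_test.copy()
    for j, mask in enumerate(masks):
        if params.jitter_boundary_prob <= 0:
            continue
        removable, addable = _boundary_voxels(mask)
        rm = removable[rng.random(len(removable)) < params.jitter_boundary_prob]
        add = addable[rng.random(len(addable)) < params.jitter_boundary_prob]
        new_mask = mask.copy()
        new_mask[tuple(rm.T)] = False
        if not new_mask.any():  # never let jitter erase a lesion entirely
            new_mask[tuple(removable[0])] = True
        # additions restricted to background (separation makes collisions impossible)
        add = add[labels_test[tuple(add.T)] == 0]
        new_mask[tuple(add.T)] = True
        labels_retest[mask] = 0
        labels_retest[new_mask] = j + 1

    # SUV plateaus: per-lesion uptake noise on each scan, bias on retest only
    suv_retest = np.full(grid_shape, _BACKGROUND_SUV, dtype=np.float64)
    noise_t = (
        rng.normal(0.0, params.lesion_noise_sd, n_lesions)
        if params.lesion_noise_sd > 0
        else np.zeros(n_lesions)
    )
    noise_r = (
        rng.normal(0.0, params.lesion_noise_sd, n_lesions)
        if params.lesion_noise_sd > 0
        else np.zeros(n_lesions)
    )
    truth_rows = []
    for j, mask in enumerate(masks):
        plateau = math.exp(log_upt[j])
        suv_test[mask] = plateau * math.exp(noise_t[j])
        suv_retest[labels_retest == j + 1] = plateau * math.exp(bias + noise_r[j])
        truth_rows.append(
            {
                "test_label": j + 1,
                "retest_label": j + 1,
                "plateau_suv": plateau,
                "voxel_volume_cc": float(np.prod(voxel_mm)) / 1000.0,
                "test_voxels": int(mask.sum()),
                "retest_voxels": int((labels_retest == j + 1).sum()),
                "center_x_mm": centers[j][0],
                "center_y_mm": centers[j][1],
                "center_z_mm": centers[j][2],
            }
        )

    if smooth_sigma_mm is not None and smooth_sigma_mm > 0:
        from scipy import ndimage

        sig = smooth_sigma_mm / voxel_mm
        suv_test = ndimage.gaussian_filter(suv_test, sig)
        suv_retest = ndimage.gaussian_filter(suv_retest, sig)

    return PhantomPair(
        suv_test=suv_test,
        suv_retest=suv_retest,
        labels_test=labels_test,
        labels_retest=labels_retest,
        voxel_size_mm=tuple(float(v) for v in voxel_mm),
        patient_id=pid,
        truth=pd.DataFrame(truth_rows),
    )
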