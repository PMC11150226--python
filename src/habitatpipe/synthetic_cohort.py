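"""Synthetic CT cohort generator with known ground truth.

Each patient is an ellipsoidal "tumor" placed in a noisy lung-like background,
partitioned into ``true_k`` contiguous textural sub-regions (Voronoi cells of
random interior seed points) with distinct intensity distributions.  One
designated sub-region carries the outcome signal: its intensity distribution is
shifted in mean (and inflated in variance) for non-responders, so that both the
intensity and the local-entropy channel separate the classes.  Two rater masks
are emulated by perturbing the true boundary, and progression-free / overall
survival times are drawn from log-normal models consistent with the 6-month
durable-benefit (PFS6) dichotomy.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imaging_io import CTVolume, Mask, write_volume, write_mask, write_labels

__all__ = [
    "CohortConfig",
    "OutcomeRecord",
    "SyntheticPatient",
    "generate_tumor_volume",
    "generate_cohort",
    "perturb_mask",
    "simulate_outcomes",
    "dice",
    "write_cohort",
]


@dataclass
class CohortConfig:
    """Study conditions of the simulated cohort.

    Defaults mirror the separated three-habitat regime used throughout the
    test-bench: intensity means 60/120/180 on a Hounsfield-like scale with a
    within-habitat SD of 10, a 1.5-SD outcome effect carried by the brightest
    sub-region, ~60% responders, 20% censoring, and a mild two-rater
    delineation disagreement.
    """

    n_patients: int = 60
    true_k: int = 3
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    habitat_intensity_means: tuple[float, ...] = (60.0, 120.0, 180.0)
    habitat_noise_sd: float = 10.0
    #: per-habitat texture scale: habitat h has noise SD
    #: ``habitat_noise_sd * habitat_entropy_scales[h-1]``, giving each
    #: sub-region a distinct local-entropy signature as well as a distinct
    #: mean intensity; None -> geometric spread 0.4 .. 2.5 across habitats
    habitat_entropy_scales: tuple[float, ...] | None = None
    signal_habitat: int = 3  # 1-based index of the sub-region carrying signal
    effect_size: float = 1.5
    responder_fraction: float = 0.6
    censor_rate: float = 0.2
    rater2_perturb_voxels: int = 15
    seed: int = 0
    # geometry knobs (not part of the study conditions; sized so the tumor
    # always fits with >= 500 voxels)
    min_semi_axis: float = 8.0
    max_semi_axis: float = 12.0
    background_mean: float = 0.0
    background_sd: float = 15.0
    bias_amplitude: float = 10.0

    def __post_init__(self) -> None:
        if len(self.habitat_intensity_means) != self.true_k:
            raise ValueError("habitat_intensity_means must have length true_k")
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValueError("responder_fraction must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 1 <= self.signal_habitat <= self.true_k:
            raise ValueError("signal_habitat must be in 1..true_k")
        if self.habitat_entropy_scales is None:
            self.habitat_entropy_scales = tuple(
                np.geomspace(0.4, 2.5, self.true_k).tolist()
            )
        if len(self.habitat_entropy_scales) != self.true_k:
            raise ValueError("habitat_entropy_scales must have length true_k")


@dataclass
class OutcomeRecord:
    pfs_months: float
    pfs_event: bool
    os_months: float
    os_event: bool
    responder: bool


@dataclass
class SyntheticPatient:
    patient_id: str
    volume: CTVolume
    mask_rater1: Mask
    mask_rater2: Mask
    truth_habitats: np.ndarray  # int labels, 0 outside, 1..true_k inside
    outcome: OutcomeRecord


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary arrays."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    denom = a.sum() + b.sum()
    return 2.0 * float(np.logical_and(a, b).sum()) / denom if denom else 0.0


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _smooth_bias_field(shape, amplitude, rng) -> np.ndarray:
    """Mild smooth multiplicative-free additive bias: low-res noise upsampled."""
    coarse = rng.normal(0.0, 1.0, size=(4, 4, 4))
    zoom = [n / 4 for n in shape]
    field_ = ndimage.zoom(coarse, zoom, order=3, mode="nearest")
    field_ = field_[: shape[0], : shape[1], : shape[2]]
    return amplitude * field_


def generate_tumor_volume(
    config: CohortConfig, patient_seed: int, responder: bool | None = None
) -> SyntheticPatient:
    """Generate one synthetic patient (volume, rater masks, truth labels).

    ``responder`` fixes the class; when None it is drawn Bernoulli
    ``responder_fraction``.  The outcome record is filled with survival times
    via :func:`simulate_outcomes`.  Raises ``ValueError`` if the tumor cannot
    fit inside ``volume_shape``.
    """
    rng = np.random.default_rng(patient_seed)
    shape = tuple(int(n) for n in config.volume_shape)

    max_ax = config.max_semi_axis
    if any(n < 2 * max_ax + 4 for n in shape):
        raise ValueError(
            f"volume_shape {shape} too small for tumors with semi-axes up to {max_ax}"
        )

    if responder is None:
        responder = bool(rng.random() < config.responder_fraction)

    # ellipsoid placement: random semi-axes, center jittered around the middle
    semi = rng.uniform(config.min_semi_axis, config.max_semi_axis, size=3)
    center = [n / 2.0 + rng.uniform(-2, 2) for n in shape]
    tumor = _ellipsoid_mask(shape, center, semi)
    if tumor.sum() < 500:
        # enlarge the smallest axis until the floor is met (bounded loop)
        while tumor.sum() < 500 and semi.min() < max_ax:
            semi[np.argmin(semi)] += 0.5
            tumor = _ellipsoid_mask(shape, center, semi)
        if tumor.sum() < 500:
            raise ValueError("could not place a tumor of >= 500 voxels")

    coords = np.argwhere(tumor)

    # Voronoi sub-regions from true_k interior seed points; a few Lloyd
    # relaxations balance the cell sizes (still contiguous and irregular)
    seed_idx = rng.choice(len(coords), size=config.true_k, replace=False)
    seeds = coords[seed_idx].astype(float)
    for _ in range(5):
        d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for c in range(config.true_k):
            sel = assign == c
            if sel.any():
                seeds[c] = coords[sel].mean(axis=0)
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)  # 0..true_k-1
    truth = np.zeros(shape, dtype=np.int16)
    truth[tuple(coords.T)] = assign + 1

    # intensities
    data = rng.normal(config.background_mean, config.background_sd, size=shape)
    data += _smooth_bias_field(shape, config.bias_amplitude, rng)
    sd = config.habitat_noise_sd
    for h in range(1, config.true_k + 1):
        mean = float(config.habitat_intensity_means[h - 1])
        h_sd = sd * float(config.habitat_entropy_scales[h - 1])
        if h == config.signal_habitat and not responder:
            # non-responders: signal habitat shifted by effect_size SD and
            # noisier, so intensity and entropy both separate
            mean += config.effect_size * sd
            h_sd *= 1.0 + 0.5 * config.effect_size
        vox = truth == h
        data[vox] = rng.normal(mean, h_sd, size=int(vox.sum()))

    mask1 = Mask(tumor, spacing_mm=config.spacing_mm)
    mask2 = Mask(
        perturb_mask(mask1.data, config.rater2_perturb_voxels, int(rng.integers(2**31))),
        spacing_mm=config.spacing_mm,
    )
    outcome = simulate_outcomes(config, [responder], int(rng.integers(2**31)))[0]
    return SyntheticPatient(
        patient_id=f"P{patient_seed:06d}",
        volume=CTVolume(data, spacing_mm=config.spacing_mm),
        mask_rater1=mask1,
        mask_rater2=mask2,
        truth_habitats=truth,
        outcome=outcome,
    )


def perturb_mask(mask: np.ndarray, n_voxels: int, seed: int) -> np.ndarray:
    """Toggle up to ``n_voxels`` boundary voxels (morphological add/remove).

    Emulates a second rater's delineation.  Guarantees a nonempty result with
    Dice > 0.5 against the original; raises ``ValueError`` if the perturbation
    would empty the mask.
    """
    mask = np.asarray(mask) > 0
    if mask.sum() == 0:
        raise ValueError("cannot perturb an empty mask")
    if n_voxels == 0:
        return mask.copy().astype(np.uint8)

    rng = np.random.default_rng(seed)
    out = mask.copy()
    inner_boundary = mask & ~ndimage.binary_erosion(mask)
    outer_boundary = ndimage.binary_dilation(mask) & ~mask
    cand = np.argwhere(inner_boundary | outer_boundary)
    rng.shuffle(cand)
    budget = min(n_voxels, len(cand))
    floor = max(1, int(np.ceil(mask.sum() / 3)))  # keeps Dice > 0.5
    toggled = 0
    for z, y, x in cand:
        if toggled >= budget:
            break
        if out[z, y, x] and out.sum() <= floor:
            continue  # removing would risk emptiness / low overlap
        out[z, y, x] = ~out[z, y, x]
        toggled += 1
    if out.sum() == 0:
        raise ValueError("perturbation emptied the mask")
    return out.astype(np.uint8)


#: log-normal PFS medians (months) for responders / non-responders
PFS_MEDIAN_RESPONDER = 12.0
PFS_MEDIAN_NONRESPONDER = 3.0
PFS_LOG_SD = 0.5
OS_GAP_LOG_MEAN = np.log(8.0)
OS_GAP_LOG_SD = 0.6


def simulate_outcomes(
    config: CohortConfig, responder_flags, seed: int
) -> list[OutcomeRecord]:
    """Draw censored PFS/OS records consistent with the PFS6 responder rule.

    PFS is log-normal with median 12 months for responders and 3 for
    non-responders, truncated to the correct side of 6 months so the label
    always matches the rule when the event is observed.  OS = PFS plus an
    independent log-normal gap (monotone in PFS plus noise); OS and PFS are
    censored independently at rate ``censor_rate`` by uniform censoring times.
    """
    rng = np.random.default_rng(seed)
    records: list[OutcomeRecord] = []
    for flag in responder_flags:
        flag = bool(flag)
        median = PFS_MEDIAN_RESPONDER if flag else PFS_MEDIAN_NONRESPONDER
        pfs = float(rng.lognormal(np.log(median), PFS_LOG_SD))
        for _ in range(1000):
            if (pfs > 6.0) == flag:
                break
            pfs = float(rng.lognormal(np.log(median), PFS_LOG_SD))
        os_t = pfs + float(rng.lognormal(OS_GAP_LOG_MEAN, OS_GAP_LOG_SD))

        pfs_event, os_event = True, True
        if rng.random() < config.censor_rate:
            pfs = float(rng.uniform(0.0, pfs))
            pfs_event = False
        if rng.random() < config.censor_rate:
            os_t = float(rng.uniform(0.0, os_t))
            os_event = False
        records.append(
            OutcomeRecord(
                pfs_months=pfs,
                pfs_event=pfs_event,
                os_months=os_t,
                os_event=os_event,
                responder=flag,
            )
        )
    return records


def generate_cohort(config: CohortConfig, seed: int | None = None) -> list[SyntheticPatient]:
    """Generate ``n_patients`` synthetic patients, deterministically.

    Responder labels are drawn first (so the class balance follows
    ``responder_fraction`` exactly in expectation), then each patient gets an
    independent child seed.
    """
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(base)
    flags = rng.random(config.n_patients) < config.responder_fraction
    # guard against degenerate single-class cohorts at small n
    if flags.all():
        flags[0] = False
    if not flags.any():
        flags[0] = True
    child_seeds = rng.integers(0, 2**31 - 1, size=config.n_patients)
    return [
        generate_tumor_volume(config, int(child_seeds[i]), responder=bool(flags[i]))
        for i in range(config.n_patients)
    ]


def write_cohort(patients: list[SyntheticPatient], out_dir: str | Path) -> Path:
    """Write per-patient NIfTI volumes/masks/truth labels and a manifest CSV."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        vol_path = out_dir / f"{p.patient_id}_ct.nii.gz"
        m1_path = out_dir / f"{p.patient_id}_mask_r1.nii.gz"
        m2_path = out_dir / f"{p.patient_id}_mask_r2.nii.gz"
        tr_path = out_dir / f"{p.patient_id}_truth.nii.gz"
        write_volume(p.volume, vol_path)
        write_mask(p.mask_rater1, m1_path)
        write_mask(p.mask_rater2, m2_path)
        write_labels(p.truth_habitats, p.volume.spacing_mm, tr_path)
        rows.append(
            {
                "patient_id": p.patient_id,
                "volume": vol_path.name,
                "mask_rater1": m1_path.name,
                "mask_rater2": m2_path.name,
                "truth": tr_path.name,
                "pfs_months": p.outcome.pfs_months,
                "pfs_event": int(p.outcome.pfs_event),
                "os_months": p.outcome.os_months,
                "os_event": int(p.outcome.os_event),
                "responder": int(p.outcome.responder),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
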