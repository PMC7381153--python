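"""Synthetic designs, cohorts, and multi-subject BOLD data with known truth.

Three block-design experiments are modelled after a two-group face-voice
study:

``integration``
    Auditory (A), visual (V) and audiovisual (AV) presentation of 60
    face/voice items, allocated to 12 blocks of five stimuli per modality
    (8 s blocks, 180 presentations per participant).  The modality order is
    randomized under the constraint that no more than two adjacent blocks
    share a modality.
``voice``
    Voice-sensitivity localizer: 12 blocks of human vocal sounds (V), six of
    animal (A) and six of environmental (E) sounds plus 12 silent periods,
    all 8 s.
``face``
    Face-sensitivity localizer: eight 16-s blocks each of faces (F), houses
    (H), objects (O) and natural scenes (S).

The BOLD simulator mirrors the analysis model: condition boxcars convolved
with the canonical HRF, scaled by per-condition 3D amplitude maps, spatially
smoothed, plus slow cosine drift and AR(1) Gaussian noise (optionally with
an extra white component).  Every stochastic operation takes an explicit
seed; there is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .acquisition import AcquisitionSpec
from .containers import BoldDataset, ContrastImage

__all__ = [
    "EXPERIMENTS",
    "BlockSequence",
    "GroundTruth",
    "TABLE1_TARGETS",
    "GROUP_PEAK_MM",
    "generate_block_sequence",
    "generate_cohort",
    "make_integration_truth",
    "make_sensitivity_truth",
    "n_scans_for",
    "simulate_contrast_maps",
    "simulate_subject_bold",
]

_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Experiment catalogue: per-condition block counts, block duration (s),
#: default inter-block interval (s), max same-condition run length
#: (None = unconstrained), unmodelled baseline conditions, stimuli per block.
EXPERIMENTS = {
    "integration": dict(
        counts={"A": 12, "V": 12, "AV": 12},
        duration=8.0,
        gap=8.0,
        max_run=2,
        baseline=(),
        stimuli_per_block=5,
    ),
    "voice": dict(
        counts={"V": 12, "A": 6, "E": 6, "silence": 12},
        duration=8.0,
        gap=0.0,
        max_run=None,
        baseline=("silence",),
        stimuli_per_block=None,
    ),
    "face": dict(
        counts={"F": 8, "H": 8, "O": 8, "S": 8},
        duration=16.0,
        gap=0.0,
        max_run=None,
        baseline=(),
        stimuli_per_block=20,
    ),
}


@dataclass
class BlockSequence:
    """An ordered, non-overlapping stimulation-block timeline.

    Onsets are in seconds relative to the first retained (post-dummy) scan.
    ``baseline`` lists condition labels present in the timeline but not
    modelled as regressors (e.g. silent periods).
    """

    blocks: list[tuple[str, float, float]]
    condition_set: tuple[str, ...]
    baseline: tuple[str, ...] = ()
    experiment: str = "custom"
    stimuli_per_block: Optional[int] = None

    def __post_init__(self) -> None:
        blocks = sorted(self.blocks, key=lambda b: b[1])
        t = -np.inf
        for label, onset, dur in blocks:
            if label not in self.condition_set:
                raise ValueError(f"block condition {label!r} not in condition_set")
            if dur <= 0:
                raise ValueError(f"non-positive block duration {dur}")
            if onset < t - 1e-9:
                raise ValueError("blocks overlap")
            t = onset + dur
        self.blocks = blocks

    @property
    def conditions(self) -> tuple[str, ...]:
        """Modelled (non-baseline) conditions."""
        return tuple(c for c in self.condition_set if c not in self.baseline)

    @property
    def labels(self) -> list[str]:
        return [b[0] for b in self.blocks]

    @property
    def end(self) -> float:
        """Offset of the last block in seconds."""
        return max(onset + dur for _, onset, dur in self.blocks)

    @property
    def n_stimuli(self) -> Optional[int]:
        if self.stimuli_per_block is None:
            return None
        return self.stimuli_per_block * sum(
            1 for label, _, _ in self.blocks if label not in self.baseline
        )

    def count(self, condition: str) -> int:
        return sum(1 for label, _, _ in self.blocks if label == condition)

    def max_run_length(self) -> int:
        best = run = 0
        prev = None
        for label in self.labels:
            run = run + 1 if label == prev else 1
            prev = label
            best = max(best, run)
        return best

    def to_events(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            [(onset, dur, label) for label, onset, dur in self.blocks],
            columns=["onset", "duration", "trial_type"],
        )


def _order_with_max_run(
    counts: dict[str, int], max_run: Optional[int], rng: np.random.Generator, max_attempts: int
) -> list[str]:
    labels = [c for c, k in counts.items() for _ in range(k)]
    if max_run is None or len(set(labels)) <= 1 and len(labels) <= (max_run or len(labels)):
        labels = list(labels)
        rng.shuffle(labels)
        return labels
    for _ in range(max_attempts):
        perm = list(labels)
        rng.shuffle(perm)
        run, prev, ok = 0, None, True
        for lab in perm:
            run = run + 1 if lab == prev else 1
            prev = lab
            if run > max_run:
                ok = False
                break
        if ok:
            return perm
    raise RuntimeError(
        f"could not satisfy max-run-{max_run} adjacency constraint for "
        f"counts {counts} within {max_attempts} attempts"
    )


def generate_block_sequence(
    experiment: str = "integration",
    n_blocks_per_condition: Optional[int] = None,
    block_duration: Optional[float] = None,
    gap: Optional[float] = None,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> BlockSequence:
    """Generate a randomized block timeline for one experiment.

    Parameters
    ----------
    experiment : {"integration", "voice", "face"}
    n_blocks_per_condition : int, optional
        Override of the per-condition block count.  For the ``voice``
        experiment the catalogue's 2:1:1:2 ratio (V:A:E:silence) is scaled.
    block_duration, gap : float, optional
        Block length and inter-block interval in seconds (catalogue defaults
        if omitted).
    seed : int
        Seed for the ordering; orderings violating the experiment's
        adjacency constraint (integration: at most two adjacent blocks of
        one modality) are rejection-sampled away.

    Raises
    ------
    RuntimeError
        If the adjacency constraint cannot be satisfied within
        ``max_attempts`` shuffles.
    """
    try:
        cat = EXPERIMENTS[experiment]
    except KeyError:
        raise ValueError(f"unknown experiment {experiment!r}; expected one of {sorted(EXPERIMENTS)}")
    counts = dict(cat["counts"])
    if n_blocks_per_condition is not None:
        if n_blocks_per_condition < 1:
            raise ValueError("n_blocks_per_condition must be >= 1")
        ref = max(counts.values())
        counts = {
            c: max(1, round(k * n_blocks_per_condition / ref)) for c, k in counts.items()
        }
    duration = cat["duration"] if block_duration is None else float(block_duration)
    gap_s = cat["gap"] if gap is None else float(gap)
    rng = np.random.default_rng(seed)
    order = _order_with_max_run(counts, cat["max_run"], rng, max_attempts)
    blocks = [
        (label, i * (duration + gap_s), duration) for i, label in enumerate(order)
    ]
    return BlockSequence(
        blocks=blocks,
        condition_set=tuple(cat["counts"]),
        baseline=tuple(cat["baseline"]),
        experiment=experiment,
        stimuli_per_block=cat["stimuli_per_block"],
    )


def n_scans_for(seq: BlockSequence, tr: float, tail_s: float = 16.0) -> int:
    """Scan count covering the sequence plus ``tail_s`` seconds of washout."""
    return int(math.ceil((seq.end + tail_s) / tr))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

#: Group summary targets for the simulated cohort: per continuous variable
#: (mean, SD); gender and study site as category counts out of n=18.
TABLE1_TARGETS = {
    "SAD": {
        "age": (23.3, 3.3),
        "lsas": (72.2, 22.3),
        "stai_x1": (43.4, 7.5),
        "stai_x2": (48.6, 7.5),
        "mwt_b": (32.1, 2.4),
        "gender": {"f": 12, "m": 6},
        "site": {"T": 13, "G": 5},
    },
    "HC": {
        "age": (24.8, 2.0),
        "lsas": (12.8, 9.7),
        "stai_x1": (33.6, 7.2),
        "stai_x2": (37.3, 8.2),
        "mwt_b": (30.7, 2.6),
        "gender": {"f": 10, "m": 8},
        "site": {"T": 10, "G": 8},
    },
}

CONTINUOUS_VARS = ("age", "lsas", "stai_x1", "stai_x2", "mwt_b")


def _exact_gaussian(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian draws affinely rescaled to the exact sample mean and SD."""
    if n < 2:
        raise ValueError("exact-match mode needs n >= 2 (sample SD undefined)")
    z = rng.standard_normal(n)
    s = z.std(ddof=1)
    if s == 0:  # pragma: no cover - probability-zero degenerate draw
        raise RuntimeError("degenerate draw with zero sample SD")
    z = (z - z.mean()) / s
    return mean + sd * z


def _categorical_counts(n: int, target_counts: dict[str, int]) -> list[str]:
    total = sum(target_counts.values())
    labels, taken = [], 0
    items = sorted(target_counts.items())
    for i, (label, k) in enumerate(items):
        m = n - taken if i == len(items) - 1 else int(round(n * k / total))
        labels.extend([label] * m)
        taken += m
    return labels[:n]


def generate_cohort(
    n_per_group: int = 18,
    targets: Optional[dict] = None,
    seed: int = 0,
    exact: bool = True,
) -> pd.DataFrame:
    """Simulate a two-group cohort table (one row per subject).

    Continuous psychometrics (age, LSAS, STAI-X1/X2, MWT-B) are Gaussian per
    group; with ``exact=True`` each group's draws are affinely rescaled so
    the sample mean and SD equal the targets to numerical precision, and
    gender/site category counts are matched exactly (scaled for other group
    sizes).  With ``exact=False`` categories are drawn with the target
    proportions and continuous variables are plain Gaussian draws.

    Returns a :class:`pandas.DataFrame` with columns ``subject_id, group,
    age, gender, site, lsas, stai_x1, stai_x2, mwt_b``; lower scores are
    clipped at zero only in non-exact mode (scores are non-negative scales).
    """
    targets = TABLE1_TARGETS if targets is None else targets
    if exact and n_per_group < 2:
        raise ValueError("exact-match mode requires n_per_group >= 2")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for group in targets:
        tg = targets[group]
        cont = {}
        for var in CONTINUOUS_VARS:
            mean, sd = tg[var]
            if exact:
                cont[var] = _exact_gaussian(n_per_group, mean, sd, rng)
            else:
                cont[var] = np.clip(mean + sd * rng.standard_normal(n_per_group), 0, None)
        if exact:
            gender = _categorical_counts(n_per_group, tg["gender"])
            site = _categorical_counts(n_per_group, tg["site"])
            rng.shuffle(gender)
            rng.shuffle(site)
        else:
            g_labels, g_counts = zip(*sorted(tg["gender"].items()))
            s_labels, s_counts = zip(*sorted(tg["site"].items()))
            gender = rng.choice(g_labels, size=n_per_group, p=np.array(g_counts) / sum(g_counts))
            site = rng.choice(s_labels, size=n_per_group, p=np.array(s_counts) / sum(s_counts))
        for i in range(n_per_group):
            rows.append(
                {
                    "subject_id": f"sub-{group}{i:02d}",
                    "group": group,
                    "age": cont["age"][i],
                    "gender": gender[i],
                    "site": site[i],
                    "lsas": cont["lsas"][i],
                    "stai_x1": cont["stai_x1"][i],
                    "stai_x2": cont["stai_x2"][i],
                    "mwt_b": cont["mwt_b"][i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground truth and BOLD simulation
# ---------------------------------------------------------------------------

#: Default true group mean peak locations of the integration effect in the
#: right STS slab (mm): controls posterior, patients shifted anterior and
#: slightly inferior along the sulcus.
GROUP_PEAK_MM = {"HC": (59.3, -30.5, 8.3), "SAD": (61.3, -12.0, 2.7)}


@dataclass
class GroundTruth:
    """Generative truth for one simulated subject.

    ``beta_maps`` hold the per-condition effect amplitudes (arbitrary units
    relative to ``innovation_sd``); ``peak_location_mm`` is the true
    integration peak.  ``ppi_gain`` maps condition labels to the extra
    seed-to-target coupling active during that condition (used by the PPI
    simulator).  Noise is AR(1) with coefficient ``ar_rho`` and innovation
    SD ``innovation_sd``, plus an optional additional white component.
    """

    beta_maps: dict[str, np.ndarray]
    peak_location_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ppi_gain: dict[str, float] = field(default_factory=dict)
    ppi_target_mm: Optional[np.ndarray] = None
    ppi_base_coupling: float = 0.5
    ppi_latent_sd: float = 1.0
    ppi_latent_rho: float = 0.5
    ppi_blob_fwhm_mm: float = 12.0
    ar_rho: float = 0.2
    innovation_sd: float = 1.0
    white_sd: float = 0.0
    drift_amplitude: float = 0.0

    def __post_init__(self) -> None:
        self.peak_location_mm = np.asarray(self.peak_location_mm, dtype=float)
        if self.ppi_target_mm is not None:
            self.ppi_target_mm = np.asarray(self.ppi_target_mm, dtype=float)
        for cond, bmap in self.beta_maps.items():
            bmap = np.asarray(bmap, dtype=float)
            if not np.all(np.isfinite(bmap)):
                raise ValueError(f"beta map for {cond!r} contains non-finite values")
            self.beta_maps[cond] = bmap

    def validate_grid(self, grid_shape: Sequence[int]) -> None:
        for cond, bmap in self.beta_maps.items():
            if bmap.shape != tuple(grid_shape):
                raise ValueError(
                    f"beta map for {cond!r} has shape {bmap.shape}, "
                    f"expected grid {tuple(grid_shape)}"
                )


def _gaussian_blob(spec: AcquisitionSpec, center_mm: np.ndarray, fwhm_mm: float) -> np.ndarray:
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in spec.grid_shape], indexing="ij"), -1)
    mm = ijk @ spec.affine[:3, :3].T + spec.affine[:3, 3]
    sigma = fwhm_mm / _FWHM_TO_SIGMA
    d2 = ((mm - np.asarray(center_mm)) ** 2).sum(-1)
    return np.exp(-0.5 * d2 / sigma**2)


def _clip_to_grid(spec: AcquisitionSpec, mm: np.ndarray, margin_vox: float = 1.0) -> np.ndarray:
    """Clamp an mm coordinate so its voxel lies inside the grid."""
    inv = np.linalg.inv(spec.affine)
    ijk = inv[:3, :3] @ np.asarray(mm, dtype=float) + inv[:3, 3]
    hi = np.asarray(spec.grid_shape) - 1 - margin_vox
    ijk = np.clip(ijk, margin_vox, np.maximum(margin_vox, hi))
    return spec.affine[:3, :3] @ ijk + spec.affine[:3, 3]


def make_integration_truth(
    spec: AcquisitionSpec,
    group: str = "HC",
    seed: int = 0,
    amp_a: float = 2.0,
    amp_v: float = 0.8,
    integration_gain: Optional[float] = None,
    group_gains: dict[str, float] = {"HC": 0.5, "SAD": 1.0},
    group_peak_mm: Optional[dict] = None,
    peak_jitter_sd_mm: float = 4.0,
    blob_fwhm_mm: float = 16.0,
    ar_rho: float = 0.2,
    innovation_sd: float = 1.0,
    drift_amplitude: float = 1.0,
    ppi_gain: Optional[dict[str, float]] = None,
    ppi_target_mm: Optional[np.ndarray] = None,
) -> GroundTruth:
    """Ground truth for one integration-experiment subject.

    The unimodal auditory response dominates the visual one in the simulated
    voice-sensitive STS region (``amp_a > amp_v``), and the audiovisual
    amplitude exceeds the unimodal maximum by ``integration_gain`` (larger
    for the SAD group by default), so the true minimum-difference statistic
    AV - max(A, V) equals the gain at the subject's peak.  The subject peak
    is drawn around the group mean location (SAD anteriorized along y),
    giving every subject their own spatial truth for topography tests.
    """
    rng = np.random.default_rng(seed)
    peaks = GROUP_PEAK_MM if group_peak_mm is None else group_peak_mm
    if group not in peaks:
        raise ValueError(f"unknown group {group!r}")
    center = np.asarray(peaks[group], dtype=float) + peak_jitter_sd_mm * rng.standard_normal(3)
    center = _clip_to_grid(spec, center)
    gain = group_gains[group] if integration_gain is None else integration_gain
    blob = _gaussian_blob(spec, center, blob_fwhm_mm)
    beta = {
        "A": amp_a * blob,
        "V": amp_v * blob,
        "AV": (max(amp_a, amp_v) + gain) * blob,
    }
    return GroundTruth(
        beta_maps=beta,
        peak_location_mm=center,
        ppi_gain=dict(ppi_gain or {}),
        ppi_target_mm=None if ppi_target_mm is None else np.asarray(ppi_target_mm, float),
        ar_rho=ar_rho,
        innovation_sd=innovation_sd,
        drift_amplitude=drift_amplitude,
    )


def make_sensitivity_truth(
    spec: AcquisitionSpec,
    experiment: str,
    center_mm: Optional[np.ndarray] = None,
    seed: int = 0,
    preferred_amp: float = 2.0,
    other_amp: float = 0.5,
    blob_fwhm_mm: float = 24.0,
    amp_jitter_sd: float = 0.3,
    peak_jitter_sd_mm: float = 4.0,
    ar_rho: float = 0.2,
    innovation_sd: float = 1.0,
    drift_amplitude: float = 1.0,
) -> GroundTruth:
    """Ground truth for a voice- or face-sensitivity localizer subject.

    For ``voice``, vocal sounds (V) drive the STS blob harder than animal or
    environmental sounds; for ``face``, the same region responds weakly and
    equally to all picture categories (the simulated STS patch is
    voice-sensitive but not face-sensitive), so the face-sensitivity
    statistic F - max(H, O, S) is centred at zero there.
    """
    if experiment not in ("voice", "face"):
        raise ValueError("experiment must be 'voice' or 'face'")
    rng = np.random.default_rng(seed)
    if center_mm is None:
        # midpoint of the STS integration strip: the voice-sensitive belt is
        # elongated and covers both the anterior and posterior group peaks
        center_mm = np.mean([GROUP_PEAK_MM["HC"], GROUP_PEAK_MM["SAD"]], axis=0)
    center = np.asarray(center_mm, dtype=float) + peak_jitter_sd_mm * rng.standard_normal(3)
    center = _clip_to_grid(spec, center)
    blob = _gaussian_blob(spec, center, blob_fwhm_mm)
    # per-subject responsiveness scaling (shared across conditions would
    # cancel in difference contrasts, so each condition gets its own jitter)
    def _amp(base):
        return base * max(0.1, 1.0 + amp_jitter_sd * rng.standard_normal())
    if experiment == "voice":
        beta = {"V": _amp(preferred_amp) * blob, "A": _amp(other_amp) * blob,
                "E": _amp(other_amp) * blob}
    else:
        beta = {c: _amp(other_amp) * blob for c in ("F", "H", "O", "S")}
    return GroundTruth(
        beta_maps=beta,
        peak_location_mm=center,
        ar_rho=ar_rho,
        innovation_sd=innovation_sd,
        drift_amplitude=drift_amplitude,
    )


def _smooth_fwhm(vol: np.ndarray, spec: AcquisitionSpec, fwhm_mm: float) -> np.ndarray:
    if fwhm_mm <= 0:
        return vol
    sigma = [fwhm_mm / _FWHM_TO_SIGMA / v for v in spec.voxel_size_mm]
    return gaussian_filter(vol, sigma=sigma)


def ar1_noise(
    shape: tuple[int, ...],
    rho: float,
    innovation_sd: float,
    rng: np.random.Generator,
    burn_in: int = 100,
) -> np.ndarray:
    """AR(1) series along the last axis, started from stationarity."""
    if not -1 < rho < 1:
        raise ValueError(f"AR coefficient must lie in (-1, 1), got {rho}")
    n = shape[-1]
    eps = innovation_sd * rng.standard_normal(shape[:-1] + (n + burn_in,))
    series = lfilter([1.0], [1.0, -rho], eps, axis=-1)
    return series[..., burn_in:]


def drift_basis(n_scans: int, orders: Sequence[int] = (1, 2)) -> np.ndarray:
    """Low-order discrete-cosine drift shapes, columns of shape (n_scans,)."""
    n = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans)) for k in orders]
    return np.stack(cols, axis=-1)


def simulate_subject_bold(
    spec: AcquisitionSpec,
    seq: BlockSequence,
    truth: GroundTruth,
    seed: int = 0,
    subject_id: str = "sub-00",
    transient_amplitude: float = 10.0,
    motion_amplitude: float = 0.0,
) -> BoldDataset:
    """Simulate one subject's 4D BOLD run (dummy volumes included).

    signal(v, t) = sum_c beta_c(v) * (boxcar_c (x) HRF)(t), spatially
    smoothed at ``spec.smooth_fwhm_mm``; plus per-voxel slow cosine drift
    (two discrete-cosine shapes below the high-pass cutoff), AR(1) noise
    with ``truth.ar_rho`` and ``truth.innovation_sd`` (plus optional white
    component), and a decaying T1-equilibration transient on the
    ``spec.n_dummy`` leading volumes.  The motion table is zeros unless
    ``motion_amplitude`` adds a slow sinusoidal trace for robustness tests.
    """
    from .first_level import convolved_regressor  # local import avoids a cycle

    truth.validate_grid(spec.grid_shape)
    missing = [c for c in seq.conditions if c not in truth.beta_maps]
    if missing:
        raise ValueError(f"truth lacks beta maps for conditions {missing}")
    rng = np.random.default_rng(seed)
    grid = tuple(spec.grid_shape)
    n, nd = spec.n_scans, spec.n_dummy

    task = np.zeros(grid + (n,))
    for cond in seq.conditions:
        reg = convolved_regressor(seq, cond, spec)
        beta = _smooth_fwhm(truth.beta_maps[cond], spec, spec.smooth_fwhm_mm)
        task += beta[..., None] * reg

    data = np.zeros(grid + (spec.n_total,))
    data[..., nd:] = task

    if truth.drift_amplitude > 0:
        basis = drift_basis(spec.n_total)
        amp = truth.drift_amplitude * rng.standard_normal(grid + (basis.shape[1],))
        data += amp @ basis.T

    if truth.ppi_gain:
        # condition-dependent seed->target coupling, formed at the latent
        # level: the target receives the seed's latent fluctuation scaled by
        # a baseline coupling plus a per-condition gain, then convolved.
        if truth.ppi_target_mm is None:
            raise ValueError("truth.ppi_gain set but ppi_target_mm is undefined")
        from .first_level import canonical_hrf, condition_boxcar

        u = ar1_noise((n,), truth.ppi_latent_rho, truth.ppi_latent_sd, rng)
        hrf = canonical_hrf(spec.tr) * spec.tr
        seed_blob = _gaussian_blob(spec, truth.peak_location_mm, truth.ppi_blob_fwhm_mm)
        target_blob = _gaussian_blob(spec, truth.ppi_target_mm, truth.ppi_blob_fwhm_mm)
        modulated = truth.ppi_base_coupling * u
        for cond, gain in truth.ppi_gain.items():
            psi = condition_boxcar(seq, cond, spec)
            modulated = modulated + gain * (psi - psi.mean()) * u
        seed_sig = np.convolve(u, hrf)[:n]
        target_sig = np.convolve(modulated, hrf)[:n]
        data[..., nd:] += (
            seed_blob[..., None] * seed_sig + target_blob[..., None] * target_sig
        )

    data += ar1_noise(grid + (spec.n_total,), truth.ar_rho, truth.innovation_sd, rng)
    if truth.white_sd > 0:
        data += truth.white_sd * rng.standard_normal(grid + (spec.n_total,))

    if nd > 0 and transient_amplitude != 0:
        t_dummy = np.arange(nd) * spec.tr
        data[..., :nd] += transient_amplitude * np.exp(-t_dummy / max(spec.tr, 1.0))

    motion = np.zeros((spec.n_total, 6))
    if motion_amplitude > 0:
        t = np.arange(spec.n_total) * spec.tr
        for j in range(6):
            period = 60.0 + 15.0 * j
            motion[:, j] = motion_amplitude * np.sin(2 * np.pi * t / period + j)
    return BoldDataset(data=data, spec=spec, motion=motion, subject_id=subject_id)


def simulate_contrast_maps(
    spec: AcquisitionSpec,
    n_maps: int,
    effect: Optional[np.ndarray] = None,
    noise_sd: float = 1.0,
    smooth_fwhm_mm: Optional[float] = None,
    seed: int = 0,
    name: str = "integration",
) -> list[ContrastImage]:
    """Smooth Gaussian random contrast maps, optionally around a fixed effect.

    This is the second-level test bed: each map is spatially smoothed white
    noise rescaled to ``noise_sd``, plus ``effect`` where given, emulating
    the between-subject variability of first-level contrast images without
    the cost of simulating full time series.
    """
    rng = np.random.default_rng(seed)
    fwhm = spec.smooth_fwhm_mm if smooth_fwhm_mm is None else smooth_fwhm_mm
    maps = []
    for i in range(n_maps):
        noise = _smooth_fwhm(rng.standard_normal(spec.grid_shape), spec, fwhm)
        sd = noise.std()
        if sd > 0:
            noise *= noise_sd / sd
        vals = noise if effect is None else noise + effect
        maps.append(
            ContrastImage(values=vals, affine=spec.affine, name=name, subject_id=f"sub-{i:02d}")
        )
    return maps
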