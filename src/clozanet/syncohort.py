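"""Synthetic first-episode-psychosis cohorts.

Generates the four data objects the analysis pipeline consumes — a mixed-type
clinical table, per-subject grey-matter (VBM-style) volumes, per-subject fMRI
time series plus an independent reference group's time series, and an
integer-labelled parcellation — with configurable planted group effects so
that every downstream stage (ISC mapping, region pooling, classification,
inference) can be tested end to end without access to any real cohort.

The generative model is deliberately minimal:

* every region has one shared, stimulus-driven latent time course (the
  "movie" drives all viewers); a subject's voxel time course is that latent
  signal times a coupling coefficient plus i.i.d. Gaussian noise.  Positive
  (treatment-resistant) subjects can have their coupling attenuated in
  designated regions, lowering their expected inter-subject correlation
  there.  Reference subjects always couple at full strength.
* grey-matter volumes are region-wise base levels plus voxel noise, with an
  optional additive shift for positive subjects.
* clinical variables are drawn per kind (scalar / ordinal / binary /
  categorical) with optional standardized group mean shifts, and missing
  values are planted completely at random within a designated subset of
  columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "ClinicalTable",
    "VolumeBundle",
    "CohortBundle",
    "generate_atlas",
    "generate_clinical",
    "generate_imaging",
    "generate_cohort",
    "planted_effects_config",
]

#: column kinds understood by the clinical generator and preprocessor
KINDS = ("scalar", "ordinal", "binary", "categorical")

#: amplitude of the shared latent signal relative to unit voxel noise.
#: With unit noise this gives an expected subject-reference voxel
#: correlation of a^2/(a^2+1) = 0.5 at full coupling.
SIGNAL_AMPLITUDE = 1.0

#: voxel noise standard deviation of the grey-matter volumes
VBM_NOISE_SD = 0.1


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the real study's dimensions: 38 patients of whom 7 are
    clozapine-indicated, a 44-subject reference group, 81 clinical variables
    with ~4.2 % missingness spread over 27 columns.  The grid and region
    count default to desk scale (12x12x12 voxels, 20 regions); a 274-region
    full-scale parcellation is available by configuration.
    """

    n_subjects: int = 38
    n_positive: int = 7
    n_reference: int = 44
    n_clinical: int = 81
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 20
    n_timepoints: int = 240
    clinical_effect_sizes: dict[int, float] = field(default_factory=dict)
    isc_attenuation: dict[int, float] = field(default_factory=dict)
    vbm_effects: dict[int, float] = field(default_factory=dict)
    missing_fraction: float = 0.042
    n_missing_vars: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive >= self.n_subjects:
            raise ValueError("n_positive must be smaller than n_subjects")
        for name in ("n_subjects", "n_positive", "n_reference", "n_clinical",
                     "n_regions", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must be in [0, 1)")
        for region, a in self.isc_attenuation.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(
                    f"isc_attenuation[{region}]={a} outside [0, 1]")
        if self.clinical_effect_sizes and (
                max(self.clinical_effect_sizes) >= self.n_clinical
                or min(self.clinical_effect_sizes) < 0):
            raise ValueError("clinical_effect_sizes indexes beyond n_clinical")
        if self.n_missing_vars > self.n_clinical:
            raise ValueError("n_missing_vars exceeds n_clinical")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class ClinicalTable:
    """Mixed-type clinical table with explicit missingness and column kinds.

    ``data`` holds numeric values with NaN where missing; ``kinds`` maps each
    column to one of scalar / ordinal / binary / categorical.  ``special``
    tags columns with non-default imputation rules — here the pair of a
    smoker flag and a nicotine-dependence score that only exists for smokers.
    """

    data: pd.DataFrame
    kinds: dict[str, str]
    special: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.kinds.values()) - set(KINDS)
        if unknown:
            raise ValueError(f"unknown column kinds: {sorted(unknown)}")
        if set(self.data.columns) != set(self.kinds):
            raise ValueError("kinds must cover exactly the table columns")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class VolumeBundle:
    """Imaging side of a cohort: atlas, VBM volumes and fMRI time series.

    ``subject_ts`` and ``reference_ts`` are (n, T, V) arrays of time-by-voxel
    matrices on the flattened grid; ``vbm`` is (n, V); ``atlas`` is the 3-D
    integer label volume with 0 = background and 1..R regions.
    """

    atlas: np.ndarray
    vbm: np.ndarray
    subject_ts: np.ndarray
    reference_ts: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        v = self.atlas.size
        if self.vbm.shape[1] != v or self.subject_ts.shape[2] != v \
                or self.reference_ts.shape[2] != v:
            raise ValueError("all volumes must share the atlas grid")
        if self.subject_ts.shape[1] != self.reference_ts.shape[1]:
            raise ValueError("subject and reference time lengths differ")
        if self.subject_ts.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match subject count")


@dataclass
class CohortBundle:
    """One complete analysis-ready cohort."""

    config: CohortConfig
    clinical: ClinicalTable
    volumes: VolumeBundle

    @property
    def labels(self) -> np.ndarray:
        return self.volumes.labels

    @property
    def subject_ids(self) -> list[str]:
        return self.clinical.subject_ids


def generate_atlas(config: CohortConfig) -> np.ndarray:
    """Tile the voxel grid into ``n_regions`` contiguous labelled blocks.

    A stand-in for an anatomical parcellation: labels 1..R partition the grid
    in flat (C-order) contiguous slabs, each holding at least two voxels.
    Deterministic for a given config.
    """
    R = config.n_regions
    V = config.n_voxels
    if V < 2 * R:
        raise ValueError(
            f"grid with {V} voxels too small for {R} regions "
            "(need >= 2 voxels per region)")
    # near-equal contiguous chunks; the first V % R regions get one extra voxel
    sizes = np.full(R, V // R, dtype=np.int64)
    sizes[: V % R] += 1
    flat = np.repeat(np.arange(1, R + 1, dtype=np.int32), sizes)
    return flat.reshape(config.grid_shape)


def _draw_labels(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(config.n_subjects, dtype=np.int64)
    labels[rng.choice(config.n_subjects, config.n_positive, replace=False)] = 1
    return labels


def generate_clinical(config: CohortConfig,
                      labels: np.ndarray,
                      rng: np.random.Generator | None = None) -> ClinicalTable:
    """Draw the mixed-type clinical table for one cohort.

    Column kinds cycle scalar / ordinal / binary / categorical.  Standardized
    group mean shifts from ``config.clinical_effect_sizes`` are applied on
    the latent scale of the addressed column.  Missingness is planted
    completely at random within exactly ``n_missing_vars`` columns so that
    the overall missing-cell proportion equals ``missing_fraction``.  One
    smoker-flag / nicotine-score pair exercises the conditional imputation
    rule: the score exists only for smokers.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != config.n_subjects:
        raise ValueError("labels length must equal n_subjects")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, m = config.n_subjects, config.n_clinical
    ids = [f"sub-{i:03d}" for i in range(n)]
    effects = dict(config.clinical_effect_sizes)

    cols: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    special: dict[str, str] = {}

    # reserved pair exercising the conditional-zero imputation rule
    smoker = rng.binomial(1, 0.35, size=n).astype(float)
    nicotine = np.where(
        smoker == 1,
        np.clip(np.round(rng.normal(4.0, 2.0, size=n)), 0, 10),
        np.nan)

    for j in range(m):
        name = f"var{j:02d}"
        kind = KINDS[j % 4]
        delta = effects.get(j, 0.0)
        if j == 0:
            cols[name], kinds[name] = smoker, "binary"
            special[name] = "smoker_flag"
            continue
        if j == 1:
            cols[name], kinds[name] = nicotine, "scalar"
            special[name] = "nicotine_score"
            continue
        if kind == "scalar":
            x = rng.normal(0.0, 1.0, size=n) + delta * labels
        elif kind == "ordinal":
            # BPRS/SANS-style 0..6 item from a rounded latent normal
            latent = rng.normal(3.0, 1.5, size=n) + 1.5 * delta * labels
            x = np.clip(np.round(latent), 0, 6)
        elif kind == "binary":
            logit = rng.normal(-0.5, 0.5) + delta * labels
            x = rng.binomial(1, 1.0 / (1.0 + np.exp(-logit))).astype(float)
        else:  # categorical with <= 6 levels
            k = int(rng.integers(3, 7))
            probs = rng.dirichlet(np.ones(k))
            x = rng.choice(k, size=n, p=probs).astype(float)
        cols[name], kinds[name] = x, kind

    data = pd.DataFrame(cols, index=ids)

    # plant MCAR missingness in exactly n_missing_vars columns (beyond the
    # structural nicotine gaps) at missing_fraction of all table cells
    if config.missing_fraction > 0 and config.n_missing_vars > 0:
        candidates = [c for c in data.columns if c not in special]
        k = min(config.n_missing_vars, len(candidates))
        target_cols = rng.choice(candidates, size=k, replace=False)
        n_cells = int(round(config.missing_fraction * n * m))
        n_cells = max(n_cells, k)  # each designated column gets >= 1 hole
        slots = [(c, i) for c in target_cols for i in range(n)]
        picked = rng.choice(len(slots), size=min(n_cells, len(slots)),
                            replace=False)
        # guarantee coverage of every designated column
        forced = {slots[p][0] for p in picked}
        for c in target_cols:
            if c not in forced:
                picked = np.append(picked, [
                    i for i, s in enumerate(slots) if s[0] == c][0])
        for p in picked:
            c, i = slots[p]
            data.iloc[i, data.columns.get_loc(c)] = np.nan

    return ClinicalTable(data=data, kinds=kinds, special=special)


def generate_imaging(config: CohortConfig,
                     labels: np.ndarray,
                     atlas: np.ndarray,
                     rng: np.random.Generator | None = None) -> VolumeBundle:
    """Draw VBM volumes and stimulus-locked time series for one cohort.

    Each region r carries one latent signal s_r(t) ~ N(0,1) drawn once per
    cohort.  A voxel time course is ``a * c * s_r(t) + N(0,1)`` where ``a``
    is the global signal amplitude and ``c`` the subject's coupling: 1 for
    references and negatives, ``isc_attenuation[r]`` for positives in
    designated regions.  VBM volumes are per-region base levels (U(0.3,0.7))
    plus ``vbm_effects`` for positives plus voxel noise.
    """
    labels = np.asarray(labels)
    if atlas.shape != tuple(config.grid_shape):
        raise ValueError("atlas grid does not match config.grid_shape")
    if labels.shape[0] != config.n_subjects:
        raise ValueError("labels length must equal n_subjects")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    R, T, V = config.n_regions, config.n_timepoints, config.n_voxels
    region_of = atlas.ravel() - 1  # 0-based, background would be -1
    latent = rng.normal(size=(R, T))  # the shared "movie" drive

    def draw_group(n: int, attenuate: np.ndarray) -> np.ndarray:
        ts = rng.normal(size=(n, T, V))
        for i in range(n):
            coup = np.ones(V)
            if attenuate[i]:
                for r, a in config.isc_attenuation.items():
                    coup[region_of == r - 1] = a
            ts[i] += SIGNAL_AMPLITUDE * coup * latent[region_of].T
        return ts

    subject_ts = draw_group(config.n_subjects, labels.astype(bool))
    reference_ts = draw_group(config.n_reference,
                              np.zeros(config.n_reference, dtype=bool))

    base = rng.uniform(0.3, 0.7, size=R)
    vbm = base[region_of] + rng.normal(0.0, VBM_NOISE_SD,
                                       size=(config.n_subjects, V))
    for r, eff in config.vbm_effects.items():
        vbm[labels == 1] += eff * (region_of == r - 1)

    return VolumeBundle(atlas=atlas, vbm=vbm, subject_ts=subject_ts,
                        reference_ts=reference_ts, labels=labels)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a full, mutually consistent cohort from one config."""
    rng_labels = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    labels = _draw_labels(config, rng_labels)
    atlas = generate_atlas(config)
    clinical = generate_clinical(config, labels)
    volumes = generate_imaging(config, labels, atlas)
    return CohortBundle(config=config, clinical=clinical, volumes=volumes)


def planted_effects_config(seed: int = 0, **overrides) -> CohortConfig:
    """A cohort config with strong planted group effects.

    The preset used by the signal-recovery checks: shared-signal coupling
    attenuated to 0.25 for positive subjects in four of the default twenty
    regions, a +1.2 SD shift on six scalar clinical variables, and a +0.15
    grey-matter shift in four regions.
    """
    cfg = dict(
        seed=seed,
        isc_attenuation={1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25},
        clinical_effect_sizes={4: 1.2, 8: 1.2, 12: 1.2, 16: 1.2,
                               20: 1.2, 24: 1.2},
        vbm_effects={5: 0.15, 6: 0.15, 7: 0.15, 8: 0.15},
    )
    cfg.update(overrides)
    return CohortConfig(**cfg)


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """A cohort config with no group effects anywhere (the null model)."""
    return CohortConfig(seed=seed, **overrides)
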