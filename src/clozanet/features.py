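"""Feature construction: region pooling, clinical preprocessing, assembly.

The classifier sees up to nine feature blocks per subject: one clinical
block (81 variables, imputed and min-max scaled to [0, 1] with statistics
fitted on training rows only) and eight imaging blocks — min, max, mean and
sample-SD pooling of the VBM and ISC maps over the atlas regions.  At the
full 274-region parcellation this yields 8 x 274 = 2192 imaging features.

Clinical preprocessing is leakage-safe by construction: ``PreprocessModel``
is fitted exclusively from training rows and then applied to any table, so
test subjects can never influence imputation values or scaling ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .syncohort import ClinicalTable

__all__ = [
    "MAP_NAMES",
    "RegionFeatureBlock",
    "FeatureSet",
    "PreprocessModel",
    "pool_map",
    "pool_modality",
    "fit_clinical_preprocessor",
    "apply_clinical_preprocessor",
    "assemble_feature_set",
]

logger = logging.getLogger(__name__)

POOL_STATS = ("min", "max", "mean", "sd")
MAP_NAMES = tuple(f"{mod}_{s}" for mod in ("vbm", "isc") for s in POOL_STATS)


@dataclass
class RegionFeatureBlock:
    """Per-region pooled values of one map for one or more subjects.

    ``values`` is (n_subjects, R), column r-1 holding atlas label r.
    """

    name: str
    values: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureSet:
    """Stacked per-subject feature matrix with an explicit modality layout.

    ``layout`` maps each block name to its (start, stop) column range in
    ``X``; ranges are disjoint and cover the matrix.
    """

    X: np.ndarray
    layout: dict[str, tuple[int, int]]
    subject_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        spans = sorted(self.layout.values())
        if spans[0][0] != 0 or spans[-1][1] != self.X.shape[1] or any(
                spans[i][1] != spans[i + 1][0] for i in range(len(spans) - 1)):
            raise ValueError("layout ranges must be disjoint and cover X")

    @property
    def width(self) -> int:
        return self.X.shape[1]

    def block(self, name: str) -> np.ndarray:
        a, b = self.layout[name]
        return self.X[:, a:b]

    def feature_names(self) -> list[str]:
        names = [""] * self.width
        for blk, (a, b) in self.layout.items():
            for k in range(b - a):
                names[a + k] = f"{blk}:{k}" if blk == "clinical" \
                    else f"{blk}:region{k + 1}"
        return names


def pool_map(map_volume: np.ndarray, atlas: np.ndarray) -> dict[str, np.ndarray]:
    """Min/max/mean/sample-SD of a map's voxels within each atlas region.

    Accepts a single flat/3-D map or a stack of per-subject maps (first axis
    = subjects).  Returns ``{stat: (n, R) array}``.  SD is the sample
    standard deviation (n-1 denominator).
    """
    lab = np.asarray(atlas).ravel()
    vals = np.asarray(map_volume, dtype=float)
    single = vals.ndim == len(np.shape(atlas)) and vals.size == lab.size
    flat = vals.reshape(1, -1) if single else vals.reshape(vals.shape[0], -1)
    if flat.shape[1] != lab.size:
        raise ValueError("map and atlas are not on the same grid")
    R = int(lab.max())
    inside = lab > 0
    counts = np.bincount(lab[inside], minlength=R + 1)[1:]
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        raise ValueError(f"atlas label {empty[0] + 1} has no voxels")

    n = flat.shape[0]
    out = {s: np.empty((n, R)) for s in POOL_STATS}
    lab_in = lab[inside]
    order = np.argsort(lab_in, kind="stable")
    lab_sorted = lab_in[order]
    bounds = np.searchsorted(lab_sorted, np.arange(1, R + 2))
    for i in range(n):
        v = flat[i, inside][order]
        sums = np.add.reduceat(v, bounds[:-1])
        sqs = np.add.reduceat(v * v, bounds[:-1])
        out["mean"][i] = sums / counts
        out["min"][i] = np.minimum.reduceat(v, bounds[:-1])
        out["max"][i] = np.maximum.reduceat(v, bounds[:-1])
        var = (sqs - sums**2 / counts) / np.maximum(counts - 1, 1)
        out["sd"][i] = np.sqrt(np.maximum(var, 0.0))
        out["sd"][i, counts == 1] = 0.0
    if single:
        out = {s: a[0] for s, a in out.items()}
    return out


def pool_modality(maps: np.ndarray, atlas: np.ndarray,
                  modality: str) -> list[RegionFeatureBlock]:
    """Pool a stack of per-subject maps into the modality's four blocks."""
    pooled = pool_map(maps, atlas)
    return [RegionFeatureBlock(name=f"{modality}_{s}", values=pooled[s])
            for s in POOL_STATS]


@dataclass
class PreprocessModel:
    """Training-data statistics for clinical imputation and [0,1] scaling.

    For each column: the imputation value (mean for scalar/ordinal, mode for
    binary/categorical), the level -> code mapping for categoricals (unseen
    test levels map to the extra "unknown" code), and the training min/max
    used for scaling.  Columns with max == min scale to 0 everywhere.
    """

    impute: dict[str, float]
    codes: dict[str, dict[float, int]]
    scale_min: dict[str, float]
    scale_max: dict[str, float]
    kinds: dict[str, str]
    special: dict[str, str]
    fitted_on: list[str] = field(default_factory=list)


def _smoker_column(table: ClinicalTable) -> str | None:
    for c, tag in table.special.items():
        if tag == "smoker_flag":
            return c
    return None


def fit_clinical_preprocessor(train: ClinicalTable) -> PreprocessModel:
    """Fit imputation values, categorical codes and scaling ranges on
    training rows only.

    Scalar and ordinal columns impute with the training mean, binary and
    categorical columns with the training mode.  A nicotine-dependence
    column is imputed 0 for non-smokers before its mean is taken, mirroring
    the rule that the score is defined as 0 for anyone who does not smoke.
    """
    df = train.data
    if len(df) < 2:
        raise ValueError("need at least two training subjects")
    smoker_col = _smoker_column(train)
    smoker = df[smoker_col].to_numpy(float) if smoker_col else None
    impute: dict[str, float] = {}
    codes: dict[str, dict[float, int]] = {}
    scale_min: dict[str, float] = {}
    scale_max: dict[str, float] = {}

    for col, kind in train.kinds.items():
        x = df[col].to_numpy(float).copy()
        if train.special.get(col) == "nicotine_score" and smoker is not None:
            x[np.isnan(x) & (smoker == 0)] = 0.0
        miss = np.isnan(x)
        obs = x[~miss]
        if obs.size == 0:
            raise ValueError(f"column {col!r} entirely missing in training "
                             "data and has no special rule")
        if kind in ("scalar", "ordinal"):
            impute[col] = float(obs.mean())
        else:
            levels, freq = np.unique(obs, return_counts=True)
            impute[col] = float(levels[np.argmax(freq)])
        x[miss] = impute[col]
        if kind == "categorical":
            levels = np.unique(obs)
            codes[col] = {float(v): i for i, v in enumerate(levels)}
            x = _encode_levels(x, levels)
        scale_min[col], scale_max[col] = float(x.min()), float(x.max())

    return PreprocessModel(impute=impute, codes=codes, scale_min=scale_min,
                           scale_max=scale_max, kinds=dict(train.kinds),
                           special=dict(train.special),
                           fitted_on=list(df.index))


def _encode_levels(x: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Map values to their sorted-level codes; unseen values get code
    ``len(levels)`` (the "unknown" code)."""
    pos = np.searchsorted(levels, x).clip(0, len(levels) - 1)
    seen = levels[pos] == x
    return np.where(seen, pos, len(levels)).astype(float)


def apply_clinical_preprocessor(model: PreprocessModel,
                                table: ClinicalTable) -> pd.DataFrame:
    """Impute, code and min-max scale a clinical table with fitted statistics.

    Training rows land in [0, 1] by construction; rows outside the training
    range (test subjects) are clipped to [0, 1].  Unseen categorical levels
    map to the "unknown" code and are logged.
    """
    if set(table.data.columns) != set(model.kinds):
        raise ValueError("table columns do not match the fitted model")
    df = table.data
    smoker_col = _smoker_column(table)
    smoker = df[smoker_col].to_numpy(float) if smoker_col else None
    cols = list(model.kinds)
    out = np.empty((len(df), len(cols)))
    for j, col in enumerate(cols):
        kind = model.kinds[col]
        x = df[col].to_numpy(float).copy()
        if model.special.get(col) == "nicotine_score" and smoker is not None:
            x[np.isnan(x) & (smoker == 0)] = 0.0
        x[np.isnan(x)] = model.impute[col]
        if kind == "categorical":
            levels = np.fromiter(model.codes[col], dtype=float)
            coded = _encode_levels(x, levels)
            n_unseen = int((coded == len(levels)).sum())
            if n_unseen:
                logger.debug("column %s: %d unseen level(s) mapped to the "
                             "unknown code", col, n_unseen)
            x = coded
        lo, hi = model.scale_min[col], model.scale_max[col]
        if hi == lo:  # information-free column
            out[:, j] = 0.0
        else:
            out[:, j] = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return pd.DataFrame(out, index=df.index, columns=cols)


def assemble_feature_set(selection,
                         subject_ids,
                         labels,
                         clinical: pd.DataFrame | None = None,
                         vbm_blocks: list[RegionFeatureBlock] | None = None,
                         isc_blocks: list[RegionFeatureBlock] | None = None,
                         ) -> FeatureSet:
    """Stack the selected modalities into one feature matrix with a layout.

    ``selection`` is a subset of {"clinical", "vbm", "isc"}.  Components must
    be row-aligned with ``subject_ids``.  Imaging features pass through
    unscaled; the clinical matrix is expected to be already preprocessed.
    """
    selection = list(selection)
    if not selection:
        raise ValueError("empty modality selection")
    unknown = set(selection) - {"clinical", "vbm", "isc"}
    if unknown:
        raise ValueError(f"unknown modalities: {sorted(unknown)}")
    subject_ids = list(subject_ids)
    n = len(subject_ids)

    parts: list[np.ndarray] = []
    layout: dict[str, tuple[int, int]] = {}
    pos = 0

    def add(name: str, arr: np.ndarray) -> None:
        nonlocal pos
        if arr.shape[0] != n:
            raise ValueError(f"block {name!r} has {arr.shape[0]} rows, "
                             f"expected {n}")
        parts.append(np.asarray(arr, dtype=float))
        layout[name] = (pos, pos + arr.shape[1])
        pos += arr.shape[1]

    if "clinical" in selection:
        if clinical is None:
            raise ValueError("clinical selected but no clinical matrix given")
        if list(clinical.index) != subject_ids:
            raise ValueError("clinical rows are not aligned with subject_ids")
        add("clinical", clinical.to_numpy(dtype=float))
    for mod, blocks in (("vbm", vbm_blocks), ("isc", isc_blocks)):
        if mod in selection:
            if not blocks:
                raise ValueError(f"{mod} selected but no pooled blocks given")
            for blk in blocks:
                add(blk.name, blk.values)

    return FeatureSet(X=np.hstack(parts), layout=layout,
                      subject_ids=subject_ids,
                      labels=np.asarray(labels, dtype=int))
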