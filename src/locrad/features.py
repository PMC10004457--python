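"""Global aggregation of parametric maps into 144 named radiomic features.

The pooled all-slice distribution of each of the 12 parametric maps is
summarised with the same 12 first-order statistics, giving 12 x 12 = 144
features per sample.  A feature key is ``"<MAP>-<STAT>"`` built from the
short statistic codes, e.g. ``S-MAD`` is the median absolute deviation of
the local-skewness map and ``K-M90th`` the median of the last decile of
the local-kurtosis map.  The codes (Mn = mean, M = median) keep the two
"M" statistics unambiguous while matching the names used in clinical
reports (S-MAD, K-M90th, U-CV, M-CV, E-IQR, M-IQR, ...).

The pooled-level entropy/uniformity histogram spans each pooled map's own
min-max with the same bin count as the local level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import STAT_ORDER, HistogramSpec, LocalStat, stat_from_code, stats_batch
from .imaging import CohortManifest, Group, Modality, RoiMask, ImageVolume, read_mask, read_volume
from .localmaps import ParametricMapStack, WindowSpec, build_maps

__all__ = [
    "FEATURE_KEYS",
    "feature_key",
    "parse_feature_key",
    "FeatureVector",
    "CohortTable",
    "aggregate",
    "extract_features",
    "build_cohort_table",
]

logger = logging.getLogger(__name__)


def feature_key(map_stat: LocalStat, pooled_stat: LocalStat) -> str:
    """Canonical name of one radiomic feature."""
    return f"{map_stat.code}-{pooled_stat.code}"


def parse_feature_key(key: str) -> tuple[LocalStat, LocalStat]:
    """Inverse of :func:`feature_key`; raises ``KeyError`` on unknown keys."""
    map_code, _, stat_code = key.partition("-")
    if not stat_code:
        raise KeyError(f"malformed feature key {key!r}")
    return stat_from_code(map_code), stat_from_code(stat_code)


#: the 144 canonical feature names, map-major then statistic order
FEATURE_KEYS: tuple[str, ...] = tuple(
    feature_key(m, s) for m in STAT_ORDER for s in STAT_ORDER
)


@dataclass
class FeatureVector:
    """The 144 radiomic features of one sample."""

    sample_id: str
    modality: Modality
    values: dict[str, float]

    def __post_init__(self) -> None:
        if tuple(self.values) != FEATURE_KEYS:
            if set(self.values) != set(FEATURE_KEYS):
                raise ValueError("feature vector must contain exactly the 144 canonical keys")
            self.values = {k: self.values[k] for k in FEATURE_KEYS}
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite features: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def aggregate(
    stack: ParametricMapStack,
    *,
    n_bins: int | None = None,
    cv_guard_eps: float = 1e-6,
    sample_id: str = "",
    modality: Modality = Modality.CT,
) -> FeatureVector:
    """Collapse a parametric-map stack into the 144 radiomic features.

    For each map the in-ROI values of all slices are pooled into one
    distribution and summarised with the 12 first-order statistics, using
    a histogram spanning the pooled values themselves.
    """
    if n_bins is None:
        n_bins = stack.hist.n_bins
    values: dict[str, float] = {}
    for map_stat in STAT_ORDER:
        pooled = stack.pooled(map_stat)
        if pooled.size == 0:
            raise ValueError("parametric map has empty support")
        hist = HistogramSpec.from_values(pooled, n_bins=n_bins)
        guard = cv_guard_eps * (hist.hi - hist.lo)
        row = stats_batch(pooled[None, :], hist, cv_guard_abs=guard)[0]
        for j, pooled_stat in enumerate(STAT_ORDER):
            values[feature_key(map_stat, pooled_stat)] = float(row[j])
    return FeatureVector(sample_id=sample_id, modality=modality, values=values)


def extract_features(
    volume: ImageVolume,
    mask: RoiMask,
    window: WindowSpec | None = None,
    *,
    n_bins: int = 16,
    clip_to_roi: bool = False,
    cv_guard_eps: float = 1e-6,
    sample_id: str = "",
) -> FeatureVector:
    """Convenience composition: parametric maps then global aggregation."""
    stack = build_maps(
        volume,
        mask,
        window,
        n_bins=n_bins,
        clip_to_roi=clip_to_roi,
        cv_guard_eps=cv_guard_eps,
        source_id=sample_id or None,
    )
    return aggregate(
        stack, cv_guard_eps=cv_guard_eps, sample_id=sample_id, modality=volume.modality
    )


@dataclass
class CohortTable:
    """Samples x 144 feature matrix with group labels, one modality."""

    features: pd.DataFrame          # index: sample id; columns: FEATURE_KEYS
    labels: pd.Series               # Group per sample id
    modality: Modality
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if tuple(self.features.columns) != FEATURE_KEYS:
            raise ValueError("cohort table columns must be the 144 canonical feature keys")
        if not self.features.index.equals(self.labels.index):
            raise ValueError("labels must be indexed like the feature matrix")
        if self.features.isna().any().any():
            raise ValueError("cohort table has missing cells")
        self.labels = self.labels.map(Group)

    def __len__(self) -> int:
        return len(self.features)

    def n_per_group(self) -> dict[Group, int]:
        counts = self.labels.value_counts()
        return {g: int(counts.get(g, 0)) for g in Group}

    def y(self) -> np.ndarray:
        """Binary labels, 1 for the positive (recurrence) class."""
        return (self.labels == Group.LRRC).to_numpy().astype(int)

    def to_csv(self, path) -> None:
        df = self.features.copy()
        df.insert(0, "group", self.labels.map(lambda g: g.value))
        df.insert(0, "modality", self.modality.value)
        df.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path, index_col="id")
        df.index = df.index.astype(str)
        df.index.name = None
        modality = Modality(df.pop("modality").iloc[0])
        labels = df.pop("group").map(Group)
        return cls(features=df[list(FEATURE_KEYS)], labels=labels, modality=modality)


def build_cohort_table(
    manifest: CohortManifest,
    modality: Modality,
    *,
    window: WindowSpec | None = None,
    n_bins: int = 16,
    clip_to_roi: bool = False,
    cv_guard_eps: float = 1e-6,
) -> CohortTable:
    """Run imaging -> maps -> aggregation for every manifest sample.

    Samples whose files cannot be processed are skipped with a logged
    reason and listed in ``CohortTable.skipped``.
    """
    modality = Modality(modality)
    sub = manifest.subset(modality)
    counts = sub.n_per_group()
    if min(counts.values()) < 1:
        raise ValueError(
            f"both groups must be non-empty for modality {modality.value}: {counts}"
        )
    rows: dict[str, dict[str, float]] = {}
    labels: dict[str, Group] = {}
    skipped: list[tuple[str, str]] = []
    for entry in sub:
        try:
            volume = read_volume(entry.volume_path, modality)
            mask = read_mask(entry.mask_path)
            fv = extract_features(
                volume,
                mask,
                window,
                n_bins=n_bins,
                clip_to_roi=clip_to_roi,
                cv_guard_eps=cv_guard_eps,
                sample_id=entry.sample_id,
            )
        except Exception as exc:
            logger.warning("skipping sample %s: %s", entry.sample_id, exc)
            skipped.append((entry.sample_id, str(exc)))
            continue
        rows[entry.sample_id] = fv.values
        labels[entry.sample_id] = entry.group
    if not rows:
        raise ValueError("no sample could be processed")
    features = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_KEYS))
    return CohortTable(
        features=features,
        labels=pd.Series(labels, name="group").loc[features.index],
        modality=modality,
        skipped=skipped,
    )
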