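"""Seeded generator of morphometric-feature-like classification datasets.

Emulates the shape of a FreeSurfer-derived feature table for three
diagnostic groups — normal controls (NC), mild cognitive impairment (MCI)
and Alzheimer's disease (AD) — without any real subject data. Features come
in five named blocks matching the usual morphometric families: Cortical
Volumes (CV, 70), Subcortical Volumes (SV, 42), Surface Areas (SA, 72),
Thickness Averages (TA, 70) and Thickness Std. (TS, 70); D = 324 in total.
Default per-class sample counts are 655/825/513 (N = 1993).

The class structure encodes the clinically salient facts: only a designated
subset of features carries diagnostic signal (by default 20 subcortical
volumes); NC and AD means sit ``effect_size`` within-class standard
deviations apart on those features; MCI is intermediate (its mean
interpolates NC -> AD by ``mci_position``) and heterogeneous (its spread on
the informative features is inflated by ``mci_spread_multiplier``). All
other features are pure noise, either independent standard normal or a
shared low-rank-plus-diagonal covariance mimicking global size correlations.

Labels are 1 = NC, 2 = MCI, 3 = AD. The draw is bitwise reproducible for a
fixed spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GROUP_SIZES",
    "SyntheticSpec",
    "SyntheticDataset",
    "generate",
    "tiny_fixture",
    "group_index_map",
]

DEFAULT_GROUP_SIZES: dict[str, int] = {"CV": 70, "SV": 42, "SA": 72, "TA": 70, "TS": 70}
DEFAULT_N_PER_CLASS: tuple[int, int, int] = (655, 825, 513)
CLASS_NAMES = ("NC", "MCI", "AD")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort; defaults mirror the emulated study.

    ``effect_size`` is the NC-to-AD mean separation on each informative
    feature, in units of the within-class standard deviation; 1.5 is a
    moderate, realistically attainable morphometric group difference.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_per_class: tuple[int, ...] = DEFAULT_N_PER_CLASS
    informative_features: tuple[int, ...] | None = None  # default: first 20 of SV
    effect_size: float = 1.5
    mci_position: float = 0.5
    mci_spread_multiplier: float = 2.0
    noise_cov: str = "identity"  # or "lowrank"
    noise_rank: int = 5
    noise_strength: float = 0.5
    seed: int = 0

    @property
    def n_features(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_class)

    def resolved_informative(self) -> np.ndarray:
        if self.informative_features is not None:
            return np.asarray(self.informative_features, dtype=int)
        names = list(self.group_sizes)
        if "SV" in self.group_sizes:
            start = sum(self.group_sizes[g] for g in names[: names.index("SV")])
            width = min(20, self.group_sizes["SV"])
        else:
            start, width = 0, min(20, self.n_features)
        return np.arange(start, start + width)

    def validate(self) -> None:
        if not self.group_sizes or any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("group_sizes must be positive")
        if len(self.n_per_class) != 3 or any(n < 1 for n in self.n_per_class):
            raise ValueError("n_per_class must hold three positive counts")
        info = self.resolved_informative()
        if info.size == 0 or info.min() < 0 or info.max() >= self.n_features:
            raise ValueError("informative feature indices outside 0..D-1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.mci_position <= 1.0:
            raise ValueError("mci_position must lie in [0, 1]")
        if self.mci_spread_multiplier < 1.0:
            raise ValueError("mci_spread_multiplier must be >= 1")
        if self.noise_cov not in ("identity", "lowrank"):
            raise ValueError("noise_cov must be 'identity' or 'lowrank'")


@dataclass
class SyntheticDataset:
    X: np.ndarray
    t: np.ndarray
    feature_names: list[str]
    spec: SyntheticSpec

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.t
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def group_index_map(group_sizes: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Column indices of each feature block, in declaration order."""
    group_sizes = group_sizes if group_sizes is not None else DEFAULT_GROUP_SIZES
    out: dict[str, np.ndarray] = {}
    start = 0
    for name, width in group_sizes.items():
        out[name] = np.arange(start, start + width)
        start += width
    return out


def _feature_names(group_sizes: dict[str, int]) -> list[str]:
    names = []
    for g, width in group_sizes.items():
        names.extend(f"{g}_{i:03d}" for i in range(width))
    return names


def generate(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Draw one dataset from the class-conditional Gaussian model of ``spec``.

    Class means on the informative features: NC at -effect_size/2, AD at
    +effect_size/2, MCI linearly interpolated by ``mci_position`` with its
    standard deviation multiplied by ``mci_spread_multiplier``. Everything
    else is mean-zero noise shared by all classes.
    """
    spec = spec if spec is not None else SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    D = spec.n_features
    N = spec.n_samples
    info = spec.resolved_informative()

    if spec.noise_cov == "lowrank":
        U = rng.standard_normal((D, spec.noise_rank)) * np.sqrt(
            spec.noise_strength / spec.noise_rank
        )
        X = rng.standard_normal((N, spec.noise_rank)) @ U.T + rng.standard_normal((N, D))
    else:
        X = rng.standard_normal((N, D))

    e = spec.effect_size
    class_means = {1: -e / 2.0, 2: -e / 2.0 + spec.mci_position * e, 3: +e / 2.0}
    t = np.repeat(np.array([1, 2, 3]), spec.n_per_class)
    start = 0
    for cls, n_c in zip((1, 2, 3), spec.n_per_class):
        rows = slice(start, start + n_c)
        if cls == 2 and spec.mci_spread_multiplier != 1.0:
            X[rows, info.reshape(1, -1)] *= spec.mci_spread_multiplier
        X[rows, info.reshape(1, -1)] += class_means[cls]
        start += n_c
    return SyntheticDataset(
        X=X, t=t, feature_names=_feature_names(spec.group_sizes), spec=spec
    )


# Hand-written 12-sample, 6-feature, 3-class table for exact regression tests.
# Features: two per block of a reduced {A, B, C} schema; classes 1/2/3 are
# separated on the first two features only.
_TINY_X = np.array(
    [
        [-1.20, -0.80, 0.30, -0.50, 0.10, 0.90],
        [-0.90, -1.10, -0.40, 0.20, -0.70, 0.30],
        [-1.50, -0.60, 0.80, 0.60, 0.40, -0.20],
        [-0.70, -1.30, -0.10, -0.90, -0.30, -0.60],
        [0.10, -0.20, 0.50, 0.10, -0.90, 0.40],
        [-0.30, 0.40, -0.60, -0.30, 0.70, -0.80],
        [0.40, 0.10, 0.20, 0.80, -0.10, 0.60],
        [-0.10, -0.40, -0.80, -0.20, 0.30, 0.10],
        [1.10, 0.90, 0.60, -0.40, -0.50, -0.30],
        [0.80, 1.20, -0.20, 0.50, 0.80, 0.70],
        [1.40, 0.70, 0.10, -0.70, -0.20, -0.90],
        [0.90, 1.00, -0.50, 0.30, 0.60, 0.20],
    ]
)
_TINY_T = np.array([1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3])
_TINY_NAMES = ["A_000", "A_001", "B_000", "B_001", "C_000", "C_001"]


def tiny_fixture() -> SyntheticDataset:
    """Fixed 12 x 6 three-class dataset with hand-written values.

    Shipped as constants (not generated) so regression tests are exact and
    platform independent.
    """
    spec = SyntheticSpec(
        group_sizes={"A": 2, "B": 2, "C": 2},
        n_per_class=(4, 4, 4),
        informative_features=(0, 1),
        effect_size=2.0,
        seed=0,
    )
    return SyntheticDataset(
        X=_TINY_X.copy(), t=_TINY_T.copy(), feature_names=list(_TINY_NAMES), spec=spec
    )
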