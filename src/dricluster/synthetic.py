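"""Synthetic benchmark families and the repeated-trial recovery harness.

Three artificial data families, one per data type the index supports:

* **categorical** — n=100 objects on 10 binary variables in two equal
  groups; variable j in group g is Bernoulli with a group contrast of
  0.8 vs 0.2, alternating which group carries the high rate so neither
  group is uniformly "high".
* **numerical** — n=150 points in two dimensions, three equal clusters of
  bivariate standard normals centred at (0, 0), (0, 5) and (5, -3).
* **mixed** — n=250 objects in five equal groups observed on two binary
  variables (group rates alternating 0.9/0.1), one ordinal variable with
  five levels whose distribution shifts across groups, and one numeric
  variable with unit variance and group means spaced 3.0 apart.

``run_trials`` regenerates a family repeatedly with independent seeds,
runs the deviation-ratio-index selection over k = 2..10 with the
family-appropriate distance (matching / Euclidean / Gower), and tallies
how often the selected k lands on, near, or far from the true k.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import FeatureTable, VariableSpec
from .indices import dri_curve, select_k
from .preprocess import standardize
from .proximity import DistanceSpec

__all__ = [
    "SyntheticSpec",
    "TrialTable",
    "gen_categorical",
    "gen_numerical",
    "gen_mixed",
    "generate",
    "run_trials",
    "FAMILIES",
]

FAMILIES = ("categorical", "numerical", "mixed")

NUMERICAL_CENTRES = ((0.0, 0.0), (0.0, 5.0), (5.0, -3.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic family draw.

    Family defaults (n, variable counts, true k) are fixed; the remaining
    knobs control separation and exist for sensitivity checks, not for the
    benchmark itself.
    """

    family: str
    seed: int = 0
    n: int | None = None
    true_k: int | None = None
    # categorical family: per-variable Bernoulli contrast (high, low)
    contrast: tuple[float, float] = (0.8, 0.2)
    # numerical family: cluster centres
    centres: tuple[tuple[float, float], ...] = NUMERICAL_CENTRES
    # mixed family: binary rates, ordinal levels, numeric mean spacing
    mixed_binary: tuple[float, float] = (0.95, 0.05)
    ordinal_levels: int = 5
    numeric_spacing: float = 4.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        defaults = {"categorical": (100, 2), "numerical": (150, 3),
                    "mixed": (250, 5)}
        n, k = defaults[self.family]
        if self.n is None:
            object.__setattr__(self, "n", n)
        if self.true_k is None:
            object.__setattr__(self, "true_k", k)


@dataclass(frozen=True)
class TrialTable:
    """Frequency of selected cluster numbers over repeated trials.

    Buckets count trials whose selected k fell at least two below, one
    below, on, one above, or at least two above the true k; ``none``
    counts trials where no k in the scanned range qualified.  All counts
    sum to ``trials``.
    """

    family: str
    true_k: int
    trials: int
    counts: dict[str, int] = field(default_factory=dict)
    selections: tuple[int | None, ...] = ()

    BUCKETS = ("le_km2", "km1", "k", "kp1", "ge_kp2", "none")

    def __post_init__(self) -> None:
        total = sum(self.counts.get(b, 0) for b in self.BUCKETS)
        if total != self.trials:
            raise ValueError("bucket counts do not sum to trials")

    @property
    def correct(self) -> int:
        return self.counts.get("k", 0)

    @property
    def correct_fraction(self) -> float:
        return self.correct / self.trials


def _table(values: np.ndarray, schema, prefix: str = "obj") -> FeatureTable:
    n = values.shape[0]
    return FeatureTable(
        objects=tuple(f"{prefix}{i + 1}" for i in range(n)),
        values=values,
        schema=tuple(schema),
    )


def gen_categorical(spec: SyntheticSpec) -> tuple[FeatureTable, np.ndarray]:
    """Two equal groups of Bernoulli vectors on 10 binary variables."""
    rng = np.random.default_rng(spec.seed)
    n, k, p = spec.n, spec.true_k, 10
    sizes = _equal_sizes(n, k)
    hi, lo = spec.contrast
    # alternate which group gets the high rate per variable
    rates = np.empty((k, p))
    for j in range(p):
        for g in range(k):
            rates[g, j] = hi if (g + j) % 2 == 0 else lo
    rows, labels = [], []
    for g, size in enumerate(sizes):
        rows.append(rng.random((size, p)) < rates[g])
        labels.append(np.full(size, g + 1))
    values = np.vstack(rows).astype(float)
    schema = [VariableSpec(name=f"b{j + 1}", kind="binary") for j in range(p)]
    return _table(values, schema), np.concatenate(labels)


def gen_numerical(spec: SyntheticSpec) -> tuple[FeatureTable, np.ndarray]:
    """Three equal bivariate standard-normal clusters at the family
    centres (0,0), (0,5), (5,-3)."""
    rng = np.random.default_rng(spec.seed)
    centres = np.asarray(spec.centres, dtype=float)
    k = centres.shape[0]
    sizes = _equal_sizes(spec.n, k)
    rows, labels = [], []
    for g, size in enumerate(sizes):
        rows.append(rng.standard_normal((size, centres.shape[1])) + centres[g])
        labels.append(np.full(size, g + 1))
    values = np.vstack(rows)
    schema = [
        VariableSpec(name=f"x{j + 1}", kind="numeric")
        for j in range(centres.shape[1])
    ]
    return _table(values, schema), np.concatenate(labels)


# mixed-family group design: the four distinct high/low binary profiles
# identify four groups, the fifth reuses (hi, hi); the ordinal mode and the
# numeric mean rank are permuted relative to the binary profiles so that no
# variable is monotone in the group index and no group sits at the extreme
# of every variable at once (which would make its rows near-constant and
# collapse the block-deviation initialization onto a single group)
MIXED_ORDINAL_MODES = (1, 3, 5, 2, 4)
MIXED_NUMERIC_ORDER = (1, 3, 0, 4, 2)
_MIXED_ORDINAL_NOISE = (0.05, 0.90, 0.05)  # P(mode-1), P(mode), P(mode+1)


def gen_mixed(spec: SyntheticSpec) -> tuple[FeatureTable, np.ndarray]:
    """Five equal groups on 2 binary + 1 ordinal + 1 numeric variables.

    Binary cells follow the group's high/low profile; the ordinal sits on
    a group-specific modal category with occasional one-level slips; the
    numeric variable is unit-variance normal around a group mean spaced
    ``numeric_spacing`` standard deviations apart.
    """
    rng = np.random.default_rng(spec.seed)
    n, k, M = spec.n, spec.true_k, spec.ordinal_levels
    sizes = _equal_sizes(n, k)
    hi, lo = spec.mixed_binary
    profiles = [(hi, hi), (hi, lo), (lo, hi), (lo, lo), (hi, hi)]
    rows, labels = [], []
    for g, size in enumerate(sizes):
        p1, p2 = profiles[g % len(profiles)]
        b1 = rng.random(size) < p1
        b2 = rng.random(size) < p2
        mode = MIXED_ORDINAL_MODES[g % len(MIXED_ORDINAL_MODES)]
        slips = rng.choice((-1, 0, 1), p=_MIXED_ORDINAL_NOISE, size=size)
        ranks = np.clip(mode + slips, 1, M)
        mean = spec.numeric_spacing * MIXED_NUMERIC_ORDER[g % k]
        num = rng.standard_normal(size) + mean
        rows.append(np.column_stack([b1, b2, ranks, num]).astype(float))
        labels.append(np.full(size, g + 1))
    values = np.vstack(rows)
    schema = [
        VariableSpec(name="b1", kind="binary"),
        VariableSpec(name="b2", kind="binary"),
        VariableSpec(name="ord1", kind="ordinal", levels=M),
        VariableSpec(name="num1", kind="numeric"),
    ]
    return _table(values, schema), np.concatenate(labels)


_GENERATORS = {
    "categorical": gen_categorical,
    "numerical": gen_numerical,
    "mixed": gen_mixed,
}

# distance used per family when scoring recovery (matching for pure
# categorical data, Euclidean for numeric, Gower for mixed)
FAMILY_DISTANCE = {
    "categorical": "matching",
    "numerical": "euclidean",
    "mixed": "gower",
}

# standardization applied before clustering, per family
FAMILY_STANDARDIZE = {
    "categorical": "none",
    "numerical": "minmax",
    "mixed": "minmax",
}


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, np.ndarray]:
    """Dispatch to the family's generator."""
    return _GENERATORS[spec.family](spec)


def _equal_sizes(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if g < extra else 0) for g in range(k)]


def _bucket(selected: int | None, true_k: int) -> str:
    if selected is None:
        return "none"
    if selected <= true_k - 2:
        return "le_km2"
    if selected == true_k - 1:
        return "km1"
    if selected == true_k:
        return "k"
    if selected == true_k + 1:
        return "kp1"
    return "ge_kp2"


def run_trials(
    spec: SyntheticSpec,
    trials: int = 50,
    k_min: int = 2,
    k_max: int = 10,
    distance: str | None = None,
    rule: str = "dri",
) -> TrialTable:
    """Repeatedly draw a family, select k, and tally the outcomes.

    Trial t uses seed ``spec.seed + t`` so every trial is a pure function
    of (base seed, trial index).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    method = distance or FAMILY_DISTANCE[spec.family]
    policy = FAMILY_STANDARDIZE[spec.family]
    counts = {b: 0 for b in TrialTable.BUCKETS}
    selections: list[int | None] = []
    for t in range(trials):
        trial_spec = replace(spec, seed=spec.seed + t)
        table, _truth = generate(trial_spec)
        table = standardize(table, policy)
        curve = dri_curve(
            table,
            DistanceSpec(method=method),
            k_min=k_min,
            k_max=k_max,
            compute_comparators=False,
        )
        sel = select_k(curve, rule=rule)
        selections.append(sel.k)
        counts[_bucket(sel.k, spec.true_k)] += 1
    return TrialTable(
        family=spec.family,
        true_k=spec.true_k,
        trials=trials,
        counts=counts,
        selections=tuple(selections),
    )
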