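"""Synthetic multimorbid cohorts with planted co-occurrence structure.

Administrative chronic-disease registries cannot generally be shared, so
this module generates cohorts with the same statistical shape: one
hundred to two hundred condition categories whose prevalences span a
low (<1%), moderate (1 to <7%) and high (>=7%) spectrum, a cohort
restricted to multimorbid individuals (at least two recorded
conditions), and clustered co-occurrence driven by planted condition
blocks.

The generative model is a latent-block logistic model.  Conditions are
assigned round-robin to ``n_blocks`` blocks.  Each individual activates
each block independently with probability ``block_activation_prob``;
condition ``j`` is then present with probability

    sigmoid( logit(p0_j) + block_effect * 1[block of j active] )

where the base rate ``p0_j`` is calibrated by deterministic 1-D
root-finding so that the *marginal* probability of condition j equals
its requested target.  With ``block_effect = 0`` all conditions are
mutually independent; raising it produces strong within-block pairwise
association while preserving the marginals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.special import expit, logit

from .errors import InvalidConfigError

#: Prevalence band boundaries used throughout: low < 1%, moderate
#: 1 to < 7%, high >= 7% (capped at 30% when sampling targets).
BAND_BOUNDS = {
    "low": (0.001, 0.01),
    "moderate": (0.01, 0.07),
    "high": (0.07, 0.30),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the latent-block cohort generator."""

    n_individuals: int
    n_conditions: int
    n_blocks: int
    block_effect: float
    prevalence_targets: tuple[float, ...]
    block_activation_prob: float
    seed: int
    restrict_multimorbid: bool = True

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise InvalidConfigError("n_individuals must be positive")
        if self.n_conditions < 1:
            raise InvalidConfigError("n_conditions must be positive")
        if not (1 <= self.n_blocks <= self.n_conditions):
            raise InvalidConfigError("need 1 <= n_blocks <= n_conditions")
        if self.block_effect < 0:
            raise InvalidConfigError("block_effect must be nonnegative")
        if len(self.prevalence_targets) != self.n_conditions:
            raise InvalidConfigError(
                "prevalence_targets length must equal n_conditions"
            )
        if not all(0.0 < p < 1.0 for p in self.prevalence_targets):
            raise InvalidConfigError(
                "every prevalence target must lie strictly in (0, 1)"
            )
        if not (0.0 <= self.block_activation_prob <= 1.0):
            raise InvalidConfigError("block_activation_prob must be in [0, 1]")

    @staticmethod
    def from_targets(
        prevalence_targets: Sequence[float],
        *,
        n_individuals: int,
        n_blocks: int,
        block_effect: float,
        block_activation_prob: float,
        seed: int,
        restrict_multimorbid: bool = True,
    ) -> "SyntheticConfig":
        return SyntheticConfig(
            n_individuals=n_individuals,
            n_conditions=len(prevalence_targets),
            n_blocks=n_blocks,
            block_effect=block_effect,
            prevalence_targets=tuple(float(p) for p in prevalence_targets),
            block_activation_prob=block_activation_prob,
            seed=seed,
            restrict_multimorbid=restrict_multimorbid,
        )


@dataclass
class CohortMatrix:
    """Sparse binary person x condition incidence with metadata.

    ``prevalence[j]`` is always the realised column mean of the stored
    incidence (after any multimorbidity restriction), which is the
    quantity banded low/moderate/high downstream.
    """

    incidence: sparse.csr_matrix
    condition_labels: list[str]
    prevalence: np.ndarray
    planted_blocks: np.ndarray | None = None
    _label_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.condition_labels)) != len(self.condition_labels):
            raise InvalidConfigError("condition labels must be unique")
        if self.incidence.shape[1] != len(self.condition_labels):
            raise InvalidConfigError("labels misaligned with incidence columns")
        self._label_index = {c: i for i, c in enumerate(self.condition_labels)}

    @property
    def n_individuals(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.incidence.shape[1]

    def column_index(self, label: str) -> int:
        try:
            return self._label_index[label]
        except KeyError:
            raise KeyError(f"unknown condition label {label!r}") from None

    def column(self, index: int) -> np.ndarray:
        """Dense boolean presence vector for one condition."""
        return np.asarray(self.incidence[:, index].todense()).ravel().astype(bool)

    def prevalence_map(self) -> dict[str, float]:
        return {c: float(p) for c, p in zip(self.condition_labels, self.prevalence)}


def make_prevalence_spectrum(
    n_conditions: int,
    band_mix: tuple[float, float, float],
    seed: int,
) -> list[float]:
    """Draw per-condition target prevalences from a three-band spectrum.

    ``band_mix`` gives the fraction of conditions in the low, moderate
    and high bands; counts are apportioned by largest remainder (ties
    favouring lower bands) and values drawn uniformly within each band's
    boundaries.  The returned order is shuffled.
    """
    if n_conditions < 3:
        raise InvalidConfigError("need at least 3 conditions for a spectrum")
    mix = np.asarray(band_mix, dtype=float)
    if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-9:
        raise InvalidConfigError(
            f"band_mix must be nonnegative and sum to 1, got {band_mix}"
        )
    quota = mix * n_conditions
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    # hand out leftover slots to largest remainders; ties to earlier bands
    for band in sorted(range(3), key=lambda i: (-remainder[i], i))[
        : n_conditions - counts.sum()
    ]:
        counts[band] += 1

    rng = np.random.default_rng(seed)
    values: list[float] = []
    for count, (lo, hi) in zip(counts, BAND_BOUNDS.values()):
        values.extend(rng.uniform(lo, hi, size=count).tolist())
    out = np.array(values)
    rng.shuffle(out)
    return out.tolist()


def mixed_spectrum_config(
    seed: int,
    n_individuals: int = 200_000,
    n_conditions: int = 140,
    band_mix: tuple[float, float, float] = (0.45, 0.35, 0.20),
    n_blocks: int = 10,
    block_effect: float = 3.0,
    block_activation_prob: float = 0.08,
) -> SyntheticConfig:
    """Reference cohort configuration with a full prevalence spectrum.

    Emulates the shape of a population-level chronic-disease registry:
    ~140 condition categories skewed toward rarity (45% low, 35%
    moderate, 20% high prevalence), strong clustered co-occurrence, and
    a cohort large enough that rare condition pairs can clear the
    minimum joint frequency of 15.  The low activation probability
    concentrates co-occurrence within activated blocks, which is what
    lets rare-rare dyads reach support while keeping the marginals on
    target.
    """
    targets = make_prevalence_spectrum(n_conditions, band_mix, seed)
    return SyntheticConfig.from_targets(
        targets,
        n_individuals=n_individuals,
        n_blocks=n_blocks,
        block_effect=block_effect,
        block_activation_prob=block_activation_prob,
        seed=seed,
        restrict_multimorbid=True,
    )


def _calibrate_base_logit(
    target: float, activation: float, effect: float, label: str
) -> float:
    """Base-rate logit giving marginal P(condition) == target.

    Solves (1-q) sigmoid(l) + q sigmoid(l + effect) = target for l,
    where q is the block activation probability.
    """
    if effect == 0.0 or activation == 0.0:
        return float(logit(target))

    def marginal_gap(ell: float) -> float:
        return (
            (1.0 - activation) * expit(ell)
            + activation * expit(ell + effect)
            - target
        )

    lo, hi = -40.0, 40.0
    if marginal_gap(lo) > 0 or marginal_gap(hi) < 0:
        raise InvalidConfigError(
            f"cannot calibrate base rate for condition {label!r}: "
            f"target {target} unreachable with block_effect {effect}"
        )
    return float(optimize.brentq(marginal_gap, lo, hi, xtol=1e-12))


def generate_cohort(config: SyntheticConfig) -> CohortMatrix:
    """Simulate a cohort from the latent-block logistic model.

    Deterministic given the seed: the same config always yields a
    bit-identical incidence matrix.  If ``restrict_multimorbid`` is set,
    individuals with fewer than two conditions are dropped and the
    realised prevalence is recomputed on the remaining rows.
    """
    labels = [f"C{j:03d}" for j in range(config.n_conditions)]
    blocks = np.arange(config.n_conditions) % config.n_blocks

    base_logit = np.array(
        [
            _calibrate_base_logit(
                p, config.block_activation_prob, config.block_effect, labels[j]
            )
            for j, p in enumerate(config.prevalence_targets)
        ]
    )

    rng = np.random.default_rng(config.seed)
    active = rng.random((config.n_individuals, config.n_blocks)) < (
        config.block_activation_prob
    )
    logits = base_logit[None, :] + config.block_effect * active[:, blocks]
    present = rng.random((config.n_individuals, config.n_conditions)) < expit(logits)

    if config.restrict_multimorbid:
        present = present[present.sum(axis=1) >= 2]

    incidence = sparse.csr_matrix(present.astype(np.uint8))
    prevalence = np.asarray(incidence.mean(axis=0)).ravel()
    return CohortMatrix(
        incidence=incidence,
        condition_labels=labels,
        prevalence=prevalence,
        planted_blocks=blocks,
    )


def write_long_format(cohort: CohortMatrix, path: str | Path) -> None:
    """Write one ``person_id,condition`` row per positive cell."""
    coo = cohort.incidence.tocoo()
    cells = sorted(zip(coo.row.tolist(), coo.col.tolist()))
    width = max(6, len(str(max(cohort.n_individuals - 1, 0))))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "condition"])
        for i, j in cells:
            writer.writerow([f"P{i:0{width}d}", cohort.condition_labels[j]])


def write_wide_format(cohort: CohortMatrix, path: str | Path) -> None:
    """Write the binary incidence matrix as CSV with a person_id index."""
    import pandas as pd

    width = max(6, len(str(max(cohort.n_individuals - 1, 0))))
    frame = pd.DataFrame(
        cohort.incidence.toarray(),
        index=[f"P{i:0{width}d}" for i in range(cohort.n_individuals)],
        columns=cohort.condition_labels,
    )
    frame.to_csv(path, index_label="person_id")
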