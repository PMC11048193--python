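"""Sample-level composition reports from per-particle predictions.

Per-particle category predictions for one water sample are summarized into
counts and proportions; the non-algal category (mineral/plastic suspended
particulate matter) can be removed and the remaining phyla renormalized so
their proportions compare directly with microscopy counts.  Species-level
proportions of the algal fraction are labeled *dominant* (> 10% of total
microalgae + cyanobacteria) or *common* (1% to 10%, boundaries inclusive),
and a Pearson correlation utility relates proportions to external bulk
measurements such as chlorophyll-a concentration or cell density.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CompositionResult",
    "DominanceLabel",
    "CorrelationResult",
    "summarize_composition",
    "renormalize_phyla",
    "label_dominance",
    "pearson_r",
    "composition_table",
    "dominance_grid",
]

DOMINANT_THRESHOLD = 0.10  # strictly above -> dominant
COMMON_THRESHOLD = 0.01  # inclusive lower bound of the common band


@dataclass
class CompositionResult:
    """Counts and proportions of particle categories in one sample."""

    sample_id: str
    counts: dict[str, int]
    proportions: dict[str, float]
    n_particles: int

    def __post_init__(self) -> None:
        if self.proportions:
            total = sum(self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions must sum to 1, got {total}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class DominanceLabel:
    species: str
    status: str  # "dominant" | "common" | "neither"
    proportion: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    cov: float
    var_x: float
    var_y: float


def summarize_composition(
    predictions,
    sample_id: str = "sample",
    categories: list[str] | None = None,
) -> CompositionResult:
    """Counts and fractions per category from a sample's predicted labels.

    ``categories`` fixes the category order (and includes zero-count
    categories); by default the sorted set of observed labels is used.
    """
    labels = list(predictions)
    if not labels:
        raise ValueError("empty sample: no predictions to summarize")
    counted = Counter(labels)
    if categories is None:
        categories = sorted(counted)
    unknown = set(counted) - set(categories)
    if unknown:
        raise ValueError(f"predictions outside the category list: {sorted(unknown)}")
    n = len(labels)
    counts = {c: int(counted.get(c, 0)) for c in categories}
    proportions = {c: counts[c] / n for c in categories}
    return CompositionResult(
        sample_id=sample_id, counts=counts, proportions=proportions, n_particles=n
    )


def renormalize_phyla(comp: CompositionResult, drop) -> CompositionResult:
    """Remove categories and rescale the retained proportions to sum to 1.

    Typically used to drop the non-algal suspended-particulate category so
    the three phyla proportions are comparable with microscopy.  Ratios
    among retained categories are preserved; the operation is idempotent.
    """
    drop = set([drop] if isinstance(drop, str) else drop)
    kept = {c: p for c, p in comp.proportions.items() if c not in drop}
    total = sum(kept.values())
    if total <= 0:
        raise ValueError("all retained categories have zero proportion")
    proportions = {c: p / total for c, p in kept.items()}
    counts = {c: comp.counts.get(c, 0) for c in kept}
    return CompositionResult(
        sample_id=comp.sample_id,
        counts=counts,
        proportions=proportions,
        n_particles=sum(counts.values()),
    )


def label_dominance(species_proportions: dict[str, float]) -> list[DominanceLabel]:
    """Classify species of the algal fraction as dominant, common, or neither.

    Proportions are fractions of total microalgae + cyanobacteria.  A
    species is *dominant* when its proportion strictly exceeds 10%, and
    *common* within 1% to 10% inclusive at both boundaries.
    """
    out = []
    for species, p in species_proportions.items():
        if p < 0:
            raise ValueError(f"negative proportion for {species!r}")
        if p > DOMINANT_THRESHOLD:
            status = "dominant"
        elif COMMON_THRESHOLD <= p <= DOMINANT_THRESHOLD:
            status = "common"
        else:
            status = "neither"
        out.append(DominanceLabel(species=species, status=status, proportion=float(p)))
    return out


def pearson_r(x, y) -> CorrelationResult:
    """Pearson correlation r = Cov(x, y) / sqrt(Var(x) Var(y)).

    Population (1/n) covariance and variances; r is invariant to that
    normalization choice.  Requires equal lengths of at least 3 and
    positive variance in both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    dx = x - x.mean()
    dy = y - y.mean()
    var_x = float(np.mean(dx * dx))
    var_y = float(np.mean(dy * dy))
    if var_x == 0 or var_y == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    cov = float(np.mean(dx * dy))
    r = cov / np.sqrt(var_x * var_y)
    return CorrelationResult(r=float(r), n=int(x.size), cov=cov, var_x=var_x, var_y=var_y)


def composition_table(results: list[CompositionResult]) -> pd.DataFrame:
    """Site-by-category proportion table (one row per sample)."""
    categories: list[str] = []
    for res in results:
        for c in res.proportions:
            if c not in categories:
                categories.append(c)
    rows = [
        {"sample_id": res.sample_id,
         **{c: res.proportions.get(c, 0.0) for c in categories},
         "n_particles": res.n_particles}
        for res in results
    ]
    return pd.DataFrame(rows)


def dominance_grid(per_sample: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Species-by-sample grid marking dominant (+++) and common (++) species."""
    samples = list(per_sample)
    species: list[str] = []
    for props in per_sample.values():
        for s in props:
            if s not in species:
                species.append(s)
    marks = {"dominant": "+++", "common": "++", "neither": ""}
    grid = pd.DataFrame("", index=species, columns=samples)
    for sample, props in per_sample.items():
        for lab in label_dominance(props):
            grid.loc[lab.species, sample] = marks[lab.status]
    return grid


def write_composition_report(
    results: list[CompositionResult], path: str | Path
) -> None:
    composition_table(results).to_csv(path, index=False)
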